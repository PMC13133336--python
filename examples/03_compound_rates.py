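"""Compound annual deforestation rates.

Certified documents report forest loss over windows of different lengths;
the compound-rate model F_t = F_0 (1 - r)^t makes them comparable. The
example converts two measurements of the same project to annual rates and
expresses the difference as an avoided-deforestation rate in %/yr.
"""

from datetime import date

import pacteval as pe

# certified window measured in days; remote-sensing window in whole years
window = pe.EvaluationWindow(date(2010, 3, 1), date(2016, 8, 15))
print(f"certified window: {window.t_certified:.2f} yr, remote-sensing window: {window.t_acc} yr")

r_project = pe.compound_rate(f0=9500.0, ft=8700.0, t=window.t_certified)
r_counterfactual = pe.compound_rate(f0=9500.0, ft=7900.0, t=window.t_certified)
print(f"project rate:        {100 * r_project:.3f} %/yr")
print(f"counterfactual rate: {100 * r_counterfactual:.3f} %/yr")
print(f"avoided deforestation: {pe.avoided_rate(r_counterfactual, r_project):.2f} %/yr")

avoided_ha_yr = pe.annualize_avoided(8700.0 - 7900.0, window.t_certified)
print(f"annualised avoided deforestation: {avoided_ha_yr:.1f} ha/yr")
print("\nPositive values mean the counterfactual lost forest faster than the"
      "\nproject — the surplus forest the intervention preserved each year.")
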