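"""Decompose over-crediting into its mechanisms by rate substitution.

Five avoided-deforestation rates per project are built by swapping one
ingredient at a time between the quasi-experimental and certified
assessments. Ratios of median differences attribute the over-crediting gap
to the project forest-cover layer, the reference-area choice, and ex ante
modelling. The second part reproduces the attribution implied by published
combination medians.
"""

import numpy as np
import pandas as pd

import pacteval as pe

rng = np.random.default_rng(8)
n = 17
r_project_acc = rng.uniform(0.001, 0.006, n)
rates = pd.DataFrame({
    "project_id": [f"P{i:02d}" for i in range(n)],
    "r_project_acc": r_project_acc,
    "r_project_cert": r_project_acc * rng.uniform(0.4, 0.9, n),  # bespoke layers see less loss
    "r_control_acc": r_project_acc + rng.uniform(0.0005, 0.004, n),
    "r_reference_acc": r_project_acc + rng.uniform(0.004, 0.009, n),  # biased siting
    "r_baseline_cert": r_project_acc + rng.uniform(0.007, 0.013, n),  # ex ante inflation
})

ledger = pe.build_ledger(rates)
print(f"correction coefficient k = {ledger.attrs['k']:.2f} "
      "(median certified/ACC project-rate ratio)")
print(pe.ledger_summary(ledger).round(2).to_string(index=False))
shares = pe.attribute_from_ledger(ledger)
print(f"reference-area share: {shares.share_reference_area:.0f}%  "
      f"ex ante share: {shares.share_ex_ante:.0f}%  "
      f"project-layer share: {shares.share_project_layer:.0f}%\n")

print("published combination medians (0.18, 0.20, 0.64, 0.35, 0.95 %/yr):")
pub = pe.attribute(0.18, 0.20, 0.64, 0.35, 0.95)
print(f"reference-area share: {pub.share_reference_area:.1f}%  "
      f"ex ante share: {pub.share_ex_ante:.1f}%  "
      f"project-layer share: {pub.share_project_layer:.1f}%")
print("\nMost of the gap between certified and independent estimates traces to"
      "\nreference-area selection and ex ante modelling, not to the choice of"
      "\nforest-cover product.")
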