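"""Simulate a development cohort with known ground truth.

The default recipe mirrors a small rare-disease instrument-development
study: 69 respondents, 56 items (29 clean items in four correlated
symptom/well-being domains, 3 clean standalone items, and 24 planted
defects), plus an FEV1%-like severity covariate tied to the dyspnea and
fatigue traits.
"""

import numpy as np

import promkit as pk
from promkit.pipeline import cohort_summary

spec = pk.default_cohort_spec(seed=7)
matrix, truth = pk.generate_cohort(spec)

print(f"cohort: {matrix.n} respondents x {len(spec.items)} items")
print(f"missing cells: {int(matrix.responses.isna().sum().sum())}")
print()
print(cohort_summary(matrix).to_string(index=False))
print()
counts = {}
for item, defect in truth.defect_labels.items():
    counts[defect] = counts.get(defect, 0) + 1
print("planted item classes:", counts)
print()
print("Severity is on a percent-predicted-FEV1-like scale; 'ever' oxygen "
      "use marks the more severe patients, so oxygen users should score "
      "higher (worse) on dyspnea-linked scales downstream.")
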