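"""Score the final scales and run the validity analyses.

Summation scoring with mean imputation (at least half the scale answered),
Cronbach's alpha and floor/ceiling rates per scale, then validity:
correlations with the severity covariate (within the spirometry window),
severity-tertile contrasts, and oxygen-use group comparisons with effect
sizes in standard-deviation units (SDU).
"""

import promkit as pk

spec = pk.default_cohort_spec(n_respondents=500, seed=7)
matrix, _ = pk.generate_cohort(spec)
instrument = spec.instrument()
config = pk.default_analysis_config(seed=7)

report = pk.run_deletion_algorithm(matrix, instrument, config)
survivors = instrument.subset(report.retained_ids())

rel = pk.reliability_report(matrix, survivors, config)
print("reliability and score profile:")
print(rel.round(2).to_string(index=False))
print()

val = pk.validity_report(matrix, survivors, config)
print("correlations with severity (FEV1%-like), window-restricted:")
print(val["external"].round(3).to_string(index=False))
print()
print("oxygen-use group comparison (difference in SD units):")
for scale, grp in val["oxygen"].items():
    print(f"  {scale:>18}: ever {grp.mean[0]:6.1f} vs never {grp.mean[1]:6.1f}"
          f"  SDU {grp.sdu:+.2f}  p {grp.p:.2g}")
print()
print("Expected pattern: dyspnea/fatigue/total correlate strongly and "
      "negatively with severity and separate the oxygen groups by ~1 SD; "
      "cough is unlinked to severity by design, so its correlation is near "
      "zero and its group effect stays small (though at n=500 even a small "
      "residual effect can reach nominal significance).")
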