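"""Multitrait scaling of the deletion-stage survivors.

Each surviving domain item is correlated with every domain score (its own
score excluding itself).  Off-diagonal cells are classified with the
correlated-correlations z-test: 'success' means the item correlates
significantly more strongly with its own domain than the competitor.
Items with 'failure' cells get rescaling proposals.
"""

import promkit as pk

spec = pk.default_cohort_spec(n_respondents=500, seed=7)
matrix, _ = pk.generate_cohort(spec)
instrument = spec.instrument()
config = pk.default_analysis_config(seed=7)

report = pk.run_deletion_algorithm(matrix, instrument, config)
survivors = instrument.subset(report.retained_ids())

scaling = pk.classify_cells(
    pk.item_domain_matrix(matrix.subset_items(survivors.item_ids), survivors,
                          config=config), config)

counts = scaling.summary_counts()
total = sum(counts.values())
print(f"{total} off-diagonal comparisons "
      f"({len(scaling.items)} items x {len(scaling.domains) - 1} competitors):")
for cls, c in counts.items():
    print(f"  {cls:>15}: {c}")
print()
print("correlation matrix (rows = items, columns = domains):")
print(scaling.r.round(2).head(8).to_string())
print()
proposals = pk.propose_rescaling(scaling)
print(f"rescaling proposals: {len(proposals)} "
      "(a clean, correctly hypothesized instrument should yield none)")
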