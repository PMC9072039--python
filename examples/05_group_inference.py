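"""Covariate-adjusted group comparison and blind-duration correlations.

Each metric is regressed on group (case=1), age and sex; the group
coefficient's t is reported with Bonferroni correction.  Within cases,
significant metrics are partially correlated with months of blindness.
"""

import numpy as np

import structconn as sc

cohort, truth = sc.generate_cohort(sc.SyntheticParams(seed=7))
phenos = cohort.phenotypes

ne_rows, density = [], []
for m in cohort.matrices:
    w = sc.apply_fiber_threshold(m).weights
    ne_rows.append(sc.nodal_efficiency(w))
    density.append(sc.network_density(w))

res = sc.fit_group_model(density, phenos, metric="density")
print(f"density: t={res.t:+.2f}, p={res.p:.2g}  "
      "(negative t = lower density in cases)")

nodal = sc.run_nodal_comparison(cohort, np.stack(ne_rows), metric="Ne")
sig = nodal[nodal["significant"]]
print(f"\nNe: {len(sig)} / 90 nodes significant after Bonferroni "
      f"(threshold p < {0.05 / 90:.2e})")
hit = sig["node"].isin(truth.affected_nodes).sum()
print(f"   {hit} of them are seeded regions")

cases = [p for p in phenos if p.is_case]
dur = np.array([p.blind_duration for p in cases])
cov = np.column_stack(
    [[p.age for p in cases], [1.0 if p.sex == "M" else 0.0 for p in cases]]
)
NE = np.stack(ne_rows)[[i for i, p in enumerate(phenos) if p.is_case]]
j = truth.affected_nodes[0]
pc = sc.partial_correlation(NE[:, j], dur, cov)
print(f"\n{cohort.atlas.abbreviations[j]} Ne vs blind duration: "
      f"r={pc.r:+.2f} (df={pc.df}), p={pc.p:.3g}  "
      "(negative: efficiency declines with longer blindness)")
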