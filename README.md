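# structconn

Group analysis of white-matter structural connectivity networks built from
diffusion tractography, for researchers comparing a patient cohort against
matched controls — the motivating application is early-blind adolescents vs.
sighted peers, but nothing in the package is specific to that contrast.

The input is one symmetric 90×90 matrix per subject on the AAL cortical +
subcortical parcellation, whose entry (i, j) is the streamline ("fiber
number", FN) count between regions i and j. From there the package covers:

- **Edge detection** — a connection exists only when FN > 3 (strict), the
  usual guard against spurious deterministic-tractography streamlines.
- **Weighted graph metrics** — with edge length `l_ij = 1/w_ij`:
  density, global efficiency `Eg = ⟨Ne⟩` where
  `Ne(i) = (N−1)⁻¹ Σ_{j≠i} 1/d_ij`, local efficiency `Eloc` (mean
  neighbor-subgraph efficiency), Onnela weighted clustering `Cp`,
  characteristic path length `Lp` (reachable-pairs mean), and nodal
  degree `Nd`.
- **Small-world indices** — `γ = Cp/⟨Cp_null⟩`, `λ = Lp/⟨Lp_null⟩`,
  `σ = γ/λ`, normalized against Maslov–Sneppen degree-preserving null
  networks with the weight multiset permuted onto the rewired topology.
- **Hubs** — the top 15% of regions (13 of 90) by cohort-mean nodal degree,
  with set comparison between cohorts.
- **Inference** — per-metric OLS `y ~ group + age + sex` (case = 1, M = 1)
  with Bonferroni correction (family of 8 global metrics; 90 nodes per
  nodal family), pooled two-sample t and Pearson chi-square demographics,
  and age/sex-adjusted partial correlations with months of blindness
  within cases.
- **Synthetic cohorts** — a seeded generator producing small-world
  FN-weighted networks with known group/duration effects, used to validate
  the whole pipeline end to end.

## Worked example

```python
import structconn as sc
from structconn.nullmodels import NullEnsembleParams

cohort, truth = sc.generate_cohort(sc.SyntheticParams(seed=7))
m = sc.apply_fiber_threshold(cohort.matrices[0])   # FN > 3

glob, nodal = sc.compute_all_metrics(m)
sw = sc.normalized_small_world(m, NullEnsembleParams(n_null=50, seed=1))
print(glob.density, glob.eg, sw.gamma, sw.lambda_, sw.sigma)
```

prints (subject `case-01`):

```
density = 0.199   Eg = 18.88   Eloc = 20.96
gamma = 2.74   lambda = 1.11   sigma = 2.46
```

i.e. a network at 20% density whose clustering is ~2.7× its
degree-matched random references while path length is near random —
a small-world organization (σ > 1). Running the whole pipeline,

```sh
structconn all --synthetic --out results_demo --seed 7 --n-null 20
```

reports lower density (t = −7.16), Eg (t = −6.86) and Eloc (t = −7.21) in
cases, 22 of 90 regions with significantly reduced nodal efficiency — the
15 seeded default-mode/visual/limbic regions plus their immediate
neighbors — and negative duration correlations such as left posterior
cingulate Ne: r = −0.51 (df = 17). Negative t means the metric is lower
in cases after adjusting for age and sex.

The same stages are runnable in isolation (`structconn simulate | metrics |
compare | hubs | correlate`) on intermediate CSVs, and `examples/` contains
one short narrative script per capability.

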