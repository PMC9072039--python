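# Methods

## Data model

A subject's structural connectome is a symmetric, zero-diagonal, integer
matrix `W` on an ordered region atlas; `W[i, j]` is the streamline (FN)
count linking regions i and j. The bundled atlas is the 90-region AAL
parcellation, 45 regions per hemisphere, with each region tagged by the
functional system used in reports (posterior cingulate and precuneus →
default-mode; calcarine, cuneus, lingual, superior/inferior occipital and
fusiform → visual; parahippocampal → limbic; everything else → other).
Matrix size is parameterized by atlas length so unit tests and scaled
simulations can run on small atlases; node order is fixed by the atlas
and all indices are 0-based internally, with region abbreviations as the
public labels.

Edge detection keeps an entry only when FN strictly exceeds `min_fn`
(default 3, so an edge needs ≥ 4 streamlines). The strict reading is
deliberate; an inclusive rule is available by passing `min_fn=2`. The
threshold is applied per subject, with no group-level mask.

## Graph metrics

Toolbox conventions for weighted connectomes are followed throughout:

- **Edge length** `l = 1/w`: stronger connections are shorter. Raw FN
  weights are used (no global rescaling) — the normalized indices γ/λ/σ
  are scale-free ratios and group contrasts compare like with like.
- **Distances** are all-pairs weighted shortest paths (Dijkstra via
  `scipy.sparse.csgraph`); unreachable pairs are infinite.
- **Efficiencies**: `Ne(i) = (N−1)⁻¹ Σ_{j≠i} 1/d_ij` with unreachable
  pairs contributing 0; `Eg` is the node mean of Ne (an identity asserted
  to 1e-12 in tests). `Eloc` averages, over nodes, the global efficiency
  of the subgraph induced on each node's neighbors, keeping the original
  weights (no re-normalization inside the subgraph); nodes with fewer
  than two neighbors contribute 0.
- **Path lengths**: `NLp(i)` is the mean distance from i to the nodes it
  can reach (undefined for isolated nodes, reported as NaN); `Lp`
  averages over all reachable pairs. Disconnected pairs are *excluded*
  rather than imputed, and every output carries an explicit
  connectedness flag, so the averaging scope is never silent. A harmonic
  variant of Lp is exposed (`lp_mode="harmonic"`) because toolboxes
  differ here; the arithmetic reachable-pairs mean is the default.
- **Clustering**: Onnela geometric-triangle form with weights rescaled by
  the network maximum; zero for degree < 2. Cross-checked against
  networkx's weighted clustering in the test suite.
- **Degree**: binary neighbor count by default; weighted (FN sum) as an
  option. Hub ranking, where the choice matters most, defaults to binary
  because streamline-count sums are dominated by a few massive bundles
  and the binary count better matches the "most connections" reading.

## Null models and small-worldness

γ and λ normalize Cp and Lp by their means over an ensemble of random
reference networks. The reference preserves exactly what the convention
requires and nothing more: Maslov–Sneppen double-edge swaps randomize
the binary topology while conserving each node's degree (attempted swaps
= 10 × edge count), after which the original multiset of FN weights is
randomly permuted onto the rewired edges. Degenerate topologies with no
legal swap (e.g. a triangle) return a weight-permuted copy with a warning
flag rather than failing. The ensemble default is 100 networks per
subject; normalization is per subject, each with a seed derived from the
run seed plus the subject index and recorded in the run manifest, so any
subject is reproducible in isolation. Strength-preserving weighted
rewiring and lattice nulls are out of scope.

## Hubs

Regions are ranked by the mean nodal degree across a cohort's subjects;
hubs are the top `floor(0.15 · N)` — 13 of 90 (the floor rule is forced by
that pair of numbers). Ties at the cutoff are broken by atlas index,
deterministically, and flagged in the output.

## Inference

Group contrasts use OLS `y ~ 1 + group + age + sex` with case = 1 and
M = 1 (codings recorded in the manifest since coefficient signs depend on
them), reporting the group coefficient's t and two-sided p. The solver is
a closed-form normal-equations fit shared across response columns, so the
90-node families cost one factorization; a test pins its t and p to
statsmodels OLS to 1e-10. Bonferroni families are the natural ones — 8
global metrics, 90 nodes per nodal metric — and the family size is
recorded in every output row. Nodes with undefined NLp in some subjects
are compared on the remaining subjects, with the exclusion count
reported, rather than imputed. Partial correlations residualize both
variables on [1, age, sex] and correlate the residuals, with
`df = n − 2 − k` and p from the t transform (cross-checked against
pingouin and against numeric integration of the t density). Demographic
tests are the pooled-variance two-sample t (accepting mean/sd/n summaries,
so printed tables can be re-tested) and the Pearson chi-square without
continuity correction — the uncorrected statistic is what reproduces the
published sex-table value of 0.617 from 13/8 vs 11/11.

## Synthetic cohorts

No subject-level connectivity data are available for the motivating
study, so validation runs on generated cohorts whose defaults mirror its
conditions: 21 cases (13 M/8 F) and 22 controls (11 M/11 F), ages uniform
on 11–19 years, case durations ~ Normal(177.48, 24.68²) months truncated
positive, 90 nodes at 20% density.

Both groups share one Watts–Strogatz template (ring lattice at the
nearest even degree — k = 18 at the defaults — rewired with probability
0.1, then trimmed/padded by random edges to hit the requested edge count
exactly). Subjects toggle 2% of edges for inter-subject variability.
Edge weights are `4 + NegBin(r = 2, mean 26)` — overdispersed positive
counts typical of streamline tallies, shifted so every generated edge
survives the FN > 3 threshold unless an effect pushes it below. The
weight law is an invention of the generator; no FN distribution is
published, and the dispersion and mean are configurable.

Case subjects' weights on edges incident to the affected regions (default:
the 15 default-mode/visual/limbic regions listed above) are multiplied by
`(1 − g)(1 + δ · z(duration))` and rounded, with `g = 0.3` and `δ = −0.15`
per SD of duration. Multiplicative effects were chosen over additive ones
so near-threshold edges get deleted, reproducing a density reduction and
not just a weight reduction. δ = −0.15 makes affected-node efficiency
decline by roughly a third of its group deficit across the observed
duration range, yielding within-case correlations of the magnitude
(|r| ≈ 0.5) typical of such cohorts. Duration is sampled independently of
age within cases; in real cohorts of early-onset blindness the two are
strongly coupled, and that coupling (a stressor for covariate adjustment)
is not modeled.

What passing tests therefore show: the pipeline recovers the seeded
qualitative pattern — negative group t for density/Eg/Eloc, significant
nodal-efficiency reductions concentrated in affected regions, negative
duration correlations there — and controls the family-wise false-positive
rate on null cohorts. What they do not show: robustness to tractography
artifacts, registration error, geometric embedding of real anatomy, or
age-duration confounding, none of which the generator emulates.

## Numerical and scale choices

- Monte-Carlo sizes: type-I control uses 500 null cohorts on 20-node
  atlases (the statistic is per-family, so node count only affects power
  of the check, and 20 nodes keeps the 500-replicate run to seconds);
  effect recovery uses 100 full 90-node cohorts; the small-world check
  uses 20 subjects × 100 nulls.
- Integrality of parsed matrices is accepted within 1e-9; symmetry must
  be exact for integers.
- All result CSVs have fixed column order and `%.10g` float formatting,
  and the run manifest records parameters, per-subject seeds, warnings
  and output checksums — a rerun with the same config is byte-identical.
- Per-subject seeds are derived via `SeedSequence([run_seed, index])` and
  kept below 2³¹.

## Known limitations

- Betweenness, modularity, rich-club and other metrics outside the eight
  global / four nodal set are not implemented.
- Only Bonferroni correction is provided (no FDR or permutation tests),
  matching the analysis this pipeline operationalizes.
- The connectedness handling (exclude-and-flag) biases Lp downward in
  fragmented networks relative to conventions that penalize
  disconnection; at the default density fragmentation is rare.
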