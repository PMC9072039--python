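"""Synthetic two-group cohorts of FN-weighted connectomes.

No subject-level connectivity data accompany the study this pipeline is
designed for, so the generator emulates the statistical structure the
analysis assumes and records the ground truth needed for recovery tests:

* sparse symmetric integer-weighted networks on a shared Watts–Strogatz
  small-world template (so every cohort shows gamma > 1, lambda ~ 1);
* overdispersed positive streamline counts: each edge weight is drawn as
  ``4 + NegativeBinomial`` so generated edges survive the FN > 3 edge
  threshold unless a seeded effect pushes them below it;
* a multiplicative case-group weight reduction on edges incident to a
  configurable set of affected regions (default: the default-mode, visual
  and limbic regions reported as altered), which both lowers efficiency
  and deletes near-threshold edges, reducing density;
* a multiplicative blind-duration slope on the same edges, producing a
  negative association between affected-node efficiency and duration
  within cases;
* demographics matched to the study cohort: 21 cases (13 M / 8 F) vs 22
  controls (11 M / 11 F), ages uniform on 11-19 years, case durations
  normal with mean 177.48 and SD 24.68 months (truncated positive).

Everything is reproducible from a single integer seed; each subject gets
a recorded derived seed so subjects can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .atlas import AtlasEntry, NodeAtlas, default_atlas
from .io import CohortDataset, ConnectivityMatrix, Phenotype

__all__ = [
    "SyntheticParams",
    "SyntheticGroundTruth",
    "DEFAULT_AFFECTED_REGIONS",
    "generate_base_topology",
    "generate_subject",
    "generate_cohort",
]

# Regions reported with significant nodal group differences (both nodal
# efficiency and nodal path length families), by atlas abbreviation.
DEFAULT_AFFECTED_REGIONS: tuple[str, ...] = (
    "PCG.L", "PCG.R", "PCUN.L", "PCUN.R",          # default-mode
    "CAL.L", "CAL.R", "CUN.L", "CUN.R",            # visual
    "LING.L", "LING.R", "SOG.L", "SOG.R",
    "IOG.L", "FG.R",
    "PHG.L",                                       # limbic
)


@dataclass
class SyntheticParams:
    """Cohort-generator settings; defaults reproduce the study conditions."""

    n_case: int = 21
    n_control: int = 22
    n_nodes: int = 90
    base_density: float = 0.20
    smallworld_rewire_prob: float = 0.1
    weight_mean: float = 30.0        # mean FN count per retained edge
    weight_dispersion: float = 2.0   # negative-binomial shape (smaller = more dispersed)
    group_effect: float = 0.3        # multiplicative weight reduction in cases
    affected_nodes: tuple[str, ...] | None = None  # None -> default region set
    duration_effect: float = -0.15   # per-SD-of-duration multiplicative slope
    jitter_fraction: float = 0.02    # per-subject edge toggling
    age_range: tuple[float, float] = (11.0, 19.0)
    sex_ratio_case: float = 13 / 21
    sex_ratio_control: float = 11 / 22
    duration_mean: float = 177.48    # months
    duration_sd: float = 24.68
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.base_density <= 1:
            raise ValueError("base_density must be in (0, 1]")
        if min(self.n_case, self.n_control) < 3:
            raise ValueError("need at least 3 subjects per group")
        if not 0 <= self.group_effect < 1:
            raise ValueError("group_effect must be in [0, 1)")
        if self.duration_effect > 0:
            raise ValueError("duration_effect must be <= 0")
        if self.weight_mean <= 4:
            raise ValueError("weight_mean must exceed the FN threshold shift of 4")


@dataclass
class SyntheticGroundTruth:
    """What was seeded, for effect-recovery checks."""

    affected_nodes: tuple[int, ...]
    affected_abbreviations: tuple[str, ...]
    group_effect: float
    duration_effect: float
    durations: dict[str, float]
    subject_seeds: dict[str, int]
    template_k: int
    template_n_edges: int
    seed: int


def _even_k(n_nodes: int, density: float) -> int:
    """Nearest even ring-lattice degree for the requested density."""
    k = round(density * (n_nodes - 1) / 2) * 2
    return max(2, min(k, n_nodes - 1 - (n_nodes % 2 == 0)))


def generate_base_topology(
    n_nodes: int,
    density: float,
    rewire_prob: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Watts–Strogatz small-world binary adjacency at the requested density.

    A ring lattice of (even) degree k nearest the target density is built
    and each edge rewired with probability ``rewire_prob``; the edge count
    is then adjusted by random additions/deletions to match the requested
    density exactly (the even-k constraint alone can miss it by a few
    edges).
    """
    target_edges = round(density * n_nodes * (n_nodes - 1) / 2)
    k = _even_k(n_nodes, density)
    g = nx.watts_strogatz_graph(n_nodes, k, rewire_prob, seed=rng)
    adj = np.zeros((n_nodes, n_nodes), dtype=bool)
    for a, b in g.edges():
        adj[a, b] = adj[b, a] = True
    iu, ju = np.nonzero(np.triu(adj, k=1))
    n_edges = iu.size
    if n_edges > target_edges:
        drop = rng.choice(n_edges, size=n_edges - target_edges, replace=False)
        adj[iu[drop], ju[drop]] = adj[ju[drop], iu[drop]] = False
    elif n_edges < target_edges:
        free = np.argwhere(np.triu(~adj, k=1))
        add = rng.choice(len(free), size=target_edges - n_edges, replace=False)
        for a, b in free[add]:
            adj[a, b] = adj[b, a] = True
    np.fill_diagonal(adj, False)
    return adj


def _draw_weights(
    n: int, mean: float, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Shifted negative-binomial streamline counts: 4 + NB(r, p), mean = `mean`."""
    mu = mean - 4.0
    r = dispersion
    p = r / (r + mu)
    return 4 + rng.negative_binomial(r, p, size=n)


def generate_subject(
    template: np.ndarray,
    phenotype: Phenotype,
    params: SyntheticParams,
    affected: np.ndarray,
    seed: int,
) -> ConnectivityMatrix:
    """One subject's matrix from the cohort template.

    Subject-level variability: a fraction of template edges is toggled
    (removed, with an equal number of random non-edges added) before
    weights are drawn.  For case subjects, weights on edges incident to an
    affected node are multiplied by
    ``(1 - group_effect) * (1 + duration_effect * z(duration))`` and
    rounded; weights pushed to 3 or below will be removed by the FN
    threshold downstream.
    """
    rng = np.random.default_rng(seed)
    n = template.shape[0]
    adj = template.copy()
    iu, ju = np.nonzero(np.triu(adj, k=1))
    n_toggle = round(params.jitter_fraction * iu.size)
    if n_toggle:
        drop = rng.choice(iu.size, size=n_toggle, replace=False)
        adj[iu[drop], ju[drop]] = adj[ju[drop], iu[drop]] = False
        free = np.argwhere(np.triu(~adj, k=1))
        add = rng.choice(len(free), size=n_toggle, replace=False)
        for a, b in free[add]:
            adj[a, b] = adj[b, a] = True
        np.fill_diagonal(adj, False)

    iu, ju = np.nonzero(np.triu(adj, k=1))
    w = _draw_weights(iu.size, params.weight_mean, params.weight_dispersion, rng)
    w = w.astype(float)
    if phenotype.is_case and (params.group_effect > 0 or params.duration_effect != 0):
        z = (phenotype.blind_duration - params.duration_mean) / params.duration_sd
        factor = (1.0 - params.group_effect) * (1.0 + params.duration_effect * z)
        factor = max(factor, 0.0)
        hit = affected[iu] | affected[ju]
        w[hit] = np.round(w[hit] * factor)
    weights = np.zeros((n, n), dtype=np.int64)
    w = np.maximum(np.round(w), 0).astype(np.int64)
    weights[iu, ju] = w
    weights[ju, iu] = w
    return ConnectivityMatrix(subject_id=phenotype.subject_id, weights=weights)


def _default_affected(atlas: NodeAtlas, params: SyntheticParams) -> list[int]:
    if params.affected_nodes is not None:
        return atlas.indices_of(params.affected_nodes)
    if params.n_nodes == 90:
        return atlas.indices_of(DEFAULT_AFFECTED_REGIONS)
    # scaled-down atlases: seed the same fraction of nodes (15/90) from the top
    n_aff = max(1, round(params.n_nodes * len(DEFAULT_AFFECTED_REGIONS) / 90))
    return list(range(n_aff))


def _synthetic_atlas(n_nodes: int) -> NodeAtlas:
    """Generic atlas for scaled-down simulations (hemispheres alternate)."""
    return NodeAtlas(
        AtlasEntry(
            index=i,
            name=f"Synthetic region {i + 1}",
            abbreviation=f"R{i + 1:02d}.{'L' if i % 2 == 0 else 'R'}",
            hemisphere="L" if i % 2 == 0 else "R",
            system="other",
        )
        for i in range(n_nodes)
    )


def _sample_phenotypes(
    params: SyntheticParams, rng: np.random.Generator
) -> list[Phenotype]:
    phenos = []
    for group, n, ratio, prefix in (
        ("case", params.n_case, params.sex_ratio_case, "case"),
        ("control", params.n_control, params.sex_ratio_control, "control"),
    ):
        n_male = round(ratio * n)
        sexes = np.array(["M"] * n_male + ["F"] * (n - n_male))
        rng.shuffle(sexes)
        lo, hi = params.age_range
        ages = rng.uniform(lo, hi, size=n)
        for i in range(n):
            dur = None
            if group == "case":
                dur = float(rng.normal(params.duration_mean, params.duration_sd))
                while dur <= 0:  # truncate to positive durations
                    dur = float(rng.normal(params.duration_mean, params.duration_sd))
            phenos.append(
                Phenotype(
                    subject_id=f"{prefix}-{i + 1:02d}",
                    group=group,
                    age=float(ages[i]),
                    sex=str(sexes[i]),
                    blind_duration=dur,
                )
            )
    return phenos


def generate_cohort(
    params: SyntheticParams | None = None,
) -> tuple[CohortDataset, SyntheticGroundTruth]:
    """Sample a full two-group cohort plus its seeded ground truth.

    Both groups share one small-world topology template; group and
    duration effects enter only through the seeded weight reductions, so
    with ``group_effect=0`` and ``duration_effect=0`` the two groups are
    exchangeable.
    """
    params = params or SyntheticParams()
    atlas = default_atlas() if params.n_nodes == 90 else _synthetic_atlas(params.n_nodes)
    rng = np.random.default_rng(params.seed)
    template = generate_base_topology(
        params.n_nodes, params.base_density, params.smallworld_rewire_prob, rng
    )
    affected_idx = _default_affected(atlas, params)
    affected = np.zeros(params.n_nodes, dtype=bool)
    affected[affected_idx] = True

    phenos = _sample_phenotypes(params, rng)
    # per-subject derived seeds, recorded for independent regeneration
    states = np.random.SeedSequence(params.seed).generate_state(len(phenos) + 1)
    subject_seeds = {
        p.subject_id: int(states[i + 1] % (2**31)) for i, p in enumerate(phenos)
    }
    matrices = [
        generate_subject(template, p, params, affected, subject_seeds[p.subject_id])
        for p in phenos
    ]
    cohort = CohortDataset(atlas=atlas, matrices=matrices, phenotypes=phenos)
    truth = SyntheticGroundTruth(
        affected_nodes=tuple(affected_idx),
        affected_abbreviations=tuple(atlas.abbreviations[i] for i in affected_idx),
        group_effect=params.group_effect,
        duration_effect=params.duration_effect,
        durations={
            p.subject_id: p.blind_duration for p in phenos if p.is_case
        },
        subject_seeds=subject_seeds,
        template_k=_even_k(params.n_nodes, params.base_density),
        template_n_edges=int(np.count_nonzero(np.triu(template, k=1))),
        seed=params.seed,
    )
    return cohort, truth
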