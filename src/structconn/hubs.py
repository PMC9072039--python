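"""Hub identification by cohort-mean nodal degree.

A hub is a region in the top 15% of regions ranked by the mean nodal
degree across a cohort's subjects (top floor(0.15*N) nodes; 13 of 90).
Ties at the cutoff are broken by atlas index (ascending) and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CohortDataset
from .metrics import nodal_degree

__all__ = ["HubReport", "mean_degree_ranking", "select_hubs", "compare_hub_sets"]

DEFAULT_HUB_FRACTION = 0.15


@dataclass
class HubReport:
    """Ranking table plus the selected hub set for one cohort."""

    cohort: str
    ranking: pd.DataFrame  # columns: node, abbreviation, mean_degree, rank, tied
    hubs: frozenset[int]
    atlas_abbreviations: tuple[str, ...]

    def hub_abbreviations(self) -> list[str]:
        return [self.atlas_abbreviations[i] for i in sorted(self.hubs)]

    def as_frame(self) -> pd.DataFrame:
        df = self.ranking.copy()
        df.insert(0, "cohort", self.cohort)
        df["is_hub"] = df["node"].isin(self.hubs)
        return df


def mean_degree_ranking(
    cohort: CohortDataset,
    group: str,
    mode: str = "binary",
) -> pd.DataFrame:
    """Rank nodes by mean nodal degree over a group's subjects, descending.

    Ties are ordered by atlas index and marked in a ``tied`` column (a node
    is tied when it shares its mean degree with a neighbor in the ranking).
    """
    mats = [
        m
        for m, p in zip(cohort.matrices, cohort.phenotypes)
        if p.group == group
    ]
    if not mats:
        raise ValueError(f"no subjects in group {group!r}")
    degs = np.stack([nodal_degree(m, mode=mode) for m in mats])
    mean_deg = degs.mean(axis=0)
    order = np.lexsort((np.arange(len(mean_deg)), -mean_deg))
    df = pd.DataFrame(
        {
            "node": order,
            "abbreviation": [cohort.atlas.abbreviations[i] for i in order],
            "mean_degree": mean_deg[order],
        }
    )
    df["rank"] = np.arange(1, len(df) + 1)
    vals = df["mean_degree"].to_numpy()
    tied = np.zeros(len(vals), dtype=bool)
    tied[:-1] |= vals[:-1] == vals[1:]
    tied[1:] |= vals[1:] == vals[:-1]
    df["tied"] = tied
    return df


def select_hubs(
    ranking: pd.DataFrame, fraction: float = DEFAULT_HUB_FRACTION
) -> frozenset[int]:
    """Top ``floor(fraction * N)`` nodes of a degree ranking (13 for N=90)."""
    if not 0 < fraction <= 1:
        raise ValueError(f"hub fraction must be in (0, 1], got {fraction}")
    if ranking.empty:
        raise ValueError("ranking is empty")
    n_hubs = int(np.floor(fraction * len(ranking)))
    return frozenset(int(i) for i in ranking["node"].iloc[:n_hubs])


def hub_report(
    cohort: CohortDataset,
    group: str,
    mode: str = "binary",
    fraction: float = DEFAULT_HUB_FRACTION,
) -> HubReport:
    """Ranking + hub selection for one group of a cohort."""
    ranking = mean_degree_ranking(cohort, group, mode=mode)
    return HubReport(
        cohort=group,
        ranking=ranking,
        hubs=select_hubs(ranking, fraction=fraction),
        atlas_abbreviations=tuple(cohort.atlas.abbreviations),
    )


def compare_hub_sets(
    a: HubReport, b: HubReport
) -> tuple[list[str], list[str], list[str]]:
    """Shared hubs and cohort-unique hubs, as region abbreviations."""
    if a.atlas_abbreviations != b.atlas_abbreviations:
        raise ValueError("hub reports use different atlases")
    abbr = a.atlas_abbreviations
    shared = sorted(abbr[i] for i in a.hubs & b.hubs)
    only_a = sorted(abbr[i] for i in a.hubs - b.hubs)
    only_b = sorted(abbr[i] for i in b.hubs - a.hubs)
    return shared, only_a, only_b
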