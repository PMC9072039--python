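import numpy as np
import pytest

from structconn import CohortDataset, ConnectivityMatrix, Phenotype
from structconn.atlas import AtlasEntry, NodeAtlas


def random_symmetric_weights(
    rng: np.random.Generator, n: int, p_edge: float = 0.5, max_w: int = 10
) -> np.ndarray:
    """Random symmetric nonnegative-integer matrix with zero diagonal."""
    upper = np.triu(
        (rng.random((n, n)) < p_edge) * rng.integers(1, max_w + 1, (n, n)), k=1
    )
    return (upper + upper.T).astype(np.int64)


def tiny_atlas(n: int) -> NodeAtlas:
    return NodeAtlas(
        AtlasEntry(
            index=i,
            name=f"Region {i}",
            abbreviation=f"N{i:02d}.{'L' if i % 2 == 0 else 'R'}",
            hemisphere="L" if i % 2 == 0 else "R",
            system="other",
        )
        for i in range(n)
    )


def make_cohort(
    rng: np.random.Generator,
    n_nodes: int = 6,
    n_case: int = 4,
    n_control: int = 4,
    p_edge: float = 0.6,
    min_group_size: int = 3,
) -> CohortDataset:
    atlas = tiny_atlas(n_nodes)
    matrices, phenotypes = [], []
    for g, n in (("case", n_case), ("control", n_control)):
        for i in range(n):
            sid = f"{g}-{i}"
            matrices.append(
                ConnectivityMatrix(
                    sid, random_symmetric_weights(rng, n_nodes, p_edge=p_edge)
                )
            )
            phenotypes.append(
                Phenotype(
                    sid,
                    g,
                    age=float(rng.uniform(11, 19)),
                    sex="M" if rng.random() < 0.5 else "F",
                    blind_duration=float(rng.uniform(120, 220)) if g == "case" else None,
                )
            )
    return CohortDataset(atlas=atlas, matrices=matrices, phenotypes=phenotypes, min_group_size=min_group_size)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
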