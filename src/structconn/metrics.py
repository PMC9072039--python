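"""Weighted graph-theoretic metrics of FN-weighted structural networks.

Conventions (the standard weighted formulations for streamline-count
connectomes):

* edge length: ``l_ij = 1 / w_ij`` — stronger connections are shorter;
* distances: all-pairs weighted shortest paths over those lengths;
* global efficiency ``Eg``: mean over nodes of nodal efficiency
  ``Ne(i) = (1/(N-1)) * sum_{j != i} 1/d_ij``, unreachable pairs
  contributing zero;
* characteristic path length ``Lp``: arithmetic mean of finite pairwise
  distances (reachable pairs only, with an explicit connectedness flag);
  a harmonic variant is available;
* clustering ``NCp``: Onnela geometric-mean triangle form on weights
  rescaled by the network-wide maximum, ``Cp`` its node average;
* local efficiency ``Eloc``: mean over nodes of the global efficiency of
  the subgraph induced on each node's neighbors (original weights kept);
* nodal degree ``Nd``: binary neighbor count by default, weighted (FN sum)
  as an option.

All functions accept either a :class:`~structconn.io.ConnectivityMatrix`
or a bare symmetric weight array, assumed already thresholded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .io import ConnectivityMatrix

__all__ = [
    "GlobalMetrics",
    "NodalMetrics",
    "edge_lengths",
    "shortest_paths",
    "network_density",
    "global_efficiency",
    "nodal_efficiency",
    "characteristic_path_length",
    "nodal_path_length",
    "clustering_coefficients",
    "local_efficiency",
    "nodal_degree",
    "compute_all_metrics",
]


@dataclass
class GlobalMetrics:
    """Whole-network summary metrics for one subject.

    ``lp`` is NaN when no pair of nodes is connected; ``connected`` records
    whether every pair was reachable (when False, ``lp`` averages reachable
    pairs only).  ``gamma``/``lambda_``/``sigma`` are filled in by
    null-model normalization and are None until then.
    """

    density: float
    cp: float
    lp: float
    eg: float
    eloc: float
    connected: bool
    gamma: float | None = None
    lambda_: float | None = None
    sigma: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "density": self.density,
            "Cp": self.cp,
            "Lp": self.lp,
            "Eg": self.eg,
            "Eloc": self.eloc,
            "gamma": self.gamma,
            "lambda": self.lambda_,
            "sigma": self.sigma,
        }


@dataclass
class NodalMetrics:
    """Per-node metric vectors for one subject.

    ``nlp`` is NaN for isolated nodes (no finite distance to any other
    node); every other vector is finite.
    """

    ne: np.ndarray
    ncp: np.ndarray
    nlp: np.ndarray
    nd: np.ndarray


def _weights(m: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    w = m.weights if isinstance(m, ConnectivityMatrix) else np.asarray(m)
    return w.astype(float, copy=False)


def edge_lengths(m: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Length matrix ``l_ij = 1/w_ij`` (inf where no edge, 0 diagonal)."""
    w = _weights(m)
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    np.fill_diagonal(lengths, 0.0)
    return lengths


def shortest_paths(m: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """All-pairs weighted shortest-path distances (inf for unreachable)."""
    w = _weights(m)
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    # dense csgraph input: zero entries are non-edges
    return _csgraph_shortest_path(lengths, method="D", directed=False)


def network_density(m: ConnectivityMatrix | np.ndarray) -> float:
    """Fraction of possible node pairs carrying a suprathreshold edge."""
    w = _weights(m)
    n = w.shape[0]
    if n < 2:
        raise ValueError("density needs at least 2 nodes")
    n_edges = int(np.count_nonzero(np.triu(w, k=1)))
    return n_edges / (n * (n - 1) / 2)


def nodal_efficiency(
    m: ConnectivityMatrix | np.ndarray, distances: np.ndarray | None = None
) -> np.ndarray:
    """Per-node harmonic-mean efficiency Ne(i) = mean_j 1/d_ij."""
    d = shortest_paths(m) if distances is None else distances
    n = d.shape[0]
    if n < 2:
        return np.zeros(n)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def global_efficiency(
    m: ConnectivityMatrix | np.ndarray, distances: np.ndarray | None = None
) -> float:
    """Network global efficiency: mean over nodes of nodal efficiency."""
    return float(nodal_efficiency(m, distances).mean())


def nodal_path_length(
    m: ConnectivityMatrix | np.ndarray, distances: np.ndarray | None = None
) -> np.ndarray:
    """NLp(i): mean shortest distance from i to the nodes it can reach.

    NaN for isolated nodes.
    """
    d = shortest_paths(m) if distances is None else distances
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    reach = np.isfinite(d) & off
    counts = reach.sum(axis=1)
    sums = np.where(reach, d, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def characteristic_path_length(
    m: ConnectivityMatrix | np.ndarray,
    distances: np.ndarray | None = None,
    mode: str = "arithmetic",
) -> tuple[float, bool]:
    """Characteristic path length Lp and a full-connectedness flag.

    ``mode="arithmetic"`` (default): mean distance over reachable pairs.
    ``mode="harmonic"``: harmonic mean over reachable pairs (the variant
    some toolboxes report).  Lp is NaN when no pair is reachable; the flag
    is False whenever any pair was unreachable, so the averaging scope is
    never silent.
    """
    d = shortest_paths(m) if distances is None else distances
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    connected = bool(finite.sum() == n * (n - 1))
    if not finite.any():
        return float("nan"), connected
    vals = d[finite]
    if mode == "arithmetic":
        lp = float(vals.mean())
    elif mode == "harmonic":
        lp = float(len(vals) / np.sum(1.0 / vals))
    else:
        raise ValueError(f"unknown Lp mode {mode!r}")
    return lp, connected


def clustering_coefficients(
    m: ConnectivityMatrix | np.ndarray,
) -> tuple[float, np.ndarray]:
    """Weighted clustering (Onnela form): per-node NCp and network mean Cp.

    Weights are rescaled by the network maximum; a node's coefficient is
    the mean geometric intensity of the triangles through it,
    ``NCp(i) = sum_{j,h} (w'_ij w'_ih w'_jh)^{1/3} / (k_i (k_i - 1))``,
    with binary degree ``k_i`` and zero for nodes with fewer than two
    neighbors.
    """
    w = _weights(m)
    n = w.shape[0]
    wmax = w.max()
    if wmax == 0:
        return 0.0, np.zeros(n)
    cbrt = np.cbrt(w / wmax)
    # diag of cbrt^3 counts each triangle through i twice (ordered (j,h))
    tri = np.einsum("ij,jh,hi->i", cbrt, cbrt, cbrt)
    k = (w > 0).sum(axis=1)
    denom = k * (k - 1)
    ncp = np.where(denom > 0, tri / np.maximum(denom, 1), 0.0)
    return float(ncp.mean()), ncp


def local_efficiency(m: ConnectivityMatrix | np.ndarray) -> float:
    """Mean over nodes of each neighbor-subgraph's global efficiency.

    Neighbor subgraphs keep the original FN weights; nodes with fewer than
    two neighbors contribute zero.
    """
    w = _weights(m)
    n = w.shape[0]
    total = 0.0
    for i in range(n):
        nb = np.flatnonzero(w[i] > 0)
        if nb.size < 2:
            continue
        total += global_efficiency(w[np.ix_(nb, nb)])
    return total / n if n else 0.0


def nodal_degree(
    m: ConnectivityMatrix | np.ndarray, mode: str = "binary"
) -> np.ndarray:
    """Per-node degree: neighbor count (binary) or summed FN weight."""
    w = _weights(m)
    if mode == "binary":
        return (w > 0).sum(axis=1).astype(float)
    if mode == "weighted":
        return w.sum(axis=1)
    raise ValueError(f"unknown degree mode {mode!r}")


def compute_all_metrics(
    m: ConnectivityMatrix | np.ndarray,
    degree_mode: str = "binary",
    lp_mode: str = "arithmetic",
) -> tuple[GlobalMetrics, NodalMetrics]:
    """All global and nodal metrics in one pass over a shared distance matrix."""
    w = _weights(m)
    d = shortest_paths(w)
    ne = nodal_efficiency(w, d)
    eg = float(ne.mean())
    lp, connected = characteristic_path_length(w, d, mode=lp_mode)
    cp, ncp = clustering_coefficients(w)
    glob = GlobalMetrics(
        density=network_density(w),
        cp=cp,
        lp=lp,
        eg=eg,
        eloc=local_efficiency(w),
        connected=connected,
    )
    nodal = NodalMetrics(
        ne=ne,
        ncp=ncp,
        nlp=nodal_path_length(w, d),
        nd=nodal_degree(w, mode=degree_mode),
    )
    return glob, nodal
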