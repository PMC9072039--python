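"""Connectivity matrices, phenotypes, cohort container and file I/O.

A subject's structural connectome is a symmetric, zero-diagonal matrix of
nonnegative integer edge weights: entry ``(i, j)`` is the number of
tractography streamlines ("fiber number", FN) connecting atlas regions
``i`` and ``j``.  Matrices live in plain delimited text files (comma or
whitespace separated, no header); phenotypes and atlases in small CSVs.

Edge detection follows the study convention that a connection exists only
when the streamline count exceeds a minimum: :func:`apply_fiber_threshold`
zeroes every entry ``<= min_fn`` (default 3, i.e. an edge requires FN >= 4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import NodeAtlas, default_atlas

__all__ = [
    "ConnectivityMatrix",
    "Phenotype",
    "CohortDataset",
    "ValidationError",
    "DimensionError",
    "read_connectome",
    "write_connectome",
    "read_phenotypes",
    "write_phenotypes",
    "apply_fiber_threshold",
    "write_results",
]


class ValidationError(ValueError):
    """A matrix or phenotype violates a structural invariant."""


class DimensionError(ValidationError):
    """A matrix file does not have the expected shape."""


@dataclass(frozen=True)
class ConnectivityMatrix:
    """One subject's FN-weighted structural network.

    ``weights`` is an ``n x n`` symmetric integer array with zero diagonal;
    validation runs on construction.
    """

    subject_id: str
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise DimensionError(
                f"subject {self.subject_id}: weights must be square, got shape {w.shape}"
            )
        if not np.issubdtype(w.dtype, np.integer):
            if not np.allclose(w, np.round(w), atol=1e-9):
                bad = np.argwhere(~np.isclose(w, np.round(w), atol=1e-9))[0]
                raise ValidationError(
                    f"subject {self.subject_id}: non-integral weight at "
                    f"({bad[0]}, {bad[1]})"
                )
            w = np.round(w).astype(np.int64)
        else:
            w = w.astype(np.int64)
        if (w < 0).any():
            i, j = np.argwhere(w < 0)[0]
            raise ValidationError(
                f"subject {self.subject_id}: negative weight {w[i, j]} at ({i}, {j})"
            )
        asym = np.argwhere(w != w.T)
        if asym.size:
            i, j = sorted(asym[0])
            raise ValidationError(
                f"subject {self.subject_id}: asymmetric at pair ({i}, {j}): "
                f"{w[i, j]} != {w[j, i]}"
            )
        if np.diagonal(w).any():
            i = int(np.flatnonzero(np.diagonal(w))[0])
            raise ValidationError(
                f"subject {self.subject_id}: nonzero diagonal at node {i}"
            )
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class Phenotype:
    """Subject-level record: group membership, age, sex and blind duration.

    ``blind_duration`` is months of blindness; present for every case
    subject and absent (None) for controls.
    """

    subject_id: str
    group: str  # "case" | "control"
    age: float  # years
    sex: str  # "M" | "F"
    blind_duration: float | None = None

    def __post_init__(self) -> None:
        if self.group not in ("case", "control"):
            raise ValidationError(
                f"subject {self.subject_id}: group must be case/control, "
                f"got {self.group!r}"
            )
        if self.sex not in ("M", "F"):
            raise ValidationError(
                f"subject {self.subject_id}: sex must be M/F, got {self.sex!r}"
            )
        if not (self.age > 0 and math.isfinite(self.age)):
            raise ValidationError(
                f"subject {self.subject_id}: age must be positive, got {self.age}"
            )
        if self.group == "case":
            if self.blind_duration is None or not self.blind_duration > 0:
                raise ValidationError(
                    f"subject {self.subject_id}: case subject requires a positive "
                    f"blind_duration, got {self.blind_duration}"
                )
        elif self.blind_duration is not None:
            raise ValidationError(
                f"subject {self.subject_id}: control subject must not carry a "
                f"blind_duration"
            )

    @property
    def is_case(self) -> bool:
        return self.group == "case"


@dataclass
class CohortDataset:
    """Atlas + per-subject matrices + phenotypes, matched by subject id."""

    atlas: NodeAtlas
    matrices: list[ConnectivityMatrix]
    phenotypes: list[Phenotype]
    min_group_size: int = 3

    def __post_init__(self) -> None:
        mat_ids = [m.subject_id for m in self.matrices]
        phe_ids = [p.subject_id for p in self.phenotypes]
        if sorted(mat_ids) != sorted(phe_ids):
            missing = set(mat_ids) ^ set(phe_ids)
            raise ValidationError(
                f"matrices and phenotypes do not match: unpaired ids {sorted(missing)}"
            )
        n = self.atlas.n_nodes
        for m in self.matrices:
            if m.n_nodes != n:
                raise DimensionError(
                    f"subject {m.subject_id}: matrix is {m.n_nodes}x{m.n_nodes} "
                    f"but atlas has {n} nodes"
                )
        by_id = {p.subject_id: p for p in self.phenotypes}
        self.matrices = sorted(self.matrices, key=lambda m: m.subject_id)
        self.phenotypes = [by_id[m.subject_id] for m in self.matrices]
        for g in ("case", "control"):
            if 0 < self.group_size(g) < self.min_group_size:
                raise ValidationError(
                    f"group {g!r} has fewer than {self.min_group_size} subjects"
                )

    @property
    def subject_ids(self) -> list[str]:
        return [m.subject_id for m in self.matrices]

    def group_size(self, group: str) -> int:
        return sum(p.group == group for p in self.phenotypes)

    def subset(self, group: str) -> "CohortDataset":
        keep = {p.subject_id for p in self.phenotypes if p.group == group}
        return CohortDataset(
            atlas=self.atlas,
            matrices=[m for m in self.matrices if m.subject_id in keep],
            phenotypes=[p for p in self.phenotypes if p.subject_id in keep],
            min_group_size=1,
        )

    def phenotype_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [p.subject_id for p in self.phenotypes],
                "group": [p.group for p in self.phenotypes],
                "age": [p.age for p in self.phenotypes],
                "sex": [p.sex for p in self.phenotypes],
                "blind_duration": [p.blind_duration for p in self.phenotypes],
            }
        )


def _sniff_delimiter(first_line: str) -> str | None:
    """Comma-delimited if commas present, otherwise whitespace."""
    return "," if "," in first_line else None


def read_connectome(
    path: str | Path,
    subject_id: str | None = None,
    n_nodes: int = 90,
) -> ConnectivityMatrix:
    """Read a delimited ``n_nodes x n_nodes`` weight grid from a text file.

    The delimiter (comma or whitespace) is auto-detected.  Values must be
    integral within 1e-9; the matrix must be exactly symmetric with a zero
    diagonal.
    """
    path = Path(path)
    if subject_id is None:
        subject_id = path.stem
    with open(path) as fh:
        first = fh.readline()
        fh.seek(0)
        try:
            w = np.loadtxt(fh, delimiter=_sniff_delimiter(first), ndmin=2)
        except ValueError as exc:
            raise ValidationError(f"{path}: could not parse matrix: {exc}") from exc
    if w.shape != (n_nodes, n_nodes):
        raise DimensionError(
            f"{path}: expected a {n_nodes}x{n_nodes} grid, got {w.shape[0]}x{w.shape[1]}"
        )
    return ConnectivityMatrix(subject_id=subject_id, weights=w)


def write_connectome(m: ConnectivityMatrix, path: str | Path) -> None:
    """Write a matrix as comma-delimited integers (round-trips exactly)."""
    np.savetxt(path, m.weights, fmt="%d", delimiter=",")


def read_phenotypes(path: str | Path) -> list[Phenotype]:
    """Read a phenotype CSV with columns subject_id,group,age,sex,blind_duration.

    Group and sex are normalized case-insensitively; blind_duration may be
    blank for controls only.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    required = {"subject_id", "group", "age", "sex", "blind_duration"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        age = pd.to_numeric(row.age, errors="coerce")
        if pd.isna(age):
            raise ValidationError(f"{path} row {row_no}: unparseable age {row.age!r}")
        dur = pd.to_numeric(row.blind_duration, errors="coerce")
        out.append(
            Phenotype(
                subject_id=str(row.subject_id),
                group=str(row.group).strip().lower(),
                age=float(age),
                sex=str(row.sex).strip().upper(),
                blind_duration=None if pd.isna(dur) else float(dur),
            )
        )
    return out


def write_phenotypes(phenotypes: Sequence[Phenotype], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "subject_id": [p.subject_id for p in phenotypes],
            "group": [p.group for p in phenotypes],
            "age": [p.age for p in phenotypes],
            "sex": [p.sex for p in phenotypes],
            "blind_duration": [
                "" if p.blind_duration is None else p.blind_duration
                for p in phenotypes
            ],
        }
    )
    df.to_csv(path, index=False, lineterminator="\n")


def apply_fiber_threshold(
    m: ConnectivityMatrix, min_fn: int = 3
) -> ConnectivityMatrix:
    """Zero every entry whose streamline count does not exceed ``min_fn``.

    The rule is strict: an edge survives iff its weight is strictly greater
    than ``min_fn`` (default 3, so an edge requires at least 4 streamlines).
    Idempotent, and monotone in ``min_fn``.
    """
    if min_fn < 0:
        raise ValueError(f"min_fn must be nonnegative, got {min_fn}")
    w = np.array(m.weights, copy=True)
    w[w <= min_fn] = 0
    return replace(m, weights=w)


# Fixed column orders for the exported result tables; write_results emits
# byte-identical files for identical inputs.
RESULT_SCHEMAS: Mapping[str, Sequence[str]] = {
    "global_comparison": (
        "metric", "mean_case", "mean_control", "t", "p", "p_threshold",
        "significant", "family_size",
    ),
    "nodal_comparison": (
        "node", "abbreviation", "system", "metric", "t", "p", "p_threshold",
        "significant", "n_used", "n_excluded",
    ),
    "hubs": ("cohort", "rank", "node", "abbreviation", "mean_degree", "is_hub", "tied"),
    "correlations": ("metric", "node", "abbreviation", "r", "df", "p"),
}


def write_results(
    tables: Mapping[str, pd.DataFrame], out_dir: str | Path
) -> list[Path]:
    """Write analysis tables as CSV with stable column order.

    ``tables`` maps schema names (keys of :data:`RESULT_SCHEMAS`) to frames;
    unknown keys are written with their own column order.  Returns paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in tables.items():
        schema = RESULT_SCHEMAS.get(name)
        if schema is not None:
            df = df.reindex(columns=list(schema))
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")
        paths.append(path)
    return paths


def load_cohort(
    matrix_dir: str | Path,
    phenotype_path: str | Path,
    atlas: NodeAtlas | None = None,
    pattern: str = "*.csv",
) -> CohortDataset:
    """Load a cohort from a directory of matrix files plus a phenotype CSV.

    Matrix files are matched to phenotype rows by file stem == subject_id.
    """
    atlas = atlas or default_atlas()
    phenotypes = read_phenotypes(phenotype_path)
    matrices = [
        read_connectome(p, n_nodes=atlas.n_nodes)
        for p in sorted(Path(matrix_dir).glob(pattern))
    ]
    return CohortDataset(atlas=atlas, matrices=matrices, phenotypes=phenotypes)
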