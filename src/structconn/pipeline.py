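"""End-to-end orchestration: threshold -> metrics -> null normalization ->
hubs -> group inference -> duration correlations, with a JSON run manifest.

The pipeline mirrors the study workflow.  Every per-subject random draw
(null ensembles, synthetic subjects) uses a seed derived from the run
seed plus the subject index, recorded in the manifest, so any single
subject can be recomputed in isolation and a rerun with the same config
is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atlas import NodeAtlas, default_atlas, load_atlas, write_atlas
from .hubs import compare_hub_sets, hub_report
from .io import (
    CohortDataset,
    apply_fiber_threshold,
    load_cohort,
    write_connectome,
    write_phenotypes,
    write_results,
)
from .metrics import compute_all_metrics
from .nullmodels import NullEnsembleParams, normalized_small_world
from .simulate import SyntheticParams, generate_cohort
from .stats import (
    bonferroni_correct,
    fit_group_model,
    partial_correlation,
    run_nodal_comparison,
)

log = logging.getLogger("structconn")

GLOBAL_METRIC_FAMILY = (
    "density", "Eg", "Eloc", "Cp", "Lp", "gamma", "lambda", "sigma"
)
NODAL_METRIC_FAMILY = ("Ne", "NCp", "NLp")


@dataclass
class RunConfig:
    """All pipeline settings, JSON round-trippable."""

    matrix_dir: str | None = None
    phenotype_path: str | None = None
    atlas_path: str | None = None
    synthetic: bool = False
    synthetic_params: dict = field(default_factory=dict)
    min_fn: int = 3
    degree_mode: str = "binary"
    lp_mode: str = "arithmetic"
    n_null: int = 100
    swaps_per_edge: int = 10
    alpha: float = 0.05
    hub_fraction: float = 0.15
    out_dir: str = "results"
    seed: int = 0

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _subject_seed(run_seed: int, index: int) -> int:
    """Stable per-subject seed below 2**31."""
    return int(np.random.SeedSequence([run_seed, index]).generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class AnalysisResult:
    """In-memory bundle of everything run_analysis computed."""

    cohort: CohortDataset
    global_per_subject: pd.DataFrame
    nodal_per_subject: dict[str, pd.DataFrame]
    global_comparison: pd.DataFrame
    nodal_comparisons: dict[str, pd.DataFrame]
    hub_reports: dict[str, object]
    hub_comparison: pd.DataFrame
    correlations: pd.DataFrame
    warnings: list[str]


def subject_metrics(
    cohort: CohortDataset, config: RunConfig
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], list[str]]:
    """Thresholded per-subject global and nodal metric tables."""
    warnings: list[str] = []
    rows = []
    nodal = {name: [] for name in NODAL_METRIC_FAMILY}
    abbrevs = cohort.atlas.abbreviations
    for idx, m in enumerate(cohort.matrices):
        mt = apply_fiber_threshold(m, min_fn=config.min_fn)
        glob, nod = compute_all_metrics(
            mt, degree_mode=config.degree_mode, lp_mode=config.lp_mode
        )
        if config.n_null > 0:
            sw = normalized_small_world(
                mt,
                NullEnsembleParams(
                    n_null=config.n_null,
                    swaps_per_edge=config.swaps_per_edge,
                    seed=_subject_seed(config.seed, idx),
                ),
                lp_mode=config.lp_mode,
            )
            glob.gamma, glob.lambda_, glob.sigma = sw.gamma, sw.lambda_, sw.sigma
        if not glob.connected:
            warnings.append(
                f"subject {m.subject_id}: network not fully connected; "
                f"Lp/NLp averaged over reachable pairs"
            )
        rows.append({"subject_id": m.subject_id, **glob.as_dict(),
                     "connected": glob.connected})
        for name, vec in (("Ne", nod.ne), ("NCp", nod.ncp), ("NLp", nod.nlp)):
            nodal[name].append(
                {"subject_id": m.subject_id, **dict(zip(abbrevs, vec))}
            )
    global_df = pd.DataFrame(rows)
    nodal_dfs = {name: pd.DataFrame(rows_) for name, rows_ in nodal.items()}
    return global_df, nodal_dfs, warnings


def _comparison_tables(
    cohort: CohortDataset,
    global_df: pd.DataFrame,
    nodal_dfs: dict[str, pd.DataFrame],
    config: RunConfig,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    phenos = cohort.phenotypes
    case_ids = {p.subject_id for p in phenos if p.is_case}
    results = []
    means = {}
    family = [m for m in GLOBAL_METRIC_FAMILY if global_df[m].notna().all()]
    for name in family:
        y = global_df[name].to_numpy()
        res = fit_group_model(y, phenos, metric=name)
        is_case = global_df["subject_id"].isin(case_ids).to_numpy()
        means[name] = (float(y[is_case].mean()), float(y[~is_case].mean()))
        results.append(res)
    results = bonferroni_correct(results, alpha=config.alpha, family_size=len(family))
    global_cmp = pd.DataFrame(
        {
            "metric": [r.metric for r in results],
            "mean_case": [means[r.metric][0] for r in results],
            "mean_control": [means[r.metric][1] for r in results],
            "t": [r.t for r in results],
            "p": [r.p for r in results],
            "p_threshold": [r.p_threshold for r in results],
            "significant": [r.significant for r in results],
            "family_size": [r.family_size for r in results],
        }
    )
    nodal_cmp = {}
    for name, df in nodal_dfs.items():
        values = df.drop(columns="subject_id").to_numpy()
        nodal_cmp[name] = run_nodal_comparison(
            cohort, values, metric=name, alpha=config.alpha
        )
    return global_cmp, nodal_cmp


def _duration_correlations(
    cohort: CohortDataset,
    global_df: pd.DataFrame,
    nodal_dfs: dict[str, pd.DataFrame],
    global_cmp: pd.DataFrame,
    nodal_cmps: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Partial correlations (age/sex-adjusted) with blind duration in cases,
    for every parameter showing a significant group difference."""
    cases = [p for p in cohort.phenotypes if p.is_case]
    case_ids = [p.subject_id for p in cases]
    dur = np.array([p.blind_duration for p in cases])
    cov = np.column_stack(
        [[p.age for p in cases], [1.0 if p.sex == "M" else 0.0 for p in cases]]
    )
    rows = []
    gsub = global_df.set_index("subject_id").loc[case_ids]
    for _, r in global_cmp[global_cmp["significant"].astype(bool)].iterrows():
        res = partial_correlation(gsub[r["metric"]].to_numpy(), dur, cov,
                                  metric=r["metric"])
        rows.append({"metric": r["metric"], "node": "", "abbreviation": "",
                     "r": res.r, "df": res.df, "p": res.p})
    for name, cmp_df in nodal_cmps.items():
        nsub = nodal_dfs[name].set_index("subject_id").loc[case_ids]
        for _, r in cmp_df[cmp_df["significant"].astype(bool)].iterrows():
            x = nsub[r["abbreviation"]].to_numpy()
            keep = ~np.isnan(x)
            if keep.sum() < cov.shape[1] + 3:
                continue
            res = partial_correlation(x[keep], dur[keep], cov[keep], metric=name)
            rows.append({"metric": name, "node": int(r["node"]),
                         "abbreviation": r["abbreviation"],
                         "r": res.r, "df": res.df, "p": res.p})
    return pd.DataFrame(rows, columns=["metric", "node", "abbreviation", "r", "df", "p"])


def _summary_text(result: AnalysisResult, config: RunConfig) -> str:
    c = result.cohort
    lines = [
        "Structural connectivity network analysis",
        f"subjects: {c.group_size('case')} case / {c.group_size('control')} control, "
        f"{c.atlas.n_nodes} nodes, FN threshold > {config.min_fn}",
        "",
        "Global comparison (t of the group coefficient, case=1):",
    ]
    for _, r in result.global_comparison.iterrows():
        star = " *" if r["significant"] else ""
        lines.append(f"  {r['metric']:>8}: t={r['t']:+.3f}, p={r['p']:.4g}{star}")
    for name, df in result.nodal_comparisons.items():
        sig = df[df["significant"].astype(bool)]
        lines.append(
            f"{name}: {len(sig)} of {len(df)} nodes significant "
            f"(Bonferroni, alpha={config.alpha})"
        )
        for _, r in sig.iterrows():
            lines.append(
                f"  {r['abbreviation']:>10} [{r['system']}]: "
                f"t={r['t']:+.3f}, p={r['p']:.3g}"
            )
    for grp, rep in result.hub_reports.items():
        lines.append(f"hubs ({grp}, top {len(rep.hubs)}): "
                     + ", ".join(rep.hub_abbreviations()))
    if len(result.correlations):
        lines.append("duration correlations (cases, age/sex-adjusted):")
        for _, r in result.correlations.iterrows():
            label = r["abbreviation"] or r["metric"]
            lines.append(f"  {r['metric']} {label}: r={r['r']:+.3f}, p={r['p']:.4g}")
    if result.warnings:
        lines.append(f"warnings: {len(result.warnings)} (see manifest)")
    return "\n".join(lines) + "\n"


def run_analysis(config: RunConfig) -> AnalysisResult:
    """Execute the full pipeline and write all outputs under config.out_dir."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []

    if config.synthetic:
        params = SyntheticParams(**{**config.synthetic_params, "seed": config.seed})
        cohort, truth = generate_cohort(params)
        with open(out_dir / "ground_truth.json", "w") as fh:
            json.dump(dataclasses.asdict(truth), fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        if not (config.matrix_dir and config.phenotype_path):
            raise ValueError("matrix_dir and phenotype_path required unless synthetic")
        atlas = load_atlas(config.atlas_path) if config.atlas_path else default_atlas()
        cohort = load_cohort(config.matrix_dir, config.phenotype_path, atlas)

    log.info("computing metrics for %d subjects", len(cohort.matrices))
    global_df, nodal_dfs, w = subject_metrics(cohort, config)
    warnings.extend(w)

    log.info("group inference")
    global_cmp, nodal_cmps = _comparison_tables(cohort, global_df, nodal_dfs, config)

    log.info("hub analysis")
    cohort_thr = CohortDataset(
        atlas=cohort.atlas,
        matrices=[apply_fiber_threshold(m, config.min_fn) for m in cohort.matrices],
        phenotypes=cohort.phenotypes,
    )
    reports = {
        g: hub_report(cohort_thr, g, mode=config.degree_mode,
                      fraction=config.hub_fraction)
        for g in ("case", "control")
    }
    shared, only_case, only_control = compare_hub_sets(
        reports["case"], reports["control"]
    )
    hub_cmp = pd.DataFrame(
        {
            "category": ["shared"] * len(shared)
            + ["case_only"] * len(only_case)
            + ["control_only"] * len(only_control),
            "abbreviation": shared + only_case + only_control,
        }
    )

    log.info("duration correlations")
    corr = _duration_correlations(cohort, global_df, nodal_dfs, global_cmp, nodal_cmps)

    result = AnalysisResult(
        cohort=cohort,
        global_per_subject=global_df,
        nodal_per_subject=nodal_dfs,
        global_comparison=global_cmp,
        nodal_comparisons=nodal_cmps,
        hub_reports=reports,
        hub_comparison=hub_cmp,
        correlations=corr,
        warnings=warnings,
    )

    tables = {
        "global_metrics_per_subject": global_df,
        "global_comparison": global_cmp,
        "hub_comparison": hub_cmp,
        "correlations": corr,
    }
    for name, df in nodal_dfs.items():
        tables[f"nodal_{name}_per_subject"] = df
    for name, df in nodal_cmps.items():
        tables[f"nodal_comparison_{name}"] = df
    hub_frames = pd.concat([r.as_frame() for r in reports.values()])
    tables["hubs"] = hub_frames
    paths = write_results(tables, out_dir)

    (out_dir / "summary.txt").write_text(_summary_text(result, config))
    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "subject_seeds": {
            m.subject_id: _subject_seed(config.seed, i)
            for i, m in enumerate(cohort.matrices)
        },
        "warnings": warnings,
        "checksums": {p.name: _sha256(p) for p in sorted(paths)},
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return result


def write_synthetic_cohort(
    params: SyntheticParams, out_dir: str | Path
) -> CohortDataset:
    """Materialize a synthetic cohort on disk (matrices/, phenotypes, truth)."""
    out_dir = Path(out_dir)
    (out_dir / "matrices").mkdir(parents=True, exist_ok=True)
    cohort, truth = generate_cohort(params)
    for m in cohort.matrices:
        write_connectome(m, out_dir / "matrices" / f"{m.subject_id}.csv")
    write_phenotypes(cohort.phenotypes, out_dir / "phenotypes.csv")
    write_atlas(cohort.atlas, out_dir / "atlas.csv")
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(dataclasses.asdict(truth), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return cohort
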