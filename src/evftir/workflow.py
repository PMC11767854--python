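"""End-to-end pipeline orchestration and report bundle assembly.

``run_workflow`` ties the stages together for one sample type: preprocessing
(crop, baseline, area normalization, Savitzky-Golay second derivative,
inversion), PLS discrimination on the *non-inverted* second derivative with
cross-validation and beta-coefficient peak attribution, then peak detection /
target matching / shift screening on the inverted derivative and the
Mann-Whitney group comparison.  Every resolved default is written to the run
log -- no silent defaults -- and all outputs are tidy CSV, so two runs with an
identical configuration produce byte-identical bundles.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import compare as cmp
from . import peaks as pk
from . import pls
from .preprocess import PreprocessConfig, preprocess_pipeline
from .simulate import SimConfig
from .spectra import SpectraSet, read_spectra_csv, write_spectra_csv


@dataclass(frozen=True)
class RunConfig:
    """Resolved options of one analysis run."""

    sample_type: str = "EVs"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    coding: pls.ClassCoding = field(default_factory=pls.ClassCoding)
    n_factors: int = 1
    cv_scheme: str = "loo_spectrum"
    peak_tolerance: float = pk.DEFAULT_TOLERANCE
    min_prominence: float | None = None
    max_spread: float | None = None  # None -> one grid step
    replicate_policy: str = "all_spectra"
    mw_mode: str = "auto"


@dataclass
class RunResult:
    """In-memory report bundle of one workflow run."""

    config: RunConfig
    normalized: SpectraSet
    second_deriv: SpectraSet
    inverted: SpectraSet
    scores: pd.DataFrame
    beta: pd.DataFrame
    metrics: pd.DataFrame
    beta_peaks: pd.DataFrame
    peak_table: pd.DataFrame
    comparison: pd.DataFrame
    results: list[cmp.ComparisonResult]
    log: list[str]


def run_workflow(spectra: SpectraSet, config: RunConfig | None = None) -> RunResult:
    """Run the full analysis chain on one sample type's spectra."""
    config = config or RunConfig()
    cfg = config.preprocess
    log = [
        f"sample_type = {config.sample_type}",
        f"region = {cfg.region_high:g}-{cfg.region_low:g} cm^-1",
        f"baseline_method = {cfg.baseline_method}",
        f"normalize = {cfg.normalize}",
        (
            f"savitzky_golay: side_points = {cfg.sg_side_points} "
            f"(window {2 * cfg.sg_side_points + 1}), poly_order = "
            f"{cfg.sg_poly_order}, deriv_order = {cfg.sg_deriv_order}"
        ),
        f"class_coding = {config.coding.codes}",
        f"n_factors = {config.n_factors}",
        f"cv_scheme = {config.cv_scheme}",
        f"peak_tolerance = {config.peak_tolerance:g} cm^-1",
        (
            "min_prominence = 3 x MAD of negative part (per spectrum)"
            if config.min_prominence is None
            else f"min_prominence = {config.min_prominence:g} A.U."
        ),
        (
            "max_spread = one grid step"
            if config.max_spread is None
            else f"max_spread = {config.max_spread:g} cm^-1"
        ),
        f"replicate_policy = {config.replicate_policy}",
        f"mann_whitney_mode = {config.mw_mode}",
    ]

    wrong_type = [
        m.sample_id for m in spectra.meta if m.sample_type != config.sample_type
    ]
    if wrong_type:
        raise ValueError(
            f"spectra {wrong_type} are not of sample_type {config.sample_type!r}"
        )

    normalized, deriv, inverted = preprocess_pipeline(spectra, cfg)
    log.extend(inverted.provenance)

    # --- PLS on the (non-inverted) second derivative ----------------------
    y = pls.encode_classes(deriv.meta, config.coding)
    model = pls.fit_pls(deriv, y, n_factors=config.n_factors)
    y_cv, metrics = pls.cross_validate(
        deriv, y, n_factors=config.n_factors, scheme=config.cv_scheme
    )
    scores = pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in deriv.meta],
            "condition": [m.condition for m in deriv.meta],
            "factor": 1,
            "score": model.T[:, 0],
            "y": y,
            "y_cv": y_cv,
        }
    )
    beta = pd.DataFrame(
        {"wavenumber": model.axis.values, "beta": model.beta_for(config.n_factors)}
    )
    metrics_df = pd.DataFrame(
        [
            {
                "group": config.sample_type,
                "r_cal": metrics.r_cal,
                "r_val": metrics.r_val,
                "rmsec": metrics.rmsec,
                "rmsecv": metrics.rmsecv,
            }
        ]
    )

    # --- peak analysis on the inverted second derivative ------------------
    targets = pk.target_peak_set(config.sample_type)
    beta_peaks = pls.beta_peak_attribution(
        model, targets, tolerance=config.peak_tolerance, coding=config.coding,
        n_factors=config.n_factors,
    )
    detected = pk.detect_peaks(inverted, min_prominence=config.min_prominence)
    table = pk.match_targets(
        inverted, detected, targets, tolerance=config.peak_tolerance
    )
    table = pk.check_peak_shift(
        table, max_spread=config.max_spread, grid_step=inverted.axis.spacing
    )
    results = cmp.compare_peaks(
        table, replicate_policy=config.replicate_policy, mode=config.mw_mode
    )
    comparison = cmp.summarize(results)
    log.append(f"targets = {[f'{t:g}' for t in targets]}")
    log.append(
        f"shift-excluded targets = "
        f"{sorted(set(table.loc[table['shift_flag'], 'target_cm1'])) or 'none'}"
    )
    return RunResult(
        config=config,
        normalized=normalized,
        second_deriv=deriv,
        inverted=inverted,
        scores=scores,
        beta=beta,
        metrics=metrics_df,
        beta_peaks=beta_peaks,
        peak_table=table,
        comparison=comparison,
        results=results,
        log=log,
    )


def run_workflow_files(
    spectra_path: str | Path,
    meta_path: str | Path,
    config: RunConfig | None = None,
) -> RunResult:
    spectra = read_spectra_csv(spectra_path, meta_path)
    return run_workflow(spectra, config)


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["coding"] = dict(config.coding.codes)
    return d


def write_bundle(result: RunResult, outdir: str | Path) -> Path:
    """Write the full report bundle as CSV + text files under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_spectra_csv(result.normalized, out / "normalized_spectra.csv",
                      out / "meta.csv")
    write_spectra_csv(result.second_deriv, out / "second_derivative.csv")
    write_spectra_csv(result.inverted, out / "inverted_second_derivative.csv")
    result.scores.to_csv(out / "pls_scores.csv", index=False)
    result.beta.to_csv(out / "pls_beta.csv", index=False)
    result.metrics.to_csv(out / "pls_metrics.csv", index=False)
    result.beta_peaks.to_csv(out / "beta_peaks.csv", index=False)
    result.peak_table.to_csv(out / "peak_table.csv", index=False)
    result.comparison.to_csv(out / "comparison.csv", index=False)
    (out / "run_log.txt").write_text("\n".join(result.log) + "\n")
    (out / "config.yaml").write_text(
        yaml.safe_dump(_config_dict(result.config), sort_keys=True)
    )
    return out


BUNDLE_FILES = (
    "normalized_spectra.csv", "meta.csv", "second_derivative.csv",
    "inverted_second_derivative.csv", "pls_scores.csv", "pls_beta.csv",
    "pls_metrics.csv", "beta_peaks.csv", "peak_table.csv", "comparison.csv",
    "run_log.txt", "config.yaml",
)


def render_report(
    run_dir: str | Path, plots: bool = True
) -> str:
    """Human-readable summary of a completed run directory.

    With ``plots=True`` also writes score / beta / intensity-bar figures as
    PNG files next to the tables.
    """
    run_dir = Path(run_dir)
    missing = [f for f in BUNDLE_FILES if not (run_dir / f).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run bundle, missing {missing}")
    scores = pd.read_csv(run_dir / "pls_scores.csv")
    beta = pd.read_csv(run_dir / "pls_beta.csv")
    beta_peaks = pd.read_csv(run_dir / "beta_peaks.csv")
    comparison = pd.read_csv(run_dir / "comparison.csv")
    metrics = pd.read_csv(run_dir / "pls_metrics.csv")

    lines = [f"Run summary: {run_dir}", ""]
    m = metrics.iloc[0]
    lines.append(
        f"PLS ({m['group']}): r_cal = {m['r_cal']:.3f}, r_val = {m['r_val']:.3f}, "
        f"RMSEC = {m['rmsec']:.3f}, RMSECV = {m['rmsecv']:.3f}"
    )
    pos = scores[scores["score"] > 0]["condition"].value_counts().to_dict()
    lines.append(f"factor-1 scores > 0 by condition: {pos}")
    lines.append("")
    sig = comparison[
        comparison["p"].notna() & (comparison["p"] < 0.05)
    ]
    if sig.empty:
        lines.append("no targets below 0.05")
    else:
        for _, row in sig.iterrows():
            lines.append(
                f"{row['target_cm1']:g} cm^-1: {row['direction']} "
                f"(p = {row['p']:.4g} {row['tier']})"
            )
    excluded = comparison[comparison["excluded_by_shift"]]
    if excluded.empty:
        lines.append("shift-excluded targets: none")
    else:
        lines.append(
            "shift-excluded targets: "
            + ", ".join(f"{t:g} cm^-1" for t in excluded["target_cm1"])
        )

    if plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 3, figsize=(13, 3.6))
        for cond, grp in scores.groupby("condition"):
            axes[0].scatter(range(len(grp)), grp["score"], label=cond)
        axes[0].axhline(0.0, color="k", lw=0.5)
        axes[0].set_title("factor-1 scores")
        axes[0].legend()
        axes[1].plot(beta["wavenumber"], beta["beta"], lw=1)
        matched = beta_peaks[beta_peaks["matched"]]
        axes[1].scatter(matched["found_cm1"], matched["beta"], color="r", s=12)
        axes[1].invert_xaxis()
        axes[1].set_title("beta coefficients")
        plotted = comparison[comparison["p"].notna()]
        axes[2].bar(
            [f"{t:g}" for t in plotted["target_cm1"]],
            plotted["mean_abeta"] / plotted["mean_ctrl"],
        )
        for i, (_, row) in enumerate(plotted.iterrows()):
            if row["tier"] not in (None, "ns") and isinstance(row["tier"], str):
                axes[2].text(i, row["mean_abeta"] / row["mean_ctrl"], row["tier"],
                             ha="center")
        axes[2].axhline(1.0, color="k", lw=0.5)
        axes[2].set_title("abeta / control mean intensity")
        axes[2].tick_params(axis="x", rotation=60)
        fig.tight_layout()
        fig.savefig(run_dir / "report.png", dpi=120)
        plt.close(fig)
        lines.append(f"figures written to {run_dir / 'report.png'}")
    return "\n".join(lines)
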