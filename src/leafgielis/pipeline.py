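"""Batch orchestration: simulate, fit, diagnose, compare, report.

Stages communicate through plain CSV contracts in the output directory
(``fits.csv``, ``diagnostics.csv``, ``summary.csv``, ``pairwise_tests.json``)
so each can run independently; ``run_pipeline`` composes them and is exactly
equivalent to running the stages in order.  Floats are printed with 10
significant digits so repeated runs are byte-stable.  Per-leaf failures are
logged and excluded with counts; a run aborts only when no leaf succeeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .compare import BatchSummary, summarize_batch
from .contour import ReadDialect, read_contour_directory, to_polar
from .diagnostics import diagnose
from .model import FitConfig, FitResult, fit_leaf
from .simulate import SimulationDesign, generate_population, write_population
from .superformula import GielisParameters, SGEVariant

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "stage_simulate",
    "stage_fit",
    "stage_diagnose",
    "stage_compare",
    "stage_report",
]

logger = logging.getLogger("leafgielis")

FLOAT_FMT = "%.10g"
ALL_VARIANTS = ("SGE1", "SGE2", "SGE3")


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved configuration of one pipeline run (YAML-serialisable)."""

    input_dir: str = ""
    output_dir: str = "leafgielis_out"
    variants: tuple = ALL_VARIANTS
    alpha: float = 0.05
    bias_threshold_pct: float = 1.0
    n_starts: int = 3
    xtol: float = 1e-10
    ftol: float = 1e-10
    max_iter: int = 5000
    co_optimize_pose: bool = False
    min_points: int = 50
    plots: bool = False
    log_level: str = "INFO"
    seed: int = 0

    def fit_config(self) -> FitConfig:
        return FitConfig(
            n_starts=self.n_starts, xtol=self.xtol, ftol=self.ftol,
            max_iter=self.max_iter, seed=self.seed,
            co_optimize_pose=self.co_optimize_pose,
        )

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["variants"] = list(self.variants)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        if "variants" in d:
            d["variants"] = tuple(d["variants"])
        return cls(**d)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def stage_simulate(
    output_dir,
    n_leaves: int = 20,
    variant_truth: str = "SGE1",
    n_points: int = 2000,
    noise_sd_rel: float = 0.01,
    seed: int = 0,
) -> Path:
    """Generate a synthetic population into ``output_dir`` (+ truth.csv)."""
    design = SimulationDesign(
        n_leaves=n_leaves,
        variant_truth=variant_truth,
        n_points=n_points,
        noise_sd_rel=noise_sd_rel,
        seed=seed,
    )
    contours, truth = generate_population(design)
    return write_population(contours, truth, output_dir)


def stage_fit(config: PipelineConfig) -> pd.DataFrame:
    """Fit the requested variants to every contour file; write fits.csv."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    dialect = ReadDialect(min_points=config.min_points)
    contours = read_contour_directory(config.input_dir, dialect=dialect)
    if not contours:
        raise FileNotFoundError(
            f"no contour files found in {config.input_dir!r}"
        )
    fit_config = config.fit_config()
    records = []
    failures = 0
    for contour in contours:
        try:
            fits = fit_leaf(contour, variants=config.variants,
                            config=fit_config)
        except Exception:
            failures += 1
            logger.exception("fit failed for leaf %s; excluded",
                             contour.leaf_id)
            continue
        for variant in sorted(fits, key=lambda v: v.value):
            records.append(fits[variant].to_record())
    if not records:
        raise RuntimeError("all leaves failed to fit; aborting")
    logger.info("fitted %d leaves (%d excluded)", len(contours) - failures,
                failures)
    fits_df = pd.DataFrame(records).sort_values(
        ["leaf_id", "variant"], kind="stable").reset_index(drop=True)
    _write_csv(fits_df, out / "fits.csv")
    return fits_df


def _fit_result_from_record(rec: dict) -> FitResult:
    variant = SGEVariant.coerce(rec["variant"])
    estimate = GielisParameters(
        rec["a"], rec["n1"], rec["n2"], rec["n3"], variant
    )
    return FitResult(
        leaf_id=str(rec["leaf_id"]),
        variant=variant,
        estimate=estimate,
        pole=np.array([rec["pole_x"], rec["pole_y"]]),
        axis_angle=float(rec["axis_angle"]),
        rss=float(rec["rss"]),
        rmse=float(rec["rmse"]),
        aic=float(rec["aic"]),
        n_obs=int(rec["n_obs"]),
        n_params=int(rec["n_params"]),
        converged=bool(rec["converged"]),
        best_start_index=-1,
        n_function_evals=0,
    )


def stage_diagnose(config: PipelineConfig) -> pd.DataFrame:
    """Nonlinearity diagnostics for every converged fit; diagnostics.csv."""
    out = Path(config.output_dir)
    fits_df = pd.read_csv(out / "fits.csv")
    dialect = ReadDialect(min_points=config.min_points)
    contours = {
        c.leaf_id: c
        for c in read_contour_directory(config.input_dir, dialect=dialect)
    }
    records = []
    failures = 0
    for rec in fits_df.to_dict("records"):
        fit = _fit_result_from_record(rec)
        if not fit.converged:
            failures += 1
            logger.warning("leaf %s (%s) not converged; diagnostics skipped",
                           fit.leaf_id, fit.variant.value)
            continue
        try:
            polar = to_polar(contours[fit.leaf_id], fit.pole, fit.axis_angle)
            report = diagnose(polar, fit, alpha=config.alpha,
                              bias_threshold_pct=config.bias_threshold_pct)
        except Exception:
            failures += 1
            logger.exception("diagnostics failed for leaf %s (%s); excluded",
                             fit.leaf_id, fit.variant.value)
            continue
        records.append(report.to_record())
    if not records:
        raise RuntimeError("all diagnostics failed; aborting")
    logger.info("diagnosed %d fits (%d excluded)", len(records), failures)
    diag_df = pd.DataFrame(records).sort_values(
        ["leaf_id", "variant"], kind="stable").reset_index(drop=True)
    _write_csv(diag_df, out / "diagnostics.csv")
    return diag_df


def _merged_per_leaf(out: Path) -> pd.DataFrame:
    fits_df = pd.read_csv(out / "fits.csv")
    diag_path = out / "diagnostics.csv"
    if diag_path.exists():
        diag_df = pd.read_csv(diag_path)
        return fits_df.merge(diag_df, on=["leaf_id", "variant"], how="left")
    return fits_df


def stage_compare(config: PipelineConfig) -> BatchSummary:
    """Aggregate fits + diagnostics; write summary/metrics/pairwise files."""
    out = Path(config.output_dir)
    per_leaf = _merged_per_leaf(out)
    summary = summarize_batch(per_leaf, alpha=config.alpha)
    _write_csv(summary.proportions, out / "summary.csv")
    _write_csv(summary.metric_summary, out / "metrics.csv")
    tests = summary.pairwise_tests.to_dict("records")
    with open(out / "pairwise_tests.json", "w", encoding="utf-8") as fh:
        json.dump(tests, fh, indent=2, default=float)
        fh.write("\n")
    if config.plots:
        _write_plots(summary, out)
    return summary


def _write_plots(summary: BatchSummary, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    from .compare import plot_metric_distributions, plot_proportions

    for metric in ("rmse", "aic"):
        ax = plot_metric_distributions(summary, metric)
        ax.figure.savefig(out / f"{metric}_distribution.png", dpi=120)
        plt.close(ax.figure)
    ax = plot_proportions(summary)
    ax.figure.savefig(out / "gammaT_proportions.png", dpi=120)
    plt.close(ax.figure)


def stage_report(config: PipelineConfig) -> BatchSummary:
    """Regenerate the summary from archived per-leaf tables (no refitting)."""
    return stage_compare(config)


def run_pipeline(config: PipelineConfig) -> BatchSummary:
    """fit -> diagnose -> compare, archiving the resolved config."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(),
                                      logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config_used.yaml")
    stage_fit(config)
    stage_diagnose(config)
    return stage_compare(config)
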