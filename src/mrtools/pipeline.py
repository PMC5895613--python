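"""Per-pair orchestration of the full MR analysis and study-grid reporting.

``run_pair`` chains the stages the study design prescribes for one
exposure–outcome pair: instrument selection → harmonization → IVW, MR-Egger
and weighted-median estimation → Cochran's Q → (when heterogeneity p < 0.05)
exclusion of outcome-associated variants and re-estimation → Egger-intercept
pleiotropy flag at p < 0.10 → optional user-supplied locus-exclusion rerun →
optional p-threshold relaxation scan.  ``run_grid`` maps it over an
exposures × outcomes grid, calling a pair significant when its IVW p-value
beats the Bonferroni threshold budget/(n_exposures · n_outcomes) (budget
default 0.005, giving 9.62e-5 for a 13 × 4 grid).

Non-estimable pairs (no overlapping usable variants) are recorded and the
grid continues; nothing here raises for a data-shaped reason.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .estimators import (
    EstimatorError,
    MRResult,
    egger,
    ivw_fixed,
    wald_ratio,
    weighted_median,
)
from .harmonize import HarmonizationConfig, HarmonizedPair, harmonize_set
from .sensitivity import (
    EGGER_INTERCEPT_ALPHA,
    HETEROGENEITY_ALPHA,
    ExclusionRerun,
    FStatistic,
    HeterogeneityResult,
    SensitivityReport,
    cochran_q,
    exclusion_rerun,
    f_statistic,
    threshold_scan,
)
from .sumstats import InstrumentSet, VariantAssociation, select_instruments

logger = logging.getLogger("mrtools")

__all__ = [
    "RunConfig",
    "PairReport",
    "StudyReport",
    "bonferroni_threshold",
    "run_pair",
    "run_grid",
    "export_plot_data",
]


@dataclass(frozen=True)
class RunConfig:
    """Analysis settings for one pair (and the grid's multiplicity budget)."""

    seed: int
    p_threshold: float = 5e-8
    clump_window: int = 1_000_000
    harmonization: HarmonizationConfig = field(default_factory=HarmonizationConfig)
    boot_reps: int = 1000
    bonferroni_budget: float = 0.005
    n_exposures: int = 13
    n_outcomes: int = 4
    outcome_p_cutoff: float = 0.05
    exclusion_list: tuple[str, ...] = ()
    scan_thresholds: tuple[float, ...] = ()
    exposure_r2: float | None = None
    exposure_n: int | None = None

    def __post_init__(self) -> None:
        for thr in (self.p_threshold, *self.scan_thresholds):
            if not (0 < thr < 1):
                raise ValueError(f"threshold {thr} outside (0,1)")
        if not (0 < self.bonferroni_budget < 1):
            raise ValueError("bonferroni_budget must be in (0,1)")


def bonferroni_threshold(budget: float, n_exposures: int, n_outcomes: int) -> float:
    """Family-wise significance threshold budget / (n_exposures · n_outcomes)."""
    if not (0 < budget < 1):
        raise ValueError(f"budget must be in (0,1), got {budget}")
    if n_exposures < 1 or n_outcomes < 1:
        raise ValueError("test counts must be >= 1")
    return budget / (n_exposures * n_outcomes)


@dataclass
class PairReport:
    """Everything computed for one exposure–outcome pair."""

    exposure_name: str
    outcome_name: str
    config: RunConfig
    n_instruments: int = 0
    harmonization_summary: dict = field(default_factory=dict)
    pairs: list[HarmonizedPair] = field(default_factory=list)
    results: dict[str, MRResult] = field(default_factory=dict)
    sensitivity: SensitivityReport | None = None
    user_exclusion_results: dict[str, MRResult] | None = None
    scan: list[dict] | None = None
    significance_threshold: float | None = None
    significant: bool | None = None
    estimable: bool = True
    non_estimable_reason: str = ""

    @property
    def usable_pairs(self) -> list[HarmonizedPair]:
        return [p for p in self.pairs if not p.excluded]

    def to_dict(self) -> dict:
        """JSON-ready view; deterministic for a given config and seed."""

        def conv(obj: Any) -> Any:
            if isinstance(obj, (MRResult, HeterogeneityResult, FStatistic, HarmonizationConfig)):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (SensitivityReport, ExclusionRerun)):
                return {k: conv(v) for k, v in vars(obj).items()}
            if isinstance(obj, RunConfig):
                d = dataclasses.asdict(obj)
                d["harmonization"] = dataclasses.asdict(obj.harmonization)
                return d
            if isinstance(obj, dict):
                return {k: conv(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [conv(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return {
            "exposure": self.exposure_name,
            "outcome": self.outcome_name,
            "config": conv(self.config),
            "n_instruments": self.n_instruments,
            "harmonization": conv(self.harmonization_summary),
            "results": conv(self.results),
            "sensitivity": conv(self.sensitivity),
            "user_exclusion_results": conv(self.user_exclusion_results),
            "scan": conv(self.scan),
            "significance_threshold": self.significance_threshold,
            "significant": self.significant,
            "estimable": self.estimable,
            "non_estimable_reason": self.non_estimable_reason,
        }


def _estimate_all(
    pairs: Sequence[HarmonizedPair], cfg: RunConfig
) -> dict[str, MRResult]:
    results: dict[str, MRResult] = {"ivw_fixed": ivw_fixed(pairs)}
    try:
        results["egger"] = egger(pairs)
    except EstimatorError as exc:
        logger.info("MR-Egger skipped: %s", exc)
    try:
        results["weighted_median"] = weighted_median(
            pairs, boot_reps=cfg.boot_reps, seed=cfg.seed
        )
    except EstimatorError as exc:
        logger.info("weighted median skipped: %s", exc)
    return results


def run_pair(
    exposure_assocs: Sequence[VariantAssociation] | InstrumentSet,
    outcome_assocs: Sequence[VariantAssociation],
    cfg: RunConfig,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
    preselected: bool = False,
) -> PairReport:
    """Run the full cascade for one exposure–outcome pair.

    ``exposure_assocs`` may be a raw association table (instruments are then
    selected with the config's threshold and clump window) or an existing
    :class:`InstrumentSet` / pre-filtered list (``preselected=True`` skips
    re-selection).  Deterministic given the config (the seed drives the
    weighted-median bootstrap).
    """
    report = PairReport(exposure_name=exposure_name, outcome_name=outcome_name, config=cfg)
    report.significance_threshold = bonferroni_threshold(
        cfg.bonferroni_budget, cfg.n_exposures, cfg.n_outcomes
    )

    if isinstance(exposure_assocs, InstrumentSet):
        instruments = exposure_assocs
    elif preselected:
        instruments = InstrumentSet(exposure_name=exposure_name, variants=list(exposure_assocs))
    else:
        instruments = select_instruments(
            exposure_assocs,
            p_threshold=cfg.p_threshold,
            clump_window=cfg.clump_window,
            exposure_name=exposure_name,
        )
    report.n_instruments = len(instruments)
    logger.info("%s -> %s: %d instruments selected", exposure_name, outcome_name, len(instruments))

    pairs, summary = harmonize_set(instruments, outcome_assocs, cfg.harmonization)
    report.pairs = pairs
    report.harmonization_summary = summary
    usable = report.usable_pairs
    logger.info("harmonization: %s", {k: summary[k] for k in ("matched", "retained", "missing")})

    if not usable:
        report.estimable = False
        report.non_estimable_reason = "no usable harmonized pairs"
        report.significant = None
        return report

    report.results = _estimate_all(usable, cfg)
    ivw = report.results["ivw_fixed"]
    report.significant = bool(ivw.pvalue < report.significance_threshold)

    het: HeterogeneityResult | None = None
    rerun = None
    if len(usable) >= 2:
        het = cochran_q(usable, ivw)
        logger.info("Cochran's Q=%.3f (df=%d, p=%.3g)", het.Q, het.df, het.pvalue)
        if het.pvalue < HETEROGENEITY_ALPHA:
            rerun = exclusion_rerun(
                usable,
                outcome_p_cutoff=cfg.outcome_p_cutoff,
                boot_reps=cfg.boot_reps,
                seed=cfg.seed,
            )
            logger.info(
                "heterogeneity triggered rerun without %d outcome-associated variants",
                len(rerun.excluded_variants),
            )

    fstat = None
    if cfg.exposure_r2 is not None and cfg.exposure_n is not None and report.n_instruments >= 1:
        fstat = f_statistic(cfg.exposure_r2, cfg.exposure_n, report.n_instruments)

    egger_flag = None
    if "egger" in report.results:
        egger_flag = bool(report.results["egger"].intercept_p < EGGER_INTERCEPT_ALPHA)

    if het is not None:
        report.sensitivity = SensitivityReport(
            heterogeneity=het,
            f_statistic=fstat,
            egger_pleiotropy_flag=egger_flag,
            rerun=rerun,
        )

    if cfg.exclusion_list:
        kept = [p for p in usable if p.variant_id not in set(cfg.exclusion_list)]
        if kept:
            report.user_exclusion_results = _estimate_all(kept, cfg)

    if cfg.scan_thresholds:
        if isinstance(exposure_assocs, InstrumentSet) or preselected:
            logger.warning("threshold scan skipped: needs the full exposure table")
        else:
            report.scan = threshold_scan(
                exposure_assocs,
                outcome_assocs,
                sorted(cfg.scan_thresholds),
                harmonization=cfg.harmonization,
                clump_window=cfg.clump_window,
                boot_reps=cfg.boot_reps,
                seed=cfg.seed,
            )
    return report


@dataclass
class StudyReport:
    """Grid of pair reports plus the shared significance threshold."""

    pairs: list[PairReport]
    threshold: float

    def significant_pairs(self) -> list[PairReport]:
        return [p for p in self.pairs if p.significant]

    def table(self) -> pd.DataFrame:
        """One row per (pair, method), mirroring a results-table layout."""
        rows = []
        for rep in self.pairs:
            for method, res in rep.results.items():
                rows.append(
                    {
                        "exposure": rep.exposure_name,
                        "outcome": rep.outcome_name,
                        "method": method,
                        "beta": res.beta,
                        "se": res.se,
                        "pvalue": res.pvalue,
                        "n_variants": res.n_variants,
                        "egger_intercept": res.intercept,
                        "egger_intercept_se": res.intercept_se,
                        "egger_intercept_p": res.intercept_p,
                        "heterogeneity_p": (
                            rep.sensitivity.heterogeneity.pvalue if rep.sensitivity else None
                        ),
                        "significant": rep.significant if method == "ivw_fixed" else None,
                    }
                )
        return pd.DataFrame(rows)


def run_grid(
    exposures: dict[str, Sequence[VariantAssociation]],
    outcomes: dict[str, Sequence[VariantAssociation]],
    cfg: RunConfig,
) -> StudyReport:
    """Run every exposure × outcome pair; failures of a single pair are
    recorded as non-estimable, never fatal to the grid."""
    cfg = dataclasses.replace(cfg, n_exposures=len(exposures), n_outcomes=len(outcomes))
    reports = []
    for exp_name, exp_assocs in exposures.items():
        for out_name, out_assocs in outcomes.items():
            reports.append(run_pair(exp_assocs, out_assocs, cfg, exp_name, out_name))
    return StudyReport(
        pairs=reports,
        threshold=bonferroni_threshold(cfg.bonferroni_budget, len(exposures), len(outcomes)),
    )


def export_plot_data(report: PairReport) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Forest, scatter and trend-line tables for one estimable pair.

    * forest: per-variant Wald ratio with 95% CI plus one combined row per
      pooled estimator;
    * scatter: (βx, SEx, βy, SEy) per usable variant;
    * lines: slope/intercept of the IVW (through the origin) and MR-Egger
      trend lines.
    """
    if not report.estimable:
        raise ValueError("cannot export plot data for a non-estimable pair")
    usable = report.usable_pairs
    forest_rows = []
    for p in usable:
        r = wald_ratio(p)
        lo, hi = r.ci()
        forest_rows.append(
            {"variant_id": p.variant_id, "kind": "variant", "beta": r.beta,
             "se": r.se, "ci_lower": lo, "ci_upper": hi}
        )
    for method, res in report.results.items():
        lo, hi = res.ci()
        forest_rows.append(
            {"variant_id": f"combined_{method}", "kind": "combined", "beta": res.beta,
             "se": res.se, "ci_lower": lo, "ci_upper": hi}
        )
    scatter = pd.DataFrame(
        {
            "variant_id": [p.variant_id for p in usable],
            "beta_exposure": [p.beta_exposure for p in usable],
            "se_exposure": [p.se_exposure for p in usable],
            "beta_outcome": [p.beta_outcome for p in usable],
            "se_outcome": [p.se_outcome for p in usable],
        }
    )
    line_rows = [
        {"method": "ivw_fixed", "slope": report.results["ivw_fixed"].beta, "intercept": 0.0}
    ]
    if "egger" in report.results:
        e = report.results["egger"]
        line_rows.append({"method": "egger", "slope": e.beta, "intercept": e.intercept})
    return pd.DataFrame(forest_rows), scatter, pd.DataFrame(line_rows)


def plot_pair(report: PairReport, out_prefix: str) -> list[str]:
    """Basic forest and scatter renderings (PNG); returns written paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    forest, scatter, lines = export_plot_data(report)
    paths = []

    fig, ax = plt.subplots(figsize=(6, max(3, 0.25 * len(forest))))
    ypos = np.arange(len(forest))[::-1]
    ax.errorbar(
        forest["beta"], ypos,
        xerr=np.vstack([forest["beta"] - forest["ci_lower"], forest["ci_upper"] - forest["beta"]]),
        fmt="o", markersize=3, lw=1,
    )
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_yticks(ypos)
    ax.set_yticklabels(forest["variant_id"], fontsize=6)
    ax.set_xlabel(f"causal effect on {report.outcome_name} per unit {report.exposure_name}")
    fig.tight_layout()
    p = f"{out_prefix}_forest.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(
        scatter["beta_exposure"], scatter["beta_outcome"],
        xerr=scatter["se_exposure"], yerr=scatter["se_outcome"],
        fmt="o", markersize=3, lw=0.8, alpha=0.7,
    )
    xs = np.linspace(0, scatter["beta_exposure"].max() * 1.05, 50)
    for _, row in lines.iterrows():
        ax.plot(xs, row["intercept"] + row["slope"] * xs, label=row["method"])
    ax.set_xlabel(f"variant effect on {report.exposure_name}")
    ax.set_ylabel(f"variant effect on {report.outcome_name}")
    ax.legend()
    fig.tight_layout()
    p = f"{out_prefix}_scatter.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)
    return paths
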