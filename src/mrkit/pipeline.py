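"""End-to-end orchestration of one MR direction and the bidirectional study.

A direction runs: instrument selection -> harmonization -> the estimator
suite (IVW primary; MR-Egger and weighted median as direction checks) ->
heterogeneity/pleiotropy diagnostics -> the decision gate -> (MR-PRESSO
with outlier pruning and refitting when gated) -> leave-one-out ->
evidence classification.

The gate: when the IVW Q, Egger Q and Egger-intercept p-values all exceed
``gate_alpha`` the estimates stand as fitted; otherwise MR-PRESSO runs,
flagged outliers are pruned, and the estimator suite is refitted on the
pruned set.  PRESSO can additionally run in validation mode on clean sets,
in which case its result is reported but never prunes.

Evidence classification is a reporting label, not a test: ``causal_evidence``
requires IVW p below ``gate_alpha`` and Egger/weighted-median betas whose
signs agree with (or are zero against) the IVW sign, and is never granted
from fewer than 3 instruments.  No multiple-testing adjustment is applied
across directions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .diagnostics import (
    HeterogeneityResult,
    LeaveOneOutResult,
    PleiotropyResult,
    cochran_q,
    egger_intercept_test,
    leave_one_out,
)
from .errors import InsufficientInstrumentsError
from .estimators import MREstimate, egger_estimate, ivw_estimate, wald_ratio, weighted_median_estimate
from .harmonization import HarmonizedSet, harmonize_set
from .instrument_selection import ClumpConfig, InstrumentRecord, select_instruments
from .presso import PressoResult, run_presso
from .summary_data import LDMatrix, Study, TraitAnnotation

__all__ = [
    "DirectionConfig",
    "PipelineConfig",
    "DirectionReport",
    "MRReport",
    "gate_heterogeneity",
    "classify_evidence",
    "run_direction",
    "run_bidirectional",
    "export_report",
]

logger = logging.getLogger(__name__)

CAUSAL_EVIDENCE = "causal_evidence"
NO_EVIDENCE = "no_evidence"


@dataclass(frozen=True)
class DirectionConfig:
    """Per-direction selection settings."""

    clump: ClumpConfig = field(default_factory=ClumpConfig)
    f_min: float | None = 10.0
    assoc_p: float = 5e-8
    confounder_traits: tuple[str, ...] = ()


@dataclass(frozen=True)
class PipelineConfig:
    # forward: a -> b at genome-wide significance with the F filter on;
    # reverse: b -> a at the relaxed threshold with the F filter off,
    # for weakly powered exposures lacking allele frequencies
    forward: DirectionConfig = field(default_factory=DirectionConfig)
    reverse: DirectionConfig = field(
        default_factory=lambda: DirectionConfig(clump=ClumpConfig(p_threshold=5e-6), f_min=None)
    )
    gate_alpha: float = 0.05
    presso_n_sim: int = 1000
    presso_significance: float = 0.05
    presso_validation_mode: bool = True
    wm_n_boot: int = 1000
    seed: int = 20230909

    def __post_init__(self) -> None:
        if not (0 < self.gate_alpha < 1):
            raise ValueError("gate_alpha must be in (0, 1)")


@dataclass
class DirectionReport:
    """Everything computed for one exposure -> outcome direction."""

    exposure_name: str
    outcome_name: str
    instruments: list[InstrumentRecord] = field(default_factory=list)
    harmonized: HarmonizedSet | None = None
    estimates: dict[str, MREstimate] = field(default_factory=dict)
    heterogeneity: dict[str, HeterogeneityResult] = field(default_factory=dict)
    pleiotropy: PleiotropyResult | None = None
    gate_decision: str | None = None  # proceed | run_presso
    presso: PressoResult | None = None
    pruned_snps: list[str] = field(default_factory=list)
    loo: LeaveOneOutResult | None = None
    evidence_class: str = NO_EVIDENCE
    estimable: bool = True
    narrative: list[str] = field(default_factory=list)


@dataclass
class MRReport:
    forward: DirectionReport
    reverse: DirectionReport | None = None


def gate_heterogeneity(
    q_ivw: HeterogeneityResult,
    q_egger: HeterogeneityResult,
    intercept: PleiotropyResult,
    alpha: float = 0.05,
) -> str:
    """``proceed`` iff all three p-values strictly exceed ``alpha``; otherwise
    ``run_presso`` (outlier search and refit)."""
    ps = (q_ivw.pvalue, q_egger.pvalue, intercept.pvalue)
    return "proceed" if all(p > alpha for p in ps) else "run_presso"


def classify_evidence(estimates: dict[str, MREstimate], gate_alpha: float = 0.05) -> str:
    """Causal evidence requires a significant IVW estimate whose direction is
    not contradicted by MR-Egger or the weighted median."""
    ivw = estimates["ivw"]
    if ivw.pvalue >= gate_alpha:
        return NO_EVIDENCE
    sign = np.sign(ivw.beta)
    for method in ("egger", "weighted_median"):
        other = np.sign(estimates[method].beta)
        if other != 0 and other != sign:
            return NO_EVIDENCE
    return CAUSAL_EVIDENCE


def _estimate_suite(h: HarmonizedSet, cfg: PipelineConfig) -> dict[str, MREstimate]:
    return {
        "ivw": ivw_estimate(h),
        "egger": egger_estimate(h),
        "weighted_median": weighted_median_estimate(h, n_boot=cfg.wm_n_boot, seed=cfg.seed),
    }


def run_direction(
    cfg: PipelineConfig,
    exposure: Study,
    outcome: Study,
    ld: LDMatrix,
    annotations: list[TraitAnnotation],
    direction: str = "forward",
    preselected: list[InstrumentRecord] | None = None,
) -> DirectionReport:
    """One full direction.  ``preselected`` bypasses instrument selection for
    inputs that are already a curated instrument table (e.g. a published SNP
    list)."""
    dcfg: DirectionConfig = getattr(cfg, direction)
    report = DirectionReport(exposure_name=exposure.trait_name, outcome_name=outcome.trait_name)

    if preselected is not None:
        report.instruments = preselected
    else:
        report.instruments = select_instruments(
            exposure,
            ld,
            annotations,
            dcfg.clump,
            f_min=dcfg.f_min,
            outcome_trait=outcome.trait_name,
            confounder_traits=set(dcfg.confounder_traits),
            assoc_p=dcfg.assoc_p,
        )
    n_retained = sum(r.retained for r in report.instruments)
    logger.info("%s->%s: %d/%d instruments retained", exposure.trait_name,
                outcome.trait_name, n_retained, len(report.instruments))

    h = harmonize_set(report.instruments, outcome)
    h.exposure_name = exposure.trait_name
    report.harmonized = h
    logger.info("harmonized %d SNPs, dropped %d", h.n_snp, len(h.dropped))

    if h.n_snp < 2:
        report.estimable = False
        report.narrative.append(
            f"not estimable: only {h.n_snp} instrument(s) survived selection and harmonization"
        )
        if h.n_snp == 1:
            exp_i = h.snp_ids[0]
            report.narrative.append(
                "single-instrument Wald ratio reported for reference only"
            )
            report.estimates["wald"] = wald_ratio(
                h.beta_exp[0], h.se_exp[0], h.beta_out[0], h.se_out[0]
            )
        return report

    report.estimates = _estimate_suite(h, cfg) if h.n_snp >= 3 else {"ivw": ivw_estimate(h)}
    if h.n_snp >= 3:
        report.heterogeneity = {"ivw": cochran_q(h, "ivw"), "egger": cochran_q(h, "egger")}
        report.pleiotropy = egger_intercept_test(h)
        report.gate_decision = gate_heterogeneity(
            report.heterogeneity["ivw"], report.heterogeneity["egger"],
            report.pleiotropy, cfg.gate_alpha,
        )
        if report.gate_decision == "run_presso" and h.n_snp >= 4:
            report.presso = run_presso(
                h, n_sim=cfg.presso_n_sim, seed=cfg.seed, significance=cfg.presso_significance
            )
            if report.presso.outliers:
                report.pruned_snps = list(report.presso.outliers)
                h = h.exclude(report.pruned_snps)
                report.harmonized = h
                report.narrative.append(
                    f"PRESSO pruned {len(report.pruned_snps)} outlier SNP(s): "
                    + ", ".join(report.pruned_snps)
                )
                if h.n_snp >= 3:
                    report.estimates = _estimate_suite(h, cfg)
                    report.heterogeneity = {"ivw": cochran_q(h, "ivw"), "egger": cochran_q(h, "egger")}
                    report.pleiotropy = egger_intercept_test(h)
                elif h.n_snp == 2:
                    report.estimates = {"ivw": ivw_estimate(h)}
        elif report.gate_decision == "proceed" and cfg.presso_validation_mode and h.n_snp >= 4:
            # validation-mode PRESSO: reported, never prunes
            report.presso = run_presso(
                h, n_sim=cfg.presso_n_sim, seed=cfg.seed, significance=cfg.presso_significance
            )
        if h.n_snp >= 3:
            report.loo = leave_one_out(h)

    if len(report.estimates) == 3 and h.n_snp >= 3:
        report.evidence_class = classify_evidence(report.estimates, cfg.gate_alpha)
    else:
        report.evidence_class = NO_EVIDENCE
        report.narrative.append("fewer than 3 instruments: causal evidence cannot be claimed")
    return report


def run_bidirectional(
    cfg: PipelineConfig,
    study_a: Study,
    study_b: Study,
    ld_a: LDMatrix,
    ld_b: LDMatrix,
    annotations: list[TraitAnnotation],
) -> MRReport:
    """Forward (a -> b) plus reverse (b -> a) analysis, each with its own
    direction config block."""
    forward = run_direction(cfg, study_a, study_b, ld_a, annotations, direction="forward")
    reverse = run_direction(cfg, study_b, study_a, ld_b, annotations, direction="reverse")
    return MRReport(forward=forward, reverse=reverse)


# ---------------------------------------------------------------------------
# export


def _estimate_row(name: str, e: MREstimate) -> str:
    def f(v):
        return "NA" if v is None else f"{v:.6g}"

    return "\t".join(
        [name, str(e.n_snp), f(e.beta), f(e.se), f(e.ci_low), f(e.ci_high), f(e.pvalue),
         f(e.odds_ratio), f(e.or_ci_low), f(e.or_ci_high)]
    )


def _estimate_dict(e: MREstimate) -> dict:
    return {k: v for k, v in dataclasses.asdict(e).items() if v is not None}


def export_report(report: DirectionReport, outdir: str | Path, cfg: PipelineConfig | None = None) -> None:
    """Write the per-direction tables: estimates, OR/forest table, scatter
    data with fitted lines, leave-one-out table, drop and selection logs,
    and a JSON summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "exposure": report.exposure_name,
        "outcome": report.outcome_name,
        "estimable": report.estimable,
        "evidence_class": report.evidence_class,
        "gate_decision": report.gate_decision,
        "pruned_snps": report.pruned_snps,
        "narrative": report.narrative,
    }
    if cfg is not None:
        summary["config"] = dataclasses.asdict(cfg)

    sel_lines = ["SNP\tP\tF\tSTATUS"]
    for r in report.instruments:
        f_str = "NA" if r.f_stat is None else f"{r.f_stat:.6g}"
        status = "retained" if r.retained else r.exclusion_reason.value
        sel_lines.append(f"{r.snp_id}\t{r.record.pvalue:.6g}\t{f_str}\t{status}")
    (outdir / "instrument_log.tsv").write_text("\n".join(sel_lines) + "\n")

    if report.harmonized is not None:
        report.harmonized.write_drop_log(outdir / "harmonization_drops.tsv")

    if not report.estimable:
        summary["reason"] = report.narrative
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        return

    rows = ["METHOD\tNSNP\tBETA\tSE\tCI_LOW\tCI_HIGH\tP\tOR\tOR_CI_LOW\tOR_CI_HIGH"]
    for name, e in report.estimates.items():
        rows.append(_estimate_row(name, e))
    (outdir / "estimates.tsv").write_text("\n".join(rows) + "\n")
    # forest/OR table, one row per method (odds-ratio view when binary)
    (outdir / "or_table.tsv").write_text("\n".join(rows) + "\n")

    h = report.harmonized
    scatter = ["SNP\tBX\tSEX\tBY\tSEY"]
    for i, snp in enumerate(h.snp_ids):
        scatter.append(
            f"{snp}\t{h.beta_exp[i]:.6g}\t{h.se_exp[i]:.6g}\t{h.beta_out[i]:.6g}\t{h.se_out[i]:.6g}"
        )
    (outdir / "scatter_data.tsv").write_text("\n".join(scatter) + "\n")
    lines = ["METHOD\tINTERCEPT\tSLOPE"]
    for name, e in report.estimates.items():
        lines.append(f"{name}\t{0.0 if e.intercept is None else e.intercept:.6g}\t{e.beta:.6g}")
    (outdir / "fitted_lines.tsv").write_text("\n".join(lines) + "\n")

    if report.loo is not None:
        report.loo.write_tsv(outdir / "leave_one_out.tsv")
    if report.presso is not None:
        report.presso.write_tsv(outdir / "presso.tsv")
        summary["presso"] = {
            "global_pvalue": report.presso.global_pvalue,
            "rss_observed": report.presso.rss_observed,
            "outliers": report.presso.outliers,
            "distortion_pvalue": report.presso.distortion_pvalue,
            "n_sim": report.presso.n_sim,
            "seed": report.presso.seed,
        }

    summary["estimates"] = {k: _estimate_dict(e) for k, e in report.estimates.items()}
    summary["heterogeneity"] = {
        k: dataclasses.asdict(v) for k, v in report.heterogeneity.items()
    }
    if report.pleiotropy is not None:
        summary["pleiotropy"] = dataclasses.asdict(report.pleiotropy)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
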