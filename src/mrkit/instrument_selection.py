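"""Instrument selection for two-sample MR.

Candidate SNPs pass four stages, in fixed order:

1. genome-wide significance filter (p strictly below the threshold;
   5e-8 conventionally, relaxed to 5e-6 for weakly powered traits),
2. greedy LD clumping (keep the lowest-p "leader" per correlated region,
   r2 > 0.001 within a 10,000 kb window by default),
3. confounder screening against an annotation table (drop SNPs associated
   with the outcome, or with at least two listed risk factors, at p < 5e-8),
4. weak-instrument filter on the per-SNP F statistic (strict F > 10;
   skipped when effect-allele frequencies or the filter itself are
   unavailable/disabled).

Excluded SNPs are kept with the first exclusion reason that fired, so the
selection log can be exported alongside the retained instruments.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, replace

from .errors import ValidationError
from .summary_data import LDMatrix, Study, SummaryRecord, TraitAnnotation

__all__ = [
    "ClumpConfig",
    "ExclusionReason",
    "InstrumentRecord",
    "filter_by_pvalue",
    "clump_greedy",
    "exclude_confounded",
    "compute_f_statistic",
    "select_instruments",
]

logger = logging.getLogger(__name__)


class ExclusionReason(str, enum.Enum):
    ABOVE_P_THRESHOLD = "above_p_threshold"
    CLUMPED = "clumped"
    OUTCOME_ASSOCIATED = "outcome_associated"
    MULTI_CONFOUNDER = "multi_confounder"
    WEAK_INSTRUMENT = "weak_instrument"


@dataclass(frozen=True)
class ClumpConfig:
    """Significance and LD-clumping thresholds."""

    p_threshold: float = 5e-8
    r2_threshold: float = 0.001
    window_kb: float = 10_000.0

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise ValidationError(f"p_threshold must be in (0,1), got {self.p_threshold}")
        if not (0 <= self.r2_threshold <= 1):
            raise ValidationError(f"r2_threshold must be in [0,1], got {self.r2_threshold}")
        if not self.window_kb > 0:
            raise ValidationError(f"window_kb must be > 0, got {self.window_kb}")


@dataclass(frozen=True)
class InstrumentRecord:
    """A candidate instrument together with its selection outcome."""

    record: SummaryRecord
    f_stat: float | None = None
    exclusion_reason: ExclusionReason | None = None

    @property
    def retained(self) -> bool:
        return self.exclusion_reason is None

    @property
    def snp_id(self) -> str:
        return self.record.snp_id


def filter_by_pvalue(study: Study, p_threshold: float) -> list[InstrumentRecord]:
    """Keep SNPs with association p strictly below ``p_threshold``."""
    if not (0 < p_threshold < 1):
        raise ValidationError(f"p_threshold must be in (0,1), got {p_threshold}")
    out = []
    for rec in study:
        reason = None if rec.pvalue < p_threshold else ExclusionReason.ABOVE_P_THRESHOLD
        out.append(InstrumentRecord(record=rec, exclusion_reason=reason))
    return out


def _within_window(a: SummaryRecord, b: SummaryRecord, window_kb: float) -> bool:
    # Positions are advisory: when either SNP lacks coordinates the distance
    # rule cannot exclude the pair, so clumping falls back to r2 alone.
    if a.chrom is None or b.chrom is None or a.pos is None or b.pos is None:
        return True
    return a.chrom == b.chrom and abs(a.pos - b.pos) < window_kb * 1000


def clump_greedy(
    records: list[InstrumentRecord], ld: LDMatrix, cfg: ClumpConfig
) -> list[InstrumentRecord]:
    """Greedy LD clumping: repeatedly promote the lowest-p unassigned SNP to
    index and mark every unassigned SNP correlated with it (r2 > threshold
    within the distance window) as clumped.

    Ties on p break lexicographically on snp_id, so the retained set does not
    depend on input order.  SNPs absent from ``ld`` are treated as independent.
    """
    candidates = [r for r in records if r.retained]
    missing = [r.snp_id for r in candidates if r.snp_id not in ld]
    if missing:
        logger.warning("%d SNP(s) absent from LD matrix, treated as independent: %s",
                       len(missing), ", ".join(missing))
    order = sorted(candidates, key=lambda r: (r.record.pvalue, r.snp_id))
    assigned: dict[str, ExclusionReason | None] = {}
    for index in order:
        if index.snp_id in assigned:
            continue
        assigned[index.snp_id] = None
        for other in order:
            if other.snp_id in assigned:
                continue
            if ld.get(index.snp_id, other.snp_id, default=0.0) > cfg.r2_threshold and _within_window(
                index.record, other.record, cfg.window_kb
            ):
                assigned[other.snp_id] = ExclusionReason.CLUMPED
    out = []
    for r in records:
        if not r.retained:
            out.append(r)
        else:
            out.append(replace(r, exclusion_reason=assigned[r.snp_id]))
    return out


def exclude_confounded(
    records: list[InstrumentRecord],
    annotations: list[TraitAnnotation],
    outcome_trait: str,
    confounder_traits: set[str],
    assoc_p: float = 5e-8,
) -> list[InstrumentRecord]:
    """Drop SNPs reported as associated (p < ``assoc_p``) with the outcome,
    or with at least two distinct confounder traits.  A single confounder
    association is tolerated."""
    known = {outcome_trait} | set(confounder_traits)
    unknown = sorted({a.trait for a in annotations} - known)
    if unknown:
        logger.warning("ignoring annotations for unknown trait(s): %s", ", ".join(unknown))
    hits: dict[str, set[str]] = {}
    outcome_hit: set[str] = set()
    for a in annotations:
        if a.pvalue >= assoc_p:
            continue
        if a.trait == outcome_trait:
            outcome_hit.add(a.snp_id)
        elif a.trait in confounder_traits:
            hits.setdefault(a.snp_id, set()).add(a.trait)
    out = []
    for r in records:
        if not r.retained:
            out.append(r)
        elif r.snp_id in outcome_hit:
            out.append(replace(r, exclusion_reason=ExclusionReason.OUTCOME_ASSOCIATED))
        elif len(hits.get(r.snp_id, ())) >= 2:
            out.append(replace(r, exclusion_reason=ExclusionReason.MULTI_CONFOUNDER))
        else:
            out.append(r)
    return out


def compute_f_statistic(record: SummaryRecord, method: str = "wald") -> float:
    """Per-SNP instrument-strength F statistic.

    ``wald`` (default) is the summary-data proxy F = (beta/se)^2 and needs no
    allele frequency.  ``variance_explained`` uses
    R2 = 2*eaf*(1-eaf)*beta^2 and F = R2*(N-2)/(1-R2), valid for a
    standardized continuous trait; it requires eaf and n.
    """
    if method == "wald":
        return (record.beta / record.se) ** 2
    if method == "variance_explained":
        if record.eaf is None or record.n is None:
            raise ValidationError(
                f"{record.snp_id}: variance_explained F requires eaf and n"
            )
        r2 = 2 * record.eaf * (1 - record.eaf) * record.beta**2
        if r2 >= 1:
            raise ValidationError(f"{record.snp_id}: variance explained >= 1; trait not standardized?")
        return r2 * (record.n - 2) / (1 - r2)
    raise ValidationError(f"unknown F-statistic method {method!r}")


def select_instruments(
    study: Study,
    ld: LDMatrix,
    annotations: list[TraitAnnotation],
    cfg: ClumpConfig,
    f_min: float | None = 10.0,
    outcome_trait: str = "",
    confounder_traits: set[str] | None = None,
    assoc_p: float = 5e-8,
    f_method: str = "wald",
) -> list[InstrumentRecord]:
    """Full selection cascade: p filter -> LD clumping -> confounder
    exclusion -> F filter (strict F > ``f_min``; ``f_min=None`` disables,
    F statistics are still computed and recorded)."""
    recs = filter_by_pvalue(study, cfg.p_threshold)
    recs = clump_greedy(recs, ld, cfg)
    recs = exclude_confounded(recs, annotations, outcome_trait, confounder_traits or set(), assoc_p)
    out = []
    for r in recs:
        f = compute_f_statistic(r.record, method=f_method)
        reason = r.exclusion_reason
        if reason is None and f_min is not None and not f > f_min:
            reason = ExclusionReason.WEAK_INSTRUMENT
        out.append(replace(r, f_stat=f, exclusion_reason=reason))
    if not any(r.retained for r in out):
        logger.warning("no instruments retained for %s", study.trait_name)
    return out
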