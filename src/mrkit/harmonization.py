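"""Allele harmonization between exposure and outcome summary statistics.

Two-sample MR combines effect estimates from different GWAS, which may
report the same SNP on opposite alleles or opposite strands.  Harmonization
orients every outcome effect to the exposure's effect allele:

* identical allele pair — keep as is;
* swapped pair — flip the sign of the outcome beta (and eaf -> 1 - eaf);
* strand-complement pair (direct or swapped after A<->T / C<->G mapping) —
  complement, then apply the same rules;
* palindromic SNPs (A/T or C/G) — dropped unconditionally, since allele
  labels alone cannot resolve the strand;
* anything else — dropped as an allele mismatch.

Exposure records are never altered; only outcome effects flip.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import MRKitError, ValidationError
from .instrument_selection import InstrumentRecord
from .summary_data import VALID_BASES, Study, SummaryRecord

__all__ = ["DropReason", "HarmonizedSet", "classify_palindromic", "harmonize_pair", "harmonize_set"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class DropReason(str, enum.Enum):
    PALINDROMIC = "palindromic"
    ALLELE_MISMATCH = "allele_mismatch"
    MISSING_IN_OUTCOME = "missing_in_outcome"


@dataclass
class HarmonizedSet:
    """Exposure/outcome effects aligned to a common effect allele per SNP.

    The four vectors are index-aligned with ``snp_ids``; ``dropped`` logs
    the SNPs that did not survive with the reason.
    """

    snp_ids: list[str]
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    exposure_name: str = ""
    outcome_name: str = ""
    outcome_binary: bool = False
    dropped: list[tuple[str, DropReason]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beta_exp = np.asarray(self.beta_exp, dtype=float)
        self.se_exp = np.asarray(self.se_exp, dtype=float)
        self.beta_out = np.asarray(self.beta_out, dtype=float)
        self.se_out = np.asarray(self.se_out, dtype=float)
        n = len(self.snp_ids)
        for name in ("beta_exp", "se_exp", "beta_out", "se_out"):
            if getattr(self, name).shape != (n,):
                raise ValidationError(f"{name} must have length {n}")
        if n and (np.any(self.se_exp <= 0) or np.any(self.se_out <= 0)):
            raise ValidationError("all standard errors must be > 0")

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)

    def exclude(self, snp_ids: set[str] | list[str]) -> "HarmonizedSet":
        """A copy without the listed SNPs (used by leave-one-out and PRESSO pruning)."""
        drop = set(snp_ids)
        keep = [i for i, s in enumerate(self.snp_ids) if s not in drop]
        return HarmonizedSet(
            snp_ids=[self.snp_ids[i] for i in keep],
            beta_exp=self.beta_exp[keep],
            se_exp=self.se_exp[keep],
            beta_out=self.beta_out[keep],
            se_out=self.se_out[keep],
            exposure_name=self.exposure_name,
            outcome_name=self.outcome_name,
            outcome_binary=self.outcome_binary,
            dropped=list(self.dropped),
        )

    def write_drop_log(self, path: str | Path) -> None:
        lines = ["SNP\tREASON"] + [f"{s}\t{r.value}" for s, r in self.dropped]
        Path(path).write_text("\n".join(lines) + "\n")


def classify_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is strand-ambiguous ({A,T} or {C,G})."""
    if effect_allele not in VALID_BASES or other_allele not in VALID_BASES:
        raise ValidationError(f"invalid bases {effect_allele!r}/{other_allele!r}")
    return {effect_allele, other_allele} in ({"A", "T"}, {"C", "G"})


def harmonize_pair(
    exp: SummaryRecord, out: SummaryRecord
) -> SummaryRecord | DropReason:
    """Orient one outcome record to the exposure's effect allele.

    Returns the (possibly flipped) outcome record, or a :class:`DropReason`.
    """
    if exp.snp_id != out.snp_id:
        raise MRKitError(f"snp_id mismatch: {exp.snp_id} vs {out.snp_id}")
    if classify_palindromic(exp.effect_allele, exp.other_allele):
        return DropReason.PALINDROMIC
    ea, oa = out.effect_allele, out.other_allele
    if (ea, oa) not in ((exp.effect_allele, exp.other_allele), (exp.other_allele, exp.effect_allele)):
        ea, oa = _COMPLEMENT[ea], _COMPLEMENT[oa]  # try the opposite strand
    if (ea, oa) == (exp.effect_allele, exp.other_allele):
        return replace(out, effect_allele=ea, other_allele=oa)
    if (ea, oa) == (exp.other_allele, exp.effect_allele):
        return replace(
            out,
            effect_allele=oa,
            other_allele=ea,
            beta=-out.beta,
            eaf=None if out.eaf is None else 1 - out.eaf,
        )
    return DropReason.ALLELE_MISMATCH


def harmonize_set(instruments: list[InstrumentRecord], outcome: Study) -> HarmonizedSet:
    """Align every retained instrument with its outcome record.

    Instruments absent from the outcome study are dropped as
    ``missing_in_outcome``; vector order follows instrument order.
    """
    snp_ids: list[str] = []
    bx, sx, by, sy = [], [], [], []
    dropped: list[tuple[str, DropReason]] = []
    for inst in instruments:
        if not inst.retained:
            continue
        exp = inst.record
        if exp.snp_id not in outcome:
            dropped.append((exp.snp_id, DropReason.MISSING_IN_OUTCOME))
            continue
        result = harmonize_pair(exp, outcome[exp.snp_id])
        if isinstance(result, DropReason):
            dropped.append((exp.snp_id, result))
            continue
        snp_ids.append(exp.snp_id)
        bx.append(exp.beta)
        sx.append(exp.se)
        by.append(result.beta)
        sy.append(result.se)
    return HarmonizedSet(
        snp_ids=snp_ids,
        beta_exp=np.array(bx),
        se_exp=np.array(sx),
        beta_out=np.array(by),
        se_out=np.array(sy),
        outcome_name=outcome.trait_name,
        outcome_binary=outcome.is_binary,
        dropped=dropped,
    )
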