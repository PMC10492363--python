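"""Heterogeneity, pleiotropy and sensitivity diagnostics.

* **Cochran's Q** — weighted sum of squared residuals around the fitted IVW
  (df = n-1) or MR-Egger (df = n-2) line, with weights 1/se_out^2 matching
  the fit; p from the upper chi-square tail.  Large Q flags instruments
  whose ratio estimates disagree beyond chance — a symptom of pleiotropy or
  of invalid instruments.
* **Egger intercept test** — t test of the MR-Egger intercept against zero
  (n-2 df); a nonzero intercept indicates directional pleiotropy.
* **Leave-one-out** — the IVW estimate recomputed with each instrument
  removed in turn, to expose estimates driven by a single SNP.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import InsufficientInstrumentsError, ValidationError
from .estimators import egger_estimate, ivw_estimate, _egger_fit, _ivw_fit
from .harmonization import HarmonizedSet

__all__ = [
    "HeterogeneityResult",
    "PleiotropyResult",
    "LOORow",
    "LeaveOneOutResult",
    "cochran_q",
    "egger_intercept_test",
    "leave_one_out",
]


@dataclass(frozen=True)
class HeterogeneityResult:
    method: str  # ivw | egger
    q: float
    df: int
    pvalue: float

    def __post_init__(self) -> None:
        if self.q < 0:
            raise ValidationError("Q must be >= 0")


@dataclass(frozen=True)
class PleiotropyResult:
    intercept: float
    intercept_se: float
    pvalue: float

    def __post_init__(self) -> None:
        if not self.intercept_se > 0:
            raise ValidationError("intercept SE must be > 0")


@dataclass(frozen=True)
class LOORow:
    excluded: str  # snp_id or "ALL"
    beta: float
    se: float
    pvalue: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class LeaveOneOutResult:
    rows: tuple[LOORow, ...]

    def write_tsv(self, path: str | Path) -> None:
        lines = ["EXCLUDED\tBETA\tSE\tP\tCI_LOW\tCI_HIGH"]
        for r in self.rows:
            lines.append(
                f"{r.excluded}\t{r.beta:.6g}\t{r.se:.6g}\t{r.pvalue:.6g}\t{r.ci_low:.6g}\t{r.ci_high:.6g}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


def cochran_q(h: HarmonizedSet, method: str = "ivw") -> HeterogeneityResult:
    """Cochran's Q around the IVW or Egger fit; p = chi-square upper tail."""
    w = 1.0 / h.se_out**2
    if method == "ivw":
        if h.n_snp < 2:
            raise InsufficientInstrumentsError("Q (IVW) needs >= 2 instruments")
        slope, _, _ = _ivw_fit(h)
        resid = h.beta_out - slope * h.beta_exp
        df = h.n_snp - 1
    elif method == "egger":
        if h.n_snp < 3:
            raise InsufficientInstrumentsError("Q (Egger) needs >= 3 instruments")
        coef, _, _ = _egger_fit(h)
        sign = np.where(h.beta_exp < 0, -1.0, 1.0)
        resid = sign * h.beta_out - (coef[0] + coef[1] * sign * h.beta_exp)
        df = h.n_snp - 2
    else:
        raise ValidationError(f"unknown heterogeneity method {method!r}")
    q = float(np.sum(w * resid**2))
    return HeterogeneityResult(method, q, df, float(stats.chi2.sf(q, df)))


def egger_intercept_test(h: HarmonizedSet) -> PleiotropyResult:
    """Directional-pleiotropy test from the MR-Egger intercept row."""
    est = egger_estimate(h)
    return PleiotropyResult(est.intercept, est.intercept_se, est.intercept_p)


def leave_one_out(h: HarmonizedSet) -> LeaveOneOutResult:
    """IVW re-estimated excluding each SNP in turn, plus the full-set ALL row."""
    if h.n_snp < 3:
        raise InsufficientInstrumentsError("leave-one-out needs >= 3 instruments")
    rows = []
    for snp in h.snp_ids:
        est = ivw_estimate(h.exclude([snp]))
        rows.append(LOORow(snp, est.beta, est.se, est.pvalue, est.ci_low, est.ci_high))
    full = ivw_estimate(h)
    rows.append(LOORow("ALL", full.beta, full.se, full.pvalue, full.ci_low, full.ci_high))
    return LeaveOneOutResult(tuple(rows))
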