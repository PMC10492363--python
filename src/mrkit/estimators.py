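"""Causal-effect estimators for two-sample MR on harmonized summary data.

Given per-SNP exposure effects b_Xj (SE s_Xj) and outcome effects b_Yj
(SE s_Yj), the estimators are:

* **Wald ratio** — single-SNP estimate b_Yj / b_Xj with the first-order
  delta SE s_Yj / |b_Xj|.
* **IVW** — weighted least-squares regression of b_Y on b_X through the
  origin with weights w_j = 1/s_Yj^2; the closed-form slope is
  sum(w b_X b_Y) / sum(w b_X^2).  The default SE multiplies the
  fixed-effect SE 1/sqrt(sum(w b_X^2)) by the residual scale, floored at 1
  (multiplicative random effects that collapse to the fixed-effect SE under
  underdispersion).  Pure ``fixed`` and ``random`` modes are also exposed.
* **MR-Egger** — the same weighted regression with an unconstrained
  intercept, after orienting all exposure effects positive; the intercept
  estimates directional pleiotropy and inference uses the t distribution
  with n-2 df.  Like IVW, the coefficient covariance floors the residual
  scale at 1.
* **Weighted median** — the weighted median of per-SNP Wald ratios with
  second-order delta-method variances
  V_j = s_Yj^2/b_Xj^2 + b_Yj^2 s_Xj^2 / b_Xj^4 as inverse weights;
  consistent when valid instruments carry >= 50% of the weight.  Its SE
  comes from a parametric bootstrap.

When the outcome is binary the beta scale is log odds and estimates carry
an exponentiated odds-ratio view.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .errors import InsufficientInstrumentsError, UndefinedRatioError, ValidationError
from .harmonization import HarmonizedSet

__all__ = [
    "MREstimate",
    "wald_ratio",
    "ivw_estimate",
    "egger_estimate",
    "weighted_median_estimate",
    "to_odds_ratio",
    "Z_95",
]

#: two-sided 95% normal quantile used throughout
Z_95 = 1.959964

DEFAULT_N_BOOT = 1000
DEFAULT_BOOT_SEED = 20230909


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate on the beta scale, with optional OR view."""

    method: str  # wald | ivw | egger | weighted_median
    beta: float
    se: float
    pvalue: float
    ci_low: float
    ci_high: float
    n_snp: int
    odds_ratio: float | None = None
    or_ci_low: float | None = None
    or_ci_high: float | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValidationError(f"estimate SE must be > 0, got {self.se}")
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValidationError("CI must bracket the point estimate")


def _normal_inference(beta: float, se: float) -> tuple[float, float, float]:
    p = 2 * stats.norm.sf(abs(beta) / se)
    return p, beta - Z_95 * se, beta + Z_95 * se


def wald_ratio(
    beta_exp: float, se_exp: float, beta_out: float, se_out: float
) -> MREstimate:
    """Single-SNP causal estimate beta_out/beta_exp (first-order delta SE)."""
    if beta_exp == 0:
        raise UndefinedRatioError("Wald ratio undefined: exposure effect is zero")
    beta = beta_out / beta_exp
    se = se_out / abs(beta_exp)
    p, lo, hi = _normal_inference(beta, se)
    return MREstimate("wald", beta, se, p, lo, hi, n_snp=1)


def _ivw_fit(h: HarmonizedSet) -> tuple[float, float, float]:
    """Slope, fixed-effect SE, and residual scale phi of the origin-constrained WLS."""
    w = 1.0 / h.se_out**2
    sxx = float(np.sum(w * h.beta_exp**2))
    slope = float(np.sum(w * h.beta_exp * h.beta_out)) / sxx
    se_fixed = 1.0 / np.sqrt(sxx)
    resid = h.beta_out - slope * h.beta_exp
    phi = float(np.sum(w * resid**2)) / (h.n_snp - 1) if h.n_snp > 1 else np.nan
    return slope, se_fixed, phi


def ivw_estimate(h: HarmonizedSet, se_mode: str = "floored") -> MREstimate:
    """Inverse-variance-weighted estimate over >= 2 instruments.

    ``se_mode``: ``floored`` (default) multiplies the fixed-effect SE by
    max(1, sqrt(phi)) where phi is the residual mean square; ``fixed`` and
    ``random`` use scale 1 and phi respectively.
    """
    if h.n_snp < 2:
        raise InsufficientInstrumentsError(
            "IVW needs >= 2 instruments; use wald_ratio for a single SNP"
        )
    slope, se_fixed, phi = _ivw_fit(h)
    scale = {"floored": max(1.0, np.sqrt(phi)), "fixed": 1.0, "random": np.sqrt(phi)}.get(se_mode)
    if scale is None:
        raise ValidationError(f"unknown se_mode {se_mode!r}")
    se = se_fixed * scale
    p, lo, hi = _normal_inference(slope, se)
    est = MREstimate("ivw", slope, se, p, lo, hi, n_snp=h.n_snp)
    return to_odds_ratio(est) if h.outcome_binary else est


def _egger_fit(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, float]:
    """Coefficients (intercept, slope), their SEs with the residual scale
    floored at 1, and the residual mean square, after orienting b_X >= 0."""
    sign = np.where(h.beta_exp < 0, -1.0, 1.0)
    bx, by = sign * h.beta_exp, sign * h.beta_out
    w = 1.0 / h.se_out**2
    X = np.column_stack([np.ones(h.n_snp), bx])
    xtwx = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(xtwx, X.T @ (w * by))
    resid = by - X @ coef
    df = h.n_snp - 2
    s2 = float(np.sum(w * resid**2)) / df
    cov = np.linalg.inv(xtwx) * max(1.0, s2)
    return coef, np.sqrt(np.diag(cov)), s2


def egger_estimate(h: HarmonizedSet) -> MREstimate:
    """MR-Egger regression: slope = causal estimate, intercept = average
    directional pleiotropy; t inference with n-2 df."""
    if h.n_snp < 3:
        raise InsufficientInstrumentsError("MR-Egger needs >= 3 instruments")
    coef, ses, _ = _egger_fit(h)
    (a, b), (se_a, se_b) = coef, ses
    df = h.n_snp - 2
    p = 2 * stats.t.sf(abs(b) / se_b, df)
    tq = stats.t.ppf(0.975, df)
    est = MREstimate(
        "egger",
        float(b),
        float(se_b),
        float(p),
        float(b - tq * se_b),
        float(b + tq * se_b),
        n_snp=h.n_snp,
        intercept=float(a),
        intercept_se=float(se_a),
        intercept_p=float(2 * stats.t.sf(abs(a) / se_a, df)),
    )
    return to_odds_ratio(est) if h.outcome_binary else est


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Cumulative-weight interpolation of the 50% point."""
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order]
    w = w / w.sum()
    cum = np.cumsum(w) - w / 2
    return float(np.interp(0.5, cum, r))


def _wm_point(bx, sx, by, sy) -> float:
    if np.any(bx == 0):
        raise UndefinedRatioError("weighted median undefined: some exposure effect is zero")
    ratios = by / bx
    var = sy**2 / bx**2 + by**2 * sx**2 / bx**4  # second-order delta method
    return _weighted_median(ratios, 1.0 / var)


def weighted_median_estimate(
    h: HarmonizedSet,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = DEFAULT_BOOT_SEED,
) -> MREstimate:
    """Weighted-median estimate; SE from a parametric bootstrap that redraws
    both effect vectors from normal distributions at their reported SEs.

    The point estimate is deterministic; only the SE (hence p and CI)
    depends on ``(n_boot, seed)``.
    """
    if h.n_snp < 3:
        raise InsufficientInstrumentsError("weighted median needs >= 3 instruments")
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    if np.any(h.beta_exp == 0):
        bad = h.snp_ids[int(np.argmax(h.beta_exp == 0))]
        raise UndefinedRatioError(f"exposure effect is zero for {bad}")
    point = _wm_point(h.beta_exp, h.se_exp, h.beta_out, h.se_out)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bx = rng.normal(h.beta_exp, h.se_exp)
        by = rng.normal(h.beta_out, h.se_out)
        bx = np.where(bx == 0, np.finfo(float).tiny, bx)
        boots[i] = _wm_point(bx, h.se_exp, by, h.se_out)
    se = float(np.std(boots, ddof=1)) if n_boot > 1 else float("nan")
    if not se > 0:  # degenerate bootstrap (e.g. n_boot == 1)
        se = np.finfo(float).tiny
    p, lo, hi = _normal_inference(point, se)
    est = MREstimate("weighted_median", point, se, p, lo, hi, n_snp=h.n_snp)
    return to_odds_ratio(est) if h.outcome_binary else est


def to_odds_ratio(e: MREstimate, outcome_binary: bool = True) -> MREstimate:
    """Attach the exponentiated odds-ratio view for a binary outcome.

    For a continuous outcome this is a no-op: effects stay on the beta scale,
    as is conventional when the outcome is not a disease state.
    """
    if not outcome_binary:
        return e
    return replace(
        e,
        odds_ratio=float(np.exp(e.beta)),
        or_ci_low=float(np.exp(e.ci_low)),
        or_ci_high=float(np.exp(e.ci_high)),
    )
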