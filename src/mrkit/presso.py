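"""MR-PRESSO: pleiotropy residual sum and outlier test.

The procedure detects horizontal pleiotropy as excess residual variation
around the IVW fit, using a parametric simulation of the no-pleiotropy
model:

1. **Global test** — for each SNP j, fit IVW on the set excluding j to get
   a leave-one-out slope; the observed statistic is the weighted residual
   sum of squares RSS = sum_j w_j (b_Yj - slope_{-j} * b_Xj)^2 with
   w_j = 1/se_Yj^2.  Simulated datasets redraw b*_Xj ~ N(b_Xj, se_Xj) and
   b*_Yj ~ N(slope_{-j} * b_Xj, se_Yj), recomputing the leave-one-out RSS
   each time; the Monte-Carlo p is (1 + #{RSS* >= RSS_obs}) / (1 + n_sim),
   so it can never be exactly zero.
2. **Outlier test** — the same simulated residuals give a per-SNP empirical
   p, Bonferroni-adjusted across SNPs; SNPs below the significance level
   are flagged as pleiotropic outliers.
3. **Distortion test** — when outliers exist, compares the raw IVW slope
   against the outlier-pruned slope, calibrated against removing the same
   number of random SNPs.

All simulation is vectorized and reproducible from ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InsufficientInstrumentsError, ValidationError
from .estimators import MREstimate, ivw_estimate
from .harmonization import HarmonizedSet

__all__ = ["PressoResult", "presso_global", "presso_outlier", "presso_distortion", "run_presso"]


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """IVW slope excluding each SNP in turn; vectorized over a trailing axis.

    Accepts 1-D vectors or (n_sim, n) matrices with per-column weights.
    """
    sxy = np.sum(w * bx * by, axis=-1, keepdims=True)
    sxx = np.sum(w * bx * bx, axis=-1, keepdims=True)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


@dataclass
class PressoResult:
    """Accumulating result of the PRESSO triad."""

    rss_observed: float
    global_pvalue: float
    n_sim: int
    seed: int
    snp_ids: list[str]
    obs_resid2: np.ndarray  # per-SNP observed weighted squared residual
    per_snp_pvalues: np.ndarray | None = None
    per_snp_pvalues_bonf: np.ndarray | None = None
    outliers: list[str] = field(default_factory=list)
    distortion_pvalue: float | None = None
    distortion_pct: float | None = None
    estimate_raw: MREstimate | None = None
    estimate_outlier_corrected: MREstimate | None = None
    # simulated per-SNP weighted squared residuals, shape (n_sim, n_snp);
    # retained so the outlier test can reuse the global-test draws
    sim_resid2: np.ndarray | None = None

    def write_tsv(self, path: str | Path) -> None:
        lines = [f"#GLOBAL\tRSS={self.rss_observed:.6g}\tP={self.global_pvalue:.6g}\tN_SIM={self.n_sim}"]
        lines.append("SNP\tOBS_RESID\tP_RAW\tP_BONF\tOUTLIER")
        for i, snp in enumerate(self.snp_ids):
            praw = f"{self.per_snp_pvalues[i]:.6g}" if self.per_snp_pvalues is not None else "NA"
            pb = f"{self.per_snp_pvalues_bonf[i]:.6g}" if self.per_snp_pvalues_bonf is not None else "NA"
            lines.append(f"{snp}\t{self.obs_resid2[i]:.6g}\t{praw}\t{pb}\t{snp in self.outliers}")
        Path(path).write_text("\n".join(lines) + "\n")


def presso_global(h: HarmonizedSet, n_sim: int = 1000, seed: int = 0) -> PressoResult:
    """Global pleiotropy test; retains per-SNP simulated residuals for the
    outlier test."""
    if h.n_snp < 4:
        raise InsufficientInstrumentsError("MR-PRESSO needs >= 4 instruments")
    if n_sim < 100:
        raise ValidationError("n_sim must be >= 100")
    w = 1.0 / h.se_out**2
    slopes = _loo_slopes(h.beta_exp, h.beta_out, w)
    obs_resid2 = w * (h.beta_out - slopes * h.beta_exp) ** 2
    rss_obs = float(obs_resid2.sum())

    rng = np.random.default_rng(seed)
    bx_sim = rng.normal(h.beta_exp, h.se_exp, size=(n_sim, h.n_snp))
    by_sim = rng.normal(slopes * h.beta_exp, h.se_out, size=(n_sim, h.n_snp))
    slopes_sim = _loo_slopes(bx_sim, by_sim, w)
    sim_resid2 = w * (by_sim - slopes_sim * bx_sim) ** 2
    rss_sim = sim_resid2.sum(axis=1)
    global_p = (1 + int(np.sum(rss_sim >= rss_obs))) / (1 + n_sim)

    return PressoResult(
        rss_observed=rss_obs,
        global_pvalue=global_p,
        n_sim=n_sim,
        seed=seed,
        snp_ids=list(h.snp_ids),
        obs_resid2=obs_resid2,
        sim_resid2=sim_resid2,
    )


def presso_outlier(result: PressoResult, significance: float = 0.05) -> PressoResult:
    """Per-SNP outlier test on the retained simulation draws.

    Per-SNP p = (1 + #{sim residual^2 >= observed}) / (1 + n_sim), Bonferroni
    adjusted; SNPs with adjusted p < ``significance`` are flagged.
    """
    if result.sim_resid2 is None:
        raise ValidationError("run presso_global first (simulated residuals required)")
    exceed = np.sum(result.sim_resid2 >= result.obs_resid2[None, :], axis=0)
    p_raw = (1 + exceed) / (1 + result.n_sim)
    p_bonf = np.minimum(1.0, p_raw * len(result.snp_ids))
    result.per_snp_pvalues = p_raw
    result.per_snp_pvalues_bonf = p_bonf
    result.outliers = [s for s, p in zip(result.snp_ids, p_bonf) if p < significance]
    return result


def presso_distortion(
    h: HarmonizedSet, outliers: list[str], n_sim: int = 1000, seed: int = 0
) -> tuple[float | None, float | None]:
    """Distortion test: is the shift from pruning the flagged outliers larger
    than pruning as many random SNPs?

    Returns ``(distortion_pct, pvalue)``; ``(None, None)`` when there are no
    outliers to prune.
    """
    if not outliers:
        return None, None
    raw = ivw_estimate(h).beta
    corrected = ivw_estimate(h.exclude(outliers)).beta
    if corrected == 0:
        raise ValidationError("distortion undefined: corrected estimate is zero")
    obs = (raw - corrected) / abs(corrected) * 100.0
    rng = np.random.default_rng(seed)
    k = len(outliers)
    null = np.empty(n_sim)
    ids = np.array(h.snp_ids)
    for i in range(n_sim):
        drop = rng.choice(ids, size=k, replace=False)
        b = ivw_estimate(h.exclude(list(drop))).beta
        null[i] = (raw - b) / abs(b) * 100.0 if b != 0 else np.inf
    p = (1 + int(np.sum(np.abs(null) >= abs(obs)))) / (1 + n_sim)
    return float(obs), float(p)


def run_presso(
    h: HarmonizedSet, n_sim: int = 1000, seed: int = 0, significance: float = 0.05
) -> PressoResult:
    """Full triad: global test, outlier test, and (when outliers are found)
    the distortion test with raw vs outlier-corrected IVW estimates."""
    result = presso_outlier(presso_global(h, n_sim=n_sim, seed=seed), significance)
    result.estimate_raw = ivw_estimate(h)
    # the corrected refit needs >= 2 surviving SNPs; under gross contamination
    # the outlier test can flag nearly everything, in which case only the raw
    # estimate and the outlier list are reportable
    if result.outliers and h.n_snp - len(result.outliers) >= 2:
        result.estimate_outlier_corrected = ivw_estimate(h.exclude(result.outliers))
        result.distortion_pct, result.distortion_pvalue = presso_distortion(
            h, result.outliers, n_sim=n_sim, seed=seed + 1
        )
    return result
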