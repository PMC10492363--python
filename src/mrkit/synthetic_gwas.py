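"""Synthetic paired GWAS summary statistics with known ground truth.

The generator emulates the two-sample setting the estimators assume: an
exposure GWAS and an independent outcome GWAS over the same SNP panel, tied
together by a known causal effect theta and an optional horizontal-pleiotropy
mixture.

Per SNP j:

* maf_j ~ Uniform(maf_range); alleles drawn, a configurable fraction of
  pairs strand-ambiguous (A/T or C/G);
* true SNP->exposure effect gamma_j ~ Normal(0, gamma_sd^2);
* exposure sampling SE se_Xj = 1/sqrt(2 maf_j (1-maf_j) n_exp) — the
  standard-error model for a unit-variance trait — and observed
  b_Xj ~ Normal(gamma_j, se_Xj^2);
* direct (pleiotropic) outcome effect alpha_j = 0 with probability 1 - pi,
  else Normal(mu_alpha, sigma_alpha^2); drawing alpha independently of
  gamma satisfies the InSIDE assumption MR-Egger relies on.  A nonzero
  mu_alpha is directional *relative to the exposure-increasing allele*
  (the direct effect enters as sign(gamma_j) * alpha_j), since allele
  coding is otherwise arbitrary and a fixed-sign shift on arbitrarily
  coded alleles would average out;
* outcome SE se_Yj of the same form at n_out, inflated by
  1/sqrt(cf (1-cf)) for a binary outcome with case fraction cf (log-odds
  scale), and observed b_Yj ~ Normal(theta * gamma_j + alpha_j, se_Yj^2);
* p-values are two-sided normal tests of beta/se.

Positions are laid out on one chromosome in blocks of ``ld_block_size``
consecutive SNPs; :func:`simulate_ld_matrix` gives those blocks a constant
within-block r2, zero across blocks.  Ground truth (theta, gamma, alpha) is
returned separately and never embedded in the Study objects, so pipeline
code cannot accidentally read it.

Defaults mirror the motivating study: an exposure GWAS of N = 375,833
(coffee consumption) against a binary outcome GWAS of N = 49,066 with case
fraction 0.36 (periodontitis, GLIDE).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import ValidationError
from .summary_data import LDMatrix, Study, SummaryRecord, TraitAnnotation

__all__ = ["SyntheticConfig", "simulate_summary_pair", "simulate_ld_matrix", "simulate_annotations"]

_NONPALINDROMIC_PAIRS = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"),
                         ("C", "A"), ("C", "T"), ("G", "A"), ("G", "T")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for one paired exposure/outcome dataset."""

    n_snps: int = 100
    theta: float = 0.1
    n_exp: int = 375_833
    n_out: int = 49_066
    outcome_binary: bool = True
    case_fraction: float = 17_672 / 49_066
    maf_range: tuple[float, float] = (0.05, 0.5)
    gamma_sd: float = 0.02
    pleiotropy_prob: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    ld_block_size: int = 1
    ld_r2: float = 0.0
    palindromic_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps <= 0 or self.n_exp <= 0 or self.n_out <= 0:
            raise ValidationError("n_snps, n_exp, n_out must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValidationError("maf_range must satisfy 0 < low <= high <= 0.5")
        for name in ("gamma_sd", "pleiotropy_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("pleiotropy_prob", "palindromic_prob", "ld_r2"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.outcome_binary and not (0 < self.case_fraction < 1):
            raise ValidationError("case_fraction must be in (0, 1) for a binary outcome")
        if self.ld_block_size < 1:
            raise ValidationError("ld_block_size must be >= 1")


def _pvalue(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2 * stats.norm.sf(np.abs(beta) / se)
    return np.maximum(p, np.finfo(float).tiny)  # keep p in (0, 1]


def simulate_summary_pair(cfg: SyntheticConfig) -> tuple[Study, Study, dict]:
    """Draw one paired exposure/outcome summary dataset.

    Returns ``(exposure, outcome, truth)`` where ``truth`` holds theta and
    the per-SNP gamma/alpha/maf vectors.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_snps
    maf = rng.uniform(*cfg.maf_range, size=n)
    gamma = rng.normal(0.0, cfg.gamma_sd, size=n)
    se_x = 1.0 / np.sqrt(2 * maf * (1 - maf) * cfg.n_exp)
    beta_x = rng.normal(gamma, se_x)
    pleio = rng.random(n) < cfg.pleiotropy_prob
    alpha = np.where(pleio, rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=n), 0.0)
    se_y = 1.0 / np.sqrt(2 * maf * (1 - maf) * cfg.n_out)
    if cfg.outcome_binary:
        se_y /= np.sqrt(cfg.case_fraction * (1 - cfg.case_fraction))
    # directional pleiotropy acts on the exposure-increasing orientation
    beta_y = rng.normal(cfg.theta * gamma + np.sign(gamma) * alpha, se_y)

    palindromic = rng.random(n) < cfg.palindromic_prob
    pairs = [
        _PALINDROMIC_PAIRS[rng.integers(len(_PALINDROMIC_PAIRS))]
        if pal
        else _NONPALINDROMIC_PAIRS[rng.integers(len(_NONPALINDROMIC_PAIRS))]
        for pal in palindromic
    ]
    # consecutive blocks of ld_block_size SNPs, 1 Mb apart within a block,
    # 100 Mb between blocks -> within-block pairs sit inside a 10,000 kb window
    positions = [
        1 + (j // cfg.ld_block_size) * 100_000_000 + (j % cfg.ld_block_size) * 1_000_000
        for j in range(n)
    ]

    px, py = _pvalue(beta_x, se_x), _pvalue(beta_y, se_y)
    exposure = Study("synthetic_exposure", "continuous", n_total=cfg.n_exp)
    outcome = Study(
        "synthetic_outcome",
        "binary" if cfg.outcome_binary else "continuous",
        n_total=cfg.n_out,
    )
    if cfg.outcome_binary:
        outcome.n_cases = round(cfg.case_fraction * cfg.n_out)
        outcome.n_controls = cfg.n_out - outcome.n_cases
    for j in range(n):
        ea, oa = pairs[j]
        common = dict(snp_id=f"rs{j + 1}", effect_allele=ea, other_allele=oa,
                      chrom="1", pos=positions[j], eaf=float(maf[j]))
        exposure.add(SummaryRecord(beta=float(beta_x[j]), se=float(se_x[j]),
                                   pvalue=float(px[j]), n=cfg.n_exp, **common))
        outcome.add(SummaryRecord(beta=float(beta_y[j]), se=float(se_y[j]),
                                  pvalue=float(py[j]), n=cfg.n_out, **common))
    truth = {
        "theta": cfg.theta,
        "gamma": gamma.tolist(),
        "alpha": alpha.tolist(),
        "maf": maf.tolist(),
        "config": asdict(cfg),
    }
    return exposure, outcome, truth


def simulate_ld_matrix(cfg: SyntheticConfig) -> LDMatrix:
    """Block-diagonal r2 matrix matching the generator's position layout."""
    n = cfg.n_snps
    block = np.arange(n) // cfg.ld_block_size
    r2 = np.where(block[:, None] == block[None, :], cfg.ld_r2, 0.0)
    np.fill_diagonal(r2, 1.0)
    return LDMatrix([f"rs{j + 1}" for j in range(n)], r2)


def simulate_annotations(
    cfg: SyntheticConfig, traits: list[str], hit_prob: float
) -> tuple[list[TraitAnnotation], dict]:
    """Random SNP-trait annotation table for confounder-screening tests.

    Each SNP is linked to each trait independently with probability
    ``hit_prob`` at a genome-wide-significant p (~1e-10).  Returns the
    annotations plus a truth map {snp_id: [traits]}.
    """
    if not (0 <= hit_prob <= 1):
        raise ValidationError("hit_prob must be in [0, 1]")
    rng = np.random.default_rng(cfg.seed + 1)
    annotations: list[TraitAnnotation] = []
    truth: dict[str, list[str]] = {}
    for j in range(cfg.n_snps):
        snp = f"rs{j + 1}"
        for trait in traits:
            if rng.random() < hit_prob:
                annotations.append(TraitAnnotation(snp, trait, 1e-10))
                truth.setdefault(snp, []).append(trait)
    return annotations, truth


def write_truth_json(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1))
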