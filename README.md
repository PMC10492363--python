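# mrkit

Two-sample bidirectional Mendelian randomization (MR) from GWAS summary
statistics, for epidemiologists who want a tested, scriptable pipeline:
instrument selection (significance filter, LD clumping, confounder
screening, F-statistic filter), allele harmonization with palindromic-SNP
dropping, the IVW / MR-Egger / weighted-median estimator suite,
heterogeneity and pleiotropy diagnostics (Cochran's Q, Egger intercept,
leave-one-out), a full MR-PRESSO reimplementation (global, outlier and
distortion tests), and a synthetic summary-statistics generator with known
ground truth for validation.

The core estimate is the inverse-variance-weighted (IVW) slope over n
instruments with exposure effects β_Xj (SE σ_Xj) and outcome effects β_Yj
(SE σ_Yj), weights w_j = 1/σ_Yj²:

    θ̂ = Σ w_j β_Xj β_Yj / Σ w_j β_Xj²

with the residual scale of its SE floored at 1 (multiplicative random
effects collapsing to the fixed-effect SE under underdispersion). MR-Egger
adds an unconstrained intercept (directional-pleiotropy estimate, t
inference at n−2 df) and the weighted median interpolates the per-SNP Wald
ratios β_Yj/β_Xj at cumulative weight 0.5 using second-order delta-method
variances. For binary outcomes, effects are log odds and estimates carry an
OR = exp(θ̂) view. See `docs/methods.md` for the full model, conventions
and limitations.

The package ships the published 8-instrument table for continuous coffee
consumption (N = 375,833) against periodontitis from the GLIDE consortium
(N = 49,066; binary, no effect-allele frequencies) as its worked example.

## Worked example

```python
from mrkit import (
    load_table1_fixture, harmonize_set, ivw_estimate,
    egger_estimate, weighted_median_estimate,
)
from mrkit.instrument_selection import InstrumentRecord
from mrkit.diagnostics import cochran_q, egger_intercept_test

exposure, outcome = load_table1_fixture()          # 8 SNPs, coffee -> periodontitis
h = harmonize_set([InstrumentRecord(record=r) for r in exposure], outcome)

ivw = ivw_estimate(h)
print(f"IVW     OR {ivw.odds_ratio:.4f} (95% CI {ivw.or_ci_low:.4f}-{ivw.or_ci_high:.4f}) p={ivw.pvalue:.4f}")
print(f"Egger   OR {egger_estimate(h).odds_ratio:.4f}, intercept p={egger_intercept_test(h).pvalue:.4f}")
print(f"WMedian OR {weighted_median_estimate(h).odds_ratio:.4f}")
print(f"Q(IVW) p={cochran_q(h, 'ivw').pvalue:.4f}  Q(Egger) p={cochran_q(h, 'egger').pvalue:.4f}")
```

prints

```
IVW     OR 1.0104 (95% CI 1.0016-1.0194) p=0.0212
Egger   OR 1.0004, intercept p=0.5192
WMedian OR 1.0077
Q(IVW) p=0.9605  Q(Egger) p=0.9582
```

i.e. per SD of coffee consumed the odds of periodontitis rise by about
1.04%, the IVW estimate is significant at 0.05, both validation estimators
point the same way, and neither heterogeneity (Q) nor directional
pleiotropy (Egger intercept) is detected — so the IVW estimate stands
without outlier pruning.

There is also a CLI (`mrkit simulate | select | harmonize | estimate | run`);
`mrkit run --config cfg.yaml --outdir out/` executes a whole direction (or
`direction: both`) from TSV inputs and writes estimate/diagnostic tables,
scatter and leave-one-out data, drop logs and a JSON summary.

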