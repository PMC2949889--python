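# hawkestre

Multivariate nonlinear Hawkes process models for the occurrence of
transcriptional regulatory elements (TREs) along the genome.

## The problem

ChIP-seq / ChIP-chip experiments locate the enriched regions bound by
transcription factors, cofactors and histone marks.  Reducing each
enriched region to its midpoint turns the data for K regulators into a
marked point process along each chromosome: a sequence of positions, each
labelled by the TRE it belongs to.  The scientific question is how the
occurrence of one TRE modulates the *local rate* of occurrence of the
others — which pairs attract or avoid each other, at which distances, and
whether an observed pairwise association is direct or mediated by the
other TREs in the model.  Binning- or clustering-based co-occurrence
analyses answer this only at the scale of the bins; a conditional-
intensity model answers it at base-pair resolution without any
pre-aggregation.

## The model

For mark k in window i (a chromosome or an analysis region), the
conditional intensity is log-linear in the history and covariates:

    log λ_k^{(i)}(t) = (α^{(i)k})' X_i(t) + Σ_m Σ_{s ∈ N_m^{(i)}, s < t} h^{mk}(t − s)

* `X_i(t)` contains a constant (so the first α element is the log
  baseline rate, shared across windows or per-window) and optional {0,1}
  indicator covariates such as histone-modification tracks; the
  fold-change of the baseline due to covariate j is γ_j^k = exp(α_j^k).
* Each transfer function `h^{mk}` is a cubic spline, `h(t) = β' B(t)`,
  on 8 simple equidistant knots spanning −400 to 1000 bp — 4 free
  coefficients per ordered pair, and no dependence beyond 1000 bp.
* `g_{m,k}(s) = exp(h^{mk}(s))` is the multiplicative effect of an
  upstream mark-m point on mark k at downstream distance s: g > 1 means
  the distance is favored, g < 1 avoided, g ≡ 1 means mark k is *locally
  independent* of mark m given the remaining marks.

The exact log-likelihood `l = Σ_events log λ − ∫ λ` is concave in the
parameters; it is discretized by a midpoint rule at resolution r,
assembled into one large sparse design matrix, and maximized per mark by
L-BFGS with analytic gradients.  Standard errors come from the inverse
observed information; `H0: g_{m,k} = 1` is tested by a likelihood-ratio
statistic referred to χ²(4), with Holm correction across all K² ordered
pairs.  TREs are grouped by Ward clustering of the integrated absolute
transfer functions `H^{mk} = ∫₀^1000 |h^{mk}|`.  A thinning sampler
(with a linear cap on the intensity that prevents explosion) simulates
from the model for calibration and power studies.

## Worked example

```python
import numpy as np
from hawkestre import HawkesPointProcess, make_synthetic_dataset

# two marks; planted transfer g_{A,B} peaking at 3 near lag 200 bp
dataset, truth = make_synthetic_dataset("one_pair_excitation", seed=3)
model = HawkesPointProcess(dataset, resolution=5.0)
res = model.fit()
print(res.summary())

band = res.g_function("tfA", "tfB")          # curve + pointwise 95% band
print(round(band.estimate.max(), 2))          # -> 3.75  (truth: 3.0)

table = res.test_all_pairs(alpha=0.05)       # 4 LRTs, Holm-corrected
print(table[["source", "target", "Q", "p_raw", "holm_reject"]])
```

Output of the fit summary and test table:

```
Multivariate Hawkes process fit
======================================
windows: 10  baseline mode: shared  resolution: 5 bp
spline: 8 knots on [-400, 1000], 4 basis functions

mark tfA: n = 1018, loglik = -10372.766, converged = True
  baseline rate: 0.0001011 / bp

mark tfB: n = 1081, loglik = -10906.470, converged = True
  baseline rate: 0.0001014 / bp

  source target          Q         p_raw  holm_reject
0    tfA    tfA   4.017501  4.036425e-01        False
1    tfB    tfA   2.409016  6.609986e-01        False
2    tfA    tfB  88.790362  2.379182e-18         True
3    tfB    tfB   5.065911  2.806012e-01        False
```

Only the planted pair tfA→tfB is declared locally dependent
(Q = 88.8 on 4 df).  The fitted peak fold-change 3.75 overshoots the
planted 3.0 in this particular draw — the pointwise 95% band covers the
true curve at 92% of lags here — and the estimated baseline rates match
the simulated 1e-4/bp.

The same analyses run from the shell on BED inputs:

```sh
hawkestre simulate --preset one_pair_excitation --seed 3 --out sim/
hawkestre fit  --tre tfA=sim/tfA.bed --tre tfB=sim/tfB.bed \
               --windows sim/windows.bed --resolution 5 --out fit/
hawkestre test --tre tfA=sim/tfA.bed --tre tfB=sim/tfB.bed \
               --windows sim/windows.bed --resolution 5 --out fit/
hawkestre cluster --fit fit/fit.json --out fit/
```

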