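"""Fit results: uncertainty, local-independence testing, summaries.

The MLE is asymptotically normal with covariance estimated by the inverse
of the negative log-likelihood Hessian at the optimum.  Pointwise 95%
confidence bands for a transfer function use

    h(t) +/- z_{0.975} sqrt( B(t)' Sigma B(t) )

exponentiated to the g scale.  Local independence of mark k on mark m
(H0: g_{m,k} = 1, i.e. beta^{mk} = 0) is tested by the likelihood-ratio
statistic Q = 2 (l_full - l_reduced), where the reduced model refits all
remaining parameters; Q is referred to a chi-square distribution with
``n_basis`` (default 4) degrees of freedom.  The K^2 tests over all
ordered mark pairs (self-pairs included) are corrected jointly with Holm's
step-down procedure.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .splines import evaluate_h

logger = logging.getLogger(__name__)

Z975 = float(stats.norm.ppf(0.975))

__all__ = ["GFunction", "HawkesResults", "holm_adjust"]


def holm_adjust(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Holm step-down decisions (True = reject) at family-wise level alpha."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((pvalues < 0) | (pvalues > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(pvalues, alpha=alpha, method="holm")
    return reject


@dataclass
class GFunction:
    """An estimated transfer fold-change curve with pointwise 95% band."""

    source: str
    target: str
    lags: np.ndarray
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lag": self.lags,
                "estimate": self.estimate,
                "lower": self.lower,
                "upper": self.upper,
            }
        )

    def plot(self, ax=None):  # pragma: no cover - convenience only
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.fill_between(self.lags, self.lower, self.upper, alpha=0.3)
        ax.plot(self.lags, self.estimate)
        ax.axhline(1.0, color="grey", lw=0.5)
        ax.set_xlabel("lag (bp)")
        ax.set_ylabel(f"g {self.source}->{self.target}")
        return ax


class HawkesResults:
    """Results of a maximum-likelihood Hawkes fit.

    Attributes
    ----------
    params : HawkesParams
        Estimates at the optimum.
    loglik : dict mark -> float
        Maximized per-mark log-likelihood values.
    converged : dict mark -> bool
    """

    def __init__(self, model, params, per_mark: dict, fixed_zero=(), marks=None):
        self.model = model
        self.params = params
        self._per_mark = per_mark
        self.fixed_zero = tuple(fixed_zero)
        self.marks_fitted = tuple(marks) if marks is not None else model.dataset.marks
        self.loglik = {k: info["loglik"] for k, info in per_mark.items()}
        self.converged = {k: info["converged"] for k, info in per_mark.items()}

    # --- accessors ----------------------------------------------------------

    def cov(self, mark: str) -> np.ndarray:
        """Parameter covariance for target mark (inverse observed information)."""
        info = self._per_mark[mark]
        if not info["cov_available"]:
            raise ValueError(f"covariance unavailable for mark {mark!r} (singular Hessian)")
        return info["cov"]

    def total_loglik(self) -> float:
        return float(sum(self.loglik.values()))

    # --- uncertainty --------------------------------------------------------

    def g_function(self, m: str, k: str, lags=None) -> GFunction:
        """Estimated g_{m,k} with pointwise 95% confidence band."""
        spec = self.model.spline
        if lags is None:
            lags = np.arange(0.0, spec.last_knot + 1.0)
        lags = np.asarray(lags, dtype=float)
        h = evaluate_h(lags, self.params.beta[(m, k)], spec)
        B = spec.basis_matrix(lags)
        sl = self.model.layout.beta_cols(m)
        Sig = self.cov(k)[sl, sl]
        var = np.einsum("ij,jk,ik->i", B, Sig, B)
        sd = np.sqrt(np.maximum(var, 0.0))
        return GFunction(
            m, k, lags, np.exp(h), np.exp(h - Z975 * sd), np.exp(h + Z975 * sd)
        )

    def covariate_fold_change(self, k: str, j) -> tuple[float, float, float]:
        """Fold-change gamma = exp(alpha_j^k) with 95% CI."""
        lay = self.model.layout
        if isinstance(j, str):
            j = list(self.params.covariate_names).index(j)
        col = lay.cov_col(j)
        a = float(self.params.alpha[k][j])
        se = float(np.sqrt(max(self.cov(k)[col, col], 0.0)))
        return np.exp(a), np.exp(a - Z975 * se), np.exp(a + Z975 * se)

    # --- testing ------------------------------------------------------------

    def lrt_local_independence(self, m: str, k: str) -> tuple[float, float]:
        """LRT of H0: g_{m,k} = 1 (local independence of N_k on N_m).

        The reduced model refits mark k with beta^{mk} fixed at zero and
        every other parameter free; Q = 2 (l1 - l0) is referred to the
        chi-square distribution with ``n_basis`` degrees of freedom.
        """
        if (m, k) in self.fixed_zero:
            return 0.0, 1.0
        reduced = self.model._fit_mark(k, fixed_zero=self.fixed_zero + ((m, k),))
        if not reduced["converged"]:
            logger.warning("reduced fit for pair (%s, %s) did not converge", m, k)
        q = 2.0 * (self.loglik[k] - reduced["loglik"])
        if q < 0:
            if q < -1e-6:
                warnings.warn(
                    f"negative LRT statistic {q:.3g} for ({m}, {k}) clipped to 0",
                    RuntimeWarning,
                )
            q = 0.0
        df = self.model.spline.n_basis
        return float(q), float(stats.chi2.sf(q, df))

    def test_all_pairs(self, alpha: float = 0.05) -> pd.DataFrame:
        """All K^2 ordered-pair local-independence tests, Holm-corrected.

        Returns a table with one row per ordered pair (source m, target k),
        self-pairs included, with columns Q, df, raw p, and the Holm
        decision over the whole K^2 family at level ``alpha``.
        """
        rows = []
        for k in self.marks_fitted:
            for m in self.model.dataset.marks:
                q, p = self.lrt_local_independence(m, k)
                rows.append({"source": m, "target": k, "Q": q, "df": self.model.spline.n_basis, "p_raw": p})
        table = pd.DataFrame(rows)
        table["holm_reject"] = holm_adjust(table["p_raw"].to_numpy(), alpha)
        return table

    # --- downstream ---------------------------------------------------------

    def interaction_weights(self) -> pd.DataFrame:
        """K x K matrix of integrated absolute transfer functions."""
        from .clustering import interaction_matrix

        return interaction_matrix(self.params)

    def cluster(self, n_clusters: int = 2):
        """Ward clustering of marks on their interaction-weight profiles."""
        from .clustering import cluster_tres

        return cluster_tres(self.interaction_weights(), n_clusters=n_clusters)

    def simulate(self, seed: int, windows=None):
        """Sample a synthetic dataset from the fitted parameters."""
        from .simulate import simulate_dataset

        return simulate_dataset(
            self.params,
            windows or self.model.dataset.windows,
            covariates={
                key: track for key, track in self.model.dataset.covariates.items()
            },
            seed=seed,
        )

    # --- reporting ----------------------------------------------------------

    def summary(self) -> str:
        """Human-readable fit summary (baselines, fold-changes, loglik)."""
        lines = ["Multivariate Hawkes process fit", "=" * 38]
        lines.append(f"windows: {self.model.dataset.n_windows}  "
                     f"baseline mode: {self.model.baseline_mode}  "
                     f"resolution: {self.model.resolution:g} bp")
        spec = self.model.spline
        lines.append(
            f"spline: {spec.n_knots} knots on [{spec.first_knot:g}, "
            f"{spec.last_knot:g}], {spec.n_basis} basis functions"
        )
        for k in self.marks_fitted:
            n = self.model.dataset.n_points(k)
            lines.append("")
            lines.append(f"mark {k}: n = {n}, loglik = {self.loglik[k]:.3f}, "
                         f"converged = {self.converged[k]}")
            lb = self.params.log_baseline[k]
            if lb.size == 1:
                lines.append(f"  baseline rate: {np.exp(lb[0]):.4g} / bp")
            else:
                lines.append(f"  baseline rates: {np.exp(lb.min()):.3g} .. {np.exp(lb.max()):.3g} / bp")
            for j, name in enumerate(self.params.covariate_names):
                try:
                    g, lo, hi = self.covariate_fold_change(k, j)
                    lines.append(f"  gamma[{name}] = {g:.3g}  (95% CI {lo:.3g} - {hi:.3g})")
                except ValueError:
                    lines.append(f"  gamma[{name}]: covariance unavailable")
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        out = {
            "params": self.params.to_dict(),
            "loglik": self.loglik,
            "converged": self.converged,
            "fixed_zero": [list(p) for p in self.fixed_zero],
            "resolution": self.model.resolution,
            "baseline_mode": self.model.baseline_mode,
            "cov": {
                k: info["cov"].tolist() if info["cov_available"] else None
                for k, info in self._per_mark.items()
            },
        }
        text = json.dumps(out, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text
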