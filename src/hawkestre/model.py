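"""Conditional-intensity model, sparse design, and exact log-likelihood.

The intensity for mark k in window i is log-linear in the history and the
covariates:

    log lambda_k^{(i)}(t) = alpha^{(i)k}' X_i(t)
                            + sum_m  sum_{s in N_m^{(i)}, s < t}  h^{mk}(t - s)

where X_i(t) holds a constant (so the first alpha element is the log
baseline, either shared across windows or per-window) and the {0,1}
covariate indicators, and h^{mk} is a cubic spline (see
:mod:`hawkestre.splines`).  The history sum uses the *strict* past: a point
never contributes to its own intensity, and truncates at the left window
edge (no burn-in correction for unobserved upstream points).

The log-likelihood over all windows is

    l = sum_events log lambda(t_j) - integral lambda(s) ds ,

approximated by a midpoint Riemann sum at resolution r.  All row linear
predictors are collected in one large sparse design matrix: one row per
quadrature node (weight ~ r) plus one zero-weight row per event of the
target mark, and one column block per parameter group.  Because the
per-mark likelihood terms share no parameters, each mark is fitted
independently; the log-likelihood is concave in the parameters, so any
local optimum found by the quasi-Newton optimizer is the global MLE.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import minimize

from .data import MarkedPointDataset
from .splines import SplineSpec, evaluate_h

logger = logging.getLogger(__name__)

#: clamp on the linear predictor inside exp() during estimation only; the
#: simulator's linear cap (simulate.capped_intensity) is a model change,
#: this is a numerical overflow guard.
ETA_MAX = 50.0

__all__ = [
    "HawkesParams",
    "ParamLayout",
    "Design",
    "build_design",
    "loglik",
    "score",
    "hessian",
    "linear_predictor",
    "g_function",
    "HawkesPointProcess",
]


@dataclass(frozen=True)
class ParamLayout:
    """Column layout of the per-target-mark parameter vector.

    Order: baseline block (one column, or one per window), covariate
    block, then ``n_basis`` spline coefficients per source mark in mark
    order.
    """

    marks: tuple[str, ...]
    covariate_names: tuple[str, ...]
    n_windows: int
    d_beta: int
    baseline_mode: str = "shared"  # "shared" | "per_window"

    def __post_init__(self):
        if self.baseline_mode not in ("shared", "per_window"):
            raise ValueError(f"unknown baseline_mode {self.baseline_mode!r}")

    @property
    def n_baseline(self) -> int:
        return self.n_windows if self.baseline_mode == "per_window" else 1

    @property
    def n_cov(self) -> int:
        return len(self.covariate_names)

    @property
    def n_params(self) -> int:
        return self.n_baseline + self.n_cov + self.d_beta * len(self.marks)

    def baseline_cols(self) -> slice:
        return slice(0, self.n_baseline)

    def cov_col(self, j: int) -> int:
        return self.n_baseline + j

    def beta_cols(self, m: str) -> slice:
        m_idx = self.marks.index(m)
        lo = self.n_baseline + self.n_cov + m_idx * self.d_beta
        return slice(lo, lo + self.d_beta)


@dataclass
class HawkesParams:
    """Model parameters: log-baselines, covariate effects, spline blocks.

    ``log_baseline[k]`` has length 1 (shared) or ``n_windows``;
    ``alpha[k]`` holds the covariate coefficients (fold-change on the log
    scale, ``gamma = exp(alpha)``); ``beta[(m, k)]`` is the spline
    coefficient vector of the transfer function from mark m to mark k.
    """

    marks: tuple[str, ...]
    covariate_names: tuple[str, ...]
    spline: SplineSpec
    baseline_mode: str = "shared"
    n_windows: int = 1
    log_baseline: dict = field(default_factory=dict)
    alpha: dict = field(default_factory=dict)
    beta: dict = field(default_factory=dict)

    @property
    def layout(self) -> ParamLayout:
        return ParamLayout(
            self.marks,
            self.covariate_names,
            self.n_windows,
            self.spline.n_basis,
            self.baseline_mode,
        )

    @classmethod
    def zeros(cls, marks, spline, covariate_names=(), baseline_mode="shared",
              n_windows=1, log_baseline=None) -> "HawkesParams":
        marks = tuple(marks)
        covariate_names = tuple(covariate_names)
        p = cls(marks, covariate_names, spline, baseline_mode, n_windows)
        nb = n_windows if baseline_mode == "per_window" else 1
        for k in marks:
            p.log_baseline[k] = np.full(nb, 0.0 if log_baseline is None else log_baseline)
            p.alpha[k] = np.zeros(len(covariate_names))
            for m in marks:
                p.beta[(m, k)] = np.zeros(spline.n_basis)
        return p

    def vector(self, k: str) -> np.ndarray:
        """Parameter vector for target mark k in the design-column order."""
        lay = self.layout
        theta = np.zeros(lay.n_params)
        theta[lay.baseline_cols()] = self.log_baseline[k]
        for j in range(lay.n_cov):
            theta[lay.cov_col(j)] = self.alpha[k][j]
        for m in self.marks:
            theta[lay.beta_cols(m)] = self.beta[(m, k)]
        return theta

    def set_vector(self, k: str, theta: np.ndarray) -> None:
        lay = self.layout
        self.log_baseline[k] = np.array(theta[lay.baseline_cols()])
        self.alpha[k] = np.array([theta[lay.cov_col(j)] for j in range(lay.n_cov)])
        for m in self.marks:
            self.beta[(m, k)] = np.array(theta[lay.beta_cols(m)])

    def baseline_for_window(self, k: str, i: int) -> float:
        lb = self.log_baseline[k]
        return float(lb[i] if lb.size > 1 else lb[0])

    def to_dict(self) -> dict:
        return {
            "marks": list(self.marks),
            "covariate_names": list(self.covariate_names),
            "spline": self.spline.to_dict(),
            "baseline_mode": self.baseline_mode,
            "n_windows": self.n_windows,
            "log_baseline": {k: list(v) for k, v in self.log_baseline.items()},
            "alpha": {k: list(v) for k, v in self.alpha.items()},
            "beta": {f"{m}->{k}": list(v) for (m, k), v in self.beta.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HawkesParams":
        p = cls(
            tuple(d["marks"]),
            tuple(d["covariate_names"]),
            SplineSpec.from_dict(d["spline"]),
            d["baseline_mode"],
            d["n_windows"],
        )
        p.log_baseline = {k: np.asarray(v, float) for k, v in d["log_baseline"].items()}
        p.alpha = {k: np.asarray(v, float) for k, v in d["alpha"].items()}
        for key, v in d["beta"].items():
            m, k = key.split("->")
            p.beta[(m, k)] = np.asarray(v, float)
        return p


@dataclass
class Design:
    """Sparse discretized design for one target mark.

    ``X`` has one row per quadrature node and per event of the target
    mark; ``w`` holds the quadrature weights (zero on event rows);
    ``event_rows`` indexes the event rows (used for the sum-log-intensity
    term).
    """

    X: sp.csr_matrix
    w: np.ndarray
    event_rows: np.ndarray
    layout: ParamLayout
    mark: str
    resolution: float

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]


def _window_grid(a: float, b: float, r: float):
    """Midpoint-rule nodes and weights covering [a, b] at resolution r."""
    length = b - a
    n_cells = int(np.ceil(length / r - 1e-12))
    edges = a + r * np.arange(n_cells + 1)
    edges[-1] = b
    nodes = 0.5 * (edges[:-1] + edges[1:])
    weights = np.diff(edges)
    return nodes, weights


def _repeat_ranges(lo: np.ndarray, hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flatten the index ranges [lo_i, hi_i); returns (flat_idx, owner)."""
    counts = hi - lo
    total = int(counts.sum())
    owner = np.repeat(np.arange(lo.size), counts)
    flat = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts) + np.repeat(lo, counts)
    return flat, owner


def _design_block(
    dataset: MarkedPointDataset,
    pos_per_window: list[np.ndarray],
    spline: SplineSpec,
    lay: ParamLayout,
) -> sp.csr_matrix:
    """Sparse design block for arbitrary sorted positions, one array per
    window: baseline indicator, covariate indicators, and per-source-mark
    spline columns ``sum_j B_l(t - t_j^m)`` over source events strictly
    upstream of t within the spline support."""
    reach = spline.last_knot
    offsets = np.cumsum([0] + [p.size for p in pos_per_window])
    n_rows = int(offsets[-1])
    rows_l, cols_l, vals_l = [], [], []
    for i, positions in enumerate(pos_per_window):
        if positions.size == 0:
            continue
        off = offsets[i]
        ridx = off + np.arange(positions.size)
        bcol = i if lay.baseline_mode == "per_window" else 0
        rows_l.append(ridx)
        cols_l.append(np.full(positions.size, bcol))
        vals_l.append(np.ones(positions.size))
        for j, name in enumerate(dataset.covariate_names):
            xv = dataset.covariate_indicator(i, name, positions)
            nz = np.nonzero(xv)[0]
            if nz.size:
                rows_l.append(ridx[nz])
                cols_l.append(np.full(nz.size, lay.cov_col(j)))
                vals_l.append(xv[nz])
        for m in dataset.marks:
            src = dataset.get_points(i, m)
            if src.size == 0:
                continue
            lo = np.searchsorted(positions, src, side="right")
            hi = np.searchsorted(positions, src + reach, side="right")
            flat, owner = _repeat_ranges(lo, hi)
            if flat.size == 0:
                continue
            lags = positions[flat] - src[owner]
            B = spline.basis_matrix(lags)
            cols = lay.beta_cols(m)
            for l in range(spline.n_basis):
                v = B[:, l]
                nz = np.nonzero(v)[0]
                if nz.size:
                    rows_l.append(off + flat[nz])
                    cols_l.append(np.full(nz.size, cols.start + l))
                    vals_l.append(v[nz])
    if rows_l:
        rows = np.concatenate(rows_l)
        cols = np.concatenate(cols_l)
        vals = np.concatenate(vals_l)
    else:  # degenerate: no positions at all
        rows = cols = vals = np.empty(0)
    return sp.coo_matrix(
        (vals, (rows, cols)), shape=(n_rows, lay.n_params)
    ).tocsr()


def _grid_positions(dataset: MarkedPointDataset, resolution: float):
    nodes_l, weights_l = [], []
    for w in dataset.windows:
        nodes, weights = _window_grid(w.a, w.b, resolution)
        nodes_l.append(nodes)
        weights_l.append(weights)
    return nodes_l, weights_l


def build_design(
    dataset: MarkedPointDataset,
    mark: str,
    spline: SplineSpec | None = None,
    resolution: float = 1.0,
    baseline_mode: str = "shared",
    _grid_block=None,
) -> Design:
    """Build the sparse design matrix for target ``mark``.

    Rows: per window, midpoint-rule quadrature nodes at
    ``a + r/2, a + 3r/2, ...`` (last cell truncated at ``b``) carrying the
    cell width as quadrature weight, followed by one zero-weight row per
    event of the target mark.  The grid block is identical for every
    target mark and can be passed in pre-built (``_grid_block``) to avoid
    recomputation.
    """
    spline = spline or SplineSpec()
    if resolution < 1e-9:
        raise ValueError("resolution must be positive")
    shortest = min(w.length for w in dataset.windows)
    if resolution > shortest:
        raise ValueError(
            f"resolution {resolution} exceeds shortest window length {shortest}"
        )
    lay = ParamLayout(
        dataset.marks, dataset.covariate_names, dataset.n_windows,
        spline.n_basis, baseline_mode,
    )
    if _grid_block is None:
        nodes_l, weights_l = _grid_positions(dataset, resolution)
        X_grid = _design_block(dataset, nodes_l, spline, lay)
        w_grid = np.concatenate(weights_l)
        _grid_block = (X_grid, w_grid)
    X_grid, w_grid = _grid_block
    ev_l = [dataset.get_points(i, mark) for i in range(dataset.n_windows)]
    X_ev = _design_block(dataset, ev_l, spline, lay)
    X = sp.vstack([X_grid, X_ev], format="csr")
    w_all = np.concatenate([w_grid, np.zeros(X_ev.shape[0])])
    event_rows = (X_grid.shape[0] + np.arange(X_ev.shape[0])).astype(np.intp)
    return Design(X, w_all, event_rows, lay, mark, resolution)


def _eta(theta: np.ndarray, design: Design) -> np.ndarray:
    return design.X @ theta


def _clamped_exp(eta: np.ndarray) -> np.ndarray:
    if np.any(eta > ETA_MAX):
        warnings.warn(
            "linear predictor clamped at %.0f during estimation" % ETA_MAX,
            RuntimeWarning,
            stacklevel=3,
        )
        eta = np.minimum(eta, ETA_MAX)
    return np.exp(eta)


def loglik(theta: np.ndarray, design: Design) -> float:
    """Exact discretized log-likelihood sum_ev eta - sum_grid w exp(eta)."""
    eta = _eta(theta, design)
    return float(eta[design.event_rows].sum() - design.w @ _clamped_exp(eta))


def score(theta: np.ndarray, design: Design) -> np.ndarray:
    """Gradient: sum_ev x - sum_grid w exp(eta) x."""
    eta = _eta(theta, design)
    lam_w = design.w * _clamped_exp(eta)
    g_ev = np.asarray(design.X[design.event_rows].sum(axis=0)).ravel()
    return g_ev - design.X.T @ lam_w


def hessian(theta: np.ndarray, design: Design) -> np.ndarray:
    """Hessian -sum_grid w exp(eta) x x' (negative semidefinite)."""
    eta = _eta(theta, design)
    lam_w = design.w * _clamped_exp(eta)
    Xw = design.X.multiply(lam_w[:, None])
    return -np.asarray((design.X.T @ Xw).todense())


def linear_predictor(
    t: float,
    k: str,
    i: int,
    dataset: MarkedPointDataset,
    params: HawkesParams,
    spec: SplineSpec | None = None,
) -> float:
    """Direct (design-free) evaluation of log lambda_k^{(i)}(t).

    Sums h^{mk}(t - s) over all source points s strictly before t within
    the spline support; used by the simulator and as a cross-check of the
    sparse design path.
    """
    spec = spec or params.spline
    eta = params.baseline_for_window(k, i)
    for j, name in enumerate(params.covariate_names):
        eta += params.alpha[k][j] * float(dataset.covariate_indicator(i, name, t)[0])
    for m in params.marks:
        src = dataset.get_points(i, m)
        if src.size == 0:
            continue
        lo = np.searchsorted(src, t - spec.last_knot, side="left")
        hi = np.searchsorted(src, t, side="left")
        if hi > lo:
            eta += evaluate_h(t - src[lo:hi], params.beta[(m, k)], spec).sum()
    return float(eta)


def g_function(m: str, k: str, s, params: HawkesParams, spec: SplineSpec | None = None):
    """Transfer fold-change g_{m,k}(s) = exp(h^{mk}(s)); 1 outside support."""
    spec = spec or params.spline
    return np.exp(evaluate_h(s, params.beta[(m, k)], spec))


class HawkesPointProcess:
    """Multivariate nonlinear Hawkes process model for a point dataset.

    Parameters
    ----------
    dataset : MarkedPointDataset
        Observation windows, per-mark point positions, covariate tracks.
    spline : SplineSpec, optional
        Transfer-function basis (default: 8 simple knots on [-400, 1000]).
    resolution : float
        Quadrature resolution r in bp for the intensity integral.
    baseline_mode : str
        "shared" (one baseline for all windows, chromosome-style) or
        "per_window" (one per analysis region, ENCODE-style).

    Examples
    --------
    >>> model = HawkesPointProcess(dataset, resolution=10)
    >>> res = model.fit()
    >>> res.summary()
    """

    def __init__(
        self,
        dataset: MarkedPointDataset,
        spline: SplineSpec | None = None,
        resolution: float = 1.0,
        baseline_mode: str = "shared",
    ):
        dataset.validate()
        self.dataset = dataset
        self.spline = spline or SplineSpec()
        self.resolution = float(resolution)
        self.baseline_mode = baseline_mode
        self.layout = ParamLayout(
            dataset.marks, dataset.covariate_names, dataset.n_windows,
            self.spline.n_basis, baseline_mode,
        )
        self._designs: dict[str, Design] = {}
        self._grid_block = None

    def design(self, mark: str) -> Design:
        if mark not in self._designs:
            if self._grid_block is None:
                nodes_l, weights_l = _grid_positions(self.dataset, self.resolution)
                X_grid = _design_block(self.dataset, nodes_l, self.spline, self.layout)
                self._grid_block = (X_grid, np.concatenate(weights_l))
            self._designs[mark] = build_design(
                self.dataset, mark, self.spline, self.resolution,
                self.baseline_mode, _grid_block=self._grid_block,
            )
        return self._designs[mark]

    # --- likelihood surface -------------------------------------------------

    def loglike(self, params: HawkesParams, mark: str | None = None) -> float:
        marks = [mark] if mark else list(self.dataset.marks)
        return sum(loglik(params.vector(k), self.design(k)) for k in marks)

    def score(self, params: HawkesParams, mark: str) -> np.ndarray:
        return score(params.vector(mark), self.design(mark))

    def hessian(self, params: HawkesParams, mark: str) -> np.ndarray:
        return hessian(params.vector(mark), self.design(mark))

    # --- estimation ---------------------------------------------------------

    def _start_vector(self, mark: str) -> np.ndarray:
        """Zero-interaction start: beta = 0, covariate alpha = 0, baseline
        at the homogeneous-Poisson MLE log(n / |C|)."""
        lay = self.layout
        theta = np.zeros(lay.n_params)
        if self.baseline_mode == "per_window":
            for i, w in enumerate(self.dataset.windows):
                n = max(self.dataset.get_points(i, mark).size, 0.5)
                theta[i] = np.log(n / w.length)
        else:
            n = max(self.dataset.n_points(mark), 0.5)
            theta[0] = np.log(n / self.dataset.total_length)
        return theta

    def _free_mask(self, mark: str, fixed_zero) -> np.ndarray:
        lay = self.layout
        mask = np.ones(lay.n_params, dtype=bool)
        for (m, k) in fixed_zero:
            if k == mark:
                mask[lay.beta_cols(m)] = False
        return mask

    def _fit_mark(self, mark: str, fixed_zero=(), maxiter: int = 1000,
                  gtol: float = 1e-7):
        design = self.design(mark)
        mask = self._free_mask(mark, fixed_zero)
        theta0 = self._start_vector(mark)

        def negll(free):
            theta = np.zeros(mask.size)
            theta[mask] = free
            return -loglik(theta, design)

        def neggrad(free):
            theta = np.zeros(mask.size)
            theta[mask] = free
            return -score(theta, design)[mask]

        res = minimize(
            negll,
            theta0[mask],
            jac=neggrad,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-12},
        )
        theta = np.zeros(mask.size)
        theta[mask] = res.x
        # L-BFGS occasionally stops in the line search after reaching the
        # optimum to numerical precision; a small gradient is convergence
        converged = bool(res.success)
        if not converged:
            gnorm = float(np.max(np.abs(score(theta, design)[mask])))
            scale = max(1.0, abs(res.fun))
            converged = gnorm <= 1e-4 * scale
        H = hessian(theta, design)
        Hf = H[np.ix_(mask, mask)]
        cov = np.zeros((mask.size, mask.size))
        cov_ok = True
        try:
            cov_free = np.linalg.inv(-Hf)
        except np.linalg.LinAlgError:
            cov_ok = False
            cov_free = np.full_like(Hf, np.nan)
        if not np.all(np.isfinite(cov_free)):
            cov_ok = False
        cov[np.ix_(mask, mask)] = cov_free
        return {
            "theta": theta,
            "loglik": -float(res.fun),
            "converged": converged,
            "cov": cov,
            "cov_available": cov_ok,
            "mask": mask,
            "message": res.message,
            "nit": int(res.nit),
        }

    def fit(self, fixed_zero=(), maxiter: int = 1000, marks=None):
        """Maximum-likelihood fit; each mark's term is maximized separately.

        Parameters
        ----------
        fixed_zero : iterable of (m, k) pairs
            Transfer functions constrained to zero (g = 1).
        marks : iterable of str, optional
            Restrict fitting to these target marks (default: all).

        Returns
        -------
        HawkesResults
        """
        from .results import HawkesResults

        fixed_zero = tuple(fixed_zero)
        marks = tuple(marks) if marks is not None else self.dataset.marks
        params = HawkesParams.zeros(
            self.dataset.marks, self.spline, self.dataset.covariate_names,
            self.baseline_mode, self.dataset.n_windows,
        )
        per_mark = {}
        for k in marks:
            info = self._fit_mark(k, fixed_zero, maxiter)
            params.set_vector(k, info["theta"])
            per_mark[k] = info
            if not info["converged"]:
                logger.warning("fit for mark %s did not converge: %s", k, info["message"])
        return HawkesResults(self, params, per_mark, fixed_zero, marks)
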