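"""BOLD-constrained perfusion (BCP) estimation.

The estimator treats the measured ASL and BOLD series as two noisy windows
into the same underlying flow fluctuation and fits them jointly under the
constraint that every estimated point lies on the heuristic model curve

    b = b0 * (1 + k * g(f / f0)),      g(x) = (x - 1) / x,

with a single lumped scale ``k`` held constant over the analysis window.
This is an errors-in-both-variables fit: for a candidate ``k`` each
measured pair ``(a_t, b_t)`` is mapped to the closest point ``(f_t, b_t')``
on the curve under the inverse-variance-weighted squared distance

    w_asl * (a_t - f_t)**2 + w_bold * (b_t - b_t')**2,

and the summed distance is minimized over ``k`` by golden-section search.
Only the ratio of the two weights affects the fitted ``k``.

The output is a denoised flow series ``f_hat`` (constrained to be
consistent with the BOLD measurement), the matching ``b_hat``, and ``k_hat``
itself, which under a hypercapnia calibration carries the CMRO2/CBF
coupling ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.exceptions import NotFittedError

from .preprocess import NoiseWeights, TimeSeriesPair

__all__ = [
    "SearchSettings",
    "BCPResult",
    "BCPEstimator",
    "golden_section_fraction",
    "golden_section_minimize",
    "project_to_model",
    "bcp_cost",
    "fit_bcp",
    "fit_epochs",
]


def golden_section_fraction() -> float:
    """Interior-point fraction of the golden-section search, ``(3 - sqrt 5)/2``.

    The probe point is placed this fraction of the distance from the
    current intermediate point toward the more distant bracket, i.e. at
    38.197% of the interval.
    """
    return (3.0 - np.sqrt(5.0)) / 2.0


@dataclass(frozen=True)
class SearchSettings:
    """Golden-section search and projection settings.

    ``tolerance`` is the terminal bracket width in units of ``k``
    (default 0.001).  ``f_floor`` and ``f_cap`` bound the admissible
    constrained flow as fractions of baseline: ``g`` is singular at zero
    flow and physiological flow never vanishes.
    """

    bracket_lo: float = -0.1
    bracket_hi: float = 0.3
    tolerance: float = 1e-3
    f_floor: float = 0.05
    f_cap: float = 5.0

    def __post_init__(self) -> None:
        if not self.bracket_lo < self.bracket_hi:
            raise ValueError("bracket_lo must be strictly below bracket_hi")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if not 0 < self.f_floor < 1:
            raise ValueError("f_floor must lie in (0, 1)")
        if self.f_cap <= 1:
            raise ValueError("f_cap must exceed 1")


@dataclass
class BCPResult:
    """Constrained series, fitted scale and search diagnostics."""

    f_hat: np.ndarray
    b_hat: np.ndarray
    k_hat: float
    cost: float
    n_evals: int
    bracket: tuple[float, float]
    settings: SearchSettings = field(default_factory=SearchSettings)


def _curve(f, k, f0, b0):
    """Model BOLD level at flow ``f`` (signal units both axes)."""
    return b0 * (1.0 + k * (f - f0) / f)


def project_to_model(
    a_t,
    b_t,
    k: float,
    f0: float,
    b0: float,
    weights: NoiseWeights,
    f_floor: float = 0.05,
    f_cap: float = 5.0,
    n_grid: int = 129,
    n_iter: int = 48,
):
    """Closest point on the model curve to each measured ``(a_t, b_t)`` pair.

    Minimizes ``w_asl*(a - f)**2 + w_bold*(b - b0*(1 + k*g(f/f0)))**2`` over
    the single free coordinate ``f`` on ``[f_floor*f0, f_cap*f0]``.  A coarse
    grid locates the basin; golden-section refinement within the bracketing
    grid cell then converges far below 1e-9 relative width.  Vectorized over
    time points.

    Returns ``(f_hat, b_hat)`` with the shape of the inputs.
    """
    a = np.asarray(a_t, dtype=float)
    b = np.asarray(b_t, dtype=float)
    scalar = a.ndim == 0 and b.ndim == 0
    a, b = np.atleast_1d(a), np.atleast_1d(b)
    if a.shape != b.shape:
        raise ValueError("a_t and b_t must have the same shape")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("measured samples must be finite")
    if f0 <= 0 or b0 <= 0:
        raise ValueError("baselines f0 and b0 must be positive")
    w_a, w_b = weights.w_asl, weights.w_bold

    grid = np.linspace(f_floor * f0, f_cap * f0, n_grid)
    J = w_a * (a[:, None] - grid) ** 2 + w_b * (b[:, None] - _curve(grid, k, f0, b0)) ** 2
    i = np.argmin(J, axis=1)
    lo = grid[np.maximum(i - 1, 0)]
    hi = grid[np.minimum(i + 1, n_grid - 1)]

    rho = golden_section_fraction()

    def obj(f):
        return w_a * (a - f) ** 2 + w_b * (b - _curve(f, k, f0, b0)) ** 2

    for _ in range(n_iter):
        d = hi - lo
        x1 = lo + rho * d
        x2 = hi - rho * d
        keep_low = obj(x1) <= obj(x2)
        hi = np.where(keep_low, x2, hi)
        lo = np.where(keep_low, lo, x1)
    f_hat = 0.5 * (lo + hi)
    b_hat = _curve(f_hat, k, f0, b0)
    if scalar:
        return float(f_hat[0]), float(b_hat[0])
    return f_hat, b_hat


def bcp_cost(
    pair: TimeSeriesPair,
    k: float,
    weights: NoiseWeights,
    settings: SearchSettings | None = None,
) -> float:
    """Weighted sum of squared residuals to the curve at a candidate ``k``."""
    settings = settings or SearchSettings()
    if pair.f0 is None or pair.b0 is None:
        raise ValueError("pair baselines f0/b0 must be populated")
    f_hat, b_hat = project_to_model(
        pair.asl, pair.bold, k, pair.f0, pair.b0, weights,
        f_floor=settings.f_floor, f_cap=settings.f_cap,
    )
    return float(
        weights.w_asl * np.sum((pair.asl - f_hat) ** 2)
        + weights.w_bold * np.sum((pair.bold - b_hat) ** 2)
    )


def golden_section_minimize(
    objective: Callable[[float], float],
    settings: SearchSettings | None = None,
) -> tuple[float, dict]:
    """Derivative-free scalar minimization over a bracketed interval.

    At every step the probe point sits at the golden-section fraction
    (38.197%) of the current interval, measured from the intermediate point
    toward the more distant bracket; the interval shrinks by the golden
    ratio each iteration until its width is at most ``settings.tolerance``.
    Assumes a unimodal objective on the bracket.

    Returns ``(x_min, diagnostics)`` where diagnostics holds ``n_evals``
    and the final ``bracket``.
    """
    settings = settings or SearchSettings()
    lo, hi = settings.bracket_lo, settings.bracket_hi
    rho = golden_section_fraction()
    n_evals = 0

    def ev(x: float) -> float:
        nonlocal n_evals
        n_evals += 1
        v = float(objective(x))
        if not np.isfinite(v):
            raise FloatingPointError(f"objective non-finite at k={x!r}")
        return v

    x1 = lo + rho * (hi - lo)
    x2 = hi - rho * (hi - lo)
    f1, f2 = ev(x1), ev(x2)
    while hi - lo > settings.tolerance:
        if f1 <= f2:
            hi, x2, f2 = x2, x1, f1
            x1 = lo + rho * (hi - lo)
            f1 = ev(x1)
        else:
            lo, x1, f1 = x1, x2, f2
            x2 = hi - rho * (hi - lo)
            f2 = ev(x2)
    x_min = 0.5 * (lo + hi)
    return x_min, {"n_evals": n_evals, "bracket": (lo, hi)}


def _scan_unimodality(objective, settings, n_scan: int = 11) -> None:
    """Warn if a coarse scan of the cost profile is visibly non-unimodal."""
    ks = np.linspace(settings.bracket_lo, settings.bracket_hi, n_scan)
    vals = np.array([objective(k) for k in ks])
    interior = (vals[1:-1] < vals[:-2]) & (vals[1:-1] < vals[2:])
    if int(interior.sum()) > 1:
        warnings.warn(
            "cost profile over the k bracket appears non-unimodal; "
            "golden-section search may return a local minimum",
            RuntimeWarning,
            stacklevel=3,
        )


class BCPEstimator(TransformerMixin, BaseEstimator):
    """Scikit-learn style BOLD-constrained perfusion denoiser.

    ``fit`` expects ``X`` of shape ``(n_samples, 2)`` whose columns are the
    measured ASL- and BOLD-weighted series in raw signal units (rows are
    time points).  It learns the lumped model scale ``k_hat_`` by
    golden-section search over the errors-in-variables cost, and stores the
    constrained series.  ``transform`` projects (possibly new) measured
    pairs onto the fitted curve, returning denoised ``(f_hat, b_hat)``
    columns.

    Parameters
    ----------
    baseline_n : int
        Samples averaged for the baselines when ``f0`` / ``b0`` are not
        given (task-run convention: first 20 samples).
    f0, b0 : float, optional
        Baseline ASL and BOLD levels in signal units; estimated from the
        first ``baseline_n`` samples when omitted.
    var_asl, var_bold : float, optional
        Noise variances of the two series (signal units squared); their
        reciprocals weight the cost.  Equal weights when omitted.  Only the
        ratio affects ``k_hat_``.
    bracket : tuple of float
        Initial search interval for ``k``.
    tol : float
        Terminal bracket width in ``k`` units.
    f_floor, f_cap : float
        Admissible constrained-flow range as fractions of ``f0``.
    check_unimodal : bool
        Run an 11-point diagnostic scan of the cost profile before the
        search and warn if it is non-unimodal.

    Attributes
    ----------
    k_hat_ : float
        Fitted lumped scale.
    f_hat_, b_hat_ : ndarray
        Constrained (denoised) ASL and BOLD series for the training window.
    cost_ : float
        Final value of the weighted cost.
    n_evals_ : int
        Number of cost evaluations spent by the search.
    bracket_ : tuple of float
        Final search interval (width at most ``tol``).
    f0_, b0_ : float
        Baselines actually used.
    """

    def __init__(
        self,
        baseline_n: int = 20,
        f0: float | None = None,
        b0: float | None = None,
        var_asl: float | None = None,
        var_bold: float | None = None,
        bracket: tuple[float, float] = (-0.1, 0.3),
        tol: float = 1e-3,
        f_floor: float = 0.05,
        f_cap: float = 5.0,
        check_unimodal: bool = False,
    ) -> None:
        self.baseline_n = baseline_n
        self.f0 = f0
        self.b0 = b0
        self.var_asl = var_asl
        self.var_bold = var_bold
        self.bracket = bracket
        self.tol = tol
        self.f_floor = f_floor
        self.f_cap = f_cap
        self.check_unimodal = check_unimodal

    def _validate(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have shape (n_samples, 2): columns asl, bold")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 time points")
        if not np.all(np.isfinite(X)):
            raise ValueError("X must be finite")
        return X

    def _settings(self) -> SearchSettings:
        lo, hi = self.bracket
        return SearchSettings(lo, hi, self.tol, self.f_floor, self.f_cap)

    def _weights(self) -> NoiseWeights:
        if (self.var_asl is None) != (self.var_bold is None):
            raise ValueError("provide both var_asl and var_bold, or neither")
        if self.var_asl is None:
            return NoiseWeights(1.0, 1.0)
        return NoiseWeights(self.var_asl, self.var_bold)

    def fit(self, X, y=None) -> "BCPEstimator":
        X = self._validate(X)
        settings = self._settings()
        weights = self._weights()
        if self.f0 is None or self.b0 is None:
            n = min(self.baseline_n, X.shape[0])
            f0 = float(X[:n, 0].mean()) if self.f0 is None else float(self.f0)
            b0 = float(X[:n, 1].mean()) if self.b0 is None else float(self.b0)
        else:
            f0, b0 = float(self.f0), float(self.b0)
        if f0 <= 0 or b0 <= 0:
            raise ValueError("baselines must be positive; pass f0/b0 explicitly")

        pair = TimeSeriesPair(X[:, 0], X[:, 1], tr=1.0, f0=f0, b0=b0)

        def objective(k: float) -> float:
            return bcp_cost(pair, k, weights, settings)

        if self.check_unimodal:
            _scan_unimodality(objective, settings)
        k_hat, diag = golden_section_minimize(objective, settings)
        f_hat, b_hat = project_to_model(
            X[:, 0], X[:, 1], k_hat, f0, b0, weights,
            f_floor=settings.f_floor, f_cap=settings.f_cap,
        )
        self.f0_, self.b0_ = f0, b0
        self.weights_ = weights
        self.k_hat_ = float(k_hat)
        self.f_hat_, self.b_hat_ = f_hat, b_hat
        self.cost_ = float(
            weights.w_asl * np.sum((X[:, 0] - f_hat) ** 2)
            + weights.w_bold * np.sum((X[:, 1] - b_hat) ** 2)
        )
        self.n_evals_ = diag["n_evals"]
        self.bracket_ = diag["bracket"]
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "k_hat_"):
            raise NotFittedError("BCPEstimator must be fitted before transform")
        X = self._validate(X)
        f_hat, b_hat = project_to_model(
            X[:, 0], X[:, 1], self.k_hat_, self.f0_, self.b0_, self.weights_,
            f_floor=self.f_floor, f_cap=self.f_cap,
        )
        return np.column_stack([f_hat, b_hat])

    def result_(self) -> BCPResult:
        """Fitted quantities bundled as a :class:`BCPResult`."""
        if not hasattr(self, "k_hat_"):
            raise NotFittedError("BCPEstimator must be fitted first")
        return BCPResult(
            f_hat=self.f_hat_,
            b_hat=self.b_hat_,
            k_hat=self.k_hat_,
            cost=self.cost_,
            n_evals=self.n_evals_,
            bracket=self.bracket_,
            settings=self._settings(),
        )


def fit_bcp(
    pair: TimeSeriesPair,
    weights: NoiseWeights,
    settings: SearchSettings | None = None,
) -> BCPResult:
    """Fit the BCP model to a measured series pair (functional interface).

    Thin wrapper over :class:`BCPEstimator`; the pair must carry its
    baselines ``f0`` and ``b0``.
    """
    settings = settings or SearchSettings()
    if pair.f0 is None or pair.b0 is None:
        raise ValueError("pair baselines f0/b0 must be populated")
    est = BCPEstimator(
        f0=pair.f0,
        b0=pair.b0,
        var_asl=weights.var_asl,
        var_bold=weights.var_bold,
        bracket=(settings.bracket_lo, settings.bracket_hi),
        tol=settings.tolerance,
        f_floor=settings.f_floor,
        f_cap=settings.f_cap,
    )
    est.fit(np.column_stack([pair.asl, pair.bold]))
    return est.result_()


def fit_epochs(
    pair: TimeSeriesPair,
    epochs: Mapping[str, np.ndarray],
    weights: NoiseWeights,
    settings: SearchSettings | None = None,
) -> dict[str, BCPResult]:
    """Fit the BCP model separately to named epoch windows.

    ``epochs`` maps an epoch name to the sample indices belonging to it
    (concatenated across stimulus cycles).  Each epoch needs at least two
    samples.
    """
    out: dict[str, BCPResult] = {}
    for name, idx in epochs.items():
        idx = np.asarray(idx, dtype=int)
        if idx.size < 2:
            raise ValueError(f"epoch {name!r} selects fewer than 2 samples")
        out[name] = fit_bcp(pair.subset(idx), weights, settings)
    return out
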