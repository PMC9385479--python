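"""Nonlinear least-squares estimation of kinetic parameters.

Progress curves are fit in the identifiable observable parameterization

    P(t) = A * (1 - exp(-lam * t)) + m * t

(burst amplitude ``A``, burst rate ``lam``, steady-state slope ``m``), which
is linear in ``(A, m)`` for fixed ``lam``.  The fit therefore uses variable
projection — a 1-D search over ``lam`` with the conditionally optimal linear
coefficients solved exactly — followed by a full trust-region polish.  The
mechanistic parameters are recovered by back-solving

    k2 = lam² A / (m + lam A),   k3 = lam - k2,   E = (m + lam A)² / (A lam²)

which is the unique preimage of ``(A, lam, m)`` under the burst model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .models import (
    BurstParams,
    HyperbolaParams,
    RateConstants,
    burst_product,
    derived_rates,
    hyperbolic_rate,
)

__all__ = [
    "ProgressCurve",
    "BurstFitResult",
    "TitrationSeries",
    "TitrationFitResult",
    "FitError",
    "NoDetectableProductError",
    "fit_burst",
    "fit_titration",
    "bootstrap_cis",
    "grid_oracle_fit",
    "fold_stimulation",
]


class FitError(ValueError):
    """Raised when a fit cannot be attempted or is structurally degenerate."""


class NoDetectableProductError(FitError):
    """Raised when the signal is all-zero or flat (nothing to fit)."""


# --------------------------------------------------------------------------
# data containers
# --------------------------------------------------------------------------


@dataclass
class ProgressCurve:
    """One cleavage time course.

    ``times`` (min) must be strictly increasing with at least 4 points;
    ``product`` (nM) has the same length and is non-negative.  ``tol``
    is the noise allowance for the ``product <= s_total`` check.
    """

    times: np.ndarray
    product: np.ndarray
    e_nominal: float
    s_total: float
    condition: dict = field(default_factory=dict)
    tol: float = 0.25
    replicate_products: np.ndarray | None = None  # optional (n_rep, n_t) matrix

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.product = np.asarray(self.product, dtype=float)
        if self.times.ndim != 1 or self.product.ndim != 1:
            raise ValueError("times and product must be 1-D")
        if len(self.times) != len(self.product):
            raise ValueError(
                f"times and product lengths differ: {len(self.times)} vs {len(self.product)}"
            )
        if len(self.times) < 4:
            raise ValueError(f"need >= 4 time points, got {len(self.times)}")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times[0] < 0:
            raise ValueError("times must start at >= 0")
        if np.any(self.product < 0):
            raise ValueError("product concentrations must be >= 0")
        if self.s_total > 0 and np.any(self.product > self.s_total * (1 + self.tol)):
            raise ValueError("product exceeds total substrate beyond noise tolerance")
        if self.replicate_products is not None:
            self.replicate_products = np.atleast_2d(
                np.asarray(self.replicate_products, dtype=float)
            )
            if self.replicate_products.shape[1] != len(self.times):
                raise ValueError("replicate matrix width must match times")


@dataclass
class BurstFitResult:
    params: BurstParams
    k_burst: float
    k_ss: float
    ssr: float
    ci: dict[str, tuple[float, float]]
    converged: bool
    n_points: int

    def as_dict(self) -> dict:
        return {
            "e_active_nM": self.params.e_active,
            "k2_per_min": self.params.rates.k2,
            "k3_per_min": self.params.rates.k3,
            "k_burst_per_min": self.k_burst,
            "k_ss_per_min": self.k_ss,
            "ssr_nM2": self.ssr,
            "ci": {k: list(v) for k, v in self.ci.items()},
            "converged": self.converged,
            "n_points": self.n_points,
        }


@dataclass
class TitrationSeries:
    """Observed pre-steady-state rates vs activator concentration."""

    concs: np.ndarray
    k_burst_obs: np.ndarray
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.concs = np.asarray(self.concs, dtype=float)
        self.k_burst_obs = np.asarray(self.k_burst_obs, dtype=float)
        if len(self.concs) != len(self.k_burst_obs):
            raise ValueError("concs and rates must have the same length")
        if len(np.unique(self.concs)) < 3:
            raise ValueError(f"need >= 3 distinct concentrations, got {len(np.unique(self.concs))}")
        if np.any(self.concs < 0) or np.any(self.k_burst_obs < 0):
            raise ValueError("concentrations and rates must be >= 0")


@dataclass
class TitrationFitResult:
    params: HyperbolaParams
    ci: dict[str, tuple[float, float]]
    ssr: float
    converged: bool

    def as_dict(self) -> dict:
        return {
            "k_pot_per_min": self.params.k_pot,
            "kd_nM": self.params.kd,
            "ssr": self.ssr,
            "ci": {k: list(v) for k, v in self.ci.items()},
            "converged": self.converged,
        }


# --------------------------------------------------------------------------
# burst fit
# --------------------------------------------------------------------------


def _obs_curve(t, A, lam, m):
    return A * -np.expm1(-lam * t) + m * t


def _linear_coeffs(t, y, lam):
    """Nonnegative least-squares (A, m) for fixed lam, plus SSR."""
    X = np.column_stack([-np.expm1(-lam * t), t])
    coef, _ = optimize.nnls(X, y)
    resid = y - X @ coef
    return coef[0], coef[1], float(resid @ resid)

def _backsolve(A, lam, m):
    """Unique (e_active, k2, k3) reproducing observables (A, lam, m)."""
    if A <= 0 or lam <= 0:
        raise FitError("degenerate fit: burst amplitude or rate is zero")
    denom = m + lam * A
    k2 = lam * lam * A / denom
    k3 = lam - k2
    k3 = max(k3, 0.0)
    e = denom * denom / (A * lam * lam)
    return e, k2, k3


def fit_burst(
    curve: ProgressCurve,
    fix_e_active: float | None = None,
    n_starts: int = 5,
) -> BurstFitResult:
    """Fit the burst-and-steady-state model to a progress curve.

    Parameters
    ----------
    curve : ProgressCurve
    fix_e_active : float, optional
        Pin the active-enzyme concentration instead of fitting it.
    n_starts : int
        Number of log-spaced multi-start values for the burst rate.

    Returns
    -------
    BurstFitResult
        Confidence intervals are left empty here; use :func:`bootstrap_cis`.
    """
    t = curve.times
    y = curve.product
    if np.all(y <= 0) or np.ptp(y) == 0:
        raise NoDetectableProductError("no detectable product: signal is flat or all zero")

    # init: slope of the last third -> m0; its intercept -> A0; time to
    # half the extrapolated amplitude -> lam0
    n = len(t)
    i0 = max(n - max(n // 3, 2), 0)
    m0, c0 = np.polyfit(t[i0:], y[i0:], 1)
    m0 = max(m0, 0.0)
    A0 = max(c0, np.max(y) * 0.1)
    half = A0 / 2.0
    above = np.nonzero(y >= half)[0]
    t_half = t[above[0]] if len(above) and t[above[0]] > 0 else t[max(n // 4, 1)]
    lam0 = np.log(2.0) / t_half

    best = None
    for lam_start in np.geomspace(lam0 / 10, lam0 * 10, n_starts):
        res = optimize.minimize_scalar(
            lambda loglam: _linear_coeffs(t, y, np.exp(loglam))[2],
            bracket=(np.log(lam_start) - 1.0, np.log(lam_start) + 1.0),
            method="brent",
            options={"xtol": 1e-12},
        )
        lam = float(np.exp(res.x))
        A, m, ssr = _linear_coeffs(t, y, lam)
        if best is None or ssr < best[3]:
            best = (A, lam, m, ssr)

    A, lam, m, _ = best
    # full trust-region polish in (A, lam, m)
    lsq = optimize.least_squares(
        lambda p: _obs_curve(t, *p) - y,
        x0=[max(A, 1e-12), lam, max(m, 0.0)],
        bounds=([0, 1e-12, 0], [np.inf, np.inf, np.inf]),
        method="trf",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        x_scale="jac",
    )
    A, lam, m = lsq.x
    converged = bool(lsq.success)

    if fix_e_active is not None:
        # constrained refit: E fixed, parameters (k2, k3)
        def resid_fixed(p):
            k2, k3 = p
            bp = BurstParams(fix_e_active, RateConstants(k2, k3))
            return burst_product(t, bp) - y

        e0, k20, k30 = _backsolve(max(A, 1e-12), lam, m)
        lsq2 = optimize.least_squares(
            resid_fixed, x0=[k20, max(k30, 1e-12)],
            bounds=([0, 0], [np.inf, np.inf]), method="trf",
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        k2, k3 = lsq2.x
        e = fix_e_active
        ssr = float(lsq2.fun @ lsq2.fun)
        converged = bool(lsq2.success)
    else:
        e, k2, k3 = _backsolve(A, lam, m)
        ssr = float(lsq.fun @ lsq.fun)

    params = BurstParams(e, RateConstants(k2, k3))
    k_burst, k_ss = derived_rates(params.rates)
    return BurstFitResult(
        params=params,
        k_burst=k_burst,
        k_ss=k_ss,
        ssr=ssr,
        ci={},
        converged=converged,
        n_points=len(t),
    )


# --------------------------------------------------------------------------
# titration fit
# --------------------------------------------------------------------------


def _hyperbola_profile(c, y, basal):
    """SSR profiled over the linear coefficients, as a function of log kd."""
    if basal:
        def ssr_of(logkd):
            X = np.column_stack([c / (np.exp(logkd) + c), np.ones_like(c)])
            coef, _ = optimize.nnls(X, y)
            r = y - X @ coef
            return float(r @ r), coef
    else:
        def ssr_of(logkd):
            x = c / (np.exp(logkd) + c)
            k_pot = max(float(x @ y) / float(x @ x), 0.0)
            r = y - k_pot * x
            return float(r @ r), np.array([k_pot])
    return ssr_of


def fit_titration(
    series: TitrationSeries, basal_offset: bool = False, polish: bool = True
) -> TitrationFitResult:
    """Fit the activator hyperbola ``k = k_pot*c/(kd+c)`` to a titration.

    The hyperbola is linear in ``k_pot`` for fixed ``kd``, so the fit is a
    1-D profiled search over ``log kd`` followed by a trust-region polish
    (skippable via ``polish=False`` for speed in resampling loops).  With
    ``basal_offset=True`` an additive basal rate ``k0`` is co-fit (off by
    default: the canonical model has no intercept).
    """
    c = series.concs
    y = series.k_burst_obs
    if np.ptp(y) == 0:
        raise FitError("saturated or flat series: all observed rates identical")

    half = float(np.max(y)) / 2.0
    above = np.nonzero(y >= half)[0]
    kd0 = float(c[above[0]]) if len(above) and c[above[0]] > 0 else float(np.median(c[c > 0]))

    ssr_of = _hyperbola_profile(c, y, basal_offset)
    best = None
    for scale in (1.0, 0.03, 30.0):
        res = optimize.minimize_scalar(
            lambda lk: ssr_of(lk)[0],
            bracket=(np.log(kd0 * scale) - 1.0, np.log(kd0 * scale) + 1.0),
            method="brent",
            options={"xtol": 1e-13},
        )
        if best is None or res.fun < best.fun:
            best = res
    kd = float(np.exp(best.x))
    ssr, coef = ssr_of(best.x)
    k_pot = float(coef[0])
    k0 = float(coef[1]) if basal_offset else 0.0
    converged = True

    if polish:
        if basal_offset:
            def resid(p):
                return p[0] * c / (p[1] + c) + p[2] - y
            x0, lo = [k_pot, kd, k0], [0, 1e-12, 0]
        else:
            def resid(p):
                return p[0] * c / (p[1] + c) - y
            x0, lo = [k_pot, kd], [0, 1e-12]
        lsq = optimize.least_squares(
            resid, x0, bounds=(lo, [np.inf] * len(x0)), method="trf",
            xtol=1e-14, ftol=1e-14, gtol=1e-14, x_scale="jac",
        )
        if float(lsq.fun @ lsq.fun) <= ssr:
            k_pot, kd = float(lsq.x[0]), float(lsq.x[1])
            ssr = float(lsq.fun @ lsq.fun)
            converged = bool(lsq.success)

    params = HyperbolaParams(k_pot=k_pot, kd=kd)
    return TitrationFitResult(params=params, ci={}, ssr=ssr, converged=converged)


# --------------------------------------------------------------------------
# bootstrap confidence intervals
# --------------------------------------------------------------------------

_BURST_KEYS = ("e_active", "k2", "k3", "k_burst", "k_ss")
_TITRATION_KEYS = ("k_pot", "kd")


def bootstrap_cis(
    kind: str,
    data,
    point_fit,
    n_boot: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
    interval: str = "basic",
    scale_residuals: bool | None = None,
) -> dict[str, tuple[float, float]]:
    """Residual-resampling bootstrap confidence intervals.

    ``kind`` is ``"burst"`` or ``"titration"``; ``data`` the corresponding
    curve/series and ``point_fit`` its converged fit result.  The same seed
    always yields identical intervals.

    ``interval="basic"`` (default) uses the reversed-percentile construction
    ``[2θ̂ − q_{1−α/2}, 2θ̂ − q_{α/2}]``; the plain percentile interval is
    available via ``interval="percentile"`` but undercovers for the
    saturating-rate parameter under multiplicative noise at assay-scale n.
    With ``scale_residuals`` (default for titrations, where the signal never
    touches zero) relative residuals are resampled and re-applied
    multiplicatively, matching gel-densitometry-style heteroscedasticity.
    """
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100, got {n_boot}")
    if interval not in ("basic", "percentile"):
        raise ValueError(f"unknown interval type: {interval!r}")
    if not point_fit.converged:
        raise FitError("point fit did not converge; intervals undefined")
    rng = np.random.default_rng(seed)
    alpha = (1.0 - level) / 2.0

    if kind == "burst":
        fitted = burst_product(data.times, point_fit.params)
        y = data.product
        keys = _BURST_KEYS
        point = dict(
            zip(keys, (point_fit.params.e_active, point_fit.params.rates.k2,
                       point_fit.params.rates.k3, point_fit.k_burst, point_fit.k_ss))
        )
        if scale_residuals is None:
            scale_residuals = False
    elif kind == "titration":
        fitted = hyperbolic_rate(data.concs, point_fit.params)
        y = data.k_burst_obs
        keys = _TITRATION_KEYS
        point = dict(zip(keys, (point_fit.params.k_pot, point_fit.params.kd)))
        if scale_residuals is None:
            scale_residuals = True
    else:
        raise ValueError(f"unknown model kind: {kind!r}")

    resid = y - fitted
    if np.allclose(resid, 0.0, atol=1e-12):
        # degenerate: noiseless data -> zero-width intervals at the estimate
        return {k: (v, v) for k, v in point.items()}

    scale = np.maximum(fitted, 1e-3 * np.max(fitted)) if scale_residuals else None
    rel = resid / scale if scale_residuals else None

    draws: dict[str, list[float]] = {k: [] for k in keys}
    n = len(y)
    for _ in range(n_boot):
        if scale_residuals:
            y_b = fitted * (1.0 + rng.choice(rel, size=n, replace=True))
        else:
            y_b = fitted + rng.choice(resid, size=n, replace=True)
        y_b = np.clip(y_b, 0.0, None)
        try:
            if kind == "burst":
                curve_b = ProgressCurve(
                    data.times, y_b, data.e_nominal, data.s_total, tol=np.inf
                )
                f = fit_burst(curve_b)
                vals = (f.params.e_active, f.params.rates.k2, f.params.rates.k3,
                        f.k_burst, f.k_ss)
            else:
                series_b = TitrationSeries(data.concs, y_b)
                f = fit_titration(series_b, polish=False)
                vals = (f.params.k_pot, f.params.kd)
        except (FitError, ValueError):
            continue
        for k, v in zip(keys, vals):
            draws[k].append(v)

    out: dict[str, tuple[float, float]] = {}
    for k, v in draws.items():
        if len(v) < n_boot // 2:
            continue
        q_lo, q_hi = np.quantile(v, [alpha, 1 - alpha])
        if interval == "basic":
            lo, hi = 2 * point[k] - q_hi, 2 * point[k] - q_lo
        else:
            lo, hi = q_lo, q_hi
        out[k] = (float(lo), float(hi))
    return out


# --------------------------------------------------------------------------
# brute-force oracle and derived comparisons
# --------------------------------------------------------------------------


def grid_oracle_fit(
    curve: ProgressCurve,
    e_grid,
    k2_grid,
    k3_grid,
) -> tuple[BurstParams, float]:
    """Exhaustive SSR minimization over a finite (e_active, k2, k3) grid.

    Ties are broken by smallest (k2, k3, e_active).  Deliberately independent
    of :func:`fit_burst` — used as a testing oracle.
    """
    e_grid = np.atleast_1d(np.asarray(e_grid, dtype=float))
    k2_grid = np.atleast_1d(np.asarray(k2_grid, dtype=float))
    k3_grid = np.atleast_1d(np.asarray(k3_grid, dtype=float))
    if e_grid.size == 0 or k2_grid.size == 0 or k3_grid.size == 0:
        raise ValueError("empty parameter grid")

    t = curve.times
    y = curve.product
    best_key = None
    best = None
    for k2 in k2_grid:
        for k3 in k3_grid:
            lam = k2 + k3
            if lam <= 0:
                model_unit = np.zeros_like(t)
            else:
                model_unit = (k2 / lam) ** 2 * -np.expm1(-lam * t) + (k2 * k3 / lam) * t
            for e in e_grid:
                r = e * model_unit - y
                ssr = float(r @ r)
                key = (ssr, k2, k3, e)
                if best_key is None or key < best_key:
                    best_key = key
                    best = (e, k2, k3, ssr)
    e, k2, k3, ssr = best
    return BurstParams(e, RateConstants(k2, k3)), ssr


def fold_stimulation(fit_a: BurstFitResult, fit_b: BurstFitResult) -> float:
    """Ratio of pre-steady-state rates ``k_burst(b) / k_burst(a)``."""
    if not (fit_a.converged and fit_b.converged):
        raise FitError("both fits must have converged")
    if fit_a.k_burst <= 0:
        raise FitError("reference k_burst is zero; fold undefined")
    return fit_b.k_burst / fit_a.k_burst
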