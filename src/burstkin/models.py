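"""Closed-form kinetic models.

All quantities use the package-wide unit convention: time in minutes,
concentrations in nM, first-order rate constants in min⁻¹.

The central model is the biphasic progress curve for an enzyme that cleaves
its substrate quickly (rate ``k2``) but releases the cleaved products slowly
(rate ``k3``)::

    P(t) = E * [ (k2/(k2+k3))² * (1 - exp(-(k2+k3) t)) + (k2 k3/(k2+k3)) t ]

yielding a pre-steady-state exponential burst with rate ``k_burst = k2 + k3``
followed by a linear steady-state phase with turnover rate
``k_ss = k2*k3/(k2+k3)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RateConstants",
    "BurstParams",
    "HyperbolaParams",
    "burst_product",
    "derived_rates",
    "hyperbolic_rate",
    "single_turnover_product",
]


@dataclass(frozen=True)
class RateConstants:
    """First-order rate constants of the two-step cleavage scheme.

    Attributes
    ----------
    k2 : float
        Rate of the cleavage (chemistry) step, min⁻¹.
    k3 : float
        Rate of product release, min⁻¹.
    """

    k2: float
    k3: float

    def __post_init__(self) -> None:
        if self.k2 < 0 or self.k3 < 0:
            raise ValueError(f"rate constants must be >= 0, got k2={self.k2}, k3={self.k3}")


@dataclass(frozen=True)
class BurstParams:
    """Parameters of the burst-and-steady-state progress curve.

    Attributes
    ----------
    e_active : float
        Apparent concentration of catalytically active enzyme, nM.
    rates : RateConstants
        The (k2, k3) pair.
    """

    e_active: float
    rates: RateConstants

    def __post_init__(self) -> None:
        if self.e_active < 0:
            raise ValueError(f"e_active must be >= 0, got {self.e_active}")

    @property
    def k_burst(self) -> float:
        return derived_rates(self.rates)[0]

    @property
    def k_ss(self) -> float:
        return derived_rates(self.rates)[1]


@dataclass(frozen=True)
class HyperbolaParams:
    """Hyperbolic activator-response parameters.

    Attributes
    ----------
    k_pot : float
        Maximum observable pre-steady-state rate at saturating activator, min⁻¹.
    kd : float
        Activator dissociation constant, nM.
    """

    k_pot: float
    kd: float

    def __post_init__(self) -> None:
        if self.k_pot < 0:
            raise ValueError(f"k_pot must be >= 0, got {self.k_pot}")
        if self.kd <= 0:
            raise ValueError(f"kd must be > 0, got {self.kd}")


def derived_rates(rates: RateConstants) -> tuple[float, float]:
    """Return ``(k_burst, k_ss)`` derived from ``(k2, k3)``.

    ``k_burst = k2 + k3`` and ``k_ss = k2*k3/(k2+k3)``; the steady-state rate
    is defined as 0 when both constants vanish.  By the AM–GM inequality
    ``k_ss <= k_burst / 4`` always, with equality iff ``k2 == k3``.
    """
    k2, k3 = rates.k2, rates.k3
    lam = k2 + k3
    if lam == 0.0:
        return 0.0, 0.0
    return lam, k2 * k3 / lam


def burst_product(t, params: BurstParams):
    """Product concentration (nM) at time(s) ``t`` (min).

    Evaluates the burst-and-steady-state progress curve.  Accepts a scalar or
    array of non-negative times; the return type follows the input.  The
    model is unbounded in ``t`` (the linear phase never saturates); callers
    responsible for physical validity must truncate at the total substrate
    themselves (the synthetic-data generator does).
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be >= 0")
    k2, k3 = params.rates.k2, params.rates.k3
    lam = k2 + k3
    if lam == 0.0:
        out = np.zeros_like(t_arr)
        return out if t_arr.ndim else float(out)
    amp_frac = (k2 / lam) ** 2
    kss = k2 * k3 / lam
    out = params.e_active * (amp_frac * -np.expm1(-lam * t_arr) + kss * t_arr)
    return out if t_arr.ndim else float(out)


def hyperbolic_rate(conc, params: HyperbolaParams):
    """Pre-steady-state rate (min⁻¹) at activator concentration(s) ``conc`` (nM).

    ``k_burst = k_pot * conc / (kd + conc)`` — no intercept; the curve passes
    through the origin and asymptotes to ``k_pot``.
    """
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("activator concentration must be >= 0")
    out = params.k_pot * c / (params.kd + c)
    return out if c.ndim else float(out)


def single_turnover_product(t, amplitude: float, k: float):
    """Single-exponential product accumulation ``A * (1 - exp(-k t))``.

    Used for enzyme-excess (single-turnover) assays, which have no linear
    phase.  Bounded above by ``amplitude``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be >= 0")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if k < 0:
        raise ValueError("rate must be >= 0")
    out = amplitude * -np.expm1(-k * t_arr)
    return out if t_arr.ndim else float(out)
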