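"""Assay-realistic synthetic data with known ground truth.

Emulates gel-quantified cleavage assays: progress curves with burst + linear
phases whose amplitude is set by the apparent active enzyme, activator
titration series, and guide-length panels.  Noise is heteroscedastic —
multiplicative (gel densitometry scales with band intensity) plus a small
additive floor — and always seeded.  The closed-form model is unbounded in
time, so generated product is truncated at the total substrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fitting import ProgressCurve, TitrationSeries
from .models import BurstParams, HyperbolaParams, RateConstants, burst_product, hyperbolic_rate

__all__ = [
    "NoiseModel",
    "AssayDesign",
    "SubstrateExhaustedError",
    "gen_progress_curve",
    "gen_titration",
    "gen_guide_length_panel",
    "DEFAULT_GUIDE_30NT",
    "DEFAULT_LENGTH_TRUTHS",
    "rates_from_phases",
    "guide_for_length",
    "target_for_length",
]


class SubstrateExhaustedError(ValueError):
    """Truth cleaves all substrate before the second time point."""


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative cv + additive floor, seeded.

    ``P_obs = max(0, P * (1 + eps_cv) + eps_floor)`` with independent normal
    draws.  A seed is mandatory for any nonzero noise.
    """

    cv: float = 0.05
    floor: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.cv < 0 or self.floor < 0:
            raise ValueError("cv and floor must be >= 0")
        if (self.cv > 0 or self.floor > 0) and self.seed is None:
            raise ValueError("a seed is required for nonzero noise")

    @property
    def is_zero(self) -> bool:
        return self.cv == 0 and self.floor == 0

    def apply(self, p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.is_zero:
            return p.copy()
        out = p * (1.0 + rng.normal(0.0, self.cv, size=p.shape))
        out += rng.normal(0.0, self.floor, size=p.shape)
        return np.clip(out, 0.0, None)


def _default_grid() -> np.ndarray:
    # denser early sampling to resolve the burst
    return np.unique(np.concatenate([
        [0.0], np.geomspace(0.25, 8.0, 9), np.linspace(12.0, 60.0, 9)
    ]))


@dataclass(frozen=True)
class AssayDesign:
    """Assay layout: time grid, nominal concentrations, replicates."""

    times: np.ndarray = field(default_factory=_default_grid)
    e_nominal: float = 5.0
    active_fraction: float = 0.35
    s_total: float = 5.0
    replicates: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.e_nominal <= 0 or self.s_total <= 0:
            raise ValueError("concentrations must be > 0")
        if not 0 < self.active_fraction <= 1:
            raise ValueError("active fraction must be in (0, 1]")
        if self.replicates < 1:
            raise ValueError("need >= 1 replicate")

    @property
    def e_active(self) -> float:
        return self.e_nominal * self.active_fraction


def gen_progress_curve(
    design: AssayDesign,
    truth: BurstParams | RateConstants,
    noise: NoiseModel | None = None,
    seed: int | None = None,
    condition: dict | None = None,
) -> tuple[ProgressCurve, BurstParams]:
    """Generate one progress curve plus its ground truth.

    ``truth`` may be a full :class:`BurstParams` (its own ``e_active`` wins)
    or bare :class:`RateConstants`, in which case the active enzyme is
    ``e_nominal * active_fraction`` from the design.  Product is truncated at
    ``s_total`` before noise.  ``seed`` overrides ``noise.seed``.
    """
    if noise is None:
        noise = NoiseModel(cv=0.0, floor=0.0)
    if isinstance(truth, RateConstants):
        truth = BurstParams(design.e_active, truth)
    clean = np.minimum(burst_product(design.times, truth), design.s_total)
    interior = clean[design.times > 0]
    if len(interior) and interior[0] >= design.s_total:
        raise SubstrateExhaustedError(
            "substrate exhausted before the second time point; sample the burst more densely"
        )
    rng = np.random.default_rng(seed if seed is not None else noise.seed)
    reps = np.vstack([noise.apply(clean, rng) for _ in range(design.replicates)])
    curve = ProgressCurve(
        times=design.times,
        product=reps.mean(axis=0),
        e_nominal=design.e_nominal,
        s_total=design.s_total,
        condition=dict(condition or {}),
        replicate_products=reps if design.replicates > 1 else None,
    )
    return curve, truth


def gen_titration(
    concs,
    truth: HyperbolaParams,
    noise: NoiseModel | None = None,
    seed: int | None = None,
    labels: dict | None = None,
) -> tuple[TitrationSeries, HyperbolaParams]:
    """Generate a rate-vs-activator-concentration series plus its truth."""
    concs = np.asarray(concs, dtype=float)
    if concs.size == 0:
        raise ValueError("empty concentration list")
    if np.any(concs < 0) or np.any(concs > 1e5):
        raise ValueError("concentrations must lie in [0, 1e5] nM")
    if noise is None:
        noise = NoiseModel(cv=0.0, floor=0.0)
    rng = np.random.default_rng(seed if seed is not None else noise.seed)
    clean = hyperbolic_rate(concs, truth)
    # rates have no additive densitometry floor; multiplicative term only
    rates = clean * (1.0 + rng.normal(0.0, noise.cv, size=clean.shape)) if noise.cv else clean
    rates = np.clip(rates, 0.0, None)
    meta = dict(labels or {})
    meta["max_conc_over_kd"] = float(np.max(concs) / truth.kd)
    series = TitrationSeries(concs=concs, k_burst_obs=rates, labels=meta)
    return series, truth


# --------------------------------------------------------------------------
# guide-length panel
# --------------------------------------------------------------------------

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: Fixed 30-nt guide; shorter guides are 5'-anchored truncations (3' trimming).
DEFAULT_GUIDE_30NT = "UAGCUAGGCAUUACGGCUAAGCGUACCGAU"


def rates_from_phases(k_burst: float, k_ss: float) -> RateConstants:
    """Invert (k_burst, k_ss) to the (k2, k3) pair with k2 >= k3.

    Requires ``k_ss <= k_burst/4``; k2 and k3 are the roots of
    ``x² - k_burst·x + k_burst·k_ss = 0``.
    """
    disc = k_burst * k_burst - 4.0 * k_burst * k_ss
    if disc < 0:
        raise ValueError(f"infeasible pair: k_ss={k_ss} exceeds k_burst/4={k_burst / 4}")
    root = np.sqrt(disc)
    return RateConstants(k2=(k_burst + root) / 2.0, k3=(k_burst - root) / 2.0)


#: Default per-length truths, calibrated to the published fold-relations
#: (>=50x k_burst drop and ~9-10x k_ss rise for 16 vs 30 nt), expressed as
#: (k_burst, k_ss) and converted to (k2, k3).
DEFAULT_LENGTH_TRUTHS: dict[int, RateConstants] = {
    16: rates_from_phases(0.02, 0.0040),
    21: rates_from_phases(0.15, 0.0020),
    26: rates_from_phases(0.50, 0.0010),
    30: rates_from_phases(1.10, 0.0004),
}


def guide_for_length(length: int) -> str:
    if not 10 <= length <= len(DEFAULT_GUIDE_30NT):
        raise ValueError(f"guide length {length} outside [10, 30]")
    return DEFAULT_GUIDE_30NT[:length]


def target_for_length(length: int) -> str:
    """Target fully complementary to guide positions g2..g<length>."""
    g = guide_for_length(length)
    return "".join(_COMPLEMENT[b] for b in reversed(g[1:]))


def gen_guide_length_panel(
    lengths=(16, 21, 26, 30),
    truth_map: dict[int, RateConstants] | None = None,
    noise: NoiseModel | None = None,
    seed: int | None = None,
    design: AssayDesign | None = None,
    allow_nonmonotone: bool = False,
) -> dict[int, tuple[ProgressCurve, BurstParams]]:
    """One progress curve per guide length, with guide/target metadata.

    The truth map must obey the observed law — shorter guide: smaller
    ``k_burst``, larger ``k_ss`` — unless ``allow_nonmonotone`` is set.
    """
    lengths = sorted(lengths)
    if truth_map is None:
        truth_map = DEFAULT_LENGTH_TRUTHS
    missing = [ln for ln in lengths if ln not in truth_map]
    if missing:
        raise ValueError(f"truth map missing lengths: {missing}")

    if not allow_nonmonotone:
        from .models import derived_rates

        phases = [derived_rates(truth_map[ln]) for ln in lengths]
        kb = [p[0] for p in phases]
        ks = [p[1] for p in phases]
        if any(b2 <= b1 for b1, b2 in zip(kb, kb[1:])) or any(
            s2 >= s1 for s1, s2 in zip(ks, ks[1:])
        ):
            raise ValueError(
                "truth map violates the length law (k_burst must rise and k_ss fall "
                "with guide length); pass allow_nonmonotone=True to override"
            )

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(lengths))
    panel: dict[int, tuple[ProgressCurve, BurstParams]] = {}
    base_design = design or AssayDesign()
    for ln, child in zip(lengths, child_seeds):
        sub_seed = int(child.generate_state(1)[0]) if seed is not None else None
        curve, truth = gen_progress_curve(
            base_design,
            truth_map[ln],
            noise=noise,
            seed=sub_seed,
            condition={
                "guide_length_nt": ln,
                "guide": guide_for_length(ln),
                "target": target_for_length(ln),
            },
        )
        panel[ln] = (curve, truth)
    return panel
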