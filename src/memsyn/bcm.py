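"""Triplet-STDP rate model and its generalized BCM learning rule.

In the rate formulation of last-spike-dominating triplet STDP, the expected
drift of the synaptic weight under uncorrelated Poisson pre/post trains at
rates ρx, ρy is

    dGc/dt = − Ã₂⁻ τ₋ ρx ρy − A₃⁻ τ₋ τx ρx² ρy + Ã₂⁺ τ₊ ρx ρy
             + A₃⁺ τ₊ τy ρx ρy²                                        (µS/s)

with pair amplitudes A₂± (µS), triplet amplitudes A₃± (µS), pair windows
τ± (s) and triplet windows τx, τy (s).  The pair amplitudes are activity
scaled, Ã₂± = A₂± ⟨ρyᵖ⟩ / ρ₀ᵖ, which turns the rule into a BCM law: the rate
threshold separating depression from potentiation,

    θ = ⟨ρyᵖ⟩ (A₂⁻ τ₋ − A₂⁺ τ₊) / (ρ₀ᵖ A₃⁺ τ₊ τy)                      (Hz)

slides with the running average ⟨ρyᵖ⟩ of postsynaptic activity.

The *minimal* rule used throughout sets A₂⁺ = A₃⁻ = 0, A₂⁻ = 0.02 µS,
A₃⁺ = 0.96 µS, τ₊ = 38 ms, τ₋ = 30 ms, τx = 16 ms, with ρ₀ = 10 Hz and p = 2.
The remaining window τy must be strictly positive for the potentiating
triplet term (and the threshold formula) to exist; it is treated here as a
calibration constant solved from the measured threshold at the G₀ = 0.5 µS
anchor (θ = 40 Hz), giving τy ≈ 6.6 ms by default.

History dependence enters through the experienced conductance G₀ of the
device: ⟨ρy⟩ is tied to G₀ by a power law ⟨ρy⟩ = a·G₀^q whose two constants
are solved exactly from two (G₀, θ) anchor pairs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "BCMCurve",
    "MINIMAL_TRIPLET",
    "DEFAULT_ANCHORS",
    "RateAverager",
    "SlidingCalibration",
    "SlidingParams",
    "TripletParams",
    "bcm_curve",
    "calibrate_sliding",
    "default_calibration",
    "dgc_dt",
    "fit_triplet_params",
    "integrate_weight_change",
    "map_g0_to_mean_rate",
    "threshold",
]


@dataclass(frozen=True)
class TripletParams:
    """Amplitudes (µS) and time windows (s) of the triplet rule."""

    a2_plus: float
    a2_minus: float
    a3_plus: float
    a3_minus: float
    tau_plus: float
    tau_minus: float
    tau_x: float
    tau_y: float

    def __post_init__(self) -> None:
        for name in ("a2_plus", "a2_minus", "a3_plus", "a3_minus"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("tau_plus and tau_minus must be > 0")
        if self.tau_x < 0:
            raise ValueError("tau_x must be >= 0")
        if self.tau_y <= 0:
            raise ValueError(
                "tau_y must be > 0: the potentiating triplet term and the "
                "threshold both carry a factor tau_y"
            )


@dataclass(frozen=True)
class SlidingParams:
    """Sliding-threshold constants: reference rate ρ₀ (Hz) and exponent p."""

    rho0: float = 10.0
    p: float = 2.0

    def __post_init__(self) -> None:
        if self.rho0 <= 0:
            raise ValueError("rho0 must be > 0")
        if self.p < 1:
            raise ValueError("p must be >= 1")


def _default_tau_y(
    theta_anchor: float = 40.0,
    a2_minus: float = 0.02,
    a3_plus: float = 0.96,
    tau_plus: float = 0.038,
    tau_minus: float = 0.030,
    sliding: SlidingParams = SlidingParams(),
) -> float:
    """τy solved so that θ = θ_anchor at the self-consistent point ⟨ρy⟩ = θ_anchor."""
    return (
        theta_anchor ** sliding.p
        * a2_minus
        * tau_minus
        / (sliding.rho0 ** sliding.p * a3_plus * tau_plus * theta_anchor)
    )


#: minimal triplet rule: pair depression + triplet potentiation only
MINIMAL_TRIPLET = TripletParams(
    a2_plus=0.0,
    a2_minus=0.02,
    a3_plus=0.96,
    a3_minus=0.0,
    tau_plus=0.038,
    tau_minus=0.030,
    tau_x=0.016,
    tau_y=_default_tau_y(),
)

#: measured (G₀ µS, θ Hz) threshold anchors of the sliding effect
DEFAULT_ANCHORS: tuple[tuple[float, float], ...] = ((0.5, 40.0), (7.0, 90.0))


@dataclass
class RateAverager:
    """Exponential running average of ρyᵖ (the BCM history variable ⟨ρyᵖ⟩).

    ``tau`` is in seconds; with one-second presentations the default
    corresponds to averaging over roughly ten presentations.
    """

    mean_rate_p: float = 0.0
    tau: float = 10.0
    p: float = 2.0

    def __post_init__(self) -> None:
        if self.mean_rate_p < 0:
            raise ValueError("mean_rate_p must be >= 0")
        if self.tau <= 0:
            raise ValueError("averaging time constant must be > 0")

    def update(self, rho_y: float, duration: float) -> None:
        lam = 1.0 - math.exp(-duration / self.tau)
        self.mean_rate_p += lam * (rho_y ** self.p - self.mean_rate_p)


def dgc_dt(
    rho_x: float,
    rho_y: float,
    mean_rate_p: float,
    params: TripletParams,
    sliding: SlidingParams = SlidingParams(),
) -> float:
    """Weight drift (µS/s) of the activity-scaled triplet rule at (ρx, ρy)."""
    if rho_x < 0 or rho_y < 0:
        raise ValueError("rates must be >= 0")
    scale = mean_rate_p / sliding.rho0 ** sliding.p
    a2_plus = params.a2_plus * scale
    a2_minus = params.a2_minus * scale
    return (
        -a2_minus * params.tau_minus * rho_x * rho_y
        - params.a3_minus * params.tau_minus * params.tau_x * rho_x**2 * rho_y
        + a2_plus * params.tau_plus * rho_x * rho_y
        + params.a3_plus * params.tau_plus * params.tau_y * rho_x * rho_y**2
    )


def threshold(
    params: TripletParams,
    sliding: SlidingParams,
    mean_rate_p: float,
) -> float:
    """Closed-form depression/potentiation threshold θ (Hz).

    θ is the positive root of ``dgc_dt`` in ρy (for A₃⁻ = 0), i.e. the rate
    at which the pair depression and triplet potentiation terms balance.
    """
    denom = sliding.rho0 ** sliding.p * params.a3_plus * params.tau_plus * params.tau_y
    if denom == 0:
        raise ValueError("threshold undefined: a3_plus·tau_plus·tau_y is zero")
    return (
        mean_rate_p
        * (params.a2_minus * params.tau_minus - params.a2_plus * params.tau_plus)
        / denom
    )


@dataclass(frozen=True)
class SlidingCalibration:
    """Power-law link between experienced conductance and mean activity.

    ⟨ρy⟩ = a · G₀^q (Hz for G₀ in µS); ⟨ρyᵖ⟩ = (a · G₀^q)ᵖ.
    """

    a: float
    q: float
    g0_range: tuple[float, float] = (0.0, math.inf)

    def mean_rate(self, g0: float) -> float:
        return self.a * g0**self.q


def calibrate_sliding(
    anchors,
    params: TripletParams = MINIMAL_TRIPLET,
    sliding: SlidingParams = SlidingParams(),
) -> SlidingCalibration:
    """Solve the G₀ → ⟨ρy⟩ power law from measured (G₀, θ) anchors.

    With θ ∝ ⟨ρy⟩ᵖ and ⟨ρy⟩ = a·G₀^q, two anchors give q exactly:
    ``q = ln(θ₂/θ₁) / (p·ln(G₀₂/G₀₁))``.  The scale ``a`` is set by the
    self-consistency convention that the running rate at the first anchor
    equals its threshold (the BCM fixed point), which also pins τy; the
    default parameter set already carries the τy solved this way, so here
    only (a, q) are returned.  Additional anchors must be consistent and are
    checked for monotonicity.
    """
    anchors = sorted((float(g), float(t)) for g, t in anchors)
    if len(anchors) < 1:
        raise ValueError("at least one (g0, theta) anchor is required")
    thetas = [t for _, t in anchors]
    if any(t2 <= t1 for t1, t2 in zip(thetas, thetas[1:])):
        raise ValueError("anchor thresholds must increase with g0")
    if len(anchors) == 1:
        (g1, t1) = anchors[0]
        return SlidingCalibration(a=t1, q=0.0, g0_range=(g1, g1))
    (g1, t1), (g2, t2) = anchors[0], anchors[-1]
    q = math.log(t2 / t1) / (sliding.p * math.log(g2 / g1))
    a = t1 / g1**q
    return SlidingCalibration(a=a, q=q, g0_range=(g1, g2))


def default_calibration() -> SlidingCalibration:
    """Calibration against the measured 40/90 Hz thresholds at 0.5/7.0 µS."""
    return calibrate_sliding(DEFAULT_ANCHORS)


def map_g0_to_mean_rate(
    g0: float,
    calibration: SlidingCalibration,
    sliding: SlidingParams = SlidingParams(),
) -> float:
    """⟨ρyᵖ⟩ (Hzᵖ) implied by an experienced conductance G₀ (µS)."""
    if g0 <= 0:
        raise ValueError("g0 must be > 0")
    lo, hi = calibration.g0_range
    if not (lo <= g0 <= hi):
        warnings.warn(
            f"g0 = {g0} µS outside the calibrated range [{lo}, {hi}] µS; "
            "extrapolating the power law",
            stacklevel=2,
        )
    return calibration.mean_rate(g0) ** sliding.p


@dataclass(frozen=True)
class BCMCurve:
    """ΔGc versus postsynaptic rate for one G₀, with its threshold θ."""

    rho_y: np.ndarray
    delta_g: np.ndarray
    theta: float
    g0: float


def bcm_curve(
    params: TripletParams,
    sliding: SlidingParams,
    calibration: SlidingCalibration,
    g0: float,
    grid: np.ndarray,
    duration: float = 1.0,
    rho_x: float | None = None,
    forgetting_offset: float = 0.0,
) -> BCMCurve:
    """BCM curve ΔGc(ρy) for a device with experienced conductance G₀.

    By default the presynaptic rate tracks the postsynaptic one (ρx = ρy),
    matching the symmetric triplet protocols where both trains share one
    frequency; pass ``rho_x`` to pin it instead.  ``forgetting_offset``
    (µS per unit ΔGc scale, ≥ 0) adds the device's spontaneous decay as a
    rate-saturating negative term when emulating device curves; the pure
    rate rule (offset 0) already vanishes at ρy = 0.
    """
    mean_p = map_g0_to_mean_rate(g0, calibration, sliding)
    grid = np.asarray(grid, dtype=float)
    values = np.empty_like(grid)
    for i, ry in enumerate(grid):
        rx = ry if rho_x is None else rho_x
        values[i] = dgc_dt(rx, ry, mean_p, params, sliding) * duration
        if forgetting_offset > 0.0:
            values[i] -= forgetting_offset * (1.0 - math.exp(-ry / sliding.rho0))
    return BCMCurve(
        rho_y=grid,
        delta_g=values,
        theta=threshold(params, sliding, mean_p),
        g0=g0,
    )


def fit_triplet_params(
    table: pd.DataFrame,
    fixed: dict[str, float] | None = None,
    sliding: SlidingParams = SlidingParams(),
    calibration: SlidingCalibration | None = None,
    x0: TripletParams = MINIMAL_TRIPLET,
    duration: float = 1.0,
    free: tuple[str, ...] = ("a2_minus", "a3_plus", "tau_y"),
) -> tuple[TripletParams, dict]:
    """Nonlinear least squares for triplet amplitudes/windows on ΔGc data.

    ``table`` needs columns ``rho_y``, ``g0`` and ``delta_g`` (ρx = ρy rows);
    ``free`` names the parameters to optimize (log-parameterized, so they
    stay positive), starting from ``x0`` — by default the minimal
    rule.  Note A₃⁺ and τy enter the rule only through their product, so the
    fit constrains that product while the split between the two follows the
    starting point.  Returns the fitted parameter set and diagnostics
    (residual norm, convergence flag, per-parameter estimates).
    """
    if len(table) < 8:
        raise ValueError("need at least 8 rows to fit the triplet rule")
    if not (table["delta_g"] > 0).any() or not (table["delta_g"] < 0).any():
        raise ValueError("fit table must span both signs of delta_g")
    calibration = default_calibration() if calibration is None else calibration
    base = replace(x0, **(fixed or {}))

    rho_y = table["rho_y"].to_numpy(float)
    g0 = table["g0"].to_numpy(float)
    target = table["delta_g"].to_numpy(float)
    mean_p = np.array(
        [map_g0_to_mean_rate(g, calibration, sliding) for g in g0]
    )

    def unpack(x: np.ndarray) -> TripletParams:
        return replace(base, **{name: math.exp(v) for name, v in zip(free, x)})

    def residuals(x: np.ndarray) -> np.ndarray:
        p = unpack(x)
        model = np.array(
            [
                dgc_dt(ry, ry, mp, p, sliding) * duration
                for ry, mp in zip(rho_y, mean_p)
            ]
        )
        return model - target

    start = np.array([math.log(getattr(base, name)) for name in free])
    # trust-region in log-space: robust to the rank-deficient a3_plus/tau_y
    # direction (they enter only through their product)
    sol = least_squares(
        residuals,
        start,
        method="trf",
        bounds=(start - math.log(1e3), start + math.log(1e3)),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    fitted = unpack(sol.x)
    if not sol.success:
        raise RuntimeError(
            f"triplet fit did not converge: final residual norm {sol.cost:.3e}"
        )
    diagnostics = {
        "residual_norm": float(np.linalg.norm(sol.fun)),
        "success": bool(sol.success),
        "n_points": int(len(table)),
        "estimates": {name: getattr(fitted, name) for name in free},
    }
    return fitted, diagnostics


def integrate_weight_change(
    rho_x: float,
    rho_y: float,
    duration: float,
    averager: RateAverager,
    params: TripletParams,
    sliding: SlidingParams,
    g: float,
    bounds: tuple[float, float],
) -> float:
    """Apply the rate rule for ``duration`` seconds from weight ``g``.

    Returns the realized ΔGc (µS), clipped so ``g + ΔGc`` stays within
    ``bounds``; the running ⟨ρyᵖ⟩ is updated with ρy over the same duration.
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    lo, hi = bounds
    delta = dgc_dt(rho_x, rho_y, averager.mean_rate_p, params, sliding) * duration
    delta = min(max(delta, lo - g), hi - g)
    if duration > 0:
        averager.update(rho_y, duration)
    return delta
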