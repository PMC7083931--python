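"""Phenomenological model of a second-order memristive synapse.

The device carries two state variables: a long-term conductance ``g``
(the synaptic weight, in µS) and a fast signed internal state ``u`` in
[−1, 1] standing in for the interfacial ion balance, the solid-state
analogue of synaptic Ca²⁺.  Positive effective voltage (top minus bottom
electrode) accumulates ions (u → +1), negative voltage depletes them
(u → −1), and ``u`` relaxes back with a time constant of ~130 ms, which
sets the ≤ 400 ms EPSC decay and the paired-pulse facilitation window.

Long-term writes require a super-threshold voltage but take their *sign*
from the instantaneous ion balance: an accumulated interface potentiates
under stimulation, a depleted one depresses.  Each pathway is silent below
an activation level (so single short spikes and read pulses never write)
and the potentiation pathway saturates under very strong sustained drive.
A constant-rate leak toward a resting conductance, growing with the
experienced conductance G₀ set by prior training, supplies the
history-dependent forgetting that slides the depression/potentiation
balance of the timing protocols.

The model is a behavioural stand-in for an oxide-based memristive synapse;
it makes no claim about the underlying ion drift/diffusion physics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ConvergenceError",
    "CurrentTrace",
    "DeviceParams",
    "DeviceState",
    "PulseWaveform",
    "apply_waveform",
    "init_device",
    "read_conductance",
    "relax",
    "set_experience",
    "simulate_epsc",
    "simulate_ppf",
    "simulate_rate_train",
    "step",
]

#: reference write amplitude (V); single-electrode spikes use ±2 V
V_REF = 2.0


class ConvergenceError(RuntimeError):
    """Raised when an iterative drive procedure exhausts its pulse budget."""


@dataclass(frozen=True)
class DeviceParams:
    """Device constants.

    Conductances are in µS, times in seconds, voltages in volts.  The default
    values were calibrated once against the behavioural contracts of the
    reference experiments (EPSC relaxation inside 400 ms, paired-pulse
    facilitation, rate-dependent facilitation at 20/50/100 Hz, and the
    sliding depression/potentiation threshold of symmetric triplet sweeps at
    experienced conductances 0.5–7.0 µS) and are not meant to be re-tuned
    per run.
    """

    g_min: float = 0.1          # lower conductance bound (µS)
    g_max: float = 8.0          # upper conductance bound (µS)
    g_rest: float = 0.3         # middle state the device forgets toward (µS)
    tau_u: float = 0.13         # internal-state relaxation time (s)
    tau_forget: float = 50721.5  # inverse leak scale (s·µS^forget_exp per µS)
    forget_exp: float = 0.22571  # sublinear growth of the leak with G₀ excess
    v_write_threshold: float = 1.0   # |v| below this never writes (V)
    v_read: float = 0.2         # read bias (V)
    read_width: float = 0.05    # read pulse width (s)
    alpha_u: float = 20.0       # u pump rate at the reference amplitude (1/s)
    eta_pot: float = 10.0       # potentiation gain (µS per unit drive·s)
    eta_dep: float = 20.0       # depression gain (µS per unit drive·s)
    u_exp_pot: float = 2.0      # potentiation drive exponent in u
    u_exp_dep: float = 2.0      # depression drive exponent in u
    u_on_pot: float = 0.30      # accumulation level where potentiation activates
    u_on_dep: float = 0.25      # depletion level where depression activates
    u_sat_pot: float = 0.35     # u excess above which potentiation saturates
    u_sat_dep: float = math.inf  # u excess above which depression shuts down
    bound_exp_pot: float = 0.0  # soft-bound exponent, potentiation side
    bound_exp_dep: float = 0.0  # soft-bound exponent, depression side
    epsc_gain: float = 3.0      # transient current gain β: I = g·v·(1 + β·u)
    noise_sd: float = 0.0       # relative (multiplicative) readout noise

    def __post_init__(self) -> None:
        if not (self.g_min < self.g_rest < self.g_max):
            raise ValueError(
                f"require g_min < g_rest < g_max, got "
                f"{self.g_min}, {self.g_rest}, {self.g_max}"
            )
        if self.tau_u <= 0:
            raise ValueError("tau_u must be positive")
        if self.v_write_threshold <= self.v_read:
            raise ValueError("v_write_threshold must exceed v_read")
        if self.eta_pot < 0 or self.eta_dep < 0:
            raise ValueError("write gains eta_pot, eta_dep must be >= 0")


@dataclass
class DeviceState:
    """Instantaneous device state.

    ``g`` is the long-term conductance Gc, ``u`` the fast ion-accumulation
    state, ``g0`` the experienced conductance G₀ (the long-term level set by
    prior stimulation, which controls the forgetting pressure), and ``t`` the
    device clock in seconds.
    """

    g: float
    u: float = 0.0
    g0: float = 0.0
    t: float = 0.0
    seed: int = 0

    def copy(self) -> "DeviceState":
        return replace(self)


@dataclass(frozen=True)
class PulseWaveform:
    """Piecewise-constant voltage waveform on one electrode.

    ``segments`` is a time-sorted sequence of ``(start, duration, amplitude)``
    with non-overlapping supports; outside all segments the electrode is held
    at 0 V.
    """

    segments: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        prev_end = -math.inf
        for start, duration, amplitude in self.segments:
            if duration <= 0:
                raise ValueError(f"segment duration must be > 0, got {duration}")
            if not (math.isfinite(start) and math.isfinite(amplitude)):
                raise ValueError("segment start and amplitude must be finite")
            if start < prev_end - 1e-12:
                raise ValueError(
                    f"overlapping segments: segment starting at {start} s begins "
                    f"before the previous one ends at {prev_end} s"
                )
            prev_end = start + duration

    @classmethod
    def from_pulses(
        cls, pulses: Sequence[tuple[float, float, float]]
    ) -> "PulseWaveform":
        """Build a waveform from possibly-overlapping pulses.

        Overlapping pulses on the same electrode sum their amplitudes, as for
        superposed generator outputs on one line.
        """
        if not pulses:
            return cls()
        edges = sorted({t for s, d, _ in pulses for t in (s, s + d)})
        segments: list[tuple[float, float, float]] = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            amp = sum(a for s, d, a in pulses if s <= lo + 1e-15 and s + d >= hi - 1e-15)
            if amp != 0.0:
                segments.append((lo, hi - lo, amp))
        # merge adjacent segments with equal amplitude
        merged: list[tuple[float, float, float]] = []
        for seg in segments:
            if merged and abs(merged[-1][2] - seg[2]) < 1e-15 and \
                    abs(merged[-1][0] + merged[-1][1] - seg[0]) < 1e-12:
                s, d, a = merged[-1]
                merged[-1] = (s, d + seg[1], a)
            else:
                merged.append(seg)
        return cls(tuple(merged))

    @property
    def start(self) -> float:
        return self.segments[0][0] if self.segments else 0.0

    @property
    def end(self) -> float:
        if not self.segments:
            return 0.0
        s, d, _ = self.segments[-1]
        return s + d

    def voltage_at(self, t: float) -> float:
        for start, duration, amplitude in self.segments:
            if start <= t < start + duration:
                return amplitude
        return 0.0


@dataclass(frozen=True)
class CurrentTrace:
    """Sampled current response: times in seconds, current in µA."""

    times: np.ndarray
    current: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        if len(self.times) != len(self.current):
            raise ValueError("times and current must have equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("trace times must be strictly increasing")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.current))):
            raise ValueError("trace values must be finite")

    @property
    def peak(self) -> float:
        return float(np.max(self.current))


# ---------------------------------------------------------------------------
# core dynamics
# ---------------------------------------------------------------------------


def init_device(g_init: float, params: DeviceParams, seed: int = 0) -> DeviceState:
    """Create a device at conductance ``g_init`` with a quiet internal state."""
    if g_init < params.g_min:
        raise ValueError(
            f"g_init = {g_init} µS is below the lower bound g_min = {params.g_min} µS"
        )
    if g_init > params.g_max:
        raise ValueError(
            f"g_init = {g_init} µS is above the upper bound g_max = {params.g_max} µS"
        )
    return DeviceState(g=float(g_init), u=0.0, g0=float(g_init), t=0.0, seed=seed)


def _u_drive(v: float, params: DeviceParams) -> float:
    """Signed pump strength of the internal state.

    Positive effective voltage accumulates ions (u → +1), negative voltage
    depletes them (u → −1).  The magnitude is zero at/below the read bias and
    saturates at the reference write amplitude, so superposed electrode
    pulses do not pump faster than a full-amplitude spike.
    """
    mag = min(max(abs(v) - params.v_read, 0.0) / (V_REF - params.v_read), 1.0)
    return math.copysign(mag, v)


def _phi(u: float, onset: float, exponent: float, sat: float) -> float:
    """u-dependence of a write pathway.

    Silent below the activation level ``onset`` (weak stimulation leaves the
    long-term state untouched), power-law rise above it, and an optional
    exponential shut-off ``sat`` for pathways that close again under very
    strong drive.
    """
    x = u - onset
    if x <= 0.0:
        return 0.0
    out = x ** exponent
    if math.isfinite(sat):
        out *= math.exp(-x / sat)
    return out


def _forget_rate(g0: float, params: DeviceParams) -> float:
    """Spontaneous leak rate (µS/s) toward g_rest.

    The leak is constant in time but grows (sublinearly, with exponent
    ``forget_exp``) with the experienced conductance G₀, reflecting the
    stronger relaxation pressure of a more strongly activated interface.
    A device never driven above the resting state does not leak.
    """
    excess = max(g0 - params.g_rest, 0.0)
    return excess**params.forget_exp / params.tau_forget


def _leak(g: float, g0: float, duration: float, params: DeviceParams) -> float:
    """Closed-form leak of g toward g_rest over ``duration`` seconds."""
    lam = _forget_rate(g0, params)
    if lam <= 0.0 or duration <= 0.0:
        return g
    excess = g - params.g_rest
    return params.g_rest + math.copysign(
        max(abs(excess) - lam * duration, 0.0), excess
    )


def step(state: DeviceState, v: float, dt: float, params: DeviceParams) -> DeviceState:
    """Advance the device by ``dt`` seconds under a constant voltage ``v``.

    The internal state is integrated exactly over the step (its equation is
    linear for constant voltage); the conductance uses a first-order update
    with the step-average u, which is accurate for dt ≪ tau_u.  Long-term
    writes require a super-threshold voltage but take their *sign* from the
    instantaneous ion balance u: an accumulated interface (u > 0) potentiates
    under stimulation, a depleted one (u < 0) depresses.
    """
    if not (math.isfinite(v) and math.isfinite(dt)):
        raise ValueError("voltage and dt must be finite")
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")

    # --- fast internal state: du/dt = a·(1 − sign(a)·u) − u/tau_u
    a = params.alpha_u * _u_drive(v, params)
    rate = abs(a) + 1.0 / params.tau_u
    u_inf = a / rate
    decay = math.exp(-rate * dt)
    u_new = u_inf + (state.u - u_inf) * decay
    u_mean = u_inf + (state.u - u_inf) * (1.0 - decay) / (rate * dt)

    # --- long-term conductance
    g = state.g
    if abs(v) >= params.v_write_threshold:
        span = params.g_max - params.g_min
        if u_mean > 0:
            bound = ((params.g_max - g) / span) ** params.bound_exp_pot
            g += (
                params.eta_pot
                * _phi(u_mean, params.u_on_pot, params.u_exp_pot, params.u_sat_pot)
                * bound
                * dt
            )
        elif u_mean < 0:
            bound = ((g - params.g_min) / span) ** params.bound_exp_dep
            g -= (
                params.eta_dep
                * _phi(-u_mean, params.u_on_dep, params.u_exp_dep, params.u_sat_dep)
                * bound
                * dt
            )
    # spontaneous forgetting toward the middle state (closed form)
    g = _leak(g, state.g0, dt, params)
    g = min(max(g, params.g_min), params.g_max)

    return DeviceState(g=g, u=u_new, g0=state.g0, t=state.t + dt, seed=state.seed)


def relax(state: DeviceState, duration: float, params: DeviceParams) -> DeviceState:
    """Let the device sit unbiased for ``duration`` seconds (closed form)."""
    if duration < 0:
        raise ValueError("relaxation duration must be >= 0")
    if duration == 0:
        return state.copy()
    u = state.u * math.exp(-duration / params.tau_u)
    g = _leak(state.g, state.g0, duration, params)
    g = min(max(g, params.g_min), params.g_max)
    return DeviceState(g=g, u=u, g0=state.g0, t=state.t + duration, seed=state.seed)


def read_conductance(
    state: DeviceState, params: DeviceParams, rng: np.random.Generator | None = None
) -> float:
    """Non-destructive readout of the long-term conductance (µS).

    Emulates a small read pulse (0.2 V, 50 ms): the bias is below the write
    threshold, so the state is untouched.  With ``noise_sd > 0`` the returned
    value carries multiplicative Gaussian noise.
    """
    g = state.g
    if params.noise_sd > 0.0:
        if rng is None:
            rng = np.random.default_rng(state.seed)
        g = g * (1.0 + params.noise_sd * rng.standard_normal())
    return float(g)


def apply_waveform(
    state: DeviceState,
    top: PulseWaveform,
    bottom: PulseWaveform,
    dt: float,
    params: DeviceParams,
) -> tuple[DeviceState, CurrentTrace]:
    """Drive the device with electrode waveforms and record the current.

    The effective device voltage is ``v_top(t) - v_bottom(t)``.  The current
    sample at each step is ``g·v_eff·(1 + β·u)`` (µA for µS and V); between
    stimulation and trace end the device is monitored at the read bias.
    """
    if dt <= 0 or not math.isfinite(dt):
        raise ValueError("dt must be positive and finite")
    if not top.segments and not bottom.segments:
        empty = CurrentTrace(np.empty(0), np.empty(0), dt)
        return state.copy(), empty

    t0 = min(
        [w.start for w in (top, bottom) if w.segments]
    )
    t1 = max([w.end for w in (top, bottom) if w.segments])
    n = max(int(round((t1 - t0) / dt)), 1)
    out = state.copy()
    if t0 > 0:
        out = relax(out, t0, params)
    times = np.empty(n)
    current = np.empty(n)
    for i in range(n):
        t_mid = t0 + (i + 0.5) * dt
        v = top.voltage_at(t_mid) - bottom.voltage_at(t_mid)
        out = step(out, v, dt, params)
        times[i] = t0 + (i + 1) * dt
        current[i] = out.g * v * (1.0 + params.epsc_gain * out.u)
    return out, CurrentTrace(times, current, dt)


# ---------------------------------------------------------------------------
# reference experiments
# ---------------------------------------------------------------------------


def _pulse_train_trace(
    state: DeviceState,
    params: DeviceParams,
    onsets: Sequence[float],
    amplitude: float,
    width: float,
    follow: float,
    dt: float,
) -> tuple[DeviceState, CurrentTrace]:
    """Simulate pulses at ``onsets`` and monitor at the read bias afterwards."""
    t_end = (max(onsets) + width if onsets else 0.0) + follow
    n = int(round(t_end / dt))
    out = state.copy()
    times = np.empty(n)
    current = np.empty(n)
    for i in range(n):
        t_mid = (i + 0.5) * dt
        v = params.v_read
        for onset in onsets:
            if onset <= t_mid < onset + width:
                v = amplitude
                break
        out = step(out, v, dt, params)
        times[i] = (i + 1) * dt
        current[i] = out.g * v * (1.0 + params.epsc_gain * out.u)
    return out, CurrentTrace(times, current, dt)


def simulate_epsc(
    state: DeviceState,
    params: DeviceParams,
    amplitude: float = 2.0,
    width: float = 0.01,
    follow: float = 1.0,
    dt: float = 1e-3,
) -> CurrentTrace:
    """Excitatory-postsynaptic-current analogue of a single presynaptic spike.

    A [2 V, 10 ms] pulse in the reference experiment; the current is then
    monitored under the read bias.  The transient relaxes with ``tau_u``.
    """
    if follow <= 0:
        raise ValueError("follow time must be > 0")
    _, trace = _pulse_train_trace(state, params, [0.0], amplitude, width, follow, dt)
    return trace


def simulate_ppf(
    state: DeviceState,
    params: DeviceParams,
    interval: float,
    amplitude: float = 2.0,
    width: float = 0.01,
    dt: float = 1e-3,
) -> tuple[float, float]:
    """Paired-pulse facilitation: peak currents (P1, P2) of two spikes.

    ``interval`` is onset-to-onset; the second peak exceeds the first when the
    internal state has not yet relaxed.
    """
    if interval <= width:
        raise ValueError(f"interval must exceed the pulse width {width} s")
    _, trace = _pulse_train_trace(
        state, params, [0.0, interval], amplitude, width, follow=5 * params.tau_u, dt=dt
    )
    n1 = int(round(width / dt))
    split = int(round(interval / dt))
    p1 = float(np.max(trace.current[:n1]))
    p2 = float(np.max(trace.current[split : split + int(round(width / dt))]))
    return p1, p2


def simulate_rate_train(
    state: DeviceState,
    params: DeviceParams,
    rate: float,
    n_pulses: int = 8,
    amplitude: float = 2.0,
    width: float = 0.01,
    dt: float = 1e-3,
) -> CurrentTrace:
    """Presynaptic spike train at a given rate (Hz); 8 × [2 V, 10 ms] reference."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    period = 1.0 / rate
    if period < width:
        raise ValueError(
            f"rate {rate} Hz gives a period below the pulse width {width} s; "
            "pulses would overlap"
        )
    onsets = [i * period for i in range(n_pulses)]
    _, trace = _pulse_train_trace(
        state, params, onsets, amplitude, width, follow=5 * params.tau_u, dt=dt
    )
    return trace


def set_experience(
    state: DeviceState,
    g0_target: float,
    params: DeviceParams,
    rate: float = 20.0,
    amplitude: float = 2.0,
    width: float = 0.03,
    tol: float = 0.02,
    max_pulses: int = 100_000,
    dt: float = 1e-3,
) -> DeviceState:
    """Drive the device to an experienced conductance G₀ and record it.

    Pulse trains (potentiating +2 V at the given rate, or sparse −2 V pulses
    for downward drive) are applied until the readout is within ``tol`` of
    the target; the reached conductance is then recorded as ``g0``, after
    which forgetting pressure scales with ``g0 - g_rest``.  The device is
    left relaxed (u ≈ 0).
    """
    if not (params.g_min <= g0_target <= params.g_max):
        raise ValueError(
            f"g0_target = {g0_target} µS outside [{params.g_min}, {params.g_max}] µS"
        )
    out = state.copy()
    if abs(out.g - g0_target) <= tol * g0_target:
        out = relax(out, 5 * params.tau_u, params)
        out.g0 = out.g
        return out

    gap_up = max(1.0 / rate - width, 0.0)
    # downward drive must be sparse: dense negative pulses keep u high, which
    # feeds the potentiation pathway instead of depressing
    gap_down = max(gap_up, 3.0 * params.tau_u)
    pulse_width = width
    for n in range(max_pulses):
        err = g0_target - out.g
        if abs(err) <= tol * g0_target:
            break
        v = amplitude if err > 0 else -amplitude
        steps = max(int(round(pulse_width / dt)), 1)
        for _ in range(steps):
            out = step(out, v, dt, params)
        out = relax(out, gap_up if err > 0 else gap_down, params)
        # halve the pulse width on overshoot so the 2% band is always reachable
        if (g0_target - out.g) * err < 0 and pulse_width > dt:
            pulse_width = max(pulse_width / 2.0, dt)
    else:
        raise ConvergenceError(
            f"could not reach g0 = {g0_target} µS within {max_pulses} pulses "
            f"(stopped at {out.g:.4f} µS)"
        )
    out = relax(out, 5 * params.tau_u, params)
    out.g0 = out.g
    return out
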