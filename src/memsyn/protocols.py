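"""Pair, triplet and rate stimulation protocols for the memristive synapse.

A *spike* here is an electrical event on one electrode: a pair of abutting
rectangular pulses of amplitude V⁺ = +2 V and V⁻ = −2 V, each 50 ms wide.
Presynaptic spikes go to the top electrode, postsynaptic spikes to the bottom
electrode, and the device sees ``v_top − v_bottom``, so the *same* physical
spike contributes with opposite polarity depending on its side — that is what
makes the device sensitive to the pre/post identity and ordering of spikes,
not only to their times.

Pulse order within a spike is a declared convention of this artifact (the
reference experiments do not fix it): V⁻ leads on both electrodes, so a
presynaptic spike contributes [−2, +2] V to the effective voltage and a
postsynaptic spike [+2, −2] V.  Of the two side-sensitive orderings this is
the one whose tight 'post-pre-post' waveform lets the accumulation stretches
coincide with an already-elevated internal state — potentiation-dominant —
while the mirrored 'pre-post-pre' sequence is depression-dominant and hence
clipped to near-zero at the conductance floor, reproducing the
last-spike-dominating triplet behaviour at low experienced conductance.

Triplet timing follows the (Δt₁, Δt₂) convention: each Δt is
``t_post − t_pre`` of one pairing, the first pairing giving Δt₁ and the
second Δt₂, so e.g. 'post-pre-post' always has Δt₁ < 0 and Δt₂ > 0
(quadrant II of the timing plane).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .device import (
    DeviceParams,
    DeviceState,
    PulseWaveform,
    apply_waveform,
    init_device,
    read_conductance,
    relax,
    set_experience,
)

__all__ = [
    "SpikeEvent",
    "SpikeShape",
    "TripletProtocol",
    "ProtocolResult",
    "TRIPLET_KINDS",
    "build_pair",
    "build_triplet",
    "decompose_triplet",
    "compile_waveforms",
    "frequency_from_timing",
    "prepare_device",
    "run_protocol",
    "sweep_symmetric_triplet",
    "sweep_asymmetric_triplet",
    "sweep_quadrants",
    "sweep_rate_pairs",
    "threshold_frequency",
]

Side = Literal["pre", "post"]

#: the six triplet sequences with their (sign of Δt₁, sign of Δt₂) constraints
#: and, for same-sign quadrants, the required ordering of |Δt₁| vs |Δt₂|
TRIPLET_KINDS: dict[str, tuple[int, int]] = {
    "post-pre-post": (-1, +1),
    "pre-post-pre": (+1, -1),
    "pre-pre-post": (+1, +1),
    "pre-post-post": (+1, +1),
    "post-post-pre": (-1, -1),
    "post-pre-pre": (-1, -1),
}


@dataclass(frozen=True)
class SpikeEvent:
    """A single pre- or postsynaptic spike time (seconds)."""

    time: float
    side: Side

    def __post_init__(self) -> None:
        if not math.isfinite(self.time):
            raise ValueError("spike time must be finite")
        if self.side not in ("pre", "post"):
            raise ValueError(f"side must be 'pre' or 'post', got {self.side!r}")


@dataclass(frozen=True)
class SpikeShape:
    """Electrical shape of one spike: a V⁺/V⁻ pulse pair, each ``width`` wide."""

    v_plus: float = 2.0
    v_minus: float = -2.0
    width: float = 0.05
    order: Literal["plus_first", "minus_first"] = "minus_first"

    def __post_init__(self) -> None:
        if not (self.v_plus > 0 > self.v_minus):
            raise ValueError("require v_plus > 0 > v_minus")
        if self.width <= 0:
            raise ValueError("pulse width must be > 0")

    @property
    def duration(self) -> float:
        return 2.0 * self.width

    def pulses(self, onset: float) -> list[tuple[float, float, float]]:
        first, second = (
            (self.v_plus, self.v_minus)
            if self.order == "plus_first"
            else (self.v_minus, self.v_plus)
        )
        return [(onset, self.width, first), (onset + self.width, self.width, second)]


@dataclass(frozen=True)
class TripletProtocol:
    """A triplet spike sequence parameterized by kind and (Δt₁, Δt₂)."""

    kind: str
    dt1: float
    dt2: float

    def __post_init__(self) -> None:
        _validate_triplet(self.kind, self.dt1, self.dt2)

    def events(self) -> list[SpikeEvent]:
        pre, post = build_triplet(self.kind, self.dt1, self.dt2)
        return sorted(pre + post, key=lambda e: e.time)


@dataclass(frozen=True)
class ProtocolResult:
    """Outcome of one stimulation run: ΔGc = G_final − reference.

    The reference is the experienced conductance G₀ when one was prepared
    (here G₀ is always recorded on the state), per the readout convention of
    the triplet experiments.
    """

    g_initial: float
    g_final: float
    delta_g: float
    g0: float
    descriptor: str
    warn_saturated: bool = False


def _validate_triplet(kind: str, dt1: float, dt2: float) -> None:
    if kind not in TRIPLET_KINDS:
        raise ValueError(f"unknown triplet kind {kind!r}")
    s1, s2 = TRIPLET_KINDS[kind]
    if dt1 * s1 <= 0:
        raise ValueError(
            f"{kind} requires dt1 {'> 0' if s1 > 0 else '< 0'}, got {dt1}"
        )
    if dt2 * s2 <= 0:
        raise ValueError(
            f"{kind} requires dt2 {'> 0' if s2 > 0 else '< 0'}, got {dt2}"
        )
    if kind in ("pre-pre-post", "post-post-pre") and not abs(dt1) > abs(dt2):
        raise ValueError(f"{kind} requires |dt1| > |dt2| (first pairing is wider)")
    if kind in ("pre-post-post", "post-pre-pre") and not abs(dt2) > abs(dt1):
        raise ValueError(f"{kind} requires |dt2| > |dt1| (second pairing is wider)")


def build_pair(dt: float) -> tuple[list[SpikeEvent], list[SpikeEvent]]:
    """One pre and one post spike with ``t_post − t_pre = dt`` (earliest at 0)."""
    if dt == 0:
        raise ValueError("dt = 0 is undefined: simultaneous pre/post spikes")
    if dt > 0:
        pre, post = [SpikeEvent(0.0, "pre")], [SpikeEvent(dt, "post")]
    else:
        pre, post = [SpikeEvent(-dt, "pre")], [SpikeEvent(0.0, "post")]
    return pre, post


def build_triplet(
    kind: str, dt1: float, dt2: float
) -> tuple[list[SpikeEvent], list[SpikeEvent]]:
    """Three spike events realizing a triplet; earliest event at t = 0.

    Each Δt is measured between the shared spike of the two pairings and the
    other spike of that pairing, as ``t_post − t_pre``.
    """
    _validate_triplet(kind, dt1, dt2)
    if kind == "post-pre-post":
        # shared middle pre; posts on both sides
        pre = [-dt1]
        post = [0.0, -dt1 + dt2]
    elif kind == "pre-post-pre":
        pre = [0.0, dt1 - dt2]
        post = [dt1]
    elif kind == "pre-pre-post":
        # shared post after two pres
        pre = [0.0, dt1 - dt2]
        post = [dt1]
    elif kind == "pre-post-post":
        pre = [0.0]
        post = [dt1, dt2]
    elif kind == "post-post-pre":
        # both posts precede the shared pre; earliest post at t = 0
        post = [0.0, dt2 - dt1]
        pre = [-dt1]
    else:  # post-pre-pre
        post = [0.0]
        pre = [-dt1, -dt2]
    return (
        [SpikeEvent(t, "pre") for t in sorted(pre)],
        [SpikeEvent(t, "post") for t in sorted(post)],
    )


def decompose_triplet(
    kind: str, pre: Sequence[SpikeEvent], post: Sequence[SpikeEvent]
) -> tuple[float, float]:
    """Recover (Δt₁, Δt₂) from built triplet events (round-trip of build)."""
    pre_t = sorted(e.time for e in pre)
    post_t = sorted(e.time for e in post)
    if kind == "post-pre-post":
        (p,) = pre_t
        return post_t[0] - p, post_t[1] - p
    if kind == "pre-post-pre":
        (q,) = post_t
        return q - pre_t[0], q - pre_t[1]
    if kind == "pre-pre-post":
        (q,) = post_t
        return q - pre_t[0], q - pre_t[1]
    if kind == "pre-post-post":
        (p,) = pre_t
        return post_t[0] - p, post_t[1] - p
    if kind == "post-post-pre":
        (p,) = pre_t
        return post_t[0] - p, post_t[1] - p
    if kind == "post-pre-pre":
        (q,) = post_t
        return q - pre_t[0], q - pre_t[1]
    raise ValueError(f"unknown triplet kind {kind!r}")


def compile_waveforms(
    pre: Iterable[SpikeEvent],
    post: Iterable[SpikeEvent],
    shape: SpikeShape = SpikeShape(),
) -> tuple[PulseWaveform, PulseWaveform]:
    """Compile spike events to top (pre) and bottom (post) electrode waveforms.

    Overlapping pulses on the same electrode sum their amplitudes.
    """
    top_pulses: list[tuple[float, float, float]] = []
    bottom_pulses: list[tuple[float, float, float]] = []
    for event in pre:
        top_pulses.extend(shape.pulses(event.time))
    for event in post:
        bottom_pulses.extend(shape.pulses(event.time))
    return PulseWaveform.from_pulses(top_pulses), PulseWaveform.from_pulses(
        bottom_pulses
    )


def frequency_from_timing(dt1: float, dt2: float) -> float:
    """Postsynaptic-rate reading of a triplet: ρy = 1/(|Δt₁| + |Δt₂|) in Hz."""
    denom = abs(dt1) + abs(dt2)
    if denom <= 0:
        raise ValueError("|dt1| + |dt2| must be positive")
    return 1.0 / denom


def prepare_device(
    g0: float,
    params: DeviceParams,
    g_start: float | None = None,
    seed: int = 0,
) -> DeviceState:
    """Fresh device activated from a low initial state to experienced G₀."""
    g_start = params.g_min if g_start is None else g_start
    state = init_device(g_start, params, seed=seed)
    return set_experience(state, g0, params)


def run_protocol(
    device: DeviceState,
    protocol: TripletProtocol | tuple[Sequence[SpikeEvent], Sequence[SpikeEvent]] | None,
    params: DeviceParams,
    shape: SpikeShape = SpikeShape(),
    relax_after: float = 60.0,
    dt: float = 1e-3,
) -> ProtocolResult:
    """Apply a protocol, wait ``relax_after`` device-clock seconds, read ΔGc.

    The long-term change is read against the experienced conductance recorded
    on the state (equal to the initial conductance for a fresh device).
    """
    if isinstance(protocol, TripletProtocol):
        pre, post = build_triplet(protocol.kind, protocol.dt1, protocol.dt2)
        descriptor = f"{protocol.kind}({protocol.dt1 * 1e3:+.1f},{protocol.dt2 * 1e3:+.1f} ms)"
    elif protocol is None:
        pre, post = [], []
        descriptor = "empty"
    else:
        pre, post = list(protocol[0]), list(protocol[1])
        descriptor = f"{len(pre)}pre+{len(post)}post"

    g_initial = read_conductance(device, params)
    eps = 1e-12
    warn = device.g <= params.g_min + eps or device.g >= params.g_max - eps

    top, bottom = compile_waveforms(pre, post, shape)
    state, _ = apply_waveform(device, top, bottom, dt, params)
    state = relax(state, relax_after, params)
    g_final = read_conductance(state, params)
    return ProtocolResult(
        g_initial=g_initial,
        g_final=g_final,
        delta_g=g_final - device.g0,
        g0=device.g0,
        descriptor=descriptor,
        warn_saturated=warn,
    )


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------


def _run_cell(
    base: DeviceState,
    kind: str,
    dt1: float,
    dt2: float,
    params: DeviceParams,
    shape: SpikeShape,
    relax_after: float,
    dt: float,
) -> dict:
    result = run_protocol(
        base.copy(), TripletProtocol(kind, dt1, dt2), params, shape, relax_after, dt
    )
    return {
        "kind": kind,
        "g0_uS": result.g0,
        "dt1_ms": dt1 * 1e3,
        "dt2_ms": dt2 * 1e3,
        "rho_y_Hz": frequency_from_timing(dt1, dt2),
        "delta_g_uS": result.delta_g,
        "warn_saturated": result.warn_saturated,
    }


def sweep_symmetric_triplet(
    g0_levels: Sequence[float],
    dt_grid: Sequence[float],
    params: DeviceParams = DeviceParams(),
    kinds: Sequence[str] = ("post-pre-post", "pre-post-pre"),
    shape: SpikeShape = SpikeShape(),
    relax_after: float = 60.0,
    dt: float = 1e-3,
) -> pd.DataFrame:
    """Symmetric-timing triplet sweep (|Δt₁| = |Δt₂|) over kinds × G₀ × Δt.

    Every cell runs on a fresh device prepared at its G₀; preparation is
    deterministic, so one prepared snapshot per G₀ level is reused.
    """
    rows = []
    for g0 in g0_levels:
        base = prepare_device(g0, params)
        for kind in kinds:
            s1, s2 = TRIPLET_KINDS[kind]
            for dt_abs in dt_grid:
                rows.append(
                    _run_cell(
                        base, kind, s1 * dt_abs, s2 * dt_abs,
                        params, shape, relax_after, dt,
                    )
                )
    return pd.DataFrame(rows)


def sweep_asymmetric_triplet(
    fixed_dt1: float,
    dt2_grid: Sequence[float],
    kind: str,
    g0: float,
    params: DeviceParams = DeviceParams(),
    shape: SpikeShape = SpikeShape(),
    relax_after: float = 60.0,
    dt: float = 1e-3,
) -> pd.DataFrame:
    """Asymmetric sweep: Δt₁ held fixed while Δt₂ varies (fresh device per cell)."""
    base = prepare_device(g0, params)
    rows = [
        _run_cell(base, kind, fixed_dt1, dt2, params, shape, relax_after, dt)
        for dt2 in dt2_grid
    ]
    return pd.DataFrame(rows)


def sweep_quadrants(
    dt1_grid: Sequence[float],
    dt2_grid: Sequence[float],
    g0: float = 3.0,
    params: DeviceParams = DeviceParams(),
    shape: SpikeShape = SpikeShape(),
    relax_after: float = 60.0,
    dt: float = 1e-3,
) -> pd.DataFrame:
    """Full (Δt₁, Δt₂) map over all six triplet kinds, labelled by quadrant.

    The grids are magnitudes; signs come from each kind's constraint, so the
    four quadrants of the timing plane are all populated.  A relatively high
    G₀ (default 3.0 µS) highlights the history-dependent structure.
    """
    base = prepare_device(g0, params)
    quadrant = {
        (+1, +1): "I",
        (-1, +1): "II",
        (-1, -1): "III",
        (+1, -1): "IV",
    }
    rows = []
    for kind, (s1, s2) in TRIPLET_KINDS.items():
        for a1 in dt1_grid:
            for a2 in dt2_grid:
                dt1, dt2 = s1 * abs(a1), s2 * abs(a2)
                try:
                    _validate_triplet(kind, dt1, dt2)
                except ValueError:
                    continue  # ordering constraint (|dt1| vs |dt2|) not met
                row = _run_cell(base, kind, dt1, dt2, params, shape, relax_after, dt)
                row["quadrant"] = quadrant[(s1, s2)]
                rows.append(row)
    return pd.DataFrame(rows)


def sweep_rate_pairs(
    freqs: Sequence[float],
    n_pairs: int = 3,
    g0: float = 0.5,
    pair_dt: float = 0.04,
    params: DeviceParams = DeviceParams(),
    shape: SpikeShape = SpikeShape(),
    relax_after: float = 60.0,
    dt: float = 1e-3,
) -> pd.DataFrame:
    """Rate dependence of pair stimulation: n pairs of pre/post spikes at each rate.

    Pre and post trains share the same rate (ρx = ρy = freq).  The pairing
    sign is the within-pair timing: +|pair_dt| (pre leads, LTP pairing) or
    −|pair_dt| (post leads, LTD pairing).
    """
    rows = []
    base = prepare_device(g0, params)
    for freq in freqs:
        if freq <= 0:
            raise ValueError("pair rate must be positive")
        period = 1.0 / freq
        for sign, label in ((+1, "LTP"), (-1, "LTD")):
            pre, post = [], []
            for i in range(n_pairs):
                p, q = build_pair(sign * pair_dt)
                pre.extend(SpikeEvent(e.time + i * period, "pre") for e in p)
                post.extend(SpikeEvent(e.time + i * period, "post") for e in q)
            result = run_protocol(
                base.copy(), (pre, post), params, shape, relax_after, dt
            )
            rows.append(
                {
                    "freq_Hz": freq,
                    "pairing": label,
                    "pair_dt_ms": sign * pair_dt * 1e3,
                    "g0_uS": result.g0,
                    "delta_g_uS": result.delta_g,
                    "warn_saturated": result.warn_saturated,
                }
            )
    return pd.DataFrame(rows)


def threshold_frequency(table: pd.DataFrame) -> float:
    """Interpolated zero-crossing rate (Hz) of ΔGc on the frequency axis.

    Expects a single-kind, single-G₀ sweep table with columns ``rho_y_Hz``
    and ``delta_g_uS``; returns the rate at which depression turns into
    potentiation, found by linear interpolation around the sign change.
    """
    tab = table.sort_values("rho_y_Hz")
    f = tab["rho_y_Hz"].to_numpy(float)
    y = tab["delta_g_uS"].to_numpy(float)
    sign_change = np.nonzero(np.diff(np.sign(y)) != 0)[0]
    if len(sign_change) == 0:
        raise ValueError("no zero crossing of delta_g on the sweep")
    i = sign_change[-1]  # crossing at the highest rate
    f0, f1, y0, y1 = f[i], f[i + 1], y[i], y[i + 1]
    if y1 == y0:
        return float(0.5 * (f0 + f1))
    return float(f0 - y0 * (f1 - f0) / (y1 - y0))
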