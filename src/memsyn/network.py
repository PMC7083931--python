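"""Winner-take-all feedforward network with triplet-BCM plasticity.

An input layer of 81 Poisson neurons (a 9×9 pixel array) feeds 4 output
neurons through a full 81×4 weight matrix (conductances, µS).  Each training
presentation shows either one of four oriented bars (0°, 45°, 90°, 135°;
9 high-rate pixels at 40 Hz against a 10 Hz background) or a random noise
pattern (9 uniformly chosen high pixels).  Output rates are the weighted sums
of realized input rates; only the neuron with the maximal rate fires
(winner-take-all) and updates its weights and sliding threshold with the
triplet-BCM rule.  Because the threshold of a frequently winning neuron
rises, that neuron eventually depresses its response to all but one pattern,
and the four neurons settle on pairwise distinct preferred orientations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bcm import (
    MINIMAL_TRIPLET,
    RateAverager,
    SlidingParams,
    TripletParams,
    dgc_dt,
    threshold,
)

__all__ = [
    "NetworkConfig",
    "NetworkState",
    "PatternSet",
    "SelectivityReport",
    "ORIENTATIONS",
    "assign_rates",
    "compute_post_rates",
    "evaluate_selectivity",
    "make_noise_pattern",
    "make_orientation_patterns",
    "sample_realized_rates",
    "train",
    "train_step",
    "winner_take_all",
]

ORIENTATIONS = (0, 45, 90, 135)


@dataclass(frozen=True)
class PatternSet:
    """The four 9×9 orientation-bar masks, keyed by angle in degrees."""

    masks: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        for angle, mask in self.masks.items():
            if mask.shape != (9, 9) or mask.dtype != bool:
                raise ValueError(f"mask for {angle}° must be a 9×9 boolean grid")
            if int(mask.sum()) != 9:
                raise ValueError(f"mask for {angle}° must have exactly 9 high pixels")


@dataclass(frozen=True)
class NetworkConfig:
    """Network and training constants.

    Rates are mean Poisson rates in Hz; weights in µS.  ``post_rate_gain``
    converts the weighted input-rate sum into an output rate
    (ρyⁿ = gain·Σ ρx·G in Hz per Hz·µS); the default places the initial
    responses (~34 Hz) just under the quiescent BCM fixed point (40 Hz) and
    the selective fixed point (~300 Hz) well inside the weight bounds.
    ``sample_duration`` is the window over which realized Poisson rates are
    measured; ``plasticity_duration`` is the effective integration time of
    the rate rule per presentation, which sets the learning-rate scale.
    ``weight_decay`` is the per-presentation stimulated-forgetting leak of
    the firing neuron's synapses toward the weight floor.
    """

    n_pre: int = 81
    n_post: int = 4
    rate_high: float = 40.0
    rate_low: float = 10.0
    sample_duration: float = 1.0
    plasticity_duration: float = 0.005
    epochs: int = 2000
    seed: int = 0
    w_min: float = 0.01
    w_max: float = 8.0
    w_init_low: float = 0.1
    w_init_high: float = 0.15
    post_rate_gain: float = 0.25
    averager_tau: float = 3.0
    weight_decay: float = 0.005

    def __post_init__(self) -> None:
        if not (self.rate_high > self.rate_low > 0):
            raise ValueError("require rate_high > rate_low > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (self.w_min < self.w_max):
            raise ValueError("require w_min < w_max")


@dataclass
class NetworkState:
    """Mutable training state: weights (81×4), per-neuron θ and ⟨ρyᵖ⟩."""

    weights: np.ndarray
    averagers: list[RateAverager]
    rng: np.random.Generator
    epoch: int = 0

    def thetas(self, params: TripletParams, sliding: SlidingParams) -> np.ndarray:
        return np.array(
            [threshold(params, sliding, a.mean_rate_p) for a in self.averagers]
        )


@dataclass(frozen=True)
class SelectivityReport:
    """Per-neuron orientation preference and bar/background weight contrast."""

    preferred: tuple[int, ...]           # degrees, one per output neuron
    selectivity_index: tuple[float, ...]  # mean bar weight / mean background weight
    distinct_count: int
    success: bool


def make_orientation_patterns() -> PatternSet:
    """Centered bars: 0° = middle row, 90° = middle column, 45°/135° = diagonals."""
    masks: dict[int, np.ndarray] = {}
    eye = np.eye(9, dtype=bool)
    base = np.zeros((9, 9), dtype=bool)
    row = base.copy()
    row[4, :] = True
    col = base.copy()
    col[:, 4] = True
    masks[0] = row
    masks[90] = col
    masks[45] = eye[:, ::-1]   # rising diagonal
    masks[135] = eye
    return PatternSet(masks)


def make_noise_pattern(rng: np.random.Generator) -> np.ndarray:
    """Nine high pixels drawn uniformly without replacement over the 81."""
    mask = np.zeros(81, dtype=bool)
    mask[rng.choice(81, size=9, replace=False)] = True
    return mask.reshape(9, 9)


def assign_rates(mask: np.ndarray, config: NetworkConfig) -> np.ndarray:
    """Mean-rate vector (length 81): high on masked pixels, low elsewhere."""
    flat = np.asarray(mask, dtype=bool).ravel()
    if flat.size != config.n_pre:
        raise ValueError(f"mask must have {config.n_pre} pixels")
    return np.where(flat, config.rate_high, config.rate_low).astype(float)


def sample_realized_rates(
    rates: np.ndarray, duration: float, rng: np.random.Generator
) -> np.ndarray:
    """Realized rates of Poisson trains: counts over ``duration`` divided by it."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    counts = rng.poisson(np.asarray(rates, dtype=float) * duration)
    return counts / duration


def compute_post_rates(
    realized_rates: np.ndarray, weights: np.ndarray, gain: float
) -> np.ndarray:
    """Output rates ρyⁿ = gain · Σₘ ρx,m Gₘⁿ (Hz)."""
    realized_rates = np.asarray(realized_rates, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if weights.ndim != 2 or realized_rates.shape != (weights.shape[0],):
        raise ValueError(
            f"dimension mismatch: rates {realized_rates.shape} vs weights "
            f"{weights.shape}"
        )
    return gain * (realized_rates @ weights)


def winner_take_all(rho_y: np.ndarray) -> int:
    """Index of the maximal output rate; ties go to the lowest index."""
    return int(np.argmax(rho_y))


def init_state(config: NetworkConfig) -> NetworkState:
    """Stochastic initial state with low weights, seeded.

    Each running average ⟨ρyᵖ⟩ starts at the neuron's own response to the
    session-average input rate, so the sliding thresholds begin consistent
    with the initial activity instead of at zero — an all-zero start makes
    the first win explosively potentiating and lets one or two neurons
    monopolize every pattern before the others ever fire.
    """
    rng = np.random.default_rng(config.seed)
    weights = rng.uniform(
        config.w_init_low, config.w_init_high, size=(config.n_pre, config.n_post)
    )
    mean_rate = (9 * config.rate_high + 72 * config.rate_low) / 81.0
    base_resp = config.post_rate_gain * mean_rate * weights.sum(axis=0)
    averagers = [
        RateAverager(
            mean_rate_p=float(base_resp[n]) ** 2.0,
            tau=config.averager_tau,
            p=2.0,
        )
        for n in range(config.n_post)
    ]
    return NetworkState(weights=weights, averagers=averagers, rng=rng)


def train_step(
    state: NetworkState,
    stimulus_mask: np.ndarray,
    config: NetworkConfig,
    params: TripletParams = MINIMAL_TRIPLET,
    sliding: SlidingParams = SlidingParams(),
) -> int:
    """One presentation: sample rates, pick the winner, update its column.

    Only the winning neuron fires, so only its 81 weights move; the losers'
    columns are untouched.  The running ⟨ρyᵖ⟩ (hence the threshold θⁿ) of
    *every* neuron tracks its own computed rate: the sliding threshold is a
    property of postsynaptic activity history, and letting it follow the
    subthreshold rate as well keeps a frequently-winning neuron's θ high
    enough that its non-preferred responses are depressed below the
    untrained level, which is what allows the remaining orientations to be
    handed over to the other neurons.
    """
    rates = assign_rates(stimulus_mask, config)
    realized = sample_realized_rates(rates, config.sample_duration, state.rng)
    rho_y = compute_post_rates(realized, state.weights, config.post_rate_gain)
    winner = winner_take_all(rho_y)
    ry = float(rho_y[winner])
    drift = config.plasticity_duration * np.array(
        [
            dgc_dt(rx, ry, state.averagers[winner].mean_rate_p, params, sliding)
            for rx in realized
        ]
    )
    column = state.weights[:, winner]
    # the firing neuron's memristive synapses also forget: a small
    # stimulation-driven leak toward the weight floor, as in the device
    updated = column + drift - config.weight_decay * (column - config.w_min)
    state.weights[:, winner] = np.clip(updated, config.w_min, config.w_max)
    for n, averager in enumerate(state.averagers):
        averager.update(float(rho_y[n]), config.sample_duration)
    return winner


def train(
    config: NetworkConfig = NetworkConfig(),
    params: TripletParams = MINIMAL_TRIPLET,
    sliding: SlidingParams = SlidingParams(),
    patterns: PatternSet | None = None,
    history_every: int = 10,
) -> tuple[NetworkState, pd.DataFrame, SelectivityReport]:
    """Full training run: per epoch, 4 oriented bars + 4 fresh noise patterns.

    The eight presentations of an epoch are shuffled (equal probability for
    patterns and noise).  History rows record, every ``history_every``
    epochs, each neuron's response rate to each orientation, its threshold,
    and its mean on-bar weight.
    """
    patterns = make_orientation_patterns() if patterns is None else patterns
    state = init_state(config)
    records: list[dict] = []
    angles = list(patterns.masks)
    for epoch in range(config.epochs):
        stimuli: list[np.ndarray] = [patterns.masks[a] for a in angles]
        stimuli += [make_noise_pattern(state.rng) for _ in range(len(angles))]
        order = state.rng.permutation(len(stimuli))
        for idx in order:
            train_step(state, stimuli[idx], config, params, sliding)
        state.epoch = epoch + 1
        if (epoch + 1) % history_every == 0 or epoch == config.epochs - 1:
            thetas = state.thetas(params, sliding)
            for n in range(config.n_post):
                for angle in angles:
                    mean_rates = assign_rates(patterns.masks[angle], config)
                    ry = compute_post_rates(
                        mean_rates, state.weights, config.post_rate_gain
                    )[n]
                    records.append(
                        {
                            "epoch": epoch + 1,
                            "neuron": n,
                            "orientation_deg": angle,
                            "rho_y_Hz": float(ry),
                            "theta_Hz": float(thetas[n]),
                            "mean_bar_weight_uS": float(
                                state.weights[patterns.masks[angle].ravel(), n].mean()
                            ),
                        }
                    )
    history = pd.DataFrame(records)
    report = evaluate_selectivity(state, patterns)
    return state, history, report


def evaluate_selectivity(
    state: NetworkState, patterns: PatternSet
) -> SelectivityReport:
    """Preferred orientation and bar/background contrast of each neuron."""
    preferred: list[int] = []
    indices: list[float] = []
    for n in range(state.weights.shape[1]):
        column = state.weights[:, n]
        bar_means = {
            angle: column[mask.ravel()].mean()
            for angle, mask in patterns.masks.items()
        }
        best = max(bar_means, key=lambda a: bar_means[a])
        off_bar = column[~patterns.masks[best].ravel()]
        preferred.append(best)
        indices.append(float(bar_means[best] / off_bar.mean()))
    distinct = len(set(preferred))
    return SelectivityReport(
        preferred=tuple(preferred),
        selectivity_index=tuple(indices),
        distinct_count=distinct,
        success=distinct == state.weights.shape[1],
    )
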