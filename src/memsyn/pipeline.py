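"""End-to-end pipeline: device demos → timing sweeps → BCM curves → network.

Each stage writes delimited-text tables under the configured output
directory and the whole run is summarized in a JSON report.  The same
functions back the numbered analysis scripts.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .bcm import (
    MINIMAL_TRIPLET,
    SlidingParams,
    bcm_curve,
    default_calibration,
    dgc_dt,
    map_g0_to_mean_rate,
)
from .config import RunConfig, substream
from .device import init_device, simulate_epsc, simulate_ppf
from .network import NetworkConfig, train
from .protocols import (
    sweep_quadrants,
    sweep_symmetric_triplet,
    threshold_frequency,
)

def _version() -> str:
    from . import __version__

    return __version__


__all__ = ["RunReport", "make_fixtures", "run_pipeline"]


@dataclass(frozen=True)
class RunReport:
    """What a pipeline run produced: file paths and headline metrics."""

    outputs: dict[str, str]
    metrics: dict[str, float | bool | list]
    seed: int
    version: str

    def validate(self) -> None:
        missing = [p for p in self.outputs.values() if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing pipeline outputs: {missing}")


def _stage_device(config: RunConfig, out: Path) -> dict[str, str]:
    params = config.device
    state = init_device(params.g_min, params)
    trace = simulate_epsc(state, params)
    epsc = pd.DataFrame({"t_s": trace.times, "current_uA": trace.current})
    epsc_path = out / "device_epsc.csv"
    epsc.to_csv(epsc_path, index=False)

    rows = []
    for interval in (0.05, 0.1, 0.2, 0.4, 0.8):
        p1, p2 = simulate_ppf(state, params, interval)
        rows.append({"interval_s": interval, "p1_uA": p1, "p2_uA": p2,
                     "ppf_ratio": p2 / p1})
    ppf_path = out / "device_ppf.csv"
    pd.DataFrame(rows).to_csv(ppf_path, index=False)
    return {"device_epsc": str(epsc_path), "device_ppf": str(ppf_path)}


def _stage_sweeps(config: RunConfig, out: Path) -> tuple[dict[str, str], dict]:
    proto = config.protocols
    table = sweep_symmetric_triplet(
        proto.g0_levels,
        proto.dt_grid,
        config.device,
        kinds=("post-pre-post",),
        relax_after=proto.relax_after,
    )
    sweep_path = out / "sweep_symmetric.csv"
    table.to_csv(sweep_path, index=False)
    thresholds = {}
    for g0 in proto.g0_levels:
        sub = table[(table["g0_uS"] - g0).abs() < 0.05 * g0]
        try:
            thresholds[g0] = threshold_frequency(sub)
        except ValueError:
            thresholds[g0] = float("nan")
    quad = sweep_quadrants(
        np.arange(0.02, 0.121, 0.02),
        np.arange(0.02, 0.121, 0.02),
        g0=3.0,
        params=config.device,
        relax_after=proto.relax_after,
    )
    quad_path = out / "sweep_quadrants.csv"
    quad.to_csv(quad_path, index=False)
    metrics = {f"threshold_Hz_at_{g0}uS": t for g0, t in thresholds.items()}
    return {"sweep_symmetric": str(sweep_path), "sweep_quadrants": str(quad_path)}, metrics


def _stage_bcm(config: RunConfig, out: Path) -> tuple[dict[str, str], dict]:
    calibration = default_calibration()
    sliding = config.bcm
    grid = np.linspace(0.0, 120.0, 241)
    frames = []
    thetas = {}
    for g0 in config.protocols.g0_levels:
        curve = bcm_curve(MINIMAL_TRIPLET, sliding, calibration, g0, grid)
        thetas[g0] = curve.theta
        frames.append(
            pd.DataFrame(
                {"g0_uS": g0, "rho_y_Hz": curve.rho_y, "delta_g_uS": curve.delta_g}
            )
        )
    curves_path = out / "bcm_curves.csv"
    pd.concat(frames).to_csv(curves_path, index=False)
    report = {
        "calibration": {"a": calibration.a, "q": calibration.q},
        "tau_y_s": MINIMAL_TRIPLET.tau_y,
        "thresholds_Hz": {str(k): v for k, v in thetas.items()},
    }
    fit_path = out / "bcm_calibration.json"
    fit_path.write_text(json.dumps(report, indent=2))
    metrics = {f"bcm_theta_Hz_at_{g0}uS": t for g0, t in thetas.items()}
    return {"bcm_curves": str(curves_path), "bcm_calibration": str(fit_path)}, metrics


def _stage_network(config: RunConfig, out: Path) -> tuple[dict[str, str], dict]:
    state, history, report = train(config.network, MINIMAL_TRIPLET, config.bcm)
    hist_path = out / "network_history.csv"
    history.to_csv(hist_path, index=False)
    weights = pd.DataFrame(
        state.weights, columns=[f"neuron_{n}" for n in range(state.weights.shape[1])]
    )
    weights_path = out / "network_weights.csv"
    weights.to_csv(weights_path, index=False)
    report_path = out / "network_report.json"
    report_path.write_text(
        json.dumps(
            {
                "preferred_deg": list(report.preferred),
                "selectivity_index": list(report.selectivity_index),
                "distinct_count": report.distinct_count,
                "success": report.success,
            },
            indent=2,
        )
    )
    metrics = {
        "selectivity_success": report.success,
        "preferred_orientations_deg": list(report.preferred),
    }
    return {
        "network_history": str(hist_path),
        "network_weights": str(weights_path),
        "network_report": str(report_path),
    }, metrics


def run_pipeline(config: RunConfig) -> RunReport:
    """Run all stages, write tables and the JSON run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    metrics: dict = {}
    network_config = replace(config.network, seed=config.seed)
    config = replace(config, network=network_config)
    stages = [
        ("device", lambda: (_stage_device(config, out), {})),
        ("protocols", lambda: _stage_sweeps(config, out)),
        ("bcm", lambda: _stage_bcm(config, out)),
        ("network", lambda: _stage_network(config, out)),
    ]
    for name, fn in stages:
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 — annotate the failing stage
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        files, stage_metrics = result if isinstance(result, tuple) else (result, {})
        outputs.update(files)
        metrics.update(stage_metrics)
        if config.verbosity:
            print(f"[{name}] done in {time.perf_counter() - t0:.1f} s")
    report = RunReport(
        outputs=outputs, metrics=metrics, seed=config.seed, version=_version()
    )
    report_path = out / "run_report.json"
    report_path.write_text(
        json.dumps(
            {
                "outputs": report.outputs,
                "metrics": report.metrics,
                "seed": report.seed,
                "version": report.version,
            },
            indent=2,
        )
    )
    object.__setattr__(report, "outputs", {**report.outputs, "run_report": str(report_path)})
    report.validate()
    return report


def make_fixtures(seed: int, out_dir: str | Path = "results/fixtures") -> dict[str, str]:
    """Small canned datasets used by the test suite (regenerated, not stored).

    Writes a 10-point BCM table spanning both signs of ΔGc, a 3×3 quadrant
    sweep, and a 100-epoch training history.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = substream(seed, "fixtures")
    calibration = default_calibration()
    sliding = SlidingParams()

    rho_y = np.linspace(5.0, 90.0, 10)
    rows = []
    for ry in rho_y:
        g0 = 0.5
        mean_p = map_g0_to_mean_rate(g0, calibration, sliding)
        rows.append(
            {
                "rho_y": ry,
                "g0": g0,
                "delta_g": dgc_dt(ry, ry, mean_p, MINIMAL_TRIPLET, sliding),
            }
        )
    bcm_path = out / "fixture_bcm_table.csv"
    pd.DataFrame(rows).to_csv(bcm_path, index=False)

    quad = sweep_quadrants(
        np.array([0.02, 0.05, 0.08]), np.array([0.02, 0.05, 0.08]), g0=3.0
    )
    quad_path = out / "fixture_quadrants.csv"
    quad.to_csv(quad_path, index=False)

    net_config = NetworkConfig(epochs=100, seed=int(rng.integers(2**31)))
    _, history, _ = train(net_config)
    hist_path = out / "fixture_history.csv"
    history.to_csv(hist_path, index=False)
    return {
        "bcm_table": str(bcm_path),
        "quadrants": str(quad_path),
        "history": str(hist_path),
    }
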