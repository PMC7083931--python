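"""Rate-model BCM curves and triplet-parameter fitting.

Calibrates the experienced-conductance -> mean-activity power law from the
measured threshold anchors (40 Hz at 0.5 uS, 90 Hz at 7.0 uS), evaluates the
BCM curves of the minimal triplet rule for the three conductance levels, and
demonstrates parameter recovery by refitting noisy model-generated data.
Writes curves and the fit report under results/bcm/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from memsyn.bcm import (
    MINIMAL_TRIPLET,
    SlidingParams,
    bcm_curve,
    default_calibration,
    dgc_dt,
    fit_triplet_params,
    map_g0_to_mean_rate,
)

OUT = Path("results/bcm")
OUT.mkdir(parents=True, exist_ok=True)
sliding = SlidingParams()
calibration = default_calibration()
print(f"calibration: <rho_y> = {calibration.a:.2f} * G0^{calibration.q:.4f} Hz, "
      f"tau_y = {MINIMAL_TRIPLET.tau_y * 1e3:.2f} ms")

frames = []
for g0 in (0.5, 3.0, 7.0):
    curve = bcm_curve(
        MINIMAL_TRIPLET, sliding, calibration, g0, np.linspace(0.0, 120.0, 481)
    )
    dep = curve.delta_g[(curve.rho_y > 0) & (curve.rho_y < curve.theta)]
    ede = curve.rho_y[1:][np.argmax(np.abs(dep))]
    print(f"G0 = {g0} uS: theta = {curve.theta:.1f} Hz, "
          f"deepest depression at {ede:.1f} Hz")
    frames.append(pd.DataFrame(
        {"g0_uS": g0, "rho_y_Hz": curve.rho_y, "delta_g_uS": curve.delta_g}
    ))
pd.concat(frames).to_csv(OUT / "bcm_curves.csv", index=False)

# --- parameter recovery on noisy model-generated data
rng = np.random.default_rng(0)
rows = []
for ry in np.linspace(5.0, 110.0, 50):
    g0 = float(rng.choice([0.5, 3.0, 7.0]))
    mp = map_g0_to_mean_rate(g0, calibration, sliding)
    dg = dgc_dt(ry, ry, mp, MINIMAL_TRIPLET, sliding)
    rows.append({"rho_y": ry, "g0": g0, "delta_g": dg * (1 + 0.05 * rng.standard_normal())})
table = pd.DataFrame(rows)
table.to_csv(OUT / "fit_input.csv", index=False)
fitted, diag = fit_triplet_params(table)
(OUT / "fit_report.json").write_text(json.dumps(diag, indent=2))
print("fit on 5%-noise data:", {k: round(v, 5) for k, v in diag["estimates"].items()},
      f"residual norm {diag['residual_norm']:.2e}")
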