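"""Triplet-timing sweeps on the calibrated device.

Runs the quadrant-II diagonal (symmetric post-pre-post) sweeps at the three
experienced-conductance levels and reads off the depression-to-potentiation
threshold frequencies; then the asymmetric sweeps with one pairing fixed at
70 ms, the full (dt1, dt2) quadrant map at 3.0 uS, and the rate-pair trains.
Writes all tables under results/sweeps/.
"""

from pathlib import Path

import numpy as np

from memsyn.device import DeviceParams
from memsyn.protocols import (
    sweep_asymmetric_triplet,
    sweep_quadrants,
    sweep_rate_pairs,
    sweep_symmetric_triplet,
    threshold_frequency,
)

OUT = Path("results/sweeps")
OUT.mkdir(parents=True, exist_ok=True)
params = DeviceParams()

# --- symmetric diagonal: the triplet-based BCM thresholds
grid = [0.002 + 0.001 * k for k in range(119)]
table = sweep_symmetric_triplet((0.5, 3.0, 7.0), grid, params, kinds=("post-pre-post",))
table.to_csv(OUT / "symmetric_diagonal.csv", index=False)
for g0 in (0.5, 3.0, 7.0):
    sub = table[(table.g0_uS - g0).abs() < 0.05 * g0]
    thr = threshold_frequency(sub)
    pos = sub[sub.delta_g_uS > 0].dt2_ms.max()
    print(f"G0 = {g0} uS: threshold {thr:.1f} Hz, potentiation up to {pos:.0f} ms")

# --- asymmetric timing: LTD pairing fixed at -70 ms, LTP interval growing
asym = sweep_asymmetric_triplet(
    -0.07, np.arange(0.01, 0.121, 0.01), "post-pre-post", 3.0, params
)
asym.to_csv(OUT / "asymmetric_post_pre_post.csv", index=False)
flip = asym[asym.delta_g_uS < 0].dt2_ms.min()
print(f"asymmetric post-pre-post at 3.0 uS flips to depression from dt2 = {flip:.0f} ms")

# --- full quadrant map
quad = sweep_quadrants(
    np.arange(0.02, 0.121, 0.02), np.arange(0.02, 0.121, 0.02), 3.0, params
)
quad.to_csv(OUT / "quadrant_map.csv", index=False)
print("quadrant mean dGc (uS):")
print(quad.groupby("quadrant").delta_g_uS.mean().round(4).to_string())

# --- rate dependence of pre/post pair trains
pairs = sweep_rate_pairs((1.0, 2.0, 5.0, 10.0), g0=0.5, params=params)
pairs.to_csv(OUT / "rate_pairs.csv", index=False)
pivot = pairs.pivot(index="freq_Hz", columns="pairing", values="delta_g_uS")
print("rate pairs: LTP branch", np.round(pivot["LTP"].to_numpy(), 4),
      "| LTD branch", np.round(pivot["LTD"].to_numpy(), 4))
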