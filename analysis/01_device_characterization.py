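"""Short-term response of the synthetic memristive synapse.

Reproduces the single-device reference experiments: the EPSC transient of a
single [2 V, 10 ms] spike, paired-pulse facilitation versus inter-spike
interval, and the rate dependence of 8-pulse spike trains.  Writes the traces
and summary tables under results/device/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from memsyn.device import DeviceParams, init_device, simulate_epsc, simulate_ppf, simulate_rate_train

OUT = Path("results/device")
OUT.mkdir(parents=True, exist_ok=True)

params = DeviceParams()
state = init_device(0.1, params)

# --- EPSC transient
trace = simulate_epsc(state, params)
pd.DataFrame({"t_s": trace.times, "current_uA": trace.current}).to_csv(
    OUT / "epsc_trace.csv", index=False
)
baseline = 0.1 * params.v_read
after = trace.current[10:]
t_return = (np.nonzero(np.abs(after - baseline) <= 0.05 * baseline)[0][0] + 1)
print(f"EPSC: peak {trace.peak:.3f} uA, back within 5% of baseline after {t_return} ms")

# --- paired-pulse facilitation
rows = []
for interval in (0.02, 0.05, 0.1, 0.2, 0.4, 0.7, 1.0):
    p1, p2 = simulate_ppf(state, params, interval)
    rows.append({"interval_s": interval, "p1_uA": p1, "p2_uA": p2, "ratio": p2 / p1})
ppf = pd.DataFrame(rows)
ppf.to_csv(OUT / "ppf.csv", index=False)
print(
    "PPF: ratio %.3f at 50 ms falling to %.3f at 1 s"
    % (ppf.ratio.iloc[1], ppf.ratio.iloc[-1])
)

# --- spike-rate dependence of the train response
rows = []
for rate in (20, 50, 100):
    peak = simulate_rate_train(state, params, rate).peak
    rows.append({"rate_Hz": rate, "final_peak_uA": peak})
trains = pd.DataFrame(rows)
trains.to_csv(OUT / "rate_trains.csv", index=False)
print("rate trains (8 pulses):",
      ", ".join(f"{r.rate_Hz:.0f} Hz -> {r.final_peak_uA:.3f} uA" for r in trains.itertuples()))
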