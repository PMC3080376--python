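"""Characterize the JNK and ROS time courses that decide the cell's fate.

Extracts the early pJNK peak under TNF alone (time, height, depth of the
MKP-mediated termination), the ROS-driven second pJNK phase and the total-JNK
upregulation (100 -> ~507 by 8 h) under TNF+ActD, and the ROS clearance vs
plateau contrast.  Writes a feature table under results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from hepapop import StimulusProtocol, build_default_parameters, simulate
from hepapop.scenarios import pjnk_peaks

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

params = build_default_parameters()
tnf = simulate(StimulusProtocol(tnf_on=True, t_end=10.0), params)
actd = simulate(StimulusProtocol(tnf_on=True, actd=True, t_end=10.0), params)
bha = simulate(StimulusProtocol(tnf_on=True, actd=True, bha=True, t_end=10.0), params)

pk_times, pk_heights = pjnk_peaks(tnf)
t, x = tnf.t, tnf["pJNK"]
features = {
    "tnf_pjnk_peak_time_h": pk_times[0],
    "tnf_pjnk_peak_height": pk_heights[0],
    "tnf_pjnk_at_1h_over_peak": float(np.max(x[t >= 1.0]) / pk_heights[0]),
    "actd_pjnk_8h": actd.at("pJNK", 8.0),
    "actd_total_jnk_8h": actd.at("JNK+pJNK", 8.0),
    "actd_ros_plateau_5_10h": float(np.mean(actd["ROS"][(actd.t >= 5) & (actd.t <= 10)])),
    "tnf_ros_max_after_5h": float(np.max(tnf["ROS"][tnf.t >= 5.05])),
    "bha_ros_max": float(np.max(bha["ROS"])),
    "bha_pjnk_8h": bha.at("pJNK", 8.0),
}
pd.Series(features).to_csv(OUT / "jnk_ros_features.csv", header=["value"])
for k, v in features.items():
    print(f"{k:32s} {v:10.3f}")
print("\nThe single early pJNK peak is quenched by the phosphatase/MKP loop but")
print("retains a small MKK7-driven tail (see docs/methods.md on the depth of")
print("this termination); only the ROS burst under ActD reopens the pathway.")
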