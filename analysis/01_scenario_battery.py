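"""Run the nine stimulation scenarios and tabulate the apoptosis outcomes.

Reproduces the simulated conditions of the study: survival under TNF alone,
type-I (medium) apoptosis under FasL, full type-II apoptosis under TNF+ActD,
TNF+CHX and TNF/FasL sensitizing, the protective effect of the antioxidant
BHA, and the Bid / XIAP knockouts.  Writes the outcome matrix and the
figure-style time-course panels under results/.
"""

from pathlib import Path

import pandas as pd

from hepapop import SCENARIOS, build_default_parameters, run_scenario
from hepapop.plotting import plot_scenario

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

params = build_default_parameters()
rows = []
for name in SCENARIOS:
    traj, rep = run_scenario(name, params)
    d = rep.as_dict()
    d["scenario"] = name
    rows.append(d)
    plot_scenario(traj, title=name, path=OUT / f"scenario_{name}.png")
    traj.to_wide_df().to_csv(OUT / f"trajectory_{name}.csv", index=False)

df = pd.DataFrame(rows).set_index("scenario")
df.to_csv(OUT / "outcome_matrix.csv")
print(df[["c3_class", "c3_max", "c3_max_time", "momp_time", "total_jnk_8h",
          "ros_plateau"]].to_string(float_format="%.2f"))
print("\nKey findings:")
print(" - TNF alone and TNF+ActD+BHA leave caspase-3 silent;")
print(" - FasL gives the XIAP-limited medium response without cytochrome-c release;")
print(" - TNF+ActD, TNF+CHX and sensitizing all converge on the same maximal,")
print("   MOMP-driven caspase-3 output.")
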