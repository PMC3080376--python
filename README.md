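# hepapop

An ODE model of TNFα-induced apoptosis in primary hepatocytes, for systems
biologists studying death-receptor signalling and for anyone who needs a
worked example of integrating signalling modules (receptor core + NF-κB
transcription module) into one executable model.

TNFα alone does not kill hepatocytes: NF-κB-driven transcription installs a
ROS scavenger that defuses a mitochondrial ROS burst arriving at ~4 h. Block
transcription (actinomycin D) or translation (cycloheximide) and the burst
persists, oxidizes the MAP-kinase phosphatases, drives a massive second phase
of JNK activation, and pushes the Bim/Bid/Bax-Bak switch past the 20%
threshold at which mitochondria release cytochrome c and executioner
caspase-3 fires. The package implements this as a 53-species, 74-parameter
mass-action ODE system,

dx/dt = S·v(x, p, u),  v bilinear/linear,  u = Boolean stimuli {TNF, FasL, ActD, CHX, BHA},

with two discrete mechanisms (a prescribed 100-AU ROS pulse at 4 h; a latched
cytochrome-c release event at 20% Bax/Bak activation), plus:

- a scenario library (TNF, FasL, TNF+ActD ± BHA, TNF+CHX, TNF→FasL
  sensitizing, Bid and XIAP knockouts) with a none/medium/high caspase-3
  classifier,
- local sensitivity and four-order-of-magnitude robustness analysis,
- a synthetic-assay generator (DEVDase, DCF, Western-blot densitometry,
  2^-ΔΔCT) and a least-squares parameter-recovery harness.

## Worked example

```python
from hepapop import run_scenario

traj, rep = run_scenario("TNF_ActD")
print(rep.c3_class, round(rep.total_jnk_8h, 1), round(rep.momp_time, 2))
print(round(traj.at("pJNK", 8.0), 1), round(rep.ros_plateau, 1))
```

prints

```
high 507.0 6.57
65.1 48.4
```

i.e. under TNFα + actinomycin D the total JNK pool has grown from 100 to 507
AU by 8 h (the ROS-driven upregulation), mitochondrial permeabilisation fires
at 6.57 h, ROS sit on a ~48-AU plateau, phospho-JNK is in its sustained
second phase, and caspase-3 reaches the maximal ("high") class. Running
`run_scenario("TNF")` instead gives class `none`: the same ROS burst is
scavenged within minutes and total JNK stays at ~100.

The numbered drivers under `analysis/` reproduce the full study:

| script | what it does |
|---|---|
| `01_scenario_battery.py` | nine-scenario outcome matrix + time-course panels |
| `02_jnk_ros_dynamics.py` | pJNK peak/termination/second-phase and ROS features |
| `03_sensitivity.py` | 3×74 local log-sensitivity matrix (TNF scenario) |
| `04_robustness.py` | robust/fragile verdicts over 1e-2..1e2 perturbations |
| `05_synthetic_recovery.py` | parameter recovery vs assay noise |

Each writes its tables/figures to `results/`. A thin CLI wraps the same
functions (`hepapop simulate|run-all|sensitivity|robustness|synth|fit`).

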