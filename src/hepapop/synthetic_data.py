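"""Pseudo-experimental readouts and a parameter-recovery harness.

Real measurements of this system are fold-scale assays, not species amounts:
DEVDase fluorescence (caspase-3/-7 activity over untreated control), DCF
fluorescence (ROS fold over control), Western-blot densitometry (band
intensity in arbitrary gain units) and qRT-PCR 2^-ddCT (transcript fold over
untreated).  This module maps model trajectories through those assay
semantics, adds multiplicative log-normal replicate noise, and provides a
least-squares harness that refits chosen rate constants from such tables —
so the whole fitting machinery can be exercised without any wet-lab data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model_core import ParameterSet, build_default_parameters
from .scenarios import SCENARIOS, c3_reference
from .simulation_engine import StimulusProtocol, Trajectory, simulate

__all__ = [
    "AssayConfig",
    "MeasurementTable",
    "generate_pseudo_experiment",
    "recover_parameters",
    "DEFAULT_TIMEPOINTS",
]

#: hour grids used by the corresponding bench assays
DEFAULT_TIMEPOINTS: dict[str, tuple[float, ...]] = {
    "devdase_fold": (2.0, 4.0, 5.0, 6.0, 8.0, 10.0),
    "dcf_ros_fold": (1.0, 2.0, 4.0, 5.0, 6.0, 8.0, 10.0),
    "wb_densitometry": (0.5, 1.0, 2.0, 4.0, 6.0, 8.0),
    "qpcr_ddct": (0.5, 1.0, 2.0, 4.0, 6.0, 8.0),
}

#: assumed constitutive DCF background (AU of ROS equivalent); the assay
#: reports (ROS + background)/background so the untreated fold is 1
DCF_BASELINE = 10.0
#: DEVDase baseline floor as a fraction of the TNF+ActD caspase-3 maximum
DEVDASE_FLOOR_FRACTION = 0.01


@dataclass(frozen=True)
class AssayConfig:
    """One assay panel: readout kind, target, timepoints, replicates, noise."""

    assay: str                               # one of DEFAULT_TIMEPOINTS keys
    target: str | None = None                # species expression for WB / transcript for qPCR
    timepoints: tuple[float, ...] | None = None
    replicates: int = 3
    sigma: float = 0.1                       # log-normal noise scale
    gain: float = 1.0                        # densitometry gain (WB only)

    def __post_init__(self):
        if self.assay not in DEFAULT_TIMEPOINTS:
            raise ValueError(f"unknown assay {self.assay!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.timepoints is None:
            object.__setattr__(self, "timepoints", DEFAULT_TIMEPOINTS[self.assay])
        if self.assay == "wb_densitometry" and self.target is None:
            object.__setattr__(self, "target", "JNK+pJNK")
        if self.assay == "qpcr_ddct" and self.target is None:
            object.__setattr__(self, "target", "A20t")


@dataclass
class MeasurementTable:
    """Tidy replicate table plus generation metadata."""

    data: pd.DataFrame                      # assay, target, time, replicate, value
    scenario: str
    seed: int
    sigmas: dict[str, float] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def _noiseless_readout(
    traj: Trajectory, cfg: AssayConfig, params: ParameterSet
) -> np.ndarray:
    t = np.asarray(cfg.timepoints, dtype=float)
    if t.min() < traj.t[0] - 1e-9 or t.max() > traj.t[-1] + 1e-9:
        raise ValueError(
            f"assay timepoints {t.min()}..{t.max()} h outside trajectory span "
            f"{traj.t[0]}..{traj.t[-1]} h"
        )
    if cfg.assay == "devdase_fold":
        floor = DEVDASE_FLOOR_FRACTION * c3_reference(params)
        return np.array([(traj.at("C3", ti) + floor) / floor for ti in t])
    if cfg.assay == "dcf_ros_fold":
        return np.array([(traj.at("ROS", ti) + DCF_BASELINE) / DCF_BASELINE for ti in t])
    if cfg.assay == "wb_densitometry":
        return np.array([cfg.gain * traj.at(cfg.target, ti) for ti in t])
    if cfg.assay == "qpcr_ddct":
        rest = traj.at(cfg.target, 0.0)
        eps = 1e-6 if rest == 0 else 0.0
        return np.array([(traj.at(cfg.target, ti) + eps) / (rest + eps) for ti in t])
    raise AssertionError(cfg.assay)


def generate_pseudo_experiment(
    traj: Trajectory,
    configs: Sequence[AssayConfig],
    seed: int = 0,
    params: ParameterSet | None = None,
    scenario: str = "",
) -> MeasurementTable:
    """Replicate tables from a trajectory under the configured assay semantics.

    Noise is multiplicative log-normal: value = mean * exp(eps),
    eps ~ Normal(0, sigma^2).  Identical seed => identical table.
    """
    if params is None:
        params = build_default_parameters()
    rng = np.random.default_rng(seed)
    rows = []
    for cfg in configs:
        mean = _noiseless_readout(traj, cfg, params)
        for r in range(cfg.replicates):
            eps = rng.normal(0.0, cfg.sigma, size=mean.shape) if cfg.sigma > 0 else 0.0
            vals = mean * np.exp(eps)
            for ti, v in zip(cfg.timepoints, vals):
                rows.append({
                    "assay": cfg.assay,
                    "target": cfg.target or "",
                    "time": ti,
                    "replicate": r,
                    "value": v,
                })
    df = pd.DataFrame(rows)
    return MeasurementTable(
        data=df, scenario=scenario, seed=seed,
        sigmas={cfg.assay: cfg.sigma for cfg in configs},
    )


@dataclass
class FitReport:
    estimates: dict[str, float]
    truth_free: dict[str, float]
    residual: float
    converged: bool
    n_evaluations: int
    message: str


def recover_parameters(
    data: MeasurementTable,
    free_params: Sequence[str],
    configs: Sequence[AssayConfig],
    bounds: dict[str, tuple[float, float]] | None = None,
    params_init: ParameterSet | None = None,
    scenario: str | None = None,
    max_nfev: int = 60,
) -> FitReport:
    """Refit selected rate constants against a measurement table.

    Minimizes squared log-residuals between the noiseless assay readouts of
    the simulated scenario and the table's replicate values; optimization is
    in log-parameter space within (wide default) bounds.  Non-convergence is
    flagged and the best iterate returned.
    """
    if params_init is None:
        params_init = build_default_parameters()
    scen_name = scenario or data.scenario
    if scen_name not in SCENARIOS:
        raise KeyError(f"unknown scenario {scen_name!r}")
    protocol = SCENARIOS[scen_name]
    free = list(free_params)
    for name in free:
        if name not in params_init:
            raise KeyError(f"unknown parameter {name!r}")

    # observed log-values grouped per assay config in a fixed order
    obs = []
    for cfg in configs:
        sub = data.data[(data.data["assay"] == cfg.assay)
                        & (data.data["target"] == (cfg.target or ""))]
        piv = sub.pivot_table(index="time", columns="replicate", values="value")
        piv = piv.reindex(list(cfg.timepoints))
        obs.append(np.log(piv.to_numpy(dtype=float)))

    x0 = np.log([params_init[n] for n in free])
    if bounds:
        lo = np.log([bounds.get(n, (params_init[n] / 1e3, params_init[n] * 1e3))[0] for n in free])
        hi = np.log([bounds.get(n, (params_init[n] / 1e3, params_init[n] * 1e3))[1] for n in free])
    else:
        lo, hi = x0 - np.log(1e3), x0 + np.log(1e3)
    x0 = np.clip(x0, lo, hi)

    def residuals(x):
        p = params_init.with_overrides({n: float(np.exp(v)) for n, v in zip(free, x)})
        traj = simulate(protocol, p)
        res = []
        for cfg, ob in zip(configs, obs):
            pred = np.log(np.maximum(_noiseless_readout(traj, cfg, p), 1e-12))
            res.append((ob - pred[:, None]).ravel())
        return np.concatenate(res)

    # diff_step must dominate the integrator's noise floor or the Jacobian
    # is garbage and the fit stalls short of the optimum
    sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                        diff_step=1e-3, xtol=1e-12, ftol=1e-14, gtol=1e-12,
                        max_nfev=max_nfev)
    est = {n: float(np.exp(v)) for n, v in zip(free, sol.x)}
    return FitReport(
        estimates=est,
        truth_free={n: params_init[n] for n in free},
        residual=float(0.5 * np.sum(sol.fun ** 2)),
        converged=bool(sol.status > 0 and sol.nfev < max_nfev),
        n_evaluations=int(sol.nfev),
        message=sol.message,
    )
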