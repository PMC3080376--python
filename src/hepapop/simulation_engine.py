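"""Integration of the coupled 53-state system with events.

Two discrete mechanisms sit outside the smooth right-hand side:

* the mitochondrial ROS release, a prescribed rectangular pulse at 4 h whose
  edges are treated as integration breakpoints so the stiff solver cannot
  step over it;
* mitochondrial outer-membrane permeabilisation (MOMP), a latched
  state-discontinuity event: when the activated Bax/Bak fraction first
  reaches the pore-formation threshold (20%), the entire mitochondrial
  cytochrome-c pool is transferred to the cytosol instantaneously and the
  event can never fire again.

Integration uses LSODA with event localisation; the Fas-ligand onset is a
right-continuous step at which integration is restarted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import nfkb_module
from .model_core import (
    CORE_INDEX,
    CORE_SPECIES,
    ModelInputs,
    ParameterSet,
    build_initial_state,
    core_rhs,
    ros_release_rate,
)
from .nfkb_module import NFKB_SPECIES, nfkb_rhs

__all__ = ["StimulusProtocol", "Trajectory", "simulate", "momp_check", "ALL_SPECIES"]

#: Composite state ordering: 37 core species then 16 NF-kB-module species.
ALL_SPECIES: tuple[str, ...] = CORE_SPECIES + NFKB_SPECIES
ALL_INDEX: dict[str, int] = {name: i for i, name in enumerate(ALL_SPECIES)}

_N_CORE = len(CORE_SPECIES)
_I_ROS = CORE_INDEX["ROS"]
_I_BB = CORE_INDEX["BaxBak"]
_I_BBA = CORE_INDEX["BaxBakA"]
_I_CYTM = CORE_INDEX["Cytc_mito"]
_I_CYTC = CORE_INDEX["Cytc_cyto"]
_I_P = _N_CORE + nfkb_module.NFKB_INDEX["P"]


@dataclass(frozen=True)
class StimulusProtocol:
    """Stimulation conditions for one in-silico experiment.

    TNF (if on) acts from t=0; ActD/CHX/BHA are constant from t=0 (ActD is
    added 30 min before TNF in the experiments, i.e. transcription is already
    stopped at model time zero).  ``fasl_time`` is the onset of a sustained
    Fas-ligand stimulus.  ``knockouts`` zero initial pools; overrides replace
    named rate parameters or structural constants.
    """

    tnf_on: bool = False
    fasl_time: float | None = None
    actd: bool = False
    chx: bool = False
    bha: bool = False
    knockouts: frozenset[str] = frozenset()
    t_end: float = 10.0
    parameter_overrides: tuple = ()

    def __post_init__(self):
        if self.fasl_time is not None and not (0.0 <= self.fasl_time <= self.t_end):
            raise ValueError(
                f"fasl_time must lie in [0, t_end]; got {self.fasl_time} with t_end {self.t_end}"
            )
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        object.__setattr__(self, "knockouts", frozenset(self.knockouts))
        if isinstance(self.parameter_overrides, Mapping):
            object.__setattr__(
                self, "parameter_overrides", tuple(sorted(self.parameter_overrides.items()))
            )

    def inputs(self) -> ModelInputs:
        tnf = (lambda t: 1.0) if self.tnf_on else (lambda t: 0.0)
        if self.fasl_time is None:
            fasl = lambda t: 0.0
        else:
            t_on = self.fasl_time
            fasl = lambda t: 1.0 if t >= t_on else 0.0
        return ModelInputs(tnf=tnf, fasl=fasl, actd=self.actd, chx=self.chx, bha=self.bha)


@dataclass
class Trajectory:
    """Dense, event-annotated solution of one simulation."""

    t: np.ndarray
    y: np.ndarray                      # shape (len(t), 53)
    events: list[tuple[str, float]] = field(default_factory=list)
    protocol: StimulusProtocol | None = None

    @property
    def species(self) -> tuple[str, ...]:
        return ALL_SPECIES

    def __getitem__(self, name: str) -> np.ndarray:
        """Time course of one species, or a '+'-joined sum (e.g. 'JNK+pJNK')."""
        parts = [p.strip() for p in name.split("+")]
        out = np.zeros_like(self.t)
        for p in parts:
            out = out + self.y[:, ALL_INDEX[p]]
        return out

    def at(self, name: str, time: float) -> float:
        """Linear interpolation of one species (or sum) at a time point."""
        if not (self.t[0] - 1e-9 <= time <= self.t[-1] + 1e-9):
            raise ValueError(f"time {time} outside trajectory span [{self.t[0]}, {self.t[-1]}]")
        return float(np.interp(time, self.t, self[name]))

    @property
    def momp_time(self) -> float | None:
        for name, time in self.events:
            if name == "MOMP":
                return time
        return None

    def to_wide_df(self) -> pd.DataFrame:
        df = pd.DataFrame(self.y, columns=list(ALL_SPECIES))
        df.insert(0, "time", self.t)
        return df

    def to_tidy_df(self) -> pd.DataFrame:
        return self.to_wide_df().melt(id_vars="time", var_name="species", value_name="value")

    def events_json(self) -> str:
        return json.dumps([{"event": n, "time": t} for n, t in self.events])


def momp_check(state: np.ndarray, params: ParameterSet) -> bool:
    """True iff the activated Bax/Bak fraction has reached the MOMP threshold."""
    bb, bba = state[_I_BB], state[_I_BBA]
    total = bb + bba
    if total <= 0:
        raise ValueError("Bax/Bak pool is empty; MOMP fraction undefined")
    return bool(bba / total >= params.structural["momp_threshold"])


def _composite_rhs(t, y, params, inputs, nfkbn_ref, param_map):
    yc = np.maximum(y, 0.0)
    core = yc[:_N_CORE]
    nf = yc[_N_CORE:]
    p_prot = yc[_I_P]
    ros_in = ros_release_rate(t, inputs, params)
    d = np.empty_like(y)
    d[:_N_CORE] = core_rhs(t, core, param_map, inputs,
                           p_protein=p_prot, ros_input=ros_in)
    d[_N_CORE:] = nfkb_rhs(t, nf, param_map, TR=inputs.tnf(t),
                           ActD=inputs.actd, CHX=inputs.chx, nfkbn_ref=nfkbn_ref)
    # P consumption by ROS lives on the core side of the unit bridge
    d[_I_P] -= param_map["k_scav"] * yc[_I_ROS] * p_prot
    return d


def initial_composite_state(protocol: StimulusProtocol, params: ParameterSet) -> np.ndarray:
    """Core resting state + NF-kB resting steady state (cached)."""
    y0 = np.empty(len(ALL_SPECIES))
    y0[:_N_CORE] = build_initial_state(protocol.knockouts)
    y0[_N_CORE:] = nfkb_module.compute_resting_steady_state(params)
    return y0


def simulate(
    protocol: StimulusProtocol,
    params: ParameterSet | None = None,
    rtol: float = 1e-7,
    atol: float = 1e-9,
) -> Trajectory:
    """Integrate the full 53-species model under one stimulation protocol.

    Returns a dense trajectory (grid resolution 0.01 h, refined around the
    ROS pulse) with the MOMP event, if any, in the event log.
    """
    from .model_core import build_default_parameters

    if params is None:
        params = build_default_parameters()
    if protocol.parameter_overrides:
        params = params.with_overrides(dict(protocol.parameter_overrides))

    inputs = protocol.inputs()
    nfkbn_ref = nfkb_module.resting_nfkbn(params)
    param_map = params.as_dict()
    y0 = initial_composite_state(protocol, params)

    momp_threshold = params.structural["momp_threshold"]

    def momp_event(t, y, *_args):
        total = y[_I_BB] + y[_I_BBA]
        if total <= 0:
            return -momp_threshold
        return y[_I_BBA] / total - momp_threshold

    momp_event.terminal = True
    momp_event.direction = 1.0

    # breakpoints: ROS pulse edges and the FasL onset
    t0p = params.structural["ros_pulse_time"]
    w = params.structural["ros_pulse_width"]
    breaks = {0.0, protocol.t_end}
    if protocol.tnf_on and not protocol.bha:
        for edge in (t0p - w / 2.0, t0p + w / 2.0):
            if 0.0 < edge < protocol.t_end:
                breaks.add(edge)
    if protocol.fasl_time is not None and 0.0 < protocol.fasl_time < protocol.t_end:
        breaks.add(protocol.fasl_time)
    grid_breaks = sorted(breaks)

    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    events: list[tuple[str, float]] = []
    momp_fired = False
    y = y0.copy()

    segments = list(zip(grid_breaks[:-1], grid_breaks[1:]))
    si = 0
    while si < len(segments):
        ta, tb = segments[si]
        n = max(2, int(np.ceil((tb - ta) / 0.01)) + 1)
        t_eval = np.linspace(ta, tb, n)
        sol = solve_ivp(
            _composite_rhs, (ta, tb), y, method="LSODA",
            t_eval=t_eval, rtol=rtol, atol=atol,
            events=None if momp_fired else [momp_event],
            args=(params, inputs, nfkbn_ref, param_map),
            max_step=(tb - ta),
        )
        if not sol.success:
            raise RuntimeError(
                f"integrator failed in [{ta}, {tb}]: {sol.message}; "
                f"last good state at t={sol.t[-1] if len(sol.t) else ta}"
            )
        ts.append(sol.t)
        ys.append(np.maximum(sol.y.T, 0.0))
        if (not momp_fired) and sol.t_events and len(sol.t_events[0]):
            t_momp = float(sol.t_events[0][0])
            y = np.maximum(sol.y_events[0][0].copy(), 0.0)
            # instantaneous, complete, irreversible cytochrome-c release
            y[_I_CYTC] += y[_I_CYTM]
            y[_I_CYTM] = 0.0
            events.append(("MOMP", t_momp))
            momp_fired = True
            if tb - t_momp > 1e-12:
                segments.insert(si + 1, (t_momp, tb))
            si += 1
            continue
        y = np.maximum(sol.y[:, -1].copy(), 0.0)
        si += 1

    t_all = np.concatenate(ts)
    y_all = np.vstack(ys)
    # collapse restart duplicates, keeping the post-event state at the seam
    t_final, y_final = [], []
    last_t = None
    for ti, yi in zip(t_all, y_all):
        if last_t is not None and ti - last_t <= 1e-12:
            t_final[-1] = ti
            y_final[-1] = yi
        else:
            t_final.append(ti)
            y_final.append(yi)
        last_t = ti
    return Trajectory(
        t=np.asarray(t_final), y=np.asarray(y_final), events=events, protocol=protocol
    )
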