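"""Named stimulation scenarios and the qualitative outcome classifier.

The scenario library mirrors the simulated conditions of the study: TNF
alone, Fas ligand alone, TNF+ActD (with and without the antioxidant BHA or a
Bid knockout), TNF+cycloheximide, the TNF/FasL sensitizing protocol (12 h TNF
preincubation, FasL at 12 h, 20 h horizon) and the XIAP-knockout variants.

Caspase-3 outcomes are classed ordinally: *none* / *medium* / *high*,
measured against the TNF+ActD response under the same parameter set (the
maximal response the wild-type model can produce).  The cut points (5% and
60% of that reference) are conventions of this package; the underlying
biology is ordinal only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .model_core import ParameterSet, build_default_parameters
from .simulation_engine import StimulusProtocol, Trajectory, simulate

__all__ = [
    "SCENARIOS", "OutcomeReport",
    "run_scenario", "classify_outcome", "compare_actd_chx",
]

SCENARIOS: dict[str, StimulusProtocol] = {
    "TNF": StimulusProtocol(tnf_on=True, t_end=10.0),
    "FasL": StimulusProtocol(fasl_time=0.0, t_end=10.0),
    "TNF_ActD": StimulusProtocol(tnf_on=True, actd=True, t_end=10.0),
    "TNF_ActD_BHA": StimulusProtocol(tnf_on=True, actd=True, bha=True, t_end=10.0),
    "TNF_CHX": StimulusProtocol(tnf_on=True, chx=True, t_end=10.0),
    "SENSITIZING": StimulusProtocol(tnf_on=True, fasl_time=12.0, t_end=20.0),
    "TNF_ActD_BidKO": StimulusProtocol(
        tnf_on=True, actd=True, t_end=10.0, knockouts=frozenset({"Bid"})
    ),
    "FasL_XIAPKO": StimulusProtocol(
        fasl_time=0.0, t_end=10.0, knockouts=frozenset({"XIAP"})
    ),
    "SENSITIZING_XIAPKO": StimulusProtocol(
        tnf_on=True, fasl_time=12.0, t_end=20.0, knockouts=frozenset({"XIAP"})
    ),
}

#: class cut points, as fractions of the TNF_ActD caspase-3 maximum
C3_NONE_BELOW = 0.05
C3_HIGH_FROM = 0.60


@dataclass
class OutcomeReport:
    """Qualitative class plus the quantitative features behind it."""

    c3_class: str
    c3_max: float
    c3_max_time: float
    c3_ref: float
    pjnk_peak_times: tuple[float, ...]
    pjnk_peak_heights: tuple[float, ...]
    ros_plateau: float
    momp_time: float | None
    total_jnk_8h: float

    def as_dict(self) -> dict:
        return {
            "c3_class": self.c3_class,
            "c3_max": self.c3_max,
            "c3_max_time": self.c3_max_time,
            "c3_ref": self.c3_ref,
            "pjnk_peak_times": list(self.pjnk_peak_times),
            "pjnk_peak_heights": list(self.pjnk_peak_heights),
            "ros_plateau": self.ros_plateau,
            "momp_time": self.momp_time,
            "total_jnk_8h": self.total_jnk_8h,
        }


_REF_CACHE: dict[tuple, float] = {}


def c3_reference(params: ParameterSet) -> float:
    """Caspase-3 maximum of the wild-type TNF+ActD run (the class yardstick)."""
    key = params.key()
    if key not in _REF_CACHE:
        traj = simulate(SCENARIOS["TNF_ActD"], params)
        _REF_CACHE[key] = float(np.max(traj["C3"]))
        if len(_REF_CACHE) > 64:
            _REF_CACHE.pop(next(iter(_REF_CACHE)))
    return _REF_CACHE[key]


def pjnk_peaks(traj: Trajectory, min_rel_height: float = 0.05) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Times and heights of distinct pJNK peaks (prominence-filtered)."""
    x = traj["pJNK"]
    top = float(np.max(x))
    if top <= 0:
        return (), ()
    idx, _ = find_peaks(x, height=min_rel_height * top, prominence=min_rel_height * top)
    # a phase still rising at t_end has no turning point; count it as a peak
    if x[-1] >= 0.98 * top and (len(idx) == 0 or traj.t[-1] - traj.t[idx[-1]] > 1.0):
        idx = np.append(idx, len(x) - 1)
    return tuple(float(traj.t[i]) for i in idx), tuple(float(x[i]) for i in idx)


def classify_outcome(traj: Trajectory, params: ParameterSet | None = None) -> OutcomeReport:
    """Summarise a trajectory into the none/medium/high caspase-3 classes.

    The reference level is the TNF+ActD caspase-3 maximum under the same
    parameters; the trajectory must cover at least 10 h so late activation is
    not missed.
    """
    if params is None:
        params = build_default_parameters()
    if traj.t[-1] - traj.t[0] < 10.0 - 1e-9:
        raise ValueError("trajectory must cover at least 10 h for classification")

    c3 = traj["C3"]
    c3_max = float(np.max(c3))
    c3_max_time = float(traj.t[int(np.argmax(c3))])
    ref = c3_reference(params)
    frac = c3_max / ref if ref > 0 else 0.0
    if frac < C3_NONE_BELOW:
        klass = "none"
    elif frac < C3_HIGH_FROM:
        klass = "medium"
    else:
        klass = "high"

    times, heights = pjnk_peaks(traj)
    late = (traj.t >= 5.0) & (traj.t <= min(10.0, traj.t[-1]))
    ros_plateau = float(np.mean(traj["ROS"][late])) if late.any() else 0.0
    t8 = 8.0 if traj.t[-1] >= 8.0 else traj.t[-1]
    return OutcomeReport(
        c3_class=klass,
        c3_max=c3_max,
        c3_max_time=c3_max_time,
        c3_ref=ref,
        pjnk_peak_times=times,
        pjnk_peak_heights=heights,
        ros_plateau=ros_plateau,
        momp_time=traj.momp_time,
        total_jnk_8h=float(traj.at("JNK+pJNK", t8)),
    )


def run_scenario(
    name: str, params: ParameterSet | None = None
) -> tuple[Trajectory, OutcomeReport]:
    """Simulate a named scenario and classify its outcome (deterministic)."""
    if name not in SCENARIOS:
        raise KeyError(
            f"unknown scenario {name!r}; valid names: {', '.join(sorted(SCENARIOS))}"
        )
    if params is None:
        params = build_default_parameters()
    traj = simulate(SCENARIOS[name], params)
    return traj, classify_outcome(traj, params)


def compare_actd_chx(params: ParameterSet | None = None) -> dict:
    """TNF+ActD vs TNF+CHX: equal caspase-3 output, different cFLIP fate.

    The model predicts no difference in caspase-3 activity between the two
    costimuli (both scenarios are decided by complete cytochrome-c release),
    while cFLIP is stable under ActD but degraded by the Itch chain under
    cycloheximide, with correspondingly stronger caspase-8 activation.
    """
    if params is None:
        params = build_default_parameters()
    traj_a, rep_a = run_scenario("TNF_ActD", params)
    traj_c, rep_c = run_scenario("TNF_CHX", params)
    c3_rel_diff = abs(rep_a.c3_max - rep_c.c3_max) / max(rep_a.c3_max, rep_c.c3_max)
    return {
        "c3_max_actd": rep_a.c3_max,
        "c3_max_chx": rep_c.c3_max,
        "c3_rel_diff": c3_rel_diff,
        "c3_equal_1pct": bool(c3_rel_diff <= 0.01),
        "cflip_end_actd": float(traj_a["cFLIP"][-1]),
        "cflip_end_chx": float(traj_c["cFLIP"][-1]),
        "c8_max_actd": float(np.max(traj_a["C8"])),
        "c8_max_chx": float(np.max(traj_c["C8"])),
    }
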