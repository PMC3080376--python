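"""Local sensitivity, robustness scanning, and the qualitative constraint set.

The constraint checker encodes the qualitative requirement profile the model
parameterization must satisfy (survival after TNF alone, graded apoptosis
across the stimulation scenarios, knockout behaviour); it is both a
diagnostic and the gate used when calibrating unprinted rate constants.

Sensitivity coefficients are normalized local log-derivatives,
S[i,j] = d ln y_i / d ln p_j, by central finite differences around the
working point.  Robustness scans rerun the scenario battery under
multiplicative single-parameter perturbations spanning four orders of
magnitude and ask whether the constraint profile survives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import ParameterSet, build_default_parameters
from .scenarios import SCENARIOS, run_scenario
from .simulation_engine import Trajectory, simulate

__all__ = [
    "SENSITIVITY_OUTPUTS",
    "SensitivityResult",
    "RobustnessResult",
    "local_sensitivity",
    "robustness_scan",
    "check_constraints",
]

#: Default readouts: pJNK at 8 h, the pre-MOMP maximum of activated Bax/Bak,
#: and active caspase-3 at 10 h.
SENSITIVITY_OUTPUTS: tuple[str, ...] = ("pJNK_8h", "BaxBakA_premomp_max", "C3_10h")


def _evaluate_outputs(traj: Trajectory, outputs: tuple[str, ...]) -> np.ndarray:
    vals = []
    for out in outputs:
        if out == "pJNK_8h":
            vals.append(traj.at("pJNK", min(8.0, traj.t[-1])))
        elif out == "BaxBakA_premomp_max":
            tm = traj.momp_time
            mask = traj.t <= (tm if tm is not None else traj.t[-1])
            vals.append(float(np.max(traj["BaxBakA"][mask])))
        elif out == "C3_10h":
            vals.append(traj.at("C3", min(10.0, traj.t[-1])))
        elif out == "momp_time":
            tm = traj.momp_time
            vals.append(float("nan") if tm is None else tm)
        else:  # "<species>_max" or "<species>_<T>h"
            if out.endswith("_max"):
                vals.append(float(np.max(traj[out[:-4]])))
            else:
                name, tpart = out.rsplit("_", 1)
                vals.append(traj.at(name, float(tpart.rstrip("h"))))
    return np.asarray(vals)


@dataclass
class SensitivityResult:
    """Normalized local sensitivity coefficients S[output, parameter]."""

    outputs: tuple[str, ...]
    parameters: tuple[str, ...]
    matrix: np.ndarray                       # d ln y / d ln p
    absolute: np.ndarray                     # d y / d p (fallback scale)
    zero_output_flags: np.ndarray            # True where log-sensitivity undefined
    rel_step: float
    scenario: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.outputs),
                            columns=list(self.parameters))


def local_sensitivity(
    params: ParameterSet | None = None,
    scenario: str = "TNF",
    outputs: tuple[str, ...] = SENSITIVITY_OUTPUTS,
    rel_step: float = 0.01,
    parameters: tuple[str, ...] | None = None,
) -> SensitivityResult:
    """Central-difference log-sensitivities of scenario readouts.

    Outputs that are identically zero at the working point are flagged and
    reported with an absolute (non-normalized) coefficient instead.
    """
    if not (0.0 < rel_step <= 0.1):
        raise ValueError("rel_step must lie in (0, 0.1]")
    if params is None:
        params = build_default_parameters()
    if scenario not in SCENARIOS:
        raise KeyError(f"unknown scenario {scenario!r}")
    names = tuple(parameters) if parameters is not None else params.names()

    base = _evaluate_outputs(simulate(SCENARIOS[scenario], params), outputs)
    n_out, n_par = len(outputs), len(names)
    mat = np.zeros((n_out, n_par))
    absolute = np.zeros((n_out, n_par))
    zero_flags = np.abs(base) < 1e-12

    dlnp = np.log(1.0 + rel_step) - np.log(1.0 - rel_step)
    for j, pname in enumerate(names):
        p0 = params[pname]
        if p0 == 0.0:
            mat[:, j] = 0.0
            continue
        up = _evaluate_outputs(
            simulate(SCENARIOS[scenario], params.scaled(pname, 1.0 + rel_step)), outputs)
        dn = _evaluate_outputs(
            simulate(SCENARIOS[scenario], params.scaled(pname, 1.0 - rel_step)), outputs)
        absolute[:, j] = (up - dn) / (2.0 * rel_step * p0)
        for i in range(n_out):
            if zero_flags[i] or up[i] <= 0.0 or dn[i] <= 0.0:
                mat[i, j] = 0.0
            else:
                mat[i, j] = (np.log(up[i]) - np.log(dn[i])) / dlnp
    return SensitivityResult(
        outputs=tuple(outputs), parameters=names, matrix=mat, absolute=absolute,
        zero_output_flags=zero_flags, rel_step=rel_step, scenario=scenario,
    )


#: The seven qualitative constraints of the requirement profile.
CONSTRAINT_NAMES: tuple[str, ...] = (
    "tnf_alone_no_caspase3",
    "fasl_medium_caspase3",
    "sensitizing_high_caspase3",
    "xiap_ko_fasl_not_enhanced_by_sensitizing",
    "tnf_actd_high_caspase3",
    "tnf_actd_bha_no_caspase3",
    "bid_ko_tnf_actd_not_high",
)

#: "not further enhanced": sensitizing may not raise the XIAP-KO FasL
#: caspase-3 maximum by more than this factor.
XIAP_KO_ENHANCEMENT_TOLERANCE = 1.2


@dataclass
class ConstraintReport:
    name: str
    passed: bool
    measured: dict = field(default_factory=dict)


def check_constraints(params: ParameterSet | None = None) -> list[ConstraintReport]:
    """Evaluate the seven qualitative constraints at a parameter point."""
    if params is None:
        params = build_default_parameters()
    reps = {}
    for name in ("TNF", "FasL", "SENSITIZING", "FasL_XIAPKO", "SENSITIZING_XIAPKO",
                 "TNF_ActD", "TNF_ActD_BHA", "TNF_ActD_BidKO"):
        _, reps[name] = run_scenario(name, params)

    out = [
        ConstraintReport(
            "tnf_alone_no_caspase3",
            reps["TNF"].c3_class == "none",
            {"c3_class": reps["TNF"].c3_class, "c3_max": reps["TNF"].c3_max},
        ),
        ConstraintReport(
            "fasl_medium_caspase3",
            reps["FasL"].c3_class == "medium" and reps["FasL"].momp_time is None,
            {"c3_class": reps["FasL"].c3_class, "momp_time": reps["FasL"].momp_time},
        ),
        ConstraintReport(
            "sensitizing_high_caspase3",
            reps["SENSITIZING"].c3_class == "high",
            {"c3_class": reps["SENSITIZING"].c3_class, "c3_max": reps["SENSITIZING"].c3_max},
        ),
        ConstraintReport(
            "xiap_ko_fasl_not_enhanced_by_sensitizing",
            (reps["FasL_XIAPKO"].c3_max > reps["FasL"].c3_max
             and reps["SENSITIZING_XIAPKO"].c3_max
             <= XIAP_KO_ENHANCEMENT_TOLERANCE * reps["FasL_XIAPKO"].c3_max),
            {"fasl_xiapko": reps["FasL_XIAPKO"].c3_max,
             "sens_xiapko": reps["SENSITIZING_XIAPKO"].c3_max},
        ),
        ConstraintReport(
            "tnf_actd_high_caspase3",
            reps["TNF_ActD"].c3_class == "high" and reps["TNF_ActD"].momp_time is not None,
            {"c3_class": reps["TNF_ActD"].c3_class, "momp_time": reps["TNF_ActD"].momp_time},
        ),
        ConstraintReport(
            "tnf_actd_bha_no_caspase3",
            reps["TNF_ActD_BHA"].c3_class == "none",
            {"c3_class": reps["TNF_ActD_BHA"].c3_class},
        ),
        ConstraintReport(
            "bid_ko_tnf_actd_not_high",
            reps["TNF_ActD_BidKO"].c3_class != "high",
            {"c3_class": reps["TNF_ActD_BidKO"].c3_class},
        ),
    ]
    return out


@dataclass
class RobustnessResult:
    parameter: str
    factors: tuple[float, ...]
    pattern_holds: tuple[bool, ...]
    failed_constraints: tuple[tuple[str, ...], ...]
    verdict: str                      # "robust" | "fragile"
    largest_preserving_factor: float


DEFAULT_FACTORS: tuple[float, ...] = (1e-2, 1e-1, 1.0, 1e1, 1e2)


def robustness_scan(
    params: ParameterSet | None = None,
    param_name: str = "k_asm_disc",
    factors: tuple[float, ...] = DEFAULT_FACTORS,
) -> RobustnessResult:
    """Single-parameter multiplicative perturbation scan.

    The verdict is *robust* iff the full seven-constraint profile holds at
    every factor of the (by default four-order-of-magnitude) battery.
    Integrator failure at an extreme factor is recorded as a pattern change.
    """
    if params is None:
        params = build_default_parameters()
    if any(f <= 0 for f in factors):
        raise ValueError("factors must be positive")
    holds, failures = [], []
    for f in factors:
        try:
            reports = check_constraints(params.scaled(param_name, f))
            bad = tuple(r.name for r in reports if not r.passed)
        except Exception as exc:  # step-size collapse etc.
            bad = (f"integrator_failure: {exc}",)
        holds.append(len(bad) == 0)
        failures.append(bad)
    ok_factors = [f for f, h in zip(factors, holds) if h]
    spread = (max(ok_factors) / min(ok_factors)) if ok_factors else 0.0
    return RobustnessResult(
        parameter=param_name,
        factors=tuple(factors),
        pattern_holds=tuple(holds),
        failed_constraints=tuple(failures),
        verdict="robust" if all(holds) else "fragile",
        largest_preserving_factor=spread,
    )
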