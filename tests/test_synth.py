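"""Pseudo-experimental assays and the parameter-recovery harness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hepapop import AssayConfig, StimulusProtocol, generate_pseudo_experiment, recover_parameters, simulate
from hepapop.synthetic_data import DEFAULT_TIMEPOINTS


@pytest.fixture(scope="module")
def resting_traj(params):
    return simulate(StimulusProtocol(t_end=10.0), params)


def test_assay_config_validation():
    with pytest.raises(ValueError, match="unknown assay"):
        AssayConfig("elisa")
    with pytest.raises(ValueError, match="sigma"):
        AssayConfig("dcf_ros_fold", sigma=-0.1)
    cfg = AssayConfig("dcf_ros_fold")
    assert cfg.timepoints == DEFAULT_TIMEPOINTS["dcf_ros_fold"]


def test_resting_dcf_fold_is_one(params, resting_traj):
    cfg = AssayConfig("dcf_ros_fold", sigma=0.0, replicates=2)
    table = generate_pseudo_experiment(resting_traj, [cfg], seed=0, params=params)
    assert np.allclose(table.data["value"], 1.0)


def test_resting_devdase_fold_is_one(params, resting_traj, battery):
    cfg = AssayConfig("devdase_fold", sigma=0.0, replicates=1)
    table = generate_pseudo_experiment(resting_traj, [cfg], seed=0, params=params)
    assert np.allclose(table.data["value"], 1.0)


def test_wb_reads_the_jnk_upregulation(params, battery):
    """Densitometry of total JNK under TNF+ActD: 100 at rest, ~507 at 8 h."""
    traj, _ = battery["TNF_ActD"]
    cfg = AssayConfig("wb_densitometry", target="JNK+pJNK",
                      timepoints=(0.5, 8.0), sigma=0.0, replicates=1)
    table = generate_pseudo_experiment(traj, [cfg], seed=0, params=params)
    v = table.data.set_index("time")["value"]
    assert v[0.5] == pytest.approx(100.0, rel=0.02)
    assert v[8.0] == pytest.approx(507.0, rel=0.05)


def test_same_seed_identical_tables(params, resting_traj):
    cfgs = [AssayConfig("dcf_ros_fold", sigma=0.2), AssayConfig("qpcr_ddct", sigma=0.1)]
    a = generate_pseudo_experiment(resting_traj, cfgs, seed=42, params=params)
    b = generate_pseudo_experiment(resting_traj, cfgs, seed=42, params=params)
    pd.testing.assert_frame_equal(a.data, b.data)
    c = generate_pseudo_experiment(resting_traj, cfgs, seed=43, params=params)
    assert not np.allclose(a.data["value"], c.data["value"])


def test_timepoint_outside_trajectory_rejected(params, resting_traj):
    cfg = AssayConfig("dcf_ros_fold", timepoints=(2.0, 12.0))
    with pytest.raises(ValueError, match="outside trajectory"):
        generate_pseudo_experiment(resting_traj, [cfg], seed=0, params=params)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(sigma=st.floats(0.0, 0.5), seed=st.integers(0, 2**16), reps=st.integers(1, 4))
def test_fold_values_positive_and_row_counts(sigma, seed, reps, params, resting_traj):
    cfg = AssayConfig("dcf_ros_fold", sigma=sigma, replicates=reps)
    table = generate_pseudo_experiment(resting_traj, [cfg], seed=seed, params=params)
    assert (table.data["value"] > 0).all()
    assert len(table.data) == len(cfg.timepoints) * reps


WB_CFG = dict(target="JNK+pJNK", timepoints=(2.0, 4.0, 5.0, 6.0, 7.0, 8.0))


class TestRecovery:
    def test_zero_noise_round_trip(self, params, battery):
        traj, _ = battery["TNF_ActD"]
        cfg = AssayConfig("wb_densitometry", sigma=0.0, replicates=1, **WB_CFG)
        table = generate_pseudo_experiment(traj, [cfg], seed=0, params=params,
                                           scenario="TNF_ActD")
        start = params.with_overrides({"k_jnk_inc": 1.0})
        rep = recover_parameters(table, ["k_jnk_inc"], [cfg], params_init=start)
        assert rep.estimates["k_jnk_inc"] == pytest.approx(2.0, rel=1e-3)

    def test_noise_monotonicity_of_rmse(self, params, battery):
        """Estimator RMSE is non-decreasing in the assay noise scale."""
        traj, _ = battery["TNF_ActD"]
        start = params.with_overrides({"k_jnk_inc": 1.0})
        rmse = []
        for sigma in (0.0, 0.1, 0.3):
            errs = []
            for seed in (0, 1):
                cfg = AssayConfig("wb_densitometry", sigma=sigma, replicates=3, **WB_CFG)
                table = generate_pseudo_experiment(traj, [cfg], seed=seed, params=params,
                                                   scenario="TNF_ActD")
                rep = recover_parameters(table, ["k_jnk_inc"], [cfg],
                                         params_init=start, max_nfev=25)
                errs.append(rep.estimates["k_jnk_inc"] - 2.0)
            rmse.append(float(np.sqrt(np.mean(np.square(errs)))))
        assert rmse[0] <= rmse[1] + 1e-6 <= rmse[2] + 2e-3

    def test_unknown_free_parameter_rejected(self, params, battery):
        traj, _ = battery["TNF_ActD"]
        cfg = AssayConfig("wb_densitometry", sigma=0.0, replicates=1, **WB_CFG)
        table = generate_pseudo_experiment(traj, [cfg], seed=0, params=params,
                                           scenario="TNF_ActD")
        with pytest.raises(KeyError):
            recover_parameters(table, ["k_bogus"], [cfg], params_init=params)
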