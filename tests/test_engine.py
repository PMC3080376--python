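"""Simulation engine: protocol handling, MOMP event semantics, stability."""

import numpy as np
import pytest

from hepapop import StimulusProtocol, build_default_parameters, momp_check, simulate
from hepapop.model_core import CORE_INDEX
from hepapop.simulation_engine import ALL_SPECIES, initial_composite_state


def test_all_off_protocol_stays_at_rest(params):
    traj = simulate(StimulusProtocol(t_end=10.0), params)
    y0 = traj.y[0]
    drift = np.max(np.abs(traj.y - y0), axis=0)
    scale = np.maximum(np.abs(y0), 1.0)
    assert np.max(drift / scale) < 1e-6


def test_protocol_validation():
    with pytest.raises(ValueError, match="fasl_time"):
        StimulusProtocol(fasl_time=15.0, t_end=10.0)
    with pytest.raises(ValueError, match="t_end"):
        StimulusProtocol(t_end=-1.0)


class TestMompCheck:
    def _state(self, params, frac):
        y = initial_composite_state(StimulusProtocol(), params)
        y[CORE_INDEX["BaxBak"]] = 100.0 * (1 - frac)
        y[CORE_INDEX["BaxBakA"]] = 100.0 * frac
        return y

    def test_below_threshold(self, params):
        assert momp_check(self._state(params, 0.19), params) is False

    def test_at_threshold(self, params):
        assert momp_check(self._state(params, 0.20), params) is True

    def test_empty_pool_rejected(self, params):
        y = initial_composite_state(StimulusProtocol(), params)
        y[CORE_INDEX["BaxBak"]] = 0.0
        y[CORE_INDEX["BaxBakA"]] = 0.0
        with pytest.raises(ValueError, match="Bax/Bak"):
            momp_check(y, params)


class TestMompEvent:
    def test_momp_fires_once_and_latches(self, battery):
        traj, _ = battery["TNF_ActD"]
        momp_events = [e for e in traj.events if e[0] == "MOMP"]
        assert len(momp_events) == 1
        t_momp = momp_events[0][1]
        # full pool transferred instantaneously, never released again
        after = traj.t > t_momp + 1e-9
        assert np.all(traj["Cytc_mito"][after] == 0.0)

    def test_cytochrome_c_conserved_across_event(self, battery):
        traj, _ = battery["TNF_ActD"]
        t_momp = traj.momp_time
        i_after = int(np.searchsorted(traj.t, t_momp + 1e-9))
        total_before = traj["Cytc_mito"][0] + traj["Cytc_cyto"][0]
        total_after = traj["Cytc_mito"][i_after] + traj["Cytc_cyto"][i_after]
        # conserved up to the brief decay between event and next grid point
        assert total_after == pytest.approx(total_before, rel=1e-2)

    def test_no_momp_without_stimulus(self, battery):
        assert battery["TNF"][0].momp_time is None
        assert battery["FasL"][0].momp_time is None


def test_trajectory_non_negative(battery):
    for name in ("TNF", "TNF_ActD", "SENSITIZING", "TNF_CHX"):
        traj, _ = battery[name]
        assert traj.y.min() >= 0.0


def test_solver_tolerance_refinement(params):
    """Halving tolerances changes total JNK at 8 h (TNF+ActD) by < 0.1%."""
    proto = StimulusProtocol(tnf_on=True, actd=True, t_end=8.0)
    a = simulate(proto, params).at("JNK+pJNK", 8.0)
    b = simulate(proto, params, rtol=5e-8, atol=5e-10).at("JNK+pJNK", 8.0)
    assert abs(a - b) / a < 1e-3


def test_trajectory_accessors(battery):
    traj, _ = battery["TNF"]
    assert traj.y.shape[1] == len(ALL_SPECIES) == 53
    assert np.all(np.diff(traj.t) > 0)
    total = traj["JNK+pJNK"]
    assert total[0] == pytest.approx(100.0)
    with pytest.raises(ValueError, match="outside trajectory"):
        traj.at("C3", 99.0)
    df = traj.to_wide_df()
    assert list(df.columns[:1]) == ["time"] and df.shape[1] == 54
    tidy = traj.to_tidy_df()
    assert set(tidy.columns) == {"time", "species", "value"}


def test_parameter_override_in_protocol(params):
    proto = StimulusProtocol(tnf_on=True, t_end=1.0,
                             parameter_overrides={"k_asm_c1": 0.0})
    traj = simulate(proto, params)
    assert np.max(traj["complex1"]) == 0.0
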