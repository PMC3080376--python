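"""Rate laws of the 37-species core: fixed point, hand-derived fluxes,
conservation, and an independent Euler oracle for the JNK/MKP subnetwork."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from hepapop import ModelInputs, build_initial_state, core_rhs, ros_release_rate
from hepapop.model_core import CORE_INDEX, CORE_SPECIES

OFF = ModelInputs()
TNF_ON = ModelInputs(tnf=lambda t: 1.0)


def test_resting_state_is_fixed_point(params):
    d = core_rhs(0.0, build_initial_state(frozenset()), params, OFF)
    assert np.max(np.abs(d)) == 0.0


def test_tnf_drives_complex1_at_hand_computed_rate(params):
    # d(complex1)/dt at t=0 under TNF = k_asm_c1 * complex0 = 0.05 * 100
    d = core_rhs(0.0, build_initial_state(frozenset()), params, TNF_ON)
    assert d[CORE_INDEX["complex1"]] == pytest.approx(5.0)
    assert d[CORE_INDEX["complex0"]] == pytest.approx(-5.0)  # production balances decay at rest


def test_ros_feeds_jnk_and_oxidizes_mkp(params):
    y = build_initial_state(frozenset())
    y[CORE_INDEX["ROS"]] = 10.0
    d = core_rhs(0.0, y, params, OFF)
    # JNK production k_jnk_inc * ROS = 2 * 10; MKP oxidation 0.1 * 10 * 50
    assert d[CORE_INDEX["JNK"]] == pytest.approx(2.0 * 10.0)
    assert d[CORE_INDEX["MKP"]] == pytest.approx(-0.1 * 10.0 * 50.0)
    assert d[CORE_INDEX["MKPox"]] == pytest.approx(+0.1 * 10.0 * 50.0)
    # the oxidation consumes the ROS
    assert d[CORE_INDEX["ROS"]] == pytest.approx(-0.1 * 10.0 * 50.0)


def test_negative_state_rejected(params):
    y = build_initial_state(frozenset())
    y[CORE_INDEX["JNK"]] = -1.0
    with pytest.raises(ValueError, match="negative state"):
        core_rhs(0.0, y, params, OFF)


@pytest.mark.parametrize("members", [
    ("JNK", "pJNK"),                       # with ROS = 0
    ("proMKK7", "MKK7"),
    ("prophosphatase", "phosphatase"),
    ("MKP", "MKPox"),
    ("Itch", "ItchP", "ItchPP", "ItchPPP"),
    ("BaxBak", "BaxBakA"),
])
def test_conserved_subnetwork_totals(params, members):
    """Activation/deactivation cycles move amounts within a pool, never out."""
    rng = np.random.default_rng(7)
    y = build_initial_state(frozenset())
    # random positive excursion over every species keeps all reactions live
    y = y + rng.uniform(0.0, 5.0, size=y.shape)
    y[CORE_INDEX["ROS"]] = 0.0  # JNK total grows only via ROS
    d = core_rhs(0.3, y, params, ModelInputs(tnf=lambda t: 1.0, chx=True))
    total = sum(d[CORE_INDEX[m]] for m in members)
    assert total == pytest.approx(0.0, abs=1e-9)


def test_bcl2_neutralization_consumes_both_partners(params):
    y = build_initial_state(frozenset())
    y[CORE_INDEX["pBim"]] = 4.0
    d = core_rhs(0.0, y, params, OFF)
    v = params["k_bcl2_pbim"] * 100.0 * 4.0
    assert d[CORE_INDEX["Bcl2"]] == pytest.approx(-v)
    assert d[CORE_INDEX["pBim"]] == pytest.approx(-v - params["k_dec_pbim"] * 4.0)


def test_itch_chain_requires_cycloheximide(params):
    y = build_initial_state(frozenset())
    y[CORE_INDEX["pJNK"]] = 50.0
    d_nochx = core_rhs(0.0, y, params, TNF_ON)
    assert d_nochx[CORE_INDEX["Itch"]] == 0.0
    d_chx = core_rhs(0.0, y, params, ModelInputs(tnf=lambda t: 1.0, chx=True))
    assert d_chx[CORE_INDEX["Itch"]] == pytest.approx(-params["k_itch1"] * 50.0 * 100.0)


class TestRosRelease:
    def test_pulse_integral_is_100_units(self, params):
        ts = np.linspace(0.0, 10.0, 200001)
        rates = np.array([ros_release_rate(t, TNF_ON, params) for t in ts])
        assert np.trapezoid(rates, ts) == pytest.approx(100.0, rel=1e-3)

    def test_bha_abolishes_release(self, params):
        inp = ModelInputs(tnf=lambda t: 1.0, bha=True)
        assert all(ros_release_rate(t, inp, params) == 0.0 for t in np.linspace(0, 10, 501))

    def test_no_tnf_no_release(self, params):
        assert all(ros_release_rate(t, OFF, params) == 0.0 for t in np.linspace(0, 10, 501))

    def test_pulse_supported_near_4h(self, params):
        assert ros_release_rate(4.0, TNF_ON, params) > 0.0
        assert ros_release_rate(3.0, TNF_ON, params) == 0.0
        assert ros_release_rate(5.0, TNF_ON, params) == 0.0


def test_jnk_subnetwork_matches_explicit_euler_oracle(params):
    """JNK<->pJNK under fixed MKK7 and MKP against a hand-written fine-step
    Euler integration of the same two mass-action fluxes."""
    mkk7, mkp = 5.0, 50.0
    y0 = np.zeros(len(CORE_SPECIES))
    y0[CORE_INDEX["JNK"]] = 100.0
    y0[CORE_INDEX["MKP"]] = mkp
    y0[CORE_INDEX["MKK7"]] = mkk7  # no phosphatase, no complex1: MKK7 frozen

    sol = solve_ivp(
        lambda t, y: core_rhs(t, np.maximum(y, 0.0), params, OFF),
        (0.0, 1.0), y0, method="LSODA", rtol=1e-10, atol=1e-12,
    )
    jnk_model = sol.y[CORE_INDEX["JNK"], -1]
    pjnk_model = sol.y[CORE_INDEX["pJNK"], -1]

    # independent oracle: explicit Euler, dt = 1e-5 h
    kp, kd = 0.4, 0.9
    jnk, pjnk = 100.0, 0.0
    dt = 1e-5
    for _ in range(100000):
        v1 = kp * mkk7 * jnk
        v2 = kd * mkp * pjnk
        jnk += dt * (-v1 + v2)
        pjnk += dt * (v1 - v2)
    assert jnk_model == pytest.approx(jnk, rel=1e-3)
    assert pjnk_model == pytest.approx(pjnk, rel=1e-3)
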