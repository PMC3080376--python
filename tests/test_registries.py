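"""Species and parameter registries: counts, resting state, printed values."""

import numpy as np
import pytest

from hepapop import CORE_SPECIES, NFKB_SPECIES, build_default_parameters, build_initial_state
from hepapop.export import parameter_registry, species_registry
from hepapop.model_core import CORE_INDEX
from hepapop.nfkb_module import NFKB_PARAM_NAMES


def test_species_counts():
    assert len(CORE_SPECIES) == 37
    assert len(NFKB_SPECIES) == 16
    assert len(set(CORE_SPECIES) | set(NFKB_SPECIES)) == 53


def test_parameter_count_is_74(params):
    assert len(params) == 74
    assert len(NFKB_PARAM_NAMES) == 30


@pytest.mark.parametrize("name,value", [
    ("k_asm_c1", 0.05),
    ("k_asm_c2", 0.001),
    ("k_c8_disc", 0.8),
    ("k_c8_c2", 0.08),
    ("k_flip_disc", 8.0),
    ("k_flip_c2", 8.0),
    ("k_jnk_inc", 2.0),
    ("k_phos_jnk", 0.4),
    ("k_deph_jnk", 0.9),
    ("k_ox_mkp", 0.1),
    ("k_rec_mkp", 0.01),
    ("k_scav", 1.0),
    ("k_transl_P", 25.0),
])
def test_published_rate_values(params, name, value):
    assert params[name] == pytest.approx(value)


def test_parameter_invariants(params):
    # successive Itch phosphorylations are cooperative (increasing rates)
    assert params["k_itch1"] < params["k_itch2"] < params["k_itch3"]
    # caspase-8 activation is ten times weaker at complex2 than at the DISC
    assert params["k_c8_c2"] == pytest.approx(params["k_c8_disc"] / 10.0)
    # strictly positive except the NF-kB module's constitutive transcription
    # rates, which the source model sets to zero
    zero_ok = {"c2", "c2a", "c2p"}
    for name, v in params.as_dict().items():
        assert v > 0 or (name in zero_ok and v == 0)
    assert params.structural["momp_threshold"] == pytest.approx(0.20)
    assert params.structural["ros_pulse_amount"] == pytest.approx(100.0)
    assert params.structural["ros_pulse_time"] == pytest.approx(4.0)


def test_resting_initial_state():
    y0 = build_initial_state(frozenset())
    expected = {"complex0": 100, "cFLIP": 100, "JNK": 100, "proMKK7": 100,
                "Itch": 100, "prophosphatase": 100, "proDISC": 100,
                "MKP": 50, "FADD": 200, "ROS": 0}
    for name, v in expected.items():
        assert y0[CORE_INDEX[name]] == pytest.approx(v)
    # all activated / complexed forms start at zero
    for name in ("complex1", "complex2", "pJNK", "MKPox", "tBid", "pBim",
                 "BaxBakA", "C3", "C3_XIAP", "Cytc_cyto", "DISC", "C8"):
        assert y0[CORE_INDEX[name]] == 0.0


@pytest.mark.parametrize("ko,zeroed", [
    ({"Bid"}, ["Bid"]),
    ({"XIAP"}, ["XIAP"]),
    ({"C8"}, ["C8", "proC8"]),
])
def test_knockouts_zero_pools(ko, zeroed):
    y0 = build_initial_state(frozenset(ko))
    ref = build_initial_state(frozenset())
    for name in zeroed:
        assert y0[CORE_INDEX[name]] == 0.0
    touched = {CORE_INDEX[n] for n in zeroed}
    for i in range(len(CORE_SPECIES)):
        if i not in touched:
            assert y0[i] == ref[i]


def test_unknown_knockout_rejected():
    with pytest.raises(KeyError, match="unknown species"):
        build_initial_state(frozenset({"NotASpecies"}))


def test_override_and_scaling(params):
    p2 = params.with_overrides({"k_jnk_inc": 3.0})
    assert p2["k_jnk_inc"] == 3.0 and params["k_jnk_inc"] == 2.0
    p3 = params.scaled("k_asm_c2", 10.0)
    assert p3["k_asm_c2"] == pytest.approx(0.01)
    with pytest.raises(KeyError):
        params.with_overrides({"bogus": 1.0})
    with pytest.raises(ValueError):
        params.with_overrides({"k_jnk_inc": -1.0})


def test_json_registries(params):
    sp = species_registry()
    assert len(sp) == 53
    pr = parameter_registry(params)
    rate_rows = [r for r in pr if r["block"] != "structural"]
    assert len(rate_rows) == 74
    assert {r["block"] for r in rate_rows} == {"extension", "nfkb", "sensitizing_core"}
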