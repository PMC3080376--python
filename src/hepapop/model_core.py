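"""Core reaction network of TNF-alpha-induced hepatocyte apoptosis.

This module owns the 37 "core" species (everything outside the NF-kB
transcription module): the TNF receptor complexes (complex0/1/2), the Fas
DISC, the caspase-8/cFLIP competition, the MKK7-JNK-phosphatase-MKP loop with
its ROS feedback, the Itch chain that degrades cFLIP under cycloheximide, and
the Bim/Bid/Bcl2/Bax-Bak mitochondrial switch with its caspase-3/XIAP
effector arm.

All kinetics are bilinear/linear mass action in arbitrary units (AU), time in
hours.  The Boolean stimuli TNF, FasL, ActD, CHX and BHA enter the rate laws
as 0/1 multipliers.  Mitochondrial cytochrome c release is *not* part of the
right-hand side: it is a discrete event handled by the simulation engine once
the activated Bax/Bak fraction crosses the pore-formation threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

__all__ = [
    "CORE_SPECIES",
    "ParameterSet",
    "ModelInputs",
    "build_default_parameters",
    "build_initial_state",
    "core_rhs",
    "ros_release_rate",
]

# ---------------------------------------------------------------------------
# Species registry
# ---------------------------------------------------------------------------

#: Canonical ordering of the 37 core species.  The composite state vector used
#: by the simulation engine is this list followed by the 16 NF-kB species.
CORE_SPECIES: tuple[str, ...] = (
    "complex0", "complex1", "FADD", "complex2", "c2FLIP",
    "proDISC", "DISC", "DcFLIP", "cFLIP",
    "proC8", "C8",
    "proMKK7", "MKK7", "JNK", "pJNK",
    "prophosphatase", "phosphatase", "MKP", "MKPox",
    "Itch", "ItchP", "ItchPP", "ItchPPP",
    "ROS",
    "Bim", "pBim", "Bid", "tBid", "Bcl2",
    "BaxBak", "BaxBakA",
    "Cytc_mito", "Cytc_cyto",
    "proC3", "C3", "XIAP", "C3_XIAP",
)

CORE_INDEX: dict[str, int] = {name: i for i, name in enumerate(CORE_SPECIES)}

# Resting amounts (AU, "%" of the reference pools).  Everything not listed
# starts at zero.
_CORE_INITIAL: dict[str, float] = {
    "complex0": 100.0,
    "proDISC": 100.0,
    "cFLIP": 100.0,
    "JNK": 100.0,
    "proMKK7": 100.0,
    "Itch": 100.0,
    "prophosphatase": 100.0,
    "MKP": 50.0,
    "FADD": 200.0,
    # Pools of the retained sensitizing core.  Bim and Bcl2 are equal by
    # construction: phosphorylated Bim alone must exactly exhaust the Bcl2
    # buffer, so that apoptosis additionally requires caspase-8-derived tBid
    # (the Bid-knockout discriminator).
    "Bim": 100.0,
    "Bcl2": 100.0,
    "Bid": 100.0,
    "BaxBak": 100.0,
    "Cytc_mito": 100.0,
    "proC8": 100.0,
    "proC3": 100.0,
    "XIAP": 80.0,
}

#: Knockouts zero a species and, where the name denotes an activatable pool,
#: the precursor pool it is drawn from.
_KNOCKOUT_ALIASES: dict[str, tuple[str, ...]] = {
    "Bid": ("Bid",),
    "XIAP": ("XIAP",),
    "Bim": ("Bim",),
    "Bcl2": ("Bcl2",),
    "C8": ("C8", "proC8"),
    "C3": ("C3", "proC3"),
    "JNK": ("JNK",),
    "MKP": ("MKP",),
    "cFLIP": ("cFLIP",),
    "Itch": ("Itch",),
    "FADD": ("FADD",),
}


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

# 28 parameters of the model extension (Table-1 block).  Printed values are
# used verbatim; the remainder was calibrated once against the qualitative
# requirement profile (see docs/methods.md) and frozen here.
_EXTENSION_PARAMS: dict[str, float] = {
    "k_asm_c1": 0.05,      # assembly of complex1 from complex0 (x TNF)
    "k_asm_c2": 0.001,     # assembly of complex2 (complex1 + FADD)
    "k_c8_c2": 0.08,       # caspase-8 activation at complex2 (= k_c8_disc/10)
    "k_c8_disc": 0.8,      # caspase-8 activation at the DISC
    "k_act_mkk7": 0.6,    # activation of proMKK7 by complex1
    "k_phos_jnk": 0.4,     # phosphorylation of JNK by MKK7
    "k_act_ppase": 0.0027,   # activation of prophosphatase by pJNK
    "k_dec_ppase": 2e-5,    # relaxation of active phosphatase
    "k_deph_mkk7": 75.0,    # dephosphorylation of MKK7 by the phosphatase
    "k_transl_P": 25.0,    # translation of scavenger protein P (used in nfkb)
    "k_scav": 1.0,         # absorption of ROS by protein P
    "k_ox_mkp": 0.1,       # oxidation of MKPs by ROS
    "k_rec_mkp": 0.01,     # recovery of oxidized MKPs
    "k_jnk_inc": 2.0,      # linear increase of JNK amount with ROS
    "k_deph_jnk": 0.9,     # dephosphorylation of pJNK by MKPs
    "k_itch1": 0.002,      # 1st Itch phosphorylation by pJNK (x CHX)
    "k_itch2": 0.02,       # 2nd Itch phosphorylation by pJNK
    "k_itch3": 0.2,        # 3rd Itch phosphorylation by pJNK
    "k_flip_deg": 0.05,    # degradation of cFLIP by ItchPPP
    "k_flip_c2": 8.0,      # inhibition of complex2 by cFLIP
    "k_flip_disc": 8.0,    # inhibition of the DISC by cFLIP
    "k_dec_c2flip": 25.0,   # dissociation/decay of c2FLIP
    "k_dec_dcflip": 0.1,   # dissociation/decay of DcFLIP
    "k_turn_c0": 0.01,     # turnover (decay leg) of complex0; production =
                           # 100 x k_turn_c0 so complex0 rests at 100
    "k_dec_c1": 1.0,       # decay of complex1
    "k_dec_c2": 1.0,       # decay of complex2
    "k_dec_disc": 0.05,    # decay of the DISC
    "k_asm_disc": 5.0,     # assembly of the DISC (x FasL)
}

# 16 retained parameters of the sensitizing core (values recalibrated inside
# the extended framework, as in the source model's own integration step).
_SENSITIZING_PARAMS: dict[str, float] = {
    "k_c8_bid": 0.0065,     # cleavage of Bid by caspase-8
    "k_dec_c8": 0.3,       # decay of active caspase-8
    "k_jnk_bim": 0.045,     # phosphorylation of Bim by pJNK
    "k_bcl2_pbim": 20.0,    # neutralization of pBim by Bcl2
    "k_bcl2_tbid": 60.0,    # neutralization of tBid by Bcl2
    "k_bb_pbim": 0.1,      # Bax/Bak activation by pBim
    "k_bb_tbid": 14.0,      # Bax/Bak activation by tBid
    "k_bb_deact": 0.5,     # spontaneous Bax/Bak deactivation
    "k_c3_cytc": 0.1,      # caspase-3 activation by cytosolic cytochrome c
    "k_c3_c8": 0.0065,      # direct caspase-3 activation by caspase-8
    "k_xiap_on": 10.0,     # C3 + XIAP association
    "k_xiap_off": 0.005,   # C3.XIAP dissociation
    "k_dec_c3": 0.005,      # decay of active caspase-3
    "k_dec_pbim": 0.005,    # decay of pBim
    "k_dec_tbid": 0.02,    # decay of tBid
    "k_dec_cytc": 0.02,    # decay of cytosolic cytochrome c
}

# Structural constants (not rate parameters, not counted in the 74).
_STRUCTURAL: dict[str, float] = {
    "momp_threshold": 0.20,    # activated fraction of Bax/Bak firing MOMP
    "ros_pulse_amount": 100.0, # AU of ROS released
    "ros_pulse_time": 4.0,     # h, center of the release window
    "ros_pulse_width": 0.1,    # h, width of the rectangular release window
    "p0_ratio": 100.0,         # complex0 production/decay ratio (rest level)
}


class ParameterSet:
    """Named, positive rate parameters plus structural constants.

    The 74 rate parameters split into the 28 extension parameters, the 16
    retained sensitizing-core parameters (both owned here) and the 30 NF-kB
    module parameters (owned by :mod:`hepapop.nfkb_module` but carried in the
    same namespace for lookup, overrides and sensitivity analysis).
    """

    def __init__(self, values: Mapping[str, float], structural: Mapping[str, float] | None = None):
        self._values = dict(values)
        self.structural = dict(_STRUCTURAL)
        if structural:
            self.structural.update(structural)
        self._validate()

    def _validate(self) -> None:
        for name, v in self._values.items():
            if v < 0:
                raise ValueError(f"parameter {name!r} must be non-negative, got {v}")

    # Mapping-ish surface -------------------------------------------------
    def __getitem__(self, name: str) -> float:
        return self._values[name]

    def __contains__(self, name: str) -> bool:
        return name in self._values

    def __len__(self) -> int:
        return len(self._values)

    def names(self) -> tuple[str, ...]:
        return tuple(self._values)

    def as_dict(self) -> dict[str, float]:
        return dict(self._values)

    def with_overrides(self, overrides: Mapping[str, float]) -> "ParameterSet":
        """Return a copy with named parameters (or structural constants) replaced."""
        vals = dict(self._values)
        struct = dict(self.structural)
        for name, v in overrides.items():
            if name in vals:
                vals[name] = float(v)
            elif name in struct:
                struct[name] = float(v)
            else:
                raise KeyError(f"unknown parameter {name!r}")
        return ParameterSet(vals, struct)

    def scaled(self, name: str, factor: float) -> "ParameterSet":
        return self.with_overrides({name: self[name] * factor})

    def key(self) -> tuple:
        """Hashable identity used for memoising scenario reference runs."""
        return (tuple(sorted(self._values.items())), tuple(sorted(self.structural.items())))


@dataclass
class ModelInputs:
    """Boolean stimuli as functions of time (evaluate to 0 or 1)."""

    tnf: Callable[[float], float] = lambda t: 0.0
    fasl: Callable[[float], float] = lambda t: 0.0
    actd: bool = False
    chx: bool = False
    bha: bool = False


def build_default_parameters() -> ParameterSet:
    """Default parameterization: printed values verbatim, the rest as frozen
    calibration results (see docs/methods.md)."""
    from .nfkb_module import nfkb_parameter_values

    values: dict[str, float] = {}
    values.update(_EXTENSION_PARAMS)
    values.update(nfkb_parameter_values())
    values.update(_SENSITIZING_PARAMS)
    return ParameterSet(values)


def build_initial_state(knockouts: set[str] | frozenset[str] = frozenset()) -> np.ndarray:
    """Resting amounts of the 37 core species, with optional knockouts.

    Knocked-out species (and their precursor pools, e.g. proC8 for C8) are
    zeroed, emulating a different expression pattern / knockout mouse.  The
    16 NF-kB entries of the composite state are owned by
    :func:`hepapop.nfkb_module.compute_resting_steady_state`.
    """
    y0 = np.zeros(len(CORE_SPECIES))
    for name, v in _CORE_INITIAL.items():
        y0[CORE_INDEX[name]] = v
    for ko in knockouts:
        if ko in _KNOCKOUT_ALIASES:
            targets = _KNOCKOUT_ALIASES[ko]
        elif ko in CORE_INDEX:
            targets = (ko,)
        else:
            raise KeyError(
                f"unknown species {ko!r}; valid names: {', '.join(CORE_SPECIES)}"
            )
        for t in targets:
            y0[CORE_INDEX[t]] = 0.0
    return y0


def ros_release_rate(t: float, inputs: ModelInputs, params: ParameterSet) -> float:
    """Mitochondrial ROS release as a prescribed narrow pulse.

    A rectangular pulse centered at ``ros_pulse_time`` (default 4 h) whose time
    integral is ``ros_pulse_amount`` (100 AU) when TNF has been on since t=0.
    The antioxidant BHA abolishes the release entirely.
    """
    if inputs.bha or inputs.tnf(0.0) == 0.0:
        return 0.0
    t0 = params.structural["ros_pulse_time"]
    w = params.structural["ros_pulse_width"]
    if t0 - w / 2.0 <= t < t0 + w / 2.0:
        return params.structural["ros_pulse_amount"] / w
    return 0.0


def core_rhs(
    t: float,
    state: np.ndarray,
    params: ParameterSet | Mapping[str, float],
    inputs: ModelInputs,
    p_protein: float = 0.0,
    ros_input: float = 0.0,
) -> np.ndarray:
    """Mass-action derivatives of the 37 core species.

    ``p_protein`` is the current amount of the NF-kB-induced scavenger protein
    P (its own balance lives in the NF-kB module; only its ROS-consuming
    action appears here).  ``ros_input`` is the instantaneous mitochondrial
    release rate from :func:`ros_release_rate`.
    """
    y = np.asarray(state, dtype=float)
    if y.min() < -1e-9:
        bad = CORE_SPECIES[int(np.argmin(y))]
        raise ValueError(f"negative state entry for species {bad!r}: {y.min()}")

    p = params if isinstance(params, Mapping) else params.as_dict()
    if isinstance(params, ParameterSet):
        getp = params.__getitem__
        p0_ratio = params.structural["p0_ratio"]
    else:
        getp = p.__getitem__
        p0_ratio = _STRUCTURAL["p0_ratio"]

    (c0, c1, fadd, c2, c2flip, prodisc, disc, dcflip, cflip,
     proc8, c8, promkk7, mkk7, jnk, pjnk, proph, ph, mkp, mkpox,
     itch, itchp, itchpp, itchppp, ros,
     bim, pbim, bid, tbid, bcl2, bb, bba,
     cytm, cytc, proc3, c3, xiap, c3x) = y

    tnf = inputs.tnf(t)
    fasl = inputs.fasl(t)
    chx = 1.0 if inputs.chx else 0.0

    k = getp
    d = np.zeros_like(y)

    # --- TNF receptor complexes -------------------------------------------
    p0_deg = k("k_turn_c0")
    p0_prod = p0_ratio * p0_deg
    v_asm_c1 = k("k_asm_c1") * tnf * c0
    v_asm_c2 = k("k_asm_c2") * c1 * fadd
    v_flip_c2 = k("k_flip_c2") * c2 * cflip
    v_rel_c2 = k("k_dec_c2flip") * c2flip

    d[0] = p0_prod - p0_deg * c0 - v_asm_c1                       # complex0
    d[1] = v_asm_c1 - v_asm_c2 - k("k_dec_c1") * c1               # complex1
    d[3] = v_asm_c2 - v_flip_c2 + v_rel_c2 - k("k_dec_c2") * c2   # complex2
    d[4] = v_flip_c2 - v_rel_c2                                   # c2FLIP

    # --- Fas DISC ----------------------------------------------------------
    v_asm_disc = k("k_asm_disc") * fasl * prodisc * fadd
    v_flip_disc = k("k_flip_disc") * disc * cflip
    v_rel_disc = k("k_dec_dcflip") * dcflip
    d[5] = -v_asm_disc                                            # proDISC
    d[6] = v_asm_disc - v_flip_disc + v_rel_disc - k("k_dec_disc") * disc
    d[7] = v_flip_disc - v_rel_disc                               # DcFLIP
    d[2] = -v_asm_c2 - v_asm_disc                                 # FADD

    # --- caspase-8 / cFLIP --------------------------------------------------
    v_c8 = k("k_c8_c2") * c2 * proc8 + k("k_c8_disc") * disc * proc8
    d[9] = -v_c8                                                  # proC8
    d[10] = v_c8 - k("k_dec_c8") * c8                             # C8
    v_flip_deg = k("k_flip_deg") * itchppp * cflip
    d[8] = -v_flip_c2 + v_rel_c2 - v_flip_disc + v_rel_disc - v_flip_deg

    # --- MKK7 / JNK / phosphatase / MKP loop --------------------------------
    v_act_mkk7 = k("k_act_mkk7") * c1 * promkk7
    v_deph_mkk7 = k("k_deph_mkk7") * ph * mkk7
    v_phos_jnk = k("k_phos_jnk") * mkk7 * jnk
    v_deph_jnk = k("k_deph_jnk") * mkp * pjnk
    v_act_pp = k("k_act_ppase") * pjnk * proph
    v_dec_pp = k("k_dec_ppase") * ph
    d[11] = -v_act_mkk7 + v_deph_mkk7                             # proMKK7
    d[12] = v_act_mkk7 - v_deph_mkk7                              # MKK7
    d[13] = -v_phos_jnk + v_deph_jnk + k("k_jnk_inc") * ros       # JNK
    d[14] = v_phos_jnk - v_deph_jnk                               # pJNK
    d[15] = -v_act_pp + v_dec_pp                                  # prophosphatase
    d[16] = v_act_pp - v_dec_pp                                   # phosphatase

    # --- MKP redox / ROS ----------------------------------------------------
    v_ox = k("k_ox_mkp") * ros * mkp
    v_rec = k("k_rec_mkp") * mkpox
    d[17] = -v_ox + v_rec                                         # MKP
    d[18] = v_ox - v_rec                                          # MKPox
    d[23] = ros_input - k("k_scav") * ros * p_protein - v_ox      # ROS

    # --- Itch chain (only under cycloheximide) ------------------------------
    v_i1 = chx * k("k_itch1") * pjnk * itch
    v_i2 = chx * k("k_itch2") * pjnk * itchp
    v_i3 = chx * k("k_itch3") * pjnk * itchpp
    d[19] = -v_i1
    d[20] = v_i1 - v_i2
    d[21] = v_i2 - v_i3
    d[22] = v_i3

    # --- BH3-only proteins, Bcl2 buffer, Bax/Bak ----------------------------
    v_pbim = k("k_jnk_bim") * pjnk * bim
    v_tbid = k("k_c8_bid") * c8 * bid
    v_bcl2_pbim = k("k_bcl2_pbim") * bcl2 * pbim
    v_bcl2_tbid = k("k_bcl2_tbid") * bcl2 * tbid
    d[24] = -v_pbim                                               # Bim
    d[25] = v_pbim - v_bcl2_pbim - k("k_dec_pbim") * pbim         # pBim
    d[26] = -v_tbid                                               # Bid
    d[27] = v_tbid - v_bcl2_tbid - k("k_dec_tbid") * tbid         # tBid
    d[28] = -v_bcl2_pbim - v_bcl2_tbid                            # Bcl2
    v_bb = (k("k_bb_pbim") * pbim + k("k_bb_tbid") * tbid) * bb
    d[29] = -v_bb + k("k_bb_deact") * bba                         # BaxBak
    d[30] = v_bb - k("k_bb_deact") * bba                          # BaxBakA

    # --- effector caspase arm ----------------------------------------------
    v_c3 = (k("k_c3_cytc") * cytc + k("k_c3_c8") * c8) * proc3
    v_on = k("k_xiap_on") * c3 * xiap
    v_off = k("k_xiap_off") * c3x
    d[31] = 0.0                                                   # Cytc_mito (event only)
    d[32] = -k("k_dec_cytc") * cytc                               # Cytc_cyto
    d[33] = -v_c3                                                 # proC3
    d[34] = v_c3 - v_on + v_off - k("k_dec_c3") * c3              # C3
    d[35] = -v_on + v_off                                         # XIAP
    d[36] = v_on - v_off                                          # C3.XIAP

    return d
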