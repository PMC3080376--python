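"""The 16-species NF-kB / transcription subsystem.

Adopted from the published two-compartment NF-kB regulatory module (IKK,
IkBa, A20, NF-kB and their complexes; cytoplasm and nucleus as separate
compartments) with three modifications made by the adopting apoptosis model:
the cytoplasm:nucleus volume ratio is 3, time is rescaled to hours, and every
transcript-synthesis term is gated by (1-ActD) so that actinomycin D stops
all mRNA production.  The source model's generic target-gene transcript is
repurposed as P_mRNA; its protein product P is the ROS scavenger that couples
this module to the core network.

Species live in the source module's native units (micromolar); the scavenger
protein P is translated into core arbitrary units by the bridge rate
k_transl_P (25 AU per transcript-unit per hour).
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "NFKB_SPECIES",
    "NFKB_PARAM_NAMES",
    "nfkb_parameter_values",
    "nfkb_rhs",
    "compute_resting_steady_state",
]

#: Canonical ordering of the 16 NF-kB-module species (appended to the 37 core
#: species in the composite state vector).
NFKB_SPECIES: tuple[str, ...] = (
    "IKKn", "IKKa", "IKKi",
    "IKKa_IkBa", "IKKa_IkBa_NFkB",
    "NFkB", "NFkBn",
    "A20", "A20t",
    "IkBa", "IkBan", "IkBa_NFkB", "IkBan_NFkBn", "IkBat",
    "P_mRNA", "P",
)

NFKB_INDEX: dict[str, int] = {name: i for i, name in enumerate(NFKB_SPECIES)}

#: The module's 30 parameters: 25 per-second rate constants (converted to
#: per-hour at load), the volume ratio kv, the resting IKKn pool knn, and the
#: three repurposed P-gene constants (already per hour).
NFKB_PARAM_NAMES: tuple[str, ...] = (
    "kv", "knn", "kprod", "kdeg", "k1", "k2", "k3",
    "a1", "a2", "a3", "t1", "t2",
    "c1", "c2", "c3", "c4", "c5",
    "c1a", "c2a", "c3a", "c4a", "c5a", "c6a",
    "i1", "i1a", "e1a", "e2a",
    "c1p", "c2p", "c3p",
)


def _load_constants() -> dict:
    with resources.files("hepapop.data").joinpath("nfkb_parameters.json").open() as fh:
        return json.load(fh)


@lru_cache(maxsize=1)
def nfkb_parameter_values() -> dict[str, float]:
    """The 30 module parameters in working units (hours, micromolar)."""
    raw = _load_constants()
    vals: dict[str, float] = {}
    vals["kv"] = raw["volume_ratio"]["kv"]
    vals["knn"] = raw["resting_pools_uM"]["knn"]
    for name, v in raw["rates_per_second"].items():
        vals[name] = v * 3600.0
    vals.update(raw["p_gene_rates_per_hour"])
    assert tuple(sorted(vals)) == tuple(sorted(NFKB_PARAM_NAMES))
    return vals


def nfkb_rhs(
    t: float,
    nstate: np.ndarray,
    nparams,
    TR: float,
    ActD: bool = False,
    CHX: bool = False,
    nfkbn_ref: float = 0.0,
) -> np.ndarray:
    """Derivatives of the 16 NF-kB-module species.

    ``TR`` is the Boolean TNF-receptor input; with ``ActD`` every transcript
    synthesis term (A20t, IkBat, P_mRNA) is zero.  ``CHX`` blocks the
    translation of P (cycloheximide inhibits protein synthesis; without this
    the scavenger would still be made from pre-existing transcript).
    ``nfkbn_ref`` is the resting free nuclear NF-kB level: only the excess
    over it induces P_mRNA, because the model tracks only the P additionally
    induced by TNF (and it makes the unstimulated state a true fixed point).

    ``nparams`` may be a mapping or a :class:`~hepapop.model_core.ParameterSet`
    carrying the module's names; ``k_transl_P`` is read from the same
    namespace.
    """
    y = np.asarray(nstate, dtype=float)
    if y.min() < -1e-9:
        bad = NFKB_SPECIES[int(np.argmin(y))]
        raise ValueError(f"negative NF-kB-module state entry for {bad!r}: {y.min()}")

    k = nparams.__getitem__
    (ikkn, ikka, ikki, ikka_ikba, ikka_ikba_nfkb,
     nfkb, nfkbn, a20, a20t, ikba, ikban, ikba_nfkb, ikban_nfkbn,
     ikbat, p_mrna, p_prot) = y

    kv = k("kv")
    tr = 1.0 if TR else 0.0
    g = 0.0 if ActD else 1.0       # transcription gate
    gt = 0.0 if CHX else 1.0       # translation gate for P

    d = np.zeros_like(y)

    v_a2 = k("a2") * ikka * ikba
    v_a3 = k("a3") * ikka * ikba_nfkb
    v_t1 = k("t1") * ikka_ikba
    v_t2 = k("t2") * ikka_ikba_nfkb
    v_a1c = k("a1") * ikba * nfkb
    v_a1n = k("a1") * ikban * nfkbn

    d[0] = k("kprod") - k("kdeg") * ikkn - tr * k("k1") * ikkn                    # IKKn
    d[1] = (tr * k("k1") * ikkn - k("k3") * ikka - tr * k("k2") * ikka * a20
            - k("kdeg") * ikka - v_a2 + v_t1 - v_a3 + v_t2)                       # IKKa
    d[2] = k("k3") * ikka + tr * k("k2") * ikka * a20 - k("kdeg") * ikki          # IKKi
    d[3] = v_a2 - v_t1                                                            # IKKa.IkBa
    d[4] = v_a3 - v_t2                                                            # IKKa.IkBa.NFkB
    d[5] = k("c6a") * ikba_nfkb - v_a1c + v_t2 - k("i1") * nfkb                   # NFkB
    d[6] = k("i1") * kv * nfkb - v_a1n                                            # NFkBn
    d[7] = k("c4") * a20t - k("c5") * a20                                         # A20
    d[8] = g * (k("c2") + k("c1") * nfkbn) - k("c3") * a20t                       # A20t
    d[9] = (-v_a2 - v_a1c + k("c4a") * ikbat - k("c5a") * ikba
            - k("i1a") * ikba + k("e1a") * ikban)                                 # IkBa
    d[10] = -v_a1n + k("i1a") * kv * ikba - k("e1a") * kv * ikban                 # IkBan
    d[11] = v_a1c - k("c6a") * ikba_nfkb - v_a3 + k("e2a") * ikban_nfkbn          # IkBa.NFkB
    d[12] = v_a1n - k("e2a") * kv * ikban_nfkbn                                   # IkBan.NFkBn
    d[13] = g * (k("c2a") + k("c1a") * nfkbn) - k("c3a") * ikbat                  # IkBat
    d[14] = g * (k("c2p") + k("c1p") * max(nfkbn - nfkbn_ref, 0.0)) \
        - k("c3p") * p_mrna                                                       # P_mRNA
    try:
        ktp = k("k_transl_P")
    except KeyError:  # standalone module use without the Table-1 bridge rate
        ktp = 25.0
    d[15] = gt * ktp * p_mrna                                                     # P
    return d


def nfkb_total(nstate: np.ndarray, kv: float) -> float:
    """Conserved total NF-kB (cytoplasmic basis; nuclear amounts / kv)."""
    y = np.asarray(nstate, dtype=float)
    i = NFKB_INDEX
    return (
        y[i["NFkB"]] + y[i["IkBa_NFkB"]] + y[i["IKKa_IkBa_NFkB"]]
        + (y[i["NFkBn"]] + y[i["IkBan_NFkBn"]]) / kv
    )


@lru_cache(maxsize=8)
def _resting_state_cached(param_items: tuple) -> tuple[np.ndarray, float]:
    nparams = dict(param_items)
    y0 = np.zeros(len(NFKB_SPECIES))
    i = NFKB_INDEX
    raw = _load_constants()
    y0[i["IKKn"]] = raw["resting_pools_uM"]["knn"]
    y0[i["IkBa_NFkB"]] = raw["resting_pools_uM"]["nfkb_total"]
    y0[i["IkBa"]] = 0.002

    def rhs(t, y):
        # resting solve: the P gene is silent by definition of the reference
        return nfkb_rhs(t, np.maximum(y, 0.0), nparams, TR=0, nfkbn_ref=np.inf)

    y = y0
    for span in (500.0, 1500.0, 4000.0):
        sol = solve_ivp(rhs, (0.0, span), y, method="LSODA",
                        rtol=1e-10, atol=1e-14)
        if not sol.success:
            raise RuntimeError(f"NF-kB resting-state integration failed: {sol.message}")
        y = np.maximum(sol.y[:, -1], 0.0)
        if np.max(np.abs(rhs(0.0, y))) < 1e-10:
            break
    resid = np.max(np.abs(rhs(0.0, y)))
    if resid >= 1e-8:
        raise RuntimeError(
            f"NF-kB module did not reach a resting steady state (|dy/dt| = {resid:.2e})"
        )
    return y, float(y[i["NFkBn"]])


def _module_items(nparams) -> tuple:
    vals = nparams.as_dict() if hasattr(nparams, "as_dict") else dict(nparams)
    return tuple((n, vals[n]) for n in NFKB_PARAM_NAMES if n in vals)


def compute_resting_steady_state(nparams) -> np.ndarray:
    """Resting (TR=0) steady state, obtained by long unstimulated integration.

    Returns the 16-vector with P_mRNA = P = 0; the derivative norm under
    TR=0 is below 1e-8.
    """
    y, _ = _resting_state_cached(_module_items(nparams))
    return y.copy()


def resting_nfkbn(nparams) -> float:
    """Free nuclear NF-kB at rest (the P-gene induction reference)."""
    _, ref = _resting_state_cached(_module_items(nparams))
    return ref
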