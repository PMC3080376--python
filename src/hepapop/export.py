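"""JSON export of the species and parameter registries."""

from __future__ import annotations

import json

from .model_core import (
    _CORE_INITIAL,
    _EXTENSION_PARAMS,
    _SENSITIZING_PARAMS,
    CORE_SPECIES,
    ParameterSet,
    build_default_parameters,
)
from .nfkb_module import NFKB_PARAM_NAMES, NFKB_SPECIES

__all__ = ["species_registry", "parameter_registry", "export_registries"]


def species_registry() -> list[dict]:
    """All 53 species with module, unit and resting amount."""
    out = []
    for name in CORE_SPECIES:
        out.append({
            "name": name,
            "module": "core",
            "unit": "AU (%)",
            "initial": _CORE_INITIAL.get(name, 0.0),
        })
    for name in NFKB_SPECIES:
        out.append({
            "name": name,
            "module": "nfkb",
            "unit": "uM" if name != "P" else "AU (%)",
            "initial": "resting steady state",
        })
    return out


def parameter_registry(params: ParameterSet | None = None) -> list[dict]:
    """All 74 rate parameters with value, unit and owning block."""
    if params is None:
        params = build_default_parameters()
    blocks = (
        [(n, "extension") for n in _EXTENSION_PARAMS]
        + [(n, "nfkb") for n in NFKB_PARAM_NAMES]
        + [(n, "sensitizing_core") for n in _SENSITIZING_PARAMS]
    )
    out = []
    for name, block in blocks:
        out.append({
            "name": name,
            "block": block,
            "value": params[name],
            "unit": "per hour (AU/uM basis as applicable)" if name != "kv" else "dimensionless",
        })
    for name, v in params.structural.items():
        out.append({"name": name, "block": "structural", "value": v,
                    "unit": "h / AU / fraction"})
    return out


def export_registries(path_species, path_params, params: ParameterSet | None = None) -> None:
    with open(path_species, "w") as fh:
        json.dump(species_registry(), fh, indent=1)
    with open(path_params, "w") as fh:
        json.dump(parameter_registry(params), fh, indent=1)
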