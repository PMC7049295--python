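"""Packaged default parameters and the YAML override mechanism."""

from __future__ import annotations

from importlib import resources

import yaml

from .qs_dynamics import QSParams
from .run_tumble import ChemotaxisParams

__all__ = ["load_default_params", "load_params"]


def _read_packaged() -> dict:
    with resources.files("swarmqs.data").joinpath("default_params.yaml").open() as fh:
        return yaml.safe_load(fh)


def _build(raw: dict) -> tuple[ChemotaxisParams, QSParams]:
    chemo = ChemotaxisParams(**raw.get("chemotaxis", {}))
    qs_raw = dict(raw.get("qs", {}))
    if "Rd_per_hour" in qs_raw:
        qs_raw["Rd"] = qs_raw.pop("Rd_per_hour") / 3600.0
    qs = QSParams(**qs_raw)
    return chemo, qs


def load_default_params() -> tuple[ChemotaxisParams, QSParams]:
    """The packaged chemotaxis and QS parameter bundles."""
    return _build(_read_packaged())


def load_params(path) -> tuple[ChemotaxisParams, QSParams]:
    """Packaged defaults with per-scenario overrides from a YAML file.

    The file may contain ``chemotaxis:`` and/or ``qs:`` sections; unlisted
    fields keep their packaged values.
    """
    base = _read_packaged()
    with open(path) as fh:
        override = yaml.safe_load(fh) or {}
    for section in ("chemotaxis", "qs"):
        if section in override:
            base.setdefault(section, {}).update(override[section])
    return _build(base)
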