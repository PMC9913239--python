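"""Bundled registry of published cell-line coefficients.

Ships reference Arrhenius, shoulder-delay and R_CEM values for three
murine cell lines (KPC and Pan02 pancreatic cancer, STO fibroblasts) so
that forward predictions and synthetic-data generation work out of the
box. Values were derived from 24 h post-heating viability measurements.
"""

from __future__ import annotations

from importlib import resources
from typing import Mapping

import yaml

from .errors import InvalidArgumentError
from .injury_models import ArrheniusParams, DelayParams

_CACHE: dict | None = None


def load_registry() -> dict:
    """Raw registry mapping (parsed once, cached)."""
    global _CACHE
    if _CACHE is None:
        text = resources.files("thermokin.data").joinpath("cell_lines.yaml").read_text()
        _CACHE = yaml.safe_load(text)
    return _CACHE


def available_cell_lines() -> list[str]:
    return sorted(load_registry()["cell_lines"])


def cell_line_params(name: str) -> tuple[ArrheniusParams, DelayParams]:
    """Arrhenius and delay coefficients for a registered cell line."""
    reg = load_registry()
    try:
        block = reg["cell_lines"][name]
    except KeyError:
        raise InvalidArgumentError(
            f"unknown cell line {name!r}; available: {available_cell_lines()}") from None
    arr = ArrheniusParams(block["ln_frequency_factor"], block["activation_energy"],
                          reg.get("gas_constant", 8.314))
    delay = DelayParams(block["delay_slope_m"], block["delay_intercept_b"])
    return arr, delay


def reference_r_cem(name: str) -> float:
    """Published fitted R_CEM (above the 43 degC break) for a cell line."""
    reg = load_registry()
    try:
        return float(reg["cell_lines"][name]["r_cem"])
    except KeyError:
        raise InvalidArgumentError(
            f"unknown cell line {name!r}; available: {available_cell_lines()}") from None


def default_truth() -> Mapping[str, tuple[ArrheniusParams, DelayParams]]:
    """Registry as a truth mapping for the synthetic-data generator."""
    return {name: cell_line_params(name) for name in available_cell_lines()}
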