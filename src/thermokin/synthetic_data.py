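"""Synthetic viability datasets emulating water-bath hyperthermia assays.

The generator reproduces the statistical structure of a plate-based
thermal-injury experiment: monolayer cultures in n = 6 wells of a 96-well
plate are held at a setpoint in the 42.5-50 degC range for 3-60 minutes,
allowed to recover for 6 or 24 h, and read out with a colorimetric
viability assay normalized to unheated 37 degC control plates.

Noise model (all multiplicative, all driven by one seed):

* *temperature jitter* — the realized bath temperature differs from the
  setpoint by a normal offset drawn once per plate, shared by its wells,
  emulating the degree-tenths accuracy of thermocouple-monitored baths;
* *control normalization error* — a lognormal factor shared by all wells
  of a plate, from the division by the control plate's optical density;
* *well noise* — an independent lognormal factor per well, from assay
  chemistry and pipetting. Lognormal factors have unit mean so that well
  averages converge to the noiseless survival.

True survival follows the delayed Arrhenius law
S = exp(-k(T') * max(0, t - t_d(T'))); the 6 h readout applies a scalar
multiplier (< 1) on the log-kill to emulate death that has not yet fully
manifested, a phenomenological stand-in documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidArgumentError
from .injury_models import (
    ArrheniusParams,
    DelayParams,
    TwoStateParams,
    rate_constant,
    time_delay,
    two_state_survival,
)
from .profiles import (
    BODY_TEMPERATURE_K,
    CELSIUS_OFFSET,
    TemperatureProfile,
    _time_grid,
)

#: Default exposure design: bath setpoints (degC) and durations (minutes).
DEFAULT_SETPOINTS_C = (42.5, 44.0, 46.0, 50.0)
DEFAULT_DURATIONS_MIN = (3.0, 5.0, 10.0, 15.0, 20.0, 30.0, 45.0, 60.0)
DEFAULT_N_WELLS = 6

#: Multiplier on log-kill at each recovery time; injury is fully expressed
#: by 24 h and only partially at 6 h.
DEFAULT_RECOVERY_SCALE = {6.0: 0.7, 24.0: 1.0}


@dataclass(frozen=True)
class NoiseSpec:
    """Noise magnitudes for the plate assay emulation (see module docstring)."""

    well_cv: float = 0.05
    control_cv: float = 0.02
    temperature_jitter_sd: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if min(self.well_cv, self.control_cv, self.temperature_jitter_sd) < 0:
            raise InvalidArgumentError("noise magnitudes must be >= 0")


NOISELESS = NoiseSpec(0.0, 0.0, 0.0)


class ViabilityDataset:
    """Normalized survival observations by condition and replicate well.

    Thin wrapper over a :class:`pandas.DataFrame` with one row per plate
    condition: ``cell_line``, ``setpoint_K``, ``duration_s``,
    ``recovery_h``, ``well_1 .. well_n`` (survival fractions) and
    ``mean_survival``. Internal units are kelvin and seconds; the CSV
    boundary uses degC and minutes.
    """

    def __init__(self, df: pd.DataFrame):
        if not len(df):
            raise InvalidArgumentError("empty viability dataset")
        self._df = df.reset_index(drop=True)
        wells = self.well_columns
        if not wells:
            raise InvalidArgumentError("dataset has no well columns")
        means = self._df[wells].mean(axis=1)
        if not np.allclose(self._df["mean_survival"], means, rtol=1e-9, atol=1e-12):
            raise InvalidArgumentError("mean_survival inconsistent with well values")
        if (self._df[wells] < 0).any().any():
            raise InvalidArgumentError("well survival values must be >= 0")

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def well_columns(self) -> list[str]:
        return [c for c in self._df.columns if c.startswith("well_")]

    @property
    def n_wells(self) -> int:
        return len(self.well_columns)

    @property
    def cell_lines(self) -> list[str]:
        return sorted(self._df["cell_line"].unique())

    def filter(self, cell_line: str | None = None,
               recovery_h: float | None = None) -> "ViabilityDataset":
        df = self._df
        if cell_line is not None:
            df = df[df["cell_line"] == cell_line]
        if recovery_h is not None:
            df = df[df["recovery_h"] == recovery_h]
        return ViabilityDataset(df)

    def conditions(self) -> pd.DataFrame:
        """(cell_line, setpoint_K, duration_s, recovery_h, mean_survival) view."""
        return self._df[["cell_line", "setpoint_K", "duration_s",
                         "recovery_h", "mean_survival"]].copy()

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other) -> bool:
        return isinstance(other, ViabilityDataset) and self._df.equals(other._df)

    # -- I/O ---------------------------------------------------------------

    def write_csv(self, path) -> None:
        out = self._df.copy()
        out.insert(1, "setpoint_C", out.pop("setpoint_K") - CELSIUS_OFFSET)
        out.insert(2, "duration_min", out.pop("duration_s") / 60.0)
        out.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def read_csv(cls, path) -> "ViabilityDataset":
        df = pd.read_csv(path, float_precision="round_trip")
        required = {"cell_line", "setpoint_C", "duration_min", "recovery_h",
                    "mean_survival"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"viability CSV missing columns {sorted(missing)}", line=1)
        df.insert(1, "setpoint_K", df.pop("setpoint_C") + CELSIUS_OFFSET)
        df.insert(2, "duration_s", df.pop("duration_min") * 60.0)
        return cls(df)


def _unit_mean_lognormal(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Lognormal factors with mean exactly 1 and coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv ** 2))
    return rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=size)


def _assemble(rows: list[dict], n_wells: int) -> ViabilityDataset:
    df = pd.DataFrame(rows)
    well_cols = [f"well_{i + 1}" for i in range(n_wells)]
    df["mean_survival"] = df[well_cols].mean(axis=1)
    return ViabilityDataset(df)


def generate_viability_dataset(
        truth: Mapping[str, tuple[ArrheniusParams, DelayParams]],
        setpoints: Sequence[float] | None = None,
        durations: Sequence[float] | None = None,
        recovery_scale: Mapping[float, float] | None = None,
        noise: NoiseSpec = NoiseSpec(),
        n_wells: int = DEFAULT_N_WELLS) -> ViabilityDataset:
    """Simulate the full plate experiment for every cell line in ``truth``.

    ``setpoints`` are kelvin and ``durations`` seconds; the defaults are
    the standard design (42.5/44/46/50 degC for 3-60 min). One plate is
    simulated per (cell line, setpoint, duration, recovery) combination.
    Deterministic for a fixed ``noise.seed``.
    """
    if setpoints is None:
        setpoints = [c + CELSIUS_OFFSET for c in DEFAULT_SETPOINTS_C]
    if durations is None:
        durations = [m * 60.0 for m in DEFAULT_DURATIONS_MIN]
    if recovery_scale is None:
        recovery_scale = dict(DEFAULT_RECOVERY_SCALE)
    if not truth or not len(setpoints) or not len(durations) or not recovery_scale:
        raise InvalidArgumentError("truth, setpoints, durations and recovery_scale must be non-empty")
    rng = np.random.default_rng(noise.seed)
    rows = []
    for cell_line in truth:
        arr, delay = truth[cell_line]
        for setpoint in setpoints:
            for duration in durations:
                for recovery_h, scale in sorted(recovery_scale.items()):
                    temp = setpoint + rng.normal(0.0, noise.temperature_jitter_sd)
                    effective = max(0.0, duration - time_delay(delay, temp))
                    s_true = np.exp(-scale * rate_constant(arr, temp) * effective)
                    control = _unit_mean_lognormal(rng, noise.control_cv, 1)[0]
                    wells = s_true * control * _unit_mean_lognormal(rng, noise.well_cv, n_wells)
                    row = {"cell_line": cell_line, "setpoint_K": float(setpoint),
                           "duration_s": float(duration), "recovery_h": float(recovery_h)}
                    row.update({f"well_{i + 1}": wells[i] for i in range(n_wells)})
                    rows.append(row)
    return _assemble(rows, n_wells)


def generate_two_state_dataset(
        truth: TwoStateParams,
        setpoints: Sequence[float] | None = None,
        durations: Sequence[float] | None = None,
        noise: NoiseSpec = NoiseSpec(),
        n_wells: int = DEFAULT_N_WELLS,
        cell_line: str = "synthetic",
        recovery_h: float = 24.0) -> ViabilityDataset:
    """Simulate plates whose true survival follows the two-state logistic law."""
    if setpoints is None:
        setpoints = [c + CELSIUS_OFFSET for c in DEFAULT_SETPOINTS_C]
    if durations is None:
        durations = [m * 60.0 for m in DEFAULT_DURATIONS_MIN]
    rng = np.random.default_rng(noise.seed)
    rows = []
    for setpoint in setpoints:
        for duration in durations:
            temp = setpoint + rng.normal(0.0, noise.temperature_jitter_sd)
            s_true = two_state_survival(duration, temp, truth)
            control = _unit_mean_lognormal(rng, noise.control_cv, 1)[0]
            wells = s_true * control * _unit_mean_lognormal(rng, noise.well_cv, n_wells)
            row = {"cell_line": cell_line, "setpoint_K": float(setpoint),
                   "duration_s": float(duration), "recovery_h": float(recovery_h)}
            row.update({f"well_{i + 1}": wells[i] for i in range(n_wells)})
            rows.append(row)
    return _assemble(rows, n_wells)


def generate_ablation_periphery_profile(
        peak: float, rise_constant: float = 120.0, duration: float = 600.0,
        step: float = 1.0,
        baseline: float = BODY_TEMPERATURE_K) -> TemperatureProfile:
    """Non-isothermal heating typical of the periphery of a thermal-ablation
    zone: a saturating-exponential approach from 37 degC toward ``peak``
    (K) over ``duration`` seconds (default 10 min)."""
    if peak <= baseline:
        raise InvalidArgumentError("peak must exceed the 37 degC baseline")
    if rise_constant <= 0 or duration <= 0 or step <= 0:
        raise InvalidArgumentError("rise_constant, duration and step must be > 0")
    times = _time_grid(duration, step)
    temps = baseline + (peak - baseline) * (1.0 - np.exp(-times / rise_constant))
    return TemperatureProfile(times, temps,
                              label=f"ablation periphery peak {peak - CELSIUS_OFFSET:.1f} degC")
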