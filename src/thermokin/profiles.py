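"""Time-temperature profiles.

A :class:`TemperatureProfile` is the domain of every forward injury model in
this package: a finite sequence of (time, temperature) samples starting at
t = 0 with strictly increasing times. Temperatures are held in kelvin
internally; degrees Celsius appear only at file and CLI boundaries, because
the rate laws all use absolute temperature.

Besides plain construction and CSV I/O, this module builds synthetic
water-bath transients (linear ramp, constant hold, exponential cool-down)
of the kind produced when a sealed multi-well plate is immersed in a
temperature-controlled bath.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidArgumentError

CELSIUS_OFFSET = 273.15

#: Physiological baseline, 37 degC in kelvin.
BODY_TEMPERATURE_K = 310.15


def celsius_to_kelvin(temp_c):
    return np.asarray(temp_c, dtype=float) + CELSIUS_OFFSET


def kelvin_to_celsius(temp_k):
    return np.asarray(temp_k, dtype=float) - CELSIUS_OFFSET


@dataclass(frozen=True)
class TemperatureProfile:
    """Sampled time-temperature trajectory T(t).

    Parameters
    ----------
    times
        Sample times in seconds, strictly increasing, first sample at 0.
    temperatures
        One absolute temperature (kelvin) per sample; finite and positive.
    label
        Free-text description, carried through to outputs.
    """

    times: np.ndarray
    temperatures: np.ndarray
    label: str = ""

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        temps = np.asarray(self.temperatures, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "temperatures", temps)
        if times.ndim != 1 or temps.ndim != 1 or times.shape != temps.shape:
            raise InvalidArgumentError("times and temperatures must be 1-D arrays of equal length")
        if times.size < 2:
            raise InvalidArgumentError("a profile needs at least 2 samples")
        if times[0] != 0.0:
            raise InvalidArgumentError("profile must start at t = 0")
        if not np.all(np.diff(times) > 0):
            raise InvalidArgumentError("times must be strictly increasing")
        if not np.all(np.isfinite(temps)) or not np.all(temps > 0):
            raise InvalidArgumentError("temperatures must be finite and > 0 K")

    @property
    def duration(self) -> float:
        """Total span in seconds."""
        return float(self.times[-1])

    @property
    def temperatures_celsius(self) -> np.ndarray:
        return kelvin_to_celsius(self.temperatures)

    def temperature_at(self, t) -> np.ndarray:
        """Linear interpolation of T at arbitrary times within the span."""
        return np.interp(np.asarray(t, dtype=float), self.times, self.temperatures)

    def mean_temperature(self) -> float:
        """Duration-weighted mean temperature (trapezoidal) in kelvin."""
        return float(np.trapezoid(self.temperatures, self.times) / self.duration)


@dataclass(frozen=True)
class TransientSpec:
    """Parameters of a synthetic water-bath exposure.

    The heating protocol is idealized as three phases: a linear ramp from
    ``baseline_temperature`` to ``target_temperature`` over ``ramp_time``,
    a constant hold of ``hold_time``, and an exponential relaxation back
    toward baseline with time constant ``cooldown_time / 3`` (so the
    profile is within 5% of baseline when the cool-down phase ends).
    """

    target_temperature: float
    ramp_time: float
    hold_time: float
    cooldown_time: float
    sampling_step: float = 1.0
    baseline_temperature: float = BODY_TEMPERATURE_K
    label: str = field(default="")

    def __post_init__(self):
        if min(self.ramp_time, self.hold_time, self.cooldown_time) < 0:
            raise InvalidArgumentError("phase durations must be >= 0")
        if self.sampling_step <= 0:
            raise InvalidArgumentError("sampling_step must be > 0")
        if self.target_temperature <= 0 or self.baseline_temperature <= 0:
            raise InvalidArgumentError("temperatures must be > 0 K")


def _time_grid(duration: float, step: float) -> np.ndarray:
    """Uniform grid from 0 with the exact endpoint appended when duration
    is not an integer multiple of step, so integrals cover the full span."""
    n = int(np.floor(duration / step + 1e-9))
    times = np.arange(n + 1, dtype=float) * step
    if times[-1] < duration * (1 - 1e-12):
        times = np.append(times, duration)
    else:
        times[-1] = min(times[-1], duration)
    return times


def make_constant_profile(temperature: float, duration: float, step: float,
                          label: str = "") -> TemperatureProfile:
    """Isothermal exposure at ``temperature`` (K) for ``duration`` seconds."""
    if duration <= 0 or step <= 0:
        raise InvalidArgumentError("duration and step must be > 0")
    times = _time_grid(duration, step)
    return TemperatureProfile(times, np.full_like(times, float(temperature)),
                              label=label or f"constant {temperature:.2f} K")


def make_transient_profile(spec: TransientSpec) -> TemperatureProfile:
    """Piecewise ramp/hold/cool-down profile described by ``spec``.

    The hold phase sits exactly at the target temperature; measurement
    noise belongs to the synthetic-data layer, not here.
    """
    total = spec.ramp_time + spec.hold_time + spec.cooldown_time
    if total <= 0:
        raise InvalidArgumentError("transient spec has zero total duration")
    times = _time_grid(total, spec.sampling_step)
    base, target = spec.baseline_temperature, spec.target_temperature
    temps = np.full_like(times, target)
    if spec.ramp_time > 0:
        in_ramp = times < spec.ramp_time
        temps[in_ramp] = base + (target - base) * times[in_ramp] / spec.ramp_time
    if spec.cooldown_time > 0:
        t_cool = spec.ramp_time + spec.hold_time
        in_cool = times > t_cool
        tau = spec.cooldown_time / 3.0
        temps[in_cool] = base + (target - base) * np.exp(-(times[in_cool] - t_cool) / tau)
    label = spec.label or (
        f"bath {kelvin_to_celsius(target):.1f} degC "
        f"(ramp {spec.ramp_time:g}s, hold {spec.hold_time:g}s, cool {spec.cooldown_time:g}s)")
    return TemperatureProfile(times, temps, label=label)


def resample_profile(profile: TemperatureProfile, step: float) -> TemperatureProfile:
    """Linear interpolation onto a uniform grid spanning the original profile."""
    if step <= 0:
        raise InvalidArgumentError("step must be > 0")
    times = _time_grid(profile.duration, step)
    return TemperatureProfile(times, profile.temperature_at(times), label=profile.label)


def concatenate_profiles(first: TemperatureProfile,
                         second: TemperatureProfile) -> TemperatureProfile:
    """Append ``second`` after ``first``, shifting its clock to start where
    ``first`` ends. The first sample of ``second`` lands exactly on the end
    time of ``first`` so no artificial interval is created at the seam.

    Damage and dose integrals are additive over the pieces exactly when
    the seam is continuous (``second`` starts at the temperature where
    ``first`` ends); a genuine step discontinuity cannot be represented
    in a single sampled series and the seam interval then blends the two
    temperatures."""
    shifted = second.times + first.duration
    times = np.concatenate([first.times, shifted])
    temps = np.concatenate([first.temperatures, second.temperatures])
    # seam duplicate: keep the later sample's temperature
    if shifted[0] == first.duration:
        keep = np.ones(times.size, dtype=bool)
        keep[first.times.size - 1] = False
        times, temps = times[keep], temps[keep]
    return TemperatureProfile(times, temps,
                              label=f"{first.label} + {second.label}".strip(" +"))


_HEADERS = {"temp_K": 0.0, "temp_C": CELSIUS_OFFSET}


def read_profile(path) -> TemperatureProfile:
    """Read a profile CSV with header ``time_s,temp_C`` or ``time_s,temp_K``.

    The temperature unit is taken from the header; Celsius values are
    converted to kelvin on read.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - normalize to format error
        raise FormatError(f"cannot parse profile CSV {path!s}: {exc}") from exc
    cols = list(df.columns)
    if len(cols) != 2 or cols[0] != "time_s" or cols[1] not in _HEADERS:
        raise FormatError(
            f"expected header 'time_s,temp_C' or 'time_s,temp_K', got {','.join(map(str, cols))}",
            line=1)
    times = df["time_s"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(times) <= 0)
    if bad.size:
        raise FormatError("times are not strictly increasing", line=int(bad[0]) + 3)
    temps = df[cols[1]].to_numpy(dtype=float) + _HEADERS[cols[1]]
    return TemperatureProfile(times, temps, label=str(path))


def write_profile(profile: TemperatureProfile, path, unit: str = "K") -> None:
    """Write a profile CSV; ``unit`` selects the temp_K or temp_C column.

    Values are written with enough digits that write/read round-trips to
    well under 1e-6.
    """
    if unit not in ("K", "C"):
        raise InvalidArgumentError("unit must be 'K' or 'C'")
    temps = profile.temperatures if unit == "K" else profile.temperatures_celsius
    df = pd.DataFrame({"time_s": profile.times, f"temp_{unit}": temps})
    df.to_csv(path, index=False, float_format="%.9f")
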