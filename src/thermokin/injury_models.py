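"""Forward models of heat-induced cell death.

Four model families are evaluated on arbitrary time-temperature profiles:

* **Arrhenius damage integral** — cell death as a first-order reaction with
  rate k(T) = A exp(-Ea / (R T)). The damage state is
  Omega(t) = integral of k(T(tau)) dtau; the surviving fraction is
  exp(-Omega) and the injury probability is 100 (1 - exp(-Omega)).
* **Time-delayed Arrhenius** — identical kinetics, but damage accumulation
  only begins after a temperature-dependent delay t_d(T) = max(0, b - m T),
  which reproduces the "shoulder" of survival curves at mild temperatures.
* **Two-state survival** — logistic model in which the log-odds of staying
  viable is bilinear in temperature and exposure time:
  logit C = gamma T - beta - alpha tau.
* **CEM43 thermal isoeffective dose** — cumulative equivalent minutes at
  43 degC, t43 = sum_i dt_i R^(43 - T_i) with R = 0.5 above the 43 degC
  break and 0.25 at or below it.

All temperatures are kelvin and all times seconds unless a name says
otherwise; CEM43 returns minutes, as the dose is conventionally quoted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.special import expit

from .errors import InvalidArgumentError
from .profiles import CELSIUS_OFFSET, TemperatureProfile

#: Universal gas constant, J K^-1 mol^-1.
GAS_CONSTANT = 8.314


@dataclass(frozen=True)
class ArrheniusParams:
    """First-order kinetic coefficients of a cell line.

    ``ln_frequency_factor`` is ln A with A in s^-1; ``activation_energy``
    is Ea in J/mol. The gas constant is carried so that published
    parameter sets derived with a rounded constant can be reproduced
    bit-for-bit.
    """

    ln_frequency_factor: float
    activation_energy: float
    gas_constant: float = GAS_CONSTANT

    def __post_init__(self):
        if self.activation_energy <= 0:
            raise InvalidArgumentError("activation_energy must be > 0")
        if self.gas_constant <= 0:
            raise InvalidArgumentError("gas_constant must be > 0")


@dataclass(frozen=True)
class DelayParams:
    """Shoulder coefficients of the delayed model: t_d(T) = b - m T, clamped at 0."""

    slope_m: float
    intercept_b: float

    def __post_init__(self):
        if self.slope_m < 0:
            raise InvalidArgumentError("slope_m must be >= 0")


@dataclass(frozen=True)
class TwoStateParams:
    """Logistic injury coefficients: logit C = gamma*T - beta - alpha*tau."""

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self):
        for name in ("alpha", "beta", "gamma"):
            if not np.isfinite(getattr(self, name)):
                raise InvalidArgumentError(f"{name} must be finite")


@dataclass(frozen=True)
class DoseParams:
    """CEM43 per-degree isoeffect factors.

    ``r_above`` applies strictly above ``break_temperature`` (43 degC by
    default), ``r_below`` at or below it.
    """

    r_above: float = 0.5
    r_below: float = 0.25
    break_temperature: float = 316.15

    def __post_init__(self):
        if not (0 < self.r_above < 1) or not (0 < self.r_below < 1):
            raise InvalidArgumentError("isoeffect factors must lie in (0, 1)")


@dataclass(frozen=True)
class DamageResult:
    """Omega trajectory with derived survival and injury probability."""

    times: np.ndarray
    omega: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "omega", np.asarray(self.omega, dtype=float))
        if np.any(self.omega < 0) or np.any(np.diff(self.omega) < -1e-12):
            raise InvalidArgumentError("omega must be non-negative and non-decreasing")

    @property
    def survival_fraction(self) -> np.ndarray:
        return np.exp(-self.omega)

    @property
    def injury_probability_pct(self) -> np.ndarray:
        return 100.0 * (1.0 - np.exp(-self.omega))

    @property
    def final_survival(self) -> float:
        return float(np.exp(-self.omega[-1]))


def rate_constant(params: ArrheniusParams, temperature) -> np.ndarray | float:
    """Arrhenius rate k(T) = exp(ln A - Ea / (R T)) in s^-1."""
    temperature = np.asarray(temperature, dtype=float)
    if np.any(temperature <= 0):
        raise InvalidArgumentError("temperature must be > 0 K")
    k = np.exp(params.ln_frequency_factor
               - params.activation_energy / (params.gas_constant * temperature))
    return float(k) if k.ndim == 0 else k


def damage_integral(profile: TemperatureProfile,
                    params: ArrheniusParams) -> DamageResult:
    """Omega(t) = cumulative trapezoidal integral of k(T(tau)) over the profile."""
    rates = rate_constant(params, profile.temperatures)
    omega = cumulative_trapezoid(rates, profile.times, initial=0.0)
    return DamageResult(profile.times, omega)


def time_delay(delay: DelayParams, temperature) -> np.ndarray | float:
    """Shoulder duration t_d(T) = max(0, b - m T) in seconds.

    Negative raw values (hot enough that the shoulder vanishes) are
    clamped to zero: the delayed model only distinguishes before/after.
    """
    temperature = np.asarray(temperature, dtype=float)
    if np.any(temperature <= 0):
        raise InvalidArgumentError("temperature must be > 0 K")
    td = np.maximum(0.0, delay.intercept_b - delay.slope_m * temperature)
    return float(td) if td.ndim == 0 else td


def _delay_completion_time(profile: TemperatureProfile,
                           delay: DelayParams) -> float | None:
    """Time at which the shoulder is exhausted on a (possibly non-isothermal)
    profile, or None if it never is.

    The delay is tracked with a normalized accumulator
    xi(t) = integral of dtau / t_d(T(tau)); damage begins once xi >= 1.
    At constant temperature this reduces exactly to waiting t_d(T).
    An instant with t_d = 0 completes the delay immediately.
    """
    td = time_delay(delay, profile.temperatures)
    times = profile.times
    zero = np.flatnonzero(td == 0.0)
    t_zero = times[zero[0]] if zero.size else np.inf
    if t_zero == times[0]:
        return float(times[0])
    inv = np.where(td > 0, 1.0 / np.where(td > 0, td, 1.0), np.nan)
    xi = 0.0
    for i in range(times.size - 1):
        dt = times[i + 1] - times[i]
        if np.isnan(inv[i]) or np.isnan(inv[i + 1]):
            # delay hits zero at the right end of this interval
            return float(min(times[i + 1], t_zero))
        dxi = dt * 0.5 * (inv[i] + inv[i + 1])
        if xi + dxi >= 1.0:
            # linear crossing inside the interval
            return float(times[i] + (1.0 - xi) * dt / dxi)
        xi += dxi
    return None


def damage_integral_delayed(profile: TemperatureProfile,
                            params: ArrheniusParams,
                            delay: DelayParams) -> DamageResult:
    """Delayed Arrhenius damage: Omega stays 0 until the shoulder is spent,
    then accumulates with the ordinary rate law from that point forward.

    For a constant-temperature profile this yields
    Omega(t) = k(T) * max(0, t - t_d(T)) at every sample.
    """
    t_start = _delay_completion_time(profile, delay)
    times = profile.times
    omega = np.zeros_like(times)
    if t_start is None:
        return DamageResult(times, omega)
    rates = np.asarray(rate_constant(params, profile.temperatures))
    after = times > t_start
    if not np.any(after):
        return DamageResult(times, omega)
    first = int(np.argmax(after))
    k_start = float(np.interp(t_start, times, rates))
    partial = 0.5 * (k_start + rates[first]) * (times[first] - t_start)
    tail = cumulative_trapezoid(rates[first:], times[first:], initial=0.0)
    omega[first:] = partial + tail
    return DamageResult(times, omega)


def two_state_survival(exposure_time, temperature, params: TwoStateParams):
    """Viable fraction C(tau, T) = logistic(gamma T - beta - alpha tau)."""
    tau = np.asarray(exposure_time, dtype=float)
    if np.any(tau < 0):
        raise InvalidArgumentError("exposure_time must be >= 0")
    arg = params.gamma * np.asarray(temperature, dtype=float) - params.beta - params.alpha * tau
    out = expit(arg)
    return float(out) if np.ndim(out) == 0 else out


def cem43(profile: TemperatureProfile, dose: DoseParams = DoseParams()) -> float:
    """Cumulative equivalent minutes at 43 degC for an arbitrary profile.

    Each sampling interval contributes dt_min * R^(43 - T_mid) where T_mid
    is the interval's midpoint temperature in degC and R switches at the
    break temperature (strictly above -> ``r_above``).
    """
    dt_min = np.diff(profile.times) / 60.0
    t_mid = 0.5 * (profile.temperatures[:-1] + profile.temperatures[1:])
    r = np.where(t_mid > dose.break_temperature, dose.r_above, dose.r_below)
    exponent = 43.0 - (t_mid - CELSIUS_OFFSET)
    return float(np.sum(dt_min * r ** exponent))
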