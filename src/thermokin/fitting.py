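"""Inverse procedures: estimate kinetic coefficients from viability data.

The estimation cascade mirrors how isothermal water-bath experiments are
analyzed in practice:

1. per temperature, fit log-linear decay S = exp(-k (t - t_d)) to the
   surviving fraction versus exposure time (:func:`fit_decay_rate`),
   either forced through S(0) = 1 or with a free intercept whose positive
   x-intercept is read as the shoulder duration t_d;
2. regress ln k on 1/T to obtain the activation energy and frequency
   factor (:func:`fit_arrhenius`);
3. regress the shoulder durations on T to obtain the delay line
   t_d = b - m T (:func:`fit_time_delay`);
4. regress logit survival on (T, tau) for the two-state model
   (:func:`fit_two_state`);
5. regress log isoeffect time on temperature to obtain the per-degree
   dose factor R_CEM (:func:`fit_rcem`).

Every fit here is linear after a transform, so ordinary least squares is
used throughout; there is no iterative optimisation to tune.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateFitError, FitWarning, InvalidArgumentError
from .injury_models import (
    GAS_CONSTANT,
    ArrheniusParams,
    DelayParams,
    TwoStateParams,
    rate_constant,
    time_delay,
    two_state_survival,
)
from .profiles import CELSIUS_OFFSET

#: Survival fractions are clipped to [CLIP_EPS, 1.5] before log fits and to
#: [CLIP_EPS, 1 - CLIP_EPS] before logit fits. Control-normalized viability
#: can legitimately exceed 1; dropping such wells would bias early times.
CLIP_EPS = 1e-4
CLIP_HIGH = 1.5


@dataclass(frozen=True)
class DecayRateEstimate:
    """Per-temperature exponential decay fit."""

    temperature: float          # kelvin
    rate_k: float               # s^-1
    shoulder_td: float          # seconds, 0 when absent or clamped
    r_squared: float
    n_points: int

    def __post_init__(self):
        if self.rate_k <= 0:
            raise InvalidArgumentError("rate_k must be > 0")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise InvalidArgumentError("r_squared must lie in [0, 1]")


@dataclass
class FitReport:
    """Goodness-of-fit summary for one fitted model."""

    model_name: str
    params: object
    r_squared: float
    rmse_pct: float
    residuals: pd.DataFrame = field(default_factory=pd.DataFrame)
    rmse_by_cell_line: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.rmse_pct < 0:
            raise InvalidArgumentError("rmse_pct must be >= 0")


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line y = slope*x + intercept; returns (slope, intercept, r2)."""
    coeffs, *_ = np.linalg.lstsq(np.column_stack([x, np.ones_like(x)]), y, rcond=None)
    slope, intercept = float(coeffs[0]), float(coeffs[1])
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - float(np.sum(resid ** 2)) / ss_tot)
    return slope, intercept, min(r2, 1.0)


def fit_decay_rate(durations: Sequence[float], survival: Sequence[float],
                   mode: str = "free_intercept",
                   temperature: float = np.nan) -> DecayRateEstimate:
    """Fit S = exp(-k t) (``through_origin``) or S = exp(-k (t - t_d))
    (``free_intercept``) to survival-versus-duration data at one temperature.

    In ``free_intercept`` mode the log-linear regression is restricted to
    exposure times past the shoulder (chosen by a changepoint scan, see
    below) and the positive x-intercept of the fitted line is reported as
    the shoulder duration t_d.
    ``temperature`` is metadata carried into the estimate for the
    downstream Arrhenius/delay regressions.
    """
    t = np.asarray(durations, dtype=float)
    s = np.clip(np.asarray(survival, dtype=float), CLIP_EPS, CLIP_HIGH)
    if t.size < 3 or np.unique(t).size < 3:
        raise InvalidArgumentError("need at least 3 distinct durations")
    if t.size != s.size:
        raise InvalidArgumentError("durations and survival must have equal length")
    if np.ptp(s) == 0:
        raise DegenerateFitError("all survival values identical; no decay to fit")
    # Observations at the clip floor are below the assay's detection limit;
    # regressing on such censored values flattens the slope, so they are
    # excluded whenever at least two informative points remain.
    above_floor = s > CLIP_EPS
    if above_floor.sum() >= 2:
        t, s = t[above_floor], s[above_floor]
    y = np.log(s)

    if mode == "through_origin":
        denom = float(np.sum(t * t))
        if denom == 0:
            raise DegenerateFitError("all durations zero")
        slope = float(np.sum(t * y)) / denom
        if slope >= 0:
            raise DegenerateFitError("non-negative slope: survival does not decay")
        resid = y - slope * t
        ss_tot = float(np.sum(y ** 2))  # model has no intercept
        r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - float(np.sum(resid ** 2)) / ss_tot)
        return DecayRateEstimate(temperature, -slope, 0.0, min(r2, 1.0), int(t.size))

    if mode != "free_intercept":
        raise InvalidArgumentError(f"unknown mode {mode!r}")

    order = np.argsort(t)
    t, y = t[order], y[order]
    overall_slope, _, _ = _ols_line(t, y)
    if overall_slope >= 0:
        raise DegenerateFitError("non-negative slope: survival does not decay")
    td_hat, k_hat, sse = _hinge_fit(t, y)
    if k_hat is None:
        raise DegenerateFitError("non-negative slope: survival does not decay")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, min(1.0, 1.0 - sse / ss_tot))
    td = max(0.0, td_hat)
    # A shoulder shorter than the earliest sampled exposure is extrapolation
    # beyond the data (every observed point already decays); report it as
    # zero, i.e. "no shoulder seen", rather than as a measured delay.
    if td < max(1e-6 * float(t.max()), float(t.min())):
        td = 0.0
    n_used = int(np.sum(t > td_hat))
    return DecayRateEstimate(temperature, k_hat, float(td), r2, n_used)


def _hinge_sse(td: float, t: np.ndarray, y: np.ndarray):
    """Best-fitting rate and SSE of the hinge ln S = -k (t - td)+ at fixed td."""
    u = np.maximum(0.0, t - td)
    uu = float(np.sum(u * u))
    if uu == 0:
        return None, float(np.sum(y * y))
    k = -float(np.sum(y * u)) / uu
    if k <= 0:
        return None, np.inf
    return k, float(np.sum((y + k * u) ** 2))


def _hinge_fit(t: np.ndarray, y: np.ndarray):
    """Least-squares continuous hinge fit of ln S = -k max(0, t - td).

    The plateau (ln S = 0 for t <= td) and the decay line are fitted to
    all points jointly, the line being forced through (td, 0); for td at
    or below the earliest exposure this is ordinary free-intercept OLS.
    The profile likelihood over td is minimized per inter-point interval.
    Returns (td, k, sse); k is None when survival does not decay.
    """
    from scipy.optimize import minimize_scalar

    best_td, best_k, best_sse = 0.0, None, np.inf
    # unconstrained free line, valid when its x-intercept precedes all data
    slope, intercept, _ = _ols_line(t, y)
    if slope < 0:
        x_int = intercept / -slope
        if x_int <= t[0]:
            resid = y - (slope * t + intercept)
            best_td, best_k, best_sse = x_int, -slope, float(np.sum(resid ** 2))
    for lo, hi in zip(t[:-1], t[1:]):
        if hi <= lo:
            continue
        res = minimize_scalar(lambda td: _hinge_sse(td, t, y)[1],
                              bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-7 * t[-1]})
        k, sse = _hinge_sse(float(res.x), t, y)
        if k is not None and sse < best_sse:
            best_td, best_k, best_sse = float(res.x), k, sse
        # interval endpoints, in case the optimum sits on a data point
        for td in (lo, hi):
            k, sse = _hinge_sse(td, t, y)
            if k is not None and sse < best_sse:
                best_td, best_k, best_sse = td, k, sse
    return best_td, best_k, best_sse


def with_temperature(estimate: DecayRateEstimate, temperature: float) -> DecayRateEstimate:
    """Return a copy of ``estimate`` carrying its exposure temperature (K)."""
    return DecayRateEstimate(float(temperature), estimate.rate_k,
                             estimate.shoulder_td, estimate.r_squared,
                             estimate.n_points)


def _require_temperatures(estimates: Iterable[DecayRateEstimate]) -> list[DecayRateEstimate]:
    ests = list(estimates)
    if any(not np.isfinite(e.temperature) for e in ests):
        raise InvalidArgumentError("estimates must carry their temperature")
    return ests


def fit_arrhenius(estimates: Iterable[DecayRateEstimate],
                  gas_constant: float = GAS_CONSTANT) -> tuple[ArrheniusParams, float]:
    """Estimate (ln A, Ea) from per-temperature rates via OLS of ln k on 1/T.

    The slope is -Ea/R and the intercept ln A.
    """
    ests = _require_temperatures(estimates)
    temps = np.array([e.temperature for e in ests])
    if np.unique(temps).size < 2:
        raise InvalidArgumentError("need rates at >= 2 distinct temperatures")
    x = 1.0 / temps
    y = np.log([e.rate_k for e in ests])
    slope, intercept, r2 = _ols_line(x, y)
    return ArrheniusParams(intercept, -slope * gas_constant, gas_constant), r2


def fit_time_delay(estimates: Iterable[DecayRateEstimate],
                   censor_bound_s: float = 0.0) -> DelayParams:
    """Estimate the shoulder line t_d = b - m T from per-temperature delays.

    Temperatures whose estimated delay was clamped at zero are censored
    observations ("no shoulder seen, so the true delay is at most the
    earliest sampled duration"), not points on the line. They are excluded
    from the regression but enforced as one-sided constraints: if the
    unconstrained line predicts a delay above ``censor_bound_s`` at a
    censored temperature, the fit is re-solved with the line pinned to the
    bound at the most-violated (lowest) censored temperature. Without this,
    noise in the observed delays can extrapolate a spurious shoulder into
    temperatures where the decay fits saw immediate exponential kill.

    If every delay is zero the data carry no shoulder signal and
    (m, b) = (0, 0) is returned with a :class:`FitWarning`.
    """
    ests = _require_temperatures(estimates)
    nonzero = [e for e in ests if e.shoulder_td > 0]
    if not nonzero:
        warnings.warn("all shoulder delays are zero; returning the no-delay line",
                      FitWarning, stacklevel=2)
        return DelayParams(0.0, 0.0)
    if len(nonzero) < 2:
        raise InvalidArgumentError("need shoulder delays at >= 2 temperatures")
    temps = np.array([e.temperature for e in nonzero])
    if np.unique(temps).size < 2:
        raise InvalidArgumentError("need shoulder delays at >= 2 distinct temperatures")
    td = np.array([e.shoulder_td for e in nonzero])
    slope, intercept, _ = _ols_line(temps, td)
    m, b = max(0.0, -slope), intercept
    censored = sorted(e.temperature for e in ests if e.shoulder_td == 0)
    if censored:
        # the line decreases with T, so the binding constraint is the
        # lowest censored temperature
        t_star = censored[0]
        if b - m * t_star > censor_bound_s:
            x = t_star - temps
            m = float(np.sum(x * (td - censor_bound_s)) / np.sum(x * x))
            m = max(0.0, m)
            b = censor_bound_s + m * t_star
    return DelayParams(m, b)


def fit_two_state(conditions: Sequence[tuple[float, float, float]],
                  ) -> tuple[TwoStateParams, FitReport]:
    """Bilinear least-squares fit of logit(C) = gamma T - beta - alpha tau.

    ``conditions`` is a sequence of (temperature K, duration s, survival
    fraction) triples spanning at least two temperatures and two durations.
    Survival is clipped to [eps, 1-eps]; exact 0/1 observations are kept.
    """
    arr = np.asarray(conditions, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 4:
        raise InvalidArgumentError("need >= 4 (temperature, duration, survival) conditions")
    temps, taus, surv = arr[:, 0], arr[:, 1], arr[:, 2]
    if np.unique(temps).size < 2 or np.unique(taus).size < 2:
        raise InvalidArgumentError("conditions must span >= 2 temperatures and >= 2 durations")
    c = np.clip(surv, CLIP_EPS, 1.0 - CLIP_EPS)
    y = np.log(c / (1.0 - c))
    design = np.column_stack([temps, taus, np.ones_like(temps)])
    if np.linalg.matrix_rank(design) < 3:
        raise DegenerateFitError("rank-deficient design for two-state fit")
    coeffs, *_ = np.linalg.lstsq(design, y, rcond=None)
    gamma, alpha, beta = float(coeffs[0]), -float(coeffs[1]), -float(coeffs[2])
    params = TwoStateParams(alpha, beta, gamma)
    fitted = design @ coeffs
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, min(1.0, 1.0 - float(np.sum((y - fitted) ** 2)) / ss_tot))
    pred_pct = 100.0 * two_state_survival(taus, temps, params)
    resid = pred_pct - 100.0 * surv
    report = FitReport(
        model_name="two_state", params=params, r_squared=r2,
        rmse_pct=float(np.sqrt(np.mean(resid ** 2))),
        residuals=pd.DataFrame({"temperature_K": temps, "duration_s": taus,
                                "measured_pct": 100.0 * surv,
                                "predicted_pct": pred_pct,
                                "residual_pct": resid}))
    return params, report


def fit_rcem(estimates: Iterable[DecayRateEstimate],
             above_break_only: bool = True,
             break_temperature: float = 316.15) -> float:
    """Estimate the per-degree isoeffect factor R_CEM from decay rates.

    The isoeffect exposure time at temperature T scales as 1/k(T), so
    ln t_iso is regressed on T (degC); R_CEM = exp(slope). For pure
    Arrhenius kinetics this approaches exp(-Ea / (R_gas T (T+1))).
    """
    ests = _require_temperatures(estimates)
    if above_break_only:
        ests = [e for e in ests if e.temperature > break_temperature]
    temps = np.array([e.temperature for e in ests])
    if np.unique(temps).size < 2:
        raise InvalidArgumentError("need >= 2 usable temperatures to estimate R_CEM")
    x = temps - CELSIUS_OFFSET
    y = -np.log([e.rate_k for e in ests])  # ln t_iso up to an additive constant
    slope, _, _ = _ols_line(x, y)
    return float(np.exp(slope))


def predict_survival_pct(model: str, temperature: float, duration: float,
                         params) -> float:
    """Isothermal survival (%) predicted by a fitted model at (T, t).

    ``model`` is one of ``arrhenius``, ``arrhenius_delayed`` (params then a
    (ArrheniusParams, DelayParams) pair) or ``two_state``.
    """
    if model == "arrhenius":
        omega = rate_constant(params, temperature) * duration
    elif model == "arrhenius_delayed":
        arr, delay = params
        td = time_delay(delay, temperature)
        omega = rate_constant(arr, temperature) * max(0.0, duration - td)
    elif model == "two_state":
        return 100.0 * two_state_survival(duration, temperature, params)
    else:
        raise InvalidArgumentError(f"unknown model {model!r}")
    return 100.0 * float(np.exp(-omega))


def evaluate_fit(dataset, model: str, params) -> FitReport:
    """Pooled RMSE (percentage points) of a fitted model over a dataset.

    ``params`` may be a single parameter block or a mapping
    cell_line -> block. Predictions use each condition's setpoint and
    duration through the isothermal forward model; the result is invariant
    to the ordering of conditions.
    """
    df = dataset.df if hasattr(dataset, "df") else pd.DataFrame(dataset)
    if df.empty:
        raise InvalidArgumentError("empty dataset")
    rows = []
    for _, rec in df.iterrows():
        block = params[rec["cell_line"]] if isinstance(params, dict) else params
        pred = predict_survival_pct(model, rec["setpoint_K"], rec["duration_s"], block)
        rows.append((rec["cell_line"], rec["setpoint_K"], rec["duration_s"],
                     rec.get("recovery_h", np.nan),
                     100.0 * rec["mean_survival"], pred))
    res = pd.DataFrame(rows, columns=["cell_line", "setpoint_K", "duration_s",
                                      "recovery_h", "measured_pct", "predicted_pct"])
    res["residual_pct"] = res["predicted_pct"] - res["measured_pct"]
    rmse = float(np.sqrt(np.mean(res["residual_pct"] ** 2)))
    by_line = {name: float(np.sqrt(np.mean(g["residual_pct"] ** 2)))
               for name, g in res.groupby("cell_line")}
    ss_tot = float(np.sum((res["measured_pct"] - res["measured_pct"].mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, min(1.0, 1.0 - float(
        np.sum(res["residual_pct"] ** 2)) / ss_tot))
    return FitReport(model_name=model, params=params, r_squared=r2,
                     rmse_pct=rmse, residuals=res, rmse_by_cell_line=by_line)
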