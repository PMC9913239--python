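"""End-to-end analysis: fit every injury model, compare them, predict.

:func:`run_analysis` reproduces the standard workflow for plate-based
thermal-injury experiments: per cell line and recovery time it estimates
per-temperature decay rates (two arms — forced through S(0) = 1 for the
simple Arrhenius model, free-intercept for the shoulder-corrected one),
regresses out the Arrhenius coefficients and the delay line, fits the
two-state logistic model, estimates R_CEM, and scores all three models by
pooled RMSE on the percentage scale. :func:`validate_on_profile` then
applies the fitted coefficients to arbitrary non-isothermal
time-temperature profiles.

The report is a pydantic model; its JSON schema is published with the
package (``data/report_schema.json``) and serialization is deterministic,
so identical inputs produce byte-identical report files.
"""

from __future__ import annotations

import json
import warnings
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .errors import FitWarning, InvalidArgumentError
from .fitting import (
    DecayRateEstimate,
    evaluate_fit,
    fit_arrhenius,
    fit_decay_rate,
    fit_rcem,
    fit_time_delay,
    fit_two_state,
)
from .injury_models import (
    ArrheniusParams,
    DelayParams,
    DoseParams,
    TwoStateParams,
    cem43,
    damage_integral,
    damage_integral_delayed,
    two_state_survival,
)
from .profiles import TemperatureProfile
from .synthetic_data import ViabilityDataset

MODELS = ("arrhenius", "arrhenius_delayed", "two_state")


class AnalysisConfig(BaseModel):
    """Knobs of the analysis, logged verbatim into the report."""

    model_config = ConfigDict(frozen=True)

    gas_constant: float = 8.314
    recovery_h: float = 24.0
    simple_mode: str = "through_origin"
    delayed_mode: str = "free_intercept"
    r_above: float = 0.5
    r_below: float = 0.25
    break_temperature_K: float = 316.15

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


class ArrheniusBlock(BaseModel):
    ln_frequency_factor: float
    activation_energy: float
    gas_constant: float
    r_squared: float


class DelayedBlock(ArrheniusBlock):
    slope_m: float
    intercept_b: float


class TwoStateBlock(BaseModel):
    alpha: float
    beta: float
    gamma: float
    r_squared: float


class CellLineBlock(BaseModel):
    arrhenius: ArrheniusBlock
    arrhenius_delayed: DelayedBlock
    two_state: TwoStateBlock
    r_cem: float | None = None


class ModelComparisonRow(BaseModel):
    model: str
    recovery_h: float
    rmse_pct: float = Field(ge=0)
    rmse_by_cell_line: dict[str, float]


class ValidationRow(BaseModel):
    profile_label: str
    cell_line: str
    cem43_min: float
    predicted_survival_pct: dict[str, float]
    reference_survival_pct: float | None = None
    abs_error_pct: dict[str, float] | None = None


class AnalysisReport(BaseModel):
    config: AnalysisConfig
    cell_lines: dict[str, CellLineBlock]
    model_comparison: list[ModelComparisonRow]
    validation: list[ValidationRow] = Field(default_factory=list)

    def to_json(self) -> str:
        """Deterministic (sorted-key) JSON serialization."""
        return json.dumps(self.model_dump(), sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        return cls.model_validate(json.loads(text))


def report_schema() -> dict:
    """The published JSON schema of :class:`AnalysisReport`."""
    text = resources.files("thermokin.data").joinpath("report_schema.json").read_text()
    return json.loads(text)


# -- parameter extraction helpers -----------------------------------------

def arrhenius_params(block: ArrheniusBlock) -> ArrheniusParams:
    return ArrheniusParams(block.ln_frequency_factor, block.activation_energy,
                           block.gas_constant)


def delay_params(block: DelayedBlock) -> DelayParams:
    return DelayParams(block.slope_m, block.intercept_b)


def two_state_params(block: TwoStateBlock) -> TwoStateParams:
    return TwoStateParams(block.alpha, block.beta, block.gamma)


def _model_params(block: CellLineBlock, model: str):
    if model == "arrhenius":
        return arrhenius_params(block.arrhenius)
    if model == "arrhenius_delayed":
        return arrhenius_params(block.arrhenius_delayed), delay_params(block.arrhenius_delayed)
    if model == "two_state":
        return two_state_params(block.two_state)
    raise InvalidArgumentError(f"unknown model {model!r}")


# -- fitting orchestration -------------------------------------------------

def _fit_cell_line(subset: ViabilityDataset, cell_line: str,
                   config: AnalysisConfig) -> CellLineBlock:
    """All fits for one cell line at one recovery time (well-mean survival)."""
    df = subset.df
    simple_ests: list[DecayRateEstimate] = []
    free_ests: list[DecayRateEstimate] = []
    for setpoint, group in df.groupby("setpoint_K"):
        t = group["duration_s"].to_numpy()
        s = group["mean_survival"].to_numpy()
        try:
            simple_ests.append(fit_decay_rate(t, s, config.simple_mode, setpoint))
            free_ests.append(fit_decay_rate(t, s, config.delayed_mode, setpoint))
        except Exception as exc:
            raise type(exc)(
                f"cell line {cell_line}, setpoint {setpoint:.2f} K: {exc}") from exc
    try:
        arr_simple, r2_simple = fit_arrhenius(simple_ests, config.gas_constant)
        arr_free, r2_free = fit_arrhenius(free_ests, config.gas_constant)
        try:
            delay = fit_time_delay(free_ests,
                                   censor_bound_s=float(df["duration_s"].min()))
        except InvalidArgumentError:
            # a single non-zero shoulder cannot pin down the delay line;
            # degrade to the no-delay model rather than abort
            warnings.warn(f"cell line {cell_line}: underdetermined delay line, "
                          "using t_d = 0", FitWarning, stacklevel=2)
            delay = DelayParams(0.0, 0.0)
        conds = df[["setpoint_K", "duration_s", "mean_survival"]].to_numpy()
        ts_params, ts_report = fit_two_state(conds)
        r_cem = None
        usable = [e for e in free_ests if e.temperature > config.break_temperature_K]
        if len({e.temperature for e in usable}) >= 2:
            r_cem = fit_rcem(free_ests, above_break_only=True,
                             break_temperature=config.break_temperature_K)
    except Exception as exc:
        raise type(exc)(f"cell line {cell_line}: {exc}") from exc
    return CellLineBlock(
        arrhenius=ArrheniusBlock(
            ln_frequency_factor=arr_simple.ln_frequency_factor,
            activation_energy=arr_simple.activation_energy,
            gas_constant=arr_simple.gas_constant, r_squared=r2_simple),
        arrhenius_delayed=DelayedBlock(
            ln_frequency_factor=arr_free.ln_frequency_factor,
            activation_energy=arr_free.activation_energy,
            gas_constant=arr_free.gas_constant, r_squared=r2_free,
            slope_m=delay.slope_m, intercept_b=delay.intercept_b),
        two_state=TwoStateBlock(alpha=ts_params.alpha, beta=ts_params.beta,
                                gamma=ts_params.gamma, r_squared=ts_report.r_squared),
        r_cem=r_cem)


def run_analysis(dataset: ViabilityDataset,
                 config: AnalysisConfig = AnalysisConfig()) -> AnalysisReport:
    """Fit and score every injury model on a viability dataset.

    Fits are run separately per recovery time; the report's per-cell-line
    parameter blocks come from ``config.recovery_h`` (falling back to the
    latest recovery present), while the model-comparison table covers all
    recovery times in the dataset.
    """
    df = dataset.df
    if df["setpoint_K"].nunique() < 2:
        raise InvalidArgumentError("dataset must span >= 2 temperatures")
    per_temp = df.groupby(["cell_line", "recovery_h", "setpoint_K"])["duration_s"].nunique()
    if (per_temp < 3).any():
        raise InvalidArgumentError("each temperature needs >= 3 distinct durations")

    recoveries = sorted(df["recovery_h"].unique())
    report_recovery = (config.recovery_h if config.recovery_h in recoveries
                       else recoveries[-1])
    blocks_by_recovery: dict[float, dict[str, CellLineBlock]] = {}
    comparison: list[ModelComparisonRow] = []
    for rec in recoveries:
        sub = dataset.filter(recovery_h=rec)
        blocks = {cell: _fit_cell_line(sub.filter(cell_line=cell), cell, config)
                  for cell in sub.cell_lines}
        blocks_by_recovery[rec] = blocks
        for model in MODELS:
            params = {cell: _model_params(block, model) for cell, block in blocks.items()}
            fr = evaluate_fit(sub, model, params)
            comparison.append(ModelComparisonRow(
                model=model, recovery_h=rec, rmse_pct=fr.rmse_pct,
                rmse_by_cell_line=fr.rmse_by_cell_line))
    return AnalysisReport(config=config,
                          cell_lines=blocks_by_recovery[report_recovery],
                          model_comparison=comparison)


def validate_on_profile(profile: TemperatureProfile, report: AnalysisReport,
                        cell_line: str,
                        reference_survival_pct: float | None = None) -> ValidationRow:
    """Predict end-of-profile survival for every fitted model on a
    non-isothermal profile, plus its CEM43 dose.

    The Arrhenius models integrate the full time-temperature history; the
    two-state model, being defined for isothermal (tau, T) pairs, is
    evaluated at the profile's duration and duration-weighted mean
    temperature. ``reference_survival_pct`` (measured or simulated) turns
    the row into an absolute-error comparison.
    """
    try:
        block = report.cell_lines[cell_line]
    except KeyError:
        raise InvalidArgumentError(f"report has no cell line {cell_line!r}") from None
    dose = DoseParams(report.config.r_above, report.config.r_below,
                      report.config.break_temperature_K)
    preds = {
        "arrhenius": 100.0 * damage_integral(
            profile, arrhenius_params(block.arrhenius)).final_survival,
        "arrhenius_delayed": 100.0 * damage_integral_delayed(
            profile, arrhenius_params(block.arrhenius_delayed),
            delay_params(block.arrhenius_delayed)).final_survival,
        "two_state": 100.0 * two_state_survival(
            profile.duration, profile.mean_temperature(),
            two_state_params(block.two_state)),
    }
    errors = None
    if reference_survival_pct is not None:
        errors = {m: abs(p - reference_survival_pct) for m, p in preds.items()}
    return ValidationRow(profile_label=profile.label, cell_line=cell_line,
                         cem43_min=cem43(profile, dose),
                         predicted_survival_pct=preds,
                         reference_survival_pct=reference_survival_pct,
                         abs_error_pct=errors)


# -- fitted-parameter YAML round trip (CLI boundary) -----------------------

def params_to_yaml(report: AnalysisReport, path) -> None:
    """Write the report's per-cell-line parameter blocks as flat YAML."""
    out = {cell: block.model_dump() for cell, block in report.cell_lines.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=True)


def load_params_yaml(path) -> dict[str, CellLineBlock]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {cell: CellLineBlock.model_validate(block) for cell, block in raw.items()}
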