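#!/usr/bin/env python
"""Fit all three injury models to the simulated viability data.

Runs the full estimation cascade per cell line and recovery time
(per-temperature decay rates in both fitting arms, Arrhenius regression,
shoulder delay line, bilinear two-state fit, R_CEM), then compares the
models by pooled RMSE on the percentage scale. Recovered coefficients are
printed next to the generating truth so estimator bias under the assay
noise model is visible at a glance.

Inputs:  results/viability.csv  (from 01_simulate_dataset.py)
Outputs: results/analysis_report.json, results/fitted_parameters.yaml,
         results/model_comparison.csv
"""

import warnings
from pathlib import Path

import pandas as pd

import thermokin as tk
from thermokin.errors import FitWarning
from thermokin.pipeline import params_to_yaml, run_analysis

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    dataset = tk.ViabilityDataset.read_csv(RESULTS / "viability.csv")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FitWarning)
        report = run_analysis(dataset)

    (RESULTS / "analysis_report.json").write_text(report.to_json())
    params_to_yaml(report, RESULTS / "fitted_parameters.yaml")

    print("recovered kinetic coefficients (24 h recovery, shoulder-corrected arm)")
    print(f"{'cell':>6s} {'Ea fit':>10s} {'Ea true':>10s} {'lnA fit':>8s} "
          f"{'lnA true':>8s} {'R_CEM fit':>9s} {'R_CEM pub':>9s}")
    for cell in sorted(report.cell_lines):
        block = report.cell_lines[cell].arrhenius_delayed
        truth, _ = tk.cell_line_params(cell)
        print(f"{cell:>6s} {block.activation_energy:10.0f} "
              f"{truth.activation_energy:10.0f} {block.ln_frequency_factor:8.2f} "
              f"{truth.ln_frequency_factor:8.2f} "
              f"{report.cell_lines[cell].r_cem:9.3f} "
              f"{tk.reference_r_cem(cell):9.3f}")

    rows = [{"model": r.model, "recovery_h": r.recovery_h, "rmse_pct": r.rmse_pct,
             **{f"rmse_{c}_pct": v for c, v in r.rmse_by_cell_line.items()}}
            for r in report.model_comparison]
    comparison = pd.DataFrame(rows).sort_values(["recovery_h", "rmse_pct"])
    comparison.to_csv(RESULTS / "model_comparison.csv", index=False)

    print("\npooled RMSE by model (percentage points of survival)")
    for _, row in comparison.iterrows():
        print(f"  {row.model:>18s} @ {row.recovery_h:4.0f} h: {row.rmse_pct:6.2f}%")
    best = comparison[comparison.recovery_h == 24.0].iloc[0]
    print(f"\nbest 24 h model: {best.model} ({best.rmse_pct:.2f}%) — the "
          "time-delay term absorbs the shoulder that the simple model "
          "over-penalizes and the bilinear two-state fit cannot follow the "
          "temperature dependence of the decay rate.")


if __name__ == "__main__":
    main()
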