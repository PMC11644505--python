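#!/usr/bin/env python
"""Fit the multiple linear yield model on the selected features.

Reports coefficients with 95 % CIs, LOOCV metrics, standardized residuals
and permutation importances, and compares the importance ranking with the
correlation ranking.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from tuberspec.feature_selection import screen
from tuberspec.yield_model import (
    fit_mlr, importance_vs_correlation_report, loocv_evaluate,
    permutation_importance, standardized_residuals,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    cache = ROOT / "scratch" / f"features_seed{args.seed}"
    aggregated = pd.read_parquet(cache / "aggregated.parquet")
    yields = pd.read_parquet(cache / "yields.parquet")["yield_g"]

    selection = screen(aggregated, yields, alpha=0.05, threshold=0.7)
    features = aggregated[selection.kept_names]

    model = fit_mlr(features, yields)
    loocv = loocv_evaluate(features, yields)
    residuals = standardized_residuals(loocv.predictions.dropna(), yields)
    importances = permutation_importance(model, features, yields, n_rep=50,
                                         seed=args.seed)
    comparison = importance_vs_correlation_report(selection.kept, importances)

    outdir = ROOT / "results"
    model.coefficients_table().to_csv(outdir / "coefficients.csv", index=False)
    importances.to_csv(outdir / "importances.csv", index=False)
    comparison.to_csv(outdir / "importance_vs_correlation.csv", index=False)
    preds = pd.DataFrame({
        "plant_id": loocv.predictions.index,
        "predicted_g": loocv.predictions.to_numpy(),
        "observed_g": yields.loc[loocv.predictions.index].to_numpy(),
        "residual_standardized": residuals.reindex(
            loocv.predictions.index).to_numpy(),
    })
    preds.to_csv(outdir / "loocv_predictions.csv", index=False)
    metrics = {
        "n_plants": int(len(features)),
        "n_features": int(features.shape[1]),
        "loocv_rmse_g": loocv.rmse,
        "loocv_pct_rmse": loocv.pct_rmse,
        "loocv_r2": loocv.r2,
        "n_significant_coefficients": int(model.significant.sum()),
    }
    (outdir / "model_metrics.json").write_text(json.dumps(metrics, indent=1))

    print(f"MLR on {metrics['n_features']} features, "
          f"{metrics['n_plants']} plants")
    print(f"LOOCV: RMSE {loocv.rmse:.0f} g, %RMSE {loocv.pct_rmse:.1f} %, "
          f"R2 {loocv.r2:.2f}")
    print(f"{metrics['n_significant_coefficients']} coefficients significant "
          "at 95 %")
    print("most important features:")
    print(comparison.head(5).to_string(index=False))


if __name__ == "__main__":
    main()
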