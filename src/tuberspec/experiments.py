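"""Recovery experiments on synthetic fields with known ground truth.

These drive the full pipeline over several generator seeds and measure how
reliably it recovers what was planted: the mid-season coupling window, the
direction of strongly coupled features in the fitted model, a LOOCV error
close to the irreducible noise floor, and agreement between the
permutation-importance ranking and the correlation ranking.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .pipeline import RunConfig, run_pipeline
from .synthetic_field import FieldConfig, coupling_direction, generate_field
from .temporal_selection import DESK_RF_PARAMS, RFParams

#: number of top-ranked kept features whose coefficient sign is checked
#: against the planted coupling direction. With two planted channels
#: (chlorophyll, water) the top-2 kept features are their dominant
#: representatives; deeper-ranked features share up to |r| = 0.7 with a
#: stronger kept regressor, so their partial OLS coefficients are not
#: expected to carry the marginal (planted) sign even for an oracle model.
N_SIGN_CHECKED = 2


def run_seed(
    seed: int,
    field_config: FieldConfig | None = None,
    rf_params: RFParams | None = None,
    n_permutation_reps: int = 30,
) -> dict:
    """One full pipeline run on a fresh synthetic field; recovery metrics."""
    fc = field_config if field_config is not None else FieldConfig()
    fc = replace(fc, seed=seed)
    samples, records, truth = generate_field(fc)
    config = RunConfig(
        field=fc, seed=seed,
        rf_params=rf_params if rf_params is not None else DESK_RF_PARAMS,
        n_permutation_reps=n_permutation_reps,
    )
    result = run_pipeline(config, samples=samples, records=records)

    lo, hi = truth.coupling_window
    w_lo, w_hi = result.manifest["selected_window"]
    overlaps = not (w_hi < lo or w_lo > hi)

    kept_ids = [r.plant_id for r in result.records]
    floor = truth.noise_floor_g(kept_ids)
    rmse_ratio = result.loocv.rmse / floor

    strong = result.selection.kept.head(N_SIGN_CHECKED)
    n_checked = 0
    n_matched = 0
    coef = dict(zip(result.model.feature_names, result.model.coef))
    for _, row in strong.iterrows():
        direction = coupling_direction(row["feature"], fc)
        if direction == 0:
            continue
        n_checked += 1
        if np.sign(coef[row["feature"]]) == direction:
            n_matched += 1

    top2_imp = set(
        result.importances.sort_values("importance", ascending=False)
        ["feature"].head(2)
    )
    top2_r = set(result.selection.kept["feature"].head(2))

    return {
        "seed": seed,
        "selected_start": w_lo,
        "selected_end": w_hi,
        "selected_statistic": result.manifest["selected_statistic"],
        "window_overlaps_truth": bool(overlaps),
        "loocv_rmse_g": result.loocv.rmse,
        "noise_floor_g": floor,
        "rmse_ratio": rmse_ratio,
        "n_sign_checked": n_checked,
        "n_sign_matched": n_matched,
        "signs_recovered": bool(n_checked > 0 and n_matched == n_checked),
        "top2_importance_matches_top2_r": bool(top2_imp == top2_r),
        "n_kept": result.manifest["n_kept"],
        "loocv_r2": result.loocv.r2,
    }


def recovery_experiment(
    n_seeds: int = 10,
    base_seed: int = 1,
    field_config: FieldConfig | None = None,
    rf_params: RFParams | None = None,
) -> pd.DataFrame:
    """Per-seed recovery metrics over ``n_seeds`` independent fields."""
    rows = [
        run_seed(base_seed + k, field_config=field_config, rf_params=rf_params)
        for k in range(n_seeds)
    ]
    return pd.DataFrame(rows)
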