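"""End-to-end orchestration: field -> features -> window -> model -> report.

The stages mirror the field protocol: plants flagged for rodent damage are
excluded; spectra are resampled to the unified 1 nm grid; per measurement
day a feature table of retained band reflectances (masked grid, columns
``x.<nm>``) plus the 116-entry vegetation-index bank is built; contiguous
day windows x {sum, mean, max} are scored by bootstrap random-forest RMSE;
the winning aggregation is screened by the significance + decorrelation
filter; and a centred/scaled multiple linear regression with LOOCV,
coefficient CIs and permutation importance produces the final report.
Every stage's counts land in a JSON-serialisable run manifest.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from . import feature_selection, temporal_selection, vegindex, yield_model
from .spectra import (
    MaskSpec, PlantRecord, SpectrumSample, exclude_damaged,
    records_to_frame, resample_to_1nm, retained_band_count, TARGET_GRID,
)
from .synthetic_field import FieldConfig, generate_field
from .temporal_selection import RFParams, DESK_RF_PARAMS


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    field: FieldConfig = dc_field(default_factory=FieldConfig)
    mask: MaskSpec = dc_field(default_factory=MaskSpec)
    alpha: float = 0.05
    decorrelation_threshold: float = 0.7
    statistics: Sequence[str] = temporal_selection.STATISTICS
    rf_params: RFParams = dc_field(default_factory=lambda: DESK_RF_PARAMS)
    n_permutation_reps: int = 50
    select_per_window: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        fc = FieldConfig(**raw.pop("field", {}))
        mask_ranges = raw.pop("mask_ranges", None)
        mask = MaskSpec(mask_ranges) if mask_ranges else MaskSpec()
        rf = RFParams(**raw.pop("rf_params", {}))
        return cls(field=fc, mask=mask, rf_params=rf, **raw)


def build_day_tables(
    samples: Sequence[SpectrumSample],
    mask: MaskSpec | None = None,
) -> dict[int, pd.DataFrame]:
    """Per-day feature tables: retained bands + vegetation indices.

    Samples must already be on the 1 nm grid. Band columns are named
    ``x.<nm>`` for the bands surviving the mask; index columns carry the
    registry names and are computed from the pre-mask spectrum. Plants from
    all years are pooled by day ordinal.
    """
    mask = mask if mask is not None else MaskSpec()
    keep = mask.keep_mask(TARGET_GRID)
    band_cols = [f"x.{int(w)}" for w in TARGET_GRID[keep]]
    by_day: dict[int, list[SpectrumSample]] = {}
    for s in samples:
        by_day.setdefault(s.day_index, []).append(s)
    tables: dict[int, pd.DataFrame] = {}
    for day, group in sorted(by_day.items()):
        matrix = np.vstack([s.reflectance for s in group])
        ids = [s.plant_id for s in group]
        bands = pd.DataFrame(matrix[:, keep], index=ids, columns=band_cols)
        vis = vegindex.evaluate_matrix(TARGET_GRID, matrix)
        vis.index = ids
        tables[day] = pd.concat([bands, vis], axis=1)
    return tables


def _days_in_all_years(samples: Sequence[SpectrumSample]) -> tuple[int, set[int]]:
    """Max day ordinal and the ordinals absent from at least one year."""
    per_year: dict[int, set[int]] = {}
    for s in samples:
        per_year.setdefault(s.year, set()).add(s.day_index)
    n_days = max(max(v) for v in per_year.values())
    common = set.intersection(*per_year.values())
    excluded = set(range(1, n_days + 1)) - common
    return n_days, excluded


@dataclass
class PipelineResult:
    manifest: dict
    window_table: pd.DataFrame
    best_choice: temporal_selection.AggregationChoice
    selection: feature_selection.SelectionResult
    model: yield_model.MLRFit
    loocv: yield_model.LoocvResult
    residuals: pd.Series
    importances: pd.DataFrame
    comparison: pd.DataFrame
    records: list[PlantRecord]
    features: pd.DataFrame          # aggregated table restricted to kept features


def run_pipeline(
    config: RunConfig | None = None,
    samples: Sequence[SpectrumSample] | None = None,
    records: Sequence[PlantRecord] | None = None,
) -> PipelineResult:
    """Execute the full analysis; synthesise the field when no data given."""
    config = config if config is not None else RunConfig()
    stage = "simulate"
    try:
        if samples is None or records is None:
            fc = config.field
            if fc.seed != config.seed:
                fc = FieldConfig(**{**fc.__dict__, "seed": config.seed})
            samples, records, _ = generate_field(fc)
        samples = list(samples)
        records = list(records)
        n_total = len(records)

        stage = "exclude_damaged"
        records, samples = exclude_damaged(records, samples)
        n_excluded = n_total - len(records)
        if not records:
            raise PipelineError("no plants left after rodent exclusion")

        stage = "preprocess"
        samples = [resample_to_1nm(s) for s in samples]

        stage = "features"
        day_tables = build_day_tables(samples, config.mask)
        n_bands = retained_band_count(config.mask)
        n_vis = vegindex.N_INDICES
        total_features = n_bands + n_vis
        yields = pd.Series(
            {r.plant_id: r.yield_g for r in records}, name="yield_g"
        )

        stage = "select_window"
        n_days, excluded_days = _days_in_all_years(samples)
        if config.select_per_window:
            best, window_table = _select_best_per_window(
                day_tables, yields, n_days, excluded_days, config
            )
        else:
            best, window_table = temporal_selection.select_best(
                day_tables, yields, n_days=n_days,
                excluded_days=sorted(excluded_days),
                statistics=config.statistics,
                rf_params=config.rf_params, seed=config.seed,
            )

        stage = "select_features"
        aggregated = temporal_selection.aggregate(
            day_tables, best.window, best.statistic
        )
        selection = feature_selection.screen(
            aggregated, yields, alpha=config.alpha,
            threshold=config.decorrelation_threshold,
        )
        if not selection.kept_names:
            raise PipelineError("no significant features")
        kept_features = aggregated[selection.kept_names]

        stage = "fit"
        model = yield_model.fit_mlr(kept_features, yields)
        loocv = yield_model.loocv_evaluate(kept_features, yields)
        residuals = yield_model.standardized_residuals(
            loocv.predictions.dropna(), yields
        )
        importances = yield_model.permutation_importance(
            model, kept_features, yields,
            n_rep=config.n_permutation_reps, seed=config.seed + 7,
        )
        comparison = yield_model.importance_vs_correlation_report(
            selection.kept, importances
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    import sklearn

    manifest = {
        "package_version": __version__,
        "versions": {"numpy": np.__version__, "sklearn": sklearn.__version__},
        "seed": config.seed,
        "n_plants_total": n_total,
        "n_excluded_rodent": n_excluded,
        "n_plants_retained": len(records),
        "retained_bands": n_bands,
        "vi_count": n_vis,
        "total_features_per_day": total_features,
        "n_days": n_days,
        "excluded_days": sorted(excluded_days),
        "n_windows": len(temporal_selection.enumerate_windows(
            n_days, excluded_days)),
        "n_candidates": int(len(window_table)),
        "selected_window": [best.window.start, best.window.end],
        "selected_statistic": best.statistic,
        "selected_rmse_point": best.rmse_point,
        "selected_rmse_ci": [best.ci_low, best.ci_high],
        "n_significant": int(len(selection.kept) + len(selection.removed_redundant)),
        "n_nonsignificant": int(len(selection.removed_nonsignificant)),
        "n_kept": int(len(selection.kept)),
        "n_redundant": int(len(selection.removed_redundant)),
        "alpha": config.alpha,
        "decorrelation_threshold": config.decorrelation_threshold,
        "loocv_rmse_g": loocv.rmse,
        "loocv_pct_rmse": loocv.pct_rmse,
        "loocv_r2": loocv.r2,
        "mean_yield_g": float(yields.mean()),
    }
    return PipelineResult(
        manifest=manifest, window_table=window_table, best_choice=best,
        selection=selection, model=model, loocv=loocv, residuals=residuals,
        importances=importances, comparison=comparison, records=records,
        features=kept_features,
    )


def _select_best_per_window(day_tables, yields, n_days, excluded_days, config):
    """Per-candidate mode: re-run feature screening inside every candidate."""
    results = []
    windows = temporal_selection.enumerate_windows(n_days, sorted(excluded_days))
    for wi, window in enumerate(windows):
        for si, stat in enumerate(config.statistics):
            feats = temporal_selection.aggregate(day_tables, window, stat)
            sel = feature_selection.screen(
                feats, yields, alpha=config.alpha,
                threshold=config.decorrelation_threshold,
            )
            use = feats[sel.kept_names] if sel.kept_names else feats
            results.append(temporal_selection.score_choice(
                use, yields, window, stat, rf_params=config.rf_params,
                seed=config.seed + 1000 * wi + si,
            ))
    best = min(results, key=temporal_selection._tie_key)
    table = pd.DataFrame({
        "window": [str(c.window) for c in results],
        "start": [c.window.start for c in results],
        "end": [c.window.end for c in results],
        "statistic": [c.statistic for c in results],
        "rmse_point": [c.rmse_point for c in results],
        "ci_low": [c.ci_low for c in results],
        "ci_high": [c.ci_high for c in results],
    })
    return best, table


def write_report(result: PipelineResult, outdir: str | Path) -> None:
    """Write manifest, tables and a plain-text summary; archive any prior run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists():
        archive = outdir / "archive"
        archive.mkdir(exist_ok=True)
        n = len(list(archive.glob("manifest.*.json"))) + 1
        shutil.move(str(manifest_path), archive / f"manifest.{n:03d}.json")
    manifest_path.write_text(json.dumps(result.manifest, indent=1))
    result.window_table.to_csv(outdir / "window_search.csv", index=False)
    result.model.coefficients_table().to_csv(
        outdir / "coefficients.csv", index=False
    )
    result.selection.kept.to_csv(outdir / "selected_features.csv", index=False)
    result.selection.removed_redundant.to_csv(
        outdir / "removed_redundant.csv", index=False
    )
    result.importances.to_csv(outdir / "importances.csv", index=False)
    result.comparison.to_csv(outdir / "importance_vs_correlation.csv", index=False)
    pred = pd.DataFrame({
        "plant_id": result.loocv.predictions.index,
        "predicted_g": result.loocv.predictions.to_numpy(),
        "observed_g": [
            {r.plant_id: r.yield_g for r in result.records}[p]
            for p in result.loocv.predictions.index
        ],
    })
    pred["residual_standardized"] = result.residuals.reindex(
        pred["plant_id"]).to_numpy()
    pred.to_csv(outdir / "loocv_predictions.csv", index=False)
    records_to_frame(result.records).to_csv(outdir / "plants.csv", index=False)
    m = result.manifest
    summary = (
        f"plants: {m['n_plants_retained']}/{m['n_plants_total']} retained "
        f"({m['n_excluded_rodent']} rodent-damaged excluded)\n"
        f"features/day: {m['retained_bands']} bands + {m['vi_count']} VIs "
        f"= {m['total_features_per_day']}\n"
        f"window search: {m['n_candidates']} candidates over "
        f"{m['n_windows']} windows\n"
        f"selected: {m['selected_statistic']} over d{m['selected_window'][0]}"
        f"-d{m['selected_window'][1]} (RMSE {m['selected_rmse_point']:.0f} g)\n"
        f"screening: {m['n_kept']} kept / {m['n_redundant']} redundant / "
        f"{m['n_nonsignificant']} non-significant\n"
        f"LOOCV: RMSE {m['loocv_rmse_g']:.0f} g, "
        f"%RMSE {m['loocv_pct_rmse']:.1f} %, R2 "
        f"{m['loocv_r2'] if m['loocv_r2'] is None else round(m['loocv_r2'], 3)}\n"
    )
    (outdir / "summary.txt").write_text(summary)
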