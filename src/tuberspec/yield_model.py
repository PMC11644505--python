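"""Multiple linear regression of yield on selected spectral features.

Features are centred and scaled before fitting; coefficients are reported
in standardized units (grams per SD of the feature) with normal-theory 95 %
confidence intervals (estimate +/- 1.96 SE) and, for convenience, back-
transformed to the original feature scale. Out-of-sample performance comes
from leave-one-out cross-validation with the standardization refit inside
each fold (no leakage): RMSE, %RMSE (RMSE / mean yield x 100) and R^2 as
the squared Pearson correlation between held-out predictions and observed
yields. Feature influence is measured by permutation importance: the mean
increase in RMSE when one feature's column is shuffled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm


class DegenerateFeatureError(ValueError):
    """Zero-variance column where variation is required."""


class CollinearityError(ValueError):
    """Rank-deficient design matrix."""


@dataclass
class Standardizer:
    """Column centring/scaling with retained transform parameters."""

    center: pd.Series
    scale: pd.Series

    @classmethod
    def fit(cls, features: pd.DataFrame) -> "Standardizer":
        center = features.mean()
        scale = features.std(ddof=1)
        bad = scale[scale == 0]
        if len(bad):
            raise DegenerateFeatureError(
                f"zero-variance feature(s): {list(bad.index)}"
            )
        return cls(center=center, scale=scale)

    def transform(self, features: pd.DataFrame) -> pd.DataFrame:
        return (features - self.center) / self.scale


def standardize(features: pd.DataFrame) -> tuple[pd.DataFrame, Standardizer]:
    """Centre/scale every column to mean 0, SD 1 (ddof=1)."""
    st = Standardizer.fit(features)
    return st.transform(features), st


@dataclass
class MLRFit:
    """OLS fit on standardized features with normal-theory 95 % CIs."""

    feature_names: list[str]
    intercept: float
    coef: np.ndarray           # standardized scale (g per feature SD)
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    significant: np.ndarray    # CI excludes zero
    intercept_se: float
    standardizer: Standardizer
    in_sample_rmse: float

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        Z = self.standardizer.transform(features[self.feature_names])
        return self.intercept + Z.to_numpy(dtype=float) @ self.coef

    def coefficients_table(self) -> pd.DataFrame:
        """Coefficient report (standardized and original-scale columns)."""
        rows = [{
            "feature": "(Intercept)", "coefficient": self.intercept,
            "ci_low": self.intercept - 1.96 * self.intercept_se,
            "ci_high": self.intercept + 1.96 * self.intercept_se,
            "significant": bool(
                abs(self.intercept) > 1.96 * self.intercept_se
            ),
            "coefficient_raw_scale": np.nan,
        }]
        raw = self.coef / self.standardizer.scale[self.feature_names].to_numpy()
        for i, name in enumerate(self.feature_names):
            rows.append({
                "feature": name, "coefficient": self.coef[i],
                "ci_low": self.ci_low[i], "ci_high": self.ci_high[i],
                "significant": bool(self.significant[i]),
                "coefficient_raw_scale": raw[i],
            })
        return pd.DataFrame(rows)


def fit_mlr(features: pd.DataFrame, yields: pd.Series) -> MLRFit:
    """OLS of yield on centred/scaled features; CI = estimate +/- 1.96 SE."""
    y = yields.loc[features.index].to_numpy(dtype=float)
    n, p = features.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    Z, st = standardize(features)
    X = sm.add_constant(Z.to_numpy(dtype=float))
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        corr = np.corrcoef(Z.to_numpy(dtype=float), rowvar=False)
        np.fill_diagonal(corr, 0.0)
        worst = [
            features.columns[i]
            for i in np.unique(np.argwhere(np.abs(corr) > 0.9999))
        ]
        raise CollinearityError(f"rank-deficient design; near-duplicates: {worst}")
    res = sm.OLS(y, X).fit()
    coef = res.params[1:]
    se = res.bse[1:]
    ci_low = coef - 1.96 * se
    ci_high = coef + 1.96 * se
    resid = y - res.fittedvalues
    return MLRFit(
        feature_names=list(features.columns),
        intercept=float(res.params[0]),
        coef=np.asarray(coef),
        se=np.asarray(se),
        ci_low=np.asarray(ci_low),
        ci_high=np.asarray(ci_high),
        significant=(ci_low > 0) | (ci_high < 0),
        intercept_se=float(res.bse[0]),
        standardizer=st,
        in_sample_rmse=float(np.sqrt(np.mean(resid**2))),
    )


@dataclass
class LoocvResult:
    rmse: float
    pct_rmse: float
    r2: float | None
    predictions: pd.Series     # held-out prediction per plant
    n_skipped_folds: int = 0


def loocv_evaluate(features: pd.DataFrame, yields: pd.Series) -> LoocvResult:
    """Leave-one-out CV with per-fold re-standardization."""
    y = yields.loc[features.index].to_numpy(dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 plants for LOOCV")
    preds = np.full(n, np.nan)
    skipped = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        train = features.iloc[mask]
        try:
            Z, st = standardize(train)
        except DegenerateFeatureError:
            skipped += 1
            warnings.warn(f"fold {i}: zero-variance feature; fold skipped")
            continue
        X = np.column_stack([np.ones(mask.sum()), Z.to_numpy(dtype=float)])
        beta, _, rank, _ = np.linalg.lstsq(X, y[mask], rcond=None)
        if rank < X.shape[1]:
            skipped += 1
            warnings.warn(f"fold {i}: rank-deficient fold skipped")
            continue
        z_i = st.transform(features.iloc[[i]]).to_numpy(dtype=float)[0]
        preds[i] = beta[0] + float(z_i @ beta[1:])
    ok = ~np.isnan(preds)
    rmse = float(np.sqrt(np.mean((y[ok] - preds[ok]) ** 2)))
    pct = 100.0 * rmse / float(np.mean(y))
    if np.std(y[ok]) == 0 or np.std(preds[ok]) == 0:
        warnings.warn("R^2 undefined (constant observations or predictions)")
        r2 = None
    else:
        r2 = float(np.corrcoef(preds[ok], y[ok])[0, 1] ** 2)
    return LoocvResult(
        rmse=rmse, pct_rmse=pct, r2=r2,
        predictions=pd.Series(preds, index=features.index),
        n_skipped_folds=skipped,
    )


def standardized_residuals(
    predictions: pd.Series, yields: pd.Series
) -> pd.Series:
    """(observed - predicted) in units of the raw-residual SD (ddof=1)."""
    y = yields.loc[predictions.index].to_numpy(dtype=float)
    resid = y - predictions.to_numpy(dtype=float)
    sd = float(np.std(resid, ddof=1)) if len(resid) > 1 else 0.0
    if sd == 0:
        warnings.warn("zero residual variance; returning zeros")
        return pd.Series(np.zeros_like(resid), index=predictions.index)
    return pd.Series(resid / sd, index=predictions.index)


def permutation_importance(
    model: MLRFit,
    features: pd.DataFrame,
    yields: pd.Series,
    n_rep: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean RMSE increase when one feature column is shuffled.

    Returns one row per feature with the mean loss difference and its
    2.5/97.5 permutation percentiles.
    """
    if n_rep < 2:
        raise ValueError("n_rep must be >= 2")
    y = yields.loc[features.index].to_numpy(dtype=float)
    base_pred = model.predict(features)
    base_rmse = float(np.sqrt(np.mean((y - base_pred) ** 2)))
    rng = np.random.default_rng(seed)
    rows = []
    for name in model.feature_names:
        deltas = np.empty(n_rep)
        for r in range(n_rep):
            shuffled = features.copy()
            shuffled[name] = rng.permutation(shuffled[name].to_numpy())
            pred = model.predict(shuffled)
            deltas[r] = float(np.sqrt(np.mean((y - pred) ** 2))) - base_rmse
        rows.append({
            "feature": name,
            "importance": float(deltas.mean()),
            "ci_low": float(np.percentile(deltas, 2.5)),
            "ci_high": float(np.percentile(deltas, 97.5)),
        })
    return pd.DataFrame(rows)


def importance_vs_correlation_report(
    selection_kept: pd.DataFrame, importances: pd.DataFrame
) -> pd.DataFrame:
    """Standardized |r| and importance scores side by side, by importance.

    Both score vectors are centred and scaled (SD 1) so their rankings are
    comparable on one axis; with a single feature the standardized scores
    degenerate to 0 (warned).
    """
    sel = selection_kept.set_index("feature")
    imp = importances.set_index("feature")
    if set(sel.index) != set(imp.index):
        raise ValueError("feature sets differ between selection and importances")
    imp = imp.loc[sel.index]
    abs_r = sel["r"].abs()

    def _std(v: pd.Series) -> pd.Series:
        sd = v.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            warnings.warn("degenerate scaling in comparison report")
            return v * 0.0
        return (v - v.mean()) / sd

    out = pd.DataFrame({
        "feature": sel.index,
        "abs_r": abs_r.to_numpy(),
        "importance": imp["importance"].to_numpy(),
        "abs_r_standardized": _std(abs_r).to_numpy(),
        "importance_standardized": _std(imp["importance"]).to_numpy(),
    })
    return out.sort_values("importance", ascending=False).reset_index(drop=True)
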