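"""Correlation-based feature screening and greedy decorrelation.

The aggregated feature table (retained bands + vegetation indices) is
reduced in two steps: (1) keep only features whose Pearson correlation with
yield is significant at a chosen level and rank them by |r| descending;
(2) walk the ranking top-down, keeping a feature only if its pairwise |r|
with every already-kept feature stays at or below a redundancy threshold
(default 0.7). Because the walk is in descending |r|-with-yield order,
dropping a redundant feature always discards the one less correlated with
yield. The threshold applies to |r|: a strongly negative pairwise
correlation is just as redundant as a positive one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class DegenerateInputError(ValueError):
    """Zero-variance or otherwise degenerate input."""


@dataclass
class SelectionResult:
    """Outcome of the two-step screening.

    ``kept`` is ordered by descending |r| with yield; every removed feature
    records why it left (non-significant, or redundant with a named kept
    feature at a given pairwise r).
    """

    kept: pd.DataFrame                 # columns: feature, r, p
    removed_nonsignificant: pd.DataFrame  # columns: feature, r, p
    removed_redundant: pd.DataFrame    # columns: feature, culprit, pairwise_r

    @property
    def kept_names(self) -> list[str]:
        return list(self.kept["feature"])


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided p-value (t-test on n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length 1-D vectors with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("zero variance input to Pearson correlation")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _columnwise_pearson(features: pd.DataFrame, y: np.ndarray):
    """Vectorised per-column r and p against y (matches pearson_with_p)."""
    X = features.to_numpy(dtype=float)
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return r, p, sx


def significance_filter(
    features: pd.DataFrame, yields: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Features significantly correlated with yield, ranked by |r| descending.

    Zero-variance columns cannot be tested and are treated as
    non-significant (with a warning). Rank ties break by feature name so
    the ordering is deterministic. Returns a frame with columns
    ``feature, r, p`` (the non-significant remainder is available from
    :func:`screen`).
    """
    if features.isna().any().any():
        raise ValueError("feature table contains missing cells")
    y = yields.loc[features.index].to_numpy(dtype=float)
    r, p, sx = _columnwise_pearson(features, y)
    degenerate = sx == 0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} zero-variance features skipped")
    table = pd.DataFrame({"feature": features.columns, "r": r, "p": p})
    table.loc[degenerate, "p"] = 1.0
    table.loc[degenerate, "r"] = 0.0
    sig = table[table["p"] < alpha].copy()
    if sig.empty:
        warnings.warn("no features pass the significance filter")
    sig["abs_r"] = sig["r"].abs()
    sig = sig.sort_values(
        ["abs_r", "feature"], ascending=[False, True], kind="mergesort"
    ).drop(columns="abs_r")
    return sig.reset_index(drop=True)


def greedy_decorrelate(
    features: pd.DataFrame,
    ranked: pd.DataFrame,
    threshold: float = 0.7,
) -> SelectionResult:
    """Top-down redundancy removal at pairwise |r| > threshold.

    ``ranked`` must be the output of :func:`significance_filter` (features
    in descending |r|-with-yield order). A candidate is kept iff its
    pairwise |r| with every already-kept feature is <= threshold; otherwise
    it is recorded as redundant with the first offending kept feature.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    kept_rows = []
    removed_rows = []
    kept_cols: list[np.ndarray] = []
    kept_names: list[str] = []
    X = features
    for _, row in ranked.iterrows():
        col = X[row["feature"]].to_numpy(dtype=float)
        colc = col - col.mean()
        denom = np.sqrt((colc**2).sum())
        culprit = None
        culprit_r = None
        for name, kc in zip(kept_names, kept_cols):
            kd = np.sqrt((kc**2).sum())
            r_pair = float(colc @ kc / (denom * kd)) if denom * kd > 0 else 1.0
            if abs(r_pair) > threshold:
                culprit, culprit_r = name, r_pair
                break
        if culprit is None:
            kept_rows.append(row)
            kept_cols.append(colc)
            kept_names.append(row["feature"])
        else:
            removed_rows.append(
                {"feature": row["feature"], "culprit": culprit,
                 "pairwise_r": culprit_r}
            )
    return SelectionResult(
        kept=pd.DataFrame(kept_rows).reset_index(drop=True)
        if kept_rows else pd.DataFrame(columns=["feature", "r", "p"]),
        removed_nonsignificant=pd.DataFrame(columns=["feature", "r", "p"]),
        removed_redundant=pd.DataFrame(
            removed_rows, columns=["feature", "culprit", "pairwise_r"]
        ),
    )


def screen(
    features: pd.DataFrame,
    yields: pd.Series,
    alpha: float = 0.05,
    threshold: float = 0.7,
) -> SelectionResult:
    """Full two-step screening: significance filter then greedy decorrelation."""
    ranked = significance_filter(features, yields, alpha=alpha)
    y = yields.loc[features.index].to_numpy(dtype=float)
    r_all, p_all, _ = _columnwise_pearson(features, y)
    all_table = pd.DataFrame({"feature": features.columns, "r": r_all, "p": p_all})
    nonsig = all_table[~all_table["feature"].isin(ranked["feature"])]
    result = greedy_decorrelate(features, ranked, threshold=threshold)
    result.removed_nonsignificant = nonsig.reset_index(drop=True)
    return result
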