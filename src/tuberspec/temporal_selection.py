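"""Search over contiguous measurement-day windows and aggregation statistics.

Per-plant feature tables exist for each measurement day d1..dn. A candidate
temporal aggregation is a contiguous window of day ordinals plus a summary
statistic (sum, mean or max) applied elementwise across the window's days;
single-day windows pass that day's values through verbatim. Each candidate
is scored by the bootstrap RMSE of a random-forest regression of yield on
the aggregated features (mean RMSE over out-of-bag plants across resamples,
with a 2.5/97.5 percentile interval), and the candidate with the lowest
point RMSE wins. With six usable days the search space is 21 windows x 3
statistics = 63 candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

STATISTICS = ("max", "mean", "sum")  # order is also the tie-break preference


class DesignError(ValueError):
    """Invalid search design (no usable days, unknown statistic, ...)."""


@dataclass(frozen=True, order=True)
class WindowSpec:
    """Contiguous day-ordinal interval [start, end], 1-based inclusive."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise DesignError(f"invalid window [{self.start}, {self.end}]")

    @property
    def days(self) -> tuple[int, ...]:
        return tuple(range(self.start, self.end + 1))

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"d{self.start}" if self.start == self.end else \
            f"d{self.start}-d{self.end}"


@dataclass
class RFParams:
    """Random-forest scoring parameters.

    Defaults follow the caret bootstrap convention (25 resamples, 500
    trees, mtry = p/3 for regression). Searches over many candidates on a
    single CPU typically run with smaller forests; see
    :data:`DESK_RF_PARAMS`.
    """

    n_boot: int = 25
    n_trees: int = 500
    mtry: float | str = "third"  # "third", "sqrt", int or float fraction
    min_samples_leaf: int = 5

    def max_features(self, n_features: int):
        if self.mtry == "third":
            return max(1, n_features // 3)
        return self.mtry


#: reduced parameters for desk-scale searches (documented in the methods note)
DESK_RF_PARAMS = RFParams(n_boot=12, n_trees=15, mtry="sqrt")


@dataclass
class AggregationChoice:
    """One scored (window, statistic) candidate."""

    window: WindowSpec
    statistic: str
    rmse_point: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if self.statistic not in STATISTICS:
            raise DesignError(f"unknown statistic {self.statistic!r}")
        if self.ci_low > self.ci_high:
            raise DesignError("ci_low exceeds ci_high")


def enumerate_windows(
    n_days: int, excluded_days: Sequence[int] | set[int] = ()
) -> list[WindowSpec]:
    """All contiguous intervals over the non-excluded day ordinals.

    Excluded ordinals (e.g. a day measured in only one year) are removed
    from the *end* of the usable sequence; for m usable days the count is
    m(m+1)/2.
    """
    if n_days < 1:
        raise DesignError("n_days must be >= 1")
    usable = [d for d in range(1, n_days + 1) if d not in set(excluded_days)]
    if not usable:
        raise DesignError("all measurement days excluded")
    windows: list[WindowSpec] = []
    for i, start in enumerate(usable):
        for end in usable[i:]:
            if end - start == usable.index(end) - i:  # contiguous in usable set
                windows.append(WindowSpec(start, end))
    return windows


def aggregate(
    day_tables: Mapping[int, pd.DataFrame], window: WindowSpec, statistic: str
) -> pd.DataFrame:
    """Elementwise summary of per-day feature tables across a window.

    Plants missing any day in the window are dropped (with a warning when
    that happens); a single-day window returns that day's table verbatim.
    """
    if statistic not in STATISTICS:
        raise DesignError(f"unknown statistic {statistic!r}")
    missing = [d for d in window.days if d not in day_tables]
    if missing:
        raise DesignError(f"no feature table for day(s) {missing}")
    tables = [day_tables[d] for d in window.days]
    common = tables[0].index
    for t in tables[1:]:
        common = common.intersection(t.index)
    n_dropped = max(len(t.index) for t in tables) - len(common)
    if n_dropped:
        import warnings

        warnings.warn(f"{n_dropped} plants missing a day in {window}; dropped")
    aligned = [t.loc[common] for t in tables]
    if len(aligned) == 1:
        return aligned[0].copy()
    stack = np.stack([t.to_numpy(dtype=float) for t in aligned])
    if statistic == "sum":
        agg = stack.sum(axis=0)
    elif statistic == "mean":
        agg = stack.mean(axis=0)
    else:
        agg = stack.max(axis=0)
    return pd.DataFrame(agg, index=common, columns=tables[0].columns)


def score_choice(
    features: pd.DataFrame,
    yields: pd.Series,
    window: WindowSpec,
    statistic: str,
    rf_params: RFParams | None = None,
    seed: int = 0,
) -> AggregationChoice:
    """Bootstrap random-forest RMSE for one aggregated feature table.

    Each resample fits a forest on a bootstrap draw of plants and evaluates
    RMSE on the out-of-bag plants; the point estimate is the mean resample
    RMSE and the interval the 2.5th/97.5th percentiles.
    """
    rf_params = rf_params if rf_params is not None else RFParams()
    if rf_params.n_boot < 2:
        raise DesignError("n_boot must be >= 2")
    features = features.sort_index()  # canonical row order: plant-order invariant
    X = features.to_numpy(dtype=float)
    y = yields.loc[features.index].to_numpy(dtype=float)
    n = len(y)
    if n < 20:
        raise DesignError(f"need at least 20 plants, got {n}")
    if np.isnan(X).any():
        raise DesignError("feature table contains missing cells")
    rng = np.random.default_rng(seed)
    rmses = []
    for b in range(rf_params.n_boot):
        idx = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), idx)
        if oob.size == 0:  # pathologically small n; resample
            continue
        model = RandomForestRegressor(
            n_estimators=rf_params.n_trees,
            max_features=rf_params.max_features(X.shape[1]),
            min_samples_leaf=rf_params.min_samples_leaf,
            random_state=int(rng.integers(0, 2**31 - 1)),
            n_jobs=1,
        )
        model.fit(X[idx], y[idx])
        pred = model.predict(X[oob])
        rmses.append(float(np.sqrt(np.mean((y[oob] - pred) ** 2))))
    rmses_arr = np.asarray(rmses)
    return AggregationChoice(
        window=window,
        statistic=statistic,
        rmse_point=float(rmses_arr.mean()),
        ci_low=float(np.percentile(rmses_arr, 2.5)),
        ci_high=float(np.percentile(rmses_arr, 97.5)),
    )


def _tie_key(choice: AggregationChoice) -> tuple:
    return (
        round(choice.rmse_point, 9),
        choice.window.length,
        choice.window.start,
        STATISTICS.index(choice.statistic),
    )


def select_best(
    day_tables: Mapping[int, pd.DataFrame],
    yields: pd.Series,
    n_days: int | None = None,
    excluded_days: Sequence[int] = (),
    statistics: Sequence[str] = STATISTICS,
    rf_params: RFParams | None = None,
    seed: int = 0,
) -> tuple[AggregationChoice, pd.DataFrame]:
    """Score every (window, statistic) candidate and return the winner.

    Ties in point RMSE break toward the shorter window, then the earlier
    start, then the statistic order max > mean > sum. Also returns the full
    results table (one row per candidate).
    """
    n_days = n_days if n_days is not None else max(day_tables)
    windows = enumerate_windows(n_days, excluded_days)
    results: list[AggregationChoice] = []
    for wi, window in enumerate(windows):
        for si, stat in enumerate(statistics):
            feats = aggregate(day_tables, window, stat)
            results.append(score_choice(
                feats, yields, window, stat, rf_params=rf_params,
                seed=seed + 1000 * wi + si,
            ))
    best = min(results, key=_tie_key)
    table = pd.DataFrame(
        {
            "window": [str(c.window) for c in results],
            "start": [c.window.start for c in results],
            "end": [c.window.end for c in results],
            "statistic": [c.statistic for c in results],
            "rmse_point": [c.rmse_point for c in results],
            "ci_low": [c.ci_low for c in results],
            "ci_high": [c.ci_high for c in results],
        }
    )
    return best, table
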