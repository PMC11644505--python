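"""Pearson screening and greedy decorrelation, with a brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

from tuberspec.feature_selection import (
    DegenerateInputError, greedy_decorrelate, pearson_with_p, screen,
    significance_filter,
)


def brute_force_decorrelate(features: pd.DataFrame, ranked_names, threshold):
    """Independent replay of the top-down rule using a full pairwise matrix."""
    corr = features.corr().abs()
    kept = []
    removed = []
    for name in ranked_names:
        offender = next((k for k in kept if corr.loc[name, k] > threshold), None)
        if offender is None:
            kept.append(name)
        else:
            removed.append((name, offender))
    return kept, removed


def _correlated_triplet(n=50):
    """Columns A, B, C with controlled correlations and a response y.

    Construction mixes orthonormal basis vectors so that r(A,B)=0.8,
    r(A,C)=0.2, r(B,C)~0.3 and |r_y| ranks A > B > C.
    """
    rng = np.random.default_rng(0)
    raw = rng.normal(size=(n, 4))
    raw -= raw.mean(axis=0)  # center so Pearson r equals the dot products
    q, _ = np.linalg.qr(raw)
    u1, u2, u3, u4 = q.T
    A = u1
    B = 0.8 * u1 + 0.6 * u2
    a, b = 0.2, (0.3 - 0.8 * 0.2) / 0.6
    c = np.sqrt(1 - a**2 - b**2)
    C = a * u1 + b * u2 + c * u3
    al = 0.9
    be = (0.8 - 0.8 * al) / 0.6
    ga = (0.5 - a * al - b * be) / c
    de = np.sqrt(1 - al**2 - be**2 - ga**2)
    y = al * u1 + be * u2 + ga * u3 + de * u4
    X = pd.DataFrame({"A": A, "B": B, "C": C})
    return X, pd.Series(y, index=X.index)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10, dtype=float)
        r, p = pearson_with_p(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-12

    def test_exact_orthogonal(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=10)
        v = rng.normal(size=10)
        xc = x - x.mean()
        y = v - v.mean()
        y = y - (y @ xc) / (xc @ xc) * xc  # project out x exactly
        r, p = pearson_with_p(x, y)
        assert abs(r) < 1e-12
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_matches_covariance_definition(self):
        x = np.array([1.0, 4.0, 2.0, 8.0, 5.0, 7.0, 3.0, 6.0])
        y = np.array([2.0, 3.0, 1.0, 9.0, 4.0, 8.0, 2.5, 5.0])
        r, _ = pearson_with_p(x, y)
        brute = (
            np.sum((x - x.mean()) * (y - y.mean()))
            / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        )
        assert r == pytest.approx(brute, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            pearson_with_p(np.ones(5), np.arange(5.0))


class TestSignificanceFilter:
    def test_noise_keeps_about_alpha_fraction(self):
        rng = np.random.default_rng(3)
        n, p = 200, 800
        X = pd.DataFrame(rng.normal(size=(n, p)),
                         columns=[f"f{j}" for j in range(p)])
        y = pd.Series(rng.normal(size=n), index=X.index)
        kept = significance_filter(X, y, alpha=0.05)
        frac = len(kept) / p
        # binomial 4-sigma band around 0.05
        assert abs(frac - 0.05) < 4 * np.sqrt(0.05 * 0.95 / p)

    def test_planted_feature_ranked_first(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 120
            X = pd.DataFrame(rng.normal(size=(n, 30)),
                             columns=[f"f{j}" for j in range(30)])
            y = pd.Series(2.0 * X["f7"].to_numpy() + rng.normal(0, 0.8, n),
                          index=X.index)
            kept = significance_filter(X, y)
            if len(kept) and kept["feature"].iloc[0] == "f7":
                hits += 1
        assert hits >= 9

    def test_alpha_zero_empty(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 5)))
        X.columns = [f"f{j}" for j in range(5)]
        y = pd.Series(rng.normal(size=30), index=X.index)
        with pytest.warns(UserWarning, match="no features"):
            assert significance_filter(X, y, alpha=0.0).empty

    def test_ranking_descends_in_abs_r(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 20)))
        X.columns = [f"f{j}" for j in range(20)]
        y = pd.Series(X["f0"].to_numpy() + rng.normal(0, 1, 60), index=X.index)
        kept = significance_filter(X, y, alpha=0.5)
        r = kept["r"].abs().to_numpy()
        assert (np.diff(r) <= 1e-15).all()


class TestGreedyDecorrelate:
    def test_hand_traced_example(self):
        X, y = _correlated_triplet()
        ranked = significance_filter(X, y, alpha=0.05)
        assert list(ranked["feature"]) == ["A", "B", "C"]
        result = greedy_decorrelate(X, ranked, threshold=0.7)
        assert result.kept_names == ["A", "C"]
        removed = result.removed_redundant
        assert list(removed["feature"]) == ["B"]
        assert list(removed["culprit"]) == ["A"]
        assert removed["pairwise_r"].iloc[0] == pytest.approx(0.8, abs=1e-9)

    def test_all_below_threshold_identity(self, rng):
        q, _ = np.linalg.qr(rng.normal(size=(40, 6)))
        X = pd.DataFrame(q, columns=[f"f{j}" for j in range(6)])
        y = pd.Series(q.sum(axis=1), index=X.index)
        ranked = significance_filter(X, y, alpha=1.0)
        result = greedy_decorrelate(X, ranked, threshold=0.7)
        assert set(result.kept_names) == set(X.columns)

    def test_duplicate_column_removed(self, rng):
        base = rng.normal(size=50)
        X = pd.DataFrame({"orig": base, "copy": base.copy(),
                          "other": rng.normal(size=50)})
        y = pd.Series(base + rng.normal(0, 0.3, 50), index=X.index)
        result = screen(X, y, alpha=0.9)
        assert "copy" not in result.kept_names or "orig" not in result.kept_names
        assert len(result.removed_redundant) >= 1
        assert result.removed_redundant["pairwise_r"].abs().iloc[0] == \
            pytest.approx(1.0)

    def test_invalid_threshold_rejected(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=10)})
        ranked = pd.DataFrame({"feature": ["a"], "r": [0.5], "p": [0.01]})
        with pytest.raises(ValueError, match="threshold"):
            greedy_decorrelate(X, ranked, threshold=1.5)

    def test_kept_set_is_maximal_greedy(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 10)) @ rng.normal(size=(10, 10)))
        X.columns = [f"f{j}" for j in range(10)]
        y = pd.Series(rng.normal(size=60), index=X.index)
        result = screen(X, y, alpha=1.0, threshold=0.5)
        corr = X.corr().abs()
        for feat in result.removed_redundant["feature"]:
            assert any(
                corr.loc[feat, k] > 0.5 for k in result.kept_names
            ), feat

    def test_threshold_one_removes_only_exact_duplicates(self, rng):
        base = rng.normal(size=50)
        X = pd.DataFrame({
            "a": base, "b": 0.9 * base + rng.normal(0, 0.5, 50),
            "c": rng.normal(size=50),
        })
        y = pd.Series(base + rng.normal(0, 1, 50), index=X.index)
        result = screen(X, y, alpha=1.0, threshold=1.0)
        assert set(result.kept_names) == {"a", "b", "c"}

    def test_every_removal_exceeds_threshold(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 8)) @ rng.normal(size=(8, 8)))
        X.columns = [f"f{j}" for j in range(8)]
        y = pd.Series(rng.normal(size=50), index=X.index)
        for t in (0.3, 0.5, 0.7):
            result = screen(X, y, alpha=1.0, threshold=t)
            if len(result.removed_redundant):
                assert (result.removed_redundant["pairwise_r"].abs() > t).all()

    @pytest.mark.parametrize("n_feats", [3, 8, 12])
    def test_matches_brute_force_oracle(self, n_feats):
        for seed in range(25):
            rng = np.random.default_rng(seed)
            mix = rng.normal(size=(n_feats, n_feats))
            X = pd.DataFrame(rng.normal(size=(40, n_feats)) @ mix,
                             columns=[f"f{j}" for j in range(n_feats)])
            y = pd.Series(rng.normal(size=40), index=X.index)
            ranked = significance_filter(X, y, alpha=1.0)
            result = greedy_decorrelate(X, ranked, threshold=0.7)
            kept, removed = brute_force_decorrelate(
                X, list(ranked["feature"]), 0.7
            )
            assert result.kept_names == kept
            assert list(result.removed_redundant["feature"]) == \
                [r[0] for r in removed]
            assert list(result.removed_redundant["culprit"]) == \
                [r[1] for r in removed]


class TestScreen:
    def test_partition_of_input_features(self, rng):
        X = pd.DataFrame(rng.normal(size=(80, 15)) @ rng.normal(size=(15, 15)))
        X.columns = [f"f{j}" for j in range(15)]
        y = pd.Series(X["f0"].to_numpy() + rng.normal(0, 2, 80), index=X.index)
        result = screen(X, y)
        names = (
            set(result.kept_names)
            | set(result.removed_nonsignificant["feature"])
            | set(result.removed_redundant["feature"])
        )
        assert names == set(X.columns)
        total = (len(result.kept) + len(result.removed_nonsignificant)
                 + len(result.removed_redundant))
        assert total == 15
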