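"""Spectral data model: IO round-trips, averaging, resampling and masking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tuberspec.spectra import (
    DEFAULT_MASK_RANGES, MaskSpec, PlantRecord, SpectrumError, SpectrumSample,
    TARGET_GRID, apply_mask, average_replicates, exclude_damaged,
    read_spectrum_csv, resample_to_1nm, retained_band_count, write_spectrum_csv,
)


def _sample(wl, refl, **meta):
    defaults = dict(plant_id="p1", variety="V", plot="A", year=2020, dap=50,
                    day_index=1)
    defaults.update(meta)
    return SpectrumSample(wavelengths=np.asarray(wl, float),
                          reflectance=np.asarray(refl, float), **defaults)


class TestReadWrite:
    def test_three_row_file(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("350,0.1\n351,0.2\n352,0.1\n")
        s = read_spectrum_csv(p, plant_id="x")
        assert s.n_bands == 3
        assert np.allclose(s.reflectance, [0.1, 0.2, 0.1])

    def test_reflectance_out_of_unit_interval_rejected(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("350,0.5\n351,1.2\n352,0.1\n")
        with pytest.raises(SpectrumError, match=r"\[0, 1\]"):
            read_spectrum_csv(p)

    def test_non_numeric_reports_line_number(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("350,0.5\n351,oops\n")
        with pytest.raises(SpectrumError, match=":2:"):
            read_spectrum_csv(p)

    def test_duplicate_wavelength_rejected(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("350,0.5\n350,0.6\n351,0.1\n")
        with pytest.raises(SpectrumError, match="non-monotone"):
            read_spectrum_csv(p)

    def test_round_trip(self, tmp_path):
        s = _sample([350, 400.5, 2500], [0.1, 0.25, 0.9])
        path = tmp_path / "out" / "s.csv"
        write_spectrum_csv(s, path)
        back = read_spectrum_csv(path)
        assert back.plant_id == s.plant_id
        assert back.year == s.year and back.day_index == s.day_index
        np.testing.assert_allclose(back.wavelengths, s.wavelengths)
        np.testing.assert_allclose(back.reflectance, s.reflectance)


class TestAverageReplicates:
    def test_single_sample_identity(self):
        s = _sample([350, 351], [0.2, 0.3])
        out = average_replicates([s])
        np.testing.assert_array_equal(out.reflectance, s.reflectance)

    def test_two_sample_mean(self):
        a = _sample([350, 351], [0.2, 0.2])
        b = _sample([350, 351], [0.4, 0.4])
        np.testing.assert_allclose(average_replicates([a, b]).reflectance, 0.3)

    def test_five_replicates_match_per_band_mean(self, rng):
        wl = np.arange(350, 360, dtype=float)
        reps = [_sample(wl, rng.uniform(0, 1, wl.size)) for _ in range(5)]
        out = average_replicates(reps)
        brute = np.array([
            np.mean([r.reflectance[i] for r in reps]) for i in range(wl.size)
        ])
        np.testing.assert_allclose(out.reflectance, brute, atol=1e-15)

    def test_grid_mismatch_rejected(self):
        a = _sample([350, 351], [0.2, 0.2])
        b = _sample([350, 352], [0.4, 0.4])
        with pytest.raises(SpectrumError, match="grids differ"):
            average_replicates([a, b])


class TestResample:
    def test_integer_grid_unchanged(self):
        s = _sample(TARGET_GRID, np.linspace(0.1, 0.9, TARGET_GRID.size))
        out = resample_to_1nm(s)
        np.testing.assert_array_equal(out.reflectance, s.reflectance)

    def test_linear_midpoint(self):
        s = _sample([350.0, 2500.0], [0.0, 1.0])
        out = resample_to_1nm(s)
        assert out.reflectance[np.where(out.wavelengths == 1425)[0][0]] == \
            pytest.approx(0.5)

    def test_output_length_2151(self):
        s = _sample([350.0, 1000.0, 2500.0], [0.1, 0.5, 0.2])
        assert resample_to_1nm(s).n_bands == 2151

    def test_insufficient_span_rejected(self):
        s = _sample([400.0, 2500.0], [0.0, 1.0])
        with pytest.raises(SpectrumError, match="cover"):
            resample_to_1nm(s)


class TestMask:
    def _grid_sample(self):
        return _sample(TARGET_GRID, np.full(TARGET_GRID.size, 0.5))

    def test_default_mask_retains_1678(self):
        out = apply_mask(self._grid_sample())
        assert out.n_bands == 1678
        assert retained_band_count() == 1678

    def test_empty_mask_keeps_all(self):
        out = apply_mask(self._grid_sample(), MaskSpec([]))
        assert out.n_bands == 2151

    def test_single_interval_inclusive_count(self):
        out = apply_mask(self._grid_sample(), MaskSpec([(1350, 1460)]))
        assert out.n_bands == 2151 - 111

    def test_masking_pure_subsetting_and_idempotent(self, rng):
        s = _sample(TARGET_GRID, rng.uniform(0, 1, TARGET_GRID.size))
        once = apply_mask(s)
        twice = apply_mask(once)
        np.testing.assert_array_equal(once.reflectance, twice.reflectance)
        keep = MaskSpec().keep_mask(s.wavelengths)
        np.testing.assert_array_equal(once.reflectance, s.reflectance[keep])

    def test_disjoint_intervals_commute(self, rng):
        s = _sample(TARGET_GRID, rng.uniform(0, 1, TARGET_GRID.size))
        ab = apply_mask(apply_mask(s, MaskSpec([(1350, 1460)])),
                        MaskSpec([(1790, 2000)]))
        ba = apply_mask(apply_mask(s, MaskSpec([(1790, 2000)])),
                        MaskSpec([(1350, 1460)]))
        np.testing.assert_array_equal(ab.reflectance, ba.reflectance)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(
        st.tuples(st.integers(350, 2400), st.integers(0, 80)),
        min_size=0, max_size=4,
    ))
    def test_retained_count_identity(self, raw):
        # build sorted non-overlapping inclusive intervals
        intervals = []
        cursor = 350
        for start, width in sorted(raw):
            a = max(start, cursor)
            b = min(a + width, 2500)
            if a > 2500 or b < a:
                continue
            intervals.append((a, b))
            cursor = b + 2
        mask = MaskSpec(intervals)
        expected = 2151 - sum(b - a + 1 for a, b in intervals)
        assert retained_band_count(mask) == expected

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(SpectrumError, match="overlap"):
            MaskSpec([(1350, 1460), (1400, 1500)])


class TestPlantRecordAndExclusion:
    def _rec(self, pid, damaged=False):
        return PlantRecord(plant_id=pid, variety="V", plot="A", year=2020,
                           yield_g=1000.0, n_tubers=5, n_large=1, n_medium=3,
                           n_small=1, rodent_damaged=damaged)

    def test_caliber_counts_must_sum(self):
        with pytest.raises(ValueError, match="caliber"):
            PlantRecord(plant_id="p", variety="V", plot="A", year=2020,
                        yield_g=1.0, n_tubers=4, n_large=1, n_medium=1,
                        n_small=1, rodent_damaged=False)

    def test_no_flags_identity(self):
        recs = [self._rec("a"), self._rec("b")]
        s = [_sample([350, 351], [0.1, 0.2], plant_id="a")]
        kept_r, kept_s = exclude_damaged(recs, s)
        assert [r.plant_id for r in kept_r] == ["a", "b"]
        assert len(kept_s) == 1

    def test_all_flagged_warns_and_empties(self):
        recs = [self._rec("a", True), self._rec("b", True)]
        with pytest.warns(UserWarning, match="all plants"):
            kept_r, kept_s = exclude_damaged(recs, [])
        assert kept_r == [] and kept_s == []

    def test_default_rodent_rate_near_expectation(self):
        # binomial mean 0.27 * 360 = 97.2; average over 5 generator seeds
        from tuberspec.synthetic_field import FieldConfig, generate_field

        counts = []
        for seed in range(5):
            _, records, _ = generate_field(FieldConfig(
                seed=seed, noise_sd_reflectance=0.0, n_replicates=1,
                measurement_daps=[[46], [55]], coupling_window=(1, 1),
            ))
            counts.append(sum(r.rodent_damaged for r in records))
        mean = np.mean(counts)
        # 4 sigma band for the mean of 5 binomial draws
        se = np.sqrt(360 * 0.27 * 0.73 / 5)
        assert abs(mean - 97.2) < 4 * se
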