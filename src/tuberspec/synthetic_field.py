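"""Synthetic two-year potato field trial with a known spectra-yield coupling.

The generator emulates the design of a per-plant handheld-spectroradiometer
campaign: two years, three plots per year, six varieties with ten plants per
variety per plot (360 plants), six or seven measurement days per year at
fixed days-after-planting (DAP), a per-plant tuber yield around 2.4 kg with
variety/plot/plant heterogeneity, and roughly 27 % of plants flagged for
rodent damage.

Reflectance curves come from a smooth parametric canopy template (mixtures
of sigmoids and Gaussians over a soil background) driven by three latent
proxies: chlorophyll, water and fractional canopy cover. The chlorophyll
trajectory rises logistically after emergence and senesces late in the
season; its seasonal *amplitude* is an affine function of the plant's final
tuber yield plus latent noise, so red-edge and chlorophyll-sensitive
features are most informative in mid-season (the coupling window). The
canopy water amplitude is a second, independently noisy channel affine in
yield, so SWIR water features carry complementary signal. Because yield
reaches the spectra only through these two amplitudes, the irreducible
error of any spectra-based yield model is known exactly. The template is
deliberately simple plumbing, not a radiative-transfer model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .spectra import PlantRecord, SpectrumSample, records_to_frame, write_spectrum_csv

DEFAULT_VARIETIES = ("Spunta", "Sifra", "Lucinda", "Fabula", "Agria", "Rudolf")
#: measurement days (DAP) for each year, ranked; year 1 has six days, year 2 seven
DEFAULT_DAPS = (
    (46, 56, 86, 93, 100, 107),
    (55, 62, 81, 91, 98, 109, 118),
)
FIRST_YEAR = 2020

#: ASD-style native sampling: 1.4 nm below 1000 nm, 2 nm above
INSTRUMENT_GRID = np.concatenate(
    [np.arange(350.0, 1000.0, 1.4), np.arange(1000.0, 2500.0 + 1e-9, 2.0)]
)


class ConfigurationError(ValueError):
    """Invalid generator configuration; message names the offending field."""


@dataclass
class FieldConfig:
    """Study-design and coupling parameters of the synthetic trial."""

    n_years: int = 2
    plots_per_year: int = 3
    varieties: Sequence[str] = DEFAULT_VARIETIES
    plants_per_variety_per_plot: int = 10
    measurement_daps: Sequence[Sequence[int]] = DEFAULT_DAPS
    mean_yield_g: float = 2400.0
    variety_sd_g: float = 500.0
    plot_sd_g: float = 250.0
    plant_sd_g: float = 550.0
    rodent_fraction: float = 0.27
    coupling_window: tuple[int, int] = (2, 5)  # 1-based day ordinals
    coupling_strength: float = 0.25
    amplitude_base: float = 2.0
    amplitude_noise_sd: float = 0.45
    water_coupling_strength: float = 0.25
    water_noise_sd: float = 0.3
    phenology_jitter_sd_days: float = 4.0
    brightness_jitter_sd: float = 0.0
    noise_sd_reflectance: float = 0.01
    n_replicates: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_years", "plots_per_year", "plants_per_variety_per_plot",
                     "n_replicates"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if not self.varieties:
            raise ConfigurationError("varieties must be non-empty")
        if not 0.0 <= self.rodent_fraction <= 1.0:
            raise ConfigurationError("rodent_fraction must lie in [0, 1]")
        if len(self.measurement_daps) < self.n_years:
            raise ConfigurationError(
                "measurement_daps must provide a day list for every year"
            )
        for daps in self.measurement_daps:
            if list(daps) != sorted(set(daps)):
                raise ConfigurationError(
                    "measurement_daps must be strictly increasing within a year"
                )
        lo, hi = self.coupling_window
        shortest = min(len(d) for d in self.measurement_daps[: self.n_years])
        if not (1 <= lo <= hi <= shortest):
            raise ConfigurationError(
                "coupling_window indices must be valid for the shortest year"
            )
        if self.noise_sd_reflectance < 0:
            raise ConfigurationError("noise_sd_reflectance must be >= 0")

    @property
    def yield_sd_nominal(self) -> float:
        """Nominal total yield SD used to scale the amplitude coupling."""
        return float(
            np.sqrt(self.variety_sd_g**2 + self.plot_sd_g**2 + self.plant_sd_g**2)
        )


@dataclass
class CanopyState:
    """Latent drivers of the reflectance template at one moment."""

    chlorophyll_proxy: float
    water_proxy: float
    cover_proxy: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.chlorophyll_proxy, self.water_proxy,
                            self.cover_proxy]).all():
            raise ConfigurationError("canopy state fields must be finite")
        if self.chlorophyll_proxy < 0 or self.water_proxy < 0:
            raise ConfigurationError("chlorophyll/water proxies must be >= 0")
        if not 0.0 <= self.cover_proxy <= 1.0:
            raise ConfigurationError("cover_proxy must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Latent quantities the generator drew, for downstream recovery checks."""

    config: FieldConfig
    plant_ids: list[str]
    yields_g: np.ndarray
    amplitudes: np.ndarray        # chlorophyll seasonal amplitude A_i
    amplitude_noise: np.ndarray   # latent noise eps_i in A_i
    water_amplitudes: np.ndarray  # canopy water amplitude W_i
    variety_effects: dict[str, float]
    plot_effects: dict[str, float]
    rise_days: np.ndarray
    senescence_days: np.ndarray
    coupling_window: tuple[int, int]
    coupling_slope_per_g: float   # dA/dyield

    def noise_floor_g(self, plant_ids: Sequence[str] | None = None) -> float:
        """Irreducible RMSE of the best linear yield predictor.

        Spectra depend on yield only through the chlorophyll and water
        amplitudes (A, W), so no model reading spectra can beat an OLS of
        yield on the true amplitudes. Returns the residual RMSE of that
        regression over the given plants (default: all), the benchmark for
        LOOCV error of the fitted pipeline.
        """
        idx = np.arange(len(self.plant_ids))
        if plant_ids is not None:
            wanted = set(plant_ids)
            idx = np.array(
                [i for i, p in enumerate(self.plant_ids) if p in wanted], dtype=int
            )
        a = self.amplitudes[idx]
        w = self.water_amplitudes[idx]
        y = self.yields_g[idx]
        X = np.column_stack([np.ones_like(a), a, w])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return float(np.sqrt(np.mean(resid**2)))


# ---------------------------------------------------------------------------
# reflectance template
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


#: spectral correlation length of instrument noise (nm). Field-spectrometer
#: noise is smooth across neighbouring bands (detector + export smoothing),
#: not independent per 1 nm sample; this is what lets a redundancy filter
#: collapse adjacent bands.
NOISE_CORRELATION_NM = 20.0


def _correlated_noise(
    rng: np.random.Generator, shape: tuple, wavelengths: np.ndarray, sd: float
) -> np.ndarray:
    """Gaussian noise smooth along the wavelength axis, marginal SD ``sd``."""
    from scipy.ndimage import gaussian_filter1d

    if sd == 0.0:
        return np.zeros(shape)
    white = rng.normal(0.0, 1.0, size=shape)
    step = float(np.median(np.diff(wavelengths)))
    sigma = NOISE_CORRELATION_NM / max(step, 1e-9)
    smooth = gaussian_filter1d(white, sigma=sigma, axis=-1, mode="nearest")
    # restore unit marginal variance after smoothing, then scale to sd
    gain = float(np.sqrt(2.0 * sigma * np.sqrt(np.pi)))
    return smooth * gain * sd


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-(((wl - center) / width) ** 2))


def reflectance_template(
    chl: np.ndarray, water: np.ndarray, cover: np.ndarray, wavelengths: np.ndarray
) -> np.ndarray:
    """Noise-free canopy reflectance for latent states (vectorised).

    ``chl``/``water``/``cover`` broadcast against each other; the result has
    shape ``state_shape + (n_wavelengths,)``. The vegetation curve has a
    green peak near 550 nm, a red absorption well at 670 nm deepening with
    chlorophyll, a red-edge inflection between 700 and 750 nm shifting to
    longer wavelengths with chlorophyll, a NIR plateau, and SWIR water dips
    near 1450/1940 nm deepening with the water proxy. The soil baseline is a
    gentle upward slope; the two mix by fractional cover.
    """
    wl = np.asarray(wavelengths, dtype=float)
    if wl.min() < 350.0 or wl.max() > 2500.0:
        raise ConfigurationError("wavelengths must lie within [350, 2500] nm")
    chl = np.asarray(chl, dtype=float)[..., None]
    water = np.asarray(water, dtype=float)[..., None]
    cover = np.asarray(cover, dtype=float)[..., None]

    absorb = chl / (chl + 1.2)  # saturating pigment absorption in (0, 1)
    vis = (
        0.30
        - 0.24 * absorb * (0.85 * _gauss(wl, 670.0, 42.0) + 0.9 * _gauss(wl, 450.0, 40.0))
        + 0.10 * (1.0 - 0.5 * absorb) * _gauss(wl, 550.0, 25.0)
    )
    red_edge_pos = 700.0 + 20.0 * chl / (chl + 2.0)
    s_re = _sigmoid((wl - red_edge_pos) / 14.0)
    nir = (
        0.48 * (1.0 - 0.10 * np.clip((wl - 800.0) / 1700.0, 0.0, None))
        - water * (
            0.20 * _gauss(wl, 1450.0, 55.0)
            + 0.26 * _gauss(wl, 1940.0, 70.0)
            + 0.05 * _gauss(wl, 1200.0, 45.0)
            + 0.03 * _gauss(wl, 970.0, 35.0)
        )
        - 0.10 * _sigmoid((wl - 2200.0) / 120.0)
    )
    veg = vis * (1.0 - s_re) + nir * s_re
    soil = (
        0.12
        + 0.16 * (wl - 350.0) / 2150.0
        - 0.03 * _gauss(wl, 1940.0, 90.0)
        - 0.02 * _gauss(wl, 1450.0, 70.0)
    )
    mixed = cover * veg + (1.0 - cover) * soil
    return np.clip(mixed, 0.0, 1.0)


def canopy_reflectance(
    state: CanopyState,
    wavelengths: np.ndarray,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Reflectance vector for one canopy state, with optional Gaussian noise."""
    clean = reflectance_template(
        np.float64(state.chlorophyll_proxy),
        np.float64(state.water_proxy),
        np.float64(state.cover_proxy),
        wavelengths,
    )
    if noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng(0)
        clean = clean + _correlated_noise(
            rng, clean.shape, np.asarray(wavelengths, float), noise_sd
        )
    return np.clip(clean, 0.0, 1.0)


# ---------------------------------------------------------------------------
# phenology
# ---------------------------------------------------------------------------

def _phenology_anchor_days(config: FieldConfig, daps: Sequence[int]) -> tuple[float, float]:
    """Mean green-up and senescence day placing peak canopy in the window."""
    lo, hi = config.coupling_window
    daps = list(daps)
    rise = (daps[lo - 1] + daps[lo - 2]) / 2.0 if lo > 1 else daps[0] - 6.0
    sen = (daps[hi - 1] + daps[hi]) / 2.0 if hi < len(daps) else daps[-1] + 6.0
    return rise, sen


def _growth_curve(dap: np.ndarray, rise: np.ndarray, sen: np.ndarray) -> np.ndarray:
    return _sigmoid((dap - rise) / 5.0) * _sigmoid((sen - dap) / 5.0)


# ---------------------------------------------------------------------------
# field generation
# ---------------------------------------------------------------------------

def generate_field(
    config: FieldConfig | None = None,
) -> tuple[list[SpectrumSample], list[PlantRecord], GroundTruth]:
    """Draw the full synthetic trial: spectra, harvest records, ground truth.

    Identical config (including seed) gives byte-identical output.
    """
    config = config if config is not None else FieldConfig()
    rng = np.random.default_rng(config.seed)

    varieties = list(config.varieties)
    variety_effects = {
        v: e for v, e in zip(varieties, rng.normal(0.0, config.variety_sd_g,
                                                   len(varieties)))
    }

    samples: list[SpectrumSample] = []
    records: list[PlantRecord] = []
    plant_ids: list[str] = []
    yields_all: list[float] = []
    amps_all: list[float] = []
    eps_all: list[float] = []
    water_all: list[float] = []
    rise_all: list[float] = []
    sen_all: list[float] = []
    plot_effects: dict[str, float] = {}

    sigma_nominal = config.yield_sd_nominal
    slope = config.coupling_strength * config.amplitude_base / sigma_nominal

    for yi in range(config.n_years):
        year = FIRST_YEAR + yi
        daps = list(config.measurement_daps[yi])
        rise_mean, sen_mean = _phenology_anchor_days(config, daps)
        for pi in range(config.plots_per_year):
            plot = f"{year}-P{pi + 1}"
            plot_eff = float(rng.normal(0.0, config.plot_sd_g))
            plot_effects[plot] = plot_eff
            for v in varieties:
                n = config.plants_per_variety_per_plot
                plant_noise = rng.normal(0.0, config.plant_sd_g, n)
                rodent = rng.random(n) < config.rodent_fraction
                eps = rng.normal(0.0, config.amplitude_noise_sd, n)
                eta = rng.normal(0.0, config.water_noise_sd, n)
                rises = rise_mean + rng.normal(0.0, config.phenology_jitter_sd_days, n)
                sens = sen_mean + rng.normal(0.0, config.phenology_jitter_sd_days, n)
                y_vec = np.maximum(
                    0.0,
                    config.mean_yield_g + variety_effects[v] + plot_eff + plant_noise,
                )
                z_vec = (y_vec - config.mean_yield_g) / sigma_nominal
                water_base = np.maximum(
                    0.1, 1.0 + config.water_coupling_strength * z_vec + eta
                )
                for k in range(n):
                    pid = f"{year}-P{pi + 1}-{v}-{k + 1:02d}"
                    y_g = float(y_vec[k])
                    amp = max(
                        0.05,
                        config.amplitude_base
                        + slope * (y_g - config.mean_yield_g)
                        + float(eps[k]),
                    )
                    n_tubers = 1 + int(rng.poisson(max(y_g, 1.0) / 300.0))
                    n_large, n_medium, n_small = rng.multinomial(
                        n_tubers, [0.2, 0.6, 0.2]
                    )
                    records.append(PlantRecord(
                        plant_id=pid, variety=v, plot=plot, year=year,
                        yield_g=y_g, n_tubers=n_tubers, n_large=int(n_large),
                        n_medium=int(n_medium), n_small=int(n_small),
                        rodent_damaged=bool(rodent[k]),
                    ))
                    plant_ids.append(pid)
                    yields_all.append(y_g)
                    amps_all.append(amp)
                    eps_all.append(float(eps[k]))
                    water_all.append(float(water_base[k]))
                    rise_all.append(float(rises[k]))
                    sen_all.append(float(sens[k]))

                # spectra for this variety block, one day at a time
                block = records[-n:]
                for di, dap in enumerate(daps, start=1):
                    g = _growth_curve(np.full(n, float(dap)), rises, sens)
                    chl = np.asarray(amps_all[-n:]) * g
                    cov = np.clip(
                        0.95
                        * _sigmoid((dap - (rises - 8.0)) / 6.0)
                        * _sigmoid(((sens + 8.0) - dap) / 10.0),
                        0.0, 1.0,
                    )
                    wat = water_base * _sigmoid((dap - (rises - 4.0)) / 6.0) * _sigmoid(
                        ((sens + 4.0) - dap) / 8.0
                    )
                    clean = reflectance_template(chl, wat, cov, INSTRUMENT_GRID)
                    # optional illumination/geometry brightness jitter per
                    # plant-day: multiplicative, spectrally flat, uncoupled
                    # to yield (ratio indices cancel it); off by default
                    if config.brightness_jitter_sd > 0:
                        bright = np.maximum(
                            0.5,
                            rng.normal(1.0, config.brightness_jitter_sd, n),
                        )
                    else:
                        bright = np.ones(n)
                    noise = _correlated_noise(
                        rng, (config.n_replicates,) + clean.shape,
                        INSTRUMENT_GRID, config.noise_sd_reflectance,
                    ).mean(axis=0)
                    refl = np.clip(clean * bright[:, None] + noise, 0.0, 1.0)
                    for k, rec in enumerate(block):
                        samples.append(SpectrumSample(
                            plant_id=rec.plant_id, variety=v, plot=plot,
                            year=year, dap=int(dap), day_index=di,
                            wavelengths=INSTRUMENT_GRID.copy(),
                            reflectance=refl[k],
                        ))

    truth = GroundTruth(
        config=config,
        plant_ids=plant_ids,
        yields_g=np.asarray(yields_all),
        amplitudes=np.asarray(amps_all),
        amplitude_noise=np.asarray(eps_all),
        water_amplitudes=np.asarray(water_all),
        variety_effects=variety_effects,
        plot_effects=plot_effects,
        rise_days=np.asarray(rise_all),
        senescence_days=np.asarray(sen_all),
        coupling_window=tuple(config.coupling_window),
        coupling_slope_per_g=slope,
    )
    return samples, records, truth


def coupling_direction(feature_name: str, config: FieldConfig | None = None) -> int:
    """Sign of a feature's response to the planted chlorophyll amplitude.

    Evaluates the feature (band ``x.NNN`` or registry index) on the
    noise-free mid-season template at the mean latent state and at the state
    reached by a +1 SD move in yield (which raises both the chlorophyll and
    the water amplitude through their couplings), and returns the sign of
    the finite difference; 0 if the response is negligible. This is the
    expected sign of the feature's association with yield.
    """
    from . import vegindex
    from .spectra import TARGET_GRID

    config = config if config is not None else FieldConfig()
    a0 = config.amplitude_base
    da = config.coupling_strength * config.amplitude_base
    dw = config.water_coupling_strength
    vals = []
    for amp, wat in ((a0, 1.0), (a0 + da, 1.0 + dw)):
        refl = reflectance_template(
            np.float64(amp), np.float64(wat), np.float64(0.95), TARGET_GRID
        )
        if feature_name.startswith("x."):
            wl = float(feature_name[2:])
            vals.append(float(refl[int(wl) - 350]))
        else:
            defn = vegindex.get_index(feature_name)
            acc = vegindex.BandAccessor(TARGET_GRID, refl[None, :])
            vals.append(float(defn.compute(acc)[0]))
    diff = vals[1] - vals[0]
    scale = max(abs(vals[0]), abs(vals[1]), 1e-12)
    if abs(diff) < 1e-3 * scale:
        return 0
    return 1 if diff > 0 else -1


def write_field(
    samples: Sequence[SpectrumSample],
    records: Sequence[PlantRecord],
    truth: GroundTruth,
    outdir: str | Path,
) -> None:
    """Write the trial to disk: per-plant spectrum CSVs, plants.csv, truth JSON."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for s in samples:
        path = outdir / str(s.year) / s.plot / s.plant_id / f"d{s.day_index}.csv"
        write_spectrum_csv(s, path)
    records_to_frame(records).to_csv(outdir / "plants.csv", index=False)
    payload = {
        "coupling_window": list(truth.coupling_window),
        "coupling_slope_per_g": truth.coupling_slope_per_g,
        "noise_floor_g": truth.noise_floor_g(),
        "variety_effects": truth.variety_effects,
        "plot_effects": truth.plot_effects,
        "plants": [
            {
                "plant_id": p, "yield_g": float(y), "amplitude": float(a),
                "amplitude_noise": float(e), "water_amplitude": float(w),
            }
            for p, y, a, e, w in zip(
                truth.plant_ids, truth.yields_g, truth.amplitudes,
                truth.amplitude_noise, truth.water_amplitudes
            )
        ],
    }
    (outdir / "ground_truth.json").write_text(json.dumps(payload, indent=1))
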