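"""Spectral data model: samples, replicate averaging, resampling and masking.

A field campaign with an ASD-style spectroradiometer yields one reflectance
curve per plant per measurement day on the instrument's native dual-resolution
grid (1.4 nm below ~1000 nm, 2 nm above). Analysis happens on a unified 1 nm
integer grid spanning 350-2500 nm (2151 bands), from which water-absorption
and noisy shortwave regions are masked out before band features enter any
model. With the default mask (1350-1460, 1790-2000 and 2350-2500 nm, both
ends inclusive) exactly 1678 bands remain.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: unified analysis grid: one band per nanometre, 350..2500 inclusive.
GRID_MIN_NM = 350
GRID_MAX_NM = 2500
TARGET_GRID = np.arange(GRID_MIN_NM, GRID_MAX_NM + 1, dtype=float)

#: masked intervals (nm, inclusive): two water-absorption windows plus the
#: noisy long-SWIR tail.
DEFAULT_MASK_RANGES: tuple[tuple[float, float], ...] = (
    (1350.0, 1460.0),
    (1790.0, 2000.0),
    (2350.0, 2500.0),
)


class SpectrumError(ValueError):
    """Malformed or inconsistent spectral data."""


@dataclass
class SpectrumSample:
    """One plant's (replicate-averaged) reflectance curve on one day.

    ``day_index`` is the 1-based ordinal of the measurement day within its
    year (d1..dn, ranked by days-after-planting); it is the coordinate used
    to align measurement days across years.
    """

    plant_id: str
    variety: str
    plot: str
    year: int
    dap: int
    day_index: int
    wavelengths: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelengths.ndim != 1 or self.reflectance.ndim != 1:
            raise SpectrumError("wavelengths and reflectance must be 1-D")
        if self.wavelengths.shape != self.reflectance.shape:
            raise SpectrumError(
                f"length mismatch: {self.wavelengths.size} wavelengths vs "
                f"{self.reflectance.size} reflectance values"
            )
        if not np.all(np.diff(self.wavelengths) > 0):
            raise SpectrumError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.reflectance)):
            raise SpectrumError("reflectance contains non-finite values")
        if self.reflectance.min() < 0.0 or self.reflectance.max() > 1.0:
            raise SpectrumError("reflectance outside [0, 1]")

    @property
    def n_bands(self) -> int:
        return int(self.wavelengths.size)


@dataclass
class PlantRecord:
    """Harvest bookkeeping for one plant.

    Tuber counts by caliber (>75 mm large, 40-75 mm medium, <40 mm small)
    are contextual only; the response modelled downstream is ``yield_g``.
    """

    plant_id: str
    variety: str
    plot: str
    year: int
    yield_g: float
    n_tubers: int
    n_large: int
    n_medium: int
    n_small: int
    rodent_damaged: bool

    def __post_init__(self) -> None:
        if self.yield_g < 0:
            raise ValueError(f"negative yield for {self.plant_id}")
        if self.n_large + self.n_medium + self.n_small != self.n_tubers:
            raise ValueError(
                f"caliber counts do not sum to n_tubers for {self.plant_id}"
            )


@dataclass
class MaskSpec:
    """Inclusive wavelength intervals to drop from the unified grid."""

    removed_ranges: Sequence[tuple[float, float]] = field(
        default_factory=lambda: list(DEFAULT_MASK_RANGES)
    )

    def __post_init__(self) -> None:
        rng = [(float(a), float(b)) for a, b in self.removed_ranges]
        for a, b in rng:
            if a > b:
                raise SpectrumError(f"mask interval reversed: [{a}, {b}]")
            if a < GRID_MIN_NM or b > GRID_MAX_NM:
                raise SpectrumError(f"mask interval [{a}, {b}] outside [350, 2500]")
        rng.sort()
        for (_, b0), (a1, _) in zip(rng, rng[1:]):
            if a1 <= b0:
                raise SpectrumError("mask intervals overlap")
        self.removed_ranges = rng

    def keep_mask(self, wavelengths: np.ndarray) -> np.ndarray:
        """Boolean mask of bands to *keep*."""
        wl = np.asarray(wavelengths, dtype=float)
        keep = np.ones(wl.shape, dtype=bool)
        for a, b in self.removed_ranges:
            keep &= ~((wl >= a) & (wl <= b))
        return keep


def read_spectrum_csv(
    path: str | Path,
    *,
    plant_id: str = "",
    variety: str = "",
    plot: str = "",
    year: int = 0,
    dap: int = 0,
    day_index: int = 0,
) -> SpectrumSample:
    """Read a two-column (wavelength_nm, reflectance) CSV into a sample.

    Metadata defaults are taken from a ``#`` header sidecar written by
    :func:`write_spectrum_csv` when present; keyword arguments override.
    """
    path = Path(path)
    meta = {
        "plant_id": plant_id, "variety": variety, "plot": plot,
        "year": year, "dap": dap, "day_index": day_index,
    }
    wl: list[float] = []
    refl: list[float] = []
    with path.open() as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row:
                continue
            if row[0].startswith("#"):
                key, _, val = row[0].lstrip("# ").partition("=")
                key = key.strip()
                if key in meta and not meta[key]:
                    meta[key] = val.strip()
                continue
            if row[0].strip().lower() in {"wavelength_nm", "wavelength"}:
                continue
            if len(row) < 2:
                raise SpectrumError(f"{path}:{lineno}: expected two columns")
            try:
                wl.append(float(row[0]))
                refl.append(float(row[1]))
            except ValueError as exc:
                raise SpectrumError(f"{path}:{lineno}: non-numeric value") from exc
    order = np.argsort(wl)
    wl_arr = np.asarray(wl, dtype=float)[order]
    if np.any(np.diff(wl_arr) <= 0):
        dup = wl_arr[np.where(np.diff(wl_arr) <= 0)[0][0]]
        raise SpectrumError(f"{path}: non-monotone wavelength grid near {dup} nm")
    return SpectrumSample(
        plant_id=str(meta["plant_id"]), variety=str(meta["variety"]),
        plot=str(meta["plot"]), year=int(meta["year"] or 0),
        dap=int(meta["dap"] or 0), day_index=int(meta["day_index"] or 0),
        wavelengths=wl_arr, reflectance=np.asarray(refl, dtype=float)[order],
    )


def write_spectrum_csv(sample: SpectrumSample, path: str | Path) -> None:
    """Write a sample as CSV with a commented metadata header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        for key in ("plant_id", "variety", "plot", "year", "dap", "day_index"):
            fh.write(f"# {key}={getattr(sample, key)}\n")
        writer = csv.writer(fh)
        writer.writerow(["wavelength_nm", "reflectance"])
        for w, r in zip(sample.wavelengths, sample.reflectance):
            writer.writerow([f"{w:.10g}", f"{r:.10g}"])


def average_replicates(samples: Sequence[SpectrumSample]) -> SpectrumSample:
    """Pointwise mean of replicate measurements of the same plant and day."""
    if not samples:
        raise SpectrumError("no samples to average")
    first = samples[0]
    for s in samples[1:]:
        if s.wavelengths.shape != first.wavelengths.shape or not np.allclose(
            s.wavelengths, first.wavelengths
        ):
            raise SpectrumError("replicate wavelength grids differ")
        if (s.plant_id, s.year, s.day_index) != (
            first.plant_id, first.year, first.day_index
        ):
            raise SpectrumError("replicates have mismatched plant/day metadata")
    mean = np.mean([s.reflectance for s in samples], axis=0)
    return replace(first, reflectance=mean)


def resample_to_1nm(sample: SpectrumSample) -> SpectrumSample:
    """Linearly interpolate onto the 2151-point integer grid 350..2500 nm."""
    wl = sample.wavelengths
    if wl[0] > GRID_MIN_NM or wl[-1] < GRID_MAX_NM:
        raise SpectrumError(
            f"input grid [{wl[0]:g}, {wl[-1]:g}] does not cover [350, 2500] nm"
        )
    refl = np.interp(TARGET_GRID, wl, sample.reflectance)
    return replace(sample, wavelengths=TARGET_GRID.copy(), reflectance=refl)


def apply_mask(sample: SpectrumSample, mask: MaskSpec | None = None) -> SpectrumSample:
    """Drop bands inside the masked intervals; pure subsetting."""
    mask = mask if mask is not None else MaskSpec()
    keep = mask.keep_mask(sample.wavelengths)
    return replace(
        sample,
        wavelengths=sample.wavelengths[keep],
        reflectance=sample.reflectance[keep],
    )


def retained_band_count(mask: MaskSpec | None = None) -> int:
    """Number of 1 nm bands surviving the mask on the unified grid."""
    mask = mask if mask is not None else MaskSpec()
    return int(mask.keep_mask(TARGET_GRID).sum())


def exclude_damaged(
    records: Iterable[PlantRecord], samples: Iterable[SpectrumSample]
) -> tuple[list[PlantRecord], list[SpectrumSample]]:
    """Drop rodent-damaged plants and their spectra.

    Rodent damage destroys tubers below ground without a reliable signature
    in canopy reflectance, so flagged plants are removed from both tables
    rather than modelled.
    """
    records = list(records)
    damaged = {r.plant_id for r in records if r.rodent_damaged}
    kept_records = [r for r in records if r.plant_id not in damaged]
    kept_samples = [s for s in samples if s.plant_id not in damaged]
    logger.info(
        "excluded %d rodent-damaged plants (%d retained)",
        len(damaged), len(kept_records),
    )
    if not kept_records:
        warnings.warn("all plants flagged as rodent-damaged; nothing retained")
    return kept_records, kept_samples


def records_to_frame(records: Sequence[PlantRecord]):
    """Plant records as a pandas DataFrame (plants.csv schema)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "plant_id": [r.plant_id for r in records],
            "variety": [r.variety for r in records],
            "plot": [r.plot for r in records],
            "year": [r.year for r in records],
            "yield_g": [r.yield_g for r in records],
            "n_tubers": [r.n_tubers for r in records],
            "n_large": [r.n_large for r in records],
            "n_medium": [r.n_medium for r in records],
            "n_small": [r.n_small for r in records],
            "rodent_damaged": [r.rodent_damaged for r in records],
        }
    )
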