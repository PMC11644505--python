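"""Registry of 116 vegetation indices evaluated on 1 nm reflectance spectra.

The bank mirrors the classic hyperspectral index collections used in field
phenomics: 115 literature indices (simple ratios, normalized differences,
chlorophyll/carotenoid/anthocyanin indices, red-edge position estimators,
derivative indices and SWIR water/soil indices) plus the crop-specific
Potato Productivity Index (PPI). Each entry records the wavelengths it
needs, a literature citation, and whether it is invariant to multiplying the
whole spectrum by a positive constant (pure ratios and normalized
differences are; indices with additive constants or absolute radiometric
terms are not).

Indices are evaluated on the *pre-mask* resampled spectrum: masking is a
feature-selection step for individual bands, not a destruction of the
measurement, so an index whose wavelengths fall inside a masked interval
(e.g. CAI at 2000 nm) still evaluates.

Derivative-based indices use a Savitzky-Golay smoothed first derivative
(window 15 nm, order 2) when the sample is on the uniform 1 nm grid, which
keeps them usable at realistic instrument noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .spectra import SpectrumSample


class ResolutionError(KeyError):
    """A required wavelength is absent from the sample grid."""


class RegistryError(ValueError):
    """Registry integrity problem (duplicate or unknown index name)."""


class BandAccessor:
    """Vectorised reflectance lookup over a (n_samples, n_bands) matrix."""

    def __init__(self, wavelengths: np.ndarray, matrix: np.ndarray):
        self.wavelengths = np.asarray(wavelengths, dtype=float)
        self.matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
        self._index = {float(w): i for i, w in enumerate(self.wavelengths)}
        self._deriv: np.ndarray | None = None

    def R(self, wl: float) -> np.ndarray:
        """Reflectance column at an exact wavelength (nm)."""
        try:
            return self.matrix[:, self._index[float(wl)]]
        except KeyError:
            raise ResolutionError(
                f"wavelength {wl} nm not on the sample grid"
            ) from None

    def _slice(self, lo: float, hi: float) -> np.ndarray:
        sel = (self.wavelengths >= lo) & (self.wavelengths <= hi)
        if not sel.any():
            raise ResolutionError(f"no bands in [{lo}, {hi}] nm on the sample grid")
        return sel

    def mean(self, lo: float, hi: float) -> np.ndarray:
        # contiguous copy keeps per-row reduction order identical for any
        # batch size (exact batch/serial equality)
        return np.ascontiguousarray(self.matrix[:, self._slice(lo, hi)]).mean(axis=1)

    @property
    def derivative(self) -> np.ndarray:
        """First derivative dR/dlambda, smoothed on uniform 1 nm grids."""
        if self._deriv is None:
            diffs = np.diff(self.wavelengths)
            if self.wavelengths.size >= 15 and np.allclose(diffs, 1.0):
                self._deriv = savgol_filter(
                    self.matrix, window_length=15, polyorder=2, deriv=1,
                    delta=1.0, axis=1,
                )
            else:
                self._deriv = np.gradient(self.matrix, self.wavelengths, axis=1)
        return self._deriv

    def D(self, wl: float) -> np.ndarray:
        try:
            return self.derivative[:, self._index[float(wl)]]
        except KeyError:
            raise ResolutionError(
                f"wavelength {wl} nm not on the sample grid"
            ) from None

    def dmax(self, lo: float, hi: float) -> np.ndarray:
        return self.derivative[:, self._slice(lo, hi)].max(axis=1)

    def dsum(self, lo: float, hi: float) -> np.ndarray:
        return np.ascontiguousarray(self.derivative[:, self._slice(lo, hi)]).sum(axis=1)

    def dargmax_wl(self, lo: float, hi: float) -> np.ndarray:
        sel = self._slice(lo, hi)
        wl = self.wavelengths[sel]
        return wl[np.argmax(self.derivative[:, sel], axis=1)]

    def integral(self, lo: float, hi: float) -> np.ndarray:
        sel = self._slice(lo, hi)
        return np.trapezoid(np.ascontiguousarray(self.matrix[:, sel]),
                            self.wavelengths[sel], axis=1)


def _div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Elementwise division propagating NaN where the denominator is 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.asarray(num, dtype=float) / np.asarray(den, dtype=float)
    out = np.where(np.isfinite(out), out, np.nan)
    return out


@dataclass(frozen=True)
class IndexDefinition:
    """One vegetation index: name, needed wavelengths, formula, citation."""

    name: str
    required_wavelengths: tuple[float, ...]
    compute: Callable[[BandAccessor], np.ndarray]
    citation: str
    scale_invariant: bool

    def __post_init__(self) -> None:
        for wl in self.required_wavelengths:
            if not 350.0 <= wl <= 2500.0:
                raise RegistryError(f"{self.name}: wavelength {wl} outside range")


def _nd(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return _div(a - b, a + b)


def _rep_le(a: BandAccessor) -> np.ndarray:
    """Red-edge position by linear extrapolation of two derivative flanks."""
    m1 = _div(a.D(700) - a.D(680), np.full_like(a.D(700), 20.0))
    c1 = a.D(680) - m1 * 680.0
    m2 = _div(a.D(760) - a.D(725), np.full_like(a.D(700), 35.0))
    c2 = a.D(725) - m2 * 725.0
    return _div(c2 - c1, m1 - m2)


def _build_registry() -> list[IndexDefinition]:
    defs: list[IndexDefinition] = []

    def add(name, wl, fn, cite, inv):
        defs.append(IndexDefinition(name, tuple(float(w) for w in wl), fn, cite, inv))

    # -- derivative and curvature indices ---------------------------------
    add("Boochs", [703], lambda a: a.D(703), "Boochs et al. 1990", False)
    add("Boochs2", [720], lambda a: a.D(720), "Boochs et al. 1990", False)
    add("CAI", [2000, 2100, 2200],
        lambda a: 0.5 * (a.R(2000) + a.R(2200)) - a.R(2100),
        "Nagler et al. 2003", False)
    def _cari(a):
        slope = (a.R(700) - a.R(550)) / 150.0
        inter = a.R(550) - slope * 550.0
        return _div(a.R(700), a.R(670)) * _div(
            np.abs(slope * 670.0 + a.R(670) + inter), np.sqrt(slope**2 + 1.0)
        )
    add("CARI", [550, 670, 700], _cari, "Kim et al. 1994", False)
    add("Carter", [695, 420], lambda a: _div(a.R(695), a.R(420)),
        "Carter 1994", True)
    add("Carter2", [695, 760], lambda a: _div(a.R(695), a.R(760)),
        "Carter 1994", True)
    add("Carter3", [605, 760], lambda a: _div(a.R(605), a.R(760)),
        "Carter 1994", True)
    add("Carter4", [710, 760], lambda a: _div(a.R(710), a.R(760)),
        "Carter 1994", True)
    add("Carter5", [695, 670], lambda a: _div(a.R(695), a.R(670)),
        "Carter 1994", True)
    add("Carter6", [550], lambda a: a.R(550), "Carter 1994", False)
    add("Chlred-edge", [760, 720], lambda a: _div(a.R(760), a.R(720)) - 1.0,
        "Gitelson et al. 2003", True)
    add("CI", [675, 690, 683],
        lambda a: _div(a.R(675) * a.R(690), a.R(683) ** 2),
        "Zarco-Tejada et al. 2001", True)
    add("CI2", [760, 700], lambda a: _div(a.R(760), a.R(700)) - 1.0,
        "Gitelson et al. 2003", True)
    add("ClAInt", [600, 735], lambda a: a.integral(600, 735),
        "Oppelt & Mauser 2004", False)
    add("CRI1", [515, 550], lambda a: _div(1.0, a.R(515)) - _div(1.0, a.R(550)),
        "Gitelson et al. 2002", False)
    add("CRI2", [515, 770], lambda a: _div(1.0, a.R(515)) - _div(1.0, a.R(770)),
        "Gitelson et al. 2002", False)
    add("CRI3", [515, 550, 770],
        lambda a: (_div(1.0, a.R(515)) - _div(1.0, a.R(550))) * a.R(770),
        "Gitelson et al. 2002", True)
    add("CRI4", [515, 700, 770],
        lambda a: (_div(1.0, a.R(515)) - _div(1.0, a.R(700))) * a.R(770),
        "Gitelson et al. 2002", True)
    add("D1", [730, 706], lambda a: _div(a.D(730), a.D(706)),
        "Zarco-Tejada et al. 2001", True)
    add("D2", [705, 722], lambda a: _div(a.D(705), a.D(722)),
        "Zarco-Tejada et al. 2001", True)
    add("Datt", [850, 710, 680],
        lambda a: _div(a.R(850) - a.R(710), a.R(850) - a.R(680)),
        "Datt 1999", True)
    add("Datt2", [850, 710], lambda a: _div(a.R(850), a.R(710)), "Datt 1999", True)
    add("Datt3", [754, 704], lambda a: _div(a.D(754), a.D(704)), "Datt 1999", True)
    add("Datt4", [672, 550, 708],
        lambda a: _div(a.R(672), a.R(550) * a.R(708)), "Datt 1998", False)
    add("Datt5", [672, 550], lambda a: _div(a.R(672), a.R(550)), "Datt 1998", True)
    add("Datt6", [860, 550, 708],
        lambda a: _div(a.R(860), a.R(550) * a.R(708)), "Datt 1998", False)
    add("DD", [749, 720, 701, 672],
        lambda a: (a.R(749) - a.R(720)) - (a.R(701) - a.R(672)),
        "Le Maire et al. 2004", False)
    add("DDn", [710, 660, 760],
        lambda a: 2.0 * a.R(710) - a.R(660) - a.R(760),
        "Le Maire et al. 2008", False)
    add("DPI", [688, 710, 697],
        lambda a: _div(a.D(688) * a.D(710), a.D(697) ** 2),
        "Zarco-Tejada et al. 2003", True)
    add("DWSI1", [800, 1660], lambda a: _div(a.R(800), a.R(1660)),
        "Apan et al. 2004", True)
    add("DWSI2", [1660, 550], lambda a: _div(a.R(1660), a.R(550)),
        "Apan et al. 2004", True)
    add("DWSI3", [1660, 680], lambda a: _div(a.R(1660), a.R(680)),
        "Apan et al. 2004", True)
    add("DWSI4", [550, 680], lambda a: _div(a.R(550), a.R(680)),
        "Apan et al. 2004", True)
    add("DWSI5", [800, 550, 1660, 680],
        lambda a: _div(a.R(800) + a.R(550), a.R(1660) + a.R(680)),
        "Apan et al. 2004", True)
    add("EGFN", [500, 550, 650, 750],
        lambda a: _nd(a.dmax(650, 750), a.dmax(500, 550)),
        "Penuelas et al. 1994", True)
    add("EGFR", [500, 550, 650, 750],
        lambda a: _div(a.dmax(650, 750), a.dmax(500, 550)),
        "Penuelas et al. 1994", True)
    add("EVI", [800, 670, 475],
        lambda a: 2.5 * _div(a.R(800) - a.R(670),
                             a.R(800) + 6.0 * a.R(670) - 7.5 * a.R(475) + 1.0),
        "Huete et al. 2002", False)
    for p in (2, 3, 4):
        add(f"GDVI_{p}", [800, 680],
            (lambda q: lambda a: _div(a.R(800) ** q - a.R(680) ** q,
                                      a.R(800) ** q + a.R(680) ** q))(p),
            "Wu 2014", True)
    add("GI", [554, 677], lambda a: _div(a.R(554), a.R(677)),
        "Smith et al. 1995", True)
    add("Gitelson", [700], lambda a: _div(1.0, a.R(700)),
        "Gitelson et al. 1999", False)
    add("Gitelson2", [695, 740, 750, 800],
        lambda a: _div(a.mean(750, 800), a.mean(695, 740)) - 1.0,
        "Gitelson et al. 2003 (red-edge chlorophyll index)", True)
    add("GMI1", [750, 550], lambda a: _div(a.R(750), a.R(550)),
        "Gitelson & Merzlyak 1997", True)
    add("GMI2", [750, 700], lambda a: _div(a.R(750), a.R(700)),
        "Gitelson & Merzlyak 1997", True)
    add("Green NDVI", [800, 550], lambda a: _nd(a.R(800), a.R(550)),
        "Gitelson et al. 1996", True)
    add("LWVI1", [1094, 983], lambda a: _nd(a.R(1094), a.R(983)),
        "Galvao et al. 2005", True)
    add("LWVI2", [1094, 1205], lambda a: _nd(a.R(1094), a.R(1205)),
        "Galvao et al. 2005", True)
    add("Maccioni", [780, 710, 680],
        lambda a: _div(a.R(780) - a.R(710), a.R(780) - a.R(680)),
        "Maccioni et al. 2001", True)

    def _mcari(a):
        return ((a.R(700) - a.R(670)) - 0.2 * (a.R(700) - a.R(550))) * _div(
            a.R(700), a.R(670))

    def _mcari2(a):
        return ((a.R(750) - a.R(705)) - 0.2 * (a.R(750) - a.R(550))) * _div(
            a.R(750), a.R(705))

    def _osavi(a):
        return 1.16 * _div(a.R(800) - a.R(670), a.R(800) + a.R(670) + 0.16)

    def _osavi2(a):
        return 1.16 * _div(a.R(750) - a.R(705), a.R(750) + a.R(705) + 0.16)

    add("MCARI", [700, 670, 550], _mcari, "Daughtry et al. 2000", False)
    add("MCARI/OSAVI", [700, 670, 550, 800],
        lambda a: _div(_mcari(a), _osavi(a)), "Daughtry et al. 2000", False)
    add("MCARI2", [750, 705, 550], _mcari2, "Wu et al. 2008", False)
    add("MCARI2/OSAVI2", [750, 705, 550],
        lambda a: _div(_mcari2(a), _osavi2(a)), "Wu et al. 2008", False)
    add("mND705", [750, 705, 445],
        lambda a: _div(a.R(750) - a.R(705), a.R(750) + a.R(705) - 2.0 * a.R(445)),
        "Sims & Gamon 2002", True)
    add("mNDVI", [800, 680, 445],
        lambda a: _div(a.R(800) - a.R(680), a.R(800) + a.R(680) - 2.0 * a.R(445)),
        "Sims & Gamon 2002", True)
    add("MPRI", [515, 530], lambda a: _nd(a.R(515), a.R(530)),
        "Hernandez-Clemente et al. 2011", True)
    add("mREIP", [680, 750], lambda a: a.dargmax_wl(680, 750),
        "Miller et al. 1990 (derivative red-edge position)", True)
    add("MSAVI", [800, 670],
        lambda a: 0.5 * (2.0 * a.R(800) + 1.0
                         - np.sqrt(np.clip((2.0 * a.R(800) + 1.0) ** 2
                                           - 8.0 * (a.R(800) - a.R(670)), 0, None))),
        "Qi et al. 1994", False)
    add("mSR", [800, 445, 680],
        lambda a: _div(a.R(800) - a.R(445), a.R(680) - a.R(445)),
        "Sims & Gamon 2002", True)
    add("mSR2", [750, 705],
        lambda a: _div(_div(a.R(750), a.R(705)) - 1.0,
                       np.sqrt(_div(a.R(750), a.R(705)) + 1.0)),
        "Chen 1996", True)
    add("mSR705", [750, 445, 705],
        lambda a: _div(a.R(750) - a.R(445), a.R(705) - a.R(445)),
        "Sims & Gamon 2002", True)
    add("MTCI", [754, 709, 681],
        lambda a: _div(a.R(754) - a.R(709), a.R(709) - a.R(681)),
        "Dash & Curran 2004", True)
    add("MTVI", [800, 550, 670],
        lambda a: 1.2 * (1.2 * (a.R(800) - a.R(550)) - 2.5 * (a.R(670) - a.R(550))),
        "Haboudane et al. 2004", False)
    add("NDLI", [1754, 1680],
        lambda a: _nd(np.log(_div(1.0, a.R(1754))), np.log(_div(1.0, a.R(1680)))),
        "Serrano et al. 2002", False)
    add("NDNI", [1510, 1680],
        lambda a: _nd(np.log(_div(1.0, a.R(1510))), np.log(_div(1.0, a.R(1680)))),
        "Serrano et al. 2002", False)
    add("NDVI", [800, 680], lambda a: _nd(a.R(800), a.R(680)),
        "Rouse et al. 1974", True)
    add("NDVI2", [750, 705], lambda a: _nd(a.R(750), a.R(705)),
        "Gitelson & Merzlyak 1994", True)
    add("NDVI3", [682, 553], lambda a: _nd(a.R(682), a.R(553)),
        "Gandia et al. 2004", True)
    add("NDWI", [860, 1240], lambda a: _nd(a.R(860), a.R(1240)),
        "Gao 1996", True)
    add("NPCI", [680, 430], lambda a: _nd(a.R(680), a.R(430)),
        "Penuelas et al. 1994", True)
    add("NPQI", [415, 435], lambda a: _nd(a.R(415), a.R(435)),
        "Barnes et al. 1992", True)
    add("OSAVI", [800, 670], _osavi, "Rondeaux et al. 1996", False)
    add("OSAVI2", [750, 705], _osavi2, "Wu et al. 2008", False)
    add("PARS", [746, 513], lambda a: _div(a.R(746), a.R(513)),
        "Chappelle et al. 1992", True)

    def _pri(a):
        return _nd(a.R(531), a.R(570))

    def _rdvi(a):
        return _div(a.R(800) - a.R(670), np.sqrt(a.R(800) + a.R(670)))

    add("PRI", [531, 570], _pri, "Gamon et al. 1992", True)
    add("PRI*CI2", [531, 570, 760, 700],
        lambda a: _pri(a) * (_div(a.R(760), a.R(700)) - 1.0),
        "Garrity et al. 2011", True)
    add("PRI_norm", [531, 570, 800, 670, 700],
        lambda a: _div(-_pri(a), _rdvi(a) * _div(a.R(700), a.R(670))),
        "Zarco-Tejada et al. 2013", False)
    add("PSRI", [678, 500, 750],
        lambda a: _div(a.R(678) - a.R(500), a.R(750)),
        "Merzlyak et al. 1999", True)
    add("PSSR", [800, 635], lambda a: _div(a.R(800), a.R(635)),
        "Blackburn 1998", True)
    add("PSND", [800, 470], lambda a: _nd(a.R(800), a.R(470)),
        "Blackburn 1998", True)
    add("PWI", [900, 970], lambda a: _div(a.R(900), a.R(970)),
        "Penuelas et al. 1997", True)
    add("RDVI", [800, 670], _rdvi, "Roujean & Breon 1995", False)
    add("REP_LE", [680, 700, 725, 760], _rep_le,
        "Cho & Skidmore 2006 (linear extrapolation)", True)
    add("REP_Li", [670, 780, 700, 740],
        lambda a: 700.0 + 40.0 * _div((a.R(670) + a.R(780)) / 2.0 - a.R(700),
                                      a.R(740) - a.R(700)),
        "Guyot & Baret 1988", True)
    add("SAVI", [800, 670],
        lambda a: 1.5 * _div(a.R(800) - a.R(670), a.R(800) + a.R(670) + 0.5),
        "Huete 1988", False)
    add("SIPI", [800, 445, 680],
        lambda a: _div(a.R(800) - a.R(445), a.R(800) - a.R(680)),
        "Penuelas et al. 1995", True)
    add("SPVI", [800, 670, 530],
        lambda a: 0.4 * 3.7 * (a.R(800) - a.R(670))
        - 1.2 * np.abs(a.R(530) - a.R(670)),
        "Vincini et al. 2006", False)
    add("SR", [800, 680], lambda a: _div(a.R(800), a.R(680)),
        "Jordan 1969", True)
    add("SR1", [750, 700], lambda a: _div(a.R(750), a.R(700)),
        "Gitelson & Merzlyak 1997", True)
    add("SR2", [752, 690], lambda a: _div(a.R(752), a.R(690)),
        "Gitelson & Merzlyak 1997", True)
    add("SR3", [750, 550], lambda a: _div(a.R(750), a.R(550)),
        "Gitelson & Merzlyak 1997", True)
    add("SR4", [700, 670], lambda a: _div(a.R(700), a.R(670)),
        "McMurtrey et al. 1994", True)
    add("SR5", [675, 700], lambda a: _div(a.R(675), a.R(700)),
        "Chappelle et al. 1992", True)
    add("SR6", [750, 710], lambda a: _div(a.R(750), a.R(710)),
        "Zarco-Tejada & Miller 1999", True)
    add("SR7", [440, 690], lambda a: _div(a.R(440), a.R(690)),
        "Lichtenthaler et al. 1996", True)
    add("SR8", [515, 550], lambda a: _div(a.R(515), a.R(550)),
        "Hernandez-Clemente et al. 2012", True)
    add("SRPI", [430, 680], lambda a: _div(a.R(430), a.R(680)),
        "Penuelas et al. 1995", True)
    add("SRWI", [850, 1240], lambda a: _div(a.R(850), a.R(1240)),
        "Zarco-Tejada et al. 2003", True)
    add("Sum_Dr1", [626, 795], lambda a: a.dsum(626, 795),
        "Elvidge & Chen 1995", False)
    add("Sum_Dr2", [680, 780], lambda a: a.dsum(680, 780),
        "Filella & Penuelas 1994", False)
    add("SWIR FI", [2133, 2225, 2209],
        lambda a: _div(a.R(2133) ** 2, a.R(2225) * a.R(2209) ** 3),
        "Levin et al. 2007", False)
    add("SWIR LI", [2210, 2090, 2280],
        lambda a: 3.87 * (a.R(2210) - a.R(2090))
        - 27.51 * (a.R(2280) - a.R(2090)) - 0.2,
        "Lobell & Asner 2001", False)
    add("SWIR SI", [2210, 2090, 2280],
        lambda a: -41.59 * (a.R(2210) - a.R(2090))
        + 1.24 * (a.R(2280) - a.R(2090)) + 0.64,
        "Lobell & Asner 2001", False)
    add("SWIR VI", [2210, 2090, 2280],
        lambda a: 37.72 * (a.R(2210) - a.R(2090))
        + 26.27 * (a.R(2280) - a.R(2090)) + 0.57,
        "Lobell & Asner 2001", False)

    def _tcari(a):
        return 3.0 * ((a.R(700) - a.R(670))
                      - 0.2 * (a.R(700) - a.R(550)) * _div(a.R(700), a.R(670)))

    def _tcari2(a):
        return 3.0 * ((a.R(750) - a.R(705))
                      - 0.2 * (a.R(750) - a.R(550)) * _div(a.R(750), a.R(705)))

    add("TCARI", [700, 670, 550], _tcari, "Haboudane et al. 2002", False)
    add("TCARI/OSAVI", [700, 670, 550, 800],
        lambda a: _div(_tcari(a), _osavi(a)), "Haboudane et al. 2002", False)
    add("TCARI2", [750, 705, 550], _tcari2, "Wu et al. 2008", False)
    add("TCARI2/OSAVI2", [750, 705, 550],
        lambda a: _div(_tcari2(a), _osavi2(a)), "Wu et al. 2008", False)
    add("TGI", [670, 550, 480],
        lambda a: -0.5 * (190.0 * (a.R(670) - a.R(550))
                          - 120.0 * (a.R(670) - a.R(480))),
        "Hunt et al. 2013", False)
    add("TVI", [750, 550, 670],
        lambda a: 0.5 * (120.0 * (a.R(750) - a.R(550))
                         - 200.0 * (a.R(670) - a.R(550))),
        "Broge & Leblanc 2001", False)
    add("Vogelmann", [740, 720], lambda a: _div(a.R(740), a.R(720)),
        "Vogelmann et al. 1993", True)
    add("Vogelmann2", [734, 747, 715, 726],
        lambda a: _div(a.R(734) - a.R(747), a.R(715) + a.R(726)),
        "Vogelmann et al. 1993", True)
    add("Vogelmann3", [715, 705], lambda a: _div(a.D(715), a.D(705)),
        "Vogelmann et al. 1993", True)
    add("Vogelmann4", [734, 747, 715, 720],
        lambda a: _div(a.R(734) - a.R(747), a.R(715) + a.R(720)),
        "Vogelmann et al. 1993", True)
    add("ARI", [550, 700],
        lambda a: _div(1.0, a.R(550)) - _div(1.0, a.R(700)),
        "Gitelson et al. 2001", False)

    n_literature = len(defs)
    assert n_literature == 115, f"literature bank has {n_literature} entries"

    # crop-specific potato productivity index: red-edge normalized
    # difference on the 842/705 nm band centres (package's adopted variant)
    add("PPI", [842, 705], lambda a: _nd(a.R(842), a.R(705)),
        "potato productivity index (red-edge normalized difference variant)",
        True)

    names = [d.name for d in defs]
    if len(set(names)) != len(names):
        raise RegistryError("duplicate index names in registry")
    return defs


_REGISTRY: list[IndexDefinition] = _build_registry()
_BY_NAME = {d.name: d for d in _REGISTRY}

#: number of literature indices (excluding PPI)
N_LITERATURE_INDICES = 115
#: total bank size
N_INDICES = len(_REGISTRY)


def registry() -> list[IndexDefinition]:
    """The full index bank (115 literature indices + PPI), fixed order."""
    return list(_REGISTRY)


def get_index(name: str) -> IndexDefinition:
    try:
        return _BY_NAME[name]
    except KeyError:
        raise RegistryError(f"unknown vegetation index: {name!r}") from None


def index_names() -> list[str]:
    return [d.name for d in _REGISTRY]


def evaluate(defn: IndexDefinition, sample: SpectrumSample) -> float:
    """Evaluate one index on one sample; NaN (with a warning) on 0-division."""
    acc = BandAccessor(sample.wavelengths, sample.reflectance[None, :])
    for wl in defn.required_wavelengths:
        acc.R(wl)  # raises ResolutionError naming the wavelength
    value = float(np.asarray(defn.compute(acc)).ravel()[0])
    if np.isnan(value):
        warnings.warn(f"{defn.name}: undefined value (zero denominator)")
    return value


def evaluate_matrix(
    wavelengths: np.ndarray, matrix: np.ndarray,
    definitions: Sequence[IndexDefinition] | None = None,
) -> pd.DataFrame:
    """Evaluate the bank on a (n_samples, n_bands) reflectance matrix."""
    definitions = list(definitions) if definitions is not None else registry()
    acc = BandAccessor(wavelengths, matrix)
    cols = {}
    n_nan = 0
    for d in definitions:
        vals = np.asarray(d.compute(acc), dtype=float)
        n_nan += int(np.isnan(vals).sum())
        cols[d.name] = vals
    if n_nan:
        warnings.warn(f"{n_nan} undefined index values set to NaN")
    return pd.DataFrame(cols)


def evaluate_all(samples: Sequence[SpectrumSample]) -> pd.DataFrame:
    """Per-sample VI table (rows follow the input order; 116 columns)."""
    if not samples:
        return pd.DataFrame(columns=index_names())
    wl = samples[0].wavelengths
    for s in samples[1:]:
        if s.wavelengths.shape != wl.shape or not np.array_equal(s.wavelengths, wl):
            raise ResolutionError("samples are not on a common wavelength grid")
    matrix = np.vstack([s.reflectance for s in samples])
    out = evaluate_matrix(wl, matrix)
    out.index = [s.plant_id for s in samples]
    return out
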