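"""Spectral containers and Beer-Lambert spectral unmixing.

UV-Vis spectra of flavoenzyme redox titrations are linear mixtures of the
extinction spectra of the species present (oxidized / semiquinone / reduced
flavin, oxidized / leuco reporter dye).  This module holds the containers for
single spectra, time- or step-stamped spectral series and extinction basis
sets, and decomposes measured spectra into species concentrations by
non-negative least squares.  The per-pool oxidized/reduced fractions extracted
here feed the Minnaert potentiometry in :mod:`bbekit.redox` and the 450-nm
kinetic traces in :mod:`bbekit.kinetics`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear

__all__ = [
    "Spectrum",
    "SpectralSeries",
    "BasisSet",
    "PoolSpec",
    "UnmixResult",
    "IllPosedUnmixingError",
    "unmix",
    "series_fractions",
    "absorbance_at",
    "semiquinone_signal",
]


class IllPosedUnmixingError(ValueError):
    """Basis is rank-deficient over the requested wavelength window."""


@dataclass(frozen=True)
class Spectrum:
    """A single absorbance spectrum on a strictly increasing wavelength grid."""

    wavelengths_nm: np.ndarray
    absorbance_AU: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        ab = np.asarray(self.absorbance_AU, dtype=float)
        if wl.ndim != 1 or ab.ndim != 1 or wl.size != ab.size:
            raise ValueError("wavelengths and absorbances must be 1-D and equal length")
        if wl.size == 0:
            raise ValueError("empty spectrum")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "absorbance_AU", ab)

    def at(self, wavelength_nm: float) -> float:
        """Absorbance at a wavelength, linearly interpolated inside the grid."""
        wl = self.wavelengths_nm
        if not (wl[0] <= wavelength_nm <= wl[-1]):
            raise ValueError(f"wavelength {wavelength_nm} nm outside grid [{wl[0]}, {wl[-1]}]")
        return float(np.interp(wavelength_nm, wl, self.absorbance_AU))


class SpectralSeries:
    """An ordered set of spectra sharing one grid, stamped by step index or time.

    Parameters
    ----------
    stamps
        Nondecreasing step indices or times (seconds).
    wavelengths_nm
        Shared strictly increasing wavelength grid.
    absorbance_AU
        Array of shape ``(n_stamps, n_wavelengths)``.
    """

    def __init__(self, stamps: Sequence[float], wavelengths_nm: Sequence[float],
                 absorbance_AU: np.ndarray) -> None:
        self.stamps = np.asarray(stamps, dtype=float)
        self.wavelengths_nm = np.asarray(wavelengths_nm, dtype=float)
        self.absorbance_AU = np.asarray(absorbance_AU, dtype=float)
        if self.stamps.ndim != 1:
            raise ValueError("stamps must be 1-D")
        if np.any(np.diff(self.stamps) < 0):
            raise ValueError("stamps must be nondecreasing")
        if not np.all(np.diff(self.wavelengths_nm) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.absorbance_AU.shape != (self.stamps.size, self.wavelengths_nm.size):
            raise ValueError("absorbance array shape must be (n_stamps, n_wavelengths)")

    def __len__(self) -> int:
        return self.stamps.size

    def __iter__(self) -> Iterator[tuple[float, Spectrum]]:
        for i, stamp in enumerate(self.stamps):
            yield float(stamp), Spectrum(self.wavelengths_nm, self.absorbance_AU[i])

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.wavelengths_nm, self.absorbance_AU[i])

    # -- long-format CSV interchange (step_or_time, wavelength_nm, absorbance) --

    def to_csv(self, path_or_buf) -> None:
        n_s, n_w = self.absorbance_AU.shape
        df = pd.DataFrame({
            "step_or_time": np.repeat(self.stamps, n_w),
            "wavelength_nm": np.tile(self.wavelengths_nm, n_s),
            "absorbance": self.absorbance_AU.ravel(),
        })
        df.to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "SpectralSeries":
        df = pd.read_csv(path_or_buf)
        pivot = df.pivot_table(index="step_or_time", columns="wavelength_nm",
                               values="absorbance", sort=True)
        return cls(pivot.index.to_numpy(), pivot.columns.to_numpy(), pivot.to_numpy())


@dataclass(frozen=True)
class BasisSet:
    """Per-species extinction spectra (M^-1 cm^-1) on a shared grid."""

    species_ids: tuple[str, ...]
    wavelengths_nm: np.ndarray
    extinction: np.ndarray  # shape (n_species, n_wavelengths)
    path_length_cm: float = 1.0

    def __post_init__(self) -> None:
        ids = tuple(self.species_ids)
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        ext = np.asarray(self.extinction, dtype=float)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate species ids in basis")
        if len(ids) == 0:
            raise ValueError("basis needs at least one species")
        if wl.size == 0:
            raise ValueError("empty wavelength grid")
        if ext.shape != (len(ids), wl.size):
            raise ValueError("extinction matrix must be (n_species, n_wavelengths)")
        if np.any(ext < 0):
            raise ValueError("extinction coefficients must be nonnegative")
        object.__setattr__(self, "species_ids", ids)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "extinction", ext)

    def column(self, species_id: str) -> np.ndarray:
        return self.extinction[self.species_ids.index(species_id)]

    def subset(self, species_ids: Iterable[str]) -> "BasisSet":
        """A basis restricted to the given species (e.g. dropping the
        semiquinone for 2-electron ox/red titration analysis)."""
        ids = tuple(species_ids)
        rows = [self.species_ids.index(s) for s in ids]
        return BasisSet(ids, self.wavelengths_nm, self.extinction[rows],
                        self.path_length_cm)

    def absorbance(self, concentrations_M: Mapping[str, float]) -> np.ndarray:
        """Noise-free Beer-Lambert forward model A(lambda) for given concentrations."""
        a = np.zeros_like(self.wavelengths_nm)
        for sp, c in concentrations_M.items():
            a += c * self.column(sp)
        return a * self.path_length_cm


@dataclass(frozen=True)
class PoolSpec:
    """A two-state redox pool (oxidized/reduced species pair).

    ``total_conc_M`` is required when the reduced member is spectrally silent
    over the fitting window (e.g. leuco thionine): its concentration is then
    inferred by mass balance instead of from the fit.
    """

    ox_species: str
    red_species: str
    total_conc_M: float | None = None


@dataclass(frozen=True)
class UnmixResult:
    concentrations_M: dict[str, float]
    baseline_AU: float
    residual_rms_AU: float


def _window_mask(wavelengths: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    if lo >= hi:
        raise ValueError("window must be (low, high) with low < high")
    mask = (wavelengths >= lo) & (wavelengths <= hi)
    if not mask.any():
        raise ValueError("wavelength window does not overlap the grid")
    return mask


def unmix(spectrum: Spectrum, basis: BasisSet,
          window: tuple[float, float] = (320.0, 700.0),
          baseline: bool = True) -> UnmixResult:
    """Decompose a spectrum into nonnegative species concentrations.

    Solves ``min ||A - M c||`` over the window with ``c >= 0`` per species;
    an optional unconstrained constant column absorbs wavelength-independent
    baseline drift.  Species whose extinction is identically zero over the
    window are reported at concentration 0 (they carry no spectral
    information).

    Raises
    ------
    IllPosedUnmixingError
        If the informative basis columns are rank-deficient over the window.
    """
    if not np.array_equal(spectrum.wavelengths_nm, basis.wavelengths_nm):
        raise ValueError("spectrum and basis must share one wavelength grid")
    mask = _window_mask(spectrum.wavelengths_nm, window)
    m_full = basis.extinction[:, mask].T * basis.path_length_cm  # (n_wl, n_species)
    y = spectrum.absorbance_AU[mask]

    active = [i for i in range(m_full.shape[1]) if np.any(m_full[:, i] != 0)]
    m = m_full[:, active]
    if m.shape[1] and m.shape[0] < m.shape[1] + int(baseline):
        raise ValueError("window too narrow for the number of species")
    if m.shape[1] and np.linalg.matrix_rank(m) < m.shape[1]:
        raise IllPosedUnmixingError("basis is rank-deficient over the window")

    n = m.shape[1]
    if baseline:
        design = np.column_stack([m, np.ones(m.shape[0])])
        lb = np.concatenate([np.zeros(n), [-np.inf]])
        ub = np.full(n + 1, np.inf)
    else:
        design = m
        lb = np.zeros(n)
        ub = np.full(n, np.inf)

    if design.shape[1] == 0:
        raise ValueError("no informative basis columns over the window")
    sol = lsq_linear(design, y, bounds=(lb, ub), method="bvls")
    coef = sol.x
    resid = y - design @ coef
    conc = dict.fromkeys(basis.species_ids, 0.0)
    for k, i in enumerate(active):
        conc[basis.species_ids[i]] = float(coef[k])
    base = float(coef[-1]) if baseline else 0.0
    return UnmixResult(conc, base, float(np.sqrt(np.mean(resid**2))))


def series_fractions(series: SpectralSeries, basis: BasisSet,
                     pools: Mapping[str, PoolSpec],
                     window: tuple[float, float] = (320.0, 700.0),
                     baseline: bool = True,
                     min_fraction: float = 1e-4) -> pd.DataFrame:
    """Per-stamp species concentrations and per-pool ox/red fractions.

    Returns a tidy DataFrame with one row per (stamp, pool): columns ``stamp``,
    ``pool``, ``conc_ox_M``, ``conc_red_M``, ``f_ox``, ``f_red``, ``f_sq``
    (flavin semiquinone fraction when ``flavin_asq`` is in the basis, else 0;
    the semiquinone never counts toward the 2-electron ox/red pool) and
    ``usable`` (False when either fraction is below ``min_fraction``, which
    would blow up downstream log-ratios).
    """
    mask = _window_mask(series.wavelengths_nm, window)
    records = []
    has_sq = "flavin_asq" in basis.species_ids
    for i, stamp in enumerate(series.stamps):
        res = unmix(series.spectrum(i), basis, window=window, baseline=baseline)
        c = res.concentrations_M
        c_sq = c.get("flavin_asq", 0.0)
        for name, pool in pools.items():
            ext_red = basis.column(pool.red_species)[mask]
            red_silent = not np.any(ext_red != 0)
            c_ox = c[pool.ox_species]
            if red_silent:
                if pool.total_conc_M is None:
                    raise ValueError(
                        f"pool '{name}': reduced species {pool.red_species!r} has no "
                        "extinction over the window; total_conc_M is required")
                c_red = max(pool.total_conc_M - c_ox, 0.0)
            else:
                c_red = c[pool.red_species]
            total = c_ox + c_red
            f_ox = c_ox / total if total > 0 else np.nan
            f_red = c_red / total if total > 0 else np.nan
            is_flavin = has_sq and pool.ox_species.startswith("flavin")
            f_sq = c_sq / (total + c_sq) if (is_flavin and total + c_sq > 0) else 0.0
            usable = (np.isfinite(f_ox) and min_fraction < f_ox < 1 - min_fraction)
            records.append({
                "stamp": float(stamp), "pool": name,
                "conc_ox_M": c_ox, "conc_red_M": c_red,
                "f_ox": f_ox, "f_red": f_red, "f_sq": f_sq,
                "usable": usable,
                "residual_rms_AU": res.residual_rms_AU,
            })
    return pd.DataFrame.from_records(records)


def absorbance_at(series: SpectralSeries, wavelength_nm: float) -> list[tuple[float, float]]:
    """Absorbance at one wavelength for every stamp (linear interpolation)."""
    wl = series.wavelengths_nm
    if not (wl[0] <= wavelength_nm <= wl[-1]):
        raise ValueError(f"wavelength {wavelength_nm} nm outside grid")
    vals = [float(np.interp(wavelength_nm, wl, row)) for row in series.absorbance_AU]
    return list(zip((float(s) for s in series.stamps), vals))


def semiquinone_signal(series: SpectralSeries, basis: BasisSet,
                       window: tuple[float, float] = (320.0, 700.0),
                       baseline: bool = True) -> tuple[float, float]:
    """Maximum anionic-semiquinone fraction over a series and its stamp.

    The fraction is [asq] / ([ox] + [asq] + [red]) of the flavin pool.
    Returns ``(0.0, first stamp)`` when the semiquinone is never populated.
    """
    if "flavin_asq" not in basis.species_ids:
        raise ValueError("basis must contain flavin_asq")
    best_frac, best_stamp = 0.0, float(series.stamps[0])
    for i, stamp in enumerate(series.stamps):
        res = unmix(series.spectrum(i), basis, window=window, baseline=baseline)
        c = res.concentrations_M
        tot = c.get("flavin_ox", 0.0) + c.get("flavin_asq", 0.0) + c.get("flavin_red", 0.0)
        frac = c.get("flavin_asq", 0.0) / tot if tot > 0 else 0.0
        if frac > best_frac:
            best_frac, best_stamp = frac, float(stamp)
    return best_frac, best_stamp
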