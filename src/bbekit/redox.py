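"""Nernstian electron partitioning and Minnaert dye-equilibrium potentiometry.

The midpoint potential of a flavoenzyme can be measured without a potentiometer
by reducing it slowly in the presence of a reporter dye of known potential
(thionine acetate, E0 = +64 mV): as long as enzyme and dye stay at mutual
equilibrium, log10([ox]/[red]) of both couples falls on a line (the Minnaert
plot) whose slope is n_enzyme/n_dye and whose intercept encodes the potential
difference.  Here both couples are treated as 2-electron couples by default;
the electron counts are explicit parameters.

Conventions: potentials in mV at 25 degC / pH 7; the Nernst slope
s = ln(10)*R*T/F = 59.16 mV is recomputed when the temperature is overridden.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy import stats

from .spectra import BasisSet, PoolSpec, SpectralSeries, series_fractions

__all__ = [
    "GAS_CONSTANT_J",
    "FARADAY_C",
    "RedoxCouple",
    "EquilibriumPoint",
    "MinnaertFit",
    "nernst_slope_mV",
    "nernst_log_ratio",
    "partition_electrons",
    "points_from_fractions",
    "minnaert_fit",
    "estimate_potential",
    "plot_minnaert",
]

GAS_CONSTANT_J = 8.314
FARADAY_C = 96485.0


def nernst_slope_mV(temperature_K: float = 298.15) -> float:
    """ln(10)*R*T/F in mV (59.16 mV at 25 degC)."""
    return np.log(10.0) * GAS_CONSTANT_J * temperature_K / FARADAY_C * 1000.0


@dataclass(frozen=True)
class RedoxCouple:
    """A two-state redox couple: midpoint potential, electron count, concentration."""

    E0_mV: float
    n_electrons: int = 2
    conc_M: float = 0.0

    def __post_init__(self) -> None:
        if self.n_electrons not in (1, 2):
            raise ValueError("n_electrons must be 1 or 2")
        if self.conc_M < 0:
            raise ValueError("concentration must be nonnegative")


@dataclass(frozen=True)
class EquilibriumPoint:
    """One titration step on the Minnaert plot (finite log ratios only)."""

    log10_ratio_enzyme: float
    log10_ratio_dye: float
    stamp: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.log10_ratio_enzyme) and np.isfinite(self.log10_ratio_dye)):
            raise ValueError("log ratios must be finite (filter upstream)")


@dataclass(frozen=True)
class MinnaertFit:
    """OLS result of the log-log equilibrium plot and the derived potential."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    E0_enzyme_mV: float
    E0_se_mV: float
    n_points_used: int


def nernst_log_ratio(E_mV: float, couple: RedoxCouple,
                     temperature_K: float = 298.15) -> float:
    """log10([ox]/[red]) of a couple poised at solution potential E."""
    s = nernst_slope_mV(temperature_K)
    return couple.n_electrons * (E_mV - couple.E0_mV) / s


def _fraction_reduced(E_mV: float, couple: RedoxCouple, s: float) -> float:
    # f_red = 1 / (1 + [ox]/[red]); stable for large |E - E0|
    x = couple.n_electrons * (E_mV - couple.E0_mV) / s
    return float(1.0 / (1.0 + 10.0 ** x))


def partition_electrons(reduced_equiv_total: float, enzyme: RedoxCouple,
                        dye: RedoxCouple,
                        temperature_K: float = 298.15) -> tuple[float, float, float]:
    """Partition delivered reducing equivalents between two equilibrated couples.

    ``reduced_equiv_total`` is in M of electrons.  Returns
    ``(f_red_enzyme, f_red_dye, E_solution_mV)`` such that both couples sit at
    the same solution potential and the consumed equivalents
    ``n_e*[E]*f_e + n_d*[D]*f_d`` match the delivered total to better than
    1e-12 of the capacity.
    """
    capacity = enzyme.n_electrons * enzyme.conc_M + dye.n_electrons * dye.conc_M
    if capacity <= 0:
        raise ValueError("both couples have zero capacity")
    if not (0.0 <= reduced_equiv_total <= capacity * (1 + 1e-12)):
        raise ValueError(f"total {reduced_equiv_total} outside [0, capacity={capacity}]")
    if reduced_equiv_total == 0:
        return 0.0, 0.0, np.inf
    if reduced_equiv_total >= capacity:
        return 1.0, 1.0, -np.inf

    s = nernst_slope_mV(temperature_K)

    def excess(E: float) -> float:
        return (enzyme.n_electrons * enzyme.conc_M * _fraction_reduced(E, enzyme, s)
                + dye.n_electrons * dye.conc_M * _fraction_reduced(E, dye, s)
                - reduced_equiv_total)

    lo = min(enzyme.E0_mV, dye.E0_mV) - 1500.0
    hi = max(enzyme.E0_mV, dye.E0_mV) + 1500.0
    e_sol = brentq(excess, lo, hi, xtol=1e-13, maxiter=200)
    return (_fraction_reduced(e_sol, enzyme, s),
            _fraction_reduced(e_sol, dye, s),
            float(e_sol))


def points_from_fractions(fractions: pd.DataFrame,
                          enzyme_pool: str = "enzyme",
                          dye_pool: str = "dye") -> list[EquilibriumPoint]:
    """Build Minnaert points from a :func:`bbekit.spectra.series_fractions` table.

    Only stamps where both pools are flagged usable (fractions away from 0/1)
    yield a point.
    """
    enz = fractions[fractions["pool"] == enzyme_pool].set_index("stamp")
    dye = fractions[fractions["pool"] == dye_pool].set_index("stamp")
    points = []
    for stamp in enz.index.intersection(dye.index):
        e, d = enz.loc[stamp], dye.loc[stamp]
        if not (bool(e["usable"]) and bool(d["usable"])):
            continue
        points.append(EquilibriumPoint(
            log10_ratio_enzyme=float(np.log10(e["f_ox"] / e["f_red"])),
            log10_ratio_dye=float(np.log10(d["f_ox"] / d["f_red"])),
            stamp=float(stamp)))
    return points


def minnaert_fit(points: Sequence[EquilibriumPoint], dye: RedoxCouple,
                 n_enzyme: int = 2,
                 usable_window: tuple[float, float] = (0.1, 0.9),
                 temperature_K: float = 298.15) -> MinnaertFit:
    """OLS fit of log10 ratio(enzyme) vs log10 ratio(dye); derive E0 of the enzyme.

    Points are filtered to the usable reduction window (default: both pools
    10-90% reduced, i.e. |log10 ratio| <= log10(9)).  With the line
    ``y = slope*x + intercept`` the enzyme potential is
    ``E0_enzyme = E0_dye - intercept * s / n_enzyme``.

    Raises
    ------
    ValueError
        Fewer than 3 usable points, or a nonpositive slope (the two couples
        were not at equilibrium).
    """
    lo, hi = usable_window
    if not (0.0 < lo < hi < 1.0):
        raise ValueError("usable_window must satisfy 0 < lo < hi < 1")
    # f_red in (lo, hi)  <=>  log10([ox]/[red]) in (log10((1-hi)/hi), log10((1-lo)/lo))
    bound_low = np.log10((1 - hi) / hi)
    bound_high = np.log10((1 - lo) / lo)
    xs, ys, used = [], [], []
    for p in points:
        if (bound_low <= p.log10_ratio_enzyme <= bound_high
                and bound_low <= p.log10_ratio_dye <= bound_high):
            xs.append(p.log10_ratio_dye)
            ys.append(p.log10_ratio_enzyme)
            used.append(p)
    if len(xs) < 3:
        raise ValueError(f"<3 usable points after windowing (got {len(xs)})")
    reg = stats.linregress(xs, ys)
    if reg.slope <= 0:
        raise ValueError("nonpositive Minnaert slope: data not at equilibrium")
    s = nernst_slope_mV(temperature_K)
    e0 = dye.E0_mV - reg.intercept * s / n_enzyme
    e0_se = reg.intercept_stderr * s / n_enzyme
    return MinnaertFit(slope=float(reg.slope), intercept=float(reg.intercept),
                       slope_se=float(reg.stderr), intercept_se=float(reg.intercept_stderr),
                       E0_enzyme_mV=float(e0), E0_se_mV=float(e0_se),
                       n_points_used=len(xs))


def estimate_potential(series: SpectralSeries, basis: BasisSet, dye: RedoxCouple,
                       n_enzyme: int = 2,
                       pools: Mapping[str, PoolSpec] | None = None,
                       window: tuple[float, float] = (320.0, 700.0),
                       usable_window: tuple[float, float] = (0.1, 0.9),
                       temperature_K: float = 298.15) -> MinnaertFit:
    """Full pipeline: spectra -> pool fractions -> Minnaert points -> E0 fit."""
    if pools is None:
        pools = {
            "enzyme": PoolSpec("flavin_ox", "flavin_red"),
            "dye": PoolSpec("dye_ox", "dye_red", total_conc_M=dye.conc_M or None),
        }
    frac = series_fractions(series, basis, pools, window=window)
    points = points_from_fractions(frac)
    return minnaert_fit(points, dye, n_enzyme=n_enzyme,
                        usable_window=usable_window, temperature_K=temperature_K)


def plot_minnaert(points: Sequence[EquilibriumPoint], fit: MinnaertFit, path: str) -> None:
    """Write the double-logarithmic equilibrium plot (PNG/SVG by extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = [p.log10_ratio_dye for p in points]
    ys = [p.log10_ratio_enzyme for p in points]
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.plot(xs, ys, "ko", ms=4, label="titration steps")
    grid = np.linspace(min(xs), max(xs), 50)
    ax.plot(grid, fit.slope * grid + fit.intercept, "r-",
            label=f"slope {fit.slope:.3f}, E0 {fit.E0_enzyme_mV:.1f} mV")
    ax.set_xlabel("log10([ox]/[red]) dye")
    ax.set_ylabel("log10([ox]/[red]) enzyme")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
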