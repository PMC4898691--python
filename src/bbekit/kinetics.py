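"""Stopped-flow reoxidation kinetics of reduced flavoenzymes.

Mixing photoreduced enzyme with air-saturated buffer under pseudo-first-order
conditions ([O2] >> [enzyme]) gives a monoexponential recovery of the 450-nm
flavin absorbance, A(t) = A_inf - dA * exp(-k_obs * t).  Dividing the observed
rate by the dissolved O2 concentration yields the bimolecular rate constant
k2 = k_obs / [O2], which is compared against free FAD (250 M^-1 s^-1) to
classify the enzyme's oxygen reactivity: true oxidases accelerate the
reaction, dehydrogenases suppress it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "FREE_FAD_K2",
    "KineticTrace",
    "MonoExpFit",
    "BimolecularResult",
    "fit_monoexponential",
    "bimolecular_constant",
    "classify_oxygen_reactivity",
]

#: Bimolecular rate constant of free FAD with O2 (M^-1 s^-1), the reference
#: point for oxidase/dehydrogenase classification.
FREE_FAD_K2 = 250.0


@dataclass(frozen=True)
class KineticTrace:
    """A 450-nm absorbance trace: strictly increasing times (s) from >= 0."""

    time_s: np.ndarray
    A450_AU: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        a = np.asarray(self.A450_AU, dtype=float)
        if t.ndim != 1 or t.size != a.size:
            raise ValueError("time and absorbance must be 1-D and equal length")
        if t.size and (t[0] < 0 or np.any(np.diff(t) <= 0)):
            raise ValueError("time must start >= 0 and be strictly increasing")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "A450_AU", a)

    def to_csv(self, path_or_buf) -> None:
        pd.DataFrame({"time_s": self.time_s, "A450": self.A450_AU}).to_csv(
            path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "KineticTrace":
        df = pd.read_csv(path_or_buf)
        return cls(df["time_s"].to_numpy(), df["A450"].to_numpy())


@dataclass(frozen=True)
class MonoExpFit:
    """Result of A(t) = A_inf - dA*exp(-k*t); k_obs is None when indeterminate."""

    A_inf_AU: float
    delta_A_AU: float
    k_obs_per_s: float | None
    k_obs_se_per_s: float | None
    rmse_AU: float
    converged: bool
    # retained for residual bootstrapping of k2
    time_s: np.ndarray = field(repr=False, default=None)
    residuals_AU: np.ndarray = field(repr=False, default=None)
    fitted_AU: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class BimolecularResult:
    k2_per_M_per_s: float
    k2_se: float | None
    O2_conc_M: float
    fold_vs_free_FAD: float
    reactivity_class: str


def _model(t: np.ndarray, a_inf: float, delta_a: float, k: float) -> np.ndarray:
    return a_inf - delta_a * np.exp(-k * t)


def _initial_guess(t: np.ndarray, a: np.ndarray) -> tuple[float, float, float]:
    # A_inf from the last decile, dA from the first point, k from the time at
    # half recovery: a derivative-free start that is robust to noise.
    n_tail = max(1, t.size // 10)
    a_inf = float(np.mean(a[-n_tail:]))
    delta_a = a_inf - float(a[0])
    half = a_inf - delta_a / 2.0
    crossing = np.nonzero((a - half) * np.sign(delta_a) >= 0)[0]
    t_half = float(t[crossing[0]]) if crossing.size and t[crossing[0]] > 0 else \
        float(t[t.size // 2]) or float(t[-1])
    k0 = np.log(2.0) / t_half if t_half > 0 else 1.0
    return a_inf, delta_a, k0


def _noise_estimate(a: np.ndarray) -> float:
    """Point-to-point noise SD from first differences (trend-insensitive)."""
    if a.size < 3:
        return 0.0
    return float(np.std(np.diff(a)) / np.sqrt(2.0))


def fit_monoexponential(trace: KineticTrace) -> MonoExpFit:
    """Nonlinear least-squares monoexponential fit of a reoxidation trace.

    A trace whose total excursion is indistinguishable from its point-to-point
    noise (flat trace) is declared indeterminate: ``converged`` is False and no
    rate is reported.  Warns when fewer than 5 points are given or the trace
    does not span a full half-life.
    """
    t, a = trace.time_s, trace.A450_AU
    if t.size < 5:
        warnings.warn("fewer than 5 points: monoexponential fit is fragile")
    noise = _noise_estimate(a)
    # trend test: head vs tail decile means against their standard error
    n_dec = max(1, a.size // 10)
    excursion = abs(float(np.mean(a[-n_dec:]) - np.mean(a[:n_dec])))
    se = noise * np.sqrt(2.0 / n_dec)
    if np.ptp(a) == 0.0 or (noise > 0 and excursion < 5.0 * se):
        return MonoExpFit(float(np.mean(a)), 0.0, None, None,
                          float(np.std(a)), False, t, a - np.mean(a),
                          np.full_like(a, np.mean(a)))
    p0 = _initial_guess(t, a)
    try:
        popt, pcov = curve_fit(_model, t, a, p0=p0,
                               bounds=([-np.inf, -np.inf, 1e-12],
                                       [np.inf, np.inf, np.inf]),
                               maxfev=10000)
    except (RuntimeError, ValueError):
        return MonoExpFit(p0[0], p0[1], None, None, float(np.std(a)), False,
                          t, a - np.mean(a), np.full_like(a, np.mean(a)))
    fitted = _model(t, *popt)
    resid = a - fitted
    k = float(popt[2])
    k_se = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else None
    if t[-1] * k < np.log(2.0):
        warnings.warn("trace spans less than one half-life; k_obs poorly constrained")
    return MonoExpFit(float(popt[0]), float(popt[1]), k, k_se,
                      float(np.sqrt(np.mean(resid**2))), True, t, resid, fitted)


def bimolecular_constant(fit: MonoExpFit, O2_conc_M: float,
                         n_bootstrap: int = 200, seed: int = 0) -> BimolecularResult:
    """k2 = k_obs / [O2], with SE from a residual bootstrap of the trace fit.

    The bootstrap resamples fit residuals with replacement onto the fitted
    curve and refits; set ``n_bootstrap=0`` to fall back on the delta-method SE
    from the covariance of the original fit.
    """
    if O2_conc_M <= 0:
        raise ValueError("O2 concentration must be positive")
    if not fit.converged or fit.k_obs_per_s is None:
        raise ValueError("cannot derive k2 from an unconverged fit")
    k2 = fit.k_obs_per_s / O2_conc_M
    k2_se = None
    if n_bootstrap > 0 and fit.residuals_AU is not None:
        rng = np.random.default_rng(seed)
        ks = []
        for _ in range(n_bootstrap):
            resampled = fit.fitted_AU + rng.choice(fit.residuals_AU,
                                                   size=fit.residuals_AU.size,
                                                   replace=True)
            boot = fit_monoexponential(KineticTrace(fit.time_s, resampled))
            if boot.converged and boot.k_obs_per_s is not None:
                ks.append(boot.k_obs_per_s)
        if len(ks) >= 10:
            k2_se = float(np.std(ks, ddof=1) / O2_conc_M)
    if k2_se is None and fit.k_obs_se_per_s is not None:
        k2_se = fit.k_obs_se_per_s / O2_conc_M
    return BimolecularResult(float(k2), k2_se, float(O2_conc_M),
                             float(k2 / FREE_FAD_K2),
                             classify_oxygen_reactivity(k2))


def classify_oxygen_reactivity(k2_per_M_per_s: float,
                               reference: float = FREE_FAD_K2,
                               oxidase_fold: float = 2.0,
                               dehydrogenase_fold: float = 0.5) -> str:
    """Classify oxygen reactivity relative to free FAD.

    ``oxidase-like`` at >= 2x the free-FAD rate, ``dehydrogenase-like`` at
    <= 0.5x, ``indeterminate`` in between (thresholds configurable).
    """
    if k2_per_M_per_s <= 0:
        raise ValueError("k2 must be positive")
    if k2_per_M_per_s >= oxidase_fold * reference:
        return "oxidase-like"
    if k2_per_M_per_s <= dehydrogenase_fold * reference:
        return "dehydrogenase-like"
    return "indeterminate"
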