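"""Michaelis-Menten specificity constants and relative cleavage efficiencies.

Steady-state endonuclease kinetics on damaged and undamaged substrates are
compared through the specificity constant Vmax/KM (the low-substrate slope
of the v0 vs [S] curve), and through its ratio to an undamaged reference.
Measured KM/Vmax values are taken as printed inputs; the fitting helper
exists to support synthetic kinetics fixtures, not to re-derive published
constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "KineticsRecord",
    "specificity",
    "relative_efficiency",
    "mm_rate",
    "fit_michaelis_menten",
]


def specificity(v_max: float, k_m: float) -> float:
    """Specificity constant Vmax/KM in min^-1 (Vmax in nM/min, KM in nM)."""
    if k_m <= 0:
        raise ValueError("KM must be positive")
    return v_max / k_m


@dataclass
class KineticsRecord:
    """One substrate row: KM, Vmax, specificity and efficiency vs reference.

    For substrates that never reach saturation, KM and Vmax may be None and
    the specificity constant supplied directly (as determined from the
    linear slope of v0 vs [S]).
    """

    site: str
    k_m: float | None = None  # nM
    v_max: float | None = None  # nM min^-1
    specificity_const: float | None = None  # min^-1
    relative: float | None = None

    def __post_init__(self):
        if self.specificity_const is None:
            if self.k_m is None or self.v_max is None:
                raise ValueError(
                    f"{self.site}: need KM and Vmax, or a direct specificity")
            self.specificity_const = specificity(self.v_max, self.k_m)


def relative_efficiency(site: KineticsRecord, reference: KineticsRecord) -> float:
    """Specificity ratio of a substrate to the undamaged reference."""
    if not reference.specificity_const:
        raise ValueError("reference specificity undefined or zero")
    if site.specificity_const is None:
        raise ValueError(f"{site.site}: specificity undefined")
    return site.specificity_const / reference.specificity_const


def mm_rate(v_max: float, k_m: float, s: float | np.ndarray):
    """Michaelis-Menten initial rate v0 = Vmax * S / (KM + S).

    In the low-substrate limit v0 -> (Vmax/KM) * S, the linear regime from
    which specificity constants of non-saturable substrates are read.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("substrate concentration must be >= 0")
    v = v_max * s / (k_m + s)
    return float(v) if v.ndim == 0 else v


def fit_michaelis_menten(s: np.ndarray, v0: np.ndarray) -> tuple[float, float]:
    """Least-squares (Vmax, KM) refit from (S, v0) points.

    Support for synthetic parameter-recovery studies; initial guesses come
    from the data (max rate; half-max crossing).
    """
    s = np.asarray(s, float)
    v0 = np.asarray(v0, float)
    vmax0 = float(v0.max()) * 1.2
    km0 = float(s[np.argmin(np.abs(v0 - vmax0 / 2))]) or float(np.median(s))
    popt, _ = curve_fit(lambda x, vm, km: vm * x / (km + x), s, v0,
                        p0=(vmax0, km0), maxfev=10000)
    return float(popt[0]), float(popt[1])
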