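"""Diffusion-ordered NMR (DOSY) decays and hydrodynamic radii.

Gradient-attenuated intensities follow I(x) = I0 * sum_i a_i exp(-D_i x),
where x is the diffusion-encoding attenuation variable (the Stejskal-Tanner
prefactor gamma^2 g^2 delta^2 (Delta - delta/3) folded in, units s/cm^2) and
D_i are translational diffusion coefficients in cm^2/s.  An internal
reference of known hydrodynamic radius (1% dioxane, R_h = 2.12 Å) converts a
measured D into R_h at identical temperature and viscosity:

    R_h = R_h,ref * D_ref / D.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "DosyDecay",
    "DiffusionFit",
    "ReferenceStandard",
    "DIOXANE",
    "stejskal_tanner_x",
    "fit_decay",
    "rh_from_reference",
]


@dataclass(frozen=True)
class DosyDecay:
    x: np.ndarray  # attenuation variable, s/cm^2
    intensity: np.ndarray  # signal units
    species_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, float))
        if self.x.size != self.intensity.size:
            raise ValueError("x and intensity must have equal length")
        if np.any(self.x < 0) or np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be non-negative and increasing")
        if self.intensity[0] <= 0:
            raise ValueError("intensity must be positive at x = 0")


@dataclass(frozen=True)
class DiffusionFit:
    d_values: tuple[float, ...]  # cm^2/s, sorted descending
    amplitudes: tuple[float, ...]  # fractions summing to 1
    i0: float
    model: Literal["single", "double"]
    rss: float = np.nan
    uncertainties: dict[str, float] | None = None
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class ReferenceStandard:
    d_ref: float  # cm^2/s
    rh_ref: float  # Å

    def __post_init__(self) -> None:
        if self.d_ref <= 0 or self.rh_ref <= 0:
            raise ValueError("reference D and R_h must be > 0")


# 1% dioxane internal standard: D = 6.8e-6 cm^2/s, R_h = 2.12 Å
DIOXANE = ReferenceStandard(d_ref=6.8e-6, rh_ref=2.12)


def stejskal_tanner_x(
    gamma: float, g: np.ndarray, delta: float, big_delta: float
) -> np.ndarray:
    """Attenuation variable x = gamma^2 g^2 delta^2 (Delta - delta/3).

    gamma in rad/(s*G), g in G/cm, delta and Delta in s -> x in s/cm^2.
    """
    g = np.asarray(g, float)
    return gamma**2 * g**2 * delta**2 * (big_delta - delta / 3.0)


def fit_decay(decay: DosyDecay, n_species: int = 1) -> DiffusionFit:
    """Least-squares mono- or bi-exponential fit of a DOSY decay.

    The two-species fit is initialized from the single-species solution,
    splitting its D into (D, D/3); a warning is attached when the two fitted
    coefficients are closer than a factor of 1.5 (practically
    indistinguishable).
    """
    if n_species not in (1, 2):
        raise ValueError("n_species must be 1 or 2")
    x, y = decay.x, decay.intensity
    if x.size < 8:
        raise ValueError("need at least 8 points")
    if np.any(y <= 0):
        raise ValueError("intensities must be positive")

    i0_0 = y[0]
    # log-linear slope as initial D
    d0 = max(-np.polyfit(x, np.log(y), 1)[0], 1e-12)

    if n_species == 1:
        popt, pcov = curve_fit(
            lambda xx, i0, d: i0 * np.exp(-d * xx),
            x,
            y,
            p0=[i0_0, d0],
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            maxfev=20000,
        )
        i0, d = popt
        resid = y - i0 * np.exp(-d * x)
        perr = np.sqrt(np.diag(pcov))
        return DiffusionFit(
            d_values=(float(d),),
            amplitudes=(1.0,),
            i0=float(i0),
            model="single",
            rss=float(resid @ resid),
            uncertainties={"i0": float(perr[0]), "d": float(perr[1])},
        )

    def model(xx, i0, a, d1, d2):
        return i0 * (a * np.exp(-d1 * xx) + (1.0 - a) * np.exp(-d2 * xx))

    popt, pcov = curve_fit(
        model,
        x,
        y,
        p0=[i0_0, 0.7, d0, d0 / 3.0],
        bounds=([0.0, 0.0, 0.0, 0.0], [np.inf, 1.0, np.inf, np.inf]),
        maxfev=40000,
    )
    i0, a, d1, d2 = popt
    if d1 < d2:
        d1, d2 = d2, d1
        a = 1.0 - a
    warns: list[str] = []
    if d2 > 0 and d1 / d2 < 1.5:
        warns.append("fitted diffusion coefficients differ by < 1.5x: "
                     "species are practically indistinguishable")
    resid = y - model(x, *popt)
    perr = np.sqrt(np.diag(pcov))
    return DiffusionFit(
        d_values=(float(d1), float(d2)),
        amplitudes=(float(a), float(1.0 - a)),
        i0=float(i0),
        model="double",
        rss=float(resid @ resid),
        uncertainties={
            "i0": float(perr[0]),
            "a": float(perr[1]),
            "d1": float(perr[2]),
            "d2": float(perr[3]),
        },
        warnings=tuple(warns),
    )


def rh_from_reference(d: float, std: ReferenceStandard = DIOXANE) -> float:
    """Hydrodynamic radius in Å from D via the internal reference."""
    if d <= 0:
        raise ValueError("diffusion coefficient must be > 0")
    return std.rh_ref * std.d_ref / d
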