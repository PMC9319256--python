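"""Equilibrium binding isotherms with explicit ligand depletion.

Fluorescence titrations at micromolar concentrations operate in the
depletion regime: the bound fraction of titrant is not negligible, so the
hyperbolic isotherm is replaced by the exact 1:1 mass-action solution.
With S the total titrant concentration, N the total concentration of the
fixed species and Kd the dissociation constant, the complex concentration
is the smaller root of the quadratic

    [complex]^2 - (S + N + Kd) [complex] + S N = 0,

and the observed signal is

    F = F0 + dFmax * [complex] / N,

i.e. F0 plus the saturating amplitude scaled by the bound fraction of the
fixed species.  Both titration conventions (titrating receptor into fixed
cargo, or cargo into fixed receptor) reduce to the same symmetric model;
the ``convention`` switch only records which physical species was held
fixed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "TitrationSeries",
    "BindingFit",
    "bound_complex",
    "depletion_model",
    "inner_filter_correct",
    "fit_titration",
]

Convention = Literal["fixed_is_cargo", "fixed_is_receptor"]


@dataclass(frozen=True)
class TitrationSeries:
    """One blank-subtracted titration: fixed species + titrant grid + signal."""

    fixed_conc: float  # µM, the species held constant
    titrant_concs: np.ndarray  # µM, total added titrant per point
    signal: np.ndarray  # arbitrary fluorescence units
    temperature: float = 298.15  # K

    def __post_init__(self) -> None:
        object.__setattr__(self, "titrant_concs", np.asarray(self.titrant_concs, float))
        object.__setattr__(self, "signal", np.asarray(self.signal, float))
        if self.fixed_conc <= 0:
            raise ValueError("fixed_conc must be > 0")
        t = self.titrant_concs
        if t.ndim != 1 or t.size != self.signal.size:
            raise ValueError("titrant_concs and signal must be 1-D and equal length")
        if np.any(t < 0):
            raise ValueError("titrant concentrations must be >= 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("titrant concentrations must be strictly increasing")


@dataclass(frozen=True)
class BindingFit:
    kd: float  # µM
    f0: float
    dfmax: float
    uncertainties: dict[str, float]
    residual_norm: float
    convention: Convention = "fixed_is_cargo"


def bound_complex(
    kd: float, total_a: np.ndarray | float, total_b: np.ndarray | float
) -> np.ndarray:
    """Equilibrium 1:1 complex concentration from totals (all µM, broadcastable).

    Smaller root of the mass-action quadratic; numerically safe for kd = 0
    (stoichiometric limit, bound = min(A, B)).
    """
    a = np.asarray(total_a, dtype=float)
    b = np.asarray(total_b, dtype=float)
    s = a + b + kd
    disc = s * s - 4.0 * a * b
    if np.any(disc < -1e-9 * np.maximum(s * s, 1.0)):
        raise ArithmeticError("negative discriminant in mass-action quadratic")
    return 0.5 * (s - np.sqrt(np.maximum(disc, 0.0)))


def depletion_model(
    kd: float,
    f0: float,
    dfmax: float,
    fixed_conc: float,
    titrant_conc: np.ndarray | float,
    convention: Convention = "fixed_is_cargo",
) -> np.ndarray:
    """Depletion-corrected signal at total titrant concentration(s)."""
    if kd < 0:
        raise ValueError("kd must be >= 0")
    if fixed_conc <= 0:
        raise ValueError("fixed_conc must be > 0")
    if convention not in ("fixed_is_cargo", "fixed_is_receptor"):
        raise ValueError(f"unknown convention {convention!r}")
    if np.any(np.asarray(titrant_conc) < 0):
        raise ValueError("titrant concentrations must be >= 0")
    complex_conc = bound_complex(kd, titrant_conc, fixed_conc)
    return f0 + dfmax * complex_conc / fixed_conc


def inner_filter_correct(
    f_obs: np.ndarray | float, a_ex: float, a_em: float
) -> np.ndarray | float:
    """Inner-filter correction F_corr = F_obs * 10^((A_ex + A_em)/2)."""
    if a_ex < 0 or a_em < 0:
        raise ValueError("absorbances must be >= 0")
    return np.asarray(f_obs, float) * 10.0 ** ((a_ex + a_em) / 2.0)


def fit_titration(
    series: TitrationSeries,
    convention: Convention = "fixed_is_cargo",
    weights: Sequence[float] | None = None,
) -> BindingFit:
    """Nonlinear least-squares fit of the depletion isotherm.

    Starting heuristic: f0 = first signal, dfmax = last - first, kd = titrant
    concentration nearest half-amplitude.  Unweighted unless per-point
    standard deviations are supplied.
    """
    t = series.titrant_concs
    y = series.signal
    if t.size < 5:
        raise ValueError("need at least 5 titration points")
    if np.ptp(y) == 0:
        raise ValueError("no binding signal: flat titration curve")

    f0_0 = y[0]
    dfmax_0 = y[-1] - y[0]
    half = f0_0 + 0.5 * dfmax_0
    kd_0 = float(t[np.argmin(np.abs(y - half))])
    kd_0 = max(kd_0, 1e-3)

    def model(s, kd, f0, dfmax):
        return depletion_model(kd, f0, dfmax, series.fixed_conc, s, convention)

    sigma = None if weights is None else np.asarray(weights, float)
    try:
        popt, pcov = curve_fit(
            model,
            t,
            y,
            p0=[kd_0, f0_0, dfmax_0],
            sigma=sigma,
            bounds=([0.0, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy message passthrough
        raise RuntimeError(f"titration fit did not converge: {exc}") from exc

    resid = y - model(t, *popt)
    perr = np.sqrt(np.diag(pcov))
    return BindingFit(
        kd=float(popt[0]),
        f0=float(popt[1]),
        dfmax=float(popt[2]),
        uncertainties={"kd": float(perr[0]), "f0": float(perr[1]), "dfmax": float(perr[2])},
        residual_norm=float(np.linalg.norm(resid)),
        convention=convention,
    )
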