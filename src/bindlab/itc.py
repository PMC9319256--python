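"""Isothermal titration calorimetry: single-site model, fitting, thermodynamics.

The forward model reproduces the integrated heat per injection for a 1:1
binding reaction in a fixed-volume (overflow) cell.  Injection bookkeeping
uses the standard discrete displacement correction: each injection of
volume dV expels an equal volume of pre-injection cell content, so totals
update as

    [M]_i = [M]_{i-1} (1 - dV/V0)
    [L]_i = [L]_{i-1} (1 - dV/V0) + [L]_syr dV/V0

and the heat of injection i is the enthalpy times the change in complex
moles inside the cell, crediting the complex expelled during the injection:

    q_i = dH * V0 * ([PL]_i - [PL]_{i-1} (1 - dV/V0)) + q_bg.

The stoichiometry parameter n scales the binding-competent macromolecule
concentration (n * [M]).  A constant per-injection background heat q_bg
absorbs buffer-mismatch/dilution heats (large in glycerol-containing
buffers).  Units: concentrations µM, volumes µL, dH kcal/mol, heats µcal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .titration import bound_complex

__all__ = [
    "GAS_CONSTANT_KCAL",
    "ITCExperiment",
    "ITCFit",
    "ThermoDecomposition",
    "single_site_heats",
    "fit_itc",
    "thermo_derive",
    "confidence_intervals_95",
]

GAS_CONSTANT_KCAL = 1.9872e-3  # kcal / (mol K)


@dataclass(frozen=True)
class ITCExperiment:
    cell_conc: float  # µM macromolecule in the cell, [M]0
    syringe_conc: float  # µM titrant in the syringe, [L]0
    cell_volume: float  # µL
    injection_volumes: np.ndarray  # µL per injection
    heats: np.ndarray  # µcal per injection
    temperature: float = 298.15  # K

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "injection_volumes", np.asarray(self.injection_volumes, float)
        )
        object.__setattr__(self, "heats", np.asarray(self.heats, float))
        if self.cell_conc <= 0 or self.syringe_conc <= 0 or self.cell_volume <= 0:
            raise ValueError("concentrations and volumes must be > 0")
        if self.injection_volumes.size != self.heats.size:
            raise ValueError("injection_volumes and heats must have equal length")
        if np.any(self.injection_volumes <= 0):
            raise ValueError("injection volumes must be > 0")


@dataclass(frozen=True)
class ITCFit:
    ka: float  # M^-1
    dh: float  # kcal/mol
    n: float  # stoichiometry / binding-competent fraction
    q_bg: float  # µcal per injection
    uncertainties: dict[str, float] = field(default_factory=dict)
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)
    residual_norm: float = 0.0
    warnings: tuple[str, ...] = ()

    @property
    def kd_uM(self) -> float:
        return 1e6 / self.ka


@dataclass(frozen=True)
class ThermoDecomposition:
    dg: float  # kcal/mol
    dh: float  # kcal/mol
    minus_tds: float  # kcal/mol, = dg - dh
    temperature: float  # K


def _cell_totals(exp: ITCExperiment) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-injection (M_tot, L_tot, dilution factor) after each injection."""
    v0 = exp.cell_volume
    dv = exp.injection_volumes
    fdil = 1.0 - dv / v0
    p = np.cumprod(fdil)  # cumulative dilution of the initial content
    m = exp.cell_conc * p
    # l_i = c * p_i * sum_{j<=i} (dv_j/v0)/p_j (discrete displacement recurrence)
    l = exp.syringe_conc * p * np.cumsum((dv / v0) / p)
    return m, l, fdil


def single_site_heats(
    ka: float, dh: float, n: float, q_bg: float, exp: ITCExperiment
) -> np.ndarray:
    """Model heats (µcal) per injection for the 1:1 model."""
    if not np.isfinite([ka, dh, n, q_bg]).all():
        raise ValueError("parameters must be finite")
    if ka <= 0:
        raise ValueError("ka must be > 0")
    kd_uM = 1e6 / ka
    m_tot, l_tot, fdil = _cell_totals(exp)
    pl = bound_complex(kd_uM, l_tot, n * m_tot)
    pl_prev = np.concatenate(([0.0], pl[:-1]))
    # kcal/mol * µL * µM -> 1e-3 µcal
    return dh * exp.cell_volume * (pl - pl_prev * fdil) * 1e-3 + q_bg


def thermo_derive(ka: float, dh: float, temperature: float = 298.15) -> ThermoDecomposition:
    """ΔG = −RT ln K_a and −TΔS = ΔG − ΔH (kcal/mol)."""
    if ka <= 0:
        raise ValueError("ka must be > 0")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    dg = -GAS_CONSTANT_KCAL * temperature * np.log(ka)
    return ThermoDecomposition(
        dg=float(dg), dh=dh, minus_tds=float(dg - dh), temperature=temperature
    )


def _fit_params(
    exp: ITCExperiment,
    heats: np.ndarray,
    p0: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares over (log10 K_a, dH, n, q_bg); ``mask`` selects which
    injections enter the residuals (the dilution bookkeeping always uses all
    of them)."""
    if mask is None:
        mask = np.ones(heats.size, dtype=bool)
    idx = np.arange(int(mask.sum()))

    def model(_i, log10_ka, dh, n, q_bg):
        return single_site_heats(10.0**log10_ka, dh, n, q_bg, exp)[mask]

    if p0 is None:
        q_bg0 = float(np.mean(heats[mask][-3:]))
        total = float(np.sum(heats[mask] - q_bg0))
        dh0 = total / (exp.cell_volume * exp.cell_conc * 1e-3)
        if dh0 == 0:
            dh0 = -1.0
        p0 = [5.0, dh0, 1.0, q_bg0]
    popt, pcov = curve_fit(
        model,
        idx,
        heats[mask],
        p0=p0,
        bounds=([0.0, -np.inf, 0.01, -np.inf], [12.0, np.inf, 10.0, np.inf]),
        maxfev=40000,
    )
    return popt, pcov


def fit_itc(exp: ITCExperiment, drop_first: bool = False) -> ITCFit:
    """Nonlinear least-squares fit of (K_a, ΔH, n, q_bg) to injection heats.

    K_a is optimized on a log10 scale for conditioning; reported in M⁻¹.
    ``drop_first`` excludes the first injection (common practice for the
    partial first-injection artifact) — by default it is fitted.
    """
    heats = exp.heats
    mask = np.ones(heats.size, dtype=bool)
    if drop_first:
        mask[0] = False  # heat excluded; the injected volume still dilutes
    if heats.size < 10:
        raise ValueError("need at least 10 injections")
    if np.allclose(heats, 0.0, atol=1e-12):
        raise ValueError("no binding signal: all heats are zero")
    if np.ptp(heats[mask]) == 0:
        raise ValueError("no binding signal: flat thermogram")

    try:
        popt, pcov = _fit_params(exp, heats, mask=mask)
    except RuntimeError as exc:
        raise RuntimeError(f"ITC fit did not converge: {exc}") from exc

    log10_ka, dh, n, q_bg = popt
    ka = 10.0**log10_ka
    perr = np.sqrt(np.diag(pcov))
    # d(ka)/d(log10 ka) = ka ln 10
    unc = {
        "ka": float(perr[0] * ka * np.log(10.0)),
        "dh": float(perr[1]),
        "n": float(perr[2]),
        "q_bg": float(perr[3]),
    }
    resid = (heats - single_site_heats(ka, dh, n, q_bg, exp))[mask]
    warns: list[str] = []
    c_value = ka * exp.cell_conc * 1e-6
    if not (1.0 <= c_value <= 1e4):
        warns.append(
            f"c-value {c_value:.3g} outside [1, 1e4]: low information content"
        )
    return ITCFit(
        ka=float(ka),
        dh=float(dh),
        n=float(n),
        q_bg=float(q_bg),
        uncertainties=unc,
        residual_norm=float(np.linalg.norm(resid)),
        warnings=tuple(warns),
    )


def confidence_intervals_95(
    fit: ITCFit,
    exp: ITCExperiment,
    n_boot: int = 200,
    seed: int | None = None,
) -> dict[str, tuple[float, float]]:
    """Residual-resampling bootstrap 95% confidence intervals.

    Model residuals, rescaled by sqrt(n / (n - p)) to undo the downward bias
    of plug-in residual variance (p = 4 fitted parameters), are resampled
    with replacement onto the fitted curve and each pseudo-dataset is refit;
    the 2.5/97.5 percentiles of each parameter form the interval (asymmetric
    intervals arise naturally, especially for K_a).  Raises if more than 20%
    of refits fail.
    """
    rng = np.random.default_rng(seed)
    yhat = single_site_heats(fit.ka, fit.dh, fit.n, fit.q_bg, exp)
    n_pts = exp.heats.size
    resid = (exp.heats - yhat) * np.sqrt(n_pts / max(n_pts - 4, 1))
    p_hat = np.array([np.log10(fit.ka), fit.dh, fit.n, fit.q_bg])
    samples: dict[str, list[float]] = {"ka": [], "dh": [], "n": [], "q_bg": []}
    failures = 0
    for _ in range(n_boot):
        y_star = yhat + rng.choice(resid, size=resid.size, replace=True)
        exp_star = ITCExperiment(
            exp.cell_conc,
            exp.syringe_conc,
            exp.cell_volume,
            exp.injection_volumes,
            y_star,
            exp.temperature,
        )
        try:
            popt, _ = _fit_params(exp_star, y_star, p0=p_hat)
        except RuntimeError:
            failures += 1
            continue
        samples["ka"].append(10.0 ** popt[0])
        samples["dh"].append(popt[1])
        samples["n"].append(popt[2])
        samples["q_bg"].append(popt[3])
    if failures > 0.2 * n_boot:
        raise RuntimeError(f"bootstrap refit failure rate too high: {failures}/{n_boot}")
    return {
        name: (float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5)))
        for name, vals in samples.items()
    }
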