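"""Biolayer interferometry kinetics.

Association phases are fitted to one or two exponentials approaching the
steady-state response R_eq,

    single:  R(t) = R_eq - R_eq exp(-k_obs (t - t0))
    double:  R(t) = R_eq - R_eq exp(-k_obs (t - t0)) - R'_eq exp(-k'_obs2 (t - t0))

where the double model adds a small transient second phase (the equilibrium
response at infinite time is still R_eq).  Dissociation is always a single
exponential R(t) = R1 exp(-k_off (t - t0)).  The concentration-dependent
rate of the dominant phase follows pseudo-first-order kinetics,

    k_obs = k_on * C + k_off,

so a linear regression of k_obs on analyte concentration yields k_on
(slope), k_off (intercept) and K_d = k_off / k_on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

__all__ = [
    "Sensorgram",
    "PhaseFit",
    "KineticFit",
    "fit_association",
    "select_model",
    "fit_dissociation",
    "pseudo_first_order",
    "kd_from_rates",
]

Model = Literal["single", "double"]


@dataclass(frozen=True)
class Sensorgram:
    time: np.ndarray  # s
    response: np.ndarray  # RU
    analyte_conc: float  # µM
    t0_assoc: float = 180.0  # s, start of association
    t0_dissoc: float = 300.0  # s, start of dissociation

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, float))
        object.__setattr__(self, "response", np.asarray(self.response, float))
        if self.time.size != self.response.size:
            raise ValueError("time and response must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not (self.t0_assoc < self.t0_dissoc <= self.time[-1]):
            raise ValueError("need t0_assoc < t0_dissoc <= max(time)")

    def association_window(self) -> tuple[np.ndarray, np.ndarray]:
        m = (self.time >= self.t0_assoc) & (self.time < self.t0_dissoc)
        return self.time[m], self.response[m]

    def dissociation_window(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.time >= self.t0_dissoc
        return self.time[m], self.response[m]


@dataclass(frozen=True)
class PhaseFit:
    model: Model
    req: float  # RU, amplitude of the dominant (fast) phase
    kobs: float  # s^-1, rate of the dominant phase
    req2: float = 0.0  # RU, second-phase amplitude (double model)
    kobs2: float = 0.0  # s^-1, second-phase rate
    r1: float = 0.0  # RU, dissociation amplitude
    koff_local: float = 0.0  # s^-1, per-sensorgram dissociation rate
    rss: float = np.nan
    tss: float = np.nan
    n_points: int = 0
    uncertainties: dict[str, float] = field(default_factory=dict)
    fstat: float = np.nan
    p_value: float = np.nan
    warnings: tuple[str, ...] = ()

    @property
    def minor_fraction(self) -> float:
        tot = abs(self.req) + abs(self.req2)
        return abs(self.req2) / tot if tot > 0 else 0.0


@dataclass(frozen=True)
class KineticFit:
    kon: float  # µM^-1 s^-1
    koff: float  # s^-1
    kd: float  # µM
    kon_se: float = np.nan
    koff_se: float = np.nan
    kd_se: float = np.nan


def _assoc_single(t, req, kobs, t0):
    return req - req * np.exp(-kobs * (t - t0))


def _assoc_double(t, req, kobs, req2, kobs2, t0):
    return (
        req
        - req * np.exp(-kobs * (t - t0))
        - req2 * np.exp(-kobs2 * (t - t0))
    )


def fit_association(sg: Sensorgram, model: Model = "double") -> PhaseFit:
    """Fit the association window to one or two exponentials.

    For the double model the larger-amplitude term is designated the primary
    phase (its rate is the k_obs used downstream); a warning is attached if
    its amplitude fraction drops to 50% or below.
    """
    t, r = sg.association_window()
    if t.size < 20:
        raise ValueError("need at least 20 samples in the association window")
    if np.ptp(r) < 1e-12:
        raise ValueError("no association signal: flat response")
    t0 = sg.t0_assoc
    req0 = r[-1]
    # crude rate guess from time to half-saturation
    half_idx = int(np.argmin(np.abs(r - 0.5 * req0)))
    t_half = max(t[half_idx] - t0, (t[1] - t[0]))
    kobs0 = np.log(2.0) / t_half

    warns: list[str] = []
    if model == "single":
        popt, pcov = curve_fit(
            lambda tt, req, kobs: _assoc_single(tt, req, kobs, t0),
            t,
            r,
            p0=[req0, kobs0],
            bounds=([-np.inf, 0.0], [np.inf, np.inf]),
            maxfev=20000,
        )
        req, kobs = popt
        resid = r - _assoc_single(t, req, kobs, t0)
        perr = np.sqrt(np.diag(pcov))
        return PhaseFit(
            model="single",
            req=float(req),
            kobs=float(kobs),
            rss=float(resid @ resid),
            tss=float(np.sum((r - r.mean()) ** 2)),
            n_points=int(t.size),
            uncertainties={"req": float(perr[0]), "kobs": float(perr[1])},
        )
    if model != "double":
        raise ValueError(f"unknown model {model!r}")
    popt, pcov = curve_fit(
        lambda tt, req, kobs, req2, kobs2: _assoc_double(tt, req, kobs, req2, kobs2, t0),
        t,
        r,
        p0=[req0, kobs0, 0.05 * req0, 0.1 * kobs0],
        bounds=([-np.inf, 0.0, -np.inf, 0.0], [np.inf, np.inf, np.inf, np.inf]),
        maxfev=40000,
    )
    req, kobs, req2, kobs2 = popt
    perr = np.sqrt(np.diag(pcov))
    # designate the larger-amplitude exponential as the primary phase
    if abs(req2) > abs(req):
        req, req2 = req2, req
        kobs, kobs2 = kobs2, kobs
        perr = perr[[2, 3, 0, 1]]
    frac = abs(req) / (abs(req) + abs(req2))
    if frac <= 0.5:
        warns.append("primary-phase amplitude fraction <= 50%")
    resid = r - _assoc_double(t, popt[0], popt[1], popt[2], popt[3], t0)
    return PhaseFit(
        model="double",
        req=float(req),
        kobs=float(kobs),
        req2=float(req2),
        kobs2=float(kobs2),
        rss=float(resid @ resid),
        tss=float(np.sum((r - r.mean()) ** 2)),
        n_points=int(t.size),
        uncertainties={
            "req": float(perr[0]),
            "kobs": float(perr[1]),
            "req2": float(perr[2]),
            "kobs2": float(perr[3]),
        },
        warnings=tuple(warns),
    )


def select_model(fit_single: PhaseFit, fit_double: PhaseFit, n_points: int) -> Model:
    """Nested-model F-test (95% confidence) between one and two exponentials.

    F = ((RSS1 - RSS2)/(p2 - p1)) / (RSS2/(n - p2)) with p1 = 2, p2 = 4
    parameters; the double model is chosen iff p < 0.05.
    """
    p1, p2 = 2, 4
    if n_points <= p2:
        raise ValueError("fewer points than parameters")
    rss1, rss2 = fit_single.rss, fit_double.rss
    # both models at machine precision (noiseless data): keep the simpler one
    tss = fit_single.tss
    if np.isfinite(tss) and tss > 0 and rss1 <= 1e-12 * tss:
        return "single"
    if rss2 <= 0 or rss1 <= rss2 * (1 + 1e-12):
        return "single"
    f = ((rss1 - rss2) / (p2 - p1)) / (rss2 / (n_points - p2))
    p = float(stats.f.sf(f, p2 - p1, n_points - p2))
    return "double" if p < 0.05 else "single"


def fit_dissociation(sg: Sensorgram) -> PhaseFit:
    """Single-exponential dissociation fit R(t) = R1 exp(-k_off (t - t0))."""
    t, r = sg.dissociation_window()
    if t.size < 20:
        raise ValueError("need at least 20 samples after t0_dissoc")
    t0 = sg.t0_dissoc
    r10 = r[0] if r[0] != 0 else 1.0
    warns: list[str] = []
    if np.ptp(r) < 1e-9 * max(abs(r10), 1.0):
        # no measurable decay
        warns.append("no dissociation observed: response is flat")
        return PhaseFit(
            model="single",
            req=0.0,
            kobs=0.0,
            r1=float(np.mean(r)),
            koff_local=0.0,
            rss=float(np.sum((r - np.mean(r)) ** 2)),
            n_points=int(t.size),
            warnings=tuple(warns),
        )
    popt, pcov = curve_fit(
        lambda tt, r1, koff: r1 * np.exp(-koff * (tt - t0)),
        t,
        r,
        p0=[r10, 0.01],
        bounds=([-np.inf, 0.0], [np.inf, np.inf]),
        maxfev=20000,
    )
    r1, koff = popt
    resid = r - r1 * np.exp(-koff * (t - t0))
    perr = np.sqrt(np.diag(pcov))
    return PhaseFit(
        model="single",
        req=0.0,
        kobs=0.0,
        r1=float(r1),
        koff_local=float(koff),
        rss=float(resid @ resid),
        n_points=int(t.size),
        uncertainties={"r1": float(perr[0]), "koff": float(perr[1])},
    )


def pseudo_first_order(
    kobs_by_conc: Sequence[tuple[float, float]],
    kobs_se: Sequence[float] | None = None,
) -> KineticFit:
    """Linear regression k_obs = k_on C + k_off over analyte concentrations.

    Unweighted by default; per-point k_obs standard errors weight the fit if
    supplied.  The K_d standard error is propagated with the delta method
    from the slope/intercept covariance.
    """
    conc = np.array([p[0] for p in kobs_by_conc], float)
    kobs = np.array([p[1] for p in kobs_by_conc], float)
    if np.unique(conc).size < 3:
        raise ValueError("need at least 3 distinct concentrations")
    if kobs_se is None:
        w = np.ones_like(conc)
    else:
        w = 1.0 / np.asarray(kobs_se, float) ** 2
    order = np.argsort(conc)
    conc, kobs, w = conc[order], kobs[order], w[order]
    X = np.column_stack([conc, np.ones_like(conc)])
    W = np.diag(w)
    xtwx = X.T @ W @ X
    beta = np.linalg.solve(xtwx, X.T @ W @ kobs)
    kon, koff = float(beta[0]), float(beta[1])
    if kon <= 0:
        raise ValueError("no concentration dependence: non-positive slope")
    resid = kobs - X @ beta
    dof = conc.size - 2
    s2 = float(resid @ W @ resid) / dof if dof > 0 else 0.0
    cov = s2 * np.linalg.inv(xtwx)
    kon_se = float(np.sqrt(cov[0, 0]))
    koff_se = float(np.sqrt(cov[1, 1]))
    kd = koff / kon
    # delta method: kd = koff/kon
    grad = np.array([-koff / kon**2, 1.0 / kon])
    kd_se = float(np.sqrt(grad @ cov @ grad))
    return KineticFit(
        kon=kon, koff=koff, kd=kd, kon_se=kon_se, koff_se=koff_se, kd_se=kd_se
    )


def analyze_sensorgrams(
    sensorgrams: Sequence[Sensorgram],
    weighted: bool = True,
) -> tuple[KineticFit, list[PhaseFit], list[PhaseFit]]:
    """Two-step kinetic analysis of a concentration series.

    Per sensorgram: fit one and two exponentials to the association phase,
    keep the model favored by the 95% F-test, and fit the dissociation
    phase.  The double fit is discarded in favor of the single fit when its
    designated primary rate is not identifiable (non-finite standard error,
    or standard error exceeding the rate itself), which happens at low
    signal-to-noise.  The k_obs values are then regressed on concentration
    (weighted by their standard errors by default) to give k_on, k_off and
    K_d = k_off/k_on.
    """
    assoc_fits: list[PhaseFit] = []
    dissoc_fits: list[PhaseFit] = []
    for sg in sensorgrams:
        single = fit_association(sg, model="single")
        double = fit_association(sg, model="double")
        chosen = select_model(single, double, single.n_points)
        fit = double if chosen == "double" else single
        se = fit.uncertainties.get("kobs", np.inf)
        if fit.model == "double" and not (np.isfinite(se) and se < fit.kobs):
            fit = single
        assoc_fits.append(fit)
        dissoc_fits.append(fit_dissociation(sg))
    pairs = [(sg.analyte_conc, f.kobs) for sg, f in zip(sensorgrams, assoc_fits)]
    ses = [f.uncertainties.get("kobs", np.nan) for f in assoc_fits]
    use_w = weighted and np.all(np.isfinite(ses)) and np.all(np.asarray(ses) > 0)
    kin = pseudo_first_order(pairs, kobs_se=ses if use_w else None)
    return kin, assoc_fits, dissoc_fits


def kd_from_rates(koff: float, kon: float) -> float:
    """K_d = k_off / k_on (µM for k_on in µM^-1 s^-1)."""
    if kon <= 0:
        raise ValueError("kon must be > 0")
    if koff < 0:
        raise ValueError("koff must be >= 0")
    return koff / kon
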