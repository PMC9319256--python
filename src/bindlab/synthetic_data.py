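"""Seeded synthetic-data generators for every fitting stage.

Each generator is a pure function of (truth, design, seed) built on the
corresponding forward model, so zero-noise output is exactly the model
curve and fixed seeds give byte-identical datasets.  Generators return the
dataset together with a :class:`SyntheticTruth` carrying the generating
parameters, for parameter-recovery tests.

The named ``SCENARIOS`` encode the study conditions: fluorescence
titrations of a 3 µM cargo with micromolar K_d; calorimetric titrations of
20 x 2 µL injections of 100 µM titrant into 10 µM receptor with a constant
background injection heat; sensorgrams at 1-7 µM analyte with association
starting at 180 s and dissociation at 300 s, plus a slow minor phase below
5% amplitude; and mono/bi-exponential DOSY decays.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .bli import Sensorgram
from .fragscan import FragmentScore, aggregate_per_residue, call_core_region
from .hydrodynamics import DosyDecay
from .itc import ITCExperiment, single_site_heats
from .peptides import PeptideSequence, make_fragments
from .titration import TitrationSeries, depletion_model

__all__ = [
    "SyntheticTruth",
    "SCENARIOS",
    "gen_titration",
    "gen_itc",
    "gen_bli",
    "gen_dosy",
    "gen_affinity_landscape",
]


@dataclass(frozen=True)
class SyntheticTruth:
    model_name: str
    parameters: dict
    noise_sd: float
    seed: int | None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


# Study parameter sets (equilibrium constants in µM or M^-1, enthalpies in
# kcal/mol, rates in µM^-1 s^-1 / s^-1, diffusion coefficients in cm^2/s).
SCENARIOS: dict[str, dict] = {
    # fluorescence titrations (fixed cargo 3 µM)
    "padi4_impa3_fluorescence": {"kd": 3.9, "f0": 100.0, "dfmax": 50.0, "fixed_conc": 3.0},
    "padi4_dimpa3_fluorescence": {"kd": 6.0, "f0": 100.0, "dfmax": 50.0, "fixed_conc": 3.0},
    # calorimetric titrations (ka M^-1, dh kcal/mol, n, q_bg µcal)
    "padi4_impa3_itc": {"ka": 2.1e5, "dh": -65.5, "n": 0.97, "q_bg": -0.8},
    "padi4_dimpa3_itc": {"ka": 7.8e5, "dh": -38.4, "n": 0.84, "q_bg": -0.8},
    "nls1_impa3_itc": {"ka": 2.3e5, "dh": -21.3, "n": 1.24, "q_bg": -0.8},
    "nls1_dimpa3_itc": {"ka": 6.5e5, "dh": -8.7, "n": 1.22, "q_bg": -0.8},
    "nls2_impa3_itc": {"ka": 0.43e5, "dh": -35.7, "n": 1.08, "q_bg": -0.8},
    "nls2_dimpa3_itc": {"ka": 2.3e5, "dh": -11.2, "n": 1.10, "q_bg": -0.8},
    # interferometry kinetics
    "nls1_impa3_bli": {"kon": 0.0037, "koff": 0.0685, "rmax": 1.0,
                       "minor_frac": 0.04, "kobs2": 0.005},
    "nls1_dimpa3_bli": {"kon": 0.011, "koff": 0.046, "rmax": 1.0,
                        "minor_frac": 0.04, "kobs2": 0.005},
    "nls2_impa3_bli": {"kon": 0.003, "koff": 0.32, "rmax": 1.0,
                       "minor_frac": 0.04, "kobs2": 0.005},
    "nls2_dimpa3_bli": {"kon": 0.020, "koff": 0.23, "rmax": 1.0,
                        "minor_frac": 0.04, "kobs2": 0.005},
    # DOSY decays
    "nls1_dosy_two_species": {"d_list": [8.8e-7, 4.0e-7], "amp_list": [0.7, 0.3]},
    "nls2_dosy_single": {"d_list": [9.6e-7], "amp_list": [1.0]},
}


def gen_titration(
    truth: Mapping[str, float],
    points: int = 12,
    noise_sd: float = 0.5,
    seed: int | None = None,
) -> tuple[TitrationSeries, SyntheticTruth]:
    """Depletion-isotherm titration with additive Gaussian noise.

    Titrant grid: 0 plus ``points - 1`` evenly spaced concentrations up to
    5 x max(kd, fixed_conc), spanning sub- to super-stoichiometric titrant.
    """
    if points < 5:
        raise ValueError("need at least 5 points")
    kd, f0, dfmax = truth["kd"], truth["f0"], truth["dfmax"]
    fixed = truth["fixed_conc"]
    top = 5.0 * max(kd, fixed)
    titrant = np.linspace(0.0, top, points)
    rng = np.random.default_rng(seed)
    signal = depletion_model(kd, f0, dfmax, fixed, titrant)
    signal = signal + rng.normal(0.0, noise_sd, size=points)
    series = TitrationSeries(fixed_conc=fixed, titrant_concs=titrant, signal=signal)
    return series, SyntheticTruth("depletion_titration", dict(truth), noise_sd, seed)


def gen_itc(
    truth: Mapping[str, float],
    n_injections: int = 20,
    injection_volume: float = 2.0,
    cell_conc: float = 10.0,
    syringe_conc: float = 100.0,
    cell_volume: float = 200.0,
    noise_sd: float = 0.1,
    seed: int | None = None,
) -> tuple[ITCExperiment, SyntheticTruth]:
    """Single-site calorimetric titration with Gaussian heat noise (µcal)."""
    volumes = np.full(n_injections, injection_volume)
    base = ITCExperiment(
        cell_conc=cell_conc,
        syringe_conc=syringe_conc,
        cell_volume=cell_volume,
        injection_volumes=volumes,
        heats=np.zeros(n_injections),
    )
    heats = single_site_heats(truth["ka"], truth["dh"], truth["n"], truth["q_bg"], base)
    rng = np.random.default_rng(seed)
    heats = heats + rng.normal(0.0, noise_sd, size=n_injections)
    exp = ITCExperiment(
        cell_conc=cell_conc,
        syringe_conc=syringe_conc,
        cell_volume=cell_volume,
        injection_volumes=volumes,
        heats=heats,
    )
    return exp, SyntheticTruth("itc_single_site", dict(truth), noise_sd, seed)


def gen_bli(
    truth: Mapping[str, float],
    concs: Sequence[float] = (1.0, 2.0, 3.0, 5.0, 7.0),
    t0_assoc: float = 180.0,
    t0_dissoc: float = 300.0,
    t_end: float = 500.0,
    dt: float = 0.5,
    noise_sd: float = 0.02,
    seed: int | None = None,
) -> tuple[list[Sensorgram], SyntheticTruth]:
    """Sensorgrams at several analyte concentrations.

    Association: two exponentials with the dominant rate k_obs = kon C + koff
    and steady-state response R_eq = Rmax C/(C + K_d); the minor phase has
    amplitude ``minor_frac * R_eq`` and the concentration-independent rate
    ``kobs2``.  Dissociation: single exponential at koff from the response
    level reached at t0_dissoc.
    """
    kon, koff = truth["kon"], truth["koff"]
    rmax = truth.get("rmax", 1.0)
    minor_frac = truth.get("minor_frac", 0.0)
    kobs2 = truth.get("kobs2", 0.0)
    if minor_frac < 0 or minor_frac > 0.05:
        raise ValueError("minor_frac must be within [0, 0.05]")
    kd = koff / kon
    rng = np.random.default_rng(seed)
    time = np.arange(0.0, t_end + dt / 2, dt)
    out: list[Sensorgram] = []
    for c in concs:
        req = rmax * c / (c + kd)
        req2 = minor_frac * req
        kobs = kon * c + koff
        r = np.zeros_like(time)
        assoc = (time >= t0_assoc) & (time < t0_dissoc)
        ta = time[assoc] - t0_assoc
        r[assoc] = req - req * np.exp(-kobs * ta) - req2 * (
            np.exp(-kobs2 * ta) if kobs2 > 0 else 1.0
        )
        # response level at the start of dissociation
        td0 = t0_dissoc - t0_assoc
        r1 = req - req * np.exp(-kobs * td0) - req2 * (
            np.exp(-kobs2 * td0) if kobs2 > 0 else 1.0
        )
        dis = time >= t0_dissoc
        r[dis] = r1 * np.exp(-koff * (time[dis] - t0_dissoc))
        r = r + rng.normal(0.0, noise_sd, size=time.size)
        out.append(
            Sensorgram(time=time, response=r, analyte_conc=float(c),
                       t0_assoc=t0_assoc, t0_dissoc=t0_dissoc)
        )
    return out, SyntheticTruth("bli_two_phase", dict(truth), noise_sd, seed)


def gen_dosy(
    truth: Mapping[str, Sequence[float]],
    n_points: int = 32,
    x_max: float | None = None,
    i0: float = 1.0,
    noise_sd: float = 0.005,
    seed: int | None = None,
) -> tuple[DosyDecay, SyntheticTruth]:
    """Mono/bi-exponential gradient decay with additive Gaussian noise.

    The default attenuation grid follows standard DOSY design: the maximum
    gradient attenuates even the slowest component to under 10% of its
    initial intensity (x_max = 2.5 / min(D)), so both decay scales are
    sampled.
    """
    d_list = np.asarray(truth["d_list"], float)
    amp_list = np.asarray(truth["amp_list"], float)
    if d_list.size != amp_list.size:
        raise ValueError("d_list and amp_list must have equal length")
    if not np.isclose(amp_list.sum(), 1.0):
        raise ValueError("amplitudes must sum to 1")
    if x_max is None:
        x_max = 2.5 / d_list.min()
    x = np.linspace(0.0, x_max, n_points)
    rng = np.random.default_rng(seed)
    intensity = i0 * (amp_list[None, :] * np.exp(-np.outer(x, d_list))).sum(axis=1)
    intensity = intensity + rng.normal(0.0, noise_sd, size=n_points)
    decay = DosyDecay(x=x, intensity=intensity)
    params = {"d_list": list(map(float, d_list)),
              "amp_list": list(map(float, amp_list)), "i0": i0}
    return decay, SyntheticTruth("dosy_decay", params, noise_sd, seed)


_LANDSCAPE_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def gen_affinity_landscape(
    seq_length: int = 27,
    start_number: int = 58,
    core_center: int = 68,
    core_depth: float = 2.0,
    core_halfwidth: float = 2.0,
    baseline: float = -6.5,
    noise_sd: float = 0.05,
    seed: int | None = None,
    window: int = 7,
    step: int = 2,
) -> tuple[list[FragmentScore], PeptideSequence, SyntheticTruth]:
    """Fragment scores over a random peptide with a single affinity minimum.

    Fragments whose midpoint lies within ``core_halfwidth`` residues of
    ``core_center`` score ``baseline - core_depth``; all others score
    ``baseline`` (plus noise).  After per-residue averaging over the
    overlapping windows this yields a single-minimum profile whose residue
    values are quantized at fractions {0, 1/4, 1/3, 1/2, 2/3} of
    ``core_depth`` below baseline (the 3/4-coverage parity of a window-7 /
    step-2 tiling).  The default depth of 2 kcal/mol places every level
    1/6 kcal/mol or more away from the default 0.5 kcal/mol core-calling
    margin, so at the default score noise (0.05 kcal/mol, the scale of
    docking score quantization) the constructed core is recovered
    essentially always.  The truth records the core region that
    :func:`bindlab.fragscan.call_core_region` returns on the noiseless
    landscape.
    """
    rng = np.random.default_rng(seed)
    residues = "".join(rng.choice(list(_LANDSCAPE_ALPHABET), size=seq_length))
    parent = PeptideSequence(residues, start_number=start_number)
    fragments = make_fragments(parent, window=window, step=step)

    def clean_score(frag):
        mid = 0.5 * (frag.start_number + frag.end_number)
        in_core = abs(mid - core_center) <= core_halfwidth
        return baseline - (core_depth if in_core else 0.0)

    clean = [FragmentScore(f, clean_score(f)) for f in fragments]
    true_core = call_core_region(aggregate_per_residue(clean, parent))
    scores = [
        FragmentScore(f, clean_score(f) + rng.normal(0.0, noise_sd))
        for f in fragments
    ]
    params = {
        "core_center": core_center,
        "core_depth": core_depth,
        "core_halfwidth": core_halfwidth,
        "baseline": baseline,
        "core_region": true_core,
        "sequence": residues,
        "start_number": start_number,
    }
    return scores, parent, SyntheticTruth("affinity_landscape", params, noise_sd, seed)
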