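# Methods

This note records the models implemented in `bindlab`, the defaults and
their rationale, what the synthetic generators do and do not emulate, and
the numerical choices a maintainer would otherwise have to reverse-engineer.

## Equilibrium titrations (`bindlab.titration`)

The depletion isotherm solves the 1:1 mass-action quadratic exactly and
scales the saturating amplitude ΔF_max by the bound fraction of the fixed
species. Both experimental conventions — titrating the receptor into fixed
cargo, or the peptide into fixed receptor — reduce to the same symmetric
model; the `convention` flag only records which species was held fixed.
The amplitude is treated as a signal quantity (dimensionally consistent
with the fitted data), not a concentration.

Fitting is unweighted nonlinear least squares (`scipy.optimize.curve_fit`)
with starting values F₀ = first point, ΔF_max = last − first, K_d = titrant
concentration nearest half-amplitude — robust on monotone curves. K_d is
bounded below by zero. Standard errors come from the local curvature.
The inner-filter correction is the standard
F·10^((A_ex+A_em)/2) form and is pluggable.

Degenerate inputs: a flat signal raises "no binding signal"; fewer than
five points is rejected; the mass-action discriminant is clipped at zero
(it is analytically non-negative; the clip only absorbs float rounding).

## Single-site calorimetry (`bindlab.itc`)

Injection bookkeeping uses the discrete displacement model for a
fixed-volume cell: each injection of volume dV dilutes the existing
content by (1 − dV/V₀) and the expelled volume carries pre-injection
complex, credited in the heat of that injection:

    q_i = ΔH·V₀·([PL]_i − [PL]_{i−1}(1 − dV_i/V₀)) + q_bg.

The per-injection totals have a closed cumulative-product form, so the
model is fully vectorized; an independent bisection solver reproduces it
to 1e−8 in the tests. n scales the binding-competent macromolecule
concentration. K_a is optimized as log₁₀K_a for conditioning (bounds
10⁰–10¹²). The first injection is fitted by default; `drop_first`
removes its heat from the residuals while keeping its volume in the
dilution bookkeeping.

Confidence intervals are residual-resampling bootstrap percentiles
(default 200 draws, seeded), with residuals rescaled by √(n/(n−p)) to
undo the downward bias of plug-in residual variance at n = 20 points and
p = 4 parameters; without the rescaling, measured coverage of the 95%
intervals fell several points short of nominal. Refits start from the
point estimate; a failure rate above 20% aborts.

**Information limits.** With the default schedule (20 × 2 µL of 100 µM
into 10 µM, final molar ratio ≈ 2) the low-enthalpy scenarios
(|ΔH| ≲ 20 kcal/mol) and the low-c scenario (c = K_a·[M]₀ ≈ 0.4) are
weakly identifiable: K_a, ΔH and n trade off along a nearly flat
likelihood valley, and point estimates far from truth can have residuals
identical to truth-started fits. The package flags c outside [1, 10⁴]
with a low-information warning, and the bootstrap intervals widen
accordingly (see `analysis/03_itc_thermodynamics.py`). Parameter-recovery
guarantees are therefore only claimed for the high-enthalpy scenarios.

−TΔS is reported as ΔG − ΔH, so a binding that is enthalpically driven
against entropy carries a **positive** −TΔS (e.g. +58.2 kcal/mol for
ΔG = −7.3, ΔH = −65.5). Published tables sometimes print this column with
the opposite sign convention; the identity ΔG = ΔH + (−TΔS) is the
package's invariant.

## Interferometry kinetics (`bindlab.bli`)

Association fits use one or two exponentials with the equilibrium
response carried by the fast phase; the larger-amplitude term is
designated primary (its rate is the downstream k_obs), with a warning if
its amplitude fraction is ≤ 50%. Model choice is a nested F-test at 95%
(p₁ = 2, p₂ = 4 parameters). On noiseless data both models sit at machine
precision and the F-ratio is meaningless, so fits with RSS below
10⁻¹²·TSS resolve to the single model by parsimony.

`analyze_sensorgrams` implements the two-step study procedure per
concentration series and adds two robustness rules, both within the
stated method: (i) if the selected double fit's primary rate is not
identifiable (non-finite standard error, or standard error exceeding the
rate — the low signal-to-noise regime at the lowest analyte
concentrations), the single fit is used instead; (ii) the
pseudo-first-order regression is weighted by the per-point k_obs standard
errors (unweighted remains the `pseudo_first_order` default). The K_d
standard error is propagated from the slope/intercept covariance by the
delta method.

A known small bias: when the F-test (correctly, at its 5% level) fails to
detect the genuine ~4% slow phase on noisy data, the single-exponential
compromise rate is slightly low, giving k_off a systematic ≈ −9% bias at
the default noise. The regression parameters k_on and k_off are the
quantities with controlled bias; K_d = k_off/k_on is a heavy-tailed ratio
whose replicate mean is Jensen-biased upward, so aggregate checks on K_d
use the median.

## DOSY hydrodynamics (`bindlab.hydrodynamics`)

The module consumes a pre-computed attenuation variable x (s/cm²); a
helper builds x = γ²g²δ²(Δ − δ/3) from acquisition parameters. Two-species
fits are initialized from the single-species solution split into
(D, D/3), stable for ~2× separations; coefficients closer than 1.5×
trigger an indistinguishability warning. The internal-reference
conversion assumes identical temperature and viscosity for analyte and
reference (same tube), making R_h a pure ratio — homogeneous under
rescaling of both D values.

The inverse random-coil relation applied to the printed rounded study
values does not exactly reproduce the printed downstream numbers
(34 Å → 15,858 Da here vs a printed 16,421.9 Da; unrounded intermediates
were evidently used upstream). The package reports computed values; the
oligomer-order call (hexamer) is the same either way.

## Peptide arithmetic (`bindlab.peptides`)

Average (not monoisotopic) residue masses from the standard atomic
weights; cap adjustments are configurable deltas (acetyl +42.037,
C-terminal amide −0.984, methyl caps +14.027 per terminus relative to
free). The free-termini mass of the NLS1 27-mer and the acetyl+amide mass
of the NLS2 29-mer both land within 0.05 Da of their study values —
note those two printed values follow different cap conventions, a
discrepancy the package documents rather than resolves. Residue numbering
is 1-based and anchored to the parent protein; fragments inherit it.
If (L − W) is not divisible by the step, the final exactly-fitting window
is used and a warning logged (both study tilings are exact).
Oligomer order rounds half away from zero (5.83 → 6, 2.5 → 3).

## Fragment-docking aggregation (`bindlab.fragscan`)

Scores are affinities in kcal/mol, lower is better. Per-residue means are
exact arithmetic means over covering windows; terminal residues, covered
by fewer windows, are flagged as less accurate. The core-region margin
default is 0.5 kcal/mol: the study distinguishes its minimum as more than
1 kcal/mol more favorable than the rest, and half that margin keeps the
called region compact; it is configurable. Disjoint within-margin runs
resolve to the one containing the global minimum, with a warning. Pose
classification is by minimum backbone–backbone distance to reference
crystallographic ligand coordinates (default cutoff 5 Å), because the
receptor's binding sites are best defined by bound-ligand positions.
The docking engine is an external pluggable callable; results are cached
to CSV and cached runs never re-invoke the engine.

## Synthetic data (`bindlab.synthetic_data`)

All generators are pure functions of (truth, design, seed) built directly
on the forward models, so zero-noise output is the model curve exactly and
reruns are byte-identical. Noise is homoscedastic Gaussian. Defaults
encode the study conditions: 3 µM fixed species and 12-point titrant
grids to 5× max(K_d, fixed) with 1% signal noise; 20 × 2 µL injections of
100 µM into 10 µM in a 200 µL cell with 0.1 µcal heat noise (the scale of
a modern automated calorimeter) and a −0.8 µcal background; sensorgrams
at 1–7 µM with association at 180 s, dissociation at 300 s, 2% response
noise and a 4% slow phase at 0.005 s⁻¹; 32-point gradient grids reaching
x_max = 2.5/min(D), the standard design that attenuates even the slowest
species below 10%.

The affinity-landscape generator builds a flat-top (box) well on fragment
midpoints rather than a Gaussian dip. Reason: with a window-7/step-2
tiling, interior residues alternate between 3 and 4 covering fragments,
which quantizes per-residue means at {0, ¼, ⅓, ½, ⅔} of the fragment
depth below baseline. A depth of 2 kcal/mol places every level at least
1/6 kcal/mol from the 0.5 kcal/mol calling margin — the structural
optimum — so at the default score noise of 0.05 kcal/mol (the scale of
docking score quantization) the constructed core is recovered essentially
always; a smooth Gaussian dip necessarily puts some residue near the
margin threshold and cannot achieve this. The constructed truth is the
core called on the noiseless landscape.

What the generators do **not** emulate: wavelength-resolved spectra, raw
power thermograms, baseline drift or mass-transport effects in
sensorgrams, NMR FIDs or spectral processing, and any correlation
structure in the noise. Passing recovery tests therefore validate the
estimators under the stated statistical model, not instrument-specific
artifacts.

## Problem sizes

Recovery statistics use 100 seeded replicates per scenario with 200
bootstrap draws per calorimetric interval; oracle comparisons use a few
hundred random parameter draws. The full test suite runs in under two
minutes on one CPU.
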