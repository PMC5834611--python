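# Methods

## Kinetic model

The core model is the linear three-state scheme
6c ⇌(k1/k−1) 5c ⇌(k2[CO]/k−2) CO-bound, solved under pseudo-first-order
conditions ([CO] held constant; a guard warns when [CO] < 10× the supplied
heme concentration, matching the experimental practice of mixing ~2 μM
protein with ≥25 μM CO). Units are fixed package-wide: concentrations in
μM, time in s (the ultrafast module works in ps and converts at its
boundary), first-order rates in s⁻¹, second-order rates in μM⁻¹ s⁻¹ —
matching the units in which every constant of interest is quoted.

The 3×3 system is solved analytically by eigen-decomposition of the rate
matrix; when the eigenvalue spectrum is near-degenerate (relative gap
< 1e-10) the solver falls back to a stiff numerical integrator (LSODA,
rtol 1e-10). Trajectories are clipped of sub-1e-12 round-off negatives and
renormalized within the 1e-9 mass-conservation budget.

The hyperbolic observable-rate law k_obs = k1·k2[CO]/(k−1 + k2[CO]) is an
accurate reduction of the full scheme only when two conditions hold: the
CO-bound state is a sink (k−2 ≪ k_CO·[CO]) *and* the 6c/5c pre-equilibrium
is fast (k1 ≪ k−1 + k2[CO]). `validity_check` reports the sink ratio
k−2/k_CO (units μM; default warning threshold 0.01 μM, configurable — the
default rates give 0.185 μM, so the reduction is questionable only at
sub-μM CO where no measurements are made). The oracle tests compare the law
against the exact slowest eigenvalue only in the regime where both
conditions hold.

**Default rate constants.** Only k1 = 25 s⁻¹, k_CO = k1·k2/k−1
= 0.27 μM⁻¹ s⁻¹ and k−2 = 0.05 s⁻¹ are experimentally determined; k−1 and
k2 are not individually identifiable from those observables. The package
default `DEFAULT_RATES` fixes k−1 = 5000 s⁻¹ and k2 = 54 μM⁻¹ s⁻¹, which
(i) reproduces both printed composites exactly (half-saturation
K = k−1/k2 ≈ 92.6 μM), and (ii) places the system deep in the rapid
pre-equilibrium regime (k1/k−1 = 0.005) where the hyperbolic law is valid
to ≲1% over the measured 25–800 μM range. Any other (k−1, k2) pair on the
same ray is observationally equivalent at this level; derived quantities
never depend on the individual values.

The exact equilibrium half-saturation [CO] of the bound fraction is
K_d,kinetic·(1 + k1/k−1); with the default rates the correction factor is
1.005, so the kinetic K_d is also the practical equilibrium half-saturation
point.

Ligand replacement is modeled as a perfect trap by default: with excess NO
capturing every transiently vacant heme, the 420 nm decay reports k−2
directly. A `trap_efficiency` parameter f scales the observable to k−2·f
for competitive rebinding; it defaults to 1 (the ~75% NO-complex yield
quoted for the replacement experiment is not clearly a kinetic
partitioning, so no correction is applied by default).

## Synthetic data generators

All generators are pure functions of (parameters, seed); noise is additive
Gaussian, absolute or relative to the peak |clean signal| ("2% noise" in
the recovery protocols means sigma = 0.02 × peak). Default sigmas: 0.002 AU
(spectra), 0.003 AU (stopped-flow), 2% of peak (ultrafast), 0.5 pA
(patch) — the experiments quote no noise statistics, so these are chosen as
typical of the respective instruments.

* **UV-vis titrations** use the exact quadratic mass balance for the bound
  fraction (never the free≈total approximation) and a species catalogue of
  Gaussian bands placed at the characterized Soret/Q maxima (ferrous 6c:
  split 425 nm + 390 nm shoulder, Q 531/559; ferrous-CO: sharp 420 nm,
  Q 540/569; ferric 413 nm; hemin standardized at ε385 = 58.4 mM⁻¹ cm⁻¹).
  Bands are Gaussian in the wavelength coordinate, a documented
  simplification (real Soret bands are asymmetric in energy). The ligand
  axis is total added ligand; cuvette dilution is neglected (volumes are
  not reported for the emulated protocol). Titration grids default to the
  experimental style: ~10 points spanning 0 to several K_d.
* **Stopped-flow** transients project the simulated state fractions through
  per-species absorbances at 420 nm and start at t = 0 from pure 6c (the
  instrument dead time is not stated and is not modeled).
* **Ultrafast matrices** use decaying phases of 22 ps (14%), 150 ps (26%)
  and 2.5 ns (50%) plus a 10% long-lived population as the default truth.
  All phases share one 5c-minus-CO difference-spectrum shape (they
  interconvert the same two species). The default grid is 60 log-spaced
  delays from 10 ps to 4 ns and 20 wavelengths spanning the Soret region —
  a typical femtosecond dataset; the published figure shows a subset of 11
  delays. No instrument-response convolution (delays ≥ 10 ps make the IRF
  negligible) and no photoselection/anisotropy.
* **Patch records** sum independent two-state Markov channels (exponential
  dwell times, drawn in alternating blocks), scaled by a unitary current of
  5.46 pA (78 pS × 70 mV), filtered with a single-pole low-pass at 2 kHz,
  sampled at 10 kHz for 120 s — the stated recording configuration. Default
  gating kinetics: mean open time 20 ms (close rate 50 s⁻¹) with the open
  rate set by the requested Popen; channel gating in the emulated system is
  not characterized at dwell-time resolution, so this is a representative
  choice, and the Popen estimator is insensitive to it as long as dwells
  are long relative to the filter rise time (~0.08 ms).

What the generators do *not* emulate — instrument drift, photobleaching,
baseline wander, correlated noise, stray-light nonlinearity, channel
rundown — means that passing recovery tests demonstrate estimator
correctness and statistical efficiency at realistic noise, not robustness
to every systematic error of real instruments.

## Fitters

All fitters are deterministic pure functions of their inputs. Lifetimes are
parameterized in log space (enforcing positivity); amplitudes are
unconstrained in sign (transient spectra contain both bleach and induced
absorption) and are always solved exactly by variable projection (linear
least squares) at each candidate lifetime set. Multi-start: 8 log-spaced
lifetimes between 2× the minimum time step and 2× the record span, all
n-combinations (capped at 64 starts); the best three grid starts are
refined by Levenberg–Marquardt on the projected residual. Equal-SSR ties
break toward the lexicographically smallest lifetime vector. Exponential
amplitudes refer to t = 0 (extrapolated when the grid starts later, the
convention for photodissociation transients). Fits are unweighted by
default (per-point weights are accepted). Standard errors come from the
linearized covariance at the optimum and are approximate.

`fit_kobs_curve` initializes deterministically (k1⁰ = 1.2 × max k_obs, K⁰ =
concentration nearest half-maximum) and propagates the error of
k_CO = k1/K by the first-order delta method including the k1–K covariance.
When the data cover only the linear regime, k1 and K are individually
unidentifiable — their standard errors blow up — while k_CO (the initial
slope) remains well determined; tests assert exactly this behavior.

`select_n_phases` adds phases until an F-test (α = 0.05, 2 extra
parameters) stops improving the fit, with an early exit when the SSR
reaches the numerical noise floor (≤1e-12 × signal energy); ties break
toward fewer phases.

`global_das_fit` shares lifetimes across wavelengths and solves the full
amplitude matrix per candidate in a single least-squares solve. The
optional non-decaying component absorbs the long-lived (escaped-CO)
population. Wavelength order is canonicalized internally, so lifetimes are
independent of input column order. `geminate_summary` weights each
component by the Euclidean norm of its DAS (exact when all phases share one
spectral shape, as the generator's physics dictates); the geminate yield is
1 − the long-lived fraction. For a single-trace fit the fitted offset
plays the long-lived role.

## Titration analysis

The isotherm response is A(λ) − A(λ) of the zero-ligand spectrum
(optionally ΔΔA against a reference wavelength for difference titrations);
the analysis wavelength snaps to the nearest grid point with a warning.
The CO titration defaults to 420 nm, the CO-complex Soret maximum (the
exact analysis wavelength is not stated for the emulated experiment).
Responses are fitted with a free Rmax — the emulated protocol never
normalizes — so K_d and Rmax are jointly estimated. The Morrison quadratic
always takes the minus root (the plus root exceeds 1 for any positive
P, L, K_d; property-tested). `model="auto"` fits the hyperbola first and
switches to Morrison when the fitted K_d < 10 × protein concentration,
i.e. whenever ligand depletion is non-negligible; this puts the CO case
(K_d 0.6 μM at P = 3 μM) firmly in Morrison territory. Fitting tight-binding
data hyperbolically overestimates K_d (depletion bias); a test pins the
bias direction.

## Vibrational analysis

Band deconvolution uses Gaussian line shapes (the emulated analysis choice;
no Voigt) with FWHM hard-bounded to 16–24 cm⁻¹ by default (relaxable) on a
linear baseline. Initial centers come from local maxima of the smoothed
spectrum plus maxima of the negative second derivative (which exposes
shoulders), deduplicated at half the minimum width; in auto mode, fitted
bands below 1% of total area are pruned. The protein-bound fraction is
area-based — area(≈494 cm⁻¹ band)/(area(494) + area(525)) with a 6 cm⁻¹
matching tolerance — since areas, not amplitudes, are the standard currency
of Gaussian deconvolution; the choice matters little at equal widths.

Backbonding classification measures the perpendicular Euclidean distance in
raw (ν(C–O), ν(Fe–CO)) wavenumber coordinates to each reference correlation
line — the simplest defensible metric, applied consistently. The packaged
reference table is a synthetic, literature-style set of class-labelled
pairs (His-proximal, thiolate, weak-trans-ligand 5c), clearly marked
non-authoritative; users with a curated compilation should supply their own
lines.

## Single-channel analysis

Idealization is the standard half-amplitude multi-level ladder: a sample at
current I is assigned open level k = round(I/i_unit). NPo is the
time-average level and Popen = NPo/N with N the known channel count (auto:
maximum observed level). No event-duration correction for filter rise time
is applied — a documented limitation that biases very brief events; at the
default gating kinetics the bias is negligible. `compare_conditions` adds
a routine paired t-test as a convenience summary only.

## Problem sizes and determinism

Recovery ensembles use 100 replicates for the scalar fits (k_obs curve,
titrations, first-order rates), 50 for the global DAS analysis, and 25 for
the 120 s patch simulations; the standing test suite runs the same checks
at 25 replicates. All ensembles are seeded; workflow stages derive their
seeds deterministically from the run seed, so identical configurations
yield byte-identical reports (timestamps appear only in logs).

## Known limitations

* The generators' noise model is i.i.d. Gaussian; no heteroscedastic or
  correlated noise.
* NO trapping in the replacement experiment is idealized (no model of the
  NO donor's release kinetics); O₂ binding is out of scope.
* No Bayesian uncertainty; confidence intervals are linearized
  approximations.
* No Hill/cooperativity binding models; the analyzed system shows none.
* Porphyrin marker modes (ν2/ν3/ν4) are not assigned, and
  photodissociation of the Raman samples is not modeled.
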