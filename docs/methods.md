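# Methods

## Binding scheme

The package models a ligand L that bridges two copies of a receptor chain P
through two sequential equilibria:

    P + L  ⇌  PL      Kd1 = [P][L] / [PL]
    PL + P ⇌  P2L     Kd2 = [PL][P] / [P2L]

No cooperativity factor beyond Kd2 itself is introduced, and no higher
oligomers (e.g. a 2:2 species) are considered: this is the minimal scheme
that reproduces both a biphasic ITC isotherm and the bell-shaped dimer
population seen by size-exclusion chromatography. Suppression of the dimer
at ligand excess is not an extra penalty term — it emerges from mass action,
because at saturating [L] every chain is sequestered as PL and the second
equilibrium is starved of free P.

### Species solver

Substituting the ligand mass balance
`l_free = l_total / (1 + p/Kd1 + p²/(Kd1·Kd2))` into the receptor balance
leaves one scalar equation in `p = [P]` that is strictly increasing on
`[0, p_total]`, with negative value at 0 and nonnegative value at
`p_total`. The root is therefore unique and always bracketed; it is found
with Brent's method at relative tolerance 1e−14 (mass balances and both
mass-action laws then hold to better than 1e−9 relative, which is the
documented contract). This formulation is preferred over the equivalent
cubic polynomial because the polynomial coefficients become severely
ill-conditioned at extreme Kd ratios, while the bracketed residual does
not. `kd2 = inf` is accepted and reproduces the closed-form 1:1 quadratic
exactly; zero totals return the trivial state rather than erroring.

An optional `active_fraction` multiplier on `p_total` (default 1.0)
accommodates binding-incompetent receptor preparations; it is a fixed
input, never a fitted parameter.

## ITC simulation

The perfusion (overflow) convention for a constant-volume cell: injection
*i* of volume vᵢ displaces an equal volume of pre-injection contents, so
totals are first scaled by `d = 1 − vᵢ/V₀`, then the injected ligand
`c_syr·vᵢ/V₀` is added. The heat of injection *i* is

    qᵢ = V₀·[ΔH1·(Δ[PL] + Δ[P2L]) + ΔH2·Δ[P2L]] + q_dil

with Δ measured between the post-injection equilibrium and the diluted
pre-injection equilibrium concentrations. Summing over injections
telescopes to the final binding heat plus the heat carried out with
displaced liquid; the test suite checks this against an independent
accumulation built on a brute-force speciation oracle. Heats are kept in
µcal and normalized heats in kcal per mole of injectant (instrument
convention; 1 cal = 4.184 J, but calories are the native unit throughout).

The per-injection loop reuses the previous post-injection equilibrium as
the next pre-injection state, so a 56-injection simulation costs 57 root
solves.

## Fitting

`ThermogramFitter` minimizes squared residuals of normalized heats
(uniform weights by default; per-injection σ accepted). For fixed
(Kd1, Kd2) the model is *linear* in (ΔH1, ΔH2, q_dil), so the fitter uses
variable projection: the outer nonlinear problem runs over
(log₁₀Kd1, log₁₀Kd2) only, with the linear block solved by least squares
at every step. The outer problem is multistarted from a deterministic
3×3 grid of log-Kd values spanning 10⁻⁷·⁵–10⁻³ M (eight or more starts
always); the best basin is then polished with a full 5-parameter
Levenberg–Marquardt run whose Jacobian supplies the covariance. Standard
errors for the Kd's are delta-method transforms of the log-space errors;
a parametric bootstrap is available as an alternative. The 1:1
`single_site` scheme (3 parameters: Kd1, ΔH1, q_dil) uses the same
machinery with the second event removed, and model comparison reports
`AIC = n·ln(RSS/n) + 2k`. An optional flag excludes the first injection,
the common correction for syringe-tip diffusion; it defaults to off
because the synthetic data have no such artefact.

Noise-free synthetic thermograms are recovered to ~1e−14 relative in all
five parameters, and a truth-started fit lands on the same optimum as the
multistart grid, which is the evidence that the optimizer reaches the
global minimum in practice.

## Identifiability of Kd2 — a known limitation

At the bench conditions (20 µM receptor, Kd2 = 61.5 µM) the sandwich
never exceeds ~11% of receptor chains, so the second event contributes
little heat. The Fisher information at the truth gives a Cramér–Rao
relative standard deviation of ≈ 120% for Kd2 at 0.5 µcal injection
noise (Kd2–ΔH2 correlation 0.97). Single-experiment fits therefore
scatter widely in Kd2 — the median over replicates lands within ~15–20%
of truth, but individual fits are often far off, occasionally collapsing
to the Kd2→∞ (single-site) basin. This is a property of the experiment
design, not of the optimizer: no physically plausible ΔH2 (the bound
scales only as 1/|ΔH2|) makes a single titration at these concentrations
pin Kd2 to 25%. Precise Kd2 values from such data require replicate
titrations analyzed globally, which is out of scope here. Kd1, in
contrast, is well determined (CRLB ≈ 18% per dataset; the median over 50
replicates recovers it within ~7%).

## Synthetic data

The generator emulates a VP-ITC-style experiment: 250 µM ligand in 56
injections of 8 µL into a 1.4 mL cell with 20 µM receptor at 25 °C;
truth Kd1 = 2.9 µM, Kd2 = 61.5 µM; i.i.d. Gaussian noise of 0.5 µcal per
integrated heat. Enthalpy defaults are ΔH1 = −8000, ΔH2 = +8000 cal/mol:
magnitudes typical of micromolar protein–ligand events, opposite signs so
the two events are visible as an interior extremum in the normalized-heat
curve. (ΔH2 magnitudes much below this leave the curve monotone and the
second event invisible by eye.) The ΔH values and the noise figure are
package choices — they are not measured quantities.

The STD generator produces mono-exponential build-up series at
saturation times 0.3, 0.6, 1.0, 2.0, 3.0 s for seven protons of one
symmetric half of a polysulfonated naphthylurea ligand, with 2%
multiplicative Gaussian noise on the on-resonance intensities and one
overlap group of two protons reported jointly.

What the generator does **not** emulate: baseline drift and peak-
integration error in raw power traces, first-injection artefacts, active-
fraction uncertainty, inter-experiment variability, spin diffusion and
T1 bias in STD intensities beyond the mono-exponential form, and spectral
overlap beyond a fixed grouping. Passing recovery tests on these data
show the estimators are correct under the assumed noise model; they do
not certify performance on real instrument output.

## STD epitope mapping

Relative STD per cell is `(I_off − I_on)/I_off`. Build-up fits use
`std(t) = STDmax·(1 − e^(−k_sat·t))` by bounded least squares; a proton
with fewer than three usable points is reported unfitted, and an all-flat
series is flagged with initial slope zero. Epitope maps normalize either
the single-time values (reference 0.6 s by convention) or the initial
slopes `STD0 = STDmax·k_sat` so the strongest proton is exactly 100%;
both methods are provided because single-time maps are T1-biased while
initial slopes need the full build-up series. Overlapping protons receive
their group's mean value and keep the group flag; protons with
nonpositive STD are dropped from the map as carrying no epitope signal.

## Numerical choices

- Root solve: Brent, rtol 1e−14, bracket `[0, p_total]` guaranteed by sign.
- Outer fit: LM on log₁₀Kd, grid stage at ftol 1e−9, polish at 1e−13;
  log-Kd arguments clipped to [−15, 6] to keep extreme trial steps finite.
- AIC uses RSS over fitted points only; excluded injections still appear
  in the reported residual vector.
- Text formats: UTF-8, LF, comma delimiter, `.` decimal, 12 significant
  digits — strict parsing with line-numbered errors, decimal commas
  rejected rather than guessed.
- Determinism: simulations are noise-free deterministic; every stochastic
  path takes a single integer seed (numpy `default_rng`); the STD stream
  is decoupled from the ITC stream by seed offset.

## Problem sizes

The shipped study uses 50 replicate titrations for recovery statistics,
11 replicate datasets for the model-selection medians, 200-point log
grids for speciation profiles, and 1000 random instances for the
solver-vs-oracle check — sizes at which the full analysis reruns in about
a minute on one CPU while keeping Monte-Carlo error in the reported
medians near 1%.
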