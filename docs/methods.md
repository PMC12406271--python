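# Methods

This note documents the models, the synthetic-data generator, the numerical
choices in the fitters, and the known limitations of `petkin`.

## Observable: PET proximity quenching

A labelled cysteine pair reports its inter-dye distance through photoinduced
electron transfer: fluorescence is reduced to a floor `q_floor` at or below
`d_quench` (default 5 Å) and fully recovered at or above `d_free` (default
15 Å). The floor defaults to 0.05 rather than 0 because close-contact
quenching is strong but not complete.

Between the two limits the map interpolates with a cubic smoothstep applied
to the `sharpness`-th power of the normalized distance
(`q = q_floor + (1 − q_floor)·S(x^s)`, `S(u) = 3u² − 2u³`,
`x = (d − 5)/10`, default `s = 8`). The power skews the transition towards
the free limit: PET is a short-range contact phenomenon, and in this assay
family a pair at 14 Å is still strongly quenched while 15 Å is essentially
free — a symmetric interpolant would instead put 14 Å at ~97% fluorescence
and make the SBDβ–interface docking signal almost invisible against
instrument noise. With the default map, q(14 Å) ≈ 0.43. `sharpness = 1`
recovers the plain symmetric smoothstep. The map is continuous,
differentiable and monotone; the endpoints are exact by construction.

## Generative model

A trace is produced by an irreversible first-order chain of conformational
states (apo → linker docked → NBC closed → SBDβ docked → lid open for
nucleotide binding), each state carrying one inter-dye distance per probe.
Nucleotide-free chaperone is a weighted mixture of subpopulations that share
the downstream chain but enter it with distinct association rates; the
observed fluorescence is the mixture average of the per-state quench values
times the instrument full scale (10 AU ≙ the 10 V convention), plus i.i.d.
Gaussian noise per sample (default σ = 0.3% of full scale, photometric noise
at high count rates; no drift by default). Stopped-flow dead time (default
2.3 ms) is implemented as sample truncation, matching how such traces are
reported, not as a convolution.

The chain is solved by spectral decomposition of the triangular rate matrix;
repeated (confluent) rates fall back to a matrix exponential per time point.
The classic partial-fraction (Bateman) solution serves as an independent
test oracle only.

### Wild-type binding preset

Absolute conformational rates are not published as numbers for this assay,
so the preset declares synthetic values: three apo subpopulations with
weights 0.5/0.3/0.2 and association rates 800/60/4 s⁻¹, followed by fast
downstream steps (1·10⁵, 7·10⁴, 5·10⁴ s⁻¹). Making the downstream steps much
faster than every association rate has two deliberate consequences: the
observed kinetics at every probe are tri-phasic with phases tracking the
association mixture (an early design with a slow final lid step collapsed
all subpopulations onto a single observed rate, contradicting the tri-phasic
phenotype the generator must emulate), and uniform rate rescaling of the
whole scheme — how variant presets encode their published fold factors
(1/2000 for R151A, 1/4 for K414I, 1/325 for AMPPCP, 0.64/0.52/0.31 for
ATPαS/ATPγS/AMPPNP) — carries through the fitting pipeline with only a few
percent distortion from the fixed dead time. The single-subpopulation D481A
preset instead sets its association rate to the wild-type weighted rate
divided by 640. All fold factors hold exactly by construction
(`petkin.fold_constraints()` exposes stated vs constructed values).

### Interface-variant trace pairs

Interface-destabilized variants show a fast fluorescence decrease (SBDβ
docking, 20 → 14 Å, 200 s⁻¹ visible docking rate, synthetic) followed by a
slow increase (detachment into the domain-undocked 37 Å state). The slow
conversion runs through a partially-opened intermediate (14.4 Å, synthetic)
with rates 0.03 and 0.006 s⁻¹, making the slow rise genuinely two-phase
(~44/56 amplitude split) — the reason the slow window needs bi- or
tri-exponential fits — with the two rates separated 5-fold so the
decomposition is identifiable. The published slow/fast amplitude ratios are
encoded through the subpopulation structure:

* *R151A-like (17×), D393A-like (1.8×)*: a visible docking subpopulation of
  weight 1/fold; the remainder starts pre-docked (per-subpopulation starting
  distances, the "different starting conformation" hook) and contributes
  only to the rise.
* *K414I-like (0.7×)*: all molecules dock visibly; 30% never detach (their
  slow step is distance-neutral).
* *D481A-like (≈1×)*: one subpopulation, full dock-then-detach path.
* *wild-type-like*: no slow state; the long trace is flat after
  equilibration.

The long recording receives a seeded uniform voltage offset (±1 AU) so the
splice step of the analysis has real work to do.

### Single-turnover presets

The biphasic hydrolysis model is evaluated directly with the published
rates (ATP 1.605·10⁻⁴, ATPαS 0.794·10⁻⁴, ATP+pep65 8.479·10⁻⁴,
ATPαS+pep65 3.971·10⁻⁴ s⁻¹). F0 = 2 AU, Fmax = 10 AU and the
pre-commitment rates (10⁻² s⁻¹; 5·10⁻⁴ s⁻¹ for ATPαS without peptide, giving
the characteristic slow first phase) are synthetic. Suggested acquisitions
cover ≥ 3.5/k₂ at plate-reader cadence (720 cycles). ADP and AMPPNP
controls are flat at the quenched level.

## Fitting

**Multi-exponential fits** use variable projection: for fixed rates (and
stretching exponents) the baseline and amplitudes are a linear least-squares
solve, and only the log-rates and β values are optimized with
`scipy.optimize.least_squares`. Multi-start comes from a fixed grid of 8
log-spaced rates (all size-n combinations coarsely ranked by projected SSE,
the best 6 polished); the lowest SSE wins with a first-index tie-break, so
fitting is fully deterministic. Fits are unweighted (the generator's noise
is homoscedastic); per-sample weights are a hook.

Rate bounds are identifiability-driven: `k_min = 1/(4·span)` (slower
components are indistinguishable from baseline drift over the window) and
`k_max = min(1/(2·Δt_min), ln(10⁴)/t_start)` for windows starting after
zero (a faster component has decayed below any recoverable amplitude before
the first sample). β is bounded to [0.2, 1] to avoid pathological stretched
fits. Each phase amplitude is capped at 5× the observed data range (bounded
linear solve, only engaged when the unconstrained solution violates the
cap): near-degenerate rate sets can otherwise fit noise with huge
mutually-cancelling amplitudes. Rates above 1000 s⁻¹ are flagged
`rate_uncertain` (dead-time limit).

**Model-order selection** fits 1..3 phases and accepts a richer model only
if the extra-sum-of-squares F-test is significant at α = 0.01 AND every
contribution is ≥ 2% AND all rates are mutually ≥ 1.5-fold separated, so the
chosen model never contains an unidentifiable rate pair. The
Wald–Wolfowitz runs test on residual signs (normal approximation,
implemented in-module) is reported as the objective stand-in for "randomly
distributed residuals".

**Single-turnover fits** parameterize `k₁ = k₂(1 + e^θ)` to enforce
`k₁ > k₂`, initialize k₂ from the late-time exponential tail, and
multi-start over a fixed grid of k₁/k₂ ratios. t₀ is fixed at 0 by default
(the dead-time offset is essentially unobservable). Only Fmax and k₂ are
flagged high-confidence; asymptotic standard errors come from the Jacobian.
Traces whose smoothed peak-to-peak span is below 3× the estimated noise are
flagged `non_informative`; fits whose dip falls before the first sample are
flagged `k1_unresolved`.

**Splice and two-window analysis.** The long recording is y-transformed by
`c = (10 − Y0_short) + (y_short(0.025 s) − y_long(0.025 s))` (linear
interpolation at the reference point) so the combined kinetics starts at
10 AU. The fast window [dead time, 0.25 s] is fitted with model-order
selection plus a linear drift column that absorbs the in-window onset of the
slow rise (the optional drift extension of the model layer; without it the
extrapolated fast amplitude is biased by the slow-phase bleed), with a
completeness bound `k ≥ 2/span` (only phases that substantially finish
inside the window have trustworthy amplitudes there). The slow window
[10, 250 s] is fitted with the requested family (bi-exponential,
bi-exponential with stretched slowest term, or tri-exponential), with
`k ∈ [1/span, ln(20)/t_start]` for the same identifiability reasons. Within
the stretched family the stretched term is retained only when it beats the
plain fit in a nested F-test at α = 0.01 — a stretched term redistributes
fitted amplitude outside the window and must earn its keep. Families are
tried in the given order and the first whose runs test exceeds p = 0.05 is
kept; if none passes, the best is returned flagged `residual-structure`.
The summary reports `|A_slow,total| / |A_fast,total|` and
`log₁₀(k_w,fast / k_w,slow)`.

## Derived statistics

The weighted rate `k_w = Σ cᵢkᵢ` with `cᵢ = |Aᵢ|/Σ|Aⱼ|` is permutation
invariant, bounded by the extreme rates, covariant under uniform time
rescaling and invariant under uniform amplitude rescaling. Amplitude
correction divides by the exact single-site fraction bound (stable quadratic
form); a zero-complex condition is an explicit error. Variant comparisons
are descriptive fold tables only — significance machinery is deliberately
out of scope; the tidy CSV is consumable by any stats environment.

## Problem sizes and what the tests show

Default problem sizes: 10 000 samples per 0.25 s stopped-flow trace, 2 000
log-spaced samples per 250 s recording, 720 plate-reader cycles per
turnover trace; recovery studies use 5–50 seeded replicates. The test suite
and the acceptance script complete in a few minutes on one CPU.

Passing recovery tests show that the pipeline is unbiased and precise for
data generated by its own forward model: homoscedastic Gaussian noise, exact
first-order kinetics, no photobleaching, no mixing artifacts, no instrument
drift, dead time as pure truncation. Real stopped-flow records violate all
of these to some degree (correlated noise, lamp drift, bleaching on long
timescales), so real-data performance is expected to be worse than the
synthetic benchmarks, particularly for small-amplitude phases near the
dead-time limit.

## Known limitations

* The conformational chain is irreversible; reversible schemes and
  equilibrium constants are out of scope (the solver is written against the
  full rate matrix, so a reversible extension is mechanical).
* Stochastic single-molecule trajectories (Gillespie), diffusion/mixing
  artifacts and photophysics beyond the static distance→quench map are not
  modelled.
* The confluent limit k₁ = k₂ of the single-turnover model is an error, not
  a limit form.
* Fold-change tables carry no confidence intervals; a bootstrap hook is the
  natural extension.
* Global (linked) fitting across traces and Bayesian posterior sampling are
  not provided.
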