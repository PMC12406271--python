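# petkin

Kinetic analysis of proximity-quenching (PET) fluorescence traces for
resolving the allosteric conformational dynamics of Hsp70 chaperones.

## The problem

Hsp70 chaperones such as *E. coli* DnaK couple ATP binding and hydrolysis in
their nucleotide-binding domain (NBD) to opening and closing of their
substrate-binding domain (SBD). These conformational changes can be watched
in real time by labelling cysteine pairs with dyes that quench each other by
photoinduced electron transfer (PET): fluorescence is suppressed below
~5 Å inter-dye distance and unaffected above ~15 Å, so each labelled probe
(lower crevice, interdomain linker, nucleotide-binding cleft, SBDβ–NBD
interface, α-helical lid) reports one allostery-related distance change.
Mixing apo chaperone with ATP in a stopped-flow instrument yields
fluorescence relaxations; fitting them resolves the rates and amplitudes of
the individual steps of allosteric signal transmission.

`petkin` implements the complete analysis chain for this kind of data,
together with a first-class synthetic-data generator (no raw instrument
recordings are publicly deposited for this assay family, so simulated traces
with known ground truth are both the test bed and the benchmark):

* **models** — closed-form equations: multi-exponential relaxations
  `F(t) = Y0 + Σᵢ Aᵢ(1 − e^{−(kᵢt)^βᵢ})` (negative amplitude = inter-dye
  distance decrease, i.e. docking/closing), the biphasic single-turnover
  hydrolysis curve
  `F = F0 + (Fmax − F0)·e^{−k₁(t−t₀)} + (Fmax − F0)(1 − e^{−k₂(t−t₀)})`,
  the PET quenching map, and the exact single-site fraction-bound solution.
* **simulate** — an irreversible first-order conformational chain with a
  weighted mixture of apo-state subpopulations (distinct ATP-association
  rates), observed through the quenching map, with instrument dead time
  (2.3 ms), Gaussian noise and seeded randomness; named presets encode the
  published rate and distance constraints (e.g. hydrolysis rate
  1.605·10⁻⁴ s⁻¹ for ATP, lid-opening rate folds of 1/2000 for R151A and
  1/4 for K414I, SBDβ–IB distances of 14 Å docked / 37 Å detached).
* **fitting** — scikit-learn-style estimators (`MultiExponentialRegressor`,
  `SingleTurnoverRegressor`) with variable-projection multi-start fitting,
  objective model-order selection (nested F-tests + contribution and
  rate-separation thresholds, Wald–Wolfowitz runs test on residuals), the
  short/long trace y-transformation splice, and the two-window
  (0.25 s / 10–250 s) analysis of interface-destabilized variants.
* **stats** — contribution-weighted average rates
  `k_w = Σᵢ cᵢkᵢ, cᵢ = |Aᵢ|/Σⱼ|Aⱼ|`, K_d-based amplitude correction
  `A_corr = A_obs / f_bound`, and descriptive variant-vs-reference fold
  tables.
* **io / CLI** — CSV traces with JSON sidecars, YAML run configs, and a
  `petkin` command with `simulate-binding`, `simulate-turnover`,
  `simulate-long-pair`, `fit-trace`, `analyze-turnover`, `analyze-long` and
  `recover` subcommands.

## Worked example

Simulate one plate-reader single-turnover trace for the ATP preset and refit
the biphasic hydrolysis model:

```bash
$ petkin simulate-turnover --preset turnover_ATP --seed 1 --out atp.csv
wrote 720 samples to atp.csv
$ petkin analyze-turnover --input atp.csv
{
  "F0": 1.9945060542635302,
  "Fmax": 9.997885316435315,
  "k1": 0.00996163899861851,
  "k2": 0.00016059098683565148,
  ...
  "high_confidence": { "F0": false, "Fmax": true, "k1": false, "k2": true, "t0": false },
  ...
}
```

The fitted hydrolysis rate `k2 = 1.606·10⁻⁴ s⁻¹` recovers the preset's
ground-truth 1.605·10⁻⁴ s⁻¹ within 0.1%; only `Fmax` and `k2` are flagged
high-confidence because the fluorescence drop on nucleotide association is
partly hidden in the mixing dead time.

A full recovery experiment (simulate → fit → aggregate over seeds) runs from
a shipped config:

```bash
$ petkin recover --config examples/recover_binding.yaml
{
  "wt_ATP": {
    "n_phases":      { "mean": 3.0,   "sd": 0.0,  "n": 2 },
    "weighted_rate": { "mean": 424.8, "sd": 10.2, "n": 2 },
    "total_amplitude": { "mean": 9.64, "sd": 0.10, "n": 2 },
    ...
  }
}
```

Wild-type ATP binding observed at the lid probe is recognized as
tri-phasic (the three apo subpopulations with association rates near 800,
60 and 4 s⁻¹), and the contribution-weighted rate ≈ 420 s⁻¹ summarizes the
population average.

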