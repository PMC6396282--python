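# Methods

## The photocycle model

Melanopsin is a bistable GPCR photopigment whose signaling lifetime and
regeneration are controlled by two adaptor proteins with divergent roles:
β-arrestin 2 terminates signaling of the light-activated, phosphorylated
receptor, while β-arrestin 1 supports chromophore exchange that returns the
deactivated receptor to the photoexcitable dark state. `melanocycle`
formalizes this division of labor as a linear five-pool model of the total
pigment of a cell:

```
dark ──σ·Φ(t)──▶ active ──k_phos──▶ phospho_active
phospho_active ──k_d2eff──▶ arr_bound ──k_r1eff──▶ dark
active, phospho_active ──k_spont──▶ spent ──k_turnover──▶ dark
```

with the genotype-resolved effective rates

```
k_d2eff = (k_deact2·arr2 + k_deact_cross·arr1) · binding_scale · deact_accel
k_r1eff =  k_regen1·arr1 + k_regen_cross·arr2 + retinal_supply_rate
```

* `dark` — 11-*cis*-bound, photoexcitable pigment; photon capture converts
  it to `active` at rate σ·Φ, where Φ is the photon flux
  (photons cm⁻² s⁻¹) and σ the activation efficiency.
* `active` / `phospho_active` — the signaling states. C-terminal
  phosphorylation (`k_phos`) creates the arrestin binding site;
  `eps_phospho` sets the signaling weight of the phosphorylated state
  (default 1: phosphorylation per se does not silence the receptor, only
  arrestin binding does).
* `arr_bound` — arrestin-bound, deactivated pigment awaiting
  β-arrestin-1-mediated chromophore exchange (`k_r1eff`). Whether the return
  proceeds by exchange or direct photoregeneration is not resolved; both are
  collapsed into one first-order rate.
* `spent` — an arrestin-independent dead end fed by the slow spontaneous
  decay of the signaling states (`k_spont`) and drained only by de novo
  pigment turnover (`k_turnover`). It carries the rundown of genotypes that
  park pigment in the signaling states for long times.

Cross rates (`k_deact_cross`, `k_regen_cross`) encode the partial mutual
substitution of the two arrestins; they default to 6–8 % of the principal
rates. Phosphosite mutants scale the phospho-dependent arrestin rates
through `binding_scale` (1.0, 0.8, 0.6, 0.45, 0.2, 0.05 for 0A…9A; the
values are free parameters, only their monotone decrease is meaningful).
The C-terminally truncated pigment is modeled by `deact_accel` ≥ 1.
Supplementation with exogenous 11-*cis*-retinal is either an instantaneous
event moving a fraction ρ of `arr_bound + spent` back to `dark` (bath
application, approximated as a single transfer at the stated time) or a
sustained first-order return `retinal_supply_rate` added to both recovery
rates (systemic injection).

## Integration

Within every interval of constant flux the system is `x' = Ax` with a
constant 5×5 rate matrix, integrated by classical RK4 at a 1-ms internal
step. For a linear system the RK4 update is the constant matrix
`I + hA + … + (hA)⁴/24`, so propagation reduces to matrix–vector products
(composed by matrix powers between storage points). A renormalization guard
pins `Σ fractions = 1` at every stored step; in practice conservation holds
to ~1e-15 and the trajectory matches a matrix-exponential oracle to better
than 1e-12. A `StabilityError` is raised when the step exceeds one tenth of
the fastest kinetic timescale (relevant at the brightest phototaxis
irradiance, where σ·Φ ≈ 8–80 s⁻¹; simulations there use a 0.1-ms step).

## Transduction, spiking, and readouts

The drive `D(t) = gain·(active + eps_phospho·phospho_active)` is low-pass
filtered (τ = 1.5 s, the cascade sluggishness behind the slow response
onset), thresholded at θ and mapped through a Hill function bounded by
`r_base` and `r_base + r_max`. Spikes are an inhomogeneous Poisson process
generated by thinning with a 3-ms absolute refractory period; the constant-
rate mean matches the renewal formula λ/(1+λτ). Raw MEA-like traces are
10-kHz Gaussian noise with a fixed biphasic negative-peak template added at
each spike time. Population heterogeneity is a unit-mean lognormal scaling
of per-cell pigment content (CV 0.25) and firing threshold (CV 0.2); all
randomness descends from one root seed through `numpy.random.SeedSequence`
spawning, so any cell is reproducible from (seed, cell index).

Pupil diameter relaxes first-order (τ = 1.5 s) toward
`d_dark·(1 − c_max·S(drive))` with `S(x) = x/(x+K)`. Pup locomotion is a
2-D random walk with exponential step lengths whose mean is suppressed by
the same saturating function of drive (maximum suppression 60 %).

## Quantification pipeline

* Noise SD of a raw trace: scaled median absolute deviation, so embedded
  spikes do not inflate the estimate (the faithful reading of a "noise SD"
  on a spike-bearing channel).
* Detection: negative threshold at 5 noise SDs, event time at the trough of
  each excursion (sub-sample-stable alignment), 1-ms dead time, 1 ms/2 ms
  cutouts; boundary cutouts are zero-padded and flagged.
* Response metrics: PSTH at 0.5-s bins (configurable; the onset resolution
  is therefore ±0.5 s at defaults); baseline is the 60 s of darkness
  preceding each stimulus; onset requires ≥ 2 consecutive bins above
  baseline mean + 2 SD; the response extends while supra-threshold,
  tolerating gaps of ≤ 4 bins; `mean_rate_hz` is computed over the stimulus
  window.
* Adaptation: per-cell OLS slope of duration (or spike count) across the
  five repetitions of the 1-min stimulus, reported as mean ± SEM with a
  one-sample t test against zero; group contrasts use Welch's t test.
* LRAM: population-mean durations per (stimulus duration, repetition), each
  duration's repetition series replaced by its OLS fit, interpolated
  bilinearly across log₁₀(duration) × repetition; the grid axes include the
  measured durations as exact nodes, where values equal the fits exactly.
  The log₁₀ spacing matches the decade-spaced {0.1, 1, 10, 60} s design.
  Mean (not median) aggregation is the default, configurable.
* Subtype clustering: k-means (k = 2) on max-normalized 1-s-binned 1-min
  response profiles, clusters relabeled by descending median response
  duration; rows are fitted in a canonical sorted order so the partition is
  order-invariant. Latency classes use an Otsu-style 1-D minimum
  within-class-variance split.
* Phototaxis: distance per 1-s bin from head-centroid coordinates; pups
  whose mean dark-period activity is below 5 px/bin are excluded (the mean
  is compared to the threshold — chosen over a per-bin reading for
  robustness); light activity is normalized to the 2-min dark mean, with
  per-irradiance-step values also reported. Pupillometry normalizes to the
  mean over the first minute of darkness; constriction is 100·(1 − d/d₀).

## Default calibration

Rates are calibration constants of this package, not measured values. They
were chosen so that a simulated wild-type cell at the standard MEA
irradiance (5×10¹² photons cm⁻² s⁻¹, 480 nm) shows ~2-s onset latency to a
60-s pulse within the repetition protocol, sustains the full pulse, and
persists a few seconds beyond light OFF, while the knockouts fall in their
qualitative regimes: arr2-null responses persist ~45 s beyond OFF with
latency slightly shorter than WT; arr1-null responses shorten and slow
across the protocol as pigment accumulates in the arrestin-bound pool
(regeneration τ ≈ 300 s against 3-min dark gaps) and run down steeply
across repeated 1-min stimuli.

## Known limitations

* The model is linear and time-invariant in the pigment pool, with a single
  irreversible leak (`spent`). Two consequences are structural. First,
  because slow deactivation keeps pigment in the signaling states, the
  arr2-null steady-state signaling fraction under continuous light always
  exceeds WT's; a 20-min stimulus therefore cannot terminate the arr2-null
  response before the WT response unless the leak is made strong enough to
  also produce a clearly negative repetition slope — the observed early
  dropout of deactivation-deficient retinas under prolonged light involves
  processes outside the pigment cycle (depolarization block, Ca²⁺-store
  depletion), which are out of scope here. Second, any pool rundown changes
  response duration in proportion to the post-OFF decay time constant,
  which is larger in the arr2-null by the same mechanism that produces its
  persistence phenotype; a WT rundown that is statistically significant at
  n = 30 would therefore imply an even larger arr2-null rundown. The
  shipped calibration resolves both tensions in favor of the arrestin-2
  phenotypes (flat arr2-null adaptation, persistence, fast latency); the
  WT repetition slope is negative in direction but small, and the 20-min
  genotype ordering holds between arr2-null and arr1-null but not between
  WT and arr2-null.
* A brief (1-s) pupillometry flash from the dark-adapted state cannot
  expose the arr1-null regeneration deficit, so the simulated arr1-null
  pupil constricts like WT; the arr2-null relaxation deficit is reproduced.
* Synthetic data are single-unit by construction: no waveform sorting, no
  electrode geometry, no drift, no bursting or depolarization block.
  Passing tests show the pipeline recovers what the generator encodes; they
  do not validate the model against recordings.
* Problem sizes in the test suite and acceptance script (30 cells/genotype,
  50 cells for parameter recovery, 10 pups/group, 20 noise traces) were
  chosen as the smallest populations at which the phenotype contrasts are
  stable across seeds.
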