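# Methods

## Signal model

The detector is modelled as a 1-D array of `n_wires` collection wires
(default 40, one per MLC leaf pair) at pitch `wire_pitch` (default 1.0 cm,
the isocenter projection of an MLCi2-class leaf width). For a static
segment with separation vector *S* (mm at isocenter) and monitor units MU,
the raw response of wire *A* is

R_A = MU · k · Σ_W S_W · κ(|A−W|·pitch),  κ(D) = exp(−λD) for D ≤ D_cut, else 0.

Implementation is `numpy.convolve` of *S* with the sampled kernel; a
brute-force O(n²) double sum is kept in the test suite as an independent
oracle and the two agree to 1e−9 relative. The *W = A* kernel term is 1, so
that term is exactly the primary response S_A·MU·k.

Parameters, units and defaults:

| parameter | meaning | default | notes |
|---|---|---|---|
| `k` | signal per (mm·MU) | 1.0 | arbitrary-units scale; calibrated or cancelled by relative comparison |
| `lateral_exponent` λ | scatter decay, per cm | 1.4034 | stored as a positive magnitude; the kernel carries the minus sign, which removes the double-negative ambiguity of quoting fitted exponents as negative numbers |
| `scatter_cutoff` | kernel support, cm | 4.0 | lateral scatter beyond 4 cm is below the detection threshold; implemented as a hard zero so the kernel is compactly supported |
| `closed_threshold` | closed-pair cut, mm | 1.0 | separations at or below it count as closed; leaf-tip leakage is not modelled |
| `in_field_sigma` | relative uncertainty of in-field wires | 0.01 | matches the observed repeat-delivery reproducibility |

The distance metric is `|A−W| · wire_pitch`, which makes the unit of λ
(per cm vs per wire index) explicit and configurable — fitted exponents are
only meaningful together with the pitch used to express distance.

## Field edges and penumbra

A wire is in-field for a segment iff its separation exceeds
`closed_threshold` and, when jaw positions along the wire axis are given,
its position lies inside the jaw aperture. (Only the jaw pair on the wire
axis can shadow whole wires; both jaw pairs are accepted on input and the
rule is explicit configuration rather than an implicit convention.)

Penumbral and out-of-field primary radiation is hard to model from first
principles, so out-of-field wires are predicted as zero except the first
four beyond each field edge, which get fixed fractions P₁ ≥ P₂ ≥ P₃ ≥ P₄
of the *predicted* last in-field wire on that side. Fractions are applied
on both sides of every contiguous in-field run; where two runs are closer
than eight wires a gap wire takes the larger of its two candidates
(conservative, avoids double counting). At the detector boundary the
sequence truncates without error. Penumbral wires carry the fractions'
relative standard deviations as uncertainty; summation over segments and
beams combines sigmas in quadrature.

The packaged default fractions (0.30, 0.10, 0.04, 0.015; relative sigmas
0.10) are the values the calibration fit recovers from the simulator's
generating penumbral model; on a real device they must be refit from
measured treatments (`wiresignal calibrate --mode penumbra`), since the
drop-off depends on jaw geometry and plate scatter of the specific unit.

## Calibration

* **k** — per (pair, separation) group, least-squares slope of the open
  pair's wire signal vs MU; then the least-squares slope of those gradients
  vs separation. Both stages keep an intercept (spreadsheet trend-line
  behaviour); with noiseless input the recovery is exact, and the second
  intercept is a diagnostic for nonlinearity. Degenerate designs (one MU,
  one separation, all-zero signals) raise.
* **λ from a profile** — the four wires either side of the open pair are
  normalized to the open pair's wire, pooled over all deliveries and the
  two mirrored sides, and averaged. Each distance's sigma combines the
  pooled standard deviation with the 1% repeat-delivery uncertainty in
  quadrature. The fit is linear least squares on ln(response) vs distance
  (closed-form, deterministic); the returned λ is the slope magnitude with
  its standard error. The fit is a fixed point of the forward model for any
  λ in the physically relevant range.
* **λ by grid search** — the exponent actually used for prediction is
  found by comparing predictions with the measurements of one treatment
  over a grid of candidates. Both vectors are normalized by their in-field
  sums before taking squared relative deviations over in-field wires, so
  the objective is invariant to a global rescaling of the measurement
  (k cancels) and is driven purely by profile shape. Out-of-field wires are
  excluded: the penumbral model is the least certain part of the chain and
  including it destabilizes the fit. Ties go to the smaller candidate.
  This route matters because real detectors show per-pair exponent spread
  (measured magnitudes 1.44–1.55 across pairs): a single profile fit picks
  one pair's value, while the grid search finds the best single effective
  exponent for whole-field prediction.
* **Penumbral fractions** — out-of-field wires within four wires of a
  single unambiguous field edge are normalized to the measured last
  in-field wire and pooled per position over edges, beams and treatments;
  means and standard deviations become the fractions and their (relative)
  sigmas. The means are forced non-increasing by a running minimum, since
  noise can marginally invert adjacent positions. A single observation
  yields sigma 0 with a warning. With multi-segment beams the pooled ratios
  mix segment edges that do not coincide with the beam-union edge; the
  resulting spread is genuine and is exactly what the fractions' sigmas are
  meant to carry.

## Verification

Relative deviations (measured−predicted)/predicted are computed on
beam-summed signals (5% tolerance), the fraction sum (2.5%), and per wire
(advisory only; wires predicted below 1e−6 of the maximum are masked to
avoid meaningless ratios). "Within tolerance" is inclusive; a 1e−12
absolute guard on the comparison keeps a mathematically exact boundary
case from flipping on floating-point rounding. A delivery is flagged when
any beam or the fraction exceeds its tolerance. Because all comparisons
are relative, verdicts are invariant to a common rescaling of predicted
and measured signals.

## Simulator

The simulator emulates the clinical test material — five-field
head-and-neck-like step-and-shoot treatments — and the detector's known
imperfections:

* apertures are contiguous runs of 10–25 open pairs with independent
  separations of 10–150 mm and 2–20 MU per segment, 5–15 segments per
  beam; a 4-wire closed margin keeps penumbral regions on the detector;
* each wire has its own true lateral exponent, drawn once per seed
  uniformly from the measured per-pair magnitude span [1.44, 1.55] (a
  property of the simulated detector, fixed across plans); scatter from
  the aperture above wire *W* decays with *W*'s own exponent;
* the true penumbral fractions are jittered per treatment (relative sd
  0.10) around (0.30, 0.10, 0.04, 0.015);
* measurement noise is multiplicative Gaussian, sd 0.3%, independent per
  wire per segment per replicate, with three replicates averaged. Only the
  <1% in-field reproducibility spread of the real device is known; the
  Gaussian form and the 0.3% sd are the package's stand-in, chosen so the
  three-replicate spread stays below that bound, and are isolated in
  configuration.

Characterization sweeps are simulated from the same forward truth but
*without* the penumbral override: with a single open pair, the
neighbouring wires' signals are precisely the lateral scatter profile the
sweep exists to measure. Treatment measurements *do* apply the true
penumbral model — on a real device the out-of-field signal shows the
penumbral drop-off the fractions describe. This asymmetry mirrors what the
physical measurements contain, not an inconsistency of the truth model.

All randomness flows from a single seed through separate
`numpy.random.SeedSequence` spawn keys per stream (plan geometry, detector
exponents, penumbral jitter, noise, sweeps), so the whole
generate → simulate → inject pipeline is reproducible and individual
streams can be varied independently.

What passing tests on this simulator do **not** show: accuracy on real
devices with energy dependence, jaw transmission, non-exponential scatter
tails, drifting electrometer gain, or VMAT/sliding-window deliveries —
none of which the generator emulates.

## Problem sizes and numerics

The package's study uses ten five-field treatments (50 beams) for the
accuracy envelope and the ±5% error-detection experiment, one extra
treatment for exponent calibration (grid 1.30–1.60, step 0.005), and the
standard 9-separation × 5-MU sweep for k; this is the scale of the
emulated clinical material and runs in seconds. Convolution/double-sum
agreement is asserted at 1e−9 relative; exact algebraic identities
(linearity in MU and k, additivity, mirror symmetry) at 1e−12 or exactly.
Noiseless parameter recovery is exact to 1e−9 relative; under 1% sweep
noise, k is recovered within 1% and λ within 0.05 across 100 replicate
sweeps.

## Known limitations

* The penumbral model is the weakest link (as its larger sigmas encode);
  a fluence-level model would be needed to do better.
* A single prediction exponent cannot capture per-pair heterogeneity; with
  truth spanning 1.44–1.55 and a literal 1.4034 prediction the beam-level
  bias approaches −4%, inside but near the 5% tolerance — hence the grid
  calibration step in the recommended workflow.
* Step-and-shoot only: plans whose leaves move while meterset accumulates
  are rejected rather than approximated.
* No detector attenuation of the therapeutic beam, no energy dependence,
  no patient/phantom backscatter, no per-wire gain map.
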