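# wiresignal

Computed-baseline in vivo dosimetry for step-and-shoot IMRT with a
collimator-mounted multi-wire transmission detector.

Transmission detectors of this class sit on the linac collimator, one
collection wire per MLC leaf pair (40 wires for an MLCi2-class MLC), and
stay in the beam for the whole treatment. The usual workflow measures a
baseline signal during phantom-based pretreatment verification and compares
every subsequent fraction against it — which costs linac time for every
plan. `wiresignal` instead **predicts** the per-wire signal directly from
the RT DICOM plan, so a delivery can be verified against a computed
baseline on the very first fraction.

## The model

The signal of wire *A* during a static segment combines primary radiation
through its own leaf pair and scatter generated in the detector's acrylic
plate by radiation incident above other wires:

- primary: *R*ₚ = *S* · MU · *k*, with *S* the leaf-pair separation (mm at
  isocenter), MU the segment's monitor units, and *k* a proportionality
  factor;
- scatter from wire *B* to wire *A*: *R*ₚ(*B*) · e^(−λ·D_AB), with λ a
  fitted decay constant (per cm) and D_AB the isocenter-projected wire
  distance — scatter beyond 4 cm is below detectability and treated as zero.

Per wire, for a segment:

```
R_A = MU · k · Σ_W  S_W · exp(−λ · |A−W| · pitch)
```

i.e. a discrete convolution of the separation vector with the scatter
kernel. Out-of-field wires are predicted as fixed penumbral fractions
P₁..P₄ of the last in-field wire (first four beyond each field edge) and
zero further out. Segments sum to beams, beams to the fraction; in-field
predictions carry a 1% relative standard uncertainty and penumbral wires
the fractions' fitted relative spreads, combined in quadrature on
summation. Beam-level deviations |measured−predicted|/predicted are checked
against a 5% tolerance and the full fraction against 2.5%.

Calibration mirrors bench practice: *k* from a single-leaf-pair
separation × MU sweep (two stacked linear fits), λ either log-linearly from
the normalized lateral profile of such a sweep, or — as used for
prediction — by grid search against one measured treatment. Because the
measured per-pair decay constants spread over 1.44–1.55, the single
prediction exponent is best obtained by that grid search.

Everything is testable without hardware: the `simulate` module generates
head-and-neck-like five-field step-and-shoot plans and emulates
measurements with per-wire exponent heterogeneity, 0.3% reproducibility
noise (three averaged replicates) and penumbral jitter, plus fault
injection (MU scaling, leaf offsets, stuck pairs, output scaling).

## Worked example

Simulate two treatments with emulated measurements, calibrate the
prediction exponent on the second, then verify the first:

```
$ wiresignal --seed 42 --out-dir ds simulate --n-plans 2
wrote 2 plans to ds/plans

$ wiresignal calibrate --mode exponent-iterative \
    --plan ds/plans/sim-001.plan.tsv \
    --measured ds/measured/sim-001_B1.signal.tsv ... (one per beam) \
    --grid 1.3:1.6:0.005 --out-config calibrated.yaml
optimal exponent = 1.5000
wrote calibrated.yaml

$ wiresignal --config calibrated.yaml verify \
    ds/plans/sim-000.plan.tsv ds/measured/sim-000_B*.signal.tsv
beam B1: -0.48% (PASS)
beam B2: -0.39% (PASS)
beam B3: -0.34% (PASS)
beam B4: -0.61% (PASS)
beam B5: -0.47% (PASS)
fraction: -0.43% (PASS)
verdict: PASS
```

Each beam's summed measured signal agrees with the computed baseline to
better than 1%, well inside the 5%/2.5% tolerances, so the delivery
passes (exit status 0). Redelivering the same plan with all segment MUs
scaled by +5% (`simulate --fault mu_scale=1.05`):

```
$ wiresignal --config calibrated.yaml verify \
    ds2/plans/sim-000.plan.tsv ds2/measured/sim-000_B*.fault.signal.tsv
beam B1: +4.49% (PASS)
...
fraction: +4.54% (FAIL)
verdict: FAIL
```

The fraction-level deviation exceeds its 2.5% tolerance and the delivery
is flagged (exit status 2), exactly the behaviour wanted for a gross
output/calibration error. `predict` writes per-beam and fraction baseline
signal files for a plan (DICOM or the text dialect); every command writes
a JSON run manifest with config snapshot, input digests and seed.

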