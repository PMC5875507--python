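"""Synthetic plans, emulated detector measurements, and fault injection.

The simulator stands in for the physical detector and linac: it generates
head-and-neck-like step-and-shoot plans (contiguous apertures of 10-25 open
leaf pairs, segment MUs of a few to a few tens of MU), evaluates the
forward model with *true* parameters that differ realistically from the
calibrated prediction model, and corrupts the result with multiplicative
reproducibility noise.

Deliberate realism knobs:

* each wire carries its own true lateral exponent, drawn once per seed from
  the measured per-pair spread (magnitudes 1.44-1.55);
* the true penumbral fractions are jittered per treatment (relative sd
  ``penumbra_jitter``) around their nominal values, emulating
  treatment-to-treatment variation of the penumbral drop-off;
* every wire of every segment of every replicate receives independent
  multiplicative Gaussian noise of sd ``noise_sd`` (0.3% by default, which
  keeps the 3-replicate in-field spread below the 1% observed on the real
  device); replicates are averaged as in clinical use.

Faults (MU scaling, single-pair leaf offsets, stuck pairs, global output
scaling) are applied to copies, never in place.

All randomness derives from ``SimulationConfig.seed`` through distinct
``numpy.random.SeedSequence`` spawn keys, so the whole
generate -> simulate -> inject pipeline is reproducible.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .calibration import (
    CHARACTERIZATION_MUS,
    CHARACTERIZATION_SEPARATIONS_MM,
    CharacterizationSweep,
    SweepRecord,
    wire_for_pair,
)
from .errors import ConfigError, InputDomainError
from .model import (
    Beam,
    DetectorModel,
    PenumbraModel,
    Plan,
    Segment,
    SignalVector,
    apply_penumbra,
    in_field_mask,
)

__all__ = [
    "SimulationConfig",
    "generate_plan",
    "simulate_measurement",
    "simulate_sweep",
    "inject_fault",
    "true_exponents",
]

# SeedSequence spawn-key stream ids
_SK_PLAN = 1
_SK_LAMBDA = 2
_SK_PENUMBRA = 3
_SK_NOISE = 4
_SK_SWEEP = 5


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of the synthetic study.

    Defaults emulate the clinical test material: five-field head-and-neck
    step-and-shoot treatments, contiguous apertures, and a detector whose
    reproducibility keeps the three-replicate in-field spread under 1%.
    """

    seed: int = 0
    n_plans: int = 10
    n_beams: int = 5
    segments_per_beam: tuple[int, int] = (5, 15)
    mu_per_segment: tuple[float, float] = (2.0, 20.0)
    field_wires: tuple[int, int] = (10, 25)
    separation_range: tuple[float, float] = (10.0, 150.0)
    edge_margin: int = 4
    noise_sd: float = 0.003
    n_replicates: int = 3
    true_k: float = 1.0
    lambda_range: tuple[float, float] = (1.44, 1.55)
    true_penumbra: tuple[float, float, float, float] = (0.30, 0.10, 0.04, 0.015)
    penumbra_jitter: float = 0.10
    detector: DetectorModel = field(default_factory=DetectorModel)

    def __post_init__(self) -> None:
        for name in ("segments_per_beam", "mu_per_segment", "field_wires", "separation_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ConfigError(f"invalid range for {name}: ({lo}, {hi})")
        if self.noise_sd < 0 or self.penumbra_jitter < 0:
            raise ConfigError("noise_sd and penumbra_jitter must be >= 0")
        if self.true_k <= 0:
            raise ConfigError("true_k must be > 0")
        lo, hi = self.lambda_range
        if lo <= 0 or hi < lo:
            raise ConfigError("invalid lambda_range")
        n = self.detector.n_wires
        if self.field_wires[1] + 2 * self.edge_margin > n:
            raise ConfigError("largest aperture does not fit inside the detector")
        if self.n_replicates < 1 or self.n_beams < 1:
            raise ConfigError("n_replicates and n_beams must be >= 1")

    def with_(self, **changes) -> "SimulationConfig":
        return replace(self, **changes)


def _rng(config: SimulationConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=key))


def true_exponents(config: SimulationConfig) -> np.ndarray:
    """Per-wire true lateral exponents, fixed for a given seed.

    A property of the simulated detector, not of any one plan: drawn once,
    uniformly over ``lambda_range``.
    """
    rng = _rng(config, _SK_LAMBDA)
    lo, hi = config.lambda_range
    return rng.uniform(lo, hi, size=config.detector.n_wires)


def generate_plan(config: SimulationConfig, plan_index: int) -> Plan:
    """Generate one synthetic step-and-shoot plan, deterministic for
    (seed, plan_index).

    Each segment opens a contiguous run of leaf pairs (length and position
    random within configuration) to independent random separations, with at
    least ``edge_margin`` closed pairs kept on each side so the penumbral
    region fits on the detector.
    """
    rng = _rng(config, _SK_PLAN, plan_index)
    n = config.detector.n_wires
    beams = []
    for b in range(config.n_beams):
        n_seg = int(rng.integers(config.segments_per_beam[0], config.segments_per_beam[1] + 1))
        segments = []
        for _ in range(n_seg):
            length = int(rng.integers(config.field_wires[0], config.field_wires[1] + 1))
            start = int(rng.integers(config.edge_margin, n - config.edge_margin - length + 1))
            separations = np.zeros(n)
            separations[start : start + length] = rng.uniform(
                config.separation_range[0], config.separation_range[1], size=length
            )
            mu = float(rng.uniform(*config.mu_per_segment))
            segments.append(Segment(separations=separations, mu=mu))
        beams.append(Beam(segments=segments, beam_id=f"B{b + 1}"))
    return Plan(beams=beams, plan_id=f"sim-{plan_index:03d}")


def _truth_response(
    segment: Segment, config: SimulationConfig, lam: np.ndarray
) -> np.ndarray:
    """Forward model with per-wire (source) exponents: the scatter reaching
    wire A from the aperture above wire W decays with W's own exponent."""
    det = config.detector
    n = det.n_wires
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) * det.wire_pitch
    kernel = np.where(d <= det.scatter_cutoff, np.exp(-d * lam[None, :]), 0.0)
    return segment.mu * config.true_k * (kernel @ segment.separations)


def _jittered_penumbra(config: SimulationConfig, rng: np.random.Generator) -> PenumbraModel:
    base = np.array(config.true_penumbra)
    if config.penumbra_jitter == 0:
        fr = base
    else:
        fr = np.clip(base * (1.0 + config.penumbra_jitter * rng.standard_normal(4)), 0.0, 1.0)
        fr = np.minimum.accumulate(fr)
    return PenumbraModel(fractions=tuple(fr), sigmas=(0.0, 0.0, 0.0, 0.0))


def simulate_measurement(
    plan: Plan,
    config: SimulationConfig,
    plan_index: int = 0,
    return_replicates: bool = False,
):
    """Emulate measured per-beam signals for a plan.

    The truth forward model (per-wire exponents, jittered true penumbral
    fractions) is evaluated per segment, corrupted per replicate with
    multiplicative Gaussian noise per wire per segment, summed over
    segments, and averaged over replicates.

    Returns a list of beam-level :class:`SignalVector`; with
    ``return_replicates=True`` also the raw per-replicate beam sums as an
    array of shape (n_beams, n_replicates, n_wires).
    """
    lam = true_exponents(config)
    pen_rng = _rng(config, _SK_PENUMBRA, plan_index)
    pen_true = _jittered_penumbra(config, pen_rng)
    noise_rng = _rng(config, _SK_NOISE, plan_index)
    det = config.detector
    n = det.n_wires
    measured: list[SignalVector] = []
    replicate_sums = np.zeros((len(plan.beams), config.n_replicates, n))
    for bi, beam in enumerate(plan.beams):
        for seg in beam.segments:
            truth = _truth_response(seg, config, lam)
            mask = in_field_mask(seg, det)
            truth = apply_penumbra(
                SignalVector(values=truth, sigmas=np.zeros(n), level="segment"),
                mask,
                pen_true,
                in_field_sigma=0.0,
            ).values
            for r in range(config.n_replicates):
                noise = 1.0 + config.noise_sd * noise_rng.standard_normal(n)
                replicate_sums[bi, r] += truth * noise
        values = replicate_sums[bi].mean(axis=0)
        measured.append(SignalVector(values=values, sigmas=np.zeros(n), level="beam"))
    if return_replicates:
        return measured, replicate_sums
    return measured


def simulate_sweep(
    config: SimulationConfig,
    leaf_pair: int = 0,
    separations: Sequence[float] = CHARACTERIZATION_SEPARATIONS_MM,
    mus: Sequence[float] = CHARACTERIZATION_MUS,
    true_lambda: float | None = None,
    n_replicates: int | None = None,
    sweep_index: int = 0,
) -> CharacterizationSweep:
    """Emulate a single-leaf-pair characterization sweep.

    One record per (separation, MU) with replicate-averaged noisy signals.
    The open pair's scatter decays with its own true exponent (or with
    ``true_lambda`` when given).  No penumbral override is applied: with a
    single open pair the neighbouring wires' signals *are* the lateral
    scatter profile being characterized.
    """
    det = config.detector
    n = det.n_wires
    wire = wire_for_pair(leaf_pair, n)
    lam = true_lambda if true_lambda is not None else float(true_exponents(config)[wire])
    reps = n_replicates if n_replicates is not None else config.n_replicates
    rng = _rng(config, _SK_SWEEP, sweep_index, leaf_pair)
    d = np.abs(np.arange(n) - wire) * det.wire_pitch
    kernel = np.where(d <= det.scatter_cutoff, np.exp(-lam * d), 0.0)
    records = []
    for sep in separations:
        for mu in mus:
            clean = sep * mu * config.true_k * kernel
            noisy = np.zeros(n)
            for _ in range(reps):
                noisy += clean * (1.0 + config.noise_sd * rng.standard_normal(n))
            records.append(
                SweepRecord(
                    leaf_pair=leaf_pair,
                    separation=float(sep),
                    mu=float(mu),
                    signals=np.clip(noisy / reps, 0.0, None),
                )
            )
    return CharacterizationSweep(records)


def inject_fault(obj, fault: dict):
    """Return a modified deep copy of a Plan or measurement list.

    ``fault`` holds exactly one of:

    * ``{"mu_scale": factor}`` — multiply every segment MU (Plan);
    * ``{"leaf_offset": (wire, mm)}`` — widen one pair's separation by a
      fixed offset in every segment, clamped at zero (Plan);
    * ``{"stuck_pair": wire}`` — freeze one pair at its first-segment
      separation throughout each beam (Plan);
    * ``{"output_scale": factor}`` — scale measured signals (list of
      SignalVector).
    """
    if not isinstance(fault, dict) or len(fault) != 1:
        raise InputDomainError("fault spec must hold exactly one entry")
    (kind, arg), = fault.items()
    if kind == "mu_scale":
        _require_plan(obj, kind)
        out = copy.deepcopy(obj)
        for beam in out.beams:
            for seg in beam.segments:
                seg.mu *= float(arg)
        return out
    if kind == "leaf_offset":
        _require_plan(obj, kind)
        wire, offset = arg
        out = copy.deepcopy(obj)
        for beam in out.beams:
            for seg in beam.segments:
                seg.separations[wire] = max(0.0, seg.separations[wire] + float(offset))
        return out
    if kind == "stuck_pair":
        _require_plan(obj, kind)
        wire = int(arg)
        out = copy.deepcopy(obj)
        for beam in out.beams:
            stuck_at = beam.segments[0].separations[wire]
            for seg in beam.segments:
                seg.separations[wire] = stuck_at
        return out
    if kind == "output_scale":
        if not isinstance(obj, (list, tuple)):
            raise InputDomainError("output_scale applies to a measurement list")
        return [
            SignalVector(values=sv.values * float(arg), sigmas=sv.sigmas.copy(), level=sv.level)
            for sv in obj
        ]
    raise InputDomainError(f"unknown fault kind {kind!r}")


def _require_plan(obj, kind: str) -> None:
    if not isinstance(obj, Plan):
        raise InputDomainError(f"fault {kind!r} applies to a Plan")
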