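"""Comparison of predicted against measured signals with tolerance verdicts.

Relative deviations (measured - predicted) / predicted are computed per
wire, per beam (on beam-summed signals) and for the full fraction (sum over
beams).  Beam deviations are checked against a 5% tolerance, the fraction
deviation against 2.5%; a delivery is flagged when any beam or the fraction
deviation exceeds its tolerance in magnitude.  Per-wire deviations are
reported for diagnosis but do not drive the verdict; wires whose predicted
value sits below a relative signal floor are masked to avoid meaningless
ratios against near-zero out-of-field predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Sequence

import numpy as np

from .errors import ComparisonError, StructuralError
from .model import (
    Beam,
    DetectorModel,
    PenumbraModel,
    Plan,
    SignalVector,
    beam_in_field_mask,
    penumbra_assignments,
    predict_beam,
)

__all__ = [
    "ComparisonReport",
    "propagate_uncertainty",
    "compare",
    "detect_output_change",
    "write_report",
]


@dataclass
class ComparisonReport:
    """Deviations, tolerances and verdicts of one predicted/measured
    comparison.  Verdicts are pass (True) / fail (False); the comparison
    fails strictly when |deviation| > tolerance."""

    per_wire_deviations: np.ndarray
    wire_mask: np.ndarray
    beam_deviations: np.ndarray
    fraction_deviation: float
    beam_tolerance: float = 0.05
    fraction_tolerance: float = 0.025
    plan_id: str = ""
    beam_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.beam_tolerance <= 0 or self.fraction_tolerance <= 0:
            raise StructuralError("tolerances must be > 0")

    # Boundary rule: "within tolerance" is inclusive; a delivery fails only
    # strictly beyond it.  The tiny absolute guard keeps a mathematically
    # exact boundary deviation (e.g. a measurement scaled by exactly 1.05)
    # from flipping on floating-point rounding.
    _EDGE_GUARD = 1e-12

    @property
    def beam_verdicts(self) -> np.ndarray:
        return np.abs(self.beam_deviations) <= self.beam_tolerance + self._EDGE_GUARD

    @property
    def fraction_verdict(self) -> bool:
        return abs(self.fraction_deviation) <= self.fraction_tolerance + self._EDGE_GUARD

    @property
    def passed(self) -> bool:
        return bool(self.fraction_verdict and self.beam_verdicts.all())


def propagate_uncertainty(
    signal: SignalVector,
    in_field_mask: np.ndarray,
    pen: PenumbraModel,
    in_field_sigma: float = 0.01,
) -> SignalVector:
    """Assign standard uncertainties by field position.

    In-field wires get ``in_field_sigma`` relative; the first four wires
    beyond each edge get the penumbral relative sigmas; all remaining wires
    get zero.  Values are untouched.
    """
    mask = np.asarray(in_field_mask, dtype=bool)
    if len(mask) != len(signal):
        raise StructuralError("mask length must match signal length")
    sigmas = np.where(mask, in_field_sigma * np.abs(signal.values), 0.0)
    for wire, candidates in penumbra_assignments(mask).items():
        rank = min(r for _, r in candidates)
        sigmas[wire] = pen.sigmas[rank - 1] * abs(signal.values[wire])
    return SignalVector(values=signal.values.copy(), sigmas=sigmas, level=signal.level)


def compare(
    predicted_beams: Sequence[SignalVector],
    measured_beams: Sequence[SignalVector],
    beam_tolerance: float = 0.05,
    fraction_tolerance: float = 0.025,
    signal_floor: float = 1e-6,
    plan_id: str = "",
    beam_ids: Sequence[str] | None = None,
) -> ComparisonReport:
    """Compare per-beam predictions with measurements.

    ``signal_floor`` is relative to the largest predicted fraction-level
    wire value; wires predicted below it are excluded from the per-wire
    deviation report.
    """
    if len(predicted_beams) != len(measured_beams):
        raise StructuralError("one measured vector per predicted beam required")
    if not predicted_beams:
        raise StructuralError("nothing to compare")
    n = len(predicted_beams[0])
    for sv in (*predicted_beams, *measured_beams):
        if len(sv) != n:
            raise StructuralError("signal vectors differ in length")
    pred_frac = np.sum([sv.values for sv in predicted_beams], axis=0)
    meas_frac = np.sum([sv.values for sv in measured_beams], axis=0)
    if not np.any(pred_frac > 0):
        raise ComparisonError("all-zero prediction; comparison undefined")
    beam_devs = []
    for p, m in zip(predicted_beams, measured_beams):
        psum = p.values.sum()
        if psum <= 0:
            raise ComparisonError("beam with nonpositive predicted sum")
        beam_devs.append((m.values.sum() - psum) / psum)
    fraction_dev = (meas_frac.sum() - pred_frac.sum()) / pred_frac.sum()
    floor = signal_floor * pred_frac.max()
    wire_mask = pred_frac > floor
    per_wire = np.zeros(n)
    per_wire[wire_mask] = (meas_frac[wire_mask] - pred_frac[wire_mask]) / pred_frac[wire_mask]
    return ComparisonReport(
        per_wire_deviations=per_wire,
        wire_mask=wire_mask,
        beam_deviations=np.array(beam_devs),
        fraction_deviation=float(fraction_dev),
        beam_tolerance=beam_tolerance,
        fraction_tolerance=fraction_tolerance,
        plan_id=plan_id,
        beam_ids=list(beam_ids) if beam_ids is not None else [],
    )


def detect_output_change(
    plan: Plan,
    model: DetectorModel,
    pen: PenumbraModel,
    measured_beams: Sequence[SignalVector],
    beam_tolerance: float = 0.05,
    fraction_tolerance: float = 0.025,
) -> tuple[bool, ComparisonReport]:
    """Predict the plan, compare with measurements, and flag the delivery.

    Returns ``(flagged, report)`` where ``flagged`` is True iff any beam or
    the fraction deviation exceeds its tolerance.
    """
    predicted = [predict_beam(beam, model, pen) for beam in plan.beams]
    report = compare(
        predicted,
        measured_beams,
        beam_tolerance=beam_tolerance,
        fraction_tolerance=fraction_tolerance,
        plan_id=plan.plan_id,
        beam_ids=[b.beam_id for b in plan.beams],
    )
    return (not report.passed, report)


def write_report(report: ComparisonReport, file: str | Path | IO[str]) -> None:
    """Write a report as a tab-separated wire table plus a summary block."""

    def _write(fh: IO[str]) -> None:
        fh.write(f"# comparison report\tplan_id={report.plan_id}\n")
        fh.write("wire\tdeviation\tvalid\n")
        for i, (dev, ok) in enumerate(
            zip(report.per_wire_deviations, report.wire_mask), start=1
        ):
            fh.write(f"{i}\t{dev:.6g}\t{int(ok)}\n")
        fh.write("# summary\n")
        for j, dev in enumerate(report.beam_deviations):
            bid = report.beam_ids[j] if j < len(report.beam_ids) else str(j + 1)
            verdict = "PASS" if report.beam_verdicts[j] else "FAIL"
            fh.write(f"# beam {bid}\tdeviation={100 * dev:+.2f}%\t{verdict}\n")
        fv = "PASS" if report.fraction_verdict else "FAIL"
        fh.write(f"# fraction\tdeviation={100 * report.fraction_deviation:+.2f}%\t{fv}\n")
        fh.write(f"# overall\t{'PASS' if report.passed else 'FAIL'}\n")

    if hasattr(file, "write"):
        _write(file)  # type: ignore[arg-type]
    else:
        with open(file, "w") as fh:
            _write(fh)
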