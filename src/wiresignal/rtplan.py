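"""Plan input: RT DICOM (RTPLAN) and a plain-text dialect.

Step-and-shoot beams are stored in DICOM as control-point sequences in
which the geometry (MLC leaf banks, jaws) is static while meterset weight
accumulates; each consecutive pair of control points with a weight increase
and unchanged geometry is one segment.  Segment MU is the weight increment
times the beam meterset, normalized by the final cumulative weight.

Leaf-pair separations are bank-B minus bank-A positions (mm at isocenter),
clamped at zero — crossed or closed leaves carry no aperture.  Leaf pairs
map positionally onto wires (pair i -> wire i); ``reverse_wires`` covers a
detector mounted rotated by 180 degrees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO

import numpy as np
import pydicom

from .errors import (
    GeometryMismatchError,
    PlanParseError,
    UnsupportedPlanError,
)
from .model import Beam, Plan, Segment

__all__ = ["RawControlPoint", "read_rtplan", "read_plan_text", "write_plan_text", "read_plan"]

logger = logging.getLogger(__name__)

_WEIGHT_TOL = 1e-9
_GEOM_TOL = 1e-6  # mm; leaf positions equal within this are "static"


@dataclass
class RawControlPoint:
    """Resolved state of one control point (after carrying forward
    unchanged DICOM attributes)."""

    index: int
    cumulative_weight: float
    bank_a: np.ndarray
    bank_b: np.ndarray
    jaw_x: tuple[float, float] | None
    jaw_y: tuple[float, float] | None


def _positions_by_type(cp) -> dict[str, list[float]]:
    out: dict[str, list[float]] = {}
    for item in getattr(cp, "BeamLimitingDevicePositionSequence", []):
        out[item.RTBeamLimitingDeviceType.upper()] = [
            float(v) for v in item.LeafJawPositions
        ]
    return out


def _resolve_control_points(beam) -> list[RawControlPoint]:
    """Carry geometry forward through the control-point sequence."""
    mlc: list[float] | None = None
    jaw_x: tuple[float, float] | None = None
    jaw_y: tuple[float, float] | None = None
    resolved: list[RawControlPoint] = []
    for i, cp in enumerate(beam.ControlPointSequence):
        pos = _positions_by_type(cp)
        for key in ("MLCX", "MLCY"):
            if key in pos:
                mlc = pos[key]
        for key in ("ASYMX", "X"):
            if key in pos:
                jaw_x = (pos[key][0], pos[key][1])
        for key in ("ASYMY", "Y"):
            if key in pos:
                jaw_y = (pos[key][0], pos[key][1])
        if mlc is None:
            raise PlanParseError(f"control point {i} has no MLC positions")
        if len(mlc) % 2:
            raise PlanParseError("odd number of MLC leaf positions")
        half = len(mlc) // 2
        resolved.append(
            RawControlPoint(
                index=i,
                cumulative_weight=float(cp.CumulativeMetersetWeight),
                bank_a=np.array(mlc[:half], dtype=float),
                bank_b=np.array(mlc[half:], dtype=float),
                jaw_x=jaw_x,
                jaw_y=jaw_y,
            )
        )
    return resolved


def _metersets(ds) -> dict[int, float]:
    out: dict[int, float] = {}
    for fg in getattr(ds, "FractionGroupSequence", []):
        for rb in getattr(fg, "ReferencedBeamSequence", []):
            if hasattr(rb, "BeamMeterset"):
                out[int(rb.ReferencedBeamNumber)] = float(rb.BeamMeterset)
    return out


def read_rtplan(
    source: str | Path | pydicom.Dataset,
    n_wires: int = 40,
    reverse_wires: bool = False,
) -> Plan:
    """Read a step-and-shoot Plan from an RT DICOM file or dataset.

    Raises :class:`UnsupportedPlanError` for dynamic (intra-segment moving)
    control points, :class:`PlanParseError` for missing metersets and
    :class:`GeometryMismatchError` when the leaf count is not twice the
    wire count.
    """
    ds = source if isinstance(source, pydicom.Dataset) else pydicom.dcmread(source)
    if getattr(ds, "Modality", "RTPLAN") != "RTPLAN":
        raise PlanParseError(f"not an RT Plan (Modality={ds.Modality!r})")
    metersets = _metersets(ds)
    beams: list[Beam] = []
    for beam_ds in getattr(ds, "BeamSequence", []):
        if getattr(beam_ds, "TreatmentDeliveryType", "TREATMENT") != "TREATMENT":
            continue
        beam_number = int(getattr(beam_ds, "BeamNumber", len(beams) + 1))
        if beam_number not in metersets:
            raise PlanParseError(f"no meterset for beam {beam_number}")
        meterset = metersets[beam_number]
        cps = _resolve_control_points(beam_ds)
        if len(cps) < 2:
            raise PlanParseError(f"beam {beam_number} has <2 control points")
        final_weight = float(
            getattr(beam_ds, "FinalCumulativeMetersetWeight", cps[-1].cumulative_weight)
        )
        if final_weight <= 0:
            raise PlanParseError(f"beam {beam_number} has nonpositive final weight")
        segments: list[Segment] = []
        for cp0, cp1 in zip(cps, cps[1:]):
            dw = cp1.cumulative_weight - cp0.cumulative_weight
            if dw < -_WEIGHT_TOL:
                raise PlanParseError(
                    f"cumulative weight decreases at control point {cp1.index}"
                )
            if dw <= _WEIGHT_TOL:
                continue  # geometry-change step, beam off
            moving = np.max(np.abs(cp1.bank_a - cp0.bank_a)) > _GEOM_TOL or np.max(
                np.abs(cp1.bank_b - cp0.bank_b)
            ) > _GEOM_TOL
            if moving:
                raise UnsupportedPlanError(
                    f"leaves move while meterset accumulates at control point "
                    f"{cp0.index}->{cp1.index}: not a step-and-shoot plan"
                )
            if len(cp0.bank_a) != n_wires:
                raise GeometryMismatchError(
                    f"{2 * len(cp0.bank_a)} leaves in plan, detector expects "
                    f"{2 * n_wires}"
                )
            separations = np.clip(cp0.bank_b - cp0.bank_a, 0.0, None)
            if reverse_wires:
                separations = separations[::-1]
            mu = dw / final_weight * meterset
            if mu < 1e-9:
                logger.info(
                    "beam %s: near-zero MU segment retained (%.3g MU)",
                    beam_number,
                    mu,
                )
            segments.append(Segment(separations=separations, mu=mu, jaw_y=cp0.jaw_y))
        if not segments:
            raise PlanParseError(f"beam {beam_number} yields no segments")
        beams.append(Beam(segments=segments, beam_id=str(getattr(beam_ds, "BeamName", beam_number))))
    if not beams:
        raise PlanParseError("plan contains no treatment beams")
    return Plan(beams=beams, plan_id=str(getattr(ds, "RTPlanLabel", "")) or "rtplan")


# ---------------------------------------------------------------------------
# Text dialect.  Header lines give plan_id and n_wires; each following row is
#   beam_id <TAB> segment_id <TAB> mu <TAB> s1 ... s40 [<TAB> jaw_y1 <TAB> jaw_y2]


def write_plan_text(plan: Plan, file: str | Path | IO[str]) -> None:
    """Deterministic serialization of a Plan to the text dialect."""
    n_wires = len(plan.beams[0].segments[0].separations)

    def _write(fh: IO[str]) -> None:
        fh.write(f"# plan_id={plan.plan_id}\n")
        fh.write(f"# n_wires={n_wires}\n")
        for beam in plan.beams:
            for si, seg in enumerate(beam.segments):
                if seg.mu == 0:
                    logger.info(
                        "plan %s beam %s: zero-MU segment %d written",
                        plan.plan_id,
                        beam.beam_id,
                        si,
                    )
                fields = [beam.beam_id, str(si), f"{seg.mu:.17g}"]
                fields += [f"{s:.17g}" for s in seg.separations]
                if seg.jaw_y is not None:
                    fields += [f"{seg.jaw_y[0]:.17g}", f"{seg.jaw_y[1]:.17g}"]
                fh.write("\t".join(fields) + "\n")

    if hasattr(file, "write"):
        _write(file)  # type: ignore[arg-type]
    else:
        with open(file, "w") as fh:
            _write(fh)


def read_plan_text(file: str | Path | IO[str]) -> Plan:
    """Read a Plan from the text dialect; parse errors carry line numbers."""
    if hasattr(file, "read"):
        lines = file.read().splitlines()  # type: ignore[union-attr]
    else:
        lines = Path(file).read_text().splitlines()
    plan_id = ""
    n_wires: int | None = None
    beams: dict[str, list[Segment]] = {}
    order: list[str] = []
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("plan_id="):
                plan_id = body.split("=", 1)[1]
            elif body.startswith("n_wires="):
                try:
                    n_wires = int(body.split("=", 1)[1])
                except ValueError as exc:
                    raise PlanParseError(f"line {lineno}: bad n_wires") from exc
            continue
        if n_wires is None:
            raise PlanParseError(f"line {lineno}: data before n_wires header")
        parts = line.split("\t")
        if len(parts) not in (3 + n_wires, 5 + n_wires):
            raise PlanParseError(
                f"line {lineno}: expected {3 + n_wires} or {5 + n_wires} "
                f"fields, got {len(parts)}"
            )
        beam_id = parts[0]
        try:
            mu = float(parts[2])
            separations = np.array([float(v) for v in parts[3 : 3 + n_wires]])
            jaw_y = None
            if len(parts) == 5 + n_wires:
                jaw_y = (float(parts[-2]), float(parts[-1]))
        except ValueError as exc:
            raise PlanParseError(f"line {lineno}: non-numeric field ({exc})") from exc
        if beam_id not in beams:
            beams[beam_id] = []
            order.append(beam_id)
        beams[beam_id].append(Segment(separations=separations, mu=mu, jaw_y=jaw_y))
    if not beams:
        raise PlanParseError("no segments found in plan file")
    return Plan(
        beams=[Beam(segments=beams[b], beam_id=b) for b in order],
        plan_id=plan_id,
    )


def read_plan(path: str | Path, n_wires: int = 40) -> Plan:
    """Read a plan from DICOM or the text dialect, sniffing the format."""
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(132)
    if len(head) >= 132 and head[128:132] == b"DICM":
        return read_rtplan(path, n_wires=n_wires)
    return read_plan_text(path)
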