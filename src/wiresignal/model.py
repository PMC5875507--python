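"""Forward model for a collimator-mounted multi-wire transmission detector.

The detector has one collection wire per MLC leaf pair (40 for an MLCi2-class
collimator).  The signal collected by a wire during a static (step-and-shoot)
segment has two components:

* primary radiation through the aperture of the wire's own leaf pair,
  proportional to the leaf-pair separation ``S`` (mm at isocenter) and the
  delivered monitor units: ``Rp = S * MU * k``;
* scatter generated in the detector's acrylic plate by radiation incident
  above *other* wires, falling off exponentially with the isocenter-projected
  lateral distance ``D``: ``Rs_A(B) = Rp_B * exp(-lambda * D_AB)``.

Summing both over all leaf pairs gives, per wire ``A``,

    R_A = MU * k * sum_W S_W * exp(-lambda * D_AW)

which is a discrete convolution of the separation vector with the scatter
kernel; the ``W == A`` term is exactly the primary signal.  Scatter beyond a
cutoff distance (4 cm by default) is below the detection threshold and is
treated as zero, so the kernel is compactly supported.

Wires outside the field receive no primary signal; the first four wires
beyond each field edge are modelled as fixed penumbral fractions ``P1..P4``
of the last in-field wire's predicted signal, and all further out-of-field
wires are predicted as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np

from .errors import InputDomainError, StructuralError

__all__ = [
    "DetectorModel",
    "Segment",
    "Beam",
    "Plan",
    "SignalVector",
    "PenumbraModel",
    "DEFAULT_PENUMBRA",
    "primary_response",
    "scatter_kernel",
    "predict_segment",
    "in_field_mask",
    "beam_in_field_mask",
    "apply_penumbra",
    "predict_beam",
    "predict_fraction",
    "write_signal",
    "read_signal",
]


@dataclass(frozen=True)
class DetectorModel:
    """Detector geometry and model parameters.

    Parameters
    ----------
    n_wires
        Number of collection wires (one per leaf pair).
    wire_pitch
        Isocenter-projected distance between adjacent wires, cm.
    k
        Proportionality factor, signal units per (mm * MU).
    lateral_exponent
        Positive decay constant of the lateral scatter response, per cm of
        isocenter-projected distance.  Stored as a magnitude; the kernel is
        ``exp(-lateral_exponent * D)``.
    scatter_cutoff
        Distance in cm beyond which scatter is below detectability and is
        treated as exactly zero.
    closed_threshold
        Leaf-pair separations at or below this value (mm) count as closed
        when building the in-field mask.
    in_field_sigma
        Relative standard uncertainty assigned to in-field predictions.
    """

    n_wires: int = 40
    wire_pitch: float = 1.0
    k: float = 1.0
    lateral_exponent: float = 1.4034
    scatter_cutoff: float = 4.0
    closed_threshold: float = 1.0
    in_field_sigma: float = 0.01

    def __post_init__(self) -> None:
        if self.n_wires < 1:
            raise InputDomainError("n_wires must be >= 1")
        if self.wire_pitch <= 0:
            raise InputDomainError("wire_pitch must be > 0")
        if self.k <= 0:
            raise InputDomainError("k must be > 0")
        if self.lateral_exponent <= 0:
            raise InputDomainError("lateral_exponent must be > 0")
        if self.scatter_cutoff < 0:
            raise InputDomainError("scatter_cutoff must be >= 0")

    def wire_positions(self) -> np.ndarray:
        """Wire positions along the leaf-pair axis, mm at isocenter,
        centered on the detector midline."""
        idx = np.arange(self.n_wires, dtype=float)
        return (idx - (self.n_wires - 1) / 2.0) * self.wire_pitch * 10.0

    def with_(self, **changes) -> "DetectorModel":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


@dataclass
class Segment:
    """One static aperture and its monitor units.

    ``separations`` holds one leaf-pair separation per wire, mm at
    isocenter, zero for closed pairs.  ``jaw_y`` optionally restricts the
    field along the wire axis (pair of edge positions, mm at isocenter).
    """

    separations: np.ndarray
    mu: float
    jaw_y: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.separations = np.asarray(self.separations, dtype=float)
        if self.separations.ndim != 1:
            raise StructuralError("separations must be a 1-D vector")
        if np.any(self.separations < 0):
            raise InputDomainError("separations must be >= 0")
        if self.mu < 0:
            raise InputDomainError("mu must be >= 0")


@dataclass
class Beam:
    segments: list[Segment]
    beam_id: str = ""

    def __post_init__(self) -> None:
        if len(self.segments) < 1:
            raise StructuralError("a beam needs at least one segment")


@dataclass
class Plan:
    beams: list[Beam]
    plan_id: str = ""

    def __post_init__(self) -> None:
        if len(self.beams) < 1:
            raise StructuralError("a plan needs at least one beam")


@dataclass
class SignalVector:
    """Per-wire responses with standard uncertainties.

    ``level`` records the aggregation level: ``segment``, ``beam`` or
    ``fraction``.
    """

    values: np.ndarray
    sigmas: np.ndarray
    level: str = "segment"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        if self.values.shape != self.sigmas.shape:
            raise StructuralError("values and sigmas must have equal length")
        if np.any(self.sigmas < 0):
            raise InputDomainError("sigmas must be >= 0")
        if self.level not in ("segment", "beam", "fraction"):
            raise StructuralError(f"unknown level {self.level!r}")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class PenumbraModel:
    """Penumbral drop-off fractions P1..P4 with relative standard deviations.

    The i-th wire beyond a field edge is predicted as ``fractions[i-1]``
    times the last in-field wire's predicted signal.
    """

    fractions: tuple[float, float, float, float]
    sigmas: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        fr = tuple(float(f) for f in self.fractions)
        sg = tuple(float(s) for s in self.sigmas)
        object.__setattr__(self, "fractions", fr)
        object.__setattr__(self, "sigmas", sg)
        if len(fr) != 4 or len(sg) != 4:
            raise StructuralError("exactly 4 penumbral fractions and sigmas")
        if any(f < 0 or f > 1 for f in fr):
            raise InputDomainError("fractions must lie in [0, 1]")
        if any(s < 0 for s in sg):
            raise InputDomainError("sigmas must be >= 0")
        if any(fr[i] < fr[i + 1] for i in range(3)):
            raise InputDomainError("fractions must be non-increasing")


#: Packaged default penumbral model; produced by running the calibration
#: module's fraction fit on simulator output (see docs/methods.md).
DEFAULT_PENUMBRA = PenumbraModel(
    fractions=(0.30, 0.10, 0.04, 0.015), sigmas=(0.10, 0.10, 0.10, 0.10)
)


def primary_response(separation: float, mu: float, k: float) -> float:
    """Primary signal of a wire: separation (mm) x MU x k."""
    if separation < 0:
        raise InputDomainError("separation must be >= 0")
    if mu < 0:
        raise InputDomainError("mu must be >= 0")
    if k <= 0:
        raise InputDomainError("k must be > 0")
    return separation * mu * k


def scatter_kernel(distance, lateral_exponent: float, scatter_cutoff: float = 4.0):
    """Lateral scatter response ``exp(-lambda * D)``, zero beyond the cutoff.

    Accepts scalars or arrays of distances (cm, >= 0).
    """
    if lateral_exponent <= 0:
        raise InputDomainError("lateral_exponent must be > 0")
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise InputDomainError("distance must be >= 0")
    out = np.where(d <= scatter_cutoff, np.exp(-lateral_exponent * d), 0.0)
    if np.isscalar(distance) or np.ndim(distance) == 0:
        return float(out)
    return out


def _kernel_vector(model: DetectorModel) -> np.ndarray:
    """Full symmetric kernel sampled at wire offsets -(n-1)..(n-1)."""
    offsets = np.arange(-(model.n_wires - 1), model.n_wires)
    return scatter_kernel(
        np.abs(offsets) * model.wire_pitch,
        model.lateral_exponent,
        model.scatter_cutoff,
    )


def predict_segment(segment: Segment, model: DetectorModel) -> SignalVector:
    """Predict the raw per-wire signal of one segment.

    Discrete convolution of the separation vector with the scatter kernel,
    scaled by MU and k.  Identical to the double sum
    ``R_A = MU * k * sum_W S_W * exp(-lambda * |A - W| * pitch)`` with the
    cutoff applied.  The penumbral/out-of-field treatment is a separate step
    (:func:`apply_penumbra`); sigmas are zero here.
    """
    n = model.n_wires
    if len(segment.separations) != n:
        raise StructuralError(
            f"segment has {len(segment.separations)} separations, "
            f"detector has {n} wires"
        )
    kern = _kernel_vector(model)
    full = np.convolve(segment.separations, kern)
    values = segment.mu * model.k * full[n - 1 : 2 * n - 1]
    return SignalVector(values=values, sigmas=np.zeros(n), level="segment")


def in_field_mask(segment: Segment, model: DetectorModel) -> np.ndarray:
    """Boolean mask of wires that are in-field for a segment.

    A wire is in-field iff its leaf-pair separation exceeds the closed
    threshold and, when ``jaw_y`` is given, its position lies inside the
    jaw aperture along the wire axis.
    """
    mask = segment.separations > model.closed_threshold
    if segment.jaw_y is not None:
        lo, hi = sorted(segment.jaw_y)
        pos = model.wire_positions()
        mask = mask & (pos >= lo) & (pos <= hi)
    return mask


def beam_in_field_mask(beam: Beam, model: DetectorModel) -> np.ndarray:
    """Union of the segment masks: wires in-field in at least one segment."""
    mask = np.zeros(model.n_wires, dtype=bool)
    for seg in beam.segments:
        mask |= in_field_mask(seg, model)
    return mask


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of a boolean mask as (start, stop) index pairs,
    stop exclusive."""
    runs: list[tuple[int, int]] = []
    n = len(mask)
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def penumbra_assignments(mask: np.ndarray) -> dict[int, list[tuple[int, int]]]:
    """Map each penumbral wire to its (edge wire, rank) candidates.

    For every contiguous in-field run, the up-to-four out-of-field wires on
    each side get rank 1..4 by distance from the edge.  A wire lying within
    four wires of two field edges collects both candidates; walking outward
    stops when another in-field run is reached.
    """
    n = len(mask)
    out: dict[int, list[tuple[int, int]]] = {}
    for start, stop in _runs(mask):
        for rank in range(1, 5):  # left side
            w = start - rank
            if w < 0 or mask[w]:
                break
            out.setdefault(w, []).append((start, rank))
        for rank in range(1, 5):  # right side
            w = stop - 1 + rank
            if w >= n or mask[w]:
                break
            out.setdefault(w, []).append((stop - 1, rank))
    return out


def apply_penumbra(
    predicted: SignalVector,
    mask: np.ndarray,
    pen: PenumbraModel,
    in_field_sigma: float = 0.01,
) -> SignalVector:
    """Apply the out-of-field/penumbral rule to a raw segment prediction.

    In-field wires keep their convolution value and receive a relative
    standard uncertainty ``in_field_sigma``; the first four wires beyond
    each field edge get ``P_i`` times the nearest in-field wire's value with
    the penumbral relative sigmas; all other out-of-field wires are set to
    zero.  Where two field edges compete for a wire, the larger penumbral
    candidate wins.
    """
    mask = np.asarray(mask, dtype=bool)
    if len(mask) != len(predicted):
        raise StructuralError("mask length must match signal length")
    if not mask.any():
        if np.any(predicted.values > 0):
            raise StructuralError("nonzero signal but empty in-field mask")
        return SignalVector(
            values=np.zeros(len(predicted)),
            sigmas=np.zeros(len(predicted)),
            level=predicted.level,
        )
    values = np.where(mask, predicted.values, 0.0)
    sigmas = np.where(mask, in_field_sigma * np.abs(values), 0.0)
    for wire, candidates in penumbra_assignments(mask).items():
        best_val = 0.0
        best_sig = 0.0
        for edge, rank in candidates:
            val = pen.fractions[rank - 1] * predicted.values[edge]
            if val > best_val:
                best_val = val
                best_sig = pen.sigmas[rank - 1] * val
        values[wire] = best_val
        sigmas[wire] = best_sig
    return SignalVector(values=values, sigmas=sigmas, level=predicted.level)


def predict_beam(beam: Beam, model: DetectorModel, pen: PenumbraModel) -> SignalVector:
    """Predicted beam signal: element-wise sum of penumbra-adjusted segment
    predictions, sigmas combined in quadrature."""
    values = np.zeros(model.n_wires)
    var = np.zeros(model.n_wires)
    for seg in beam.segments:
        raw = predict_segment(seg, model)
        adj = apply_penumbra(raw, in_field_mask(seg, model), pen, model.in_field_sigma)
        values += adj.values
        var += adj.sigmas**2
    return SignalVector(values=values, sigmas=np.sqrt(var), level="beam")


def predict_fraction(plan: Plan, model: DetectorModel, pen: PenumbraModel) -> SignalVector:
    """Predicted full-fraction signal: sum of beam predictions, sigmas in
    quadrature."""
    values = np.zeros(model.n_wires)
    var = np.zeros(model.n_wires)
    for beam in plan.beams:
        sv = predict_beam(beam, model, pen)
        values += sv.values
        var += sv.sigmas**2
    return SignalVector(values=values, sigmas=np.sqrt(var), level="fraction")


# ---------------------------------------------------------------------------
# SignalVector serialization: tab-separated, one row per wire (1-based).


def write_signal(
    sv: SignalVector,
    file: str | Path | IO[str],
    plan_id: str = "",
    beam_id: str = "",
) -> None:
    """Write a SignalVector as tab-separated text.

    Header line carries the aggregation level and plan/beam identifiers;
    rows are ``wire  value  sigma`` with 1-based wire indices.
    """

    def _write(fh: IO[str]) -> None:
        fh.write(f"# level={sv.level}\tplan_id={plan_id}\tbeam_id={beam_id}\n")
        fh.write("wire\tvalue\tsigma\n")
        for i, (v, s) in enumerate(zip(sv.values, sv.sigmas), start=1):
            fh.write(f"{i}\t{v:.17g}\t{s:.17g}\n")

    if hasattr(file, "write"):
        _write(file)  # type: ignore[arg-type]
    else:
        with open(file, "w") as fh:
            _write(fh)


def read_signal(file: str | Path | IO[str]) -> tuple[SignalVector, dict[str, str]]:
    """Read a SignalVector written by :func:`write_signal`.

    Returns the vector and a metadata dict (level, plan_id, beam_id).
    """
    if hasattr(file, "read"):
        lines = file.read().splitlines()  # type: ignore[union-attr]
    else:
        lines = Path(file).read_text().splitlines()
    if not lines or not lines[0].startswith("#"):
        raise StructuralError("missing signal header line")
    meta: dict[str, str] = {}
    for tok in lines[0].lstrip("#").split("\t"):
        tok = tok.strip()
        if "=" in tok:
            key, val = tok.split("=", 1)
            meta[key] = val
    values: list[float] = []
    sigmas: list[float] = []
    for line in lines[1:]:
        line = line.strip()
        if not line or line.startswith(("wire", "#")):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise StructuralError(f"malformed signal row: {line!r}")
        values.append(float(parts[1]))
        sigmas.append(float(parts[2]))
    return (
        SignalVector(
            values=np.array(values),
            sigmas=np.array(sigmas),
            level=meta.get("level", "segment"),
        ),
        meta,
    )
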