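"""Calibration of the detector model from characterization measurements.

The characterization procedure opens a single leaf pair to a series of
separations and delivers a series of MU through each one:

* the proportionality factor ``k`` comes from two stacked linear fits —
  central-wire signal vs MU per separation, then those gradients vs
  separation;
* the lateral scatter exponent comes from the neighbouring wires' signals
  normalized to the open pair's wire, averaged, and fitted log-linearly;
* the single exponent used for prediction can alternatively be tuned by
  grid search against a measured treatment (the route used for the packaged
  default);
* penumbral fractions P1..P4 come from out-of-field signals of measured
  treatments normalized to the last in-field wire.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CalibrationError, InputDomainError, StructuralError
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
    "SweepRecord",
    "CharacterizationSweep",
    "LateralProfile",
    "CHARACTERIZATION_SEPARATIONS_MM",
    "CHARACTERIZATION_MUS",
    "fit_k",
    "extract_lateral_profile",
    "fit_lateral_exponent",
    "optimize_exponent",
    "fit_penumbra_fractions",
    "read_sweep",
    "write_sweep",
]

#: Leaf-pair separations (mm at isocenter) of the standard characterization grid.
CHARACTERIZATION_SEPARATIONS_MM = (20.0, 40.0, 70.0, 100.0, 150.0, 200.0, 300.0, 350.0, 400.0)
#: Monitor units delivered through each separation.
CHARACTERIZATION_MUS = (5.0, 10.0, 25.0, 50.0, 100.0)


@dataclass
class SweepRecord:
    """One delivery: open pair (0-based offset from the central pair),
    separation (mm), MU, and the full per-wire signal vector."""

    leaf_pair: int
    separation: float
    mu: float
    signals: np.ndarray

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if np.any(self.signals < 0):
            raise InputDomainError("signals must be >= 0")


@dataclass
class CharacterizationSweep:
    records: list[SweepRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise StructuralError("sweep has no records")
        n = len(self.records[0].signals)
        if any(len(r.signals) != n for r in self.records):
            raise StructuralError("inconsistent signal lengths in sweep")

    @property
    def n_wires(self) -> int:
        return len(self.records[0].signals)


@dataclass
class LateralProfile:
    """Normalized lateral response: (distance cm, response, sigma) points."""

    distances: np.ndarray
    responses: np.ndarray
    sigmas: np.ndarray

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        if not (len(self.distances) == len(self.responses) == len(self.sigmas)):
            raise StructuralError("profile arrays must have equal length")
        if np.any(self.distances < 0):
            raise InputDomainError("distances must be >= 0")


def wire_for_pair(leaf_pair: int, n_wires: int) -> int:
    """Wire index (0-based) of a leaf pair given as offset from center."""
    wire = n_wires // 2 + leaf_pair
    if not 0 <= wire < n_wires:
        raise StructuralError(f"leaf pair offset {leaf_pair} outside detector")
    return wire


def fit_k(sweep: CharacterizationSweep) -> tuple[float, dict]:
    """Two-stage linear fit of the proportionality factor k.

    Stage 1: per (pair, separation), least-squares slope of the open pair's
    wire signal vs MU.  Stage 2: least-squares slope of those gradients vs
    separation; that slope is k.  Returns (k, diagnostics).
    """
    n = sweep.n_wires
    groups: dict[tuple[int, float], list[tuple[float, float]]] = {}
    for rec in sweep.records:
        wire = wire_for_pair(rec.leaf_pair, n)
        groups.setdefault((rec.leaf_pair, rec.separation), []).append(
            (rec.mu, rec.signals[wire])
        )
    gradients: list[tuple[float, float]] = []
    stage1_rss = 0.0
    for (pair, sep), pts in sorted(groups.items()):
        mus = np.array([p[0] for p in pts])
        sig = np.array([p[1] for p in pts])
        if len(np.unique(mus)) < 2:
            raise CalibrationError(
                f"need >=2 distinct MU values for pair {pair}, separation {sep}"
            )
        slope, intercept = np.polyfit(mus, sig, 1)
        stage1_rss += float(np.sum((sig - (slope * mus + intercept)) ** 2))
        gradients.append((sep, slope))
    seps = np.array([g[0] for g in gradients])
    grads = np.array([g[1] for g in gradients])
    if len(np.unique(seps)) < 2:
        raise CalibrationError("need >=2 distinct separations")
    k, intercept = np.polyfit(seps, grads, 1)
    if k <= 0:
        raise CalibrationError(f"degenerate sweep: fitted k = {k}")
    diagnostics = {
        "stage1_rss": stage1_rss,
        "stage2_residuals": grads - (k * seps + intercept),
        "stage2_intercept": float(intercept),
        "gradients": gradients,
    }
    return float(k), diagnostics


def extract_lateral_profile(
    sweep: CharacterizationSweep,
    n_side: int = 4,
    wire_pitch: float = 1.0,
    base_uncertainty: float = 0.01,
) -> LateralProfile:
    """Normalized lateral response from a single-open-pair sweep.

    Signals of the ``n_side`` wires on either side of the open pair's wire
    are normalized to that wire, pooled over all deliveries and over the two
    mirrored sides, and averaged.  The sigma at each distance combines the
    pooled standard deviation with the repeat-delivery standard uncertainty
    in quadrature.
    """
    pairs = {rec.leaf_pair for rec in sweep.records}
    if len(pairs) != 1:
        raise CalibrationError("profile extraction needs a single open leaf pair")
    n = sweep.n_wires
    center = wire_for_pair(pairs.pop(), n)
    pooled: dict[int, list[float]] = {d: [] for d in range(1, n_side + 1)}
    for rec in sweep.records:
        central = rec.signals[center]
        if central == 0:
            raise CalibrationError("central wire signal is zero; cannot normalize")
        for d in range(1, n_side + 1):
            for w in (center - d, center + d):
                if 0 <= w < n:
                    pooled[d].append(rec.signals[w] / central)
    distances = [0.0]
    responses = [1.0]
    sigmas = [0.0]
    for d in range(1, n_side + 1):
        vals = np.array(pooled[d])
        if len(vals) == 0:
            continue
        distances.append(d * wire_pitch)
        responses.append(float(vals.mean()))
        spread = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        sigmas.append(float(np.hypot(spread, base_uncertainty * vals.mean())))
    return LateralProfile(np.array(distances), np.array(responses), np.array(sigmas))


def fit_lateral_exponent(profile: LateralProfile) -> tuple[float, float]:
    """Log-linear least-squares fit of the lateral decay constant.

    Fits ``ln(response) = a - lambda * distance`` and returns the positive
    magnitude lambda with the standard error of the slope.
    """
    if len(profile.distances) < 3:
        raise CalibrationError("need >=3 profile points")
    if np.any(profile.responses <= 0):
        raise CalibrationError("profile responses must be > 0 for a log fit")
    d = profile.distances
    y = np.log(profile.responses)
    slope, intercept = np.polyfit(d, y, 1)
    lam = -float(slope)
    if lam <= 0:
        raise CalibrationError("fitted exponent is not a decay")
    resid = y - (slope * d + intercept)
    dof = len(d) - 2
    sxx = float(np.sum((d - d.mean()) ** 2))
    se = float(np.sqrt(np.sum(resid**2) / dof / sxx)) if dof > 0 else 0.0
    return lam, se


def optimize_exponent(
    plan: Plan,
    measured_beams: Sequence[SignalVector],
    grid: Sequence[float],
    model: DetectorModel,
    pen: PenumbraModel,
) -> float:
    """Grid search for the single prediction exponent against a measured
    treatment.

    For each candidate the plan's beams are predicted and compared to the
    measurements over the in-field wires; predicted and measured vectors are
    each normalized by their in-field sum first, so the objective depends on
    profile shape only and is invariant to a global rescaling of the
    measurement.  The candidate with the smallest summed squared relative
    deviation wins; ties go to the smaller exponent.
    """
    grid = sorted(float(g) for g in grid)
    if not grid:
        raise InputDomainError("candidate grid is empty")
    if any(g <= 0 for g in grid):
        raise InputDomainError("candidates must be > 0")
    if len(measured_beams) != len(plan.beams):
        raise StructuralError("one measured vector per beam required")
    best_lam = None
    best_obj = np.inf
    for lam in grid:
        candidate = model.with_(lateral_exponent=lam)
        obj = 0.0
        for beam, meas in zip(plan.beams, measured_beams):
            mask = beam_in_field_mask(beam, candidate)
            if not mask.any():
                continue
            p = predict_beam(beam, candidate, pen).values[mask]
            m = meas.values[mask]
            p_hat = p / p.sum()
            m_hat = m / m.sum()
            obj += float(np.sum(((m_hat - p_hat) / p_hat) ** 2))
        if obj < best_obj:
            best_obj = obj
            best_lam = lam
    return float(best_lam)


def fit_penumbra_fractions(
    plans: Sequence[Plan],
    measurements: Sequence[Sequence[SignalVector]],
    model: DetectorModel,
) -> PenumbraModel:
    """Fit P1..P4 from measured out-of-field signals.

    For each beam, out-of-field wires within four wires of a single field
    edge are normalized to the measured signal of that edge wire; ratios are
    pooled per position over all edges, beams and plans.  Returns the means
    (forced non-increasing by a running minimum) with relative standard
    deviations.  Wires claimed by two field edges are skipped as ambiguous.
    """
    pooled: dict[int, list[float]] = {r: [] for r in range(1, 5)}
    for plan, beam_meas in zip(plans, measurements):
        for beam, meas in zip(plan.beams, beam_meas):
            mask = beam_in_field_mask(beam, model)
            for wire, candidates in penumbra_assignments(mask).items():
                if len(candidates) != 1:
                    continue
                edge, rank = candidates[0]
                if meas.values[edge] > 0:
                    pooled[rank].append(meas.values[wire] / meas.values[edge])
    if all(len(v) == 0 for v in pooled.values()):
        raise CalibrationError("no out-of-field observations")
    means = []
    sds = []
    for rank in range(1, 5):
        vals = np.array(pooled[rank])
        if len(vals) == 0:
            raise CalibrationError(f"no observations for penumbral position {rank}")
        means.append(float(vals.mean()))
        if len(vals) > 1:
            sds.append(float(vals.std(ddof=1)))
        else:
            warnings.warn(
                f"single observation at penumbral position {rank}; sigma set to 0",
                stacklevel=2,
            )
            sds.append(0.0)
    means_arr = np.minimum.accumulate(np.clip(np.array(means), 0.0, 1.0))
    rel = np.array(
        [sd / m if m > 0 else 0.0 for sd, m in zip(sds, means_arr)]
    )
    return PenumbraModel(fractions=tuple(means_arr), sigmas=tuple(rel))


# ---------------------------------------------------------------------------
# Sweep file I/O: tab-separated, columns leaf_pair, separation_mm, mu,
# wire_1..wire_n, one delivery per row.


def write_sweep(sweep: CharacterizationSweep, path: str | Path) -> None:
    n = sweep.n_wires
    rows = [
        {
            "leaf_pair": rec.leaf_pair,
            "separation_mm": rec.separation,
            "mu": rec.mu,
            **{f"wire_{i + 1}": rec.signals[i] for i in range(n)},
        }
        for rec in sweep.records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sweep(path: str | Path) -> CharacterizationSweep:
    df = pd.read_csv(path, sep="\t")
    required = {"leaf_pair", "separation_mm", "mu"}
    if not required.issubset(df.columns):
        raise CalibrationError(f"sweep file missing columns {sorted(required - set(df.columns))}")
    wire_cols = sorted(
        (c for c in df.columns if c.startswith("wire_")),
        key=lambda c: int(c.split("_")[1]),
    )
    if not wire_cols:
        raise CalibrationError("sweep file has no wire_* columns")
    records = [
        SweepRecord(
            leaf_pair=int(row["leaf_pair"]),
            separation=float(row["separation_mm"]),
            mu=float(row["mu"]),
            signals=row[wire_cols].to_numpy(dtype=float),
        )
        for _, row in df.iterrows()
    ]
    return CharacterizationSweep(records)
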