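"""Trial containers, raw-sensor CoP computation, CSV I/O and scenario cuts.

Center-of-pressure recordings live in the insole's normalized coordinate
system: the medio-lateral (ML) axis spans -0.5 to +0.5 and the
anterior-posterior (AP) axis approximately -0.574 to +0.426, identically
for both feet.  The insole firmware exports CoP directly; the weighted
ground-reaction-force average over the 16 pressure sensors is
implemented here as well so raw-sensor inputs remain supported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ML_BOUNDS",
    "AP_BOUNDS",
    "N_SENSORS",
    "SENSOR_LAYOUT",
    "PHASES",
    "WALK_PHASES",
    "CoPTrajectory",
    "SensorFrame",
    "SimulatedTrial",
    "TrialFormatError",
    "compute_cop",
    "compute_cop_series",
    "write_trial",
    "read_trial",
    "extract_scenario",
]

ML_BOUNDS = (-0.5, 0.5)
AP_BOUNDS = (-0.574, 0.426)
_BOUND_TOL = 1e-9

N_SENSORS = 16

#: Fixed per-foot sensor coordinates (ML, AP) in normalized units,
#: anatomically ordered: 4 heel, 4 midfoot, 5 metatarsal, 3 toe sensors.
SENSOR_LAYOUT = np.array(
    [
        (-0.20, -0.50), (0.12, -0.50), (-0.24, -0.38), (0.16, -0.38),   # heel
        (-0.28, -0.22), (0.20, -0.22), (-0.30, -0.06), (0.22, -0.06),   # midfoot
        (-0.34, 0.10), (-0.16, 0.14), (0.02, 0.16), (0.18, 0.14), (0.32, 0.10),  # metatarsal
        (-0.24, 0.32), (0.00, 0.38), (0.22, 0.32),                      # toes
    ]
)

#: TUG phases in temporal order.
PHASES = ("sit_to_stand", "walk_out", "turn", "walk_back", "turn_to_sit")
WALK_PHASES = ("walk_out", "walk_back")

_SCENARIOS = ("full_tug", "walking")


class TrialFormatError(ValueError):
    """Raised when a trial file violates the CSV dialect or invariants."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


@dataclass
class CoPTrajectory:
    """One foot's CoP path sampled uniformly at ``fs`` Hz.

    Timestamps are implicit (``arange(n) / fs``), which guarantees the
    uniform-spacing invariant.  ``breaks`` marks sample indices that
    start a new contiguous segment (e.g. the walk-out / walk-back
    junction of the walking scenario); velocity-type features exclude
    differences that bridge a break.
    """

    ml: np.ndarray
    ap: np.ndarray
    fs: float
    phase_labels: np.ndarray | None = None
    breaks: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.ml = _as_float_array(self.ml, "ml")
        self.ap = _as_float_array(self.ap, "ap")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.ml.shape != self.ap.shape:
            raise ValueError("ml and ap must have equal length")
        finite_ml = self.ml[np.isfinite(self.ml)]
        finite_ap = self.ap[np.isfinite(self.ap)]
        if finite_ml.size and (
            finite_ml.min() < ML_BOUNDS[0] - _BOUND_TOL
            or finite_ml.max() > ML_BOUNDS[1] + _BOUND_TOL
        ):
            raise ValueError(f"ml samples outside normalized bounds {ML_BOUNDS}")
        if finite_ap.size and (
            finite_ap.min() < AP_BOUNDS[0] - _BOUND_TOL
            or finite_ap.max() > AP_BOUNDS[1] + _BOUND_TOL
        ):
            raise ValueError(f"ap samples outside normalized bounds {AP_BOUNDS}")
        if self.phase_labels is not None:
            self.phase_labels = np.asarray(self.phase_labels, dtype=object)
            if self.phase_labels.shape != self.ml.shape:
                raise ValueError("phase_labels must match sample count")
        self.breaks = np.asarray(self.breaks, dtype=int)

    def __len__(self) -> int:
        return self.ml.size

    @property
    def n_samples(self) -> int:
        return self.ml.size

    @property
    def duration(self) -> float:
        return self.ml.size / self.fs

    @property
    def timestamps(self) -> np.ndarray:
        return np.arange(self.ml.size) / self.fs

    def xy(self) -> np.ndarray:
        """Samples as an (n, 2) array of (ml, ap)."""
        return np.column_stack([self.ml, self.ap])


@dataclass
class SensorFrame:
    """One time sample of the 16 per-foot pressure-sensor forces."""

    forces: np.ndarray
    coords: np.ndarray = field(default_factory=lambda: SENSOR_LAYOUT.copy())

    def __post_init__(self) -> None:
        self.forces = _as_float_array(self.forces, "forces")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.forces.size != N_SENSORS:
            raise ValueError(f"expected {N_SENSORS} sensor forces, got {self.forces.size}")
        if self.coords.shape != (N_SENSORS, 2):
            raise ValueError("coords must be (16, 2)")
        if np.any(self.forces < 0):
            raise ValueError("sensor forces must be non-negative")

    @property
    def in_contact(self) -> bool:
        return bool(self.forces.sum() > 0)


@dataclass
class SimulatedTrial:
    """A two-foot TUG recording with group label and phase annotations."""

    left: CoPTrajectory
    right: CoPTrajectory
    group_label: str
    participant_id: str
    phase_annotations: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.group_label not in ("PD", "Control"):
            raise ValueError(f"group_label must be 'PD' or 'Control', got {self.group_label!r}")
        if len(self.left) != len(self.right):
            raise ValueError("left and right trajectories must share length")
        if self.left.fs != self.right.fs:
            raise ValueError("left and right trajectories must share sampling rate")
        if self.phase_annotations is None and self.left.phase_labels is not None:
            self.phase_annotations = self.left.phase_labels
        if self.phase_annotations is not None:
            self.phase_annotations = np.asarray(self.phase_annotations, dtype=object)
            if self.phase_annotations.shape != (len(self.left),):
                raise ValueError("phase_annotations must match sample count")

    @property
    def fs(self) -> float:
        return self.left.fs

    def foot(self, side: str) -> CoPTrajectory:
        if side == "left":
            return self.left
        if side == "right":
            return self.right
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")


def compute_cop(frame: SensorFrame) -> tuple[float, float]:
    """CoP as the force-weighted mean sensor position.

    ``cop_x = sum(d_xi * F_i) / sum(F_i)`` and analogously for the AP
    axis.  An all-zero force frame is a swing-phase (no-contact) sample:
    it yields ``(nan, nan)`` rather than raising, so a trial-long
    sequence can be processed without interruption.
    """
    total = frame.forces.sum()
    if total <= 0:
        return (float("nan"), float("nan"))
    cop = frame.coords.T @ frame.forces / total
    return (float(cop[0]), float(cop[1]))


def compute_cop_series(
    forces: np.ndarray, coords: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized CoP over an (n, 16) force matrix.

    Returns ``(ml, ap, contact)`` where no-contact rows are NaN with
    ``contact`` False.
    """
    forces = np.asarray(forces, dtype=float)
    if forces.ndim != 2 or forces.shape[1] != N_SENSORS:
        raise ValueError(f"forces must be (n, {N_SENSORS})")
    if np.any(forces < 0):
        raise ValueError("sensor forces must be non-negative")
    if coords is None:
        coords = SENSOR_LAYOUT
    totals = forces.sum(axis=1)
    contact = totals > 0
    ml = np.full(forces.shape[0], np.nan)
    ap = np.full(forces.shape[0], np.nan)
    ml[contact] = forces[contact] @ coords[:, 0] / totals[contact]
    ap[contact] = forces[contact] @ coords[:, 1] / totals[contact]
    return ml, ap, contact


# ---------------------------------------------------------------------------
# CSV trial dialect

_MANDATORY_COLUMNS = ("time", "ml_left", "ap_left", "ml_right", "ap_right")
_TIME_TOL = 1e-6


def _force_columns() -> list[str]:
    return [f"f_{side}_{i:02d}" for side in ("left", "right") for i in range(1, N_SENSORS + 1)]


def write_trial(trial: SimulatedTrial, path, forces: dict[str, np.ndarray] | None = None) -> None:
    """Write a trial in the package CSV dialect (UTF-8, one row per sample).

    ``forces`` may map ``'left'``/``'right'`` to (n, 16) raw force
    matrices, stored in 32 extra columns.
    """
    n = len(trial.left)
    data: dict[str, np.ndarray] = {
        "time": np.arange(n) / trial.fs,
        "ml_left": trial.left.ml,
        "ap_left": trial.left.ap,
        "ml_right": trial.right.ml,
        "ap_right": trial.right.ap,
    }
    if trial.phase_annotations is not None:
        data["phase"] = trial.phase_annotations
    if forces is not None:
        for side in ("left", "right"):
            mat = np.asarray(forces[side], dtype=float)
            if mat.shape != (n, N_SENSORS):
                raise ValueError(f"{side} force matrix must be ({n}, {N_SENSORS})")
            for i in range(N_SENSORS):
                data[f"f_{side}_{i + 1:02d}"] = mat[:, i]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def read_trial(
    path,
    participant_id: str = "unknown",
    group_label: str = "Control",
    recompute_cop: bool = False,
) -> SimulatedTrial:
    """Read a trial CSV; validates schema, bounds and timestamp spacing.

    CoP columns take precedence over raw sensor columns when both are
    present; ``recompute_cop=True`` forces recomputation from the 32
    force columns via the weighted-average formula.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (ValueError, OSError) as exc:
        raise TrialFormatError(f"cannot parse trial file {path}: {exc}") from exc
    missing = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    have_forces = all(c in df.columns for c in _force_columns())
    if missing and not (have_forces and set(missing) <= {"ml_left", "ap_left", "ml_right", "ap_right"}):
        raise TrialFormatError(f"trial file {path} missing mandatory columns: {missing}")

    time = df["time"].to_numpy(dtype=float)
    if time.size >= 2:
        steps = np.diff(time)
        if np.any(steps <= 0):
            row = int(np.argmax(steps <= 0)) + 2  # +1 diff offset, +1 header line

            raise TrialFormatError(f"non-increasing timestamps at line {row} in {path}")
        if np.ptp(steps) > _TIME_TOL:
            row = int(np.argmax(np.abs(steps - steps[0]) > _TIME_TOL)) + 2
            raise TrialFormatError(f"non-uniform timestamps at line {row} in {path}")
        fs = 1.0 / steps.mean()
    else:
        fs = 100.0

    cop: dict[str, np.ndarray] = {}
    if recompute_cop or missing:
        if not have_forces:
            raise TrialFormatError(f"{path}: CoP recomputation requested but force columns absent")
        for side in ("left", "right"):
            cols = [f"f_{side}_{i:02d}" for i in range(1, N_SENSORS + 1)]
            ml, ap, _ = compute_cop_series(df[cols].to_numpy(dtype=float))
            cop[f"ml_{side}"], cop[f"ap_{side}"] = ml, ap
    else:
        for col in ("ml_left", "ap_left", "ml_right", "ap_right"):
            values = df[col].to_numpy(dtype=float)
            lo, hi = ML_BOUNDS if col.startswith("ml") else AP_BOUNDS
            # NaN marks a no-contact sample and is retained; infinities
            # and out-of-range values are file defects
            bad = ~np.isnan(values) & ((values < lo - _BOUND_TOL) | (values > hi + _BOUND_TOL))
            if bad.any():
                row = int(np.argmax(bad)) + 2
                raise TrialFormatError(
                    f"{path}: column {col!r} out of normalized bounds "
                    f"[{lo}, {hi}] at line {row} (value {values[bad][0]:g})"
                )
            cop[col] = values

    phases = df["phase"].to_numpy(dtype=object) if "phase" in df.columns else None
    left = CoPTrajectory(cop["ml_left"], cop["ap_left"], fs, phase_labels=phases)
    right = CoPTrajectory(cop["ml_right"], cop["ap_right"], fs, phase_labels=phases)
    return SimulatedTrial(left, right, group_label, participant_id, phases)


def extract_scenario(trial: SimulatedTrial, scenario: str) -> tuple[CoPTrajectory, CoPTrajectory]:
    """Cut a trial into a scenario: the full TUG or the 3 m walking segment.

    ``full_tug`` returns both whole trajectories.  ``walking``
    concatenates the walk-out and walk-back samples in time order,
    marking the junction as a segment break so that velocity features
    exclude the single bridging difference.
    """
    if scenario not in _SCENARIOS:
        raise ValueError(f"scenario must be one of {_SCENARIOS}, got {scenario!r}")
    if scenario == "full_tug":
        return trial.left, trial.right
    if trial.phase_annotations is None:
        raise ValueError("walking scenario requires per-sample phase annotations")
    phases = trial.phase_annotations
    masks = [phases == p for p in WALK_PHASES]
    idx = np.concatenate([np.flatnonzero(m) for m in masks])
    if idx.size == 0:
        raise ValueError("trial has no walking-phase samples")
    breaks = np.array([int(masks[0].sum())]) if masks[0].any() and masks[1].any() else np.empty(0, int)

    def cut(traj: CoPTrajectory) -> CoPTrajectory:
        return CoPTrajectory(
            traj.ml[idx], traj.ap[idx], traj.fs,
            phase_labels=phases[idx], breaks=breaks,
        )

    return cut(trial.left), cut(trial.right)
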