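"""Synthetic two-foot TUG CoP recordings with controllable group effects.

No generative model exists for real insole CoP during the Timed Up and
Go, so trials are composed from three ingredients per foot and axis:

* a deterministic phase template — quasi-static anterior shift during
  sit-to-stand, anti-phase heel-to-toe stepping oscillation during the
  two walks, a lateral excursion during the turn, and a posterior ramp
  back while sitting down;
* a band-limited oscillatory sway component (one tone below 0.5 Hz, one
  in the 0.5–2 Hz band) with random phases;
* a first-order autoregressive stochastic component whose innovation
  variance sets the trajectory's "complexity".

Group contrasts enter only through multipliers on these parts
(:class:`EffectProfile`): overall sway magnitude, a lateralized per-foot
asymmetry gain, a shift of oscillatory power below 0.5 Hz, and a
reduction of the autoregressive innovation variance.  With all effects
neutral, PD and Control trials are drawn from the same law — the basis
of the pipeline's null-calibration checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.spatial import Delaunay

from .sensor_io import (
    AP_BOUNDS,
    ML_BOUNDS,
    N_SENSORS,
    PHASES,
    SENSOR_LAYOUT,
    CoPTrajectory,
    SimulatedTrial,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EffectProfile",
    "SimulationConfig",
    "DEFAULT_PHASE_DURATIONS",
    "simulate_trial",
    "simulate_cohort",
    "distribute_forces",
]

#: Default per-phase durations in seconds; the 15 s total keeps the
#: diffusion and spectral fits well-posed.
DEFAULT_PHASE_DURATIONS: dict[str, float] = {
    "sit_to_stand": 2.0,
    "walk_out": 4.0,
    "turn": 2.0,
    "walk_back": 4.0,
    "turn_to_sit": 3.0,
}

_GROUPS = ("PD", "Control")

# baseline sway magnitudes (normalized units), shared by both groups
_A_LOW = 0.012       # < 0.5 Hz tone amplitude
_A_MID = 0.020       # 0.5–2 Hz tone amplitude
_F_LOW = 0.3         # Hz
_F_MID = 1.3         # Hz
_AR_PHI = 0.97       # AR(1) pole
_AR_SIGMA = 0.004    # AR(1) innovation standard deviation
_PARTICIPANT_SD = 0.15   # log-normal between-participant sway variability
_FOOT_JITTER_SD = 0.05   # log-normal per-foot amplitude jitter (baseline asymmetry)


@dataclass(frozen=True)
class EffectProfile:
    """Multiplicative group contrasts applied to PD trials.

    ``sway_amplitude_ratio`` scales both sway components of both feet;
    ``asymmetry_gain`` additionally scales one randomly lateralized
    foot; ``lowfreq_power_shift`` moves that fraction of the mid-band
    oscillatory power below 0.5 Hz; ``complexity_reduction`` shrinks
    the autoregressive innovation variance (more regular, less complex
    sway).  All neutral values leave PD and Control identically
    distributed.
    """

    sway_amplitude_ratio: float = 1.3
    asymmetry_gain: float = 1.4
    lowfreq_power_shift: float = 0.3
    complexity_reduction: float = 0.3

    def __post_init__(self) -> None:
        if self.sway_amplitude_ratio <= 0 or self.asymmetry_gain <= 0:
            raise ValueError("effect ratios must be positive")
        if not 0.0 <= self.lowfreq_power_shift <= 1.0:
            raise ValueError("lowfreq_power_shift must lie in [0, 1]")
        if not 0.0 <= self.complexity_reduction < 1.0:
            raise ValueError("complexity_reduction must lie in [0, 1)")

    @classmethod
    def zero(cls) -> "EffectProfile":
        """All effects neutral: PD and Control share one distribution."""
        return cls(1.0, 1.0, 0.0, 0.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation settings."""

    n_pd: int = 39
    n_control: int = 38
    sampling_rate: float = 100.0
    phase_durations: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHASE_DURATIONS)
    )
    effect: EffectProfile = field(default_factory=EffectProfile)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pd < 0 or self.n_control < 0:
            raise ValueError("participant counts must be non-negative")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if set(self.phase_durations) != set(PHASES):
            raise ValueError(f"phase_durations must define exactly the phases {PHASES}")
        if any(d <= 0 for d in self.phase_durations.values()):
            raise ValueError("all phase durations must be positive")


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _phase_template(
    config: SimulationConfig, turn_direction: float, foot_phase: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic (ml, ap) template and per-sample phase labels."""
    fs = config.sampling_rate
    ml_parts, ap_parts, labels = [], [], []
    for phase in PHASES:
        dur = config.phase_durations[phase]
        n = max(int(round(dur * fs)), 1)
        tau = np.arange(n) / fs
        if phase == "sit_to_stand":
            ap = -0.40 + 0.35 * _smoothstep(tau / dur)
            ml = np.zeros(n)
        elif phase in ("walk_out", "walk_back"):
            # integer number of step cycles keeps the template continuous
            f_step = max(1.0, round(0.9 * dur)) / dur
            ap = -0.05 + 0.25 * np.sin(2 * np.pi * f_step * tau + foot_phase)
            ml = 0.04 * np.sin(2 * np.pi * f_step * tau + foot_phase)
        elif phase == "turn":
            ap = np.full(n, -0.05)
            ml = turn_direction * 0.12 * np.sin(np.pi * tau / dur)
        else:  # turn_to_sit
            ap = -0.05 - 0.35 * _smoothstep(tau / dur)
            ml = np.zeros(n)
        ml_parts.append(ml)
        ap_parts.append(ap)
        labels.extend([phase] * n)
    return (
        np.concatenate(ml_parts),
        np.concatenate(ap_parts),
        np.asarray(labels, dtype=object),
    )


def _sway_components(
    rng: np.random.Generator,
    n: int,
    fs: float,
    a_low: float,
    a_mid: float,
    ar_sigma: float,
) -> np.ndarray:
    """Oscillatory tones plus an AR(1) process for one axis."""
    t = np.arange(n) / fs
    phase_low, phase_mid = rng.uniform(0, 2 * np.pi, size=2)
    tones = a_low * np.sin(2 * np.pi * _F_LOW * t + phase_low)
    tones += a_mid * np.sin(2 * np.pi * _F_MID * t + phase_mid)
    innovations = rng.normal(0.0, ar_sigma, size=n)
    ar = lfilter([1.0], [1.0, -_AR_PHI], innovations)
    return tones + ar


def simulate_trial(
    config: SimulationConfig, group: str, participant_seed: int
) -> SimulatedTrial:
    """Generate one two-foot TUG trial.

    Identical ``(config, group, participant_seed)`` inputs reproduce the
    trial bit for bit.  PD trials realize the configured
    :class:`EffectProfile`; Control trials always use neutral effects.
    """
    if group not in _GROUPS:
        raise ValueError(f"group must be one of {_GROUPS}, got {group!r}")
    rng = np.random.default_rng([config.seed, _GROUPS.index(group), participant_seed])

    effect = config.effect if group == "PD" else EffectProfile.zero()
    fs = config.sampling_rate

    # participant-level draws (same draw order for both groups)
    turn_direction = 1.0 if rng.random() < 0.5 else -1.0
    lateral_side = "left" if rng.random() < 0.5 else "right"
    participant_scale = float(np.exp(rng.normal(0.0, _PARTICIPANT_SD)))

    # oscillatory power shift below 0.5 Hz (power = amplitude^2 / 2)
    shift = effect.lowfreq_power_shift
    a_low = np.sqrt(_A_LOW**2 + shift * _A_MID**2)
    a_mid = _A_MID * np.sqrt(1.0 - shift)
    ar_sigma = _AR_SIGMA * (1.0 - effect.complexity_reduction)

    feet: dict[str, CoPTrajectory] = {}
    labels = None
    for side, foot_phase in (("left", 0.0), ("right", np.pi)):
        ml_t, ap_t, labels = _phase_template(config, turn_direction, foot_phase)
        n = ml_t.size
        foot_jitter = float(np.exp(rng.normal(0.0, _FOOT_JITTER_SD)))
        gain = participant_scale * foot_jitter * effect.sway_amplitude_ratio
        if side == lateral_side:
            gain *= effect.asymmetry_gain
        ml = ml_t + gain * _sway_components(rng, n, fs, a_low, a_mid, ar_sigma)
        ap = ap_t + gain * _sway_components(rng, n, fs, a_low, a_mid, ar_sigma)
        feet[side] = CoPTrajectory(
            np.clip(ml, *ML_BOUNDS),
            np.clip(ap, *AP_BOUNDS),
            fs,
            phase_labels=labels,
        )

    return SimulatedTrial(
        left=feet["left"],
        right=feet["right"],
        group_label=group,
        participant_id=f"P{participant_seed:04d}",
        phase_annotations=labels,
    )


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[SimulatedTrial], pd.DataFrame]:
    """Generate ``n_pd + n_control`` single-trial participants.

    Returns the trials plus a metadata table (participant_id, group,
    seed).  Deterministic under ``config.seed``.
    """
    if config.n_pd + config.n_control == 0:
        logger.warning("simulate_cohort called with a zero-participant cohort")
    trials: list[SimulatedTrial] = []
    records = []
    index = 0
    for group, count in (("PD", config.n_pd), ("Control", config.n_control)):
        for _ in range(count):
            trial = simulate_trial(config, group, participant_seed=index)
            trials.append(trial)
            records.append(
                {"participant_id": trial.participant_id, "group": group, "seed": index}
            )
            index += 1
    metadata = pd.DataFrame(records, columns=["participant_id", "group", "seed"])
    return trials, metadata


# ---------------------------------------------------------------------------
# CoP-consistent force distribution (testing aid for the raw-sensor path)

_DELAUNAY = Delaunay(SENSOR_LAYOUT)


def distribute_forces(
    ml: np.ndarray, ap: np.ndarray, total_force: float = 700.0
) -> np.ndarray:
    """Distribute forces over the 16 sensors so the weighted mean equals
    the target CoP exactly.

    Each sample's load goes to the vertices of the Delaunay triangle of
    the sensor layout containing the point, with barycentric weights.
    Raises for points outside the sensors' convex hull.
    """
    ml = np.atleast_1d(np.asarray(ml, dtype=float))
    ap = np.atleast_1d(np.asarray(ap, dtype=float))
    points = np.column_stack([ml, ap])
    simplices = _DELAUNAY.find_simplex(points)
    if np.any(simplices < 0):
        bad = int(np.argmax(simplices < 0))
        raise ValueError(
            f"CoP sample ({ml[bad]:.3f}, {ap[bad]:.3f}) lies outside the sensor hull"
        )
    transform = _DELAUNAY.transform[simplices]
    bary2 = np.einsum("nij,nj->ni", transform[:, :2, :], points - transform[:, 2, :])
    bary = np.concatenate([bary2, 1.0 - bary2.sum(axis=1, keepdims=True)], axis=1)
    bary = np.clip(bary, 0.0, None)
    forces = np.zeros((points.shape[0], N_SENSORS))
    vertices = _DELAUNAY.simplices[simplices]
    rows = np.repeat(np.arange(points.shape[0]), 3)
    forces[rows, vertices.ravel()] = total_force * bary.ravel()
    return forces
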