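"""Synthetic sessions, trial kinematics, motion series, and ROI BOLD.

Every downstream stage of the pipeline is testable without recordings:
this module generates (a) balanced block-design session ledgers with
jittered inter-trial intervals, (b) 60 Hz six-marker reach-to-grasp
trials with known phase boundaries, aperture minima, marker dropout and
band-limited positional noise, (c) per-TR head rigid-motion parameters
weakly coupled to arm motion, and (d) HRF-convolved ROI BOLD series
with known condition, modulator and motion effects plus AR(1) noise.

Conventions: positions in mm (RAS axes), angles in radians, time in
seconds, frame rate 60 Hz, TR 0.8 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as ssignal

from . import glm as _glm

__all__ = [
    "MARKERS",
    "CONDITIONS",
    "MOVEMENT_CONDITIONS",
    "SessionSpec",
    "TrialGroundTruth",
    "MotionGenParams",
    "BoldGenParams",
    "ErrorRates",
    "TrialKinematics",
    "build_session",
    "sample_ground_truth",
    "simulate_trial",
    "simulate_motion_series",
    "simulate_bold",
    "simulate_factor_table",
    "inject_annotations",
]

#: tracked segments, matching the recorded marker layout
MARKERS = ("elbow", "forearm", "wrist", "hand", "index_tip", "thumb_tip")

CONDITIONS = ("MoveVisible", "MoveInvisible", "NoMovement")
MOVEMENT_CONDITIONS = ("MoveVisible", "MoveInvisible")
GRIP_TYPES = ("precision", "power")


class ConfigurationError(ValueError):
    """Raised for invalid session or generator specifications."""


class GenerationError(ValueError):
    """Raised when a trial cannot be generated as specified."""


@dataclass(frozen=True)
class SessionSpec:
    """Block-design session layout.

    Defaults reproduce the reference design: 7 participants, 4 runs of
    15 blocks (5 per condition), 3 trials per block, TR 0.8 s, 60 Hz
    kinematics.  The inter-trial interval (target offset to next onset)
    follows a truncated exponential on [2.5, 10.5] s with mean 4.5 s;
    measured onset-to-onset this is the equivalent 5-13 s (mean 7 s)
    interval, since targets stay on for 2.5 s.  Set
    ``iti_onset_to_onset=True`` to parameterize onset-to-onset instead.
    """

    participants: int = 7
    runs_per_participant: int = 4
    blocks_per_run: int = 15
    trials_per_block: int = 3
    conditions: tuple[str, ...] = CONDITIONS
    tr_s: float = 0.8
    frame_rate_hz: float = 60.0
    iti_min_s: float = 2.5
    iti_max_s: float = 10.5
    iti_mean_s: float = 4.5
    iti_onset_to_onset: bool = False
    target_duration_s: float = 2.5
    instruction_duration_s: float = 0.6
    instruction_gap_s: float = 0.4

    def validate(self) -> None:
        if self.participants < 1 or self.runs_per_participant < 1:
            raise ConfigurationError("need at least one participant and run")
        if self.trials_per_block < 1:
            raise ConfigurationError("trials_per_block must be >= 1")
        if self.blocks_per_run % len(self.conditions) != 0:
            raise ConfigurationError(
                "blocks_per_run must be divisible by the number of conditions"
            )
        if self.tr_s <= 0 or self.frame_rate_hz <= 0:
            raise ConfigurationError("tr_s and frame_rate_hz must be positive")
        if not self.iti_min_s <= self.iti_mean_s <= self.iti_max_s:
            raise ConfigurationError("ITI must satisfy min <= mean <= max")

    @property
    def trials_per_participant(self) -> int:
        return self.runs_per_participant * self.blocks_per_run * self.trials_per_block

    @property
    def total_trials(self) -> int:
        return self.participants * self.trials_per_participant


@dataclass
class TrialGroundTruth:
    """Generative parameters (and exact outcomes) of one movement trial.

    Durations parameterize the still-move-still-move-still phase
    structure; aperture minima depend on the grip type (precision grips
    close on a narrow object section, leaving wider finger apertures
    than the whole-hand power grip closure).  ``phase_boundary_frames``
    and ``peak_wrist_speed_mm_s`` are filled in exactly by
    :func:`simulate_trial`.
    """

    grip_type: str = "power"
    reaction_latency_s: float = 0.624
    reaching_duration_s: float = 0.789
    grip_duration_s: float = 1.132
    back_duration_s: float = 1.040
    min_grip_aperture_mm: float = 45.0
    min_hand_aperture_mm: float = 122.0
    open_grip_aperture_mm: float = 115.0
    grip_squeeze_mm: float = 6.0
    reach_distance_mm: float = 300.0
    reach_curvature_height_mm: float = 20.0
    back_curvature_height_mm: float = 40.0
    peak_wrist_speed_mm_s: float = 0.0
    phase_boundary_frames: tuple[int, int, int, int] | None = None

    def validate(self) -> None:
        if self.grip_type not in GRIP_TYPES:
            raise ConfigurationError(f"unknown grip type: {self.grip_type}")
        for name in ("reaction_latency_s", "reaching_duration_s",
                     "grip_duration_s", "back_duration_s"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.min_hand_aperture_mm <= self.min_grip_aperture_mm / 2:
            raise ConfigurationError("hand aperture too small for grip aperture")
        if self.phase_boundary_frames is not None:
            b = self.phase_boundary_frames
            if not all(b[i] < b[i + 1] for i in range(3)):
                raise ConfigurationError("phase boundaries must strictly increase")

    def boundaries(self, frame_rate_hz: float) -> tuple[int, int, int, int]:
        """Phase-boundary frames implied by latency and durations."""
        b0 = int(round(self.reaction_latency_s * frame_rate_hz))
        b1 = b0 + max(2, int(round(self.reaching_duration_s * frame_rate_hz)))
        b2 = b1 + max(2, int(round(self.grip_duration_s * frame_rate_hz)))
        b3 = b2 + max(2, int(round(self.back_duration_s * frame_rate_hz)))
        return b0, b1, b2, b3


@dataclass(frozen=True)
class MotionGenParams:
    """Head-motion generator settings.

    ``head_amplitude_mm`` scales the head FD distribution (the default
    puts its mean near 0.1 mm, typical of cushioned task fMRI);
    ``arm_head_coupling`` is the target correlation between head FD and
    arm FD within movement blocks, reflecting the mild mechanical drive
    of arm movements on the head.
    """

    head_amplitude_mm: float = 0.045
    head_rot_amplitude_rad: float = 0.0004
    arm_head_coupling: float = 0.23
    arm_fd_move_mm: float = 20.0
    hand_fd_scale: float = 0.55
    noise_sd_mm: float = 0.02
    dropout_prob_per_frame: float = 0.0

    def validate(self) -> None:
        if not -1.0 <= self.arm_head_coupling <= 1.0:
            raise ConfigurationError("coupling must lie in [-1, 1]")
        if self.head_amplitude_mm < 0 or self.head_rot_amplitude_rad < 0:
            raise ConfigurationError("amplitudes must be >= 0")
        if not 0.0 <= self.dropout_prob_per_frame < 1.0:
            raise ConfigurationError("dropout probability must lie in [0, 1)")


@dataclass(frozen=True)
class BoldGenParams:
    """Ground-truth effects for the ROI BOLD generator."""

    baseline: float = 100.0
    condition_betas: dict = field(
        default_factory=lambda: {
            "MoveVisible": 2.0, "MoveInvisible": 2.0, "NoMovement": 0.5
        }
    )
    modulator_betas: dict = field(default_factory=dict)
    motion_beta: float = 0.0
    ar1_coefficient: float = 0.35
    noise_sd: float = 1.0

    def validate(self) -> None:
        if not abs(self.ar1_coefficient) < 1:
            raise ConfigurationError("AR(1) coefficient magnitude must be < 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


@dataclass(frozen=True)
class ErrorRates:
    """Per-trial injection rates for the error-ledger categories.

    Defaults follow the observed frequencies in a 1260-trial session set
    (7 tracking losses, 43 feedback bugs, 9 unexpected movements, 17
    movements during no-movement trials).  Feedback bugs and unexpected
    movements are annotation-style flags (they emulate visual
    inspection); tracking loss and no-movement violations alter the
    generated kinematics and are detected computationally downstream.
    """

    tracking_loss: float = 7 / 1260
    feedback_bug: float = 43 / 1260
    unexpected_movement: float = 9 / 1260
    moved_in_no_movement: float = 17 / 1260


# ---------------------------------------------------------------------------
# session ledger


def _truncated_exp_scale(low: float, high: float, mean: float) -> float:
    """Scale of the shifted exponential truncated to [low, high] whose
    truncated mean equals ``mean``."""
    from scipy.optimize import brentq

    span = high - low
    target = mean - low
    if target <= 0:
        return 1e-9

    def truncated_mean(s: float) -> float:
        q = np.exp(-span / s)
        return s - span * q / (1.0 - q)

    # truncated mean is increasing in s and bounded above by span / 2
    if target >= span / 2:
        return 1e6
    return brentq(lambda s: truncated_mean(s) - target, 1e-6, 1e4)


def _sample_jitter(rng: np.random.Generator, spec: SessionSpec, n: int) -> np.ndarray:
    """Rejection-sample ITIs from the truncated exponential."""
    scale = _truncated_exp_scale(spec.iti_min_s, spec.iti_max_s, spec.iti_mean_s)
    span = spec.iti_max_s - spec.iti_min_s
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.exponential(scale, size=2 * (n - filled) + 8)
        draw = draw[draw <= span][: n - filled]
        out[filled : filled + len(draw)] = draw
        filled += len(draw)
    return spec.iti_min_s + out


def _counterbalanced_grips(rng: np.random.Generator, n: int) -> list[str]:
    half = n // 2
    grips = ["precision"] * half + ["power"] * (n - half)
    rng.shuffle(grips)
    return grips


def build_session(spec: SessionSpec, seed: int = 0) -> pd.DataFrame:
    """Build the ordered trial ledger for a full session set.

    Returns one row per trial with columns ``participant, run, block,
    trial, trial_type, onset, duration, grip_type``.  Conditions are
    balanced within each run (block order permuted), onsets increase
    strictly within a run, inter-trial jitters follow the truncated
    exponential, and grip types are counterbalanced within each
    participant x condition cell.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    blocks_per_cond = spec.blocks_per_run // len(spec.conditions)
    rows = []
    for part in range(1, spec.participants + 1):
        for run in range(1, spec.runs_per_participant + 1):
            block_conditions = np.repeat(spec.conditions, blocks_per_cond)
            rng.shuffle(block_conditions)
            t = 0.0
            jitters = iter(
                _sample_jitter(rng, spec, spec.blocks_per_run * spec.trials_per_block)
            )
            for block, cond in enumerate(block_conditions, start=1):
                t += spec.instruction_duration_s + spec.instruction_gap_s
                for trial in range(1, spec.trials_per_block + 1):
                    rows.append(
                        {
                            "participant": part,
                            "run": run,
                            "block": block,
                            "trial": trial,
                            "trial_type": cond,
                            "onset": round(t, 6),
                            "duration": spec.target_duration_s,
                        }
                    )
                    jit = next(jitters)
                    t += jit if spec.iti_onset_to_onset else spec.target_duration_s + jit
    ledger = pd.DataFrame(rows)

    ledger["grip_type"] = ""
    for part in range(1, spec.participants + 1):
        for cond in spec.conditions:
            mask = (ledger["participant"] == part) & (ledger["trial_type"] == cond)
            ledger.loc[mask, "grip_type"] = _counterbalanced_grips(rng, int(mask.sum()))
    return ledger


def inject_annotations(
    ledger: pd.DataFrame, rates: ErrorRates = ErrorRates(), seed: int = 0
) -> pd.DataFrame:
    """Mark trials for error injection and annotation.

    Adds an ``annotation`` column (``ok``, ``feedback_bug`` or
    ``unexpected_movement`` -- flags that emulate the visual-inspection
    step) and boolean ``inject_tracking_loss`` / ``inject_movement``
    columns consumed by the kinematics generator.
    """
    rng = np.random.default_rng(seed)
    out = ledger.copy()
    out["annotation"] = "ok"
    out["inject_tracking_loss"] = False
    out["inject_movement"] = False
    movement = out["trial_type"].isin(MOVEMENT_CONDITIONS).to_numpy()
    u = rng.random(len(out))
    out.loc[movement & (u < rates.tracking_loss), "inject_tracking_loss"] = True
    u = rng.random(len(out))
    out.loc[movement & (u < rates.feedback_bug), "annotation"] = "feedback_bug"
    u = rng.random(len(out))
    mask = movement & (u < rates.unexpected_movement) & (out["annotation"] == "ok")
    out.loc[mask, "annotation"] = "unexpected_movement"
    u = rng.random(len(out))
    out.loc[~movement & (u < rates.moved_in_no_movement), "inject_movement"] = True
    return out


# ---------------------------------------------------------------------------
# trial kinematics


@dataclass
class TrialKinematics:
    """60 Hz multi-marker position/orientation series for one trial.

    ``markers``/``orientations`` map marker names to (n, 3) arrays (mm /
    rad); dropout frames are NaN.  ``positions(name)`` returns the raw
    trace; call :meth:`interpolated` first when a complete trace is
    required.
    """

    frame_rate_hz: float
    markers: dict
    orientations: dict
    condition: str | None = None
    grip_type: str | None = None
    participant: int | None = None
    run: int | None = None
    ground_truth: TrialGroundTruth | None = None

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.markers.values())))

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz

    def positions(self, marker: str) -> np.ndarray:
        return self.markers[marker]

    def interpolated(self, window: int = 5, max_gap_frames: int = 10) -> "TrialKinematics":
        """Return a copy with dropout gaps interpolated (all markers)."""
        from .segment import interpolate_dropouts

        markers = {
            name: interpolate_dropouts(pos, window, max_gap_frames)
            for name, pos in self.markers.items()
        }
        orientations = {
            name: interpolate_dropouts(ori, window, max_gap_frames)
            for name, ori in self.orientations.items()
        }
        return replace(self, markers=markers, orientations=orientations)

    def to_long_frame(self) -> pd.DataFrame:
        """Tab-separable long format: frame, time_s, marker, xyz, rxyz."""
        frames = []
        t = self.time_s
        for marker in MARKERS:
            pos = self.markers[marker]
            ori = self.orientations[marker]
            frames.append(
                pd.DataFrame(
                    {
                        "frame": np.arange(self.n_frames),
                        "time_s": t,
                        "marker": marker,
                        "x_mm": pos[:, 0],
                        "y_mm": pos[:, 1],
                        "z_mm": pos[:, 2],
                        "rx_rad": ori[:, 0],
                        "ry_rad": ori[:, 1],
                        "rz_rad": ori[:, 2],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


#: resting pose (mm, RAS): hand on the abdomen, elbow resting lateral
_START_WRIST = np.array([60.0, 120.0, -250.0])
_ELBOW_OFFSET = np.array([120.0, -80.0, 260.0])   # 300 mm from the wrist
_REACH_DIRECTION = np.array([-0.25, 0.35, -0.90])  # toward the feet, slightly up
_HAND_UP = np.array([0.0, 1.0, 0.0])               # aperture-offset axis
_GRIP_AXIS = np.array([1.0, 0.0, 0.0])             # finger-opposition axis

#: fraction of peak speed at movement onset/offset -- the transport bell is
#: scaled into [floor, 1] x peak so phase edges are crisp at 60 Hz
_SPEED_FLOOR = 0.5


def sample_ground_truth(
    rng: np.random.Generator, grip_type: str = "power"
) -> TrialGroundTruth:
    """Draw one trial's generative parameters.

    Latency and phase-duration moments follow the reported group
    kinematics (reaction 624 +/- 85 ms, reach 789 +/- 166 ms, grip
    1132 ms, back 1040 +/- 232 ms); aperture minima follow the reported
    grip-type contrast (power 45 / precision 72 mm grip aperture, 122 /
    162 mm hand aperture), with clipping keeping the contrast strict at
    the single-trial level.  The back movement is slowed relative to the
    reach (duration ratio ~1.3) and its path lengthened accordingly so
    both movements stay well separated from stillness.
    """
    latency = float(np.clip(rng.normal(0.624, 0.085), 0.35, 1.0))
    reach = float(np.clip(rng.normal(0.789, 0.166), 0.5, 1.25))
    grip = float(np.clip(rng.normal(1.132, 0.30), 0.5, 2.0))
    back_ratio = float(np.clip(rng.normal(1.32, 0.12), 1.05, 1.5))
    back = reach * back_ratio

    if grip_type == "power":
        grip_min = float(np.clip(rng.normal(45.0, 4.0), 35.0, 55.0))
        hand_min = float(np.clip(rng.normal(122.0, 6.0), 105.0, 140.0))
    elif grip_type == "precision":
        grip_min = float(np.clip(rng.normal(72.0, 5.0), 60.0, 88.0))
        hand_min = float(np.clip(rng.normal(162.0, 6.0), 146.0, 178.0))
    else:
        raise ConfigurationError(f"unknown grip type: {grip_type}")

    distance = float(np.clip(rng.normal(300.0, 25.0), 220.0, 380.0))
    h_reach = float(np.clip(rng.normal(20.0, 7.0), 3.0, 45.0))
    speed_ratio = float(np.clip(rng.normal(0.82, 0.05), 0.75, 0.92))
    # lengthen the return path so its peak speed stays near the reach's
    target_ci_back = speed_ratio * back_ratio
    h_back = _height_for_curvature(max(target_ci_back, 1.004), distance)

    open_ap = float(np.clip(rng.normal(115.0, 8.0), 95.0, 135.0))
    open_ap = max(open_ap, grip_min + 15.0)

    return TrialGroundTruth(
        grip_type=grip_type,
        reaction_latency_s=latency,
        reaching_duration_s=reach,
        grip_duration_s=grip,
        back_duration_s=back,
        min_grip_aperture_mm=grip_min,
        min_hand_aperture_mm=hand_min,
        open_grip_aperture_mm=open_ap,
        grip_squeeze_mm=float(rng.uniform(4.0, 8.0)),
        reach_distance_mm=distance,
        reach_curvature_height_mm=h_reach,
        back_curvature_height_mm=h_back,
    )


def _height_for_curvature(ci: float, chord: float) -> float:
    """Lateral arc height giving the requested curvature index."""
    from scipy.optimize import brentq

    if ci <= 1.0005:
        return 3.0

    def f(h: float) -> float:
        return _arc_curvature(h, chord) - ci

    hi = chord
    return float(brentq(f, 1e-3, hi))


def _arc_curvature(h: float, chord: float) -> float:
    s = np.linspace(0.0, 1.0, 801)
    x = chord * s
    y = h * np.sin(np.pi * s)
    return float(
        np.hypot(np.diff(x), np.diff(y)).sum() / chord
    )


def _bell(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk speed bell, normalized to unit peak."""
    return 16.0 * tau**2 * (1.0 - tau) ** 2


def _movement_positions(
    start: np.ndarray,
    end: np.ndarray,
    height_mm: float,
    normal: np.ndarray,
    n_steps: int,
) -> np.ndarray:
    """Wrist positions for one transport movement (n_steps + 1 frames).

    The path is a lateral sine arc from ``start`` to ``end``; the speed
    along the path follows the minimum-jerk bell scaled into
    [_SPEED_FLOOR, 1] of its peak, so motion onset and offset are crisp
    relative to the 60 Hz frame grid.
    """
    dense = np.linspace(0.0, 1.0, 2001)
    chord = end - start
    curve = (
        start[None, :]
        + dense[:, None] * chord[None, :]
        + height_mm * np.sin(np.pi * dense)[:, None] * normal[None, :]
    )
    seglen = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    cumlen = np.concatenate([[0.0], np.cumsum(seglen)])

    tau = (np.arange(n_steps) + 0.5) / n_steps
    weights = _SPEED_FLOOR + (1.0 - _SPEED_FLOOR) * _bell(tau)
    arc = np.concatenate([[0.0], np.cumsum(weights)])
    arc *= cumlen[-1] / arc[-1]

    u = np.interp(arc, cumlen, dense)
    out = np.empty((n_steps + 1, 3))
    for axis in range(3):
        out[:, axis] = np.interp(u, dense, curve[:, axis])
    out[0], out[-1] = start, end
    return out


def _ar1_noise(
    rng: np.random.Generator, shape: tuple, sd: float, rho: float = 0.9
) -> np.ndarray:
    """Band-limited Gaussian noise with marginal sd ``sd`` (AR(1) over time).

    Optical marker jitter is temporally correlated; white noise at 60 Hz
    would imply inter-frame velocity noise real tracking systems do not
    show.
    """
    if sd == 0:
        return np.zeros(shape)
    w = rng.normal(0.0, sd, size=shape)
    w[0] /= np.sqrt(1.0 - rho**2)
    out = ssignal.lfilter([1.0], [1.0, -rho], w * np.sqrt(1.0 - rho**2), axis=0)
    return out


def simulate_trial(
    ground_truth: TrialGroundTruth,
    frame_rate_hz: float = 60.0,
    noise_sd_mm: float = 0.0,
    dropout_prob: float = 0.0,
    window_s: float | None = None,
    seed: int = 0,
    still: bool = False,
    inject_tracking_loss: bool = False,
    inject_extra_movement: bool = False,
) -> TrialKinematics:
    """Generate one trial's six-marker kinematics.

    The wrist is still until the reaction latency, transports to the
    target along a curved path with a bell-shaped speed profile, stays
    still during the grip phase while the fingers close to the aperture
    minimum, transports back, and rests.  Ground-truth boundary frames
    and the exact peak wrist speed are written back onto
    ``ground_truth``.  With ``still=True`` (no-movement trials) all
    markers hold the resting pose.
    """
    gt = ground_truth
    gt.validate()
    rng = np.random.default_rng(seed)
    fr = frame_rate_hz

    b0, b1, b2, b3 = gt.boundaries(fr)
    if window_s is None:
        window_s = b3 / fr + 1.0
    n = int(round(window_s * fr)) + 1
    if not still and b3 >= n:
        raise GenerationError("phases exceed the trial window")

    start = _START_WRIST
    direction = _REACH_DIRECTION / np.linalg.norm(_REACH_DIRECTION)
    target = start + gt.reach_distance_mm * direction
    normal = np.cross(direction, _HAND_UP)
    normal /= np.linalg.norm(normal)

    wrist = np.tile(start, (n, 1))
    if not still and gt.reach_distance_mm > 0:
        reach = _movement_positions(start, target, gt.reach_curvature_height_mm,
                                    normal, b1 - b0)
        back = _movement_positions(target, start, gt.back_curvature_height_mm,
                                   -normal, b3 - b2)
        wrist[b0 : b1 + 1] = reach
        wrist[b1 : b2 + 1] = target
        wrist[b2 : b3 + 1] = back
        steps = np.linalg.norm(np.diff(wrist, axis=0), axis=1)
        gt.peak_wrist_speed_mm_s = float(steps.max() * fr)
        gt.phase_boundary_frames = (b0, b1, b2, b3)
    else:
        gt.peak_wrist_speed_mm_s = 0.0
        gt.phase_boundary_frames = None

    if inject_extra_movement and not still:
        # a spurious second reach after the trial proper, if there is room
        m = n - 1 - b3
        if m >= 24:
            half = min((m - 10) // 2, int(round(0.35 * fr)))
            bump_target = start + 0.45 * gt.reach_distance_mm * direction
            out = _movement_positions(start, bump_target, 5.0, normal, half)
            ret = _movement_positions(bump_target, start, 5.0, -normal, half)
            s0 = b3 + 5
            wrist[s0 : s0 + half + 1] = out
            wrist[s0 + half : s0 + 2 * half + 1] = ret

    # finger apertures: open -> preshape during the reach -> squeeze dip
    # around the grip midpoint -> reopen on the way back
    a_open = gt.open_grip_aperture_mm
    a_min = gt.min_grip_aperture_mm
    amp = min(gt.grip_squeeze_mm, (a_open - a_min) / 2.0)
    aperture = np.full(n, a_open)
    if not still:
        closed = a_min + amp
        tau_r = np.linspace(0.0, 1.0, b1 - b0 + 1)
        aperture[b0 : b1 + 1] = a_open + (closed - a_open) * (1 - np.cos(np.pi * tau_r)) / 2
        # squeeze dip anchored on the frame grid so the minimum is attained
        # exactly at a sampled frame
        n_g = b2 - b1
        idx = np.arange(n_g + 1)
        mid = n_g // 2
        half = max(mid, n_g - mid, 1)
        aperture[b1 : b2 + 1] = a_min + amp * ((idx - mid) / half) ** 2
        tau_b = np.linspace(0.0, 1.0, b3 - b2 + 1)
        aperture[b2 : b3 + 1] = closed + (a_open - closed) * (1 - np.cos(np.pi * tau_b)) / 2

    palm = np.sqrt(gt.min_hand_aperture_mm**2 - gt.min_grip_aperture_mm**2 / 4.0)
    index_tip = wrist + palm * _HAND_UP + (aperture[:, None] / 2.0) * _GRIP_AXIS
    thumb_tip = wrist + palm * _HAND_UP - (aperture[:, None] / 2.0) * _GRIP_AXIS

    # transport progress in [0, 1]: out during the reach, back during return
    progress = np.zeros(n)
    if not still and gt.reach_distance_mm > 0:
        travelled = np.linalg.norm(wrist - start, axis=1)
        progress = travelled / max(travelled.max(), 1e-9)

    elbow = _START_WRIST + _ELBOW_OFFSET + 0.1 * (wrist - start)
    forearm = (elbow + wrist) / 2.0
    hand = wrist + 0.5 * palm * _HAND_UP

    flexion = (a_open - aperture) / a_open
    orientations = {m: np.zeros((n, 3)) for m in MARKERS}
    orientations["forearm"] = progress[:, None] * np.array([0.35, -0.20, 0.15])
    orientations["hand"] = (
        progress[:, None] * np.array([0.50, 0.30, -0.20])
        + flexion[:, None] * np.array([0.60, 0.0, 0.0])
    )

    markers = {
        "elbow": elbow, "forearm": forearm, "wrist": wrist,
        "hand": hand, "index_tip": index_tip, "thumb_tip": thumb_tip,
    }
    if noise_sd_mm > 0:
        for m in MARKERS:
            markers[m] = markers[m] + _ar1_noise(rng, (n, 3), noise_sd_mm)
            orientations[m] = orientations[m] + _ar1_noise(
                rng, (n, 3), noise_sd_mm / 500.0
            )

    if dropout_prob > 0:
        for m in MARKERS:
            lost = rng.random(n) < dropout_prob
            markers[m][lost] = np.nan
            orientations[m][lost] = np.nan
    if inject_tracking_loss:
        gap_len = 12 + int(rng.integers(0, 8))
        gap_at = int(rng.integers(b0, max(b0 + 1, b2 - gap_len)))
        for m in ("wrist", "index_tip", "thumb_tip"):
            markers[m][gap_at : gap_at + gap_len] = np.nan
            orientations[m][gap_at : gap_at + gap_len] = np.nan

    return TrialKinematics(
        frame_rate_hz=fr,
        markers=markers,
        orientations=orientations,
        grip_type=gt.grip_type,
        ground_truth=gt,
    )


# ---------------------------------------------------------------------------
# head motion and BOLD


def _tr_block_labels(
    events: pd.DataFrame, n_tr: int, tr_s: float
) -> np.ndarray:
    """Label each TR with the condition of the block it falls in."""
    labels = np.full(n_tr, "baseline", dtype=object)
    group_cols = ["run", "block"] if "run" in events.columns else ["block"]
    for _, sub in events.groupby(group_cols):
        start = int(np.floor(sub["onset"].min() / tr_s))
        stop = int(np.ceil((sub["onset"].max() + sub["duration"].max() + 2.0) / tr_s))
        labels[start : min(stop, n_tr)] = sub["trial_type"].iloc[0]
    return labels


def simulate_motion_series(
    events: pd.DataFrame,
    params: MotionGenParams = MotionGenParams(),
    tr_s: float = 0.8,
    seed: int = 0,
    n_tr: int | None = None,
) -> pd.DataFrame:
    """Per-TR head rigid-motion parameters plus arm/hand FD series.

    ``events`` is the trial ledger of a single run.  Arm and hand FD
    burst during movement trials and sit near zero elsewhere; the head
    FD series is constructed so that, within movement blocks, its
    correlation with arm FD converges to ``params.arm_head_coupling``.
    The head FD is then decomposed into six cumulative rigid-motion
    parameters (r = 50 mm) whose frame-wise displacement reproduces it
    exactly.

    Returns a DataFrame with the six motion-parameter columns plus
    ``arm_fd``, ``hand_fd``, ``block`` and ``is_movement``.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    if n_tr is None:
        n_tr = int(np.ceil((events["onset"].max() + events["duration"].max() + 8.0) / tr_s))

    blocks = _tr_block_labels(events, n_tr, tr_s)
    is_movement_block = np.isin(blocks, MOVEMENT_CONDITIONS)

    # effector FD: bursts while the arm is in flight
    arm = np.abs(rng.normal(0.0, 0.05, n_tr))
    hand = np.abs(rng.normal(0.0, 0.04, n_tr))
    movement = events[events["trial_type"].isin(MOVEMENT_CONDITIONS)]
    for _, ev in movement.iterrows():
        t0 = int(np.floor((ev["onset"] + 0.5) / tr_s))
        t1 = int(np.ceil((ev["onset"] + 3.8) / tr_s))
        t0, t1 = max(t0, 0), min(t1, n_tr)
        if t1 <= t0:
            continue
        arm[t0:t1] += params.arm_fd_move_mm * np.abs(
            rng.normal(1.0, 0.35, t1 - t0)
        )
        hand[t0:t1] += params.hand_fd_scale * params.arm_fd_move_mm * np.abs(
            rng.normal(1.0, 0.35, t1 - t0)
        )

    # head FD weakly coupled to arm FD within movement blocks
    c = params.arm_head_coupling
    eps = rng.normal(0.0, 1.0, n_tr)
    z = np.zeros(n_tr)
    if is_movement_block.any() and arm[is_movement_block].std() > 0:
        sub = arm[is_movement_block]
        z[is_movement_block] = (sub - sub.mean()) / sub.std()
    shape = 2.2
    head_fd = params.head_amplitude_mm * np.maximum(
        shape + c * z + np.sqrt(max(1.0 - c**2, 0.0)) * eps, 0.0
    )
    head_fd[0] = 0.0

    # decompose head FD into six rigid parameters reproducing it exactly
    use_rot = params.head_rot_amplitude_rad > 0
    n_axes = 6 if use_rot else 3
    weights = rng.dirichlet(np.ones(n_axes), size=n_tr)
    signs = rng.choice([-1.0, 1.0], size=(n_tr, n_axes))
    deltas = np.zeros((n_tr, 6))
    deltas[:, :3] = signs[:, :3] * weights[:, :3] * head_fd[:, None]
    if use_rot:
        deltas[:, 3:] = signs[:, 3:] * weights[:, 3:] * head_fd[:, None] / 50.0
    params_cum = np.cumsum(deltas, axis=0)

    out = pd.DataFrame(
        params_cum,
        columns=["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"],
    )
    out["arm_fd"] = arm
    out["hand_fd"] = hand
    out["block"] = blocks
    out["is_movement"] = is_movement_block
    return out


def simulate_bold(
    events: pd.DataFrame,
    scores: pd.DataFrame | None,
    params: BoldGenParams,
    n_tr: int,
    tr_s: float = 0.8,
    fd: np.ndarray | None = None,
    seed: int = 0,
) -> np.ndarray:
    """One ROI's BOLD series with known ground-truth effects.

    signal = baseline + sum(condition_beta * HRF-convolved condition
    regressor) + sum(modulator_beta * modulator regressor) +
    motion_beta * FD + AR(1) noise with marginal sd ``noise_sd``.
    The regressors are built exactly as the analysis design matrix
    builds them, so noiseless data admit exact beta recovery.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    design = _glm.build_design_matrix(
        events, scores, tr_s, n_tr, fd_head=fd,
    )
    y = np.full(n_tr, params.baseline, dtype=float)
    for cond, beta in params.condition_betas.items():
        if cond in design:
            y += beta * design[cond].to_numpy()
    for col in design.columns:
        if "_x_" in col:
            comp = col.split("_x_", 1)[1]
            beta = params.modulator_betas.get(comp, 0.0)
            y += beta * design[col].to_numpy()
    if fd is not None:
        y += params.motion_beta * np.asarray(fd, dtype=float)
    if params.noise_sd > 0:
        y += _ar1_noise(rng, (n_tr,), params.noise_sd, rho=params.ar1_coefficient)
    return y


def simulate_factor_table(
    n_trials: int = 800,
    n_factors: int = 7,
    n_measures: int = 28,
    loading: float = 0.8,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Measure table with a planted orthogonal-factor structure.

    Measures split into ``n_factors`` equal groups; each measure loads
    ``loading`` on its own factor and carries independent uniqueness
    noise of variance ``1 - loading**2`` (unit-variance columns).
    Returns ``(table, loadings, factor_scores)``.
    """
    if n_measures % n_factors != 0:
        raise ConfigurationError("n_measures must divide evenly into n_factors groups")
    rng = np.random.default_rng(seed)
    lam = np.zeros((n_measures, n_factors))
    per = n_measures // n_factors
    for f in range(n_factors):
        lam[f * per : (f + 1) * per, f] = loading
    scores = rng.normal(size=(n_trials, n_factors))
    unique = rng.normal(scale=np.sqrt(1.0 - loading**2), size=(n_trials, n_measures))
    table = pd.DataFrame(
        scores @ lam.T + unique,
        columns=[f"m{i + 1:02d}" for i in range(n_measures)],
    )
    return table, lam, scores
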