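"""Per-trial kinematic measures.

For each accepted trial, 28 measures are computed: for the reaching and
back-movement phases, duration, path length, peak and mean speed,
curvature index, and maximum deviation of the arm (wrist) plus the same
trajectory measures (sans duration) of the hand (index fingertip
relative to the wrist); for the grip phase, the minimum, maximum and
mean of the grip aperture (index tip to thumb tip) and the hand
aperture (index tip to wrist).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .segment import PhaseSegmentation, SpeedSeries, compute_speed, smooth

__all__ = [
    "FEATURE_NAMES",
    "path_length",
    "curvature_index",
    "max_deviation",
    "velocity_stats",
    "apertures",
    "extract_features",
]

_PHASES = ("reaching", "back")
_ARM_MEASURES = ("duration_s", "distance_mm", "vmax_mm_s", "vmean_mm_s",
                 "curvature_index", "max_deviation_mm")
_HAND_MEASURES = ("distance_mm", "vmax_mm_s", "vmean_mm_s",
                  "curvature_index", "max_deviation_mm")
_GRIP_MEASURES = tuple(
    f"grip_{ap}_{st}_mm" for ap in ("grip_aperture", "hand_aperture")
    for st in ("min", "max", "mean")
)

#: canonical ordering of the 28 per-trial kinematic measures
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{phase}_arm_{m}" for phase in _PHASES for m in _ARM_MEASURES
) + tuple(
    f"{phase}_hand_{m}" for phase in _PHASES for m in _HAND_MEASURES
) + _GRIP_MEASURES

assert len(FEATURE_NAMES) == 28

#: net displacements below this (mm) make the curvature index undefined
CURVATURE_TOLERANCE_MM = 1.0


class ParseFailureError(ValueError):
    """Raised when features are requested for an unparsed trial."""


def path_length(positions: np.ndarray) -> float:
    """Total distance travelled: sum of consecutive Euclidean steps (mm)."""
    positions = np.asarray(positions, dtype=float)
    if len(positions) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(positions, axis=0), axis=1).sum())


def curvature_index(
    positions: np.ndarray, tolerance_mm: float = CURVATURE_TOLERANCE_MM
) -> float:
    """Ratio of path length to straight start-to-end distance (>= 1).

    Returns NaN (an undefined-measure flag, imputed downstream) when the
    net displacement is below ``tolerance_mm``.
    """
    positions = np.asarray(positions, dtype=float)
    chord = float(np.linalg.norm(positions[-1] - positions[0]))
    if chord < tolerance_mm:
        return math.nan
    return path_length(positions) / chord


def max_deviation(positions: np.ndarray) -> float:
    """Maximum perpendicular distance (mm) from the straight-line path.

    The reference is the infinite line through the first and last point;
    degenerate (zero-chord) trajectories fall back to the distance from
    the start point.
    """
    positions = np.asarray(positions, dtype=float)
    start, end = positions[0], positions[-1]
    direction = end - start
    norm = np.linalg.norm(direction)
    rel = positions - start
    if norm == 0:
        return float(np.linalg.norm(rel, axis=1).max())
    cross = np.cross(rel, direction / norm)
    return float(np.linalg.norm(cross, axis=1).max())


def velocity_stats(speed: SpeedSeries | np.ndarray) -> tuple[float, float]:
    """Peak and mean speed (mm/s) over an interval."""
    values = speed.values if isinstance(speed, SpeedSeries) else np.asarray(speed, float)
    if len(values) == 0:
        raise ValueError("empty speed interval")
    return float(values.max()), float(values.mean())


def apertures(
    index_tip: np.ndarray, thumb_tip: np.ndarray, wrist: np.ndarray
) -> dict[str, float]:
    """Grip and hand aperture summary statistics over the grip interval.

    Grip aperture is the index-tip-to-thumb-tip distance; hand aperture
    the index-tip-to-wrist distance (both mm).
    """
    grip = np.linalg.norm(np.asarray(index_tip) - np.asarray(thumb_tip), axis=1)
    hand = np.linalg.norm(np.asarray(index_tip) - np.asarray(wrist), axis=1)
    out: dict[str, float] = {}
    for name, series in (("grip_aperture", grip), ("hand_aperture", hand)):
        out[f"grip_{name}_min_mm"] = float(series.min())
        out[f"grip_{name}_max_mm"] = float(series.max())
        out[f"grip_{name}_mean_mm"] = float(series.mean())
    return out


def _phase_block(
    prefix: str,
    positions: np.ndarray,
    speed_values: np.ndarray,
    duration_s: float | None,
) -> dict[str, float]:
    vmax, vmean = velocity_stats(speed_values)
    block = {}
    if duration_s is not None:
        block[f"{prefix}_duration_s"] = duration_s
    block.update(
        {
            f"{prefix}_distance_mm": path_length(positions),
            f"{prefix}_vmax_mm_s": vmax,
            f"{prefix}_vmean_mm_s": vmean,
            f"{prefix}_curvature_index": curvature_index(positions),
            f"{prefix}_max_deviation_mm": max_deviation(positions),
        }
    )
    return block


def extract_features(trial, seg: PhaseSegmentation, window: int = 5) -> pd.Series:
    """Compute all 28 kinematic measures for one segmented trial.

    Arm measures use the wrist trajectory; hand measures the index-tip
    trajectory expressed relative to the wrist.  Speeds come from the
    same five-frame-smoothed series used for segmentation.  Refuses
    trials whose segmentation failed.

    Parameters
    ----------
    trial
        A :class:`~graspkin.synth.TrialKinematics` (anything exposing a
        ``positions(marker)`` method returning interpolated (n, 3) mm
        arrays for ``wrist``, ``index_tip`` and ``thumb_tip``).
    seg
        A successful phase segmentation of the same trial.
    """
    if not seg.parse_ok:
        raise ParseFailureError(
            f"cannot extract features from unparsed trial ({seg.failure_reason})"
        )
    fr = seg.frame_rate_hz
    wrist = trial.positions("wrist")
    index_tip = trial.positions("index_tip")
    thumb_tip = trial.positions("thumb_tip")
    hand_rel = index_tip - wrist

    arm_speed = smooth(compute_speed(wrist, fr), window).values
    hand_speed = smooth(compute_speed(hand_rel, fr), window).values

    values: dict[str, float] = {}
    for phase in _PHASES:
        s, e = seg.phase_interval(phase)
        duration = (e - s) / fr
        # positions span one more frame than the speed interval
        values.update(_phase_block(f"{phase}_arm", wrist[s : e + 1],
                                   arm_speed[s:e], duration))
        values.update(_phase_block(f"{phase}_hand", hand_rel[s : e + 1],
                                   hand_speed[s:e], None))

    gs, ge = seg.grip
    values.update(apertures(index_tip[gs : ge + 1], thumb_tip[gs : ge + 1],
                            wrist[gs : ge + 1]))

    if set(values) != set(FEATURE_NAMES):
        raise AssertionError("feature schema violated")
    return pd.Series(values, dtype=float).reindex(FEATURE_NAMES)
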