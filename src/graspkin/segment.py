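"""Movement-phase segmentation of reach-to-grasp trials.

The wrist speed series of a correct trial follows a
still -> moving (reach) -> still (grip) -> moving (return) -> still
pattern.  Frames are classified as still or moving by 2-cluster k-means
on the smoothed speed, and the four phases are parsed from the run
structure of the labels.  All speeds are in mm/s, positions in mm,
time in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "SpeedSeries",
    "PhaseSegmentation",
    "compute_speed",
    "smooth",
    "classify_still_moving",
    "parse_phases",
    "interpolate_dropouts",
    "segment_trial",
]

#: minimum run duration merged away before phase parsing (s)
DEFAULT_MIN_RUN_S = 0.1
#: dropout gaps longer than this many frames flag the trial as tracking loss
DEFAULT_MAX_GAP_FRAMES = 10


class DegenerateSpeedError(ValueError):
    """Raised when the speed series carries no variance to cluster."""


class TrackingLossError(ValueError):
    """Raised when a dropout gap exceeds the interpolation limit."""


@dataclass
class SpeedSeries:
    """Inter-frame wrist (or fingertip) speed in mm/s.

    ``values[i]`` is the speed over the interval from frame ``i`` to
    frame ``i + 1``; the series is one sample shorter than the position
    trace it derives from.
    """

    values: np.ndarray
    frame_rate_hz: float
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("speed series must be one-dimensional")
        if np.any(self.values < 0):
            raise ValueError("speeds cannot be negative")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class PhaseSegmentation:
    """Frame boundaries of the four trial phases.

    Intervals are half-open ``[start, end)`` on the speed-series frame
    grid and partition ``[reaction_frame, trial_end_frame)`` exactly.
    When parsing fails every interval is empty and ``failure_reason``
    names the cause.
    """

    reaction_frame: int
    reaching: tuple[int, int]
    grip: tuple[int, int]
    back: tuple[int, int]
    trial_end_frame: int
    parse_ok: bool
    failure_reason: str = ""
    frame_rate_hz: float = 60.0

    @property
    def reaction_time_s(self) -> float:
        """Latency from trial start to movement onset, in seconds."""
        return self.reaction_frame / self.frame_rate_hz

    def phase_interval(self, phase: str) -> tuple[int, int]:
        return {"reaching": self.reaching, "grip": self.grip, "back": self.back}[phase]

    @classmethod
    def failed(cls, reason: str, frame_rate_hz: float = 60.0) -> "PhaseSegmentation":
        return cls(
            reaction_frame=0,
            reaching=(0, 0),
            grip=(0, 0),
            back=(0, 0),
            trial_end_frame=0,
            parse_ok=False,
            failure_reason=reason,
            frame_rate_hz=frame_rate_hz,
        )


def compute_speed(positions: np.ndarray, frame_rate_hz: float) -> SpeedSeries:
    """Instantaneous speed from consecutive 3D positions.

    ``values[i] = ||p[i+1] - p[i]|| * frame_rate_hz`` -- the Euclidean
    distance between consecutive frames divided by the frame interval.
    Missing frames must be interpolated beforehand.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[1] != 3:
        raise ValueError("positions must be an (n, 3) array")
    if positions.shape[0] < 2:
        raise ValueError("need at least two frames to compute speed")
    if np.isnan(positions).any():
        raise ValueError("positions contain missing frames; interpolate first")
    steps = np.linalg.norm(np.diff(positions, axis=0), axis=1)
    return SpeedSeries(values=steps * frame_rate_hz, frame_rate_hz=frame_rate_hz)


def smooth(series: SpeedSeries, window: int = 5) -> SpeedSeries:
    """Centered moving average with shrinking windows at the edges.

    Edge samples average over however many frames fall inside the
    series, so no data is invented beyond the trial.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if window == 1:
        return SpeedSeries(series.values.copy(), series.frame_rate_hz, smoothed=True)
    sm = (
        pd.Series(series.values)
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return SpeedSeries(sm, series.frame_rate_hz, smoothed=True)


def classify_still_moving(speed: SpeedSeries, seed: int = 0) -> np.ndarray:
    """Label every speed frame as moving (True) or still (False).

    A 2-cluster k-means on the 1-D speed values; the cluster with the
    higher centroid is the moving one. Deterministic given ``seed``.
    """
    values = speed.values
    if len(values) < 4:
        raise ValueError("speed series too short to cluster (need >= 4 frames)")
    if np.ptp(values) == 0:
        raise DegenerateSpeedError("speed series has zero variance")
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    labels = km.fit_predict(values.reshape(-1, 1))
    moving_cluster = int(np.argmax(km.cluster_centers_.ravel()))
    return labels == moving_cluster


def _runs(labels: np.ndarray) -> list[tuple[bool, int, int]]:
    """Run-length encode a boolean series as (value, start, end) triples."""
    out: list[tuple[bool, int, int]] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append((bool(labels[start]), start, i))
            start = i
    return out


def _merge_short_runs(labels: np.ndarray, min_len: int) -> np.ndarray:
    """Flip runs shorter than ``min_len`` into their neighbours.

    The shortest offending run is merged first; merging re-joins its
    neighbours so the process always terminates.  Runs at the series
    edges are merged too, except when the whole series would flip.
    """
    labels = labels.copy()
    while True:
        runs = _runs(labels)
        if len(runs) <= 1:
            return labels
        short = [(e - s, idx) for idx, (_, s, e) in enumerate(runs) if e - s < min_len]
        if not short:
            return labels
        _, idx = min(short)
        _, s, e = runs[idx]
        labels[s:e] = ~labels[s:e]


def parse_phases(
    moving: np.ndarray,
    frame_rate_hz: float,
    min_run_s: float = DEFAULT_MIN_RUN_S,
) -> PhaseSegmentation:
    """Parse the four trial phases from still/moving frame labels.

    After merging runs shorter than ``min_run_s``, the expected pattern
    is still-moving-still-moving(-still): the first still->moving
    transition is the reaction frame, the first moving run the reaching
    phase, the enclosed still run the grip phase, and the second moving
    run the back movement whose last frame ends the trial.  Failures are
    reported through ``parse_ok``/``failure_reason``, never raised.
    """
    moving = np.asarray(moving, dtype=bool)
    min_len = max(1, int(round(min_run_s * frame_rate_hz)))
    merged = _merge_short_runs(moving, min_len)
    runs = _runs(merged)

    moving_runs = [(s, e) for val, s, e in runs if val]
    if len(moving_runs) == 0:
        return PhaseSegmentation.failed("no_movement", frame_rate_hz)
    if runs[0][0]:
        return PhaseSegmentation.failed("moving_at_start", frame_rate_hz)
    if len(moving_runs) == 1:
        return PhaseSegmentation.failed("incomplete_movement", frame_rate_hz)
    if len(moving_runs) > 2:
        return PhaseSegmentation.failed("extra_movement", frame_rate_hz)

    (r_start, r_end), (b_start, b_end) = moving_runs
    if b_start != r_end and not any(
        (not val and s == r_end and e == b_start) for val, s, e in runs
    ):
        return PhaseSegmentation.failed("bad_phase_pattern", frame_rate_hz)

    return PhaseSegmentation(
        reaction_frame=r_start,
        reaching=(r_start, r_end),
        grip=(r_end, b_start),
        back=(b_start, b_end),
        trial_end_frame=b_end,
        parse_ok=True,
        frame_rate_hz=frame_rate_hz,
    )


def interpolate_dropouts(
    positions: np.ndarray,
    window: int = 5,
    max_gap_frames: int = DEFAULT_MAX_GAP_FRAMES,
) -> np.ndarray:
    """Fill missing (NaN) frames by linear interpolation.

    Gaps are bridged linearly between the nearest observed neighbours;
    the ``window``-frame moving-average smoother is then applied to the
    interpolated spans only, leaving observed frames untouched.  A gap
    longer than ``max_gap_frames`` raises :class:`TrackingLossError` so
    the trial can be routed to the error ledger.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[1] != 3:
        raise ValueError("positions must be an (n, 3) array")
    missing = np.isnan(positions).any(axis=1)
    if not missing.any():
        return positions.copy()
    if missing.all():
        raise TrackingLossError("no observed frames in trial")

    gap_len = 0
    for m in missing:
        gap_len = gap_len + 1 if m else 0
        if gap_len > max_gap_frames:
            raise TrackingLossError(
                f"dropout gap exceeds {max_gap_frames} frames"
            )

    idx = np.arange(len(positions))
    filled = positions.copy()
    obs = ~missing
    for axis in range(3):
        filled[missing, axis] = np.interp(idx[missing], idx[obs], positions[obs, axis])

    smoothed = (
        pd.DataFrame(filled)
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    out = filled.copy()
    out[missing] = smoothed[missing]
    return out


def smooth_positions(positions: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving-average smoothing of a position trace (per axis)."""
    return (
        pd.DataFrame(np.asarray(positions, dtype=float))
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def segment_trial(
    wrist_positions: np.ndarray,
    frame_rate_hz: float,
    window: int = 5,
    min_run_s: float = DEFAULT_MIN_RUN_S,
    max_gap_frames: int = DEFAULT_MAX_GAP_FRAMES,
    seed: int = 0,
    presmooth_positions: bool = True,
) -> PhaseSegmentation:
    """Convenience end-to-end segmentation of one trial.

    Interpolates dropouts, computes and smooths the wrist speed,
    clusters frames into still/moving, and parses the phases.  By
    default positions are five-frame smoothed first, mirroring the
    smoothing the acquisition chain applies to movement data; without
    it, differentiating raw marker jitter inflates the apparent speed
    of still frames and erodes the still/moving separation.  Tracking
    loss and degenerate (motionless) speed series are converted into
    failed segmentations rather than exceptions.
    """
    try:
        clean = interpolate_dropouts(wrist_positions, window, max_gap_frames)
    except TrackingLossError:
        return PhaseSegmentation.failed("tracking_loss", frame_rate_hz)
    unsmoothed_speed = compute_speed(clean, frame_rate_hz)
    if presmooth_positions:
        clean = smooth_positions(clean, window)
    speed = smooth(compute_speed(clean, frame_rate_hz), window)
    try:
        moving = classify_still_moving(speed, seed=seed)
    except DegenerateSpeedError:
        return PhaseSegmentation.failed("no_movement", frame_rate_hz)
    seg = parse_phases(moving, frame_rate_hz, min_run_s)
    if seg.parse_ok:
        # transition localization is SNR-adaptive: on clean data the
        # lightly averaged raw speed keeps onsets frame-exact, while on
        # jittery data the position-smoothed speed is more reliable
        light = smooth(unsmoothed_speed, 3).values
        still_level = float(np.median(light[~moving])) if (~moving).any() else 0.0
        peak = float(light[moving].max())
        if peak > 0 and still_level <= 0.1 * peak:
            refine_series = light
        else:
            refine_series = compute_speed(clean, frame_rate_hz).values
        seg = refine_boundaries(seg, refine_series, moving)
    return seg


def refine_boundaries(
    seg: PhaseSegmentation,
    raw_speed: np.ndarray,
    moving: np.ndarray,
    max_shift: int = 5,
) -> PhaseSegmentation:
    """Localize phase boundaries on the unsmoothed speed series.

    The smoothed series k-means clusters on spreads each transition over
    the smoothing window; this step re-places every boundary at the
    nearest crossing of the cluster-centroid midpoint in the raw speed,
    within ``max_shift`` frames of the parsed boundary.
    """
    c_still = raw_speed[~moving].mean() if (~moving).any() else 0.0
    n = len(raw_speed)

    def run_threshold(interval: tuple[int, int]) -> float:
        # each movement is localized against its own speed scale
        peak = raw_speed[interval[0] : interval[1]].max()
        return c_still + 0.3 * (peak - c_still)

    def nearest_crossing(b: int, rising: bool, theta: float) -> int:
        above = raw_speed >= theta
        best = b
        best_dist = max_shift + 1
        lo, hi = max(1, b - max_shift), min(n, b + max_shift + 1)
        for i in range(lo, hi):
            is_cross = (above[i] and not above[i - 1]) if rising else (
                above[i - 1] and not above[i]
            )
            if is_cross and abs(i - b) < best_dist:
                best, best_dist = i, abs(i - b)
        return best

    th_reach = run_threshold(seg.reaching)
    th_back = run_threshold(seg.back)
    b0 = nearest_crossing(seg.reaching[0], True, th_reach)
    b1 = nearest_crossing(seg.reaching[1], False, th_reach)
    b2 = nearest_crossing(seg.back[0], True, th_back)
    b3 = nearest_crossing(seg.back[1], False, th_back)
    if not b0 < b1 < b2 < b3:
        return seg
    return PhaseSegmentation(
        reaction_frame=b0,
        reaching=(b0, b1),
        grip=(b1, b2),
        back=(b2, b3),
        trial_end_frame=b3,
        parse_ok=True,
        frame_rate_hz=seg.frame_rate_hz,
    )
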