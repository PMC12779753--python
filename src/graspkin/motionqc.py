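"""Effector-wise motion quality control.

Frame-wise displacement (FD) summarises rigid motion between successive
functional volumes as

    FD_i = |dx_i| + |dy_i| + |dz_i| + r * (|da_i| + |db_i| + |dg_i|)

with translations in mm, rotations in radians, and rotations converted
to arc length on a sphere of radius ``r``.  The same index is applied to
three effectors with effector-appropriate radii: the head (r = 50 mm,
the conventional cortex-to-centre distance), the forearm (r = 300 mm,
wrist-to-elbow), and the hand (r = 180 mm, fingertip-to-wrist).
Complementary indices: Jenkinson's relative RMS displacement (RMSD) and
standardized DVARS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EFFECTOR_RADII_MM",
    "MOTION_PARAM_COLUMNS",
    "FDSeries",
    "framewise_displacement",
    "params_to_deltas",
    "kinematics_to_tr",
    "rmsd",
    "std_dvars",
    "censoring_stats",
    "retention_curve",
    "fd_correlation",
    "fd_correlation_group",
]

#: default rotation-to-translation conversion radius per effector (mm)
EFFECTOR_RADII_MM = {"head": 50.0, "arm": 300.0, "hand": 180.0}

#: column order of rigid-motion parameter tables (cumulative, per TR)
MOTION_PARAM_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")

#: FD censoring thresholds in common use (mm): lenient and stringent
DEFAULT_FD_THRESHOLDS = (0.5, 0.2)


@dataclass
class FDSeries:
    """Per-TR frame-wise displacement for one effector."""

    effector: str
    radius_mm: float
    values: np.ndarray
    tr_s: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("FD values cannot be negative")

    def __len__(self) -> int:
        return len(self.values)


def _as_deltas(frames) -> np.ndarray:
    arr = (
        frames[list(MOTION_PARAM_COLUMNS)].to_numpy()
        if isinstance(frames, pd.DataFrame)
        else np.asarray(frames, dtype=float)
    )
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise ValueError("motion frames must be (n, 6): 3 translations + 3 rotations")
    if not np.isfinite(arr).all():
        raise ValueError("motion frames contain non-finite values")
    return arr


def framewise_displacement(
    frames,
    r_mm: float,
    effector: str = "head",
    tr_s: float = 0.8,
) -> FDSeries:
    """FD from per-TR rigid displacements (frame i relative to i - 1).

    ``frames`` is an (n, 6) array or DataFrame of displacement deltas
    ``dx, dy, dz`` (mm) and ``da, db, dg`` (rad); the first frame of a
    run should be all zeros.
    """
    deltas = _as_deltas(frames)
    fd = np.abs(deltas[:, :3]).sum(axis=1) + r_mm * np.abs(deltas[:, 3:]).sum(axis=1)
    return FDSeries(effector=effector, radius_mm=r_mm, values=fd, tr_s=tr_s)


def params_to_deltas(params) -> np.ndarray:
    """Backward differences of cumulative motion parameters.

    Converts a realignment-style table (absolute position per TR) into
    the per-TR displacements FD operates on; the first row is zero.
    """
    arr = _as_deltas(params)
    return np.diff(arr, axis=0, prepend=arr[:1])


def kinematics_to_tr(
    positions: np.ndarray,
    reference: np.ndarray,
    orientations: np.ndarray | None,
    frame_rate_hz: float,
    tr_s: float = 0.8,
    rotation_strategy: str = "orientation-delta",
) -> np.ndarray:
    """Resample 60 Hz marker kinematics onto the TR grid as rigid deltas.

    Translations are the per-TR differences of ``positions`` expressed
    relative to ``reference`` (wrist relative to elbow for the arm;
    index tip relative to wrist for the hand); rotations are the per-TR
    differences of the recorded segment orientation angles, or zero
    under the ``"none"`` strategy.  Samples are taken every
    ``tr_s * frame_rate_hz`` frames (stride 48 at 60 Hz and TR 0.8 s);
    missing samples are filled from the nearest observed frame.

    Returns an (n_tr, 6) delta array suitable for
    :func:`framewise_displacement`.
    """
    if rotation_strategy not in ("orientation-delta", "none"):
        raise ValueError(f"unknown rotation strategy: {rotation_strategy}")
    stride_f = tr_s * frame_rate_hz
    stride = int(round(stride_f))
    if not np.isclose(stride_f, stride):
        raise ValueError("tr_s must be a whole number of frames")

    rel = np.asarray(positions, dtype=float) - np.asarray(reference, dtype=float)
    idx = np.arange(0, len(rel), stride)
    sampled = _nearest_fill(rel)[idx]
    deltas = np.zeros((len(idx), 6))
    deltas[1:, :3] = np.diff(sampled, axis=0)
    if rotation_strategy == "orientation-delta" and orientations is not None:
        ori = _nearest_fill(np.asarray(orientations, dtype=float))[idx]
        deltas[1:, 3:] = np.diff(ori, axis=0)
    return deltas


def _nearest_fill(arr: np.ndarray) -> np.ndarray:
    """Nearest-neighbour fill of missing (NaN) rows."""
    missing = np.isnan(arr).any(axis=1)
    if not missing.any():
        return arr
    if missing.all():
        raise ValueError("all frames missing")
    idx = np.arange(len(arr))
    out = arr.copy()
    obs = idx[~missing]
    nearest = obs[np.abs(obs[None, :] - idx[missing, None]).argmin(axis=1)]
    out[missing] = arr[nearest]
    return out


def _rotation_matrix(angles: np.ndarray) -> np.ndarray:
    """Rotation matrix for small rigid-body angles, R = Rz @ Ry @ Rx."""
    ax, ay, az = angles
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def rmsd(params, radius_mm: float = 80.0) -> float:
    """Run-level relative RMS displacement (Jenkinson formulation), mm.

    For each pair of successive rigid alignments the relative transform
    ``M = T_i T_{i-1}^{-1}`` is decomposed into ``A = R - I`` and
    translation ``t``, and the displacement averaged over a sphere of
    ``radius_mm`` is ``sqrt(radius^2 / 5 * tr(A'A) + t't)``.  The run
    summary is the mean over frame pairs.
    """
    arr = _as_deltas(params)
    if len(arr) < 2:
        return 0.0
    vals = []
    for i in range(1, len(arr)):
        r_prev = _rotation_matrix(arr[i - 1, 3:])
        r_cur = _rotation_matrix(arr[i, 3:])
        rel_rot = r_cur @ r_prev.T
        a = rel_rot - np.eye(3)
        t = arr[i, :3] - rel_rot @ arr[i - 1, :3]
        vals.append(np.sqrt(radius_mm**2 / 5.0 * np.trace(a.T @ a) + t @ t))
    return float(np.mean(vals))


def std_dvars(timeseries) -> np.ndarray:
    """Standardized DVARS of a multi-channel (TR x channel) panel.

    DVARS_t is the RMS over channels of the temporal difference at TR t,
    divided by its expectation under temporally-independent fluctuations
    at the observed channel variances, so a clean series hovers near 1.
    The first frame has no predecessor and is set to 0.
    """
    ts = (
        timeseries.to_numpy() if isinstance(timeseries, pd.DataFrame)
        else np.asarray(timeseries, dtype=float)
    )
    if ts.ndim != 2:
        raise ValueError("timeseries must be (n_tr, n_channels)")
    diffs = np.diff(ts, axis=0)
    dvars = np.sqrt((diffs**2).mean(axis=1))
    channel_var = ts.var(axis=0, ddof=1)
    expected = np.sqrt(2.0 * channel_var.mean())
    out = np.zeros(len(ts))
    if expected > 0:
        out[1:] = dvars / expected
    return out


def censoring_stats(
    fd: FDSeries,
    block_labels,
    thresholds=DEFAULT_FD_THRESHOLDS,
) -> pd.DataFrame:
    """Volume-censoring summary per block type and FD threshold.

    For each block label and each threshold: the fraction of TRs whose
    FD falls below the threshold and the minutes of data retained.
    """
    labels = np.asarray(block_labels)
    if len(labels) != len(fd.values):
        raise ValueError("block labels must match the FD series length")
    rows = []
    for block in pd.unique(labels):
        mask = labels == block
        for thr in thresholds:
            retained = int((fd.values[mask] < thr).sum())
            rows.append(
                {
                    "block_type": block,
                    "threshold_mm": thr,
                    "n_tr": int(mask.sum()),
                    "fraction_retained": retained / mask.sum(),
                    "retained_minutes": retained * fd.tr_s / 60.0,
                }
            )
    return pd.DataFrame(rows)


def retention_curve(fd: FDSeries, thresholds: np.ndarray) -> np.ndarray:
    """Cumulative fraction of volumes with FD below each threshold."""
    thresholds = np.asarray(thresholds, dtype=float)
    return (fd.values[None, :] < thresholds[:, None]).mean(axis=1)


def fd_correlation(head_fd, effector_fd, mask=None) -> float:
    """Pearson correlation between two FD series within masked TRs."""
    a = np.asarray(head_fd.values if isinstance(head_fd, FDSeries) else head_fd, float)
    b = np.asarray(
        effector_fd.values if isinstance(effector_fd, FDSeries) else effector_fd, float
    )
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        a, b = a[mask], b[mask]
    if len(a) < 3:
        raise ValueError("need at least 3 TRs to correlate")
    return float(stats.pearsonr(a, b)[0])


def fd_correlation_group(per_subject_r) -> dict[str, float]:
    """One-sample group test on Fisher-transformed per-subject correlations."""
    r = np.asarray(per_subject_r, dtype=float)
    z = np.arctanh(r)
    t, p = stats.ttest_1samp(z, 0.0)
    return {
        "mean_r": float(np.tanh(z.mean())),
        "t": float(t),
        "p": float(p),
        "dof": len(r) - 1,
    }
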