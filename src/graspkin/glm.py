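"""Parametric-modulation GLM on ROI-level BOLD time series.

Each trial is modelled as a canonical (double-gamma) haemodynamic
response time-locked to trial onset.  Trial-level kinematic component
scores enter as parametric modulators: zero-centred, convolved with the
HRF, and orthogonalized to their condition's main regressor.  Nuisance
motion regressors follow a fixed orthogonalization scheme (arm FD
against head FD, hand FD against arm FD).  Inference uses AR(1)
prewhitened least squares by default, with t contrasts, partial F tests
over the modulator columns, and Benjamini-Hochberg correction across
ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

__all__ = [
    "HRFParams",
    "hrf_canonical",
    "build_condition_regressor",
    "build_modulator",
    "orthogonalize",
    "build_design_matrix",
    "GLMFit",
    "fit",
    "contrast_t",
    "modulation_F",
    "motion_variance_share",
    "bh_correct",
]


@dataclass(frozen=True)
class HRFParams:
    """Double-gamma HRF parameters (conventional canonical values)."""

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    peak_undershoot_ratio: float = 6.0
    kernel_length_s: float = 32.0


def _gamma_pdf(t: np.ndarray, shape: float, scale: float) -> np.ndarray:
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    out[pos] = np.exp(
        (shape - 1) * np.log(tp) - tp / scale - shape * np.log(scale) - gammaln(shape)
    )
    return out


def hrf_canonical(tr_s: float, params: HRFParams = HRFParams()) -> np.ndarray:
    """Canonical double-gamma HRF sampled on the TR grid, peak-normalized.

    The kernel is the difference of two gamma densities (response minus
    undershoot scaled by ``1/peak_undershoot_ratio``), zero at t = 0 and
    peaking near 5-6 s with the default parameters.
    """
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    t = np.arange(0, params.kernel_length_s + tr_s / 2, tr_s)
    peak = _gamma_pdf(t, params.peak_delay_s / params.peak_dispersion,
                      params.peak_dispersion)
    under = _gamma_pdf(t, params.undershoot_delay_s / params.undershoot_dispersion,
                       params.undershoot_dispersion)
    kernel = peak - under / params.peak_undershoot_ratio
    return kernel / kernel.max()


def _onset_impulses(
    onsets_s, tr_s: float, n_tr: int, amplitudes=None, duration_s: float = 0.0
) -> np.ndarray:
    onsets = np.asarray(onsets_s, dtype=float)
    amps = np.ones(len(onsets)) if amplitudes is None else np.asarray(amplitudes, float)
    if len(amps) != len(onsets):
        raise ValueError("one amplitude per onset required")
    impulses = np.zeros(n_tr)
    n_box = max(1, int(round(duration_s / tr_s)))
    for onset, amp in zip(onsets, amps):
        start = int(round(onset / tr_s))
        if start >= n_tr:
            continue
        impulses[start : min(start + n_box, n_tr)] += amp
    return impulses


def build_condition_regressor(
    onsets_s,
    tr_s: float,
    n_tr: int,
    kernel: np.ndarray | None = None,
    duration_s: float = 0.0,
) -> np.ndarray:
    """HRF-convolved condition regressor on the TR grid.

    Unit impulses at the trial-onset TRs (or boxcars of ``duration_s``)
    are convolved with the canonical kernel and truncated to ``n_tr``.
    """
    if kernel is None:
        kernel = hrf_canonical(tr_s)
    impulses = _onset_impulses(onsets_s, tr_s, n_tr, duration_s=duration_s)
    return np.convolve(impulses, kernel)[:n_tr]


def build_modulator(
    onsets_s,
    scores,
    tr_s: float,
    n_tr: int,
    main_column: np.ndarray,
    kernel: np.ndarray | None = None,
    duration_s: float = 0.0,
) -> np.ndarray:
    """Parametric-modulator regressor for one kinematic component.

    Trial scores are zero-centred, placed as impulse weights at the
    trial onsets, convolved with the HRF, and residualized against the
    condition's main regressor.
    """
    if kernel is None:
        kernel = hrf_canonical(tr_s)
    scores = np.asarray(scores, dtype=float)
    centred = scores - scores.mean()
    impulses = _onset_impulses(onsets_s, tr_s, n_tr, centred, duration_s)
    column = np.convolve(impulses, kernel)[:n_tr]
    return orthogonalize(column, main_column)


def orthogonalize(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Residualize ``a`` against ``b``: a - b (b'a)/(b'b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    bb = b @ b
    if bb == 0:
        return a.copy()
    return a - b * (b @ a) / bb


def build_design_matrix(
    events: pd.DataFrame,
    scores: pd.DataFrame | None,
    tr_s: float,
    n_tr: int,
    fd_head: np.ndarray | None = None,
    fd_arm: np.ndarray | None = None,
    fd_hand: np.ndarray | None = None,
    confounds: pd.DataFrame | None = None,
    hrf_params: HRFParams = HRFParams(),
    event_duration_s: float = 0.0,
    modulated_conditions=("MoveVisible", "MoveInvisible"),
) -> pd.DataFrame:
    """Assemble the per-run design matrix.

    Columns, in order: one main regressor per condition present in
    ``events`` (with ``k`` modulator columns after each modulated
    condition), error-trial regressors if an ``error`` column marks any,
    head FD, arm FD orthogonalized to head FD, hand FD orthogonalized to
    (orthogonalized) arm FD, any pre-supplied confound columns, and a
    constant term last.

    ``scores`` must carry one row per movement trial, aligned with the
    rows of ``events`` via its index.
    """
    kernel = hrf_canonical(tr_s, hrf_params)
    cols: dict[str, np.ndarray] = {}

    err_mask = (
        events["error"].astype(bool)
        if "error" in events.columns
        else pd.Series(False, index=events.index)
    )
    clean = events[~err_mask]

    for cond in pd.unique(events["trial_type"]):
        sub = clean[clean["trial_type"] == cond]
        if len(sub) == 0:
            continue
        main = build_condition_regressor(
            sub["onset"], tr_s, n_tr, kernel, event_duration_s
        )
        cols[cond] = main
        if scores is not None and cond in modulated_conditions:
            trial_scores = scores.loc[scores.index.intersection(sub.index)]
            trial_scores = trial_scores.reindex(sub.index).dropna()
            kept = sub.loc[trial_scores.index]
            for comp in trial_scores.columns:
                cols[f"{cond}_x_{comp}"] = build_modulator(
                    kept["onset"], trial_scores[comp], tr_s, n_tr, main,
                    kernel, event_duration_s,
                )

    if err_mask.any():
        err = events[err_mask]
        # error trials split by whether the participant actually moved
        moved = (
            err["error_moved"].astype(bool)
            if "error_moved" in err.columns
            else err["trial_type"] != "NoMovement"
        )
        for name, sub in (("error_move", err[moved]), ("error_still", err[~moved])):
            if len(sub):
                cols[name] = build_condition_regressor(
                    sub["onset"], tr_s, n_tr, kernel, event_duration_s
                )

    if fd_head is not None:
        cols["fd_head"] = np.asarray(fd_head, dtype=float)
    if fd_arm is not None:
        arm = np.asarray(fd_arm, dtype=float)
        if fd_head is not None:
            arm = orthogonalize(arm, cols["fd_head"])
        cols["fd_arm"] = arm
    if fd_hand is not None:
        hand = np.asarray(fd_hand, dtype=float)
        if fd_arm is not None:
            hand = orthogonalize(hand, cols["fd_arm"])
        cols["fd_hand"] = hand

    if confounds is not None:
        for name in confounds.columns:
            if name in cols:
                raise ValueError(f"duplicate design column: {name}")
            cols[str(name)] = confounds[name].to_numpy(dtype=float)

    cols["constant"] = np.ones(n_tr)
    design = pd.DataFrame(cols)
    if len(design) != n_tr:
        raise ValueError("design columns must all have n_tr rows")
    return design


@dataclass
class GLMFit:
    """Least-squares fit of a design matrix to one ROI series."""

    design: pd.DataFrame
    betas: pd.Series
    residuals: np.ndarray
    sigma2: float
    dof: int
    rank: int
    rank_deficient: bool
    ar_rho: float
    whitened_X: np.ndarray
    whitened_y: np.ndarray

    @property
    def rss(self) -> float:
        return float(self.residuals @ self.residuals)


def _ols(x: np.ndarray, y: np.ndarray):
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return beta, resid, rank


def _ar1_apply(rho: float, q: np.ndarray) -> np.ndarray:
    """V @ q for the unit-variance AR(1) covariance V_ij = rho^|i-j|."""
    from scipy.signal import lfilter

    fwd = lfilter([1.0], [1.0, -rho], q, axis=0)
    bwd = lfilter([1.0], [1.0, -rho], q[::-1], axis=0)[::-1]
    return fwd + bwd - q


def _expected_lag1_ratio(rho: float, q: np.ndarray) -> float:
    """E[e'Le / e'e] for OLS residuals e = (I - QQ')eps, eps ~ AR(1)(rho).

    The projection onto the design absorbs part of the smooth noise, so
    the naive residual lag-1 autocorrelation underestimates rho; this
    computes its expectation by trace matching (Q is an orthonormal
    design basis, L the symmetrized lag operator).
    """
    n, _ = q.shape
    vq = _ar1_apply(rho, q)                      # V Q
    qvq = q.T @ vq                               # Q' V Q
    avq = np.zeros_like(vq)                      # L_sym V Q
    avq[1:] += 0.5 * vq[:-1]
    avq[:-1] += 0.5 * vq[1:]
    qavq = q.T @ avq                             # Q' L_sym V Q
    aq = np.zeros_like(q)                        # L_sym Q
    aq[1:] += 0.5 * q[:-1]
    aq[:-1] += 0.5 * q[1:]
    qaq = q.T @ aq                               # Q' L_sym Q
    t0 = n - np.trace(qvq)
    t1 = (n - 1) * rho - 2.0 * np.trace(qavq) + np.trace(qaq @ qvq)
    return t1 / t0 if t0 > 0 else rho


def _bias_corrected_rho(x: np.ndarray, resid: np.ndarray) -> float:
    """AR(1) coefficient whose expected residual autocorrelation matches
    the observed one under the design's projection."""
    from scipy.optimize import brentq

    denom = resid @ resid
    if denom <= 0 or len(resid) < 10:
        return 0.0
    observed = float(resid[1:] @ resid[:-1]) / denom
    q, _ = np.linalg.qr(x)

    def gap(rho: float) -> float:
        return _expected_lag1_ratio(rho, q) - observed

    lo, hi = -0.95, 0.95
    if gap(lo) * gap(hi) > 0:
        return float(np.clip(observed, -0.95, 0.95))
    return float(brentq(gap, lo, hi, xtol=1e-4))


def _whiten(x: np.ndarray, y: np.ndarray, rho: float):
    """Cochrane-Orcutt AR(1) transform, first observation scaled."""
    scale = np.sqrt(1.0 - rho**2)
    xw = np.empty_like(x)
    yw = np.empty_like(y)
    xw[0] = x[0] * scale
    yw[0] = y[0] * scale
    xw[1:] = x[1:] - rho * x[:-1]
    yw[1:] = y[1:] - rho * y[:-1]
    return xw, yw


def fit(design: pd.DataFrame, y, ar_model: str = "ar1") -> GLMFit:
    """Fit the GLM by (optionally prewhitened) least squares.

    ``ar_model="ar1"`` (default) estimates the lag-1 autocorrelation of
    the OLS residuals and refits on AR(1)-whitened data, the standard
    correction for serially correlated BOLD noise; ``"none"`` performs
    plain OLS.  Rank deficiency is reported, not raised.
    """
    if ar_model not in ("ar1", "none"):
        raise ValueError(f"unknown ar_model: {ar_model}")
    x = design.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) != len(x):
        raise ValueError("y must have one sample per design row")

    beta, resid, rank = _ols(x, y)
    xw, yw = x, y
    rho = 0.0
    if ar_model == "ar1" and len(resid) > 2:
        # the naive residual autocorrelation is biased low because the
        # (smooth) design absorbs autocorrelated noise; correct by trace
        # matching before whitening
        rho = _bias_corrected_rho(x, resid)
        if rho != 0.0:
            xw, yw = _whiten(x, y, rho)
            beta, resid, rank = _ols(xw, yw)

    dof = len(y) - rank
    sigma2 = float(resid @ resid / dof) if dof > 0 else np.nan
    return GLMFit(
        design=design,
        betas=pd.Series(beta, index=design.columns),
        residuals=resid,
        sigma2=sigma2,
        dof=dof,
        rank=rank,
        rank_deficient=rank < x.shape[1],
        ar_rho=rho,
        whitened_X=xw,
        whitened_y=yw,
    )


def contrast_t(glm_fit: GLMFit, weights) -> dict[str, float]:
    """t statistic (and p) for a linear contrast of the betas."""
    if isinstance(weights, dict):
        c = np.array([weights.get(name, 0.0) for name in glm_fit.design.columns])
    else:
        c = np.asarray(weights, dtype=float)
    xtx_inv = np.linalg.pinv(glm_fit.whitened_X.T @ glm_fit.whitened_X)
    var = glm_fit.sigma2 * (c @ xtx_inv @ c)
    effect = float(c @ glm_fit.betas.to_numpy())
    t = 0.0 if effect == 0 else effect / np.sqrt(var)
    p = 2 * sstats.t.sf(abs(t), glm_fit.dof)
    return {"effect": effect, "t": float(t), "p": float(p), "dof": glm_fit.dof}


def modulation_F(glm_fit: GLMFit, columns) -> dict[str, float]:
    """Partial F test over a named set of design columns.

    Compares the full model with the model dropping ``columns`` (on the
    same whitened data), the standard omnibus test for an overall effect
    of the kinematic modulators.
    """
    columns = list(columns)
    keep = [c for c in glm_fit.design.columns if c not in columns]
    if len(keep) == len(glm_fit.design.columns):
        raise ValueError("no tested column found in the design")
    idx = [glm_fit.design.columns.get_loc(c) for c in keep]
    _, resid_red, _ = _ols(glm_fit.whitened_X[:, idx], glm_fit.whitened_y)
    rss_full = glm_fit.rss
    rss_red = float(resid_red @ resid_red)
    df1 = len(columns)
    df2 = glm_fit.dof
    f = ((rss_red - rss_full) / df1) / (rss_full / df2)
    f = max(f, 0.0)
    p = sstats.f.sf(f, df1, df2)
    return {"F": float(f), "df1": df1, "df2": df2, "p": float(p)}


def motion_variance_share(glm_fit: GLMFit, columns=("fd_arm", "fd_hand")) -> float:
    """Partial R-squared (percent) of the motion columns given all others.

    The share of residual BOLD variance -- after adjusting for every
    other regressor in the design -- explained by instantaneous arm and
    hand motion.
    """
    columns = [c for c in columns if c in glm_fit.design.columns]
    if not columns:
        return 0.0
    keep = [c for c in glm_fit.design.columns if c not in columns]
    idx = [glm_fit.design.columns.get_loc(c) for c in keep]
    _, resid_red, _ = _ols(glm_fit.whitened_X[:, idx], glm_fit.whitened_y)
    rss_red = float(resid_red @ resid_red)
    if rss_red == 0:
        return 0.0
    share = 100.0 * (rss_red - glm_fit.rss) / rss_red
    return float(np.clip(share, 0.0, 100.0))


def bh_correct(pvals, alpha: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg FDR correction across ROIs."""
    p = np.asarray(pvals, dtype=float)
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return pd.DataFrame({"p": p, "p_fdr": p_adj, "significant": reject})
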