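"""PCA-based dimensionality reduction of the kinematic measures.

The 28 per-trial measures mix units (s, mm, mm/s, unitless), so the
PCA operates on the correlation matrix: measures are z-scored across
all trials (pooled over participants and movement conditions), the
number of components is selected by Horn's parallel analysis against
column-permuted null tables, the retained loadings are varimax-rotated
with Kaiser normalization, and per-trial scores are the
loading-weighted sums of the z-scored measures.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "ComponentModel",
    "impute_missing",
    "standardize",
    "parallel_analysis",
    "varimax",
    "fit_pca_varimax",
    "score_trials",
]


@dataclass
class ComponentModel:
    """Varimax-rotated principal components of the measure table."""

    n_components: int
    loadings: pd.DataFrame          # measures x components
    variance_pct: np.ndarray        # rotated variance share per component
    total_variance_pct: float
    mean_: pd.Series                # per-measure standardization moments
    sd_: pd.Series
    rotation: np.ndarray            # orthogonal rotation applied to the loadings


def impute_missing(features: pd.DataFrame, participants=None) -> pd.DataFrame:
    """Fill undefined measures with the column mean within participant.

    Measures can be legitimately undefined for single trials (e.g., the
    curvature index of a near-zero net displacement); they are imputed
    by the participant-wise column mean, falling back to the grand
    column mean when a participant has no valid value at all.
    """
    out = features.copy()
    if participants is not None:
        participants = np.asarray(participants)
        for p in pd.unique(participants):
            mask = participants == p
            block = out.loc[mask]
            out.loc[mask] = block.fillna(block.mean())
    return out.fillna(out.mean())


def standardize(features: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Z-score each measure over all trials; returns (Z, mean, sd).

    Raises on constant columns (zero variance carries no correlation
    structure and would divide by zero).  Missing values must already be
    imputed.
    """
    if features.isna().any().any():
        raise ValueError("impute missing values before standardization")
    mean = features.mean()
    sd = features.std(ddof=1)
    if (sd == 0).any():
        bad = sd.index[sd == 0].tolist()
        raise ValueError(f"constant measure column(s): {bad}")
    return (features - mean) / sd, mean, sd


def _corr_eigvals(z: np.ndarray) -> np.ndarray:
    corr = np.corrcoef(z, rowvar=False)
    return np.linalg.eigvalsh(corr)[::-1]


def parallel_analysis(
    z: pd.DataFrame | np.ndarray,
    n_perm: int = 1000,
    percentile: float = 95.0,
    seed: int = 0,
) -> int:
    """Horn's parallel analysis for the number of retained components.

    The observed correlation-matrix eigenvalues are compared, position
    by position, with the given percentile of eigenvalues from tables
    whose columns are independently permuted (destroying correlation,
    preserving marginals); k counts the leading observed eigenvalues
    exceeding their null counterpart.
    """
    zmat = np.asarray(z, dtype=float)
    n, p = zmat.shape
    if n < p:
        warnings.warn(
            f"fewer trials ({n}) than measures ({p}); parallel analysis is unstable",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    observed = _corr_eigvals(zmat)
    null = np.empty((n_perm, p))
    perm = zmat.copy()
    for i in range(n_perm):
        for j in range(p):
            rng.shuffle(perm[:, j])
        null[i] = _corr_eigvals(perm)
    cutoff = np.percentile(null, percentile, axis=0)
    exceeds = observed > cutoff
    k = int(np.argmin(exceeds)) if not exceeds.all() else p
    return k


def varimax(
    loadings: np.ndarray,
    kaiser_normalize: bool = True,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation of a loading matrix.

    Iteratively finds the orthogonal rotation maximizing the variance of
    the squared loadings within components (the standard SVD-based
    algorithm).  With Kaiser normalization rows are scaled to unit
    communality during rotation.  Returns (rotated, rotation).
    """
    a = np.asarray(loadings, dtype=float)
    p, k = a.shape
    if k < 2:
        return a.copy(), np.eye(k)
    comm = np.sqrt((a**2).sum(axis=1)) if kaiser_normalize else np.ones(p)
    comm[comm == 0] = 1.0
    x = a / comm[:, None]
    rot = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        lam = x @ rot
        u, s, vt = np.linalg.svd(
            x.T @ (lam**3 - lam @ np.diag((lam**2).sum(axis=0)) / p)
        )
        rot = u @ vt
        var_new = s.sum()
        if var_new < var_old * (1 + tol):
            break
        var_old = var_new
    rotated = (x @ rot) * comm[:, None]
    return rotated, rot


def fit_pca_varimax(
    z: pd.DataFrame,
    k: int,
    mean: pd.Series | None = None,
    sd: pd.Series | None = None,
) -> ComponentModel:
    """Top-k correlation PCA with varimax rotation.

    Loadings are the principal axes scaled by the square roots of their
    eigenvalues, varimax-rotated (Kaiser-normalized), re-ordered by
    rotated variance share, and sign-fixed so each component's largest
    loading is positive.  ``variance_pct`` holds the rotated sums of
    squared loadings as percentages of the total variance (= number of
    measures, for a correlation PCA).
    """
    if not 1 <= k <= z.shape[1]:
        raise ValueError("k must be between 1 and the number of measures")
    zmat = z.to_numpy(dtype=float)
    corr = np.corrcoef(zmat, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    raw = eigvec[:, :k] * np.sqrt(np.maximum(eigval[:k], 0.0))

    rotated, rot = varimax(raw)

    ss = (rotated**2).sum(axis=0)
    order = np.argsort(ss)[::-1]
    rotated, rot, ss = rotated[:, order], rot[:, order], ss[order]
    signs = np.sign(rotated[np.abs(rotated).argmax(axis=0), np.arange(k)])
    signs[signs == 0] = 1.0
    rotated *= signs
    rot *= signs

    p = z.shape[1]
    loadings = pd.DataFrame(
        rotated, index=z.columns, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return ComponentModel(
        n_components=k,
        loadings=loadings,
        variance_pct=100.0 * ss / p,
        total_variance_pct=float(100.0 * ss.sum() / p),
        mean_=mean if mean is not None else pd.Series(0.0, index=z.columns),
        sd_=sd if sd is not None else pd.Series(1.0, index=z.columns),
        rotation=rot,
    )


def score_trials(z: pd.DataFrame, model: ComponentModel) -> pd.DataFrame:
    """Per-trial component scores: loading-weighted sums of z-measures.

    ``score = z-row . loadings`` (not regression scores); scores are
    zero-mean over the fitted trial set because the z-columns are.
    """
    if list(z.columns) != list(model.loadings.index):
        raise ValueError("measure columns do not match the fitted model")
    scores = z.to_numpy(dtype=float) @ model.loadings.to_numpy()
    return pd.DataFrame(scores, index=z.index, columns=model.loadings.columns)
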