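"""Subject-level playback-response scoring.

Six response variables per subject — four vocal (song overlaps, total
songs, songs during playback, singing duration) and two spatial (time
within 5 m of the loudspeaker, latency to approach) — are summarized by
principal components of their correlation matrix, varimax-rotated with
Kaiser normalization.  Components with eigenvalue > 1 are retained; on
tables with the intended structure this yields a vocal component (PC1)
and a spatial component (PC2).  Sampling-adequacy diagnostics (KMO,
Bartlett's sphericity) accompany the scores.  Body condition is the
residual of a weight-on-tarsus regression across the cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .world import RESPONSE_COLUMNS

__all__ = [
    "PCAResult",
    "body_condition",
    "bartlett_sphericity",
    "kmo",
    "varimax",
    "pca_varimax",
    "score_subjects",
]


@dataclass(frozen=True)
class PCAResult:
    """Rotated-PCA summary: eigenvalues, loadings, scores, diagnostics."""

    eigenvalues: np.ndarray  # all p, non-increasing
    variance_explained: np.ndarray  # % per component, sums to 100 over all p
    n_retained: int
    loadings: np.ndarray  # (p, k) varimax-rotated
    scores: np.ndarray  # (n, k) regression-method scores
    kmo: float
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float
    rotation_iterations: int = 0

    def __post_init__(self) -> None:
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues must be non-increasing")


def body_condition(weight: np.ndarray, tarsus: np.ndarray) -> np.ndarray:
    """Residual body mass: OLS of weight (g) on tarsus length (mm).

    The residual removes the structural-size component of mass; positive
    values mean heavier than expected for skeletal size.
    """
    weight = np.asarray(weight, float)
    tarsus = np.asarray(tarsus, float)
    if len(weight) < 3:
        raise ValueError("need >= 3 birds for the condition regression")
    if np.ptp(tarsus) == 0:
        raise ValueError("degenerate regression: tarsus has zero variance")
    X = np.column_stack([np.ones_like(tarsus), tarsus])
    beta, *_ = np.linalg.lstsq(X, weight, rcond=None)
    return weight - X @ beta


def bartlett_sphericity(R: np.ndarray, n: int) -> tuple[float, int, float]:
    """Bartlett's test that a correlation matrix is the identity.

    ``chi2 = -(n - 1 - (2p + 5)/6) * ln det(R)`` on ``p(p-1)/2`` df.
    """
    R = np.asarray(R, float)
    p = R.shape[0]
    if R.shape != (p, p) or not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("R must be a symmetric correlation matrix")
    if n <= p:
        raise ValueError("need n > p observations")
    eig = np.linalg.eigvalsh(R)
    if eig.min() <= 0:
        raise ValueError(
            f"R is not positive-definite (smallest eigenvalue {eig.min():.3g})"
        )
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * float(np.log(np.prod(eig)))
    chi2 = max(chi2, 0.0)
    df = p * (p - 1) // 2
    return chi2, df, float(stats.chi2.sf(chi2, df))


def kmo(R: np.ndarray) -> float:
    """Kaiser–Meyer–Olkin measure of sampling adequacy.

    Compares observed correlations with anti-image partial correlations
    ``q_ij = -inv_ij / sqrt(inv_ii inv_jj)``:
    ``KMO = sum r_ij^2 / (sum r_ij^2 + sum q_ij^2)`` over i != j.
    Near 1 when variables share broad common variance; 0.5 is the
    two-variable fixed point.
    """
    R = np.asarray(R, float)
    p = R.shape[0]
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError as e:
        raise ValueError("R is singular; KMO undefined") from e
    s = np.sqrt(np.diag(Rinv))
    Q = -Rinv / np.outer(s, s)
    off = ~np.eye(p, dtype=bool)
    r2 = float((R[off] ** 2).sum())
    q2 = float((Q[off] ** 2).sum())
    return r2 / (r2 + q2)


def varimax(
    loadings: np.ndarray,
    kaiser_normalize: bool = True,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Varimax rotation (orthogonal), optionally with Kaiser normalization.

    Maximizes the variance of squared loadings per factor.  With Kaiser
    normalization the rows are scaled to unit communality before rotation
    and rescaled after.  Returns (rotated loadings, rotation matrix,
    iterations).
    """
    L = np.asarray(loadings, float).copy()
    p, k = L.shape
    if k < 2:
        return L, np.eye(k), 0
    h = np.sqrt((L**2).sum(axis=1))
    if kaiser_normalize:
        if np.any(h == 0):
            raise ValueError("zero-communality row; cannot Kaiser-normalize")
        L = L / h[:, None]
    T = np.eye(k)
    var_old = 0.0
    it = 0
    for it in range(1, max_iter + 1):
        Lr = L @ T
        u, s, vt = np.linalg.svd(
            L.T @ (Lr**3 - Lr * (Lr**2).sum(axis=0) / p)
        )
        T = u @ vt
        var_new = s.sum()
        if var_new - var_old < tol:
            break
        var_old = var_new
    Lr = L @ T
    if kaiser_normalize:
        Lr = Lr * h[:, None]
    return Lr, T, it


def pca_varimax(
    table: pd.DataFrame | np.ndarray,
    columns: list[str] | None = None,
    eigen_threshold: float = 1.0,
) -> PCAResult:
    """Rotated PCA of the response table, with retention and diagnostics.

    Components are extracted from the correlation matrix (the variables
    mix counts and seconds), retained when their eigenvalue exceeds 1,
    Kaiser-normalized varimax rotated, and signed so that each
    component's largest-|loading| variable loads positively.  Scores use
    the regression method, ``Z R^{-1} Lambda``, and are mean-zero.
    """
    if isinstance(table, pd.DataFrame):
        cols = columns or [c for c in RESPONSE_COLUMNS if c in table.columns]
        X = table[cols].to_numpy(float)
    else:
        X = np.asarray(table, float)
        cols = columns or [f"v{i}" for i in range(X.shape[1])]
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [cols[i] for i in np.nonzero(sd == 0)[0]]
        raise ValueError(f"constant column(s): {bad}")
    if n < 3 * p:
        warnings.warn(
            f"n={n} < 3 x {p} variables: eigenvalue-based retention is fragile",
            UserWarning,
            stacklevel=2,
        )
    Z = (X - X.mean(axis=0)) / sd
    R = np.corrcoef(X, rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    var_pct = 100.0 * eigval / p

    k = int(np.sum(eigval > eigen_threshold))
    # sampling-fluctuation guard: near-threshold top eigenvalue on a
    # correlation matrix close to identity means retention is unstable
    if k == 0 or eigval[0] < 1.0 + 3.0 * np.sqrt(p / n):
        warnings.warn(
            "no clearly dominant component: eigenvalue>1 retention is unstable "
            f"(largest eigenvalue {eigval[0]:.3f} at n={n})",
            UserWarning,
            stacklevel=2,
        )
    k = max(k, 1)
    A = eigvec[:, :k] * np.sqrt(eigval[:k])  # unrotated loadings
    if k >= 2:
        L, _, iters = varimax(A, kaiser_normalize=True)
        # keep columns ordered by explained variance after rotation
        ssl = (L**2).sum(axis=0)
        L = L[:, np.argsort(ssl)[::-1]]
    else:
        L, iters = A, 0
    # sign convention: dominant variable of each component loads positively
    for j in range(L.shape[1]):
        i = int(np.argmax(np.abs(L[:, j])))
        if L[i, j] < 0:
            L[:, j] = -L[:, j]
    W = np.linalg.solve(R, L)  # regression-method score weights
    scores = Z @ W

    chi2, df, p_b = bartlett_sphericity(R, n)
    return PCAResult(
        eigenvalues=eigval,
        variance_explained=var_pct,
        n_retained=k,
        loadings=L,
        scores=scores,
        kmo=kmo(R),
        bartlett_chi2=chi2,
        bartlett_df=df,
        bartlett_p=p_b,
        rotation_iterations=iters,
    )


def score_subjects(
    responses: pd.DataFrame, manifest: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, dict]:
    """Full scoring stage: condition + rotated PC scores + diagnostics.

    Returns the scored table (adds ``condition_g``, ``pc1_vocal``,
    ``pc2_spatial``) and a JSON-serializable diagnostics dict.  The
    component whose loadings are dominated by the four vocal variables is
    labelled vocal regardless of rotation order.
    """
    df = responses.copy()
    src = manifest if manifest is not None else responses
    morpho = src.set_index("subject_id" if "subject_id" in src.columns else "bird_id")
    ids = df["subject_id"]
    weight = morpho["weight_g"].reindex(ids).to_numpy(float)
    tarsus = morpho["tarsus_mm"].reindex(ids).to_numpy(float)
    df["condition_g"] = body_condition(weight, tarsus)

    res = pca_varimax(df)
    vocal_mass = (res.loadings[:4] ** 2).sum(axis=0)
    order = np.argsort(vocal_mass)[::-1]
    if res.n_retained >= 2:
        vocal_j, spatial_j = int(order[0]), int(order[1])
        df["pc1_vocal"] = res.scores[:, vocal_j]
        df["pc2_spatial"] = res.scores[:, spatial_j]
    else:
        df["pc1_vocal"] = res.scores[:, 0]
        df["pc2_spatial"] = np.nan

    diagnostics = {
        "kmo": res.kmo,
        "bartlett_chi2": res.bartlett_chi2,
        "bartlett_df": res.bartlett_df,
        "bartlett_p": res.bartlett_p,
        "eigenvalues": res.eigenvalues.tolist(),
        "variance_explained_pct": res.variance_explained.tolist(),
        "n_retained": res.n_retained,
        "rotated_loadings": res.loadings.tolist(),
        "variables": [c for c in RESPONSE_COLUMNS if c in responses.columns],
        "rotation_iterations": res.rotation_iterations,
    }
    return df, diagnostics
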