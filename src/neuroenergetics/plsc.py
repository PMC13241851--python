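"""Partial Least Squares Correlation between regional metrics and clinical variables.

PLSC takes the correlation matrix between regional values (rEP or rAG) and
clinical variables (age, sex), and decomposes it by SVD into paired latent
variables: brain saliences (region weights) and clinical saliences whose
subject-level scores maximally covary.  Significance of each latent variable
is assessed by permutation of subject rows, and the stability of the brain
saliences by bootstrap resampling with orthogonal Procrustes alignment.

This serves as an independent validation route for the SSM-PCA patterns:
both should land on essentially the same age-related topography.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import svd

__all__ = ["PlscResult", "plsc_fit", "plsc_permutation", "plsc_bootstrap"]


@dataclass(frozen=True)
class PlscResult:
    """SVD of the clinical-by-region correlation matrix plus inference fields."""

    brain_saliences: np.ndarray      # regions x LVs, column-orthonormal
    clinical_saliences: np.ndarray   # variables x LVs, column-orthonormal
    singular_values: np.ndarray      # descending, non-negative
    brain_scores: np.ndarray         # subjects x LVs
    clinical_scores: np.ndarray      # subjects x LVs
    clinical_names: list[str] = field(default_factory=list)
    perm_p: np.ndarray | None = None
    bootstrap_ratios: np.ndarray | None = None


def _standardize(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    sd = A.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant column cannot be standardized")
    return (A - A.mean(axis=0)) / sd


def _cross_correlation(Xs: np.ndarray, Ys: np.ndarray) -> np.ndarray:
    return Ys.T @ Xs / (Xs.shape[0] - 1)


def plsc_fit(X: np.ndarray, Y: np.ndarray,
             clinical_names: list[str] | None = None) -> PlscResult:
    """Fit PLSC: SVD of the clinical-by-region correlation matrix.

    X is subjects x regions, Y subjects x clinical variables (e.g. age and
    sex coded +/-0.5); both are column-standardized, so
    ``C = Y_s' X_s / (n-1)`` holds the Pearson correlations.  The SVD
    ``C = U S V'`` gives clinical saliences U and brain saliences V; subject
    scores are the projections ``X_s V`` and ``Y_s U``.  Each latent
    variable's sign is fixed so its largest-magnitude clinical salience is
    positive.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of subjects")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    Xs, Ys = _standardize(X), _standardize(Y)
    C = _cross_correlation(Xs, Ys)
    U, s, Vt = svd(C, full_matrices=False)
    V = Vt.T
    for k in range(s.size):
        j = np.argmax(np.abs(U[:, k]))
        if U[j, k] < 0:
            U[:, k] = -U[:, k]
            V[:, k] = -V[:, k]
    return PlscResult(
        brain_saliences=V, clinical_saliences=U, singular_values=s,
        brain_scores=Xs @ V, clinical_scores=Ys @ U,
        clinical_names=list(clinical_names or
                            [f"var_{j}" for j in range(Y.shape[1])]))


def plsc_permutation(X: np.ndarray, Y: np.ndarray, n_perm: int = 1000,
                     seed: int | None = 0) -> np.ndarray:
    """Permutation p-value per latent variable.

    Subject rows of Y are permuted; ``p_k = (1 + #{perm s_k >= observed
    s_k}) / (n_perm + 1)``, so p is always in (0, 1].
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    rng = np.random.default_rng(seed)
    Xs, Ys = _standardize(X), _standardize(Y)
    s_obs = svd(_cross_correlation(Xs, Ys), compute_uv=False)
    exceed = np.zeros_like(s_obs)
    n = X.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        s_perm = svd(_cross_correlation(Xs, Ys[perm]), compute_uv=False)
        exceed += s_perm >= s_obs
    return (1.0 + exceed) / (n_perm + 1.0)


def plsc_bootstrap(X: np.ndarray, Y: np.ndarray, n_boot: int = 500,
                   seed: int | None = 0) -> np.ndarray:
    """Bootstrap ratios (original salience / bootstrap SD) per region and LV.

    Subjects are resampled with replacement; each resampled brain-salience
    matrix is aligned to the original by orthogonal Procrustes (resolving
    sign and rotation indeterminacy) before its spread is accumulated.
    Degenerate resamples (constant clinical column) are redrawn.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    rng = np.random.default_rng(seed)
    base = plsc_fit(X, Y)
    V0 = base.brain_saliences
    n = X.shape[0]
    samples = np.empty((n_boot,) + V0.shape)
    b = 0
    attempts = 0
    while b < n_boot:
        attempts += 1
        if attempts > 20 * n_boot:
            raise RuntimeError("too many degenerate bootstrap resamples")
        idx = rng.integers(0, n, size=n)
        try:
            res = plsc_fit(X[idx], Y[idx])
        except ValueError:
            continue
        Vb = res.brain_saliences
        # orthogonal Procrustes: rotate Vb onto V0
        A, _, Bt = svd(Vb.T @ V0, full_matrices=False)
        samples[b] = Vb @ (A @ Bt)
        b += 1
    sd = samples.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(sd > 0, V0 / sd, np.inf * np.sign(V0))
    return ratios
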