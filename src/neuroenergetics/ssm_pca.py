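"""Age-related spatial covariance patterns via SSM-PCA with CV recombination.

The Scaled Subprofile Model (SSM) double-demeans a subjects x regions data
matrix (removing subject and region main effects), PCA decomposes the
residual profile into spatial patterns (region weights) with subject scores,
and the components are recombined by forward-stepwise logistic regression
(AIC-guided) into a single pattern whose scores maximally separate younger
from older subjects.  Robustness comes from repeated stratified five-fold
cross-validation: the final pattern is the mean of the per-fold patterns and
the per-region SD across folds measures weight stability.

Candidate components must explain more than ``vaf_min`` percent of the
residual variance and separate the age groups at p < ``p_max`` (two-tailed
two-sample t-test) before entering the stepwise model — a pre-filter that,
together with AIC, keeps the recombination from chasing noise in small
cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import expit

from .energetics import AgeGroupSplit

__all__ = [
    "ResidualProfile",
    "PatternComponent",
    "CovariancePattern",
    "PatternDerivationError",
    "ssm_residual",
    "pca_components",
    "filter_components",
    "stepwise_logistic_aic",
    "crossvalidate_pattern",
    "separation_stats",
    "age_relationship",
    "display_mask",
    "posthoc_region_trends",
]


class PatternDerivationError(RuntimeError):
    """Raised when cross-validation produces no usable pattern at all."""


@dataclass(frozen=True)
class ResidualProfile:
    """Double-demeaned subjects x regions matrix (row and column means zero)."""

    matrix: np.ndarray
    metric: str = ""
    subject_ids: list[str] | None = None
    region_names: list[str] | None = None

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or min(m.shape) < 2:
            raise ValueError("residual profile must be at least 2x2")
        object.__setattr__(self, "matrix", m)


@dataclass(frozen=True)
class PatternComponent:
    """One principal component: unit-norm region weights, scores, VAF (%)."""

    weights: np.ndarray
    scores: np.ndarray
    vaf: float
    index: int = 0


@dataclass(frozen=True)
class CovariancePattern:
    """Cross-validated covariance pattern with stability and fit statistics."""

    metric: str
    region_names: list[str]
    weights: np.ndarray            # mean over CV folds, unit norm
    weight_sd: np.ndarray          # per-region SD over CV folds
    scores: np.ndarray             # full-cohort residual projection
    subject_ids: list[str]
    separation_t: float
    separation_p: float
    cohens_d: float
    age_r2: float
    age_p: float
    components_used: dict[int, int] = field(default_factory=dict)
    n_folds_retained: int = 0
    n_folds_total: int = 0


# ---------------------------------------------------------------------------
# Residual profile and PCA
# ---------------------------------------------------------------------------

def ssm_residual(X: np.ndarray, metric: str = "",
                 subject_ids=None, region_names=None) -> ResidualProfile:
    """Double-center a subjects x regions matrix (subject and region demeaning).

    ``R = X - row_means - col_means + grand_mean``; every row mean and
    column mean of R is zero.  Removes effects common across subjects
    (regional baseline topography) and across regions (per-subject offsets),
    leaving subject-by-region interaction variance.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or min(X.shape) < 2:
        raise ValueError("need >=2 subjects and >=2 regions")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in input")
    R = (X - X.mean(axis=1, keepdims=True) - X.mean(axis=0, keepdims=True)
         + X.mean())
    return ResidualProfile(matrix=R, metric=metric, subject_ids=subject_ids,
                           region_names=region_names)


def pca_components(R: ResidualProfile, tol: float = 1e-8) -> list[PatternComponent]:
    """SVD of the residual profile into spatial patterns and subject scores.

    Region weights are the right singular vectors (unit norm, sign fixed so
    the largest-magnitude weight is positive), subject scores their
    projections ``R @ w``, and VAF the percent of total residual variance,
    ``100 * s_k^2 / sum s^2``.  Components are returned in descending VAF
    order; VAF sums to 100% over the full list.
    """
    M = R.matrix
    if (np.abs(M.mean(axis=0)).max() > 1e-8 * max(1.0, np.abs(M).max())
            or np.abs(M.mean(axis=1)).max() > 1e-8 * max(1.0, np.abs(M).max())):
        raise ValueError("input is not double-centered; run ssm_residual first")
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    total = float((s ** 2).sum())
    if total == 0:
        return []
    comps = []
    for k in range(s.size):
        if s[k] <= tol * s[0]:
            continue
        w = Vt[k]
        if w[np.argmax(np.abs(w))] < 0:
            w = -w
        comps.append(PatternComponent(weights=w, scores=M @ w,
                                      vaf=100.0 * s[k] ** 2 / total, index=k))
    return comps


def filter_components(components, split: AgeGroupSplit,
                      vaf_min: float = 5.0, p_max: float = 0.2):
    """Keep components with VAF > vaf_min and group-separating scores p < p_max.

    The t-test is the equal-variance two-sample form, two-tailed.
    """
    split.require_both_groups()
    kept = []
    for c in components:
        if c.vaf <= vaf_min:
            continue
        _, p = stats.ttest_ind(c.scores[split.older], c.scores[~split.older],
                               equal_var=True)
        if p < p_max:
            kept.append(c)
    return kept


# ---------------------------------------------------------------------------
# Ridge-guarded logistic regression and AIC-stepwise recombination
# ---------------------------------------------------------------------------

def _logistic_fit(X: np.ndarray, y: np.ndarray, ridge: float = 1e-8,
                  max_iter: int = 25):
    """Newton-Raphson logistic fit with a tiny L2 ridge and iteration cap.

    The ridge and cap keep the solve finite under perfect separation (likely
    at n ~ 24); the returned log-likelihood is the *unpenalized* one, which
    is what enters AIC.  X must include an intercept column.
    """
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu) - ridge * beta
        H = (X.T * w) @ X + ridge * np.eye(p)
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.abs(step).max() < 1e-10:
            break
    eta = X @ beta
    loglik = float(y @ eta - np.logaddexp(0.0, eta).sum())
    return beta, loglik


def _aic(loglik: float, k: int) -> float:
    return 2.0 * k - 2.0 * loglik


def stepwise_logistic_aic(components, split: AgeGroupSplit,
                          ridge: float = 1e-8):
    """Forward-stepwise logistic recombination of PCA components.

    Components (ordered by VAF) compete to predict older-group membership
    from their subject scores; at each step the one lowering AIC the most is
    added, stopping when no addition lowers AIC.  Returns
    ``(weights, coefficients)`` where weights are the unit-norm combination
    ``sum_k beta_k * w_k`` over selected components, or ``(None, {})`` when
    the intercept-only model wins (no component helps).
    """
    split.require_both_groups()
    if len(components) == 0:
        return None, {}
    comps = sorted(components, key=lambda c: -c.vaf)
    y = split.older.astype(float)
    n = y.size
    ones = np.ones((n, 1))
    _, ll0 = _logistic_fit(ones, y, ridge=ridge)
    best_aic = _aic(ll0, 1)
    selected: list[int] = []
    coefs = np.zeros(0)
    remaining = list(range(len(comps)))
    while remaining:
        trial_results = []
        for j in remaining:
            cols = selected + [j]
            X = np.hstack([ones] + [comps[c].scores[:, None] for c in cols])
            beta, ll = _logistic_fit(X, y, ridge=ridge)
            trial_results.append((_aic(ll, len(cols) + 1), j, beta))
        aic_j, j, beta = min(trial_results, key=lambda t: t[0])
        if aic_j >= best_aic:
            break
        best_aic = aic_j
        selected.append(j)
        remaining.remove(j)
        coefs = beta[1:]
    if not selected:
        return None, {}
    combined = np.zeros_like(comps[0].weights)
    coef_map = {}
    for c_idx, b in zip(selected, coefs):
        combined += b * comps[c_idx].weights
        coef_map[comps[c_idx].index] = float(b)
    norm = np.linalg.norm(combined)
    if norm == 0:
        return None, {}
    return combined / norm, coef_map


# ---------------------------------------------------------------------------
# Cross-validated pattern derivation
# ---------------------------------------------------------------------------

def _stratified_folds(split: AgeGroupSplit, k: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    """Random k-fold partition stratified by age group.

    Stratification keeps both groups represented in every training set,
    which the component t-test filter requires.
    """
    folds = [[] for _ in range(k)]
    for mask in (split.older, ~split.older):
        idx = np.flatnonzero(mask)
        rng.shuffle(idx)
        for pos, subject in enumerate(idx):
            folds[pos % k].append(subject)
    return [np.sort(np.asarray(f, dtype=int)) for f in folds]


def crossvalidate_pattern(X: np.ndarray, split: AgeGroupSplit,
                          n_iter: int = 500, k_folds: int = 5,
                          seed: int | None = 0, vaf_min: float = 5.0,
                          p_max: float = 0.2, metric: str = "",
                          subject_ids=None, region_names=None) -> CovariancePattern:
    """Derive a robust age-related covariance pattern by repeated k-fold CV.

    Per iteration: a random stratified k-fold partition; on each (k-1)/k
    training set the full chain runs afresh (residual profile -> PCA ->
    VAF/p filter -> AIC stepwise), yielding a candidate pattern that is
    sign-aligned to a running reference.  The final weights (SD) are the
    mean (SD) across all retained fold-patterns, renormalized to unit norm,
    and the final scores project the *full-cohort* residual profile onto
    them.  Orientation is fixed so that scores increase with age.
    """
    X = np.asarray(X, dtype=float)
    split.require_both_groups()
    n, m = X.shape
    rng = np.random.default_rng(seed)
    collected = []
    used: dict[int, int] = {}
    total_folds = 0
    reference = None
    for _ in range(n_iter):
        for fold in _stratified_folds(split, k_folds, rng):
            total_folds += 1
            train = np.setdiff1d(np.arange(n), fold)
            tr_split = AgeGroupSplit(cutoff=split.cutoff,
                                     older=split.older[train],
                                     ages=split.ages[train])
            if not (tr_split.older.any() and (~tr_split.older).any()):
                continue
            R = ssm_residual(X[train])
            comps = pca_components(R)
            cand = filter_components(comps, tr_split, vaf_min=vaf_min,
                                     p_max=p_max)
            w, coef_map = stepwise_logistic_aic(cand, tr_split)
            if w is None:
                continue
            for idx in coef_map:
                used[idx] = used.get(idx, 0) + 1
            if reference is None:
                reference = w.copy()
            elif w @ reference < 0:
                w = -w
            collected.append(w)
    if not collected:
        raise PatternDerivationError(
            f"all {total_folds} CV folds produced empty models "
            f"(vaf_min={vaf_min}, p_max={p_max}); no age-related pattern")
    W = np.vstack(collected)
    mean_w = W.mean(axis=0)
    norm = np.linalg.norm(mean_w)
    if norm == 0:
        raise PatternDerivationError("fold-pattern mean is identically zero")
    weights = mean_w / norm
    weight_sd = W.std(axis=0, ddof=1) / norm if len(collected) > 1 \
        else np.zeros(m)

    full_R = ssm_residual(X).matrix
    scores = full_R @ weights
    if np.corrcoef(scores, split.ages)[0, 1] < 0:
        weights = -weights
        scores = -scores
    t, p, d = separation_stats(scores, split)
    r2, age_p = age_relationship(scores, split.ages)
    return CovariancePattern(
        metric=metric,
        region_names=list(region_names) if region_names is not None
        else [f"region_{i + 1:03d}" for i in range(m)],
        weights=weights, weight_sd=weight_sd, scores=scores,
        subject_ids=list(subject_ids) if subject_ids is not None
        else [f"sub-{i + 1:03d}" for i in range(n)],
        separation_t=t, separation_p=p, cohens_d=d,
        age_r2=r2, age_p=age_p, components_used=dict(sorted(used.items())),
        n_folds_retained=len(collected), n_folds_total=total_folds)


# ---------------------------------------------------------------------------
# Summary statistics and display helpers
# ---------------------------------------------------------------------------

def separation_stats(scores: np.ndarray, split: AgeGroupSplit):
    """Two-sample t (pooled variance), two-tailed p, and Cohen's d.

    d is the older-minus-younger mean difference over the pooled SD.
    """
    a = np.asarray(scores, dtype=float)[split.older]
    b = np.asarray(scores, dtype=float)[~split.older]
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need >=2 subjects")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    pooled = np.sqrt(((a.size - 1) * a.var(ddof=1)
                      + (b.size - 1) * b.var(ddof=1))
                     / (a.size + b.size - 2))
    d = (a.mean() - b.mean()) / pooled if pooled > 0 else 0.0
    return float(t), float(p), float(d)


def age_relationship(scores: np.ndarray, ages: np.ndarray):
    """Squared Pearson correlation of scores with age and its two-tailed p.

    Returns (nan, nan) for constant scores (undefined correlation).
    """
    scores = np.asarray(scores, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if scores.std() == 0 or ages.std() == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(scores, ages)
    return float(r * r), float(p)


def display_mask(pattern: CovariancePattern, threshold: float = 1.0,
                 laterality: dict[str, str] | None = None) -> list[str]:
    """Regions whose standardized weight magnitude clears its CV SD.

    Weights are standardized to SD 1 across regions (the SDs scaled by the
    same factor); a region is shown when ``|w| - sd > threshold``.  With a
    laterality map (region -> bilateral partner), the partner is included
    whenever either side passes.
    """
    w = np.asarray(pattern.weights, dtype=float)
    sd = np.asarray(pattern.weight_sd, dtype=float)
    scale = w.std(ddof=1)
    if scale == 0:
        return []
    passing = (np.abs(w / scale) - sd / scale) > threshold
    names = set(np.asarray(pattern.region_names)[passing])
    if laterality:
        for r in list(names):
            partner = laterality.get(r)
            if partner:
                names.add(partner)
    return [r for r in pattern.region_names if r in names]


def posthoc_region_trends(ds, table, region: str) -> dict[str, float]:
    """Pearson r of z(CMRglu), z(CBF), rEP and rAG with age for one region.

    Descriptive decomposition of a pattern region's age trend into its
    flow/metabolism constituents; not a formal test (no p-values).
    """
    try:
        j = table.region_names.index(region)
    except ValueError:
        raise KeyError(f"unknown region {region!r}") from None
    out = {}
    for name in ("z_cmrglu", "z_cbf", "rep", "rag"):
        r, _ = stats.pearsonr(table.metric(name)[:, j], ds.ages)
        out[name] = float(r)
    return out
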