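"""Comparison of age-related patterns with disease-related metabolic patterns.

Subject expression of an externally derived disease pattern (PDRP, PDCP,
ADRP or a stand-in) is scored by a regionalized Topographic Profile Rating:
each subject's log regional CMRglu is centered by its own global mean rate
(rGMR) and by the disease cohort's group mean profile (rGMP), and the
resulting residual profile (rSRP) is projected onto the disease pattern
weights (rDRP).  Spatial similarity between patterns uses Spearman rank
correlation (topographic similarity need not be linear); expression
similarity uses Pearson correlation; families of comparisons are
Bonferroni-adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .quantification import LabelVolume, aggregate_roi
from .synthetic_cohort import DiseasePattern

__all__ = [
    "DiseasePattern",
    "TprScores",
    "tpr_scores",
    "regionalize_voxel_pattern",
    "compare_weights",
    "compare_scores",
    "bonferroni",
]


@dataclass(frozen=True)
class TprScores:
    """Residual profiles and prospective pattern-expression scores.

    Score magnitudes are not clinically meaningful (no standardization is
    applied); only their covariance with other expression measures is used.
    """

    rsrp: np.ndarray             # subjects x regions
    scores: np.ndarray           # per subject
    pattern_label: str = ""


def tpr_scores(rcmrglu: np.ndarray, dp: DiseasePattern,
               center_rdrp: bool = True) -> TprScores:
    """Regionalized Topographic Profile Rating.

    Per subject: ``L = log(regional CMRglu)``, ``rGMR = mean(L)``,
    ``rSRP = L - rGMR - rGMP``, and the score is the dot product of rSRP
    with the rDRP weights.  Natural log is used throughout; the log base
    only rescales all scores by a common factor.

    With ``center_rdrp`` (default) the weights are mean-centered across
    regions before projection, which additionally makes scores invariant to
    any region-constant offset of the residual profile.
    """
    rcmrglu = np.atleast_2d(np.asarray(rcmrglu, dtype=float))
    if rcmrglu.shape[1] != len(dp.region_names):
        raise ValueError(
            f"region mismatch: data has {rcmrglu.shape[1]} regions, "
            f"pattern has {len(dp.region_names)}")
    if np.any(rcmrglu <= 0) or not np.all(np.isfinite(rcmrglu)):
        raise ValueError("regional CMRglu must be finite and strictly positive")
    L = np.log(rcmrglu)
    rgmr = L.mean(axis=1, keepdims=True)
    rsrp = L - rgmr - dp.rgmp[None, :]
    w = dp.rdrp - dp.rdrp.mean() if center_rdrp else dp.rdrp
    return TprScores(rsrp=rsrp, scores=rsrp @ w, pattern_label=dp.label)


def regionalize_voxel_pattern(voxel_pattern: np.ndarray,
                              voxel_gmp: np.ndarray,
                              labels: LabelVolume,
                              label_name: str = "") -> DiseasePattern:
    """Average a voxelwise disease pattern and group mean profile over ROIs."""
    w = aggregate_roi(voxel_pattern, labels)
    g = aggregate_roi(voxel_gmp, labels)
    present = w.notna() & g.notna()
    if not present.all():
        missing = list(w.index[~present])
        raise ValueError(f"labels absent from the grid: {missing}")
    return DiseasePattern(region_names=list(w.index), rdrp=w.to_numpy(),
                          rgmp=g.to_numpy(), label=label_name)


def compare_weights(p1: np.ndarray, p2: np.ndarray):
    """Spearman rank correlation between two region-weight vectors.

    Average ranks on ties; two-tailed p from the t approximation.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape or p1.ndim != 1:
        raise ValueError("weight vectors must be aligned 1-D arrays")
    if p1.size < 4:
        raise ValueError("need at least 4 regions")
    rho, p = stats.spearmanr(p1, p2)
    return float(rho), float(p)


def compare_scores(s1: np.ndarray, s2: np.ndarray):
    """Pearson correlation between two subject-score vectors."""
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if s1.shape != s2.shape or s1.ndim != 1:
        raise ValueError("score vectors must be aligned 1-D arrays")
    if s1.size < 3:
        raise ValueError("need at least 3 subjects")
    rho, p = stats.pearsonr(s1, s2)
    return float(rho), float(p)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: ``min(1, m * p)`` per value.

    ``m`` defaults to the number of p-values supplied; the age-vs-disease
    comparison family here has m = 6 ({rEP, rAG} x {PDRP, PDCP, ADRP}).
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size if m is None else int(m)
    if m < 1:
        raise ValueError("family size must be >= 1")
    return np.minimum(1.0, m * p)
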