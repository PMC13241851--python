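"""Relative energy production (rEP) and relative aerobic glycolysis (rAG).

Regional CMRglu and CBF values are z-scored across regions within each
subject, then rotated 45 degrees in the (z(CBF), z(CMRglu)) plane:

    rEP = (z(CBF) + z(CMRglu)) / sqrt(2)
    rAG = (z(CMRglu) - z(CBF)) / sqrt(2)

rEP is the projection onto the line of unity — concurrently high (low)
relative flow and metabolism mean high (low) relative energy production.
rAG is the orthogonal distance from that line — relative CMRglu exceeding
relative CBF suggests a preference for glycolysis, and, under spatially
uniform oxygen extraction, relatively elevated aerobic glycolysis.  Both
metrics describe the spatial *distribution* of energetics, not absolute
rates: per-subject z-scoring removes any global multiplicative or additive
factor of either modality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_cohort import RegionalDataset

__all__ = [
    "EnergeticsTable",
    "AgeGroupSplit",
    "zscore_regions",
    "rotate_energetics",
    "inverse_rotation",
    "build_energetics_table",
    "group_shift",
]

_SQRT2 = np.sqrt(2.0)


def zscore_regions(values: np.ndarray) -> np.ndarray:
    """Z-score a regional vector: (v - mean) / SD with sample SD (N-1)."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need a 1-D vector of >=2 regions")
    if not np.all(np.isfinite(v)):
        raise ValueError("missing or non-finite regional values")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance across regions")
    return (v - v.mean()) / sd


def rotate_energetics(z_cbf, z_cmrglu):
    """Rotate (z(CBF), z(CMRglu)) by 45 degrees onto (rEP, rAG).

    Accepts scalars or arrays (element-wise).  Positive rAG iff relative
    CMRglu exceeds relative CBF.  The rotation is orthonormal, so it
    preserves the Euclidean norm of each (z_cbf, z_cmrglu) pair.
    """
    z_cbf = np.asarray(z_cbf, dtype=float)
    z_cmrglu = np.asarray(z_cmrglu, dtype=float)
    if not (np.all(np.isfinite(z_cbf)) and np.all(np.isfinite(z_cmrglu))):
        raise ValueError("inputs must be finite")
    rep = (z_cbf + z_cmrglu) / _SQRT2
    rag = (z_cmrglu - z_cbf) / _SQRT2
    return rep, rag


def inverse_rotation(rep, rag):
    """Recover (z_cbf, z_cmrglu) from (rEP, rAG) — the transpose rotation."""
    rep = np.asarray(rep, dtype=float)
    rag = np.asarray(rag, dtype=float)
    return (rep - rag) / _SQRT2, (rep + rag) / _SQRT2


@dataclass(frozen=True)
class EnergeticsTable:
    """Per-subject, per-region z-scores and their rEP/rAG rotation."""

    z_cmrglu: np.ndarray
    z_cbf: np.ndarray
    rep: np.ndarray
    rag: np.ndarray
    subject_ids: list[str]
    region_names: list[str]

    def __post_init__(self):
        shape = np.asarray(self.z_cmrglu).shape
        for name in ("z_cbf", "rep", "rag"):
            if np.asarray(getattr(self, name)).shape != shape:
                raise ValueError("all matrices must share one shape")
        if (len(self.subject_ids), len(self.region_names)) != shape:
            raise ValueError("id/name lengths must match the matrices")

    def metric(self, name: str) -> np.ndarray:
        """Return one of the four matrices by name (rep, rag, z_cmrglu, z_cbf)."""
        if name not in ("rep", "rag", "z_cmrglu", "z_cbf"):
            raise KeyError(name)
        return getattr(self, name)


@dataclass(frozen=True)
class AgeGroupSplit:
    """Younger (age <= cutoff) vs older (age > cutoff) group assignment."""

    cutoff: float
    older: np.ndarray           # boolean mask per subject
    ages: np.ndarray

    def __post_init__(self):
        older = np.asarray(self.older, dtype=bool)
        ages = np.asarray(self.ages, dtype=float)
        if older.shape != ages.shape:
            raise ValueError("older mask and ages must have equal length")
        object.__setattr__(self, "older", older)
        object.__setattr__(self, "ages", ages)

    @classmethod
    def from_ages(cls, ages, cutoff: float = 60.0) -> "AgeGroupSplit":
        """Split at the cutoff; subjects at exactly the cutoff are 'younger'.

        The default 60 y cutoff splits a 35-80 y cohort into groups of
        roughly equal size with maximal mean-age difference.
        """
        ages = np.asarray(ages, dtype=float)
        return cls(cutoff=float(cutoff), older=ages > cutoff, ages=ages)

    def require_both_groups(self):
        if not (self.older.any() and (~self.older).any()):
            raise ValueError("both age groups must be non-empty")


def build_energetics_table(ds: RegionalDataset) -> EnergeticsTable:
    """Per-subject z-scoring of each modality across regions, then rotation."""
    z_glu = np.vstack([zscore_regions(row) for row in ds.cmrglu])
    z_cbf = np.vstack([zscore_regions(row) for row in ds.cbf])
    rep, rag = rotate_energetics(z_cbf, z_glu)
    return EnergeticsTable(z_cmrglu=z_glu, z_cbf=z_cbf, rep=rep, rag=rag,
                           subject_ids=list(ds.subject_ids),
                           region_names=list(ds.region_names))


def group_shift(table: EnergeticsTable, split: AgeGroupSplit) -> dict[str, np.ndarray]:
    """Older-group mean minus younger-group mean, per region and quantity.

    The per-region shift vectors of rEP/rAG are exactly the rotation of the
    z_cbf/z_cmrglu shift vectors (group averaging is linear).
    """
    split.require_both_groups()
    out = {}
    for name in ("rep", "rag", "z_cmrglu", "z_cbf"):
        mat = table.metric(name)
        out[name] = mat[split.older].mean(axis=0) - mat[~split.older].mean(axis=0)
    return out
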