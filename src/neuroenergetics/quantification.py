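"""Kinetic and volumetric quantification of regional CMRglu.

Turns dynamic FDG data into regional metabolic rates: Patlak graphical
estimation of the net uptake rate Ki, the lumped-constant scaling to CMRglu,
a simplified image-derived input-function (IDIF) voxel selection anchored to
late venous samples, per-label ROI aggregation of parametric volumes, and the
anterior/middle/posterior subdivision of the putamen by 1-D k-means on
anterior-posterior voxel indices.

CBF maps are consumed as ready-made parametric volumes; no perfusion model is
fitted here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "TimeActivityCurve",
    "PlasmaInputCurve",
    "KiEstimate",
    "LabelVolume",
    "patlak_ki",
    "cmrglu_from_ki",
    "select_idif",
    "aggregate_roi",
    "subdivide_putamen",
    "kmeans_1d",
    "DEFAULT_LUMPED_CONSTANT",
]

#: Lumped constant converting FDG kinetics to glucose kinetics.
DEFAULT_LUMPED_CONSTANT = 0.65


def _as_curve_arrays(times, values):
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != v.shape:
        raise ValueError("times and values must be 1-D arrays of equal length")
    if t.size == 0:
        raise ValueError("empty frame schedule")
    if not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    if not np.all(np.isfinite(v)):
        raise ValueError("curve values must be finite")
    return t, v


@dataclass(frozen=True)
class TimeActivityCurve:
    """Tissue activity concentration (kBq/mL) sampled at frame mid-times (min)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        t, v = _as_curve_arrays(self.times, self.values)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class PlasmaInputCurve:
    """Plasma activity concentration (kBq/mL) on its own sampling grid (min)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        t, v = _as_curve_arrays(self.times, self.values)
        if np.any(v < 0):
            raise ValueError("plasma activity must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class KiEstimate:
    """Patlak fit result: net uptake rate (1/min) plus fit diagnostics."""

    ki: float
    intercept: float
    r2: float
    n_points: int


@dataclass(frozen=True)
class LabelVolume:
    """Integer region labels on a 3-D grid.

    ``ap_axis`` declares which array axis runs anterior-posterior, and
    ``anterior_low`` whether low indices along that axis are anterior.  These
    are metadata the caller must supply; nothing is guessed from headers.
    """

    data: np.ndarray
    names: dict[int, str]
    ap_axis: int = 1
    anterior_low: bool = True

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.ndim != 3 or min(arr.shape) == 0:
            raise ValueError("label volume must be a non-empty 3-D array")
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("label volume must hold integer labels")
        if not 0 <= self.ap_axis <= 2:
            raise ValueError("ap_axis must be 0, 1 or 2")
        object.__setattr__(self, "data", arr)


# ---------------------------------------------------------------------------
# Patlak graphical analysis
# ---------------------------------------------------------------------------

def patlak_ki(tac: TimeActivityCurve, input_fn: PlasmaInputCurve,
              t_star: float = 20.0) -> KiEstimate:
    """Estimate the net FDG uptake rate Ki by Patlak graphical analysis.

    Ordinary least squares of C_tissue(t)/C_p(t) against
    ``integral_0^t C_p dtau / C_p(t)`` over all frames with mid-time >=
    ``t_star``.  The cumulative plasma integral is computed by the trapezoid
    rule on the input curve's own grid and linearly interpolated to the frame
    mid-times.  The slope is Ki (1/min); for an irreversible two-tissue
    system with rates K1, k2, k3 it converges to K1*k3/(k2+k3).

    The default ``t_star`` of 20 min keeps only frames where the reversible
    compartment has equilibrated under typical FDG kinetics; it is
    configurable because the appropriate start time depends on k2+k3.
    """
    mask = tac.times >= t_star
    if int(mask.sum()) < 2:
        raise ValueError(
            f"need >=2 frames at or after t_star={t_star} min, "
            f"got {int(mask.sum())}")
    cum = cumulative_trapezoid(input_fn.values, input_fn.times, initial=0.0)
    cp = np.interp(tac.times[mask], input_fn.times, input_fn.values)
    cum_t = np.interp(tac.times[mask], input_fn.times, cum)
    if np.any(cp <= 0):
        raise ValueError("plasma input is zero/negative at a used frame")
    x = cum_t / cp
    y = tac.values[mask] / cp
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    # a constant y is fitted exactly by slope 0; report r2=1 rather than 0/0
    if ss_tot <= 1e-20 * max(1.0, float(y @ y)):
        r2 = 1.0
    else:
        r2 = max(0.0, 1.0 - ss_res / ss_tot)
    return KiEstimate(ki=float(slope), intercept=float(intercept),
                      r2=min(1.0, r2), n_points=int(mask.sum()))


def cmrglu_from_ki(ki: float, cglu: float,
                   lc: float = DEFAULT_LUMPED_CONSTANT) -> float:
    """CMRglu = Ki * Cglu / LC.

    ``cglu`` is the plasma glucose concentration (mmol/L, from blood samples)
    and ``lc`` the lumped constant accounting for phosphorylation differences
    between glucose and FDG (default 0.65).
    """
    if lc <= 0:
        raise ValueError("lumped constant must be positive")
    if cglu < 0:
        raise ValueError("plasma glucose must be non-negative")
    return ki * cglu / lc


# ---------------------------------------------------------------------------
# Image-derived input function
# ---------------------------------------------------------------------------

def select_idif(dynamic_volume: np.ndarray, frame_times: np.ndarray,
                mip_threshold: float, venous_samples: np.ndarray,
                min_voxels: int = 4) -> PlasmaInputCurve:
    """Simplified image-derived input function selection.

    Candidate voxels are those whose temporal maximum-intensity-projection
    value exceeds ``mip_threshold`` times the global MIP maximum (the bright
    early bolus in the carotids).  From these, voxels are pruned greedily:
    at each step the voxel whose removal most reduces the summed squared
    deviation between the mean candidate curve (interpolated at the venous
    sample times) and the venous values is dropped, stopping when no removal
    improves the fit or when ``min_voxels`` would be violated.  The mean
    curve of the retained voxels is returned.

    This is a deliberately simplified stand-in for full spatiotemporal IDIF
    voxel selection; it reproduces the anchoring of the curve tail to late
    venous samples, where arterial-venous differences are minimal.
    """
    dyn = np.asarray(dynamic_volume, dtype=float)
    if dyn.ndim != 4:
        raise ValueError("dynamic volume must be 4-D (x, y, z, frame)")
    frame_times = np.asarray(frame_times, dtype=float)
    if frame_times.shape != (dyn.shape[-1],):
        raise ValueError("frame_times length must match the frame axis")
    if not 0 < mip_threshold < 1:
        raise ValueError("mip_threshold must be in (0, 1)")
    venous = np.atleast_2d(np.asarray(venous_samples, dtype=float))
    if venous.shape[0] < 3 or venous.shape[1] != 2:
        raise ValueError("need >=3 venous (time, value) samples")
    v_times, v_vals = venous[:, 0], venous[:, 1]
    if v_times.min() < frame_times[0] or v_times.max() > frame_times[-1]:
        raise ValueError("venous samples outside the scan window")

    mip = dyn.max(axis=-1)
    cand = mip > mip_threshold * mip.max()
    if not cand.any():
        raise ValueError("no candidate voxels above the MIP threshold")
    tacs = dyn[cand]                      # n_voxels x n_frames
    n = tacs.shape[0]
    min_voxels = max(1, int(min_voxels))

    def residual(curve_sum: np.ndarray, count: int) -> float:
        mean = curve_sum / count
        at_samples = np.interp(v_times, frame_times, mean)
        d = at_samples - v_vals
        return float(d @ d)

    keep = np.ones(n, dtype=bool)
    total = tacs.sum(axis=0)
    best = residual(total, n)
    while keep.sum() > min_voxels:
        idx = np.flatnonzero(keep)
        trials = [(residual(total - tacs[i], keep.sum() - 1), i) for i in idx]
        trial_best, drop = min(trials)
        if trial_best >= best:
            break
        keep[drop] = False
        total = total - tacs[drop]
        best = trial_best
    return PlasmaInputCurve(frame_times, total / keep.sum())


# ---------------------------------------------------------------------------
# ROI aggregation
# ---------------------------------------------------------------------------

def aggregate_roi(volume: np.ndarray, labels: LabelVolume) -> pd.Series:
    """Per-region mean of a parametric volume over a label volume.

    Returns a Series indexed by region name.  Regions whose label is absent
    from the grid are reported as NaN (missing), never as zero.
    """
    vol = np.asarray(volume, dtype=float)
    if vol.shape != labels.data.shape:
        raise ValueError(
            f"grid mismatch: volume {vol.shape} vs labels {labels.data.shape}")
    ids = sorted(labels.names)
    present = {int(l) for l in np.unique(labels.data)}
    out = pd.Series(np.nan, index=[labels.names[i] for i in ids], dtype=float)
    used = [i for i in ids if i in present]
    if used:
        means = ndimage.mean(vol, labels=labels.data, index=used)
        for i, m in zip(used, np.atleast_1d(means)):
            out[labels.names[i]] = m
    return out


# ---------------------------------------------------------------------------
# Putamen subdivision by 1-D k-means
# ---------------------------------------------------------------------------

def kmeans_1d(values: np.ndarray, k: int = 3):
    """Exact 1-D k-means: the globally optimal contiguous partition.

    In one dimension the minimal within-cluster-SS partition is always a set
    of contiguous intervals of the sorted values, so the optimum is found by
    searching cluster boundaries over the distinct values (weighted by their
    multiplicity, with O(1) segment costs from prefix sums).  This is
    deterministic and initialization-free; among equal-cost partitions the
    one with the lowest boundaries (most voxels in later clusters) is kept.
    Returns (assignments ordered by value, sorted cluster means).  Only
    k = 3 is needed here and supported.
    """
    if k != 3:
        raise ValueError("only k=3 is supported")
    v = np.asarray(values, dtype=float)
    uniq, counts = np.unique(v, return_counts=True)
    u = uniq.size
    if u < k:
        raise ValueError(f"need >= {k} distinct values for {k} clusters")
    cw = np.concatenate([[0.0], np.cumsum(counts)])             # weights
    cs = np.concatenate([[0.0], np.cumsum(counts * uniq)])      # sums
    cq = np.concatenate([[0.0], np.cumsum(counts * uniq ** 2)])  # squares

    def seg_cost(i, j):
        # within-SS of distinct values [i, j) with multiplicities
        w = cw[j] - cw[i]
        s = cs[j] - cs[i]
        return (cq[j] - cq[i]) - s * s / w

    best, best_cost = None, np.inf
    for b1 in range(1, u - 1):
        c1 = seg_cost(0, b1)
        if c1 >= best_cost:
            continue
        for b2 in range(b1 + 1, u):
            cost = c1 + seg_cost(b1, b2) + seg_cost(b2, u)
            if cost < best_cost - 1e-12:
                best_cost, best = cost, (b1, b2)
    b1, b2 = best
    cluster_of_value = np.zeros(u, dtype=int)
    cluster_of_value[b1:b2] = 1
    cluster_of_value[b2:] = 2
    assign = cluster_of_value[np.searchsorted(uniq, v)]
    centers = np.array([(cs[b1] - cs[0]) / (cw[b1] - cw[0]),
                        (cs[b2] - cs[b1]) / (cw[b2] - cw[b1]),
                        (cs[u] - cs[b2]) / (cw[u] - cw[b2])])
    return assign, centers


def subdivide_putamen(labels: LabelVolume, putamen_label: int) -> LabelVolume:
    """Split a putamen ROI into anterior/middle/posterior thirds.

    1-D k-means (k=3) is run on the anterior-posterior voxel indices of the
    putamen segmentation; the three clusters become new labels named
    ``<name>_anterior``, ``<name>_middle``, ``<name>_posterior`` ordered along
    the declared AP axis.  Pathology gradients along this axis motivate the
    subdivision.
    """
    if putamen_label not in labels.names:
        raise KeyError(f"label {putamen_label} not in the label map")
    coords = np.nonzero(labels.data == putamen_label)
    ap = coords[labels.ap_axis].astype(float)
    if np.unique(ap).size < 3:
        raise ValueError("fewer than 3 distinct anterior-posterior indices")
    # work in a coordinate where "more anterior" is "smaller", so cluster 0 is
    # always the anterior third and assignment ties resolve anteriorly
    assign, _ = kmeans_1d(ap if labels.anterior_low else -ap, k=3)

    base = labels.names[putamen_label]
    new_ids = [max(labels.names) + 1 + j for j in range(3)]
    part_names = ["anterior", "middle", "posterior"]
    names = {i: n for i, n in labels.names.items() if i != putamen_label}
    for nid, part in zip(new_ids, part_names):
        names[nid] = f"{base}_{part}"

    data = labels.data.copy()
    flat_idx = tuple(c for c in coords)
    data[flat_idx] = np.asarray(new_ids)[assign]
    return replace(labels, data=data, names=names)
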