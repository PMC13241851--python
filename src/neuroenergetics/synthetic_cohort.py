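"""Synthetic cohorts with the statistical structure the analysis assumes.

The generative model is log-additive: for subject ``i``, region ``r`` and
modality ``m`` (CMRglu or CBF),

    log value[i, m, r] = g_i + b[m, r] + e_i * P[m, r] + noise

where ``g_i`` is a per-subject global factor (multiplicative on the linear
scale), ``b`` a region-specific baseline profile, ``P`` a unit-norm planted
spatial pattern and ``e_i`` its expression, varying linearly with age plus an
optional extra offset for the older (> cutoff) group.  Concordant plants put
the same pattern into both modalities (an energy-production effect, visible
to rEP); discordant plants put +P into CMRglu and -P into CBF (an aerobic
glycolysis effect, visible to rAG).  A log-additive model is used so that
multiplicative per-subject global scaling aligns with the additive demeaning
the downstream residual analysis performs.

All randomness flows from a single integer seed through named
``numpy.random.SeedSequence`` children; the stream order (baselines, pattern,
ages, global factors, CMRglu noise, CBF noise) is fixed, so a given seed
always yields bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .quantification import PlasmaInputCurve, TimeActivityCurve

__all__ = [
    "CohortConfig",
    "RegionalDataset",
    "DiseasePattern",
    "GammaInputModel",
    "generate_regional_cohort",
    "generate_tacs",
    "generate_disease_pattern",
    "default_frame_times",
    "REGION_GROUPS",
]

REGION_GROUPS = (
    "basal_ganglia", "cerebellum", "frontal", "parietal",
    "occipital", "temporal", "limbic", "other",
)

# stream indices for SeedSequence children (documented stream order)
_STREAMS = {"baseline": 0, "pattern": 1, "ages": 2, "global": 3,
            "noise_cmrglu": 4, "noise_cbf": 5, "tacs": 6, "disease": 7}


def _child_rng(seed: int, stream: str) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],))
    return np.random.default_rng(ss)


@dataclass(frozen=True)
class CohortConfig:
    """Generative settings for a regional cohort.

    Defaults emulate the study conditions: 24 healthy subjects aged 35-80,
    97 regions, and an age-linked planted pattern.  ``age_slope`` is in
    expression units (log-scale pattern amplitude) per year; the default
    makes the planted topography clearly recoverable at the default regional
    noise (see the methods note), yielding a strong age effect.
    ``noise_sd`` and ``global_scale_sd`` are log-scale standard deviations.
    """

    n_subjects: int = 24
    n_regions: int = 97
    age_range: tuple[float, float] = (35.0, 80.0)
    baseline_profile: dict[str, np.ndarray] | None = None
    planted_pattern: np.ndarray | None = None
    pattern_mode: str = "concordant"        # concordant | discordant | none
    age_slope: float = 0.15
    group_effect: float = 0.0
    group_cutoff: float = 60.0
    noise_sd: float = 0.3
    global_scale_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 4:
            raise ValueError("need at least 4 subjects")
        if self.n_regions < 3:
            raise ValueError("need at least 3 regions")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must satisfy min < max")
        if self.pattern_mode not in ("concordant", "discordant", "none"):
            raise ValueError(f"unknown pattern_mode {self.pattern_mode!r}")
        for name in ("age_slope", "group_effect", "noise_sd",
                     "global_scale_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.noise_sd < 0 or self.global_scale_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.planted_pattern is not None:
            p = np.asarray(self.planted_pattern, dtype=float)
            if p.shape != (self.n_regions,):
                raise ValueError("planted_pattern length must equal n_regions")
            if self.pattern_mode != "none" and not np.isclose(
                    np.linalg.norm(p), 1.0, atol=1e-8):
                raise ValueError("planted_pattern must have unit norm")
            object.__setattr__(self, "planted_pattern", p)
        if self.baseline_profile is not None:
            for mod in ("cmrglu", "cbf"):
                b = np.asarray(self.baseline_profile[mod], dtype=float)
                if b.shape != (self.n_regions,):
                    raise ValueError(
                        f"baseline profile for {mod} must have n_regions entries")
                if not np.all(np.isfinite(b)):
                    raise ValueError("baseline profiles must be finite")


@dataclass(frozen=True)
class RegionalDataset:
    """Subjects x regions values for both modalities plus subject metadata."""

    cmrglu: np.ndarray          # subjects x regions, positive (umol/100 g/min scale)
    cbf: np.ndarray             # subjects x regions, positive (mL/100 g/min scale)
    ages: np.ndarray            # years
    sex: np.ndarray             # 0/1 code
    region_names: list[str]
    region_groups: dict[str, str] = field(default_factory=dict)
    subject_ids: list[str] | None = None

    def __post_init__(self):
        cm = np.asarray(self.cmrglu, dtype=float)
        cb = np.asarray(self.cbf, dtype=float)
        if cm.ndim != 2 or cm.shape != cb.shape:
            raise ValueError("cmrglu and cbf must be equal-shape 2-D matrices")
        for name, arr in (("cmrglu", cm), ("cbf", cb)):
            if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
                raise ValueError(f"{name} must contain finite positive values")
        if len(self.region_names) != cm.shape[1]:
            raise ValueError("region_names length mismatch")
        if len(set(self.region_names)) != len(self.region_names):
            raise ValueError("duplicate region names")
        ages = np.asarray(self.ages, dtype=float)
        sex = np.asarray(self.sex, dtype=int)
        if ages.shape != (cm.shape[0],) or sex.shape != (cm.shape[0],):
            raise ValueError("ages/sex length must equal number of subjects")
        ids = self.subject_ids or [f"sub-{i + 1:03d}" for i in range(cm.shape[0])]
        if len(ids) != cm.shape[0]:
            raise ValueError("subject_ids length mismatch")
        object.__setattr__(self, "cmrglu", cm)
        object.__setattr__(self, "cbf", cb)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "sex", sex)
        object.__setattr__(self, "subject_ids", list(ids))

    @property
    def n_subjects(self) -> int:
        return self.cmrglu.shape[0]

    @property
    def n_regions(self) -> int:
        return self.cmrglu.shape[1]


@dataclass(frozen=True)
class DiseasePattern:
    """Regionalized disease-related pattern (rDRP) and group mean profile (rGMP)."""

    region_names: list[str]
    rdrp: np.ndarray
    rgmp: np.ndarray
    label: str = "synthetic"

    def __post_init__(self):
        w = np.asarray(self.rdrp, dtype=float)
        g = np.asarray(self.rgmp, dtype=float)
        if w.ndim != 1 or w.shape != g.shape or len(self.region_names) != w.size:
            raise ValueError("rdrp/rgmp/region_names lengths must agree")
        if not (np.all(np.isfinite(w)) and np.all(np.isfinite(g))):
            raise ValueError("pattern values must be finite")
        if np.allclose(w, 0):
            raise ValueError("degenerate all-zero pattern weights")
        object.__setattr__(self, "rdrp", w)
        object.__setattr__(self, "rgmp", g)


def _default_baselines(n_regions: int, seed: int) -> dict[str, np.ndarray]:
    rng = _child_rng(seed, "baseline")
    # grey-matter-like means: CMRglu ~ 30 umol/100 g/min, CBF ~ 45 mL/100 g/min,
    # with ~25% regional spread on the log scale
    return {
        "cmrglu": np.log(30.0) + 0.25 * rng.standard_normal(n_regions),
        "cbf": np.log(45.0) + 0.25 * rng.standard_normal(n_regions),
    }


def _default_pattern(n_regions: int, seed: int) -> np.ndarray:
    rng = _child_rng(seed, "pattern")
    p = rng.standard_normal(n_regions)
    return p / np.linalg.norm(p)


def _region_names(n_regions: int) -> tuple[list[str], dict[str, str]]:
    names = [f"region_{i + 1:03d}" for i in range(n_regions)]
    groups = {n: REGION_GROUPS[i % len(REGION_GROUPS)]
              for i, n in enumerate(names)}
    return names, groups


def generate_regional_cohort(config: CohortConfig) -> RegionalDataset:
    """Draw a cohort from the log-additive generative model.

    Ages are uniform over ``age_range``; sex alternates 0/1 (balanced).
    Pattern expression for subject ``i`` is
    ``age_slope * (age_i - mean age) + group_effect * [age_i > cutoff]``.
    Deterministic given ``config.seed``.
    """
    n, m = config.n_subjects, config.n_regions
    baselines = config.baseline_profile or _default_baselines(m, config.seed)
    if config.pattern_mode == "none":
        pattern = np.zeros(m)
    elif config.planted_pattern is not None:
        pattern = config.planted_pattern
    else:
        pattern = _default_pattern(m, config.seed)

    ages = _child_rng(config.seed, "ages").uniform(*config.age_range, size=n)
    sex = np.arange(n) % 2
    expr = config.age_slope * (ages - ages.mean())
    expr = expr + config.group_effect * (ages > config.group_cutoff)

    glob = config.global_scale_sd * _child_rng(
        config.seed, "global").standard_normal(n)
    sign = {"concordant": {"cmrglu": 1.0, "cbf": 1.0},
            "discordant": {"cmrglu": 1.0, "cbf": -1.0},
            "none": {"cmrglu": 0.0, "cbf": 0.0}}[config.pattern_mode]

    mats = {}
    for mod in ("cmrglu", "cbf"):
        noise = config.noise_sd * _child_rng(
            config.seed, f"noise_{mod}").standard_normal((n, m))
        log_vals = (glob[:, None]
                    + np.asarray(baselines[mod], dtype=float)[None, :]
                    + sign[mod] * np.outer(expr, pattern)
                    + noise)
        mats[mod] = np.exp(log_vals)

    names, groups = _region_names(m)
    return RegionalDataset(cmrglu=mats["cmrglu"], cbf=mats["cbf"], ages=ages,
                           sex=sex, region_names=names, region_groups=groups)


# ---------------------------------------------------------------------------
# Dynamic data: two-tissue-compartment TACs with a gamma-variate input
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GammaInputModel:
    """Gamma-variate plasma bolus plus a slow washout tail.

    ``Cp(t) = peak * (t/t_peak)^alpha * exp(alpha * (1 - t/t_peak))
              + peak * tail_frac * (1 - exp(-t/t_peak)) * exp(-t/tail_tau)``

    The first term is a normalized gamma variate peaking at ``t_peak``
    (default ~1 min post-injection); the second keeps plasma activity
    realistically non-zero at late times where venous samples are drawn.
    """

    peak: float = 100.0           # kBq/mL at the bolus peak
    t_peak: float = 1.0           # min
    alpha: float = 3.0
    tail_frac: float = 0.1
    tail_tau: float = 80.0        # min

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        with np.errstate(invalid="ignore"):
            rel = np.where(t > 0, t / self.t_peak, 0.0)
            bolus = np.where(
                t > 0, rel ** self.alpha * np.exp(self.alpha * (1.0 - rel)), 0.0)
        tail = (1.0 - np.exp(-np.maximum(t, 0.0) / self.t_peak)) \
            * np.exp(-np.maximum(t, 0.0) / self.tail_tau)
        return self.peak * (bolus + self.tail_frac * tail)


def default_frame_times() -> np.ndarray:
    """Frame mid-times (min) of a 4x1, 3x2, 8x5, 1x10 min dynamic schedule."""
    durations = [1.0] * 4 + [2.0] * 3 + [5.0] * 8 + [10.0]
    ends = np.cumsum(durations)
    starts = ends - durations
    return (starts + ends) / 2.0


def generate_tacs(kinetics, input_model: GammaInputModel | None = None,
                  frame_times: np.ndarray | None = None,
                  noise_sd: float = 0.0, seed: int = 0,
                  input_dt: float = 0.05):
    """Simulate irreversible two-tissue-compartment tissue curves.

    ``kinetics`` is a sequence of (K1, k2, k3) rate triples (1/min).  The
    free compartment obeys ``dC1/dt = K1*Cp - (k2+k3)*C1`` and the trapped
    one ``dC2/dt = k3*C1``; both are integrated on a fine time grid
    (trapezoidal convolution with the exact exponential kernel) and the
    tissue curve ``C1+C2`` is sampled at the frame mid-times.  Optional
    Gaussian noise of absolute SD ``noise_sd`` is added per frame.

    Returns ``(list of TimeActivityCurve, PlasmaInputCurve)``; the plasma
    curve is tabulated on the fine grid for downstream integration.
    """
    input_model = input_model or GammaInputModel()
    if frame_times is None:
        frame_times = default_frame_times()
    frame_times = np.asarray(frame_times, dtype=float)
    if frame_times.size == 0:
        raise ValueError("empty frame schedule")
    if not np.all(np.diff(frame_times) > 0):
        raise ValueError("frame times must be strictly increasing")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")

    t_end = frame_times[-1]
    grid = np.arange(0.0, t_end + input_dt, input_dt)
    cp = input_model(grid)
    rng = _child_rng(seed, "tacs")

    curves = []
    for K1, k2, k3 in np.atleast_2d(np.asarray(kinetics, dtype=float)):
        if min(K1, k2, k3) < 0:
            raise ValueError("rate constants must be non-negative")
        lam = k2 + k3
        # C1 = K1 * Cp (x) exp(-lam t): exact one-step exponential update with
        # trapezoidal treatment of Cp within each dt
        c1 = np.zeros_like(grid)
        decay = np.exp(-lam * input_dt)
        for j in range(1, grid.size):
            c1[j] = c1[j - 1] * decay + K1 * input_dt * 0.5 * (
                cp[j] + cp[j - 1] * decay)
        c2 = k3 * cumulative_trapezoid(c1, grid, initial=0.0)
        tissue = np.interp(frame_times, grid, c1 + c2)
        if noise_sd > 0:
            tissue = tissue + noise_sd * rng.standard_normal(tissue.shape)
        curves.append(TimeActivityCurve(frame_times, tissue))
    return curves, PlasmaInputCurve(grid, cp)


# ---------------------------------------------------------------------------
# Toy disease-related patterns
# ---------------------------------------------------------------------------

def generate_disease_pattern(region_names, seed: int = 0,
                             label: str = "synthetic",
                             reference: np.ndarray | None = None,
                             overlap: float | None = None) -> DiseasePattern:
    """Random unit-norm rDRP weights plus a compatible rGMP profile.

    With ``reference`` and ``overlap`` given, the weights are built by
    Gram-Schmidt mixing so that their *sample* Pearson correlation with the
    reference equals ``2*sin(pi*overlap/6)`` — the bivariate-normal value
    whose Spearman rank correlation is ``overlap`` — giving a rank overlap
    close to the request.  Deterministic given ``seed``.
    """
    region_names = list(region_names)
    m = len(region_names)
    if m < 3:
        raise ValueError("need at least 3 regions")
    rng = _child_rng(seed, "disease")
    raw = rng.standard_normal(m)
    if reference is not None:
        ref = np.asarray(reference, dtype=float)
        if ref.shape != (m,):
            raise ValueError("reference pattern length mismatch")
        if overlap is None or not -1.0 < overlap < 1.0:
            raise ValueError("overlap must be in (-1, 1) when reference given")
        r = 2.0 * np.sin(np.pi * overlap / 6.0)
        u1 = ref - ref.mean()
        u1 = u1 / np.linalg.norm(u1)
        u2 = raw - raw.mean()
        u2 = u2 - (u2 @ u1) * u1
        u2 = u2 / np.linalg.norm(u2)
        raw = r * u1 + np.sqrt(1.0 - r * r) * u2
    w = raw / np.linalg.norm(raw)
    rgmp = np.log(30.0) + 0.25 * rng.standard_normal(m)
    return DiseasePattern(region_names=region_names, rdrp=w, rgmp=rgmp,
                          label=label)
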