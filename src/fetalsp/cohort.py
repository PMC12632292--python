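"""Synthetic fetal cohort generator with closed-form ground truth.

Emulates the statistical structure of a cross-sectional fetal MRI study of
subplate (SP) morphometry: 68 fetuses spanning 22-32 weeks gestational age
(GA), with per-region, per-hemisphere SP thickness / surface area / volume /
depth following GA-dependent growth laws (linear or quadratic), a
brain-volume size scaling, planted hemispheric asymmetries, multiplicative
Gaussian noise, and a small fraction of gross outlier rows.

Every generated cohort carries a :class:`GroundTruth` with the planted
trajectory parameters, trimester percent changes, asymmetry indices, and
growth-archetype (cluster) labels, so each downstream stage of the analysis
can be validated against known answers.

Growth laws are expressed as shape polynomials in ``t = GA - 22`` with
value 1 at 22 wGA, scaled by a per-region baseline; the rate curves used for
clustering depend only on the shape, never on the baseline scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .regions import ANALYSIS_METRICS, HEMISPHERES, METRICS, REGIONS_17, validate_regions

__all__ = [
    "GrowthLaw",
    "CohortConfig",
    "GroundTruth",
    "CohortResult",
    "make_default_config",
    "generate_cohort",
]


@dataclass(frozen=True)
class GrowthLaw:
    """Shape polynomial ``1 + b*t + c*t**2`` in ``t = GA - 22`` weeks."""

    name: str
    b: float
    c: float = 0.0

    @property
    def degree(self) -> int:
        return 2 if self.c != 0.0 else 1

    def __call__(self, ga: np.ndarray) -> np.ndarray:
        t = np.asarray(ga, dtype=float) - 22.0
        return 1.0 + self.b * t + self.c * t * t

    def mean_on(self, lo: float, hi: float) -> float:
        """Exact mean of the shape over GA uniform on [lo, hi]."""
        t0, t1 = lo - 22.0, hi - 22.0
        et = 0.5 * (t0 + t1)
        et2 = (t1**3 - t0**3) / (3.0 * (t1 - t0))
        return 1.0 + self.b * et + self.c * et2

    def raw_coefficients(self, scale: float = 1.0) -> np.ndarray:
        """Coefficients of ``scale * shape`` in the raw GA basis (low first)."""
        b, c = self.b, self.c
        # 1 + b(g-22) + c(g-22)^2 = (1 - 22b + 484c) + (b - 44c) g + c g^2
        return scale * np.array([1.0 - 22.0 * b + 484.0 * c, b - 44.0 * c, c])


# Archetype shapes per metric. Early shapes decelerate (concave), late shapes
# accelerate (convex); coefficients chosen so trimester percent changes land
# in realistic ranges (thickness ~ 30-45%, area ~ 64% and uniform,
# volume ~ 70-95%).
ARCHETYPES: dict[str, dict[int, GrowthLaw]] = {
    "thickness": {
        1: GrowthLaw("early", 0.160, -0.004),
        2: GrowthLaw("steady", 0.0969),
        3: GrowthLaw("late", 0.0282, 0.004),
    },
    "area": {
        1: GrowthLaw("late_steep", 0.0569, 0.010),
        2: GrowthLaw("late_mid", 0.08315, 0.008),
        3: GrowthLaw("late_shallow", 0.1094, 0.006),
    },
    "volume": {
        1: GrowthLaw("early", 0.297, -0.006),
        2: GrowthLaw("late_high", 0.2978, 0.004),
        3: GrowthLaw("late", 0.1367, 0.009),
    },
    "depth": {1: GrowthLaw("steady", 0.05)},
}

_THICK = {
    "superior_frontal": 1, "paracentral_lobule": 1, "lingual": 1, "cuneus": 1,
    "middle_frontal": 3, "inferior_frontal": 3, "superior_parietal": 3,
    "inferior_parietal": 3, "supramarginal": 3, "precuneus": 3,
}
_AREA = {
    "superior_frontal": 1, "middle_frontal": 1, "inferior_frontal": 1,
    "precentral": 1,
    "postcentral": 2, "paracentral_lobule": 2, "superior_parietal": 2,
    "inferior_parietal": 2, "supramarginal": 2, "superior_temporal": 2,
    "middle_temporal": 2,
}
_VOL = {
    "postcentral": 1, "middle_temporal": 1, "precentral": 1,
    "paracentral_lobule": 1,
    "superior_parietal": 2, "inferior_parietal": 2, "supramarginal": 2,
    "lateral_occipital": 2, "inferior_temporal": 2, "fusiform": 2,
}


def _default_clusters() -> dict[str, dict[str, int]]:
    out: dict[str, dict[str, int]] = {}
    for metric, table, other in (
        ("thickness", _THICK, 2),
        ("area", _AREA, 3),
        ("volume", _VOL, 3),
    ):
        out[metric] = {r: table.get(r, other) for r in REGIONS_17}
    out["depth"] = {r: 1 for r in REGIONS_17}
    return out


def _default_asymmetry() -> dict[str, dict[str, float]]:
    """Planted asymmetry index (%) per metric x region; positive = rightward."""
    ai: dict[str, dict[str, float]] = {m: {r: 0.0 for r in REGIONS_17} for m in METRICS}
    ai["thickness"].update({
        "middle_frontal": 18.0, "postcentral": 15.0, "fusiform": 8.0,
        "precuneus": -16.0, "superior_temporal": -15.0, "inferior_parietal": -5.0,
    })
    ai["area"].update({
        "middle_frontal": 16.0, "inferior_frontal": 15.0, "lingual": 6.0,
        "supramarginal": -15.0, "precuneus": -8.0,
    })
    ai["volume"].update({
        "postcentral": 16.0, "lingual": 15.0, "middle_frontal": 10.0,
        "precuneus": -20.0, "precentral": -15.0, "inferior_parietal": -8.0,
    })
    return ai


# Size-allometry exponents: how each measure scales with the subject's
# residual (GA-independent) brain-size deviation.
SIZE_EXPONENTS = {"volume": 1.0, "area": 2.0 / 3.0, "thickness": 1.0 / 3.0,
                  "depth": 1.0 / 3.0}

#: Supratentorial brain-volume law, mm^3 vs GA (quadratic, ~60 mL at 22 wGA
#: to ~250 mL at 32 wGA).
BRAIN_VOLUME_LAW = GrowthLaw("brain", 12000.0 / 60000.0, 700.0 / 60000.0)
BRAIN_VOLUME_SCALE = 60000.0


@dataclass
class CohortConfig:
    """Full specification of a synthetic cohort; defaults are the study
    conditions (68 fetuses, 22-32 wGA, 10% measurement CV, 3% gross
    outliers)."""

    n_subjects: int = 68
    ga_range: tuple[float, float] = (22.0, 32.0)
    region_names: tuple[str, ...] = REGIONS_17
    cluster_assignment: dict[str, dict[str, int]] = field(default_factory=_default_clusters)
    archetypes: dict[str, dict[int, GrowthLaw]] = field(default_factory=lambda: dict(ARCHETYPES))
    asymmetry_offsets: dict[str, dict[str, float]] = field(default_factory=_default_asymmetry)
    #: per-metric measurement noise as coefficient of variation
    noise_cv: dict[str, float] = field(
        default_factory=lambda: {m: 0.10 for m in METRICS})
    brain_volume_cv: float = 0.05
    outlier_fraction: float = 0.03
    sex_volume_effect: float = 0.0  # fractional male brain-volume offset
    group_boundary: float = 27.0
    seed: int = 1

    def validate(self) -> "CohortConfig":
        if self.n_subjects < 10:
            raise ValueError("n_subjects must be >= 10 for group statistics")
        lo, hi = self.ga_range
        if not (22.0 <= lo < hi <= 32.0):
            raise ValueError("ga_range must lie within [22, 32] weeks")
        if not (0.0 <= self.outlier_fraction < 0.25):
            raise ValueError(
                "outlier_fraction must be < 0.25 (RANSAC 75% inclusion)")
        validate_regions(self.region_names)
        for m in METRICS:
            for r in self.region_names:
                a = self.cluster_assignment[m][r]
                if a not in self.archetypes[m]:
                    raise ValueError(f"unknown archetype {a} for {m}/{r}")
        return self

    def noiseless(self) -> "CohortConfig":
        """Copy with all noise, outliers, and asymmetry-free jitter off."""
        return replace(
            self,
            noise_cv={m: 0.0 for m in METRICS},
            brain_volume_cv=0.0,
            outlier_fraction=0.0,
        )


@dataclass
class GroundTruth:
    """Planted answers for a generated cohort.

    percent_change columns: exact (uniform-GA closed form) and conditional
    (means over the realized GA draws — what a perfect, noise-free analysis
    of this sample recovers).
    """

    trajectory_params: pd.DataFrame   # region, hemisphere, metric, c0, c1, c2, degree
    percent_change: pd.DataFrame      # region, metric, pc_exact, pc_conditional
    asymmetry: pd.DataFrame           # region, metric, ai_percent
    cluster_labels: pd.DataFrame      # region, metric, archetype


@dataclass
class CohortResult:
    subjects: pd.DataFrame
    measures: pd.DataFrame
    truth: GroundTruth
    config: CohortConfig


def _draw_subjects(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_subjects
    ga = rng.uniform(cfg.ga_range[0], cfg.ga_range[1], size=n)
    sex = rng.choice(["M", "F", "unknown"], size=n, p=[0.50, 0.47, 0.03])
    size_dev = rng.normal(0.0, cfg.brain_volume_cv, size=n)
    bv = BRAIN_VOLUME_SCALE * BRAIN_VOLUME_LAW(ga) * (1.0 + size_dev)
    bv = bv * (1.0 + cfg.sex_volume_effect * (sex == "M"))
    return pd.DataFrame({
        "subject_id": [f"sub{i:03d}" for i in range(n)],
        "ga_weeks": ga,
        "sex": sex,
        "brain_volume_mm3": bv,
        "_size_dev": size_dev,
    })


def _region_scales(cfg: CohortConfig) -> dict[str, dict[str, float]]:
    """Deterministic per-region baseline scales (value at 22 wGA).

    Spread around field-realistic magnitudes: thickness ~2.3 mm, regional
    area ~700 mm^2, regional volume ~1200 mm^3, depth ~3 mm. A fixed internal
    RNG makes the spread non-monotone in region order yet reproducible.
    """
    base = {"thickness": 2.3, "area": 700.0, "volume": 1200.0, "depth": 3.0}
    r = np.random.default_rng(20240622)
    out: dict[str, dict[str, float]] = {m: {} for m in METRICS}
    for m in METRICS:
        mult = r.uniform(0.6, 1.5, size=len(cfg.region_names))
        for name, f in zip(cfg.region_names, mult):
            out[m][name] = base[m] * float(f)
    return out


def _ground_truth(cfg: CohortConfig, ga: np.ndarray,
                  scales: dict[str, dict[str, float]]) -> GroundTruth:
    lo, hi, g = cfg.ga_range[0], cfg.ga_range[1], cfg.group_boundary
    in1 = ga <= g
    rows_t, rows_pc, rows_ai, rows_cl = [], [], [], []
    for m in METRICS:
        for r in cfg.region_names:
            law = cfg.archetypes[m][cfg.cluster_assignment[m][r]]
            ai = cfg.asymmetry_offsets[m][r]
            scale = scales[m][r]
            for h in HEMISPHERES:
                factor = 1.0 + (1 if h == "R" else -1) * ai / 200.0
                c = law.raw_coefficients(scale * factor)
                rows_t.append((r, h, m, c[0], c[1], c[2], law.degree))
            m1x, m2x = law.mean_on(lo, g), law.mean_on(g, hi)
            m1c = float(law(ga[in1]).mean())
            m2c = float(law(ga[~in1]).mean())
            rows_pc.append((r, m, 100.0 * (m2x - m1x) / m1x,
                            100.0 * (m2c - m1c) / m1c))
            rows_ai.append((r, m, ai))
            rows_cl.append((r, m, cfg.cluster_assignment[m][r]))
    return GroundTruth(
        trajectory_params=pd.DataFrame(
            rows_t, columns=["region", "hemisphere", "metric",
                             "c0", "c1", "c2", "degree"]),
        percent_change=pd.DataFrame(
            rows_pc, columns=["region", "metric", "pc_exact", "pc_conditional"]),
        asymmetry=pd.DataFrame(rows_ai, columns=["region", "metric", "ai_percent"]),
        cluster_labels=pd.DataFrame(rows_cl, columns=["region", "metric", "archetype"]),
    )


def generate_cohort(config: CohortConfig) -> CohortResult:
    """Generate a cohort: subject table, long measure table, ground truth.

    Each measure value is
    ``scale_region * shape_archetype(GA) * size_scaling * (1 +/- AI/200)``
    with multiplicative Gaussian noise; a fraction of rows is replaced by
    gross deviates (>= 5 noise SD from the clean value). Deterministic for a
    given config (``config.seed`` drives every draw).
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)
    subjects = _draw_subjects(cfg, rng)
    ga = subjects["ga_weeks"].to_numpy()
    size_dev = subjects.pop("_size_dev").to_numpy()
    scales = _region_scales(cfg)
    truth = _ground_truth(cfg, ga, scales)

    n = cfg.n_subjects
    recs = []
    for m in METRICS:
        cv = cfg.noise_cv[m]
        gamma = SIZE_EXPONENTS[m]
        size_factor = (1.0 + size_dev) ** gamma
        for r in cfg.region_names:
            law = cfg.archetypes[m][cfg.cluster_assignment[m][r]]
            ai = cfg.asymmetry_offsets[m][r]
            base = scales[m][r] * law(ga) * size_factor
            for h in HEMISPHERES:
                factor = 1.0 + (1 if h == "R" else -1) * ai / 200.0
                clean = base * factor
                value = clean * (1.0 + rng.normal(0.0, cv, size=n))
                if cfg.outlier_fraction > 0.0:
                    is_out = rng.random(n) < cfg.outlier_fraction
                    mag = rng.uniform(5.0, 8.0, size=n) * max(cv, 0.05)
                    sign = rng.choice([-1.0, 1.0], size=n)
                    value = np.where(is_out, clean * (1.0 + sign * mag), value)
                recs.append(pd.DataFrame({
                    "subject_id": subjects["subject_id"],
                    "region": r,
                    "hemisphere": h,
                    "metric": m,
                    "value": value,
                }))
    measures = pd.concat(recs, ignore_index=True)
    return CohortResult(subjects=subjects, measures=measures,
                        truth=truth, config=cfg)


def make_default_config(**overrides) -> CohortConfig:
    """The study-condition cohort configuration, optionally overridden."""
    return replace(CohortConfig(), **overrides) if overrides else CohortConfig()


def planted_variance_dataset(n: int = 200, ga_fraction: float = 0.8,
                             seed: int = 0) -> pd.DataFrame:
    """Dataset whose realized GA-explained variance fraction is planted
    exactly.

    The response is a linear GA signal plus noise that is orthogonalized
    against the GA design (intercept + slope) and rescaled so that
    ``||signal||^2 / (||signal||^2 + ||noise||^2) = ga_fraction`` holds in
    the sample, not merely in expectation. An ANCOVA of y on GA therefore
    recovers a partial eta squared of exactly ``ga_fraction`` (up to
    floating point), which pins down the effect-size computation.
    """
    if not (0.0 < ga_fraction < 1.0):
        raise ValueError("ga_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    ga = rng.uniform(22.0, 32.0, size=n)
    sex = rng.choice(["M", "F"], size=n)
    signal = ga - ga.mean()
    X = np.column_stack([np.ones(n), signal])
    noise = rng.normal(size=n)
    noise = noise - X @ np.linalg.lstsq(X, noise, rcond=None)[0]
    noise *= np.sqrt((1.0 - ga_fraction) / ga_fraction
                     * signal @ signal / (noise @ noise))
    return pd.DataFrame({"ga_weeks": ga, "sex": sex,
                         "y": 1.0 + signal + noise})
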