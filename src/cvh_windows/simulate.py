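"""Synthetic longitudinal cohort generator.

Emulates a pooled multi-cohort design of repeated clinical examinations over
ages 8-55.99 years: five cohorts with overlapping baseline-age windows,
subject-level random intercepts and slopes, a continuous piecewise-linear
population mean for the clinical cardiovascular-health (CVH) score with up to
two change points, and additive categorical covariate effects (sex, race,
cohort).  A raw-metric mode emits the underlying clinical measurements (BMI,
blood pressure, cholesterol, glucose) with age/sex-anchored means so the
scoring module can be exercised end to end.

The ``paper2021`` preset encodes the published adjusted-model estimates as
ground truth (change points at 16.9 and 37.2 years; segment slopes 0.01,
-0.07, -0.08 points/year) over a five-cohort design whose sampling fractions
follow the pooled cohort's composition.  Variance components are calibration
choices (documented in docs/methods.md) targeting the published baseline
mean (SD) clinical CVH score of 6.9 (1.2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TrueModel",
    "CohortDesign",
    "GeneratorConfig",
    "ConfigError",
    "generate_scores",
    "generate_raw_metrics",
    "preset",
    "AGE_MIN",
    "AGE_MAX",
    "SCORE_COLUMNS",
]

AGE_MIN = 8.0
AGE_MAX = 55.99

#: canonical long-format CSV schema (unused columns left empty)
SCORE_COLUMNS = [
    "subject_id", "cohort", "sex", "race", "age",
    "bmi", "bmi_pct", "sbp", "dbp", "bp_pct",
    "total_chol", "glucose", "bp_med", "lipid_med", "glucose_med",
    "cvh_score",
]


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class TrueModel:
    """Ground-truth population model for the clinical CVH score.

    The population mean is continuous piecewise-linear in age starting at
    ``intercept_at_age8`` points at age 8, with slope ``segment_slopes[k]``
    (points/year) between consecutive change points ``psi``.  Random effects
    are a bivariate-normal intercept (at age 8) and slope per subject;
    ``resid_sd`` is visit-level noise.
    """

    intercept_at_age8: float
    psi: tuple[float, ...] = ()
    segment_slopes: tuple[float, ...] = (0.0,)
    covariate_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    re_sd_intercept: float = 0.0
    re_sd_slope: float = 0.0
    re_corr: float = 0.0
    resid_sd: float = 0.0

    def __post_init__(self) -> None:
        psi = tuple(float(p) for p in self.psi)
        if list(psi) != sorted(set(psi)):
            raise ConfigError("change points must be strictly increasing")
        if any(not (AGE_MIN < p < AGE_MAX) for p in psi):
            raise ConfigError(f"change points must lie inside ({AGE_MIN}, {AGE_MAX})")
        if len(self.segment_slopes) != len(psi) + 1:
            raise ConfigError("need exactly one slope per segment (|psi| + 1)")
        if self.re_sd_intercept < 0 or self.re_sd_slope < 0 or self.resid_sd < 0:
            raise ConfigError("standard deviations must be nonnegative")
        if abs(self.re_corr) > 1:
            raise ConfigError("|re_corr| must be <= 1")

    def mean_score(self, age):
        """Population-mean score mu(age), continuous at every change point."""
        age = np.asarray(age, dtype=float)
        out = np.full(age.shape, self.intercept_at_age8, dtype=float)
        knots = (AGE_MIN, *self.psi)
        for k, slope in enumerate(self.segment_slopes):
            lo = knots[k]
            hi = self.psi[k] if k < len(self.psi) else np.inf
            out += slope * np.clip(age - lo, 0.0, hi - lo)
        return out if out.shape else float(out)

    def re_cov(self) -> np.ndarray:
        c = self.re_corr * self.re_sd_intercept * self.re_sd_slope
        return np.array([
            [self.re_sd_intercept ** 2, c],
            [c, self.re_sd_slope ** 2],
        ])


@dataclass(frozen=True)
class CohortDesign:
    """Sampling design of one cohort: baseline window and visit schedule."""

    name: str
    n_subjects: int
    baseline_age_range: tuple[float, float]
    visit_interval: float
    n_visits: int
    sex_p: float = 0.5  # probability female
    race_levels: dict[str, float] = field(default_factory=lambda: {"White": 1.0})

    def __post_init__(self) -> None:
        lo, hi = self.baseline_age_range
        if not (AGE_MIN <= lo <= hi <= AGE_MAX):
            raise ConfigError(
                f"cohort {self.name!r}: baseline ages must lie in [{AGE_MIN}, {AGE_MAX}]"
            )
        if self.n_subjects < 1:
            raise ConfigError(f"cohort {self.name!r}: n_subjects must be >= 1")
        if self.visit_interval <= 0:
            raise ConfigError(f"cohort {self.name!r}: visit_interval must be > 0")
        if not 0.0 <= self.sex_p <= 1.0:
            raise ConfigError(f"cohort {self.name!r}: sex_p must be a probability")
        tot = sum(self.race_levels.values())
        if not np.isclose(tot, 1.0):
            raise ConfigError(f"cohort {self.name!r}: race probabilities must sum to 1")


@dataclass(frozen=True)
class GeneratorConfig:
    true_model: TrueModel
    cohorts: tuple[CohortDesign, ...]
    seed: int = 0
    missing_exam_p: float = 0.0
    raw_metric_mode: bool = False
    integer_scores: bool = False
    raw_noise_scale: float = 1.0

    def __post_init__(self) -> None:
        if not self.cohorts:
            raise ConfigError("at least one cohort is required")
        if not 0.0 <= self.missing_exam_p < 1.0:
            raise ConfigError("missing_exam_p must be in [0, 1)")

    def to_dict(self) -> dict:
        tm = self.true_model
        return {
            "true_model": {
                "intercept_at_age8": tm.intercept_at_age8,
                "psi": list(tm.psi),
                "segment_slopes": list(tm.segment_slopes),
                "covariate_effects": [
                    {"covariate": c, "level": lv, "effect": e}
                    for (c, lv), e in tm.covariate_effects.items()
                ],
                "re_sd_intercept": tm.re_sd_intercept,
                "re_sd_slope": tm.re_sd_slope,
                "re_corr": tm.re_corr,
                "resid_sd": tm.resid_sd,
            },
            "cohorts": [
                {
                    "name": c.name,
                    "n_subjects": c.n_subjects,
                    "baseline_age_range": list(c.baseline_age_range),
                    "visit_interval": c.visit_interval,
                    "n_visits": c.n_visits,
                    "sex_p": c.sex_p,
                    "race_levels": dict(c.race_levels),
                }
                for c in self.cohorts
            ],
            "seed": self.seed,
            "missing_exam_p": self.missing_exam_p,
            "raw_metric_mode": self.raw_metric_mode,
            "integer_scores": self.integer_scores,
            "raw_noise_scale": self.raw_noise_scale,
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "GeneratorConfig":
        tm = dict(raw["true_model"])
        tm["psi"] = tuple(tm.get("psi", ()))
        tm["segment_slopes"] = tuple(tm.get("segment_slopes", (0.0,)))
        tm["covariate_effects"] = {
            (d["covariate"], d["level"]): d["effect"]
            for d in tm.get("covariate_effects", [])
        }
        cohorts = tuple(
            CohortDesign(
                name=c["name"],
                n_subjects=c["n_subjects"],
                baseline_age_range=tuple(c["baseline_age_range"]),
                visit_interval=c["visit_interval"],
                n_visits=c["n_visits"],
                sex_p=c.get("sex_p", 0.5),
                race_levels=dict(c.get("race_levels", {"White": 1.0})),
            )
            for c in raw["cohorts"]
        )
        extras = {
            k: raw[k]
            for k in ("seed", "missing_exam_p", "raw_metric_mode",
                      "integer_scores", "raw_noise_scale")
            if k in raw
        }
        return cls(TrueModel(**tm), cohorts, **extras)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _draw_subjects(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Subject-level frame: id, cohort, sex, race, baseline age, random effects."""
    rows = []
    counter = 0
    cov = config.true_model.re_cov()
    for cohort in config.cohorts:
        n = cohort.n_subjects
        lo, hi = cohort.baseline_age_range
        baseline = rng.uniform(lo, hi, size=n)
        female = rng.random(n) < cohort.sex_p
        races = rng.choice(
            list(cohort.race_levels), size=n, p=list(cohort.race_levels.values())
        )
        if cov[0, 0] > 0 and cov[1, 1] > 0 and abs(config.true_model.re_corr) < 1:
            re = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="cholesky")
        else:  # degenerate covariance (a zero SD or |corr| = 1)
            z = rng.standard_normal((n, 2))
            sd0, sd1 = np.sqrt(cov[0, 0]), np.sqrt(cov[1, 1])
            rho = config.true_model.re_corr
            re = np.column_stack(
                [sd0 * z[:, 0], sd1 * (rho * z[:, 0] + np.sqrt(1 - rho**2) * z[:, 1])]
            )
        for i in range(n):
            rows.append(
                (
                    f"{cohort.name}-{counter + i:05d}",
                    cohort.name,
                    "female" if female[i] else "male",
                    races[i],
                    baseline[i],
                    re[i, 0],
                    re[i, 1],
                    cohort.n_visits,
                    cohort.visit_interval,
                )
            )
        counter += n
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id", "cohort", "sex", "race", "baseline_age",
            "_b0", "_b1", "_n_visits", "_interval",
        ],
    )


def _expand_visits(subjects: pd.DataFrame) -> pd.DataFrame:
    """One row per scheduled visit, truncated at the design's maximum age."""
    reps = subjects["_n_visits"].to_numpy()
    long = subjects.loc[subjects.index.repeat(reps)].reset_index(drop=True)
    k = np.concatenate([np.arange(r) for r in reps])
    long["age"] = long["baseline_age"] + k * long["_interval"]
    return long[long["age"] <= AGE_MAX].reset_index(drop=True)


def _covariate_effect(model: TrueModel, df: pd.DataFrame) -> np.ndarray:
    eff = np.zeros(len(df))
    for (col, level), value in model.covariate_effects.items():
        eff += np.where(df[col].to_numpy() == level, value, 0.0)
    return eff


def generate_scores(config: GeneratorConfig) -> pd.DataFrame:
    """Generate the long-format clinical CVH score dataset.

    Each visit's score is ``mu(age) + covariate effects + b0 + b1*(age-8) +
    eps``.  With ``integer_scores`` the latent value is clamped to [0, 8] and
    rounded.  Visits hit by ``missing_exam_p`` carry a missing score
    (emulating an exam lacking at least one of the four factors) and are
    removed by the completeness filter downstream.  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    model = config.true_model
    subjects = _draw_subjects(config, rng)
    long = _expand_visits(subjects)
    age = long["age"].to_numpy()
    score = (
        model.mean_score(age)
        + _covariate_effect(model, long)
        + long["_b0"].to_numpy()
        + long["_b1"].to_numpy() * (age - AGE_MIN)
        + rng.normal(0.0, model.resid_sd, size=len(long))
    )
    if config.integer_scores:
        score = np.clip(np.round(score), 0.0, 8.0)
    if config.missing_exam_p > 0:
        score = np.where(rng.random(len(long)) < config.missing_exam_p, np.nan, score)
    out = long[["subject_id", "cohort", "sex", "race", "age"]].copy()
    out["cvh_score"] = score
    return out


# ---------------------------------------------------------------------------
# raw clinical metrics
# ---------------------------------------------------------------------------

#: anchor ages for the per-metric mean/SD trajectories
_ANCHOR_AGES = np.array([8.0, 17.0, 37.0, 55.0])

#: sex-specific (mean, SD) anchors per clinical metric at the anchor ages
RAW_METRIC_ANCHORS: dict[str, dict[str, tuple[tuple[float, ...], tuple[float, ...]]]] = {
    "bmi": {
        "female": ((17.2, 22.2, 27.5, 31.4), (3.1, 4.5, 7.2, 7.7)),
        "male": ((17.0, 22.3, 27.6, 30.3), (2.9, 4.1, 5.4, 6.1)),
    },
    "sbp": {
        "female": ((96.5, 110.7, 109.7, 117.6), (8.8, 9.0, 14.4, 15.9)),
        "male": ((96.8, 117.0, 116.2, 121.4), (8.3, 11.7, 12.9, 15.9)),
    },
    "dbp": {
        "female": ((45.1, 61.1, 70.7, 72.6), (12.0, 8.6, 11.0, 11.2)),
        "male": ((44.1, 59.6, 75.0, 73.9), (10.9, 10.3, 10.4, 10.3)),
    },
    "total_chol": {
        "female": ((167.6, 163.3, 181.4, 201.7), (27.9, 30.6, 33.1, 36.3)),
        "male": ((164.2, 151.1, 193.3, 182.4), (25.8, 28.2, 40.5, 35.9)),
    },
    "glucose": {
        "female": ((80.7, 81.6, 90.1, 95.9), (8.0, 8.2, 18.0, 15.8)),
        "male": ((82.4, 86.0, 96.3, 104.0), (9.0, 8.4, 25.9, 21.9)),
    },
}

#: share of a metric's variance attributed to a stable subject-level offset
_RAW_RE_FRACTION = 0.6

_METRICS = ("bmi", "sbp", "dbp", "total_chol", "glucose")
_FACTORS = ("bmi", "bp", "total_chol", "glucose")  # sbp/dbp jointly = bp


def raw_metric_mean_sd(metric: str, sex: str, age) -> tuple[np.ndarray, np.ndarray]:
    """Anchored mean and SD trajectory for one metric, piecewise-linear in age
    between the anchor ages and flat outside them."""
    means, sds = RAW_METRIC_ANCHORS[metric][sex]
    age = np.asarray(age, dtype=float)
    return (
        np.interp(age, _ANCHOR_AGES, means),
        np.interp(age, _ANCHOR_AGES, sds),
    )


def generate_raw_metrics(config: GeneratorConfig) -> pd.DataFrame:
    """Generate raw clinical measurements (one row per subject-visit).

    Metric values follow the anchored age/sex mean trajectories plus a
    subject-level offset and visit noise (both scaled by
    ``config.raw_noise_scale``; zero gives exactly the anchor means).
    Pediatric percentile columns are the within-age/sex normal rank of the
    simulated value: present for BMI below age 20 and blood pressure below
    age 18 (the BP percentile is the larger of the systolic and diastolic
    ranks).  Medication flags default to False.  With ``missing_exam_p`` a
    visit loses one randomly chosen factor.
    """
    if not config.raw_metric_mode:
        raise ConfigError("generate_raw_metrics requires raw_metric_mode=True")
    from scipy.stats import norm

    rng = np.random.default_rng(config.seed)
    subjects = _draw_subjects(config, rng)
    long = _expand_visits(subjects)
    n = len(long)
    age = long["age"].to_numpy()
    female = long["sex"].to_numpy() == "female"

    out = long[["subject_id", "cohort", "sex", "race", "age"]].copy()
    scale = config.raw_noise_scale
    subj_codes, subj_index = pd.factorize(long["subject_id"], sort=False)
    z_subject = rng.normal(size=(len(subj_index), len(_METRICS)))
    zed = {}
    for k, metric in enumerate(_METRICS):
        mean = np.empty(n)
        sd = np.empty(n)
        for sex, mask in (("female", female), ("male", ~female)):
            m, s = raw_metric_mean_sd(metric, sex, age[mask])
            mean[mask], sd[mask] = m, s
        re_part = np.sqrt(_RAW_RE_FRACTION) * z_subject[subj_codes, k]
        noise = np.sqrt(1.0 - _RAW_RE_FRACTION) * rng.normal(size=n)
        z = scale * (re_part + noise)
        out[metric] = mean + sd * z
        zed[metric] = z  # standardized position within the age/sex distribution

    out["bmi_pct"] = np.where(
        age < 20.0, np.round(100.0 * norm.cdf(zed["bmi"]), 2), np.nan
    )
    bp_rank = np.maximum(norm.cdf(zed["sbp"]), norm.cdf(zed["dbp"]))
    out["bp_pct"] = np.where(age < 18.0, np.round(100.0 * bp_rank, 2), np.nan)
    for flag in ("bp_med", "lipid_med", "glucose_med"):
        out[flag] = False

    if config.missing_exam_p > 0:
        hit = rng.random(n) < config.missing_exam_p
        which = rng.integers(0, len(_FACTORS), size=n)
        for k, factor in enumerate(_FACTORS):
            mask = hit & (which == k)
            if factor == "bp":
                out.loc[mask, ["sbp", "dbp", "bp_pct"]] = np.nan
            elif factor == "bmi":
                out.loc[mask, ["bmi", "bmi_pct"]] = np.nan
            else:
                out.loc[mask, factor] = np.nan
    return out


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


def _paper2021_config(seed: int) -> GeneratorConfig:
    """Published-estimate preset: ground truth from the adjusted two-change-
    point model (psi 16.9/37.2, slopes 0.01/-0.07/-0.08), five cohorts with
    the pooled design's sampling fractions scaled to ~2000 subjects, variance
    components calibrated to the published baseline score mean/SD 6.9 (1.2).
    """
    model = TrueModel(
        intercept_at_age8=7.11,
        psi=(16.9, 37.2),
        segment_slopes=(0.01, -0.07, -0.08),
        covariate_effects={
            ("sex", "male"): -0.10,
            ("race", "Black"): -0.15,
            ("cohort", "young_finns"): 0.10,
            ("cohort", "cardia"): -0.05,
            ("cohort", "strip"): 0.05,
        },
        re_sd_intercept=1.00,
        re_sd_slope=0.012,
        re_corr=-0.25,
        resid_sd=0.55,
    )
    cohorts = (
        CohortDesign("bogalusa", 1004, (8.0, 17.0), 4.0, 9, 0.50,
                     {"White": 0.60, "Black": 0.40}),
        CohortDesign("cardia", 556, (18.0, 30.0), 4.0, 9, 0.55,
                     {"White": 0.50, "Black": 0.50}),
        CohortDesign("young_finns", 342, (8.0, 18.0), 5.0, 7, 0.52,
                     {"White": 1.0}),
        CohortDesign("strip", 54, (8.0, 11.0), 2.0, 6, 0.49,
                     {"White": 1.0}),
        CohortDesign("heartbeat", 44, (8.0, 14.0), 1.0, 4, 0.51,
                     {"White": 0.80, "Black": 0.20}),
    )
    return GeneratorConfig(model, cohorts, seed=seed, missing_exam_p=0.10)


def _single_break_config(seed: int) -> GeneratorConfig:
    model = TrueModel(
        intercept_at_age8=7.0,
        psi=(25.0,),
        segment_slopes=(0.0, -0.08),
        re_sd_intercept=0.9,
        re_sd_slope=0.015,
        re_corr=-0.2,
        resid_sd=0.6,
    )
    cohorts = (
        CohortDesign("sim", 300, (8.0, 30.0), 5.0, 6, 0.5, {"White": 1.0}),
    )
    return GeneratorConfig(model, cohorts, seed=seed)


def _linear_null_config(seed: int) -> GeneratorConfig:
    model = TrueModel(
        intercept_at_age8=7.0,
        psi=(),
        segment_slopes=(-0.03,),
        re_sd_intercept=0.9,
        re_sd_slope=0.015,
        re_corr=-0.2,
        resid_sd=0.6,
    )
    cohorts = (
        CohortDesign("sim", 300, (8.0, 30.0), 5.0, 6, 0.5, {"White": 1.0}),
    )
    return GeneratorConfig(model, cohorts, seed=seed)


_PRESETS = {
    "paper2021": _paper2021_config,
    "single_break": _single_break_config,
    "linear_null": _linear_null_config,
}


def preset(name: str, seed: int = 0, n_subjects: int | None = None) -> GeneratorConfig:
    """Return a named generator configuration.

    ``n_subjects`` rescales every cohort proportionally (each keeps at least
    one subject), for quick smaller or larger versions of the same design.
    """
    try:
        config = _PRESETS[name](seed)
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None
    if n_subjects is not None:
        total = sum(c.n_subjects for c in config.cohorts)
        scaled = tuple(
            replace(c, n_subjects=max(1, round(c.n_subjects * n_subjects / total)))
            for c in config.cohorts
        )
        config = replace(config, cohorts=scaled)
    return config
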