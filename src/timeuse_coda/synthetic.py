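"""Synthetic cohort generator.

Stands in for the unreleased study data: draws 4-part 24-h time-use
compositions from a logistic-normal distribution on the simplex (multivariate
normal on the ilr scale — the distribution under which the downstream
regression model is correctly specified), covariates matching the published
sample marginals of a two-site Australian cohort of 60-70-year-olds, and
cognitive outcomes as linear functions of ilr coordinates, covariates and
optional composition x moderator interactions with Gaussian noise.  Null and
alternative scenarios differ only in the effect-size fields of the config,
so type-I-error and power/recovery simulations share one code path.

Defaults reflect the published sample: compositions centred at
(503, 668, 178, 89) min of sleep/SB/LPA/MVPA, age 65.5 +/- 3.0 truncated to
the 60-70 eligibility window, 263/384 female, education 16.5 +/- 3.2 years,
and the published smoking, sleep-quality-rating and recreational-PA
category frequencies.  The ilr covariance is a stated choice (the source
reports no second moments on the log-ratio scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .accelerometry import EPOCHS_PER_DAY, EpochDay, EpochSeries
from .cognition import MEASURES
from .composition import PARTS, closure, ilr_inverse, ilr_transform
from .inference import CATEGORY_LEVELS, assign_moderators

DEFAULT_MEAN_COMPOSITION = closure([503.0, 668.0, 178.0, 89.0])
DEFAULT_ILR_COVARIANCE = np.diag([0.03, 0.06, 0.25])

#: value bands (g-min) used when materialising epochs for each label
EPOCH_BANDS = {
    "sleep": (0.0, 25.0),
    "nonwear": (0.0, 25.0),
    "sb": (25.5, 48.0),
    "lpa": (48.5, 93.0),
    "mvpa": (93.5, 500.0),
}


@dataclass
class CovariateSpec:
    """Marginal distributions of the participant-level covariates."""

    age_mean: float = 65.5
    age_sd: float = 3.0
    age_bounds: tuple[float, float] = (60.0, 70.0)
    female_p: float = 263.0 / 384.0
    adelaide_p: float = 207.0 / 384.0
    education_mean: float = 16.5
    education_sd: float = 3.2
    smoking_p: dict[str, float] = field(
        default_factory=lambda: {"never": 234 / 384, "previous": 7 / 384, "current": 143 / 384}
    )
    #: PSQI sleep-quality item: 0 very good .. 3 very bad
    sleep_rating_p: tuple[float, ...] = (0.27, 0.54, 0.17, 0.02)
    #: TV minutes: mixture over the low/medium/high viewing groups
    tv_component_means: tuple[float, ...] = (44.0, 126.0, 224.0)
    tv_component_sds: tuple[float, ...] = (30.0, 20.0, 59.0)
    #: recreational PA: none / up to 30 min / over 30 min
    recpa_p: dict[str, float] = field(
        default_factory=lambda: {"none": 207 / 384, "upto30": 1.0 - 207 / 384 - 0.267, "over30": 0.267}
    )
    recpa_upto30_mean: float = 19.0
    recpa_upto30_sd: float = 8.0
    recpa_over30_mean: float = 80.0
    recpa_over30_sd: float = 53.0

    def validate(self) -> None:
        for name, probs in (("smoking_p", self.smoking_p.values()),
                            ("sleep_rating_p", self.sleep_rating_p),
                            ("recpa_p", self.recpa_p.values())):
            probs = list(probs)
            if any(p < 0 or p > 1 for p in probs):
                raise ValueError(f"{name} has probabilities outside [0, 1]")
            if abs(sum(probs) - 1.0) > 1e-6:
                raise ValueError(f"{name} probabilities must sum to 1")
        for p in (self.female_p, self.adelaide_p):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class OutcomeEffects:
    """Data-generating coefficients for one cognitive outcome."""

    intercept: float = 0.0
    beta_composition: tuple[float, float, float] = (0.0, 0.0, 0.0)
    #: keyed by design-column name, e.g. "age", "sex_female", "tv_high"
    beta_covariates: dict[str, float] = field(default_factory=dict)
    #: moderator -> level -> 3 ilr coefficients added on top of beta_composition
    beta_interaction: dict[str, dict[str, tuple[float, float, float]]] = field(default_factory=dict)
    noise_sd: float = 1.0

    def validate(self) -> None:
        if len(self.beta_composition) != 3:
            raise ValueError("beta_composition must have 3 ilr coefficients")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for mod, levels in self.beta_interaction.items():
            if mod not in ("tv", "recpa", "sleep_quality"):
                raise ValueError(f"unknown moderator {mod!r}")
            for level, beta in levels.items():
                if level not in CATEGORY_LEVELS[mod][1:]:
                    raise ValueError(f"unknown non-reference level {level!r} for {mod!r}")
                if len(beta) != 3:
                    raise ValueError("interaction coefficients must have 3 ilr components")


def _default_outcomes() -> dict[str, OutcomeEffects]:
    # ACE-III lives on its own 0-100 scale; the four composites are ~ z-scaled
    return {
        "global_cognition": OutcomeEffects(intercept=95.1, noise_sd=3.6),
        "ltm": OutcomeEffects(),
        "stm": OutcomeEffects(),
        "exec": OutcomeEffects(),
        "speed": OutcomeEffects(),
    }


@dataclass
class CohortConfig:
    n: int = 384
    seed: int = 0
    mean_composition: np.ndarray = field(default_factory=lambda: DEFAULT_MEAN_COMPOSITION.copy())
    ilr_covariance: np.ndarray = field(default_factory=lambda: DEFAULT_ILR_COVARIANCE.copy())
    covariates: CovariateSpec = field(default_factory=CovariateSpec)
    outcomes: dict[str, OutcomeEffects] = field(default_factory=_default_outcomes)
    #: fraction of participants flagged as failing the accelerometry valid-week rule
    invalid_accel_fraction: float = 0.0
    #: fraction (disjoint where possible) with a covariate blanked to missing
    missing_covariate_fraction: float = 0.0

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be at least 1")
        mean = np.asarray(self.mean_composition, dtype=float)
        if mean.shape != (4,) or np.any(mean <= 0):
            raise ValueError("mean_composition must be 4 strictly positive parts")
        cov = np.asarray(self.ilr_covariance, dtype=float)
        if cov.shape != (3, 3) or not np.allclose(cov, cov.T):
            raise ValueError("ilr_covariance must be a symmetric 3x3 matrix")
        if np.min(np.linalg.eigvalsh(cov)) < -1e-10:
            raise ValueError("ilr_covariance must be positive semidefinite")
        for frac in (self.invalid_accel_fraction, self.missing_covariate_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        self.covariates.validate()
        for eff in self.outcomes.values():
            eff.validate()


# ---------------------------------------------------------------------------
# generators


def generate_compositions(
    n: int, mean_composition, ilr_covariance, seed: int
) -> np.ndarray:
    """Logistic-normal compositions: MVN on the ilr scale, centred at the
    ilr image of the mean composition, mapped back and closed to 1440."""
    mean = np.asarray(mean_composition, dtype=float)
    if np.any(mean <= 0):
        raise ValueError("mean_composition parts must be strictly positive")
    cov = np.asarray(ilr_covariance, dtype=float)
    if cov.shape != (3, 3) or not np.allclose(cov, cov.T):
        raise ValueError("ilr_covariance must be a symmetric 3x3 matrix")
    if np.min(np.linalg.eigvalsh(cov)) < -1e-10:
        raise ValueError("ilr_covariance must be positive semidefinite")
    rng = np.random.default_rng(seed)
    centre = ilr_transform(closure(mean))
    z = rng.multivariate_normal(centre, cov, size=n, method="svd")
    return ilr_inverse(z)


def _truncated_normal(rng, mean, sd, low, high, size):
    a, b = (low - mean) / sd, (high - mean) / sd
    return scipy.stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _categorical_exact(rng, levels, probs, n):
    """Randomly ordered draw hitting the target category proportions exactly
    (largest-remainder counts).  The published marginals are fixed sample
    counts, so emulating them exactly both matches the source table and keeps
    rare categories (2% previous smokers) represented in every cohort."""
    target = np.asarray(probs, dtype=float) * n
    counts = np.floor(target).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(target - counts))
    counts[order[:short]] += 1
    return rng.permutation(np.repeat(np.asarray(levels), counts))


def generate_covariates(n: int, spec: CovariateSpec | None = None, seed: int = 0) -> pd.DataFrame:
    """One row per participant: demographics plus the self-report moderator
    inputs (TV minutes, recreational-PA minutes, sleep-quality rating)."""
    spec = spec or CovariateSpec()
    spec.validate()
    rng = np.random.default_rng(seed)
    age = _truncated_normal(rng, spec.age_mean, spec.age_sd, *spec.age_bounds, size=n)
    sex = _categorical_exact(rng, ["female", "male"], [spec.female_p, 1 - spec.female_p], n)
    site = _categorical_exact(
        rng, ["adelaide", "newcastle"], [spec.adelaide_p, 1 - spec.adelaide_p], n
    )
    education = np.clip(rng.normal(spec.education_mean, spec.education_sd, size=n), 0.0, None)
    smoking_levels = list(spec.smoking_p)
    smoking = _categorical_exact(
        rng, smoking_levels, [spec.smoking_p[k] for k in smoking_levels], n
    )
    sleep_rating = _categorical_exact(rng, np.arange(4), spec.sleep_rating_p, n)
    comp = rng.integers(0, len(spec.tv_component_means), size=n)
    tv = np.clip(
        rng.normal(np.asarray(spec.tv_component_means)[comp],
                   np.asarray(spec.tv_component_sds)[comp]),
        0.0, None,
    )
    recpa_levels = list(spec.recpa_p)
    recpa_cat = _categorical_exact(
        rng, recpa_levels, [spec.recpa_p[k] for k in recpa_levels], n
    )
    recpa = np.zeros(n)
    m_upto = recpa_cat == "upto30"
    m_over = recpa_cat == "over30"
    recpa[m_upto] = _truncated_normal(
        rng, spec.recpa_upto30_mean, spec.recpa_upto30_sd, 0.5, 30.0, size=int(m_upto.sum())
    )
    recpa[m_over] = _truncated_normal(
        rng, spec.recpa_over30_mean, spec.recpa_over30_sd, 30.5, np.inf, size=int(m_over.sum())
    )
    return pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "site": site,
            "education": education,
            "smoking": smoking,
            "sleep_rating": sleep_rating,
            "tv_minutes": tv,
            "recpa_minutes": recpa,
        }
    )


def _design_dummies(table: pd.DataFrame) -> pd.DataFrame:
    """Non-reference dummies for every categorical term (generation-side
    mirror of the analysis design, kept independent of the model fitter)."""
    out = {}
    for var in ("sex", "site", "smoking", "sleep_quality", "tv", "recpa"):
        for level in CATEGORY_LEVELS[var][1:]:
            out[f"{var}_{level}"] = (table[var] == level).astype(float)
    out["age"] = table["age"].astype(float)
    out["education"] = table["education"].astype(float)
    return pd.DataFrame(out, index=table.index)


def generate_outcomes(
    table: pd.DataFrame,
    effects: OutcomeEffects,
    seed: int = 0,
) -> np.ndarray:
    """y = intercept + beta' ilr + gamma' covariates (+ interactions) + noise.

    ``table`` must carry the behaviour-minute columns plus covariates and the
    moderator categories (``tv``, ``recpa``, ``sleep_quality``).
    """
    effects.validate()
    rng = np.random.default_rng(seed)
    z = ilr_transform(table[["sleep_min", "sb_min", "lpa_min", "mvpa_min"]].to_numpy(float))
    dummies = _design_dummies(table)
    y = np.full(len(table), effects.intercept, dtype=float)
    y += z @ np.asarray(effects.beta_composition, dtype=float)
    for name, coef in effects.beta_covariates.items():
        if name not in dummies.columns:
            raise ValueError(f"unknown covariate term {name!r}")
        y += coef * dummies[name].to_numpy()
    for mod, levels in effects.beta_interaction.items():
        for level, beta in levels.items():
            ind = dummies[f"{mod}_{level}"].to_numpy()
            y += ind * (z @ np.asarray(beta, dtype=float))
    if effects.noise_sd > 0:
        y += rng.normal(0.0, effects.noise_sd, size=len(table))
    return y


def generate_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """Full participant table: compositions, covariates, moderator
    categories, the five outcomes, and eligibility flags.

    Deterministic given ``config.seed``; sub-stage seeds are derived from a
    seeded sequence so stages stay reproducible in isolation.
    """
    config = config or CohortConfig()
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4 + len(config.outcomes))]
    comps = generate_compositions(
        config.n, config.mean_composition, config.ilr_covariance, seed=seeds[0]
    )
    table = generate_covariates(config.n, config.covariates, seed=seeds[1])
    table.insert(0, "participant_id", [f"P{i:04d}" for i in range(1, config.n + 1)])
    for j, part in enumerate(PARTS):
        table[f"{part}_min"] = comps[:, j]
    table = pd.concat(
        [table, assign_moderators(table["tv_minutes"], table["recpa_minutes"], table["sleep_rating"])],
        axis=1,
    )
    for k, (name, eff) in enumerate(config.outcomes.items()):
        table[name] = generate_outcomes(table, eff, seed=seeds[2 + k])

    rng = np.random.default_rng(seeds[-2])
    flags = np.ones(config.n, dtype=bool)
    n_bad = int(round(config.invalid_accel_fraction * config.n))
    n_miss = int(round(config.missing_covariate_fraction * config.n))
    order = rng.permutation(config.n)
    bad_idx = order[:n_bad]
    miss_idx = order[n_bad : n_bad + n_miss]  # disjoint from the invalid-accel set
    flags[bad_idx] = False
    table["accel_valid"] = flags
    if n_miss:
        table.loc[table.index[miss_idx], "education"] = np.nan
    return table


# ---------------------------------------------------------------------------
# epoch-series fixtures


def generate_epoch_series(
    daily_targets: Sequence[dict], seed: int = 0, participant_id: str = "P0001"
) -> EpochSeries:
    """Materialise 1-min epochs hitting exact per-day class-minute targets.

    Each target dict carries ``day_type`` plus integer minutes for sleep,
    sb, lpa, mvpa and nonwear summing to 1440.  Epoch values are drawn
    uniformly within each label's cut-point band, sleep intervals become
    diary intervals, and non-wear is laid down as a single contiguous run —
    so the accelerometry pipeline recovers the targets exactly.  A non-wear
    target in (0, 60) min cannot be realised as a detectable run and is
    rejected.
    """
    rng = np.random.default_rng(seed)
    days = []
    for t in daily_targets:
        mins = {k: int(t[k]) for k in ("sleep", "sb", "lpa", "mvpa", "nonwear")}
        if sum(mins.values()) != EPOCHS_PER_DAY:
            raise ValueError(f"day targets must sum to {EPOCHS_PER_DAY}: {mins}")
        if 0 < mins["nonwear"] < 60:
            raise ValueError("a non-wear target in (0, 60) min cannot form a detectable run")
        values = np.empty(EPOCHS_PER_DAY)
        pos = 0
        sleep_intervals = []
        for label in ("sleep", "nonwear", "sb", "lpa", "mvpa"):
            m = mins[label]
            if m == 0:
                continue
            low, high = EPOCH_BANDS[label]
            values[pos : pos + m] = rng.uniform(low, high, size=m)
            if label == "sleep":
                sleep_intervals.append((pos, pos + m))
            pos += m
        days.append(
            EpochDay(day_type=t["day_type"], epochs=values, sleep_intervals=sleep_intervals)
        )
    return EpochSeries(participant_id=participant_id, days=days)


def day_targets_from_composition(
    comp, n_weekdays: int = 5, n_weekend: int = 2, nonwear: int = 0
) -> list[dict]:
    """Integer per-day targets approximating a closed composition.

    Minutes are integerised by largest remainder so each day sums to 1440
    (after reserving ``nonwear``); weekdays come first.
    """
    comp = np.asarray(comp, dtype=float)
    scaled = comp * (EPOCHS_PER_DAY - nonwear) / comp.sum()
    floors = np.floor(scaled).astype(int)
    short = int(EPOCHS_PER_DAY - nonwear - floors.sum())
    order = np.argsort(-(scaled - floors))
    floors[order[:short]] += 1
    base = dict(zip(PARTS, (int(v) for v in floors)), nonwear=int(nonwear))
    return [
        dict(base, day_type="weekday" if i < n_weekdays else "weekend")
        for i in range(n_weekdays + n_weekend)
    ]


def epoch_frame(series_list: Sequence[EpochSeries]) -> pd.DataFrame:
    """Long epoch table in the CSV schema the accelerometry reader expects."""
    frames = []
    for series in series_list:
        for d_idx, day in enumerate(series.days):
            flags = np.zeros(EPOCHS_PER_DAY, dtype=bool)
            for s, e in day.sleep_intervals:
                flags[s:e] = True
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": series.participant_id,
                        "day_index": d_idx,
                        "day_type": day.day_type,
                        "epoch_index": np.arange(EPOCHS_PER_DAY),
                        "value": day.epochs,
                        "in_sleep_interval": flags,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def generate_cognitive_scores(n: int, seed: int = 0, missing_fraction: float = 0.0) -> pd.DataFrame:
    """Plausible raw CANTAB-style scores and per-test accuracies.

    Scores are independent draws within each measure's valid range (these
    synthetic raws carry no composition signal; they exercise the composite
    construction, not the regression).  ``missing_fraction`` blanks random
    cells to test the completeness rule.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for m in MEASURES:
        low, high = m.score_range
        if not np.isfinite(high):
            out[m.name] = rng.gamma(4.0, 2000.0, size=n)  # open-ended latency, ms
        else:
            centre, width = (low + high) / 2.0, (high - low) / 2.0
            out[m.name] = np.clip(rng.normal(centre, width / 3.0, size=n), low, high)
    for test in ("vrm", "pal", "mtt", "ots", "rti"):
        out[f"{test}_accuracy"] = np.clip(rng.normal(0.85, 0.12, size=n), 0.0, 1.0)
    out["ace_iii_total"] = np.clip(rng.normal(95.1, 3.6, size=n), 0.0, 100.0)
    df = pd.DataFrame(out)
    if missing_fraction > 0:
        measure_cols = [m.name for m in MEASURES]
        mask = rng.random((n, len(measure_cols))) < missing_fraction
        df[measure_cols] = df[measure_cols].mask(mask)
    return df
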