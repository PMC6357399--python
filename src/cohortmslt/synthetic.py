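"""Synthetic longitudinal disability panels with known ground truth.

The generator emulates the design of a paired-birth-cohort panel study of
the oldest old: baseline interviews of octogenarians (80-89),
nonagenarians (90-99) and centenarians (100-105), follow-up waves at
+2/+4 years for the earlier cohort and +3/+6 years for the later cohort,
deaths with recorded dates, and covariate-dependent (MAR) loss to
follow-up.  Individual state paths evolve annually under a known pair of
partial-proportional-odds transition models, so every downstream stage
(expansion, fitting, weighting, life-table computation, bootstrap) can be
tested against exact ground truth.

An optional *frailty* mixture adds a binary auxiliary covariate that
worsens transitions and raises dropout but is excluded from the
transition model — the mechanism that makes unweighted complete-case
estimation biased and inverse-probability-of-attrition weighting
informative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import (DAYS_PER_YEAR, DEAD, DISABLED, NONDISABLED,
                    PROFILE_RURAL, PROFILE_SCHOOLED, PROFILE_WOMAN,
                    PanelDataset, validate_panel)
from .ppo import PPOModel, build_matrix_set
from .mslt import BaselineDistribution, LifeTableEstimate, occupancy_oracle


@dataclass(frozen=True)
class FrailtySpec:
    """Binary frailty mixture: prevalence and the (negative) shift applied
    to both cumulative logits for frail individuals (more disability and
    death)."""

    prevalence: float = 0.25
    shift: float = -0.8


@dataclass(frozen=True)
class AttritionSpec:
    """Logistic dropout model (MAR: depends only on generated baseline
    covariates).

    ``per_wave=True`` draws dropout independently at each follow-up wave
    among individuals still under observation (deaths already reported
    stay reported).  ``per_wave=False`` draws a single baseline decision:
    a dropped individual is lost from the first follow-up wave onward and
    any death goes unrecorded — under this mechanism complete-case status
    is exactly independent of the health path given covariates, the
    setting in which inverse-probability weighting is the exact
    correction.
    """

    intercept: float = -2.2
    woman: float = 0.0
    rural: float = 0.3
    schooled: float = -0.2
    disabled: float = 0.4     # baseline disability
    frail: float = 0.0
    per_wave: bool = True

    def dropout_probability(self, woman, rural, schooled, disabled, frail):
        from scipy.special import expit
        eta = (self.intercept + self.woman * woman + self.rural * rural
               + self.schooled * schooled + self.disabled * disabled
               + self.frail * frail)
        return expit(eta)


@dataclass
class GeneratorConfig:
    """Ground-truth configuration for one simulated birth cohort."""

    n_individuals: int
    age_window: tuple[int, int]
    baseline_disabled_prevalence: float
    wave_offsets: tuple[int, ...]
    model_nondisabled: PPOModel
    model_disabled: PPOModel
    profile_distribution: np.ndarray = field(
        default_factory=lambda: DEFAULT_PROFILE_DISTRIBUTION.copy())
    attrition: AttritionSpec | None = None
    frailty: FrailtySpec | None = None
    sampling_weight_rule: str = "unit"       # "unit" or "two_stratum"
    cohort_label: str = "synthetic"
    baseline_date: str = "1998-07-01"
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        lo, hi = self.age_window
        if hi < lo:
            raise ValueError(f"empty age window {self.age_window}")
        offs = np.asarray(self.wave_offsets)
        if len(offs) < 2 or offs[0] != 0 or np.any(np.diff(offs) <= 0):
            raise ValueError("wave_offsets must start at 0 and strictly increase")
        if not 0 <= self.baseline_disabled_prevalence <= 1:
            raise ValueError("baseline_disabled_prevalence must be in [0, 1]")
        p = np.asarray(self.profile_distribution, dtype=float)
        if p.shape != (8,) or np.any(p < 0) or abs(p.sum() - 1) > 1e-9:
            raise ValueError("profile_distribution must be 8 probabilities summing to 1")
        if self.frailty is not None and not 0 <= self.frailty.prevalence <= 1:
            raise ValueError("frailty prevalence must be in [0, 1]")
        if self.sampling_weight_rule not in ("unit", "two_stratum"):
            raise ValueError(f"unknown sampling_weight_rule {self.sampling_weight_rule!r}")
        if self.model_nondisabled.origin != NONDISABLED:
            raise ValueError("model_nondisabled must have origin nondisabled")
        if self.model_disabled.origin != DISABLED:
            raise ValueError("model_disabled must have origin disabled")


# Joint distribution of (woman, rural, schooled) for the oldest old:
# women are the majority, most individuals live rurally, and formal
# schooling is much rarer among women.  Stated modeling assumption.
def _default_profiles() -> np.ndarray:
    p = np.zeros(8)
    p_woman, p_rural = 0.58, 0.66
    p_school = {0: 0.55, 1: 0.12}  # by woman indicator
    for i in range(8):
        w, r, s = (i >> 2) & 1, (i >> 1) & 1, i & 1
        pw = p_woman if w else 1 - p_woman
        pr = p_rural if r else 1 - p_rural
        ps = p_school[w] if s else 1 - p_school[w]
        p[i] = pw * pr * ps
    return p / p.sum()


DEFAULT_PROFILE_DISTRIBUTION = _default_profiles()


def generate_panel(config: GeneratorConfig, seed: int | None = None) -> PanelDataset:
    """Simulate one cohort's panel; fully reproducible given the seed
    (``config.seed`` unless overridden)."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_individuals
    lo, hi = config.age_window
    offsets = np.asarray(config.wave_offsets, dtype=np.int64)
    n_waves = len(offsets)
    horizon = int(offsets[-1])

    prof = rng.choice(8, size=n, p=np.asarray(config.profile_distribution, float))
    woman = PROFILE_WOMAN[prof].astype(float)
    rural = PROFILE_RURAL[prof].astype(float)
    schooled = PROFILE_SCHOOLED[prof].astype(float)
    base_age = rng.integers(lo, hi + 1, size=n)
    state0 = (rng.random(n) < config.baseline_disabled_prevalence).astype(np.int64)
    if config.frailty is not None:
        frail = (rng.random(n) < config.frailty.prevalence).astype(np.int8)
        shift = config.frailty.shift * frail
    else:
        frail = np.zeros(n, dtype=np.int8)
        shift = np.zeros(n)

    # annual state path over the follow-up horizon
    path = np.empty((n, horizon + 1), dtype=np.int64)
    path[:, 0] = state0
    death_year = np.full(n, -1, dtype=np.int64)  # year index of death transition
    for t in range(horizon):
        s = path[:, t]
        new = s.copy()
        for origin, model in ((NONDISABLED, config.model_nondisabled),
                              (DISABLED, config.model_disabled)):
            m = s == origin
            if not m.any():
                continue
            p = model.predict(base_age[m] + t, woman[m], rural[m], schooled[m],
                              shift=shift[m])
            u = rng.random(m.sum())
            c1 = p[:, 0]
            new[m] = (u >= c1).astype(np.int64) + (u >= c1 + p[:, 1]).astype(np.int64)
        just_died = (new == DEAD) & (s != DEAD)
        death_year[just_died] = t
        path[:, t + 1] = new

    # death dates: uniform within the death year, day precision
    days_into_year = 1 + rng.integers(0, 364, size=n)
    death_days = np.round(death_year * DAYS_PER_YEAR).astype(np.int64) + days_into_year
    death_age_full = base_age + death_days / DAYS_PER_YEAR

    # wave-by-wave observation with MAR dropout
    obs = np.full((n, n_waves), -1, dtype=np.int8)
    obs[:, 0] = state0.astype(np.int8)
    lost = np.zeros(n, dtype=bool)
    dead_observed = np.zeros(n, dtype=bool)
    if config.attrition is not None:
        p_drop = config.attrition.dropout_probability(
            woman, rural, schooled, state0.astype(float), frail.astype(float))
    else:
        p_drop = np.zeros(n)
    baseline_drop = rng.random(n) < p_drop  # used only when not per_wave
    per_wave = config.attrition is None or config.attrition.per_wave
    for k in range(1, n_waves):
        off = int(offsets[k])
        if not per_wave:
            if k == 1:
                lost |= baseline_drop
            died_before = (death_year >= 0) & (death_year < off) & ~lost & ~dead_observed
            dead_observed |= died_before
            observe = ~lost & ~dead_observed
            obs[observe, k] = path[observe, off].astype(np.int8)
            continue
        died_before = (death_year >= 0) & (death_year < off) & ~lost & ~dead_observed
        dead_observed |= died_before
        alive_at_wave = ~lost & ~dead_observed
        drops = alive_at_wave & (rng.random(n) < p_drop)
        lost |= drops
        observe = alive_at_wave & ~drops
        obs[observe, k] = path[observe, off].astype(np.int8)

    death_age = np.where(dead_observed, death_age_full, np.nan)

    if config.sampling_weight_rule == "two_stratum":
        sw = np.where(rural == 1, 0.85, 1.3)
    else:
        sw = np.ones(n)

    individuals = pd.DataFrame({
        "id": [f"{config.cohort_label}-{i:06d}" for i in range(n)],
        "baseline_age": base_age.astype(np.int64),
        "woman": woman.astype(np.int8),
        "rural": rural.astype(np.int8),
        "schooled": schooled.astype(np.int8),
        "dead": dead_observed,
        "death_age": death_age,
        "lost": lost,
        "sampling_weight": sw,
        "baseline_date": pd.Timestamp(config.baseline_date),
        "frail": frail,
    })
    data = PanelDataset(individuals=individuals, obs_state=obs,
                        wave_offsets=offsets, cohort=config.cohort_label,
                        age_window=config.age_window, aux_columns=("frail",))
    validate_panel(data)
    return data


def synthetic_person_years(model: PPOModel, n: int, age_range: tuple[int, int],
                           seed: int | None = 0):
    """Draw ``n`` annual person-year records directly from a transition
    model (balanced design: ages uniform over ``age_range``, all eight
    profiles equally likely) — the clean setting for parameter-recovery
    tests, free of any interval-censoring artefacts."""
    from .personyears import PersonYearTable

    rng = np.random.default_rng(seed)
    age = rng.integers(age_range[0], age_range[1] + 1, size=n)
    prof = rng.integers(0, 8, size=n)
    woman = PROFILE_WOMAN[prof]
    rural = PROFILE_RURAL[prof]
    schooled = PROFILE_SCHOOLED[prof]
    p = model.predict(age.astype(float), woman.astype(float),
                      rural.astype(float), schooled.astype(float))
    u = rng.random(n)
    dest = (u >= p[:, 0]).astype(np.int64) + (u >= p[:, 0] + p[:, 1]).astype(np.int64)
    return PersonYearTable(
        ind=np.arange(n), age=age.astype(np.int16),
        origin=np.full(n, model.origin, dtype=np.int8), dest=dest.astype(np.int8),
        woman=woman.astype(np.int8), rural=rural.astype(np.int8),
        schooled=schooled.astype(np.int8), weight=np.ones(n), cohort="synthetic")


# ---------------------------------------------------------------------------
# Ground-truth life-table quantities
# ---------------------------------------------------------------------------

def true_baseline_distribution(config: GeneratorConfig) -> BaselineDistribution:
    p = np.asarray(config.profile_distribution, float)
    prev = config.baseline_disabled_prevalence
    return BaselineDistribution(weights=np.column_stack([p * (1 - prev), p * prev]))


def true_estimates(config: GeneratorConfig,
                   window: tuple[int, int] | None = None,
                   death_credit: float = 0.5) -> LifeTableEstimate:
    """Exact partial LE / DFLE / disabled LE implied by the config's true
    transition models and baseline distribution (deterministic; mixes over
    the frailty strata when present)."""
    if window is None:
        window = config.age_window
    lo, hi = window
    mlo, mhi = config.age_window
    if lo < mlo or hi < lo:
        raise ValueError(f"window {window} outside modeled ages")
    ages = np.arange(lo, hi + 1)
    baseline = true_baseline_distribution(config)
    strata = [(1.0, 0.0)]
    if config.frailty is not None and config.frailty.prevalence > 0:
        fp = config.frailty.prevalence
        strata = [(1 - fp, 0.0), (fp, config.frailty.shift)]
    nd = dis = 0.0
    for mass, shift in strata:
        matrices = build_matrix_set(config.model_nondisabled, config.model_disabled,
                                    ages, shift=shift)
        est = occupancy_oracle(matrices, baseline, window, death_credit=death_credit)
        nd += mass * est.dfle
        dis += mass * est.disabled_le
    return LifeTableEstimate(window=window, total_le=nd + dis, dfle=nd,
                             disabled_le=dis, n_simulated=0,
                             death_credit=death_credit)


# ---------------------------------------------------------------------------
# Default study conditions: three paired age groups, earlier/later cohorts
# ---------------------------------------------------------------------------

# Calibrated ground-truth coefficients per age group.  Intercepts were
# chosen once (via the deterministic occupancy oracle) so that implied
# partial LE magnitudes sit in the observed range for these ages
# (octogenarian partial total LE roughly 6-7 years over ages 80-89,
# nonagenarian roughly 4 years over 90-99, centenarian roughly 1.4 years
# over 100-105); they are a calibration, not estimates from any survey.
_TRUTH_INTERCEPTS = {
    # age group: (nd alpha1, nd alpha2, d alpha1, d alpha2), centered at window lower bound
    "octogenarian": (2.05, 2.80, -0.70, 1.25),
    "nonagenarian": (0.95, 1.80, -1.30, 0.85),
    "centenarian": (-0.35, 0.15, -1.95, -0.45),
}
_TRUTH_SLOPES = {"nd_age": -0.085, "d_age": -0.075}
_TRUTH_GAMMA_ND = {"woman": (-0.15, 0.20), "rural": (-0.05, -0.10), "schooled": (0.10, 0.10)}
_TRUTH_GAMMA_D = {"woman": (-0.10, 0.25), "rural": (-0.05, -0.10), "schooled": (0.05, 0.05)}
# Later-cohort improvement: a modest upward shift of both cumulative logits
# (less disability onset and death, more recovery).
_LATER_SHIFT = {"octogenarian": (0.03, 0.045), "nonagenarian": (0.22, -0.03),
                "centenarian": (0.10, 0.00)}

_AGE_GROUPS = {
    "octogenarian": {"window": (80, 89), "n_total": 7334,
                     "prevalence": {"earlier": 0.173, "later": 0.118}},
    "nonagenarian": {"window": (90, 99), "n_total": 7705,
                     "prevalence": {"earlier": 0.29, "later": 0.24}},
    "centenarian": {"window": (100, 105), "n_total": 5481,
                    "prevalence": {"earlier": 0.50, "later": 0.44}},
}
_COHORT_DESIGN = {
    "earlier": {"offsets": (0, 2, 4), "baseline_date": "1998-07-01"},
    "later": {"offsets": (0, 3, 6), "baseline_date": "2008-07-01"},
}


def coverage_validation_config(n: int = 2000, seed: int = 0) -> GeneratorConfig:
    """Annually observed octogenarian cohort with no attrition: the setting
    in which the discrete-time estimator is exactly correctly specified
    (at most one transition per observation interval), so bootstrap
    interval calibration can be assessed against exact ground truth."""
    nd, d = default_true_models("octogenarian", "earlier")
    return GeneratorConfig(
        n_individuals=n, age_window=(80, 89), baseline_disabled_prevalence=0.173,
        wave_offsets=(0, 1, 2, 3, 4), model_nondisabled=nd, model_disabled=d,
        attrition=None, cohort_label="coverage", seed=seed)


def ipw_validation_config(n: int = 20_000, seed: int = 0) -> GeneratorConfig:
    """Annually observed cohort with a frailty mixture driving both worse
    transitions and strong baseline-decided dropout: unweighted
    complete-case estimation is upward-biased (the frail drop out), and
    inverse-probability-of-attrition weighting removes the selection
    component of that bias."""
    nd, d = default_true_models("octogenarian", "earlier")
    return GeneratorConfig(
        n_individuals=n, age_window=(80, 89), baseline_disabled_prevalence=0.173,
        wave_offsets=(0, 1, 2, 3), model_nondisabled=nd, model_disabled=d,
        attrition=AttritionSpec(intercept=-1.7, rural=0.3, schooled=-0.2,
                                disabled=0.5, frail=2.2, per_wave=False),
        frailty=FrailtySpec(prevalence=0.35, shift=-0.8),
        cohort_label="ipw", seed=seed)


def default_true_models(age_group: str, cohort: str) -> tuple[PPOModel, PPOModel]:
    """Ground-truth transition models for one age group and cohort."""
    a1_nd, a2_nd, a1_d, a2_d = _TRUTH_INTERCEPTS[age_group]
    center = float(_AGE_GROUPS[age_group]["window"][0])
    s1, s2 = _LATER_SHIFT[age_group] if cohort == "later" else (0.0, 0.0)
    nd = PPOModel(origin=NONDISABLED, center=center,
                  alpha=(a1_nd + s1, a2_nd + s2),
                  shared={"age": _TRUTH_SLOPES["nd_age"]},
                  gamma=dict(_TRUTH_GAMMA_ND))
    d = PPOModel(origin=DISABLED, center=center,
                 alpha=(a1_d + s1, a2_d + s2),
                 shared={"age": _TRUTH_SLOPES["d_age"]},
                 gamma=dict(_TRUTH_GAMMA_D))
    return nd, d


def default_study_configs(attrition: bool = True) -> dict[str, GeneratorConfig]:
    """Six named configs (3 age groups x earlier/later) emulating the study
    conditions: sample sizes splitting the per-age-group totals, wave
    offsets (0, 2, 4) for earlier vs (0, 3, 6) for later cohorts, and the
    calibrated default true models."""
    configs = {}
    for group, spec in _AGE_GROUPS.items():
        n_total = spec["n_total"]
        sizes = {"earlier": n_total // 2, "later": n_total - n_total // 2}
        for cohort, design in _COHORT_DESIGN.items():
            nd, d = default_true_models(group, cohort)
            name = f"{group}_{cohort}"
            configs[name] = GeneratorConfig(
                n_individuals=sizes[cohort],
                age_window=spec["window"],
                baseline_disabled_prevalence=spec["prevalence"][cohort],
                wave_offsets=design["offsets"],
                model_nondisabled=nd,
                model_disabled=d,
                attrition=AttritionSpec() if attrition else None,
                cohort_label=name,
                baseline_date=design["baseline_date"],
                seed=0,
            )
    return configs
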