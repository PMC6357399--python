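"""Full-pipeline bootstrap inference for cohort differences in LE/DFLE.

Every replicate resamples individuals with replacement within a cohort and
re-runs the entire analysis sequence — attrition weighting, person-year
expansion (with the transition placements re-drawn so placement
uncertainty propagates), transition-model fitting and microsimulation —
so the resulting intervals reflect both parameter and simulation
uncertainty.  Intervals are the central 95% of the replicate
distribution; cohort-difference p-values are nonparametric sign counts
over index-paired replicate differences.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .mslt import BaselineDistribution, LifeTableEstimate, microsimulate
from .panel import DISABLED, NONDISABLED, PanelDataset
from .personyears import expand_to_person_years
from .ppo import CrossingError, FitError, build_matrix_set, fit_ppo
from .weights import compute_analysis_weights, fit_attrition_model

logger = logging.getLogger(__name__)

QUANTITIES = ("total_le", "dfle", "disabled_le")


@dataclass
class AnalysisSpec:
    """Configuration of one cohort analysis run."""

    window: tuple[int, int]
    microsim_n: int = 100_000
    replicate_microsim_n: int | None = None   # defaults to microsim_n
    death_credit: float = 0.5
    truncation: tuple[float, float] | None = (1, 99)
    use_ipw: bool = True
    redraw_placement: bool = True   # re-draw transition placements per replicate
    allocation: str = "sample"
    ppo_terms: tuple[str, ...] = ("age",)
    ppo_covariates: tuple[str, ...] = ("woman", "rural", "schooled")

    def to_dict(self) -> dict:
        return {"window": list(self.window), "microsim_n": self.microsim_n,
                "replicate_microsim_n": self.replicate_microsim_n,
                "death_credit": self.death_credit,
                "truncation": list(self.truncation) if self.truncation else None,
                "use_ipw": self.use_ipw, "redraw_placement": self.redraw_placement,
                "allocation": self.allocation, "ppo_terms": list(self.ppo_terms),
                "ppo_covariates": list(self.ppo_covariates)}


def run_estimate(data: PanelDataset, spec: AnalysisSpec,
                 seed: int | np.random.SeedSequence = 0,
                 microsim_n: int | None = None,
                 keep_tallies: bool = False) -> LifeTableEstimate:
    """One pass of the full analysis sequence on one cohort panel:
    weights -> person-year expansion -> PPO fits -> transition matrices ->
    microsimulation."""
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    expand_ss, sim_ss = ss.spawn(2)
    if spec.use_ipw and data.individuals["lost"].any():
        model = fit_attrition_model(data)
        w = compute_analysis_weights(model, data, truncation=spec.truncation)
    else:
        # no IPW: every individual contributes their observed records
        w = data.individuals["sampling_weight"].to_numpy(float).copy()
    table = expand_to_person_years(data, seed=expand_ss, weights=w)
    m_nd = fit_ppo(table, NONDISABLED, terms=spec.ppo_terms,
                   covariates=spec.ppo_covariates, center=float(spec.window[0]))
    m_d = fit_ppo(table, DISABLED, terms=spec.ppo_terms,
                  covariates=spec.ppo_covariates, center=float(spec.window[0]))
    ages = np.arange(spec.window[0], spec.window[1] + 1)
    matrices = build_matrix_set(m_nd, m_d, ages)
    baseline_w = np.where(w > 0, w, 0.0)
    if not baseline_w.any():
        baseline_w = None
    baseline = BaselineDistribution.from_panel(data, weights=baseline_w)
    n = microsim_n if microsim_n is not None else spec.microsim_n
    return microsimulate(matrices, baseline, spec.window, n=n, seed=sim_ss,
                         death_credit=spec.death_credit,
                         allocation=spec.allocation, keep_tallies=keep_tallies)


@dataclass
class BootstrapResult:
    """Point estimate plus B full-pipeline bootstrap replicates."""

    point: LifeTableEstimate
    replicates: dict[str, np.ndarray]    # quantity -> length-B array
    B: int
    seed: int | None
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_redrawn: int = 0

    def to_dict(self) -> dict:
        return {"point": self.point.to_dict(),
                "replicates": {k: v.tolist() for k, v in self.replicates.items()},
                "B": self.B, "seed": self.seed,
                "ci": {k: list(v) for k, v in self.ci.items()},
                "n_redrawn": self.n_redrawn}


def percentile_interval(samples) -> tuple[float, float]:
    """Central 95% of the replicate distribution: linearly interpolated
    2.5th and 97.5th percentiles."""
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("percentile interval requires at least 2 samples")
    lo, hi = np.quantile(x, [0.025, 0.975], method="linear")
    return float(lo), float(hi)


def bootstrap_pipeline(data: PanelDataset, spec: AnalysisSpec, B: int = 499,
                       seed: int = 0, max_redraws: int = 5) -> BootstrapResult:
    """Full-pipeline bootstrap: the point estimate uses the complete sample;
    each of the B replicates resamples individuals with replacement and
    re-runs the entire sequence.  Replicates whose fit fails (e.g. an
    empty outcome category in a small resample) are re-drawn up to
    ``max_redraws`` times, then dropped with a warning."""
    if B < 1:
        raise ValueError("B must be >= 1")
    ss = np.random.SeedSequence(seed)
    point_ss, resample_ss, rep_root = ss.spawn(3)
    point = run_estimate(data, spec, seed=point_ss, microsim_n=spec.microsim_n)
    rng = np.random.default_rng(resample_ss)
    rep_n = (spec.replicate_microsim_n if spec.replicate_microsim_n is not None
             else spec.microsim_n)
    rep_seeds = rep_root.spawn(B * (max_redraws + 1))
    values = {q: [] for q in QUANTITIES}
    n_redrawn = 0
    expand_seed_cache = None if spec.redraw_placement else 12345
    for b in range(B):
        for attempt in range(max_redraws + 1):
            idx = rng.integers(0, data.n, size=data.n)
            sub = data.subset(idx)
            try:
                rep_ss = rep_seeds[b * (max_redraws + 1) + attempt]
                if not spec.redraw_placement:
                    # fixed placement seed: placement noise excluded by design
                    est = _estimate_fixed_placement(sub, spec, rep_ss,
                                                   expand_seed_cache, rep_n)
                else:
                    est = run_estimate(sub, spec, seed=rep_ss, microsim_n=rep_n)
                break
            except (FitError, CrossingError, np.linalg.LinAlgError) as exc:
                n_redrawn += 1
                logger.debug("replicate %d attempt %d failed: %s", b, attempt, exc)
        else:
            warnings.warn(f"bootstrap replicate {b} dropped after "
                          f"{max_redraws} redraws", stacklevel=2)
            continue
        for q in QUANTITIES:
            values[q].append(getattr(est, q))
    replicates = {q: np.asarray(v) for q, v in values.items()}
    ci = {q: percentile_interval(v) for q, v in replicates.items()} \
        if len(replicates["dfle"]) >= 2 else {}
    return BootstrapResult(point=point, replicates=replicates,
                           B=len(replicates["dfle"]), seed=seed, ci=ci,
                           n_redrawn=n_redrawn)


def _estimate_fixed_placement(sub, spec, rep_ss, expand_seed, rep_n):
    """Replicate estimate with a frozen transition-placement seed
    (documented switch for excluding placement re-draws)."""
    sim_ss = rep_ss.spawn(1)[0]
    if spec.use_ipw and sub.individuals["lost"].any():
        model = fit_attrition_model(sub)
        w = compute_analysis_weights(model, sub, truncation=spec.truncation)
    else:
        w = sub.individuals["sampling_weight"].to_numpy(float).copy()
    table = expand_to_person_years(sub, seed=expand_seed, weights=w)
    m_nd = fit_ppo(table, NONDISABLED, terms=spec.ppo_terms,
                   covariates=spec.ppo_covariates, center=float(spec.window[0]))
    m_d = fit_ppo(table, DISABLED, terms=spec.ppo_terms,
                  covariates=spec.ppo_covariates, center=float(spec.window[0]))
    ages = np.arange(spec.window[0], spec.window[1] + 1)
    matrices = build_matrix_set(m_nd, m_d, ages)
    baseline = BaselineDistribution.from_panel(sub, weights=np.where(w > 0, w, 0.0))
    return microsimulate(matrices, baseline, spec.window, n=rep_n, seed=sim_ss,
                         death_credit=spec.death_credit, allocation=spec.allocation)


def nonparametric_p(diff_replicates) -> float:
    """Two-sided nonparametric p-value from the replicate-difference
    distribution: p = 2 min(#{d <= 0}, #{d >= 0}) / B, capped at 1.
    A zero count yields 0.0 (reported as "< 0.001")."""
    d = np.asarray(diff_replicates, dtype=float)
    if d.size < 1:
        raise ValueError("need at least one replicate difference")
    le = int((d <= 0).sum())
    ge = int((d >= 0).sum())
    return min(2 * min(le, ge) / d.size, 1.0)


@dataclass
class CohortComparison:
    """Later-minus-earlier difference in one life-table quantity."""

    quantity: str
    diff: float
    ci: tuple[float, float] | None
    p_value: float
    earlier_point: float
    later_point: float
    earlier_ci: tuple[float, float] | None = None
    later_ci: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        return {"quantity": self.quantity, "diff": self.diff,
                "ci": list(self.ci) if self.ci else None, "p_value": self.p_value,
                "earlier_point": self.earlier_point, "later_point": self.later_point,
                "earlier_ci": list(self.earlier_ci) if self.earlier_ci else None,
                "later_ci": list(self.later_ci) if self.later_ci else None}


def compare_cohorts(earlier: BootstrapResult, later: BootstrapResult,
                    pairing: str = "index") -> dict[str, CohortComparison]:
    """Cohort comparison per quantity.  The replicate-difference
    distribution pairs replicates by index (default) or forms all pairs
    (``pairing="pooled"``); under independent resampling the two agree
    within Monte-Carlo tolerance."""
    if earlier.point.window != later.point.window:
        raise ValueError("cohort windows differ")
    out = {}
    for q in QUANTITIES:
        e, l = earlier.replicates[q], later.replicates[q]
        if pairing == "index":
            if len(e) != len(l):
                raise ValueError(f"mismatched replicate counts ({len(e)} vs {len(l)})")
            d = l - e
        elif pairing == "pooled":
            d = (l[:, None] - e[None, :]).ravel()
        else:
            raise ValueError(f"unknown pairing {pairing!r}")
        diff = getattr(later.point, q) - getattr(earlier.point, q)
        ci = percentile_interval(d) if d.size >= 2 else None
        out[q] = CohortComparison(
            quantity=q, diff=diff, ci=ci, p_value=nonparametric_p(d),
            earlier_point=getattr(earlier.point, q),
            later_point=getattr(later.point, q),
            earlier_ci=earlier.ci.get(q), later_ci=later.ci.get(q))
    return out
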