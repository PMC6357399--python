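"""Inverse-probability-of-attrition weights.

Complete cases (individuals not lost to follow-up; death counts as a
complete observation of the outcome) are weighted by the reciprocal of
their modeled probability of being a complete case, multiplied by the
cross-sectional sampling weight.  The weight-generating logistic model
includes the sociodemographic profile, baseline disability state, any
auxiliary attrition predictors carried by the panel, and the sampling
weight itself as a covariate.  Weights are fit per dataset — i.e.
separately by cohort and age group when the pipeline is run per cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .panel import DISABLED, PanelDataset

logger = logging.getLogger(__name__)

BASE_PREDICTORS = ("woman", "rural", "schooled", "baseline_disabled", "sampling_weight")


class SeparationError(RuntimeError):
    """Perfect separation in the attrition model."""


@dataclass
class AttritionModel:
    """Fitted logistic model of being a complete case."""

    params: pd.Series | None
    predictors: tuple[str, ...]
    loglik: float | None
    converged: bool
    trivial: bool = False   # no dropout observed: predicts probability 1

    def predict(self, data: PanelDataset) -> np.ndarray:
        if self.trivial:
            return np.ones(data.n)
        X = _design(data, self.predictors)
        eta = X @ self.params.to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))


def _design(data: PanelDataset, predictors) -> np.ndarray:
    ind = data.individuals
    cols = [np.ones(data.n)]
    for p in predictors:
        if p == "baseline_disabled":
            cols.append((data.baseline_state == DISABLED).astype(float))
        else:
            cols.append(ind[p].to_numpy(float))
    return np.column_stack(cols)


def fit_attrition_model(data: PanelDataset,
                        extra_predictors: tuple[str, ...] | None = None) -> AttritionModel:
    """Maximum-likelihood logistic model of complete-case status.

    ``extra_predictors`` defaults to the panel's auxiliary covariate
    columns.  A panel with no dropout yields a trivial model predicting
    probability 1 for everyone.
    """
    if extra_predictors is None:
        extra_predictors = data.aux_columns
    complete = ~data.individuals["lost"].to_numpy(bool)
    if complete.all():
        return AttritionModel(params=None, predictors=(), loglik=None,
                              converged=True, trivial=True)
    predictors = list(BASE_PREDICTORS) + [p for p in extra_predictors
                                          if p not in BASE_PREDICTORS]
    X = _design(data, predictors)
    # drop constant columns (e.g. unit sampling weights collinear with intercept)
    keep = [0] + [j for j in range(1, X.shape[1]) if np.ptp(X[:, j]) > 0]
    predictors = tuple(predictors[j - 1] for j in keep[1:])
    X = X[:, keep]
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(complete.astype(float), X).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparationError subclasses
        raise SeparationError(
            f"attrition model failed (possible perfect separation) on predictors "
            f"{predictors}: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise SeparationError(
            f"attrition model did not converge; largest |coef| on "
            f"{predictors[int(np.argmax(np.abs(res.params[1:])))]}")
    params = pd.Series(res.params, index=["intercept"] + list(predictors))
    return AttritionModel(params=params, predictors=predictors,
                          loglik=float(res.llf), converged=True)


def compute_analysis_weights(model: AttritionModel, data: PanelDataset,
                             truncation: tuple[float, float] | None = (1, 99)
                             ) -> np.ndarray:
    """Per-individual analysis weights: sampling weight divided by the
    predicted complete-case probability for complete cases, 0 for cases
    lost to follow-up (complete-case analysis).  Positive weights are
    truncated at the given percentile pair (pass None to disable)."""
    sw = data.individuals["sampling_weight"].to_numpy(float)
    if np.any(sw <= 0) or np.any(~np.isfinite(sw)):
        raise ValueError("sampling weights must be positive and finite")
    complete = ~data.individuals["lost"].to_numpy(bool)
    p = model.predict(data)
    w = np.where(complete, sw / np.clip(p, 1e-12, None), 0.0)
    if truncation is not None and complete.any():
        lo, hi = np.percentile(w[complete], truncation)
        w[complete] = np.clip(w[complete], lo, hi)
    logger.info("analysis weights: n_complete=%d sum=%.3f",
                int(complete.sum()), float(w.sum()))
    return w
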