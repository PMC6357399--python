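"""Partial-proportional-odds cumulative-logit models of annual transitions.

Annual transitions out of a living origin state are modeled on the ordered
outcome nondisabled < disabled < dead with two cumulative logits

    P(Y <= j) = expit(alpha_j + beta . x + gamma_j . z),   j = 1, 2,

where x are shared-slope terms (age, optionally age^2 and age x sex) and
z = (woman, rural, schooled) carry logit-specific coefficients — i.e. the
proportional-odds assumption is relaxed for sex, residence and schooling.
Fits are weighted maximum likelihood via Newton iteration on the analytic
gradient; models are fit separately by origin state, and the fitted pair
yields age- and profile-indexed 3x3 transition matrices with death
absorbing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .panel import (DEAD, DISABLED, NONDISABLED,
                    PROFILE_RURAL, PROFILE_SCHOOLED, PROFILE_WOMAN,
                    CovariateProfile, STATE_LABELS)

GAMMA_COVARIATES = ("woman", "rural", "schooled")
SHARED_TERMS = ("age", "age2", "age_x_woman")

# Largest tolerated negative middle-category probability before a hard
# error: partial-PO curves may cross slightly from rounding; anything
# beyond this signals a genuinely invalid model.
CROSSING_TOLERANCE = 1e-8


class FitError(RuntimeError):
    """Raised when a PPO fit cannot be completed."""


class CrossingError(ValueError):
    """Cumulative curves cross: negative category probability beyond tolerance."""


@dataclass
class PPOModel:
    """Fitted (or ground-truth) partial-proportional-odds coefficients for
    transitions out of one origin state."""

    origin: int                                  # NONDISABLED or DISABLED
    center: float                                # age centering constant
    alpha: tuple[float, float]                   # cutpoints for the two logits
    shared: dict[str, float]                     # shared-slope terms, keys in SHARED_TERMS
    gamma: dict[str, tuple[float, float]]        # per-logit coefficients, keys in GAMMA_COVARIATES
    se: dict[str, float] | None = None
    loglik: float | None = None
    n_iter: int | None = None
    converged: bool = True
    n_obs: int | None = None
    sum_weights: float | None = None

    def linear_predictors(self, age, woman, rural, schooled, shift=0.0):
        """Both cumulative-logit linear predictors; broadcasts over arrays."""
        age = np.asarray(age, dtype=float)
        x = age - self.center
        shared = self.shared.get("age", 0.0) * x
        if "age2" in self.shared:
            shared = shared + self.shared["age2"] * x * x
        if "age_x_woman" in self.shared:
            shared = shared + self.shared["age_x_woman"] * x * np.asarray(woman)
        z = {"woman": np.asarray(woman), "rural": np.asarray(rural),
             "schooled": np.asarray(schooled)}
        g1 = sum(self.gamma[k][0] * z[k] for k in self.gamma)
        g2 = sum(self.gamma[k][1] * z[k] for k in self.gamma)
        eta1 = self.alpha[0] + shared + g1 + shift
        eta2 = self.alpha[1] + shared + g2 + shift
        return eta1, eta2

    def predict(self, age, woman, rural, schooled, shift=0.0) -> np.ndarray:
        """Category probabilities (nondisabled, disabled, dead); final axis 3.

        Tiny negative middle-category values (within the crossing
        tolerance) are clamped to zero and the row renormalized; larger
        violations raise CrossingError.
        """
        eta1, eta2 = self.linear_predictors(age, woman, rural, schooled, shift)
        f1, f2 = expit(eta1), expit(eta2)
        p = np.stack([f1, f2 - f1, 1.0 - f2], axis=-1)
        mid = p[..., 1]
        if np.any(mid < -CROSSING_TOLERANCE):
            worst = float(np.min(mid))
            raise CrossingError(
                f"cumulative curves cross for origin {STATE_LABELS[self.origin]}: "
                f"middle-category probability {worst:.3g}")
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=-1, keepdims=True)
        return p

    def coefficient_names(self) -> list[str]:
        names = ["alpha1", "alpha2"] + [f"beta_{t}" for t in self.shared]
        names += [f"gamma1_{k}" for k in self.gamma] + [f"gamma2_{k}" for k in self.gamma]
        return names

    def coefficients(self) -> dict[str, float]:
        out = {"alpha1": self.alpha[0], "alpha2": self.alpha[1]}
        out.update({f"beta_{t}": v for t, v in self.shared.items()})
        out.update({f"gamma1_{k}": v[0] for k, v in self.gamma.items()})
        out.update({f"gamma2_{k}": v[1] for k, v in self.gamma.items()})
        return out

    def to_dict(self) -> dict:
        return {"origin": int(self.origin), "center": self.center,
                "alpha": list(self.alpha), "shared": dict(self.shared),
                "gamma": {k: list(v) for k, v in self.gamma.items()},
                "se": self.se, "loglik": self.loglik, "n_iter": self.n_iter,
                "converged": self.converged, "n_obs": self.n_obs,
                "sum_weights": self.sum_weights}

    @classmethod
    def from_dict(cls, d: dict) -> "PPOModel":
        return cls(origin=d["origin"], center=d["center"], alpha=tuple(d["alpha"]),
                   shared=dict(d["shared"]),
                   gamma={k: tuple(v) for k, v in d["gamma"].items()},
                   se=d.get("se"), loglik=d.get("loglik"), n_iter=d.get("n_iter"),
                   converged=d.get("converged", True), n_obs=d.get("n_obs"),
                   sum_weights=d.get("sum_weights"))


def predict_transition(model: PPOModel, age, profile: CovariateProfile,
                       shift: float = 0.0) -> np.ndarray:
    """Probability vector over (nondisabled, disabled, dead) at one age/profile."""
    return model.predict(age, profile.woman, profile.rural, profile.schooled, shift)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _aggregate(records, origin: int):
    """Collapse person-year records with a common origin into weighted counts
    per (age, profile) cell: returns ages, woman, rural, schooled arrays of
    length m and an (m, 3) weight matrix over destinations."""
    mask = records.origin == origin
    if not np.any(mask):
        raise FitError(f"no person-years with origin {STATE_LABELS[origin]}")
    age = records.age[mask].astype(np.int64)
    dest = records.dest[mask].astype(np.int64)
    prof = (records.woman[mask].astype(np.int64) * 4
            + records.rural[mask].astype(np.int64) * 2
            + records.schooled[mask].astype(np.int64))
    w = records.weight[mask]
    amin = int(age.min())
    n_ages = int(age.max()) - amin + 1
    code = ((age - amin) * 8 + prof) * 3 + dest
    totals = np.bincount(code, weights=w, minlength=n_ages * 24).reshape(n_ages * 8, 3)
    keep = totals.sum(axis=1) > 0
    cell = np.nonzero(keep)[0]
    cell_age = amin + cell // 8
    cell_prof = cell % 8
    return (cell_age.astype(float), PROFILE_WOMAN[cell_prof].astype(float),
            PROFILE_RURAL[cell_prof].astype(float),
            PROFILE_SCHOOLED[cell_prof].astype(float), totals[keep])


class _PPOLikelihood:
    """Weighted cumulative-logit log-likelihood on aggregated cells.

    Parameter vector layout: [alpha1, alpha2, beta (shared terms...),
    gamma1 (covariates...), gamma2 (covariates...)].
    """

    def __init__(self, age, woman, rural, schooled, w3, center,
                 terms=("age",), covariates=GAMMA_COVARIATES):
        self.terms = tuple(terms)
        self.covariates = tuple(covariates)
        x = age - center
        cols = []
        for t in self.terms:
            if t == "age":
                cols.append(x)
            elif t == "age2":
                cols.append(x * x)
            elif t == "age_x_woman":
                cols.append(x * woman)
            else:
                raise ValueError(f"unknown shared term {t!r}")
        self.X = np.column_stack(cols) if cols else np.zeros((len(age), 0))
        zmap = {"woman": woman, "rural": rural, "schooled": schooled}
        self.Z = (np.column_stack([zmap[c] for c in self.covariates])
                  if self.covariates else np.zeros((len(age), 0)))
        self.W = w3
        self.n_shared = self.X.shape[1]
        self.n_z = self.Z.shape[1]
        self.n_params = 2 + self.n_shared + 2 * self.n_z

    def unpack(self, theta):
        k = 2 + self.n_shared
        return (theta[0], theta[1], theta[2:k],
                theta[k:k + self.n_z], theta[k + self.n_z:])

    def etas(self, theta):
        a1, a2, b, g1, g2 = self.unpack(theta)
        shared = self.X @ b
        return a1 + shared + self.Z @ g1, a2 + shared + self.Z @ g2

    def nll(self, theta) -> float:
        eta1, eta2 = self.etas(theta)
        f1, f2 = expit(eta1), expit(eta2)
        mid = f2 - f1
        w = self.W
        if np.any((mid <= 0) & (w[:, 1] > 0)):
            return np.inf
        with np.errstate(divide="ignore"):
            ll = (w[:, 0] * np.log(f1)
                  + np.where(w[:, 1] > 0, w[:, 1] * np.log(np.maximum(mid, 1e-300)), 0.0)
                  + w[:, 2] * np.log1p(-f2))
        return -float(ll.sum())

    def grad(self, theta) -> np.ndarray:
        eta1, eta2 = self.etas(theta)
        f1, f2 = expit(eta1), expit(eta2)
        mid = np.maximum(f2 - f1, 1e-300)
        w = self.W
        d1 = f1 * (1 - f1)
        d2 = f2 * (1 - f2)
        # dll/deta1, dll/deta2 per cell
        g_eta1 = w[:, 0] * (1 - f1) - w[:, 1] * d1 / mid
        g_eta2 = w[:, 1] * d2 / mid - w[:, 2] * f2
        g = np.empty(self.n_params)
        g[0] = g_eta1.sum()
        g[1] = g_eta2.sum()
        k = 2 + self.n_shared
        if self.n_shared:
            g[2:k] = self.X.T @ (g_eta1 + g_eta2)
        if self.n_z:
            g[k:k + self.n_z] = self.Z.T @ g_eta1
            g[k + self.n_z:] = self.Z.T @ g_eta2
        return -g

    def _jacobians(self):
        """Cells x params Jacobians of the two linear predictors."""
        m = len(self.W)
        ones, zeros = np.ones((m, 1)), np.zeros((m, 1))
        J1 = np.hstack([ones, zeros, self.X, self.Z, np.zeros_like(self.Z)])
        J2 = np.hstack([zeros, ones, self.X, np.zeros_like(self.Z), self.Z])
        return J1, J2

    def hess(self, theta) -> np.ndarray:
        """Analytic Hessian of the negative log-likelihood."""
        eta1, eta2 = self.etas(theta)
        f1c, f2c = expit(eta1), expit(eta2)
        w = self.W
        # middle-category terms only contribute where w2 > 0 (and there the
        # line search keeps f2 - f1 strictly positive)
        has_mid = w[:, 1] > 0
        D2 = np.where(has_mid, np.maximum(f2c - f1c, 1e-12), 1.0) ** 2
        D = np.where(has_mid, np.maximum(f2c - f1c, 1e-12), 1.0)
        f1 = f1c * (1 - f1c)
        f2 = f2c * (1 - f2c)
        # second partials of the log-likelihood in (eta1, eta2)
        h11 = -w[:, 0] * f1 - w[:, 1] * (f1 * (1 - 2 * f1c) * D + f1 ** 2) / D2
        h22 = w[:, 1] * (f2 * (1 - 2 * f2c) * D - f2 ** 2) / D2 - w[:, 2] * f2
        h12 = w[:, 1] * f1 * f2 / D2
        J1, J2 = self._jacobians()
        H = (J1.T * h11) @ J1 + (J2.T * h22) @ J2
        C = (J1.T * h12) @ J2
        H += C + C.T
        return -H


def _start_values(lik: _PPOLikelihood) -> np.ndarray:
    w = lik.W.sum(axis=0)
    total = w.sum()
    c1 = min(max(w[0] / total, 1e-4), 1 - 1e-4)
    c2 = min(max((w[0] + w[1]) / total, c1 + 1e-4), 1 - 1e-4)
    theta = np.zeros(lik.n_params)
    theta[0] = np.log(c1 / (1 - c1))
    theta[1] = np.log(c2 / (1 - c2))
    return theta


def _newton(lik: _PPOLikelihood, theta0: np.ndarray, gtol: float = 1e-8,
            max_iter: int = 100):
    theta = theta0.copy()
    f = lik.nll(theta)
    trace = [f]
    for it in range(1, max_iter + 1):
        g = lik.grad(theta)
        gnorm = np.max(np.abs(g))
        if gnorm < gtol:
            return theta, f, it - 1, True, trace
        H = lik.hess(theta)
        # ridge the Hessian if needed: the partial-PO likelihood is not
        # globally concave, so the raw Newton direction can fail to descend
        step = None
        ridge = 0.0
        eye = np.eye(len(theta))
        for _ in range(12):
            try:
                cand = np.linalg.solve(H + ridge * eye, -g)
            except np.linalg.LinAlgError:
                cand = None
            if cand is not None and g @ cand < 0:
                step = cand
                break
            ridge = 1e-6 * np.abs(np.diag(H)).max() if ridge == 0.0 else ridge * 10
        if step is None:
            step = -g
        lam = 1.0
        for _ in range(60):
            f_new = lik.nll(theta + lam * step)
            if f_new < f:
                break
            lam *= 0.5
        else:
            # objective decrease below float resolution; in the quadratic
            # region the full Newton step still shrinks the gradient —
            # accept it as long as it does, else we are done
            g_new = lik.grad(theta + step)
            if np.isfinite(lik.nll(theta + step)) \
                    and np.max(np.abs(g_new)) < 0.5 * gnorm:
                theta = theta + step
                f = lik.nll(theta)
                trace.append(f)
                continue
            return theta, f, it, gnorm < 1e-5, trace
        theta = theta + lam * step
        f = f_new
        trace.append(f)
    g = lik.grad(theta)
    return theta, f, max_iter, np.max(np.abs(g)) < gtol, trace


def fit_ppo(records, origin: int, terms=("age",), covariates=GAMMA_COVARIATES,
            center: float | None = None, gtol: float = 1e-8,
            max_iter: int = 100) -> PPOModel:
    """Weighted maximum-likelihood fit of the PPO model for one origin state.

    ``records`` is a PersonYearTable; ``terms`` are shared-slope terms
    (subset of ``("age", "age2", "age_x_woman")``); ``covariates`` get
    logit-specific coefficients.  Deterministic given the data.
    """
    if origin not in (NONDISABLED, DISABLED):
        raise ValueError("origin must be nondisabled or disabled")
    age, woman, rural, schooled, W = _aggregate(records, origin)
    cat_totals = W.sum(axis=0)
    if np.any(cat_totals <= 0):
        empty = [STATE_LABELS[i] for i in range(3) if cat_totals[i] <= 0]
        raise FitError(
            f"empty outcome category {empty} for origin {STATE_LABELS[origin]}: "
            "cumulative-logit MLE is on the boundary")
    if center is None:
        center = float(np.floor(age.min()))
    lik = _PPOLikelihood(age, woman, rural, schooled, W, center,
                         terms=terms, covariates=covariates)
    theta, f, n_iter, converged, trace = _newton(lik, _start_values(lik), gtol, max_iter)
    if not converged:
        raise FitError(
            f"PPO fit did not converge in {max_iter} iterations "
            f"(origin {STATE_LABELS[origin]}); nll trace tail {trace[-5:]}")
    H = lik.hess(theta)
    try:
        cov = np.linalg.inv(H)
        se_vec = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se_vec = np.full(lik.n_params, np.nan)
    k = 2 + lik.n_shared
    model = PPOModel(
        origin=origin, center=center,
        alpha=(float(theta[0]), float(theta[1])),
        shared={t: float(v) for t, v in zip(terms, theta[2:k])},
        gamma={c: (float(theta[k + i]), float(theta[k + lik.n_z + i]))
               for i, c in enumerate(covariates)},
        loglik=-f, n_iter=n_iter, converged=converged,
        n_obs=int(np.sum(records.origin == origin)),
        sum_weights=float(W.sum()),
    )
    model.se = dict(zip(model.coefficient_names(), se_vec))
    bad = check_validity(model, np.arange(int(age.min()), int(age.max()) + 1))
    if bad:
        warnings.warn(
            f"partial-PO cumulative curves cross on the data domain for "
            f"{len(bad)} (age, profile) cells, e.g. {bad[:3]}", stacklevel=2)
    return model


def check_validity(model: PPOModel, ages) -> list[tuple[int, int]]:
    """Cells of the age x profile grid where the middle-category probability
    is negative beyond the crossing tolerance."""
    ages = np.asarray(ages)
    eta1, eta2 = model.linear_predictors(
        ages[:, None], PROFILE_WOMAN[None, :], PROFILE_RURAL[None, :],
        PROFILE_SCHOOLED[None, :])
    mid = expit(eta2) - expit(eta1)
    bad = np.argwhere(mid < -CROSSING_TOLERANCE)
    return [(int(ages[i]), int(j)) for i, j in bad]


def loglik_at(records, origin: int, model: PPOModel, terms=None,
              covariates=None) -> float:
    """Evaluate the weighted log-likelihood of ``records`` at a given model
    (used for optimality checks and cross-validation against references)."""
    terms = tuple(model.shared) if terms is None else terms
    covariates = tuple(model.gamma) if covariates is None else covariates
    age, woman, rural, schooled, W = _aggregate(records, origin)
    lik = _PPOLikelihood(age, woman, rural, schooled, W, model.center,
                         terms=terms, covariates=covariates)
    theta = np.concatenate([
        model.alpha,
        [model.shared[t] for t in terms],
        [model.gamma[c][0] for c in covariates],
        [model.gamma[c][1] for c in covariates]])
    return -lik.nll(np.asarray(theta, dtype=float))


def test_extra_terms(records, origin: int, alpha: float = 0.05,
                     base_terms=("age",), extra_terms=("age2", "age_x_woman"),
                     covariates=GAMMA_COVARIATES) -> dict:
    """Fit the model extended with ``extra_terms`` and report a Wald test
    per extra term with a keep/drop recommendation at the given level."""
    model = fit_ppo(records, origin, terms=tuple(base_terms) + tuple(extra_terms),
                    covariates=covariates)
    report = {}
    for t in extra_terms:
        coef = model.shared[t]
        se = model.se[f"beta_{t}"]
        z = coef / se if se > 0 else np.nan
        p = 2 * norm.sf(abs(z)) if np.isfinite(z) else np.nan
        report[t] = {"coef": coef, "se": se, "z": z, "p": p,
                     "keep": bool(np.isfinite(p) and p < alpha)}
    return report


# ---------------------------------------------------------------------------
# Transition matrices
# ---------------------------------------------------------------------------

@dataclass
class TransitionMatrixSet:
    """Age- and profile-indexed 3x3 annual transition matrices.

    ``probs`` has shape (n_ages, 8, 3, 3) over (age, profile, origin,
    destination); rows are stochastic and dead is absorbing.
    """

    ages: np.ndarray
    probs: np.ndarray

    def __post_init__(self):
        self.ages = np.asarray(self.ages)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (len(self.ages), 8, 3, 3):
            raise ValueError(f"probs must have shape (n_ages, 8, 3, 3), got {self.probs.shape}")

    def validate(self, atol: float = 1e-12) -> None:
        sums = self.probs.sum(axis=-1)
        if np.any(np.abs(sums - 1.0) > atol):
            raise ValueError("transition-matrix rows do not sum to 1")
        if np.any((self.probs < 0) | (self.probs > 1)):
            raise ValueError("transition probabilities outside [0, 1]")
        dead_row = self.probs[:, :, DEAD, :]
        if not (np.all(dead_row[..., DEAD] == 1.0)
                and np.all(dead_row[..., :DEAD] == 0.0)):
            raise ValueError("dead is not absorbing")

    def age_index(self, age: int) -> int:
        idx = np.searchsorted(self.ages, age)
        if idx >= len(self.ages) or self.ages[idx] != age:
            raise KeyError(f"age {age} not covered by this matrix set")
        return int(idx)

    def row(self, age: int, profile_idx: int, state: int) -> np.ndarray:
        return self.probs[self.age_index(age), profile_idx, state]


def build_matrix_set(model_nd: PPOModel, model_d: PPOModel, ages,
                     shift: float = 0.0) -> TransitionMatrixSet:
    """Transition matrices over an age range from the fitted origin-state
    models; the dead row is (0, 0, 1)."""
    if model_nd.origin != NONDISABLED or model_d.origin != DISABLED:
        raise ValueError("models must be (origin nondisabled, origin disabled)")
    ages = np.asarray(ages)
    grid_w = PROFILE_WOMAN[None, :].astype(float)
    grid_r = PROFILE_RURAL[None, :].astype(float)
    grid_s = PROFILE_SCHOOLED[None, :].astype(float)
    age_grid = ages[:, None].astype(float)
    probs = np.zeros((len(ages), 8, 3, 3))
    probs[:, :, NONDISABLED, :] = model_nd.predict(age_grid, grid_w, grid_r, grid_s, shift)
    probs[:, :, DISABLED, :] = model_d.predict(age_grid, grid_w, grid_r, grid_s, shift)
    probs[:, :, DEAD, DEAD] = 1.0
    out = TransitionMatrixSet(ages=ages, probs=probs)
    out.validate(atol=1e-9)
    # Renormalize away float round-off so downstream consumers see exact rows.
    out.probs /= out.probs.sum(axis=-1, keepdims=True)
    return out
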