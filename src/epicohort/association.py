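"""Covariate-adjusted permutation test of incremental predictive value.

For each outcome variable the question is whether a binary exposure improves
out-of-sample prediction beyond a covariate block.  The statistic is the
increment in leave-one-out cross-validated R-squared,

    delta = R2_loocv(covariates + exposure) - R2_loocv(covariates),

with R2 = 1 - sum (y_i - yhat_(-i))^2 / sum (y_i - ybar)^2 using the
full-sample mean in the denominator (so R2 can be negative: a model that
predicts worse than the mean).  The null distribution of delta is built by
uniformly permuting the exposure labels, which preserves the covariate
structure and both group sizes; the empirical p-value uses the add-one rule
(#{delta_b >= delta_obs} + 1) / (B + 1), never returning 0.  Family-wise
adjustment across outcome variables is plain Bonferroni by default (a Holm
step-down variant is available).

Regressors are pluggable: ordinary least squares (with per-fold column
standardization, a no-op for OLS predictions but kept for parity with the
scaled pipeline), random forest, extremely-randomized trees, and gradient
boosting.  For the linear family the LOOCV predictions are computed exactly
through the leave-one-out identity e_i / (1 - h_ii) on the hat matrix
(rank-truncated SVD, valid for collinear designs), which makes
thousand-permutation runs cheap; tree families use an explicit refit loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    ExtraTreesRegressor,
    GradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import LeaveOneOut, cross_val_predict
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .errors import ConfigurationError, InputError
from .simulate import CohortTable

FAMILIES = ("linear", "random-forest", "extra-trees", "gradient-boosting")
FAMILY_ABBREV = {
    "linear": "LR",
    "random-forest": "RF",
    "extra-trees": "ET",
    "gradient-boosting": "GB",
}

#: tolerance absorbing float jitter when counting permuted deltas >= observed
_TIE_EPS = 1e-12


@dataclass(frozen=True)
class RegressorSpec:
    """One regression family plus its hyperparameters."""

    family: str
    params: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(
                f"family must be one of {FAMILIES}, got {self.family!r}"
            )

    def build(self, seed: int | None = None):
        """Instantiate the sklearn estimator with a fixed fit seed."""
        params = dict(self.params or {})
        rs = self.seed if seed is None else seed
        try:
            if self.family == "linear":
                return Pipeline(
                    [("scale", StandardScaler()), ("ols", LinearRegression(**params))]
                )
            if self.family == "random-forest":
                params.setdefault("n_estimators", 100)
                return RandomForestRegressor(random_state=rs, **params)
            if self.family == "extra-trees":
                params.setdefault("n_estimators", 100)
                return ExtraTreesRegressor(random_state=rs, **params)
            params.setdefault("n_estimators", 100)
            params.setdefault("max_depth", 3)
            params.setdefault("learning_rate", 0.1)
            return GradientBoostingRegressor(random_state=rs, **params)
        except TypeError as exc:
            raise ConfigurationError(
                f"invalid hyperparameters for {self.family}: {exc}"
            ) from exc


def default_regressor_specs(seed: int = 0) -> list[RegressorSpec]:
    """The four standard families with their default hyperparameters."""
    return [RegressorSpec(family, seed=seed) for family in FAMILIES]


@dataclass
class AssocResult:
    """One (outcome, regressor) cell of the association analysis.

    ``delta_r2`` is the observed test statistic (full minus covariates-only
    baseline); ``delta_vs_permuted`` is the full-model R2 minus the mean
    permuted full-model R2, the increment conventionally printed in summary
    tables.  ``p_adjusted`` is filled by the family-wise adjustment step.
    """

    dv: str
    family: str
    r2_full_true: float
    r2_baseline: float
    r2_permuted_mean: float
    p_base: float
    n_permutations: int
    p_adjusted: float | None = None

    @property
    def delta_r2(self) -> float:
        return self.r2_full_true - self.r2_baseline

    @property
    def delta_vs_permuted(self) -> float:
        return self.r2_full_true - self.r2_permuted_mean


# ---------------------------------------------------------------------------
# LOOCV


def _check_xy(features, response):
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(response, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise InputError("features and response disagree on n")
    if X.shape[0] < 3:
        raise InputError("LOOCV needs n >= 3")
    if np.isnan(X).any() or np.isnan(y).any():
        raise InputError("missing values in features or response")
    if np.ptp(y) == 0:
        raise InputError("constant response: R2 denominator is zero")
    return X, y


def _linear_loocv_predictions(X: np.ndarray, y: np.ndarray) -> np.ndarray | None:
    """Exact LOOCV predictions for OLS via the hat-matrix identity.

    Uses the projection onto the design's column space (rank-truncated SVD),
    so collinear designs are handled like sklearn's least-squares solution.
    Returns None when a leverage reaches 1 (a fold whose deleted fit is not
    identified); callers then fall back to the explicit refit loop.
    """
    design = np.column_stack([np.ones_like(y), X])
    u, s, _ = np.linalg.svd(design, full_matrices=False)
    keep = s > s[0] * max(design.shape) * np.finfo(float).eps
    u = u[:, keep]
    leverage = np.einsum("ij,ij->i", u, u)
    residual = y - u @ (u.T @ y)
    denom = 1.0 - leverage
    if np.any(denom < 1e-10):
        return None
    return y - residual / denom


def loocv_r2(spec: RegressorSpec, features, response, seed: int | None = None) -> float:
    """Leave-one-out cross-validated out-of-sample R-squared.

    R2 = 1 - sum_i (y_i - yhat_(-i))^2 / sum_i (y_i - ybar)^2 with ybar the
    full-sample mean; may be negative.  Deterministic given (spec, data,
    seed).
    """
    X, y = _check_xy(features, response)
    preds = None
    if spec.family == "linear":
        preds = _linear_loocv_predictions(X, y)
    if preds is None:
        est = spec.build(seed)
        preds = cross_val_predict(est, X, y, cv=LeaveOneOut())
    ss_res = float(np.sum((y - preds) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# permutation test


def draw_permutations(n: int, B: int, seed) -> np.ndarray:
    """B uniform random permutations of range(n), as a (B, n) index array."""
    rng = np.random.default_rng(seed)
    return np.array([rng.permutation(n) for _ in range(B)])


def _exhaustive_exposures(exposure: np.ndarray) -> np.ndarray:
    """All distinct label arrangements with the observed group sizes."""
    n = len(exposure)
    values = np.unique(exposure)
    k = int(np.sum(exposure == values[1]))
    rows = []
    for pos in combinations(range(n), k):
        row = np.full(n, values[0], dtype=float)
        row[list(pos)] = values[1]
        rows.append(row)
    return np.array(rows)


def permutation_assoc_test(
    response,
    covariates,
    exposure,
    spec: RegressorSpec,
    B: int = 10_000,
    seed: int | None = 0,
    *,
    permutations: np.ndarray | None = None,
    exhaustive: bool = False,
    dv_name: str = "",
) -> AssocResult:
    """Permutation test of the exposure's incremental LOOCV R-squared.

    The observed statistic is delta_obs = R2(covariates + exposure) -
    R2(covariates); each permutation refits the full model with a uniformly
    shuffled exposure vector.  ``permutations`` may supply pre-drawn index
    arrays (shape (B, n)) so several regressors see identical nulls;
    ``exhaustive=True`` instead enumerates every distinct label arrangement
    (feasible only for small n) and reports the exact permutation p-value,
    the observed arrangement included.
    """
    X, y = _check_xy(covariates, response)
    expo = np.asarray(exposure, dtype=float)
    if expo.shape[0] != y.shape[0]:
        raise InputError("exposure length mismatch")
    if len(np.unique(expo)) < 2:
        raise InputError("exposure must contain both labels")
    if not exhaustive and B < 1:
        raise InputError("B must be >= 1")

    r2_baseline = loocv_r2(spec, X, y, seed)
    r2_full = loocv_r2(spec, np.column_stack([X, expo]), y, seed)
    delta_obs = r2_full - r2_baseline

    if exhaustive:
        permuted_exposures = _exhaustive_exposures(expo)
    elif permutations is not None:
        permuted_exposures = expo[np.asarray(permutations)]
    else:
        permuted_exposures = expo[draw_permutations(len(y), B, seed)]

    r2_perm = np.array(
        [
            loocv_r2(spec, np.column_stack([X, pe]), y, seed)
            for pe in permuted_exposures
        ]
    )
    deltas = r2_perm - r2_baseline
    n_ge = int(np.sum(deltas >= delta_obs - _TIE_EPS))
    n_perm = len(permuted_exposures)
    if exhaustive:
        p_base = n_ge / n_perm  # observed arrangement is among the n_perm
    else:
        p_base = (n_ge + 1) / (n_perm + 1)
    return AssocResult(
        dv=dv_name,
        family=spec.family,
        r2_full_true=r2_full,
        r2_baseline=r2_baseline,
        r2_permuted_mean=float(r2_perm.mean()),
        p_base=p_base,
        n_permutations=n_perm,
    )


# ---------------------------------------------------------------------------
# multiplicity


def adjust_pvalues(p_values, m: int | None = None, method: str = "bonferroni"):
    """Family-wise adjustment across outcome variables.

    ``bonferroni`` (default): min(1, p * m).  ``holm``: step-down with
    multipliers m, m-1, ... enforcing monotonicity.  ``m`` may exceed the
    vector length when the family is larger than the p-values at hand.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise InputError("p-values must lie in (0, 1]")
    if m is None:
        m = len(p)
    if m < len(p):
        raise InputError(f"family size m={m} smaller than {len(p)} p-values")
    if method == "bonferroni":
        return np.minimum(1.0, p * m)
    if method == "holm":
        order = np.argsort(p, kind="stable")
        adj = np.empty_like(p)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, min(1.0, p[idx] * (m - rank)))
            adj[idx] = running
        return adj
    raise ConfigurationError(f"unknown adjustment method {method!r}")


# ---------------------------------------------------------------------------
# full analysis


def run_full_analysis(
    cohort: CohortTable,
    dvs: list[str] | None = None,
    covariates: list[str] | None = None,
    exposure: str | None = None,
    specs: list[RegressorSpec] | None = None,
    B: int = 10_000,
    seed: int = 0,
    adjust_method: str = "bonferroni",
) -> list[AssocResult]:
    """One permutation test per (outcome, regressor) cell.

    Permutation draws are shared across regressors within each outcome so
    every family sees the identical null labelings; the family-wise
    adjustment is applied per regressor family across the outcomes.
    Group-restricted covariates are excluded from the default covariate
    block (they are missing for one group).
    """
    if dvs is None:
        dvs = list(cohort.dependent)
    if covariates is None:
        covariates = [c for c in cohort.covariate_names if c not in cohort.restricted]
    if exposure is None:
        exposure = cohort.group_col
    if specs is None:
        specs = default_regressor_specs(seed)
    missing = [
        c for c in list(dvs) + list(covariates) + [exposure]
        if c not in cohort.data.columns
    ]
    if missing:
        raise InputError(f"columns not in cohort: {missing}")
    selected = cohort.data[list(dvs) + list(covariates) + [exposure]]
    if selected.isna().any().any():
        bad = selected.columns[selected.isna().any()].tolist()
        raise InputError(f"missing values in selected columns: {bad}")

    X = cohort.data[list(covariates)].to_numpy(dtype=float)
    expo = cohort.data[exposure].to_numpy(dtype=float)
    n = len(expo)
    results: list[AssocResult] = []
    for d, dv in enumerate(dvs):
        y = cohort.data[dv].to_numpy(dtype=float)
        perms = draw_permutations(n, B, [seed, d])
        for s, spec in enumerate(specs):
            res = permutation_assoc_test(
                y, X, expo, spec, B=B, seed=int(np.random.default_rng([seed, d, s]).integers(2**31)),
                permutations=perms, dv_name=dv,
            )
            results.append(res)
    for spec in specs:
        fam_results = [r for r in results if r.family == spec.family]
        adjusted = adjust_pvalues(
            [r.p_base for r in fam_results], m=len(dvs), method=adjust_method
        )
        for r, a in zip(fam_results, adjusted):
            r.p_adjusted = float(a)
    results.sort(key=lambda r: (r.dv, r.family))
    return results


def association_report(results: list[AssocResult]) -> pd.DataFrame:
    """Summary-table-shaped frame: one row per (outcome, regressor)."""
    return pd.DataFrame(
        {
            "variable": [r.dv for r in results],
            "model": [FAMILY_ABBREV[r.family] for r in results],
            "permuted_r2_mean": [r.r2_permuted_mean for r in results],
            "baseline_r2": [r.r2_baseline for r in results],
            "full_r2_true": [r.r2_full_true for r in results],
            "delta_r2": [r.delta_r2 for r in results],
            "delta_vs_permuted": [r.delta_vs_permuted for r in results],
            "p_base": [r.p_base for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
        }
    )
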