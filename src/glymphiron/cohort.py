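"""Cohort-level statistics: Spearman correlations with Bonferroni control and
covariate-adjusted standardised regression.

The correlation stage relates each of the seven nucleus susceptibilities to
the ALPS index (and to age); with seven nucleus tests the Bonferroni
threshold at alpha = 0.05 is 0.05/7 ~= 0.007. The adjusted stage regresses
each nucleus value on the ALPS index plus covariates (age alone, or age +
WMH volume + the two atrophy scores), reporting standardised coefficients.

Spearman's rho and the standardised OLS fit are implemented from first
principles (mid-rank Pearson correlation; normal equations) and are
validated against independent oracles in the test suite.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import ValidationError
from .qsm import NUCLEUS_COLUMNS

logger = logging.getLogger(__name__)

#: Columns a cohort table must provide.
COHORT_COLUMNS = (
    "subject_id",
    "age",
    "sex",
    "alps",
    *NUCLEUS_COLUMNS.values(),
    "wmh_volume",
    "atrophy_cortical",
    "atrophy_central",
)

#: Sample size below which the Spearman p-value is computed by exhaustive
#: permutation instead of the t approximation.
EXACT_PERMUTATION_MAX_N = 8


@dataclass(frozen=True)
class CorrelationResult:
    pair: tuple[str, str]
    r: float
    p: float
    n: int
    significant_bonferroni: bool = False


@dataclass(frozen=True)
class AdjustedModelResult:
    """Standardised OLS fit of one nucleus outcome on named predictors."""

    outcome: str
    covariate_set: str
    beta: dict[str, float]
    p: dict[str, float]
    n: int


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

def _midranks(x: np.ndarray) -> np.ndarray:
    """Average ranks (1-based), ties receiving their mid-rank."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x))
    sx = x[order]
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _rank_pearson(rx: np.ndarray, ry: np.ndarray) -> float:
    dx = rx - rx.mean()
    dy = ry - ry.mean()
    return float(dx @ dy / math.sqrt((dx @ dx) * (dy @ dy)))


def spearman(x: np.ndarray, y: np.ndarray, pair: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of mid-ranks. For n > 8 the p-value uses
    the t approximation ``t = r sqrt((n-2)/(1-r^2))``; for n <= 8 it is exact,
    from the permutation distribution of rho over all n! orderings.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("spearman expects two 1-D vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValidationError(f"spearman needs n >= 3, got n = {n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("spearman inputs must be finite")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValidationError("spearman is undefined for a constant vector")
    rx, ry = _midranks(x), _midranks(y)
    r = _rank_pearson(rx, ry)

    if n <= EXACT_PERMUTATION_MAX_N:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            rp = _rank_pearson(rx, ry[list(perm)])
            total += 1
            if abs(rp) >= abs(r) - 1e-12:
                count += 1
        p = count / total
    else:
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * math.sqrt((n - 2) / (1.0 - r * r))
            p = 2.0 * float(sstats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(pair=pair, r=r, p=min(p, 1.0), n=n)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold alpha / m for m tests."""
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    if m < 1:
        raise ValidationError(f"m must be >= 1, got {m}")
    return alpha / m


# ---------------------------------------------------------------------------
# Standardised OLS
# ---------------------------------------------------------------------------

def _zscore(v: np.ndarray, name: str) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValidationError(f"column {name!r} is constant; cannot standardise")
    return (v - v.mean()) / sd


def standardized_ols(
    outcome: np.ndarray,
    predictors: dict[str, np.ndarray],
    outcome_name: str = "outcome",
    covariate_set: str = "",
) -> AdjustedModelResult:
    """Standardised-coefficient OLS via the normal equations.

    Outcome and every predictor are z-scored (so the intercept vanishes and
    coefficients are standardised betas); two-sided p-values come from the t
    distribution with ``n - k - 1`` degrees of freedom, matching a fit that
    carries an intercept. Ordinal covariates are entered as numeric.
    """
    names = list(predictors)
    y = np.asarray(outcome, dtype=float)
    n, k = len(y), len(names)
    if n <= k + 1:
        raise ValidationError(f"need n > {k + 1} rows for {k} predictors, got n = {n}")
    X = np.column_stack([_zscore(np.asarray(predictors[c], dtype=float), c) for c in names])
    if X.shape[0] != n:
        raise ValidationError("outcome and predictors have different lengths")
    yz = _zscore(y, outcome_name)

    rank = np.linalg.matrix_rank(X)
    if rank < k:
        # name the offending columns via the QR diagonal
        _, R = np.linalg.qr(X)
        bad = [names[i] for i in range(k) if abs(R[i, i]) < 1e-8 * abs(R[0, 0])]
        raise ValidationError(
            f"design matrix is rank deficient (rank {rank} < {k}); "
            f"collinear columns: {bad or names}"
        )

    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ yz)
    resid = yz - X @ beta
    dof = n - k - 1
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(np.diag(np.linalg.inv(xtx)) * sigma2)
    tvals = beta / se
    pvals = 2.0 * sstats.t.sf(np.abs(tvals), df=dof)
    return AdjustedModelResult(
        outcome=outcome_name,
        covariate_set=covariate_set,
        beta=dict(zip(names, beta.tolist())),
        p=dict(zip(names, pvals.tolist())),
        n=n,
    )


# ---------------------------------------------------------------------------
# Table-level drivers
# ---------------------------------------------------------------------------

def _complete_cases(cohort: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    missing = [c for c in columns if c not in cohort.columns]
    if missing:
        raise ValidationError(f"cohort table lacks columns {missing}")
    sub = cohort[columns]
    complete = sub.dropna()
    dropped = len(sub) - len(complete)
    if dropped:
        logger.info("excluded %d records with missing fields", dropped)
    return complete


def run_table2(cohort: pd.DataFrame, alpha: float = 0.05, family: int = 7) -> list[CorrelationResult]:
    """Nucleus-vs-ALPS Spearman correlations plus the age correlations.

    The seven nucleus-ALPS tests form the Bonferroni family (threshold
    ``alpha / family``); the age-ALPS and age-nucleus correlations are
    reported with the same per-family control for the nucleus set and an
    uncorrected flag for age-ALPS. Output order is deterministic.
    """
    thr = bonferroni_threshold(alpha, family)
    results: list[CorrelationResult] = []

    for name, col in NUCLEUS_COLUMNS.items():
        data = _complete_cases(cohort, [col, "alps"])
        if len(data) < 3:
            raise ValidationError(f"fewer than 3 complete records for {name}")
        res = spearman(data[col].to_numpy(), data["alps"].to_numpy(), pair=(name, "alps"))
        results.append(
            CorrelationResult(res.pair, res.r, res.p, res.n, significant_bonferroni=res.p < thr)
        )

    data = _complete_cases(cohort, ["age", "alps"])
    res = spearman(data["age"].to_numpy(), data["alps"].to_numpy(), pair=("age", "alps"))
    results.append(CorrelationResult(res.pair, res.r, res.p, res.n, res.p < alpha))

    for name, col in NUCLEUS_COLUMNS.items():
        data = _complete_cases(cohort, ["age", col])
        res = spearman(data["age"].to_numpy(), data[col].to_numpy(), pair=("age", name))
        results.append(CorrelationResult(res.pair, res.r, res.p, res.n, res.p < thr))

    return results


#: Predictor sets of the two adjusted models.
MODEL_A = ("alps", "age")
MODEL_B = ("alps", "age", "wmh_volume", "atrophy_cortical", "atrophy_central")


def run_table3(cohort: pd.DataFrame) -> list[AdjustedModelResult]:
    """Adjusted models per nucleus: outcome = nucleus susceptibility.

    Model A adjusts the ALPS coefficient for age; model B additionally for
    WMH volume and the two atrophy scores. Atrophy ordinals enter as numeric
    0/1/2.
    """
    results = []
    for name, col in NUCLEUS_COLUMNS.items():
        for tag, predictors in (("age-only", MODEL_A), ("age+wmh+atrophy", MODEL_B)):
            data = _complete_cases(cohort, [col, *predictors])
            res = standardized_ols(
                data[col].to_numpy(),
                {p: data[p].to_numpy() for p in predictors},
                outcome_name=name,
                covariate_set=tag,
            )
            results.append(res)
    return results


def table1_summary(cohort: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Mean/SD descriptive summary of the continuous cohort variables."""
    out: dict[str, dict[str, float]] = {}
    for col in ("age", "alps", *NUCLEUS_COLUMNS.values(), "wmh_volume"):
        v = cohort[col].dropna().to_numpy(dtype=float)
        out[col] = {"mean": float(v.mean()), "sd": float(v.std(ddof=1)), "n": int(len(v))}
    for col in ("atrophy_cortical", "atrophy_central"):
        v = cohort[col].dropna().to_numpy(dtype=float)
        out[col] = {"median": float(np.median(v)), "n": int(len(v))}
    n_female = int((cohort["sex"] == "female").sum())
    out["sex"] = {"n_female": n_female, "n": int(len(cohort))}
    return out
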