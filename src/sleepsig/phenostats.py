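"""Covariate-adjusted partial correlations among the five phenotypes.

The partial correlation of x and y given covariates C is the Pearson
correlation of the residuals of x and y after each is regressed (OLS, with
intercept) on C.  Inference uses the exact null of the Pearson coefficient:
with k covariate columns, under independence

    (1 + r) / 2  ~  Beta(n_eff / 2, n_eff / 2),   n_eff = n - k - 2,

which is equivalent to the classic t transform with n_eff degrees of freedom.
Confidence intervals are Fisher-z intervals at a configurable level; the
analysis convention is 99% intervals so that the five-phenotype family is
controlled at the 0.05 level.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .associations import check_full_rank, design_matrix
from .errors import (InsufficientSampleError, InvalidArgumentError,
                     SchemaError, UndefinedCorrelationError)
from .synthetic import PHENOTYPES

#: Covariates entering the phenotypic correlation models.  The accelerometry
#: time offset is added only for pairs involving the accelerometer-derived
#: sleep measure.
PHENO_COVARIATES_NUMERIC = ("age", "sex", "ses", "education")
PHENO_COVARIATES_CATEGORICAL = ("site", "ethnicity")
ACCEL_OFFSET = "accel_time_offset"
SLEEP = "sleep_bout_h"


@dataclass(frozen=True)
class CorrelationResult:
    """A partial correlation with its exact-null p and Fisher-z interval."""

    r: float
    n_eff: int
    p: float
    ci_low: float
    ci_high: float
    conf_level: float

    @property
    def significant(self) -> bool:
        """True when the confidence interval excludes zero."""
        return self.ci_low > 0.0 or self.ci_high < 0.0


def _residualize(v: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def _pearson(a: np.ndarray, b: np.ndarray,
             scale_a: float = 1.0, scale_b: float = 1.0) -> float:
    """Pearson r of residual vectors.

    ``scale_*`` are the pre-residualisation standard deviations: a residual
    whose variance is negligible relative to its variable's original scale is
    numerically zero (the variable lies in the covariate span).
    """
    sa, sb = a.std(), b.std()
    if sa <= 1e-10 * max(scale_a, 1e-300) or \
            sb <= 1e-10 * max(scale_b, 1e-300):
        raise UndefinedCorrelationError(
            "residuals have zero variance; correlation undefined")
    return float(np.dot(a - a.mean(), b - b.mean()) / (len(a) * sa * sb))


def beta_null_p(r: float, n_eff: int) -> float:
    """Two-sided p for a Pearson r from its exact beta-distribution null."""
    if n_eff < 2:
        raise InsufficientSampleError(
            f"need n_eff >= 2 for inference, got {n_eff}")
    a = n_eff / 2.0
    cdf = sp_stats.beta.cdf((1.0 + r) / 2.0, a, a)
    return float(min(1.0, 2.0 * min(cdf, 1.0 - cdf)))


def partial_correlation(x: np.ndarray, y: np.ndarray,
                        covariates: Optional[pd.DataFrame] = None,
                        conf_level: float = 0.99) -> CorrelationResult:
    """Partial correlation of ``x`` and ``y`` adjusting for ``covariates``.

    ``covariates`` is a numeric design table (no intercept column; one is
    added).  With no covariates this reduces to the plain Pearson correlation
    with exact beta-null inference.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidArgumentError("x and y must be equal-length vectors")
    n = len(x)
    if covariates is not None and len(covariates) != n:
        raise InvalidArgumentError("covariates must match x/y length")
    if covariates is not None and covariates.shape[1] > 0:
        X = pd.concat([pd.Series(np.ones(n), name="intercept",
                                 index=covariates.index),
                       covariates.astype(float)], axis=1)
        check_full_rank(X)
        A = X.to_numpy(float)
        k = covariates.shape[1]
    else:
        A = np.ones((n, 1))
        k = 0
    if n <= k + 3:
        raise InsufficientSampleError(
            f"need n > covariate df + 3 ({k + 3}), got {n}")
    rx = _residualize(x, A)
    ry = _residualize(y, A)
    r = _pearson(rx, ry, x.std(), y.std())
    r = float(np.clip(r, -1.0, 1.0))
    n_eff = n - k - 2
    p = beta_null_p(r, n_eff)
    # Fisher z interval; n - k - 3 = n_eff - 1 plays the role of n - 3
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    zse = 1.0 / np.sqrt(n_eff - 1)
    zcrit = sp_stats.norm.ppf(0.5 + conf_level / 2.0)
    lo, hi = np.tanh(z - zcrit * zse), np.tanh(z + zcrit * zse)
    if r == 1.0:
        hi = 1.0
    if r == -1.0:
        lo = -1.0
    return CorrelationResult(r, n_eff, p, float(lo), float(hi), conf_level)


def _pair_covariates(table: pd.DataFrame, a: str, b: str,
                     education_as_categorical: bool = False) -> pd.DataFrame:
    numeric = list(PHENO_COVARIATES_NUMERIC)
    categorical = list(PHENO_COVARIATES_CATEGORICAL)
    if education_as_categorical:
        numeric.remove("education")
        categorical.append("education")
    if SLEEP in (a, b):
        numeric.append(ACCEL_OFFSET)
    X = design_matrix(table, numeric=numeric, categorical=categorical,
                      add_intercept=False)
    return X


def pairwise_partial_correlations(
        table: pd.DataFrame,
        phenotypes: Sequence[str] = PHENOTYPES,
        conf_level: float = 0.99,
        education_as_categorical: bool = False) -> pd.DataFrame:
    """All pairwise partial correlations among the phenotypes.

    Each pair is analysed on its complete cases.  Returns a long-format frame
    (phenotype_a, phenotype_b, r, n_eff, p, ci_low, ci_high, significant);
    use :func:`correlation_matrix` for the symmetric 5x5 matrix view.
    """
    missing = [p for p in phenotypes if p not in table.columns]
    if missing:
        raise SchemaError(f"phenotype columns missing from table: {missing}")
    rows = []
    for a, b in combinations(phenotypes, 2):
        cols = ([a, b] + list(PHENO_COVARIATES_NUMERIC)
                + list(PHENO_COVARIATES_CATEGORICAL))
        if SLEEP in (a, b):
            cols.append(ACCEL_OFFSET)
        sub = table[cols].dropna()
        cov = _pair_covariates(sub, a, b, education_as_categorical)
        res = partial_correlation(sub[a].to_numpy(float),
                                  sub[b].to_numpy(float),
                                  cov, conf_level=conf_level)
        rows.append({"phenotype_a": a, "phenotype_b": b, "r": res.r,
                     "n_eff": res.n_eff, "p": res.p,
                     "ci_low": res.ci_low, "ci_high": res.ci_high,
                     "significant": res.significant})
    return pd.DataFrame(rows)


def correlation_matrix(pairs: pd.DataFrame,
                       phenotypes: Sequence[str] = PHENOTYPES,
                       value: str = "r") -> pd.DataFrame:
    """Pivot the long-format pairwise table into a symmetric matrix.

    The diagonal is left as NaN (a phenotype's partial correlation with
    itself is not a meaningful quantity here).
    """
    m = pd.DataFrame(np.nan, index=list(phenotypes), columns=list(phenotypes))
    for _, row in pairs.iterrows():
        m.loc[row["phenotype_a"], row["phenotype_b"]] = row[value]
        m.loc[row["phenotype_b"], row["phenotype_a"]] = row[value]
    return m


def partial_correlation_via_precision(df: pd.DataFrame, a: str, b: str,
                                      others: Sequence[str]) -> float:
    """Partial correlation from the inverse correlation matrix of the joined
    variable set -- an independent formula used for cross-checking."""
    cols = [a, b] + list(others)
    C = np.corrcoef(df[cols].to_numpy(float), rowvar=False)
    P = np.linalg.inv(C)
    return float(-P[0, 1] / np.sqrt(P[0, 0] * P[1, 1]))
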