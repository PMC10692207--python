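"""Second-level OLS association engine.

One model per brain unit (region or connectivity edge): the unit's outcome is
regressed on a standardised phenotype plus modality-specific covariates.  The
vector of phenotype coefficients across units is the phenotype's *neural
signature*; for task decoding maps the coefficient is additionally divided by
the classification error (1 - accuracy, floored) to up-weight regions whose
voxels respond strongly to the stimuli.

The engine exposes a single-outcome :func:`fit_ols` with full statistics and
a vectorised :func:`map_association` fast path that solves all units sharing
one design matrix in a single orthogonal decomposition (numerically identical
to looping :func:`fit_ols`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

from .errors import InvalidArgumentError, SingularDesignError

#: Significance convention: corrected p compared to alpha / (number of
#: phenotypes), matching a five-phenotype analysis.
ALPHA = 0.05
N_PHENOTYPES = 5

# Modality-specific covariate sets.  The task models additionally adjust for
# task performance statistics; anatomical (thickness) models drop head motion
# and task performance; the accelerometry time offset enters only for models
# of the accelerometer-derived sleep phenotype.
_COMMON = ("sex", "age", "ses", "education")
MODALITY_COVARIATES: Dict[str, Tuple[str, ...]] = {
    "task": _COMMON + ("head_motion",
                       "task_acc_mean", "task_rt_mean", "task_rt_sd"),
    "rest": _COMMON + ("head_motion",),
    "anat": _COMMON,
}
CATEGORICAL_COVARIATES = ("site", "ethnicity")
SLEEP_PHENOTYPE = "sleep_bout_h"


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def design_matrix(table: pd.DataFrame,
                  numeric: Sequence[str] = (),
                  categorical: Sequence[str] = (),
                  interactions: Sequence[Tuple[str, str]] = (),
                  add_intercept: bool = True) -> pd.DataFrame:
    """Build a named design matrix.

    Categorical columns are one-hot expanded dropping the first (reference)
    level; interactions are products of two numeric columns.  The returned
    frame is checked for full column rank and a :class:`SingularDesignError`
    naming the first numerically collinear column is raised otherwise.
    """
    cols: Dict[str, np.ndarray] = {}
    if add_intercept:
        cols["intercept"] = np.ones(len(table))
    for c in numeric:
        cols[c] = table[c].to_numpy(float)
    for c in categorical:
        levels = np.sort(pd.unique(table[c]))
        for lv in levels[1:]:
            cols[f"{c}_{lv}"] = (table[c].to_numpy() == lv).astype(float)
    for a, b in interactions:
        cols[f"{a}:{b}"] = (table[a].to_numpy(float)
                            * table[b].to_numpy(float))
    X = pd.DataFrame(cols, index=table.index)
    check_full_rank(X)
    return X


def check_full_rank(X: pd.DataFrame, rtol: float = 1e-8) -> None:
    """Raise :class:`SingularDesignError` naming the first collinear column."""
    A = X.to_numpy(float)
    # incremental rank: the first column that does not increase the rank of
    # the preceding block is the collinear one
    _, r = np.linalg.qr(A)
    diag = np.abs(np.diag(r))
    scale = np.max(np.abs(A), axis=0)
    scale[scale == 0] = 1.0
    bad = np.where(diag <= rtol * max(diag.max(), 1.0))[0]
    if bad.size:
        raise SingularDesignError(
            f"design is rank deficient: column {X.columns[bad[0]]!r} is "
            "collinear with the preceding columns")


def modality_design(table: pd.DataFrame, modality: str,
                    phenotype: str) -> pd.DataFrame:
    """Covariate design for one imaging modality and phenotype.

    All imaging models include a sex-by-age interaction; the accelerometry
    time offset is added only when modelling the accelerometer sleep measure.
    """
    if modality not in MODALITY_COVARIATES:
        raise InvalidArgumentError(
            f"unknown modality {modality!r}; expected one of "
            f"{sorted(MODALITY_COVARIATES)}")
    numeric = list(MODALITY_COVARIATES[modality])
    if phenotype == SLEEP_PHENOTYPE:
        numeric.append("accel_time_offset")
    return design_matrix(table, numeric=numeric,
                         categorical=CATEGORICAL_COVARIATES,
                         interactions=[("sex", "age")])


# ---------------------------------------------------------------------------
# OLS
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OlsFit:
    """Least-squares fit: coefficient vector with classic OLS inference."""

    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    residuals: np.ndarray
    df_resid: int
    columns: Tuple[str, ...]


def fit_ols(y: np.ndarray, X: Union[pd.DataFrame, np.ndarray]) -> OlsFit:
    """Ordinary least squares via QR, with two-sided t-distribution p-values.

    ``X`` must include its intercept column and have more rows than columns.
    """
    if isinstance(X, pd.DataFrame):
        columns = tuple(map(str, X.columns))
        check_full_rank(X)
        A = X.to_numpy(float)
    else:
        A = np.asarray(X, float)
        columns = tuple(f"x{i}" for i in range(A.shape[1]))
        check_full_rank(pd.DataFrame(A, columns=columns))
    y = np.asarray(y, float)
    n, k = A.shape
    if n <= k:
        raise InvalidArgumentError(
            f"need more observations ({n}) than design columns ({k})")
    q, r = np.linalg.qr(A)
    beta = np.linalg.solve(r, q.T @ y)
    resid = y - A @ beta
    df = n - k
    sigma2 = float(resid @ resid) / df
    rinv = np.linalg.inv(r)
    xtx_inv_diag = np.sum(rinv * rinv, axis=1)
    se = np.sqrt(sigma2 * xtx_inv_diag)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * sp_stats.t.sf(np.abs(t), df)
    return OlsFit(beta, se, t, p, resid, df, columns)


def _multi_ols_phenotype_stats(Y: np.ndarray, X: np.ndarray,
                               coef_index: int):
    """Solve OLS for many outcomes sharing one design; return the statistics
    of a single coefficient (vectorised equivalent of looping fit_ols)."""
    n, k = X.shape
    q, r = np.linalg.qr(X)
    beta = np.linalg.solve(r, q.T @ Y)           # (k, U)
    resid = Y - X @ beta
    df = n - k
    sigma2 = np.sum(resid ** 2, axis=0) / df
    rinv = np.linalg.inv(r)
    xtx_inv_diag = np.sum(rinv * rinv, axis=1)
    se = np.sqrt(sigma2 * xtx_inv_diag[coef_index])
    b = beta[coef_index]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, b / se, np.inf * np.sign(b))
    p = 2.0 * sp_stats.t.sf(np.abs(t), df)
    return b, se, t, p, df


# ---------------------------------------------------------------------------
# Multiplicity adjustment
# ---------------------------------------------------------------------------

def adjust_fdr_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, float)
    if p.size and (np.min(p) < 0 or np.max(p) > 1):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def adjust_bonferroni(p: np.ndarray, m: int) -> np.ndarray:
    """Bonferroni adjustment with an explicit test-universe size ``m``."""
    if m < 1:
        raise InvalidArgumentError(f"m must be >= 1, got {m}")
    p = np.asarray(p, float)
    if p.size and (np.min(p) < 0 or np.max(p) > 1):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * m)


# ---------------------------------------------------------------------------
# Association maps
# ---------------------------------------------------------------------------

def map_association(outcome_by_unit: pd.DataFrame,
                    table: pd.DataFrame,
                    phenotype: str,
                    modality: str = "task",
                    accuracy_by_unit: Optional[np.ndarray] = None,
                    error_floor: Optional[float] = None,
                    n_samples: int = 60,
                    adjust: str = "fdr_bh",
                    bonferroni_m: Optional[int] = None) -> pd.DataFrame:
    """Fit one OLS model per unit and return the association map.

    Parameters
    ----------
    outcome_by_unit
        (n_subjects, n_units) frame; column names are the unit ids.
    table
        Cohort phenotype/covariate table aligned with the outcome rows.
    phenotype
        Which phenotype's signature to compute; it is z-scored before fitting
        so betas are comparable across phenotypes.
    accuracy_by_unit
        Optional per-(subject, unit) decoding accuracies; when provided,
        ``beta_normalized = beta / max(1 - mean accuracy of the unit, floor)``
        is added.  The floor defaults to ``1 / (2 * n_samples)`` so a unit
        decoded perfectly still yields a finite normalised coefficient.
    adjust
        ``"fdr_bh"`` (within-map Benjamini-Hochberg) or ``"bonferroni"``
        (requires ``bonferroni_m``).

    Returns a frame with columns unit, phenotype, beta, se, t, p, p_adjusted
    (and beta_normalized when accuracies are supplied).
    """
    pz = table[phenotype].to_numpy(float)
    sd = pz.std()
    if sd == 0:
        raise InvalidArgumentError(f"phenotype {phenotype} has zero variance")
    pz = (pz - pz.mean()) / sd
    cov = modality_design(table, modality, phenotype)
    X = np.column_stack([cov.to_numpy(float)[:, :1], pz,
                         cov.to_numpy(float)[:, 1:]])
    names = ["intercept", phenotype] + list(cov.columns[1:])
    check_full_rank(pd.DataFrame(X, columns=names))
    Y = outcome_by_unit.to_numpy(float)
    b, se, t, p, _ = _multi_ols_phenotype_stats(Y, X, coef_index=1)
    if adjust == "fdr_bh":
        p_adj = adjust_fdr_bh(p)
    elif adjust == "bonferroni":
        if bonferroni_m is None:
            raise InvalidArgumentError(
                "bonferroni adjustment needs bonferroni_m")
        p_adj = adjust_bonferroni(p, bonferroni_m)
    else:
        raise InvalidArgumentError(f"unknown adjustment {adjust!r}")
    out = pd.DataFrame({
        "unit": list(outcome_by_unit.columns),
        "phenotype": phenotype,
        "beta": b, "se": se, "t": t, "p": p, "p_adjusted": p_adj})
    if accuracy_by_unit is not None:
        acc = np.asarray(accuracy_by_unit, float)
        if acc.ndim == 2:
            acc = acc.mean(axis=0)
        floor = (1.0 / (2.0 * n_samples)) if error_floor is None \
            else float(error_floor)
        out["beta_normalized"] = b / np.maximum(1.0 - acc, floor)
    return out


def significant(map_df: pd.DataFrame,
                alpha: float = ALPHA,
                n_phenotypes: int = N_PHENOTYPES) -> pd.Series:
    """Significance flag: adjusted p below alpha divided by phenotype count."""
    return map_df["p_adjusted"] < alpha / n_phenotypes
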