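"""Brain-wide / network-wise mean connectivity and connectome-based
predictive modeling (CPM).

Global mean connectivity is the average over the R(R-1)/2 unique region
pairs; network block means aggregate the same pairs within and between the
seven canonical networks (the pair-count-weighted blocks recompose the global
mean exactly).  The same summaries apply to task-condition representational
connectivity matrices, which is what lets the task-hypo / rest-hyper contrast
be read off a single scalar per subject per condition.

CPM residualises every edge on the covariates, selects edges whose training-
fold correlation with the phenotype has p < 0.01 (strict), averages the
selected edges into one summary feature, fits a simple regression on the
training fold and evaluates the Pearson correlation between pooled
out-of-fold predictions and the true phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .errors import (AtlasIncompleteError, InvalidArgumentError,
                     InvalidMatrixError)
from .restconn import edge_index_pairs
from .synthetic import Atlas, YEO7_NETWORKS


def global_mean_connectivity(matrix: np.ndarray,
                             atol: float = 1e-8) -> float:
    """Mean over the unique off-diagonal pairs of a symmetric matrix."""
    m = np.asarray(matrix, float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise InvalidMatrixError("matrix must be square")
    if np.max(np.abs(m - m.T)) > atol:
        raise InvalidMatrixError(
            "matrix is asymmetric beyond tolerance")
    i, j = edge_index_pairs(m.shape[0])
    return float(m[i, j].mean())


def network_block_means(matrix: np.ndarray, atlas: Atlas) -> pd.DataFrame:
    """7x7 within/between-network mean connectivity.

    Block (a, b) is the mean over unique pairs with one region in network a
    and the other in network b; within-network blocks use the unique pairs
    inside the network.  Returned as a symmetric labelled DataFrame.
    """
    m = np.asarray(matrix, float)
    if m.shape != (atlas.n_regions, atlas.n_regions):
        raise InvalidArgumentError("matrix size must match the atlas")
    nets = np.asarray(atlas.network)
    if not np.all(np.isin(nets, YEO7_NETWORKS)):
        raise AtlasIncompleteError("atlas has regions with unknown networks")
    present = [n for n in YEO7_NETWORKS if np.any(nets == n)]
    i, j = edge_index_pairs(atlas.n_regions)
    vals = m[i, j]
    ni, nj = nets[i], nets[j]
    out = pd.DataFrame(np.nan, index=present, columns=present)
    for a_idx, a in enumerate(present):
        for b in present[a_idx:]:
            mask = ((ni == a) & (nj == b)) | ((ni == b) & (nj == a))
            if mask.any():
                v = float(vals[mask].mean())
                out.loc[a, b] = v
                out.loc[b, a] = v
    return out


def network_block_pair_counts(atlas: Atlas) -> pd.DataFrame:
    """Number of unique region pairs per network block (for recomposition)."""
    nets = np.asarray(atlas.network)
    present = [n for n in YEO7_NETWORKS if np.any(nets == n)]
    i, j = edge_index_pairs(atlas.n_regions)
    ni, nj = nets[i], nets[j]
    out = pd.DataFrame(0, index=present, columns=present)
    for a_idx, a in enumerate(present):
        for b in present[a_idx:]:
            c = int((((ni == a) & (nj == b)) | ((ni == b) & (nj == a))).sum())
            out.loc[a, b] = c
            out.loc[b, a] = c
    return out


def task_global_connectivity(repconn_matrices: np.ndarray) -> np.ndarray:
    """Per-subject global mean of representational connectivity matrices.

    ``repconn_matrices`` is (n_subjects, R, R); returns (n_subjects,) means
    over unique pairs -- the task-condition counterpart of the resting
    global mean, fed to the same association models.
    """
    m = np.asarray(repconn_matrices, float)
    if m.ndim != 3 or m.shape[1] != m.shape[2]:
        raise InvalidArgumentError("expected (n_subjects, R, R)")
    i, j = edge_index_pairs(m.shape[1])
    return m[:, i, j].mean(axis=1)


def global_mean_association_table(values: np.ndarray, table: pd.DataFrame,
                                  condition: str,
                                  alpha: float = 0.05,
                                  n_phenotypes: int = 5) -> pd.DataFrame:
    """Association of a per-subject global connectivity mean with each
    phenotype.

    One OLS model per phenotype (standardised) with the resting covariate
    set; confidence intervals at the Bonferroni-corrected level
    ``1 - alpha / n_phenotypes`` (99% under the default five-phenotype
    convention), so a CI excluding zero is family-wise significant.
    """
    from .associations import fit_ols, modality_design
    from .synthetic import PHENOTYPES

    rows = []
    level = 1.0 - alpha / n_phenotypes
    for phen in PHENOTYPES:
        z = table[phen].to_numpy(float)
        z = (z - z.mean()) / z.std()
        cov = modality_design(table, "rest", phen)
        X = pd.concat([cov.iloc[:, :1],
                       pd.Series(z, name=phen, index=cov.index),
                       cov.iloc[:, 1:]], axis=1)
        fit = fit_ols(np.asarray(values, float), X)
        b, se = fit.beta[1], fit.se[1]
        tcrit = sp_stats.t.ppf(0.5 + level / 2.0, fit.df_resid)
        lo, hi = b - tcrit * se, b + tcrit * se
        rows.append({"condition": condition, "phenotype": phen,
                     "beta": b, "se": se, "t": fit.t[1], "p": fit.p[1],
                     "ci_low": lo, "ci_high": hi,
                     "significant": bool(lo > 0 or hi < 0)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Connectome-based predictive modeling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CpmResult:
    """Cross-validated CPM performance and bookkeeping."""

    performance_r: float
    predictions: np.ndarray        # pooled out-of-fold predictions
    y_true: np.ndarray             # aligned true phenotype values
    fold_assignment: np.ndarray    # fold index per subject
    n_selected: Tuple[int, ...]    # edges selected per training fold
    empty_folds: Tuple[int, ...]   # folds where no edge passed selection
    selection_p: float
    n_folds: int


def _residualize_columns(M: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, M, rcond=None)
    return M - X @ beta


def cpm_fit_predict(edge_vectors: np.ndarray, phenotype: np.ndarray,
                    covariates: Optional[pd.DataFrame] = None,
                    sel_p: float = 0.01, n_folds: int = 10, seed: int = 0,
                    residualize: str = "full") -> CpmResult:
    """Connectome-based predictive modeling with K-fold cross-validation.

    ``residualize="full"`` regresses the covariates out of every edge on the
    full sample before cross-validation (the protocol as stated, which leaks
    covariate fits across folds); ``"within"`` refits the residualisation on
    each training fold only.  Edge selection (training-fold Pearson p <
    ``sel_p``, strict) and the feature regression always happen within the
    training fold.  A fold in which no edge is selected predicts the training
    mean and is reported in ``empty_folds``.
    """
    E = np.asarray(edge_vectors, float)
    y = np.asarray(phenotype, float)
    if E.ndim != 2 or len(E) != len(y):
        raise InvalidArgumentError(
            "edge_vectors must be (n_subjects, E) aligned with phenotype")
    n = len(y)
    if residualize not in ("full", "within"):
        raise InvalidArgumentError(
            f"residualize must be 'full' or 'within', got {residualize!r}")
    X = None
    if covariates is not None and covariates.shape[1] > 0:
        X = np.column_stack([np.ones(n), covariates.to_numpy(float)])
        if n < 10 * (covariates.shape[1] + 2):
            raise InvalidArgumentError(
                "too few subjects for the covariate count in CPM")
        if residualize == "full":
            E = _residualize_columns(E, X)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC9A]))
    fold = rng.permutation(n) % n_folds
    preds = np.empty(n)
    n_sel: List[int] = []
    empty: List[int] = []
    df = None
    for k in range(n_folds):
        tr = fold != k
        te = fold == k
        Etr, Ete = E[tr], E[te]
        if X is not None and residualize == "within":
            beta, *_ = np.linalg.lstsq(X[tr], Etr, rcond=None)
            Etr = Etr - X[tr] @ beta
            Ete = Ete - X[te] @ beta
        ytr = y[tr]
        ntr = tr.sum()
        yc = ytr - ytr.mean()
        Ec = Etr - Etr.mean(axis=0)
        denom = np.linalg.norm(Ec, axis=0) * np.linalg.norm(yc)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, Ec.T @ yc / denom, 0.0)
        r = np.clip(r, -0.999999999, 0.999999999)
        t = r * np.sqrt((ntr - 2) / (1.0 - r ** 2))
        p = 2.0 * sp_stats.t.sf(np.abs(t), ntr - 2)
        sel = p < sel_p
        n_sel.append(int(sel.sum()))
        if not sel.any():
            empty.append(k)
            preds[te] = ytr.mean()
            continue
        f_tr = Etr[:, sel].mean(axis=1)
        f_te = Ete[:, sel].mean(axis=1)
        var = f_tr.var()
        if var == 0:
            empty.append(k)
            preds[te] = ytr.mean()
            continue
        slope = np.cov(f_tr, ytr, bias=True)[0, 1] / var
        intercept = ytr.mean() - slope * f_tr.mean()
        preds[te] = intercept + slope * f_te
    if np.std(preds) == 0 or np.std(y) == 0:
        perf = 0.0
    else:
        perf = float(np.corrcoef(preds, y)[0, 1])
    return CpmResult(perf, preds, y.copy(), fold, tuple(n_sel),
                     tuple(empty), sel_p, n_folds)
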