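"""Resting-state connectivity construction and edge-wise association models.

Region-level connectivity is the Pearson correlation matrix of region time
series (a region-level stand-in for voxel-wise dual regression: downstream
analyses only consume region-by-region values).  Seed-based matrices whose
diagonal holds autocorrelation values are row-normalised by that diagonal and
re-symmetrised.  Edge-wise association models delegate to the association
engine with the resting covariate set and Bonferroni adjustment.

Edge vectorisation convention (used everywhere in the package): row-major
lower triangle, i > j, i ascending and j ascending within i.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .associations import map_association
from .errors import (DegenerateSeriesError, InvalidArgumentError,
                     InvalidDiagonalError, InvalidMatrixError)


# ---------------------------------------------------------------------------
# Lower-triangle vectorisation
# ---------------------------------------------------------------------------

def edge_index_pairs(n_nodes: int) -> Tuple[np.ndarray, np.ndarray]:
    """(i, j) node indices of the edge vector, in the declared order."""
    return np.tril_indices(n_nodes, -1)


def matrix_to_edges(matrix: np.ndarray) -> np.ndarray:
    """Vectorise a symmetric matrix's lower triangle (declared order)."""
    m = np.asarray(matrix, float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise InvalidArgumentError("matrix must be square")
    i, j = edge_index_pairs(m.shape[0])
    return m[i, j]


def edges_to_matrix(edges: np.ndarray, n_nodes: int,
                    diagonal: float = 1.0) -> np.ndarray:
    """Rebuild the symmetric matrix from an edge vector."""
    edges = np.asarray(edges, float)
    expected = n_nodes * (n_nodes - 1) // 2
    if edges.shape != (expected,):
        raise InvalidArgumentError(
            f"edge vector must have length {expected}, got {edges.shape}")
    m = np.full((n_nodes, n_nodes), 0.0)
    i, j = edge_index_pairs(n_nodes)
    m[i, j] = edges
    m[j, i] = edges
    np.fill_diagonal(m, diagonal)
    return m


# ---------------------------------------------------------------------------
# Connectivity matrices
# ---------------------------------------------------------------------------

def region_correlation_matrix(region_series: np.ndarray) -> np.ndarray:
    """Full-correlation connectivity from an (R, T) region time-series array."""
    x = np.asarray(region_series, float)
    if x.ndim != 2 or x.shape[1] < 3:
        raise InvalidArgumentError("region_series must be (R, T) with T >= 3")
    sd = x.std(axis=1)
    bad = np.where(sd == 0)[0]
    if bad.size:
        raise DegenerateSeriesError(
            f"region {bad[0]} has zero-variance time series")
    m = np.corrcoef(x)
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 1.0)
    return m


def normalize_rows_by_diagonal(matrix: np.ndarray) -> np.ndarray:
    """Divide each row by the matrix's diagonal entry, then re-symmetrise.

    Seed-based maps carry autocorrelation values on the diagonal; dividing
    row i by entry (i, i) rescales each seed's profile to unit self-
    connectivity.  The result is symmetrised by averaging with its transpose
    (downstream averaging assumes symmetry).  A symmetric unit-diagonal input
    passes through unchanged.
    """
    m = np.asarray(matrix, float)
    d = np.diag(m)
    bad = np.where(d <= 0)[0]
    if bad.size:
        raise InvalidDiagonalError(
            f"diagonal entry {bad[0]} is non-positive ({d[bad[0]]:.3g})")
    out = m / d[:, None]
    out = (out + out.T) / 2.0
    return out


# ---------------------------------------------------------------------------
# Edge-wise association models
# ---------------------------------------------------------------------------

def edge_columns(n_nodes: int, prefix: str = "edge") -> list:
    i, j = edge_index_pairs(n_nodes)
    # 1-based node ids in names, matching on-disk conventions
    return [f"{prefix}_{a + 1}_{b + 1}" for a, b in zip(i, j)]


def edge_associations(edge_vectors: np.ndarray, table: pd.DataFrame,
                      phenotype: str, m_tests: Optional[int] = None,
                      n_nodes: Optional[int] = None) -> pd.DataFrame:
    """One OLS model per connectivity edge, Bonferroni-adjusted.

    ``edge_vectors`` is (n_subjects, E) in the declared lower-triangle order
    and must be consistent across subjects.  ``m_tests`` defaults to the
    number of phenotypes times the number of edges (the full multiplicity
    universe of the edge analysis); pass an explicit value to reproduce other
    conventions.
    """
    edge_vectors = np.asarray(edge_vectors, float)
    if edge_vectors.ndim != 2:
        raise InvalidArgumentError("edge_vectors must be (n_subjects, E)")
    n_subj, E = edge_vectors.shape
    if n_nodes is not None and E != n_nodes * (n_nodes - 1) // 2:
        raise InvalidArgumentError(
            f"edge count {E} does not match n_nodes={n_nodes}")
    if m_tests is None:
        m_tests = 5 * E
    cols = (edge_columns(n_nodes) if n_nodes is not None
            else [f"edge_{k}" for k in range(E)])
    outcome = pd.DataFrame(edge_vectors, columns=cols, index=table.index)
    return map_association(outcome, table, phenotype, modality="rest",
                           adjust="bonferroni", bonferroni_m=int(m_tests))


def fisher_z(edges: np.ndarray) -> np.ndarray:
    """Fisher z-transform of correlation-scale edges (analysis-scale switch)."""
    e = np.asarray(edges, float)
    if np.any(np.abs(e) >= 1):
        raise InvalidArgumentError("Fisher z requires |r| < 1")
    return np.arctanh(e)
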