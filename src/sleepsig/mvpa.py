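"""Region-wise face/shape decoding, univariate contrast, and RDMs.

The per-region pipeline mirrors a standard block-design MVPA protocol:

1. stimulus labels are shifted later by 5 volumes (3.675 s at TR = 0.735 s)
   to compensate for the hemodynamic delay;
2. each voxel's slow signal drift is removed by linear detrending (the run
   mean is preserved);
3. voxels are converted to percent signal change about their run mean;
4. volumes belonging to the same within-block subsample group are averaged
   (60 samples, 30 per class, under the default design);
5. rest volumes are dropped and the sample order is shuffled.

Decoding is 6-fold cross-validated binary classification with a linear
soft-margin SVM; mean accuracy across folds serves as the region's proxy for
stimulus-evoked signal strength.  The 7-category representational
dissimilarity matrix (RDM) and the second-order correlation between regions'
RDM lower triangles ("representational connectivity") are computed from the
same preprocessed samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _svm
from .errors import (DegenerateVoxelError, DesignOverflowError,
                     IncompleteDesignError, InvalidArgumentError,
                     InvalidLabelsError, UndefinedCorrelationError)
from .synthetic import (Atlas, CATEGORIES, CATEGORY_CLASS, CouplingSpec,
                        TaskDesign, TaskRegionData, default_task_design,
                        generate_task_data)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PreprocessedRun:
    """Classifier-ready samples for one subject-region run."""

    samples: np.ndarray           # (n_samples, V) percent signal change
    class_labels: np.ndarray      # (n_samples,) "face" / "shape"
    category_labels: np.ndarray   # (n_samples,) one of the 7 categories


def preprocess_run(data: TaskRegionData,
                   shift_volumes: Optional[int] = None,
                   seed: int = 0,
                   detrend_order: int = 1) -> PreprocessedRun:
    """Run the MVPA preprocessing pipeline on one voxel-by-time array.

    ``shift_volumes`` defaults to the design's hemodynamic delay (5 volumes).
    ``detrend_order`` is the polynomial order of the slow-drift fit (1 =
    linear); the fit is subtracted with the run mean added back, so percent
    signal change uses the original run mean.
    """
    design = data.design
    shift = design.hemodynamic_delay_volumes if shift_volumes is None \
        else int(shift_volumes)
    V, T = data.voxels_by_time.shape
    for onset, length, _ in design.blocks:
        if onset + shift + length > T:
            raise DesignOverflowError(
                f"shift of {shift} volumes pushes the block at {onset} "
                f"(length {length}) past the run end (T={T})")
    x = data.voxels_by_time.astype(float)
    run_mean = x.mean(axis=1)
    bad = np.where(np.abs(run_mean) < 1e-12)[0]
    if bad.size:
        raise DegenerateVoxelError(
            f"voxel {bad[0]} has zero run mean; percent signal change "
            "undefined")
    # polynomial detrend preserving the run mean
    t = np.arange(T, dtype=float)
    basis = np.vander(t, detrend_order + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(basis, x.T, rcond=None)
    fitted = (basis @ coef).T
    x = x - fitted + run_mean[:, None]
    psc = 100.0 * (x - run_mean[:, None]) / run_mean[:, None]
    samples, cats = [], []
    for onset, length, cat in design.blocks:
        lo = onset + shift
        for s in range(design.samples_per_block):
            a = lo + s * design.vols_per_sample
            b = a + design.vols_per_sample
            samples.append(psc[:, a:b].mean(axis=1))
            cats.append(cat)
    samples = np.asarray(samples)
    cats = np.asarray(cats)
    order = np.random.default_rng(
        np.random.SeedSequence([int(seed), 0x5AFF])).permutation(len(cats))
    samples, cats = samples[order], cats[order]
    classes = np.asarray([CATEGORY_CLASS[c] for c in cats])
    return PreprocessedRun(samples, classes, cats)


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DecodingResult:
    """Cross-validated decoding accuracy for one subject-region."""

    accuracy: float
    n_samples: int
    fold_accuracies: Tuple[float, ...]
    subject_id: Optional[int] = None
    region_id: Optional[int] = None


def _canonical_order(samples: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Deterministic sample ordering independent of input permutation."""
    keys = tuple(samples[:, v] for v in range(samples.shape[1] - 1, -1, -1))
    return np.lexsort(keys + (y,))


def _stratified_folds(y: np.ndarray, n_folds: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Assign each sample to a fold, class-balanced, by seeded dealing."""
    fold = np.empty(len(y), int)
    for cls in np.unique(y):
        idx = np.where(y == cls)[0]
        if len(idx) < n_folds:
            raise InvalidLabelsError(
                f"class {cls} has {len(idx)} samples, fewer than "
                f"{n_folds} folds")
        perm = rng.permutation(idx)
        fold[perm] = np.arange(len(perm)) % n_folds
    return fold


def decode_region(samples: np.ndarray, labels: np.ndarray,
                  n_folds: int = 6, seed: int = 0, C: float = 1.0,
                  backend: str = "dcd",
                  subject_id: Optional[int] = None,
                  region_id: Optional[int] = None) -> DecodingResult:
    """6-fold cross-validated linear-SVM decoding of face vs shape.

    Samples are first put into a canonical order (so the result does not
    depend on the order they arrive in), then dealt into seeded stratified
    folds; a linear soft-margin SVM is trained per fold and the mean test
    accuracy across folds is returned.
    """
    samples = np.asarray(samples, float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise InvalidLabelsError(
            f"decoding needs both classes; got only {classes!r}")
    if len(classes) > 2:
        raise InvalidLabelsError(
            f"binary decoding got {len(classes)} classes")
    y = np.where(labels == classes[0], -1.0, 1.0)
    order = _canonical_order(samples, y)
    samples, y = samples[order], y[order]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xF01D]))
    fold = _stratified_folds(y, n_folds, rng)
    accs = []
    for k in range(n_folds):
        tr, te = fold != k, fold == k
        accs.append(_svm.fold_accuracy(samples[tr], y[tr],
                                       samples[te], y[te], C=C,
                                       backend=backend))
    return DecodingResult(float(np.mean(accs)), len(y), tuple(accs),
                          subject_id, region_id)


def univariate_contrast(samples: np.ndarray, labels: np.ndarray) -> float:
    """Faces-minus-shapes contrast of the voxel-mean signal."""
    labels = np.asarray(labels)
    vm = np.asarray(samples, float).mean(axis=1)
    face = vm[labels == "face"]
    shape = vm[labels == "shape"]
    if face.size == 0 or shape.size == 0:
        raise InvalidLabelsError("both classes must be present")
    return float(face.mean() - shape.mean())


# ---------------------------------------------------------------------------
# RDMs and representational connectivity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RDM:
    """7x7 representational dissimilarity matrix for one subject-region."""

    matrix: np.ndarray
    categories: Tuple[str, ...] = CATEGORIES
    subject_id: Optional[int] = None
    region_id: Optional[int] = None

    @property
    def lower_triangle(self) -> np.ndarray:
        i, j = np.tril_indices(len(self.categories), -1)
        return self.matrix[i, j]


def compute_rdm(samples: np.ndarray, category_labels: np.ndarray,
                metric: str = "correlation",
                categories: Sequence[str] = CATEGORIES,
                subject_id: Optional[int] = None,
                region_id: Optional[int] = None) -> RDM:
    """Representational dissimilarity matrix over the stimulus categories.

    Voxel patterns are averaged per category; the dissimilarity between two
    category vectors is ``1 - Pearson r`` (default) or Euclidean distance.
    """
    category_labels = np.asarray(category_labels)
    missing = [c for c in categories if not np.any(category_labels == c)]
    if missing:
        raise IncompleteDesignError(
            f"categories absent from run: {missing}")
    means = np.stack([np.asarray(samples, float)[category_labels == c]
                      .mean(axis=0) for c in categories])
    k = len(categories)
    if metric == "correlation":
        sd = means.std(axis=1)
        if np.any(sd == 0):
            raise UndefinedCorrelationError(
                "a category mean pattern has zero variance")
        d = 1.0 - np.corrcoef(means)
    elif metric == "euclidean":
        diff = means[:, None, :] - means[None, :, :]
        d = np.sqrt(np.sum(diff ** 2, axis=2))
    else:
        raise InvalidArgumentError(f"unknown RDM metric {metric!r}")
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return RDM(d, tuple(categories), subject_id, region_id)


def representational_connectivity(rdm_a: RDM, rdm_b: RDM) -> float:
    """Pearson correlation between the lower triangles of two RDMs."""
    if rdm_a.categories != rdm_b.categories:
        raise InvalidArgumentError("RDMs must share the category ordering")
    a, b = rdm_a.lower_triangle, rdm_b.lower_triangle
    if a.std() == 0 or b.std() == 0:
        raise UndefinedCorrelationError(
            "RDM lower triangle has zero variance")
    return float(np.corrcoef(a, b)[0, 1])


def representational_connectivity_matrix(
        triangles: np.ndarray) -> np.ndarray:
    """All-pairs representational connectivity from stacked RDM triangles.

    ``triangles`` is (R, 21).  Returns the symmetric R x R correlation matrix
    with a unit diagonal.
    """
    triangles = np.asarray(triangles, float)
    if np.any(triangles.std(axis=1) == 0):
        raise UndefinedCorrelationError(
            "an RDM lower triangle has zero variance")
    m = np.corrcoef(triangles)
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 1.0)
    return m


# ---------------------------------------------------------------------------
# Cohort-scale driver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaskCohortResult:
    """Decoding accuracies (and optional RDM triangles) for a whole cohort."""

    accuracy: pd.DataFrame        # (n_subjects, R), columns = region names
    contrast: pd.DataFrame        # (n_subjects, R) univariate contrasts
    rdm_triangles: Optional[np.ndarray]  # (n_subjects, R, 21) or None


def decode_cohort(phenotypes: pd.DataFrame, atlas: Atlas,
                  design: Optional[TaskDesign] = None,
                  coupling: Optional[CouplingSpec] = None,
                  seed: int = 0, n_voxels: int = 24,
                  backend: str = "dcd",
                  compute_rdms: bool = False) -> TaskCohortResult:
    """Generate, preprocess and decode task data for every subject-region.

    Data are generated lazily and discarded after decoding, so memory stays
    flat in the cohort size.  Per-(subject, region) fold and shuffle seeds are
    derived from ``seed`` and the ids, making the whole cohort reproducible.
    """
    design = design or default_task_design()
    n, R = len(phenotypes), atlas.n_regions
    acc = np.empty((n, R))
    con = np.empty((n, R))
    tris = np.empty((n, R, 21)) if compute_rdms else None
    gen = generate_task_data(phenotypes, atlas, design, coupling,
                             seed=seed, n_voxels=n_voxels)
    for idx, data in enumerate(gen):
        s, g = divmod(idx, R)
        run = preprocess_run(
            data, seed=int(data.subject_id) * 100_003 + data.region_id)
        res = decode_region(
            run.samples, run.class_labels,
            seed=int(data.subject_id) * 100_003 + data.region_id,
            backend=backend)
        acc[s, g] = res.accuracy
        con[s, g] = univariate_contrast(run.samples, run.class_labels)
        if compute_rdms:
            tris[s, g] = compute_rdm(run.samples,
                                     run.category_labels).lower_triangle
    cols = [f"region_{i:03d}" for i in atlas.region_id]
    index = pd.Index(phenotypes["subject_id"].to_numpy(), name="subject_id")
    return TaskCohortResult(pd.DataFrame(acc, columns=cols, index=index),
                            pd.DataFrame(con, columns=cols, index=index),
                            tris)
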