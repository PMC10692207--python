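"""Synthetic cohort generator with planted sleep/depression/cognition effects.

This module emulates the statistical structure of a large population-imaging
study relating five behavioural phenotypes -- accelerometer-measured duration
of the longest sleep bout, self-reported insomnia frequency, self-reported
daytime dozing frequency, PHQ-2 depressive symptoms, and a symbol-digit
cognition score -- to three imaging modalities:

* block-design task fMRI voxel patterns whose face-vs-shape separability is
  linearly coupled to the phenotypes (input to region-wise decoding),
* resting-state connectivity edge vectors whose edge-level and global-mean
  values are coupled to the phenotypes with independently configurable signs
  (so the task-hypo / rest-hyper phenomenon can be planted), and
* per-region cortical thickness.

Phenotypes are generated with a Gaussian copula: a latent multivariate normal
vector is transformed marginal-by-marginal (thresholding to ordinal scales,
affine maps for continuous ones).  Because ordinal discretisation attenuates
correlations, the latent correlation matrix is calibrated iteratively so that
the *realised* covariate-adjusted partial correlations match the requested
targets.

All randomness is funnelled through ``numpy.random.SeedSequence`` keyed on the
caller's seed, so identical seeds give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .errors import InvalidArgumentError

# ---------------------------------------------------------------------------
# Vocabulary
# ---------------------------------------------------------------------------

#: The five behavioural phenotypes, in canonical order.
PHENOTYPES: Tuple[str, ...] = (
    "sleep_bout_h", "insomnia", "dozing", "phq2", "cognition")

#: Covariates carried by every generated cohort table.
COVARIATES: Tuple[str, ...] = (
    "age", "sex", "site", "ses", "education", "ethnicity",
    "accel_time_offset", "head_motion",
    "task_acc_mean", "task_rt_mean", "task_rt_sd")

#: Canonical seven-network cortical grouping used for network-wise aggregation.
YEO7_NETWORKS: Tuple[str, ...] = (
    "Visual", "Somatomotor", "DorsalAttention", "VentralAttention",
    "Limbic", "Frontoparietal", "Default")

#: The seven stimulus categories of the face-shape matching task and the
#: binary class each belongs to.
CATEGORIES: Tuple[str, ...] = (
    "circle", "h_ellipse", "v_ellipse",
    "male_face", "female_face", "angry_face", "fearful_face")
CATEGORY_CLASS: Dict[str, str] = {
    "circle": "shape", "h_ellipse": "shape", "v_ellipse": "shape",
    "male_face": "face", "female_face": "face",
    "angry_face": "face", "fearful_face": "face"}

# Marginal category probabilities for the ordinal phenotypes.  The PHQ-2 tail
# is set so that roughly 3% of subjects score >= 3, matching the prevalence of
# the "depressed" stratum in a general-population imaging cohort.
_ORDINAL_PROBS: Dict[str, Tuple[float, ...]] = {
    "insomnia": (0.25, 0.35, 0.25, 0.15),
    "dozing": (0.72, 0.20, 0.06, 0.02),
    "phq2": (0.62, 0.22, 0.129, 0.013, 0.008, 0.006, 0.004),
}

_SLEEP_MEAN_H = 6.8   # median split value reported for the cohort
_SLEEP_SD_H = 1.1
_COG_MEAN = 19.0      # symbol-digit correct matches
_COG_SD = 5.0


# ---------------------------------------------------------------------------
# Atlas
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atlas:
    """Bilateral cortical parcellation with spherical centroids.

    Each region is a merge of a homotopic left/right pair and therefore
    carries one centroid per hemisphere; the left centroid is the x-mirror of
    the right one.  ``centroids_left``/``centroids_right`` are (R, 3) arrays
    of unit vectors.
    """

    region_id: np.ndarray          # (R,) int, 1..R contiguous
    name: np.ndarray               # (R,) str
    network: np.ndarray            # (R,) str, one of YEO7_NETWORKS
    centroids_left: np.ndarray     # (R, 3) float, unit norm
    centroids_right: np.ndarray    # (R, 3) float, unit norm

    @property
    def n_regions(self) -> int:
        return len(self.region_id)

    def to_frame(self) -> pd.DataFrame:
        cl, cr = self.centroids_left, self.centroids_right
        return pd.DataFrame({
            "region_id": self.region_id, "name": self.name,
            "network": self.network,
            "clx": cl[:, 0], "cly": cl[:, 1], "clz": cl[:, 2],
            "crx": cr[:, 0], "cry": cr[:, 1], "crz": cr[:, 2]})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Atlas":
        cl = df[["clx", "cly", "clz"]].to_numpy(float)
        cr = df[["crx", "cry", "crz"]].to_numpy(float)
        return cls(df["region_id"].to_numpy(int),
                   df["name"].to_numpy(str), df["network"].to_numpy(str),
                   cl, cr)

    def validate(self) -> None:
        rid = self.region_id
        if not np.array_equal(rid, np.arange(1, len(rid) + 1)):
            raise InvalidArgumentError(
                "region ids must be unique and contiguous from 1")
        for side, c in (("left", self.centroids_left),
                        ("right", self.centroids_right)):
            norms = np.linalg.norm(c, axis=1)
            if np.max(np.abs(norms - 1.0)) > 1e-9:
                raise InvalidArgumentError(
                    f"{side} centroids are not unit-norm within 1e-9")
        if not set(self.network) <= set(YEO7_NETWORKS):
            raise InvalidArgumentError("unknown network label in atlas")


def generate_atlas(n_regions: int = 180, seed: int = 0) -> Atlas:
    """Generate a bilateral atlas with mirror-symmetric spherical centroids.

    Regions are assigned round-robin to the seven canonical networks.  Right
    centroids are drawn uniformly on the unit hemisphere (x > 0); the left
    centroid of a region is the x-negated mirror of its right centroid.
    """
    if n_regions < 4:
        raise InvalidArgumentError(
            f"n_regions must be >= 4, got {n_regions}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA71A5]))
    v = rng.standard_normal((n_regions, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    v[:, 0] = np.abs(v[:, 0])
    # guard against the measure-zero x == 0 case so hemispheres stay disjoint
    v[v[:, 0] < 1e-12, 0] = 1e-6
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    right = v
    left = v * np.array([-1.0, 1.0, 1.0])
    ids = np.arange(1, n_regions + 1)
    networks = np.array([YEO7_NETWORKS[i % len(YEO7_NETWORKS)]
                         for i in range(n_regions)])
    names = np.array([f"region_{i:03d}" for i in ids])
    atlas = Atlas(ids, names, networks, left, right)
    atlas.validate()
    return atlas


# ---------------------------------------------------------------------------
# Coupling specification
# ---------------------------------------------------------------------------

def _default_phenotype_corr() -> np.ndarray:
    """Target partial-correlation matrix among the five phenotypes.

    Off-diagonal defaults are the cohort's reported pairwise partial
    correlations: PHQ-2 with insomnia 0.15, sleep bout with insomnia -0.072,
    with dozing -0.11 and with cognition 0.036, insomnia with dozing 0.081;
    all remaining pairs 0.
    """
    m = np.eye(5)
    pairs = {("sleep_bout_h", "insomnia"): -0.072,
             ("sleep_bout_h", "dozing"): -0.11,
             ("sleep_bout_h", "cognition"): 0.036,
             ("insomnia", "dozing"): 0.081,
             ("phq2", "insomnia"): 0.15}
    idx = {p: i for i, p in enumerate(PHENOTYPES)}
    for (a, b), r in pairs.items():
        m[idx[a], idx[b]] = m[idx[b], idx[a]] = r
    return m


@dataclass(frozen=True)
class CouplingSpec:
    """Effect structure planted by the generator.

    ``task_coupling`` gives, per phenotype, the slope of the decoding-signal
    amplitude per standard deviation of the (standardised) phenotype;
    ``rest_global_coupling`` shifts every connectivity edge uniformly on the
    Fisher-z scale, while ``rest_edge_coupling`` scales a shared spatial edge
    profile so that different phenotypes can imprint *correlated* edge-level
    patterns (what the signature-correlation analysis detects).  Thickness
    couplings are mm per phenotype SD.
    """

    phenotype_corr: np.ndarray = field(default_factory=_default_phenotype_corr)
    task_coupling: Dict[str, float] = field(default_factory=lambda: {
        "sleep_bout_h": 0.05, "insomnia": -0.015, "dozing": 0.0,
        "phq2": -0.04, "cognition": 0.025})
    task_base_range: Tuple[float, float] = (0.05, 0.30)
    rest_global_coupling: Dict[str, float] = field(default_factory=lambda: {
        "sleep_bout_h": 0.02, "insomnia": 0.02, "dozing": -0.03,
        "phq2": 0.02, "cognition": 0.0})
    rest_edge_coupling: Dict[str, float] = field(default_factory=lambda: {
        "sleep_bout_h": 0.04, "insomnia": 0.03, "dozing": -0.04,
        "phq2": 0.03, "cognition": 0.01})
    thickness_coupling: Dict[str, float] = field(default_factory=lambda: {
        "sleep_bout_h": 0.010, "insomnia": 0.0, "dozing": -0.008,
        "phq2": -0.010, "cognition": 0.012})
    covariate_leakage: Dict[Tuple[str, str], float] = field(
        default_factory=dict)
    # task noise model
    voxel_noise_sd: float = 1.0
    ar1: float = 0.1
    drift_amplitude: float = 0.5
    baseline: float = 100.0
    category_jitter: float = 0.3
    # rest noise model (Fisher-z scale)
    rest_noise_sd: float = 0.25
    rest_base_mean: float = 0.15
    rest_base_sd: float = 0.15
    # thickness model
    thickness_baseline: float = 2.5
    thickness_noise_sd: float = 0.10

    def __post_init__(self) -> None:
        m = np.asarray(self.phenotype_corr, float)
        if m.shape != (5, 5):
            raise InvalidArgumentError("phenotype_corr must be 5x5")
        if not np.allclose(m, m.T, atol=1e-12):
            raise InvalidArgumentError("phenotype_corr must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-12):
            raise InvalidArgumentError("phenotype_corr must have unit diagonal")
        w = np.linalg.eigvalsh(m)
        if w[0] <= 0:
            raise InvalidArgumentError(
                "phenotype_corr is not positive definite: smallest eigenvalue "
                f"{w[0]:.3e}")
        object.__setattr__(self, "phenotype_corr", m)

    @classmethod
    def null(cls) -> "CouplingSpec":
        """All couplings zero, independent phenotypes, zero task signal."""
        zero = {p: 0.0 for p in PHENOTYPES}
        return cls(phenotype_corr=np.eye(5),
                   task_coupling=dict(zero), task_base_range=(0.0, 0.0),
                   rest_global_coupling=dict(zero),
                   rest_edge_coupling=dict(zero),
                   thickness_coupling=dict(zero))


def default_coupling() -> CouplingSpec:
    """The package's default study conditions (printed correlation targets)."""
    return CouplingSpec()


# ---------------------------------------------------------------------------
# Phenotypes (Gaussian copula + latent calibration)
# ---------------------------------------------------------------------------

def _draw_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    return pd.DataFrame({
        "age": rng.uniform(45.0, 80.0, n),
        "sex": rng.binomial(1, 0.53, n),
        "site": rng.choice(3, n, p=[0.45, 0.35, 0.20]),
        "ses": rng.normal(-1.5, 2.8, n),
        "education": rng.choice(
            6, n, p=[0.05, 0.10, 0.20, 0.25, 0.25, 0.15]),
        "ethnicity": rng.choice(4, n, p=[0.94, 0.03, 0.02, 0.01]),
        "accel_time_offset": np.clip(rng.normal(730.0, 300.0, n), 0.0, None),
        "head_motion": rng.lognormal(np.log(0.12), 0.4, n),
        "task_acc_mean": np.clip(rng.normal(0.92, 0.06, n), 0.30, 1.0),
        "task_rt_mean": rng.normal(900.0, 150.0, n),
        "task_rt_sd": np.abs(rng.normal(300.0, 80.0, n)) + 20.0,
    })


def _ordinal_from_latent(x: np.ndarray, probs: Sequence[float]) -> np.ndarray:
    thresholds = sp_stats.norm.ppf(np.cumsum(probs)[:-1])
    return np.searchsorted(thresholds, x, side="left").astype(int)


def _latent_to_phenotypes(x: np.ndarray) -> pd.DataFrame:
    """Apply the fixed marginal transforms to (n, 5) latent standard normals."""
    return pd.DataFrame({
        "sleep_bout_h": _SLEEP_MEAN_H + _SLEEP_SD_H * x[:, 0],
        "insomnia": _ordinal_from_latent(x[:, 1], _ORDINAL_PROBS["insomnia"]),
        "dozing": _ordinal_from_latent(x[:, 2], _ORDINAL_PROBS["dozing"]),
        "phq2": _ordinal_from_latent(x[:, 3], _ORDINAL_PROBS["phq2"]),
        "cognition": np.clip(
            np.rint(_COG_MEAN + _COG_SD * x[:, 4]), 0, None).astype(int),
    })


def _covariate_matrix(cov: pd.DataFrame) -> np.ndarray:
    """Numeric covariate design (one-hot categoricals, drop-first) used for
    the calibration's internal residualisation."""
    cols = [np.ones(len(cov))]
    for c in ("age", "sex", "ses", "education", "accel_time_offset"):
        cols.append(cov[c].to_numpy(float))
    for c in ("site", "ethnicity"):
        vals = np.sort(np.unique(cov[c]))
        for v in vals[1:]:
            cols.append((cov[c].to_numpy() == v).astype(float))
    return np.column_stack(cols)


def _realized_partial_corr(pheno: pd.DataFrame,
                           cov: pd.DataFrame) -> np.ndarray:
    X = _covariate_matrix(cov)
    Y = pheno[list(PHENOTYPES)].to_numpy(float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return np.corrcoef(resid, rowvar=False)


def _draw_latent(n: int, latent_corr: np.ndarray, coupling: CouplingSpec,
                 cov: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
    chol = np.linalg.cholesky(latent_corr)
    x = rng.standard_normal((n, 5)) @ chol.T
    if coupling.covariate_leakage:
        scale = np.ones(5)
        idx = {p: i for i, p in enumerate(PHENOTYPES)}
        for (cname, pname), lam in coupling.covariate_leakage.items():
            c = cov[cname].to_numpy(float)
            c = (c - c.mean()) / c.std()
            x[:, idx[pname]] += lam * c
            scale[idx[pname]] += lam ** 2
        x /= np.sqrt(scale)
    return x


def _project_to_correlation(m: np.ndarray) -> np.ndarray:
    """Nearest-ish positive-definite correlation matrix (eigenvalue clip)."""
    m = (m + m.T) / 2
    w, v = np.linalg.eigh(m)
    w = np.clip(w, 1e-6, None)
    m = (v * w) @ v.T
    d = np.sqrt(np.diag(m))
    m = m / np.outer(d, d)
    np.fill_diagonal(m, 1.0)
    return m


_CALIBRATION_CACHE: Dict[bytes, np.ndarray] = {}


def calibrate_latent_corr(coupling: CouplingSpec,
                          n_cal: int = 80_000,
                          max_iter: int = 12,
                          tol: float = 0.004) -> np.ndarray:
    """Find the latent Gaussian correlation matrix whose transformed marginals
    realise the target partial correlations.

    Ordinal thresholding attenuates Pearson correlations, so the latent
    matrix must over-state the targets.  A fixed-point iteration adds the
    residual target error to the latent matrix each round, measuring the
    realised covariate-adjusted partial correlations on a large Monte-Carlo
    sample.  The iteration uses its own fixed internal random stream so that
    the calibrated matrix is a deterministic function of the coupling spec
    (results are cached per spec).
    """
    target = coupling.phenotype_corr
    key = target.tobytes() + repr(sorted(
        coupling.covariate_leakage.items())).encode()
    cached = _CALIBRATION_CACHE.get(key)
    if cached is not None:
        return cached
    latent = target.copy()
    for it in range(max_iter):
        rng = np.random.default_rng(
            np.random.SeedSequence([0xCA11B, it]))
        cov = _draw_covariates(n_cal, rng)
        x = _draw_latent(n_cal, latent, coupling, cov, rng)
        realized = _realized_partial_corr(_latent_to_phenotypes(x), cov)
        err = target - realized
        np.fill_diagonal(err, 0.0)
        if np.max(np.abs(err)) < tol:
            break
        latent = _project_to_correlation(latent + err)
    _CALIBRATION_CACHE[key] = latent
    return latent


def generate_phenotypes(n_subjects: int,
                        coupling: Optional[CouplingSpec] = None,
                        seed: int = 0,
                        calibrate: bool = True) -> pd.DataFrame:
    """Generate the cohort phenotype/covariate table.

    Returns a DataFrame with ``subject_id``, the five phenotypes and the
    covariate columns.  With ``calibrate=True`` (default) the latent
    correlations are first adjusted so realised partial correlations match
    ``coupling.phenotype_corr``; with ``calibrate=False`` the target matrix is
    used directly on the latent scale (ordinals then come out attenuated).
    """
    coupling = coupling or default_coupling()
    if n_subjects <= 20:
        raise InvalidArgumentError(
            "n_subjects must exceed the number of model terms (> 20)")
    latent_corr = (calibrate_latent_corr(coupling) if calibrate
                   else coupling.phenotype_corr)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x9E07]))
    cov = _draw_covariates(n_subjects, rng)
    x = _draw_latent(n_subjects, latent_corr, coupling, cov, rng)
    pheno = _latent_to_phenotypes(x)
    out = pd.concat(
        [pd.DataFrame({"subject_id": np.arange(1, n_subjects + 1)}),
         pheno, cov], axis=1)
    return out


def standardized_phenotypes(table: pd.DataFrame) -> pd.DataFrame:
    """Z-score the five phenotype columns (population standardisation)."""
    z = {}
    for p in PHENOTYPES:
        v = table[p].to_numpy(float)
        sd = v.std()
        if sd == 0:
            raise InvalidArgumentError(f"phenotype {p} has zero variance")
        z[p] = (v - v.mean()) / sd
    return pd.DataFrame(z, index=table.index)


# ---------------------------------------------------------------------------
# Task design and task voxel data
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaskDesign:
    """Block design of the face-shape matching run.

    ``blocks`` is a list of ``(onset_volume, length_volumes, category)``; each
    block is divided into ``samples_per_block`` consecutive groups of
    ``vols_per_sample`` volumes which are averaged into one classifier sample.
    The default design has 10 blocks per class, 3 samples per block and 2
    volumes per sample, which yields exactly 60 class-balanced samples.
    ``hemodynamic_delay_volumes`` is where the generator places the response
    relative to block onset and is the default label shift at preprocessing.
    """

    tr_s: float = 0.735
    n_volumes: int = 209
    blocks: Tuple[Tuple[int, int, str], ...] = ()
    samples_per_block: int = 3
    vols_per_sample: int = 2
    hemodynamic_delay_volumes: int = 5

    @property
    def block_length(self) -> int:
        return self.samples_per_block * self.vols_per_sample

    @property
    def n_samples(self) -> int:
        return len(self.blocks) * self.samples_per_block

    def validate(self) -> None:
        occupied = np.zeros(self.n_volumes, bool)
        classes = set()
        for onset, length, cat in self.blocks:
            if cat not in CATEGORY_CLASS:
                raise InvalidArgumentError(f"unknown category {cat!r}")
            if length != self.block_length:
                raise InvalidArgumentError(
                    "block length must equal samples_per_block * "
                    "vols_per_sample")
            if onset < 0 or onset + length > self.n_volumes:
                raise InvalidArgumentError(
                    f"block at {onset} out of run range")
            if occupied[onset:onset + length].any():
                raise InvalidArgumentError(f"block at {onset} overlaps")
            occupied[onset:onset + length] = True
            classes.add(CATEGORY_CLASS[cat])
        if classes != {"face", "shape"}:
            raise InvalidArgumentError("both classes must be present")


def default_task_design() -> TaskDesign:
    """The default 20-block design (60 balanced samples).

    Blocks alternate face/shape; shape blocks cycle through the three shape
    categories and face blocks through the four face categories so that every
    one of the seven categories occurs at least twice.
    """
    shapes = [c for c in CATEGORIES if CATEGORY_CLASS[c] == "shape"]
    faces = [c for c in CATEGORIES if CATEGORY_CLASS[c] == "face"]
    blocks = []
    onset, gap, length = 5, 4, 6
    for k in range(10):
        blocks.append((onset, length, faces[k % 4]))
        onset += length + gap
        blocks.append((onset, length, shapes[k % 3]))
        onset += length + gap
    design = TaskDesign(blocks=tuple(blocks))
    design.validate()
    return design


@dataclass(frozen=True)
class TaskRegionData:
    """Voxel-by-time array for one subject and region, plus its design."""

    subject_id: int
    region_id: int
    voxels_by_time: np.ndarray   # (V, T)
    design: TaskDesign

    def __post_init__(self) -> None:
        v = self.voxels_by_time
        if v.ndim != 2 or v.shape[0] < 2:
            raise InvalidArgumentError("voxels_by_time must be (V>=2, T)")
        if v.shape[1] != self.design.n_volumes:
            raise InvalidArgumentError("T must equal design.n_volumes")
        if not np.all(np.isfinite(v)):
            raise InvalidArgumentError("voxel data must be finite")


def _region_task_params(atlas: Atlas, coupling: CouplingSpec, n_voxels: int,
                        seed: int):
    """Per-region base amplitudes and category patterns (deterministic)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x7A5C]))
    lo, hi = coupling.task_base_range
    a0 = rng.uniform(lo, hi, atlas.n_regions)
    patterns = {}
    for g in range(atlas.n_regions):
        p_class = {"face": rng.standard_normal(n_voxels),
                   "shape": rng.standard_normal(n_voxels)}
        patterns[g] = {
            cat: p_class[CATEGORY_CLASS[cat]]
            + coupling.category_jitter * rng.standard_normal(n_voxels)
            for cat in CATEGORIES}
    return a0, patterns


def task_amplitudes(phenotypes: pd.DataFrame, atlas: Atlas,
                    coupling: CouplingSpec, seed: int = 0) -> np.ndarray:
    """Planted decoding-signal amplitude per (subject, region), floored at 0."""
    z = standardized_phenotypes(phenotypes)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x7A5C]))
    lo, hi = coupling.task_base_range
    a0 = rng.uniform(lo, hi, atlas.n_regions)
    shift = np.zeros(len(phenotypes))
    for p in PHENOTYPES:
        shift += coupling.task_coupling.get(p, 0.0) * z[p].to_numpy()
    return np.maximum(a0[None, :] + shift[:, None], 0.0)


def _ar1_noise(rng: np.random.Generator, shape: Tuple[int, int],
               sd: float, rho: float) -> np.ndarray:
    e = rng.standard_normal(shape) * sd * np.sqrt(max(1.0 - rho ** 2, 1e-12))
    if rho == 0.0:
        return e
    return sp_signal.lfilter([1.0], [1.0, -rho], e, axis=1)


def generate_task_data(phenotypes: pd.DataFrame, atlas: Atlas,
                       design: Optional[TaskDesign] = None,
                       coupling: Optional[CouplingSpec] = None,
                       seed: int = 0,
                       n_voxels: int = 24) -> Iterator[TaskRegionData]:
    """Yield task voxel arrays per (subject, region), subjects outer.

    Each region has a fixed multivariate pattern per stimulus category; during
    a block's (hemodynamically delayed) volumes that pattern is added with
    subject-by-region amplitude ``a_sg = max(0, a0_g + sum_k c_k z_k(s))``.
    Noise is AR(1) per voxel plus a slow sinusoidal drift over a positive
    baseline, so detrending and percent-signal-change normalisation have real
    structure to remove.
    """
    design = design or default_task_design()
    design.validate()
    coupling = coupling or default_coupling()
    if not all(np.isfinite(list(coupling.task_coupling.values()))):
        raise InvalidArgumentError("task couplings must be finite")
    a0, patterns = _region_task_params(atlas, coupling, n_voxels, seed)
    z = standardized_phenotypes(phenotypes)
    shift = np.zeros(len(phenotypes))
    for p in PHENOTYPES:
        shift += coupling.task_coupling.get(p, 0.0) * z[p].to_numpy()
    T = design.n_volumes
    t = np.arange(T)
    delay = design.hemodynamic_delay_volumes
    subj_ids = phenotypes["subject_id"].to_numpy()
    for s_idx, sid in enumerate(subj_ids):
        for g in range(atlas.n_regions):
            rng = np.random.default_rng(np.random.SeedSequence(
                [int(seed), 0xDA7A, int(sid), int(atlas.region_id[g])]))
            a = max(a0[g] + shift[s_idx], 0.0)
            data = np.full((n_voxels, T), coupling.baseline)
            freq = rng.uniform(0.5, 1.5, n_voxels)
            phase = rng.uniform(0, 2 * np.pi, n_voxels)
            data += coupling.drift_amplitude * np.sin(
                2 * np.pi * freq[:, None] * t[None, :] / T + phase[:, None])
            data += _ar1_noise(rng, (n_voxels, T),
                               coupling.voxel_noise_sd, coupling.ar1)
            if a > 0:
                for onset, length, cat in design.blocks:
                    lo = onset + delay
                    hi = min(lo + length, T)
                    data[:, lo:hi] += a * patterns[g][cat][:, None]
            yield TaskRegionData(int(sid), int(atlas.region_id[g]),
                                 data, design)


# ---------------------------------------------------------------------------
# Resting-state connectivity
# ---------------------------------------------------------------------------

def n_edges(n_nodes: int) -> int:
    """Number of unique node pairs (lower-triangle edges)."""
    return n_nodes * (n_nodes - 1) // 2


@dataclass(frozen=True)
class RestCohort:
    """Per-subject connectivity edge vectors.

    ``edges`` is (n_subjects, R(R-1)/2) in row-major lower-triangle order
    (i > j, i ascending, j ascending within i) on the correlation scale;
    ``ic_edges`` is the analogous (n_subjects, 210) array for the 21
    independent components.
    """

    subject_id: np.ndarray
    n_regions: int
    edges: np.ndarray
    n_ics: int
    ic_edges: np.ndarray

    def __post_init__(self) -> None:
        if self.edges.shape != (len(self.subject_id),
                                n_edges(self.n_regions)):
            raise InvalidArgumentError(
                "edge vector length must equal R(R-1)/2")
        if self.ic_edges.shape != (len(self.subject_id),
                                   n_edges(self.n_ics)):
            raise InvalidArgumentError(
                "IC edge vector length must equal n_ics(n_ics-1)/2")


def _edge_block(rng: np.random.Generator, n_nodes: int, z: pd.DataFrame,
                coupling: CouplingSpec) -> np.ndarray:
    """Generate one family of subject edge vectors on the Fisher-z scale."""
    E = n_edges(n_nodes)
    base = rng.normal(coupling.rest_base_mean, coupling.rest_base_sd, E)
    loadings = rng.standard_normal(n_nodes)
    ii, jj = np.tril_indices(n_nodes, -1)
    profile = (loadings[ii] + loadings[jj]) / np.sqrt(2.0)
    n = len(z)
    zmat = np.column_stack([z[p].to_numpy() for p in PHENOTYPES])
    g = np.array([coupling.rest_global_coupling.get(p, 0.0)
                  for p in PHENOTYPES])
    s = np.array([coupling.rest_edge_coupling.get(p, 0.0)
                  for p in PHENOTYPES])
    # (n, E): uniform global shift + shared-profile edge effects + noise
    vals = (base[None, :]
            + (zmat @ g)[:, None]
            + np.outer(zmat @ s, profile)
            + rng.standard_normal((n, E)) * coupling.rest_noise_sd)
    return np.tanh(vals)


def generate_rest_data(phenotypes: pd.DataFrame, atlas: Atlas,
                       coupling: Optional[CouplingSpec] = None,
                       seed: int = 0, n_ics: int = 21) -> RestCohort:
    """Generate region-level and IC-level connectivity edge vectors.

    Values are built on the Fisher-z scale (base edge pattern + phenotype
    couplings + Gaussian noise) and mapped through tanh, which keeps them in
    (-1, 1) like correlations.
    """
    coupling = coupling or default_coupling()
    for d in (coupling.rest_global_coupling, coupling.rest_edge_coupling):
        if not all(np.isfinite(list(d.values()))):
            raise InvalidArgumentError("rest couplings must be finite")
    z = standardized_phenotypes(phenotypes)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x8E57]))
    edges = _edge_block(rng, atlas.n_regions, z, coupling)
    ic_edges = _edge_block(rng, n_ics, z, coupling)
    return RestCohort(phenotypes["subject_id"].to_numpy(), atlas.n_regions,
                      edges, n_ics, ic_edges)


# ---------------------------------------------------------------------------
# Cortical thickness
# ---------------------------------------------------------------------------

def generate_thickness(phenotypes: pd.DataFrame, atlas: Atlas,
                       coupling: Optional[CouplingSpec] = None,
                       seed: int = 0) -> pd.DataFrame:
    """Generate a subject x region cortical-thickness table (mm).

    thickness = baseline + sum_k theta_k(region) * z_k(subject) + noise.
    ``coupling.thickness_coupling`` values may be scalars (uniform across
    regions) or length-R arrays for region-specific planted effects.
    """
    coupling = coupling or default_coupling()
    z = standardized_phenotypes(phenotypes)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x741C]))
    n, R = len(phenotypes), atlas.n_regions
    vals = np.full((n, R), coupling.thickness_baseline)
    for p in PHENOTYPES:
        theta = np.broadcast_to(
            np.asarray(coupling.thickness_coupling.get(p, 0.0), float), (R,))
        vals = vals + np.outer(z[p].to_numpy(), theta)
    vals = vals + rng.standard_normal((n, R)) * coupling.thickness_noise_sd
    out = pd.DataFrame(vals, columns=[f"region_{i:03d}"
                                      for i in atlas.region_id])
    out.insert(0, "subject_id", phenotypes["subject_id"].to_numpy())
    return out
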