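"""Second-order correlations between neural signatures, with spin-test nulls.

A phenotype's *neural signature* is its vector of association betas across
brain units (regions for task/thickness maps, edges for connectivity maps).
The similarity of two phenotypes' brain-wide patterns is the Pearson
correlation between their signatures.  Parametric inference uses the exact
beta-distribution null of the Pearson coefficient; for region-based maps a
spatial spin test additionally preserves cortical spatial autocorrelation by
applying random 3D rotations to the region centroids (mirror-image rotations
on the two hemispheres, values averaged across sides since regions are
bilateral merges) and re-assigning values by nearest original centroid.

A pair is flagged significant only when *both* the parametric and the spin
p-value fall below the Bonferroni-corrected threshold (alpha / 5).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import special_ortho_group

from .errors import (AtlasIncompleteError, InsufficientSampleError,
                     InvalidArgumentError, StratificationError,
                     UndefinedCorrelationError)
from .phenostats import beta_null_p
from .synthetic import Atlas, PHENOTYPES

ALPHA = 0.05
N_PHENOTYPES = 5


def signature_correlation(map_a: np.ndarray, map_b: np.ndarray) -> float:
    """Pearson correlation between two signature vectors over units."""
    a = np.asarray(map_a, float)
    b = np.asarray(map_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidArgumentError(
            "signatures must be equal-length vectors with matching unit "
            "ordering")
    if len(a) < 3:
        raise InsufficientSampleError("need at least 3 units")
    if a.std() == 0 or b.std() == 0:
        raise UndefinedCorrelationError("signature has zero variance")
    return float(np.corrcoef(a, b)[0, 1])


def pearson_p_beta(r: float, n: int) -> float:
    """Two-sided p for Pearson r under the exact beta-distribution null.

    Under independence (1 + r) / 2 ~ Beta((n - 2) / 2, (n - 2) / 2);
    p = 2 * min(F, 1 - F).  Equivalent to the classic t transform with
    n - 2 degrees of freedom.
    """
    if n < 4:
        raise InsufficientSampleError(f"need n >= 4, got {n}")
    return beta_null_p(float(r), n - 2)


# ---------------------------------------------------------------------------
# Spin test
# ---------------------------------------------------------------------------

_MIRROR = np.diag([-1.0, 1.0, 1.0])


def _spin_permutations(atlas: Atlas, n_perm: int,
                       rng: np.random.Generator
                       ) -> Tuple[np.ndarray, np.ndarray]:
    """Nearest-centroid re-assignment index per permutation and hemisphere.

    For each permutation one uniform rotation Q is drawn; the left-hemisphere
    centroids are rotated by Q and the right-hemisphere centroids by the
    x-mirrored rotation M Q M, so the two sides spin as mirror images.  Each
    original region then takes the value of the region whose rotated centroid
    lies nearest (duplicates allowed, as in the classic spin procedure).
    """
    cl, cr = atlas.centroids_left, atlas.centroids_right
    if not (np.all(np.isfinite(cl)) and np.all(np.isfinite(cr))):
        raise AtlasIncompleteError("atlas centroids contain non-finite values")
    rots = special_ortho_group.rvs(3, size=n_perm, random_state=rng)
    if n_perm == 1:
        rots = rots[None]
    perm_l = np.empty((n_perm, atlas.n_regions), int)
    perm_r = np.empty((n_perm, atlas.n_regions), int)
    for k in range(n_perm):
        q = rots[k]
        qm = _MIRROR @ q @ _MIRROR
        rot_l = cl @ q.T          # rotated position of each region, left
        rot_r = cr @ qm.T
        # original region i takes the value of the region whose rotated
        # centroid is closest to i's original centroid
        perm_l[k] = np.argmax(rot_l @ cl.T, axis=0)
        perm_r[k] = np.argmax(rot_r @ cr.T, axis=0)
    return perm_l, perm_r


def spin_test(map_a: np.ndarray, map_b: np.ndarray, atlas: Atlas,
              n_perm: int = 1000, seed: int = 0,
              scheme: str = "rotation") -> float:
    """Spatial permutation p-value for the correlation of two region maps.

    ``scheme="rotation"`` (default) uses mirrored hemisphere rotations with
    nearest-centroid re-assignment; ``scheme="labels"`` is a plain seeded
    permutation of region labels (no spatial structure preserved), provided
    as a fallback.  The p-value is the fraction of permutations whose |r|
    reaches |r_obs| (count / n_perm, no +1 correction, following the
    percentage-of-permutations definition).
    """
    a = np.asarray(map_a, float)
    b = np.asarray(map_b, float)
    r_obs = signature_correlation(a, b)
    if len(a) != atlas.n_regions:
        raise InvalidArgumentError("map length must equal atlas regions")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5417]))
    if scheme == "rotation":
        perm_l, perm_r = _spin_permutations(atlas, n_perm, rng)
        a_perm = (a[perm_l] + a[perm_r]) / 2.0    # (n_perm, R)
    elif scheme == "labels":
        a_perm = np.stack([a[rng.permutation(len(a))]
                           for _ in range(n_perm)])
    else:
        raise InvalidArgumentError(f"unknown spin scheme {scheme!r}")
    ac = a_perm - a_perm.mean(axis=1, keepdims=True)
    bc = b - b.mean()
    denom = np.linalg.norm(ac, axis=1) * np.linalg.norm(bc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r_perm = np.where(denom > 0, ac @ bc / denom, 0.0)
    return float(np.mean(np.abs(r_perm) >= abs(r_obs)))


# ---------------------------------------------------------------------------
# Signature tables
# ---------------------------------------------------------------------------

def signature_correlation_table(maps: pd.DataFrame,
                                atlas: Optional[Atlas] = None,
                                n_perm: int = 1000, seed: int = 0,
                                alpha: float = ALPHA,
                                n_phenotypes: int = N_PHENOTYPES
                                ) -> pd.DataFrame:
    """All pairwise signature correlations for a units-by-phenotypes frame.

    When an atlas is given (region-based maps) the spin test is run and a
    pair is significant only if both p_beta and p_spin fall below
    alpha / n_phenotypes; for edge-based maps (no atlas) only the parametric
    criterion applies and p_spin is NaN.
    """
    thr = alpha / n_phenotypes
    rows = []
    for a, b in combinations(maps.columns, 2):
        va, vb = maps[a].to_numpy(float), maps[b].to_numpy(float)
        r = signature_correlation(va, vb)
        p_beta = pearson_p_beta(r, len(va))
        if atlas is not None:
            p_spin = spin_test(va, vb, atlas, n_perm=n_perm, seed=seed)
            sig = (p_beta < thr) and (p_spin < thr)
        else:
            p_spin = np.nan
            sig = p_beta < thr
        rows.append({"phenotype_a": a, "phenotype_b": b, "r": r,
                     "n_units": len(va), "p_beta": p_beta,
                     "p_spin": p_spin, "significant": sig})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Stratified re-analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StratumSpec:
    """A two-group cohort split on one phenotype at a threshold.

    Subjects at or above the threshold go to ``label_high``.  The two
    canonical splits are PHQ-2 >= 3 ("depressed" vs "not-depressed") and
    sleep bout >= 6.8 h ("long sleepers" vs "short sleepers").
    """

    variable: str
    threshold: float
    label_high: str
    label_low: str


PHQ2_SPLIT = StratumSpec("phq2", 3.0, "depressed", "not-depressed")
SLEEP_SPLIT = StratumSpec("sleep_bout_h", 6.8, "long sleepers",
                          "short sleepers")


def assign_strata(table: pd.DataFrame, spec: StratumSpec) -> pd.Series:
    """Stratum label per subject (>= threshold goes to the high label)."""
    v = table[spec.variable].to_numpy(float)
    return pd.Series(np.where(v >= spec.threshold, spec.label_high,
                              spec.label_low), index=table.index,
                     name="stratum")


def stratified_signatures(table: pd.DataFrame, spec: StratumSpec,
                          map_builder: Callable[[pd.DataFrame], pd.DataFrame],
                          atlas: Optional[Atlas] = None,
                          n_perm: int = 1000, seed: int = 0,
                          min_extra_df: int = 10
                          ) -> Dict[str, pd.DataFrame]:
    """Refit signatures within each stratum of a cohort split.

    ``map_builder`` takes the stratum's sub-table and returns a
    units-by-phenotypes beta frame (it should refit every unit-level model
    within the stratum).  Returns ``{stratum label: signature table}``.
    """
    strata = assign_strata(table, spec)
    out: Dict[str, pd.DataFrame] = {}
    for label in (spec.label_high, spec.label_low):
        sub = table.loc[strata == label]
        if len(sub) == 0:
            raise StratificationError(f"stratum {label!r} is empty")
        if len(sub) < 20 + min_extra_df:
            raise StratificationError(
                f"stratum {label!r} has only {len(sub)} subjects; too few "
                "to fit the association models")
        maps = map_builder(sub)
        out[label] = signature_correlation_table(
            maps, atlas=atlas, n_perm=n_perm, seed=seed)
    return out
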