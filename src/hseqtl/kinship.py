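"""Genetic and phenotypic relatedness.

Relatedness between individuals is expressed as a square symmetric
*distance* matrix: the manhattan (city-block) distance between dosage
vectors, computed genome-wide, per chromosome, or over the two markers
flanking a single interval.  Phenotype distance between samples is the
absolute expression difference.  Matrix correlation (Pearson over the
strictly-upper triangle) and the Mantel permutation test quantify how
similar two relatedness structures are.

Distances are raw manhattan sums, not normalized by marker count, which
keeps per-chromosome matrices additive: summing them over chromosomes
reproduces the genome-wide matrix exactly.  ``normalize=True`` divides by
the number of markers for cross-scope comparability.

Mixed-model machinery needs a positive semi-definite similarity matrix;
:func:`distance_to_similarity` converts S = 1 - D/max(D) and projects to
the nearest PSD matrix by zeroing negative eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from hseqtl.markers import Interval, MarkerMap


def _check_dosages(dosages: np.ndarray) -> np.ndarray:
    d = np.asarray(dosages, dtype=float)
    if d.ndim != 2:
        raise ValueError("dosage matrix must be 2-D (individuals x markers)")
    if np.isnan(d).any():
        raise ValueError("missing dosages; impute first (see impute_mean)")
    return d


def impute_mean(dosages: np.ndarray) -> np.ndarray:
    """Replace missing (NaN) dosages by the per-marker mean."""
    d = np.asarray(dosages, dtype=float).copy()
    col_mean = np.nanmean(d, axis=0)
    nan_idx = np.where(np.isnan(d))
    d[nan_idx] = col_mean[nan_idx[1]]
    return d


def genome_kinship(dosages: np.ndarray, normalize: bool = False) -> np.ndarray:
    """Pairwise manhattan distance over all markers.

    entry(i, j) = sum_m |dosage_i[m] - dosage_j[m]|; a genome-wide
    dissimilarity playing the role of the kinship matrix in the mixed
    model.
    """
    d = _check_dosages(dosages)
    if d.shape[0] < 2:
        raise ValueError("need at least 2 individuals")
    K = squareform(pdist(d, metric="cityblock"))
    if normalize:
        K = K / d.shape[1]
    return K


def chromosome_kinship(
    dosages: np.ndarray, marker_map: MarkerMap, chrom: str, normalize: bool = False
) -> np.ndarray:
    """Manhattan distance restricted to one chromosome's markers."""
    sl = marker_map.chrom_slice(str(chrom))
    return genome_kinship(np.asarray(dosages)[:, sl], normalize=normalize)


def interval_distance(
    dosages: np.ndarray, interval: Interval, normalize: bool = False
) -> np.ndarray:
    """Manhattan distance over the two markers flanking one interval."""
    cols = [interval.left, interval.right]
    return genome_kinship(np.asarray(dosages)[:, cols], normalize=normalize)


def phenotype_distance(values: np.ndarray) -> np.ndarray:
    """|y_i - y_j| pairwise absolute-difference matrix for one probe."""
    y = np.asarray(values, dtype=float).ravel()
    return np.abs(y[:, None] - y[None, :])


def _upper(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    iu = np.triu_indices(a.shape[0], k=1)
    return a[iu]


def matrix_correlation(A: np.ndarray, B: np.ndarray) -> float:
    """Pearson correlation of the strictly-upper-triangle entries.

    Returns NaN when either matrix is constant off-diagonal (the
    correlation is undefined there).
    """
    A, B = np.asarray(A, float), np.asarray(B, float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    a, b = _upper(A), _upper(B)
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass(frozen=True)
class MantelResult:
    r: float
    p_value: float
    n_permutations: int


def mantel_test(
    A: np.ndarray,
    B: np.ndarray,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    exhaustive: bool = False,
) -> MantelResult:
    """Mantel permutation test of matrix correlation.

    The null is built by simultaneous row/column permutation of B; the
    two-sided p-value uses the add-one convention
    p = (1 + #{|r_perm| >= |r_obs|}) / (1 + n_perm), so p > 0 always.
    With ``exhaustive=True`` all n! permutations are enumerated (small n
    only) and p = #{|r_perm| >= |r_obs|}/n!, the identity permutation
    guaranteeing p > 0.
    """
    if n_perm < 1 and not exhaustive:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    r_obs = matrix_correlation(A, B)
    if np.isnan(r_obs):
        raise ValueError("matrix correlation undefined (constant matrix)")
    n = A.shape[0]
    a = _upper(A)
    a = (a - a.mean()) / a.std()
    B = np.asarray(B, float)

    def r_of(perm) -> float:
        b = _upper(B[np.ix_(perm, perm)])
        return float(np.mean(a * (b - b.mean()) / b.std()))

    if exhaustive:
        from itertools import permutations as _perms
        from math import factorial

        count = sum(abs(r_of(list(p))) >= abs(r_obs) - 1e-12 for p in _perms(range(n)))
        return MantelResult(r=r_obs, p_value=count / factorial(n), n_permutations=factorial(n))

    count = sum(abs(r_of(rng.permutation(n))) >= abs(r_obs) - 1e-12 for _ in range(n_perm))
    p = (1 + count) / (1 + n_perm)
    return MantelResult(r=r_obs, p_value=p, n_permutations=n_perm)


def genotype_outlier_removal(K_genome: np.ndarray, sd_cutoff: float = 2.0):
    """Flag individuals genetically far from the population.

    Each individual's mean distance to all others is computed from the
    genome-wide distance matrix; individuals more than ``sd_cutoff``
    standard deviations *above* the mean of these averages are removed
    (single pass).  Returns (kept_idx, removed_idx).
    """
    K = np.asarray(K_genome, float)
    n = K.shape[0]
    if n < 3:
        raise ValueError("need at least 3 individuals")
    mean_dist = K.sum(axis=1) / (n - 1)
    mu, sd = mean_dist.mean(), mean_dist.std()
    removed = np.where(mean_dist > mu + sd_cutoff * sd)[0] if sd > 0 else np.empty(0, int)
    kept = np.setdiff1d(np.arange(n), removed)
    return kept, removed


def distance_to_similarity(D: np.ndarray) -> np.ndarray:
    """Convert a distance matrix to a PSD similarity matrix.

    S = 1 - D/max(D), then the nearest-PSD projection (negative
    eigenvalues zeroed).  An all-zero distance matrix maps to the all-ones
    (perfect similarity) matrix.
    """
    D = np.asarray(D, float)
    mx = D.max()
    S = np.ones_like(D) if mx == 0 else 1.0 - D / mx
    S = 0.5 * (S + S.T)
    w, U = np.linalg.eigh(S)
    if w.min() < 0:
        S = (U * np.clip(w, 0.0, None)) @ U.T
        S = 0.5 * (S + S.T)
    return S
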