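"""Multilocus gametic disequilibrium via the index of association I_A.

For every unordered pair of haploid isolates, K is the number of loci at
which they differ.  V_O is the variance of K over all pairs; under linkage
equilibrium its expectation is V_E = sum_j h_j (1 - h_j), with h_j the
gene diversity 1 - sum_i p_ij^2 at locus j.  The index of association

    I_A = V_O / V_E - 1

is near zero under random mating and positive when alleles are associated
across loci (clonality).  Significance is assessed against a permutation
null that shuffles alleles among isolates independently within each locus:
this preserves every per-locus allele frequency while destroying inter-locus
association, which is exactly the hypothesis under test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .core import MISSING, PopulationDataset
from .io_core import substream_seed

logger = logging.getLogger("cryptosex")


@dataclass(frozen=True)
class MismatchDistribution:
    K_values: np.ndarray      # per-pair mismatch counts, length n(n-1)/2
    n_pairs: int
    mean_K: float
    V_O: float


@dataclass
class IaResult:
    species: str
    site: str
    n_mlh: int
    V_O: float
    V_E: float
    I_A: float
    p_perm: float | None = None
    n_perm: int = 0
    seed: int | None = None

    def report_row(self) -> dict:
        return {
            "species": self.species,
            "site": self.site,
            "n_mlh": self.n_mlh,
            "V_O": self.V_O,
            "V_E": self.V_E,
            "I_A": self.I_A,
            "p_perm": self.p_perm,
            "n_perm": self.n_perm,
        }


def _retained_matrix(pop: PopulationDataset) -> np.ndarray:
    """Integer-coded genotype matrix after dropping missing-data isolates.

    Isolates carrying any missing allele are excluded before pair
    enumeration; allele codes are factorized per locus (the statistic only
    sees same/different).
    """
    kept = [iso for iso in pop.isolates if not iso.has_missing]
    dropped = pop.n_isolates - len(kept)
    if dropped:
        logger.info(
            "I_A %s/%s: excluded %d isolates with missing data",
            pop.species, pop.site, dropped,
        )
    if len(kept) < 3:
        raise ValueError(
            f"population {pop.species}/{pop.site}: fewer than 3 isolates "
            "after missing-data exclusion"
        )
    raw = np.array([iso.genotype for iso in kept], dtype=object)
    coded = np.empty(raw.shape, dtype=np.int64)
    for j in range(raw.shape[1]):
        _, coded[:, j] = np.unique(raw[:, j].astype(str), return_inverse=True)
    return coded


def _pair_mismatches(matrix: np.ndarray) -> np.ndarray:
    """K for every unordered pair of rows (i < j, row-major order)."""
    i1, i2 = np.triu_indices(matrix.shape[0], k=1)
    return (matrix[i1] != matrix[i2]).sum(axis=1)


def _vo(matrix: np.ndarray, denominator: str = "n") -> float:
    K = _pair_mismatches(matrix)
    ddof = 0 if denominator == "n" else 1
    return float(K.var(ddof=ddof))


def mismatch_distribution(pop: PopulationDataset) -> MismatchDistribution:
    """Distribution of per-pair mismatch counts K over all isolate pairs.

    V_O uses the population (divide-by-n_pairs) variance of the mismatch
    distribution.
    """
    matrix = _retained_matrix(pop)
    K = _pair_mismatches(matrix)
    return MismatchDistribution(
        K_values=K,
        n_pairs=len(K),
        mean_K=float(K.mean()),
        V_O=float(K.var(ddof=0)),
    )


def expected_variance(
    pop: PopulationDataset, unbiased_h: bool = False
) -> tuple[float, np.ndarray]:
    """Expected variance of K under linkage equilibrium and per-locus
    diversities.

    h_j is the plug-in gene diversity 1 - sum_i p_ij^2; ``unbiased_h``
    applies the n/(n-1) sample-size correction.  Monomorphic loci
    contribute zero.
    """
    matrix = _retained_matrix(pop)
    n = matrix.shape[0]
    h = np.empty(matrix.shape[1])
    for j in range(matrix.shape[1]):
        counts = np.bincount(matrix[:, j])
        freqs = counts[counts > 0] / n
        hj = 1.0 - float((freqs**2).sum())
        if unbiased_h:
            hj *= n / (n - 1)
        h[j] = hj
    return float((h * (1.0 - h)).sum()), h


def _ia_from_matrix(matrix: np.ndarray, denominator: str = "n",
                    unbiased_h: bool = False) -> tuple[float, float, float]:
    n = matrix.shape[0]
    V_O = _vo(matrix, denominator)
    h = np.empty(matrix.shape[1])
    for j in range(matrix.shape[1]):
        counts = np.bincount(matrix[:, j])
        freqs = counts[counts > 0] / n
        hj = 1.0 - float((freqs**2).sum())
        if unbiased_h:
            hj *= n / (n - 1)
        h[j] = hj
    V_E = float((h * (1.0 - h)).sum())
    if V_E <= 0.0:
        raise ValueError("V_E = 0 (all loci monomorphic): I_A undefined")
    return V_O, V_E, V_O / V_E - 1.0


def index_of_association(
    pop: PopulationDataset, denominator: str = "n", unbiased_h: bool = False
) -> IaResult:
    """I_A = V_O / V_E - 1 for a clone-corrected population (statistic only)."""
    matrix = _retained_matrix(pop)
    V_O, V_E, ia = _ia_from_matrix(matrix, denominator, unbiased_h)
    return IaResult(
        species=pop.species, site=pop.site, n_mlh=matrix.shape[0],
        V_O=V_O, V_E=V_E, I_A=ia,
    )


def permutation_test_ia(
    pop: PopulationDataset,
    n_perm: int = 999,
    seed: int | None = None,
    denominator: str = "n",
    unbiased_h: bool = False,
) -> IaResult:
    """Permutation test of I_A against the linkage-equilibrium null.

    Each replicate independently shuffles the allele column of every locus
    among isolates, leaving allele frequencies (hence V_E) untouched, and
    recomputes I_A.  The p-value is (1 + #{I_A_perm >= I_A_obs}) /
    (n_perm + 1); a fixed seed gives identical results regardless of
    execution order.  ``n_perm = 0`` returns the statistic only.
    """
    if 0 < n_perm < 99:
        warnings.warn("n_perm < 99 is underpowered for a permutation test")
    matrix = _retained_matrix(pop)
    V_O, V_E, ia = _ia_from_matrix(matrix, denominator, unbiased_h)
    result = IaResult(
        species=pop.species, site=pop.site, n_mlh=matrix.shape[0],
        V_O=V_O, V_E=V_E, I_A=ia, n_perm=n_perm, seed=seed,
    )
    if n_perm == 0:
        return result
    if seed is None:
        seed = substream_seed(f"{pop.species}/{pop.site}", 0)
        result.seed = seed
    rng = np.random.default_rng(seed)
    # V_E is permutation-invariant, so I_A_perm >= I_A_obs iff V_O_perm >= V_O.
    perm_vo = _batch_permuted_vo(matrix, n_perm, rng, denominator)
    exceed = int((perm_vo >= V_O - 1e-12).sum())
    result.p_perm = (1 + exceed) / (n_perm + 1)
    return result


def _batch_permuted_vo(
    matrix: np.ndarray, n_perm: int, rng: np.random.Generator,
    denominator: str = "n",
) -> np.ndarray:
    """V_O for ``n_perm`` within-locus shuffles, vectorized over replicates.

    Uses the exact decomposition of the mismatch variance into per-locus
    and locus-pair terms: with d_j the fraction of pairs differing at
    locus j (permutation-invariant) and d_jk the fraction differing at
    both j and k,

        E[K]   = sum_j d_j
        E[K^2] = sum_j d_j + 2 sum_{j<k} d_jk,

    and only the joint same-at-both probabilities in d_jk move under a
    within-locus shuffle.  This avoids materializing all pairwise
    comparisons for every replicate.
    """
    n, L = matrix.shape
    n_pairs = n * (n - 1) // 2
    k_sizes = matrix.max(axis=0) + 1

    def _same_prob(counts_sq_sum: np.ndarray) -> np.ndarray:
        return (counts_sq_sum - n) / 2 / n_pairs

    # permutation-invariant per-locus same-pair probabilities
    s = np.empty(L)
    for j in range(L):
        c = np.bincount(matrix[:, j])
        s[j] = _same_prob(np.array((c.astype(np.int64) ** 2).sum()))
    d = 1.0 - s
    mean_K = d.sum()

    perms = np.empty((n_perm, n, L), dtype=np.int64)
    for j in range(L):
        col = np.broadcast_to(matrix[:, j], (n_perm, n))
        perms[:, :, j] = rng.permuted(col, axis=1)

    offsets = np.arange(n_perm, dtype=np.int64)[:, None]
    cross = np.zeros(n_perm)
    for j in range(L):
        for k in range(j + 1, L):
            cells = int(k_sizes[j] * k_sizes[k])
            joint = perms[:, :, j] * k_sizes[k] + perms[:, :, k]
            flat = (joint + offsets * cells).ravel()
            counts = np.bincount(flat, minlength=n_perm * cells).reshape(n_perm, cells)
            s_jk = _same_prob((counts.astype(np.int64) ** 2).sum(axis=1))
            cross += 1.0 - s[j] - s[k] + s_jk
    e_k2 = mean_K + 2.0 * cross
    vo = e_k2 - mean_K**2
    if denominator != "n":
        vo = vo * n_pairs / (n_pairs - 1)
    return vo
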