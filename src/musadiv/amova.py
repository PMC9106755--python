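"""One-level AMOVA with permutation-tested Phi_ST and population diversity.

The analysis partitions the total squared genetic distance among genotypes
into among- and within-population variance components. For dominant band
data the squared distance between two genotypes is the band-mismatch count
(squared Euclidean distance on 0/1 vectors). With N genotypes in k
populations of sizes n_p:

    SS_total  = (1/N)  sum_{i<j} d2(i, j)
    SS_within = sum_p (1/n_p) sum_{i<j in p} d2(i, j)
    SS_among  = SS_total - SS_within
    df_among = k - 1, df_within = N - k, MS = SS/df
    n0 = (N - sum_p n_p**2 / N) / (k - 1)
    sigma2_w = MS_within,  sigma2_a = (MS_among - MS_within) / n0
    Phi_ST = sigma2_a / (sigma2_a + sigma2_w)

Significance comes from shuffling whole genotypes across population labels;
the p-value uses the add-one estimator (1 + #{perm Phi >= observed}) /
(1 + n_perm), so p is never exactly zero. A negative sigma2_a (MS_among <
MS_within) is reported as-is, with Phi possibly below zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from musadiv.io_formats import BandMatrix, PopulationMap


def squared_distance_matrix(matrix: BandMatrix) -> np.ndarray:
    """Pairwise band-mismatch counts over jointly scored loci."""
    if matrix.n_genotypes < 2:
        raise ValueError("need >= 2 genotypes")
    X = matrix.values
    n = matrix.n_genotypes
    D2 = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            keep = ~(np.isnan(X[i]) | np.isnan(X[j]))
            if not keep.any():
                raise ValueError(
                    f"genotypes {matrix.genotype_ids[i]!r} and "
                    f"{matrix.genotype_ids[j]!r} share no scored locus"
                )
            d = float(np.sum(X[i, keep] != X[j, keep]))
            D2[i, j] = D2[j, i] = d
    return D2


@dataclass
class AmovaResult:
    df_among: int
    df_within: int
    df_total: int
    SS_among: float
    SS_within: float
    SS_total: float
    MS_among: float
    MS_within: float
    n0: float
    var_among: float
    var_within: float
    percent_among: float
    percent_within: float
    phi_st: float
    p_value: float
    n_permutations: int
    degenerate: bool = False  # True when total variance is zero


def phi_from_components(var_among: float, var_within: float) -> float:
    """Phi_ST from already-estimated variance components."""
    total = var_among + var_within
    if total == 0:
        raise ValueError("total variance is zero; Phi undefined")
    return var_among / total


def _ss_partition(D2: np.ndarray, groups: list[np.ndarray], N: int):
    ss_total = float(D2[np.triu_indices(N, k=1)].sum()) / N
    ss_within = 0.0
    for idx in groups:
        n_p = len(idx)
        sub = D2[np.ix_(idx, idx)]
        ss_within += float(sub.sum()) / 2.0 / n_p
    return ss_total, ss_within, ss_total - ss_within


def _phi_of_labels(D2: np.ndarray, codes: np.ndarray, k: int, N: int, n0: float):
    groups = [np.flatnonzero(codes == c) for c in range(k)]
    _, ss_within, ss_among = _ss_partition(D2, groups, N)
    ms_among = ss_among / (k - 1)
    ms_within = ss_within / (N - k)
    var_a = (ms_among - ms_within) / n0
    var_w = ms_within
    total = var_a + var_w
    return var_a / total if total != 0 else 0.0


def amova(
    D2: np.ndarray,
    populations: Sequence[str] | PopulationMap,
    n_perm: int = 999,
    seed: int | None = 0,
    genotype_ids: Sequence[str] | None = None,
) -> AmovaResult:
    """One-level AMOVA on a squared-distance matrix.

    ``populations`` is either a label per matrix row or a
    :class:`PopulationMap` (then ``genotype_ids`` gives the row order).
    ``n_perm`` label permutations (>= 99, or 0 to skip the test).
    """
    D2 = np.asarray(D2, dtype=float)
    N = D2.shape[0]
    if isinstance(populations, PopulationMap):
        if genotype_ids is None:
            raise ValueError("genotype_ids required with a PopulationMap")
        labels = [populations.population_of(g) for g in genotype_ids]
    else:
        labels = list(populations)
    if len(labels) != N:
        raise ValueError("one population label per matrix row required")
    if n_perm != 0 and n_perm < 99:
        raise ValueError("n_perm must be >= 99 (or 0 to skip)")
    pop_order = sorted(set(labels))
    k = len(pop_order)
    if k < 2:
        raise ValueError("need >= 2 populations")
    codes = np.array([pop_order.index(l) for l in labels])
    sizes = np.bincount(codes, minlength=k)
    if (sizes == 0).any():
        raise ValueError("a population has no members")

    groups = [np.flatnonzero(codes == c) for c in range(k)]
    ss_total, ss_within, ss_among = _ss_partition(D2, groups, N)
    df_among, df_within = k - 1, N - k
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    n0 = (N - float((sizes**2).sum()) / N) / (k - 1)
    var_w = ms_within
    var_a = (ms_among - ms_within) / n0
    total_var = var_a + var_w
    degenerate = total_var == 0
    if degenerate:
        warnings.warn(
            "total molecular variance is zero; Phi_ST reported as 0",
            stacklevel=2,
        )
        phi = 0.0
        pct_a = pct_w = 0.0
    else:
        phi = var_a / total_var
        pct_a = 100.0 * var_a / total_var
        pct_w = 100.0 * var_w / total_var

    p_value = float("nan")
    if n_perm and not degenerate:
        rng = np.random.default_rng(seed)
        ge = 0
        for _ in range(n_perm):
            perm = rng.permutation(codes)
            if _phi_of_labels(D2, perm, k, N, n0) >= phi:
                ge += 1
        p_value = (1 + ge) / (1 + n_perm)

    return AmovaResult(
        df_among=df_among,
        df_within=df_within,
        df_total=N - 1,
        SS_among=ss_among,
        SS_within=ss_within,
        SS_total=ss_total,
        MS_among=ms_among,
        MS_within=ms_within,
        n0=n0,
        var_among=var_a,
        var_within=var_w,
        percent_among=pct_a,
        percent_within=pct_w,
        phi_st=phi,
        p_value=p_value,
        n_permutations=n_perm if not degenerate else 0,
        degenerate=degenerate,
    )


def pairwise_phist(
    D2: np.ndarray,
    populations: Sequence[str],
    n_perm: int = 0,
    seed: int | None = 0,
):
    """Pairwise Phi_ST between all population pairs.

    Returns ``(pop_order, matrix)``; entries involving a singleton
    population are NaN (undefined).
    """
    labels = list(populations)
    pop_order = sorted(set(labels))
    k = len(pop_order)
    codes = np.array([pop_order.index(l) for l in labels])
    out = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            idx = np.flatnonzero((codes == a) | (codes == b))
            if (codes == a).sum() < 2 or (codes == b).sum() < 2:
                out[a, b] = out[b, a] = np.nan
                continue
            sub = D2[np.ix_(idx, idx)]
            sub_labels = [labels[i] for i in idx]
            res = amova(sub, sub_labels, n_perm=n_perm, seed=seed)
            out[a, b] = out[b, a] = res.phi_st
    return pop_order, out


@dataclass
class PopDiversity:
    population: str
    n: int
    gene_diversity: float
    heterozygosity: float
    unbiased: bool  # False when n = 1 and the n/(n-1) correction was skipped


def population_diversity(
    matrix: BandMatrix,
    pop_map: PopulationMap,
    scheme: str = "diploid_hwe",
    ploidy: int = 2,
) -> list[PopDiversity]:
    """Per-population gene diversity and expected heterozygosity.

    Gene diversity is the locus mean of 1 - sum(p_i**2) over the two inferred
    alleles, with the small-sample factor n/(n-1) applied when n >= 2.
    Heterozygosity for dominant input is the expected value 2pq from the
    within-population dominant allele-frequency estimate.
    """
    pop_map.check_matches(matrix)
    results = []
    for pop in pop_map.populations():
        members = [g for g in matrix.genotype_ids
                   if pop_map.population_of(g) == pop]
        if not members:
            continue
        rows = [matrix.genotype_ids.index(g) for g in members]
        sub_values = matrix.values[rows]
        n = len(members)
        m = 2 if scheme == "diploid_hwe" else ploidy
        if scheme not in ("diploid_hwe", "ploidy_aware"):
            raise ValueError(f"unknown scheme {scheme!r}")
        gd_terms, het_terms = [], []
        for j in range(sub_values.shape[1]):
            col = sub_values[:, j]
            scored = col[~np.isnan(col)]
            if scored.size == 0:
                continue
            p_bar = float(scored.mean())
            q = (1.0 - p_bar) ** (1.0 / m)
            p = 1.0 - q
            h = 1.0 - (p**2 + q**2)
            if n >= 2:
                h *= n / (n - 1)
            gd_terms.append(min(h, 1.0))
            het_terms.append(2.0 * p * q)
        if n < 2:
            warnings.warn(
                f"population {pop!r} has a single member; unbiased "
                f"correction skipped",
                stacklevel=2,
            )
        results.append(
            PopDiversity(
                population=pop,
                n=n,
                gene_diversity=float(np.mean(gd_terms)),
                heterozygosity=float(np.mean(het_terms)),
                unbiased=n >= 2,
            )
        )
    return results
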