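"""Shared-band similarity and UPGMA dendrograms.

Genetic similarity between two fingerprint lanes is the shared-amplification-
product coefficient 2a/(n_a + n_b) (Dice / Nei-Li): a = bands present in both
lanes, n_a and n_b = bands present in each lane, joint absences ignored.
Distances for clustering are 1 - S. UPGMA merges the pair of clusters with the
smallest size-weighted average distance; ties are broken by the
lexicographically smallest pair of member-label tuples so trees are
deterministic regardless of input order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class UndefinedSimilarityError(ValueError):
    """Raised when two lanes share no scored band at all (n_a + n_b = 0)."""


def shared_band_similarity(
    lane_a, lane_b, coefficient: str = "dice"
) -> float:
    """Similarity of two 0/1/missing band vectors.

    Loci missing (nan) in either lane are excluded pairwise. ``coefficient``
    selects ``dice`` (default, joint absences ignored), ``jaccard`` or
    ``simple_matching``.
    """
    a = np.asarray(lane_a, dtype=float)
    b = np.asarray(lane_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("lanes differ in length")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    n11 = float(np.sum((a == 1) & (b == 1)))
    n10 = float(np.sum((a == 1) & (b == 0)))
    n01 = float(np.sum((a == 0) & (b == 1)))
    n00 = float(np.sum((a == 0) & (b == 0)))
    if coefficient == "dice":
        denom = 2 * n11 + n10 + n01
        if denom == 0:
            raise UndefinedSimilarityError(
                "no bands present in either lane after pairwise exclusion"
            )
        return 2 * n11 / denom
    if coefficient == "jaccard":
        denom = n11 + n10 + n01
        if denom == 0:
            raise UndefinedSimilarityError(
                "no bands present in either lane after pairwise exclusion"
            )
        return n11 / denom
    if coefficient == "simple_matching":
        total = n11 + n10 + n01 + n00
        if total == 0:
            raise UndefinedSimilarityError("no jointly scored loci")
        return (n11 + n00) / total
    raise ValueError(f"unknown coefficient {coefficient!r}")


def similarity_matrix(matrix, system: str | None = None,
                      coefficient: str = "dice") -> tuple[list[str], np.ndarray]:
    """Pairwise similarity over all loci (optionally one marker system).

    Returns ``(labels, S)`` with S symmetric, unit diagonal.
    """
    if system is not None:
        matrix = matrix.select_system(system)
    if matrix.n_genotypes < 2:
        raise ValueError("similarity matrix needs >= 2 genotypes")
    n = matrix.n_genotypes
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = shared_band_similarity(
                matrix.values[i], matrix.values[j], coefficient
            )
    return list(matrix.genotype_ids), S


@dataclass
class Dendrogram:
    """Ultrametric UPGMA tree.

    ``merges`` is an (n-1, 4) array of rows (cluster_a, cluster_b, height,
    size): leaves are clusters 0..n-1, the k-th merge creates cluster n+k.
    Heights are cophenetic distances (full, not halved) and nondecrease.
    """

    labels: list[str]
    merges: np.ndarray

    def __post_init__(self) -> None:
        self.merges = np.asarray(self.merges, dtype=float)
        n = len(self.labels)
        if self.merges.shape != (max(n - 1, 0), 4):
            raise ValueError(
                f"expected {n - 1} merges for {n} leaves, got shape "
                f"{self.merges.shape}"
            )
        heights = self.merges[:, 2]
        if len(heights) and ((heights < -1e-12).any()
                             or (np.diff(heights) < -1e-9).any()):
            raise ValueError("merge heights must be nonnegative, nondecreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def cophenetic_matrix(self) -> np.ndarray:
        """Leaf x leaf matrix of merge heights (ultrametric distances)."""
        n = self.n_leaves
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        C = np.zeros((n, n))
        for k, (a, b, h, _) in enumerate(self.merges):
            ma, mb = members.pop(int(a)), members.pop(int(b))
            for i in ma:
                for j in mb:
                    C[i, j] = C[j, i] = h
            members[n + k] = ma + mb
        return C

    def to_scipy_linkage(self) -> np.ndarray:
        """Scipy-convention linkage matrix (same cluster numbering)."""
        return self.merges.copy()


def upgma(D: np.ndarray, labels: list[str]) -> Dendrogram:
    """Average-linkage (UPGMA) clustering of a distance matrix.

    New-cluster distances are size-weighted means of member distances; the
    merge height recorded for a join is the average distance between the two
    clusters (halved per branch only at serialisation time). Tied minimal
    distances are resolved toward the lexicographically smallest pair of
    sorted member-label tuples.
    """
    D = np.asarray(D, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    if (D < -1e-12).any():
        raise ValueError("distance matrix has negative entries")
    if np.abs(np.diag(D)).max() > 1e-12:
        raise ValueError("distance matrix diagonal is not zero")
    if n < 2:
        raise ValueError("need >= 2 items to cluster")

    # active cluster state: id -> (size, sorted member-label tuple)
    size = {i: 1 for i in range(n)}
    key = {i: (labels[i],) for i in range(n)}
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(D[i, j])
    active = set(range(n))
    merges = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best = None
        for (i, j), d in dist.items():
            pair_key = tuple(sorted((key[i], key[j])))
            cand = (d, pair_key, (i, j))
            if best is None or cand[:2] < best[:2]:
                best = cand
        d_min, _, (i, j) = best
        # order merge children by member-label key for determinism
        a, b = (i, j) if key[i] <= key[j] else (j, i)
        merges[step] = (a, b, d_min, size[i] + size[j])
        new_key = tuple(sorted(key[i] + key[j]))
        new_size = size[i] + size[j]
        active.discard(i)
        active.discard(j)
        new_dist = {}
        for k in active:
            dik = dist.pop((min(i, k), max(i, k)))
            djk = dist.pop((min(j, k), max(j, k)))
            new_dist[(k, next_id)] = (size[i] * dik + size[j] * djk) / new_size
        dist.pop((min(i, j), max(i, j)))
        dist.update(new_dist)
        size[next_id] = new_size
        key[next_id] = new_key
        active.add(next_id)
        next_id += 1
    # guard against tiny negative rounding in monotone heights
    for s in range(1, n - 1):
        if merges[s, 2] < merges[s - 1, 2]:
            if merges[s - 1, 2] - merges[s, 2] > 1e-9:
                raise AssertionError("UPGMA produced decreasing merge heights")
            merges[s, 2] = merges[s - 1, 2]
    return Dendrogram(list(labels), merges)


def cut_at_similarity(tree: Dendrogram, s: float) -> list[list[str]]:
    """Partition leaves into groups connected below cophenetic distance 1 - s.

    ``s = 1`` puts every leaf in its own group; ``s = 0`` yields a single
    group whenever the root merge is below distance 1.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError("similarity level must lie in [0, 1]")
    threshold = 1.0 - s
    n = tree.n_leaves
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for k, (a, b, h, _) in enumerate(tree.merges):
        a, b = int(a), int(b)
        if h < threshold and a in members and b in members:
            members[n + k] = members.pop(a) + members.pop(b)
    groups = [
        sorted(tree.labels[i] for i in idxs) for idxs in members.values()
    ]
    return sorted(groups)


def cophenetic_correlation(tree: Dendrogram, D: np.ndarray) -> float:
    """Pearson correlation between cophenetic and input distances."""
    D = np.asarray(D, dtype=float)
    C = tree.cophenetic_matrix()
    iu = np.triu_indices(tree.n_leaves, k=1)
    d, c = D[iu], C[iu]
    if np.allclose(d, d[0]) or np.allclose(c, c[0]):
        raise ValueError("correlation undefined for constant distances")
    return float(stats.pearsonr(d, c).statistic)
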