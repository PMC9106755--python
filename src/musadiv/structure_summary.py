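"""Post-processing of external Bayesian-clustering (STRUCTURE-style) runs.

The number of clusters K is chosen with the Evanno second-difference
statistic on replicate log-probabilities LnP(D):

    L'(K)  = mean LnP(D | K) - mean LnP(D | K-1)
    L''(K) = L'(K+1) - L'(K)
    deltaK = |L''(K)| / sd(LnP(D | K))

Genotypes are assigned to the argmax cluster of their membership (Q) row,
called unassigned when the maximum fraction falls below the membership
threshold C, and split into "pure" versus "admixture" by a separate
purity threshold on the same maximum (the field reports such splits without
stating a rule; the default purity threshold is 0.7 and is configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from musadiv.io_formats import StructureRuns


def evanno_delta_k(runs: StructureRuns) -> pd.DataFrame:
    """Evanno table: per K, mean/sd LnP(D), L'(K), |L''(K)| and deltaK.

    Requires >= 2 replicates at every K, contiguous K values and at least
    four K values (three interior-evaluable points are needed for the second
    difference). ``deltaK`` is NaN at the boundary K values and where the
    replicate sd is zero (flagged, not inferred).
    """
    ks = runs.k_values()
    if len(ks) < 4:
        raise ValueError("need >= 4 contiguous K values for deltaK")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError(f"K values {ks} are not contiguous")
    for k in ks:
        if len(runs.lnpd[k]) < 2:
            raise ValueError(
                f"K = {k} has {len(runs.lnpd[k])} replicate(s); deltaK needs >= 2"
            )
    mean = np.array([np.mean(runs.lnpd[k]) for k in ks])
    sd = np.array([np.std(runs.lnpd[k], ddof=1) for k in ks])
    n = len(ks)
    lprime = np.full(n, np.nan)
    lprime[1:] = np.diff(mean)
    lsecond = np.full(n, np.nan)
    lsecond[1:-1] = np.abs(np.diff(mean, n=2))
    delta_k = np.full(n, np.nan)
    for i in range(1, n - 1):
        if sd[i] > 0:
            delta_k[i] = lsecond[i] / sd[i]
    return pd.DataFrame(
        {
            "K": ks,
            "mean_lnpd": mean,
            "sd_lnpd": sd,
            "lprime": lprime,
            "abs_lsecond": lsecond,
            "delta_k": delta_k,
        }
    )


def optimal_k(table: pd.DataFrame) -> int:
    """argmax of deltaK over the interior K values."""
    if table["delta_k"].isna().all():
        raise ValueError("deltaK undefined at every K")
    return int(table.loc[table["delta_k"].idxmax(), "K"])


@dataclass
class MembershipCall:
    genotype: str
    assigned_cluster: int  # 1-based argmax cluster; 0 when unassigned
    max_q: float
    status: str  # "pure" | "admixture" | "unassigned"


def classify_membership(
    Q: pd.DataFrame,
    C: float = 0.44,
    purity_threshold: float = 0.7,
) -> tuple[list[MembershipCall], pd.DataFrame]:
    """Classify genotypes from a genotype x K membership matrix.

    A genotype is unassigned when its maximum membership fraction is below
    the threshold ``C``; otherwise it belongs to the argmax cluster, as
    "pure" when the maximum reaches ``purity_threshold`` and "admixture"
    below it. Returns the per-genotype calls and a per-cluster tally frame.
    """
    if not 0.0 < C < 1.0:
        raise ValueError("membership threshold C must lie in (0, 1)")
    arr = Q.to_numpy(dtype=float)
    if (arr < 0).any() or np.abs(arr.sum(axis=1) - 1.0).max() > 1e-6:
        bad = Q.index[np.abs(arr.sum(axis=1) - 1.0).argmax()]
        raise ValueError(f"malformed Q row for genotype {bad!r}")
    calls = []
    for g, row in zip(Q.index, arr):
        max_q = float(row.max())
        cluster = int(row.argmax()) + 1
        if max_q < C:
            calls.append(MembershipCall(str(g), 0, max_q, "unassigned"))
        elif max_q >= purity_threshold:
            calls.append(MembershipCall(str(g), cluster, max_q, "pure"))
        else:
            calls.append(MembershipCall(str(g), cluster, max_q, "admixture"))
    k = arr.shape[1]
    tallies = pd.DataFrame(
        0,
        index=pd.Index(range(1, k + 1), name="cluster"),
        columns=["pure", "admixture", "total"],
    )
    for call in calls:
        if call.assigned_cluster:
            tallies.loc[call.assigned_cluster, call.status] += 1
            tallies.loc[call.assigned_cluster, "total"] += 1
    return calls, tallies
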