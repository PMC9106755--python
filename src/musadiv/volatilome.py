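"""GC-MS volatile-table analytics.

Covers Kovats retention-index calibration against an n-alkane ladder
(C8-C20), retention-index tolerance matching, chemical-class composition
with per-cultivar breakdowns, and presence/absence clustering of cultivars
(Dice similarity + UPGMA, shared with the fingerprint machinery).

Under a linear temperature programme the Kovats index of a peak eluting at
retention time t between the C_n and C_{n+1} alkanes is

    RI = 100 n + 100 (t - t_n) / (t_{n+1} - t_n)

so every alkane anchors exactly at 100 times its carbon number.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import NamedTuple

import numpy as np
import pandas as pd

from musadiv.io_formats import (
    AlkaneLadder,
    CHEMICAL_CLASSES,
    VolatileTable,
    read_volatile_table,
)
from musadiv.similarity import Dendrogram, shared_band_similarity, upgma

#: Default RI matching tolerance, in index units — typical working width for
#: semi-standard non-polar (5% phenyl) columns.
DEFAULT_RI_TOLERANCE = 15.0


def kovats_ri(rt: float, ladder: AlkaneLadder) -> float:
    """Kovats retention index by linear interpolation on the alkane ladder."""
    lo, hi = ladder.span
    if not lo <= rt <= hi:
        raise ValueError(
            f"retention time {rt} min outside ladder span ({lo}, {hi})"
        )
    return float(
        100.0 * np.interp(rt, ladder.retention_times, ladder.carbons)
    )


class RiMatch(NamedTuple):
    match: bool
    delta: float  # signed experimental - reference


def match_compound(
    experimental_ri: float,
    reference_ri: float,
    tolerance: float = DEFAULT_RI_TOLERANCE,
) -> RiMatch:
    """Compare an experimental RI against a library value."""
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    delta = experimental_ri - reference_ri
    return RiMatch(abs(delta) <= tolerance, delta)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class ClassComposition:
    class_counts: pd.Series          # compounds per chemical class
    percent: pd.Series               # unrounded, sums to exactly 100
    percent_rounded: pd.Series       # half-up integers for reporting
    per_cultivar: pd.DataFrame       # class x cultivar presence counts
    total_compounds: int


def class_composition(table: VolatileTable) -> ClassComposition:
    """Chemical-class composition, overall and per cultivar.

    Percentages are counts over the total compound number; the rounded
    column uses half-up rounding to integers (so 30/54 reports as 56).
    """
    classes = [
        c for c in CHEMICAL_CLASSES if (table.data["chemical_class"] == c).any()
    ]
    counts = pd.Series(
        [int((table.data["chemical_class"] == c).sum()) for c in classes],
        index=classes,
        name="count",
    )
    total = int(counts.sum())
    percent = 100.0 * counts / total
    rounded = percent.map(_round_half_up)
    pres = table.presence()
    per_cultivar = pd.DataFrame(
        {
            cult: [
                int(pres.loc[table.data["chemical_class"] == c, cult].sum())
                for c in classes
            ]
            for cult in table.cultivars
        },
        index=classes,
    )
    return ClassComposition(
        class_counts=counts,
        percent=percent,
        percent_rounded=rounded,
        per_cultivar=per_cultivar,
        total_compounds=total,
    )


def cultivar_counts(table: VolatileTable) -> pd.DataFrame:
    """Per-cultivar compound totals with the per-class breakdown.

    Returns a class x cultivar frame with a final ``Total`` row equal to the
    column sums of the presence matrix.
    """
    comp = class_composition(table)
    out = comp.per_cultivar.copy()
    out.loc["Total"] = table.presence().sum(axis=0)
    return out


def cultivar_ester_share(table: VolatileTable, cultivar: str) -> int:
    """Half-up integer percentage of a cultivar's compounds that are esters."""
    counts = cultivar_counts(table)
    if cultivar not in counts.columns:
        raise ValueError(f"unknown cultivar {cultivar!r}")
    total = int(counts.loc["Total", cultivar])
    if total == 0:
        raise ValueError(f"cultivar {cultivar!r} has no compounds")
    esters = int(counts.loc["ester", cultivar]) if "ester" in counts.index else 0
    return _round_half_up(100.0 * esters / total)


def cultivar_volatile_clustering(table: VolatileTable) -> Dendrogram:
    """UPGMA dendrogram of cultivars from compound presence/absence.

    The cultivar x compound 0/1 matrix feeds the shared-band (Dice)
    similarity; clustering runs on distance 1 - S.
    """
    cults = table.cultivars
    if len(cults) < 2:
        raise ValueError("need >= 2 cultivars to cluster")
    P = table.presence().to_numpy().T.astype(float)
    from musadiv.similarity import UndefinedSimilarityError

    empty = [c for c, row in zip(cults, P) if row.sum() == 0]
    if empty:
        raise UndefinedSimilarityError(
            f"cultivar(s) with zero compounds: {empty}"
        )
    n = len(cults)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = 1.0 - shared_band_similarity(P[i], P[j])
    return upgma(D, list(cults))


def packaged_volatile_table() -> VolatileTable:
    """The packaged nine-cultivar, 54-compound reference volatile table."""
    ref = resources.files("musadiv") / "fixtures" / "table10_volatiles.csv"
    with resources.as_file(ref) as path:
        return read_volatile_table(path)
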