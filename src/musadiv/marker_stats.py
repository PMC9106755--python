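"""Per-locus allele frequencies and per-primer informativeness statistics.

Dominant bands (RAPD/ISSR, and SSRs scored as bands) carry a presence allele
with frequency p and a null allele with frequency q = 1 - p. Under random
union of m allele copies the band-absence frequency is q**m, so q is
estimated as the m-th root of (1 - band frequency): m = 2 under the default
diploid Hardy-Weinberg scheme, or the panel ploidy under the ploidy-aware
scheme. Locus diversity follows the two-allele formulas

    Ne = 1/(p**2 + q**2)          effective allele number
    I  = -(p ln p + q ln q)       Shannon information index
    He = 2 p q                    expected heterozygosity
    uHe = 2N/(2N - 1) * He        unbiased expected heterozygosity

and primer informativeness uses

    PIC = 2 pbar (1 - pbar)                       (dominant convention)
    RP  = sum over bands of 1 - 2|0.5 - pbar|     (resolving power)
    MI  = mean PIC * EMR,  EMR = n_poly * (n_poly / n_loci)
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from musadiv.io_formats import BandMatrix, LocusId


@dataclass
class AlleleFreqs:
    locus: LocusId
    band_freq: float      # observed fraction of lanes showing the band
    p: float              # presence-allele frequency
    q: float              # null-allele frequency
    n_scored: int


def estimate_allele_freqs(
    matrix: BandMatrix,
    locus: LocusId,
    scheme: str = "diploid_hwe",
    ploidy: int = 2,
) -> AlleleFreqs:
    """Estimate presence/null allele frequencies at one dominant locus.

    ``scheme`` is ``diploid_hwe`` (m = 2) or ``ploidy_aware`` (m = ``ploidy``).
    Missing cells are excluded locus-wise.
    """
    try:
        j = matrix.loci.index(locus)
    except ValueError:
        raise ValueError(f"locus {locus!r} not in matrix") from None
    col = matrix.values[:, j]
    scored = col[~np.isnan(col)]
    if scored.size == 0:
        raise ValueError(f"all cells missing at locus {locus.encode()!r}")
    if scheme == "diploid_hwe":
        m = 2
    elif scheme == "ploidy_aware":
        if ploidy < 1:
            raise ValueError("ploidy must be >= 1")
        m = ploidy
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    p_bar = float(scored.mean())
    q = (1.0 - p_bar) ** (1.0 / m)
    return AlleleFreqs(locus, p_bar, 1.0 - q, q, int(scored.size))


def locus_diversity(freqs: AlleleFreqs, N: int | None = None):
    """(Na, Ne, I, He, uHe) for a two-allele locus.

    ``N`` defaults to the number of scored genotypes in ``freqs``.
    """
    if N is None:
        N = freqs.n_scored
    if N < 1:
        raise ValueError("N must be >= 1")
    p, q = freqs.p, freqs.q
    if abs(p + q - 1.0) > 1e-9:
        raise ValueError("allele frequencies must sum to 1")
    Na = int(p > 0) + int(q > 0)
    Ne = 1.0 / (p * p + q * q)
    I = -sum(x * math.log(x) for x in (p, q) if x > 0)
    He = 2.0 * p * q
    uHe = (2.0 * N) / (2.0 * N - 1.0) * He
    return Na, Ne, I, He, uHe


def pic_dominant(p_bar: float) -> float:
    """Polymorphic information content of a dominant band, 2 pbar (1 - pbar)."""
    if not 0.0 <= p_bar <= 1.0:
        raise ValueError("band frequency must lie in [0, 1]")
    return 2.0 * p_bar * (1.0 - p_bar)


def pic_gene_diversity(p: float, q: float) -> float:
    """Alternative PIC convention 1 - sum p_i**2 on the allele frequencies."""
    return 1.0 - (p * p + q * q)


_STAT_FIELDS = (
    "percent_polymorphism",
    "avg_polymorphic_bands_per_genotype",
    "total_loci",
    "PIC",
    "Na",
    "Ne",
    "I",
    "He",
    "uHe",
    "RP",
    "MI",
)


@dataclass
class PrimerStats:
    """One summary row per primer (amplicon counts plus locus-mean statistics)."""

    primer_name: str
    total_amplicons: int
    polymorphic_amplicons: int
    percent_polymorphism: float
    avg_polymorphic_bands_per_genotype: float
    total_loci: int
    PIC: float = math.nan
    Na: float = math.nan
    Ne: float = math.nan
    I: float = math.nan
    He: float = math.nan
    uHe: float = math.nan
    RP: float = math.nan
    MI: float = math.nan

    def __post_init__(self) -> None:
        if self.polymorphic_amplicons > self.total_amplicons:
            raise ValueError(
                f"{self.primer_name}: polymorphic amplicons exceed total"
            )
        if not 0.0 <= self.percent_polymorphism <= 100.0:
            raise ValueError(
                f"{self.primer_name}: percent polymorphism outside [0, 100]"
            )

    @classmethod
    def from_counts(
        cls,
        primer_name: str,
        polymorphic_amplicons: int,
        total_amplicons: int,
        n_genotypes: int,
        total_loci: int = 0,
    ) -> "PrimerStats":
        """Build a counts-only row (diversity fields NaN), e.g. from a
        published polymorphism table."""
        percent = (
            100.0 * polymorphic_amplicons / total_amplicons
            if total_amplicons
            else 0.0
        )
        return cls(
            primer_name,
            total_amplicons,
            polymorphic_amplicons,
            percent,
            polymorphic_amplicons / n_genotypes if n_genotypes else math.nan,
            total_loci,
        )


def primer_summary(
    matrix: BandMatrix,
    primer_name: str,
    n_genotypes: int | None = None,
    scheme: str = "diploid_hwe",
    ploidy: int = 2,
    pic_method: str = "dominant",
) -> PrimerStats:
    """Summarise one primer: amplicon counts plus locus-averaged diversity.

    A locus is polymorphic iff its scored cells contain both 0 and 1;
    total amplicons = number of 1-cells over the primer's loci, polymorphic
    amplicons = 1-cells restricted to polymorphic loci.
    """
    sub = matrix.select_primer(primer_name)
    if n_genotypes is None:
        n_genotypes = sub.n_genotypes
    total = 0
    poly_amp = 0
    n_poly = 0
    pics, nas, nes, Is, hes, uhes, ibs = [], [], [], [], [], [], []
    for j, locus in enumerate(sub.loci):
        col = sub.values[:, j]
        scored = col[~np.isnan(col)]
        ones = int((scored == 1).sum())
        total += ones
        polymorphic = (scored == 1).any() and (scored == 0).any()
        if polymorphic:
            poly_amp += ones
            n_poly += 1
        freqs = estimate_allele_freqs(matrix, locus, scheme, ploidy)
        Na, Ne, I, He, uHe = locus_diversity(freqs)
        if pic_method == "dominant":
            pics.append(pic_dominant(freqs.band_freq))
        elif pic_method == "gene_diversity":
            pics.append(pic_gene_diversity(freqs.p, freqs.q))
        else:
            raise ValueError(f"unknown pic_method {pic_method!r}")
        nas.append(Na)
        nes.append(Ne)
        Is.append(I)
        hes.append(He)
        uhes.append(uHe)
        ibs.append(1.0 - 2.0 * abs(0.5 - freqs.band_freq))
    if total == 0:
        warnings.warn(
            f"primer {primer_name!r} has no amplicons; polymorphism % "
            f"reported as 0",
            stacklevel=2,
        )
        percent = 0.0
    else:
        percent = 100.0 * poly_amp / total
    n_loci = sub.n_loci
    mean_pic = float(np.mean(pics))
    emr = n_poly * (n_poly / n_loci)
    return PrimerStats(
        primer_name=primer_name,
        total_amplicons=total,
        polymorphic_amplicons=poly_amp,
        percent_polymorphism=percent,
        avg_polymorphic_bands_per_genotype=poly_amp / n_genotypes,
        total_loci=n_loci,
        PIC=mean_pic,
        Na=float(np.mean(nas)),
        Ne=float(np.mean(nes)),
        I=float(np.mean(Is)),
        He=float(np.mean(hes)),
        uHe=float(np.mean(uhes)),
        RP=float(np.sum(ibs)),
        MI=mean_pic * emr,
    )


def panel_summary(stats: list[PrimerStats]) -> PrimerStats:
    """Arithmetic mean row across primers (typically one marker system).

    The polymorphism mean is the mean of the per-primer percentages (each
    recomputed from its own counts), not the pooled ratio.
    """
    if not stats:
        raise ValueError("no primer statistics to summarise")
    percents = [
        100.0 * s.polymorphic_amplicons / s.total_amplicons
        if s.total_amplicons
        else 0.0
        for s in stats
    ]
    mean_row = PrimerStats(
        primer_name="Mean",
        total_amplicons=float(np.mean([s.total_amplicons for s in stats])),
        polymorphic_amplicons=float(
            np.mean([s.polymorphic_amplicons for s in stats])
        ),
        percent_polymorphism=float(np.mean(percents)),
        avg_polymorphic_bands_per_genotype=float(
            np.mean([s.avg_polymorphic_bands_per_genotype for s in stats])
        ),
        total_loci=0,
    )
    # float means for the remaining fields (NaN-tolerant only if all NaN)
    for name in ("PIC", "Na", "Ne", "I", "He", "uHe", "RP", "MI"):
        setattr(mean_row, name, float(np.mean([getattr(s, name) for s in stats])))
    mean_row.total_loci = float(np.mean([s.total_loci for s in stats]))
    return mean_row


def mean_amplicon_ratio(stats: list[PrimerStats]) -> tuple[float, float]:
    """Mean polymorphic and total amplicon counts across primers."""
    if not stats:
        raise ValueError("no primer statistics")
    return (
        float(np.mean([s.polymorphic_amplicons for s in stats])),
        float(np.mean([s.total_amplicons for s in stats])),
    )


def system_summary_table(
    matrix: BandMatrix,
    system: str,
    scheme: str = "diploid_hwe",
    ploidy: int = 2,
    pic_method: str = "dominant",
):
    """Per-primer statistics rows plus a mean row for one marker system."""
    import pandas as pd

    sub = matrix.select_system(system)
    rows = [
        primer_summary(sub, primer, matrix.n_genotypes, scheme, ploidy, pic_method)
        for primer in sub.primers()
    ]
    mean_row = panel_summary(rows)
    records = []
    for s in rows + [mean_row]:
        records.append(
            {
                "primer": s.primer_name,
                "polymorphic_amplicons": s.polymorphic_amplicons,
                "total_amplicons": s.total_amplicons,
                "percent_polymorphism": s.percent_polymorphism,
                "avg_polymorphic_bands_per_genotype":
                    s.avg_polymorphic_bands_per_genotype,
                "total_loci": s.total_loci,
                "PIC": s.PIC,
                "Na": s.Na,
                "Ne": s.Ne,
                "I": s.I,
                "He": s.He,
                "uHe": s.uHe,
                "RP": s.RP,
                "MI": s.MI,
            }
        )
    return pd.DataFrame.from_records(records)
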