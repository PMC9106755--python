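"""Seeded generators for fingerprint matrices, clustering-run summaries and
volatile tables.

The band simulator uses the Balding-Nichols model: each locus draws an
ancestral band-allele frequency p0 ~ Uniform(0.1, 0.9), each population k
draws its own frequency

    p_k ~ Beta(p0 (1-F)/F, (1-p0) (1-F)/F)      (p_k = p0 when F = 0)

so E[p_k] = p0 and Var[p_k] = F p0 (1-p0); F is the target fixation index.
A genotype of ploidy m shows the (dominant) band with probability
1 - (1-p_k)**m, i.e. when at least one of its m allele copies carries the
band allele — this is what makes mixed-ploidy panels (2x-4x) exercisable.

Defaults mirror the study panel the package is aimed at: 20 genotypes in
4 subpopulations, genome groups cycling through AA/AB/AAA/AAB/ABB/AAAB,
34 primers (11 RAPD with 75 loci, 11 ISSR with 69 loci, 12 SSR with 24
loci), and differentiation F = 0.23. All draws flow from a single
numpy Generator so a run is fully replayable from one seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from musadiv.io_formats import (
    AlkaneLadder,
    BandMatrix,
    CHEMICAL_CLASSES,
    LocusId,
    PopRecord,
    PopulationMap,
    StructureRuns,
    VolatileTable,
)

#: (name, system, n_loci) for the default 34-primer panel. RAPD and ISSR
#: locus counts follow the published per-primer panel (75 and 69 loci);
#: SSR counts are a plausible split of the panel's 24 SSR loci.
DEFAULT_PRIMERS: list[tuple[str, str, int]] = [
    ("OPC-08", "RAPD", 6), ("OPA-10", "RAPD", 7), ("OPA-11", "RAPD", 5),
    ("OPA-12", "RAPD", 6), ("OPA-13", "RAPD", 8), ("OPA-17", "RAPD", 7),
    ("OPA-18", "RAPD", 5), ("OPD-15", "RAPD", 5), ("OPD-20", "RAPD", 8),
    ("OPD-18", "RAPD", 10), ("OPN-02", "RAPD", 8),
    ("ISSR-815", "ISSR", 8), ("ISSR-818", "ISSR", 8), ("ISSR-822", "ISSR", 7),
    ("ISSR-827", "ISSR", 7), ("ISSR-825", "ISSR", 5), ("ISSR-841", "ISSR", 6),
    ("ISSR-857", "ISSR", 6), ("UBC-810", "ISSR", 9), ("UBC-820", "ISSR", 5),
    ("UBC-826", "ISSR", 5), ("UBC-858", "ISSR", 3),
    ("AGMI93-94", "SSR", 2), ("Ma-1-16", "SSR", 2), ("Ma-3-2", "SSR", 1),
    ("Ma-3-103", "SSR", 2), ("CNPMF-4", "SSR", 2), ("CNPMF-8", "SSR", 3),
    ("CNPMF-9", "SSR", 3), ("CNPMF-10", "SSR", 2), ("CNPMF-12", "SSR", 1),
    ("CNPMF-13", "SSR", 4), ("CNPMF-16", "SSR", 1), ("CNPMF-19", "SSR", 1),
]

_GENOME_CYCLE = ("AA", "AB", "AAA", "AAB", "ABB", "AAAB")

DEFAULT_FST = 0.23
DEFAULT_SIZES = (5, 5, 5, 5)


@dataclass
class SimulationTruth:
    """Ground truth behind a simulated band matrix (for parameter recovery)."""

    seed: int
    n_populations: int
    sizes: list[int]
    target_fst: float
    p0: np.ndarray                  # ancestral frequency per locus
    p_k: np.ndarray                 # population x locus band-allele frequency
    assignment: dict[str, str]      # genotype -> population label
    ploidy: dict[str, int]
    genome_group: dict[str, str] = field(default_factory=dict)

    def to_population_map(self) -> PopulationMap:
        records = {
            g: PopRecord(
                self.assignment[g],
                self.genome_group.get(g, "A" * self.ploidy[g]),
                self.ploidy[g],
            )
            for g in self.assignment
        }
        return PopulationMap(records)

    def expected_band_freq(self) -> np.ndarray:
        """Population x locus expected band presence 1 - (1-p_k)**m.

        Uses each population's mean ploidy (panels may mix ploidies).
        """
        pops = sorted(set(self.assignment.values()))
        out = np.zeros_like(self.p_k)
        for i, pop in enumerate(pops):
            ms = [self.ploidy[g] for g, p in self.assignment.items() if p == pop]
            m = float(np.mean(ms))
            out[i] = 1.0 - (1.0 - self.p_k[i]) ** m
        return out

    def to_json(self, target=None) -> str:
        payload = {
            "seed": self.seed,
            "n_populations": self.n_populations,
            "sizes": self.sizes,
            "target_fst": self.target_fst,
            "p0": self.p0.tolist(),
            "p_k": self.p_k.tolist(),
            "assignment": self.assignment,
            "ploidy": self.ploidy,
            "genome_group": self.genome_group,
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if target is not None:
            with open(target, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text


def simulate_structured_bands(
    n_pops: int = 4,
    sizes: tuple[int, ...] | None = None,
    primers: list[tuple[str, str, int]] | None = None,
    F: float = DEFAULT_FST,
    ploidy_map: dict[str, int] | None = None,
    seed: int = 0,
    missing_rate: float = 0.0,
) -> tuple[BandMatrix, SimulationTruth]:
    """Simulate a dominant band matrix under the Balding-Nichols model."""
    if sizes is None:
        sizes = DEFAULT_SIZES[:n_pops] if n_pops <= 4 else (5,) * n_pops
    sizes = tuple(int(s) for s in sizes)
    if len(sizes) != n_pops:
        raise ValueError(f"{n_pops} populations but {len(sizes)} sizes")
    if any(s < 2 for s in sizes):
        raise ValueError("every population size must be >= 2")
    if not 0.0 <= F < 0.95:
        raise ValueError("F must lie in [0, 0.95) (Beta parameters degenerate)")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must lie in [0, 1)")
    if primers is None:
        primers = DEFAULT_PRIMERS
    if any(n < 1 for _, _, n in primers):
        raise ValueError("each primer needs >= 1 locus")
    rng = np.random.default_rng(seed)

    loci: list[LocusId] = []
    for name, system, n_loci in primers:
        for b in range(n_loci):
            loci.append(LocusId(name, system, f"b{b + 1}"))
    L = len(loci)
    n_total = sum(sizes)
    genotypes = [f"G{i + 1:02d}" for i in range(n_total)]
    pop_labels = [f"SP{k + 1}" for k in range(n_pops)]
    assignment: dict[str, str] = {}
    genome: dict[str, str] = {}
    ploidy: dict[str, int] = {}
    i = 0
    for k, s in enumerate(sizes):
        for _ in range(s):
            g = genotypes[i]
            assignment[g] = pop_labels[k]
            if ploidy_map is not None:
                ploidy[g] = int(ploidy_map[g])
                genome[g] = "A" * ploidy[g]
            else:
                genome[g] = _GENOME_CYCLE[i % len(_GENOME_CYCLE)]
                ploidy[g] = len(genome[g])
            i += 1

    p0 = rng.uniform(0.1, 0.9, size=L)
    if F == 0.0:
        p_k = np.tile(p0, (n_pops, 1))
    else:
        a = p0 * (1.0 - F) / F
        b = (1.0 - p0) * (1.0 - F) / F
        p_k = rng.beta(np.tile(a, (n_pops, 1)), np.tile(b, (n_pops, 1)))

    values = np.zeros((n_total, L))
    for idx, g in enumerate(genotypes):
        k = pop_labels.index(assignment[g])
        m = ploidy[g]
        present_prob = 1.0 - (1.0 - p_k[k]) ** m
        values[idx] = (rng.random(L) < present_prob).astype(float)
    if missing_rate > 0:
        mask = rng.random(values.shape) < missing_rate
        # never blank out a whole locus
        for j in range(L):
            if mask[:, j].all():
                mask[rng.integers(n_total), j] = False
        values[mask] = np.nan

    matrix = BandMatrix(genotypes, loci, values)
    truth = SimulationTruth(
        seed=seed,
        n_populations=n_pops,
        sizes=list(sizes),
        target_fst=F,
        p0=p0,
        p_k=p_k,
        assignment=assignment,
        ploidy=ploidy,
        genome_group=genome,
    )
    return matrix, truth


def simulate_structure_runs(
    true_assignment: dict[str, str] | int,
    K_range: range | tuple[int, int] = (1, 10),
    seed: int = 0,
    n_replicates: int = 5,
    noise_sd: float = 0.5,
    lnpd_at_k1: float = -4000.0,
    gain_before: float = 120.0,
    gain_after: float = 8.0,
) -> StructureRuns:
    """Simulate replicate LnP(D) traces with a curvature kink at the true K.

    The mean curve rises steeply (``gain_before`` per K) until the true K and
    shallowly (``gain_after``) beyond it, so the steepest second difference —
    hence the Evanno deltaK peak — sits at the true K. Replicates add
    Normal(0, ``noise_sd``) noise.
    """
    if isinstance(true_assignment, dict):
        true_k = len(set(true_assignment.values()))
    else:
        true_k = int(true_assignment)
    if isinstance(K_range, range):
        ks = list(K_range)
    else:
        lo, hi = K_range
        ks = list(range(lo, hi + 1))
    if len(ks) < 4:
        raise ValueError("K_range must cover >= 4 contiguous values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("K_range must be contiguous")
    if n_replicates < 2:
        raise ValueError("deltaK needs >= 2 replicates per K")
    if not ks[0] < true_k < ks[-1]:
        raise ValueError(
            f"true K = {true_k} must be interior to K range {ks[0]}..{ks[-1]}"
        )
    rng = np.random.default_rng(seed)
    lnpd: dict[int, list[float]] = {}
    for k in ks:
        mean = (
            lnpd_at_k1
            + gain_before * (min(k, true_k) - ks[0])
            + gain_after * max(k - true_k, 0)
        )
        lnpd[k] = [
            float(mean + rng.normal(0.0, noise_sd)) for _ in range(n_replicates)
        ]
    return StructureRuns(lnpd)


#: Class sizes of the reference volatile table (54 compounds, esters ~56%).
DEFAULT_CLASS_COUNTS: dict[str, int] = {
    "ester": 30,
    "aromatic aldehyde": 2,
    "alcohol": 7,
    "hydrocarbon": 3,
    "ketone": 2,
    "ether": 3,
    "carboxylic acid": 1,
    "diverse functional group": 5,
    "chlorine-containing": 1,
}

DEFAULT_CULTIVARS = tuple(f"CV{i + 1}" for i in range(9))


def simulate_volatile_table(
    cultivars: tuple[str, ...] = DEFAULT_CULTIVARS,
    class_counts: dict[str, int] | None = None,
    presence_prob: float | dict[str, float] = 0.33,
    rt_range: tuple[float, float] = (4.5, 58.5),
    seed: int = 0,
    ladder: AlkaneLadder | None = None,
    ri_noise_sd: float = 5.0,
) -> tuple[VolatileTable, AlkaneLadder]:
    """Simulate a GC-MS volatile table plus its n-alkane calibration ladder.

    Retention times are uniform in ``rt_range`` and sorted; experimental
    retention indices are computed from the (monotone) ladder, and reference
    indices add Normal(0, ``ri_noise_sd``) calibration scatter. Presence per
    cultivar is Bernoulli(``presence_prob``); every compound is forced to be
    present in at least one cultivar so similarities stay defined.
    """
    from musadiv.volatilome import kovats_ri

    if class_counts is None:
        class_counts = DEFAULT_CLASS_COUNTS
    unknown = set(class_counts) - set(CHEMICAL_CLASSES)
    if unknown:
        raise ValueError(f"unknown chemical class(es) {sorted(unknown)}")
    total = sum(class_counts.values())
    if total < 1:
        raise ValueError("class counts must sum to >= 1")
    if isinstance(presence_prob, dict):
        probs = {c: float(presence_prob[c]) for c in cultivars}
    else:
        probs = {c: float(presence_prob) for c in cultivars}
    if any(not 0.0 <= v <= 1.0 for v in probs.values()):
        raise ValueError("presence probabilities must lie in [0, 1]")
    rt_lo, rt_hi = rt_range
    if not 0 < rt_lo < rt_hi:
        raise ValueError("rt_range must be increasing and positive")
    if ladder is None:
        margin = 0.02 * (rt_hi - rt_lo)
        ladder = AlkaneLadder(
            np.arange(8, 21),
            np.linspace(rt_lo - margin, rt_hi + margin, 13),
        )
    lo, hi = ladder.span
    if rt_lo < lo or rt_hi > hi:
        raise ValueError(
            f"rt_range {rt_range} lies outside the alkane ladder span "
            f"({lo:.3f}, {hi:.3f})"
        )
    rng = np.random.default_rng(seed)
    rts = np.sort(rng.uniform(rt_lo, rt_hi, size=total))
    classes: list[str] = []
    for cls in CHEMICAL_CLASSES:
        classes.extend([cls] * class_counts.get(cls, 0))
    rows = []
    for i, (rt, cls) in enumerate(zip(rts, classes)):
        exp_ri = kovats_ri(rt, ladder)
        ref_ri = exp_ri + rng.normal(0.0, ri_noise_sd)
        presence = {
            c: int(rng.random() < probs[c]) for c in cultivars
        }
        if sum(presence.values()) == 0:
            lucky = cultivars[int(rng.integers(len(cultivars)))]
            presence[lucky] = 1
        rows.append(
            {
                "retention_time": round(float(rt), 4),
                "compound": f"compound_{i + 1:02d}",
                "reference_ri": round(float(ref_ri), 1),
                "experimental_ri": round(float(exp_ri), 1),
                "chemical_class": cls,
                **presence,
            }
        )
    return VolatileTable(pd.DataFrame(rows)), ladder
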