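"""Readers, writers and the shared data model.

All tabular files are comma-separated UTF-8 with ``NA`` for missing values;
band-locus columns are encoded ``PRIMER|system|band`` so per-primer statistics
need no side table. Writers are deterministic (fixed column order, ``%.4f``
floats) so pipeline bundles are byte-reproducible.
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from musadiv.similarity import Dendrogram

MARKER_SYSTEMS = ("RAPD", "ISSR", "SSR")

#: The nine chemical classes of the volatile table.
CHEMICAL_CLASSES = (
    "ester",
    "aromatic aldehyde",
    "alcohol",
    "hydrocarbon",
    "ketone",
    "ether",
    "carboxylic acid",
    "diverse functional group",
    "chlorine-containing",
)


class LocusId(NamedTuple):
    """A scored band locus: primer, marker system and band label.

    Band labels are kept as free text (fragment sizes appear both as
    ``0.75 Kb`` and ``750 bp`` in practice); no unit parsing is attempted.
    """

    primer: str
    system: str
    band: str

    def encode(self) -> str:
        return f"{self.primer}|{self.system}|{self.band}"

    @classmethod
    def decode(cls, text: str) -> "LocusId":
        parts = text.split("|")
        if len(parts) != 3:
            raise ValueError(
                f"locus id {text!r} is not of the form PRIMER|system|band"
            )
        primer, system, band = (p.strip() for p in parts)
        if system not in MARKER_SYSTEMS:
            raise ValueError(
                f"locus id {text!r}: unknown marker system {system!r} "
                f"(expected one of {MARKER_SYSTEMS})"
            )
        return cls(primer, system, band)


@dataclass
class BandMatrix:
    """Genotypes x scored band loci, values in {0, 1, missing}.

    ``values`` is a float array where missing cells are ``nan``; 0/1 cells are
    exact. Loci are grouped by primer through their :class:`LocusId`.
    """

    genotype_ids: list[str]
    loci: list[LocusId]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genotype_ids), len(self.loci)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genotype_ids)} genotypes x {len(self.loci)} loci"
            )
        if len(set(self.genotype_ids)) != len(self.genotype_ids):
            dupes = _duplicates(self.genotype_ids)
            raise ValueError(f"duplicate genotype ids: {dupes}")
        if len(set(self.loci)) != len(self.loci):
            dupes = _duplicates(self.loci)
            raise ValueError(f"duplicate locus ids: {dupes}")
        system_by_primer: dict[str, str] = {}
        for locus in self.loci:
            seen = system_by_primer.setdefault(locus.primer, locus.system)
            if seen != locus.system:
                raise ValueError(
                    f"primer {locus.primer!r} appears under two marker "
                    f"systems ({seen!r} and {locus.system!r})"
                )
        finite = self.values[~np.isnan(self.values)]
        bad = finite[(finite != 0.0) & (finite != 1.0)]
        if bad.size:
            i, j = np.argwhere(
                ~np.isnan(self.values)
                & (self.values != 0.0)
                & (self.values != 1.0)
            )[0]
            raise ValueError(
                f"cell ({self.genotype_ids[i]!r}, {self.loci[j].encode()!r}) "
                f"has value {self.values[i, j]!r}; expected 0, 1 or NA"
            )
        n_scored = (~np.isnan(self.values)).sum(axis=0)
        if (n_scored < 1).any():
            j = int(np.argmin(n_scored))
            raise ValueError(
                f"locus {self.loci[j].encode()!r} has no scored (non-missing) cells"
            )

    @property
    def n_genotypes(self) -> int:
        return len(self.genotype_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def primers(self) -> list[str]:
        out: list[str] = []
        for locus in self.loci:
            if locus.primer not in out:
                out.append(locus.primer)
        return out

    def systems(self) -> list[str]:
        out: list[str] = []
        for locus in self.loci:
            if locus.system not in out:
                out.append(locus.system)
        return out

    def select_system(self, system: str) -> "BandMatrix":
        """Restrict to one marker system (RAPD, ISSR or SSR)."""
        if system not in MARKER_SYSTEMS:
            raise ValueError(f"unknown marker system {system!r}")
        cols = [j for j, l in enumerate(self.loci) if l.system == system]
        if not cols:
            raise ValueError(f"no loci of system {system!r} in matrix")
        return BandMatrix(
            list(self.genotype_ids),
            [self.loci[j] for j in cols],
            self.values[:, cols],
        )

    def select_primer(self, primer: str) -> "BandMatrix":
        cols = [j for j, l in enumerate(self.loci) if l.primer == primer]
        if not cols:
            raise ValueError(f"no loci of primer {primer!r} in matrix")
        return BandMatrix(
            list(self.genotype_ids),
            [self.loci[j] for j in cols],
            self.values[:, cols],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.genotype_ids, name="genotype"),
            columns=[l.encode() for l in self.loci],
        )


def _duplicates(items: Iterable) -> list:
    seen: set = set()
    out = []
    for it in items:
        if it in seen and it not in out:
            out.append(it)
        seen.add(it)
    return sorted(set(out), key=repr)


def read_band_matrix(source) -> BandMatrix:
    """Read a band-score CSV (rows = genotypes, columns = encoded loci)."""
    # header=None keeps duplicate locus columns visible to validation
    # (pandas would silently rename them otherwise)
    df = pd.read_csv(source, dtype=str, keep_default_na=False, header=None)
    if df.shape[1] < 2 or df.shape[0] < 2:
        raise ValueError("band matrix needs a genotype column and >= 1 locus")
    header = [str(c).strip() for c in df.iloc[0, 1:]]
    genotypes = [str(g) for g in df.iloc[1:, 0]]
    loci = [LocusId.decode(c) for c in header]
    body = df.iloc[1:, 1:].to_numpy()
    values = np.empty((len(genotypes), len(loci)))
    for i in range(len(genotypes)):
        for j, col in enumerate(header):
            cell = str(body[i, j]).strip()
            if cell == "NA" or cell == "":
                values[i, j] = np.nan
            elif cell in ("0", "1"):
                values[i, j] = float(cell)
            else:
                raise ValueError(
                    f"cell ({genotypes[i]!r}, {col!r}) has value {cell!r}; "
                    f"expected 0, 1 or NA"
                )
    return BandMatrix(genotypes, loci, values)


def write_band_matrix(matrix: BandMatrix, target=None) -> str:
    """Serialise a band matrix back to canonical CSV text."""
    lines = ["genotype," + ",".join(l.encode() for l in matrix.loci)]
    for i, g in enumerate(matrix.genotype_ids):
        cells = [
            "NA" if np.isnan(v) else str(int(v)) for v in matrix.values[i]
        ]
        lines.append(g + "," + ",".join(cells))
    text = "\n".join(lines) + "\n"
    if target is not None:
        with open(target, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


@dataclass(frozen=True)
class PopRecord:
    population: str
    genome_group: str
    ploidy: int


_GENOME_RE = re.compile(r"^[AB]{2,4}$")


@dataclass
class PopulationMap:
    """genotype -> (population, genome group, ploidy).

    Genome groups are strings over {A, B} (e.g. ``AAB``); the ploidy must
    equal the genome-group length and lie in {2, 3, 4}.
    """

    records: dict[str, PopRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("population map contains no genotypes")
        for genotype, rec in self.records.items():
            if not _GENOME_RE.match(rec.genome_group):
                raise ValueError(
                    f"genotype {genotype!r}: genome group {rec.genome_group!r} "
                    f"is not a string of 2-4 letters over {{A,B}}"
                )
            if rec.ploidy != len(rec.genome_group):
                raise ValueError(
                    f"genotype {genotype!r}: ploidy {rec.ploidy} inconsistent "
                    f"with genome group {rec.genome_group!r} "
                    f"(length {len(rec.genome_group)})"
                )

    def genotypes(self) -> list[str]:
        return list(self.records)

    def populations(self) -> list[str]:
        out: list[str] = []
        for rec in self.records.values():
            if rec.population not in out:
                out.append(rec.population)
        return out

    def population_of(self, genotype: str) -> str:
        return self.records[genotype].population

    def ploidy_of(self, genotype: str) -> int:
        return self.records[genotype].ploidy

    def members(self, population: str) -> list[str]:
        return [
            g for g, rec in self.records.items() if rec.population == population
        ]

    def check_matches(self, matrix: BandMatrix) -> None:
        missing = [g for g in matrix.genotype_ids if g not in self.records]
        if missing:
            raise ValueError(
                f"genotypes absent from population map: {missing}"
            )


def read_population_map(source) -> PopulationMap:
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    required = ["genotype", "population", "genome_group", "ploidy"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"population map is missing column {col!r}")
    if df.empty:
        raise ValueError("population map contains no genotypes")
    records: dict[str, PopRecord] = {}
    for _, row in df.iterrows():
        g = row["genotype"]
        if g in records:
            raise ValueError(f"duplicate genotype {g!r} in population map")
        try:
            ploidy = int(row["ploidy"])
        except ValueError:
            raise ValueError(
                f"genotype {g!r}: ploidy {row['ploidy']!r} is not an integer"
            ) from None
        records[g] = PopRecord(row["population"], row["genome_group"], ploidy)
    return PopulationMap(records)


def write_population_map(pop_map: PopulationMap, target=None) -> str:
    lines = ["genotype,population,genome_group,ploidy"]
    for g, rec in pop_map.records.items():
        lines.append(f"{g},{rec.population},{rec.genome_group},{rec.ploidy}")
    text = "\n".join(lines) + "\n"
    if target is not None:
        with open(target, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


@dataclass
class StructureRuns:
    """Replicated log-probability traces from external Bayesian clustering.

    ``lnpd`` maps K -> list of replicate LnP(D) values; ``q_matrices``
    optionally maps K -> (genotype x K) membership-fraction frame.
    """

    lnpd: dict[int, list[float]]
    q_matrices: dict[int, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ks = sorted(self.lnpd)
        if not ks:
            raise ValueError("no K values provided")
        for k in ks:
            if k < 1:
                raise ValueError(f"K = {k} is not a positive integer")
            if not self.lnpd[k]:
                raise ValueError(f"K = {k} has no replicates")
        for k, q in self.q_matrices.items():
            arr = q.to_numpy(dtype=float)
            if arr.shape[1] != k:
                raise ValueError(
                    f"Q matrix for K = {k} has {arr.shape[1]} columns"
                )
            if (arr < 0).any():
                raise ValueError(f"Q matrix for K = {k} has negative entries")
            if np.abs(arr.sum(axis=1) - 1.0).max() > 1e-6:
                bad = q.index[np.abs(arr.sum(axis=1) - 1.0).argmax()]
                raise ValueError(
                    f"Q row for genotype {bad!r} (K = {k}) does not sum to 1"
                )

    def k_values(self) -> list[int]:
        return sorted(self.lnpd)


def read_structure_lnpd(source) -> StructureRuns:
    """Read a (K, replicate, lnpd) CSV into :class:`StructureRuns`."""
    df = pd.read_csv(source)
    for col in ("K", "replicate", "lnpd"):
        if col not in df.columns:
            raise ValueError(f"structure-run CSV is missing column {col!r}")
    lnpd: dict[int, list[float]] = {}
    for k, sub in df.groupby("K"):
        lnpd[int(k)] = [float(v) for v in sub["lnpd"]]
    return StructureRuns(lnpd)


def write_structure_lnpd(runs: StructureRuns, target=None) -> str:
    lines = ["K,replicate,lnpd"]
    for k in runs.k_values():
        for r, v in enumerate(runs.lnpd[k], start=1):
            lines.append(f"{k},{r},{v:.4f}")
    text = "\n".join(lines) + "\n"
    if target is not None:
        with open(target, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def read_structure_q(source) -> pd.DataFrame:
    """Read a Q-matrix CSV (first column genotype, then one column per cluster)."""
    df = pd.read_csv(source)
    df = df.set_index(df.columns[0])
    return df.astype(float)


@dataclass
class AlkaneLadder:
    """n-alkane calibration ladder (C8-C20) for Kovats retention indices."""

    carbons: np.ndarray
    retention_times: np.ndarray

    def __post_init__(self) -> None:
        self.carbons = np.asarray(self.carbons, dtype=int)
        self.retention_times = np.asarray(self.retention_times, dtype=float)
        if self.carbons.shape != self.retention_times.shape:
            raise ValueError("carbons and retention_times differ in length")
        if len(self.carbons) < 2:
            raise ValueError("alkane ladder needs >= 2 anchors")
        if (self.carbons < 8).any() or (self.carbons > 20).any():
            raise ValueError("alkane carbon numbers must lie in [8, 20]")
        if not (np.diff(self.carbons) > 0).all():
            raise ValueError("alkane carbon numbers must strictly increase")
        if not (np.diff(self.retention_times) > 0).all():
            raise ValueError("alkane retention times must strictly increase")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.retention_times[0]), float(self.retention_times[-1])


def read_alkane_ladder(source) -> AlkaneLadder:
    df = pd.read_csv(source)
    for col in ("carbon_number", "retention_time"):
        if col not in df.columns:
            raise ValueError(f"alkane ladder CSV is missing column {col!r}")
    return AlkaneLadder(
        df["carbon_number"].to_numpy(), df["retention_time"].to_numpy()
    )


def write_alkane_ladder(ladder: AlkaneLadder, target=None) -> str:
    lines = ["carbon_number,retention_time"]
    for c, rt in zip(ladder.carbons, ladder.retention_times):
        lines.append(f"{c},{rt:.4f}")
    text = "\n".join(lines) + "\n"
    if target is not None:
        with open(target, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


_META_COLS = [
    "retention_time",
    "compound",
    "reference_ri",
    "experimental_ri",
    "chemical_class",
]


@dataclass
class VolatileTable:
    """GC-MS volatile compound records with per-cultivar presence.

    ``data`` holds one row per compound with the meta columns
    (retention_time, compound, reference_ri, experimental_ri, chemical_class)
    followed by one 0/1 column per cultivar. Compound names need not be
    unique; a record is identified by (retention time, name, class).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in _META_COLS:
            if col not in self.data.columns:
                raise ValueError(f"volatile table is missing column {col!r}")
        if self.data.empty:
            raise ValueError("volatile table is empty")
        bad_class = set(self.data["chemical_class"]) - set(CHEMICAL_CLASSES)
        if bad_class:
            raise ValueError(
                f"unknown chemical class(es) {sorted(bad_class)}; expected "
                f"one of {CHEMICAL_CLASSES}"
            )
        if (self.data["retention_time"].astype(float) <= 0).any():
            row = self.data[self.data["retention_time"].astype(float) <= 0].iloc[0]
            raise ValueError(
                f"compound {row['compound']!r} has non-positive retention time"
            )
        for col in ("reference_ri", "experimental_ri"):
            if (self.data[col].astype(float) < 100).any():
                row = self.data[self.data[col].astype(float) < 100].iloc[0]
                raise ValueError(
                    f"compound {row['compound']!r} has {col} < 100"
                )
        pres = self.presence().to_numpy()
        if not np.isin(pres, (0, 1)).all():
            raise ValueError("presence cells must be 0 or 1")

    @property
    def cultivars(self) -> list[str]:
        return [c for c in self.data.columns if c not in _META_COLS]

    def presence(self) -> pd.DataFrame:
        """Compound x cultivar 0/1 presence matrix."""
        return self.data[self.cultivars].astype(int)

    @property
    def n_compounds(self) -> int:
        return len(self.data)


def read_volatile_table(source) -> VolatileTable:
    df = pd.read_csv(source)
    return VolatileTable(df)


def write_volatile_table(table: VolatileTable, target=None) -> str:
    df = table.data.copy()
    buf = _io.StringIO()
    df.to_csv(buf, index=False, float_format="%.4f")
    text = buf.getvalue()
    if target is not None:
        with open(target, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


_NEWICK_SAFE = re.compile(r"^[A-Za-z0-9_.|-]+$")


def _newick_label(label: str) -> str:
    if _NEWICK_SAFE.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_newick(tree: "Dendrogram", target=None) -> str:
    """Serialise an ultrametric dendrogram to Newick with branch lengths.

    Merge heights are cophenetic distances; each branch gets half the merge
    height so leaf-to-leaf path lengths reproduce the cophenetic matrix.
    Labels containing spaces or other unsafe characters are single-quoted.
    """
    n = len(tree.labels)
    # node id -> (newick text without trailing length, half-height of node)
    nodes: dict[int, tuple[str, float]] = {
        i: (_newick_label(tree.labels[i]), 0.0) for i in range(n)
    }
    node_id = n
    for a, b, height, _ in tree.merges:
        half = height / 2.0
        parts = []
        for child in sorted((int(a), int(b))):
            text, child_half = nodes.pop(child)
            length = half - child_half
            parts.append(f"{text}:{format(length, '.10g')}")
        nodes[node_id] = ("(" + ",".join(parts) + ")", half)
        node_id += 1
    (root_text, _), = nodes.values()
    out = root_text + ";"
    if target is not None:
        with open(target, "w", encoding="utf-8") as fh:
            fh.write(out + "\n")
    return out


def write_similarity_csv(labels: Sequence[str], S: np.ndarray, target=None) -> str:
    lines = ["genotype," + ",".join(labels)]
    for i, lab in enumerate(labels):
        lines.append(lab + "," + ",".join(f"{v:.4f}" for v in S[i]))
    text = "\n".join(lines) + "\n"
    if target is not None:
        with open(target, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def read_distance_csv(source) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(source, index_col=0)
    labels = [str(x) for x in df.index]
    return labels, df.to_numpy(dtype=float)
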