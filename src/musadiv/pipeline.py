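"""Config-driven end-to-end runs producing the study's table/figure artifacts.

A run consumes whatever inputs the config provides (band matrix, population
map, clustering-run summaries, volatile table) and writes per-primer
statistics, similarity matrices + Newick dendrograms per marker system and
combined, PCoA coordinates, AMOVA + pairwise Phi_ST tables, population
diversity, the Evanno deltaK table, volatile composition + dendrogram, and a
machine-readable manifest (package version, seed, input checksums). Stages
whose inputs are absent are skipped with a log line; the bundle is
byte-reproducible under a fixed seed and config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from musadiv import __version__
from musadiv.amova import (
    amova,
    pairwise_phist,
    population_diversity,
    squared_distance_matrix,
)
from musadiv.io_formats import (
    read_alkane_ladder,
    read_band_matrix,
    read_population_map,
    read_structure_lnpd,
    read_structure_q,
    read_volatile_table,
    write_newick,
    write_similarity_csv,
)
from musadiv.marker_stats import system_summary_table
from musadiv.ordination import pcoa
from musadiv.similarity import similarity_matrix, upgma
from musadiv.structure_summary import classify_membership, evanno_delta_k, optimal_k
from musadiv.volatilome import (
    class_composition,
    cultivar_counts,
    cultivar_volatile_clustering,
)

logger = logging.getLogger("musadiv.pipeline")


@dataclass
class RunConfig:
    out_dir: str
    band_matrix: str | None = None
    population_map: str | None = None
    structure_lnpd: str | None = None
    structure_q: str | None = None
    volatile_table: str | None = None
    alkane_ladder: str | None = None
    systems: list[str] = field(default_factory=lambda: ["RAPD", "ISSR", "SSR"])
    coefficient: str = "dice"
    n_permutations: int = 999
    seed: int = 0
    membership_threshold: float = 0.44
    purity_threshold: float = 0.7
    ri_tolerance: float = 15.0

    def __post_init__(self) -> None:
        for name in (
            "band_matrix",
            "population_map",
            "structure_lnpd",
            "structure_q",
            "volatile_table",
            "alkane_ladder",
        ):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name} path {path!r} does not exist")


def load_config(path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage the config's inputs allow; return the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    inputs: dict[str, str] = {}
    skipped: list[str] = []

    def _write_df(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = out / name
        df.to_csv(path, index=index, float_format="%.4f")
        artifacts[name] = _sha256(path)

    t0 = time.monotonic()
    matrix = None
    if config.band_matrix:
        matrix = read_band_matrix(config.band_matrix)
        inputs["band_matrix"] = _sha256(config.band_matrix)
    pop_map = None
    if config.population_map:
        pop_map = read_population_map(config.population_map)
        inputs["population_map"] = _sha256(config.population_map)

    if matrix is not None:
        present_systems = [s for s in config.systems if s in matrix.systems()]
        for system in present_systems:
            stats = system_summary_table(matrix, system)
            _write_df(stats, f"marker_stats_{system}.csv")
        # similarity + dendrogram per system and combined
        scopes = [(s, s) for s in present_systems]
        if len(present_systems) > 1:
            scopes.append(("combined", None))
        for tag, system in scopes:
            labels, S = similarity_matrix(
                matrix, system=system, coefficient=config.coefficient
            )
            path = out / f"similarity_{tag}.csv"
            write_similarity_csv(labels, S, path)
            artifacts[path.name] = _sha256(path)
            tree = upgma(1.0 - S, labels)
            path = out / f"dendrogram_{tag}.nwk"
            write_newick(tree, path)
            artifacts[path.name] = _sha256(path)
        # PCoA on the combined (or only) distance matrix
        labels, S = similarity_matrix(matrix, coefficient=config.coefficient)
        res = pcoa(1.0 - S, labels)
        coords = pd.DataFrame(
            res.coordinates,
            index=pd.Index(labels, name="genotype"),
            columns=[f"axis{i + 1}" for i in range(res.n_axes)],
        )
        _write_df(coords, "pcoa_coordinates.csv", index=True)
        eig = pd.DataFrame(
            {
                "eigenvalue": res.eigenvalues[: res.n_axes],
                "percent_variance": res.percent_variance,
                "cumulative_percent": res.cumulative_percent,
            }
        )
        _write_df(eig, "pcoa_eigenvalues.csv")
    else:
        skipped.append("marker stages (no band matrix)")

    if matrix is not None and pop_map is not None:
        pop_map.check_matches(matrix)
        pops = [pop_map.population_of(g) for g in matrix.genotype_ids]
        D2 = squared_distance_matrix(matrix)
        res = amova(D2, pops, n_perm=config.n_permutations, seed=config.seed)
        table = pd.DataFrame(
            {
                "Source": ["Among populations", "Within populations", "Total"],
                "df": [res.df_among, res.df_within, res.df_total],
                "SS": [res.SS_among, res.SS_within, res.SS_total],
                "MS": [res.MS_among, res.MS_within, float("nan")],
                "Est_var": [res.var_among, res.var_within,
                            res.var_among + res.var_within],
                "Percent": [res.percent_among, res.percent_within, 100.0],
                "Stat": ["PhiST", "", ""],
                "Value": [res.phi_st, float("nan"), float("nan")],
                "P": [res.p_value, float("nan"), float("nan")],
            }
        )
        _write_df(table, "amova.csv")
        pop_order, M = pairwise_phist(D2, pops)
        _write_df(
            pd.DataFrame(M, index=pd.Index(pop_order, name="population"),
                         columns=pop_order),
            "pairwise_phist.csv",
            index=True,
        )
        div = population_diversity(matrix, pop_map)
        _write_df(
            pd.DataFrame(
                [
                    {
                        "population": d.population,
                        "n": d.n,
                        "gene_diversity": d.gene_diversity,
                        "heterozygosity": d.heterozygosity,
                    }
                    for d in div
                ]
            ),
            "population_diversity.csv",
        )
    else:
        skipped.append("AMOVA stages (band matrix + population map required)")

    if config.structure_lnpd:
        runs = read_structure_lnpd(config.structure_lnpd)
        inputs["structure_lnpd"] = _sha256(config.structure_lnpd)
        table = evanno_delta_k(runs)
        table.attrs["optimal_k"] = optimal_k(table)
        _write_df(table, "delta_k.csv")
    else:
        skipped.append("deltaK (no structure-run summary)")

    if config.structure_q:
        Q = read_structure_q(config.structure_q)
        inputs["structure_q"] = _sha256(config.structure_q)
        calls, tallies = classify_membership(
            Q, config.membership_threshold, config.purity_threshold
        )
        _write_df(
            pd.DataFrame(
                [
                    {
                        "genotype": c.genotype,
                        "assigned_cluster": c.assigned_cluster,
                        "max_q": c.max_q,
                        "status": c.status,
                    }
                    for c in calls
                ]
            ),
            "membership.csv",
        )
        _write_df(tallies, "membership_tallies.csv", index=True)
    else:
        skipped.append("membership calls (no Q matrix)")

    if config.volatile_table:
        table = read_volatile_table(config.volatile_table)
        inputs["volatile_table"] = _sha256(config.volatile_table)
        if config.alkane_ladder:
            read_alkane_ladder(config.alkane_ladder)  # validated; RI column is trusted
            inputs["alkane_ladder"] = _sha256(config.alkane_ladder)
        comp = class_composition(table)
        _write_df(
            pd.DataFrame(
                {
                    "chemical_class": comp.class_counts.index,
                    "count": comp.class_counts.values,
                    "percent": comp.percent.values,
                    "percent_rounded": comp.percent_rounded.values,
                }
            ),
            "volatile_composition.csv",
        )
        _write_df(cultivar_counts(table), "volatile_cultivar_counts.csv",
                  index=True)
        tree = cultivar_volatile_clustering(table)
        path = out / "volatile_dendrogram.nwk"
        write_newick(tree, path)
        artifacts[path.name] = _sha256(path)
    else:
        skipped.append("volatilome (no volatile table)")

    for stage in skipped:
        logger.warning("skipped %s", stage)

    manifest = {
        "package": "musadiv",
        "version": __version__,
        "seed": config.seed,
        "inputs": inputs,
        "artifacts": artifacts,
        "skipped": skipped,
    }
    path = out / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    logger.info(
        "pipeline finished: %d artifacts in %.1f s",
        len(artifacts),
        time.monotonic() - t0,
    )
    return manifest
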