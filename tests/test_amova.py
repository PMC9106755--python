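"""AMOVA: distance matrix, SS partition, permutation test, diversity."""

import numpy as np
import pytest

from musadiv.amova import (
    amova,
    pairwise_phist,
    phi_from_components,
    population_diversity,
    squared_distance_matrix,
)
from musadiv.io_formats import BandMatrix, LocusId, PopRecord, PopulationMap
from musadiv.synthetic import simulate_structured_bands


def _matrix(values, primer="P1"):
    values = np.asarray(values, dtype=float)
    loci = [LocusId(primer, "RAPD", f"b{j}") for j in range(values.shape[1])]
    return BandMatrix(
        [f"g{i}" for i in range(values.shape[0])], loci, values
    )


class TestSquaredDistance:
    def test_identical_and_single_mismatch(self):
        m = _matrix([[1, 0, 1], [1, 0, 1], [0, 0, 1]])
        D2 = squared_distance_matrix(m)
        assert D2[0, 1] == 0
        assert D2[0, 2] == 1

    def test_matches_brute_force_with_missing(self):
        rng = np.random.default_rng(2)
        values = (rng.random((5, 8)) < 0.5).astype(float)
        values[rng.random((5, 8)) < 0.15] = np.nan
        # keep every locus scored somewhere and every pair jointly scored
        values[0] = (rng.random(8) < 0.5).astype(float)
        m = _matrix(values)
        D2 = squared_distance_matrix(m)
        for i in range(5):
            for j in range(5):
                count = sum(
                    1
                    for l in range(8)
                    if not np.isnan(values[i, l])
                    and not np.isnan(values[j, l])
                    and values[i, l] != values[j, l]
                )
                assert D2[i, j] == count

    def test_no_jointly_scored_pair_rejected(self):
        values = np.array([[1.0, np.nan], [np.nan, 1.0]])
        m = _matrix(values)
        with pytest.raises(ValueError, match="share no scored locus"):
            squared_distance_matrix(m)


def _coordinate_ss(values, pops):
    """Independent SS partition from band coordinates (not from distances)."""
    values = np.asarray(values, dtype=float)
    grand = values.mean(axis=0)
    ss_total = ((values - grand) ** 2).sum()
    ss_within = 0.0
    for pop in sorted(set(pops)):
        sub = values[[i for i, p in enumerate(pops) if p == pop]]
        ss_within += ((sub - sub.mean(axis=0)) ** 2).sum()
    return ss_total, ss_within


class TestAmova:
    def test_ss_partition_matches_coordinate_oracle(self):
        rng = np.random.default_rng(4)
        values = (rng.random((8, 12)) < 0.5).astype(float)
        values[0, 0] = 1.0  # ensure at least one band everywhere
        pops = ["A", "A", "A", "B", "B", "B", "C", "C"]
        m = _matrix(values)
        res = amova(squared_distance_matrix(m), pops, n_perm=0)
        ss_total, ss_within = _coordinate_ss(values, pops)
        assert res.SS_total == pytest.approx(ss_total, abs=1e-8)
        assert res.SS_within == pytest.approx(ss_within, abs=1e-8)
        assert res.SS_among == pytest.approx(ss_total - ss_within, abs=1e-8)

    def test_complete_separation_gives_phi_one(self):
        values = np.array(
            [[1, 1, 1, 0], [1, 1, 1, 0], [0, 0, 0, 1], [0, 0, 0, 1]],
            dtype=float,
        )
        res = amova(
            squared_distance_matrix(_matrix(values)),
            ["A", "A", "B", "B"],
            n_perm=0,
        )
        assert res.phi_st == pytest.approx(1.0)
        assert res.percent_among == pytest.approx(100.0)

    def test_conservation_invariants(self):
        m, truth = simulate_structured_bands(seed=21)
        pops = [truth.assignment[g] for g in m.genotype_ids]
        res = amova(squared_distance_matrix(m), pops, n_perm=0)
        assert res.SS_among + res.SS_within == pytest.approx(
            res.SS_total, abs=1e-8
        )
        assert res.percent_among + res.percent_within == pytest.approx(
            100.0, abs=1e-6
        )
        assert res.df_among + res.df_within == res.df_total == 19
        assert res.MS_among == pytest.approx(res.SS_among / res.df_among)

    def test_null_labels_give_near_zero_phi(self):
        phis = []
        for seed in range(20):
            m, truth = simulate_structured_bands(
                n_pops=2,
                sizes=(10, 10),
                primers=[("P1", "RAPD", 100)],
                F=0.0,
                seed=seed,
            )
            rng = np.random.default_rng(1000 + seed)
            pops = list(rng.permutation(["A"] * 10 + ["B"] * 10))
            phis.append(
                amova(squared_distance_matrix(m), pops, n_perm=0).phi_st
            )
        assert abs(np.mean(phis)) < 0.05

    def test_permutation_p_reproducible(self):
        m, truth = simulate_structured_bands(seed=33)
        pops = [truth.assignment[g] for g in m.genotype_ids]
        D2 = squared_distance_matrix(m)
        r1 = amova(D2, pops, n_perm=199, seed=5)
        r2 = amova(D2, pops, n_perm=199, seed=5)
        assert r1.p_value == r2.p_value

    def test_structured_data_significant(self):
        m, truth = simulate_structured_bands(F=0.3, seed=2)
        pops = [truth.assignment[g] for g in m.genotype_ids]
        res = amova(squared_distance_matrix(m), pops, n_perm=999, seed=0)
        assert res.p_value <= 0.01  # minimum achievable is 1/1000

    def test_identical_genotypes_degenerate(self):
        values = np.ones((4, 3))
        with pytest.warns(UserWarning, match="zero"):
            res = amova(
                squared_distance_matrix(_matrix(values)),
                ["A", "A", "B", "B"],
                n_perm=0,
            )
        assert res.phi_st == 0.0

    def test_phi_from_components(self):
        assert phi_from_components(0.859, 2.876) == pytest.approx(0.23, abs=5e-4)


class TestPairwisePhist:
    def test_identical_populations_zero_and_symmetric(self):
        # A and B consist of the same constant genotype -> no molecular
        # variance in that pair, Phi reported as 0 (flagged); A vs C separates.
        x = np.array([1.0, 0.0, 1.0, 1.0])
        y = np.array([0.0, 1.0, 0.0, 1.0])
        values = np.vstack([x, x, x, x, y, y])
        pops = ["A", "A", "B", "B", "C", "C"]
        with pytest.warns(UserWarning, match="zero"):
            order, M = pairwise_phist(
                squared_distance_matrix(_matrix(values)), pops
            )
        np.testing.assert_allclose(M, M.T)
        a, b, c = (order.index(p) for p in "ABC")
        assert M[a, b] == 0.0
        assert M[a, c] == pytest.approx(1.0)

    def test_singleton_population_flagged_nan(self):
        rng = np.random.default_rng(7)
        values = (rng.random((5, 10)) < 0.5).astype(float)
        values[:, 0] = 1.0
        pops = ["A", "A", "B", "B", "C"]
        order, M = pairwise_phist(
            squared_distance_matrix(_matrix(values)), pops
        )
        c = order.index("C")
        assert np.isnan(M[c, order.index("A")])
        assert not np.isnan(M[order.index("A"), order.index("B")])

    def test_ordering_follows_simulated_divergence(self):
        def mean_pair_phi(F):
            vals = []
            for seed in range(10):
                m, truth = simulate_structured_bands(
                    n_pops=2,
                    sizes=(8, 8),
                    primers=[("P1", "RAPD", 150)],
                    F=F,
                    seed=seed,
                )
                pops = [truth.assignment[g] for g in m.genotype_ids]
                _, M = pairwise_phist(squared_distance_matrix(m), pops)
                vals.append(M[0, 1])
            return float(np.mean(vals))

        assert mean_pair_phi(0.05) < mean_pair_phi(0.3)


class TestPopulationDiversity:
    def _map_for(self, matrix, pops):
        return PopulationMap(
            {
                g: PopRecord(p, "AA", 2)
                for g, p in zip(matrix.genotype_ids, pops)
            }
        )

    def test_fixed_loci_zero_diversity(self):
        m = _matrix(np.ones((4, 5)))
        res = population_diversity(m, self._map_for(m, ["A"] * 2 + ["B"] * 2))
        assert all(d.gene_diversity == 0 for d in res)
        assert all(d.heterozygosity == 0 for d in res)

    def test_balanced_locus_approaches_half(self):
        # band frequency 0.75 -> p = q = 0.5 -> unbiased gene diversity
        # 0.5 * n/(n-1)
        n = 100
        values = np.zeros((n, 1))
        values[:75, 0] = 1.0
        m = _matrix(values)
        res = population_diversity(m, self._map_for(m, ["A"] * n))
        assert res[0].gene_diversity == pytest.approx(0.5 * n / (n - 1))
        assert res[0].heterozygosity == pytest.approx(0.5)

    def test_singleton_population_flagged(self):
        values = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        m = _matrix(values)
        with pytest.warns(UserWarning, match="single member"):
            res = population_diversity(
                m, self._map_for(m, ["A", "A", "B"])
            )
        flags = {d.population: d.unbiased for d in res}
        assert flags == {"A": True, "B": False}

    def test_expected_heterozygosity_tracks_hwe_simulation(self):
        m, truth = simulate_structured_bands(
            n_pops=1,
            sizes=(1500,),
            primers=[("P1", "RAPD", 40)],
            F=0.0,
            ploidy_map={f"G{i + 1:02d}": 2 for i in range(1500)},
            seed=17,
        )
        pm = truth.to_population_map()
        res = population_diversity(m, pm)
        expected = float(np.mean(2 * truth.p0 * (1 - truth.p0)))
        assert res[0].heterozygosity == pytest.approx(expected, abs=0.02)
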