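"""Coalescent simulators, spatial patterns, and the power-study harness."""

import numpy as np
import pytest
from scipy import stats

import spca_eigentest as se
from spca_eigentest.genodata import ValidationError
from spca_eigentest.simgen import default_knn_k
from tests.conftest import cell_value


class TestSimulateSnps:
    def test_every_locus_segregating_biallelic(self):
        sc = se.SimScenario(model="IS", migration_rate=0.01, n_loci=60)
        g = se.simulate_snps(sc, seed=4)
        assert g.dosages.shape == (100, 60)
        assert set(np.unique(g.dosages)) <= {0.0, 1.0, 2.0}
        assert not g.monomorphic_mask.any()

    def test_fixed_seed_identical_dosages(self):
        sc = se.SimScenario(model="SS", migration_rate=0.01, n_loci=30)
        a = se.simulate_snps(sc, seed=9)
        b = se.simulate_snps(sc, seed=9)
        np.testing.assert_array_equal(a.dosages, b.dosages)

    def test_panmixia_limit_fst_near_zero(self):
        # one migrant per individual per generation: far beyond the
        # panmixia threshold (expected FST ~ 0.002)
        sc = se.SimScenario(model="IS", migration_rate=1.0, n_loci=200)
        labels = sc.deme_labels
        fsts = [
            se.mean_fst(se.simulate_snps(sc, seed=300 + r), labels) for r in range(20)
        ]
        assert abs(np.mean(fsts)) < 0.02

    def test_island_fst_matches_coalescent_expectation(self):
        """Mean Hudson FST agrees with the exact finite-island coalescent value.

        For total immigration rate m split over the d-1 other demes and
        diploid deme size N, first-step analysis of the two-lineage
        structured coalescent gives E[T_within] = 2Nd and
        E[T_between] = 2Nd + (d-1)/(2m), hence
        FST = 1 / (1 + 4Nm d/(d-1)).
        """
        m, N, d = 0.005, 100, 4
        sc = se.SimScenario(model="IS", migration_rate=m, deme_size=N, n_loci=200)
        labels = sc.deme_labels
        reps = 20
        fsts = np.array(
            [se.mean_fst(se.simulate_snps(sc, seed=700 + r), labels) for r in range(reps)]
        )
        expected = 1.0 / (1.0 + 4 * N * m * d / (d - 1))
        se_mean = fsts.std(ddof=1) / np.sqrt(reps)
        assert abs(fsts.mean() - expected) <= 3 * se_mean

    def test_stepping_stone_distance_decay(self):
        """Under SS, adjacent demes are less differentiated than end demes."""
        sc = se.SimScenario(model="SS", migration_rate=0.01, n_loci=200)
        g = se.simulate_snps(sc, seed=21)
        labels = sc.deme_labels
        near = se.mean_fst(
            se.GenotypeTable(g.unit_ids[:50], g.dosages[:50], g.locus_ids),
            labels[:50],
        )
        far_sel = (labels == 0) | (labels == 3)
        far = se.mean_fst(
            se.GenotypeTable(
                [u for u, k in zip(g.unit_ids, far_sel) if k],
                g.dosages[far_sel],
                g.locus_ids,
            ),
            labels[far_sel],
        )
        assert far > near

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValidationError):
            se.SimScenario(model="IS", migration_rate=0.0)


class TestCoordinates:
    def test_random_points_inside_square(self):
        c = se.random_coordinates(100, grid_scale=3.0, seed=1)
        assert c.n == 100
        assert np.all((c.xy >= 0) & (c.xy <= 3.0))

    def test_random_seeded_and_distinct(self):
        a = se.random_coordinates(50, seed=5)
        b = se.random_coordinates(50, seed=5)
        c = se.random_coordinates(50, seed=6)
        np.testing.assert_array_equal(a.xy, b.xy)
        assert not np.array_equal(a.xy, c.xy)

    def test_patched_quadrants(self):
        sc = se.SimScenario(model="SS", migration_rate=0.01)
        c = se.patched_coordinates(sc, seed=2)
        labels = sc.deme_labels
        halves_x = c.xy[:, 0] >= 0.5
        halves_y = c.xy[:, 1] >= 0.5
        quad = halves_y.astype(int) * 2 + halves_x.astype(int)
        # each deme occupies exactly one quadrant
        for d in range(4):
            assert len(set(quad[labels == d])) == 1
        assert len(set(quad[::25])) == 4

    def test_patched_centroids_separated(self):
        sc = se.SimScenario(model="SS", migration_rate=0.01)
        c = se.patched_coordinates(sc, seed=3)
        labels = sc.deme_labels
        centroids = np.array([c.xy[labels == d].mean(axis=0) for d in range(4)])
        spread = max(
            np.linalg.norm(c.xy[labels == d] - centroids[d], axis=1).mean()
            for d in range(4)
        )
        dmin = min(
            np.linalg.norm(centroids[a] - centroids[b])
            for a in range(4)
            for b in range(a + 1, 4)
        )
        assert dmin > spread

    def test_gradient_mode_orders_centroids(self):
        sc = se.SimScenario(model="SS", migration_rate=0.01, gradient=True)
        c = se.patched_coordinates(sc, seed=4)
        labels = sc.deme_labels
        xs = [c.xy[labels == d, 0].mean() for d in range(4)]
        assert np.all(np.diff(xs) > 0)


class TestLocalPatternGraph:
    def test_edges_join_separated_clusters_only(self, rng):
        # two tight, well-separated genetic clusters: every upper-quartile
        # distance pair straddles the clusters
        block = np.vstack(
            [np.zeros((10, 20)), np.ones((10, 20)) * 2.0]
        ) + rng.normal(scale=0.01, size=(20, 20))
        g = se.GenotypeTable(
            [f"u{i}" for i in range(20)],
            np.clip(block, 0, 2).round(0),
            [f"l{j}" for j in range(20)],
        )
        W, coords, kept = se.local_pattern_graph(g)
        labels = np.array([0] * 10 + [1] * 10)[[int(u[1:]) for u in kept]]
        edges = np.argwhere(W.L > 0)
        assert np.all(labels[edges[:, 0]] != labels[edges[:, 1]])

    def test_upper_quartile_edge_count(self):
        sc = se.SimScenario(model="SS", migration_rate=0.005, n_loci=100)
        g = se.simulate_snps(sc, seed=13)
        W, _, kept = se.local_pattern_graph(g)
        n_pairs = g.n_units * (g.n_units - 1) // 2
        n_edges = int((W.L > 0).sum()) // 2
        # exactly the upper-quartile pairs, allowing tie blocks at the cut
        assert n_edges >= np.ceil(0.25 * n_pairs)
        assert n_edges <= 0.27 * n_pairs

    def test_first_pc_moran_negative_on_adversarial_graph(self):
        sc = se.SimScenario(model="SS", migration_rate=0.005, n_loci=100)
        g = se.simulate_snps(sc, seed=29)
        W, coords, kept = se.local_pattern_graph(g)
        # coords.xy[:, 0] is the first genetic PC of the retained units
        assert se.moran_index(coords.xy[:, 0], W) < 0

    def test_degenerate_genotypes_rejected(self):
        g = se.GenotypeTable(
            [f"u{i}" for i in range(8)],
            np.tile([0.0, 1.0], (8, 4)),
            [f"l{j}" for j in range(8)],
        )
        with pytest.raises(ValidationError):
            se.local_pattern_graph(g)


class TestPowerStudy:
    def test_seeding_contract_first_half_identical(self):
        kwargs = dict(
            models=["IS"],
            rates=[0.1],
            patterns=["random"],
            n_loci_list=[30],
            B=99,
            alphas=[0.05],
            seed=8,
            scenario_kwargs={"per_deme": 10},
        )
        a, _ = se.power_study(n_reps=20, **kwargs)
        b, _ = se.power_study(n_reps=40, **kwargs)
        # with the same counter-based seed stream the first 20 replicates of
        # the longer run reproduce the shorter run's rejections exactly
        pa = a["proportion_significant"].to_numpy() * 20
        pb = b["proportion_significant"].to_numpy() * 40
        assert np.all(pb >= pa)  # the shorter run's rejections are a subset

    def test_default_network_density(self):
        assert default_knn_k(100) == 10
        assert default_knn_k(3) == 2
        assert default_knn_k(1) == 1

    def test_pvalues_uniform_under_random_pattern(self):
        """With random coordinates the permutation test is exact, so both
        p-values are uniform; the KS check passes in >= 9 of 10 calibrations."""
        passes_g = passes_l = 0
        n_cal, reps, B = 10, 50, 99
        for cal in range(n_cal):
            pg, pl = [], []
            for rep in range(reps):
                sc = se.SimScenario(
                    model="IS", migration_rate=0.1, n_loci=30, pattern="random"
                )
                ds = se.build_dataset(sc, seed=100_000 + cal * reps + rep)
                X = se.centre_frequencies(ds.genotypes)
                res = se.spca_randtest(
                    X, ds.weights, B=B, seed=np.random.default_rng(cal * reps + rep)
                )
                pg.append(res.p_global)
                pl.append(res.p_local)
            passes_g += stats.kstest(pg, "uniform").pvalue > 0.01
            passes_l += stats.kstest(pl, "uniform").pvalue > 0.01
        assert passes_g >= 9
        assert passes_l >= 9


class TestPowerTrends:
    """Directional claims of the benchmark, on the shared 100-replicate cells."""

    def test_power_decreases_with_migration_rate(self, power_cells):
        df, _ = power_cells
        lo = cell_value(df, rate=0.005, loci=200)
        hi = cell_value(df, rate=0.1, loci=200)
        assert lo >= hi

    def test_more_loci_no_less_power(self, power_cells):
        df, _ = power_cells
        assert cell_value(df, rate=0.005, loci=200) >= cell_value(
            df, rate=0.005, loci=40
        )

    def test_significant_rank_histogram_present_for_strong_pattern(self, power_cells):
        _, hist = power_cells
        strong = hist[(hist["rate"] == 0.005) & (hist["loci"] == 200) & (hist["side"] == "pos")]
        assert not strong.empty
        assert strong.loc[strong["rank"] == 1, "frequency"].iloc[0] > 0.5
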