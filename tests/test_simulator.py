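"""Genotype panel generation, kinship, variance calibration, phenotypes."""

import numpy as np
import pytest

from isisblasso.simulator import (
    SimulationConfig,
    compute_kinship,
    qtn_effect_from_h2,
    resolve_qtn_indices,
    simulate_genotypes,
    simulate_phenotypes,
    total_phenotypic_variance,
)


class TestSimulateGenotypes:
    def test_deterministic_under_seed(self):
        a = simulate_genotypes(50, 100, 0.3, seed=7)
        b = simulate_genotypes(50, 100, 0.3, seed=7)
        np.testing.assert_array_equal(a.matrix, b.matrix)

    def test_qtn_columns_hit_target_frequency(self):
        n = 199
        g = simulate_genotypes(n, 500, 0.3, seed=3, qtn_indices=np.array([10, 250]))
        tol = 3 * np.sqrt(0.3 * 0.7 / n)
        for j in (10, 250):
            assert abs(g.matrix[:, j].mean() - 0.3) <= tol

    def test_five_chromosomes_evenly_loaded(self):
        g = simulate_genotypes(20, 10_000, 0.3, seed=1)
        labels, counts = np.unique(np.asarray(g.chromosome, dtype=str), return_counts=True)
        assert sorted(labels) == ["1", "2", "3", "4", "5"]
        assert all(c == 2000 for c in counts)

    def test_positions_positive_and_spaced(self):
        g = simulate_genotypes(10, 100, 0.3, seed=1)
        assert np.all(g.position_bp > 0)
        chr1 = g.position_bp[np.asarray(g.chromosome, dtype=str) == "1"]
        assert np.all(np.diff(chr1) == 10_000)

    def test_invalid_maf_rejected(self):
        with pytest.raises(ValueError):
            simulate_genotypes(10, 100, 0.8, seed=1)


class TestKinship:
    def test_identical_lines_get_identical_rows(self):
        g = simulate_genotypes(30, 200, 0.3, seed=5)
        g.matrix[1] = g.matrix[0]
        g.monomorphic = g.matrix.var(axis=0) == 0
        K = compute_kinship(g).values
        np.testing.assert_allclose(K[0], K[1], atol=1e-12)

    def test_symmetric_psd_unit_diagonal_mean(self):
        g = simulate_genotypes(40, 300, 0.3, seed=6)
        K = compute_kinship(g).values
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        assert np.linalg.eigvalsh(K).min() >= -1e-10
        assert np.diag(K).mean() == pytest.approx(1.0, abs=0.1)


class TestVarianceCalibration:
    def test_experiment1_total_variance(self):
        h2 = (0.10, 0.05, 0.05, 0.15, 0.05, 0.05)
        assert total_phenotypic_variance(h2, 10.0) == pytest.approx(10 / 0.55)

    def test_experiment2_polygenic_heritability_is_0092(self):
        h2 = (0.10, 0.05, 0.05, 0.15, 0.05, 0.05)
        V = total_phenotypic_variance(h2, 10.0, polygenic_var=2.0)
        assert V == pytest.approx(12 / 0.55)
        assert 2.0 / V == pytest.approx(0.092, abs=0.0005)

    def test_experiment3_epistatic_heritability_is_005_each(self):
        h2 = (0.10, 0.05, 0.05, 0.15, 0.05, 0.05)
        V = total_phenotypic_variance(h2, 10.0, epi_vars=(1.25, 1.25, 1.25))
        assert V == pytest.approx(25.0)
        assert 1.25 / V == pytest.approx(0.05)

    def test_effect_solves_h2_identity(self):
        a = qtn_effect_from_h2(0.15, 0.21, 18.18)
        assert a**2 * 0.21 == pytest.approx(0.15 * 18.18)

    def test_infeasible_heritability_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            total_phenotypic_variance((0.6, 0.5), 10.0)


class TestSimulatePhenotypes:
    def test_null_config_variance_matches_residual(self):
        cfg = SimulationConfig(
            n=199, p=50, qtn_h2=(1e-9,) * 6, n_replicates=100, seed=2
        )
        g = simulate_genotypes(cfg.n, cfg.p, cfg.maf, seed=11,
                               qtn_indices=resolve_qtn_indices(cfg))
        reps = simulate_phenotypes(g, cfg)
        mean_var = np.mean([r.phenotypes.var(ddof=1) for r in reps])
        bound = 3 * np.sqrt(2 * 10.0**2 / (199 - 1)) / np.sqrt(100)
        assert abs(mean_var - 10.0) <= 3 * bound  # wide MC bound

    def test_experiment1_realized_qtn4_share(self):
        cfg = SimulationConfig(n=199, p=200, n_replicates=200, seed=4)
        g = simulate_genotypes(cfg.n, cfg.p, cfg.maf, seed=12,
                               qtn_indices=resolve_qtn_indices(cfg))
        reps = simulate_phenotypes(g, cfg)
        qtn = resolve_qtn_indices(cfg)
        a4 = reps[0].true_effects[int(qtn[3])]
        x4 = g.matrix[:, int(qtn[3])]
        share = a4**2 * x4.var(ddof=1) / np.mean(
            [r.phenotypes.var(ddof=1) for r in reps]
        )
        assert share == pytest.approx(0.15, abs=0.03)

    def test_bit_identical_under_fixed_seed(self):
        cfg = SimulationConfig(n=50, p=40, n_replicates=3, seed=9)
        g = simulate_genotypes(50, 40, 0.3, seed=1, qtn_indices=resolve_qtn_indices(cfg))
        a = simulate_phenotypes(g, cfg)
        b = simulate_phenotypes(g, cfg)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.phenotypes, rb.phenotypes)

    def test_noise_stream_independent_of_panel_width(self):
        """Same seed, different p: the residual draws are identical, so
        phenotype differences trace only to the genetic terms."""
        cfg_small = SimulationConfig(n=40, p=60, n_replicates=1, seed=5,
                                     qtn_snps=(1, 2, 3, 4, 5, 6))
        cfg_big = SimulationConfig(n=40, p=120, n_replicates=1, seed=5,
                                   qtn_snps=(1, 2, 3, 4, 5, 6))
        g_small = simulate_genotypes(40, 60, 0.3, seed=2, qtn_indices=np.arange(1, 7))
        g_big = simulate_genotypes(40, 120, 0.3, seed=3, qtn_indices=np.arange(1, 7))
        ya = simulate_phenotypes(g_small, cfg_small)[0]
        yb = simulate_phenotypes(g_big, cfg_big)[0]
        # subtract the deterministic genetic part: residuals must agree
        ga = 10 + g_small.matrix[:, 1:7] @ [ya.true_effects[i] for i in range(1, 7)]
        gb = 10 + g_big.matrix[:, 1:7] @ [yb.true_effects[i] for i in range(1, 7)]
        np.testing.assert_allclose(ya.phenotypes - ga, yb.phenotypes - gb, atol=1e-10)

    def test_polygenic_term_adds_configured_share(self):
        cfg = SimulationConfig(n=100, p=300, polygenic_var=2.0, n_replicates=200, seed=3)
        g = simulate_genotypes(cfg.n, cfg.p, cfg.maf, seed=8,
                               qtn_indices=resolve_qtn_indices(cfg))
        reps = simulate_phenotypes(g, cfg)
        poly_share = np.mean([r.components["polygenic"] for r in reps])
        assert poly_share == pytest.approx(2.0, rel=0.3)

    def test_epistatic_pairs_contribute_configured_variance(self):
        cfg = SimulationConfig.experiment(3, n=150, p=200, n_replicates=5, seed=6)
        g = simulate_genotypes(cfg.n, cfg.p, cfg.maf, seed=7,
                               qtn_indices=resolve_qtn_indices(cfg))
        reps = simulate_phenotypes(g, cfg)
        # three independent-ish pairs each scaled to 1.25
        assert reps[0].components["epistatic"] == pytest.approx(3 * 1.25, rel=0.4)

    def test_experiment_factory_wiring(self):
        e2 = SimulationConfig.experiment(2)
        assert e2.polygenic_var == 2.0 and not e2.epistasis
        e3 = SimulationConfig.experiment(3)
        assert len(e3.epistasis) == 3
        assert all(v == 1.25 for _, v in e3.epistasis)
        qtn = set(resolve_qtn_indices(e3).tolist())
        epi_loci = {i for pair, _ in e3.epistasis for i in pair}
        assert not (qtn & epi_loci)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(maf=0.7)
        with pytest.raises(ValueError):
            SimulationConfig(qtn_h2=(0.5, 0.6))
        with pytest.raises(ValueError):
            SimulationConfig(residual_var=0.0)


def test_simulated_dataset_round_trip(tmp_path):
    from isisblasso.simulator import read_simulated_phenotypes, write_simulated_dataset

    cfg = SimulationConfig(n=30, p=40, n_replicates=3, seed=13)
    g = simulate_genotypes(30, 40, 0.3, seed=2, qtn_indices=resolve_qtn_indices(cfg))
    reps = simulate_phenotypes(g, cfg)
    write_simulated_dataset(g, reps, tmp_path / "study")
    back = read_simulated_phenotypes(tmp_path / "study" / "phenotypes.tsv")
    assert len(back) == 3
    for a, b in zip(reps, back):
        np.testing.assert_allclose(a.phenotypes, b, atol=1e-12)
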