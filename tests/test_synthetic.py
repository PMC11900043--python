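"""Generator contracts: determinism, ordering, planted correlation kernel,
fold/fitness recovery."""

import numpy as np
import pandas as pd
import pytest

from locus_echo import coexpression as cx
from locus_echo.genome_map import AnnotationTable
from locus_echo.synthetic import (
    SimulationConfig,
    correlation_kernel,
    nearest_psd,
    simulate_expression,
    simulate_genome,
    simulate_growth,
    simulate_qpcr,
)


class TestConfigValidation:
    def test_kernel_bound(self):
        with pytest.raises(ValueError, match="baseline_corr"):
            SimulationConfig(decay_amplitude=0.8, baseline_corr=0.3)

    def test_positive_decay_length(self):
        with pytest.raises(ValueError, match="decay_length"):
            SimulationConfig(decay_length=0)

    @pytest.mark.parametrize("field", ["n_chromosomes", "genes_per_chromosome",
                                       "n_blocks", "samples_per_block"])
    def test_counts_at_least_one(self, field):
        with pytest.raises(ValueError, match=field):
            SimulationConfig(**{field: 0})


class TestSimulateGenome:
    def test_gene_count_and_ordering(self):
        cfg = SimulationConfig(n_chromosomes=1, genes_per_chromosome=7, seed=5)
        ann = simulate_genome(cfg)
        genes = ann.chromosome_genes("chr1")
        assert len(genes) == 7
        assert genes["start"].is_monotonic_increasing
        # non-overlapping: each gene ends before the next starts
        assert (genes["start"].to_numpy()[1:] > genes["end"].to_numpy()[:-1]).all()

    def test_one_centromere_per_chromosome(self):
        ann = simulate_genome(SimulationConfig(n_chromosomes=3, seed=1))
        cen = ann.features[ann.features["feature_type"] == "centromere"]
        assert sorted(cen["chromosome"]) == ["chr1", "chr2", "chr3"]

    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=9)
        a = simulate_genome(cfg)
        b = simulate_genome(cfg)
        pd.testing.assert_frame_equal(a.genes, b.genes)
        pd.testing.assert_frame_equal(a.features, b.features)

    def test_single_gene_chromosome_gives_empty_neighborhood(self):
        from locus_echo.genome_map import neighborhood

        cfg = SimulationConfig(n_chromosomes=1, genes_per_chromosome=1, seed=2)
        ann = simulate_genome(cfg)
        gid = ann.genes.iloc[0]["gene_id"]
        assert neighborhood(ann, gid, k=3).neighbors == []


class TestSimulateExpression:
    def test_seed_determinism(self, two_gene_annotation):
        cfg = SimulationConfig(n_chromosomes=1, genes_per_chromosome=2, seed=3)
        a = simulate_expression(two_gene_annotation, cfg)
        b = simulate_expression(two_gene_annotation, cfg)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_kernel_correlation_at_known_distance(self, two_gene_annotation):
        # genes 1 kb apart, a0=0.8, c0=0, lambda0=5 kb -> rho = 0.8*exp(-0.2)
        cfg = SimulationConfig(
            n_chromosomes=1, genes_per_chromosome=2, decay_amplitude=0.8,
            baseline_corr=0.0, decay_length=5000, n_blocks=1,
            samples_per_block=2000, seed=3,
        )
        expr = simulate_expression(two_gene_annotation, cfg)
        r, n = cx.pcc(expr.gene("gA"), expr.gene("gB"))
        assert n == 2000
        assert r == pytest.approx(0.8 * np.exp(-1000 / 5000), abs=0.05)

    def test_short_decay_length_leaves_baseline_only(self, two_gene_annotation):
        # lambda0 -> 0: neighbor correlation collapses to c0
        cfg = SimulationConfig(
            n_chromosomes=1, genes_per_chromosome=2, decay_amplitude=0.8,
            baseline_corr=0.1, decay_length=1.0, n_blocks=2,
            samples_per_block=250, seed=8,
        )
        expr = simulate_expression(two_gene_annotation, cfg)
        block = cfg.blocks[0]
        cols = expr.block_samples(block)
        r, _ = cx.pcc(expr.values.loc["gA", cols], expr.values.loc["gB", cols])
        assert r == pytest.approx(0.1, abs=0.15)

    def test_inter_chromosome_independence(self):
        cfg = SimulationConfig(
            n_chromosomes=2, genes_per_chromosome=2, decay_amplitude=0.9,
            baseline_corr=0.1, n_blocks=1, samples_per_block=1500, seed=4,
        )
        ann = simulate_genome(cfg)
        expr = simulate_expression(ann, cfg)
        g1 = ann.chromosome_genes("chr1").iloc[0]["gene_id"]
        g2 = ann.chromosome_genes("chr2").iloc[0]["gene_id"]
        r, _ = cx.pcc(expr.gene(g1), expr.gene(g2))
        assert abs(r) < 0.1

    def test_manifest_covers_all_samples(self, small_sim):
        _, _, expr = small_sim
        assert set(expr.values.columns) <= set(expr.block_manifest.index)
        assert len(expr.blocks()) == 3


class TestNearestPsd:
    def test_repairs_indefinite_matrix(self):
        bad = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.9], [0.1, 0.9, 1.0]])
        assert np.linalg.eigvalsh(bad).min() < 0
        fixed = nearest_psd(bad)
        assert np.linalg.eigvalsh(fixed).min() >= 0
        np.testing.assert_allclose(np.diag(fixed), 1.0, atol=1e-12)

    def test_psd_input_unchanged(self):
        good = correlation_kernel(np.array([[0.0, 1e3], [1e3, 0.0]]), 0.5, 5e3, 0.1)
        np.fill_diagonal(good, 1.0)
        np.testing.assert_allclose(nearest_psd(good), good, atol=1e-12)


class TestSimulateQpcr:
    def test_determinism_and_schema(self):
        a = simulate_qpcr({"mut": 2.0}, n_replicates=3, seed=7)
        b = simulate_qpcr({"mut": 2.0}, n_replicates=3, seed=7)
        pd.testing.assert_frame_equal(a, b)
        assert set(a.columns) == {"sample", "strain", "gene", "replicate", "Ct",
                                  "melt_ok"}
        assert (a["Ct"] > 0).all()

    def test_null_fold_centers_ddct_on_zero(self):
        from locus_echo.qpcr import ddct

        table = simulate_qpcr({"m1": 1.0, "m2": 1.0}, n_replicates=24, seed=11)
        est = ddct(table, target="YCP4", calibrator="WT")
        for strain in ("m1", "m2"):
            assert est[strain].ddct == pytest.approx(0.0, abs=0.15)

    def test_fold_recovery(self):
        # Monte-Carlo oracle: mean recovered fold over seeds approaches truth
        from locus_echo.qpcr import ddct

        folds = []
        for seed in range(20):
            table = simulate_qpcr({"mut": 4.0}, n_replicates=8, seed=seed,
                                  noise_sd=0.1)
            folds.append(ddct(table, target="YCP4", calibrator="WT")["mut"].fold)
        assert np.mean(folds) == pytest.approx(4.0, rel=0.15)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            simulate_qpcr({"m": -1.0})
        with pytest.raises(ValueError):
            simulate_qpcr({"m": 2.0}, n_replicates=1)


class TestSimulateGrowth:
    def test_scores_bounded_and_monotone_in_expectation(self):
        control, stress = simulate_growth({"s": 0.7}, n_dilutions=6,
                                          n_replicates=200, seed=5)
        for df in (control, stress):
            assert df["score"].between(0, 1).all()
            mean_by_step = df.groupby("dilution")["score"].mean()
            # means decrease along the dilution series up to sampling noise
            # (sem ~ 0.0035 at 200 replicates)
            assert (np.diff(mean_by_step.to_numpy()) <= 0.02).all()

    def test_zero_fitness_gives_allzero_stress_grid(self):
        _, stress = simulate_growth({"dead": 0.0}, seed=1)
        assert (stress["score"] == 0).all()

    def test_identity_fitness_ratio_near_one(self):
        from locus_echo.growth_assay import grids_from_frame, relative_growth

        control, stress = simulate_growth({"s": 1.0}, n_replicates=20, seed=3)
        rel = relative_growth(grids_from_frame(stress), grids_from_frame(control))
        assert rel == pytest.approx(1.0, abs=0.1)

    def test_determinism(self):
        a = simulate_growth({"s": 0.5}, seed=2)
        b = simulate_growth({"s": 0.5}, seed=2)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])
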