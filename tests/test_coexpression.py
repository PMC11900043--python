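"""Pearson correlation, locus profiles, locus averages and the clustered
condition heatmap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from locus_echo import coexpression as cx
from locus_echo import genome_map
from locus_echo.coexpression import (
    CorrelationProfile,
    ExpressionError,
    ExpressionMatrix,
    ProfileEntry,
    condition_heatmap,
    load_expression,
    locus_average_pcc,
    locus_profile,
    pcc,
)


def _raw_pcc(x, y):
    """From-scratch product-moment oracle."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float(np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2)))


class TestPcc:
    def test_hand_computed_example(self):
        r, n = pcc([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8, abs=1e-15)
        assert n == 4

    def test_self_correlation_exactly_one(self):
        x = np.random.default_rng(0).normal(size=50)
        r, _ = pcc(x, x)
        assert r == 1.0

    def test_matches_product_moment_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            m = rng.integers(3, 20)
            x, y = rng.normal(size=m), rng.normal(size=m)
            r, _ = pcc(x, y)
            assert r == pytest.approx(_raw_pcc(x, y), abs=1e-12)

    def test_constant_series_undefined(self):
        r, _ = pcc([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])
        assert np.isnan(r)

    def test_too_few_pairs_undefined(self):
        r, n = pcc([1, 2, np.nan, np.nan], [1, np.nan, 2, 3])
        assert np.isnan(r) and n == 1

    def test_pairwise_deletion(self):
        x = [1, 2, 3, 4, np.nan]
        y = [1, 3, 2, 4, 10.0]
        r, n = pcc(x, y)
        assert n == 4
        assert r == pytest.approx(0.8, abs=1e-15)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-50, 50), min_size=4, max_size=20),
        st.floats(0.1, 5),
        st.floats(-10, 10),
    )
    def test_shift_scale_invariance(self, xs, a, b):
        rng = np.random.default_rng(len(xs))
        y = rng.normal(size=len(xs))
        r1, _ = pcc(xs, y)
        r2, _ = pcc(xs, a * y + b)
        if not np.isnan(r1):
            assert r1 == pytest.approx(r2, abs=1e-9)


def _matrix(genes, samples, values, block="b1"):
    vals = pd.DataFrame(values, index=genes, columns=samples)
    manifest = pd.Series(block, index=samples)
    return ExpressionMatrix(values=vals, block_manifest=manifest)


class TestExpressionMatrix:
    def test_round_trip(self, small_sim, tmp_path):
        _, _, expr = small_sim
        expr.to_files(tmp_path / "m.tsv", tmp_path / "manifest.tsv")
        loaded = load_expression(tmp_path / "m.tsv", tmp_path / "manifest.tsv")
        pd.testing.assert_frame_equal(loaded.values, expr.values)
        assert loaded.blocks() == expr.blocks()

    def test_sample_missing_from_manifest_named(self):
        vals = pd.DataFrame(np.zeros((1, 2)), index=["g"], columns=["s1", "s2"])
        with pytest.raises(ExpressionError, match="s2"):
            ExpressionMatrix(values=vals, block_manifest=pd.Series({"s1": "b"}))


class TestLocusProfile:
    def test_duplicated_focal_gives_unit_pcc(self, two_gene_annotation):
        rng = np.random.default_rng(1)
        row = rng.normal(size=10)
        expr = _matrix(["gA", "gB"], [f"s{i}" for i in range(10)],
                       np.vstack([row, row]))
        nbhd = genome_map.neighborhood(two_gene_annotation, "gA", 1)
        prof = locus_profile(expr, nbhd, "b1")
        assert prof.entries[0].pcc == 1.0

    def test_independent_noise_uncorrelated(self, two_gene_annotation):
        rng = np.random.default_rng(2)
        expr = _matrix(["gA", "gB"], [f"s{i}" for i in range(1000)],
                       rng.normal(size=(2, 1000)))
        nbhd = genome_map.neighborhood(two_gene_annotation, "gA", 1)
        prof = locus_profile(expr, nbhd, "b1")
        assert abs(prof.entries[0].pcc) < 0.1

    def test_kernel_monotone_decay_in_expectation(self, small_sim):
        # neighbor PCC should fall with |distance| under the planted kernel,
        # averaged across blocks to tame sampling noise
        cfg, ann, expr = small_sim
        genes = ann.chromosome_genes("chr1")
        focal = genes.iloc[len(genes) // 2]["gene_id"]
        nbhd = genome_map.neighborhood(ann, focal, k=5)
        rows = []
        for block in expr.blocks():
            prof = locus_profile(expr, nbhd, block)
            rows += [(abs(e.signed_distance), e.pcc) for e in prof.defined()]
        df = pd.DataFrame(rows, columns=["d", "r"])
        near = df[df["d"] < df["d"].median()]["r"].mean()
        far = df[df["d"] >= df["d"].median()]["r"].mean()
        assert near > far

    def test_missing_focal_raises(self, two_gene_annotation):
        expr = _matrix(["gB"], ["s1", "s2", "s3"], np.zeros((1, 3)))
        nbhd = genome_map.neighborhood(two_gene_annotation, "gA", 1)
        with pytest.raises(ExpressionError, match="gA"):
            locus_profile(expr, nbhd, "b1")

    def test_absent_neighbor_skipped(self, two_gene_annotation):
        rng = np.random.default_rng(3)
        expr = _matrix(["gA"], [f"s{i}" for i in range(5)],
                       rng.normal(size=(1, 5)))
        nbhd = genome_map.neighborhood(two_gene_annotation, "gA", 1)
        prof = locus_profile(expr, nbhd, "b1")
        assert prof.entries == []


class TestLocusAverage:
    def test_arithmetic_mean(self):
        prof = CorrelationProfile(
            focal="f", block="b",
            entries=[ProfileEntry("n1", 1e3, 0.8, 10),
                     ProfileEntry("n2", -2e3, 0.0, 10)],
        )
        assert locus_average_pcc(prof) == pytest.approx(0.4)

    def test_undefined_entries_excluded(self):
        prof = CorrelationProfile(
            focal="f", block="b",
            entries=[ProfileEntry("n1", 1e3, 0.6, 10),
                     ProfileEntry("n2", -2e3, float("nan"), 2)],
        )
        assert locus_average_pcc(prof) == pytest.approx(0.6)

    def test_all_undefined_is_nan(self):
        prof = CorrelationProfile(
            focal="f", block="b",
            entries=[ProfileEntry("n1", 1e3, float("nan"), 2)],
        )
        assert np.isnan(locus_average_pcc(prof))

    def test_within_entry_range(self):
        prof = CorrelationProfile(
            focal="f", block="b",
            entries=[ProfileEntry("n1", 1e3, 0.9, 9),
                     ProfileEntry("n2", 2e3, -0.3, 9),
                     ProfileEntry("n3", 3e3, 0.2, 9)],
        )
        avg = locus_average_pcc(prof)
        assert -0.3 <= avg <= 0.9

    def test_fisher_option(self):
        prof = CorrelationProfile(
            focal="f", block="b",
            entries=[ProfileEntry("n1", 1e3, 0.9, 9),
                     ProfileEntry("n2", 2e3, 0.1, 9)],
        )
        assert locus_average_pcc(prof, method="fisher") > locus_average_pcc(prof)


def _profiles_for(nbhd, pccs_by_block):
    out = {}
    for block, pccs in pccs_by_block.items():
        entries = [
            ProfileEntry(n.gene_id, n.signed_distance, r, 20)
            for n, r in zip(nbhd.neighbors, pccs)
        ]
        out[block] = CorrelationProfile(focal=nbhd.focal, block=block,
                                        entries=entries)
    return out


class TestConditionHeatmap:
    def _nbhd(self, yeast_map):
        return genome_map.neighborhood(yeast_map, "YCP4", 2)

    def test_rows_in_genomic_order_and_focal_unity(self, yeast_map):
        nbhd = self._nbhd(yeast_map)
        profiles = _profiles_for(
            nbhd,
            {"b1": [0.1, 0.2, 0.3, 0.4], "b2": [0.4, 0.3, 0.2, 0.1],
             "b3": [0.0, 0.0, 0.5, 0.5]},
        )
        heat = condition_heatmap(profiles, nbhd)
        assert list(heat.values.index) == nbhd.ordered_window()
        assert (heat.values.loc["YCP4"] == 1.0).all()

    def test_identical_columns_cluster_together(self, yeast_map):
        nbhd = self._nbhd(yeast_map)
        profiles = _profiles_for(
            nbhd,
            {"hot": [0.9, 0.8, 0.7, 0.6], "cold": [-0.5, -0.4, -0.3, -0.2],
             "hot2": [0.9, 0.8, 0.7, 0.6]},
        )
        heat = condition_heatmap(profiles, nbhd)
        cols = list(heat.values.columns)
        assert abs(cols.index("hot") - cols.index("hot2")) == 1

    def test_input_order_invariance(self, yeast_map):
        nbhd = self._nbhd(yeast_map)
        spec = {"a": [0.9, 0.1, 0.3, 0.2], "b": [0.2, 0.8, 0.1, 0.0],
                "c": [0.85, 0.15, 0.35, 0.25]}
        h1 = condition_heatmap(_profiles_for(nbhd, spec), nbhd)
        reordered = {k: spec[k] for k in ["c", "a", "b"]}
        h2 = condition_heatmap(_profiles_for(nbhd, reordered), nbhd)
        assert list(h1.values.columns) == list(h2.values.columns)

    def test_strong_mask_threshold(self, yeast_map):
        nbhd = self._nbhd(yeast_map)
        profiles = _profiles_for(
            nbhd, {"b1": [0.6, 0.2, -0.7, 0.0], "b2": [0.1, 0.2, 0.3, 0.4]}
        )
        heat = condition_heatmap(profiles, nbhd)
        assert bool(heat.strong_mask.loc["CDC10", "b1"])  # 0.6
        assert bool(heat.strong_mask.loc["CIT2", "b1"])  # |-0.7|
        assert not heat.strong_mask.loc["MRPL32", "b1"]  # 0.2
        assert heat.strong_mask.loc["YCP4"].all()  # focal row is 1 everywhere

    def test_all_missing_block_dropped(self, yeast_map):
        nbhd = self._nbhd(yeast_map)
        profiles = _profiles_for(
            nbhd,
            {"ok1": [0.1, 0.2, 0.3, 0.4], "ok2": [0.4, 0.3, 0.2, 0.1],
             "dead": [float("nan")] * 4},
        )
        with pytest.warns(UserWarning, match="dead"):
            heat = condition_heatmap(profiles, nbhd)
        assert "dead" not in heat.values.columns
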