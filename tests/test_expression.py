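"""RPKM machinery, TMM normalization and the differential test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pksmine import expression, simulate
from pksmine.expression import (
    CountMatrix,
    categorize,
    differential,
    expressed_call,
    expression_records,
    expression_table,
    log2_cpm,
    read_counts,
    rpkm,
    tmm_factors,
)


class TestRPKM:
    @pytest.mark.parametrize(
        "count,length,lib,expected",
        [(10, 1000, 1e6, 10.0), (0, 1000, 1e6, 0.0), (1000, 500, 1e6, 2000.0)],
    )
    def test_formula(self, count, length, lib, expected):
        assert rpkm(count, length, lib) == expected

    @given(
        st.integers(min_value=0, max_value=10**6),
        st.integers(min_value=1, max_value=10**5),
        st.integers(min_value=1, max_value=10**8),
        st.integers(min_value=2, max_value=50),
    )
    @settings(derandomize=True, max_examples=100)
    def test_scale_invariance(self, count, length, lib, k):
        assert rpkm(count * k, length, lib * k) == pytest.approx(
            rpkm(count, length, lib), rel=1e-12
        )

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            rpkm(1, 0, 1e6)


class TestExpressedCall:
    @pytest.mark.parametrize(
        "log2rpkm,expressed,reported",
        [
            (0.5, False, 0.0),
            (1.0, True, 1.0),  # boundary inclusive
            (5.0, True, 5.0),
            (float("-inf"), False, 0.0),  # RPKM of exactly zero
        ],
    )
    def test_threshold_and_floor(self, log2rpkm, expressed, reported):
        assert expressed_call(log2rpkm) == (expressed, reported)


class TestCategorize:
    @pytest.mark.parametrize(
        "e24,e48,cat",
        [
            (False, False, "Cat1"),
            (False, True, "Cat2"),
            (True, False, "Cat2"),
            (True, True, "Cat3"),
        ],
    )
    def test_table(self, e24, e48, cat):
        assert categorize(e24, e48) == cat


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        rng = np.random.default_rng(7)
        col = rng.negative_binomial(5, 0.1, 400)
        factors = tmm_factors(np.column_stack([col, col]))
        assert factors == pytest.approx([1.0, 1.0])

    def test_depth_change_without_composition_change(self):
        rng = np.random.default_rng(8)
        col = rng.negative_binomial(5, 0.05, 500) + 1  # no zeros
        factors = tmm_factors(np.column_stack([col, 2 * col]))
        assert factors == pytest.approx([1.0, 1.0], abs=0.01)

    def test_factors_have_geometric_mean_one(self):
        rng = np.random.default_rng(9)
        counts = rng.negative_binomial(4, 0.08, size=(600, 5))
        factors = tmm_factors(counts)
        assert np.exp(np.mean(np.log(factors))) == pytest.approx(1.0, abs=1e-12)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(10)
        counts = rng.negative_binomial(4, 0.08, size=(300, 4))
        factors = tmm_factors(counts)
        perm = rng.permutation(300)
        assert tmm_factors(counts[perm]) == pytest.approx(factors)

    def test_all_zero_sample_rejected(self):
        counts = np.zeros((10, 2))
        counts[:, 0] = 5
        with pytest.raises(ValueError):
            tmm_factors(counts)

    def test_matches_edger_reference_values(self):
        """Frozen oracle: edgeR 4.0 calcNormFactors on this exact matrix."""
        rng = np.random.default_rng(20240615)
        mu = np.exp(rng.normal(3.0, 1.2, 300))
        scale = np.array([1.0, 1.6, 0.7, 1.2])
        size = 1.0 / 0.15
        counts = np.column_stack(
            [rng.negative_binomial(size, size / (size + mu * s)) for s in scale]
        )
        expected = [1.0518545536, 1.0048828301, 0.9202749532, 1.0280430010]
        assert tmm_factors(counts) == pytest.approx(expected, abs=1e-8)


class TestDifferential:
    def test_identical_groups_are_null(self):
        a = np.array([[3.0, 3.1, 2.9], [5.0, 5.0, 5.0]])
        log2fc, p, sig, strong = differential(a, a)
        assert log2fc == pytest.approx([0.0, 0.0])
        assert p[1] == 1.0  # exact equality degenerate case
        assert not sig.any() and not strong.any()

    def test_sub_twofold_change_can_be_significant_but_not_strong(self):
        a = np.array([[0.0, 0.01, -0.01]])
        b = a + 0.8
        log2fc, p, sig, strong = differential(a, b)
        assert log2fc[0] == pytest.approx(0.8)
        assert p[0] < 0.05 and sig[0] and not strong[0]

    def test_single_replicate_gives_no_pvalue(self):
        log2fc, p, sig, _ = differential(np.array([[1.0]]), np.array([[3.0]]))
        assert log2fc[0] == 2.0
        assert np.isnan(p[0]) and not sig[0]

    def test_power_for_fourfold_change_low_dispersion(self):
        """A planted 4x change at n=3, dispersion 0.05 is recovered >= 90%."""
        rng = np.random.default_rng(42)
        n_genes, phi = 400, 0.05
        mu = 100.0
        size = 1.0 / phi
        a = rng.negative_binomial(size, size / (size + mu), (n_genes, 3))
        b = rng.negative_binomial(size, size / (size + 4 * mu), (n_genes, 3))
        counts = np.hstack([a, b])
        lib = np.full(6, 1e6)
        lcpm = log2_cpm(counts, lib)
        _, p, sig, strong = differential(lcpm[:, :3], lcpm[:, 3:])
        assert np.mean(sig & strong) >= 0.9


class TestExpressionTable:
    def test_categories_partition_all_genes(self, sim_run):
        _, _, cm = sim_run
        table = expression_table(cm)
        tally = table["category"].value_counts()
        assert tally.sum() == len(cm.gene_ids)
        assert set(tally.index) <= {"Cat1", "Cat2", "Cat3"}

    def test_flags_consistent_with_category(self, sim_run):
        _, _, cm = sim_run
        table = expression_table(cm)
        n_expressed = table["expressed_24h"].astype(int) + table[
            "expressed_48h"
        ].astype(int)
        expected = n_expressed.map({0: "Cat1", 1: "Cat2", 2: "Cat3"})
        assert (table["category"] == expected).all()
        # significant implies p < 0.05; strong implies at least twofold
        sig = table[table["significant"]]
        assert (sig["p_value"] < 0.05).all()
        strong = table[table["strong"]]
        assert (strong["log2fc"].abs() >= 1.0).all()

    def test_records_mirror_table(self, sim_run):
        _, _, cm = sim_run
        table = expression_table(cm)
        records = expression_records(table)
        gene = table.index[0]
        assert records[gene].category == table.loc[gene, "category"]
        assert records[gene].expressed_48h == bool(table.loc[gene, "expressed_48h"])


def test_counts_tsv_roundtrip(tmp_path, sim_run):
    _, truth, cm = sim_run
    counts_path = tmp_path / "counts.tsv"
    samples_path = tmp_path / "samples.tsv"
    out = cm.counts.copy()
    out.insert(0, "length_bp", cm.lengths)
    out.insert(0, "gene_id", out.index)
    out.to_csv(counts_path, sep="\t", index=False)
    pd.DataFrame(
        {"sample": cm.conditions.index, "condition": cm.conditions.values}
    ).to_csv(samples_path, sep="\t", index=False)
    back = read_counts(counts_path, samples_path)
    assert (back.counts == cm.counts).all().all()
    assert (back.lengths == cm.lengths).all()
    assert (back.conditions == cm.conditions).all()
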