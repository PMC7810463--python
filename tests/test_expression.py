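"""Normalization, differential expression and gene classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bifate import expression as ex


def make_matrix(counts: pd.DataFrame, compartments: list[str]) -> ex.ExpressionMatrix:
    meta = pd.DataFrame(
        {"sample": counts.columns, "compartment": compartments,
         "replicate": list(range(1, len(counts.columns) + 1))}
    )
    return ex.ExpressionMatrix(counts=counts, sample_meta=meta)


class TestNormalization:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"s1": [10, 20, 5], "s2": [10, 20, 5]})
        factors, norm = ex.normalize_median_of_ratios(counts)
        assert np.allclose(factors, 1.0)
        pd.testing.assert_frame_equal(norm, counts.astype(float))

    def test_doubled_column_factor_ratio(self):
        rng = np.random.default_rng(0)
        a = rng.integers(5, 200, size=50)
        counts = pd.DataFrame({"a": a, "b": 2 * a})
        factors, _ = ex.normalize_median_of_ratios(counts)
        assert factors["b"] / factors["a"] == pytest.approx(2.0)

    def test_zero_gene_excluded_from_reference(self):
        rng = np.random.default_rng(1)
        a = rng.integers(5, 200, size=30)
        counts = pd.DataFrame({"a": a, "b": a})
        factors_before, _ = ex.normalize_median_of_ratios(counts)
        with_zero = counts.copy()
        with_zero.loc[len(with_zero)] = [0, 17]  # zero in one sample
        factors_after, _ = ex.normalize_median_of_ratios(with_zero)
        # brute-force: the all-positive reference is unchanged, so factors match
        assert np.allclose(factors_before.to_numpy(), factors_after.to_numpy())

    def test_no_all_positive_gene_raises(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="pseudo-reference"):
            ex.normalize_median_of_ratios(counts)


def brute_force_bh(pvals):
    """Step-up definition: p_(i) * m / i, cumulative min from the largest."""
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, pvals[idx] * m / rank)
        adj[idx] = running
    return adj


class TestBenjaminiHochberg:
    def test_worked_example(self):
        adj = ex.benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.8]))
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.8])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_step_up_definition(self, pvals):
        p = np.array(pvals)
        assert np.allclose(ex.benjamini_hochberg(p), brute_force_bh(p))


class TestDifferentialExpression:
    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(2)
        base = rng.poisson(100, size=(200, 3)).astype(float)
        norm = pd.DataFrame(
            np.hstack([base, base]), columns=[f"s{i}" for i in range(6)]
        )
        de = ex.differential_expression(norm, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert de["significant"].sum() == 0
        assert (de["p_value"] == 1.0).all()  # duplicated columns: zero log2FC, ties

    def test_zero_variance_gene_p_one(self):
        norm = pd.DataFrame(
            {"a1": [5.0, 9], "a2": [5.0, 8], "b1": [5.0, 2], "b2": [5.0, 1]}
        )
        de = ex.differential_expression(norm, ["a1", "a2"], ["b1", "b2"])
        assert de.loc[de["gene"] == 0, "p_value"].iloc[0] == 1.0

    def test_missing_group_raises(self):
        norm = pd.DataFrame({"a1": [1.0], "a2": [1.0]})
        with pytest.raises(ValueError):
            ex.differential_expression(norm, ["a1", "a2"], ["nope1", "nope2"])

    def test_planted_recall_and_fdr(self):
        # 2000 genes, 10% planted at 4x, n=5 per group
        rng = np.random.default_rng(7)
        n_genes, n_planted, n = 2000, 200, 5
        mean = np.full((n_genes, 2 * n), 100.0)
        mean[:n_planted, :n] *= 4.0  # planted_log2fc = 2
        r = 10.0  # dispersion 0.1
        counts = rng.negative_binomial(r, r / (r + mean))
        norm = pd.DataFrame(
            counts.astype(float), columns=[f"s{i}" for i in range(2 * n)]
        )
        de = ex.differential_expression(
            norm, [f"s{i}" for i in range(n)], [f"s{i}" for i in range(n, 2 * n)]
        )
        called = set(de.loc[de["significant"], "gene"])
        planted = set(range(n_planted))
        recall = len(called & planted) / n_planted
        fdr = len(called - planted) / max(len(called), 1)
        assert recall >= 0.9
        assert fdr <= 0.1

    def test_significant_set_invariant_to_global_rescaling(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            rng.poisson(100, size=(300, 6)), columns=[f"s{i}" for i in range(6)]
        )
        counts.iloc[:30, :3] *= 5
        def sig(c):
            _, norm = ex.normalize_median_of_ratios(c)
            de = ex.differential_expression(norm, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
            return set(de.loc[de["significant"], "gene"])
        assert sig(counts) == sig(counts * 7)


class TestClassification:
    def _matrix(self, rows, labels):
        comps = (
            ["remote_tenocyte"] * 2 + ["adjacent_tenocyte"] * 2
            + ["attachment"] * 2 + ["adjacent_chondrocyte"] * 2
            + ["remote_chondrocyte"] * 2
        )
        counts = pd.DataFrame(
            rows, columns=[f"s{i}" for i in range(10)],
            index=labels,
        )
        return make_matrix(counts, comps)

    def test_mixed_vs_unclassified_rules(self):
        rng = np.random.default_rng(4)
        # 30 background genes keep normalization and BH realistic
        bg = rng.poisson(100, size=(30, 10))
        t_no_a = [400] * 4 + [0] * 2 + [100] * 4  # high in T, absent in A
        t_with_a = [400] * 4 + [200] * 2 + [100] * 4  # planted tenogenic
        flat = [150] * 10  # expressed everywhere, not DE
        rows = np.vstack([bg, t_no_a, t_with_a, flat])
        labels = [f"bg{i}" for i in range(30)] + ["tNoA", "tWithA", "flat"]
        matrix = self._matrix(rows, labels)
        _, norm = ex.normalize_median_of_ratios(matrix.counts)
        teno = matrix.samples_of(ex.TENOCYTE_COMPARTMENTS)
        chon = matrix.samples_of(ex.CHONDROCYTE_COMPARTMENTS)
        de = ex.differential_expression(norm, teno, chon, contrast="teno_vs_chondro")
        mixed = ex.classify_mixed_genes(de, norm, matrix)
        # high in T but silent in attachment: differential, yet not "mixed"
        assert mixed["tNoA"] == "unclassified"
        assert mixed["tWithA"] == "tenogenic_mixed"
        assert mixed["flat"] == "unclassified"
        out = ex.classify_genes(matrix).set_index("gene")["label"]
        assert out["tWithA"] == "tenogenic_mixed"
        assert out["flat"] == "unclassified"

    def test_attachment_unique_rules(self):
        rng = np.random.default_rng(5)
        bg = rng.poisson(100, size=(30, 10))
        uniform = [100] * 10
        att_up = [100] * 4 + [500] * 2 + [100] * 4
        up_vs_t_only = [50] * 4 + [200] * 2 + [200] * 4  # flat vs C
        rows = np.vstack([bg, uniform, att_up, up_vs_t_only])
        labels = [f"bg{i}" for i in range(30)] + ["uniform", "attUp", "upTOnly"]
        matrix = self._matrix(rows, labels)
        _, norm = ex.normalize_median_of_ratios(matrix.counts)
        up, down = ex.detect_attachment_unique(norm, matrix)
        assert "uniform" not in up and "uniform" not in down
        assert "attUp" in up
        assert "upTOnly" not in up

    def test_negative_threshold_raises(self):
        rng = np.random.default_rng(6)
        matrix = self._matrix(rng.poisson(100, size=(10, 10)), [f"g{i}" for i in range(10)])
        with pytest.raises(ValueError):
            ex.classify_genes(matrix, attachment_expr_threshold=-1)

    def test_every_gene_gets_exactly_one_label(self, pipeline_run):
        _, _, _, outdir = pipeline_run
        labels = pd.read_csv(outdir / "gene_labels.tsv", sep="\t")
        assert labels["gene"].is_unique
        assert labels["label"].isin(ex.GENE_CLASSES).all()


class TestSimilarity:
    def test_attachment_equal_to_tenocyte_profile(self):
        rng = np.random.default_rng(8)
        teno = rng.uniform(10, 1000, size=40)
        chondro = rng.uniform(10, 1000, size=40)
        cols = {}
        comps = []
        for comp in ex.COMPARTMENTS:
            base = chondro if "chondrocyte" in comp else teno
            for i in range(2):
                cols[f"{comp}_{i}"] = base
                comps.append(comp)
        counts = pd.DataFrame(cols)
        matrix = make_matrix(counts, comps)
        rep = ex.compartment_similarity(counts, matrix, list(range(40)))
        assert rep.closer_to == "tenocyte"
        assert rep.distance_to_tenocyte == pytest.approx(0.0, abs=1e-12)

    def test_midpoint_attachment_centroid_between_on_pc1(self):
        rng = np.random.default_rng(9)
        log_t = rng.uniform(2, 10, size=60)
        log_c = rng.uniform(2, 10, size=60)
        cols, comps = {}, {}
        comps = []
        for comp in ex.COMPARTMENTS:
            for i in range(3):
                if "tenocyte" in comp:
                    base = log_t
                elif "chondrocyte" in comp:
                    base = log_c
                else:
                    base = (log_t + log_c) / 2
                cols[f"{comp}_{i}"] = 2.0 ** (base + rng.normal(0, 0.05, size=60)) - 1
                comps.append(comp)
        counts = pd.DataFrame(cols).clip(lower=0)
        matrix = make_matrix(counts, comps)
        rep = ex.compartment_similarity(counts, matrix, list(range(60)))
        pc1 = rep.pca_coordinates.groupby("compartment")["PC1"].mean()
        t = (pc1["remote_tenocyte"] + pc1["adjacent_tenocyte"]) / 2
        c = (pc1["remote_chondrocyte"] + pc1["adjacent_chondrocyte"]) / 2
        a = pc1["attachment"]
        assert min(t, c) < a < max(t, c)
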