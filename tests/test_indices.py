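"""Weighted transcriptome indices, ENC, relative expression and RBH."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import phylotrx as px

from conftest import toy_stage_expression


def naive_index(expr, weights):
    """Loop-based oracle for the expression-weighted mean, per stage."""
    out = {}
    for stage in expr.stage_order:
        num = den = 0.0
        for gene in expr.values.index:
            if gene in weights.index and not np.isnan(weights[gene]):
                e = expr.values.loc[gene, stage]
                num += weights[gene] * e
                den += e
        out[stage] = num / den
    return pd.Series(out)


class TestWeightedIndex:
    def test_constant_weights_give_flat_profile(self):
        expr = toy_stage_expression([[1, 2], [3, 1], [2, 2]])
        w = pd.Series(5.0, index=expr.values.index)
        profile = px.weighted_transcriptome_index(expr, w)
        np.testing.assert_allclose(profile.values, 5.0)

    def test_hand_weighted_mean(self):
        expr = toy_stage_expression([[1.0], [3.0]])
        w = pd.Series([1.0, 5.0], index=["g0", "g1"])
        profile = px.weighted_transcriptome_index(expr, w)
        assert profile.values.iloc[0] == pytest.approx(4.0)  # (1*1+3*5)/(1+3)

    def test_stage_rescaling_invariance(self):
        expr = toy_stage_expression([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        w = pd.Series([1.0, 2.0, 3.0], index=expr.values.index)
        base = px.weighted_transcriptome_index(expr, w)
        scaled = toy_stage_expression(
            expr.values.to_numpy() * np.array([10.0, 1.0, 0.01])
        )
        rescaled = px.weighted_transcriptome_index(scaled, w)
        np.testing.assert_allclose(base.values, rescaled.values, rtol=1e-12)

    def test_missing_weights_excluded_and_counted(self):
        expr = toy_stage_expression([[1, 1], [1, 1], [1, 1]])
        w = pd.Series([2.0, np.nan, 4.0], index=expr.values.index)
        profile = px.weighted_transcriptome_index(expr, w)
        assert profile.n_genes_used == 2
        np.testing.assert_allclose(profile.values, 3.0)

    def test_zero_expression_stage_is_error(self):
        expr = toy_stage_expression([[1, 0], [2, 0]])
        w = pd.Series([1.0, 2.0], index=expr.values.index)
        with pytest.raises(ValueError, match="s1"):
            px.weighted_transcriptome_index(expr, w)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_naive_oracle_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        expr = toy_stage_expression(rng.uniform(0.01, 1.0, size=(20, 6)))
        w = pd.Series(rng.uniform(1, 18, 20), index=expr.values.index)
        profile = px.weighted_transcriptome_index(expr, w)
        np.testing.assert_allclose(profile.values, naive_index(expr, w), rtol=1e-12)
        assert (profile.values >= w.min() - 1e-12).all()
        assert (profile.values <= w.max() + 1e-12).all()

    def test_monotone_response_to_single_gene(self):
        rng = np.random.default_rng(1)
        expr = toy_stage_expression(rng.uniform(0.1, 1.0, size=(10, 3)))
        w = pd.Series(rng.uniform(1, 10, 10), index=expr.values.index)
        base = px.weighted_transcriptome_index(expr, w)
        top_gene = w.idxmax()  # weight above every stage value
        bumped = expr.values.copy()
        bumped.loc[top_gene] *= 2
        higher = px.weighted_transcriptome_index(
            px.StageExpression(values=bumped, stage_order=expr.stage_order), w
        )
        assert (higher.values > base.values).all()


class TestIndexFamilies:
    def test_all_same_ps_gives_constant_tai(self):
        expr = toy_stage_expression([[1, 2], [3, 4]])
        evol = px.GeneEvolStats(
            pd.DataFrame({"ps": [5, 5]}, index=expr.values.index)
        )
        np.testing.assert_allclose(px.tai(expr, evol).values, 5.0)

    def test_index_twins_use_their_weight(self, small_expr, small_catalog):
        evol = px.GeneEvolStats(
            small_catalog.table.rename(columns={"true_ps": "ps"})[["ps", "dN", "dS"]]
        )
        t1 = px.tai(small_expr, evol)
        t2 = px.tdni(small_expr, evol)
        t3 = px.tdsi(small_expr, evol)
        assert t1.weight_name == "ps" and t2.weight_name == "dN" and t3.weight_name == "dS"
        assert not np.allclose(t1.values, t2.values)

    def test_coupled_divergence_profiles_co_move(self, small_expr, small_catalog):
        # dN scale grows with ps in the generator, so TAI and TdNI profiles
        # must rank stages similarly
        from scipy.stats import spearmanr

        evol = px.GeneEvolStats(
            small_catalog.table.rename(columns={"true_ps": "ps"})[["ps", "dN", "dS"]]
        )
        rho, _ = spearmanr(px.tai(small_expr, evol).values, px.tdni(small_expr, evol).values)
        assert rho > 0

    def test_enc_capped_into_range(self):
        evol = px.GeneEvolStats(pd.DataFrame({"enc": [10.0, 70.0, 45.0]}, index=list("abc")))
        assert evol.table["enc"].tolist() == [20.0, 61.0, 45.0]


class TestCumulativeTai:
    def test_full_set_reproduces_tai(self, small_expr, small_catalog):
        evol = px.GeneEvolStats(
            small_catalog.table.rename(columns={"true_ps": "ps"})[["ps"]]
        )
        full = px.cumulative_tai(small_expr, evol, k=small_catalog.n_ps)
        np.testing.assert_allclose(full.values, px.tai(small_expr, evol).values, rtol=1e-12)

    def test_first_stratum_is_constant_one(self, small_expr, small_catalog):
        evol = px.GeneEvolStats(
            small_catalog.table.rename(columns={"true_ps": "ps"})[["ps"]]
        )
        np.testing.assert_allclose(px.cumulative_tai(small_expr, evol, k=1).values, 1.0)

    def test_hourglass_stabilizes_with_depth(self, small_expr, small_catalog, small_config):
        evol = px.GeneEvolStats(
            small_catalog.table.rename(columns={"true_ps": "ps"})[["ps"]]
        )
        argmins = {
            k: px.cumulative_tai(small_expr, evol, k).argmin_stage()
            for k in range(2, small_catalog.n_ps + 1)
        }
        # once enough strata are included the designed phylotypic minimum holds
        assert argmins[small_catalog.n_ps] == small_config.phylotypic_stage

    def test_out_of_range_k(self, small_expr, small_catalog):
        evol = px.GeneEvolStats(
            small_catalog.table.rename(columns={"true_ps": "ps"})[["ps"]]
        )
        with pytest.raises(ValueError):
            px.cumulative_tai(small_expr, evol, k=0)


class TestMinMaxNormalize:
    def test_hand_arithmetic(self):
        profile = px.IndexProfile(
            values=pd.Series([2.0, 5.0, 3.0], index=["a", "b", "c"]),
            n_genes_used=3,
            weight_name="ps",
        )
        norm = px.min_max_normalize_profile(profile)
        np.testing.assert_allclose(norm.values, [0.0, 1.0, 1 / 3], rtol=1e-12)

    def test_constant_profile_is_error(self):
        profile = px.IndexProfile(
            values=pd.Series([2.0, 2.0], index=["a", "b"]), n_genes_used=2, weight_name="ps"
        )
        with pytest.raises(ValueError, match="constant"):
            px.min_max_normalize_profile(profile)


class TestRelativeExpression:
    def test_two_gene_toy_matches_hand_computation(self):
        expr = toy_stage_expression([[1, 2, 3], [3, 2, 1], [5, 5, 8]])
        evol = px.GeneEvolStats(
            pd.DataFrame({"ps": [1, 2, 2]}, index=expr.values.index)
        )
        re = px.relative_expression(expr, evol)
        # stratum 1: (1,2,3) -> (0, 1/2, 1); stratum 2 means (4, 3.5, 4.5)
        np.testing.assert_allclose(re.loc[1], [0.0, 0.5, 1.0], rtol=1e-12)
        np.testing.assert_allclose(re.loc[2], [0.5, 0.0, 1.0], rtol=1e-12)

    def test_rows_span_unit_interval(self, small_expr, small_catalog):
        evol = px.GeneEvolStats(
            small_catalog.table.rename(columns={"true_ps": "ps"})[["ps"]]
        )
        re = px.relative_expression(small_expr, evol)
        np.testing.assert_allclose(re.min(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(re.max(axis=1), 1.0, atol=1e-12)

    def test_hand_oracle_on_stratum(self):
        expr = toy_stage_expression([[1.0, 4.0, 2.0], [3.0, 6.0, 3.0]])
        evol = px.GeneEvolStats(pd.DataFrame({"ps": [3, 3]}, index=expr.values.index))
        re = px.relative_expression(expr, evol)
        # means (2, 5, 2.5); min 2, max 5 -> (0, 1, 1/6)
        np.testing.assert_allclose(re.loc[3], [0.0, 1.0, 1 / 6], rtol=1e-12)

    def test_constant_stratum_is_error(self):
        expr = toy_stage_expression([[1.0, 1.0]])
        evol = px.GeneEvolStats(pd.DataFrame({"ps": [1]}, index=expr.values.index))
        with pytest.raises(ValueError, match="constant"):
            px.relative_expression(expr, evol)


class TestENC:
    def test_fully_biased_sequence_is_exactly_20(self):
        from phylotrx.indices import AA_DEGENERACY
        from phylotrx.synthetic import _FAMILY_CODONS

        seq = "".join(_FAMILY_CODONS[aa][0] * 3 for aa in sorted(AA_DEGENERACY))
        assert px.effective_number_of_codons(seq) == pytest.approx(20.0)

    def test_uniform_usage_near_61(self):
        rng = np.random.default_rng(0)
        from phylotrx.synthetic import _FAMILY_CODONS

        fams = sorted(_FAMILY_CODONS)
        seq = "".join(
            _FAMILY_CODONS[a][rng.integers(len(_FAMILY_CODONS[a]))]
            for a in rng.choice(fams, 10000)
        )
        assert 59.0 <= px.effective_number_of_codons(seq) <= 61.0

    def test_internal_stop_rejected_but_skippable(self):
        seq = "ATGTAAGCT"
        with pytest.raises(ValueError, match="stop"):
            px.effective_number_of_codons(seq)
        # skipping the stop leaves too few degenerate codons -> still an error,
        # but a different one
        with pytest.raises(ValueError, match="family"):
            px.effective_number_of_codons(seq, on_bad_codon="skip")

    def test_terminal_stop_allowed(self):
        seq = "GCTGCAGCTGCA" + "TAA"
        assert px.effective_number_of_codons(seq) > 0

    def test_duplication_invariance_large_n(self):
        cfg = px.SimulationConfig(n_genes=2, n_ps=2, seed=5)
        cat = px.simulate_gene_catalog(cfg)
        cds = px.simulate_cds(cat, seed=5)
        seq = max(cds.values(), key=len)
        if len(seq) < 24000:  # the estimator's 1/n bias decays slowly
            seq = seq * (24000 // len(seq) + 1)
        one = px.effective_number_of_codons(seq)
        two = px.effective_number_of_codons(seq * 2)
        assert abs(one - two) < 0.1

    def test_non_triplet_length_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            px.effective_number_of_codons("ATGC")


class TestRBH:
    def mk(self, rows):
        return pd.DataFrame(rows, columns=["query", "subject", "evalue", "bitscore"])

    def test_mutual_best_pair_retained(self):
        ab = self.mk([("A1", "B1", 1e-50, 300.0)])
        ba = self.mk([("B1", "A1", 1e-50, 300.0)])
        pairs = px.reciprocal_best_hits(ab, ba)
        assert pairs.values.tolist() == [["A1", "B1"]]

    def test_reciprocity_failure_drops_pair(self):
        ab = self.mk([("A1", "B1", 1e-50, 300.0)])
        ba = self.mk([("B1", "A2", 1e-60, 400.0), ("B1", "A1", 1e-50, 300.0)])
        assert px.reciprocal_best_hits(ab, ba).empty

    def test_e_threshold_applied(self):
        ab = self.mk([("A1", "B1", 1e-3, 300.0)])
        ba = self.mk([("B1", "A1", 1e-50, 300.0)])
        assert px.reciprocal_best_hits(ab, ba, e_threshold=1e-5).empty

    def test_deterministic_tie_break(self):
        ab = self.mk([("A1", "B2", 1e-50, 300.0), ("A1", "B1", 1e-50, 300.0)])
        ba = self.mk([("B1", "A1", 1e-50, 300.0), ("B2", "A1", 1e-50, 300.0)])
        pairs = px.reciprocal_best_hits(ab, ba)
        assert pairs.values.tolist() == [["A1", "B1"]]  # lexicographic tie-break

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        score = rng.integers(1, 1000, size=(5, 5)).astype(float)
        a_ids = [f"A{i}" for i in range(5)]
        b_ids = [f"B{j}" for j in range(5)]
        ab = self.mk(
            [(a_ids[i], b_ids[j], 1e-20, score[i, j]) for i in range(5) for j in range(5)]
        )
        ba = self.mk(
            [(b_ids[j], a_ids[i], 1e-20, score[i, j]) for i in range(5) for j in range(5)]
        )
        pairs = px.reciprocal_best_hits(ab, ba)
        # brute force over all (i, j): mutual argmax of the score matrix,
        # ties broken toward the lexicographically smaller partner id
        expected = []
        for i in range(5):
            best_j = min(range(5), key=lambda j: (-score[i, j], b_ids[j]))
            best_i = min(range(5), key=lambda k: (-score[k, best_j], a_ids[k]))
            if best_i == i:
                expected.append([a_ids[i], b_ids[best_j]])
        assert pairs.values.tolist() == sorted(expected)


class TestDivergenceTable:
    def test_roundtrip(self, tmp_path, small_catalog):
        p = tmp_path / "div.tsv"
        small_catalog.table[["dN", "dS"]].to_csv(p, sep="\t", index_label="gene")
        back = px.read_divergence_table(p)
        pd.testing.assert_frame_equal(back, small_catalog.table[["dN", "dS"]])

    def test_empty_table_gives_no_values(self, tmp_path):
        p = tmp_path / "div.tsv"
        p.write_text("gene\tdN\tdS\n")
        assert px.read_divergence_table(p).empty

    def test_duplicate_genes_rejected(self, tmp_path):
        p = tmp_path / "div.tsv"
        p.write_text("gene\tdN\tdS\ng1\t0.1\t0.2\ng1\t0.3\t0.4\n")
        with pytest.raises(ValueError, match="duplicate"):
            px.read_divergence_table(p)

    def test_malformed_rows_reported_with_line_numbers(self, tmp_path):
        p = tmp_path / "div.tsv"
        p.write_text("gene\tdN\tdS\ng1\t0.1\t0.2\ng2\tnot_a_number\t0.4\n")
        with pytest.raises(ValueError, match="line 3"):
            px.read_divergence_table(p)
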