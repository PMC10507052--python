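"""ssGSEA, diversity-proxy and pathway-network tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hexspot import preprocess, signatures
from hexspot.containers import GeneSetCollection, SpotMatrix
from hexspot.errors import InvalidArgumentError
from hexspot.synthdata import make_visium_lattice
from scipy import sparse


class TestSsgseaScores:
    def test_top_gene_set_beats_bottom_gene_set(self):
        norm = pd.DataFrame({"s1": [5.0, 4.0, 3.0, 2.0, 1.0]},
                            index=[f"g{i}" for i in range(1, 6)])
        sets = GeneSetCollection({"TOP": {"g1"}, "BOTTOM": {"g5"}})
        scores = signatures.ssgsea_scores(norm, sets, min_set_size=1)
        assert scores.loc["TOP", "s1"] > scores.loc["BOTTOM", "s1"]

    def test_hand_enumerated_running_sum(self):
        # 5-gene universe, expression 5>4>3>2>1, set {g1, g3}, alpha=0.25.
        # Walking the descending ranking, the in-set CDF steps are
        # 5^0.25/(5^0.25+3^0.25) at g1 and the rest at g3; the out-set CDF
        # steps 1/3 at g2, g4, g5.  Integrated difference:
        a = 5 ** 0.25 / (5 ** 0.25 + 3 ** 0.25)
        expected = (a) + (a - 1 / 3) + (1 - 1 / 3) + (1 - 2 / 3) + (1 - 1)
        norm = pd.DataFrame({"s1": [5.0, 4.0, 3.0, 2.0, 1.0]},
                            index=["g1", "g2", "g3", "g4", "g5"])
        sets = GeneSetCollection({"S": {"g1", "g3"}})
        scores = signatures.ssgsea_scores(norm, sets)
        assert scores.loc["S", "s1"] == pytest.approx(expected, rel=1e-12)

    def test_monotone_transform_invariance(self, st_norm):
        sets = GeneSetCollection({"S": set(st_norm.index[:10])})
        sub = st_norm.iloc[:, :20]
        s1 = signatures.ssgsea_scores(sub, sets)
        s2 = signatures.ssgsea_scores(np.exp(sub) + 7.0, sets)
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), rtol=1e-12)

    def test_gene_order_within_set_irrelevant(self):
        rng = np.random.default_rng(0)
        norm = pd.DataFrame(rng.normal(size=(20, 5)),
                            index=[f"g{i}" for i in range(20)],
                            columns=[f"s{j}" for j in range(5)])
        a = signatures.ssgsea_scores(norm, GeneSetCollection({"S": {"g3", "g7", "g11"}}))
        b = signatures.ssgsea_scores(norm, GeneSetCollection({"S": {"g11", "g3", "g7"}}))
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy())

    def test_small_sets_skipped(self, caplog):
        norm = pd.DataFrame({"s1": [1.0, 2.0, 3.0]}, index=["g1", "g2", "g3"])
        sets = GeneSetCollection({"TINY": {"g1"}, "OK": {"g1", "g2"}})
        scores = signatures.ssgsea_scores(norm, sets, min_set_size=2)
        assert list(scores.index) == ["OK"]

    def test_empty_collection_rejected(self, st_norm):
        with pytest.raises(InvalidArgumentError):
            signatures.ssgsea_scores(st_norm, GeneSetCollection({}))

    def test_planted_signature_region_scores_higher(self, st_sim, st_norm):
        _, _, truth = st_sim
        sets = GeneSetCollection({"SIG": set(truth.signature_genes)})
        scores = signatures.ssgsea_scores(st_norm, sets)
        in_region = truth.labels["subtype"] == truth.signature_region
        s = scores.loc["SIG"]
        from scipy.stats import mannwhitneyu
        _, p = mannwhitneyu(s[in_region.to_numpy()], s[~in_region.to_numpy()],
                            alternative="greater")
        assert p < 0.01


class TestScoreSubtypeComparison:
    def test_identical_scores_not_significant(self):
        scores = pd.DataFrame(np.ones((1, 9)), index=["S"],
                              columns=[f"s{i}" for i in range(9)])
        subtype = pd.Series(["A", "B", "C"] * 3, index=scores.columns)
        table = signatures.score_subtype_comparison(scores, subtype)
        assert table.loc["S", "p"] == pytest.approx(1.0)
        assert len(table.attrs["dunn"]["S"]) == 3

    def test_planted_region_effect_detected(self, st_sim, st_norm):
        _, _, truth = st_sim
        sets = GeneSetCollection({"SIG": set(truth.signature_genes)})
        scores = signatures.ssgsea_scores(st_norm, sets)
        table = signatures.score_subtype_comparison(scores,
                                                    truth.labels["subtype"])
        assert table.loc["SIG", "p"] < 0.01


class TestDiversityScore:
    def _sm(self, counts):
        counts = np.asarray(counts)
        return SpotMatrix(genes=[f"g{i}" for i in range(counts.shape[0])],
                          spots=[f"s{j}" for j in range(counts.shape[1])],
                          counts=sparse.csr_matrix(counts))

    def test_counts_expressed_genes(self):
        sm = self._sm([[1, 0], [2, 0], [3, 5]])
        div = signatures.diversity_score(sm)
        assert div.tolist() == [3.0, 1.0]

    def test_depth_invariance_without_new_genes(self):
        a = self._sm([[1, 4], [0, 2]])
        b = self._sm([[2, 8], [0, 4]])
        assert signatures.diversity_score(a).tolist() == \
            signatures.diversity_score(b).tolist()

    def test_smoothed_interior_is_seven_spot_mean(self):
        lat = make_visium_lattice(3, 3)
        from hexspot.preprocess import build_neighbor_graph
        graph = build_neighbor_graph(lat)
        counts = np.zeros((10, 9), dtype=int)
        rng = np.random.default_rng(1)
        for j in range(9):
            counts[: rng.integers(1, 10), j] = 1
        sm = SpotMatrix(genes=[f"g{i}" for i in range(10)],
                        spots=lat.spot_ids, counts=sparse.csr_matrix(counts))
        raw = signatures.diversity_score(sm)
        smoothed = signatures.diversity_score(sm, graph)
        center = lat.table.query("array_row == 1 and array_col == 1").index[0]
        members = [center] + graph.neighbors(center)
        assert smoothed[center] == pytest.approx(raw[members].mean())


class TestDifferentiationCorrelatedGenes:
    def test_score_as_pseudo_gene_ranks_first(self, st_norm, st_sim):
        sm, _, _ = st_sim
        div = signatures.diversity_score(sm)
        norm = pd.concat([st_norm,
                          div.rename("PSEUDO").to_frame().T.astype(float)])
        table = signatures.differentiation_correlated_genes(norm, div)
        assert table.gene.iloc[0] == "PSEUDO"
        assert table.coefficient.iloc[0] == pytest.approx(1.0)

    def test_planted_gradient_genes_land_in_extremes(self, st_norm, st_sim):
        sm, _, _ = st_sim
        div = signatures.diversity_score(sm)
        rng = np.random.default_rng(5)
        noise = rng.normal(0, 0.1 * div.std(), size=len(div))
        up = pd.Series(div.to_numpy() + noise, index=st_norm.columns, name="UP")
        down = pd.Series(-div.to_numpy() + noise, index=st_norm.columns,
                         name="DOWN")
        norm = pd.concat([st_norm, up.to_frame().T, down.to_frame().T])
        table = signatures.differentiation_correlated_genes(norm, div)
        decile = max(1, len(table) // 10)
        assert "UP" in set(table.gene.head(decile))
        assert "DOWN" in set(table.gene.tail(decile))

    def test_constant_gene_untestable(self, st_norm, st_sim):
        sm, _, _ = st_sim
        div = signatures.diversity_score(sm)
        flat = pd.DataFrame(np.ones((1, st_norm.shape[1])), index=["FLAT"],
                            columns=st_norm.columns)
        table = signatures.differentiation_correlated_genes(
            pd.concat([st_norm, flat]), div)
        row = table[table.gene == "FLAT"].iloc[0]
        assert not row.testable and np.isnan(row.coefficient)


class TestPathwayNetwork:
    def test_half_overlap(self):
        sets = GeneSetCollection({"P1": {"A", "B", "C"}, "P2": {"B", "C", "D"}})
        g = signatures.pathway_jaccard_network(sets)
        assert g["P1"]["P2"]["weight"] == pytest.approx(0.5)

    def test_disjoint_sets_no_edge(self):
        sets = GeneSetCollection({"P1": {"A"}, "P2": {"B"}})
        g = signatures.pathway_jaccard_network(sets)
        assert g.number_of_edges() == 0

    def test_identical_sets_weight_one(self):
        sets = GeneSetCollection({"P1": {"A", "B"}, "P2": {"A", "B"}})
        g = signatures.pathway_jaccard_network(sets)
        assert g["P1"]["P2"]["weight"] == 1.0

    @settings(deadline=None, max_examples=40)
    @given(trip=st.tuples(*[st.sets(st.integers(0, 8), min_size=1, max_size=6)
                            for _ in range(3)]))
    def test_jaccard_complement_is_metric(self, trip):
        def jd(x, y):  # 1 - Jaccard distance
            return 1 - len(x & y) / len(x | y)
        a, b, c = (frozenset(s) for s in trip)
        assert jd(a, a) == 0
        assert jd(a, b) == jd(b, a)
        assert jd(a, c) <= jd(a, b) + jd(b, c) + 1e-12
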