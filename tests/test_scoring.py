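"""Normalization, scoring, ranking and isomer-weight regression."""

import numpy as np
import pytest

from graphin import (
    DiseaseFamily,
    InteractionNetwork,
    build_feature_matrix,
    fit_weights,
    normalize,
    outflow_totals,
    score_genes,
)
from graphin.scoring import (
    FeatureMatrix,
    ScoreTable,
    normalization_set,
    summed_normalized,
)
from graphin.synth import protocol_fixture, schema_fixtures

from conftest import random_networks

SMALL = [1, 2, 3, 4, 5]


class TestNormalization:
    def test_single_target_normalizes_to_one(self, icat):
        net = InteractionNetwork([("d", "x"), ("x", "y"), ("d", "y")])
        totals = outflow_totals(net, "d", {"x"}, icat)
        from graphin.counting import pair_counts
        v = pair_counts(net, "d", "x", icat)
        normed = normalize(v.counts, totals)
        nz = v.counts > 0
        assert np.allclose(normed[nz], 1.0)
        assert np.all(normed[~nz] == 0)

    def test_zero_vector_stays_zero(self):
        assert np.all(normalize(np.zeros(28), np.zeros(28)) == 0)

    def test_zero_total_yields_zero_not_nan(self):
        counts = np.zeros(28)
        counts[0] = 0
        totals = np.zeros(28)
        out = normalize(counts, totals)
        assert np.all(np.isfinite(out)) and np.all(out == 0)

    def test_closure_over_normalization_set(self, icat):
        """Normalized values sum to 1 across the set for every isomer the
        disease gene exhibits at all."""
        from graphin.counting import pair_counts
        net = random_networks(1, seed=31)[0]
        i = sorted(net.nodes)[0]
        others = sorted(net.nodes - {i})
        totals = outflow_totals(net, i, others, icat)
        acc = np.zeros(28)
        for j in others:
            acc += normalize(pair_counts(net, i, j, icat).counts, totals)
        nz = totals > 0
        assert np.allclose(acc[nz], 1.0)
        assert np.all(acc[~nz] == 0)

    def test_outflow_errors(self, triangle, icat):
        with pytest.raises(ValueError):
            outflow_totals(triangle, "A", set(), icat)
        with pytest.raises(ValueError):
            outflow_totals(triangle, "A", {"A", "B"}, icat)

    def test_star_center_edge_total(self, star4, icat):
        totals = outflow_totals(star4, "c", {"l1", "l2", "l3"}, icat)
        assert totals[0] == 3  # I1 outflow equals the edges into the set

    def test_totals_bound_individual_counts(self, icat):
        from graphin.counting import pair_counts
        net = random_networks(1, seed=37)[0]
        i = sorted(net.nodes)[0]
        others = sorted(net.nodes - {i})
        totals = outflow_totals(net, i, others, icat)
        for j in others:
            assert np.all(pair_counts(net, i, j, icat).counts <= totals)


class TestWorkedExamples:
    def test_protocol_network_node2(self, icat):
        """Two disease genes, five small isomers, unit weights: node 2
        collects 0.83 + 0 + 0 + 1.67 + 1 = 3.5."""
        net, family = protocol_fixture()
        table = score_genes(net, family, isomers=SMALL, norm_mode="all")
        assert table.score_of("2") == pytest.approx(3.5, abs=1e-12)
        assert table.rank_of("2") == 1

    def test_protocol_summed_normalized_vector(self, icat):
        net, family = protocol_fixture()
        totals = {i: outflow_totals(net, i, net.nodes - {i}, icat)
                  for i in family.known_genes}
        v = summed_normalized(net, sorted(family.known_genes), "2",
                              totals, icat)
        assert np.round(v[:5], 2).tolist() == [0.83, 0.0, 0.0, 1.67, 1.0]

    def test_high_degree_schema_scores(self, icat):
        (net, fam), _ = schema_fixtures()
        table = score_genes(net, fam, isomers=SMALL, norm_mode="all")
        assert table.score_of("B") == pytest.approx(2.0)
        assert table.score_of("C") == pytest.approx(1.0)

    def test_high_degree_schema_vectors(self, icat):
        from graphin.counting import pair_counts
        (net, _), _ = schema_fixtures()
        assert pair_counts(net, "A", "B", icat).restrict(SMALL).tolist() == \
            [1, 0, 1, 3, 0]
        assert pair_counts(net, "A", "C", icat).restrict(SMALL).tolist() == \
            [1, 0, 1, 0, 0]

    def test_shared_complex_schema_scores(self, icat):
        _, (net, fam) = schema_fixtures()
        table = score_genes(net, fam, isomers=SMALL, norm_mode="all")
        assert table.score_of("B") == pytest.approx(1.0)
        assert table.score_of("C") == pytest.approx(0.75)
        # B wins although only C is adjacent to the disease gene
        assert net.a("A", "C") == 1 and net.a("A", "B") == 0


class TestScoreGenes:
    def test_zero_weights_zero_scores(self, icat):
        net, family = protocol_fixture()
        table = score_genes(net, family, np.zeros(28))
        assert all(s == 0 for s in table.as_dict().values())

    def test_empty_disease_set_rejected(self, icat):
        net, _ = protocol_fixture()
        fam = DiseaseFamily("empty", frozenset(), frozenset({"2"}))
        with pytest.raises(ValueError):
            score_genes(net, fam)

    def test_gene_absent_from_network_scores_zero(self, icat, caplog):
        net, family = protocol_fixture()
        fam = DiseaseFamily(family.family_id, family.known_genes,
                            family.candidates | {"ghost"})
        table = score_genes(net, fam)
        assert table.score_of("ghost") == 0.0

    def test_scores_nonnegative_and_additive_over_disease_genes(self, icat):
        net, family = protocol_fixture()
        both = score_genes(net, family, norm_mode="all", genes=["2", "4", "5"])
        parts = []
        for i in sorted(family.known_genes):
            fam_i = DiseaseFamily("f", frozenset({i}), family.candidates)
            parts.append(score_genes(net, fam_i, norm_mode="all",
                                     genes=["2", "4", "5"]))
        for g in ["2", "4", "5"]:
            assert both.score_of(g) >= 0
            assert both.score_of(g) == pytest.approx(
                sum(p.score_of(g) for p in parts))

    def test_adding_disease_edge_never_decreases_score(self, icat):
        """With non-negative unit weights, linking a candidate to a disease
        gene cannot lower that candidate's score (checked empirically)."""
        import networkx as nx
        rng = np.random.default_rng(5)
        for seed in range(4):
            g = nx.gnp_random_graph(10, 0.3, seed=seed)
            net = InteractionNetwork.from_networkx(g)
            nodes = sorted(net.nodes)
            d, j = nodes[0], nodes[-1]
            if net.a(d, j):
                continue
            fam = DiseaseFamily("f", frozenset({d}), frozenset(nodes[1:]))
            before = score_genes(net, fam, norm_mode="all").score_of(j)
            g2 = g.copy()
            g2.add_edge(int(d), int(j))
            net2 = InteractionNetwork.from_networkx(g2)
            after = score_genes(net2, fam, norm_mode="all").score_of(j)
            assert after >= before - 1e-12

    def test_rank_tie_break_lexicographic(self):
        table = ScoreTable.from_scores({"b": 1.0, "a": 1.0, "c": 2.0})
        assert table.frame["gene"].tolist() == ["c", "a", "b"]
        assert table.frame["rank"].tolist() == [1, 2, 3]

    def test_normalization_set_modes(self, icat):
        net, family = protocol_fixture()
        assert normalization_set(net, family, "1", "all") == \
            frozenset({"2", "3", "4", "5"})
        fam = DiseaseFamily("f", frozenset({"1", "3"}), frozenset({"2", "4"}))
        assert normalization_set(net, fam, "1", "candidates") == \
            frozenset({"2", "3", "4"})


class TestFeatureMatrix:
    def test_disconnected_candidate_row_is_zero(self, icat):
        net = InteractionNetwork([("d1", "d2"), ("d1", "x")], nodes=["iso"])
        fam = DiseaseFamily("f", frozenset({"d1", "d2"}),
                            frozenset({"iso", "x", "d1", "d2"}))
        fm = build_feature_matrix(net, [fam], icat)
        row = dict(zip(fm.rows, fm.X))["f", "iso"]
        assert np.all(row == 0)
        labels = dict(zip(fm.rows, fm.labels))
        assert labels["f", "iso"] == 0 and labels["f", "d1"] == 1

    def test_disease_rows_exclude_self(self, icat):
        """A disease gene's own row is computed against D minus itself, so a
        2-gene family gives it exactly the other gene's normalized vector."""
        net = InteractionNetwork([("d1", "d2"), ("d2", "x"), ("d1", "x")])
        fam = DiseaseFamily("f", frozenset({"d1", "d2"}),
                            frozenset({"d1", "d2", "x"}))
        fm = build_feature_matrix(net, [fam], icat)
        row_d1 = dict(zip(fm.rows, fm.X))["f", "d1"]
        totals = outflow_totals(net, "d2",
                                normalization_set(net, fam, "d2"), icat)
        expected = summed_normalized(net, ["d2"], "d1", {"d2": totals}, icat)
        assert np.allclose(row_d1, expected)

    def test_entries_bounded_by_family_size(self, icat):
        net = random_networks(1, seed=41)[0]
        nodes = sorted(net.nodes)
        fam = DiseaseFamily("f", frozenset(nodes[:3]), frozenset(nodes[:8]))
        fm = build_feature_matrix(net, [fam], icat)
        assert fm.X.min() >= 0
        assert fm.X.max() <= len(fam.known_genes)

    def test_no_usable_family_is_error(self, icat):
        net = InteractionNetwork([("a", "b")])
        fam = DiseaseFamily("f", frozenset({"a"}), frozenset({"a", "b"}))
        with pytest.raises(ValueError):
            build_feature_matrix(net, [fam], icat)
        with pytest.raises(ValueError):
            build_feature_matrix(net, [], icat)


class TestFitWeights:
    def test_recovers_known_weights_noiselessly(self):
        rng = np.random.default_rng(17)
        X = rng.uniform(0, 2, size=(200, 28))
        v_true = rng.normal(size=28)
        fm = FeatureMatrix(X, X @ v_true, tuple(("f", str(r)) for r in range(200)),
                           tuple(range(1, 29)))
        v = fit_weights(fm)
        assert np.max(np.abs(v - v_true)) < 1e-8

    def test_one_hot_rows_return_labels(self):
        X = np.eye(28)
        s = np.arange(28.0)
        fm = FeatureMatrix(X, s, tuple(("f", str(r)) for r in range(28)),
                           tuple(range(1, 29)))
        assert np.allclose(fit_weights(fm), s)

    def test_duplicated_rows_still_solvable(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.uniform(size=(10, 28))] * 2)
        s = np.concatenate([np.ones(10), np.ones(10)])
        fm = FeatureMatrix(X, s, tuple(("f", str(r)) for r in range(20)),
                           tuple(range(1, 29)))
        assert np.all(np.isfinite(fit_weights(fm)))

    def test_all_zero_matrix_is_error(self):
        fm = FeatureMatrix(np.zeros((5, 28)), np.zeros(5),
                           tuple(("f", str(r)) for r in range(5)),
                           tuple(range(1, 29)))
        with pytest.raises(ValueError):
            fit_weights(fm)
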