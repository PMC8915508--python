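"""Multimorbidity-network arithmetic against brute-force and dense oracles."""

import math
from datetime import date

import networkx as nx
import numpy as np
import pytest

from losnet.network import (
    build_mn,
    build_patient_disease_matrix,
    cooccurrence_counts,
    edge_table,
    eigenvector_centrality,
    katz_ci,
    katz_dispersion,
    relative_risk,
)

from conftest import make_record


def brute_force_counts(disease_sets, codes):
    """O(patients · pairs) pair counting, the oracle for the sparse product."""
    k = len(codes)
    table = np.zeros((k, k), dtype=int)
    for s in disease_sets:
        idx = [codes.index(c) for c in s]
        for a in idx:
            for b in idx:
                table[a, b] += 1
    return table


class TestPatientDiseaseMatrix:
    def test_or_aggregation_over_records(self):
        catalog_codes = {"A01", "B02", "C03"}
        from losnet.records import ChronicDiseaseCatalog

        cat = ChronicDiseaseCatalog.from_codes(catalog_codes)
        recs = [
            make_record(record_id="R1", patient_id="P1",
                        diagnoses=(("A01", True), ("B02", False))),
            make_record(record_id="R2", patient_id="P1",
                        diagnoses=(("B02", True), ("C03", True))),
        ]
        M = build_patient_disease_matrix(recs, cat)
        assert M.patient_ids == ["P1"]
        assert M.disease_codes == ["A01", "B02", "C03"]
        assert M.matrix.toarray().tolist() == [[1, 1, 1]]

    def test_disjoint_patients_give_identity_pattern(self):
        from losnet.records import ChronicDiseaseCatalog

        cat = ChronicDiseaseCatalog.from_codes({"A01", "B02"})
        recs = [
            make_record(record_id="R1", patient_id="P1",
                        diagnoses=(("A01", True),)),
            make_record(record_id="R2", patient_id="P2",
                        diagnoses=(("B02", True),)),
        ]
        M = build_patient_disease_matrix(recs, cat)
        assert M.matrix.toarray().tolist() == [[1, 0], [0, 1]]

    def test_non_catalog_code_contributes_no_column(self):
        from losnet.records import ChronicDiseaseCatalog

        cat = ChronicDiseaseCatalog.from_codes({"A01"})
        recs = [make_record(diagnoses=(("A01", True), ("Z99", True)))]
        M = build_patient_disease_matrix(recs, cat)
        assert M.disease_codes == ["A01"]

    def test_era_restriction(self):
        from losnet.records import ChronicDiseaseCatalog

        cat = ChronicDiseaseCatalog.from_codes({"A01", "B02"})
        recs = [
            make_record(record_id="R1", patient_id="P1",
                        admission=date(2016, 1, 1), diagnoses=(("A01", True),)),
            make_record(record_id="R2", patient_id="P1",
                        admission=date(2018, 1, 1), diagnoses=(("B02", True),)),
        ]
        M = build_patient_disease_matrix(
            recs, cat, era=(date(2015, 1, 1), date(2017, 12, 31)))
        assert M.disease_codes == ["A01"]


class TestCooccurrence:
    def test_matches_brute_force_on_tiny_fixture(self, tiny_cohort):
        records, truth = tiny_cohort
        M = build_patient_disease_matrix(records, truth.catalog())
        sets = [
            {M.disease_codes[j] for j in M.matrix[i].nonzero()[1]}
            for i in range(M.n_patients)
        ]
        expected = brute_force_counts(sets, M.disease_codes)
        assert (cooccurrence_counts(M) == expected).all()

    def test_single_patient_two_diseases(self):
        from losnet.records import ChronicDiseaseCatalog

        cat = ChronicDiseaseCatalog.from_codes({"A01", "B02"})
        M = build_patient_disease_matrix(
            [make_record(diagnoses=(("A01", True), ("B02", True)))], cat)
        counts = cooccurrence_counts(M)
        assert counts.tolist() == [[1, 1], [1, 1]]


class TestRelativeRisk:
    def test_hand_value(self):
        assert relative_risk(10, 20, 50, 1000) == pytest.approx(10.0)

    def test_independence_point(self):
        assert relative_risk(1, 20, 50, 1000) == pytest.approx(1.0)

    def test_no_cooccurrence(self):
        assert relative_risk(0, 20, 50, 1000) == 0.0

    def test_symmetry(self):
        assert relative_risk(7, 30, 80, 500) == relative_risk(7, 80, 30, 500)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            relative_risk(0, 0, 50, 1000)


class TestKatzCI:
    def test_sigma_as_printed_hand_value(self):
        sigma = katz_dispersion(10, 20, 50, 1000)
        assert sigma == pytest.approx(0.1 + 0.001 - 0.001 - 1e-6, abs=1e-12)

    def test_ci_as_printed_hand_values(self):
        lo, hi = katz_ci(10.0, 10, 20, 50, 1000)
        assert lo == pytest.approx(10 * math.exp(-2.58 * 0.099999), abs=1e-9)
        assert hi == pytest.approx(10 * math.exp(2.58 * 0.099999), abs=1e-9)
        # printed-precision sanity on the ≈(7.725, 12.944) hand interval
        assert lo == pytest.approx(7.725, abs=2e-3)
        assert hi == pytest.approx(12.944, abs=2e-3)

    def test_sqrt_mode_widens_small_count_interval(self):
        lo_p, hi_p = katz_ci(10.0, 10, 20, 50, 1000, sigma_mode="as_printed")
        lo_s, hi_s = katz_ci(10.0, 10, 20, 50, 1000, sigma_mode="sqrt")
        assert hi_s > hi_p and lo_s < lo_p   # σ<1 here, so sqrt is larger

    def test_zero_multiplier_degenerates_to_point(self):
        assert katz_ci(10.0, 10, 20, 50, 1000, z=0.0) == (10.0, 10.0)

    def test_undefined_for_zero_cooccurrence(self):
        with pytest.raises(ValueError):
            katz_ci(0.0, 0, 20, 50, 1000)

    def test_ci_width_shrinks_as_counts_grow_with_fixed_ratios(self):
        widths = []
        for scale in (1, 4, 16):
            rr = relative_risk(10 * scale, 20 * scale, 50 * scale, 1000 * scale)
            lo, hi = katz_ci(rr, 10 * scale, 20 * scale, 50 * scale,
                             1000 * scale)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]


class TestBuildMn:
    def test_all_rule_matches_brute_force_pair_count(self, tiny_cohort):
        records, truth = tiny_cohort
        M = build_patient_disease_matrix(records, truth.catalog())
        counts = cooccurrence_counts(M)
        iu, ju = np.triu_indices(len(M.disease_codes), k=1)
        expected_edges = int((counts[iu, ju] >= 1).sum())
        g = build_mn(M, edge_rule="all")
        assert g.number_of_edges() == expected_edges

    def test_edge_attributes_complete_and_consistent(self, tiny_cohort):
        records, truth = tiny_cohort
        M = build_patient_disease_matrix(records, truth.catalog())
        g = build_mn(M, edge_rule="all")
        for _, _, d in g.edges(data=True):
            assert d["rr"] > 0
            assert d["ci_low"] <= d["rr"] <= d["ci_high"]
            assert d["c_ij"] >= 1

    def test_min_pair_count_prunes_candidates(self, small_cohort):
        records, truth = small_cohort
        M = build_patient_disease_matrix(records, truth.catalog())
        g1 = build_mn(M, edge_rule="all", min_pair_count=1)
        g5 = build_mn(M, edge_rule="all", min_pair_count=5)
        assert g5.number_of_edges() <= g1.number_of_edges()
        assert all(d["c_ij"] >= 5 for _, _, d in g5.edges(data=True))

    def test_edge_table_export_columns(self, tiny_cohort):
        records, truth = tiny_cohort
        M = build_patient_disease_matrix(records, truth.catalog())
        df = edge_table(build_mn(M, edge_rule="all"))
        assert list(df.columns) == [
            "disease_i", "disease_j", "c_ij", "rr", "ci_low", "ci_high"]


class TestEigenvectorCentrality:
    def test_complete_graph_scores_equal(self):
        g = nx.complete_graph(5)
        g = nx.relabel_nodes(g, {i: f"D{i:02d}" for i in range(5)})
        scores = eigenvector_centrality(g, weight_mode="binary")
        for v in scores.values():
            assert v == pytest.approx(1 / math.sqrt(5), abs=1e-9)

    def test_star_center_dominates_leaves(self):
        g = nx.star_graph(6)
        scores = eigenvector_centrality(g, weight_mode="binary")
        assert all(scores[0] > scores[k] for k in range(1, 7))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_eigendecomposition(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        g = nx.gnp_random_graph(n, 0.3, seed=seed)
        for u, v in g.edges:
            g[u][v]["rr"] = float(rng.uniform(0.5, 10))
        scores = eigenvector_centrality(g)
        # dense oracle per connected component
        for comp in nx.connected_components(g):
            nodes = sorted(comp)
            if len(nodes) == 1:
                continue
            a = nx.to_numpy_array(g, nodelist=nodes, weight="rr")
            w, v = np.linalg.eigh(a)
            x = np.abs(v[:, np.argmax(w)])
            x /= np.linalg.norm(x)
            got = np.array([scores[u] for u in nodes])
            assert np.max(np.abs(got - x)) < 1e-6

    def test_scaling_invariance(self):
        rng = np.random.default_rng(0)
        g = nx.gnp_random_graph(20, 0.4, seed=1)
        for u, v in g.edges:
            g[u][v]["rr"] = float(rng.uniform(0.5, 5))
        base = eigenvector_centrality(g)
        for u, v in g.edges:
            g[u][v]["rr"] *= 37.0
        scaled = eigenvector_centrality(g)
        for k in base:
            assert scaled[k] == pytest.approx(base[k], abs=1e-8)

    def test_disconnected_components_normalized_separately(self):
        g = nx.Graph()
        g.add_edges_from([("A01", "B01"), ("C01", "D01"), ("C01", "E01")])
        scores = eigenvector_centrality(g, weight_mode="binary")
        n1 = scores["A01"] ** 2 + scores["B01"] ** 2
        n2 = scores["C01"] ** 2 + scores["D01"] ** 2 + scores["E01"] ** 2
        assert n1 == pytest.approx(1.0, abs=1e-9)
        assert n2 == pytest.approx(1.0, abs=1e-9)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            eigenvector_centrality(nx.Graph())
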