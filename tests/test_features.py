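"""Feature groups: hand-computed examples, widths, zero-fill, no leakage."""

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from losnet.eci import EciMapping, VAN_WALRAVEN_WEIGHTS, default_eci_mapping
from losnet.features import (
    DiseaseRiskTable,
    HISTORY_COLUMNS,
    assemble,
    baseline_block,
    baseline_features,
    disease_risk_features,
    evc_block,
    evc_features,
    evc_vocabulary,
    historical_features,
    history_block,
    los_mean_per_disease,
    psn_features,
    split_dependent_blocks,
)
from losnet.similarity import NeighborList

from conftest import make_record


class TestBaseline:
    def test_width_is_69_under_full_schema(self, eci_map):
        f = baseline_features(make_record(), eci_map)
        assert len(f) == 69

    def test_address_flag(self, eci_map):
        same = make_record(patient_address_code=5, hospital_address_code=5)
        diff = make_record(patient_address_code=5, hospital_address_code=9)
        assert baseline_features(same, eci_map)["address_match"] == 1.0
        assert baseline_features(diff, eci_map)["address_match"] == 0.0

    def test_poa_disease_count(self, eci_map):
        rec = make_record(diagnoses=(("I10", True), ("E11", True),
                                     ("N18", True), ("K21", False)))
        assert baseline_features(rec, eci_map)["n_poa_diseases"] == 3.0

    def test_unmapped_codes_give_zero_flags_and_score(self, eci_map):
        rec = make_record(diagnoses=(("Q99", True),))
        f = baseline_features(rec, eci_map)
        assert sum(v for k, v in f.items() if k.startswith("eci_")) == 0.0

    def test_one_hot_blocks_sum_to_one(self, eci_map):
        f = baseline_features(make_record(), eci_map)
        for prefix, levels in [("sex_", 2), ("source_", 4), ("ethnic_", 2),
                               ("job_", 13), ("marital_", 4)]:
            block = [v for k, v in f.items() if k.startswith(prefix)]
            assert len(block) == levels and sum(block) == 1.0

    def test_unknown_level_routed_to_other_with_warning(self, eci_map):
        rec = make_record(job=99)
        with pytest.warns(UserWarning, match="job"):
            f = baseline_features(rec, eci_map)
        assert f["job_other"] == 1.0

    def test_date_parts(self, eci_map):
        rec = make_record(admission=date(2018, 6, 1))  # a Friday
        f = baseline_features(rec, eci_map)
        assert (f["adm_year"], f["adm_month"], f["adm_weekday"]) == (2018, 6, 5)


class TestEciScore:
    def test_empty_flags_score_zero(self, eci_map):
        assert eci_map.score({c: 0 for c in VAN_WALRAVEN_WEIGHTS}) == 0

    def test_single_flag_scores_its_weight(self, eci_map):
        flags = eci_map.flags({"I50"})
        assert flags["chf"] == 1
        assert eci_map.score(flags) == VAN_WALRAVEN_WEIGHTS["chf"]

    def test_weights_sum(self, eci_map):
        flags = eci_map.flags({"K74", "F32"})   # liver +11, depression −3
        assert eci_map.score(flags) == 8

    def test_31_categories_always_present(self, eci_map):
        assert len(eci_map.flags(set())) == 31


class TestHistorical:
    def test_no_history_is_all_zero(self):
        cur = make_record()
        assert historical_features(cur, []) == dict.fromkeys(HISTORY_COLUMNS, 0.0)

    def test_single_prior_hand_values(self):
        cur = make_record(record_id="R2", admission=date(2018, 6, 1))
        prior = make_record(record_id="R1",
                            admission=date(2018, 6, 1) - timedelta(days=40),
                            los=10)
        f = historical_features(cur, [prior])
        assert f == {
            "hist_count": 1.0, "hist_los_mean": 10.0, "hist_los_std": 0.0,
            "hist_los_median": 10.0, "hist_los_min": 10.0, "hist_los_max": 10.0,
            "last_discharge_interval": 30.0, "last_los": 10.0,
        }

    def test_window_boundary_three_years(self):
        cur = make_record(record_id="R9", admission=date(2018, 6, 1))
        at_boundary = make_record(record_id="R1", admission=date(2015, 6, 1))
        past_boundary = make_record(record_id="R2", admission=date(2015, 5, 31))
        f = historical_features(cur, [at_boundary, past_boundary])
        assert f["hist_count"] == 1.0

    def test_same_day_admission_not_history(self):
        cur = make_record(record_id="R2", admission=date(2018, 6, 1))
        same_day = make_record(record_id="R1", admission=date(2018, 6, 1))
        assert historical_features(cur, [same_day])["hist_count"] == 0.0

    def test_multi_prior_statistics(self):
        cur = make_record(record_id="C", admission=date(2018, 6, 1))
        priors = [
            make_record(record_id=f"R{i}", admission=date(2017, m, 1), los=v)
            for i, (m, v) in enumerate([(1, 2), (3, 4), (5, 9)])
        ]
        f = historical_features(cur, priors)
        assert f["hist_count"] == 3
        assert f["hist_los_mean"] == 5.0
        assert f["hist_los_median"] == 4.0
        assert f["hist_los_std"] == pytest.approx(np.std([2, 4, 9]))
        assert f["last_los"] == 9.0

    def test_brute_force_window_agreement(self, small_cohort):
        records, _ = small_cohort
        by_patient = {}
        for r in records:
            by_patient.setdefault(r.patient_id, []).append(r)
        multi = [r for r in records
                 if len(by_patient[r.patient_id]) > 1][:50]
        for cur in multi:
            f = historical_features(cur, by_patient[cur.patient_id])
            lo = date(cur.admission_date.year - 3, cur.admission_date.month,
                      1 if cur.admission_date.day == 29
                      and cur.admission_date.month == 2
                      else cur.admission_date.day)
            brute = [p for p in by_patient[cur.patient_id]
                     if lo <= p.admission_date < cur.admission_date]
            assert f["hist_count"] == len(brute)


class TestDiseaseRisk:
    def test_los_mean_hand_values(self):
        rows = [
            make_record(record_id="R1", los=4, diagnoses=(("I10", True),)),
            make_record(record_id="R2", los=6, diagnoses=(("I10", True),)),
            make_record(record_id="R3", los=9, diagnoses=(("E11", True),)),
            make_record(record_id="R4", los=9, diagnoses=(("N18", False),)),
        ]
        lm = los_mean_per_disease(rows)
        assert lm == {"I10": 5.0, "E11": 9.0}   # N18 never at PoA → absent

    def test_risk_score_is_evc_times_los_mean(self):
        table = DiseaseRiskTable({"I10": 10.0}, {"I10": 0.5, "E11": 0.9})
        assert table.risk_score == {"I10": 5.0}

    def test_single_disease_aggregates(self):
        table = DiseaseRiskTable({"I10": 10.0}, {"I10": 0.5})
        f = disease_risk_features({"I10"}, table)
        assert f == {"risk_count": 1.0, "risk_max": 5.0,
                     "risk_mean": 5.0, "risk_sum": 5.0}

    def test_two_disease_aggregates(self):
        table = DiseaseRiskTable({"A01": 4.0, "B02": 8.0},
                                 {"A01": 0.5, "B02": 0.5})
        f = disease_risk_features({"A01", "B02"}, table)
        assert f == {"risk_count": 2.0, "risk_max": 4.0,
                     "risk_mean": 3.0, "risk_sum": 6.0}

    def test_uncovered_diseases_zero_filled(self):
        table = DiseaseRiskTable({}, {})
        f = disease_risk_features({"I10"}, table)
        assert set(f.values()) == {0.0}


class TestEvcFeatures:
    def test_empty_poa_set_gives_zero_vector(self):
        v = evc_features(set(), {"I10": 0.7}, ["I10", "E11"])
        assert v.tolist() == [0.0, 0.0]

    def test_single_hot_carries_evc_score(self):
        v = evc_features({"I10"}, {"I10": 0.7, "E11": 0.4}, ["I10", "E11"])
        assert v.tolist() == [0.7, 0.0]

    def test_disease_outside_vocabulary_ignored(self):
        vocab = ["A01", "B02", "C03"]
        evc = {"A01": 0.2, "B02": 0.3, "C03": 0.4, "D04": 0.9}
        v = evc_features({"D04", "B02"}, evc, vocab)
        assert v.tolist() == [0.0, 0.3, 0.0]

    def test_vocabulary_is_mn_nodes_observed_at_poa(self):
        evc = {"I10": 0.5, "E11": 0.5, "N18": 0.5}
        recs = [make_record(diagnoses=(("I10", True), ("N18", False),
                                       ("Q99", True)))]
        assert evc_vocabulary(evc, recs) == ["I10"]


class TestPsnFeatures:
    def test_constant_neighbors(self):
        nl = NeighborList("Q", [(f"T{i}", 0.5) for i in range(100)])
        los = {f"T{i}": 9 for i in range(100)}
        f = psn_features(nl, los)
        assert f == {"psn_los_mean": 9.0, "psn_los_std": 0.0,
                     "psn_los_median": 9.0, "psn_los_min": 9.0,
                     "psn_los_max": 9.0}

    def test_hand_statistics(self):
        nl = NeighborList("Q", [("A", 0.9), ("B", 0.5), ("C", 0.2)])
        f = psn_features(nl, {"A": 2, "B": 4, "C": 9})
        assert f["psn_los_mean"] == 5.0
        assert f["psn_los_median"] == 4.0
        assert f["psn_los_std"] == pytest.approx(np.std([2, 4, 9]))

    def test_empty_list_zero_filled(self):
        f = psn_features(NeighborList("Q", []), {})
        assert set(f.values()) == {0.0}


class TestAssemble:
    def _blocks(self, records, eci_map):
        evc = {"I10": 0.6, "E11": 0.8}
        return {
            "baseline": baseline_block(records, eci_map),
            "history": history_block(records, records),
            "mn": evc_block(records, evc, ["I10", "E11"]),
            "psn": pd.DataFrame(
                0.0, index=[r.record_id for r in records],
                columns=["psn_los_mean", "psn_los_std", "psn_los_median",
                         "psn_los_min", "psn_los_max"]),
        }

    def test_groups_partition_columns(self, eci_map):
        records = [make_record(record_id=f"R{i}") for i in range(3)]
        table = assemble(records, self._blocks(records, eci_map))
        widths = {g: table.width_of(g) for g in ("baseline", "history", "mn", "psn")}
        assert widths == {"baseline": 69, "history": 8, "mn": 2, "psn": 5}
        assert sum(widths.values()) + 1 == table.df.shape[1]   # +1 label col

    def test_no_missing_values(self, eci_map):
        records = [make_record(record_id=f"R{i}") for i in range(3)]
        table = assemble(records, self._blocks(records, eci_map))
        assert not table.df.isna().any().any()

    def test_dropping_psn_shrinks_by_five(self, eci_map):
        records = [make_record(record_id=f"R{i}") for i in range(3)]
        blocks = self._blocks(records, eci_map)
        full = assemble(records, blocks)
        del blocks["psn"]
        smaller = assemble(records, blocks)
        assert full.df.shape[1] - smaller.df.shape[1] == 5

    def test_misaligned_block_rejected(self, eci_map):
        records = [make_record(record_id=f"R{i}") for i in range(3)]
        blocks = self._blocks(records, eci_map)
        blocks["psn"] = blocks["psn"].iloc[:2]
        with pytest.raises(ValueError, match="misaligned"):
            assemble(records, blocks)

    def test_paper_shaped_vocabulary_gives_657_mn_columns(self, eci_map):
        """A 653-wide centrality vocabulary plus the 4 risk aggregates."""
        records = [make_record(record_id=f"R{i}") for i in range(2)]
        vocab = [f"{chr(65 + i // 100)}{i % 100:02d}" for i in range(653)]
        evc = {c: 0.01 for c in vocab}
        mn = pd.concat([
            evc_block(records, evc, vocab),
            pd.DataFrame(0.0, index=[r.record_id for r in records],
                         columns=["risk_count", "risk_max", "risk_mean",
                                  "risk_sum"]),
        ], axis=1)
        table = assemble(records, {"mn": mn})
        assert table.width_of("mn") == 657

    def test_row_order_invariance(self, small_cohort, eci_map):
        records, _ = small_cohort
        sub = records[:60]
        t1 = assemble(sub, self._blocks(sub, eci_map))
        rev = list(reversed(sub))
        t2 = assemble(rev, self._blocks(rev, eci_map))
        pd.testing.assert_frame_equal(
            t1.df.sort_index(), t2.df.sort_index()[t1.df.sort_index().columns])


class TestNoTestLeakage:
    def test_removing_a_test_row_changes_no_other_rows_features(self,
                                                                small_cohort):
        records, truth = small_cohort
        sub = records[:400]
        evc = {c: 0.1 for c in truth.codes}
        train_ids = {r.record_id for r in sub[:300]}
        dep_full = split_dependent_blocks(sub, train_ids, evc,
                                          truth.catalog(), k=20)
        victim = sub[350].record_id          # a non-training row
        reduced = [r for r in sub if r.record_id != victim]
        dep_red = split_dependent_blocks(reduced, train_ids, evc,
                                         truth.catalog(), k=20)
        pd.testing.assert_frame_equal(dep_full.risk.drop(index=victim),
                                      dep_red.risk)
        pd.testing.assert_frame_equal(dep_full.psn.drop(index=victim),
                                      dep_red.psn)

    def test_los_mean_uses_training_rows_only(self, small_cohort):
        records, truth = small_cohort
        sub = records[:200]
        train = sub[:150]
        lm = los_mean_per_disease(train, truth.catalog())
        lm_again = los_mean_per_disease(train + sub[150:151][:0], truth.catalog())
        assert lm == lm_again
        # a disease seen only in non-training rows must be absent
        brute = {}
        for r in train:
            for c in r.poa_codes() & truth.catalog().codes:
                brute.setdefault(c, []).append(r.los)
        assert lm == {c: sum(v) / len(v) for c, v in brute.items()}
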