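"""The four feature groups available at the point of admission.

* ``baseline`` — demographics, hospital attributes, admission date parts,
  diagnosis count and Elixhauser flags/score (69 columns under the full
  one-hot schema);
* ``history`` — 8 summaries of the patient's own stays in the past 3 years;
* ``mn`` — multimorbidity-network features: a multi-hot vector carrying the
  eigenvector centrality of each admission-time disease, plus 4 aggregates
  of per-disease risk scores (EVC × mean LOS of the disease's carriers);
* ``psn`` — 5 summaries of the LOS of the admission's top-k most similar
  training admissions.

Missing values are represented as zero throughout (no-history patients,
diseases unseen in training, empty neighbor lists), so assembled tables are
dense.  Anything derived from observed LOS — the per-disease mean LOS, the
neighbor LOS summaries — is computed from the *training* rows only, so test
rows never contribute to any other row's features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .eci import EciMapping
from .records import AdmissionRecord, ChronicDiseaseCatalog
from .similarity import NeighborList, SimilarityIndex, build_index, poa_set, query_neighbors

GROUPS = ("baseline", "history", "mn", "psn")

_ONE_HOT_LEVELS = {
    "sex": ["male", "female"],
    "admission_source": [1, 2, 3, 4],
    "ethnic_group": ["han", "minority"],
    "job": list(range(1, 14)),
    "marital_status": [1, 2, 3, 4],
}


def _one_hot(prefix: str, value, levels: list) -> dict[str, float]:
    cols = {f"{prefix}_{lv}": 0.0 for lv in levels}
    if value in levels:
        cols[f"{prefix}_{value}"] = 1.0
    else:
        warnings.warn(
            f"unknown {prefix} level {value!r} routed to {prefix}_other",
            stacklevel=3,
        )
        cols[f"{prefix}_other"] = 1.0
    return cols


def baseline_features(record: AdmissionRecord, eci_map: EciMapping
                      ) -> dict[str, float]:
    """Admission-time demographics, hospital and comorbidity-index features.

    Ordinal fields stay numeric; nominal fields are one-hot encoded; the 31
    Elixhauser flags are computed from the PoA diagnosis codes and summed
    into the weighted score.  69 columns when every level is known.
    """
    f: dict[str, float] = {
        "adm_year": float(record.admission_date.year),
        "adm_month": float(record.admission_date.month),
        "adm_weekday": float(record.admission_date.isoweekday()),
        "age": float(record.age),
        "hospital_affiliation": float(record.hospital_affiliation),
        "admission_status": float(record.admission_status),
        "patient_address_code": float(record.patient_address_code),
        "hospital_address_code": float(record.hospital_address_code),
        "address_match": float(
            record.patient_address_code == record.hospital_address_code
        ),
        "hospital_level": float(record.hospital_level),
        "hospital_grade": float(record.hospital_grade),
        "n_poa_diseases": float(len(record.poa_codes())),
    }
    f.update(_one_hot("sex", record.sex, _ONE_HOT_LEVELS["sex"]))
    f.update(_one_hot("source", record.admission_source,
                      _ONE_HOT_LEVELS["admission_source"]))
    f.update(_one_hot("ethnic", record.ethnic_group,
                      _ONE_HOT_LEVELS["ethnic_group"]))
    f.update(_one_hot("job", record.job, _ONE_HOT_LEVELS["job"]))
    f.update(_one_hot("marital", record.marital_status,
                      _ONE_HOT_LEVELS["marital_status"]))
    flags = eci_map.flags(record.poa_codes())
    f.update({f"eci_{cat}": float(v) for cat, v in flags.items()})
    f["eci_score"] = float(eci_map.score(flags))
    return f


def _years_before(d: date, years: int) -> date:
    try:
        return d.replace(year=d.year - years)
    except ValueError:        # Feb 29 → Feb 28
        return d.replace(year=d.year - years, day=28)


HISTORY_COLUMNS = [
    "hist_count", "hist_los_mean", "hist_los_std", "hist_los_median",
    "hist_los_min", "hist_los_max", "last_discharge_interval", "last_los",
]


def historical_features(
    current: AdmissionRecord,
    prior_admissions: Sequence[AdmissionRecord],
    window_years: int = 3,
) -> dict[str, float]:
    """Summaries of the patient's own stays within the lookback window.

    The window is [current admission − ``window_years`` years, current
    admission), closed on the left and open on the right.  The standard
    deviation is the population convention (a single prior stay gives 0).
    Patients with no window history get all-zero features.
    """
    lo = _years_before(current.admission_date, window_years)
    window = [
        r for r in prior_admissions
        if r.patient_id == current.patient_id
        and lo <= r.admission_date < current.admission_date
        and r.record_id != current.record_id
    ]
    if not window:
        return dict.fromkeys(HISTORY_COLUMNS, 0.0)
    los = np.array([r.los for r in window], dtype=float)
    last = max(window, key=lambda r: (r.admission_date, r.record_id))
    return {
        "hist_count": float(len(window)),
        "hist_los_mean": float(los.mean()),
        "hist_los_std": float(los.std()),         # population sd
        "hist_los_median": float(np.median(los)),
        "hist_los_min": float(los.min()),
        "hist_los_max": float(los.max()),
        "last_discharge_interval": float(
            (current.admission_date - last.discharge_date).days
        ),
        "last_los": float(last.los),
    }


def los_mean_per_disease(
    training: Iterable[AdmissionRecord],
    catalog: ChronicDiseaseCatalog | None = None,
) -> dict[str, float]:
    """Mean LOS per disease over the training admissions whose PoA set
    carries it.  Diseases never seen at the PoA in training are absent
    (their downstream feature contribution is zero)."""
    total: dict[str, float] = {}
    count: dict[str, int] = {}
    for r in training:
        for c in poa_set(r, catalog):
            total[c] = total.get(c, 0.0) + r.los
            count[c] = count.get(c, 0) + 1
    return {c: total[c] / count[c] for c in total}


@dataclass(frozen=True)
class DiseaseRiskTable:
    """Per-disease mean LOS and risk score = EVC × mean LOS."""

    los_mean: Mapping[str, float]
    evc: Mapping[str, float]

    @property
    def risk_score(self) -> dict[str, float]:
        return {
            c: self.evc[c] * self.los_mean[c]
            for c in self.los_mean.keys() & self.evc.keys()
        }


RISK_COLUMNS = ["risk_count", "risk_max", "risk_mean", "risk_sum"]


def disease_risk_features(poa_codes: Iterable[str], table: DiseaseRiskTable
                          ) -> dict[str, float]:
    """Count/max/mean/sum of the risk scores of the admission's diseases."""
    scores = table.risk_score
    vals = [scores[c] for c in set(poa_codes) if c in scores]
    if not vals:
        return dict.fromkeys(RISK_COLUMNS, 0.0)
    return {
        "risk_count": float(len(vals)),
        "risk_max": float(max(vals)),
        "risk_mean": float(np.mean(vals)),
        "risk_sum": float(sum(vals)),
    }


def evc_features(poa_codes: Iterable[str], evc: Mapping[str, float],
                 feature_vocab: Sequence[str]) -> np.ndarray:
    """Multi-hot vector over ``feature_vocab`` with ones replaced by the
    disease's centrality score; diseases outside the vocabulary contribute
    nothing."""
    codes = set(poa_codes)
    return np.array(
        [evc.get(c, 0.0) if c in codes else 0.0 for c in feature_vocab]
    )


PSN_COLUMNS = ["psn_los_mean", "psn_los_std", "psn_los_median",
               "psn_los_min", "psn_los_max"]


def psn_features(neighbors: NeighborList, train_los: Mapping[str, int]
                 ) -> dict[str, float]:
    """Mean/std/median/min/max of the neighbors' LOS (population std;
    all-zero when the neighbor list is empty)."""
    if not neighbors.entries:
        return dict.fromkeys(PSN_COLUMNS, 0.0)
    los = np.array([train_los[rid] for rid in neighbors.ids()], dtype=float)
    return {
        "psn_los_mean": float(los.mean()),
        "psn_los_std": float(los.std()),
        "psn_los_median": float(np.median(los)),
        "psn_los_min": float(los.min()),
        "psn_los_max": float(los.max()),
    }


@dataclass
class FeatureTable:
    """Group-tagged dense feature matrix aligned to admission records."""

    df: pd.DataFrame                  # indexed by record_id, includes "los"
    groups: dict[str, str]            # column → group tag

    def __post_init__(self):
        missing = set(self.groups) - set(self.df.columns)
        if missing:
            raise ValueError(f"tagged columns absent from the table: {missing}")
        if self.df[list(self.groups)].isna().any().any():
            raise ValueError("feature table contains missing values")

    def columns_of(self, *groups: str) -> list[str]:
        return [c for c in self.df.columns if self.groups.get(c) in groups]

    def width_of(self, group: str) -> int:
        return len(self.columns_of(group))

    def subset(self, groups: Sequence[str]) -> pd.DataFrame:
        unknown = set(groups) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown feature groups: {sorted(unknown)}")
        return self.df[self.columns_of(*groups)]

    def save(self, csv_path, schema_path) -> None:
        import json

        self.df.to_csv(csv_path)
        with open(schema_path, "w") as fh:
            json.dump(self.groups, fh, indent=1, sort_keys=True)


def assemble(records: Sequence[AdmissionRecord],
             blocks: Mapping[str, pd.DataFrame]) -> FeatureTable:
    """Column-concatenate group blocks into one dense table.

    Every block must be indexed by exactly the record ids of ``records``;
    misalignment raises.  The LOS label column is appended untagged.
    """
    ids = pd.Index([r.record_id for r in records], name="record_id")
    parts, groups = [], {}
    for group, block in blocks.items():
        if group not in GROUPS:
            raise ValueError(f"unknown feature group {group!r}")
        if set(block.index) != set(ids) or len(block) != len(ids):
            raise ValueError(f"block {group!r} is misaligned with the records")
        block = block.reindex(ids).fillna(0.0)
        parts.append(block)
        groups.update({c: group for c in block.columns})
    df = pd.concat(parts, axis=1)
    df["los"] = [r.los for r in records]
    return FeatureTable(df, groups)


# ---------------------------------------------------------------------------
# Orchestration over a modeling cohort

def baseline_block(records: Sequence[AdmissionRecord], eci_map: EciMapping
                   ) -> pd.DataFrame:
    rows = [baseline_features(r, eci_map) for r in records]
    df = pd.DataFrame(rows, index=[r.record_id for r in records]).fillna(0.0)
    df.index.name = "record_id"
    return df


def history_block(records: Sequence[AdmissionRecord],
                  all_records: Sequence[AdmissionRecord],
                  window_years: int = 3) -> pd.DataFrame:
    by_patient: dict[str, list[AdmissionRecord]] = {}
    for r in all_records:
        by_patient.setdefault(r.patient_id, []).append(r)
    rows = [
        historical_features(r, by_patient.get(r.patient_id, ()), window_years)
        for r in records
    ]
    df = pd.DataFrame(rows, index=[r.record_id for r in records])
    df.index.name = "record_id"
    return df


def evc_vocabulary(evc: Mapping[str, float],
                   records: Sequence[AdmissionRecord],
                   catalog: ChronicDiseaseCatalog | None = None) -> list[str]:
    """Network nodes actually observed at the PoA in the modeling era."""
    observed = set()
    for r in records:
        observed |= poa_set(r, catalog)
    return sorted(set(evc) & observed)


def evc_block(records: Sequence[AdmissionRecord],
              evc: Mapping[str, float], vocab: Sequence[str],
              catalog: ChronicDiseaseCatalog | None = None) -> pd.DataFrame:
    mat = np.vstack([
        evc_features(poa_set(r, catalog), evc, vocab) for r in records
    ]) if records else np.zeros((0, len(vocab)))
    df = pd.DataFrame(mat, columns=[f"evc_{c}" for c in vocab],
                      index=[r.record_id for r in records])
    df.index.name = "record_id"
    return df


@dataclass
class SplitFeatures:
    """Split-dependent feature blocks plus what produced them."""

    risk: pd.DataFrame
    psn: pd.DataFrame
    risk_table: DiseaseRiskTable
    index: SimilarityIndex


def split_dependent_blocks(
    records: Sequence[AdmissionRecord],
    train_ids: set[str],
    evc: Mapping[str, float],
    catalog: ChronicDiseaseCatalog | None = None,
    k: int = 100,
    backend: str = "exact",
    exclude_same_patient: bool = True,
    seed: int = 0,
) -> SplitFeatures:
    """Disease-risk and neighbor-LOS blocks computed from training rows only.

    The per-disease mean LOS is estimated on the training split; the
    similarity index contains only training admissions.  Feature rows are
    produced for every record (training rows never see themselves or, by
    default, their patient's other admissions among their neighbors).
    """
    train = [r for r in records if r.record_id in train_ids]
    if not train:
        raise ValueError("empty training split")
    table = DiseaseRiskTable(los_mean_per_disease(train, catalog), evc)
    risk_rows = [
        disease_risk_features(poa_set(r, catalog), table) for r in records
    ]
    risk = pd.DataFrame(risk_rows, index=[r.record_id for r in records])
    risk.index.name = "record_id"

    index = build_index(train, backend=backend, catalog=catalog, seed=seed)
    los = index.los_lookup()
    psn_rows = [
        psn_features(
            query_neighbors(index, r, k=k,
                            exclude_same_patient=exclude_same_patient),
            los,
        )
        for r in records
    ]
    psn = pd.DataFrame(psn_rows, index=[r.record_id for r in records])
    psn.index.name = "record_id"
    return SplitFeatures(risk, psn, table, index)
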