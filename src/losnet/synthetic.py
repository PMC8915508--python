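"""Synthetic discharge-record cohorts with planted statistical structure.

The generator emulates the structure of an administrative elderly-cohort
discharge dataset: each patient carries a persistent set of chronic diseases
(Bernoulli marginals at configured prevalences, with selected disease pairs
given an exact target relative risk of co-occurrence through a shared latent
component), is admitted one or more times over a multi-year span, and accrues
a length of stay assembled from additive disease effects, an age slope, a
patient-level frailty and admission-level noise.

Because the planted quantities (pairwise RR, per-disease LOS effects,
frailties) are known exactly, every downstream stage — network construction,
similarity search, feature engineering, the ablation harness — has a ground
truth to be checked against.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .records import AdmissionRecord, ChronicDiseaseCatalog, MAX_DIAGNOSES

# Real 3-character ICD-10 codes of common chronic conditions in the elderly;
# used as column labels so downstream code handles realistic identifiers.
DEFAULT_CHRONIC_CODES = [
    "I10", "E11", "I25", "I50", "J44", "N18", "I63", "I48", "E78", "M81",
    "F32", "G20", "E10", "M17", "I67", "K74", "C34", "N40", "H25", "E03",
    "I20", "J45", "M05", "G30", "I11", "E14", "K21", "N39", "D64", "I70",
]

# Non-chronic filler assigned to disease-free patients so their records are
# well-formed; excluded by the chronic-at-admission inclusion criterion.
ACUTE_FILLER_CODE = "Z00"

_AGE_BANDS = [(65, 69), (70, 74), (75, 79), (80, 84), (85, 89), (90, 99)]
_AGE_BAND_P = [0.23, 0.25, 0.23, 0.16, 0.09, 0.04]


def chronic_codes(n: int) -> list[str]:
    """n distinct well-formed chronic-disease codes (real ones first)."""
    codes = list(DEFAULT_CHRONIC_CODES[:n])
    letters = string.ascii_uppercase
    i = 0
    while len(codes) < n:
        cand = f"{letters[i // 100 % 26]}{i % 100:02d}"
        if cand not in codes and cand != ACUTE_FILLER_CODE:
            codes.append(cand)
        i += 1
    return codes


@dataclass(frozen=True)
class PlantedPair:
    """A disease pair whose co-occurrence RR is planted exactly."""

    i: int
    j: int
    target_rr: float

    def __post_init__(self):
        if self.target_rr < 1:
            raise ValueError("target RR must be ≥ 1")
        if self.i == self.j:
            raise ValueError("a planted pair needs two distinct diseases")


@dataclass(frozen=True)
class SyntheticParams:
    """Generator configuration; defaults describe a small elderly cohort."""

    n_patients: int = 2_000
    n_diseases: int = 20
    prevalence: float | Sequence[float] = 0.10
    planted_pairs: tuple[PlantedPair, ...] = ()
    admissions_mean: float = 2.0
    admissions_dispersion: float = 1.0
    date_span: tuple[date, date] = (date(2015, 1, 1), date(2019, 12, 31))
    base_days: float = 9.0
    #: per-disease additive LOS effects in days; None → cyclic 0.75·(i mod 7)
    effect_days: tuple[float, ...] | None = None
    age_slope: float = 0.05        # days of LOS per year of age above 65
    frailty_sd: float = 2.0        # patient-level random effect, days
    noise_sd: float = 2.5          # admission-level noise, days
    poa_rate: float = 0.8          # chance a carried disease is flagged at PoA
    accrual_rate: float = 0.0      # chance per admission of a new disease
    male_fraction: float = 0.5
    han_fraction: float = 0.996
    seed: int = 0

    def prevalences(self) -> np.ndarray:
        p = np.broadcast_to(np.asarray(self.prevalence, dtype=float),
                            (self.n_diseases,)).copy()
        if np.any((p <= 0) | (p >= 1)):
            raise ValueError("prevalences must lie in (0, 1)")
        return p

    def effects(self) -> np.ndarray:
        if self.effect_days is not None:
            e = np.asarray(self.effect_days, dtype=float)
            if e.shape != (self.n_diseases,):
                raise ValueError("effect_days must have length n_diseases")
            return e
        return 0.75 * (np.arange(self.n_diseases) % 7)


@dataclass
class GroundTruth:
    """What the generator planted, for downstream checks."""

    codes: list[str]
    prevalence: np.ndarray
    effect_days: np.ndarray
    planted_pairs: list[PlantedPair]
    frailty: dict[str, float]
    age_slope: float
    base_days: float
    disease_sets: dict[str, list[str]] = field(default_factory=dict)

    def catalog(self) -> ChronicDiseaseCatalog:
        return ChronicDiseaseCatalog.from_codes(self.codes, "synthetic")

    def pair_counts(self, code_i: str, code_j: str) -> tuple[int, int, int, int]:
        """(C_ij, C_i, C_j, N) over the *full* generated population.

        The planted relative risk is defined on all patients, including
        those who carry no chronic disease; a matrix built from admission
        records drops disease-free patients and therefore measures the RR
        conditional on cohort membership, which is smaller by the factor
        P(≥1 disease).
        """
        c_i = c_j = c_ij = 0
        for diseases in self.disease_sets.values():
            has_i, has_j = code_i in diseases, code_j in diseases
            c_i += has_i
            c_j += has_j
            c_ij += has_i and has_j
        return c_ij, c_i, c_j, len(self.disease_sets)

    def marginal_prevalence(self, code: str) -> float:
        n = len(self.disease_sets)
        return sum(code in d for d in self.disease_sets.values()) / n


def _shared_component_prob(p_i: float, p_j: float, rr: float) -> float:
    """Probability q of the shared latent Bernoulli giving P(both) = rr·p_i·p_j.

    Diseases are generated as X = Z or B with Z ~ Bern(q) shared by the pair
    and B ~ Bern((p−q)/(1−q)) independent, which preserves the marginals and
    gives P(both) = q + (p_i−q)(p_j−q)/(1−q).
    """
    target = rr * p_i * p_j
    p_min = min(p_i, p_j)
    if target > p_min + 1e-12:
        raise ValueError(
            f"planted RR {rr} infeasible: requires P(both)={target:.4f} > "
            f"min marginal {p_min:.4f}"
        )
    if rr == 1.0:
        return 0.0

    def f(q):
        return q + (p_i - q) * (p_j - q) / (1 - q) - target

    return float(brentq(f, 0.0, p_min, xtol=1e-14))


def _sample_disease_matrix(params: SyntheticParams, rng: np.random.Generator
                           ) -> np.ndarray:
    p = params.prevalences()
    n, d = params.n_patients, params.n_diseases
    planted_idx = set()
    for pair in params.planted_pairs:
        if pair.i in planted_idx or pair.j in planted_idx:
            raise ValueError("each disease may belong to at most one planted pair")
        planted_idx.update((pair.i, pair.j))
        if not (0 <= pair.i < d and 0 <= pair.j < d):
            raise ValueError("planted pair indexes a nonexistent disease")

    X = rng.random((n, d)) < p          # independent marginals
    for pair in params.planted_pairs:
        q = _shared_component_prob(p[pair.i], p[pair.j], pair.target_rr)
        z = rng.random(n) < q
        for k in (pair.i, pair.j):
            r = (p[k] - q) / (1 - q)
            X[:, k] = z | (rng.random(n) < r)
    return X


def generate_cohort(params: SyntheticParams
                    ) -> tuple[list[AdmissionRecord], GroundTruth]:
    """Generate a cohort; deterministic given ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    codes = chronic_codes(params.n_diseases)
    effects = params.effects()
    X = _sample_disease_matrix(params, rng)

    # Demographics, sampled once per patient.
    bands = rng.choice(len(_AGE_BANDS), size=params.n_patients, p=_AGE_BAND_P)
    base_age = np.array([
        rng.integers(_AGE_BANDS[b][0], _AGE_BANDS[b][1] + 1) for b in bands
    ])
    sex = np.where(rng.random(params.n_patients) < params.male_fraction,
                   "male", "female")
    ethnic = np.where(rng.random(params.n_patients) < params.han_fraction,
                      "han", "minority")
    frailty = rng.normal(0.0, params.frailty_sd, params.n_patients)

    # Admission counts: shifted negative binomial, every patient ≥ 1 stay.
    r = params.admissions_dispersion
    mu = max(params.admissions_mean - 1.0, 1e-9)
    n_adm = 1 + rng.negative_binomial(r, r / (r + mu), params.n_patients)

    start, end = params.date_span
    span_days = (end - start).days

    n_hospitals = 20
    hosp_level = rng.integers(1, 4, n_hospitals)
    hosp_grade = rng.integers(1, 4, n_hospitals)
    hosp_affil = rng.integers(1, 4, n_hospitals)
    hosp_addr = rng.integers(1, 21, n_hospitals)

    records: list[AdmissionRecord] = []
    truth = GroundTruth(
        codes=codes, prevalence=params.prevalences(), effect_days=effects,
        planted_pairs=list(params.planted_pairs),
        frailty={}, age_slope=params.age_slope, base_days=params.base_days,
    )
    rec_no = 0
    for p_idx in range(params.n_patients):
        pid = f"P{p_idx:06d}"
        truth.frailty[pid] = float(frailty[p_idx])
        carried = list(np.flatnonzero(X[p_idx]))
        adm_days = np.sort(rng.integers(0, span_days + 1, n_adm[p_idx]))
        p_addr = int(rng.integers(1, 21))
        job = int(rng.integers(1, 14))
        marital = int(rng.integers(1, 5))
        for adm_offset in adm_days:
            adm_date = start + timedelta(days=int(adm_offset))
            if params.accrual_rate > 0 and rng.random() < params.accrual_rate:
                new = [k for k in range(params.n_diseases) if k not in carried]
                if new:
                    carried.append(int(rng.choice(new)))
            age = int(base_age[p_idx] + (adm_date.year - start.year))
            los_latent = params.base_days + (
                float(effects[carried].sum()) if carried else 0.0
            )
            los_latent += (
                params.age_slope * (age - 65)
                + frailty[p_idx]
                + rng.normal(0.0, params.noise_sd)
            )
            los = max(1, round(los_latent))

            if carried:
                flags = rng.random(len(carried)) < params.poa_rate
                if not flags.any():
                    # force the highest-effect disease to be present on
                    # admission so every stay has a chronic PoA diagnosis
                    flags[int(np.argmax(effects[carried]))] = True
                order = sorted(
                    range(len(carried)),
                    key=lambda t: (-int(flags[t]), -effects[carried[t]], carried[t]),
                )
                diagnoses = tuple(
                    (codes[carried[t]], bool(flags[t]))
                    for t in order[:MAX_DIAGNOSES]
                )
            else:
                diagnoses = ((ACUTE_FILLER_CODE, True),)

            h = int(rng.integers(0, n_hospitals))
            records.append(AdmissionRecord(
                record_id=f"R{rec_no:07d}",
                patient_id=pid,
                sex=str(sex[p_idx]),
                age=age,
                ethnic_group=str(ethnic[p_idx]),
                admission_date=adm_date,
                discharge_date=adm_date + timedelta(days=los),
                los=los,
                hospital_id=f"H{h:03d}",
                hospital_level=int(hosp_level[h]),
                hospital_grade=int(hosp_grade[h]),
                hospital_affiliation=int(hosp_affil[h]),
                hospital_address_code=int(hosp_addr[h]),
                patient_address_code=p_addr,
                admission_status=int(rng.choice([1, 2, 3], p=[0.05, 0.15, 0.8])),
                admission_source=int(rng.choice([1, 2, 3, 4],
                                                p=[0.25, 0.6, 0.1, 0.05])),
                job=job,
                marital_status=marital,
                diagnoses=diagnoses,
            ))
            rec_no += 1
        truth.disease_sets[pid] = [codes[k] for k in sorted(carried)]
    return records, truth


#: Named presets used across the test suite; seeds are part of the contract.
FIXTURE_PRESETS: dict[str, SyntheticParams] = {
    "tiny": SyntheticParams(
        n_patients=50, n_diseases=8,
        planted_pairs=(PlantedPair(0, 1, 4.0),),
        seed=101,
    ),
    "small": SyntheticParams(
        n_patients=2_000, n_diseases=20,
        planted_pairs=(PlantedPair(0, 1, 5.0), PlantedPair(2, 3, 3.0)),
        seed=202,
    ),
    "medium": SyntheticParams(
        n_patients=20_000, n_diseases=40,
        planted_pairs=(
            PlantedPair(0, 1, 5.0), PlantedPair(2, 3, 3.0),
            PlantedPair(4, 5, 2.0),
        ),
        seed=303,
    ),
}


def make_fixture(name: str) -> tuple[list[AdmissionRecord], GroundTruth]:
    """Reproducible named cohort preset ('tiny', 'small' or 'medium')."""
    try:
        params = FIXTURE_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; choose from {sorted(FIXTURE_PRESETS)}"
        ) from None
    return generate_cohort(params)
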