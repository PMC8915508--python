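"""Elixhauser comorbidity categories, weights and a pluggable ICD-10 mapping.

The Elixhauser index summarizes a diagnosis list into 31 binary comorbidity
categories; the van Walraven weights collapse the flags into a single score.
Category definitions over full ICD-10 code ranges are external publications,
so the mapping here is pluggable: :func:`default_eci_mapping` ships all 31
canonical categories with van Walraven weights and a deliberately simplified
3-character code map covering the common chronic conditions the synthetic
cohorts use; a complete map can be loaded from CSV with
:func:`EciMapping.from_csv`.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: The 31 canonical comorbidity categories.
ECI_CATEGORIES = [
    "chf", "arrhythmia", "valvular", "pulm_circ", "pvd",
    "htn_uncomplicated", "htn_complicated", "paralysis", "other_neuro",
    "chronic_pulm", "dm_uncomplicated", "dm_complicated", "hypothyroid",
    "renal_failure", "liver", "pud", "aids_hiv", "lymphoma", "mets",
    "solid_tumor", "rheumatoid", "coagulopathy", "obesity", "weight_loss",
    "fluid_electrolyte", "blood_loss_anemia", "deficiency_anemia",
    "alcohol_abuse", "drug_abuse", "psychoses", "depression",
]

#: van Walraven weights per category (zero-weighted categories included).
VAN_WALRAVEN_WEIGHTS = {
    "chf": 7, "arrhythmia": 5, "valvular": -1, "pulm_circ": 4, "pvd": 2,
    "htn_uncomplicated": 0, "htn_complicated": 0, "paralysis": 7,
    "other_neuro": 6, "chronic_pulm": 3, "dm_uncomplicated": 0,
    "dm_complicated": 0, "hypothyroid": 0, "renal_failure": 5, "liver": 11,
    "pud": 0, "aids_hiv": 0, "lymphoma": 9, "mets": 12, "solid_tumor": 4,
    "rheumatoid": 0, "coagulopathy": 3, "obesity": -4, "weight_loss": 6,
    "fluid_electrolyte": 5, "blood_loss_anemia": -2, "deficiency_anemia": -2,
    "alcohol_abuse": 0, "drug_abuse": -7, "psychoses": 0, "depression": -3,
}

# Simplified 3-character ICD-10 → category map (common chronic conditions
# of the elderly only; NOT the full published mapping).
_SIMPLIFIED_CODE_MAP = {
    "I50": {"chf"},
    "I48": {"arrhythmia"},
    "I10": {"htn_uncomplicated"},
    "I11": {"htn_complicated"},
    "I70": {"pvd"},
    "G20": {"other_neuro"},
    "G30": {"other_neuro"},
    "J44": {"chronic_pulm"},
    "J45": {"chronic_pulm"},
    "E10": {"dm_uncomplicated"},
    "E11": {"dm_uncomplicated"},
    "E14": {"dm_uncomplicated"},
    "E03": {"hypothyroid"},
    "N18": {"renal_failure"},
    "K74": {"liver"},
    "C34": {"solid_tumor"},
    "M05": {"rheumatoid"},
    "D64": {"deficiency_anemia"},
    "F32": {"depression"},
}


@dataclass(frozen=True)
class EciMapping:
    """ICD-10 3-char code → Elixhauser categories, plus category weights."""

    code_map: dict[str, frozenset[str]]
    weights: dict[str, int]
    label: str = "custom"

    def __post_init__(self):
        unknown = {
            cat for cats in self.code_map.values() for cat in cats
        } - set(ECI_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown comorbidity categories: {sorted(unknown)}")
        missing = set(ECI_CATEGORIES) - set(self.weights)
        if missing:
            raise ValueError(f"weights missing for categories: {sorted(missing)}")

    def flags(self, codes) -> dict[str, int]:
        """31 binary category indicators for a diagnosis-code set."""
        hit = set()
        for c in codes:
            hit |= self.code_map.get(c, frozenset())
        return {cat: int(cat in hit) for cat in ECI_CATEGORIES}

    def score(self, flags: dict[str, int]) -> int:
        """Weighted comorbidity score: Σ weight over set flags."""
        return int(sum(self.weights[c] for c, v in flags.items() if v))

    @classmethod
    def from_csv(cls, path, weights: dict[str, int] | None = None,
                 label: str = "csv") -> "EciMapping":
        """Load a mapping from CSV with columns ``code,category``."""
        df = pd.read_csv(path, dtype=str)
        cmap: dict[str, set[str]] = {}
        for code, cat in zip(df["code"], df["category"]):
            cmap.setdefault(code, set()).add(cat)
        return cls(
            {c: frozenset(v) for c, v in cmap.items()},
            dict(weights or VAN_WALRAVEN_WEIGHTS),
            label,
        )

    def to_csv(self, path) -> None:
        rows = [
            {"code": code, "category": cat}
            for code in sorted(self.code_map)
            for cat in sorted(self.code_map[code])
        ]
        pd.DataFrame(rows, columns=["code", "category"]).to_csv(path, index=False)


def default_eci_mapping() -> EciMapping:
    """The bundled simplified mapping with van Walraven weights."""
    return EciMapping(
        {c: frozenset(v) for c, v in _SIMPLIFIED_CODE_MAP.items()},
        dict(VAN_WALRAVEN_WEIGHTS),
        label="simplified-builtin",
    )
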