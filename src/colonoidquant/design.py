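"""Factorial study design and dosing metadata.

The experiment crosses six treatment arms with two oxygen tensions
(2% physioxia vs. 20% atmospheric) across a set of colonoid donors.
Every downstream table — well summaries, section scores, blot folds,
chemokine panels — is keyed by the same ``SampleKey`` tuple so that the
statistics layer can join them without ad-hoc renaming.

Condition 1 (DMSO vehicle) is the reference level for all fold changes
and model contrasts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from importlib import resources

import pandas as pd

__all__ = [
    "Condition",
    "CONDITION_ALIASES",
    "SampleKey",
    "Dose",
    "condition_manifest",
    "resolve_condition",
    "molar_to_mass_concentration",
    "validate_design",
    "DesignReport",
]


class Condition(Enum):
    """The six treatment arms, indexed 1-6 as in the figure legends.

    DMSO (vehicle control) is the reference; TNF_PIC denotes stimulation
    with TNF + Poly(I:C); the last two arms combine a drug pre-treatment
    with that stimulation.
    """

    DMSO = 1
    TOFA = 2
    BUD = 3
    TNF_PIC = 4
    TOFA_TNF_PIC = 5
    BUD_TNF_PIC = 6

    @property
    def index(self) -> int:
        return self.value

    @property
    def label(self) -> str:
        return self.name


#: Synonyms accepted in input files, mapped to canonical labels.
CONDITION_ALIASES: dict[str, Condition] = {
    "dmso": Condition.DMSO,
    "vehicle": Condition.DMSO,
    "control": Condition.DMSO,
    "tofa": Condition.TOFA,
    "tofacitinib": Condition.TOFA,
    "bud": Condition.BUD,
    "budesonide": Condition.BUD,
    "tnf_pic": Condition.TNF_PIC,
    "tnf+pic": Condition.TNF_PIC,
    "tnf_polyic": Condition.TNF_PIC,
    "tofa_tnf_pic": Condition.TOFA_TNF_PIC,
    "tofacitinib_tnf_pic": Condition.TOFA_TNF_PIC,
    "bud_tnf_pic": Condition.BUD_TNF_PIC,
    "budesonide_tnf_pic": Condition.BUD_TNF_PIC,
}

#: Oxygen levels used throughout; 2% is the reference level.
OXYGEN_LEVELS = ("2%", "20%")

#: DMSO vehicle fraction (volume %). Stored as a constant: the stock
#: concentrations needed to derive it are not part of the dosing records.
DMSO_VEHICLE_FRACTION_PERCENT = 0.033


def resolve_condition(token: str | int | Condition) -> Condition:
    """Map a label, synonym, or 1-based index to its canonical Condition."""
    if isinstance(token, Condition):
        return token
    if isinstance(token, int):
        return Condition(token)
    key = str(token).strip().lower().replace(" ", "_").replace("-", "_")
    if key in CONDITION_ALIASES:
        return CONDITION_ALIASES[key]
    try:
        return Condition(int(key))
    except ValueError:
        raise KeyError(f"unknown condition label {token!r}") from None


def condition_manifest() -> list[dict]:
    """Load the canonical six-condition manifest shipped with the package."""
    text = resources.files("colonoidquant").joinpath("data/conditions.json").read_text()
    return json.loads(text)


@dataclass(frozen=True)
class SampleKey:
    """Unique key of one measurement row.

    donor identifiers follow the HC*/UC* scheme (healthy control vs.
    ulcerative colitis); the diagnosis encoded in the prefix is metadata
    only and never branches computation.
    """

    donor: str
    oxygen: str
    condition: Condition
    well: int = 1
    experiment: int = 1

    def __post_init__(self):
        if self.oxygen not in OXYGEN_LEVELS:
            raise ValueError(f"oxygen must be one of {OXYGEN_LEVELS}, got {self.oxygen!r}")
        if self.well < 1 or self.experiment < 1:
            raise ValueError("well and experiment are 1-based positive integers")


@dataclass(frozen=True)
class Dose:
    """Drug dose with molarity <-> mass-concentration bookkeeping."""

    molar_concentration: float  # µmol/L
    molar_mass: float  # g/mol

    @property
    def mass_concentration(self) -> float:
        """Mass concentration in µg/mL."""
        return molar_to_mass_concentration(self.molar_concentration, self.molar_mass)


def molar_to_mass_concentration(
    molar_concentration: float, molar_mass: float, decimals: int | None = None
) -> float:
    """Convert a molar concentration (µmol/L) to mass concentration (µg/mL).

    µmol/L × g/mol = µg/L, hence the division by 1000 to reach µg/mL.
    ``decimals`` is a presentation option; the exact value is returned
    when it is None.

    >>> molar_to_mass_concentration(50, 504.5, decimals=1)
    25.2
    """
    import math

    if not (math.isfinite(molar_concentration) and math.isfinite(molar_mass)):
        raise ValueError("concentration and molar mass must be finite")
    if molar_concentration < 0 or molar_mass < 0:
        raise ValueError("concentration and molar mass must be non-negative")
    value = molar_concentration * molar_mass / 1000.0
    return round(value, decimals) if decimals is not None else value


@dataclass
class DesignReport:
    """Completeness report for a design table. Report-only, never mutates."""

    complete: bool
    missing_cells: list[tuple]
    duplicate_keys: list[tuple]

    def __str__(self) -> str:
        if self.complete and not self.duplicate_keys:
            return "complete"
        lines = []
        if self.missing_cells:
            lines.append(f"missing cells: {self.missing_cells}")
        if self.duplicate_keys:
            lines.append(f"duplicate keys: {self.duplicate_keys}")
        return "; ".join(lines) or "complete"


KEY_COLUMNS = ["donor", "oxygen", "condition", "well", "experiment"]


def validate_design(table: pd.DataFrame) -> DesignReport:
    """Check a design table for missing donor×condition×oxygen cells and
    duplicate keys.

    The table must carry the columns donor, oxygen, condition, well,
    experiment. Conditions may be given as labels, synonyms or indices.
    """
    if table.empty:
        raise ValueError("design table is empty")
    missing_cols = [c for c in KEY_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"design table lacks columns {missing_cols}")

    df = table.copy()
    df["condition"] = df["condition"].map(resolve_condition)

    observed = set(zip(df["donor"], df["oxygen"], df["condition"]))
    missing = [
        (donor, oxygen, cond.label)
        for donor in sorted(df["donor"].unique())
        for oxygen in OXYGEN_LEVELS
        for cond in Condition
        if (donor, oxygen, cond) not in observed
    ]

    key_tuples = list(zip(df["donor"], df["oxygen"], df["condition"], df["well"], df["experiment"]))
    seen: set = set()
    dupes = []
    for key in key_tuples:
        if key in seen:
            dupes.append((key[0], key[1], key[2].label, key[3], key[4]))
        seen.add(key)

    return DesignReport(complete=not missing, missing_cells=missing, duplicate_keys=dupes)
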