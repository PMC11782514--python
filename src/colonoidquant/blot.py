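"""Immunoblot band-intensity normalization.

Band intensities arrive as a tidy table (one row per donor × oxygen ×
condition × target) with the loading-control (GAPDH) intensity on the
same row. Quantities are densitometry arbitrary units; the module
starts from the numbers a gel imager exports, not from blot images.

Normalization is two-step and on the linear scale: divide the target
band by GAPDH in the same lane, then divide by the same ratio in the
DMSO vehicle lane of the same donor × oxygen group, yielding a fold
change of 1.0 for every DMSO row by construction. Paired markers
(pMLKL/MLKL, cleaved caspase-3/caspase-3) are further expressed as the
ratio of the two GAPDH-normalized signals before the DMSO fold step.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import Condition, resolve_condition

__all__ = ["normalize_blot", "marker_ratio"]

REQUIRED = ["donor", "oxygen", "condition", "target", "intensity", "gapdh"]


def _check_table(rows: pd.DataFrame, floor: float) -> pd.DataFrame:
    missing = [c for c in REQUIRED if c not in rows.columns]
    if missing:
        raise ValueError(f"blot table lacks columns {missing}")
    df = rows.copy()
    df["condition"] = df["condition"].map(lambda c: resolve_condition(c).label)
    bad = df[(df["intensity"] <= floor) | (df["gapdh"] <= floor)]
    if not bad.empty:
        rows_desc = bad[["donor", "oxygen", "condition"]].to_records(index=False).tolist()
        raise ValueError(
            f"band intensities at or below the floor ({floor}) in rows {rows_desc}; "
            "rejecting rather than clipping to avoid division blow-ups"
        )
    return df


def normalize_blot(rows: pd.DataFrame, floor: float = 0.0) -> pd.DataFrame:
    """GAPDH-normalize and express as fold change over DMSO.

    Returns the input keys plus ``ratio`` (target/GAPDH) and ``fold``
    (ratio / DMSO ratio within the donor × oxygen × target group).
    Raises when a group lacks its DMSO reference row or when any
    intensity is at or below ``floor``.
    """
    df = _check_table(rows, floor)
    df["ratio"] = df["intensity"] / df["gapdh"]

    out = []
    for (donor, oxygen, target), group in df.groupby(["donor", "oxygen", "target"]):
        ref = group[group["condition"] == Condition.DMSO.label]
        if ref.empty:
            raise ValueError(f"no DMSO reference row for group donor={donor}, oxygen={oxygen}, target={target}")
        ref_ratio = float(ref["ratio"].mean())
        g = group.copy()
        g["fold"] = g["ratio"] / ref_ratio
        out.append(g)
    result = pd.concat(out, ignore_index=True)
    return result[["donor", "oxygen", "condition", "target", "ratio", "fold"]]


def marker_ratio(
    rows_numerator: pd.DataFrame, rows_denominator: pd.DataFrame, floor: float = 0.0
) -> pd.DataFrame:
    """Ratio of two GAPDH-normalized markers, as fold over DMSO.

    Typical use: phospho/total (pMLKL over MLKL) or cleaved/total
    (cleaved caspase-3 over caspase-3). Both tables must cover the same
    donor × oxygen × condition keys; an unmatched key raises.
    """
    num = _check_table(rows_numerator, floor)
    den = _check_table(rows_denominator, floor)
    keys = ["donor", "oxygen", "condition"]
    num = num.assign(num_ratio=num["intensity"] / num["gapdh"])
    den = den.assign(den_ratio=den["intensity"] / den["gapdh"])
    merged = num[keys + ["target", "num_ratio"]].merge(
        den[keys + ["den_ratio"]], on=keys, how="outer", indicator=True
    )
    unmatched = merged[merged["_merge"] != "both"]
    if not unmatched.empty:
        raise ValueError(
            "unmatched keys between marker tables: "
            f"{unmatched[keys].to_records(index=False).tolist()}"
        )
    merged["ratio"] = merged["num_ratio"] / merged["den_ratio"]

    out = []
    for (donor, oxygen), group in merged.groupby(["donor", "oxygen"]):
        ref = group[group["condition"] == Condition.DMSO.label]
        if ref.empty:
            raise ValueError(f"no DMSO reference row for group donor={donor}, oxygen={oxygen}")
        g = group.copy()
        g["fold"] = g["ratio"] / float(ref["ratio"].mean())
        out.append(g)
    result = pd.concat(out, ignore_index=True)
    return result[["donor", "oxygen", "condition", "target", "ratio", "fold"]]
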