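"""Plate-level normalization for the phagocytosis screen.

The screen reads out two fluorescence channels per well: pHrodo ("red",
engulfed synaptosomes in acidic phagosomes) and calcein AM ("green", live-cell
mass).  Phagocytosis activity is quantified as the red:green ratio, then
expressed as a percent of the per-plate median ratio so that plates imaged at
different gains are comparable.  Toxicity is called from green loss relative
to the plate median green signal.

All functions operate on pandas DataFrames carrying the eight well columns in
:data:`WELL_COLUMNS`; :func:`read_well_table` loads and validates such a table
from CSV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegeneratePlateError, SchemaError, TableParseError

#: Canonical column order of a raw well table.
WELL_COLUMNS = [
    "plate_id",
    "well_row",
    "well_col",
    "role",
    "compound_id",
    "concentration_um",
    "red_intensity",
    "green_intensity",
]

#: Valid well roles.
ROLES = frozenset({"data", "high_control", "low_control", "positive_control"})

_NUMERIC_COLUMNS = ["red_intensity", "green_intensity"]


@dataclass(frozen=True)
class ScreenThresholds:
    """Cut-offs used by normalization and hit calling.

    toxicity_fraction
        A well is toxic when its green signal is more than this fraction
        below the plate median green (default 0.30, i.e. green < 70% of the
        plate median).
    decrease_cut_pct / increase_cut_pct
        Percent-of-median bands for calling decreased (<70) or increased
        (>130) phagocytosis.
    dose_gate_um
        Only doses strictly above this concentration (µM) are eligible for
        effect calls.
    high_dose_um
        Crossings confined to doses above this value fall in the
        "above 20 µM" sub-categories.
    """

    toxicity_fraction: float = 0.30
    decrease_cut_pct: float = 70.0
    increase_cut_pct: float = 130.0
    dose_gate_um: float = 5.0
    high_dose_um: float = 20.0

    def __post_init__(self) -> None:
        if not (0.0 < self.toxicity_fraction < 1.0):
            raise ValueError("toxicity_fraction must be in (0, 1)")
        if not (0.0 < self.decrease_cut_pct < 100.0 < self.increase_cut_pct):
            raise ValueError(
                "need 0 < decrease_cut_pct < 100 < increase_cut_pct"
            )


def read_well_table(path) -> pd.DataFrame:
    """Read a raw well table (CSV with header) into a typed DataFrame.

    Raises :class:`SchemaError` naming any missing column and
    :class:`TableParseError` with the 1-based data row number of the first
    non-numeric intensity.
    """
    df = pd.read_csv(path, dtype={"plate_id": str, "compound_id": str})
    missing = [c for c in WELL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    for col in _NUMERIC_COLUMNS + ["concentration_um"]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if col in _NUMERIC_COLUMNS and bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise TableParseError(
                f"non-numeric value {df[col].iloc[row - 1]!r} in column "
                f"{col!r} at data row {row}"
            )
        df[col] = coerced
    df["compound_id"] = df["compound_id"].fillna("")
    # stable per-plate grouping, original row order preserved within plates
    return df.sort_values("plate_id", kind="stable").reset_index(drop=True)


def _plate_median_green(plate: pd.DataFrame) -> float:
    data = plate[plate["role"] == "data"]
    if data.empty:
        raise DegeneratePlateError("plate has no data wells")
    med = float(data["green_intensity"].median())
    if med == 0.0:
        raise DegeneratePlateError("plate data-well green signal is all zero")
    return med


def flag_toxic_wells(plate: pd.DataFrame, thresholds: ScreenThresholds | None = None) -> pd.Series:
    """Toxicity flags for one plate's data wells.

    A data well is toxic iff its green intensity is *strictly* below
    ``(1 - toxicity_fraction) x median(green over the plate's data wells)``.
    Control wells are never flagged.  Returns a boolean Series aligned with
    ``plate``'s index.
    """
    thresholds = thresholds or ScreenThresholds()
    med = _plate_median_green(plate)
    cut = (1.0 - thresholds.toxicity_fraction) * med
    is_data = plate["role"] == "data"
    return (is_data & (plate["green_intensity"] < cut)).rename("toxic")


def normalize_plate(
    plate: pd.DataFrame,
    thresholds: ScreenThresholds | None = None,
    normalize_to: str = "plate_median",
) -> pd.DataFrame:
    """Normalize one plate to percent-of-median red:green ratio.

    Adds columns ``rg_ratio``, ``pct_phagocytosis``, ``toxic``,
    ``plate_median_green`` and ``plate_median_rg``.  The reference median is
    taken over non-toxic data wells (``normalize_to="plate_median"``, the
    default) or over high-control wells (``normalize_to="high_control"``).
    Zero-green wells are flagged toxic, their ratio is reported as missing,
    and they never enter a median.
    """
    thresholds = thresholds or ScreenThresholds()
    if normalize_to not in ("plate_median", "high_control"):
        raise ValueError(f"unknown normalize_to: {normalize_to!r}")
    out = plate.copy()
    toxic = flag_toxic_wells(out, thresholds)
    # zero-green wells: no live cells, ratio undefined
    zero_green = (out["role"] == "data") & (out["green_intensity"] <= 0.0)
    toxic = toxic | zero_green
    with np.errstate(divide="ignore", invalid="ignore"):
        rg = out["red_intensity"] / out["green_intensity"]
    rg[out["green_intensity"] <= 0.0] = np.nan

    usable = (out["role"] == "data") & ~toxic & rg.notna()
    if normalize_to == "plate_median":
        ref_rows = usable
    else:
        ref_rows = (out["role"] == "high_control") & rg.notna()
    if not ref_rows.any():
        raise DegeneratePlateError(
            "plate has no usable wells for the normalization reference"
        )
    median_rg = float(rg[ref_rows].median())
    if median_rg == 0.0:
        raise DegeneratePlateError("plate reference red:green median is zero")

    out["rg_ratio"] = rg
    out["toxic"] = toxic.to_numpy()
    out["pct_phagocytosis"] = 100.0 * rg / median_rg
    out["plate_median_green"] = _plate_median_green(out)
    out["plate_median_rg"] = median_rg
    return out


def normalize_screen(
    screen: pd.DataFrame,
    thresholds: ScreenThresholds | None = None,
    normalize_to: str = "plate_median",
) -> pd.DataFrame:
    """Apply :func:`normalize_plate` plate-by-plate to a whole screen."""
    parts = [
        normalize_plate(plate, thresholds, normalize_to)
        for _, plate in screen.groupby("plate_id", sort=True)
    ]
    return pd.concat(parts, ignore_index=True)


def plate_control_summary(plate: pd.DataFrame) -> dict:
    """Median red/green per well role for one plate, for QC display.

    No filtering is applied.  A role absent from the plate yields NaN fields
    and a warning rather than an error.
    """
    summary: dict = {"plate_id": plate["plate_id"].iloc[0] if len(plate) else None}
    for role in ("high_control", "low_control", "positive_control", "data"):
        rows = plate[plate["role"] == role]
        if rows.empty:
            if role != "data":
                warnings.warn(f"plate has no {role} wells", stacklevel=2)
            summary[f"{role}_median_red"] = float("nan")
            summary[f"{role}_median_green"] = float("nan")
        else:
            summary[f"{role}_median_red"] = float(rows["red_intensity"].median())
            summary[f"{role}_median_green"] = float(rows["green_intensity"].median())
    return summary
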