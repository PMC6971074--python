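"""Readers and writers for the pipeline's file formats.

Multi-page TIFF for image stacks and label masks, CSV for single-cell
and clinical tables, YAML for the marker-panel manifest. The single-cell
CSV is the hub format every stage consumes and produces: columns
``cell_id, case_id, x_um, y_um, area_um2`` followed by one mean-intensity
column per marker in panel order (``cluster_id`` / ``cell_type`` appended
downstream).
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .model import (
    FormatError,
    LabelMask,
    MarkerPanel,
    MultiplexImage,
    SchemaError,
    ValidationError,
)

BASE_COLUMNS = ["cell_id", "case_id", "x_um", "y_um", "area_um2"]

CLINICAL_COLUMNS = [
    "case_id", "age", "menopause", "figo", "tmn", "size_cm",
    "mitoses_per_10hpf", "necrosis", "mhc_class_i", "mhc_dynamics",
    "desmin", "b7h3", "axl", "ido", "total_cells_per_mm2",
    "segmented_over_dapi_pct", "predominant_phenotype",
]

MENOPAUSE_VALUES = {"Yes", "No"}
NECROSIS_VALUES = {"Present", "Focal", "Absent"}
PHENOTYPE_STATES = ("T_ex-acute", "T_ex-chronic", "T_ex-mixed", "Deserted")


# ---------------------------------------------------------------- images

def read_multiplex_image(path: str | Path, panel: MarkerPanel) -> MultiplexImage:
    """Read a multi-page TIFF whose pages are the panel's channels, in order."""
    try:
        arr = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read TIFF {path}: {exc}") from exc
    arr = np.atleast_3d(arr)
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected a (pages, y, x) stack, got shape {arr.shape}")
    if arr.shape[0] != panel.n_channels:
        raise FormatError(
            f"{path}: page count mismatch — panel declares {panel.n_channels} "
            f"markers, file has {arr.shape[0]} pages"
        )
    return MultiplexImage(channels=arr.astype(float), panel=panel)


def write_multiplex_image(image: MultiplexImage, path: str | Path) -> None:
    tifffile.imwrite(path, image.channels.astype(np.float32), photometric="minisblack")


def write_image_stack(channels: np.ndarray, path: str | Path) -> None:
    """Write a raw channel stack preserving its dtype (integer stacks roundtrip bitwise)."""
    tifffile.imwrite(path, np.asarray(channels), photometric="minisblack")


def read_image_stack(path: str | Path) -> np.ndarray:
    return np.atleast_3d(tifffile.imread(path))


def write_label_mask(mask: LabelMask, path: str | Path) -> None:
    if mask.n_labels > np.iinfo(np.uint16).max:
        raise ValidationError(f"{mask.n_labels} labels exceed uint16 range")
    tifffile.imwrite(path, mask.labels.astype(np.uint16), photometric="minisblack")


def read_label_mask(path: str | Path, kind: str, pixel_size_um: float) -> LabelMask:
    arr = tifffile.imread(path)
    return LabelMask(labels=arr.astype(np.int32), kind=kind, pixel_size_um=pixel_size_um)


# ---------------------------------------------------------------- panels

def write_panel(panel: MarkerPanel, path: str | Path) -> None:
    doc = {
        "markers": list(panel.markers),
        "pixel_size_um": float(panel.pixel_size_um),
        "rounds": int(panel.rounds),
        "dapi_channel_per_round": {int(k): int(v) for k, v in panel.dapi_channel_per_round.items()},
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_panel(path: str | Path) -> MarkerPanel:
    doc = yaml.safe_load(Path(path).read_text())
    return MarkerPanel(
        markers=tuple(doc["markers"]),
        pixel_size_um=float(doc["pixel_size_um"]),
        rounds=int(doc.get("rounds", 1)),
        dapi_channel_per_round={int(k): int(v) for k, v in doc.get("dapi_channel_per_round", {}).items()},
    )


# ----------------------------------------------------- single-cell tables

def single_cell_columns(panel: MarkerPanel) -> list[str]:
    return BASE_COLUMNS + list(panel.markers)


def validate_single_cell_table(table: pd.DataFrame, panel: MarkerPanel | None = None) -> None:
    required = BASE_COLUMNS + (list(panel.markers) if panel is not None else [])
    for col in required:
        if col not in table.columns:
            raise SchemaError(f"single-cell table missing required column {col!r}")
    if len(table) and table["cell_id"].duplicated().any():
        dup = table.loc[table["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise ValidationError(f"duplicate cell_id {dup}")
    if len(table) and (table["area_um2"] <= 0).any():
        raise ValidationError("non-positive area_um2")


def write_single_cell_table(table: pd.DataFrame, path: str | Path, panel: MarkerPanel | None = None) -> None:
    """Write the hub CSV with fixed column order and >= 6 significant digits."""
    validate_single_cell_table(table, panel)
    cols = single_cell_columns(panel) if panel is not None else list(table.columns)
    extra = [c for c in table.columns if c not in cols]
    table[cols + extra].to_csv(path, index=False, float_format="%.10g")


def read_single_cell_table(path: str | Path, panel: MarkerPanel | None = None) -> pd.DataFrame:
    table = pd.read_csv(path)
    validate_single_cell_table(table, panel)
    return table


# ----------------------------------------------------- clinical table

def _check_enum(value: str, allowed, column: str, case_id) -> None:
    if value not in allowed:
        raise ValidationError(
            f"case {case_id}: invalid {column} value {value!r}; allowed: {sorted(allowed)}"
        )


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read and validate the per-case clinicopathologic table.

    ``figo`` and ``tmn`` admit NA; the semiquantitative IHC grading
    columns (mhc_class_i, desmin, b7h3, axl, ido) are carried verbatim
    as strings and never computed on.
    """
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"clinical table missing columns: {missing}")
    df = df[CLINICAL_COLUMNS].copy()
    df["figo"] = df["figo"].replace({"NA": pd.NA, "N/A": pd.NA, "": pd.NA})
    df["tmn"] = df["tmn"].replace({"NA": pd.NA, "N/A": pd.NA, "": pd.NA})
    for col in ("age", "size_cm", "mitoses_per_10hpf", "total_cells_per_mm2",
                "segmented_over_dapi_pct"):
        df[col] = pd.to_numeric(df[col])
    for _, row in df.iterrows():
        cid = row["case_id"]
        if not 0 < row["age"] < 120:
            raise ValidationError(f"case {cid}: age {row['age']} outside (0, 120)")
        _check_enum(row["menopause"], MENOPAUSE_VALUES, "menopause", cid)
        _check_enum(row["necrosis"], NECROSIS_VALUES, "necrosis", cid)
        _check_enum(row["predominant_phenotype"], set(PHENOTYPE_STATES), "predominant_phenotype", cid)
        if not 0 <= row["segmented_over_dapi_pct"] <= 100:
            raise ValidationError(f"case {cid}: segmented_over_dapi_pct outside [0, 100]")
    return df


def load_cohort_table() -> pd.DataFrame:
    """The packaged 21-case uterine leiomyosarcoma clinical table."""
    ref = importlib.resources.files("plexcell.data") / "ulms_cohort.csv"
    with importlib.resources.as_file(ref) as p:
        return read_clinical_table(p)
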