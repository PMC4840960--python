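"""Artifact I/O: per-channel TIFF field images, plate layouts, score tables.

Conventions used throughout the package:

* Pixel coordinates are 0-based, row-major ``(row, col)``.
* Each channel of a field is one single-plane 16-bit grayscale TIFF; a field
  is the triple MBP / Olig2 / DAPI acquired with the same camera geometry.
* Well coordinates are normalized to letter + 2-digit form (``"B7"`` ->
  ``"B07"``).
* All tables are comma-delimited UTF-8 with a header row.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, LayoutError

#: Channel names, in canonical order.
CHANNELS = ("MBP", "Olig2", "DAPI")

MAX_INTENSITY = 65535

_WELL_RE = re.compile(r"^([A-Pa-p])(\d{1,2})$")


def normalize_well(well: str) -> str:
    """Normalize a well coordinate to letter + 2-digit form (``"B7"`` -> ``"B07"``)."""
    m = _WELL_RE.match(well.strip())
    if not m:
        raise LayoutError(f"not a well coordinate: {well!r}")
    row, col = m.group(1).upper(), int(m.group(2))
    if col < 1:
        raise LayoutError(f"well column must be >= 1: {well!r}")
    return f"{row}{col:02d}"


@dataclass
class FieldImage:
    """One imaged microscope field: three co-registered intensity rasters.

    Parameters
    ----------
    plate_id : str
    well : str
        Well coordinate; normalized on construction.
    field_index : int
        1-based index of the field within the well (default design images
        4 fields per well).
    channels : dict
        Maps ``"MBP"``, ``"Olig2"``, ``"DAPI"`` to 2-D non-negative integer
        rasters in 16-bit range, all of identical shape.
    pixel_size_um : float
        Microns per pixel; lengths are reported in pixels unless converted.
    """

    plate_id: str
    well: str
    field_index: int
    channels: dict[str, np.ndarray]
    pixel_size_um: float = 1.0
    fields_per_well: int = 4

    def __post_init__(self) -> None:
        self.well = normalize_well(self.well)
        missing = [c for c in CHANNELS if c not in self.channels]
        if missing:
            raise FormatError(f"missing channel(s): {missing}")
        shapes = {c: np.asarray(a).shape for c, a in self.channels.items()}
        ref = shapes[CHANNELS[0]]
        for c, s in shapes.items():
            if len(s) != 2:
                raise FormatError(f"channel {c} is not a 2-D raster (shape {s})")
            if s != ref:
                raise FormatError(
                    f"channel shape mismatch: {c} has {s}, {CHANNELS[0]} has {ref}"
                )
        for c in CHANNELS:
            a = np.asarray(self.channels[c])
            if a.size and (a.min() < 0 or a.max() > MAX_INTENSITY):
                raise FormatError(f"channel {c} intensities outside [0, {MAX_INTENSITY}]")
        if not (1 <= self.field_index <= self.fields_per_well):
            raise FormatError(
                f"field_index {self.field_index} outside 1..{self.fields_per_well}"
            )
        if self.pixel_size_um <= 0:
            raise FormatError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return np.asarray(self.channels[CHANNELS[0]]).shape


def read_field_image(
    paths: Mapping[str, str | Path],
    plate_id: str,
    well: str,
    field_index: int,
    pixel_size_um: float = 1.0,
) -> FieldImage:
    """Read one field from per-channel single-plane grayscale TIFF files.

    Rasters are returned exactly as stored; no rescaling or clipping.
    """
    channels: dict[str, np.ndarray] = {}
    for name in CHANNELS:
        if name not in paths:
            raise FormatError(f"no path given for channel {name}")
        try:
            arr = tifffile.imread(paths[name])
        except Exception as exc:  # noqa: BLE001 - surfaced with channel context
            raise FormatError(f"cannot read channel {name} from {paths[name]}: {exc}") from exc
        if arr.ndim != 2:
            raise FormatError(
                f"channel {name}: expected a single-plane grayscale image, got shape {arr.shape}"
            )
        channels[name] = arr
    return FieldImage(plate_id, well, field_index, channels, pixel_size_um)


def write_field_image(image: FieldImage, directory: str | Path) -> dict[str, Path]:
    """Write a field as one uint16 TIFF per channel; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    stem = f"{image.plate_id}_{image.well}_f{image.field_index}"
    for name in CHANNELS:
        path = directory / f"{stem}_{name}.tif"
        tifffile.imwrite(path, np.asarray(image.channels[name], dtype=np.uint16))
        out[name] = path
    return out


# ---------------------------------------------------------------------------
# Plate layouts
# ---------------------------------------------------------------------------

ROLES = ("test", "positive_control", "negative_control", "empty")


@dataclass
class WellInfo:
    role: str
    compound_id: str | None = None
    concentration_uM: float = 0.0


@dataclass
class PlateLayout:
    """96-well screening plate layout.

    Design constraints (validated): at least 8 control wells split between
    positive (1 uM DAPT) and negative (0.1 % DMSO) roles, and every test
    compound-concentration pair present in exactly 2 wells.
    """

    plate_id: str
    wells: dict[str, WellInfo] = field(default_factory=dict)
    min_control_wells: int = 8

    def __post_init__(self) -> None:
        self.wells = {normalize_well(w): info for w, info in self.wells.items()}
        self.validate()

    def validate(self) -> None:
        problems: list[str] = []
        n_pos = sum(1 for w in self.wells.values() if w.role == "positive_control")
        n_neg = sum(1 for w in self.wells.values() if w.role == "negative_control")
        if n_pos + n_neg < self.min_control_wells:
            problems.append(
                f"only {n_pos + n_neg} control wells (need >= {self.min_control_wells})"
            )
        if n_pos == 0:
            problems.append("no positive-control (DAPT) wells")
        if n_neg == 0:
            problems.append("no negative-control (DMSO) wells")
        counts: dict[tuple[str, float], int] = {}
        for info in self.wells.values():
            if info.role == "test":
                key = (str(info.compound_id), float(info.concentration_uM))
                counts[key] = counts.get(key, 0) + 1
        for (cid, conc), n in sorted(counts.items()):
            if n != 2:
                problems.append(
                    f"test condition {cid} @ {conc:g} uM present in {n} wells (need exactly 2)"
                )
        for well, info in self.wells.items():
            if info.role not in ROLES:
                problems.append(f"well {well}: unknown role {info.role!r}")
        if problems:
            raise LayoutError(f"plate {self.plate_id}: " + "; ".join(problems))

    def wells_by_role(self, role: str) -> list[str]:
        return sorted(w for w, info in self.wells.items() if info.role == role)

    def test_conditions(self) -> dict[tuple[str, float], list[str]]:
        """Map (compound_id, concentration) -> the 2 duplicate wells."""
        out: dict[tuple[str, float], list[str]] = {}
        for well in sorted(self.wells):
            info = self.wells[well]
            if info.role == "test":
                out.setdefault((str(info.compound_id), float(info.concentration_uM)), []).append(well)
        return out


_LAYOUT_COLUMNS = ["well", "role", "compound_id", "concentration_uM"]


def load_plate_layout(path: str | Path, plate_id: str | None = None) -> PlateLayout:
    """Load a plate layout CSV with columns well, role, compound_id, concentration_uM."""
    df = pd.read_csv(path, dtype={"well": str, "role": str, "compound_id": str})
    missing = [c for c in _LAYOUT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"layout {path}: missing column(s) {missing}")
    wells: dict[str, WellInfo] = {}
    dupes: list[str] = []
    for _, row in df.iterrows():
        well = normalize_well(str(row["well"]))
        if well in wells:
            dupes.append(well)
            continue
        cid = row["compound_id"]
        cid = None if pd.isna(cid) or str(cid) == "" else str(cid)
        conc = row["concentration_uM"]
        conc = 0.0 if pd.isna(conc) else float(conc)
        wells[well] = WellInfo(str(row["role"]).strip().lower(), cid, conc)
    if dupes:
        raise LayoutError(f"layout {path}: duplicate well rows {sorted(set(dupes))}")
    pid = plate_id if plate_id is not None else Path(path).stem
    return PlateLayout(pid, wells)


def write_plate_layout(layout: PlateLayout, path: str | Path) -> None:
    rows = [
        {
            "well": well,
            "role": info.role,
            "compound_id": "" if info.compound_id is None else info.compound_id,
            "concentration_uM": info.concentration_uM,
        }
        for well, info in sorted(layout.wells.items())
    ]
    pd.DataFrame(rows, columns=_LAYOUT_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Score tables
# ---------------------------------------------------------------------------

#: Fixed column order of the normalized screen score table.
SCORE_COLUMNS = [
    "compound_id",
    "concentration",
    "pct_dapt_myelination",
    "fiber_mbp_score",
    "pct_dapt_olig2",
    "dapi_olig2_ratio",
    "n_fields_used",
]


@dataclass
class ScoreTable:
    """Normalized per compound-concentration screen results.

    One row per compound-concentration; ``pct_dapt_myelination`` and
    ``pct_dapt_olig2`` are percent-of-DAPT normalized, ``fiber_mbp_score`` is
    the raw fiber-score / MBP-score quotient, ``dapi_olig2_ratio`` the total
    nuclei per Olig2+ nucleus.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in SCORE_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"score table missing column(s): {missing}")
        self.data = df = df[SCORE_COLUMNS].reset_index(drop=True)
        if len(df):
            if df.duplicated(["compound_id", "concentration"]).any():
                raise FormatError("score table has duplicate compound-concentration rows")
            if (df["n_fields_used"] > 8).any():
                raise FormatError("n_fields_used exceeds 8")
            fm = df["fiber_mbp_score"].dropna()
            if (fm < 0).any():
                raise FormatError("fiber_mbp_score must be >= 0")

    def __len__(self) -> int:
        return len(self.data)


def write_score_table(table: ScoreTable, path: str | Path) -> None:
    """Write a score table as CSV; float rendering round-trips exactly."""
    table.data.to_csv(path, index=False)


def read_score_table(path: str | Path) -> ScoreTable:
    return ScoreTable(pd.read_csv(path, dtype={"compound_id": str}))
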