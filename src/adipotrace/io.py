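"""File contracts: multi-channel TIFF fields, label maps, CSV tables, JSON.

Fields are written as one multi-page TIFF per field (page order nuclear, gfp,
rfp, marker) with a JSON sidecar recording the channel order and acquisition
metadata.  Tables are comma-separated UTF-8 with a mandatory header row and
'.' decimals.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import tifffile

from .quantify import NucleusRecord, WellSummary
from .segmentation import CHANNEL_ROLES, FieldImage, FieldMetadata
from .simulate import GroundTruth, GroundTruthCell

__all__ = [
    "write_field",
    "read_field",
    "read_field_from_paths",
    "write_label_map",
    "read_label_map",
    "write_ground_truth",
    "records_to_frame",
    "frame_to_records",
    "write_records",
    "read_records",
    "summaries_to_frame",
    "write_summaries",
    "write_json",
]

PathLike = Union[str, Path]

RECORD_COLUMNS = {
    "nucleus_id": "int64",
    "well": "string",
    "field": "string",
    "timepoint_h": "float64",
    "condition": "string",
    "area": "float64",
    "centroid_y": "float64",
    "centroid_x": "float64",
    "mean_gfp": "float64",
    "mean_rfp": "float64",
    "integrated_marker": "float64",
    "ratio": "float64",
    "is_gfp_pos": "boolean",
    "is_marker_pos": "boolean",
}


def write_field(fieldimg: FieldImage, path: PathLike) -> Path:
    """Write a field as a multi-page TIFF plus a `.json` metadata sidecar."""
    path = Path(path)
    roles = [r for r in CHANNEL_ROLES if r in fieldimg.channels]
    stack = np.stack([fieldimg.channels[r] for r in roles])
    tifffile.imwrite(path, stack, photometric="minisblack")
    sidecar = {
        "channel_order": roles,
        "metadata": dataclasses.asdict(fieldimg.metadata),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_field(path: PathLike) -> FieldImage:
    """Read a multi-page TIFF written by :func:`write_field` (sidecar required)."""
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"metadata sidecar {sidecar_path} not found; "
            "use read_field_from_paths with an explicit role map instead"
        )
    sidecar = json.loads(sidecar_path.read_text())
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    roles = sidecar["channel_order"]
    if len(roles) != stack.shape[0]:
        raise ValueError(
            f"sidecar lists {len(roles)} channels but TIFF has {stack.shape[0]} pages"
        )
    return FieldImage(
        channels={role: stack[i] for i, role in enumerate(roles)},
        metadata=FieldMetadata(**sidecar["metadata"]),
    )


def read_field_from_paths(
    role_paths: dict[str, PathLike],
    metadata: FieldMetadata = FieldMetadata(),
) -> FieldImage:
    """Assemble a field from per-channel single-page TIFFs.

    ``role_paths`` maps channel roles (nuclear/gfp/rfp/marker) to files.
    Channels must agree in shape and bit depth.
    """
    channels: dict[str, np.ndarray] = {}
    for role, p in role_paths.items():
        arr = tifffile.imread(Path(p))
        if arr.ndim != 2:
            raise ValueError(f"channel {role!r} file {p} is not a single 2-D page")
        channels[role] = arr
    dtypes = {a.dtype for a in channels.values()}
    if len(dtypes) > 1:
        raise ValueError(f"channel bit depths differ: {sorted(map(str, dtypes))}")
    return FieldImage(channels=channels, metadata=metadata)


def write_label_map(labels: np.ndarray, path: PathLike) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(labels, dtype=np.int32))
    return path


def read_label_map(path: PathLike) -> np.ndarray:
    return tifffile.imread(Path(path))


def write_ground_truth(truth: GroundTruth, stem: PathLike) -> tuple[Path, Path]:
    """Write ground truth as `<stem>_labels.tif` + `<stem>_cells.csv`."""
    stem = Path(stem)
    label_path = stem.with_name(stem.name + "_labels.tif")
    csv_path = stem.with_name(stem.name + "_cells.csv")
    write_label_map(truth.labels, label_path)
    pd.DataFrame([dataclasses.asdict(c) for c in truth.cells]).to_csv(
        csv_path, index=False
    )
    return label_path, csv_path


def records_to_frame(records: Sequence[NucleusRecord]) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(r) for r in records], columns=list(RECORD_COLUMNS))
    return df.astype(RECORD_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[NucleusRecord]:
    records = []
    for row in df.to_dict(orient="records"):
        for flag in ("is_gfp_pos", "is_marker_pos"):
            v = row.get(flag)
            row[flag] = None if v is None or (isinstance(v, float) and math.isnan(v)) or pd.isna(v) else bool(v)
        records.append(NucleusRecord(**{k: row[k] for k in RECORD_COLUMNS}))
    return records


def write_records(records: Sequence[NucleusRecord], path: PathLike) -> Path:
    path = Path(path)
    # %.17g keeps float64 round-trips lossless through the CSV
    records_to_frame(records).to_csv(path, index=False, float_format="%.17g")
    return path


def read_records(path: PathLike) -> list[NucleusRecord]:
    df = pd.read_csv(Path(path), float_precision="round_trip").astype(RECORD_COLUMNS)
    return frame_to_records(df)


def summaries_to_frame(summaries: Sequence[WellSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = dataclasses.asdict(s)
        # computed percentages; NaN marks an undefined (zero-denominator) value
        row["pct_gfp_pos"] = np.nan if s.pct_gfp_pos is None else s.pct_gfp_pos
        row["pct_marker_in_gfp_pos"] = (
            np.nan if s.pct_marker_in_gfp_pos is None else s.pct_marker_in_gfp_pos
        )
        row["pct_marker_in_gfp_neg"] = (
            np.nan if s.pct_marker_in_gfp_neg is None else s.pct_marker_in_gfp_neg
        )
        rows.append(row)
    return pd.DataFrame(rows)


def write_summaries(summaries: Sequence[WellSummary], path: PathLike) -> Path:
    path = Path(path)
    summaries_to_frame(summaries).to_csv(path, index=False)
    return path


def write_json(obj, path: PathLike) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))
    return path
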