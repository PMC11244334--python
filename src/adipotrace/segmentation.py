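"""Nuclear segmentation from a DNA counterstain and per-nucleus measurement.

The measurement contract is the standard high-content one: individual nuclei
are detected from the nuclear-stain (Hoechst/DAPI) channel; reporter signals
(GFP, RFP) are averaged over each nucleus area, and the proliferation-marker
signal (e.g. EdU, phospho-H3) is integrated (summed) over each nucleus.

Pipeline: Gaussian smooth -> threshold (Otsu or fixed) -> fill holes ->
distance-transform peaks as seeds -> watershed split of touching nuclei ->
area filter -> optional border exclusion -> dense relabelling (1..K).
All steps are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.segmentation import clear_border, relabel_sequential, watershed

from .quantify import NucleusRecord

__all__ = [
    "FieldMetadata",
    "FieldImage",
    "SegmentationParams",
    "segment_nuclei",
    "measure_nuclei",
    "MatchResult",
    "match_to_ground_truth",
]

CHANNEL_ROLES = ("nuclear", "gfp", "rfp", "marker")


@dataclass(frozen=True)
class FieldMetadata:
    """Acquisition metadata for one imaged field."""

    well: str = "A1"
    field: str = "f0"
    timepoint_h: float = 0.0
    condition: str = "control"
    pixel_size_um: Optional[float] = None


@dataclass
class FieldImage:
    """One multi-channel fluorescence field.

    ``channels`` maps channel roles (subset of nuclear/gfp/rfp/marker) to 2-D
    intensity rasters of identical shape; intensities are non-negative
    arbitrary fluorescence units.
    """

    channels: dict[str, np.ndarray]
    metadata: FieldMetadata = field(default_factory=FieldMetadata)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("FieldImage needs at least one channel")
        shapes = set()
        for role, arr in self.channels.items():
            if role not in CHANNEL_ROLES:
                raise ValueError(
                    f"unknown channel role {role!r}; expected one of {CHANNEL_ROLES}"
                )
            arr = np.asarray(arr)
            if arr.ndim != 2:
                raise ValueError(f"channel {role!r} must be 2-D, got shape {arr.shape}")
            if np.any(np.asarray(arr, dtype=float) < 0):
                raise ValueError(f"channel {role!r} has negative intensities")
            shapes.add(arr.shape)
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {sorted(shapes)}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, role: str) -> np.ndarray:
        try:
            return self.channels[role]
        except KeyError:
            raise KeyError(f"field has no channel with role {role!r}") from None


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the nuclear segmentation pipeline.

    ``threshold`` is either ``"otsu"`` or a fixed numeric intensity.
    ``seed_min_distance`` is the minimum separation (px) of watershed seeds;
    a good default is ~0.8x the expected nuclear radius.  Areas are in px².
    """

    smoothing_sigma: float = 1.0
    threshold: Union[str, float] = "otsu"
    min_area: int = 30
    max_area: int = 2000
    seed_min_distance: int = 6
    exclude_border: bool = True

    def __post_init__(self) -> None:
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be >= 0")
        if not (0 < self.min_area < self.max_area):
            raise ValueError("need 0 < min_area < max_area")
        if self.seed_min_distance < 1:
            raise ValueError("seed_min_distance must be >= 1 px")
        if isinstance(self.threshold, str) and self.threshold != "otsu":
            raise ValueError(f"threshold must be 'otsu' or a number, got {self.threshold!r}")


def segment_nuclei(
    nuclear: np.ndarray, params: SegmentationParams = SegmentationParams()
) -> np.ndarray:
    """Detect nuclei in a nuclear-stain raster; returns an integer label map.

    Background pixels are 0; nuclei are labelled densely 1..K.  A blank or
    constant image yields an all-zero map (not an error).  The same raster
    always produces the identical label map.
    """
    arr = np.asarray(nuclear)
    if arr.ndim != 2:
        raise ValueError(f"nuclear channel must be 2-D, got shape {arr.shape}")
    img = arr.astype(float)
    labels = np.zeros(arr.shape, dtype=np.int32)
    if img.max() == img.min():
        return labels

    if params.smoothing_sigma > 0:
        img = gaussian(img, sigma=params.smoothing_sigma, preserve_range=True)

    if params.threshold == "otsu":
        thr = threshold_otsu(img)
    else:
        thr = float(params.threshold)
    mask = img > thr
    if not mask.any():
        return labels
    mask = ndi.binary_fill_holes(mask)

    distance = ndi.distance_transform_edt(mask)
    peak_coords = peak_local_max(
        distance,
        min_distance=params.seed_min_distance,
        labels=mask,
        exclude_border=False,
    )
    if len(peak_coords) == 0:
        return labels
    seeds = np.zeros(mask.shape, dtype=np.int32)
    seeds[tuple(peak_coords.T)] = np.arange(1, len(peak_coords) + 1)
    labels = watershed(-distance, markers=seeds, mask=mask).astype(np.int32)

    # area filter
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    bad = ids[(counts < params.min_area) | (counts > params.max_area)]
    if bad.size:
        labels[np.isin(labels, bad)] = 0
    if params.exclude_border:
        labels = clear_border(labels)
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def measure_nuclei(labels: np.ndarray, fieldimg: FieldImage) -> list[NucleusRecord]:
    """Measure every labelled nucleus in the field's reporter/marker channels.

    Per label: pixel area, intensity-independent centroid, mean GFP, mean RFP,
    integrated (summed) marker signal, and the nGFP/nTomato ratio
    ``(mean_gfp + eps)/(mean_rfp + eps)`` with ``eps = 1e-6 x`` the larger of
    the two reporter channels' maxima (guarding against division by zero).
    """
    labels = np.asarray(labels)
    if labels.shape != fieldimg.shape:
        raise ValueError(
            f"label map shape {labels.shape} != field shape {fieldimg.shape}"
        )
    for role in ("gfp", "rfp", "marker"):
        if role not in fieldimg.channels:
            raise KeyError(f"field is missing required channel role {role!r}")

    ids = np.unique(labels[labels > 0])
    if ids.size == 0:
        return []

    gfp = fieldimg.channel("gfp").astype(float)
    rfp = fieldimg.channel("rfp").astype(float)
    marker = fieldimg.channel("marker").astype(float)
    eps = 1e-6 * max(float(gfp.max()), float(rfp.max()))
    if eps == 0.0:
        eps = 1e-6

    areas = ndi.sum_labels(np.ones_like(labels, dtype=float), labels, ids)
    centroids = ndi.center_of_mass(np.ones_like(labels, dtype=float), labels, ids)
    mean_gfp = ndi.mean(gfp, labels, ids)
    mean_rfp = ndi.mean(rfp, labels, ids)
    sum_marker = ndi.sum_labels(marker, labels, ids)

    md = fieldimg.metadata
    records = []
    for k, nid in enumerate(ids):
        mg, mr = float(mean_gfp[k]), float(mean_rfp[k])
        records.append(
            NucleusRecord(
                nucleus_id=int(nid),
                well=md.well,
                field=md.field,
                timepoint_h=md.timepoint_h,
                condition=md.condition,
                area=float(areas[k]),
                centroid_y=float(centroids[k][0]),
                centroid_x=float(centroids[k][1]),
                mean_gfp=mg,
                mean_rfp=mr,
                integrated_marker=float(sum_marker[k]),
                ratio=(mg + eps) / (mr + eps),
            )
        )
    return records


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching detected nuclei to simulation ground truth."""

    pairs: tuple[tuple[int, int, float], ...]  # (nucleus_id, cell_id, distance px)
    unmatched_records: tuple[int, ...]
    unmatched_cells: tuple[int, ...]

    @property
    def n_matched(self) -> int:
        return len(self.pairs)

    @property
    def recall(self) -> float:
        n_truth = self.n_matched + len(self.unmatched_cells)
        return self.n_matched / n_truth if n_truth else float("nan")

    @property
    def precision(self) -> float:
        n_det = self.n_matched + len(self.unmatched_records)
        return self.n_matched / n_det if n_det else float("nan")

    @property
    def mean_centroid_error(self) -> float:
        if not self.pairs:
            return float("nan")
        return float(np.mean([d for _, _, d in self.pairs]))


def match_to_ground_truth(
    records: Sequence[NucleusRecord],
    truth: "GroundTruth",
    max_distance: float = 5.0,
) -> MatchResult:
    """Greedy nearest-centroid one-to-one matching of detections to truth cells.

    Candidate pairs within ``max_distance`` px are taken in order of
    increasing centroid distance, each record and cell used at most once.
    """
    if not max_distance > 0:
        raise ValueError("max_distance must be > 0")
    rec_xy = np.array([(r.centroid_y, r.centroid_x) for r in records], dtype=float)
    cell_xy = np.array([(c.center_y, c.center_x) for c in truth.cells], dtype=float)
    rec_ids = [r.nucleus_id for r in records]
    cell_ids = [c.cell_id for c in truth.cells]

    if len(records) == 0 or len(truth.cells) == 0:
        return MatchResult((), tuple(rec_ids), tuple(cell_ids))

    dists = np.linalg.norm(rec_xy[:, None, :] - cell_xy[None, :, :], axis=2)
    candidates = np.argwhere(dists <= max_distance)
    order = np.argsort(dists[candidates[:, 0], candidates[:, 1]], kind="stable")

    used_r: set[int] = set()
    used_c: set[int] = set()
    pairs = []
    for i, j in candidates[order]:
        if i in used_r or j in used_c:
            continue
        used_r.add(int(i))
        used_c.add(int(j))
        pairs.append((rec_ids[i], cell_ids[j], float(dists[i, j])))

    unmatched_r = tuple(rec_ids[i] for i in range(len(records)) if i not in used_r)
    unmatched_c = tuple(cell_ids[j] for j in range(len(cell_ids)) if j not in used_c)
    return MatchResult(tuple(pairs), unmatched_r, unmatched_c)
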