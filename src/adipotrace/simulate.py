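"""Synthetic reporter-mouse microscopy fields with exact ground truth.

Emulates endpoint fluorescence imaging of cultures from Adipoq:Cre reporter
mice.  Each simulated cell belongs to one of two populations:

* GFP-positive — adipocyte-derived cells (the Cre-switched lineage), a
  configurable minority of the culture;
* GFP-negative — tdTomato-expressing non-adipocyte cells.

A proliferation marker (EdU or phospho-H3) is positive with a population-
conditional probability, so "proliferation restricted to the GFP-negative
population" is a single configuration away.

Two reporter geometries are supported: ``nuclear_ratio`` (nT/nG-style nuclear
GFP/tdTomato, enabling per-nucleus ratio gating) and ``membrane``
(mT/mG-style, reporters rendered as a ring around each cell; used only to
check that nuclear-stain segmentation is robust to off-nucleus fluorescence).

Nuclei are rendered as flat-intensity disks so every downstream area/intensity
oracle is analytic.  Per-cell brightness is log-normal around a configurable
median; each drawn intensity is rounded to an integer before rendering and the
rounded value is stored in the ground truth, so on noise-free fields the
per-nucleus channel mean equals the ground-truth intensity exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from skimage.draw import disk as draw_disk

from .segmentation import FieldImage, FieldMetadata

__all__ = [
    "ChannelIntensity",
    "SimulationConfig",
    "GroundTruthCell",
    "GroundTruth",
    "PlacementError",
    "place_nuclei",
    "sample_cells",
    "simulate_field",
    "DesignEntry",
    "simulate_experiment",
    "cells_to_records",
]


class PlacementError(RuntimeError):
    """Raised when the requested cell density cannot be placed."""


@dataclass(frozen=True)
class ChannelIntensity:
    """Per-channel intensity model.

    ``fg_pos``/``fg_neg`` are median foreground intensities for cells that are
    positive/negative for the channel's relevant flag (the GFP flag for the
    gfp and rfp channels, the marker flag for the marker channel; the nuclear
    stain uses ``fg_pos`` for every cell).  A foreground of 0 means the
    channel shows only background in that population.  ``log_sigma`` is the
    scale of the per-cell log-normal brightness (natural log); 0 disables
    cell-to-cell variability.
    """

    background: float
    fg_pos: float
    fg_neg: float
    log_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.background < 0 or self.fg_pos < 0 or self.fg_neg < 0:
            raise ValueError("intensities must be non-negative")
        if self.log_sigma < 0:
            raise ValueError("log_sigma must be >= 0")


def _default_intensity() -> dict[str, ChannelIntensity]:
    # 16-bit-realistic levels: bright Hoechst, well separated reporter states,
    # marker bright enough that its nuclear integral dwarfs background.
    return {
        "nuclear": ChannelIntensity(background=100, fg_pos=8000, fg_neg=8000, log_sigma=0.2),
        "gfp": ChannelIntensity(background=100, fg_pos=6000, fg_neg=150, log_sigma=0.3),
        "rfp": ChannelIntensity(background=100, fg_pos=150, fg_neg=6000, log_sigma=0.3),
        "marker": ChannelIntensity(background=100, fg_pos=20000, fg_neg=0, log_sigma=0.3),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one simulated field.

    Defaults emulate a differentiated-SVF culture imaged at 10x: a ~6%
    GFP-positive (adipocyte-derived) minority, proliferation confined to the
    GFP-negative population, moderate density, 16-bit camera with Gaussian
    read noise.
    """

    image_height: int = 512
    image_width: int = 512
    n_cells: int = 60
    nucleus_radius_mean: float = 8.0
    nucleus_radius_sd: float = 1.0
    min_center_distance: float = 24.0
    clump_fraction: float = 0.0  # fraction of cells allowed to violate min distance
    frac_gfp_pos: float = 0.06
    p_marker_pos_given_gfp_pos: float = 0.0
    p_marker_pos_given_gfp_neg: float = 0.04
    intensity: dict[str, ChannelIntensity] = field(default_factory=_default_intensity)
    read_noise_sd: float = 30.0
    poisson_noise: bool = False
    reporter_mode: Literal["nuclear_ratio", "membrane"] = "nuclear_ratio"
    bit_depth: Literal[8, 16] = 16
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if self.image_height < 1 or self.image_width < 1:
            problems.append("image_height/image_width must be >= 1")
        if self.n_cells < 0:
            problems.append("n_cells must be >= 0")
        if not self.nucleus_radius_mean > 0:
            problems.append("nucleus_radius_mean must be > 0")
        if self.nucleus_radius_sd < 0:
            problems.append("nucleus_radius_sd must be >= 0")
        if self.min_center_distance < 0:
            problems.append("min_center_distance must be >= 0")
        for name in (
            "clump_fraction",
            "frac_gfp_pos",
            "p_marker_pos_given_gfp_pos",
            "p_marker_pos_given_gfp_neg",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                problems.append(f"{name} must be in [0, 1], got {v!r}")
        if set(self.intensity) != {"nuclear", "gfp", "rfp", "marker"}:
            problems.append(
                "intensity must define exactly the channels nuclear/gfp/rfp/marker"
            )
        else:
            cap = 2 ** self.bit_depth - 1
            for role, ch in self.intensity.items():
                if max(ch.background, ch.fg_pos, ch.fg_neg) > cap:
                    problems.append(
                        f"intensity[{role!r}] exceeds {self.bit_depth}-bit range (max {cap})"
                    )
        if self.read_noise_sd < 0:
            problems.append("read_noise_sd must be >= 0")
        if self.reporter_mode not in ("nuclear_ratio", "membrane"):
            problems.append(f"unknown reporter_mode {self.reporter_mode!r}")
        if self.bit_depth not in (8, 16):
            problems.append(f"bit_depth must be 8 or 16, got {self.bit_depth!r}")
        if problems:
            raise ValueError("invalid SimulationConfig: " + "; ".join(problems))

    @property
    def dtype(self) -> np.dtype:
        return np.dtype(np.uint8 if self.bit_depth == 8 else np.uint16)

    @property
    def max_value(self) -> int:
        return 2 ** self.bit_depth - 1


@dataclass(frozen=True)
class GroundTruthCell:
    """True state of one simulated cell (the test oracle for one nucleus)."""

    cell_id: int
    center_y: float
    center_x: float
    radius: float
    is_gfp_pos: bool
    is_marker_pos: bool
    # rendered (rounded) foreground intensities per channel role
    intensity_nuclear: float = 0.0
    intensity_gfp: float = 0.0
    intensity_rfp: float = 0.0
    intensity_marker: float = 0.0


@dataclass(frozen=True)
class GroundTruth:
    """All simulated cells plus the reference label raster (0 = background)."""

    cells: tuple[GroundTruthCell, ...]
    labels: np.ndarray

    def __post_init__(self) -> None:
        raster_ids = set(np.unique(self.labels[self.labels > 0]).tolist())
        cell_ids = {c.cell_id for c in self.cells}
        if raster_ids != cell_ids:
            raise ValueError(
                "label raster ids and cell ids disagree: "
                f"raster-only={sorted(raster_ids - cell_ids)}, "
                f"cells-only={sorted(cell_ids - raster_ids)}"
            )

    @property
    def n_gfp_pos(self) -> int:
        return sum(c.is_gfp_pos for c in self.cells)


def place_nuclei(
    config: SimulationConfig, rng: np.random.Generator
) -> list[tuple[tuple[float, float], float]]:
    """Dart-throwing placement of nucleus centers with a minimum-distance rule.

    Returns exactly ``n_cells`` ``((y, x), radius)`` placements.  Centers keep
    at least one radius from the border so every disk lies fully inside the
    image.  A configurable ``clump_fraction`` of cells is instead placed close
    to an existing nucleus, deliberately violating the distance rule (to
    exercise watershed splitting).  Deterministic given the generator state.
    """
    placements: list[tuple[tuple[float, float], float]] = []
    h, w = config.image_height, config.image_width
    n_clumped = int(round(config.clump_fraction * config.n_cells))
    n_spread = config.n_cells - n_clumped
    budget = max(1000, 1000 * config.n_cells)
    attempts = 0

    def draw_radius() -> float:
        r = rng.normal(config.nucleus_radius_mean, config.nucleus_radius_sd)
        return float(np.clip(r, max(2.0, 0.25 * config.nucleus_radius_mean), None))

    while len(placements) < n_spread:
        if attempts >= budget:
            raise PlacementError(
                f"placed only {len(placements)}/{config.n_cells} nuclei after "
                f"{budget} attempts; min_center_distance={config.min_center_distance} "
                f"is too large for a {h}x{w} field at this density"
            )
        attempts += 1
        r = draw_radius()
        margin = math.ceil(r)
        if 2 * margin >= h or 2 * margin >= w:
            raise PlacementError(f"nucleus radius {r:.1f} does not fit the field")
        y = rng.uniform(margin, h - 1 - margin)
        x = rng.uniform(margin, w - 1 - margin)
        ok = all(
            math.hypot(y - cy, x - cx) >= config.min_center_distance
            for (cy, cx), _ in placements
        )
        if ok:
            placements.append(((y, x), r))

    for _ in range(n_clumped):
        r = draw_radius()
        margin = math.ceil(r)
        if placements:
            (ay, ax), ar = placements[rng.integers(len(placements))]
            theta = rng.uniform(0, 2 * math.pi)
            d = 0.75 * (r + ar)  # touching/overlapping neighbour
            y = float(np.clip(ay + d * math.sin(theta), margin, h - 1 - margin))
            x = float(np.clip(ax + d * math.cos(theta), margin, w - 1 - margin))
        else:
            y = rng.uniform(margin, h - 1 - margin)
            x = rng.uniform(margin, w - 1 - margin)
        placements.append(((y, x), r))

    return placements


def _draw_intensity(
    ch: ChannelIntensity, positive: bool, rng: np.random.Generator, cap: int
) -> float:
    """One cell's rendered foreground intensity: rounded log-normal, clipped."""
    median = ch.fg_pos if positive else ch.fg_neg
    if median == 0:
        return 0.0
    value = median * (math.exp(rng.normal(0.0, ch.log_sigma)) if ch.log_sigma > 0 else 1.0)
    return float(np.clip(round(value), 1, cap))


def sample_cells(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> list[GroundTruthCell]:
    """Place cells and draw their population flags and true intensities.

    This is the generative half of :func:`simulate_field`, exposed separately
    so population-level statistics (gating accuracy, fraction recovery) can be
    tested at large n without rendering images.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    placements = place_nuclei(config, rng)
    cells = []
    for i, ((y, x), r) in enumerate(placements, start=1):
        gfp = bool(rng.random() < config.frac_gfp_pos)
        p_marker = (
            config.p_marker_pos_given_gfp_pos if gfp
            else config.p_marker_pos_given_gfp_neg
        )
        marker = bool(rng.random() < p_marker)
        cells.append(
            GroundTruthCell(
                cell_id=i,
                center_y=y,
                center_x=x,
                radius=r,
                is_gfp_pos=gfp,
                is_marker_pos=marker,
                intensity_nuclear=_draw_intensity(
                    config.intensity["nuclear"], True, rng, config.max_value
                ),
                intensity_gfp=_draw_intensity(
                    config.intensity["gfp"], gfp, rng, config.max_value
                ),
                intensity_rfp=_draw_intensity(
                    config.intensity["rfp"], gfp, rng, config.max_value
                ),
                intensity_marker=_draw_intensity(
                    config.intensity["marker"], marker, rng, config.max_value
                ),
            )
        )
    return cells


def _disk_coords(
    cy: float, cx: float, r: float, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    return draw_disk((cy, cx), r, shape=shape)


def _ring_coords(
    cy: float, cx: float, r_outer: float, width: float, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    yy_o, xx_o = draw_disk((cy, cx), r_outer, shape=shape)
    inner = np.zeros(shape, dtype=bool)
    yy_i, xx_i = draw_disk((cy, cx), max(r_outer - width, 0.0), shape=shape)
    inner[yy_i, xx_i] = True
    keep = ~inner[yy_o, xx_o]
    return yy_o[keep], xx_o[keep]


def simulate_field(
    config: SimulationConfig,
    metadata: FieldMetadata = FieldMetadata(),
    rng: Optional[np.random.Generator] = None,
) -> tuple[FieldImage, GroundTruth]:
    """Render one four-channel field plus its exact ground truth.

    Channel semantics: the nuclear stain lights every nucleus; in
    ``nuclear_ratio`` mode GFP-positive cells have bright nuclear GFP and dim
    nuclear tdTomato (and conversely); in ``membrane`` mode the reporters are
    rendered as a 2 px ring at twice the nuclear radius.  The marker channel
    has foreground only in marker-positive nuclei.  Foreground replaces
    background inside a nucleus, so with noise disabled the channel mean over
    a true nucleus mask equals the ground-truth intensity exactly.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cells = sample_cells(config, rng)
    shape = (config.image_height, config.image_width)

    channels = {
        role: np.full(shape, config.intensity[role].background, dtype=float)
        for role in ("nuclear", "gfp", "rfp", "marker")
    }
    labels = np.zeros(shape, dtype=np.int32)

    for cell in cells:
        yy, xx = _disk_coords(cell.center_y, cell.center_x, cell.radius, shape)
        labels[yy, xx] = cell.cell_id
        channels["nuclear"][yy, xx] = cell.intensity_nuclear
        if cell.intensity_marker > 0:
            channels["marker"][yy, xx] = cell.intensity_marker
        if config.reporter_mode == "nuclear_ratio":
            channels["gfp"][yy, xx] = max(
                cell.intensity_gfp, config.intensity["gfp"].background
            )
            channels["rfp"][yy, xx] = max(
                cell.intensity_rfp, config.intensity["rfp"].background
            )
        else:  # membrane: 2 px ring at the cell boundary (2x nuclear radius)
            ry, rx = _ring_coords(
                cell.center_y, cell.center_x, 2.0 * cell.radius, 2.0, shape
            )
            channels["gfp"][ry, rx] = max(
                cell.intensity_gfp, config.intensity["gfp"].background
            )
            channels["rfp"][ry, rx] = max(
                cell.intensity_rfp, config.intensity["rfp"].background
            )

    for role, arr in channels.items():
        if config.poisson_noise:
            arr = rng.poisson(np.clip(arr, 0, None)).astype(float)
        if config.read_noise_sd > 0:
            arr = arr + rng.normal(0.0, config.read_noise_sd, size=shape)
        channels[role] = np.clip(np.rint(arr), 0, config.max_value).astype(config.dtype)

    # cells fully occluded by clumped overlaps would break the id<->raster
    # bijection; drop them from the truth (only possible with clump_fraction>0)
    surviving = set(np.unique(labels[labels > 0]).tolist())
    kept = tuple(c for c in cells if c.cell_id in surviving)

    return (
        FieldImage(channels=channels, metadata=metadata),
        GroundTruth(cells=kept, labels=labels),
    )


@dataclass(frozen=True)
class DesignEntry:
    """One well/timepoint/condition arm of a simulated experiment."""

    well: str
    timepoint_h: float
    condition: str
    config: SimulationConfig
    n_fields: int = 1


def simulate_experiment(
    design: Sequence[DesignEntry | tuple],
) -> list[tuple[FieldImage, GroundTruth]]:
    """Simulate every field of a multi-well, multi-timepoint experiment.

    ``design`` entries may be :class:`DesignEntry` or plain
    ``(well, timepoint_h, condition, config[, n_fields])`` tuples.  The
    (well, timepoint) keys must be distinct.  Each field gets its own child
    seed derived from the entry config's seed, so the whole experiment is
    reproducible from the design alone.
    """
    entries = [
        e if isinstance(e, DesignEntry) else DesignEntry(*e) for e in design
    ]
    keys = [(e.well, e.timepoint_h) for e in entries]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValueError(f"duplicate (well, timepoint) design keys: {dupes}")

    out: list[tuple[FieldImage, GroundTruth]] = []
    for entry in entries:
        if entry.n_fields < 1:
            raise ValueError("n_fields must be >= 1")
        children = np.random.SeedSequence(entry.config.seed).spawn(entry.n_fields)
        for i, child in enumerate(children):
            md = FieldMetadata(
                well=entry.well,
                field=f"f{i}",
                timepoint_h=entry.timepoint_h,
                condition=entry.condition,
            )
            out.append(
                simulate_field(entry.config, md, rng=np.random.default_rng(child))
            )
    return out


def cells_to_records(
    cells: Iterable[GroundTruthCell],
    config: SimulationConfig,
    metadata: FieldMetadata = FieldMetadata(),
):
    """Build idealised NucleusRecords directly from ground-truth cells.

    Bypasses rendering and segmentation: each record carries the cell's true
    reporter intensities as channel means and ``intensity * disk area`` (or
    ``background * area`` for marker-negative cells) as the integrated marker.
    Used to test gating behaviour at large n.
    """
    from .quantify import NucleusRecord

    shape = (config.image_height, config.image_width)
    eps_base = max(config.intensity["gfp"].fg_pos, config.intensity["rfp"].fg_neg)
    eps = 1e-6 * eps_base if eps_base > 0 else 1e-6
    records = []
    for c in cells:
        yy, _ = _disk_coords(c.center_y, c.center_x, c.radius, shape)
        area = float(len(yy))
        marker_level = (
            c.intensity_marker
            if c.intensity_marker > 0
            else config.intensity["marker"].background
        )
        mg = max(c.intensity_gfp, config.intensity["gfp"].background)
        mr = max(c.intensity_rfp, config.intensity["rfp"].background)
        records.append(
            NucleusRecord(
                nucleus_id=c.cell_id,
                well=metadata.well,
                field=metadata.field,
                timepoint_h=metadata.timepoint_h,
                condition=metadata.condition,
                area=area,
                centroid_y=c.center_y,
                centroid_x=c.center_x,
                mean_gfp=mg,
                mean_rfp=mr,
                integrated_marker=marker_level * area,
                ratio=(mg + eps) / (mr + eps),
            )
        )
    return records
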