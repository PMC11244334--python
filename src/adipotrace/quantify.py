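"""Gating of per-nucleus measurements and replicate statistics.

Cells are classified with a single fixed cutoff pair applied identically to
every sample in an experiment, mirroring standard fixed-gate scoring of
reporter fluorescence:

* GFP-positive (adipocyte-derived) ⇔ nGFP/nTomato ratio strictly above
  ``gfp_ratio_cutoff``;
* marker-positive (e.g. EdU or phospho-H3) ⇔ integrated nuclear marker signal
  strictly above ``marker_cutoff``.

Summaries are per well (the biological replicate); replicate statistics are
mean ± SEM and pooled-variance Student t tests across wells.  Per-cell records
are never treated as independent replicates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import signal as spsig
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "NucleusRecord",
    "GateConfig",
    "WellSummary",
    "GroupStats",
    "TTestResult",
    "gate_cells",
    "suggest_cutoff",
    "summarize_wells",
    "mean_sem",
    "two_sample_t_test",
    "timecourse_table",
]


@dataclass
class NucleusRecord:
    """One segmented nucleus: geometry, per-channel signal, and gate flags.

    ``mean_gfp``/``mean_rfp`` are channel means over the nucleus pixels;
    ``integrated_marker`` is the channel sum (integral) over the nucleus.
    ``ratio`` is ``(mean_gfp + eps) / (mean_rfp + eps)`` with a small ``eps``
    guarding against division by zero.  The gate flags are ``None`` until
    :func:`gate_cells` sets them.
    """

    nucleus_id: int
    well: str
    field: str
    timepoint_h: float
    condition: str
    area: float
    centroid_y: float
    centroid_x: float
    mean_gfp: float
    mean_rfp: float
    integrated_marker: float
    ratio: float
    is_gfp_pos: Optional[bool] = None
    is_marker_pos: Optional[bool] = None


@dataclass(frozen=True)
class GateConfig:
    """Fixed cutoffs applied to an entire experiment.

    ``provenance`` records how the cutoffs were chosen (``manual``,
    ``auto_log_valley`` or ``auto_otsu``); ``epsilon`` is the ratio guard
    actually used when the records were measured.
    """

    gfp_ratio_cutoff: float = 1.0
    marker_cutoff: float = 2.0e5
    provenance: str = "manual"
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if not self.gfp_ratio_cutoff > 0:
            raise ValueError("gfp_ratio_cutoff must be > 0")
        if not self.marker_cutoff > 0:
            raise ValueError("marker_cutoff must be > 0")


@dataclass(frozen=True)
class WellSummary:
    """Counts and percentages for one (well, timepoint, condition) group.

    Percentages with a zero denominator are ``None`` (undefined, never
    silently 0).
    """

    well: str
    timepoint_h: float
    condition: str
    n_total: int
    n_gfp_pos: int
    n_gfp_neg: int
    n_marker_pos_in_gfp_pos: int
    n_marker_pos_in_gfp_neg: int

    @property
    def pct_gfp_pos(self) -> Optional[float]:
        if self.n_total == 0:
            return None
        return 100.0 * self.n_gfp_pos / self.n_total

    @property
    def pct_marker_in_gfp_pos(self) -> Optional[float]:
        if self.n_gfp_pos == 0:
            return None
        return 100.0 * self.n_marker_pos_in_gfp_pos / self.n_gfp_pos

    @property
    def pct_marker_in_gfp_neg(self) -> Optional[float]:
        if self.n_gfp_neg == 0:
            return None
        return 100.0 * self.n_marker_pos_in_gfp_neg / self.n_gfp_neg


@dataclass(frozen=True)
class GroupStats:
    """Replicate statistics for one group of well-level values."""

    label: str
    n: int
    mean: float
    sem: Optional[float]  # None when n < 2


@dataclass(frozen=True)
class TTestResult:
    """Two-sample t test output.

    ``degenerate`` flags the zero-variance/unequal-means case where the test
    statistic diverges and p underflows to 0.
    """

    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    equal_var: bool
    degenerate: bool = False


def gate_cells(
    records: Iterable[NucleusRecord], gate: GateConfig
) -> list[NucleusRecord]:
    """Set ``is_gfp_pos`` / ``is_marker_pos`` on every record (returns copies).

    Strictly-greater convention: a value exactly at a cutoff is negative.
    The same cutoffs are applied to every record.
    """
    gated = []
    for rec in records:
        for name in ("ratio", "integrated_marker"):
            value = getattr(rec, name)
            if value is None or (isinstance(value, float) and math.isnan(value)):
                raise ValueError(
                    f"record {rec.nucleus_id} has unset measurement field {name!r}"
                )
        gated.append(
            replace(
                rec,
                is_gfp_pos=bool(rec.ratio > gate.gfp_ratio_cutoff),
                is_marker_pos=bool(rec.integrated_marker > gate.marker_cutoff),
            )
        )
    return gated


def suggest_cutoff(
    values: Sequence[float],
    method: Literal["auto_log_valley", "auto_otsu"] = "auto_log_valley",
    bins: int = 256,
    smooth_sigma_bins: float = 3.0,
) -> float:
    """Suggest a positive/negative cutoff for a bimodal positive-valued signal.

    Values are log10-transformed; the cutoff is either the valley of a smoothed
    histogram between the two dominant modes (``auto_log_valley``) or the Otsu
    threshold of the log values (``auto_otsu``), back-transformed to the
    original scale.  Deterministic given the value list.

    Raises ``ValueError`` on degenerate or apparently unimodal input, in which
    case a manually chosen cutoff should be used instead.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2 or np.unique(arr).size < 2:
        raise ValueError(
            "need at least two distinct values; choose a cutoff manually"
        )
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite and strictly positive")
    log_vals = np.log10(arr)

    if method == "auto_otsu":
        from skimage.filters import threshold_otsu

        cutoff_log = threshold_otsu(log_vals, nbins=bins)
        below = np.count_nonzero(log_vals <= cutoff_log)
        if below == 0 or below == log_vals.size:
            raise ValueError(
                "Otsu threshold does not separate the values; "
                "input looks unimodal — choose a cutoff manually"
            )
        return float(10.0 ** cutoff_log)

    if method != "auto_log_valley":
        raise ValueError(f"unknown method {method!r}")

    counts, edges = np.histogram(log_vals, bins=bins)
    smoothed = ndi.gaussian_filter1d(counts.astype(float), smooth_sigma_bins)
    # zero-pad so modes in the outermost bins still register as peaks
    peaks, _ = spsig.find_peaks(
        np.pad(smoothed, 1), prominence=max(1.0, 0.01 * smoothed.max())
    )
    peaks = peaks - 1
    if peaks.size < 2:
        raise ValueError(
            "histogram of log10 values is not bimodal; choose a cutoff manually"
        )
    # two dominant modes = highest smoothed counts
    order = np.argsort(smoothed[peaks])[::-1]
    p1, p2 = sorted(peaks[order[:2]])
    valley = p1 + int(np.argmin(smoothed[p1 : p2 + 1]))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return float(10.0 ** centers[valley])


def _group_key(rec: NucleusRecord) -> tuple[str, float, str]:
    return (rec.well, rec.timepoint_h, rec.condition)


def summarize_wells(records: Iterable[NucleusRecord]) -> list[WellSummary]:
    """Per-(well, timepoint, condition) counts and percentages of gated records.

    Records must have been gated; an ungated record raises ``ValueError``.
    Groups are returned sorted by (timepoint, condition, well).
    """
    groups: dict[tuple[str, float, str], list[NucleusRecord]] = {}
    for rec in records:
        if rec.is_gfp_pos is None or rec.is_marker_pos is None:
            raise ValueError(
                f"record {rec.nucleus_id} is not gated; run gate_cells first"
            )
        groups.setdefault(_group_key(rec), []).append(rec)

    summaries = []
    for (well, tp, cond), recs in sorted(
        groups.items(), key=lambda kv: (kv[0][1], kv[0][2], kv[0][0])
    ):
        n_pos = sum(r.is_gfp_pos for r in recs)
        n_neg = len(recs) - n_pos
        summaries.append(
            WellSummary(
                well=well,
                timepoint_h=tp,
                condition=cond,
                n_total=len(recs),
                n_gfp_pos=n_pos,
                n_gfp_neg=n_neg,
                n_marker_pos_in_gfp_pos=sum(
                    r.is_marker_pos for r in recs if r.is_gfp_pos
                ),
                n_marker_pos_in_gfp_neg=sum(
                    r.is_marker_pos for r in recs if not r.is_gfp_pos
                ),
            )
        )
    return summaries


def mean_sem(values: Sequence[float]) -> tuple[float, Optional[float]]:
    """Arithmetic mean and standard error of the mean (sample sd / sqrt(n)).

    For a single value the SEM is undefined and returned as ``None``.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("mean_sem requires at least one value")
    mean = float(arr.mean())
    if arr.size == 1:
        return mean, None
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size))
    return mean, sem


def two_sample_t_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_var: bool = True,
) -> TTestResult:
    """Two-tailed two-sample t test.

    Default is the pooled-variance Student t with ``df = n_a + n_b - 2``;
    ``equal_var=False`` gives the Welch variant (Welch–Satterthwaite df).
    Zero variance with equal means is defined as ``t = 0, p = 1``; zero
    variance with unequal means yields ``p = 0`` with ``degenerate=True``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    na, nb = a.size, b.size
    ma, mb = float(a.mean()), float(b.mean())
    va, vb = float(a.var(ddof=1)), float(b.var(ddof=1))

    if equal_var:
        df = float(na + nb - 2)
        pooled = ((na - 1) * va + (nb - 1) * vb) / df
        se = math.sqrt(pooled * (1.0 / na + 1.0 / nb))
    else:
        se = math.sqrt(va / na + vb / nb)
        if se > 0:
            df = (va / na + vb / nb) ** 2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
        else:
            df = float(na + nb - 2)

    if se == 0.0:
        if ma == mb:
            return TTestResult(0.0, df, 1.0, ma, mb, na, nb, equal_var)
        t = math.inf if ma > mb else -math.inf
        return TTestResult(t, df, 0.0, ma, mb, na, nb, equal_var, degenerate=True)

    t = (ma - mb) / se
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TTestResult(t, df, p, ma, mb, na, nb, equal_var)


def timecourse_table(summaries: Sequence[WellSummary]) -> pd.DataFrame:
    """Long-format marker-positive percentages by timepoint, condition and GFP status.

    One row per (timepoint, condition, population in {gfp_pos, gfp_neg}) with
    the number of replicate wells contributing a defined fraction, their mean
    and SEM.  Wells with an undefined fraction (zero denominator) are dropped
    from that population's row and logged; a (timepoint, condition, population)
    with no defined well at all yields no row.
    """
    buckets: dict[tuple[float, str, str], list[float]] = {}
    for s in summaries:
        for population, pct in (
            ("gfp_pos", s.pct_marker_in_gfp_pos),
            ("gfp_neg", s.pct_marker_in_gfp_neg),
        ):
            if pct is None:
                logger.info(
                    "well %s t=%sh %s: pct_marker_in_%s undefined (empty population)",
                    s.well, s.timepoint_h, s.condition, population,
                )
                continue
            buckets.setdefault((s.timepoint_h, s.condition, population), []).append(pct)

    rows = []
    for (tp, cond, population), vals in sorted(buckets.items()):
        mean, sem = mean_sem(vals)
        rows.append(
            {
                "timepoint_h": tp,
                "condition": cond,
                "population": population,
                "n_wells": len(vals),
                "mean_pct_marker_pos": mean,
                "sem_pct_marker_pos": sem if sem is not None else np.nan,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "timepoint_h", "condition", "population",
            "n_wells", "mean_pct_marker_pos", "sem_pct_marker_pos",
        ],
    )
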