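"""Genome-wide scan for putative novel/alternative promoters.

The scan slides a 10 kb window one bin (100 bp) at a time over binned
four-mark coverage, builds each window's 400-bin concatenated log
profile, and correlates it (Pearson) with every active cluster's
characteristic pattern. A window whose correlation strictly exceeds the
cluster's threshold — the lower empirical 100*alpha percentile of the
training members' correlations with their own pattern — is a
*significance window*. Overlapping same-cluster windows merge into
*significance regions*; transitively overlapping regions across
clusters merge into a *putative promoter* assigned to the cluster with
the largest maximum window correlation.

Correlations are computed on the same log scale used to form the
characteristic patterns, since Pearson r is not invariant to the log
map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .mixture import CharacteristicPattern
from .profiles import (
    BINS_PER_MARK,
    MAX_COUNT_THRESHOLD,
    PROFILE_LEN,
    WINDOW_BP,
    GenomeTrack,
    ProfileMatrix,
)

logger = logging.getLogger(__name__)


@dataclass
class ThresholdSet:
    """Per-cluster scan thresholds at significance level alpha."""

    alpha: float
    thresholds: dict[int, float]

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        for k, t in self.thresholds.items():
            if not (-1 <= t <= 1):
                raise ValueError(f"threshold for cluster {k} outside [-1, 1]: {t}")


@dataclass(frozen=True)
class SignificanceWindow:
    """A 10 kb scanned window significantly correlated with one cluster."""

    chrom: str
    start: int  # 1-based inclusive
    end: int
    cluster_id: int
    r: float


@dataclass
class SignificanceRegion:
    """Union of a maximal run of overlapping same-cluster windows."""

    chrom: str
    start: int
    end: int
    cluster_id: int
    max_r: float
    first_window: SignificanceWindow
    last_window: SignificanceWindow
    n_windows: int = 1


@dataclass
class PutativePromoter:
    """Union of transitively overlapping regions across clusters."""

    chrom: str
    start: int
    end: int
    cluster_id: int
    evidence: list[SignificanceRegion] = field(default_factory=list)

    @property
    def max_r(self) -> float:
        return max(r.max_r for r in self.evidence)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; NaN (with a logged note) for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.linalg.norm(xc) * np.linalg.norm(yc)
    if denom == 0:
        logger.info("constant vector in correlation; treated as undefined")
        return float("nan")
    return float(np.clip(xc @ yc / denom, -1.0, 1.0))


def lower_percentile(values: np.ndarray, alpha: float) -> float:
    """Lower empirical 100*alpha percentile (inverse ECDF).

    The smallest data value whose empirical CDF reaches alpha — always
    an observed value, so a strict "exceeds" comparison is unambiguous.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no values")
    return float(np.quantile(values, alpha, method="inverted_cdf"))


def correlation_thresholds(
    matrix: ProfileMatrix,
    patterns: Sequence[CharacteristicPattern],
    labels: np.ndarray,
    alpha: float = 0.4,
) -> ThresholdSet:
    """Lower empirical 100*alpha percentile of within-cluster correlations.

    For each cluster, every member profile is correlated (log scale)
    with the cluster's characteristic pattern; the threshold is the
    smallest member correlation whose empirical CDF reaches alpha
    (numpy's ``inverted_cdf`` quantile), a data-valued cutoff so that
    "exceeds the threshold" is unambiguous.
    """
    labels = np.asarray(labels)
    if len(labels) != matrix.n:
        raise ValueError("labels do not cover all profiles")
    log_values = matrix.values if matrix.transform_state == "log" else np.log1p(matrix.values)
    thresholds: dict[int, float] = {}
    for p in patterns:
        member = log_values[labels == p.cluster_id]
        if len(member) < 2:
            raise ValueError(f"cluster {p.cluster_id} has fewer than 2 members")
        rs = np.array([pearson(row, p.mean_log) for row in member])
        rs = rs[~np.isnan(rs)]
        if len(rs) == 0:
            raise ValueError(f"cluster {p.cluster_id}: all correlations undefined")
        thresholds[p.cluster_id] = lower_percentile(rs, alpha)
    return ThresholdSet(alpha, thresholds)


def _sliding_profiles(track: GenomeTrack, stride_bins: int):
    """All 100-bin-per-mark window profiles of a track, vectorized.

    Returns (starts, raw) where raw is (n_windows, 400) raw counts and
    starts are 1-based window start coordinates.
    """
    n_full = track.n_bins - BINS_PER_MARK + 1
    if n_full <= 0:
        return np.array([], dtype=int), np.empty((0, PROFILE_LEN))
    idx = np.arange(0, n_full, stride_bins)
    views = [
        np.lib.stride_tricks.sliding_window_view(c, BINS_PER_MARK)[idx]
        for c in track.counts_per_mark
    ]
    raw = np.concatenate(views, axis=1)
    starts = track.offset + idx * track.bin_size
    return starts, raw


def scan_genome(
    tracks: GenomeTrack | Mapping[str, GenomeTrack],
    patterns: Sequence[CharacteristicPattern],
    thresholds: ThresholdSet,
    known_promoters: Iterable[tuple[str, int, int]] = (),
    stride_bins: int = 1,
    max_count_threshold: float = MAX_COUNT_THRESHOLD,
) -> list[SignificanceWindow]:
    """Slide a 10 kb window across the genome and emit significance windows.

    A window is tested only if it does not overlap any known promoter
    window and its maximum raw count exceeds ``max_count_threshold``
    (strictly, matching the stated scan rule). One window may be emitted
    for several clusters; windows are returned sorted by (chrom, start,
    cluster).
    """
    if isinstance(tracks, GenomeTrack):
        tracks = {tracks.chrom: tracks}
    known_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in known_promoters:
        known_by_chrom.setdefault(c, []).append((s, e))

    out: list[SignificanceWindow] = []
    for chrom in sorted(tracks):
        track = tracks[chrom]
        starts, raw = _sliding_profiles(track, stride_bins)
        if len(starts) == 0:
            continue
        ends = starts + WINDOW_BP - 1

        keep = raw.max(axis=1) > max_count_threshold
        for a, b in known_by_chrom.get(chrom, []):
            keep &= ~((starts <= b) & (ends >= a))
        if not keep.any():
            continue
        starts, ends, raw = starts[keep], ends[keep], raw[keep]

        X = np.log1p(raw)
        Xc = X - X.mean(axis=1, keepdims=True)
        xnorm = np.linalg.norm(Xc, axis=1)
        for p in patterns:
            thr = thresholds.thresholds.get(p.cluster_id)
            if thr is None:
                continue
            pc = p.mean_log - p.mean_log.mean()
            pnorm = np.linalg.norm(pc)
            if pnorm == 0:
                logger.info("cluster %d pattern is constant; skipped", p.cluster_id)
                continue
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (Xc @ pc) / (xnorm * pnorm)
            sig = np.flatnonzero(r > thr)  # NaN (constant window) never passes
            out.extend(
                SignificanceWindow(chrom, int(starts[i]), int(ends[i]), p.cluster_id, float(r[i]))
                for i in sig
            )
    out.sort(key=lambda w: (w.chrom, w.start, w.cluster_id))
    return out


def merge_windows(
    windows: Sequence[SignificanceWindow], cluster_id: int | None = None
) -> list[SignificanceRegion]:
    """Collapse maximal runs of overlapping same-cluster windows.

    Two windows chain when they share at least 1 bp; the region spans
    [min start, max end] of its run and records the extreme windows,
    the maximum correlation and the number of member windows.
    """
    if cluster_id is not None:
        windows = [w for w in windows if w.cluster_id == cluster_id]
    if not windows:
        return []
    cids = {w.cluster_id for w in windows}
    if len(cids) > 1:
        raise ValueError(f"merge_windows got windows from several clusters: {sorted(cids)}")
    regions: list[SignificanceRegion] = []
    for chrom in sorted({w.chrom for w in windows}):
        ws = sorted((w for w in windows if w.chrom == chrom), key=lambda w: (w.start, w.end))
        cur = SignificanceRegion(chrom, ws[0].start, ws[0].end, ws[0].cluster_id,
                                 ws[0].r, ws[0], ws[0], 1)
        for w in ws[1:]:
            if w.start <= cur.end:  # >= 1 bp shared
                cur.end = max(cur.end, w.end)
                cur.max_r = max(cur.max_r, w.r)
                if w.start > cur.last_window.start:
                    cur.last_window = w
                cur.n_windows += 1
            else:
                regions.append(cur)
                cur = SignificanceRegion(chrom, w.start, w.end, w.cluster_id, w.r, w, w, 1)
        regions.append(cur)
    return regions


def group_and_assign(
    regions: Sequence[SignificanceRegion], min_windows: int = 1
) -> list[PutativePromoter]:
    """Group transitively overlapping regions (all clusters) into promoters.

    Each promoter spans the union of its member regions; its cluster is
    the member with the largest ``max_r``, ties broken toward the
    lowest cluster index. ``min_windows`` optionally drops thin "spike"
    regions supported by fewer windows before grouping (default 1 = off).
    """
    regions = [r for r in regions if r.n_windows >= min_windows]
    promoters: list[PutativePromoter] = []
    for chrom in sorted({r.chrom for r in regions}):
        rs = sorted((r for r in regions if r.chrom == chrom), key=lambda r: (r.start, r.end))
        group = [rs[0]]
        group_end = rs[0].end
        for r in rs[1:]:
            if r.start <= group_end:
                group.append(r)
                group_end = max(group_end, r.end)
            else:
                promoters.append(_make_promoter(chrom, group))
                group = [r]
                group_end = r.end
        promoters.append(_make_promoter(chrom, group))
    return promoters


def _make_promoter(chrom: str, group: list[SignificanceRegion]) -> PutativePromoter:
    winner = min(group, key=lambda r: (-r.max_r, r.cluster_id))
    return PutativePromoter(
        chrom, min(r.start for r in group), max(r.end for r in group),
        winner.cluster_id, list(group),
    )


def shorten_region(obj, mode: str = "both"):
    """Trim a region or promoter by half of its first/last window.

    ``first`` raises the start by half the first contributing window's
    width (5 kb at defaults), ``last`` lowers the end likewise, ``both``
    does both, ``none`` is the identity. If trimming would invert the
    interval the input is returned unchanged with a warning.
    """
    if mode == "none":
        return obj
    if mode not in ("first", "last", "both"):
        raise ValueError(f"mode must be one of none/first/last/both, got {mode!r}")
    if isinstance(obj, PutativePromoter):
        first = min((r.first_window for r in obj.evidence), key=lambda w: w.start)
        last = max((r.last_window for r in obj.evidence), key=lambda w: w.end)
    else:
        first, last = obj.first_window, obj.last_window
    new_start, new_end = obj.start, obj.end
    if mode in ("first", "both"):
        new_start = obj.start + (first.end - first.start + 1) // 2
    if mode in ("last", "both"):
        new_end = obj.end - (last.end - last.start + 1) // 2
    if new_start > new_end:
        logger.warning(
            "shortening %s:%d-%d (mode=%s) would invert the interval; left unchanged",
            obj.chrom, obj.start, obj.end, mode,
        )
        return obj
    return replace(obj, start=new_start, end=new_end)
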