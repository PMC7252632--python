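"""Overlap of putative promoters with annotation interval sets.

Summarizes, per cluster and overall, how predicted promoters intersect
three annotation tracks (typically ESTs, CpG islands and common SNPs)
as the seven cells of a three-set Venn diagram plus the fraction
overlapping at least one annotation. Overlap means sharing >= 1 bp.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .scan import PutativePromoter


@dataclass
class AnnotationSet:
    """Named, per-chromosome sorted intervals (1-based inclusive)."""

    name: str
    intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    # per chrom: (starts sorted, ends, running max of ends)

    @classmethod
    def from_intervals(cls, name: str, intervals: Sequence[tuple[str, int, int]]) -> "AnnotationSet":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for c, s, e in intervals:
            if s > e:
                raise ValueError(f"invalid interval {c}:{s}-{e}")
            by_chrom.setdefault(c, []).append((s, e))
        packed = {}
        for c, ivs in by_chrom.items():
            ivs.sort()
            starts = np.array([s for s, _ in ivs])
            ends = np.array([e for _, e in ivs])
            packed[c] = (starts, ends, np.maximum.accumulate(ends))
        return cls(name, packed)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end] shares >= 1 bp with any interval."""
        packed = self.intervals.get(chrom)
        if packed is None:
            return False
        starts, _, max_ends = packed
        i = int(np.searchsorted(starts, end, side="right"))
        return i > 0 and max_ends[i - 1] >= start


def load_bed(path: str | Path, name: str | None = None) -> AnnotationSet:
    """Load a BED3+ file, converting to 1-based inclusive coordinates.

    A 1-bp BED feature (e.g. a SNP, ``start = end - 1``) becomes a
    1-bp point interval.
    """
    path = Path(path)
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if start < 0 or end <= start:
                raise ValueError(f"{path}:{lineno}: malformed interval {start}-{end}")
            intervals.append((chrom, start + 1, end))
    return AnnotationSet.from_intervals(name or path.stem, intervals)


@dataclass
class OverlapSummary:
    """Venn-cell counts of promoter/annotation overlap, per cluster."""

    annotation_names: tuple[str, str, str]
    per_cluster: dict[int, dict[str, int]]  # cluster -> cell label -> count
    overall: dict[str, int]
    n_promoters: int

    @property
    def n_overlapping(self) -> int:
        return self.n_promoters - self.overall["none"]

    @property
    def pct_overlapping(self) -> float:
        """Percent of promoters overlapping >= 1 annotation."""
        return 100.0 * self.n_overlapping / self.n_promoters if self.n_promoters else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cluster, cells in sorted(self.per_cluster.items()):
            n = sum(cells.values())
            n_any = n - cells["none"]
            rows.append({"cluster": cluster, "n": n, **cells,
                         "pct_any": 100.0 * n_any / n if n else 0.0})
        n_any = self.n_promoters - self.overall["none"]
        rows.append({"cluster": "all", "n": self.n_promoters, **self.overall,
                     "pct_any": self.pct_overlapping})
        return pd.DataFrame(rows)


def _cell_labels(names: tuple[str, str, str]) -> dict[tuple[bool, bool, bool], str]:
    labels = {}
    for a in (False, True):
        for b in (False, True):
            for c in (False, True):
                hit = [n for n, f in zip(names, (a, b, c)) if f]
                labels[(a, b, c)] = "+".join(hit) if hit else "none"
    return labels


def overlap_summary(
    promoters: Sequence[PutativePromoter], annotations: Sequence[AnnotationSet]
) -> OverlapSummary:
    """Classify each promoter into one of the 7 Venn cells (or "none").

    The cells partition the promoters: a promoter overlapping all three
    sets is counted once, in the triple-intersection cell.
    """
    if len(annotations) != 3:
        raise ValueError(f"expected 3 annotation sets, got {len(annotations)}")
    names = tuple(a.name for a in annotations)
    labels = _cell_labels(names)
    per_cluster: dict[int, dict[str, int]] = {}
    overall = {lab: 0 for lab in labels.values()}
    for p in promoters:
        membership = tuple(a.overlaps(p.chrom, p.start, p.end) for a in annotations)
        cell = labels[membership]
        cells = per_cluster.setdefault(p.cluster_id, {lab: 0 for lab in labels.values()})
        cells[cell] += 1
        overall[cell] += 1
    return OverlapSummary(names, per_cluster, overall, len(promoters))
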