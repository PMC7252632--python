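"""Promoter profile construction from binned histone-mark coverage.

A promoter profile is the concatenation, in fixed mark order
(H3K4me2, H3K4me3, H3K9ac, H4K20me1), of four 100-bin windows of
100-bp intensity counts centred on a transcription start site (TSS):
a 400-length vector ``y(t)``, ``t in {1..400}``, spanning 10 kb per mark.

Coordinates are 1-based inclusive internally; BED/bedGraph I/O converts
to and from 0-based half-open (see :mod:`chromsig.io`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Fixed histone mark order of the concatenated profile segments.
MARKS: tuple[str, ...] = ("H3K4me2", "H3K4me3", "H3K9ac", "H4K20me1")
N_MARKS = len(MARKS)
BINS_PER_MARK = 100
PROFILE_LEN = N_MARKS * BINS_PER_MARK
DEFAULT_BIN_SIZE = 100
WINDOW_BP = 10_000
#: QC threshold on the maximum intensity count of a profile.
MAX_COUNT_THRESHOLD = 7


@dataclass
class GenomeTrack:
    """Binned coverage of one chromosome for all four histone marks.

    ``counts_per_mark[i][b]`` is the intensity count of mark ``MARKS[i]``
    in the bin covering genomic positions
    ``[offset + b*bin_size, offset + (b+1)*bin_size - 1]`` (1-based).
    """

    chrom: str
    counts_per_mark: list[np.ndarray]
    bin_size: int = DEFAULT_BIN_SIZE
    offset: int = 1

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError(f"bin_size must be positive, got {self.bin_size}")
        if len(self.counts_per_mark) != N_MARKS:
            raise ValueError(
                f"expected {N_MARKS} mark vectors, got {len(self.counts_per_mark)}"
            )
        self.counts_per_mark = [np.asarray(c, dtype=float) for c in self.counts_per_mark]
        lengths = {len(c) for c in self.counts_per_mark}
        if len(lengths) != 1:
            raise ValueError(f"mark vectors have unequal lengths: {sorted(lengths)}")
        for name, c in zip(MARKS, self.counts_per_mark):
            if np.any(c < 0):
                raise ValueError(f"negative counts in track for {name}")

    @property
    def n_bins(self) -> int:
        return len(self.counts_per_mark[0])

    @property
    def span(self) -> tuple[int, int]:
        """1-based inclusive genomic span covered by the bins."""
        return self.offset, self.offset + self.n_bins * self.bin_size - 1


@dataclass(frozen=True)
class TSSRecord:
    """A transcription start site anchoring one promoter window."""

    chrom: str
    tss: int
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.tss < 1:
            raise ValueError(f"tss must be >= 1, got {self.tss} ({self.gene_id})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass
class ProfileMatrix:
    """n stacked 400-bin concatenated promoter profiles.

    ``transform_state`` tracks whether values are raw intensity counts
    or log-transformed (``ln(1 + y)``).
    """

    values: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    windows: list[tuple[str, int, int]] = field(default_factory=list)
    transform_state: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.size and self.values.shape[1] != PROFILE_LEN:
            raise ValueError(
                f"profiles must have length {PROFILE_LEN}, got {self.values.shape[1]}"
            )
        if not self.gene_ids:
            self.gene_ids = [f"profile_{i}" for i in range(self.n)]
        if len(self.gene_ids) != self.n:
            raise ValueError("gene_ids length does not match number of profiles")
        if self.transform_state not in ("raw", "log"):
            raise ValueError(f"unknown transform_state {self.transform_state!r}")

    @property
    def n(self) -> int:
        return 0 if self.values.size == 0 else self.values.shape[0]

    def segments(self, row: int) -> list[np.ndarray]:
        """De-concatenate one profile into its four per-mark windows."""
        y = self.values[row]
        return [y[i * BINS_PER_MARK : (i + 1) * BINS_PER_MARK] for i in range(N_MARKS)]


def bin_coverage(
    intervals_per_mark: Sequence[Iterable[tuple[str, int, int, float]]],
    bin_size: int = DEFAULT_BIN_SIZE,
    chrom: str | None = None,
    span: tuple[int, int] | None = None,
) -> GenomeTrack:
    """Quantify per-base coverage intervals into consecutive fixed-width bins.

    Parameters
    ----------
    intervals_per_mark
        One interval list per mark, in the fixed mark order. Each interval is
        ``(chrom, start, end, value)`` with 1-based inclusive coordinates and
        a non-negative per-base value; intervals of one mark must not overlap.
    span
        Optional 1-based inclusive ``(start, end)`` to tile with bins; by
        default the union span of all intervals. Required if all lists are
        empty.

    Each bin's count is the sum of the per-base values over its bases.
    """
    if len(intervals_per_mark) != N_MARKS:
        raise ValueError(f"expected {N_MARKS} interval lists, got {len(intervals_per_mark)}")
    lists = [list(iv) for iv in intervals_per_mark]

    for mark, ivs in zip(MARKS, lists):
        for i, (c, s, e, v) in enumerate(ivs):
            if s < 1 or e < s:
                raise ValueError(f"{mark} line {i + 1}: malformed interval {c}:{s}-{e}")
            if v < 0:
                raise ValueError(f"{mark} line {i + 1}: negative value {v}")
            if chrom is None:
                chrom = c
            elif c != chrom:
                raise ValueError(f"{mark} line {i + 1}: chromosome {c!r} != {chrom!r}")

    if span is None:
        all_iv = [iv for ivs in lists for iv in ivs]
        if not all_iv:
            raise ValueError("no intervals and no span declared")
        span = (min(iv[1] for iv in all_iv), max(iv[2] for iv in all_iv))
    offset = span[0]
    n_bins = max(1, math.ceil((span[1] - offset + 1) / bin_size))

    counts = []
    for ivs in lists:
        vec = np.zeros(n_bins)
        for c, s, e, v in ivs:
            b0 = (s - offset) // bin_size
            b1 = (e - offset) // bin_size
            for b in range(max(b0, 0), min(b1, n_bins - 1) + 1):
                bs = offset + b * bin_size
                be = bs + bin_size - 1
                overlap = min(e, be) - max(s, bs) + 1
                if overlap > 0:
                    vec[b] += v * overlap
        counts.append(vec)
    return GenomeTrack(chrom or "chr?", counts, bin_size=bin_size, offset=offset)


def extract_window(
    track: GenomeTrack, tss: TSSRecord, flank_bins: int = 50
) -> np.ndarray | None:
    """Extract the ``2*flank_bins`` bins of each mark around a TSS.

    The window covers ``[tss - flank_bins*bin_size + 1, tss + flank_bins*bin_size]``
    (10 kb at defaults), i.e. ``flank_bins`` bins upstream of and including
    the TSS and ``flank_bins`` downstream. For minus-strand records the bin
    order is reversed so index 0 is always the most-upstream bin.

    Returns an ``(4, 2*flank_bins)`` array, or ``None`` (with a logged
    warning) when the window exceeds the track span.
    """
    win_start = tss.tss - flank_bins * track.bin_size + 1
    idx = (win_start - track.offset) // track.bin_size
    n = 2 * flank_bins
    if idx < 0 or idx + n > track.n_bins:
        logger.warning(
            "window for %s (%s:%d) exceeds track span; record skipped",
            tss.gene_id, tss.chrom, tss.tss,
        )
        return None
    out = np.stack([c[idx : idx + n] for c in track.counts_per_mark])
    if tss.strand == "-":
        out = out[:, ::-1]
    return out


def build_profiles(
    tracks: GenomeTrack | Mapping[str, GenomeTrack],
    tss_list: Sequence[TSSRecord],
    flank_bins: int = 50,
) -> ProfileMatrix:
    """Build the concatenated 400-bin profile for each TSS.

    ``tracks`` is a single :class:`GenomeTrack` or a mapping from chromosome
    name to track. TSS records whose chromosome is absent or whose window
    falls off the track are skipped with a warning.
    """
    if isinstance(tracks, GenomeTrack):
        tracks = {tracks.chrom: tracks}
    grids = {(t.bin_size, t.offset % t.bin_size) for t in tracks.values()}
    if len(grids) > 1:
        raise ValueError(f"tracks do not share a bin grid: {sorted(grids)}")

    rows, ids, windows = [], [], []
    for rec in tss_list:
        track = tracks.get(rec.chrom)
        if track is None:
            logger.warning("no track for chromosome %s; %s skipped", rec.chrom, rec.gene_id)
            continue
        win = extract_window(track, rec, flank_bins)
        if win is None:
            continue
        rows.append(win.reshape(-1))
        ids.append(rec.gene_id)
        half = flank_bins * track.bin_size
        windows.append((rec.chrom, rec.tss - half + 1, rec.tss + half))
    values = np.array(rows) if rows else np.empty((0, N_MARKS * 2 * flank_bins))
    return ProfileMatrix(values, ids, windows, transform_state="raw")


def filter_low_signal(
    matrix: ProfileMatrix, threshold: float = MAX_COUNT_THRESHOLD, mode: str = "promoter"
) -> ProfileMatrix:
    """QC-filter profiles by their maximum intensity count.

    ``promoter`` mode drops profiles whose maximum is *less than* the
    threshold (keeps max >= threshold); ``scan`` mode keeps only profiles
    whose maximum is *greater than* the threshold. The two rules differ at
    exactly the threshold and both are kept as stated.
    """
    if matrix.transform_state != "raw":
        raise ValueError("filter_low_signal requires raw-scale counts")
    if mode not in ("promoter", "scan"):
        raise ValueError(f"unknown mode {mode!r}")
    if matrix.n == 0:
        return matrix
    maxima = matrix.values.max(axis=1)
    keep = maxima >= threshold if mode == "promoter" else maxima > threshold
    return ProfileMatrix(
        matrix.values[keep],
        [g for g, k in zip(matrix.gene_ids, keep) if k],
        [w for w, k in zip(matrix.windows, keep) if k] if matrix.windows else [],
        transform_state="raw",
    )


def remove_overlapping_promoters(
    tss_list: Sequence[TSSRecord], window_bp: int = WINDOW_BP
) -> list[TSSRecord]:
    """Drop every TSS whose window overlaps another TSS's window.

    Both members of an overlapping pair are removed (ambiguous attribution
    of counts). Windows are the same 10 kb regions used for profiles; two
    windows on one chromosome overlap iff their TSSs are closer than
    ``window_bp``.
    """
    bad: set[int] = set()
    by_chrom: dict[str, list[int]] = {}
    for i, rec in enumerate(tss_list):
        by_chrom.setdefault(rec.chrom, []).append(i)
    for idxs in by_chrom.values():
        idxs = sorted(idxs, key=lambda i: tss_list[i].tss)
        for a, b in zip(idxs, idxs[1:]):
            if tss_list[b].tss - tss_list[a].tss < window_bp:
                bad.add(a)
                bad.add(b)
    return [rec for i, rec in enumerate(tss_list) if i not in bad]


def log_transform(matrix: ProfileMatrix) -> ProfileMatrix:
    """Elementwise ``ln(1 + y)``; marks the matrix as log-scale.

    ``ln(1+y)`` rather than ``ln(y)`` because raw bins contain zeros.
    """
    if matrix.transform_state != "raw":
        raise ValueError("matrix is already log-transformed")
    return replace(matrix, values=np.log1p(matrix.values), transform_state="log")
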