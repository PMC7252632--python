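"""Readers and writers for the text formats the pipeline speaks.

bedGraph and BED use 0-based half-open coordinates on disk; everything
in memory is 1-based inclusive. Profiles travel as TSV with one row per
gene and 400 columns named ``<mark>_bin<k>``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .profiles import BINS_PER_MARK, MARKS, PROFILE_LEN, GenomeTrack, ProfileMatrix, TSSRecord

PROFILE_COLUMNS = [f"{mark}_bin{b + 1}" for mark in MARKS for b in range(BINS_PER_MARK)]


def read_bedgraph(path: str | Path) -> list[tuple[str, int, int, float]]:
    """Read a 4-column bedGraph into 1-based inclusive intervals."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            try:
                chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if start < 0 or end <= start:
                raise ValueError(f"{path}:{lineno}: malformed interval {start}-{end}")
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative value {value}")
            intervals.append((chrom, start + 1, end, value))
    return intervals


def write_bedgraph(track: GenomeTrack, mark: str, path: str | Path) -> None:
    """Write one mark of a track as bedGraph (one line per non-zero bin)."""
    mi = MARKS.index(mark)
    counts = track.counts_per_mark[mi]
    with open(path, "w") as fh:
        for b, v in enumerate(counts):
            if v == 0:
                continue
            start0 = track.offset - 1 + b * track.bin_size
            fh.write(f"{track.chrom}\t{start0}\t{start0 + track.bin_size}\t{v:g}\n")


def read_tss_bed(path: str | Path) -> list[TSSRecord]:
    """Read a BED6 TSS list.

    The TSS is the strand-aware 5' end of the record: ``start + 1``
    (1-based) for plus-strand entries, ``end`` for minus-strand.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: BED6 requires 6 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name, strand = parts[3], parts[5]
            tss = start + 1 if strand == "+" else end
            records.append(TSSRecord(chrom, tss, strand, name))
    return records


def write_profiles_tsv(matrix: ProfileMatrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.values, columns=PROFILE_COLUMNS)
    df.insert(0, "gene_id", matrix.gene_ids)
    if matrix.windows:
        df.insert(1, "chrom", [w[0] for w in matrix.windows])
        df.insert(2, "start", [w[1] for w in matrix.windows])
        df.insert(3, "end", [w[2] for w in matrix.windows])
    df.to_csv(path, sep="\t", index=False)


def read_profiles_tsv(path: str | Path, transform_state: str = "raw") -> ProfileMatrix:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing {len(missing)} profile columns (e.g. {missing[0]})")
    windows = []
    if {"chrom", "start", "end"} <= set(df.columns):
        windows = list(zip(df["chrom"], df["start"].astype(int), df["end"].astype(int)))
    return ProfileMatrix(
        df[PROFILE_COLUMNS].to_numpy(dtype=float),
        list(df["gene_id"].astype(str)),
        windows,
        transform_state=transform_state,
    )


def write_labels_tsv(gene_ids: Sequence[str], labels: np.ndarray,
                     responsibilities: np.ndarray, path: str | Path) -> None:
    df = pd.DataFrame({"gene_id": list(gene_ids), "cluster": labels})
    for k in range(responsibilities.shape[1]):
        df[f"resp_cluster{k + 1}"] = responsibilities[:, k]
    df.to_csv(path, sep="\t", index=False)


def write_patterns_tsv(patterns, path: str | Path) -> None:
    rows = []
    for p in patterns:
        rows.append({"cluster": p.cluster_id, "scale": "raw", "n_members": p.n_members,
                     **dict(zip(PROFILE_COLUMNS, p.mean_raw))})
        rows.append({"cluster": p.cluster_id, "scale": "log", "n_members": p.n_members,
                     **dict(zip(PROFILE_COLUMNS, p.mean_log))})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_promoters_bed(promoters, path: str | Path) -> None:
    """Putative promoters as BED6: name = cluster, score = round(1000*max_r)."""
    with open(path, "w") as fh:
        for p in promoters:
            score = int(round(1000 * max(0.0, min(1.0, p.max_r))))
            fh.write(f"{p.chrom}\t{p.start - 1}\t{p.end}\tcluster{p.cluster_id}\t{score}\t.\n")


def write_promoters_tsv(promoters, path: str | Path) -> None:
    rows = []
    for p in promoters:
        for r in p.evidence:
            rows.append({
                "chrom": p.chrom, "start": p.start, "end": p.end,
                "cluster": p.cluster_id, "max_r": p.max_r,
                "evidence_cluster": r.cluster_id, "evidence_start": r.start,
                "evidence_end": r.end, "evidence_max_r": r.max_r,
                "evidence_n_windows": r.n_windows,
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_manifest(path: str | Path, **params) -> None:
    """Record run parameters (alpha, thresholds, seed, ...) as JSON."""
    with open(path, "w") as fh:
        json.dump(params, fh, indent=2, default=float)
        fh.write("\n")
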