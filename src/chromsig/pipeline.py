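"""End-to-end orchestration: QC -> FPCA -> EM -> thresholds -> scan.

Thin glue over the stage modules; every step is available separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import fpca as _fpca
from . import mixture as _mixture
from . import scan as _scan
from .profiles import GenomeTrack, ProfileMatrix, filter_low_signal, log_transform


@dataclass
class TrainedModel:
    """Everything learned from the training promoters."""

    fpca: _fpca.FPCAModel
    mixture: _mixture.MixtureModel
    patterns: list[_mixture.CharacteristicPattern]
    thresholds: _scan.ThresholdSet
    scan_clusters: list[int]
    matrix_raw: ProfileMatrix


def train(
    matrix_raw: ProfileMatrix,
    K: int = 4,
    fve_threshold: float = 0.90,
    q_override: int | None = None,
    alpha: float = 0.4,
    seed: int = 0,
    n_restarts: int = 10,
    qc_filter: bool = True,
    exclude_inactive: bool = True,
) -> TrainedModel:
    """Learn characteristic patterns and scan thresholds from raw profiles.

    Applies the promoter QC filter (max count >= 7) unless ``qc_filter``
    is off, log-transforms, fits FPCA (q by FVE), clusters the scores by
    EM, renumbers clusters canonically (descending mean total signal),
    and computes the per-cluster 100*alpha-percentile correlation
    thresholds. With ``exclude_inactive`` the least-active cluster (the
    canonical last, capturing inactive promoters) is left out of the
    scan cluster list.
    """
    if qc_filter:
        matrix_raw = filter_low_signal(matrix_raw, mode="promoter")
    matrix_log = log_transform(matrix_raw)
    model = _fpca.fit_fpca(matrix_log, fve_threshold=fve_threshold, q_override=q_override)
    mix = _mixture.fit_em(model.scores, K, seed=seed, n_restarts=n_restarts)
    mix = _mixture.canonicalize(mix, matrix_raw)
    patterns = _mixture.characteristic_patterns(matrix_raw, mix.labels)
    scan_clusters = [p.cluster_id for p in patterns]
    if exclude_inactive and K > 1:
        scan_clusters = scan_clusters[:-1]
    scan_patterns = [p for p in patterns if p.cluster_id in scan_clusters]
    thresholds = _scan.correlation_thresholds(matrix_raw, scan_patterns, mix.labels, alpha=alpha)
    return TrainedModel(model, mix, patterns, thresholds, scan_clusters, matrix_raw)


def predict(
    tracks: GenomeTrack | Mapping[str, GenomeTrack],
    trained: TrainedModel,
    known_promoters: Iterable[tuple[str, int, int]] = (),
    stride_bins: int = 1,
    max_count_threshold: float = 7,
    min_windows: int = 1,
    shorten: str = "none",
) -> list[_scan.PutativePromoter]:
    """Scan tracks with the trained patterns and call putative promoters."""
    scan_patterns = [p for p in trained.patterns if p.cluster_id in trained.scan_clusters]
    windows = _scan.scan_genome(
        tracks, scan_patterns, trained.thresholds, known_promoters,
        stride_bins=stride_bins, max_count_threshold=max_count_threshold,
    )
    regions: list[_scan.SignificanceRegion] = []
    for k in trained.scan_clusters:
        regions.extend(_scan.merge_windows(windows, cluster_id=k))
    promoters = _scan.group_and_assign(regions, min_windows=min_windows)
    if shorten != "none":
        promoters = [_scan.shorten_region(p, mode=shorten) for p in promoters]
    return promoters


def clustering_accuracy(labels: np.ndarray, truth: np.ndarray) -> float:
    """Best-permutation agreement between predicted and true labels.

    Maximizes accuracy over all assignments of predicted clusters to
    true clusters (Hungarian algorithm on the contingency table).
    """
    from scipy.optimize import linear_sum_assignment

    labels = np.asarray(labels)
    truth = np.asarray(truth)
    ks = np.unique(np.concatenate([labels, truth]))
    table = np.zeros((len(ks), len(ks)))
    index = {k: i for i, k in enumerate(ks)}
    for a, b in zip(labels, truth):
        table[index[a], index[b]] += 1
    row, col = linear_sum_assignment(-table)
    return float(table[row, col].sum() / len(labels))
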