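"""Synthetic profiles and genome tracks with the structure the method assumes.

Four cluster-specific mean shapes on the log-count scale mirror the
promoter signatures the method is built to recover: elevated signal
upstream of the TSS (descending ramp), downstream (ascending ramp), a
symmetric unimodal peak at the TSS, and a flat inactive baseline. The
first three shapes are shared by the H3K4me2/H3K4me3/H3K9ac segments;
the H4K20me1 segment stays at baseline in every cluster. Profiles are
the shape plus iid Gaussian noise on the log scale, exponentiated and
rounded to non-negative integer counts — matching the
Gaussian-after-log assumption of the mixture step. The genome simulator
embeds full four-mark signatures into a low-count Poisson background at
known positions and reports them as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .profiles import (
    BINS_PER_MARK,
    DEFAULT_BIN_SIZE,
    N_MARKS,
    PROFILE_LEN,
    WINDOW_BP,
    GenomeTrack,
    ProfileMatrix,
)

#: Log-scale baseline, ~ exp(1)-1 ~ 1.7 counts of background per bin.
DEFAULT_BASELINE = 1.0
#: Log-scale peak height above baseline; profile max ~ exp(3.5)-1 ~ 32
#: counts, well above the QC threshold of 7, while the flat cluster
#: hovers near baseline so that some of its profiles fail QC.
DEFAULT_AMPLITUDE = 2.5
#: Per-bin log-scale noise used for profile simulation ("moderate").
DEFAULT_NOISE_SD = 0.4

N_CLUSTERS = 4
ACTIVE_CLUSTERS = (1, 2, 3)
MIN_SITE_SPACING_BP = 20_000


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic-profile generator."""

    n_per_cluster: tuple[int, int, int, int] = (100, 100, 100, 100)
    noise_sd: float = DEFAULT_NOISE_SD
    amplitude: float = DEFAULT_AMPLITUDE
    baseline: float = DEFAULT_BASELINE
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_cluster) != N_CLUSTERS:
            raise ValueError(f"n_per_cluster needs {N_CLUSTERS} entries")
        if any(n < 0 for n in self.n_per_cluster):
            raise ValueError("n_per_cluster must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def make_patterns(amplitude: float = DEFAULT_AMPLITUDE,
                  baseline: float = DEFAULT_BASELINE) -> np.ndarray:
    """The four cluster mean shapes, (4, 400) on the log scale.

    Per 100-bin segment of the first three marks:
      cluster 1 — ramp descending from ``baseline + amplitude`` at the
        upstream edge to baseline at bin 50 (the TSS), flat after;
      cluster 2 — the mirror ascending ramp, baseline until the TSS
        then rising to ``baseline + amplitude`` at the downstream edge;
      cluster 3 — a symmetric unimodal (Gaussian-shaped) peak centred
        on the TSS;
      cluster 4 — flat baseline.
    The fourth (H4K20me1) segment is flat baseline in all four.
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    half = BINS_PER_MARK // 2
    seg1 = np.full(BINS_PER_MARK, baseline)
    seg1[:half] += amplitude * np.linspace(1.0, 0.0, half)
    seg2 = np.full(BINS_PER_MARK, baseline)
    seg2[half:] += amplitude * np.linspace(0.0, 1.0, half)
    b = np.arange(BINS_PER_MARK)
    centre = (BINS_PER_MARK - 1) / 2
    seg3 = baseline + amplitude * np.exp(-0.5 * ((b - centre) / 12.0) ** 2)
    seg4 = np.full(BINS_PER_MARK, baseline)

    flat = np.full(BINS_PER_MARK, baseline)
    patterns = np.empty((N_CLUSTERS, PROFILE_LEN))
    for k, seg in enumerate((seg1, seg2, seg3, seg4)):
        active = seg if k < 3 else flat
        patterns[k] = np.concatenate([active, active, active, flat])
    return patterns


def _log_to_counts(log_values: np.ndarray) -> np.ndarray:
    return np.maximum(np.rint(np.expm1(log_values)), 0.0)


def simulate_profiles(spec: SyntheticSpec) -> tuple[ProfileMatrix, np.ndarray]:
    """Draw raw-count profiles from the four patterns plus log-scale noise.

    Returns the raw :class:`ProfileMatrix` and the true 1-based cluster
    labels. Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    patterns = make_patterns(spec.amplitude, spec.baseline)
    rows, labels, ids = [], [], []
    for k, n_k in enumerate(spec.n_per_cluster, start=1):
        noise = rng.normal(0.0, spec.noise_sd, size=(n_k, PROFILE_LEN))
        rows.append(_log_to_counts(patterns[k - 1] + noise))
        labels.extend([k] * n_k)
        ids.extend(f"sim_c{k}_{i:04d}" for i in range(n_k))
    values = np.vstack(rows) if rows else np.empty((0, PROFILE_LEN))
    return ProfileMatrix(values, ids, transform_state="raw"), np.array(labels, dtype=int)


class SiteTruth(NamedTuple):
    """Ground-truth location and cluster of one embedded signature."""

    chrom: str
    start: int  # 1-based inclusive, width 10 kb
    end: int
    cluster_id: int


def simulate_genome(
    spec: SyntheticSpec,
    n_sites: int,
    genome_length: int,
    background_level: float = 1.0,
    chrom: str = "chrS",
) -> tuple[GenomeTrack, list[SiteTruth]]:
    """A toy chromosome of Poisson background with embedded signatures.

    ``n_sites`` full four-mark signatures of randomly chosen active
    clusters (1-3) are written at positions spaced >= 20 kb apart so
    neighbouring signatures cannot merge during the scan. Returns the
    four-mark track and the truth records.
    """
    bin_size = DEFAULT_BIN_SIZE
    n_bins = genome_length // bin_size
    window_bins = WINDOW_BP // bin_size
    spacing_bins = MIN_SITE_SPACING_BP // bin_size
    rng = np.random.default_rng(spec.seed)

    counts = rng.poisson(background_level, size=(N_MARKS, n_bins)).astype(float)
    patterns = make_patterns(spec.amplitude, spec.baseline)

    truth: list[SiteTruth] = []
    if n_sites > 0:
        usable = n_bins - window_bins
        step = usable // n_sites
        if step < spacing_bins:
            raise ValueError(
                f"genome of {genome_length} bp too short for {n_sites} sites "
                f"spaced >= {MIN_SITE_SPACING_BP} bp"
            )
        jitter = rng.integers(0, step - spacing_bins + 1, size=n_sites)
        clusters = rng.choice(ACTIVE_CLUSTERS, size=n_sites)
        for i in range(n_sites):
            sb = i * step + int(jitter[i])
            k = int(clusters[i])
            sig = patterns[k - 1] + rng.normal(0.0, spec.noise_sd, PROFILE_LEN)
            sig = _log_to_counts(sig).reshape(N_MARKS, window_bins)
            counts[:, sb : sb + window_bins] = sig
            start = 1 + sb * bin_size
            truth.append(SiteTruth(chrom, start, start + WINDOW_BP - 1, k))

    track = GenomeTrack(chrom, list(counts), bin_size=bin_size, offset=1)
    return track, truth


def write_truth_bed(truth: list[SiteTruth], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in truth:
            fh.write(f"{t.chrom}\t{t.start - 1}\t{t.end}\tcluster{t.cluster_id}\t0\t.\n")
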