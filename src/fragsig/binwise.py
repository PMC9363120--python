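"""Genome-binned fragmentomics.

Tiles the genome into fixed-size bins (250 kb by default), builds per-bin
fragment-length histograms, aggregates them across healthy controls, screens
out bins with aberrant coverage (median +/- 2*IQR on the per-bin mean
fragment count), learns chromatin-state length signatures by bin-wise
KL-NMF, and projects per-sample per-bin histograms onto fixed signatures to
produce classification features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fragments import FilterCounters, FragmentFilterConfig, _iter_fragments, \
    _open_alignment
from .histograms import HistogramMatrix, LengthHistogram, assemble_matrix, \
    normalize_rows
from .nmf import Factorization, fit_nmf, transform_weights_array

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicBin",
    "BinMatrix",
    "read_chrom_sizes",
    "make_bins",
    "binned_histograms",
    "aggregate_controls",
    "qc_bins",
    "binwise_signatures",
    "per_bin_weight_features",
    "signal_rank_correlation",
]

DEFAULT_BIN_SIZE = 250_000

#: hg-style autosome names, the default chromosome universe
AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23)) + tuple(str(i) for i in range(1, 23))


@dataclass(frozen=True)
class GenomicBin:
    """One tile of the genome, 0-based half-open."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid bin bounds {self.start}..{self.end}")

    @property
    def bin_id(self) -> str:
        return f"{self.chromosome}:{self.start}-{self.end}"


@dataclass
class BinMatrix:
    """Bins x lengths histogram matrix with provenance and QC bookkeeping."""

    matrix: HistogramMatrix
    provenance: str = "single-sample"   # or "aggregated-controls"
    kept_bins: list[str] | None = None

    def __post_init__(self) -> None:
        if self.kept_bins is not None:
            missing = set(self.kept_bins) - set(self.matrix.row_labels)
            if missing:
                raise ValueError(f"kept_bins not in matrix: {sorted(missing)[:5]}")


def read_chrom_sizes(path: str, autosomes_only: bool = True) -> dict[str, int]:
    """Read a two-column chrom.sizes TSV (name, length)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"],
                     usecols=[0, 1])
    sizes = {str(c): int(s) for c, s in zip(df["chrom"], df["size"])}
    if autosomes_only:
        filtered = {c: s for c, s in sizes.items() if c in AUTOSOMES}
        if filtered:
            sizes = filtered
    for chrom, size in sizes.items():
        if size <= 0:
            raise ValueError(f"non-positive size for {chrom}")
    return sizes


def make_bins(chrom_sizes: dict[str, int],
              bin_size: int = DEFAULT_BIN_SIZE) -> list[GenomicBin]:
    """Tile each chromosome with non-overlapping bins; terminal bins may be short."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    bins = []
    for chrom, size in chrom_sizes.items():
        for start in range(0, size, bin_size):
            bins.append(GenomicBin(chrom, start, min(start + bin_size, size)))
    return bins


def binned_histograms(
    alignment_file: str,
    bins: list[GenomicBin],
    filters: FragmentFilterConfig | None = None,
) -> BinMatrix:
    """Per-bin fragment-length histograms for one sample.

    Each retained fragment is assigned to exactly one bin by its midpoint.
    Fragments on chromosomes outside the bin set are skipped (counted).
    """
    filters = filters or FragmentFilterConfig()
    grid = filters.grid()
    by_chrom: dict[str, list[GenomicBin]] = {}
    for b in bins:
        by_chrom.setdefault(b.chromosome, []).append(b)
    bin_size = max((b.end - b.start for b in bins), default=0)
    counts = {b.bin_id: np.zeros(grid.size, dtype=np.int64) for b in bins}
    counters = FilterCounters()
    lo = int(grid[0])
    with _open_alignment(alignment_file) as af:
        for mates, length in _iter_fragments(af, filters, counters):
            first = mates[0]
            chrom_bins = by_chrom.get(first.reference_name)
            if chrom_bins is None:
                counters.skipped_chromosome += 1
                continue
            midpoint = first.reference_start + length // 2
            idx = min(midpoint // bin_size, len(chrom_bins) - 1)
            b = chrom_bins[idx]
            if lo <= length <= int(grid[-1]):
                counts[b.bin_id][length - lo] += 1
    hists = [LengthHistogram(b.bin_id, counts[b.bin_id], grid.copy()) for b in bins]
    return BinMatrix(assemble_matrix(hists), provenance="single-sample")


def aggregate_controls(per_sample: list[BinMatrix]) -> BinMatrix:
    """Element-wise sum of per-sample bin matrices (healthy controls)."""
    if not per_sample:
        raise ValueError("no control matrices to aggregate")
    ref = per_sample[0].matrix
    total = ref.values.astype(np.int64).copy()
    for bm in per_sample[1:]:
        m = bm.matrix
        if m.row_labels != ref.row_labels or np.any(m.lengths != ref.lengths):
            raise ValueError("bin sets or length grids differ between controls")
        total += m.values
    agg = HistogramMatrix(list(ref.row_labels), ref.lengths.copy(), total,
                          normalized=False)
    return BinMatrix(agg, provenance="aggregated-controls")


def qc_bins(per_sample_controls: list[BinMatrix]) -> list[str]:
    """Coverage-based bin QC across control samples.

    Computes each bin's mean fragment count over the controls, then the
    median and IQR (linear-interpolation quartiles) of those means over bins,
    and keeps bins whose mean lies within [median - 2*IQR, median + 2*IQR]
    (inclusive). Screens out mappability artefacts at both extremes.
    """
    if len(per_sample_controls) < 2:
        raise ValueError("bin QC needs at least 2 control samples")
    ref = per_sample_controls[0].matrix
    totals = np.vstack([bm.matrix.row_totals() for bm in per_sample_controls])
    for bm in per_sample_controls[1:]:
        if bm.matrix.row_labels != ref.row_labels:
            raise ValueError("bin sets differ between controls")
    means = totals.mean(axis=0)
    median = float(np.median(means))
    q1, q3 = np.percentile(means, [25, 75])  # type-7 linear interpolation
    iqr = float(q3 - q1)
    lo, hi = median - 2 * iqr, median + 2 * iqr
    kept = [lab for lab, m in zip(ref.row_labels, means) if lo <= m <= hi]
    logger.info("bin QC: kept %d / %d bins (window [%.1f, %.1f])",
                len(kept), len(ref.row_labels), lo, hi)
    return kept


def binwise_signatures(aggregated: BinMatrix, k: int, restarts: int = 20,
                       seed: int = 0, max_iter: int = 2000,
                       tol: float = 1e-6) -> Factorization:
    """Chromatin-state length signatures from the aggregated control bins.

    Restricts to QC-kept bins when available, drops empty bins, row-normalizes
    and fits KL-NMF with random restarts.
    """
    m = aggregated.matrix
    if aggregated.kept_bins is not None:
        m = m.select_rows(aggregated.kept_bins)
    norm = normalize_rows(m, drop_empty=True)
    return fit_nmf(norm, k, restarts=restarts, max_iter=max_iter, tol=tol,
                   seed=seed)


def per_bin_weight_features(
    sample_bins: BinMatrix,
    H_fixed: np.ndarray,
    component: int = 0,
    kept_bins: list[str] | None = None,
    min_fragments: int = 100,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> pd.Series:
    """Per-bin weight of one signature in one sample, as a feature vector.

    Each kept bin's histogram is normalized and projected onto the fixed
    signatures; the selected component's weight is emitted. Bins with fewer
    than ``min_fragments`` fragments yield NaN rather than noisy weights.
    """
    m = sample_bins.matrix
    kept = kept_bins if kept_bins is not None else \
        (sample_bins.kept_bins if sample_bins.kept_bins is not None
         else list(m.row_labels))
    H_fixed = np.asarray(H_fixed, dtype=float)
    if H_fixed.shape[1] != m.lengths.size:
        raise ValueError("signature grid does not match bin matrix grid")
    if not 0 <= component < H_fixed.shape[0]:
        raise ValueError(f"component {component} out of range")
    sub = m.select_rows(kept)
    totals = sub.row_totals()
    ok = totals >= min_fragments
    feats = np.full(len(kept), np.nan)
    if ok.any():
        freq = sub.values[ok] / totals[ok, None]
        W = transform_weights_array(freq, H_fixed, max_iter=max_iter, tol=tol)
        feats[ok] = W[:, component]
    return pd.Series(feats, index=pd.Index(kept, name="bin_id"), name="weight")


def signal_rank_correlation(features: pd.Series, signal: pd.DataFrame | pd.Series,
                            method: str = "spearman") -> float:
    """Rank correlation between per-bin features and an external per-bin signal.

    ``signal`` is either a Series indexed by bin id or a (bin_id, value)
    table, e.g. chromatin accessibility from ATAC-seq; correlation is over
    bins present in both, pairwise-complete.
    """
    from .ctdna import correlate
    if isinstance(signal, pd.DataFrame):
        signal = signal.set_index(signal.columns[0])[signal.columns[1]]
    common = features.index.intersection(signal.index)
    if len(common) < 3:
        raise ValueError("fewer than 3 bins shared with the signal")
    return correlate(features.loc[common].to_numpy(),
                     signal.loc[common].to_numpy(), method=method)
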