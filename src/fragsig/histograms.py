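"""Fragment-length histograms and sample x length matrices.

The central containers of the package: a :class:`LengthHistogram` holds the
integer fragment-length counts of one sample (or one genomic bin) on a
contiguous length grid, and a :class:`HistogramMatrix` stacks many of them
into the samples-by-lengths matrix that the NMF deconvolution consumes.
Matrices round-trip losslessly through a plain TSV dialect (first column
``label``, remaining columns headed by the integer lengths).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default fragment-length grid bounds (bp). Fragments shorter than 30 bp are
#: indistinguishable from adapter artefacts; above 700 bp tri-nucleosome and
#: high-molecular-weight contamination dominate.
DEFAULT_MIN_LENGTH = 30
DEFAULT_MAX_LENGTH = 700


def default_grid(min_length: int = DEFAULT_MIN_LENGTH,
                 max_length: int = DEFAULT_MAX_LENGTH) -> np.ndarray:
    """Contiguous integer length grid ``min_length .. max_length`` inclusive."""
    if not 0 < min_length <= max_length:
        raise ValueError(f"invalid length bounds [{min_length}, {max_length}]")
    return np.arange(min_length, max_length + 1)


@dataclass
class LengthHistogram:
    """Integer fragment counts for one sample or genomic bin.

    Parameters
    ----------
    label : str
        Sample or bin identifier.
    counts : ndarray of int
        One count per grid position, all non-negative.
    lengths : ndarray of int
        Contiguous, strictly increasing length grid (bp).
    """

    label: str
    counts: np.ndarray
    lengths: np.ndarray = field(default_factory=default_grid)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        if self.counts.shape != self.lengths.shape:
            raise ValueError(
                f"histogram {self.label!r}: {self.counts.size} counts for "
                f"{self.lengths.size} grid positions")
        if np.any(self.counts < 0):
            raise ValueError(f"histogram {self.label!r}: negative counts")
        if self.lengths.size == 0 or np.any(np.diff(self.lengths) != 1):
            raise ValueError(f"histogram {self.label!r}: grid must be contiguous")

    @property
    def total(self) -> int:
        """Total number of fragments in the histogram."""
        return int(self.counts.sum())

    def frequencies(self) -> np.ndarray:
        """Counts normalized to sum to one; errors on an empty histogram."""
        if self.total == 0:
            raise ValueError(f"histogram {self.label!r} is empty; cannot normalize")
        return self.counts / self.total

    def add(self, length: int, n: int = 1) -> None:
        """Increment the count at ``length`` by ``n`` (no-op outside the grid)."""
        lo = int(self.lengths[0])
        if lo <= length <= int(self.lengths[-1]):
            self.counts[length - lo] += n


@dataclass
class HistogramMatrix:
    """Samples (or genomic bins) x fragment lengths matrix.

    ``values`` holds raw integer counts when ``normalized`` is False and
    row-stochastic frequencies when True.
    """

    row_labels: list[str]
    lengths: np.ndarray
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.row_labels = list(self.row_labels)
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        self.values = np.asarray(self.values,
                                 dtype=np.float64 if self.normalized else np.int64)
        if self.values.shape != (len(self.row_labels), self.lengths.size):
            raise ValueError("values shape does not match labels x lengths")
        if len(set(self.row_labels)) != len(self.row_labels):
            raise ValueError("duplicate row labels")
        if np.any(np.diff(self.lengths) != 1):
            raise ValueError("length grid must be contiguous and increasing")
        if np.any(self.values < 0):
            raise ValueError("negative matrix entries")
        if self.normalized:
            sums = self.values.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                bad = [self.row_labels[i] for i in np.flatnonzero(
                    ~np.isclose(sums, 1.0, atol=1e-9))]
                raise ValueError(f"rows not summing to one: {bad[:5]}")

    @property
    def n_rows(self) -> int:
        return len(self.row_labels)

    def row(self, label: str) -> np.ndarray:
        return self.values[self.row_labels.index(label)]

    def row_totals(self) -> np.ndarray:
        return self.values.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.row_labels, name="label"),
                            columns=self.lengths)

    def select_rows(self, labels: list[str]) -> "HistogramMatrix":
        idx = [self.row_labels.index(l) for l in labels]
        return HistogramMatrix(labels, self.lengths, self.values[idx],
                               normalized=self.normalized)

    def histograms(self) -> list[LengthHistogram]:
        """Split the (count) matrix back into per-row histograms."""
        if self.normalized:
            raise ValueError("cannot split a normalized matrix into count histograms")
        return [LengthHistogram(lab, self.values[i], self.lengths)
                for i, lab in enumerate(self.row_labels)]


def assemble_matrix(histograms: list[LengthHistogram]) -> HistogramMatrix:
    """Stack per-sample histograms into a raw count matrix.

    All histograms must share one length grid; labels must be unique.
    """
    if not histograms:
        raise ValueError("no histograms to assemble")
    grid = histograms[0].lengths
    for h in histograms[1:]:
        if h.lengths.size != grid.size or np.any(h.lengths != grid):
            raise ValueError(
                f"histogram {h.label!r} is on a different length grid "
                f"({h.lengths[0]}..{h.lengths[-1]} vs {grid[0]}..{grid[-1]})")
    labels = [h.label for h in histograms]
    values = np.vstack([h.counts for h in histograms])
    return HistogramMatrix(labels, grid.copy(), values, normalized=False)


def normalize_rows(matrix: HistogramMatrix, drop_empty: bool = False) -> HistogramMatrix:
    """Scale every row to sum to one.

    Empty rows are fatal by default; with ``drop_empty`` they are removed
    with a warning instead (genome bins can legitimately be empty).
    """
    if matrix.normalized:
        raise ValueError("matrix is already normalized")
    totals = matrix.values.sum(axis=1)
    empty = np.flatnonzero(totals == 0)
    values, labels = matrix.values, matrix.row_labels
    if empty.size:
        bad = [labels[i] for i in empty]
        if not drop_empty:
            raise ValueError(f"cannot normalize all-zero rows: {bad[:10]}")
        logger.warning("dropping %d empty rows before normalization (first: %s)",
                       empty.size, bad[:3])
        keep = np.flatnonzero(totals > 0)
        values = values[keep]
        labels = [labels[i] for i in keep]
        totals = totals[keep]
    freq = values / totals[:, None]
    return HistogramMatrix(labels, matrix.lengths.copy(), freq, normalized=True)


def subsample_histogram(hist: LengthHistogram, n: int,
                        seed: int | np.random.Generator) -> LengthHistogram:
    """Draw ``n`` fragments from a histogram without replacement.

    Sampling individual fragments from a pooled library and re-tallying their
    lengths is a multivariate hypergeometric draw on the length counts, which
    is what this returns. Reproducible given ``seed``.
    """
    if not 0 < n <= hist.total:
        raise ValueError(f"subsample size {n} outside (0, {hist.total}]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = rng.multivariate_hypergeometric(hist.counts, n)
    return LengthHistogram(hist.label, counts, hist.lengths.copy())


# ---------------------------------------------------------------------------
# TSV serialization. First column "label", remaining columns integer lengths.

def write_matrix_tsv(matrix: HistogramMatrix, path: str) -> None:
    df = matrix.to_frame()
    # repr-precision floats so normalized matrices round-trip bit-exactly
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_matrix_tsv(path: str) -> HistogramMatrix:
    df = pd.read_csv(path, sep="\t", index_col="label",
                     float_precision="round_trip")
    lengths = df.columns.astype(np.int64).to_numpy()
    values = df.to_numpy()
    is_int = np.issubdtype(values.dtype, np.integer)
    return HistogramMatrix(list(df.index.astype(str)), lengths, values,
                           normalized=not is_int)


def write_histogram_tsv(hist: LengthHistogram, path: str) -> None:
    """Two-column (length, count) TSV for a single sample."""
    pd.DataFrame({"length": hist.lengths, "count": hist.counts}).to_csv(
        path, sep="\t", index=False)


def read_histogram_tsv(path: str, label: str | None = None) -> LengthHistogram:
    df = pd.read_csv(path, sep="\t")
    if not {"length", "count"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'length' and 'count'")
    return LengthHistogram(label or path, df["count"].to_numpy(),
                           df["length"].to_numpy())
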