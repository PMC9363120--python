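"""Scalar ctDNA-burden and fragmentomics summaries.

Converts driver-variant allele fractions from deep targeted sequencing into
tumor cell purity and ctDNA fraction, and computes the short/long fragment
ratio (the DELFI ratio) plus the correlation utilities used to compare
weight estimates against external ctDNA measurements.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .histograms import LengthHistogram

logger = logging.getLogger(__name__)

__all__ = [
    "VariantObservation",
    "PloidyModel",
    "select_driver_vaf",
    "purity_from_vaf",
    "ctdna_fraction",
    "delfi_ratio",
    "correlate",
    "ctdna_table",
]


@dataclass
class VariantObservation:
    """One somatic variant call in one plasma sample."""

    sample: str
    vaf: float
    loh: bool = False
    supporting_reads: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.vaf < 1.0:
            raise ValueError(f"VAF must lie in (0, 1), got {self.vaf}")
        if self.supporting_reads < 0:
            raise ValueError("supporting_reads must be >= 0")


@dataclass
class PloidyModel:
    """Tumor/normal ploidy pair; normal cells are assumed diploid."""

    tumor_ploidy: float = 2.0
    normal_ploidy: float = 2.0

    def __post_init__(self) -> None:
        if self.tumor_ploidy <= 0:
            raise ValueError("tumor ploidy must be positive")


def select_driver_vaf(observations: list[VariantObservation],
                      window: float = 0.02) -> float:
    """Pick the sample's clonal driver VAF.

    The variant with the highest VAF is taken as the clear driver; when
    several variants fall within ``window`` (absolute VAF, default +/-2
    percentage points) of the maximum, their median is used instead, damping
    single-variant sampling noise.
    """
    if not observations:
        raise ValueError("no variant observations for sample")
    vafs = np.array([o.vaf for o in observations], dtype=float)
    top = vafs.max()
    return float(np.median(vafs[vafs >= top - window]))


def purity_from_vaf(vaf: float, loh: bool) -> float:
    """Tumor cell purity implied by a clonal heterozygous driver VAF.

    Without loss of heterozygosity a clonal het variant sits on one of two
    tumor alleles, so purity = 2*VAF. Under LOH the wild-type allele is lost
    in tumor cells and purity = 2 / (1/VAF + 1). Values exceeding 1 (e.g.
    VAF > 0.5 without an LOH annotation) are clipped with a warning.
    """
    if not 0.0 < vaf < 1.0:
        raise ValueError(f"VAF must lie in (0, 1), got {vaf}")
    purity = 2.0 / (1.0 / vaf + 1.0) if loh else 2.0 * vaf
    if purity > 1.0:
        logger.warning("purity %.3f > 1 at VAF %.3f (loh=%s); clipping to 1",
                       purity, vaf, loh)
        purity = 1.0
    return purity


def ctdna_fraction(purity: float, ploidy: PloidyModel | float = 2.0) -> float:
    """ctDNA fraction from tumor cell purity, adjusted for tumor ploidy.

    ctDNA% = p*t / (p*t + (1-p)*n) with p the tumor purity, t the tumor
    ploidy and n the normal ploidy (2): tumor cells shed DNA in proportion to
    their genome copy number.
    """
    if not 0.0 <= purity <= 1.0:
        raise ValueError(f"purity must lie in [0, 1], got {purity}")
    model = ploidy if isinstance(ploidy, PloidyModel) else PloidyModel(float(ploidy))
    tumor = purity * model.tumor_ploidy
    normal = (1.0 - purity) * model.normal_ploidy
    if tumor + normal == 0:
        return 0.0
    return tumor / (tumor + normal)


def delfi_ratio(hist: LengthHistogram,
                short_range: tuple[int, int] = (100, 150),
                long_range: tuple[int, int] = (151, 220)) -> float:
    """Ratio of short (100-150 bp) to long (151-220 bp) fragment counts.

    Bounds inclusive. An empty long-fragment denominator yields NaN with a
    warning rather than infinity, since sparse genomic bins are routine.
    """
    lo = int(hist.lengths[0])
    hi = int(hist.lengths[-1])
    if lo > short_range[0] or hi < long_range[1]:
        raise ValueError(f"grid {lo}..{hi} does not cover "
                         f"{short_range[0]}..{long_range[1]}")
    short = int(hist.counts[short_range[0] - lo: short_range[1] - lo + 1].sum())
    long = int(hist.counts[long_range[0] - lo: long_range[1] - lo + 1].sum())
    if long == 0:
        logger.warning("histogram %r has no long fragments; ratio undefined",
                       hist.label)
        return math.nan
    return short / long


def correlate(x: np.ndarray, y: np.ndarray, method: str = "pearson") -> float:
    """Pearson or Spearman correlation with pairwise-complete NaN handling."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in input vector")
    if method == "pearson":
        return float(pearsonr(x, y).statistic)
    if method == "spearman":
        return float(spearmanr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")


def ctdna_table(variants: pd.DataFrame, window: float = 0.02) -> pd.DataFrame:
    """Per-sample ctDNA fraction from a variant table.

    Expects columns ``sample``, ``vaf``, ``loh`` (0/1) and optionally
    ``tumor_ploidy`` (default 2). The driver VAF is selected per sample; its
    LOH flag is taken from the selected maximal-VAF variant.
    """
    required = {"sample", "vaf", "loh"}
    if not required <= set(variants.columns):
        raise ValueError(f"variant table must have columns {sorted(required)}")
    out = []
    for sample, grp in variants.groupby("sample", sort=False):
        obs = [VariantObservation(str(sample), float(r.vaf), bool(r.loh),
                                  int(getattr(r, "supporting_reads", 0)))
               for r in grp.itertuples()]
        vaf = select_driver_vaf(obs, window=window)
        top = max(obs, key=lambda o: o.vaf)
        purity = purity_from_vaf(vaf, top.loh)
        ploidy = float(grp["tumor_ploidy"].iloc[0]) if "tumor_ploidy" in grp else 2.0
        out.append((sample, vaf, top.loh, purity,
                    ctdna_fraction(purity, PloidyModel(ploidy))))
    return pd.DataFrame(out, columns=["sample", "driver_vaf", "loh",
                                      "purity", "ctdna_fraction"])
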