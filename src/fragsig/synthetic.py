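"""Synthetic cfDNA fragment-length cohorts with known ground truth.

Plasma cfDNA is cut preferentially between nucleosomes, giving a dominant
mono-nucleosome mode near 166 bp, a di-nucleosome echo one nucleosomal unit
further out, and — below the main mode — a comb of sub-peaks spaced by the
~10 bp helical repeat of DNA on the histone core. Tumor-derived fragments are
left-shifted, show an amplified 10 bp comb and a relatively larger
di-nucleosome peak. The generator builds parametric length profiles with
those features, mixes them with per-sample tumor weights and draws multinomial
read counts, so that deconvolution accuracy can be scored against a known
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .histograms import HistogramMatrix, default_grid

__all__ = [
    "SourceProfile",
    "CohortConfig",
    "background_profile",
    "tumor_profile",
    "build_profile",
    "simulate_cohort",
    "simulate_binned_cohort",
]


@dataclass
class SourceProfile:
    """Parametric fragment-length profile of one cfDNA source.

    Parameters
    ----------
    mode_length : float
        Location of the mono-nucleosome mode (bp).
    mode_sd : float
        Width of the mono-nucleosome mode (bp).
    dinucleosome_offset : float
        Distance from the main mode to the di-nucleosome mode (bp); one
        nucleosomal repeat, ~167 bp.
    dinucleosome_weight : float
        Mass of the di-nucleosome peak relative to the main peak.
    periodicity : float
        Spacing of the sub-nucleosomal comb below the main mode (bp). The
        helical repeat of nucleosomal DNA, 10.4 bp by default.
    periodicity_amplitude : float
        Amplitude of the comb relative to the main peak; tumor profiles use a
        much larger value than background.
    comb_sd : float
        Width of each comb tooth (bp).
    comb_decay : float
        e-folding (in comb teeth) of tooth amplitude away from the mode.
    min_length, max_length : int
        Support of the profile (bp).
    """

    mode_length: float = 166.0
    mode_sd: float = 22.0
    dinucleosome_offset: float = 167.0
    dinucleosome_weight: float = 0.12
    dinucleosome_sd: float = 35.0
    periodicity: float = 10.4
    periodicity_amplitude: float = 0.0
    comb_sd: float = 2.5
    comb_decay: float = 4.0
    min_length: int = 30
    max_length: int = 700

    def grid(self) -> np.ndarray:
        return default_grid(self.min_length, self.max_length)


def background_profile(**overrides) -> SourceProfile:
    """Healthy (mostly hematopoietic) cfDNA: 166 bp mode, mild comb."""
    params = dict(mode_length=166.0, mode_sd=22.0, dinucleosome_weight=0.12,
                  periodicity_amplitude=0.02)
    params.update(overrides)
    return SourceProfile(**params)


def tumor_profile(**overrides) -> SourceProfile:
    """ctDNA: left-shifted mode, strong 10 bp comb, enlarged second peak."""
    params = dict(mode_length=145.0, mode_sd=18.0, dinucleosome_weight=0.25,
                  periodicity_amplitude=0.25)
    params.update(overrides)
    return SourceProfile(**params)


def _gaussian_density(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    """Unit-mass Gaussian evaluated on the grid."""
    return np.exp(-0.5 * ((x - mu) / sd) ** 2) / (sd * np.sqrt(2.0 * np.pi))


def build_profile(config: SourceProfile) -> np.ndarray:
    """Evaluate the profile as a probability vector on its length grid.

    The profile is a mixture of a main Gaussian mode, a di-nucleosome
    Gaussian at ``mode + dinucleosome_offset`` carrying
    ``dinucleosome_weight`` of the main peak's mass, and a comb of Gaussian
    teeth every ``periodicity`` bp below the mode whose amplitudes are
    ``periodicity_amplitude`` of the main peak height, decaying away from
    it; the sum is renormalized to one.
    """
    x = config.grid().astype(float)
    p = _gaussian_density(x, config.mode_length, config.mode_sd)
    p += config.dinucleosome_weight * _gaussian_density(
        x, config.mode_length + config.dinucleosome_offset, config.dinucleosome_sd)
    if config.periodicity_amplitude > 0:
        mode_peak = 1.0 / (config.mode_sd * np.sqrt(2.0 * np.pi))
        j = 1
        while True:
            mu = config.mode_length - j * config.periodicity
            if mu < config.min_length:
                break
            tooth = config.periodicity_amplitude * np.exp(-j / config.comb_decay)
            p += tooth * mode_peak * np.exp(-0.5 * ((x - mu) / config.comb_sd) ** 2)
            j += 1
    total = p.sum()
    if total <= 0 or np.any(p < 0):
        raise ValueError("profile parameters yield a non-positive density")
    return p / total


@dataclass
class CohortConfig:
    """Sampling design of a simulated cohort.

    ``tumor_weights`` may be an explicit per-sample array; when None, weights
    are drawn uniformly on [``weight_low``, ``weight_high``] (the spread of
    ctDNA burdens seen in a metastatic cohort).
    """

    n_samples: int = 50
    depth: int = 1_000_000
    seed: int = 0
    tumor_weights: np.ndarray | None = None
    weight_low: float = 0.0
    weight_high: float = 0.9
    label_prefix: str = "sample"


def simulate_cohort(
    background: SourceProfile | None = None,
    tumor: SourceProfile | None = None,
    cohort: CohortConfig | None = None,
) -> tuple[HistogramMatrix, pd.DataFrame]:
    """Simulate a cohort of mixed tumor/background length histograms.

    For sample ``s`` with tumor weight ``w``, counts are drawn
    multinomial(depth, (1-w)*background + w*tumor) with a per-sample RNG
    stream derived from the cohort seed.

    Returns
    -------
    matrix : HistogramMatrix
        Raw count matrix, one row per sample.
    truth : DataFrame
        Columns ``label`` and ``tumor_weight`` (the generating mixing weight).
    """
    background = background or background_profile()
    tumor = tumor or tumor_profile()
    cohort = cohort or CohortConfig()
    if (background.min_length, background.max_length) != (
            tumor.min_length, tumor.max_length):
        raise ValueError("background and tumor profiles use different grids")
    p_bg = build_profile(background)
    p_tu = build_profile(tumor)
    ss = np.random.SeedSequence(cohort.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    if cohort.tumor_weights is not None:
        w = np.asarray(cohort.tumor_weights, dtype=float)
        if w.size != cohort.n_samples:
            raise ValueError("tumor_weights length != n_samples")
    else:
        w = rng.uniform(cohort.weight_low, cohort.weight_high, cohort.n_samples)
    if np.any((w < 0) | (w > 1)):
        raise ValueError("tumor weights must lie in [0, 1]")
    child_seeds = ss.spawn(cohort.n_samples + 1)[1:]
    rows = np.empty((cohort.n_samples, p_bg.size), dtype=np.int64)
    for i, (wi, child) in enumerate(zip(w, child_seeds)):
        mix = (1.0 - wi) * p_bg + wi * p_tu
        rows[i] = np.random.default_rng(child).multinomial(cohort.depth, mix)
    labels = [f"{cohort.label_prefix}{i:03d}" for i in range(cohort.n_samples)]
    matrix = HistogramMatrix(labels, background.grid(), rows, normalized=False)
    truth = pd.DataFrame({"label": labels, "tumor_weight": w})
    return matrix, truth


def simulate_binned_cohort(
    open_profile: SourceProfile | None = None,
    closed_profile: SourceProfile | None = None,
    n_bins: int = 500,
    openness: np.ndarray | None = None,
    depth_per_bin: int = 100_000,
    seed: int = 0,
) -> tuple[HistogramMatrix, pd.DataFrame]:
    """Simulate per-genomic-bin histograms mixing two chromatin states.

    Each bin draws multinomial(depth_per_bin, openness*open + (1-openness)*closed),
    emulating the aggregated-control bin matrix used to learn chromatin-state
    length signatures. The returned truth table carries the per-bin openness,
    usable as a stand-in external accessibility signal (ATAC-like) for
    rank-correlation checks.
    """
    # open chromatin: shorter, more exposed fragments; closed: canonical 166 bp
    open_profile = open_profile or SourceProfile(
        mode_length=152.0, mode_sd=20.0, dinucleosome_weight=0.10,
        periodicity_amplitude=0.12)
    closed_profile = closed_profile or SourceProfile(
        mode_length=168.0, mode_sd=24.0, dinucleosome_weight=0.18,
        periodicity_amplitude=0.02)
    if (open_profile.min_length, open_profile.max_length) != (
            closed_profile.min_length, closed_profile.max_length):
        raise ValueError("open and closed profiles use different grids")
    p_open = build_profile(open_profile)
    p_closed = build_profile(closed_profile)
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    if openness is None:
        openness = rng.uniform(0.0, 1.0, n_bins)
    else:
        openness = np.asarray(openness, dtype=float)
        if openness.size != n_bins:
            raise ValueError("openness length != n_bins")
    child_seeds = ss.spawn(n_bins + 1)[1:]
    rows = np.empty((n_bins, p_open.size), dtype=np.int64)
    for i, (oi, child) in enumerate(zip(openness, child_seeds)):
        mix = oi * p_open + (1.0 - oi) * p_closed
        rows[i] = np.random.default_rng(child).multinomial(depth_per_bin, mix)
    labels = [f"bin{i:04d}" for i in range(n_bins)]
    matrix = HistogramMatrix(labels, open_profile.grid(), rows, normalized=False)
    truth = pd.DataFrame({"label": labels, "openness": openness})
    return matrix, truth
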