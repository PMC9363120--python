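"""Kullback-Leibler non-negative matrix factorization of length histograms.

A row-normalized samples x lengths frequency matrix V is approximated as
W @ H with W, H >= 0, minimizing the generalized KL divergence

    D(V || WH) = sum_ij [ V_ij log(V_ij / (WH)_ij) - V_ij + (WH)_ij ]

by the classical multiplicative updates, which never increase the loss.
Each row of H is a fragment-length *signature* — the length distribution of
one cfDNA source — and each row of W holds the mixing *weights* of those
sources in one sample (or genomic bin). After fitting, both are rescaled to
be row-stochastic so weights read directly as source proportions. The
component with the lowest mean fragment length is taken to be the
tumor-derived source, matching the left shift of ctDNA fragments.

:class:`KLNMF` is a scikit-learn style estimator (``fit`` / ``transform`` /
``get_params``); the module-level functions are thin wrappers over it that
speak the package's own :class:`~fragsig.histograms.HistogramMatrix` type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.metrics.pairwise import cosine_similarity

from .histograms import HistogramMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "KLNMF",
    "Factorization",
    "kl_divergence",
    "rescale",
    "fit_nmf",
    "transform_weights",
    "tumor_signature_index",
    "max_cosine_similarity",
    "stability_experiment",
    "holdout_experiment",
]


def kl_divergence(V: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """Generalized KL divergence D(V || WH), with the 0*log(0) = 0 convention.

    Entries where (WH)_ij = 0 but V_ij > 0 contribute +inf.
    """
    V = np.asarray(V, dtype=float)
    W = np.asarray(W, dtype=float)
    H = np.asarray(H, dtype=float)
    if np.any(V < 0) or np.any(W < 0) or np.any(H < 0):
        raise ValueError("kl_divergence requires non-negative inputs")
    WH = W @ H
    pos = V > 0
    if np.any(WH[pos] == 0):
        return float("inf")
    with np.errstate(divide="ignore", invalid="ignore"):
        log_term = np.where(pos, V * np.log(np.where(pos, V, 1.0) / np.where(WH > 0, WH, 1.0)), 0.0)
    return float(log_term.sum() - V.sum() + WH.sum())


def rescale(W: np.ndarray, H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Make each signature (H row) and each weight vector (W row) sum to one.

    The H row scales are absorbed into the matching W columns first, so the
    reconstruction W @ H changes only by a positive per-row factor (the row
    sum of the scale-absorbed W), and not at all after row renormalization
    of the reconstruction.
    """
    W = np.asarray(W, dtype=float)
    H = np.asarray(H, dtype=float)
    h_sums = H.sum(axis=1)
    if np.any(h_sums == 0):
        raise ValueError("all-zero signature row")
    H_scaled = H / h_sums[:, None]
    W_scaled = W * h_sums[None, :]
    w_sums = W_scaled.sum(axis=1)
    if np.any(w_sums == 0):
        raise ValueError("all-zero weight row")
    return W_scaled / w_sums[:, None], H_scaled


def _mu_update_W(V: np.ndarray, W: np.ndarray, H: np.ndarray, eps: float) -> np.ndarray:
    ratio = V / (W @ H + eps)
    return W * (ratio @ H.T) / (H.sum(axis=1)[None, :] + eps)


def _mu_update_H(V: np.ndarray, W: np.ndarray, H: np.ndarray, eps: float) -> np.ndarray:
    ratio = V / (W @ H + eps)
    return H * (W.T @ ratio) / (W.sum(axis=0)[:, None] + eps)


class KLNMF(BaseEstimator, TransformerMixin):
    """KL-loss NMF with multiplicative updates and random restarts.

    Parameters
    ----------
    n_components : int
        Number of cfDNA sources (signatures) to extract.
    n_restarts : int, default 20
        Independent random initializations; the fit with the lowest final
        loss is kept.
    max_iter : int, default 2000
        Maximum multiplicative-update iterations per restart.
    tol : float, default 1e-6
        Stop when the relative loss improvement over one iteration falls
        below this.
    eps : float, default 1e-12
        Numerical floor inside the update divisions, guarding 0/0.
    random_state : int, default 0
        Master seed; per-restart streams are split from it deterministically,
        so adding restarts never changes the earlier ones.

    Attributes
    ----------
    components_ : ndarray, (n_components, n_lengths)
        Row-stochastic fragment-length signatures.
    weights_ : ndarray, (n_samples, n_components)
        Row-stochastic per-sample source weights.
    reconstruction_err_ : float
        Final generalized KL divergence of the selected restart.
    n_iter_ : int
        Iterations run by the selected restart.
    loss_history_ : ndarray
        Per-iteration loss of the selected restart (non-increasing).
    """

    def __init__(self, n_components: int = 2, n_restarts: int = 20,
                 max_iter: int = 2000, tol: float = 1e-6,
                 eps: float = 1e-12, random_state: int = 0):
        self.n_components = n_components
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.eps = eps
        self.random_state = random_state

    # -- internals -----------------------------------------------------------

    def _validate(self, V: np.ndarray) -> np.ndarray:
        V = np.asarray(V, dtype=float)
        if V.ndim != 2:
            raise ValueError("V must be a 2-D matrix")
        if np.any(V < 0) or not np.all(np.isfinite(V)):
            raise ValueError("V must be non-negative and finite")
        if not 1 <= self.n_components <= min(V.shape):
            raise ValueError(
                f"n_components={self.n_components} out of range for shape {V.shape}")
        return V

    def _init_pair(self, V: np.ndarray, rng: np.random.Generator
                   ) -> tuple[np.ndarray, np.ndarray]:
        # uniform on (0, 1] scaled by mean(V)/k, as a scale-free positive start
        scale = V.mean() / self.n_components
        n, m = V.shape
        W = (1.0 - rng.random((n, self.n_components))) * scale
        H = (1.0 - rng.random((self.n_components, m))) * scale
        return W, H

    def _run_one(self, V: np.ndarray, rng: np.random.Generator
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        W, H = self._init_pair(V, rng)
        losses = [kl_divergence(V, W, H)]
        for _ in range(self.max_iter):
            H = _mu_update_H(V, W, H, self.eps)
            W = _mu_update_W(V, W, H, self.eps)
            loss = kl_divergence(V, W, H)
            prev = losses[-1]
            losses.append(loss)
            if prev - loss < self.tol * max(prev, self.eps):
                break
        return W, H, np.asarray(losses)

    # -- estimator API -------------------------------------------------------

    def fit(self, X, y=None) -> "KLNMF":
        """Factorize X; keeps the best of ``n_restarts`` random starts."""
        V = self._validate(X)
        seeds = np.random.SeedSequence(self.random_state).spawn(self.n_restarts)
        best = None
        for r, seed in enumerate(seeds):
            W, H, losses = self._run_one(V, np.random.default_rng(seed))
            if best is None or losses[-1] < best[3][-1]:
                best = (r, W, H, losses)
        r, W, H, losses = best
        self.best_restart_ = r
        self.raw_W_, self.raw_H_ = W, H
        self.weights_, self.components_ = rescale(W, H)
        self.reconstruction_err_ = float(losses[-1])
        self.loss_history_ = losses
        self.n_iter_ = losses.size - 1
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).weights_

    def transform(self, X) -> np.ndarray:
        """Infer row-stochastic weights for new rows under the fitted signatures."""
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "components_")
        return transform_weights_array(
            np.asarray(X, dtype=float), self.components_,
            max_iter=self.max_iter, tol=self.tol, eps=self.eps,
            random_state=self.random_state)


def transform_weights_array(V: np.ndarray, H_fixed: np.ndarray,
                            max_iter: int = 2000, tol: float = 1e-6,
                            eps: float = 1e-12, random_state: int = 0) -> np.ndarray:
    """W-only multiplicative updates against fixed signatures; row-stochastic."""
    V = np.asarray(V, dtype=float)
    H = np.asarray(H_fixed, dtype=float)
    if V.ndim == 1:
        V = V[None, :]
    if V.shape[1] != H.shape[1]:
        raise ValueError(f"grid mismatch: V has {V.shape[1]} columns, "
                         f"signatures have {H.shape[1]}")
    rng = np.random.default_rng(np.random.SeedSequence(random_state))
    k = H.shape[0]
    W = (1.0 - rng.random((V.shape[0], k))) * (V.mean() / k + eps)
    prev = kl_divergence(V, W, H)
    for _ in range(max_iter):
        W = _mu_update_W(V, W, H, eps)
        loss = kl_divergence(V, W, H)
        if prev - loss < tol * max(prev, eps):
            break
        prev = loss
    sums = W.sum(axis=1)
    sums[sums == 0] = 1.0
    return W / sums[:, None]


# ---------------------------------------------------------------------------
# HistogramMatrix-facing surface

@dataclass
class Factorization:
    """Result of a KL-NMF fit on a histogram matrix."""

    W: np.ndarray              # rows aligned to matrix rows, row-stochastic
    H: np.ndarray              # k signatures over the length grid, row-stochastic
    loss: float                # final generalized KL divergence
    k: int
    restarts: int
    seed: int
    iterations_run: int
    row_labels: list[str]
    lengths: np.ndarray

    def weights_frame(self) -> pd.DataFrame:
        cols = [f"signature{c + 1}" for c in range(self.k)]
        return pd.DataFrame(self.W, index=pd.Index(self.row_labels, name="label"),
                            columns=cols)

    def signatures_frame(self) -> pd.DataFrame:
        idx = pd.Index([f"signature{c + 1}" for c in range(self.k)], name="signature")
        return pd.DataFrame(self.H, index=idx, columns=self.lengths)


def _require_normalized(matrix: HistogramMatrix) -> None:
    if not matrix.normalized:
        raise ValueError("matrix must be row-normalized before NMF "
                         "(see histograms.normalize_rows)")


def fit_nmf(matrix: HistogramMatrix, k: int, restarts: int = 20,
            max_iter: int = 2000, tol: float = 1e-6, seed: int = 0) -> Factorization:
    """Fit KL-NMF to a normalized histogram matrix and rescale the factors."""
    _require_normalized(matrix)
    model = KLNMF(n_components=k, n_restarts=restarts, max_iter=max_iter,
                  tol=tol, random_state=seed).fit(matrix.values)
    return Factorization(
        W=model.weights_, H=model.components_, loss=model.reconstruction_err_,
        k=k, restarts=restarts, seed=seed, iterations_run=model.n_iter_,
        row_labels=list(matrix.row_labels), lengths=matrix.lengths.copy())


def transform_weights(matrix_new: HistogramMatrix, H_fixed: np.ndarray,
                      max_iter: int = 2000, tol: float = 1e-6,
                      seed: int = 0) -> np.ndarray:
    """Infer weights for new normalized rows under fixed signatures."""
    _require_normalized(matrix_new)
    return transform_weights_array(matrix_new.values, H_fixed,
                                   max_iter=max_iter, tol=tol, random_state=seed)


def signature_mean_lengths(H: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Mean fragment length of each signature distribution."""
    H = np.asarray(H, dtype=float)
    return (H / H.sum(axis=1, keepdims=True)) @ np.asarray(lengths, dtype=float)


def tumor_signature_index(fact: Factorization, lengths: np.ndarray | None = None) -> int:
    """Index of the tumor-like component: the one with the lowest mean length.

    ctDNA fragments are systematically shorter than the hematopoietic
    background, so among the fitted signatures the shortest-mean one is
    attributed to the tumor. Exact ties break to the lowest index with a
    warning.
    """
    grid = fact.lengths if lengths is None else np.asarray(lengths)
    means = signature_mean_lengths(fact.H, grid)
    idx = int(np.argmin(means))
    if np.sum(means == means[idx]) > 1:
        logger.warning("tie in signature mean lengths; choosing index %d", idx)
    return idx


def max_cosine_similarity(H_a: np.ndarray, H_b: np.ndarray) -> np.ndarray:
    """Best cosine match of each signature in H_a against the set H_b."""
    H_a = np.atleast_2d(np.asarray(H_a, dtype=float))
    H_b = np.atleast_2d(np.asarray(H_b, dtype=float))
    if H_a.shape[1] != H_b.shape[1]:
        raise ValueError("signature sets on different length grids")
    if np.any(np.linalg.norm(H_a, axis=1) == 0) or np.any(np.linalg.norm(H_b, axis=1) == 0):
        raise ValueError("zero-norm signature")
    return cosine_similarity(H_a, H_b).max(axis=1)


def stability_experiment(matrix: HistogramMatrix, k: int,
                         subset_sizes: list[int], replicates: int = 100,
                         seed: int = 0, restarts: int = 20,
                         max_iter: int = 2000, tol: float = 1e-6) -> pd.DataFrame:
    """Signature stability under cohort down-sampling.

    For each subset size and replicate, fit NMF on a random sample subset
    (without replacement) and record, per signature, the maximum cosine
    similarity to the signatures fitted on the full cohort.
    """
    _require_normalized(matrix)
    full = fit_nmf(matrix, k, restarts=restarts, max_iter=max_iter, tol=tol, seed=seed)
    ss = np.random.SeedSequence(seed)
    rows = []
    rep_seeds = iter(ss.spawn(len(subset_sizes) * replicates))
    for size in subset_sizes:
        if size > matrix.n_rows:
            raise ValueError(f"subset size {size} exceeds {matrix.n_rows} rows")
        for rep in range(replicates):
            child = next(rep_seeds)
            if size < k:
                logger.warning("subset size %d < k=%d; skipped", size, k)
                continue
            rng = np.random.default_rng(child)
            pick = rng.choice(matrix.n_rows, size=size, replace=False)
            sub = matrix.select_rows([matrix.row_labels[i] for i in pick])
            sub_fit = fit_nmf(sub, k, restarts=restarts, max_iter=max_iter,
                              tol=tol, seed=int(child.generate_state(1)[0] >> 1))
            sims = max_cosine_similarity(sub_fit.H, full.H)
            for c, sim in enumerate(sims):
                rows.append((size, rep, c, float(sim)))
    return pd.DataFrame(rows, columns=["subset_size", "replicate",
                                       "signature", "similarity"])


def holdout_experiment(matrix: HistogramMatrix, ctdna: np.ndarray, k: int = 2,
                       repeats: int = 20, seed: int = 0, restarts: int = 20,
                       max_iter: int = 2000, tol: float = 1e-6) -> pd.DataFrame:
    """Train/test half-split generalization of tumor-weight estimates.

    Per repeat: split the cohort in two equal halves, fit NMF on the training
    half, infer test weights under the trained signatures, and correlate
    (Pearson) the tumor-signature weight with the external ctDNA fraction in
    each half.
    """
    _require_normalized(matrix)
    ctdna = np.asarray(ctdna, dtype=float)
    if ctdna.size != matrix.n_rows:
        raise ValueError("ctdna vector not aligned to matrix rows")
    if matrix.n_rows < 2 * k:
        raise ValueError(f"need at least {2 * k} rows for a half-split with k={k}")
    ss = np.random.SeedSequence(seed)
    out = []
    for rep, child in enumerate(ss.spawn(repeats)):
        rng = np.random.default_rng(child)
        perm = rng.permutation(matrix.n_rows)
        half = matrix.n_rows // 2
        tr, te = perm[:half], perm[half: 2 * half]
        m_tr = matrix.select_rows([matrix.row_labels[i] for i in tr])
        m_te = matrix.select_rows([matrix.row_labels[i] for i in te])
        fit = fit_nmf(m_tr, k, restarts=restarts, max_iter=max_iter, tol=tol,
                      seed=int(child.generate_state(1)[0] >> 1))
        t = tumor_signature_index(fit)
        w_te = transform_weights(m_te, fit.H, max_iter=max_iter, tol=tol)
        r_tr = pearsonr(fit.W[:, t], ctdna[tr]).statistic
        r_te = pearsonr(w_te[:, t], ctdna[te]).statistic
        out.append((rep, float(r_tr), float(r_te)))
    return pd.DataFrame(out, columns=["repeat", "train_correlation",
                                      "test_correlation"])
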