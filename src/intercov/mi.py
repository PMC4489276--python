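"""Corrected mutual information between alignment columns.

The score pipeline is: weighted amino-acid frequencies with a per-cell
low-count correction, raw MI in nats, the average product correction (APC)
to strip background signal shared by whole columns, and a z-score against a
null built from column-shuffled alignments (which preserve per-column
composition and conservation but destroy covariation).

The MI alphabet is the 20 amino acids: gaps and 'X' contribute no counts,
and a pair observation requires both positions to be non-gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .msa import Msa, SequenceWeights


@dataclass
class WeightedFrequencies:
    """Weighted single and pairwise amino-acid frequencies.

    ``single[i, a]`` and ``pair[i, a, j, b]`` are pseudocounted relative
    frequencies over the 20-state alphabet; ``pair`` is stored as an
    (L, 20, L, 20) array (pair-complete rows only).
    """

    single: np.ndarray
    pair: np.ndarray
    pseudocount: float
    meff: float

    @property
    def length(self) -> int:
        return self.single.shape[0]


def weighted_frequencies(msa: Msa, weights: SequenceWeights,
                         pseudocount: float = 0.05) -> WeightedFrequencies:
    """Weighted, pseudocounted column and column-pair frequencies.

    Single frequencies: f_i(a) = (λ + Σ_r w_r [x_ri = a]) / (20λ + N_i)
    with N_i the weighted non-gap count of column i. Pair frequencies are
    analogous with λ per cell over the 400 cells, counting only rows where
    both positions are non-gap.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    codes = msa.codes()
    w = np.asarray(weights.weights, dtype=np.float64)
    if w.shape[0] != msa.n_records:
        raise ValueError("weights not aligned to records")
    single, pair = _frequencies_from_codes(codes, w, pseudocount)
    return WeightedFrequencies(single, pair, pseudocount, weights.meff)


def _frequencies_from_codes(codes: np.ndarray, w: np.ndarray,
                            lam: float) -> tuple[np.ndarray, np.ndarray]:
    n, L = codes.shape
    onehot = np.zeros((n, L, 20), dtype=np.float64)
    aa = codes < 20
    rows, cols = np.nonzero(aa)
    onehot[rows, cols, codes[rows, cols]] = 1.0

    counts1 = np.einsum("r,rla->la", w, onehot)
    n_valid = counts1.sum(axis=1)
    if np.any(n_valid <= 0):
        col = int(np.argmin(n_valid))
        raise ValueError(f"column {col + 1} has no non-gap residues")
    single = (lam + counts1) / (20 * lam + n_valid)[:, None]

    flat = onehot.reshape(n, L * 20)
    counts2 = flat.T @ (flat * w[:, None])            # (L*20, L*20)
    counts2 = counts2.reshape(L, 20, L, 20)
    n_pair = counts2.sum(axis=(1, 3))                  # weighted complete rows
    pair = (lam + counts2) / (400 * lam + n_pair)[:, None, :, None]
    return single, pair


def mutual_information(freqs: WeightedFrequencies) -> np.ndarray:
    """Raw MI matrix in nats: MI(i,j) = Σ_ab f_ij log(f_ij / (f_i f_j)).

    0·log 0 := 0; tiny negative values (pseudocount marginal mismatch) are
    clamped to zero; the diagonal is set to zero.
    """
    f1, f2 = freqs.single, freqs.pair
    outer = f1[:, :, None, None] * f1[None, None, :, :]   # (L,20,L,20)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(f2 > 0, f2 / np.maximum(outer, 1e-300), 1.0)
        terms = np.where(f2 > 0, f2 * np.log(ratio), 0.0)
    mi = terms.sum(axis=(1, 3))
    mi = np.maximum(mi, 0.0)
    mi = 0.5 * (mi + mi.T)
    np.fill_diagonal(mi, 0.0)
    return mi


def apc_correct(mi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average product correction: APC(i,j) = m_i m_j / m, with row means
    m_i and grand mean m taken over off-diagonal entries.

    Returns (apc, mip = mi - apc). A grand mean of zero defines APC = 0.
    """
    mi = np.asarray(mi, dtype=np.float64)
    L = mi.shape[0]
    if mi.shape != (L, L) or L < 3:
        raise ValueError("apc_correct requires a symmetric matrix with L >= 3")
    if not np.allclose(mi, mi.T, atol=1e-8):
        raise ValueError("apc_correct requires a symmetric matrix")
    off = ~np.eye(L, dtype=bool)
    row_mean = (mi.sum(axis=1) - np.diag(mi)) / (L - 1)
    grand_mean = mi[off].mean()
    if grand_mean == 0:
        apc = np.zeros_like(mi)
    else:
        apc = np.outer(row_mean, row_mean) / grand_mean
    np.fill_diagonal(apc, 0.0)
    mip = mi - apc
    np.fill_diagonal(mip, 0.0)
    return apc, mip


@dataclass
class NullModel:
    """Pooled null distribution of APC-corrected MI from shuffled MSAs."""

    n_replicates: int
    seed: int
    null_mean: float
    null_sd: float


@dataclass
class MiMatrix:
    """Raw MI, its APC component, the corrected score, and the z-score."""

    raw_mi: np.ndarray
    apc: np.ndarray
    mip: np.ndarray
    zscore: np.ndarray


def mi_zscores(msa: Msa, weights: SequenceWeights,
               pseudocount: float = 0.05, n_replicates: int = 100,
               seed: int = 0) -> tuple[MiMatrix, NullModel]:
    """APC-corrected MI with z-scores against a column-shuffle null.

    Each replicate permutes the residues of every column independently
    across rows (replicate r uses seed + r), recomputes the corrected MI,
    and all replicate pair values are pooled into one null mean/sd; then
    z(i,j) = (mip(i,j) − null_mean) / null_sd. The observed sequence
    weights are reused for the shuffled alignments.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be at least 2")
    codes = msa.codes()
    w = np.asarray(weights.weights, dtype=np.float64)
    n, L = codes.shape
    iu = np.triu_indices(L, k=1)

    single, pair = _frequencies_from_codes(codes, w, pseudocount)
    freqs = WeightedFrequencies(single, pair, pseudocount, weights.meff)
    raw = mutual_information(freqs)
    apc, mip = apc_correct(raw)

    null_values = np.empty((n_replicates, iu[0].size))
    for r in range(n_replicates):
        rng = np.random.default_rng(seed + r)
        shuffled = np.empty_like(codes)
        for col in range(L):
            shuffled[:, col] = codes[rng.permutation(n), col]
        s1, s2 = _frequencies_from_codes(shuffled, w, pseudocount)
        null_raw = mutual_information(
            WeightedFrequencies(s1, s2, pseudocount, weights.meff))
        _, null_mip = apc_correct(null_raw)
        null_values[r] = null_mip[iu]

    null_mean = float(null_values.mean())
    null_sd = float(null_values.std(ddof=1))
    if null_sd <= 0:
        raise ValueError("degenerate null: zero standard deviation")
    z = (mip - null_mean) / null_sd
    np.fill_diagonal(z, 0.0)
    return (MiMatrix(raw, apc, mip, z),
            NullModel(n_replicates, seed, null_mean, null_sd))


def position_conservation(freqs: WeightedFrequencies,
                          background: np.ndarray | None = None) -> np.ndarray:
    """Per-column conservation as KL divergence from a background.

    KL(i) = Σ_a f_i(a) log(f_i(a)/q_a), in nats; zero iff the column
    frequencies equal the background. Default background is uniform over
    the 20 amino acids (a fully conserved column then scores log 20).
    """
    if background is None:
        background = np.full(20, 1.0 / 20)
    background = np.asarray(background, dtype=np.float64)
    if background.shape != (20,):
        raise ValueError("background must be a 20-vector")
    if np.any(background <= 0):
        raise ValueError("background must have strictly positive entries")
    if not np.isclose(background.sum(), 1.0, atol=1e-6):
        raise ValueError("background must sum to 1")
    f = freqs.single
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log(f / background[None, :]), 0.0)
    kl = terms.sum(axis=1)
    return np.maximum(kl, 0.0)
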