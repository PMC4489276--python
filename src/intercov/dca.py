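"""Direct-coupling analysis of paired alignments.

Two estimators of the same Potts (Markov random field) model are provided:

* mean-field DCA: couplings from the negative inverse of the connected
  correlation matrix of pseudocounted frequencies, scored by direct
  information (DI) — the mutual information of the two-site model whose
  auxiliary fields are iterated until its marginals match the empirical
  single-site frequencies;
* pseudo-likelihood DCA: a symmetric L2-regularized fit of fields and
  couplings by maximizing the weighted pseudo-likelihood, scored by the
  APC-corrected Frobenius norm of the coupling blocks.

Both use the 21-state alphabet (20 amino acids + gap as an explicit state;
unknown residues are mapped onto the gap state). The Frobenius score is
taken over the 20x20 amino-acid block only, after the zero-sum gauge fix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .alphabet import Q_DCA, codes21
from .mi import apc_correct
from .msa import Msa, SequenceWeights, _identity_matrix


def pair_index(i: int, j: int, L: int) -> int:
    """Packed index of the unordered pair (i < j) among L positions."""
    if not 0 <= i < j < L:
        raise IndexError(f"invalid pair ({i}, {j}) for L={L}")
    return i * L - i * (i + 1) // 2 + (j - i - 1)


@dataclass
class CouplingModel:
    """Potts fields and pairwise couplings over q states.

    Couplings are stored once per unordered pair i < j in a packed
    (L(L-1)/2, q, q) array; ``coupling(i, j)`` returns the block oriented
    with axis 0 indexing the states of i.
    """

    q: int
    fields: np.ndarray                 # (L, q)
    couplings: np.ndarray              # (n_pairs, q, q), i < j
    gauge: str
    single_freqs: np.ndarray | None = None
    converged: bool = True
    method: str = ""

    @property
    def length(self) -> int:
        return self.fields.shape[0]

    def coupling(self, i: int, j: int) -> np.ndarray:
        if i == j:
            raise IndexError("no self-coupling")
        if i < j:
            return self.couplings[pair_index(i, j, self.length)]
        return self.couplings[pair_index(j, i, self.length)].T


def zero_sum_gauge(model: CouplingModel) -> CouplingModel:
    """Shift to the zero-sum (Ising) gauge, compensating the fields.

    Each coupling block is double-centred; the removed column means are
    absorbed into the fields, and fields are centred per site, so every
    site-conditional distribution — hence the pseudo-likelihood — is
    unchanged.
    """
    L, q = model.fields.shape
    e = model.couplings
    row = e.mean(axis=1, keepdims=True)       # over states of i -> fn of b
    col = e.mean(axis=2, keepdims=True)       # over states of j -> fn of a
    grand = e.mean(axis=(1, 2), keepdims=True)
    new_e = e - row - col + grand
    h = model.fields.copy()
    for i in range(L):
        for j in range(i + 1, L):
            k = pair_index(i, j, L)
            h[i] += col[k, :, 0] - grand[k, 0, 0]
            h[j] += row[k, 0, :] - grand[k, 0, 0]
    h -= h.mean(axis=1, keepdims=True)
    return CouplingModel(q, h, new_e, "zero-sum", model.single_freqs,
                         model.converged, model.method)


def reweight_sequences(msa: Msa, theta: float = 0.8) -> SequenceWeights:
    """Standard DCA reweighting: w_r = 1 / #{s : identity(r, s) >= theta}.

    The neighbourhood count includes the sequence itself; Meff = sum of
    weights.
    """
    if not 0 < theta <= 1:
        raise ValueError("theta must be in (0, 1]")
    ident = _identity_matrix(msa.codes())
    neighbours = (ident >= theta - 1e-9).sum(axis=1)
    neighbours = np.maximum(neighbours, 1)
    w = 1.0 / neighbours
    return SequenceWeights(w, float(w.sum()))


# ---------------------------------------------------------------------------
# mean-field DCA


def _onehot21(codes: np.ndarray, q: int) -> np.ndarray:
    n, L = codes.shape
    oh = np.zeros((n, L, q), dtype=np.float64)
    oh[np.arange(n)[:, None], np.arange(L)[None, :], codes] = 1.0
    return oh


def _weighted_freqs21(codes: np.ndarray, w: np.ndarray,
                      q: int) -> tuple[np.ndarray, np.ndarray]:
    n, L = codes.shape
    oh = _onehot21(codes, q)
    wsum = w.sum()
    f1 = np.einsum("r,rla->la", w, oh) / wsum
    flat = oh.reshape(n, L * q)
    f2 = (flat.T @ (flat * w[:, None])).reshape(L, q, L, q) / wsum
    return f1, f2


def couplings_from_frequencies(f1: np.ndarray, f2: np.ndarray,
                               q: int) -> np.ndarray:
    """Mean-field couplings from pseudocounted frequencies.

    Builds the connected-correlation matrix over the first q-1 states of
    every site (the last state is gauged out), inverts it, and returns the
    packed (n_pairs, q, q) coupling blocks in the last-state-zero gauge:
    e = -C^{-1} on the reduced states, zero on the last row/column.
    """
    L = f1.shape[0]
    qr = q - 1
    C = (f2[:, :qr, :, :qr]
         - f1[:, :qr, None, None] * f1[None, None, :, :qr])
    # exact single-site blocks: f_ii(a,b) = delta_ab f_i(a)
    for i in range(L):
        C[i, :, i, :] = np.diag(f1[i, :qr]) - np.outer(f1[i, :qr], f1[i, :qr])
    C = C.reshape(L * qr, L * qr)
    try:
        Jred = -np.linalg.inv(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular correlation matrix; increase the pseudocount "
            "fraction or provide more diverse sequences") from exc
    Jred = Jred.reshape(L, qr, L, qr)
    n_pairs = L * (L - 1) // 2
    e = np.zeros((n_pairs, q, q))
    for i in range(L):
        for j in range(i + 1, L):
            e[pair_index(i, j, L), :qr, :qr] = Jred[i, :, j, :]
    return e


def mfdca_fit(msa: Msa, weights: SequenceWeights,
              pseudocount_fraction: float = 0.5) -> CouplingModel:
    """Mean-field DCA fit on the 21-state alphabet.

    Frequencies are mixed with a flat pseudocount, f <- (1-pc) f_data +
    pc/q (pc/q^2 for pairs); couplings are the negative inverse of the
    connected-correlation matrix with the gap state gauged out, re-expressed
    in the zero-sum gauge. Deterministic.
    """
    if msa.length < 2:
        raise ValueError("mfDCA requires at least 2 columns")
    if not 0 <= pseudocount_fraction < 1:
        raise ValueError("pseudocount_fraction must be in [0, 1)")
    q = Q_DCA
    codes = codes21(msa.codes())
    w = np.asarray(weights.weights, dtype=np.float64)
    f1, f2 = _weighted_freqs21(codes, w, q)
    pc = pseudocount_fraction
    f1 = (1 - pc) * f1 + pc / q
    f2 = (1 - pc) * f2 + pc / (q * q)
    e = couplings_from_frequencies(f1, f2, q)
    with np.errstate(divide="ignore"):
        h = np.log(f1) - np.log(f1[:, -1:])
    model = CouplingModel(q, h, e, "last-state-zero", single_freqs=f1,
                          method="mfdca")
    return zero_sum_gauge(model)


def direct_information(model: CouplingModel,
                       freqs: np.ndarray | None = None,
                       tol: float = 1e-6, max_iter: int = 2000) -> np.ndarray:
    """Direct information of every pair of the coupling model.

    For each pair, the two-site distribution P(a,b) ∝ exp(e_ij(a,b))
    μ_i(a) μ_j(b) is given auxiliary fields μ iterated until its marginals
    match the single-site frequencies within ``tol``; DI is the mutual
    information of that distribution. DI >= 0, zero when e_ij = 0.
    """
    if freqs is None:
        freqs = model.single_freqs
    if freqs is None:
        raise ValueError("single-site frequencies required for DI")
    L, q = model.fields.shape
    di = np.zeros((L, L))
    for i in range(L):
        fi = freqs[i]
        for j in range(i + 1, L):
            fj = freqs[j]
            W = np.exp(model.coupling(i, j))
            mu_i = np.full(q, 1.0 / q)
            mu_j = np.full(q, 1.0 / q)
            for _ in range(max_iter):
                new_i = fi / (W @ mu_j)
                new_i /= new_i.sum()
                new_j = fj / (W.T @ new_i)
                new_j /= new_j.sum()
                P = new_i[:, None] * W * new_j[None, :]
                P /= P.sum()
                err = max(np.abs(P.sum(axis=1) - fi).max(),
                          np.abs(P.sum(axis=0) - fj).max())
                mu_i, mu_j = new_i, new_j
                if err < tol:
                    break
            else:
                raise RuntimeError(
                    f"DI marginal matching did not converge for pair "
                    f"({i}, {j})")
            outer = fi[:, None] * fj[None, :]
            with np.errstate(divide="ignore", invalid="ignore"):
                terms = np.where(P > 0, P * np.log(P / outer), 0.0)
            di[i, j] = di[j, i] = max(terms.sum(), 0.0)
    return di


# ---------------------------------------------------------------------------
# pseudo-likelihood DCA


def _plm_objective(x, Xoh, w, n, L, q, lam_h, lam_e, diag_mask):
    Lq = L * q
    h = x[:Lq].astype(np.float32).reshape(L, q)
    W = x[Lq:].astype(np.float32).reshape(Lq, Lq)
    W = 0.5 * (W + W.T)
    W[diag_mask] = 0.0

    Z = (Xoh @ W).reshape(n, L, q) + h[None, :, :]
    Zmax = Z.max(axis=2, keepdims=True)
    expZ = np.exp(Z - Zmax)
    norm = expZ.sum(axis=2)
    lse = np.log(norm) + Zmax[:, :, 0]
    z_true = (Z * Xoh.reshape(n, L, q)).sum(axis=2)
    nll = float(np.einsum("r,rl->", w.astype(np.float64),
                          (lse - z_true).astype(np.float64)))

    P = expZ / norm[:, :, None]
    delta = (P - Xoh.reshape(n, L, q)) * w[:, None, None]
    gh = delta.sum(axis=0)
    G = Xoh.reshape(n, Lq).T @ delta.reshape(n, Lq)
    G = 0.5 * (G + G.T)
    G[diag_mask] = 0.0

    Wd = W.astype(np.float64)
    hd = h.astype(np.float64)
    f = nll + lam_h * float((hd ** 2).sum()) + 0.5 * lam_e * float((Wd ** 2).sum())
    grad = np.concatenate([
        (gh.astype(np.float64) + 2 * lam_h * hd).ravel(),
        (G.astype(np.float64) + lam_e * Wd).ravel(),
    ])
    return f, grad


def plmdca_fit(msa: Msa, weights: SequenceWeights, lam_h: float = 0.01,
               lam_e: float | None = None, max_iter: int = 300,
               gtol: float = 1e-4) -> CouplingModel:
    """Symmetric pseudo-likelihood Potts fit (fields + couplings).

    Minimizes the weighted negative pseudo-log-likelihood with L2 penalties
    lam_h on fields and lam_e (default 0.2·(L-1)) on each unordered
    coupling block, from a deterministic zero initialization, with L-BFGS
    run to gradient tolerance ``gtol``. On non-convergence the best iterate
    is returned with ``converged=False`` and a warning.
    """
    codes = codes21(msa.codes())
    n, L = codes.shape
    if L < 1:
        raise ValueError("empty alignment")
    q = Q_DCA
    w = np.asarray(weights.weights, dtype=np.float64)
    if weights.meff < 2:
        raise ValueError("at least 2 effective sequences are required")
    if lam_e is None:
        lam_e = 0.2 * max(L - 1, 1)
    Lq = L * q

    if L == 1:
        # no couplings; closed-form style fit of the fields alone
        f1, _ = _weighted_freqs21(codes, w, q)
        # regularized independent-site fit via the same objective
        Xoh = _onehot21(codes, q).reshape(n, Lq).astype(np.float32)
        diag_mask = np.ones((Lq, Lq), dtype=bool)

    else:
        Xoh = _onehot21(codes, q).reshape(n, Lq).astype(np.float32)
        site = np.repeat(np.arange(L), q)
        diag_mask = site[:, None] == site[None, :]

    x0 = np.zeros(Lq + Lq * Lq)
    res = minimize(_plm_objective, x0, jac=True, method="L-BFGS-B",
                   args=(Xoh, w, n, L, q, lam_h, lam_e, diag_mask),
                   options={"maxiter": max_iter, "gtol": gtol,
                            "ftol": 1e-12, "maxcor": 8})
    converged = bool(res.success)
    if not converged:
        warnings.warn(f"plmDCA did not reach the gradient tolerance "
                      f"({res.message}); returning the best iterate")
    h = res.x[:Lq].reshape(L, q)
    W = res.x[Lq:].reshape(Lq, Lq)
    W = 0.5 * (W + W.T)
    n_pairs = L * (L - 1) // 2
    e = np.zeros((n_pairs, q, q))
    for i in range(L):
        for j in range(i + 1, L):
            e[pair_index(i, j, L)] = W[i * q:(i + 1) * q, j * q:(j + 1) * q]
    f1, _ = _weighted_freqs21(codes, w, q)
    model = CouplingModel(q, h, e, "plm", single_freqs=f1,
                          converged=converged, method="plmdca")
    return zero_sum_gauge(model)


def pseudolikelihood(model: CouplingModel, msa: Msa,
                     weights: SequenceWeights) -> float:
    """Weighted negative pseudo-log-likelihood of the data under the model
    (no regularization terms); used e.g. to verify gauge invariance."""
    codes = codes21(msa.codes())
    n, L = codes.shape
    q = model.q
    w = np.asarray(weights.weights, dtype=np.float64)
    total = 0.0
    for i in range(L):
        logits = np.tile(model.fields[i], (n, 1))
        for j in range(L):
            if j == i:
                continue
            logits += model.coupling(i, j)[:, codes[:, j]].T
        lse = logsumexp(logits, axis=1)
        z_true = logits[np.arange(n), codes[:, i]]
        total += float(np.sum(w * (lse - z_true)))
    return total


def save_coupling_model(model: CouplingModel, path) -> None:
    """Dump a fitted model to a plain-text file.

    Header lines (``# key value``) carry q, L, gauge, method and the
    convergence flag; ``h i a value`` lines carry the fields and
    ``e i j a b value`` lines the couplings (i < j, 0-based)."""
    L = model.length
    with open(path, "w") as fh:
        fh.write(f"# q {model.q}\n# L {L}\n# gauge {model.gauge}\n")
        fh.write(f"# method {model.method}\n")
        fh.write(f"# converged {int(model.converged)}\n")
        for i in range(L):
            for a in range(model.q):
                fh.write(f"h {i} {a} {model.fields[i, a]:.17g}\n")
        for i in range(L):
            for j in range(i + 1, L):
                block = model.couplings[pair_index(i, j, L)]
                for a in range(model.q):
                    for b in range(model.q):
                        fh.write(f"e {i} {j} {a} {b} {block[a, b]:.17g}\n")


def load_coupling_model(path) -> CouplingModel:
    """Read a model written by :func:`save_coupling_model`."""
    meta = {}
    entries_h, entries_e = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "#":
                meta[parts[1]] = " ".join(parts[2:])
            elif parts[0] == "h":
                entries_h.append(parts[1:])
            elif parts[0] == "e":
                entries_e.append(parts[1:])
    q, L = int(meta["q"]), int(meta["L"])
    fields = np.zeros((L, q))
    for i, a, v in entries_h:
        fields[int(i), int(a)] = float(v)
    couplings = np.zeros((L * (L - 1) // 2, q, q))
    for i, j, a, b, v in entries_e:
        couplings[pair_index(int(i), int(j), L), int(a), int(b)] = float(v)
    return CouplingModel(q, fields, couplings, meta.get("gauge", "unknown"),
                         converged=bool(int(meta.get("converged", 1))),
                         method=meta.get("method", ""))


def frobenius_apc_score(model: CouplingModel) -> np.ndarray:
    """APC-corrected Frobenius norms of the coupling blocks.

    Norms are taken over the 20x20 amino-acid block (gap state excluded)
    after the zero-sum gauge fix; the average product correction is then
    applied exactly as for MI.
    """
    gauged = model if model.gauge == "zero-sum" else zero_sum_gauge(model)
    L, q = gauged.fields.shape
    block = slice(0, 20) if q == Q_DCA else slice(0, q)
    S = np.zeros((L, L))
    for i in range(L):
        for j in range(i + 1, L):
            e = gauged.couplings[pair_index(i, j, L)][block, block]
            S[i, j] = S[j, i] = np.sqrt((e ** 2).sum())
    if L < 3:
        return S
    _, fapc = apc_correct(S)
    return fapc
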