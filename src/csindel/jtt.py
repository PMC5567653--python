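"""Jones-Taylor-Thornton (JTT) empirical amino-acid substitution model.

Embeds the published JTT accepted-point-mutation exchangeabilities and
equilibrium frequencies (the standard 190-value lower triangle in
A R N D C Q E G H I L K M F P S T W Y V order, as distributed with the
common phylogenetics packages).  The rate matrix is normalised so one
unit of branch length equals one expected substitution per site:
mu = sum_i pi_i * sum_{j != i} S_ij * pi_j, Q /= mu.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

# Lower triangle of the symmetric exchangeability matrix S, row by row
# (row R first).  Integer mutation counts as published.
_JTT_LOWER = [
      58,
      54,   45,
      81,   16,  528,
      56,  113,   34,   10,
      57,  310,   86,   49,    9,
     105,   29,   58,  767,    5,  323,
     179,  137,   81,  130,   59,   26,  119,
      27,  328,  391,  112,   69,  597,   26,   23,
      36,   22,   47,   11,   17,    9,   12,    6,   16,
      30,   38,   12,    7,   23,   72,    9,    6,   56,  229,
      35,  646,  263,   26,    7,  292,  181,   27,   45,   21,   14,
      54,   44,   30,   15,   31,   43,   18,   14,   33,  479,  388,   65,
      15,    5,   10,    4,   78,    4,    5,    5,   40,   89,  248,    4,   43,
     194,   74,   15,   15,   14,  164,   18,   24,  115,   10,  102,   21,   16,   17,
     378,  101,  503,   59,  223,   53,   30,  201,   73,   40,   59,   47,   29,   92,  285,
     475,   64,  232,   38,   42,   51,   32,   33,   46,  245,   25,  103,  226,   12,  118,  477,
       9,  126,    8,    4,  115,   18,   10,   55,    8,    9,   52,   10,   24,   53,    6,   35,   12,
      11,   20,   70,   46,  209,   24,    7,    8,  573,   32,   24,    8,   18,  536,   10,   63,   21,   71,
     298,   17,   16,   31,   62,   20,   45,   47,   11,  961,  180,   14,  323,   62,   23,   38,  112,   25,   16,
]

_JTT_FREQS = [
    0.076748, 0.051691, 0.042645, 0.051544, 0.019803,
    0.040752, 0.061830, 0.073152, 0.022944, 0.053761,
    0.091904, 0.058676, 0.023826, 0.040126, 0.050901,
    0.068765, 0.058565, 0.014261, 0.032102, 0.066005,
]


def exchangeability_matrix() -> np.ndarray:
    """Symmetric 20x20 exchangeability matrix S (zero diagonal)."""
    S = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            S[i, j] = S[j, i] = _JTT_LOWER[k]
            k += 1
    return S


def equilibrium_frequencies() -> np.ndarray:
    """Equilibrium amino-acid frequencies pi (sum exactly 1)."""
    pi = np.asarray(_JTT_FREQS, dtype=float)
    return pi / pi.sum()


def matrix_checksum() -> int:
    """Sum of the 190 exchangeability integers; printed by --version so
    a run records which constants it used."""
    return int(sum(_JTT_LOWER))


@lru_cache(maxsize=1)
def rate_matrix() -> np.ndarray:
    """Reversible rate matrix Q_ij = S_ij * pi_j, rows summing to zero,
    scaled to one expected substitution per site per unit time."""
    S = exchangeability_matrix()
    pi = equilibrium_frequencies()
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    return Q / mu


@lru_cache(maxsize=1)
def _eigensystem():
    """Spectral decomposition of Q via the symmetrised form
    B = diag(sqrt(pi)) Q diag(1/sqrt(pi)) (reversibility makes B
    symmetric, so eigh is stable)."""
    Q = rate_matrix()
    pi = equilibrium_frequencies()
    rt = np.sqrt(pi)
    B = (rt[:, None] * Q) / rt[None, :]
    lam, U = np.linalg.eigh((B + B.T) / 2.0)
    left = U.T * rt[None, :]          # U^T diag(sqrt(pi))
    right = U / rt[:, None]           # diag(1/sqrt(pi)) U
    return lam, right, left


def transition_matrix(t: float) -> np.ndarray:
    """P(t) = exp(Qt); rows sum to 1, entries clipped at 0."""
    if t < 0:
        raise ValueError(f"negative branch length {t}")
    lam, right, left = _eigensystem()
    P = (right * np.exp(lam * t)[None, :]) @ left
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


def transition_matrices(ts: np.ndarray) -> np.ndarray:
    """Stack of P(t) for an array of times (shape (len(ts), 20, 20))."""
    lam, right, left = _eigensystem()
    ts = np.asarray(ts, dtype=float)
    P = np.einsum("ik,tk,kj->tij", right, np.exp(np.outer(ts, lam)), left)
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=2, keepdims=True)
    return P


def encode(seq: str) -> np.ndarray:
    """Residue string -> indices in AA_ORDER; gaps/ambiguity -> -1."""
    out = np.full(len(seq), -1, dtype=np.int64)
    for i, ch in enumerate(seq):
        out[i] = AA_INDEX.get(ch, -1)
    return out
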