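"""Shared alignment machinery: alphabet, substitution scores, Gotoh DP kernels.

Every alignment-shaped computation in the package (pairwise sequence
identity, profile-profile comparison, sequence-vs-profile scanning) runs
through the two numba kernels defined here, operating on a precomputed
column-pair score matrix ``S``. Callers build ``S`` however their score model
demands (BLOSUM62 lookups for sequences, expected-substitution scores for
profiles) and pass gap penalties; the kernels are agnostic to what the rows
and columns mean.

Gap convention: a gap run of length k costs ``gap_open + (k - 1) * gap_ext``
(the opening residue pays ``gap_open``), matching Biopython's
``open_gap_score``/``extend_gap_score`` convention so the PairwiseAligner can
serve as an external cross-check.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

#: The 20 standard amino acids, in the fixed order used for every profile
#: column and count vector in the package.
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Gap characters. 'X' (unknown residue) is deliberately grouped with gaps:
#: it carries no usable conservation signal, so every column statistic in the
#: package excludes it from residue pairs.
GAP_CHARS = frozenset("-.X")

#: Background amino-acid frequencies (order of AMINO_ACIDS). A rounded
#: database-composition table; sums to exactly 1.
BACKGROUND_FREQS = np.array(
    [
        0.074,  # A
        0.052,  # R
        0.045,  # N
        0.059,  # D
        0.025,  # C
        0.034,  # Q
        0.054,  # E
        0.074,  # G
        0.026,  # H
        0.068,  # I
        0.099,  # L
        0.058,  # K
        0.025,  # M
        0.047,  # F
        0.039,  # P
        0.057,  # S
        0.051,  # T
        0.013,  # W
        0.032,  # Y
        0.068,  # V
    ]
)
assert abs(BACKGROUND_FREQS.sum() - 1.0) < 1e-12


def _blosum62_20x20() -> np.ndarray:
    mat = substitution_matrices.load("BLOSUM62")
    out = np.empty((20, 20))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            out[i, j] = mat[a, b]
    return out


#: BLOSUM62 restricted to the 20 standard residues, AMINO_ACIDS order.
BLOSUM62 = _blosum62_20x20()


def _similarity_kernel() -> np.ndarray:
    """sim(x, y) = max(0, (B62(x,y) + 4) / (max(B62(x,x), B62(y,y)) + 4)).

    A substitution-matrix kernel rescaled into [0, 1] with sim(x, x) = 1,
    used for column conservation and differential-conservation scoring.
    """
    diag = np.diag(BLOSUM62)
    denom = np.maximum.outer(diag, diag) + 4.0
    return np.maximum(0.0, (BLOSUM62 + 4.0) / denom)


#: Pairwise residue similarity in [0, 1] (AMINO_ACIDS order).
SIMILARITY = _similarity_kernel()


def encode(seq: str) -> np.ndarray:
    """Encode a residue string as int8 indices into AMINO_ACIDS; gaps/X -> -1."""
    out = np.full(len(seq), -1, dtype=np.int8)
    for i, ch in enumerate(seq):
        out[i] = AA_INDEX.get(ch, -1)
    return out


def seq_pair_score_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """BLOSUM62 score matrix for two encoded sequences (no gap entries)."""
    return BLOSUM62[np.ix_(a, b)]


@njit(cache=False)
def gotoh_score(S, gap_open, gap_ext):  # pragma: no cover - numba
    """Global affine-gap alignment score over column-pair scores ``S``."""
    n, m = S.shape
    NEG = -1e30
    M = np.full(m + 1, NEG)
    Ix = np.full(m + 1, NEG)  # gap in the column axis (vertical)
    Iy = np.full(m + 1, NEG)  # gap in the row axis (horizontal)
    M[0] = 0.0
    for j in range(1, m + 1):
        Iy[j] = gap_open + (j - 1) * gap_ext
    for i in range(1, n + 1):
        prevM = M.copy()
        prevIx = Ix.copy()
        prevIy = Iy.copy()
        M[0] = NEG
        Ix[0] = gap_open + (i - 1) * gap_ext
        Iy[0] = NEG
        for j in range(1, m + 1):
            best_prev = prevM[j - 1]
            if prevIx[j - 1] > best_prev:
                best_prev = prevIx[j - 1]
            if prevIy[j - 1] > best_prev:
                best_prev = prevIy[j - 1]
            m_ij = best_prev + S[i - 1, j - 1]
            ix = max(prevM[j] + gap_open, prevIx[j] + gap_ext)
            iy = max(M[j - 1] + gap_open, Iy[j - 1] + gap_ext)
            M[j] = m_ij
            Ix[j] = ix
            Iy[j] = iy
    return max(M[m], Ix[m], Iy[m])


@njit(cache=False)
def _gotoh_traceback(S, gap_open, gap_ext):  # pragma: no cover - numba
    n, m = S.shape
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    # traceback: 0=fromM, 1=fromIx, 2=fromIy
    tbM = np.zeros((n + 1, m + 1), dtype=np.uint8)
    tbIx = np.zeros((n + 1, m + 1), dtype=np.uint8)
    tbIy = np.zeros((n + 1, m + 1), dtype=np.uint8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = gap_open + (i - 1) * gap_ext
        tbIx[i, 0] = 1 if i > 1 else 0
    for j in range(1, m + 1):
        Iy[0, j] = gap_open + (j - 1) * gap_ext
        tbIy[0, j] = 2 if j > 1 else 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # M
            best = M[i - 1, j - 1]
            src = 0
            if Ix[i - 1, j - 1] > best:
                best = Ix[i - 1, j - 1]
                src = 1
            if Iy[i - 1, j - 1] > best:
                best = Iy[i - 1, j - 1]
                src = 2
            M[i, j] = best + S[i - 1, j - 1]
            tbM[i, j] = src
            # Ix (consume row i, gap in columns of second axis)
            o = M[i - 1, j] + gap_open
            e = Ix[i - 1, j] + gap_ext
            if o >= e:
                Ix[i, j] = o
                tbIx[i, j] = 0
            else:
                Ix[i, j] = e
                tbIx[i, j] = 1
            # Iy
            o = M[i, j - 1] + gap_open
            e = Iy[i, j - 1] + gap_ext
            if o >= e:
                Iy[i, j] = o
                tbIy[i, j] = 0
            else:
                Iy[i, j] = e
                tbIy[i, j] = 2
    # choose final state
    score = M[n, m]
    state = 0
    if Ix[n, m] > score:
        score = Ix[n, m]
        state = 1
    if Iy[n, m] > score:
        score = Iy[n, m]
        state = 2
    # walk back; steps encoded: 0 = diagonal, 1 = up (gap in b), 2 = left (gap in a)
    steps = np.empty(n + m, dtype=np.uint8)
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            steps[k] = 0
            nxt = tbM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            steps[k] = 1
            nxt = tbIx[i, j]
            i -= 1
        else:
            steps[k] = 2
            nxt = tbIy[i, j]
            j -= 1
        state = nxt
        k += 1
    return score, steps[:k][::-1].copy()


def gotoh_align(S: np.ndarray, gap_open: float, gap_ext: float):
    """Global affine alignment with traceback.

    Returns ``(score, a_idx, b_idx)`` where the index arrays give, for each
    alignment column, the source column in a / b or -1 for a gap.
    """
    score, steps = _gotoh_traceback(
        np.ascontiguousarray(S, dtype=np.float64), float(gap_open), float(gap_ext)
    )
    a_idx = []
    b_idx = []
    i = j = 0
    for s in steps:
        if s == 0:
            a_idx.append(i)
            b_idx.append(j)
            i += 1
            j += 1
        elif s == 1:
            a_idx.append(i)
            b_idx.append(-1)
            i += 1
        else:
            a_idx.append(-1)
            b_idx.append(j)
            j += 1
    return score, np.array(a_idx, dtype=np.int64), np.array(b_idx, dtype=np.int64)


def run_gotoh_score(S: np.ndarray, gap_open: float, gap_ext: float) -> float:
    """Convenience wrapper ensuring dtype/contiguity for the numba kernel."""
    return float(
        gotoh_score(
            np.ascontiguousarray(S, dtype=np.float64), float(gap_open), float(gap_ext)
        )
    )
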