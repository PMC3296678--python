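"""Smith-Waterman local alignment with affine gaps and Karlin-Altschul e-values.

The scoring convention: a gap of length L costs ``gap_open + L * gap_extend``
(the opening charge is paid once, every gapped residue pays the extension).
Ambiguity codes (N and friends) never score as matches: any column involving
an ambiguous base scores as a mismatch.

E-values follow the extreme-value law P(S >= x) = 1 - exp(-K m n e^(-lambda x));
``KARLIN_LAMBDA`` and ``KARLIN_K`` were fitted once by maximum likelihood
(Gumbel fit) to optimal local scores of 10,000 independent random pairs of
length 200 under the default scoring, and are cached here.
``fit_karlin_altschul`` reproduces the fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

# alphabet encoding: A C G T = 0..3, every ambiguity code = 4
_ENCODE = np.full(256, 4, dtype=np.int8)
for i, base in enumerate("ACGT"):
    _ENCODE[ord(base)] = i
    _ENCODE[ord(base.lower())] = i

DEFAULT_SCORING = dict(match=5, mismatch=-4, gap_open=12, gap_extend=2)

# Fitted once against the shuffle null (see module docstring); regenerate with
# fit_karlin_altschul(n_pairs=10000, length=200, seed=0).
KARLIN_LAMBDA = 0.12398
KARLIN_K = 0.02011


def encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=False)
def _sw_score_kernel(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n = a.shape[0]
    m = b.shape[0]
    prev_h = np.zeros(m + 1, dtype=np.int64)
    prev_e = np.full(m + 1, -10**9, dtype=np.int64)
    best = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        h_diag = 0  # prev_h[0] of previous row
        cur_h = 0
        f = -10**9
        for j in range(1, m + 1):
            if ai == b[j - 1] and ai < 4:
                s = match
            else:
                s = mismatch
            e = prev_e[j]
            cand_e = prev_h[j] - gap_open - gap_extend
            ext_e = e - gap_extend
            e = cand_e if cand_e > ext_e else ext_e
            cand_f = cur_h - gap_open - gap_extend
            ext_f = f - gap_extend
            f = cand_f if cand_f > ext_f else ext_f
            h = h_diag + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            h_diag = prev_h[j]
            prev_h[j] = h
            prev_e[j] = e
            cur_h = h
            if h > best:
                best = h
    return best


@njit(cache=False)
def _sw_traceback_kernel(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n = a.shape[0]
    m = b.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), -10**8, dtype=np.int32)
    F = np.full((n + 1, m + 1), -10**8, dtype=np.int32)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            if ai == b[j - 1] and ai < 4:
                s = match
            else:
                s = mismatch
            e1 = H[i - 1, j] - gap_open - gap_extend
            e2 = E[i - 1, j] - gap_extend
            E[i, j] = e1 if e1 > e2 else e2
            f1 = H[i, j - 1] - gap_open - gap_extend
            f2 = F[i, j - 1] - gap_extend
            F[i, j] = f1 if f1 > f2 else f2
            h = H[i - 1, j - 1] + s
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback from (bi, bj) in H state
    i = bi
    j = bj
    n_match = 0
    n_cols = 0
    state = 0  # 0 = H, 1 = E (gap in b / vertical), 2 = F (gap in a / horizontal)
    while i > 0 and j > 0:
        if state == 0:
            h = H[i, j]
            if h == 0:
                break
            if ai_eq(a, b, i, j, match, mismatch) + H[i - 1, j - 1] == h:
                n_cols += 1
                if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                    n_match += 1
                i -= 1
                j -= 1
            elif h == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            n_cols += 1
            if E[i, j] == H[i - 1, j] - gap_open - gap_extend:
                state = 0
            i -= 1
        else:
            n_cols += 1
            if F[i, j] == H[i, j - 1] - gap_open - gap_extend:
                state = 0
            j -= 1
    return best, i, bi, j, bj, n_match, n_cols


@njit(cache=False)
def ai_eq(a, b, i, j, match, mismatch):  # pragma: no cover
    if a[i - 1] == b[j - 1] and a[i - 1] < 4:
        return match
    return mismatch


@dataclass
class SimilarityHit:
    """A local-alignment hit between two sequences."""

    query_id: str
    target_id: str
    score: int
    identity_pct: float
    query_coverage_pct: float
    e_value: float
    query_span: tuple[int, int] = (0, 0)
    target_span: tuple[int, int] = (0, 0)
    strand: str = "+"


def karlin_evalue(score: float, m: int, n: int,
                  lam: float = KARLIN_LAMBDA, k: float = KARLIN_K) -> float:
    """Expected number of chance local alignments with at least this score."""
    return k * m * n * math.exp(-lam * score)


def sw_score(query: str, target: str, scoring: dict | None = None) -> int:
    """Optimal local alignment score only (no traceback)."""
    sc = scoring or DEFAULT_SCORING
    return int(_sw_score_kernel(encode(query), encode(target), sc["match"],
                                sc["mismatch"], sc["gap_open"], sc["gap_extend"]))


def local_align(query: str, target: str, scoring: dict | None = None,
                query_id: str = "query", target_id: str = "target") -> SimilarityHit:
    """Optimal Smith-Waterman local alignment of two nucleotide sequences.

    Returns the score, percent identity over aligned columns, query coverage
    and the Karlin-Altschul e-value. Sequences containing only ambiguous
    bases yield a zero-score hit.
    """
    if not query or not target:
        raise ValueError("local_align requires nonempty sequences")
    sc = scoring or DEFAULT_SCORING
    score, q0, q1, t0, t1, n_match, n_cols = _sw_traceback_kernel(
        encode(query), encode(target), sc["match"], sc["mismatch"],
        sc["gap_open"], sc["gap_extend"])
    if score <= 0:
        return SimilarityHit(query_id, target_id, 0, 0.0, 0.0,
                             karlin_evalue(0, len(query), len(target)))
    identity = 100.0 * n_match / n_cols if n_cols else 0.0
    coverage = 100.0 * (q1 - q0) / len(query)
    return SimilarityHit(
        query_id=query_id, target_id=target_id, score=int(score),
        identity_pct=identity, query_coverage_pct=coverage,
        e_value=karlin_evalue(score, len(query), len(target)),
        query_span=(q0, q1), target_span=(t0, t1))


def fit_karlin_altschul(n_pairs: int = 10000, length: int = 200,
                        seed: int = 0, scoring: dict | None = None) -> tuple[float, float]:
    """Fit (lambda, K) by ML Gumbel fit to null local-alignment scores.

    Draws ``n_pairs`` independent uniform-random sequence pairs of the given
    length, records the optimal local score of each, and fits a Gumbel
    location/scale by maximum likelihood: lambda = 1/scale,
    K = exp(lambda * loc) / (length^2).
    """
    from scipy.stats import gumbel_r

    rng = np.random.default_rng(seed)
    sc = scoring or DEFAULT_SCORING
    scores = np.empty(n_pairs)
    for i in range(n_pairs):
        a = rng.integers(0, 4, size=length).astype(np.int8)
        b = rng.integers(0, 4, size=length).astype(np.int8)
        scores[i] = _sw_score_kernel(a, b, sc["match"], sc["mismatch"],
                                     sc["gap_open"], sc["gap_extend"])
    loc, scale = gumbel_r.fit(scores)
    lam = 1.0 / scale
    k = math.exp(lam * loc) / (length * length)
    return lam, k
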