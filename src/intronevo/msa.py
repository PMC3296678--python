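"""Marker-bearing multiple alignment of ortholog coding sequences.

Intron positions are represented by artificial introns: a block of 30 ``X``
characters spliced into the CDS at each intron offset. A progressive
profile-profile global aligner (UPGMA guide tree on 6-mer distances) then
stacks homologous marker blocks into shared columns: ``X`` scores strongly
against ``X``, harshly against nucleotides, and is free to stand opposite a
gap, so a lineage lacking the intron simply opens a 30-column gap.

Gap costs are affine with a high opening charge and zero extension, which
keeps gaps few and block-shaped (the spirit of a high gap-open / zero
gap-extension setting in classic progressive aligners).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.cluster.hierarchy import linkage

from .models import GeneModel

MARKER_LEN = 30
ALPHABET = "ACGTNX-"
_IDX = {c: i for i, c in enumerate(ALPHABET)}

# substitution scores: match +5, transition -3, transversion -4, N neutral,
# X/nucleotide -20, X or anything vs existing gap 0. The X/X bonus is
# calibrated against the match score so that two marker blocks only stack
# when their positions differ by less than the 10-column homology window:
# stacking 30 X's gains 30*b and forfeits 5*d of flanking matches, so
# b = 1.6 puts the stacking threshold at d = 9.6 nt.
_S = np.zeros((7, 7))
for a in range(4):
    for b in range(4):
        if a == b:
            _S[a, b] = 5.0
        elif {a, b} in ({0, 2}, {1, 3}):   # A<->G, C<->T
            _S[a, b] = -3.0
        else:
            _S[a, b] = -4.0
for a in range(4):
    _S[a, 5] = _S[5, a] = -20.0
_S[5, 5] = 1.6

DEFAULT_MSA_PENALTIES = dict(gap_open=30.0, gap_extend=0.0)


def insert_markers(gene: GeneModel, marker_len: int = MARKER_LEN) -> str:
    """CDS with an ``X``-block spliced in at every intron offset."""
    out = []
    prev = 0
    for intron in gene.introns:
        out.append(gene.cds_seq[prev:intron.cds_offset])
        out.append("X" * marker_len)
        prev = intron.cds_offset
    out.append(gene.cds_seq[prev:])
    return "".join(out)


def strip_markers(row: str) -> str:
    return row.replace("X", "").replace("-", "")


@dataclass
class MarkedAlignment:
    """Rows over {A,C,G,T,N,X,-} with per-row marker block locations."""

    rows: dict[str, str]
    # per row: (first column, last column, intron index) of each X-block
    block_spans: dict[str, list[tuple[int, int, int]]] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def marker_blocks(self) -> dict[str, list[tuple[int, int]]]:
        return {sp: [(s, i) for s, _, i in spans]
                for sp, spans in self.block_spans.items()}


@dataclass
class ColumnClass:
    """One homologous intron-position class."""

    class_id: str
    column: int                      # leftmost block start column
    span: tuple[int, int]            # [min start, max end] over member blocks
    members: list[tuple[str, int]]   # (species, intron index)


@dataclass
class IntronColumnMap:
    columns: list[ColumnClass]

    def species_with(self, class_id: str) -> set[str]:
        for c in self.columns:
            if c.class_id == class_id:
                return {sp for sp, _ in c.members}
        raise KeyError(class_id)


@njit(cache=False)
def _nw_profile_kernel(M, gap_open, gap_extend):  # pragma: no cover
    la, lb = M.shape
    NEG = -1e30
    H = np.empty((la + 1, lb + 1))
    E = np.empty((la + 1, lb + 1))
    F = np.empty((la + 1, lb + 1))
    H[0, 0] = 0.0
    E[0, 0] = NEG
    F[0, 0] = NEG
    for i in range(1, la + 1):
        E[i, 0] = -(gap_open + gap_extend * i)
        H[i, 0] = E[i, 0]
        F[i, 0] = NEG
    for j in range(1, lb + 1):
        F[0, j] = -(gap_open + gap_extend * j)
        H[0, j] = F[0, j]
        E[0, j] = NEG
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            e1 = H[i - 1, j] - gap_open - gap_extend
            e2 = E[i - 1, j] - gap_extend
            E[i, j] = e1 if e1 > e2 else e2
            f1 = H[i, j - 1] - gap_open - gap_extend
            f2 = F[i, j - 1] - gap_extend
            F[i, j] = f1 if f1 > f2 else f2
            h = H[i - 1, j - 1] + M[i - 1, j - 1]
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            H[i, j] = h
    # state-aware traceback (0 = main, 1 = gap in B, 2 = gap in A);
    # diagonal preferred on ties
    ops = np.empty(la + lb, dtype=np.uint8)
    k = 0
    i, j = la, lb
    state = 0
    while i > 0 or j > 0:
        if state == 0:
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + M[i - 1, j - 1]:
                ops[k] = 0
                k += 1
                i -= 1
                j -= 1
            elif i > 0 and H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            ops[k] = 1
            k += 1
            if E[i, j] == H[i - 1, j] - gap_open - gap_extend:
                state = 0
            i -= 1
        else:
            ops[k] = 2
            k += 1
            if F[i, j] == H[i, j - 1] - gap_open - gap_extend:
                state = 0
            j -= 1
    return ops[:k][::-1].copy()


def _profile(rows: list[str]) -> np.ndarray:
    n = len(rows)
    arr = np.zeros((len(rows[0]), 7))
    for row in rows:
        idx = np.array([_IDX[c] for c in row], dtype=np.int64)
        arr[np.arange(len(row)), idx] += 1.0
    return arr / n


def _merge(rows_a: list[str], rows_b: list[str], penalties: dict) -> tuple[list[str], list[str]]:
    fa = _profile(rows_a)
    fb = _profile(rows_b)
    M = fa @ _S @ fb.T
    ops = _nw_profile_kernel(M, penalties["gap_open"], penalties["gap_extend"])
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op == 0:
            for r, row in zip(out_a, rows_a):
                r.append(row[ia])
            for r, row in zip(out_b, rows_b):
                r.append(row[ib])
            ia += 1
            ib += 1
        elif op == 1:
            for r, row in zip(out_a, rows_a):
                r.append(row[ia])
            for r in out_b:
                r.append("-")
            ia += 1
        else:
            for r in out_a:
                r.append("-")
            for r, row in zip(out_b, rows_b):
                r.append(row[ib])
            ib += 1
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def _kmer_set(seq: str, k: int = 6) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def _marker_spans_unaligned(marked: str) -> list[tuple[int, int]]:
    """(start, end) half-open spans of X-runs in an unaligned marked string."""
    spans = []
    i = 0
    while i < len(marked):
        if marked[i] == "X":
            j = i
            while j < len(marked) and marked[j] == "X":
                j += 1
            for s in range(i, j, MARKER_LEN):
                spans.append((s, s + MARKER_LEN))
            i = j
        else:
            i += 1
    return spans


def align_group(marked: dict[str, str],
                penalties: dict | None = None) -> MarkedAlignment:
    """Progressive global alignment of marked CDS strings.

    The guide tree is UPGMA on 6-mer Jaccard distance of the marker-stripped
    sequences (ties broken by species name order); profiles are merged
    bottom-up with the marker-aware scoring above.
    """
    if len(marked) < 2:
        raise ValueError("align_group requires at least two sequences")
    penalties = penalties or DEFAULT_MSA_PENALTIES
    names = sorted(marked)
    kmers = [_kmer_set(strip_markers(marked[n])) for n in names]
    n = len(names)
    cond = []
    for i in range(n):
        for j in range(i + 1, n):
            union = len(kmers[i] | kmers[j])
            inter = len(kmers[i] & kmers[j])
            cond.append(1.0 - (inter / union if union else 0.0))
    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([names[i]], [marked[names[i]]]) for i in range(n)}
    if n > 2:
        Z = linkage(np.array(cond), method="average")
        merges = [(int(r[0]), int(r[1])) for r in Z]
    else:
        merges = [(0, 1)]
    nxt = n
    for ca, cb in merges:
        names_a, rows_a = clusters.pop(ca)
        names_b, rows_b = clusters.pop(cb)
        rows_a, rows_b = _merge(rows_a, rows_b, penalties)
        clusters[nxt] = (names_a + names_b, rows_a + rows_b)
        nxt += 1
    final_names, final_rows = clusters.popitem()[1]
    rows = dict(zip(final_names, final_rows))
    spans: dict[str, list[tuple[int, int, int]]] = {}
    for sp in names:
        row = rows[sp]
        colmap = np.flatnonzero(np.frombuffer(row.encode(), dtype=np.uint8)
                                != ord("-"))
        sp_spans = []
        for idx, (s, e) in enumerate(_marker_spans_unaligned(marked[sp])):
            sp_spans.append((int(colmap[s]), int(colmap[e - 1]), idx))
        spans[sp] = sp_spans
    return MarkedAlignment(rows=rows, block_spans=spans)


def map_intron_columns(aln: MarkedAlignment,
                       max_offset_cols: int = 10) -> IntronColumnMap:
    """Cluster marker blocks into homologous intron-position classes.

    Blocks whose start columns lie within ``max_offset_cols`` of each other
    (single linkage over sorted starts) merge into one class; classes are
    ordered left to right.
    """
    blocks = []
    for sp, spans in aln.block_spans.items():
        for s, e, idx in spans:
            blocks.append((s, e, sp, idx))
    blocks.sort(key=lambda b: (b[0], b[2], b[3]))
    classes: list[ColumnClass] = []
    cur: list[tuple[int, int, str, int]] = []
    for b in blocks:
        if cur and b[0] - cur[-1][0] > max_offset_cols:
            classes.append(_finish_class(cur, len(classes)))
            cur = []
        cur.append(b)
    if cur:
        classes.append(_finish_class(cur, len(classes)))
    return IntronColumnMap(columns=classes)


def _finish_class(blocks, i: int) -> ColumnClass:
    return ColumnClass(
        class_id=f"k{i}",
        column=min(b[0] for b in blocks),
        span=(min(b[0] for b in blocks), max(b[1] for b in blocks)),
        members=[(sp, idx) for _, _, sp, idx in blocks])
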