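"""Mechanistic signatures of intron gain and loss.

Attribution evidence per event class:

* RTMIL (reverse-transcriptase-mediated intron loss) leaves no direct scar;
  it is probed through biases: positional uniformity of losses (one-sample
  KS against Uniform(0,1)), germline-expression enrichment (Pearson 2x2
  chi-square, no continuity correction), and excess loss of adjacent introns
  (within-gene permutation null, goodness-of-fit chi-square).
* Genomic deletion / NHEJ: residual nucleotides at a former intron-exon
  junction that align to the conserved orthologous intron; direct repeats
  (>= 5 bp) at junctions.
* Transposon insertion: the gained intron aligns to a transposon library
  element at high coverage, with a target site duplication (TSD) at the
  intron 5' start recurring near the 3' junction.
* DSBR filler: the gained intron aligns to the mitochondrial genome
  (coverage >= 90%, e <= 0.1); the best hit is validated against a
  1000-shuffle mononucleotide permutation null.
* Intron sliding: two nearby (but unmerged) intron-position classes whose
  intron sequences align at e <= 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .align import DEFAULT_SCORING, encode, karlin_evalue, local_align, _sw_score_kernel
from .models import GeneModel, revcomp
from .msa import IntronColumnMap, MarkedAlignment


@dataclass
class SignatureHit:
    """A local-alignment or repeat match supporting a mechanism."""

    event_ref: str
    mechanism: str               # transposon | mito_dsbr | nhej_loss | sliding
    partner: str
    identity_pct: float
    coverage_pct: float
    e_value: float
    shuffle_p: Optional[float] = None
    repeat: Optional[str] = None
    tsd: Optional[str] = None
    strand: str = "+"
    shift_cols: int = 0
    target_span: tuple[int, int] = (0, 0)


@dataclass
class BiasReport:
    test: str
    statistic: float
    p_value: float
    counts: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# positional and expression biases (RTMIL)
# ---------------------------------------------------------------------------

@dataclass
class ResolvedEvent:
    """An event call tied to a representative member gene carrying the intron."""

    event_ref: str
    type: str
    gene: GeneModel
    intron_index: int


def relative_positions(resolved: Sequence[ResolvedEvent]) -> list[float]:
    """Relative CDS position (scale of 1) of each event's intron."""
    out = []
    for r in resolved:
        off = r.gene.introns[r.intron_index].cds_offset
        out.append(off / len(r.gene.cds_seq))
    return out


def ks_uniform(positions: Sequence[float]) -> BiasReport:
    """Two-sided one-sample KS test of positions against Uniform(0,1).

    D is computed from the empirical CDF; the p-value is the asymptotic
    Kolmogorov distribution at sqrt(n)*D.
    """
    n = len(positions)
    if n < 5:
        raise ValueError(f"KS uniformity test needs >= 5 positions, got {n}")
    x = np.sort(np.asarray(positions, dtype=float))
    cdf = x  # Uniform(0,1) CDF
    d_plus = np.max(np.arange(1, n + 1) / n - cdf)
    d_minus = np.max(cdf - np.arange(0, n) / n)
    d = max(d_plus, d_minus)
    p = float(stats.kstwobign.sf(np.sqrt(n) * d))
    return BiasReport(test="ks_uniform", statistic=float(d),
                      p_value=min(1.0, p), counts={"n": n})


def germline_enrichment(event_germline: int, event_total: int,
                        background_germline: int, background_total: int) -> BiasReport:
    """Pearson chi-square (2x2, no continuity correction) for germline bias."""
    a, n1 = event_germline, event_total
    b, n2 = background_germline, background_total
    if not (0 <= a <= n1 and 0 <= b <= n2):
        raise ValueError("germline counts exceed totals")
    table = np.array([[a, n1 - a], [b, n2 - b]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square table has a zero margin")
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    stat = float(((table - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(stat, df=1))
    return BiasReport(test="germline_chi2", statistic=stat, p_value=p,
                      counts={"event_germline": a, "event_total": n1,
                              "background_germline": b, "background_total": n2})


def goodness_of_fit(observed: float, expected: float) -> BiasReport:
    """One-cell goodness-of-fit chi-square (df=1), e.g. adjacent-loss excess."""
    if expected <= 0:
        raise ValueError("expected count must be positive")
    stat = (observed - expected) ** 2 / expected
    return BiasReport(test="gof_chi2", statistic=float(stat),
                      p_value=float(stats.chi2.sf(stat, df=1)),
                      counts={"observed": observed, "expected": expected})


def adjacent_loss_test(loss_positions: dict[tuple[str, str], list[int]],
                       intron_counts: dict[str, int],
                       n_perm: int = 10000, seed: int = 0) -> BiasReport:
    """Excess of simultaneous adjacent intron losses.

    ``loss_positions`` maps (gene, branch) to the ordinal intron positions
    lost on that branch; ``intron_counts`` gives each gene's number of intron
    positions. Observed = pairs of losses at consecutive positions on one
    branch of one gene; the expectation redistributes each branch's losses
    uniformly over the gene's positions (``n_perm`` permutations) and the
    excess is scored by a df=1 goodness-of-fit chi-square.
    """
    rng = np.random.default_rng(seed)

    def count_adjacent(groups: dict[tuple[str, str], list[int]]) -> int:
        total = 0
        for pos in groups.values():
            s = sorted(pos)
            total += sum(1 for i in range(len(s) - 1) if s[i + 1] - s[i] == 1)
        return total

    for (gene, _), pos in loss_positions.items():
        if len(pos) > intron_counts[gene]:
            raise ValueError(f"{gene}: more losses than intron positions")
    observed = count_adjacent(loss_positions)
    sims = np.empty(n_perm)
    for it in range(n_perm):
        perm = {}
        for (gene, branch), pos in loss_positions.items():
            perm[(gene, branch)] = list(
                rng.choice(intron_counts[gene], size=len(pos), replace=False))
        sims[it] = count_adjacent(perm)
    expected = float(sims.mean())
    if expected == 0:
        return BiasReport(test="adjacent_loss", statistic=float("inf") if observed else 0.0,
                          p_value=0.0 if observed else 1.0,
                          counts={"observed": observed, "expected": expected})
    rep = goodness_of_fit(observed, expected)
    rep.test = "adjacent_loss"
    return rep


# ---------------------------------------------------------------------------
# direct repeats and TSDs
# ---------------------------------------------------------------------------

@dataclass
class RepeatHit:
    seq: str
    side: str          # "5prime" | "3prime" junction
    exon_pos: int      # start within the exon-flank window
    intron_pos: int    # start within the intron-terminal window


def _maximal_common_substrings(a: str, b: str, min_len: int) -> list[tuple[str, int, int]]:
    hits = []
    for i in range(len(a)):
        for j in range(len(b)):
            if a[i] != b[j] or a[i] not in "ACGT":
                continue
            if i > 0 and j > 0 and a[i - 1] == b[j - 1] and a[i - 1] in "ACGT":
                continue    # not maximal: extendable left
            k = 0
            while (i + k < len(a) and j + k < len(b)
                   and a[i + k] == b[j + k] and a[i + k] in "ACGT"):
                k += 1
            if k >= min_len:
                hits.append((a[i:i + k], i, j))
    return hits


def find_direct_repeats(left_exon_flank: str, intron_seq: str,
                        right_exon_flank: str, min_len: int = 5,
                        window: int = 30) -> list[RepeatHit]:
    """Exact direct repeats (>= min_len) shared by an exon terminus and the
    adjacent intron terminus, at either junction; longest first, ties by
    leftmost exon position."""
    out: list[RepeatHit] = []
    exon5 = left_exon_flank[-window:]
    intron5 = intron_seq[:window]
    for seq, i, j in _maximal_common_substrings(exon5, intron5, min_len):
        out.append(RepeatHit(seq=seq, side="5prime", exon_pos=i, intron_pos=j))
    intron3 = intron_seq[-window:]
    exon3 = right_exon_flank[:window]
    for seq, j, i in _maximal_common_substrings(intron3, exon3, min_len):
        out.append(RepeatHit(seq=seq, side="3prime", exon_pos=i, intron_pos=j))
    out.sort(key=lambda h: (-len(h.seq), h.exon_pos, h.side))
    return out


def repeat_flanking_rate(junctions: Sequence[tuple[str, str, str]],
                         min_len: int = 5, window: int = 30) -> float:
    """Fraction of introns with at least one flanking direct repeat."""
    if not junctions:
        raise ValueError("repeat_flanking_rate needs at least one intron")
    n_hit = sum(1 for left, intron, right in junctions
                if find_direct_repeats(left, intron, right, min_len, window))
    return n_hit / len(junctions)


def compare_repeat_rates(hits_a: int, total_a: int,
                         hits_b: int, total_b: int) -> BiasReport:
    """Chi-square comparison of repeat-flanking rates between two intron sets."""
    rep = germline_enrichment(hits_a, total_a, hits_b, total_b)
    rep.test = "repeat_rate_chi2"
    return rep


def detect_tsd(upstream_exon_flank: str, intron_seq: str,
               downstream_exon_flank: str, min_len: int = 4,
               max_len: int = 15, max_mismatch: int = 1) -> Optional[str]:
    """Target-site duplication: the intron 5' prefix recurring near the 3'
    junction (within ``max_len`` nt on either side) with at most
    ``max_mismatch`` mismatches. Returns the longest such prefix, or None."""
    L = len(intron_seq)
    for l in range(min(max_len, L // 2), min_len - 1, -1):
        prefix = intron_seq[:l]
        best = None
        # second copy starting inside the intron within max_len of the junction
        for start in range(max(l, L - max_len), L - l + 1):
            mm = sum(1 for a, b in zip(prefix, intron_seq[start:start + l]) if a != b)
            if mm <= max_mismatch:
                best = prefix
                break
        if best is None:
            # or starting in the downstream exon within max_len of the junction
            for start in range(0, min(max_len, len(downstream_exon_flank) - l + 1)):
                mm = sum(1 for a, b in
                         zip(prefix, downstream_exon_flank[start:start + l]) if a != b)
                if mm <= max_mismatch:
                    best = prefix
                    break
        if best is not None:
            return best
    return None


# ---------------------------------------------------------------------------
# insertion-source scans (transposon / mitochondrial filler)
# ---------------------------------------------------------------------------

def scan_insertion_source(gained_intron: str, library: dict[str, str],
                          mechanism: str, event_ref: str = "",
                          min_coverage: float = 90.0, max_e: float = 0.1,
                          min_identity: float = 60.0,
                          scoring: dict | None = None) -> list[SignatureHit]:
    """Align a gained intron (both strands) against a sequence library.

    Hits passing the coverage, e-value and identity thresholds are returned
    best-first (by e-value). The identity floor guards against the long,
    low-identity chance alignments that permissive gap costs admit at
    e <= 0.1; genuine insertion sources align near-identically. The caller
    attaches TSD/repeat evidence afterwards.
    """
    if len(gained_intron) < 20:
        raise ValueError("scan requires an intron of >= 20 nt")
    hits: list[SignatureHit] = []
    for lib_id in sorted(library):
        target = library[lib_id]
        for strand, query in (("+", gained_intron), ("-", revcomp(gained_intron))):
            h = local_align(query, target, scoring, query_id=event_ref,
                            target_id=lib_id)
            if (h.query_coverage_pct >= min_coverage and h.e_value <= max_e
                    and h.identity_pct >= min_identity):
                hits.append(SignatureHit(
                    event_ref=event_ref, mechanism=mechanism, partner=lib_id,
                    identity_pct=h.identity_pct,
                    coverage_pct=h.query_coverage_pct,
                    e_value=h.e_value, strand=strand,
                    target_span=h.target_span))
    hits.sort(key=lambda h: (h.e_value, h.partner))
    return hits


def shuffle_null_p(query: str, target: str, n_shuffles: int = 1000,
                   seed: int = 0, scoring: dict | None = None) -> float:
    """Permutation p-value of a local alignment score.

    The query is mononucleotide-shuffled ``n_shuffles`` times and realigned
    against the fixed target; p = (1 + #{shuffled score >= observed}) /
    (n_shuffles + 1).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    sc = scoring or DEFAULT_SCORING
    rng = np.random.default_rng(seed)
    q = encode(query)
    t = encode(target)
    observed = _sw_score_kernel(q, t, sc["match"], sc["mismatch"],
                                sc["gap_open"], sc["gap_extend"])
    ge = 0
    for _ in range(n_shuffles):
        shuf = rng.permutation(q)
        s = _sw_score_kernel(shuf, t, sc["match"], sc["mismatch"],
                             sc["gap_open"], sc["gap_extend"])
        if s >= observed:
            ge += 1
    return (1 + ge) / (n_shuffles + 1)


# ---------------------------------------------------------------------------
# imprecise (NHEJ) loss and intron sliding
# ---------------------------------------------------------------------------

def extract_junction_residues(aln: MarkedAlignment, span: tuple[int, int],
                              losing_species: str, donor_species: str,
                              window: int = 20) -> str:
    """Nucleotides of the losing species aligned opposite the donor's marker
    block or gaps around a former intron position."""
    lo = max(0, span[0] - window)
    hi = min(aln.length, span[1] + 1 + window)
    loser = aln.rows[losing_species]
    donor = aln.rows[donor_species]
    return "".join(loser[c] for c in range(lo, hi)
                   if loser[c] in "ACGT" and donor[c] in "-X")


def detect_imprecise_loss(event_ref: str, aln: MarkedAlignment,
                          span: tuple[int, int], losing_species: str,
                          donor_species: str, donor_intron_seq: str,
                          donor_flanks: tuple[str, str] = ("", ""),
                          max_e: float = 0.1, min_residues: int = 6,
                          scoring: dict | None = None) -> Optional[SignatureHit]:
    """NHEJ signature of an intron loss: junction residues matching the
    conserved orthologous intron of the donor species."""
    residues = extract_junction_residues(aln, span, losing_species, donor_species)
    if len(residues) < min_residues:
        return None
    h = local_align(residues, donor_intron_seq, scoring,
                    query_id=event_ref, target_id=donor_species)
    if h.e_value > max_e:
        return None
    repeats = find_direct_repeats(donor_flanks[0], donor_intron_seq,
                                  donor_flanks[1])
    return SignatureHit(event_ref=event_ref, mechanism="nhej_loss",
                        partner=donor_species, identity_pct=h.identity_pct,
                        coverage_pct=h.query_coverage_pct, e_value=h.e_value,
                        repeat=repeats[0].seq if repeats else None)


def detect_sliding(colmap: IntronColumnMap,
                   intron_seq_of: dict[tuple[str, int], str],
                   min_shift_cols: int = 10, max_shift_cols: int = 100,
                   max_e: float = 0.1, event_ref: str = "",
                   marker_len: int = 30,
                   scoring: dict | None = None) -> list[SignatureHit]:
    """Intron sliding: near column-class pairs (unmerged but < max shift
    apart) with disjoint species sets whose intron sequences align.

    The reported shift is in sequence positions: when the two marker blocks
    occupy disjoint column ranges, the block separation includes the marker
    itself, which is subtracted out.
    """
    hits: list[SignatureHit] = []
    cols = colmap.columns
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            shift = cols[j].column - cols[i].column
            if cols[j].column > cols[i].span[1]:
                shift -= marker_len
            if not min_shift_cols < shift <= max_shift_cols:
                continue
            sp_i = {sp for sp, _ in cols[i].members}
            sp_j = {sp for sp, _ in cols[j].members}
            if sp_i & sp_j:
                continue
            a = intron_seq_of[min(cols[i].members)]
            b = intron_seq_of[min(cols[j].members)]
            h = local_align(a, b, scoring)
            if h.e_value <= max_e:
                hits.append(SignatureHit(
                    event_ref=event_ref or f"{cols[i].class_id}~{cols[j].class_id}",
                    mechanism="sliding",
                    partner=f"{cols[i].class_id}~{cols[j].class_id}",
                    identity_pct=h.identity_pct,
                    coverage_pct=h.query_coverage_pct,
                    e_value=h.e_value, shift_cols=shift))
    return hits
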