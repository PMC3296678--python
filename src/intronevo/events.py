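"""Intron gain/loss calling: presence/absence matrices, flank-quality
filtering, Dollo parsimony with outgroup polarisation, and the QC rules for
single-species gains.

Dollo parsimony lets the derived state (intron presence) arise exactly once;
the gain is placed on the edge to the most recent common ancestor of all
present leaves, unless the outgroup also carries the intron, in which case
the intron is ancestral and only losses are called. Losses are the minimal
edge set below the gain node whose removal explains every absent leaf;
missing data (species without a group member) constrains nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import dendropy
import pandas as pd

from .models import GeneModel, IntronRecord, SpeciesTree
from .msa import ColumnClass, IntronColumnMap, MarkedAlignment

STOPS = ("TAA", "TAG", "TGA")
CANONICAL_SPLICE = {("GT", "AG")}

PRESENT, ABSENT, MISSING = 1, 0, None


@dataclass
class MatrixRow:
    group_id: str
    class_id: str
    column: int
    states: dict[str, Optional[int]]     # ingroup species -> 1/0/None
    outgroup_state: Optional[int] = None


@dataclass
class IntronPresenceMatrix:
    rows: list[MatrixRow] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            rec = {"group": r.group_id, "class": r.class_id, "column": r.column,
                   "outgroup": r.outgroup_state}
            rec.update(r.states)
            recs.append(rec)
        return pd.DataFrame(recs)


@dataclass
class EventCall:
    group_id: str
    class_id: str
    type: str                     # gain | loss
    branch: str                   # child-node label of the edge
    leaves: tuple[str, ...]       # leaves affected by the event
    qc_flags: set[str] = field(default_factory=set)
    status: str = "accepted"

    @property
    def single_species(self) -> bool:
        return len(self.leaves) == 1 and self.branch == self.leaves[0]


# ---------------------------------------------------------------------------
# flank-quality filter
# ---------------------------------------------------------------------------

def flank_filter(aln: MarkedAlignment, column: ColumnClass,
                 window: int = 15, min_mean_identity: float = 0.8,
                 min_comparable: int = 5) -> bool:
    """Keep a column only if the alignment flanking it is trustworthy.

    Each side's window is the nearest ``window`` *comparable* columns
    (columns where at least two rows carry unambiguous bases) walking
    outward from the block span, so gap stretches such as the scar of an
    imprecise loss do not consume the window. Mean pairwise identity over
    those columns must reach the threshold (inclusive) on both sides; a side
    with fewer than ``min_comparable`` comparable columns fails.
    """
    lo, hi = column.span
    left = _side_identity(aln, lo - 1, -1, window, min_comparable)
    right = _side_identity(aln, hi + 1, +1, window, min_comparable)
    if left is None or right is None:
        return False
    return left >= min_mean_identity and right >= min_mean_identity


def _side_identity(aln: MarkedAlignment, start: int, step: int,
                   window: int, min_comparable: int) -> Optional[float]:
    rows = list(aln.rows.values())
    cols = []
    c = start
    while 0 <= c < aln.length and len(cols) < window:
        chars = [r[c] for r in rows]
        if sum(ch in "ACGT" for ch in chars) >= 2:
            cols.append(c)
        c += step
    if len(cols) < min_comparable:
        return None
    idents = []
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            match = comp = 0
            for col in cols:
                a, b = rows[i][col], rows[j][col]
                if a in "ACGT" and b in "ACGT":
                    comp += 1
                    if a == b:
                        match += 1
            if comp:
                idents.append(match / comp)
    if not idents:
        return None
    return sum(idents) / len(idents)


# ---------------------------------------------------------------------------
# Dollo machinery
# ---------------------------------------------------------------------------

def _loss_edges(node: dendropy.Node, states: dict[str, Optional[int]],
                tree: SpeciesTree) -> list[dendropy.Node]:
    """Minimal edges below ``node`` whose removal explains all absences."""
    losses: list[dendropy.Node] = []

    def informative(n: dendropy.Node) -> tuple[bool, bool]:
        """(has non-missing leaf, has present leaf) below n."""
        any_state = any_present = False
        for leaf in n.leaf_iter():
            st = states.get(leaf.taxon.label, MISSING)
            if st is not None:
                any_state = True
                if st == PRESENT:
                    any_present = True
        return any_state, any_present

    def recurse(n: dendropy.Node) -> None:
        for child in n.child_nodes():
            has_state, has_present = informative(child)
            if not has_state:
                continue
            if has_present:
                recurse(child)
            else:
                losses.append(child)

    recurse(node)
    return losses


def dollo_reconstruct(states: dict[str, Optional[int]],
                      tree: SpeciesTree,
                      outgroup_state: Optional[int]) -> list[tuple[str, str, tuple[str, ...]]]:
    """Single-gain Dollo reconstruction of one presence/absence row.

    Returns (type, branch, affected leaves) triples. With a present
    outgroup the intron is ancestral (no gain event); otherwise the gain is
    placed on the edge into the MRCA of the present leaves.
    """
    present = sorted(sp for sp, st in states.items() if st == PRESENT)
    if not present:
        return []
    events: list[tuple[str, str, tuple[str, ...]]] = []
    if outgroup_state == PRESENT:
        start = tree.node(_ingroup_root_label(tree))
    else:
        start = tree.mrca(present)
        gained_leaves = tuple(sorted(
            sp for sp in tree.leaves_below(start)
            if states.get(sp) == PRESENT))
        events.append(("gain", SpeciesTree.label(start), gained_leaves))
    for lost in _loss_edges(start, states, tree):
        affected = tuple(sorted(
            sp for sp in tree.leaves_below(lost)
            if states.get(sp) is not None))
        events.append(("loss", SpeciesTree.label(lost), affected))
    return events


def _ingroup_root_label(tree: SpeciesTree) -> str:
    root = tree.tree.seed_node
    if tree.outgroup is None:
        return SpeciesTree.label(root)
    for child in root.child_nodes():
        below = set(tree.leaves_below(child))
        if tree.outgroup not in below:
            return SpeciesTree.label(child)
    raise ValueError("outgroup does not hang off the root")


def partition_outgroup_need(states: dict[str, Optional[int]],
                            tree: SpeciesTree) -> str:
    """Decide whether ingroup states alone polarise the row.

    Compares the two single-gain reconstructions — gain on the edge into the
    MRCA of present leaves versus presence at the ingroup root — by event
    count; a tie means the outgroup is required.
    """
    present = sorted(sp for sp, st in states.items() if st == PRESENT)
    non_missing = sum(1 for st in states.values() if st is not None)
    if non_missing < 2:
        raise ValueError("row has fewer than two informative states")
    if not present:
        return "internal"
    root = tree.node(_ingroup_root_label(tree))
    mrca = tree.mrca(present)
    cost_inside = 1 + len(_loss_edges(mrca, states, tree))
    cost_root = len(_loss_edges(root, states, tree))
    return "internal" if cost_inside != cost_root else "needs_outgroup"


def dollo_events(matrix: IntronPresenceMatrix, tree: SpeciesTree,
                 outgroup_states: Optional[dict[tuple[str, str], Optional[int]]] = None
                 ) -> list[EventCall]:
    """Call gains and losses for every matrix row.

    Rows classified as needing the outgroup are skipped when no outgroup
    state is available (mirroring the exclusion of alignments without an
    outgroup ortholog). The ingroup subtree is used throughout; branches are
    named by their child node.
    """
    calls: list[EventCall] = []
    for row in matrix.rows:
        present = [sp for sp, st in row.states.items() if st == PRESENT]
        if not present:
            continue
        og = row.outgroup_state
        if outgroup_states is not None:
            og = outgroup_states.get((row.group_id, row.class_id), og)
        need = partition_outgroup_need(row.states, tree)
        if need == "needs_outgroup" and og is None:
            continue
        for type_, branch, leaves in dollo_reconstruct(row.states, tree, og):
            calls.append(EventCall(group_id=row.group_id, class_id=row.class_id,
                                   type=type_, branch=branch, leaves=leaves))
    return calls


# ---------------------------------------------------------------------------
# QC filters for single-species gains
# ---------------------------------------------------------------------------

def _inframe_stop_in_intron(intron_seq: str, cds_offset: int) -> bool:
    first = (-cds_offset) % 3
    for i in range(first, len(intron_seq) - 2, 3):
        if intron_seq[i:i + 3] in STOPS:
            return True
    return False


def qc_gain_filters(call: EventCall, intron: IntronRecord, gene: GeneModel,
                    canonical_splice: set[tuple[str, str]] = CANONICAL_SPLICE
                    ) -> EventCall:
    """Apply annotation-error filters to a gain confined to one species.

    A 3n-length intron without a premature termination codon in the host
    reading frame looks like a mis-annotated exon segment and is rejected;
    so is any single-species gain with noncanonical splice dinucleotides.
    Ancestral gains and all losses are exempt.
    """
    if call.type != "gain" or len(call.leaves) != 1:
        return call
    if (intron.length_nt % 3 == 0
            and not _inframe_stop_in_intron(intron.seq, intron.cds_offset)):
        call.qc_flags.add("len3n_noPTC")
    if (intron.donor2, intron.acceptor2) not in canonical_splice:
        call.qc_flags.add("noncanonical_splice")
    if call.qc_flags:
        call.status = "rejected"
    return call


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize_events(calls: list[EventCall], tree: SpeciesTree) -> pd.DataFrame:
    """Per-branch gain/loss table over accepted calls.

    One row per tree edge (named by child node) plus a ``total`` row;
    ``single_species`` counts events confined to one leaf, ``ancestral`` the
    rest, and the two always sum to the branch total.
    """
    leaves = set(tree.leaf_names())
    rows = []
    accepted = [c for c in calls if c.status == "accepted"]
    for _, child in tree.edges():
        if child == tree.outgroup:
            continue
        sub = [c for c in accepted if c.branch == child]
        rec = {"branch": child, "is_leaf": child in leaves}
        for t, plural in (("gain", "gains"), ("loss", "losses")):
            events = [c for c in sub if c.type == t]
            rec[plural] = len(events)
            rec[f"{plural}_single"] = sum(1 for c in events if len(c.leaves) == 1
                                          and c.branch in leaves)
        rows.append(rec)
    df = pd.DataFrame(rows)
    total = {"branch": "total", "is_leaf": False}
    for col in ("gains", "losses", "gains_single", "losses_single"):
        total[col] = int(df[col].sum()) if len(df) else 0
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)
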