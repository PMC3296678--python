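import itertools

import pytest

from intronevo.events import (EventCall, IntronPresenceMatrix, MatrixRow,
                              dollo_events, dollo_reconstruct, flank_filter,
                              partition_outgroup_need, qc_gain_filters,
                              summarize_events)
from intronevo.models import GeneModel, IntronRecord, SpeciesTree
from intronevo.msa import ColumnClass, MarkedAlignment

TREE4 = SpeciesTree.from_newick("(((A,B)n1,(C,D)n2)ing,OUT)root;", outgroup="OUT")


# ---------------------------------------------------------------------------
# flank filter
# ---------------------------------------------------------------------------

def _aln(rows, span):
    return (MarkedAlignment(rows=rows, block_spans={}),
            ColumnClass("k0", span[0], span, members=[]))


def test_identical_flanks_kept():
    row = "ACGTACGTACGTACGTACGT" + "X" * 30 + "ACGTACGTACGTACGTACGT"
    aln, col = _aln({"a": row, "b": row, "c": row}, (20, 49))
    assert flank_filter(aln, col)


def test_randomised_left_flank_dropped():
    left_a = "ACGTACGTACGTACGTACGT"
    left_b = "TGCATGCATGCATGCATGCA"
    right = "ACGTACGTACGTACGTACGT"
    aln, col = _aln({"a": left_a + "X" * 30 + right,
                     "b": left_b + "X" * 30 + right}, (20, 49))
    assert not flank_filter(aln, col)


def test_identity_exactly_at_threshold_is_kept():
    # 12 matches / 15 comparable = 0.8 on the left; right side identical
    left_a = "AAAAAAAAAAAAAAA"
    left_b = "TTTAAAAAAAAAAAA"
    right = "ACGTACGTACGTACGTACGT"
    aln, col = _aln({"a": left_a + "X" * 30 + right,
                     "b": left_b + "X" * 30 + right}, (15, 44))
    assert flank_filter(aln, col, window=15, min_mean_identity=0.8)


def test_too_few_comparable_columns_dropped():
    aln, col = _aln({"a": "ACG" + "X" * 30 + "ACGTACGTACGTACGT",
                     "b": "ACG" + "X" * 30 + "ACGTACGTACGTACGT"}, (3, 32))
    assert not flank_filter(aln, col)


# ---------------------------------------------------------------------------
# outgroup partition
# ---------------------------------------------------------------------------

def test_presence_in_nested_clade_is_internal():
    states = {"A": 1, "B": 0, "C": 0, "D": 0}
    assert partition_outgroup_need(states, TREE4) == "internal"


def test_presence_everywhere_is_internal():
    states = {"A": 1, "B": 1, "C": 1, "D": 1}
    assert partition_outgroup_need(states, TREE4) == "internal"


def test_basal_clade_presence_needs_outgroup():
    # gain on the edge to (A,B) and loss of an ancestral intron on the edge
    # to (C,D) tie at one event each
    states = {"A": 1, "B": 1, "C": 0, "D": 0}
    assert partition_outgroup_need(states, TREE4) == "needs_outgroup"


def test_single_informative_state_is_an_error():
    with pytest.raises(ValueError):
        partition_outgroup_need({"A": 1, "B": None, "C": None, "D": None},
                                TREE4)


# ---------------------------------------------------------------------------
# Dollo reconstruction
# ---------------------------------------------------------------------------

def _events(states, outgroup_state):
    return dollo_reconstruct(states, TREE4, outgroup_state)


def test_gain_on_clade_edge_without_losses():
    ev = _events({"A": 1, "B": 1, "C": 0, "D": 0}, 0)
    assert ev == [("gain", "n1", ("A", "B"))]


def test_scattered_presence_gain_at_root_with_losses():
    ev = _events({"A": 1, "B": 0, "C": 1, "D": 0}, 0)
    assert ("gain", "ing", ("A", "C")) in ev
    losses = {(t, b) for t, b, _ in ev if t == "loss"}
    assert losses == {("loss", "B"), ("loss", "D")}


def test_all_present_with_outgroup_present_yields_no_events():
    assert _events({"A": 1, "B": 1, "C": 1, "D": 1}, 1) == []


def test_outgroup_presence_makes_intron_ancestral():
    ev = _events({"A": 1, "B": 1, "C": 0, "D": 0}, 1)
    assert ev == [("loss", "n2", ("C", "D"))]


def test_missing_leaves_constrain_nothing():
    # D is missing, so the loss is placed on the maximal subtree edge (n2)
    # and only the informative leaf C is reported as affected
    ev = _events({"A": 1, "B": None, "C": 0, "D": None}, 1)
    assert ev == [("loss", "n2", ("C",))]


def test_no_present_leaves_no_events():
    assert _events({"A": 0, "B": 0, "C": 0, "D": 0}, 0) == []


# exhaustive check against brute force on a 5-leaf asymmetric tree
TREE5 = SpeciesTree.from_newick("((((A,B)n1,C)n2,(D,E)n3)ing,OUT)root;",
                                outgroup="OUT")


def brute_force_min_events(tree, states):
    """Minimum single-gain Dollo cost by exhaustive state assignment."""
    nodes = list(tree.node("ing").preorder_iter())
    best = None
    for gain in nodes:
        below = list(gain.preorder_iter())
        internal = [n for n in below if not n.is_leaf()]
        for assign in itertools.product([0, 1], repeat=len(internal)):
            state = {id(n): s for n, s in zip(internal, assign)}
            for leaf in tree.tree.leaf_node_iter():
                state[id(leaf)] = states.get(
                    leaf.taxon.label if leaf.is_leaf() else None)
            if state[id(gain)] != 1:
                continue
            ok = True
            losses = 0
            for n in below:
                for ch in n.child_nodes():
                    s_p, s_c = state[id(n)], state.get(id(ch))
                    if s_c is None:
                        continue
                    if s_p == 0 and s_c == 1:
                        ok = False
                        break
                    if s_p == 1 and s_c == 0:
                        losses += 1
                if not ok:
                    break
            if not ok:
                continue
            # leaves outside the gain subtree must be absent or missing
            outside = [l for l in tree.node("ing").leaf_iter()
                       if l not in below]
            if any(states.get(l.taxon.label) == 1 for l in outside):
                continue
            cost = 1 + losses
            if best is None or cost < best:
                best = cost
    return best


def test_dollo_matches_brute_force_on_five_leaves():
    leaves = ["A", "B", "C", "D", "E"]
    for bits in itertools.product([0, 1], repeat=5):
        states = dict(zip(leaves, bits))
        if sum(bits) == 0:
            continue
        ev = dollo_reconstruct(states, TREE5, 0)
        gains = [e for e in ev if e[0] == "gain"]
        assert len(gains) == 1
        present = [l for l, s in states.items() if s == 1]
        assert set(gains[0][2]) == set(present)
        assert len(ev) == brute_force_min_events(TREE5, states)


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

def _gain_call(leaf="A"):
    return EventCall(group_id="og1", class_id="k0", type="gain", branch=leaf,
                     leaves=(leaf,))


def _gene_with(intron_seq, offset=10):
    cds = "ATG" + "AAA" * 20 + "TAA"
    return GeneModel(gene_id="g", species="A", seq_region="r", strand="+",
                     cds_exons=[(0, offset), (offset + len(intron_seq),
                                              offset + len(intron_seq)
                                              + len(cds) - offset)],
                     cds_seq=cds,
                     introns=[IntronRecord(0, offset, intron_seq)]), 0


def test_3n_stop_free_intron_rejected():
    # 60 nt, no stop in the frame set by offset 9 (frame 0 inside the intron)
    intron = "GT" + "CCA" * 18 + "CCAG"[:2] + "AG"
    intron = "GT" + "CCC" * 18 + "CAAG"[-4:]
    intron = ("GTC" + "CCA" * 18 + "AAG")  # 60 nt, codons CCA only
    assert len(intron) == 60
    gene, idx = _gene_with(intron, offset=9)
    call = qc_gain_filters(_gain_call(), gene.introns[idx], gene)
    assert call.status == "rejected" and "len3n_noPTC" in call.qc_flags


def test_61nt_canonical_intron_accepted():
    intron = "GT" + "C" * 57 + "AG"
    assert len(intron) == 61
    gene, idx = _gene_with(intron, offset=9)
    call = qc_gain_filters(_gain_call(), gene.introns[idx], gene)
    assert call.status == "accepted" and not call.qc_flags


def test_3n_intron_with_inframe_stop_accepted():
    intron = "GTC" + "TAA" + "CCA" * 17 + "AAG"
    assert len(intron) == 60
    gene, idx = _gene_with(intron, offset=9)
    call = qc_gain_filters(_gain_call(), gene.introns[idx], gene)
    assert call.status == "accepted"


def test_noncanonical_splice_rejected():
    intron = "GC" + "C" * 57 + "AG"
    gene, idx = _gene_with(intron, offset=9)
    call = qc_gain_filters(_gain_call(), gene.introns[idx], gene)
    assert call.status == "rejected" and "noncanonical_splice" in call.qc_flags


def test_ancestral_gains_exempt_from_qc():
    call = EventCall(group_id="og1", class_id="k0", type="gain", branch="n1",
                     leaves=("A", "B"))
    intron = "GTC" + "CCA" * 18 + "AAG"   # would fail the 3n filter
    gene, idx = _gene_with(intron, offset=9)
    out = qc_gain_filters(call, gene.introns[idx], gene)
    assert out.status == "accepted"


# ---------------------------------------------------------------------------
# summaries and dollo_events plumbing
# ---------------------------------------------------------------------------

def test_summary_totals_and_partition():
    calls = [
        EventCall("og1", "k0", "gain", "A", ("A",)),
        EventCall("og1", "k1", "loss", "n2", ("C", "D")),
        EventCall("og2", "k0", "loss", "B", ("B",)),
        EventCall("og2", "k1", "gain", "C", ("C",), qc_flags={"len3n_noPTC"},
                  status="rejected"),
    ]
    df = summarize_events(calls, TREE4)
    total = df[df["branch"] == "total"].iloc[0]
    assert total["gains"] == 1 and total["losses"] == 2
    assert total["gains_single"] == 1 and total["losses_single"] == 1
    per_branch = df[df["branch"] != "total"]
    assert per_branch["gains"].sum() == total["gains"]
    assert per_branch["losses"].sum() == total["losses"]


def test_row_needing_outgroup_without_state_is_skipped():
    row = MatrixRow(group_id="og1", class_id="k0", column=0,
                    states={"A": 1, "B": 1, "C": 0, "D": 0},
                    outgroup_state=None)
    calls = dollo_events(IntronPresenceMatrix(rows=[row]), TREE4)
    assert calls == []
    row.outgroup_state = 0
    calls = dollo_events(IntronPresenceMatrix(rows=[row]), TREE4)
    assert [(c.type, c.branch) for c in calls] == [("gain", "n1")]


def test_each_row_yields_at_most_one_gain(small_inference):
    per_row = {}
    for c in small_inference.calls:
        if c.type == "gain":
            per_row.setdefault((c.group_id, c.class_id), []).append(c)
    assert all(len(v) == 1 for v in per_row.values())
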