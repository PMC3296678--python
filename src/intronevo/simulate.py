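"""Forward simulation of a gene family over a species tree with
mechanism-labelled intron gains and losses.

Every dataset the downstream stages consume (genomes, annotations, tree,
transposon library, mitochondrial genome, expression flags) is emitted from
here together with a ground-truth event log, so ortholog detection, Dollo
event calling and mechanism attribution are all testable without external
data.

Mechanisms emulated
-------------------
gains:  ``transposon_tsd``  a library element bracketed by a duplicated
                            target site (the TSD starts with the donor GT);
        ``mito_filler``     a slice of a simulated high-AT mitochondrial
                            genome, optionally preceded by a direct repeat
                            copied from the upstream exon terminus;
        ``plain``           random sequence with canonical GT..AG ends.
losses: ``precise``         the intron is removed exactly;
        ``nhej_imprecise``  the intron is removed but a frame-preserving
                            run of its 5' nucleotides stays behind in the
                            coding sequence.
Optionally, introns may *slide* (relocate by a small distance with their
sequence conserved) and leaves may acquire annotation-error pseudo-introns
(length 3n, stop-free in frame) that the QC stage is expected to reject.

All offsets are tracked in the coordinate frame of the root CDS; residues
left behind by imprecise losses are the only source of exonic length change
and are converted to lineage-local coordinates when leaf genes are
materialised.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from .models import GeneModel, IntronRecord, SpeciesTree, revcomp

STOPS = ("TAA", "TAG", "TGA")
_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    Rates are expected events per gene per unit branch length; the
    substitution rate is expected substitutions per site per unit branch
    length. Mechanism mixes must each sum to 1.
    """

    seed: int = 0
    n_species: int = 8
    n_genes: int = 50
    newick: Optional[str] = None          # explicit tree overrides n_species
    outgroup_name: str = "outgrp"
    root_introns: tuple[int, int] = (2, 6)      # uniform inclusive
    cds_codons: tuple[int, int] = (120, 300)    # uniform inclusive
    substitution_rate: float = 0.005
    gain_rate: float = 0.08
    loss_rate: float = 0.12
    slide_rate: float = 0.0
    pseudo_gain_prob: float = 0.0               # per leaf gene
    # When False, event placement avoids coverage degeneracies that no
    # parsimony method can resolve: each column is lost at most once
    # tree-wide, only ancestral (root) introns are lost, and the branch into
    # the ingroup root carries no losses. Used for exact-recovery checks.
    allow_homoplasy: bool = True
    gain_mix: dict = field(default_factory=lambda: {
        "transposon_tsd": 0.2, "mito_filler": 0.2, "plain": 0.6})
    loss_mix: dict = field(default_factory=lambda: {
        "precise": 0.8, "nhej_imprecise": 0.2})
    intron_len_log_mean: float = 5.86           # ~350 nt median
    intron_len_log_sigma: float = 0.7
    intron_len_range: tuple[int, int] = (61, 2000)
    mito_len: int = 16000
    mito_at: float = 0.8
    mito_slice: tuple[float, float, int, int] = (113.0, 8.0, 110, 140)
    repeat_prob: float = 0.3
    repeat_len: tuple[int, int] = (5, 7)
    tsd_len: int = 8
    n_transposons: int = 5
    transposon_len: tuple[int, int] = (200, 800)
    nhej_residual_choices: tuple[int, ...] = (15, 18, 21)
    branch_length_range: tuple[float, float] = (0.4, 1.2)
    outgroup_branch_length: float = 3.0
    germline_prob_event: float = 0.66
    germline_prob_background: float = 0.52

    def validate(self) -> None:
        for name in ("gain_mix", "loss_mix"):
            mix = getattr(self, name)
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities must sum to 1")
        for name in ("substitution_rate", "gain_rate", "loss_rate",
                     "slide_rate", "pseudo_gain_prob"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("germline_prob_event", "germline_prob_background",
                     "repeat_prob", "mito_at"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.intron_len_range[0] < 30:
            raise ValueError("introns shorter than 30 nt are not representable")
        if self.cds_codons[0] < 30:
            raise ValueError("CDS too short for intron placement")


@dataclass
class TruthEvent:
    """One simulated gain/loss/slide with its mechanism label."""

    family: str
    column: str
    branch: str            # child-node label of the edge carrying the event
    type: str              # gain | loss | slide
    mechanism: str
    offset: int            # root-frame CDS offset of the affected position
    seq: str = ""          # inserted intron / deleted intron / residues left
    repeat: Optional[str] = None
    tsd: Optional[str] = None
    shift: int = 0         # slides only


@dataclass
class SimTruth:
    """Ground truth for a simulated dataset."""

    seed: int
    events: list[TruthEvent]
    # (species, family) -> list of (intron_index, column_id, origin_mechanism)
    leaf_introns: dict
    germline: dict                      # family -> 0/1
    mito: str
    transposons: dict[str, str]
    tree: SpeciesTree
    config: SimConfig

    def events_of(self, type_: Optional[str] = None,
                  mechanism: Optional[str] = None) -> list[TruthEvent]:
        out = []
        for ev in self.events:
            if type_ is not None and ev.type != type_:
                continue
            if mechanism is not None and ev.mechanism != mechanism:
                continue
            out.append(ev)
        return out


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _rand_at_seq(rng: np.random.Generator, n: int, at: float) -> str:
    p = [(1 - at) / 2, at / 2, (1 - at) / 2, at / 2]  # C A G T order below
    return "".join(np.array(list("CAGT"))[rng.choice(4, size=n, p=p)])


def _stopfree_extend(rng: np.random.Generator, prefix: str, n: int) -> str:
    """Extend ``prefix`` by n bases so no stop codon appears in any frame."""
    out = list(prefix)
    while len(out) < len(prefix) + n:
        b = _BASES[rng.integers(0, 4)]
        if len(out) >= 2 and "".join(out[-2:]) + b in STOPS:
            continue
        out.append(b)
    return "".join(out[len(prefix):])


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    codons = []
    while len(codons) < n_codons - 2:
        c = _rand_seq(rng, 3)
        if c not in STOPS:
            codons.append(c)
    stop = ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
    return "ATG" + "".join(codons) + stop


def _has_internal_stop(cds: str) -> bool:
    for i in range(3, len(cds) - 3, 3):
        if cds[i:i + 3] in STOPS:
            return True
    return False


def _inframe_stop_in_intron(intron: str, cds_offset: int) -> bool:
    """Stop codon fully inside the intron, in the host reading frame."""
    first = (-cds_offset) % 3
    for l in range(first, len(intron) - 2, 3):
        if intron[l:l + 3] in STOPS:
            return True
    return False


# ---------------------------------------------------------------------------
# tree generation
# ---------------------------------------------------------------------------

def random_species_tree(config: SimConfig, rng: np.random.Generator) -> SpeciesTree:
    """Random rooted bifurcating ingroup plus a long-branch outgroup."""
    lo, hi = config.branch_length_range

    def build(names: list[str]) -> str:
        if len(names) == 1:
            return f"{names[0]}:{rng.uniform(lo, hi):.4f}"
        k = int(rng.integers(1, len(names)))
        left, right = names[:k], names[k:]
        bl = rng.uniform(lo, hi)
        return f"({build(left)},{build(right)}):{bl:.4f}"

    species = [f"sp{i + 1:02d}" for i in range(config.n_species)]
    perm = rng.permutation(len(species))
    ingroup = build([species[i] for i in perm])
    newick = f"({ingroup},{config.outgroup_name}:{config.outgroup_branch_length});"
    return SpeciesTree.from_newick(newick, outgroup=config.outgroup_name)


# ---------------------------------------------------------------------------
# gene state during evolution
# ---------------------------------------------------------------------------

@dataclass
class _Intron:
    col: str
    root_off: int
    seq: str
    origin: str


@dataclass
class _GeneState:
    cds: str                              # lineage-local spliced CDS
    introns: list[_Intron]
    inserts: list[tuple[int, int]]        # (root_off, k) residue insertions

    def copy(self) -> "_GeneState":
        return _GeneState(self.cds, [dataclasses.replace(i) for i in self.introns],
                          list(self.inserts))

    def local_off(self, root_off: int) -> int:
        return root_off + sum(k for ro, k in self.inserts if ro <= root_off)


class _Family:
    """Bookkeeping for one gene family across the whole tree."""

    def __init__(self, fam_id: str, root: _GeneState):
        self.id = fam_id
        self.root = root
        self.reserved: set[int] = {i.root_off for i in root.introns}
        self.next_col = len(root.introns)
        self.lost_cols: set[str] = set()

    def new_column(self) -> str:
        col = f"c{self.next_col}"
        self.next_col += 1
        return col

    def free_offset(self, rng: np.random.Generator, cds_len: int,
                    min_gap: int = 15) -> Optional[int]:
        for _ in range(200):
            off = int(rng.integers(6, cds_len - 5))
            if all(abs(off - r) >= min_gap for r in self.reserved):
                self.reserved.add(off)
                return off
        return None


# ---------------------------------------------------------------------------
# intron constructors
# ---------------------------------------------------------------------------

def _draw_intron_length(config: SimConfig, rng: np.random.Generator) -> int:
    lo, hi = config.intron_len_range
    length = int(round(rng.lognormal(config.intron_len_log_mean,
                                     config.intron_len_log_sigma)))
    return int(np.clip(length, lo, hi))


def _make_plain_intron(config: SimConfig, rng: np.random.Generator) -> str:
    length = _draw_intron_length(config, rng)
    head = "GT" + _stopfree_extend(rng, "GT", 22)
    return head + _rand_seq(rng, length - len(head) - 2) + "AG"


def _ensure_qc_visible(intron: str, cds_offset: int,
                       rng: np.random.Generator) -> str:
    """Make a genuine gained intron distinguishable from an annotation error.

    Real novel introns in the simulator either have a non-3n length or carry
    an in-frame stop; a 3n, stop-free intron is indistinguishable from a
    mis-annotation and would be (correctly) rejected by QC, so one base is
    added before the acceptor to break the 3n length.
    """
    if len(intron) % 3 == 0 and not _inframe_stop_in_intron(intron, cds_offset):
        return intron[:-2] + _rand_seq(rng, 1) + "AG"
    return intron


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------

class FamilySimulator:
    def __init__(self, config: SimConfig):
        config.validate()
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.mito = _rand_at_seq(self.rng, config.mito_len, config.mito_at)
        self.transposons = {
            f"TE{i + 1}": _rand_seq(self.rng, int(self.rng.integers(
                config.transposon_len[0], config.transposon_len[1] + 1)))
            for i in range(config.n_transposons)}
        if config.newick is not None:
            self.tree = SpeciesTree.from_newick(config.newick,
                                               outgroup=config.outgroup_name
                                               if config.outgroup_name in config.newick
                                               else None)
        else:
            self.tree = random_species_tree(config, self.rng)

    # -- root gene ---------------------------------------------------------
    def simulate_root_state(self, rng: np.random.Generator) -> _GeneState:
        cfg = self.config
        n_codons = int(rng.integers(cfg.cds_codons[0], cfg.cds_codons[1] + 1))
        cds = _random_orf(rng, n_codons)
        n_introns = int(rng.integers(cfg.root_introns[0], cfg.root_introns[1] + 1))
        offsets: list[int] = []
        for _ in range(n_introns):
            for _ in range(200):
                off = int(rng.integers(6, len(cds) - 5))
                if all(abs(off - o) >= 15 for o in offsets):
                    offsets.append(off)
                    break
        introns = [_Intron(f"c{i}", off, _make_plain_intron(cfg, rng), "root")
                   for i, off in enumerate(sorted(offsets))]
        return _GeneState(cds=cds, introns=introns, inserts=[])

    # -- gains -------------------------------------------------------------
    def _build_gain(self, state: _GeneState, mech: str, root_off: int,
                    rng: np.random.Generator):
        cfg = self.config
        local = state.local_off(root_off)
        repeat = None
        tsd = None
        if mech == "plain":
            seq = _make_plain_intron(cfg, rng)
        elif mech == "transposon_tsd":
            te_id = list(self.transposons)[rng.integers(0, len(self.transposons))]
            tsd = "GT" + _rand_seq(rng, cfg.tsd_len - 2)
            seq = tsd + self.transposons[te_id] + tsd + "AG"
        elif mech == "mito_filler":
            mean, sd, lo, hi = cfg.mito_slice
            slen = int(np.clip(round(rng.normal(mean, sd)), lo, hi))
            start = int(rng.integers(0, cfg.mito_len - slen))
            piece = self.mito[start:start + slen]
            if rng.random() < 0.5:
                piece = revcomp(piece)
            if rng.random() < cfg.repeat_prob:
                r = int(rng.integers(cfg.repeat_len[0], cfg.repeat_len[1] + 1))
                repeat = state.cds[local - r:local]
                seq = "GT" + repeat + piece + "AG"
            else:
                seq = "GT" + piece + "AG"
        else:  # pragma: no cover - guarded by config validation
            raise ValueError(f"unknown gain mechanism {mech!r}")
        seq = _ensure_qc_visible(seq, local, rng)
        return seq, repeat, tsd

    def _build_pseudo_intron(self, cds_offset: int,
                             rng: np.random.Generator) -> str:
        """Annotation-error-like intron: 3n length, stop-free in frame."""
        length = int(rng.integers(30, 51)) * 3
        while True:
            seq = "GT" + _rand_seq(rng, length - 4) + "AG"
            if not _inframe_stop_in_intron(seq, cds_offset):
                return seq

    # -- per-branch evolution ---------------------------------------------
    def _evolve_branch(self, fam: _Family, state: _GeneState, branch: str,
                       bl: float, events: list[TruthEvent],
                       rng: np.random.Generator) -> None:
        cfg = self.config
        # losses first: they act on introns present at branch start
        if cfg.allow_homoplasy:
            eligible = list(range(len(state.introns)))
        else:
            eligible = [i for i, iv in enumerate(state.introns)
                        if iv.origin == "root" and iv.col not in fam.lost_cols]
            if branch == getattr(self, "_ingroup_root_label", None):
                eligible = []
        n_loss = rng.poisson(cfg.loss_rate * bl)
        n_loss = min(n_loss, len(eligible))
        loss_idx = sorted(rng.choice(eligible, size=n_loss,
                                     replace=False)) if n_loss else []
        touched: set[str] = set()
        for idx in reversed(loss_idx):
            intron = state.introns[idx]
            mechs = list(cfg.loss_mix)
            mech = mechs[rng.choice(len(mechs), p=[cfg.loss_mix[m] for m in mechs])]
            residues = ""
            if mech == "nhej_imprecise":
                k = int(rng.choice(cfg.nhej_residual_choices))
                residues = intron.seq[:k]
                local = state.local_off(intron.root_off)
                cand = state.cds[:local] + residues + state.cds[local:]
                if _has_internal_stop(cand):
                    mech, residues = "precise", ""   # NHEJ scar would break the ORF
                else:
                    state.cds = cand
                    state.inserts.append((intron.root_off, k))
            events.append(TruthEvent(fam.id, intron.col, branch, "loss", mech,
                                     intron.root_off, seq=residues or intron.seq))
            touched.add(intron.col)
            fam.lost_cols.add(intron.col)
            del state.introns[idx]
        # gains
        n_gain = rng.poisson(cfg.gain_rate * bl)
        for _ in range(n_gain):
            root_off = fam.free_offset(rng, len(fam.root.cds))
            if root_off is None:
                continue
            mechs = list(cfg.gain_mix)
            mech = mechs[rng.choice(len(mechs), p=[cfg.gain_mix[m] for m in mechs])]
            seq, repeat, tsd = self._build_gain(state, mech, root_off, rng)
            col = fam.new_column()
            state.introns.append(_Intron(col, root_off, seq, mech))
            state.introns.sort(key=lambda i: i.root_off)
            events.append(TruthEvent(fam.id, col, branch, "gain", mech,
                                     root_off, seq=seq, repeat=repeat, tsd=tsd))
            touched.add(col)
        # slides
        n_slide = rng.poisson(cfg.slide_rate * bl)
        candidates = [i for i in state.introns if i.col not in touched]
        for _ in range(min(n_slide, len(candidates))):
            intron = candidates.pop(int(rng.integers(0, len(candidates))))
            shift = int(rng.integers(12, 31)) * (1 if rng.random() < 0.5 else -1)
            new_off = intron.root_off + shift
            if not 6 <= new_off <= len(fam.root.cds) - 6:
                continue
            if any(abs(new_off - r) >= 0 and abs(new_off - r) < 15
                   for r in fam.reserved - {intron.root_off}):
                continue
            fam.reserved.add(new_off)
            events.append(TruthEvent(fam.id, intron.col, branch, "slide",
                                     "sliding", intron.root_off, seq=intron.seq,
                                     shift=shift))
            intron.root_off = new_off
            state.introns.sort(key=lambda i: i.root_off)
        # neutral substitutions, sparing splice dinucleotides and start/stop
        p = cfg.substitution_rate * bl
        if p > 0:
            state.cds = self._mutate(state.cds, p, 3, 3, rng)
            for intron in state.introns:
                intron.seq = self._mutate(intron.seq, p, 2, 2, rng)

    @staticmethod
    def _mutate(seq: str, p: float, protect5: int, protect3: int,
                rng: np.random.Generator) -> str:
        arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        lo, hi = protect5, len(arr) - protect3
        if hi <= lo:
            return seq
        hits = np.nonzero(rng.random(hi - lo) < p)[0] + lo
        for i in hits:
            cur = chr(arr[i])
            others = [b for b in "ACGT" if b != cur]
            arr[i] = ord(others[rng.integers(0, 3)])
        return arr.tobytes().decode()

    # -- whole-family evolution --------------------------------------------
    def run(self) -> tuple[dict[str, list[GeneModel]], SimTruth]:
        cfg = self.config
        rng = self.rng
        events: list[TruthEvent] = []
        leaf_states: dict[tuple[str, str], _GeneState] = {}
        out_label = self.tree.outgroup
        self._ingroup_root_label = None
        if out_label is not None:
            for child in self.tree.tree.seed_node.child_nodes():
                if out_label not in set(self.tree.leaves_below(child)):
                    self._ingroup_root_label = SpeciesTree.label(child)
        families: dict[str, _Family] = {}
        for g in range(cfg.n_genes):
            fam_id = f"fam{g + 1:04d}"
            root_state = self.simulate_root_state(rng)
            fam = _Family(fam_id, root_state)
            families[fam_id] = fam
            # preorder walk carrying gene state down the tree
            stack = [(self.tree.tree.seed_node, root_state)]
            while stack:
                node, state = stack.pop()
                if node.is_leaf():
                    leaf_states[(node.taxon.label, fam_id)] = state
                    continue
                for child in node.child_nodes():
                    child_state = state.copy()
                    label = SpeciesTree.label(child)
                    bl = child.edge.length or 1.0
                    if label != out_label:   # the outgroup is a static polarizer
                        self._evolve_branch(fam, child_state, label, bl,
                                            events, rng)
                    stack.append((child, child_state))
        # annotation-error pseudo-introns on leaves
        if cfg.pseudo_gain_prob > 0:
            for (species, fam_id), state in sorted(leaf_states.items()):
                if species == out_label:
                    continue
                if rng.random() >= cfg.pseudo_gain_prob:
                    continue
                # keep clear of every intron position the family ever used,
                # so the pseudo-intron forms its own column
                off = families[fam_id].free_offset(
                    rng, len(families[fam_id].root.cds))
                if off is None:
                    continue
                local = state.local_off(off)
                seq = self._build_pseudo_intron(local, rng)
                col = f"pseudo_{species}"
                state.introns.append(_Intron(col, off, seq, "annotation_error"))
                state.introns.sort(key=lambda i: i.root_off)
                events.append(TruthEvent(fam_id, col, species, "gain",
                                         "annotation_error", off, seq=seq))
        # germline labels
        fams_with_event = {ev.family for ev in events
                           if ev.mechanism != "annotation_error"}
        germline = {}
        for g in range(cfg.n_genes):
            fam_id = f"fam{g + 1:04d}"
            p = (cfg.germline_prob_event if fam_id in fams_with_event
                 else cfg.germline_prob_background)
            germline[fam_id] = int(rng.random() < p)
        # materialise leaf gene models
        models: dict[str, list[GeneModel]] = {s: [] for s in self.tree.leaf_names()}
        leaf_introns: dict = {}
        for (species, fam_id), state in sorted(leaf_states.items()):
            models[species].append(_state_to_model(state, species, fam_id))
            leaf_introns[(species, fam_id)] = [
                (i, intron.col, intron.origin)
                for i, intron in enumerate(state.introns)]
        truth = SimTruth(seed=cfg.seed, events=events, leaf_introns=leaf_introns,
                         germline=germline, mito=self.mito,
                         transposons=self.transposons, tree=self.tree,
                         config=cfg)
        return models, truth


def _state_to_model(state: _GeneState, species: str, fam_id: str) -> GeneModel:
    """Materialise a lineage gene state as a region-local GeneModel."""
    pieces = []
    exons = []
    introns = []
    pos = 0
    prev = 0
    for i, intron in enumerate(state.introns):
        local = state.local_off(intron.root_off)
        exon = state.cds[prev:local]
        pieces.append(exon)
        exons.append((pos, pos + len(exon)))
        pos += len(exon)
        pieces.append(intron.seq)
        introns.append(IntronRecord(index=i, cds_offset=local, seq=intron.seq))
        pos += len(intron.seq)
        prev = local
    tail = state.cds[prev:]
    pieces.append(tail)
    exons.append((pos, pos + len(tail)))
    return GeneModel(gene_id=f"{species}_{fam_id}", species=species,
                     seq_region=f"{species}_{fam_id}_region", strand="+",
                     cds_exons=exons, cds_seq=state.cds, introns=introns)


def simulate_root_gene(config: SimConfig, rng: Optional[np.random.Generator] = None
                       ) -> GeneModel:
    """Draw one ancestral gene: an ORF with canonical GT..AG root introns."""
    sim = FamilySimulator(config)
    state = sim.simulate_root_state(rng if rng is not None else sim.rng)
    return _state_to_model(state, "root", "fam0000")


def evolve_family(config: SimConfig) -> tuple[dict[str, list[GeneModel]], SimTruth]:
    """Simulate all gene families over the tree; returns leaf models + truth."""
    return FamilySimulator(config).run()


# ---------------------------------------------------------------------------
# dataset emission
# ---------------------------------------------------------------------------

def _gff_lines(gene: GeneModel, species: str) -> list[str]:
    g0 = min(s for s, _ in gene.cds_exons)
    g1 = max(e for _, e in gene.cds_exons)
    gid, tid = gene.gene_id, gene.gene_id + "_t1"
    rows = [
        f"{gene.seq_region}\tintronevo\tgene\t{g0 + 1}\t{g1}\t.\t{gene.strand}\t.\tID={gid}",
        f"{gene.seq_region}\tintronevo\tmRNA\t{g0 + 1}\t{g1}\t.\t{gene.strand}\t.\tID={tid};Parent={gid}",
    ]
    cum = 0
    phased = []
    for s, e in gene.cds_exons:      # transcription order
        phase = (3 - cum % 3) % 3
        phased.append((s, e, phase))
        cum += e - s
    for s, e, phase in sorted(phased):
        rows.append(f"{gene.seq_region}\tintronevo\tCDS\t{s + 1}\t{e}\t.\t"
                    f"{gene.strand}\t{phase}\tParent={tid}")
    return rows


def emit_dataset(models: dict[str, list[GeneModel]], truth: SimTruth,
                 outdir: str) -> dict[str, list[GeneModel]]:
    """Write the dataset files and return the finalised (placed) gene models.

    Per species one chromosome is assembled: random spacer, then each gene
    region (reverse-complemented for minus-strand placements), and so on.
    Reading the emitted FASTA+GFF3 back through ``genomic_io.read_gff_genes``
    reproduces the returned models exactly.
    """
    from .genomic_io import write_fasta, write_newick

    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng((truth.seed + 1) % 2**31)
    placed: dict[str, list[GeneModel]] = {}
    for species in sorted(models):
        genes = models[species]
        chrom_id = f"{species}_chr1"
        parts = []
        pos = 0
        gff_rows = ["##gff-version 3"]
        placed[species] = []
        for gene in genes:
            spacer = _rand_seq(rng, int(rng.integers(150, 401)))
            parts.append(spacer)
            pos += len(spacer)
            region_len = max(e for _, e in gene.cds_exons)
            strand = "+" if rng.random() < 0.5 else "-"
            region = _region_seq(gene)
            if strand == "+":
                exons = [(pos + s, pos + e) for s, e in gene.cds_exons]
                parts.append(region)
            else:
                exons = [(pos + region_len - e, pos + region_len - s)
                         for s, e in gene.cds_exons]
                parts.append(revcomp(region))
            pos += region_len
            new = GeneModel(gene_id=gene.gene_id, species=species,
                            seq_region=chrom_id, strand=strand,
                            cds_exons=exons, cds_seq=gene.cds_seq,
                            introns=[dataclasses.replace(i) for i in gene.introns])
            placed[species].append(new)
            gff_rows.extend(_gff_lines(new, species))
        parts.append(_rand_seq(rng, int(rng.integers(150, 401))))
        write_fasta({chrom_id: "".join(parts)},
                    os.path.join(outdir, f"{species}.genome.fasta"))
        with open(os.path.join(outdir, f"{species}.gff3"), "w") as fh:
            fh.write("\n".join(gff_rows) + "\n")
    write_newick(truth.tree, os.path.join(outdir, "tree.nwk"))
    write_fasta(truth.transposons, os.path.join(outdir, "transposons.fasta"))
    write_fasta({"mito": truth.mito}, os.path.join(outdir, "mito.fasta"))
    with open(os.path.join(outdir, "expression.tsv"), "w") as fh:
        fh.write("gene_id\tfamily\tgermline\n")
        for species in sorted(placed):
            for gene in placed[species]:
                fam = gene.gene_id.split("_", 1)[1]
                fh.write(f"{gene.gene_id}\t{fam}\t{truth.germline[fam]}\n")
    with open(os.path.join(outdir, "truth_events.tsv"), "w") as fh:
        fh.write("family\tcolumn\tbranch\ttype\tmechanism\toffset\tshift\t"
                 "repeat\ttsd\tseq\n")
        for ev in truth.events:
            fh.write(f"{ev.family}\t{ev.column}\t{ev.branch}\t{ev.type}\t"
                     f"{ev.mechanism}\t{ev.offset}\t{ev.shift}\t"
                     f"{ev.repeat or ''}\t{ev.tsd or ''}\t{ev.seq}\n")
    with open(os.path.join(outdir, "truth_leaf_introns.tsv"), "w") as fh:
        fh.write("species\tfamily\tintron_index\tcolumn\torigin\n")
        for (species, fam), rows in sorted(truth.leaf_introns.items()):
            for idx, col, origin in rows:
                fh.write(f"{species}\t{fam}\t{idx}\t{col}\t{origin}\n")
    manifest = {
        "species": sorted(models),
        "outgroup": truth.tree.outgroup,
        "seed": truth.seed,
        "n_genes": truth.config.n_genes,
        "config": dataclasses.asdict(truth.config),
    }
    with open(os.path.join(outdir, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return placed


def _region_seq(gene: GeneModel) -> str:
    """Rebuild the plus-frame genomic region of a region-local gene model."""
    out = []
    for i, (s, e) in enumerate(gene.cds_exons):
        off = sum(b - a for a, b in gene.cds_exons[:i])
        out.append(gene.cds_seq[off:off + (e - s)])
        if i < len(gene.introns):
            out.append(gene.introns[i].seq)
    return "".join(out)
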