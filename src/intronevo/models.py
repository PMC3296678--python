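"""Core domain types: gene models with explicit intron records, and species trees.

Coordinates are 0-based half-open throughout; GFF3's 1-based closed convention
is converted at the parsing boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import dendropy

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def revcomp(seq: str) -> str:
    """Reverse complement (uppercase IUPAC)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class IntronRecord:
    """One intron of a gene, in transcription order.

    ``cds_offset`` is the position in the spliced CDS immediately 3' of the
    intron: the intron sits between ``cds_seq[cds_offset - 1]`` and
    ``cds_seq[cds_offset]``.
    """

    index: int
    cds_offset: int
    seq: str

    @property
    def length_nt(self) -> int:
        return len(self.seq)

    @property
    def donor2(self) -> str:
        return self.seq[:2]

    @property
    def acceptor2(self) -> str:
        return self.seq[-2:]


@dataclass
class GeneModel:
    """A single-transcript protein-coding gene in one species.

    ``cds_exons`` are genomic intervals in transcription order (for minus-strand
    genes the first interval has the highest genomic coordinates). ``cds_seq``
    is spliced and strand-corrected, so it always reads 5'->3' in mRNA sense.
    """

    gene_id: str
    species: str
    seq_region: str
    strand: str
    cds_exons: list[tuple[int, int]]
    cds_seq: str
    introns: list[IntronRecord] = field(default_factory=list)
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.cds_seq) < 3:
            raise ValueError(f"{self.gene_id}: CDS shorter than one codon")
        if len(self.introns) != max(len(self.cds_exons) - 1, 0):
            raise ValueError(
                f"{self.gene_id}: {len(self.introns)} introns but "
                f"{len(self.cds_exons)} exons"
            )
        offsets = [iv.cds_offset for iv in self.introns]
        if offsets != sorted(set(offsets)):
            raise ValueError(f"{self.gene_id}: intron offsets not strictly increasing")
        for iv in self.introns:
            if not 0 < iv.cds_offset < len(self.cds_seq):
                raise ValueError(f"{self.gene_id}: intron offset {iv.cds_offset} outside CDS")

    def validate_against_genome(self, genome_seq: str) -> None:
        """Check that re-splicing the genomic sequence reproduces ``cds_seq``."""
        parts = []
        for start, end in self.cds_exons:
            sub = genome_seq[start:end]
            parts.append(revcomp(sub) if self.strand == "-" else sub)
        if "".join(parts) != self.cds_seq:
            raise ValueError(f"{self.gene_id}: exon concatenation != cds_seq")

    def exon_flanks(self, intron_index: int, width: int = 30) -> tuple[str, str]:
        """Spliced exonic sequence immediately up/downstream of an intron."""
        off = self.introns[intron_index].cds_offset
        return self.cds_seq[max(0, off - width):off], self.cds_seq[off:off + width]


class SpeciesTree:
    """Rooted species tree with uniquely labelled leaves and named internal nodes.

    Internal nodes without labels are assigned stable names (``n1``, ``n2``, ...)
    in preorder; the root is labelled ``root``. Branches are referred to by the
    label of their child node.
    """

    def __init__(self, tree: dendropy.Tree, outgroup: Optional[str] = None):
        self.tree = tree
        self.tree.is_rooted = True
        self._label_nodes()
        leaves = self.leaf_names()
        if len(leaves) != len(set(leaves)):
            raise ValueError("duplicate leaf labels in species tree")
        if outgroup is not None and outgroup not in leaves:
            raise ValueError(f"outgroup {outgroup!r} is not a leaf of the tree")
        self.outgroup = outgroup
        self._by_label = {self.label(n): n for n in self.tree.preorder_node_iter()}
        self._depth = {}
        for node in self.tree.preorder_node_iter():
            parent = node.parent_node
            self._depth[self.label(node)] = (
                0 if parent is None else self._depth[self.label(parent)] + 1)

    # -- construction ------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str, outgroup: Optional[str] = None) -> "SpeciesTree":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True,
                                 rooting="force-rooted")
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise ValueError("species tree contains an unlabelled leaf")
        return cls(tree, outgroup=outgroup)

    def _label_nodes(self) -> None:
        counter = 1
        for node in self.tree.preorder_node_iter():
            if node.is_leaf():
                continue
            if node.parent_node is None:
                if not node.label:
                    node.label = "root"
            elif not node.label:
                node.label = f"n{counter}"
                counter += 1
            else:
                counter += 1

    # -- queries -----------------------------------------------------------
    @staticmethod
    def label(node: dendropy.Node) -> str:
        return node.taxon.label if node.is_leaf() else node.label

    def leaf_names(self) -> list[str]:
        return [l.taxon.label for l in self.tree.leaf_node_iter()]

    def ingroup_names(self) -> list[str]:
        return [s for s in self.leaf_names() if s != self.outgroup]

    def node(self, label: str) -> dendropy.Node:
        return self._by_label[label]

    def mrca(self, leaf_labels: Sequence[str]) -> dendropy.Node:
        labels = sorted(set(leaf_labels))
        node = self._by_label[labels[0]]
        for other in labels[1:]:
            node = self._lca2(node, self._by_label[other])
        return node

    def _lca2(self, a: dendropy.Node, b: dendropy.Node) -> dendropy.Node:
        da, db = self._depth[self.label(a)], self._depth[self.label(b)]
        while da > db:
            a = a.parent_node
            da -= 1
        while db > da:
            b = b.parent_node
            db -= 1
        while a is not b:
            a = a.parent_node
            b = b.parent_node
        return a

    def leaves_below(self, node: dendropy.Node) -> list[str]:
        return [l.taxon.label for l in node.leaf_iter()]

    def edges(self) -> Iterator[tuple[str, str]]:
        """Yield (parent_label, child_label) for every edge."""
        for node in self.tree.preorder_node_iter():
            if node.parent_node is not None:
                yield self.label(node.parent_node), self.label(node)

    def patristic_distance(self, leaf_a: str, leaf_b: str) -> float:
        if leaf_a == leaf_b:
            return 0.0
        pdm = self._pdm()
        ta = self.tree.taxon_namespace.get_taxon(leaf_a)
        tb = self.tree.taxon_namespace.get_taxon(leaf_b)
        return pdm.patristic_distance(ta, tb)

    def _pdm(self):
        if not hasattr(self, "_pdm_cache"):
            self._pdm_cache = self.tree.phylogenetic_distance_matrix()
        return self._pdm_cache

    def distance_to_leaf(self, node_label: str, leaf: str) -> float:
        """Topological proxy distance from a branch (child node) to a leaf.

        Counts edges from the node to the leaf through the tree; used to pick
        the representative gene nearest to an event's branch.
        """
        node = self._by_label[node_label]
        target = self._by_label[leaf]
        anc_node = {self.label(a) for a in self._ancestors(node)}
        steps = 0
        cur = target
        while self.label(cur) not in anc_node and self.label(cur) != node_label:
            cur = cur.parent_node
            steps += 1
        up = 0
        c2 = node
        while self.label(c2) != self.label(cur):
            c2 = c2.parent_node
            up += 1
        return steps + up

    def _ancestors(self, node: dendropy.Node):
        out = [node]
        while node.parent_node is not None:
            node = node.parent_node
            out.append(node)
        return out

    def as_newick(self) -> str:
        s = self.tree.as_string(schema="newick", suppress_rooting=True,
                                unquoted_underscores=True,
                                suppress_internal_node_labels=False)
        return s.strip()
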