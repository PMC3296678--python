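"""Readers and writers for the standard formats the pipeline touches.

FASTA parsing goes through Biopython, GFF3 through gffutils (in-memory DB),
Newick through dendropy. Gene models are assembled with explicit intron
records in transcription order.
"""

from __future__ import annotations

import os
from typing import Optional

import gffutils
from Bio import SeqIO

from .models import GeneModel, IntronRecord, SpeciesTree, revcomp


def read_fasta(path: str) -> dict[str, str]:
    """Read a multi-record FASTA into ``{id: sequence}``.

    Sequences are uppercased and U is normalised to T. Duplicate ids and empty
    files are errors.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper().replace("U", "T")
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_newick(path: str, outgroup: Optional[str] = None) -> SpeciesTree:
    """Read a single rooted Newick tree; multifurcations are preserved."""
    with open(path) as fh:
        return SpeciesTree.from_newick(fh.read(), outgroup=outgroup)


def write_newick(tree: SpeciesTree, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(tree.as_newick() + "\n")


def _transcript_cds(db, mrna) -> list[tuple[int, int, str]]:
    """CDS intervals (0-based half-open) of one transcript, genomic order."""
    out = []
    for cds in db.children(mrna, featuretype="CDS", order_by="start"):
        out.append((cds.start - 1, cds.end, cds.seqid))
    return out


def read_gff_genes(gff_path: str, genome: dict[str, str],
                   species: Optional[str] = None) -> list[GeneModel]:
    """Assemble one GeneModel per gene from GFF3 gene/mRNA/CDS features.

    Multi-isoform genes are reduced to the transcript with the longest total
    CDS (ties broken lexicographically by transcript id). Minus-strand genes
    are strand-corrected so ``cds_seq`` and intron records read in
    transcription order. A CDS length not divisible by 3 is flagged
    (``cds_not_3n``) but the model is retained.
    """
    if species is None:
        species = os.path.basename(gff_path).split(".")[0]
    db = gffutils.create_db(gff_path, ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        best: Optional[tuple[int, str, list[tuple[int, int, str]]]] = None
        for mrna in db.children(gene, featuretype="mRNA", order_by="start"):
            cds = _transcript_cds(db, mrna)
            if not cds:
                continue
            total = sum(e - s for s, e, _ in cds)
            key = (-total, mrna.id)
            if best is None or key < (-best[0], best[1]):
                best = (total, mrna.id, cds)
        if best is None:
            continue
        _, _, cds_iv = best
        seq_region = cds_iv[0][2]
        if seq_region not in genome:
            raise ValueError(
                f"{gene.id}: CDS references absent seq_region {seq_region!r}")
        chrom = genome[seq_region]
        strand = gene.strand
        # genomic order ascending; transcription order flips for minus strand
        iv_genomic = sorted((s, e) for s, e, _ in cds_iv)
        iv_tx = iv_genomic if strand == "+" else iv_genomic[::-1]
        exon_seqs = []
        for s, e in iv_tx:
            sub = chrom[s:e]
            exon_seqs.append(revcomp(sub) if strand == "-" else sub)
        cds_seq = "".join(exon_seqs)
        introns = []
        offset = 0
        for i in range(len(iv_tx) - 1):
            offset += iv_tx[i][1] - iv_tx[i][0]
            if strand == "+":
                gs, ge = iv_tx[i][1], iv_tx[i + 1][0]
                iseq = chrom[gs:ge]
            else:
                gs, ge = iv_tx[i + 1][1], iv_tx[i][0]
                iseq = revcomp(chrom[gs:ge])
            introns.append(IntronRecord(index=i, cds_offset=offset, seq=iseq))
        flags = set()
        if len(cds_seq) % 3 != 0:
            flags.add("cds_not_3n")
        genes.append(GeneModel(
            gene_id=gene.id, species=species, seq_region=seq_region,
            strand=strand, cds_exons=[(s, e) for s, e in iv_tx],
            cds_seq=cds_seq, introns=introns, flags=flags))
    return genes
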