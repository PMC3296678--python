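import textwrap

import pytest

from intronevo.genomic_io import (read_fasta, read_gff_genes, read_newick,
                                  write_fasta)
from intronevo.models import revcomp


def test_read_fasta_normalises_case_and_u(tmp_path):
    p = tmp_path / "a.fasta"
    p.write_text(">a\nacgu\n")
    assert read_fasta(str(p)) == {"a": "ACGT"}


def test_read_fasta_multiple_records(tmp_path):
    p = tmp_path / "b.fasta"
    p.write_text(">a\nAC\n>b\nGT\n")
    assert read_fasta(str(p)) == {"a": "AC", "b": "GT"}


def test_read_fasta_duplicate_id_errors(tmp_path):
    p = tmp_path / "dup.fasta"
    p.write_text(">a\nAC\n>a\nGT\n")
    with pytest.raises(ValueError, match="'a'"):
        read_fasta(str(p))


def test_read_fasta_empty_errors(tmp_path):
    p = tmp_path / "empty.fasta"
    p.write_text("")
    with pytest.raises(ValueError):
        read_fasta(str(p))


def test_fasta_round_trip(tmp_path):
    records = {"x": "ACGT" * 40, "y": "TTTTAAAA"}
    p = tmp_path / "rt.fasta"
    write_fasta(records, str(p))
    assert read_fasta(str(p)) == records


GFF_HEADER = "##gff-version 3\n"


def _write_gff(tmp_path, body):
    p = tmp_path / "genes.gff3"
    p.write_text(GFF_HEADER + textwrap.dedent(body))
    return str(p)


def test_single_exon_gene_has_no_introns(tmp_path):
    genome = {"chr": "AAATGGGTTTAACCC"}
    gff = _write_gff(tmp_path, """\
        chr\tt\tgene\t3\t11\t.\t+\t.\tID=g1
        chr\tt\tmRNA\t3\t11\t.\t+\t.\tID=t1;Parent=g1
        chr\tt\tCDS\t3\t11\t.\t+\t0\tParent=t1
        """)
    genes = read_gff_genes(gff, genome, species="sp")
    assert len(genes) == 1
    assert genes[0].introns == []
    assert genes[0].cds_seq == "ATGGGTTTA"


def test_plus_strand_intron_donor_acceptor(tmp_path):
    # exon1 = ATGAAA, intron = GTCCAG, exon2 = TTTTAA
    genome = {"chr": "ATGAAAGTCCAGTTTTAA"}
    gff = _write_gff(tmp_path, """\
        chr\tt\tgene\t1\t18\t.\t+\t.\tID=g1
        chr\tt\tmRNA\t1\t18\t.\t+\t.\tID=t1;Parent=g1
        chr\tt\tCDS\t1\t6\t.\t+\t0\tParent=t1
        chr\tt\tCDS\t13\t18\t.\t+\t0\tParent=t1
        """)
    gene = read_gff_genes(gff, genome, species="sp")[0]
    assert gene.cds_seq == "ATGAAATTTTAA"
    (iv,) = gene.introns
    assert (iv.donor2, iv.acceptor2) == ("GT", "AG")
    assert iv.cds_offset == 6
    gene.validate_against_genome(genome["chr"])


def test_minus_strand_gene_is_reverse_complemented(tmp_path):
    # A 40 nt toy locus transcribed on the minus strand. In transcription
    # order: exon1 = ATGCCC, intron = GTAAAG (genomic revcomp CTTTAC),
    # exon2 = GGGTAA; worked out by hand below.
    exon1, intron, exon2 = "ATGCCC", "GTAAAG", "GGGTAA"
    plus = "AAAA" + revcomp(exon2) + revcomp(intron) + revcomp(exon1) + "AAAAAA" * 3
    assert len(plus) == 40
    genome = {"chr": plus}
    # genomic coordinates (1-based closed): exon2 at 5..10, exon1 at 17..22
    gff = _write_gff(tmp_path, """\
        chr\tt\tgene\t5\t22\t.\t-\t.\tID=g1
        chr\tt\tmRNA\t5\t22\t.\t-\t.\tID=t1;Parent=g1
        chr\tt\tCDS\t5\t10\t.\t-\t0\tParent=t1
        chr\tt\tCDS\t17\t22\t.\t-\t0\tParent=t1
        """)
    gene = read_gff_genes(gff, genome, species="sp")[0]
    assert gene.strand == "-"
    assert gene.cds_seq == exon1 + exon2
    (iv,) = gene.introns
    assert iv.seq == intron
    assert iv.seq == revcomp(plus[10:16])
    gene.validate_against_genome(genome["chr"])


def test_longest_cds_isoform_wins(tmp_path):
    genome = {"chr": "ATGAAAGTCCAGTTTTAA"}
    gff = _write_gff(tmp_path, """\
        chr\tt\tgene\t1\t18\t.\t+\t.\tID=g1
        chr\tt\tmRNA\t1\t18\t.\t+\t.\tID=tShort;Parent=g1
        chr\tt\tCDS\t1\t6\t.\t+\t0\tParent=tShort
        chr\tt\tmRNA\t1\t18\t.\t+\t.\tID=tLong;Parent=g1
        chr\tt\tCDS\t1\t6\t.\t+\t0\tParent=tLong
        chr\tt\tCDS\t13\t18\t.\t+\t0\tParent=tLong
        """)
    gene = read_gff_genes(gff, genome, species="sp")[0]
    assert gene.cds_seq == "ATGAAATTTTAA"


def test_cds_on_absent_seq_region_errors(tmp_path):
    gff = _write_gff(tmp_path, """\
        nowhere\tt\tgene\t1\t6\t.\t+\t.\tID=g1
        nowhere\tt\tmRNA\t1\t6\t.\t+\t.\tID=t1;Parent=g1
        nowhere\tt\tCDS\t1\t6\t.\t+\t0\tParent=t1
        """)
    with pytest.raises(ValueError, match="nowhere"):
        read_gff_genes(gff, {"chr": "ACGT"}, species="sp")


def test_non_3n_cds_flagged_but_kept(tmp_path):
    genome = {"chr": "ATGAAAGG"}
    gff = _write_gff(tmp_path, """\
        chr\tt\tgene\t1\t8\t.\t+\t.\tID=g1
        chr\tt\tmRNA\t1\t8\t.\t+\t.\tID=t1;Parent=g1
        chr\tt\tCDS\t1\t8\t.\t+\t0\tParent=t1
        """)
    gene = read_gff_genes(gff, genome, species="sp")[0]
    assert "cds_not_3n" in gene.flags


def test_read_newick_counts_and_outgroup(tmp_path):
    p = tmp_path / "t.nwk"
    p.write_text("((A,B),(C,D));\n")
    tree = read_newick(str(p))
    assert sorted(tree.leaf_names()) == ["A", "B", "C", "D"]
    internal = [n for n in tree.tree.preorder_node_iter() if not n.is_leaf()]
    assert len(internal) == 3

    p2 = tmp_path / "t2.nwk"
    p2.write_text("((A,B),C);\n")
    tree2 = read_newick(str(p2), outgroup="C")
    assert tree2.outgroup == "C"


def test_read_newick_preserves_multifurcation(tmp_path):
    p = tmp_path / "t3.nwk"
    p.write_text("(A,B,C);\n")
    tree = read_newick(str(p))
    root = tree.tree.seed_node
    assert len(root.child_nodes()) == 3


def test_simulated_genes_resplice_exactly(small_dataset):
    """Re-splicing the emitted genome by cds_exons reproduces every cds_seq."""
    dataset, _, _ = small_dataset
    from intronevo.genomic_io import read_fasta
    import os
    for sp in dataset.species:
        genome = read_fasta(os.path.join(dataset.root, f"{sp}.genome.fasta"))
        for gene in dataset.models[sp]:
            gene.validate_against_genome(genome[gene.seq_region])
            offsets = [iv.cds_offset for iv in gene.introns]
            assert offsets == sorted(set(offsets))
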