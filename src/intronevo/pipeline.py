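"""End-to-end orchestration: dataset loading, ortholog mapping, event
inference, and mechanism scanning.

The stages mirror the analysis the package automates: all-against-all CDS
comparison and reciprocal-best-hit orthology; marker-bearing progressive
alignment and intron-column mapping with a flank-identity filter; Dollo
parsimony event calling polarised by an outgroup; then per-event signature
scans and cohort-level bias tests.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .align import SimilarityHit, local_align
from .config import PipelineConfig
from .events import (EventCall, IntronPresenceMatrix, MatrixRow, dollo_events,
                     flank_filter, qc_gain_filters, summarize_events)
from .genomic_io import read_fasta, read_gff_genes, read_newick
from .mechanisms import (BiasReport, ResolvedEvent, SignatureHit,
                         adjacent_loss_test, detect_imprecise_loss,
                         detect_sliding, detect_tsd, find_direct_repeats,
                         germline_enrichment, ks_uniform, relative_positions,
                         repeat_flanking_rate, scan_insertion_source,
                         shuffle_null_p)
from .models import GeneModel, SpeciesTree
from .msa import (IntronColumnMap, MarkedAlignment, align_group,
                  insert_markers, map_intron_columns)
from .orthology import OrthologGroup, all_vs_all_hits, reciprocal_best_hits

import yaml


# ---------------------------------------------------------------------------
# dataset
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    root: str
    species: list[str]
    outgroup: Optional[str]
    tree: SpeciesTree
    models: dict[str, list[GeneModel]]
    genes: dict[str, GeneModel]
    transposons: dict[str, str]
    mito: dict[str, str]
    germline: dict[str, int]           # gene_id -> 0/1 (may be empty)


def load_dataset(root: str) -> Dataset:
    with open(os.path.join(root, "manifest.yaml")) as fh:
        manifest = yaml.safe_load(fh)
    species = manifest["species"]
    outgroup = manifest.get("outgroup")
    tree = read_newick(os.path.join(root, "tree.nwk"), outgroup=outgroup)
    models: dict[str, list[GeneModel]] = {}
    genes: dict[str, GeneModel] = {}
    for sp in species:
        genome = read_fasta(os.path.join(root, f"{sp}.genome.fasta"))
        models[sp] = read_gff_genes(os.path.join(root, f"{sp}.gff3"), genome,
                                    species=sp)
        for g in models[sp]:
            genes[g.gene_id] = g
    transposons = {}
    te_path = os.path.join(root, "transposons.fasta")
    if os.path.exists(te_path):
        transposons = read_fasta(te_path)
    mito = {}
    mito_path = os.path.join(root, "mito.fasta")
    if os.path.exists(mito_path):
        mito = read_fasta(mito_path)
    germline: dict[str, int] = {}
    expr_path = os.path.join(root, "expression.tsv")
    if os.path.exists(expr_path):
        expr = pd.read_csv(expr_path, sep="\t")
        germline = dict(zip(expr["gene_id"], expr["germline"].astype(int)))
    return Dataset(root=root, species=species, outgroup=outgroup, tree=tree,
                   models=models, genes=genes, transposons=transposons,
                   mito=mito, germline=germline)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

@dataclass
class GroupData:
    group: OrthologGroup
    aln: MarkedAlignment
    colmap: IntronColumnMap
    kept: list[str]                     # class ids passing the flank filter
    outgroup_gene: Optional[str] = None


@dataclass
class Inference:
    groups: list[OrthologGroup]
    data: dict[str, GroupData]
    matrix: IntronPresenceMatrix
    calls: list[EventCall]
    summary: pd.DataFrame = field(default_factory=pd.DataFrame)

    def accepted(self) -> list[EventCall]:
        return [c for c in self.calls if c.status == "accepted"]


def _attach_outgroup(group: OrthologGroup,
                     hits: dict[tuple[str, str], SimilarityHit],
                     species_of: dict[str, str], outgroup: str,
                     cfg: PipelineConfig) -> Optional[str]:
    """Best reciprocal outgroup ortholog of a group, at looser thresholds."""
    rep = sorted(group.members.values())[0]
    best: Optional[SimilarityHit] = None
    for (q, t), h in hits.items():
        if q == rep and species_of[t] == outgroup:
            if best is None or h.score > best.score:
                best = h
    if best is None:
        return None
    back_best: Optional[SimilarityHit] = None
    for (q, t), h in hits.items():
        if q == best.target_id and species_of[t] == species_of[rep]:
            if back_best is None or h.score > back_best.score:
                back_best = h
    if back_best is None or back_best.target_id != rep:
        return None
    if (best.identity_pct < cfg.outgroup_min_identity
            or best.query_coverage_pct < cfg.outgroup_min_coverage):
        return None
    return best.target_id


def infer_events(dataset: Dataset, cfg: PipelineConfig) -> Inference:
    tree = dataset.tree
    outgroup = dataset.outgroup
    cds = {g.gene_id: g.cds_seq for g in dataset.genes.values()}
    species_of = {g.gene_id: g.species for g in dataset.genes.values()}
    hits = all_vs_all_hits(cds, species_of)
    ingroup_hits = {k: v for k, v in hits.items()
                    if outgroup not in (species_of[k[0]], species_of[k[1]])}
    groups = reciprocal_best_hits(ingroup_hits, species_of,
                                  min_identity=cfg.rbh_min_identity,
                                  min_coverage=cfg.rbh_min_coverage,
                                  max_e=cfg.rbh_max_e)
    data: dict[str, GroupData] = {}
    matrix = IntronPresenceMatrix()
    calls: list[EventCall] = []
    ingroup_species = tree.ingroup_names()
    for group in groups:
        og_gene = None
        if outgroup is not None:
            og_gene = _attach_outgroup(group, hits, species_of, outgroup, cfg)
        marked = {sp: insert_markers(dataset.genes[gid], cfg.marker_len)
                  for sp, gid in group.members.items()}
        if og_gene is not None:
            marked[outgroup] = insert_markers(dataset.genes[og_gene],
                                              cfg.marker_len)
        aln = align_group(marked)
        colmap = map_intron_columns(aln, cfg.max_offset_cols)
        kept = []
        for col in colmap.columns:
            if not flank_filter(aln, col, cfg.flank_window,
                                cfg.flank_min_identity):
                continue
            kept.append(col.class_id)
            states: dict[str, Optional[int]] = {}
            members = {sp for sp, _ in col.members}
            for sp in ingroup_species:
                if sp in group.members:
                    states[sp] = 1 if sp in members else 0
                else:
                    states[sp] = None
            og_state = None
            if og_gene is not None:
                og_state = 1 if outgroup in members else 0
            matrix.rows.append(MatrixRow(
                group_id=group.group_id, class_id=col.class_id,
                column=col.column, states=states, outgroup_state=og_state))
        data[group.group_id] = GroupData(group=group, aln=aln, colmap=colmap,
                                         kept=kept, outgroup_gene=og_gene)
    raw_calls = dollo_events(matrix, tree)
    for call in raw_calls:
        if call.type == "gain" and len(call.leaves) == 1:
            gene, idx = _class_member(dataset, data[call.group_id],
                                      call.class_id, call.leaves[0])
            if gene is not None:
                call = qc_gain_filters(call, gene.introns[idx], gene,
                                       canonical_splice=cfg.splice_set())
        calls.append(call)
    summary = summarize_events(calls, tree)
    return Inference(groups=groups, data=data, matrix=matrix, calls=calls,
                     summary=summary)


def _class_member(dataset: Dataset, gd: GroupData, class_id: str,
                  species: str) -> tuple[Optional[GeneModel], int]:
    for col in gd.colmap.columns:
        if col.class_id != class_id:
            continue
        for sp, idx in col.members:
            if sp == species:
                return dataset.genes[gd.group.members[sp]], idx
    return None, -1


def resolve_event(dataset: Dataset, gd: GroupData, call: EventCall,
                  tree: SpeciesTree) -> Optional[ResolvedEvent]:
    """Representative member gene for an event: the species carrying the
    intron that is nearest (fewest edges) to the event's branch."""
    col = next(c for c in gd.colmap.columns if c.class_id == call.class_id)
    carriers = sorted({sp for sp, _ in col.members}
                      - ({tree.outgroup} if tree.outgroup else set()))
    if not carriers:
        return None
    ref = f"{call.group_id}:{call.class_id}:{call.type}:{call.branch}"
    sp = min(carriers, key=lambda s: (tree.distance_to_leaf(call.branch, s), s))
    gene, idx = _class_member(dataset, gd, call.class_id, sp)
    return ResolvedEvent(event_ref=ref, type=call.type, gene=gene,
                         intron_index=idx)


# ---------------------------------------------------------------------------
# mechanism scan
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    bias_reports: dict[str, BiasReport]
    verdicts: pd.DataFrame
    hits: list[SignatureHit]
    sliding: list[SignatureHit]
    skipped: list[str] = field(default_factory=list)


def run_scan(dataset: Dataset, inference: Inference, cfg: PipelineConfig) -> ScanResult:
    tree = dataset.tree
    accepted = inference.accepted()
    gains = [c for c in accepted if c.type == "gain"]
    losses = [c for c in accepted if c.type == "loss"]
    reports: dict[str, BiasReport] = {}
    skipped: list[str] = []

    resolved: dict[str, tuple[EventCall, ResolvedEvent]] = {}
    for call in accepted:
        r = resolve_event(dataset, inference.data[call.group_id], call, tree)
        if r is not None:
            resolved[r.event_ref] = (call, r)

    # positional biases
    for name, subset in (("gain_positions", gains), ("loss_positions", losses)):
        pos = relative_positions([resolved[_ref(c)][1] for c in subset
                                  if _ref(c) in resolved])
        if len(pos) >= 5:
            reports[name] = ks_uniform(pos)
        else:
            skipped.append(f"{name}: insufficient events (n={len(pos)})")

    # germline enrichment (families with events vs all families)
    if dataset.germline:
        germ_of_group = {}
        for gid, gd in inference.data.items():
            flags = [dataset.germline.get(g) for g in gd.group.members.values()
                     if g in dataset.germline]
            if flags:
                germ_of_group[gid] = flags[0]
        bg_total = len(germ_of_group)
        bg_germ = sum(germ_of_group.values())
        for name, subset in (("germline_gain", gains), ("germline_loss", losses)):
            fams = sorted({c.group_id for c in subset if c.group_id in germ_of_group})
            if fams and 0 < bg_germ < bg_total:
                reports[name] = germline_enrichment(
                    sum(germ_of_group[f] for f in fams), len(fams),
                    bg_germ, bg_total)
            else:
                skipped.append(f"{name}: no events or degenerate background")
    else:
        skipped.append("germline tests: no expression table")

    # adjacent losses
    loss_pos: dict[tuple[str, str], list[int]] = {}
    intron_counts: dict[str, int] = {}
    for gid, gd in inference.data.items():
        intron_counts[gid] = len(gd.kept)
    kept_rank = {(gid, cid): i for gid, gd in inference.data.items()
                 for i, cid in enumerate(gd.kept)}
    for c in losses:
        key = (c.group_id, c.branch)
        loss_pos.setdefault(key, []).append(kept_rank[(c.group_id, c.class_id)])
    if loss_pos:
        reports["adjacent_loss"] = adjacent_loss_test(
            loss_pos, intron_counts, n_perm=cfg.adjacent_n_perm, seed=cfg.seed)
    else:
        skipped.append("adjacent_loss: no losses")

    # per-event verdicts
    rows = []
    hits_all: list[SignatureHit] = []
    for i, call in enumerate(accepted):
        ref = _ref(call)
        if ref not in resolved:
            continue
        _, r = resolved[ref]
        row = {"event": ref, "group": call.group_id, "class": call.class_id,
               "type": call.type, "branch": call.branch,
               "species": ";".join(call.leaves), "verdict": "unknown",
               "partner": "", "identity_pct": np.nan, "coverage_pct": np.nan,
               "e_value": np.nan, "shuffle_p": np.nan, "repeat": "", "tsd": ""}
        if call.type == "gain":
            intron = r.gene.introns[r.intron_index]
            up, down = r.gene.exon_flanks(r.intron_index, cfg.repeat_window)
            verdict_hit = None
            if len(intron.seq) >= 20 and dataset.transposons:
                te_hits = scan_insertion_source(
                    intron.seq, dataset.transposons, "transposon", ref,
                    cfg.scan_min_coverage, cfg.scan_max_e,
                    cfg.scan_min_identity)
                if te_hits:
                    verdict_hit = te_hits[0]
                    verdict_hit.tsd = detect_tsd(up, intron.seq, down,
                                                 cfg.tsd_min_len,
                                                 cfg.tsd_max_len,
                                                 cfg.tsd_max_mismatch)
            if verdict_hit is None and len(intron.seq) >= 20 and dataset.mito:
                mt_hits = scan_insertion_source(
                    intron.seq, dataset.mito, "mito_dsbr", ref,
                    cfg.scan_min_coverage, cfg.scan_max_e,
                    cfg.scan_min_identity)
                if mt_hits:
                    verdict_hit = mt_hits[0]
                    # shuffle against the matched segment (padded), i.e. the
                    # two sequences of the reported alignment
                    target = dataset.mito[verdict_hit.partner]
                    t0, t1 = verdict_hit.target_span
                    pad = len(intron.seq)
                    segment = target[max(0, t0 - pad):t1 + pad]
                    q = intron.seq if verdict_hit.strand == "+" else \
                        _rc(intron.seq)
                    verdict_hit.shuffle_p = shuffle_null_p(
                        q, segment, cfg.n_shuffles,
                        seed=(cfg.seed + 17 * i) % 2**31)
            repeats = find_direct_repeats(up, intron.seq, down,
                                          cfg.repeat_min_len, cfg.repeat_window)
            if repeats:
                row["repeat"] = repeats[0].seq
            if verdict_hit is not None:
                hits_all.append(verdict_hit)
                row.update(verdict=verdict_hit.mechanism,
                           partner=verdict_hit.partner,
                           identity_pct=verdict_hit.identity_pct,
                           coverage_pct=verdict_hit.coverage_pct,
                           e_value=verdict_hit.e_value,
                           shuffle_p=verdict_hit.shuffle_p,
                           tsd=verdict_hit.tsd or "")
        else:  # loss
            gd = inference.data[call.group_id]
            col = next(c for c in gd.colmap.columns
                       if c.class_id == call.class_id)
            donor_sp = r.gene.species
            for loser in call.leaves:
                if loser not in gd.aln.rows:
                    continue
                donor_intron = r.gene.introns[r.intron_index]
                up, down = r.gene.exon_flanks(r.intron_index, cfg.repeat_window)
                hit = detect_imprecise_loss(
                    ref, gd.aln, col.span, loser, donor_sp, donor_intron.seq,
                    donor_flanks=(up, down), max_e=cfg.scan_max_e)
                if hit is not None:
                    hits_all.append(hit)
                    row.update(verdict="nhej_loss", partner=donor_sp,
                               identity_pct=hit.identity_pct,
                               coverage_pct=hit.coverage_pct,
                               e_value=hit.e_value, repeat=hit.repeat or "")
                    break
            else:
                row["verdict"] = "precise_loss"
        rows.append(row)
    verdicts = pd.DataFrame(rows)

    # sliding scan per group
    sliding: list[SignatureHit] = []
    for gid, gd in sorted(inference.data.items()):
        seq_of = {}
        for col in gd.colmap.columns:
            for sp, idx in col.members:
                gene_id = gd.group.members.get(sp)
                if gene_id is None and sp == dataset.outgroup:
                    gene_id = gd.outgroup_gene
                if gene_id is not None:
                    seq_of[(sp, idx)] = dataset.genes[gene_id].introns[idx].seq
        for h in detect_sliding(gd.colmap, seq_of, cfg.sliding_min_shift,
                                cfg.sliding_max_shift, cfg.sliding_max_e,
                                event_ref=gid):
            sliding.append(h)

    return ScanResult(bias_reports=reports, verdicts=verdicts, hits=hits_all,
                      sliding=sliding, skipped=skipped)


def _ref(call: EventCall) -> str:
    return f"{call.group_id}:{call.class_id}:{call.type}:{call.branch}"


def _rc(seq: str) -> str:
    from .models import revcomp
    return revcomp(seq)
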