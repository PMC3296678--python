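"""Ortholog detection by reciprocal best hits over all-against-all CDS
comparisons.

The all-vs-all stage seeds candidate pairs with a shared-6/8-mer prescreen
(as seeded search tools do) and scores candidates with the in-repo
Smith-Waterman; pairs are kept only when each gene is the other's unique
best hit in the partner species and both directions clear the identity,
coverage and e-value thresholds. Groups are connected components of kept
pairs; any component holding two genes of one species is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import SimilarityHit, local_align

RBH_MIN_IDENTITY = 70.0
RBH_MIN_COVERAGE = 80.0
RBH_MAX_E = 1e-30


@dataclass
class OrthologGroup:
    group_id: str
    members: dict[str, str]          # species -> gene_id


def _kmers(seq: str, k: int = 8) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def all_vs_all_hits(cds: dict[str, str], species_of: dict[str, str],
                    scoring: dict | None = None,
                    prescreen_jaccard: float = 0.05) -> dict[tuple[str, str], SimilarityHit]:
    """Directed similarity hits between genes of different species.

    For every unordered candidate pair (shared 8-mer Jaccard above the
    prescreen threshold) one Smith-Waterman alignment is computed; score and
    identity are direction-symmetric, coverage and e-value are derived per
    direction.
    """
    ids = sorted(cds)
    kmer = {g: _kmers(cds[g]) for g in ids}
    hits: dict[tuple[str, str], SimilarityHit] = {}
    for i, qa in enumerate(ids):
        for qb in ids[i + 1:]:
            if species_of[qa] == species_of[qb]:
                continue
            inter = len(kmer[qa] & kmer[qb])
            if not inter:
                continue
            union = len(kmer[qa] | kmer[qb])
            if inter / union < prescreen_jaccard:
                continue
            hit = local_align(cds[qa], cds[qb], scoring,
                              query_id=qa, target_id=qb)
            back = SimilarityHit(
                query_id=qb, target_id=qa, score=hit.score,
                identity_pct=hit.identity_pct,
                query_coverage_pct=100.0 * (hit.target_span[1] - hit.target_span[0])
                / len(cds[qb]),
                e_value=hit.e_value,
                query_span=hit.target_span, target_span=hit.query_span)
            hits[(qa, qb)] = hit
            hits[(qb, qa)] = back
    return hits


def reciprocal_best_hits(all_hits: dict[tuple[str, str], SimilarityHit],
                         species_of: dict[str, str],
                         min_identity: float = RBH_MIN_IDENTITY,
                         min_coverage: float = RBH_MIN_COVERAGE,
                         max_e: float = RBH_MAX_E) -> list[OrthologGroup]:
    """Form ortholog groups from reciprocal unique best hits."""
    # best hit of each gene within each partner species (None on score tie)
    best: dict[tuple[str, str], str | None] = {}
    score_at: dict[tuple[str, str], int] = {}
    for (q, t), hit in all_hits.items():
        key = (q, species_of[t])
        if key not in score_at or hit.score > score_at[key]:
            score_at[key] = hit.score
            best[key] = t
        elif hit.score == score_at[key] and best[key] != t:
            best[key] = None            # tied best: not unique
    def passes(q: str, t: str) -> bool:
        hit = all_hits[(q, t)]
        return (hit.identity_pct >= min_identity
                and hit.query_coverage_pct >= min_coverage
                and hit.e_value <= max_e)

    kept: set[tuple[str, str]] = set()
    for (q, sp_t), t in best.items():
        if t is None or q > t:
            continue
        if best.get((t, species_of[q])) != q:
            continue
        if passes(q, t) and passes(t, q):
            kept.add((q, t))
    # connected components
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for q, t in kept:
        parent[find(q)] = find(t)
    comps: dict[str, list[str]] = {}
    for g in parent:
        comps.setdefault(find(g), []).append(g)
    groups: list[OrthologGroup] = []
    for members in sorted(comps.values(), key=lambda m: sorted(m)[0]):
        sp_seen = [species_of[g] for g in members]
        if len(sp_seen) != len(set(sp_seen)):
            continue                     # in-species duplicate: discard
        if len(members) < 2:
            continue
        groups.append(OrthologGroup(
            group_id=f"og{len(groups) + 1:04d}",
            members={species_of[g]: g for g in sorted(members)}))
    return groups
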