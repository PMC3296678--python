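# Methods

## Scope and model

`intronevo` infers spliceosomal intron gains and losses among orthologous
protein-coding genes on a rooted species tree and attributes events to
molecular mechanisms. The character model is Dollo parsimony on intron
presence/absence at homologous positions: a given intron position arises
exactly once in the history of a gene family and may be lost any number of
times. This is appropriate because the joint probability of two
independent insertions creating an intron at the same coding position with
the same phase is negligible on the timescales considered, whereas losses
(precise deletion via cDNA recombination, genomic deletion) recur readily.

The pipeline assumes: one analysed transcript per gene (for multi-isoform
annotations, the longest CDS is used, ties broken by transcript id);
introns bounded by GT..AG unless configured otherwise; an outgroup species
that diverged before the ingroup radiation and whose intron complement is
informative about the root state.

## Alignment machinery

Local alignment is an affine-gap Smith–Waterman (numba-compiled): match
+5, mismatch −4, gap open 12, gap extend 2 per gapped position; ambiguity
codes never count as matches. Significance uses the extreme-value law
P(S ≥ x) = 1 − exp(−K·m·n·e^(−λx)). λ = 0.12398 and K = 0.02011 were
fitted once by maximum likelihood (Gumbel fit) to the optimal local scores
of 10,000 independent random pairs of length 200 under this scoring;
`intronevo.align.fit_karlin_altschul` reproduces the fit. The fit is an
empirical calibration of the gapped-alignment null at the length scales
the pipeline uses; no edge-length correction is applied, so e-values for
very short queries (< ~15 nt) are conservative to a factor of order one.

Ortholog groups come from reciprocal unique best hits (e ≤ 1e−30,
identity ≥ 70 %, query coverage ≥ 80 %), formed into connected components;
components containing two genes of one species are discarded. An
all-vs-all comparison is seeded by a shared-8-mer prescreen (Jaccard ≥
0.05), the standard seeded-search shortcut; orthologs at the identity
levels the thresholds demand always share abundant 8-mers.

### Marker-bearing multiple alignment

Intron positions are made alignable by splicing a 30-character `X` block
into the CDS at each intron offset. Groups are aligned progressively
(UPGMA guide tree on 6-mer Jaccard distances; profile–profile merges with
a state-aware affine traceback). Scoring: nucleotide match +5, transition
−3, transversion −4 (the transition-weight idea of classic progressive
aligners), N neutral, X vs nucleotide −20, X or anything vs an existing
gap 0, new gaps 30 to open and free to extend (the high-open/zero-extend
spirit of the original protocol; a separation penalty is approximated by
the high opening charge, which already disfavours scattered gaps).

The X/X bonus is +1.6, a deliberate calibration: stacking two 30-long
marker blocks gains 30·b while forfeiting 5 per nucleotide of offset
between the true positions, so the stacking threshold in nucleotides is
6·b. At b = 1.6 blocks stack only when their positions differ by < 9.6 nt,
matching the 10-column window used downstream to merge block starts into
one intron-position class. A much larger bonus would fuse non-homologous
positions up to tens of nucleotides apart and make intron sliding
undetectable.

Classes are single-linkage clusters of block start columns within 10
columns. The flank filter keeps a class only if the mean pairwise identity
over the nearest 15 *comparable* columns (≥ 2 unambiguous bases) on each
side is ≥ 0.8 (inclusive); walking outward over comparable columns rather
than a fixed window prevents the gap scar of an imprecise loss from
consuming the window. Fewer than 5 comparable columns on a side fails the
filter. This automates what was historically a manual alignment
inspection; window and threshold are config keys.

## Event calling

Each class yields a row of present/absent/missing states over the ingroup
(missing = species absent from the group, treated as uninformative — the
conservative choice). Rows where the two candidate reconstructions (gain
on the edge into the MRCA of present leaves versus presence at the
ingroup root) tie in event count cannot be polarised internally and
require a non-missing outgroup state; without one the row is excluded,
mirroring the exclusion of alignments lacking an outgroup ortholog.
Reconstruction: outgroup present ⇒ the intron is ancestral and only
losses are called; otherwise one gain on the edge into the MRCA of the
present leaves. Losses are the edges into maximal subtrees whose
informative leaves are all absent — the unique minimal explanation under
single-gain Dollo (verified exhaustively against brute-force minimisation
for every rooted binary topology with ≤ 6 leaves and every state vector).

QC for single-species gains: reject if length ≡ 0 (mod 3) with no stop
codon fully inside the intron in the host reading frame (the signature of
a mis-annotated exon segment rather than a real intron), or if the splice
dinucleotides are not GT..AG (the canonical set is configurable, e.g. to
admit GC–AG). Ancestral gains and all losses are exempt.

## Mechanism attribution

* **Transposon insertion**: the gained intron aligns to a library element
  at coverage ≥ 90 % and e ≤ 0.1; a target site duplication (TSD) is
  sought as the intron's 5′ prefix (4–15 nt) recurring within 15 nt of the
  3′ junction with ≤ 1 mismatch.
* **DSBR/mitochondrial filler**: same thresholds against the
  mitochondrial genome, both strands; the best hit is validated by
  shuffling the query 1000 times (mononucleotide permutation, preserving
  composition; a dinucleotide shuffle is not implemented because the
  detection targets planted near-identity, not composition artefacts) and
  realigning against the matched segment; p = (1 + #{score ≥ observed}) /
  (n + 1).
* Both scans additionally require identity ≥ 60 %: under these permissive
  gap costs, random intron-vs-library pairs occasionally reach e ≈ 0.004
  through long ~54 %-identity alignments, and the floor removes such
  chance attributions without affecting recall of genuine insertions,
  which align near-identically.
* **NHEJ imprecise loss**: nucleotides of the losing species aligned
  opposite the donor's marker block or gaps (±20 columns) are extracted;
  ≥ 6 residues aligning to the donor's intron at e ≤ 0.1 constitute a
  scar. Junction direct repeats (≥ 5 bp within 30 nt of either junction)
  are reported as microhomology evidence.
* **RTMIL biases** (no direct scar exists): KS uniformity of relative
  positions (cds_offset / cds_length of the member gene topologically
  closest to the event branch, alphabetical tie-break), Pearson χ² (2×2,
  no continuity correction) of germline expression in event families
  versus all families, and the adjacent-loss excess: observed pairs of
  losses at consecutive positions on one branch of one gene versus the
  mean under within-gene uniform redistribution (10,000 permutations),
  scored by a df = 1 goodness-of-fit χ².
* **Intron sliding**: pairs of classes 10–100 columns apart with disjoint
  species sets whose intron sequences align at e ≤ 0.1; the reported shift
  subtracts the 30-column marker block when the blocks are disjoint, so it
  is in nucleotides of displacement.

## The simulator

`synthetic_evolution` draws a random rooted bifurcating ingroup (branch
lengths U(0.4, 1.2)) plus a basal outgroup (branch length 3), and one
ancestral gene per family: a random ORF of 120–300 codons with 2–6 introns
(lognormal lengths, median ≈ 350 nt, clipped to [61, 2000]). Events per
branch are Poisson(rate × branch length). Gains insert, at an offset ≥ 15
nt from every position the family has ever used (so each event founds its
own column): a transposon with a duplicated GT-initial target site
(element 200–800 nt, TSD 8 nt, copy within the intron's 3′ terminus); a
mitochondrial slice (~113 ± 8 nt, from a simulated 16-kb 80 %-AT
mitochondrial genome, either strand), optionally preceded by a direct
repeat copied from the upstream exon terminus (probability 0.3, length
5–7); or a plain random intron. Gains that would be 3n and stop-free in
frame get one extra base before the acceptor, because a real novel intron
indistinguishable from an annotation error would be (correctly) removed by
QC and is not a useful planted signal. Losses are precise or imprecise;
imprecise losses leave the intron's first k ∈ {15, 18, 21} nucleotides in
the CDS (frame-preserving; intron heads are generated stop-free in all
frames, and a loss that would still create an ORF-breaking junction codon
falls back to precise). Residues shorter than ~12 nt cannot reach e ≤ 0.1
against a donor intron under the fitted statistics, so the scar lengths
are chosen to be detectable at the pipeline's own threshold. Substitutions
(per-site probability rate × branch length) follow events and never touch
splice dinucleotides or start/stop codons. The outgroup branch carries no
events: the outgroup's role is to polarise the root state, and events
there would be unidentifiable in principle. Germline flags are drawn per
family (0.66 with ≥ 1 event, 0.52 otherwise, echoing the enrichment levels
the published counts imply).

With `allow_homoplasy=False` the simulator restricts events to histories
any parsimony method can recover exactly: each column is lost at most once
tree-wide, only ancestral (root) introns are lost, and the ingroup-root
edge carries no losses. Exact-recovery validation uses this mode, because
two independent losses of one column are indistinguishable from a single
ancestral loss — a limit of parsimony, not of the implementation. The
default (homoplasy allowed) is the realistic condition.

What the simulator does **not** emulate: alternative splicing, real codon
usage and amino-acid conservation, indel evolution in exons (the only
exonic length changes are NHEJ scars), transposon families with internal
structure (LTRs, ORFs), intron gain by tandem duplication/intronization/
intron transfer, and real expression measurements (germline labels are
synthetic flags). Passing recovery tests therefore demonstrates
correctness of the inference machinery under known ground truth, not
performance on diverged real genomes, where alignment ambiguity and
annotation error dominate.

## Numerical and design choices

* Coordinates are 0-based half-open internally; GFF3 conversion happens at
  the parser boundary. Minus-strand genes are strand-corrected at load.
* Progressive-alignment ties break deterministically (diagonal preferred;
  species sorted lexicographically); all randomness flows from explicit
  seeds, and a dataset is byte-identical under a fixed seed.
* Column-class merge ambiguities resolve by nearest start, ties leftmost.
* Degenerate inputs: sequences of only ambiguity codes score 0; empty
  event sets produce valid empty outputs; the KS test refuses n < 5; the
  shuffle null refuses n = 0; a zero-margin 2×2 table is an error.
* Problem sizes in the validation suite (50 genes × 8 taxa for recovery,
  30 genes for attribution, 500 replicates for null calibration, all
  rooted trees ≤ 6 leaves for the Dollo oracle) were chosen as the
  smallest sets that exercise every code path with comfortable event
  counts (≥ 100 events, ≥ 10 per mechanism).

## Known limitations

* E-values ignore length-dependent edge corrections; for queries under
  ~15 nt they are only accurate to a factor of order one.
* The flank filter depends on alignment quality; at substitution levels
  far above ~0.1/site, columns of genuinely homologous introns start to be
  discarded (by design — the original protocol did the same).
* Dollo parsimony under-counts events when losses are homoplastic, and
  places a gain too shallow when later losses empty one side of the true
  gain node; both are inherent to parsimony.
* The germline χ² treats families as exchangeable; phylogenetic
  non-independence of gene families is ignored, as in the original
  analysis.
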