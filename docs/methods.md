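# Methods

Models, algorithms, parameter defaults and limitations, per module.
Internal coordinates are 0-based half-open everywhere; file formats (GFF3,
feature tables, BLAST-6, SSR reports) use their conventional 1-based
inclusive coordinates. All randomness is `numpy.random.default_rng` seeded
explicitly; generators fan a global seed out to fixed per-generator stream
offsets, so every artifact is a pure function of (specification, seed).

## Data model (`plastokit.model`)

Sequences are uppercase A/C/G/T/N strings; ambiguity codes other than N are
rejected so GC and codon arithmetic stay exact. `GenomeInterval` may wrap
the circular origin (`wraps_origin`, stored with `end < start`), which keeps
region sizes summing exactly to the genome length on any rotation.
`RegionPartition` validates the quadripartite layout: regions disjoint,
lengths summing to the genome, and |IRb| = |IRa|. GC content is computed
over unambiguous bases only (N excluded from numerator and denominator).

## IR detection and canonicalization (`plastokit.structure`)

`detect_inverted_repeat` seeds exact `k`-mer matches (default `seed_k=21`)
between the doubled sequence and its reverse complement, then extends each
seed outward without gaps. Extension tolerates at most 25 consecutive
mismatches and trims each arm back to the longest extent that ends on a
match with an overall mismatch fraction ≤ `max_mismatch_rate` (default
0.005). Candidate arm pairs are deduplicated per antidiagonal; the longest
candidate wins, ties broken by the smallest normalized start. The shorter
gap between the two arms is called the SSC. Arms below `min_ir_len`
(default 50) raise `NoQuadripartiteStructure`. Detection is rotation
invariant by construction (the sequence is doubled).

`canonicalize` rotates the genome so the LSC starts at position 0 with the
layout LSC→IRb→SSC→IRa, then chooses between this rotation and the
equivalent rotation of the flipped (reverse-complemented) molecule by
taking the lexicographically smaller sequence. This convention makes
canonicalization idempotent and invariant to both rotation and flip; the
two flip-flop isoforms of one molecule therefore canonicalize to the same
representative. Features are remapped so that extracted gene sequences are
unchanged.

`partition_stats` paints every base with a single class (priority: exon
over intron over intergenic; protein over tRNA over rRNA where exons of
different genes overlap). Gaps up to 10 kb between consecutive same-strand
exons of one gene copy are classed as intron. IR copies of a gene share a
name and count once in gene tallies. Percentages round half away from
zero to 1 decimal.

## Codon usage (`plastokit.codons`)

Codon counting is frame-0 over annotated CDS sequences and includes the
terminal stop codon, so the three stop codons form one three-member
synonymous family and their total equals the number of CDS counted. CDS
with internal in-frame stops are rejected by name (pseudogene candidates)
unless explicitly allowed; lengths must be divisible by 3.

RSCU(c) = count(c) / mean(count over the synonymous family of c). A family
with zero total is reported as RSCU 0 (the statistic is undefined there);
within-amino-acid frequency is NaN in that case. All published-value
comparisons use rounding half away from zero (`round_half_up`, implemented
with `decimal` on the shortest repr, not float banker's rounding).

Anticodon/codon recognition is strict Watson–Crick: an anticodon recognizes
exactly the codon equal to its reverse complement; wobble and modified
bases are not modeled (a documented simplification — the real decoding set
of a plastid tRNA is larger). When counts are supplied, the overlap between
recognized codons and each family's most-common codon is reported,
excluding single-codon families (ATG, TGG) for which "most common" is
vacuous.

## Tandem repeats (`plastokit.repeats`)

Maximal perfect tandem runs are found per unit length: a run starts where
it cannot be extended left, requires the motif to be primitive (not itself
a repetition), and extends while `seq[x] == seq[x-u]`. Microsatellites use
per-unit minimum full-copy thresholds (10, 5, 4, 3, 3, 3 for units 1–6 bp);
minisatellites use units 10–60 bp with ≥ 2.0 (fractional) copies.
Overlapping runs are resolved greedily — longest array first, then smallest
start, then smallest unit — so no reported loci overlap and output is
deterministic. The canonical motif of a locus is the lexicographic minimum
over all rotations of the motif and of its reverse complement.

Loci are labelled with their region; junction-spanning loci are flagged and
assigned by midpoint. `dedup_ir` counts IR-duplicated loci once by dropping
each IRa locus whose reverse-complement twin sits at the mirrored offset in
IRb (canonical orientation required). Scanning is linear and does not cross
the circular origin; a repeat spanning the origin of the chosen rotation is
a known blind spot, avoided in practice by canonicalizing first (the origin
then falls at the LSC start).

## SSC-orientation isoforms (`plastokit.orientation`)

Mate pairs are informative for the flip-flop state only when one mate lies
wholly in the LSC and the other wholly in the SSC. Filters, in order:
multi-mapping, identity < 90%, aligned fraction < 0.6, any mate inside an
IR or straddling a junction while touching an IR (placement ambiguous under
the duplication), any other junction straddler, then the LSC/SSC region
requirement. The class string orders the LSC mate's strand first (FR, RF,
FF, RR), making the labels symmetric in mate order; FR+RF support form A
(the reference orientation), FF+RR support form B. The form-B fraction gets
an exact Clopper–Pearson binomial interval (default level 0.95); the
verdict is `two_forms` when both forms have ≥ `min_support` (default 3)
pairs. `relabel_reference_form` re-expresses a classification on the
form-B reference by swapping FR↔FF and RF↔RR (an involution). Insert-size
information is not used; only orientation carries signal here.

## Nuclear plastid insertions (`plastokit.nupt`)

The query is the plastome with one IR copy removed (LSC+IRb+SSC, canonical
orientation required; double stripping is rejected by a length check), so
IR-derived insertions are not double-counted. Hits come either from the
internal aligner or from a BLAST-6 tabular file; filters are strict —
alignment length > 100 bp and e-value < 1e-5 by default. The per-base
insertion value counts retained hits covering each stripped-coordinate
base; for display the IRb values are halved and mirrored onto both IR
copies. Per-chromosome summaries merge overlapping nuclear intervals before
summing bases and report each chromosome's share of insertion bases
(percent) and per-mille of the chromosome covered, plus a totals row.

## Internal aligner (`plastokit.align`)

Ungapped seed-and-extend: exact `k`-mer seeds (default 21), X-drop
extension (default 30) with match +2 / mismatch −3, per-diagonal
deduplication, both strands. E-values follow Karlin–Altschul,
E = K·m·n·e^(−λS) with λ = 0.625 and K = 0.41 (ungapped DNA defaults for
this scoring). Minus-strand hits are reported in original-query
coordinates. No gaps are modeled: diverged insertions containing indels
fragment into multiple hits, which is acceptable at the package's
desk-scale defaults and is the main limitation versus a full aligner.

## IR boundary evolution (`plastokit.boundary`)

Each gene's relation to the IR is an ordered three-state character:
SC (0) — partial_IR (1) — complete_IR (2). Profiles pool IR copies by gene
name: all exons inside an IR → complete_IR; any junction overlap →
partial_IR with the spanned junction (JLB, JSB, JSA, JLA) recorded; a gene
over two junctions is invalid. Profile diffs report per-gene transitions
plus gene gain/loss as separate records.

Ancestral reconstruction is Sankoff small parsimony with cost
|Δstate| per branch, so a direct SC→complete_IR change costs 2 (junction
migration is stepwise). A supplied root state charges any change away from
it. Among co-optimal assignments the deterministic reconstruction prefers
the parent's state, placing changes as late (tipward) as possible; all
co-optimal assignments can be enumerated exhaustively for small trees.
Branch lengths are ignored; the tree is an input, never estimated here.

## Marker diversity (`plastokit.markers`)

Genotypes are integer fragment sizes (NaN = missing). Distinct alleles are
counted per marker per accession group, exactly by default; an optional
size tolerance clusters alleles whose sizes differ by ≤ t bp. Group means
over markers are rounded to 2 decimals half away from zero. Nested groups
yield monotone non-increasing counts. All-missing marker×group cells count
0 and are flagged in the result's `attrs`.

## Assembly support (`plastokit.assembly`)

`bin_plastid_reads` keeps a read when its best ungapped local score against
the circularly doubled reference reaches `min_score_fraction` (default 0.5)
of the read's maximal self-score; the decision is strand invariant.

`elongate_contig` grows both contig ends by majority overlap consensus.
Per round and per end, reads whose prefix anchors on the terminal window
(longest overlap in [`min_overlap`=30, `window`=100] with ≤ 2 mismatches)
contribute their overhangs; the extension takes the base-wise majority
while ≥ `min_support` (default 5) reads cover the column with ≥
`min_agree` (default 0.8) agreement. Stops: `no_support`, `ambiguous`
(the expected outcome where single-copy flanks diverge at an IR exit —
reads shorter than the IR cannot resolve it, and the stop is reported, not
"fixed"), `circularized` (ends overlap ≥ `window` with ≤ 2 mismatches; the
duplicate overlap is trimmed), or `max_rounds`. Existing contig bases are
never rewritten. `order_contigs` places contigs by best-hit reference
midpoint and strand; IR-placed contigs are flagged duplicated and reported
at the IRb slot.

## Synthetic data (`plastokit.simulate`)

Defaults model a 1/50-scale plastome: LSC 1800, SSC 250, IR 700 bp
(genome 3450 bp), 8 protein genes (valid CDS: ATG start, no internal
stops, terminal stop; every third gene gets an intron), 4 tRNA and 2 rRNA
genes, base composition A/C/G/T = 0.31/0.19/0.19/0.31. The rRNA genes are
written into IRb and mirrored (with names shared) into IRa, which is the
exact reverse complement of IRb. Two guard mechanisms make planted truth
exact: 12-bp junction guards break chance reverse-complementarity across
the first/last bases of each single-copy region so the planted IR pair is
exactly maximal, and planted tandem repeats get non-matching boundary bases
(placed ≥ 16 bp from region edges so guards never touch them) so planted
runs are maximal. Mate-pair, NUPT, genotype and read-set generators record
complete ground truth (positions, strands, substitution counts, labels).

## Limitations

- Anticodon recognition ignores wobble pairing and base modifications.
- The aligner is ungapped; indel-containing homology fragments into
  multiple hits.
- Repeat scanning does not cross the circular origin (canonicalize first).
- IR detection assumes exactly one IR pair; plastomes that have lost an IR
  raise `NoQuadripartiteStructure` rather than degrading gracefully.
- Boundary reconstruction treats each gene as an independent character and
  ignores branch lengths.
- Elongation models substitution errors only (no indels) and cannot
  traverse repeats longer than the read length — by design it stops and
  says so.
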