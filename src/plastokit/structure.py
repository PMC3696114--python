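"""Quadripartite plastome structure: IR detection, canonicalization, statistics.

The inverted-repeat pair is found by exact k-mer seeding between the genome
and its reverse complement followed by ungapped extension with a mismatch
budget, on the doubled sequence so the result is invariant to the record's
rotation.  The shorter single-copy gap between the two IR copies is the SSC,
the longer the LSC; IRb is the copy that follows the LSC in canonical
forward-strand order LSC → IRb → SSC → IRa.
"""

from __future__ import annotations

from dataclasses import dataclass

from .codons import GENETIC_CODE, STOP_CODONS, round_half_up
from .model import (
    GeneFeature,
    GenomeInterval,
    RegionPartition,
    SequenceRecord,
    ValidationError,
    extract_feature_sequence,
    gc_content,
    revcomp,
)

__all__ = [
    "NoQuadripartiteStructure",
    "PartitionStats",
    "detect_inverted_repeat",
    "canonicalize",
    "partition_stats",
    "detect_internal_stops",
    "rotate_record",
    "flip_record",
]


class NoQuadripartiteStructure(Exception):
    """No inverted repeat of the required length exists (valid for some taxa)."""


# ---------------------------------------------------------------------------
# IR detection
# ---------------------------------------------------------------------------

def _extend_palindrome(
    d: str, p0: int, p1: int, q0: int, q1: int, limit: int, max_rate: float
) -> tuple[int, int, int, int]:
    """Extend a seed pair X=[p0,p1) / Y=[q0,q1) with Y == revcomp(X).

    Outward ungapped extension stepping over mismatches; the reported extent
    is trimmed back to the longest window whose overall mismatch fraction is
    ≤ max_rate and whose boundary bases match exactly.  ``limit`` caps total
    pair footprint so X and Y never overlap.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "X"}
    max_consec = 25  # give up after this many consecutive mismatches

    # right of X pairs with left of Y; left of X pairs with right of Y
    def grow(side: int) -> list[bool]:
        hits = []
        consec = 0
        i, j = (p1, q0 - 1) if side == 0 else (p0 - 1, q1)
        step = 1 if side == 0 else -1
        while 0 <= j < len(d) and 0 <= i < len(d):
            if side == 0 and (q0 - len(hits) - 1) - (p1 + len(hits)) <= 0:
                break  # X and Y would meet
            if len(hits) >= limit:
                break
            ok = comp[d[i]] == d[j]
            hits.append(ok)
            consec = 0 if ok else consec + 1
            if consec >= max_consec:
                break
            i += step
            j -= step
        return hits

    right = grow(0)
    left = grow(1)

    core = p1 - p0  # exact seed length
    # choose extents (a bases left, b bases right) maximizing length under rate
    def best_extent(hits: list[bool]) -> list[int]:
        # candidate extents ending on a match
        cands = [0]
        for k in range(len(hits)):
            if hits[k]:
                cands.append(k + 1)
        return cands

    best = (core, 0, 0)
    lcands = best_extent(left)
    rcands = best_extent(right)
    lmis = [0]
    for h in left:
        lmis.append(lmis[-1] + (not h))
    rmis = [0]
    for h in right:
        rmis.append(rmis[-1] + (not h))
    for a in lcands:
        for b in rcands:
            length = core + a + b
            mism = lmis[a] + rmis[b]
            if mism <= max_rate * length and length > best[0]:
                best = (length, a, b)
    _, a, b = best
    return p0 - a, p1 + b, q0 - b, q1 + a


def detect_inverted_repeat(
    record: SequenceRecord,
    min_ir_len: int = 50,
    max_mismatch_rate: float = 0.005,
    seed_k: int = 21,
) -> RegionPartition:
    """Locate the maximal inverted-repeat pair and delimit LSC/SSC.

    Returns a RegionPartition in the record's own rotation (intervals may
    wrap the origin).  Raises NoQuadripartiteStructure when no IR pair of at
    least ``min_ir_len`` exists.
    """
    if min_ir_len < seed_k:
        seed_k = max(8, min_ir_len // 2)
    seq = record.residues
    n = len(seq)
    if n < 2 * min_ir_len + 2:
        raise NoQuadripartiteStructure(f"sequence too short ({n} bp)")
    d = seq + seq if record.circular else seq
    m = len(d)

    # index k-mers of d by sequence
    index: dict[str, list[int]] = {}
    for j in range(m - seed_k + 1):
        index.setdefault(d[j : j + seed_k], []).append(j)

    stride = max(1, (min_ir_len - seed_k) // 4)
    # palindromic matches live on antidiagonals i+j = const of the
    # sequence-vs-revcomp match matrix; remember extents already extended
    seen: dict[int, list[tuple[int, int]]] = {}
    best: tuple[int, int, int, int, int] | None = None  # (len, p0, p1, q0, q1)

    for i in range(0, n, stride):
        kmer = d[i : i + seed_k]
        if "N" in kmer:
            continue
        for j in index.get(revcomp(kmer), ()):
            # X=[i,i+k) pairs with Y=[j,j+k); require X left of Y, disjoint,
            # and within one turn of the circle
            if j <= i + seed_k - 1 or j >= i + n:
                continue
            anti = i + j
            if any(a <= i < b for a, b in seen.get(anti, ())):
                continue
            p0, p1, q0, q1 = _extend_palindrome(
                d, i, i + seed_k, j, j + seed_k,
                limit=n, max_rate=max_mismatch_rate,
            )
            seen.setdefault(anti, []).append((p0, p1))
            length = p1 - p0
            if q0 - p1 <= 0 or length < min_ir_len:
                continue
            cand = (length, p0, p1, q0, q1)
            if best is None or length > best[0] or (
                length == best[0] and (p0 % n) < (best[1] % n)
            ):
                best = cand

    if best is None:
        raise NoQuadripartiteStructure(
            f"no inverted repeat ≥ {min_ir_len} bp in record {record.id!r}"
        )
    length, p0, p1, q0, q1 = best

    def make_iv(a: int, ln: int) -> GenomeInterval:
        a %= n
        e = a + ln
        if e <= n:
            return GenomeInterval(a, e)
        return GenomeInterval(a, e - n, wraps_origin=True)

    ir1 = make_iv(p0, length)
    ir2 = make_iv(q0, length)
    # gaps between the IRs around the circle (forward order ir1 → ir2 → ir1)
    gap12 = (q0 - p1) % n if record.circular else q0 - p1
    gap21 = n - 2 * length - gap12
    if gap21 < 0 or (gap12 == 0 and gap21 == 0):
        raise NoQuadripartiteStructure("IR copies leave no single-copy gap")

    sc12 = make_iv(p1, gap12) if gap12 > 0 else None
    sc21 = make_iv(q1, gap21) if gap21 > 0 else None
    if sc12 is None or sc21 is None:
        raise NoQuadripartiteStructure("a single-copy region is empty")

    if gap12 <= gap21:
        ssc, lsc = sc12, sc21
        irb, ira = ir1, ir2  # LSC → ir1(=IRb) → SSC → ir2(=IRa)
    else:
        ssc, lsc = sc21, sc12
        irb, ira = ir2, ir1
    return RegionPartition(lsc=lsc, irb=irb, ssc=ssc, ira=ira, genome_length=n)


# ---------------------------------------------------------------------------
# Canonicalization
# ---------------------------------------------------------------------------

def rotate_record(record: SequenceRecord, offset: int) -> SequenceRecord:
    """Rotate a circular record so old position ``offset`` becomes position 0."""
    if not record.circular:
        raise ValidationError("cannot rotate a linear record")
    n = len(record.residues)
    offset %= n
    return SequenceRecord(
        id=record.id,
        residues=record.residues[offset:] + record.residues[:offset],
        circular=True,
    )


def _shift_interval(iv: GenomeInterval, offset: int, n: int) -> GenomeInterval:
    s = (iv.start - offset) % n
    e = s + iv.length(n)
    if e <= n:
        return GenomeInterval(s, e, strand=iv.strand)
    return GenomeInterval(s, e - n, strand=iv.strand, wraps_origin=True)


def _flip_interval(iv: GenomeInterval, n: int) -> GenomeInterval:
    """Mirror an interval under full reverse complement of the genome."""
    ln = iv.length(n)
    s = (n - iv.start - ln) % n if iv.wraps_origin else n - iv.end
    strand = "-" if iv.strand == "+" else "+"
    e = s + ln
    if e <= n:
        return GenomeInterval(s, e, strand=strand)
    return GenomeInterval(s, e - n, strand=strand, wraps_origin=True)


def flip_record(record: SequenceRecord) -> SequenceRecord:
    return SequenceRecord(id=record.id, residues=revcomp(record.residues),
                          circular=record.circular)


def _map_features(features, mapper) -> list[GeneFeature]:
    return [
        GeneFeature(
            name=f.name, gene_class=f.gene_class,
            parts=tuple(mapper(p) for p in f.parts),
            pseudo=f.pseudo, anticodon=f.anticodon,
        )
        for f in features
    ]


def canonicalize(
    record: SequenceRecord,
    partition: RegionPartition,
    features: list[GeneFeature] | None = None,
) -> tuple[SequenceRecord, RegionPartition, list[GeneFeature]]:
    """Rotate (and possibly flip) to the canonical LSC,IRb,SSC,IRa layout.

    The output starts at LSC position 0.  Between the two sequences that
    realise the canonical layout (the rotation of the input and the rotation
    of its reverse complement) the lexicographically smaller one is chosen,
    so the result is a pure function of the circular molecule.  Features are
    remapped so extracted feature sequences are unchanged.
    """
    features = features or []
    n = partition.genome_length

    def canonical_rotation(rec, part, feats):
        off = part.lsc.start
        rec2 = rotate_record(rec, off)
        part2 = RegionPartition(
            lsc=_shift_interval(part.lsc, off, n),
            irb=_shift_interval(part.irb, off, n),
            ssc=_shift_interval(part.ssc, off, n),
            ira=_shift_interval(part.ira, off, n),
            genome_length=n,
        )
        feats2 = _map_features(feats, lambda p: _shift_interval(p, off, n))
        return rec2, part2, feats2

    fwd = canonical_rotation(record, partition, features)

    flipped_part = RegionPartition(
        lsc=_flip_interval(partition.lsc, n),
        irb=_flip_interval(partition.ira, n),  # IRb/IRa swap under flip
        ssc=_flip_interval(partition.ssc, n),
        ira=_flip_interval(partition.irb, n),
        genome_length=n,
    )
    rev = canonical_rotation(
        flip_record(record),
        flipped_part,
        _map_features(features, lambda p: _flip_interval(p, n)),
    )

    return fwd if fwd[0].residues <= rev[0].residues else rev


# ---------------------------------------------------------------------------
# Statistics panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PartitionStats:
    """Plastome characteristics: sizes, percentages, GC, gene counts.

    Every base is assigned exactly one class in priority order exon
    (protein > tRNA > rRNA) > intron > intergenic spacer; percentages are
    100·size/genome size rounded to one decimal, half away from zero.
    """

    genome_size: int
    lsc_size: int
    ssc_size: int
    ir_size: int
    coding_size: int
    protein_size: int
    trna_size: int
    rrna_size: int
    intron_size: int
    igs_size: int
    gc_overall: float
    gc_protein: float
    gc_trna: float
    gc_rrna: float
    gc_intron: float
    gc_igs: float
    n_genes_distinct: int
    n_protein_genes: int
    n_trna_genes: int
    n_rrna_genes: int
    n_ir_duplicated: int
    n_junction_partial: int
    n_intron_genes: int

    def percent(self, size: int) -> float:
        return round_half_up(100.0 * size / self.genome_size, 1)


_CLASS_PRIORITY = {"protein": 0, "tRNA": 1, "rRNA": 2}


def partition_stats(
    record: SequenceRecord,
    partition: RegionPartition,
    features: list[GeneFeature],
) -> PartitionStats:
    """Compute the plastome characteristics panel.

    IR copies of a gene (same name) are counted once in the gene counts;
    exon/intron/IGS base classes are assigned with priority exon > intron >
    IGS, and overlapping exons of different genes resolve by class priority
    protein > tRNA > rRNA.
    """
    import numpy as np

    n = len(record.residues)
    # 0=IGS, 1=intron, 2=rRNA exon, 3=tRNA exon, 4=protein exon
    cls = np.zeros(n, dtype=np.int8)
    code = {"protein": 4, "tRNA": 3, "rRNA": 2}

    def paint(iv: GenomeInterval, value: int, keep_max: bool) -> None:
        for s, e in iv.segments(n):
            seg = cls[s:e]
            if keep_max:
                np.maximum(seg, value, out=seg)
            else:
                seg[seg == 0] = value

    # introns first at low priority, then exons override
    for f in features:
        parts = sorted(f.parts, key=lambda p: p.start)
        same_strand = len({p.strand for p in f.parts}) == 1
        if same_strand and not any(p.wraps_origin for p in f.parts):
            for a, b in zip(parts, parts[1:]):
                gap = b.start - a.end
                # trans-spliced or rearranged parts produce huge/negative gaps;
                # only plausible intron gaps are painted
                if 0 < gap <= 10000:
                    paint(GenomeInterval(a.end, b.start), 1, keep_max=False)
    for f in features:
        for p in f.parts:
            paint(p, code[f.gene_class], keep_max=True)

    arr = np.frombuffer(record.residues.encode(), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    is_acgt = is_gc | (arr == ord("A")) | (arr == ord("T"))

    def size_and_gc(mask) -> tuple[int, float]:
        size = int(mask.sum())
        acgt = int((mask & is_acgt).sum())
        gcn = int((mask & is_gc).sum())
        return size, (100.0 * gcn / acgt if acgt else float("nan"))

    protein_size, gc_protein = size_and_gc(cls == 4)
    trna_size, gc_trna = size_and_gc(cls == 3)
    rrna_size, gc_rrna = size_and_gc(cls == 2)
    intron_size, gc_intron = size_and_gc(cls == 1)
    igs_size, gc_igs = size_and_gc(cls == 0)
    coding_size = protein_size + trna_size + rrna_size

    # gene counts, one per distinct name
    by_name: dict[str, list[GeneFeature]] = {}
    for f in features:
        by_name.setdefault(f.name, []).append(f)
    irs = [partition.irb, partition.ira]
    n_dup = n_partial = 0
    n_intron_genes = 0
    class_counts = {"protein": 0, "tRNA": 0, "rRNA": 0}
    for name, copies in by_name.items():
        class_counts[copies[0].gene_class] += 1
        if any(c.intron_count > 0 for c in copies):
            n_intron_genes += 1
        all_parts = [p for c in copies for p in c.parts]
        inside = [
            any(ir.contains(p, n) for ir in irs) for p in all_parts
        ]
        touches = [
            any(ir.overlaps(p, n) for ir in irs) for p in all_parts
        ]
        if len(copies) > 1 and all(inside):
            n_dup += 1
        elif any(touches) and not all(inside):
            n_partial += 1

    return PartitionStats(
        genome_size=n,
        lsc_size=partition.lsc.length(n),
        ssc_size=partition.ssc.length(n),
        ir_size=partition.ir_length,
        coding_size=coding_size,
        protein_size=protein_size,
        trna_size=trna_size,
        rrna_size=rrna_size,
        intron_size=intron_size,
        igs_size=igs_size,
        gc_overall=gc_content(record.residues),
        gc_protein=gc_protein,
        gc_trna=gc_trna,
        gc_rrna=gc_rrna,
        gc_intron=gc_intron,
        gc_igs=gc_igs,
        n_genes_distinct=len(by_name),
        n_protein_genes=class_counts["protein"],
        n_trna_genes=class_counts["tRNA"],
        n_rrna_genes=class_counts["rRNA"],
        n_ir_duplicated=n_dup,
        n_junction_partial=n_partial,
        n_intron_genes=n_intron_genes,
    )


def detect_internal_stops(cds_sequence: str) -> int:
    """Count in-frame internal stop codons (terminal codon excluded).

    A count above zero recommends flagging the gene as a pseudogene.  A CDS
    whose length is not divisible by 3 is counted with truncation under a
    frame-broken warning.
    """
    import warnings

    cds = cds_sequence.upper()
    if len(cds) % 3:
        warnings.warn("frame-broken CDS: length not divisible by 3, truncating")
        cds = cds[: len(cds) - len(cds) % 3]
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    return sum(1 for c in codons[:-1] if c in STOP_CODONS)
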