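"""Deterministic synthetic-data generators with recorded ground truth.

Every pipeline stage can be exercised without downloads: a quadripartite
circular plastome with placed genes and planted tandem repeats, mate-pair
populations mixing the two SSC-orientation isoforms, nuclear chromosomes
carrying planted plastome insertions, genotype tables over nested accession
groups, and mixed plastid/nuclear read sets.

Default dimensions are 1/50 of a typical large-IR plastome (LSC 1.8 kb,
IR 700 bp, SSC 250 bp) — the same topology at a size where whole-pipeline
tests run in seconds.  All generators are pure functions of their spec and
seed: one global seed fans out to per-generator numpy streams by fixed
offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codons import GENETIC_CODE, STOP_CODONS
from .markers import GenotypeTable
from .model import (
    GeneFeature,
    GenomeInterval,
    RegionPartition,
    SequenceRecord,
    revcomp,
)
from .orientation import MateAlignment
from .repeats import RepeatLocus, is_primitive

__all__ = [
    "PlastomeSimSpec",
    "SimTruth",
    "make_plastome",
    "make_isoform_mate_pairs",
    "make_nuclear_with_nupts",
    "make_genotype_table",
    "make_read_set",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# fixed per-generator stream offsets fanned out from the global seed
_STREAM = {
    "plastome": 0,
    "mate_pairs": 101,
    "nuclear": 202,
    "genotypes": 303,
    "reads": 404,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(int(seed) + _STREAM[stream])


def _random_seq(rng: np.random.Generator, length: int, probs=None) -> str:
    idx = rng.choice(4, size=length, p=probs)
    return _BASES[idx].tobytes().decode()


@dataclass(frozen=True)
class PlastomeSimSpec:
    """Dimensions, gene numbers, planted repeats and composition of a
    simulated quadripartite plastome."""

    lsc_len: int = 1800
    ssc_len: int = 250
    ir_len: int = 700
    n_protein_genes: int = 8
    n_trna_genes: int = 4
    n_rrna_genes: int = 2
    planted_repeats: tuple = ()  # (motif, copies, region) triples
    base_composition: tuple = (0.31, 0.19, 0.19, 0.31)  # A,C,G,T
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lsc_len, self.ssc_len, self.ir_len) <= 0:
            raise ValueError("region lengths must be positive")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base composition must sum to 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for motif, copies, region in self.planted_repeats:
            if not is_primitive(motif.upper()):
                raise ValueError(f"planted motif {motif!r} is not primitive")
            if region not in ("LSC", "SSC", "IRb"):
                raise ValueError("planted region must be LSC, SSC or IRb")

    @property
    def genome_length(self) -> int:
        return self.lsc_len + self.ssc_len + 2 * self.ir_len


@dataclass
class SimTruth:
    """Ground truth recorded by make_plastome."""

    partition: RegionPartition
    features: list[GeneFeature]
    repeats: list[RepeatLocus]


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random non-stop codons + one stop codon."""
    sense = [c for c in GENETIC_CODE if c not in STOP_CODONS and c != "ATG"]
    body = [sense[i] for i in rng.integers(0, len(sense), size=n_codons - 2)]
    stop = ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
    return "ATG" + "".join(body) + stop


def make_plastome(spec: PlastomeSimSpec) -> tuple[SequenceRecord, list[GeneFeature], SimTruth]:
    """Simulate a canonical LSC+IRb+SSC+IRa circular plastome.

    IRa is the exact reverse complement of IRb; genes are placed
    non-overlapping (IRb genes are mirrored into IRa with the same name,
    i.e. IR-duplicated); planted repeats overwrite background at recorded,
    boundary-guarded positions.  Same spec ⇒ identical bytes.
    """
    rng = _rng(spec.seed, "plastome")
    probs = np.asarray(spec.base_composition, float)
    n = spec.genome_length
    lsc0, irb0 = 0, spec.lsc_len
    ssc0 = irb0 + spec.ir_len
    ira0 = ssc0 + spec.ssc_len

    seq = list(_random_seq(rng, spec.lsc_len + spec.ir_len + spec.ssc_len, probs))

    regions = {
        "LSC": (lsc0, irb0),
        "IRb": (irb0, ssc0),
        "SSC": (ssc0, ira0),
    }
    occupied: dict[str, list[tuple[int, int]]] = {r: [] for r in regions}

    def place(region: str, length: int, margin: int = 16) -> int | None:
        """Find a free start for a block of `length` within the region."""
        s, e = regions[region]
        for _ in range(200):
            if e - s < length + 2 * margin:
                return None
            start = int(rng.integers(s + margin, e - length - margin + 1))
            if all(
                start + length + margin <= a or start >= b + margin
                for a, b in occupied[region]
            ):
                occupied[region].append((start, start + length))
                return start
        return None

    features: list[GeneFeature] = []

    def write_gene(region: str, gene_seq: str, name: str, gclass: str,
                   strand: str, intron: int = 0, anticodon=None,
                   pseudo: bool = False) -> bool:
        total = len(gene_seq) + intron
        start = place(region, total)
        if start is None:
            return False
        if intron:
            half = len(gene_seq) // 2 // 3 * 3 or 3
            exon1, exon2 = gene_seq[:half], gene_seq[half:]
            if strand == "-":
                # genomic layout: exon2' then exon1' (5' exon downstream)
                seq[start : start + len(exon2)] = revcomp(exon2)
                g2 = start + len(exon2) + intron
                seq[g2 : g2 + len(exon1)] = revcomp(exon1)
                parts = (
                    GenomeInterval(g2, g2 + len(exon1), strand="-"),
                    GenomeInterval(start, start + len(exon2), strand="-"),
                )
            else:
                seq[start : start + len(exon1)] = exon1
                g2 = start + len(exon1) + intron
                seq[g2 : g2 + len(exon2)] = exon2
                parts = (
                    GenomeInterval(start, start + len(exon1), strand="+"),
                    GenomeInterval(g2, g2 + len(exon2), strand="+"),
                )
        else:
            placed = gene_seq if strand == "+" else revcomp(gene_seq)
            seq[start : start + len(gene_seq)] = placed
            parts = (GenomeInterval(start, start + len(gene_seq), strand=strand),)
        features.append(
            GeneFeature(name=name, gene_class=gclass, parts=parts,
                        pseudo=pseudo, anticodon=anticodon)
        )
        return True

    # protein genes: most in LSC, one in SSC, one in IRb; every third has an intron
    for i in range(spec.n_protein_genes):
        region = "LSC" if i < spec.n_protein_genes - 2 else ("SSC" if i % 2 else "IRb")
        n_codons = int(rng.integers(25, 60))
        cds = _random_cds(rng, n_codons)
        strand = "+" if rng.random() < 0.5 else "-"
        intron = int(rng.integers(30, 80)) if i % 3 == 2 else 0
        write_gene(region, cds, f"pcg{i+1:02d}", "protein", strand, intron=intron)
    for i in range(spec.n_trna_genes):
        region = "LSC" if i % 2 == 0 else "IRb"
        body = _random_seq(rng, 72, probs)
        anticodon = _BASES[rng.integers(0, 4, size=3)].tobytes().decode()
        strand = "+" if rng.random() < 0.5 else "-"
        write_gene(region, body, f"trn{i+1:02d}", "tRNA", strand, anticodon=anticodon)
    for i in range(spec.n_rrna_genes):
        body = _random_seq(rng, 120, probs)
        write_gene("IRb", body, f"rrn{i+1:02d}", "rRNA", "+")

    # planted tandem repeats, boundary-guarded so the planted run is maximal
    truth_repeats: list[RepeatLocus] = []
    for motif, copies, region in spec.planted_repeats:
        motif = motif.upper()
        u = len(motif)
        block = motif * int(copies)
        # margin must exceed the 12 bp junction guard below so the guards
        # can never rewrite planted bases
        start = place(region, len(block), margin=16)
        if start is None:
            raise ValueError(
                f"planted repeat {motif!r}×{copies} does not fit in {region}"
            )
        seq[start : start + len(block)] = block
        # guard bases: prevent accidental left/right extension of the run
        alt = {"A": "C", "C": "A", "G": "T", "T": "G"}
        seq[start - 1] = alt[motif[-1]]
        seq[start + len(block)] = alt[seq[start + len(block) - u]]
        truth_repeats.append(
            RepeatLocus(
                interval=GenomeInterval(start, start + len(block)),
                unit=motif,
                copies=float(copies),
                repeat_class="micro" if u <= 6 else "mini",
                region=region,
            )
        )

    # junction guards: break sequence palindromy across the first/last bases
    # of each single-copy region so the planted IR pair is exactly maximal
    # (IR extension pairs SSC[j] with SSC[-1-j] and LSC[j] with LSC[-1-j])
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    guard = 12
    for (r0, r1) in ((lsc0, irb0), (ssc0, ira0)):
        if r1 - r0 < 2 * guard + 2:
            continue
        for j in range(guard):
            partner = seq[r1 - 1 - j]
            if seq[r0 + j] == comp[partner]:
                # any base other than the complement breaks the pairing
                seq[r0 + j] = partner

    body = "".join(seq)
    ira_seq = revcomp(body[irb0:ssc0])
    full = body + ira_seq
    record = SequenceRecord(id=f"sim_plastome_seed{spec.seed}", residues=full,
                            circular=True)

    partition = RegionPartition(
        lsc=GenomeInterval(lsc0, irb0),
        irb=GenomeInterval(irb0, ssc0),
        ssc=GenomeInterval(ssc0, ira0),
        ira=GenomeInterval(ira0, n),
        genome_length=n,
    )

    # mirror IRb features into IRa (same names: IR-duplicated)
    ir_len = spec.ir_len
    mirrored: list[GeneFeature] = []
    for f in features:
        if all(irb0 <= p.start and p.end <= ssc0 for p in f.parts):
            new_parts = []
            for p in reversed(f.parts):
                off0, off1 = p.start - irb0, p.end - irb0
                ms = ira0 + (ir_len - off1)
                me = ira0 + (ir_len - off0)
                new_parts.append(
                    GenomeInterval(ms, me, strand="-" if p.strand == "+" else "+")
                )
            mirrored.append(
                GeneFeature(name=f.name, gene_class=f.gene_class,
                            parts=tuple(new_parts), pseudo=f.pseudo,
                            anticodon=f.anticodon)
            )
    all_features = features + mirrored

    truth = SimTruth(partition=partition, features=all_features,
                     repeats=truth_repeats)
    return record, all_features, truth


# ---------------------------------------------------------------------------
# Isoform mate pairs
# ---------------------------------------------------------------------------

def make_isoform_mate_pairs(
    plastome: SequenceRecord,
    truth: SimTruth,
    n_pairs: int,
    form_b_fraction: float,
    insert_len: int,
    read_len: int,
    seed: int,
) -> tuple[list[tuple[MateAlignment, MateAlignment]], list[str]]:
    """Simulate mate pairs from a mixture of the two SSC-orientation forms.

    Each pair's source form is a seeded coin; fragments are sampled uniformly
    on the source circle and both mates are reported as alignments to the
    form-A reference.  Mates wholly inside the SSC of a form-B fragment map
    to mirrored SSC coordinates with flipped strand at identity 100; mates
    chimeric across the SSC boundary of form B get proportionally reduced
    identity (they do not exist as contiguous form-A sequence).
    """
    if not 0 <= form_b_fraction <= 1:
        raise ValueError("form_b_fraction must be in [0,1]")
    n = len(plastome.residues)
    if insert_len > n:
        raise ValueError("insert length exceeds genome length")
    if insert_len < 2 * read_len:
        raise ValueError("insert too short for two mates")
    rng = _rng(seed, "mate_pairs")
    part = truth.partition
    b0, b1 = part.ssc.start, part.ssc.end

    def to_form_a(start: int, end: int, strand: str, is_b: bool):
        """Map a mate interval from source-form coords to form-A coords."""
        if not is_b:
            return start, end, strand, 100.0
        # overlap with SSC
        inter = max(0, min(end, b1) - max(start, b0))
        if inter == end - start:  # wholly in SSC: mirror
            ns = b0 + (b1 - end)
            ne = b0 + (b1 - start)
            return ns, ne, ("R" if strand == "F" else "F"), 100.0
        if inter == 0:
            return start, end, strand, 100.0
        # chimeric across the junction on form B: best contiguous piece
        frac = max(inter, (end - start) - inter) / (end - start)
        return start, end, strand, 100.0 * frac

    pairs = []
    labels = []
    for i in range(n_pairs):
        is_b = bool(rng.random() < form_b_fraction)
        p = int(rng.integers(0, n))
        m1 = (p, p + read_len, "F")
        m2 = (p + insert_len - read_len, p + insert_len, "R")
        mates = []
        for j, (s, e, st) in enumerate((m1, m2)):
            s %= n
            e = s + read_len
            if e > n:
                # wraps the origin: identical on both forms (outside SSC)
                iv = GenomeInterval(s, e - n, wraps_origin=True)
                a_st, ident = st, 100.0
            else:
                a_s, a_e, a_st, ident = to_form_a(s, e, st, is_b)
                iv = GenomeInterval(a_s, a_e)
            mates.append(
                MateAlignment(
                    mate_id=f"pair{i}/{j+1}",
                    interval=iv,
                    strand=a_st,
                    identity=ident,
                    aligned_fraction=1.0,
                )
            )
        pairs.append((mates[0], mates[1]))
        labels.append("B" if is_b else "A")
    return pairs, labels


# ---------------------------------------------------------------------------
# Nuclear chromosomes with planted plastome insertions
# ---------------------------------------------------------------------------

def make_nuclear_with_nupts(
    plastome: SequenceRecord,
    partition: RegionPartition,
    n_chrom: int = 3,
    n_insertions: int = 6,
    len_range: tuple[int, int] = (150, 600),
    divergence_rate: float = 0.0,
    chrom_len: int = 8000,
    seed: int = 0,
) -> tuple[list[SequenceRecord], list[dict]]:
    """Random chromosomes carrying plastome fragments at recorded positions.

    Fragments are drawn from the plastome with one IR removed (LSC+IRb+SSC)
    and mutated by substitutions at ``divergence_rate``; truth records both
    coordinate systems.  Insertions overwrite background sequence, keeping
    chromosome length fixed.
    """
    if divergence_rate >= 0.2:
        raise ValueError("divergence_rate must be < 0.2")
    rng = _rng(seed, "nuclear")
    stripped = plastome.residues[: partition.ssc.end]
    chroms = [
        list(_random_seq(rng, chrom_len)) for _ in range(n_chrom)
    ]
    occupied: list[list[tuple[int, int]]] = [[] for _ in range(n_chrom)]
    truth = []
    for k in range(n_insertions):
        flen = int(rng.integers(len_range[0], len_range[1] + 1))
        if flen > chrom_len:
            raise ValueError("insertion longer than chromosome")
        src = int(rng.integers(0, len(stripped) - flen + 1))
        frag = list(stripped[src : src + flen])
        n_subs = 0
        if divergence_rate > 0:
            for pos in range(flen):
                if rng.random() < divergence_rate:
                    cur = frag[pos]
                    frag[pos] = {"A": "G", "G": "A", "C": "T", "T": "C"}[cur]
                    n_subs += 1
        strand = "+" if rng.random() < 0.5 else "-"
        placed = frag if strand == "+" else list(revcomp("".join(frag)))
        for _ in range(200):
            ci = int(rng.integers(0, n_chrom))
            pos = int(rng.integers(0, chrom_len - flen + 1))
            if all(pos + flen + 25 <= a or pos >= b + 25 for a, b in occupied[ci]):
                break
        else:
            raise ValueError("could not place insertion without overlap")
        chroms[ci][pos : pos + flen] = placed
        occupied[ci].append((pos, pos + flen))
        truth.append(
            {
                "chromosome": f"chr{ci+1:02d}",
                "nuclear_interval": GenomeInterval(pos, pos + flen),
                "plastome_interval": GenomeInterval(src, src + flen),
                "strand": strand,
                "length": flen,
                "n_substitutions": n_subs,
            }
        )
    records = [
        SequenceRecord(id=f"chr{i+1:02d}", residues="".join(c))
        for i, c in enumerate(chroms)
    ]
    return records, truth


# ---------------------------------------------------------------------------
# Genotype tables
# ---------------------------------------------------------------------------

def make_genotype_table(
    n_markers: int,
    group_sizes: list[int],
    allele_pool: list[int] | None = None,
    seed: int = 0,
    group_names: list[str] | None = None,
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Random genotype table over nested accession groups with truth counts.

    ``group_sizes`` are non-increasing nested group sizes (the largest group
    holds all accessions, each subsequent group is a prefix subset).  Returns
    the table and the truth distinct-allele counts per marker per group.
    """
    if any(s < 1 for s in group_sizes):
        raise ValueError("group sizes must be ≥ 1")
    if sorted(group_sizes, reverse=True) != list(group_sizes):
        raise ValueError("group sizes must be non-increasing (nested groups)")
    rng = _rng(seed, "genotypes")
    pool = allele_pool or [180 + 2 * i for i in range(8)]
    n_acc = group_sizes[0]
    accessions = [f"acc{i+1:02d}" for i in range(n_acc)]
    names = group_names or [f"group{j+1}" for j in range(len(group_sizes))]
    groups = {
        name: set(accessions[:size]) for name, size in zip(names, group_sizes)
    }
    data = pd.DataFrame(
        {
            f"marker{m+1:02d}": [
                int(pool[rng.integers(0, len(pool))]) for _ in accessions
            ]
            for m in range(n_markers)
        },
        index=accessions,
        dtype="float64",
    )
    table = GenotypeTable(data=data, groups=groups)
    truth_rows = {}
    for marker in data.columns:
        truth_rows[marker] = {
            name: int(data.loc[sorted(groups[name]), marker].nunique())
            for name in names
        }
    truth = pd.DataFrame.from_dict(truth_rows, orient="index")[names]
    return table, truth


# ---------------------------------------------------------------------------
# Mixed read sets
# ---------------------------------------------------------------------------

def make_read_set(
    plastome: SequenceRecord,
    nuclear: list[SequenceRecord],
    plastid_fraction: float,
    n_reads: int,
    read_len: int,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[SequenceRecord], list[str]]:
    """Single-end reads from the circular plastome and the nuclear background,
    with seeded substitution errors and truth origin labels."""
    if not 0.0 <= plastid_fraction <= 1.0:
        raise ValueError("plastid_fraction must be in [0,1]")
    if plastid_fraction < 1.0 and not nuclear:
        raise ValueError("nuclear sequences required when plastid_fraction < 1")
    rng = _rng(seed, "reads")
    p2 = plastome.residues + plastome.residues  # circular doubling
    if read_len > len(plastome.residues) or any(
        read_len > len(c.residues) for c in nuclear
    ):
        raise ValueError("read length exceeds a source sequence")
    reads, labels = [], []
    for i in range(n_reads):
        from_plastid = bool(rng.random() < plastid_fraction)
        if from_plastid:
            start = int(rng.integers(0, len(plastome.residues)))
            raw = p2[start : start + read_len]
            label = "plastid"
        else:
            c = nuclear[int(rng.integers(0, len(nuclear)))]
            start = int(rng.integers(0, len(c.residues) - read_len + 1))
            raw = c.residues[start : start + read_len]
            label = "nuclear"
        if rng.random() < 0.5:
            raw = revcomp(raw)
        if error_rate > 0:
            chars = list(raw)
            for pos in range(read_len):
                if rng.random() < error_rate:
                    chars[pos] = {"A": "G", "G": "A", "C": "T", "T": "C"}[chars[pos]]
            raw = "".join(chars)
        reads.append(SequenceRecord(id=f"read{i:05d}", residues=raw))
        labels.append(label)
    return reads, labels
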