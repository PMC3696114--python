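"""Core sequence/feature data model and file I/O for plastome analysis.

Internal coordinates are 0-based half-open throughout; all file dialects
(FASTA headers aside) use 1-based inclusive coordinates.  Circular genomes
are first-class: an interval may wrap the origin (``wraps_origin``) instead
of being represented on a doubled sequence, so region sizes always sum to
the genome length exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "FormatError",
    "ValidationError",
    "SequenceRecord",
    "GenomeInterval",
    "GeneFeature",
    "RegionPartition",
    "revcomp",
    "gc_content",
    "read_fasta",
    "write_fasta",
    "read_annotation",
    "write_annotation",
    "extract_feature_sequence",
]

VALID_RESIDUES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised for malformed input files."""


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A nucleotide sequence, optionally circular.

    Residues are uppercase A/C/G/T/N; ambiguity codes other than N are
    rejected so downstream GC and codon arithmetic stays exact.
    """

    id: str
    residues: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        object.__setattr__(self, "residues", self.residues.upper())
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            pos = next(i for i, c in enumerate(self.residues) if c in bad)
            raise ValidationError(
                f"record {self.id!r}: illegal residue {self.residues[pos]!r} at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def slice(self, interval: "GenomeInterval") -> str:
        """Sequence under an interval, honoring origin wrap and strand."""
        n = len(self.residues)
        if interval.wraps_origin:
            if not self.circular:
                raise ValidationError(
                    f"record {self.id!r}: origin-wrapping interval on a linear record"
                )
            raw = self.residues[interval.start:] + self.residues[: interval.end]
        else:
            if interval.end > n:
                raise ValidationError(
                    f"record {self.id!r}: interval [{interval.start},{interval.end}) "
                    f"outside sequence of length {n}"
                )
            raw = self.residues[interval.start : interval.end]
        return revcomp(raw) if interval.strand == "-" else raw


@dataclass(frozen=True)
class GenomeInterval:
    """0-based half-open interval; ``wraps_origin`` encodes circular wrap.

    For a wrapping interval the stored ``end`` is smaller than ``start``:
    the interval covers [start, n) + [0, end) of a circular genome.
    """

    start: int
    end: int
    strand: str = "+"
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"bad strand {self.strand!r}")
        if self.start < 0 or self.end < 0:
            raise ValidationError("negative coordinate")
        if self.wraps_origin:
            if self.end >= self.start:
                raise ValidationError(
                    "wrapping interval requires end < start "
                    f"(got [{self.start},{self.end}))"
                )
        elif self.start >= self.end:
            raise ValidationError(
                f"empty or inverted interval [{self.start},{self.end})"
            )

    def length(self, genome_length: int | None = None) -> int:
        if self.wraps_origin:
            if genome_length is None:
                raise ValueError("genome_length required for a wrapping interval")
            return genome_length - self.start + self.end
        return self.end - self.start

    def contains(self, other: "GenomeInterval", genome_length: int | None = None) -> bool:
        """Whole containment of ``other`` (both non-wrapping, or self wrapping)."""
        for s, e in other.segments(genome_length):
            if not any(ss <= s and e <= ee for ss, ee in self.segments(genome_length)):
                return False
        return True

    def segments(self, genome_length: int | None = None) -> list[tuple[int, int]]:
        """Linear (start, end) pieces covering the interval."""
        if not self.wraps_origin:
            return [(self.start, self.end)]
        if genome_length is None:
            raise ValueError("genome_length required for a wrapping interval")
        segs = [(self.start, genome_length)]
        if self.end > 0:
            segs.append((0, self.end))
        return segs

    def overlaps(self, other: "GenomeInterval", genome_length: int | None = None) -> bool:
        for s1, e1 in self.segments(genome_length):
            for s2, e2 in other.segments(genome_length):
                if s1 < e2 and s2 < e1:
                    return True
        return False


@dataclass(frozen=True)
class GeneFeature:
    """A gene with one or more exon intervals, ordered 5'→3' on the coding strand.

    Trans-spliced genes are a single feature whose parts may be distant and on
    different strands; coding-sequence extraction concatenates the parts in
    the declared order.
    """

    name: str
    gene_class: str  # {protein, tRNA, rRNA}
    parts: tuple[GenomeInterval, ...]
    pseudo: bool = False
    anticodon: str | None = None

    def __post_init__(self) -> None:
        if self.gene_class not in ("protein", "tRNA", "rRNA"):
            raise ValidationError(f"gene {self.name!r}: bad class {self.gene_class!r}")
        if not self.parts:
            raise ValidationError(f"gene {self.name!r}: no exons")
        object.__setattr__(self, "parts", tuple(self.parts))
        # exons of one gene must not overlap each other
        segs = [seg for p in self.parts for seg in ([(p.start, p.end)] if not p.wraps_origin else [])]
        segs.sort()
        for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
            if s2 < e1:
                raise ValidationError(f"gene {self.name!r}: overlapping exons")
        if self.anticodon is not None:
            if self.gene_class != "tRNA":
                raise ValidationError(f"gene {self.name!r}: anticodon on non-tRNA")
            if len(self.anticodon) != 3 or set(self.anticodon) - set("ACGT"):
                raise ValidationError(f"gene {self.name!r}: bad anticodon {self.anticodon!r}")

    @property
    def intron_count(self) -> int:
        return len(self.parts) - 1

    def span_length(self, genome_length: int | None = None) -> int:
        return sum(p.length(genome_length) for p in self.parts)


@dataclass(frozen=True)
class RegionPartition:
    """The quadripartite LSC/IRb/SSC/IRa layout of a plastome.

    Canonical order along the forward strand is LSC → IRb → SSC → IRa;
    intervals may wrap the origin on non-canonical rotations.  Strand on the
    member intervals is ignored.
    """

    lsc: GenomeInterval
    irb: GenomeInterval
    ssc: GenomeInterval
    ira: GenomeInterval
    genome_length: int

    def __post_init__(self) -> None:
        n = self.genome_length
        total = sum(r.length(n) for r in (self.lsc, self.irb, self.ssc, self.ira))
        if total != n:
            raise ValidationError(
                f"region lengths sum to {total}, genome is {n}"
            )
        if self.irb.length(n) != self.ira.length(n):
            raise ValidationError("IRb and IRa lengths differ")
        covered = []
        for r in (self.lsc, self.irb, self.ssc, self.ira):
            covered.extend(r.segments(n))
        covered.sort()
        for (s1, e1), (s2, e2) in zip(covered, covered[1:]):
            if s2 < e1:
                raise ValidationError("regions overlap")

    @property
    def ir_length(self) -> int:
        return self.irb.length(self.genome_length)

    def regions(self) -> dict[str, GenomeInterval]:
        return {"LSC": self.lsc, "IRb": self.irb, "SSC": self.ssc, "IRa": self.ira}

    def region_of(self, interval: GenomeInterval) -> str | None:
        """Region wholly containing ``interval``, or None if it straddles."""
        for name, reg in self.regions().items():
            if reg.contains(interval, self.genome_length):
                return name
        return None


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_fasta(path, circular: bool = False) -> list[SequenceRecord]:
    """Read a (multi-)FASTA file into SequenceRecords.

    Lowercase is uppercased; U is mapped to T with a warning; any residue
    outside IUPAC {A,C,G,T,U,N} raises FormatError naming the offset.
    """
    records: list[SequenceRecord] = []
    with open(path) as fh:
        header: str | None = None
        chunks: list[str] = []

        def flush() -> None:
            if header is None:
                return
            seq = "".join(chunks).upper()
            if "U" in seq:
                warnings.warn(f"record {header!r}: U residues mapped to T")
                seq = seq.replace("U", "T")
            bad = set(seq) - VALID_RESIDUES
            if bad:
                pos = next(i for i, c in enumerate(seq) if c in bad)
                raise FormatError(
                    f"record {header!r}: illegal residue {seq[pos]!r} at position {pos}"
                )
            if not seq:
                raise FormatError(f"record {header!r}: empty sequence")
            records.append(SequenceRecord(id=header, residues=seq, circular=circular))

        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0]
                chunks = []
            else:
                if header is None:
                    raise FormatError("sequence data before first FASTA header")
                chunks.append(line)
        flush()
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(path, records: Iterable[SequenceRecord], width: int = 70) -> None:
    """Write records as FASTA, ``width`` residues per line (byte-deterministic)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Annotation I/O
# ---------------------------------------------------------------------------

_CLASS_TO_GFF = {"protein": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}
_GFF_TO_CLASS = {v: k for k, v in _CLASS_TO_GFF.items()}


def _order_parts_5p(parts: list[GenomeInterval]) -> list[GenomeInterval]:
    """Order exons 5'→3' on the coding strand (single-strand genes only)."""
    strands = {p.strand for p in parts}
    if len(strands) > 1:
        return parts  # trans-spliced: keep declared order
    rev = strands == {"-"}
    return sorted(parts, key=lambda p: p.start, reverse=rev)


def read_annotation(path, dialect: str = "gff3", genome_length: int | None = None) -> list[GeneFeature]:
    """Read gene features from GFF3 or a minimal tab-separated feature table.

    File coordinates are 1-based inclusive in both dialects and are converted
    to internal 0-based half-open.  Multi-exon genes are grouped into one
    feature with exons ordered 5'→3' on the coding strand.
    """
    if dialect == "gff3":
        return _read_gff3(path, genome_length)
    if dialect == "feature_table":
        return _read_feature_table(path, genome_length)
    raise ValueError(f"unknown dialect {dialect!r}")


def _check_part(name: str, start1: int, end1: int, genome_length: int | None) -> None:
    """Validate a 1-based inclusive exon range against sequence bounds."""
    if end1 < start1:
        raise ValidationError(f"gene {name!r}: exon of non-positive length ({start1}..{end1})")
    if start1 < 1:
        raise ValidationError(f"gene {name!r}: exon start {start1} < 1")
    if genome_length is not None and end1 > genome_length:
        raise ValidationError(
            f"gene {name!r}: exon end {end1} outside sequence of length {genome_length}"
        )
    return None  # placeholder, strand filled by caller


def _read_gff3(path, genome_length: int | None) -> list[GeneFeature]:
    groups: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            _, _, ftype, start1, end1, _, strand, _, attrs = cols
            if ftype not in _GFF_TO_CLASS:
                continue
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if kv and "=" in kv
            )
            name = attr.get("ID") or attr.get("Parent")
            if name is None:
                raise FormatError(f"{path}:{lineno}: feature without ID/Parent")
            # one gene may appear as several copies (IR duplication): suffix #copy
            s1, e1 = int(start1), int(end1)
            _check_part(name, s1, e1, genome_length)
            iv = GenomeInterval(s1 - 1, e1, strand=strand)  # 1-based → 0-based half-open
            g = groups.setdefault(
                name,
                {
                    "class": _GFF_TO_CLASS[ftype],
                    "parts": [],
                    "pseudo": attr.get("pseudo", "false").lower() == "true",
                    "anticodon": attr.get("anticodon"),
                },
            )
            g["parts"].append(iv)
            if name not in order:
                order.append(name)
    feats = []
    for name in order:
        g = groups[name]
        base = name.split("#", 1)[0]
        feats.append(
            GeneFeature(
                name=base,
                gene_class=g["class"],
                parts=tuple(_order_parts_5p(g["parts"])),
                pseudo=g["pseudo"],
                anticodon=g["anticodon"],
            )
        )
    return feats


def _read_feature_table(path, genome_length: int | None) -> list[GeneFeature]:
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 5:
                raise FormatError(f"{path}:{lineno}: expected ≥5 tab-separated columns")
            name, gclass, strand, ranges, pseudo = cols[:5]
            anticodon = cols[5] if len(cols) > 5 and cols[5] else None
            parts = []
            for rng in ranges.split(","):
                s1, e1 = (int(x) for x in rng.split(".."))
                _check_part(name, s1, e1, genome_length)
                parts.append(GenomeInterval(s1 - 1, e1, strand=strand))
            feats.append(
                GeneFeature(
                    name=name,
                    gene_class=gclass,
                    parts=tuple(_order_parts_5p(parts)),
                    pseudo=pseudo.lower() in ("1", "true", "yes"),
                    anticodon=anticodon,
                )
            )
    return feats


def write_annotation(path, features: Sequence[GeneFeature], dialect: str = "gff3",
                     seqid: str = "genome") -> None:
    """Write features in the given dialect (1-based inclusive coordinates)."""
    if dialect == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            counts: dict[str, int] = {}
            for f in features:
                counts[f.name] = counts.get(f.name, 0) + 1
                name = f.name if counts[f.name] == 1 else f"{f.name}#{counts[f.name]}"
                for p in f.parts:
                    attrs = [f"ID={name}"]
                    if f.pseudo:
                        attrs.append("pseudo=true")
                    if f.anticodon:
                        attrs.append(f"anticodon={f.anticodon}")
                    fh.write(
                        "\t".join(
                            [
                                seqid, "plastokit", _CLASS_TO_GFF[f.gene_class],
                                str(p.start + 1), str(p.end), ".", p.strand, ".",
                                ";".join(attrs),
                            ]
                        )
                        + "\n"
                    )
    elif dialect == "feature_table":
        with open(path, "w") as fh:
            for f in features:
                ranges = ",".join(f"{p.start + 1}..{p.end}" for p in f.parts)
                strand = f.parts[0].strand
                fh.write(
                    "\t".join(
                        [f.name, f.gene_class, strand, ranges,
                         "true" if f.pseudo else "false", f.anticodon or ""]
                    )
                    + "\n"
                )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Sequence operations
# ---------------------------------------------------------------------------

def extract_feature_sequence(record: SequenceRecord, feature: GeneFeature) -> str:
    """Spliced coding-strand sequence of a feature.

    Exon sequences are taken in the declared (5'→3') part order, each
    reverse-complemented when its strand is '-'; origin-wrapping exons are
    allowed only on circular records.
    """
    return "".join(record.slice(p) for p in feature.parts)


def gc_content(seq: str) -> float:
    """GC percentage over unambiguous bases; N is excluded entirely."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    denom = gc + seq.count("A") + seq.count("T")
    if denom == 0:
        raise ValueError("GC content undefined: no unambiguous bases")
    return 100.0 * gc / denom
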