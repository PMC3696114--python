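"""Nuclear plastid DNA (NUPT) profiling.

Plastome fragments transferred to the nucleus are found by comparing the
plastome — with one inverted-repeat copy removed, so IR-derived insertions
are not double-counted — against nuclear chromosomes, keeping hits strictly
longer than 100 bp with e-value strictly below 1e-5.  A per-base insertion
value over the plastome counts, for every plastid base, how many retained
hits cover it; for display the IR values are halved and mirrored onto both
IR copies.  Per-chromosome summaries merge overlapping nuclear intervals
before summing bases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import local_align
from .model import GenomeInterval, RegionPartition, SequenceRecord, ValidationError

__all__ = [
    "InsertionHit",
    "InsertionProfile",
    "strip_one_ir",
    "map_back_to_full",
    "find_insertions",
    "insertion_profile",
    "chromosome_summary",
    "read_blast6",
    "write_blast6",
]


@dataclass(frozen=True)
class InsertionHit:
    """One plastome→nucleus hit (plastome side in IR-stripped coordinates)."""

    plastome_interval: GenomeInterval
    chromosome: str
    nuclear_interval: GenomeInterval
    identity: float
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValidationError("negative e-value")

    @property
    def length(self) -> int:
        return self.plastome_interval.end - self.plastome_interval.start


@dataclass(frozen=True)
class InsertionProfile:
    """Per-base insertion values over the stripped and full plastome."""

    stripped_values: np.ndarray  # int, length = LSC+IRb+SSC
    display_values: np.ndarray  # float, length = full genome, IRs halved/mirrored
    covered_fraction: float  # percent of stripped bases with value > 0


def strip_one_ir(record: SequenceRecord, partition: RegionPartition) -> SequenceRecord:
    """LSC+IRb+SSC concatenation (IRa removed), canonical orientation required.

    Calling it again on an already-stripped record fails the length check,
    so double stripping is rejected.
    """
    n = partition.genome_length
    if len(record.residues) != n:
        raise ValidationError(
            f"record length {len(record.residues)} does not match partition "
            f"genome length {n} (already stripped?)"
        )
    if partition.lsc.start != 0 or partition.ira.end != n or any(
        r.wraps_origin for r in (partition.lsc, partition.irb, partition.ssc, partition.ira)
    ):
        raise ValidationError("canonical LSC,IRb,SSC,IRa orientation required")
    stripped = record.residues[: partition.ssc.end]
    return SequenceRecord(id=record.id + "|IR-stripped", residues=stripped, circular=False)


def map_back_to_full(
    interval: GenomeInterval, partition: RegionPartition
) -> list[GenomeInterval]:
    """Map a stripped-coordinate interval onto the full genome.

    Positions in LSC/SSC map to themselves; IRb positions map to both IR
    copies (the IRa image is the reverse-complement mirror).
    """
    n = partition.genome_length
    out = [GenomeInterval(interval.start, interval.end, strand=interval.strand)]
    irb = partition.irb
    s = max(interval.start, irb.start)
    e = min(interval.end, irb.end)
    if s < e:
        off0, off1 = s - irb.start, e - irb.start
        ir_len = partition.ir_length
        ms = partition.ira.start + (ir_len - off1)
        me = partition.ira.start + (ir_len - off0)
        out.append(GenomeInterval(ms, me, strand="-" if interval.strand == "+" else "+"))
    return out


def find_insertions(
    nuclear: list[SequenceRecord] | None = None,
    query: SequenceRecord | None = None,
    hits_file: str | None = None,
    min_len: int = 100,
    max_e: float = 1e-5,
    seed_k: int = 21,
) -> list[InsertionHit]:
    """Find plastome insertions in nuclear chromosomes.

    Either align ``query`` (the IR-stripped plastome) against ``nuclear``
    chromosomes with the internal aligner, or parse a tabular (BLAST-6) hit
    file whose e-values are trusted.  Filters are strict: alignment length
    > ``min_len`` and e-value < ``max_e``.
    """
    if hits_file is not None:
        raw = read_blast6(hits_file)
    elif nuclear is not None and query is not None:
        raw = []
        for chrom in nuclear:
            for h in local_align(query.residues, chrom.residues, k=seed_k):
                raw.append(
                    InsertionHit(
                        plastome_interval=GenomeInterval(h.q0, h.q1, strand=h.strand),
                        chromosome=chrom.id,
                        nuclear_interval=GenomeInterval(h.t0, h.t1),
                        identity=h.identity,
                        evalue=h.evalue,
                        bit_score=float(h.score),
                    )
                )
    else:
        raise ValueError("provide either sequences (nuclear + query) or a hits file")
    return [h for h in raw if h.length > min_len and h.evalue < max_e]


def insertion_profile(
    hits: list[InsertionHit],
    plastome: SequenceRecord,
    partition: RegionPartition,
) -> InsertionProfile:
    """Per-base insertion value over the plastome.

    value(b) = number of retained hits whose plastome interval covers base b,
    computed on the IR-stripped coordinate system; the covered fraction is
    the percentage of stripped bases with a positive value.  The display
    vector projects IRb values at half weight onto both IR copies.
    """
    n = partition.genome_length
    stripped_len = partition.ssc.end
    values = np.zeros(stripped_len, dtype=np.int64)
    for h in hits:
        iv = h.plastome_interval
        if iv.end > stripped_len or iv.start < 0:
            raise ValidationError(
                f"hit [{iv.start},{iv.end}) outside stripped plastome of "
                f"length {stripped_len}"
            )
        values[iv.start : iv.end] += 1

    display = np.zeros(n, dtype=float)
    display[: partition.irb.start] = values[: partition.irb.start]
    display[partition.ssc.start : partition.ssc.end] = values[
        partition.ssc.start : partition.ssc.end
    ]
    irb_vals = values[partition.irb.start : partition.irb.end].astype(float) / 2.0
    display[partition.irb.start : partition.irb.end] = irb_vals
    display[partition.ira.start : partition.ira.end] = irb_vals[::-1]

    covered = 100.0 * float((values > 0).sum()) / stripped_len
    return InsertionProfile(values, display, covered)


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def chromosome_summary(
    hits: list[InsertionHit],
    nuclear_lengths: dict[str, int],
) -> "pd.DataFrame":
    """Per-chromosome hit counts and cumulative covered nuclear bases.

    Overlapping nuclear hit intervals are merged before summing.  Adds the
    per-chromosome share of all insertion bases (percent) and the per-mille
    of the nuclear genome covered, plus a totals row.
    """
    import pandas as pd

    by_chrom: dict[str, list[InsertionHit]] = {c: [] for c in nuclear_lengths}
    for h in hits:
        if h.chromosome not in by_chrom:
            raise ValidationError(f"hit on unknown chromosome {h.chromosome!r}")
        by_chrom[h.chromosome].append(h)

    rows = []
    for chrom in sorted(nuclear_lengths):
        hs = by_chrom[chrom]
        merged = merge_intervals(
            [(h.nuclear_interval.start, h.nuclear_interval.end) for h in hs]
        )
        nb_bases = sum(e - s for s, e in merged)
        rows.append({"chromosome": chrom, "n_hits": len(hs), "n_bases": nb_bases})
    df = pd.DataFrame(rows)
    total_bases = int(df["n_bases"].sum())
    total_nuclear = sum(nuclear_lengths.values())
    df["pct_of_insertions"] = np.where(
        total_bases > 0, 100.0 * df["n_bases"] / max(total_bases, 1), 0.0
    )
    df["permille_of_chromosome"] = 1000.0 * df["n_bases"] / df["chromosome"].map(
        nuclear_lengths
    )
    totals = {
        "chromosome": "total",
        "n_hits": int(df["n_hits"].sum()),
        "n_bases": total_bases,
        "pct_of_insertions": float(df["pct_of_insertions"].sum()),
        "permille_of_chromosome": 1000.0 * total_bases / total_nuclear,
    }
    return pd.concat([df, pd.DataFrame([totals])], ignore_index=True)


# ---------------------------------------------------------------------------
# BLAST-6 tabular I/O (qseqid sseqid pident length mismatch gapopen
#                      qstart qend sstart send evalue bitscore)
# ---------------------------------------------------------------------------

def read_blast6(path) -> list[InsertionHit]:
    """Read tabular hits; 1-based inclusive file coordinates, strand from
    subject coordinate order."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            qstart, qend = int(f[6]), int(f[7])
            sstart, send = int(f[8]), int(f[9])
            strand = "+" if send >= sstart else "-"
            if strand == "-":
                sstart, send = send, sstart
            out.append(
                InsertionHit(
                    plastome_interval=GenomeInterval(qstart - 1, qend, strand=strand),
                    chromosome=f[1],
                    nuclear_interval=GenomeInterval(sstart - 1, send),
                    identity=float(f[2]),
                    evalue=float(f[10]),
                    bit_score=float(f[11]),
                )
            )
    return out


def write_blast6(path, hits: list[InsertionHit], query_id: str = "plastome") -> None:
    with open(path, "w") as fh:
        for h in hits:
            iv, niv = h.plastome_interval, h.nuclear_interval
            length = iv.end - iv.start
            mism = round(length * (1 - h.identity / 100.0))
            sstart, send = niv.start + 1, niv.end
            if iv.strand == "-":
                sstart, send = send, sstart
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        query_id, h.chromosome, f"{h.identity:.2f}", length, mism, 0,
                        iv.start + 1, iv.end, sstart, send,
                        f"{h.evalue:.2e}", f"{h.bit_score:.1f}",
                    )
                )
                + "\n"
            )
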