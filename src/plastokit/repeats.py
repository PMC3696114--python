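"""Tandem repeat mining: microsatellites (MISA-style thresholds) and minisatellites.

Both classes are detected as maximal *perfect* tandem runs of a primitive
unit.  Microsatellites use per-unit-length minimum copy thresholds
(default 10, 5, 4, 3, 3, 3 full copies for units of 1–6 bp); minisatellites
are units of ≥10 bp repeated at least twice, with a partial final copy
counted fractionally.  Overlapping candidates within a class are resolved
deterministically (longest array first, then smallest start), so no two
reported loci of the same class overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .model import GenomeInterval, RegionPartition, revcomp

__all__ = [
    "RepeatLocus",
    "MICRO_MIN_REPEATS",
    "find_microsatellites",
    "find_minisatellites",
    "dedup_ir",
    "extract_flanks",
    "canonical_motif",
    "is_primitive",
]

#: minimum number of full copies for unit lengths 1..6
MICRO_MIN_REPEATS: tuple[int, ...] = (10, 5, 4, 3, 3, 3)


def is_primitive(motif: str) -> bool:
    """True when the motif is not itself a repetition of a shorter unit."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def canonical_motif(motif: str) -> str:
    """Lexicographic minimum over all rotations of the motif and its reverse complement."""
    rc = revcomp(motif)
    variants = [motif[i:] + motif[:i] for i in range(len(motif))]
    variants += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(variants)


@dataclass(frozen=True)
class RepeatLocus:
    """A perfect tandem array: unit motif, copy number (rational), class, region."""

    interval: GenomeInterval
    unit: str
    copies: float
    repeat_class: str  # {micro, mini}
    region: str | None = None
    junction_spanning: bool = False

    def __post_init__(self) -> None:
        u = len(self.unit)
        length = self.interval.end - self.interval.start
        if self.repeat_class == "micro" and not 1 <= u <= 6:
            raise ValueError("microsatellite unit length must be 1–6")
        if self.repeat_class == "mini" and u < 10:
            raise ValueError("minisatellite unit length must be ≥10")
        if not (self.copies * u <= length < (self.copies + 1) * u):
            raise ValueError("copies inconsistent with interval length")

    @property
    def unit_len(self) -> int:
        return len(self.unit)

    @property
    def canonical(self) -> str:
        return canonical_motif(self.unit)


def _maximal_runs(seq: str, unit_len: int) -> list[tuple[int, int]]:
    """All maximal perfect tandem runs [start, end) of the given period
    whose starting motif is primitive and which span ≥ 2 units' worth
    of bases... callers apply their own copy thresholds."""
    n = len(seq)
    runs = []
    i = 0
    while i + unit_len <= n:
        motif = seq[i : i + unit_len]
        # left-maximality: a run of this period starting earlier covers i
        if i > 0 and seq[i - 1] == seq[i - 1 + unit_len]:
            i += 1
            continue
        if not is_primitive(motif):
            i += 1
            continue
        j = i + unit_len
        while j < n and seq[j] == seq[j - unit_len]:
            j += 1
        if j - i >= 2 * unit_len:
            runs.append((i, j))
            i = j - unit_len + 1  # next run of this period starts after
        else:
            i += 1
    return runs


def _resolve_overlaps(loci: list[RepeatLocus]) -> list[RepeatLocus]:
    """Greedy selection: longest array first, then smallest start, then shortest unit."""
    chosen: list[RepeatLocus] = []
    for loc in sorted(
        loci,
        key=lambda l: (-(l.interval.end - l.interval.start), l.interval.start, l.unit_len),
    ):
        if all(
            loc.interval.end <= c.interval.start or c.interval.end <= loc.interval.start
            for c in chosen
        ):
            chosen.append(loc)
    return sorted(chosen, key=lambda l: l.interval.start)


def find_microsatellites(
    sequence: str, min_repeats: tuple[int, ...] = MICRO_MIN_REPEATS
) -> list[RepeatLocus]:
    """Scan for microsatellites of unit length 1–6.

    A maximal perfect run is reported under its smallest primitive unit when
    its number of *full* copies reaches the threshold for that unit length;
    runs contained in a longer reported run of a different unit are
    suppressed by the overlap-resolution policy.
    """
    sequence = sequence.upper()
    cands = []
    for u in range(1, 7):
        for s, e in _maximal_runs(sequence, u):
            full = (e - s) // u
            if full >= min_repeats[u - 1]:
                cands.append(
                    RepeatLocus(
                        interval=GenomeInterval(s, e),
                        unit=sequence[s : s + u],
                        copies=(e - s) / u,
                        repeat_class="micro",
                    )
                )
    return _resolve_overlaps(cands)


def find_minisatellites(
    sequence: str, min_unit: int = 10, max_unit: int = 60, min_copies: float = 2.0
) -> list[RepeatLocus]:
    """Scan for minisatellites: primitive units of ≥10 bp tandemly repeated
    at least ``min_copies`` times (the final partial copy counts fractionally)."""
    if min_unit < 10:
        raise ValueError("min_unit must be ≥ 10")
    sequence = sequence.upper()
    cands = []
    for u in range(min_unit, max_unit + 1):
        for s, e in _maximal_runs(sequence, u):
            copies = (e - s) / u
            if copies >= min_copies:
                cands.append(
                    RepeatLocus(
                        interval=GenomeInterval(s, e),
                        unit=sequence[s : s + u],
                        copies=copies,
                        repeat_class="mini",
                    )
                )
    return _resolve_overlaps(cands)


def assign_regions(
    loci: list[RepeatLocus], partition: RegionPartition
) -> list[RepeatLocus]:
    """Label each locus with its region; junction-spanning loci are flagged
    and labelled by the region holding the locus midpoint."""
    n = partition.genome_length
    out = []
    for loc in loci:
        region = partition.region_of(loc.interval)
        if region is None:
            mid = (loc.interval.start + loc.interval.end) // 2 % n
            point = GenomeInterval(mid, mid + 1)
            region = partition.region_of(point)
            out.append(replace(loc, region=region, junction_spanning=True))
        else:
            out.append(replace(loc, region=region))
    return out


def dedup_ir(loci: list[RepeatLocus], partition: RegionPartition) -> list[RepeatLocus]:
    """Count IR-duplicated repeats once: drop each IRa locus whose
    reverse-complement twin sits at the mirrored offset in IRb.

    Requires canonical orientation.  Junction-spanning loci are kept (and
    remain flagged); LSC/SSC loci are untouched.
    """
    n = partition.genome_length
    labelled = assign_regions(loci, partition)
    ira, irb = partition.ira, partition.irb
    irb_keys = set()
    for loc in labelled:
        if loc.region == "IRb" and not loc.junction_spanning:
            irb_keys.add(
                (loc.interval.start - irb.start, loc.interval.end - irb.start,
                 canonical_motif(loc.unit))
            )
    ir_len = partition.ir_length
    out = []
    for loc in labelled:
        if loc.region == "IRa" and not loc.junction_spanning:
            d0 = loc.interval.start - ira.start
            d1 = loc.interval.end - ira.start
            mirrored = (ir_len - d1, ir_len - d0, canonical_motif(loc.unit))
            if mirrored in irb_keys:
                continue
        out.append(loc)
    return out


def extract_flanks(
    locus: RepeatLocus, sequence: str, flank_len: int = 200, circular: bool = False
) -> tuple[str, str]:
    """Flanking sequences of a locus (for downstream primer design).

    On circular sequences flanks wrap the origin; on linear sequences they
    are clipped at the ends.  A flank longer than the whole genome is an error.
    """
    n = len(sequence)
    if flank_len > n:
        raise ValueError("flank longer than the sequence")
    s, e = locus.interval.start, locus.interval.end
    if flank_len == 0:
        return "", ""
    if circular:
        d = sequence + sequence
        ls = (s - flank_len) % n
        return d[ls : ls + flank_len], d[e % n : e % n + flank_len]
    return sequence[max(0, s - flank_len) : s], sequence[e : min(n, e + flank_len)]
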