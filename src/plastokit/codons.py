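"""Codon usage statistics for plastid protein-coding genes.

Implements codon counting over CDS sets, relative synonymous codon usage
(RSCU = a codon's count divided by the mean count of its synonymous family),
within-amino-acid codon frequencies, and strict Watson–Crick codon–anticodon
recognition analysis for the tRNA complement.

Conventions (chosen for arithmetic consistency of the published plastome
tables): terminal stop codons are counted and the three stops form one
synonymous family; pseudogenes are excluded by the caller; IR-duplicated
genes contribute once.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

from .model import GeneFeature, revcomp

__all__ = [
    "GENETIC_CODE",
    "SYNONYMOUS_FAMILIES",
    "CodonCounts",
    "CodonUsageRow",
    "count_codons",
    "rscu",
    "aa_frequency",
    "usage_table",
    "anticodon_recognition",
    "round_half_up",
]

_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*W"  # TTT..TGG
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)

#: Standard bacterial/plastid genetic code, codon → one-letter amino acid ('*' = stop).
GENETIC_CODE: dict[str, str] = {
    b1 + b2 + b3: _AA[16 * i + 4 * j + k]
    for i, b1 in enumerate(_BASES)
    for j, b2 in enumerate(_BASES)
    for k, b3 in enumerate(_BASES)
}

#: amino acid → tuple of synonymous codons (stops are the '*' family).
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon in sorted(GENETIC_CODE):
    SYNONYMOUS_FAMILIES.setdefault(GENETIC_CODE[_codon], tuple())
    SYNONYMOUS_FAMILIES[GENETIC_CODE[_codon]] += (_codon,)

STOP_CODONS = frozenset(SYNONYMOUS_FAMILIES["*"])


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (table convention), exact in decimal."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


class CodonUsageError(ValueError):
    pass


@dataclass(frozen=True)
class CodonCounts:
    """Frame-0 codon counts over a CDS set, terminal stops included."""

    counts: Mapping[str, int]
    total: int

    def __post_init__(self) -> None:
        if self.total != sum(self.counts.values()):
            raise CodonUsageError("total does not equal sum of counts")

    def __getitem__(self, codon: str) -> int:
        return self.counts.get(codon, 0)


@dataclass(frozen=True)
class CodonUsageRow:
    amino_acid: str
    codon: str
    count: int
    rscu: float
    freq_within_aa: float
    recognized_by_trna: bool
    most_common_in_aa: bool


def count_codons(
    cds_list: Iterable[str],
    names: Sequence[str] | None = None,
    allow_internal_stops: bool = False,
) -> CodonCounts:
    """Count frame-0 codons over CDS sequences (terminal stop included).

    Each CDS must have length divisible by 3; a CDS with an in-frame internal
    stop is rejected by name unless ``allow_internal_stops`` — the caller
    decides whether such genes are pseudogenes to exclude.
    """
    counts: dict[str, int] = {}
    total = 0
    for idx, cds in enumerate(cds_list):
        name = names[idx] if names is not None else f"cds_{idx}"
        cds = cds.upper()
        if len(cds) % 3:
            raise CodonUsageError(f"{name}: CDS length {len(cds)} not divisible by 3")
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        if not allow_internal_stops and any(c in STOP_CODONS for c in codons[:-1]):
            raise CodonUsageError(f"{name}: internal stop codon")
        for c in codons:
            if c not in GENETIC_CODE:
                raise CodonUsageError(f"{name}: ambiguous codon {c!r}")
            counts[c] = counts.get(c, 0) + 1
            total += 1
    return CodonCounts(counts=counts, total=total)


def rscu(counts: CodonCounts | Mapping[str, int]) -> dict[str, float]:
    """RSCU per codon: count divided by the mean count of its synonymous family.

    A family whose total count is zero gets RSCU 0 for all its members (the
    statistic is undefined there; 0 flags the degenerate case).
    """
    get = counts.__getitem__ if isinstance(counts, CodonCounts) else (
        lambda c: counts.get(c, 0)
    )
    out: dict[str, float] = {}
    for family in SYNONYMOUS_FAMILIES.values():
        total = sum(get(c) for c in family)
        if total == 0:
            for c in family:
                out[c] = 0.0
        else:
            mean = total / len(family)
            for c in family:
                out[c] = get(c) / mean
    return out


def aa_frequency(counts: CodonCounts | Mapping[str, int]) -> dict[str, float]:
    """Per-codon percentage within its amino-acid family (sums to 100)."""
    get = counts.__getitem__ if isinstance(counts, CodonCounts) else (
        lambda c: counts.get(c, 0)
    )
    out: dict[str, float] = {}
    for family in SYNONYMOUS_FAMILIES.values():
        total = sum(get(c) for c in family)
        for c in family:
            out[c] = 100.0 * get(c) / total if total else float("nan")
    return out


def most_common_codons(counts: CodonCounts | Mapping[str, int]) -> set[str]:
    """Codons with the maximal count in their family (all tied codons flagged)."""
    get = counts.__getitem__ if isinstance(counts, CodonCounts) else (
        lambda c: counts.get(c, 0)
    )
    out: set[str] = set()
    for family in SYNONYMOUS_FAMILIES.values():
        mx = max(get(c) for c in family)
        if mx > 0:
            out.update(c for c in family if get(c) == mx)
    return out


def usage_table(
    counts: CodonCounts | Mapping[str, int],
    recognized: frozenset[str] | set[str] = frozenset(),
) -> list[CodonUsageRow]:
    """Full 64-row usage table (unrounded RSCU/frequency), codon-sorted per family."""
    r = rscu(counts)
    f = aa_frequency(counts)
    common = most_common_codons(counts)
    get = counts.__getitem__ if isinstance(counts, CodonCounts) else (
        lambda c: counts.get(c, 0)
    )
    rows = []
    for aa, family in SYNONYMOUS_FAMILIES.items():
        for c in family:
            rows.append(
                CodonUsageRow(
                    amino_acid=aa,
                    codon=c,
                    count=get(c),
                    rscu=r[c],
                    freq_within_aa=f[c],
                    recognized_by_trna=c in recognized,
                    most_common_in_aa=c in common,
                )
            )
    return rows


def anticodon_recognition(
    trna_features: Iterable[GeneFeature] | Iterable[str],
    counts: CodonCounts | Mapping[str, int] | None = None,
) -> dict:
    """Codons recognized by a tRNA set under strict Watson–Crick pairing.

    Accepts tRNA features carrying anticodons (5'→3') or plain anticodon
    strings; the recognized codon is the reverse complement of the anticodon
    (no wobble).  When codon counts are supplied, each recognized codon is
    joined with its most-common-in-family flag, and the overlap count is the
    number of recognized codons that are also the most common of a family
    with more than one member (single-codon families carry no usage signal).
    """
    anticodons: list[str] = []
    for t in trna_features:
        ac = t if isinstance(t, str) else t.anticodon
        if ac is None:
            raise CodonUsageError(
                f"tRNA {getattr(t, 'name', t)!r} has no anticodon"
            )
        ac = ac.upper().replace("U", "T")
        if len(ac) != 3 or set(ac) - set("ACGT"):
            raise CodonUsageError(f"bad anticodon {ac!r}")
        anticodons.append(ac)
    codons = {revcomp(ac) for ac in anticodons}
    result: dict = {"recognized_codons": codons, "n_anticodons": len(set(anticodons))}
    if counts is not None:
        common = most_common_codons(counts)
        multi = {
            c
            for fam in SYNONYMOUS_FAMILIES.values()
            if len(fam) > 1
            for c in fam
        }
        result["most_common_flags"] = {c: c in common for c in sorted(codons)}
        result["n_recognized_most_common"] = len(codons & common & multi)
    return result
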