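"""Published reference values for the Musa acuminata chloroplast genome (ENA HF677508).

These are inputs, not expected outputs: the codon-usage table drives the
RSCU/frequency computations and the codon–anticodon recognition analysis; the
nuclear-insertion and marker-allele tables drive the corresponding summary
statistics.  Derived quantities (RSCU, within-amino-acid frequencies, group
means) are always recomputed, never read from here.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Codon usage of the 79 distinct protein-coding genes (23,199 codons).
# (amino_acid, codon, count, published RSCU, published frequency %,
#  recognized) — ``recognized`` marks codons that are the strict
# Watson–Crick complement of an anticodon of a tRNA encoded in the plastome.
# ---------------------------------------------------------------------------
CODON_USAGE: list[tuple[str, str, int, float, float, bool]] = [
    ("F", "TTT", 839, 1.28, 64.19, False),
    ("F", "TTC", 468, 0.72, 35.81, True),
    ("L", "TTA", 750, 1.91, 31.91, True),
    ("L", "TTG", 497, 1.27, 21.15, True),
    ("L", "CTT", 465, 1.19, 19.79, False),
    ("L", "CTC", 158, 0.40, 6.72, False),
    ("L", "CTA", 324, 0.83, 13.79, True),
    ("L", "CTG", 156, 0.40, 6.64, False),
    ("I", "ATT", 980, 1.47, 48.98, False),
    ("I", "ATC", 384, 0.58, 19.19, True),
    ("I", "ATA", 637, 0.96, 31.83, False),
    ("M", "ATG", 546, 1.00, 100.00, True),
    ("V", "GTT", 468, 1.42, 35.51, False),
    ("V", "GTC", 168, 0.51, 12.75, True),
    ("V", "GTA", 505, 1.53, 38.32, True),
    ("V", "GTG", 177, 0.54, 13.43, False),
    ("S", "TCT", 512, 1.72, 28.72, False),
    ("S", "TCC", 290, 0.98, 16.26, True),
    ("S", "TCA", 342, 1.15, 19.18, True),
    ("S", "TCG", 161, 0.54, 9.03, False),
    ("S", "AGT", 390, 1.31, 21.87, False),
    ("S", "AGC", 88, 0.30, 4.94, True),
    ("P", "CCT", 374, 1.57, 39.33, False),
    ("P", "CCC", 196, 0.82, 20.61, False),
    ("P", "CCA", 280, 1.18, 29.44, True),
    ("P", "CCG", 101, 0.42, 10.62, False),
    ("T", "ACT", 454, 1.54, 38.41, False),
    ("T", "ACC", 235, 0.80, 19.88, True),
    ("T", "ACA", 366, 1.24, 30.96, True),
    ("T", "ACG", 127, 0.43, 10.74, False),
    ("A", "GCT", 575, 1.85, 46.18, False),
    ("A", "GCC", 195, 0.63, 15.66, False),
    ("A", "GCA", 353, 1.13, 28.35, True),
    ("A", "GCG", 122, 0.39, 9.80, False),
    ("Y", "TAT", 682, 1.58, 78.75, False),
    ("Y", "TAC", 184, 0.42, 21.25, True),
    ("H", "CAT", 432, 1.55, 77.56, False),
    ("H", "CAC", 125, 0.45, 22.44, True),
    ("Q", "CAA", 640, 1.54, 77.11, True),
    ("Q", "CAG", 190, 0.46, 22.89, False),
    ("N", "AAT", 850, 1.55, 77.27, False),
    ("N", "AAC", 250, 0.45, 22.73, True),
    ("K", "AAA", 907, 1.51, 75.52, True),
    ("K", "AAG", 294, 0.49, 24.48, False),
    ("D", "GAT", 763, 1.61, 80.32, False),
    ("D", "GAC", 187, 0.39, 19.68, True),
    ("E", "GAA", 976, 1.50, 74.90, True),
    ("E", "GAG", 327, 0.50, 25.10, False),
    ("C", "TGT", 200, 1.49, 74.35, False),
    ("C", "TGC", 69, 0.51, 25.65, True),
    ("W", "TGG", 394, 1.00, 100.00, True),
    ("R", "CGT", 326, 1.39, 23.24, True),
    ("R", "CGC", 76, 0.33, 5.42, False),
    ("R", "CGA", 312, 1.33, 22.24, False),
    ("R", "CGG", 105, 0.45, 7.48, False),
    ("R", "AGA", 441, 1.89, 31.43, True),
    ("R", "AGG", 143, 0.61, 10.19, False),
    ("G", "GGT", 539, 1.38, 34.46, False),
    ("G", "GGC", 154, 0.39, 9.85, True),
    ("G", "GGA", 643, 1.64, 41.11, True),
    ("G", "GGG", 228, 0.58, 14.58, False),
    ("*", "TAA", 41, 1.56, 51.90, False),
    ("*", "TAG", 20, 0.76, 25.32, False),
    ("*", "TGA", 18, 0.68, 22.78, False),
]

CODON_COUNTS: dict[str, int] = {codon: n for _, codon, n, _, _, _ in CODON_USAGE}

#: Codons recognized (strict Watson–Crick) by the 28 distinct plastome tRNA anticodons.
RECOGNIZED_CODONS: frozenset[str] = frozenset(
    codon for _, codon, _, _, _, rec in CODON_USAGE if rec
)

#: Leucine codon counts, the largest synonymous family of the table.
LEUCINE_COUNTS: dict[str, int] = {
    c: CODON_COUNTS[c] for c in ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG")
}

# ---------------------------------------------------------------------------
# Plastome-derived insertions on the 11 nuclear chromosomes (hits >100 bp,
# e-value <1e-5): chromosome → (hit count, cumulative nuclear bases).
# ---------------------------------------------------------------------------
NUCLEAR_INSERTIONS: dict[str, tuple[int, int]] = {
    "chr01": (57, 10_468),
    "chr02": (24, 4_637),
    "chr03": (44, 9_629),
    "chr04": (63, 17_752),
    "chr05": (39, 6_993),
    "chr06": (83, 21_129),
    "chr07": (42, 10_838),
    "chr08": (44, 10_482),
    "chr09": (48, 11_125),
    "chr10": (60, 13_659),
    "chr11": (59, 17_779),
}

# ---------------------------------------------------------------------------
# BAC-end mate-pair orientation counts on the form-A reference
# (LSC mate first): FR/RF support the assembled SSC orientation (form A),
# FF/RR support the flipped SSC (form B).
# ---------------------------------------------------------------------------
BES_ORIENTATION_COUNTS: dict[str, int] = {"FR": 29, "RF": 48, "FF": 29, "RR": 74}

# ---------------------------------------------------------------------------
# Distinct SSR alleles per marker within nested accession groups
# (Musaceae ⊇ Eumusa ⊇ M. acuminata ssp ⊇ chloroplastic group II).
# ---------------------------------------------------------------------------
MARKER_GROUPS: tuple[str, ...] = ("Musaceae", "Eumusa", "M_acuminata", "cp_group_II")

MARKER_ALLELE_COUNTS: dict[str, tuple[int, int, int, int]] = {
    "mMaCIRcp01": (4, 4, 4, 3),
    "mMaCIRcp02": (2, 2, 2, 2),
    "mMaCIRcp19": (4, 3, 2, 1),
    "mMaCIRcp20": (5, 4, 3, 3),
    "mMaCIRcp25": (4, 4, 4, 4),
    "mMaCIRcp27": (4, 3, 3, 2),
    "mMaCIRcp29": (4, 3, 2, 1),
    "mMaCIRcp30": (5, 4, 3, 2),
    "mMaCIRcp31": (3, 3, 2, 1),
    "mMaCIRcp32": (4, 3, 3, 3),
    "mMaCIRcp33": (5, 5, 5, 4),
    "mMaCIRcp34": (4, 3, 2, 2),
}
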