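"""SSC-orientation isoform inference from LSC↔SSC-bridging mate pairs.

Plastomes co-exist as two "flip-flop" conformations that differ only in the
orientation of the SSC relative to the LSC.  Mate pairs (e.g. BAC-end
sequences) with one mate wholly in the LSC and the other wholly in the SSC
are informative: on the form-A reference, pairs from form A map in
Forward/Reverse or Reverse/Forward orientation while pairs from form B (SSC
reverse-complemented) map Forward/Forward or Reverse/Reverse.  Classes are
ordered LSC mate first, which makes FR vs RF reproducible; only the
{FR,RF} vs {FF,RR} split carries the biological signal.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .model import GenomeInterval, RegionPartition

__all__ = [
    "MateAlignment",
    "PairClassification",
    "FormSummary",
    "classify_mate_pair",
    "summarize_forms",
    "relabel_reference_form",
]


@dataclass(frozen=True)
class MateAlignment:
    """One mate's alignment to the form-A reference."""

    mate_id: str
    interval: GenomeInterval
    strand: str  # {F, R}
    identity: float  # percent
    aligned_fraction: float
    multi_mapping: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.identity <= 100:
            raise ValueError("identity must be a percentage")
        if not 0 < self.aligned_fraction <= 1:
            raise ValueError("aligned fraction must be in (0,1]")
        if self.strand not in ("F", "R"):
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class PairClassification:
    pair_id: str
    orientation_class: str  # {FR, RF, FF, RR, filtered}
    filter_reason: str | None = None
    regions: tuple[str | None, str | None] = (None, None)


@dataclass(frozen=True)
class FormSummary:
    counts: dict
    form_a_support: int
    form_b_support: int
    n_classified: int
    form_b_fraction: float
    ci_low: float
    ci_high: float
    ci_level: float
    verdict: str  # {single_form_A, single_form_B, two_forms, no_informative_pairs}


def classify_mate_pair(
    mate1: MateAlignment,
    mate2: MateAlignment,
    partition: RegionPartition,
    min_identity: float = 90.0,
    min_cov: float = 0.60,
    pair_id: str | None = None,
) -> PairClassification:
    """Classify one mate pair by orientation on the form-A reference.

    A pair is informative only when both mates pass the identity/coverage
    filters and one mate lies wholly in the SSC while the other lies wholly
    in the LSC; mates overlapping an IR (or any junction) are ambiguous
    because the repeat makes their placement unreliable.  The class string
    orders the LSC mate's strand first.  Classification is symmetric in mate
    order.
    """
    pid = pair_id or f"{mate1.mate_id}/{mate2.mate_id}"

    def fail(reason: str, regions=(None, None)) -> PairClassification:
        return PairClassification(pid, "filtered", reason, regions)

    for m in (mate1, mate2):
        if m.multi_mapping:
            return fail("multi-mapping")
        if m.identity < min_identity:
            return fail("identity")
        if m.aligned_fraction < min_cov:
            return fail("coverage")

    r1 = partition.region_of(mate1.interval)
    r2 = partition.region_of(mate2.interval)
    regions = (r1, r2)
    n = partition.genome_length
    for r, m in ((r1, mate1), (r2, mate2)):
        touches_ir = partition.irb.overlaps(m.interval, n) or partition.ira.overlaps(
            m.interval, n
        )
        if r in ("IRa", "IRb") or (r is None and touches_ir):
            return fail("IR-ambiguous", regions)
        if r is None:
            return fail("junction-straddling", regions)
    if {r1, r2} != {"LSC", "SSC"}:
        return fail("region", regions)

    lsc_mate, ssc_mate = (mate1, mate2) if r1 == "LSC" else (mate2, mate1)
    cls = lsc_mate.strand + ssc_mate.strand  # e.g. FR
    return PairClassification(pid, cls, None, regions)


def summarize_forms(
    classifications: list[PairClassification],
    ci_level: float = 0.95,
    min_support: int = 3,
) -> FormSummary:
    """Summarize orientation classes into form support and a verdict.

    Form A is supported by FR+RF pairs, form B by FF+RR; the form-B fraction
    gets an exact (Clopper–Pearson) binomial confidence interval.  Verdict
    ``two_forms`` requires at least ``min_support`` pairs for each form.
    """
    counts = {c: 0 for c in ("FR", "RF", "FF", "RR")}
    for cl in classifications:
        if cl.orientation_class in counts:
            counts[cl.orientation_class] += 1
    a = counts["FR"] + counts["RF"]
    b = counts["FF"] + counts["RR"]
    total = a + b
    if total == 0:
        return FormSummary(counts, 0, 0, 0, float("nan"), float("nan"),
                           float("nan"), ci_level, "no_informative_pairs")
    frac = b / total
    lo, hi = _clopper_pearson(b, total, ci_level)
    if a >= min_support and b >= min_support:
        verdict = "two_forms"
    elif b > a:
        verdict = "single_form_B"
    else:
        verdict = "single_form_A"
    return FormSummary(counts, a, b, total, frac, lo, hi, ci_level, verdict)


def _clopper_pearson(k: int, n: int, level: float) -> tuple[float, float]:
    alpha = 1 - level
    lo = 0.0 if k == 0 else stats.beta.ppf(alpha / 2, k, n - k + 1)
    hi = 1.0 if k == n else stats.beta.ppf(1 - alpha / 2, k + 1, n - k)
    return float(lo), float(hi)


def relabel_reference_form(classification: PairClassification) -> PairClassification:
    """Reinterpret a classification after reverse-complementing the SSC of the
    reference (declaring form B the reference): the SSC mate's strand flips,
    so FR↔FF and RF↔RR swap exactly."""
    swap = {"FR": "FF", "FF": "FR", "RF": "RR", "RR": "RF"}
    cls = classification.orientation_class
    if cls in swap:
        return PairClassification(
            classification.pair_id, swap[cls],
            classification.filter_reason, classification.regions,
        )
    return classification
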