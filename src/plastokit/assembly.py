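"""Reference-guided read binning and iterative contig-end elongation.

Plastid reads are extracted from a mixed read set by local-alignment
similarity to any related plastome (the reference need not be conspecific);
contigs are then grown outward by overlap consensus: each round gathers
reads whose prefix anchors (exactly or with ≤2 mismatches) onto the contig's
terminal window and extends by the base-wise majority of their overhangs,
stopping on lost support, on consensus ambiguity (the expected outcome at
single-copy/IR branch points), on circularization, or on the round cap.
Existing contig bases are never rewritten.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import best_local_score, local_align, MATCH
from .model import SequenceRecord, revcomp

__all__ = [
    "ElongationState",
    "bin_plastid_reads",
    "elongate_contig",
    "order_contigs",
]


def bin_plastid_reads(
    reads: list[SequenceRecord],
    reference_plastome: SequenceRecord,
    min_score_fraction: float = 0.5,
    seed_k: int = 11,
) -> list[SequenceRecord]:
    """Keep reads whose best local score against the (circularly doubled)
    reference reaches ``min_score_fraction`` of the read's maximal self-score.

    Both read strands are scored, so the decision is invariant to reverse
    complementation of a read.
    """
    if not reads:
        raise ValueError("empty read set")
    ref = reference_plastome.residues
    if reference_plastome.circular:
        ref = ref + ref
    kept = []
    for r in reads:
        self_score = MATCH * len(r.residues)
        if best_local_score(r.residues, ref, k=seed_k) >= min_score_fraction * self_score:
            kept.append(r)
    return kept


@dataclass
class ElongationState:
    contig: str
    rounds: list[dict] = field(default_factory=list)  # per-round extension log
    stop_reason: str = "max_rounds"  # {no_support, circularized, max_rounds, ambiguous}

    @property
    def total_extension(self) -> int:
        return sum(r["extended"] for r in self.rounds)


def _hamming_le(a: str, b: str, limit: int) -> bool:
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > limit:
                return False
    return True


def _collect_overhangs(
    contig: str, reads: list[str], window: int, min_overlap: int, max_anchor_mism: int
) -> list[str]:
    """Overhangs of reads whose prefix anchors a suffix of the contig.

    A read anchors when its prefix matches contig[-ov:] for some overlap
    ov in [min_overlap, window] with ≤ max_anchor_mism mismatches; the
    overhang is the rest of the read.  The longest anchoring overlap wins.
    """
    overhangs = []
    tail = contig[-window:]
    for read in reads:
        for ov in range(min(window, len(read)), min_overlap - 1, -1):
            if ov > len(contig):
                continue
            if _hamming_le(read[:ov], contig[-ov:], max_anchor_mism):
                if len(read) > ov:
                    overhangs.append(read[ov:])
                break
    return overhangs


def _consensus_step(
    overhangs: list[str], min_support: int, min_agree: float
) -> tuple[str, str | None]:
    """Base-wise majority extension; returns (extension, stop_reason_or_None)."""
    ext = []
    pos = 0
    while True:
        column = [o[pos] for o in overhangs if len(o) > pos]
        if len(column) < min_support:
            return "".join(ext), ("no_support" if pos == 0 else None)
        best = max("ACGT", key=column.count)
        agree = column.count(best) / len(column)
        if agree < min_agree:
            return "".join(ext), "ambiguous"
        ext.append(best)
        pos += 1


def elongate_contig(
    contig: str,
    reads: list[SequenceRecord] | list[str],
    window: int = 100,
    min_support: int = 5,
    min_agree: float = 0.8,
    max_rounds: int = 10000,
    min_overlap: int = 30,
    max_anchor_mismatch: int = 2,
) -> ElongationState:
    """Grow both contig ends by majority overlap consensus.

    Reads are used on both strands.  Per round the right end is extended
    from reads anchoring on the terminal window, then the left end (as the
    right end of the reverse complement).  Circularization is declared when
    the two ends overlap by at least ``window`` with ≤2 mismatches, and the
    duplicated overlap is trimmed.
    """
    seqs = [r.residues if isinstance(r, SequenceRecord) else r for r in reads]
    pool = seqs + [revcomp(s) for s in seqs]
    state = ElongationState(contig=contig)

    for rnd in range(max_rounds):
        extended_this_round = 0
        reasons = []
        for end in ("right", "left"):
            cur = state.contig if end == "right" else revcomp(state.contig)
            overhangs = _collect_overhangs(
                cur, pool, window, min_overlap, max_anchor_mismatch
            )
            ext, reason = _consensus_step(overhangs, min_support, min_agree)
            if ext:
                cur = cur + ext
                state.contig = cur if end == "right" else revcomp(cur)
                extended_this_round += len(ext)
            if reason:
                reasons.append(reason)
        state.rounds.append({"round": rnd, "extended": extended_this_round})

        # circularization: contig end overlaps contig start
        c = state.contig
        if len(c) > 2 * window:
            for ov in range(window, min(len(c) // 2, 3 * window)):
                if _hamming_le(c[-ov:], c[:ov], 2):
                    state.contig = c[:-ov]
                    state.stop_reason = "circularized"
                    return state
        if "ambiguous" in reasons and extended_this_round == 0:
            state.stop_reason = "ambiguous"
            return state
        if extended_this_round == 0:
            state.stop_reason = (
                "ambiguous" if "ambiguous" in reasons else "no_support"
            )
            return state
    state.stop_reason = "max_rounds"
    return state


def order_contigs(
    contigs: list[SequenceRecord],
    reference: SequenceRecord,
    partition=None,
    seed_k: int = 15,
) -> list[dict]:
    """Order and orient contigs along a reference plastome by best local hit.

    Contigs are placed by the reference midpoint of their best hit and
    oriented by its strand; contigs whose best placement falls inside an IR
    are flagged duplicated (their position is ambiguous between the two IR
    copies); contigs without any hit are reported unplaced.
    """
    placements = []
    for c in contigs:
        hits = local_align(c.residues, reference.residues, k=seed_k)
        if not hits:
            placements.append(
                {"contig": c.id, "placed": False, "midpoint": None,
                 "strand": None, "ir_duplicated": False}
            )
            continue
        h = hits[0]
        mid = (h.t0 + h.t1) // 2
        dup = False
        if partition is not None:
            from .model import GenomeInterval

            point = GenomeInterval(mid, mid + 1)
            region = partition.region_of(point)
            dup = region in ("IRa", "IRb")
            if region == "IRa":
                # report at the IRb slot: mirror the midpoint
                off = mid - partition.ira.start
                mid = partition.irb.start + (partition.ir_length - 1 - off)
        placements.append(
            {"contig": c.id, "placed": True, "midpoint": mid,
             "strand": h.strand, "ir_duplicated": dup}
        )
    placed = [p for p in placements if p["placed"]]
    unplaced = [p for p in placements if not p["placed"]]
    placed.sort(key=lambda p: p["midpoint"])
    return placed + unplaced
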