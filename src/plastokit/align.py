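"""Minimal ungapped seed-and-extend local aligner.

Exact k-mer seeds between query and target are extended on their diagonal in
both directions with an X-drop criterion; scores use BLASTN-like ungapped
scoring (match +2, mismatch -3) and are converted to e-values with
Karlin–Altschul scaling using the published ungapped constants for that
scoring (λ = 0.625, K = 0.41).  Substitution-divergence only — the synthetic
data this aligner is calibrated for plants substitutions, not indels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .model import revcomp

__all__ = ["LocalHit", "local_align", "best_local_score"]

MATCH = 2
MISMATCH = -3
LAMBDA = 0.625
K_PARAM = 0.41


@dataclass(frozen=True)
class LocalHit:
    """An ungapped local alignment between query [q0,q1) and target [t0,t1)."""

    q0: int
    q1: int
    t0: int
    t1: int
    strand: str  # query strand relative to target, {+,-}
    matches: int
    mismatches: int
    score: int
    evalue: float

    @property
    def length(self) -> int:
        return self.q1 - self.q0

    @property
    def identity(self) -> float:
        return 100.0 * self.matches / self.length


def _evalue(score: int, m: int, n: int) -> float:
    return K_PARAM * m * n * math.exp(-LAMBDA * score)


def _extend(q: str, t: str, qi: int, ti: int, k: int, xdrop: int) -> tuple[int, int, int, int]:
    """X-drop extension of an exact seed q[qi:qi+k] == t[ti:ti+k].

    Returns (q0, q1, matches, mismatches) of the best-scoring extent; the
    target extent follows from the common diagonal.
    """
    best_r = 0
    score = 0
    best_score = 0
    i = 0
    while qi + k + i < len(q) and ti + k + i < len(t):
        score += MATCH if q[qi + k + i] == t[ti + k + i] else MISMATCH
        i += 1
        if score > best_score:
            best_score, best_r = score, i
        elif score < best_score - xdrop:
            break
    best_l = 0
    score = 0
    best_score = 0
    i = 0
    while qi - 1 - i >= 0 and ti - 1 - i >= 0:
        score += MATCH if q[qi - 1 - i] == t[ti - 1 - i] else MISMATCH
        i += 1
        if score > best_score:
            best_score, best_l = score, i
        elif score < best_score - xdrop:
            break
    q0, q1 = qi - best_l, qi + k + best_r
    matches = sum(
        1 for a, b in zip(q[q0:q1], t[ti - best_l : ti + k + best_r]) if a == b
    )
    return q0, q1, matches, (q1 - q0) - matches


def _align_one_strand(
    query: str, target: str, index: dict, k: int, xdrop: int, strand: str,
    m: int, n: int,
) -> list[LocalHit]:
    hits: dict[tuple[int, int], LocalHit] = {}
    covered: dict[int, list[tuple[int, int]]] = {}  # diagonal -> query extents
    for qi in range(0, len(query) - k + 1):
        kmer = query[qi : qi + k]
        if "N" in kmer:
            continue
        for ti in index.get(kmer, ()):
            diag = ti - qi
            if any(a <= qi < b for a, b in covered.get(diag, ())):
                continue
            q0, q1, mt, mm = _extend(query, target, qi, ti, k, xdrop)
            covered.setdefault(diag, []).append((q0, q1))
            score = MATCH * mt + MISMATCH * mm
            t0 = q0 + diag
            hit = LocalHit(
                q0=q0, q1=q1, t0=t0, t1=t0 + (q1 - q0), strand=strand,
                matches=mt, mismatches=mm, score=score,
                evalue=_evalue(score, m, n),
            )
            key = (diag, q0)
            if key not in hits or hits[key].score < score:
                hits[key] = hit
    return list(hits.values())


def local_align(
    query: str,
    target: str,
    k: int = 21,
    xdrop: int = 30,
    both_strands: bool = True,
) -> list[LocalHit]:
    """All ungapped local hits between query and target (both query strands).

    Minus-strand hits report query coordinates on the forward query after
    mapping back from the reverse complement.
    """
    query = query.upper()
    target = target.upper()
    index: dict[str, list[int]] = {}
    for ti in range(0, len(target) - k + 1):
        index.setdefault(target[ti : ti + k], []).append(ti)
    m, n = len(query), len(target)
    hits = _align_one_strand(query, target, index, k, xdrop, "+", m, n)
    if both_strands:
        rc = revcomp(query)
        for h in _align_one_strand(rc, target, index, k, xdrop, "-", m, n):
            # map query coords back to the forward strand
            hits.append(
                LocalHit(
                    q0=m - h.q1, q1=m - h.q0, t0=h.t0, t1=h.t1, strand="-",
                    matches=h.matches, mismatches=h.mismatches,
                    score=h.score, evalue=h.evalue,
                )
            )
    return sorted(hits, key=lambda h: (-h.score, h.t0, h.q0))


def best_local_score(query: str, target: str, k: int = 11, xdrop: int = 20) -> int:
    """Best ungapped local alignment score of query (either strand) vs target."""
    hits = local_align(query, target, k=k, xdrop=xdrop)
    return hits[0].score if hits else 0
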