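"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written for clarity over speed and only intended for
sequences of a few kilobases / trees of a few tips.
"""

from __future__ import annotations

import itertools

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


# ---------------------------------------------------------------------------
# Longest exact inverted repeat (circular)
# ---------------------------------------------------------------------------

def _ir_exists(seq: str, arm_len: int) -> bool:
    """True when two disjoint arms of the given length exist on the circle
    such that one is the exact reverse complement of the other."""
    n = len(seq)
    if arm_len == 0:
        return True
    if 2 * arm_len > n:
        return False
    d = seq + seq
    pos: dict[str, list[int]] = {}
    for i in range(n):
        pos.setdefault(d[i : i + arm_len], []).append(i)
    for j in range(n):
        rc = naive_revcomp(d[j : j + arm_len])
        for i in pos.get(rc, []):
            span1 = {(i + t) % n for t in range(arm_len)}
            span2 = {(j + t) % n for t in range(arm_len)}
            if not span1 & span2:
                return True
    return False


def longest_exact_ir(seq: str) -> int:
    """Maximal arm length of an exact inverted repeat with disjoint arms on
    the circular sequence (binary search over the monotone predicate)."""
    lo, hi = 0, len(seq) // 2
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if _ir_exists(seq, mid):
            lo = mid
        else:
            hi = mid - 1
    return lo


# ---------------------------------------------------------------------------
# Naive tandem-repeat scan
# ---------------------------------------------------------------------------

def _naive_primitive(motif: str) -> bool:
    for d in range(1, len(motif)):
        if len(motif) % d == 0 and motif == motif[:d] * (len(motif) // d):
            return False
    return True


def _naive_runs(seq: str, unit: int) -> list[tuple[int, int, str, float]]:
    """Maximal perfect tandem runs (start, end, motif, copies) for one unit
    length: every position x ≥ start+unit satisfies seq[x] == seq[x-unit],
    the run is left-maximal, covers ≥ 2 units, and has a primitive motif."""
    out = []
    n = len(seq)
    for i in range(n - 2 * unit + 1):
        if i > 0 and seq[i - 1] == seq[i - 1 + unit]:
            continue  # extendable left: not a run start
        motif = seq[i : i + unit]
        if not _naive_primitive(motif):
            continue
        end = i + unit
        while end < n and seq[end] == seq[end - unit]:
            end += 1
        if end - i >= 2 * unit:
            out.append((i, end, motif, (end - i) / unit))
    return out


def _naive_resolve(runs: list[tuple[int, int, str, float]]) -> list:
    """Greedy overlap resolution: longest first, then smallest start, then
    smallest unit; later runs overlapping a kept one are dropped."""
    kept: list[tuple[int, int, str, float]] = []
    for run in sorted(runs, key=lambda r: (-(r[1] - r[0]), r[0], len(r[2]))):
        if all(run[1] <= k[0] or run[0] >= k[1] for k in kept):
            kept.append(run)
    return sorted(kept, key=lambda r: r[0])


def naive_microsatellites(
    seq: str, min_repeats: tuple[int, ...] = (10, 5, 4, 3, 3, 3)
) -> list[tuple[int, int, str, float]]:
    runs = []
    for unit in range(1, 7):
        for start, end, motif, copies in _naive_runs(seq, unit):
            if (end - start) // unit >= min_repeats[unit - 1]:
                runs.append((start, end, motif, copies))
    return _naive_resolve(runs)


def naive_minisatellites(
    seq: str, min_unit: int = 10, max_unit: int = 60, min_copies: float = 2.0
) -> list[tuple[int, int, str, float]]:
    runs = []
    for unit in range(min_unit, min(max_unit, len(seq) // 2) + 1):
        for start, end, motif, copies in _naive_runs(seq, unit):
            if copies >= min_copies:
                runs.append((start, end, motif, copies))
    return _naive_resolve(runs)


# ---------------------------------------------------------------------------
# Interval union
# ---------------------------------------------------------------------------

def naive_union_size(intervals: list[tuple[int, int]]) -> int:
    covered: set[int] = set()
    for start, end in intervals:
        covered.update(range(start, end))
    return len(covered)


# ---------------------------------------------------------------------------
# Exhaustive ordered-ladder parsimony
# ---------------------------------------------------------------------------

def exhaustive_parsimony(
    tree, tip_states: dict[str, str], root_state: str | None = None
) -> tuple[int, list[dict[int, int]]]:
    """Minimum ladder cost and every optimal internal-state assignment.

    States are indices 0..2 of ("SC", "partial_IR", "complete_IR"); branch
    cost is |parent - child|; a given root_state charges any change from it.
    """
    import dendropy

    states = ("SC", "partial_IR", "complete_IR")
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    internal = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    best_cost = None
    optima: list[dict[int, int]] = []
    for combo in itertools.product(range(3), repeat=len(internal)):
        assign = {id(nd): s for nd, s in zip(internal, combo)}
        cost = 0
        if root_state is not None:
            cost += abs(states.index(root_state) - combo[0])
        for nd in internal:
            for ch in nd.child_nodes():
                child = (
                    states.index(tip_states[ch.taxon.label])
                    if ch.is_leaf()
                    else assign[id(ch)]
                )
                cost += abs(assign[id(nd)] - child)
        if best_cost is None or cost < best_cost:
            best_cost, optima = cost, [assign]
        elif cost == best_cost:
            optima.append(assign)
    return best_cost, optima
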