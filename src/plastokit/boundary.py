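"""IR-boundary expansion/contraction analysis on a phylogeny.

Each gene's relation to the inverted repeat is an ordered three-state
character — single copy (SC), partially duplicated across a junction
(partial_IR), fully inside the IR (complete_IR) — because junction migration
moves a gene into or out of the IR stepwise.  Per-taxon profiles are
computed from annotation/partition overlap, diffed against a reference
architecture, and mapped onto a given tree by small parsimony (Sankoff)
with unit step costs on the ordered ladder, so a direct SC→complete change
costs 2.  Ancestral ties resolve deterministically by placing changes as
late (tipward) as possible; all co-optimal assignments can be enumerated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import dendropy

from .model import GeneFeature, RegionPartition, ValidationError

__all__ = [
    "STATES",
    "BoundaryProfile",
    "ExpansionEvent",
    "profile_boundaries",
    "diff_profiles",
    "infer_events",
    "parsimony_length",
    "enumerate_optimal_assignments",
]

STATES = ("SC", "partial_IR", "complete_IR")
_STATE_INDEX = {s: i for i, s in enumerate(STATES)}
JUNCTIONS = ("JLB", "JSB", "JSA", "JLA")


@dataclass(frozen=True)
class BoundaryProfile:
    """Per-gene IR-membership states for one taxon, plus junction genes."""

    taxon: str
    states: dict  # gene -> {SC, partial_IR, complete_IR}
    junction_genes: dict  # junction -> gene name or None
    partial_junctions: dict  # gene -> junction (for partial_IR genes)


@dataclass(frozen=True)
class ExpansionEvent:
    branch: str  # head-node label: tip name or smallest-tip-set signature
    gene: str
    transition: str  # e.g. "SC->complete_IR"
    junction: str | None = None

    @property
    def is_expansion(self) -> bool:
        a, b = self.transition.split("->")
        return _STATE_INDEX[b] > _STATE_INDEX[a]


def profile_boundaries(
    features: list[GeneFeature],
    partition: RegionPartition,
    taxon: str = "taxon",
) -> BoundaryProfile:
    """IR-membership state per gene from exon/IR overlap.

    IR copies of a gene share a name and are pooled: all exons inside an IR
    → complete_IR, any partial overlap → partial_IR with the spanned junction
    recorded, no overlap → SC.  A gene overlapping two junctions is invalid.
    """
    n = partition.genome_length
    irs = {"IRb": partition.irb, "IRa": partition.ira}
    junction_points = {
        "JLB": partition.irb.start,
        "JSB": partition.ssc.start,
        "JSA": partition.ira.start,
        "JLA": partition.ira.end % n,
    }
    by_name: dict[str, list[GeneFeature]] = {}
    for f in features:
        by_name.setdefault(f.name, []).append(f)

    states: dict[str, str] = {}
    partial_junctions: dict[str, str] = {}
    for name, copies in by_name.items():
        parts = [p for c in copies for p in c.parts]
        inside = [any(ir.contains(p, n) for ir in irs.values()) for p in parts]
        touches = [any(ir.overlaps(p, n) for ir in irs.values()) for p in parts]
        if all(inside):
            states[name] = "complete_IR"
        elif any(touches):
            states[name] = "partial_IR"
            spanned = []
            for jname, jpos in junction_points.items():
                for p in parts:
                    for s, e in p.segments(n):
                        if s < jpos < e:
                            spanned.append(jname)
            spanned = sorted(set(spanned))
            if len(spanned) > 1:
                raise ValidationError(
                    f"gene {name!r} overlaps two junctions: {spanned}"
                )
            if spanned:
                partial_junctions[name] = spanned[0]
        else:
            states[name] = "SC"

    junction_genes: dict[str, str | None] = {}
    for jname, jpos in junction_points.items():
        gene_at = None
        for name, copies in by_name.items():
            for c in copies:
                for p in c.parts:
                    for s, e in p.segments(n):
                        if s < jpos < e:
                            gene_at = name
        junction_genes[jname] = gene_at

    return BoundaryProfile(taxon, states, junction_genes, partial_junctions)


def diff_profiles(profile: BoundaryProfile, reference: BoundaryProfile) -> list[dict]:
    """Per-gene transitions reference → observed.

    Genes in only one profile are reported as gene gain/loss records rather
    than folded into the ordered ladder.
    """
    out = []
    genes = sorted(set(profile.states) | set(reference.states))
    for g in genes:
        ref = reference.states.get(g)
        obs = profile.states.get(g)
        if ref is None:
            out.append({"gene": g, "kind": "gene_gain", "transition": None})
        elif obs is None:
            out.append({"gene": g, "kind": "gene_loss", "transition": None})
        elif ref != obs:
            junction = profile.partial_junctions.get(g)
            if junction is None:
                # attribute IR/SSC vs IR/LSC from where the gene sits
                junction = None
            out.append(
                {
                    "gene": g,
                    "kind": "state_change",
                    "transition": f"{ref}->{obs}",
                    "junction": junction,
                }
            )
    return out


# ---------------------------------------------------------------------------
# Small parsimony on the ordered ladder
# ---------------------------------------------------------------------------

def _node_label(node) -> str:
    if node.is_leaf():
        return node.taxon.label
    tips = sorted(leaf.taxon.label for leaf in node.leaf_iter())
    return "{" + ",".join(tips) + "}"


def _sankoff_down(node, tip_states: dict, costs: dict) -> None:
    if node.is_leaf():
        s = tip_states[node.taxon.label]
        node.sankoff = [0 if i == _STATE_INDEX[s] else float("inf") for i in range(3)]
        return
    for ch in node.child_nodes():
        _sankoff_down(ch, tip_states, costs)
    node.sankoff = []
    for i in range(3):
        total = 0.0
        for ch in node.child_nodes():
            total += min(ch.sankoff[j] + abs(i - j) for j in range(3))
        node.sankoff.append(total)


def _assign(node, parent_state: int | None, events: list, gene: str,
            prefer_late: bool = True) -> None:
    """Top-down optimal state choice; among co-optimal child states prefer
    the parent's (changes as late as possible)."""
    if node.is_leaf():
        state = node.sankoff.index(0)
    else:
        if parent_state is None:
            best = min(node.sankoff)
            opts = [i for i in range(3) if node.sankoff[i] == best]
        else:
            vals = [node.sankoff[i] + abs(parent_state - i) for i in range(3)]
            best = min(vals)
            opts = [i for i in range(3) if vals[i] == best]
        if parent_state in opts and prefer_late:
            state = parent_state
        else:
            state = opts[0]
    if parent_state is not None and state != parent_state:
        events.append(
            ExpansionEvent(
                branch=_node_label(node),
                gene=gene,
                transition=f"{STATES[parent_state]}->{STATES[state]}",
            )
        )
    for ch in node.child_nodes():
        _assign(ch, state, events, gene, prefer_late)


def parsimony_length(tree: str | dendropy.Tree, tip_states: dict[str, str],
                     root_state: str | None = None) -> int:
    """Minimum total ordered-ladder cost of the character on the tree."""
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    root = tree.seed_node
    _sankoff_down(root, tip_states, {})
    if root_state is None:
        return int(min(root.sankoff))
    i = _STATE_INDEX[root_state]
    # the root architecture is given: charge any change from it
    return int(min(root.sankoff[j] + abs(i - j) for j in range(3)))


def infer_events(
    profiles: list[BoundaryProfile],
    tree: str | dendropy.Tree,
    root_state: str = "SC",
    genes: list[str] | None = None,
    junction_of_gene: dict[str, str] | None = None,
) -> dict[str, list[ExpansionEvent]]:
    """Map minimal-change IR expansion/contraction events onto tree branches.

    Each gene's states are an ordered character (SC=0, partial=1, complete=2)
    with |Δstate| branch costs; ``root_state`` fixes the reference
    architecture at the root.  Events are reported on the branch leading to
    the node where the state changes, with ties resolved by changing as late
    as possible (the deterministic primary reconstruction).
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    by_taxon = {p.taxon: p for p in profiles}
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if tips != set(by_taxon):
        raise ValidationError(
            f"tree tips {sorted(tips)} do not match profiles {sorted(by_taxon)}"
        )
    if genes is None:
        genes = sorted({g for p in profiles for g in p.states})

    events_by_gene: dict[str, list[ExpansionEvent]] = {}
    for gene in genes:
        tip_states = {t: by_taxon[t].states.get(gene, "SC") for t in tips}
        root = tree.seed_node
        _sankoff_down(root, tip_states, {})
        events: list[ExpansionEvent] = []
        _assign(root, _STATE_INDEX[root_state], events, gene)
        if junction_of_gene and gene in junction_of_gene:
            events = [
                ExpansionEvent(e.branch, e.gene, e.transition,
                               junction_of_gene[gene])
                for e in events
            ]
        events_by_gene[gene] = events
    return events_by_gene


def enumerate_optimal_assignments(
    tree: str | dendropy.Tree, tip_states: dict[str, str],
    root_state: str | None = None, limit: int = 10000,
) -> list[dict[str, str]]:
    """All minimum-cost ancestral state assignments (internal node label → state).

    Exhaustive over internal nodes; intended for small trees where the
    co-optimal placements of 'putative' events should all be listed.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    internal = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    best = None
    results: list[tuple[int, dict]] = []
    for combo in itertools.product(range(3), repeat=len(internal)):
        state_of = {id(nd): s for nd, s in zip(internal, combo)}
        cost = 0
        if root_state is not None:
            cost += abs(_STATE_INDEX[root_state] - combo[0])
        for nd in tree.preorder_node_iter():
            for ch in nd.child_nodes():
                s_parent = state_of[id(nd)]
                s_child = (
                    _STATE_INDEX[tip_states[ch.taxon.label]]
                    if ch.is_leaf()
                    else state_of[id(ch)]
                )
                cost += abs(s_parent - s_child)
        results.append((cost, {
            _node_label(nd): STATES[state_of[id(nd)]] for nd in internal
        }))
        if len(results) > limit:
            raise ValueError("tree too large for exhaustive enumeration")
    best = min(c for c, _ in results)
    return [a for c, a in results if c == best]
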