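"""Clonal grouping, class-switch detection and lineage tree reconstruction.

A B-cell clone is the set of sequences descending from one V(D)J
rearrangement; operationally, sequences sharing the same V gene, J gene and
byte-identical junction nucleotides (conserved Cys-104 through Trp-118).
Within clones, two signatures of in-situ class switch recombination are
reported separately, because "identical V(D)J" can be read two ways:

* strict events — groups of byte-identical V(D)J nucleotide sequences
  carrying two or more IgG subclasses (switching with no interleaved SHM);
* clonal events — clone groups (identical junction, possibly mutated V
  bodies) carrying two or more subclasses (switching within an expanded,
  mutating lineage).

Lineage trees are rooted at the germline and minimise the total number of
substitutions, with hypothetical intermediate nodes (unobserved progenitors)
inserted where two or more descendants share mutations. Mutations within a
clone are assumed irreversible and unique per site (infinite-sites);
violations (the same position mutated to different bases in different
members) are detected and reported, not resolved.

The minimisation exploits the structure of the irreversible model. In a
tree whose nodes are mutation sets ordered by containment, the total
mutation count is sum(|v| - |parent(v)|), so once the node set is fixed the
optimum is separable: every node simply takes the largest strict subset
present as its parent. The combinatorial choice is *which* hypothetical
intermediates to include; every useful intermediate is an intersection of
observed mutation sets, so the exact mode enumerates all subsets of the
intersection closure, scores each candidate node set with the independent
max-parent rule, and keeps the cheapest (clones of <= 12 members, closure of
<= 16 optional intermediates). Larger clones fall back to greedy
agglomeration (repeatedly join the pair sharing the most mutations and add
the shared set as an intermediate). Intermediates left with fewer than two
children are spliced out of the final tree.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx

from .annotate import AnnotatedSequence

__all__ = [
    "CloneGroup",
    "LineageTree",
    "SwitchEvent",
    "group_clones",
    "detect_class_switch",
    "build_lineage_tree",
    "EXACT_MEMBER_LIMIT",
]

EXACT_MEMBER_LIMIT = 12


@dataclass
class CloneGroup:
    """Sequences sharing a V call, J call and identical junction nucleotides."""

    clone_id: str
    members: list                 # AnnotatedSequence records
    v_call: str
    j_call: str
    junction_nt: str

    @property
    def seq_ids(self) -> list:
        return [m.seq_id for m in self.members]

    @property
    def subclasses(self) -> list:
        """Multiset of assigned subclasses across members."""
        return [m.subclass for m in self.members if m.subclass is not None]

    @property
    def is_expanded(self) -> bool:
        return len({m.seq_id for m in self.members}) >= 2


def group_clones(records: Sequence[AnnotatedSequence],
                 junction_tolerance: int = 0):
    """Partition annotated records into clones by (v_call, j_call, junction).

    Records lacking a junction are routed to an ungrouped bucket. With the
    default tolerance 0 the junction key is exact byte identity; a positive
    Hamming tolerance merges groups whose equal-length junctions differ at
    up to that many positions (for noisy data; merging is transitive
    single-linkage in input order).
    Returns ``(clone_groups, ungrouped_records)``.
    """
    buckets: dict[tuple, list] = {}
    ungrouped = []
    for rec in records:
        if rec.junction_nt is None or rec.j_call is None:
            ungrouped.append(rec)
            continue
        buckets.setdefault((rec.v_call, rec.j_call, rec.junction_nt),
                           []).append(rec)
    keys = list(buckets)
    if junction_tolerance > 0:
        merged = _merge_similar_junctions(keys, junction_tolerance)
    else:
        merged = [[k] for k in keys]
    groups = []
    for i, keygroup in enumerate(merged):
        members = [rec for k in keygroup for rec in buckets[k]]
        v_call, j_call, junction = keygroup[0]
        groups.append(CloneGroup(clone_id=f"C{i:04d}", members=members,
                                 v_call=v_call, j_call=j_call,
                                 junction_nt=junction))
    return groups, ungrouped


def _merge_similar_junctions(keys, tolerance):
    def close(k1, k2):
        if k1[0] != k2[0] or k1[1] != k2[1] or len(k1[2]) != len(k2[2]):
            return False
        return sum(a != b for a, b in zip(k1[2], k2[2])) <= tolerance

    clusters: list[list] = []
    for k in keys:
        home = None
        for cluster in clusters:
            if any(close(k, other) for other in cluster):
                home = cluster
                break
        if home is None:
            clusters.append([k])
        else:
            home.append(k)
    return clusters


@dataclass(frozen=True)
class SwitchEvent:
    """One detected class-switch signature."""

    kind: str                    # "strict" | "clonal"
    clone_id: Optional[str]
    seq_ids: tuple
    subclass_set: tuple          # sorted distinct subclasses


def detect_class_switch(groups: Sequence[CloneGroup]) -> list[SwitchEvent]:
    """Detect class-switch events within clone groups.

    Strict events: byte-identical V(D)J nucleotide sequences bearing >= 2
    subclasses. Clonal events: whole clone groups bearing >= 2 subclasses.
    A strict event always implies a clonal event for its clone; both are
    reported, tagged by kind.
    """
    events = []
    for group in groups:
        with_call = [m for m in group.members if m.subclass is not None]
        # strict: identical V(D)J nucleotide sequences, multiple subclasses
        # (compared over the VH region only — the constant fragment encodes
        # the subclass itself, so full amplicons of switched cells differ)
        by_seq: dict[str, list] = {}
        for m in with_call:
            by_seq.setdefault(m.vh_nt, []).append(m)
        for members in by_seq.values():
            subs = sorted({m.subclass for m in members})
            if len(subs) >= 2:
                events.append(SwitchEvent(
                    kind="strict", clone_id=group.clone_id,
                    seq_ids=tuple(m.seq_id for m in members),
                    subclass_set=tuple(subs)))
        subs = sorted({m.subclass for m in with_call})
        if len(subs) >= 2:
            events.append(SwitchEvent(
                kind="clonal", clone_id=group.clone_id,
                seq_ids=tuple(m.seq_id for m in with_call),
                subclass_set=tuple(subs)))
    return events


# ---------------------------------------------------------------------------
# lineage trees
# ---------------------------------------------------------------------------

Mutation = tuple  # (nt_pos, germline_base, observed_base)


@dataclass
class LineageTree:
    """Rooted minimum-mutation clonal family tree.

    ``graph`` is a directed tree (edges parent -> child). Node attributes:
    ``kind`` in {"germline", "observed", "inferred"}, ``labels`` (seq ids for
    observed nodes; inferred progenitors are the 'x' nodes), ``subclasses``,
    and ``mutations`` (the node's full mutation set vs germline). Edge
    attribute ``mutations`` lists the substitutions acquired along the edge.
    """

    clone_id: str
    graph: nx.DiGraph
    root: str
    total_mutations: int
    exact: bool
    conflicts: list = field(default_factory=list)

    def to_newick(self) -> str:
        """Newick string with node labels; inferred nodes are named x1, x2, ..."""
        def fmt(node):
            children = list(self.graph.successors(node))
            label = self.graph.nodes[node]["newick_label"]
            length = len(self.graph.nodes[node].get("edge_mutations", ()))
            if children:
                inner = ",".join(fmt(c) for c in children)
                return f"({inner}){label}:{length}"
            return f"{label}:{length}"
        return fmt(self.root) + ";"

    def edge_table(self) -> list:
        """Edge list rows: (parent, child, n_mutations, mutations, subclasses)."""
        rows = []
        for u, v, data in self.graph.edges(data=True):
            muts = data["mutations"]
            rows.append({
                "clone_id": self.clone_id,
                "parent": self.graph.nodes[u]["newick_label"],
                "child": self.graph.nodes[v]["newick_label"],
                "n_mutations": len(muts),
                "mutations": ";".join(f"{p}:{a}>{b}" for p, a, b in muts),
                "subclasses": ",".join(self.graph.nodes[v]["subclasses"]),
            })
        return rows


def _mutation_set(record: AnnotatedSequence) -> frozenset:
    return frozenset((ev.nt_pos, ev.germline_base, ev.observed_base)
                     for ev in record.mutation_events)


def _find_conflicts(sets: dict) -> list:
    """Positions mutated to different bases across members (infinite-sites breaks)."""
    by_pos: dict[int, set] = {}
    for s in sets.values():
        for pos, _a, b in s:
            by_pos.setdefault(pos, set()).add(b)
    return sorted(pos for pos, targets in by_pos.items() if len(targets) > 1)


_OPTIONAL_CAP = 16   # exhaustive intermediate search up to 2^16 subsets


def _intersection_closure(observed: set, cap: int = 4096) -> set:
    closure = set(observed)
    closure.add(frozenset())
    frontier = list(closure)
    while frontier:
        new = set()
        for s in frontier:
            for t in list(closure):
                inter = s & t
                if inter not in closure and inter not in new:
                    new.add(inter)
        if not new:
            break
        closure |= new
        frontier = list(new)
        if len(closure) > cap:
            break
    return closure


def _greedy_intermediates(observed: set) -> set:
    """Shared-mutation intermediates by greedy pairwise agglomeration."""
    nodes = set(observed)
    nodes.add(frozenset())
    active = list(observed)
    while len(active) > 1:
        best = None
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                inter = active[i] & active[j]
                if best is None or len(inter) > len(best[0]):
                    best = (inter, i, j)
        inter, i, j = best
        nodes.add(inter)
        merged = [a for k, a in enumerate(active) if k not in (i, j)]
        merged.append(inter)
        active = merged
    return nodes


def _assign_parents(node_sets: list) -> tuple[int, dict]:
    """Cheapest containment tree on a fixed node set.

    With the node set fixed the cost sum(|v| - |parent(v)|) is separable, so
    each node takes the largest strict subset present as its parent (ties
    broken deterministically by the sorted mutation tuple). Returns
    ``(total_cost, parent_map)``.
    """
    ordered = sorted(node_sets, key=lambda s: (len(s), tuple(sorted(s))))
    parent: dict[frozenset, frozenset] = {}
    cost = 0
    for v in ordered:
        if not v:
            continue
        best = frozenset()
        for u in ordered:
            if len(u) >= len(v):
                break
            if len(u) > len(best) and u < v:
                best = u
        parent[v] = best
        cost += len(v) - len(best)
    return cost, parent


def _optimal_intermediates(observed_sets: set) -> tuple[int, dict, bool]:
    """Exact minimum-mutation tree by exhaustive intermediate selection.

    Candidate intermediates are the intersection closure of the observed
    sets; every subset of candidates is scored (as integer bitmasks, for
    speed) with the separable max-parent rule. Falls back to the
    all-candidates assignment (flagged inexact) when the candidate count
    exceeds the enumeration cap.
    """
    closure = _intersection_closure(observed_sets)
    if len(closure - observed_sets - {frozenset()}) > _OPTIONAL_CAP:
        cost, parent = _assign_parents(list(closure | {frozenset()}))
        return cost, parent, False

    chars = sorted(set().union(*observed_sets)) if observed_sets else []
    bit = {c: 1 << i for i, c in enumerate(chars)}

    def to_mask(s):
        m = 0
        for c in s:
            m |= bit[c]
        return m

    key_of = {s: (len(s), tuple(sorted(s))) for s in closure}
    mandatory = [to_mask(s) for s in observed_sets] + [0]
    optional_sets = sorted(closure - observed_sets - {frozenset()},
                           key=key_of.get)
    optional = [to_mask(s) for s in optional_sets]

    def masked_cost(nodes):
        nodes = sorted(set(nodes), key=lambda m: m.bit_count())
        cost = 0
        for i, v in enumerate(nodes):
            if v == 0:
                continue
            nv = v.bit_count()
            best = 0
            for u in nodes[:i]:
                nu = u.bit_count()
                if nu >= nv:
                    break
                if nu > best.bit_count() and (u & v) == u:
                    best = u
            cost += nv - best.bit_count()
        return cost

    best = None
    for mask in range(1 << len(optional)):
        chosen = mandatory + [optional[i] for i in range(len(optional))
                              if mask >> i & 1]
        cost = masked_cost(chosen)
        key = (cost, bin(mask).count("1"), mask)
        if best is None or key < best[0]:
            best = (key, mask)
    chosen_sets = (list(observed_sets) + [frozenset()]
                   + [optional_sets[i] for i in range(len(optional))
                      if best[1] >> i & 1])
    cost, parent = _assign_parents(chosen_sets)
    return cost, parent, True


def build_lineage_tree(clone: CloneGroup,
                       germline_name: Optional[str] = None) -> LineageTree:
    """Reconstruct the minimum-total-mutation family tree of one clone.

    Nodes are mutation sets relative to the clone's germline V assignment;
    the germline root carries the empty set. Observed members with identical
    mutation sets collapse onto one node. Hypothetical intermediates
    (unobserved progenitors) are inserted only where they join >= 2
    descendant branches. ``exact`` is True when the complete intersection
    closure was searched (clones of <= 12 members).
    """
    members = clone.members
    if not members:
        raise ValueError(f"{clone.clone_id}: empty clone")
    sets = {m.seq_id: _mutation_set(m) for m in members}
    conflicts = _find_conflicts(sets)
    observed_sets = set(sets.values())

    if len(members) <= EXACT_MEMBER_LIMIT:
        _cost, parent, exact = _optimal_intermediates(observed_sets)
    else:
        candidates = _greedy_intermediates(observed_sets)
        _cost, parent = _assign_parents(list(candidates | {frozenset()}))
        exact = False

    children: dict[frozenset, list] = {frozenset(): []}
    for node in parent:
        children.setdefault(node, [])
    for node, par in parent.items():
        children.setdefault(par, []).append(node)

    # splice out inferred nodes with < 2 children (cost telescopes, so this
    # never increases the total; leaf intermediates would only add cost)
    def is_observed(s):
        return s in observed_sets
    changed = True
    while changed:
        changed = False
        for node in list(children):
            if not node or is_observed(node):
                continue
            kids = children.get(node, [])
            if len(kids) >= 2:
                continue
            par = parent[node]
            for kid in kids:
                parent[kid] = par
                children[par].append(kid)
            children[par].remove(node)
            del children[node]
            del parent[node]
            changed = True

    nodes = set(children) | set(parent)
    g = nx.DiGraph()
    inferred_counter = 0
    node_name: dict[frozenset, str] = {}
    for s in sorted(nodes, key=lambda s: (len(s), sorted(s))):
        recs = [m for m in members if sets[m.seq_id] == s]
        if not s:
            # germline root; observed sequences identical to germline sit here
            name, kind = "germline", "germline"
            labels = [m.seq_id for m in recs]
            subs = sorted({m.subclass for m in recs if m.subclass})
        elif recs:
            name, kind = recs[0].seq_id, "observed"
            labels = [m.seq_id for m in recs]
            subs = sorted({m.subclass for m in recs if m.subclass})
        else:
            inferred_counter += 1
            name, kind = f"x{inferred_counter}", "inferred"
            labels, subs = [], []
        node_name[s] = name
        g.add_node(name, kind=kind, labels=labels, subclasses=subs,
                   mutations=sorted(s), newick_label=name)

    total = 0
    for node, par in parent.items():
        muts = sorted(node - par)
        total += len(muts)
        g.add_edge(node_name[par], node_name[node], mutations=muts)
        g.nodes[node_name[node]]["edge_mutations"] = muts

    root = node_name.get(frozenset(), "germline")
    if "germline" not in g:
        g.add_node("germline", kind="germline", labels=[], subclasses=[],
                   mutations=[], newick_label="germline")
        root = "germline"
    return LineageTree(clone_id=clone.clone_id, graph=g, root=root,
                       total_mutations=total, exact=exact,
                       conflicts=conflicts)
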