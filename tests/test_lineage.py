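"""Clone grouping, class-switch detection and minimum-mutation trees."""
import itertools

import numpy as np
import pytest

from igprofile.annotate import AnnotatedSequence, MutationEvent
from igprofile.lineage import (CloneGroup, build_lineage_tree,
                               detect_class_switch, group_clones)


def make_record(seq_id, junction="JUNC", v_call="IGHV3-23", j_call="IGHJ4",
                subclass="IgG1", sequence=None, mutations=()):
    events = [MutationEvent(nt_pos=p, imgt_codon=p // 3 + 1, region="FR1",
                            germline_base=a, observed_base=b, silent=False)
              for p, a, b in mutations]
    return AnnotatedSequence(
        seq_id=seq_id, sequence=sequence or f"SEQ-{seq_id}",
        v_call=v_call, v_identity=1.0, j_call=j_call, j_identity=1.0,
        d_call=None, vh_family=3, junction_nt=junction, junction_aa=None,
        cdr3_nt=None, cdr3_aa=None, cdr3_length=None, productive=True,
        subclass=subclass, c_identity=1.0, subclass_reason=None,
        region_mutations={}, mutation_events=events)


# ---------------------------------------------------------------------------
# independent exhaustive-parsimony oracle: enumerate every multifurcating
# rooted topology over the distinct mutation sets; for each irreversible
# character the minimum number of gains is the number of maximal subtrees
# whose leaves all carry it; minimise the total over topologies.
# ---------------------------------------------------------------------------

def _topologies(leaves):
    leaves = tuple(leaves)
    if len(leaves) == 1:
        yield leaves[0]
        return
    for partition in _set_partitions(leaves):
        if len(partition) < 2:
            continue
        for combo in itertools.product(*(_topologies(block)
                                         for block in partition)):
            yield tuple(combo)


def _set_partitions(items):
    if len(items) == 1:
        yield [tuple(items)]
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [(first,) + part[i]] + part[i + 1:]
        yield [(first,)] + part


def _tree_cost(tree, sets):
    chars = set().union(*sets.values()) if sets else set()

    def leafset(node):
        if isinstance(node, str):
            return frozenset([node])
        return frozenset().union(*(leafset(c) for c in node))

    def count_char(node, char):
        # number of maximal subtrees whose leaves all carry `char`
        ls = leafset(node)
        if all(char in sets[leaf] for leaf in ls):
            return 1
        if isinstance(node, str):
            return 0
        return sum(count_char(c, char) for c in node)

    return sum(count_char(tree, ch) for ch in chars)


def exhaustive_parsimony(sets):
    """Minimum total mutations over all rooted topologies (root = germline)."""
    distinct = {}
    for sid, s in sets.items():
        distinct.setdefault(s, sid)
    names = {sid: s for s, sid in distinct.items()}
    leaves = list(names)
    nonroot = [l for l in leaves if names[l]]
    if not nonroot:
        return 0
    best = None
    for topo in _topologies(tuple(nonroot)):
        cost = _tree_cost(topo, names)
        best = cost if best is None else min(best, cost)
    return best


class TestGroupClones:
    def test_shared_key_forms_expanded_clone(self):
        records = [make_record(f"s{i}") for i in range(3)]
        groups, ungrouped = group_clones(records)
        assert len(groups) == 1 and groups[0].is_expanded
        assert sorted(groups[0].seq_ids) == ["s0", "s1", "s2"]
        assert not ungrouped

    def test_distinct_junctions_are_singletons(self):
        records = [make_record(f"s{i}", junction=f"J{i}") for i in range(4)]
        groups, _ = group_clones(records)
        assert len(groups) == 4
        assert not any(g.is_expanded for g in groups)

    def test_missing_junction_routed_to_ungrouped(self):
        records = [make_record("s0"), make_record("s1", junction=None)]
        groups, ungrouped = group_clones(records)
        assert len(groups) == 1 and len(ungrouped) == 1

    def test_hamming_tolerance_merges_near_junctions(self):
        records = [make_record("s0", junction="AAAA"),
                   make_record("s1", junction="AAAT")]
        strict, _ = group_clones(records)
        loose, _ = group_clones(records, junction_tolerance=1)
        assert len(strict) == 2 and len(loose) == 1

    def test_partition_refines_strict_identity(self, annotated_small):
        groups, _ = group_clones(annotated_small)
        for g in groups:
            # byte-identical VH sequences never straddle two clones
            for g2 in groups:
                if g is g2:
                    continue
                assert not ({m.vh_nt for m in g.members}
                            & {m.vh_nt for m in g2.members})

    def test_simulated_partition_equals_truth(self, sim_small,
                                              annotated_small):
        truth = sim_small.truth.set_index("sequence_id")["clone_id"]
        groups, ungrouped = group_clones(annotated_small)
        assert not ungrouped
        for g in groups:
            assert truth[g.seq_ids].nunique() == 1
        assert len(groups) == truth.nunique()


class TestDetectClassSwitch:
    def test_strict_event_on_identical_vdj(self):
        records = [make_record("s0", sequence="SAME", subclass="IgG1"),
                   make_record("s1", sequence="SAME", subclass="IgG4"),
                   make_record("s2", sequence="SAME", subclass="IgG1")]
        groups, _ = group_clones(records)
        events = detect_class_switch(groups)
        strict = [e for e in events if e.kind == "strict"]
        assert len(strict) == 1
        assert strict[0].subclass_set == ("IgG1", "IgG4")

    def test_clonal_event_without_strict(self):
        records = [make_record("s0", sequence="AAA", subclass="IgG2",
                               mutations=((1, "A", "C"),)),
                   make_record("s1", sequence="AAC", subclass="IgG4")]
        groups, _ = group_clones(records)
        events = detect_class_switch(groups)
        assert sum(e.kind == "strict" for e in events) == 0
        clonal = [e for e in events if e.kind == "clonal"]
        assert len(clonal) == 1
        assert clonal[0].subclass_set == ("IgG2", "IgG4")

    def test_single_subclass_clone_is_silent(self):
        records = [make_record(f"s{i}", subclass="IgG1") for i in range(3)]
        groups, _ = group_clones(records)
        assert detect_class_switch(groups) == []


class TestBuildLineageTree:
    def test_chain_of_nested_mutations(self):
        clone = CloneGroup("c", [
            make_record("s1", mutations=((10, "A", "C"),)),
            make_record("s2", mutations=((10, "A", "C"), (20, "A", "G")))],
            "IGHV3-23", "IGHJ4", "JUNC")
        tree = build_lineage_tree(clone)
        assert tree.total_mutations == 2
        assert tree.to_newick() == "((s2:1)s1:1)germline:0;"

    def test_disjoint_daughters_form_star(self):
        clone = CloneGroup("c", [
            make_record("s1", mutations=((10, "A", "C"),)),
            make_record("s2", mutations=((20, "A", "G"),))],
            "IGHV3-23", "IGHJ4", "JUNC")
        tree = build_lineage_tree(clone)
        assert tree.total_mutations == 2
        kinds = [d["kind"] for _, d in tree.graph.nodes(data=True)]
        assert kinds.count("inferred") == 0

    def test_shared_mutation_creates_intermediate(self):
        clone = CloneGroup("c", [
            make_record("s1", mutations=((1, "A", "C"), (2, "A", "C"))),
            make_record("s2", mutations=((1, "A", "C"), (3, "A", "C")))],
            "IGHV3-23", "IGHJ4", "JUNC")
        tree = build_lineage_tree(clone)
        assert tree.total_mutations == 3
        inferred = [n for n, d in tree.graph.nodes(data=True)
                    if d["kind"] == "inferred"]
        assert len(inferred) == 1
        assert tree.graph.nodes[inferred[0]]["mutations"] == [(1, "A", "C")]

    def test_conflicting_target_bases_reported(self):
        clone = CloneGroup("c", [
            make_record("s1", mutations=((10, "A", "C"),)),
            make_record("s2", mutations=((10, "A", "G"),))],
            "IGHV3-23", "IGHJ4", "JUNC")
        tree = build_lineage_tree(clone)
        assert tree.conflicts == [10]

    def test_total_matches_exhaustive_oracle_on_random_clones(self):
        """Reconstructed total mutation count equals exhaustive parsimony
        over every rooted topology, for random clones of <= 5 members."""
        rng = np.random.default_rng(99)
        universe = [(p, "A", "CGT"[p % 3]) for p in range(7)]
        for trial in range(60):
            k = int(rng.integers(2, 6))
            members = []
            for i in range(k):
                size = int(rng.integers(0, 5))
                idx = rng.choice(len(universe), size=size, replace=False)
                members.append(make_record(
                    f"s{i}", mutations=tuple(universe[j] for j in idx)))
            clone = CloneGroup("c", members, "IGHV3-23", "IGHJ4", "JUNC")
            tree = build_lineage_tree(clone)
            sets = {m.seq_id: frozenset(
                (ev.nt_pos, ev.germline_base, ev.observed_base)
                for ev in m.mutation_events) for m in members}
            assert tree.total_mutations == exhaustive_parsimony(sets), sets

    def test_total_never_exceeds_sum_of_hamming_distances(self):
        rng = np.random.default_rng(5)
        universe = [(p, "A", "C") for p in range(9)]
        for _ in range(30):
            members = []
            for i in range(int(rng.integers(2, 7))):
                idx = rng.choice(9, size=int(rng.integers(0, 6)),
                                 replace=False)
                members.append(make_record(
                    f"s{i}", mutations=tuple(universe[j] for j in idx)))
            clone = CloneGroup("c", members, "IGHV3-23", "IGHJ4", "JUNC")
            tree = build_lineage_tree(clone)
            naive_sum = sum(len(m.mutation_events) for m in members)
            assert tree.total_mutations <= naive_sum

    def test_empty_clone_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            build_lineage_tree(CloneGroup("c", [], "V", "J", "X"))

    def test_newick_has_all_observed_labels(self):
        clone = CloneGroup("c", [
            make_record("s1", mutations=((1, "A", "C"),)),
            make_record("s2", mutations=((1, "A", "C"), (2, "A", "C"))),
            make_record("s3", mutations=((3, "A", "C"),))],
            "IGHV3-23", "IGHJ4", "JUNC")
        nwk = build_lineage_tree(clone).to_newick()
        for sid in ("s1", "s2", "s3"):
            assert sid in nwk
        assert nwk.endswith("germline:0;")


class TestSwitchOnSimulatedData:
    def test_no_switching_no_events(self, reference):
        from igprofile.annotate import annotate_repertoire
        from igprofile.simulate import SimConfig, simulate_repertoire
        cfg = SimConfig(n_clones=20, switch_prob=0.0, seed=41)
        rep = simulate_repertoire(cfg, reference)
        annotated, _ = annotate_repertoire(rep.sequences, reference)
        groups, _ = group_clones(annotated)
        assert detect_class_switch(groups) == []

    def test_truth_switch_lineages_all_detected(self, reference):
        from igprofile.annotate import annotate_repertoire
        from igprofile.simulate import SimConfig, simulate_repertoire
        cfg = SimConfig(n_clones=25, switch_prob=0.2,
                        clone_size_law=("fixed", 3), seed=43)
        rep = simulate_repertoire(cfg, reference)
        truth_switched = set(
            rep.truth.groupby("clone_id")["subclass"]
            .nunique().pipe(lambda s: s[s >= 2]).index)
        annotated, _ = annotate_repertoire(rep.sequences, reference)
        groups, _ = group_clones(annotated)
        events = [e for e in detect_class_switch(groups) if e.kind == "clonal"]
        truth_by_seq = rep.truth.set_index("sequence_id")["clone_id"]
        detected = {truth_by_seq[e.seq_ids[0]] for e in events}
        assert detected == truth_switched
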