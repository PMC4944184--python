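"""Annotation: gene assignment, junction extraction, mutation counting, subclass."""
import numpy as np
import pytest
from Bio.Data import CodonTable

from igprofile.annotate import (NonIgHError, annotate_repertoire,
                                annotate_sequence, assign_germline,
                                assign_subclass, count_mutations,
                                dedupe_unique)
from igprofile.simulate import SimConfig, simulate_repertoire

# independent codon-table oracle built from the raw NCBI standard table data
_FWD = CodonTable.unambiguous_dna_by_id[1].forward_table
_STOPS = set(CodonTable.unambiguous_dna_by_id[1].stop_codons)


def _aa(codon):
    return "*" if codon in _STOPS else _FWD[codon]


def _identity_map(n):
    return np.arange(n, dtype=np.int64)


class TestAssignGermline:
    def test_unmutated_sequences_recover_truth_exactly(self, sim_unmutated,
                                                       annotated_unmutated):
        truth = sim_unmutated.truth.set_index("sequence_id")
        for rec in annotated_unmutated:
            t = truth.loc[rec.seq_id]
            assert rec.v_call == t["v_call"]
            assert rec.v_identity == 1.0
            assert rec.j_call == t["j_call"]
            assert rec.junction_nt == t["junction"]
            assert rec.subclass == t["subclass"]
            assert rec.total_mutations == 0

    def test_mutated_repertoire_recovers_v_calls(self, reference):
        cfg = SimConfig(n_clones=40, shm_rate=0.05, seed=13)
        rep = simulate_repertoire(cfg, reference)
        annotated, rejected = annotate_repertoire(rep.sequences, reference)
        assert not rejected
        truth = rep.truth.set_index("sequence_id")
        hits = sum(rec.v_call == truth.loc[rec.seq_id, "v_call"]
                   for rec in annotated)
        assert hits / len(annotated) >= 0.95

    def test_random_sequence_rejected_as_non_igh(self, reference):
        rng = np.random.default_rng(0)
        junk = "".join("ACGT"[i] for i in rng.integers(0, 4, size=400))
        with pytest.raises(NonIgHError, match="below"):
            assign_germline(junk, reference)

    def test_short_query_rejected(self, reference):
        with pytest.raises(ValueError, match="short"):
            assign_germline("ACGT" * 10, reference)

    def test_d_call_requires_five_nt_match(self, reference,
                                           annotated_unmutated,
                                           sim_unmutated):
        truth = sim_unmutated.truth.set_index("sequence_id")
        called = [r for r in annotated_unmutated if r.d_call is not None]
        # most unmutated simulated sequences retain a >=5 nt D remnant
        assert len(called) > len(annotated_unmutated) // 2
        for rec in called:
            d_seq = reference.d_genes[truth.loc[rec.seq_id, "d_call"]]
            assert rec.d_call in reference.d_genes


class TestCountMutations:
    @pytest.mark.parametrize("germ_codon,obs_codon,silent,nonsilent", [
        ("GCT", "GCC", 1, 0),   # Ala -> Ala
        ("GCT", "ACT", 0, 1),   # Ala -> Thr
        ("GCT", "GTC", 1, 1),   # pos2 GTT=Val (nonsilent), pos3 GCC=Ala (silent)
    ])
    def test_codon_classification(self, reference, germ_codon, obs_codon,
                                  silent, nonsilent):
        v = reference.v_genes["IGHV3-23"]
        # graft the codon pair onto codon 10 (FR1) of a real gene
        start = 9 * 3
        germ = v.nt_sequence
        assert_codon = germ[:start] + germ_codon + germ[start + 3:]
        from igprofile.germline import GermlineGene
        v_mod = GermlineGene(name=v.name, segment_class="V",
                             nt_sequence=assert_codon)
        query = assert_codon[:start] + obs_codon + assert_codon[start + 3:]
        counts, events, uncallable = count_mutations(
            query, v_mod, _identity_map(len(query)))
        assert counts["FR1"]["silent"] == silent
        assert counts["FR1"]["nonsilent"] == nonsilent
        assert uncallable == 0

    def test_classification_matches_codon_table_oracle(self, reference):
        """Random substitutions: per-substitution classification equals an
        independent single-substitution codon-table evaluation."""
        rng = np.random.default_rng(7)
        v = reference.v_genes["IGHV1-2"]
        germ = v.nt_sequence
        for _ in range(50):
            query = list(germ)
            n_mut = rng.integers(1, 12)
            positions = rng.choice(312, size=n_mut, replace=False)
            for p in positions:
                p = int(p)
                query[p] = rng.choice([b for b in "ACGT" if b != germ[p]])
            query = "".join(query)
            counts, events, _ = count_mutations(query, v,
                                                _identity_map(len(query)))
            assert len(events) == n_mut
            for ev in events:
                c0 = 3 * (ev.imgt_codon - 1)
                codon = germ[c0:c0 + 3]
                sub = codon[:ev.nt_pos - c0] + ev.observed_base \
                    + codon[ev.nt_pos - c0 + 1:]
                assert ev.silent == (_aa(codon) == _aa(sub))
            total = sum(c["silent"] + c["nonsilent"]
                        for c in counts.values())
            assert total == n_mut

    def test_ambiguity_characters_are_uncallable(self, reference):
        v = reference.v_genes["IGHV1-2"]
        query = "N" + v.nt_sequence[1:]
        counts, events, uncallable = count_mutations(
            query, v, _identity_map(len(query)))
        assert uncallable == 1 and not events


class TestAssignSubclass:
    def _mutate(self, seq, frac, rng):
        chars = list(seq)
        for p in rng.choice(len(seq), size=int(frac * len(seq)),
                            replace=False):
            p = int(p)
            chars[p] = rng.choice([b for b in "ACGT" if b != seq[p]])
        return "".join(chars)

    def test_highest_identity_wins_above_threshold(self, reference):
        rng = np.random.default_rng(1)
        frag = self._mutate(reference.c_genes["IGHG4"].nt_sequence, 0.05, rng)
        sub, identity, reason = assign_subclass(frag, reference)
        assert sub == "IgG4" and identity >= 0.90 and reason is None

    def test_below_threshold_is_unassigned(self, reference):
        rng = np.random.default_rng(2)
        frag = self._mutate(reference.c_genes["IGHG1"].nt_sequence, 0.2, rng)
        sub, identity, reason = assign_subclass(frag, reference)
        assert sub is None and "threshold" in reason

    def test_empty_fragment_unassigned_with_reason(self, reference):
        sub, identity, reason = assign_subclass("", reference)
        assert sub is None and "empty" in reason

    def test_exact_tie_between_subclasses_is_unassigned(self, tmp_path,
                                                        reference):
        from igprofile.germline import load_germline_reference
        seq = reference.c_genes["IGHG1"].nt_sequence
        p = tmp_path / "ref.fasta"
        p.write_text(f">IGHG1|C|IgG1\n{seq}\n>IGHG2|C|IgG2\n{seq}\n")
        tie_ref = load_germline_reference(p, require_complete=False)
        sub, identity, reason = assign_subclass(seq, tie_ref)
        assert sub is None and "tie" in reason


class TestJunctionAndCdr3:
    def test_cdr3_length_is_aa_length(self, annotated_unmutated):
        for rec in annotated_unmutated:
            assert rec.cdr3_length == len(rec.cdr3_aa)
            assert rec.junction_aa.startswith("C")   # Cys-104 anchor
            assert rec.junction_aa.endswith("W")     # Trp-118 anchor

    def test_stop_codon_in_cdr3_flags_non_productive(self, reference,
                                                     annotated_unmutated):
        rec = annotated_unmutated[0]
        pos = rec.sequence.find(rec.cdr3_nt)
        broken = rec.sequence[:pos] + "TAA" + rec.sequence[pos + 3:]
        out = annotate_sequence("broken", broken, reference)
        assert out.productive is False

    def test_vh_region_excludes_constant_fragment(self, reference,
                                                  annotated_unmutated,
                                                  sim_unmutated):
        truth = sim_unmutated.truth.set_index("sequence_id")
        for rec in annotated_unmutated[:10]:
            c_frag = reference.c_genes[truth.loc[rec.seq_id, "c_call"]]
            assert rec.vh_nt + c_frag.nt_sequence == rec.sequence


class TestDedupe:
    def _mk(self, seq_id, seq, annotated_unmutated):
        import copy
        rec = copy.copy(annotated_unmutated[0])
        rec.seq_id = seq_id
        rec.sequence = seq
        return rec

    def test_identical_sequences_collapse_with_counts(self, annotated_unmutated):
        recs = [self._mk(f"s{i}", "AAA", annotated_unmutated) for i in range(3)]
        recs.append(self._mk("s3", "CCC", annotated_unmutated))
        unique = dedupe_unique(recs)
        assert len(unique) == 2
        assert sorted(r.duplicate_count for r in unique) == [1, 3]

    def test_all_distinct_is_identity(self, annotated_unmutated):
        recs = [self._mk(f"s{i}", f"AAA{i}", annotated_unmutated)
                for i in range(4)]
        assert len(dedupe_unique(recs)) == 4

    def test_empty_input(self):
        assert dedupe_unique([]) == []


def test_mean_identity_monotone_in_shm_rate(reference):
    """Raising the SHM rate never increases mean germline V identity."""
    means = []
    for rate in (0.0, 0.02, 0.05):
        cfg = SimConfig(n_clones=12, clone_size_law=("fixed", 2),
                        shm_rate=rate, seed=31)
        rep = simulate_repertoire(cfg, reference)
        annotated, _ = annotate_repertoire(rep.sequences, reference)
        means.append(np.mean([r.v_identity for r in annotated]))
    assert means[0] >= means[1] >= means[2]


def test_mutation_reconciliation_on_simulated_data(sim_small, annotated_small):
    """silent + nonsilent over regions equals nucleotide mismatches to the
    assigned germline V in the numbered V region (truth mutation list)."""
    truth = sim_small.truth.set_index("sequence_id")
    for rec in annotated_small:
        t = truth.loc[rec.seq_id]
        if rec.v_call != t["v_call"]:
            continue
        muts = [] if t["mutations"] == "" else t["mutations"].split(";")
        assert rec.total_mutations == len(muts)
        assert rec.uncallable == 0
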