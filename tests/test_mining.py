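import pytest

from idrpatterns import (
    Pattern,
    allowed_substitutions,
    extract_candidates,
    greedy_select,
    histag_proximity,
    match,
    mine_library,
    pattern_stats,
    synthesize_xpatterns,
)
from idrpatterns.mining import expand_candidates, filter_lowcomplexity
from idrpatterns.fixtures import plant_motifs

from conftest import make_record


class TestMatch:
    def test_x_position_matches_any_residue(self):
        assert match(Pattern("ASXTGGQQMGR"), "ASNTGGQQMGR") == [0]

    def test_all_x_matches_everywhere(self):
        assert match(Pattern("XXX"), "ACDEFGHIKL") == list(range(8))

    def test_literal_substring(self):
        assert match(Pattern("SSPAK"), "GGSSPAKGG") == [2]

    def test_overlapping_matches_all_reported(self):
        assert match(Pattern("AXA"), "AAAAA") == [0, 1, 2]

    def test_sequence_x_only_matches_pattern_x(self):
        assert match(Pattern("AXA"), "AXA") == [0]
        assert match(Pattern("AAA"), "AXA") == []


class TestExtractCandidates:
    def test_half_disordered_positions_inclusive(self, single_chain_forest):
        seq = "MKVLWAAGQR"
        r1 = make_record("1aaa", seq, "SUUUUUSSSS")
        r2 = make_record("1aab", seq, "S" * 10, chain="B")
        forest = single_chain_forest([r1])
        forest.assignment[100] = {r1.key: 0, r2.key: 0}
        forest.assignment[75] = {r1.key: 0, r2.key: 0}
        cands = extract_candidates([r1, r2], forest)
        assert [c.letters for c in cands] == ["KVLWA"]

    def test_fully_ordered_clusters_yield_nothing(self, single_chain_forest):
        rec = make_record("1aaa", "MKVLWAAGQR", "S" * 10)
        assert extract_candidates([rec], single_chain_forest([rec])) == []

    def test_single_chain_leading_run(self, single_chain_forest):
        rec = make_record("1aaa", "MKVLWAAGQR", "UUUUSSSSSS")
        cands = extract_candidates([rec], single_chain_forest([rec]))
        assert [c.letters for c in cands] == ["MKVL"]

    def test_runs_shorter_than_three_dropped(self, single_chain_forest):
        rec = make_record("1aaa", "MKVLWAAGQR", "UUSSSSSSUS")
        assert extract_candidates([rec], single_chain_forest([rec])) == []

    def test_duplicate_fragments_reported_once(self, single_chain_forest):
        r1 = make_record("1aaa", "MKVLWAAGQR", "UUUUSSSSSS")
        r2 = make_record("1bbb", "MKVLWAAGQR", "UUUUSSSSSS")
        forest = single_chain_forest([r1, r2])
        cands = extract_candidates([r1, r2], forest)
        assert [c.letters for c in cands] == ["MKVL"]


class TestAllowedSubstitutions:
    @pytest.mark.parametrize(
        "length,expected",
        [(3, 0), (5, 0), (6, 1), (8, 1), (10, 1), (11, 2), (13, 2), (15, 2), (16, 3)],
    )
    def test_five_wide_bands(self, length, expected):
        assert allowed_substitutions(length) == expected


class TestSynthesizeXPatterns:
    def test_worked_homologue_merging_example(self):
        candidate = Pattern("ASMTGGQQMGR")
        homologs = ["ASMTGGNNMGR", "ASMTSSQQMGR", "ASNTGGQQMGR"]
        got = {p.letters for p in synthesize_xpatterns(candidate, homologs)}
        expected_subset = {
            "ASMTGGQQMGR",
            "ASMTGGXXMGR",
            "ASMTXXQQMGR",
            "ASXTGGQQMGR",
            "ASMTXXXXMGR",
            "ASXTXXXXMGR",
        }
        assert expected_subset <= got
        # full pairwise closure also contains the remaining combinations
        assert got - expected_subset == {"ASXTGGXXMGR", "ASXTXXQQMGR"}

    def test_identical_homolog_returns_candidate_only(self):
        candidate = Pattern("ASMTGG")
        got = synthesize_xpatterns(candidate, ["ASMTGG"])
        assert [p.letters for p in got] == ["ASMTGG"]

    def test_disjoint_single_mismatches_close_under_union(self):
        candidate = Pattern("MKVLWA")
        got = {p.letters for p in synthesize_xpatterns(candidate, ["MKALWA", "MKVLWG"])}
        assert got == {"MKVLWA", "MKXLWA", "MKVLWX", "MKXLWX"}

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            synthesize_xpatterns(Pattern("MKVLWA"), ["MKVLW"])

    def test_too_many_substitutions_rejected(self):
        with pytest.raises(ValueError):
            synthesize_xpatterns(Pattern("MKVLWA"), ["MKAAAA"])

    def test_expand_candidates_short_patterns_pass_through(self):
        cands = [Pattern("MKVLW"), Pattern("MKVLA")]
        # length 5: no homologue search, both kept as-is
        assert expand_candidates(cands) == cands


class TestFilterLowComplexity:
    def test_drops_ac2_and_homorepeats_keeps_complex(self):
        cands = [
            Pattern("GSGSGSGS"),  # AC2
            Pattern("HHHHHH"),  # homo-repeat
            Pattern("MKVLWA"),  # complex
            Pattern("GSXSGS"),  # has X: kept
        ]
        kept = filter_lowcomplexity(cands)
        assert [p.letters for p in kept] == ["MKVLWA", "GSXSGS"]


class TestPatternStats:
    def test_no_match_gives_zero_stats(self, single_chain_forest):
        rec = make_record("1aaa", "MKVLWAAGQR", "U" * 10)
        st = pattern_stats(Pattern("WWW"), [rec], single_chain_forest([rec]))
        assert (st.n_u, st.n_f, st.c_u, st.c_f, st.d) == (0, 0, 0, 0, 0)

    def test_single_chain_direct_count(self, single_chain_forest):
        rec = make_record("1aaa", "MKVLWAAGQR", "UUUUSSSSSS")
        st = pattern_stats(Pattern("MKVLW"), [rec], single_chain_forest([rec]))
        assert st.n_u == 4 and st.n_f == 1
        assert st.c_u == 1 and st.c_f == 0
        assert st.d == 3

    def test_two_level_averaging_within_c75(self, single_chain_forest):
        # one C75 cluster, two C100 sub-clusters of sizes 2 and 1
        seq = "GGMKVLWGG"
        r1 = make_record("1aaa", seq, "SSUUUUUSS")
        r2 = make_record("1aab", seq, "SSUUUSSSS", chain="B")
        r3 = make_record("2bbb", seq, "SSUUUUUSS")
        forest = single_chain_forest([r1])
        forest.assignment[100] = {r1.key: 0, r2.key: 0, r3.key: 1}
        forest.assignment[75] = {r1.key: 0, r2.key: 0, r3.key: 0}
        st = pattern_stats(Pattern("MKVLW"), [r1, r2, r3], forest)
        # sub-cluster means: ((5,0)+(3,2))/2 = (4,1); (5,0) -> cluster (4.5, 0.5)
        assert st.n_u == pytest.approx(4.5)
        assert st.n_f == pytest.approx(0.5)
        assert (st.c_u, st.c_f) == (1, 0)

    def test_consumed_residues_not_recounted(self, single_chain_forest):
        rec = make_record("1aaa", "MKVLWAAGQR", "UUUUUSSSSS")
        forest = single_chain_forest([rec])
        consumed = {rec.key: set(range(0, 5))}
        st = pattern_stats(Pattern("MKVLW"), [rec], forest, consumed)
        assert st.n_u == 0 and st.n_f == 0

    def test_naive_per_chain_oracle_on_single_chain_forest(self, single_chain_forest):
        import numpy as np

        from idrpatterns.fixtures import random_sequence

        rng = np.random.Generator(np.random.PCG64(21))
        pat = Pattern("QWKR")
        records = []
        for i in range(6):
            seq = random_sequence(rng, 60, avoid=["QWKR"])
            pos = int(rng.integers(5, 50))
            seq = seq[:pos] + "QWKR" + seq[pos + 4 :]
            mask = "".join(rng.choice(["U", "S"], size=60))
            records.append(make_record(f"6r{i:02d}", seq, mask))
        forest = single_chain_forest(records)
        st = pattern_stats(pat, records, forest)
        # oracle: plain per-chain counting over matched positions
        n_u = n_f = c_u = c_f = 0
        for rec in records:
            covered = set()
            for s in match(pat, rec.sequence):
                covered.update(range(s, s + 4))
            if not covered:
                continue
            u = sum(rec.disorder_mask[i] == "U" for i in covered)
            f = len(covered) - u
            n_u += u
            n_f += f
            if u > f:
                c_u += 1
            else:
                c_f += 1
        assert st.n_u == pytest.approx(n_u)
        assert st.n_f == pytest.approx(n_f)
        assert (st.c_u, st.c_f) == (c_u, c_f)


class TestGreedySelect:
    def test_empty_candidates_give_empty_library(self, single_chain_forest):
        rec = make_record("1aaa", "MKVLWAAGQR", "U" * 10)
        assert greedy_select([], [rec], single_chain_forest([rec])) == []

    def test_c1_requires_five_clusters(self):
        records, forest, _ = plant_motifs([("QWERTY", 4, True)], seed=3)
        lib = greedy_select([Pattern("QWERTY")], records, forest, d_min=0)
        assert lib == []

    def test_planted_pattern_selected_with_planted_score(self):
        records, forest, _ = plant_motifs([("MKVLW", 6, True)], seed=4)
        lib = greedy_select([Pattern("MKVLW")], records, forest)
        assert len(lib) == 1
        pat, st = lib[0]
        assert pat.letters == "MKVLW"
        assert st.d == pytest.approx(30.0)  # 6 clusters x 5 disordered residues

    def test_ordered_planting_fails_c3(self):
        records, forest, _ = plant_motifs([("MKVLW", 6, False)], seed=5)
        assert greedy_select([Pattern("MKVLW")], records, forest, d_min=0) == []

    def test_consumption_blocks_nested_pattern(self):
        records, forest, _ = plant_motifs([("MKVLWARQ", 6, True)], seed=6)
        inner = Pattern("KVLWA")  # matches only inside the planted motif
        outer = Pattern("MKVLWARQ")
        lib = greedy_select([inner, outer], records, forest, d_min=0)
        assert [p.letters for p, _ in lib] == ["MKVLWARQ"]

    def test_d_min_filters_final_library(self):
        records, forest, _ = plant_motifs([("MKVLW", 4, True)], seed=7)
        # 4 clusters x 5 residues = 20 < 25, and c_u = 4 < 5: rejected twice over
        assert greedy_select([Pattern("MKVLW")], records, forest) == []

    def test_deterministic_output(self):
        records, forest, _ = plant_motifs(
            [("MKVLW", 6, True), ("QWERTY", 5, True)], seed=8
        )
        cands = [Pattern("MKVLW"), Pattern("QWERTY")]
        a = greedy_select(cands, records, forest)
        b = greedy_select(list(cands), records, forest)
        assert a == b


class TestHistagProximity:
    def _records(self, seqs):
        return [
            make_record(f"7h{i:02d}", s, "S" * len(s)) for i, s in enumerate(seqs)
        ]

    def test_far_from_any_his_run(self):
        seq = "MKVLW" + "A" * 60 + "HHHHHH"
        (pc, label) = histag_proximity(Pattern("MKVLW"), self._records([seq]))
        assert pc == 0.0 and label.startswith("PC = 0%")

    def test_adjacent_to_his_run(self):
        seq = "GG" + "MKVLW" + "HHHHHH" + "GG"
        (pc, label) = histag_proximity(Pattern("MKVLW"), self._records([seq]))
        assert pc == 100.0 and label.startswith("PC = 100%")

    def test_one_of_three_near_boundary_inclusive(self):
        near = "MKVLWHHHHHH" + "A" * 20
        far1 = "MKVLW" + "A" * 60
        far2 = "G" * 50 + "MKVLW" + "G" * 50
        (pc, label) = histag_proximity(Pattern("MKVLW"), self._records([near, far1, far2]))
        assert pc == pytest.approx(100 / 3)
        assert label == "33% <= PC <= 67%"

    def test_no_occurrences_reported_not_applicable(self):
        (pc, label) = histag_proximity(Pattern("WWWWW"), self._records(["A" * 50]))
        assert pc is None and label == "n/a"

    def test_window_boundary_is_strict(self):
        # exactly 40 residues between pattern end and His run: not near
        seq = "MKVLW" + "A" * 40 + "HHHH"
        (pc, _) = histag_proximity(Pattern("MKVLW"), self._records([seq]))
        assert pc == 0.0
        # 39 residues: near
        seq2 = "MKVLW" + "A" * 39 + "HHHH"
        (pc2, _) = histag_proximity(Pattern("MKVLW"), self._records([seq2]))
        assert pc2 == 100.0


class TestMineLibrary:
    def test_recovers_planted_motifs_in_weight_order(self):
        motifs = [("DKTHTNQ", 6, True), ("QWERTY", 6, True), ("MKVLW", 6, True)]
        records, forest, _ = plant_motifs(motifs, seed=9)
        lib = mine_library(records, forest)
        # planted weights: 42, 36, 30
        assert list(lib["pattern"]) == ["DKTHTNQ", "QWERTY", "MKVLW"]
        assert list(lib["d"]) == [42.0, 36.0, 30.0]
        assert (lib["histag_bin"] == "PC = 0% (far)").all()

    def test_byte_identical_reruns(self):
        motifs = [("DKTHTNQ", 6, True), ("MKVLW", 5, True)]
        records, forest, _ = plant_motifs(motifs, seed=10)
        a = mine_library(records, forest).to_csv(index=False)
        b = mine_library(records, forest).to_csv(index=False)
        assert a == b
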