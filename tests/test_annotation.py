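"""V/J assignment, window-protected error correction, CDR3 and N-region inference."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcrarep.annotate import (
    AnnotatedSequence,
    RawRead,
    assign_segment,
    correct_errors,
    estimate_n_bases,
    extract_cdr3,
    filter_singletons,
)
from tcrarep.keys import KeyScheme

from conftest import TOY_J1, TOY_V1

LEN_V = len(TOY_V1)  # 30
LEN_J = len(TOY_J1)  # 21


def _mutate(seq: str, pos: int) -> str:
    other = {"A": "C", "C": "A", "G": "T", "T": "G"}
    return seq[:pos] + other[seq[pos]] + seq[pos + 1 :]


class TestAssignment:
    def test_exact_read_assigns_true_v_with_zero_mismatches(self, toy_groups):
        read = RawRead("r1", TOY_V1 + "GGG" + TOY_J1)
        res = assign_segment(read, toy_groups, "V")
        assert res.assignable
        assert res.group_id == "TRAV01-1A"
        assert res.mismatch_count == 0
        assert res.span == (0, LEN_V)

    def test_single_substitution_tolerated(self, toy_groups):
        read = RawRead("r1", _mutate(TOY_V1, 19) + "GGG" + TOY_J1)
        res = assign_segment(read, toy_groups, "V")
        assert res.assignable
        assert res.group_id == "TRAV01-1A"
        assert res.mismatch_count == 1

    def test_j_assignment_is_suffix_anchored(self, toy_groups):
        read = RawRead("r1", TOY_V1 + "GGG" + TOY_J1)
        res = assign_segment(read, toy_groups, "J")
        assert res.assignable
        assert res.group_id == "TRAJ01"
        assert res.span == (len(read.nt_sequence) - LEN_J, len(read.nt_sequence))

    def test_random_read_is_unassignable(self, toy_groups):
        rng = np.random.default_rng(11)
        read = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 60)])
        # brute force: no toy segment shares a long exact stretch with it
        res = assign_segment(RawRead("r1", read), toy_groups, "V")
        assert not res.assignable

    def test_empty_group_set_is_an_error(self, toy_groups):
        with pytest.raises(ValueError, match="no ambiguity groups"):
            assign_segment(RawRead("r1", TOY_V1), [g for g in toy_groups if g.kind == "J"], "V")


class TestCorrection:
    READ = TOY_V1 + "GG" + TOY_J1  # junction of 2 untemplated bases

    def test_mismatch_five_nt_before_v_end_is_corrected(self):
        raw = _mutate(self.READ, LEN_V - 5)
        res = correct_errors(raw, TOY_V1, TOY_J1)
        assert res.corrected_nt == self.READ
        assert res.corrections_applied == 1

    def test_mismatch_exactly_three_nt_before_v_end_is_protected(self):
        raw = _mutate(self.READ, LEN_V - 3)
        res = correct_errors(raw, TOY_V1, TOY_J1)
        assert res.corrected_nt == raw
        assert res.corrections_applied == 0

    def test_j_side_window_mirrors_v_side(self):
        j_start = LEN_V + 2
        corrected = correct_errors(_mutate(self.READ, j_start + 3), TOY_V1, TOY_J1)
        assert corrected.corrected_nt == self.READ  # 4th J nucleotide: correctable
        protected = correct_errors(_mutate(self.READ, j_start + 2), TOY_V1, TOY_J1)
        assert protected.corrections_applied == 0  # 3rd J nucleotide: protected

    def test_germline_identical_read_untouched(self):
        res = correct_errors(self.READ, TOY_V1, TOY_J1)
        assert res.corrected_nt == self.READ
        assert res.corrections_applied == 0
        assert not res.overlap

    @settings(derandomize=True, max_examples=60)
    @given(
        trim_v=st.integers(0, 3),
        trim_j=st.integers(0, 3),
        n_len=st.integers(0, 6),
        data=st.data(),
    )
    def test_corrections_stay_outside_protected_windows(self, trim_v, trim_j, n_len, data):
        """Whatever the errors, nothing within 3 nt of the predicted V end or
        J start changes, and every change restores the germline base."""
        rng_seed = data.draw(st.integers(0, 10_000))
        rng = np.random.default_rng(rng_seed)
        n_seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, n_len)])
        pre = TOY_V1[: LEN_V - trim_v] + n_seq + TOY_J1[trim_j:]
        raw = pre
        for pos in rng.choice(len(pre), size=rng.integers(0, 4), replace=False):
            raw = _mutate(raw, int(pos))
        res = correct_errors(raw, TOY_V1, TOY_J1)
        off = len(raw) - LEN_J
        for p, (before, after) in enumerate(zip(raw, res.corrected_nt)):
            if before == after:
                continue
            in_v = p <= res.v_end - 4 and after == TOY_V1[p]
            in_j = p >= res.j_start + 3 and after == TOY_J1[p - off]
            assert in_v or in_j, f"illegal correction at {p}"


class TestCdr3:
    def _groups(self, toy_groups):
        by_id = {g.group_id: g for g in toy_groups}
        return by_id["TRAV01-1A"], by_id["TRAJ01"]

    def test_blunt_join_translates_caagtf(self, toy_groups):
        # manual translation: TGT GCT GCA GGA ACT TTT -> C A A G T F
        v, j = self._groups(toy_groups)
        read = TOY_V1 + TOY_J1
        res = extract_cdr3(read, v, j, (0, LEN_V), (len(read) - LEN_J, len(read)))
        assert res.ok
        assert res.cdr3_aa == "CAAGTF"
        assert res.productive
        assert len(res.cdr3_nt) == 3 * len(res.cdr3_aa)

    def test_out_of_frame_junction_is_unproductive(self, toy_groups):
        v, j = self._groups(toy_groups)
        read = TOY_V1 + "G" + TOY_J1
        res = extract_cdr3(read, v, j, (0, LEN_V), (len(read) - LEN_J, len(read)))
        assert res.ok and not res.productive
        assert len(res.cdr3_nt) % 3 != 0

    def test_internal_stop_codon_is_unproductive(self, toy_groups):
        v, j = self._groups(toy_groups)
        read = TOY_V1 + "TAG" + TOY_J1
        res = extract_cdr3(read, v, j, (0, LEN_V), (len(read) - LEN_J, len(read)))
        assert res.ok and not res.productive
        assert "*" in res.cdr3_aa

    def test_anchor_outside_span_fails(self, toy_groups):
        v, j = self._groups(toy_groups)
        read = TOY_V1 + TOY_J1
        res = extract_cdr3(read, v, j, (0, 10), (len(read) - LEN_J, len(read)))
        assert not res.ok


class TestNBases:
    def test_pure_germline_read_has_zero(self):
        assert estimate_n_bases(TOY_V1 + TOY_J1, TOY_V1, TOY_J1) == 0

    def test_four_inserted_bases_counted(self):
        assert estimate_n_bases(TOY_V1 + "GGCC" + TOY_J1, TOY_V1, TOY_J1) == 4

    def test_maximal_v_extension_absorbs_matching_insert(self):
        # V trimmed by 2 ends ...TGTGCTG; inserting "CC" restores the trimmed
        # C, so maximal-V-first attribution leaves a single N base.
        read = TOY_V1[:-2] + "CC" + TOY_J1
        assert TOY_V1[-2] == "C"
        assert estimate_n_bases(read, TOY_V1, TOY_J1) == 1

    def test_matches_brute_force_attribution(self):
        """Oracle: enumerate every germline split (max V prefix, then max J
        suffix on the remainder) by slice comparison."""
        rng = np.random.default_rng(5)
        bases = np.array(list("ACGT"))
        for _ in range(200):
            tv, tj = rng.integers(0, 4, 2)
            n_seq = "".join(bases[rng.integers(0, 4, rng.integers(0, 7))])
            read = TOY_V1[: LEN_V - tv] + n_seq + TOY_J1[tj:]
            v_ext = max(
                k
                for k in range(min(len(read), LEN_V) + 1)
                if read[:k] == TOY_V1[:k]
            )
            rest = len(read) - v_ext
            j_ext = max(
                k
                for k in range(min(rest, LEN_J) + 1)
                if k == 0 or read[len(read) - k :] == TOY_J1[LEN_J - k :]
            )
            expected = len(read) - v_ext - j_ext
            assert estimate_n_bases(read, TOY_V1, TOY_J1) == expected


def _ann(read_id, v="TRAV01-1A", j="TRAJ01", cdr3="CAAGTF", sample="s1"):
    return AnnotatedSequence(
        read_id=read_id,
        sample_id=sample,
        v_group=v,
        j_group=j,
        corrected_nt="",
        cdr3_nt="",
        cdr3_aa=cdr3,
        n_bases=0,
        productive=True,
        corrections_applied=0,
    )


class TestSingletonFilter:
    def test_sequences_occurring_once_are_eliminated(self):
        anns = [_ann(f"x{i}") for i in range(3)] + [_ann("y", cdr3="CARF")]
        kept = filter_singletons(anns)
        assert len(kept) == 3
        assert all(a.cdr3_aa == "CAAGTF" for a in kept)

    def test_all_unique_gives_empty_repertoire(self):
        anns = [_ann(f"r{i}", cdr3=f"CA{c}F") for i, c in enumerate("RSG")]
        assert filter_singletons(anns) == []

    def test_exact_count_tabulation(self):
        anns = (
            [_ann(f"x{i}") for i in range(2)]
            + [_ann(f"y{i}", cdr3="CARF") for i in range(2)]
            + [_ann("z", cdr3="CASF")]
        )
        kept = filter_singletons(anns)
        assert len(kept) == 4
        assert {a.cdr3_aa for a in kept} == {"CAAGTF", "CARF"}

    def test_empty_input_is_not_an_error(self):
        assert filter_singletons([]) == []

    def test_mixed_samples_rejected(self):
        with pytest.raises(ValueError, match="one sample"):
            filter_singletons([_ann("a", sample="s1"), _ann("b", sample="s2")])

    def test_key_scheme_changes_what_counts_as_identical(self):
        anns = [_ann("a", v="TRAV01-1A"), _ann("b", v="TRAV02-1A")]
        assert filter_singletons(anns, KeyScheme.FULL_TCRA) == []
        assert len(filter_singletons(anns, KeyScheme.CDR3_ONLY)) == 2
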