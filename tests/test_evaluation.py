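"""WER alignment, voted appropriateness, correlation, star ratings."""

import edlib
import pytest
from hypothesis import given
from hypothesis import strategies as st

from recuerda.errors import (
    ConstantInputError,
    EmptyInputError,
    EmptyReferenceError,
    InvalidVoteError,
    LengthMismatchError,
    RangeError,
)
from recuerda.evaluation import (
    EvaluationDialogue,
    VoteTable,
    aggregate_wer,
    agreement_percentages,
    pearson,
    read_votes_csv,
    round_half_up,
    rvoted,
    sid_alignment,
    star_rating_summary,
    wer_table,
    word_error_rate,
    write_votes_csv_scaffold,
)

# ---------------------------------------------------------------------------
# WER
# ---------------------------------------------------------------------------


def recursive_edit_distance(a, b):
    """Brute-force recursive oracle (memoized), independent of the DP."""
    memo = {}

    def rec(i, j):
        if i == len(a):
            return len(b) - j
        if j == len(b):
            return len(a) - i
        if (i, j) not in memo:
            memo[i, j] = min(
                rec(i + 1, j + 1) + (a[i] != b[j]),
                rec(i + 1, j) + 1,
                rec(i, j + 1) + 1,
            )
        return memo[i, j]

    return rec(0, 0)


class TestWordErrorRate:
    def test_identical_transcripts_have_zero_wer(self):
        res = word_error_rate("Nací en Puebla en 1940", "Nací en Puebla en 1940")
        assert res.wer == 0.0
        assert (res.S, res.I, res.D) == (0, 0, 0)

    def test_normalization_insensitivity(self):
        assert word_error_rate("¿Cómo ESTÁS?", "cómo estás").wer == 0.0

    def test_empty_hypothesis_is_all_deletions(self):
        res = word_error_rate("uno dos tres", "")
        assert (res.N, res.S, res.I, res.D) == (3, 0, 0, 3)
        assert res.wer == 1.0

    def test_mixed_errors(self):
        res = word_error_rate("a b c d", "a x c")
        assert (res.S, res.I, res.D) == (1, 0, 1)
        assert res.wer == 0.5

    def test_wer_can_exceed_one(self):
        assert word_error_rate("a", "x y z").wer > 1.0

    def test_empty_reference_rejected(self):
        with pytest.raises(EmptyReferenceError):
            word_error_rate("...", "hola")

    @given(
        st.lists(st.sampled_from("abc"), max_size=5),
        st.lists(st.sampled_from("abc"), max_size=5),
    )
    def test_alignment_matches_recursive_oracle_and_bounds(self, ref, hyp):
        s, i, d = sid_alignment(ref, hyp)
        total = s + i + d
        assert total == recursive_edit_distance(ref, hyp)
        assert abs(len(ref) - len(hyp)) <= total <= max(len(ref), len(hyp), total)
        if ref or hyp:
            assert total <= max(len(ref), len(hyp))
        assert len(ref) - len(hyp) == d - i

    @given(
        st.lists(st.sampled_from(["casa", "sol", "mar", "pan"]), max_size=6),
        st.lists(st.sampled_from(["casa", "sol", "mar", "pan"]), max_size=6),
    )
    def test_alignment_distance_agrees_with_edlib(self, ref, hyp):
        """Cross-check against an independent alignment library."""
        s, i, d = sid_alignment(ref, hyp)
        alphabet = {w: chr(65 + k) for k, w in enumerate(["casa", "sol", "mar", "pan"])}
        q = "".join(alphabet[w] for w in ref)
        t = "".join(alphabet[w] for w in hyp)
        if q and t:
            assert s + i + d == edlib.align(q, t, task="distance")["editDistance"]


class TestAggregation:
    def test_printed_asr_benchmark_column(self):
        col = [0.39, 0.27, 0.43, 0.34, 0.50, 0.37, 0.41, 0.45]
        assert round_half_up(aggregate_wer(col), 3) == 0.395

    def test_single_and_constant_values(self):
        assert aggregate_wer([0.3]) == 0.3
        assert aggregate_wer([0.2] * 8) == pytest.approx(0.2)

    def test_accepts_wer_results(self):
        results = [word_error_rate("a b", "a b"), word_error_rate("a b", "x b")]
        assert aggregate_wer(results) == pytest.approx(0.25)

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            aggregate_wer([])

    def test_wer_table_layout(self):
        table = wer_table({"ASR": [0.39, 0.27]}, labels=["af1", "af2"])
        lines = table.splitlines()
        assert lines[-1].startswith("Average")
        assert "0.330" in lines[-1]


# ---------------------------------------------------------------------------
# voted appropriateness
# ---------------------------------------------------------------------------


def _dialogue(did="d1"):
    return EvaluationDialogue(
        dialogue_id=did,
        context_id="family",
        turns=(
            ("system", "¿Cómo estás?"),
            ("user", "bien"),
            ("system", "¿Quieres platicar de tu familia?"),
            ("user", "sí"),
        ),
        candidates=("r0", "r1", "r2", "r3"),
    )


class TestRvoted:
    def test_unanimous_vote(self):
        votes = VoteTable("d1", {f"ev{i}": 0 for i in range(11)})
        res = rvoted(_dialogue(), votes)
        assert res.counts == (11, 0, 0, 0)
        assert res.rmax == 11

    def test_no_votes(self):
        res = rvoted(_dialogue(), VoteTable("d1", {}))
        assert res.counts == (0, 0, 0, 0)
        assert res.rmax == 0

    def test_vote_conservation(self):
        votes = {f"ev{i}": c for i, c in enumerate([0] * 5 + [1] * 4 + [2] * 2)}
        res = rvoted(_dialogue(), VoteTable("d1", votes))
        assert sum(res.counts) == 11
        assert res.counts == (5, 4, 2, 0)
        assert res.rmax == 5

    def test_out_of_range_vote_rejected(self):
        with pytest.raises(InvalidVoteError):
            VoteTable("d1", {"ev1": 4})


class TestAgreement:
    def test_fraction_of_dialogues(self):
        dialogues = [_dialogue(f"d{i}") for i in range(40)]
        votes = []
        for i in range(40):
            winner = 0 if i < 25 else 1
            votes.append(VoteTable(f"d{i}", {"ev1": winner, "ev2": winner, "ev3": 2}))
        pct = agreement_percentages(dialogues, votes)
        assert pct[0] == 62.5
        assert pct[1] == 37.5
        assert pct[2] == 0.0 and pct[3] == 0.0

    def test_ties_count_for_every_position(self):
        dialogues = [_dialogue("d0")]
        votes = [VoteTable("d0", {"ev1": 0, "ev2": 1})]
        pct = agreement_percentages(dialogues, votes)
        assert pct[0] == 100.0 and pct[1] == 100.0
        assert sum(pct) > 100.0

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(LengthMismatchError):
            agreement_percentages([_dialogue()], [])

    @given(st.lists(st.integers(0, 3), min_size=11, max_size=11), st.integers(0, 5))
    def test_some_position_always_reaches_rmax(self, choices, n_dialogues_seed):
        dialogues = [_dialogue("d0")]
        votes = [VoteTable("d0", {f"ev{i}": c for i, c in enumerate(choices)})]
        pct = agreement_percentages(dialogues, votes)
        assert sum(pct) >= 100.0


class TestPearson:
    def test_perfect_correlations(self):
        assert pearson([1, 2, 3, 4], [1, 2, 3, 4]).r == pytest.approx(1.0)
        assert pearson([1, 2, 3, 4], [-1, -2, -3, -4]).r == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # x=(1,2,3,4), y=(1,2,3,5): cov=1.75/..., direct formula gives 0.982708
        res = pearson([1, 2, 3, 4], [1, 2, 3, 5])
        sx = [1, 2, 3, 4]
        sy = [1, 2, 3, 5]
        mx, my = sum(sx) / 4, sum(sy) / 4
        num = sum((a - mx) * (b - my) for a, b in zip(sx, sy))
        den = (sum((a - mx) ** 2 for a in sx) * sum((b - my) ** 2 for b in sy)) ** 0.5
        assert res.r == pytest.approx(num / den)
        assert res.n == 4
        assert 0 <= res.p_value <= 1

    def test_constant_input_rejected(self):
        with pytest.raises(ConstantInputError):
            pearson([1, 1, 1], [1, 2, 3])

    def test_length_mismatch_rejected(self):
        with pytest.raises(LengthMismatchError):
            pearson([1, 2, 3], [1, 2])

    @given(
        st.lists(st.integers(0, 11), min_size=4, max_size=40),
        st.integers(0, 10**6),
    )
    def test_r_is_bounded(self, xs, salt):
        import random

        ys = [random.Random(salt + i).randint(0, 11) for i, _ in enumerate(xs)]
        try:
            res = pearson(xs, ys)
        except ConstantInputError:
            return
        assert -1.0 <= res.r <= 1.0


class TestStarRatings:
    def test_printed_distribution(self):
        summary = star_rating_summary([4] * 7 + [5] * 3 + [3])
        assert summary.mean == 4.18
        assert summary.counts[4] == 7 and summary.counts[5] == 3 and summary.counts[3] == 1
        assert summary.percentages[4] == 63.6

    def test_edge_distributions(self):
        assert star_rating_summary([5, 5, 5]).mean == 5.0
        assert star_rating_summary([3]).mean == 3.0

    @pytest.mark.parametrize("bad", [0, 6, -1])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(RangeError):
            star_rating_summary([4, bad])


class TestVotesCSV:
    def test_round_trip_and_scaffold(self, tmp_path):
        path = tmp_path / "votes.csv"
        write_votes_csv_scaffold(path, [_dialogue("d1"), _dialogue("d2")], ["ev1", "ev2"])
        assert read_votes_csv(path) == {}  # scaffold rows are blank
        filled = path.read_text().replace("d1,ev1,", "d1,ev1,0").replace(
            "d2,ev2,", "d2,ev2,3"
        )
        path.write_text(filled)
        tables = read_votes_csv(path)
        assert tables["d1"].votes == {"ev1": 0}
        assert tables["d2"].votes == {"ev2": 3}

    def test_duplicate_evaluator_rejected(self, tmp_path):
        path = tmp_path / "votes.csv"
        path.write_text(
            "dialogue_id,evaluator_id,chosen_candidate\nd1,ev1,0\nd1,ev1,1\n"
        )
        with pytest.raises(InvalidVoteError):
            read_votes_csv(path)

    def test_out_of_range_candidate_rejected(self, tmp_path):
        path = tmp_path / "votes.csv"
        path.write_text("dialogue_id,evaluator_id,chosen_candidate\nd1,ev1,7\n")
        with pytest.raises(InvalidVoteError):
            read_votes_csv(path)
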