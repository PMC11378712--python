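"""Trial table I/O, adaptive cutoffs, exclusion cascade, sequence coding."""

import numpy as np
import pandas as pd
import pytest

from rtseq import (
    ALTERNATION,
    REPETITION,
    UNDEFINED,
    FilterConfig,
    TrialTable,
    code_sequence,
    determine_lower_bound,
    exclude_participants,
    filter_trials,
    load_trials,
    write_trials,
)
from rtseq.preprocessing import FormatError, ValidationError


def _table(rows, paradigm="two_choice", **design):
    df = pd.DataFrame(
        rows,
        columns=["participant", "block", "trial", "stimulus_type", "correct", "rt_ms"],
    )
    df["paradigm"] = paradigm
    df["stimulus_detail"] = "x"
    df["response"] = "f"
    return TrialTable(df, **design)


class TestIO:
    def test_round_trip_identity(self, tmp_path, vs_dataset):
        table, _ = vs_dataset
        path = tmp_path / "trials.csv"
        write_trials(table, path)
        back = load_trials(path, "visual_search")
        lhs = table.df.reset_index(drop=True)
        rhs = back.df[lhs.columns].reset_index(drop=True)
        pd.testing.assert_frame_equal(lhs, rhs, check_dtype=False)

    def test_small_file_loads_ordered(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "participant,paradigm,block,trial,stimulus_type,stimulus_detail,"
            "response,correct,rt_ms\n"
            "p1,two_choice,1,2,majority_red,red,j,1,450\n"
            "p1,two_choice,1,1,majority_green,green,f,1,400\n"
            "p1,two_choice,1,3,majority_red,red,j,0,500\n"
        )
        t = load_trials(path, "two_choice")
        assert len(t) == 3
        assert list(t.df["trial"]) == [1, 2, 3]

    def test_negative_rt_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "participant,paradigm,block,trial,stimulus_type,stimulus_detail,"
            "response,correct,rt_ms\np1,two_choice,1,1,majority_red,red,j,1,-5\n"
        )
        with pytest.raises(ValidationError, match="row"):
            load_trials(path, "two_choice")

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("participant,block\np1,1\n")
        with pytest.raises(FormatError):
            load_trials(path, "two_choice")

    def test_unknown_stimulus_type_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "participant,paradigm,block,trial,stimulus_type,stimulus_detail,"
            "response,correct,rt_ms\np1,two_choice,1,1,congruent,red,j,1,400\n"
        )
        with pytest.raises(ValidationError):
            load_trials(path, "two_choice")


class TestLowerBound:
    def test_hand_traced_rule(self):
        # bins from 0: empty, empty, empty, empty (0-200); then counts built
        # so that per-bin accuracy is [.40,.55,.90,.95] from 200 ms on and
        # cumulative accuracy crosses .5 only from the 300-350 bin onward
        rows = []
        i = 1

        def add(lo, n_corr, n_err):
            nonlocal i
            for _ in range(n_corr):
                rows.append(("p1", 1, i, "majority_red", 1, lo + 10))
                i += 1
            for _ in range(n_err):
                rows.append(("p1", 1, i, "majority_red", 0, lo + 10))
                i += 1

        add(200, 8, 12)   # .40, cum .40
        add(250, 11, 9)   # .55, cum .475
        add(300, 18, 2)   # .90, cum .617  -> first of two good bins
        add(350, 19, 1)   # .95, cum .70
        t = _table(rows, trials_per_block=200)
        assert determine_lower_bound(t) == 300.0

    def test_all_perfect_returns_first_bin(self):
        rows = [("p1", 1, i + 1, "majority_red", 1, 420 + i) for i in range(20)]
        t = _table(rows)
        assert determine_lower_bound(t) == 400.0

    def test_no_bound_found_raises(self):
        rows = [("p1", 1, i + 1, "majority_red", 0, 420 + i) for i in range(20)]
        with pytest.raises(ValueError, match="no-bound-found"):
            determine_lower_bound(_table(rows))


class TestFilter:
    def _twelve(self):
        rows = []
        for i in range(1, 13):
            correct = 0 if i == 5 else 1
            rt = 3500 if i == 7 else 600
            rows.append(("p1", 1, i, "majority_red", correct, rt))
        return _table(rows, n_blocks=1, trials_per_block=12)

    def test_hand_enumeration(self):
        filt, rep = filter_trials(self._twelve(), FilterConfig(lower_rt_ms=250))
        assert rep.n_excluded_by_rule == {
            "practice": 0, "warmup": 2, "post_error": 1, "rt_range": 1,
        }
        assert len(filt) == 8
        assert 6 not in set(filt.df["trial"])  # post-error trial
        assert 7 not in set(filt.df["trial"])  # slow trial

    def test_clean_table_loses_only_warmups(self):
        rows = [
            ("p1", b, i, "majority_red", 1, 500)
            for b in (1, 2, 3)
            for i in range(1, 11)
        ]
        t = _table(rows, n_blocks=3, trials_per_block=10)
        filt, rep = filter_trials(t, FilterConfig(lower_rt_ms=250))
        assert len(filt) == len(t) - 2 * 3
        assert rep.n_excluded == 6

    def test_idempotent(self, vs_dataset):
        table, _ = vs_dataset
        cfg = FilterConfig(lower_rt_ms=300)
        once, _ = filter_trials(table, cfg)
        twice, rep2 = filter_trials(once, cfg)
        pd.testing.assert_frame_equal(once.df, twice.df)
        # second pass removes nothing new except re-flagged warmups? none:
        assert rep2.n_excluded == 0

    def test_counts_conserve(self, vs_dataset):
        table, _ = vs_dataset
        filt, rep = filter_trials(table, FilterConfig(lower_rt_ms=300))
        assert rep.n_input == len(filt) + rep.n_excluded


class TestParticipantExclusion:
    def _participants(self, specs):
        rows = []
        for pid, pc, rt in specs:
            n = 100
            n_corr = int(round(pc * n))
            for i in range(1, n + 1):
                rows.append((pid, 1, i, "majority_red", 1 if i <= n_corr else 0, rt))
        return _table(rows, trials_per_block=100)

    def test_low_accuracy_dropped(self):
        t = self._participants([("p1", 0.65, 500), ("p2", 0.95, 500), ("p3", 0.93, 500)])
        out, rep = exclude_participants(t)
        assert rep["accuracy"] == ["p1"]
        assert set(out.df["participant"]) == {"p2", "p3"}

    def test_identical_participants_none_dropped(self):
        t = self._participants([(f"p{i}", 0.9, 500) for i in range(5)])
        out, rep = exclude_participants(t)
        assert all(v == [] for v in rep.values())
        assert out.df["participant"].nunique() == 5

    def test_log_rt_outlier_dropped(self, rng):
        # 30 participants, mean log RT ~ N(log 500, 0.05); one shifted +5
        # population SDs, far enough that the 3-sample-SD rule must fire
        rows = []
        for p in range(30):
            mu = np.log(500) + rng.normal(0, 0.05)
            if p == 0:
                mu = np.log(500) + 5 * 0.05
            rts = np.exp(rng.normal(mu, 0.05, 80))
            err = rng.random(80) < 0.05
            for i, (r, e) in enumerate(zip(rts, err), start=1):
                rows.append((f"p{p:02d}", 1, i, "majority_red", int(not e), float(r)))
        t = _table(rows, trials_per_block=80)
        out, rep = exclude_participants(t)
        assert rep["log_rt_3sd"] == ["p00"]
        assert rep["accuracy"] == []


class TestSequenceCoding:
    def _coded(self, paradigm, types):
        rows = [
            ("p1", 1, i + 1, st, 1, 500.0) for i, st in enumerate(types)
        ]
        t = _table(rows, paradigm=paradigm, trials_per_block=len(types))
        return list(code_sequence(t).df["sequence"])

    @pytest.mark.parametrize(
        "paradigm,types,expected",
        [
            (
                "visual_search",
                ["absent", "color", "color", "form"],
                [UNDEFINED, UNDEFINED, REPETITION, ALTERNATION],
            ),
            (
                "two_choice",
                ["majority_green", "majority_green", "majority_red"],
                [UNDEFINED, REPETITION, ALTERNATION],
            ),
            (
                "task_switching",
                ["color_task", "form_task", "form_task"],
                [UNDEFINED, ALTERNATION, REPETITION],
            ),
            (
                "interference",
                ["congruent", "congruent", "incongruent", "incongruent"],
                [UNDEFINED, REPETITION, ALTERNATION, REPETITION],
            ),
        ],
    )
    def test_paradigm_rules(self, paradigm, types, expected):
        assert self._coded(paradigm, types) == expected

    def test_block_first_trial_never_defined(self, ts_dataset):
        table, _ = ts_dataset
        coded = code_sequence(table)
        firsts = coded.df[coded.df["trial"] == 1]
        assert (firsts["sequence"] == UNDEFINED).all()

    def test_iid_two_choice_repetition_fraction_half(self, rng):
        n = 4000
        types = rng.choice(["majority_green", "majority_red"], n)
        rows = [("p1", 1, i + 1, st, 1, 500.0) for i, st in enumerate(types)]
        t = _table(rows, paradigm="two_choice", trials_per_block=n)
        seq = code_sequence(t).df["sequence"]
        defined = seq[seq != UNDEFINED]
        frac = (defined == REPETITION).mean()
        # 4 binomial SEs around 1/2
        assert abs(frac - 0.5) < 4 * 0.5 / np.sqrt(len(defined))

    def test_unknown_paradigm_raises(self):
        rows = [("p1", 1, 1, "majority_red", 1, 500.0)]
        t = _table(rows)
        t.df["paradigm"] = "simon"
        with pytest.raises(ValueError):
            code_sequence(t)
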