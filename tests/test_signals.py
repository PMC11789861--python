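import numpy as np
import pytest

from conftest import table
from pvsignal import datasets
from pvsignal.exceptions import UnmappedTermError
from pvsignal.signals import (
    SignalRecord,
    annotate_label,
    detect_signals,
    exclude_socs,
    rank_signals,
    summarize_by_soc,
)
from pvsignal.stats import compute_bcpnn, compute_ror


def make_tables(rng, n, n_total=20_000):
    out = []
    for i in range(n):
        a = int(rng.integers(1, 40))
        b = int(rng.integers(0, 500))
        c = int(rng.integers(0, 2000))
        d = n_total - a - b - c
        out.append(table(a, b, c, d, pt=f"pt{i:04d}"))
    return out


class TestDetectSignals:
    def test_independence_table_is_not_signal(self):
        (rec,) = detect_signals([table(10, 10, 10, 10)])
        assert not rec.is_signal

    def test_worked_example_is_signal(self):
        (rec,) = detect_signals([table(5, 10, 20, 965)])
        assert rec.is_signal
        assert rec.ror_result.ci_lower == pytest.approx(7.55, abs=0.01)
        assert rec.bcpnn_result.ic025 == pytest.approx(0.60, abs=0.01)

    def test_low_count_never_signals(self):
        """a=2 with an enormous ROR still fails the a >= 3 rule."""
        (rec,) = detect_signals([table(2, 1, 1, 9996)])
        assert rec.ror_result.ror > 100
        assert not rec.is_signal

    def test_subthreshold_pairs_are_retained(self):
        recs = detect_signals([table(1, 5, 5, 989), table(5, 10, 20, 965)])
        assert len(recs) == 2
        assert [r.is_signal for r in recs] == [False, True]

    def test_equals_brute_force_conjunction(self):
        """The emitted signal set is exactly the intersection of the three
        conditions recomputed independently per table."""
        rng = np.random.default_rng(8)
        tables = make_tables(rng, 300)
        got = {r.pt_name for r in detect_signals(tables) if r.is_signal}
        expected = set()
        for t in tables:
            ror = compute_ror(t)
            ic = compute_bcpnn(t)
            if t.a >= 3 and ror.ci_lower > 1 and ic.ic025 > 0:
                expected.add(t.pt_name)
        assert got == expected
        assert 0 < len(expected) < len(tables)

    def test_monotone_in_thresholds(self):
        """Raising min_count or widening the CI never adds signals."""
        rng = np.random.default_rng(9)
        tables = make_tables(rng, 200)
        base = {r.pt_name for r in detect_signals(tables) if r.is_signal}
        stricter_count = {
            r.pt_name for r in detect_signals(tables, min_count=5) if r.is_signal
        }
        stricter_ci = {
            r.pt_name for r in detect_signals(tables, z=2.58) if r.is_signal
        }
        assert stricter_count <= base
        assert stricter_ci <= base


class TestRankSignals:
    def _records(self, tables):
        return detect_signals(tables)

    def test_tie_on_frequency_breaks_by_ci_then_name(self):
        recs = self._records(
            [table(5, 10, 20, 965, pt="ptb"), table(5, 40, 20, 935, pt="pta")]
        )
        ranked = rank_signals(recs, "frequency", 2)
        assert [r.pt_name for r in ranked] == ["ptb", "pta"]  # higher CI first

    def test_exact_tie_breaks_by_name(self):
        recs = self._records(
            [table(5, 10, 20, 965, pt="ptz"), table(5, 10, 20, 965, pt="pta")]
        )
        assert [r.pt_name for r in rank_signals(recs, "frequency", 2)] == ["pta", "ptz"]

    def test_top_n_larger_than_list(self):
        recs = self._records([table(5, 10, 20, 965)])
        assert len(rank_signals(recs, "frequency", 100)) == 1

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(10)
        recs = self._records(make_tables(rng, 100))
        for key, attr in [
            ("frequency", lambda r: (r.a, r.ror_result.ci_lower)),
            ("ror_ci_lower", lambda r: (r.ror_result.ci_lower, r.a)),
        ]:
            expected = sorted(
                recs, key=lambda r: (-attr(r)[0], -attr(r)[1], r.pt_name)
            )[:30]
            assert rank_signals(recs, key, 30) == expected

    def test_bad_arguments_rejected(self):
        with pytest.raises(ValueError):
            rank_signals([], "frequency", 0)
        with pytest.raises(ValueError):
            rank_signals([], "nonsense", 5)


class TestExcludeSocs:
    def _recs_with_socs(self):
        tables = [table(5, 10, 20, 965, pt=f"pt{i}") for i in range(6)]
        soc_map = {f"pt{i}": f"soc{i % 3}" for i in range(6)}
        return detect_signals(tables, pt_soc_map=soc_map)

    def test_empty_exclusion_is_identity(self):
        recs = self._recs_with_socs()
        assert exclude_socs(recs, []) == recs

    def test_all_excluded_gives_empty(self):
        recs = self._recs_with_socs()
        assert exclude_socs(recs, {"soc0", "soc1", "soc2"}) == []

    def test_mixed_matches_set_membership_scan(self):
        recs = self._recs_with_socs()
        excluded = {"soc1"}
        got = exclude_socs(recs, excluded)
        assert got == [r for r in recs if r.soc_name not in excluded]
        assert len(got) == 4


class TestAnnotateLabel:
    def _recs(self, pts):
        return detect_signals([table(5, 10, 20, 965, pt=p) for p in pts])

    def test_membership_sets_flag(self):
        recs = annotate_label(self._recs(["nausea", "vertigo"]), ["Nausea"])
        assert [r.in_label for r in recs] == [True, False]

    def test_no_label_list_gives_unknown(self):
        recs = annotate_label(self._recs(["nausea"]), None)
        assert recs[0].in_label is None

    def test_example_label_partition(self):
        """The bundled 79 capmatinib signal PTs against the 66-term label
        list leave exactly 13 flagged as not in the label."""
        pts = datasets.capmatinib_signal_pts()["pt"].tolist()
        recs = annotate_label(self._recs(pts), datasets.capmatinib_label_pts())
        assert len(recs) == 79
        assert sum(1 for r in recs if r.in_label is False) == 13
        assert sum(1 for r in recs if r.in_label) == 66


class TestSummarizeBySoc:
    def test_single_signal(self):
        recs = detect_signals([table(5, 10, 20, 965)], pt_soc_map={"pt0001": "socx"})
        (summary,) = summarize_by_soc(recs, {"pt0001": "socx"})
        assert summary.n_signal_pts == 1 and summary.n_reports == 5

    def test_totals_conserved_single_soc(self):
        tables = [table(3 + i, 10, 20, 967 - i, pt=f"pt{i}") for i in range(4)]
        soc_map = {f"pt{i}": "soconly" for i in range(4)}
        recs = detect_signals(tables, pt_soc_map=soc_map)
        (summary,) = summarize_by_soc(recs, soc_map)
        assert summary.n_signal_pts == 4
        assert summary.n_reports == sum(t.a for t in tables)

    def test_matches_groupby_oracle(self):
        import pandas as pd

        rng = np.random.default_rng(13)
        tables = make_tables(rng, 80)
        soc_map = {t.pt_name: f"soc{rng.integers(0, 8)}" for t in tables}
        recs = detect_signals(tables, pt_soc_map=soc_map)
        summaries = summarize_by_soc(recs, soc_map)
        df = pd.DataFrame({"soc": [soc_map[r.pt_name] for r in recs], "a": [r.a for r in recs]})
        oracle = df.groupby("soc").agg(n=("a", "size"), tot=("a", "sum"))
        assert len(summaries) == len(oracle)
        for s in summaries:
            assert s.n_signal_pts == oracle.loc[s.soc_name, "n"]
            assert s.n_reports == oracle.loc[s.soc_name, "tot"]
        assert sum(s.n_signal_pts for s in summaries) == len(recs)
        assert sum(s.n_reports for s in summaries) == sum(r.a for r in recs)

    def test_unmapped_pt_raises_with_offenders(self):
        recs = detect_signals([table(5, 10, 20, 965, pt="mystery")])
        with pytest.raises(UnmappedTermError) as exc:
            summarize_by_soc(recs, {"other": "soc"})
        assert "mystery" in str(exc.value)
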