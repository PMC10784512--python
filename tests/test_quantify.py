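"""Accounting pipeline: pools, derived statistics, pore health."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import run_pools, truth_assignment
from poresift import quantify, simulate, synthesize
from poresift.iofmt import (
    AlignmentRecord,
    Decision,
    DecisionRecord,
    PoreScanRecord,
    SummaryRecord,
)
from poresift.quantify import (
    CountTable,
    binned_efficiency,
    build_report,
    composition,
    count_reads_bases,
    coverage_profile,
    fold_reduction,
    percent_increase,
    pool_by_decision,
    pore_decay,
    pore_hazard_mle,
    qc_filter,
    rejected_pool_stats,
    split_by_channel,
    top_share,
)


def _summary(read_id, channel=1, q=9.0, length=100, t=0.0):
    return SummaryRecord(read_id, channel, t, length, q)


class TestPreprocessing:
    def test_q_threshold_is_inclusive(self):
        recs = [_summary("a", q=6.9), _summary("b", q=7.0),
                _summary("c", q=7.1)]
        assert qc_filter(recs, 7.0) == {"b", "c"}

    @settings(derandomize=True, max_examples=20)
    @given(st.lists(st.floats(0, 20, allow_nan=False), max_size=30))
    def test_q_filter_matches_brute_force(self, qs):
        recs = [_summary(f"r{i}", q=q) for i, q in enumerate(qs)]
        assert qc_filter(recs, 7.0) == {
            r.read_id for r in recs if r.mean_q >= 7.0
        }

    def test_channel_split_boundary(self):
        recs = [_summary("a", channel=256), _summary("b", channel=257)]
        bulk, as_side = split_by_channel(recs, (257, 512))
        assert bulk == {"a"} and as_side == {"b"}

    def test_channel_outside_flow_cell_rejected(self):
        with pytest.raises(ValueError, match="channel"):
            split_by_channel([_summary("a", channel=513)], (257, 512))

    def test_pool_rule_stop_and_no_decision_accepted(self):
        decisions = [
            DecisionRecord("a", 300, Decision.STOP_RECEIVING),
            DecisionRecord("b", 300, Decision.NO_DECISION),
            DecisionRecord("c", 300, Decision.UNBLOCK),
        ]
        accepted, rejected = pool_by_decision({"a", "b", "c"}, decisions)
        assert accepted == {"a", "b"} and rejected == {"c"}

    def test_missing_decision_row_is_an_error(self):
        with pytest.raises(ValueError, match="ghost"):
            pool_by_decision({"ghost"}, [])

    @settings(derandomize=True, max_examples=20)
    @given(st.lists(st.sampled_from(list(Decision)), max_size=40))
    def test_pools_partition_as_reads(self, decisions):
        recs = [DecisionRecord(f"r{i}", 300, d)
                for i, d in enumerate(decisions)]
        ids = {r.read_id for r in recs}
        accepted, rejected = pool_by_decision(ids, recs)
        assert accepted | rejected == ids
        assert accepted.isdisjoint(rejected)

    def test_count_reads_bases(self):
        assignment = {f"r{i}": ("tx1", 100) for i in range(3)}
        ct = count_reads_bases(assignment, assignment, "bulk")
        assert ct.rows == {"tx1": (3, 300)}
        assert count_reads_bases([], {}, "bulk").rows == {}

    def test_two_primary_alignments_rejected(self):
        alns = [
            AlignmentRecord("r1", "a", 0, 10, "+", 0, 10),
            AlignmentRecord("r1", "b", 0, 10, "+", 0, 10),
        ]
        with pytest.raises(ValueError, match="r1"):
            quantify.assignment_from_alignments(alns)


PRINTED_STATS = [
    # (bulk, adaptive, decimals, rounding, expected)
    (16227, 19867, 0, "half_up", 22.0),
    (16149, 17252, 0, "half_up", 7.0),
    (27469, 36840, 0, "half_up", 34.0),
    (28844, 37174, 0, "half_up", 29.0),
    (26542, 33631, 0, "half_up", 27.0),
    (18_030_000, 22_150_000, 1, "truncate", 22.8),
    (30912, 35057, 1, "half_up", 13.4),
]

PRINTED_FOLDS = [
    (56695, 12006, 2, 4.72),
    (52850, 12786, 1, 4.1),
    (12113, 4268, 2, 2.84),
    (18952, 15048, 2, 1.26),  # fold increase: numerator is the larger pool
]


class TestDerivedStatistics:
    @pytest.mark.parametrize("bulk,adaptive,dec,mode,expected",
                             PRINTED_STATS)
    def test_percent_increase_reproduces_reported_values(
            self, bulk, adaptive, dec, mode, expected):
        assert percent_increase(bulk, adaptive, dec, mode) == expected

    @pytest.mark.parametrize("bulk,adaptive,dec,expected", PRINTED_FOLDS)
    def test_fold_change_reproduces_reported_values(
            self, bulk, adaptive, dec, expected):
        assert fold_reduction(bulk, adaptive, dec) == expected

    def test_identity_cases(self):
        assert percent_increase(1234, 1234) == 0
        assert fold_reduction(1234, 1234) == 1.0

    def test_undefined_denominators(self):
        with pytest.raises(ValueError):
            percent_increase(0, 10)
        with pytest.raises(ValueError):
            fold_reduction(10, 0)

    def test_rejected_pool_definitions(self):
        ct = CountTable("as_rejected",
                        {"t": (95, 0), "o": (5, 0)})
        purity, frr = rejected_pool_stats(ct, {"t"}, "deplete")
        assert purity == pytest.approx(0.95)
        assert frr == pytest.approx(0.05)
        purity_e, frr_e = rejected_pool_stats(ct, {"t"}, "enrich")
        assert purity_e == pytest.approx(0.05)
        assert purity + frr == pytest.approx(1.0)

    def test_composition_and_top_share(self):
        ct = CountTable("bulk", {f"t{i}": (10, 100) for i in range(4)})
        comp = composition(ct)
        assert all(v == 0.25 for v in comp.values())
        assert sum(comp.values()) == pytest.approx(1.0)
        assert top_share(ct, 4) == 1.0
        assert top_share(ct, 2) == 0.5

    @settings(derandomize=True, max_examples=20)
    @given(st.lists(st.integers(1, 1000), min_size=1, max_size=30))
    def test_composition_always_normalized(self, counts):
        ct = CountTable("bulk",
                        {f"t{i}": (c, c) for i, c in enumerate(counts)})
        assert sum(composition(ct).values()) == pytest.approx(1.0)


class TestBinnedEfficiency:
    def test_single_bin_reproduces_composition(self):
        bulk = CountTable("bulk", {"a": (30, 0), "b": (70, 0)})
        acc = CountTable("as_accepted", {"a": (50, 0), "b": (50, 0)})
        attr = {"a": 300.0, "b": 2000.0}
        df = binned_efficiency(bulk, acc, attr, edges=(0, math.inf))
        assert df.loc[0, "bulk_pct"] == pytest.approx(100.0)
        assert df.loc[0, "as_pct"] == pytest.approx(100.0)

    def test_matches_brute_force_binning(self):
        rng = np.random.default_rng(1)
        tids = [f"t{i}" for i in range(40)]
        attr = {t: float(rng.integers(200, 3000)) for t in tids}
        bulk = CountTable("bulk",
                          {t: (int(rng.integers(1, 50)), 0) for t in tids})
        acc = CountTable("as_accepted",
                         {t: (int(rng.integers(1, 50)), 0) for t in tids})
        edges = (200, 400, 600, 1000, math.inf)
        df = binned_efficiency(bulk, acc, attr, edges)
        for i, (lo, hi) in enumerate(zip(edges, edges[1:])):
            members = [t for t in tids if lo <= attr[t] < hi]
            b = 100 * sum(bulk.reads(t) for t in members) / bulk.total_reads
            a = 100 * sum(acc.reads(t) for t in members) / acc.total_reads
            assert df.loc[i, "bulk_pct"] == pytest.approx(b)
            assert df.loc[i, "as_pct"] == pytest.approx(a)

    def test_missing_attribute_is_an_error(self):
        bulk = CountTable("bulk", {"a": (1, 0)})
        acc = CountTable("as_accepted", {"a": (1, 0)})
        with pytest.raises(ValueError, match="a"):
            binned_efficiency(bulk, acc, {}, (0, math.inf))


class TestPoreHealth:
    @staticmethod
    def _scans_from_counts(counts, interval=5400.0, n_channels=256):
        scans = []
        for i, count in enumerate(counts):
            for ch in range(1, n_channels + 1):
                state = "single_pore" if ch <= count else "unavailable"
                scans.append(PoreScanRecord(i * interval, ch, state))
        return scans

    def test_constant_counts_give_zero_rate(self):
        scans = self._scans_from_counts([200] * 5)
        fit = pore_decay(scans, {"all": (1, 256)})["all"]
        assert fit.rate_per_hour == pytest.approx(0.0, abs=1e-12)

    def test_planted_exponential_recovered(self):
        """Counts following exp(-h t) return h from the log-linear fit."""
        h = 0.01  # per hour
        times_h = np.arange(0, 68, 1.5)
        counts = np.round(256 * np.exp(-h * times_h)).astype(int)
        scans = self._scans_from_counts(counts, interval=1.5 * 3600)
        fit = pore_decay(scans, {"all": (1, 256)})["all"]
        assert abs(fit.rate_per_hour - h) / h < 0.05

    def test_equal_hazards_indistinguishable(self):
        hz = math.log(2) / (68 * 3600)
        scans = simulate.simulate_pore_scans(256, hz, 68 * 3600, seed=5)
        scans += simulate.simulate_pore_scans(256, hz, 68 * 3600, seed=6,
                                              first_channel=257)
        r1, se1 = pore_hazard_mle(scans, (1, 256))
        r2, se2 = pore_hazard_mle(scans, (257, 512))
        z = abs(r1 - r2) / math.sqrt(se1 ** 2 + se2 ** 2)
        assert z <= 3.0

    def test_too_few_scans_rejected(self):
        with pytest.raises(ValueError):
            pore_decay(self._scans_from_counts([100]), {"all": (1, 256)})


class TestCoverage:
    def test_full_length_read_covers_everything(self):
        alns = [AlignmentRecord("r", "t", 0, 100, "+", 0, 100)]
        depth, frac = coverage_profile(alns, 100)
        assert (depth == 1).all()
        assert frac == 1.0

    def test_rejected_reads_leave_five_prime_bare(self):
        # 3'-anchored 245-base rejects on a 1000-base transcript
        alns = [AlignmentRecord(f"r{i}", "t", 755, 1000, "+", 0, 245)
                for i in range(10)]
        depth, frac = coverage_profile(alns, 1000)
        assert (depth[:500] == 0).all()
        assert (depth[755:] == 10).all()
        assert frac == pytest.approx(0.245)

    def test_depleted_transcript_shows_three_prime_pileup(self, ivt_pool):
        cfg = simulate.RunConfig(mode="deplete",
                                 targets=frozenset({"ENO2"}),
                                 duration=1800.0, n_channels=16, seed=12)
        out = simulate.run_simulation(ivt_pool, cfg)
        alns = simulate.perfect_alignments(out, ivt_pool)
        eno2 = [a for a in alns if a.target_id == "ENO2"]
        rejected_ids = {r.read_id for r in out.reads
                        if r.decision == "unblock"}
        rej = [a for a in eno2 if a.read_id in rejected_ids]
        acc = [a for a in eno2 if a.read_id not in rejected_ids]
        _, frac_rej = coverage_profile(rej, ivt_pool["ENO2"].length)
        _, frac_acc = coverage_profile(acc, ivt_pool["ENO2"].length)
        assert frac_rej < 0.5 * frac_acc


@pytest.fixture(scope="module")
def deplete_run(ivt_pool):
    cfg = simulate.RunConfig(mode="deplete", targets=frozenset({"ENO2"}),
                             duration=3600.0, n_channels=32, seed=13,
                             scan_interval=900.0, pore_hazard=1e-5)
    return simulate.run_simulation(ivt_pool, cfg)


class TestReport:

    def test_report_self_consistency(self, ivt_pool, deplete_run):
        out = deplete_run
        rep = build_report(
            out.summary, out.decisions, truth_assignment(out),
            mode="deplete", targets={"ENO2"},
            as_channels=out.config.as_channels,
            n_channels=out.config.n_channels,
            attrs={"length": {t.id: t.length for t in ivt_pool}},
            scans=out.pore_scans,
        )
        assert rep.rejected_pool_purity + rep.false_rejection_rate \
            == pytest.approx(1.0)
        for comp in rep.compositions.values():
            assert sum(comp.values()) == pytest.approx(1.0)
        assert rep.rejected_pool_purity > 0.99
        assert rep.fold_reduction_reads["ENO2"] > 1.0
        assert rep.median_reject_len == 245
        assert set(rep.pore_decay) == {"as", "bulk"}

    def test_report_deterministic(self, ivt_pool, deplete_run):
        out = deplete_run
        kwargs = dict(
            mode="deplete", targets={"ENO2"},
            as_channels=out.config.as_channels,
            n_channels=out.config.n_channels,
        )
        a = build_report(out.summary, out.decisions,
                         truth_assignment(out), **kwargs)
        b = build_report(out.summary, out.decisions,
                         truth_assignment(out), **kwargs)
        assert a.to_json() == b.to_json()

    def test_pools_partition_q_passing_reads(self, deplete_run):
        out = deplete_run
        bulk_ct, acc_ct, rej_ct = run_pools(out)
        passing = qc_filter(out.summary, 7.0)
        # pools are disjoint and cover exactly the Q-passing reads
        total = (bulk_ct.total_reads + acc_ct.total_reads
                 + rej_ct.total_reads)
        bulk_ids, as_ids = split_by_channel(
            [r for r in out.summary if r.read_id in passing],
            out.config.as_channels, out.config.n_channels)
        assert total == len(bulk_ids) + len(as_ids)
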