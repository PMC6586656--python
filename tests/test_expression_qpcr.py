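"""DE candidate filtering and the qPCR ΔCq statistics pipeline."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy.stats import mannwhitneyu, rankdata
from statsmodels.stats.multitest import multipletests

from hsp70typer.expression_qpcr import (
    CqMeasurement,
    ExpressionRecord,
    FilterConfig,
    analyze_qpcr,
    delta_cq,
    filter_de,
    holm_adjust,
    mann_whitney,
    qc_cq,
)
from hsp70typer.synthetic_fixtures import gen_cq_table, gen_de_table


def _record(tid="t1", lfc=3.0, padj=1e-5, tpm=500.0):
    return ExpressionRecord(
        transcript_id=tid,
        annotation="hsp70",
        mean_tpm={"control": tpm, "heat_shock": tpm},
        log2fc=lfc,
        pvalue=None,
        padj=padj,
    )


class TestFilterDe:
    @pytest.mark.parametrize("n_total,n_pass", [(155, 23), (108, 19), (20, 0)])
    def test_planted_pass_counts_recovered(self, n_total, n_pass):
        records, truth = gen_de_table(seed=1, n_total=n_total, n_pass=n_pass)
        flags, _ = filter_de(records)
        passing = sorted(
            f.transcript_id for f in flags if f.de_significant and f.abundant
        )
        assert len(passing) == n_pass
        assert passing == truth["passing_ids"]

    def test_thresholds_are_strict(self):
        flags, _ = filter_de([_record(lfc=1.0)])
        assert not flags[0].de_significant
        flags, _ = filter_de([_record(padj=0.001)])
        assert not flags[0].de_significant
        flags, _ = filter_de([_record(tpm=200.0)])
        assert not flags[0].abundant

    def test_negative_fold_change_counts(self):
        flags, _ = filter_de([_record(lfc=-2.5)])
        assert flags[0].de_significant

    def test_missing_padj_not_significant_with_warning(self):
        flags, warnings = filter_de([_record(padj=None)])
        assert not flags[0].de_significant
        assert any("missing padj" in w for w in warnings)

    def test_malformed_row_skipped_others_proceed(self):
        rows = [_record("good"), _record("bad", padj=1.5), _record("also_good")]
        flags, warnings = filter_de(rows)
        assert [f.transcript_id for f in flags] == ["good", "also_good"]
        assert any("bad" in w for w in warnings)

    def test_flags_equal_bruteforce_row_evaluation(self):
        records, _ = gen_de_table(seed=7, n_total=80, n_pass=11)
        cfg = FilterConfig()
        flags, _ = filter_de(records, cfg)
        by_id = {f.transcript_id: f for f in flags}
        for rec in records:
            expected_sig = (
                rec.padj is not None
                and abs(rec.log2fc) > cfg.lfc_min
                and rec.padj < cfg.padj_max
            )
            tpms = list(rec.mean_tpm.values())
            expected_abund = sum(tpms) / len(tpms) > cfg.tpm_min
            f = by_id[rec.transcript_id]
            assert f.de_significant == expected_sig
            assert f.abundant == expected_abund


class TestQcCq:
    def _sample(self, sid, ref_cq, minus_rt=None):
        return [
            CqMeasurement(sid, "control", "gapdh", ref_cq, minus_rt),
            CqMeasurement(sid, "control", "hsp70_II", 25.0),
        ]

    def test_reference_over_cutoff_below_detection(self):
        kept, discarded = qc_cq(self._sample("s1", 31.0))
        assert kept == []
        assert discarded[0].reason == "below_detection"

    def test_minus_rt_below_cutoff_contaminated(self):
        _, discarded = qc_cq(self._sample("s1", 25.0, minus_rt=28.0))
        assert discarded[0].reason == "contaminated"

    def test_clean_sample_kept(self):
        kept, discarded = qc_cq(self._sample("s1", 25.0))
        assert discarded == [] and len(kept) == 2

    def test_missing_reference(self):
        _, discarded = qc_cq([CqMeasurement("s1", "control", "hsp70_II", 25.0)])
        assert discarded[0].reason == "missing_reference"


class TestDeltaCq:
    def test_sign_convention(self):
        ms = [
            CqMeasurement("s1", "control", "gapdh", 20.0),
            CqMeasurement("s1", "control", "hsp70_II", 25.0),
            CqMeasurement("s2", "control", "gapdh", 25.0),
            CqMeasurement("s2", "control", "hsp70_II", 20.0),
        ]
        values = {d.sample_id: d.value for d in delta_cq(ms)}
        assert values == {"s1": 5.0, "s2": -5.0}

    def test_undetected_target_is_censored(self):
        ms = [
            CqMeasurement("s1", "control", "gapdh", 20.0),
            CqMeasurement("s1", "control", "hsp70_II", None),
        ]
        (d,) = delta_cq(ms)
        assert d.censored and d.value is None


def _mw_oracle_p(a, b):
    """Exact two-sided p by full enumeration, with U computed from pairwise
    comparisons (greater = 1, tie = 1/2) rather than rank sums."""
    pooled = list(a) + list(b)
    n, m = len(a), len(b)

    def u_stat(ga, gb):
        return sum(
            (1.0 if x > y else 0.5 if x == y else 0.0) for x in ga for y in gb
        )

    mu = n * m / 2.0
    d_obs = abs(u_stat(a, b) - mu)
    count = 0
    total = 0
    for idx in combinations(range(n + m), n):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(n + m) if i not in idx]
        total += 1
        if abs(u_stat(ga, gb) - mu) >= d_obs - 1e-9:
            count += 1
    return count / total


class TestMannWhitney:
    def test_separated_groups_of_three(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.method == "exact"
        assert res.p == pytest.approx(0.1)

    def test_identical_multisets_give_p_one(self):
        res = mann_whitney([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert res.p == 1.0

    def test_exact_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            n = int(rng.integers(2, 7))
            m = int(rng.integers(2, 13 - n))
            # integer draws to provoke ties
            a = list(rng.integers(0, 6, size=n).astype(float))
            b = list(rng.integers(0, 6, size=m).astype(float))
            res = mann_whitney(a, b)
            assert res.method == "exact"
            assert res.p == pytest.approx(_mw_oracle_p(a, b))

    def test_u_statistic_matches_scipy(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=10), rng.normal(size=12)
        res = mann_whitney(a, b)
        assert res.method == "normal_approx"
        assert res.u == mannwhitneyu(a, b).statistic

    def test_large_sample_p_close_to_scipy_asymptotic(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(size=15), rng.normal(size=14)
        res = mann_whitney(a, b)
        ref = mannwhitneyu(a, b, method="asymptotic").pvalue
        assert res.p == pytest.approx(ref, abs=1e-8)

    def test_exact_and_approx_agree_for_six_vs_six(self):
        rng = np.random.default_rng(19)
        worst = 0.0
        for _ in range(500):
            a, b = rng.normal(size=6), rng.normal(size=6)
            p_exact = mann_whitney(a, b).p
            p_approx = mann_whitney(a, b, exact_limit=0).p
            worst = max(worst, abs(p_exact - p_approx))
        assert worst <= 0.02

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


def exact_null_rejection_probability(n, m, alpha):
    """The exact P(p <= alpha) of the enumeration test under a continuous
    null, computed from the permutation distribution of U."""
    ranks = np.arange(1, n + m + 1, dtype=float)
    combos = np.array(list(combinations(range(n + m), n)))
    u = ranks[combos].sum(axis=1) - n * (n + 1) / 2.0
    d = np.abs(u - n * m / 2.0)
    ps = np.array([np.mean(d >= dd - 1e-9) for dd in d])
    return float(np.mean(ps <= alpha))


class TestNullCalibration:
    def test_null_rejection_rate_matches_exact_attained_size(self):
        """10,000 null replicates: the exact test rejects at its
        enumerated attained size and never above the nominal level."""
        n = m = 6
        alpha = 0.05
        attained = exact_null_rejection_probability(n, m, alpha)
        rng = np.random.default_rng(101)
        rejections = 0
        reps = 10_000
        for _ in range(reps):
            a, b = rng.normal(size=n), rng.normal(size=m)
            rejections += mann_whitney(a, b).p <= alpha
        rate = rejections / reps
        se = math.sqrt(attained * (1 - attained) / reps)
        assert abs(rate - attained) <= 3 * se
        assert rate <= alpha + 3 * math.sqrt(alpha * (1 - alpha) / reps)


class TestHolm:
    def test_two_values(self):
        assert holm_adjust([0.01, 0.04]) == [0.02, 0.04]

    def test_single_value_unchanged(self):
        assert holm_adjust([0.3]) == [0.3]

    def test_step_down_with_monotonicity(self):
        # sorted: 0.01*3 = 0.03; 0.03*2 = 0.06; max(0.06, 0.04*1) = 0.06
        assert holm_adjust([0.03, 0.01, 0.04]) == [0.06, 0.03, 0.06]

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])

    def test_properties_and_statsmodels_crosscheck(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            ps = list(rng.uniform(0, 1, size=int(rng.integers(1, 12))))
            adj = holm_adjust(ps)
            assert all(a >= p for a, p in zip(adj, ps))  # >= raw
            assert all(a <= 1.0 for a in adj)
            order = np.argsort(ps)
            ranked = [adj[i] for i in order]
            assert ranked == sorted(ranked)  # monotone in rank order
            # a second application is inflationary, never deflationary, and
            # preserves the rank order of the adjusted values
            twice = holm_adjust(adj)
            assert all(t >= a for t, a in zip(twice, adj))
            ranked_twice = [twice[i] for i in order]
            assert ranked_twice == sorted(ranked_twice)
            assert adj == pytest.approx(multipletests(ps, method="holm")[1])


class TestAnalyzeQpcr:
    def test_planted_qc_failure_discarded(self):
        ms, _ = gen_cq_table(seed=3, qc_failures=[("C2", "below_detection")])
        result = analyze_qpcr(ms)
        assert [(d.sample_id, d.reason) for d in result.discarded] == [
            ("C2", "below_detection")
        ]

    def test_strong_induction_rejects_at_one_percent(self):
        """ΔCq shift of −6 cycles with six replicates per group is detected
        in at least 95% of 200 simulated experiments at alpha = 0.01."""
        hits = 0
        for seed in range(200):
            ms, _ = gen_cq_table(seed=seed, n_per_group=6, effect_size=-6.0)
            result = analyze_qpcr(ms)
            (comp,) = result.comparisons
            hits += comp.p_raw is not None and comp.p_raw <= 0.01
        assert hits >= 190

    def test_no_effect_rejection_rate_near_alpha(self):
        rejections = 0
        reps = 1000
        for seed in range(reps):
            ms, _ = gen_cq_table(seed=10_000 + seed, n_per_group=6, effect_size=0.0)
            (comp,) = analyze_qpcr(ms).comparisons
            rejections += comp.p_raw <= 0.05
        attained = exact_null_rejection_probability(6, 6, 0.05)
        se = math.sqrt(attained * (1 - attained) / reps)
        assert abs(rejections / reps - attained) <= 4 * se

    def test_holm_family_is_across_target_genes(self):
        ms, _ = gen_cq_table(
            seed=5, n_per_group=6, effect_size=-6.0,
            target_genes=("hsp70_II", "hsp70_III"),
        )
        result = analyze_qpcr(ms)
        raw = [c.p_raw for c in result.comparisons]
        adj = [c.p_holm for c in result.comparisons]
        assert adj == holm_adjust(raw)

    def test_censored_values_excluded_but_counted(self):
        ms, _ = gen_cq_table(seed=9, n_per_group=6)
        # make two control targets undetected
        censored = 0
        for m in ms:
            if m.gene != "gapdh" and m.group == "control" and censored < 2:
                m.cq = None
                censored += 1
        (comp,) = analyze_qpcr(ms).comparisons
        assert comp.n_censored_control == 2
        assert comp.n_control == 4
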