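"""Gating, summaries and replicate statistics, checked against independent oracles."""

import math

import numpy as np
import pytest
import scipy.stats as sps

from adipotrace.quantify import (
    GateConfig,
    NucleusRecord,
    WellSummary,
    gate_cells,
    mean_sem,
    suggest_cutoff,
    summarize_wells,
    timecourse_table,
    two_sample_t_test,
)
from adipotrace.simulate import SimulationConfig, cells_to_records, sample_cells


def make_record(nid=1, ratio=1.0, marker=0.0, well="A1", tp=0.0, cond="c",
                gfp=None, mpos=None):
    return NucleusRecord(
        nucleus_id=nid, well=well, field="f0", timepoint_h=tp, condition=cond,
        area=100.0, centroid_y=0.0, centroid_x=0.0,
        mean_gfp=1.0, mean_rfp=1.0, integrated_marker=marker, ratio=ratio,
        is_gfp_pos=gfp, is_marker_pos=mpos,
    )


class TestGateCells:
    def test_strictly_greater_convention(self):
        gate = GateConfig(gfp_ratio_cutoff=1.0, marker_cutoff=100.0)
        records = [
            make_record(1, ratio=10.0, marker=100.0),
            make_record(2, ratio=1.0, marker=101.0),
        ]
        gated = gate_cells(records, gate)
        assert gated[0].is_gfp_pos is True
        assert gated[0].is_marker_pos is False  # exactly at cutoff -> negative
        assert gated[1].is_gfp_pos is False     # exactly at cutoff -> negative
        assert gated[1].is_marker_pos is True

    def test_zero_marker_everything_negative(self):
        gated = gate_cells([make_record(i, marker=0.0) for i in range(5)], GateConfig())
        assert not any(r.is_marker_pos for r in gated)

    def test_nan_measurement_rejected(self):
        with pytest.raises(ValueError, match="unset measurement"):
            gate_cells([make_record(1, ratio=float("nan"))], GateConfig())

    def test_inputs_left_unmodified(self):
        rec = make_record(1, ratio=10.0)
        gate_cells([rec], GateConfig())
        assert rec.is_gfp_pos is None

    def test_well_separated_mixture_accuracy(self):
        """Default cutoffs classify a well-separated 1000-cell log-normal
        mixture with >= 99% accuracy against the generator's true flags."""
        cfg = SimulationConfig(
            n_cells=1000, image_height=2000, image_width=2000,
            min_center_distance=10.0, frac_gfp_pos=0.3,
            p_marker_pos_given_gfp_neg=0.3, seed=17,
        )
        cells = sample_cells(cfg)
        gated = gate_cells(cells_to_records(cells, cfg), GateConfig())
        truth = {c.cell_id: c for c in cells}
        acc_gfp = np.mean([g.is_gfp_pos == truth[g.nucleus_id].is_gfp_pos
                           for g in gated])
        acc_marker = np.mean([g.is_marker_pos == truth[g.nucleus_id].is_marker_pos
                              for g in gated])
        assert acc_gfp >= 0.99 and acc_marker >= 0.99

    def test_monotone_in_cutoff(self):
        cfg = SimulationConfig(n_cells=200, image_height=1000, image_width=1000,
                               min_center_distance=12.0, frac_gfp_pos=0.4, seed=8)
        records = cells_to_records(sample_cells(cfg), cfg)
        counts = []
        for cutoff in (0.1, 1.0, 10.0, 100.0):
            gated = gate_cells(records, GateConfig(gfp_ratio_cutoff=cutoff))
            counts.append(sum(r.is_gfp_pos for r in gated))
        assert counts == sorted(counts, reverse=True)


class TestSuggestCutoff:
    def test_two_clusters_cutoff_between(self):
        values = [0.1] * 50 + [10.0] * 50
        for method in ("auto_log_valley", "auto_otsu"):
            cut = suggest_cutoff(values, method=method)
            assert 0.1 < cut < 10.0

    def test_identical_values_error(self):
        with pytest.raises(ValueError, match="manual"):
            suggest_cutoff([5.0] * 10)

    def test_unimodal_log_valley_error(self, rng):
        values = np.exp(rng.normal(0, 0.2, size=500))
        with pytest.raises(ValueError, match="manual"):
            suggest_cutoff(values, method="auto_log_valley")

    def test_near_optimal_on_lognormal_mixture(self, rng):
        """Suggested cutoff misclassifies at most 2% more than the analytic
        equal-likelihood boundary of the known mixture."""
        mu0, mu1, sigma = math.log(0.1), math.log(10.0), 0.5
        n = 4000
        lo = np.exp(rng.normal(mu0, sigma, n // 2))
        hi = np.exp(rng.normal(mu1, sigma, n // 2))
        values = np.concatenate([lo, hi])
        labels = np.r_[np.zeros(n // 2, bool), np.ones(n // 2, bool)]
        # equal weights, equal sigmas: boundary at the midpoint of the log means
        boundary = math.exp(0.5 * (mu0 + mu1))

        def miss(cut):
            return np.mean((values > cut) != labels)

        for method in ("auto_log_valley", "auto_otsu"):
            cut = suggest_cutoff(values, method=method)
            assert miss(cut) <= miss(boundary) + 0.02


class TestSummaries:
    def _gated(self, n_pos, n_neg, n_marker_pos, n_marker_neg_pop, well="A1"):
        # n_marker_pos within GFP-; marker split in GFP- population
        records = []
        nid = 0
        for _ in range(n_pos):
            nid += 1
            records.append(make_record(nid, well=well, gfp=True, mpos=False))
        for i in range(n_neg):
            nid += 1
            records.append(make_record(nid, well=well, gfp=False,
                                       mpos=i < n_marker_pos))
        return records

    def test_gfp_fraction_arithmetic(self):
        # 27 GFP+ of 440 -> 6.136%
        (summary,) = summarize_wells(self._gated(27, 413, 0, 0))
        assert summary.n_total == 440
        assert summary.pct_gfp_pos == pytest.approx(100 * 27 / 440)
        assert summary.pct_gfp_pos == pytest.approx(6.136, abs=1e-3)

    def test_marker_fraction_arithmetic(self):
        # 8 marker+ of 204 GFP- -> 3.922%
        (summary,) = summarize_wells(self._gated(13, 204, 8, 196))
        assert summary.n_marker_pos_in_gfp_neg == 8
        assert summary.pct_marker_in_gfp_neg == pytest.approx(100 * 8 / 204)
        assert summary.pct_marker_in_gfp_neg == pytest.approx(3.922, abs=1e-3)

    def test_zero_gfp_pos_fraction_is_undefined(self):
        (summary,) = summarize_wells(self._gated(0, 10, 2, 8))
        assert summary.pct_marker_in_gfp_pos is None
        assert summary.pct_marker_in_gfp_neg == pytest.approx(20.0)

    def test_count_conservation(self):
        (summary,) = summarize_wells(self._gated(5, 20, 3, 17))
        assert summary.n_gfp_pos + summary.n_gfp_neg == summary.n_total

    def test_ungated_records_rejected(self):
        with pytest.raises(ValueError, match="not gated"):
            summarize_wells([make_record(1)])

    def test_groups_split_by_well_and_timepoint(self):
        records = (self._gated(2, 8, 1, 7, well="A1")
                   + self._gated(3, 7, 2, 5, well="A2"))
        summaries = summarize_wells(records)
        assert {s.well for s in summaries} == {"A1", "A2"}


class TestMeanSem:
    def test_constant_values(self):
        assert mean_sem([5.0, 5.0, 5.0]) == (5.0, 0.0)

    def test_hand_computed(self):
        mean, sem = mean_sem([1.0, 2.0, 3.0])
        assert mean == 2.0
        assert sem == pytest.approx(1.0 / math.sqrt(3), rel=1e-12)

    def test_single_value_sem_undefined(self):
        assert mean_sem([7.0]) == (7.0, None)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_sem([])


def pooled_t_oracle(a, b):
    """Independent brute-force pooled-variance Student t."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * (1 - sps.t.cdf(abs(t), na + nb - 2))
    return t, p


class TestTTest:
    def test_identical_groups(self):
        res = two_sample_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_matches_formula_oracle(self):
        res = two_sample_t_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        t, p = pooled_t_oracle([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert res.t == pytest.approx(t, rel=1e-10)
        assert res.p == pytest.approx(p, rel=1e-10)
        assert res.df == 4

    def test_matches_scipy_on_random_groups(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(2, 10))
            b = rng.normal(0.5, 2, rng.integers(2, 10))
            for equal_var in (True, False):
                res = two_sample_t_test(a, b, equal_var=equal_var)
                ref = sps.ttest_ind(a, b, equal_var=equal_var)
                assert res.t == pytest.approx(ref.statistic, rel=1e-10)
                assert res.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_against_permutation_oracle(self, rng):
        a = [3.1, 4.5, 2.2, 5.0]
        b = [6.0, 7.1, 5.5, 8.2]
        res = two_sample_t_test(a, b)
        pooled = np.array(a + b)
        n_perm = 20000
        t_obs = abs(res.t)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            t_perm, _ = pooled_t_oracle(perm[:4], perm[4:])
            count += abs(t_perm) >= t_obs - 1e-12
        p_perm = count / n_perm
        # permutation p for small normalish samples approximates the t p-value
        assert abs(p_perm - res.p) < 0.02

    def test_zero_variance_unequal_means_flagged(self):
        res = two_sample_t_test([1.0, 1.0], [2.0, 2.0])
        assert res.p == 0.0 and res.degenerate
        assert res.t == -math.inf

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t_test([1.0], [1.0, 2.0])


class TestTimecourse:
    def _summary(self, well, tp, cond, n_pos, n_neg, mk_pos, mk_neg):
        return WellSummary(
            well=well, timepoint_h=tp, condition=cond,
            n_total=n_pos + n_neg, n_gfp_pos=n_pos, n_gfp_neg=n_neg,
            n_marker_pos_in_gfp_pos=mk_pos, n_marker_pos_in_gfp_neg=mk_neg,
        )

    def test_reduces_to_mean_sem_of_well_fractions(self):
        summaries = [
            self._summary(f"A{i}", 24.0, "control", 10, 90, 0, mk)
            for i, mk in enumerate((9, 18, 27))
        ]
        table = timecourse_table(summaries)
        row = table[(table.population == "gfp_neg")].iloc[0]
        fractions = [10.0, 20.0, 30.0]
        mean, sem = mean_sem(fractions)
        assert row.n_wells == 3
        assert row.mean_pct_marker_pos == pytest.approx(mean)
        assert row.sem_pct_marker_pos == pytest.approx(sem)

    def test_undefined_wells_dropped_not_zeroed(self):
        summaries = [
            self._summary("A1", 0.0, "control", 0, 50, 0, 5),  # no GFP+ cells
            self._summary("A2", 0.0, "control", 4, 46, 1, 5),
        ]
        table = timecourse_table(summaries)
        pos_row = table[table.population == "gfp_pos"].iloc[0]
        assert pos_row.n_wells == 1
        assert pos_row.mean_pct_marker_pos == pytest.approx(25.0)

    def test_rows_sorted_by_timepoint(self):
        summaries = [
            self._summary("B1", 48.0, "control", 5, 45, 0, 9),
            self._summary("A1", 0.0, "control", 5, 45, 0, 9),
        ]
        table = timecourse_table(summaries)
        assert list(table.timepoint_h)[0] == 0.0
        assert table.timepoint_h.is_monotonic_increasing

    def test_missing_condition_row_absent(self):
        summaries = [self._summary("A1", 0.0, "control", 5, 45, 0, 9)]
        table = timecourse_table(summaries)
        assert not ((table.timepoint_h == 24.0) | (table.condition == "tgfb")).any()


class TestParameterRecovery:
    def test_gfp_fraction_unbiased_across_seeds(self):
        """Across 20 seeds the mean absolute error of the estimated GFP+
        percentage stays within 3x the binomial SEM at the configured n."""
        frac, n = 0.06, 500
        errors = []
        for seed in range(20):
            cfg = SimulationConfig(
                n_cells=n, image_height=1500, image_width=1500,
                min_center_distance=10.0, frac_gfp_pos=frac, seed=seed,
            )
            gated = gate_cells(cells_to_records(sample_cells(cfg), cfg), GateConfig())
            est = np.mean([r.is_gfp_pos for r in gated])
            errors.append(abs(est - frac))
        sem = math.sqrt(frac * (1 - frac) / n)
        assert np.mean(errors) <= 3 * sem
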