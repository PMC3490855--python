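"""Effect metrics, ANOVA routines and the signed-rank test, each checked
against an independent oracle (brute-force enumeration or a library
implementation)."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import rdksim as r
from rdksim.stimulus import ValidationError


class TestEffectMetrics:
    @pytest.mark.parametrize(
        "perceived, delta, diff, norm",
        [(16.0, 30.0, -14.0, -14 / 30), (30.0, 30.0, 0.0, 0.0), (42.0, 30.0, 12.0, 0.4)],
    )
    def test_difference_and_normalized(self, perceived, delta, diff, norm):
        d, n = r.effect_metrics(perceived, delta)
        assert d == pytest.approx(diff)
        assert n == pytest.approx(norm)
        assert n * delta == pytest.approx(d)  # exact consistency invariant

    def test_zero_veridical_rejected(self):
        with pytest.raises(ValidationError):
            r.effect_metrics(10.0, 0.0)

    def test_invert_attraction_is_involution(self):
        vals = [-0.47, -0.3, 0.0, 0.2]
        flipped = r.invert_attraction(vals)
        assert np.allclose(flipped, [0.47, 0.3, 0.0, -0.2])
        assert np.allclose(r.invert_attraction(flipped), vals)


class TestOneWayAnova:
    def test_degrees_of_freedom(self):
        row = r.one_way_anova([[1, 2, 3, 4]] * 6)
        assert (row.df_num, row.df_den) == (5, 18)
        row = r.one_way_anova([[1, 2, 3, 4]] * 8)
        assert (row.df_num, row.df_den) == (7, 24)

    def test_identical_groups_give_zero_f(self):
        row = r.one_way_anova([[1.0, 2.0, 3.0]] * 4)
        assert row.F == pytest.approx(0.0)
        assert row.p == pytest.approx(1.0)

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            groups = [rng.normal(rng.uniform(-1, 1), 1.0, size=5) for _ in range(4)]
            ours = r.one_way_anova(groups)
            ref = sps.f_oneway(*groups)
            assert ours.F == pytest.approx(ref.statistic, rel=1e-10)
            assert ours.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_exhaustive_small_integer_tables(self):
        """Oracle equivalence over all 2x(2,2) integer tables on {0,1,2}."""
        for a0, a1, b0, b1 in itertools.product(range(3), repeat=4):
            groups = [[a0, a1], [b0, b1]]
            if np.ptp(groups[0]) == 0 and np.ptp(groups[1]) == 0:
                continue  # zero within-group variance: F undefined/infinite
            ours = r.one_way_anova(groups)
            ref = sps.f_oneway(*[np.array(g, float) for g in groups])
            assert ours.F == pytest.approx(ref.statistic, abs=1e-10)

    def test_type_one_error_rate_under_null(self):
        """Null simulation: rejection at alpha=0.05 in 5% +/- 1.5% of runs."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_runs = 2000
        for _ in range(n_runs):
            groups = rng.standard_normal((6, 4))
            if r.one_way_anova(list(groups)).p < 0.05:
                rejections += 1
        assert abs(rejections / n_runs - 0.05) < 0.015

    def test_validation(self):
        with pytest.raises(ValidationError):
            r.one_way_anova([[1.0, 2.0]])
        with pytest.raises(ValidationError):
            r.one_way_anova([[1.0, 2.0], [3.0]])


def brute_force_rm_anova(y):
    """Independent sums-of-squares oracle, written with explicit loops."""
    n, a, b = y.shape
    grand = y.mean()
    ss = {"A": 0.0, "B": 0.0, "AB": 0.0, "AS": 0.0, "BS": 0.0, "ABS": 0.0}
    for i in range(a):
        ss["A"] += n * b * (y[:, i, :].mean() - grand) ** 2
    for j in range(b):
        ss["B"] += n * a * (y[:, :, j].mean() - grand) ** 2
    for i in range(a):
        for j in range(b):
            ss["AB"] += n * (
                y[:, i, j].mean() - y[:, i, :].mean() - y[:, :, j].mean() + grand
            ) ** 2
    for s in range(n):
        for i in range(a):
            ss["AS"] += b * (
                y[s, i, :].mean() - y[:, i, :].mean() - y[s].mean() + grand
            ) ** 2
        for j in range(b):
            ss["BS"] += a * (
                y[s, :, j].mean() - y[:, :, j].mean() - y[s].mean() + grand
            ) ** 2
        for i in range(a):
            for j in range(b):
                ss["ABS"] += (
                    y[s, i, j]
                    - y[:, i, j].mean()
                    - y[s, i, :].mean()
                    - y[s, :, j].mean()
                    + y[:, i, :].mean()
                    + y[:, :, j].mean()
                    + y[s].mean()
                    - grand
                ) ** 2
    f_a = (ss["A"] / (a - 1)) / (ss["AS"] / ((a - 1) * (n - 1)))
    f_b = (ss["B"] / (b - 1)) / (ss["BS"] / ((b - 1) * (n - 1)))
    f_ab = (ss["AB"] / ((a - 1) * (b - 1))) / (
        ss["ABS"] / ((a - 1) * (b - 1) * (n - 1))
    )
    return f_a, f_b, f_ab


def rm_table(y):
    n, a, b = y.shape
    rows = [
        {"subject_id": f"S{s}", "coherence": i, "direction_separation": j,
         "value": y[s, i, j]}
        for s in range(n) for i in range(a) for j in range(b)
    ]
    return pd.DataFrame(rows)


class TestTwoWayRmAnova:
    def test_paper_design_degrees_of_freedom(self):
        rng = np.random.default_rng(1)
        rows = r.two_way_rm_anova(rm_table(rng.standard_normal((4, 2, 8))))
        dfs = [(row.df_num, row.df_den) for row in rows]
        assert dfs == [(1, 3), (7, 21), (7, 21)]

    def test_matches_brute_force_on_toy_table(self):
        """F values agree with the explicit-loop oracle to 1e-10 on a 2x2x3
        integer table."""
        y = np.array(
            [[[3, 1, 4], [1, 5, 9]], [[2, 6, 5], [3, 5, 8]],
             [[9, 7, 9], [3, 2, 3]], [[8, 4, 6], [2, 6, 4]]],
            dtype=float,
        )  # shape (4 subjects, 2 A-levels, 3 B-levels)
        rows = r.two_way_rm_anova(rm_table(y))
        f_a, f_b, f_ab = brute_force_rm_anova(y)
        assert rows[0].F == pytest.approx(f_a, abs=1e-10)
        assert rows[1].F == pytest.approx(f_b, abs=1e-10)
        assert rows[2].F == pytest.approx(f_ab, abs=1e-10)

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            y = rng.standard_normal((5, 3, 4))
            rows = r.two_way_rm_anova(rm_table(y))
            for ours, ref in zip(rows, brute_force_rm_anova(y)):
                assert ours.F == pytest.approx(ref, rel=1e-10)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        y = rng.standard_normal((6, 2, 4))
        ours = r.two_way_rm_anova(rm_table(y))
        ref = pingouin.rm_anova(
            data=rm_table(y), dv="value",
            within=["coherence", "direction_separation"], subject="subject_id",
        )
        for row, (_, ref_row) in zip(ours, ref.iterrows()):
            assert row.F == pytest.approx(ref_row["F"], rel=1e-6)
            assert row.p == pytest.approx(ref_row["p_unc"], rel=1e-6)

    def test_null_type_one_error_for_factor_a(self):
        """With no A effect and no interaction, F_A stays below the 5%
        critical value in >= 94% of null simulations."""
        rng = np.random.default_rng(7)
        crit = sps.f.isf(0.05, 1, 3)
        below = 0
        n_runs = 500
        for _ in range(n_runs):
            subject_offset = rng.standard_normal((4, 1, 1))
            b_effect = rng.standard_normal((1, 1, 8))
            y = subject_offset + b_effect + 0.5 * rng.standard_normal((4, 2, 8))
            if r.two_way_rm_anova(rm_table(y))[0].F < crit:
                below += 1
        assert below / n_runs >= 0.94

    def test_missing_cells_rejected(self):
        rng = np.random.default_rng(0)
        table = rm_table(rng.standard_normal((4, 2, 3))).iloc[:-1]
        with pytest.raises(ValidationError):
            r.two_way_rm_anova(table)

    def test_duplicate_cells_rejected(self):
        rng = np.random.default_rng(0)
        table = rm_table(rng.standard_normal((4, 2, 3)))
        table = pd.concat([table, table.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValidationError):
            r.two_way_rm_anova(table)

    def test_gg_correction_only_raises_p(self):
        rng = np.random.default_rng(9)
        y = rng.standard_normal((5, 2, 6))
        plain = r.two_way_rm_anova(rm_table(y))
        gg = r.two_way_rm_anova(rm_table(y), gg_correction=True)
        for a, b in zip(plain, gg):
            assert b.p >= a.p - 1e-12


def brute_force_signed_rank(d):
    """Full 2^n enumeration of the positive-rank-sum null distribution."""
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[np.asarray(d) > 0].sum()
    n = len(d)
    sums = []
    for signs in itertools.product([0, 1], repeat=n):
        sums.append(sum(rk for rk, s in zip(ranks, signs) if s))
    sums = np.array(sums)
    p_le = (sums <= w_obs + 1e-9).mean()
    p_ge = (sums >= w_obs - 1e-9).mean()
    return w_obs, min(1.0, 2 * min(p_le, p_ge))


class TestWilcoxonSignedRank:
    def test_symmetric_values_give_p_one(self):
        res = r.wilcoxon_signed_rank([-2, -1, 1, 2, 3, -3])
        assert res.method == "exact"
        assert res.p == pytest.approx(1.0)

    def test_minimal_p_all_positive_n6(self):
        res = r.wilcoxon_signed_rank([1, 2, 3, 4, 5, 6])
        assert res.p == pytest.approx(2 / 64)

    @pytest.mark.parametrize("n", [5, 8, 12, 15])
    def test_exact_branch_matches_full_enumeration(self, n):
        rng = np.random.default_rng(n)
        for _ in range(5):
            d = np.round(rng.standard_normal(n) * 3, 1)
            d = d[d != 0]
            if d.size < 5:
                continue
            ours = r.wilcoxon_signed_rank(d, method="exact")
            w_ref, p_ref = brute_force_signed_rank(d)
            assert ours.statistic == pytest.approx(w_ref)
            assert ours.p == pytest.approx(p_ref, rel=1e-12)

    def test_exact_matches_scipy(self):
        rng = np.random.default_rng(5)
        d = rng.standard_normal(14)
        ours = r.wilcoxon_signed_rank(d, method="exact")
        ref = sps.wilcoxon(d, method="exact", alternative="two-sided")
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-9)

    @pytest.mark.parametrize("seed", [1, 5, 6, 7])
    def test_branches_agree_at_n25(self, seed):
        # the normal approximation is only expected to track the exact p
        # outside the deep tail, so representative (null-like) data is used
        rng = np.random.default_rng(seed)
        d = rng.standard_normal(25)
        exact = r.wilcoxon_signed_rank(d, method="exact")
        approx = r.wilcoxon_signed_rank(d, method="approx")
        assert approx.p == pytest.approx(exact.p, rel=0.10)

    def test_auto_switches_to_approximation(self):
        rng = np.random.default_rng(0)
        res = r.wilcoxon_signed_rank(rng.standard_normal(32) + 1.0)
        assert res.method == "approx"
        assert res.p < 0.001

    def test_validation(self):
        with pytest.raises(ValidationError):
            r.wilcoxon_signed_rank([0.0, 0.0, 0.0])
        with pytest.raises(ValidationError):
            r.wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0])


class TestSummarize:
    def make_dataset(self, estimates, delta=30.0, coherence=1.0):
        rows = []
        for si, vals in enumerate(estimates):
            for ki, v in enumerate(np.atleast_1d(vals)):
                rows.append(
                    {"subject_id": f"S{si}", "direction_separation": delta,
                     "coherence": coherence, "staircase_id": ki + 1,
                     "matching_angle": float(v), "termination": "reversals_complete"}
                )
        return pd.DataFrame(rows)

    def test_mean_and_standard_error(self):
        table = self.make_dataset([40.0, 42.0, 44.0, 42.0])
        out = r.summarize(table)
        assert out.loc[0, "perceived_mean"] == pytest.approx(42.0)
        assert out.loc[0, "perceived_se"] == pytest.approx(np.sqrt(8 / 3) / 2)

    def test_shared_value_zero_se(self):
        out = r.summarize(self.make_dataset([42.0, 42.0, 42.0]))
        assert out.loc[0, "perceived_se"] == 0.0

    def test_single_subject_rejected(self):
        with pytest.raises(ValidationError):
            r.summarize(self.make_dataset([42.0]))

    def test_subject_level_averaging_precedes_condition_mean(self):
        # staircases average within subject first: (10,20)->15 and 30 -> 22.5
        table = self.make_dataset([[10.0, 20.0], [30.0, 30.0]])
        out = r.summarize(table)
        assert out.loc[0, "perceived_mean"] == pytest.approx(22.5)


class TestEndToEndSignPattern:
    def test_analyze_reproduces_repulsion_and_attraction_signs(self):
        """A default simulated study shows a positive normalized effect at
        full coherence and a negative one at 60%, with the coherence main
        effect significant at alpha=0.01."""
        from rdksim.experiment import default_cohort

        cohort = default_cohort(4, seed=2)
        ds = r.run_experiment(r.design_experiment2(), cohort, seed=2)
        report = r.experiment2_report(ds)
        summary = report["summary"]
        hi = summary[summary.coherence == 1.0]
        lo = summary[summary.coherence == 0.6]
        assert (hi.loc[hi.direction_separation == 30.0, "normalized_mean"] > 0).all()
        assert (lo.loc[lo.direction_separation == 30.0, "normalized_mean"] < 0).all()
        coh_row = next(row for row in report["rm_anova"] if row.name == "coherence")
        assert coh_row.p < 0.01
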