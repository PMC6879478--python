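import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ctpipe.diffexp import (
    DEError,
    DESpec,
    adjust_pvalues,
    aggregate_category,
    group_summary,
    rank_products,
    rankprod_de,
    rankprod_pfp,
    run_diffexp,
    ttest_de,
    wilcoxon_de,
)
from ctpipe.qpcr_io import OK, UNDETERMINED

from conftest import make_dataset, make_treatment

NAN = math.nan


class TestGroupSummary:
    def test_published_metastatic_row(self):
        # means as printed for the strongest up-regulated microRNA
        mean_cal, mean_tgt, ddct, fc = group_summary([25.793], [21.378])
        assert ddct == pytest.approx(-4.415, abs=1e-9)
        # printed ddCt -4.414 was computed from unrounded means
        assert ddct == pytest.approx(-4.414, abs=1.5e-3)
        assert fc == pytest.approx(2 ** 4.415, rel=1e-12)

    def test_zero_ddct_unit_fc(self):
        *_, ddct, fc = group_summary([25.0, 25.0], [25.0])
        assert ddct == 0 and fc == 1.0

    def test_published_downregulated_row(self):
        assert round(2.0 ** -3.300, 3) == 0.102

    def test_missing_group_errors(self):
        with pytest.raises(DEError):
            group_summary([NAN], [21.0])


class TestAdjust:
    def test_bh_against_step_up_oracle(self):
        p = [0.01, 0.02, 0.03]
        # independent step-up: p_(i) * n / i with running minimum from the top
        n = len(p)
        order = np.argsort(p)
        raw = np.array(p)[order] * n / np.arange(1, n + 1)
        for i in range(n - 2, -1, -1):
            raw[i] = min(raw[i], raw[i + 1])
        expected = np.empty(n)
        expected[order] = np.minimum(raw, 1)
        np.testing.assert_allclose(adjust_pvalues(p, "BH"), expected)
        np.testing.assert_allclose(adjust_pvalues(p, "BH"), [0.03, 0.03, 0.03])

    def test_bonferroni_single(self):
        np.testing.assert_allclose(adjust_pvalues([0.01], "bonferroni"), [0.01])

    def test_none_identity(self):
        p = [0.5, 0.01, 0.99]
        np.testing.assert_array_equal(adjust_pvalues(p, "none"), p)

    def test_out_of_range_rejected(self):
        with pytest.raises(DEError):
            adjust_pvalues([1.5], "BH")

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30),
           st.sampled_from(["BH", "BY", "bonferroni", "holm", "hochberg", "hommel"]))
    @settings(max_examples=60, deadline=None)
    def test_adjusted_at_least_raw(self, p, method):
        adj = adjust_pvalues(p, method)
        assert (adj >= np.array(p) - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=20))
    @settings(max_examples=40, deadline=None)
    def test_bh_monotone_in_raw_order(self, p):
        adj = adjust_pvalues(p, "BH")
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestAggregateCategory:
    def test_all_ok(self):
        assert aggregate_category([OK, OK, OK], True) == OK
        assert aggregate_category([OK, OK, OK], False) == OK

    def test_stringent_any_failure(self):
        assert aggregate_category([OK, UNDETERMINED], True) == UNDETERMINED

    def test_lenient_majority(self):
        assert aggregate_category([OK, OK, UNDETERMINED], False) == OK
        assert aggregate_category([OK, UNDETERMINED], False) == UNDETERMINED

    def test_empty_errors(self):
        with pytest.raises(DEError):
            aggregate_category([], True)


def two_group_dataset(cal_rows, tgt_rows, **kw):
    """rows: list per gene of (calibrator values, target values)."""
    m = np.array([list(c) + list(t) for c, t in zip(cal_rows, tgt_rows)])
    ds = make_dataset(m, **kw)
    tm = make_treatment(len(cal_rows[0]), len(tgt_rows[0]))
    return ds, tm


class TestTtest:
    def test_welch_closed_form_oracle(self):
        ds, tm = two_group_dataset([[1.0, 2.0, 3.0]], [[4.0, 5.0, 6.0]])
        table = ttest_de(ds, tm, DESpec(method="ttest"))
        # independent Welch computation
        c, t = np.array([1.0, 2, 3]), np.array([4.0, 5, 6])
        se = math.sqrt(c.var(ddof=1) / 3 + t.var(ddof=1) / 3)
        t_stat = (t.mean() - c.mean()) / se
        df = (c.var(ddof=1) / 3 + t.var(ddof=1) / 3) ** 2 / (
            (c.var(ddof=1) / 3) ** 2 / 2 + (t.var(ddof=1) / 3) ** 2 / 2)
        p = 2 * sps.t.sf(abs(t_stat), df)
        assert table.loc[0, "t.test"] == pytest.approx(t_stat)
        assert table.loc[0, "t.test"] == pytest.approx(3.674, abs=1e-3)
        assert table.loc[0, "p.value"] == pytest.approx(p)
        assert table.loc[0, "p.value"] == pytest.approx(0.0214, abs=2e-4)

    def test_identical_groups_degenerate(self):
        ds, tm = two_group_dataset([[5.0, 5.0]], [[5.0, 5.0]])
        table = ttest_de(ds, tm, DESpec(method="ttest"))
        assert table.loc[0, "t.test"] == 0
        assert table.loc[0, "p.value"] == 1

    def test_paired_constant_shift_degenerate(self):
        ds, tm = two_group_dataset([[1.0, 2.0, 3.0]], [[2.0, 3.0, 4.0]])
        table = ttest_de(ds, tm, DESpec(method="ttest", paired=True))
        assert table.loc[0, "t.test"] == 0
        assert table.loc[0, "p.value"] == 1

    def test_label_swap_symmetry(self, rng):
        m = rng.normal(25, 2, (10, 8))
        ds = make_dataset(m)
        tm = make_treatment(4, 4)
        tm_swapped = make_treatment(4, 4, cal="CASE", tgt="CTRL")
        # swapping which group is calibrator == relabeling groups
        t1 = ttest_de(ds, tm, DESpec()).set_index("genes")
        m2 = np.column_stack([m[:, 4:], m[:, :4]])
        ds2 = make_dataset(m2)
        t2 = ttest_de(ds2, tm, DESpec()).set_index("genes")
        for g in t1.index:
            assert t1.loc[g, "p.value"] == pytest.approx(t2.loc[g, "p.value"], rel=1e-9)
            assert t1.loc[g, "t.test"] == pytest.approx(-t2.loc[g, "t.test"], rel=1e-9)
            assert t1.loc[g, "ddCt"] == pytest.approx(-t2.loc[g, "ddCt"], abs=1e-9)
            assert t1.loc[g, "FC"] == pytest.approx(1 / t2.loc[g, "FC"], rel=1e-9)

    def test_rows_sorted_by_pvalue(self, rng):
        m = rng.normal(25, 2, (20, 8))
        m[0, 4:] += 5  # make one gene strongly significant
        table = ttest_de(make_dataset(m), make_treatment(4, 4), DESpec())
        assert (table["p.value"].diff().dropna() >= 0).all()
        assert table.loc[0, "genes"] == "g0"

    def test_fc_ddct_product_identity(self, rng):
        m = rng.normal(25, 2, (15, 8))
        table = ttest_de(make_dataset(m), make_treatment(4, 4), DESpec())
        np.testing.assert_allclose(table["FC"] * 2.0 ** table["ddCt"], 1.0,
                                   atol=1e-12)

    def test_replicates_collapse(self):
        m = np.array([[20.0, 22.0, 30.0, 32.0],
                      [22.0, 24.0, 32.0, 34.0]])
        ds = make_dataset(m, feature_names=["gA", "gA"])
        tm = make_treatment(2, 2)
        table = ttest_de(ds, tm, DESpec(replicates=True))
        assert len(table) == 1
        # collapsed to per-sample means [21, 23, 31, 33]
        assert table.loc[0, "meanCalibrator"] == pytest.approx(22.0)
        assert table.loc[0, "meanTarget"] == pytest.approx(32.0)

    def test_missing_values_use_available(self):
        ds, tm = two_group_dataset([[20.0, 21.0, NAN]], [[25.0, 26.0, 27.0]])
        table = ttest_de(ds, tm, DESpec())
        assert table.loc[0, "meanCalibrator"] == pytest.approx(20.5)

    def test_category_columns(self):
        m = np.array([[20.0, 21.0, 25.0, 26.0]])
        cats = np.array([[OK, UNDETERMINED, OK, OK]], dtype=object)
        ds = make_dataset(m, categories=cats)
        tm = make_treatment(2, 2)
        strict = ttest_de(ds, tm, DESpec(stringent=True))
        lenient = ttest_de(ds, tm, DESpec(stringent=False))
        assert strict.loc[0, "categoryCalibrator"] == UNDETERMINED
        assert lenient.loc[0, "categoryCalibrator"] == UNDETERMINED  # 1/2 not majority
        assert strict.loc[0, "categoryTarget"] == OK


class TestWilcoxon:
    def test_exact_enumeration_oracle(self):
        ds, tm = two_group_dataset([[1.0, 2.0, 3.0]], [[4.0, 5.0, 6.0]])
        table = wilcoxon_de(ds, tm, DESpec(method="wilcoxon"))
        # oracle: enumerate all C(6,3)=20 assignments of ranks to groups
        pooled = [1, 2, 3, 4, 5, 6]
        obs_u = 0.0  # every calibrator value below every target value
        count = 0
        for combo in itertools.combinations(range(6), 3):
            tgt = [pooled[i] for i in combo]
            cal = [pooled[i] for i in range(6) if i not in combo]
            u = sum(1 for a in tgt for b in cal if a > b) + \
                0.5 * sum(1 for a in tgt for b in cal if a == b)
            if min(u, 9 - u) <= min(obs_u, 9 - obs_u):
                count += 1
        assert table.loc[0, "p.value"] == pytest.approx(count / 20)
        assert table.loc[0, "p.value"] == pytest.approx(0.1)

    def test_full_overlap_p_one(self):
        ds, tm = two_group_dataset([[1.0, 2.0]], [[1.0, 2.0]])
        table = wilcoxon_de(ds, tm, DESpec(method="wilcoxon"))
        assert table.loc[0, "p.value"] == pytest.approx(1.0)

    def test_large_monotone_shift_significant(self, rng):
        cal = rng.normal(20, 0.5, 10)
        tgt = rng.normal(30, 0.5, 10)
        ds, tm = two_group_dataset([cal], [tgt])
        table = wilcoxon_de(ds, tm, DESpec(method="wilcoxon"))
        assert table.loc[0, "p.value"] < 0.001

    def test_approximation_close_to_exact_at_small_n(self, rng):
        # the asymptotic path (forced by a tie) stays near the exact p
        cal = [1.0, 2.0, 3.0, 4.0, 5.0]
        tgt = [3.0, 6.0, 7.0, 8.0, 9.0]
        ds, tm = two_group_dataset([cal], [tgt])
        p_impl = wilcoxon_de(ds, tm, DESpec(method="wilcoxon")).loc[0, "p.value"]
        exact = sps.mannwhitneyu(tgt, cal, alternative="two-sided",
                                 method="asymptotic").pvalue
        assert p_impl == pytest.approx(exact)

    def test_paired_signed_rank(self, rng):
        cal = rng.normal(20, 1, 6)
        tgt = cal + rng.normal(2, 0.2, 6)
        ds, tm = two_group_dataset([cal], [tgt])
        table = wilcoxon_de(ds, tm, DESpec(method="wilcoxon", paired=True))
        assert table.loc[0, "p.value"] < 0.05


class TestRankProduct:
    def test_min_rp_for_always_first_gene(self):
        m = np.array([
            [10.0, 11.0, 30.0, 31.0],   # most down in... no: target higher
            [25.0, 25.0, 25.0, 25.0],
            [30.0, 31.0, 10.0, 11.0],
        ])
        rp_up, rp_down = rank_products(m, [0, 1], [2, 3])
        # gene 0: largest positive diff in every pair -> rank 1 ascending of -diff
        assert rp_up[0] == pytest.approx(1.0)
        assert rp_down[2] == pytest.approx(1.0)

    def test_label_swap_exchanges_up_and_down(self, rng):
        m = rng.normal(25, 2, (6, 4))
        up1, down1 = rank_products(m, [0, 1], [2, 3])
        up2, down2 = rank_products(m, [2, 3], [0, 1])
        np.testing.assert_allclose(up1, down2)
        np.testing.assert_allclose(down1, up2)

    def test_pfp_matches_exhaustive_enumeration_pure_python(self):
        # 3 genes, 2 vs 2: enumerate all (3!)^4 column shufflings by hand
        m = np.array([[20.0, 21.0, 26.0, 27.0],
                      [25.0, 24.0, 24.0, 25.0],
                      [30.0, 31.0, 28.0, 27.0]])
        cal, tgt = [0, 1], [2, 3]
        rp_up, rp_down, pfp_up, pfp_down = rankprod_pfp(
            m, cal, tgt, exhaustive=True)

        def ranks(vals):
            order = sorted(range(len(vals)), key=lambda i: vals[i])
            r = [0.0] * len(vals)
            i = 0
            while i < len(order):
                j = i
                while j + 1 < len(order) and vals[order[j + 1]] == vals[order[i]]:
                    j += 1
                avg = (i + j) / 2 + 1
                for k in range(i, j + 1):
                    r[order[k]] = avg
                i = j + 1
            return r

        def rp_of(mat):
            n_genes = len(mat)
            log_up = [0.0] * n_genes
            log_down = [0.0] * n_genes
            n_pairs = 0
            for ci in cal:
                for tj in tgt:
                    diff = [mat[g][tj] - mat[g][ci] for g in range(n_genes)]
                    rd = ranks(diff)
                    ru = ranks([-d for d in diff])
                    for g in range(n_genes):
                        log_down[g] += math.log(rd[g])
                        log_up[g] += math.log(ru[g])
                    n_pairs += 1
            return ([math.exp(v / n_pairs) for v in log_up],
                    [math.exp(v / n_pairs) for v in log_down])

        obs_up, obs_down = rp_of(m.tolist())
        np.testing.assert_allclose(rp_up, obs_up)
        np.testing.assert_allclose(rp_down, obs_down)

        perms = list(itertools.permutations(range(3)))
        null_up, null_down = [], []
        for combo in itertools.product(perms, repeat=4):
            mat = [[m[combo[j][g], j] for j in range(4)] for g in range(3)]
            u, d = rp_of(mat)
            null_up.extend(u)
            null_down.extend(d)
        n_perm = len(perms) ** 4

        for g in range(3):
            for obs, null, pfp in ((obs_up, null_up, pfp_up),
                                   (obs_down, null_down, pfp_down)):
                expected_count = sum(1 for v in null if v <= obs[g] + 1e-12)
                e = expected_count / n_perm
                rank = 1 + sum(1 for v in obs if v < obs[g] - 1e-12) + \
                    0.5 * sum(1 for h, v in enumerate(obs)
                              if h != g and abs(v - obs[g]) <= 1e-12)
                assert pfp[g] == pytest.approx(e / rank, rel=1e-9)

    def test_monte_carlo_close_to_exhaustive(self):
        m = np.array([[20.0, 21.0, 26.0, 27.0],
                      [25.0, 24.0, 24.0, 25.0],
                      [30.0, 31.0, 28.0, 27.0]])
        cal, tgt = [0, 1], [2, 3]
        *_, pfp_up_ex, _ = rankprod_pfp(m, cal, tgt, exhaustive=True)
        *_, pfp_up_mc, _ = rankprod_pfp(m, cal, tgt, permutations=4000, seed=11)
        np.testing.assert_allclose(pfp_up_mc, pfp_up_ex, atol=0.08)

    def test_de_table_contract(self, rng):
        m = rng.normal(25, 1, (8, 6))
        m[0, 3:] -= 4  # strongly down in Ct = up-expressed
        ds = make_dataset(m)
        tm = make_treatment(3, 3)
        table = rankprod_de(ds, tm, DESpec(method="rankprod", permutations=200,
                                           seed=5))
        assert list(table.columns)[:3] == ["genes", "RP", "p.value"]
        spiked = table.set_index("genes").loc["g0"]
        assert spiked["RP"] == pytest.approx(1.0)  # first in every pair
        assert spiked["p.value"] <= 0.1
        assert ((table["p.value"] >= 0) & (table["p.value"] <= 1)).all()

    def test_seed_reproducibility(self, rng):
        m = rng.normal(25, 1, (6, 6))
        a = rankprod_pfp(m, [0, 1, 2], [3, 4, 5], permutations=50, seed=9)
        b = rankprod_pfp(m, [0, 1, 2], [3, 4, 5], permutations=50, seed=9)
        np.testing.assert_array_equal(a[2], b[2])

    def test_requires_complete_data(self):
        m = np.array([[1.0, NAN, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]])
        with pytest.raises(DEError, match="complete"):
            rankprod_de(make_dataset(m), make_treatment(2, 2),
                        DESpec(method="rankprod"))


class TestSimulationProperties:
    def test_null_type_one_rate_within_binomial_bounds(self):
        rng = np.random.default_rng(2024)
        m = rng.normal(25, 1, (200, 16))
        table = ttest_de(make_dataset(m), make_treatment(8, 8), DESpec())
        frac = (table["p.value"] < 0.05).mean()
        # 99% binomial bounds around 0.05 with n=200
        sd = math.sqrt(0.05 * 0.95 / 200)
        assert 0.05 - 2.576 * sd <= frac <= 0.05 + 2.576 * sd

    def test_spiked_recovery(self):
        rng = np.random.default_rng(7)
        n, spiked = 200, 40
        m = rng.normal(25, 0.5, (n, 16))
        m[:spiked, 8:] += np.where(np.arange(spiked)[:, None] % 2 == 0, 2.0, -2.0)
        table = ttest_de(make_dataset(m), make_treatment(8, 8), DESpec())
        hits = table.set_index("genes").loc[[f"g{i}" for i in range(spiked)],
                                            "p.value"] < 0.05
        assert hits.mean() >= 0.9


def test_run_diffexp_none_returns_none(rng):
    ds = make_dataset(rng.normal(25, 1, (4, 4)))
    assert run_diffexp(ds, make_treatment(2, 2), DESpec(method="none")) is None
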