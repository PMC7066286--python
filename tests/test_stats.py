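"""Rank-sum, BH-FDR and Spearman against independent oracles."""
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from p3tacs.stats import (
    bh_adjust,
    correlation_matrix,
    rank_sum_test,
    run_hypothesis_suite,
    spearman,
)


def brute_force_ranksum_p(x, y, tail):
    """Exhaustive-permutation p-value for tie-free samples: enumerate all
    assignments of the pooled ranks to group 1."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    ws = np.array(
        [sum(c) for c in itertools.combinations(ranks, n1)]
    )
    if tail == "greater":
        return np.mean(ws >= w_obs - 1e-9)
    if tail == "less":
        return np.mean(ws <= w_obs + 1e-9)
    lo = np.mean(ws <= w_obs + 1e-9)
    hi = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(lo, hi))


class TestRankSum:
    def test_separated_samples_left_tail(self):
        r = rank_sum_test([1, 2, 3], [4, 5, 6], tail="less")
        assert r.w_statistic == 6
        assert r.u_statistic == 0
        assert r.p_raw == pytest.approx(1 / 20)

    def test_interleaved_samples_null_expectation(self):
        r = rank_sum_test([1, 4], [2, 3], tail="two-sided")
        assert r.w_statistic == 5  # equals n1(n1+n2+1)/2, the null mean
        assert r.p_raw == pytest.approx(1.0)

    def test_u_w_identity_and_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n1, n2 = rng.integers(1, 8, 2)
            x, y = rng.normal(size=n1), rng.normal(size=n2)
            r = rank_sum_test(x, y)
            assert r.u_statistic == pytest.approx(r.w_statistic - n1 * (n1 + 1) / 2)
            assert 0 <= r.u_statistic <= n1 * n2
            assert n1 * (n1 + 1) / 2 <= r.w_statistic <= n1 * (n1 + 1) / 2 + n1 * n2

    @pytest.mark.parametrize("tail", ["less", "greater", "two-sided"])
    def test_exact_p_matches_enumeration(self, tail):
        rng = np.random.default_rng(42)
        for _ in range(15):
            n1, n2 = rng.integers(2, 6, 2)
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            r = rank_sum_test(x, y, tail=tail)
            assert r.p_raw == pytest.approx(brute_force_ranksum_p(x, y, tail), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestBH:
    def test_hand_computed_step_up(self):
        adj = bh_adjust([0.01, 0.02, 0.04])
        assert np.allclose(adj, [0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_equal_ps_collapse(self):
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2, 0.2]), 0.2)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12)
    )
    @settings(deadline=None, max_examples=50)
    def test_step_up_rule_and_idempotence(self, ps):
        adj = bh_adjust(ps)
        # independent hand implementation of the step-up rule
        p = np.asarray(ps, float)
        m = len(p)
        order = np.argsort(p, kind="stable")
        stepped = p[order] * m / np.arange(1, m + 1)
        stepped = np.minimum.accumulate(stepped[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(stepped, 1.0)
        assert np.allclose(adj, expected, atol=1e-12)
        assert np.all(adj >= p - 1e-12) and np.all(adj <= 1.0 + 1e-12)
        # adjusted values keep the ordering of the raw p-values
        order2 = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order2]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestSpearman:
    def test_monotone_and_reversed(self):
        x = np.arange(10.0)
        assert spearman(x, x**3 + 1).rho == pytest.approx(1.0)
        assert spearman(x, -x).rho == pytest.approx(-1.0)

    def test_hand_computed_rho(self):
        # sum d^2 = 4 -> rho = 1 - 24/60 = 0.6
        c = spearman([1, 2, 3, 4], [2, 1, 4, 3])
        assert c.rho == pytest.approx(0.6)

    def test_equals_pearson_on_ranks(self):
        rng = np.random.default_rng(3)
        for n in (5, 8, 15):
            x, y = rng.normal(size=n), rng.normal(size=n)
            c = spearman(x, y)
            pear = sps.pearsonr(sps.rankdata(x), sps.rankdata(y))[0]
            assert c.rho == pytest.approx(pear, abs=1e-12)

    def test_exact_p_matches_null_enumeration(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 5.0]
        c = spearman(x, y)
        # enumerate all 5! permutations directly
        rhos = [
            sps.pearsonr(np.arange(5), np.array(p))[0]
            for p in itertools.permutations(range(5))
        ]
        expected = np.mean([abs(r) >= abs(c.rho) - 1e-12 for r in rhos])
        assert c.p_two_sided == pytest.approx(expected)

    def test_constant_input_degenerate(self):
        c = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert c.degenerate and np.isnan(c.rho)

    def test_correlation_matrix_symmetric_diagonal(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(12, 3)), columns=list("abc"))
        m = correlation_matrix(df, ["a", "b", "c"])
        diag = m[(m.measure_x == m.measure_y)]
        assert (diag.rho == 1.0).all()


def _null_outcomes(rng, n_per_group=9):
    rows = []
    for g in ("stim", "sham"):
        for i in range(n_per_group):
            pre, post = rng.normal(8, 2, 2)
            rows.append(dict(subject=f"{g}{i}", group=g, condition="pre", p3_amp_uv=abs(pre)))
            rows.append(dict(subject=f"{g}{i}", group=g, condition="post", p3_amp_uv=abs(post)))
    return pd.DataFrame(rows)


class TestSuite:
    def test_three_adjusted_p_per_behavioral_measure(self):
        rng = np.random.default_rng(8)
        rows = []
        for g in ("stim", "sham"):
            for i in range(5):
                for cond in ("pre", "during", "post"):
                    rows.append(
                        dict(
                            subject=f"{g}{i}",
                            group=g,
                            condition=cond,
                            p3_amp_uv=abs(rng.normal(8, 2)) if cond != "during" else np.nan,
                            rt_mean_ms=rng.normal(450, 30),
                            rt_sd_ms=abs(rng.normal(100, 10)),
                            omissions=rng.integers(0, 6),
                        )
                    )
        res = run_hypothesis_suite(pd.DataFrame(rows))
        for measure in ("rt_mean_ms", "rt_sd_ms", "omissions"):
            fam = res[res.measure == measure]
            assert len(fam) == 3
            assert (fam.p_adjusted >= fam.p_raw - 1e-12).all()
            assert set(fam["tail"]) == {"less", "two-sided"}
        h1 = res[(res.measure == "p3_amp_uv")]
        assert len(h1) == 1 and h1.iloc[0]["tail"] == "greater"
        assert pd.isna(h1.iloc[0].p_adjusted)

    def test_detects_built_in_amplitude_effect(self):
        """A 1-SD group effect on the relative amplitude change is found
        in the majority of replicates."""
        rng = np.random.default_rng(9)
        hits = 0
        n_rep = 60
        for _ in range(n_rep):
            df = _null_outcomes(rng)
            boost = (df.group == "stim") & (df.condition == "post")
            df.loc[boost, "p3_amp_uv"] *= 1.6
            res = run_hypothesis_suite(df)
            hits += res[res.measure == "p3_amp_uv"].iloc[0].p_raw < 0.05
        assert hits > n_rep / 2

    def test_missing_group_rejected(self):
        df = _null_outcomes(np.random.default_rng(0))
        with pytest.raises(ValueError):
            run_hypothesis_suite(df[df.group == "stim"])
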