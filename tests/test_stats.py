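"""Repeated-measures ANOVA, Holm adjustment, Kendall tau and contrasts."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from soundloc3d import stats as st3d


def long_table(y, factors):
    """(n_subj, l1, ..., lk) array -> long-format DataFrame."""
    n_subj = y.shape[0]
    levels = [range(s) for s in y.shape[1:]]
    rows = []
    for s in range(n_subj):
        for cell in itertools.product(*levels):
            rows.append(
                {"participant": s, **{f: f"l{c}" for f, c in zip(factors, cell)}, "y": y[(s, *cell)]}
            )
    return pd.DataFrame(rows)


def holm_oracle(p):
    """Step-down Holm by direct enumeration (independent of statsmodels)."""
    p = np.asarray(p, float)
    order = np.argsort(p)
    n = len(p)
    adj = np.empty(n)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (n - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def kendall_oracle(x, y):
    """Brute-force tau over all pairs (no ties)."""
    n = len(x)
    s = sum(
        np.sign((x[i] - x[j]) * (y[i] - y[j]))
        for i in range(n)
        for j in range(i + 1, n)
    )
    return s / (n * (n - 1) / 2)


class TestRmAnova:
    def test_two_level_factor_equals_paired_t_squared(self, rng):
        y = rng.normal(0, 1, (14, 2)) + rng.normal(0, 2, (14, 1))
        table = long_table(y, ["cond"])
        res = st3d.rm_anova(table, "y", ["cond"])
        t, p = sps.ttest_rel(y[:, 0], y[:, 1])
        assert res[0].value == pytest.approx(t**2, abs=1e-9)
        assert res[0].p_raw == pytest.approx(p, abs=1e-9)

    def test_zero_effect_gives_zero_f(self, rng):
        base = rng.normal(0, 1, (10, 1))
        y = np.repeat(base, 2, axis=1)  # identical condition means per participant
        res = st3d.rm_anova(long_table(y, ["cond"]), "y", ["cond"])
        assert res[0].value == 0.0 and res[0].p_raw == 1.0

    def test_matches_pingouin_two_way(self, rng):
        """Cross-check F, GG-corrected p, epsilon and ges against pingouin."""
        pg = pytest.importorskip("pingouin")
        y = rng.normal(0, 1, (12, 2, 3)) + rng.normal(0, 1.5, (12, 1, 1))
        y[:, 1, 2] += 1.0
        table = long_table(y, ["A", "B"])
        ours = {r.name: r for r in st3d.rm_anova(table, "y", ["A", "B"])}
        ref = pg.rm_anova(
            data=table, dv="y", within=["A", "B"], subject="participant",
            correction=True, effsize="ng2", detailed=True,
        ).set_index("Source")
        for ours_name, ref_name in [("A", "A"), ("B", "B"), ("A x B", "A * B")]:
            r = ours[ours_name]
            assert r.value == pytest.approx(ref.loc[ref_name, "F"], rel=1e-9)
            assert r.effect_size == pytest.approx(ref.loc[ref_name, "ng2"], rel=1e-9)
            expected_p = ref.loc[ref_name, "p_GG_corr"] if r.df1 > 1 or r.correction == "GG" else ref.loc[ref_name, "p_unc"]
            if not np.isnan(expected_p):
                assert r.p_raw == pytest.approx(expected_p, rel=1e-6)

    def test_three_way_design_runs_and_decomposes(self, rng):
        y = rng.normal(0, 1, (8, 2, 2, 3))
        res = st3d.rm_anova(long_table(y, ["A", "B", "C"]), "y", ["A", "B", "C"])
        assert len(res) == 7  # 3 mains + 3 two-way + 1 three-way
        names = {r.name for r in res}
        assert "A x B x C" in names
        # total within-cells SS decomposition sanity: all SS non-negative
        assert all(r.extras["ss"] >= 0 for r in res)

    def test_gg_correction_never_lowers_p(self, rng):
        y = rng.normal(0, 1, (10, 4))
        y[:, 3] += np.linspace(0, 2, 10)  # break sphericity
        table = long_table(y, ["f"])
        corrected = st3d.rm_anova(table, "y", ["f"], gg=True)[0]
        raw = st3d.rm_anova(table, "y", ["f"], gg=False)[0]
        assert corrected.p_raw >= raw.p_raw
        assert corrected.df1 <= raw.df1

    def test_missing_cell_reported(self):
        table = long_table(np.zeros((4, 2)), ["cond"])
        with pytest.raises(ValueError, match="missing cells"):
            st3d.rm_anova(table.iloc[:-1], "y", ["cond"])

    def test_interaction_power_on_simulated_2x2(self, rng):
        """A 2x2 within design with a 1.5-unit interaction (noise SD 1) should

        be detected with power > 0.8 at n = 20 (paired-contrast d = 0.75).
        """
        n_sims, n, delta = 1000, 20, 1.5
        hits = 0
        for _ in range(n_sims):
            y = rng.normal(0, 1, (n, 2, 2))
            y[:, 1, 1] += delta
            res = st3d.rm_anova(long_table(y, ["A", "B"]), "y", ["A", "B"])
            inter = next(r for r in res if r.name == "A x B")
            hits += inter.p_raw < 0.05
        power = hits / n_sims
        # analytic oracle: paired t on the interaction scores, d = delta/2
        d = delta / 2.0
        crit = sps.t.ppf(0.975, n - 1)
        analytic = 1 - sps.nct.cdf(crit, n - 1, d * np.sqrt(n)) + sps.nct.cdf(-crit, n - 1, d * np.sqrt(n))
        assert power > 0.8
        assert power == pytest.approx(analytic, abs=0.05)


class TestHolm:
    def test_single_p_unchanged(self):
        assert st3d.holm_adjust([0.03])[0] == pytest.approx(0.03)

    def test_two_p_step_down(self):
        np.testing.assert_allclose(st3d.holm_adjust([0.01, 0.04]), [0.02, 0.04])

    def test_ties_capped_monotone(self):
        np.testing.assert_allclose(st3d.holm_adjust([0.03, 0.03, 0.03]), [0.09, 0.09, 0.09])

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=5))
    def test_matches_enumeration_oracle(self, ps):
        np.testing.assert_allclose(st3d.holm_adjust(ps), holm_oracle(ps), atol=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=8))
    def test_adjusted_at_least_raw_and_order_preserving(self, ps):
        adj = st3d.holm_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestKendall:
    def test_strictly_increasing(self):
        assert st3d.kendall_correlation([1, 2, 3, 4], [10, 20, 30, 40]).value == pytest.approx(1.0)

    def test_one_swap(self):
        r = st3d.kendall_correlation([1, 2, 3], [1, 3, 2])
        assert r.value == pytest.approx(1 / 3)
        assert r.value == pytest.approx(kendall_oracle(np.array([1, 2, 3]), np.array([1, 3, 2])))

    def test_reversed(self):
        assert st3d.kendall_correlation([1, 2, 3], [3, 2, 1]).value == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            st3d.kendall_correlation([1, 1, 1], [1, 2, 3])

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_on_random_tie_free_data(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.permutation(5).astype(float)
        y = rng.permutation(5).astype(float)
        r = st3d.kendall_correlation(x, y)
        assert r.value == pytest.approx(kendall_oracle(x, y), abs=1e-12)


class TestContrasts:
    def test_identical_samples(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        r = st3d.condition_contrast(a, a.copy())
        assert r.value == 0.0 and r.p_raw == 1.0

    def test_constant_shift_zero_variance_flagged(self):
        a = np.array([1.0, 2.0, 3.0])
        r = st3d.condition_contrast(a + 0.5, a)
        assert r.extras.get("degenerate") and np.isnan(r.p_raw)

    def test_family_holm_adjusts(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0, 1, 10)
        fam = st3d.contrast_family({"c1": (a, b), "c2": (a + 2, b)})
        for r in fam:
            assert r.p_adjusted >= r.p_raw - 1e-15
            assert "holm" in r.correction

    def test_power_against_analytic_oracle(self, rng):
        """Paired contrast at d = 1, n = 20: rejection rate matches closed form."""
        n, n_sims = 20, 2000
        crit = sps.t.ppf(0.975, n - 1)
        ncp = 1.0 * np.sqrt(n)
        analytic = 1 - sps.nct.cdf(crit, n - 1, ncp) + sps.nct.cdf(-crit, n - 1, ncp)
        hits = 0
        for _ in range(n_sims):
            diffs = rng.normal(1.0, 1.0, n)
            hits += st3d.condition_contrast(diffs, np.zeros(n)).p_raw < 0.05
        assert hits / n_sims == pytest.approx(analytic, abs=0.03)
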