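"""From-scratch ANOVA machinery, sphericity, Huynh-Feldt, Ryan post-hoc."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg, stats as sps

import fishstim as fs


def null_design(g=3, n=20, k=4, seed=0):
    rng = np.random.default_rng(seed)
    return fs.MixedDesignData(
        scores=rng.normal(size=(g * n, k)),
        groups=np.repeat([f"g{i}" for i in range(g)], n),
    )


class TestOnewayAnova:
    def test_all_equal_gives_nan_with_warning(self):
        with pytest.warns(UserWarning, match="zero error variance"):
            tab = fs.oneway_anova(np.ones(12), np.repeat(["a", "b", "c"], 4))
        assert np.isnan(tab.loc["group", "F"])

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=10), rng.normal(1.0, 1.0, size=12)
        tab = fs.oneway_anova(np.concatenate([x, y]), np.repeat(["a", "b"], [10, 12]))
        t, p = sps.ttest_ind(x, y)
        assert tab.loc["group", "F"] == pytest.approx(t**2)
        assert tab.loc["group", "p"] == pytest.approx(p)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(4)
        samples = [rng.normal(m, 1.0, size=9) for m in (0, 0.5, 1.0, 0.2)]
        values = np.concatenate(samples)
        groups = np.repeat([f"g{i}" for i in range(4)], 9)
        tab = fs.oneway_anova(values, groups)
        f, p = sps.f_oneway(*samples)
        assert tab.loc["group", "F"] == pytest.approx(f)
        assert tab.loc["group", "p"] == pytest.approx(p)


class TestMixedAnova:
    @pytest.mark.parametrize("g,N,expected", [(6, 108, (5, 102)), (6, 144, (5, 138))])
    def test_group_degrees_of_freedom(self, g, N, expected):
        rng = np.random.default_rng(0)
        data = fs.MixedDesignData(
            scores=rng.normal(size=(N, 6)),
            groups=np.repeat([f"g{i}" for i in range(g)], N // g),
        )
        tab = fs.mixed_anova(data)
        assert (tab.loc["group", "df1"], tab.loc["group", "df2"]) == expected
        assert (tab.loc["time", "df1"], tab.loc["time", "df2"]) == (5, (N - g) * 5)
        assert tab.loc["group x time", "df1"] == 25

    def test_matches_bruteforce_marginal_means(self):
        """2 groups x 3 subjects x 3 times: SS from explicit cell means."""
        y = np.array(
            [[1.0, 2.0, 4.0], [2.0, 1.0, 3.0], [0.0, 3.0, 5.0],
             [5.0, 4.0, 7.0], [6.0, 6.0, 9.0], [4.0, 5.0, 8.0]]
        )
        groups = np.repeat(["a", "b"], 3)
        tab = fs.mixed_anova(fs.MixedDesignData(scores=y, groups=groups))
        grand = y.mean()
        subj = y.mean(axis=1)
        ss_between_subj = 3 * ((subj - grand) ** 2).sum()
        ss_group = 3 * 3 * sum((y[groups == g].mean() - grand) ** 2 for g in "ab")
        ss_time = 6 * ((y.mean(axis=0) - grand) ** 2).sum()
        cells = np.array([y[groups == g].mean(axis=0) for g in "ab"])
        ss_cells = 3 * ((cells - grand) ** 2).sum()
        assert tab.loc["group", "SS"] == pytest.approx(ss_group)
        assert tab.loc["time", "SS"] == pytest.approx(ss_time)
        assert tab.loc["group x time", "SS"] == pytest.approx(
            ss_cells - ss_group - ss_time
        )
        err = tab.attrs["error_terms"]
        assert err["subject(group)"]["SS"] == pytest.approx(ss_between_subj - ss_group)

    def test_agrees_with_pingouin(self):
        import pingouin as pg

        data = null_design(g=3, n=8, k=4, seed=5)
        mine = fs.mixed_anova(data)
        n_tot, k = data.scores.shape
        df = pd.DataFrame(
            {
                "score": data.scores.ravel(),
                "time": np.tile([f"t{j}" for j in range(k)], n_tot),
                "subject": np.repeat(np.arange(n_tot), k),
                "group": np.repeat(data.groups, k),
            }
        )
        theirs = pg.mixed_anova(df, dv="score", within="time",
                                subject="subject", between="group").set_index("Source")
        for ours, ref in [("group", "group"), ("time", "time"),
                          ("group x time", "Interaction")]:
            assert mine.loc[ours, "F"] == pytest.approx(theirs.loc[ref, "F"])
            assert mine.loc[ours, "p"] == pytest.approx(theirs.loc[ref, "p_unc"])

    def test_sum_of_squares_conservation(self):
        data = null_design(seed=11)
        tab = fs.mixed_anova(data)
        err = tab.attrs["error_terms"]
        total = (
            tab["SS"].sum()
            + err["subject(group)"]["SS"]
            + err["time x subject(group)"]["SS"]
        )
        assert total == pytest.approx(tab.attrs["SS_total"])

    def test_subject_permutation_invariance(self):
        data = null_design(seed=12)
        perm = np.random.default_rng(0).permutation(data.n_subjects)
        shuffled = fs.MixedDesignData(
            scores=data.scores[perm], groups=data.groups[perm]
        )
        a, b = fs.mixed_anova(data), fs.mixed_anova(shuffled)
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())


class TestSphericity:
    def test_identity_contrast_covariance_gives_null_result(self):
        """Pooled contrast covariance exactly proportional to I: W=1, p=1."""
        k, p, n = 4, 3, 7
        C = linalg.helmert(k, full=False)
        H = linalg.helmert(n, full=False)  # rows orthonormal, sum to zero
        Z = H[:p].T * 2.0  # (n, p): centred columns, Z'Z = 4 I
        scores = Z @ C  # one group's data
        data = fs.MixedDesignData(
            scores=np.vstack([scores, scores + 5.0]),
            groups=np.repeat(["a", "b"], n),
        )
        res = fs.mendoza_sphericity(data)
        assert res.W == pytest.approx(1.0)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p == pytest.approx(1.0)
        assert res.eps_gg == pytest.approx(1.0)
        assert res.eps_hf == 1.0

    def test_epsilon_bounds(self):
        for seed in range(5):
            res = fs.mendoza_sphericity(null_design(seed=seed))
            k = 4
            assert 1.0 / (k - 1) <= res.eps_gg <= 1.0
            assert res.eps_gg <= res.eps_hf <= 1.0

    def test_null_rejection_rate_near_alpha(self):
        """400-rep spot check; the full 2000-rep calibration runs elsewhere."""
        rej = sum(
            fs.mendoza_sphericity(null_design(seed=s)).p < 0.05 for s in range(400)
        )
        assert 0.02 <= rej / 400 <= 0.09

    def test_ar1_covariance_detected(self):
        """Strong AR(1) dependence: rejection approaches 1 with larger n."""
        rng = np.random.default_rng(6)
        k, rho = 4, 0.9
        cov = rho ** np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
        L = np.linalg.cholesky(cov)
        rej = 0
        for _ in range(50):
            scores = rng.normal(size=(60, k)) @ L.T
            data = fs.MixedDesignData(
                scores=scores, groups=np.repeat(["a", "b", "c"], 20)
            )
            rej += fs.mendoza_sphericity(data).p < 0.05
        assert rej >= 48

    def test_singular_pooled_covariance_rejected(self):
        y = np.tile(np.array([[1.0, 2.0, 3.0, 4.0]]), (8, 1))  # zero covariance
        data = fs.MixedDesignData(scores=y, groups=np.repeat(["a", "b"], 4))
        with pytest.raises(ValueError, match="singular"):
            fs.mendoza_sphericity(data)


class TestHuynhFeldt:
    def test_eps_one_leaves_table_unchanged(self):
        tab = fs.mixed_anova(null_design(seed=1))
        out = fs.huynh_feldt_correction(tab, 1.0)
        pd.testing.assert_frame_equal(out, tab)

    def test_printed_corrected_dfs_reproduced(self):
        """k=6 designs: time df 5 x 0.714 -> 3.57; interaction 25 x 0.7996 -> 19.99."""
        rng = np.random.default_rng(2)
        data = fs.MixedDesignData(
            scores=rng.normal(size=(108, 6)),
            groups=np.repeat([f"g{i}" for i in range(6)], 18),
        )
        tab = fs.mixed_anova(data)
        out = fs.huynh_feldt_correction(tab, 0.714)
        assert out.loc["time", "df1"] == pytest.approx(3.57)
        out2 = fs.huynh_feldt_correction(tab, 0.7996)
        assert out2.loc["group x time", "df1"] == pytest.approx(19.99)

    def test_between_effect_untouched_and_p_recomputed(self):
        tab = fs.mixed_anova(null_design(seed=3))
        out = fs.huynh_feldt_correction(tab, 0.6)
        assert out.loc["group", "df1"] == tab.loc["group", "df1"]
        f = tab.loc["time", "F"]
        expect = sps.f.sf(f, tab.loc["time", "df1"] * 0.6, tab.loc["time", "df2"] * 0.6)
        assert out.loc["time", "p"] == pytest.approx(expect)

    def test_invalid_eps_rejected(self):
        tab = fs.mixed_anova(null_design(seed=4))
        with pytest.raises(ValueError):
            fs.huynh_feldt_correction(tab, 1.2)


class TestSimpleMainEffects:
    def test_single_group_slice_equals_rm_anova(self):
        data = null_design(g=3, n=10, k=4, seed=7)
        sme = fs.simple_main_effects(data)
        ref = fs.oneway_rm_anova(data.scores[data.groups == "g1"])
        row = sme.loc["time @ g1"]
        assert row["F"] == pytest.approx(ref.loc["time", "F"])
        assert row["p"] == pytest.approx(ref.loc["time", "p"])

    def test_group_slice_equals_oneway(self):
        data = null_design(g=3, n=10, k=4, seed=8)
        sme = fs.simple_main_effects(data)
        ref = fs.oneway_anova(data.scores[:, 2], data.groups)
        assert sme.loc["group @ t2", "F"] == pytest.approx(ref.loc["group", "F"])

    def test_planted_effect_localised_to_final_level(self):
        """Group separation only at the last time level shows up only there."""
        rng = np.random.default_rng(9)
        scores = rng.normal(size=(60, 4), scale=0.5)
        groups = np.repeat(["a", "b", "c"], 20)
        scores[groups == "a", 3] += 5.0
        sme = fs.simple_main_effects(
            fs.MixedDesignData(scores=scores, groups=groups)
        )
        assert sme.loc["group @ t3", "p"] < 1e-6
        assert sme.loc["group @ t0", "p"] > 0.01


class TestRyanPosthoc:
    def test_two_means_reduces_to_plain_t_test(self):
        rng = np.random.default_rng(10)
        x, y = rng.normal(size=8), rng.normal(2.0, 1.0, size=8)
        ms = (x.var(ddof=1) + y.var(ddof=1)) / 2
        res = fs.ryan_posthoc(
            np.array([x.mean(), y.mean()]), np.array([8, 8]), ms, 14, alpha=0.05
        )
        assert len(res) == 1
        assert res["alpha_nominal"].iloc[0] == pytest.approx(0.05)
        t, p = sps.ttest_ind(x, y)
        assert res["p"].iloc[0] == pytest.approx(p)

    def test_planted_deviant_isolated(self):
        """One far-off mean among six: exactly its 5 pairs are significant."""
        means = np.array([0.0, 0.1, -0.1, 0.05, -0.05, 10.0])
        res = fs.ryan_posthoc(means, np.full(6, 20), 1.0, 114, alpha=0.05)
        sig = res[res["significant"]]
        assert len(sig) == 5
        assert all("m5" in p for p in sig["pair"])

    def test_stepwise_coherence(self):
        """No significant pair strictly inside a non-significant span."""
        rng = np.random.default_rng(11)
        for _ in range(30):
            means = rng.normal(size=5)
            res = fs.ryan_posthoc(means, np.full(5, 10), 1.0, 45)
            order = np.argsort(means)
            rank = {f"m{i}": r for r, i in enumerate(order)}
            spans = {
                (min(rank[r["lo"]], rank[r["hi"]]), max(rank[r["lo"]], rank[r["hi"]])):
                r["significant"]
                for _, r in res.iterrows()
            }
            for (a, b), sig in spans.items():
                if sig:
                    for (c, d), outer_sig in spans.items():
                        if c <= a and d >= b and (c, d) != (a, b):
                            assert outer_sig

    def test_nominal_levels_shrink_with_stretch(self):
        res = fs.ryan_posthoc(np.arange(6.0), np.full(6, 10), 1.0, 54)
        by_stretch = res.groupby("stretch")["alpha_nominal"].first()
        assert by_stretch.is_monotonic_decreasing  # stretch 2 .. 6 ascending index
        assert by_stretch.loc[6] == pytest.approx(2 * 0.05 / (6 * 5))
        assert by_stretch.loc[2] == pytest.approx(2 * 0.05 / 6)


class TestAnalyzeScores:
    def test_full_chain_on_planted_cohort(self):
        """score -> exclude -> difference -> ANOVA -> Ryan isolates the planted group."""
        from fishstim.cli import demo_assay_params

        traces = fs.simulate_assay(demo_assay_params(1, seed=17))
        table = fs.difference_scores(fs.exclude_baseline(fs.score_subjects(traces)))
        res = fs.analyze_scores(fs.scores_to_long(table))
        assert res["anova"].loc["group", "p"] < 0.05
        ph = res["posthoc_group"]
        normal_pairs = ph[(ph["hi"] == "Normal") | (ph["lo"] == "Normal")]
        assert normal_pairs["significant"].all()
        assert (normal_pairs["hi"] == "Normal").all()
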