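"""Behavioral analysis: accuracy coding, tests, ANOVA, chunks, d-prime."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from melagl import analysis as an

# ---------------------------------------------------------------------------
# helpers


def toy_manifest():
    rows = []
    for i in range(3):
        rows.append({"id": f"g{i}", "category": "old_gram", "error_type": 0})
        rows.append({"id": f"n{i}", "category": "new_gram", "error_type": 0})
    for et in range(1, 6):
        rows.append({"id": f"u{et}", "category": "ungram", "error_type": et})
    return pd.DataFrame(rows)


def responses_for(manifest, participant, familiar_fn):
    return pd.DataFrame(
        {
            "participant": participant,
            "stimulus": manifest["id"],
            "familiar": [familiar_fn(r) for _, r in manifest.iterrows()],
        }
    )


class TestCodeAccuracy:
    def test_yes_sayer_splits_categories(self):
        man = toy_manifest()
        resp = responses_for(man, "p1", lambda r: 1)
        acc = an.code_accuracy(resp, man)
        row = acc.iloc[0]
        assert row["gram_all"] == 1.0 and row["ungram_all"] == 0.0
        assert row["overall"] == pytest.approx(6 / 11)

    def test_no_sayer_is_mirror(self):
        man = toy_manifest()
        acc = an.code_accuracy(responses_for(man, "p1", lambda r: 0), man)
        row = acc.iloc[0]
        assert row["gram_all"] == 0.0 and row["ungram_all"] == 1.0

    def test_perfect_responder(self):
        man = toy_manifest()
        perfect = lambda r: int(r["category"] != "ungram")
        acc = an.code_accuracy(responses_for(man, "p1", perfect), man)
        assert acc.iloc[0]["overall"] == 1.0

    def test_unknown_stimulus_raises(self):
        man = toy_manifest()
        resp = pd.DataFrame(
            {"participant": "p1", "stimulus": ["nope"], "familiar": [1]}
        )
        with pytest.raises(KeyError):
            an.code_accuracy(resp, man)


class TestExcludeOutliers:
    def test_two_planted_extremes_excluded(self):
        rng = np.random.default_rng(0)
        overall = np.concatenate([0.6 + 0.03 * rng.standard_normal(29), [0.99, 0.98]])
        acc = pd.DataFrame({"participant": range(31), "overall": overall})
        kept, excl = an.exclude_outliers(acc, k=2.0)
        assert len(kept) == 29 and len(excl) == 2
        assert set(excl["participant"]) == {29, 30}

    def test_homogeneous_group_keeps_everyone(self):
        acc = pd.DataFrame({"participant": range(5), "overall": [0.6, 0.61, 0.59, 0.6, 0.6]})
        kept, excl = an.exclude_outliers(acc)
        assert len(excl) == 0

    def test_k_zero_boundary(self):
        acc = pd.DataFrame({"participant": range(4), "overall": [0.5, 0.5, 0.5, 0.9]})
        kept, excl = an.exclude_outliers(acc, k=0.0)
        assert all(kept["overall"] == kept["overall"].mean())

    def test_criterion_not_iterated(self):
        # after removing the extreme, a second pass would also flag 0.8;
        # the rule applies once on the full group
        acc = pd.DataFrame(
            {"participant": range(6), "overall": [0.6, 0.6, 0.6, 0.6, 0.8, 2.0]}
        )
        kept, excl = an.exclude_outliers(acc, k=2.0)
        assert 0.8 in kept["overall"].values


class TestOneSampleT:
    @given(
        st.lists(st.floats(0.0, 1.0), min_size=5, max_size=40).filter(
            lambda v: np.std(v) > 1e-6
        ),
        st.floats(0.2, 0.8),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_reference_implementation(self, values, mu):
        res = an.one_sample_t(values, mu)
        ref_t, ref_p = stats.ttest_1samp(values, mu)
        assert res.t == pytest.approx(float(ref_t))
        assert res.p == pytest.approx(float(ref_p))
        assert res.df == len(values) - 1

    def test_mean_equal_mu(self):
        res = an.one_sample_t([0.4, 0.5, 0.6], 0.5)
        assert res.t == pytest.approx(0.0) and res.p == pytest.approx(1.0)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            an.one_sample_t([0.5, 0.5, 0.5], 0.4)


class TestHolm:
    def test_all_rejected(self):
        assert an.holm_adjust([0.01, 0.02, 0.04], 0.05).tolist() == [True] * 3

    def test_step_down_stops_at_first_failure(self):
        assert an.holm_adjust([0.03, 0.04, 0.05], 0.05).tolist() == [False] * 3

    def test_single_p_reduces_to_plain_test(self):
        assert an.holm_adjust([0.04], 0.05).tolist() == [True]

    def test_decisions_in_original_order(self):
        out = an.holm_adjust([0.04, 0.001], 0.05)
        assert out.tolist() == [True, True]

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    @settings(max_examples=200, deadline=None)
    def test_sandwiched_between_bonferroni_and_uncorrected(self, pvals):
        alpha = 0.05
        holm = an.holm_adjust(pvals, alpha)
        p = np.asarray(pvals)
        bonf = p <= alpha / len(p)
        raw = p <= alpha
        assert np.all(bonf <= holm)  # no less powerful than Bonferroni
        assert np.all(holm <= raw)  # no more liberal than uncorrected


# ---------------------------------------------------------------------------
# mixed ANOVA with an independent sums-of-squares oracle


def split_plot_oracle(wide, levels):
    """Classical balanced split-plot decomposition from cell means.

    ``wide``: DataFrame with group, musician, one column per within level.
    Returns dict of effect -> (F, df_num, df_den).  Assumes equal cell sizes.
    """
    K = len(levels)
    Y = wide[levels].to_numpy(dtype=float)
    gi = wide["group"].to_numpy()
    mi = wide["musician"].to_numpy()
    groups = sorted(set(gi))
    mus = sorted(set(mi))
    n = len(wide) // (len(groups) * len(mus))
    G = Y.mean()
    subj = Y.mean(axis=1)

    def cellmask(a, b):
        return (gi == a) & (mi == b)

    # between part (on subject means, scaled by K)
    ss_a = K * sum(
        (subj[gi == a].mean() - G) ** 2 * (gi == a).sum() for a in groups
    )
    ss_b = K * sum((subj[mi == b].mean() - G) ** 2 * (mi == b).sum() for b in mus)
    ss_cells = K * sum(
        (subj[cellmask(a, b)].mean() - G) ** 2 * cellmask(a, b).sum()
        for a in groups
        for b in mus
    )
    ss_ab = ss_cells - ss_a - ss_b
    ss_serr = K * sum(
        ((subj[cellmask(a, b)] - subj[cellmask(a, b)].mean()) ** 2).sum()
        for a in groups
        for b in mus
    )
    df_serr = len(wide) - len(groups) * len(mus)

    # within part
    lev_mean = Y.mean(axis=0)
    ss_w = len(wide) * ((lev_mean - G) ** 2).sum()
    ss_wa = 0.0
    for a in groups:
        m = Y[gi == a].mean(axis=0)
        ss_wa += (gi == a).sum() * ((m - lev_mean - subj[gi == a].mean() + G) ** 2).sum()
    ss_wb = 0.0
    for b in mus:
        m = Y[mi == b].mean(axis=0)
        ss_wb += (mi == b).sum() * ((m - lev_mean - subj[mi == b].mean() + G) ** 2).sum()
    ss_wcells = 0.0
    for a in groups:
        for b in mus:
            mask = cellmask(a, b)
            m = Y[mask].mean(axis=0)
            ss_wcells += mask.sum() * ((m - lev_mean - subj[mask].mean() + G) ** 2).sum()
    ss_wab = ss_wcells - ss_wa - ss_wb
    ss_werr = 0.0
    for a in groups:
        for b in mus:
            mask = cellmask(a, b)
            cell_lev = Y[mask].mean(axis=0)
            resid = Y[mask] - subj[mask][:, None] - cell_lev[None, :] + subj[mask].mean()
            ss_werr += (resid**2).sum()
    df_werr = df_serr * (K - 1)

    def F(ss, dfn, ss_err, df_err):
        return (ss / dfn) / (ss_err / df_err)

    g_levels = len(groups) - 1
    m_levels = len(mus) - 1
    return {
        "group": (F(ss_a, g_levels, ss_serr, df_serr), g_levels, df_serr),
        "musician": (F(ss_b, m_levels, ss_serr, df_serr), m_levels, df_serr),
        "group:musician": (
            F(ss_ab, g_levels * m_levels, ss_serr, df_serr),
            g_levels * m_levels,
            df_serr,
        ),
        "level": (F(ss_w, K - 1, ss_werr, df_werr), K - 1, df_werr),
        "level:group": (F(ss_wa, K - 1, ss_werr, df_werr), K - 1, df_werr),
        "level:musician": (F(ss_wb, K - 1, ss_werr, df_werr), K - 1, df_werr),
        "level:group:musician": (F(ss_wab, K - 1, ss_werr, df_werr), K - 1, df_werr),
    }


def balanced_toy(seed=0, n_per_cell=2, effects=True):
    rng = np.random.default_rng(seed)
    levels = ["L1", "L2", "L3"]
    rows = []
    pid = 0
    for gp in ("A", "B"):
        for mu in (0, 1):
            for _ in range(n_per_cell):
                base = 0.6 + rng.normal(0, 0.05)
                if effects:
                    base += 0.1 * (gp == "A") + 0.02 * mu
                for k, lev in enumerate(levels):
                    val = base + (0.05 * k if effects else 0) + rng.normal(0, 0.02)
                    rows.append(
                        dict(participant=f"p{pid}", group=gp, musician=mu,
                             level=lev, value=val)
                    )
                pid += 1
    return pd.DataFrame(rows), levels


class TestMixedAnova:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_split_plot_oracle_on_balanced_toys(self, seed):
        data, levels = balanced_toy(seed=seed)
        table = an.mixed_anova(data, levels)
        wide = data.pivot_table(index="participant", columns="level", values="value")
        meta = data.drop_duplicates("participant").set_index("participant")
        wide = wide.join(meta[["group", "musician"]])
        oracle = split_plot_oracle(wide, levels)
        for effect, (F, dfn, dfd) in oracle.items():
            row = table.loc[effect]
            assert row["F"] == pytest.approx(F, rel=1e-8), effect
            assert (row["df_num"], row["df_den"]) == (dfn, dfd)

    def test_constant_within_factor_gives_zero_within_F(self):
        data, levels = balanced_toy(effects=False, seed=3)
        wide = data.pivot_table(index="participant", columns="level", values="value")
        flat = data.copy()
        per = wide.mean(axis=1)
        flat["value"] = flat["participant"].map(per)
        table = an.mixed_anova(flat, levels)
        assert table.loc["level", "F"] == pytest.approx(0.0, abs=1e-18)

    def test_duplicated_groups_give_zero_group_F(self):
        data, levels = balanced_toy(seed=4, effects=False)
        mirrored = data.copy()
        a = data.copy()
        a["group"] = "A"
        b = data.copy()
        b["group"] = "B"
        b["participant"] = b["participant"] + "_dup"
        table = an.mixed_anova(pd.concat([a, b]), levels)
        assert table.loc["group", "F"] == pytest.approx(0.0, abs=1e-12)

    def test_partial_eta_sq_in_unit_interval(self):
        data, levels = balanced_toy(seed=5)
        table = an.mixed_anova(data, levels)
        assert ((table["partial_eta_sq"] >= 0) & (table["partial_eta_sq"] <= 1)).all()

    def test_incomplete_within_raises(self):
        data, levels = balanced_toy(seed=6)
        broken = data[~((data["participant"] == "p0") & (data["level"] == "L2"))]
        with pytest.raises(ValueError):
            an.mixed_anova(broken, levels)


class TestWithinContrasts:
    def test_identical_levels_give_zero_F(self):
        data, levels = balanced_toy(seed=7)
        same = data.copy()
        wide = data.pivot_table(index="participant", columns="level", values="value")
        per = wide.mean(axis=1)
        same["value"] = same["participant"].map(per)
        out = an.within_contrasts(same, levels, "simple")
        assert np.allclose(out["F"], 0.0)

    def test_planted_difference_matches_closed_form(self):
        rng = np.random.default_rng(8)
        n = 20
        d = 0.1 + rng.normal(0, 0.05, n)
        base = rng.normal(0.6, 0.1, n)
        rows = []
        for i in range(n):
            rows.append(dict(participant=i, group="A", musician=0, level="x", value=base[i]))
            rows.append(dict(participant=i, group="A", musician=0, level="y", value=base[i] + d[i]))
        out = an.within_contrasts(pd.DataFrame(rows), ["x", "y"], "simple")
        t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
        assert out.iloc[0]["F"] == pytest.approx(t * t)

    def test_repeated_contrasts_count(self):
        rng = np.random.default_rng(9)
        rows = []
        for i in range(6):
            for k in range(5):
                rows.append(
                    dict(participant=i, group="A", musician=0, level=f"et{k+1}",
                         value=rng.uniform(0.4, 0.9))
                )
        out = an.within_contrasts(pd.DataFrame(rows), [f"et{k+1}" for k in range(5)], "repeated")
        assert len(out) == 4

    def test_fewer_than_two_levels_raises(self):
        rows = [dict(participant=0, group="A", musician=0, level="x", value=0.5)]
        with pytest.raises(ValueError):
            an.within_contrasts(pd.DataFrame(rows), ["x"], "simple")


# ---------------------------------------------------------------------------
# chunk strength


def brute_force_acs(stimulus, corpus, n):
    grams = [tuple(stimulus[i : i + n]) for i in range(len(stimulus) - n + 1)]
    total = 0
    for gram in grams:
        for item in corpus:
            for j in range(len(item) - n + 1):
                total += tuple(item[j : j + n]) == gram
    return total / len(grams)


class TestChunkStrength:
    def test_worked_example(self):
        corpus = ["ABAB", "ABC"]
        assert an.chunk_strength("ABC", corpus, 2, view="symbol") == pytest.approx(2.0)

    def test_self_corpus_full_length(self):
        assert an.chunk_strength("ABCD", ["ABCD"], 4, view="symbol") == 1.0

    def test_absent_ngram_contributes_zero(self):
        assert an.chunk_strength("ZZ", ["ABCD"], 2, view="symbol") == 0.0

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            an.chunk_strength("AB", ["ABCD"], 3, view="symbol")

    @given(
        st.lists(st.integers(60, 64), min_size=3, max_size=8),
        st.lists(st.lists(st.integers(60, 64), min_size=3, max_size=8), min_size=1, max_size=4),
        st.integers(1, 3),
    )
    @settings(max_examples=100, deadline=None)
    def test_equals_brute_force_and_corpus_order_invariant(self, stim, corpus, n):
        a = an.chunk_strength(stim, corpus, n, view="pitch")
        assert a == pytest.approx(brute_force_acs(stim, corpus, n))
        assert a == pytest.approx(
            an.chunk_strength(stim, list(reversed(corpus)), n, view="pitch")
        )

    def test_interval_view_uses_differences(self):
        # stimulus transposed relative to corpus: pitch view misses,
        # interval view matches
        corpus = [[60, 62, 64]]
        assert an.chunk_strength([70, 72, 74], corpus, 2, view="pitch") == 0.0
        assert an.chunk_strength([70, 72, 74], corpus, 2, view="interval") == 1.0


# ---------------------------------------------------------------------------
# logistic regression


class TestParticipantLogistic:
    def test_null_features_give_near_zero_slopes(self):
        rng = np.random.default_rng(0)
        n = 4000
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        y = rng.integers(0, 2, n)
        fit = an.fit_participant_logistic(X, y)
        assert fit.converged
        assert abs(fit.coef["a"]) < 0.1 and abs(fit.coef["b"]) < 0.1

    def test_parameter_recovery(self):
        rng = np.random.default_rng(1)
        n = 20000
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-0.8 * x))
        y = rng.random(n) < p
        fit = an.fit_participant_logistic(pd.DataFrame({"acs2": x}), y.astype(int))
        assert fit.coef["acs2"] == pytest.approx(0.8, abs=0.06)

    def test_separated_data_stays_finite(self):
        X = pd.DataFrame({"x": [-2.0, -1.0, 1.0, 2.0]})
        y = [0, 0, 1, 1]
        fit = an.fit_participant_logistic(X, y)
        assert np.isfinite(fit.coef).all()
        assert fit.separated

    def test_constant_predictor_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"x": rng.normal(size=50), "const": 1.0})
        y = rng.integers(0, 2, 50)
        with pytest.warns(UserWarning, match="constant"):
            fit = an.fit_participant_logistic(X, y)
        assert np.isnan(fit.coef["const"])
        assert np.isfinite(fit.coef["x"])


class TestGroupBetaTests:
    def test_matches_one_sample_t(self):
        rng = np.random.default_rng(3)
        betas = pd.DataFrame({"b1": rng.normal(0.5, 1, 29), "b2": rng.normal(0, 2, 29)})
        out = an.group_beta_tests(betas)
        for col in betas.columns:
            ref = an.one_sample_t(betas[col], 0.0)
            assert out.loc[col, "t"] == pytest.approx(ref.t)
            assert out.loc[col, "df"] == 28

    def test_all_zero_betas_raise(self):
        betas = pd.DataFrame({"b": np.zeros(10)})
        with pytest.raises(ValueError):
            an.group_beta_tests(betas)


# ---------------------------------------------------------------------------
# Type-2 d' and exposure


class TestType2Dprime:
    def test_no_metaknowledge(self):
        correct = [1, 1, 0, 0] * 5
        conf = [1, 0, 1, 0] * 5
        assert an.type2_dprime(correct, conf) == pytest.approx(0.0)

    def test_hit_08_fa_02(self):
        correct = [1] * 10 + [0] * 10
        conf = [1] * 8 + [0] * 2 + [1] * 2 + [0] * 8
        expected = 2 * stats.norm.ppf(0.8)
        assert an.type2_dprime(correct, conf) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(1.683, abs=2e-3)

    def test_extreme_rate_correction(self):
        correct = [1] * 33 + [0] * 33
        conf = [1] * 33 + [0] * 33
        hit = 1 - 1 / 66
        fa = 1 / 66
        expected = stats.norm.ppf(hit) - stats.norm.ppf(fa)
        assert an.type2_dprime(correct, conf) == pytest.approx(expected)

    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=8, max_size=60))
    @settings(max_examples=150, deadline=None)
    def test_antisymmetric_in_confidence(self, trials):
        correct = [int(c) for c, _ in trials]
        conf = [int(h) for _, h in trials]
        if not (0 < sum(correct) < len(correct)):
            return
        d1 = an.type2_dprime(correct, conf)
        d2 = an.type2_dprime(correct, [1 - h for h in conf])
        assert d1 == pytest.approx(-d2)

    def test_missing_cell_raises(self):
        with pytest.raises(ValueError):
            an.type2_dprime([1, 1, 1], [1, 0, 1])


class TestExposure:
    def test_identical_vectors(self):
        r, p = an.exposure_correlation([1, 2, 3, 4], [1, 2, 3, 4])
        assert r == pytest.approx(1.0)

    def test_anti_ordered(self):
        r, _ = an.exposure_correlation([1, 2, 3, 4], [4, 3, 2, 1])
        assert r == pytest.approx(-1.0)

    def test_independent_large_n_near_zero(self):
        rng = np.random.default_rng(4)
        r, _ = an.exposure_correlation(rng.normal(size=3000), rng.normal(size=3000))
        assert abs(r) < 0.05

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            an.exposure_correlation([1, 1, 1], [1, 2, 3])
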