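"""Mixed models, ANOVA, nonparametrics, Holm and effect sizes vs. oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from psmem.stats import (LmmSpec, cohens_d, f_squared, fit_lmm, holm_adjust,
                         mixed_anova, partial_eta_squared, variance_inflation,
                         wilcoxon_signed_rank, build_design)


def _lmm_fixture():
    """Deterministic dataset; the frozen expectations below were computed
    with an independent restricted-maximum-likelihood implementation
    (type III tests with Satterthwaite degrees of freedom, sum-to-zero
    contrasts) on exactly this table."""
    rng = np.random.default_rng(42)
    rows = []
    for s in range(12):
        u = rng.normal(0, 0.6)
        x = rng.standard_normal(20)
        f = np.where(rng.random(20) < 0.5, "a", "b")
        y = 0.5 + 0.3 * x + 0.25 * (f == "a") + u + rng.standard_normal(20)
        rows.append(pd.DataFrame({"pid": f"p{s:02d}", "x": x, "f": f, "y": y}))
    return pd.concat(rows, ignore_index=True)


def test_lmm_matches_independent_reml_oracle():
    res = fit_lmm(_lmm_fixture(), LmmSpec(outcome="y", fixed=("x", "f", "x:f"),
                                          groups="pid"))
    expected = {
        # effect: (F, denominator df, p)
        "x": (10.4385, 228.0444, 0.0014163),
        "f": (7.47855, 227.3166, 0.0067360),
        "x:f": (4.69556, 229.5975, 0.0312696),
    }
    got = {t.effect: t for t in res.tests}
    for effect, (F, df2, p) in expected.items():
        assert got[effect].statistic == pytest.approx(F, rel=1e-4)
        assert got[effect].df2 == pytest.approx(df2, rel=1e-3)
        assert got[effect].p == pytest.approx(p, rel=1e-3)
    assert res.sigma2_re == pytest.approx(0.1522176, rel=1e-4)
    assert res.sigma2_resid == pytest.approx(0.9760345, rel=1e-4)
    assert not res.singular
    assert max(res.vif.values()) < 5


def test_lmm_reduces_to_ols_without_random_variance():
    """Zero between-subject variance: type-III F matches the OLS ANOVA."""
    rng = np.random.default_rng(1)
    n_sub, n_obs = 20, 15
    rows = []
    for s in range(n_sub):
        x = rng.standard_normal(n_obs)
        g = rng.random(n_obs) < 0.5
        y = 0.2 * x + 0.3 * g + rng.standard_normal(n_obs)  # no subject effect
        rows.append(pd.DataFrame({"participant_id": s, "x": x, "g": g, "y": y}))
    df = pd.concat(rows, ignore_index=True)
    spec = LmmSpec(outcome="y", fixed=("x", "g"))
    res = fit_lmm(df, spec)
    # OLS oracle with the same coding
    X, names, slices = build_design(df, spec)
    yv = df["y"].to_numpy()
    beta, _, _, _ = np.linalg.lstsq(X, yv, rcond=None)
    resid = yv - X @ beta
    dof = len(yv) - X.shape[1]
    s2 = resid @ resid / dof
    C = np.linalg.inv(X.T @ X) * s2
    got = {t.effect: t for t in res.tests}
    for term, sl in slices.items():
        j = sl.start
        F_ols = beta[j] ** 2 / C[j, j]
        assert got[term].statistic == pytest.approx(F_ols, rel=1e-3)
        assert got[term].df2 == pytest.approx(dof, rel=0.02)


def test_lmm_recovers_planted_effect():
    rng = np.random.default_rng(3)
    rows = []
    beta_true = 0.4
    for s in range(50):
        u = rng.normal(0, 0.5)
        x = rng.standard_normal(40)
        y = beta_true * x + u + rng.standard_normal(40)
        rows.append(pd.DataFrame({"participant_id": s, "x": x, "y": y}))
    res = fit_lmm(pd.concat(rows, ignore_index=True),
                  LmmSpec(outcome="y", fixed=("x",)))
    est = res.coefficients.set_index("term").loc["x"]
    assert abs(est["estimate"] - beta_true) < 3 * est["se"]


def test_lmm_type_iii_invariant_to_term_order():
    df = _lmm_fixture()
    a = fit_lmm(df, LmmSpec(outcome="y", fixed=("x", "f"), groups="pid"),
                compute_effect_sizes=False)
    b = fit_lmm(df, LmmSpec(outcome="y", fixed=("f", "x"), groups="pid"),
                compute_effect_sizes=False)
    fa = {t.effect: t.statistic for t in a.tests}
    fb = {t.effect: t.statistic for t in b.tests}
    for k in fa:
        assert fa[k] == pytest.approx(fb[k], rel=1e-8)


def test_lmm_flags_rank_deficiency():
    df = _lmm_fixture().assign(x2=lambda d: d["x"] * 2.0)
    with pytest.raises(ValueError, match="rank deficient"):
        fit_lmm(df, LmmSpec(outcome="y", fixed=("x", "x2"), groups="pid"))


def test_vif_detects_collinearity(rng):
    x = rng.standard_normal(200)
    z = x + 0.05 * rng.standard_normal(200)
    X = np.column_stack([np.ones(200), x, z])
    vif = variance_inflation(X, ["intercept", "x", "z"])
    assert vif["x"] > 5 and vif["z"] > 5
    X2 = np.column_stack([np.ones(200), x, rng.standard_normal(200)])
    vif2 = variance_inflation(X2, ["intercept", "x", "w"])
    assert max(vif2["x"], vif2["w"]) < 1.5


# ---------------------------------------------------------------------------
# mixed (split-plot) ANOVA

def _splitplot_oracle(df, dv, within, between, subject):
    """Textbook sums-of-squares split-plot ANOVA for balanced 2x2 designs."""
    gm = df[dv].mean()
    W = df[within].nunique()
    subj_means = df.groupby([subject, between])[dv].mean().reset_index()
    grp_means = df.groupby(between)[dv].mean()
    win_means = df.groupby(within)[dv].mean()
    cell_means = df.groupby([between, within])[dv].mean()
    n_per_group = subj_means.groupby(between).size()
    N = n_per_group.sum()
    ss_between = W * sum(n_per_group[g] * (grp_means[g] - gm) ** 2
                         for g in grp_means.index)
    ss_subj = W * sum((row[dv] - grp_means[row[between]]) ** 2
                      for _, row in subj_means.iterrows())
    ss_within = N * sum((win_means[w] - gm) ** 2 for w in win_means.index)
    ss_inter = sum(n_per_group[g] * (cell_means[(g, w)] - grp_means[g]
                                     - win_means[w] + gm) ** 2
                   for g in grp_means.index for w in win_means.index)
    sm = df.merge(subj_means.rename(columns={dv: "subj_mean"}), on=[subject, between])
    sm = sm.merge(cell_means.rename("cell_mean").reset_index(), on=[between, within])
    sm = sm.assign(grp_mean=sm[between].map(grp_means))
    ss_err_w = ((sm[dv] - sm["subj_mean"] - sm["cell_mean"] + sm["grp_mean"]) ** 2).sum()
    G = len(grp_means)
    out = {
        "between": (ss_between / (G - 1)) / (ss_subj / (N - G)),
        "within": (ss_within / (W - 1)) / (ss_err_w / ((N - G) * (W - 1))),
        "interaction": (ss_inter / ((G - 1) * (W - 1)))
        / (ss_err_w / ((N - G) * (W - 1))),
    }
    return out


def _anova_table(seed=0, gap=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(16):
        grp = "cortisol" if s % 2 else "placebo"
        base = rng.normal(0, 0.5)
        for cond in ("task_relevant", "task_irrelevant"):
            val = base + rng.normal(0, 0.3) + (gap if cond == "task_relevant" else 0)
            rows.append({"participant_id": f"s{s:02d}", "group": grp,
                         "condition": cond, "mean_z": val})
    return pd.DataFrame(rows)


def test_mixed_anova_matches_splitplot_oracle():
    df = _anova_table(seed=2, gap=0.3)
    res = {t.effect: t for t in mixed_anova(df, dv="mean_z", within="condition",
                                            between="group")}
    oracle = _splitplot_oracle(df, "mean_z", "condition", "group", "participant_id")
    assert res["group"].statistic == pytest.approx(oracle["between"], abs=1e-8)
    assert res["condition"].statistic == pytest.approx(oracle["within"], abs=1e-8)
    assert res["Interaction"].statistic == pytest.approx(oracle["interaction"],
                                                         abs=1e-8)


def test_mixed_anova_zero_within_effect():
    df = _anova_table(seed=3)
    df["mean_z"] = df.groupby("participant_id")["mean_z"].transform("mean")
    res = {t.effect: t for t in mixed_anova(df, dv="mean_z", within="condition",
                                            between="group")}
    assert res["condition"].statistic == pytest.approx(0.0, abs=1e-10)


def test_mixed_anova_planted_gap_power():
    """A planted within-condition gap is detected in most replicates."""
    hits = 0
    n_rep = 40
    for rep in range(n_rep):
        df = _anova_table(seed=100 + rep, gap=0.35)
        res = {t.effect: t for t in mixed_anova(df, dv="mean_z",
                                                within="condition",
                                                between="group")}
        hits += res["condition"].p < 0.05
    assert hits / n_rep >= 0.8


def test_mixed_anova_requires_two_per_group():
    df = _anova_table(seed=1)
    solo = df[df["participant_id"].isin(["s00", "s01", "s03"])]
    with pytest.raises(ValueError):
        mixed_anova(solo, dv="mean_z", within="condition", between="group")


# ---------------------------------------------------------------------------
# Wilcoxon, Holm, effect sizes

def test_wilcoxon_all_positive_n3():
    res = wilcoxon_signed_rank(np.array([2.0, 3.0, 4.0]), np.array([1.0, 1.0, 1.0]),
                               alternative="greater")
    assert res.statistic == 6.0
    assert res.p == pytest.approx(0.125)  # enumeration of the 8 sign patterns


def test_wilcoxon_identical_samples_is_missing():
    res = wilcoxon_signed_rank(np.arange(5.0), np.arange(5.0))
    assert np.isnan(res.statistic) and np.isnan(res.p)


def test_wilcoxon_matches_bruteforce_rank_sum(rng):
    for _ in range(20):
        x = rng.standard_normal(10)
        y = rng.standard_normal(10)
        res = wilcoxon_signed_rank(x, y)
        d = x - y
        ranks = sps.rankdata(np.abs(d))
        assert res.statistic == pytest.approx(ranks[d > 0].sum())
        scipy_p = sps.wilcoxon(x, y, method="exact").pvalue
        assert res.p == pytest.approx(scipy_p, abs=1e-12)


def test_wilcoxon_normal_approximation_with_ties():
    rng = np.random.default_rng(8)
    x = rng.integers(0, 4, size=40).astype(float)
    y = rng.integers(0, 4, size=40).astype(float)
    res = wilcoxon_signed_rank(x, y)
    ref = sps.wilcoxon(x, y, zero_method="wilcox", correction=False,
                       method="approx").pvalue
    assert res.p == pytest.approx(ref, abs=1e-10)


def test_holm_hand_computed_example():
    np.testing.assert_allclose(holm_adjust([0.01, 0.02, 0.04]), [0.03, 0.04, 0.04])
    np.testing.assert_allclose(holm_adjust([0.2]), [0.2])


def test_holm_matches_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests

    for _ in range(20):
        p = rng.random(rng.integers(1, 12))
        _, ref, _, _ = multipletests(p, method="holm")
        np.testing.assert_allclose(holm_adjust(p), ref, atol=1e-12)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=15))
def test_holm_properties(ps):
    p = np.array(ps)
    adj = holm_adjust(p)
    assert np.all(adj >= p - 1e-15)
    assert np.all(adj <= 1.0)
    # monotone: preserves the ordering of the raw p-values
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(adj[order]) >= -1e-15)
    # permutation equivariant
    perm = np.argsort(p)[::-1]
    np.testing.assert_allclose(holm_adjust(p[perm]), adj[perm], atol=1e-12)


def test_effect_size_formulas(rng):
    assert f_squared(0.5, 0.4) == pytest.approx(0.2)
    assert partial_eta_squared(3.0, 9.0) == pytest.approx(0.25)
    x = rng.standard_normal(200) + 0.5
    y = rng.standard_normal(200)
    pooled = np.sqrt(((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1))
                     / (len(x) + len(y) - 2))
    assert cohens_d(x, y) == pytest.approx((x.mean() - y.mean()) / pooled)
    assert cohens_d(x, x) == 0.0
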