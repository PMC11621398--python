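"""ANOVAs against sums-of-squares oracles; Sidak; paired t; rank correlations."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from oddwave import stats as st


def toy_rm_table(n_subj=4, a_levels=("t1", "t2"), b_levels=("c1", "c2"), seed=0):
    rng = np.random.default_rng(seed)
    rows = [(f"s{s}", a, b, rng.normal())
            for s in range(n_subj) for a in a_levels for b in b_levels]
    return pd.DataFrame(rows, columns=["subj", "treat", "chan", "y"])


def rm_anova_oracle(df):
    """Hand-computed two-way within-subject sums of squares (loop form)."""
    subs = sorted(df.subj.unique())
    a_l = sorted(df.treat.unique())
    b_l = sorted(df.chan.unique())
    y = {(r.subj, r.treat, r.chan): r.y for r in df.itertuples()}
    n, a, b = len(subs), len(a_l), len(b_l)
    grand = np.mean(list(y.values()))
    mean_s = {s: np.mean([y[(s, ai, bi)] for ai in a_l for bi in b_l]) for s in subs}
    mean_a = {ai: np.mean([y[(s, ai, bi)] for s in subs for bi in b_l]) for ai in a_l}
    mean_b = {bi: np.mean([y[(s, ai, bi)] for s in subs for ai in a_l]) for bi in b_l}
    mean_sa = {(s, ai): np.mean([y[(s, ai, bi)] for bi in b_l]) for s in subs for ai in a_l}
    mean_sb = {(s, bi): np.mean([y[(s, ai, bi)] for ai in a_l]) for s in subs for bi in b_l}
    mean_ab = {(ai, bi): np.mean([y[(s, ai, bi)] for s in subs]) for ai in a_l for bi in b_l}
    ss_a = n * b * sum((mean_a[ai] - grand) ** 2 for ai in a_l)
    ss_b = n * a * sum((mean_b[bi] - grand) ** 2 for bi in b_l)
    ss_as = b * sum((mean_sa[(s, ai)] - mean_s[s] - mean_a[ai] + grand) ** 2
                    for s in subs for ai in a_l)
    ss_bs = a * sum((mean_sb[(s, bi)] - mean_s[s] - mean_b[bi] + grand) ** 2
                    for s in subs for bi in b_l)
    ss_ab = n * sum((mean_ab[(ai, bi)] - mean_a[ai] - mean_b[bi] + grand) ** 2
                    for ai in a_l for bi in b_l)
    ss_res = sum(
        (y[(s, ai, bi)] - mean_sa[(s, ai)] - mean_sb[(s, bi)] - mean_ab[(ai, bi)]
         + mean_s[s] + mean_a[ai] + mean_b[bi] - grand) ** 2
        for s in subs for ai in a_l for bi in b_l)
    f_a = (ss_a / (a - 1)) / (ss_as / ((n - 1) * (a - 1)))
    f_b = (ss_b / (b - 1)) / (ss_bs / ((n - 1) * (b - 1)))
    f_ab = (ss_ab / ((a - 1) * (b - 1))) / (ss_res / ((n - 1) * (a - 1) * (b - 1)))
    return {"treat": f_a, "chan": f_b, "treat * chan": f_ab}


class TestRmAnova:
    def test_f_matches_hand_sums_of_squares_oracle(self):
        df = toy_rm_table()
        res = st.rm_anova(df, "y", "subj", ("treat", "chan")).set_index("Source")
        oracle = rm_anova_oracle(df)
        for source, f_val in oracle.items():
            assert res.loc[source, "F"] == pytest.approx(f_val, rel=1e-10)

    def test_f_matches_oracle_on_larger_design(self):
        df = toy_rm_table(n_subj=6, a_levels=("t1", "t2", "t3"),
                          b_levels=("c1", "c2", "c3", "c4"), seed=3)
        res = st.rm_anova(df, "y", "subj", ("treat", "chan")).set_index("Source")
        for source, f_val in rm_anova_oracle(df).items():
            assert res.loc[source, "F"] == pytest.approx(f_val, rel=1e-10)

    def test_matches_pingouin_on_main_effects(self):
        pg = pytest.importorskip("pingouin")
        df = toy_rm_table(n_subj=8, a_levels=("t1", "t2", "t3"),
                          b_levels=("c1", "c2", "c3", "c4"), seed=7)
        mine = st.rm_anova(df, "y", "subj", ("treat", "chan")).set_index("Source")
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = pg.rm_anova(data=df, dv="y", within=["treat", "chan"],
                              subject="subj").set_index("Source")
        for src in ("treat", "chan"):
            assert mine.loc[src, "F"] == pytest.approx(ref.loc[src, "F"], rel=1e-9)
            assert mine.loc[src, "p"] == pytest.approx(ref.loc[src, "p_unc"], rel=1e-9)
            assert mine.loc[src, "eps_gg"] == pytest.approx(ref.loc[src, "eps"], rel=1e-6)

    def test_equal_treatment_means_give_zero_f(self):
        df = toy_rm_table(seed=1)
        # symmetrise: remove the treatment main effect exactly
        means = df.groupby("treat")["y"].transform("mean")
        df["y"] = df["y"] - means
        res = st.rm_anova(df, "y", "subj", ("treat", "chan")).set_index("Source")
        assert res.loc["treat", "F"] == pytest.approx(0.0, abs=1e-20)

    def test_treatment_shift_scales_ss_quadratically(self):
        df = toy_rm_table(seed=2)
        df["y"] -= df.groupby("treat")["y"].transform("mean")   # null base

        def ss_treat(delta):
            d = df.copy()
            d.loc[d.treat == "t2", "y"] += delta
            res = st.rm_anova(d, "y", "subj", ("treat", "chan"))
            return res.set_index("Source").loc["treat", "SS"]

        assert ss_treat(2.0) == pytest.approx(4.0 * ss_treat(1.0), rel=1e-10)
        assert ss_treat(3.0) == pytest.approx(9.0 * ss_treat(1.0), rel=1e-10)

    def test_constant_shift_leaves_f_invariant(self):
        df = toy_rm_table(seed=5)
        r1 = st.rm_anova(df, "y", "subj", ("treat", "chan"))
        df2 = df.assign(y=df.y + 1000.0)
        r2 = st.rm_anova(df2, "y", "subj", ("treat", "chan"))
        assert np.allclose(r1["F"], r2["F"], rtol=1e-8)

    def test_incomplete_layout_raises_toward_between_path(self):
        df = toy_rm_table().iloc[1:]
        with pytest.raises(ValueError, match="between_anova"):
            st.rm_anova(df, "y", "subj", ("treat", "chan"))


def between_oracle_2x2(cells):
    """Textbook balanced 2x2 fixed-effects decomposition; cells[(a,b)] = list."""
    ys = np.array([v for vals in cells.values() for v in vals])
    grand = ys.mean()
    n = len(next(iter(cells.values())))
    a_means = {a: np.mean([v for (ai, _), vals in cells.items() if ai == a
                           for v in vals]) for a in (0, 1)}
    b_means = {b: np.mean([v for (_, bi), vals in cells.items() if bi == b
                           for v in vals]) for b in (0, 1)}
    cell_means = {k: np.mean(v) for k, v in cells.items()}
    ss_a = 2 * n * sum((m - grand) ** 2 for m in a_means.values())
    ss_b = 2 * n * sum((m - grand) ** 2 for m in b_means.values())
    ss_ab = n * sum((cell_means[(a, b)] - a_means[a] - b_means[b] + grand) ** 2
                    for a in (0, 1) for b in (0, 1))
    ss_err = sum((v - cell_means[k]) ** 2 for k, vals in cells.items() for v in vals)
    df_err = 4 * (n - 1)
    return {"A": ss_a / (ss_err / df_err), "B": ss_b / (ss_err / df_err),
            "A * B": (ss_ab) / (ss_err / df_err)}


class TestBetweenAnova:
    def test_matches_textbook_oracle_on_balanced_2x2(self):
        rng = np.random.default_rng(4)
        cells = {(a, b): list(rng.normal(a + 2 * b, 1.0, 5))
                 for a in (0, 1) for b in (0, 1)}
        rows = [{"A": a, "B": b, "y": v} for (a, b), vals in cells.items()
                for v in vals]
        res = st.between_anova(pd.DataFrame(rows), "y", ("A", "B")).set_index("Source")
        oracle = between_oracle_2x2(cells)
        for src, f in oracle.items():
            assert res.loc[src, "F"] == pytest.approx(f, rel=1e-10)

    def test_equal_group_means_give_near_zero_f(self):
        rows = [{"A": a, "B": b, "y": y}
                for a in (0, 1) for b in (0, 1) for y in (1.0, 2.0, 3.0)]
        res = st.between_anova(pd.DataFrame(rows), "y", ("A", "B")).set_index("Source")
        assert res.loc["A", "F"] == pytest.approx(0.0, abs=1e-12)

    def test_empty_cell_raises(self):
        rows = [{"A": a, "B": b, "y": 1.0} for a, b in ((0, 0), (0, 1), (1, 0))]
        with pytest.raises(ValueError, match="empty"):
            st.between_anova(pd.DataFrame(rows), "y", ("A", "B"))


class TestSidak:
    def test_closed_form_values(self):
        assert st.sidak_adjust([0.05], 1)[0] == pytest.approx(0.05)
        assert st.sidak_adjust([0.05], 2)[0] == pytest.approx(0.0975)
        assert st.sidak_adjust([0.01], 5)[0] == pytest.approx(1 - 0.99**5)

    def test_monotone_and_never_below_unadjusted(self):
        p = np.linspace(0.001, 0.9, 25)
        adj = st.sidak_adjust(p, 7)
        assert np.all(np.diff(adj) >= 0)
        assert np.all(adj >= p)
        assert np.all(adj <= 1.0)

    def test_invalid_p_raises(self):
        with pytest.raises(ValueError):
            st.sidak_adjust([1.5])


class TestPairedT:
    def test_identical_samples_give_t_zero_p_one(self):
        res = st.paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["t"] == 0.0 and res["p"] == 1.0

    def test_differences_one_two_three(self):
        res = st.paired_t([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert res["t"] == pytest.approx(2 * math.sqrt(3), rel=1e-12)
        assert res["df"] == 2

    def test_sign_flip_flips_t_keeps_p(self):
        x = np.array([1.0, 3.0, 2.5, 4.0])
        y = np.array([0.5, 2.0, 3.0, 3.0])
        a = st.paired_t(x, y)
        b = st.paired_t(y, x)
        assert a["t"] == pytest.approx(-b["t"])
        assert a["p"] == pytest.approx(b["p"])

    def test_constant_nonzero_difference_raises(self):
        with pytest.raises(ValueError, match="variance"):
            st.paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])


class TestSpearman:
    def test_monotone_relation_is_rho_one_very_strong(self):
        x = np.array([1.0, 2.0, 5.0, 7.0, 11.0, 13.0])
        res = st.spearman(x, np.exp(x))
        assert res["rho"] == pytest.approx(1.0)
        assert res["label"] == "very strong"

    def test_tied_data_matches_rank_pearson_oracle(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0]
        y = [5.0, 5.0, 7.0, 8.0, 6.0]
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert st.spearman(x, y)["rho"] == pytest.approx(oracle, rel=1e-12)

    def test_invariant_under_strictly_monotone_transforms(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=(2, 12))
        base = st.spearman(x, y)["rho"]
        assert st.spearman(np.exp(x), y**3)["rho"] == pytest.approx(base, rel=1e-12)

    def test_label_thresholds(self):
        for rho, label in ((0.05, "negligible"), (0.15, "weak"), (0.55, "moderate"),
                           (-0.75, "strong"), (0.95, "very strong")):
            assert st.correlation_label(rho) == label

    def test_exact_permutation_p_for_small_n(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 5.0]
        res = st.spearman(x, y)
        # brute force over all 5! pairings
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        obs = np.corrcoef(rx, ry)[0, 1]
        count = sum(
            abs(np.corrcoef(rx, np.array(p))[0, 1]) >= abs(obs) - 1e-12
            for p in itertools.permutations(ry))
        assert res["p"] == pytest.approx(count / math.factorial(5))

    def test_constant_input_raises(self):
        with pytest.raises(ValueError, match="constant"):
            st.spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


class TestPartialSpearman:
    def test_matches_residual_regression_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            x, y, z = rng.normal(size=(3, 8))
            rx, ry, rz = (sps.rankdata(v) for v in (x, y, z))
            # two-stage oracle: correlate OLS residuals of ranks on control ranks
            def resid(a, b):
                beta = np.polyfit(b, a, 1)
                return a - np.polyval(beta, b)
            oracle = np.corrcoef(resid(rx, rz), resid(ry, rz))[0, 1]
            assert st.partial_spearman(x, y, z)["rho"] == pytest.approx(
                oracle, rel=1e-10)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(10)
        x, y, z = rng.normal(size=(3, 12))
        ref = pg.partial_corr(data=pd.DataFrame({"x": x, "y": y, "z": z}),
                              x="x", y="y", covar="z", method="spearman")
        mine = st.partial_spearman(x, y, z)
        assert mine["rho"] == pytest.approx(float(ref["r"].iloc[0]), rel=1e-9)
        assert mine["p"] == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_orthogonal_control_reduces_to_plain_spearman(self):
        # ranks of z constructed orthogonal (on ranks) to both x and y
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0, 8.0, 7.0])
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        target = None
        for perm in itertools.permutations(range(1, 9)):
            rz = np.array(perm, float)
            if (abs(np.corrcoef(rx, rz)[0, 1]) < 1e-12
                    and abs(np.corrcoef(ry, rz)[0, 1]) < 1e-12):
                target = rz
                break
        assert target is not None
        plain = st.spearman(x, y, exact_below_n=0)["rho"]
        assert st.partial_spearman(x, y, target)["rho"] == pytest.approx(
            plain, rel=1e-12)

    def test_control_equal_to_x_raises(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        with pytest.raises(ValueError, match="degenerate"):
            st.partial_spearman(x, x[::-1], x)


def test_correlation_matrix_shapes_and_adjustment():
    rng = np.random.default_rng(11)
    subjects = [f"r{i}" for i in range(10)]
    markers = pd.DataFrame(rng.normal(size=(10, 3)), index=subjects,
                           columns=["P1N1", "N1P2", "gamma"])
    drinking = pd.DataFrame(rng.normal(size=(10, 2)), index=subjects,
                            columns=["BL", "ADE"])
    out = st.correlation_matrix(markers, drinking)
    assert len(out) == 6
    assert set(out.columns) >= {"marker", "metric", "rho", "p", "p_adj", "label"}
    m = markers.shape[1]
    expect = 1 - (1 - out["p"]) ** m
    assert np.allclose(out["p_adj"], expect)
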