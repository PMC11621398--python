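"""Inferential layer: factorial ANOVAs, Sidak adjustment, paired t-tests,
Spearman and partial Spearman correlations.

The repeated-measures ANOVA is a balanced two-way within-subject
decomposition (factors crossed within every subject, e.g. treatment x
channel), each effect tested against its own subject-by-effect error stratum.
Sphericity is assessed per effect with Mauchly's test; the Greenhouse-Geisser
corrected p-value is always reported alongside the uncorrected one, and
``p_report`` selects the corrected value when Mauchly rejects (p < 0.05).
Effect sizes are partial eta squared for ANOVAs and rho for correlations.

Correlation strength labels follow |rho| >= 0.1 weak, >= 0.4 moderate,
>= 0.7 strong, >= 0.9 very strong. Spearman p-values use the t approximation
for n >= 10 and the exact permutation distribution for smaller samples, since
cohorts of about ten animals sit right at that boundary.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats as sps

LABEL_THRESHOLDS = ((0.9, "very strong"), (0.7, "strong"), (0.4, "moderate"),
                    (0.1, "weak"))


def correlation_label(rho: float) -> str:
    a = abs(rho)
    for thr, name in LABEL_THRESHOLDS:
        if a >= thr:
            return name
    return "negligible"


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (rows orthogonal to the mean)."""
    full = np.eye(k) - 1.0 / k
    q, _ = np.linalg.qr(full.T)
    return q[:, : k - 1].T


def _gg_epsilon(d: np.ndarray, contrasts: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from subject x condition data ``d``."""
    m = contrasts @ np.cov(d, rowvar=False) @ contrasts.T
    p = m.shape[0]
    tr = np.trace(m)
    denom = p * np.sum(m * m)
    return float(tr**2 / denom) if denom > 0 else 1.0


def _mauchly(d: np.ndarray, contrasts: np.ndarray) -> tuple[float, float]:
    """Mauchly's sphericity test; returns (W, p). NaN when not estimable."""
    n = d.shape[0]
    m = contrasts @ np.cov(d, rowvar=False) @ contrasts.T
    p = m.shape[0]
    if p < 2:
        return 1.0, np.nan
    if n - 1 < p:
        return np.nan, np.nan          # covariance singular by construction
    sign, logdet = np.linalg.slogdet(m)
    if sign <= 0:
        return np.nan, np.nan
    log_w = logdet - p * np.log(np.trace(m) / p)
    f = 1.0 - (2.0 * p**2 + p + 2.0) / (6.0 * p * (n - 1))
    chi2 = -(n - 1) * f * log_w
    df = p * (p + 1) // 2 - 1
    return float(np.exp(log_w)), float(sps.chi2.sf(chi2, df))


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    within: tuple[str, str],
) -> pd.DataFrame:
    """Two-way fully-within repeated-measures ANOVA on a balanced table.

    Returns one row per effect (two mains and the interaction) with SS, df,
    F, p, Greenhouse-Geisser epsilon and corrected p, Mauchly's W and p,
    partial eta squared, and ``p_report`` (GG-corrected when Mauchly
    p < 0.05, uncorrected otherwise).
    """
    fa, fb = within
    counts = data.groupby([subject, fa, fb])[dv].count()
    if (counts != 1).any() or counts.unstack([fa, fb]).isna().any().any():
        raise ValueError(
            "unbalanced or incomplete within-subject layout; every subject must "
            "be observed exactly once per factor combination (for group designs "
            "use between_anova)"
        )
    cube = (
        data.pivot_table(index=subject, columns=[fa, fb], values=dv)
        .sort_index(axis=1)
    )
    a_levels = cube.columns.get_level_values(0).unique()
    b_levels = cube.columns.get_level_values(1).unique()
    n, a, b = cube.shape[0], len(a_levels), len(b_levels)
    y = cube.to_numpy().reshape(n, a, b)

    grand = y.mean()
    s_mean = y.mean(axis=(1, 2))
    a_mean = y.mean(axis=(0, 2))
    b_mean = y.mean(axis=(0, 1))
    sa = y.mean(axis=2)
    sb = y.mean(axis=1)
    ab = y.mean(axis=0)

    ss_a = n * b * np.sum((a_mean - grand) ** 2)
    ss_b = n * a * np.sum((b_mean - grand) ** 2)
    ss_ab = n * np.sum((ab - a_mean[:, None] - b_mean[None, :] + grand) ** 2)
    ss_as = b * np.sum((sa - s_mean[:, None] - a_mean[None, :] + grand) ** 2)
    ss_bs = a * np.sum((sb - s_mean[:, None] - b_mean[None, :] + grand) ** 2)
    resid = (
        y - sa[:, :, None] - sb[:, None, :] - ab[None, :, :]
        + s_mean[:, None, None] + a_mean[None, :, None] + b_mean[None, None, :]
        - grand
    )
    ss_abs = np.sum(resid**2)

    ca = _orthonormal_contrasts(a)
    cb = _orthonormal_contrasts(b)
    cab = np.kron(ca, cb)
    effects = [
        (fa, ss_a, a - 1, ss_as, (n - 1) * (a - 1), sa, ca),
        (fb, ss_b, b - 1, ss_bs, (n - 1) * (b - 1), sb, cb),
        (f"{fa} * {fb}", ss_ab, (a - 1) * (b - 1), ss_abs,
         (n - 1) * (a - 1) * (b - 1), y.reshape(n, a * b), cab),
    ]
    rows = []
    for name, ss_eff, df1, ss_err, df2, d, c in effects:
        ms_eff, ms_err = ss_eff / df1, ss_err / df2
        f_val = ms_eff / ms_err if ms_err > 0 else np.nan
        p = float(sps.f.sf(f_val, df1, df2)) if np.isfinite(f_val) else np.nan
        eps = _gg_epsilon(d, c) if df1 > 1 else 1.0
        p_gg = (
            float(sps.f.sf(f_val, df1 * eps, df2 * eps))
            if np.isfinite(f_val) else np.nan
        )
        w, p_m = _mauchly(d, c) if df1 > 1 else (1.0, np.nan)
        p_report = p_gg if (np.isfinite(p_m) and p_m < 0.05) else p
        rows.append({
            "Source": name, "SS": ss_eff, "SS_error": ss_err, "df1": df1,
            "df2": df2, "F": f_val, "p": p, "eps_gg": eps, "p_gg": p_gg,
            "mauchly_W": w, "mauchly_p": p_m, "p_report": p_report,
            "partial_eta_sq": ss_eff / (ss_eff + ss_err) if ss_eff + ss_err > 0 else np.nan,
        })
    return pd.DataFrame(rows)


def between_anova(
    data: pd.DataFrame,
    dv: str,
    between: tuple[str, str],
) -> pd.DataFrame:
    """Two-way fixed-effects (between-subjects) ANOVA with interaction.

    Delegates the fit to statsmodels OLS + anova_lm (type II); raises on any
    empty factor-combination cell.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    fa, fb = between
    cells = data.groupby([fa, fb])[dv].count()
    full = pd.MultiIndex.from_product(
        [data[fa].unique(), data[fb].unique()], names=[fa, fb]
    )
    cells = cells.reindex(full, fill_value=0)
    if (cells == 0).any():
        empty = cells[cells == 0].index.tolist()
        raise ValueError(f"empty design cells: {empty}")
    df = data.rename(columns={dv: "_y", fa: "_a", fb: "_b"})
    model = smf.ols("_y ~ C(_a) * C(_b)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    ss_res = float(table.loc["Residual", "sum_sq"])
    rows = []
    names = {"C(_a)": fa, "C(_b)": fb, "C(_a):C(_b)": f"{fa} * {fb}"}
    for key, name in names.items():
        ss = float(table.loc[key, "sum_sq"])
        rows.append({
            "Source": name, "SS": ss, "df1": float(table.loc[key, "df"]),
            "df2": float(table.loc["Residual", "df"]),
            "F": float(table.loc[key, "F"]), "p": float(table.loc[key, "PR(>F)"]),
            "partial_eta_sq": ss / (ss + ss_res) if ss + ss_res > 0 else np.nan,
        })
    return pd.DataFrame(rows)


def sidak_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Sidak multiple-comparison adjustment: p_adj = 1 - (1 - p)^m."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if m is None else int(m)
    return np.clip(1.0 - (1.0 - p) ** m, 0.0, 1.0)


def paired_t(x, y, two_sided: bool = True) -> dict:
    """Classical paired t-test on the differences x - y."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-d arrays, n >= 2")
    d = x - y
    if d.std(ddof=1) == 0.0:
        if d.mean() == 0.0:           # identical samples: define t = 0, p = 1
            return {"t": 0.0, "df": len(x) - 1, "p": 1.0}
        raise ValueError("zero variance of differences")
    res = sps.ttest_rel(x, y, alternative="two-sided" if two_sided else "greater")
    return {"t": float(res.statistic), "df": len(x) - 1, "p": float(res.pvalue)}


# ---------------------------------------------------------------------------
# rank correlations
# ---------------------------------------------------------------------------

def _midranks(x) -> np.ndarray:
    return sps.rankdata(np.asarray(x, float), method="average")


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt(np.sum(a**2) * np.sum(b**2))
    if denom == 0:
        raise ValueError("constant input")
    return float(np.sum(a * b) / denom)


def _t_approx_p(rho: float, n: int, dof: int | None = None) -> float:
    dof = n - 2 if dof is None else dof
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt(dof / (1.0 - rho**2))
    return float(2.0 * sps.t.sf(abs(t), dof))


def _exact_perm_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Exact permutation p for Spearman's rho (all n! pairings of the ranks)."""
    n = len(rx)
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]                                # (n!, n)
    rx_c = rx - rx.mean()
    ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt(np.sum(rx_c**2) * np.sum(ry_c**2, axis=1))
    rhos = (ry_c @ rx_c) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman(x, y, exact_below_n: int = 10) -> dict:
    """Spearman rank correlation with midrank ties and a strength label.

    p-value: two-sided t approximation for n >= ``exact_below_n``; exact
    permutation distribution for smaller samples.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or len(x) < 4:
        raise ValueError("need paired samples with n >= 4")
    rx, ry = _midranks(x), _midranks(y)
    rho = _pearson(rx, ry)
    if len(x) < exact_below_n:
        p = _exact_perm_p(rx, ry, rho)
    else:
        p = _t_approx_p(rho, len(x))
    return {"rho": rho, "p": p, "n": len(x), "label": correlation_label(rho)}


def partial_spearman(x, y, control) -> dict:
    """First-order partial Spearman correlation of x and y given a control.

    All three variables are midrank-transformed, then
    rho_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2));
    p from the t approximation with n - 3 degrees of freedom.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(control, float)
    if not (x.shape == y.shape == z.shape) or len(x) < 5:
        raise ValueError("need complete triples with n >= 5")
    rx, ry, rz = _midranks(x), _midranks(y), _midranks(z)
    r_xy, r_xz, r_yz = _pearson(rx, ry), _pearson(rx, rz), _pearson(ry, rz)
    if abs(r_xz) >= 1.0 - 1e-12 or abs(r_yz) >= 1.0 - 1e-12:
        raise ValueError("control is rank-degenerate with x or y")
    rho = (r_xy - r_xz * r_yz) / math.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2))
    p = _t_approx_p(rho, len(x), dof=len(x) - 3)
    return {"rho": rho, "p": p, "n": len(x), "label": correlation_label(rho)}


# ---------------------------------------------------------------------------
# correlation matrices (neural markers x drinking metrics)
# ---------------------------------------------------------------------------

def average_channels(table: pd.DataFrame, value: str, subject: str = "subject",
                     by: tuple[str, ...] = ()) -> pd.DataFrame:
    """Mean of a per-(subject, channel) measure over channels."""
    keys = [subject, *by]
    return table.groupby(keys, as_index=False)[value].mean()


def correlation_matrix(
    markers: pd.DataFrame,
    drinking: pd.DataFrame,
    control: pd.DataFrame | None = None,
    adjust: str = "per_metric",
) -> pd.DataFrame:
    """Correlate every neural-marker column with every drinking-metric column.

    ``markers``/``drinking``/``control`` are subject-indexed wide tables
    (aligned on index). Plain Spearman without a control table; partial
    Spearman given one (``control`` must share the marker columns). Sidak
    adjustment is applied per drinking-metric family (``per_metric``),
    globally, or not at all.
    """
    common = markers.index.intersection(drinking.index)
    rows = []
    for metric in drinking.columns:
        for marker in markers.columns:
            x = markers.loc[common, marker]
            yv = drinking.loc[common, metric]
            if control is not None:
                res = partial_spearman(x, yv, control.loc[common, marker])
            else:
                res = spearman(x, yv)
            rows.append({"marker": marker, "metric": metric, **res})
    out = pd.DataFrame(rows)
    if adjust == "per_metric":
        out["p_adj"] = out.groupby("metric")["p"].transform(
            lambda p: sidak_adjust(p.to_numpy())
        )
    elif adjust == "global":
        out["p_adj"] = sidak_adjust(out["p"].to_numpy())
    elif adjust == "none":
        out["p_adj"] = out["p"]
    else:
        raise ValueError(f"unknown adjust scope {adjust!r}")
    return out
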