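"""The study's statistical battery over tidy measurement tables.

Within-group threshold trajectories are compared with the Friedman test
(tie-corrected) followed by Bonferroni-adjusted pairwise post hocs; group
pairs at a fixed timepoint with the Mann-Whitney U test (exact by full
split enumeration at the small group sizes used here); per-condition
morphometry/densitometry with one-way ANOVA followed by Bonferroni or
Games-Howell post hocs; group-by-frequency structure with two-way ANOVA
(Type II sums of squares for unbalanced data); and the size-OD relationship
with Pearson and Spearman coefficients, in the layout of the study's
correlation table.

The Friedman post hoc deserves a note.  "Friedman followed by Bonferroni"
does not name a pairwise test; with n = 3-6 subjects the exact Wilcoxon
signed-rank test cannot produce p below 2/2**n, so a Wilcoxon-based post hoc
can never be significant after Bonferroni at these sizes.  SPSS's
related-samples procedure instead compares Friedman *rank means* pairwise
with a normal approximation (a Dunn-type test), which is what ``dunn``
(the default) implements; ``wilcoxon`` is available for larger designs.
All tests are two-sided at alpha = 0.05.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "friedman_statistic",
    "friedman_with_posthoc",
    "mann_whitney",
    "anova_oneway_posthoc",
    "anova_twoway",
    "correlation_table",
]

ALPHA = 0.05


@dataclass(frozen=True)
class StatResult:
    """Uniform container for a test outcome plus optional post hoc table."""

    test: str
    statistic: float
    df: tuple | float | None
    p_value: float
    posthoc: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


# --------------------------------------------------------------------------
# Friedman
# --------------------------------------------------------------------------


def friedman_statistic(data: np.ndarray) -> tuple[float, int, float]:
    """Tie-corrected Friedman chi-square on a (subjects x treatments) array.

    Uses midranks within each subject and the general tie-corrected form
    chi2 = (k-1) * sum_j (R_j - n(k+1)/2)^2 / (sum_ij r_ij^2 - n k (k+1)^2 / 4).
    Returns (statistic, df, p).  All-tied data give statistic 0, p 1.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 treatments")
    n, k = data.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, data)
    rj = ranks.sum(axis=0)
    denom = (ranks**2).sum() - n * k * (k + 1) ** 2 / 4.0
    if denom <= 0:  # every subject fully tied
        return 0.0, k - 1, 1.0
    stat = (k - 1) * ((rj - n * (k + 1) / 2.0) ** 2).sum() / denom
    return float(stat), k - 1, float(sps.chi2.sf(stat, k - 1))


def friedman_with_posthoc(
    table: pd.DataFrame,
    subject: str = "animal",
    within: str = "timepoint_day",
    value: str = "value",
    method: str = "dunn",
    comparisons: str = "baseline",
    baseline=None,
) -> StatResult:
    """Friedman over complete blocks with Bonferroni-adjusted post hocs.

    ``comparisons="baseline"`` compares every treatment against the baseline
    level (the lowest, or ``baseline``), mirroring timepoint-vs-day-0
    contrasts; ``"all"`` runs every pair.  Blocks must be complete; missing
    cells are reported by name.
    """
    wide = table.pivot(index=subject, columns=within, values=value)
    if wide.isna().any().any():
        missing = [
            (s, c) for s, row in wide.iterrows() for c in wide.columns if pd.isna(row[c])
        ]
        raise ValueError(f"incomplete blocks; missing cells: {missing[:10]}")
    data = wide.to_numpy()
    n, k = data.shape
    stat, df, p = friedman_statistic(data)

    levels = list(wide.columns)
    if comparisons == "all":
        pairs = list(itertools.combinations(levels, 2))
    elif comparisons == "baseline":
        base = levels[0] if baseline is None else baseline
        if base not in levels:
            raise ValueError(f"baseline level {base!r} not present")
        pairs = [(base, l) for l in levels if l != base]
    else:
        raise ValueError("comparisons must be 'baseline' or 'all'")

    ranks = np.apply_along_axis(sps.rankdata, 1, data)
    mean_ranks = dict(zip(levels, ranks.mean(axis=0)))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        if method == "dunn":
            se = np.sqrt(k * (k + 1) / (6.0 * n))
            z = (mean_ranks[b] - mean_ranks[a]) / se
            raw = 2.0 * sps.norm.sf(abs(z))
            statistic = z
        elif method == "wilcoxon":
            xa, xb = wide[a].to_numpy(), wide[b].to_numpy()
            if np.all(xa == xb):
                statistic, raw = 0.0, 1.0
            else:
                res = sps.wilcoxon(xa, xb)
                statistic, raw = float(res.statistic), float(res.pvalue)
        else:
            raise ValueError("method must be 'dunn' or 'wilcoxon'")
        rows.append(
            {
                "level_a": a,
                "level_b": b,
                "statistic": float(statistic),
                "p_raw": float(raw),
                "p_adj": float(min(1.0, raw * m)),
            }
        )
    return StatResult(
        test="friedman",
        statistic=stat,
        df=df,
        p_value=p,
        posthoc=pd.DataFrame(rows),
        extras={"n_subjects": n, "k": k, "posthoc_method": method},
    )


# --------------------------------------------------------------------------
# Mann-Whitney
# --------------------------------------------------------------------------


@lru_cache(maxsize=32)
def _split_indices(n_total: int, n_a: int) -> np.ndarray:
    """All C(n_total, n_a) index subsets, as a (combos, n_a) int array."""
    return np.array(list(itertools.combinations(range(n_total), n_a)), dtype=np.intp)


def mann_whitney(a, b, mode: str = "auto") -> StatResult:
    """Mann-Whitney U with exact two-sided p for small samples.

    ``exact`` enumerates all splits of the pooled midranks (conditional on
    ties), feasible for n_a + n_b <= 12 — the group sizes of this design.
    Two-sided p = min(1, 2 * min(P(U <= u), P(U >= u))).  ``normal`` uses
    the tie-corrected asymptotic approximation.  ``auto`` picks exact when
    feasible.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_a = ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0
    if mode == "auto":
        mode = "exact" if n_a + n_b <= 12 else "normal"
    if mode == "exact":
        combos = _split_indices(n_a + n_b, n_a)
        u_all = ranks[combos].sum(axis=1) - n_a * (n_a + 1) / 2.0
        tol = 1e-9
        p_le = np.mean(u_all <= u_a + tol)
        p_ge = np.mean(u_all >= u_a - tol)
        p = min(1.0, 2.0 * min(p_le, p_ge))
    elif mode == "normal":
        p = float(
            sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        )
    else:
        raise ValueError("mode must be 'auto', 'exact' or 'normal'")
    return StatResult(
        test="mann_whitney",
        statistic=float(u_a),
        df=(n_a, n_b),
        p_value=float(p),
        extras={"mode": mode},
    )


# --------------------------------------------------------------------------
# One-way ANOVA with Bonferroni / Games-Howell post hocs
# --------------------------------------------------------------------------


def _oneway_f(groups: dict) -> tuple[float, tuple, float, float]:
    """F, (df1, df2), p, MSE from standard sums of squares."""
    ks = list(groups)
    if len(ks) < 2 or any(len(groups[k]) < 2 for k in ks):
        raise ValueError("need >= 2 groups with >= 2 values each")
    all_v = np.concatenate([np.asarray(groups[k], dtype=float) for k in ks])
    gm = all_v.mean()
    ssb = sum(len(groups[k]) * (np.mean(groups[k]) - gm) ** 2 for k in ks)
    ssw = sum(((np.asarray(groups[k], dtype=float) - np.mean(groups[k])) ** 2).sum() for k in ks)
    df1 = len(ks) - 1
    df2 = all_v.size - len(ks)
    if ssw == 0:
        if ssb == 0:
            return 0.0, (df1, df2), 1.0, 0.0
        return float("inf"), (df1, df2), 0.0, 0.0
    mse = ssw / df2
    f = (ssb / df1) / mse
    return float(f), (df1, df2), float(sps.f.sf(f, df1, df2)), float(mse)


def anova_oneway_posthoc(groups: dict, posthoc: str = "games_howell") -> StatResult:
    """One-way ANOVA over ``{group: values}`` with a pairwise post hoc.

    ``bonferroni``: pooled-variance pairwise t tests on the ANOVA MSE with
    Bonferroni-adjusted p.  ``games_howell``: Welch-df pairwise comparisons
    against the studentized-range distribution, robust to unequal variances.
    A zero within-group variance everywhere with unequal means yields an
    infinite F, flagged in ``extras``.
    """
    f, dfs, p, mse = _oneway_f(groups)
    ks = list(groups)
    k = len(ks)
    stats_by = {
        g: (np.mean(groups[g]), np.var(groups[g], ddof=1), len(groups[g])) for g in ks
    }
    rows = []
    pairs = list(itertools.combinations(ks, 2))
    for ga, gb in pairs:
        ma, va, na = stats_by[ga]
        mb, vb, nb = stats_by[gb]
        diff = mb - ma
        if posthoc == "bonferroni":
            if mse == 0:
                raw = 1.0 if diff == 0 else 0.0
                t = 0.0 if diff == 0 else float("inf")
            else:
                se = np.sqrt(mse * (1.0 / na + 1.0 / nb))
                t = diff / se
                raw = 2.0 * sps.t.sf(abs(t), dfs[1])
            rows.append(
                {
                    "group_a": ga,
                    "group_b": gb,
                    "diff": float(diff),
                    "statistic": float(t),
                    "p_raw": float(raw),
                    "p_adj": float(min(1.0, raw * len(pairs))),
                }
            )
        elif posthoc == "games_howell":
            se2 = va / na + vb / nb
            if se2 == 0:
                q, adj, df_w = (0.0, 1.0, na + nb - 2) if diff == 0 else (float("inf"), 0.0, na + nb - 2)
            else:
                q = abs(diff) / np.sqrt(se2) * np.sqrt(2.0)
                df_w = se2**2 / (
                    (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
                )
                adj = float(sps.studentized_range.sf(q, k, df_w))
            rows.append(
                {
                    "group_a": ga,
                    "group_b": gb,
                    "diff": float(diff),
                    "statistic": float(q),
                    "df": float(df_w),
                    "p_adj": float(adj),
                }
            )
        else:
            raise ValueError("posthoc must be 'bonferroni' or 'games_howell'")
    return StatResult(
        test="anova_oneway",
        statistic=f,
        df=dfs,
        p_value=p,
        posthoc=pd.DataFrame(rows),
        extras={"mse": mse, "posthoc": posthoc, "degenerate": not np.isfinite(f)},
    )


# --------------------------------------------------------------------------
# Two-way ANOVA
# --------------------------------------------------------------------------


def anova_twoway(
    df: pd.DataFrame,
    value: str,
    factor_a: str,
    factor_b: str,
    ss_type: int = 2,
) -> StatResult:
    """Two-way fixed-effects ANOVA (main effects + interaction).

    Type II sums of squares by default, appropriate for unbalanced data
    when the interaction is not the emphasis.  Empty factor cells are an
    error, listed by name.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    counts = df.groupby([factor_a, factor_b], observed=True)[value].count()
    la = df[factor_a].unique()
    lb = df[factor_b].unique()
    if len(la) < 2 or len(lb) < 2:
        raise ValueError("each factor needs at least two levels")
    empty = [
        (a, b) for a in la for b in lb if (a, b) not in counts.index or counts[(a, b)] == 0
    ]
    if empty:
        raise ValueError(f"empty design cells: {empty}")
    d = df.rename(columns={value: "_y", factor_a: "_fa", factor_b: "_fb"})
    model = smf.ols("_y ~ C(_fa) * C(_fb)", data=d).fit()
    tab = sm.stats.anova_lm(model, typ=ss_type)
    f_a = float(tab.loc["C(_fa)", "F"])
    p_a = float(tab.loc["C(_fa)", "PR(>F)"])
    tab = tab.rename(
        index={
            "C(_fa)": factor_a,
            "C(_fb)": factor_b,
            "C(_fa):C(_fb)": f"{factor_a}:{factor_b}",
        }
    )
    return StatResult(
        test="anova_twoway",
        statistic=f_a,
        df=(float(tab.loc[factor_a, "df"]), float(tab.loc["Residual", "df"])),
        p_value=p_a,
        posthoc=None,
        extras={
            "table": tab,
            "p_values": {
                factor_a: p_a,
                factor_b: float(tab.loc[factor_b, "PR(>F)"]),
                "interaction": float(tab.loc[f"{factor_a}:{factor_b}", "PR(>F)"]),
            },
        },
    )


# --------------------------------------------------------------------------
# Correlation table
# --------------------------------------------------------------------------


def correlation_table(
    df: pd.DataFrame,
    group_col: str = "condition",
    area_col: str = "area_um2",
    od_col: str = "norm_od",
) -> pd.DataFrame:
    """Per-group size-OD correlation summary in the published table's layout.

    Reports the per-group n, mean/SD of normalised OD and of area, both the
    Pearson and Spearman coefficients with p-values, and a ``coefficient``
    column selected by a Shapiro normality screen of both variables at 0.05
    (Pearson when neither rejects, Spearman otherwise).  Zero variance in
    either variable flags the row rather than emitting a coefficient.
    """
    rows = []
    for g, sub in df.groupby(group_col, sort=False):
        x = sub[area_col].to_numpy(dtype=float)
        y = sub[od_col].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if x.size < 3:
            raise ValueError(f"group {g!r} has fewer than 3 complete pairs")
        row = {
            "group": g,
            "n": int(x.size),
            "mean_od": float(np.mean(y)),
            "sd_od": float(np.std(y, ddof=1)),
            "mean_area": float(np.mean(x)),
            "sd_area": float(np.std(x, ddof=1)),
        }
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            row.update(
                pearson_r=np.nan, pearson_p=np.nan, spearman_rho=np.nan,
                spearman_p=np.nan, coefficient=np.nan, coefficient_kind="undefined",
                degenerate=True,
            )
        else:
            pr = sps.pearsonr(x, y)
            sr = sps.spearmanr(x, y)
            normal = (
                x.size >= 3
                and sps.shapiro(x).pvalue > ALPHA
                and sps.shapiro(y).pvalue > ALPHA
            )
            kind = "pearson" if normal else "spearman"
            row.update(
                pearson_r=float(pr.statistic),
                pearson_p=float(pr.pvalue),
                spearman_rho=float(sr.statistic),
                spearman_p=float(sr.pvalue),
                coefficient=float(pr.statistic if kind == "pearson" else sr.statistic),
                coefficient_kind=kind,
                degenerate=False,
            )
        rows.append(row)
    return pd.DataFrame(rows)
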