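"""Repeated-measures statistics for sweep-based unit data.

Implements the battery used to compare firing rates across behavioural states
and photoinactivation conditions: two-factor repeated-measures ANOVA (both
factors within-subject, or with the condition factor between subjects),
Bonferroni correction by multiplication, robust outlier removal (ROUT with
FDR level Q), t tests, and the linear-trend contrast for ordered groups.

The within-subject "subjects" are units: every unit contributes one rate per
design cell (e.g. spontaneous/evoked × control/photoinactivation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class AnovaResult:
    """Effect table plus Bonferroni-corrected post-hoc comparisons."""

    table: pd.DataFrame  # effect, SS, df1, df2, F, p
    posthoc: pd.DataFrame = field(default_factory=pd.DataFrame)
    design: str = "both_within"

    def p_value(self, effect: str) -> float:
        row = self.table[self.table["effect"] == effect]
        if row.empty:
            raise KeyError(effect)
        return float(row["p"].iloc[0])


def _pivot_complete(
    data: pd.DataFrame, subject: str, row: str, col: str, value: str
) -> tuple[np.ndarray, list, list, list]:
    wide = data.pivot_table(index=subject, columns=[row, col], values=value, aggfunc="mean")
    if wide.isna().any().any():
        raise ValueError("incomplete design: every subject needs every cell")
    subjects = list(wide.index)
    rows = sorted(data[row].unique())
    cols = sorted(data[col].unique())
    y = np.empty((len(subjects), len(rows), len(cols)))
    for i, a in enumerate(rows):
        for j, b in enumerate(cols):
            y[:, i, j] = wide[(a, b)].to_numpy()
    return y, subjects, rows, cols


def two_way_rm_anova(
    data: pd.DataFrame,
    subject: str = "subject",
    row: str = "row",
    col: str = "col",
    value: str = "value",
    design: str = "both_within",
    posthoc_m: int | None = None,
) -> AnovaResult:
    """Two-factor ANOVA with repeated measures.

    ``design="both_within"`` treats both factors as within-subject: each
    effect is tested against its own effect-by-subject interaction.
    ``design="mixed"`` treats the column factor as between-subjects (subjects
    nested in column groups).  Post-hoc: paired (or unpaired, for mixed)
    t tests between column levels within each row level, Bonferroni-corrected
    by the number of comparisons.

    No sphericity correction is applied: with two levels per within factor —
    the designs this package produces — sphericity holds trivially.
    """
    if design == "both_within":
        result = _anova_both_within(data, subject, row, col, value)
    elif design == "mixed":
        result = _anova_mixed(data, subject, row, col, value)
    else:
        raise ValueError("design must be 'both_within' or 'mixed'")
    result.posthoc = _posthoc_by_row(data, subject, row, col, value, design, posthoc_m)
    return result


def _anova_both_within(data, subject, row, col, value) -> AnovaResult:
    y, subjects, rows, cols = _pivot_complete(data, subject, row, col, value)
    n, a, b = y.shape
    if n < 2:
        raise ValueError("need at least two subjects")
    g = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_ab = y.mean(axis=0)
    m_as = y.mean(axis=2)
    m_bs = y.mean(axis=1)

    ss_total = float(((y - g) ** 2).sum())
    ss_s = a * b * float(((m_s - g) ** 2).sum())
    ss_a = n * b * float(((m_a - g) ** 2).sum())
    ss_b = n * a * float(((m_b - g) ** 2).sum())
    ss_ab = n * float(((m_ab - m_a[:, None] - m_b[None, :] + g) ** 2).sum())
    ss_as = b * float(((m_as - m_a[None, :] - m_s[:, None] + g) ** 2).sum())
    ss_bs = a * float(((m_bs - m_b[None, :] - m_s[:, None] + g) ** 2).sum())
    ss_abs = ss_total - (ss_s + ss_a + ss_b + ss_ab + ss_as + ss_bs)

    def f_row(name, ss, df1, ss_err, df2):
        ms, ms_e = ss / df1, ss_err / df2
        f = ms / ms_e if ms_e > 0 else (0.0 if ms == 0 else np.inf)
        p = float(sps.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
        if ms_e == 0 and ms == 0:
            p = 1.0
        return {"effect": name, "SS": ss, "df1": df1, "df2": df2, "F": f, "p": p}

    table = pd.DataFrame(
        [
            f_row("row", ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
            f_row("col", ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
            f_row("interaction", ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1)),
            {
                "effect": "subject",
                "SS": ss_s,
                "df1": n - 1,
                "df2": np.nan,
                "F": np.nan,
                "p": np.nan,
            },
            {
                "effect": "total",
                "SS": ss_total,
                "df1": n * a * b - 1,
                "df2": np.nan,
                "F": np.nan,
                "p": np.nan,
            },
        ]
    )
    return AnovaResult(table=table, design="both_within")


def _anova_mixed(data, subject, row, col, value) -> AnovaResult:
    # column factor between subjects: subjects nested in column groups
    wide = data.pivot_table(index=[subject, col], columns=row, values=value, aggfunc="mean")
    if wide.isna().any().any():
        raise ValueError("incomplete design: every subject needs every row level")
    rows = list(wide.columns)
    a = len(rows)
    y = wide.to_numpy()  # (subjects, row levels)
    groups = wide.index.get_level_values(1).to_numpy()
    cols = sorted(pd.unique(groups))
    n_total = y.shape[0]
    if n_total < 2 or len(cols) < 2:
        raise ValueError("need >=2 subjects and >=2 column groups")

    g = y.mean()
    m_s = y.mean(axis=1)
    m_a = y.mean(axis=0)
    ss_total = float(((y - g) ** 2).sum())
    ss_between_subj = a * float(((m_s - g) ** 2).sum())
    ss_b = 0.0
    ss_ab = 0.0
    for blev in cols:
        sel = groups == blev
        nb = int(sel.sum())
        mb = y[sel].mean()
        ss_b += a * nb * (mb - g) ** 2
        mab = y[sel].mean(axis=0)
        ss_ab += nb * float(((mab - m_a - mb + g) ** 2).sum())
    ss_sb = ss_between_subj - ss_b
    ss_a = n_total * float(((m_a - g) ** 2).sum())
    ss_within = ss_total - ss_between_subj
    ss_as_b = ss_within - ss_a - ss_ab

    b = len(cols)
    df_b, df_sb = b - 1, n_total - b
    df_a = a - 1
    df_err = (n_total - b) * (a - 1)

    def f_row(name, ss, df1, ss_err, df2):
        ms, ms_e = ss / df1, ss_err / df2
        f = ms / ms_e if ms_e > 0 else (0.0 if ms == 0 else np.inf)
        p = float(sps.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
        if ms_e == 0 and ms == 0:
            p = 1.0
        return {"effect": name, "SS": ss, "df1": df1, "df2": df2, "F": f, "p": p}

    table = pd.DataFrame(
        [
            f_row("row", ss_a, df_a, ss_as_b, df_err),
            f_row("col", ss_b, df_b, ss_sb, df_sb),
            f_row("interaction", ss_ab, df_a * df_b, ss_as_b, df_err),
            {
                "effect": "subject",
                "SS": ss_sb,
                "df1": df_sb,
                "df2": np.nan,
                "F": np.nan,
                "p": np.nan,
            },
            {
                "effect": "total",
                "SS": ss_total,
                "df1": y.size - 1,
                "df2": np.nan,
                "F": np.nan,
                "p": np.nan,
            },
        ]
    )
    return AnovaResult(table=table, design="mixed")


def _posthoc_by_row(data, subject, row, col, value, design, m) -> pd.DataFrame:
    rows = sorted(data[row].unique())
    cols = sorted(data[col].unique())
    if len(cols) != 2:
        return pd.DataFrame()
    m = m if m is not None else len(rows)
    out = []
    for a in rows:
        sub = data[data[row] == a]
        piv = sub.pivot_table(index=subject, columns=col, values=value, aggfunc="mean")
        x = piv[cols[0]].dropna().to_numpy()
        y = piv[cols[1]].dropna().to_numpy()
        mode = "paired" if design == "both_within" else "unpaired"
        res = t_tests(x, y, mode=mode)
        out.append(
            {
                "row_level": a,
                "comparison": f"{cols[0]} vs {cols[1]}",
                "t": res["t"],
                "df": res["df"],
                "p": res["p"],
                "p_bonferroni": bonferroni_adjust([res["p"]], m)[0],
            }
        )
    return pd.DataFrame(out)


def bonferroni_adjust(p_values, m: int) -> list[float]:
    """Multiply each p by the number of comparisons, capping at 1."""
    if m < 1:
        raise ValueError("m must be >= 1")
    out = []
    for p in p_values:
        if not (0.0 <= p <= 1.0):
            raise ValueError("p-values must lie in [0, 1]")
        out.append(min(1.0, p * m))
    return out


def rout_outliers(values, q_percent: float = 1.0) -> np.ndarray:
    """Robust outlier flagging for a single sample (ROUT-style, FDR level Q).

    The location is the sample median; the robust scale (RSDR) is the 68.27th
    percentile of absolute residuals with a small-sample correction
    sqrt(n/(n-1)).  Each point gets a two-sided p-value from a t distribution
    on its standardized residual, and points are flagged by a
    Benjamini–Hochberg sweep at rate Q.  Flags are invariant to affine
    rescaling of the data.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least three values")
    if not (0.0 < q_percent < 100.0):
        raise ValueError("Q must be a percentage in (0, 100)")
    resid = x - np.median(x)
    rsdr = np.percentile(np.abs(resid), 68.27) * np.sqrt(n / (n - 1))
    mask = np.zeros(n, dtype=bool)
    if rsdr == 0.0:
        mask[resid != 0] = True  # any deviation from an otherwise constant sample
        return mask
    t = np.abs(resid) / rsdr
    p = 2.0 * sps.t.sf(t, df=n - 1)
    order = np.argsort(p)
    q = q_percent / 100.0
    k_flag = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= q * rank / n:
            k_flag = rank
    mask[order[:k_flag]] = True
    return mask


def t_tests(x, y=None, mode: str = "one_sample", popmean: float = 0.0) -> dict:
    """t statistics with a fixed no-difference convention for degenerate data.

    Modes: ``paired``, ``unpaired`` (Student, equal variances), and
    ``one_sample`` against ``popmean``.  When the relevant variance is zero
    and the means coincide, the result is reported as t = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    if mode == "one_sample":
        d = x - popmean
        df = x.size - 1
        if np.allclose(d.std(ddof=0), 0.0):
            if np.allclose(d.mean(), 0.0):
                return {"t": 0.0, "df": df, "p": 1.0}
            return {"t": np.inf * np.sign(d.mean()), "df": df, "p": 0.0}
        r = sps.ttest_1samp(x, popmean)
        return {"t": float(r.statistic), "df": df, "p": float(r.pvalue)}
    y = np.asarray(y, dtype=float)
    if mode == "paired":
        if x.size != y.size:
            raise ValueError("paired samples must have equal length")
        return t_tests(x - y, mode="one_sample", popmean=0.0)
    if mode == "unpaired":
        df = x.size + y.size - 2
        pooled = np.concatenate([x - x.mean(), y - y.mean()])
        if np.allclose(pooled.std(ddof=0), 0.0):
            if np.allclose(x.mean(), y.mean()):
                return {"t": 0.0, "df": df, "p": 1.0}
            return {"t": np.inf * np.sign(x.mean() - y.mean()), "df": df, "p": 0.0}
        r = sps.ttest_ind(x, y, equal_var=True)
        return {"t": float(r.statistic), "df": df, "p": float(r.pvalue)}
    raise ValueError("mode must be 'paired', 'unpaired' or 'one_sample'")


def linear_trend_contrast(groups: list) -> dict:
    """Linear-trend contrast across ordered groups in a one-way layout.

    Uses evenly spaced centered coefficients on the group means, tested
    against the pooled within-group mean square.  Returns the signed t, the
    equivalent F = t², degrees of freedom and the two-sided p.
    """
    if len(groups) < 3:
        raise ValueError("need at least three ordered groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrs)
    ns = np.array([a.size for a in arrs])
    if np.any(ns < 2):
        raise ValueError("each group needs at least two observations")
    means = np.array([a.mean() for a in arrs])
    coef = np.arange(k, dtype=float) - (k - 1) / 2.0
    L = float((coef * means).sum())
    ss_contrast = L**2 / float((coef**2 / ns).sum())
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrs))
    df2 = int(ns.sum() - k)
    ms_within = ss_within / df2
    if ms_within == 0.0:
        if L == 0.0:
            return {"t": 0.0, "F": 0.0, "df1": 1, "df2": df2, "p": 1.0}
        return {"t": np.inf * np.sign(L), "F": np.inf, "df1": 1, "df2": df2, "p": 0.0}
    f = ss_contrast / ms_within
    t = float(np.sign(L) * np.sqrt(f))
    return {"t": t, "F": float(f), "df1": 1, "df2": df2, "p": float(sps.f.sf(f, 1, df2))}
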