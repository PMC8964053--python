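"""Group statistics for microstate cohort tables.

Implements the statistical layer of a two-group resting-state microstate
comparison: Pearson chi-square for sex distribution, pooled two-sample
t-tests for continuous demographics, a mixed repeated-measures ANOVA
(within factors: parameter x class; between factor: group) with the
Greenhouse-Geisser sphericity correction, post-hoc two-group univariate
ANOVAs with partial eta squared, and Pearson correlations between metrics
and symptom subscores.

The rm-ANOVA follows the classical univariate mixed-model approach: each
within-subject effect is tested on orthonormal contrast scores of the
per-subject cell vector, with the Greenhouse-Geisser epsilon estimated from
the pooled within-group covariance of those contrast scores and applied as
a multiplicative degrees-of-freedom correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "chi_square_2x2",
    "two_sample_t",
    "rm_anova_mixed",
    "posthoc_univariate",
    "pearson_correlation",
    "run_statistics",
    "RmAnovaResult",
    "UnivariateResult",
    "CorrelationResult",
    "PARAMETERS",
]

PARAMETERS = ("duration", "contribution", "occurrence")


# --------------------------------------------------------------------------
# demographics
# --------------------------------------------------------------------------

def chi_square_2x2(
    counts, correction: str = "none"
) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 contingency table.

    ``correction="yates"`` applies the continuity correction.  Returns
    (statistic, two-sided p from the chi-square(1) tail).
    """
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(table < 0) or np.any(table != np.round(table)):
        raise ValueError("counts must be non-negative integers")
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero margin: chi-square undefined")
    expected = np.outer(row, col) / table.sum()
    diff = np.abs(table - expected)
    if correction == "yates":
        diff = np.maximum(diff - 0.5, 0.0)
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")
    stat = float(np.sum(diff**2 / expected))
    return stat, float(sstats.chi2.sf(stat, df=1))


def two_sample_t(
    group1,
    group2,
    variance: str = "pooled",
) -> tuple[float, float, float]:
    """Two-sample t-test from raw vectors or (mean, sd, n) summaries.

    Returns (t, df, two-tailed p).  ``variance="pooled"`` is the classical
    Student test; ``"welch"`` drops the equal-variance assumption.
    """
    def summarize(g):
        if isinstance(g, (tuple, list)) and len(g) == 3 and np.isscalar(g[0]):
            m, sd, n = g
        else:
            arr = np.asarray(g, dtype=float)
            if arr.size < 2:
                raise ValueError("need n >= 2 per group")
            m, sd, n = arr.mean(), arr.std(ddof=1), arr.size
        if n < 2:
            raise ValueError("need n >= 2 per group")
        return float(m), float(sd), int(n)

    m1, s1, n1 = summarize(group1)
    m2, s2, n2 = summarize(group2)
    if s1 == 0 and s2 == 0:
        if m1 == m2:
            return 0.0, float(n1 + n2 - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    equal_var = {"pooled": True, "welch": False}.get(variance)
    if equal_var is None:
        raise ValueError(f"unknown variance option {variance!r}")
    res = sstats.ttest_ind_from_stats(
        m1, s1, n1, m2, s2, n2, equal_var=equal_var
    )
    df = n1 + n2 - 2 if equal_var else _welch_df(s1, n1, s2, n2)
    return float(res.statistic), float(df), float(res.pvalue)


def _welch_df(s1: float, n1: int, s2: float, n2: int) -> float:
    a, b = s1**2 / n1, s2**2 / n2
    return (a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))


# --------------------------------------------------------------------------
# mixed repeated-measures ANOVA with Greenhouse-Geisser correction
# --------------------------------------------------------------------------

@dataclass
class RmAnovaResult:
    effect: str
    df1: float
    df2: float
    epsilon: float
    df1_corrected: float
    df2_corrected: float
    F: float
    p_uncorrected: float
    p: float  # Greenhouse-Geisser corrected (equals uncorrected when eps=1)

    def as_dict(self) -> dict:
        return {
            "effect": self.effect,
            "df1": self.df1,
            "df2": self.df2,
            "epsilon": self.epsilon,
            "df1_gg": self.df1_corrected,
            "df2_gg": self.df2_corrected,
            "F": self.F,
            "p_uncorrected": self.p_uncorrected,
            "p_gg": self.p,
        }


def _orthonormal_contrasts(q: int) -> np.ndarray:
    """(q-1) x q orthonormal rows orthogonal to the unit vector (Helmert)."""
    h = np.zeros((q - 1, q))
    for i in range(1, q):
        h[i - 1, :i] = 1.0
        h[i - 1, i] = -i
        h[i - 1] /= np.linalg.norm(h[i - 1])
    return h


def _gg_epsilon(z: np.ndarray, groups: np.ndarray) -> float:
    """Box/Greenhouse-Geisser epsilon from contrast scores z (n x p), using
    the within-group pooled covariance."""
    p = z.shape[1]
    if p == 1:
        return 1.0
    pooled = np.zeros((p, p))
    dof = 0
    for g in np.unique(groups):
        zg = z[groups == g]
        if len(zg) > 1:
            pooled += np.cov(zg, rowvar=False) * (len(zg) - 1)
            dof += len(zg) - 1
    pooled /= dof
    tr = np.trace(pooled)
    tr2 = np.trace(pooled @ pooled)
    eps = tr**2 / (p * tr2)
    return float(np.clip(eps, 1.0 / p, 1.0))


def _between_test(z: np.ndarray, groups: np.ndarray
                  ) -> tuple[float, float, float, float]:
    """Type-III intercept and group SS for contrast scores z (n x p) with a
    two-level (or g-level) between factor; returns
    (ss_effect, ss_interaction, ss_error, n_levels)."""
    levels = np.unique(groups)
    g = len(levels)
    means = np.stack([z[groups == lv].mean(axis=0) for lv in levels])
    ns = np.array([(groups == lv).sum() for lv in levels], dtype=float)
    # error: within-cell residual SS
    ss_err = 0.0
    for i, lv in enumerate(levels):
        resid = z[groups == lv] - means[i]
        ss_err += float(np.sum(resid**2))
    # Type-III intercept: unweighted grand mean of cell means; the Wald SS
    # is ||grand||^2 / [(1/g^2) sum_i 1/n_i]
    grand = means.mean(axis=0)
    ss_int = float(np.sum(grand**2) / (np.sum(1.0 / ns) / g**2))
    # Type-III group effect via effect-coded GLM (exact in unbalanced designs)
    ss_grp = _type3_group_ss(z, groups, levels)
    return ss_int, ss_grp, ss_err, g


def _type3_group_ss(z, groups, levels) -> float:
    """Type-III SS for the between factor via effect-coded OLS, summed over
    contrast columns."""
    g = len(levels)
    n = len(groups)
    x = np.ones((n, g))  # intercept + g-1 effect codes
    for j, lv in enumerate(levels[:-1]):
        x[:, j + 1] = np.where(
            groups == lv, 1.0, np.where(groups == levels[-1], -1.0, 0.0)
        )
    ss_full_resid = 0.0
    ss_red_resid = 0.0
    x_red = x[:, :1]
    for col in range(z.shape[1]):
        y = z[:, col]
        for design, acc in ((x, "full"), (x_red, "red")):
            beta, *_ = np.linalg.lstsq(design, y, rcond=None)
            resid = y - design @ beta
            if acc == "full":
                ss_full_resid += float(resid @ resid)
            else:
                ss_red_resid += float(resid @ resid)
    return ss_red_resid - ss_full_resid


def rm_anova_mixed(
    table: pd.DataFrame,
    within: tuple[str, ...] = ("parameter", "class"),
    between: str = "group",
    subject: str = "subject",
    value: str = "value",
    scale: str = "raw",
) -> list[RmAnovaResult]:
    """Mixed-design repeated-measures ANOVA on a long-format table.

    ``table`` holds one row per subject x within-cell with columns named by
    ``subject``, ``between``, the within factor(s) and ``value``.  Every
    subject must have a complete within-cell grid.  ``scale="zscore"``
    standardizes ``value`` within each level of the first within factor
    (useful when parameters carry different units).

    Returns results for the between main effect, every within main effect,
    every within x between interaction, and (with two within factors) the
    within-interaction and its three-way interaction with group.
    Greenhouse-Geisser correction is applied to all within effects.
    """
    df = table.copy()
    if scale == "zscore":
        first = within[0]
        df[value] = df.groupby(first)[value].transform(
            lambda v: (v - v.mean()) / v.std(ddof=1)
        )
    elif scale != "raw":
        raise ValueError(f"unknown scale {scale!r}")

    levels = {w: sorted(df[w].unique()) for w in within}
    cells = list(product(*(levels[w] for w in within)))
    subjects = df[subject].unique()
    wide = df.pivot_table(
        index=subject, columns=list(within), values=value, aggfunc="first"
    )
    wide = wide.reindex(columns=pd.MultiIndex.from_tuples(cells)
                        if len(within) > 1 else [c[0] for c in cells])
    if wide.isna().any().any():
        i, j = np.argwhere(wide.isna().to_numpy())[0]
        raise ValueError(
            f"incomplete within-cell grid: subject {wide.index[i]!r}, "
            f"cell {wide.columns[j]!r}"
        )
    y = wide.to_numpy(dtype=float)
    groups = (
        df.drop_duplicates(subject).set_index(subject)[between]
        .reindex(wide.index).to_numpy()
    )
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least two groups")
    for lv in np.unique(groups):
        if (groups == lv).sum() < 2:
            raise ValueError("need >= 2 subjects per group")

    n = len(subjects)
    g = len(np.unique(groups))
    q = len(cells)

    contrast_sets: dict[str, np.ndarray] = {}
    per_factor = {w: _orthonormal_contrasts(len(levels[w])) for w in within}
    unit = {w: np.full((1, len(levels[w])), 1.0 / np.sqrt(len(levels[w])))
            for w in within}
    if len(within) == 1:
        w0 = within[0]
        contrast_sets[w0] = per_factor[w0]
    else:
        w0, w1 = within
        contrast_sets[w0] = np.kron(per_factor[w0], unit[w1])
        contrast_sets[w1] = np.kron(unit[w0], per_factor[w1])
        contrast_sets[f"{w0}*{w1}"] = np.kron(per_factor[w0], per_factor[w1])

    results: list[RmAnovaResult] = []

    # between main effect on the subject means (unit contrast)
    unit_all = np.full((1, q), 1.0 / np.sqrt(q))
    z0 = y @ unit_all.T
    ss_int, ss_grp, ss_err, _ = _between_test(z0, groups)
    df1, df2 = g - 1, n - g
    f_between = (ss_grp / df1) / (ss_err / df2)
    p_between = float(sstats.f.sf(f_between, df1, df2))
    results.append(
        RmAnovaResult(between, df1, df2, 1.0, df1, df2,
                      float(f_between), p_between, p_between)
    )

    for name, m in contrast_sets.items():
        z = y @ m.T  # (n, p)
        p_dim = z.shape[1]
        ss_eff, ss_ia, ss_err, _ = _between_test(z, groups)
        eps = _gg_epsilon(z, groups)
        df_err = p_dim * (n - g)
        for label, ss, df1 in (
            (name, ss_eff, p_dim),
            (f"{name}*{between}", ss_ia, p_dim * (g - 1)),
        ):
            f = (ss / df1) / (ss_err / df_err)
            p_unc = float(sstats.f.sf(f, df1, df_err))
            p_gg = float(sstats.f.sf(f, eps * df1, eps * df_err))
            results.append(
                RmAnovaResult(label, df1, df_err, eps, eps * df1,
                              eps * df_err, float(f), p_unc, p_gg)
            )
    return results


def rm_anova_table(results: list[RmAnovaResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in results])


# --------------------------------------------------------------------------
# post-hoc univariate ANOVA
# --------------------------------------------------------------------------

@dataclass
class UnivariateResult:
    parameter: str
    class_name: str
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float

    def as_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "class": self.class_name,
            "group1_mean": self.mean1,
            "group1_sd": self.sd1,
            "group2_mean": self.mean2,
            "group2_sd": self.sd2,
            "F": self.F,
            "p": self.p,
            "partial_eta_sq": self.partial_eta_sq,
        }


def partial_eta_squared(f: float, df1: float, df2: float) -> float:
    """Effect size from the F statistic: F*df1 / (F*df1 + df2)."""
    return float(f * df1 / (f * df1 + df2))


def posthoc_univariate(
    group1,
    group2,
    parameter: str = "",
    class_name: str = "",
) -> UnivariateResult:
    """Two-group one-way ANOVA (simple effect) on one metric cell.

    Accepts raw vectors or (mean, sd, n) summaries per group.  F equals the
    square of the pooled t statistic; partial eta squared uses the
    F/(F + df2) identity (df1 = 1).
    """
    t, df, p = two_sample_t(group1, group2, variance="pooled")
    f = t**2
    def summ(gr):
        if isinstance(gr, (tuple, list)) and len(gr) == 3 and np.isscalar(gr[0]):
            return float(gr[0]), float(gr[1]), int(gr[2])
        arr = np.asarray(gr, dtype=float)
        return float(arr.mean()), float(arr.std(ddof=1)), int(arr.size)

    m1, s1, n1 = summ(group1)
    m2, s2, n2 = summ(group2)
    return UnivariateResult(
        parameter, class_name, m1, s1, n1, m2, s2, n2,
        float(f), 1, int(df), float(p),
        partial_eta_squared(f, 1, df),
    )


# --------------------------------------------------------------------------
# correlations
# --------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    x_name: str
    y_name: str
    n: int
    r: float
    p: float

    def as_dict(self) -> dict:
        return {"x": self.x_name, "y": self.y_name, "n": self.n,
                "r": self.r, "p": self.p}


def pearson_correlation(x, y, x_name: str = "x", y_name: str = "y"
                        ) -> CorrelationResult:
    """Pearson product-moment correlation with the two-tailed p-value from
    t = r sqrt(n-2) / sqrt(1-r^2) on t(n-2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need n >= 3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = sstats.pearsonr(x, y)
    return CorrelationResult(x_name, y_name, int(x.size),
                             float(res.statistic), float(res.pvalue))


def correlation_p_from_r(r: float, n: int) -> float:
    """Analytic two-tailed p for a given r and sample size."""
    if not abs(r) < 1:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
    return float(2 * sstats.t.sf(abs(t), n - 2))


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------

def cohort_long(table: pd.DataFrame, class_labels: list[str]
                ) -> pd.DataFrame:
    """Melt a wide cohort table (columns ``<parameter>_<class>``) into long
    format (subject, group, parameter, class, value)."""
    rows = []
    for param in PARAMETERS:
        for cls in class_labels:
            col = f"{param}_{cls}"
            for _, r in table.iterrows():
                rows.append(
                    {
                        "subject": r["subject"],
                        "group": r["group"],
                        "parameter": param,
                        "class": cls,
                        "value": r[col],
                    }
                )
    return pd.DataFrame(rows)


def run_statistics(
    table: pd.DataFrame,
    class_labels: list[str] = ("A", "B", "C", "D"),
    scale: str = "raw",
    variance: str = "pooled",
    chi2_correction: str = "none",
    posthoc_gate: bool = True,
    alpha: float = 0.05,
) -> dict:
    """Run the full statistical layer on a wide cohort table.

    Emits a demographics table, the omnibus mixed rm-ANOVA, the post-hoc
    grid of two-group univariate ANOVAs (gated, if ``posthoc_gate``, on a
    significant group effect or group interaction in the omnibus test), and
    Pearson correlations of all symptom subscores against all metrics in
    the symptom-scored group.  No multiple-testing correction is applied to
    the post-hoc or correlation grids.
    """
    class_labels = list(class_labels)
    groups = list(pd.unique(table["group"]))
    if len(groups) != 2:
        raise ValueError("expected exactly two groups")
    g1 = table[table["group"] == groups[0]]
    g2 = table[table["group"] == groups[1]]
    log: list[str] = []

    demo_rows = []
    if "sex" in table.columns:
        counts = [
            [(g["sex"] == "M").sum(), (g["sex"] == "F").sum()]
            for g in (g1, g2)
        ]
        try:
            stat, p = chi_square_2x2(counts, correction=chi2_correction)
            demo_rows.append({"variable": "sex (M/F)", "statistic": stat,
                              "p": p, "test": "chi2"})
        except ValueError as exc:
            log.append(f"sex chi-square skipped: {exc}")
    for var in ("age", "education_years"):
        if var in table.columns:
            t, _, p = two_sample_t(g1[var], g2[var], variance=variance)
            demo_rows.append({"variable": var, "statistic": t, "p": p,
                              "test": f"t ({variance})"})
    demographics = pd.DataFrame(demo_rows)

    long = cohort_long(table, class_labels)
    omnibus = rm_anova_mixed(long, scale=scale)
    omnibus_df = rm_anova_table(omnibus)

    group_related = [
        r for r in omnibus if r.effect == "group" or r.effect.endswith("*group")
    ]
    gate_open = (not posthoc_gate) or any(r.p < alpha for r in group_related)
    log.append(
        f"post-hoc gate {'open' if gate_open else 'closed'}: min group-effect "
        f"p = {min(r.p for r in group_related):.4g}"
    )

    posthoc_df = pd.DataFrame()
    if gate_open:
        cells = []
        for param in PARAMETERS:
            for cls in class_labels:
                col = f"{param}_{cls}"
                res = posthoc_univariate(
                    g1[col].to_numpy(), g2[col].to_numpy(), param, cls
                )
                cells.append(res.as_dict())
        posthoc_df = pd.DataFrame(cells)

    corr_df = pd.DataFrame()
    symptom_cols = [c for c in table.columns if c.startswith("panss")]
    if symptom_cols:
        scored = table.dropna(subset=symptom_cols[:1])
        scored = scored[scored[symptom_cols[0]].notna()]
        rows = []
        for sc in symptom_cols:
            sub = scored[scored[sc].notna()]
            for param in PARAMETERS:
                for cls in class_labels:
                    col = f"{param}_{cls}"
                    try:
                        res = pearson_correlation(
                            sub[sc], sub[col], sc, col
                        )
                    except ValueError:
                        continue
                    rows.append(res.as_dict())
        corr_df = pd.DataFrame(rows)
    else:
        log.append("no symptom subscores: correlation section omitted")

    return {
        "demographics": demographics,
        "rm_anova": omnibus_df,
        "posthoc": posthoc_df,
        "correlations": corr_df,
        "log": log,
    }
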