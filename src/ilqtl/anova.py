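"""Variance decomposition, heritability, and trait correlations.

The experiment is completely randomized.  Two fixed-effects decompositions
are provided:

* separate (one-way, within a treatment): genotype + error;
* combined (two-way across treatments): genotype + treatment + G x T + error,
  with balanced-design sums of squares and all F tests against the error MS.

Broad-sense heritability is estimated from the one-way expected mean squares
under a random-genotype interpretation:

    sigma_e^2 = MS_E,   sigma_g^2 = max(0, (MS_G - MS_E) / r),
    Hb% = 100 * sigma_g^2 / (sigma_g^2 + sigma_e^2 / r),

with r replicates; equivalently Hb% = 100 * (1 - MS_E / MS_G) when
MS_G > MS_E.  The F tests treat genotype as fixed while the variance
components treat it as random -- both conventions are deliberate and
implemented explicitly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AnovaResult:
    """One fitted ANOVA: per-term df/SS/MS/F/p plus CV% and R^2.

    ``terms`` is indexed by term name (``G``, and for the combined model
    ``T`` and ``G:T``, plus ``error``) with columns df, ss, ms, F, p.
    """

    model: str  # "separate" | "combined"
    trait: str
    treatment: str | None
    terms: pd.DataFrame
    cv_percent: float
    r_squared: float
    grand_mean: float
    n_obs: int

    @property
    def ms_error(self) -> float:
        return float(self.terms.loc["error", "ms"])

    def summary(self) -> str:
        lines = [f"ANOVA ({self.model}) for {self.trait}"
                 + (f" under {self.treatment}" if self.treatment else "")]
        lines.append(self.terms.to_string(
            float_format=lambda v: f"{v:.4g}"))
        lines.append(f"CV% = {self.cv_percent:.1f}   R^2 = {self.r_squared:.2f}"
                     f"   n = {self.n_obs}")
        return "\n".join(lines)


@dataclass
class HeritabilityEstimate:
    trait: str
    treatment: str | None
    sigma2_g: float
    sigma2_e: float
    sigma2_p: float
    hb_percent: float
    replicates: int


def _anova_frame(entries: list[tuple[str, float, float]],
                 ss_total: float) -> pd.DataFrame:
    """Assemble the term table from (name, df, ss) rows; last row is error."""
    names = [e[0] for e in entries]
    df = pd.DataFrame({"df": [e[1] for e in entries],
                       "ss": [e[2] for e in entries]}, index=names)
    with np.errstate(invalid="ignore", divide="ignore"):
        df["ms"] = df["ss"] / df["df"]
    ms_e = df.loc["error", "ms"]
    df_e = df.loc["error", "df"]
    F, p = [], []
    for name in names:
        if name == "error" or df_e <= 0:
            F.append(math.nan)
            p.append(math.nan)
        elif ms_e == 0:
            # degenerate: no residual noise
            f = math.inf if df.loc[name, "ss"] > 0 else 0.0
            F.append(f)
            p.append(0.0 if f == math.inf else 1.0)
        else:
            f = df.loc[name, "ms"] / ms_e
            F.append(f)
            p.append(float(stats.f.sf(f, df.loc[name, "df"], df_e)))
    df["F"] = F
    df["p"] = p
    return df


def separate_anova(table: pd.DataFrame, trait: str, treatment: str) -> AnovaResult:
    """One-way genotype ANOVA within a single treatment.

    Lines without observations are dropped with a warning; requires at least
    two lines and a positive error df.
    """
    sub = table[(table["trait"] == trait) & (table["treatment"] == treatment)]
    sub = sub.dropna(subset=["value"])
    if sub.empty:
        raise ValueError(f"no data for trait {trait!r} under {treatment!r}")
    groups = sub.groupby("line_id")["value"]
    sizes = groups.size()
    if (sizes < 1).any():
        warnings.warn("lines without observations dropped")
    if len(sizes) < 2:
        raise ValueError("need >= 2 lines for a one-way ANOVA")
    y = sub["value"].to_numpy()
    grand = y.mean()
    means = groups.mean()
    ss_g = float((sizes * (means - grand) ** 2).sum())
    ss_total = float(((y - grand) ** 2).sum())
    ss_e = ss_total - ss_g
    df_g = len(sizes) - 1
    df_e = len(y) - len(sizes)
    if df_e <= 0:
        raise ValueError("zero error degrees of freedom (need replication)")
    terms = _anova_frame([("G", df_g, ss_g), ("error", df_e, max(ss_e, 0.0))],
                         ss_total)
    ms_e = terms.loc["error", "ms"]
    cv = 100.0 * math.sqrt(ms_e) / grand if grand != 0 else math.nan
    r2 = ss_g / ss_total if ss_total > 0 else 0.0
    return AnovaResult("separate", trait, treatment, terms, cv, r2, grand, len(y))


def combined_anova(table: pd.DataFrame, trait: str,
                   strict_balance: bool = True) -> AnovaResult:
    """Two-way genotype x treatment ANOVA with replication.

    Balanced layouts use the closed-form balanced-design decomposition.
    With missing cells (or unequal replication) the strict policy raises;
    the tolerant policy falls back to an OLS Type-II decomposition as a
    proportional-subclass approximation, with a warning.
    """
    sub = table[table["trait"] == trait].dropna(subset=["value"])
    if sub.empty:
        raise ValueError(f"no data for trait {trait!r}")
    cell_sizes = sub.groupby(["line_id", "treatment"])["value"].size()
    n_lines = sub["line_id"].nunique()
    n_trt = sub["treatment"].nunique()
    balanced = (len(cell_sizes) == n_lines * n_trt
                and cell_sizes.nunique() == 1)
    if not balanced:
        if strict_balance:
            raise ValueError(
                "unbalanced genotype x treatment layout; rerun with "
                "strict_balance=False for the approximate decomposition")
        warnings.warn("unbalanced layout: using Type-II OLS approximation")
        return _combined_anova_ols(sub, trait)

    r = int(cell_sizes.iloc[0])
    if r < 2:
        raise ValueError("need >= 2 replicates per cell")
    y = sub["value"].to_numpy()
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    g_means = sub.groupby("line_id")["value"].mean()
    t_means = sub.groupby("treatment")["value"].mean()
    cell_means = sub.groupby(["line_id", "treatment"])["value"].mean()
    ss_g = float(n_trt * r * ((g_means - grand) ** 2).sum())
    ss_t = float(n_lines * r * ((t_means - grand) ** 2).sum())
    interaction_dev = (cell_means
                       - g_means.reindex(cell_means.index.get_level_values(0)).values
                       - t_means.reindex(cell_means.index.get_level_values(1)).values
                       + grand)
    ss_gt = float(r * (interaction_dev ** 2).sum())
    ss_e = ss_total - ss_g - ss_t - ss_gt
    df_g, df_t = n_lines - 1, n_trt - 1
    df_gt = df_g * df_t
    df_e = n_lines * n_trt * (r - 1)
    terms = _anova_frame([("G", df_g, ss_g), ("T", df_t, ss_t),
                          ("G:T", df_gt, ss_gt),
                          ("error", df_e, max(ss_e, 0.0))], ss_total)
    ms_e = terms.loc["error", "ms"]
    cv = 100.0 * math.sqrt(ms_e) / grand if grand != 0 else math.nan
    r2 = (ss_g + ss_t + ss_gt) / ss_total if ss_total > 0 else 0.0
    return AnovaResult("combined", trait, None, terms, cv, r2, grand, len(y))


def _combined_anova_ols(sub: pd.DataFrame, trait: str) -> AnovaResult:
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = sub.rename(columns={"line_id": "G", "treatment": "T"})
    fit = smf.ols("value ~ C(G) + C(T) + C(G):C(T)", data=data).fit()
    tab = sm.stats.anova_lm(fit, typ=2)
    entries = [("G", float(tab.loc["C(G)", "df"]), float(tab.loc["C(G)", "sum_sq"])),
               ("T", float(tab.loc["C(T)", "df"]), float(tab.loc["C(T)", "sum_sq"])),
               ("G:T", float(tab.loc["C(G):C(T)", "df"]),
                float(tab.loc["C(G):C(T)", "sum_sq"])),
               ("error", float(tab.loc["Residual", "df"]),
                float(tab.loc["Residual", "sum_sq"]))]
    y = data["value"].to_numpy()
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    terms = _anova_frame(entries, ss_total)
    ms_e = terms.loc["error", "ms"]
    cv = 100.0 * math.sqrt(ms_e) / grand if grand != 0 else math.nan
    return AnovaResult("combined", trait, None, terms, cv,
                       float(fit.rsquared), grand, len(y))


def heritability(anova: AnovaResult, r: int) -> HeritabilityEstimate:
    """Broad-sense heritability from a one-way (separate) ANOVA.

    Negative genotypic-variance estimates are truncated at zero, so
    Hb lies in [0, 100].
    """
    if anova.model != "separate":
        raise ValueError("heritability requires the separate (one-way) ANOVA")
    ms_g = float(anova.terms.loc["G", "ms"])
    ms_e = anova.ms_error
    sigma2_e = ms_e
    sigma2_g = max(0.0, (ms_g - ms_e) / r)
    sigma2_p = sigma2_g + sigma2_e / r
    hb = 100.0 * sigma2_g / sigma2_p if sigma2_p > 0 else 0.0
    return HeritabilityEstimate(anova.trait, anova.treatment,
                                sigma2_g, sigma2_e, sigma2_p, hb, r)


def correlation_matrix(table: pd.DataFrame, treatment: str,
                       traits: list[str],
                       level: str = "line") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlations among traits within a treatment.

    By default traits are first reduced to per-line LS-means (arithmetic
    means in the balanced design) within the treatment; ``level='replicate'``
    correlates raw replicate values instead.  Returns (r, p) DataFrames with
    unit diagonal; zero-variance traits yield missing entries with a warning.
    """
    sub = table[(table["treatment"] == treatment) & table["trait"].isin(traits)]
    if level == "line":
        wide = sub.pivot_table(index="line_id", columns="trait", values="value",
                               aggfunc="mean")
    elif level == "replicate":
        wide = sub.pivot_table(index=["line_id", "replicate"], columns="trait",
                               values="value", aggfunc="first")
    else:
        raise ValueError(f"unknown level {level!r}")
    wide = wide.reindex(columns=[t for t in traits if t in wide.columns])
    if len(wide) < 3:
        raise ValueError("need >= 3 lines for correlations")
    cols = wide.columns
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.where(np.eye(len(cols)), 0.0, np.nan),
                     index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            pair = wide[[a, b]].dropna()
            if len(pair) < 3 or pair[a].std() == 0 or pair[b].std() == 0:
                warnings.warn(f"correlation undefined for {a} vs {b}")
                r.loc[a, b] = r.loc[b, a] = math.nan
                continue
            res = stats.pearsonr(pair[a], pair[b])
            r.loc[a, b] = r.loc[b, a] = res.statistic
            p.loc[a, b] = p.loc[b, a] = res.pvalue
    return r, p
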