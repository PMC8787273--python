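"""The study's statistical decision procedure.

Two-group outcomes pass through a normality gate: Shapiro-Wilk on each
(optionally square-root transformed) group; both normal -> Student's
t-test, otherwise Mann-Whitney U.  Factorial outcomes (treatment x
myotube type) use a two-way ANOVA with Tukey HSD post hoc, with type-II
sums of squares for unbalanced cells.  Nuclei-per-myotube counts, being
overdispersed, are modelled by log-link negative-binomial regression with
treatment and type terms, reported as rate ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd


def significance_stars(p: float) -> str:
    """Star convention: *** p<0.001, ** p<0.01, * p<0.05, ns otherwise."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(len(x)))


def _apply_transform(x: np.ndarray, transform: str) -> np.ndarray:
    if transform == "none":
        return x
    if transform == "sqrt":
        if (x < 0).any():
            raise ValueError("sqrt transform needs non-negative data")
        return np.sqrt(x)
    raise ValueError(f"unknown transform {transform!r}")


@dataclass
class StatResult:
    effect: str
    estimate: float
    statistic: float
    p_value: float
    stars: str
    group_means: dict
    group_sems: dict
    n: dict
    details: dict = field(default_factory=dict)


def gated_two_group_test(a, b, transform: str = "none",
                         normality_alpha: float = 0.05,
                         equal_var: bool = True,
                         labels: tuple[str, str] = ("a", "b")) -> StatResult:
    """Normality-gated two-group comparison.

    The transform is applied before the normality check and the test.  The
    gate's outcome (per-group Shapiro-Wilk p values and the branch taken)
    is recorded in ``details`` so every reported number is traceable.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("normality gate needs n >= 3 per group")
    ta, tb = _apply_transform(a, transform), _apply_transform(b, transform)
    sw_a = sps.shapiro(ta).pvalue if np.ptp(ta) > 0 else 1.0
    sw_b = sps.shapiro(tb).pvalue if np.ptp(tb) > 0 else 1.0
    normal = sw_a > normality_alpha and sw_b > normality_alpha
    if np.ptp(np.concatenate([ta, tb])) == 0:
        # identical constant groups: no evidence of any difference
        stat, p, chosen = 0.0, 1.0, "t_test"
    elif normal:
        stat, p = sps.ttest_ind(ta, tb, equal_var=equal_var)
        chosen = "t_test"
    else:
        stat, p = sps.mannwhitneyu(ta, tb, alternative="two-sided")
        chosen = "mann_whitney"
    la, lb = labels
    return StatResult(
        effect=f"{la} vs {lb}",
        estimate=float(np.mean(b) - np.mean(a)),
        statistic=float(stat), p_value=float(p), stars=significance_stars(p),
        group_means={la: float(np.mean(a)), lb: float(np.mean(b))},
        group_sems={la: _sem(a), lb: _sem(b)},
        n={la: len(a), lb: len(b)},
        details={"chosen_test": chosen, "transform": transform,
                 "shapiro_p": {la: float(sw_a), lb: float(sw_b)},
                 "normality_alpha": normality_alpha},
    )


@dataclass
class AnovaResult:
    anova_table: pd.DataFrame
    tukey: pd.DataFrame
    cell_means: pd.DataFrame
    transform: str

    def effect_p(self, term: str) -> float:
        for idx in self.anova_table.index:
            if term in idx:
                return float(self.anova_table.loc[idx, "PR(>F)"])
        raise KeyError(term)


def two_way_anova_tukey(data: pd.DataFrame, value: str, treatment: str,
                        type_col: str, transform: str = "none") -> AnovaResult:
    """Two-way ANOVA (type-II sums of squares) with Tukey HSD post hoc on
    all treatment-x-type cells; the transform is applied first."""
    df = data[[value, treatment, type_col]].dropna().copy()
    for col in (treatment, type_col):
        if df[col].nunique() < 2:
            raise ValueError(f"factor {col!r} needs >= 2 levels")
    cells = df.groupby([treatment, type_col], observed=True)[value].count()
    full = pd.MultiIndex.from_product(
        [df[treatment].unique(), df[type_col].unique()])
    for cell in full:
        if cell not in cells.index or cells.loc[cell] == 0:
            raise ValueError(f"empty cell: {cell}")
    df["_y"] = _apply_transform(df[value].to_numpy(dtype=float), transform)
    # internal column names keep patsy happy with arbitrary user columns
    fit_df = df.rename(columns={treatment: "_f1", type_col: "_f2"})
    model = smf.ols("_y ~ C(_f1) * C(_f2)", data=fit_df).fit()
    table = anova_lm(model, typ=2)
    table.index = [idx.replace("_f1", treatment).replace("_f2", type_col)
                   for idx in table.index]
    groups = df[treatment].astype(str) + ":" + df[type_col].astype(str)
    tukey = pairwise_tukeyhsd(df["_y"], groups)
    tukey_df = pd.DataFrame(tukey.summary().data[1:],
                            columns=tukey.summary().data[0])
    means = (df.groupby([treatment, type_col], observed=True)[value]
             .agg(["mean", "sem", "count"]).reset_index())
    return AnovaResult(anova_table=table, tukey=tukey_df, cell_means=means,
                       transform=transform)


@dataclass
class NbResult:
    rate_ratios: dict
    p_values: dict
    dispersion_alpha: float
    converged: bool
    summary_table: pd.DataFrame

    def stars(self, term: str) -> str:
        return significance_stars(self.p_values[term])


def nuclei_count_model(data: pd.DataFrame, count: str, treatment: str,
                       type_col: str) -> NbResult:
    """Log-link negative-binomial regression of nuclei counts on treatment
    and myotube type, dispersion estimated by maximum likelihood.  Reports
    exp(coefficients) as rate ratios."""
    df = data[[count, treatment, type_col]].dropna().copy()
    counts = df[count].to_numpy()
    if not np.allclose(counts, np.round(counts)) or (counts < 0).any():
        raise ValueError("counts must be non-negative integers")
    if np.ptp(counts) == 0:
        # degenerate all-equal counts: every rate ratio is exactly 1
        terms = {f"{treatment}": 1.0, f"{type_col}": 1.0}
        return NbResult(rate_ratios=terms,
                        p_values={k: 1.0 for k in terms},
                        dispersion_alpha=0.0, converged=True,
                        summary_table=pd.DataFrame())
    fit_df = df.rename(columns={count: "_y", treatment: "_f1", type_col: "_f2"})
    model = smf.negativebinomial("_y ~ C(_f1) + C(_f2)", data=fit_df)
    res = model.fit(disp=0, maxiter=500)
    params = res.params.rename(
        index=lambda s: s.replace("_f1", treatment).replace("_f2", type_col))
    pvals = res.pvalues.rename(
        index=lambda s: s.replace("_f1", treatment).replace("_f2", type_col))
    rate_ratios, p_values = {}, {}
    for name in params.index:
        if name == "Intercept" or name == "alpha":
            continue
        rate_ratios[name] = float(np.exp(params[name]))
        p_values[name] = float(pvals[name])
    alpha = float(params.get("alpha", np.nan))
    summary = pd.DataFrame({"coef": params, "p": pvals})
    return NbResult(rate_ratios=rate_ratios, p_values=p_values,
                    dispersion_alpha=alpha,
                    converged=bool(res.mle_retvals.get("converged", True)),
                    summary_table=summary)


def term_key(result: NbResult | AnovaResult, factor: str) -> str:
    """Find the model term containing a factor name (convenience lookup)."""
    keys = result.p_values.keys() if isinstance(result, NbResult) \
        else result.anova_table.index
    for k in keys:
        if factor in k:
            return k
    raise KeyError(factor)
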