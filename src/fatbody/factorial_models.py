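"""Factorial ANOVA models, variance/outlier checks, and FDR adjustment.

For the full-factorial labeled data each protein's normalized log2
abundance is modeled as

    Y = treatment + genotype + age
        + treatment:genotype + treatment:age + genotype:age
        + treatment:genotype:age + ~sample + error

with all crossed factors fixed and a random intercept per biological
sample.  Every fixed effect is a between-sample contrast, so with the
containment convention its F-test denominator is the sample-level variation:
the model is fitted on per-sample means, which for balanced designs is the
classical expected-mean-squares mixed-model F.  With a single measurement
per sample the random intercept is absorbed into the residual and the fit
reduces exactly to the fixed-effects three-way ANOVA.

Metabolite (lipid, glucose) values are analyzed on the log2 scale with a
two-way factorial ANOVA (Type II sums of squares by default, the
conventional choice for unbalanced factorials without a significant
interaction), after a Levene homogeneity check and a Dixon ratio test for a
single extreme outlier.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .design import Design
from .errors import DomainError, InsufficientDataError

__all__ = [
    "AnovaResult",
    "DixonResult",
    "f_tail_p",
    "two_way_anova",
    "fit_mixed_anova",
    "mixed_anova_all",
    "levene_check",
    "dixon_outlier",
    "bh_fdr",
]

FIXED_EFFECTS = [
    "treatment",
    "genotype",
    "age",
    "treatment:genotype",
    "treatment:age",
    "genotype:age",
    "treatment:genotype:age",
]


def f_tail_p(F: float, df1: int, df2: int) -> float:
    """Upper-tail probability of the F distribution."""
    if df1 < 1 or df2 < 1:
        raise DomainError(f"degrees of freedom must be >= 1 (got {df1}, {df2})")
    if F < 0:
        raise DomainError(f"F must be non-negative (got {F})")
    return float(stats.f.sf(F, df1, df2))


@dataclass
class AnovaResult:
    """Per-effect F tests for one response (one protein or metabolite)."""

    table: pd.DataFrame  # index: effect; columns: F, df1, df2, p
    random_variance: float = 0.0
    method: str = "fixed"
    untestable: tuple[str, ...] = ()


def _anova_from_ols(model, typ: int) -> pd.DataFrame:
    aov = sm.stats.anova_lm(model, typ=typ)
    resid_row = aov.index[-1]
    df2 = float(aov.loc[resid_row, "df"])
    rows = {}
    for effect in aov.index:
        if effect == resid_row:
            continue
        name = effect.replace("C(", "").replace(")", "")
        f = aov.loc[effect, "F"]
        rows[name] = {
            "F": float(f),
            "df1": float(aov.loc[effect, "df"]),
            "df2": df2,
            "p": float(aov.loc[effect, "PR(>F)"]),
        }
    return pd.DataFrame(rows).T[["F", "df1", "df2", "p"]]


def two_way_anova(
    values,
    genotype,
    treatment,
    ss_type: int = 2,
) -> AnovaResult:
    """Two-factor factorial ANOVA with interaction (unbalanced allowed).

    ``ss_type`` selects the sums-of-squares convention (1, 2 or 3; Type III
    uses sum-to-zero contrasts).  With an empty design cell the interaction
    is untestable and main effects come from the additive model.
    """
    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "genotype": np.asarray(genotype, dtype=object),
            "treatment": np.asarray(treatment, dtype=object),
        }
    ).dropna()
    cells = df.groupby(["genotype", "treatment"], sort=False).size()
    n_g = df["genotype"].nunique()
    n_t = df["treatment"].nunique()
    if n_g < 2 or n_t < 2:
        raise InsufficientDataError("both factors need >= 2 observed levels")
    if (cells < 2).any():
        raise InsufficientDataError("each design cell needs >= 2 observations")
    contrast = "C(genotype, Sum)" if ss_type == 3 else "C(genotype)"
    contrast_t = "C(treatment, Sum)" if ss_type == 3 else "C(treatment)"
    full_cells = n_g * n_t
    untestable: tuple[str, ...] = ()
    if len(cells) < full_cells:
        formula = f"value ~ {contrast} + {contrast_t}"
        untestable = ("genotype:treatment",)
    else:
        formula = f"value ~ {contrast} * {contrast_t}"
    model = smf.ols(formula, data=df).fit()
    table = _anova_from_ols(model, typ=ss_type)
    table.index = [
        i.replace(", Sum", "").replace("genotype", "genotype").replace("treatment", "treatment")
        for i in table.index
    ]
    return AnovaResult(table=table, method=f"ols-type{ss_type}", untestable=untestable)


def fit_mixed_anova(
    values: pd.Series,
    d: Design,
    ss_type: int = 2,
) -> AnovaResult:
    """Mixed-model three-way ANOVA for one protein.

    ``values`` is indexed by sample id (one or more measurements per
    biological sample); missing rows are dropped (complete-case).  The
    random per-sample intercept is handled by the containment strategy:
    between-sample fixed effects are tested against sample-level variation,
    i.e. the three-way ANOVA is computed on per-sample means.  The residual
    (within-sample) variance and the method used are reported; when every
    sample carries a single measurement the fit is exactly the fixed-effects
    three-way ANOVA.  Effects whose factor collapses to one observed level
    are marked untestable; the remaining effects are still reported.
    """
    vals = values.dropna()
    if len(vals) < 8:
        raise InsufficientDataError(f"too few observations ({len(vals)})")
    meta = d.frame.loc[vals.index]
    df = pd.DataFrame(
        {
            "value": vals.to_numpy(dtype=float),
            "treatment": meta["treatment"].astype(str).to_numpy(),
            "genotype": meta["genotype"].astype(str).to_numpy(),
            "age": meta["age"].astype(str).to_numpy(),
            "sample": vals.index,
        }
    )
    replicated = df.groupby("sample").size().max() > 1
    random_variance = 0.0
    method = "fixed-reduction"
    if replicated:
        per_sample = df.groupby(["sample", "treatment", "genotype", "age"], sort=False)[
            "value"
        ].mean().reset_index()
        within = df.groupby("sample")["value"].var(ddof=1)
        random_variance = float(np.nanmean(within.to_numpy()))
        work = per_sample
        method = "containment"
    else:
        work = df
    factors = ["treatment", "genotype", "age"]
    present = [f for f in factors if work[f].nunique() >= 2]
    dropped = [f for f in factors if f not in present]
    untestable = tuple(e for e in FIXED_EFFECTS if any(f in e.split(":") for f in dropped))
    if len(present) == 0:
        raise InsufficientDataError("no factor with >= 2 observed levels")
    terms = [f"C({f}, Sum)" if ss_type == 3 else f"C({f})" for f in present]
    formula = "value ~ " + " * ".join(terms)
    model = smf.ols(formula, data=work).fit()
    table = _anova_from_ols(model, typ=ss_type)
    table.index = [i.replace(", Sum", "") for i in table.index]
    return AnovaResult(
        table=table,
        random_variance=random_variance,
        method=method,
        untestable=untestable,
    )


def mixed_anova_all(
    values: pd.DataFrame,
    d: Design,
    ss_type: int = 2,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-protein mixed ANOVA over a protein x sample table, with FDR.

    Returns a long DataFrame (protein, effect, F, df1, df2, p, q) where q is
    the Benjamini-Hochberg adjusted p computed separately per effect across
    proteins.
    """
    rows = []
    for prot in values.index:
        try:
            res = fit_mixed_anova(values.loc[prot], d, ss_type=ss_type)
        except InsufficientDataError:
            continue
        for effect, r in res.table.iterrows():
            rows.append(
                {
                    "protein": prot,
                    "effect": effect,
                    "F": r["F"],
                    "df1": r["df1"],
                    "df2": r["df2"],
                    "p": r["p"],
                }
            )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["q"] = np.nan
    for effect, idx in out.groupby("effect").groups.items():
        out.loc[idx, "q"] = bh_fdr(out.loc[idx, "p"].to_numpy())
    out["significant"] = out["q"] < fdr_alpha
    return out


def levene_check(values, groups, center: str = "mean") -> tuple[float, float]:
    """Levene's homogeneity-of-variance test.

    One-way ANOVA F on absolute deviations from the group center (mean for
    classic Levene; ``center='median'`` gives the Brown-Forsythe variant).
    Degenerate data with all deviations equal returns ``(0.0, 1.0)``.
    """
    df = pd.DataFrame({"v": np.asarray(values, dtype=float), "g": np.asarray(groups, dtype=object)}).dropna()
    sizes = df.groupby("g").size()
    if len(sizes) < 2 or (sizes < 2).any():
        raise InsufficientDataError("need >= 2 groups of >= 2 observations")
    centerer = {"mean": np.mean, "median": np.median}[center]
    dev = df.groupby("g")["v"].transform(lambda x: np.abs(x - centerer(x)))
    k = len(sizes)
    n = len(df)
    grand = dev.mean()
    group_means = dev.groupby(df["g"]).mean()
    ss_between = float((sizes * (group_means - grand) ** 2).sum())
    ss_within = float(((dev - dev.groupby(df["g"]).transform("mean")) ** 2).sum())
    if ss_within == 0 and ss_between == 0:
        return 0.0, 1.0
    if ss_within == 0:
        return float("inf"), 0.0
    w = (ss_between / (k - 1)) / (ss_within / (n - k))
    return float(w), f_tail_p(w, k - 1, n - k)


# Dixon ratio-test critical values, two-sided, after the standard tables
# (r10 for n<=7, r11 for 8-10, r21 for 11-13, r22 for 14-30).
_DIXON_CRIT = {
    0.05: {
        3: 0.970, 4: 0.829, 5: 0.710, 6: 0.625, 7: 0.568,
        8: 0.608, 9: 0.564, 10: 0.530,
        11: 0.619, 12: 0.583, 13: 0.557,
        14: 0.586, 15: 0.565, 16: 0.546, 17: 0.529, 18: 0.514, 19: 0.501,
        20: 0.489, 21: 0.478, 22: 0.468, 23: 0.459, 24: 0.451, 25: 0.443,
        26: 0.436, 27: 0.429, 28: 0.423, 29: 0.417, 30: 0.412,
    },
    0.01: {
        3: 0.994, 4: 0.926, 5: 0.821, 6: 0.740, 7: 0.680,
        8: 0.717, 9: 0.672, 10: 0.635,
        11: 0.709, 12: 0.660, 13: 0.638,
        14: 0.670, 15: 0.647, 16: 0.627, 17: 0.610, 18: 0.594, 19: 0.580,
        20: 0.567, 21: 0.555, 22: 0.544, 23: 0.535, 24: 0.526, 25: 0.517,
        26: 0.510, 27: 0.502, 28: 0.495, 29: 0.489, 30: 0.483,
    },
}


@dataclass
class DixonResult:
    Q: float
    suspect: float
    suspect_side: str  # 'low' | 'high'
    rejected: bool
    statistic: str
    critical: float
    degenerate: bool = False


def dixon_outlier(values, alpha: float = 0.05) -> DixonResult:
    """Dixon ratio test for a single extreme value (3 <= n <= 30).

    The ratio statistic follows Dixon's convention for the sample size:
    r10 (gap to nearest neighbor over range) for n <= 7, r11 for 8-10, r21
    for 11-13 and r22 for 14-30, computed for both extremes; the suspect is
    the side with the larger ratio and is rejected when the ratio exceeds
    the two-sided critical value at ``alpha`` (0.05 or 0.01).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if not 3 <= n <= 30:
        raise DomainError(f"Dixon test defined for 3 <= n <= 30 (got {n})")
    if alpha not in _DIXON_CRIT:
        raise DomainError(f"alpha must be one of {sorted(_DIXON_CRIT)} (got {alpha})")
    if x[-1] == x[0]:
        return DixonResult(0.0, x[0], "high", False, "degenerate", np.nan, True)
    if n <= 7:
        stat = "r10"
        q_low = (x[1] - x[0]) / (x[-1] - x[0])
        q_high = (x[-1] - x[-2]) / (x[-1] - x[0])
    elif n <= 10:
        stat = "r11"
        q_low = (x[1] - x[0]) / (x[-2] - x[0])
        q_high = (x[-1] - x[-2]) / (x[-1] - x[1])
    elif n <= 13:
        stat = "r21"
        q_low = (x[2] - x[0]) / (x[-2] - x[0])
        q_high = (x[-1] - x[-3]) / (x[-1] - x[1])
    else:
        stat = "r22"
        q_low = (x[2] - x[0]) / (x[-3] - x[0])
        q_high = (x[-1] - x[-3]) / (x[-1] - x[2])
    q_low = float(q_low) if np.isfinite(q_low) else 0.0
    q_high = float(q_high) if np.isfinite(q_high) else 0.0
    if q_high >= q_low:
        q, side, suspect = q_high, "high", float(x[-1])
    else:
        q, side, suspect = q_low, "low", float(x[0])
    crit = _DIXON_CRIT[alpha][n]
    return DixonResult(q, suspect, side, q > crit, stat, crit)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1).

    NaN entries are passed through untouched and do not count toward the
    number of tests.
    """
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise DomainError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out
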