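"""Group statistics: covariate screening, factorial ANCOVA, effect sizes.

The analysis stage compares parents of autistic children with comparison
parents on the masculinity score and the sex-discriminating facial
distances: Pearson screening of age and facial area as confounders, a
2 (family group) x 2 (sex) ANCOVA per variable with Type-III tests and
effects (Sum) coding, Bonferroni-adjusted significance, a
covariate-adjusted standardised mean difference d with a noncentral-t
confidence interval, an LDA classifying the children's diagnostic status
from the parents' facial variables, and kernel-density summaries of the
score distributions per group-by-sex cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .gender import FisherLDA, cv_accuracy

FAMILY_GROUPS = ("autism_parent", "comparison_parent")
SEXES = ("female", "male")


# -- covariate screening ---------------------------------------------------

@dataclass(frozen=True)
class CovariateScreenResult:
    variable: str
    covariate: str
    pearson_r: float
    p_value: float
    include: bool  # flagged for ANCOVA inclusion (p < alpha)


def screen_covariates(table: pd.DataFrame, variables: list[str],
                      covariates: tuple[str, ...] = ("age", "facial_area"),
                      alpha: float = 0.05) -> list[CovariateScreenResult]:
    """Pearson correlation of every (variable, covariate) pair.

    Pairs with two-sided p below ``alpha`` are flagged for inclusion as
    ANCOVA covariates.
    """
    out = []
    for var in variables:
        for cov in covariates:
            sub = table[[var, cov]].dropna()
            if len(sub) < 3:
                raise ValueError(
                    f"need >= 3 complete cases for ({var}, {cov})"
                )
            x = sub[var].to_numpy(dtype=float)
            y = sub[cov].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                raise ValueError(
                    f"zero-variance column in pair ({var}, {cov})"
                )
            r, p = sps.pearsonr(x, y)
            out.append(CovariateScreenResult(var, cov, float(r), float(p),
                                             bool(p < alpha)))
    return out


# -- Bonferroni ------------------------------------------------------------

def bonferroni_alpha(family_size: int, familywise_rate: float = 0.05) -> float:
    """Per-test alpha under Bonferroni correction."""
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    return familywise_rate / family_size


# -- factorial ANCOVA ------------------------------------------------------

@dataclass
class GroupComparisonResult:
    variable: str
    n: int
    F_group: float
    df_group: tuple[int, int]
    p_group: float
    d_adjusted: float
    d_ci95: tuple[float, float]
    F_sex: float
    p_sex: float
    d_sex: float
    F_interaction: float
    p_interaction: float
    covariates_used: list[str] = field(default_factory=list)
    alpha: float = 0.005
    significant: bool = False
    mse: float = float("nan")


def _d_ci_noncentral_t(t_obs: float, df: int, scale: float,
                       level: float = 0.95) -> tuple[float, float]:
    """CI for d = t * scale via noncentral-t pivoting on the ncp.

    ``sf(t_obs; df, ncp)`` increases with the ncp, so the lower CI bound
    is the ncp putting ``t_obs`` in the far right tail.
    """
    from scipy.optimize import brentq

    def bound(prob):
        f = lambda nc: sps.nct.sf(t_obs, df, nc) - prob
        lo, hi = t_obs - 10 - 5 * abs(t_obs), t_obs + 10 + 5 * abs(t_obs)
        return brentq(f, lo, hi, xtol=1e-8)

    nc_lo = bound((1 - level) / 2)
    nc_hi = bound((1 + level) / 2)
    return (nc_lo * scale, nc_hi * scale)


def ancova_test(table: pd.DataFrame, variable: str,
                covariates: tuple[str, ...] = ("facial_area", "age"),
                alpha: float = 0.005) -> GroupComparisonResult:
    """2 (family group) x 2 (sex) ANCOVA on one variable.

    Linear model: intercept + group + sex + group:sex (+ covariates),
    effects coding, Type-III F tests.  The adjusted effect size is

        d = (adjusted autism - comparison mean difference) / sqrt(MSE)

    positive when parents of autistic children have the larger (more
    masculine) adjusted mean, with a 95% CI from the noncentral-t
    distribution of its t statistic.  ``d_sex`` is male minus female.
    """
    cols = [variable, "family_group", "sex", *covariates]
    data = table[cols].dropna().copy()
    n = len(data)
    cells = data.groupby(["family_group", "sex"], observed=True).size()
    if len(cells) < 4 or cells.min() == 0:
        raise ValueError(
            f"{variable}: all four group x sex cells must be non-empty"
        )
    for cov in covariates:
        if data[cov].std() == 0:
            raise ValueError(f"constant covariate {cov!r}")

    rhs = "C(family_group, Sum) * C(sex, Sum)"
    for cov in covariates:
        rhs += f" + {cov}"
    model = smf.ols(f"Q('{variable}') ~ {rhs}", data=data).fit()
    if np.linalg.cond(model.model.exog) > 1e10:
        raise ValueError(
            f"{variable}: collinear design (condition number "
            f"{np.linalg.cond(model.model.exog):.2e})"
        )
    aov = anova_lm(model, typ=3)

    key_g = "C(family_group, Sum)"
    key_s = "C(sex, Sum)"
    key_gs = "C(family_group, Sum):C(sex, Sum)"
    df_resid = int(aov.loc["Residual", "df"])
    mse = float(aov.loc["Residual", "sum_sq"] / df_resid)

    # Sum coding: the group coefficient is the deviation of the first
    # level (autism_parent) from the unweighted grand mean, so the
    # adjusted group difference is twice the coefficient.
    coef_g = float(model.params[f"{key_g}[S.{FAMILY_GROUPS[0]}]"])
    se_g = float(model.bse[f"{key_g}[S.{FAMILY_GROUPS[0]}]"])
    diff_adj = 2.0 * coef_g
    d_adj = diff_adj / np.sqrt(mse)
    t_g = coef_g / se_g
    scale = 2.0 * se_g / np.sqrt(mse)
    d_ci = _d_ci_noncentral_t(t_g, df_resid, scale)

    coef_s = float(model.params[f"{key_s}[S.{SEXES[0]}]"])  # female deviation
    d_sex = (-2.0 * coef_s) / np.sqrt(mse)                  # male - female

    res = GroupComparisonResult(
        variable=variable,
        n=n,
        F_group=float(aov.loc[key_g, "F"]),
        df_group=(int(aov.loc[key_g, "df"]), df_resid),
        p_group=float(aov.loc[key_g, "PR(>F)"]),
        d_adjusted=float(d_adj),
        d_ci95=d_ci,
        F_sex=float(aov.loc[key_s, "F"]),
        p_sex=float(aov.loc[key_s, "PR(>F)"]),
        d_sex=float(d_sex),
        F_interaction=float(aov.loc[key_gs, "F"]),
        p_interaction=float(aov.loc[key_gs, "PR(>F)"]),
        covariates_used=list(covariates),
        alpha=alpha,
        mse=mse,
    )
    res.significant = bool(res.p_group < alpha)
    return res


def comparison_table(results: list[GroupComparisonResult],
                     table: pd.DataFrame) -> pd.DataFrame:
    """Result table mirroring the usual report layout: per-cell mean and
    s.d., then F, p, d and its CI for the family-group effect."""
    rows = []
    for r in results:
        row: dict[str, object] = {"variable": r.variable}
        for grp in FAMILY_GROUPS:
            for sex in ("male", "female"):
                cell = table[(table.family_group == grp) & (table.sex == sex)]
                row[f"M_{grp}_{sex}"] = cell[r.variable].mean()
                row[f"SD_{grp}_{sex}"] = cell[r.variable].std(ddof=1)
        row.update({
            "F": r.F_group, "df1": r.df_group[0], "df2": r.df_group[1],
            "p": r.p_group, "d": r.d_adjusted,
            "d_ci_low": r.d_ci95[0], "d_ci_high": r.d_ci95[1],
            "significant": r.significant,
        })
        rows.append(row)
    return pd.DataFrame(rows)


# -- diagnosis-status classification --------------------------------------

def classify_diagnosis(table: pd.DataFrame, variables: list[str],
                       k: int = 10, seed: int = 0,
                       balance: bool = False) -> float:
    """Stratified k-fold CV accuracy of an LDA predicting family group
    (child diagnosis status) from the parents' facial variables.

    With ``balance=True`` the majority group is seeded-downsampled to the
    minority size before CV, so chance accuracy is 0.5.
    """
    data = table[[*variables, "family_group"]].dropna()
    if balance:
        rng = np.random.default_rng(seed)
        groups = [g for _, g in data.groupby("family_group", observed=True)]
        n_min = min(len(g) for g in groups)
        data = pd.concat([
            g.iloc[rng.permutation(len(g))[:n_min]] for g in groups
        ])
    X = data[list(variables)]
    y = data["family_group"].to_numpy()
    return cv_accuracy(FisherLDA(), X, y, k=k, seed=seed)


# -- score density summaries ----------------------------------------------

@dataclass
class CellDensity:
    family_group: str
    sex: str
    n: int
    grid: np.ndarray
    density: np.ndarray
    mode: float
    mean: float


def density_report(scores: pd.DataFrame, score_col: str = "masculinity_score",
                   grid_size: int = 512) -> list[CellDensity]:
    """Per group-x-sex cell kernel density of masculinity scores on [0, 1].

    Gaussian KDE with Silverman bandwidth, reflected at both boundaries so
    each density integrates to 1 over the unit interval.  A degenerate
    cell (zero variance) falls back to a narrow Gaussian at its value.
    """
    grid = np.linspace(0.0, 1.0, grid_size)
    out = []
    for (grp, sex), cell in scores.groupby(["family_group", "sex"],
                                           observed=True):
        vals = np.clip(cell[score_col].to_numpy(dtype=float), 0.0, 1.0)
        if len(vals) < 5:
            raise ValueError(
                f"cell ({grp}, {sex}) has {len(vals)} subjects; >= 5 required"
            )
        if np.std(vals) < 1e-12:
            dens = sps.norm.pdf(grid, loc=vals[0], scale=0.005)
            dens += sps.norm.pdf(-grid, loc=vals[0], scale=0.005)
            dens += sps.norm.pdf(2 - grid, loc=vals[0], scale=0.005)
        else:
            kde = sps.gaussian_kde(vals, bw_method="silverman")
            dens = kde(grid) + kde(-grid) + kde(2.0 - grid)
        out.append(CellDensity(
            family_group=grp, sex=sex, n=len(vals), grid=grid, density=dens,
            mode=float(grid[np.argmax(dens)]), mean=float(np.mean(vals)),
        ))
    return out


def density_table(cells: list[CellDensity]) -> pd.DataFrame:
    """Flatten density summaries to a long-format grid table (CSV-ready)."""
    frames = []
    for c in cells:
        frames.append(pd.DataFrame({
            "family_group": c.family_group, "sex": c.sex,
            "score": c.grid, "density": c.density,
        }))
    return pd.concat(frames, ignore_index=True)
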