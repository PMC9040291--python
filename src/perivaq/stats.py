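"""Group comparison statistics for nested imaging measures.

The layer mirrors how perivascular quantification is analysed in practice:
one- and two-way ANOVA with Dunnett / Tukey / Sidak post hoc corrections,
linear mixed models with a random intercept per animal or subject (vessels
and ROIs are pseudo-replicates nested in animals), Welch two-sample t-tests,
and ordinary least squares with covariate control plus partial-regression
coordinates for visualisation.

Raw (unadjusted) pairwise p-values are always computed from the same pooled
error as the adjusted ones, so adjusted >= raw holds exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

__all__ = [
    "StatsResult",
    "anova_posthoc",
    "mixed_model",
    "regression_partial",
    "unpaired_t",
]

log = logging.getLogger(__name__)


@dataclass
class StatsResult:
    """Uniform result record for every test in the layer."""

    model: str
    effects: pd.DataFrame  # term-level estimates / F tests
    comparisons: pd.DataFrame | None = None  # pairwise contrasts with p_raw <= p_adj
    r2: float | None = None
    r2_adj: float | None = None
    group_ns: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    @property
    def pvalue(self) -> float:
        """Headline p-value: the first effect row's p."""
        return float(self.effects["p"].iloc[0])


def _check_groups(values_by_group: dict[str, np.ndarray], min_n: int = 2) -> None:
    if len(values_by_group) < 2:
        raise ValueError("need at least two groups")
    for g, v in values_by_group.items():
        if len(v) < min_n:
            raise ValueError(f"group {g!r} has {len(v)} observation(s); need >= {min_n}")


def _split(values, groups) -> dict[str, np.ndarray]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    return {str(g): values[groups == g] for g in pd.unique(groups)}


def anova_posthoc(
    values,
    groups,
    design: str = "one_way",
    correction: str = "tukey",
    reference: str | None = None,
    factor2=None,
) -> StatsResult:
    """ANOVA with named post hoc pairwise comparisons.

    ``correction`` is one of ``dunnett`` ((k-1) comparisons against
    ``reference``), ``tukey`` (all k(k-1)/2 pairs) or ``sidak`` (all pairs,
    Sidak-adjusted Welch tests).  ``design='two_way'`` additionally needs
    ``factor2`` and tests both main effects and their interaction; post hoc
    comparisons then run over the cell means.
    """
    if design not in ("one_way", "two_way"):
        raise ValueError(f"unknown design {design!r}")
    if design == "two_way":
        return _two_way(values, groups, factor2, correction, reference)
    by = _split(values, groups)
    _check_groups(by)
    labels = list(by)
    ns = {g: len(v) for g, v in by.items()}
    means = {g: float(np.mean(v)) for g, v in by.items()}
    N, k = sum(ns.values()), len(labels)
    df_within = N - k
    sse = sum(float(np.sum((v - means[g]) ** 2)) for g, v in by.items())
    grand = float(np.mean(np.concatenate(list(by.values()))))
    ssb = sum(ns[g] * (means[g] - grand) ** 2 for g in labels)
    mse = sse / df_within
    if mse == 0:
        distinct = len(set(means.values())) > 1
        f_stat, p = (np.inf, 0.0) if distinct else (0.0, 1.0)
        log.info("zero within-group variance: F treated as %s", f_stat)
    else:
        f_stat = (ssb / (k - 1)) / mse
        p = float(sps.f.sf(f_stat, k - 1, df_within))
    effects = pd.DataFrame(
        [{"term": "group", "F": f_stat, "df1": k - 1, "df2": df_within, "p": p}]
    )
    comparisons = _pairwise(by, correction, reference, mse, df_within)
    return StatsResult(
        model=f"one-way ANOVA + {correction}",
        effects=effects,
        comparisons=comparisons,
        group_ns=ns,
    )


def _pooled_t(a, b, mse, dfw) -> tuple[float, float]:
    """Pairwise t on the pooled ANOVA error; returns (estimate, raw p)."""
    diff = float(np.mean(a) - np.mean(b))
    if mse == 0:
        return diff, (1.0 if diff == 0 else 0.0)
    se = np.sqrt(mse * (1 / len(a) + 1 / len(b)))
    return diff, float(2 * sps.t.sf(abs(diff) / se, dfw))


def _pairwise(by, correction, reference, mse, dfw) -> pd.DataFrame:
    labels = list(by)
    rows = []
    if correction == "dunnett":
        if reference is None:
            raise ValueError("Dunnett correction needs a reference group")
        if reference not in by:
            raise ValueError(f"reference group {reference!r} not found in {labels}")
        treat = [g for g in labels if g != reference]
        if mse == 0:
            adj = [(1.0 if np.mean(by[g]) == np.mean(by[reference]) else 0.0) for g in treat]
        else:
            # fixed rng: the Dunnett p integrates a multivariate t by
            # quasi-Monte Carlo; seeding makes reruns byte-identical
            res = sps.dunnett(*[by[g] for g in treat], control=by[reference], rng=0)
            adj = list(np.atleast_1d(res.pvalue))
        for g, pa in zip(treat, adj):
            est, praw = _pooled_t(by[g], by[reference], mse, dfw)
            rows.append((f"{g} - {reference}", est, praw, max(pa, praw)))
    elif correction == "tukey":
        if mse == 0:
            padj_fn = None
            res = None
        else:
            res = sps.tukey_hsd(*[by[g] for g in labels])
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                est, praw = _pooled_t(by[labels[i]], by[labels[j]], mse, dfw)
                pa = praw if mse == 0 else float(res.pvalue[i, j])
                rows.append((f"{labels[i]} - {labels[j]}", est, praw, max(pa, praw)))
    elif correction == "sidak":
        pairs = [(i, j) for i in range(len(labels)) for j in range(i + 1, len(labels))]
        m = len(pairs)
        for i, j in pairs:
            a, b = by[labels[i]], by[labels[j]]
            t_res = sps.ttest_ind(a, b, equal_var=False)
            praw = float(t_res.pvalue)
            if np.isnan(praw):  # zero variance in both samples
                praw = 1.0 if np.mean(a) == np.mean(b) else 0.0
            pa = float(1 - (1 - praw) ** m)
            rows.append(
                (f"{labels[i]} - {labels[j]}", float(np.mean(a) - np.mean(b)), praw, max(pa, praw))
            )
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return pd.DataFrame(rows, columns=["contrast", "estimate", "p_raw", "p_adj"])


def _two_way(values, f1, f2, correction, reference) -> StatsResult:
    if f2 is None:
        raise ValueError("two-way design needs factor2")
    df = pd.DataFrame({"value": np.asarray(values, float), "f1": f1, "f2": f2})
    cell_counts = df.groupby(["f1", "f2"]).size()
    if (cell_counts < 2).any():
        bad = cell_counts[cell_counts < 2].index.tolist()
        raise ValueError(f"cells with < 2 observations: {bad}")
    fit = smf.ols("value ~ C(f1) * C(f2)", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    effects = pd.DataFrame(
        {
            "term": ["f1", "f2", "f1:f2"],
            "F": table["F"].iloc[:3].to_numpy(),
            "df1": table["df"].iloc[:3].to_numpy(),
            "df2": table["df"].iloc[-1],
            "p": table["PR(>F)"].iloc[:3].to_numpy(),
        }
    )
    cells = {
        f"{a}/{b}": sub["value"].to_numpy() for (a, b), sub in df.groupby(["f1", "f2"])
    }
    mse = float(fit.mse_resid)
    comparisons = _pairwise(cells, correction, reference, mse, int(fit.df_resid))
    return StatsResult(
        model=f"two-way ANOVA + {correction}",
        effects=effects,
        comparisons=comparisons,
        group_ns={g: len(v) for g, v in cells.items()},
        extras={"anova_table": table},
    )


def mixed_model(
    data: pd.DataFrame,
    value_col: str = "value",
    group_col: str = "group",
    cluster_col: str = "animal",
    covariate_cols: tuple[str, ...] = (),
    correction: str = "sidak",
    reference: str | None = None,
) -> StatsResult:
    """Random-intercept mixed model for measures nested in animals/subjects.

    value ~ group (+ covariates) with a random intercept per cluster, fitted
    by REML.  Fixed effects are tested on t with between-within denominator
    degrees of freedom (terms constant within clusters are judged against
    the number of clusters, not the number of vessels), which keeps type-I
    error near nominal for the few-animal designs this is built for.
    Missing values are dropped listwise with a logged count.
    """
    cols = [value_col, group_col, cluster_col, *covariate_cols]
    df = data[cols].copy()
    n0 = len(df)
    df = df.dropna()
    if len(df) < n0:
        log.info("mixed_model: dropped %d row(s) with missing values", n0 - len(df))
    clusters = df[cluster_col].unique()
    if len(clusters) < 2:
        raise ValueError(
            "only one cluster: fit an ordinary fixed-effects model instead"
        )
    rhs = f"C({group_col})" + "".join(f" + {c}" for c in covariate_cols)
    md = smf.mixedlm(f"{value_col} ~ {rhs}", df, groups=df[cluster_col])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary variance fits warn; handled below
        fit = md.fit(reml=True)
        if not fit.converged or not np.all(np.isfinite(fit.bse_fe)):
            fit = md.fit(reml=True, method="powell")

    exog = pd.DataFrame(md.exog, columns=md.exog_names)
    exog[cluster_col] = df[cluster_col].to_numpy()
    between_level = {
        name: (exog.groupby(cluster_col)[name].nunique() == 1).all()
        for name in md.exog_names
    }
    q_between = sum(between_level.values())
    G, N, p_total = len(clusters), len(df), len(md.exog_names)
    df_between = max(G - q_between, 1)
    df_within = max(N - G - (p_total - q_between), 1)

    rows = []
    for name in md.exog_names:
        est, se = float(fit.params[name]), float(fit.bse[name])
        ddf = df_between if between_level[name] else df_within
        t = est / se if se > 0 else np.inf
        rows.append(
            {
                "term": name,
                "estimate": est,
                "se": se,
                "t": t,
                "df": ddf,
                "p": float(2 * sps.t.sf(abs(t), ddf)),
            }
        )
    effects = pd.DataFrame(rows)
    # headline row first: group effect(s) before intercept/covariates
    is_group = effects["term"].str.startswith(f"C({group_col})")
    effects = pd.concat([effects[is_group], effects[~is_group]], ignore_index=True)

    comparisons = _mixed_posthoc(
        fit, md, df, group_col, df_between, correction, reference
    )
    var_re = float(np.asarray(fit.cov_re)[0, 0])
    return StatsResult(
        model=f"mixed model (random intercept per {cluster_col}) + {correction}",
        effects=effects,
        comparisons=comparisons,
        group_ns=df.groupby(group_col).size().to_dict(),
        extras={
            "cluster_sd": float(np.sqrt(var_re)),
            "residual_sd": float(np.sqrt(fit.scale)),
            "n_clusters": int(G),
            "df_between": int(df_between),
            "df_within": int(df_within),
        },
    )


def _mixed_posthoc(fit, md, df, group_col, ddf, correction, reference):
    levels = sorted(df[group_col].astype(str).unique())
    if len(levels) < 2:
        return None
    base = levels[0]
    coef = {base: 0.0}
    var = {base: 0.0}
    names = {}
    for lv in levels[1:]:
        name = f"C({group_col})[T.{lv}]"
        if name not in fit.params.index:
            return None
        names[lv] = name
        coef[lv] = float(fit.params[name])
    cov = fit.cov_params()
    if correction == "dunnett" and reference is not None:
        pairs = [(lv, reference) for lv in levels if lv != reference]
    else:
        pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1 :]]
    m = len(pairs)
    rows = []
    for a, b in pairs:
        est = coef[a] - coef[b]
        v = 0.0
        na, nb = names.get(a), names.get(b)
        if na:
            v += cov.loc[na, na]
        if nb:
            v += cov.loc[nb, nb]
        if na and nb:
            v -= 2 * cov.loc[na, nb]
        se = float(np.sqrt(max(v, 0.0)))
        t = est / se if se > 0 else np.inf
        praw = float(2 * sps.t.sf(abs(t), ddf))
        padj = float(1 - (1 - praw) ** m)  # Sidak family adjustment
        rows.append((f"{a} - {b}", est, praw, max(padj, praw)))
    return pd.DataFrame(rows, columns=["contrast", "estimate", "p_raw", "p_adj"])


def regression_partial(
    data: pd.DataFrame,
    response: str,
    predictor: str,
    covariates: tuple[str, ...] = (),
) -> StatsResult:
    """OLS of ``response`` on ``predictor`` controlling for ``covariates``.

    Besides the coefficient table, returns partial-regression coordinates:
    residuals of response ~ covariates against residuals of
    predictor ~ covariates.  By the Frisch-Waugh-Lovell identity the slope
    through those pairs equals the multiple-regression coefficient exactly.
    """
    cols = [response, predictor, *covariates]
    df = data[cols].dropna().copy()
    n = len(df)
    if n <= len(covariates) + 2:
        raise ValueError(f"n={n} too small for {len(covariates) + 1} predictors")
    X = sm.add_constant(df[[predictor, *covariates]])
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = df[[predictor, *covariates]].corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax()
        raise ValueError(f"collinear design (worst pair: {worst[0]} ~ {worst[1]})")
    fit = sm.OLS(df[response], X).fit()

    Z = sm.add_constant(df[list(covariates)]) if covariates else np.ones((n, 1))
    ry = sm.OLS(df[response], Z).fit().resid
    rx = sm.OLS(df[predictor], Z).fit().resid
    effects = pd.DataFrame(
        [
            {
                "term": predictor,
                "estimate": float(fit.params[predictor]),
                "se": float(fit.bse[predictor]),
                "t": float(fit.tvalues[predictor]),
                "df": float(fit.df_resid),
                "p": float(fit.pvalues[predictor]),
            }
        ]
    )
    return StatsResult(
        model=f"OLS {response} ~ {predictor}"
        + (f" + {' + '.join(covariates)}" if covariates else ""),
        effects=effects,
        r2=float(fit.rsquared),
        r2_adj=float(fit.rsquared_adj),
        group_ns={"n": n},
        extras={
            "partial_pairs": np.column_stack([np.asarray(rx), np.asarray(ry)]),
            "all_params": fit.params.to_dict(),
        },
    )


def unpaired_t(a, b, welch: bool = True) -> StatsResult:
    """Two-sample t-test (Welch by default; pooled-variance selectable)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            log.info("both samples constant and equal: t=0, p=1 by convention")
            t, p = 0.0, 1.0
        else:
            t, p = np.inf, 0.0
    else:
        res = sps.ttest_ind(a, b, equal_var=not welch)
        t, p = float(res.statistic), float(res.pvalue)
    effects = pd.DataFrame(
        [
            {
                "term": "mean difference",
                "estimate": float(a.mean() - b.mean()),
                "t": t,
                "p": p,
            }
        ]
    )
    return StatsResult(
        model="Welch t-test" if welch else "pooled t-test",
        effects=effects,
        group_ns={"a": len(a), "b": len(b)},
    )
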