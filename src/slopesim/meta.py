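"""Meta-analysis of condition-level Monte Carlo outcomes.

The unit of analysis is the design condition (one row per condition,
e.g. 648 for the default grid); per-replication outcomes are never fed
to these ANOVAs.  All six design factors are treated as categorical.
Effect sizes are eta-squared, eta^2 = SS_term / SS_total.  Post-hoc
pairwise comparisons use Tukey's HSD on the studentized-range
distribution with the residual mean square of the fitted ANOVA,
conventionally gated at eta^2 > 0.03.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.anova import anova_lm

__all__ = [
    "DESIGN_FACTORS",
    "IncompleteFactorialError",
    "anova_eta2",
    "tukey_hsd",
    "threshold_percentages",
]

#: The six design factors, as columns of a grid summary table.
DESIGN_FACTORS = (
    "n_waves",
    "class_size",
    "n_classrooms",
    "prop_treatment",
    "icc",
    "effect_label",
)


class IncompleteFactorialError(ValueError):
    """The summary table is not a complete balanced factorial."""


def _check_balanced(summaries: pd.DataFrame, factors=DESIGN_FACTORS) -> None:
    missing_cols = [f for f in factors if f not in summaries.columns]
    if missing_cols:
        raise IncompleteFactorialError(f"missing factor column(s): {missing_cols}")
    levels = {f: sorted(summaries[f].unique()) for f in factors}
    counts = summaries.groupby(list(factors), sort=False).size()
    n_expected = int(np.prod([len(v) for v in levels.values()]))
    if len(counts) != n_expected or counts.nunique() != 1:
        present = set(counts.index)
        missing = [
            cell
            for cell in itertools.product(*(levels[f] for f in factors))
            if cell not in present
        ]
        raise IncompleteFactorialError(
            f"incomplete/unbalanced factorial: {len(missing)} missing cell(s), "
            f"e.g. {missing[:5]}"
        )


def _clean_term(term: str) -> str:
    return term.replace("C(", "").replace(")", "").replace(":", " x ")


def anova_eta2(
    summaries: pd.DataFrame,
    outcome: str,
    include_two_way: bool = False,
    factors=DESIGN_FACTORS,
) -> pd.DataFrame:
    """Fixed-effects ANOVA of a condition-level outcome on the design factors.

    ``include_two_way`` adds all pairwise factor interactions (the
    convention for power; convergence and singularity use main effects
    only).  Returns one row per term plus the residual, with columns
    ``term, F, df, p, eta_squared``.
    """
    _check_balanced(summaries, factors)
    if outcome not in summaries.columns:
        raise ValueError(f"unknown outcome column {outcome!r}")
    terms = [f"C({f})" for f in factors]
    if include_two_way:
        terms += [f"C({a}):C({b})" for a, b in itertools.combinations(factors, 2)]
    formula = f"Q('{outcome}') ~ " + " + ".join(terms)
    fit = smf.ols(formula, data=summaries).fit()
    tab = anova_lm(fit, typ=2)
    ss_total = float(tab["sum_sq"].sum())
    # a (numerically) constant outcome has no variance to decompose
    scale = float(summaries[outcome].abs().max()) + 1.0
    if ss_total <= 1e-12 * scale**2 * len(summaries):
        ss_total = 0.0
    rows = []
    for term, r in tab.iterrows():
        rows.append(
            {
                "term": _clean_term(term) if term != "Residual" else "Residual",
                "F": float(r["F"]) if np.isfinite(r["F"]) else np.nan,
                "df": int(r["df"]),
                "p": float(r["PR(>F)"]) if np.isfinite(r["PR(>F)"]) else np.nan,
                "eta_squared": float(r["sum_sq"]) / ss_total if ss_total > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def tukey_hsd(
    summaries: pd.DataFrame,
    factor: str,
    outcome: str,
    alpha: float = 0.05,
    factors=DESIGN_FACTORS,
) -> pd.DataFrame:
    """All pairwise level comparisons of one factor, Tukey-adjusted.

    The error term is the residual mean square of the main-effects
    ANOVA of ``outcome`` on all design factors, which controls the
    family-wise error rate at ``alpha`` across the factor's pairs.
    Returns ``factor, level_1, level_2, mean_difference, p_unadjusted,
    adjusted_p, significant``.
    """
    _check_balanced(summaries, factors)
    if factor not in factors:
        raise ValueError(f"unknown factor {factor!r}")
    levels = sorted(summaries[factor].unique())
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has a single level")
    terms = " + ".join(f"C({f})" for f in factors)
    fit = smf.ols(f"Q('{outcome}') ~ {terms}", data=summaries).fit()
    mse = float(fit.mse_resid)
    df_resid = float(fit.df_resid)
    k = len(levels)
    groups = summaries.groupby(factor)[outcome]
    means = groups.mean()
    ns = groups.size()
    rows = []
    for a, b in itertools.combinations(levels, 2):
        diff = float(means[b] - means[a])
        # Tukey-Kramer standard error; equals sqrt(MSE/n) for balanced groups
        se_q = np.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
        q = abs(diff) / se_q if se_q > 0 else np.inf
        p_adj = float(sps.studentized_range.sf(q, k, df_resid))
        t = q / np.sqrt(2.0)
        p_un = float(2.0 * sps.t.sf(t, df_resid))
        rows.append(
            {
                "factor": factor,
                "level_1": a,
                "level_2": b,
                "mean_difference": diff,
                "p_unadjusted": p_un,
                "adjusted_p": min(p_adj, 1.0),
                "significant": p_adj < alpha,
            }
        )
    return pd.DataFrame(rows)


def threshold_percentages(
    summaries: pd.DataFrame,
    outcome: str,
    predicate,
    slice_factors,
) -> pd.DataFrame:
    """Percentage of conditions satisfying ``predicate`` within each slice.

    ``predicate`` is a vectorizable callable on the outcome values (e.g.
    ``lambda p: p < 0.8`` for "underpowered").  Slices over the full
    cross of the observed levels of ``slice_factors``; combinations
    absent from ``summaries`` are reported with a missing percentage
    rather than zero.
    """
    slice_factors = list(slice_factors)
    for f in slice_factors:
        if f not in summaries.columns:
            raise ValueError(f"unknown slice factor {f!r}")
    flags = np.asarray(predicate(summaries[outcome].to_numpy()), dtype=float)
    work = summaries[slice_factors].copy()
    work["_flag"] = flags
    grouped = work.groupby(slice_factors)["_flag"].agg(["mean", "size"])
    if len(slice_factors) == 1:
        full = pd.Index(sorted(summaries[slice_factors[0]].unique()),
                        name=slice_factors[0])
    else:
        full = pd.MultiIndex.from_product(
            [sorted(summaries[f].unique()) for f in slice_factors],
            names=slice_factors,
        )
    grouped = grouped.reindex(full)
    out = grouped.reset_index()
    out["percent"] = out["mean"] * 100.0
    out["n"] = out["size"]
    return out.drop(columns=["mean", "size"])
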