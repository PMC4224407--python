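"""Study-level statistics: factorial ANOVA, Tukey HSD, descriptives.

The study design crosses the bedrest intervention with disc level and
region; fixed-effects factorial ANOVA with all interactions tests the
main effects and their interactions (Type II sums of squares, which for
a balanced design coincide with the classical decomposition and are
invariant to factor order).  Where an effect is significant at alpha,
pairwise group differences are assessed with Tukey's honestly significant
difference test based on the studentized range distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import studentized_range
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import DesignError, GroupingError, InputError

__all__ = [
    "AnovaResult",
    "TukeyResult",
    "factorial_anova",
    "tukey_hsd",
    "describe",
]

ALPHA_DEFAULT = 0.05


@dataclass
class AnovaResult:
    """Fixed-effects ANOVA table.

    ``table`` has one row per effect (main factors, then interactions,
    then Residual) with columns sum_sq, df, F, p.
    """

    table: pd.DataFrame
    response: str
    factors: tuple[str, ...]
    alpha: float = ALPHA_DEFAULT

    @property
    def residual_ss(self) -> float:
        return float(self.table.loc["Residual", "sum_sq"])

    @property
    def residual_df(self) -> float:
        return float(self.table.loc["Residual", "df"])

    def significant_effects(self) -> list[str]:
        eff = self.table.drop(index="Residual")
        return list(eff.index[eff["p"] < self.alpha])


@dataclass
class TukeyResult:
    """Pairwise Tukey HSD comparisons for one factor.

    ``table`` columns: group1, group2, diff (mean(group1)-mean(group2)),
    q (studentized-range statistic), p_adj, reject.
    """

    table: pd.DataFrame
    factor: str
    mse: float
    df_resid: int
    alpha: float = ALPHA_DEFAULT


def _check_table(table: pd.DataFrame, response: str, factors) -> pd.DataFrame:
    missing = [c for c in (response, *factors) if c not in table.columns]
    if missing:
        raise InputError(f"columns missing from table: {missing}")
    data = table[[response, *factors]].dropna()
    if not len(data):
        raise InputError("no complete observations")
    return data


def factorial_anova(
    table: pd.DataFrame,
    response: str,
    factors: list[str] | tuple[str, ...],
    alpha: float = ALPHA_DEFAULT,
) -> AnovaResult:
    """Fixed-effects factorial ANOVA with all interactions.

    Each factor needs >= 2 observed levels and the design must leave at
    least one residual degree of freedom.  Aliased (confounded) factors
    raise :class:`DesignError`.  Unbalanced designs use Type II sums of
    squares; for balanced designs these equal the classical decomposition.
    """
    factors = tuple(factors)
    if not (1 <= len(factors) <= 3):
        raise DesignError("supply 1 to 3 factors")
    data = _check_table(table, response, factors)
    for f in factors:
        if data[f].nunique() < 2:
            raise DesignError(f"factor {f!r} has fewer than 2 levels")

    rhs = " * ".join(f"C(Q('{f}'))" for f in factors)
    model = smf.ols(f"Q('{response}') ~ {rhs}", data=data).fit()
    if model.df_resid < 1:
        raise DesignError("no residual degrees of freedom")
    # aliased factors leave the design matrix rank-deficient
    exog = model.model.exog
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise DesignError("factors are aliased (rank-deficient design matrix)")

    aov = sm.stats.anova_lm(model, typ=2)
    aov = aov.rename(columns={"PR(>F)": "p"})

    def _clean(name: str) -> str:
        name = name.replace("C(Q('", "").replace("'))", "")
        return name
    aov.index = [_clean(i) for i in aov.index]
    aov = aov[["sum_sq", "df", "F", "p"]]
    return AnovaResult(table=aov, response=response, factors=factors, alpha=alpha)


def tukey_hsd(
    table: pd.DataFrame,
    response: str,
    factor: str,
    alpha: float = ALPHA_DEFAULT,
) -> TukeyResult:
    """Tukey HSD pairwise comparisons over the levels of one factor.

    Uses the residual mean square of the one-factor fit; the adjusted p
    of a pair is the studentized-range tail probability of
    q = |diff| / sqrt(MSE/2 * (1/n1 + 1/n2)) at (k groups, residual df).
    Every group needs n >= 2.
    """
    data = _check_table(table, response, [factor])
    groups = {lev: np.asarray(g[response], dtype=float)
              for lev, g in data.groupby(factor, observed=True)}
    if len(groups) < 2:
        raise GroupingError("need at least 2 groups")
    for lev, v in groups.items():
        if v.size < 2:
            raise GroupingError(f"group {lev!r} has n < 2")

    k = len(groups)
    n_total = sum(v.size for v in groups.values())
    df_resid = n_total - k
    sse = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    mse = sse / df_resid

    rows = []
    levels = sorted(groups)
    for i in range(k):
        for j in range(i + 1, k):
            g1, g2 = levels[i], levels[j]
            v1, v2 = groups[g1], groups[g2]
            diff = float(v1.mean() - v2.mean())
            se = np.sqrt(mse / 2.0 * (1.0 / v1.size + 1.0 / v2.size))
            q = abs(diff) / se if se > 0 else np.inf
            p_adj = float(np.clip(studentized_range.sf(q, k, df_resid), 0.0, 1.0))
            rows.append({"group1": g1, "group2": g2, "diff": diff,
                         "q": float(q), "p_adj": p_adj, "reject": p_adj < alpha})
    return TukeyResult(table=pd.DataFrame(rows), factor=factor,
                       mse=float(mse), df_resid=int(df_resid), alpha=alpha)


def describe(values) -> tuple[float, float | None, int]:
    """Arithmetic mean, sample sd (n-1 denominator) and n.

    The sd is None for a single observation.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 1:
        raise InputError("values must be a non-empty 1-D sequence")
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size >= 2 else None
    return mean, sd, int(v.size)
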