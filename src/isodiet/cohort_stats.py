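"""Group-comparison statistics: two-way ANOVA and Tukey HSD.

Sequential (Type-I) sums of squares in the declared term order, as fit
by ordinary least squares; post-hoc pairwise comparisons via the
studentized-range (Tukey HSD) procedure.  With unbalanced groups the SS
type and term order matter, so both are explicit and configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = ["AnovaResult", "DesignError", "two_way_anova", "tukey_hsd"]


class DesignError(ValueError):
    """The factorial design cannot be estimated (e.g. empty cells)."""


@dataclass
class AnovaResult:
    """ANOVA table: one row per term plus the residual.

    ``table`` columns: ``sum_sq``, ``df``, ``F``, ``p``; the index holds
    term names in fitted (sequential) order, with ``Residual`` last.
    """

    table: pd.DataFrame
    term_order: Tuple[str, ...]

    @property
    def residual_ss(self) -> float:
        return float(self.table.loc["Residual", "sum_sq"])

    @property
    def residual_df(self) -> int:
        return int(self.table.loc["Residual", "df"])

    def f_statistic(self, term: str) -> float:
        return float(self.table.loc[term, "F"])

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "p"])


def two_way_anova(
    values: Sequence[float],
    factor_a: Sequence[str],
    factor_b: Sequence[str],
    *,
    names: Tuple[str, str] = ("A", "B"),
    include_interaction: bool = True,
) -> AnovaResult:
    """Two-way fixed-effects ANOVA with sequential (Type-I) SS.

    Terms enter in the order (factor_a, factor_b, interaction); swap the
    arguments to swap the order — in balanced designs the decomposition
    is order-invariant, in unbalanced designs it is not.  The
    interaction requires every a x b cell to be occupied; an empty cell
    raises :class:`DesignError`.
    """
    y = np.asarray(values, dtype=float)
    a = np.asarray(factor_a, dtype=object)
    b = np.asarray(factor_b, dtype=object)
    if not (len(y) == len(a) == len(b)):
        raise ValueError("values and factors must have equal length")
    if len(set(a)) < 2 or len(set(b)) < 2:
        raise DesignError("each factor needs at least 2 levels")
    if include_interaction:
        counts = pd.crosstab(pd.Series(a), pd.Series(b))
        if (counts == 0).any().any():
            raise DesignError(
                "empty factor cells: interaction is inestimable "
                "(use include_interaction=False)"
            )
    n_params = len(set(a)) + len(set(b)) - 1
    if include_interaction:
        n_params = len(set(a)) * len(set(b))
    if len(y) <= n_params:
        raise DesignError("not enough observations for the model")

    df = pd.DataFrame({"y": y, "fa": a.astype(str), "fb": b.astype(str)})
    terms = ["C(fa)", "C(fb)"] + (["C(fa):C(fb)"] if include_interaction else [])
    fit = smf.ols("y ~ " + " + ".join(terms), data=df).fit()
    table = sm.stats.anova_lm(fit, typ=1)

    pretty = {
        "C(fa)": names[0],
        "C(fb)": names[1],
        "C(fa):C(fb)": f"{names[0]}:{names[1]}",
    }
    table = table.rename(index=pretty)
    table = table.rename(columns={"PR(>F)": "p"})
    table["df"] = table["df"].astype(int)

    if np.ptp(y) == 0.0:  # constant response: define F = 0, p = 1
        term_rows = table.index != "Residual"
        table.loc[term_rows, "F"] = 0.0
        table.loc[term_rows, "p"] = 1.0

    order = tuple(t for t in table.index if t != "Residual")
    return AnovaResult(table=table[["sum_sq", "df", "F", "p"]], term_order=order)


def tukey_hsd(
    values: Sequence[float],
    groups: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All pairwise group comparisons with Tukey HSD adjustment.

    Returns a DataFrame with one row per pair: ``group1``, ``group2``,
    ``meandiff``, ``p_adj`` (from the studentized-range distribution,
    computed numerically), ``lower``/``upper`` simultaneous confidence
    bounds at ``1 - alpha``, and ``reject``.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups, dtype=object).astype(str)
    if len(y) != len(g):
        raise ValueError("values and groups must have equal length")
    labels, counts = np.unique(g, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if np.any(counts < 2):
        bad = labels[counts < 2].tolist()
        raise ValueError(f"singleton group(s): {bad}")

    res = pairwise_tukeyhsd(endog=y, groups=g, alpha=alpha)
    frame = pd.DataFrame(
        res.summary().data[1:],
        columns=[c.replace("-", "_") for c in res.summary().data[0]],
    )
    frame = frame.rename(columns={"p_adj": "p_adj", "meandiff": "meandiff"})
    # summary() rounds; take exact values from the result object
    frame["meandiff"] = res.meandiffs
    frame["p_adj"] = res.pvalues
    frame["lower"] = res.confint[:, 0]
    frame["upper"] = res.confint[:, 1]
    frame["reject"] = res.reject
    return frame[["group1", "group2", "meandiff", "p_adj", "lower", "upper", "reject"]]
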