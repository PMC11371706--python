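"""Behavioural statistics: infestation rates and egg-laying ANOVA.

Oviposition is standardised to eggs per gram of fruit (egg count divided by
berry weight), log(x+1) transformed, and analysed by fixed-effects n-way
ANOVA with sequential sums of squares — in a balanced design the term sums of
squares are order-invariant. Pairwise cultivar differences use Bonferroni-
adjusted two-sample t tests summarised as a compact letter display.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats


def infestation_rate(infested: int, total: int) -> float:
    """Percentage of infested berries, to one decimal (e.g. 13/30 -> 43.3)."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= infested <= total:
        raise ValueError("infested must lie in [0, total]")
    return round(100.0 * infested / total, 1)


def eggs_per_gram(eggs: float, weight_g: float) -> float:
    """Egg count standardised by berry weight."""
    if weight_g <= 0:
        raise ValueError("berry weight must be positive")
    if eggs < 0:
        raise ValueError("egg count must be non-negative")
    return eggs / weight_g


def _check_balanced(table: pd.DataFrame, factors: list[str]) -> None:
    counts = table.groupby(factors, observed=True).size()
    n_cells = int(np.prod([table[f].nunique() for f in factors]))
    if len(counts) != n_cells:
        raise ValueError(
            f"unbalanced design over {factors}: {n_cells - len(counts)} empty cells "
            "(sequential sums of squares would be order-dependent)"
        )
    if counts.nunique() != 1:
        raise ValueError(
            f"unbalanced design over {factors}: cell sizes {sorted(counts.unique())} "
            "(sequential sums of squares would be order-dependent)"
        )


def anova_nway(
    table: pd.DataFrame,
    terms: list[str],
    response: str = "eggs_per_gram",
    transform: str = "log1p",
) -> pd.DataFrame:
    """Fixed-effects ANOVA of (transformed) eggs per gram on design terms.

    ``terms`` may contain factor names and interactions written ``"A:B"``.
    The response is log(x+1) transformed by default (natural log; F and p are
    base-invariant). The design must be balanced over the crossed factors. A
    constant response yields all-zero sums of squares, reported with F = 0
    and a ``degenerate`` flag in ``DataFrame.attrs``.
    """
    df = table.copy()
    if response == "eggs_per_gram" and "eggs_per_gram" not in df.columns:
        df["eggs_per_gram"] = df.apply(lambda r: eggs_per_gram(r["eggs"], r["berry_weight"]), axis=1)
    if transform == "log1p":
        df["_y"] = np.log1p(df[response])
    elif transform in (None, "none"):
        df["_y"] = df[response]
    else:
        raise ValueError(f"unknown transform {transform!r}")

    factors = sorted({f for t in terms for f in t.split(":")})
    for f in factors:
        if df[f].nunique() < 2:
            raise ValueError(f"term {f!r} has fewer than 2 levels (0 df)")
        df[f] = df[f].astype(str)
    _check_balanced(df, factors)

    if np.allclose(df["_y"].std(), 0):
        out = pd.DataFrame(
            {"df": [0] * len(terms), "sum_sq": 0.0, "mean_sq": 0.0, "F": 0.0, "p": 1.0},
            index=terms,
        )
        out.attrs["degenerate"] = True
        return out

    rhs = " + ".join(
        ":".join(f"C({f})" for f in t.split(":")) for t in terms
    )
    model = smf.ols(f"_y ~ {rhs}", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=1)
    anova.index = [i.replace("C(", "").replace(")", "") for i in anova.index]
    out = anova.rename(
        columns={"df": "df", "sum_sq": "sum_sq", "F": "F", "PR(>F)": "p"}
    )
    out["df"] = out["df"].astype(int)
    out["mean_sq"] = out["sum_sq"] / out["df"].replace(0, np.nan)
    out = out[["df", "sum_sq", "mean_sq", "F", "p"]]
    out.index = [i if i != "Residual" else "Residuals" for i in out.index]
    return out


def bonferroni_pairwise(
    groups: dict[str, np.ndarray] | pd.core.groupby.SeriesGroupBy,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Bonferroni-adjusted pairwise t tests plus a compact letter display.

    Each pair of levels is compared with a pooled-variance two-sample t test;
    p-values are multiplied by the number of pairs (capped at 1). Levels
    sharing a letter are not significantly different at ``alpha``.
    """
    if not isinstance(groups, dict):
        groups = {str(k): np.asarray(v, dtype=float) for k, v in groups}
    levels = list(groups)
    if len(levels) < 2:
        raise ValueError("need at least 2 levels")
    for lv, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"level {lv!r} has fewer than 2 observations")

    pairs = list(combinations(levels, 2))
    m = len(pairs)
    rows = []
    sig = {}
    for a, b in pairs:
        t, p = stats.ttest_ind(groups[a], groups[b], equal_var=True)
        p_adj = min(1.0, p * m)
        rows.append({"level_a": a, "level_b": b, "t": t, "p_raw": p, "p_adj": p_adj})
        sig[(a, b)] = sig[(b, a)] = p_adj < alpha
    result = pd.DataFrame(rows)

    letters = _compact_letter_display(levels, sig, {lv: float(np.mean(v)) for lv, v in groups.items()})
    return result, letters


def _compact_letter_display(
    levels: list[str],
    significant: dict[tuple[str, str], bool],
    means: dict[str, float],
) -> dict[str, str]:
    """Insert-and-absorb letter assignment (levels ordered by descending mean)."""
    ordered = sorted(levels, key=lambda lv: (-means[lv], lv))
    # groups are maximal sets of mutually non-different levels
    groups: list[set[str]] = []
    for lv in ordered:
        placed = False
        for g in groups:
            if all(not significant[(lv, other)] for other in g):
                g.add(lv)
                placed = True
        if not placed:
            groups.append({lv})
    # absorb subsets
    groups = [g for i, g in enumerate(groups) if not any(g < h for j, h in enumerate(groups) if i != j)]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {lv: "" for lv in levels}
    for letter, g in zip(alphabet, groups):
        for lv in g:
            letters[lv] += letter
    return {lv: "".join(sorted(letters[lv])) for lv in levels}
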