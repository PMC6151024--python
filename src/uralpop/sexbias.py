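"""Sex-biased ancestry: autosomal vs chrX affinity against Y co-ancestry.

For pairs of populations, outgroup f3 values computed on autosomes and on
chrX are contrasted between pairs with a high probability of sharing chrY
hg N3-M178 ancestry (p(M178-coA) > 0.10) and pairs where that probability
is low (< 0.05).  Because chrX spends two thirds of its history in
females while autosomes split evenly, male-biased gene flow leaves
autosomal affinity in excess of chrX affinity for the high-co-ancestry
pairs; the contrast is tested by ANOVA on a linear model of f3_auto
against f3_chrX with a group term (intercept shift) and an interaction
(slope shift).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .allele_stats import BlockSpec, FreqTable, outgroup_f3


@dataclass
class SexbiasAnova:
    params: pd.Series           # OLS coefficients of f3_auto ~ f3_chrX * group
    f_group: float
    p_group: float
    f_interaction: float
    p_interaction: float
    n_high: int
    n_low: int


def coancestry_probability(freqA: float, freqB: float) -> float:
    """p(M178-coA): probability two random males (one from each population)
    both carry hg N3-M178 - the product of the two population frequencies."""
    if not (0 <= freqA <= 1 and 0 <= freqB <= 1):
        raise ValueError("haplogroup frequencies must lie in [0, 1]")
    return float(freqA * freqB)


def classify_pairs(pairs: pd.DataFrame, high_min: float = 0.10,
                   low_max: float = 0.05) -> pd.DataFrame:
    """Assign each pair to the high / low co-ancestry group.

    Strict inequalities: p_coA > high_min is "high", p_coA < low_max is
    "low", the closed interval [low_max, high_min] is "excluded".
    """
    if not 0 <= low_max < high_min <= 1:
        raise ValueError("require 0 <= low_max < high_min <= 1")
    pairs = pairs.copy()
    p = pairs["p_coA"]
    pairs["group"] = np.select([p > high_min, p < low_max],
                               ["high", "low"], default="excluded")
    return pairs


def paired_f3_table(freqs_auto: FreqTable, freqs_chrx: FreqTable,
                    outgroup: str, test_pops: list[str],
                    comparison_pops: list[str], blocks_auto: BlockSpec,
                    blocks_x: BlockSpec, n3_freqs: dict[str, float],
                    pairs: list[tuple[str, str]] | None = None
                    ) -> pd.DataFrame:
    """Outgroup f3 on autosomes and chrX plus p(M178-coA) per pair.

    By default every (test, comparison) combination with distinct members
    is evaluated; an explicit ``pairs`` list restricts the table (e.g. to
    disjoint pairs).  Pairs whose f3 is unavailable are dropped.
    """
    if outgroup in set(test_pops) | set(comparison_pops):
        raise ValueError("outgroup must not appear among test/comparison pops")
    if pairs is None:
        pairs = [(t, c) for t in test_pops for c in comparison_pops if t != c]
    rows = []
    for test, comp in pairs:
        try:
            fa = outgroup_f3(freqs_auto, outgroup, test, comp, blocks_auto)
            fx = outgroup_f3(freqs_chrx, outgroup, test, comp, blocks_x)
        except (ValueError, KeyError):
            continue
        p_coa = coancestry_probability(n3_freqs[test], n3_freqs[comp])
        rows.append((test, comp, fa.estimate, fx.estimate, p_coa))
    return pd.DataFrame(rows, columns=["test_pop", "comparison_pop",
                                       "f3_auto", "f3_chrX", "p_coA"])


def sexbias_anova(pairs: pd.DataFrame) -> SexbiasAnova:
    """ANOVA contrast of the high vs low co-ancestry regression lines.

    Fits f3_auto ~ f3_chrX * group by OLS on the high/low rows and tests
    the group (intercept shift) and interaction (slope shift) terms with
    Type-II nested-model F-tests.  Requires at least 3 pairs per group.
    """
    data = pairs[pairs["group"].isin(["high", "low"])].copy()
    n_high = int((data["group"] == "high").sum())
    n_low = int((data["group"] == "low").sum())
    if n_high < 3 or n_low < 3:
        raise ValueError(f"need >= 3 pairs per group (high={n_high}, low={n_low})")
    data["group"] = pd.Categorical(data["group"], categories=["low", "high"])
    fit = smf.ols("f3_auto ~ f3_chrX * group", data=data).fit()
    if fit.df_resid < 1 or np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise ValueError("rank-deficient design")
    table = sm.stats.anova_lm(fit, typ=2)
    return SexbiasAnova(
        params=fit.params,
        f_group=float(table.loc["group", "F"]),
        p_group=float(table.loc["group", "PR(>F)"]),
        f_interaction=float(table.loc["f3_chrX:group", "F"]),
        p_interaction=float(table.loc["f3_chrX:group", "PR(>F)"]),
        n_high=n_high, n_low=n_low,
    )
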