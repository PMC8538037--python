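"""Statistical routing and reporting for between-condition comparisons.

Two-sample comparisons are routed on distributional grounds: Shapiro–Wilk
normality on each group at the chosen alpha; if both pass, a (Welch)
two-sided t-test, otherwise a Mann–Whitney U test. Factorial comparisons
across the 3 morphologies x 2 substrates use a two-way ANOVA (type-II sums
of squares, robust to unbalanced cell counts) followed by Bonferroni-
adjusted pairwise post-tests. Significance stars follow the usual
convention: * p < 0.05, ** p < 0.01, *** p < 0.001, else ns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "route_and_compare",
    "anova2_bonferroni",
    "significance_stars",
]

#: Shapiro–Wilk loses meaning at huge n; larger samples are subsampled.
SHAPIRO_CAP = 5000


def significance_stars(p: float) -> str:
    """Star string for a p-value (strict inequalities; p >= 0.05 is ns)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p-value must lie in [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class ComparisonResult:
    test_name: str
    p_value: float
    stars: str
    normality_p: tuple[float, float] | None = None
    statistic: float = np.nan
    group_summaries: dict = field(default_factory=dict)
    notes: str = ""


def _shapiro_p(x: np.ndarray, seed: int = 0) -> float:
    if np.ptp(x) < 1e-12:
        return np.nan  # constant sample: normality undefined
    if len(x) > SHAPIRO_CAP:
        rng = np.random.default_rng(seed)
        x = rng.choice(x, SHAPIRO_CAP, replace=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(sps.shapiro(x).pvalue)


def _summary(x: np.ndarray, normal: bool) -> dict:
    if normal:
        return {"kind": "mean±SD", "mean": float(np.mean(x)), "sd": float(np.std(x, ddof=1))}
    q = np.percentile(x, [5, 25, 50, 75, 95])
    return {
        "kind": "median+quartiles",
        "median": float(q[2]),
        "q1": float(q[1]),
        "q3": float(q[3]),
        "whisker_lo": float(q[0]),
        "whisker_hi": float(q[4]),
    }


def route_and_compare(a, b, alpha: float = 0.05, seed: int = 0) -> ComparisonResult:
    """Normality-routed two-sample comparison.

    Both groups Shapiro–Wilk-normal at ``alpha`` → Welch t-test; otherwise
    Mann–Whitney U. Constant samples make normality undefined and route to
    Mann–Whitney with a warning. Group summaries follow the plotting
    convention: mean ± SD when normal (bar chart), median with quartiles
    and 5th/95th-percentile whiskers otherwise (box plot).
    """
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each sample needs at least 3 observations")
    pa, pb = _shapiro_p(a, seed), _shapiro_p(b, seed + 1)
    degenerate = np.isnan(pa) or np.isnan(pb)
    if degenerate:
        warnings.warn("constant sample: normality undefined, using Mann-Whitney U")
    normal = (not degenerate) and pa > alpha and pb > alpha
    if normal:
        res = sps.ttest_ind(a, b, equal_var=False)
        name = "t-test"
    else:
        if np.array_equal(np.sort(a), np.sort(b)):
            # identical samples: U test p-value is 1 by symmetry
            res = sps.mannwhitneyu(a, b, method="asymptotic")
        else:
            res = sps.mannwhitneyu(a, b)
        name = "Mann-Whitney U"
    p = float(res.pvalue)
    return ComparisonResult(
        test_name=name,
        p_value=p,
        stars=significance_stars(p),
        normality_p=(pa, pb),
        statistic=float(res.statistic),
        group_summaries={"a": _summary(a, normal), "b": _summary(b, normal)},
    )


def anova2_bonferroni(
    values,
    factor_morph,
    factor_substrate,
    alpha: float = 0.05,
    pairwise: str = "within-morph",
) -> dict:
    """Two-way ANOVA (morphology x substrate) + Bonferroni post-tests.

    Type-II sums of squares accommodate unbalanced cell counts. Post-tests
    are pairwise t-tests with adjusted p = min(1, m·p_raw); the default
    compares substrates within each morphology, ``pairwise='all'`` compares
    every pair of design cells.

    Returns a dict with the ANOVA table (DataFrame) and a DataFrame of
    post-test :class:`ComparisonResult`-like rows.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {
            "value": np.asarray(values, float),
            "morph": np.asarray(factor_morph, dtype=object),
            "substrate": np.asarray(factor_substrate, dtype=object),
        }
    )
    counts = df.groupby(["morph", "substrate"], observed=True).size()
    morphs = sorted(df["morph"].unique())
    subs = sorted(df["substrate"].unique())
    if len(subs) < 2:
        raise ValueError(
            f"design cell (substrate != {subs[0]}) is empty: the crossed design needs both substrates"
        )
    for m in morphs:
        for s in subs:
            if (m, s) not in counts.index or counts[(m, s)] < 2:
                raise ValueError(f"design cell (morph={m}, substrate={s}) has fewer than 2 observations")

    # morph may legitimately collapse to a single level (single-class data);
    # the model formula adapts while the substrate contrast is always present
    formula = "value ~ C(morph) * C(substrate)" if len(morphs) > 1 else "value ~ C(substrate)"
    model = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)

    cells = [(m, s) for m in morphs for s in subs]
    if pairwise == "within-morph":
        pairs = [((m, subs[0]), (m, subs[1])) for m in morphs if len(subs) == 2]
    elif pairwise == "all":
        pairs = [(cells[i], cells[j]) for i in range(len(cells)) for j in range(i + 1, len(cells))]
    else:
        raise ValueError("pairwise must be 'within-morph' or 'all'")
    m_comp = len(pairs)

    rows = []
    for (m1, s1), (m2, s2) in pairs:
        g1 = df.query("morph == @m1 and substrate == @s1")["value"].to_numpy()
        g2 = df.query("morph == @m2 and substrate == @s2")["value"].to_numpy()
        t = sps.ttest_ind(g1, g2, equal_var=False)
        p_adj = min(1.0, m_comp * float(t.pvalue))
        rows.append(
            {
                "group_a": f"{m1}/{s1}",
                "group_b": f"{m2}/{s2}",
                "p_raw": float(t.pvalue),
                "p_adj": p_adj,
                "stars": significance_stars(p_adj),
            }
        )
    return {"anova": table, "posthoc": pd.DataFrame(rows), "n_comparisons": m_comp}
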