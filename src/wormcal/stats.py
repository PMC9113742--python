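"""Immunoblot band-ratio quantification and the inferential toolbox.

Complex-member band intensities are expressed relative to the UNC-68 band
of the same lane, and the resulting ratios are compared with the standard
battery: unpaired two-tailed Student t for two groups, one-way ANOVA with
Tukey–Kramer pairwise comparisons for three or more, and two-way ANOVA
(type-II sums of squares) for factorial designs.  Ratios are analysed on
the ratio scale by default, with a log option.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "band_ratio",
    "band_ratio_table",
    "t_test",
    "one_way_anova",
    "tukey_kramer",
    "two_way_anova",
]


def band_ratio(intensity: float, unc68_intensity: float) -> float:
    """Band ratio R = member intensity / UNC-68 intensity of the same lane."""
    if intensity <= 0 or unc68_intensity <= 0:
        raise ValueError("band intensities must be > 0")
    return intensity / unc68_intensity


def band_ratio_table(df: pd.DataFrame, log: bool = False) -> pd.DataFrame:
    """Add a ``ratio`` column to a densitometry table.

    Expects columns ``intensity`` and ``unc68_intensity``.  With ``log=True``
    the natural log-ratio is added instead (option for heavily skewed blots).
    """
    required = {"intensity", "unc68_intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"table needs columns {sorted(required)}")
    if (df["intensity"] <= 0).any() or (df["unc68_intensity"] <= 0).any():
        raise ValueError("band intensities must be > 0")
    out = df.copy()
    r = out["intensity"] / out["unc68_intensity"]
    out["ratio"] = np.log(r) if log else r
    return out


def t_test(a, b) -> tuple[float, float]:
    """Unpaired two-tailed Student t test (pooled variance).

    Two identical constant samples are a defined edge case: t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf") * np.sign(a.mean() - b.mean()), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def one_way_anova(groups) -> tuple[float, float]:
    """One-way ANOVA F and p across three or more groups.

    For two groups use :func:`t_test` (the classical identity t^2 = F makes
    them equivalent); this function refuses to silently degrade.
    All-identical input is a defined edge case: F = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("one_way_anova needs >= 3 groups; use t_test for two")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    grand = np.concatenate(groups)
    ssb = sum(g.size * (g.mean() - grand.mean()) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ssw == 0 and ssb == 0:
        return 0.0, 1.0
    f, p = sps.f_oneway(*groups)
    return float(f), float(p)


def tukey_kramer(groups, alpha: float = 0.05) -> list[tuple[int, int, float, bool]]:
    """Tukey–Kramer pairwise comparisons (studentized range, unequal n).

    Returns (i, j, adjusted p, significant at alpha) per pair.  The
    studentized-range tail probability is evaluated by numerical
    integration (scipy), not table lookup.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("tukey_kramer needs >= 3 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    if all(g.std(ddof=1) == 0 for g in groups) and len({g.mean() for g in groups}) == 1:
        return [
            (i, j, 1.0, False)
            for i in range(len(groups)) for j in range(i + 1, len(groups))
        ]
    res = sps.tukey_hsd(*groups)
    out = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            p = float(res.pvalue[i, j])
            out.append((i, j, p, p < alpha))
    return out


def two_way_anova(table: pd.DataFrame, value: str, factor_a: str,
                  factor_b: str) -> pd.DataFrame:
    """Two-way ANOVA with interaction, type-II sums of squares.

    Type II tolerates mild imbalance; a completely empty cell is an error.
    Returns a frame indexed by effect with sum_sq, df, F and p columns.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    for col in (value, factor_a, factor_b):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    counts = table.groupby([factor_a, factor_b], observed=True).size().unstack()
    if counts.isna().any().any() or (counts == 0).any().any():
        raise ValueError("two-way design has an empty cell")
    df = table.rename(columns={value: "_y", factor_a: "_fa", factor_b: "_fb"})
    model = smf.ols("_y ~ C(_fa) * C(_fb)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    anova = anova.rename(index={
        "C(_fa)": factor_a,
        "C(_fb)": factor_b,
        "C(_fa):C(_fb)": f"{factor_a}:{factor_b}",
        "Residual": "residual",
    })
    return anova.rename(columns={"sum_sq": "sum_sq", "PR(>F)": "p_value"})
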