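"""Statistical comparison layer: two-sample t tests against the reference
distribution, main-effects ANOVA over the orthogonal factors, Duncan's
multiple range test, and significance stars.

The t test defaults to the pooled-variance form (Welch available behind a
flag).  The ANOVA fits all five factors as categorical main effects with no
interactions, so with the 16-run design and r replicates the error term has
16*r - 16 degrees of freedom.  Duncan's test ranks group means and compares
stretches of p consecutive means against least significant ranges built
from the studentized range distribution at protection level
(1 - alpha)^(p-1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "ComparisonResult",
    "MainEffectsResult",
    "t_independent",
    "anova_main_effects",
    "duncan_mrt",
    "star_level",
]


def star_level(p: float) -> str:
    """Significance stars: *** below 0.01, ** below 0.05, * below 0.1."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


@dataclass
class ComparisonResult:
    """A two-sample comparison with its significance star level."""

    attribute: str
    mean_x: float
    sd_x: float
    mean_y: float
    sd_y: float
    t: float
    df: float
    p: float
    stars: str


def t_independent(
    x, y, attribute: str = "", equal_var: bool = True
) -> ComparisonResult:
    """Independent two-sample t test (pooled variance by default).

    Degenerate input with zero variance in both samples and equal means
    yields t = 0, p = 1 rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if equal_var:
        df = x.size + y.size - 2
    else:
        num = (vx / x.size + vy / y.size) ** 2
        den = (vx / x.size) ** 2 / (x.size - 1) + (vy / y.size) ** 2 / (y.size - 1)
        df = num / den if den > 0 else x.size + y.size - 2
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            t, p = 0.0, 1.0
        else:
            t, p = np.inf if x.mean() > y.mean() else -np.inf, 0.0
    else:
        t, p = sps.ttest_ind(x, y, equal_var=equal_var)
        t, p = float(t), float(p)
    return ComparisonResult(
        attribute=attribute,
        mean_x=float(x.mean()),
        sd_x=float(np.sqrt(vx)),
        mean_y=float(y.mean()),
        sd_y=float(np.sqrt(vy)),
        t=t,
        df=float(df),
        p=p,
        stars=star_level(p),
    )


@dataclass
class MainEffectsResult:
    """Per-factor F statistics and per-level observed means."""

    attribute: str
    effects: pd.DataFrame  # factor, F, df_num, df_den, p, stars
    level_means: pd.DataFrame  # factor, level, mean, n


def anova_main_effects(
    table: pd.DataFrame,
    attribute: str,
    factors: tuple[str, ...] = ("L_AS1", "L_AS12", "M_1", "L_ID", "M_ID"),
) -> MainEffectsResult:
    """Fixed-effects ANOVA with categorical main effects, no interactions."""
    data = table[[attribute, *factors]].dropna().copy()
    for f in factors:
        n_levels = data[f].nunique()
        if n_levels < 2:
            raise ValueError(f"factor {f} has fewer than 2 observed levels")
        counts = data.groupby(f)[attribute].count()
        if (counts < 2).any():
            raise ValueError(f"factor {f} has levels with fewer than 2 observations")
    data = data.rename(columns={attribute: "_y"})
    constant_response = float(data["_y"].var(ddof=0)) == 0.0
    formula = "_y ~ " + " + ".join(f"C({f})" for f in factors)
    model = smf.ols(formula, data=data).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = sm.stats.anova_lm(model, typ=2)
    df_den = float(aov.loc["Residual", "df"])
    rows = []
    for f in factors:
        key = f"C({f})"
        F = aov.loc[key, "F"]
        p = aov.loc[key, "PR(>F)"]
        if constant_response or not np.isfinite(F):
            F, p = 0.0, 1.0
        rows.append(
            {
                "factor": f,
                "F": float(F),
                "df_num": float(aov.loc[key, "df"]),
                "df_den": df_den,
                "p": float(p),
                "stars": star_level(float(p)),
            }
        )
    means = (
        data.melt(
            id_vars="_y", value_vars=list(factors), var_name="factor", value_name="level"
        )
        .groupby(["factor", "level"])["_y"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "mean", "count": "n"})
    )
    return MainEffectsResult(attribute, pd.DataFrame(rows), means)


def duncan_mrt(
    groups: dict,
    alpha: float = 0.05,
    df_error: float | None = None,
    ms_error: float | None = None,
) -> list[list]:
    """Duncan's multiple range test: ordered homogeneous subsets of levels.

    ``groups`` maps a level key to its sample.  The error term defaults to
    the pooled within-group variance; pass ``df_error``/``ms_error`` to use
    the residual of a surrounding ANOVA instead.  Unbalanced group sizes are
    handled with the harmonic mean n (with a warning).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    keys = list(groups)
    samples = {k: np.asarray(groups[k], dtype=float) for k in keys}
    for k, s in samples.items():
        if s.size < 2:
            raise ValueError(f"group {k!r} has fewer than 2 observations")
    ns = np.array([samples[k].size for k in keys], dtype=float)
    if df_error is None or ms_error is None:
        df_error = float(sum(n - 1 for n in ns))
        ms_error = float(
            sum((samples[k].size - 1) * samples[k].var(ddof=1) for k in keys)
            / df_error
        )
    if len(set(ns)) > 1:
        warnings.warn("unbalanced groups: using harmonic mean n")
    n_h = len(ns) / np.sum(1.0 / ns)
    se = np.sqrt(ms_error / n_h)

    order = sorted(keys, key=lambda k: samples[k].mean())
    means = np.array([samples[k].mean() for k in order])

    def critical_range(p: int) -> float:
        if se == 0:
            return 0.0
        q = sps.studentized_range.ppf((1 - alpha) ** (p - 1), p, df_error)
        return float(q * se)

    homogeneous: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()

    def explore(i: int, j: int) -> None:
        if (i, j) in seen:
            return
        seen.add((i, j))
        if i == j or means[j] - means[i] <= critical_range(j - i + 1) + 1e-12:
            homogeneous.append((i, j))
            return
        explore(i, j - 1)
        explore(i + 1, j)

    explore(0, len(order) - 1)
    # keep maximal stretches only
    maximal = [
        (i, j)
        for (i, j) in homogeneous
        if not any((a <= i and j <= b) and (a, b) != (i, j) for a, b in homogeneous)
    ]
    maximal.sort()
    return [order[i : j + 1] for i, j in maximal]
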