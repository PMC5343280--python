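"""The study's statistical battery.

Two-way ANOVA (group x metabolite, full factorial with interaction, Type III
sums of squares on sum-to-zero contrasts) followed by uncorrected Fisher's
least-significant-difference posttests; Pearson correlation with a two-sided
p from the t transform; and pooled-variance unpaired two-sided Student's
t-tests.  No multiplicity correction anywhere, alpha = 0.05.

The ANOVA is computed directly from least-squares fits of the full and
reduced design matrices (Type III: each effect's SS is the fit deterioration
when only that effect's columns are dropped).  This matches the commercial
package the field uses for unbalanced layouts and is fast enough for
simulation-based calibration; statsmodels is used as an independent
cross-check in the test suite, not here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "PosttestResult",
    "CorrelationResult",
    "TTestResult",
    "two_way_anova",
    "fisher_lsd",
    "pearson",
    "unpaired_t",
]

ALPHA = 0.05


@dataclass(frozen=True)
class EffectRow:
    ss: float
    df: int
    f: float
    p: float


@dataclass
class AnovaResult:
    effects: dict[str, EffectRow]
    residual_ss: float
    residual_df: int
    group_col: str = "group"
    within_col: str = "metabolite"
    value_col: str = "value"

    @property
    def residual_ms(self) -> float:
        return self.residual_ss / self.residual_df

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"effect": name, "ss": e.ss, "df": e.df, "F": e.f, "p": e.p}
            for name, e in self.effects.items()
        ]
        rows.append(
            {
                "effect": "residual",
                "ss": self.residual_ss,
                "df": self.residual_df,
                "F": np.nan,
                "p": np.nan,
            }
        )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class PosttestResult:
    metabolite: str
    mean_diff: float  # first group level minus second
    t: float
    df: int
    p: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float
    flag: str = ""


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    means: tuple[float, float] = field(default=(np.nan, np.nan))
    flag: str = ""


def _sum_coded(levels: pd.Series) -> tuple[np.ndarray, list]:
    """Sum-to-zero contrast columns for a categorical factor."""
    cats = sorted(pd.unique(levels))
    k = len(cats)
    cols = np.zeros((len(levels), k - 1))
    idx = {c: i for i, c in enumerate(cats)}
    for row, val in enumerate(levels):
        i = idx[val]
        if i < k - 1:
            cols[row, i] = 1.0
        else:
            cols[row, :] = -1.0
    return cols, cats


def _sse(x: np.ndarray, y: np.ndarray) -> float:
    resid = y - x @ np.linalg.lstsq(x, y, rcond=None)[0]
    return float(resid @ resid)


def two_way_anova(
    table: pd.DataFrame,
    value_col: str = "value",
    group_col: str = "group",
    within_col: str = "metabolite",
) -> AnovaResult:
    """Full-factorial two-way ANOVA with Type III sums of squares.

    Requires >= 2 levels per factor and at least one observation per cell;
    raises on empty cells.  With zero residual df the F tests are undefined
    and reported as NaN.
    """
    df = table[[value_col, group_col, within_col]].dropna()
    if not np.isfinite(df[value_col].to_numpy(dtype=float)).all():
        raise ValueError("values must be finite")
    a_levels = df[group_col].nunique()
    b_levels = df[within_col].nunique()
    if a_levels < 2 or b_levels < 2:
        raise ValueError("both factors need at least 2 levels")
    counts = df.groupby([group_col, within_col], observed=True).size()
    if len(counts) < a_levels * b_levels:
        have = set(counts.index)
        missing = [
            (g, m)
            for g in df[group_col].unique()
            for m in df[within_col].unique()
            if (g, m) not in have
        ]
        raise ValueError(f"empty design cells: {missing}")

    y = df[value_col].to_numpy(dtype=float)
    a_cols, _ = _sum_coded(df[group_col])
    b_cols, _ = _sum_coded(df[within_col])
    ab_cols = np.einsum("ni,nj->nij", a_cols, b_cols).reshape(len(df), -1)
    intercept = np.ones((len(df), 1))
    blocks = {group_col: a_cols, within_col: b_cols, "interaction": ab_cols}

    full = np.hstack([intercept, a_cols, b_cols, ab_cols])
    sse_full = _sse(full, y)
    df_resid = len(df) - full.shape[1]

    # scale-relative floor so numerically-zero sums of squares are exact zeros
    tss = float(((y - y.mean()) ** 2).sum())
    eps = 1e-12 * max(tss, 1.0)
    if sse_full < eps:
        sse_full = 0.0

    effects: dict[str, EffectRow] = {}
    for name, cols in blocks.items():
        others = [intercept] + [c for n, c in blocks.items() if n != name]
        ss = max(_sse(np.hstack(others), y) - sse_full, 0.0)
        if ss < eps:
            ss = 0.0
        df_eff = cols.shape[1]
        if df_resid > 0 and ss == 0.0:
            f, p = 0.0, 1.0
        elif df_resid > 0 and sse_full > 0:
            f = (ss / df_eff) / (sse_full / df_resid)
            p = float(sps.f.sf(f, df_eff, df_resid))
        else:
            f, p = np.nan, np.nan
        effects[name] = EffectRow(ss, df_eff, f, p)
    return AnovaResult(effects, sse_full, df_resid, group_col, within_col, value_col)


def fisher_lsd(
    anova: AnovaResult,
    table: pd.DataFrame,
    metabolites: list[str] | None = None,
) -> list[PosttestResult]:
    """Uncorrected Fisher's LSD posttests between the two group levels,
    within each metabolite, using the ANOVA residual mean square and df.

    Group levels are taken in sorted order; ``mean_diff`` is first minus
    second (NoSE minus SE with the package's group labels).
    """
    df = table[[anova.value_col, anova.group_col, anova.within_col]].dropna()
    groups = sorted(df[anova.group_col].unique())
    if len(groups) != 2:
        raise ValueError("LSD posttests here compare exactly 2 group levels")
    g1, g2 = groups
    if metabolites is None:
        metabolites = sorted(df[anova.within_col].unique())
    ms, dfr = anova.residual_ms, anova.residual_df
    out = []
    for met in metabolites:
        block = df[df[anova.within_col] == met]
        if block.empty:
            raise ValueError(f"metabolite {met} absent from table")
        x1 = block.loc[block[anova.group_col] == g1, anova.value_col].to_numpy()
        x2 = block.loc[block[anova.group_col] == g2, anova.value_col].to_numpy()
        diff = float(x1.mean() - x2.mean())
        se = np.sqrt(ms * (1.0 / len(x1) + 1.0 / len(x2)))
        if se == 0:
            t = 0.0 if diff == 0 else np.inf
        else:
            t = diff / se
        p = float(2 * sps.t.sf(abs(t), dfr))
        out.append(PosttestResult(met, diff, float(t), dfr, p))
    return out


def pearson(x, y) -> CorrelationResult:
    """Sample Pearson r with a two-sided p from t = r sqrt((n-2)/(1-r^2))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(np.nan, n, np.nan, "constant_vector")
    xc, yc = x - x.mean(), y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        return CorrelationResult(r, n, 0.0)
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return CorrelationResult(r, n, float(2 * sps.t.sf(abs(t), n - 2)))


def unpaired_t(x, y) -> TTestResult:
    """Pooled-variance unpaired two-sided Student's t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    m1, m2 = float(x.mean()), float(y.mean())
    df = n1 + n2 - 2
    pooled = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    if pooled == 0:
        if m1 == m2:
            return TTestResult(0.0, df, 1.0, (m1, m2))
        return TTestResult(np.inf, df, np.nan, (m1, m2), "zero_variance_unequal_means")
    t = (m1 - m2) / np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    return TTestResult(float(t), df, float(2 * sps.t.sf(abs(t), df)), (m1, m2))
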