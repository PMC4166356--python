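"""The statistical battery applied to per-projection measure tables.

The unit of analysis is the *projection*: one eye together with its
contralateral superior colliculus, treated as independent because
glaucomatous pathology affects the two eyes of an animal differentially.
The battery comprises:

* a two-way between-subjects factorial ANOVA of percent-intact label with
  factors ``label`` (CTB, FG, ERRbeta) and ``group`` (strain/age), using
  Type II sums of squares since group sizes are unequal;
* protected Fisher's LSD pairwise comparisons (pairwise t on the pooled
  residual MS; the ``protected`` flag records whether the omnibus effect
  reached ``alpha``, rather than suppressing unprotected output);
* within-projection paired t-tests between labels;
* Pearson correlation (two-sided p via the t transform with n-2 df); and
* unity-line deviation analysis: per-case ``y - x`` with an exact two-sided
  binomial sign test on the below- vs above-line counts (ties excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .errors import (
    DegenerateDataError,
    DegenerateDesignError,
    InsufficientDataError,
    PairingError,
    UnknownLevelError,
)

__all__ = [
    "AnovaEffect",
    "AnovaResult",
    "PairwiseResult",
    "factorial_anova",
    "fisher_lsd",
    "paired_t",
    "pearson_r",
    "unity_deviation",
    "UnityResult",
    "cohort_to_long",
]

LABEL_COLUMNS = {"CTB": "ctb_intact_pct", "FG": "fg_intact_pct",
                 "ERRB": "errb_intact_pct"}


@dataclass
class AnovaEffect:
    name: str
    ss: float
    df: int
    f: float
    p: float

    @property
    def ms(self) -> float:
        return self.ss / self.df


@dataclass
class AnovaResult:
    """Two-way ANOVA table: main effects, interaction, residual."""

    effects: dict[str, AnovaEffect]
    residual_ss: float
    residual_df: int
    factors: tuple[str, str]
    value: str

    @property
    def mse(self) -> float:
        return self.residual_ss / self.residual_df

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"effect": e.name, "ss": e.ss, "df": e.df, "ms": e.ms,
             "F": e.f, "p": e.p}
            for e in self.effects.values()
        ]
        rows.append({"effect": "residual", "ss": self.residual_ss,
                     "df": self.residual_df, "ms": self.mse,
                     "F": np.nan, "p": np.nan})
        return pd.DataFrame(rows)


@dataclass
class PairwiseResult:
    level_a: str
    level_b: str
    mean_difference: float
    t: float
    df: int
    p: float
    protected: bool


def factorial_anova(
    table: pd.DataFrame,
    value: str = "value",
    factors: tuple[str, str] = ("label", "group"),
) -> AnovaResult:
    """Two-way between-subjects factorial ANOVA with Type II SS.

    ``table`` is long-format: one row per observation, with a numeric
    ``value`` column and two categorical factor columns. Type II sums of
    squares are used because group sizes are unequal (each main effect is
    tested against the model containing the other main effect).
    """
    fa, fb = factors
    for f in factors:
        if table[f].nunique() < 2:
            raise DegenerateDesignError(f"factor {f!r} has fewer than two levels")
    n_cells_max = table[fa].nunique() * table[fb].nunique()
    if len(table) - n_cells_max < 1:
        raise InsufficientDataError("zero residual degrees of freedom")

    data = table[[value, fa, fb]].rename(
        columns={value: "_y", fa: "_a", fb: "_b"}
    )
    model = smf.ols("_y ~ C(_a) * C(_b)", data=data).fit()
    if model.df_resid < 1:
        raise InsufficientDataError("zero residual degrees of freedom")
    aov = anova_lm(model, typ=2)

    key_map = {"C(_a)": fa, "C(_b)": fb, "C(_a):C(_b)": f"{fa}:{fb}"}
    effects = {}
    for key, name in key_map.items():
        row = aov.loc[key]
        effects[name] = AnovaEffect(
            name=name, ss=float(row["sum_sq"]), df=int(row["df"]),
            f=float(row["F"]), p=float(row["PR(>F)"]),
        )
    resid = aov.loc["Residual"]
    return AnovaResult(
        effects=effects,
        residual_ss=float(resid["sum_sq"]),
        residual_df=int(resid["df"]),
        factors=factors,
        value=value,
    )


def fisher_lsd(
    table: pd.DataFrame,
    anova: AnovaResult,
    factor: str,
    alpha: float = 0.05,
    levels: list[str] | None = None,
) -> list[PairwiseResult]:
    """Protected Fisher's LSD pairwise comparisons for one factor.

    Each pair is tested with
    ``t = (mean_i - mean_j) / sqrt(MSE * (1/n_i + 1/n_j))`` on the ANOVA's
    residual df, two-sided, with no multiplicity correction. ``protected``
    is False for every pair when the omnibus effect for ``factor`` has
    p > ``alpha`` — reported, not suppressed.
    """
    if factor not in anova.effects:
        raise UnknownLevelError(factor)
    value = anova.value
    present = list(pd.unique(table[factor]))
    if levels is None:
        levels = present
    else:
        missing = [lv for lv in levels if lv not in present]
        if missing:
            raise UnknownLevelError(f"levels absent from table: {missing}")

    omnibus_ok = anova.effects[factor].p <= alpha
    mse = anova.mse
    df = anova.residual_df
    grouped = table.groupby(factor)[value]
    means = grouped.mean()
    ns = grouped.count()

    out = []
    for i, la in enumerate(levels):
        for lb in levels[i + 1:]:
            diff = float(means[la] - means[lb])
            se = float(np.sqrt(mse * (1.0 / ns[la] + 1.0 / ns[lb])))
            t = diff / se if se > 0 else 0.0
            p = 2.0 * float(sps.t.sf(abs(t), df)) if se > 0 else 1.0
            out.append(PairwiseResult(
                level_a=la, level_b=lb, mean_difference=diff,
                t=t, df=df, p=min(p, 1.0), protected=omnibus_ok,
            ))
    return out


def paired_t(x, y) -> tuple[float, int, float]:
    """Paired two-sided t-test on per-projection differences.

    Returns ``(t, df, p)`` with df = n - 1. All-zero differences give
    (0, n-1, 1); zero-variance *nonzero* differences are degenerate and
    raise rather than reporting an infinite statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise PairingError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 2:
        raise PairingError("paired test needs at least two pairs")
    d = x - y
    sd = float(np.std(d, ddof=1))
    md = float(np.mean(d))
    if sd == 0.0:
        if md == 0.0:
            return 0.0, n - 1, 1.0
        raise DegenerateDataError(
            "differences have zero variance but nonzero mean"
        )
    t = md / (sd / np.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), n - 1))
    return float(t), n - 1, min(p, 1.0)


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with two-sided p (t transform, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise PairingError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise PairingError("correlation needs at least three pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateDataError("constant vector has no defined correlation")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class UnityResult:
    """Deviation of paired percent measures from the unity line y = x."""

    deviations: np.ndarray
    n_below: int
    n_above: int
    fraction_below: float
    sign_test_p: float  # NaN when every point sits on the line

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"deviation": self.deviations})


def unity_deviation(x, y) -> UnityResult:
    """Per-case ``y - x`` deviations and an exact binomial sign test.

    ``fraction_below`` is the share of cases strictly below the line among
    the off-line cases (ties excluded). The sign test is two-sided exact
    binomial on below-vs-above counts; with no off-line cases there are no
    counts and the p-value is NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise PairingError(f"length mismatch: {x.shape} vs {y.shape}")
    d = y - x
    n_below = int(np.count_nonzero(d < 0))
    n_above = int(np.count_nonzero(d > 0))
    m = n_below + n_above
    if m == 0:
        return UnityResult(deviations=d, n_below=0, n_above=0,
                           fraction_below=0.0, sign_test_p=float("nan"))
    p = float(sps.binomtest(n_below, m, 0.5, alternative="two-sided").pvalue)
    return UnityResult(
        deviations=d, n_below=n_below, n_above=n_above,
        fraction_below=n_below / m, sign_test_p=p,
    )


def cohort_to_long(cohort: pd.DataFrame) -> pd.DataFrame:
    """Melt a per-projection cohort into label x group long format.

    Output columns: ``projection_id, group, label, value`` with label in
    {CTB, FG, ERRB} and value the corresponding percent-intact measure.
    """
    frames = []
    for label, col in LABEL_COLUMNS.items():
        frames.append(pd.DataFrame({
            "projection_id": cohort["projection_id"],
            "group": cohort["group"],
            "label": label,
            "value": cohort[col].astype(float),
        }))
    return pd.concat(frames, ignore_index=True)
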