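"""Accuracy-improvement efficiency (AIE) and its factorial analysis.

Comparing classifiers across input datasets needs a common yardstick.  The
worst overall kappa obtained on the baseline dataset (the plain
high-resolution multispectral stack, "HMS") is taken as the standard level
``OKC_min``, and every classifier x dataset combination is scored by its
relative improvement

    AIE = (OKC - OKC_min) / OKC_min.

Two kinds of OKC enter: *performance* (training samples) and *accuracy*
(independent test samples), each with its own baseline.

The AIE table is then analysed as a fixed-effects two-way factorial
design,

    Y = b0 + b1*X1 + b2*X2 + b12*X1X2 + e

with X1 = dataset, X2 = classifier.  With a single AIE per cell the
interaction would not be estimable; the two OKC kinds serve as the two
replicates per cell (documented design choice).  Effects are judged at
alpha = 0.05, and Duncan's new multiple range test groups factor levels,
with critical ranges from the studentized-range distribution at protection
level ``alpha_p = 1 - (1 - alpha)^(p-1)`` for a stretch of p means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .accuracy import AccuracyReport

__all__ = [
    "aie",
    "AIETable",
    "build_aie_table",
    "AnovaResult",
    "two_way_anova",
    "DuncanGrouping",
    "duncan_groups",
    "duncan_from_anova",
]

BASELINE_DATASET = "HMS"
_ROLE_TO_TYPE = {"training": "performance", "test": "accuracy"}


def aie(okc: float, okc_min: float) -> float:
    """Relative kappa improvement over the baseline level."""
    if okc_min <= 0:
        raise ValueError("okc_min must be positive")
    return (okc - okc_min) / okc_min


@dataclass
class AIETable:
    """Long-format classifier x dataset x okc_type table with AIE filled in."""

    table: pd.DataFrame  # columns: classifier, dataset, okc_type, okc, aie
    okc_min: Mapping[str, float]  # per okc_type baseline

    def __post_init__(self) -> None:
        need = {"classifier", "dataset", "okc_type", "okc", "aie"}
        missing = need - set(self.table.columns)
        if missing:
            raise ValueError(f"AIE table missing columns {sorted(missing)}")


def build_aie_table(
    reports: Sequence[AccuracyReport],
    baseline_dataset: str = BASELINE_DATASET,
) -> AIETable:
    """Assemble the AIE table from accuracy reports.

    For each okc_type (performance = training role, accuracy = test role)
    the baseline is the minimum OKC among the reports on the baseline
    dataset of that type.
    """
    rows = []
    for r in reports:
        okc_type = _ROLE_TO_TYPE.get(r.role, r.role)
        rows.append(
            {
                "classifier": r.classifier_name,
                "dataset": r.dataset_name,
                "okc_type": okc_type,
                "okc": r.okc,
            }
        )
    df = pd.DataFrame(rows)
    okc_min: dict[str, float] = {}
    for t, grp in df.groupby("okc_type"):
        base = grp[grp["dataset"] == baseline_dataset]
        if base.empty:
            raise ValueError(
                f"no {baseline_dataset} reports for okc_type {t!r}; "
                "cannot set the baseline"
            )
        okc_min[t] = float(base["okc"].min())
        if okc_min[t] <= 0:
            raise ValueError(f"baseline OKC for {t!r} is non-positive")
    df["aie"] = [
        aie(o, okc_min[t]) for o, t in zip(df["okc"], df["okc_type"])
    ]
    return AIETable(df, okc_min)


@dataclass
class AnovaResult:
    """Fixed-effects two-way ANOVA of the AIE table."""

    anova_table: pd.DataFrame  # statsmodels anova_lm layout
    effects: pd.Series  # fitted coefficients (treatment coding)
    residual_df: int
    residual_variance: float  # mean-squared error
    alpha: float = 0.05
    n_per_cell: int = 1

    def f_stat(self, term: str) -> float:
        return float(self.anova_table.loc[term, "F"])

    def p_value(self, term: str) -> float:
        return float(self.anova_table.loc[term, "PR(>F)"])

    def significant_terms(self) -> list[str]:
        t = self.anova_table.dropna(subset=["PR(>F)"])
        return list(t.index[t["PR(>F)"] <= self.alpha])

    def to_dataframe(self) -> pd.DataFrame:
        out = self.anova_table.copy()
        out["significant"] = out["PR(>F)"] <= self.alpha
        return out


def two_way_anova(
    table: AIETable, alpha: float = 0.05, interaction: bool = True
) -> AnovaResult:
    """Factorial ANOVA of AIE on dataset, classifier and their interaction.

    Requires at least two levels per factor, and replication within cells
    (the two okc_types) when the interaction term is requested.
    """
    df = table.table.copy()
    for factor in ("dataset", "classifier"):
        if df[factor].nunique() < 2:
            raise ValueError(f"need >= 2 levels of {factor!r}")
    n_cells = df.groupby(["dataset", "classifier"]).size()
    if interaction and (n_cells < 2).any():
        raise ValueError(
            "interaction test needs >= 2 replicates per cell (both okc "
            "types); run with interaction=False for the additive model"
        )
    formula = (
        "aie ~ C(dataset) * C(classifier)"
        if interaction
        else "aie ~ C(dataset) + C(classifier)"
    )
    fit = smf.ols(formula, data=df).fit()
    anova = sm.stats.anova_lm(fit, typ=2)
    return AnovaResult(
        anova_table=anova,
        effects=fit.params,
        residual_df=int(fit.df_resid),
        residual_variance=float(fit.mse_resid),
        alpha=alpha,
        n_per_cell=int(n_cells.min()),
    )


@dataclass
class DuncanGrouping:
    """Duncan's-multiple-range grouping of factor-level means.

    ``levels``/``means`` are sorted by descending mean; levels sharing a
    letter are not significantly different at ``alpha``.
    """

    levels: list[str]
    means: np.ndarray
    letters: list[str]
    alpha: float
    critical_ranges: dict[int, float] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"level": self.levels, "mean_aie": self.means, "group": self.letters}
        )


def _duncan_critical_ranges(
    k: int, ms_error: float, df_error: int, n_per_mean: int, alpha: float
) -> dict[int, float]:
    """Least significant range for stretches of p = 2..k ordered means."""
    se = np.sqrt(ms_error / n_per_mean)
    ranges = {}
    for p in range(2, k + 1):
        alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
        q = stats.studentized_range.ppf(1.0 - alpha_p, p, df_error)
        ranges[p] = float(q * se)
    return ranges


def duncan_groups(
    cell_means: Mapping[str, float],
    ms_error: float,
    df_error: int,
    n_per_mean: int,
    alpha: float = 0.05,
) -> DuncanGrouping:
    """Group factor levels by Duncan's new multiple range test.

    Means are sorted descending.  A contiguous stretch of p ordered means
    is homogeneous when its range does not exceed the least significant
    range R_p; following Duncan's protection rule, any difference inside a
    homogeneous stretch is declared nonsignificant.  Letters are assigned
    to the maximal homogeneous stretches, so the grouping is automatically
    order-consistent.
    """
    if ms_error <= 0:
        raise ValueError("ms_error must be positive")
    if df_error < 1:
        raise ValueError("df_error must be >= 1")
    items = sorted(cell_means.items(), key=lambda kv: -kv[1])
    levels = [k for k, _ in items]
    means = np.array([v for _, v in items], dtype=float)
    k = len(levels)
    if k == 1:
        return DuncanGrouping(levels, means, ["a"], alpha)
    ranges = _duncan_critical_ranges(k, ms_error, df_error, n_per_mean, alpha)

    def homogeneous(i: int, j: int) -> bool:
        return i == j or (means[i] - means[j]) <= ranges[j - i + 1]

    # all homogeneous stretches (the range test is not monotone in stretch
    # length, so every end point must be checked), then the maximal ones
    stretches = [
        (i, max(j for j in range(i, k) if homogeneous(i, j)))
        for i in range(k)
    ]
    maximal = [
        (a, b)
        for a, b in stretches
        if not any((c <= a and b <= d) and (a, b) != (c, d) for c, d in stretches)
    ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = ["" for _ in range(k)]
    for idx, (a, b) in enumerate(sorted(maximal)):
        ch = alphabet[idx % len(alphabet)]
        for pos in range(a, b + 1):
            letters[pos] += ch
    return DuncanGrouping(levels, means, letters, alpha, ranges)


def duncan_from_anova(
    table: AIETable,
    anova: AnovaResult,
    factor: str,
    alpha: float = 0.05,
) -> DuncanGrouping:
    """Duncan grouping of one factor's mean AIEs using the ANOVA error term."""
    if factor not in ("dataset", "classifier"):
        raise ValueError("factor must be 'dataset' or 'classifier'")
    df = table.table
    means = df.groupby(factor)["aie"].mean().to_dict()
    n_per_mean = int(df.groupby(factor).size().min())
    return duncan_groups(
        means,
        ms_error=anova.residual_variance,
        df_error=anova.residual_df,
        n_per_mean=n_per_mean,
        alpha=alpha,
    )
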