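"""Diagnostic evaluation of the count-of-criteria classifier.

Given per-category improvement counts (category = number of cut-point
criteria met, 0-3), this module derives every reported evaluation statistic:

* per-category improvement probability (positive predictive value, the
  "probability of accuracy");
* the 2x2 table at a count threshold k, with sensitivity, specificity,
  positive/negative likelihood ratios (LR+ = sens / (1 - spec),
  LR- = (1 - sens) / spec);
* the four-point empirical ROC curve swept over k in {3, 2, 1, 0};
* one-way ANOVA across count categories of the rectal-temperature deltas,
  Fisher's LSD pairwise contrasts (unadjusted t tests on the pooled ANOVA
  error term, 95% CIs), and Hedges' g effect sizes with magnitude labels.

Truth is the observed improvement label (rectal temperature dropped);
"positive" is predicted improvement at the count threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError

__all__ = [
    "CategoryCounts",
    "ContingencyTable",
    "DiagnosticStats",
    "GroupComparison",
    "DiagnosticsReport",
    "build_contingency",
    "diagnostic_stats",
    "ppv_per_category",
    "roc_over_k",
    "one_way_anova",
    "lsd_pairwise",
    "hedges_g",
    "magnitude_label",
    "build_report",
]

_CATEGORIES = (0, 1, 2, 3)


@dataclass(frozen=True)
class CategoryCounts:
    """Improved / total observation counts per criteria-met category 0..3."""

    improved: tuple[int, int, int, int]
    total: tuple[int, int, int, int]

    def __post_init__(self):
        for c in _CATEGORIES:
            if not 0 <= self.improved[c] <= self.total[c]:
                raise DataError(
                    f"category {c}: improved {self.improved[c]} exceeds total {self.total[c]}"
                )

    @classmethod
    def from_classification(
        cls, classified: pd.DataFrame, observations: pd.DataFrame
    ) -> "CategoryCounts":
        """Tally categories from a classification table joined to labels."""
        merged = classified.merge(
            observations[["participant_id", "induction", "improved"]],
            on=["participant_id", "induction"],
            validate="one_to_one",
        )
        improved = [0, 0, 0, 0]
        total = [0, 0, 0, 0]
        for c, grp in merged.groupby("criteria_met"):
            total[int(c)] = len(grp)
            improved[int(c)] = int(grp["improved"].sum())
        return cls(tuple(improved), tuple(total))

    @property
    def n_improved_total(self) -> int:
        return sum(self.improved)

    @property
    def n_total(self) -> int:
        return sum(self.total)

    def merged(self) -> dict[str, tuple[int, int]]:
        """(improved, total) per reported category: '0', '1', '2-3'."""
        return {
            "0": (self.improved[0], self.total[0]),
            "1": (self.improved[1], self.total[1]),
            "2-3": (
                self.improved[2] + self.improved[3],
                self.total[2] + self.total[3],
            ),
        }


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: positive = predicted improved at the count threshold."""

    tp: int
    fp: int
    fn: int
    tn: int


@dataclass(frozen=True)
class DiagnosticStats:
    sensitivity: float
    specificity: float
    lr_positive: float  # +inf when specificity == 1
    lr_negative: float
    ppv: float


def build_contingency(counts: CategoryCounts, k: int) -> ContingencyTable:
    """2x2 table for the rule "predict improved when criteria_met >= k"."""
    if k not in (0, 1, 2, 3):
        raise ConfigurationError(f"count threshold k must lie in 0..3, got {k}")
    tp = sum(counts.improved[c] for c in _CATEGORIES if c >= k)
    pos = sum(counts.total[c] for c in _CATEGORIES if c >= k)
    fp = pos - tp
    fn = counts.n_improved_total - tp
    tn = (counts.n_total - counts.n_improved_total) - fp
    return ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn)


def diagnostic_stats(table: ContingencyTable) -> DiagnosticStats:
    """Sensitivity, specificity, likelihood ratios, and PPV of a 2x2 table."""
    n_pos_truth = table.tp + table.fn
    n_neg_truth = table.fp + table.tn
    if n_pos_truth == 0:
        raise DataError("no truly improved observations (sensitivity undefined)")
    if n_neg_truth == 0:
        raise DataError("no truly non-improved observations (specificity undefined)")
    sens = table.tp / n_pos_truth
    spec = table.tn / n_neg_truth
    lr_pos = math.inf if spec == 1.0 else sens / (1.0 - spec)
    lr_neg = math.inf if spec == 0.0 else (1.0 - sens) / spec
    n_pred_pos = table.tp + table.fp
    ppv = table.tp / n_pred_pos if n_pred_pos else float("nan")
    return DiagnosticStats(
        sensitivity=sens,
        specificity=spec,
        lr_positive=lr_pos,
        lr_negative=lr_neg,
        ppv=ppv,
    )


def ppv_per_category(counts: CategoryCounts) -> dict[str, float]:
    """Improvement probability per reported category ('0', '1', '2-3').

    Empty categories are omitted with a warning.  Values are proportions;
    multiply by 100 for the percentage form (e.g. 22/23 -> 95.7%).
    """
    out = {}
    for name, (n_imp, n_tot) in counts.merged().items():
        if n_tot == 0:
            warnings.warn(f"category {name!r} is empty; omitted from PPV report")
            continue
        out[name] = n_imp / n_tot
    return out


def roc_over_k(counts: CategoryCounts) -> list[tuple[float, float]]:
    """Empirical ROC points (1 - specificity, sensitivity) over k = 3, 2, 1, 0.

    Includes the trivial (0, 0) endpoint; the k = 0 rule predicts everything
    positive and lands at (1, 1).  Points are monotone non-decreasing in both
    coordinates as k decreases.
    """
    points = [(0.0, 0.0)]
    for k in (3, 2, 1, 0):
        s = diagnostic_stats(build_contingency(counts, k))
        points.append((1.0 - s.specificity, s.sensitivity))
    return points


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA F and p across the per-category delta groups.

    Requires >= 2 groups of >= 2 values; degenerate inputs with zero
    within-group variance everywhere raise rather than returning NaN.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise DataError("ANOVA needs >= 2 groups with >= 2 values each")
    if all(np.ptp(a) == 0 for a in arrays):
        raise DataError("zero within-group variance in every group; F undefined")
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def hedges_g(
    n_a: int, mean_a: float, sd_a: float, n_b: int, mean_b: float, sd_b: float
) -> tuple[float, str]:
    """Bias-corrected standardized mean difference (a minus b) and magnitude.

    g = J * (mean_a - mean_b) / s_p with pooled SD
    s_p = sqrt(((n_a-1) sd_a^2 + (n_b-1) sd_b^2) / (n_a+n_b-2)) and
    small-sample correction J = 1 - 3 / (4 (n_a+n_b-2) - 1).
    """
    if n_a < 2 or n_b < 2:
        raise DataError("Hedges' g needs n >= 2 per group")
    if sd_a < 0 or sd_b < 0:
        raise DataError("SDs must be non-negative")
    df = n_a + n_b - 2
    s_p = math.sqrt(((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df)
    if s_p == 0:
        raise DataError("pooled SD is zero; effect size undefined")
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = j * (mean_a - mean_b) / s_p
    return g, magnitude_label(g)


def magnitude_label(g: float) -> str:
    """Magnitude bands on |g|: <0.2 negligible, [0.2,0.5) small,
    [0.5,0.8) medium, >=0.8 large."""
    a = abs(g)
    if a < 0.2:
        return "negligible"
    if a < 0.5:
        return "small"
    if a < 0.8:
        return "medium"
    return "large"


def lsd_pairwise(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> pd.DataFrame:
    """Fisher's LSD pairwise contrasts on the pooled ANOVA error term.

    For each pair (a, b): t = (m_a - m_b) / sqrt(MSE (1/n_a + 1/n_b)) on
    N - g degrees of freedom; the CI uses the same standard error and t
    critical value.  No multiplicity adjustment (that is what LSD means).
    Groups with n < 2 are excluded with a warning.
    """
    usable: dict[str, np.ndarray] = {}
    for name, vals in groups.items():
        a = np.asarray(vals, dtype=float)
        if len(a) < 2:
            warnings.warn(f"group {name!r} has n < 2; excluded from LSD contrasts")
            continue
        usable[name] = a
    if len(usable) < 2:
        raise DataError("LSD needs >= 2 groups with n >= 2")

    n_total = sum(len(a) for a in usable.values())
    n_groups = len(usable)
    df_err = n_total - n_groups
    ssw = sum(((a - a.mean()) ** 2).sum() for a in usable.values())
    mse = ssw / df_err
    if mse == 0:
        raise DataError("zero pooled error variance; LSD undefined")
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df_err)

    rows = []
    for name_a, name_b in combinations(usable, 2):
        a, b = usable[name_a], usable[name_b]
        diff = a.mean() - b.mean()
        se = math.sqrt(mse * (1.0 / len(a) + 1.0 / len(b)))
        t_stat = diff / se
        p = 2.0 * stats.t.sf(abs(t_stat), df_err)
        g, mag = hedges_g(len(a), a.mean(), a.std(ddof=1), len(b), b.mean(), b.std(ddof=1))
        rows.append(
            {
                "pair": f"{name_a} vs {name_b}",
                "mean_difference": diff,
                "ci95_low": diff - t_crit * se,
                "ci95_high": diff + t_crit * se,
                "t": t_stat,
                "lsd_p": p,
                "hedges_g": g,
                "magnitude": mag,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GroupComparison:
    """Per-category delta summaries with ANOVA and LSD contrasts."""

    summaries: pd.DataFrame  # columns: category, n, mean, sd
    anova_f: float
    anova_p: float
    pairwise: pd.DataFrame


@dataclass
class DiagnosticsReport:
    """Machine-readable evaluation of the classifier at one count threshold."""

    k: int
    counts: CategoryCounts
    ppv: dict[str, float]
    stats: DiagnosticStats
    roc: list[tuple[float, float]]
    groups: GroupComparison | None = None
    logistic: list = field(default_factory=list)

    def to_dict(self) -> dict:
        def _num(x):
            if x is None or (isinstance(x, float) and math.isnan(x)):
                return None
            if isinstance(x, float) and math.isinf(x):
                return "inf"
            return float(x)

        out = {
            "k": self.k,
            "category_counts": {
                name: {"improved": imp, "total": tot}
                for name, (imp, tot) in self.counts.merged().items()
            },
            "ppv": {name: _num(v) for name, v in self.ppv.items()},
            "ppv_percent": {name: _num(100.0 * v) for name, v in self.ppv.items()},
            "sensitivity": _num(self.stats.sensitivity),
            "specificity": _num(self.stats.specificity),
            "lr_positive": _num(self.stats.lr_positive),
            "lr_negative": _num(self.stats.lr_negative),
            "roc": [[_num(x), _num(y)] for x, y in self.roc],
        }
        if self.groups is not None:
            out["anova"] = {"F": _num(self.groups.anova_f), "p": _num(self.groups.anova_p)}
            out["group_summaries"] = self.groups.summaries.to_dict(orient="records")
            out["pairwise"] = self.groups.pairwise.to_dict(orient="records")
        if self.logistic:
            out["logistic"] = [
                {
                    "variable": f.variable,
                    "intercept": _num(f.intercept),
                    "slope": _num(f.slope),
                    "wald_p": _num(f.wald_p),
                    "pseudo_r2_cox_snell": _num(f.pseudo_r2_cox_snell),
                    "pseudo_r2_nagelkerke": _num(f.pseudo_r2_nagelkerke),
                    "converged": bool(f.converged),
                }
                for f in self.logistic
            ]
        return out

    def text_summary(self) -> str:
        """Venn-style plain-text rendering of the classifier result."""
        lines = ["Criteria-count regions (improved / total, PPV):"]
        for name, (imp, tot) in self.counts.merged().items():
            if tot:
                lines.append(
                    f"  {name:>4} criteria met: {imp:3d} / {tot:3d}  ({100.0 * imp / tot:.1f}%)"
                )
            else:
                lines.append(f"  {name:>4} criteria met: (empty)")
        s = self.stats
        lr_pos = "inf" if math.isinf(s.lr_positive) else f"{s.lr_positive:.1f}"
        lines.append(
            f"At k >= {self.k}: sensitivity {s.sensitivity:.2f}, "
            f"specificity {s.specificity:.2f}, LR+ {lr_pos}, LR- {s.lr_negative:.2f}"
        )
        return "\n".join(lines)


def build_report(
    observations: pd.DataFrame,
    classified: pd.DataFrame,
    k: int = 2,
    logistic_fits=(),
) -> DiagnosticsReport:
    """Assemble the full diagnostics report from pooled observations.

    The group comparison pools rectal-temperature deltas by reported
    category ('2-3', '1', '0') and runs ANOVA + LSD when at least two
    categories have n >= 2.
    """
    counts = CategoryCounts.from_classification(classified, observations)
    stats_k = diagnostic_stats(build_contingency(counts, k))
    ppv = ppv_per_category(counts)
    roc = roc_over_k(counts)

    merged = classified.merge(
        observations[["participant_id", "induction", "d_trec"]],
        on=["participant_id", "induction"],
        validate="one_to_one",
    )
    cat_name = np.where(merged["criteria_met"] >= 2, "2-3", merged["criteria_met"].astype(str))
    merged = merged.assign(category=cat_name)
    group_vals = {
        name: grp["d_trec"].to_numpy()
        for name, grp in merged.groupby("category")
        if len(grp) >= 2
    }
    groups = None
    if len(group_vals) >= 2:
        f, p = one_way_anova(list(group_vals.values()))
        pairwise = lsd_pairwise(group_vals)
        summaries = pd.DataFrame(
            [
                {
                    "category": name,
                    "n": len(v),
                    "mean_d_trec": float(np.mean(v)),
                    "sd_d_trec": float(np.std(v, ddof=1)),
                }
                for name, v in sorted(group_vals.items(), reverse=True)
            ]
        )
        groups = GroupComparison(summaries=summaries, anova_f=f, anova_p=p, pairwise=pairwise)

    return DiagnosticsReport(
        k=k, counts=counts, ppv=ppv, stats=stats_k, roc=roc,
        groups=groups, logistic=list(logistic_fits),
    )
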