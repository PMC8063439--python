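"""Survival stratification by marker-gene expression.

Patients are dichotomized on a single gene's expression (median split by
default, or lowest tertile vs rest), Kaplan-Meier curves are estimated per
group and the groups are compared with the log-rank test.  Follows the
Model/Results pattern: ``SurvivalStratification(...).fit()`` returns a
results object with the curves, the test and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, SampleAnnotation
from .stats import TestResult, km_estimate, logrank

__all__ = ["SurvivalStratification", "SurvivalResults", "survival_stratify"]


class SurvivalStratification:
    """Dichotomize expression of one gene and compare survival between groups.

    Parameters
    ----------
    expr, annot
        Expression matrix and sample annotation carrying ``survival_time``
        (days) and ``event`` (1 = event observed, 0 = censored).
    marker_gene
        Gene whose expression stratifies the patients.
    rule
        ``"median"`` (low = below median) or ``"tertile_low_vs_rest"``
        (low = lowest tertile).
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        annot: SampleAnnotation,
        marker_gene: str,
        rule: str = "median",
    ) -> None:
        if marker_gene not in expr.values.columns:
            raise ValueError(f"marker gene {marker_gene!r} not in expression matrix")
        if rule not in ("median", "tertile_low_vs_rest"):
            raise ValueError(f"unknown dichotomization rule {rule!r}")
        self.expr = expr
        self.annot = annot
        self.marker_gene = marker_gene
        self.rule = rule

    def fit(self) -> "SurvivalResults":
        t = self.annot.indexed()
        marker = self.expr.values[self.marker_gene]
        shared = [s for s in marker.index if s in t.index]
        surv = pd.DataFrame(
            {
                "expr": marker.loc[shared],
                "time": pd.to_numeric(t.loc[shared, "survival_time"], errors="coerce"),
                "event": pd.to_numeric(t.loc[shared, "event"], errors="coerce"),
            }
        ).dropna()
        if self.rule == "median":
            cut = surv["expr"].median()
        else:
            cut = surv["expr"].quantile(1 / 3)
        low = surv["expr"] < cut
        if low.sum() < 2 or (~low).sum() < 2:
            raise ValueError("need >= 2 patients with survival data per group")
        groups = {"low": surv[low], "high": surv[~low]}
        km = {
            name: km_estimate(g["time"], g["event"].astype(int)) for name, g in groups.items()
        }
        test = logrank(
            groups["low"]["time"], groups["low"]["event"].astype(int),
            groups["high"]["time"], groups["high"]["event"].astype(int),
        )
        return SurvivalResults(
            marker_gene=self.marker_gene,
            rule=self.rule,
            cutpoint=float(cut),
            group_sizes={k: len(v) for k, v in groups.items()},
            events={k: int(v["event"].sum()) for k, v in groups.items()},
            km=km,
            logrank=test,
        )


@dataclass
class SurvivalResults:
    marker_gene: str
    rule: str
    cutpoint: float
    group_sizes: dict[str, int]
    events: dict[str, int]
    km: dict[str, tuple[np.ndarray, np.ndarray]]
    logrank: TestResult

    def summary(self) -> str:
        return "\n".join(
            [
                f"Survival by {self.marker_gene} expression ({self.rule} split)",
                "=" * 41,
                f"low group   n={self.group_sizes['low']:>4d}, events={self.events['low']}",
                f"high group  n={self.group_sizes['high']:>4d}, events={self.events['high']}",
                f"log-rank chi2 = {self.logrank.statistic:.3f}, p = {self.logrank.p_value:.4g}",
            ]
        )

    def plot(self, ax=None):
        """Kaplan-Meier curves for the low/high expression groups."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for name, (t, s) in self.km.items():
            ax.step(t, s, where="post", label=f"{name} {self.marker_gene}")
        ax.set_xlabel("time (days)")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.02)
        ax.legend()
        return ax


def survival_stratify(
    expr: ExpressionMatrix,
    annot: SampleAnnotation,
    marker_gene: str,
    rule: str = "median",
) -> SurvivalResults:
    """Functional wrapper around :class:`SurvivalStratification`."""
    return SurvivalStratification(expr, annot, marker_gene, rule=rule).fit()
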