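"""Cohort-level methylation summaries, control QC and molecular associations.

These operations mirror the first stage of a promoter-methylation study:
global beta-value summaries per sample and per probe, checks on the
unmethylated / in-vitro-methylated control samples and technical replicates,
and two-sample comparisons of global methylation between molecular feature
groups (MSI status, driver-gene mutations) plus the doubling-time
association.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BetaMatrix, SampleAnnotation
from .stats import TestResult, pearson, spearman, two_sample_t

__all__ = [
    "CohortSummary",
    "summarize_cohort",
    "ControlReport",
    "qc_controls",
    "feature_association",
    "growth_association",
]


@dataclass
class CohortSummary:
    """Global methylation summary of one cohort."""

    sample_means: pd.Series
    sample_mean_range: tuple[float, float]
    probe_means: pd.Series
    bin_edges: np.ndarray
    histogram_fractions: np.ndarray  # fraction of probes per bin, sums to 1
    fraction_below_02: float
    fraction_above_05: float


def summarize_cohort(beta: BetaMatrix, bins=None) -> CohortSummary:
    """Per-sample and per-probe mean betas with a binned probe-mean histogram.

    Bins default to width 0.1 over [0,1]; they are closed on the left and
    open on the right except the top bin, which is closed on both sides.
    Missing values are ignored in every mean.
    """
    if beta.values.size == 0:
        raise ValueError("empty beta matrix")
    edges = np.asarray(bins, float) if bins is not None else np.linspace(0.0, 1.0, 11)
    sample_means = beta.values.mean(axis=1, skipna=True)
    probe_means = beta.values.mean(axis=0, skipna=True)
    pm = probe_means.dropna().to_numpy()
    counts, _ = np.histogram(pm, bins=edges)  # numpy: left-closed, top bin closed
    fractions = counts / counts.sum() if counts.sum() else counts.astype(float)
    return CohortSummary(
        sample_means=sample_means,
        sample_mean_range=(float(sample_means.min()), float(sample_means.max())),
        probe_means=probe_means,
        bin_edges=edges,
        histogram_fractions=fractions,
        fraction_below_02=float((pm < 0.2).mean()),
        fraction_above_05=float((pm > 0.5).mean()),
    )


@dataclass
class ControlReport:
    """Control-sample means, replicate correlations and raised QC flags."""

    control_means: dict[str, float]  # sample_id -> mean beta
    replicate_r: dict[tuple[str, str], float]
    flags: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.flags


def qc_controls(
    beta: BetaMatrix,
    annot: SampleAnnotation,
    neg_max: float = 0.15,
    pos_min: float = 0.70,
    replicate_r_min: float = 0.95,
) -> ControlReport:
    """Check control-sample means and replicate-pair Pearson correlation."""
    t = annot.indexed()
    means: dict[str, float] = {}
    reps: dict[tuple[str, str], float] = {}
    flags: list[str] = []
    for sid, role in t["control_role"].fillna("none").astype(str).items():
        if sid not in beta.values.index:
            continue
        if role in ("unmethylated_control", "methylated_control"):
            m = float(beta.values.loc[sid].mean())
            means[sid] = m
            if role == "unmethylated_control" and m > neg_max:
                flags.append(f"negative control {sid} mean beta {m:.3f} > {neg_max}")
            if role == "methylated_control" and m < pos_min:
                flags.append(f"positive control {sid} mean beta {m:.3f} < {pos_min}")
        elif role.startswith("replicate_of:"):
            src = role.split(":", 1)[1]
            if src in beta.values.index:
                r = pearson(beta.values.loc[sid], beta.values.loc[src]).statistic
                reps[(src, sid)] = float(r)
                if r < replicate_r_min:
                    flags.append(f"replicate pair ({src}, {sid}) r {r:.3f} < {replicate_r_min}")
    return ControlReport(control_means=means, replicate_r=reps, flags=flags)


def _sample_mean_beta(beta: BetaMatrix, annot: SampleAnnotation,
                      cohort: str | None) -> pd.Series:
    samples = annot.analysis_samples()
    if cohort is not None:
        t = annot.indexed()
        samples = [s for s in samples if t.loc[s, "cohort"] == cohort]
    samples = [s for s in samples if s in beta.values.index]
    return beta.values.loc[samples].mean(axis=1, skipna=True)


def feature_association(
    beta: BetaMatrix,
    annot: SampleAnnotation,
    feature: str,
    cohort: str | None = None,
    welch: bool = False,
) -> TestResult:
    """t-test of per-sample mean beta between two feature groups.

    ``feature`` is ``"msi"`` (MSI vs MSS) or ``"mutation:<GENE>"`` (mut vs
    wt); samples with unknown status are excluded.  The returned
    ``estimate`` is mean(first group) - mean(second group), so its sign
    reports which group is more methylated.
    """
    means = _sample_mean_beta(beta, annot, cohort)
    t = annot.indexed()
    if feature == "msi":
        labels = t.loc[means.index, "msi_status"].astype(str)
        groups = ("MSI", "MSS")
    elif feature.startswith("mutation:"):
        gene = feature.split(":", 1)[1]
        if gene not in t.columns:
            raise ValueError(f"no mutation column for gene {gene!r}")
        labels = t.loc[means.index, gene].astype(str)
        groups = ("mut", "wt")
    else:
        raise ValueError(f"unknown feature {feature!r}")
    a = means[labels == groups[0]]
    b = means[labels == groups[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"feature {feature!r}: need >= 2 samples per group, got {len(a)} vs {len(b)}"
        )
    return two_sample_t(a, b, welch=welch)


def growth_association(
    beta: BetaMatrix,
    annot: SampleAnnotation,
    method: str = "pearson",
    cohort: str | None = None,
) -> TestResult:
    """Correlation between per-sample mean beta and doubling time (hours).

    A negative correlation means hypermethylated samples grow faster.
    Samples with missing doubling times are dropped pairwise.
    """
    means = _sample_mean_beta(beta, annot, cohort)
    t = annot.indexed()
    dt = pd.to_numeric(t.loc[means.index, "doubling_time"], errors="coerce")
    if method == "pearson":
        return pearson(means, dt)
    if method == "spearman":
        return spearman(means, dt)
    raise ValueError(f"unknown method {method!r}")
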