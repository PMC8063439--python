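"""Seeded synthetic cohorts with the statistical structure the screen assumes.

The generator emulates an Infinium-27K-style promoter methylation study of
colorectal cancer cell lines plus an independent tumor cohort:

* bimodal beta values: each CpG probe has a high-methylation propensity; the
  realised state per (probe, sample) is Bernoulli in that propensity plus a
  per-sample global effect, and beta is drawn from a low (mean ~0.1) or high
  (mean ~0.8) Beta component accordingly;
* an unmethylated control sample (mean beta ~0.05), an in-vitro methylated
  control (~0.86) and one technical replicate pair;
* MSI samples receive extra high-component weight producing a configurable
  mean beta shift;
* planted silenced genes: monotone-negative (Spearman rho ~ -0.8 between
  promoter beta and expression) and L-shaped (expression high only at low
  beta, floor elsewhere, weak rank correlation);
* promoter sequences with Gardiner-Garden-Frommer-compliant CpG islands
  embedded in CpG-depleted background at a configurable per-class rate;
* exponential survival with an elevated hazard for the below-median group of
  a methylation-silenced marker gene, and doubling times negatively
  correlated with global methylation.

Everything is deterministic given ``SimulationConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    BetaMatrix,
    ExpressionMatrix,
    ProbeAnnotation,
    PromoterSequence,
    SampleAnnotation,
    MUTATION_GENES,
)

__all__ = [
    "SimulationConfig",
    "StudyData",
    "plan_gene_classes",
    "simulate_methylation",
    "simulate_expression",
    "simulate_promoters",
    "simulate_survival",
    "simulate_doubling_time",
    "simulate_study",
]

_LOW_BETA = (2.0, 18.0)  # Beta(a,b), mean 0.1 — unmethylated component
_HIGH_BETA = (16.0, 4.0)  # mean 0.8 — methylated component
_PROPENSITY_LEVELS = (0.05, 0.35, 0.8)  # mostly-low, intermediate, mostly-high
_PROPENSITY_WEIGHTS = (0.54, 0.10, 0.36)
_PLANTED_PROPENSITY = 0.5  # planted genes vary across samples
_BETA_SPAN = 0.7  # mean(high) - mean(low); converts propensity to beta scale


@dataclass
class SimulationConfig:
    """Cohort sizes, effect sizes and noise levels of the synthetic study.

    Defaults reproduce the study conditions the screen was designed for:
    45 cell lines profiled for methylation, expression for the first 30,
    an independent cohort of 223 tumors, ~2 probes per promoter, controls
    with mean beta 0.05 / 0.86, a 0.05 MSI beta shift, and survival follow-up
    for 132 patients with a hazard ratio of 3 for the low-expression group of
    the marker gene.
    """

    n_samples_cellline: int = 45
    n_samples_expression: int = 30  # cell lines with expression data
    n_samples_tumor: int = 223
    n_genes: int = 2000
    probes_per_gene: int = 2
    frac_silenced_monotone: float = 0.10
    frac_silenced_lshape: float = 0.01
    msi_fraction: float = 0.30
    msi_beta_shift: float = 0.05
    control_means: tuple[float, float] = (0.05, 0.86)
    noise_sd_expr: float = 0.5
    target_rho_monotone: float = -0.8
    lshape_beta_cut: float = 0.33
    lshape_high_fraction: float = 0.5
    island_fraction: float = 0.66
    island_fraction_silenced: float = 0.79
    promoter_length: int = 1500
    island_length: int = 300
    tss_offset: int = 1000
    sample_effect_sd: float = 0.055
    replicate_noise_sd: float = 0.01
    # survival (times in days)
    n_samples_survival: int = 132
    baseline_hazard: float = 1.0 / 1500.0
    hazard_ratio_low_expr: float = 3.0
    censoring_rate: float = 0.30
    # doubling time (hours), negatively tied to global methylation
    doubling_time_intercept: float = 55.0
    doubling_time_slope: float = 70.0
    doubling_time_noise_sd: float = 4.0
    tumor_gene_availability: float = 0.882
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = {
            "frac_silenced_monotone": self.frac_silenced_monotone,
            "frac_silenced_lshape": self.frac_silenced_lshape,
            "msi_fraction": self.msi_fraction,
            "island_fraction": self.island_fraction,
            "island_fraction_silenced": self.island_fraction_silenced,
            "tumor_gene_availability": self.tumor_gene_availability,
        }
        for name, v in fracs.items():
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if self.frac_silenced_monotone + self.frac_silenced_lshape > 1:
            raise ValueError("planted fractions sum to more than 1")
        for name in ("n_samples_cellline", "n_samples_expression", "n_samples_tumor",
                     "n_genes", "probes_per_gene"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for m in self.control_means:
            if not 0 <= m <= 1:
                raise ValueError("control means must lie in [0,1]")

    def to_dict(self) -> dict:
        return asdict(self)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _beta_with_mean(rng: np.random.Generator, mean: float, conc: float, size) -> np.ndarray:
    a = mean * conc
    b = (1 - mean) * conc
    return rng.beta(a, b, size=size)


def plan_gene_classes(cfg: SimulationConfig, rng: np.random.Generator) -> pd.Series:
    """Assign each gene to 'null' / 'monotone' / 'lshape' (the truth table)."""
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    n_mono = int(round(cfg.frac_silenced_monotone * cfg.n_genes))
    n_l = int(round(cfg.frac_silenced_lshape * cfg.n_genes))
    classes = np.array(["null"] * cfg.n_genes, dtype=object)
    idx = rng.permutation(cfg.n_genes)
    classes[idx[:n_mono]] = "monotone"
    classes[idx[n_mono : n_mono + n_l]] = "lshape"
    return pd.Series(classes, index=genes, name="gene_class")


def _probe_layout(cfg: SimulationConfig, gene_classes: pd.Series,
                  rng: np.random.Generator) -> tuple[ProbeAnnotation, np.ndarray]:
    """Probe annotation plus per-probe high-methylation propensity."""
    genes = list(gene_classes.index)
    probe_ids, gene_of_probe, prop = [], [], []
    for gi, gene in enumerate(genes):
        planted = gene_classes[gene] != "null"
        for k in range(cfg.probes_per_gene):
            probe_ids.append(f"cg{gi:05d}_{k}")
            gene_of_probe.append(gene)
            if planted:
                prop.append(_PLANTED_PROPENSITY)
            else:
                prop.append(rng.choice(_PROPENSITY_LEVELS, p=_PROPENSITY_WEIGHTS))
    table = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "gene_symbol": gene_of_probe,
            "chromosome": "chr1",
            "position": np.arange(len(probe_ids)) * 1000,
        }
    )
    return ProbeAnnotation(table), np.asarray(prop, dtype=float)


def simulate_methylation(
    cfg: SimulationConfig,
    gene_classes: pd.Series,
    probes: ProbeAnnotation,
    propensity: np.ndarray,
    cohort: str = "cell_line",
    rng: np.random.Generator | None = None,
) -> tuple[BetaMatrix, SampleAnnotation]:
    """Draw the beta matrix and sample annotation for one cohort.

    Cell-line cohorts get the two control samples and one technical
    replicate appended; tumor cohorts get plain samples only.
    """
    rng = rng if rng is not None else cfg.rng()
    n = cfg.n_samples_cellline if cohort == "cell_line" else cfg.n_samples_tumor
    prefix = "CL" if cohort == "cell_line" else "TU"
    sample_ids = [f"{prefix}{i:03d}" for i in range(n)]
    n_probes = len(propensity)

    msi = rng.random(n) < cfg.msi_fraction
    sample_effect = rng.normal(0.0, cfg.sample_effect_sd, size=n)
    shift_w = cfg.msi_beta_shift / _BETA_SPAN

    # planted genes share one methylation state across their probes per sample
    gene_of_probe = probes.table["gene_symbol"].to_numpy()
    planted_mask = gene_classes.loc[gene_of_probe].to_numpy() != "null"

    p = np.clip(
        propensity[None, :] + sample_effect[:, None] + shift_w * msi[:, None],
        0.005,
        0.995,
    )
    u = rng.random((n, n_probes))
    if planted_mask.any():
        # reuse the first probe's uniform for all probes of a planted gene
        first_idx = pd.Series(np.arange(n_probes)).groupby(gene_of_probe).transform("min").to_numpy()
        u[:, planted_mask] = u[:, first_idx[planted_mask]]
    high = u < p
    low_draw = rng.beta(*_LOW_BETA, size=(n, n_probes))
    high_draw = rng.beta(*_HIGH_BETA, size=(n, n_probes))
    values = np.where(high, high_draw, low_draw)

    frame = pd.DataFrame(values, index=sample_ids, columns=probes.table["probe_id"])
    annot = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "cohort": cohort,
            "msi_status": np.where(msi, "MSI", "MSS"),
            "control_role": "none",
        }
    )
    for gene in MUTATION_GENES:
        freq = {"APC": 0.6, "BRAF": 0.1, "TP53": 0.5, "KRAS": 0.4, "PIK3CA": 0.2}[gene]
        annot[gene] = np.where(rng.random(n) < freq, "mut", "wt")

    if cohort == "cell_line":
        neg = _beta_with_mean(rng, cfg.control_means[0], 40.0, n_probes)
        pos = _beta_with_mean(rng, cfg.control_means[1], 20.0, n_probes)
        rep_src = sample_ids[0]
        rep = np.clip(
            frame.loc[rep_src].to_numpy() + rng.normal(0, cfg.replicate_noise_sd, n_probes),
            0.0,
            1.0,
        )
        extra = pd.DataFrame(
            [neg, pos, rep],
            index=["CTRL_NEG", "CTRL_POS", f"{rep_src}_rep"],
            columns=frame.columns,
        )
        frame = pd.concat([frame, extra])
        extra_annot = pd.DataFrame(
            {
                "sample_id": ["CTRL_NEG", "CTRL_POS", f"{rep_src}_rep"],
                "cohort": cohort,
                "msi_status": "unknown",
                "control_role": [
                    "unmethylated_control",
                    "methylated_control",
                    f"replicate_of:{rep_src}",
                ],
            }
        )
        annot = pd.concat([annot, extra_annot], ignore_index=True)

    return BetaMatrix(frame), SampleAnnotation(annot)


def _gene_level_beta(beta: BetaMatrix, probes: ProbeAnnotation,
                     samples: Sequence[str]) -> pd.DataFrame:
    mapping = probes.probe_to_gene
    sub = beta.values.loc[list(samples)]
    return sub.T.groupby(mapping.loc[sub.columns]).mean().T


def simulate_expression(
    cfg: SimulationConfig,
    beta: BetaMatrix,
    probes: ProbeAnnotation,
    gene_classes: pd.Series,
    samples: Sequence[str],
    rng: np.random.Generator,
    gene_subset: Sequence[str] | None = None,
) -> ExpressionMatrix:
    """Expression tied to realised promoter beta according to each gene's class.

    null: independent Gaussian around a gene-specific mean.
    monotone: linear in beta with slope set so Spearman rho ~ target.
    lshape: high arm only below ``lshape_beta_cut`` (with probability
    ``lshape_high_fraction``), floor plus noise elsewhere.
    """
    gene_beta = _gene_level_beta(beta, probes, samples)
    genes = list(gene_classes.index) if gene_subset is None else list(gene_subset)
    n = len(samples)
    out = pd.DataFrame(index=list(samples), columns=genes, dtype=float)
    # Fixed signal amplitude (log2 units): slope * sd(beta) = 0.875, calibrated
    # so that with the default noise SD of 0.5 the realised Spearman rho of a
    # monotone-silenced gene on bimodal beta values is ~ target_rho_monotone.
    # As noise -> 0 the association becomes strictly monotone (rho -> -1).
    signal_sd = 0.875 * abs(cfg.target_rho_monotone) / 0.8
    for gene in genes:
        cls = gene_classes[gene]
        mu = rng.uniform(4.0, 10.0)
        noise = rng.normal(0.0, cfg.noise_sd_expr, size=n)
        b = gene_beta[gene].to_numpy(float)
        if cls == "monotone":
            slope = signal_sd / max(b.std(), 1e-6)
            out[gene] = mu + slope * (b.mean() - b) + noise
        elif cls == "lshape":
            floor = 2.0
            high = rng.uniform(6.0, 10.0, size=n)
            arm = (b < cfg.lshape_beta_cut) & (rng.random(n) < cfg.lshape_high_fraction)
            out[gene] = np.where(arm, high, floor + noise)
        else:
            out[gene] = mu + rng.normal(0.0, 1.0, size=n)
    return ExpressionMatrix(out)


def _random_dna(rng: np.random.Generator, length: int, gc: float, cpg_deplete: float = 0.9) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    letters = np.array(list("ACGT"))
    arr = rng.choice(4, size=length, p=p)
    seq = letters[arr]
    # deplete CpG dinucleotides: break most C->G adjacencies
    for i in np.flatnonzero((seq[:-1] == "C") & (seq[1:] == "G")):
        if rng.random() < cpg_deplete:
            seq[i + 1] = "A"
    return "".join(seq)


def _island_dna(rng: np.random.Generator, length: int) -> str:
    """CpG-rich GC-rich segment satisfying the GGF thresholds with margin."""
    out: list[str] = []
    letters = np.array(list("ACGT"))
    p = np.array([0.15, 0.32, 0.32, 0.21])
    while len(out) < length:
        if rng.random() < 0.22:
            out.extend("CG")
        else:
            out.append(str(rng.choice(letters, p=p)))
    return "".join(out[:length])


def simulate_promoters(
    cfg: SimulationConfig,
    gene_classes: pd.Series,
    rng: np.random.Generator,
) -> tuple[list[PromoterSequence], pd.DataFrame]:
    """Promoter sequences with truth intervals for embedded CpG islands.

    Silenced (planted) genes carry an island at ``island_fraction_silenced``;
    null genes at ``island_fraction``.  Islands are embedded overlapping the
    TSS so the default promoter window finds them.
    """
    seqs, truth_rows = [], []
    start = cfg.tss_offset - cfg.island_length // 2
    for gene, cls in gene_classes.items():
        frac = cfg.island_fraction if cls == "null" else cfg.island_fraction_silenced
        has_island = rng.random() < frac
        background = _random_dna(rng, cfg.promoter_length, gc=0.4)
        if has_island:
            island = _island_dna(rng, cfg.island_length)
            seq = background[:start] + island + background[start + cfg.island_length :]
            truth_rows.append((gene, True, start, start + cfg.island_length))
        else:
            seq = background
            truth_rows.append((gene, False, -1, -1))
        seqs.append(PromoterSequence(gene, seq, tss_offset=cfg.tss_offset))
    truth = pd.DataFrame(
        truth_rows, columns=["gene", "has_island", "island_start", "island_end"]
    ).set_index("gene")
    return seqs, truth


def simulate_survival(
    cfg: SimulationConfig,
    expr: ExpressionMatrix,
    marker_gene: str,
    annot: SampleAnnotation,
    rng: np.random.Generator,
    n_patients: int | None = None,
) -> SampleAnnotation:
    """Exponential event times; below-median marker expression raises hazard.

    Censoring is independent exponential, calibrated so that a fraction
    ``censoring_rate`` of baseline-group records is censored;
    ``censoring_rate >= 1`` censors everything.
    """
    marker = expr.values[marker_gene]
    n_pat = n_patients if n_patients is not None else cfg.n_samples_survival
    patients = list(expr.sample_ids)[: min(n_pat, len(expr.sample_ids))]
    marker = marker.loc[patients]
    low = marker < marker.median()
    rate = cfg.baseline_hazard * np.where(low, cfg.hazard_ratio_low_expr, 1.0)
    event_t = rng.exponential(1.0 / rate)
    if cfg.censoring_rate >= 1.0:
        times, events = rng.exponential(1.0 / cfg.baseline_hazard, size=len(patients)), np.zeros(len(patients), int)
    elif cfg.censoring_rate <= 0.0:
        times, events = event_t, np.ones(len(patients), int)
    else:
        c_rate = cfg.baseline_hazard * cfg.censoring_rate / (1 - cfg.censoring_rate)
        censor_t = rng.exponential(1.0 / c_rate, size=len(patients))
        times = np.minimum(event_t, censor_t)
        events = (event_t <= censor_t).astype(int)
    table = annot.table.copy().set_index("sample_id")
    table.loc[patients, "survival_time"] = times
    table.loc[patients, "event"] = events
    return SampleAnnotation(table.reset_index())


def simulate_doubling_time(
    cfg: SimulationConfig,
    beta: BetaMatrix,
    annot: SampleAnnotation,
    rng: np.random.Generator,
) -> SampleAnnotation:
    """Doubling times negatively correlated with per-sample mean methylation."""
    table = annot.table.copy().set_index("sample_id")
    samples = annot.analysis_samples()
    mean_beta = beta.values.loc[samples].mean(axis=1)
    dt = (
        cfg.doubling_time_intercept
        - cfg.doubling_time_slope * mean_beta
        + rng.normal(0, cfg.doubling_time_noise_sd, size=len(samples))
    )
    table.loc[samples, "doubling_time"] = np.maximum(dt, 5.0)
    return SampleAnnotation(table.reset_index())


@dataclass
class StudyData:
    """Full synthetic study: two cohorts, promoters, truth tables, marker."""

    config: SimulationConfig
    beta_cellline: BetaMatrix
    annot_cellline: SampleAnnotation
    expr_cellline: ExpressionMatrix
    beta_tumor: BetaMatrix
    annot_tumor: SampleAnnotation
    expr_tumor: ExpressionMatrix
    probes: ProbeAnnotation
    promoters: list[PromoterSequence]
    gene_classes: pd.Series
    island_truth: pd.DataFrame
    terms: dict[str, set[str]] = field(default_factory=dict)
    marker_gene: str = ""


def _synthetic_terms(gene_classes: pd.Series, rng: np.random.Generator,
                     n_random_terms: int = 20) -> dict[str, set[str]]:
    """Annotation terms: one enriched in planted genes plus random terms."""
    genes = np.array(gene_classes.index)
    planted = genes[gene_classes.to_numpy() != "null"]
    nulls = genes[gene_classes.to_numpy() == "null"]
    zinc: set[str] = set()
    if len(planted):
        zinc |= set(rng.choice(planted, size=max(1, int(0.3 * len(planted))), replace=False))
    if len(nulls):
        zinc |= set(rng.choice(nulls, size=max(1, int(0.03 * len(nulls))), replace=False))
    terms = {"ZINC_FINGER_LIKE": zinc}
    max_size = max(3, min(120, len(genes) // 2))
    for i in range(n_random_terms):
        size = int(rng.integers(2, max_size))
        terms[f"RANDOM_{i:02d}"] = set(rng.choice(genes, size=size, replace=False))
    return terms


def simulate_study(cfg: SimulationConfig) -> StudyData:
    """Generate the complete two-cohort study deterministically from the seed."""
    rng = cfg.rng()
    gene_classes = plan_gene_classes(cfg, rng)
    probes, propensity = _probe_layout(cfg, gene_classes, rng)

    beta_cl, annot_cl = simulate_methylation(cfg, gene_classes, probes, propensity,
                                             cohort="cell_line", rng=rng)
    expr_samples = annot_cl.analysis_samples()[: cfg.n_samples_expression]
    expr_cl = simulate_expression(cfg, beta_cl, probes, gene_classes, expr_samples, rng)
    annot_cl = simulate_doubling_time(cfg, beta_cl, annot_cl, rng)

    beta_tu, annot_tu = simulate_methylation(cfg, gene_classes, probes, propensity,
                                             cohort="tumor", rng=rng)
    n_avail = int(round(cfg.tumor_gene_availability * cfg.n_genes))
    avail_genes = sorted(rng.choice(gene_classes.index.to_numpy(), size=n_avail, replace=False))
    expr_tu = simulate_expression(cfg, beta_tu, probes, gene_classes,
                                  annot_tu.analysis_samples(), rng, gene_subset=avail_genes)

    promoters, island_truth = simulate_promoters(cfg, gene_classes, rng)

    # marker gene: a monotone-silenced gene observable in the survival cohort
    available = set(expr_tu.values.columns)
    mono = [str(g) for g in gene_classes.index[gene_classes == "monotone"] if str(g) in available]
    marker = mono[0] if mono else str(next(iter(sorted(available))))
    annot_tu = simulate_survival(cfg, expr_tu, marker, annot_tu, rng)

    terms = _synthetic_terms(gene_classes, rng)
    return StudyData(
        config=cfg,
        beta_cellline=beta_cl,
        annot_cellline=annot_cl,
        expr_cellline=expr_cl,
        beta_tumor=beta_tu,
        annot_tumor=annot_tu,
        expr_tumor=expr_tu,
        probes=probes,
        promoters=promoters,
        gene_classes=gene_classes,
        island_truth=island_truth,
        terms=terms,
        marker_gene=marker,
    )
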