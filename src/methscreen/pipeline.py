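"""End-to-end orchestration: simulate -> qc -> screen -> islands -> enrich -> survival.

``run_full`` executes every stage deterministically from a :class:`RunConfig`
(usually loaded from a YAML file), writes per-stage TSVs plus a single
human-readable summary, and logs every threshold and seed used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import feature_association, growth_association, qc_controls, summarize_cohort
from .enrichment import enrich_terms
from .io import (
    SampleAnnotation,
    read_fasta,
    read_matrix,
    read_probe_annotation,
    read_sample_annotation,
    write_fasta,
    write_matrix,
    write_table,
    align_cohort,
)
from .islands import associate_islands, ggf_scan, island_enrichment
from .screen import LShapeConfig, SilencingScreen
from .simulate import SimulationConfig, StudyData, simulate_study
from .survival import survival_stratify

__all__ = ["RunConfig", "run_full", "write_study"]

log = logging.getLogger("methscreen")


@dataclass
class RunConfig:
    """Paths, thresholds and the seed for a full pipeline run."""

    output_dir: str = "methscreen_run"
    simulate: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # input paths, used when simulate is False
    beta_path: str | None = None
    expr_path: str | None = None
    probe_annotation_path: str | None = None
    sample_annotation_path: str | None = None
    beta2_path: str | None = None
    expr2_path: str | None = None
    sample_annotation2_path: str | None = None
    promoter_fasta_path: str | None = None
    gmt_path: str | None = None
    # thresholds
    q_threshold: float = 0.2
    lshape: LShapeConfig = field(default_factory=LShapeConfig)
    ggf_window_min: int = 200
    ggf_gc_min: float = 0.5
    ggf_oe_min: float = 0.6
    promoter_window: tuple[int, int] = (2000, 500)
    n_random_sets: int = 10
    survival_rule: str = "median"
    marker_gene: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.q_threshold <= 1:
            raise ValueError("q_threshold must lie in (0,1]")
        if self.n_random_sets < 1:
            raise ValueError("n_random_sets must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        lshape_raw = raw.pop("lshape", {})
        if "weight_matrix" in lshape_raw:
            lshape_raw["weight_matrix"] = np.asarray(lshape_raw["weight_matrix"], float)
        lshape = LShapeConfig(**lshape_raw)
        pw = raw.pop("promoter_window", (2000, 500))
        cfg = cls(simulation=sim, lshape=lshape, promoter_window=tuple(pw), **raw)
        cfg.simulation.seed = raw.get("seed", cfg.seed) if "seed" not in raw else raw["seed"]
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["lshape"]["weight_matrix"] = np.asarray(d["lshape"]["weight_matrix"]).tolist()
        d["promoter_window"] = list(self.promoter_window)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def write_study(study: StudyData, outdir: str | Path) -> None:
    """Write the full synthetic file set (TSV matrices, annotations, FASTA, GMT, truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(study.beta_cellline, outdir / "beta_cellline.tsv")
    write_matrix(study.expr_cellline, outdir / "expr_cellline.tsv")
    write_matrix(study.beta_tumor, outdir / "beta_tumor.tsv")
    write_matrix(study.expr_tumor, outdir / "expr_tumor.tsv")
    write_table(study.probes, outdir / "probe_annotation.tsv")
    write_table(study.annot_cellline, outdir / "sample_annotation_cellline.tsv")
    write_table(study.annot_tumor, outdir / "sample_annotation_tumor.tsv")
    write_fasta(study.promoters, outdir / "promoters.fasta")
    study.gene_classes.to_frame().to_csv(outdir / "truth_gene_classes.tsv", sep="\t")
    study.island_truth.to_csv(outdir / "truth_islands.tsv", sep="\t")
    with open(outdir / "annotations.gmt", "w") as fh:
        for term, genes in study.terms.items():
            fh.write("\t".join([term, term] + sorted(genes)) + "\n")
    with open(outdir / "marker_gene.txt", "w") as fh:
        fh.write(study.marker_gene + "\n")


def _provenance(cfg: RunConfig) -> str:
    return (
        f"# methscreen {__version__} | seed={cfg.seed} | q_threshold={cfg.q_threshold} "
        f"| ggf=({cfg.ggf_window_min},{cfg.ggf_gc_min},{cfg.ggf_oe_min}) "
        f"| promoter_window={cfg.promoter_window} | survival_rule={cfg.survival_rule}\n"
    )


def _write_tsv(frame: pd.DataFrame, path: Path, cfg: RunConfig, index_label=None) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(cfg))
        frame.to_csv(fh, sep="\t", index_label=index_label)


def run_full(cfg: RunConfig) -> dict:
    """Execute every stage in order; returns the summary dictionary.

    Each stage failure aborts the run with the stage name and cause.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    summary: dict = {"seed": cfg.seed, "version": __version__}
    stage = "configuration"
    try:
        cfg.to_yaml(outdir / "config_used.yaml")
        log.info("config: seed=%s q_threshold=%s ggf=(%s,%s,%s) window=%s",
                 cfg.seed, cfg.q_threshold, cfg.ggf_window_min, cfg.ggf_gc_min,
                 cfg.ggf_oe_min, cfg.promoter_window)

        stage = "inputs"
        if cfg.simulate:
            cfg.simulation.seed = cfg.seed
            study = simulate_study(cfg.simulation)
            write_study(study, outdir / "simulated")
            beta, annot, expr = study.beta_cellline, study.annot_cellline, study.expr_cellline
            probes = study.probes
            beta2, annot2, expr2 = study.beta_tumor, study.annot_tumor, study.expr_tumor
            promoters = study.promoters
            terms = study.terms
            marker = cfg.marker_gene or study.marker_gene
        else:
            for p in (cfg.beta_path, cfg.expr_path, cfg.probe_annotation_path,
                      cfg.sample_annotation_path):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"required input missing: {p}")
            beta = read_matrix(cfg.beta_path, "beta")
            expr = read_matrix(cfg.expr_path, "expression")
            probes = read_probe_annotation(cfg.probe_annotation_path)
            annot = read_sample_annotation(cfg.sample_annotation_path)
            beta2 = read_matrix(cfg.beta2_path, "beta") if cfg.beta2_path else None
            expr2 = read_matrix(cfg.expr2_path, "expression") if cfg.expr2_path else None
            annot2 = (read_sample_annotation(cfg.sample_annotation2_path)
                      if cfg.sample_annotation2_path else None)
            promoters = read_fasta(cfg.promoter_fasta_path) if cfg.promoter_fasta_path else None
            terms = None
            marker = cfg.marker_gene

        stage = "qc"
        from .io import BetaMatrix

        analysis = [s for s in annot.analysis_samples() if s in beta.values.index]
        cs = summarize_cohort(BetaMatrix(beta.values.loc[analysis]))
        qc = qc_controls(beta, annot)
        summary["qc"] = {
            "sample_mean_range": cs.sample_mean_range,
            "fraction_probes_below_0.2": cs.fraction_below_02,
            "fraction_probes_above_0.5": cs.fraction_above_05,
            "control_means": qc.control_means,
            "replicate_r": {f"{a}|{b}": r for (a, b), r in qc.replicate_r.items()},
            "flags": qc.flags,
        }
        for f in qc.flags:
            log.warning("QC flag: %s", f)

        stage = "associations"
        assoc_rows = []
        for feature in ["msi"] + [f"mutation:{g}" for g in ("APC", "BRAF", "TP53", "KRAS", "PIK3CA")]:
            try:
                r = feature_association(beta, annot, feature)
                assoc_rows.append((feature, r.statistic, r.p_value, r.estimate))
            except ValueError as e:
                log.info("association %s skipped: %s", feature, e)
        try:
            g = growth_association(beta, annot)
            assoc_rows.append(("doubling_time", g.statistic, g.p_value, g.estimate))
        except ValueError as e:
            log.info("growth association skipped: %s", e)
        assoc = pd.DataFrame(assoc_rows, columns=["feature", "statistic", "p", "estimate"])
        _write_tsv(assoc.set_index("feature"), outdir / "associations.tsv", cfg)
        summary["associations"] = assoc.to_dict("records")

        stage = "screen"
        cohort1 = align_cohort(beta, expr, probes, samples=annot.analysis_samples())
        screen = SilencingScreen(cohort1, q_threshold=cfg.q_threshold,
                                 lshape_config=cfg.lshape)
        results = screen.fit()
        summary["screen"] = {
            "genes_annotated": cohort1.n_genes_annotated,
            "genes_retained": cohort1.n_genes_retained,
            "retained_fraction": cohort1.retained_fraction,
            "tested": results.n_tested,
            "correlation_hits": results.n_sig_neg,
            "l_only_hits": results.n_l_only,
            "candidates": results.n_candidates,
            "candidate_fraction": results.candidate_fraction,
        }

        validated_set = results.candidates
        if beta2 is not None and expr2 is not None:
            stage = "validation"
            samples2 = annot2.analysis_samples() if annot2 is not None else None
            cohort2 = align_cohort(beta2, expr2, probes, samples=samples2)
            val = results.validate(cohort2)
            summary["validation"] = {
                "candidates": val.n_candidates,
                "available": val.n_available,
                "availability_fraction": val.availability_fraction,
                "validated": val.n_validated,
                "validated_fraction": val.validated_fraction,
            }
            validated_set = val.validated

        island_flags = None
        if promoters is not None:
            stage = "islands"
            calls = []
            flags = {}
            for seq in promoters:
                islands = ggf_scan(seq, window_min=cfg.ggf_window_min,
                                   gc_min=cfg.ggf_gc_min, oe_min=cfg.ggf_oe_min)
                flags[seq.gene_symbol] = associate_islands(
                    islands, seq.tss_offset, len(seq), cfg.promoter_window)
                calls.extend(islands)
            island_flags = pd.Series(flags)
            results.annotate_islands(island_flags)
            bed = pd.DataFrame(
                [(c.gene_symbol, c.start, c.end, f"{c.gc_fraction:.3f}",
                  f"{c.obs_exp:.3f}", c.qualifies_merged) for c in calls],
                columns=["gene", "start", "end", "gc_fraction", "obs_exp", "qualifies_merged"],
            )
            _write_tsv(bed.set_index("gene"), outdir / "islands.tsv", cfg)
            target = [g for g in validated_set if g in island_flags.index]
            if target:
                enr = island_enrichment(island_flags, target,
                                        n_random_sets=cfg.n_random_sets,
                                        seed=np.random.default_rng(cfg.seed))
                summary["islands"] = {
                    "target_size": enr.n_target,
                    "island_fraction_target": enr.observed_fraction,
                    "island_fraction_baseline": enr.baseline_fraction,
                    "island_fraction_universe": enr.universe_fraction,
                    "fisher_p": enr.fisher.p_value,
                    "hypergeom_p": enr.hypergeom_p,
                }

        if terms:
            stage = "term_enrichment"
            universe = set(results.table.index[results.table["tested"]])
            target = [g for g in validated_set if g in universe]
            tbl = enrich_terms(target, terms, universe, q_threshold=cfg.q_threshold)
            _write_tsv(tbl, outdir / "term_enrichment.tsv", cfg)
            summary["term_enrichment"] = {
                "n_enriched": int(tbl["enriched"].sum()),
                "top_term": tbl.index[0],
                "top_q": float(tbl["q"].iloc[0]),
            }

        if marker is not None and annot2 is not None and expr2 is not None:
            stage = "survival"
            sv = survival_stratify(expr2, annot2, marker, rule=cfg.survival_rule)
            summary["survival"] = {
                "marker": marker,
                "rule": cfg.survival_rule,
                "group_sizes": sv.group_sizes,
                "logrank_statistic": sv.logrank.statistic,
                "logrank_p": sv.logrank.p_value,
            }

        stage = "report"
        _write_tsv(results.table, outdir / "screen_results.tsv", cfg, index_label="gene")
        with open(outdir / "summary.txt", "w") as fh:
            fh.write(_provenance(cfg))
            fh.write(_render_summary(summary))
        return summary
    except Exception as e:
        log.error("stage %s failed: %s", stage, e)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
    finally:
        log.removeHandler(handler)
        handler.close()


def _render_summary(s: dict) -> str:
    lines = []
    for section, content in s.items():
        lines.append(f"[{section}]")
        if isinstance(content, dict):
            for k, v in content.items():
                lines.append(f"  {k} = {v}")
        elif isinstance(content, list):
            for item in content:
                lines.append(f"  {item}")
        else:
            lines.append(f"  {content}")
    return "\n".join(lines) + "\n"
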