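"""Domain containers and readers/writers for methylation-expression cohorts.

Matrices are stored on disk as tab-separated text with features (CpG probes or
genes) on rows and samples on columns; in memory they are pandas DataFrames
oriented samples x features.  All genomic coordinates in this package are
0-based, half-open.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "BetaMatrix",
    "ExpressionMatrix",
    "ProbeAnnotation",
    "SampleAnnotation",
    "PromoterSequence",
    "AlignedCohort",
    "read_matrix",
    "write_matrix",
    "read_probe_annotation",
    "read_sample_annotation",
    "write_table",
    "align_cohort",
    "read_fasta",
    "write_fasta",
]

DNA_ALPHABET = frozenset("ACGTN")

MUTATION_GENES = ("APC", "BRAF", "TP53", "KRAS", "PIK3CA")

SAMPLE_ANNOTATION_COLUMNS = (
    "sample_id",
    "cohort",
    "msi_status",
    *MUTATION_GENES,
    "doubling_time",
    "control_role",
    "survival_time",
    "event",
)


def _check_unique(ids: Iterable[str], what: str) -> None:
    ids = list(ids)
    seen: set[str] = set()
    dups = [i for i in ids if i in seen or seen.add(i)]  # type: ignore[func-returns-value]
    if dups:
        raise ValueError(f"duplicate {what}: {sorted(set(dups))[:5]}")


@dataclass
class _Matrix:
    """Samples x features numeric matrix with unique identifiers."""

    values: pd.DataFrame  # index: sample ids, columns: feature ids

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "sample ids")
        _check_unique(self.values.columns, self._feature_name + " ids")
        self.values = self.values.astype(float)

    _feature_name = "feature"

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class BetaMatrix(_Matrix):
    """Samples x CpG probes matrix of beta values (methylated fraction in [0,1])."""

    _feature_name = "probe"

    def __post_init__(self) -> None:
        super().__post_init__()
        v = self.values.to_numpy()
        bad = (v < 0) | (v > 1)
        if np.any(bad & np.isfinite(v)):
            s, p = np.argwhere(bad & np.isfinite(v))[0]
            raise ValueError(
                f"beta value out of [0,1] at sample {self.values.index[s]!r}, "
                f"probe {self.values.columns[p]!r}: {v[s, p]}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ExpressionMatrix(_Matrix):
    """Samples x genes matrix of log2 expression values."""

    _feature_name = "gene"

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ProbeAnnotation:
    """Maps CpG probes to gene symbols and genomic positions (0-based)."""

    table: pd.DataFrame  # columns: probe_id, gene_symbol, chromosome, position

    REQUIRED = ("probe_id", "gene_symbol", "chromosome", "position")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"probe annotation missing columns: {missing}")
        _check_unique(self.table["probe_id"], "probe ids")
        self.table = self.table.reset_index(drop=True)

    @property
    def probe_to_gene(self) -> pd.Series:
        return self.table.set_index("probe_id")["gene_symbol"]


@dataclass
class SampleAnnotation:
    """Per-sample metadata: cohort, MSI status, mutation flags, growth, survival.

    ``control_role`` is one of ``none``, ``unmethylated_control``,
    ``methylated_control`` or ``replicate_of:<sample_id>``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "sample_id" not in self.table.columns:
            raise ValueError("sample annotation requires a sample_id column")
        _check_unique(self.table["sample_id"], "sample ids")
        for col in SAMPLE_ANNOTATION_COLUMNS:
            if col not in self.table.columns:
                self.table[col] = np.nan
        st = pd.to_numeric(self.table["survival_time"], errors="coerce")
        if (st.dropna() < 0).any():
            raise ValueError("negative survival_time")
        self.table = self.table.reset_index(drop=True)

    def indexed(self) -> pd.DataFrame:
        return self.table.set_index("sample_id")

    def analysis_samples(self) -> list[str]:
        """Sample ids excluding technical controls and replicate re-runs."""
        t = self.indexed()
        role = t["control_role"].fillna("none").astype(str)
        keep = (role == "none") | (role == "nan")
        return list(t.index[keep])


@dataclass
class PromoterSequence:
    """A promoter DNA sequence with the TSS position marked inside it."""

    gene_symbol: str
    sequence: str
    tss_offset: int = 0

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.gene_symbol!r}")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"illegal characters {sorted(bad)} in sequence for {self.gene_symbol!r}"
            )
        if not 0 <= self.tss_offset < len(self.sequence):
            raise ValueError(
                f"tss_offset {self.tss_offset} outside sequence of length "
                f"{len(self.sequence)} for {self.gene_symbol!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# matrix IO


def _parse_matrix_frame(path: str | Path) -> pd.DataFrame:
    """Parse a features-on-rows TSV, reporting the first offending cell."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    _check_unique(sample_ids, "sample ids")
    raw = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False, skip_blank_lines=True
    )
    raw.columns = sample_ids
    _check_unique(raw.index, "feature ids")
    out = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        cells = raw[col].str.strip()
        blank = cells.isin(("", "NA", "NaN", "nan"))
        numeric = pd.to_numeric(cells.where(~blank), errors="coerce")
        bad = numeric.isna() & ~blank
        if bad.any():
            row = raw.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"non-numeric cell at row {row!r}, column {col!r}: {cells[bad].iloc[0]!r}"
            )
        out[col] = numeric
    return out


def read_matrix(path: str | Path, kind: Literal["beta", "expression"]) -> BetaMatrix | ExpressionMatrix:
    """Read a tab-separated matrix (features on rows, samples on columns).

    ``kind='beta'`` enforces values in [0,1]; blank/NA cells become missing.
    """
    frame = _parse_matrix_frame(path).T  # -> samples x features
    if kind == "beta":
        return BetaMatrix(frame)
    if kind == "expression":
        return ExpressionMatrix(frame)
    raise ValueError(f"unknown matrix kind {kind!r}")


def write_matrix(matrix: _Matrix, path: str | Path) -> None:
    """Write a matrix as features-on-rows TSV (inverse of :func:`read_matrix`)."""
    matrix.values.T.to_csv(path, sep="\t", na_rep="")


def read_probe_annotation(path: str | Path) -> ProbeAnnotation:
    t = pd.read_csv(path, sep="\t")
    t["position"] = t["position"].astype(int)
    return ProbeAnnotation(t)


def read_sample_annotation(path: str | Path) -> SampleAnnotation:
    return SampleAnnotation(pd.read_csv(path, sep="\t"))


def write_table(obj: ProbeAnnotation | SampleAnnotation, path: str | Path) -> None:
    obj.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# cohort alignment


@dataclass
class AlignedCohort:
    """Paired per-sample promoter methylation and expression over shared genes.

    ``meth`` columns are gene symbols in ``mean`` mode, probe ids in
    ``per-probe`` mode (with ``probe_to_gene`` giving the mapping).
    """

    meth: pd.DataFrame  # samples x (genes | probes)
    expr: pd.DataFrame  # samples x genes
    mode: str = "mean"
    probe_to_gene: pd.Series | None = None
    n_genes_annotated: int = 0
    n_genes_retained: int = 0

    @property
    def sample_ids(self) -> list[str]:
        return list(self.meth.index)

    @property
    def gene_symbols(self) -> list[str]:
        if self.mode == "per-probe":
            return sorted(set(self.probe_to_gene))
        return list(self.meth.columns)

    @property
    def retained_fraction(self) -> float:
        return self.n_genes_retained / self.n_genes_annotated

    def gene_pairs(self, gene: str) -> tuple[np.ndarray, np.ndarray]:
        """Pairwise-complete (beta, expression) vectors for one gene (mean mode)."""
        x = self.meth[gene].to_numpy(float)
        y = self.expr[gene].to_numpy(float)
        ok = np.isfinite(x) & np.isfinite(y)
        return x[ok], y[ok]


def align_cohort(
    beta: BetaMatrix,
    expr: ExpressionMatrix,
    probes: ProbeAnnotation,
    samples: Iterable[str] | None = None,
    mode: Literal["mean", "per-probe"] = "mean",
) -> AlignedCohort:
    """Pair promoter methylation with expression using gene symbols as keys.

    Per-gene promoter methylation is the unweighted mean of that gene's probe
    betas per sample (missing probes ignored); ``per-probe`` mode keeps probes
    separate for most-significant-probe screening downstream.
    """
    mapping = probes.probe_to_gene
    present = [p for p in beta.probe_ids if p in mapping.index]
    annotated_genes = sorted(set(mapping.loc[present]))
    shared_genes = sorted(set(annotated_genes) & set(expr.gene_symbols))
    shared_samples = [s for s in beta.sample_ids if s in set(expr.sample_ids)]
    if samples is not None:
        allowed = set(samples)
        shared_samples = [s for s in shared_samples if s in allowed]
    if not shared_samples:
        raise ValueError("no shared samples between methylation and expression")
    if not shared_genes:
        raise ValueError("no shared genes between methylation and expression")

    keep_probes = [p for p in present if mapping[p] in set(shared_genes)]
    sub = beta.values.loc[shared_samples, keep_probes]
    expr_sub = expr.values.loc[shared_samples, shared_genes]
    if mode == "mean":
        meth = sub.T.groupby(mapping.loc[keep_probes]).mean().T[shared_genes]
        p2g = None
    elif mode == "per-probe":
        meth = sub
        p2g = mapping.loc[keep_probes]
    else:
        raise ValueError(f"unknown alignment mode {mode!r}")
    return AlignedCohort(
        meth=meth,
        expr=expr_sub,
        mode=mode,
        probe_to_gene=p2g,
        n_genes_annotated=len(annotated_genes),
        n_genes_retained=len(shared_genes),
    )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[PromoterSequence]:
    """Read promoter sequences; the header is ``>GENE [tss=<int>] ...``."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tss = 0
        for token in rec.description.split()[1:]:
            if token.startswith("tss="):
                tss = int(token.split("=", 1)[1])
        out.append(PromoterSequence(rec.id, str(rec.seq), tss_offset=tss))
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def write_fasta(seqs: Iterable[PromoterSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.sequence), id=s.gene_symbol, description=f"tss={s.tss_offset}")
        for s in seqs
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
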