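"""Promoter-silencing discovery screen.

The screen pairs per-gene promoter methylation (beta) with log2 expression
across a cohort and flags genes whose expression is negatively associated with
methylation, by two complementary routes:

1. a rank-correlation route: Spearman's rho per gene, Benjamini-Hochberg
   adjustment over the whole tested universe, significant-negative = rho < 0
   and q < 0.2 (default);
2. an "L-shape" route for nonlinear silencing: genes whose scatter shows high
   expression only at low methylation and a uniformly low floor elsewhere are
   invisible to rank correlation but recognisable on a coarse 3x3 grid.

Candidates are the union; an independent second cohort re-screens the
candidates for validation.  The module follows the Model/Results pattern:
``SilencingScreen(...).fit()`` returns a :class:`ScreenResults` carrying the
per-gene table, headline counts and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AlignedCohort, BetaMatrix, ExpressionMatrix, ProbeAnnotation, align_cohort
from .stats import bh_adjust, spearman

__all__ = [
    "LShapeConfig",
    "LShapeResult",
    "lshape_classify",
    "SilencingScreen",
    "ScreenResults",
    "ValidationResults",
]

DEFAULT_WEIGHTS = np.array(
    [
        [+2.0, -1.0, -10.0],  # top row (high expression)
        [+1.0, 0.0, -2.0],
        [+1.0, +1.0, +2.0],  # bottom row (low expression)
    ]
)


@dataclass
class LShapeConfig:
    """Grid, weights and thresholds for the L-shape detector.

    The unit square (min-max normalised beta on x, expression on y) is cut
    into a 3x3 grid; the score is the count-weighted mean of cell weights.
    A gene is flagged when the score reaches ``score_threshold``, at most
    ``max_topright_frac`` of points sit in the high-expression/high-beta
    corner (which directly contradicts silencing), and both arms of the L
    are populated: at least ``min_topleft_frac`` of points in the
    high-expression/low-beta cell and ``min_bottomright_frac`` in the
    low-expression/high-beta cell.  Without the arm-occupancy conditions a
    gene whose methylation never leaves the leftmost column is trivially
    scored as an L by any corner-rewarding weight matrix.
    """

    x_cuts: tuple[float, float] = (1 / 3, 2 / 3)
    y_cuts: tuple[float, float] = (1 / 3, 2 / 3)
    weight_matrix: np.ndarray = field(default_factory=lambda: DEFAULT_WEIGHTS.copy())
    min_points: int = 10
    max_topright_frac: float = 0.05
    score_threshold: float = 0.25
    min_topleft_frac: float = 0.1
    min_bottomright_frac: float = 0.1

    def __post_init__(self) -> None:
        for cuts in (self.x_cuts, self.y_cuts):
            if not (0 < cuts[0] < cuts[1] < 1):
                raise ValueError(f"cut points must be strictly increasing in (0,1): {cuts}")
        self.weight_matrix = np.asarray(self.weight_matrix, dtype=float)
        if self.weight_matrix.shape != (3, 3) or not np.all(np.isfinite(self.weight_matrix)):
            raise ValueError("weight_matrix must be a finite 3x3 matrix")


@dataclass
class LShapeResult:
    score: float
    flag: bool
    counts: np.ndarray  # 3x3, rows top (high expression) -> bottom
    n: int
    tested: bool = True


def _bin_lower_closed(v: np.ndarray, cuts: tuple[float, float]) -> np.ndarray:
    """3-way binning; a value exactly on a cut belongs to the lower cell."""
    return np.where(v <= cuts[0], 0, np.where(v <= cuts[1], 1, 2))


def lshape_classify(x, y, cfg: LShapeConfig | None = None) -> LShapeResult:
    """Score one gene's (beta, expression) scatter for an L shape.

    Both axes are min-max normalised over the gene before gridding; rows of
    the count matrix run top (high expression) to bottom.
    """
    cfg = cfg or LShapeConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    empty = np.zeros((3, 3), dtype=int)
    if n < cfg.min_points:
        return LShapeResult(score=np.nan, flag=False, counts=empty, n=n, tested=False)
    xr = x.max() - x.min()
    yr = y.max() - y.min()
    if xr == 0 or yr == 0:
        return LShapeResult(score=np.nan, flag=False, counts=empty, n=n, tested=False)
    xn = (x - x.min()) / xr
    yn = (y - y.min()) / yr
    col = _bin_lower_closed(xn, cfg.x_cuts)
    yband = _bin_lower_closed(yn, cfg.y_cuts)  # 0 = low expression
    row = 2 - yband  # row 0 = top = high expression
    counts = np.zeros((3, 3), dtype=int)
    np.add.at(counts, (row, col), 1)
    score = float((cfg.weight_matrix * counts).sum() / n)
    flag = bool(
        score >= cfg.score_threshold
        and counts[0, 2] / n <= cfg.max_topright_frac
        and counts[0, 0] / n >= cfg.min_topleft_frac
        and counts[2, 2] / n >= cfg.min_bottomright_frac
    )
    return LShapeResult(score=score, flag=flag, counts=counts, n=n)


class SilencingScreen:
    """Per-gene negative-association screen over an aligned cohort.

    Parameters
    ----------
    cohort
        Output of :func:`methscreen.io.align_cohort` (``mean`` or
        ``per-probe`` mode).
    q_threshold
        BH-adjusted p cut-off for a significant negative correlation.
    lshape_config
        Grid configuration for the nonlinear detector.
    min_pairs
        Genes with fewer complete (beta, expression) pairs are reported as
        untested.
    """

    def __init__(
        self,
        cohort: AlignedCohort,
        q_threshold: float = 0.2,
        lshape_config: LShapeConfig | None = None,
        min_pairs: int = 4,
    ) -> None:
        if cohort.meth.shape[1] == 0:
            raise ValueError("empty cohort: no genes to screen")
        if not 0 < q_threshold <= 1:
            raise ValueError("q_threshold must lie in (0,1]")
        self.cohort = cohort
        self.q_threshold = q_threshold
        self.lshape_config = lshape_config or LShapeConfig()
        self.min_pairs = min_pairs

    @classmethod
    def from_matrices(
        cls,
        beta: BetaMatrix,
        expr: ExpressionMatrix,
        probes: ProbeAnnotation,
        samples=None,
        mode: str = "mean",
        **kwargs,
    ) -> "SilencingScreen":
        return cls(align_cohort(beta, expr, probes, samples=samples, mode=mode), **kwargs)

    # -- correlation route ------------------------------------------------
    def _gene_correlations(self, meth: pd.DataFrame, expr: pd.DataFrame, genes) -> pd.DataFrame:
        rows = []
        for gene in genes:
            x = meth[gene].to_numpy(float)
            y = expr[gene].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            n = int(ok.sum())
            if n < self.min_pairs:
                rows.append((gene, n, np.nan, np.nan, False))
                continue
            try:
                res = spearman(x[ok], y[ok])
            except ValueError:  # zero rank variance
                rows.append((gene, n, np.nan, np.nan, False))
                continue
            rows.append((gene, n, res.statistic, res.p_value, True))
        return pd.DataFrame(rows, columns=["gene", "n_pairs", "rho", "p", "tested"]).set_index("gene")

    def fit(self) -> "ScreenResults":
        """Run both screening routes and assemble the candidate set."""
        c = self.cohort
        if c.mode == "per-probe":
            per_probe = self._gene_correlations(c.meth, c.expr[c.probe_to_gene.to_numpy()]
                                                .set_axis(c.meth.columns, axis=1), c.meth.columns)
            per_probe["gene_symbol"] = c.probe_to_gene.loc[per_probe.index].to_numpy()
            tested = per_probe[per_probe["tested"]]
            # most significant probe represents the gene
            best = tested.sort_values("p").groupby("gene_symbol").head(1)
            best_probe = dict(zip(best["gene_symbol"], best.index))
            table = best.set_index("gene_symbol")[["n_pairs", "rho", "p", "tested"]]
            untested_genes = sorted(
                set(per_probe["gene_symbol"]) - set(table.index)
            )
            for g in untested_genes:
                table.loc[g] = [per_probe[per_probe["gene_symbol"] == g]["n_pairs"].max(), np.nan, np.nan, False]
            meth_for_lshape = c.meth.rename(columns=dict(zip(best.index, best["gene_symbol"])))
            expr_for_lshape = c.expr
            gene_order = list(table.index)
            table = table.loc[sorted(gene_order)]
            self._best_probe = best_probe
        else:
            table = self._gene_correlations(c.meth, c.expr, c.meth.columns)
            meth_for_lshape = c.meth
            expr_for_lshape = c.expr

        tested_mask = table["tested"].to_numpy(bool)
        q = np.full(len(table), np.nan)
        if tested_mask.sum() == 0:
            raise ValueError("no gene has enough complete pairs to test")
        q[tested_mask] = bh_adjust(table["p"].to_numpy(float)[tested_mask])
        table["q"] = q
        table["sig_neg"] = tested_mask & (table["rho"] < 0) & (table["q"] < self.q_threshold)

        scores, flags, ltested = [], [], []
        for gene in table.index:
            if gene in meth_for_lshape.columns and gene in expr_for_lshape.columns:
                res = lshape_classify(
                    meth_for_lshape[gene].to_numpy(float),
                    expr_for_lshape[gene].to_numpy(float),
                    self.lshape_config,
                )
            else:
                res = LShapeResult(np.nan, False, np.zeros((3, 3), int), 0, tested=False)
            scores.append(res.score)
            flags.append(res.flag)
            ltested.append(res.tested)
        table["lshape_score"] = scores
        table["lshape_flag"] = flags
        table["lshape_tested"] = ltested
        table["l_only"] = table["lshape_flag"] & ~table["sig_neg"]
        table["candidate"] = table["sig_neg"] | table["lshape_flag"]
        table["island_flag"] = pd.NA
        table["validated"] = pd.NA
        return ScreenResults(table=table, q_threshold=self.q_threshold, screen=self)


@dataclass
class ScreenResults:
    """Per-gene screen output with headline counts and validation hooks."""

    table: pd.DataFrame
    q_threshold: float
    screen: SilencingScreen | None = None

    # -- counts -----------------------------------------------------------
    @property
    def n_tested(self) -> int:
        return int(self.table["tested"].sum())

    @property
    def n_sig_neg(self) -> int:
        return int(self.table["sig_neg"].sum())

    @property
    def n_l_only(self) -> int:
        return int(self.table["l_only"].sum())

    @property
    def n_candidates(self) -> int:
        return int(self.table["candidate"].sum())

    @property
    def candidate_fraction(self) -> float:
        return self.n_candidates / self.n_tested

    @property
    def candidates(self) -> list[str]:
        return list(self.table.index[self.table["candidate"]])

    def annotate_islands(self, flags) -> None:
        """Attach per-gene CpG-island flags (from :mod:`methscreen.islands`)."""
        flags = pd.Series(flags)
        self.table["island_flag"] = self.table.index.map(flags.to_dict())

    # -- cross-cohort validation -----------------------------------------
    def validate(self, cohort2: AlignedCohort, q_threshold: float | None = None,
                 min_pairs: int | None = None) -> "ValidationResults":
        """Re-screen the candidate set in an independent cohort.

        BH adjustment is computed within the candidate subset that has data in
        the second cohort; validated = rho < 0 and q < threshold there.
        """
        qt = q_threshold if q_threshold is not None else self.q_threshold
        mp = min_pairs if min_pairs is not None else (self.screen.min_pairs if self.screen else 4)
        candidates = self.candidates
        if not candidates:
            raise ValueError("no candidates to validate")
        present = [g for g in candidates if g in cohort2.meth.columns and g in cohort2.expr.columns]
        rows = []
        for gene in present:
            x, y = cohort2.gene_pairs(gene)
            if len(x) < mp:
                continue
            try:
                res = spearman(x, y)
            except ValueError:
                continue
            rows.append((gene, len(x), res.statistic, res.p_value))
        if not rows:
            raise ValueError("no candidate has usable data in the second cohort")
        t2 = pd.DataFrame(rows, columns=["gene", "n_pairs", "rho", "p"]).set_index("gene")
        t2["q"] = bh_adjust(t2["p"].to_numpy())
        t2["validated"] = (t2["rho"] < 0) & (t2["q"] < qt)
        self.table["validated"] = self.table.index.map(t2["validated"].to_dict())
        return ValidationResults(
            table=t2,
            n_candidates=len(candidates),
            n_available=len(t2),
            q_threshold=qt,
        )

    # -- presentation ------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Promoter-silencing screen",
            "=" * 41,
            f"genes tested                 {self.n_tested:>8d}",
            f"significant negative (q<{self.q_threshold:g}) "
            f"{self.n_sig_neg:>5d} ({100 * self.n_sig_neg / self.n_tested:.1f}%)",
            f"L-shape only                 {self.n_l_only:>8d}",
            f"candidates                   {self.n_candidates:>8d} "
            f"({100 * self.candidate_fraction:.1f}%)",
        ]
        if self.table["validated"].notna().any():
            v = int(self.table["validated"].eq(True).sum())
            lines.append(f"validated in second cohort   {v:>8d}")
        return "\n".join(lines)

    def plot_gene(self, gene: str, ax=None):
        """Scatter of expression against promoter beta for one gene."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.screen.cohort
        ax.scatter(c.meth[gene], c.expr[gene], s=12)
        ax.set_xlabel("promoter methylation (beta)")
        ax.set_ylabel("log2 expression")
        ax.set_title(gene)
        return ax


@dataclass
class ValidationResults:
    """Second-cohort re-screen of the candidate set."""

    table: pd.DataFrame
    n_candidates: int
    n_available: int
    q_threshold: float

    @property
    def availability_fraction(self) -> float:
        return self.n_available / self.n_candidates

    @property
    def n_validated(self) -> int:
        return int(self.table["validated"].sum())

    @property
    def validated_fraction(self) -> float:
        return self.n_validated / self.n_available

    @property
    def validated(self) -> list[str]:
        return list(self.table.index[self.table["validated"]])

    def summary(self) -> str:
        return "\n".join(
            [
                "Cross-cohort validation",
                "=" * 41,
                f"candidates                   {self.n_candidates:>8d}",
                f"with data in cohort 2        {self.n_available:>8d} "
                f"({100 * self.availability_fraction:.1f}%)",
                f"validated (rho<0, q<{self.q_threshold:g})    {self.n_validated:>8d} "
                f"({100 * self.validated_fraction:.1f}%)",
            ]
        )
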