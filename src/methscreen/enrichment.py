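"""Annotation-term over-representation for candidate gene lists.

A generic Fisher-exact over-representation test over gene-set annotations
(GMT-style files), with Benjamini-Hochberg adjustment across terms.  Only
plain one-sided enrichment (odds ratio > 1) is flagged; no EASE-style
correction or term clustering is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .stats import bh_adjust, fisher_exact_2x2

__all__ = ["TermAnnotation", "read_gmt", "enrich_terms"]


@dataclass
class TermAnnotation:
    term_id: str
    term_name: str
    genes: set[str]


def read_gmt(path: str | Path) -> list[TermAnnotation]:
    """Read a GMT file: term_id <tab> description <tab> gene1 <tab> gene2 ..."""
    out = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            out.append(TermAnnotation(parts[0], parts[1], {g for g in parts[2:] if g}))
    if not out:
        raise ValueError(f"no terms parsed from {path}")
    return out


def enrich_terms(
    target: Iterable[str],
    annotations: Sequence[TermAnnotation] | Mapping[str, Iterable[str]],
    universe: Iterable[str],
    q_threshold: float = 0.2,
) -> pd.DataFrame:
    """Per-term Fisher over-representation of ``target`` within ``universe``.

    Returns a DataFrame (one row per term) with overlap counts, odds ratio,
    p, BH-adjusted q and an ``enriched`` flag (q < threshold and OR > 1).
    Terms are intersected with the universe first.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    target = set(target)
    if not target <= universe:
        raise ValueError("target set must be a subset of the universe")
    if isinstance(annotations, Mapping):
        annotations = [TermAnnotation(k, k, set(v)) for k, v in annotations.items()]
    rows = []
    for term in annotations:
        genes = term.genes & universe
        a = len(genes & target)  # in target, in term
        b = len(target) - a  # in target, not in term
        c = len(genes) - a  # in term, not in target
        d = len(universe) - len(target) - c
        res = fisher_exact_2x2([[a, b], [c, d]])
        rows.append((term.term_id, term.term_name, a, len(genes), res.estimate, res.p_value))
    out = pd.DataFrame(
        rows, columns=["term_id", "term_name", "n_overlap", "n_term", "odds_ratio", "p"]
    ).set_index("term_id")
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["enriched"] = (out["q"] < q_threshold) & (out["odds_ratio"] > 1)
    return out.sort_values("q")
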