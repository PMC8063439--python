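"""Gardiner-Garden-Frommer CpG island calling and island enrichment.

A CpG island is defined by the classical sliding-window rule: any window of at
least ``window_min`` bp (default 200) with GC fraction >= ``gc_min`` (default
0.5) and observed/expected CpG ratio >= ``oe_min`` (default 0.6).  Overlapping
or adjacent qualifying windows are merged into maximal islands; the merged
span's own GC and Obs/Exp are re-reported because a union of qualifying
windows need not itself qualify.

Coordinates are 0-based, half-open within each promoter sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import PromoterSequence
from .stats import TestResult, fisher_exact_2x2

__all__ = [
    "IslandCall",
    "gc_fraction",
    "obs_exp_cpg",
    "ggf_scan",
    "associate_islands",
    "island_enrichment",
    "EnrichmentReport",
]


@dataclass
class IslandCall:
    """A merged CpG island within a promoter sequence."""

    gene_symbol: str
    start: int  # 0-based, inclusive
    end: int  # 0-based, exclusive
    gc_fraction: float
    obs_exp: float
    qualifies_merged: bool = True  # merged span itself meets the thresholds

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


def gc_fraction(window: str) -> float:
    """(#C + #G) / non-N length of the window; N bases are excluded."""
    w = window.upper()
    if not w:
        raise ValueError("empty window")
    n_len = len(w) - w.count("N")
    if n_len == 0:
        return 0.0
    return (w.count("C") + w.count("G")) / n_len


def obs_exp_cpg(window: str) -> float:
    """Observed/expected CpG: (#CpG * non-N length) / (#C * #G); 0 if no C or G.

    CpG dinucleotides are counted at every overlapping position.
    """
    w = window.upper()
    if not w:
        raise ValueError("empty window")
    c = w.count("C")
    g = w.count("G")
    if c == 0 or g == 0:
        return 0.0
    cpg = sum(1 for i in range(len(w) - 1) if w[i] == "C" and w[i + 1] == "G")
    n_len = len(w) - w.count("N")
    return cpg * n_len / (c * g)


def _window_stats(seq: str, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized GC fraction and Obs/Exp for all windows of given length."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    is_n = arr == ord("N")
    is_cpg = np.zeros(len(arr), dtype=bool)
    if len(arr) > 1:
        is_cpg[:-1] = is_c[:-1] & is_g[1:]

    def win_sum(mask: np.ndarray, length: int) -> np.ndarray:
        cs = np.concatenate([[0], np.cumsum(mask)])
        return cs[length:] - cs[: len(mask) - length + 1]

    n_win = len(arr) - window + 1
    c = win_sum(is_c, window).astype(float)[:n_win]
    g = win_sum(is_g, window).astype(float)[:n_win]
    nn = win_sum(is_n, window).astype(float)[:n_win]
    # CpG pairs fully inside the window: positions [i, i+window-1)
    cpg = win_sum(is_cpg, window - 1).astype(float)
    cpg = cpg[: n_win] if len(cpg) >= n_win else cpg
    eff_len = window - nn
    with np.errstate(divide="ignore", invalid="ignore"):
        gc = np.where(eff_len > 0, (c + g) / eff_len, 0.0)
        oe = np.where((c > 0) & (g > 0), cpg * eff_len / (c * g), 0.0)
    return gc, oe


def ggf_scan(
    seq: PromoterSequence,
    window_min: int = 200,
    gc_min: float = 0.5,
    oe_min: float = 0.6,
    step: int = 1,
) -> list[IslandCall]:
    """Slide ``window_min``-bp windows and merge qualifying ones into islands."""
    s = seq.sequence
    if len(s) < window_min:
        return []
    gc, oe = _window_stats(s, window_min)
    starts = np.arange(0, len(gc), step)
    qual = starts[(gc[starts] >= gc_min) & (oe[starts] >= oe_min)]
    if len(qual) == 0:
        return []
    # merge overlapping/adjacent qualifying windows [i, i + window_min)
    islands: list[tuple[int, int]] = []
    cur_start = int(qual[0])
    cur_end = cur_start + window_min
    for i in qual[1:]:
        i = int(i)
        if i <= cur_end:  # overlap or adjacency
            cur_end = i + window_min
        else:
            islands.append((cur_start, cur_end))
            cur_start, cur_end = i, i + window_min
    islands.append((cur_start, cur_end))
    out = []
    for a, b in islands:
        sub = s[a:b]
        gcf = gc_fraction(sub)
        oef = obs_exp_cpg(sub)
        out.append(
            IslandCall(
                gene_symbol=seq.gene_symbol,
                start=a,
                end=b,
                gc_fraction=gcf,
                obs_exp=oef,
                qualifies_merged=bool(gcf >= gc_min and oef >= oe_min),
            )
        )
    return out


def associate_islands(
    islands: Iterable[IslandCall],
    tss_offset: int,
    seq_length: int,
    promoter_window: tuple[int, int] = (2000, 500),
) -> bool:
    """Flag a gene whose promoter window around the TSS overlaps any island.

    The window is [tss - upstream, tss + downstream), truncated at sequence
    edges.
    """
    up, down = promoter_window
    lo = max(0, tss_offset - up)
    hi = min(seq_length, tss_offset + down)
    return any(isl.overlaps(lo, hi) for isl in islands)


@dataclass
class EnrichmentReport:
    """Island enrichment of a target gene set against a resampled baseline."""

    n_target: int
    n_flagged: int
    observed_fraction: float
    baseline_fraction: float  # mean over random same-size gene sets
    n_random_sets: int
    fisher: TestResult  # observed vs rounded baseline counts
    hypergeom_p: float  # exact comparison against the universe fraction
    universe_fraction: float


def island_enrichment(
    flags: Mapping[str, bool] | pd.Series,
    target_set: Sequence[str],
    n_random_sets: int = 10,
    seed: int | np.random.Generator = 0,
) -> EnrichmentReport:
    """Compare a target set's island fraction with random same-size gene sets.

    The baseline is the mean island fraction over ``n_random_sets`` draws
    without replacement from the universe; the headline p-value is a Fisher
    exact test of the observed counts against the rounded baseline counts.
    Because a 10-set baseline is noisy, the exact hypergeometric tail against
    the full-universe fraction is always reported as a cross-check.
    """
    flags = pd.Series(flags).astype(bool)
    universe = list(flags.index)
    target = list(target_set)
    missing = set(target) - set(universe)
    if missing:
        raise ValueError(f"target genes outside universe: {sorted(missing)[:5]}")
    if len(target) > len(universe):
        raise ValueError("target set larger than universe")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n = len(target)
    observed = int(flags.loc[target].sum())
    fracs = []
    flag_values = flags.to_numpy()
    for _ in range(n_random_sets):
        idx = rng.choice(len(universe), size=n, replace=False)
        fracs.append(flag_values[idx].mean())
    baseline = float(np.mean(fracs))
    exp_flagged = int(round(baseline * n))
    fisher = fisher_exact_2x2(
        [[observed, n - observed], [exp_flagged, n - exp_flagged]]
    )
    from scipy.stats import hypergeom

    k_universe = int(flags.sum())
    hyper_p = float(hypergeom.sf(observed - 1, len(universe), k_universe, n))
    return EnrichmentReport(
        n_target=n,
        n_flagged=observed,
        observed_fraction=observed / n,
        baseline_fraction=baseline,
        n_random_sets=n_random_sets,
        fisher=fisher,
        hypergeom_p=hyper_p,
        universe_fraction=k_universe / len(universe),
    )
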