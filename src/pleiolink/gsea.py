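"""Preranked gene-set enrichment analysis.

Genes are ranked by log2 fold change (descending); each gene set gets a
weighted Kolmogorov–Smirnov running-sum enrichment score (ES), a null
distribution from random gene sets of equal size resampled from the ranked
universe, a sign-matched normalized score (NES), a smoothed one-sided
permutation p-value, and a BH FDR across all retained sets. The gene-set
resampling null (rather than sample-label permutation) is the standard
choice when the input is a preranked list.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import bh_adjust

__all__ = ["RankedList", "GSEAResult", "rank_genes", "enrichment_score",
           "gsea_preranked", "read_gmt", "write_gmt"]


@dataclass
class RankedList:
    """Genes ordered by score, descending; ties broken by gene id ascending."""

    genes: list
    scores: np.ndarray

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GSEAResult:
    table: pd.DataFrame  # set, size, ES, NES, pvalue, fdr, leading_edge
    excluded: pd.DataFrame  # set, reason
    n_permutations: int
    seed: int


def rank_genes(de_table: pd.DataFrame, score_col: str = "log2FC") -> RankedList:
    """Build a ranked list from a per-gene DE table (descending log2FC)."""
    scores = de_table[score_col]
    bad = de_table.index[~np.isfinite(scores)]
    if len(bad):
        raise ValueError(f"non-finite ranking scores for genes: {list(bad)[:10]}")
    if de_table.index.duplicated().any():
        raise ValueError("duplicate gene ids in DE table")
    order = sorted(de_table.index, key=lambda g: (-scores[g], str(g)))
    return RankedList(genes=order,
                      scores=np.array([scores[g] for g in order], dtype=float))


def enrichment_score(ranked: RankedList, gene_set, weight: float = 1.0
                     ) -> tuple[float, np.ndarray, list]:
    """Weighted KS running-sum enrichment score.

    Hits step up by |score|^weight (normalized over hits), misses step down
    by 1/(N − set size); ES is the extremum of largest magnitude. The leading
    edge is the hits at or before a positive extremum, or at or after a
    negative one.
    """
    hit_mask = np.array([g in gene_set for g in ranked.genes])
    n_hits = int(hit_mask.sum())
    if n_hits == 0:
        raise ValueError("gene set has no overlap with the ranked universe")
    n = len(ranked)
    if n_hits == n:
        raise ValueError("gene set covers the whole universe: miss step undefined")
    weights = np.abs(ranked.scores) ** weight
    hit_weights = np.where(hit_mask, weights, 0.0)
    denom = hit_weights.sum()
    if denom == 0:  # all hit scores zero (possible at weight>0): uniform steps
        hit_weights = hit_mask.astype(float)
        denom = float(n_hits)
    steps = hit_weights / denom - (~hit_mask) / (n - n_hits)
    running = np.cumsum(steps)
    i_max, i_min = int(np.argmax(running)), int(np.argmin(running))
    es = (float(running[i_max]) if running[i_max] >= -running[i_min]
          else float(running[i_min]))
    if es >= 0:
        leading = [g for k, g in enumerate(ranked.genes[: i_max + 1])
                   if hit_mask[k]]
    else:
        leading = [g for k, g in enumerate(ranked.genes) if k >= i_min
                   and hit_mask[k]]
    return es, running, leading


def _es_only(weights: np.ndarray, miss_step: float, hit_idx: np.ndarray,
             n: int) -> float:
    """ES for a hit-index set, vectorized for the permutation null."""
    hw = weights[hit_idx]
    denom = hw.sum()
    if denom == 0:
        hw = np.ones_like(hw)
        denom = float(len(hw))
    steps = np.full(n, -miss_step)
    steps[hit_idx] = hw / denom
    running = np.cumsum(steps)
    hi, lo = running.max(), running.min()
    return float(hi) if hi >= -lo else float(lo)


def gsea_preranked(ranked: RankedList, collection: dict[str, set],
                   n_perm: int = 1000, min_size: int = 5, max_size: int = 500,
                   weight: float = 1.0, seed: int = 0) -> GSEAResult:
    """Run preranked GSEA over a gene-set collection.

    Sets are intersected with the ranked universe before size filtering.
    NES = ES / mean(|null ES| of matching sign); nominal p is one-sided
    within the matching-sign null with (1+b)/(1+n_perm) smoothing, so it is
    never exactly zero; BH FDR runs across all retained sets.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    universe = set(ranked.genes)
    n = len(ranked)
    weights = np.abs(ranked.scores) ** weight
    rng = np.random.default_rng(seed)

    rows, excluded = [], []
    for name in sorted(collection):
        members = set(collection[name]) & universe
        size = len(members)
        if size < min_size or size > max_size:
            excluded.append((name, f"size {size} outside [{min_size}, {max_size}]"))
            continue
        es, _, leading = enrichment_score(ranked, members, weight)
        miss_step = 1.0 / (n - size)
        null = np.array([
            _es_only(weights, miss_step, rng.choice(n, size=size, replace=False), n)
            for _ in range(n_perm)
        ])
        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        if len(same_sign) == 0:
            nes = np.nan
            pvalue = 1.0 / (1.0 + n_perm)
            flagged = True
        else:
            nes = es / np.abs(same_sign).mean()
            b = int((np.abs(same_sign) >= abs(es)).sum())
            pvalue = (1.0 + b) / (1.0 + len(same_sign))
            flagged = False
        rows.append((name, size, es, nes, pvalue, flagged,
                     ",".join(str(g) for g in leading)))
    table = pd.DataFrame(rows, columns=["set", "size", "ES", "NES", "pvalue",
                                        "null_sign_flag", "leading_edge"])
    table["fdr"] = bh_adjust(table["pvalue"]) if len(table) else []
    table = table[["set", "size", "ES", "NES", "pvalue", "fdr",
                   "null_sign_flag", "leading_edge"]]
    return GSEAResult(table=table,
                      excluded=pd.DataFrame(excluded, columns=["set", "reason"]),
                      n_permutations=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# GMT format

def read_gmt(path) -> dict[str, set]:
    """Read a GMT gene-set file: name <tab> description <tab> gene ids..."""
    sets: dict[str, set] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line has <3 fields: {line[:60]!r}")
        sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(collection: dict[str, set], path,
              descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection):
            desc = (descriptions or {}).get(name, "na")
            genes = "\t".join(sorted(str(g) for g in collection[name]))
            fh.write(f"{name}\t{desc}\t{genes}\n")
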