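"""Gene-set enrichment over a capped differential ranking.

Genes are ranked by ``log2FC x min(-log10 p, cap)`` with a default cap of
3, so that very small p-values cannot dominate the ranking; adjusted
p-values are used for every metric except s2b, which uses raw p.  The
enrichment score is the standard weighted Kolmogorov-Smirnov running-sum
statistic, with significance from gene-label permutations of set
membership (the pipeline receives a precomputed ranking, so sample-label
permutation is unavailable at this stage).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger("riboscreen.gsea")


def ranking_metric(log2fc, p_used, cap: float = 3.0):
    """Capped GSEA ranking score: log2FC x min(-log10 p, cap).

    ``p_used`` is the adjusted p-value for RNA/RO/uORF-RO/TE rankings and
    the raw p-value for s2b.  p = 0 is treated as hitting the cap (logged),
    never as an infinite score.
    """
    lfc = np.asarray(log2fc, dtype=float)
    p = np.asarray(p_used, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p_used must lie in [0, 1]")
    n_zero = int(np.sum(p == 0))
    if n_zero:
        log.info("ranking_metric: %d zero p-values treated as cap %g", n_zero, cap)
    with np.errstate(divide="ignore"):
        mult = np.minimum(-np.log10(np.where(p == 0, 1.0, p)), cap)
    mult = np.where(p == 0, cap, mult)
    out = lfc * mult
    return float(out) if out.ndim == 0 else out


def rank_genes(diff_table: pd.DataFrame, use_adjusted: bool = True,
               cap: float = 3.0) -> pd.DataFrame:
    """Build a ranked list (descending score) from a differential table.

    Only tested genes are ranked; ties are broken by gene_id so the
    ordering is deterministic.
    """
    t = diff_table[diff_table["tested"]]
    score = ranking_metric(t["log2FC"], t["adjP" if use_adjusted else "p"], cap)
    ranked = pd.DataFrame({"gene_id": t["gene_id"].to_numpy(), "score": score})
    ranked = ranked.sort_values(["score", "gene_id"],
                                ascending=[False, True], ignore_index=True)
    return ranked


def enrichment_score(ranked: pd.DataFrame, members,
                     weight: float = 1.0) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score and the running sum over positions.

    Hits increment by |score|^weight normalized by the in-set total;
    misses decrement by 1/(N - n_set).  ES is the running-sum value of
    maximum absolute deviation (signed).  Raises if no member overlaps the
    list; a set covering every gene degenerates to ES = 1 (logged).
    """
    genes = ranked["gene_id"].to_numpy()
    scores = ranked["score"].to_numpy(dtype=float)
    hit = np.isin(genes, list(members))
    return _es_from_mask(scores, hit, weight)


def _es_from_mask(scores: np.ndarray, hit: np.ndarray,
                  weight: float) -> tuple[float, np.ndarray]:
    n = scores.size
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    w = np.abs(scores[hit]) ** weight
    total = w.sum()
    steps = np.zeros(n)
    if total > 0:
        steps[hit] = w / total
    else:  # all in-set scores zero: fall back to equal hit weights
        steps[hit] = 1.0 / n_hit
    n_miss = n - n_hit
    if n_miss == 0:
        log.info("enrichment_score: set covers the whole list (degenerate ES=1)")
        running = np.cumsum(steps)
        return 1.0, running
    steps[~hit] = -1.0 / n_miss
    running = np.cumsum(steps)
    imax = int(np.argmax(np.abs(running)))
    return float(running[imax]), running


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    p: float
    fdr_q: float
    size: int


def gsea_permutation(ranked: pd.DataFrame, sets: dict[str, list[str]],
                     n_perm: int = 1000, seed: int = 0, weight: float = 1.0,
                     min_set: int = 5, max_set: int = 500) -> pd.DataFrame:
    """Permutation GSEA over a ranked list.

    Null enrichment scores come from gene-label permutations of set
    membership.  Nominal p is one-sided against same-sign null scores;
    NES = ES / mean |same-sign null ES|; FDR q follows the standard
    pooled-NES ratio.  Fixed seed gives identical output.
    """
    if n_perm < 100:
        raise ValueError("n_perm < 100 gives unusable p-value resolution")
    rng = np.random.default_rng(seed)
    genes = ranked["gene_id"].to_numpy()
    scores = ranked["score"].to_numpy(dtype=float)
    n = genes.size
    gene_index = {g: i for i, g in enumerate(genes)}

    rows = []
    null_nes_pos: list[np.ndarray] = []
    null_nes_neg: list[np.ndarray] = []
    kept = []
    for name, members in sets.items():
        idx = np.array(sorted({gene_index[g] for g in members if g in gene_index}),
                       dtype=int)
        if idx.size == 0:
            log.info("gsea: set %s has no overlap with ranking; skipped", name)
            continue
        if not (min_set <= idx.size <= min(max_set, n - 1)):
            log.info("gsea: set %s size %d outside [%d, %d]; skipped",
                     name, idx.size, min_set, max_set)
            continue
        hit = np.zeros(n, dtype=bool)
        hit[idx] = True
        es, _ = _es_from_mask(scores, hit, weight)

        null = np.empty(n_perm)
        for b in range(n_perm):
            perm = rng.choice(n, size=idx.size, replace=False)
            mask = np.zeros(n, dtype=bool)
            mask[perm] = True
            null[b], _ = _es_from_mask(scores, mask, weight)

        same = null[null >= 0] if es >= 0 else null[null < 0]
        if same.size == 0:
            p = 1.0 / (n_perm + 1)
            nes = 0.0
        else:
            p = (1 + np.sum(np.abs(same) >= abs(es))) / (1 + same.size)
            nes = es / np.mean(np.abs(same))
        pos = null[null >= 0]
        neg = null[null < 0]
        null_nes_pos.append(pos / pos.mean() if pos.size else np.empty(0))
        null_nes_neg.append(neg / np.abs(neg).mean() if neg.size else np.empty(0))
        kept.append((name, es, nes, p, idx.size))
        rows.append(None)

    if not kept:
        return pd.DataFrame(columns=["set_name", "es", "nes", "p", "fdr_q", "size"])

    all_pos = np.concatenate(null_nes_pos) if null_nes_pos else np.empty(0)
    all_neg = np.concatenate(null_nes_neg) if null_nes_neg else np.empty(0)
    obs_nes = np.array([k[2] for k in kept])
    out_rows = []
    for name, es, nes, p, size in kept:
        if nes >= 0:
            null_frac = (np.sum(all_pos >= nes) / all_pos.size) if all_pos.size else 0.0
            obs_frac = np.sum(obs_nes >= nes) / max(np.sum(obs_nes >= 0), 1)
        else:
            null_frac = (np.sum(all_neg <= nes) / all_neg.size) if all_neg.size else 0.0
            obs_frac = np.sum(obs_nes <= nes) / max(np.sum(obs_nes < 0), 1)
        q = min(null_frac / obs_frac, 1.0) if obs_frac > 0 else 1.0
        out_rows.append({"set_name": name, "es": es, "nes": nes, "p": p,
                         "fdr_q": q, "size": size})
    return pd.DataFrame(out_rows)
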