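"""Dropout scoring of a pooled CRISPR screen.

Counts are median-of-ratios normalized (with a pseudocount), guide-level
log2 fold changes end/T0 are computed per replicate pair, and each gene's
score — the mean of its guides' replicate-averaged LFCs — is compared
against a null of size-matched resamples from the nontargeting guide pool.
The empirical p-value is depletion-sided (a dropout screen); enrichment is
informational only.  This is a fully specified resampling replacement for
pipeline-style screen callers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .difftrans import bh_adjust, size_factors
from .io_tables import SampleSheet

log = logging.getLogger("riboscreen.screen")

DROPOUT = "DROPOUT"
NEUTRAL = "NEUTRAL"


def normalize_screen(counts: pd.DataFrame, pseudocount: float = 1.0
                     ) -> tuple[pd.DataFrame, np.ndarray]:
    """Pseudocounted counts scaled by median-of-ratios size factors."""
    if counts.shape[1] < 2:
        raise ValueError("screen normalization needs >= 2 samples (T0 and end)")
    mat = counts.to_numpy(dtype=float) + pseudocount
    sf = size_factors(mat)
    norm = pd.DataFrame(mat / sf[None, :], index=counts.index,
                        columns=counts.columns)
    return norm, sf


def guide_lfc(norm: pd.DataFrame, pairing: list[tuple[str, str]]) -> pd.DataFrame:
    """Per-guide log2 fold change end/T0 for each replicate pair.

    ``pairing`` is a list of (t0_sample, end_sample) column pairs; the
    normalized table already carries the pseudocount, so LFCs are finite
    even at zero raw counts.
    """
    cols = {}
    for t0, end in pairing:
        cols[f"{end}_vs_{t0}"] = np.log2(norm[end]) - np.log2(norm[t0])
    return pd.DataFrame(cols, index=norm.index)


def replicate_pairing(sheet: SampleSheet) -> list[tuple[str, str]]:
    """Match SCREEN_T0 to SCREEN_END samples by replicate number."""
    t0 = {s.replicate: s.sample_id for s in sheet if s.assay == "SCREEN_T0"}
    end = {s.replicate: s.sample_id for s in sheet if s.assay == "SCREEN_END"}
    common = sorted(set(t0) & set(end))
    if not common:
        raise ValueError("no replicate-matched T0/end sample pairs in sheet")
    return [(t0[r], end[r]) for r in common]


@dataclass
class ScreenResults:
    """Gene-level dropout results.

    ``table`` columns: gene_id, mean_lfc, p, adjP, n_guides, call.  The
    empirical p is bounded below by 1/(n_resamples+1); DROPOUT requires
    adjP below the FDR threshold and a negative mean LFC.
    """

    table: pd.DataFrame
    guide_table: pd.DataFrame
    n_resamples: int
    fdr: float
    n_nontargeting: int

    @property
    def dropouts(self) -> pd.DataFrame:
        return self.table[self.table["call"] == DROPOUT]

    def summary(self) -> str:
        t = self.table
        return "\n".join([
            f"Dropout screen: {len(t)} genes, {len(self.guide_table)} guides, "
            f"{self.n_nontargeting} nontargeting",
            f"  resamples: {self.n_resamples}  FDR: {self.fdr:g}",
            f"  dropout calls: {len(self.dropouts)}",
            f"  median gene LFC: {t['mean_lfc'].median():.3f}",
        ])

    def write(self, path, guide_path=None, **meta) -> None:
        from .io_tables import write_tsv
        write_tsv(self.table, path, **meta)
        if guide_path is not None:
            write_tsv(self.guide_table.reset_index(), guide_path, **meta)


class DropoutScreen:
    """Model object for scoring a dropout screen.

    Parameters
    ----------
    counts : guides x samples raw count table (index = guide_id).
    library : guide annotation with guide_id, gene_id, class columns
        (nontargeting guides identified by class == "nontargeting").
    sheet : sample sheet with SCREEN_T0 / SCREEN_END assays.
    """

    def __init__(self, counts: pd.DataFrame, library: pd.DataFrame,
                 sheet: SampleSheet, pseudocount: float = 1.0,
                 min_nontargeting: int = 20):
        lib = library.set_index("guide_id")
        missing = counts.index.difference(lib.index)
        if len(missing):
            raise ValueError(f"count table guides absent from library: "
                             f"{list(missing[:5])}")
        self.counts = counts
        self.library = lib.loc[counts.index]
        self.sheet = sheet
        self.pseudocount = pseudocount
        nt_mask = self.library["class"] == "nontargeting"
        if int(nt_mask.sum()) < min_nontargeting:
            raise ValueError(
                f"only {int(nt_mask.sum())} nontargeting guides; "
                f">= {min_nontargeting} required to define the null")
        self.nt_mask = nt_mask.to_numpy()

    def fit(self, n_resamples: int = 10000, seed: int = 0,
            fdr: float = 0.05) -> ScreenResults:
        rng = np.random.default_rng(seed)
        norm, _ = normalize_screen(self.counts, self.pseudocount)
        pairs = replicate_pairing(self.sheet)
        lfcs = guide_lfc(norm, pairs)
        guide_mean = lfcs.mean(axis=1).to_numpy()

        nt_pool = guide_mean[self.nt_mask]
        target = self.library.loc[~self.nt_mask & (self.library["gene_id"] != "")]
        by_gene: dict[str, np.ndarray] = {}
        pos = {g: i for i, g in enumerate(self.counts.index)}
        for gene, sub in target.groupby("gene_id"):
            idx = np.array([pos[g] for g in sub.index])
            if idx.size < 2:
                log.warning("gene %s has %d guide(s); skipped (need >= 2)",
                            gene, idx.size)
                continue
            by_gene[gene] = idx

        # shared null per guide-count class: means of random nontargeting draws
        sizes = sorted({idx.size for idx in by_gene.values()})
        nulls = {k: rng.choice(nt_pool, size=(n_resamples, k), replace=True)
                 .mean(axis=1) for k in sizes}

        rows = []
        for gene in sorted(by_gene):
            idx = by_gene[gene]
            score = float(guide_mean[idx].mean())
            null = nulls[idx.size]
            p = (1 + int(np.sum(null <= score))) / (n_resamples + 1)
            rows.append({"gene_id": gene, "mean_lfc": score, "p": p,
                         "n_guides": int(idx.size)})
        table = pd.DataFrame(rows)
        table["adjP"] = bh_adjust(table["p"].to_numpy())
        table["call"] = np.where((table["adjP"] < fdr) & (table["mean_lfc"] < 0),
                                 DROPOUT, NEUTRAL)
        table = table[["gene_id", "mean_lfc", "p", "adjP", "n_guides", "call"]]

        guide_table = lfcs.copy()
        guide_table["mean_lfc"] = guide_mean
        guide_table["gene_id"] = self.library["gene_id"].to_numpy()
        guide_table["class"] = self.library["class"].to_numpy()
        log.info("DropoutScreen: %d genes scored, %d DROPOUT at FDR %g",
                 len(table), int((table["call"] == DROPOUT).sum()), fdr)
        return ScreenResults(table, guide_table, n_resamples, fdr,
                             int(self.nt_mask.sum()))
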