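"""Positional footprint quantification: region counts, RO, uORF RO, TPM, s2b.

Ribosome occupancy (RO) is the footprint count over a transcript's CDS and
uORF RO the count over its 5'UTR.  The start-to-body ratio (s2b) captures
initiation-proximal ribosome accumulation: the ratio of P-site counts in
the first 30 codons (90 nt) of the CDS to counts over the rest of the CDS,
multiplied by (CDS length - 90) so that uniform coverage yields the same
value (90) regardless of CDS length.  Genes with few CDS footprints or a
CDS shorter than 100 nt are excluded from s2b analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .annotation import AnnotationRecord

log = logging.getLogger("riboscreen.quantify")

# s2b exclusion reasons; SHORT_CDS is reported first when both apply.
SHORT_CDS = "SHORT_CDS"
LOW_RPF = "LOW_RPF"
INFINITE = "INFINITE"


@dataclass
class PositionalProfile:
    """P-site counts per nucleotide of one transcript in one sample."""

    transcript_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("profile counts must be a 1-D vector")
        if (self.counts < 0).any():
            raise ValueError("profile counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class RegionCounts:
    """Exact partition of a profile into annotation regions.

    ``cds_start`` covers CDS offsets [0, start_window) and ``cds_body``
    [start_window, cds_len); ``utr5 + cds_start + cds_body + utr3`` always
    equals the profile total.  ``short_start_window`` flags transcripts
    whose CDS is shorter than the start window (body empty).
    """

    utr5: int
    cds_start: int
    cds_body: int
    utr3: int
    short_start_window: bool = False

    @property
    def cds_total(self) -> int:
        return self.cds_start + self.cds_body

    @property
    def total(self) -> int:
        return self.utr5 + self.cds_total + self.utr3


@dataclass(frozen=True)
class S2BResult:
    """s2b value or an exclusion; excluded values never enter testing."""

    value: float | None
    excluded: bool
    reason: str | None = None


def assign_psites(alignments: pd.DataFrame,
                  tx_lengths: Mapping[str, int],
                  offset: int = 12,
                  len_range: tuple[int, int] = (19, 32),
                  ) -> dict[str, PositionalProfile]:
    """Collapse footprint alignments to per-nucleotide P-site profiles.

    Footprints outside ``len_range`` (inclusive) are discarded; the P-site
    of a kept footprint is its 5'-end offset plus ``offset``.  Footprints
    whose P-site falls outside the transcript are dropped.  Both discard
    counts are logged.

    Parameters
    ----------
    alignments : DataFrame with columns transcript_id, five_prime_pos
        (0-based), length, and optional count.
    tx_lengths : transcript_id -> transcript length (nt).
    """
    lo, hi = len_range
    if not (0 <= offset < lo):
        raise ValueError(f"offset {offset} must satisfy 0 <= offset < min length {lo}")
    if "count" not in alignments.columns:
        alignments = alignments.assign(count=1)
    unknown = sorted(set(alignments["transcript_id"]) - set(tx_lengths))
    if unknown:
        raise KeyError(f"alignments reference unknown transcripts: {unknown[:10]}"
                       + ("..." if len(unknown) > 10 else ""))

    lengths = alignments["length"].to_numpy()
    in_range = (lengths >= lo) & (lengths <= hi)
    n_out = int(alignments.loc[~in_range, "count"].sum())
    if n_out:
        log.info("assign_psites: discarded %d footprints outside length range [%d, %d]",
                 n_out, lo, hi)
    kept = alignments.loc[in_range]

    profiles = {tid: PositionalProfile(tid, np.zeros(tx_lengths[tid], dtype=np.int64))
                for tid in tx_lengths}
    n_off = 0
    for tid, sub in kept.groupby("transcript_id", sort=False):
        arr = profiles[tid].counts
        pos = sub["five_prime_pos"].to_numpy() + offset
        cnt = sub["count"].to_numpy()
        ok = (pos >= 0) & (pos < arr.size)
        n_off += int(cnt[~ok].sum())
        np.add.at(arr, pos[ok], cnt[ok])
    if n_off:
        log.info("assign_psites: dropped %d footprints with out-of-transcript P-sites",
                 n_off)
    return profiles


def region_counts(profile: PositionalProfile, model: AnnotationRecord,
                  start_window_nt: int = 90) -> RegionCounts:
    """Partition a profile into 5'UTR / CDS-start / CDS-body / 3'UTR counts."""
    counts = profile.counts
    if counts.size != model.tx_len:
        raise ValueError(
            f"profile length {counts.size} != transcript length {model.tx_len} "
            f"for {model.transcript_id}")
    a, b = model.cds_start, model.cds_end
    window = min(start_window_nt, model.cds_len)
    short = start_window_nt > model.cds_len
    if short:
        log.info("region_counts: %s CDS (%d nt) shorter than start window (%d nt)",
                 model.transcript_id, model.cds_len, start_window_nt)
    return RegionCounts(
        utr5=int(counts[:a].sum()),
        cds_start=int(counts[a:a + window].sum()),
        cds_body=int(counts[a + window:b].sum()),
        utr3=int(counts[b:].sum()),
        short_start_window=short,
    )


def compute_s2b(rc: RegionCounts, cds_len: int,
                min_rpf: int = 32, min_cds_len: int = 100,
                start_window_nt: int = 90,
                multiplier: str = "length_minus_90") -> S2BResult:
    """Start-to-body ratio with exclusion filters.

    s2b = (cds_start / cds_body) x (cds_len - start_window); with the
    ``length_ratio`` variant the multiplier is
    (cds_len - start_window) / start_window instead.  Exclusions:
    CDS shorter than ``min_cds_len`` -> SHORT_CDS (reported first), fewer
    than ``min_rpf`` CDS footprints -> LOW_RPF.  A zero body with a nonzero
    start yields an infinite sentinel, excluded from differential testing;
    a zero start with nonzero body yields s2b = 0, retained.
    """
    if cds_len < min_cds_len:
        return S2BResult(None, True, SHORT_CDS)
    if rc.cds_total < min_rpf:
        return S2BResult(None, True, LOW_RPF)
    factor = float(cds_len - start_window_nt)
    if multiplier == "length_ratio":
        factor /= start_window_nt
    elif multiplier != "length_minus_90":
        raise ValueError(f"unknown s2b multiplier {multiplier!r}")
    if rc.cds_body == 0:
        if rc.cds_start == 0:
            return S2BResult(None, True, LOW_RPF)
        return S2BResult(math.inf, True, INFINITE)
    return S2BResult(rc.cds_start / rc.cds_body * factor, False, None)


def tpm(counts: np.ndarray | pd.Series, lengths: np.ndarray | pd.Series) -> np.ndarray:
    """Length-normalized abundance in transcripts-per-million style units."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be positive")
    rate = counts / lengths
    total = rate.sum()
    if total == 0:
        log.warning("tpm: all counts zero; returning zeros")
        return np.zeros_like(rate)
    return rate / total * 1e6


def quantify_sample(profiles: Mapping[str, PositionalProfile],
                    models: Mapping[str, AnnotationRecord],
                    start_window_nt: int = 90,
                    s2b_min_rpf: int = 32,
                    s2b_min_cds_len: int = 100,
                    s2b_multiplier: str = "length_minus_90") -> pd.DataFrame:
    """Occupancy metrics for one sample over per-gene primary transcripts.

    Returns one row per gene: RO (CDS count), uORF_RO (5'UTR count), utr3
    count, s2b (NaN when excluded) and the exclusion reason.
    """
    rows = []
    n_excl = {SHORT_CDS: 0, LOW_RPF: 0, INFINITE: 0}
    for gene, model in models.items():
        prof = profiles.get(model.transcript_id)
        if prof is None:
            prof = PositionalProfile(model.transcript_id,
                                     np.zeros(model.tx_len, dtype=np.int64))
        rc = region_counts(prof, model, start_window_nt)
        s2b = compute_s2b(rc, model.cds_len, s2b_min_rpf, s2b_min_cds_len,
                          start_window_nt, s2b_multiplier)
        if s2b.excluded:
            n_excl[s2b.reason] += 1
        rows.append({
            "gene_id": gene,
            "transcript_id": model.transcript_id,
            "cds_len": model.cds_len,
            "RO": rc.cds_total,
            "uORF_RO": rc.utr5,
            "utr3_count": rc.utr3,
            "cds_start": rc.cds_start,
            "cds_body": rc.cds_body,
            "s2b": (s2b.value if s2b.value is not None and not s2b.excluded
                    else np.nan),
            "s2b_excluded": s2b.excluded,
            "s2b_reason": s2b.reason if s2b.excluded else "",
        })
    log.info("quantify: s2b exclusions SHORT_CDS=%d LOW_RPF=%d INFINITE=%d of %d genes",
             n_excl[SHORT_CDS], n_excl[LOW_RPF], n_excl[INFINITE], len(rows))
    return pd.DataFrame(rows)


def quantify_samples(profiles_by_sample: Mapping[str, Mapping[str, PositionalProfile]],
                     models: Mapping[str, AnnotationRecord],
                     **kwargs) -> pd.DataFrame:
    """Stack :func:`quantify_sample` over samples (adds a ``sample_id`` column)."""
    frames = []
    for sample_id, profiles in profiles_by_sample.items():
        df = quantify_sample(profiles, models, **kwargs)
        df.insert(0, "sample_id", sample_id)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def occupancy_matrix(occupancy: pd.DataFrame, value: str,
                     sample_ids: Iterable[str] | None = None) -> pd.DataFrame:
    """Pivot a stacked occupancy table to genes x samples for one metric."""
    mat = occupancy.pivot(index="gene_id", columns="sample_id", values=value)
    if sample_ids is not None:
        mat = mat[list(sample_ids)]
    mat.columns.name = None
    return mat
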