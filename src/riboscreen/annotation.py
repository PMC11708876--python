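"""Transcript annotation: region structure and primary-transcript selection.

A transcript is modelled as three contiguous regions laid out 5'->3' in
transcript coordinates: 5'UTR, CDS, 3'UTR.  All internal coordinates are
0-based half-open offsets from the transcript 5' end; GTF input (1-based,
closed) is converted once at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

log = logging.getLogger("riboscreen.annotation")

_TSV_COLUMNS = ("transcript_id", "gene_id", "utr5_len", "cds_len", "utr3_len",
                "appris_primary")


@dataclass(frozen=True)
class AnnotationRecord:
    """Per-transcript region structure.

    ``utr5_len``, ``cds_len`` and ``utr3_len`` are nucleotide counts; the
    transcript length is their sum.  ``appris_primary`` marks the
    transcript designated as the gene's principal isoform.
    """

    transcript_id: str
    gene_id: str
    utr5_len: int
    cds_len: int
    utr3_len: int
    appris_primary: bool = False

    def __post_init__(self) -> None:
        for name in ("utr5_len", "cds_len", "utr3_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")

    @property
    def tx_len(self) -> int:
        return self.utr5_len + self.cds_len + self.utr3_len

    @property
    def cds_start(self) -> int:
        """0-based transcript offset of the first CDS nucleotide."""
        return self.utr5_len

    @property
    def cds_end(self) -> int:
        """0-based half-open transcript offset just past the CDS."""
        return self.utr5_len + self.cds_len


class AnnotationError(ValueError):
    """Malformed annotation input."""


def _check_cds_frame(rec: AnnotationRecord, source: str) -> None:
    if rec.cds_len > 0 and rec.cds_len % 3 != 0:
        log.warning("%s: transcript %s CDS length %d not divisible by 3; kept",
                    source, rec.transcript_id, rec.cds_len)


def read_annotation(path: str | Path) -> dict[str, AnnotationRecord]:
    """Read an annotation file (tabular or GTF) into records keyed by transcript.

    The tabular dialect has a header line with columns
    ``transcript_id gene_id utr5_len cds_len utr3_len appris_primary``.
    The GTF dialect uses ``exon`` and ``CDS`` features with 1-based closed
    coordinates; exons of a transcript must tile a single contiguous
    interval (transcript coordinates), and the 5'UTR/CDS/3'UTR lengths are
    derived from the CDS span within it.
    """
    path = Path(path)
    if not path.exists():
        raise AnnotationError(f"annotation file not found: {path}")
    with open(path) as fh:
        head = fh.readline()
    if head == "":
        log.warning("annotation file %s is empty", path)
        return {}
    if "\t" in head and head.split("\t")[0] == "transcript_id":
        return _read_annotation_tsv(path)
    return _read_annotation_gtf(path)


def _read_annotation_tsv(path: Path) -> dict[str, AnnotationRecord]:
    records: dict[str, AnnotationRecord] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _TSV_COLUMNS:
            raise AnnotationError(
                f"{path}: expected columns {_TSV_COLUMNS}, got {tuple(header)}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise AnnotationError(f"{path}:{lineno}: expected 6 fields")
            tid, gid, u5, cds, u3, primary = fields
            try:
                rec = AnnotationRecord(tid, gid, int(u5), int(cds), int(u3),
                                       primary.strip().lower() in ("true", "1", "yes"))
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
            if tid in records:
                raise AnnotationError(f"{path}:{lineno}: duplicate transcript_id {tid}")
            _check_cds_frame(rec, str(path))
            records[tid] = rec
    return records


def _parse_gtf_attrs(attr_field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in attr_field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if " " in part:
            key, _, val = part.partition(" ")
            attrs[key] = val.strip().strip('"')
    return attrs


def _read_annotation_gtf(path: Path) -> dict[str, AnnotationRecord]:
    # collect exon and CDS intervals per transcript (1-based closed)
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    genes: dict[str, str] = {}
    tags: dict[str, bool] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise AnnotationError(f"{path}:{lineno}: expected >= 9 GTF fields")
            feature, start_s, end_s = fields[2], fields[3], fields[4]
            if feature not in ("exon", "CDS"):
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}:{lineno}: malformed coordinates {start_s!r}/{end_s!r}") from exc
            if start < 1 or end < start:
                raise AnnotationError(
                    f"{path}:{lineno}: invalid interval {start}-{end}")
            attrs = _parse_gtf_attrs(fields[8])
            tid = attrs.get("transcript_id")
            if tid is None:
                raise AnnotationError(f"{path}:{lineno}: missing transcript_id")
            genes.setdefault(tid, attrs.get("gene_id", tid))
            if attrs.get("tag") == "appris_principal" or \
                    attrs.get("appris_primary", "").lower() == "true":
                tags[tid] = True
            (exons if feature == "exon" else cds).setdefault(tid, []).append((start, end))

    records: dict[str, AnnotationRecord] = {}
    for tid, ex in exons.items():
        ex = sorted(ex)
        tx_start, tx_end = ex[0][0], ex[-1][1]
        tx_len = sum(e - s + 1 for s, e in ex)
        if tx_len != tx_end - tx_start + 1:
            raise AnnotationError(
                f"transcript {tid}: exons are not contiguous in transcript "
                "coordinates (multi-exon genomic layout is out of scope)")
        spans = cds.get(tid, [])
        if spans:
            cstart = min(s for s, _ in spans)
            cend = max(e for _, e in spans)
            utr5 = cstart - tx_start
            cds_len = cend - cstart + 1
            utr3 = tx_end - cend
        else:
            utr5, cds_len, utr3 = 0, 0, tx_len
        rec = AnnotationRecord(tid, genes[tid], utr5, cds_len, utr3,
                               tags.get(tid, False))
        _check_cds_frame(rec, str(path))
        records[tid] = rec
    if not records:
        log.warning("annotation file %s contained no exon features", path)
    return records


def write_annotation_tsv(records: Mapping[str, AnnotationRecord] | Iterable[AnnotationRecord],
                         path: str | Path) -> None:
    """Write records in the tabular dialect accepted by :func:`read_annotation`."""
    if isinstance(records, Mapping):
        records = records.values()
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for rec in records:
            fh.write(f"{rec.transcript_id}\t{rec.gene_id}\t{rec.utr5_len}\t"
                     f"{rec.cds_len}\t{rec.utr3_len}\t{str(rec.appris_primary).lower()}\n")


def select_primary(records: Mapping[str, AnnotationRecord],
                   appris: Mapping[str, str] | None = None
                   ) -> dict[str, AnnotationRecord]:
    """Pick one representative transcript per gene.

    An explicit ``appris`` map (gene_id -> transcript_id) wins outright.
    Otherwise transcripts flagged ``appris_primary`` are preferred; among
    the remaining candidates the longest CDS wins, ties broken by
    lexicographic transcript_id (logged).
    """
    by_gene: dict[str, list[AnnotationRecord]] = {}
    for rec in records.values():
        by_gene.setdefault(rec.gene_id, []).append(rec)

    chosen: dict[str, AnnotationRecord] = {}
    for gene, recs in sorted(by_gene.items()):
        if appris is not None and gene in appris:
            tid = appris[gene]
            if tid not in records:
                raise AnnotationError(
                    f"APPRIS map names unknown transcript {tid} for gene {gene}")
            chosen[gene] = records[tid]
            continue
        flagged = [r for r in recs if r.appris_primary]
        pool = flagged if flagged else recs
        pool = sorted(pool, key=lambda r: (-r.cds_len, r.transcript_id))
        if len(pool) > 1 and pool[0].cds_len == pool[1].cds_len:
            log.info("gene %s: CDS-length tie broken lexicographically -> %s",
                     gene, pool[0].transcript_id)
        chosen[gene] = pool[0]
    return chosen
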