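"""Tabular I/O: sample sheets, count tables, gene sets, FASTA, provenance headers.

All result tables are written as TSV with ``#``-prefixed provenance header
lines (tool version, seed, config hash) that every reader here skips, so a
write/read round trip reproduces values exactly.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import __version__

log = logging.getLogger("riboscreen.io")

ASSAYS = ("RNA", "RPF", "SCREEN_T0", "SCREEN_END")


class ValidationError(ValueError):
    """Input table violates its contract."""


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    condition: str
    assay: str
    replicate: int


class SampleSheet:
    """Sample metadata: one row per sample, (condition, assay, replicate) unique."""

    def __init__(self, samples: Sequence[SampleRecord]):
        seen_ids: set[str] = set()
        seen_keys: set[tuple[str, str, int]] = set()
        for s in samples:
            if s.assay not in ASSAYS:
                raise ValidationError(f"unknown assay {s.assay!r} (choose from {ASSAYS})")
            if s.replicate < 1:
                raise ValidationError(f"replicate must be >= 1 for {s.sample_id}")
            if s.sample_id in seen_ids:
                raise ValidationError(f"duplicate sample_id {s.sample_id}")
            key = (s.condition, s.assay, s.replicate)
            if key in seen_keys:
                raise ValidationError(f"duplicate (condition, assay, replicate) {key}")
            seen_ids.add(s.sample_id)
            seen_keys.add(key)
        self.samples = list(samples)

    def __iter__(self):
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def subset(self, assay: str | None = None, condition: str | None = None) -> "SampleSheet":
        keep = [s for s in self.samples
                if (assay is None or s.assay == assay)
                and (condition is None or s.condition == condition)]
        return SampleSheet(keep)

    def conditions(self, assay: str | None = None) -> list[str]:
        out: list[str] = []
        for s in self.samples:
            if assay is not None and s.assay != assay:
                continue
            if s.condition not in out:
                out.append(s.condition)
        return out

    def condition_of(self, sample_id: str) -> str:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s.condition
        raise KeyError(sample_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.__dict__ for s in self.samples])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SampleSheet":
        required = {"sample_id", "condition", "assay", "replicate"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"sample sheet missing columns {sorted(missing)}")
        return cls([SampleRecord(str(r.sample_id), str(r.condition), str(r.assay),
                                 int(r.replicate))
                    for r in df.itertuples(index=False)])

    @classmethod
    def read(cls, path: str | Path) -> "SampleSheet":
        return cls.from_frame(read_tsv(path))

    def write(self, path: str | Path, **meta) -> None:
        write_tsv(self.to_frame(), path, **meta)


def provenance_header(**meta) -> str:
    parts = [f"riboscreen={__version__}"] + [f"{k}={v}" for k, v in meta.items()]
    return "# " + " ".join(parts)


def config_hash(config: dict) -> str:
    """Short digest of the analysis configuration (the output location does
    not alter results and is excluded)."""
    items = sorted((k, v) for k, v in config.items() if k != "out_dir")
    return hashlib.sha256(repr(items).encode()).hexdigest()[:12]


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False, **meta) -> None:
    """Write a TSV with a provenance header line."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(provenance_header(**meta) + "\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def read_counts(path: str | Path, sheet: SampleSheet,
                key_cols: Sequence[str] = ("gene_id",)) -> pd.DataFrame:
    """Read a count TSV keyed by ``key_cols`` with one column per sample.

    Columns are aligned to the sheet's sample order (the join is
    order-invariant).  Entries must be nonnegative integers; violations are
    reported with their cell address.
    """
    df = read_tsv(path)
    for col in key_cols:
        if col not in df.columns:
            raise ValidationError(f"{path}: missing key column {col!r}")
    sample_cols = [c for c in df.columns if c not in key_cols]
    unknown = [c for c in sample_cols if c not in sheet.sample_ids]
    if unknown:
        raise ValidationError(f"{path}: samples {unknown} absent from sample sheet")
    missing = [s for s in sheet.sample_ids if s not in sample_cols]
    if missing:
        raise ValidationError(f"{path}: sheet samples {missing} absent from table")
    df = df.set_index(list(key_cols))
    for col in sheet.sample_ids:
        vals = df[col]
        bad = vals.isna() | (vals != vals.astype("int64", errors="ignore"))
        try:
            as_int = vals.astype("int64")
            bad = vals != as_int
        except (ValueError, TypeError):
            bad = pd.Series(True, index=vals.index)
        if bad.any():
            row = bad.idxmax()
            raise ValidationError(
                f"{path}: non-integer entry at (row {row!r}, column {col!r}): "
                f"{vals[bad].iloc[0]!r}")
        if (as_int < 0).any():
            row = (as_int < 0).idxmax()
            raise ValidationError(
                f"{path}: negative entry at (row {row!r}, column {col!r})")
        df[col] = as_int
    return df[list(sheet.sample_ids)]


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read gene sets from GMT (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"{path}:{lineno}: GMT needs >= 3 fields")
            name = fields[0]
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set {name}")
            sets[name] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, Iterable[str]], path: str | Path,
              description: str = "riboscreen") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    out[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif name is not None:
                chunks.append(line.strip())
    if name is not None:
        out[name] = "".join(chunks)
    return out


def read_alignments(path: str | Path) -> pd.DataFrame:
    """Read transcript-coordinate footprint records.

    Columns: ``transcript_id`` (str), ``five_prime_pos`` (0-based offset of
    the footprint 5' end), ``length`` (nt), and optionally ``count``
    (collapsed multiplicity, default 1).
    """
    df = read_tsv(path)
    required = {"transcript_id", "five_prime_pos", "length"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: alignment table missing {sorted(missing)}")
    if "count" not in df.columns:
        df["count"] = 1
    for col in ("five_prime_pos", "length", "count"):
        df[col] = df[col].astype("int64")
        if (df[col] < 0).any():
            raise ValidationError(f"{path}: negative values in column {col!r}")
    return df
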