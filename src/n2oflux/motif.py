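"""Screening of putative nosZ-like protein sequences.

Nitrous oxide reductase (NosZ) and its closest homolog, cytochrome c
oxidase subunit II, share the binuclear Cu_A copper center whose binding
signature is the nine-residue motif C-X3-C-X3-H.  The catalytic Cu_Z center
of NosZ has no consensus motif but is characterized by a set of conserved
histidine residues (seven in canonical NosZ; a five-histidine cupredoxin-
like protein has been reported directly upstream of nosZ-like genes in
DPANN genomes).  This module applies those published screening rules to
protein FASTA input: a length filter (default: keep 200-800 aa, the window
used when assembling NosZ reference sets), an exhaustive Cu_A motif scan,
and a histidine count with a configurable threshold.

The FASTA reader is deliberately line-oriented so that parse errors carry
the offending line number; on valid input it agrees with standard readers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWYX")
CUA_PATTERN = re.compile(r"(?=(C.{3}C.{3}H))")
CUA_LENGTH = 9

DEFAULT_MIN_LEN = 200
DEFAULT_MAX_LEN = 800
DEFAULT_HIS_THRESHOLD = 5


class FastaParseError(ValueError):
    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence; uppercase, 20 amino-acid letters plus X."""

    id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id}: sequence must be non-empty")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            pos = next(i for i, c in enumerate(self.sequence, 1) if c in bad)
            raise ValueError(
                f"record {self.id}: illegal residue {self.sequence[pos - 1]!r} "
                f"at position {pos}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifHit:
    """One Cu_A motif occurrence, 1-based inclusive coordinates."""

    record_id: str
    pattern_name: str
    start: int
    end: int
    matched_substring: str

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.matched_substring):
            raise ValueError("hit coordinates do not match the stored substring")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein multi-FASTA; wrapped lines joined, case normalized.

    Raises :class:`FastaParseError` with the line number on an empty file,
    a malformed header, or an illegal residue character.
    """
    records: list[ProteinRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []
    chunk_lines: list[int] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaParseError(f"record {header!r} has no sequence", header_line)
        for line_no, chunk in zip(chunk_lines, chunks):
            bad = set(chunk) - AMINO_ACIDS
            if bad:
                raise FastaParseError(
                    f"illegal residue character {sorted(bad)[0]!r} in record "
                    f"{header.split()[0]!r}",
                    line_no,
                )
        fields = header.split(None, 1)
        records.append(
            ProteinRecord(
                id=fields[0],
                description=fields[1] if len(fields) > 1 else "",
                sequence=seq,
            )
        )

    n_lines = 0
    with open(path) as fh:
        for n_lines, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise FastaParseError("empty FASTA header", n_lines)
                header_line = n_lines
                chunks = []
                chunk_lines = []
            else:
                if header is None:
                    raise FastaParseError(
                        "sequence data before any FASTA header", n_lines
                    )
                chunks.append(line.upper())
                chunk_lines.append(n_lines)
    if n_lines == 0:
        raise FastaParseError("empty FASTA file", 0)
    if header is None:
        raise FastaParseError("no FASTA records found", n_lines)
    flush()
    return records


def length_filter(
    records: Sequence[ProteinRecord],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Keep records with min_len <= length <= max_len (inclusive bounds)."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} exceeds max_len {max_len}")
    kept = [rec for rec in records if min_len <= rec.length <= max_len]
    removed = [rec for rec in records if not (min_len <= rec.length <= max_len)]
    return kept, removed


def scan_cua(record: ProteinRecord) -> list[MotifHit]:
    """All (overlapping) C-X3-C-X3-H motif occurrences, 1-based coordinates."""
    hits = []
    for m in CUA_PATTERN.finditer(record.sequence):
        start = m.start() + 1
        hits.append(
            MotifHit(
                record_id=record.id,
                pattern_name="CuA",
                start=start,
                end=start + CUA_LENGTH - 1,
                matched_substring=m.group(1),
            )
        )
    return hits


def count_histidines(
    record: ProteinRecord, threshold: int = DEFAULT_HIS_THRESHOLD
) -> tuple[int, bool]:
    """Histidine count over the full sequence and whether it meets the threshold."""
    count = record.sequence.count("H")
    return count, count >= threshold


@dataclass(frozen=True)
class ScreenRow:
    record_id: str
    length: int
    kept: bool
    hits: tuple[MotifHit, ...]
    histidine_count: int
    histidine_flag: bool


@dataclass(frozen=True)
class ScreenReport:
    """Per-record screening outcomes plus totals."""

    rows: tuple[ScreenRow, ...]
    n_input: int
    n_kept: int
    n_removed: int
    min_len: int
    max_len: int
    his_threshold: int

    def __post_init__(self) -> None:
        if self.n_kept + self.n_removed != self.n_input:
            raise ValueError("kept + removed must equal the input record count")

    @property
    def total_hits(self) -> int:
        return sum(len(row.hits) for row in self.rows)

    def to_tsv(self, path: str | Path | None = None) -> str:
        lines = [
            "record_id\tlength\tkept\tn_cua_hits\tcua_positions\tn_his\this_flag"
        ]
        for row in self.rows:
            positions = ";".join(str(h.start) for h in row.hits)
            lines.append(
                f"{row.record_id}\t{row.length}\t{str(row.kept).lower()}\t"
                f"{len(row.hits)}\t{positions}\t{row.histidine_count}\t"
                f"{str(row.histidine_flag).lower()}"
            )
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def screen(
    fasta_path: str | Path,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    his_threshold: int = DEFAULT_HIS_THRESHOLD,
) -> ScreenReport:
    """Length-filter a FASTA file, then motif-scan and count histidines on kept records."""
    records = read_fasta(fasta_path)
    kept, removed = length_filter(records, min_len=min_len, max_len=max_len)
    kept_ids = {rec.id for rec in kept}
    rows = []
    for rec in records:
        is_kept = rec.id in kept_ids and min_len <= rec.length <= max_len
        if is_kept:
            hits = tuple(scan_cua(rec))
            n_his, flag = count_histidines(rec, threshold=his_threshold)
        else:
            hits = ()
            n_his, flag = 0, False
        rows.append(
            ScreenRow(
                record_id=rec.id,
                length=rec.length,
                kept=is_kept,
                hits=hits,
                histidine_count=n_his,
                histidine_flag=flag,
            )
        )
    return ScreenReport(
        rows=tuple(rows),
        n_input=len(records),
        n_kept=len(kept),
        n_removed=len(removed),
        min_len=min_len,
        max_len=max_len,
        his_threshold=his_threshold,
    )
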