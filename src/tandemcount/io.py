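"""Sequence and table I/O plus the shared sequence types.

Coordinates everywhere in this package are 0-based, half-open intervals.
Strand "+" means as-read orientation.
"""

from __future__ import annotations

import csv
import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a DNA string; N (and unknown bases) map to N."""
    cleaned = "".join(b if b in "ACGTNacgtn" else "N" for b in sequence)
    return cleaned.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RepeatUnit:
    """The known repeat-unit reference sequence.

    The unit must be a plain A/C/G/T string: it is the yardstick every read
    position is compared against, so ambiguity codes are rejected outright.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError(f"repeat unit {self.id!r} is empty")
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"repeat unit {self.id!r} contains non-ACGT characters: {sorted(bad)}"
            )

    @property
    def length_m(self) -> int:
        return len(self.sequence)


@dataclass
class ReadRecord:
    """One long read. Ambiguous bases are kept verbatim but never match."""

    id: str
    sequence: str
    qualities: Optional[Sequence[int]] = None
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"read {self.id!r} has empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.qualities)} != "
                f"sequence length {len(self.sequence)}"
            )

    def reverse_complement(self) -> "ReadRecord":
        quals = None if self.qualities is None else list(self.qualities)[::-1]
        return ReadRecord(self.id, reverse_complement(self.sequence), quals, self.source)


@dataclass(frozen=True)
class FlankPair:
    """The unique ~1-kb sequences immediately up- and downstream of the array."""

    upstream: str
    downstream: str

    def __post_init__(self) -> None:
        if not self.upstream or not self.downstream:
            raise ValueError("both flanks must be nonempty")


def _open_text(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _sniff_format(path: Path) -> str:
    name = path.name[:-3] if path.name.endswith(".gz") else path.name
    suffix = Path(name).suffix.lower()
    if suffix in {".fa", ".fasta", ".fna"}:
        return "fasta"
    if suffix in {".fq", ".fastq"}:
        return "fastq"
    with _open_text(path) as fh:
        first = fh.read(1)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise ValueError(f"cannot determine sequence format of {path}")


def read_sequences(path, format: str = "auto") -> list[ReadRecord]:
    """Parse a FASTA/FASTQ file (gzip transparently) into ReadRecords.

    Sequences are uppercased and U is mapped to T. Order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _sniff_format(path) if format == "auto" else format
    if fmt not in {"fasta", "fastq"}:
        raise ValueError(f"unsupported format {fmt!r}")
    records: list[ReadRecord] = []
    with _open_text(path) as fh:
        try:
            for rec in SeqIO.parse(fh, fmt):
                seq = str(rec.seq).upper().replace("U", "T")
                quals = rec.letter_annotations.get("phred_quality")
                records.append(
                    ReadRecord(rec.id, seq, list(quals) if quals else None, path.name)
                )
        except ValueError as exc:
            raise ValueError(f"malformed {fmt} record in {path}: {exc}") from exc
    if not records:
        warnings.warn(f"{path} contained no sequence records", stacklevel=2)
    return records


def write_sequences(records: Iterable[ReadRecord], path, format: str = "auto") -> None:
    """Write ReadRecords as FASTA or FASTQ (by extension when format='auto')."""
    path = Path(path)
    fmt = _sniff_format_for_write(path) if format == "auto" else format
    seqrecords = []
    for rec in records:
        sr = SeqRecord(Seq(rec.sequence), id=rec.id, description="")
        if fmt == "fastq":
            quals = rec.qualities if rec.qualities is not None else [30] * len(rec.sequence)
            sr.letter_annotations["phred_quality"] = list(quals)
        seqrecords.append(sr)
    with _open_text(path, "wt") as fh:
        SeqIO.write(seqrecords, fh, fmt)


def _sniff_format_for_write(path: Path) -> str:
    name = path.name[:-3] if path.name.endswith(".gz") else path.name
    suffix = Path(name).suffix.lower()
    if suffix in {".fq", ".fastq"}:
        return "fastq"
    return "fasta"


def write_table(rows: Sequence[dict], path, columns: Optional[Sequence[str]] = None) -> None:
    """Write keyed records as a TSV with header.

    All rows must share one key set; column order follows the first row (or the
    explicit ``columns``). Tabs or newlines inside a field are an error — the
    dialect is plain TSV with no escaping.
    """
    path = Path(path)
    rows = list(rows)
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    keyset = set(columns)
    for idx, row in enumerate(rows):
        if set(row.keys()) != keyset:
            rid = row.get("read_id", row.get("id", idx))
            raise ValueError(f"row {rid!r} has keys {sorted(row)} != {sorted(keyset)}")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(columns)
        for idx, row in enumerate(rows):
            values = [_format_cell(row[c], idx) for c in columns]
            writer.writerow(values)


def _format_cell(value, row_idx: int) -> str:
    text = "" if value is None else str(value)
    if "\t" in text or "\n" in text:
        raise ValueError(f"row {row_idx}: field contains a tab/newline: {text!r}")
    return text


def read_table(path) -> list[dict[str, str]]:
    """Read a TSV written by :func:`write_table` back into dicts of strings."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        return [dict(row) for row in reader]
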