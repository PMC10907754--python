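"""FASTQ reading and writing.

Single-end reads only; Sanger Phred+33 qualities; transparent gzip support
based on the ``.gz`` suffix. The reader is a streaming 4-line parser so that
malformed records can be reported with their exact line number, which the
generic FASTQ iterators in Biopython/pysam do not expose.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator


class FastqFormatError(ValueError):
    """Malformed FASTQ record; message includes the offending line number."""


@dataclass(slots=True)
class ReadRecord:
    """One sequencing read: identifier, bases and per-base Phred qualities."""

    read_id: str
    sequence: str
    qualities: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )


def _open_text(path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        if "w" in mode:
            # mtime=0 so identical content gives byte-identical archives
            import io

            gz = gzip.GzipFile(path, "wb", mtime=0)
            return io.TextIOWrapper(gz, encoding="ascii")
        return gzip.open(path, mode + "t")
    return open(path, mode + "t", encoding="ascii")


def read_fastq(path) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a (optionally gzipped) FASTQ file in order."""
    with _open_text(path, "r") as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise FastqFormatError(
                    f"{path}:{lineno}: expected '@' header, got {header[:30]!r}"
                )
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not qual:
                raise FastqFormatError(
                    f"{path}:{lineno}: truncated record for {header[1:].split()[0]!r}"
                )
            lineno += 3
            seq = seq.rstrip("\n")
            qual = qual.rstrip("\n")
            if not plus.startswith("+"):
                raise FastqFormatError(f"{path}:{lineno - 1}: expected '+' separator")
            if len(seq) != len(qual):
                raise FastqFormatError(
                    f"{path}:{lineno}: sequence/quality length mismatch"
                )
            yield ReadRecord(header[1:].split()[0] if header[1:] else "", seq, qual)


def write_fastq(records: Iterable[ReadRecord], path) -> int:
    """Write records as 4-line FASTQ; returns the number of records written."""
    n = 0
    with _open_text(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{rec.qualities}\n")
            n += 1
    return n
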