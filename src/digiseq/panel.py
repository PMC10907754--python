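"""Targeted amplicon panel definitions.

A :class:`Panel` is the unit of targeted analysis: an ordered set of
:class:`Assay` amplicons plus the run-level UMI layout (UMI length, the fixed
anchor sequence between UMI and insert, and the minimum family size required
to call a consensus read).

Panels are stored as a single tab-separated text file with ``#key<TAB>value``
directives for panel-level parameters followed by a header line and one row
per assay with its amplicon sequence inline, e.g.::

    #umi_length	12
    #anchor_seq	ACGCAGTCGT
    #min_reads_per_umi	3
    name	gene	contig	start	end	amplicon_seq
    TP53_A	TP53	chr17	7674180	7674280	ACGT...

Coordinates are 0-based half-open internally (BED convention); human-readable
reports emitted elsewhere use 1-based positions.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

VALID_BASES = frozenset("ACGTN")
DEFAULT_UMI_LENGTH = 12
DEFAULT_ANCHOR = "ACGCAGTCGT"
DEFAULT_MIN_READS_PER_UMI = 3
UMI_LENGTH_RANGE = (6, 16)


class PanelError(ValueError):
    """Raised for invalid panel definitions or configuration files."""


@dataclass(frozen=True)
class Assay:
    """One targeted amplicon: reference insert sequence plus genomic anchor."""

    name: str
    gene: str
    amplicon_seq: str
    contig: str = ""
    start: int = 0
    end: int | None = None
    excluded_positions: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if not self.name:
            raise PanelError("assay name must be non-empty")
        seq = self.amplicon_seq.upper()
        if not seq:
            raise PanelError(f"assay {self.name!r}: amplicon sequence is empty")
        bad = set(seq) - VALID_BASES
        if bad:
            raise PanelError(
                f"assay {self.name!r}: invalid bases {sorted(bad)} in amplicon"
            )
        object.__setattr__(self, "amplicon_seq", seq)
        if self.end is None:
            object.__setattr__(self, "end", self.start + len(seq))
        if self.end <= self.start:
            raise PanelError(f"assay {self.name!r}: end must exceed start")
        excl = frozenset(int(p) for p in self.excluded_positions)
        if any(p < 0 or p >= len(seq) for p in excl):
            raise PanelError(
                f"assay {self.name!r}: excluded positions outside [0, {len(seq)})"
            )
        object.__setattr__(self, "excluded_positions", excl)

    def __len__(self) -> int:
        return len(self.amplicon_seq)

    def with_exclusions(self, offsets: Iterable[int]) -> "Assay":
        """Return a copy with ``offsets`` added to the excluded positions."""
        return replace(
            self, excluded_positions=self.excluded_positions | frozenset(offsets)
        )


@dataclass(frozen=True)
class Panel:
    """Ordered collection of assays plus UMI-layout parameters."""

    assays: tuple[Assay, ...]
    umi_length: int = DEFAULT_UMI_LENGTH
    anchor_seq: str = DEFAULT_ANCHOR
    min_reads_per_umi: int = DEFAULT_MIN_READS_PER_UMI

    def __post_init__(self) -> None:
        object.__setattr__(self, "assays", tuple(self.assays))
        if not self.assays:
            raise PanelError("panel must contain at least one assay")
        names = [a.name for a in self.assays]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise PanelError(f"duplicate assay names: {dupes}")
        lo, hi = UMI_LENGTH_RANGE
        if not lo <= self.umi_length <= hi:
            raise PanelError(
                f"umi_length {self.umi_length} outside supported range {lo}-{hi}"
            )
        anchor = self.anchor_seq.upper()
        if set(anchor) - VALID_BASES:
            raise PanelError("anchor_seq contains invalid characters")
        object.__setattr__(self, "anchor_seq", anchor)
        if self.min_reads_per_umi < 1:
            raise PanelError("min_reads_per_umi must be >= 1")

    @property
    def assay_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.assays)

    def get_assay(self, name: str) -> Assay:
        for a in self.assays:
            if a.name == name:
                return a
        raise KeyError(name)

    def with_exclusions(self, mapping: Mapping[str, Iterable[int]]) -> "Panel":
        """Return a panel whose assays carry the extra excluded offsets."""
        assays = tuple(
            a.with_exclusions(mapping.get(a.name, ())) for a in self.assays
        )
        return replace(self, assays=assays)


def load_panel(path) -> Panel:
    """Parse a panel config file (directives + assay table, see module docs)."""
    directives: dict[str, str] = {}
    rows: list[list[str]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                parts = line[1:].split("\t", 1)
                if len(parts) == 1:
                    parts = line[1:].split(None, 1)
                if len(parts) == 2:
                    directives[parts[0].strip()] = parts[1].strip()
                continue
            rows.append(next(csv.reader([line], delimiter="\t")))
    if not rows:
        raise PanelError(f"{path}: no assay table found")
    header = [h.strip().lower() for h in rows[0]]
    required = {"name", "amplicon_seq"}
    if not required <= set(header):
        raise PanelError(f"{path}: assay table must define columns {sorted(required)}")
    col = {h: i for i, h in enumerate(header)}

    def _get(row: list[str], key: str, default: str = "") -> str:
        i = col.get(key)
        if i is None or i >= len(row):
            return default
        return row[i].strip()

    assays = []
    seen: set[str] = set()
    for row in rows[1:]:
        name = _get(row, "name")
        if name in seen:
            raise PanelError(f"{path}: duplicate assay name {name!r}")
        seen.add(name)
        seq = _get(row, "amplicon_seq")
        if not seq or seq == ".":
            raise PanelError(f"{path}: assay {name!r} has no amplicon sequence")
        end_s = _get(row, "end")
        assays.append(
            Assay(
                name=name,
                gene=_get(row, "gene", name),
                amplicon_seq=seq,
                contig=_get(row, "contig"),
                start=int(_get(row, "start", "0") or 0),
                end=None if end_s in ("", ".") else int(end_s),
            )
        )
    kwargs: dict = {}
    if "umi_length" in directives:
        kwargs["umi_length"] = int(directives["umi_length"])
    if "anchor_seq" in directives:
        kwargs["anchor_seq"] = directives["anchor_seq"]
    if "min_reads_per_umi" in directives:
        kwargs["min_reads_per_umi"] = int(directives["min_reads_per_umi"])
    return Panel(assays=tuple(assays), **kwargs)


def write_panel(panel: Panel, path) -> None:
    """Write ``panel`` in the format accepted by :func:`load_panel`."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"#umi_length\t{panel.umi_length}\n")
        fh.write(f"#anchor_seq\t{panel.anchor_seq}\n")
        fh.write(f"#min_reads_per_umi\t{panel.min_reads_per_umi}\n")
        fh.write("name\tgene\tcontig\tstart\tend\tamplicon_seq\n")
        for a in panel.assays:
            fh.write(
                f"{a.name}\t{a.gene}\t{a.contig}\t{a.start}\t{a.end}\t{a.amplicon_seq}\n"
            )


def load_exclusion_list(path, panel: Panel) -> dict[str, set[int]]:
    """Intersect BED intervals with panel assays, returning amplicon offsets.

    Intervals are 0-based half-open on the assays' genomic contigs. Intervals
    on contigs not used by any assay are skipped with a warning. The result
    maps assay name -> set of excluded amplicon offsets; assays without any
    overlap are absent from the mapping.
    """
    contigs = {a.contig for a in panel.assays if a.contig}
    out: dict[str, set[int]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise PanelError(f"{path}:{lineno}: BED line has <3 columns")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise PanelError(f"{path}:{lineno}: non-integer interval") from exc
            if chrom not in contigs:
                warnings.warn(
                    f"{path}:{lineno}: interval on unknown contig {chrom!r}, skipped",
                    stacklevel=2,
                )
                continue
            for assay in panel.assays:
                if assay.contig != chrom:
                    continue
                lo = max(start, assay.start)
                hi = min(end, assay.end)
                if lo < hi:
                    offs = out.setdefault(assay.name, set())
                    offs.update(range(lo - assay.start, hi - assay.start))
    return out
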