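"""Per-position base/indel count matrices against an amplicon reference.

A :class:`CountMatrix` holds, for one assay and one read level (raw or
consensus), the number of A/C/G/T/N/deletion observations at every amplicon
position plus insertion events anchored to their left-flanking position.
Coverage is defined as the row sum of the six aligned-symbol columns, so the
conservation invariant A+C+G+T+N+del == coverage holds by construction.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

BASE_COLUMNS = ("A", "C", "G", "T", "N", "del")
#: symbol for a reference position excluded from a read's contribution
#: (ambiguous consensus position or end gap); never counted.
SKIP = "."

_SYMBOLS = "ACGTN-"
# byte -> column lookup; 6 = skip
_LUT = np.full(256, 6, dtype=np.uint8)
for _i, _c in enumerate(_SYMBOLS):
    _LUT[ord(_c)] = _i
_COL_OF = {c: i for i, c in enumerate(_SYMBOLS)}

RAW = "raw"
CONSENSUS = "consensus"


class CountMatrix:
    """Base/indel counts per amplicon position for one assay and read level."""

    def __init__(self, assay_name: str, ref_seq: str, level: str):
        if level not in (RAW, CONSENSUS):
            raise ValueError(f"level must be {RAW!r} or {CONSENSUS!r}")
        self.assay_name = assay_name
        self.ref_seq = ref_seq.upper()
        self.level = level
        L = len(self.ref_seq)
        self.counts = np.zeros((L, 6), dtype=np.int64)
        self.insertions = np.zeros(L, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.ref_seq)

    @property
    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def ref_counts(self) -> np.ndarray:
        """Count of reference-matching bases per position."""
        idx = _LUT[np.frombuffer(self.ref_seq.encode(), dtype=np.uint8)]
        return self.counts[np.arange(len(self)), idx]

    # -- accumulation ----------------------------------------------------

    def add_sequences(self, seqs: Sequence[str], chunk: int = 50_000) -> None:
        """Bulk-count full-length aligned symbol strings.

        Each string must have length == len(reference) over the alphabet
        ``ACGTN-`` plus ``.`` for positions the read does not contribute to.
        """
        L = len(self)
        n = len(seqs)
        for lo in range(0, n, chunk):
            part = seqs[lo : lo + chunk]
            arr = np.frombuffer("".join(part).encode(), dtype=np.uint8)
            if arr.size != len(part) * L:
                raise ValueError("aligned sequence with wrong length")
            cols = _LUT[arr].astype(np.intp)
            pos = np.tile(np.arange(L, dtype=np.intp), len(part))
            flat = pos * 7 + cols
            bc = np.bincount(flat, minlength=L * 7).reshape(L, 7)
            self.counts += bc[:, :6]

    def add_symbols(self, symbols: Iterable[tuple[int, str]]) -> None:
        """Add individual (position, symbol) observations (slow path)."""
        for pos, sym in symbols:
            if sym == SKIP:
                continue
            self.counts[pos, _COL_OF[sym]] += 1

    def add_insertion(self, pos: int, n: int = 1) -> None:
        self.insertions[pos] += n

    # -- IO ---------------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        """1-based tabular view with deterministic column order."""
        df = pd.DataFrame(
            {
                "assay": self.assay_name,
                "level": self.level,
                "pos": np.arange(1, len(self) + 1),
                "ref": list(self.ref_seq),
            }
        )
        for i, c in enumerate(BASE_COLUMNS):
            df[c] = self.counts[:, i]
        df["ins"] = self.insertions
        df["coverage"] = self.coverage
        return df


def write_count_matrix(matrix: CountMatrix, path) -> None:
    """Write one matrix as TSV (1-based positions, fixed column order)."""
    matrix.to_dataframe().to_csv(path, sep="\t", index=False)


def read_count_matrix(path) -> CountMatrix:
    """Read a TSV written by :func:`write_count_matrix`."""
    df = pd.read_csv(path, sep="\t", dtype={"ref": str})
    assays = df["assay"].unique()
    levels = df["level"].unique()
    if len(assays) != 1 or len(levels) != 1:
        raise ValueError(f"{path}: expected a single assay/level per file")
    ref = "".join(df["ref"])
    m = CountMatrix(str(assays[0]), ref, str(levels[0]))
    for i, c in enumerate(BASE_COLUMNS):
        m.counts[:, i] = df[c].to_numpy()
    m.insertions[:] = df["ins"].to_numpy()
    cov = df["coverage"].to_numpy()
    if not np.array_equal(cov, m.coverage):
        raise ValueError(f"{path}: coverage column inconsistent with base counts")
    return m
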