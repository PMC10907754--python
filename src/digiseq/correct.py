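"""UMI consensus error correction.

Pipeline: UMI/anchor extraction -> assay assignment -> amplicon alignment ->
UMI family grouping with directional clustering -> plurality consensus with a
minimum family size -> raw and consensus pileup matrices.

Alignment policy: inserts identical to an amplicon are assigned directly;
otherwise candidate assays are screened with edlib edit distance (identity
cutoff 0.8) and the winning assay's alignment is computed either as a direct
per-position substitution overlay (equal length, few mismatches — the normal
case for fixed-length amplicon reads) or by affine-gap semiglobal dynamic
programming with free end gaps on the insert (Bio.Align).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import edlib
import numpy as np
from Bio import Align

from .panel import Assay, Panel
from .pileup import CONSENSUS, RAW, SKIP, CountMatrix
from .seqio import ReadRecord, read_fastq

DEFAULT_MIN_IDENTITY = 0.8
DEFAULT_CONSENSUS_FRACTION = 0.6
DEFAULT_CLUSTER_DISTANCE = 1
# fast-path threshold: equal-length inserts with at most this fraction of
# mismatches are treated as pure substitution alignments without DP
MAX_SUBSTITUTION_FRACTION = 0.1

_DOT = ord(SKIP)


class UmiExtraction(NamedTuple):
    """Result of UMI/anchor trimming; ``reject_reason`` is None on success."""

    umi: str | None
    insert: str | None
    reject_reason: str | None


def extract_umi(read: ReadRecord, panel: Panel) -> UmiExtraction:
    """Split a read into (UMI, insert), verifying the anchor with <=1 mismatch."""
    seq = read.sequence
    plen = panel.umi_length + len(panel.anchor_seq)
    if len(seq) <= plen:
        return UmiExtraction(None, None, "too_short")
    anchor = seq[panel.umi_length : plen]
    if anchor != panel.anchor_seq:
        mm = sum(a != b for a, b in zip(anchor, panel.anchor_seq))
        if mm > 1:
            return UmiExtraction(None, None, "anchor_mismatch")
    return UmiExtraction(seq[: panel.umi_length], seq[plen:], None)


# ---------------------------------------------------------------------------
# alignment


@dataclass(frozen=True)
class AmpliconAlignment:
    """Per-reference-position encoding of an aligned insert.

    ``symbols`` has one character per amplicon position: the aligned base
    (ACGTN), ``-`` for a deletion, or ``.`` where the insert does not cover
    the position (free end gaps). Insertions are anchored to the offset of
    their left-flanking reference base.
    """

    symbols: str
    insertions: tuple[tuple[int, str], ...] = ()
    score: float | None = None


_ALIGNER: Align.PairwiseAligner | None = None


def _aligner() -> Align.PairwiseAligner:
    global _ALIGNER
    if _ALIGNER is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = 2
        a.mismatch_score = -4
        a.open_gap_score = -6
        a.extend_gap_score = -1
        # free end gaps on the insert: amplicon overhang is unpenalized
        a.end_deletion_score = 0.0
        _ALIGNER = a
    return _ALIGNER


def _dp_align(insert: str, amplicon: str) -> AmpliconAlignment:
    aln = _aligner().align(amplicon, insert)[0]
    L = len(amplicon)
    symbols = [SKIP] * L
    insertions: list[tuple[int, str]] = []
    tgt_blocks, qry_blocks = aln.aligned
    prev_te = prev_qe = None
    for (ts, te), (qs, qe) in zip(tgt_blocks, qry_blocks):
        if prev_te is None and qs > 0:
            insertions.append((int(max(ts - 1, 0)), insert[:qs]))
        if prev_te is not None:
            gap_t = ts - prev_te
            gap_q = qs - prev_qe
            if gap_t:
                for p in range(prev_te, ts):
                    symbols[p] = "-"
            if gap_q:
                insertions.append((int(max(prev_te - 1, 0)), insert[prev_qe:qs]))
        symbols[int(ts):int(te)] = insert[int(qs):int(qe)]
        prev_te, prev_qe = te, qe
    if prev_qe is not None and prev_qe < len(insert):
        insertions.append((int(max((prev_te or 1) - 1, 0)), insert[prev_qe:]))
    return AmpliconAlignment("".join(symbols), tuple(insertions), float(aln.score))


def align_to_amplicon(
    insert: str, assay: Assay, force_dp: bool = False
) -> AmpliconAlignment:
    """Align an insert to its assay amplicon (semiglobal, affine gaps).

    Equal-length inserts with at most ``MAX_SUBSTITUTION_FRACTION`` mismatches
    take a substitution-only fast path equivalent to the DP result for
    isolated sequencing/PCR substitutions.
    """
    amp = assay.amplicon_seq
    if not force_dp and len(insert) == len(amp):
        mm = sum(a != b for a, b in zip(insert, amp))
        if mm <= max(2, int(MAX_SUBSTITUTION_FRACTION * len(amp))):
            return AmpliconAlignment(insert)
    return _dp_align(insert, amp)


def assign_assay(
    insert: str, panel: Panel, min_identity: float = DEFAULT_MIN_IDENTITY
) -> Assay | None:
    """Best-matching assay by semiglobal edit distance, or None.

    Assignment requires identity >= ``min_identity`` over the insert length;
    ties go to the earlier assay in panel order.
    """
    if not insert:
        return None
    best: Assay | None = None
    best_id = -1.0
    for assay in panel.assays:
        if insert == assay.amplicon_seq:
            return assay
        res = edlib.align(insert, assay.amplicon_seq, mode="HW", task="distance")
        ident = 1.0 - res["editDistance"] / len(insert)
        if ident > best_id:
            best_id = ident
            best = assay
    if best is not None and best_id >= min_identity:
        return best
    return None


# ---------------------------------------------------------------------------
# UMI families


class AssignedRead(NamedTuple):
    read_id: str
    assay: str
    umi: str
    insert: str


@dataclass
class UMIFamily:
    """Raw reads sharing one (error-merged) UMI within one assay."""

    assay: str
    umi: str
    read_ids: list[str] = field(default_factory=list)
    inserts: list[str] = field(default_factory=list)
    #: aligned representation of each member (filled by the pipeline)
    alignments: list[AmpliconAlignment] | None = None

    @property
    def size(self) -> int:
        return len(self.read_ids)


def _umi_neighbors(umi: str) -> Iterable[str]:
    for i, c in enumerate(umi):
        for b in "ACGT":
            if b != c:
                yield umi[:i] + b + umi[i + 1 :]


def group_and_cluster_umis(
    reads: Iterable[AssignedRead],
    panel: Panel,
    cluster_distance: int = DEFAULT_CLUSTER_DISTANCE,
) -> list[UMIFamily]:
    """Exact UMI grouping followed by directional error merging.

    Within each assay, a family B is absorbed into a larger family A when
    edit_distance(UMI_A, UMI_B) <= cluster_distance (for the fixed-length
    UMIs extracted here that is a single substitution) and
    count_A >= 2*count_B - 1; merging proceeds in descending count order and
    is transitive, as in standard directional UMI deduplication. Set
    ``cluster_distance=0`` for exact-match grouping.
    """
    by_assay: dict[str, dict[str, list[AssignedRead]]] = {}
    order: list[str] = []
    for rec in reads:
        if rec.assay not in by_assay:
            order.append(rec.assay)
        by_assay.setdefault(rec.assay, {}).setdefault(rec.umi, []).append(rec)
    families: list[UMIFamily] = []
    for assay in order:
        groups = by_assay[assay]
        counts = {u: len(g) for u, g in groups.items()}
        keys = sorted(counts, key=lambda u: (-counts[u], u))
        if cluster_distance <= 0:
            merged_into = {u: u for u in keys}
        else:
            merged_into: dict[str, str] = {}
            for seed in keys:
                if seed in merged_into:
                    continue
                merged_into[seed] = seed
                queue = [seed]
                while queue:
                    parent = queue.pop(0)
                    for nb in _umi_neighbors(parent):
                        if nb in counts and nb not in merged_into:
                            if counts[parent] >= 2 * counts[nb] - 1:
                                merged_into[nb] = seed
                                queue.append(nb)
        # descending-count order puts each cluster's seed before its members
        members_of: dict[str, list[str]] = {}
        for u in keys:
            members_of.setdefault(merged_into[u], []).append(u)
        for seed in keys:
            members = members_of.get(seed)
            if members is None:
                continue
            fam = UMIFamily(assay=assay, umi=seed)
            for u in members:
                for rec in groups[u]:
                    fam.read_ids.append(rec.read_id)
                    fam.inserts.append(rec.insert)
            families.append(fam)
    return families


# ---------------------------------------------------------------------------
# consensus


@dataclass
class ConsensusRead:
    """Per-position plurality sequence of one UMI family.

    ``sequence`` has one symbol per amplicon position (ACGTN, ``-`` deletion,
    ``.`` for ambiguous or uncovered positions, which contribute nothing to
    the consensus pileup).
    """

    assay: str
    umi: str
    sequence: str
    family_size: int
    ambiguous_positions: frozenset[int] = frozenset()
    insertions: tuple[tuple[int, str], ...] = ()


def call_consensus(
    family: UMIFamily,
    panel: Panel,
    min_reads: int | None = None,
    min_fraction: float = DEFAULT_CONSENSUS_FRACTION,
) -> ConsensusRead | None:
    """Plurality consensus of a family, or None below the size cutoff.

    At each reference position the plurality symbol among covering members is
    taken; positions whose plurality support is below ``min_fraction`` are
    marked ambiguous and excluded. Insertions are emitted only with the same
    support fraction (relative to family size).
    """
    min_reads = panel.min_reads_per_umi if min_reads is None else min_reads
    if family.size < min_reads:
        return None
    aligns = family.alignments
    if aligns is None:
        assay = panel.get_assay(family.assay)
        aligns = [align_to_amplicon(ins, assay) for ins in family.inserts]
    sym0 = aligns[0].symbols
    if all(a.symbols == sym0 and not a.insertions for a in aligns):
        return ConsensusRead(family.assay, family.umi, sym0, family.size)
    L = len(sym0)
    arr = np.frombuffer("".join(a.symbols for a in aligns).encode(), np.uint8)
    arr = arr.reshape(len(aligns), L)
    cons = bytearray(arr[0].tobytes())
    ambiguous: set[int] = set()
    diff = np.nonzero((arr != arr[0]).any(axis=0))[0]
    for c in diff:
        col = arr[:, c]
        votes = Counter(int(v) for v in col if v != _DOT)
        cover = sum(votes.values())
        if cover == 0:
            cons[c] = _DOT
            continue
        top_sym, top_n = min(votes.items(), key=lambda kv: (-kv[1], kv[0]))
        if top_n / cover >= min_fraction:
            cons[c] = top_sym
        else:
            cons[c] = _DOT
            ambiguous.add(int(c))
    ins_votes: Counter = Counter()
    for a in aligns:
        for pos, seq in a.insertions:
            ins_votes[(pos, seq)] += 1
    insertions = tuple(
        sorted(k for k, n in ins_votes.items() if n / family.size >= min_fraction)
    )
    return ConsensusRead(
        family.assay,
        family.umi,
        cons.decode(),
        family.size,
        frozenset(ambiguous),
        insertions,
    )


# ---------------------------------------------------------------------------
# pileups and composition


@dataclass
class PileupPair:
    """Raw and consensus count matrices for the same assay."""

    raw: CountMatrix
    consensus: CountMatrix

    def check_invariants(self) -> None:
        if np.any(self.consensus.coverage > self.raw.coverage):
            raise AssertionError("consensus coverage exceeds raw coverage")


def build_pileups(
    raw_alignments: Mapping[str, Sequence[AmpliconAlignment]],
    consensus_reads: Mapping[str, Sequence[ConsensusRead]],
    panel: Panel,
) -> dict[str, PileupPair]:
    """Accumulate per-position counts for raw and consensus reads."""
    pairs: dict[str, PileupPair] = {}
    for assay in panel.assays:
        raw_m = CountMatrix(assay.name, assay.amplicon_seq, RAW)
        cons_m = CountMatrix(assay.name, assay.amplicon_seq, CONSENSUS)
        raws = raw_alignments.get(assay.name, ())
        raw_m.add_sequences([a.symbols for a in raws])
        for a in raws:
            for pos, _seq in a.insertions:
                raw_m.add_insertion(pos)
        cons = consensus_reads.get(assay.name, ())
        cons_m.add_sequences([c.sequence for c in cons])
        for c in cons:
            for pos, _seq in c.insertions:
                cons_m.add_insertion(pos)
        pairs[assay.name] = PileupPair(raw_m, cons_m)
    return pairs


@dataclass
class PipelineResult:
    pileups: dict[str, PileupPair]
    families: list[UMIFamily]
    consensus: dict[str, list[ConsensusRead]]
    report: dict

    def consensus_count(self, assay: str) -> int:
        return len(self.consensus.get(assay, []))


def run_pipeline(
    source,
    panel: Panel,
    min_reads: int | None = None,
    consensus_fraction: float = DEFAULT_CONSENSUS_FRACTION,
    cluster_distance: int = DEFAULT_CLUSTER_DISTANCE,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> PipelineResult:
    """Run the full error-correction pipeline on a FASTQ path or records.

    Deterministic for a fixed input. The run report satisfies read
    conservation: reads_in == rejected + unassigned + sum(family sizes).
    """
    if isinstance(source, (str, Path)):
        source = read_fastq(source)
    min_reads = panel.min_reads_per_umi if min_reads is None else min_reads
    umi_len = panel.umi_length
    anchor = panel.anchor_seq
    plen = umi_len + len(anchor)
    exact: dict[str, str] = {}
    for a in panel.assays:
        exact.setdefault(a.amplicon_seq, a.name)
    assign_cache: dict[str, str | None] = {}
    reads_in = 0
    rejected: Counter = Counter()
    unassigned = 0
    assigned: list[AssignedRead] = []
    for rec in source:
        reads_in += 1
        seq = rec.sequence
        if len(seq) <= plen:
            rejected["too_short"] += 1
            continue
        anc = seq[umi_len:plen]
        if anc != anchor:
            mm = sum(a != b for a, b in zip(anc, anchor))
            if mm > 1:
                rejected["anchor_mismatch"] += 1
                continue
        insert = seq[plen:]
        name = exact.get(insert)
        if name is None:
            if insert in assign_cache:
                name = assign_cache[insert]
            else:
                hit = assign_assay(insert, panel, min_identity)
                name = hit.name if hit is not None else None
                assign_cache[insert] = name
            if name is None:
                unassigned += 1
                continue
        assigned.append(AssignedRead(rec.read_id, name, seq[:umi_len], insert))

    families = group_and_cluster_umis(assigned, panel, cluster_distance)

    align_cache: dict[str, dict[str, AmpliconAlignment]] = {
        a.name: {} for a in panel.assays
    }
    assay_by_name = {a.name: a for a in panel.assays}

    def _aligned(assay: str, insert: str) -> AmpliconAlignment:
        cache = align_cache[assay]
        hit = cache.get(insert)
        if hit is None:
            hit = align_to_amplicon(insert, assay_by_name[assay])
            cache[insert] = hit
        return hit

    consensus: dict[str, list[ConsensusRead]] = {a.name: [] for a in panel.assays}
    n_pass = 0
    for fam in families:
        fam.alignments = [_aligned(fam.assay, ins) for ins in fam.inserts]
        cons = call_consensus(fam, panel, min_reads, consensus_fraction)
        if cons is not None:
            consensus[fam.assay].append(cons)
            n_pass += 1

    raw_aln: dict[str, list[AmpliconAlignment]] = {a.name: [] for a in panel.assays}
    for rec in assigned:
        raw_aln[rec.assay].append(_aligned(rec.assay, rec.insert))
    pileups = build_pileups(raw_aln, consensus, panel)
    for pair in pileups.values():
        pair.check_invariants()

    report = {
        "reads_in": reads_in,
        "rejected": dict(rejected),
        "rejected_total": sum(rejected.values()),
        "unassigned": unassigned,
        "assigned": len(assigned),
        "reads_in_families": sum(f.size for f in families),
        "n_families": len(families),
        "n_consensus_reads": n_pass,
        "consensus_per_assay": {a: len(c) for a, c in consensus.items()},
        "params": {
            "min_reads_per_umi": min_reads,
            "consensus_fraction": consensus_fraction,
            "umi_cluster_distance": cluster_distance,
            "min_identity": min_identity,
        },
    }
    return PipelineResult(pileups, families, consensus, report)
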