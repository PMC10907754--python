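"""Generative simulator of a UMI-barcoded amplicon sequencing library.

The simulated process mirrors a two-PCR digital sequencing protocol:

1. Template molecules per assay (single-stranded cDNA or double-stranded
   genomic DNA), optionally carrying spike-in variants at known fractions.
2. Reverse transcription for RNA input: molecule loss (``rt_efficiency``)
   and substitution errors (``rt_error_rate``) that *precede* UMI tagging
   and are therefore not correctable by consensus.
3. Barcoding PCR (default 3 cycles): explicit per-cycle strand bookkeeping.
   Each new strand primed by the UMI-bearing primer receives a fresh random
   UMI; strands that already carry a UMI are amplified without re-tagging.
   At copy efficiency 1.0 this yields exactly 3 UMI-tagged lineages per
   single-stranded molecule and 6 per double-stranded molecule.
4. Binomial dilution (default 1/3) of UMI lineages into the adapter PCR, so
   on average 1 (ss) or 2 (ds) lineages per input molecule are sequenced.
5. Adapter PCR + sequencing: the first ``jackpot_cycles`` cycles are an
   explicit doubling tree (shared early polymerase errors that can survive
   consensus); later cycles contribute independent per-read residual
   polymerase errors; sequencing adds per-base substitution errors. Reads
   per UMI family are Poisson distributed.

Every emitted read is ``UMI + anchor + insert`` with a constant Phred
quality. A :class:`SimTruth` object records the ground truth needed to
score recovery of every downstream statistic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .panel import DEFAULT_ANCHOR, Assay, Panel
from .seqio import ReadRecord, write_fastq

SINGLE = "single"
DOUBLE = "double"

_BASES = "ACGT"
# for each current base, the three possible substitution targets
_OTHERS = {b: "".join(c for c in _BASES if c != b) for b in _BASES}
_OTHERS_BY_BYTE = {ord(b): _OTHERS[b].encode() for b in _BASES}


@dataclass(frozen=True)
class VariantSpec:
    """A spike-in substitution: assay, amplicon offset, alt base, fraction."""

    assay: str
    position: int
    alt: str
    fraction: float


@dataclass
class SimConfig:
    """All tunable parameters of one simulated library.

    Defaults follow the protocol being emulated: 3 barcoding cycles, 1/3
    dilution into a 30-cycle adapter PCR, a high-fidelity polymerase at
    3e-7 substitutions/base/synthesis, and reverse transcriptase fidelity
    of order 1e-4. The sequencing substitution rate (2e-3/base) is a free
    instrument parameter, not a protocol constant.
    """

    seed: int = 0
    n_molecules: int = 1000
    strandedness: str = SINGLE
    variants: tuple[VariantSpec, ...] = ()
    rt_error_rate: float = 1e-4
    rt_efficiency: float = 1.0
    barcode_cycles: int = 3
    barcode_efficiency: float = 1.0
    pol_error_rate: float = 3e-7
    dilution_fraction: float = 1.0 / 3.0
    adapter_cycles: int = 30
    jackpot_cycles: int = 3
    mean_reads_per_family: float = 6.0
    seq_error_rate: float = 2e-3
    read_indel_rate: float = 0.0
    phred_quality: int = 30

    def __post_init__(self) -> None:
        self.variants = tuple(
            v if isinstance(v, VariantSpec) else VariantSpec(**v) for v in self.variants
        )
        self.validate()

    def validate(self) -> None:
        if self.strandedness not in (SINGLE, DOUBLE):
            raise ValueError(f"strandedness must be {SINGLE!r} or {DOUBLE!r}")
        for name in (
            "rt_error_rate",
            "rt_efficiency",
            "barcode_efficiency",
            "pol_error_rate",
            "dilution_fraction",
            "seq_error_rate",
            "read_indel_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("barcode_cycles", "adapter_cycles", "jackpot_cycles"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.jackpot_cycles > self.adapter_cycles:
            raise ValueError("jackpot_cycles cannot exceed adapter_cycles")
        if self.n_molecules < 0:
            raise ValueError("n_molecules must be >= 0")
        if self.mean_reads_per_family < 0:
            raise ValueError("mean_reads_per_family must be >= 0")
        for v in self.variants:
            if not 0.0 <= v.fraction <= 1.0:
                raise ValueError(f"variant fraction {v.fraction} outside [0, 1]")
            if v.alt not in _BASES:
                raise ValueError(f"variant alt must be one of {_BASES}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["variants"] = [asdict(v) for v in self.variants]
        return d

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "SimConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        kwargs = dict(mapping)
        if "variants" in kwargs:
            kwargs["variants"] = tuple(
                VariantSpec(**v) if isinstance(v, Mapping) else v
                for v in kwargs["variants"]
            )
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_mapping(data)


# ---------------------------------------------------------------------------
# molecule containers


@dataclass
class AssayMolecules:
    """Template molecules of one assay, as sparse deltas vs the reference."""

    assay: str
    n: int
    strandedness: str
    # molecule index -> ((pos, alt), ...); molecules not present are reference
    deltas: dict[int, tuple] = field(default_factory=dict)
    # realized spike-ins: dicts with position/alt/n_molecules/realized_fraction
    variants: list[dict] = field(default_factory=list)
    rt_errors: list[tuple[int, int, str]] = field(default_factory=list)

    def sequence(self, reference: str, index: int) -> str:
        delta = self.deltas.get(index, ())
        if not delta:
            return reference
        ba = bytearray(reference.encode())
        for pos, alt in delta:
            ba[pos] = ord(alt)
        return ba.decode()


@dataclass
class MoleculeSet:
    """Per-assay template molecules; the simulator's ground-truth state."""

    assays: dict[str, AssayMolecules]

    def __iter__(self):
        return iter(self.assays.values())


@dataclass(frozen=True)
class BarcodedProduct:
    """One UMI-tagged strand lineage leaving the barcoding PCR."""

    assay: str
    origin: int
    umi: int
    depth: int  # barcoding cycle at which the UMI was assigned
    delta: tuple  # accumulated substitutions vs reference, incl. the template's


class BarcodedPool:
    """Array-backed collection of BarcodedProducts for one assay."""

    def __init__(
        self,
        assay: str,
        n_origins: int,
        origin: np.ndarray,
        umi: np.ndarray,
        depth: np.ndarray,
        deltas: dict[int, tuple],
    ):
        self.assay = assay
        self.n_origins = n_origins
        self.origin = origin
        self.umi = umi
        self.depth = depth
        self.deltas = deltas  # lineage index -> delta tuple (sparse)

    def __len__(self) -> int:
        return len(self.origin)

    def product(self, i: int) -> BarcodedProduct:
        return BarcodedProduct(
            self.assay,
            int(self.origin[i]),
            int(self.umi[i]),
            int(self.depth[i]),
            self.deltas.get(i, ()),
        )

    def umis_per_origin(self) -> np.ndarray:
        return np.bincount(self.origin, minlength=self.n_origins)

    def distinct_umis_per_origin(self) -> np.ndarray:
        if len(self) == 0:
            return np.zeros(self.n_origins, dtype=np.int64)
        key = self.origin.astype(np.int64) * (1 << 34) + self.umi
        uniq = np.unique(key)
        return np.bincount((uniq >> 34).astype(np.intp), minlength=self.n_origins)

    def subset(self, mask: np.ndarray) -> "BarcodedPool":
        idx = np.nonzero(mask)[0]
        remap = {int(old): new for new, old in enumerate(idx)}
        deltas = {
            remap[k]: v for k, v in self.deltas.items() if k in remap
        }
        return BarcodedPool(
            self.assay,
            self.n_origins,
            self.origin[idx],
            self.umi[idx],
            self.depth[idx],
            deltas,
        )


# ---------------------------------------------------------------------------
# truth


@dataclass
class SimTruth:
    """Ground truth of one simulated run, sufficient to score recovery."""

    config: dict
    umi_length: int
    anchor_seq: str
    assays: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def _clean(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            return obj

        return {
            "config": _clean(self.config),
            "umi_length": self.umi_length,
            "anchor_seq": self.anchor_seq,
            "assays": _clean(self.assays),
        }

    def to_json(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)


# ---------------------------------------------------------------------------
# stage 1: templates


def make_molecules(
    config: SimConfig, panel: Panel, rng: np.random.Generator | None = None
) -> MoleculeSet:
    """Create ``n_molecules`` template molecules per assay with spike-ins.

    Mutant molecules per variant are a binomial draw Binomial(n, fraction);
    variants at the same position are assigned to disjoint molecules, so
    per-position fractions must sum to <= 1.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    rngs = rng.spawn(len(panel.assays))
    by_assay: dict[str, list[VariantSpec]] = {}
    for v in config.variants:
        if v.assay not in panel.assay_names:
            raise ValueError(f"variant references unknown assay {v.assay!r}")
        by_assay.setdefault(v.assay, []).append(v)
    out: dict[str, AssayMolecules] = {}
    for assay, r in zip(panel.assays, rngs):
        n = config.n_molecules
        mols = AssayMolecules(assay.name, n, config.strandedness)
        per_pos: dict[int, float] = {}
        taken: dict[int, set[int]] = {}
        for v in by_assay.get(assay.name, []):
            if not 0 <= v.position < len(assay):
                raise ValueError(
                    f"variant offset {v.position} outside amplicon {assay.name!r}"
                )
            if assay.amplicon_seq[v.position] == v.alt:
                raise ValueError(
                    f"variant alt {v.alt!r} equals the reference base at "
                    f"{assay.name}:{v.position}"
                )
            per_pos[v.position] = per_pos.get(v.position, 0.0) + v.fraction
            if per_pos[v.position] > 1.0 + 1e-9:
                raise ValueError(
                    f"variant fractions at {assay.name}:{v.position} sum to > 1"
                )
            k = int(r.binomial(n, v.fraction)) if n else 0
            used = taken.setdefault(v.position, set())
            pool = np.setdiff1d(
                np.arange(n), np.fromiter(used, dtype=np.int64, count=len(used)),
                assume_unique=True,
            )
            chosen = r.choice(pool, size=min(k, len(pool)), replace=False)
            for i in chosen:
                i = int(i)
                used.add(i)
                mols.deltas[i] = mols.deltas.get(i, ()) + ((v.position, v.alt),)
            mols.variants.append(
                {
                    "position": v.position,
                    "alt": v.alt,
                    "fraction": v.fraction,
                    "n_molecules": int(len(chosen)),
                    "realized_fraction": len(chosen) / n if n else 0.0,
                }
            )
        out[assay.name] = mols
    return MoleculeSet(out)


# ---------------------------------------------------------------------------
# stage 2: reverse transcription


def reverse_transcribe(
    molecules: MoleculeSet,
    config: SimConfig,
    panel: Panel,
    rng: np.random.Generator | None = None,
) -> MoleculeSet:
    """Convert RNA templates to cDNA: molecule loss plus RT substitutions.

    A no-op for double-stranded input. RT errors occur once per molecule
    lineage (before UMI tagging) and are recorded as UMI-uncorrectable.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    rngs = rng.spawn(len(panel.assays))
    out: dict[str, AssayMolecules] = {}
    for assay, r in zip(panel.assays, rngs):
        mols = molecules.assays[assay.name]
        if mols.strandedness == DOUBLE:
            out[assay.name] = mols
            continue
        L = len(assay)
        n = mols.n
        if config.rt_efficiency >= 1.0:
            kept = np.arange(n)
        else:
            kept = np.nonzero(r.random(n) < config.rt_efficiency)[0]
        m = len(kept)
        new = AssayMolecules(assay.name, m, SINGLE)
        remap = {int(old): i for i, old in enumerate(kept)}
        for old, delta in mols.deltas.items():
            if old in remap:
                new.deltas[remap[old]] = delta
        # recompute realized variant counts among retained molecules
        for v in mols.variants:
            count = sum(
                1
                for d in new.deltas.values()
                if (v["position"], v["alt"]) in d
            )
            nv = dict(v)
            nv["n_molecules"] = count
            nv["realized_fraction"] = count / m if m else 0.0
            new.variants.append(nv)
        if config.rt_error_rate > 0.0 and m:
            n_err = r.binomial(m * L, config.rt_error_rate)
            flat = r.integers(0, m * L, size=n_err)
            for f in flat:
                mol, pos = int(f) // L, int(f) % L
                cur_delta = new.deltas.get(mol, ())
                cur = next(
                    (b for p, b in reversed(cur_delta) if p == pos),
                    assay.amplicon_seq[pos],
                )
                alt = _OTHERS.get(cur, _BASES)[int(r.integers(3))]
                new.deltas[mol] = cur_delta + ((pos, alt),)
                new.rt_errors.append((mol, pos, alt))
        out[assay.name] = new
    return MoleculeSet(out)


# ---------------------------------------------------------------------------
# stage 3: barcoding PCR


def _ds_depth_pattern(cycles: int) -> list[int]:
    # antisense original gets a UMI every cycle; each rp-copy of the sense
    # original (made at cycle c) is itself UMI-tagged in every later cycle
    depths = list(range(1, cycles + 1))
    for c1 in range(1, cycles + 1):
        depths.extend(range(c1 + 1, cycles + 1))
    return sorted(depths)


def _branch_molecule(
    base_delta: tuple,
    single_stranded: bool,
    cycles: int,
    eff: float,
    p_syn: float,
    err_positions: dict[int, list[int]],
    umi_iter,
    r: np.random.Generator,
    ref: str,
) -> list[tuple[int, int, tuple]]:
    """Explicit strand-by-strand branching for one molecule.

    Returns (umi, depth, delta) per UMI-assignment event. ``err_positions``
    maps local synthesis index -> error base positions (pre-sampled); if
    None, errors are sampled per synthesis with probability ``p_syn``.
    """
    # strand = (is_fp_template, umi or -1, delta)
    strands: list[tuple[bool, int, tuple]] = [(True, -1, base_delta)]
    if not single_stranded:
        strands.append((False, -1, base_delta))
    products: list[tuple[int, int, tuple]] = []
    synth = 0
    for cycle in range(1, cycles + 1):
        new: list[tuple[bool, int, tuple]] = []
        for fp, umi, delta in strands:
            if eff < 1.0 and r.random() >= eff:
                continue
            child_delta = delta
            if err_positions is not None:
                for pos in err_positions.get(synth, ()):
                    cur = next(
                        (b for p, b in reversed(child_delta) if p == pos), ref[pos]
                    )
                    alt = _OTHERS.get(cur, _BASES)[int(r.integers(3))]
                    child_delta = child_delta + ((pos, alt),)
            elif p_syn > 0.0 and r.random() < p_syn:
                pos = int(r.integers(len(ref)))
                cur = next(
                    (b for p, b in reversed(child_delta) if p == pos), ref[pos]
                )
                alt = _OTHERS.get(cur, _BASES)[int(r.integers(3))]
                child_delta = child_delta + ((pos, alt),)
            synth += 1
            if fp:
                if umi < 0:
                    u = int(next(umi_iter))
                    products.append((u, cycle, child_delta))
                    new.append((False, u, child_delta))
                else:
                    new.append((False, umi, child_delta))
            else:
                new.append((True, umi, child_delta))
        strands.extend(new)
    return products


def barcode_pcr(
    molecules: MoleculeSet,
    panel: Panel,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, BarcodedPool]:
    """Tag template molecules with UMIs over ``barcode_cycles`` PCR cycles.

    At ``barcode_efficiency`` 1.0 the lineage count per molecule is exact:
    3 for single-stranded and 6 for double-stranded templates (3 cycles).
    UMIs are drawn uniformly over 4**umi_length; collisions between origins
    are permitted and recorded in the truth.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    rngs = rng.spawn(len(panel.assays))
    umi_space = 4 ** panel.umi_length
    C = config.barcode_cycles
    eff = config.barcode_efficiency
    pools: dict[str, BarcodedPool] = {}
    for assay, r in zip(panel.assays, rngs):
        mols = molecules.assays[assay.name]
        n, L = mols.n, len(assay)
        single = mols.strandedness == SINGLE
        p_syn = 1.0 - (1.0 - config.pol_error_rate) ** L
        if eff >= 1.0:
            pattern = list(range(1, C + 1)) if single else _ds_depth_pattern(C)
            k = len(pattern)
            spm = (2 ** C - 1) * (1 if single else 2)  # syntheses per molecule
            umis = r.integers(0, umi_space, size=n * k, dtype=np.int64)
            # pre-sample polymerase error bases over all synthesis events
            err_by_mol: dict[int, dict[int, list[int]]] = {}
            if config.pol_error_rate > 0.0 and n:
                n_err = r.binomial(n * spm * L, config.pol_error_rate)
                for f in r.integers(0, n * spm * L, size=n_err):
                    f = int(f)
                    mol, rest = divmod(f, spm * L)
                    local, pos = divmod(rest, L)
                    err_by_mol.setdefault(mol, {}).setdefault(local, []).append(pos)
            origin = np.repeat(np.arange(n, dtype=np.int64), k)
            depth = np.tile(np.array(pattern, dtype=np.int64), n)
            deltas: dict[int, tuple] = {}
            for mol, delta in mols.deltas.items():
                if mol in err_by_mol:
                    continue
                for j in range(mol * k, (mol + 1) * k):
                    deltas[j] = delta
            for mol in sorted(err_by_mol):
                prods = _branch_molecule(
                    mols.deltas.get(mol, ()),
                    single,
                    C,
                    1.0,
                    0.0,
                    err_by_mol[mol],
                    iter(umis[mol * k : (mol + 1) * k]),
                    r,
                    assay.amplicon_seq,
                )
                assert len(prods) == k
                for j, (u, d, delta) in enumerate(prods):
                    umis[mol * k + j] = u
                    depth[mol * k + j] = d
                    if delta:
                        deltas[mol * k + j] = delta
            pools[assay.name] = BarcodedPool(
                assay.name, n, origin, umis, depth, deltas
            )
        else:
            origins: list[int] = []
            umi_l: list[int] = []
            depth_l: list[int] = []
            deltas = {}
            for mol in range(n):
                prods = _branch_molecule(
                    mols.deltas.get(mol, ()),
                    single,
                    C,
                    eff,
                    p_syn,
                    None,
                    _umi_stream(r, umi_space),
                    r,
                    assay.amplicon_seq,
                )
                for u, d, delta in prods:
                    if delta:
                        deltas[len(origins)] = delta
                    origins.append(mol)
                    umi_l.append(u)
                    depth_l.append(d)
            pools[assay.name] = BarcodedPool(
                assay.name,
                n,
                np.array(origins, dtype=np.int64),
                np.array(umi_l, dtype=np.int64),
                np.array(depth_l, dtype=np.int64),
                deltas,
            )
    return pools


def _umi_stream(r: np.random.Generator, umi_space: int):
    while True:
        yield int(r.integers(0, umi_space))


# ---------------------------------------------------------------------------
# stage 4: dilution


def dilute(
    pools: Mapping[str, BarcodedPool],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, BarcodedPool]:
    """Retain each UMI lineage independently with ``dilution_fraction``."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 3)
    rngs = rng.spawn(len(pools))
    out: dict[str, BarcodedPool] = {}
    for (name, pool), r in zip(pools.items(), rngs):
        if config.dilution_fraction >= 1.0:
            out[name] = pool
        elif config.dilution_fraction <= 0.0:
            out[name] = pool.subset(np.zeros(len(pool), dtype=bool))
        else:
            out[name] = pool.subset(r.random(len(pool)) < config.dilution_fraction)
    return out


# ---------------------------------------------------------------------------
# stage 5: adapter PCR + sequencing


def _umi_strings(umis: np.ndarray, k: int) -> list[str]:
    """Vectorized integer -> base-4 nucleotide string conversion."""
    if len(umis) == 0:
        return []
    shifts = np.arange(2 * (k - 1), -1, -2, dtype=np.int64)
    digits = (umis[:, None] >> shifts[None, :]) & 3
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    blob = lut[digits].tobytes().decode()
    return [blob[i * k : (i + 1) * k] for i in range(len(umis))]


def adapter_pcr_and_sequence(
    pools: Mapping[str, BarcodedPool],
    panel: Panel,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[ReadRecord], dict[str, dict]]:
    """Amplify surviving lineages and emit sequencing reads.

    Returns the reads plus per-assay stats: number of reads, reads per
    lineage, and jackpot-error events (cycle, position) per lineage.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 4)
    rngs = rng.spawn(len(panel.assays))
    records: list[ReadRecord] = []
    stats: dict[str, dict] = {}
    any_products = any(len(pools.get(a.name, ())) for a in panel.assays)
    if not any_products:
        warnings.warn("no barcoded products survive; emitting no reads", stacklevel=2)
    jp = config.jackpot_cycles
    n_leaves = 2 ** jp
    n_nodes = 2 ** jp - 1
    residual_cycles = max(config.adapter_cycles - jp, 0)
    p_res = 1.0 - (1.0 - config.pol_error_rate) ** residual_cycles
    for assay, r in zip(panel.assays, rngs):
        pool = pools.get(assay.name)
        if pool is None or len(pool) == 0:
            stats[assay.name] = {"n_reads": 0, "reads_per_lineage": []}
            continue
        L = len(assay)
        m = len(pool)
        R = panel.umi_length + len(panel.anchor_seq) + L
        reads_n = r.poisson(config.mean_reads_per_family, size=m)
        N = int(reads_n.sum())
        # jackpot tree errors: shared by a subtree of leaves
        jack: dict[int, list[tuple[int, int, int, int]]] = {}
        if jp > 0 and config.pol_error_rate > 0.0:
            n_jerr = r.binomial(m * n_nodes * L, config.pol_error_rate)
            for _ in range(int(n_jerr)):
                lin = int(r.integers(m))
                node = int(r.integers(n_nodes))  # 0-based over all tree nodes
                cyc = (node + 1).bit_length()  # doubling-tree cycle of this synthesis
                w = node + 1 - 2 ** (cyc - 1)
                pos = int(r.integers(L))
                altidx = int(r.integers(3))
                mask = (1 << cyc) - 1
                want = w + (1 << (cyc - 1))
                jack.setdefault(lin, []).append((mask, want, pos, altidx))
        # per-read substitution error counts (residual polymerase + sequencer)
        if N:
            sub_counts = r.binomial(R, p_res, size=N) + r.binomial(
                R, config.seq_error_rate, size=N
            )
            total_subs = int(sub_counts.sum())
            sub_pos = r.integers(0, R, size=total_subs)
            sub_alt = r.integers(0, 3, size=total_subs)
            if config.read_indel_rate > 0.0:
                ind_counts = r.binomial(L, config.read_indel_rate, size=N)
            else:
                ind_counts = None
        umi_strs = _umi_strings(pool.umi, panel.umi_length)
        qual = chr(33 + config.phred_quality) * R
        prefix_len = panel.umi_length + len(panel.anchor_seq)
        insert_cache: dict[tuple, str] = {(): assay.amplicon_seq}
        ridx = 0
        ptr = 0
        for li in range(m):
            delta = pool.deltas.get(li, ())
            insert = insert_cache.get(delta)
            if insert is None:
                ba = bytearray(assay.amplicon_seq.encode())
                for pos, alt in delta:
                    ba[pos] = ord(alt)
                insert = ba.decode()
                insert_cache[delta] = insert
            base_read = umi_strs[li] + panel.anchor_seq + insert
            jl = jack.get(li)
            origin = int(pool.origin[li])
            nr = int(reads_n[li])
            for j in range(nr):
                s = base_read
                k = int(sub_counts[ridx])
                jhits = None
                if jl is not None:
                    leaf = int(r.integers(n_leaves))
                    jhits = [
                        (pos, altidx)
                        for mask, want, pos, altidx in jl
                        if (leaf & mask) == want
                    ]
                nind = int(ind_counts[ridx]) if ind_counts is not None else 0
                if k or jhits or nind:
                    ba = bytearray(s.encode())
                    if jhits:
                        for pos, altidx in jhits:
                            p = prefix_len + pos
                            ba[p] = _OTHERS_BY_BYTE.get(ba[p], b"ACG")[altidx]
                    for _ in range(k):
                        p = int(sub_pos[ptr])
                        ba[p] = _OTHERS_BY_BYTE.get(ba[p], b"ACG")[int(sub_alt[ptr])]
                        ptr += 1
                    for _ in range(nind):
                        p = prefix_len + int(r.integers(L))
                        if r.random() < 0.5:
                            del ba[p]
                        else:
                            ba.insert(p, ord(_BASES[int(r.integers(4))]))
                    s = ba.decode()
                q = qual if len(s) == R else chr(33 + config.phred_quality) * len(s)
                records.append(
                    ReadRecord(f"{assay.name}|o{origin}|u{li}|r{j}", s, q)
                )
                ridx += 1
        stats[assay.name] = {
            "n_reads": N,
            "reads_per_lineage": reads_n,
            "jackpot_errors": {
                li: [(pos, altidx) for _, _, pos, altidx in ev]
                for li, ev in jack.items()
            },
        }
    return records, stats


# ---------------------------------------------------------------------------
# composition


def simulate_reads(
    config: SimConfig, panel: Panel
) -> tuple[list[ReadRecord], SimTruth]:
    """Run all five stages in memory; returns reads plus ground truth."""
    root = np.random.default_rng(np.random.SeedSequence(config.seed))
    stage_rngs = root.spawn(5)
    mols = make_molecules(config, panel, rng=stage_rngs[0])
    templates = (
        reverse_transcribe(mols, config, panel, rng=stage_rngs[1])
        if config.strandedness == SINGLE
        else mols
    )
    pools = barcode_pcr(templates, panel, config, rng=stage_rngs[2])
    surviving = dilute(pools, config, rng=stage_rngs[3])
    records, stats = adapter_pcr_and_sequence(
        surviving, panel, config, rng=stage_rngs[4]
    )
    truth = SimTruth(
        config=config.to_dict(),
        umi_length=panel.umi_length,
        anchor_seq=panel.anchor_seq,
    )
    for assay in panel.assays:
        name = assay.name
        pre = pools[name]
        post = surviving[name]
        t_mols = templates.assays[name]
        truth.assays[name] = {
            "strandedness": config.strandedness,
            "n_input_molecules": mols.assays[name].n,
            "n_templates": t_mols.n,
            "variants": t_mols.variants,
            "rt_error_count": len(t_mols.rt_errors),
            "rt_errors": [list(e) for e in t_mols.rt_errors],
            "n_lineages": len(pre),
            "umis_per_origin": pre.umis_per_origin(),
            "distinct_umis_per_origin": pre.distinct_umis_per_origin(),
            "umi_collisions": int(len(pre) - len(np.unique(pre.umi)))
            if len(pre)
            else 0,
            "n_surviving_lineages": len(post),
            "surviving_per_origin": post.umis_per_origin(),
            "surviving_origin": post.origin,
            "surviving_umi": [u for u in _umi_strings(post.umi, panel.umi_length)],
            "n_reads": stats[name]["n_reads"],
        }
    return records, truth


def simulate_run(config: SimConfig, panel: Panel, out_dir) -> dict[str, Path]:
    """Simulate and write ``reads.fastq.gz`` + ``truth.json`` + config echo.

    Identical seeds give byte-identical outputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, truth = simulate_reads(config, panel)
    fastq = out_dir / "reads.fastq.gz"
    write_fastq(records, fastq)
    truth_path = out_dir / "truth.json"
    truth.to_json(truth_path)
    cfg_path = out_dir / "sim_config.json"
    with open(cfg_path, "wt", encoding="utf-8") as fh:
        json.dump(config.to_dict(), fh, indent=1, sort_keys=True)
    return {"fastq": fastq, "truth": truth_path, "config": cfg_path}


# ---------------------------------------------------------------------------
# synthetic study panel


def synthetic_panel(
    n_assays: int = 5,
    amplicon_length: int = 100,
    seed: int = 7,
    umi_length: int = 12,
    anchor_seq: str = DEFAULT_ANCHOR,
    min_reads_per_umi: int = 3,
) -> Panel:
    """A synthetic multi-assay panel of random amplicons.

    Stands in for a real targeted panel (e.g. five TP53 regions): assay
    reference sequences are uniform random DNA, deterministic for a given
    seed, with arbitrary non-overlapping genomic coordinates.
    """
    r = np.random.default_rng(seed)
    assays = []
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in range(n_assays):
        seq = lut[r.integers(0, 4, size=amplicon_length)].tobytes().decode()
        start = 7_674_000 + i * (amplicon_length + 50)
        assays.append(
            Assay(
                name=f"TP53_{chr(65 + i)}",
                gene="TP53",
                amplicon_seq=seq,
                contig="chr17",
                start=start,
            )
        )
    return Panel(
        assays=tuple(assays),
        umi_length=umi_length,
        anchor_seq=anchor_seq,
        min_reads_per_umi=min_reads_per_umi,
    )
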