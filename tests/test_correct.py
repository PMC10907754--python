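"""UMI extraction, assay assignment, alignment, clustering and consensus."""

from collections import Counter

import numpy as np
import pytest

import digiseq as dq
from digiseq.correct import AssignedRead, UmiExtraction

MATCH, MISMATCH, OPEN, EXTEND = 2, -4, -6, -1


def semiglobal_affine_score(amp: str, ins: str) -> float:
    """Independent Gotoh DP: affine gaps, free end gaps on the insert.

    Free end gaps means reference (amplicon) bases before/after the aligned
    insert cost nothing; gaps inside, and insert overhangs, are penalized.
    """
    m, n = len(amp), len(ins)
    NEG = float("-inf")
    M = [[NEG] * (n + 1) for _ in range(m + 1)]  # amp[i-1] ~ ins[j-1]
    X = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in insert (amp consumed)
    Y = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in amp (ins consumed)
    M[0][0] = 0.0
    for i in range(1, m + 1):
        X[i][0] = 0.0  # leading reference overhang is free
    for j in range(1, n + 1):
        Y[0][j] = OPEN + EXTEND * (j - 1)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = MATCH if amp[i - 1] == ins[j - 1] else MISMATCH
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + OPEN, X[i - 1][j] + EXTEND, Y[i - 1][j] + OPEN)
            Y[i][j] = max(M[i][j - 1] + OPEN, Y[i][j - 1] + EXTEND, X[i][j - 1] + OPEN)
    # trailing reference overhang is free: take the best over all rows
    return max(max(M[i][n], X[i][n], Y[i][n]) for i in range(m + 1))


def consensus_oracle(seqs: list[str], min_fraction: float = 0.6) -> str:
    """Exhaustive per-position majority enumeration over equal-length reads."""
    out = []
    for col in zip(*seqs):
        votes = Counter(c for c in col if c != ".")
        if not votes:
            out.append(".")
            continue
        sym, n = min(votes.items(), key=lambda kv: (-kv[1], kv[0]))
        out.append(sym if n / sum(votes.values()) >= min_fraction else ".")
    return "".join(out)


def _read(panel, umi, insert, rid="r1"):
    seq = umi + panel.anchor_seq + insert
    return dq.ReadRecord(rid, seq, "I" * len(seq))


class TestExtractUmi:
    def test_exact_anchor(self, tiny_panel):
        ins = tiny_panel.assays[0].amplicon_seq
        rec = _read(tiny_panel, "ACGTACGT", ins)
        assert dq.extract_umi(rec, tiny_panel) == UmiExtraction("ACGTACGT", ins, None)

    def test_one_anchor_mismatch_accepted(self, tiny_panel):
        ins = tiny_panel.assays[0].amplicon_seq
        anchor = "T" + tiny_panel.anchor_seq[1:]
        seq = "ACGTACGT" + anchor + ins
        rec = dq.ReadRecord("r", seq, "I" * len(seq))
        assert dq.extract_umi(rec, tiny_panel).reject_reason is None

    def test_two_anchor_mismatches_rejected(self, tiny_panel):
        ins = tiny_panel.assays[0].amplicon_seq
        anchor = "TT" + tiny_panel.anchor_seq[2:]
        seq = "ACGTACGT" + anchor + ins
        rec = dq.ReadRecord("r", seq, "I" * len(seq))
        assert dq.extract_umi(rec, tiny_panel).reject_reason == "anchor_mismatch"

    def test_short_read_rejected(self, tiny_panel):
        rec = dq.ReadRecord("r", "ACGT", "IIII")
        assert dq.extract_umi(rec, tiny_panel).reject_reason == "too_short"


class TestAssignAssay:
    def test_exact_amplicon(self, tiny_panel):
        hit = dq.assign_assay(tiny_panel.assays[1].amplicon_seq, tiny_panel)
        assert hit is not None and hit.name == "B"

    def test_random_sequence_unassigned(self, panel5, rng):
        junk = "".join(rng.choice(list("ACGT"), size=100))
        # force dissimilarity: reverse of an amplicon is still random-like
        assert dq.assign_assay("AC" * 7, panel5) is None

    def test_single_substitution_assigned(self, panel1):
        amp = panel1.assays[0].amplicon_seq
        ins = amp[:50] + ("A" if amp[50] != "A" else "C") + amp[51:]
        hit = dq.assign_assay(ins, panel1)
        assert hit is not None and hit.name == "TP53_A"


class TestAlignment:
    def test_exact_match_all_match(self, panel1):
        amp = panel1.assays[0].amplicon_seq
        aln = dq.align_to_amplicon(amp, panel1.assays[0])
        assert aln.symbols == amp and aln.insertions == ()

    def test_internal_deletion_matches_dp_oracle(self, panel1):
        assay = panel1.assays[0]
        amp = assay.amplicon_seq
        ins = amp[:40] + amp[41:]
        aln = dq.align_to_amplicon(ins, assay, force_dp=True)
        assert aln.symbols.count("-") == 1
        # deletion within the homopolymer-equivalence window around offset 40
        off = aln.symbols.index("-")
        assert amp[:off] + amp[off + 1 :] == ins
        assert aln.score == semiglobal_affine_score(amp, ins)

    def test_prefix_insert_has_free_end_gap(self, panel1):
        assay = panel1.assays[0]
        ins = assay.amplicon_seq[:30]
        aln = dq.align_to_amplicon(ins, assay, force_dp=True)
        assert aln.score == semiglobal_affine_score(assay.amplicon_seq, ins)
        assert aln.score == 2 * 30  # no penalty beyond the aligned span
        assert sum(s != "." for s in aln.symbols) == 30

    @pytest.mark.parametrize("seed", range(8))
    def test_dp_score_equals_oracle_on_random_pairs(self, seed):
        r = np.random.default_rng(seed)
        bases = np.array(list("ACGT"))
        amp = "".join(r.choice(bases, size=int(r.integers(20, 50))))
        # mutated copy: substitutions plus a small indel
        ins = list(amp)
        for _ in range(int(r.integers(0, 4))):
            p = int(r.integers(len(ins)))
            ins[p] = str(r.choice(bases))
        if r.random() < 0.5 and len(ins) > 5:
            del ins[int(r.integers(len(ins)))]
        else:
            ins.insert(int(r.integers(len(ins))), str(r.choice(bases)))
        ins = "".join(ins)
        assay = dq.Assay(name="x", gene="g", amplicon_seq=amp)
        aln = dq.align_to_amplicon(ins, assay, force_dp=True)
        assert aln.score == semiglobal_affine_score(amp, ins)


class TestClustering:
    def _reads(self, umi, n, insert, assay="A"):
        return [AssignedRead(f"{umi}-{i}", assay, umi, insert) for i in range(n)]

    def test_directional_merge_absorbs_small_neighbor(self, tiny_panel):
        ins = tiny_panel.assays[0].amplicon_seq
        big = self._reads("AAAAAAAA", 100, ins)
        small = self._reads("AAAAAAAT", 2, ins)
        fams = dq.group_and_cluster_umis(big + small, tiny_panel)
        assert len(fams) == 1
        assert fams[0].size == 102 and fams[0].umi == "AAAAAAAA"

    def test_distance_two_not_merged(self, tiny_panel):
        ins = tiny_panel.assays[0].amplicon_seq
        fams = dq.group_and_cluster_umis(
            self._reads("AAAAAAAA", 100, ins) + self._reads("AAAAAATT", 2, ins),
            tiny_panel,
        )
        assert sorted(f.size for f in fams) == [2, 100]

    def test_count_rule_blocks_equal_families(self, tiny_panel):
        ins = tiny_panel.assays[0].amplicon_seq
        fams = dq.group_and_cluster_umis(
            self._reads("AAAAAAAA", 6, ins) + self._reads("AAAAAAAT", 6, ins),
            tiny_panel,
        )
        assert len(fams) == 2  # 6 < 2*6-1: neither absorbs the other

    def test_identical_umis_one_family(self, tiny_panel):
        ins = tiny_panel.assays[0].amplicon_seq
        fams = dq.group_and_cluster_umis(self._reads("GGGGGGGG", 7, ins), tiny_panel)
        assert len(fams) == 1 and fams[0].size == 7

    def test_exact_mode_disables_merging(self, tiny_panel):
        ins = tiny_panel.assays[0].amplicon_seq
        fams = dq.group_and_cluster_umis(
            self._reads("AAAAAAAA", 100, ins) + self._reads("AAAAAAAT", 2, ins),
            tiny_panel,
            cluster_distance=0,
        )
        assert len(fams) == 2


class TestConsensus:
    def _family(self, panel, seqs, umi="AAAAAAAA", assay="A"):
        fam = dq.UMIFamily(assay=assay, umi=umi)
        for i, s in enumerate(seqs):
            fam.read_ids.append(f"r{i}")
            fam.inserts.append(s)
        fam.alignments = [dq.AmpliconAlignment(s) for s in seqs]
        return fam

    def test_below_cutoff_returns_none(self, tiny_panel):
        ins = tiny_panel.assays[0].amplicon_seq
        fam = self._family(tiny_panel, [ins] * 2)
        assert dq.call_consensus(fam, tiny_panel) is None

    def test_identical_members(self, tiny_panel):
        ins = tiny_panel.assays[0].amplicon_seq
        cons = dq.call_consensus(self._family(tiny_panel, [ins] * 5), tiny_panel)
        assert cons is not None and cons.sequence == ins
        assert cons.family_size == 5 and not cons.ambiguous_positions

    def test_three_of_four_plurality_wins(self, tiny_panel):
        ins = tiny_panel.assays[0].amplicon_seq
        mutant = "T" + ins[1:] if ins[0] != "T" else "A" + ins[1:]
        cons = dq.call_consensus(
            self._family(tiny_panel, [ins] * 3 + [mutant]), tiny_panel
        )
        assert cons.sequence == ins  # 0.75 >= 0.6
        assert not cons.ambiguous_positions

    def test_split_vote_is_ambiguous(self, tiny_panel):
        ins = tiny_panel.assays[0].amplicon_seq
        mutant = ("T" if ins[0] != "T" else "A") + ins[1:]
        cons = dq.call_consensus(
            self._family(tiny_panel, [ins] * 2 + [mutant] * 2), tiny_panel
        )
        assert 0 in cons.ambiguous_positions
        assert cons.sequence[0] == "."

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_majority_oracle(self, seed):
        r = np.random.default_rng(seed)
        L = int(r.integers(5, 21))
        amp = "".join(r.choice(list("ACGT"), size=L))
        panel = dq.Panel(
            assays=(dq.Assay(name="A", gene="g", amplicon_seq=amp),),
            umi_length=8,
            min_reads_per_umi=3,
        )
        n = int(r.integers(3, 7))
        seqs = []
        for _ in range(n):
            s = list(amp)
            for _ in range(int(r.integers(0, 4))):
                s[int(r.integers(L))] = str(r.choice(list("ACGT-")))
            seqs.append("".join(s))
        fam = self._family(panel, seqs)
        cons = dq.call_consensus(fam, panel)
        assert cons.sequence == consensus_oracle(seqs)


class TestPipeline:
    def test_zero_error_run_recovers_reference_and_variant(self, panel1):
        cfg = dq.SimConfig(
            seed=2,
            n_molecules=400,
            rt_error_rate=0.0,
            pol_error_rate=0.0,
            seq_error_rate=0.0,
            variants=(dq.VariantSpec("TP53_A", 30, "A", 0.5),),
        )
        records, truth = dq.simulate_reads(cfg, panel1)
        res = dq.run_pipeline(records, panel1)
        m = res.pileups["TP53_A"].consensus
        rates = dq.position_error_rates(m)
        nonzero = np.nonzero(np.nan_to_num(rates.e_p) > 0)[0]
        assert list(nonzero) == [30]
        call = dq.estimate_maf(m, 30, "A")
        true_frac = truth.assays["TP53_A"]["variants"][0]["realized_fraction"]
        # lineage subsampling through dilution: binomial band around the truth
        sd = np.sqrt(true_frac * (1 - true_frac) / call.coverage)
        assert abs(call.maf - true_frac) < 4 * sd

    def test_empty_input_no_crash(self, panel1):
        res = dq.run_pipeline([], panel1)
        assert res.report["reads_in"] == 0
        assert res.report["n_consensus_reads"] == 0
        assert np.all(res.pileups["TP53_A"].raw.coverage == 0)

    def test_read_conservation_and_coverage_ordering(self, panel5):
        cfg = dq.SimConfig(seed=6, n_molecules=500, rt_error_rate=1e-4,
                           read_indel_rate=1e-4)
        records, _ = dq.simulate_reads(cfg, panel5)
        res = dq.run_pipeline(records, panel5)
        rep = res.report
        assert rep["reads_in"] == (
            rep["rejected_total"] + rep["unassigned"] + rep["reads_in_families"]
        )
        assert rep["n_consensus_reads"] <= rep["n_families"]
        for fam in res.families:
            cons = [c for c in res.consensus[fam.assay] if c.umi == fam.umi]
            for c in cons:
                assert c.family_size >= panel5.min_reads_per_umi
        for pair in res.pileups.values():
            assert np.all(pair.consensus.coverage <= pair.raw.coverage)
            assert np.array_equal(
                pair.raw.counts.sum(axis=1), pair.raw.coverage
            )

    def test_rerun_is_deterministic(self, panel1):
        cfg = dq.SimConfig(seed=8, n_molecules=200)
        records, _ = dq.simulate_reads(cfg, panel1)
        r1 = dq.run_pipeline(records, panel1)
        r2 = dq.run_pipeline(records, panel1)
        assert r1.report == r2.report
        assert np.array_equal(
            r1.pileups["TP53_A"].consensus.counts,
            r2.pileups["TP53_A"].consensus.counts,
        )
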