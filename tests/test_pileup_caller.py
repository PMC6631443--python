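"""Pileup semantics (rmdup, MAPQ filtering), both calling rules against
direct-computation oracles, and VCF I/O."""
import math

import numpy as np
import pysam
import pytest

from rfpsim._seq import BASES, decode
from rfpsim.genome_forge import ReferenceGenome
from rfpsim.micro_aligner import Alignment
from rfpsim.pileup_caller import (PileupSites, VariantCall, VcfParseError,
                                  build_pileup, call_A_threshold,
                                  call_B_likelihood, read_vcf, write_vcf)


def make_ref(seq="ACGT" * 500):
    arr = np.array([BASES.index(b) for b in seq], dtype=np.uint8)
    return ReferenceGenome(contigs={"c": arr}, target_regions=[], pad_length=0)


def aln(pos, seq, strand="+", mapq=30, mate_pos=0, read2=False):
    return Alignment(read_id=f"r{pos}_{seq[:3]}_{strand}_{read2}", contig="c",
                     pos=pos, strand=strand, mismatches=0, score=0, mapq=mapq,
                     tie_count=1 if mapq else 2, is_paired=True,
                     mate_pos=mate_pos, is_read2=read2, seq=seq,
                     qual="I" * len(seq))


class TestPileup:
    def test_rmdup_collapses_identical_fragments(self):
        ref = make_ref()
        seq = decode(ref.contigs["c"][0:50])
        # 10 byte-identical fragment signatures -> depth 1
        reads = [aln(1, seq, mate_pos=100) for _ in range(10)]
        pile = build_pileup(reads, ref)
        assert pile.depth("c")[0] == 1
        # distinct mate positions -> all kept
        reads = [aln(1, seq, mate_pos=100 + i) for i in range(10)]
        pile = build_pileup(reads, ref)
        assert pile.depth("c")[0] == 10

    def test_uncovered_site_absent(self):
        ref = make_ref()
        pile = build_pileup([aln(11, decode(ref.contigs["c"][10:40]))], ref)
        assert pile.site("c", 5) is None
        assert pile.site("c", 11).depth == 1

    def test_mapq_filter_excludes_tied_reads(self):
        ref = make_ref()
        seq = decode(ref.contigs["c"][0:30])
        reads = [aln(1, seq, mapq=0, mate_pos=60),
                 aln(1, seq, mapq=30, mate_pos=70)]
        assert build_pileup(reads, ref, min_mapq=0).depth("c")[0] == 2
        assert build_pileup(reads, ref, min_mapq=1).depth("c")[0] == 1
        assert build_pileup(reads, ref, min_mapq=0).site("c", 1).mapq0 == 1

    def test_counts_match_bruteforce_recount(self):
        """Allele counts equal a direct per-position recount of the reads."""
        rng = np.random.default_rng(3)
        ref = make_ref()
        reads = []
        for i in range(60):
            pos = int(rng.integers(1, 1900))
            length = 40
            codes = (ref.contigs["c"][pos - 1 : pos - 1 + length]
                     + rng.integers(0, 2, size=length)) % 4
            reads.append(aln(pos, decode(codes.astype(np.uint8)),
                             mate_pos=int(rng.integers(1, 2000))))
        pile = build_pileup(reads, ref)
        recount = np.zeros((2000, 5), dtype=int)
        seen = set()
        for a in reads:
            sig = (a.contig, a.pos, a.strand, a.mate_contig, a.mate_pos, a.is_read2)
            if sig in seen:
                continue
            seen.add(sig)
            for j, b in enumerate(a.seq):
                recount[a.pos - 1 + j, BASES.index(b)] += 1
        assert np.array_equal(pile.counts["c"], recount)

    def test_alignment_beyond_contig_end_rejected(self):
        ref = make_ref("ACGT" * 10)
        with pytest.raises(ValueError, match="beyond contig end"):
            build_pileup([aln(30, "A" * 20)], ref)


def pile_with(ref, pos1, depth, alt_count, alt="T"):
    """Hand-built pileup: depth reads, alt_count carrying ``alt``."""
    pile = PileupSites(ref)
    ref_code = int(ref.contigs["c"][pos1 - 1])
    alt_code = BASES.index(alt)
    if alt_code == ref_code:
        alt_code = (ref_code + 1) % 4
    pile.counts["c"][pos1 - 1, ref_code] = depth - alt_count
    pile.counts["c"][pos1 - 1, alt_code] = alt_count
    return pile


class TestCallerA:
    @pytest.mark.parametrize("depth,alt,called", [
        (30, 15, True),   # clear het-like site
        (30, 2, False),   # below count gate
        (4, 4, False),    # below depth gate
        (30, 6, True),    # exactly at the 0.2 fraction gate
        (30, 5, False),   # just below the fraction gate
    ])
    def test_threshold_gates(self, depth, alt, called):
        ref = make_ref()
        pile = pile_with(ref, 101, depth, alt)
        calls = call_A_threshold(pile)
        assert (len(calls) == 1) == called
        if called:
            assert calls[0].qual == alt
            assert calls[0].pos == 101

    def test_multiple_passing_alts_all_emitted(self):
        ref = make_ref()
        pile = PileupSites(ref)
        rc = int(ref.contigs["c"][100])
        others = [a for a in range(4) if a != rc]
        pile.counts["c"][100, others[0]] = 10
        pile.counts["c"][100, others[1]] = 10
        pile.counts["c"][100, rc] = 10
        calls = call_A_threshold(pile)
        assert len(calls) == 2
        assert {c.alt for c in calls} == {BASES[others[0]], BASES[others[1]]}


class TestCallerB:
    @staticmethod
    def oracle_ratio(depth, alt, error=0.01):
        """Direct binomial-likelihood computation (independent of the
        implementation's vectorized path)."""
        def binom_ll(p):
            return (math.comb(depth, alt) * p**alt * (1 - p) ** (depth - alt))
        rr = binom_ll(error)
        best = max(binom_ll(0.5), binom_ll(1 - error))
        return best / rr

    @pytest.mark.parametrize("depth,alt", [(30, 15), (30, 0), (30, 1),
                                           (30, 5), (30, 6), (10, 10)])
    def test_matches_direct_binomial_oracle(self, depth, alt):
        ref = make_ref()
        pile = pile_with(ref, 201, depth, alt)
        calls = call_B_likelihood(pile, error=0.01, min_posterior_ratio=10)
        should_call = alt > 0 and self.oracle_ratio(depth, alt) >= 10
        assert (len(calls) == 1) == should_call
        if should_call:
            expected_qual = round(10 * math.log10(self.oracle_ratio(depth, alt)))
            assert calls[0].qual == pytest.approx(expected_qual, abs=1)


def test_callers_agree_on_clear_sites(paralog_run):
    """Depth >= 20, alt fraction >= 0.4 sites: A and B concordant >= 99%;
    disagreement concentrates at marginal sites."""
    import rfpsim
    from rfpsim.rfp_engine import run_single_round
    from rfpsim.micro_aligner import build_index, map_batch
    from rfpsim.read_sampler import sample_reads, SamplerConfig
    from dataclasses import replace
    scn, _, _ = paralog_run
    index = build_index(scn.ref, 21)
    batch = sample_reads(scn.individual,
                         replace(scn.engine.sampler, seed=99))
    alnb = map_batch(batch, index, scn.engine.aligner, master_seed=99)
    pile = build_pileup(alnb, scn.ref)
    keys_a = {c.key() for c in call_A_threshold(pile)}
    keys_b = {c.key() for c in call_B_likelihood(pile)}
    clear = set()
    counts = pile.counts["c" if "c" in pile.counts else next(iter(pile.counts))]
    name = next(iter(pile.counts))
    refcodes = scn.ref.contigs[name]
    depth = counts.sum(axis=1)
    for pos0 in np.flatnonzero(depth >= 20):
        rc = int(refcodes[pos0])
        for a in range(4):
            if a == rc:
                continue
            if counts[pos0, a] >= 0.4 * depth[pos0]:
                clear.add((name, int(pos0) + 1, BASES[rc], BASES[a]))
    both = clear & keys_a & keys_b
    assert len(both) >= 0.99 * len(clear)


class TestVcfIO:
    def test_roundtrip_and_pysam_crosscheck(self, tmp_path):
        ref = make_ref()
        calls = [VariantCall("c", 5, "A", "T", 12.0, "A"),
                 VariantCall("c", 5, "A", "G", 8.0, "A"),
                 VariantCall("c", 99, "G", "C", 33.0, "B", "RFP")]
        path = tmp_path / "x.vcf"
        write_vcf(calls, ref, path, extra_filters={"RFP": "blacklisted"})
        back = read_vcf(path)
        assert sorted(c.key() for c in back) == sorted(c.key() for c in calls)
        assert {c.filter_status for c in back} == {"PASS", "RFP"}
        with pysam.VariantFile(str(path)) as vf:
            recs = list(vf)
            assert len(recs) == 3  # multiple alts as separate records
            assert recs[0].pos == 5

    def test_zero_calls_still_full_header(self, tmp_path):
        ref = make_ref()
        path = tmp_path / "empty.vcf"
        write_vcf([], ref, path)
        text = path.read_text()
        assert text.startswith("##fileformat=VCFv4.2")
        assert "##contig=<ID=c," in text
        assert read_vcf(path) == []

    @pytest.mark.parametrize("line,lineno", [
        ("c\tnotanint\t.\tA\tT\t5\tPASS\t.", 3),
        ("c\t5\t.\tAT\tT\t5\tPASS\t.", 3),
        ("c\t5\t.\tA\tT\t5", 3),
    ])
    def test_malformed_records_with_line_numbers(self, tmp_path, line, lineno):
        path = tmp_path / "bad.vcf"
        path.write_text("##fileformat=VCFv4.2\n"
                        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
                        + line + "\n")
        with pytest.raises(VcfParseError) as err:
            read_vcf(path)
        assert err.value.line == lineno
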