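"""Seed-and-extend short-read aligner with randomized tie-breaking.

The aligner is deliberately minimal: exact k-mer seeds at three fixed
offsets, ungapped Hamming extension, and — the property this package
exists to study — uniform random assignment among equally-scoring
placements, with MAPQ forced to 0 so that downstream tools can see the
ambiguity.  Reads sampled from one paralog copy whose window carries no
discriminating base are therefore scattered between copies, exactly the
behaviour of production aligners in near-identical regions.

Mates of a pair are scored independently: each mate is placed at its own
best-Hamming candidate and per-mate ties are broken by an independent
counter-based draw.  When *both* mates are tied and their candidate sets
pair up into proper pairs, the pair is placed as a unit with a single
draw.  A mate with a unique best placement anchors itself but never
overrides the other mate's tie — an aligner that cannot distinguish two
placements by score has no principled reason to prefer the one next to
its mate when both lie in copies of the same repeat.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from ._seq import decode, encode, kmer_values, kmer_values_at, revcomp, revcomp_rows, tie_break_index
from .genome_forge import ReferenceGenome
from .read_sampler import DEFAULT_QUALITY, ReadBatch

_GAP = 32  # N-sentinel run between concatenated contigs; > max k


@dataclass
class AlignerConfig:
    k: int = 21
    max_mismatch: int | None = None  # default: ceil(3 + 4 * error_rate * L)
    error_rate: float = 0.01  # only used to derive the default max_mismatch
    insert_mean: float = 500.0
    insert_sd: float = 50.0

    def resolve_max_mismatch(self, read_length: int) -> int:
        if self.max_mismatch is not None:
            return self.max_mismatch
        return int(np.ceil(3 + 4 * self.error_rate * read_length))


class KmerIndex:
    """Exact-occurrence index of every forward-strand k-mer.

    Contigs are concatenated with N sentinels; k-mers containing N are
    never indexed, so no k-mer spans a contig boundary.  Reverse-strand
    occurrences are found by looking up the reverse-complemented read,
    so both strands are represented canonically.
    """

    def __init__(self, ref: ReferenceGenome, k: int):
        if k < 8 or k > 31:
            raise ValueError("k must be in [8, 31]")
        shortest = min(len(s) for s in ref.contigs.values())
        if k > shortest:
            raise ValueError(f"k={k} exceeds shortest contig ({shortest} bp)")
        self.k = k
        self.contig_names = list(ref.contigs)
        parts = []
        offsets = {}
        cursor = 0
        gap = np.full(_GAP, 4, dtype=np.uint8)
        for i, (name, seq) in enumerate(ref.contigs.items()):
            if i:
                parts.append(gap)
                cursor += _GAP
            offsets[name] = cursor
            parts.append(seq)
            cursor += len(seq)
        self.cat = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)
        self.offsets = offsets
        self.lengths = {name: len(seq) for name, seq in ref.contigs.items()}
        self._starts = np.array([offsets[n] for n in self.contig_names], dtype=np.int64)
        self._ends = self._starts + np.array(
            [self.lengths[n] for n in self.contig_names], dtype=np.int64)

        vals = kmer_values(self.cat, k)
        valid = np.flatnonzero(vals >= 0)
        order = valid[np.argsort(vals[valid], kind="stable")]
        sorted_vals = vals[order]
        uniq, first = np.unique(sorted_vals, return_index=True)
        bounds = np.append(first, len(order))
        self._positions = order
        self._slices = {int(v): (int(first[i]), int(bounds[i + 1]))
                        for i, v in enumerate(uniq)}

    def lookup(self, kmer: int) -> np.ndarray:
        """All global start positions of an exact k-mer occurrence."""
        span = self._slices.get(kmer)
        if span is None:
            return np.empty(0, dtype=np.int64)
        return self._positions[span[0] : span[1]]

    def occurrence_count(self, kmer: int, rc_kmer: int) -> int:
        """Genome-wide occurrence count on both strands."""
        n = 0
        for v in (kmer, rc_kmer):
            span = self._slices.get(v)
            if span is not None:
                n += span[1] - span[0]
        return n

    def to_contig(self, gpos: int) -> tuple[str, int]:
        """Global position -> (contig, 0-based local position)."""
        i = int(np.searchsorted(self._ends, gpos, side="right"))
        return self.contig_names[i], gpos - int(self._starts[i])

    def contig_span(self, gpos: int, length: int) -> bool:
        """Whether [gpos, gpos+length) lies within a single contig."""
        i = int(np.searchsorted(self._ends, gpos, side="right"))
        if i >= len(self.contig_names):
            return False
        return self._starts[i] <= gpos and gpos + length <= self._ends[i]


def build_index(ref: ReferenceGenome, k: int = 21) -> KmerIndex:
    return KmerIndex(ref, k)


@dataclass
class Alignment:
    read_id: str
    contig: str
    pos: int  # 1-based leftmost; 0 when unmapped
    strand: str  # '+', '-' or '*'
    mismatches: int
    score: int
    mapq: int
    tie_count: int
    is_paired: bool = False
    is_proper: bool = False
    unmapped: bool = False
    mate_unmapped: bool = False
    is_read2: bool = False
    mate_contig: str = "*"
    mate_pos: int = 0
    mate_strand: str = "*"
    tlen: int = 0
    seq: str = "*"
    qual: str = "*"


class AlignmentBatch:
    """Columnar per-mate placements for one batch of pairs.

    Positions are global (concatenated-genome) starts, -1 if unmapped.
    Strand code 0 = forward, 1 = reverse.
    """

    def __init__(self, index: KmerIndex, batch: ReadBatch, n: int):
        self.index = index
        self.batch = batch
        shape = (2, n)
        self.pos = np.full(shape, -1, dtype=np.int64)
        self.strand = np.zeros(shape, dtype=np.int8)
        self.mm = np.full(shape, -1, dtype=np.int32)
        self.mapq = np.zeros(shape, dtype=np.int16)
        self.tie = np.zeros(shape, dtype=np.int32)
        self.proper = np.zeros(n, dtype=bool)

    @property
    def n_pairs(self) -> int:
        return self.pos.shape[1]

    def oriented_reads(self, mate: int) -> np.ndarray:
        """Read codes of the given mate in aligned (forward-genome) orientation."""
        reads = self.batch.mate1 if mate == 0 else self.batch.mate2
        out = reads.copy()
        rev = self.strand[mate] == 1
        if rev.any():
            out[rev] = revcomp_rows(reads[rev])
        return out

    def to_alignments(self) -> Iterator[Alignment]:
        rl = self.batch.read_length
        qual = chr(DEFAULT_QUALITY + 33) * rl
        oriented = [self.oriented_reads(0), self.oriented_reads(1)]
        for i in range(self.n_pairs):
            rid = self.batch.read_ids[i] if self.batch.read_ids else f"sim_{i}"
            placements = []
            for m in range(2):
                mapped = self.pos[m, i] >= 0
                if mapped:
                    contig, local = self.index.to_contig(int(self.pos[m, i]))
                else:
                    contig, local = "*", -1
                placements.append((mapped, contig, local))
            for m in range(2):
                mapped, contig, local = placements[m]
                o_mapped, o_contig, o_local = placements[1 - m]
                tlen = 0
                if mapped and o_mapped and contig == o_contig:
                    lo = min(local, o_local)
                    hi = max(local, o_local) + rl
                    tlen = (hi - lo) if local <= o_local else -(hi - lo)
                yield Alignment(
                    read_id=rid,
                    contig=contig,
                    pos=local + 1 if mapped else 0,
                    strand=("-" if self.strand[m, i] else "+") if mapped else "*",
                    mismatches=int(self.mm[m, i]) if mapped else -1,
                    score=-int(self.mm[m, i]) if mapped else 0,
                    mapq=int(self.mapq[m, i]) if mapped else 0,
                    tie_count=int(self.tie[m, i]) if mapped else 0,
                    is_paired=True,
                    is_proper=bool(self.proper[i]),
                    unmapped=not mapped,
                    mate_unmapped=not o_mapped,
                    is_read2=(m == 1),
                    mate_contig=o_contig if o_mapped else "*",
                    mate_pos=o_local + 1 if o_mapped else 0,
                    mate_strand=("-" if self.strand[1 - m, i] else "+") if o_mapped else "*",
                    tlen=tlen,
                    seq=decode(oriented[m][i]) if mapped else decode(
                        (self.batch.mate1 if m == 0 else self.batch.mate2)[i]),
                    qual=qual,
                )


def _hamming(read: np.ndarray, cat: np.ndarray, start: int, read_has_n: bool) -> int:
    g = cat[start : start + len(read)]
    mm = int(np.count_nonzero(read != g))
    if read_has_n:
        mm += int(np.count_nonzero((read == 4) & (g == 4)))
    return mm


def _candidates_for(oriented: np.ndarray, kmer_lists: list[list[int]],
                    row: int, offsets: tuple[int, ...], index: KmerIndex,
                    rl: int) -> set[int]:
    cands: set[int] = set()
    limit = len(index.cat) - rl
    for oi, off in enumerate(offsets):
        val = kmer_lists[oi][row]
        if val < 0:
            continue
        for p in index.lookup(val):
            s = int(p) - off
            if 0 <= s <= limit and index.contig_span(s, rl):
                cands.add(s)
    return cands


def _score_candidates(read: np.ndarray, cands: Iterable[int], cat: np.ndarray,
                      max_mm: int, read_has_n: bool
                      ) -> tuple[list[int], int, int]:
    """Return (tie set of best starts, best mm, second best mm)."""
    best, second = max_mm + 1, max_mm + 1
    ties: list[int] = []
    for s in cands:
        mm = _hamming(read, cat, s, read_has_n)
        if mm < best:
            second = best
            best = mm
            ties = [s]
        elif mm == best:
            ties.append(s)
        elif mm < second:
            second = mm
    if best > max_mm:
        return [], -1, -1
    return sorted(ties), best, second


def _is_proper(s_fwd: int, st_fwd: int, s_other: int, st_other: int, rl: int,
               cfg: AlignerConfig, index: KmerIndex) -> bool:
    """FR orientation with implied fragment inside insert_mean +- 4 sd,
    both placements on the same contig."""
    if st_fwd == st_other:
        return False
    if st_fwd == 1:  # normalize so first argument is the forward mate
        s_fwd, s_other = s_other, s_fwd
    if s_other < s_fwd:
        return False
    frag = s_other + rl - s_fwd
    lo = cfg.insert_mean - 4 * cfg.insert_sd
    hi = cfg.insert_mean + 4 * cfg.insert_sd
    if not (lo <= frag <= hi):
        return False
    c1, _ = index.to_contig(s_fwd)
    c2, _ = index.to_contig(s_other)
    return c1 == c2


def map_batch(batch: ReadBatch, index: KmerIndex, cfg: AlignerConfig,
              master_seed: int = 0, round_index: int = 0) -> AlignmentBatch:
    """Map every pair of a batch; deterministic given (master_seed, round)."""
    rl = batch.read_length
    if cfg.k > rl // 2:
        raise ValueError("k must be at most half the read length")
    max_mm = cfg.resolve_max_mismatch(rl)
    offsets = (0, rl // 3, 2 * rl // 3)
    k = cfg.k
    cat = index.cat

    oriented = [
        [batch.mate1, revcomp_rows(batch.mate1)],
        [batch.mate2, revcomp_rows(batch.mate2)],
    ]
    kmers = [
        [[kmer_values_at(mat, off, k).tolist() for off in offsets]
         for mat in mats]
        for mats in oriented
    ]
    has_n = [(batch.mate1 >= 4).any(axis=1), (batch.mate2 >= 4).any(axis=1)]

    out = AlignmentBatch(index, batch, batch.n_pairs)
    for i in range(batch.n_pairs):
        mate_results = []
        for m in range(2):
            # candidates over both orientations, scored together
            best, second = max_mm + 1, max_mm + 1
            ties: list[tuple[int, int]] = []  # (start, strandcode)
            for o in range(2):
                cands = _candidates_for(oriented[m][o][i], kmers[m][o], i,
                                        offsets, index, rl)
                t, b, s = _score_candidates(oriented[m][o][i], cands, cat,
                                            max_mm, bool(has_n[m][i]))
                if b < 0:
                    continue
                if b < best:
                    second = min(best, s if s >= 0 else max_mm + 1)
                    best = b
                    ties = [(x, o) for x in t]
                elif b == best:
                    ties.extend((x, o) for x in t)
                    second = best
                else:
                    second = min(second, b)
            mate_results.append((ties, best, second))

        t1, b1, s1 = mate_results[0]
        t2, b2, s2 = mate_results[1]
        choice1 = choice2 = None
        if len(t1) > 1 and len(t2) > 1:
            combos = [(p1, p2) for p1 in t1 for p2 in t2
                      if _is_proper(p1[0], p1[1], p2[0], p2[1], rl, cfg, index)]
            if combos:
                j = tie_break_index(master_seed, round_index, i * 4 + 3, len(combos))
                choice1, choice2 = combos[j]
        for m, ties_best_second in enumerate(mate_results):
            ties, best, second = ties_best_second
            if not ties:
                continue
            unit = choice1 if m == 0 else choice2
            if unit is not None:
                start, strandcode = unit
            elif len(ties) == 1:
                start, strandcode = ties[0]
            else:
                j = tie_break_index(master_seed, round_index, i * 4 + m, len(ties))
                start, strandcode = ties[j]
            out.pos[m, i] = start
            out.strand[m, i] = strandcode
            out.mm[m, i] = best
            out.tie[m, i] = len(ties)
            out.mapq[m, i] = 0 if len(ties) > 1 else min(60, 10 * (second - best) + 20)
        if out.pos[0, i] >= 0 and out.pos[1, i] >= 0:
            out.proper[i] = _is_proper(int(out.pos[0, i]), int(out.strand[0, i]),
                                       int(out.pos[1, i]), int(out.strand[1, i]),
                                       rl, cfg, index)
    return out


# ---------------------------------------------------------------------------
# single-read / single-pair API


def map_read(read, index: KmerIndex, cfg: AlignerConfig | None = None,
             max_mismatch: int | None = None, master_seed: int = 0,
             round_index: int = 0, read_id: int = 0) -> Alignment:
    """Map a single read (string or code array); ties broken by the
    counter-based draw keyed on (master_seed, round_index, read_id)."""
    cfg = cfg or AlignerConfig()
    codes = encode(read) if isinstance(read, str) else np.asarray(read, dtype=np.uint8)
    rl = len(codes)
    max_mm = max_mismatch if max_mismatch is not None else cfg.resolve_max_mismatch(rl)
    offsets = (0, rl // 3, 2 * rl // 3)
    read_has_n = bool((codes >= 4).any())
    best, second = max_mm + 1, max_mm + 1
    ties: list[tuple[int, int]] = []
    for o, orient in enumerate((codes, revcomp(codes))):
        cands: set[int] = set()
        limit = len(index.cat) - rl
        for off in offsets:
            val = int(kmer_values(orient[off : off + cfg.k], cfg.k)[0]) \
                if off + cfg.k <= rl else -1
            if val < 0:
                continue
            for p in index.lookup(val):
                s = int(p) - off
                if 0 <= s <= limit and index.contig_span(s, rl):
                    cands.add(s)
        t, b, s = _score_candidates(orient, cands, index.cat, max_mm, read_has_n)
        if b < 0:
            continue
        if b < best:
            second = min(best, s if s >= 0 else max_mm + 1)
            best = b
            ties = [(x, o) for x in t]
        elif b == best:
            ties.extend((x, o) for x in t)
            second = best
        else:
            second = min(second, b)
    if not ties:
        return Alignment(read_id=str(read_id), contig="*", pos=0, strand="*",
                         mismatches=-1, score=0, mapq=0, tie_count=0, unmapped=True,
                         seq=decode(codes))
    if len(ties) == 1:
        start, strandcode = ties[0]
        mapq = min(60, 10 * (second - best) + 20)
    else:
        j = tie_break_index(master_seed, round_index, read_id, len(ties))
        start, strandcode = ties[j]
        mapq = 0
    contig, local = index.to_contig(start)
    oriented_codes = codes if strandcode == 0 else revcomp(codes)
    return Alignment(read_id=str(read_id), contig=contig, pos=local + 1,
                     strand="-" if strandcode else "+", mismatches=best,
                     score=-best, mapq=mapq, tie_count=len(ties),
                     seq=decode(oriented_codes),
                     qual=chr(DEFAULT_QUALITY + 33) * rl)


def map_pair(pair, index: KmerIndex, cfg: AlignerConfig | None = None,
             master_seed: int = 0, round_index: int = 0,
             pair_id: int = 0) -> tuple[Alignment, Alignment]:
    """Map one read pair through the batch machinery."""
    from .read_sampler import ReadPair, batch_from_pairs

    cfg = cfg or AlignerConfig()
    if not isinstance(pair, ReadPair):
        seq1, seq2 = pair
        pair = ReadPair(read_id=str(pair_id), seq1=seq1, seq2=seq2,
                        qual1="I" * len(seq1), qual2="I" * len(seq2))
    batch = batch_from_pairs([pair])
    aln = map_batch(batch, index, cfg, master_seed=master_seed,
                    round_index=round_index)
    a1, a2 = list(aln.to_alignments())
    return a1, a2


# ---------------------------------------------------------------------------
# brute-force oracle (used by tests; intentionally independent of the
# seed-and-extend path)


def exhaustive_best_placements(read, ref: ReferenceGenome,
                               max_mismatch: int) -> tuple[list[tuple[str, int, int]], int]:
    """Full-scan Hamming search over every position and both strands.

    Returns (placements, best_mm) where placements are
    (contig, 0-based start, strand code) with minimal mismatch count,
    or ([], -1) if nothing scores within max_mismatch.
    """
    codes = encode(read) if isinstance(read, str) else np.asarray(read, dtype=np.uint8)
    rl = len(codes)
    best = max_mismatch + 1
    hits: list[tuple[str, int, int]] = []
    for name, seq in ref.contigs.items():
        if len(seq) < rl:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(seq, rl)
        for strandcode, orient in enumerate((codes, revcomp(codes))):
            mm = (windows != orient).sum(axis=1)
            if (orient >= 4).any():
                mm = mm + ((windows == 4) & (orient == 4)).sum(axis=1)
            m = int(mm.min())
            if m < best:
                best = m
                hits = [(name, int(p), strandcode) for p in np.flatnonzero(mm == m)]
            elif m == best:
                hits.extend((name, int(p), strandcode) for p in np.flatnonzero(mm == m))
    if best > max_mismatch:
        return [], -1
    return sorted(hits), best


# ---------------------------------------------------------------------------
# SAM output


def sam_header(ref: ReferenceGenome) -> str:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name, seq in ref.contigs.items():
        lines.append(f"@SQ\tSN:{name}\tLN:{len(seq)}")
    lines.append("@PG\tID:rfpsim\tPN:rfpsim")
    return "\n".join(lines) + "\n"


def _sam_flag(a: Alignment) -> int:
    flag = 0
    if a.is_paired:
        flag |= 1
        if a.is_proper:
            flag |= 2
        if a.mate_unmapped:
            flag |= 8
        if a.mate_strand == "-":
            flag |= 32
        flag |= 128 if a.is_read2 else 64
    if a.unmapped:
        flag |= 4
    if a.strand == "-":
        flag |= 16
    return flag


def read_sam(path) -> list[Alignment]:
    """Read the subset of SAM emitted by :func:`write_sam` back into
    alignment records (ungapped, NM-tagged)."""
    out: list[Alignment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("@"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 11:
                raise ValueError(f"line {lineno}: fewer than 11 SAM fields")
            qname, flag_s, rname, pos_s, mapq_s, _cigar, rnext, pnext, tlen, seq, qual = fields[:11]
            flag = int(flag_s)
            nm = -1
            ties = 1
            for tag in fields[11:]:
                if tag.startswith("NM:i:"):
                    nm = int(tag[5:])
                elif tag.startswith("XT:i:"):
                    ties = int(tag[5:])
            unmapped = bool(flag & 4)
            out.append(Alignment(
                read_id=qname,
                contig=rname,
                pos=int(pos_s),
                strand="*" if unmapped else ("-" if flag & 16 else "+"),
                mismatches=nm,
                score=-nm if nm >= 0 else 0,
                mapq=int(mapq_s),
                tie_count=ties if not unmapped else 0,
                is_paired=bool(flag & 1),
                is_proper=bool(flag & 2),
                unmapped=unmapped,
                mate_unmapped=bool(flag & 8),
                is_read2=bool(flag & 128),
                mate_contig=rname if rnext == "=" else rnext,
                mate_pos=int(pnext),
                mate_strand="-" if flag & 32 else "+",
                tlen=int(tlen),
                seq=seq,
                qual=qual,
            ))
    return out


def write_sam(alignments: Iterable[Alignment], ref: ReferenceGenome, path,
              sort_by_coordinate: bool = False) -> None:
    """Emit alignments as uncompressed SAM with NM tags."""
    alns = list(alignments)
    if sort_by_coordinate:
        order = {name: i for i, name in enumerate(ref.contigs)}
        alns.sort(key=lambda a: (a.unmapped, order.get(a.contig, len(order)), a.pos))
    with open(path, "w") as fh:
        fh.write(sam_header(ref))
        rl_cache: dict[int, str] = {}
        for a in alns:
            cigar = "*" if a.unmapped else rl_cache.setdefault(
                len(a.seq), f"{len(a.seq)}M")
            rnext = "*"
            if a.is_paired and not a.mate_unmapped:
                rnext = "=" if a.mate_contig == a.contig else a.mate_contig
            fields = [
                a.read_id, str(_sam_flag(a)), a.contig if not a.unmapped else "*",
                str(a.pos), str(a.mapq), cigar, rnext,
                str(a.mate_pos), str(a.tlen), a.seq, a.qual,
            ]
            if not a.unmapped:
                fields.append(f"NM:i:{a.mismatches}")
                fields.append(f"XT:i:{a.tie_count}")  # tie-set size
            fh.write("\t".join(fields) + "\n")
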