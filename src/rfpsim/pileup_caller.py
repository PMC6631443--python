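"""Pileup construction and two independent SNV-calling rules.

Two callers with different philosophies are provided so that their
intersection behaviour can be studied: caller ``A`` is a plain
depth/count/fraction threshold rule, caller ``B`` scores diploid
genotype likelihoods under a binomial read-sampling model.  Both operate
on the same pileups.  Duplicate fragments are collapsed before piling
(rmdup semantics), and reads with MAPQ below ``min_mapq`` are excluded —
the default of 0 *includes* tied (MAPQ 0) reads, which is what lets
misassigned reads reach the caller at all.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._seq import BASES, encode
from .genome_forge import ReferenceGenome
from .micro_aligner import Alignment, AlignmentBatch

VariantKey = tuple[str, int, str, str]  # (contig, 1-based pos, ref, alt)


@dataclass
class PileupSite:
    contig: str
    pos: int  # 1-based
    ref: str
    depth: int
    allele_counts: dict[str, int]
    mapq0: int


@dataclass
class VariantCall:
    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float
    caller_id: str
    filter_status: str = "PASS"

    def key(self) -> VariantKey:
        return (self.contig, self.pos, self.ref, self.alt)


class PileupSites:
    """Per-contig allele-count arrays (shape (L, 5): A,C,G,T,N)."""

    def __init__(self, ref: ReferenceGenome):
        self.ref = ref
        self.counts = {name: np.zeros((len(seq), 5), dtype=np.int32)
                       for name, seq in ref.contigs.items()}
        self.mapq0 = {name: np.zeros(len(seq), dtype=np.int32)
                      for name, seq in ref.contigs.items()}

    def depth(self, contig: str) -> np.ndarray:
        return self.counts[contig].sum(axis=1)

    def site(self, contig: str, pos1: int) -> PileupSite | None:
        row = self.counts[contig][pos1 - 1]
        depth = int(row.sum())
        if depth == 0:
            return None
        return PileupSite(
            contig=contig, pos=pos1,
            ref=BASES[int(self.ref.contigs[contig][pos1 - 1])],
            depth=depth,
            allele_counts={BASES[i]: int(row[i]) for i in range(5) if row[i]},
            mapq0=int(self.mapq0[contig][pos1 - 1]),
        )

    def covered_sites(self, contig: str) -> Iterable[PileupSite]:
        for pos0 in np.flatnonzero(self.depth(contig)):
            yield self.site(contig, int(pos0) + 1)


def _dedup_keys(keys: np.ndarray) -> np.ndarray:
    """Indices of the first occurrence of each row (rmdup: keep one read
    per identical fragment signature)."""
    _, first = np.unique(keys, axis=0, return_index=True)
    return np.sort(first)


def build_pileup(alignments, ref: ReferenceGenome, min_mapq: int = 0) -> PileupSites:
    """Pile aligned bases after duplicate collapse and MAPQ filtering.

    Accepts an :class:`AlignmentBatch` (fast path) or an iterable of
    :class:`Alignment` records carrying their sequences.
    """
    pile = PileupSites(ref)
    if isinstance(alignments, AlignmentBatch):
        _pile_batch(alignments, ref, min_mapq, pile)
    else:
        _pile_records(list(alignments), ref, min_mapq, pile)
    return pile


def _pile_batch(ab: AlignmentBatch, ref: ReferenceGenome, min_mapq: int,
                pile: PileupSites) -> None:
    rl = ab.batch.read_length
    n = ab.n_pairs
    # fragment signature: both mates' global positions and strands;
    # orphan mates fall back to their own coordinates with a -1 partner
    sig = np.stack([ab.pos[0], ab.strand[0].astype(np.int64),
                    ab.pos[1], ab.strand[1].astype(np.int64)], axis=1)
    keep_pairs = _dedup_keys(sig)
    keep_mask = np.zeros(n, dtype=bool)
    keep_mask[keep_pairs] = True

    offs = np.arange(rl, dtype=np.int64)
    for m in range(2):
        sel = keep_mask & (ab.pos[m] >= 0) & (ab.mapq[m] >= min_mapq)
        idx = np.flatnonzero(sel)
        if len(idx) == 0:
            continue
        oriented = ab.oriented_reads(m)[idx]
        starts = ab.pos[m][idx]
        gpos = starts[:, None] + offs[None, :]
        flat_pos = gpos.ravel()
        flat_allele = oriented.ravel().astype(np.int64)
        # translate global coords to per-contig arrays
        for ci, name in enumerate(ab.index.contig_names):
            lo = ab.index.offsets[name]
            hi = lo + ab.index.lengths[name]
            inside = (flat_pos >= lo) & (flat_pos < hi)
            if not inside.any():
                continue
            np.add.at(pile.counts[name], (flat_pos[inside] - lo, flat_allele[inside]), 1)
        m0 = ab.mapq[m][idx] == 0
        if m0.any():
            zpos = gpos[m0].ravel()
            for name in ab.index.contig_names:
                lo = ab.index.offsets[name]
                hi = lo + ab.index.lengths[name]
                inside = (zpos >= lo) & (zpos < hi)
                if inside.any():
                    np.add.at(pile.mapq0[name], zpos[inside] - lo, 1)


def _pile_records(alns: list[Alignment], ref: ReferenceGenome, min_mapq: int,
                  pile: PileupSites) -> None:
    seen: set[tuple] = set()
    for a in alns:
        if a.unmapped:
            continue
        if a.contig not in ref.contigs:
            raise ValueError(f"alignment on unknown contig {a.contig!r}")
        end0 = a.pos - 1 + len(a.seq)
        if end0 > len(ref.contigs[a.contig]):
            raise ValueError(f"alignment beyond contig end: {a.contig}:{a.pos}")
        sig = (a.contig, a.pos, a.strand, a.mate_contig, a.mate_pos, a.is_read2)
        if sig in seen:
            continue
        seen.add(sig)
        if a.mapq < min_mapq:
            continue
        codes = encode(a.seq)
        np.add.at(pile.counts[a.contig],
                  (np.arange(a.pos - 1, end0), codes.astype(np.int64)), 1)
        if a.mapq == 0:
            pile.mapq0[a.contig][a.pos - 1 : end0] += 1


# ---------------------------------------------------------------------------
# caller A: depth/count/fraction thresholds


def call_A_threshold(pileups: PileupSites, min_depth: int = 5,
                     min_alt_count: int = 3, min_alt_frac: float = 0.2
                     ) -> list[VariantCall]:
    """Emit every non-reference allele passing depth, count and fraction
    gates; qual is the supporting read count."""
    calls: list[VariantCall] = []
    for name, counts in pileups.counts.items():
        refcodes = pileups.ref.contigs[name]
        depth = counts.sum(axis=1)
        covered = depth >= min_depth
        if not covered.any():
            continue
        for allele in range(4):
            ac = counts[:, allele]
            ok = covered & (ac >= min_alt_count) & (refcodes != allele) \
                & (ac >= min_alt_frac * depth)
            for pos0 in np.flatnonzero(ok):
                calls.append(VariantCall(
                    contig=name, pos=int(pos0) + 1,
                    ref=BASES[int(refcodes[pos0])], alt=BASES[allele],
                    qual=float(ac[pos0]), caller_id="A"))
    calls.sort(key=lambda c: (c.contig, c.pos, c.alt))
    return calls


# ---------------------------------------------------------------------------
# caller B: binomial genotype likelihoods


def call_B_likelihood(pileups: PileupSites, error: float = 0.01,
                      min_posterior_ratio: float = 10.0) -> list[VariantCall]:
    """Diploid genotype-likelihood rule.

    Per covered site, the most-supported non-reference allele is tested:
    genotypes RR / RA / AA give alt-read probabilities error, 0.5 and
    1 - error under a Binomial(depth, .) model.  The site is called when
    the best non-RR likelihood exceeds the RR likelihood by
    ``min_posterior_ratio``; qual is 10 log10 of the ratio, rounded.
    """
    calls: list[VariantCall] = []
    log_e, log_1e = np.log(error), np.log(1 - error)
    log_h = np.log(0.5)
    for name, counts in pileups.counts.items():
        refcodes = pileups.ref.contigs[name]
        acgt = counts[:, :4]
        depth = acgt.sum(axis=1)
        covered = np.flatnonzero(depth > 0)
        if len(covered) == 0:
            continue
        sub = acgt[covered].astype(np.int64)
        rc = refcodes[covered].astype(np.int64)
        nonref = sub.copy()
        valid_ref = rc < 4
        nonref[valid_ref, rc[valid_ref]] = -1
        alt_allele = nonref.argmax(axis=1)
        k = nonref[np.arange(len(sub)), alt_allele]
        n = depth[covered]
        with np.errstate(invalid="ignore"):
            ll_rr = k * log_e + (n - k) * log_1e
            ll_ra = n * log_h
            ll_aa = k * log_1e + (n - k) * log_e
        best_alt_ll = np.maximum(ll_ra, ll_aa)
        log_ratio = best_alt_ll - ll_rr
        thresh = np.log(min_posterior_ratio)
        ok = (k > 0) & valid_ref & (log_ratio >= thresh)
        for i in np.flatnonzero(ok):
            pos0 = int(covered[i])
            calls.append(VariantCall(
                contig=name, pos=pos0 + 1, ref=BASES[int(rc[i])],
                alt=BASES[int(alt_allele[i])],
                qual=float(np.round(10 * log_ratio[i] / np.log(10))),
                caller_id="B"))
    calls.sort(key=lambda c: (c.contig, c.pos, c.alt))
    return calls


def call_variants(pileups: PileupSites, caller_id: str = "A", **params) -> list[VariantCall]:
    if caller_id == "A":
        return call_A_threshold(pileups, **params)
    if caller_id == "B":
        return call_B_likelihood(pileups, **params)
    raise ValueError(f"unknown caller {caller_id!r}")


# ---------------------------------------------------------------------------
# VCF 4.2 I/O


class VcfParseError(ValueError):
    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def write_vcf(calls: Sequence[VariantCall], ref: ReferenceGenome, path,
              extra_filters: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rfpsim\n")
        for name, seq in ref.contigs.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        for fid, desc in (extra_filters or {}).items():
            fh.write(f'##FILTER=<ID={fid},Description="{desc}">\n')
        fh.write('##INFO=<ID=CALLER,Number=1,Type=String,Description="Calling rule">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(calls, key=lambda c: (c.contig, c.pos, c.alt)):
            fh.write(f"{c.contig}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t"
                     f"{c.qual:g}\t{c.filter_status}\tCALLER={c.caller_id}\n")


def read_vcf(path) -> list[VariantCall]:
    calls: list[VariantCall] = []
    with open(path) as fh:
        saw_header = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                saw_header = True
                continue
            if not saw_header:
                raise VcfParseError("record before #CHROM header", lineno)
            fields = line.split("\t")
            if len(fields) < 8:
                raise VcfParseError(f"expected >=8 tab-separated fields, got {len(fields)}",
                                    lineno)
            contig, pos_s, _id, ref_a, alt_a, qual_s, filt, info = fields[:8]
            try:
                pos = int(pos_s)
            except ValueError:
                raise VcfParseError(f"non-integer POS {pos_s!r}", lineno) from None
            if not ref_a or not alt_a or len(ref_a) != 1 or len(alt_a) != 1:
                raise VcfParseError("only single-nucleotide REF/ALT supported", lineno)
            try:
                qual = float(qual_s) if qual_s != "." else 0.0
            except ValueError:
                raise VcfParseError(f"non-numeric QUAL {qual_s!r}", lineno) from None
            caller = "A"
            for kv in info.split(";"):
                if kv.startswith("CALLER="):
                    caller = kv.split("=", 1)[1]
            calls.append(VariantCall(contig=contig, pos=pos, ref=ref_a, alt=alt_a,
                                     qual=qual, caller_id=caller, filter_status=filt))
    return calls


def call_keys(calls: Iterable[VariantCall]) -> set[VariantKey]:
    return {c.key() for c in calls}
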