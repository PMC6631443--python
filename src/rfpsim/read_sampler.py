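"""Paired-end short-read simulation with substitution-only error.

Fragments are sampled uniformly, with replacement, from the padded
target space of an individual genome (the exome-capture analogue of
redundant random sampling), one haplotype per fragment.  Each base is
substituted independently at ``error_rate`` to a uniformly chosen
different base.  Mate 2 is reverse-complemented.  Qualities are a
constant Q25: downstream tools must not rely on quality variation.
"""
from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
from Bio import SeqIO

from ._seq import decode, encode, revcomp_rows
from .genome_forge import IndividualGenome

DEFAULT_QUALITY = 25


@dataclass
class SamplerConfig:
    read_length: int = 120
    error_rate: float = 0.01
    n_pairs: int | None = None
    target_coverage: float | None = None
    insert_mean: float = 500.0
    insert_sd: float = 50.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if (self.n_pairs is None) == (self.target_coverage is None):
            raise ValueError("set exactly one of n_pairs / target_coverage")
        if self.insert_mean < 2 * self.read_length:
            warnings.warn("insert_mean below twice the read length; mates will overlap",
                          stacklevel=2)


@dataclass
class ReadPair:
    read_id: str
    seq1: str
    seq2: str
    qual1: str
    qual2: str
    # true origin, for diagnostics only
    contig: str = ""
    fragment_start: int = -1
    fragment_end: int = -1
    haplotype: int = 0


@dataclass
class ReadBatch:
    """Vectorized container for one round of simulated pairs.

    ``mate1``/``mate2`` are (n_pairs, read_length) code matrices in
    sequencing orientation (mate2 already reverse-complemented).
    """

    mate1: np.ndarray
    mate2: np.ndarray
    contig: list[str]
    fragment_start: np.ndarray
    fragment_end: np.ndarray
    haplotype: np.ndarray
    read_ids: list[str] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return self.mate1.shape[0]

    @property
    def read_length(self) -> int:
        return self.mate1.shape[1]

    def __iter__(self) -> Iterator[ReadPair]:
        qual = chr(DEFAULT_QUALITY + 33) * self.read_length
        for i in range(self.n_pairs):
            rid = self.read_ids[i] if self.read_ids else f"sim_{i}"
            yield ReadPair(
                read_id=rid,
                seq1=decode(self.mate1[i]),
                seq2=decode(self.mate2[i]),
                qual1=qual,
                qual2=qual,
                contig=self.contig[i],
                fragment_start=int(self.fragment_start[i]),
                fragment_end=int(self.fragment_end[i]),
                haplotype=int(self.haplotype[i]),
            )


def _apply_errors(mat: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base independently at ``error_rate`` to one of the
    three other bases, uniformly."""
    if error_rate <= 0:
        return mat
    mask = rng.random(mat.shape) < error_rate
    if not mask.any():
        return mat
    shifts = rng.integers(1, 4, size=int(mask.sum()))
    out = mat.copy()
    out[mask] = (out[mask] + shifts) % 4
    return out


def sample_reads(individual: IndividualGenome, cfg: SamplerConfig) -> ReadBatch:
    """Simulate one batch of paired-end reads from an individual genome."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    rl = cfg.read_length
    intervals = individual.reference.sampling_intervals()
    usable = [(name, lo, hi) for name, lo, hi in intervals if hi - lo >= 2 * rl]
    if not usable:
        raise ValueError("no sampling interval can hold a read pair")
    lengths = np.array([hi - lo for _, lo, hi in usable], dtype=np.float64)
    space = float(lengths.sum())

    if cfg.n_pairs is not None:
        n_pairs = cfg.n_pairs
    else:
        n_pairs = int(np.ceil(cfg.target_coverage * space / (2 * rl)))

    iv_idx = rng.choice(len(usable), size=n_pairs, p=lengths / space)
    frag_len = rng.normal(cfg.insert_mean, cfg.insert_sd, size=n_pairs)
    frag_len = np.clip(np.rint(frag_len), 2 * rl, 2000).astype(np.int64)
    iv_lengths = np.array([hi - lo for _, lo, hi in usable], dtype=np.int64)
    too_long = frag_len > iv_lengths[iv_idx]
    if too_long.any():
        warnings.warn(f"{int(too_long.sum())} fragments truncated to fit short regions",
                      stacklevel=2)
        frag_len[too_long] = iv_lengths[iv_idx][too_long]
    start_span = iv_lengths[iv_idx] - frag_len + 1
    starts = np.array([lo for _, lo, _ in usable], dtype=np.int64)[iv_idx]
    starts = starts + (rng.random(n_pairs) * start_span).astype(np.int64)
    ends = starts + frag_len
    hap_idx = rng.integers(0, 2, size=n_pairs)

    mate1 = np.empty((n_pairs, rl), dtype=np.uint8)
    mate2 = np.empty((n_pairs, rl), dtype=np.uint8)
    contigs = [usable[int(i)][0] for i in iv_idx]
    hap_cache = {name: individual.haplotypes[name] for name in set(contigs)}
    for i in range(n_pairs):
        hap = hap_cache[contigs[i]][hap_idx[i]]
        s, e = starts[i], ends[i]
        mate1[i] = hap[s : s + rl]
        mate2[i] = hap[e - rl : e]
    mate2 = revcomp_rows(mate2)

    mate1 = _apply_errors(mate1, cfg.error_rate, rng)
    mate2 = _apply_errors(mate2, cfg.error_rate, rng)
    read_ids = [f"sim_{i}" for i in range(n_pairs)]
    return ReadBatch(mate1=mate1, mate2=mate2, contig=contigs,
                     fragment_start=starts, fragment_end=ends,
                     haplotype=hap_idx, read_ids=read_ids)


# ---------------------------------------------------------------------------
# FASTQ I/O (Phred+33, gzip-transparent)


def _open_text(path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_fastq(batch: ReadBatch | list[ReadPair], path1, path2) -> None:
    """Write mates to two FASTQ files with /1 and /2 suffixes."""
    with _open_text(path1, "w") as f1, _open_text(path2, "w") as f2:
        for pair in batch:
            f1.write(f"@{pair.read_id}/1\n{pair.seq1}\n+\n{pair.qual1}\n")
            f2.write(f"@{pair.read_id}/2\n{pair.seq2}\n+\n{pair.qual2}\n")


def read_fastq(path1, path2) -> list[ReadPair]:
    """Read mate FASTQ files back into pairs; validates length consistency."""
    pairs: list[ReadPair] = []
    with _open_text(path1, "r") as f1, _open_text(path2, "r") as f2:
        it1 = SeqIO.parse(f1, "fastq")
        it2 = SeqIO.parse(f2, "fastq")
        for rec1, rec2 in zip(it1, it2, strict=True):
            q1 = "".join(chr(q + 33) for q in rec1.letter_annotations["phred_quality"])
            q2 = "".join(chr(q + 33) for q in rec2.letter_annotations["phred_quality"])
            rid = rec1.id.removesuffix("/1")
            if rec2.id.removesuffix("/2") != rid:
                raise ValueError(f"mate id mismatch: {rec1.id} vs {rec2.id}")
            pairs.append(ReadPair(read_id=rid, seq1=str(rec1.seq).upper(),
                                  seq2=str(rec2.seq).upper(), qual1=q1, qual2=q2))
    return pairs


def batch_from_pairs(pairs: list[ReadPair]) -> ReadBatch:
    """Re-vectorize pairs read from FASTQ for alignment."""
    if not pairs:
        return ReadBatch(mate1=np.empty((0, 0), dtype=np.uint8),
                         mate2=np.empty((0, 0), dtype=np.uint8), contig=[],
                         fragment_start=np.empty(0, dtype=np.int64),
                         fragment_end=np.empty(0, dtype=np.int64),
                         haplotype=np.empty(0, dtype=np.int64), read_ids=[])
    rl = len(pairs[0].seq1)
    mate1 = np.stack([encode(p.seq1) for p in pairs])
    mate2 = np.stack([encode(p.seq2) for p in pairs])
    if mate1.shape[1] != rl or mate2.shape[1] != rl:
        raise ValueError("inconsistent read lengths")
    return ReadBatch(mate1=mate1, mate2=mate2, contig=[p.contig for p in pairs],
                     fragment_start=np.array([p.fragment_start for p in pairs]),
                     fragment_end=np.array([p.fragment_end for p in pairs]),
                     haplotype=np.array([p.haplotype for p in pairs]),
                     read_ids=[p.read_id for p in pairs])
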