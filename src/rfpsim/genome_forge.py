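"""Synthetic reference genomes with near-identical paralog families.

The generator emulates an exome-like setting: exon-sized target regions
separated by intergenic background, a configurable number of paralogous
gene families whose copies diverge at a controlled per-base rate, and
optional pseudogene-like copies that are present in the reference but
excluded from the sequenced target space.  Every difference site between
paralog copies is recorded in a :class:`ParalogLedger`, which serves as
the ground-truth oracle for the read-misassignment mechanism.

Paralogy in real genomes extends beyond coding exons into UTRs and
flanking non-coding sequence, so the duplicated unit here is the full
``copy_length`` block; the exon-like *target* is the block minus a
``pad_length`` margin on each side.  Unique (non-paralogous) targets are
plain background intervals.
"""
from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import BASES, decode, encode, random_sequence

DEFAULT_CONTIG = "synth1"


class FastaParseError(ValueError):
    """Malformed FASTA input; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass
class SyntheticGenomeSpec:
    """Parameters of a synthetic reference genome.

    ``copy_length`` is the length of the full duplicated block of a
    paralog family; the exon-like target inside each block is
    ``copy_length - 2 * pad_length``.  ``paralog_identity`` is the
    expected per-base identity between copies of a family (difference
    sites are Bernoulli at rate ``1 - paralog_identity``).
    """

    genome_length: int = 100_000
    n_paralog_families: int = 1
    copies_per_family: int = 2
    copy_length: int = 8_000
    paralog_identity: float = 0.99
    pad_length: int = 325
    gc_content: float = 0.5
    include_pseudogene: bool | Sequence[bool] = False
    rng_seed: int = 0
    # extension fields (not part of the minimal surface): unique exon-like
    # targets placed in background sequence, used for null controls and
    # for planting variants outside paralogs.
    n_unique_targets: int | None = None
    target_length: int | None = None

    def pseudogene_flags(self) -> list[bool]:
        if isinstance(self.include_pseudogene, bool):
            return [self.include_pseudogene] * self.n_paralog_families
        flags = list(self.include_pseudogene)
        if len(flags) != self.n_paralog_families:
            raise ValueError("include_pseudogene must be a bool or one flag per family")
        return flags

    def validate(self) -> None:
        if self.n_paralog_families < 0 or self.copies_per_family < 2:
            raise ValueError("need copies_per_family >= 2")
        if self.n_paralog_families > 0 and not (0.9 < self.paralog_identity < 1.0):
            raise ValueError("paralog_identity must lie strictly in (0.9, 1.0)")
        if self.copy_length <= 2 * self.pad_length:
            raise ValueError("copy_length must exceed twice pad_length")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be a fraction in (0, 1)")


@dataclass
class CopyInterval:
    contig: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    is_pseudogene: bool = False

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ParalogFamily:
    """One duplicated family: copy intervals plus difference sites.

    ``diff_sites`` maps block offset -> per-copy base codes at that
    offset (tuple of length n_copies).  ``identity`` holds the realized
    identity of each non-ancestral copy versus copy 0, computed exactly
    as ``1 - n_diff / copy_length``.
    """

    copies: list[CopyInterval]
    diff_sites: dict[int, tuple[int, ...]]
    identity: list[float]

    @property
    def copy_length(self) -> int:
        return len(self.copies[0])

    def diff_offsets(self) -> np.ndarray:
        return np.array(sorted(self.diff_sites), dtype=np.int64)

    def genome_positions(self) -> set[tuple[str, int]]:
        """All (contig, pos0) covered by any copy of this family."""
        out: set[tuple[str, int]] = set()
        for cp in self.copies:
            out.update((cp.contig, p) for p in range(cp.start, cp.end))
        return out


@dataclass
class ParalogLedger:
    """Ground truth for all duplicated intervals and their differences."""

    families: list[ParalogFamily] = field(default_factory=list)

    def locate(self, contig: str, pos0: int) -> tuple[int, int, int] | None:
        """Return (family_idx, copy_idx, offset) for a genomic position, or None."""
        for fi, fam in enumerate(self.families):
            for ci, cp in enumerate(fam.copies):
                if cp.contig == contig and cp.start <= pos0 < cp.end:
                    return fi, ci, pos0 - cp.start
        return None

    def copy_intervals(self) -> list[CopyInterval]:
        return [cp for fam in self.families for cp in fam.copies]

    def difference_site_positions(self) -> set[tuple[str, int]]:
        """Genomic (contig, pos0) of every inter-copy difference site."""
        out: set[tuple[str, int]] = set()
        for fam in self.families:
            for off in fam.diff_sites:
                for cp in fam.copies:
                    out.add((cp.contig, cp.start + off))
        return out

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        copies_rows = []
        diff_rows = []
        for fi, fam in enumerate(self.families):
            for ci, cp in enumerate(fam.copies):
                copies_rows.append(
                    dict(family=fi, copy=ci, contig=cp.contig, start0=cp.start,
                         end0=cp.end, pseudogene=cp.is_pseudogene,
                         identity_vs_copy0=fam.identity[ci])
                )
            for off, alleles in sorted(fam.diff_sites.items()):
                for ci, code in enumerate(alleles):
                    diff_rows.append(
                        dict(family=fi, offset=off, copy=ci,
                             contig=fam.copies[ci].contig,
                             pos0=fam.copies[ci].start + off, base=BASES[code])
                    )
        return pd.DataFrame(copies_rows), pd.DataFrame(diff_rows)


@dataclass
class ReferenceGenome:
    """Named contigs plus exon-like target intervals (0-based half-open)."""

    contigs: dict[str, np.ndarray]
    target_regions: list[tuple[str, int, int]]
    pad_length: int = 325

    def __post_init__(self) -> None:
        for name, start, end in self.target_regions:
            if name not in self.contigs:
                raise ValueError(f"target region on unknown contig {name!r}")
            if not (0 <= start < end <= len(self.contigs[name])):
                raise ValueError(f"target region {name}:{start}-{end} out of bounds")

    def contig_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def sampling_intervals(self) -> list[tuple[str, int, int]]:
        """Targets expanded by the pad on each side, merged where overlapping.

        This is the sequenced space: exon plus flanking padding, the
        exome-capture analogue.
        """
        expanded: dict[str, list[tuple[int, int]]] = {}
        for name, start, end in self.target_regions:
            lo = max(0, start - self.pad_length)
            hi = min(len(self.contigs[name]), end + self.pad_length)
            expanded.setdefault(name, []).append((lo, hi))
        merged: list[tuple[str, int, int]] = []
        for name, ivs in expanded.items():
            ivs.sort()
            cur_lo, cur_hi = ivs[0]
            for lo, hi in ivs[1:]:
                if lo <= cur_hi:
                    cur_hi = max(cur_hi, hi)
                else:
                    merged.append((name, cur_lo, cur_hi))
                    cur_lo, cur_hi = lo, hi
            merged.append((name, cur_lo, cur_hi))
        return merged


@dataclass
class Variant:
    contig: str
    pos0: int
    ref: str
    alt: str
    zygosity: str = "hom"  # "hom" | "het"
    label: str = "unique"  # "unique" | "paralog"
    haplotype: int = 0  # carrier haplotype for het variants

    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos0 + 1, self.ref, self.alt)


@dataclass
class IndividualGenome:
    """A genome derived from the reference by planting SNVs.

    Two realized haplotypes are kept per contig; homozygous variants
    appear on both, heterozygous variants on ``Variant.haplotype`` only.
    """

    reference: ReferenceGenome
    variants: list[Variant]
    haplotypes: dict[str, tuple[np.ndarray, np.ndarray]]

    def variant_keys(self) -> set[tuple[str, int, str, str]]:
        return {v.key() for v in self.variants}

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dict(contig=v.contig, pos0=v.pos0, ref=v.ref, alt=v.alt,
                  zygosity=v.zygosity, label=v.label) for v in self.variants]
        )


def _mutate_copy(block: np.ndarray, rate: float, rng: np.random.Generator
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Derive a diverged copy: each position flips with probability ``rate``
    to a uniformly chosen different base.  Returns (copy, diff_offsets)."""
    mask = rng.random(len(block)) < rate
    offsets = np.flatnonzero(mask)
    out = block.copy()
    out[offsets] = (out[offsets] + rng.integers(1, 4, size=len(offsets))) % 4
    return out, offsets


def build_reference(spec: SyntheticGenomeSpec) -> tuple[ReferenceGenome, ParalogLedger]:
    """Generate a reference genome and its paralog ground-truth ledger.

    Deterministic for a given spec (identical seed => identical output).
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    pad = spec.pad_length
    target_len = spec.target_length or max(500, spec.copy_length - 2 * pad)
    pseudo = spec.pseudogene_flags()

    # family sequences: ancestral copy plus diverged siblings
    fam_blocks: list[list[np.ndarray]] = []
    fam_diffs: list[dict[int, tuple[int, ...]]] = []
    for _ in range(spec.n_paralog_families):
        ancestor = random_sequence(spec.copy_length, spec.gc_content, rng)
        blocks = [ancestor]
        per_copy_offsets = [np.empty(0, dtype=np.int64)]
        for _ci in range(1, spec.copies_per_family):
            blk, offs = _mutate_copy(ancestor, 1.0 - spec.paralog_identity, rng)
            blocks.append(blk)
            per_copy_offsets.append(offs)
        all_offsets = sorted(set(np.concatenate(per_copy_offsets).tolist()))
        diffs = {
            off: tuple(int(b[off]) for b in blocks)
            for off in all_offsets
            if len({int(b[off]) for b in blocks}) > 1
        }
        fam_blocks.append(blocks)
        fam_diffs.append(diffs)

    # plan placement: paralog blocks and unique targets in shuffled order,
    # separated by gaps wide enough that padded targets never collide
    regions: list[tuple[str, int]] = []  # (kind, index) kind in {copy, unique}
    for fi in range(spec.n_paralog_families):
        for ci in range(spec.copies_per_family):
            regions.append(("copy", fi * spec.copies_per_family + ci))

    gap_lo, gap_hi = 2 * pad + 100, 2 * pad + 400
    paralog_span = spec.n_paralog_families * spec.copies_per_family * spec.copy_length
    fixed_overhead = (len(regions) + 1) * gap_hi
    if paralog_span + fixed_overhead > spec.genome_length:
        raise ValueError(
            f"paralog copies ({paralog_span} bp plus spacing) do not fit in "
            f"genome_length={spec.genome_length}"
        )
    if spec.n_unique_targets is None:
        free = spec.genome_length - paralog_span - fixed_overhead
        n_unique = max(0, int(0.7 * free) // (target_len + gap_hi))
        # worst-case feasibility with maximal gaps
        while n_unique > 0 and (paralog_span + n_unique * target_len
                                + (len(regions) + n_unique + 1) * gap_hi
                                > spec.genome_length):
            n_unique -= 1
    else:
        n_unique = spec.n_unique_targets
    for ui in range(n_unique):
        regions.append(("unique", ui))
    rng.shuffle(regions)  # type: ignore[arg-type]

    genome = random_sequence(spec.genome_length, spec.gc_content, rng)
    contig = DEFAULT_CONTIG
    copy_intervals: dict[int, CopyInterval] = {}
    targets: list[tuple[str, int, int]] = []
    cursor = 0
    for kind, idx in regions:
        cursor += int(rng.integers(gap_lo, gap_hi + 1))
        length = spec.copy_length if kind == "copy" else target_len
        if cursor + length + gap_lo > spec.genome_length:
            raise ValueError(
                "regions do not fit: reduce n_unique_targets/copies or grow genome_length"
            )
        if kind == "copy":
            fi, ci = divmod(idx, spec.copies_per_family)
            genome[cursor : cursor + length] = fam_blocks[fi][ci]
            is_pseudo = pseudo[fi] and ci == spec.copies_per_family - 1
            copy_intervals[idx] = CopyInterval(contig, cursor, cursor + length, is_pseudo)
            if not is_pseudo:
                targets.append((contig, cursor + pad, cursor + length - pad))
        else:
            targets.append((contig, cursor, cursor + length))
        cursor += length

    families = []
    for fi in range(spec.n_paralog_families):
        copies = [copy_intervals[fi * spec.copies_per_family + ci]
                  for ci in range(spec.copies_per_family)]
        diffs = fam_diffs[fi]
        blocks = fam_blocks[fi]
        ident = [1.0]
        for ci in range(1, spec.copies_per_family):
            n_diff = int((blocks[ci] != blocks[0]).sum())
            ident.append(1.0 - n_diff / spec.copy_length)
        families.append(ParalogFamily(copies=copies, diff_sites=diffs, identity=ident))

    ref = ReferenceGenome(contigs={contig: genome},
                          target_regions=sorted(targets, key=lambda t: t[1]),
                          pad_length=pad)
    return ref, ParalogLedger(families=families)


def derive_individual(
    ref: ReferenceGenome,
    n_private_snvs: int,
    fraction_in_paralogs: float = 0.0,
    zygosity_mode: str = "hom",
    seed: int = 0,
    ledger: ParalogLedger | None = None,
    base_variants: Sequence[Variant] | None = None,
    max_retries: int = 50,
) -> IndividualGenome:
    """Plant private SNVs into a copy of the reference.

    Positions are drawn uniformly without replacement from the target
    space: ``fraction_in_paralogs`` of them from targets inside paralog
    copies (requires ``ledger``), the rest from unique targets.  Ledger
    difference sites are excluded from the placement pool so planted
    alleles never coincide with inter-copy differences.  ``base_variants``
    (e.g. a shared strain background) are applied first and their
    positions blocked.
    """
    if fraction_in_paralogs > 0 and ledger is None:
        raise ValueError("fraction_in_paralogs > 0 requires the paralog ledger")
    rng = np.random.default_rng(seed)
    occupied = {(v.contig, v.pos0) for v in (base_variants or [])}

    copy_positions: set[tuple[str, int]] = set()
    diff_positions: set[tuple[str, int]] = set()
    if ledger is not None:
        for fam in ledger.families:
            copy_positions |= fam.genome_positions()
        diff_positions = ledger.difference_site_positions()

    pool_par: list[tuple[str, int]] = []
    pool_uni: list[tuple[str, int]] = []
    for name, start, end in ref.target_regions:
        for p in range(start, end):
            key = (name, p)
            if key in occupied or key in diff_positions:
                continue
            (pool_par if key in copy_positions else pool_uni).append(key)

    n_par = int(round(n_private_snvs * fraction_in_paralogs))
    n_uni = n_private_snvs - n_par
    if n_par > len(pool_par) or n_uni > len(pool_uni):
        raise ValueError("n_private_snvs exceeds available target positions")

    variants: list[Variant] = list(base_variants or [])
    for pool, count, label in ((pool_par, n_par, "paralog"), (pool_uni, n_uni, "unique")):
        if count == 0:
            continue
        picks = rng.choice(len(pool), size=count, replace=False)
        for i in picks:
            contig, pos0 = pool[int(i)]
            ref_code = int(ref.contigs[contig][pos0])
            alt_code = (ref_code + int(rng.integers(1, 4))) % 4
            if zygosity_mode == "hom":
                zyg, hap = "hom", 0
            elif zygosity_mode == "het":
                zyg, hap = "het", int(rng.integers(0, 2))
            elif zygosity_mode == "mixed":
                zyg = "hom" if rng.random() < 0.5 else "het"
                hap = 0 if zyg == "hom" else int(rng.integers(0, 2))
            else:
                raise ValueError(f"unknown zygosity_mode {zygosity_mode!r}")
            variants.append(Variant(contig, pos0, BASES[ref_code], BASES[alt_code],
                                    zygosity=zyg, label=label, haplotype=hap))

    seen: set[tuple[str, int]] = set()
    for v in variants:
        if (v.contig, v.pos0) in seen:
            raise ValueError(f"variant position collision at {v.contig}:{v.pos0}")
        seen.add((v.contig, v.pos0))
        if BASES[ref.contigs[v.contig][v.pos0]] != v.ref:
            raise ValueError(f"ref allele mismatch at {v.contig}:{v.pos0}")

    haplotypes: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, seq in ref.contigs.items():
        hap0, hap1 = seq.copy(), seq.copy()
        haplotypes[name] = (hap0, hap1)
    for v in variants:
        alt_code = BASES.index(v.alt)
        hap0, hap1 = haplotypes[v.contig]
        if v.zygosity == "hom":
            hap0[v.pos0] = alt_code
            hap1[v.pos0] = alt_code
        else:
            (hap0 if v.haplotype == 0 else hap1)[v.pos0] = alt_code
    return IndividualGenome(reference=ref, variants=variants, haplotypes=haplotypes)


def predicted_miscall_sites(
    ledger: ParalogLedger,
    ref: ReferenceGenome,
    individual: IndividualGenome | None = None,
) -> set[tuple[str, int, str, str]]:
    """Ground-truth prediction of miscall-prone variant keys.

    For every ordered pair of copies (source -> destination) in each
    family, a read sampled from the source copy and misassigned to the
    destination deposits the source base wherever it differs from the
    destination's reference base.  The predicted keys are those
    (contig, pos1, ref, alt) combinations: they cover both reference
    inter-copy difference sites and, when an individual is supplied, the
    homologs of its in-paralog variants carrying the individual's allele.
    Pseudogene copies are never a read source (they are not sequenced)
    but can be a destination.
    """
    keys: set[tuple[str, int, str, str]] = set()
    for fam in ledger.families:
        n = len(fam.copies)
        for si in range(n):
            src = fam.copies[si]
            if src.is_pseudogene:
                continue
            if individual is not None:
                src_seqs = [h[src.start : src.end]
                            for h in individual.haplotypes[src.contig]]
            else:
                src_seqs = [ref.contigs[src.contig][src.start : src.end]]
            for di in range(n):
                if di == si:
                    continue
                dst = fam.copies[di]
                dst_ref = ref.contigs[dst.contig][dst.start : dst.end]
                for src_seq in src_seqs:
                    offs = np.flatnonzero((src_seq != dst_ref) & (src_seq < 4))
                    for off in offs:
                        keys.add((dst.contig, dst.start + int(off) + 1,
                                  BASES[int(dst_ref[off])], BASES[int(src_seq[off])]))
    return keys


# ---------------------------------------------------------------------------
# FASTA / TSV I/O


def _open_text(path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def _validate_fasta_lines(path) -> None:
    with _open_text(path, "r") as fh:
        header_line = None
        seq_len = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if header_line is not None and seq_len == 0:
                    raise FastaParseError("record with empty sequence", header_line)
                header_line = lineno
                seq_len = 0
            else:
                if header_line is None:
                    raise FastaParseError("sequence data before any '>' header", lineno)
                bad = set(line.upper()) - set("ACGTN")
                if bad:
                    raise FastaParseError(
                        f"invalid sequence characters {sorted(bad)}", lineno)
                seq_len += len(line)
        if header_line is None:
            raise FastaParseError("no FASTA records found", 1)
        if seq_len == 0:
            raise FastaParseError("record with empty sequence", header_line)


def write_fasta(genome, path, wrap: int = 60) -> None:
    """Write contigs (or an individual's haplotypes) as wrapped FASTA."""
    if isinstance(genome, ReferenceGenome):
        records = genome.contigs
    elif isinstance(genome, IndividualGenome):
        records = {}
        for name, (h0, h1) in genome.haplotypes.items():
            if np.array_equal(h0, h1):
                records[name] = h0
            else:
                records[f"{name}_hap1"] = h0
                records[f"{name}_hap2"] = h1
    else:
        records = dict(genome)
    seqrecs = [SeqRecord(Seq(decode(arr)), id=name, description="")
               for name, arr in records.items()]
    with _open_text(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(seqrecs)


def read_fasta(path) -> dict[str, np.ndarray]:
    """Read FASTA into code arrays (lowercase upcased); strict validation."""
    _validate_fasta_lines(path)
    out: dict[str, np.ndarray] = {}
    with _open_text(path, "r") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in out:
                raise ValueError(f"duplicate contig name {rec.id!r}")
            out[rec.id] = encode(str(rec.seq))
    return out


def individual_from_variants(ref: ReferenceGenome,
                             variants: Iterable[Variant]) -> IndividualGenome:
    """Rebuild an individual genome from a reference plus variant records
    (e.g. a truth TSV written earlier)."""
    variants = list(variants)
    haplotypes = {name: (seq.copy(), seq.copy()) for name, seq in ref.contigs.items()}
    for v in variants:
        if BASES[ref.contigs[v.contig][v.pos0]] != v.ref:
            raise ValueError(f"ref allele mismatch at {v.contig}:{v.pos0}")
        alt_code = BASES.index(v.alt)
        hap0, hap1 = haplotypes[v.contig]
        if v.zygosity == "hom":
            hap0[v.pos0] = alt_code
            hap1[v.pos0] = alt_code
        else:
            (hap0 if v.haplotype == 0 else hap1)[v.pos0] = alt_code
    return IndividualGenome(reference=ref, variants=variants, haplotypes=haplotypes)


def read_variant_truth(path) -> list[Variant]:
    df = pd.read_csv(path, sep="\t")
    return [Variant(contig=r.contig, pos0=int(r.pos0), ref=r.ref, alt=r.alt,
                    zygosity=getattr(r, "zygosity", "hom"),
                    label=getattr(r, "label", "unique"),
                    haplotype=int(getattr(r, "haplotype", 0)))
            for r in df.itertuples()]


def write_targets(ref: ReferenceGenome, path) -> None:
    pd.DataFrame(ref.target_regions, columns=["contig", "start0", "end0"]) \
        .to_csv(path, sep="\t", index=False)


def reference_from_files(fasta_path, targets_path=None, pad_length: int = 325
                         ) -> ReferenceGenome:
    contigs = read_fasta(fasta_path)
    targets: list[tuple[str, int, int]] = []
    if targets_path is not None:
        df = pd.read_csv(targets_path, sep="\t")
        targets = [(r.contig, int(r.start0), int(r.end0)) for r in df.itertuples()]
    return ReferenceGenome(contigs=contigs, target_regions=targets,
                           pad_length=pad_length)


def write_ledger(ledger: ParalogLedger, copies_path, diffs_path) -> None:
    copies, diffs = ledger.to_frames()
    copies.to_csv(copies_path, sep="\t", index=False)
    diffs.to_csv(diffs_path, sep="\t", index=False)


def write_variant_truth(individual: IndividualGenome, path) -> None:
    individual.truth_frame().to_csv(path, sep="\t", index=False)
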