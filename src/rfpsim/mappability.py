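"""Alignability (mappability) tracks and the RFP-association test.

The per-position alignability score is 1 / (number of exact genome-wide
occurrences of the k-mer starting at that position, counting both
strands), so a unique k-mer scores 1.0 and a window duplicated across a
two-copy paralog family scores 0.5.  k defaults to the read length of
the run under analysis, since a read-length window is what the aligner
must place uniquely.  Counting is exact-match only — no mismatch
tolerance — which is sufficient for synthetic genomes whose redundancy
is by construction.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._seq import revcomp
from .genome_forge import ReferenceGenome


@dataclass
class AlignabilityTrack:
    k: int
    scores: dict[str, np.ndarray]  # per contig; length L - k + 1

    def value(self, contig: str, pos0: int) -> float:
        arr = self.scores[contig]
        if not 0 <= pos0 < len(arr):
            raise IndexError(f"position {pos0} lacks a full {self.k}-mer window")
        return float(arr[pos0])

    def values(self, sites: list[tuple[str, int]]) -> np.ndarray:
        return np.array([self.value(c, p) for c, p in sites])

    def site_value(self, contig: str, pos0: int) -> float:
        """Mean score over every window covering the position.

        A read calling a base at ``pos0`` may start anywhere in
        ``[pos0 - k + 1, pos0]``, so the ambiguity relevant to that
        site is the average uniqueness of all covering windows, not
        just the one starting there.
        """
        arr = self.scores[contig]
        lo = max(0, pos0 - self.k + 1)
        hi = min(pos0 + 1, len(arr))
        if hi <= lo:
            raise IndexError(f"no window covers position {pos0}")
        window = arr[lo:hi]
        if np.isnan(window).all():
            return float("nan")
        return float(np.nanmean(window))

    def site_values(self, sites: list[tuple[str, int]]) -> np.ndarray:
        return np.array([self.site_value(c, p) for c, p in sites])

    def write_bedgraph(self, path) -> None:
        """BedGraph-style TSV: contig, start0, end0, score (runs merged)."""
        with open(path, "w") as fh:
            for name, arr in self.scores.items():
                if len(arr) == 0:
                    continue
                breaks = np.flatnonzero(np.diff(arr) != 0)
                starts = np.concatenate([[0], breaks + 1])
                ends = np.concatenate([breaks + 1, [len(arr)]])
                for s, e in zip(starts, ends):
                    fh.write(f"{name}\t{s}\t{e}\t{arr[s]:g}\n")


def alignability_track(ref: ReferenceGenome, k: int = 120) -> AlignabilityTrack:
    """Exact-occurrence k-mer uniqueness per position, both strands.

    Occurrences are counted by pooling every k-length window of every
    contig on both strands and tallying identical rows, so any k up to
    the shortest contig length is supported (a read-length window is the
    typical choice).  Windows containing N carry no score.
    """
    shortest = min(len(s) for s in ref.contigs.values())
    if k > shortest:
        raise ValueError(f"k={k} exceeds shortest contig ({shortest} bp)")

    fwd_windows = []
    rev_windows = []
    for seq in ref.contigs.values():
        fwd_windows.append(np.lib.stride_tricks.sliding_window_view(seq, k))
        rev_windows.append(np.lib.stride_tricks.sliding_window_view(revcomp(seq), k))
    pool = np.ascontiguousarray(np.concatenate(fwd_windows + rev_windows, axis=0))
    _, inverse, counts = np.unique(pool, axis=0, return_inverse=True,
                                   return_counts=True)
    occ = counts[inverse]  # both-strand occurrence count of each pooled window

    scores = {}
    cursor = 0
    for (name, seq), fw in zip(ref.contigs.items(), fwd_windows):
        n = fw.shape[0]
        sc = 1.0 / occ[cursor : cursor + n]
        has_n = np.convolve((seq >= 4).astype(np.int64),
                            np.ones(k, dtype=np.int64), "valid") > 0
        scores[name] = np.where(has_n, np.nan, sc)
        cursor += n
    return AlignabilityTrack(k=k, scores=scores)


def compare_alignability(sites_a: list[tuple[str, int]],
                         sites_b: list[tuple[str, int]],
                         track: AlignabilityTrack,
                         aggregate: str = "covering") -> tuple[float, float]:
    """One-sided Welch t-test of mean(a) < mean(b) on track scores.

    ``aggregate='covering'`` scores each site as the mean over all
    windows covering it (the ambiguity a caller actually experiences);
    ``'start'`` uses the single window starting at the site.
    """
    if not sites_a or not sites_b:
        raise ValueError("both site sets must be non-empty")
    if aggregate == "covering":
        a = track.site_values(sites_a)
        b = track.site_values(sites_b)
    elif aggregate == "start":
        a = track.values(sites_a)
        b = track.values(sites_b)
    else:
        raise ValueError("aggregate must be 'covering' or 'start'")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("some sites lack a full k-mer window")
    if a.std() == 0 and b.std() == 0:
        raise ValueError("zero variance in both samples; t-test degenerate")
    res = stats.ttest_ind(a, b, equal_var=False, alternative="less")
    return float(res.statistic), float(res.pvalue)


def sample_random_sites(ref: ReferenceGenome, n: int,
                        within_target_regions: bool = True, seed: int = 0,
                        exclude: set[tuple[str, int]] | None = None,
                        track: AlignabilityTrack | None = None
                        ) -> list[tuple[str, int]]:
    """Uniform draw of n positions without replacement.

    Passing a ``track`` restricts the pool to positions carrying a full
    k-mer window, so the draw is directly usable in the association test.
    """
    pool: list[tuple[str, int]] = []
    if within_target_regions:
        regions = ref.target_regions
    else:
        regions = [(name, 0, len(seq)) for name, seq in ref.contigs.items()]
    for name, start, end in regions:
        limit = len(ref.contigs[name]) if track is None \
            else len(track.scores[name])
        for p in range(start, min(end, limit)):
            if exclude and (name, p) in exclude:
                continue
            pool.append((name, p))
    if n > len(pool):
        raise ValueError(f"requested {n} sites but only {len(pool)} available")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(pool), size=n, replace=False)
    return [pool[int(i)] for i in sorted(picks)]
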