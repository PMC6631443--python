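"""Cross-individual comparisons of variant calls and RFP catalogues.

Covers the population-frequency route to recurrent-false-positive
detection (a cohort of individuals stands in for rounds of one
individual: fixed strain variation near 100% frequency, rare
pedigree-specific variation below 5%, RFP in between), catalogue
similarity (Jaccard by default), the read-length sweep at matched base
coverage, dual-caller intersection, and blacklist soft-filtering.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_forge import IndividualGenome, ReferenceGenome
from .micro_aligner import KmerIndex, build_index
from .pileup_caller import VariantCall, VariantKey
from .rfp_engine import CallMatrix, EngineConfig, RFPCatalogue, classify, run_rounds


@dataclass
class CohortCallTable:
    """Individuals x variant-key presence table."""

    table: pd.DataFrame  # bool, index=individual ids, columns=VariantKey tuples

    @classmethod
    def from_call_sets(cls, call_sets) -> "CohortCallTable":
        """Build from a mapping id -> keys, or an iterable of (id, keys)."""
        items = list(call_sets.items()) if isinstance(call_sets, Mapping) \
            else [(i, set(s)) for i, s in call_sets]
        ids = [i for i, _ in items]
        if len(ids) != len(set(ids)):
            raise ValueError("individual ids must be unique")
        keys = sorted(set().union(*[set(s) for _, s in items]) if items else set())
        data = np.zeros((len(ids), len(keys)), dtype=bool)
        col = {k: j for j, k in enumerate(keys)}
        for i, (_, s) in enumerate(items):
            for k in s:
                data[i, col[k]] = True
        return cls(pd.DataFrame(data, index=ids, columns=pd.Index(keys)))

    @classmethod
    def from_call_matrix(cls, matrix: CallMatrix, prefix: str = "round"
                         ) -> "CohortCallTable":
        """Treat each round of one individual as a cohort member."""
        ids = [f"{prefix}_{r + 1}" for r in range(matrix.n_rounds)]
        data = matrix.incidence.T.copy()
        return cls(pd.DataFrame(data, index=ids, columns=pd.Index(matrix.keys)))

    @property
    def n_individuals(self) -> int:
        return len(self.table)

    def popfreq(self) -> pd.Series:
        return self.table.mean(axis=0)


def popfreq_classify(cohort: CohortCallTable, f_low: float = 0.05,
                     f_high: float = 0.95) -> pd.Series:
    """Per-key class from population frequency: ``fixed`` at or above
    f_high, ``rare`` at or below f_low, ``RFP`` strictly between."""
    if cohort.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    freq = cohort.popfreq()
    out = pd.Series(
        np.where(freq >= f_high, "fixed", np.where(freq <= f_low, "rare", "RFP")),
        index=freq.index, name="class")
    return out


def jaccard(set_a: Iterable[VariantKey], set_b: Iterable[VariantKey]) -> float:
    a, b = set(set_a), set(set_b)
    if not a and not b:
        warnings.warn("both sets empty; similarity defined as 1.0", stacklevel=2)
        return 1.0
    return len(a & b) / len(a | b)


@dataclass
class SimilarityMatrix:
    matrix: pd.DataFrame
    metric: str = "jaccard"

    def write(self, path) -> None:
        self.matrix.to_csv(path, sep="\t")

    def heatmap(self, path) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(1 + 0.4 * len(self.matrix),) * 2)
        im = ax.imshow(self.matrix.values, vmin=0, vmax=1, cmap="Oranges")
        ax.set_xticks(range(len(self.matrix)), self.matrix.columns, rotation=90)
        ax.set_yticks(range(len(self.matrix)), self.matrix.index)
        fig.colorbar(im, ax=ax, label=self.metric)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def similarity_matrix(catalogues: Mapping[str, Iterable[VariantKey]],
                      metric: str | Callable = "jaccard") -> SimilarityMatrix:
    if callable(metric):
        fn, name = metric, getattr(metric, "__name__", "custom")
    elif metric == "jaccard":
        fn, name = jaccard, "jaccard"
    else:
        raise ValueError(f"unknown metric {metric!r}")
    ids = list(catalogues)
    sets = {i: set(catalogues[i]) for i in ids}
    mat = np.ones((len(ids), len(ids)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, a in enumerate(ids):
            for j in range(i + 1, len(ids)):
                mat[i, j] = mat[j, i] = fn(sets[a], sets[ids[j]])
    return SimilarityMatrix(pd.DataFrame(mat, index=ids, columns=ids), metric=name)


@dataclass
class SweepResult:
    catalogues: dict[int, RFPCatalogue]
    summary: pd.DataFrame  # read_length, n_rfp, n_unique_to_length, frac_unique
    pairwise_jaccard: pd.DataFrame


def read_length_sweep(individual: IndividualGenome, ref: ReferenceGenome,
                      cfg: EngineConfig,
                      lengths: Sequence[int] = (80, 100, 120, 140),
                      index: KmerIndex | None = None) -> SweepResult:
    """Run the engine once per read length at matched base coverage.

    Coverage is specified in bases (``target_coverage``), so the pair
    count per round scales as 1/read_length and total sequenced bases
    stay constant across lengths — isolating the read-length effect.
    """
    if list(lengths) != sorted(lengths):
        raise ValueError("lengths must be ascending")
    if cfg.sampler.target_coverage is None:
        raise ValueError("sweep requires sampler.target_coverage (base-matched)")
    max_block = max((hi - lo) for _, lo, hi in ref.sampling_intervals())
    if any(2 * L > max_block for L in lengths):
        raise ValueError("read length too long for every sampling interval")
    if index is None:
        index = build_index(ref, cfg.aligner.k)
    catalogues: dict[int, RFPCatalogue] = {}
    for L in lengths:
        sub = replace(cfg, sampler=replace(cfg.sampler, read_length=L))
        matrix = run_rounds(individual, ref, sub, index=index)
        catalogues[L] = classify(matrix)

    rfp_sets = {L: cat.rfp_keys for L, cat in catalogues.items()}
    rows = []
    for L in lengths:
        others = set().union(*[rfp_sets[M] for M in lengths if M != L]) or set()
        n = len(rfp_sets[L])
        uniq = len(rfp_sets[L] - others)
        rows.append(dict(read_length=L, n_rfp=n, n_unique_to_length=uniq,
                         frac_unique=uniq / n if n else float("nan")))
    sim = similarity_matrix({str(L): rfp_sets[L] for L in lengths})
    return SweepResult(catalogues=catalogues, summary=pd.DataFrame(rows),
                       pairwise_jaccard=sim.matrix)


def intersect_callers(calls_a: Iterable, calls_b: Iterable) -> set[VariantKey]:
    """Variant keys present in both call sets (tool-agreement filter)."""

    def to_keys(calls) -> set[VariantKey]:
        out = set()
        for c in calls:
            out.add(c.key() if isinstance(c, VariantCall) else tuple(c))
        return out

    return to_keys(calls_a) & to_keys(calls_b)


def blacklist_filter(calls: Sequence[VariantCall], catalogue: RFPCatalogue
                     ) -> list[VariantCall]:
    """Soft-filter calls whose key is RFP-class in the catalogue
    (FILTER=RFP); everything else keeps its filter status."""
    rfp = catalogue.rfp_keys
    if rfp:
        cat_contigs = {k[0] for k in rfp}
        call_contigs = {c.contig for c in calls}
        if call_contigs and not (cat_contigs & call_contigs):
            raise ValueError(
                f"reference build mismatch: catalogue contigs {sorted(cat_contigs)} "
                f"share nothing with call contigs {sorted(call_contigs)}")
    out = []
    for c in calls:
        status = "RFP" if c.key() in rfp else c.filter_status
        out.append(replace(c, filter_status=status))
    return out
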