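"""The resample -> realign -> recall engine.

Repeatedly simulates reads from one individual genome, aligns them to
the reference and calls variants; assembles the per-round call sets into
a boolean incidence matrix; classifies every variant key by its call
frequency f across rounds (consistent f >= 0.95, sporadic f <= 0.05,
recurrent-false-positive strictly in between); and summarizes how the
catalogue of intermittent keys accumulates over rounds.

Per-round seeds are derived from the master seed by a counter-based
mix, so rounds are independent and reproducible in any execution order.
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("rfpsim")

from ._seq import derive_seed
from .genome_forge import IndividualGenome, ReferenceGenome
from .micro_aligner import AlignerConfig, KmerIndex, build_index, map_batch
from .pileup_caller import VariantKey, build_pileup, call_keys, call_variants
from .read_sampler import SamplerConfig, sample_reads

F_LOW = 0.05
F_HIGH = 0.95


@dataclass
class RoundResult:
    round_index: int
    seed: int
    keys: frozenset[VariantKey]


@dataclass
class EngineConfig:
    n_rounds: int = 10
    sampler: SamplerConfig = field(default_factory=lambda: SamplerConfig(target_coverage=30.0))
    aligner: AlignerConfig = field(default_factory=AlignerConfig)
    caller_id: str = "A"
    caller_params: dict = field(default_factory=dict)
    min_mapq: int = 0
    master_seed: int = 0


@dataclass
class CallMatrix:
    """Variant-key x round boolean incidence from repeated rounds."""

    keys: list[VariantKey]
    incidence: np.ndarray  # bool, shape (n_keys, n_rounds)
    round_seeds: list[int]
    metadata: dict = field(default_factory=dict)

    @property
    def n_rounds(self) -> int:
        return self.incidence.shape[1]

    def frequencies(self) -> np.ndarray:
        return self.incidence.sum(axis=1) / self.n_rounds

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.incidence,
                          columns=[f"round_{r + 1}" for r in range(self.n_rounds)])
        meta = pd.DataFrame(self.keys, columns=["contig", "pos", "ref", "alt"])
        return pd.concat([meta, df], axis=1)

    @classmethod
    def from_round_results(cls, rounds: list[RoundResult], metadata: dict | None = None
                           ) -> "CallMatrix":
        keys = sorted(set().union(*[r.keys for r in rounds]) if rounds else set())
        inc = np.zeros((len(keys), len(rounds)), dtype=bool)
        key_row = {k: i for i, k in enumerate(keys)}
        for j, rr in enumerate(rounds):
            for k in rr.keys:
                inc[key_row[k], j] = True
        return cls(keys=keys, incidence=inc,
                   round_seeds=[r.seed for r in rounds], metadata=metadata or {})


@dataclass
class RFPCatalogue:
    """Classified variant keys with per-key call frequency."""

    table: pd.DataFrame  # contig,pos,ref,alt,n_called,n_rounds,frequency,class
    metadata: dict = field(default_factory=dict)

    def keys_of_class(self, cls_name: str) -> set[VariantKey]:
        sub = self.table[self.table["class"] == cls_name]
        return {(r.contig, int(r.pos), r.ref, r.alt) for r in sub.itertuples()}

    @property
    def rfp_keys(self) -> set[VariantKey]:
        return self.keys_of_class("RFP")

    @property
    def consistent_keys(self) -> set[VariantKey]:
        return self.keys_of_class("consistent")

    def write(self, path, sidecar_path=None) -> None:
        self.table.to_csv(path, sep="\t", index=False)
        if sidecar_path is not None:
            with open(sidecar_path, "w") as fh:
                yaml.safe_dump(self.metadata, fh, sort_keys=True)


@dataclass
class AccumulationCurve:
    cumulative: np.ndarray  # per-round cumulative unique candidate keys
    increments: np.ndarray  # new-unique per round
    lambda_hat: float  # mean increment, rounds >= 2 (round 1 is burn-in)
    dispersion: float  # variance / mean of those increments


def run_single_round(individual: IndividualGenome, index: KmerIndex,
                     cfg: EngineConfig, round_index: int) -> RoundResult:
    seed = derive_seed(cfg.master_seed, round_index)
    sampler = replace(cfg.sampler, seed=seed)
    batch = sample_reads(individual, sampler)
    aln = map_batch(batch, index, cfg.aligner, master_seed=cfg.master_seed,
                    round_index=round_index)
    pile = build_pileup(aln, individual.reference, min_mapq=cfg.min_mapq)
    calls = call_variants(pile, caller_id=cfg.caller_id, **cfg.caller_params)
    return RoundResult(round_index=round_index, seed=seed,
                       keys=frozenset(call_keys(calls)))


def run_rounds(individual: IndividualGenome, ref: ReferenceGenome,
               cfg: EngineConfig, index: KmerIndex | None = None) -> CallMatrix:
    """Execute n_rounds of resample/realign/recall and build the matrix."""
    if cfg.n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    if index is None:
        index = build_index(ref, cfg.aligner.k)
    rounds = []
    for r in range(1, cfg.n_rounds + 1):
        t0 = time.time()
        try:
            rounds.append(run_single_round(individual, index, cfg, r))
        except Exception as exc:  # noqa: BLE001 - annotate failing round
            raise RuntimeError(f"round {r} failed: {exc}") from exc
        log.debug("round %d: seed %d, %d keys, %.2f s", r, rounds[-1].seed,
                  len(rounds[-1].keys), time.time() - t0)
    meta = dict(
        n_rounds=cfg.n_rounds,
        read_length=cfg.sampler.read_length,
        error_rate=cfg.sampler.error_rate,
        master_seed=cfg.master_seed,
        caller_id=cfg.caller_id,
        min_mapq=cfg.min_mapq,
    )
    return CallMatrix.from_round_results(rounds, metadata=meta)


def classify(matrix: CallMatrix, f_low: float = F_LOW, f_high: float = F_HIGH
             ) -> RFPCatalogue:
    """Partition keys by call frequency.

    RFP strictly between the thresholds; consistent at or above f_high
    (predominantly true variation, retained but flagged for downstream
    discarding); sporadic at or below f_low.
    """
    if not 0 < f_low < f_high < 1:
        raise ValueError("need 0 < f_low < f_high < 1")
    freq = matrix.frequencies()
    n_called = matrix.incidence.sum(axis=1)
    classes = np.where(freq >= f_high, "consistent",
                       np.where(freq <= f_low, "sporadic", "RFP"))
    table = pd.DataFrame(matrix.keys, columns=["contig", "pos", "ref", "alt"])
    table["n_called"] = n_called
    table["n_rounds"] = matrix.n_rounds
    table["frequency"] = freq
    table["class"] = classes
    table["caller_id"] = matrix.metadata.get("caller_id", "")
    meta = dict(matrix.metadata, f_low=f_low, f_high=f_high,
                round_seeds=list(matrix.round_seeds))
    return RFPCatalogue(table=table, metadata=meta)


def accumulation(matrix: CallMatrix, candidates: str = "intermediate",
                 f_low: float = F_LOW, f_high: float = F_HIGH) -> AccumulationCurve:
    """Cumulative-unique curve of intermittent keys over rounds.

    The candidate universe is fixed at the end of the run: keys whose
    final-matrix frequency is strictly between the thresholds
    (``candidates='intermediate'``), or every observed key
    (``candidates='all'``).  Increments are the new-unique candidates
    per round; lambda-hat is their sample mean over rounds >= 2 (the
    first round is burn-in: it reveals the standing catalogue, not the
    per-round discovery rate).
    """
    if matrix.n_rounds < 2:
        raise ValueError("accumulation needs at least 2 rounds")
    if candidates == "intermediate":
        freq = matrix.frequencies()
        mask = (freq > f_low) & (freq < f_high)
    elif candidates == "all":
        mask = np.ones(len(matrix.keys), dtype=bool)
    else:
        raise ValueError("candidates must be 'intermediate' or 'all'")
    inc = matrix.incidence[mask]
    if inc.shape[0] == 0:
        cum = np.zeros(matrix.n_rounds, dtype=np.int64)
    else:
        seen = np.maximum.accumulate(inc, axis=1)
        cum = seen.sum(axis=0).astype(np.int64)
    increments = np.diff(np.concatenate([[0], cum]))
    tail = increments[1:].astype(float)
    lam = float(tail.mean())
    if lam > 0 and len(tail) > 1:
        dispersion = float(tail.var(ddof=1) / lam)
    else:
        dispersion = float("nan")
    return AccumulationCurve(cumulative=cum, increments=increments,
                             lambda_hat=lam, dispersion=dispersion)


def fraction_discovered(curve: AccumulationCurve, n_small: int, n_large: int) -> float:
    """cumulative(n_small) / cumulative(n_large): the saturation
    fraction (e.g. 10 rounds vs 100)."""
    if not 1 <= n_small <= n_large <= len(curve.cumulative):
        raise ValueError("need 1 <= n_small <= n_large <= n_rounds")
    denom = int(curve.cumulative[n_large - 1])
    if denom == 0:
        raise ZeroDivisionError("no candidate keys discovered by n_large rounds")
    return float(curve.cumulative[n_small - 1] / denom)


def write_call_matrix(matrix: CallMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index=False)


def read_catalogue(path) -> RFPCatalogue:
    table = pd.read_csv(path, sep="\t")
    sidecar = Path(str(path)).with_suffix(".yaml")
    meta = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
    return RFPCatalogue(table=table, metadata=meta)
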