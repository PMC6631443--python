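"""Run configuration and end-to-end orchestration.

A :class:`RunConfig` is fully serializable to YAML; persisting the
config plus the master seed reproduces a run exactly, independent of the
execution order of rounds (all randomness is derived from the master
seed through counter-based streams).
"""
from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .genome_forge import (IndividualGenome, ReferenceGenome, SyntheticGenomeSpec,
                           build_reference, derive_individual, write_fasta,
                           write_ledger, write_targets, write_variant_truth)
from .micro_aligner import AlignerConfig, build_index
from .pileup_caller import write_vcf, VariantCall
from .read_sampler import SamplerConfig
from .rfp_engine import (CallMatrix, EngineConfig, RFPCatalogue, classify,
                         run_rounds, write_call_matrix)

log = logging.getLogger("rfpsim")


@dataclass
class IndividualSpec:
    n_private_snvs: int = 60
    fraction_in_paralogs: float = 0.5
    zygosity_mode: str = "hom"
    seed: int = 1


@dataclass
class RunConfig:
    genome: SyntheticGenomeSpec = field(default_factory=SyntheticGenomeSpec)
    individual: IndividualSpec = field(default_factory=IndividualSpec)
    sampler: SamplerConfig = field(default_factory=lambda: SamplerConfig(target_coverage=30.0))
    aligner: AlignerConfig = field(default_factory=AlignerConfig)
    caller_id: str = "A"
    caller_params: dict = field(default_factory=dict)
    rounds: int = 10
    min_mapq: int = 0
    master_seed: int = 0
    f_low: float = 0.05
    f_high: float = 0.95

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        return cls(
            genome=SyntheticGenomeSpec(**raw.get("genome", {})),
            individual=IndividualSpec(**raw.get("individual", {})),
            sampler=SamplerConfig(**raw.get("sampler", {"target_coverage": 30.0})),
            aligner=AlignerConfig(**raw.get("aligner", {})),
            caller_id=raw.get("caller_id", "A"),
            caller_params=raw.get("caller_params", {}),
            rounds=raw.get("rounds", 10),
            min_mapq=raw.get("min_mapq", 0),
            master_seed=raw.get("master_seed", 0),
            f_low=raw.get("f_low", 0.05),
            f_high=raw.get("f_high", 0.95),
        )

    def engine_config(self) -> EngineConfig:
        return EngineConfig(
            n_rounds=self.rounds, sampler=self.sampler, aligner=self.aligner,
            caller_id=self.caller_id, caller_params=self.caller_params,
            min_mapq=self.min_mapq, master_seed=self.master_seed)


@dataclass
class RunResult:
    reference: ReferenceGenome
    individual: IndividualGenome
    matrix: CallMatrix
    catalogue: RFPCatalogue


def execute_run(cfg: RunConfig, out_dir=None, keep_rounds: bool = False) -> RunResult:
    """Forge genome, derive individual, run all rounds, classify, persist."""
    t0 = time.time()
    ref, ledger = build_reference(cfg.genome)
    ind = derive_individual(
        ref, n_private_snvs=cfg.individual.n_private_snvs,
        fraction_in_paralogs=cfg.individual.fraction_in_paralogs,
        zygosity_mode=cfg.individual.zygosity_mode,
        seed=cfg.individual.seed, ledger=ledger)
    index = build_index(ref, cfg.aligner.k)
    log.info("forged genome: %d bp, %d targets, %d paralog families, %d variants",
             sum(len(s) for s in ref.contigs.values()), len(ref.target_regions),
             len(ledger.families), len(ind.variants))
    matrix = run_rounds(ind, ref, cfg.engine_config(), index=index)
    catalogue = classify(matrix, f_low=cfg.f_low, f_high=cfg.f_high)
    counts = catalogue.table["class"].value_counts().to_dict()
    log.info("classified %d keys in %.1f s: %s", len(catalogue.table),
             time.time() - t0, counts)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(out / "config.yaml")
        write_fasta(ref, out / "reference.fasta")
        write_targets(ref, out / "targets.tsv")
        write_ledger(ledger, out / "ledger.copies.tsv", out / "ledger.diffs.tsv")
        write_variant_truth(ind, out / "truth.tsv")
        write_call_matrix(matrix, out / "call_matrix.tsv")
        catalogue.write(out / "catalogue.tsv", out / "catalogue.yaml")
        if keep_rounds:
            rounds_dir = out / "rounds"
            rounds_dir.mkdir(exist_ok=True)
            for r in range(matrix.n_rounds):
                calls = [VariantCall(contig=k[0], pos=k[1], ref=k[2], alt=k[3],
                                     qual=0.0, caller_id=cfg.caller_id)
                         for k, row in zip(matrix.keys, matrix.incidence) if row[r]]
                write_vcf(calls, ref, rounds_dir / f"round_{r + 1}.vcf")
    return RunResult(reference=ref, individual=ind, matrix=matrix, catalogue=catalogue)
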