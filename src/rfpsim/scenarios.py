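"""Canonical study scenarios.

These fix the conditions under which the package's claims are tested:
read length 120 bp, 1% sequencing error, 30x base coverage, 325 bp
target padding, 5%/95% classification thresholds, and two-copy paralog
families at 99% identity.  Genome sizes are desk-scale stand-ins for an
exome (tens to hundreds of kilobases) chosen so a full multi-round run
completes in seconds to minutes; every random ingredient derives from
one master seed.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

from ._seq import derive_seed
from .genome_forge import (IndividualGenome, ParalogLedger, ReferenceGenome,
                           SyntheticGenomeSpec, build_reference, derive_individual)
from .micro_aligner import AlignerConfig
from .read_sampler import SamplerConfig
from .rfp_engine import EngineConfig


@dataclass
class Scenario:
    ref: ReferenceGenome
    ledger: ParalogLedger
    individual: IndividualGenome
    engine: EngineConfig


def _engine(seed: int, n_rounds: int, caller_id: str, min_mapq: int,
            read_length: int = 120) -> EngineConfig:
    return EngineConfig(
        n_rounds=n_rounds,
        sampler=SamplerConfig(read_length=read_length, error_rate=0.01,
                              target_coverage=30.0),
        aligner=AlignerConfig(k=21, error_rate=0.01),
        caller_id=caller_id,
        min_mapq=min_mapq,
        master_seed=seed,
    )


def null_scenario(seed: int = 1, n_rounds: int = 30, caller_id: str = "A") -> Scenario:
    """No-paralog 200 kb genome with 220 planted homozygous SNVs.

    The negative control: without genomic redundancy every planted
    variant should be called in essentially every round and no key
    should land in the intermittent band.
    """
    spec = SyntheticGenomeSpec(genome_length=200_000, n_paralog_families=0,
                               rng_seed=derive_seed(seed, 101))
    ref, ledger = build_reference(spec)
    ind = derive_individual(ref, n_private_snvs=220, fraction_in_paralogs=0.0,
                            zygosity_mode="hom", seed=derive_seed(seed, 102),
                            ledger=ledger)
    return Scenario(ref, ledger, ind, _engine(derive_seed(seed, 103),
                                              n_rounds, caller_id, 0))


def paralog_scenario(seed: int = 1, n_rounds: int = 30, caller_id: str = "A",
                     min_mapq: int = 0) -> Scenario:
    """Two-copy family at 99% identity in a 100 kb genome; 60 homozygous
    private SNVs, half of them inside the paralog blocks.

    The mechanism scenario: reads carrying an in-paralog variant whose
    window shows no inter-copy difference tie between copies, and the
    randomly misassigned half deposits the variant allele at the
    homologous position of the sister copy.
    """
    spec = SyntheticGenomeSpec(genome_length=100_000, n_paralog_families=1,
                               copies_per_family=2, copy_length=8_000,
                               paralog_identity=0.99, pad_length=325,
                               rng_seed=derive_seed(seed, 201))
    ref, ledger = build_reference(spec)
    ind = derive_individual(ref, n_private_snvs=80, fraction_in_paralogs=0.5,
                            zygosity_mode="hom", seed=derive_seed(seed, 202),
                            ledger=ledger)
    return Scenario(ref, ledger, ind, _engine(derive_seed(seed, 203),
                                              n_rounds, caller_id, min_mapq))


def sweep_scenario(seed: int = 1, n_rounds: int = 30, caller_id: str = "A") -> Scenario:
    """Smaller paralog genome used for the read-length sweep (many runs)."""
    spec = SyntheticGenomeSpec(genome_length=60_000, n_paralog_families=1,
                               copies_per_family=2, copy_length=6_000,
                               paralog_identity=0.99, pad_length=325,
                               rng_seed=derive_seed(seed, 301))
    ref, ledger = build_reference(spec)
    ind = derive_individual(ref, n_private_snvs=60, fraction_in_paralogs=2 / 3,
                            zygosity_mode="hom", seed=derive_seed(seed, 302),
                            ledger=ledger)
    return Scenario(ref, ledger, ind, _engine(derive_seed(seed, 303),
                                              n_rounds, caller_id, 0))


def individual_pair(seed: int = 1, n_private: int = 15, n_rounds: int = 20,
                    caller_id: str = "A") -> tuple[Scenario, Scenario]:
    """Two individuals sharing a strain background but carrying
    ``n_private`` individual-specific SNVs each inside the paralog
    blocks; used to study how catalogue similarity tracks genetic
    divergence between individuals."""
    spec = SyntheticGenomeSpec(genome_length=60_000, n_paralog_families=1,
                               copies_per_family=2, copy_length=6_000,
                               paralog_identity=0.99, pad_length=325,
                               rng_seed=derive_seed(seed, 401))
    ref, ledger = build_reference(spec)
    shared = derive_individual(ref, n_private_snvs=30, fraction_in_paralogs=0.5,
                               zygosity_mode="hom", seed=derive_seed(seed, 402),
                               ledger=ledger).variants
    scns = []
    for who in (1, 2):
        ind = derive_individual(ref, n_private_snvs=n_private,
                                fraction_in_paralogs=1.0, zygosity_mode="hom",
                                seed=derive_seed(seed, 410 + who), ledger=ledger,
                                base_variants=shared)
        engine = _engine(derive_seed(seed, 420 + who), n_rounds, caller_id, 0)
        scns.append(Scenario(ref, ledger, ind, engine))
    return scns[0], scns[1]


def with_min_mapq(scn: Scenario, min_mapq: int) -> Scenario:
    """Same scenario with tied (MAPQ 0) reads excluded from pileups."""
    return Scenario(scn.ref, scn.ledger, scn.individual,
                    replace(scn.engine, min_mapq=min_mapq))
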