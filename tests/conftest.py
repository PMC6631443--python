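"""Shared fixtures.

Heavy multi-round simulations are session-scoped so that the mechanism,
suppression, alignability and accumulation checks all reuse the same
runs.  All seeds are fixed: every test is deterministic.
"""
from __future__ import annotations

import numpy as np
import pytest

import rfpsim
from rfpsim import scenarios
from rfpsim._seq import random_sequence
from rfpsim.genome_forge import (ReferenceGenome, SyntheticGenomeSpec,
                                 build_reference, derive_individual)


@pytest.fixture(scope="session")
def tiny_ref():
    """Small no-paralog reference for unit tests (fast)."""
    spec = SyntheticGenomeSpec(genome_length=30_000, n_paralog_families=0,
                               copy_length=4_000, rng_seed=11)
    ref, ledger = build_reference(spec)
    return ref, ledger


@pytest.fixture(scope="session")
def tiny_individual(tiny_ref):
    ref, ledger = tiny_ref
    ind = derive_individual(ref, n_private_snvs=20, fraction_in_paralogs=0.0,
                            seed=5, ledger=ledger)
    return ind


@pytest.fixture(scope="session")
def dup_ref():
    """10 kb genome containing a two-copy paralog family, for aligner
    oracle and tie tests."""
    spec = SyntheticGenomeSpec(genome_length=10_000, n_paralog_families=1,
                               copies_per_family=2, copy_length=1_500,
                               paralog_identity=0.99, pad_length=325,
                               n_unique_targets=2, target_length=800,
                               rng_seed=23)
    ref, ledger = build_reference(spec)
    return ref, ledger


@pytest.fixture(scope="session")
def null_run():
    """Null control: 200 kb, no paralogs, 30 rounds."""
    scn = scenarios.null_scenario(seed=1, n_rounds=30)
    matrix = rfpsim.run_rounds(scn.individual, scn.ref, scn.engine)
    return scn, matrix, rfpsim.classify(matrix)


@pytest.fixture(scope="session")
def paralog_run():
    """Mechanism scenario: 2-copy family at 0.99 identity, 30 rounds."""
    scn = scenarios.paralog_scenario(seed=1, n_rounds=30)
    matrix = rfpsim.run_rounds(scn.individual, scn.ref, scn.engine)
    return scn, matrix, rfpsim.classify(matrix)


@pytest.fixture(scope="session")
def suppressed_run(paralog_run):
    """Same scenario rerun with tied (MAPQ 0) reads excluded."""
    scn, _, _ = paralog_run
    scn2 = scenarios.with_min_mapq(scn, 1)
    matrix = rfpsim.run_rounds(scn2.individual, scn2.ref, scn2.engine)
    return scn2, matrix, rfpsim.classify(matrix)


def random_reads_from(ref: ReferenceGenome, n: int, read_length: int,
                      error_rate: float, seed: int):
    """Sample single-end reads uniformly from a reference with i.i.d.
    substitution errors; returns (reads, origins)."""
    rng = np.random.default_rng(seed)
    name = next(iter(ref.contigs))
    seq = ref.contigs[name]
    starts = rng.integers(0, len(seq) - read_length + 1, size=n)
    reads, origins = [], []
    for s in starts:
        r = seq[s : s + read_length].copy()
        mask = rng.random(read_length) < error_rate
        idx = np.flatnonzero(mask)
        r[idx] = (r[idx] + rng.integers(1, 4, size=len(idx))) % 4
        reads.append(r)
        origins.append((name, int(s)))
    return reads, origins
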