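from __future__ import annotations

import numpy as np
import pytest

from selictseq.io import AlignedRead, PipelineConfig, ReferenceGenome, SgRNASpec
from selictseq.pipeline import DEFAULT_PROTOSPACER, default_site_specs
from selictseq.simulate import SimulationParams, make_genome, plant_sites, simulate_reads
from selictseq.sitecall import SamplePileup, build_pileup


@pytest.fixture(scope="session")
def sgrna() -> SgRNASpec:
    return SgRNASpec(DEFAULT_PROTOSPACER, "NGG")


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig(seed=7)


@pytest.fixture(scope="session")
def tiny_genome() -> ReferenceGenome:
    """2 kb deterministic genome for hand-built pileup tests."""
    rng = np.random.default_rng(42)
    seq = "".join("ACGT"[k] for k in rng.integers(0, 4, 2000))
    return ReferenceGenome({"chrT": seq})


def make_read(
    genome: ReferenceGenome,
    start: int,
    length: int = 50,
    strand: str = "+",
    sample: str = "sgrna_pos_rep1",
    mutate: dict[int, str] | None = None,
    mapq: int = 60,
    name: str = "r",
    contig: str | None = None,
    cigar=None,
) -> AlignedRead:
    contig = contig or next(iter(genome.sequences))
    seq = bytearray(genome.sequences[contig][start : start + length].encode())
    for off, b in (mutate or {}).items():
        seq[off] = ord(b)
    return AlignedRead(
        name=name,
        contig=contig,
        start=start,
        strand=strand,
        mapq=mapq,
        cigar=cigar or [("M", len(seq))],
        seq=seq.decode(),
        sample=sample,
    )


def signal_read(genome, position, strand, length=50, sample="sgrna_pos_rep1",
                mapq=60, name="sig"):
    """A truncated signal read placing the edited base at read position 2."""
    if strand == "+":
        start = position - 1
        return make_read(genome, start, length, "+", sample, {1: "G"}, mapq, name)
    start = position + 2 - length
    return make_read(genome, start, length, "-", sample,
                     {position - start: "C"}, mapq, name)


def empty_pileups(genome, config):
    return {
        label: SamplePileup(genome, config.min_mapq)
        for label in ("sgrna_pos_rep1", "sgrna_pos_rep2", "sgrna_neg", "untreated")
    }


@pytest.fixture(scope="session")
def small_sim(sgrna, config):
    """A full simulated 100 kb dataset shared across test modules."""
    params = SimulationParams(genome_length=100_000, depth=30, seed=7)
    genome = make_genome(params)
    specs = default_site_specs(n_dependent=10, n_independent=6,
                              n_endogenous=2, n_snp=2)
    genome, planted = plant_sites(genome, sgrna, specs, params.seed)
    pileups = {
        label: build_pileup(
            simulate_reads(genome, planted, params, label), genome, config.min_mapq
        )
        for label in ("sgrna_pos_rep1", "sgrna_pos_rep2", "sgrna_neg", "untreated")
    }
    return {
        "params": params,
        "genome": genome,
        "planted": planted,
        "pileups": pileups,
    }
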