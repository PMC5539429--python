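"""Shared fixtures: tiny hand-built references and a small simulated run."""

from __future__ import annotations

import numpy as np
import pytest

from tnseq_ci.reference import GeneRecord, Replicon
from tnseq_ci.simulate import (
    SimulationConfig,
    generate_genome,
    generate_library,
    generate_reads,
    simulate_selection,
    site_fitness,
    write_genome_files,
)


@pytest.fixture
def tiny_replicon() -> Replicon:
    rng = np.random.default_rng(42)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=400))
    return Replicon("chr", seq)


@pytest.fixture
def tiny_genes() -> list[GeneRecord]:
    return [
        GeneRecord("gA", "chr", 41, 140, "+"),
        GeneRecord("gB", "chr", 201, 380, "-"),
    ]


@pytest.fixture(scope="session")
def small_sim_config() -> SimulationConfig:
    """Desk-size simulation: quick but large enough for stable statistics."""
    return SimulationConfig(
        seed=11,
        genome_length=60_000,
        n_genes=30,
        gene_length_range=(300, 1500),
        library_size=800,
        read_depth=40_000,
        fitness={"pep": {f"gene{i:04d}": 0.63 for i in range(1, 6)}},
        treatments=("pep",),
    )


@pytest.fixture(scope="session")
def small_fastq_run(tmp_path_factory, small_sim_config):
    """A small read-level dataset: genome files, per-sample FASTQs, truth."""
    cfg = small_sim_config
    out = tmp_path_factory.mktemp("simrun")
    rng = np.random.default_rng(cfg.seed)
    replicons, genes = generate_genome(cfg, rng)
    write_genome_files(replicons, genes, out / "genome.fasta", out / "genome.ptt")
    library = generate_library(replicons, cfg, rng)
    w_u = site_fitness(library, genes, cfg.fitness_untreated)
    w_t = site_fitness(library, genes, cfg.fitness["pep"])
    samples = []
    for rep_i in (1, 2):
        jitter = rng.lognormal(0.0, cfg.replicate_jitter_sigma, size=len(library))
        base = library.abundances * jitter
        base /= base.sum()
        conditions = {
            "input": base,
            "nontreated": simulate_selection(base, w_u, cfg.doublings),
            "treated:pep": simulate_selection(base, w_t, cfg.doublings),
        }
        for cond, abund in conditions.items():
            sid = f"{cond.replace('treated:', '')}_r{rep_i}"
            fq = out / f"{sid}.fastq"
            generate_reads(abund, library, replicons, cfg, rng, sid, fq)
            samples.append(
                {"sample_id": sid, "fastq": str(fq), "condition": cond,
                 "replicate": rep_i}
            )
    return {
        "dir": out,
        "config": cfg,
        "replicons": replicons,
        "genes": genes,
        "library": library,
        "samples": samples,
    }
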