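"""Transposon-library selection simulator with known ground truth.

Generates a synthetic bacterial genome, a mariner-style insertion library
restricted to TA dinucleotides, deterministic exponential selection with
per-gene fitness effects, and sequencing reads with the junction structure
the pipeline expects (32-nt transposon end + genomic tag).  Because every
stage is generated from a seeded RNG with a recorded truth set, read
preparation, mapping, quantification and CI classification can all be
verified offline.

Selection model: over D net population doublings an insertion with
relative fitness w changes abundance by the factor w**D, after which
abundances renormalize (competition).  Insertions in a gene's core region
inherit that gene's fitness; insertions in gene edges or intergenic space
are neutral (w = 1).  The expected competition index of a gene is then
(w_treated / w_untreated) ** D.  Biological replicates are modelled as
independently jittered library compositions (per-site log-normal factor),
and sequencing as a multinomial draw of the configured depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .mapping import InsertionSite, SampleProfile
from .read_prep import DEFAULT_TN_SEQUENCE, PrepAccounting
from .reference import CoreRegion, GeneRecord, Replicon, core_region, revcomp

__all__ = [
    "SimulationConfig",
    "Library",
    "TruthSet",
    "generate_genome",
    "generate_library",
    "site_fitness",
    "simulate_selection",
    "generate_reads",
    "sample_site_counts",
    "expected_ci",
    "simulate_profiles",
    "write_genome_files",
]

_MIN_GAP = 50  # bp between simulated ORFs


@dataclass
class SimulationConfig:
    """Generative parameters; defaults mirror the screen's design scaled to
    a desk-size genome.

    ``fitness`` maps treatment label -> {gene_id: w_treated}; genes absent
    from a map are neutral (w = 1).  ``fitness_untreated`` covers genes
    whose insertions impair growth even without treatment.  ``doublings``
    defaults to 3, the midpoint of the screen's two-to-four net doublings.
    """

    seed: int = 0
    genome_length: int = 300_000
    n_genes: int = 150
    gene_length_range: tuple[int, int] = (300, 3000)
    library_size: int = 5_000
    abundance_sigma: float = 0.5
    doublings: float = 3.0
    read_depth: int = 2_000_000
    read_length: int = 60
    tn_error_rate: float = 0.01
    tag_error_rate: float = 0.0
    tag_length: int = 17
    tn_sequence: str = DEFAULT_TN_SEQUENCE
    replicate_jitter_sigma: float = 0.1
    treatments: tuple[str, ...] = ("treated",)
    fitness: dict[str, dict[str, float]] = field(default_factory=dict)
    fitness_untreated: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.doublings <= 10):
            raise ValueError("doublings must lie in [0, 10]")
        for rate in (self.tn_error_rate, self.tag_error_rate):
            if not (0 <= rate < 1):
                raise ValueError("error rates must lie in [0, 1)")
        for name in ("genome_length", "library_size", "read_depth", "read_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")


@dataclass
class Library:
    """A simulated insertion library: sites with initial relative abundances."""

    sites: list[InsertionSite]
    abundances: np.ndarray  # sums to 1

    def __len__(self) -> int:
        return len(self.sites)


@dataclass
class TruthSet:
    """Ground truth for recovery tests."""

    library: Library
    expected_ci: dict[str, dict[str, float]]  # treatment -> gene -> CI
    doublings: float


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def generate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[Replicon], list[GeneRecord]]:
    """One uniform-random replicon with non-overlapping ORFs.

    Gene lengths are uniform over ``gene_length_range``; genes are separated
    by at least 50 bp of intergenic space, with the slack distributed
    randomly.  The sequence is regenerated until >= 99% of its 17-mers are
    unique so that short-tag mapping stays essentially unambiguous.
    """
    if rng is None:
        rng = _rng(config.seed)
    lo, hi = config.gene_length_range
    for _attempt in range(10):
        lengths = rng.integers(lo, hi + 1, size=config.n_genes)
        needed = int(lengths.sum()) + _MIN_GAP * (config.n_genes + 1)
        if needed > config.genome_length:
            if config.n_genes and (lo + _MIN_GAP) * config.n_genes > config.genome_length:
                raise ValueError(
                    f"cannot fit {config.n_genes} genes of >= {lo} bp into "
                    f"{config.genome_length} bp"
                )
            continue  # unlucky draw; try again
        seq = "".join(
            np.array(list("ACGT"))[rng.integers(0, 4, size=config.genome_length)]
        )
        if _kmer_uniqueness(seq, 17) < 0.99:
            continue
        # distribute slack among the n_genes + 1 gaps
        slack = config.genome_length - needed
        extra = rng.multinomial(slack, np.full(config.n_genes + 1, 1 / (config.n_genes + 1)))
        genes: list[GeneRecord] = []
        cursor = 1 + _MIN_GAP + int(extra[0])
        for i, length in enumerate(lengths):
            start = cursor
            end = start + int(length) - 1
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            genes.append(
                GeneRecord(f"gene{i + 1:04d}", "sim1", start, end, strand,
                           product="simulated ORF")
            )
            cursor = end + 1 + _MIN_GAP + int(extra[i + 1])
        return [Replicon("sim1", seq)], genes
    raise ValueError(
        "could not generate a feasible genome for this configuration"
    )


def _kmer_uniqueness(seq: str, k: int) -> float:
    kmers: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        kmers[km] = kmers.get(km, 0) + 1
        kmers[revcomp(km)] = kmers.get(revcomp(km), 0) + 1
    unique = sum(1 for c in kmers.values() if c == 1)
    return unique / len(kmers) if kmers else 1.0


def _ta_positions(seq: str) -> np.ndarray:
    """0-based positions p with seq[p:p+2] == 'TA'."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    return np.flatnonzero((arr[:-1] == ord("T")) & (arr[1:] == ord("A")))


def generate_library(
    replicons: list[Replicon],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> Library:
    """Sample ``library_size`` insertions uniformly from TA dinucleotides.

    Strand is uniform.  On the plus strand the junction base is the T of
    the TA; on the minus strand it is the A (whose minus-strand read also
    begins TA).  Sites whose tag would run off the replicon are rejected
    during sampling.  Initial abundances are log-normal(0, sigma),
    normalized to sum to one.
    """
    if rng is None:
        rng = _rng(config.seed)
    if len(replicons) != 1:
        raise NotImplementedError("simulator emits a single replicon")
    rep = replicons[0]
    k = config.tag_length
    ta = _ta_positions(rep.sequence)
    # keep TA positions where both strand choices leave room for a full tag
    ta = ta[(ta + k <= rep.length) & (ta + 2 - k >= 0)]
    if ta.size < config.library_size:
        raise ValueError(
            f"genome has {ta.size} usable TA sites, fewer than "
            f"library_size={config.library_size}"
        )
    chosen = rng.choice(ta, size=config.library_size, replace=False)
    chosen.sort()
    strands = rng.integers(0, 2, size=config.library_size)
    sites = [
        InsertionSite("sim1", int(p) + 1, "+") if s == 0
        else InsertionSite("sim1", int(p) + 2, "-")
        for p, s in zip(chosen, strands)
    ]
    abund = rng.lognormal(0.0, config.abundance_sigma, size=config.library_size)
    abund /= abund.sum()
    return Library(sites, abund)


def site_fitness(
    library: Library,
    genes: list[GeneRecord],
    fitness_by_gene: dict[str, float],
) -> np.ndarray:
    """Per-site fitness: a gene's w inside its core region, 1 elsewhere.

    Edge-region and intergenic insertions are neutral — insertions outside
    the central 80% of an ORF may leave the product functional.
    """
    w = np.ones(len(library), dtype=float)
    cores = [(core_region(g), g.gene_id) for g in genes]
    for idx, site in enumerate(library.sites):
        for core, gene_id in cores:
            if core.core_start <= site.position <= core.core_end:
                gw = fitness_by_gene.get(gene_id)
                if gw is not None:
                    w[idx] *= gw
    return w


def simulate_selection(
    abundances: np.ndarray, w: np.ndarray, doublings: float
) -> np.ndarray:
    """Deterministic exponential selection: a_i' ~ a_i * w_i**D, renormalized."""
    out = abundances * np.power(w, doublings)
    total = out.sum()
    if total == 0:
        raise ValueError("all abundances vanished under selection")
    return out / total


def expected_ci(
    fitness: dict[str, dict[str, float]],
    fitness_untreated: dict[str, float],
    genes: list[GeneRecord],
    doublings: float,
) -> dict[str, dict[str, float]]:
    """Closed-form per-gene expected CI: (w_treated / w_untreated) ** D."""
    out: dict[str, dict[str, float]] = {}
    for treatment, wmap in fitness.items():
        per_gene = {}
        for g in genes:
            w_t = wmap.get(g.gene_id, 1.0)
            w_u = fitness_untreated.get(g.gene_id, 1.0)
            per_gene[g.gene_id] = (w_t / w_u) ** doublings if w_u > 0 else math.inf
        out[treatment] = per_gene
    return out


def sample_site_counts(
    abundances: np.ndarray, depth: int, rng: np.random.Generator
) -> np.ndarray:
    """Sequencing as a multinomial draw of *depth* reads over sites."""
    return rng.multinomial(depth, abundances)


def _profile_from_counts(
    library: Library,
    counts: np.ndarray,
    sample_id: str,
    condition: str,
    replicate: int,
) -> SampleProfile:
    site_counts = {
        site: int(c) for site, c in zip(library.sites, counts) if c
    }
    total = int(counts.sum())
    acct = PrepAccounting(
        total_reads=total, reads_no_tn=0, reads_too_short=0, reads_used=total
    )
    return SampleProfile(
        sample_id=sample_id,
        condition=condition,
        replicate=replicate,
        site_counts=site_counts,
        accounting=acct,
        aligned_reads=total,
    )


def simulate_profiles(
    config: SimulationConfig,
) -> tuple[list[Replicon], list[GeneRecord], dict[str, SampleProfile], TruthSet]:
    """Simulate a full run directly at the site-count level.

    For each biological replicate the library composition is jittered by an
    independent per-site log-normal factor, then the input, nontreated and
    treated samples are drawn as multinomials from the (selection-adjusted)
    abundances.  This is the same downstream pipeline as the read-level
    path, with read generation and re-mapping elided.
    """
    rng = _rng(config.seed)
    replicons, genes = generate_genome(config, rng)
    library = generate_library(replicons, config, rng)
    w_untreated = site_fitness(library, genes, config.fitness_untreated)
    w_treated = {
        t: site_fitness(library, genes, config.fitness.get(t, {}))
        for t in config.treatments
    }
    profiles: dict[str, SampleProfile] = {}
    for rep_i in (1, 2):
        jitter = rng.lognormal(0.0, config.replicate_jitter_sigma, size=len(library))
        base = library.abundances * jitter
        base /= base.sum()
        samples = {"input": base,
                   "nontreated": simulate_selection(base, w_untreated, config.doublings)}
        for t in config.treatments:
            samples[f"treated:{t}"] = simulate_selection(
                base, w_treated[t], config.doublings
            )
        for condition, abund in samples.items():
            counts = sample_site_counts(abund, config.read_depth, rng)
            sid = f"{condition.replace('treated:', '')}_r{rep_i}"
            profiles[sid] = _profile_from_counts(
                library, counts, sid, condition, rep_i
            )
    truth = TruthSet(
        library=library,
        expected_ci=expected_ci(
            config.fitness, config.fitness_untreated, genes, config.doublings
        ),
        doublings=config.doublings,
    )
    return replicons, genes, profiles, truth


def generate_reads(
    abundances: np.ndarray,
    library: Library,
    replicons: list[Replicon],
    config: SimulationConfig,
    rng: np.random.Generator,
    sample_id: str,
    path: str | Path,
) -> np.ndarray:
    """Write a FASTQ sample: per-site multinomial counts, junction reads.

    Each read is the transposon end sequence (with per-base substitution
    errors at ``tn_error_rate``), the genomic tag downstream of the junction
    on the site's strand (errors at ``tag_error_rate``), then random filler
    up to ``read_length``.  Quality is constant 'I' (Phred+33 Q40).
    Returns the per-site read counts actually drawn.
    """
    rep = {r.id: r for r in replicons}
    counts = sample_site_counts(abundances, config.read_depth, rng)
    k = config.tag_length
    tn = config.tn_sequence
    tags = []
    for site in library.sites:
        seq = rep[site.replicon_id].sequence
        p = site.position - 1
        if site.strand == "+":
            tags.append(seq[p : p + k])
        else:
            tags.append(revcomp(seq[p - k + 1 : p + 1]))
    filler_len = max(0, config.read_length - len(tn) - k)
    qual = b"I" * (len(tn) + k + filler_len)

    with open(path, "wb") as fh:
        read_no = 0
        for site_idx in np.flatnonzero(counts):
            n = int(counts[site_idx])
            tag = tags[site_idx]
            # vectorized per-base substitution errors for this site's reads
            tn_block = np.tile(np.frombuffer(tn.encode(), np.uint8), (n, 1))
            tn_block = _substitute(tn_block, config.tn_error_rate, rng)
            tag_block = np.tile(np.frombuffer(tag.encode(), np.uint8), (n, 1))
            tag_block = _substitute(tag_block, config.tag_error_rate, rng)
            parts = [tn_block, tag_block]
            if filler_len:
                parts.append(_BASE_BYTES[rng.integers(0, 4, size=(n, filler_len))])
            reads = np.concatenate(parts, axis=1)
            chunks = []
            for j in range(n):
                read_no += 1
                chunks.append(
                    b"@" + f"{sample_id}_{read_no}".encode() + b"\n"
                    + reads[j].tobytes() + b"\n+\n" + qual + b"\n"
                )
            fh.write(b"".join(chunks))
    return counts


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _substitute(
    block: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Apply i.i.d. substitution errors to a (reads x bases) uint8 block."""
    if rate <= 0 or block.size == 0:
        return block
    hit = rng.random(block.shape) < rate
    n_hits = int(hit.sum())
    if n_hits:
        # substitute with one of the three other bases
        orig = block[hit]
        shift = rng.integers(1, 4, size=n_hits)
        idx = np.searchsorted(_BASE_BYTES, orig)
        block[hit] = _BASE_BYTES[(idx + shift) % 4]
    return block


def write_genome_files(
    replicons: list[Replicon],
    genes: list[GeneRecord],
    fasta_path: str | Path,
    ptt_path: str | Path,
) -> None:
    """Emit the simulated genome as FASTA plus a PTT protein table."""
    with open(fasta_path, "w") as fh:
        for rep in replicons:
            fh.write(f">{rep.id}\n")
            for i in range(0, rep.length, 70):
                fh.write(rep.sequence[i : i + 70] + "\n")
    with open(ptt_path, "w") as fh:
        rep = replicons[0]
        fh.write(f"{rep.id} simulated genome - 1..{rep.length}\n")
        fh.write(f"{len(genes)} proteins\n")
        fh.write(
            "Location\tStrand\tLength\tPID\tGene\tSynonym\tCode\tCOG\tProduct\n"
        )
        for g in genes:
            aa = (g.length // 3) - 1
            fh.write(
                f"{g.start}..{g.end}\t{g.strand}\t{aa}\t-\t-\t{g.gene_id}\t-\t-\t"
                f"{g.product}\n"
            )
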