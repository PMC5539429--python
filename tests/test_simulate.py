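"""Simulator: genomes, TA libraries, selection dynamics, reads, truth."""

import numpy as np
import pytest

from tnseq_ci.mapping import is_ta_site, site_of, tally_sites
from tnseq_ci.read_prep import ReadPrepParams, process_fastq
from tnseq_ci.reference import build_tag_index, revcomp
from tnseq_ci.simulate import (
    SimulationConfig,
    expected_ci,
    generate_genome,
    generate_library,
    generate_reads,
    sample_site_counts,
    simulate_profiles,
    simulate_selection,
    site_fitness,
)

SMALL = dict(genome_length=40_000, n_genes=15, gene_length_range=(300, 1200),
             library_size=400, read_depth=20_000)


class TestGenerateGenome:
    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(seed=4, **SMALL)
        r1, g1 = generate_genome(cfg)
        r2, g2 = generate_genome(cfg)
        assert r1[0].sequence == r2[0].sequence
        assert g1 == g2

    def test_no_genes(self):
        cfg = SimulationConfig(seed=4, **{**SMALL, "n_genes": 0})
        _, genes = generate_genome(cfg)
        assert genes == []

    def test_genes_disjoint_and_in_bounds(self):
        cfg = SimulationConfig(seed=4, **SMALL)
        reps, genes = generate_genome(cfg)
        prev_end = 0
        for g in sorted(genes, key=lambda g: g.start):
            assert g.start > prev_end
            prev_end = g.end
        assert prev_end <= reps[0].length

    def test_infeasible_packing_rejected(self):
        cfg = SimulationConfig(seed=4, genome_length=5_000, n_genes=50,
                               gene_length_range=(300, 400), library_size=10)
        with pytest.raises(ValueError):
            generate_genome(cfg)


class TestGenerateLibrary:
    def test_all_sites_begin_ta_on_their_strand(self):
        cfg = SimulationConfig(seed=8, **SMALL)
        reps, _ = generate_genome(cfg)
        lib = generate_library(reps, cfg)
        rep_map = {r.id: r for r in reps}
        assert all(is_ta_site(s, rep_map) for s in lib.sites)

    def test_single_site_abundance_one(self):
        cfg = SimulationConfig(seed=8, **{**SMALL, "library_size": 1})
        reps, _ = generate_genome(cfg)
        lib = generate_library(reps, cfg)
        assert len(lib) == 1 and lib.abundances[0] == 1.0

    def test_seeds_differ(self):
        cfg1 = SimulationConfig(seed=8, **SMALL)
        cfg2 = SimulationConfig(seed=9, **SMALL)
        reps, _ = generate_genome(cfg1)
        l1 = generate_library(reps, cfg1)
        l2 = generate_library(reps, cfg2)
        assert set(l1.sites) != set(l2.sites)

    def test_too_few_ta_sites_rejected(self):
        cfg = SimulationConfig(seed=8, **{**SMALL, "library_size": 400})
        reps, _ = generate_genome(cfg)
        big = SimulationConfig(seed=8, **{**SMALL, "library_size": 50_000})
        with pytest.raises(ValueError):
            generate_library(reps, big)


class TestSelection:
    def test_neutral_fitness_no_change(self):
        a = np.array([0.25, 0.25, 0.5])
        out = simulate_selection(a, np.ones(3), doublings=3)
        np.testing.assert_allclose(out, a)

    def test_closed_form_fold_change(self):
        # one class at w = 0.63 over 3 doublings: 0.63^3 ~ 0.25-fold
        a = np.array([0.5, 0.5])
        out = simulate_selection(a, np.array([0.63, 1.0]), doublings=3)
        ratio = (out[0] / out[1]) / (a[0] / a[1])
        assert ratio == pytest.approx(0.63 ** 3)

    def test_zero_fitness_vanishes(self):
        a = np.array([0.5, 0.5])
        out = simulate_selection(a, np.array([0.0, 1.0]), doublings=2)
        assert out[0] == 0 and out[1] == 1

    def test_core_insertions_inherit_gene_fitness(self):
        cfg = SimulationConfig(seed=8, **SMALL)
        reps, genes = generate_genome(cfg)
        lib = generate_library(reps, cfg)
        target = genes[0]
        w = site_fitness(lib, genes, {target.gene_id: 0.4})
        from tnseq_ci.reference import core_region

        core = core_region(target)
        for site, wi in zip(lib.sites, w):
            inside = core.core_start <= site.position <= core.core_end
            assert wi == (0.4 if inside else 1.0)


class TestExpectedCI:
    def test_closed_form(self):
        genes = generate_genome(SimulationConfig(seed=4, **SMALL))[1]
        gid = genes[0].gene_id
        out = expected_ci({"t": {gid: 0.5}}, {}, genes, doublings=1)
        assert out["t"][gid] == 0.5
        out = expected_ci({"t": {gid: 2.0}}, {}, genes, doublings=2)
        assert out["t"][gid] == 4.0
        out = expected_ci({"t": {}}, {}, genes, doublings=3)
        assert all(v == 1.0 for v in out["t"].values())

    def test_untreated_fitness_enters_ratio(self):
        genes = generate_genome(SimulationConfig(seed=4, **SMALL))[1]
        gid = genes[0].gene_id
        out = expected_ci({"t": {gid: 0.63}}, {gid: 0.9}, genes, doublings=3)
        assert out["t"][gid] == pytest.approx((0.63 / 0.9) ** 3)


@pytest.fixture(scope="module")
def error_free_reads(tmp_path_factory):
    cfg = SimulationConfig(seed=21, tn_error_rate=0.0, **SMALL)
    reps, genes = generate_genome(cfg)
    lib = generate_library(reps, cfg)
    path = tmp_path_factory.mktemp("reads") / "s.fastq"
    rng = np.random.default_rng(99)
    counts = generate_reads(lib.abundances, lib, reps, cfg, rng, "s", path)
    return cfg, reps, lib, path, counts


class TestGenerateReads:
    def test_error_free_reads_all_pass_and_map(self, error_free_reads):
        setup = error_free_reads
        cfg, reps, lib, path, counts = setup
        tags, acct = process_fastq(path, ReadPrepParams(max_mismatches=0))
        assert acct.reads_no_tn == 0 and acct.reads_used == acct.total_reads
        index = build_tag_index(reps, k=cfg.tag_length)
        profile = tally_sites(tags, index, accounting=acct)
        assert profile.unmapped_reads == 0

    def test_error_free_reads_recover_true_sites(self, error_free_reads):
        cfg, reps, lib, path, counts = error_free_reads
        tags, acct = process_fastq(path)
        index = build_tag_index(reps, k=cfg.tag_length)
        profile = tally_sites(tags, index, accounting=acct)
        truth = {site for site, c in zip(lib.sites, counts) if c > 0}
        # sites whose tag is genome-unique must be recovered exactly
        ambiguous_truth = set()
        for site, c in zip(lib.sites, counts):
            seq = reps[0].sequence
            p = site.position - 1
            k = cfg.tag_length
            tag = (seq[p : p + k] if site.strand == "+"
                   else revcomp(seq[p - k + 1 : p + 1]))
            if index.multiplicity(tag) > 1:
                ambiguous_truth.add(site)
        recovered = set(profile.site_counts)
        assert truth - ambiguous_truth <= recovered
        assert recovered <= truth

    def test_multinomial_counts_near_expectation(self):
        rng = np.random.default_rng(5)
        n, depth = 50, 1_000_000
        p = np.full(n, 1 / n)
        counts = sample_site_counts(p, depth, rng)
        assert counts.sum() == depth
        # 99% envelope: mean +- 2.58 * sqrt(depth * p * (1-p))
        sd = np.sqrt(depth * p * (1 - p))
        inside = np.abs(counts - depth * p) <= 2.58 * sd
        assert inside.mean() >= 0.9


class TestSimulateProfiles:
    def test_determinism(self):
        cfg = SimulationConfig(seed=17, **SMALL, treatments=("t",))
        _, _, p1, _ = simulate_profiles(cfg)
        _, _, p2, _ = simulate_profiles(cfg)
        assert {s: p.site_counts for s, p in p1.items()} == {
            s: p.site_counts for s, p in p2.items()
        }

    def test_expected_samples_present(self):
        cfg = SimulationConfig(seed=17, **SMALL, treatments=("t",))
        _, _, profiles, _ = simulate_profiles(cfg)
        assert sorted(profiles) == [
            "input_r1", "input_r2", "nontreated_r1", "nontreated_r2",
            "t_r1", "t_r2",
        ]
        for p in profiles.values():
            acct = p.accounting
            assert acct.total_reads == cfg.read_depth
            assert acct.total_reads == (
                acct.reads_no_tn + acct.reads_too_short + acct.reads_used
            )

    def test_truth_ci_neutral_is_one(self):
        cfg = SimulationConfig(seed=17, **SMALL, treatments=("t",),
                               fitness={"t": {"gene0001": 0.5}})
        _, genes, _, truth = simulate_profiles(cfg)
        assert truth.expected_ci["t"]["gene0001"] == 0.5 ** 3
        neutral = [g.gene_id for g in genes if g.gene_id != "gene0001"]
        assert all(truth.expected_ci["t"][g] == 1.0 for g in neutral)
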