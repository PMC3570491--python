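"""Synthetic genome, methylome truth and bisulfite read generation."""

import numpy as np
import pytest

from drrbs.coverage import cpg_positions
from drrbs.elements import detect_cgis
from drrbs.enzymes import Fragment, SizeWindow, digest_genome, size_select
from drrbs.simulate import (
    LAMBDA_CONTIG,
    SimConfig,
    assign_methylome,
    perturb_methylome,
    simulate_reads,
    synthesize_genome,
)


@pytest.fixture(scope="module")
def sim500():
    cfg = SimConfig(seed=77, genome_length=500_000, n_cgis=10, cgi_length=500,
                    n_genes=0, lambda_length=10_000)
    genome, cgis, genes = synthesize_genome(cfg)
    return cfg, genome, cgis, genes


class TestSynthesizeGenome:
    def test_same_seed_identical(self):
        cfg = SimConfig(seed=5, genome_length=50_000, n_cgis=5, n_genes=3,
                        lambda_length=5_000)
        g1, c1, _ = synthesize_genome(cfg)
        g2, c2, _ = synthesize_genome(cfg)
        assert g1 == g2
        assert [(c.start, c.end) for c in c1] == [(c.start, c.end) for c in c2]

    def test_background_gc_near_request(self, sim500):
        cfg, genome, cgis, _ = sim500
        seq = genome["chr1"]
        # exclude island placements from the background measurement
        mask = np.ones(len(seq), dtype=bool)
        for c in cgis:
            mask[c.start : c.end] = False
        arr = np.frombuffer(seq.encode(), dtype="S1")[mask]
        gc = float(np.isin(arr, [b"G", b"C"]).mean())
        assert abs(gc - cfg.background_gc) <= 0.02

    def test_island_recovery_by_detector(self, sim500):
        """>=9 of 10 requested 500 bp islands recovered by detect_cgis."""
        _, genome, cgis, _ = sim500
        found = detect_cgis({"chr1": genome["chr1"]})
        recovered = sum(
            any(d.start < t.end and t.start < d.end for d in found) for t in cgis
        )
        assert recovered >= 9

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, genome_length=10_000, n_cgis=20, cgi_length=500)

    def test_lambda_contig_present(self, sim500):
        _, genome, _, _ = sim500
        assert LAMBDA_CONTIG in genome and len(genome[LAMBDA_CONTIG]) == 10_000


class TestAssignMethylome:
    def test_probabilities_bounded_and_deterministic(self, sim500):
        _, genome, cgis, _ = sim500
        t1 = assign_methylome(genome, cgis, seed=9)
        t2 = assign_methylome(genome, cgis, seed=9)
        assert t1.probs == t2.probs
        vals = [p for d in t1.probs.values() for p in d.values()]
        assert all(0.0 <= p <= 1.0 for p in vals)
        # every genome CpG has an entry
        assert len(t1.probs["chr1"]) == len(cpg_positions(genome)["chr1"])

    def test_class_means_near_beta_means(self):
        cfg = SimConfig(seed=78, genome_length=500_000, n_cgis=30, cgi_length=600,
                        n_genes=0, lambda_length=5_000)
        genome, cgis, _ = synthesize_genome(cfg)
        truth = assign_methylome(genome, cgis, seed=9)
        in_cgi = np.zeros(len(genome["chr1"]), dtype=bool)
        for c in cgis:
            in_cgi[c.start : c.end] = True
        cgi_vals = [p for pos, p in truth.probs["chr1"].items() if in_cgi[pos]]
        bg_vals = [p for pos, p in truth.probs["chr1"].items() if not in_cgi[pos]]
        assert len(cgi_vals) >= 1000 and len(bg_vals) >= 1000
        a, b = truth.beta_params["CGI"]
        assert abs(np.mean(cgi_vals) - a / (a + b)) <= 0.03
        a, b = truth.beta_params["OTHER"]
        assert abs(np.mean(bg_vals) - a / (a + b)) <= 0.03

    def test_lambda_unmethylated(self, sim500):
        _, genome, cgis, _ = sim500
        truth = assign_methylome(genome, cgis, seed=9)
        assert all(p == 0.0 for p in truth.probs[LAMBDA_CONTIG].values())

    def test_invalid_beta_rejected(self, sim500):
        _, genome, cgis, _ = sim500
        with pytest.raises(ValueError):
            assign_methylome(genome, cgis, beta_params={"CGI": (0.0, 1.0)}, seed=9)


def _mini_world(seed=13, n=40_000):
    cfg = SimConfig(seed=seed, genome_length=n, n_cgis=4, cgi_length=400,
                    n_genes=0, lambda_length=4_000, target_depth=8)
    genome, cgis, _ = synthesize_genome(cfg)
    truth = assign_methylome(genome, cgis, seed=seed)
    return cfg, genome, cgis, truth


class TestSimulateReads:
    def test_deterministic_per_seed(self, panel):
        cfg, genome, cgis, truth = _mini_world()
        enz = {n: panel[n] for n in ("MspI", "ApeKI")}
        frags = size_select(digest_genome(genome, enz.values()), cfg.size_window)
        p1 = simulate_reads(genome, truth, frags, cfg, enz)
        p2 = simulate_reads(genome, truth, frags, cfg, enz)
        assert [(p.name, p.r1_seq, p.r2_seq) for p in p1] == [
            (p.name, p.r1_seq, p.r2_seq) for p in p2
        ]

    def test_poisson_depth(self, panel):
        """Mean pairs per fragment tracks the target depth over >=500 fragments."""
        rng = np.random.default_rng(30)
        # synthetic fragment list over a plain random genome
        from conftest import random_dna

        genome = {"chr1": random_dna(rng, 120_000, gc=0.5)}
        frags = [
            Fragment("chr1", s, s + 100, "MspI", "MspI", s, s + 102)
            for s in range(0, 60_000, 110)
        ]
        assert len(frags) >= 500
        cfg = SimConfig(seed=31, genome_length=120_000, n_cgis=0, n_genes=0,
                        target_depth=6.0, lambda_fraction=0.0)
        truth = assign_methylome(genome, [], seed=31)
        pairs = simulate_reads(genome, truth, frags, cfg,
                               {"MspI": panel["MspI"]})
        mean = len(pairs) / len(frags)
        tol = 4 * np.sqrt(cfg.target_depth / len(frags))
        assert abs(mean - cfg.target_depth) <= tol

    def test_full_conversion_all_methylated_keeps_cpg_cytosines(self, panel):
        """Conversion 1.0 + all-methylated truth + no error: CpG cytosines
        outside fill-in bases are never converted."""
        cfg, genome, cgis, truth = _mini_world(seed=14)
        probs = {c: {p: 1.0 for p in d} for c, d in truth.probs.items()}
        truth_all = type(truth)(probs=probs, beta_params=truth.beta_params)
        cfg = SimConfig(seed=14, genome_length=cfg.genome_length, n_cgis=4,
                        cgi_length=400, n_genes=0, lambda_length=4_000,
                        target_depth=4, conversion_rate=1.0, error_rate=0.0,
                        lambda_fraction=0.0)
        enz = {n: panel[n] for n in ("MspI",)}
        frags = size_select(digest_genome(genome, enz.values()), cfg.size_window)
        pairs = simulate_reads(genome, truth_all, frags, cfg, enz)
        seq = genome["chr1"]
        for p in pairs[:200]:
            if p.contig != "chr1" or p.strand != "top":
                continue
            start = p.fragment_start
            r1 = p.r1_seq
            for i, base in enumerate(r1):
                pos = start + i
                if pos < p.fragment_end and seq[pos : pos + 2] == "CG":
                    assert base == "C"

    def test_fill_in_artifact_unmethylated(self, panel):
        """Raw apparent methylation at fill-in CpGs is below truth."""
        cfg, genome, cgis, truth = _mini_world(seed=15)
        enz = {n: panel[n] for n in ("MspI",)}
        frags = [
            f for f in size_select(digest_genome(genome, enz.values()), cfg.size_window)
            if f.contig == "chr1" and f.right_enzyme == "MspI"
        ]
        cfg = SimConfig(seed=15, genome_length=cfg.genome_length, n_cgis=4,
                        cgi_length=400, n_genes=0, lambda_length=4_000,
                        target_depth=30, conversion_rate=1.0, error_rate=0.0,
                        lambda_fraction=0.0)
        pairs = simulate_reads(genome, truth, frags, cfg, enz)
        seq = genome["chr1"]
        c_reads = t_reads = 0
        for p in pairs:
            if p.strand != "top":
                continue
            # the MspI cut CpG sits at the fragment's partition end
            pos = p.fragment_end
            if seq[pos : pos + 2] != "CG":
                continue
            off = pos - p.fragment_start
            mol = p.r1_seq
            if off >= len(mol):
                # reverse read covers the right end instead
                roff = p.filled_end - 1 - pos
                if roff >= len(p.r2_seq):
                    continue
                base = {"C": "G", "G": "C", "A": "T", "T": "A"}[p.r2_seq[roff]]
            else:
                base = mol[off]
            c_reads += base == "C"
            t_reads += base == "T"
        assert c_reads == 0 and t_reads > 50  # always converted despite truth > 0

    def test_empty_fragments_warns(self, panel):
        cfg, genome, cgis, truth = _mini_world(seed=16)
        with pytest.warns(UserWarning):
            assert simulate_reads(genome, truth, [], cfg) == []


class TestPerturbMethylome:
    def test_only_listed_regions_change(self, sim500):
        _, genome, cgis, _ = sim500
        truth = assign_methylome(genome, cgis, seed=9)
        shifted = perturb_methylome(truth, cgis[:2], (12.0, 8.0), seed=9)
        changed = {
            pos
            for pos, p in shifted.probs["chr1"].items()
            if truth.probs["chr1"][pos] != p
        }
        in_regions = set()
        for c in cgis[:2]:
            in_regions |= {
                pos for pos in truth.probs["chr1"] if c.start <= pos < c.end
            }
        assert changed <= in_regions and len(changed) > 0
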