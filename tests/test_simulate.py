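"""Simulator: determinism, truth bookkeeping, statistical structure."""

import dataclasses
import random

import numpy as np
import pytest
from scipy import stats

from lgtscreen import (ScaffoldSet, ScoringParams, SimulationConfig,
                       add_contaminants, build_index, implant_lgts, search,
                       simulate, simulate_donors, simulate_expression,
                       simulate_host, simulate_pairs)
from lgtscreen.errors import ConfigurationError
from lgtscreen.io import read_bedgraph, write_bedgraph


def small_config(**kw):
    base = dict(seed=1, n_host_scaffolds=2, host_scaffold_length=20_000,
                n_donor_taxa=2, donor_length=10_000, n_implants=4,
                implant_length_min=200, implant_length_max=800,
                n_contaminant_scaffolds=1)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfig:
    @pytest.mark.parametrize("field,value", [
        ("host_gc", 1.5), ("divergence", -0.1), ("implant_length_min", 0),
        ("n_host_scaffolds", 0), ("pair_insert_mean", 150.0),
        ("implant_length_max", 50_001),
    ])
    def test_invalid_field_named_in_error(self, field, value):
        with pytest.raises(ConfigurationError, match=field):
            small_config(**{field: value})


class TestHost:
    def test_forced_length_and_count(self):
        host = simulate_host(small_config(n_host_scaffolds=1,
                                          host_scaffold_length=10_000))
        assert len(host) == 1
        assert len(host["scaffold_1"]) == 10_000

    def test_determinism(self):
        cfg = small_config()
        a, b = simulate_host(cfg), simulate_host(cfg)
        assert dict(a) == dict(b)

    def test_gc_content_within_binomial_band(self):
        """Observed GC within 4 sd of target for a 100-kb scaffold."""
        cfg = small_config(n_host_scaffolds=1, host_scaffold_length=100_000,
                           host_gc=0.35)
        seq = simulate_host(cfg)["scaffold_1"]
        gc = sum(seq.count(b) for b in "GC") / len(seq)
        assert 0.33 <= gc <= 0.37


class TestDonors:
    def test_labelled_and_reproducible(self):
        cfg = small_config(n_donor_taxa=3)
        d1, d2 = simulate_donors(cfg), simulate_donors(cfg)
        assert len(d1) == 3
        assert len(set(d1.taxa.values())) == 3
        assert dict(d1) == dict(d2)

    def test_gc_offset_capped(self):
        cfg = small_config(host_gc=0.75, donor_gc_offset=0.10,
                           n_donor_taxa=1, donor_length=50_000)
        seq = simulate_donors(cfg)[simulate_donors(cfg).names[0]]
        gc = sum(seq.count(b) for b in "GC") / len(seq)
        assert abs(gc - 0.8) < 0.01

    @pytest.mark.parametrize("seed", range(5))
    def test_unrelated_donor_host_produce_no_hits(self, seed, scoring):
        """Independent random sequences stay below the E-value cutoff."""
        cfg = small_config(seed=seed, n_donor_taxa=1, donor_length=20_000,
                           n_host_scaffolds=1)
        host = simulate_host(cfg)
        donors = simulate_donors(cfg)
        idx = build_index(host, scoring)
        assert search(donors[donors.names[0]], idx, scoring) == []


class TestImplants:
    def test_zero_implants_no_change(self):
        cfg = small_config(n_implants=0)
        host = simulate_host(cfg)
        genome, truth = implant_lgts(host, simulate_donors(cfg), cfg)
        assert dict(genome) == dict(host)
        assert truth.implants == []

    def test_zero_divergence_identity(self):
        cfg = small_config(n_implants=1, divergence=0.0,
                           implant_length_min=500, implant_length_max=500)
        genome, truth = implant_lgts(simulate_host(cfg),
                                     simulate_donors(cfg), cfg)
        t = truth.implants[0]
        assert genome[t.scaffold][t.start:t.end] == t.source
        assert t.divergence == 0.0

    def test_divergence_hamming_in_binomial_band(self):
        """d=0.05 over 1,000 bp: Hamming distance to the recorded source in
        the binomial(1000, 0.05) central band [30, 70]."""
        cfg = small_config(seed=3, n_implants=1, divergence=0.05,
                           implant_length_min=1_000, implant_length_max=1_000)
        genome, truth = implant_lgts(simulate_host(cfg),
                                     simulate_donors(cfg), cfg)
        t = truth.implants[0]
        implanted = genome[t.scaffold][t.start:t.end]
        ham = sum(a != b for a, b in zip(implanted, t.source))
        assert 30 <= ham <= 70
        assert t.divergence == ham / 1000

    def test_length_conservation(self):
        cfg = small_config()
        host = simulate_host(cfg)
        genome, truth = implant_lgts(host, simulate_donors(cfg), cfg)
        assert genome.total_length == (host.total_length
                                       + sum(t.length for t in truth.implants))

    def test_truth_intervals_disjoint_and_in_bounds(self):
        cfg = small_config(seed=8, n_implants=6)
        genome, truth = implant_lgts(simulate_host(cfg),
                                     simulate_donors(cfg), cfg)
        truth.validate(genome)  # raises on violation

    def test_truth_recovers_donor_taxon(self, scoring):
        """Extracted truth intervals search back to their donor as best hit."""
        cfg = small_config(seed=4, divergence=0.10)
        donors = simulate_donors(cfg)
        genome, truth = implant_lgts(simulate_host(cfg), donors, cfg)
        idx = build_index(donors, scoring)
        for t in truth.implants:
            hits = search(genome[t.scaffold][t.start:t.end], idx, scoring)
            assert hits, f"no hit for implant {t}"
            assert hits[0].taxon == t.taxon


class TestContaminants:
    def test_zero_and_counts(self):
        cfg = small_config(n_contaminant_scaffolds=0)
        host = simulate_host(cfg)
        out, truth = add_contaminants(host, simulate_donors(cfg), cfg)
        assert len(out) == len(host) and truth.contaminants == []
        cfg2 = small_config(n_contaminant_scaffolds=2)
        out2, truth2 = add_contaminants(host, simulate_donors(cfg2), cfg2)
        assert len(out2) == len(host) + 2
        assert len(truth2.contaminants) == 2

    def test_contaminant_hits_cover_donor(self, scoring):
        """An appended scaffold aligns to its donor over >=95% of its length."""
        cfg = small_config(n_contaminant_scaffolds=1)
        donors = simulate_donors(cfg)
        out, truth = add_contaminants(simulate_host(cfg), donors, cfg)
        idx = build_index(donors, scoring)
        c = truth.contaminants[0]
        hits = search(out[c.scaffold], idx, scoring)
        best = hits[0]
        assert best.taxon == c.taxon
        assert (best.q_end - best.q_start) >= 0.95 * len(out[c.scaffold])


class TestPairs:
    def test_zero_depth_empty(self):
        cfg = small_config(pair_depth=0.0)
        sim_genome, truth = implant_lgts(simulate_host(cfg),
                                         simulate_donors(cfg), cfg)
        assert len(simulate_pairs(sim_genome, truth, cfg)) == 0

    def test_mates_share_scaffold(self):
        cfg = small_config()
        genome, truth = implant_lgts(simulate_host(cfg),
                                     simulate_donors(cfg), cfg)
        pairs = simulate_pairs(genome, truth, cfg)
        assert len(pairs) > 0
        assert (pairs.m1_end <= pairs.m2_start).all()
        assert (pairs.m1_start >= 0).all()

    def test_bridging_pair_count_poisson_band(self):
        """Pairs bridging a junction follow Poisson with the Lander-Waterman
        rate depth*(insert - 2*read)/insert; count must fall in the central
        99% interval."""
        cfg = small_config(seed=21, n_implants=1, n_host_scaffolds=1,
                           implant_length_min=1_000, implant_length_max=1_000,
                           pair_depth=30.0)
        genome, truth = implant_lgts(simulate_host(cfg),
                                     simulate_donors(cfg), cfg)
        pairs = simulate_pairs(genome, truth, cfg)
        t = truth.implants[0]
        j = t.start  # left junction
        m1 = pairs[["m1_start", "m1_end"]].to_numpy()
        m2 = pairs[["m2_start", "m2_end"]].to_numpy()
        bridging = int(np.sum((m1[:, 1] <= j) & (m2[:, 0] >= j)))
        lam = cfg.pair_depth * (cfg.pair_insert_mean
                                - 2 * cfg.read_length) / cfg.pair_insert_mean
        lo, hi = stats.poisson.ppf([0.005, 0.995], lam)
        assert lo <= bridging <= hi


class TestExpression:
    def test_zero_fraction_all_zero(self):
        cfg = small_config(expressed_fraction=0.0)
        genome, truth = implant_lgts(simulate_host(cfg),
                                     simulate_donors(cfg), cfg)
        tracks = simulate_expression(genome, truth, cfg)
        assert all(not v for v in tracks["male"].values())
        assert all(not v for v in tracks["female"].values())

    def test_expressed_implant_depth(self):
        cfg = small_config(seed=6, expressed_fraction=1.0,
                           expression_depth=50.0)
        genome, truth = implant_lgts(simulate_host(cfg),
                                     simulate_donors(cfg), cfg)
        tracks = simulate_expression(genome, truth, cfg)
        t = truth.implants[0]
        runs = tracks["male"][t.scaffold]
        assert (t.start, t.end, 50.0) in runs
        assert t.scaffold not in tracks["female"]

    def test_bedgraph_round_trip(self, tmp_path):
        cfg = small_config(seed=6, expressed_fraction=1.0)
        genome, truth = implant_lgts(simulate_host(cfg),
                                     simulate_donors(cfg), cfg)
        tracks = simulate_expression(genome, truth, cfg)
        p = tmp_path / "male.bedgraph"
        write_bedgraph(tracks["male"], p)
        assert read_bedgraph(p) == {k: v for k, v in tracks["male"].items() if v}


class TestFullSimulation:
    def test_byte_identical_under_same_config(self):
        cfg = small_config(seed=13)
        a, b = simulate(cfg), simulate(cfg)
        assert dict(a.genome) == dict(b.genome)
        assert a.truth.implants == b.truth.implants
        assert a.pairs.equals(b.pairs)
        assert a.expression == b.expression

    def test_different_seeds_differ(self):
        a = simulate(small_config(seed=1))
        b = simulate(small_config(seed=2))
        assert dict(a.genome) != dict(b.genome)
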