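"""Tests for the synthetic-data generators against coalescent theory."""

import math
from collections import Counter

import numpy as np
import pytest

import introdepth as idp
from introdepth.distances import jc_expected_p
from introdepth.triplet import RESOLVED, TripletTopology


def _tmrca(locus, a, b):
    """Time of the MRCA of two tips from the stored edge list (ultrametric)."""
    parent = {child: p for p, child, _ in locus.edges}
    length = {child: bl for _, child, bl in locus.edges}
    times = {locus.root: locus.tree_height}
    for p, child, bl in locus.edges:  # preorder: parent time already known
        times[child] = times[p] - bl
    tips = {lab: node for node, lab in locus.tip_labels.items()}
    anc_a = set()
    u = tips[a]
    while u in parent:
        u = parent[u]
        anc_a.add(u)
    u = tips[b]
    while u not in anc_a:
        u = parent[u]
    return times[u]


def brute_force_minority_freq(t_internal, n, seed):
    """Independent oracle: direct lineage simulation of the 3-taxon MSC.

    Two lineages (the species cherry) enter their ancestral population for
    ``t_internal`` coalescent units; if they fail to coalesce there, the
    first of the three subsequent pairings is uniform, giving each minority
    topology probability (1/3) * exp(-t_internal).
    """
    rng = np.random.default_rng(seed)
    coalesced = rng.exponential(size=n) < t_internal
    pick = rng.integers(0, 3, size=n)
    minority1 = (~coalesced) & (pick == 1)
    minority2 = (~coalesced) & (pick == 2)
    return minority1.mean(), minority2.mean()


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs, field",
        [
            (dict(t_gamma=1.5), "t_gamma"),
            (dict(tau2=0.5), "tau1"),
            (dict(tau_out=1.5), "tau_out"),
            (dict(gamma=1.5), "gamma"),
            (dict(gamma=-0.1), "gamma"),
            (dict(n_loci=0), "n_loci"),
            (dict(seq_length=0), "seq_length"),
            (dict(theta=0.0), "theta"),
            (dict(donor_recipient=("C", "C")), "donor_recipient"),
            (dict(donor_recipient=("O", "A")), "donor_recipient"),
        ],
    )
    def test_invalid_field_named_in_error(self, kwargs, field):
        with pytest.raises(ValueError, match=field):
            idp.SimulationConfig(**kwargs)


class TestGeneTrees:
    def test_full_symmetry_zero_internal_branch(self):
        # tau2 -> tau1 limit: all three topologies equally likely
        cfg = idp.SimulationConfig(
            tau1=1.0, tau2=1.0 + 1e-9, tau_out=5.0, n_loci=6000, seed=5
        )
        loci = idp.simulate_gene_trees(cfg)
        freqs = Counter(l.topology_truth for l in loci)
        se = math.sqrt((1 / 3) * (2 / 3) / cfg.n_loci)
        for topo in RESOLVED:
            assert abs(freqs[topo] / cfg.n_loci - 1 / 3) < 3 * se

    def test_long_internal_branch_is_concordant(self):
        cfg = idp.SimulationConfig(
            tau1=1.0, tau2=11.0, tau_out=15.0, n_loci=3000, seed=6
        )
        loci = idp.simulate_gene_trees(cfg)
        frac = sum(l.topology_truth is TripletTopology.AB_C for l in loci) / len(loci)
        assert frac > 0.999

    def test_minority_frequency_matches_closed_form_and_brute_force(self):
        # internal branch t=1: each minority topology at (1/3) e^-1
        n = 8000
        cfg = idp.SimulationConfig(tau1=1.0, tau2=2.0, tau_out=6.0, n_loci=n, seed=7)
        loci = idp.simulate_gene_trees(cfg)
        expected = math.exp(-1.0) / 3
        se = math.sqrt(expected * (1 - expected) / n)
        for topo in (TripletTopology.AC_B, TripletTopology.BC_A):
            freq = sum(l.topology_truth is topo for l in loci) / n
            assert abs(freq - expected) < 3 * se
        for freq in brute_force_minority_freq(1.0, 50000, seed=8):
            assert abs(freq - expected) < 3 * math.sqrt(expected * (1 - expected) / 50000)

    def test_truth_topology_matches_tree(self):
        cfg = idp.SimulationConfig(n_loci=60, gamma=0.5, seed=9)
        for locus in idp.simulate_gene_trees(cfg):
            assert idp.classify_triplet(locus.newick) is locus.topology_truth

    def test_introgression_skews_minority_topologies_and_depths(self):
        cfg = idp.SimulationConfig(
            tau1=1.0, tau2=2.0, tau_out=6.0, gamma=0.4, t_gamma=0.5,
            donor_recipient=("C", "A"), n_loci=3000, seed=10,
        )
        loci = idp.simulate_gene_trees(cfg)
        freqs = Counter(l.topology_truth for l in loci)
        assert freqs[TripletTopology.AC_B] > freqs[TripletTopology.BC_A]
        t1_intro = np.mean(
            [_tmrca(l, "A", "C") for l in loci if l.topology_truth is TripletTopology.AC_B]
        )
        t1_species = np.mean(
            [_tmrca(l, "A", "B") for l in loci if l.topology_truth is TripletTopology.AB_C]
        )
        assert t1_intro < t1_species

    def test_outgroup_coalesces_above_its_split_time(self):
        cfg = idp.SimulationConfig(n_loci=40, gamma=0.5, seed=11)
        for locus in idp.simulate_gene_trees(cfg):
            for taxon in ("A", "B", "C"):
                assert _tmrca(locus, taxon, "O") >= cfg.tau_out

    def test_seeded_runs_are_bit_reproducible(self):
        cfg = idp.SimulationConfig(n_loci=25, gamma=0.3, seed=12)
        a = idp.simulate_gene_trees(cfg)
        b = idp.simulate_gene_trees(cfg)
        assert [l.newick for l in a] == [l.newick for l in b]
        assert [l.introgressed for l in a] == [l.introgressed for l in b]


class TestAlignments:
    def test_theta_limit_identical_sequences(self):
        cfg = idp.SimulationConfig(n_loci=5, seq_length=200, theta=1e-12, seed=13)
        loci = idp.simulate_alignments(idp.simulate_gene_trees(cfg), cfg)
        for locus in loci:
            rows = set(locus.alignment.values())
            assert len(rows) == 1

    def test_fixed_seed_identical_alignments(self):
        cfg = idp.SimulationConfig(n_loci=3, seq_length=100, seed=14)
        a = idp.simulate_alignments(idp.simulate_gene_trees(cfg), cfg)
        b = idp.simulate_alignments(idp.simulate_gene_trees(cfg), cfg)
        assert all(x.alignment == y.alignment for x, y in zip(a, b))

    def test_empty_locus_list_raises(self):
        cfg = idp.SimulationConfig(seed=15)
        with pytest.raises(ValueError, match="empty"):
            idp.simulate_alignments([], cfg)

    def test_mean_divergence_matches_path_length_expectation(self):
        cfg = idp.SimulationConfig(
            tau1=1.0, tau2=2.0, tau_out=5.0, n_loci=800, seq_length=400,
            theta=0.02, seed=16,
        )
        loci = idp.simulate_alignments(idp.simulate_gene_trees(cfg), cfg)
        observed, expected, var = [], [], 0.0
        for locus in loci:
            path = 2.0 * _tmrca(locus, "A", "B")  # ultrametric patristic distance
            p = jc_expected_p(0.5 * cfg.theta * path)
            expected.append(p)
            a = np.frombuffer(locus.alignment["A"].encode(), dtype="S1")
            b = np.frombuffer(locus.alignment["B"].encode(), dtype="S1")
            observed.append(float((a != b).mean()))
            var += p * (1 - p) / cfg.seq_length
        se = math.sqrt(var) / len(loci)
        assert abs(np.mean(observed) - np.mean(expected)) < 3 * se

    def test_alignment_is_gap_free_and_full_length(self):
        cfg = idp.SimulationConfig(n_loci=4, seq_length=321, seed=17)
        loci = idp.simulate_alignments(idp.simulate_gene_trees(cfg), cfg)
        for locus in loci:
            for row in locus.alignment.values():
                assert len(row) == 321
                assert set(row) <= set("ACGT")


class TestLTRPairs:
    def test_age_zero_pairs_identical(self):
        for pair in idp.simulate_ltr_pairs(10, 0.0, length=500, seed=18):
            assert pair.seq5 == pair.seq3

    def test_negative_age_raises(self):
        with pytest.raises(ValueError, match="true_age_years"):
            idp.simulate_ltr_pairs(1, -1.0)

    def test_mean_divergence_matches_2muT(self):
        # K = 2 mu T = 0.026; corrected divergence should recover it
        mu, age, n, length = 1.3e-8, 1e6, 500, 5000
        pairs = idp.simulate_ltr_pairs(n, age, mu=mu, length=length, seed=19)
        ks = [
            idp.estimate_insertion_age(p, mu=mu, prealigned=True).k for p in pairs
        ]
        k_exp = 2 * mu * age
        p_exp = jc_expected_p(k_exp)
        # delta-method SE of corrected k from binomial site sampling
        se_k = math.sqrt(p_exp * (1 - p_exp) / length) / (1 - 4 * p_exp / 3) / math.sqrt(n)
        assert abs(np.mean(ks) - k_exp) < 3 * se_k

    def test_round_trip_age_recovery(self):
        mu, age = 1.3e-8, 1e6
        pairs = idp.simulate_ltr_pairs(500, age, mu=mu, length=5000, seed=20)
        ages = [
            idp.estimate_insertion_age(p, mu=mu, prealigned=True).t_years for p in pairs
        ]
        assert abs(np.mean(ages) / age - 1) < 0.05
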