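from __future__ import annotations

import numpy as np
import pytest

from divorph.evolver import (
    EvolutionParams,
    draw_site_rates,
    evolve_branch,
    evolve_tree,
    lg_transition_matrix,
)
from divorph.io_formats import FOUR_TAXON_TREE, ProteinRecord, parse_newick
from divorph.lg_data import LG_FREQS, lg_generator
from conftest import random_protein


class TestTransitionMatrix:
    def test_t_zero_is_identity(self):
        assert np.allclose(lg_transition_matrix(0.0), np.eye(20), atol=1e-12)

    def test_rows_sum_to_one(self):
        p = lg_transition_matrix(1.0)
        assert np.max(np.abs(p.sum(axis=1) - 1.0)) < 1e-12

    def test_negative_t_rejected(self):
        with pytest.raises(ValueError):
            lg_transition_matrix(-0.1)

    def test_generator_normalization(self):
        q = lg_generator()
        # expected substitutions per site per unit time at equilibrium
        rate = -np.sum(LG_FREQS * np.diag(q))
        assert rate == pytest.approx(1.0, abs=1e-12)

    def test_long_time_convergence_to_equilibrium(self):
        # eigen-decomposition oracle: P(t) -> pi as t -> inf
        p = lg_transition_matrix(500.0)
        assert np.max(np.abs(p - LG_FREQS[None, :])) < 1e-6


class TestSiteRates:
    def test_p_inv_one_all_zero(self, rng):
        rates = draw_site_rates(500, alpha=0.5, p_inv=1.0, rng=rng)
        assert np.all(rates == 0.0)

    def test_bad_alpha(self, rng):
        with pytest.raises(ValueError):
            draw_site_rates(10, alpha=0.0, p_inv=0.0, rng=rng)

    def test_gamma_mean_one(self, rng):
        n = 100_000
        rates = draw_site_rates(n, alpha=0.1, p_inv=0.0, rng=rng)
        # Gamma(0.1, mean 1) has variance 10
        se = np.sqrt(10.0 / n)
        assert abs(rates.mean() - 1.0) < 3 * se

    def test_gamma_variance_is_inverse_alpha(self, rng):
        n = 200_000
        for alpha in (0.1, 0.5, 1.0):
            rates = draw_site_rates(n, alpha=alpha, p_inv=0.0, rng=rng)
            var = rates.var()
            # sampling error of the variance of a gamma is wide at small
            # alpha; 10% relative tolerance is ~3 sigma at this n
            assert var == pytest.approx(1.0 / alpha, rel=0.15)

    def test_invariant_fraction(self, rng):
        n = 100_000
        rates = draw_site_rates(n, alpha=1.0, p_inv=0.1, rng=rng)
        frac = np.mean(rates == 0.0)
        se = np.sqrt(0.1 * 0.9 / n)
        assert abs(frac - 0.1) < 4 * se


class TestEvolveBranch:
    def test_t_zero_identity(self, rng):
        rec = random_protein(rng, 80)
        params = EvolutionParams(alpha=1.0)
        rates = draw_site_rates(80, 1.0, 0.0, rng)
        seq, out_rates, _ = evolve_branch(rec.sequence, rates, 0.0, params, rng)
        assert seq == rec.sequence
        assert np.array_equal(out_rates, rates)

    def test_invariant_sites_never_substituted(self, rng):
        rec = random_protein(rng, 200)
        rates = draw_site_rates(200, 1.0, 0.0, rng)
        frozen = np.arange(0, 200, 3)
        rates[frozen] = 0.0
        params = EvolutionParams(alpha=1.0)
        for t in (0.5, 2.0, 10.0):
            seq, _, _ = evolve_branch(rec.sequence, rates, t, params, rng)
            for i in frozen:
                assert seq[i] == rec.sequence[i]

    def test_difference_fraction_matches_matrix_exponential(self, rng):
        # all rates 1 (alpha -> inf proxy), no indels, t = 1:
        # P(site differs) = 1 - sum_i pi_i P_ii(1)
        n = 10_000
        rec = random_protein(rng, n)
        rates = np.ones(n)
        params = EvolutionParams(alpha=1.0)
        seq, _, _ = evolve_branch(rec.sequence, rates, 1.0, params, rng)
        observed = np.mean([a != b for a, b in zip(seq, rec.sequence)])
        p1 = lg_transition_matrix(1.0)
        # sites were drawn from LG equilibrium by random_protein
        expected = 1.0 - float(np.sum(LG_FREQS * np.diag(p1)))
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) < 3 * se

    def test_no_indel_mode_preserves_length(self, rng):
        rec = random_protein(rng, 137)
        params = EvolutionParams(alpha=0.5)
        rates = draw_site_rates(137, 0.5, 0.0, rng)
        seq, out_rates, ev = evolve_branch(rec.sequence, rates, 5.0, params, rng)
        assert len(seq) == 137
        assert len(out_rates) == 137
        assert ev["insertions"] == 0 and ev["deletions"] == 0

    def test_never_shrinks_below_one(self, rng):
        params = EvolutionParams(alpha=1.0, ins_rate=0.0, del_rate=5.0,
                                 indel_len_mean=4.0)
        rates = np.ones(3)
        for _ in range(20):
            seq, _, _ = evolve_branch("ACD", rates[: 3], 5.0, params, rng)
            assert len(seq) >= 1

    def test_empty_sequence_rejected(self, rng):
        with pytest.raises(ValueError):
            evolve_branch("", np.array([]), 1.0, EvolutionParams(alpha=1.0), rng)


class TestEvolveTree:
    def test_zero_branch_lengths_copy_root(self, rng):
        tree = parse_newick("((Taxon1:0,Taxon2:0):0,Taxon3:0);")
        root = random_protein(rng, 60, "r")
        fam = evolve_tree(root, tree, EvolutionParams(alpha=1.0), rng=rng)
        assert len(fam.descendants) == 3
        for rec in fam:
            assert rec.sequence == root.sequence

    def test_one_descendant_per_terminal(self, rng):
        tree = parse_newick(FOUR_TAXON_TREE)
        root = random_protein(rng, 50, "r")
        fam = evolve_tree(root, tree, EvolutionParams(alpha=1.0), rng=rng)
        assert sorted(fam.descendants) == ["Taxon1", "Taxon2", "Taxon3",
                                           "Taxon4"]
        assert all(r.provenance.value == "simulated" for r in fam)

    def test_event_counts_scale_with_path_length(self, rng):
        # Poisson-thinning oracle: diagnostic substitution-event counts
        # have mean L * path_length * E[rate]; path(Taxon4)=10.2,
        # path(Taxon1)=1.2
        tree = parse_newick(FOUR_TAXON_TREE)
        L, fams = 100, 60
        params = EvolutionParams(alpha=2.0)
        t4 = t1 = 0
        for i in range(fams):
            root = random_protein(rng, L, f"r{i}")
            fam = evolve_tree(root, tree, params, rng=rng)
            t4 += fam.events["Taxon4"]["substitution_events"]
            t1 += fam.events["Taxon1"]["substitution_events"]
        expected4 = fams * L * 10.2
        expected1 = fams * L * 1.2
        assert t4 == pytest.approx(expected4, rel=0.1)
        assert t1 == pytest.approx(expected1, rel=0.1)
        assert t4 / t1 == pytest.approx(10.2 / 1.2, rel=0.15)

    def test_short_branch_closer_to_root(self, rng):
        # descendants on the shortest path stay more similar to the root
        # than those on the longest in >= 95% of families
        tree = parse_newick(FOUR_TAXON_TREE)
        params = EvolutionParams(alpha=1.0)
        wins = total = 0
        for i in range(200):
            root = random_protein(rng, 80, f"r{i}")
            fam = evolve_tree(root, tree, params, rng=rng)
            def ident(rec):
                return np.mean([a == b for a, b in
                                zip(rec.sequence, root.sequence)])
            if ident(fam.descendants["Taxon1"]) > ident(
                    fam.descendants["Taxon4"]):
                wins += 1
            total += 1
        assert wins / total >= 0.95

    def test_determinism_under_fixed_seed(self, rng):
        tree = parse_newick(FOUR_TAXON_TREE)
        root = random_protein(rng, 70, "r")
        params = EvolutionParams(alpha=0.3, ins_rate=0.01, del_rate=0.01,
                                 seed=99)
        fam1 = evolve_tree(root, tree, params)
        fam2 = evolve_tree(root, tree, params)
        for label in fam1.descendants:
            assert fam1.descendants[label].sequence == \
                fam2.descendants[label].sequence
        assert fam1.events == fam2.events

    def test_indel_mode_changes_lengths(self, rng):
        tree = parse_newick(FOUR_TAXON_TREE)
        params = EvolutionParams(alpha=1.0, ins_rate=0.02, del_rate=0.02)
        lengths = set()
        for i in range(10):
            root = random_protein(rng, 100, f"r{i}")
            fam = evolve_tree(root, tree, params, rng=rng)
            lengths.add(len(fam.descendants["Taxon4"].sequence))
        assert lengths != {100}
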