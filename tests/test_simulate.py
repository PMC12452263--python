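"""Synthetic species generator, count simulator, and experiment drivers."""

import numpy as np
import pytest
from scipy.stats import chisquare

from clademix.basecalls import hamming_distances
from clademix.clades import CladeDefinition, PhylogenyModel
from clademix.classify import ClassifyParams
from clademix.model import nb_logpmf
from clademix.simulate import (
    MixtureSpec,
    SyntheticSpecies,
    holdout_experiment,
    mixture_benchmark,
    mixture_truth,
    simulate_counts,
    simulate_species,
    true_dvb,
)


class TestSimulateSpecies:
    def test_deterministic_given_seed(self):
        a = simulate_species(n_tips=8, mutation_scale=300, seed=5)
        b = simulate_species(n_tips=8, mutation_scale=300, seed=5)
        assert np.array_equal(a.genotypes, b.genotypes)
        assert np.array_equal(a.positions, b.positions)
        assert a.model.to_newick() == b.model.to_newick()

    def test_infinite_sites_hamming_equals_patristic(self, small_species):
        dist = hamming_distances(small_species.to_basecall_matrix())
        pdm = small_species.model.tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in small_species.model.tree.taxon_namespace}
        for i, g1 in enumerate(small_species.genomes):
            for g2 in small_species.genomes[i + 1:]:
                assert dist.loc[g1, g2] == pdm.patristic_distance(taxa[g1], taxa[g2])

    def test_branch_lengths_equal_mutation_counts(self, small_species):
        # every column is one mutation; total mutations == total branch length
        total_len = sum(e.length for e in small_species.model.tree.preorder_edge_iter()
                        if e.length)
        assert total_len == small_species.positions.size

    def test_bootstraps_are_one(self, small_species):
        root = small_species.model.tree.seed_node
        for nd in small_species.model.tree.preorder_internal_node_iter():
            if nd is not root:
                assert float(nd.label) == 1.0

    def test_too_few_tips_errors(self):
        with pytest.raises(ValueError):
            simulate_species(n_tips=3)


def _handmade_species(k_shared: int):
    """One 'novel' genome carrying the first k of 100 clade markers."""
    P = 120
    positions = np.arange(P)
    ref = np.zeros(P, dtype=np.int8)  # all A
    geno = np.zeros((1, P), dtype=np.int8)
    geno[0, :k_shared] = 1  # carries C at the first k marker positions
    model = PhylogenyModel.from_newick("(x:1,(y:1,z:1)1.0:1):0;", snv_scaled=True)
    sp = SyntheticSpecies(model=model, genomes=["x"], positions=positions,
                          ref_alleles=ref, genotypes=geno, seed=0, mutation_scale=1.0)
    clade = CladeDefinition("b", frozenset({"y", "z"}),
                            cs_alleles=tuple((int(p), 1) for p in range(100)))
    return sp, clade


class TestTrueDvb:
    @pytest.mark.parametrize("k_shared,expected", [
        (100, 0.0),   # diverges at the top of the branch: shares everything
        (0, 1.0),     # diverges at the bottom: shares nothing
        (50, 0.5),    # midway: 50 of 100 branch SNVs shared
    ])
    def test_shared_fraction(self, k_shared, expected):
        sp, clade = _handmade_species(k_shared)
        assert true_dvb(sp, clade, "x") == pytest.approx(expected)

    def test_requires_markers(self):
        sp, _ = _handmade_species(0)
        with pytest.raises(ValueError):
            true_dvb(sp, CladeDefinition("b", frozenset({"y"})), "x")


class TestSimulateCounts:
    def test_single_genome_clean_counts_match_genotype(self, small_species):
        g = small_species.genomes[0]
        mix = MixtureSpec(members=(g,), abundances=(1.0,), coverage=10.0,
                          error_rate=0.0, depth_overdispersion=0.3)
        pos = small_species.positions[:500]
        sample = simulate_counts(small_species, mix, pos, seed=1)
        geno = small_species.genotypes[small_species.genome_index(g), :500]
        covered = sample.counts.sum(axis=1) > 0
        assert covered.any()
        assert np.array_equal(np.argmax(sample.counts[covered], axis=1), geno[covered])

    def test_zero_coverage_gives_all_zero(self, small_species):
        mix = MixtureSpec(members=(small_species.genomes[0],), abundances=(1.0,),
                          coverage=0.0)
        sample = simulate_counts(small_species, mix, small_species.positions[:100], seed=2)
        assert sample.counts.sum() == 0

    def test_depth_marginals_match_nb(self, small_species):
        cov, alpha = 10.0, 0.3
        mix = MixtureSpec(members=(small_species.genomes[0],), abundances=(1.0,),
                          coverage=cov, error_rate=0.0, depth_overdispersion=alpha)
        pos = small_species.positions
        sample = simulate_counts(small_species, mix, pos, seed=3)
        depth = sample.counts.sum(axis=1)
        assert depth.mean() == pytest.approx(cov, rel=0.02)
        assert depth.var() == pytest.approx(cov * (1 + alpha * cov), rel=0.10)
        # chi-square goodness of fit against the NB pmf
        hi = 35
        observed = np.bincount(np.minimum(depth, hi), minlength=hi + 1)
        probs = np.exp(nb_logpmf(np.arange(hi + 1), cov, alpha))
        probs[hi] = 1.0 - probs[:hi].sum()
        _, p = chisquare(observed, probs * depth.size, ddof=0)
        assert p > 0.01

    def test_even_mixture_allele_fractions(self, small_species):
        g1, g2 = small_species.genomes[0], small_species.genomes[1]
        i1, i2 = (small_species.genome_index(g) for g in (g1, g2))
        differs = np.flatnonzero(small_species.genotypes[i1] != small_species.genotypes[i2])[:300]
        pos = small_species.positions[differs]
        mix = MixtureSpec(members=(g1, g2), abundances=(0.5, 0.5), coverage=200.0,
                          error_rate=0.0, depth_overdispersion=0.0)
        sample = simulate_counts(small_species, mix, pos, seed=4)
        a1 = small_species.genotypes[i1, differs]
        frac = sample.counts[np.arange(pos.size), a1] / sample.counts.sum(axis=1)
        assert frac.mean() == pytest.approx(0.5, abs=0.02)

    def test_deterministic_given_seed(self, small_species):
        mix = MixtureSpec(members=(small_species.genomes[0],), abundances=(1.0,),
                          coverage=5.0)
        a = simulate_counts(small_species, mix, small_species.positions[:200], seed=9)
        b = simulate_counts(small_species, mix, small_species.positions[:200], seed=9)
        assert np.array_equal(a.counts, b.counts)

    def test_abundances_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            MixtureSpec(members=("a", "b"), abundances=(0.5, 0.6), coverage=1.0)


class TestHoldoutExperiment:
    def test_row_bookkeeping_and_recovery(self, small_species):
        tab = holdout_experiment(
            small_species, coverage_grid=(10.0, 5.0), seed=2,
            classify_params=ClassifyParams(n_steps=1200, seed=0),
        )
        assert len(tab) > 0
        # every scenario contributes one row per coverage
        assert (tab.groupby("scenario").size() == 2).all()
        assert ((tab.true_dvb >= 0) & (tab.true_dvb <= 1)).all()
        ten = tab[tab.coverage == 10.0]
        # pi tracks the true divergence closely on modeled scenarios
        assert np.abs(ten.map_pi - ten.true_dvb).max() < 0.15

    def test_deterministic(self, small_species):
        kw = dict(coverage_grid=(10.0,), seed=3,
                  classify_params=ClassifyParams(n_steps=600, seed=0))
        a = holdout_experiment(small_species, **kw)
        b = holdout_experiment(small_species, **kw)
        assert a.equals(b)


class TestMixtureBenchmark:
    def test_perfect_database_high_coverage(self, small_species, small_db):
        tab = mixture_benchmark(
            small_species, db=small_db, n_replicates=3, coverage_grid=(10.0,),
            n_strains=3, seed=4, classify_params=ClassifyParams(n_steps=1200, seed=0),
        )
        assert len(tab) == 3
        assert (tab.precision.dropna() == 1.0).all()
        assert tab.recall.mean() > 0.9
        assert tab.l2.mean() < 0.1

    def test_nothing_detected_gives_na_precision(self, small_species, small_db):
        tab = mixture_benchmark(
            small_species, db=small_db, n_replicates=2, coverage_grid=(0.001,),
            n_strains=3, seed=5, classify_params=ClassifyParams(n_steps=400, seed=0),
        )
        assert tab.precision.isna().all()
        assert (tab.recall == 0.0).all()

    def test_truth_frequencies_sum_to_member_mass(self, small_db):
        members = tuple(sorted(small_db.clades[0].members))[:2]
        mix = MixtureSpec(members=members, abundances=(0.6, 0.4), coverage=1.0)
        truth = mixture_truth(small_db, mix)
        assert all(c in truth.present_clades
                   for c in [cl.clade_id for cl in small_db.clades
                             if set(members) & cl.members])
        assert sum(truth.frequencies) <= 1.0 + 1e-9
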