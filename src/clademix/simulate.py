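"""Synthetic species, metagenome mixtures, and benchmark drivers.

The generator emulates the statistical structure the classifier consumes,
without touching reads or alignment: clonal genomes evolved on a known tree
under infinite sites (every mutation hits a fresh position, so Hamming
distances equal patristic mutation counts exactly), multi-strain mixtures at
lognormal abundances, and per-position read depth with negative-binomial
overdispersion plus a uniform base-error rate.

Two experiment drivers reproduce the method's validation designs: the
clade hold-out experiment (classify a genome whose clade was removed from
the database, compare the inferred zero-inflation ``pi`` against the true
branch-sharing divergence DVb) and the multi-strain mixture benchmark
(precision / recall / F1 / L2 of clade detection at a grid of coverages).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .basecalls import BaseCallMatrix
from .clades import CladeDefinition, DatabaseParams, PhylogenyModel, ReferenceDatabase, build_database
from .classify import ClassifyParams, SampleCounts, classify_sample

__all__ = [
    "SyntheticSpecies",
    "MixtureSpec",
    "SyntheticTruth",
    "simulate_species",
    "true_dvb",
    "simulate_counts",
    "holdout_experiment",
    "mixture_benchmark",
]

_OTHER_ALLELES = np.array([[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]])


@dataclass
class SyntheticSpecies:
    """A clonal species with known phylogeny and genotypes.

    ``genotypes`` holds allele codes (0..3) for every genome at every
    polymorphic position; ``positions`` are the (sorted) reference
    coordinates those columns correspond to. Infinite-sites: each position
    mutated exactly once, and every branch length equals its mutation count.
    """

    model: PhylogenyModel
    genomes: list
    positions: np.ndarray
    ref_alleles: np.ndarray
    genotypes: np.ndarray
    seed: int
    mutation_scale: float

    def genome_index(self, genome_id: str) -> int:
        return self.genomes.index(genome_id)

    def to_basecall_matrix(self, genomes: Optional[Sequence[str]] = None) -> BaseCallMatrix:
        """Noise-free base-call matrix over the polymorphic positions.

        Synthetic stand-in for a filtered alignment of isolate genomes: no
        ambiguous calls, uniform nominal coverage.
        """
        sel = list(self.genomes) if genomes is None else list(genomes)
        idx = [self.genome_index(g) for g in sel]
        return BaseCallMatrix(
            genomes=sel,
            positions=self.positions.copy(),
            calls=self.genotypes[idx].copy(),
            genome_median_coverage=np.full(len(sel), np.nan),
            position_median_coverage=np.full(self.positions.size, np.nan),
            provenance=[{"event": "synthetic_species", "seed": self.seed}],
        )


def simulate_species(
    n_tips: int = 24,
    mutation_scale: float = 2000.0,
    genome_length: int = 2_000_000,
    seed: int = 0,
    branch_time_sigma: float = 0.8,
) -> SyntheticSpecies:
    """Evolve a clonal species on a random tree under infinite sites.

    Topology is built by random sequential joins; each branch gets an
    independent lognormal(0, ``branch_time_sigma``^2) time length and a
    Poisson(``mutation_scale`` x time) number of mutations, each at a fresh
    position drawn from a ``genome_length``-bp reference. Branch lengths are
    then set to the realized mutation counts (SNV units) and bootstrap
    supports to 1.0. Deterministic given ``seed``.
    """
    if n_tips < 4:
        raise ValueError("need at least 4 tips")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    nodes = []
    for i in range(n_tips):
        leaf = dendropy.Node()
        leaf.taxon = taxa.new_taxon(f"g{i:03d}")
        nodes.append(leaf)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = nodes[0]

    edges = [nd.edge for nd in tree.preorder_node_iter() if nd.parent_node is not None]
    times = rng.lognormal(mean=0.0, sigma=branch_time_sigma, size=len(edges))
    counts = rng.poisson(mutation_scale * times)
    total = int(counts.sum())
    if total > genome_length:
        raise ValueError("genome_length too small for the realized number of mutations")
    sites = np.sort(rng.choice(genome_length, size=total, replace=False))
    # scatter mutations over branches in preorder; infinite sites by construction
    perm = rng.permutation(total)
    ref = rng.integers(0, 4, size=total, dtype=np.int8)
    derived = ((ref + rng.integers(1, 4, size=total)) % 4).astype(np.int8)

    genomes = sorted(t.label for t in taxa)
    g_idx = {g: i for i, g in enumerate(genomes)}
    genotypes = np.tile(ref, (n_tips, 1))
    offset = 0
    for edge, m in zip(edges, counts):
        edge.length = float(m)
        muts = perm[offset: offset + m]
        offset += m
        for leaf in edge.head_node.leaf_iter():
            genotypes[g_idx[leaf.taxon.label], muts] = derived[muts]
    for nd in tree.preorder_internal_node_iter():
        if nd.parent_node is not None:
            nd.label = "1.00"
    model = PhylogenyModel(tree=tree, snv_scaled=True)
    return SyntheticSpecies(
        model=model, genomes=genomes, positions=sites, ref_alleles=ref,
        genotypes=genotypes, seed=int(seed), mutation_scale=float(mutation_scale),
    )


def true_dvb(species: SyntheticSpecies, clade: CladeDefinition, novel_genome: str) -> float:
    """True divergence of a strain from a database clade (branch b).

    Under infinite sites, a clade's marker alleles are exactly the mutations
    on its subtending branch, so the shared/total branch-length ratio equals
    the fraction of markers the novel genome carries:

        DVb = 1 - (branch length shared) / (branch length total)

    Clamped to [0, 1]; requires ``clade.cs_alleles``.
    """
    if not clade.cs_alleles:
        raise ValueError("clade has no marker alleles; run find_cs_alleles first")
    g = species.genotypes[species.genome_index(novel_genome)]
    col = {int(p): j for j, p in enumerate(species.positions)}
    shared = 0
    for p, a in clade.cs_alleles:
        if p in col and int(g[col[p]]) == a:
            shared += 1
    return float(np.clip(1.0 - shared / len(clade.cs_alleles), 0.0, 1.0))


@dataclass(frozen=True)
class MixtureSpec:
    """A synthetic metagenome recipe for one focal species.

    ``coverage`` is the focal species' total expected depth over database
    positions; member genomes split it at ``abundances`` (must sum to 1).
    ``holdout_members`` contribute an *additional*
    ``holdout_extra_frac`` x ``coverage`` of depth (novel strains spiked on
    top of the in-database community). ``error_rate`` relocates each read's
    base call uniformly to another allele; ``depth_overdispersion`` is the
    NB alpha of per-position depth.
    """

    members: tuple
    abundances: tuple
    coverage: float
    error_rate: float = 0.001
    depth_overdispersion: float = 0.3
    holdout_members: tuple = ()
    holdout_abundances: tuple = ()
    holdout_extra_frac: float = 0.25

    def __post_init__(self):
        ab = np.asarray(self.abundances, dtype=float)
        if len(self.members) != ab.size:
            raise ValueError("one abundance per member required")
        if not np.isclose(ab.sum(), 1.0):
            raise ValueError(f"abundances must sum to 1, got {ab.sum()}")
        if self.holdout_members and len(self.holdout_members) != len(self.holdout_abundances):
            raise ValueError("one abundance per held-out member required")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one mixture against one database."""

    present_clades: frozenset
    clade_set: tuple
    frequencies: tuple


def mixture_truth(db: ReferenceDatabase, mixture: MixtureSpec,
                  clade_set: Optional[Sequence[str]] = None) -> SyntheticTruth:
    """True clade presence and composition of a mixture.

    A database clade is truly present when at least one mixture member (in-
    database members only) belongs to it; the true frequency of a clade in
    the non-overlapping set is the summed abundance of its members,
    discounted by the extra depth held-out strains contribute.
    """
    members = set(mixture.members)
    present = frozenset(
        c.clade_id for c in db.clades if c.members & members
    )
    set_ids = [c.clade_id for c in db.minimal_clades()] if clade_set is None else list(clade_set)
    ab = dict(zip(mixture.members, mixture.abundances))
    # held-out strains dilute the in-database fraction of focal depth
    dilution = 1.0 / (1.0 + (mixture.holdout_extra_frac if mixture.holdout_members else 0.0))
    freqs = tuple(
        dilution * sum(ab.get(g, 0.0) for g in db.get(cid).members) for cid in set_ids
    )
    return SyntheticTruth(present_clades=present, clade_set=tuple(set_ids), frequencies=freqs)


def simulate_counts(
    species: SyntheticSpecies,
    mixture: MixtureSpec,
    db_positions: np.ndarray,
    seed=None,
    sample_id: str = "synthetic",
) -> SampleCounts:
    """Generate per-position allele counts for a mixture over ``db_positions``.

    Depth at each position is NB(total coverage, depth overdispersion);
    reads are allocated to member genomes multinomially by abundance and
    report the member's allele, except an ``error_rate`` fraction relocated
    uniformly to the other three alleles. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    db_positions = np.asarray(db_positions, dtype=np.int64)
    P = db_positions.size
    counts = np.zeros((P, 4), dtype=np.int64)
    all_members = list(mixture.members) + list(mixture.holdout_members)
    w = np.asarray(mixture.abundances, dtype=float)
    if mixture.holdout_members:
        hw = np.asarray(mixture.holdout_abundances, dtype=float)
        hw = hw / hw.sum() * mixture.holdout_extra_frac
        weights = np.concatenate([w, hw])
    else:
        weights = w
    total_cov = mixture.coverage * weights.sum()
    if total_cov <= 0 or P == 0:
        return SampleCounts(db_positions, counts, sample_id=sample_id)
    weights = weights / weights.sum()

    alpha = mixture.depth_overdispersion
    if alpha > 0:
        r = 1.0 / alpha
        depth = rng.negative_binomial(r, r / (r + total_cov), size=P)
    else:
        depth = rng.poisson(total_cov, size=P)

    split = rng.multinomial(depth, weights)  # (P, K)
    col = np.searchsorted(species.positions, db_positions)
    ok = (col < species.positions.size)
    if not np.all(species.positions[np.clip(col, 0, species.positions.size - 1)][ok] == db_positions[ok]):
        raise ValueError("db_positions must be a subset of the species' polymorphic positions")
    for k, member in enumerate(all_members):
        g = species.genotypes[species.genome_index(member)][col]  # allele per position
        n_k = split[:, k]
        if mixture.error_rate > 0:
            errs = rng.binomial(n_k, mixture.error_rate)
            correct = n_k - errs
            err_split = rng.multinomial(errs, np.full(3, 1.0 / 3.0))  # (P, 3)
            np.add.at(counts, (np.arange(P), g), correct)
            others = _OTHER_ALLELES[g]  # (P, 3)
            np.add.at(counts, (np.repeat(np.arange(P), 3), others.ravel()), err_split.ravel())
        else:
            np.add.at(counts, (np.arange(P), g), n_k)
    return SampleCounts(db_positions, counts, sample_id=sample_id)


# --- experiment drivers ----------------------------------------------------

def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def holdout_experiment(
    species: SyntheticSpecies,
    coverage_grid: Sequence[float] = (10.0,),
    seed: int = 0,
    db_params: DatabaseParams = DatabaseParams(),
    classify_params: ClassifyParams = ClassifyParams(),
    depth_overdispersion: float = 0.3,
    error_rate: float = 0.001,
    max_scenarios: Optional[int] = None,
) -> pd.DataFrame:
    """Clade hold-out validation of divergence estimates.

    For every internal non-root node, each daughter clade is held out in
    turn (root-daughter hold-outs are excluded): its genomes are removed
    from the matrix and tree, the database is rebuilt, and one held-out
    genome is classified at each coverage. The clade the novel genome
    attaches to is the merged branch formed by the node's stem plus the
    remaining daughter's branch; the scenario contributes a (true DVb,
    MAP pi) pair for that clade. Scenarios whose merged clade fails the
    database criteria are skipped.

    Returns a tidy table with one row per scenario x coverage.
    """
    root = species.model.tree.seed_node
    scenarios = []
    for nd in species.model.tree.preorder_internal_node_iter():
        if nd is root:
            continue
        kids = nd.child_nodes()
        for held in kids:
            rest = [c for c in kids if c is not held]
            if not rest:
                continue
            keep_tips = frozenset(
                leaf.taxon.label for c in rest for leaf in c.leaf_iter()
            )
            if len(keep_tips) < db_params.min_genomes:
                continue
            held_tips = frozenset(leaf.taxon.label for leaf in held.leaf_iter())
            scenarios.append((held_tips, keep_tips))
    if max_scenarios is not None:
        scenarios = scenarios[:max_scenarios]

    ss = np.random.SeedSequence(seed)
    rows = []
    for s_idx, (held_tips, sibling_tips) in enumerate(scenarios):
        kept_genomes = sorted(set(species.genomes) - held_tips)
        if len(kept_genomes) < 2:
            continue
        matrix = species.to_basecall_matrix(kept_genomes)
        pruned = species.model.tree.extract_tree_with_taxa_labels(kept_genomes)
        pruned_model = PhylogenyModel(tree=pruned, snv_scaled=True)
        try:
            db = build_database(matrix, pruned_model, db_params)
        except ValueError:
            continue
        merged = [c for c in db.clades if c.members == sibling_tips]
        if not merged:
            continue  # merged clade failed a database criterion
        merged = merged[0]
        child = ss.spawn(1)[0]
        pick_rng = np.random.default_rng(_child_seed(child))
        novel = sorted(held_tips)[pick_rng.integers(len(held_tips))]
        truth = true_dvb(species, merged, novel)
        db_pos = db.informative_positions()
        for cov in coverage_grid:
            counts = simulate_counts(
                species,
                MixtureSpec(members=(novel,), abundances=(1.0,), coverage=float(cov),
                            error_rate=error_rate, depth_overdispersion=depth_overdispersion),
                db_pos, seed=child.spawn(1)[0],
            )
            res = classify_sample(counts, db, classify_params, clade_ids=[merged.clade_id])
            fit = res.get(merged.clade_id)
            rows.append({
                "scenario": s_idx, "coverage": float(cov),
                "n_held_out": len(held_tips), "novel_genome": novel,
                "clade_id": merged.clade_id, "n_cs": merged.n_cs,
                "true_dvb": truth, "map_pi": fit.map_pi, "pi_mean": fit.pi_mean,
                "modeled": fit.modeled, "detected": fit.detected,
            })
    return pd.DataFrame(rows)


def mixture_benchmark(
    species: SyntheticSpecies,
    db: Optional[ReferenceDatabase] = None,
    n_replicates: int = 15,
    coverage_grid: Sequence[float] = (0.5, 1.0, 5.0, 10.0, 20.0),
    n_strains: int = 5,
    seed: int = 0,
    db_params: DatabaseParams = DatabaseParams(),
    classify_params: ClassifyParams = ClassifyParams(),
    freq_threshold: float = 0.01,
    lognormal_mu: float = 1.0,
    lognormal_sigma: float = 1.0,
    depth_overdispersion: float = 0.3,
    error_rate: float = 0.001,
    holdout_fraction: float = 0.0,
) -> pd.DataFrame:
    """Multi-strain mixture benchmark: detection and composition accuracy.

    Per replicate, ``n_strains`` random genomes are mixed at normalized
    lognormal(``mu``, ``sigma``) abundances and classified. A clade counts
    as detected when the classifier calls it present *and* its estimated
    frequency exceeds ``freq_threshold``. Precision = true detections /
    all detections (NA when nothing is detected), recall = true detections /
    truth clades, F1 = 2PR/(P+R); L2 is the Euclidean distance between true
    and estimated composition over the database's minimal clade set.

    With ``holdout_fraction`` > 0 that fraction of minimal clades is removed
    from the database and each mixture is spiked with ``n_strains`` held-out
    genomes carrying an extra 25% of the focal depth.
    """
    ss = np.random.SeedSequence(seed)
    setup_rng = np.random.default_rng(_child_seed(ss.spawn(1)[0]))
    holdout_pool: list = []
    if db is None or holdout_fraction > 0:
        genomes = list(species.genomes)
        if holdout_fraction > 0:
            base_db = db
            if base_db is None:
                base_db = build_database(species.to_basecall_matrix(), species.model, db_params)
            minimal = base_db.minimal_clades()
            n_drop = max(1, int(round(holdout_fraction * len(minimal))))
            drop = setup_rng.choice(len(minimal), size=n_drop, replace=False)
            dropped_genomes = set().union(*(minimal[i].members for i in drop))
            holdout_pool = sorted(dropped_genomes)
            genomes = sorted(set(genomes) - dropped_genomes)
            matrix = species.to_basecall_matrix(genomes)
            pruned = species.model.tree.extract_tree_with_taxa_labels(genomes)
            db = build_database(matrix, PhylogenyModel(tree=pruned, snv_scaled=True), db_params)
        elif db is None:
            db = build_database(species.to_basecall_matrix(), species.model, db_params)
    pool = sorted(set(species.genomes) - set(holdout_pool))
    db_pos = db.informative_positions()
    minimal_ids = [c.clade_id for c in db.minimal_clades()]

    rows = []
    for cov in coverage_grid:
        for rep in range(n_replicates):
            child = ss.spawn(1)[0]
            rng = np.random.default_rng(_child_seed(child))
            members = tuple(np.array(pool)[rng.choice(len(pool), size=n_strains, replace=False)])
            ab = rng.lognormal(mean=lognormal_mu, sigma=lognormal_sigma, size=n_strains)
            ab = tuple(ab / ab.sum())
            if holdout_pool:
                hmembers = tuple(
                    np.array(holdout_pool)[rng.choice(len(holdout_pool),
                                                      size=min(n_strains, len(holdout_pool)),
                                                      replace=False)]
                )
                hab = rng.lognormal(mean=lognormal_mu, sigma=lognormal_sigma, size=len(hmembers))
                mix = MixtureSpec(members=members, abundances=ab, coverage=float(cov),
                                  error_rate=error_rate,
                                  depth_overdispersion=depth_overdispersion,
                                  holdout_members=hmembers, holdout_abundances=tuple(hab))
            else:
                mix = MixtureSpec(members=members, abundances=ab, coverage=float(cov),
                                  error_rate=error_rate,
                                  depth_overdispersion=depth_overdispersion)
            counts = simulate_counts(species, mix, db_pos, seed=child.spawn(1)[0])
            res = classify_sample(counts, db, classify_params)
            truth = mixture_truth(db, mix, clade_set=minimal_ids)

            detected = {
                f.clade_id for f in res.fits
                if f.detected and f.frequency > freq_threshold
            }
            tp = len(detected & truth.present_clades)
            precision = tp / len(detected) if detected else np.nan
            recall = tp / len(truth.present_clades) if truth.present_clades else np.nan
            if detected and truth.present_clades and (tp > 0):
                f1 = 2 * precision * recall / (precision + recall)
            else:
                f1 = 0.0 if (detected or truth.present_clades) else np.nan
            est = np.asarray(res.frequencies)
            l2 = float(np.linalg.norm(est - np.asarray(truth.frequencies)))
            rows.append({
                "coverage": float(cov), "replicate": rep,
                "n_truth": len(truth.present_clades), "n_detected": len(detected),
                "true_positives": tp, "precision": precision, "recall": recall,
                "f1": f1, "l2": l2,
            })
    return pd.DataFrame(rows)
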