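# Methods

## Problem setting

A metagenomic sample contains an unknown mixture of strains of a focal
species. Given a collection of sequenced isolates of that species and its
phylogeny, we want (i) the relative abundance of each phylogenetic clade in
the sample, at every resolution the tree supports, and (ii) for each clade, a
measure of whether the sample's strains are *members* of that clade or
*relatives* that diverged partway along the branch leading to it. The second
quantity is what protects the first from the ubiquitous failure mode of
reference-based profiling: novel strains masquerading as low-abundance known
strains.

## Reference database

**Base calls.** Input is a table of per-strand nucleotide counts per genome
per aligned position (produced upstream by any aligner/pileup; alignment
itself is out of scope). A call is the major allele unless any ambiguity
trigger fires, in which case it is N: variant-quality FQ above −30 (when FQ
is available; otherwise the trigger is skipped with a warning), per-strand
depth below 3×, major-allele frequency below 0.85, indel support within 3 bp
above 33%, a tied major allele, or zero coverage. Filters then run in a
fixed order: (1) genomes with median coverage below 8× are dropped; (2) bases
are called on the survivors; (3) positions are dropped when more than 10% of
genomes are N, median coverage is below 5×, or median coverage exceeds twice
the median over core positions (a copy-number proxy; "core" = positions
passing the N-fraction filter, the most self-consistent reading since the
coverage filters have not yet run); (4) genomes with more than 10% N over the
retained positions are dropped. Order matters and is part of the contract:
position statistics see only genomes surviving step 1. Every removal is
recorded in a provenance log. Coordinates are 0-based internally, 1-based in
every file written or read.

**Tree scaling.** Clade discovery thresholds are in SNV units, so branch
lengths (often substitutions/site from a likelihood method) are rescaled by
the least-squares slope *through the origin* of patristic distance against
core-genome Hamming distance (N counted as a mismatch by default), provided
their Pearson correlation exceeds 0.75. The origin constraint is the only
scale-preserving choice (zero distance must map to zero SNVs). If the
correlation test fails the tree is left unscaled with a warning and the
branch-length threshold applies in tree units — the caller should then set
it deliberately.

**Clades and markers.** Every branch whose clade has ≥ 3 genomes, length
≥ 1000 SNVs, and bootstrap > 0.75 becomes a candidate clade; output is
hierarchical (nested clades are kept). The two root-incident branches are
skipped: on a midpoint-rooted tree they would duplicate each other's
complement. A clade's markers are positions where all non-ambiguous in-clade
calls agree, fewer than 10% of in-clade genomes are ambiguous, and the allele
appears in *no* genome outside the clade (at least one outside genome must
carry a different non-ambiguous call, otherwise the site marks nothing).
Genomes of *other* species that recruit reads ("outgroups") act differently:
they exclude whole positions when more than 10% of outgroup genomes have any
non-ambiguous call there. Clades retaining fewer than 10 markers are dropped
(manually specified clades included — a manual clade that cannot be detected
should be visible as such, not silently special-cased). The database
serializes to a single HDF5 container with a JSON metadata block (h5py with
timestamp tracking disabled, so identical inputs rebuild byte-identical
files) plus a TSV marker export.

## Classification model

For clade *b* with *n* informative positions, let x⁽ᵃˡˡ⁾ be the total read
depth and x⁽ᶜˢ⁾ the depth supporting the marker allele at those positions.
Positions with zero coverage are *retained* in both vectors: zeros are the
signal the model disentangles.

- Step 1: x⁽ᵃˡˡ⁾ ~ NB(λ⁽ᵃˡˡ⁾, α⁽ᵃˡˡ⁾), parameterized with mean λ and
  variance λ(1 + αλ), so α → 0 is the Poisson limit. This measures how deep
  and how overdispersed the sample is at exactly these loci.
- Step 2: x⁽ᶜˢ⁾ ~ ZINB(λ⁽ᶜˢ⁾, α⁽ᶜˢ⁾, π) = π·1[x=0] + (1−π)·NB. The
  zero-inflation π is the probability a marker is *systematically* missing.
  A strain that diverged partway along branch *b* carries only the markers
  accumulated before its divergence point, so under clock-like accumulation
  π estimates the divergence DVb = 1 − shared/total branch length. The
  step-one posterior over α⁽ᵃˡˡ⁾ becomes the prior over α⁽ᶜˢ⁾ — both counts
  arise from the same sequencing process at the same loci — which is what
  keeps π identifiable at low coverage, where "many zeros" could otherwise
  be explained by overdispersion alone.

**Priors** (the inference machinery is fully specified here because no
canonical choice exists): π ~ Uniform(0,1); λ half-flat with upper bound
10× the maximum observed count; α⁽ᵃˡˡ⁾ ~ lognormal(0, 2²) (weak); α⁽ᶜˢ⁾ ~
lognormal moment-matched to the log of the step-one α draws (σ floored at
0.05). A point-mass prior pins α⁽ᶜˢ⁾ and removes it from the sweep; a flat
prior is available for ablation.

**Sampling.** Slice-within-Gibbs: univariate slice updates (stepping-out
with at most 20 expansions, then shrinkage) in the fixed sweep order
λ → α → π, 10,000 steps by default with the first 10% discarded. Initial
widths are posterior-scale guesses (λ: sample mean; α: 0.5; π: 0.25). A
generic reference implementation lives in `model.slice_within_gibbs`; the
fits call numba-compiled kernels implementing the identical scheme with
counts collapsed to unique values (likelihood cost is O(#unique values) per
evaluation, which is what makes thousand-clade benchmark runs practical).
Everything is deterministic given a seed; per-clade seeds fan out from the
run seed through `numpy.random.SeedSequence` by database clade index, so
classifying a subset of clades reproduces the full run's numbers.

**Maximum-likelihood path.** Nelder-Mead on (λ, α) for the NB, then (λ, π)
with α fixed at the step-one MLE, five restarts spread over π; standard
errors from the numerically differentiated observed information, with
Laplace-approximate draws materialized so detection and HPD machinery treat
both paths uniformly.

**Summaries and detection.** MAP π is the mode of a Silverman-bandwidth
Gaussian KDE over the draws (posterior mean reported alongside); the 95% HPD
interval is the shortest window covering ⌊0.95·n⌋ index offsets of the
sorted draws (leftmost on ties; mass 1 returns the full range). A clade is
called present when P(π < 0.35) ≥ 0.5 *and* the HPD lower bound of π is
below 0.1. Only clades with more than 10 marker-supporting reads (summed
over positions — the per-position-maximum reading of the gate is defensible
too, but the sum is stabler at low coverage) are modeled at all. Relative
abundance is mean(λ⁽ᶜˢ⁾)/mean(λ⁽ᵃˡˡ⁾) clipped to [0,1]. Clades are fitted
independently, so frequencies over a user-chosen non-overlapping clade set
(default: the database's minimal clades) need not sum to 1; a total above 1
is rescaled and flagged, and the shortfall below 1 is reported as the
unclassified (novel) fraction.

## Synthetic data

The generator produces what the classifier consumes — counts — rather than
reads. A random-join topology receives independent lognormal(0, 0.8²)
branch time-lengths and Poisson(scale × time) mutation counts under infinite
sites; branch lengths are then the realized mutation counts, so Hamming
distances equal patristic distances exactly and every clade's markers are
exactly its branch's mutations. The default `mutation_scale` of 2000
expected SNVs per unit time puts typical internal branches above the
1000-SNV clade criterion, mimicking a species with well-separated
phylogroups and lineages. Mixtures combine genomes at normalized
lognormal(μ=1, σ=1) abundances; per-position depth is NB with
overdispersion 0.3 (a plausible shotgun value) around the focal coverage,
reads are allocated multinomially by abundance, and a base-error rate of
0.001 relocates counts uniformly to the other alleles — this error term also
stands in for read mismapping from background species, which are not
simulated explicitly.

What this does *not* emulate: recombination (markers can be acquired
laterally in real genomes, blurring the π ↔ divergence-time mapping),
homoplasy and reversion, reference bias and alignability variation along the
genome, within-position strand artifacts, and chimeric or contaminated
reference genomes. Passing benchmarks therefore demonstrate the estimator's
statistical correctness under its own model assumptions, not robustness to
every artifact of real sequencing data.

**Hold-out experiment.** For every internal non-root node, each daughter
clade is held out in turn (root-daughter hold-outs excluded, as they are
artifacts of rooting): its genomes are removed from matrix and tree, the
database is rebuilt, and one held-out genome is classified at 10× over the
database positions. The clade the novel genome attaches to is the merged
branch (the node's stem plus the remaining daughter's branch, which the tree
pruner concatenates); the scenario contributes one (true DVb, MAP π) pair,
with truth computed from genotypes as 1 − the carried fraction of the merged
clade's markers. Coverage is defined over database positions (whether the
original work measured per-clade coverage over markers or the whole genome
is not stated; the difference is a constant factor on these simulations).

**Mixture benchmark.** Five genomes per replicate, 15 replicates per
coverage in {0.5, 1, 5, 10, 20}×, perfect database; a clade is "detected"
when the posterior presence call fires *and* its estimated frequency exceeds
1%; truth is every database clade containing a mixture member. Precision =
true detections / all detections (undefined and reported as NA when nothing
is detected), recall = true detections / truth clades, F1 = 2PR/(P+R); L2 is
the Euclidean distance between true and estimated composition over the
minimal clade set. An optional mode removes a fraction of minimal clades
from the database and spikes each mixture with held-out genomes at an extra
25% of the focal depth.

## Problem sizes and chain lengths

The validation drivers use a 48-tip species for the hold-out design (which
yields 20–27 qualifying scenarios depending on topology) and a 24-tip
species for mixtures. The acceptance script runs chains of 4000 (hold-out)
and 2500 (mixture) steps, and the test suite 1500; on these posteriors —
unimodal, 2–3 parameters, hundreds to thousands of informative positions —
the summary statistics are indistinguishable from the 10,000-step default,
which remains the default for real-data use.

## Known limitations

One divergence estimate per branch: when a known clade and a close novel
relative co-occur, the more abundant signal dominates π for that branch.
Divergence is calibrated in mutations, not time, and is hard to interpret
for highly recombinogenic species. Classification is single-species;
cross-species analyses are out of scope. The MLE path's uncertainty is a
Laplace approximation and degrades when π̂ sits on the boundary.
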