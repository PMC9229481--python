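# Methods

`halorange` packages three computational strands of a virus–host-range study
of halophilic archaea: (i) building a plaque-confirmed host-range matrix with
efficiencies of plating, (ii) genome motif statistics relevant to
restriction–modification (RM) escape, and (iii) a phylogenetic-signal test for
a binary infectivity trait based on stochastic character mapping. A synthetic
data module generates every input with known ground truth so the whole
pipeline is testable offline.

## Host-range matrix and efficiency of plating

A spot-on-lawn screen detects growth inhibition, which can come from
productive infection or from halocins (antimicrobial proteins) contaminating
the lysate. The call logic is therefore strict: a virus–host pair is
*positive* if and only if plaques were observed in the quantitative
double-layer assay; spot inhibition without plaques is flagged
`halocin_suspect` and never counted.

Efficiency of plating is the ratio of plaque titers,
EOP = titer(test host) / titer(reference host), reported both raw and rounded
to one significant figure with halves rounded away from zero (the convention
that reproduces all ten published values in the bundled LR2-5 table). A titer
below detection (`-` in the table) makes the EOP *absent*, optionally with an
upper bound `detection_limit / reference titer`; the assay's detection limit
is not part of the bundled data, so bounds are off by default. `nd` cells are
*untested*. Genome-identity groups (isolates sequenced to be identical) are
input metadata, never inferred; `dedup_unique` collapses each group with at
least one positive member to a single isolate.

The bundled screening table (`halorange.data/lr25_host_range`) transcribes
the published titers of 25 isolates on their isolation hosts and on
*Haloferax gibbonsii* LR2-5, with the two identity pairs HCTV-7/HCTV-12 and
HCTV-6/HCTV-13.

## Genome motif statistics

Counting is overlapping, on a linear sequence; windows containing non-ACGT
symbols are skipped and frequencies use the number of valid windows as
denominator. Both-strand counts add occurrences of the reverse complement on
the forward strand unless the motif is its own reverse complement. Two
densities are reported (forward and both-strand, per kb); the CSV column
`density_per_kb` is the both-strand value, the one relevant for counting
restriction sites.

The avoidance statistic is the Karlin-style tetranucleotide relative
abundance with maximal-order (trinucleotide) expectation,

    tau(abcd) = f(abcd) f(bc) / ( f(abc) f(bcd) ),

with all frequencies symmetrized over the genome and its reverse complement,
making tau strand-invariant. tau ≈ 1 under a third-order-consistent
composition; tau < 0.78 — the conventional cut-off in the genome-signature
literature — flags under-representation. Both the statistic's convention and
the threshold are package choices exposed as configuration: the underlying
study names the motifs it finds avoided but not the statistic its web tool
computed. A vanished component count makes the signature "not evaluable"
rather than infinite; a vanished numerator gives tau = 0 (complete
avoidance).

The conserved-column scan reports alignment columns where the non-focal,
non-gap residues have a *unique* majority residue at conservation ≥ the
configured minimum (default 0.9) and the focal sequence has a different,
non-gap residue. Ties for the majority mean no unique consensus and the
column is skipped. Reports carry both 1-based alignment-column and ungapped
focal coordinates, the latter being the convention behind substitution names
such as T380A.

## Trait model and the phylogenetic-signal test

The binary trait (can / cannot infect the focal host strain) evolves along a
rooted tree with branch lengths under a symmetric two-state CTMC with flip
rate `mu` per unit branch length and stationary distribution (1/2, 1/2):
P(same endpoint states over time t) = (1 + e^(−2·mu·t))/2. Tip-state
likelihoods use Felsenstein pruning with per-node rescaling and a stationary
root prior. Only the trait process is modelled; trees are inputs (one tree,
or a file of trees standing in for a posterior sample), never inferred here.

`ml_rate` maximizes the likelihood over `mu` in
[1e−6, 100 · n_tips / total tree length], on the log scale, to relative
tolerance 1e−6. Monomorphic tip states return the lower bound with a
warning. Because only `mu·t` enters the likelihood, doubling all branch
lengths halves the estimate exactly — rate and time are not separately
identifiable.

Stochastic character mapping draws full change histories conditional on the
tips: internal states by backward pruning / forward sampling from their exact
joint conditional, then each branch filled with an endpoint-conditioned path.
For the symmetric chain, uniformization with dominating rate `mu` makes
virtual jumps real jumps, so the per-branch jump count is parity-restricted
Poisson — P(n) ∝ (mu·t)^n/n! over even n when the endpoints agree, odd n when
they differ, with conditional means mu·t·tanh(mu·t) and mu·t·coth(mu·t)
respectively — and change times are i.i.d. uniform on the branch. A branch of
length zero with unequal endpoint states is impossible and raises an error
naming the branch.

The signal test compares the 95% highest-posterior-density (HPD) interval of
the real jump counts against `n_null` (default 10) runs in which the tip
states are randomly *permuted* (state counts preserved — the stricter,
exchangeability-based null) and the entire procedure, including rate
estimation, is repeated. The HPD is the shortest contiguous window of the
sorted sample containing ⌈mass·n⌉ points, ties broken toward the smaller
lower bound. Decision rule: *no signal* if the real HPD intersects at least
one null HPD, *signal* if disjoint from all; per-run overlap flags are always
reported since "clear overlap" is ultimately a judgement. With multiple input
trees, mapping samples are pooled equally across trees.

### Rate uncertainty

By default the signal test does **not** condition on the ML rate point
estimate. For randomized tip states the rate likelihood typically plateaus
toward the upper search bound — the data are compatible with an arbitrarily
fast flipping process — and any single point on that plateau is arbitrary
while the implied jump distribution is not. Conditioning on such a point
makes the jump HPDs spuriously sharp and the overlap decision erratic: in our
simulations the type-I error of the decision (declaring signal on permuted
traits) was roughly 12% with the plug-in estimate and dropped to the nominal
range once the rate was marginalized. The default therefore integrates the
rate over its normalized likelihood on a 41-point log-spaced grid spanning
the ML search interval (a quadrature posterior under a log-uniform prior),
allocating mapping draws to grid points multinomially. This mirrors the fully
Bayesian treatment the method descends from, without MCMC. The plug-in
behaviour remains available via `signal_test(..., marginalize_rate=False)`
and is the sharper choice when the rate is well identified (e.g. the
perfectly clade-partitioned demonstrations).

## Synthetic data

* **Trees**: Yule (pure-birth) process — exponential waiting times from the
  root split, uniform choice of the splitting lineage, and a final
  Exp(n·birth_rate) hold so pendant edges have positive length. Yule is a
  deliberate, simpler stand-in for a coalescent tree prior; the signal test
  is agnostic to tree provenance.
* **Traits**: forward CTMC simulation from a stationary root state, returning
  tip states plus the true history and jump count.
* **Clade-structured datasets** (the power case for the signal test): Yule
  trees redrawn until both root clades hold ≥ n/3 tips, branch lengths scaled
  by 0.3, the two root-adjacent branches elongated by 5.0, and the trait set
  by the root bipartition — one change on a long basal branch explains the
  data. The balance requirement matters: an extremely lopsided root split
  yields a near-monomorphic trait that cannot carry signal no matter how the
  test behaves.
* **Genomes**: i.i.d. (order 0) or order-2 Markov sequences; avoided motifs
  are removed by locally resampling every window that matches a target motif
  or its reverse complement, sweeping until clean (bounded sweeps, then
  global regeneration, then an error). Local resampling draws from the
  marginal base composition, a deliberate approximation that keeps long
  genomes feasible; avoidance is verified post hoc by counting.
* **Screening tables**: a Bernoulli(susceptibility) truth matrix; true
  positives get spot inhibition and a log10-normal titer (mean 9, sd 1,
  mimicking the 10³–10¹² pfu/mL range of the real screen); true negatives
  get spot inhibition with probability `halocin_rate` and never plaques, so
  the plaque-confirmation rule recovers the truth exactly by construction.

All generators are bit-reproducible under a fixed seed; independent streams
are derived by spawning from a single root seed.

## What the synthetic data do and do not show

The generators emulate the *structure* of the real inputs (tree shapes,
binary traits with known change counts, motif-scrubbed genomes, screens with
a halocin confounder), not their biology: no rate heterogeneity across
lineages, no genome composition beyond order ≤ 2, no correlation between
infectivity and genome features, perfect separability of halocin effects.
Passing tests therefore demonstrate that the algorithms are correct under
their stated models, not that the models capture every property of real
screening or sequence data. The study's gene-tree-specific conclusions
require the public sequences and externally inferred trees and are exercised
only when users supply them.

## Problem sizes and numerical choices

Defaults used by the operating-characteristic checks and the acceptance
script: 32-tip trees, flip rate 0.5, 250 mapping draws per run, 10 null runs;
rate-recovery at 100 vs 400 tips; motif checks on 100 kb genomes (the scale
where tetramer counts make tau's sampling noise small against the 0.78
threshold). These sizes make all study conditions reproducible on a laptop
in minutes while leaving every statistical margin wide.

Numerics: pruning rescales partial likelihoods per node; jump-count pmfs are
truncated where the Poisson tail is negligible (≥ 12 standard deviations);
EOP rounding is decimal, half away from zero, with mantissa-carry (9.6 → 1 ×
10¹); optimizer is bounded scalar minimization on log `mu`. Degenerate
inputs: monomorphic traits give a flagged, decision-free signal-test result;
empty motif panels give empty tables; all-gap alignment columns are skipped.

## Known limitations

* The two-state symmetric model has no asymmetry and no more states; rate ×
  time non-identifiability means rates are only meaningful relative to the
  supplied branch lengths.
* The quadrature rate posterior is a one-dimensional approximation; it
  ignores tree uncertainty unless a tree sample is supplied.
* The HPD-overlap decision is a convention, deliberately conservative; the
  per-run overlap flags and raw jump samples are reported for users who want
  a different rule.
* Motif avoidance simulation preserves the marginal composition only
  approximately around scrubbed sites.
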