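# Methods

`genomesim` simulates genome-wide sequence evolution as a two-layer process:
a genealogical layer (the structured coalescent, per region) and a mutational
layer (continuous-time Markov substitution models whose per-region parameters
are drawn from user priors). A dN/dS estimation layer analyses the resulting
codon alignments. This note documents the models, the conventions every
expectation depends on, the numerical choices, and what the synthetic designs
do and do not probe.

## Genealogies: the structured coalescent

Each region of each replicate draws its own genealogy backward in time.
Within a deme holding `k` active lineages of effective size `N(t)`, every
pair coalesces at rate `1/(2N(t))` per generation. **Time/size convention:**
this is the ms-compatible diploid convention, so the population recombination
rate is `rho = 4 N r (L-1)` and, e.g., `E[TMRCA] = 4N(1 - 1/n)` for a
contemporaneous panmictic sample. All reported expectations depend on this
choice; it is fixed, not configurable.

Demography is piecewise across epochs; within an epoch `N(t) = N_e exp(-g t)`
backward in time, and coalescence waiting times under growth are drawn
exactly by inverting the cumulative hazard (no Euler stepping). Migration is
epoch-piecewise constant with backward rates `m[i][j]` per lineage; at a
population-split event the child demes' lineages move into the parent deme,
which yields the multispecies coalescent. Serial (longitudinal) samples enter
the process at their sampling times. A configuration whose demes cannot reach
a single ancestral deme is rejected up front; one that merely fails to
coalesce within `10^4 x max(2N)` generations raises a guard-horizon error.

With recombination the full Hudson ancestral recombination graph is
simulated: each lineage recombines at a rate equal to the map mass spanned by
its ancestral material (trapped non-ancestral material included, matching ms
semantics, which is also what msprime's full-ARG recorder counts — the
cross-simulator test relies on this). Breakpoints sit on nucleotide
boundaries, drawn proportionally to local map intensity, so a hotspot with
multiplier `m` over a fraction `f` of the region receives a fraction
`mf/(mf + 1 - f)` of breakpoints. Marginal trees are extracted per breakpoint
interval by replaying the event list. Gene conversion, time-continuous
migration functions and selection are out of scope.

## Substitution models

All models are reversible, `Q_ij = s_ij pi_j`, scaled so the expected rate at
stationarity is one: branch lengths are expected substitutions per site,
where "site" is a nucleotide, codon or residue according to the alphabet.
Implemented families: GTR (+I, +G) for nucleotides; GY94 and MG94 for the 61
sense codons of the universal code (stop codons are structurally excluded;
GY94 rates are `pi_target x kappa^[transition] x omega^[nonsynonymous]` for
single-position changes, MG94 replaces the target-codon frequency with the
target-nucleotide frequency at the changing position); arbitrary empirical
exchangeability matrices in the PAML ".dat" lower-triangle layout for any
alphabet, with optional "+F" frequency override. Codon frequencies may be
equal, F1x61, or F3x4 (product of per-position nucleotide frequencies,
stops removed, renormalized).

Among-site heterogeneity: a proportion `p_inv` of invariable sites (rate 0)
and **continuous** gamma rate multipliers, `Gamma(alpha, mean 1)`, drawn per
site — simulation does not discretize the gamma; discrete categories are an
estimation-side approximation and the estimator here (M0) uses none.
"Gamma across regions" is realized by drawing `alpha` per region from its
prior, not by a second within-genome gamma layer. CAT-style profile sets
(per-site equilibrium frequencies) are supported by evolving each profile
class under its own-frequency model.

`P(t) = exp(Qt)` is computed by symmetric eigendecomposition
(`S = D^{1/2} Q D^{-1/2}`, exact for reversible Q with positive frequencies;
scipy's `expm` is the fallback for degenerate frequency vectors). Round-off
below `-1e-12` raises; smaller negatives are clamped to zero.

## Priors and randomness

Per-region parameters (kappa, omega, exchangeabilities, frequencies, gamma
shape, p_inv) are drawn independently per (replicate, region) from fixed,
uniform, exponential (parameterized by its mean), gamma, beta or Dirichlet
priors. Truncation of scalar priors is by rejection with a 10^6-draw cap, so
a truncation region of essentially zero mass fails loudly instead of
spinning. Dirichlet draws use the gamma-normalization construction;
exchangeability vectors are rescaled so the last rate equals one. Every
random stream is keyed structurally as (root seed, replicate, region,
purpose), so adding regions or replicates never perturbs other draws and
output is independent of execution order.

## Sequence evolution

Root sequences are drawn at stationarity; each site then evolves
independently down the tree with `P(Q, b x mu x rate_site)`, vectorized over
sites through the spectral form (this also makes continuous per-site rates
free). In coalescent mode branch lengths are generations and `mu`
(substitutions per nucleotide site per generation) converts them; codon
models use `3 mu` per codon. In user-tree (phylogenetic) mode branch lengths
are taken directly as expected substitutions and `mu` is ignored. A Gillespie
jump-chain simulator of the same process exists solely as a test oracle for
`exp(Qt)` and for the one-event-per-unit-branch-length normalization
contract. Per-branch dN/dS multipliers rebuild the GY94 matrix per distinct
multiplier. With recombination, each marginal interval evolves on its own
tree from an independent stationary root (ancestral material beyond the
grand MRCA is unlinked — the standard coalescent-simulator convention);
for codon models breakpoints are rounded down to codon starts (a strict mode
errors instead), because faithful intracodon-breakpoint evolution requires a
specialized per-nucleotide conditional algorithm that is out of scope.

## dN/dS estimation

*Counting*: Nei–Gojobori (1986). Per-codon synonymous site counts use the
fraction of synonymous changes among **non-stop** mutational neighbors (so
`S(AAA) = 1/3`); multi-hit codons average over stop-free mutational pathways
(falling back to all pathways, stop steps counted nonsynonymous, when every
pathway is blocked); proportions are Jukes–Cantor corrected. `dS = 0` or a
saturated proportion yields an explicitly flagged undefined ratio, never an
infinity.

*Maximum likelihood*: GY94 x M0 with empirical F3x4 frequencies (floored at
1e-4 per nucleotide so short regions missing a base keep a valid positive
stationary distribution). The likelihood is Felsenstein pruning over
compressed site patterns with per-node rescaling. Without a user topology a
neighbor-joining tree is built from Jukes–Cantor nucleotide distances
(saturated distances clamped). Optimization alternates (i) per-branch Brent
line searches on a spectral reparameterization of the single-branch
likelihood (coefficients `c_k = (B^T G)_k (B^{-1} L)_k`, so each trial branch
length costs one 61-vector exponential), applied as a Jacobi pass with a
monotone sequential fallback, with (ii) bounded Brent searches on log kappa
and log omega; two omega starts (0.5, 2.0) guard against local optima, the
second start re-polishing from the first's branch lengths. A round improving
the log-likelihood by less than 0.2 units terminates the fit; exhausting the
round budget flags the fit instead of raising, and flagged fits are excluded
(and counted) in experiment summaries. Bounds: omega in [1e-4, 50], kappa in
[0.05, 100], branch lengths in [1e-7, 20] substitutions/codon.

## The heterogeneous-genome experiment

The bundled designs hold dN/dS constant across a genome of 15 codon regions
x 150 codons (n = 15 samples, N = 1000, contemporaneous, no recombination)
while per-region nuisance parameters vary: `kappa ~ U(0.5, 15)` always, and
per scenario either equal codon frequencies everywhere
("equal-frequencies") or per-region F3x4 frequencies built from per-position
Dirichlet(1,1,1,1) draws ("variable-frequencies"); optional designs add
gamma site rates (shape 0.7) or per-region shapes from Exp(mean 2) truncated
to [0.5, 5]. Each replicate is estimated twice: one genome-wide M0 fit on
the concatenation (one misspecified homogeneous model) and one M0 fit per
region with that region's own empirical F3x4. Summaries report means,
standard errors and normal-approximation 95% CIs (mean +- 1.96 SE; SE is
reported as absent, not zero, for a single replicate).

**mu**: the per-generation substitution rate is not part of the published
design; the default `mu = 2.5e-5` per nucleotide site per generation is
chosen so mean pairwise divergence is `4 N mu ~ 0.1` substitutions per
nucleotide site (~0.3 per codon), an RNA-virus-like level. It is printed
with every summary. Sensitivity runs at 4x and 8x this rate left the
genome-wide estimator's mean essentially unchanged, so conclusions below are
not divergence-limited.

**What these synthetic designs show — and what they do not.** The generator
produces exactly the stated heterogeneity and nothing else: no indels (all
alignments are gap-free by construction), no selection in the genealogy, no
codon usage beyond what F3x4 can express, and regions that are independent
given the design. Passing tests therefore demonstrate internal consistency
of simulator and estimator under this model family, not robustness on real
genomes. At desk scale (10 replicates) the pipeline reproduces the
qualitative structure of the misspecification study: with variable codon
frequencies the genome-wide estimator underestimates at omega = 2 (mean
~1.6) while the region-averaged estimator stays unbiased (~2.0) and the
equal-frequency control is accurate (~1.0). The *magnitude* of the pooling
bias is substantially milder here than the originally reported values
(1.25/0.71/0.43 at omega = 2/1/0.5), and at omega <= 1 the genome-wide
estimator is essentially unbiased in this implementation. Extensive
diagnostics (divergence scaling, per-region rate normalization conventions,
nonstationary root/frequency variants) did not close that gap; the original
magnitudes evidently depend on estimation or simulation details that their
description does not pin down. The acceptance script reports what this
implementation computes.

## Problem sizes

Default analysis sizes were chosen so the full experiment suite runs on a
single CPU in minutes: 10 replicates per scenario, 10^4 genealogies for
coalescent expectations, 10^5 draws for distributional prior checks, and
20-codon alignments for exact likelihood oracles. All are parameters, not
constants, and scale up linearly.

## Known limitations

- Only the universal genetic code; no alternative translation tables.
- M0 is the only ML model; site-class generative models beyond explicit
  discrete classes (M5-M13 style omega distributions) and their estimation
  are not implemented.
- NJ (not BioNJ) starting topologies; topology is not re-optimized during
  the M0 fit.
- The ARG replay builds marginal trees in O(intervals x events), adequate
  for per-region rho but not for chromosome-scale maps.
- Migration rates are epoch-piecewise constant; continuous-time rate
  functions are unsupported.
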