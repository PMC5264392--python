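# Methods

This note records the models, conventions and numerical choices behind
`lbalens`, in the spirit of a package methods appendix. It states no
empirical numbers beyond what the test suite and `scripts/acceptance.py`
themselves compute.

## Scope and stance

The package implements a *battery* of LBA diagnostics and mitigations at
desk scale. Large heuristic ML searches and Bayesian mixture models are
deliberately out of scope: tree inference is neighbor joining, Fitch
parsimony with NNI hill climbing, and exhaustive maximum likelihood over
all unrooted topologies (≤ 9 taxa). These are not approximations of a
particular external program; they are the smallest methods that exhibit
the phenomena of interest (parsimony/distance inconsistency in the
Felsenstein zone, its repair by model-based methods and data filtering).

## Alignment conventions

Columns are 0-based half-open internally; partition files use the
ecosystem's 1-based inclusive RAxML dialect. Reading uppercases, maps
`U→T`, and maps unknown characters to `N` (logged); IUPAC ambiguity
codes are preserved by I/O and treated per analysis — for site
classification, OV, TIGER, p-distances and Iss they are excluded from
state counts, never counted as mismatches. Translation uses NCBI table
11 (plastid) by default; a codon containing a gap translates to a gap so
amino-acid gap structure mirrors nucleotide indels; codons containing
ambiguity translate to `X`; internal stops are kept as `*` with a
warning. Genes whose aligned length is not divisible by three raise a
frame error — silently trimming would corrupt downstream codon logic.

## Site classification and rates

A column is parsimony-informative iff at least two distinct unambiguous
states each occur in at least two taxa; constant iff at most one
unambiguous state occurs (wholly missing columns are constant by
convention). OV is the mismatch fraction over taxon pairs with two
unambiguous characters; columns with fewer than two such characters
score 0 and are flagged. TIGER is computed exactly (O(L²·taxa)); the
binned approximation used by some implementations is not provided.
Rankings are stable sorts with ties broken by original column index, so
results are reproducible to the byte.

The rate-tertile partitioner sorts informative sites slowest-first,
splits them into three equal groups (remainder to slow, then medium),
and pads every group with *all* variable parsimony-uninformative
columns. Constant columns are excluded by default — this matches the
partition-width accounting used in practice, where each partition's
width equals its informative tertile plus the shared variable
uninformative sites — but `include_constant=True` adds them for users
who want constant sites present for model estimation.

## Substitution models and distances

One `SubstitutionModel` (GTR parameterisation, `Q[i,j] = s_ij π_j`,
normalised to one expected substitution per unit branch length; JC69 and
K80 as special cases) serves the simulator, the pruning likelihood and
the ML distances. Among-site rate variation is a mean-one Gamma
discretised into four equal-probability categories by category means.

Pairwise distances: JC69 and K80 use their closed forms; GTR uses the
reversible closed-form ML estimator
`d = −Σ_i π_i [log(Π⁻¹ F_sym)]_ii` on the symmetrised divergence matrix,
which is consistent at any depth; GTR+Γ fixes the rate matrix (estimated
from the pooled divergence matrix's matrix logarithm) and the Gamma
shape (profile-optimised composite likelihood) and optimises each pair's
distance numerically. Pairs beyond the model ceiling (non-positive
eigenvalues of the divergence matrix) are capped at `d_max = 5`
substitutions/site and flagged implicitly by hitting the cap. Model
choice among {JC69, K80, GTR, GTR+Γ} is by BIC on the summed pairwise
log-likelihoods; a full per-partition model-selection pipeline is out of
scope.

## Saturation diagnostics

**Iss.** Per-site entropy is averaged over columns; the
full-saturation reference `H_FSS` is the *exact expected entropy of
n_taxa independent draws* from the alignment-wide base frequencies
(enumeration of count compositions; the asymptotic `−Σ q log₂ q` is used
above 200 taxa where the bias is negligible). Using the finite-sample
expectation rather than the asymptotic entropy is essential: the plug-in
entropy of a finite column is biased low, and with the asymptotic
reference fully randomised data would plateau visibly below 1.
`Iss.c` is estimated by Monte Carlo: quartets are simulated across a
geometric grid of depths on a symmetric and on an asymmetric
(Felsenstein-zone-shaped) four-taxon tree with the gene's base
composition and length; the critical value is the mean Iss interpolated
at the depth where distance-based quartet recovery crosses 95%. The
observed Iss (averaged over random 4-taxon subsamples when the gene has
more taxa) is compared by a one-sided z-test using a site-bootstrap
standard error; a gene is flagged saturated when Iss is significantly
*above* Iss.c for the symmetric quartet at α = 0.05. The test and level
are this package's operationalisation — sources that popularised the
index leave both unstated.

**Regression.** p-distance is regressed (OLS) on patristic distance —
saturation compresses p while tree-path lengths keep growing, so
saturated genes have small slopes and R². Flagging uses a Gaussian KDE
(Silverman bandwidth) of the per-gene values: genes below the deepest
density antimode left of the global mode are flagged; with no antimode
the method falls back to a percentile cut (default 15%). Trees for
per-gene patristic distances are NJ on GTR distances.

## Block filtering

The conserved-block filter re-implements the published Gblocks 0.91b
semantics from its documented rules; bit-compatibility with the binary
is *not* promised. A column's identity count is the count of its most
frequent unambiguous residue (ambiguity codes match nothing). The three
presets carry the relaxed/default/strict parameter triples defined for a
22-taxon matrix (b1/b2 = 11/11, 11/17, 21/21; b3 = 10/8/5; b4 = 5/10/50;
gaps with-half/none/none); for other taxon counts b1 becomes
⌊taxa/2⌋+1 (relaxed/default) or ⌈taxa·21/22⌉ (strict) and b2 rescales
proportionally, never below b1. Validation is inclusive (b1 ≥ taxa/2)
so the published relaxed preset — exactly half the taxa — is
representable. Where the original's behaviour is undocumented the
choices here are: gap rejection takes precedence over identity classes;
step order is stretch-rejection, flank-trimming, gap rejection with
adjacent-nonconserved removal plus one re-trim pass, then the minimum
block length.

## OV-sorted removal and the stopping rule

The matrix is sorted fastest-first by OV; at each multiple of the
increment (default 250) partition B holds the removed fastest columns
and partition A the remainder, and two Pearson correlations over taxon
pairs are recorded: ML(A) vs ML(B), and ML(B) vs p(B). The published
criterion — stop at the end of the sharp increase in both correlations —
is qualitative; it is operationalised as: a step is a sharp increase if
its Δr exceeds `jump_factor` (default 3) × the median |Δr| of all prior
steps, *in both series*; the stopping point is the k ending the longest
run of consecutive sharp steps (first such run on ties). A trace with no
sharp increase returns an explicit no-stopping-point sentinel rather
than an error. One distance model, fit on the full matrix, is reused at
every step; refitting per step is available at cost.

## Trees and support

NJ clamps negative branch estimates to zero, moving the deficit to the
pair's other branch so the joined pair's path length is preserved.
The pruning likelihood uses plain double precision without rescaling —
adequate at the package's taxon counts and depths. Branch-length
optimisation is cyclic Brent per edge to a relative tolerance of 1e-6.
Exhaustive ML enumerates topologies by stepwise addition (each topology
exactly once); ties are first-found with the tie set reported.

Rival-trichotomy support resamples columns with replacement, infers each
replicate by NJ, parsimony or exhaustive ML, and classifies the tree
against the three resolutions of the focal trichotomy; any replicate in
which a focal clade is not monophyletic counts as "other". Stem-branch
reports root the tree on the outgroup MRCA edge (splitting that edge's
length evenly) and measure each clade's subtending edge; ratios are
relative to a named reference clade.

## Quartet species trees

The objective is the integer quartet score (gene trees as topologies
only; missing taxa skip their quartets; unresolved gene quartets score
zero). The exact optimiser enumerates all unrooted topologies (≤ 9
taxa); above that an NNI hill climb starts from NJ on mean gene-tree
internode (edge-count) distances; the seed only breaks ties among
equally scoring neighbours, so runs are deterministic. The constrained
dynamic programming of production coalescent tools is intentionally not
reproduced — the objective, not the search, is the scientific content.

## Synthetic data

The simulator draws root states from the stationary distribution,
assigns each site a Gamma category once, and evolves states with
`exp(Qt·r)` per branch. "Codon structure" is positional rate scaling —
third positions evolve 5× faster by default, normalised to mean one per
codon — not a codon model; it is sufficient to make codon-position
filtering and translation meaningful, but it generates no indels, no
compositional heterogeneity across lineages, and no selection, so
passing tests demonstrate behaviour under rate heterogeneity only.
Optional heterotachy rescales every branch per gene by a log-normal
multiplier.

The three-crown scenario (`jcx_scenario`) places an outgroup and three
three-taxon crowns: two with long stems on non-sister lineages and one
short-stemmed, separated by short internals. Defaults (stems
0.45 / 0.35 / 0.06 substitutions/site, internals 0.008, crowns 0.03,
outgroup 0.3, GTR with Γ shape 0.4, 20 genes × 300 nt) were chosen once
so that the squared terminal-change probability exceeds the
internal-change probability — the parsimony inconsistency condition —
with the homoplasy concentrated on fast sites; this is the regime in
which filtering has something real to remove. The multispecies
coalescent sampler works directly in coalescent units on the species
tree (one lineage per species), validated against the
`(2/3)e^{-t}` discordance law.

Fixture alignments are built column-class by column-class (constant;
singleton-variant; two-state splits with varying minor-allele counts so
informative sites have a genuine OV spread) and shuffled by seed; the
class counts are exact by construction and verified against the
classifier property-based.

## Problem sizes

Tests run at reduced sizes chosen for statistical clarity per check:
brute-force oracles at 4–7 taxa; consistency sweeps at 6 taxa × 1,000
matrices; the coalescent closed form at 10,000 genes; the directional
LBA contrast at 50 seeds of the default scenario; bookkeeping checks at
the full 22 × 81,423 fixture scale.

## Known limitations

* ML distances and the GTR+Γ fit use composite pairwise likelihood, not
  joint tree likelihood; at extreme divergence the cap at `d_max`
  truncates information.
* Amino-acid matrices are supported for classification, OV/TIGER,
  p-distances, block filtering and parsimony-free NJ, but not for ML
  distances or Iss.
* The Iss.c construction assumes the quartet-recovery breakpoint is a
  reasonable signal-loss proxy at the gene's own length and base
  composition; it does not reproduce any external program's lookup
  tables.
* `gblocks_filter` is faithful to the documented five-step semantics but
  is not guaranteed column-for-column identical to the original binary
  on pathological inputs.
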