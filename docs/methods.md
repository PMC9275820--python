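# Methods

This note documents the models, algorithms, numerical choices, and
limitations behind `paleotrx`. It states no empirical result beyond what
the test suite and `scripts/acceptance.py` compute.

## Binary encoding

Expression is discretized per gene and species: TPM ≥ 2.0 → expressed
(1), TPM < 2.0 → silent (0), no measurement → missing (`?`). The
comparison uses the exact stored value with no rounding, and a measured
0.0 is state 0, not missing — absence of annotation and absence of
expression are different observations. The 2.0 TPM default is the
conventional detection threshold for bulk RNA-seq abundance estimates and
is a parameter everywhere it appears.

Column filtering (before clustering and embedding only) removes genes
with any missing state and genes invariant across rows; phylogenetic
likelihood keeps `?` columns, since pruning handles them exactly (a
missing tip contributes the partial vector (1,1), so an all-missing site
has likelihood 1). Whether to filter before likelihood work is
configurable; the default retains everything, because missing data is
information about sampling, not evolution.

## Substitution model

Characters evolve on a tree under the two-state reversible model. After
normalizing to one expected substitution per unit branch length, the
model is fully determined by the stationary frequencies π = (π₀, π₁):

    Q = μ [[-π₁, π₁], [π₀, -π₀]],   μ = 1 / (2 π₀ π₁)
    P_ij(t) = π_j + (δ_ij − π_j) e^(−μ r t)

Among-site rate variation is a FreeRate mixture: k categories with free
rates r_c and weights w_c under Σw_c = 1 and Σw_c r_c = 1 (so branch
lengths keep their substitutions-per-site meaning). Model specs are
strings — `EQ`, `GTR2+FO`, `GTR2+FO+R3`, … — where `FO` frees the
frequencies and `Rk` sets the category count.

Fitting is by maximum likelihood with unconstrained parameterization:
logit(π₁), log rate ratios, and weight logits, with the mean-rate
constraint enforced by rescaling after each proposal and a 1e−9 floor on
frequencies and weights. Categories are sorted by rate after fitting for
identifiability. Model selection fits each candidate (branch lengths
re-optimized per candidate, alternating with parameter updates until the
per-round log-likelihood gain is below 0.05) and ranks by AICc,

    AICc = −2 lnL + 2k + 2k(k+1)/(n − k − 1),

counting branch lengths among the k parameters. No ascertainment-bias
correction for unobservable invariant patterns is applied.

## Likelihood engine

Felsenstein pruning over compressed site patterns (unique columns with
multiplicities; compression is computed once per matrix and reused across
trees by row permutation). All rate categories propagate together through
batched 2×2 matrix products. Per-node rescaling guards against underflow
only for trees over 40 tips; below that, double precision cannot
underflow for two-state partials. Likelihood is invariant to root
placement under the reversible model (tested), so an arbitrary internal
node serves as virtual root.

An inside/outside ("up/down") pass makes the likelihood profile of any
single branch a closed form in its length. Branch-length optimization
exploits this: one exact coordinate-ascent sweep visits edges root-outward,
propagating outside partials incrementally (sibling messages are
refreshed against already-updated lengths), so every one-dimensional
Brent search (bounded to [1e−8, 10], xatol 1e−9) sees the true
conditional profile and the total log-likelihood never decreases. Sweeps
repeat until the gain over a full sweep is below tolerance (default
1e−6).

## Tree search and supports

The maximum-likelihood topology is found by steepest-ascent NNI hill
climbing. Starting trees are a neighbor-joining tree built from pairwise
CFN distances, d = −½ ln(1 − 2p̂) with p̂ the mismatch proportion over
unambiguous sites (capped near saturation), plus random-addition-order
topologies; the NJ implementation breaks ties lexicographically so the
search is deterministic given the seed. Candidate neighbors are screened
by re-optimizing only the branches around the interchange; the best
improving move is applied and the tree re-optimized, until no move
improves the log-likelihood by more than the tolerance. The returned tree
is an NNI local optimum with respect to this screening; no SPR/TBR moves
are attempted.

Branch supports:

* **Standard bootstrap** — genes resampled with replacement (as
  multinomial pattern weights); each replicate re-runs the NNI search
  warm-started from the ML tree; support is the proportion of replicate
  trees containing the bipartition.
* **aLRT family** — per internal branch, the three NNI configurations
  around it are length-optimized; with ordered log-likelihoods
  l₁ ≥ l₂ ≥ l₃: the parametric aLRT tests 2(l₁−l₂) against the
  ½χ²₀ + ½χ²₁ mixture; aBayes is the log-space softmax of (l₁, l₂, l₃);
  SH-aLRT and the local bootstrap come from paired RELL resamples of the
  three per-site log-likelihood vectors (centered for SH-aLRT).

## Topology tests

Candidate trees are compared at fixed ML parameters via RELL: replicate b
draws multinomial site counts and totals Σ n_b(site)·logL_T(site), with
the same counts for every tree. From one replicate table: BP-RELL
(fraction of replicates each tree is best; exact ties split fractionally),
one-sided KH with Shimodaira–Hasegawa centering, SH (max over the
candidate set of centered differences), WKH/WSH (studentized by replicate
standard deviations), and c-ELW (mean normalized likelihood weight). The
AU test uses multiscale bootstrap: bootstrap proportions bp(r) at scales
0.5…1.4 (step 0.1), z(r) = Φ⁻¹(1 − bp(r)) fitted by weighted least
squares (binomial variance on the probit scale) to d√r + c/√r, and
p_AU = 1 − Φ(d − c); proportions are clamped to (1/(2B), 1 − 1/(2B)) and
trees with fewer than two informative scales get the degenerate p (0 or
1) their dominant proportion implies. A tree is inside the 95% confidence
set of a test when its p ≥ 0.05. No multiplicity correction is applied
across trees within one test.

Calibration note: a one-sided KH p-value is uniform only at the least
favorable null (neither tree better in expectation); the test suite
checks uniformity with gene columns drawn equally from both candidate
topologies, and checks the exclusion rate of the true tree (≤ α up to
Monte-Carlo error) with data generated on it.

## Ancestral reconstruction

Reconstruction is marginal and empirical-Bayes: branch lengths and model
parameters are fitted by ML on the fixed (constraint) topology, then per
gene and internal node the posterior P(state | data, MLEs) comes from the
inside/outside partials, mixed over rate categories with their posterior
weights. Tips with data report their observed state; missing tips report
the posterior implied by the rest of the tree, flagged as imputed. MAP
states discretize at 0.5, with the tie resolving to "expressed"
(deterministic, conservative toward presence). Joint matrices for
clustering stack extant observed rows over ancestral MAP rows (posteriors
are available but MAP keeps the alphabet uniform).

An independent expression loss of a gene is a branch whose parent MAP
state is 1 and whose child MAP (or observed) state is 0; tips with `?`
are excluded. Counting losses on MAP states stands in for parsimony or
stochastic mapping, which are not implemented.

## Clustering and embedding

**Logistic PCA** projects in Bernoulli natural-parameter space: the
saturated parameters are approximated by m·(2X − 1), and the rank-k
projection U is fitted by majorization (each step an eigenproblem), which
makes the deviance non-increasing. The scale m is chosen by row-wise
cross-validated deviance over a small grid (2–10) unless given. Scores
are the projections of the centered saturated parameters. This m is
unrelated to the FCM fuzzifier.

**Fuzzy C-means** uses the Bezdek updates with exponent 2/(m−1) and
Manhattan distance by default. Centroids are per-coordinate weighted
medians (the L1 minimizer), so the objective J = Σ u^m d is provably
non-increasing; Euclidean distance uses weighted means. A sample at zero
distance from a centroid takes full membership there; a centroid losing
all mass is re-seeded from a random row. Default 20 restarts from
perturbed random rows, best objective kept. The fuzzifier default is the
data-size estimate m = 1 + (1418/N + 22.05)·D⁻² +
(12.33/N + 0.243)·D^(−0.0406 ln N − 0.1134), which approaches 1 (near-hard
clustering) for transcriptome-scale D. K is surveyed over 2–9 with the
elbow statistic (largest second difference of the objective) and
re-assignment counts between consecutive K; interpretation beyond K ≈ 6
is left to the user.

## Deconvolution

A gene enters the signature matrix when its top cell type expresses it at
or above the expression threshold (default 2, TPM-like) and at least
fivefold higher than **each** other cell type (exactly fivefold passes; a
zero second-best passes whenever the top passes the threshold). Every
cell type must retain at least one marker. Bulk samples are regressed on
the marker rows by non-negative least squares (deterministic; a linear
ν-SVR variant with ν ∈ {0.25, 0.5, 0.75} by lowest residual is available),
negative weights clipped, fractions renormalized to the simplex, and the
relative residual reported. A cell type is called absent below τ = 0.005.
Markers missing from a bulk table are dropped; at least half must be
present. The permutation p-value machinery of the original deconvolution
tool is not implemented.

## Synthetic data: what it emulates, and what not

The generator produces the statistical structure the analysis assumes: a
23-taxon amniote tree (stored topology; sauropsid outgroups including a
reproductively bimodal skink, a monotreme sister to the therians, three
marsupials, 13 eutherians), placenta-type regimes with a configurable
number of independent origins of the focal epitheliochorial regime,
binary characters evolving under the two-state FreeRate model, TPM
observations drawn from truncated lognormals (expressed: location
log 16; silent: location log 0.2; both scale 1) that invert the encoding
exactly, and bulk mixtures of synthetic cell-type signatures.

Convergence is a regime-dependent equilibrium frequency: a convergent
gene uses π₁ + `regime_effect` (clamped) on branches inside the focal
regime. A single knob thus produces both tree distortion (regime members
attract each other) and regime-wise clustering.

Preset study conditions:

* `null` — no convergence; 23 taxa, 2,000 genes (desk-scale surrogate
  for a ~21,750-gene atlas), π₁ = 0.5, FreeRate R3 (rates renormalized to
  mean 1), 2% missing entries.
* `convergence` — π₁ = 0.35, half the genes convergent with effect 0.62
  (shifted equilibrium ≈ 0.97, whose large μ makes convergence fast on
  regime branches), tree depth 0.08 with the four origin branches
  stretched 3× (long independent regime lineages), fixed regime placement
  on the marsupials, two non-invasive ungulate lineages, and the
  viviparous skink. These conditions are chosen so that the convergent
  signal genuinely dominates — regime members cluster together across
  clades — which is the phenomenon the pipeline is built to detect; at
  weaker settings clustering stays phylogeny-dominated.
* `rora-loss` — background genes (π₁ = 0.35) plus one focal gene silent
  exactly in the focal regime; with stretched origin branches and
  moderately rare expression, the four planted losses are the clear
  maximum-likelihood explanation (under a symmetric model with uniform
  branch lengths, "two adjacent losses" and "one loss plus one regain"
  are nearly equiprobable and the count is not identifiable).
* `deconv` — a four-cell-type signature with clean fivefold markers and
  Dirichlet mixtures under 10% multiplicative lognormal noise.

Not emulated: read-level noise and quantification error, ortholog
mis-mapping, branch-heterogeneous processes (heterotachy), correlated
evolution among genes, and composition effects in bulk mixtures beyond
lognormal noise. Passing tests on these conditions show the machinery is
correct and well calibrated under its own model; they do not show the
model is adequate for any particular real dataset.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen as the package's own
validation conditions: 300–5,000 genes, 6–23 taxa, 10,000 RELL replicates
(100,000 available via flag), 1,000 AU replicates per scale, 20–100
simulation replicates per experiment. Key tolerances: pruning vs
enumeration 1e−8; transition kernel vs matrix exponential 1e−10;
two-taxon branch length vs closed form 1e−6; branch-sweep convergence
1e−6; FCM convergence 1e−8 on the objective. Degenerate inputs are
defined, not special-cased: all-missing sites have likelihood 1,
zero-variance replicate differences give p = 1, posterior ties go to
"expressed", invariant or missing columns are rejected by the embedding
and clustering entry points with explicit errors.

## Known limitations

* NNI-only search can miss optima that require SPR moves; multiple
  starts mitigate but do not eliminate this.
* The aLRT-family supports and the topology tests share branch lengths
  optimized on the analyzed data; very short alignments therefore
  slightly over-disperse test statistics (the calibration experiment
  sizes alignments so site variance dominates).
* Reconstruction near regime origins is genuinely ambiguous: ancestors
  sandwiched between adjacent origins take intermediate posteriors and
  can cluster with the convergent regime.
* AICc counts every branch length as a free parameter, the conventional
  but approximate choice.
* The fuzzifier estimate is a regression formula, not an optimum for any
  particular dataset.
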