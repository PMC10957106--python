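# Methods

This note documents the models, numerical choices and synthetic worlds
behind `phyloturn`, in the spirit of a package methods appendix. It states
no empirical result that the test suite or the analysis scripts do not
themselves compute.

## Trees and chronology

A `TimeTree` is a rooted tree with branch lengths in Ma; ages are
recomputed from branch lengths (tips at 0, root at the maximum root-to-tip
depth) and ultrametricity is enforced to 1e-6 Ma throughout. Newick parsing
is delegated to dendropy (underscores preserved); writing is a deterministic
serializer so that fixed seeds give byte-identical files.

**Grafting.** A subtree replacing a set of backbone tips is uniformly
rescaled so that its crown age equals the attachment age — the MRCA age of
the replaced tips, or half the terminal branch when a single tip stands in
for the clade. Uniform rescaling is the simplest order-preserving choice
and matches meta-tree practice. When the replaced tips are paraphyletic the
subtree attaches at their MRCA with a zero-length stem and the stragglers
are pruned (deterministic and conservative). Internal-node auto-names are
re-uniqued after surgery; name collisions between donor and host trees were
the one genuinely subtle bug class here.

**Time slicing.** Every branch alive at the cutoff becomes one lineage tip
(named after its alphabetically first descendant, so the mapping is
deterministic); the sliced tree is re-measured with those tips at age 0.
Composition holds: slicing at T2 equals slicing the T1-sliced tree at
T2 − T1.

## Turnover

Simpson turnover (beta-sim) is `min(b, c) / (a + min(b, c))`. In the
phylogenetic case, branches are classified against the two cells' tip sets
*strictly below the MRCA of their union* (the branch subtending that MRCA is
excluded), which makes the statistic a function of the pair's spanning
subtree only and reduces it exactly to the taxonomic index on star trees.
One degenerate case is defined explicitly: two cells containing the same
single species share just that terminal branch (a > 0, b = c = 0, turnover
0) rather than being undefined. Pairs with `a = 0` and `min(b, c) = 0` are
NaN and excluded downstream. The reversed deviation index −(TBD − PBD)/TBD
is computed from the Simpson values and is NaN when TBD = 0. Great-circle
distances use the haversine on a 6371.0-km sphere.

## Generalized dissimilarity model

The linear predictor is `η = β₀ + Σ_p Σ_k a_pk |I_pk(x_pi) − I_pk(x_pj)|`
with `d̂ = 1 − exp(−η)`. The I-splines are normalized antiderivatives of
degree-1 B-splines on the open knot vector built from the observed minimum,
median and maximum — three monotone quadratic basis functions per predictor
rising from 0 at the minimum to 1 at the maximum, so coefficient sums are
comparable across predictors. Pre-paired distances (geographic, biome)
enter their own basis directly.

Fitting minimizes the binomial-type deviance by IRLS with a non-negative
least-squares inner solve (all coefficients and the intercept ≥ 0), with
step-halving if a step increases the deviance. Convergence is declared at a
relative deviance change < 1e-8 *or* an absolute change < 1e-8 × null
deviance — the latter because a noiseless fit drives the deviance itself to
~1e-16, where relative changes are meaningless. The null model is the
intercept-only fit (mean dissimilarity through the link).

Variation partitioning stores the raw components `D(A+B) − D(B)`,
`D(A+B) − D(A)` and `D(A) + D(B) − D(A+B)` so the additive identity holds
exactly; negatives arising from numerical noise are clamped to zero only
for reporting and for the rescaled-to-one display. Geographic residuals are
plain OLS residuals of turnover on distance; a min–max copy rescaled into
[0.001, 0.999] is provided as a GDM response (the link needs an open unit
interval); numerically constant residuals map to a constant column so that
downstream fits degrade to the null, as they should.

## Phyloregionalization

Clustering uses scipy's Lance–Williams implementations: UPGMA, and Ward
applied to squared input dissimilarities (the "ward.D2" contract; verified
against a step-by-step hand recursion on a 6-point matrix). The "ward.D"
variant — the recursion on raw dissimilarities — is obtained by feeding
sqrt-transformed distances and squaring the merge heights back, which is
algebraically identical. Undefined pairs are imputed with the matrix
maximum (with a logged count): this keeps cells rather than dropping them
and biases toward separation, which is the conservative direction for
regionalization. Candidate algorithms are compared by the Pearson
correlation between cophenetic and input distances; on outlier-laden data
UPGMA chains (one giant region plus singletons), which is the documented
reason Ward is the default despite often scoring a lower cophenetic r.

Climatic distinctness: Wilcoxon rank-sum for two clusters, Kruskal–Wallis
then Dunn's z-tests with mid-ranks, tie correction and Bonferroni
adjustment for more; a cluster counts as "climatically distinct" when it
differs significantly from every other cluster.

## Niche evolution

Ancestral states under Brownian motion are computed by two-pass linear
belief propagation; each internal node's estimate equals the ML root state
of the tree re-rooted there, and the whole map equals the dense-GLS BLUP
`μ̂ + c_nᵀC⁻¹(x − μ̂1)` to 1e-8 (tested). Reported variances are
conditional variances scaled by the ML rate `σ̂² = Q/n`. Zero-length
branches are perturbed by 1e-8 with a warning. An optional outgroup is kept
during optimization and dropped from the report, mirroring the practice of
optimizing over a larger tree to stabilize deep nodes.

Pagel's λ multiplies the off-diagonal covariances; the GLS mean and rate
are profiled out analytically and λ is maximized on [0, 1] by bounded Brent
(endpoints checked explicitly). λ up to 1 keeps C positive-definite on
ultrametric trees; the significance test is a one-degree likelihood-ratio
test against λ = 0.

Niche categories: MAP dry < 1200 < intermediate < 1800 < wet (mm/yr); DSL
is inverted (wet < 4 < intermediate < 8 < dry months) and, though integer,
is reconstructed with the same continuous machinery. A shift requires
*both* a category change between the branch's endpoint values *and* an
absolute change ≥ the minimum (250 mm or 1 month); terminal branches are
eligible with the observed tip value as child state; the shift age is the
midpoint of the parent and child node ages. Per-5-Ma-bin fractions divide
shift counts by internal-node (split) counts; a branch-midpoint denominator
is available behind a flag.

## Biogeography

**Mk/ARD.** Pruning likelihood with per-branch matrix exponentials, free
off-diagonal rates optimized in log space (L-BFGS-B), root weighted by the
stationary frequencies of the fitted generator. Stochastic maps draw node
states root-down from conditional distributions, then branch histories by
forward rejection sampling conditioned on endpoints, falling back to exact
uniformization after 200 rejections. Transition branches are those whose
endpoint states conflict in ≥ half of the maps, with the majority
direction reported.

**DEC/DEC+J.** Range states are the non-empty subsets of up to 8 areas
(configurable maximum range size; the state space tops out at 255).
Dispersal adds one area at rate d per source area; extinction removes one
area at rate e *only where a valid range remains* — single-area ranges
cannot lose their last area. This deliberately omits the canonical
absorbing null range: with the null-range leak, the likelihood penalizes
single-area occupancy without any observable event, which drives ê to the
boundary on survivor-only data (the well-known e ≈ 0 pathology); on the
non-empty state space, e is identified by observed range contractions and
the forward simulator needs no survival conditioning. Cladogenesis follows
the standard weighting: sympatry for single-area parents; subset sympatry
and single-area vicariance for wider ones; founder-event jumps to areas
outside the parent range with weight j ∈ [0, 3] while the three standard
event types carry (3 − j)/3 each; outcomes are normalized per parent range
(with an equal-weight fallback in the j = 3, no-jump-possible corner). The
root prior is uniform over allowed ranges. Likelihood maximization
multi-starts (the e-profile is often nearly flat), and the DEC+J fit is
additionally seeded from the DEC optimum so the nested model can never win.

Node range probabilities come from a full up–down pass through both the
anagenetic and cladogenetic parts of the model (verified against joint
enumeration on small fixtures); model averaging weights each model by
`exp(−ΔAIC/2)`, normalized. The decided ancestral range adds areas in
decreasing per-area marginal probability (ties broken by the fixed area
order) until their combined probability exceeds 50%; a
most-probable-composite rule is available behind a flag. A dispersal event
is a branch whose child's decided range includes a region group absent from
its parent's, dated at the branch midpoint, under either the seven-region
grouping (the Americas merged) or the stricter three-region grouping
(Americas / Old World / Oceania).

## Synthetic worlds and what a green test establishes

Generators draw from per-stage RNG streams seeded from `config.seed` plus
fixed offsets, so any stage reproduces bit-identically in isolation.

* **Trees**: forward birth–death (defaults 0.3 / 0.1 per lineage per Ma)
  grown until the extant count first reaches `n_tips`, extinct lineages
  pruned, tips extended by a draw of the next-event waiting time. The
  gamma-statistic distribution matches an independent simulator (dendropy).
* **Traits**: BM on the λ-transformed tree (internal branches × λ, terminal
  branches stretched to preserve depth). The pipeline default σ² =
  40 000 mm²/Ma spreads a 60–200-species clade across the 200–3000 mm
  gradient in ~10–30 Ma.
* **Landscape**: MAP increases linearly with latitude; monthly layers are
  MAP times a fixed raised-cosine seasonal profile (amplitude 0.9), so
  dry-season length has a closed form. Occurrences are drawn at the
  latitude whose cell MAP is nearest the species' trait, with Gaussian
  latitudinal noise and uniform longitude, clipped to the extent.

The recovery experiments fix their own worlds, chosen once on
identifiability grounds and not revisited:

* **Niche shifts** (σ² = 500 mm²/Ma, baseline 700 mm, ten +900-mm jumps on
  disjoint clades of 2–6 species with stems ≥ 1.5 Ma and distinct parent
  nodes): ML reconstruction smooths; a jump on a zero-length stem, a lone
  terminal tip, or a clade comprising most of the tree is not attributable
  to a single branch by *any* smoothing estimator — the parent estimate
  absorbs a large fraction of the offset, and with a diffuse baseline both
  endpoint estimates are pulled into the intermediate band. Sensitivity
  ≥ 80% with < 5% branch false positives holds for the stated world; it
  degrades, and should be expected to degrade, as shifts become small,
  nested, or placed on uninformative branches.
* **Two-band regionalization** (clade nearest half the species shifted
  +1800 mm from a 700-mm baseline): the half-split matters because the
  per-cell richness filter silently removes whichever band holds too few
  species — an instructive failure mode for real sparse data too.
* **DEC recovery** (d = 0.02, e = 0.01, three areas, 100 tips): d is
  sharply identified; the e-profile is shallow (≲ 0.05 log-units across
  [0, 0.02] in typical replicates) and single fits frequently return 0 —
  only the median over 50 replicates is claimed, and only with multi-start
  optimization.
* **Pagel's λ**: the ML estimator's expected absolute error at λ = 0.5 on
  200-tip birth–death trees is ≈ 0.099 (sd of λ̂ ≈ 0.12) — at the claimed
  0.1 bound — so that case runs 600 replicates to make the Monte-Carlo
  error of the MAE estimate (±0.003) small against the bound.

None of the generators attempt real geography: no continental outlines, no
real climate layers, no spatial autocorrelation in the noise, and species'
ranges are climate bands rather than contiguous polygons. A green suite
establishes the estimators' correctness and calibration on worlds that obey
the models' assumptions, not the ecological claims themselves.

## Known limitations

* GDM significance testing by permutation and spline-count selection are
  out of scope; deviance comparisons are descriptive.
* DEC omits the null range (documented above) and DIVALIKE/BAYAREALIKE
  variants; dispersal matrices are time-homogeneous.
* The metachronogram machinery consumes already-dated trees; no divergence
  dating is performed.
* Exact-branch shift detection inherits the smoothing bias of ML ancestral
  reconstruction; shift *counts* are more robust than shift *placements*.
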