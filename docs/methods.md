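# Methods

`somaclock` analyses the accumulation of somatic epimutations — stochastic,
heritable gains and losses of cytosine methylation — within a single tree,
treating the tree's branching architecture as an intra-organismal phylogeny
of somatic cell lineages.  This note documents the models, the numerical
choices, and what the synthetic-data generator does and does not emulate.

## The neutral gain/loss model

Each cytosine site is a two-state Markov chain: an unmethylated site gains
methylation with probability α per year, a methylated site loses it with
probability β per year.  Time is discrete in years and the per-year
transition probabilities are identified with the rates; this is accurate
because realistic rates (~10⁻⁶–10⁻⁵) are vastly smaller than one.  Writing
π = α/(α+β) for the steady-state methylated fraction and γ = 1 − α − β for
the per-year retention factor, the chain over d years has the closed form

    P(m at t+d | m at t) = π + (1 − π) γ^d  ≡ a(d)
    P(m at t+d | u at t) = π (1 − γ^d)      ≡ b(d)

Two tips sampled τ_i and τ_j years after their most recent common branch
point, whose ancestor was methylated with probability p0, have expected
divergence (mean per-site absolute state difference)

    D = c + p0 [a_i(1−a_j) + a_j(1−a_i)] + (1−p0) [b_i(1−b_j) + b_j(1−b_i)]

where c absorbs divergence that predates the earliest datable branch point
(pairs whose ancestor *is* the earliest branch point are flagged
`root_censored` and excluded from fitting by default, since their true
divergence time cannot be dated from ring counts).  At p0 = π this reduces
to the familiar c + 2π(1−π)(1 − γ^(τ_i+τ_j)); the reduction is verified to
1e-12 in the tests.

## Fitting, identifiability, and the equilibrium constraint

Rates are estimated by bounded nonlinear least squares of observed pair
divergences against the curve above, with α, β ∈ [1e-12, 1e-2] and
c ∈ [0, 0.4], log-parameterised internally for conditioning, with an
analytic Jacobian, and multi-started from a 3×3 decade grid over (α, β)
plus a slope-informed start.  p0 is fixed to the observed mean methylated
fraction across samples rather than fitted: with only genome-wide mean
divergences per pair, the four-parameter problem (α, β, c, p0) is weakly
identified.

A structural feature of this model matters in practice.  Near equilibrium
the divergence curve constrains (α, β) essentially only through their sum
λ = α + β: expanding D for small rates gives D ≈ c + 2(1−γ^Δt)[p0 + π(1−2p0)]
plus a second-order term ~(1−γ^Δt)², so the (α − β) direction is a flat
ridge whose curvature is orders of magnitude below sampling noise at
realistic rates and divergence times (≤ ~300 yr).  The estimator therefore
also solves the equilibrium-constrained problem — steady state pinned to
the observed level, α = p0λ, β = (1−p0)λ — and adopts that solution unless
an F-test (5%) shows the unconstrained model fits significantly better.
The gain/loss split is thus resolved by the observed methylation level
whenever the divergence curve cannot resolve it, and by the curve when it
can (e.g. at large rates, where recovery of all three free parameters from
noiseless curves is exact to better than 1e-8).  Which model was adopted is
recorded in the fit notes.

### Standard errors

Pair divergences are not independent: pairs sharing a lineage share the
epimutations on their common branches.  Three SE estimators are provided:

- **asymptotic** — Jacobian-based covariance with residual variance; this
  treats pairs as independent and is anti-conservative here (in simulations
  its 2-SE intervals cover the generating rates only ~75% of the time);
- **jackknife** — delete-one-leaf, refitting without each leaf in turn;
  captures leaf-level dependence (~80–85% coverage);
- **model** (default when the pedigree and site count are available) — a
  sandwich covariance using the exact model-implied covariance of the pair
  divergences, obtained from joint four-leaf discordance probabilities
  computed by pruning on the pedigree.  This also captures variance from
  epimutations on deep shared branches, which no within-dataset resampling
  can see, and achieves ~95–100% 2-SE coverage in the recovery simulations.

A pair-resampling bootstrap (`bootstrap_se`) is available as a further
cross-check.  Between-fit comparisons use one-sided Welch statistics from
the (estimate, SE) summaries with a normal reference, since the summaries
carry no replicate counts.

## State calling

Counts per unit (site or 100-bp window) are modelled with three binomial
emission components at success probabilities p_u < p_i < p_m, estimated by
EM from initialisation (0.01, 0.5, 0.95), at most 200 iterations,
log-likelihood tolerance 1e-6, and no random restarts (determinism).  To
keep the components identifiable on sparse data, p_u is clamped to
[0.001, 0.15], p_m to [0.6, 0.999], and p_i is pinned midway between them.
The intermediate state captures somatic epiheterozygotes (one methylated
allele), visible in bulk data as ~50% methylation.  `independent` mode uses
mixture posteriors; `chain` mode couples consecutive units along genome
order with an estimated first-order transition matrix (posteriors by
scaled forward–backward).  The state is the posterior argmax with exact
ties broken toward i (conservative; such units fail the 0.99 filter
anyway).  SMPs and DMRs are confident state switches between samples at
sites and 100-bp windows respectively; units failing the posterior filter
in either sample are excluded from both numerator and denominator.  When
binning per-site calls into windows an intermediate site contributes 0.5
methylated cytosines, rounded half-up per window.

## Divergence, effect sizes and clustering

Genome-wide divergence is the mean per-site absolute difference of encoded
states (u=0, i=0.5, m=1 by default; a binary any-difference mode is the DMP
proxy), over the pairwise-complete universe of sites confidently called in
both samples.  The stem-sampling contrast subtracts the same-side replicate
mean from each opposite-side mean before taking the treatment ratio; this
fold change is invariant to affine rescaling of all three means.  Group
contrasts use one-sided Wilcoxon rank-sum tests plus Cohen's d with pooled
SD (bands: >0.2 small, >0.5 medium, >0.8 large).  Sample clustering is
average-linkage (UPGMA) on the divergence matrix, exportable as Newick for
Robinson–Foulds comparison against the known architecture; UPGMA is
appropriate because tips sampled at the same age make divergence
ultrametric in expectation.

## gbM classification

A gene is gene-body methylated when its exonic CG methylated-position
proportion is significantly above the exonic background (one-sided binomial,
BH-FDR across genes at 0.05) while exonic CHG and CHH proportions are not
significantly different from theirs (two-sided binomial at 0.05,
unadjusted — adjusting a test whose desired outcome is non-significance
would be anti-conservative).  Tests count methylated cytosine positions,
not reads.  Per-sample calls are unioned into a liberal candidate set; the
pooled intronic CHG+CHH read-level methylation of each candidate is then
compared with the median over candidates and only strictly-below-median
candidates are retained (ties at the median are removed).  By construction
this halves the informative candidates — it is a deliberate precision
filter, so label-recovery checks apply to the classification stage, not to
the filtered set.  Candidates without introns are retained with a
missing-intron flag; candidates with fewer than 5 informative intronic
positions are flagged low-information.

## The synthetic-data generator

The generator produces exactly the statistical structure the estimators
assume, which is what makes the recovery tests interpretable:

- **Topologies** are dated, binary, ultrametric in time, with branch points
  either supplied or drawn uniformly on [0.2·age, 0.95·age].
- **States** evolve independently per site; a branch of d years is sampled
  in one step from the exact d-step transition probabilities.  The
  epiheterozygote mode evolves two independent alleles and reports u/i/m by
  methylated-allele count.
- **Division-rate coupling**: rates may be given per cell division (ε)
  together with κ divisions per year; the per-year rate is 1 − (1 − ε)^κ,
  linear in κ for small ε.  This is the in-silico handle on the
  mitotic-rate hypothesis: holding ε fixed and doubling κ doubles the
  fitted per-year rates.
- **Read counts**: negative-binomial coverage (default mean 20, dispersion
  10, matching realistic WGBS spread) and binomial methylated counts at
  success probability err, 0.5, or 1−err by true state.
- **Stem design**: per stem, two same-side replicates sharing all but a
  small terminal fraction (default 2%) of their κ·age divisions, plus one
  opposite-side sample diverging at the stem core.  Defaults (4 moderate
  and 3 heavy stems, 200 yr, κ = 10 vs 18 yr⁻¹, ε_gain = 1.2e-6,
  ε_loss = 1.6e-6) give replicate and opposite-side divergences of the
  order observed in real cambium data (~1e-4 vs ~5e-3).
- **Annotations**: evaluated genes in classes gbM / teM-like / unmethylated
  (per-site methylation probabilities 0.92/0.002/0.002, 0.85/0.7/0.6, and
  0.05/0.002/0.002 for CG/CHG/CHH), plus an always-present cohort of
  unmethylated background genes — real exonic backgrounds are dominated by
  the unmethylated majority, and without them a fixture made purely of gbM
  genes would have no contrast to its own background.

What the generator does **not** emulate: linkage between neighbouring sites
(sites are independent; DMRs in real data are correlated blocks), allele
correlation through shared mitotic history (the two alleles of the
epiheterozygote mode are independent, overstating the intermediate
fraction at equilibrium), sequence-composition effects, bisulfite
non-conversion structure beyond a flat error rate, cell-layer chimerism,
and selection.  Passing recovery tests therefore demonstrate estimator
correctness under the neutral independent-site model, not robustness to
these realities.

## Problem sizes and reproducibility

The recovery protocols use 10-leaf, 200-year pedigrees with 5×10⁵ CG sites
and 20 replicates; topology-recovery uses 6–10 leaves at 3×10⁵ sites with
branch points spaced ≥ ~18 years (the resolution at which ~10⁻⁶–10⁻⁵ rates
can order branch points from divergence alone at that site count);
state-caller checks use 5×10⁴ sites at 50× depth.  These sizes give
sampling errors of a few percent on the fitted rates, comparable to the
published standard errors.  All stochastic steps take explicit seeds;
repeated runs are bit-identical, and the pipeline manifest records seeds,
options and output checksums.

## Known limitations

- Rates are "per site per haploid genome per year"; region-level fits reuse
  the same machinery on 100-bp window states.
- The equilibrium constraint makes the reported gain/loss *split* only as
  good as the assumption that the observed methylation level is stationary;
  strongly non-stationary methylomes would bias α/β (though not α+β).
- CG/CHG/CHH contexts are analysed separately and independently; no joint
  model across contexts.
- The `chain` state-calling mode estimates a single genome-wide transition
  matrix; it does not model distance-dependent transitions.
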