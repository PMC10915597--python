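# Methods

`refugia` fits three-population demographic models to joint site-frequency
spectra (SFS) of unlinked biallelic SNPs, ranks candidate models by AIC,
attaches parametric-bootstrap confidence intervals, and asks whether
geographically congruent divergences across taxa are better explained by
one shared event or by independent events.  This note records the model,
the numerical choices, and what the synthetic-data experiments do and do
not demonstrate.

## The demographic model family

A scenario relates three contemporary clusters A, B, C (Andean, northern
Atlantic Forest, central-southern Atlantic Forest; the labelling is
taxon-specific) on the fixed rooted shape ((A,B),C): A and B merge into an
ancestor at `tdiv_AB`, which merges with C at `tdiv_ABC`.  Around this
backbone a model may place:

- **migration pulses** — instantaneous admixture in which a fraction *p* of
  the destination population derives from the source at time `tmig`;
  backward in time each lineage in the destination jumps to the source
  independently with probability *p* (the standard duality);
- **exponential growth** — a per-generation rate *g* acting from the
  present, so `Ne(t) = Ne0 exp(-g t)` backward in time;
- **bottlenecks / size changes** — instantaneous changes of `Ne` at a time.

Pulses between A and B must predate `tdiv_AB`.  Pulses between the
"(A,B) side" and C must predate `tdiv_ABC` only: when such a pulse is more
recent than `tdiv_AB` the ancestor does not yet exist, and the pulse is
applied to A and B separately (for a forward flow out of the pair, each C
lineage moving backward picks A or B with equal probability).  This is
needed to accommodate published point estimates in which, for example, a
pulse out of C into the pair is much more recent than the A/B split.

The candidate catalog (models I–XV) is data-driven: one YAML document per
model under `refugia/catalog/`, with a `provenance` flag separating the
members pinned by published parameter counts (I, VI, X, XII: k = 5, 13,
14, 16) from members reconstructed from the legend categories
("divergences", "+ migrations", "+ expansions", "+ bottlenecks").  The
free-parameter count *k* is always derived from the declared bounds (a
symbol with `lo == hi` is fixed), never hard-coded.

Times are stored in years everywhere and converted to generations at
simulation time with a generation time of 2.33 y; the assumed mutation
rate is 2.5e-9 / site / generation (neither enters the conditioned
likelihood below, but both are carried for reporting and data generation).

### Default parameter bounds

Diploid effective sizes 2e4–2e6; Quaternary-scale divergences 1e4–3e6 y
(`tdiv_AB`) and 5e4–3.6e6 y (`tdiv_ABC`); the null model leaves divergence
free to 1e7 y and the barrier model constrains it to 2.6e6–1e7 y
(pre-Quaternary barrier formation); admixture fractions 0–0.6 (the upper
cap visible in published interval endpoints); growth rates 1e-8–1e-3 per
generation; bottleneck strengths 0.01–0.9.  Pulse and bottleneck times are
bounded by the divergence that must postdate them rather than by fixed
numbers (see Optimisation).

## Coalescent engine

Genealogies are simulated backward in time under the structured
coalescent: within a deme of current size `Ne(t)` each lineage pair
coalesces at rate `1/(2 Ne(t))` per generation; exponential-growth epochs
use the closed-form time transform of the non-homogeneous exponential.
The continuous-time coalescent is used as the limit of the discrete
Moran/Wright–Fisher models, appropriate because sample sizes (tens) are
orders of magnitude below the effective sizes (1e4–1e6).  The hot loop is
JIT-compiled (numba); each replicate is driven by an explicit 31-bit seed,
so identical `(model, parameters, seed)` give identical genealogies,
spectra, and datasets.  Subtended leaf sets are carried as 64-bit masks,
which caps the total sample at 60 allele copies.

The Monte-Carlo expected joint SFS accumulates each branch's length into
the cell indexed by how many sampled copies it subtends per population and
normalises over polymorphic cells.  Conditioned SNP data (one SNP per
locus) are generated by drawing one branch per independent genealogy with
probability proportional to length — exactly the infinite-sites
distribution of a site conditioned on segregating.  A pulse whose fraction
is zero is dropped *before* the event table is built, so adding it cannot
perturb the consumed random stream: the likelihood shift is exactly zero,
a property the tests assert.

The engine is cross-checked in the test suite against an independent
coalescent simulator (msprime) on TMRCA and total branch length for three
scenarios, and against closed forms (`E[T2] = 2Ne`, `E[xi_i] ∝ 1/i`,
`E[S] = θ a_n`).

## Composite likelihood and its scale invariance

With one SNP per locus there is no per-locus sequence-length information,
so the likelihood is multinomial over SNPs conditioned on polymorphism:
`lnL = Σ_c n_c log π_c(θ)`, with `n_c` the observed (possibly fractional,
see Projection) cell counts and `π_c` the normalised expected spectrum.

This likelihood is **exactly invariant** to multiplying every effective
size and every time by a constant while dividing growth rates by it: only
coalescent-scaled ratios are identified.  Absolute times therefore require
an external anchor.  The package pins the geometric mean of the three
contemporary `Ne` to a reference (`anchor_ne`, default 2e5 diploids, the
same order-of-magnitude choice the data generator documents in its truth
files) *inside* the objective, which removes the flat direction from the
search and puts all reported sizes and times on the anchor's scale.  All
recovery and coverage results below are conditional on that anchor; the
alternative of leaving the scale free makes the answer depend on the
optimiser's starting scale, which is strictly worse.  `k` still counts the
declared free symbols (13 for the four-pulse model), matching the
published bookkeeping.

### Monte-Carlo smoothing

With finite Monte-Carlo replicates, observed cells can receive zero
expected mass; a hard floor (1e-30) makes the objective a cliff dominated
by missed tail cells.  The objective therefore shrinks the spectrum toward
uniform, `π' = (π + a/K)/(1 + a)` with `a = 0.01` over the `K` polymorphic
cells, so unsampled cells are penalised smoothly.  The user-facing
`composite_loglik` keeps the plain floored form; the smoothing is an
optimisation device.

## Optimisation

Parameters are searched in a transformed box: log scale for sizes, split
times, and growth rates; linear for admixture fractions and bottleneck
strengths; event times as *fractions* of the divergence that bounds them,
so every box point decodes to a valid event ordering.  An inverted pair of
split-time coordinates is mirror-folded into the ordered pair, keeping the
surface continuous without penalties.

Each start draws log-uniform initial values and proceeds in stages:

1. **backbone stage** — sizes and split times optimised by bounded
   Nelder–Mead with event intensities held at neutral values (pulse
   fractions 0.02, no growth, no bottleneck, event times mid-window);
2. **pruning** — the best quarter of starts (at least two) survive, ranked
   under a single high-precision seed set;
3. **full stage** — Nelder–Mead over all coordinates with one restart,
   under the start's own fixed common-random-number (CRN) seeds;
4. **final selection** — all survivors (and their stage-1 points, in case
   the noisier full search wandered) re-scored with `final_mc_reps`
   replicates under one shared seed; ties break toward the smaller
   transformed-parameter norm.

The incremental schedule matters: starting the full search at large random
admixture fractions reliably traps the fit in inflated-divergence basins.
CRN makes the objective deterministic within one search, which is what
lets Nelder–Mead operate on a Monte-Carlo likelihood at all.

Defaults: 100 starts (matching the published protocol; desk-scale runs use
8–20), 96 search replicates (48 in the backbone stage), 2048–4096 final
replicates, `60 k` function evaluations per stage for a k-parameter model.

## Parametric bootstrap

Percentile intervals (no bias correction, matching the published plain 95%
intervals) from refits of datasets re-simulated under the fitted
parameters.  Replicates emulate the *full* observation process — diploid
genotypes at the original sample sizes, genotype masking at the observed
missingness, expected hypergeometric projection to the analysis sizes —
because replicating only the analysed spectrum distributes the refits
around a measurably different optimum.  The desk-scale default is 12–16
replicates per interval (the published protocol used 100).

Percentile intervals are calibrated only when the refit estimator is
distributed like the estimator that produced the observed-data fit.  Two
modes are provided: warm-started refits (fast; appropriate when the outer
fit is converged well beyond the interval's resolution) and
``warm_start=False`` refits that re-run the same random multi-start
schedule as a fresh fit.  The calibration experiments use the second mode
with one reduced-budget estimator on both sides, because mixing a
full-budget outer fit with cheap warm refits measurably mis-centres the
intervals (each side carries a different Monte-Carlo search bias).

## SFS construction

VCFs are read through cyvcf2; multiallelic and indel records are skipped
with counts, the locus ID is CHROM, and the ancestral allele comes from
the AA tag (REF assumed ancestral otherwise; if any site stays
unpolarised the spectrum folds with a warning).  The one-random-SNP-per-
locus filter is uniform per locus, seed-deterministic, order-stable and
idempotent.  Missing data are handled by **expected hypergeometric
projection**: each site contributes its exact projection distribution at
fixed projected sizes (default 80% of the per-population maximum called
copies), sites below the projection coverage are dropped with a count, and
projection mass landing on the monomorphic corners is tallied separately,
so retained + dropped mass always equals the input site count.  Folding
maps a configuration onto its complement when the summed derived count
exceeds half the total sample (lexicographic tie rule), and is idempotent.

## Shared-divergence comparison

The published question — one divergence event or several across taxa — is
operationalised as an AIC comparison inside the same composite-likelihood
framework rather than by re-implementing a Bayesian co-divergence sampler,
whose stated assumptions (constant sizes per branch, no migration) define
the template used here.  Each taxon is fitted under a constant-size
no-migration template whose contemporary sizes carry a fixed-geometric-
mean constraint (the same anchor as above) — without it the per-taxon
scale freedom would let a shared-time model mimic any free-time model and
the comparison would be vacuous.  The free variant fits each taxon's two
split times independently (4 parameters per taxon); the shared variant
forces the named split (A/B or root) to one value across taxa, fitted as a
profile likelihood over the shared time with warm-started inner refits —
far more reliable than a joint search.  All taxa share one CRN seed set,
so Monte-Carlo noise partially cancels from the comparison (paired
design).

Finite-replicate Monte-Carlo surfaces displace every optimum by more than
the 2-unit AIC margin the decision turns on, and the displacement does not
cancel between two independently optimised hypotheses.  The decision is
therefore made entirely under one large common seed set: candidate shared
times (the per-taxon free estimates, their mean, and the profile's choice)
are each given a deep constrained re-polish per taxon, warm-started from
the free fits, and scored at high precision; the winning shared states are
then added to each taxon's free candidate pool, so the nesting inequality
`lnL_free ≥ lnL_shared` holds exactly and the free hypothesis wins only
when its unconstrained fits genuinely beat the best shared configuration.
Total AIC decides: `k_shared = Σ k_taxon − (T − 1)`.

## Diversity statistics

`S`, π, Watterson's `θ_W = S/a1` and Tajima's D with the standard
coefficients.  Missing-data policy: pairwise deletion for π; columns with
at least `min(4, n)` called states for S and D, with D's π-total computed
over those same columns so the statistic is internally consistent.  These
conventions are a documented choice — the source material does not state
its handling — and reduce to the textbook definitions on complete data.

## Synthetic data

Presets mirror the empirical study shape: three clusters, 8 diploids per
cluster, 1845–2036 unlinked SNPs (one per locus), 1.5–10.41% missing
genotypes, unfolded spectra (ancestral allele = REF, recorded in the AA
tag).  The four "table5" presets carry the published best-model point
estimates as generating truths (times via 1 Ma = 1e6 y, migration
percentages divided by 100); one taxon could not support an A→B pulse, so
its preset fixes that fraction at zero.  Contemporary `Ne` values are not
published; presets use 2e5 diploids — typical for thamnophilid antbirds —
and write that choice into the truth file.  Null and barrier presets
provide constant-size scenarios with free and pre-Quaternary divergences.

What the generator does *not* emulate: sequence-level errors, genotype-
calling uncertainty, linkage within loci (irrelevant at one SNP per
locus), Z-linked loci, and spatial sampling structure within clusters.
Passing recovery tests therefore demonstrates correctness of the
inference machinery under the model's own assumptions, not robustness to
real-data artefacts.

## Desk-scale protocol sizes

The evaluation protocols (`refugia.protocols`) use: 1e5 Monte-Carlo
replicates for the analytic spectrum check; 10 recovery replicates at 2000
loci with 20 starts; 20 coverage replicates with 12 bootstrap refits each;
20 discrimination replicates (4 starts per model); 20 + 20 co-divergence
replicates at 1000 loci per taxon (3 starts); 500 neutral and 250
expansion genealogies (n = 20, θ = 6) for Tajima's D.  These sizes keep a
full evaluation within tens of minutes on one core while leaving the
acceptance margins comfortable; all of them scale up by argument.

## Known limitations

- Absolute times are anchored, not estimated: with polymorphism-
  conditioned SNP data this is a structural property of the likelihood,
  not an implementation shortcut.  Confidence intervals are conditional on
  the anchor.
- The expected SFS is Monte Carlo, not exact; a deterministic
  Moran-matrix computation would remove objective noise and is noted as a
  possible extension.
- Composite-likelihood AIC treats SNPs as independent; with one SNP per
  UCE locus this is close to true by construction, but residual linkage
  between nearby loci would make the rankings slightly anti-conservative.
- The mirror fold and anchored template make the co-divergence comparison
  depend mildly on the anchor choice when taxa differ strongly in true
  size; the calibration experiments use equal-size truths.
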