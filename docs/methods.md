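# Methods

This note documents the statistical models and procedures implemented in
`coralforage`, the assumptions behind the synthetic-data generator, the
numerical choices in the mixed-model fitter, and known limitations.

## Study design emulated by the generator

The generator (`coralforage.simulate`) emulates a shallow-reef foraging
study: three sites surveyed in each of three years, with a mass
coral-mortality event between year 1 and year 2. Per site and year it
produces

* six 50-m point-intercept benthic transects (101 points at 0.5-m spacing;
  point count is configurable since a field protocol may log 100 or 101),
* 3-minute focal-follow foraging observations for five butterflyfish
  species (default 12 follows per species × site × year; total bites per
  follow are Poisson with mean 24, matching roughly 8 bites/minute for an
  actively foraging corallivore),
* 50 × 5 m belt-transect counts of the same species.

Hard coral cover starts at `pre_cover` (default 0.55) and the event removes
`mortality_fraction` (default 0.65) of it in expectation. Losses are
apportioned across genera in proportion to susceptibility weights
(*Acropora* highest by default, *Porites* lowest, matching the well-known
susceptibility ranking of these taxa); genera whose implied loss would
exceed 100% are capped and the shortfall redistributed (water-filling), so
the aggregate loss always equals the configured fraction. Dead coral
appears as its own substrate category post-event. Transect points are
i.i.d. draws from the site-year substrate distribution — there is no
spatial autocorrelation along the transect, which real point-intercept data
do exhibit.

### Behavioural ground truth

Each species carries a genus-preference weight vector `w_s` over the seven
focal genera (*Acropora, Favites, Galaxea, Goniastrea, Montipora,
Pocillopora, Porites*). An individual fish draws its own weights

    w_ind ~ Dirichlet(kappa * w_s),      kappa = exp(a + b * cover),

so the Dirichlet concentration κ controls among-individual preference
consistency, and the log-linear link to hard coral cover (defaults a = 0.5,
b = 4, giving κ ≈ 15 pre-event and κ ≈ 3.5 post-event) makes preferences
weaken as food becomes scarce. κ was chosen as the operationalisation of
"preference strength" because it maps monotonically onto the expected
pairwise rank agreement that the downstream Preference Coefficient
measures. Bites are allocated multinomially with probabilities proportional
to availability × individual weights, so the preference signal lives in
electivity rather than in raw diet shares.

Two null configurations matter for testing. With `kappa_slope = 0` *and*
uniform `w_s`, individual rankings are exchangeable and the expected
Preference Coefficient is exactly 0.5 at any κ; this is the generator's
"no preference structure" condition. Note that `kappa_slope = 0` alone is
**not** a full null: with a shared non-uniform `w_s`, two individuals agree
on the ranking with probability above chance at every κ (as κ → 0 the
Dirichlet degenerates to near-one-hot draws and P(w_i > w_j) → w_i/(w_i +
w_j)), and rarity-driven sampling noise still couples rank agreement to
cover. Both effects are properties of electivity-based rank statistics, not
artefacts of this implementation.

`one_inflation_target` (off by default) makes a fraction √target of
individuals "archetypes" that express the species' expected diet as a fixed
deterministic (largest-remainder) bite vector; archetype–archetype pairs
then yield Preference Coefficients of exactly 1, giving controlled
one-inflation. Without it, exact ones still arise naturally from rank ties
at realistic bite counts. All randomness flows through a single seeded
generator with a fixed draw order (sites outer, years inner; community,
then foraging, then fish counts), so a (config, seed) pair is fully
reproducible.

### What passing tests on synthetic data do and do not show

The generator reproduces the *structure* of the field problem — availability
gradients, a genus-skewed mortality event, individual-level preference
noise, bounded pairwise responses with exact ones — so green tests show the
estimators recover known parameters under that structure at realistic sample
sizes. They do not show anything about effects absent from the generator:
spatial autocorrelation, observer effects, territoriality, tide or weather
covariates, or non-coral prey.

## Evenness

Hurlbert's PIE, `(N/(N−1))(1 − Σ p_i²)`, is computed per transect from
coral-species point counts (non-coral points excluded; transects with fewer
than two coral points dropped) and per fish species × site × year from
diets pooled over individuals at coral-species level (individual follows
contain too few prey taxa for stable values). Year effects are tested with
the tie-corrected Kruskal–Wallis statistic (SciPy) and Dunn's post-hoc z
tests implemented from the pooled-rank formula with tie correction. The
all-ties degenerate input is defined as H = 0 (the usual correction gives
0/0; no separation is the only defensible reading). Dunn p-values are
reported unadjusted by default — both one-sided tails are emitted because
the tail convention for a signed z is a reporting choice — with optional
Holm adjustment.

## Electivity and Preference Coefficients

Availability `p_i` is each genus's share of hard-coral points pooled over a
site-year's transects (site-level cover is what the regression uses), then
renormalised over the seven focal genera so diet and availability shares
live on the same support. `E_i` is undefined when `p_i = 0`: a fish biting
a genus never recorded on transects would otherwise get E = +1 from a
sampling zero and dominate every ranking, so such genera are excluded from
the profile instead. Pairs need at least three shared defined genera and
two non-constant vectors for a Spearman ρ (mid-ranks, SciPy); `y₁ = (ρ +
1)/2`. Diet-proportion tables report full precision plus a half-away-from-
zero rounded percent column, since printed tables elsewhere may use a
different rounding rule.

## The one-inflated beta mixed model

The response density is

    f(y) = ν·1{y=1} + (1 − ν)·Beta(y; μφ, (1−μ)φ)·1{0<y<1},

with `logit(μ) = Xβ + u_fish1 + v_fish2`, log-link precision φ (constant by
default) and logit-link inflation ν (constant by default). The two fish in
each comparison enter as two separate crossed random intercepts. Exact
zeros (perfectly opposite rankings) fall outside the support 0 < Y ≤ 1 and
are mapped to ε = 1/(2n) before fitting; the count of mapped values is
logged.

Because the random effects enter only the beta component, the likelihood
factorises exactly: ones contribute a Bernoulli likelihood in ν (whose MLE
with constant inflation is the sample proportion of ones), and the beta
part is marginalised over (u, v) by a Laplace approximation. The inner mode
is found by Fisher-scoring Newton steps with step-halving; both
random-effect blocks of the penalised Hessian are diagonal, so each step
and the log-determinant need only a Cholesky factorisation of a Schur
complement the size of the fish2 level set. The log-determinant uses the
observed curvature (floored at 1e-10, with a Fisher fallback if
factorisation fails). Outer parameters (β, log φ, log σ_u, log σ_v) are
maximised by L-BFGS-B with finite-difference gradients; without random
effects the objective is smooth and exact and much tighter steps and
tolerances are used, which makes the σ = 0, ν = 0 special case agree with
an independent beta-regression implementation to ~1e-4. Wald standard
errors come from the numerically differenced observed information of the
outer parameters; the difference step (3e-3, scaled) is chosen large enough
that inner-solver noise (~1e-6 in the log-likelihood) does not corrupt the
curvature estimate. As σ → 0 the Laplace marginal tends continuously to the
fixed-effects likelihood.

Model selection is backward elimination from the full fixed-effect set
(cover + species + site + year): at each stage the reduced model with the
lowest AIC is adopted unless the richer model improves AIC by at least 2 —
the richer model must earn its parameters — and every comparison is
recorded in a trace. The cover × species interaction is compared the same
way. The generalized R² is the likelihood-ratio (Nagelkerke-style,
uncorrected) form `1 − (L₀/L₁)^{2/n}` against an intercept-only model with
the same random terms, a definition chosen because it extends to mixture
likelihoods.

Predictions default to the population level (random effects at zero) and
report the expected response `ν + (1 − ν)μ`; conditional predictions for
one named fish pair add that pair's estimated intercepts, and a flag
switches to the beta-mean μ alone. Jackknife bands refit on random 80%
subsets, 100 replicates, and take the 5th and 95th *ordered* replicate
predictions per grid point, literally — a ~90% band; a flag selects the
2.5th/97.5th instead. Each species is predicted only over its observed
cover range. Failed replicate fits are skipped and logged, with a warning
below 80 successes.

The cover covariate is used as a proportion (0–1). On the logit scale a
coefficient on proportions is 100× the same coefficient on percent cover,
so comparisons against coefficients of unknown scale should try both.

## Overlap null models

The resource-use matrix holds genus-level bite sums for species with at
least eight observations in *every* study year (below that, proportional
allocations are too noisy). Mean pairwise Pianka overlap

    O_jk = Σ_i p_ij p_ik / sqrt(Σ_i p_ij² Σ_i p_ik²)

is compared with 1000 RA3 draws: each row's entries, zeros included, are
permuted uniformly across columns, preserving each consumer's niche breadth
and total use while letting column totals fluctuate. Randomisation operates
on raw counts; overlap is computed on row-normalised draws. Tail
probabilities use strict counting (`#{null ≥ obs}/n_sim`, ties counting
toward both tails, two-tailed = 2·min capped at 1); a flag enables the
(k+1)/(n+1) form. SES is flagged undefined (NaN) when the null is
degenerate. An alternative reading of "breadth-preserving" — permuting only
the nonzero entries among all cells — is not the default because it does
not preserve the zero structure's interpretation; the default is the
zeros-included row permutation.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run entirely on synthetic data:
calibration uses 500 observed-from-null replicates at 500 null draws each;
mixed-model recovery uses 100 replicates of 576 pairs (16 groups of 9 fish
— enough distinct cover values for well-calibrated Wald intervals);
end-to-end ground-truth recovery uses 20 replicate studies at the default
design (2,376 pairs each). These sizes were chosen to keep Monte-Carlo
error well below the assertion margins.

## Known limitations

* The Laplace approximation is a single-mode Gaussian approximation; with
  very small groups or extreme φ its likelihood (and hence AIC) carries
  approximation error. No quadrature or MCMC fallback is provided.
* ν and φ are constants by default; covariate-dependent inflation or
  precision would require extending the inflation/precision submodels.
* The generator draws transect points independently and models no fish
  movement, territoriality, or non-coral prey.
* Dunn tests are reported unadjusted by default; with many years the Holm
  flag should be used.
* Electivity profiles treat availability as known; uncertainty in `p_i`
  from finite transect sampling propagates into E and slightly biases rank
  agreement for rare genera (visible as the rarity pathway discussed
  above).
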