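# coralforage

Quantitative tools for asking how a mass coral-mortality event reshapes the
foraging behaviour of coral-feeding reef fishes (butterflyfishes, genus
*Chaetodon*): do diets become more even, do individual food preferences
weaken as food becomes scarce, and does the community partition the
remaining resources more or less than expected by chance?

The package implements the full analysis chain as a tested, reusable
pipeline, together with a synthetic study generator with known ground truth
so that every stage can be validated without field data.

## What it computes

**Evenness.** Hurlbert's Probability of Interspecific Encounter for a count
vector *n* with total *N*,

    PIE = (N / (N - 1)) * (1 - Σ_i (n_i / N)²),

per benthic point-intercept transect (coral assemblage evenness) and per
fish species × site × year from pooled diets, compared across years with
tie-corrected Kruskal–Wallis and Dunn post-hoc tests.

**Electivity.** Ivlev's index per fish and coral genus,
`E_i = (r_i − p_i) / (r_i + p_i)`, where `r_i` is the diet share of genus
*i* and `p_i` its share of hard-coral cover (both renormalised over the
seven focal genera). −1 = complete avoidance, 0 = feeding in proportion to
availability, +1 = exclusive selection.

**Preference Coefficients.** Every within-species, within-site-year pair of
fish is compared by the Spearman rank correlation ρ of their electivity
profiles, rescaled to `y₁ = (ρ + 1) / 2 ∈ [0, 1]`; 1 means identical
preference order, 0.5 no consistent order.

**One-inflated beta mixed model.** Preference Coefficients are exactly 1
with probability ν and otherwise Beta(μφ, (1 − μ)φ)-distributed, with

    logit(μ) = Xβ + u_fish1 + v_fish2,   u ~ N(0, σ_u²),  v ~ N(0, σ_v²),

estimated by maximum likelihood with a Laplace approximation over the
crossed random intercepts. Fixed effects (hard coral cover, species, site,
year) are pruned by backward AIC selection under a two-point rule, and
per-species prediction bands come from a 100-replicate 80% subsample
jackknife.

**Niche overlap.** Mean pairwise Pianka overlap of the forager × genus
bite matrix, tested against 1000 RA3 row-permutation null matrices
(consumer niche breadth preserved, column totals free), summarised as a
standardized effect size `SES = (obs − mean(null)) / sd(null)` with tail
probabilities.

## Worked example

```python
from coralforage import (SimulationConfig, generate_study,
                         availability_proportions, ivlev_electivity,
                         preference_pairs, pairs_to_frame,
                         fit_oibe, OibeModelSpec,
                         build_resource_matrix, null_model_test)
from coralforage.preference import PREFERENCE_SPECIES

bundle = generate_study(SimulationConfig(seed=3))
sy = sorted({(t.site, t.year) for t in bundle.transects})
avail = {k: availability_proportions(bundle.transects, *k) for k in sy}
print({k: round(a.hard_coral_cover, 3) for k, a in avail.items() if k[0] == "site1"})
# {('site1', 2016): 0.52, ('site1', 2017): 0.172, ('site1', 2018): 0.173}

focal = [o for o in bundle.observations if o.fish_species in PREFERENCE_SPECIES]
profiles = [p for p in (ivlev_electivity(o, avail[(o.site, o.year)]) for o in focal)
            if p.total_bites > 0]
pairs = pairs_to_frame(preference_pairs(profiles, avail))
print(pairs.groupby("fish_species").coefficient.mean().round(3).to_dict())
# {'Chaetodon citrinellus': 0.557, 'Chaetodon lunulatus': 0.591,
#  'Chaetodon plebeius': 0.551, 'Chaetodon trifascialis': 0.682}

fit = fit_oibe(pairs, OibeModelSpec(mean_terms=("cover", "species")))
print(round(fit.beta["cover"], 3))   # 1.002  (positive: preferences weaken as cover falls)

matrix = build_resource_matrix(bundle.observations, 2016, min_obs=8)
res = null_model_test(matrix, n_sim=1000, seed=1)
print(round(res.ses, 2), round(res.p_upper, 3))  # 5.05 0.0
```

The hard coral cover falls from 0.52 to 0.17 across the simulated mortality
event; mean Preference Coefficients are highest for the *Acropora*
specialist *C. trifascialis*; the positive cover coefficient on the logit
scale says preference consistency declines with coral loss; and the 2016
resource-use matrix overlaps far more than its RA3 null expectation.

A command-line interface mirrors the library:

```bash
coralforage simulate --seed 1 --out study/
coralforage evenness --foraging study/foraging.csv --benthic study/benthic.csv --out evenness.json
coralforage preference --foraging study/foraging.csv --benthic study/benthic.csv --out pairs.csv
coralforage glmm --pairs pairs.csv --full-model cover+species+site+year --out fit.json
coralforage overlap --foraging study/foraging.csv --year 2016 --nsim 1000 --seed 42 --out overlap.json
coralforage run --config run.yaml
```

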