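"""Synthetic reef-foraging studies with known ground truth.

The generator emulates a three-site, three-year shallow-reef study with a
mass coral-mortality event between the first and second year (~65% loss of
hard coral cover, heaviest in *Acropora*): point-intercept benthic
transects, 3-minute focal-follow foraging observations for several
butterflyfish species, and belt-transect fish counts.

The behavioural ground truth is a species-level genus-preference weight
vector w_s; each individual fish draws its own weights from
Dirichlet(kappa * w_s), where the concentration

    kappa = exp(a + b * hard_coral_cover)

controls among-individual preference consistency.  With b > 0, coral loss
weakens preference consistency — individual diets diverge — which is the
signal the downstream Preference-Coefficient regression is built to detect.
Bites are allocated in proportion to availability x individual weights, so
the preference signal lives in electivity, not raw diet share.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import (
    FOCAL_GENERA,
    AvailabilityProfile,
    BenthicTransect,
    FishBeltTransect,
    ForagingObservation,
    write_benthic_csv,
    write_fish_csv,
    write_foraging_csv,
)

#: Default butterflyfish assemblage (five corallivores).
DEFAULT_FISH_SPECIES = (
    "Chaetodon citrinellus",
    "Chaetodon lunulatus",
    "Chaetodon plebeius",
    "Chaetodon rafflesii",
    "Chaetodon trifascialis",
)

# Genus-preference weights over FOCAL_GENERA order
# (Acropora, Favites, Galaxea, Goniastrea, Montipora, Pocillopora, Porites).
# Chosen so the Acropora specialist takes the large majority of its bites
# from Acropora at baseline availability while the facultative species are
# progressively more even.
DEFAULT_PREF_WEIGHTS: dict[str, tuple[float, ...]] = {
    "Chaetodon trifascialis": (30.0, 1.0, 1.0, 1.0, 3.0, 1.0, 2.0),
    "Chaetodon lunulatus": (6.0, 2.0, 1.5, 1.5, 2.0, 2.0, 4.0),
    "Chaetodon citrinellus": (5.0, 1.5, 1.0, 1.5, 2.0, 3.0, 2.0),
    "Chaetodon plebeius": (1.5, 1.5, 1.0, 2.0, 2.0, 4.0, 3.0),
    "Chaetodon rafflesii": (0.8, 2.0, 2.0, 2.0, 2.0, 2.0, 3.0),
}

# Baseline genus shares of hard-coral cover: Acropora-dominated reef flat.
DEFAULT_GENUS_AVAILABILITY: dict[str, float] = {
    "Acropora": 0.35,
    "Montipora": 0.15,
    "Porites": 0.15,
    "Pocillopora": 0.10,
    "Goniastrea": 0.10,
    "Favites": 0.08,
    "Galaxea": 0.07,
}

# Relative bleaching-mortality susceptibility (Acropora highest).
DEFAULT_MORTALITY_WEIGHTS: dict[str, float] = {
    "Acropora": 8.0,
    "Pocillopora": 3.0,
    "Montipora": 2.0,
    "Goniastrea": 1.0,
    "Favites": 1.0,
    "Galaxea": 1.0,
    "Porites": 0.5,
}

# Within-genus split over three synthetic species codes per genus.
WITHIN_GENUS_SPLIT = (0.5, 0.3, 0.2)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Study design and ground-truth parameters for one synthetic study."""

    n_sites: int = 3
    years: tuple[int, ...] = (2016, 2017, 2018)
    n_transects_per_site: int = 6
    points_per_transect: int = 101
    genera: tuple[str, ...] = FOCAL_GENERA
    pre_cover: float = 0.55
    mortality_fraction: float = 0.65
    genus_mortality_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MORTALITY_WEIGHTS)
    )
    genus_availability_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENUS_AVAILABILITY)
    )
    fish_species: tuple[str, ...] = DEFAULT_FISH_SPECIES
    obs_per_species_site_year: int = 12
    bites_per_obs_mean: float = 24.0
    species_pref_weights: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: dict(DEFAULT_PREF_WEIGHTS)
    )
    kappa_intercept: float = 0.5  # a in kappa = exp(a + b * cover)
    kappa_slope: float = 4.0  # b; > 0 means consistency increases with cover
    one_inflation_target: float | None = None
    fish_per_belt_mean: float = 2.5
    seed: int = 0

    @property
    def sites(self) -> list[str]:
        return [f"site{i + 1}" for i in range(self.n_sites)]

    def validate(self) -> None:
        if not 0 <= self.mortality_fraction < 1:
            raise ConfigError("mortality_fraction must be in [0, 1)")
        if self.pre_cover <= 0 or self.pre_cover > 1:
            raise ConfigError("pre_cover must be in (0, 1]")
        if all(w == 0 for w in self.genus_mortality_weights.values()):
            raise ConfigError("all genus mortality susceptibility weights are zero")
        for sp, w in self.species_pref_weights.items():
            if len(w) != len(self.genera):
                raise ConfigError(f"weight vector for {sp} has wrong length")
            if any(x <= 0 for x in w):
                raise ConfigError(f"weight vector for {sp} must be strictly positive")
        if self.one_inflation_target is not None and not 0 <= self.one_inflation_target < 1:
            raise ConfigError("one_inflation_target must be in [0, 1)")

    def kappa(self, cover: float) -> float:
        return math.exp(self.kappa_intercept + self.kappa_slope * cover)

    def is_post_event(self, year: int) -> bool:
        return year > min(self.years)


def _genus_losses(config: SimulationConfig, shares: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Per-genus loss fractions with aggregate loss = mortality_fraction.

    Losses are proportional to susceptibility weights; genera whose implied
    loss would exceed 1 are capped at total loss and the shortfall is
    redistributed over the remaining genera (water-filling).
    """
    m = config.mortality_fraction
    loss = np.zeros_like(shares)
    active = weights > 0
    remaining = m  # share-weighted loss still to allocate
    for _ in range(len(shares) + 1):
        wbar = float(np.sum(shares[active] * weights[active]))
        if wbar <= 0:
            break
        cand = remaining * weights / wbar
        over = active & (cand >= 1.0)
        if not over.any():
            loss[active] = cand[active]
            break
        loss[over] = 1.0
        remaining -= float(np.sum(shares[over]))
        active = active & ~over
        remaining = max(remaining, 0.0)
    return np.clip(loss, 0.0, 1.0)


def _site_jitter(config: SimulationConfig, site: str) -> float:
    idx = config.sites.index(site)
    return 1.0 + 0.05 * (idx - (config.n_sites - 1) / 2.0)


def true_community_state(config: SimulationConfig, site: str, year: int) -> dict:
    """Expected substrate distribution for a site-year (the ground truth)."""
    genera = list(config.genera)
    base = np.array([config.genus_availability_weights.get(g, 0.0) for g in genera])
    base = base / base.sum()
    cover = min(0.99, config.pre_cover * _site_jitter(config, site))
    genus_cover = cover * base
    dead = 0.0
    if config.is_post_event(year):
        loss = _genus_losses(config, base, np.array(
            [config.genus_mortality_weights.get(g, 0.0) for g in genera]
        ))
        dead = float(np.sum(genus_cover * loss))
        genus_cover = genus_cover * (1.0 - loss)
    # species-level substrate probabilities
    probs: dict[str, float] = {}
    for g, c in zip(genera, genus_cover):
        for k, frac in enumerate(WITHIN_GENUS_SPLIT):
            probs[f"{g} sp{k + 1}"] = c * frac
    noncoral = 1.0 - sum(probs.values())
    live_noncoral = max(noncoral - dead, 0.0)
    probs["dead_coral"] = dead
    probs["sand"] = 0.6 * live_noncoral
    probs["algae"] = 0.4 * live_noncoral
    return {
        "cover": float(genus_cover.sum()),
        "genus_cover": {g: float(c) for g, c in zip(genera, genus_cover)},
        "substrate_probs": probs,
    }


def simulate_community(
    config: SimulationConfig, site: str, year: int, rng: np.random.Generator
) -> tuple[AvailabilityProfile, list[BenthicTransect]]:
    """Draw a site-year's benthic transects; returns the TRUE availability.

    Transect points are i.i.d. draws from the site-year substrate
    distribution; pre-event years have expected hard cover ~ pre_cover and
    post-event years pre_cover * (1 - mortality_fraction), with
    genus-specific losses proportional to susceptibility.
    """
    config.validate()
    state = true_community_state(config, site, year)
    names = list(state["substrate_probs"])
    p = np.array([state["substrate_probs"][n] for n in names])
    p = p / p.sum()
    transects = []
    for t in range(config.n_transects_per_site):
        draws = rng.choice(len(names), size=config.points_per_transect, p=p)
        transects.append(
            BenthicTransect(
                site=site,
                year=year,
                transect_id=f"{site}-{year}-T{t + 1}",
                points=[names[i] for i in draws],
            )
        )
    cover = state["cover"]
    props = (
        {g: c / cover for g, c in state["genus_cover"].items() if c > 0} if cover > 0 else {}
    )
    profile = AvailabilityProfile(
        site=site, year=year, level="genus", proportions=props, hard_coral_cover=cover
    )
    return profile, transects


def _largest_remainder(probs: np.ndarray, total: int) -> np.ndarray:
    """Deterministic integer allocation of ``total`` proportional to probs."""
    quota = probs / probs.sum() * total
    base = np.floor(quota).astype(int)
    short = total - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:short]] += 1
    return base


def simulate_foraging(
    config: SimulationConfig,
    availability: AvailabilityProfile,
    site: str,
    year: int,
    rng: np.random.Generator,
) -> list[ForagingObservation]:
    """Draw one site-year's focal-follow observations for every species.

    Each fish draws individual weights w_ind ~ Dirichlet(kappa * w_s) with
    kappa tied to hard coral cover, takes Poisson-many bites, and allocates
    them multinomially with probabilities proportional to availability x
    individual weights over the genera present.  When
    ``one_inflation_target`` is set, a fraction sqrt(target) of individuals
    are "archetypes" expressing the species' expected diet as a fixed
    deterministic bite vector, so archetype pairs later give a Preference
    Coefficient of exactly 1.
    """
    config.validate()
    genera = list(config.genera)
    genus_avail = availability.genus_proportions()
    p_avail = np.array([genus_avail.get(g, 0.0) for g in genera])
    kappa = config.kappa(availability.hard_coral_cover)
    state = true_community_state(config, site, year)
    observations: list[ForagingObservation] = []
    p_arch = math.sqrt(config.one_inflation_target) if config.one_inflation_target else 0.0
    for sp in config.fish_species:
        w_s = np.asarray(config.species_pref_weights[sp], dtype=float)
        w_s = w_s / w_s.sum()
        for i in range(config.obs_per_species_site_year):
            obs_id = f"{sp.split()[-1][:4]}-{site}-{year}-{i + 1:03d}"
            archetype = p_arch > 0 and rng.random() < p_arch
            if p_avail.sum() <= 0:
                observations.append(
                    ForagingObservation(obs_id, sp, site, year, bites={})
                )
                continue
            if archetype:
                probs = p_avail * w_s
                total = int(round(config.bites_per_obs_mean))
                genus_counts = _largest_remainder(probs, total)
                rng.random()  # keep draw count aligned with the stochastic branch
            else:
                w_ind = rng.dirichlet(kappa * w_s)
                probs = p_avail * w_ind
                if probs.sum() <= 0:
                    probs = p_avail.copy()
                total = int(rng.poisson(config.bites_per_obs_mean))
                genus_counts = (
                    rng.multinomial(total, probs / probs.sum())
                    if total > 0
                    else np.zeros(len(genera), dtype=int)
                )
            bites: dict[str, int] = {}
            for g, n in zip(genera, genus_counts):
                if n == 0:
                    continue
                gc = state["genus_cover"].get(g, 0.0)
                within = np.array(WITHIN_GENUS_SPLIT)
                if archetype:
                    sp_counts = _largest_remainder(within, int(n))
                else:
                    sp_counts = rng.multinomial(int(n), within / within.sum())
                for k, m in enumerate(sp_counts):
                    if m > 0:
                        bites[f"{g} sp{k + 1}"] = int(m)
            observations.append(ForagingObservation(obs_id, sp, site, year, bites=bites))
    return observations


def simulate_fish_counts(
    config: SimulationConfig, site: str, year: int, rng: np.random.Generator
) -> list[FishBeltTransect]:
    """Belt-transect butterflyfish counts (Poisson per species per transect)."""
    lam = config.fish_per_belt_mean
    if year == max(config.years):
        lam *= 0.5  # population decline lagging the mortality event
    out = []
    for t in range(config.n_transects_per_site):
        counts = {sp: int(rng.poisson(lam)) for sp in config.fish_species}
        out.append(
            FishBeltTransect(site, year, f"{site}-{year}-B{t + 1}", counts)
        )
    return out


@dataclass
class StudyBundle:
    """Everything one synthetic study produced, plus its ground truth."""

    config: SimulationConfig
    transects: list[BenthicTransect]
    observations: list[ForagingObservation]
    fish_counts: list[FishBeltTransect]
    true_availabilities: dict[tuple[str, int], AvailabilityProfile]
    truth: dict


def generate_study(config: SimulationConfig) -> StudyBundle:
    """Generate a full study (all sites and years), deterministic per seed.

    Draw order is fixed — sites outer, years inner; community, then
    foraging, then fish counts — so a given (config, seed) always yields
    identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    transects: list[BenthicTransect] = []
    observations: list[ForagingObservation] = []
    fish_counts: list[FishBeltTransect] = []
    avail: dict[tuple[str, int], AvailabilityProfile] = {}
    truth: dict = {
        "kappa_intercept": config.kappa_intercept,
        "kappa_slope": config.kappa_slope,
        "species_pref_weights": {
            sp: list(map(float, w)) for sp, w in config.species_pref_weights.items()
        },
        "site_years": {},
    }
    for site in config.sites:
        for year in config.years:
            profile, tr = simulate_community(config, site, year, rng)
            obs = simulate_foraging(config, profile, site, year, rng)
            fc = simulate_fish_counts(config, site, year, rng)
            transects.extend(tr)
            observations.extend(obs)
            fish_counts.extend(fc)
            avail[(site, year)] = profile
            truth["site_years"][f"{site}|{year}"] = {
                "hard_coral_cover": profile.hard_coral_cover,
                "kappa": config.kappa(profile.hard_coral_cover),
                "genus_proportions": profile.genus_proportions(),
            }
    return StudyBundle(config, transects, observations, fish_counts, avail, truth)


def write_study(bundle: StudyBundle, outdir) -> dict[str, Path]:
    """Write the three CSV tables plus truth.json; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "foraging": outdir / "foraging.csv",
        "benthic": outdir / "benthic.csv",
        "fish_counts": outdir / "fish_counts.csv",
        "truth": outdir / "truth.json",
    }
    write_foraging_csv(bundle.observations, paths["foraging"])
    write_benthic_csv(bundle.transects, paths["benthic"])
    write_fish_csv(bundle.fish_counts, paths["fish_counts"])
    paths["truth"].write_text(json.dumps(bundle.truth, indent=2, sort_keys=True))
    return paths


def simulate_preference_pairs(
    n_groups: int = 6,
    fish_per_group: int = 15,
    beta_intercept: float = 0.0,
    beta_cover: float = 2.0,
    phi: float = 10.0,
    nu: float = 0.1,
    sigma_u: float = 0.3,
    sigma_v: float = 0.3,
    cover_range: tuple[float, float] = (0.1, 0.6),
    species_effects: Mapping[str, float] | None = None,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Draw Preference-Coefficient pairs directly from the regression model.

    Used to test the one-inflated beta mixed model against known truth:
    within each group (a species x site-year cell) all unordered fish pairs
    are formed; logit(mu) = b0 + b1*cover (+ species effect) + u_fish1 +
    v_fish2, the response is Beta(mu*phi, (1-mu)*phi), and with probability
    nu it is replaced by exactly 1.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    species_names = list(species_effects) if species_effects else ["sp1"]
    rows = []
    for g in range(n_groups):
        cover = rng.uniform(*cover_range)
        sp = species_names[g % len(species_names)]
        sp_eff = species_effects[sp] if species_effects else 0.0
        ids = [f"g{g}f{i}" for i in range(fish_per_group)]
        u = rng.normal(0.0, sigma_u, size=fish_per_group)
        v = rng.normal(0.0, sigma_v, size=fish_per_group)
        for i in range(fish_per_group):
            for j in range(i + 1, fish_per_group):
                eta = beta_intercept + beta_cover * cover + sp_eff + u[i] + v[j]
                mu = float(np.clip(expit(eta), 1e-6, 1 - 1e-6))
                if rng.random() < nu:
                    y = 1.0
                else:
                    y = float(rng.beta(mu * phi, (1.0 - mu) * phi))
                    y = min(max(y, 1e-12), 1.0 - 1e-12)
                rows.append(
                    {
                        "fish1_id": ids[i],
                        "fish2_id": ids[j],
                        "fish_species": sp,
                        "site": f"s{(g % 3) + 1}",
                        "year": 2016 + (g // 3) % 3,
                        "coefficient": y,
                        "hard_coral_cover": cover,
                    }
                )
    return pd.DataFrame(rows)
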