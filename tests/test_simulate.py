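import numpy as np
import pytest

from conftest import pairs_from_bundle
from coralforage.io import AvailabilityProfile
from coralforage.simulate import (
    ConfigError,
    SimulationConfig,
    generate_study,
    simulate_community,
    simulate_foraging,
    true_community_state,
    write_study,
)

UNIFORM = {
    sp: tuple([1.0] * 7) for sp in SimulationConfig().fish_species
}


class TestCommunity:
    def test_zero_mortality_leaves_cover_unchanged(self):
        cfg = SimulationConfig(mortality_fraction=0.0)
        pre = true_community_state(cfg, "site2", 2016)
        post = true_community_state(cfg, "site2", 2017)
        assert post["cover"] == pytest.approx(pre["cover"])

    def test_post_event_cover_matches_binomial_expectation(self):
        cfg = SimulationConfig(seed=5)
        rng = np.random.default_rng(5)
        _, transects = simulate_community(cfg, "site2", 2017, rng)
        points = [p for t in transects for p in t.points]
        coral = sum(p[0].isupper() for p in points)
        n = len(points)
        p_true = true_community_state(cfg, "site2", 2017)["cover"]
        assert p_true == pytest.approx(0.55 * 0.35, rel=1e-9)  # pre_cover * (1 - 0.65)
        se = np.sqrt(p_true * (1 - p_true) / n)
        assert abs(coral / n - p_true) < 3 * se

    def test_susceptible_genus_loses_share(self):
        # Acropora 10x more susceptible: its post-event share of coral must
        # drop in expectation (checked over 200 Monte-Carlo replicates)
        weights = {g: 1.0 for g in SimulationConfig().genera}
        weights["Acropora"] = 10.0
        cfg = SimulationConfig(genus_mortality_weights=weights, seed=0)
        rng = np.random.default_rng(0)
        pre_share, post_share = [], []
        for _ in range(200):
            for year, store in ((2016, pre_share), (2017, post_share)):
                _, transects = simulate_community(cfg, "site1", year, rng)
                counts = {}
                for t in transects:
                    for sp, c in t.coral_species_counts().items():
                        counts[sp.split()[0]] = counts.get(sp.split()[0], 0) + c
                total = sum(counts.values())
                store.append(counts.get("Acropora", 0) / total)
        assert np.mean(post_share) < np.mean(pre_share)

    def test_all_zero_susceptibility_rejected(self):
        cfg = SimulationConfig(genus_mortality_weights={g: 0.0 for g in SimulationConfig().genera})
        with pytest.raises(ConfigError):
            simulate_community(cfg, "site1", 2017, np.random.default_rng(0))


class TestForaging:
    def test_uniform_fixed_weights_give_near_zero_electivity(self):
        # kappa enormous + uniform weights: bites track availability, so the
        # mean Ivlev E per genus converges to 0 (law of large numbers);
        # scored against the generator's true availability so that only
        # diet-sampling noise remains
        from coralforage.preference import ivlev_electivity

        cfg = SimulationConfig(
            n_sites=1, years=(2016,), species_pref_weights=UNIFORM,
            kappa_intercept=20.0, kappa_slope=0.0,
            obs_per_species_site_year=40, bites_per_obs_mean=2000.0, seed=3,
        )
        bundle = generate_study(cfg)
        avail = bundle.true_availabilities[("site1", 2016)]
        profiles = [ivlev_electivity(o, avail) for o in bundle.observations]
        for genus in cfg.genera:
            vals = [p.E[genus] for p in profiles if p.E[genus] is not None]
            assert abs(np.mean(vals)) < 0.06

    def test_infinite_consistency_forces_unit_coefficients(self):
        # huge kappa + strictly ordered weights + many bites: every fish of
        # the species shares one electivity ranking, so every pair has y1 = 1
        cfg = SimulationConfig(
            n_sites=1, years=(2016,),
            fish_species=("Chaetodon trifascialis",),
            species_pref_weights={"Chaetodon trifascialis": (7, 6, 5, 4, 3, 2, 1)},
            kappa_intercept=30.0, kappa_slope=0.0,
            obs_per_species_site_year=8, bites_per_obs_mean=3000.0, seed=1,
        )
        df = pairs_from_bundle(generate_study(cfg))
        assert len(df) == 28
        assert (df["coefficient"] == 1.0).all()

    def test_small_kappa_uniform_weights_mean_near_half(self):
        # kappa = 0.5 and no shared ranking: mean Preference Coefficient ~ 0.5
        cfg = SimulationConfig(
            n_sites=1, years=(2016,), species_pref_weights=UNIFORM,
            kappa_intercept=np.log(0.5), kappa_slope=0.0,
            obs_per_species_site_year=12, seed=8,
        )
        df = pairs_from_bundle(generate_study(cfg))
        assert len(df) >= 200
        assert abs(df["coefficient"].mean() - 0.5) < 0.05

    def test_no_available_genera_gives_zero_bite_observation(self):
        cfg = SimulationConfig()
        empty = AvailabilityProfile("site1", 2016, "genus", {}, 0.0)
        obs = simulate_foraging(cfg, empty, "site1", 2016, np.random.default_rng(0))
        assert all(o.total_bites == 0 for o in obs)

    def test_archetype_individuals_create_exact_ones(self):
        cfg = SimulationConfig(
            n_sites=1, years=(2016,), one_inflation_target=0.25,
            obs_per_species_site_year=12, seed=4,
        )
        df = pairs_from_bundle(generate_study(cfg))
        assert (df["coefficient"] == 1.0).mean() > 0.10


def test_null_generator_drops_cover_by_aic():
    """With no cover-linked consistency signal, model selection removes cover.

    The no-preference null is uniform species weights with kappa_slope = 0;
    cover should be eliminated in the majority of replicate studies.
    """
    from coralforage.glmm import OibeModelSpec, backward_aic_select

    dropped = 0
    for seed in (21, 22, 23):
        cfg = SimulationConfig(
            n_sites=2, obs_per_species_site_year=8, seed=seed,
            kappa_slope=0.0, species_pref_weights=UNIFORM,
        )
        df = pairs_from_bundle(generate_study(cfg))
        final, _ = backward_aic_select(df, OibeModelSpec(mean_terms=("cover", "species")))
        dropped += "cover" not in final.spec.mean_terms
    assert dropped >= 2


class TestGenerateStudy:
    def test_default_design_arithmetic(self):
        cfg = SimulationConfig()
        bundle = generate_study(cfg)
        assert len(bundle.transects) == 3 * 3 * 6
        assert len(bundle.observations) == 3 * 3 * 5 * cfg.obs_per_species_site_year

    def test_same_seed_byte_identical(self, tmp_path):
        cfg = SimulationConfig(n_sites=2, n_transects_per_site=2,
                               obs_per_species_site_year=3, seed=99)
        p1 = write_study(generate_study(cfg), tmp_path / "a")
        p2 = write_study(generate_study(cfg), tmp_path / "b")
        for key in ("foraging", "benthic", "fish_counts", "truth"):
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_different_seed_changes_bites(self, tmp_path):
        cfg1 = SimulationConfig(n_sites=1, obs_per_species_site_year=3, seed=1)
        cfg2 = SimulationConfig(n_sites=1, obs_per_species_site_year=3, seed=2)
        b1, b2 = generate_study(cfg1), generate_study(cfg2)
        assert [o.bites for o in b1.observations] != [o.bites for o in b2.observations]

    def test_truth_records_kappa_per_site_year(self, small_study):
        truth = small_study.truth["site_years"]
        assert len(truth) == 2 * 3
        for rec in truth.values():
            assert rec["kappa"] == pytest.approx(
                np.exp(0.5 + 4.0 * rec["hard_coral_cover"])
            )
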