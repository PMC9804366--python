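import pytest

from coralforage import preference as pref
from coralforage.io import availability_proportions
from coralforage.simulate import SimulationConfig, generate_study


@pytest.fixture(scope="session")
def small_config():
    """A reduced study design that keeps every pipeline stage exercised."""
    return SimulationConfig(
        n_sites=2, n_transects_per_site=3, obs_per_species_site_year=6, seed=42
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config)


def pairs_from_bundle(bundle):
    """Electivity profiles and Preference-Coefficient pairs for a study."""
    site_years = sorted({(t.site, t.year) for t in bundle.transects})
    avail = {sy: availability_proportions(bundle.transects, *sy) for sy in site_years}
    focal = [o for o in bundle.observations if o.fish_species in pref.PREFERENCE_SPECIES]
    profiles = [
        p
        for p in (pref.ivlev_electivity(o, avail[(o.site, o.year)]) for o in focal)
        if p.total_bites > 0
    ]
    return pref.pairs_to_frame(pref.preference_pairs(profiles, avail))


@pytest.fixture(scope="session")
def small_pairs(small_study):
    return pairs_from_bundle(small_study)
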