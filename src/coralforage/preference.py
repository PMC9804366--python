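"""Ivlev electivity per fish and the pairwise Preference Coefficient dataset.

Electivity for genus i contrasts the diet share r_i (proportion of a fish's
bites) with the availability share p_i (proportion of coral cover):

    E_i = (r_i - p_i) / (r_i + p_i),

ranging from -1 (complete avoidance) through 0 (feeding in proportion to
availability) to +1 (exclusive selection).  Both r and p are renormalised
over the focal genera so they share a support.

The strength of a species' dietary preferences is measured by how
consistently its individuals rank the focal genera: each within-species,
within-site-year pair of fish is compared by Spearman rank correlation of
their electivity values, rescaled to y1 = (rho + 1) / 2 in [0, 1] (the
"Preference Coefficient": 1 = identical preference order, 0.5 = no
consistent order, 0 = opposite order).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import FOCAL_GENERA, AvailabilityProfile, ForagingObservation

logger = logging.getLogger(__name__)

#: Fish species entering the preference (diet-plasticity) analysis.
PREFERENCE_SPECIES = (
    "Chaetodon citrinellus",
    "Chaetodon lunulatus",
    "Chaetodon plebeius",
    "Chaetodon trifascialis",
)


@dataclass
class ElectivityProfile:
    """One fish's Ivlev E values over the focal genera.

    ``E[genus]`` is None when undefined (genus absent from the site-year's
    transects: a +1 from a sampling zero would dominate rankings, so such
    genera are excluded from comparisons instead).
    """

    obs_id: str
    fish_species: str
    site: str
    year: int
    E: dict[str, float | None]
    total_bites: int

    def defined_genera(self) -> list[str]:
        return [g for g, e in self.E.items() if e is not None]


@dataclass
class PreferencePair:
    """One within-species pairwise preference comparison."""

    fish1_id: str
    fish2_id: str
    fish_species: str
    site: str
    year: int
    rho: float  # y0 in [-1, 1]
    coefficient: float  # y1 = (y0 + 1) / 2 in [0, 1]
    hard_coral_cover: float
    n_shared_genera: int


def ivlev_electivity(
    obs: ForagingObservation,
    availability: AvailabilityProfile,
    genera: Sequence[str] = FOCAL_GENERA,
) -> ElectivityProfile:
    """Ivlev electivity profile of one observation over the listed genera.

    Diet shares r_i are computed over bites on the listed genera only;
    availability shares p_i are the genus proportions of coral cover
    renormalised over the listed genera.  E_i is undefined (None) when
    p_i = 0, which also covers the 0/0 case r_i + p_i = 0.
    """
    genus_bites = obs.bites_by_genus()
    r_raw = {g: genus_bites.get(g, 0) for g in genera}
    r_tot = sum(r_raw.values())
    avail = availability.genus_proportions()
    p_raw = {g: avail.get(g, 0.0) for g in genera}
    p_tot = sum(p_raw.values())
    E: dict[str, float | None] = {}
    for g in genera:
        p = p_raw[g] / p_tot if p_tot > 0 else 0.0
        if p <= 0 or r_tot == 0:
            E[g] = None
            continue
        r = r_raw[g] / r_tot
        E[g] = (r - p) / (r + p)
    if r_tot == 0:
        logger.warning("obs %s has no bites on listed genera; profile undefined", obs.obs_id)
    return ElectivityProfile(
        obs_id=obs.obs_id,
        fish_species=obs.fish_species,
        site=obs.site,
        year=obs.year,
        E=E,
        total_bites=int(r_tot),
    )


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks).

    Requires length >= 3 and neither vector constant; otherwise the
    statistic is undefined and a ValueError is raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("spearman_rho requires at least 3 points")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("spearman_rho undefined for a constant vector")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def preference_pairs(
    profiles: Iterable[ElectivityProfile],
    availabilities: Mapping[tuple[str, int], AvailabilityProfile] | Sequence[AvailabilityProfile],
    min_shared_genera: int = 3,
) -> list[PreferencePair]:
    """All unordered within-species, within-site-year pairwise comparisons.

    rho is computed over the genera whose electivity is defined in BOTH
    profiles; a pair is dropped (logged) when fewer than
    ``min_shared_genera`` genera are shared or either electivity vector is
    constant over them.  Site-level hard coral cover is attached from the
    pair's site-year availability profile.
    """
    if not isinstance(availabilities, Mapping):
        availabilities = {(a.site, a.year): a for a in availabilities}
    groups: dict[tuple[str, str, int], list[ElectivityProfile]] = {}
    for pr in profiles:
        groups.setdefault((pr.fish_species, pr.site, pr.year), []).append(pr)
    pairs: list[PreferencePair] = []
    n_dropped = 0
    for (sp, site, year), members in groups.items():
        cover = availabilities[(site, year)].hard_coral_cover
        for a, b in combinations(members, 2):
            shared = [g for g in a.E if a.E[g] is not None and b.E.get(g) is not None]
            if len(shared) < min_shared_genera:
                n_dropped += 1
                continue
            xa = [a.E[g] for g in shared]
            xb = [b.E[g] for g in shared]
            try:
                rho = spearman_rho(xa, xb)
            except ValueError:
                n_dropped += 1
                continue
            pairs.append(
                PreferencePair(
                    fish1_id=a.obs_id,
                    fish2_id=b.obs_id,
                    fish_species=sp,
                    site=site,
                    year=year,
                    rho=rho,
                    coefficient=(rho + 1.0) / 2.0,
                    hard_coral_cover=cover,
                    n_shared_genera=len(shared),
                )
            )
    if n_dropped:
        logger.info("preference_pairs: dropped %d degenerate pairs", n_dropped)
    return pairs


def pairs_to_frame(pairs: Sequence[PreferencePair]) -> pd.DataFrame:
    """Preference pairs as a DataFrame (the GLMM's input format)."""
    return pd.DataFrame(
        {
            "fish1_id": [p.fish1_id for p in pairs],
            "fish2_id": [p.fish2_id for p in pairs],
            "fish_species": [p.fish_species for p in pairs],
            "site": [p.site for p in pairs],
            "year": [p.year for p in pairs],
            "rho": [p.rho for p in pairs],
            "coefficient": [p.coefficient for p in pairs],
            "hard_coral_cover": [p.hard_coral_cover for p in pairs],
            "n_shared_genera": [p.n_shared_genera for p in pairs],
        }
    )


def diet_proportions(
    observations: Iterable[ForagingObservation],
    taxon_level: str = "genus",
    group_by: Sequence[str] = ("fish_species", "year"),
) -> pd.DataFrame:
    """Bite totals and diet shares per group over all coral taxa bitten.

    The denominator is the group's total coral bites.  ``percent`` is the
    full-precision share x 100; ``percent_rounded`` rounds half away from
    zero to the nearest integer, the common print convention.
    """
    rows = []
    for o in observations:
        source = o.bites_by_genus() if taxon_level == "genus" else o.bites
        meta = {k: getattr(o, k) for k in group_by}
        for taxon, n in source.items():
            rows.append({**meta, "taxon": taxon, "bites": n})
    if not rows:
        return pd.DataFrame(columns=[*group_by, "taxon", "bites", "proportion"])
    df = pd.DataFrame(rows)
    df = df.groupby([*group_by, "taxon"], as_index=False)["bites"].sum()
    totals = df.groupby(list(group_by))["bites"].transform("sum")
    df["total_bites"] = totals
    df["proportion"] = df["bites"] / totals
    df["percent"] = 100.0 * df["proportion"]
    df["percent_rounded"] = np.floor(df["percent"] + 0.5).astype(int)
    return df
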