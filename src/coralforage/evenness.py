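"""Hurlbert PIE evenness for coral assemblages and fish diets.

Hurlbert's Probability of Interspecific Encounter,

    PIE = (N / (N - 1)) * (1 - sum_i (n_i / N)^2),

is the probability that two individuals drawn without replacement belong to
different species.  It is computed per benthic transect (coral assemblage
evenness) and per fish species x site x year from summed diets (dietary
evenness), then compared across years with a Kruskal-Wallis test and Dunn's
post-hoc pairwise tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io import BenthicTransect, ForagingObservation

logger = logging.getLogger(__name__)


class UndefinedResult(ValueError):
    """Raised when a statistic is undefined for the given input."""


@dataclass
class PieRecord:
    """One evenness value: a transect, or a species-site diet, in one year."""

    unit_id: str
    year: int
    pie: float
    n_individuals: int
    n_species: int


def hurlbert_pie(counts: Mapping[str, int]) -> float:
    """Hurlbert PIE of a count vector; undefined (raises) when N < 2."""
    n = np.asarray([c for c in counts.values() if c > 0], dtype=float)
    total = n.sum()
    if total < 2:
        raise UndefinedResult(f"PIE undefined for N={int(total)} < 2")
    p = n / total
    return float(total / (total - 1.0) * (1.0 - np.sum(p**2)))


def coral_pie_by_transect(transects: Iterable[BenthicTransect]) -> list[PieRecord]:
    """Per-transect PIE of hard-coral point counts at coral-species level.

    Non-coral points are excluded; transects with fewer than two coral
    points are dropped with a warning.
    """
    out = []
    for t in transects:
        counts = t.coral_species_counts()
        try:
            pie = hurlbert_pie(counts)
        except UndefinedResult:
            logger.warning(
                "transect %s (%s %s) dropped: <2 coral points", t.transect_id, t.site, t.year
            )
            continue
        out.append(
            PieRecord(
                unit_id=t.transect_id,
                year=t.year,
                pie=pie,
                n_individuals=int(sum(counts.values())),
                n_species=len(counts),
            )
        )
    return out


def diet_pie_by_species_site(
    observations: Iterable[ForagingObservation],
    species_whitelist: Sequence[str],
) -> list[PieRecord]:
    """Diet PIE per fish species x site x year from summed bite counts.

    Individual follows record too few prey taxa for a stable PIE, so bites
    are pooled over all individuals of a species at a site in a year, at
    coral-species level.  Species outside the whitelist are ignored; pooled
    diets with fewer than two bites are dropped.
    """
    whitelist = set(species_whitelist)
    pooled: dict[tuple[str, str, int], dict[str, int]] = {}
    for o in observations:
        if o.fish_species not in whitelist:
            continue
        key = (o.fish_species, o.site, o.year)
        d = pooled.setdefault(key, {})
        for taxon, n in o.bites.items():
            d[taxon] = d.get(taxon, 0) + n
    out = []
    for (sp, site, year), counts in pooled.items():
        try:
            pie = hurlbert_pie(counts)
        except UndefinedResult:
            logger.warning("diet %s @ %s %s dropped: <2 bites", sp, site, year)
            continue
        out.append(
            PieRecord(
                unit_id=f"{sp}|{site}",
                year=year,
                pie=pie,
                n_individuals=int(sum(counts.values())),
                n_species=len([c for c in counts.values() if c > 0]),
            )
        )
    return out


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p (df = k - 1).

    The all-ties degenerate input (every value identical) is defined as
    H = 0, p = 1: there is no evidence of separation, while the usual tie
    correction would produce 0/0.
    """
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs at least two non-empty groups")
    df = len(groups) - 1
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, df, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), df, float(p)


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    holm: bool = False,
) -> list[dict]:
    """Dunn's post-hoc z tests on pooled ranks after a Kruskal-Wallis test.

    For groups i, j with mean pooled mid-ranks Rbar:

        z_ij = (Rbar_i - Rbar_j) / sqrt(V * (1/n_i + 1/n_j)),
        V = N(N+1)/12 - sum(t^3 - t) / (12 (N-1)),

    where t are tie-group sizes in the pooled sample.  Both one-sided normal
    tail probabilities are reported (the tail convention for a signed z is a
    reporting choice, so ``p_upper`` = P(Z >= z), ``p_lower`` = P(Z <= z),
    and ``p_one_sided`` = min of the two).  ``holm=True`` additionally
    Holm-adjusts the one-sided p across pairs.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if sum(len(a) > 0 for a in arrays) < 2:
        raise ValueError("dunn_posthoc needs at least two non-empty groups")
    if labels is None:
        labels = [str(i) for i in range(len(arrays))]
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    # split ranks back into groups
    mean_ranks, sizes = [], []
    start = 0
    for a in arrays:
        r = ranks[start : start + len(a)]
        start += len(a)
        sizes.append(len(a))
        mean_ranks.append(r.mean() if len(a) else np.nan)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    variance = n_total * (n_total + 1) / 12.0 - tie_term
    results = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            if sizes[i] == 0 or sizes[j] == 0:
                continue
            se = np.sqrt(variance * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            p_upper = float(stats.norm.sf(z))
            p_lower = float(stats.norm.cdf(z))
            results.append(
                {
                    "pair": (labels[i], labels[j]),
                    "z": float(z),
                    "p_upper": p_upper,
                    "p_lower": p_lower,
                    "p_one_sided": min(p_upper, p_lower),
                }
            )
    if holm:
        ps = np.array([r["p_one_sided"] for r in results])
        order = np.argsort(ps)
        m = len(ps)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * ps[idx])
            adj[idx] = min(1.0, running)
        for r, a in zip(results, adj):
            r["p_holm"] = float(a)
    return results


def pie_year_comparison(records: Sequence[PieRecord]) -> dict:
    """Kruskal-Wallis across years plus Dunn pairwise tests on PIE records."""
    years = sorted({r.year for r in records})
    groups = [[r.pie for r in records if r.year == y] for y in years]
    h, df, p = kruskal_wallis(groups)
    dunn = dunn_posthoc(groups, labels=[str(y) for y in years])
    return {"years": years, "H": h, "df": df, "p": p, "dunn": dunn}
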