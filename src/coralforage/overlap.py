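"""Pianka niche overlap with RA3 randomization null models.

The resource-use matrix lists forager species (rows) against coral genera
(columns); entries are total bites.  With rows normalised to proportions
p_ij, pairwise Pianka overlap between consumers j and k is

    O_jk = sum_i p_ij p_ik / sqrt( sum_i p_ij^2 * sum_i p_ik^2 ),

and the community statistic is the mean over all unordered row pairs.  The
RA3 null model permutes each row's entries (zeros included) uniformly across
columns, preserving every consumer's niche breadth and total use while
letting column totals fluctuate; the observed mean overlap is compared with
the null distribution via a standardized effect size
SES = (obs - mean(null)) / sd(null) and tail proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io import FOCAL_GENERA, ForagingObservation

#: Fish species entering the resource-overlap analysis.
OVERLAP_SPECIES = (
    "Chaetodon citrinellus",
    "Chaetodon lunulatus",
    "Chaetodon plebeius",
    "Chaetodon rafflesii",
    "Chaetodon trifascialis",
)


@dataclass
class ResourceUseMatrix:
    """Forager-species x coral-genus bite totals for one year."""

    species: list[str]
    genera: list[str]
    counts: np.ndarray  # shape (n_species, n_genera), non-negative ints
    year: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValueError("bite counts must be non-negative")
        if self.counts.shape != (len(self.species), len(self.genera)):
            raise ValueError("counts shape does not match row/column labels")
        if (self.counts.sum(axis=1) == 0).any():
            raise ValueError("all-zero rows are not allowed; exclude the species first")

    def row_proportions(self) -> np.ndarray:
        c = self.counts.astype(float)
        return c / c.sum(axis=1, keepdims=True)


@dataclass
class NullModelResult:
    """Observed mean Pianka overlap against its RA3 null distribution."""

    observed: float
    null_values: np.ndarray
    ses: float
    p_lower: float
    p_upper: float
    p_two_tailed: float
    n_sim: int
    seed: int | None = None
    year: int | None = None


def build_resource_matrix(
    observations: Iterable[ForagingObservation],
    year: int,
    min_obs: int = 8,
    genera: Sequence[str] = FOCAL_GENERA,
    species: Sequence[str] | None = None,
) -> ResourceUseMatrix:
    """Genus-level bite-sum matrix for one year.

    A species qualifies only if it has at least ``min_obs`` observations in
    EVERY year present in the data (consistent sampling across the whole
    study); ``species`` optionally restricts the candidate set first.
    """
    observations = list(observations)
    if species is not None:
        observations = [o for o in observations if o.fish_species in set(species)]
    years = sorted({o.year for o in observations})
    if year not in years:
        raise ValueError(f"no observations for year {year}")
    n_obs: dict[tuple[str, int], int] = {}
    for o in observations:
        n_obs[(o.fish_species, o.year)] = n_obs.get((o.fish_species, o.year), 0) + 1
    all_species = sorted({o.fish_species for o in observations})
    qualifying = [
        sp for sp in all_species if all(n_obs.get((sp, y), 0) >= min_obs for y in years)
    ]
    counts = np.zeros((len(qualifying), len(genera)), dtype=int)
    idx = {sp: i for i, sp in enumerate(qualifying)}
    gidx = {g: j for j, g in enumerate(genera)}
    for o in observations:
        if o.year != year or o.fish_species not in idx:
            continue
        for g, n in o.bites_by_genus().items():
            if g in gidx:
                counts[idx[o.fish_species], gidx[g]] += n
    nonzero = counts.sum(axis=1) > 0
    qualifying = [sp for sp, keep in zip(qualifying, nonzero) if keep]
    counts = counts[nonzero]
    if len(qualifying) == 0:
        raise ValueError(
            f"no species with >= {min_obs} observations in every year (years={years})"
        )
    return ResourceUseMatrix(species=qualifying, genera=list(genera), counts=counts, year=year)


def pianka_pairwise(matrix: np.ndarray) -> np.ndarray:
    """Pairwise Pianka overlap of the rows of a (row-normalised) matrix."""
    p = np.asarray(matrix, dtype=float)
    p = p / p.sum(axis=1, keepdims=True)
    num = p @ p.T
    norms = np.sqrt(np.sum(p**2, axis=1))
    return num / np.outer(norms, norms)


def pianka_mean_overlap(matrix) -> float:
    """Mean pairwise Pianka overlap over all unordered row pairs."""
    counts = matrix.counts if isinstance(matrix, ResourceUseMatrix) else np.asarray(matrix)
    if counts.shape[0] < 2:
        raise ValueError("mean overlap needs at least two consumer rows")
    o = pianka_pairwise(counts)
    iu = np.triu_indices(counts.shape[0], k=1)
    return float(o[iu].mean())


def ra3_randomize(matrix: ResourceUseMatrix, rng: np.random.Generator) -> ResourceUseMatrix:
    """One RA3 draw: permute each row's entries (zeros included) across columns."""
    counts = np.stack([rng.permutation(row) for row in matrix.counts])
    return ResourceUseMatrix(
        species=list(matrix.species), genera=list(matrix.genera), counts=counts, year=matrix.year
    )


def _ra3_null_overlaps(counts: np.ndarray, n_sim: int, rng: np.random.Generator) -> np.ndarray:
    """Vectorised mean Pianka overlap of ``n_sim`` RA3 draws."""
    r, c = counts.shape
    keys = rng.random((n_sim, r, c))
    perms = np.argsort(keys, axis=2)
    draws = np.take_along_axis(np.broadcast_to(counts, (n_sim, r, c)), perms, axis=2)
    p = draws / draws.sum(axis=2, keepdims=True)
    num = np.einsum("sik,sjk->sij", p, p)
    norms = np.sqrt(np.sum(p**2, axis=2))
    o = num / (norms[:, :, None] * norms[:, None, :])
    iu = np.triu_indices(r, k=1)
    return o[:, iu[0], iu[1]].mean(axis=1)


def null_model_test(
    matrix: ResourceUseMatrix,
    n_sim: int = 1000,
    seed: int | np.random.Generator | None = None,
    continuity: bool = False,
) -> NullModelResult:
    """RA3 null-model test of mean Pianka overlap.

    ``p_upper`` is the proportion of null draws >= the observed value (one
    tail toward stronger-than-random overlap), ``p_lower`` the proportion
    <=; ties count toward both tails, and the two-tailed p is
    2 min(p_lower, p_upper) capped at 1.  ``continuity=True`` uses the
    (k + 1)/(n + 1) form instead of strict counting.  SES is NaN when the
    null distribution is degenerate (sd = 0).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = pianka_mean_overlap(matrix)
    null = _ra3_null_overlaps(matrix.counts, n_sim, rng)
    sd = null.std(ddof=1)
    ses = float((observed - null.mean()) / sd) if sd > 0 else float("nan")
    k_up = int(np.sum(null >= observed))
    k_lo = int(np.sum(null <= observed))
    if continuity:
        p_upper = (k_up + 1) / (n_sim + 1)
        p_lower = (k_lo + 1) / (n_sim + 1)
    else:
        p_upper = k_up / n_sim
        p_lower = k_lo / n_sim
    return NullModelResult(
        observed=observed,
        null_values=null,
        ses=ses,
        p_lower=float(p_lower),
        p_upper=float(p_upper),
        p_two_tailed=float(min(1.0, 2.0 * min(p_lower, p_upper))),
        n_sim=n_sim,
        seed=seed if isinstance(seed, int) else None,
        year=matrix.year,
    )
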