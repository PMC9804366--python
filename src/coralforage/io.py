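"""Domain types and CSV readers/writers for foraging-study tables.

Three input tables are supported, all UTF-8 comma-separated with a header row:

* foraging observations (long format): one row per coral taxon bitten during
  a timed focal follow, columns ``obs_id, fish_species, site, year,
  coral_taxon, bites`` (optional ``date, time, weather, duration_min``);
* benthic point-intercept transects: columns ``site, year, transect_id,
  point_index, substrate``;
* belt-transect fish counts: columns ``site, year, transect_id,
  fish_species, count``.

Coral taxa are written ``"Genus"`` or ``"Genus epithet"`` (whitespace
separated, genus capitalised); non-coral substrate categories are lowercase
codes such as ``"sand"``, ``"algae"`` or ``"dead_coral"``.
"""

from __future__ import annotations

import dataclasses
import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

SCHEMA_VERSION = "1"

#: The seven focal coral genera used for electivity and overlap analyses.
FOCAL_GENERA = (
    "Acropora",
    "Favites",
    "Galaxea",
    "Goniastrea",
    "Montipora",
    "Pocillopora",
    "Porites",
)


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """A row violates a table invariant (e.g. negative bite count)."""


def is_coral(substrate: str) -> bool:
    """True if a substrate code denotes a hard-coral taxon.

    Coral codes start with a capitalised genus token; non-coral categories
    (``sand``, ``algae``, ``dead_coral`` ...) are lowercase.
    """
    s = substrate.strip()
    return bool(s) and s[0].isupper() and s.split()[0].isalpha()


def genus_of(taxon: str) -> str:
    """Genus = first whitespace token of a coral taxon code."""
    return taxon.strip().split()[0]


@dataclass
class ForagingObservation:
    """Bite counts by coral taxon recorded during one timed focal follow."""

    obs_id: str
    fish_species: str
    site: str
    year: int
    bites: dict[str, int] = field(default_factory=dict)
    duration_min: float = 3.0
    date: str | None = None
    time: str | None = None
    weather: str | None = None

    def __post_init__(self) -> None:
        for taxon, n in self.bites.items():
            if n < 0:
                raise ValidationError(
                    f"negative bite count {n} for taxon {taxon!r} in obs {self.obs_id!r}"
                )

    @property
    def total_bites(self) -> int:
        return int(sum(self.bites.values()))

    def bites_by_genus(self) -> dict[str, int]:
        out: dict[str, int] = defaultdict(int)
        for taxon, n in self.bites.items():
            out[genus_of(taxon)] += n
        return dict(out)


@dataclass
class BenthicTransect:
    """Ordered point-intercept substrate records along one transect."""

    site: str
    year: int
    transect_id: str
    points: list[str]

    def __post_init__(self) -> None:
        if len(self.points) < 1:
            raise ValidationError(
                f"transect {self.transect_id!r} has no points"
            )

    def coral_species_counts(self) -> dict[str, int]:
        out: dict[str, int] = defaultdict(int)
        for p in self.points:
            if is_coral(p):
                out[p.strip()] += 1
        return dict(out)


@dataclass
class FishBeltTransect:
    """Belt-transect counts of fish per species."""

    site: str
    year: int
    transect_id: str
    counts: dict[str, int]

    def __post_init__(self) -> None:
        for sp, n in self.counts.items():
            if n < 0:
                raise ValidationError(f"negative count for {sp!r}")


@dataclass
class AvailabilityProfile:
    """Relative hard-coral availability for one site-year.

    ``proportions`` sum to 1 over hard-coral taxa (empty when no coral was
    recorded); ``hard_coral_cover`` is coral points / all points, pooled
    over the site-year's transects.
    """

    site: str
    year: int
    level: str  # "genus" or "species"
    proportions: dict[str, float]
    hard_coral_cover: float

    def genus_proportions(self) -> dict[str, float]:
        if self.level == "genus":
            return dict(self.proportions)
        out: dict[str, float] = defaultdict(float)
        for taxon, p in self.proportions.items():
            out[genus_of(taxon)] += p
        return dict(out)


# ---------------------------------------------------------------------------
# readers


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")


def read_foraging_csv(path) -> list[ForagingObservation]:
    """Read a long-format foraging table, grouping rows by ``obs_id``."""
    df = pd.read_csv(path, dtype={"obs_id": str})
    mandatory = ["obs_id", "fish_species", "site", "year", "coral_taxon", "bites"]
    _require_columns(df, mandatory, path)
    obs: dict[str, ForagingObservation] = {}
    for idx, row in df.iterrows():
        n = int(row["bites"])
        if n < 0:
            raise ValidationError(f"{path}: negative bites at row {idx + 2}")
        taxon = str(row["coral_taxon"]).strip()
        oid = str(row["obs_id"])
        if oid not in obs:
            obs[oid] = ForagingObservation(
                obs_id=oid,
                fish_species=str(row["fish_species"]).strip(),
                site=str(row["site"]).strip(),
                year=int(row["year"]),
                bites={},
                duration_min=float(row.get("duration_min", 3.0))
                if "duration_min" in df.columns
                else 3.0,
                date=str(row["date"]) if "date" in df.columns and pd.notna(row["date"]) else None,
                time=str(row["time"]) if "time" in df.columns and pd.notna(row["time"]) else None,
                weather=str(row["weather"])
                if "weather" in df.columns and pd.notna(row["weather"])
                else None,
            )
        obs[oid].bites[taxon] = obs[oid].bites.get(taxon, 0) + n
    return list(obs.values())


def read_benthic_csv(path) -> list[BenthicTransect]:
    """Read point-intercept transects; points ordered by ``point_index``."""
    df = pd.read_csv(path)
    _require_columns(df, ["site", "year", "transect_id", "point_index", "substrate"], path)
    transects: list[BenthicTransect] = []
    for (site, year, tid), grp in df.groupby(["site", "year", "transect_id"], sort=False):
        if grp["point_index"].duplicated().any():
            dup = grp.loc[grp["point_index"].duplicated(), "point_index"].iloc[0]
            raise ValidationError(
                f"{path}: duplicate point_index {dup} in transect {tid!r}"
            )
        grp = grp.sort_values("point_index")
        transects.append(
            BenthicTransect(
                site=str(site),
                year=int(year),
                transect_id=str(tid),
                points=[str(s).strip() for s in grp["substrate"]],
            )
        )
    return transects


def read_fish_csv(path) -> list[FishBeltTransect]:
    """Read belt-transect fish counts."""
    df = pd.read_csv(path)
    _require_columns(df, ["site", "year", "transect_id", "fish_species", "count"], path)
    out: list[FishBeltTransect] = []
    for (site, year, tid), grp in df.groupby(["site", "year", "transect_id"], sort=False):
        counts = {}
        for _, row in grp.iterrows():
            n = int(row["count"])
            if n < 0:
                raise ValidationError(f"{path}: negative count for {row['fish_species']!r}")
            counts[str(row["fish_species"]).strip()] = n
        out.append(FishBeltTransect(str(site), int(year), str(tid), counts))
    return out


# ---------------------------------------------------------------------------
# writers (inverse of the readers; round-trip safe)


def write_foraging_csv(observations: Iterable[ForagingObservation], path) -> None:
    rows = []
    for o in observations:
        for taxon in sorted(o.bites):
            rows.append(
                {
                    "obs_id": o.obs_id,
                    "fish_species": o.fish_species,
                    "site": o.site,
                    "year": o.year,
                    "coral_taxon": taxon,
                    "bites": o.bites[taxon],
                    "duration_min": o.duration_min,
                }
            )
    pd.DataFrame(
        rows,
        columns=["obs_id", "fish_species", "site", "year", "coral_taxon", "bites", "duration_min"],
    ).to_csv(path, index=False)


def write_benthic_csv(transects: Iterable[BenthicTransect], path) -> None:
    rows = []
    for t in transects:
        for i, s in enumerate(t.points):
            rows.append(
                {
                    "site": t.site,
                    "year": t.year,
                    "transect_id": t.transect_id,
                    "point_index": i,
                    "substrate": s,
                }
            )
    pd.DataFrame(
        rows, columns=["site", "year", "transect_id", "point_index", "substrate"]
    ).to_csv(path, index=False)


def write_fish_csv(transects: Iterable[FishBeltTransect], path) -> None:
    rows = []
    for t in transects:
        for sp in sorted(t.counts):
            rows.append(
                {
                    "site": t.site,
                    "year": t.year,
                    "transect_id": t.transect_id,
                    "fish_species": sp,
                    "count": t.counts[sp],
                }
            )
    pd.DataFrame(
        rows, columns=["site", "year", "transect_id", "fish_species", "count"]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# availability


def availability_proportions(
    transects: Sequence[BenthicTransect],
    site: str,
    year: int,
    level: str = "species",
) -> AvailabilityProfile:
    """Pool a site-year's transect points into a coral availability profile.

    Proportions are taken over hard-coral taxa only; ``hard_coral_cover`` is
    the coral fraction of all points.  A site-year with no coral points
    yields an empty profile with cover 0 (not an error).
    """
    if level not in ("species", "genus"):
        raise ValueError(f"level must be 'species' or 'genus', got {level!r}")
    pool = [t for t in transects if t.site == site and t.year == year]
    if not pool:
        raise ValueError(f"no transects for site {site!r}, year {year}")
    counts: dict[str, int] = defaultdict(int)
    total = 0
    coral = 0
    for t in pool:
        for p in t.points:
            total += 1
            if is_coral(p):
                coral += 1
                key = genus_of(p) if level == "genus" else p.strip()
                counts[key] += 1
    props = {k: v / coral for k, v in counts.items()} if coral else {}
    return AvailabilityProfile(
        site=site,
        year=year,
        level=level,
        proportions=props,
        hard_coral_cover=coral / total if total else 0.0,
    )


# ---------------------------------------------------------------------------
# JSON serialisation for result objects


def to_jsonable(obj):
    """Recursively convert dataclasses / numpy scalars to JSON-friendly types."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if hasattr(obj, "item") and not isinstance(obj, (str, bytes)):
        try:
            return obj.item()
        except Exception:
            pass
    return obj


def write_result_json(obj, path) -> None:
    """Serialise any result object to JSON with a ``schema_version`` field."""
    payload = {"schema_version": SCHEMA_VERSION, "result": to_jsonable(obj)}
    Path(path).write_text(json.dumps(payload, indent=2, default=str))


def read_result_json(path) -> dict:
    payload = json.loads(Path(path).read_text())
    return payload["result"]
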