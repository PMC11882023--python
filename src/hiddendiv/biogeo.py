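"""Geographic coding, overlap, endemism and range-breadth statistics.

Species occurrences are coded at three nested levels: administrative
territories (countries or islands), the floristic realms containing them
(Neotropical, African, Indo-Malesian, Australian, Holarctic, ...), and the
large lichenogeographical regions defined from foliicolous lichen
distributions (Neotropics, African Palaeotropics, Eastern Palaeotropics,
Tethyan, ...), of which three are flagged as the major tropical regions.
Compositional overlap between units uses the Sørensen index
2·|A∩B| / (|A|+|B|); endemism is restriction to a single unit at a level;
and range breadth (narrow / continental-wide / bicontinental / pantropical)
is classified from region and territory counts.  The intercontinental
fraction of a species set can be computed under two species concepts —
phenotype-based (lineages merged by morphospecies, ranges unioned) and
integrative (each delimited species on its own) — whose comparison
quantifies how much apparent intercontinentality is an artefact of lumping
cryptic species under one name.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ._util import round_half_up

__all__ = [
    "GeographicScheme",
    "SpeciesRangeTable",
    "OverlapSummary",
    "sorensen",
    "overlap_summary",
    "endemism_summary",
    "classify_breadth",
    "intercontinental_fraction",
    "venn_counts",
    "effort_correlation",
]

LEVELS = ("territory", "realm", "region")


@dataclass(frozen=True)
class GeographicScheme:
    """Territory → floristic realm → lichenogeographical region nesting."""

    realm_of: dict[str, str]
    region_of: dict[str, str]
    tropical_regions: frozenset[str]

    def __post_init__(self) -> None:
        if set(self.realm_of) != set(self.region_of):
            raise ValueError("realm_of and region_of must cover the same territories")

    @property
    def territories(self) -> frozenset[str]:
        return frozenset(self.realm_of)

    def lift(self, territory: str, level: str) -> str:
        """Map a territory to its unit label at the requested level."""
        if territory not in self.realm_of:
            raise KeyError(f"unknown territory {territory!r}")
        if level == "territory":
            return territory
        if level == "realm":
            return self.realm_of[territory]
        if level == "region":
            return self.region_of[territory]
        raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "territory": t,
                "realm": self.realm_of[t],
                "region": self.region_of[t],
                "tropical": int(self.region_of[t] in self.tropical_regions),
            }
            for t in sorted(self.realm_of)
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class SpeciesRangeTable:
    """Per-species territory sets, with optional morphospecies labels."""

    ranges: dict[str, frozenset[str]]
    morphospecies: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sp, terr in self.ranges.items():
            if not terr:
                raise ValueError(f"species {sp!r} has an empty range")

    @classmethod
    def from_long(
        cls, records: Iterable[tuple[str, str]], morphospecies: Mapping[str, str] | None = None
    ) -> "SpeciesRangeTable":
        ranges: dict[str, set[str]] = {}
        for sp, terr in records:
            ranges.setdefault(str(sp), set()).add(str(terr))
        return cls(
            ranges={sp: frozenset(t) for sp, t in ranges.items()},
            morphospecies=dict(morphospecies or {}),
        )

    def units_of(self, species: str, scheme: GeographicScheme, level: str) -> frozenset[str]:
        return frozenset(scheme.lift(t, level) for t in self.ranges[species])


@dataclass(frozen=True)
class OverlapSummary:
    level: str
    units: tuple[str, ...]
    species_per_unit: dict[str, int] = field(hash=False)
    shared: pd.DataFrame = field(hash=False)  # pairwise shared-species counts
    sorensen: pd.DataFrame = field(hash=False)  # pairwise Sørensen index


def sorensen(set_a: frozenset | set, set_b: frozenset | set) -> float:
    """Sørensen similarity 2·|A∩B| / (|A| + |B|) of two species sets."""
    if not set_a or not set_b:
        raise ValueError("Sørensen similarity is undefined for an empty species set")
    return 2.0 * len(set_a & set_b) / (len(set_a) + len(set_b))


def _species_by_unit(
    table: SpeciesRangeTable, scheme: GeographicScheme, level: str
) -> dict[str, set[str]]:
    by_unit: dict[str, set[str]] = {}
    for sp, terrs in table.ranges.items():
        for t in terrs:
            by_unit.setdefault(scheme.lift(t, level), set()).add(sp)
    return by_unit


def overlap_summary(
    table: SpeciesRangeTable, scheme: GeographicScheme, level: str
) -> OverlapSummary:
    """All pairwise shared-species counts and Sørensen values at one level."""
    by_unit = _species_by_unit(table, scheme, level)
    units = tuple(sorted(by_unit))
    n = len(units)
    shared = np.zeros((n, n), dtype=int)
    soren = np.zeros((n, n))
    for i, j in itertools.combinations_with_replacement(range(n), 2):
        inter = len(by_unit[units[i]] & by_unit[units[j]])
        shared[i, j] = shared[j, i] = inter
        s = sorensen(by_unit[units[i]], by_unit[units[j]])
        soren[i, j] = soren[j, i] = s
    return OverlapSummary(
        level=level,
        units=units,
        species_per_unit={u: len(by_unit[u]) for u in units},
        shared=pd.DataFrame(shared, index=units, columns=units),
        sorensen=pd.DataFrame(soren, index=units, columns=units),
    )


def endemism_summary(table: SpeciesRangeTable, scheme: GeographicScheme) -> dict[str, dict]:
    """Single-unit (endemic) species counts and percentages per level.

    Percentages are rounded half-up to whole percent, the precision at
    which such figures are customarily reported.
    """
    total = len(table.ranges)
    out: dict[str, dict] = {}
    for level in LEVELS:
        n_endemic = sum(
            1 for sp in table.ranges if len(table.units_of(sp, scheme, level)) == 1
        )
        out[level] = {
            "endemic": n_endemic,
            "total": total,
            "percent": round_half_up(100.0 * n_endemic / total) if total else 0,
        }
    return out


def classify_breadth(
    territories: frozenset[str] | set[str], scheme: GeographicScheme
) -> str:
    """Range-breadth class of a territory set.

    pantropical: present in every major tropical region; otherwise ≥2
    regions → bicontinental; one region but ≥2 territories →
    continental_wide; a single territory → narrow.
    """
    if not territories:
        raise ValueError("cannot classify an empty range")
    regions = {scheme.lift(t, "region") for t in territories}
    if scheme.tropical_regions and scheme.tropical_regions <= regions:
        return "pantropical"
    if len(regions) >= 2:
        return "bicontinental"
    return "continental_wide" if len(territories) >= 2 else "narrow"


def intercontinental_fraction(
    table: SpeciesRangeTable,
    scheme: GeographicScheme,
    concept: str,
    species: Iterable[str] | None = None,
) -> float:
    """Percent of taxa spanning ≥2 lichenogeographical regions.

    ``integrative``: each delimited species counts on its own range.
    ``phenotype``: species are first merged by morphospecies (ranges
    unioned) and the fraction is computed over the merged taxa — lumping
    cryptic species under one name can only widen ranges, so this fraction
    is always ≥ the integrative one.  Rounded half-up to 1 decimal.
    """
    chosen = set(species) if species is not None else set(table.ranges)
    if not chosen:
        raise ValueError("no species selected")
    if concept == "integrative":
        taxa = {sp: table.ranges[sp] for sp in chosen}
    elif concept == "phenotype":
        missing = [sp for sp in chosen if sp not in table.morphospecies]
        if missing:
            raise ValueError(
                f"phenotype concept needs morphospecies labels; missing for {missing[:5]}"
            )
        taxa = {}
        for sp in chosen:
            m = table.morphospecies[sp]
            taxa[m] = taxa.get(m, frozenset()) | table.ranges[sp]
    else:
        raise ValueError(f"unknown concept {concept!r}")
    inter = sum(
        1
        for terrs in taxa.values()
        if len({scheme.lift(t, "region") for t in terrs}) >= 2
    )
    return round_half_up(100.0 * inter / len(taxa), 1)


def venn_counts(
    table: SpeciesRangeTable,
    scheme: GeographicScheme,
    level: str,
    units: tuple[str, ...],
) -> dict[frozenset[str], int]:
    """Exclusive species counts for every non-empty combination of 2–4 units.

    Keys are the unit subsets a species occupies (restricted to ``units``);
    the counts partition the union of the units' species sets.
    """
    if not 2 <= len(units) <= 4:
        raise ValueError("venn_counts takes 2–4 units")
    by_unit = _species_by_unit(table, scheme, level)
    for u in units:
        by_unit.setdefault(u, set())
    out: dict[frozenset[str], int] = {}
    union = set().union(*(by_unit[u] for u in units))
    for sp in union:
        key = frozenset(u for u in units if sp in by_unit[u])
        out[key] = out.get(key, 0) + 1
    return out


def effort_correlation(
    specimens_per_unit: Mapping[str, int], species_per_unit: Mapping[str, int]
) -> tuple[float, float]:
    """Pearson correlation between sampling effort and observed richness.

    A correlation near 1 indicates that discovered richness still tracks
    effort — sampling is far from saturating the true diversity.
    """
    units = sorted(set(specimens_per_unit) & set(species_per_unit))
    if len(units) < 3:
        raise ValueError("need ≥ 3 units for a correlation")
    x = np.array([specimens_per_unit[u] for u in units], dtype=float)
    y = np.array([species_per_unit[u] for u in units], dtype=float)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("zero variance in specimen or species counts")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
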