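"""Four-category diversity accounting and hidden-diversity ratios.

A consensus delimitation over-delivers relative to the described taxonomy:
many consensus species are genetically distinct lineages inside a single
described morphospecies (hidden / cryptic diversity).  This module sorts
consensus species into four categories —

* ``known``          – matches a formally described species,
* ``hidden``         – a cryptic or near-cryptic lineage within a described
                       morphospecies,
* ``new_phenotype``  – a new species recognisable by phenotype alone,
* ``unidentified``   – specimens too poorly developed to assign,

links hidden species to their morphospecies complexes, and computes the
scalars that feed the global richness forecast: the taxonomic coverage
ratio (described species known worldwide vs. described species present in
the data set) and per-range-breadth mean hidden-diversity ratios.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .consensus import ConsensusPartition

__all__ = [
    "CATEGORIES",
    "BREADTH_CLASSES",
    "SpeciesRecord",
    "MorphospeciesComplex",
    "CategoryTally",
    "GrowthStatistics",
    "classify_species",
    "build_complexes",
    "tally_categories",
    "coverage_ratio",
    "compute_hidden_ratios",
    "split_unsequenced",
    "dataset_growth",
]

CATEGORIES = ("known", "hidden", "new_phenotype", "unidentified")
BREADTH_CLASSES = ("narrow", "continental_wide", "bicontinental", "pantropical")


@dataclass(frozen=True)
class SpeciesRecord:
    """One consensus species with its taxonomic status and range."""

    species_id: str
    category: str
    morphospecies: str | None
    described_name: str | None
    territories: frozenset[str]

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category == "known" and not self.described_name:
            raise ValueError(f"{self.species_id}: known species needs a described name")
        if self.category == "hidden" and not self.morphospecies:
            raise ValueError(f"{self.species_id}: hidden species needs a morphospecies")


@dataclass(frozen=True)
class MorphospeciesComplex:
    """A described morphospecies with its hidden species-level lineages."""

    morphospecies: str
    n_described_in_dataset: int
    n_hidden: int
    breadth_class: str

    @property
    def hidden_ratio(self) -> float:
        """(hidden + described) / described; ≥ 1, and 1 with no hidden lineages."""
        if self.n_described_in_dataset < 1:
            raise ValueError(
                f"{self.morphospecies}: hidden ratio undefined without a described member"
            )
        return (self.n_hidden + self.n_described_in_dataset) / self.n_described_in_dataset


@dataclass(frozen=True)
class CategoryTally:
    a: int  # known
    b: int  # hidden
    c: int  # new phenotype
    d: int  # unidentified

    @property
    def E(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class GrowthStatistics:
    """Size of the new data set relative to an earlier baseline."""

    ratio: float  # new / old
    percent_increase: float  # 100 * (new - old) / old


def classify_species(
    cons: ConsensusPartition, specimens: pd.DataFrame
) -> list[SpeciesRecord]:
    """Turn a consensus partition plus curated specimen metadata into records.

    ``specimens`` must carry columns specimen_id, morphospecies, described
    (0/1), territory.  Rules, per consensus species: no morphospecies on
    its specimens → unidentified; a morphospecies that carries a described
    name somewhere in the data → known if this cluster holds a
    name-carrying specimen, else hidden; a morphospecies never formally
    described → new_phenotype.
    """
    meta = specimens.set_index("specimen_id")
    # a morphospecies is "described" if any specimen of it carries the name
    morpho_named: dict[str, bool] = {}
    for m, grp in specimens.groupby("morphospecies"):
        if m:
            morpho_named[str(m)] = bool((grp["described"].astype(int) == 1).any())

    clusters: dict[str, list[str]] = {}
    for sp, label in cons.assignment.items():
        clusters.setdefault(label, []).append(sp)

    records = []
    for label in sorted(clusters):
        members = clusters[label]
        rows = meta.loc[members]
        morphos = [str(m) for m in rows["morphospecies"] if m]
        territories = frozenset(str(t) for t in rows["territory"] if t)
        if not morphos:
            records.append(SpeciesRecord(label, "unidentified", None, None, territories))
            continue
        morpho = Counter(morphos).most_common(1)[0][0]
        carries_name = bool((rows["described"].astype(int) == 1).any())
        if morpho_named.get(morpho, False):
            if carries_name:
                records.append(SpeciesRecord(label, "known", morpho, morpho, territories))
            else:
                records.append(SpeciesRecord(label, "hidden", morpho, None, territories))
        else:
            records.append(SpeciesRecord(label, "new_phenotype", morpho, None, territories))
    return records


def build_complexes(
    records: Iterable[SpeciesRecord],
    breadth_of: Mapping[str, str],
) -> list[MorphospeciesComplex]:
    """Group known + hidden records into morphospecies complexes.

    ``breadth_of`` maps each morphospecies to its range-breadth class
    (typically from classify_breadth on the union of member ranges).
    Morphospecies with no described member in the data set are skipped —
    their lineages are accounted as new_phenotype, and a hidden ratio
    without a described anchor is undefined.
    """
    by_morpho: dict[str, dict[str, int]] = {}
    for rec in records:
        if rec.category not in ("known", "hidden") or not rec.morphospecies:
            continue
        slot = by_morpho.setdefault(rec.morphospecies, {"known": 0, "hidden": 0})
        slot[rec.category] += 1
    out = []
    for morpho in sorted(by_morpho):
        counts = by_morpho[morpho]
        if counts["known"] < 1:
            continue
        out.append(
            MorphospeciesComplex(
                morphospecies=morpho,
                n_described_in_dataset=counts["known"],
                n_hidden=counts["hidden"],
                breadth_class=breadth_of[morpho],
            )
        )
    return out


def tally_categories(records: Iterable[SpeciesRecord]) -> CategoryTally:
    """Count species per category; the consensus estimate E is their sum."""
    c = Counter(rec.category for rec in records)
    return CategoryTally(
        a=c.get("known", 0),
        b=c.get("hidden", 0),
        c=c.get("new_phenotype", 0),
        d=c.get("unidentified", 0),
    )


def coverage_ratio(n_described_total: int, a: int) -> float:
    """Described species known worldwide per described species in the data.

    Estimates how much of the described taxonomy the data set covers; a
    value below 1 (more described species sequenced than the reference
    list holds) is suspicious and warned about.
    """
    if a < 1:
        raise ValueError("coverage ratio undefined with no described species in data")
    ratio = n_described_total / a
    if ratio < 1:
        warnings.warn(
            f"dataset contains more described species ({a}) than the reference "
            f"list ({n_described_total})",
            stacklevel=2,
        )
    return ratio


def compute_hidden_ratios(
    complexes: Iterable[MorphospeciesComplex],
    weight_by: str = "complex",
) -> dict[str, float]:
    """Mean hidden-diversity ratio per range-breadth pool.

    Pantropical complexes give ``R_pantropical``; bicontinental and
    continental-wide complexes pool into ``R_wide``; narrow species are
    fixed at 1.0 by design (hidden diversity is not extrapolated for
    narrow endemics).  The default is the unweighted arithmetic mean over
    complexes; ``weight_by="described"`` weights each complex by its
    number of described members instead.  Pools with no complexes are
    absent from the result, not reported as zero.
    """
    if weight_by not in ("complex", "described"):
        raise ValueError("weight_by must be 'complex' or 'described'")
    pools: dict[str, list[tuple[float, float]]] = {"R_pantropical": [], "R_wide": []}
    for cx in complexes:
        if cx.breadth_class == "pantropical":
            pool = "R_pantropical"
        elif cx.breadth_class in ("bicontinental", "continental_wide"):
            pool = "R_wide"
        else:
            continue
        w = cx.n_described_in_dataset if weight_by == "described" else 1.0
        pools[pool].append((cx.hidden_ratio, w))
    out: dict[str, float] = {"R_narrow": 1.0}
    for name, vals in pools.items():
        if vals:
            out[name] = sum(r * w for r, w in vals) / sum(w for _, w in vals)
    return out


def split_unsequenced(
    n_described_total: int,
    a: int,
    breadth_assignments: Mapping[str, str],
) -> tuple[int, int, int]:
    """Split the D = total − a unsequenced described species by range breadth.

    Returns (D_pantropical, D_wide, D_narrow), with bicontinental and
    continental-wide pooled into D_wide.  The breadth assignment must
    cover exactly the D unsequenced names.
    """
    d = n_described_total - a
    if len(breadth_assignments) != d:
        raise ValueError(
            f"breadth assignments cover {len(breadth_assignments)} names, expected D={d}"
        )
    counts = Counter(breadth_assignments.values())
    unknown = set(counts) - set(BREADTH_CLASSES)
    if unknown:
        raise ValueError(f"unknown breadth classes: {sorted(unknown)}")
    d_pan = counts.get("pantropical", 0)
    d_wide = counts.get("bicontinental", 0) + counts.get("continental_wide", 0)
    d_narrow = counts.get("narrow", 0)
    assert d_pan + d_wide + d_narrow == d
    return d_pan, d_wide, d_narrow


def dataset_growth(old_count: int, new_count: int) -> GrowthStatistics:
    """Growth of species-level sampling relative to an earlier study."""
    if old_count < 1:
        raise ValueError("baseline count must be ≥ 1")
    return GrowthStatistics(
        ratio=new_count / old_count,
        percent_increase=100.0 * (new_count - old_count) / old_count,
    )
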