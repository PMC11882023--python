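"""Synthetic studies with the structure the analysis chain assumes.

The generator emulates a global barcoding study of a hyperdiverse,
poorly-sampled group: a pool of true species organised into morphospecies
complexes (one described name carrier per complex, with probability
``prop_described``, the rest hidden lineages), geographic ranges drawn
from a narrow/continental-wide/bicontinental/pantropical breadth mix over
territories nested in floristic realms and lichenogeographical regions,
specimen sampling with per-species counts, and several delimitation
methods that observe the true partition through partial specimen coverage
and splitting/lumping noise.  One designated method (the "integrative"
one) covers every specimen and acts as the tie-breaking partition.

Because the generator knows the truth, it can also state the global
species richness implied by the forecast's own assumptions (area-ratio
scaling of new-phenotype species and of hidden diversity in wide-ranging
unsequenced species), which the downstream pipeline is expected to
recover from the noisy fixtures alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from ._util import derive_rng
from .accounting import BREADTH_CLASSES
from .biogeo import GeographicScheme, classify_breadth
from .consensus import Partition, PartitionSet
from .forecast import ForecastInputs, compute_G
from .richness import IncidenceMatrix

__all__ = [
    "MethodProfile",
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_species_pool",
    "simulate_sampling",
    "simulate_partitions",
    "simulate_study",
    "true_global_richness",
    "write_fixtures",
]


class ConfigurationError(ValueError):
    """A SimulationConfig field is invalid; the message names the field."""


@dataclass(frozen=True)
class MethodProfile:
    """Error model of one delimitation method."""

    name: str
    split_rate: float = 0.0
    lump_rate: float = 0.0
    coverage: float = 1.0
    is_tiebreaker: bool = False

    def __post_init__(self) -> None:
        for f in ("split_rate", "lump_rate"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"method_profiles[{self.name}].{f}={v} not in [0,1]")
        if not 0.0 < self.coverage <= 1.0:
            raise ConfigurationError(
                f"method_profiles[{self.name}].coverage={self.coverage} not in (0,1]"
            )


# Defaults mirror the study design being emulated: 473 species over 32
# territories in 5 floristic realms / 4 lichenogeographical regions;
# single-locus methods with 0.64/0.76/0.35 specimen coverage alongside a
# complete integrative partition; geometric complex sizes truncated at 35
# (the largest observed complex); ~2.7 specimens per species on average.
_REALMS = ("Neotropical", "African", "IndoMalesian", "Australian", "Holarctic")
_TERRITORIES_PER_REALM = {
    "Neotropical": 12,
    "African": 6,
    "IndoMalesian": 6,
    "Australian": 5,
    "Holarctic": 3,
}
_REGION_OF_REALM = {
    "Neotropical": "Neotropics",
    "African": "AfricanPalaeotropics",
    "IndoMalesian": "EasternPalaeotropics",
    "Australian": "EasternPalaeotropics",
    "Holarctic": "Tethyan",
}
_TROPICAL_REGIONS = ("Neotropics", "AfricanPalaeotropics", "EasternPalaeotropics")


def _default_methods() -> tuple[MethodProfile, ...]:
    return (
        MethodProfile("gmyc_multilocus", split_rate=0.05, lump_rate=0.10, coverage=0.64),
        MethodProfile("bptp", split_rate=0.10, lump_rate=0.02, coverage=0.76),
        MethodProfile("asap_mtssu", split_rate=0.05, lump_rate=0.05, coverage=0.35),
        MethodProfile("integrative", coverage=1.0, is_tiebreaker=True),
    )


@dataclass(frozen=True)
class SimulationConfig:
    n_true_species: int = 473
    realm_names: tuple[str, ...] = _REALMS
    territories_per_realm: dict[str, int] = field(
        default_factory=lambda: dict(_TERRITORIES_PER_REALM)
    )
    region_of_realm: dict[str, str] = field(default_factory=lambda: dict(_REGION_OF_REALM))
    tropical_regions: tuple[str, ...] = _TROPICAL_REGIONS
    range_breadth_weights: dict[str, float] = field(
        default_factory=lambda: {
            "narrow": 0.84,
            "continental_wide": 0.11,
            "bicontinental": 0.04,
            "pantropical": 0.01,
        }
    )
    complex_size_distribution: tuple[str, dict] = ("geometric", {"p": 0.33, "truncate": 35})
    prop_described: float = 0.76
    prop_unidentifiable: float = 0.12
    specimens_per_species: tuple[str, dict] = ("poisson", {"mean": 2.7})
    localities_per_territory: int = 10
    method_profiles: tuple[MethodProfile, ...] = field(default_factory=_default_methods)
    # bookkeeping of described species known from literature but absent from
    # the data set, per range-breadth class (feeds the forecast's D split)
    unsequenced_described: dict[str, int] = field(
        default_factory=lambda: {
            "pantropical": 18,
            "bicontinental": 44,
            "continental_wide": 28,
            "narrow": 265,
        }
    )
    area_ratio: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_true_species < 1:
            raise ConfigurationError("n_true_species must be ≥ 1")
        if abs(sum(self.range_breadth_weights.values()) - 1.0) > 1e-9:
            raise ConfigurationError("range_breadth_weights must sum to 1")
        if set(self.range_breadth_weights) != set(BREADTH_CLASSES):
            raise ConfigurationError(
                f"range_breadth_weights must cover exactly {BREADTH_CLASSES}"
            )
        for f in ("prop_described", "prop_unidentifiable"):
            if not 0.0 <= getattr(self, f) <= 1.0:
                raise ConfigurationError(f"{f} not in [0,1]")
        if sum(m.is_tiebreaker for m in self.method_profiles) != 1:
            raise ConfigurationError("method_profiles must flag exactly one tiebreaker")
        tb = next(m for m in self.method_profiles if m.is_tiebreaker)
        if tb.coverage < 1.0:
            raise ConfigurationError(
                "method_profiles: the tiebreaker must cover all specimens (coverage 1.0)"
            )
        if self.localities_per_territory < 1:
            raise ConfigurationError("localities_per_territory must be ≥ 1")
        if set(self.territories_per_realm) != set(self.realm_names):
            raise ConfigurationError("territories_per_realm must cover realm_names exactly")
        if set(self.region_of_realm) != set(self.realm_names):
            raise ConfigurationError("region_of_realm must cover realm_names exactly")
        _validate_distribution("complex_size_distribution", self.complex_size_distribution, 1)
        _validate_distribution("specimens_per_species", self.specimens_per_species, 0)
        if self.area_ratio < 1:
            raise ConfigurationError("area_ratio must be ≥ 1")

    def scheme(self) -> GeographicScheme:
        realm_of, region_of = {}, {}
        for realm in self.realm_names:
            for i in range(1, self.territories_per_realm[realm] + 1):
                terr = f"{realm}_{i:02d}"
                realm_of[terr] = realm
                region_of[terr] = self.region_of_realm[realm]
        return GeographicScheme(
            realm_of=realm_of,
            region_of=region_of,
            tropical_regions=frozenset(self.tropical_regions),
        )


def _validate_distribution(fieldname: str, dist: tuple[str, dict], support_min: int) -> None:
    name, params = dist
    if name == "fixed":
        if "value" not in params or params["value"] < support_min:
            raise ConfigurationError(f"{fieldname}: fixed value must be ≥ {support_min}")
    elif name == "geometric":
        p = params.get("p", 0)
        if not 0.0 < p <= 1.0:
            raise ConfigurationError(f"{fieldname}: geometric p={p} not in (0,1]")
    elif name == "poisson":
        if params.get("mean", -1) < 0:
            raise ConfigurationError(f"{fieldname}: poisson mean must be ≥ 0")
    else:
        raise ConfigurationError(
            f"{fieldname}: unknown distribution {name!r} (fixed | geometric | poisson)"
        )


def _draw(dist: tuple[str, dict], rng: np.random.Generator) -> int:
    name, params = dist
    if name == "fixed":
        return int(params["value"])
    if name == "geometric":
        v = int(rng.geometric(params["p"]))
        trunc = params.get("truncate")
        return min(v, int(trunc)) if trunc else v
    if name == "poisson":
        return int(rng.poisson(params["mean"]))
    raise AssertionError(name)


@dataclass
class SimulatedStudy:
    truth_table: pd.DataFrame
    specimen_table: pd.DataFrame
    partitions: PartitionSet | None
    incidence_by_level: dict[str, IncidenceMatrix]
    locality_matrices: dict[str, IncidenceMatrix]
    described_list: pd.DataFrame
    scheme: GeographicScheme
    config_echo: SimulationConfig


def _realize_range(breadth: str, scheme: GeographicScheme, rng: np.random.Generator) -> frozenset[str]:
    """Draw a territory set consistent with a breadth class."""
    by_region: dict[str, list[str]] = {}
    for t in sorted(scheme.territories):
        by_region.setdefault(scheme.region_of[t], []).append(t)
    regions = sorted(by_region)
    if breadth == "narrow":
        region = regions[rng.integers(len(regions))]
        return frozenset([by_region[region][rng.integers(len(by_region[region]))]])
    if breadth == "continental_wide":
        wide_regions = [r for r in regions if len(by_region[r]) >= 2]
        region = wide_regions[rng.integers(len(wide_regions))]
        k = int(min(len(by_region[region]), 2 + rng.integers(3)))
        return frozenset(rng.choice(by_region[region], size=k, replace=False))
    if breadth == "bicontinental":
        r1, r2 = rng.choice(regions, size=2, replace=False)
        out = set()
        for r in (r1, r2):
            k = int(min(len(by_region[r]), 1 + rng.integers(2)))
            out.update(rng.choice(by_region[r], size=k, replace=False))
        return frozenset(out)
    if breadth == "pantropical":
        out = set()
        for r in sorted(scheme.tropical_regions):
            k = int(min(len(by_region[r]), 1 + rng.integers(2)))
            out.update(rng.choice(by_region[r], size=k, replace=False))
        return frozenset(out)
    raise AssertionError(breadth)


def simulate_species_pool(config: SimulationConfig) -> pd.DataFrame:
    """Draw the true species pool as a truth table.

    Morphospecies complexes are drawn from the complex-size distribution
    until ``n_true_species`` species exist (the last complex is truncated
    to land exactly).  Each complex carries a described name with
    probability ``prop_described``; within a described complex one member
    is the name carrier (category ``known``) and the rest are ``hidden``.
    Members of unnamed complexes are ``new_phenotype``.  Independently,
    each species is unidentifiable with probability
    ``prop_unidentifiable`` (overrides its category; its specimens will
    lack a morphospecies assignment).
    """
    rng = derive_rng(config.seed, "species_pool")
    scheme = config.scheme()
    breadths = list(config.range_breadth_weights)
    weights = np.array([config.range_breadth_weights[b] for b in breadths])

    rows = []
    n_species = 0
    cx_index = 0
    while n_species < config.n_true_species:
        cx_index += 1
        size = min(_draw(config.complex_size_distribution, rng),
                   config.n_true_species - n_species)
        described = rng.random() < config.prop_described
        morpho = f"morpho{cx_index:04d}"
        carrier = int(rng.integers(size))
        for j in range(size):
            n_species += 1
            sid = f"tsp{n_species:04d}"
            unident = rng.random() < config.prop_unidentifiable
            if unident:
                category = "unidentified"
            elif described and j == carrier:
                category = "known"
            elif described:
                category = "hidden"
            else:
                category = "new_phenotype"
            breadth = breadths[rng.choice(len(breadths), p=weights)]
            territories = _realize_range(breadth, scheme, rng)
            rows.append(
                {
                    "species_id": sid,
                    "morphospecies": "" if unident else morpho,
                    "described": int(category == "known"),
                    "category": category,
                    "breadth_class": breadth,
                    "territories": ";".join(sorted(territories)),
                    "n_specimens": 0,
                }
            )
    # a complex whose carrier went unidentifiable loses its name: remaining
    # members are new to science as far as any observer can tell
    truth = pd.DataFrame(rows)
    named = set(truth.loc[truth["described"] == 1, "morphospecies"])
    unnamed_hidden = (truth["category"] == "hidden") & ~truth["morphospecies"].isin(named)
    truth.loc[unnamed_hidden, "category"] = "new_phenotype"
    return truth


def simulate_sampling(
    truth: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, IncidenceMatrix], dict[str, IncidenceMatrix]]:
    """Draw specimens and build incidence matrices.

    Returns (specimen table, updated truth table, per-level incidence
    matrices, per-territory locality matrices).  Species drawing zero
    specimens stay in the truth table with ``n_specimens = 0``.
    """
    if truth.empty:
        raise ValueError("truth table is empty")
    rng = derive_rng(config.seed, "sampling")
    scheme = config.scheme()
    rows = []
    counts = []
    spec_no = 0
    for rec in truth.itertuples():
        n = _draw(config.specimens_per_species, rng)
        counts.append(n)
        terrs = sorted(rec.territories.split(";"))
        for _ in range(n):
            spec_no += 1
            terr = terrs[rng.integers(len(terrs))]
            loc = f"{terr}_L{1 + rng.integers(config.localities_per_territory):02d}"
            rows.append(
                {
                    "specimen_id": f"spec{spec_no:05d}",
                    "species_id": rec.species_id,
                    "morphospecies": rec.morphospecies,
                    "described": rec.described,
                    "territory": terr,
                    "locality": loc,
                }
            )
    truth = truth.assign(n_specimens=counts)
    specimens = pd.DataFrame(
        rows, columns=hio.SPECIMEN_COLUMNS
    )

    incidence_by_level: dict[str, IncidenceMatrix] = {}
    locality_matrices: dict[str, IncidenceMatrix] = {}
    if not specimens.empty:
        for level in ("territory", "realm", "region"):
            pairs = [
                (sp, scheme.lift(t, level))
                for sp, t in zip(specimens["species_id"], specimens["territory"])
            ]
            incidence_by_level[level] = IncidenceMatrix.from_long(pairs)
        for terr, grp in specimens.groupby("territory"):
            locality_matrices[str(terr)] = IncidenceMatrix.from_long(
                list(zip(grp["species_id"], grp["locality"]))
            )
    return specimens, truth, incidence_by_level, locality_matrices


def _bipartition(members: list[str], rng: np.random.Generator) -> tuple[list[str], list[str]]:
    """Uniformly random proper bipartition of ≥2 members."""
    n = len(members)
    while True:
        mask = rng.integers(0, 2, size=n).astype(bool)
        if mask.any() and not mask.all():
            break
    left = [m for m, keep in zip(members, mask) if keep]
    right = [m for m, keep in zip(members, mask) if not keep]
    return left, right


def simulate_partitions(
    specimens: pd.DataFrame, truth: pd.DataFrame, config: SimulationConfig
) -> PartitionSet:
    """Noisy per-method OTU partitions of the specimen table.

    Each method sees a random specimen subset of size coverage × n, starts
    from the true species partition restricted to it, then splits each
    cluster (uniform bipartition) at ``split_rate`` and merges random
    cluster pairs sharing a morphospecies at ``lump_rate`` — errors stay
    shaped like real conflicts: oversplitting within lineages and lumping
    of look-alike congeners, never arbitrary cross-complex fusions.
    """
    if specimens.empty:
        raise ValueError("specimen table is empty")
    morpho_of = dict(zip(truth["species_id"], truth["morphospecies"]))
    species_of = dict(zip(specimens["specimen_id"], specimens["species_id"]))
    all_specs = sorted(species_of)
    partitions = []
    for profile in config.method_profiles:
        rng = derive_rng(config.seed, "partitions", profile.name)
        n_cov = max(1, int(round(profile.coverage * len(all_specs))))
        covered = sorted(rng.choice(all_specs, size=n_cov, replace=False))

        clusters: dict[str, list[str]] = {}
        for sp in covered:
            clusters.setdefault(species_of[sp], []).append(sp)
        cluster_list = [sorted(v) for _, v in sorted(clusters.items())]

        # splitting
        split_out = []
        for members in cluster_list:
            if len(members) >= 2 and rng.random() < profile.split_rate:
                left, right = _bipartition(members, rng)
                split_out.extend([left, right])
            else:
                split_out.append(members)

        # lumping within morphospecies
        by_morpho: dict[str, list[list[str]]] = {}
        final = []
        for members in split_out:
            m = morpho_of.get(species_of[members[0]], "")
            if m:
                by_morpho.setdefault(m, []).append(members)
            else:
                final.append(members)
        for m in sorted(by_morpho):
            group = by_morpho[m]
            order = rng.permutation(len(group))
            i = 0
            while i < len(order):
                if i + 1 < len(order) and rng.random() < profile.lump_rate:
                    final.append(group[order[i]] + group[order[i + 1]])
                    i += 2
                else:
                    final.append(group[order[i]])
                    i += 1

        assignment = {
            sp: f"{profile.name}_c{idx:04d}"
            for idx, members in enumerate(sorted(final, key=min), start=1)
            for sp in members
        }
        partitions.append(Partition(method_name=profile.name, assignment=assignment))
    tiebreaker = next(m.name for m in config.method_profiles if m.is_tiebreaker)
    return PartitionSet(partitions=tuple(partitions), tiebreaker=tiebreaker)


def _described_list(truth: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Global described-species ledger: sequenced names + literature-only ones."""
    scheme = config.scheme()
    rows = []
    for morpho, grp in truth[truth["described"] == 1].groupby("morphospecies"):
        union: set[str] = set()
        for t in grp["territories"]:
            union.update(t.split(";"))
        rows.append(
            {
                "name": morpho,
                "breadth_class": classify_breadth(frozenset(union), scheme),
                "in_dataset": 1,
            }
        )
    i = 0
    for breadth in sorted(config.unsequenced_described):
        for _ in range(config.unsequenced_described[breadth]):
            i += 1
            rows.append({"name": f"unseq{i:04d}", "breadth_class": breadth, "in_dataset": 0})
    return pd.DataFrame(rows, columns=hio.DESCRIBED_COLUMNS)


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Full generation chain: pool → sampling → partitions → fixtures."""
    truth = simulate_species_pool(config)
    specimens, truth, by_level, by_locality = simulate_sampling(truth, config)
    partitions = simulate_partitions(specimens, truth, config) if not specimens.empty else None
    return SimulatedStudy(
        truth_table=truth,
        specimen_table=specimens,
        partitions=partitions,
        incidence_by_level=by_level,
        locality_matrices=by_locality,
        described_list=_described_list(truth, config),
        scheme=config.scheme(),
        config_echo=config,
    )


def true_global_richness(study: SimulatedStudy) -> tuple[float, dict]:
    """Global richness implied by the generator's truth and the forecast model.

    Accounting is restricted to sampled species (a described complex only
    counts as anchored if its name carrier was sampled), class-mean hidden
    ratios are computed from the true sampled complexes with breadth taken
    from true ranges, and the unsequenced-described ledger and area ratio
    come from the configuration.  A pipeline run on the noisy fixtures is
    judged against this number.
    """
    cfg = study.config_echo
    truth = study.truth_table
    sampled = truth[truth["n_specimens"] > 0]
    carriers = set(
        sampled.loc[(sampled["described"] == 1), "morphospecies"]
    )
    cats = []
    for rec in sampled.itertuples():
        if rec.category == "unidentified":
            cats.append("unidentified")
        elif rec.described == 1:
            cats.append("known")
        elif rec.morphospecies in carriers:
            cats.append("hidden")
        else:
            cats.append("new_phenotype")
    sampled = sampled.assign(category_sampled=cats)
    e_true = len(sampled)
    c_true = int((sampled["category_sampled"] == "new_phenotype").sum())

    ratios: dict[str, list[float]] = {"R_pantropical": [], "R_wide": []}
    for morpho in sorted(carriers):
        grp = sampled[
            (sampled["morphospecies"] == morpho)
            & sampled["category_sampled"].isin(["known", "hidden"])
        ]
        n_known = int((grp["category_sampled"] == "known").sum())
        n_hidden = int((grp["category_sampled"] == "hidden").sum())
        union: set[str] = set()
        for t in grp["territories"]:
            union.update(t.split(";"))
        breadth = classify_breadth(frozenset(union), study.scheme)
        ratio = (n_hidden + n_known) / n_known
        if breadth == "pantropical":
            ratios["R_pantropical"].append(ratio)
        elif breadth in ("bicontinental", "continental_wide"):
            ratios["R_wide"].append(ratio)
    r_pan = float(np.mean(ratios["R_pantropical"])) if ratios["R_pantropical"] else 1.0
    r_wide = float(np.mean(ratios["R_wide"])) if ratios["R_wide"] else 1.0

    unseq = cfg.unsequenced_described
    inputs = ForecastInputs(
        E=e_true,
        c=c_true,
        D_pantropical=unseq.get("pantropical", 0),
        D_wide=unseq.get("bicontinental", 0) + unseq.get("continental_wide", 0),
        D_narrow=unseq.get("narrow", 0),
        R_pantropical=max(r_pan, 1.0),
        R_wide=max(r_wide, 1.0),
        area_ratio=cfg.area_ratio,
    )
    result = compute_G(inputs)
    return result.G_raw, {
        "E_true": e_true,
        "c_true": c_true,
        "R_pantropical_true": r_pan,
        "R_wide_true": r_wide,
        "n_sampled_complexes": len(carriers),
    }


def write_fixtures(study: SimulatedStudy, directory: str | Path) -> list[Path]:
    """Write every fixture file; round-trips losslessly through the readers."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []

    def _put(df: pd.DataFrame, name: str) -> None:
        path = directory / name
        hio.write_table(df, path)
        written.append(path)

    _put(study.specimen_table, "specimen_table.tsv")
    _put(study.truth_table, "truth_table.tsv")
    _put(study.described_list, "described_species.tsv")
    hio.write_geography(study.scheme, directory / "geography.tsv")
    written.append(directory / "geography.tsv")
    if study.partitions is not None:
        hio.write_partition_set(study.partitions, directory / "partitions.tsv")
        written.append(directory / "partitions.tsv")
    for level, matrix in study.incidence_by_level.items():
        path = directory / f"incidence_{level}.tsv"
        hio.write_incidence_matrix(matrix, path)
        written.append(path)
    loc_dir = directory / "localities"
    for terr, matrix in study.locality_matrices.items():
        path = loc_dir / f"incidence_{terr}.tsv"
        hio.write_incidence_matrix(matrix, path)
        written.append(path)
    return written
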