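"""Consensus species delimitation across conflicting OTU partitions.

Several delimitation methods (tree-based single- and multi-locus methods,
distance-based methods, and an integrative assessment combining molecules
with phenotype and geography) each partition a set of specimens into
putative species (OTUs).  The methods disagree: some split where others
lump, and single-locus methods cover only the specimens for which that
locus was sequenced.  This module resolves the disagreement by majority
rule over minimal conflict components, with one designated partition — the
integrative one in practice — breaking ties.

Specimen cluster labels are opaque: two methods agree on a set of specimens
when their restricted partitions are equal as sets of specimen sets,
regardless of how either method names its clusters.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "Partition",
    "PartitionSet",
    "ConflictComponent",
    "ConsensusPartition",
    "UnresolvedComponentError",
    "find_components",
    "consensus",
    "count_otus",
    "count_splits",
    "pairwise_agreement",
]

# a restriction is a partition of a specimen subset, canonicalised as a
# frozenset of frozensets so equality ignores cluster labels
Restriction = frozenset[frozenset[str]]


class UnresolvedComponentError(ValueError):
    """No method covers a conflict component, or a tie cannot be broken."""


@dataclass(frozen=True)
class Partition:
    """One method's assignment of specimens to OTU labels (possibly partial)."""

    method_name: str
    assignment: dict[str, str]

    @property
    def specimens(self) -> frozenset[str]:
        return frozenset(self.assignment)

    def clusters(self) -> Restriction:
        """The partition as a label-free set of specimen sets."""
        groups: dict[str, set[str]] = {}
        for sp, lab in self.assignment.items():
            groups.setdefault(lab, set()).add(sp)
        return frozenset(frozenset(g) for g in groups.values())

    def restrict(self, specimens: frozenset[str]) -> Restriction | None:
        """Restriction to ``specimens``; None (abstain) unless all are covered."""
        if not specimens <= self.specimens:
            return None
        groups: dict[str, set[str]] = {}
        for sp in specimens:
            groups.setdefault(self.assignment[sp], set()).add(sp)
        return frozenset(frozenset(g) for g in groups.values())


@dataclass(frozen=True)
class PartitionSet:
    """≥2 partitions plus the name of the tie-breaking (integrative) one."""

    partitions: tuple[Partition, ...]
    tiebreaker: str

    def __post_init__(self) -> None:
        if len(self.partitions) < 2:
            raise ValueError("a PartitionSet needs at least two partitions")
        names = [p.method_name for p in self.partitions]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate method names: {names}")
        if self.tiebreaker not in names:
            raise ValueError(f"tiebreaker {self.tiebreaker!r} is not a member method")

    @property
    def all_specimens(self) -> frozenset[str]:
        out: set[str] = set()
        for p in self.partitions:
            out |= p.specimens
        return frozenset(out)

    def tiebreaker_partition(self) -> Partition:
        return next(p for p in self.partitions if p.method_name == self.tiebreaker)


@dataclass(frozen=True)
class ConflictComponent:
    """A connected component of the co-clustering graph.

    Within a component every delimitation decision is self-contained: no
    method clusters any of its specimens with an outside specimen.
    """

    specimens: frozenset[str]
    candidate_restrictions: dict[str, Restriction | None] = field(hash=False)


@dataclass(frozen=True)
class ConsensusPartition:
    """Total consensus assignment with per-component rule provenance."""

    assignment: dict[str, str]
    provenance: tuple[dict, ...]  # one entry per component: specimens, rule, votes


def find_components(pset: PartitionSet) -> list[ConflictComponent]:
    """Split the specimen set into minimal independent conflict components.

    Two specimens are linked when *any* partition co-clusters them; the
    connected components of that graph are the units on which methods can
    meaningfully vote.  A method abstains on a component it does not fully
    cover (a partial restriction is not a well-defined candidate).
    """
    g: nx.Graph = nx.Graph()
    g.add_nodes_from(pset.all_specimens)
    for p in pset.partitions:
        for cluster in p.clusters():
            members = sorted(cluster)
            g.add_edges_from(zip(members, members[1:]))
    components = []
    for comp in nx.connected_components(g):
        specimens = frozenset(comp)
        restrictions = {
            p.method_name: p.restrict(specimens) for p in pset.partitions
        }
        components.append(ConflictComponent(specimens, restrictions))
    # deterministic order regardless of input listing
    components.sort(key=lambda c: min(c.specimens))
    return components


def _resolve(component: ConflictComponent, tiebreaker: str) -> tuple[Restriction, str]:
    """Pick the winning restriction for one component; returns (winner, rule)."""
    votes = {m: r for m, r in component.candidate_restrictions.items() if r is not None}
    if not votes:
        raise UnresolvedComponentError(
            f"no method covers component {sorted(component.specimens)}"
        )
    counts = Counter(votes.values())
    top = counts.most_common()
    if len(top) == 1:
        return top[0][0], "unanimous"
    best, best_n = top[0]
    if top[1][1] < best_n:
        return best, "majority"
    # tie among modal restrictions: defer to the tiebreaker even if its
    # restriction is not itself modal
    tb = component.candidate_restrictions.get(tiebreaker)
    if tb is None:
        raise UnresolvedComponentError(
            f"tie on component {sorted(component.specimens)} and the "
            f"tiebreaker {tiebreaker!r} abstains"
        )
    return tb, "tiebreaker"


def consensus(pset: PartitionSet) -> ConsensusPartition:
    """Majority-rule consensus with tiebreak, per conflict component.

    Each non-abstaining method votes for its restriction of the component;
    the modal restriction wins, ties go to the tiebreaker partition.
    Consensus species labels are freshly generated zero-padded integers in
    sorted order of each cluster's smallest specimen id, so the result is
    invariant to how partitions or specimens were listed.
    """
    clusters: list[frozenset[str]] = []
    provenance = []
    for component in find_components(pset):
        winner, rule = _resolve(component, pset.tiebreaker)
        clusters.extend(winner)
        provenance.append(
            {
                "specimens": tuple(sorted(component.specimens)),
                "rule": rule,
                "voters": tuple(
                    sorted(
                        m
                        for m, r in component.candidate_restrictions.items()
                        if r is not None
                    )
                ),
            }
        )
    clusters.sort(key=min)
    width = max(4, len(str(len(clusters))))
    assignment = {
        sp: f"sp{idx:0{width}d}"
        for idx, cluster in enumerate(clusters, start=1)
        for sp in cluster
    }
    return ConsensusPartition(assignment=assignment, provenance=tuple(provenance))


def count_otus(p: Partition | ConsensusPartition) -> int:
    """Number of distinct cluster labels (0 for an empty partition)."""
    return len(set(p.assignment.values()))


def count_splits(a: Partition, b: Partition) -> int:
    """How many clusters of ``a`` are divided by ``b``.

    Restricted to the specimens both methods cover; a cluster of ``a``
    counts once if its (restricted) members land in ≥2 clusters of ``b``.
    """
    shared = a.specimens & b.specimens
    if not shared:
        raise ValueError(
            f"partitions {a.method_name!r} and {b.method_name!r} share no specimens"
        )
    n = 0
    groups: dict[str, set[str]] = {}
    for sp in shared:
        groups.setdefault(a.assignment[sp], set()).add(sp)
    for members in groups.values():
        if len({b.assignment[sp] for sp in members}) >= 2:
            n += 1
    return n


def pairwise_agreement(pset: PartitionSet) -> list[dict]:
    """Cluster-level agreement between every ordered pair of methods.

    ``shared_otus`` counts clusters of method *i* that are identical, as
    specimen sets restricted to the jointly covered specimens, to a cluster
    of method *j* (a symmetric quantity); split counts are directional.
    """
    rows = []
    for pa, pb in itertools.combinations(pset.partitions, 2):
        shared = pa.specimens & pb.specimens
        ra = _restrict_clusters(pa, shared)
        rb = _restrict_clusters(pb, shared)
        rows.append(
            {
                "method_i": pa.method_name,
                "method_j": pb.method_name,
                "shared_otus": len(ra & rb),
                "splits_i_by_j": count_splits(pa, pb),
                "splits_j_by_i": count_splits(pb, pa),
            }
        )
    return rows


def _restrict_clusters(p: Partition, shared: frozenset[str]) -> Restriction:
    groups: dict[str, set[str]] = {}
    for sp in shared:
        groups.setdefault(p.assignment[sp], set()).add(sp)
    return frozenset(frozenset(g) for g in groups.values())
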