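"""Independent brute-force reference implementations used as test oracles.

Deliberately naive: transitive closure by Floyd–Warshall, vote counting by
explicit enumeration, rarefaction by exhaustive subset enumeration.  These
share no code with the package internals they check.
"""

from __future__ import annotations

import itertools
from collections import Counter


def reference_consensus(partitions, tiebreaker_name):
    """Exhaustive consensus on small inputs.

    ``partitions``: list of (name, {specimen: label}).  Returns
    (set of frozenset clusters, {component frozenset: rule}).
    """
    specimens = sorted(set(itertools.chain.from_iterable(a for _, a in partitions)))
    n = len(specimens)
    idx = {s: i for i, s in enumerate(specimens)}
    adj = [[i == j for j in range(n)] for i in range(n)]
    for _, a in partitions:
        for s, t in itertools.combinations(sorted(a), 2):
            if a[s] == a[t]:
                adj[idx[s]][idx[t]] = adj[idx[t]][idx[s]] = True
    for k in range(n):
        for i in range(n):
            if adj[i][k]:
                for j in range(n):
                    if adj[k][j]:
                        adj[i][j] = True
    seen, components = set(), []
    for i in range(n):
        if i in seen:
            continue
        comp = frozenset(specimens[j] for j in range(n) if adj[i][j])
        seen.update(idx[s] for s in comp)
        components.append(comp)

    clusters, rules = set(), {}
    for comp in components:
        votes = []
        tb_restriction = None
        for name, a in partitions:
            if not all(s in a for s in comp):
                continue
            groups = {}
            for s in comp:
                groups.setdefault(a[s], set()).add(s)
            restriction = frozenset(frozenset(g) for g in groups.values())
            votes.append(restriction)
            if name == tiebreaker_name:
                tb_restriction = restriction
        if not votes:
            raise ValueError(f"all methods abstain on {sorted(comp)}")
        counts = Counter(votes)
        best_n = max(counts.values())
        modal = [r for r, c in counts.items() if c == best_n]
        if len(counts) == 1:
            winner, rule = modal[0], "unanimous"
        elif len(modal) == 1:
            winner, rule = modal[0], "majority"
        else:
            if tb_restriction is None:
                raise ValueError(f"tie with abstaining tiebreaker on {sorted(comp)}")
            winner, rule = tb_restriction, "tiebreaker"
        clusters.update(winner)
        rules[comp] = rule
    return clusters, rules


def reference_rarefaction(cells, t):
    """Mean richness over all C(T, t) unit subsets of a 0/1 matrix."""
    n_units = len(cells[0])
    richness = []
    for subset in itertools.combinations(range(n_units), t):
        richness.append(sum(1 for row in cells if any(row[u] for u in subset)))
    return sum(richness) / len(richness)


def reference_venn(sets_by_unit, units):
    """Exclusive-combination species counts by direct set algebra."""
    out = {}
    union = set().union(*(sets_by_unit[u] for u in units))
    for sp in union:
        key = frozenset(u for u in units if sp in sets_by_unit[u])
        out[key] = out.get(key, 0) + 1
    return out
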