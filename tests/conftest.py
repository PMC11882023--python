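import hypothesis.strategies as st
import pytest
from hypothesis import HealthCheck, settings

from hiddendiv.consensus import Partition, PartitionSet

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[
        HealthCheck.too_slow,
        HealthCheck.filter_too_much,
        # the schemes handed to property tests are frozen dataclasses
        HealthCheck.function_scoped_fixture,
    ],
)
settings.load_profile("suite")


@st.composite
def partition_sets(draw, max_specimens: int = 8, max_methods: int = 4):
    """Random partial partition sets; the last method is a total tiebreaker.

    A total tiebreaker guarantees every conflict component has at least one
    voter and every tie is breakable, mirroring the role of an integrative
    partition covering all specimens.
    """
    n = draw(st.integers(2, max_specimens))
    specimens = [f"s{i}" for i in range(n)]
    k = draw(st.integers(2, max_methods))
    parts = []
    for m in range(k):
        total = m == k - 1
        assignment = {}
        for s in specimens:
            if total or draw(st.booleans()):
                assignment[s] = f"c{draw(st.integers(0, 3))}"
        if not assignment:
            assignment[specimens[0]] = "c0"
        parts.append(Partition(method_name=f"m{m}", assignment=assignment))
    return PartitionSet(partitions=tuple(parts), tiebreaker=f"m{k-1}")


@st.composite
def incidence_cells(draw, max_species: int = 6, max_units: int = 10):
    """Small 0/1 matrices with no all-zero rows, as row bitmasks."""
    t = draw(st.integers(2, max_units))
    s = draw(st.integers(1, max_species))
    rows = [draw(st.integers(1, 2**t - 1)) for _ in range(s)]
    return [[(r >> u) & 1 for u in range(t)] for r in rows]


@pytest.fixture
def toy_scheme():
    """Six territories in three realms / three regions, all tropical."""
    from hiddendiv.biogeo import GeographicScheme

    realm_of = {
        "bra": "Neotropical", "gua": "Neotropical",
        "mad": "African", "may": "African",
        "tai": "IndoMalesian", "ncl": "IndoMalesian",
    }
    region_of = {
        "bra": "Neo", "gua": "Neo",
        "mad": "Afr", "may": "Afr",
        "tai": "East", "ncl": "East",
    }
    return GeographicScheme(
        realm_of=realm_of, region_of=region_of,
        tropical_regions=frozenset({"Neo", "Afr", "East"}),
    )
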