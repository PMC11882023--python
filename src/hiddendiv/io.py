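"""Readers and writers for the tab-separated table dialects.

All fixtures are plain TSV.  Empty cells are meaningful (a specimen not
covered by a method, a specimen without a morphospecies), so files are
read with string dtypes and NA detection disabled.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .biogeo import GeographicScheme
from .consensus import ConsensusPartition, Partition, PartitionSet
from .richness import IncidenceMatrix

__all__ = [
    "read_table",
    "write_table",
    "read_partition_set",
    "write_partition_set",
    "write_consensus",
    "read_incidence_matrix",
    "write_incidence_matrix",
    "read_geography",
    "write_geography",
]

SPECIMEN_COLUMNS = ["specimen_id", "species_id", "morphospecies", "described", "territory", "locality"]
TRUTH_COLUMNS = [
    "species_id",
    "morphospecies",
    "described",
    "category",
    "breadth_class",
    "territories",
    "n_specimens",
]
DESCRIBED_COLUMNS = ["name", "breadth_class", "in_dataset"]


def read_table(path: str | Path) -> pd.DataFrame:
    """Generic TSV reader preserving empty strings."""
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_partition_set(pset: PartitionSet, path: str | Path) -> None:
    """Wide partition table: specimen_id + one column per method.

    An empty cell marks a specimen the method did not cover.  The
    tiebreaker is not encoded in the file; it is named when reading back.
    """
    specimens = sorted(pset.all_specimens)
    data = {"specimen_id": specimens}
    for p in pset.partitions:
        data[p.method_name] = [p.assignment.get(sp, "") for sp in specimens]
    write_table(pd.DataFrame(data), path)


def read_partition_set(path: str | Path, tiebreaker: str) -> PartitionSet:
    df = read_table(path)
    if "specimen_id" not in df.columns:
        raise ValueError(f"{path}: first column must be specimen_id")
    partitions = []
    for method in df.columns[1:]:
        assignment = {
            str(row.specimen_id): str(getattr(row, method))
            for row in df.itertuples()
            if str(getattr(row, method)) != ""
        }
        partitions.append(Partition(method_name=str(method), assignment=assignment))
    return PartitionSet(partitions=tuple(partitions), tiebreaker=tiebreaker)


def write_consensus(cons: ConsensusPartition, directory: str | Path) -> None:
    """Two files: the assignment and a per-component provenance record."""
    directory = Path(directory)
    assign = pd.DataFrame(
        sorted(cons.assignment.items()), columns=["specimen_id", "consensus_species"]
    )
    write_table(assign, directory / "consensus.tsv")
    prov = pd.DataFrame(
        [
            {
                "component": i,
                "rule": entry["rule"],
                "methods_voting": ";".join(entry["voters"]),
                "specimens": ";".join(entry["specimens"]),
            }
            for i, entry in enumerate(cons.provenance, start=1)
        ]
    )
    write_table(prov, directory / "consensus_provenance.tsv")


def write_incidence_matrix(matrix: IncidenceMatrix, path: str | Path) -> None:
    df = matrix.to_dataframe()
    df.insert(0, "species", df.index)
    write_table(df, path)


def read_incidence_matrix(path: str | Path) -> IncidenceMatrix:
    df = pd.read_csv(path, sep=None, engine="python")  # comma or tab
    df = df.set_index(df.columns[0])
    return IncidenceMatrix.from_dataframe(df.astype(int))


def write_geography(scheme: GeographicScheme, path: str | Path) -> None:
    write_table(scheme.to_dataframe(), path)


def read_geography(path: str | Path) -> GeographicScheme:
    df = read_table(path)
    realm_of = dict(zip(df["territory"], df["realm"]))
    region_of = dict(zip(df["territory"], df["region"]))
    tropical = frozenset(
        df.loc[df["tropical"].astype(int) == 1, "region"].unique().tolist()
    )
    return GeographicScheme(realm_of=realm_of, region_of=region_of, tropical_regions=tropical)
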