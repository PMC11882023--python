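"""Majority-rule consensus across conflicting OTU partitions.

Four methods disagree about five specimens of a cryptic complex; the
consensus resolves each conflict component by vote, with the integrative
partition breaking ties.
"""

import hiddendiv as hd

# two methods split specimens d/e, one lumps them, the integrative
# partition (full coverage) also lumps them -> tie broken towards lumping
partitions = (
    hd.Partition("gmyc", {"a": "1", "b": "1", "c": "2", "d": "3", "e": "4"}),
    hd.Partition("bptp", {"a": "x", "b": "x", "c": "y", "d": "z", "e": "w"}),
    hd.Partition("asap", {"a": "p", "b": "p", "c": "q", "d": "r", "e": "r"}),
    hd.Partition("integrative", {"a": "A", "b": "A", "c": "B", "d": "C", "e": "C"}),
)
pset = hd.PartitionSet(partitions, tiebreaker="integrative")

for p in partitions:
    print(f"{p.method_name:>12s}: {hd.count_otus(p)} OTUs")

cons = hd.consensus(pset)
print(f"\nconsensus: {hd.count_otus(cons)} species")
for specimen in sorted(cons.assignment):
    print(f"  {specimen} -> {cons.assignment[specimen]}")
for entry in cons.provenance:
    print(f"  component {entry['specimens']}: rule={entry['rule']}")

print("\nsplits of gmyc clusters by bptp:",
      hd.count_splits(partitions[0], partitions[1]))
# Each conflict component is decided by the modal restriction; the d/e
# component is a 2-2 tie that the integrative partition settles.
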