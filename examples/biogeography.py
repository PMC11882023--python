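"""Overlap, endemism and species-concept contrast on a small range table.

Six territories nested in three tropical lichenogeographical regions;
one cryptic complex spans two continents under a single morphospecies
name.
"""

import hiddendiv as hd

scheme = hd.GeographicScheme(
    realm_of={"brazil": "Neotropical", "guadeloupe": "Neotropical",
              "madagascar": "African", "mayotte": "African",
              "taiwan": "IndoMalesian", "newcaledonia": "IndoMalesian"},
    region_of={"brazil": "Neotropics", "guadeloupe": "Neotropics",
               "madagascar": "AfricanPalaeotropics", "mayotte": "AfricanPalaeotropics",
               "taiwan": "EasternPalaeotropics", "newcaledonia": "EasternPalaeotropics"},
    tropical_regions=frozenset(
        {"Neotropics", "AfricanPalaeotropics", "EasternPalaeotropics"}
    ),
)

table = hd.SpeciesRangeTable(
    ranges={
        "sp1": frozenset({"brazil", "guadeloupe"}),      # wide Neotropical
        "sp2": frozenset({"brazil"}),                    # narrow endemic
        "sp3": frozenset({"madagascar"}),                # cryptic lineage A
        "sp4": frozenset({"taiwan"}),                    # cryptic lineage B
        "sp5": frozenset({"brazil", "madagascar", "taiwan"}),  # pantropical
    },
    # sp3 and sp4 share one morphospecies name across two continents
    morphospecies={"sp1": "m1", "sp2": "m2", "sp3": "m3", "sp4": "m3", "sp5": "m4"},
)

summary = hd.overlap_summary(table, scheme, "territory")
print("Sørensen, brazil vs guadeloupe:",
      round(summary.sorensen.loc["brazil", "guadeloupe"], 4))

endemism = hd.endemism_summary(table, scheme)
for level, stats in endemism.items():
    print(f"endemism at {level:9s}: {stats['endemic']}/{stats['total']}"
          f" = {stats['percent']}%")

for sp in sorted(table.ranges):
    print(f"{sp}: {hd.classify_breadth(table.ranges[sp], scheme)}")

phen = hd.intercontinental_fraction(table, scheme, "phenotype")
integ = hd.intercontinental_fraction(table, scheme, "integrative")
print(f"intercontinental fraction: phenotype {phen}% vs integrative {integ}%")
# Lumping the cryptic pair under one name manufactures an apparently
# intercontinental taxon: the phenotype-based fraction exceeds the
# integrative one.

cells = hd.venn_counts(
    table, scheme, "region",
    ("Neotropics", "AfricanPalaeotropics", "EasternPalaeotropics"),
)
print("Venn cells (regions):")
for combo in sorted(cells, key=lambda c: (len(c), sorted(c))):
    print(f"  {'+'.join(sorted(combo))}: {cells[combo]}")
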