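"""Simulate a full study and recover its global richness end to end.

Generates a 473-species world with cryptic complexes and four noisy
delimitation methods, writes the fixture files, and runs the
consensus → accounting → forecast chain on them.
"""

import tempfile
from pathlib import Path

import hiddendiv as hd

config = hd.SimulationConfig(n_true_species=473, seed=1)
study = hd.simulate_study(config)

print(f"simulated {len(study.truth_table)} species, "
      f"{len(study.specimen_table)} specimens")
print("true categories:",
      study.truth_table["category"].value_counts().to_dict())

with tempfile.TemporaryDirectory() as tmp:
    files = hd.write_fixtures(study, Path(tmp))
    print(f"wrote {len(files)} fixture files, e.g. {files[0].name}")

g_true, diagnostics = hd.true_global_richness(study)
print(f"\ntrue global richness implied by the generator: {g_true:.0f}")
print(f"  (E_true={diagnostics['E_true']}, "
      f"R_pan={diagnostics['R_pantropical_true']:.2f}, "
      f"R_wide={diagnostics['R_wide_true']:.2f})")

result = hd.estimate_global_richness(
    study.partitions, study.specimen_table,
    study.described_list, study.scheme,
    area_ratio=config.area_ratio,
)
tally = result.tally
print(f"\npipeline estimate from noisy partitions:")
print(f"  consensus species E = {tally.E} "
      f"(known {tally.a}, hidden {tally.b}, new {tally.c}, unidentified {tally.d})")
print(f"  estimated ratios: {({k: round(v, 2) for k, v in result.ratios.items()})}")
print(f"  forecast: ({result.forecast.lower}-){result.forecast.G_point}"
      f"(-{result.forecast.upper})")
err = abs(result.forecast.G_raw - g_true) / g_true
print(f"  relative error vs truth: {100 * err:.1f}%")
# Despite splitting/lumping noise and partial single-locus coverage, the
# majority-rule consensus and ratio re-estimation land within a few
# percent of the generator's implied global richness.
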