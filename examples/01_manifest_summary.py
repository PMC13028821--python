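"""Curate the bundled genome manifest and summarize the nonredundant set.

The bundled table lists 22 complete *Komagataeibacter* assemblies; four are
flagged clonal/derivative and excluded before mobilome comparisons so that
near-identical genomes do not inflate sharing signals.
"""

from komagen.manifest import (
    apply_exclusions,
    reference_exclusions,
    reference_manifest,
    summarize_manifest,
)

full = reference_manifest()
nonredundant = apply_exclusions(full, reference_exclusions())
s = summarize_manifest(nonredundant)

print(f"assemblies curated : {len(full)}")
print(f"after exclusions   : {s.n_genomes}")
print(f"named species      : {s.n_species} ({s.n_singleton_species} with a single genome)")
print(f"genome size (Mb)   : median {s.size_median_mb}, range {s.size_min_mb}-{s.size_max_mb}")
print()
print("The 18-genome nonredundant set is the basis for every comparative")
print("analysis; sizes are per-assembly totals rounded to 0.01 Mb.")
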