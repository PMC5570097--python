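"""Windowed shotgun abundance estimation with host filtering.

Maps shotgun pairs to the community reference set (after removing pairs
where either mate matches the host genome), tiles each genome into 10-kb
windows, and summarises per-species abundance as the mean read count per
window, zeroed when fewer than 20 % of a genome's windows contain a read
(the breadth rule). The final value is scaled per million sample reads.
"""

import fermentome as fm

design = fm.control_mix(1, seed=42, host_fraction=0.02)
refs = fm.build_references(design)

fwd, rev, truth = fm.simulate_shotgun_reads(
    design, refs, 10_000, error_rate=0.01, seed=11
)
result = fm.run_shotgun_pipeline(fwd, rev, refs.genomes, host=refs.host)

print("pipeline stats:", result.stats)

print("\nfirst windows of the most abundant genome:")
hu = result.profiles[result.profiles["target"] == "Hanseniaspora uvarum"]
print(hu.head(5).to_string(index=False))

print("\nper-species summary (reads per 10-kb window):")
print(result.species.round(4).to_string())

print("\n'id_factor' is the mean read identity per window: at 1 % base"
      "\nerror it sits near 0.99. 'adjusted_mean' is zeroed for species"
      "\nfailing the 20 % breadth rule, suppressing spurious single-window"
      "\nsignals; 'normalized' is per million total sample reads.")
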