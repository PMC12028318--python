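"""Map recombination events onto core genes and test the divergence link.

Simulates genomes with recombination injections at hotspot genes, maps
the emitted events onto the concatenated-alignment gene coordinates,
computes per-family identity and counting dN/dS, and runs the
divergence-recombination-dN/dS association tests.
"""

import math

import phagekit as pk

sim = pk.simulate_phage_genomes(
    n_taxa=12, n_core=40, n_accessory=6, subst_rate=0.01, recomb_events=8, seed=5
)
counts, n_hit = pk.map_events_to_genes(sim.events, sim.coordinates)
print(f"{len(sim.events)} recombination events overlap {n_hit} of "
      f"{len(sim.truth.core_families)} core genes")

stats = []
for fid in sim.truth.core_families:
    s = pk.family_alignment_stats(sim.alignments[fid])
    s.recomb_event_count = int(counts[fid])
    r = pk.counting_dnds(sim.alignments[fid].codons)
    s.dnds = r.dnds if r.is_defined else math.nan
    stats.append(s)

divergent = [s for s in stats if s.is_divergent]
print(f"{len(divergent)} divergent families (<95% mean pairwise identity); "
      f"injected with recombination: {sim.truth.injected_families}")

report = pk.divergence_association(stats)
rho, p = report.spearman_identity_recomb
print(f"identity vs recombination-count: Spearman rho={rho:.2f}, p={p:.2g}")
rho_d, p_d = report.spearman_identity_dnds
print(f"identity vs dN/dS:               Spearman rho={rho_d:.2f}, p={p_d:.2g}")
# a clearly negative identity/recombination correlation with a flat
# identity/dN-dS relation reproduces the signature of divergence driven
# by recombination rather than by relaxed purifying selection
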