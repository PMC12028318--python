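"""Dollo gain/loss phylostratigraphy of accessory gene families.

Simulates genomes whose accessory families are gained and lost on
scripted branches, then reconstructs those events from the emitted
presence/absence matrix alone and compares with the script.
"""

import phagekit as pk

sim = pk.simulate_phage_genomes(n_taxa=10, n_core=10, n_accessory=8, seed=21)
acc = sim.truth.accessory_families
rec = pk.dollo_gain_loss(sim.presence.loc[acc], sim.truth.tree_newick)

exact = 0
for fid in acc:
    ok = rec.gains[fid] == sim.truth.gains[fid] and rec.losses[fid] == sim.truth.losses[fid]
    exact += ok
    gain_size = len(rec.gains[fid])
    print(f"{fid}: gained on the branch to a {gain_size}-leaf clade, "
          f"{rec.loss_count(fid)} loss(es)  [matches script: {ok}]")
print(f"\n{exact}/{len(acc)} scripted histories recovered exactly")
print(rec.branch_tallies().to_string(index=False))
# each family is gained once at the MRCA of its carriers; losses are the
# minimal set of branches explaining the absences below that gain
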