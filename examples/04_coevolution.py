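"""Do anatomical character groups change on the same branches?

Two groups are coupled at kappa = 1 here (S8 of the thelycum and PE of the
petasma): every character of both groups changes on a shared pool of
branches.  Kulczynski similarity of their event vectors is then exactly 1,
single linkage merges them at distance 0, and NMDS places them together.
ANOSIM tests a chosen two-class factor on the rank distances.
"""

import cladecoev as cc

cfg = cc.SimulationConfig(seed=9, n_taxa=17, n_chars=75, homoplasy=0.0,
                          coupled_groups=(((3, 7), 1.0),))
tree, matrix, _ = cc.simulate(cfg)
result = cc.branch_and_bound_search(matrix, cfg.outgroup)
best = result.mp_trees[0].rooted_on(cfg.outgroup)

gem = cc.group_event_matrix(cc.map_changes(best, matrix), cfg.group_map(),
                            nodes=cc.internal_branches(best))
sim = cc.group_similarity(gem)
print("Kulczynski similarity between group event vectors:")
print(sim.similarity.round(2).to_string())
print(f"\ncoupled pair S8-PE similarity: {sim.similarity.loc['S8', 'PE']}")

den = cc.single_linkage(sim)
print("\nsingle-linkage merges (height = 1 - similarity):")
for a, b, h in den.merges():
    print(f"  {sorted(a)} + {sorted(b)} at {h:.3f}")

factor = {l: ("thelycum" if l in ("S6", "AS7", "PS7", "S8") else "petasma")
          for l in sim.labels}
ares = cc.anosim(sim.distance, factor, seed=1)
print(f"\nANOSIM (thelycum vs petasma): R = {ares.r:.3f}, "
      f"p = {ares.p_value:.4f} ({'exact' if ares.exact else 'sampled'})")

nres = cc.nmds(sim.distance, dims=2, seed=1)
print(f"NMDS stress-1 = {nres.stress:.4f}")
print(nres.coordinates.round(3).to_string())
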