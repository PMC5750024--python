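"""Mapping character changes onto the branches of the best tree.

Each branch of the most-parsimonious tree is an "evolutionary event":
minimum-change reconstruction says which characters changed there.  The
unambiguous mode lists only changes present in every minimal
reconstruction; the events then collapse into a branches x anatomical
groups presence/absence matrix.
"""

import cladecoev as cc

cfg = cc.SimulationConfig(seed=3, n_taxa=17, n_chars=75, homoplasy=0.04)
tree, matrix, _ = cc.simulate(cfg)
result = cc.branch_and_bound_search(matrix, cfg.outgroup)
best = result.mp_trees[0].rooted_on(cfg.outgroup)

events = cc.map_changes(best, matrix, mode="unambiguous")
print(f"{len(events)} unambiguous change events on {matrix.n_chars} chars")
for e in events[:8]:
    frm = "/".join(map(str, sorted(e.from_states)))
    to = "/".join(map(str, sorted(e.to_states)))
    print(f"  char {e.char_id:3d}: {frm} -> {to} on "
          f"[{','.join(sorted(e.clade))}]")
print("  ...")

gem = cc.group_event_matrix(events, cfg.group_map(),
                            nodes=cc.internal_branches(best))
print("\nbranches x groups event matrix (1 = some character of the group "
      "changed on that branch):")
print(gem.df.head(8).to_string())
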