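"""End-to-end runs: partition analyses, supports, and the coevolution stage.

``run_analysis`` reproduces one of the three partition analyses (1:
thelycum-only, 2: petasma-only, 3: total evidence): exact search, tree
length, ensemble CI/RI, bootstrap and Bremer supports, and the annotated
tree.  ``run_coevolution`` takes the total-evidence tree, maps character
changes onto its branches, aggregates them by anatomical group and runs
the similarity / clustering / ANOSIM / ordination battery.

All outputs are deterministic byte-for-byte given the same configuration:
every random stage has an explicit seed and no file contains timestamps.
The JSON run log records seeds, settings, package versions and input
checksums, enough to regenerate any reported number.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coevolution import anosim, group_similarity, nmds, single_linkage
from .errors import ContractError
from .fitch import ensemble_indices
from .mapping import (clade_label, group_event_matrix, internal_branches,
                      map_changes)
from .matrix import (CharacterGroupMap, CharacterMatrix, default_group_map,
                     read_matrix, select_partition)
from .search import SearchResult, branch_and_bound_search, heuristic_search
from .support import (annotate_tree, bootstrap_support, bremer_support,
                      flag_significant)

log = logging.getLogger(__name__)

PARTITION_OF_ANALYSIS = {1: "thelycum", 2: "petasma", 3: None}


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    matrix_path: str
    matrix_format: str = "csv"
    group_map_path: str = None  # None -> packaged default layout
    outgroup: str = "OUT"
    bootstrap_reps: int = 1000
    bootstrap_seed: int = 1
    bootstrap_search: str = "heuristic"
    bremer_cap: int = 8
    mapping_mode: str = "unambiguous"
    include_terminals: bool = True
    similarity_index: str = "kulczynski"
    anosim_factor: dict = None  # group label -> class; None -> partitions
    anosim_permutations: int = 9999
    anosim_seed: int = 1
    nmds_dims: int = 2
    nmds_restarts: int = 8
    nmds_seed: int = 1
    output_dir: str = "cladecoev_out"

    def load_matrix(self) -> CharacterMatrix:
        return read_matrix(self.matrix_path, self.matrix_format)

    def load_group_map(self) -> CharacterGroupMap:
        if self.group_map_path is None:
            return default_group_map()
        return CharacterGroupMap.from_yaml(self.group_map_path)


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write_log(outdir: Path, cfg: RunConfig, extra: dict) -> None:
    doc = {"package_version": __version__, "config": asdict(cfg)}
    doc.update(extra)
    (outdir / "run_log.json").write_text(json.dumps(doc, indent=2,
                                                    sort_keys=True, default=str))


def analyse_partition(m: CharacterMatrix, gmap: CharacterGroupMap,
                      which: int, outgroup: str) -> tuple:
    """Select the partition for analysis 1/2/3 and run the exact search."""
    if which not in PARTITION_OF_ANALYSIS:
        raise ContractError("analysis must be 1, 2 or 3")
    name = PARTITION_OF_ANALYSIS[which]
    sub = m if name is None else select_partition(m, gmap, name)
    t0 = time.perf_counter()
    result = branch_and_bound_search(sub, outgroup)
    log.info("analysis %d: %d MP tree(s), length %s (%.2fs)",
             which, result.n_trees, result.best_length,
             time.perf_counter() - t0)
    return sub, result


def run_analysis(cfg: RunConfig, which: int) -> dict:
    """One partition analysis with supports; writes a report bundle."""
    outdir = Path(cfg.output_dir) / f"analysis{which}"
    outdir.mkdir(parents=True, exist_ok=True)
    m = cfg.load_matrix()
    gmap = cfg.load_group_map()
    sub, result = analyse_partition(m, gmap, which, cfg.outgroup)
    indices = ensemble_indices(result.mp_trees[0], sub)

    boot = bootstrap_support(sub, cfg.outgroup, cfg.bootstrap_reps,
                             cfg.bootstrap_seed, search=cfg.bootstrap_search)
    bremer = bremer_support(sub, cfg.outgroup, result, cap=cfg.bremer_cap)
    table = flag_significant(boot, bremer)

    (outdir / "mp_trees.nwk").write_text(
        "".join(t.newick() + "\n" for t in result.mp_trees))
    (outdir / "annotated.nwk").write_text(
        annotate_tree(result.mp_trees[0], cfg.outgroup, boot, bremer) + "\n")
    table.to_tsv(outdir / "support.tsv")
    pd.DataFrame({"char_id": sub.char_ids,
                  "steps": result.per_character_lengths}).to_csv(
        outdir / "per_character_steps.tsv", sep="\t", index=False)
    report = {
        "analysis": which,
        "partition": PARTITION_OF_ANALYSIS[which] or "total",
        "n_taxa": sub.n_taxa,
        "n_chars": sub.n_chars,
        "n_mp_trees": result.n_trees,
        "best_length": result.best_length,
        "ci": str(Fraction(indices.ci)),
        "ri": str(Fraction(indices.ri)),
        "ci_percent": indices.ci_percent,
        "ri_percent": indices.ri_percent,
        "n_significant_clades": int(table.table["significant"].sum()),
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2,
                                                   sort_keys=True))
    _write_log(outdir, cfg, {"analysis": which,
                             "matrix_sha256": _checksum(cfg.matrix_path),
                             "search_diagnostics": result.diagnostics})
    return report


def run_coevolution(cfg: RunConfig, result: SearchResult = None) -> dict:
    """Character-group co-change analysis on the total-evidence MP tree."""
    outdir = Path(cfg.output_dir) / "coevolution"
    outdir.mkdir(parents=True, exist_ok=True)
    m = cfg.load_matrix()
    gmap = cfg.load_group_map()
    if result is None:
        _, result = analyse_partition(m, gmap, 3, cfg.outgroup)
    tree = result.mp_trees[0].rooted_on(cfg.outgroup)
    if not tree.is_binary():
        raise ContractError("coevolution stage needs a fully resolved MP "
                            "tree; resolve or choose a single tree first")

    events = map_changes(tree, m, mode=cfg.mapping_mode,
                         include_terminals=cfg.include_terminals)
    nodes = internal_branches(tree, include_terminals=cfg.include_terminals)
    gem = group_event_matrix(events, gmap, nodes=nodes)
    sim = group_similarity(gem, index=cfg.similarity_index)
    dendro = single_linkage(sim)

    factor = cfg.anosim_factor
    if factor is None:
        factor = {}
        for pname, gids in gmap.partitions.items():
            for gid in gids:
                factor[gmap.groups[gid].label] = pname
    factor = {k: v for k, v in factor.items() if k in sim.labels}
    ares = anosim(sim.distance, factor, n_perm=cfg.anosim_permutations,
                  seed=cfg.anosim_seed)
    nres = nmds(sim.distance, dims=cfg.nmds_dims,
                n_restarts=cfg.nmds_restarts, seed=cfg.nmds_seed)

    gem.to_tsv(outdir / "group_events.tsv")
    sim.to_tsv(outdir / "similarity.tsv")
    sim.distance.to_csv(outdir / "distance.tsv", sep="\t",
                        index_label="group")
    dendro.to_tsv(outdir / "dendrogram_merges.tsv")
    (outdir / "dendrogram.nwk").write_text(dendro.newick() + "\n")
    nres.coordinates.to_csv(outdir / "nmds_coordinates.tsv", sep="\t",
                            index_label="group")
    events_df = pd.DataFrame(
        [{"node": clade_label(e.clade), "char_id": e.char_id,
          "from": "/".join(str(s) for s in sorted(e.from_states)),
          "to": "/".join(str(s) for s in sorted(e.to_states)),
          "ambiguous": e.ambiguous} for e in events])
    events_df.to_csv(outdir / "events.tsv", sep="\t", index=False)
    report = {
        "n_events": len(events),
        "n_groups_used": len(sim.labels),
        "anosim_r": ares.r,
        "anosim_p": ares.p_value,
        "anosim_exact": ares.exact,
        "anosim_factor": factor,
        "nmds_stress": nres.stress,
        "first_merge": sorted(dendro.merges()[0][0] | dendro.merges()[0][1]),
        "note": ("ANOSIM factor and permutation count are configuration "
                 "choices; results depend on them"),
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2,
                                                   sort_keys=True))
    _write_log(outdir, cfg, {"stage": "coevolution",
                             "matrix_sha256": _checksum(cfg.matrix_path)})
    return report


def reproduce_all(cfg: RunConfig) -> dict:
    """Chain analyses 1-3 and the coevolution stage with shared settings."""
    reports = {f"analysis{i}": run_analysis(cfg, i) for i in (1, 2, 3)}
    reports["coevolution"] = run_coevolution(cfg)
    return reports
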