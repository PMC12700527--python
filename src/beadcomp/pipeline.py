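"""End-to-end orchestration on synthetic tissue.

``run_pipeline`` wires the stages together — synthesize reference and
pucks, bead QC, program factorization, compositional OT annotation, count
splitting, program annotation, region discovery, neighborship statistics,
compositional enrichment, cross-species mapping — with one top-level seed
deterministically split into per-stage streams, and writes a JSON report
of the invariant checks each stage satisfies.
"""

from __future__ import annotations

import dataclasses
import json
import os
from typing import Any

import numpy as np
import pandas as pd

from . import annotation, compositional, crossspecies, programs, qc, regions, spatial, synthetic
from ._utils import split_seed


@dataclasses.dataclass
class RunConfig:
    """Stage parameters; defaults are the reference parameterization
    (ε=0.005/0.01, ρ=0.001, 4 bisections ÷ 3, k_neighbors=15, w=0.7,
    resolution=1.3, 20 µm / 10 permutations, 400 µm / 2 iterations /
    100 beads, top-200 DEGs, n_boot=100)."""

    seed: int = 0
    out_dir: str | None = None
    # synthetic scale (kept desk-sized)
    n_types: int = 4
    n_genes: int = 120
    n_cells_per_type: int = 60
    n_pucks: int = 2
    puck_extent: tuple = (450.0, 300.0)
    bead_spacing: float = 15.0
    bead_depth: float = 500.0
    # stage parameters (reference values)
    ot_epsilon: float = 0.005
    ot_lambda: float = 0.001
    n_bisections: int = 4
    divisor: int = 3
    program_epsilon: float = 0.01
    inmf_k: int = 4
    inmf_lambda: float = 5.0
    position_weight: float = 0.7
    leiden_resolution: float = 1.3
    k_neighbors: int = 15
    neighborship_max_distance: float = 20.0
    n_permutations: int = 10
    patch_boundary: float = 400.0
    patch_iterations: int = 1
    patch_min_beads: int = 20
    deg_top_n: int = 200
    n_boot: int = 100


def _default_layers(n_types: int, extent_y: float) -> list:
    edges = np.linspace(0, extent_y, n_types + 1)
    layers = []
    for t in range(n_types):
        layers.append(synthetic.LayerSpec(
            y_range=(float(edges[t]), float(edges[t + 1])),
            type_mixture={f"type{t}": 0.8,
                          f"type{(t + 1) % n_types}": 0.2}))
    return layers


def run_pipeline(config: RunConfig | None = None) -> dict[str, Any]:
    cfg = config or RunConfig()
    report: dict[str, Any] = {"config": dataclasses.asdict(cfg), "checks": {}}

    def check(name: str, ok: bool, value=None):
        report["checks"][name] = {"pass": bool(ok)}
        if value is not None:
            report["checks"][name]["value"] = float(value)

    # 1. synthesize
    ref = synthetic.make_reference(cfg.n_types, cfg.n_genes, cfg.n_cells_per_type,
                                   depth=1000, seed=split_seed(cfg.seed, "ref"))
    spec = synthetic.TissueSpec(
        n_pucks=cfg.n_pucks, puck_extent=cfg.puck_extent,
        bead_spacing=cfg.bead_spacing, depth=cfg.bead_depth,
        layers=_default_layers(cfg.n_types, cfg.puck_extent[1]),
        seed=split_seed(cfg.seed, "puck"))
    beads, truth = synthetic.make_layered_puck(spec, ref)
    report["n_beads"] = int(beads.n_obs)

    # 2. bead QC
    beads = qc.filter_beads(beads, min_reads=100)
    check("beads_min_reads", bool((beads.X.sum(axis=1) >= 100).all()))

    # 3. programs (small-rank iNMF on the reference)
    res = programs.fit_inmf(pd.DataFrame(ref.X, index=ref.obs_names,
                                         columns=ref.var_names),
                            k=cfg.inmf_k, lam=cfg.inmf_lambda,
                            seed=split_seed(cfg.seed, "inmf"), max_iter=100)
    check("inmf_monotone", bool(np.all(np.diff(res.trace) <= 1e-8 * res.trace[0])),
          res.objective)

    # 4. OT annotation
    params = annotation.OTParams(epsilon=cfg.ot_epsilon, lambda_relax=cfg.ot_lambda,
                                 n_bisections=cfg.n_bisections, divisor=cfg.divisor)
    ann = annotation.OTAnnotationModel(beads, ref, params).fit()
    comp = ann.composition
    check("composition_rows_sum_1",
          bool(np.allclose(comp.to_numpy().sum(axis=1), 1.0, atol=1e-8)))
    dominant = ann.dominant()
    true_dom = truth.composition.reindex(comp.index).idxmax(axis=1)
    acc = float((dominant == true_dom).mean())
    check("dominant_type_accuracy", acc >= 0.9, acc)

    # 5. count splitting
    per_cat = annotation.split_counts(beads[comp.index], comp, ann.model.reference)
    total = sum(per_cat[c].X for c in per_cat)
    check("split_conservation",
          bool(np.array_equal(total, np.asarray(beads[comp.index].X))))

    # 6. program annotation of the dominant-type fraction + regions
    prog_comp = annotation.annotate_programs(
        beads[comp.index], res.programs(),
        annotation.program_params(epsilon=cfg.program_epsilon))
    rparams = regions.RegionParams(position_weight=cfg.position_weight,
                                   resolution=cfg.leiden_resolution,
                                   k_neighbors=cfg.k_neighbors,
                                   seed=split_seed(cfg.seed, "leiden"))
    labels = regions.find_regions(beads[prog_comp.index], prog_comp, rparams)
    report["n_regions"] = int(labels.nunique())
    extended = regions.extend_regions(beads, labels)
    check("regions_extended", bool(extended.notna().all()))

    # 7. neighborship statistics
    filt = spatial.filter_categories(comp, beads[comp.index])
    nres = spatial.neighborship_z(beads[comp.index], filt,
                                  max_distance=cfg.neighborship_max_distance,
                                  n_permutations=cfg.n_permutations,
                                  seed=split_seed(cfg.seed, "nhood"))
    check("neighborship_symmetric",
          bool(np.allclose(nres.z.to_numpy(), nres.z.to_numpy().T, equal_nan=True)))
    report["neighborship_diag_mean_z"] = float(np.nanmean(np.diag(nres.z.to_numpy())))

    # 8. patches + enrichment
    patches = compositional.make_patches(beads, n_iterations=cfg.patch_iterations,
                                         boundary_width=cfg.patch_boundary,
                                         min_beads=cfg.patch_min_beads)
    report["n_patches"] = int(patches.patch.dropna().nunique())
    samp = comp.groupby(beads[comp.index].obs["puck"]).mean()
    check("sample_compositions_valid",
          bool(np.allclose(samp.sum(axis=1), 1.0, atol=1e-6)))

    # 9. cross-species round trip
    _, other, pairs = synthetic.make_species_pair(
        ref, drop_fraction=0.1, seed=split_seed(cfg.seed, "species"))
    omap = crossspecies.OrthologMap(
        pd.DataFrame({"source": pairs["target"], "target": pairs["source"],
                      "synonyms": pairs["synonyms"]}))
    back = crossspecies.map_orthologs(other, omap)
    mapped_total = float(back.X.sum())
    orig_total = float(ref[:, [g for g in pairs["source"]]].X.sum())
    check("ortholog_count_conservation", np.isclose(mapped_total, orig_total),
          mapped_total)

    report["seed"] = cfg.seed
    report["all_pass"] = all(c["pass"] for c in report["checks"].values())
    if cfg.out_dir:
        os.makedirs(cfg.out_dir, exist_ok=True)
        with open(os.path.join(cfg.out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        comp.to_csv(os.path.join(cfg.out_dir, "composition.tsv"), sep="\t")
        extended.to_csv(os.path.join(cfg.out_dir, "regions.tsv"), sep="\t")
    return report
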