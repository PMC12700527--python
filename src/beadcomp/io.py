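"""Plain-text readers and writers.

Counts travel as Matrix Market (.mtx) with TSV observation/gene metadata;
bead coordinates as CSV (bead_id, x_um, y_um, puck); ortholog tables in the
tab-separated MGI HOM report dialect; gene sets one per line, tab-separated
(name, then genes).
"""

from __future__ import annotations

import os

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from ._utils import dense_counts


def write_expression(adata: ad.AnnData, prefix: str) -> None:
    os.makedirs(os.path.dirname(prefix) or ".", exist_ok=True)
    scipy.io.mmwrite(prefix + ".mtx", sp.csr_matrix(dense_counts(adata)))
    adata.obs.to_csv(prefix + ".obs.tsv", sep="\t")
    pd.DataFrame(index=adata.var_names).to_csv(prefix + ".var.tsv", sep="\t")
    if "spatial" in adata.obsm:
        coords = pd.DataFrame(np.asarray(adata.obsm["spatial"]),
                              columns=["x_um", "y_um"], index=adata.obs_names)
        coords.insert(0, "bead_id", coords.index)
        coords["puck"] = adata.obs["puck"].to_numpy()
        coords.to_csv(prefix + ".coords.csv", index=False)


def read_expression(prefix: str) -> ad.AnnData:
    X = scipy.io.mmread(prefix + ".mtx").toarray().astype(float)
    obs = pd.read_csv(prefix + ".obs.tsv", sep="\t", index_col=0)
    var = pd.read_csv(prefix + ".var.tsv", sep="\t", index_col=0)
    obs.index = obs.index.astype(str)
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=var.index.astype(str)))
    coord_file = prefix + ".coords.csv"
    if os.path.exists(coord_file):
        coords = pd.read_csv(coord_file).set_index("bead_id")
        adata.obsm["spatial"] = coords.loc[adata.obs_names, ["x_um", "y_um"]].to_numpy()
    return adata


def write_hom_report(report: pd.DataFrame, path: str) -> None:
    report.to_csv(path, sep="\t", index=False)


def read_hom_report(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gene_sets(sets: dict, path: str) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([str(name)] + [str(g) for g in genes]) + "\n")


def read_gene_sets(path: str) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts and parts[0]:
                out[parts[0]] = parts[1:]
    return out
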