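"""Cell and bead quality filters and the three-rule doublet labelling.

The cell filter applies count/gene windows and mitochondrial/hemoglobin
fraction caps; window bounds are inclusive, fraction caps strict.  Doublets
in a partition (e.g. the immune compartment) are labelled by the union of
three rules:

1. foreign-marker rule — a cell whose count of any marker gene of another
   compartment strictly exceeds that gene's 95th percentile within the
   partition;
2. annotation-inconsistency rule — cell-wise and cluster-wise reference
   annotations disagree after coarse mapping;
3. neighbourhood rule — significantly more already-flagged neighbours in the
   expression k-NN graph than expected (one-sided Fisher, BH FDR 0.05).

The percentile rule is deliberately conservative for lowly expressed
markers: if ≥95% of the partition has 0 counts for a marker, the 95th
percentile is 0 and only cells with positive counts can be flagged, so more
than 95% of cells are always kept per marker.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from ._utils import dense_counts

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class CellQCThresholds:
    min_counts: int = 1000
    max_counts: int = 50000
    min_genes: int = 500
    max_genes: int = 7000
    max_mito_fraction: float = 0.20
    max_hemoglobin_fraction: float = 0.10

    def __post_init__(self):
        if self.min_counts > self.max_counts or self.min_genes > self.max_genes:
            raise ValueError("min must not exceed max for paired bounds")
        for f in (self.max_mito_fraction, self.max_hemoglobin_fraction):
            if not (0 <= f <= 1):
                raise ValueError("fraction caps must be in [0, 1]")


def _fraction(X: np.ndarray, mask: np.ndarray) -> np.ndarray:
    tot = X.sum(axis=1)
    sub = X[:, mask].sum(axis=1)
    return np.divide(sub, tot, out=np.zeros_like(tot, dtype=float), where=tot > 0)


def filter_cells(adata: ad.AnnData, thresholds: CellQCThresholds | None = None,
                 mito_prefix: str = "mt-", hemoglobin_prefix: str = "Hb",
                 mito_genes: Sequence[str] | None = None,
                 hemoglobin_genes: Sequence[str] | None = None,
                 ) -> tuple[ad.AnnData, pd.DataFrame]:
    """Apply the cell QC windows and fraction caps.

    Returns the filtered table and a per-cell report with boolean columns
    per failed rule ('min_counts', 'max_counts', 'min_genes', 'max_genes',
    'mito', 'hemoglobin') plus 'pass'.
    """
    thr = thresholds or CellQCThresholds()
    X = dense_counts(adata)
    genes = adata.var_names
    if mito_genes is None:
        mito_mask = np.asarray(genes.str.lower().str.startswith(mito_prefix.lower()))
    else:
        mito_mask = np.asarray(genes.isin(mito_genes))
    if hemoglobin_genes is None:
        hb_mask = np.asarray(genes.str.lower().str.startswith(hemoglobin_prefix.lower()))
    else:
        hb_mask = np.asarray(genes.isin(hemoglobin_genes))
    if not mito_mask.any():
        raise ValueError("no mitochondrial genes found for the fraction rule")
    if not hb_mask.any():
        raise ValueError("no hemoglobin genes found for the fraction rule")

    counts = X.sum(axis=1)
    n_genes = (X > 0).sum(axis=1)
    mito = _fraction(X, mito_mask)
    hb = _fraction(X, hb_mask)
    report = pd.DataFrame({
        "min_counts": counts < thr.min_counts,
        "max_counts": counts > thr.max_counts,
        "min_genes": n_genes < thr.min_genes,
        "max_genes": n_genes > thr.max_genes,
        "mito": mito >= thr.max_mito_fraction,          # strict "less than" cap
        "hemoglobin": hb >= thr.max_hemoglobin_fraction,
    }, index=adata.obs_names)
    report["pass"] = ~report.any(axis=1)
    return adata[report["pass"].to_numpy()].copy(), report


def filter_beads(beads: ad.AnnData, min_reads: int = 100) -> ad.AnnData:
    """Discard beads with fewer than ``min_reads`` total counts."""
    totals = np.asarray(dense_counts(beads).sum(axis=1))
    keep = totals >= min_reads
    if not keep.any():
        logger.warning("no beads left after the %d-read filter", min_reads)
    return beads[keep].copy()


def flag_marker_doublets(partition: ad.AnnData,
                         foreign_markers: Mapping[str, Sequence[str]],
                         percentile: float = 95.0) -> pd.Series:
    """Foreign-marker doublet rule.

    ``foreign_markers`` maps a foreign compartment name to its marker genes.
    A cell is flagged if any marker count strictly exceeds that marker's
    ``percentile``-th percentile (linear interpolation) within the partition.
    """
    if not (0 < percentile < 100):
        raise ValueError("percentile must be in (0, 100)")
    X = dense_counts(partition)
    flags = np.zeros(partition.n_obs, dtype=bool)
    for comp, markers in foreign_markers.items():
        for g in markers:
            if g not in partition.var_names:
                raise KeyError(f"marker gene {g!r} not in vocabulary")
            col = X[:, partition.var_names.get_loc(g)]
            cut = np.percentile(col, percentile)
            flags |= col > cut
    return pd.Series(flags, index=partition.obs_names, name="marker_doublet")


def flag_inconsistent_annotation(cellwise: pd.Series, clusterwise: pd.Series,
                                 coarse_map: Mapping[str, str] | None = None
                                 ) -> pd.Series:
    """Flag cells whose cell-wise and cluster-wise labels disagree.

    Both labellings are first mapped to a shared coarse vocabulary via
    ``coarse_map`` (identity by default); any label missing from the map is
    a configuration error.
    """
    if not cellwise.index.equals(clusterwise.index):
        raise ValueError("labelings must cover the same cells")
    if coarse_map is not None:
        seen = set(cellwise.unique()) | set(clusterwise.unique())
        missing = seen - set(coarse_map)
        if missing:
            raise KeyError(f"labels missing from coarse map: {sorted(missing)}")
        cellwise = cellwise.map(coarse_map)
        clusterwise = clusterwise.map(coarse_map)
    return pd.Series(cellwise.to_numpy() != clusterwise.to_numpy(),
                     index=cellwise.index, name="inconsistent_annotation")


def knn_graph(adata: ad.AnnData, k: int = 15, n_pcs: int = 30, seed: int = 0
              ) -> np.ndarray:
    """Expression k-NN neighbour indices (n_cells x k), on PCA of
    log1p-normalized counts.  Helper for the neighbourhood doublet rule."""
    from sklearn.decomposition import PCA
    from sklearn.neighbors import NearestNeighbors
    X = dense_counts(adata)
    tot = X.sum(axis=1, keepdims=True)
    tot[tot == 0] = 1
    Y = np.log1p(X / tot * 1e4)
    n_pcs = min(n_pcs, min(Y.shape) - 1)
    Z = PCA(n_components=n_pcs, random_state=seed).fit_transform(Y)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Z)
    _, idx = nn.kneighbors(Z)
    return idx[:, 1:]   # drop self


def flag_doublet_neighbors(neighbors: np.ndarray, prior_flags: pd.Series,
                           alpha: float = 0.05) -> pd.Series:
    """Neighbourhood doublet rule.

    For each cell, a one-sided Fisher's exact test of flagged vs unflagged
    cells among its k neighbours against the remaining cells of the
    partition (focal neighbourhood excluded from the background), BH
    corrected across cells; flagged where FDR ≤ alpha.
    """
    if neighbors.ndim != 2 or neighbors.shape[1] == 0:
        raise ValueError("need a n_cells x k neighbour index array with k >= 1")
    flags = prior_flags.to_numpy().astype(bool)
    n = len(flags)
    k = neighbors.shape[1]
    if not flags.any():
        return pd.Series(False, index=prior_flags.index, name="neighbor_doublet")
    pvals = np.ones(n)
    total_flagged = int(flags.sum())
    for i in range(n):
        nb = neighbors[i]
        x = int(flags[nb].sum())
        # background: all cells except the focal cell and its neighbourhood
        bg_n = n - 1 - k
        bg_flagged = total_flagged - x - int(flags[i])
        N = bg_n + k
        K = bg_flagged + x
        # P(X >= x) for X ~ Hypergeom(N, K, k): one-sided Fisher tail
        pvals[i] = hypergeom.sf(x - 1, N, K, k)
    rej, fdr, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    flagged = fdr <= alpha
    return pd.Series(flagged, index=prior_flags.index, name="neighbor_doublet")


def doublet_union(partition: ad.AnnData,
                  foreign_markers: Mapping[str, Sequence[str]],
                  cellwise: pd.Series | None = None,
                  clusterwise: pd.Series | None = None,
                  coarse_map: Mapping[str, str] | None = None,
                  percentile: float = 95.0, k: int = 15, alpha: float = 0.05,
                  seed: int = 0) -> pd.DataFrame:
    """Run the three doublet rules once, in order, and return all flags.

    Columns: 'marker', 'inconsistent', 'neighbor', 'doublet' (the union —
    the removal set)."""
    marker = flag_marker_doublets(partition, foreign_markers, percentile)
    if cellwise is not None and clusterwise is not None:
        incons = flag_inconsistent_annotation(cellwise, clusterwise, coarse_map)
    else:
        incons = pd.Series(False, index=partition.obs_names)
    prior = marker | incons
    nb = knn_graph(partition, k=k, seed=seed)
    neigh = flag_doublet_neighbors(nb, prior, alpha=alpha)
    out = pd.DataFrame({"marker": marker, "inconsistent": incons,
                        "neighbor": neigh})
    out["doublet"] = out.any(axis=1)
    return out
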