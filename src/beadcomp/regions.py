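"""Cross-puck tissue region discovery.

Regions are sets of beads with similar expression-program activity that
are also spatially coherent.  A spatial k-NN graph is built per puck (no
cross-puck spatial edges) and an expression k-NN graph across all pucks on
the square-rooted program weights — Euclidean proximity on √weights ranks
neighbours by the Bhattacharyya coefficient Σ√(p_i q_i) — and the Leiden
algorithm is run on the weighted sum

    w · A_spatial + (1 − w) · A_expression

of the binary, union-symmetrized adjacencies.  Because expression edges
cross pucks, transcriptionally matching beads on different pucks land in
the same region despite infinite spatial distance.
"""

from __future__ import annotations

import dataclasses
import logging

import anndata as ad
import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import cKDTree
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RegionParams:
    position_weight: float = 0.7
    resolution: float = 1.3
    k_neighbors: int = 15
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.position_weight <= 1):
            raise ValueError("position_weight must be in [0, 1]")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def _knn_adjacency(X: np.ndarray, k: int) -> sp.csr_matrix:
    """Binary kNN adjacency, symmetrized by union, self-edges excluded."""
    n = len(X)
    k = min(k, n - 1)
    if k < 1:
        return sp.csr_matrix((n, n))
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    rows = np.repeat(np.arange(n), k)
    cols = idx[:, 1:].ravel()
    A = sp.csr_matrix((np.ones(n * k), (rows, cols)), shape=(n, n))
    A = A.maximum(A.T)
    return A


class RegionModel:
    """Joint spatial + program-similarity clustering of beads.

    Parameters
    ----------
    beads : AnnData with obsm['spatial'] and obs['puck']; should already be
        restricted to beads carrying the relevant compartment annotation.
    program_composition : beads × programs DataFrame, rows summing to 1.
    params : :class:`RegionParams`.
    """

    def __init__(self, beads: ad.AnnData, program_composition: pd.DataFrame,
                 params: RegionParams | None = None):
        self.params = params or RegionParams()
        comp = program_composition.reindex(beads.obs_names).dropna()
        self.bead_names = comp.index
        self.comp = comp.to_numpy(dtype=float)
        sums = self.comp.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("program composition rows must sum to 1")
        sub = beads[comp.index]
        self.coords = np.asarray(sub.obsm["spatial"], dtype=float)
        self.pucks = sub.obs["puck"].to_numpy()

    def fit(self) -> "RegionResult":
        p = self.params
        n = len(self.bead_names)
        if n == 1:
            logger.warning("single bead: trivial single region")
            labels = pd.Series([0], index=self.bead_names, name="region")
            return RegionResult(self, labels)
        A_space = sp.csr_matrix((n, n))
        for puck in pd.unique(self.pucks):
            m = np.flatnonzero(self.pucks == puck)
            A = _knn_adjacency(self.coords[m], p.k_neighbors)
            A = A.tocoo()
            A_space += sp.csr_matrix((A.data, (m[A.row], m[A.col])), shape=(n, n))
        A_expr = _knn_adjacency(np.sqrt(self.comp), p.k_neighbors)
        combined = (p.position_weight * A_space
                    + (1 - p.position_weight) * A_expr).tocoo()
        g = igraph.Graph(n=n, edges=list(zip(combined.row, combined.col)),
                         edge_attrs={"weight": combined.data.tolist()},
                         directed=False)
        part = leidenalg.find_partition(
            g, leidenalg.RBConfigurationVertexPartition,
            weights="weight", resolution_parameter=p.resolution, seed=p.seed)
        labels = pd.Series(part.membership, index=self.bead_names, name="region")
        return RegionResult(self, labels)


class RegionResult:
    def __init__(self, model: RegionModel, labels: pd.Series):
        self.model = model
        self.labels = labels

    def extend(self, all_beads: ad.AnnData) -> pd.Series:
        return extend_regions(all_beads, self.labels)

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame({"region": self.labels,
                           "puck": self.model.pucks})
        out = df.groupby(["region", "puck"]).size().rename("n_beads").reset_index()
        out.attrs["n_regions"] = int(self.labels.nunique())
        return out


def find_regions(beads: ad.AnnData, program_composition: pd.DataFrame,
                 params: RegionParams | None = None) -> pd.Series:
    """Functional wrapper around :class:`RegionModel`."""
    return RegionModel(beads, program_composition, params).fit().labels


def extend_regions(all_beads: ad.AnnData, labels: pd.Series) -> pd.Series:
    """Assign unlabelled beads the region of the nearest labelled bead on
    the same puck; exact distance ties go to the smallest bead id."""
    coords = np.asarray(all_beads.obsm["spatial"], dtype=float)
    pucks = all_beads.obs["puck"].to_numpy()
    out = labels.reindex(all_beads.obs_names)
    names = all_beads.obs_names.to_numpy()
    labeled_mask = out.notna().to_numpy()
    for p in pd.unique(pucks):
        m = pucks == p
        lab = np.flatnonzero(m & labeled_mask)
        unl = np.flatnonzero(m & ~labeled_mask)
        if len(unl) == 0:
            continue
        if len(lab) == 0:
            logger.warning("puck %s has no labelled beads; left unlabelled", p)
            continue
        # labelled beads in bead-id order so index ties resolve to smallest id
        lab = lab[np.argsort(names[lab])]
        tree = cKDTree(coords[lab])
        d, _ = tree.query(coords[unl])
        for ui, di in zip(unl, d):
            cand = tree.query_ball_point(coords[ui], di * (1 + 1e-9) + 1e-9)
            winner = lab[min(cand)]
            out.iloc[ui] = out.iloc[winner]
    return out.rename("region")


def region_distance_profile(beads: ad.AnnData, labels: pd.Series, landmark,
                            composition: pd.DataFrame,
                            max_distance: float = 1000.0,
                            delta_distance: float = 10.0) -> pd.DataFrame:
    """Mean composition as a function of distance from a landmark region.

    Per bead the Euclidean distance to the nearest landmark-labelled bead
    on the same puck (censored at ``max_distance``); per half-open distance
    bin, the mean composition over categories.  Long format:
    (category, bin_center_um, value, n_beads)."""
    lab = labels.reindex(beads.obs_names)
    comp = composition.reindex(beads.obs_names)
    coords = np.asarray(beads.obsm["spatial"], dtype=float)
    pucks = beads.obs["puck"].to_numpy()
    dist = np.full(beads.n_obs, np.nan)
    for p in pd.unique(pucks):
        m = np.flatnonzero(pucks == p)
        lm = m[(lab.iloc[m] == landmark).to_numpy()]
        if len(lm) == 0:
            logger.warning("landmark absent on puck %s; skipped", p)
            continue
        tree = cKDTree(coords[lm])
        d, _ = tree.query(coords[m])
        dist[m] = np.minimum(d, max_distance)
    ok = ~np.isnan(dist) & comp.notna().all(axis=1).to_numpy()
    bins = np.minimum((dist[ok] / delta_distance).astype(int),
                      int(np.ceil(max_distance / delta_distance)) - 1)
    rows = []
    C = comp.to_numpy()[ok]
    for b in np.unique(bins):
        sel = bins == b
        center = (b + 0.5) * delta_distance
        means = C[sel].mean(axis=0)
        for ci, c in enumerate(composition.columns):
            rows.append((c, center, means[ci], int(sel.sum())))
    return pd.DataFrame(rows, columns=["category", "bin_center_um", "value",
                                       "n_beads"])
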