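"""Permutation neighborship statistics and distance-resolved co-occurrence.

Beads on a puck are not independent observations; local cell-type
co-location is therefore tested against a permutation null that shuffles
whole composition rows across beads within each puck (coordinates fixed),
which preserves both the spatial geometry and the per-puck composition
margins.  The neighborship z-score of categories (a, b) compares the
observed co-location mass within ``max_distance`` to the permutation
mean/sd.  Distances are Euclidean in µm; pairs never cross pucks.
"""

from __future__ import annotations

import dataclasses
import itertools
import math

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import cKDTree

from ._utils import as_rng, split_seed


@dataclasses.dataclass
class NeighborshipResult:
    z: pd.DataFrame                    # categories × categories, NaN = missing
    observed: pd.DataFrame
    perm_mean: pd.DataFrame
    perm_sd: pd.DataFrame
    max_distance: float
    n_permutations: int

    def summary(self) -> pd.DataFrame:
        long = self.z.stack(future_stack=True).rename("z").reset_index()
        long.columns = ["category_a", "category_b", "z"]
        return long


def filter_categories(composition: pd.DataFrame, beads: ad.AnnData | None = None,
                      min_fraction: float = 0.01) -> pd.DataFrame:
    """Keep only categories accounting for at least ``min_fraction`` of the
    total annotation mass (UMI-weighted if bead totals are available)."""
    if beads is not None:
        w = np.asarray(beads[composition.index].X.sum(axis=1)).ravel()
        mass = composition.mul(w, axis=0).sum(axis=0)
    else:
        mass = composition.sum(axis=0)
    frac = mass / mass.sum()
    return composition.loc[:, frac >= min_fraction]


def _pair_adjacency(coords: np.ndarray, max_distance: float) -> sp.csr_matrix:
    """Symmetric binary adjacency of bead pairs within max_distance
    (self-pairs excluded)."""
    tree = cKDTree(coords)
    pairs = tree.query_pairs(max_distance, output_type="ndarray")
    n = len(coords)
    if len(pairs) == 0:
        return sp.csr_matrix((n, n))
    i, j = pairs[:, 0], pairs[:, 1]
    data = np.ones(2 * len(pairs))
    A = sp.csr_matrix((data, (np.r_[i, j], np.r_[j, i])), shape=(n, n))
    return A


def _neighborship_mass(A: sp.csr_matrix, F: np.ndarray) -> np.ndarray:
    """Σ over unordered pairs of f_a(i)f_b(j)+f_b(i)f_a(j); computed as
    Fᵀ A F with the symmetric adjacency (each unordered pair counted in
    both orders)."""
    return F.T @ (A @ F)


def neighborship_z(beads: ad.AnnData, composition: pd.DataFrame,
                   max_distance: float = 20.0, n_permutations: int = 10,
                   seed: int = 0, method: str = "random") -> NeighborshipResult:
    """Neighborhood-enrichment z-scores on fractional annotations.

    ``method='exhaustive'`` enumerates all row permutations (feasible only
    for tiny inputs) instead of sampling ``n_permutations`` of them.
    """
    comp = composition.reindex(beads.obs_names).dropna()
    cats = list(comp.columns)
    coords = np.asarray(beads[comp.index].obsm["spatial"], dtype=float)
    pucks = beads[comp.index].obs["puck"].to_numpy()
    F = comp.to_numpy()

    puck_ids = pd.unique(pucks)
    adj = {}
    for p in puck_ids:
        m = pucks == p
        adj[p] = (_pair_adjacency(coords[m], max_distance), np.flatnonzero(m))

    def total_mass(Fm: np.ndarray) -> np.ndarray:
        out = np.zeros((len(cats), len(cats)))
        for p in puck_ids:
            A, idx = adj[p]
            out += _neighborship_mass(A, Fm[idx])
        return out

    observed = total_mass(F)
    if method == "exhaustive":
        if len(puck_ids) != 1:
            raise ValueError("exhaustive enumeration supports a single puck")
        n = F.shape[0]
        if math.factorial(n) > 50000:
            raise ValueError("too many beads for exhaustive enumeration")
        perms = np.array([total_mass(F[list(p)])
                          for p in itertools.permutations(range(n))])
        mean, sd = perms.mean(axis=0), perms.std(axis=0, ddof=1)
        n_used = perms.shape[0]
    else:
        samples = np.empty((n_permutations, len(cats), len(cats)))
        for r in range(n_permutations):
            Fp = F.copy()
            for p in puck_ids:
                rng = as_rng(split_seed(seed, f"perm{r}", str(p)))
                _, idx = adj[p]
                Fp[idx] = F[idx][rng.permutation(len(idx))]
            samples[r] = total_mass(Fp)
        mean, sd = samples.mean(axis=0), samples.std(axis=0, ddof=1)
        n_used = n_permutations

    with np.errstate(divide="ignore", invalid="ignore"):
        z = (observed - mean) / sd
    z[sd == 0] = np.nan
    wrap = lambda M: pd.DataFrame(M, index=cats, columns=cats)
    return NeighborshipResult(wrap(z), wrap(observed), wrap(mean), wrap(sd),
                              max_distance, n_used)


# ---------------------------------------------------------------------------
# distance-resolved co-occurrence
# ---------------------------------------------------------------------------

def co_occurrence(beads: ad.AnnData, composition: pd.DataFrame,
                  delta_distance: float = 20.0, max_distance: float = 1000.0
                  ) -> pd.DataFrame:
    """Co-occurrence of annotation categories as a function of distance.

    For distance bin d (half-open, width ``delta_distance``):
        cooc(a, b, d) = [Σ_pairs f_a(i) f_b(j) / Σ_pairs f_b(j)] / mean(f_a)
    over ordered within-puck pairs with distance in the bin.  Returned in
    long format (category_a, category_b, bin_center_um, value); empty bins
    are absent.
    """
    comp = composition.reindex(beads.obs_names).dropna()
    if len(comp) < 2:
        raise ValueError("need at least 2 beads")
    cats = list(comp.columns)
    F = comp.to_numpy()
    coords = np.asarray(beads[comp.index].obsm["spatial"], dtype=float)
    pucks = beads[comp.index].obs["puck"].to_numpy()
    mean_f = F.mean(axis=0)

    n_bins = int(np.ceil(max_distance / delta_distance))
    num = np.zeros((n_bins, len(cats), len(cats)))
    den = np.zeros((n_bins, len(cats)))
    filled = np.zeros(n_bins, dtype=bool)
    for p in pd.unique(pucks):
        m = pucks == p
        xy = coords[m]
        Fm = F[m]
        tree = cKDTree(xy)
        pairs = tree.query_pairs(max_distance * (1 + 1e-12), output_type="ndarray")
        if len(pairs) == 0:
            continue
        d = np.linalg.norm(xy[pairs[:, 0]] - xy[pairs[:, 1]], axis=1)
        bins = np.minimum((d / delta_distance).astype(int), n_bins - 1)
        keep = d < max_distance
        for b in np.unique(bins[keep]):
            sel = pairs[keep][bins[keep] == b]
            i, j = np.r_[sel[:, 0], sel[:, 1]], np.r_[sel[:, 1], sel[:, 0]]
            num[b] += Fm[i].T @ Fm[j]
            den[b] += Fm[j].sum(axis=0)
            filled[b] = True

    rows = []
    for b in range(n_bins):
        if not filled[b]:
            continue
        center = (b + 0.5) * delta_distance
        for ai, a in enumerate(cats):
            for bi, bcat in enumerate(cats):
                if den[b, bi] > 0 and mean_f[ai] > 0:
                    v = num[b, ai, bi] / den[b, bi] / mean_f[ai]
                    rows.append((a, bcat, center, v))
    return pd.DataFrame(rows, columns=["category_a", "category_b",
                                       "bin_center_um", "value"])


def annotation_distance(beads: ad.AnnData, composition: pd.DataFrame,
                        target: str, max_distance: float = 100.0,
                        delta_distance: float = 10.0,
                        critical_neighbourhood_size: float = 4.0) -> pd.Series:
    """Per-bead distance to a target annotation.

    The smallest binned radius at which the cumulative target-category
    annotation mass within that radius reaches
    ``critical_neighbourhood_size``; a bead whose own target mass already
    reaches it gets 0; beads never reaching it within ``max_distance`` are
    censored at ``max_distance``.
    """
    if critical_neighbourhood_size <= 0:
        raise ValueError("critical_neighbourhood_size must be positive")
    if target not in composition.columns:
        raise KeyError(f"target category {target!r} not present")
    comp = composition.reindex(beads.obs_names).dropna()
    f = comp[target].to_numpy()
    coords = np.asarray(beads[comp.index].obsm["spatial"], dtype=float)
    pucks = beads[comp.index].obs["puck"].to_numpy()
    n_bins = int(np.ceil(max_distance / delta_distance))
    out = np.full(len(comp), float(max_distance))
    for p in pd.unique(pucks):
        m = np.flatnonzero(pucks == p)
        xy = coords[m]
        tree = cKDTree(xy)
        # cumulative target mass per radius k·Δ
        cum = np.tile(f[m][:, None], (1, n_bins + 1)) * 0.0
        cum[:, 0] = f[m]
        pairs = tree.query_pairs(max_distance * (1 + 1e-12), output_type="ndarray")
        if len(pairs):
            d = np.linalg.norm(xy[pairs[:, 0]] - xy[pairs[:, 1]], axis=1)
            k = np.minimum(np.floor(d / delta_distance).astype(int) + 1, n_bins)
            keep = d < n_bins * delta_distance
            for (i, j), kk in zip(pairs[keep], k[keep]):
                cum[i, kk] += f[m][j]
                cum[j, kk] += f[m][i]
        cum = np.cumsum(cum, axis=1)
        reached = cum >= critical_neighbourhood_size
        first = np.where(reached.any(axis=1), reached.argmax(axis=1), n_bins + 1)
        dist = np.where(first <= n_bins, first * delta_distance, max_distance)
        out[m] = np.minimum(dist, max_distance)
    return pd.Series(out, index=comp.index, name=f"distance_to_{target}")


def restrict_by_distance(beads: ad.AnnData, distance: pd.Series,
                         min_distance: float = 75.0) -> ad.AnnData:
    """Subset to beads at least ``min_distance`` µm from the annotation
    (censored beads count as far and are kept)."""
    keep = distance.reindex(beads.obs_names) >= min_distance
    return beads[keep.fillna(False).to_numpy()].copy()
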