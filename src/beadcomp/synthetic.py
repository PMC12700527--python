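"""Synthetic tissue and reference generators with known ground truth.

Everything downstream — compositional bead annotation, region discovery,
neighborship statistics, cross-species mapping — is exercised on data from
this module, so each generator returns its ground truth alongside the
simulated measurements.

The generative model is deliberately simple: cell types are multinomial
expression profiles, beads are Poisson draws from depth-scaled mixtures of
those profiles, batch effects are per-gene multiplicative factors, and
spatial nuisance signals are Gaussian random fields.  Counts are Poisson
rather than negative binomial: in the sparse bead regime the two are close,
and Poisson keeps the oracles analytic.  An optional gamma mixing switch
adds overdispersion for robustness checks.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd

from ._utils import as_rng, dense_counts, row_normalize


# ---------------------------------------------------------------------------
# specs and ground truth
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class LayerSpec:
    """One horizontal tissue layer: a y-depth band with fixed mixtures.

    ``type_mixture`` gives the expected fraction of bead reads contributed by
    each cell type; ``program_mixture`` (optional) is the analogous mixture
    over expression programs used when beads are generated from program
    loadings instead of type profiles.
    """

    y_range: tuple[float, float]
    type_mixture: Mapping[str, float]
    program_mixture: Mapping[str, float] | None = None


@dataclasses.dataclass
class TissueSpec:
    """Layout of a multi-puck layered synthetic tissue.

    Parameters
    ----------
    n_pucks : number of replicate pucks to generate.
    puck_extent : (x, y) size in µm.
    bead_spacing : grid spacing in µm (beads sit on a square grid).
    layers : ordered list of LayerSpec tiling the y extent without overlap.
    doublet_rate : fraction of beads whose expected profile is contaminated
        by a second, randomly chosen layer.
    depth : expected total counts per bead.
    seed : RNG seed.
    """

    n_pucks: int = 1
    puck_extent: tuple[float, float] = (2000.0, 1000.0)
    bead_spacing: float = 50.0
    layers: Sequence[LayerSpec] = ()
    doublet_rate: float = 0.0
    depth: float = 500.0
    seed: int = 0
    jitter: float = 0.0

    def validate(self) -> None:
        if not self.layers:
            raise ValueError("TissueSpec requires at least one layer")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not (0 <= self.doublet_rate <= 1):
            raise ValueError("doublet_rate must be in [0, 1]")
        lo = 0.0
        for layer in self.layers:
            a, b = layer.y_range
            if not np.isclose(a, lo):
                raise ValueError("layer y ranges must tile the puck without overlap")
            if b <= a:
                raise ValueError("layer y range must be increasing")
            lo = b
            tot = sum(layer.type_mixture.values())
            if any(v < 0 for v in layer.type_mixture.values()) or not np.isclose(tot, 1.0):
                raise ValueError("type mixtures must be non-negative and sum to 1")
        if not np.isclose(lo, self.puck_extent[1]):
            raise ValueError("layers must tile the full y extent")


@dataclasses.dataclass
class GroundTruth:
    """Truth accompanying a synthetic puck: what the estimators should find."""

    composition: pd.DataFrame          # beads x types, rows sum to 1
    region: pd.Series                  # per-bead layer index (region label)
    doublet: pd.Series                 # per-bead contamination flag
    program_composition: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# reference single-cell data
# ---------------------------------------------------------------------------

def make_type_profiles(n_types: int, n_genes: int, seed=0,
                       marker_boost: float = 20.0) -> pd.DataFrame:
    """Distinct multinomial expression profiles, one per cell type.

    Each type gets a dedicated block of marker genes with ``marker_boost``-fold
    elevated intensity on top of a shared random background, which keeps
    pairwise cosine similarity well below 0.95 for any reasonable size.
    """
    if n_types < 2:
        raise ValueError("need at least 2 types")
    if n_genes < n_types:
        raise ValueError("need n_genes >= n_types")
    rng = as_rng(seed)
    base = rng.gamma(2.0, 1.0, size=(n_types, n_genes))
    block = n_genes // n_types
    for t in range(n_types):
        base[t, t * block:(t + 1) * block] *= marker_boost
    profiles = row_normalize(base)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    types = [f"type{t}" for t in range(n_types)]
    df = pd.DataFrame(profiles, index=types, columns=genes)
    # enforce the distinctness contract
    P = df.to_numpy()
    C = (P @ P.T) / np.outer(np.linalg.norm(P, axis=1), np.linalg.norm(P, axis=1))
    np.fill_diagonal(C, 0)
    if C.max() >= 0.95:
        raise RuntimeError("generated profiles are not distinct enough")
    return df


def make_reference(n_types: int, n_genes: int, n_cells_per_type: int,
                   depth: float = 1000.0,
                   batch_factors: Mapping[str, np.ndarray] | None = None,
                   seed: int = 0, overdispersion: float = 0.0) -> ad.AnnData:
    """Simulate a single-cell reference: Poisson counts from type profiles.

    Each cell's counts are Poisson(depth * batch_factor ⊙ profile(type)).
    ``batch_factors`` maps batch name -> per-gene multiplicative factor;
    cells are distributed evenly across batches.  ``overdispersion`` > 0
    switches on gamma mixing with that squared coefficient of variation.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if n_types < 2:
        raise ValueError("need at least 2 types")
    rng = as_rng(seed)
    profiles = make_type_profiles(n_types, n_genes, seed=rng)
    if batch_factors is None:
        batch_factors = {"batch0": np.ones(n_genes)}
    batches = sorted(batch_factors)
    n_cells = n_types * n_cells_per_type
    type_of = np.repeat(np.arange(n_types), n_cells_per_type)
    batch_of = np.array([batches[i % len(batches)] for i in range(n_cells)])
    lam = np.empty((n_cells, n_genes))
    P = profiles.to_numpy()
    for i in range(n_cells):
        lam[i] = depth * np.asarray(batch_factors[batch_of[i]]) * P[type_of[i]]
    if overdispersion > 0:
        shape = 1.0 / overdispersion
        lam = lam * rng.gamma(shape, 1.0 / shape, size=lam.shape)
    X = rng.poisson(lam).astype(np.float64)
    obs = pd.DataFrame({
        "cell_type": profiles.index.to_numpy()[type_of],
        "batch": batch_of,
        "sample": batch_of,
    }, index=[f"cell{i:05d}" for i in range(n_cells)])
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=profiles.columns))
    adata.uns["true_profiles"] = profiles
    return adata


def plant_doublets(reference: ad.AnnData, rate: float, seed: int = 0) -> ad.AnnData:
    """Replace a fraction of cells with simulated doublets.

    A doublet is the sum of two randomly drawn cells' counts, halved and
    re-Poissonized, which preserves the depth distribution.  The truth is
    recorded in ``obs['is_doublet']`` (and the second contributing type in
    ``obs['doublet_partner_type']``).
    """
    if not (0 <= rate <= 1):
        raise ValueError("rate must be in [0, 1]")
    rng = as_rng(seed)
    n = reference.n_obs
    X = dense_counts(reference)
    out = reference.copy()
    flags = np.zeros(n, dtype=bool)
    partner = np.array([""] * n, dtype=object)
    n_dbl = int(round(rate * n))
    idx = rng.choice(n, size=n_dbl, replace=False)
    for i in idx:
        j = int(rng.integers(n))
        lam = 0.5 * (X[i] + X[j])
        out.X[i] = rng.poisson(lam).astype(np.float64)
        flags[i] = True
        partner[i] = str(reference.obs["cell_type"].iloc[j])
    out.obs["is_doublet"] = flags
    out.obs["doublet_partner_type"] = partner
    return out


# ---------------------------------------------------------------------------
# spatial pucks
# ---------------------------------------------------------------------------

def _grid(extent: tuple[float, float], spacing: float) -> np.ndarray:
    nx = int(np.floor(extent[0] / spacing + 1e-9)) + 1
    ny = int(np.floor(extent[1] / spacing + 1e-9)) + 1
    xs = np.arange(nx) * spacing
    ys = np.arange(ny) * spacing
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    return np.column_stack([xx.ravel(), yy.ravel()])


def make_layered_puck(spec: TissueSpec, reference: ad.AnnData
                      ) -> tuple[ad.AnnData, GroundTruth]:
    """Simulate layered pucks: grid beads drawing Poisson counts from the
    depth-scaled type-profile mixture of their layer.

    Returns the bead table (AnnData with obsm['spatial'] in µm and
    obs['puck']) and the ground truth.
    """
    spec.validate()
    rng = as_rng(spec.seed)
    profiles: pd.DataFrame = reference.uns["true_profiles"]
    types = list(profiles.index)
    for layer in spec.layers:
        unknown = set(layer.type_mixture) - set(types)
        if unknown:
            raise ValueError(f"mixture references unknown types: {sorted(unknown)}")
    P = profiles.to_numpy()
    coords_one = _grid(spec.puck_extent, spec.bead_spacing)
    n_per_puck = len(coords_one)

    all_X, all_coords, all_puck, all_comp, all_region, all_dbl = [], [], [], [], [], []
    for p in range(spec.n_pucks):
        coords = coords_one.copy()
        if spec.jitter > 0:
            coords = coords + rng.normal(0, spec.jitter, size=coords.shape)
        layer_idx = np.zeros(n_per_puck, dtype=int)
        for li, layer in enumerate(spec.layers):
            a, b = layer.y_range
            in_layer = (coords_one[:, 1] >= a) & (coords_one[:, 1] < b)
            layer_idx[in_layer] = li
        # top boundary belongs to the last layer
        layer_idx[np.isclose(coords_one[:, 1], spec.puck_extent[1])] = len(spec.layers) - 1

        mix = np.zeros((n_per_puck, len(types)))
        for li, layer in enumerate(spec.layers):
            m = np.array([layer.type_mixture.get(t, 0.0) for t in types])
            mix[layer_idx == li] = m
        dbl = rng.random(n_per_puck) < spec.doublet_rate
        if dbl.any() and len(spec.layers) > 1:
            for i in np.flatnonzero(dbl):
                other = int(rng.integers(len(spec.layers)))
                m2 = np.array([spec.layers[other].type_mixture.get(t, 0.0) for t in types])
                mix[i] = 0.5 * (mix[i] + m2)
        lam = spec.depth * (mix @ P)
        X = rng.poisson(lam).astype(np.float64)
        all_X.append(X)
        all_coords.append(coords)
        all_puck.append(np.repeat(f"puck{p}", n_per_puck))
        all_comp.append(mix)
        all_region.append(layer_idx)
        all_dbl.append(dbl)

    X = np.vstack(all_X)
    bead_ids = [f"bead{i:06d}" for i in range(X.shape[0])]
    obs = pd.DataFrame({"puck": np.concatenate(all_puck)}, index=bead_ids)
    beads = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=profiles.columns))
    beads.obsm["spatial"] = np.vstack(all_coords)
    comp = pd.DataFrame(np.vstack(all_comp), index=bead_ids, columns=types)
    truth = GroundTruth(
        composition=comp,
        region=pd.Series(np.concatenate(all_region), index=bead_ids, name="region"),
        doublet=pd.Series(np.concatenate(all_dbl), index=bead_ids, name="doublet"),
    )
    return beads, truth


def make_autocorrelated_field(beads: ad.AnnData, length_scale_um: float,
                              seed: int = 0) -> pd.Series:
    """Zero-mean, unit-variance Gaussian random field over bead positions.

    Squared-exponential covariance exp(-d² / (2ℓ²)), sampled exactly via
    Cholesky, independently per puck.  In the ℓ→0 limit this is white noise;
    for ℓ much larger than the puck it is nearly constant per puck.
    """
    if length_scale_um <= 0:
        raise ValueError("length_scale must be positive")
    if beads.n_obs < 2:
        raise ValueError("need at least 2 beads")
    rng = as_rng(seed)
    coords = np.asarray(beads.obsm["spatial"], dtype=float)
    pucks = beads.obs["puck"].to_numpy()
    out = np.empty(beads.n_obs)
    for p in pd.unique(pucks):
        m = pucks == p
        xy = coords[m]
        d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
        K = np.exp(-d2 / (2 * length_scale_um**2))
        K[np.diag_indices_from(K)] += 1e-8
        L = np.linalg.cholesky(K)
        out[m] = L @ rng.standard_normal(m.sum())
    return pd.Series(out, index=beads.obs_names, name="field")


# ---------------------------------------------------------------------------
# cross-species fixture
# ---------------------------------------------------------------------------

def make_species_pair(reference: ad.AnnData, drop_fraction: float = 0.0,
                      seed: int = 0, rename_map: Mapping[str, str] | None = None,
                      n_synonyms: int = 2
                      ) -> tuple[ad.AnnData, ad.AnnData, pd.DataFrame]:
    """Create a renamed copy of a reference emulating a second species.

    The second table uses an uppercased gene vocabulary (the human-symbol
    convention) unless an explicit injective ``rename_map`` is given.  The
    returned ortholog table has one row per mapped gene pair, with columns
    ``source`` (original symbol), ``target`` (renamed symbol), ``class_key``
    and a pipe-separated ``synonyms`` column for the renamed symbol;
    ``drop_fraction`` of genes are omitted from the table (no ortholog).
    """
    if not (0 <= drop_fraction <= 1):
        raise ValueError("drop_fraction must be in [0, 1]")
    rng = as_rng(seed)
    genes = list(reference.var_names)
    if rename_map is None:
        rename_map = {g: g.upper() + "H" for g in genes}
    vals = [rename_map[g] for g in genes]
    if len(set(vals)) != len(vals):
        raise ValueError("rename_map must be injective on kept genes")
    other = reference.copy()
    other.var_names = pd.Index(vals)
    if "true_profiles" in other.uns:
        other.uns["true_profiles"] = other.uns["true_profiles"].rename(columns=rename_map)

    n_drop = int(round(drop_fraction * len(genes)))
    dropped = set(rng.choice(len(genes), size=n_drop, replace=False).tolist())
    rows = []
    for i, g in enumerate(genes):
        if i in dropped:
            continue
        syn = "|".join(f"{rename_map[g]}-S{s}" for s in range(n_synonyms))
        rows.append({"class_key": i, "source": g, "target": rename_map[g],
                     "synonyms": syn})
    table = pd.DataFrame(rows, columns=["class_key", "source", "target", "synonyms"])
    return reference, other, table


def hom_report_from_pairs(pairs: pd.DataFrame, source_organism: str = "mouse",
                          target_organism: str = "human") -> pd.DataFrame:
    """Render a pair table in the MGI HOM report dialect (two lines per pair).

    Columns follow the report: 'DB Class Key', 'Common Organism Name',
    'Symbol', 'Synonyms'.  This is the on-disk interchange format; the pair
    table is the in-memory one.
    """
    recs = []
    for _, r in pairs.iterrows():
        recs.append({"DB Class Key": r["class_key"],
                     "Common Organism Name": f"{source_organism}, laboratory",
                     "Symbol": r["source"], "Synonyms": ""})
        recs.append({"DB Class Key": r["class_key"],
                     "Common Organism Name": target_organism,
                     "Symbol": r["target"], "Synonyms": r.get("synonyms", "")})
    return pd.DataFrame(recs, columns=["DB Class Key", "Common Organism Name",
                                       "Symbol", "Synonyms"])
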