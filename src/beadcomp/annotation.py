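"""Compositional bead annotation via entropic unbalanced optimal transport.

Each bead captures reads from several cells, so annotation assigns every
bead a probability vector over reference categories (cell clusters or
expression programs) instead of a single label.  The assignment is phrased
as a transport problem between the bead read-mass distribution and the
category mass distribution (reference prior frequencies):

    min_P  <C, P>  +  ε KL(P | a ⊗ b)  +  ρ KL(Pᵀ1 | b)    s.t.  P 1 = a

where C(i, c) = 1 − cosine(bead profile i, category profile c), a is the
per-bead read mass, b the category prior.  The bead marginal is exact
(every read must come from somewhere); the category marginal is relaxed by
a KL penalty with weight ρ (``lambda_relax``) — larger ρ means tighter
adherence to the reference frequencies, ρ→0 lets the tissue's category
frequencies float freely (the "unbalanced" part).  ε is the entropic
smoothing.  Solved by log-domain Sinkhorn iterations.

Bisectioning improves sensitivity to minor contributions: per round only a
fraction (divisor−1)/divisor of each bead's transported mass is committed,
the committed reconstruction is subtracted from the bead profile (clipped
at 0), and the next round annotates the residual; the final round commits
everything.
"""

from __future__ import annotations

import dataclasses
import logging

import anndata as ad
import numpy as np
import pandas as pd
from scipy.special import logsumexp

from ._utils import dense_counts, row_normalize

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class OTParams:
    """Entropic unbalanced OT parameters.

    Defaults are the bead-annotation settings: ε=0.005, ρ=0.001, four
    rounds of bisectioning with divisor 3.  Program annotation uses
    ε=0.01, ρ=0.001 and no bisectioning (see :func:`program_params`).
    """

    epsilon: float = 0.005
    lambda_relax: float = 0.001
    n_bisections: int = 4
    divisor: int = 3
    max_iter: int = 500
    tol: float = 1e-9

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.lambda_relax < 0:
            raise ValueError("lambda_relax must be non-negative")
        if self.divisor < 2:
            raise ValueError("divisor must be at least 2")


def program_params(**kw) -> OTParams:
    """OT parameters for epithelial-program annotation.

    ε=0.01, ρ=0.001, and the same 4÷3 bisectioning as bead annotation:
    without bisectioning the near-orthogonal program profiles collapse to
    hard per-bead assignments and fractional program activity cannot be
    recovered."""
    defaults = dict(epsilon=0.01, lambda_relax=0.001, n_bisections=4, divisor=3)
    defaults.update(kw)
    return OTParams(**defaults)


@dataclasses.dataclass
class ReferenceProfiles:
    """Category mean-expression profiles (rows sum to 1) plus prior
    frequencies (sum to 1)."""

    profiles: pd.DataFrame
    priors: pd.Series | None = None

    def __post_init__(self):
        P = self.profiles.to_numpy(dtype=float)
        if P.min() < 0:
            raise ValueError("profiles must be non-negative")
        self.profiles = pd.DataFrame(row_normalize(P), index=self.profiles.index,
                                     columns=self.profiles.columns)
        if self.priors is None:
            self.priors = pd.Series(1.0 / len(self.profiles),
                                    index=self.profiles.index)
        else:
            self.priors = self.priors.reindex(self.profiles.index)
            self.priors = self.priors / self.priors.sum()

    @classmethod
    def from_reference(cls, adata: ad.AnnData, type_key: str = "cell_type"
                       ) -> "ReferenceProfiles":
        """Mean profile and frequency of each category in a labelled
        single-cell table."""
        X = dense_counts(adata)
        labels = adata.obs[type_key]
        cats = sorted(labels.unique())
        prof = np.vstack([X[(labels == c).to_numpy()].sum(axis=0) for c in cats])
        priors = pd.Series([float((labels == c).mean()) for c in cats], index=cats)
        return cls(pd.DataFrame(prof, index=cats, columns=adata.var_names), priors)


# ---------------------------------------------------------------------------
# platform normalization
# ---------------------------------------------------------------------------

def platform_normalize(reference: ReferenceProfiles, target_pseudobulk: pd.Series,
                       clip: float = 100.0) -> pd.Series:
    """Per-gene scale factors matching the reference pseudo-bulk to the
    target platform's gene fractions.

    factor_g = (target gene fraction) / (reference pseudo-bulk gene
    fraction); genes absent from the target get factor 0 (effectively
    ignored), genes absent from the reference keep factor 1; factors are
    clipped at ``clip`` to keep single genes from dominating.
    """
    genes = reference.profiles.columns
    shared = genes.intersection(target_pseudobulk.index)
    if len(shared) == 0:
        raise ValueError("reference and target share no genes")
    ref_pb = (reference.profiles.to_numpy() *
              reference.priors.to_numpy()[:, None]).sum(axis=0)
    ref_frac = pd.Series(ref_pb / ref_pb.sum(), index=genes)
    tgt = target_pseudobulk.reindex(genes).fillna(0.0)
    tgt_frac = tgt / tgt.sum()
    factors = pd.Series(0.0, index=genes)
    nz = ref_frac > 0
    factors[nz] = (tgt_frac[nz] / ref_frac[nz]).clip(upper=clip)
    factors[~nz] = 1.0
    return factors


def apply_platform_normalization(reference: ReferenceProfiles,
                                 factors: pd.Series) -> ReferenceProfiles:
    scaled = reference.profiles * factors.reindex(reference.profiles.columns).to_numpy()
    return ReferenceProfiles(scaled, reference.priors)


# ---------------------------------------------------------------------------
# Sinkhorn core
# ---------------------------------------------------------------------------

def _sinkhorn_semi_relaxed(C: np.ndarray, a: np.ndarray, b: np.ndarray,
                           epsilon: float, rho: float,
                           max_iter: int = 500, tol: float = 1e-9) -> np.ndarray:
    """Log-domain Sinkhorn for the semi-relaxed entropic problem.

    Exact row marginal a; column marginal relaxed around b with KL weight
    rho.  Returns the transport plan P (rows sum to a).
    """
    n, m = C.shape
    loga = np.log(np.maximum(a, 1e-300))
    logb = np.log(np.maximum(b, 1e-300))
    M = -C / epsilon                            # n × m
    f = np.zeros(n)
    g = np.zeros(m)
    exponent = rho / (rho + epsilon) if rho > 0 else 0.0
    for it in range(max_iter):
        f_new = -epsilon * logsumexp(M + (g / epsilon)[None, :] + logb[None, :], axis=1)
        g_new = -exponent * epsilon * logsumexp(
            M + (f_new / epsilon)[:, None] + loga[:, None], axis=0)
        delta = np.max(np.abs(f_new - f)) + np.max(np.abs(g_new - g))
        f, g = f_new, g_new
        if delta < tol:
            break
    # final exact row scaling so P 1 = a holds to machine precision
    logP = M + (f / epsilon)[:, None] + (g / epsilon)[None, :] \
        + loga[:, None] + logb[None, :]
    P = np.exp(logP)
    rows = P.sum(axis=1, keepdims=True)
    P = np.divide(P, rows, out=np.zeros_like(P), where=rows > 0) * a[:, None]
    return P


def _cosine_cost(bead_profiles: np.ndarray, cat_profiles: np.ndarray) -> np.ndarray:
    bn = np.linalg.norm(bead_profiles, axis=1, keepdims=True)
    cn = np.linalg.norm(cat_profiles, axis=1, keepdims=True)
    bn[bn == 0] = 1.0
    cn[cn == 0] = 1.0
    cos = (bead_profiles / bn) @ (cat_profiles / cn).T
    return 1.0 - np.clip(cos, -1.0, 1.0)


# ---------------------------------------------------------------------------
# annotation model
# ---------------------------------------------------------------------------

class OTAnnotationModel:
    """Compositional annotation of beads with reference categories.

    Parameters
    ----------
    beads : AnnData of bead counts (beads × genes).
    reference : :class:`ReferenceProfiles` (or a labelled AnnData, converted
        via ``ReferenceProfiles.from_reference``).
    params : :class:`OTParams`.
    platform_normalization : rescale the reference profiles to the bead
        pseudo-bulk's per-gene fractions before computing costs (default on).
    """

    def __init__(self, beads: ad.AnnData, reference, params: OTParams | None = None,
                 platform_normalization: bool = True, type_key: str = "cell_type"):
        if isinstance(reference, ad.AnnData):
            reference = ReferenceProfiles.from_reference(reference, type_key)
        self.params = params or OTParams()
        shared = reference.profiles.columns.intersection(beads.var_names)
        if len(shared) == 0:
            raise ValueError("beads and reference share no genes")
        self.genes = shared
        self.beads = beads
        X = dense_counts(beads[:, shared])
        keep = X.sum(axis=1) > 0
        if not keep.all():
            logger.warning("dropping %d all-zero beads", int((~keep).sum()))
        self.bead_names = beads.obs_names[keep]
        self.X = X[keep]
        ref = ReferenceProfiles(reference.profiles[shared], reference.priors)
        if platform_normalization:
            pseudo = pd.Series(self.X.sum(axis=0), index=shared)
            factors = platform_normalize(ref, pseudo)
            ref = apply_platform_normalization(ref, factors)
        self.reference = ref

    def fit(self) -> "AnnotationResult":
        p = self.params
        cat_profiles = self.reference.profiles.to_numpy()
        priors = self.reference.priors.to_numpy()
        residual = self.X.copy()
        committed = np.zeros((self.X.shape[0], len(priors)))
        total_mass = self.X.sum()
        for r in range(p.n_bisections):
            mass = residual.sum(axis=1)
            active = mass > 0
            if not active.any():
                break
            a = mass[active] / total_mass
            C = _cosine_cost(residual[active], cat_profiles)
            P = _sinkhorn_semi_relaxed(C, a, priors, p.epsilon, p.lambda_relax,
                                       max_iter=p.max_iter, tol=p.tol)
            frac = row_normalize(P)             # per-bead category fractions
            last = (r == p.n_bisections - 1)
            q = 1.0 if last else (p.divisor - 1) / p.divisor
            commit_mass = q * frac * mass[active][:, None]   # counts per category
            committed[active] += commit_mass
            if not last:
                recon = commit_mass @ cat_profiles
                residual[active] = np.maximum(residual[active] - recon, 0.0)
        composition = row_normalize(committed)
        comp = pd.DataFrame(composition, index=self.bead_names,
                            columns=self.reference.profiles.index)
        return AnnotationResult(self, comp)


class AnnotationResult:
    """Bead × category composition (rows sum to 1) plus count splitting."""

    def __init__(self, model: OTAnnotationModel, composition: pd.DataFrame):
        self.model = model
        self.composition = composition

    def dominant(self) -> pd.Series:
        """Per-bead highest-weight category."""
        return self.composition.idxmax(axis=1)

    def split_counts(self, compartment_of: dict | None = None,
                     min_compartment_counts: int = 50):
        return split_counts(self.model.beads[self.composition.index,
                                             self.model.genes],
                            self.composition, self.model.reference,
                            compartment_of=compartment_of,
                            min_compartment_counts=min_compartment_counts)

    def summary(self) -> pd.DataFrame:
        agg = self.composition.mean(axis=0).rename("mean_fraction").to_frame()
        agg["prior"] = self.model.reference.priors
        agg.attrs["n_beads"] = len(self.composition)
        agg.attrs["epsilon"] = self.model.params.epsilon
        agg.attrs["lambda_relax"] = self.model.params.lambda_relax
        return agg


def annotate_ot(beads: ad.AnnData, reference, params: OTParams | None = None,
                **kw) -> pd.DataFrame:
    """Functional wrapper: fit :class:`OTAnnotationModel`, return the
    bead × category composition."""
    return OTAnnotationModel(beads, reference, params, **kw).fit().composition


def annotate_programs(epithelial_beads: ad.AnnData, programs: pd.DataFrame,
                      params: OTParams | None = None) -> pd.DataFrame:
    """Annotate the epithelial read fraction of beads with expression
    programs (program loadings as category profiles, ε=0.01)."""
    params = params or program_params()
    ref = ReferenceProfiles(programs)
    return annotate_ot(epithelial_beads, ref, params)


# ---------------------------------------------------------------------------
# count splitting
# ---------------------------------------------------------------------------

def _largest_remainder(values: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` proportional to ``values``."""
    if values.sum() <= 0:
        out = np.zeros_like(values, dtype=np.int64)
        out[0] = total
        return out
    quota = values / values.sum() * total
    base = np.floor(quota).astype(np.int64)
    rem = total - int(base.sum())
    if rem > 0:
        order = np.argsort(-(quota - base), kind="stable")
        base[order[:rem]] += 1
    return base


def split_counts(beads: ad.AnnData, composition: pd.DataFrame,
                 reference: ReferenceProfiles,
                 compartment_of: dict | None = None,
                 min_compartment_counts: int = 50):
    """Partition each bead's counts across its annotated categories.

    Gene g of bead i is apportioned across categories proportional to
    composition(i, c) × profile(c, g), using largest-remainder integer
    rounding so the per-category matrices sum back to the input exactly.
    If a gene has zero probability under every weighted profile, the bead's
    composition alone is used.

    When ``compartment_of`` (category -> compartment) is given, the split
    matrices are also aggregated to compartment level, keeping only beads
    with at least ``min_compartment_counts`` counts assigned to that
    compartment.  Returns (per-category dict, per-compartment dict) in that
    case, else just the per-category dict of AnnData.
    """
    comp = composition.reindex(beads.obs_names)
    if comp.isna().any().any():
        raise ValueError("composition must cover all beads")
    rows = comp.to_numpy()
    if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("composition rows must sum to 1")
    cats = list(composition.columns)
    profiles = reference.profiles.reindex(index=cats, columns=beads.var_names) \
        .fillna(0.0).to_numpy()
    X = dense_counts(beads).astype(np.int64)
    n, g = X.shape
    out = {c: np.zeros((n, g), dtype=np.int64) for c in cats}
    for i in range(n):
        w = rows[i][:, None] * profiles          # cats × genes
        for j in np.flatnonzero(X[i]):
            col = w[:, j]
            if col.sum() <= 0:
                col = rows[i]
            alloc = _largest_remainder(col, int(X[i, j]))
            for ci, c in enumerate(cats):
                out[c][i, j] = alloc[ci]
    per_cat = {}
    for c in cats:
        A = ad.AnnData(X=out[c].astype(np.float64), obs=beads.obs.copy(),
                       var=pd.DataFrame(index=beads.var_names))
        if "spatial" in beads.obsm:
            A.obsm["spatial"] = np.asarray(beads.obsm["spatial"])
        per_cat[c] = A
    if compartment_of is None:
        return per_cat
    compartments = sorted(set(compartment_of.values()))
    per_comp = {}
    for comp_name in compartments:
        members = [c for c in cats if compartment_of[c] == comp_name]
        M = sum(out[c] for c in members)
        keep = M.sum(axis=1) >= min_compartment_counts
        A = ad.AnnData(X=M[keep].astype(np.float64),
                       obs=beads.obs.iloc[keep].copy(),
                       var=pd.DataFrame(index=beads.var_names))
        if "spatial" in beads.obsm:
            A.obsm["spatial"] = np.asarray(beads.obsm["spatial"])[keep]
        per_comp[comp_name] = A
    return per_cat, per_comp
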