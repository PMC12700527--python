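"""Compositional transforms, enrichment tests, and spatially-patched testing.

Cell-type (and program/region) fractions are compositional: they live on
the simplex, so standard tests are run on log-ratio transforms — CLR
(centered) for general enrichment, ALR (additive, against a designated
reference category) where one compartment is the natural denominator.
Enrichment between sample groups uses a two-sided Welch's t test per
category with Benjamini-Hochberg FDR across categories.

Bead-level tests on spatial data are pseudo-replicated: thousands of
correlated beads masquerade as independent observations and p-values
collapse.  The patch procedure instead splits each puck recursively along
its first principal axis, discarding a boundary band between the halves so
patches are weakly correlated, and tests patch means with a Mann-Whitney U
across patches.
"""

from __future__ import annotations

import dataclasses
import logging

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._utils import as_rng

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# log-ratio transforms
# ---------------------------------------------------------------------------

def _with_pseudocount(X: np.ndarray, policy: str = "half_min",
                      constant: float = 1.0) -> np.ndarray:
    """Replace zeros before closure: 'half_min' adds half the smallest
    positive value of the row to its zeros; 'constant' adds ``constant``
    everywhere."""
    X = np.asarray(X, dtype=float)
    if (X < 0).any():
        raise ValueError("compositions must be non-negative")
    zero_rows = np.flatnonzero(X.sum(axis=1) == 0)
    if len(zero_rows):
        raise ValueError(f"all-zero composition row(s) at index {zero_rows[:5]}")
    out = X.copy()
    if policy == "constant":
        out = out + constant
    elif policy == "half_min":
        for i in range(out.shape[0]):
            row = out[i]
            if (row == 0).any():
                delta = 0.5 * row[row > 0].min()
                row[row == 0] = delta
    else:
        raise ValueError(f"unknown pseudocount policy {policy!r}")
    return out / out.sum(axis=1, keepdims=True)


def clr(compositions: pd.DataFrame | np.ndarray, pseudocount: str = "half_min",
        constant: float = 1.0):
    """Centered log-ratio transform: log(x_i / g(x)); output rows sum to 0."""
    is_df = isinstance(compositions, pd.DataFrame)
    X = compositions.to_numpy() if is_df else np.asarray(compositions, float)
    P = _with_pseudocount(X, pseudocount, constant)
    L = np.log(P)
    out = L - L.mean(axis=1, keepdims=True)
    if is_df:
        return pd.DataFrame(out, index=compositions.index,
                            columns=compositions.columns)
    return out


def alr(compositions: pd.DataFrame, reference, pseudocount: str = "half_min",
        constant: float = 1.0) -> pd.DataFrame:
    """Additive log-ratio transform: log(x_i / x_ref), reference dropped."""
    if reference not in compositions.columns:
        raise KeyError(f"unknown reference category {reference!r}")
    P = _with_pseudocount(compositions.to_numpy(), pseudocount, constant)
    P = pd.DataFrame(P, index=compositions.index, columns=compositions.columns)
    ref = P[reference]
    rest = P.drop(columns=[reference])
    return np.log(rest.div(ref, axis=0))


def enrichment_welch(compositions: pd.DataFrame, groups: pd.Series,
                     pseudocount: str = "half_min") -> pd.DataFrame:
    """Per-category two-sided Welch's t test on CLR-transformed sample
    compositions, BH FDR across categories.

    ``groups`` must take exactly two values; direction is the sign of the
    (first group − second group) CLR mean difference.
    """
    groups = groups.reindex(compositions.index)
    levels = sorted(groups.dropna().unique())
    if len(levels) != 2:
        raise ValueError("need exactly two groups")
    g1 = compositions.index[(groups == levels[0]).to_numpy()]
    g2 = compositions.index[(groups == levels[1]).to_numpy()]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 samples")
    T = clr(compositions, pseudocount)
    rows = []
    for c in compositions.columns:
        a, b = T.loc[g1, c], T.loc[g2, c]
        t, p = stats.ttest_ind(a, b, equal_var=False)
        if np.isnan(p):          # zero variance in both groups, identical means
            t, p = 0.0, 1.0
        rows.append({"category": c, "direction": float(np.sign(a.mean() - b.mean())),
                     "t": float(t), "p": float(p)})
    out = pd.DataFrame(rows).set_index("category")
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# spatial patches
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PatchSet:
    """Partition of beads into spatially separated patches.

    ``patch`` holds a per-bead patch id ('<puck>/<code>') or NaN for
    discarded boundary beads; ``usable`` flags patches meeting the minimum
    bead count."""

    patch: pd.Series
    boundary_width: float
    n_iterations: int
    min_beads: int

    @property
    def usable(self) -> pd.Series:
        sizes = self.patch.dropna().value_counts()
        return sizes >= self.min_beads

    def patch_table(self) -> pd.DataFrame:
        sizes = self.patch.dropna().value_counts().rename("n_beads").to_frame()
        sizes["usable"] = sizes["n_beads"] >= self.min_beads
        sizes["puck"] = [p.split("/")[0] for p in sizes.index]
        return sizes


def make_patches(beads: ad.AnnData, n_iterations: int = 2,
                 boundary_width: float = 400.0, min_beads: int = 100
                 ) -> PatchSet:
    """Split each puck into weakly correlated spatial patches.

    Per iteration every current patch is split along the first principal
    axis of its bead coordinates at the median projection; beads whose
    projection lies strictly within ±boundary_width/2 of the split point
    are permanently discarded.  Patches smaller than ``min_beads`` are kept
    in the partition but flagged unusable for testing.
    """
    coords = np.asarray(beads.obsm["spatial"], dtype=float)
    pucks = beads.obs["puck"].to_numpy()
    labels = pd.Series([f"{p}/r" for p in pucks], index=beads.obs_names,
                       dtype=object)
    discarded = np.zeros(beads.n_obs, dtype=bool)
    for _ in range(n_iterations):
        for pid in labels[~discarded].unique():
            m = np.flatnonzero((labels == pid).to_numpy() & ~discarded)
            if len(m) < 2:
                logger.warning("patch %s too small to split; skipped", pid)
                continue
            xy = coords[m]
            centered = xy - xy.mean(axis=0)
            # first principal axis of the coordinate distribution
            _, _, vt = np.linalg.svd(centered, full_matrices=False)
            proj = centered @ vt[0]
            split = np.median(proj)
            band = np.abs(proj - split) < boundary_width / 2
            left = proj <= split
            if (~band & left).sum() == 0 or (~band & ~left).sum() == 0:
                logger.warning("split of patch %s would empty a side; skipped", pid)
                continue
            discarded[m[band]] = True
            labels.iloc[m[band]] = np.nan
            labels.iloc[m[~band & left]] = pid + "0"
            labels.iloc[m[~band & ~left]] = pid + "1"
    labels[discarded] = np.nan
    return PatchSet(labels.rename("patch"), boundary_width, n_iterations,
                    min_beads)


def patch_means(field: pd.Series, patches: PatchSet) -> pd.DataFrame:
    """Mean of a per-bead scalar field over each usable patch."""
    df = pd.DataFrame({"value": field, "patch": patches.patch}).dropna()
    out = df.groupby("patch")["value"].agg(["mean", "size"]).reset_index()
    usable = patches.usable
    out["usable"] = out["patch"].map(usable).fillna(False)
    out["puck"] = [p.split("/")[0] for p in out["patch"]]
    return out


def patch_enrichment(fields: pd.DataFrame | pd.Series, patches: PatchSet,
                     puck_groups: pd.Series) -> pd.DataFrame:
    """Patch-level two-sided Mann-Whitney U between puck groups, BH across
    fields.

    ``fields`` is a per-bead DataFrame (one column per field);
    ``puck_groups`` maps puck id -> group (two groups)."""
    if isinstance(fields, pd.Series):
        fields = fields.to_frame()
    levels = sorted(puck_groups.dropna().unique())
    if len(levels) != 2:
        raise ValueError("need exactly two groups of pucks")
    rows = []
    for col in fields.columns:
        pm = patch_means(fields[col], patches)
        pm = pm[pm["usable"]]
        pm["group"] = pm["puck"].map(puck_groups)
        a = pm.loc[pm["group"] == levels[0], "mean"]
        b = pm.loc[pm["group"] == levels[1], "mean"]
        if len(a) < 2 or len(b) < 2:
            logger.warning("field %s skipped: fewer than 2 usable patches in a group", col)
            rows.append({"field": col, "U": np.nan, "p": np.nan,
                         "n_patches": len(a) + len(b)})
            continue
        if np.all(a.to_numpy()[:, None] == b.to_numpy()[None, :]):
            U, p = len(a) * len(b) / 2, 1.0
        else:
            U, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append({"field": col, "U": float(U), "p": float(p),
                     "n_patches": len(a) + len(b)})
    out = pd.DataFrame(rows).set_index("field")
    ok = out["p"].notna()
    out["fdr"] = np.nan
    if ok.any():
        out.loc[ok, "fdr"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out


def bead_level_test(field: pd.Series, beads: ad.AnnData,
                    puck_groups: pd.Series) -> float:
    """The naive bead-level Mann-Whitney p-value (for comparison with the
    patch-level test; treats every bead as independent)."""
    g = beads.obs["puck"].map(puck_groups)
    levels = sorted(g.dropna().unique())
    a = field[(g == levels[0]).to_numpy()]
    b = field[(g == levels[1]).to_numpy()]
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# bootstrap method comparison
# ---------------------------------------------------------------------------

def bootstrap_comparison(compositions: pd.DataFrame, conditions: pd.Series,
                         n_boot: int = 100, seed: int = 0,
                         pseudocount: str = "half_min") -> dict:
    """Bootstrap CLR composition means per condition.

    Returns per condition the bootstrap mean and SEM (sd of bootstrap
    means) per category, the full bootstrap draws, and — when exactly two
    conditions are present — the mean difference with its SE from the all-
    pairwise-difference set of the two bootstrap ensembles.
    """
    rng = as_rng(seed)
    T = clr(compositions, pseudocount)
    conditions = conditions.reindex(compositions.index)
    out = {"mean": {}, "sem": {}, "boot": {}}
    for cond in sorted(conditions.dropna().unique()):
        rowset = np.flatnonzero((conditions == cond).to_numpy())
        draws = np.empty((n_boot, T.shape[1]))
        for r in range(n_boot):
            take = rng.choice(rowset, size=len(rowset), replace=True)
            draws[r] = T.to_numpy()[take].mean(axis=0)
        out["boot"][cond] = pd.DataFrame(draws, columns=T.columns)
        out["mean"][cond] = pd.Series(draws.mean(axis=0), index=T.columns)
        out["sem"][cond] = pd.Series(draws.std(axis=0, ddof=1), index=T.columns)
    conds = sorted(out["mean"])
    if len(conds) == 2:
        A = out["boot"][conds[0]].to_numpy()
        B = out["boot"][conds[1]].to_numpy()
        diffs = A[:, None, :] - B[None, :, :]
        out["difference"] = pd.DataFrame({
            "mean": diffs.reshape(-1, A.shape[1]).mean(axis=0),
            "se": diffs.reshape(-1, A.shape[1]).std(axis=0, ddof=1),
        }, index=T.columns)
    return out


def cross_method_pearson(mean_a: pd.Series, mean_b: pd.Series) -> float:
    """Pearson correlation between the mean composition vectors of two
    measurement methods (on shared categories)."""
    shared = mean_a.index.intersection(mean_b.index)
    return float(np.corrcoef(mean_a[shared], mean_b[shared])[0, 1])
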