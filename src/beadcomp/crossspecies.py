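"""Cross-species mapping and comparison.

Ortholog mapping translates a count table from one species' gene symbols
into another's (summing counts when several source genes share a target,
consulting synonyms only when the primary symbol misses).  On the mapped
data the module compares expression programs across species by correlating
background-normalized log-ratio profiles, scores region-derived gene sets
in pseudo-bulks with per-species standardization and a PC1 summary, and
relates scores to outcomes via quartile stratification and the logrank
test.
"""

from __future__ import annotations

import logging

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._utils import as_rng, dense_counts
from .compositional import clr

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ortholog mapping
# ---------------------------------------------------------------------------

class OrthologMap:
    """source gene -> target gene mapping with optional synonym lists.

    Lookup is case-normalized; many source genes may share one target (their
    counts are summed on mapping)."""

    def __init__(self, pairs: pd.DataFrame, provenance: str = ""):
        req = {"source", "target"}
        if not req <= set(pairs.columns):
            raise ValueError("pair table needs 'source' and 'target' columns")
        self.pairs = pairs.reset_index(drop=True)
        self.provenance = provenance
        self._primary = {str(s).casefold(): t
                         for s, t in zip(pairs["source"], pairs["target"])}
        self._synonyms: dict[str, str] = {}
        if "synonyms" in pairs.columns:
            for s, t, syn in zip(pairs["source"], pairs["target"],
                                 pairs["synonyms"].fillna("")):
                for alias in str(syn).split("|"):
                    alias = alias.strip().casefold()
                    if alias and alias not in self._synonyms:
                        self._synonyms[alias] = t
        # target-side synonyms: allow looking up a table keyed by target
        # aliases when mapping target -> source as well
        self._reverse = {str(t).casefold(): s
                         for s, t in zip(pairs["source"], pairs["target"])}

    @classmethod
    def from_hom_report(cls, report: pd.DataFrame, source_organism: str,
                        target_organism: str) -> "OrthologMap":
        """Build a map from a tab-separated MGI HOM-report-style table
        (columns 'DB Class Key', 'Common Organism Name', 'Symbol',
        'Synonyms'): genes of the two organisms sharing a class key are
        orthologs."""
        org = report["Common Organism Name"].str.lower()
        src = report[org.str.startswith(source_organism.lower())]
        tgt = report[org.str.startswith(target_organism.lower())]
        merged = src.merge(tgt, on="DB Class Key", suffixes=("_src", "_tgt"))
        pairs = pd.DataFrame({
            "source": merged["Symbol_src"],
            "target": merged["Symbol_tgt"],
            "synonyms": merged.get("Synonyms_src", pd.Series(dtype=str)),
        })
        return cls(pairs, provenance="HOM report")

    def lookup(self, symbol: str, use_synonyms: bool = True) -> str | None:
        key = str(symbol).casefold()
        hit = self._primary.get(key)
        if hit is None and use_synonyms:
            hit = self._synonyms.get(key)
        return hit


def map_orthologs(table: ad.AnnData, omap: OrthologMap,
                  use_synonyms: bool = True) -> ad.AnnData:
    """Translate a count table into the target species' gene space.

    Source genes mapping to the same target are summed; unmapped genes are
    dropped (their number recorded in ``uns['n_unmapped']``)."""
    X = dense_counts(table)
    targets: dict[str, np.ndarray] = {}
    n_unmapped = 0
    for j, g in enumerate(table.var_names):
        t = omap.lookup(g, use_synonyms)
        if t is None:
            n_unmapped += 1
            continue
        if t in targets:
            targets[t] = targets[t] + X[:, j]
        else:
            targets[t] = X[:, j].copy()
    if not targets:
        raise ValueError("no genes could be mapped")
    names = list(targets)
    out = ad.AnnData(X=np.column_stack([targets[t] for t in names]),
                     obs=table.obs.copy(), var=pd.DataFrame(index=names))
    out.uns["n_unmapped"] = n_unmapped
    return out


# ---------------------------------------------------------------------------
# program comparison
# ---------------------------------------------------------------------------

def program_similarity(programs_a: pd.DataFrame, background_a: pd.Series,
                       programs_b: pd.DataFrame, background_b: pd.Series,
                       delta: float = 1.0) -> pd.DataFrame:
    """Cross-species Pearson similarity of expression programs.

    Each program and each species background is normalized to 10,000
    counts; the program vector is log((program + δ) / (background + δ)) on
    that scale, which cancels species-specific background distortions.
    Degenerate (constant) vectors yield NaN entries.
    """
    shared = programs_a.columns.intersection(programs_b.columns)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared genes")

    def vectors(programs: pd.DataFrame, background: pd.Series) -> np.ndarray:
        P = programs[shared].to_numpy(dtype=float)
        P = P / P.sum(axis=1, keepdims=True) * 1e4
        bg = background.reindex(shared).fillna(0.0).to_numpy(dtype=float)
        bg = bg / bg.sum() * 1e4
        return np.log((P + delta) / (bg + delta)[None, :])

    VA, VB = vectors(programs_a, background_a), vectors(programs_b, background_b)
    out = np.full((len(VA), len(VB)), np.nan)
    for i in range(len(VA)):
        for j in range(len(VB)):
            if VA[i].std() == 0 or VB[j].std() == 0:
                continue
            out[i, j] = np.corrcoef(VA[i], VB[j])[0, 1]
    return pd.DataFrame(out, index=programs_a.index, columns=programs_b.index)


# ---------------------------------------------------------------------------
# region gene sets and scoring
# ---------------------------------------------------------------------------

def deg_fisher_regions(beads: ad.AnnData, labels: pd.Series, top_n: int = 200,
                       min_count: int = 1) -> dict:
    """Top differentially expressed genes per region by one-sided Fisher.

    Genes are binarized as expressed (count ≥ ``min_count``) per bead; per
    region, each gene's in-region vs out-of-region expressing-bead counts
    are tested one-sided (enrichment) with Fisher's exact test
    (hypergeometric tail).  Genes ranked by ascending p, ties by descending
    in-region expressing fraction, then lexicographic."""
    lab = labels.reindex(beads.obs_names)
    X = dense_counts(beads) >= min_count
    N = beads.n_obs
    expressed_total = X.sum(axis=0)
    genes = np.asarray(beads.var_names)
    out = {}
    for region in sorted(lab.dropna().unique()):
        m = (lab == region).to_numpy()
        n_in = int(m.sum())
        if n_in < 2:
            logger.warning("region %s has < 2 beads; skipped", region)
            continue
        k_in = X[m].sum(axis=0)
        # one-sided Fisher (greater): P(X >= k_in) under Hypergeom(N, K, n)
        p = stats.hypergeom.sf(k_in - 1, N, expressed_total.astype(int), n_in)
        frac_in = k_in / n_in
        order = sorted(range(len(genes)),
                       key=lambda i: (p[i], -frac_in[i], genes[i]))
        out[region] = [genes[i] for i in order[:top_n]]
    return out


def score_regions(pseudobulks: pd.DataFrame, gene_sets: dict,
                  species: pd.Series, groups: pd.Series | None = None,
                  orient_positive: list | None = None,
                  pseudocount: str = "constant") -> "RegionScoreResult":
    """Score region gene sets in sample pseudo-bulks and summarize by PC1.

    score(sample, region) = mean CLR-transformed pseudo-bulk expression
    over the region's gene set; scores are then zero-centered and scaled to
    unit (population) variance across samples separately per species; a PCA
    across samples of the standardized matrix yields PC1.  The PC1 sign is
    a convention: if ``orient_positive`` names regions, PC1 is flipped so
    their mean loading is positive.  When ``groups`` is given, groups are
    compared on PC1 with a two-sided Mann-Whitney U test."""
    T = clr(pseudobulks, pseudocount=pseudocount)
    scores = {}
    for region, genes in gene_sets.items():
        hit = [g for g in genes if g in T.columns]
        if not hit:
            scores[region] = pd.Series(np.nan, index=T.index)
            logger.warning("gene set %s absent from the table", region)
            continue
        scores[region] = T[hit].mean(axis=1)
    S = pd.DataFrame(scores)
    species = species.reindex(S.index)
    Z = S.copy()
    for sp in species.dropna().unique():
        m = (species == sp).to_numpy()
        mu = S[m].mean(axis=0)
        sd = S[m].std(axis=0, ddof=0)
        Z.loc[m] = (S[m] - mu) / sd.replace(0, np.nan)
    Zc = Z.fillna(0.0)
    M = Zc.to_numpy() - Zc.to_numpy().mean(axis=0, keepdims=True)
    _, _, vt = np.linalg.svd(M, full_matrices=False)
    load = pd.Series(vt[0], index=Z.columns, name="pc1_loading")
    if orient_positive:
        if load[list(orient_positive)].mean() < 0:
            load = -load
    pc1 = pd.Series(M @ load.to_numpy(), index=Z.index, name="pc1")
    comparison = None
    if groups is not None:
        groups = groups.reindex(S.index)
        levels = sorted(groups.dropna().unique())
        if len(levels) == 2:
            a = pc1[(groups == levels[0]).to_numpy()]
            b = pc1[(groups == levels[1]).to_numpy()]
            U, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            comparison = {"groups": levels, "U": float(U), "p": float(p)}
    return RegionScoreResult(S, Z, load, pc1, comparison)


class RegionScoreResult:
    def __init__(self, scores, standardized, pc1_loadings, pc1, comparison):
        self.scores = scores
        self.standardized = standardized
        self.pc1_loadings = pc1_loadings
        self.pc1 = pc1
        self.comparison = comparison

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame({"pc1_loading": self.pc1_loadings})
        if self.comparison:
            out.attrs.update(self.comparison)
        return out


# ---------------------------------------------------------------------------
# sample-level association
# ---------------------------------------------------------------------------

def sample_association(compositions: pd.DataFrame,
                       pseudocount: str = "half_min") -> pd.DataFrame:
    """Pearson correlation between CLR-transformed per-sample category
    fractions, for every category pair.  Constant categories give NaN."""
    if len(compositions) < 3:
        logger.warning("fewer than 3 samples: correlations are unreliable")
    T = clr(compositions, pseudocount).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(T.T)
    sd = T.std(axis=0)
    const = np.isclose(sd, 0, atol=1e-12)
    R[const, :] = np.nan
    R[:, const] = np.nan
    return pd.DataFrame(R, index=compositions.columns,
                        columns=compositions.columns)


# ---------------------------------------------------------------------------
# gene-set scoring on beads
# ---------------------------------------------------------------------------

def signature_score(beads: ad.AnnData, gene_set: list, seed: int = 0,
                    min_beads_expressing: int = 3, n_bins: int = 25
                    ) -> pd.Series:
    """Score a gene signature per bead against an expression-matched
    random reference.

    Counts are normalized to 10,000 per bead, log1p transformed and scaled
    (per-gene z-score); genes expressed on fewer than
    ``min_beads_expressing`` beads are removed first.  The score is the
    mean scaled value over the set minus the mean over a size-matched
    control set drawn bin-wise by average expression (seeded)."""
    X = dense_counts(beads)
    expressed = (X > 0).sum(axis=0) >= min_beads_expressing
    genes = beads.var_names[expressed]
    X = X[:, expressed]
    in_set = [g for g in gene_set if g in set(genes)]
    if not in_set:
        raise ValueError("gene set empty after expression filtering")
    tot = X.sum(axis=1, keepdims=True)
    tot[tot == 0] = 1
    Y = np.log1p(X / tot * 1e4)
    mu, sd = Y.mean(axis=0), Y.std(axis=0, ddof=0)
    sd[sd == 0] = 1
    Z = (Y - mu) / sd
    Zdf = pd.DataFrame(Z, index=beads.obs_names, columns=genes)

    rng = as_rng(seed)
    avg = Y.mean(axis=0)
    order = np.argsort(avg, kind="stable")
    bin_of = np.empty(len(genes), dtype=int)
    bin_of[order] = np.minimum(np.arange(len(genes)) * n_bins // len(genes),
                               n_bins - 1)
    gene_pos = {g: i for i, g in enumerate(genes)}
    control = []
    in_set_s = set(in_set)
    for g in in_set:
        b = bin_of[gene_pos[g]]
        pool = [gg for gg in np.asarray(genes)[bin_of == b]
                if gg not in in_set_s]
        if not pool:
            pool = [gg for gg in genes if gg not in in_set_s]
        if not pool:                # the set covers the whole vocabulary
            pool = list(np.asarray(genes)[bin_of == b])
        control.append(pool[int(rng.integers(len(pool)))])
    score = Zdf[in_set].mean(axis=1) - Zdf[control].mean(axis=1)
    return score.rename("signature_score")


# ---------------------------------------------------------------------------
# outcome stratification
# ---------------------------------------------------------------------------

def stratify_logrank(scores: pd.DataFrame, time: pd.Series, event: pd.Series
                     ) -> pd.DataFrame:
    """Quartile-stratified logrank tests per score set.

    Scores are cut at the empirical 25th/75th percentiles (linear
    interpolation, lower-closed intervals: Q1 = score < q25, Q4 = score ≥
    q75); survival in the two extreme quartiles is compared with the
    logrank test, BH FDR across score sets."""
    from lifelines.statistics import logrank_test
    if isinstance(scores, pd.Series):
        scores = scores.to_frame()
    time = time.reindex(scores.index)
    event = event.reindex(scores.index)
    if event.sum() < 2:
        raise ValueError("need at least 2 events overall")
    rows = []
    for col in scores.columns:
        s = scores[col].dropna()
        q25, q75 = np.quantile(s, [0.25, 0.75])
        low = s.index[(s < q25).to_numpy()]
        high = s.index[(s >= q75).to_numpy()]
        if len(low) == 0 or len(high) == 0:
            logger.warning("score %s: empty extreme quartile; skipped", col)
            rows.append({"score": col, "statistic": np.nan, "p": np.nan,
                         "n_low": len(low), "n_high": len(high)})
            continue
        res = logrank_test(time[low], time[high], event[low], event[high])
        rows.append({"score": col, "statistic": float(res.test_statistic),
                     "p": float(res.p_value), "n_low": len(low),
                     "n_high": len(high)})
    out = pd.DataFrame(rows).set_index("score")
    ok = out["p"].notna()
    out["fdr"] = np.nan
    if ok.any():
        out.loc[ok, "fdr"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out
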