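"""Ortholog mapping, program similarity, Fisher DEGs vs hypergeometric
oracle, region scoring with PC1 separation, associations, signature
scores, and quartile/logrank stratification."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import beadcomp as bc
from conftest import grid_beads


def _table(X, genes, obs=None):
    X = np.asarray(X, dtype=float)
    o = obs if obs is not None else pd.DataFrame(
        index=[f"c{i}" for i in range(len(X))])
    return ad.AnnData(X=X, obs=o, var=pd.DataFrame(index=genes))


class TestMapOrthologs:
    def test_identity_map(self):
        t = _table([[1, 2], [3, 4]], ["a", "b"])
        omap = bc.OrthologMap(pd.DataFrame({"source": ["a", "b"],
                                            "target": ["a", "b"]}))
        out = bc.map_orthologs(t, omap)
        assert np.array_equal(out[:, ["a", "b"]].X, t.X)

    def test_collision_sums_counts(self):
        t = _table([[1, 2, 5]], ["a", "b", "c"])
        omap = bc.OrthologMap(pd.DataFrame({"source": ["a", "b", "c"],
                                            "target": ["X", "X", "Y"]}))
        out = bc.map_orthologs(t, omap)
        assert out[:, "X"].X[0, 0] == 3.0
        assert out[:, "Y"].X[0, 0] == 5.0

    def test_conserves_mapped_counts_and_counts_unmapped(self):
        t = _table([[1, 2, 5]], ["a", "b", "zz"])
        omap = bc.OrthologMap(pd.DataFrame({"source": ["a", "b"],
                                            "target": ["A", "B"]}))
        out = bc.map_orthologs(t, omap)
        assert out.X.sum() == 3.0
        assert out.uns["n_unmapped"] == 1

    def test_case_insensitive_and_synonym_fallback(self):
        t = _table([[7, 1]], ["ALIAS1", "B"])
        omap = bc.OrthologMap(pd.DataFrame({
            "source": ["a", "b"], "target": ["ta", "tb"],
            "synonyms": ["Alias1|Alias2", ""]}))
        out = bc.map_orthologs(t, omap, use_synonyms=True)
        assert out[:, "ta"].X[0, 0] == 7.0
        out2 = bc.map_orthologs(t, omap, use_synonyms=False)
        assert "ta" not in out2.var_names

    def test_empty_vocabulary_errors(self):
        t = _table([[1]], ["zz"])
        omap = bc.OrthologMap(pd.DataFrame({"source": ["a"], "target": ["A"]}))
        with pytest.raises(ValueError):
            bc.map_orthologs(t, omap)


def test_hom_report_roundtrip(small_reference):
    """The HOM-report dialect written by the generator parses back to the
    same mapping."""
    _, other, pairs = bc.make_species_pair(small_reference, seed=0)
    report = bc.synthetic.hom_report_from_pairs(pairs, "mouse", "human")
    omap = bc.OrthologMap.from_hom_report(report, "human", "mouse")
    back = bc.map_orthologs(other, omap)
    assert set(back.var_names) == set(pairs["source"])


class TestProgramSimilarity:
    def test_self_similarity_diagonal_one(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(30)]
        P = pd.DataFrame(rng.dirichlet(np.ones(30), 4), columns=genes)
        bg = pd.Series(rng.dirichlet(np.ones(30) * 5), index=genes)
        sim = bc.program_similarity(P, bg, P, bg)
        assert np.allclose(np.diag(sim), 1.0, atol=1e-12)

    def test_program_equal_background_missing(self):
        genes = list("abcd")
        bg = pd.Series([0.4, 0.3, 0.2, 0.1], index=genes)
        P = pd.DataFrame([bg.to_numpy(), [0.7, 0.1, 0.1, 0.1]], columns=genes)
        sim = bc.program_similarity(P, bg, P, bg)
        assert np.isnan(sim.iloc[0, 0])
        assert sim.iloc[1, 1] == pytest.approx(1.0)

    def test_planted_shared_program_beats_mismatches(self):
        """A shared program survives species-specific background
        distortion: its cross-species correlation tops all mismatched
        pairs."""
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(50)]
        progs = rng.dirichlet(np.ones(50) * 0.3, 3)
        PA = pd.DataFrame(progs, columns=genes)
        bgA = pd.Series(rng.dirichlet(np.ones(50) * 5), index=genes)
        distort = rng.gamma(20, 1 / 20, 50)       # species-specific gene scaling
        PB_raw = progs * distort
        PB = pd.DataFrame(PB_raw / PB_raw.sum(1, keepdims=True), columns=genes)
        bgB_raw = bgA.to_numpy() * distort
        bgB = pd.Series(bgB_raw / bgB_raw.sum(), index=genes)
        sim = bc.program_similarity(PA, bgA, PB, bgB).to_numpy()
        for i in range(3):
            off = np.delete(sim[i], i)
            assert sim[i, i] > off.max()

    def test_too_few_shared_genes(self):
        P = pd.DataFrame([[1.0]], columns=["a"])
        with pytest.raises(ValueError):
            bc.program_similarity(P, pd.Series([1.0], index=["a"]), P,
                                  pd.Series([1.0], index=["a"]))


class TestDegFisher:
    def test_closed_form_smallest_p_first(self):
        X = np.zeros((10, 3))
        X[:5, 0] = 1          # gene 0: all in-region, no out-region
        X[:, 1] = 1           # gene 1: everywhere -> p = 1
        beads = _table(X, ["gA", "gB", "gC"])
        beads.obs["puck"] = "p"
        lab = pd.Series(["in"] * 5 + ["out"] * 5, index=beads.obs_names)
        degs = bc.deg_fisher_regions(beads, lab, top_n=3)
        assert degs["in"][0] == "gA"
        p = stats.hypergeom.sf(5 - 1, 10, 5, 5)
        assert p == pytest.approx(1 / 252)

    def test_matches_hypergeometric_oracle_all_small_tables(self):
        """p-values equal the exact hypergeometric tail on every 2x2 table
        with margins ≤ 20."""
        for n_in in range(2, 8):
            n_out = 20 - n_in
            for k_in in range(n_in + 1):
                for k_out in range(min(n_out, 6) + 1):
                    X = np.zeros((20, 1))
                    X[:k_in, 0] = 1
                    X[n_in:n_in + k_out, 0] = 1
                    beads = _table(X, ["g"])
                    lab = pd.Series(["in"] * n_in + ["out"] * n_out,
                                    index=beads.obs_names)
                    # independent oracle: Fisher's one-sided exact test
                    table = [[k_in, n_in - k_in],
                             [k_out, n_out - k_out]]
                    _, p_oracle = stats.fisher_exact(table,
                                                     alternative="greater")
                    degs = bc.deg_fisher_regions(beads, lab, top_n=1)
                    k_tot = k_in + k_out
                    p_impl = stats.hypergeom.sf(k_in - 1, 20, k_tot, n_in)
                    assert p_impl == pytest.approx(p_oracle, rel=1e-9)

    def test_bead_order_invariant(self):
        rng = np.random.default_rng(2)
        X = (rng.random((30, 10)) < 0.3).astype(float)
        beads = _table(X, [f"g{i}" for i in range(10)])
        lab = pd.Series(rng.choice(["r1", "r2"], 30), index=beads.obs_names)
        d1 = bc.deg_fisher_regions(beads, lab, top_n=5)
        perm = rng.permutation(30)
        d2 = bc.deg_fisher_regions(beads[perm].copy(), lab.iloc[perm], top_n=5)
        assert d1.keys() == d2.keys()
        for r in d1:
            assert d1[r] == d2[r]

    def test_planted_markers_recovered(self):
        """≥ 90% of planted region-marker genes rank inside the top set."""
        rng = np.random.default_rng(3)
        n_genes, n_marker = 60, 10
        lam = np.full((80, n_genes), 0.3)
        lam[:40, :n_marker] = 3.0              # markers of region 1
        X = rng.poisson(lam)
        beads = _table(X, [f"g{i:02d}" for i in range(n_genes)])
        lab = pd.Series(["r1"] * 40 + ["r2"] * 40, index=beads.obs_names)
        degs = bc.deg_fisher_regions(beads, lab, top_n=n_marker)
        hits = len(set(degs["r1"]) & {f"g{i:02d}" for i in range(n_marker)})
        assert hits >= 9


class TestScoreRegions:
    def test_one_gene_set_equals_clr_value(self):
        rng = np.random.default_rng(4)
        pb = pd.DataFrame(rng.poisson(50, (4, 6)) + 1.0,
                          index=[f"s{i}" for i in range(4)],
                          columns=[f"g{i}" for i in range(6)])
        species = pd.Series(["m"] * 4, index=pb.index)
        res = bc.score_regions(pb, {"r": ["g2"]}, species)
        T = bc.clr(pb, pseudocount="constant")
        assert np.allclose(res.scores["r"], T["g2"])

    def test_two_samples_standardize_to_pm_one(self):
        pb = pd.DataFrame([[10.0, 5.0], [2.0, 9.0]], index=["s0", "s1"],
                          columns=["g0", "g1"])
        species = pd.Series(["m", "m"], index=pb.index)
        res = bc.score_regions(pb, {"r": ["g0"]}, species)
        assert sorted(np.round(res.standardized["r"], 10)) == [-1.0, 1.0]

    def test_standardization_per_species(self):
        rng = np.random.default_rng(5)
        pb = pd.DataFrame(rng.poisson(40, (8, 10)) + 1.0,
                          index=[f"s{i}" for i in range(8)],
                          columns=[f"g{i}" for i in range(10)])
        species = pd.Series(["m"] * 4 + ["h"] * 4, index=pb.index)
        res = bc.score_regions(pb, {"r1": ["g0", "g1"], "r2": ["g5"]}, species)
        for sp in ["m", "h"]:
            sub = res.standardized[(species == sp).to_numpy()]
            assert np.allclose(sub.mean(), 0, atol=1e-10)
            assert np.allclose(sub.std(ddof=0), 1, atol=1e-10)

    def test_pc1_separates_planted_tumor_like_samples(self):
        """Tumor-like pseudo-bulks with up-shifted tumor-region genes
        separate from normal-like on PC1 (Mann-Whitney p < 0.05,
        n = 10+10)."""
        rng = np.random.default_rng(6)
        genes = [f"g{i:02d}" for i in range(40)]
        tumor_genes = genes[:8]
        base = rng.poisson(30, (20, 40)).astype(float) + 1
        base[:10, :8] *= 3.0                   # tumor samples, tumor genes up
        pb = pd.DataFrame(base, index=[f"s{i}" for i in range(20)],
                          columns=genes)
        species = pd.Series(["h"] * 20, index=pb.index)
        groups = pd.Series(["tumor"] * 10 + ["normal"] * 10, index=pb.index)
        sets = {"tumor_region": tumor_genes, "other_region": genes[20:28]}
        res = bc.score_regions(pb, sets, species, groups=groups,
                               orient_positive=["tumor_region"])
        assert res.comparison["p"] < 0.05
        assert res.pc1_loadings["tumor_region"] > 0
        assert res.pc1[:10].mean() > res.pc1[10:].mean()


class TestSampleAssociation:
    def test_perfectly_covarying(self):
        rng = np.random.default_rng(7)
        a = rng.random(10) + 0.5
        comp = pd.DataFrame({"x": a, "y": 2 * a, "z": np.exp(rng.random(10))})
        comp = comp.div(comp.sum(axis=1), axis=0)
        R = bc.sample_association(comp)
        assert R.loc["x", "y"] == pytest.approx(1.0, abs=1e-10)

    def test_closure_induced_negative_bias(self):
        """Independent Dirichlet components show the negative off-diagonal
        correlation predicted by a direct resampling oracle."""
        rng = np.random.default_rng(8)
        k, n, reps = 4, 30, 200
        mean_r = []
        for _ in range(reps):
            comp = pd.DataFrame(rng.dirichlet(np.ones(k) * 2, n),
                                columns=list("abcd"))
            R = bc.sample_association(comp).to_numpy()
            mean_r.append(R[np.triu_indices(k, 1)].mean())
        # oracle: same computation written independently
        oracle = []
        for _ in range(reps):
            X = rng.dirichlet(np.ones(k) * 2, n)
            X = np.log(X) - np.log(X).mean(1, keepdims=True)
            C = np.corrcoef(X.T)
            oracle.append(C[np.triu_indices(k, 1)].mean())
        se = np.std(oracle) / np.sqrt(reps) + np.std(mean_r) / np.sqrt(reps)
        assert np.mean(mean_r) < 0              # bias is negative
        assert abs(np.mean(mean_r) - np.mean(oracle)) < 3 * se

    def test_constant_category_missing(self):
        comp = pd.DataFrame({"a": [0.5, 0.5, 0.5], "b": [0.3, 0.2, 0.4],
                             "c": [0.2, 0.3, 0.1]})
        # make 'a' exactly constant after CLR by construction
        comp = comp.div(comp.sum(axis=1), axis=0)
        R = bc.sample_association(pd.DataFrame({
            "a": [0.25, 0.25, 0.25], "b": [0.25, 0.25, 0.25],
            "c": [0.5, 0.5, 0.5]}))
        assert R.isna().all().all()


class TestSignatureScore:
    def _beads(self, X, genes):
        b = _table(X, genes)
        b.obs["puck"] = "p"
        return b

    def test_whole_vocabulary_scores_near_zero(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(30)]
        beads = self._beads(rng.poisson(5, (50, 30)), genes)
        score = bc.signature_score(beads, genes, seed=0)
        assert abs(score.mean()) < 0.05

    def test_planted_upregulation_detected(self):
        rng = np.random.default_rng(10)
        genes = [f"g{i}" for i in range(30)]
        lam = np.full((60, 30), 4.0)
        lam[:30, :5] = 12.0                    # signature genes up in half
        beads = self._beads(rng.poisson(lam), genes)
        score = bc.signature_score(beads, genes[:5], seed=0)
        assert score[:30].mean() > score[30:].mean()

    def test_deterministic_and_filters(self):
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(20)]
        X = rng.poisson(3, (30, 20))
        X[:, 0] = 0                            # expressed on 0 beads
        beads = self._beads(X, genes)
        s1 = bc.signature_score(beads, genes[1:6], seed=3)
        s2 = bc.signature_score(beads, genes[1:6], seed=3)
        assert np.array_equal(s1.to_numpy(), s2.to_numpy())
        with pytest.raises(ValueError):
            bc.signature_score(beads, ["g0"], seed=0)


class TestStratifyLogrank:
    def test_quartile_membership_forced(self):
        scores = pd.Series(np.arange(1, 9, dtype=float),
                           index=[f"p{i}" for i in range(8)])
        time = pd.Series(np.arange(1, 9, dtype=float), index=scores.index)
        event = pd.Series([1] * 8, index=scores.index)
        out = bc.stratify_logrank(scores, time, event)
        assert out["n_low"].iloc[0] == 2 and out["n_high"].iloc[0] == 2

    def test_identical_survival_p_one(self):
        idx = [f"p{i}" for i in range(8)]
        scores = pd.Series(np.arange(8, dtype=float), index=idx)
        time = pd.Series([5.0] * 8, index=idx)
        event = pd.Series([1] * 8, index=idx)
        out = bc.stratify_logrank(scores, time, event)
        assert out["statistic"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_power_under_planted_hazard_ratio(self):
        """Exponential survival with hazard ratio 3 between the extreme
        quartiles is detected (p < 0.01) in most replicates."""
        rng = np.random.default_rng(12)
        hits = 0
        reps = 40
        for _ in range(reps):
            n = 200                            # 50 per extreme quartile
            scores = pd.Series(np.arange(n, dtype=float),
                               index=[f"p{i}" for i in range(n)])
            hazard = np.where(scores >= np.quantile(scores, 0.75), 3.0, 1.0)
            time = pd.Series(rng.exponential(1 / hazard), index=scores.index)
            event = pd.Series(np.ones(n, dtype=int), index=scores.index)
            out = bc.stratify_logrank(scores, time, event)
            hits += out["p"].iloc[0] < 0.01
        assert hits / reps >= 0.9

    def test_needs_events(self):
        idx = ["a", "b", "c", "d"]
        with pytest.raises(ValueError):
            bc.stratify_logrank(pd.Series([1.0, 2, 3, 4], index=idx),
                                pd.Series([1.0] * 4, index=idx),
                                pd.Series([0] * 4, index=idx))
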