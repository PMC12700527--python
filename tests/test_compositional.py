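"""CLR/ALR closed forms, Welch/BH enrichment calibration, patch geometry,
patch-level vs bead-level testing, bootstrap comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import beadcomp as bc
from conftest import grid_beads


class TestClr:
    def test_uniform_row_is_zero(self):
        out = bc.clr(np.array([[1 / 3, 1 / 3, 1 / 3]]))
        assert np.allclose(out, 0, atol=1e-12)

    def test_closed_form(self):
        out = bc.clr(np.array([[0.5, 0.25, 0.25]]))
        g = (0.5 * 0.25 * 0.25) ** (1 / 3)
        assert np.allclose(out, np.log([[0.5 / g, 0.25 / g, 0.25 / g]]),
                           atol=1e-10)
        assert out[0, 0] == pytest.approx(0.4621, abs=1e-4)
        assert out[0, 1] == pytest.approx(-0.2310, abs=1e-4)

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(0)
        X = rng.dirichlet(np.ones(5), size=40)
        X[X < 0.05] = 0                        # force zeros
        out = bc.clr(X)
        assert np.allclose(out.sum(axis=1), 0, atol=1e-10)

    def test_pseudocount_matches_oracle(self):
        x = np.array([[0.0, 2.0, 6.0]])
        out = bc.clr(x)
        delta = 0.5 * 2.0                      # half the smallest positive value
        y = np.array([delta, 2.0, 6.0])
        y = y / y.sum()
        oracle = np.log(y) - np.log(y).mean()
        assert np.allclose(out, oracle, atol=1e-12)

    def test_all_zero_row_errors(self):
        with pytest.raises(ValueError, match="all-zero"):
            bc.clr(np.array([[0.0, 0.0]]))


class TestAlr:
    def test_closed_form(self):
        comp = pd.DataFrame([[0.2, 0.3, 0.5]], columns=list("abc"))
        out = bc.alr(comp, "c")
        assert out.iloc[0, 0] == pytest.approx(np.log(0.4), abs=1e-10)
        assert out.iloc[0, 1] == pytest.approx(np.log(0.6), abs=1e-10)

    def test_equal_components_zero(self):
        comp = pd.DataFrame([[0.25, 0.25, 0.25, 0.25]], columns=list("abcd"))
        assert np.allclose(bc.alr(comp, "d").to_numpy(), 0, atol=1e-12)

    def test_two_category_logit(self):
        p = 0.7
        comp = pd.DataFrame([[p, 1 - p]], columns=["a", "b"])
        out = bc.alr(comp, "b")
        assert out.iloc[0, 0] == pytest.approx(np.log(p / (1 - p)), abs=1e-10)

    def test_unknown_reference_errors(self):
        with pytest.raises(KeyError):
            bc.alr(pd.DataFrame([[1.0]], columns=["a"]), "zz")


def test_clr_alr_roundtrip():
    """Softmax inverse of CLR recovers the (pseudocounted) composition."""
    rng = np.random.default_rng(1)
    X = rng.dirichlet(np.ones(4), size=10)
    T = bc.clr(X)
    back = np.exp(T) / np.exp(T).sum(axis=1, keepdims=True)
    assert np.allclose(back, X, atol=1e-10)


class TestEnrichmentWelch:
    def _comp(self, rows, n_cats=3):
        idx = [f"s{i}" for i in range(len(rows))]
        return pd.DataFrame(rows, index=idx,
                            columns=[f"c{i}" for i in range(n_cats)])

    def test_identical_groups_p_one(self):
        rows = [[0.5, 0.3, 0.2]] * 4
        comp = self._comp(rows)
        groups = pd.Series(["A", "A", "B", "B"], index=comp.index)
        out = bc.enrichment_welch(comp, groups)
        assert (out["p"] == 1.0).all()

    def test_bh_step_up_closed_form(self):
        from statsmodels.stats.multitest import multipletests
        fdr = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert np.allclose(fdr, 0.04)

    def test_detects_planted_shift(self):
        rng = np.random.default_rng(2)
        a = rng.dirichlet([20, 5, 5], size=8)
        b = rng.dirichlet([5, 5, 20], size=8)
        comp = self._comp(np.vstack([a, b]))
        groups = pd.Series(["A"] * 8 + ["B"] * 8, index=comp.index)
        out = bc.enrichment_welch(comp, groups)
        assert out.loc["c0", "fdr"] < 0.05 and out.loc["c0", "direction"] > 0
        assert out.loc["c2", "fdr"] < 0.05 and out.loc["c2", "direction"] < 0

    def test_type_one_error_calibrated_under_dirichlet_null(self):
        """Per-category rejection at α=0.05 stays within the binomial CI
        under a random group split of exchangeable Dirichlet samples."""
        rng = np.random.default_rng(3)
        rejections = 0
        trials = 1000
        for _ in range(trials):
            comp = pd.DataFrame(rng.dirichlet(np.ones(4) * 3, size=10),
                                index=[f"s{i}" for i in range(10)],
                                columns=list("abcd"))
            groups = pd.Series(rng.permutation([0] * 5 + [1] * 5),
                               index=comp.index)
            out = bc.enrichment_welch(comp, groups)
            rejections += int((out["p"] < 0.05).sum())
        rate = rejections / (trials * 4)
        ci = 1.96 * np.sqrt(0.05 * 0.95 / (trials * 4))
        # categories within a composition are negatively correlated; allow
        # a small margin beyond the iid CI
        assert abs(rate - 0.05) < ci + 0.01

    def test_small_group_errors(self):
        comp = self._comp([[0.5, 0.3, 0.2]] * 3)
        groups = pd.Series(["A", "B", "B"], index=comp.index)
        with pytest.raises(ValueError):
            bc.enrichment_welch(comp, groups)


class TestMakePatches:
    def test_line_toy_forced_by_median_split(self, line_beads):
        ps = bc.make_patches(line_beads, n_iterations=1, boundary_width=400,
                             min_beads=5)
        sizes = ps.patch.dropna().value_counts()
        assert sorted(sizes) == [9, 9]
        discarded = line_beads.obsm["spatial"][ps.patch.isna().to_numpy(), 0]
        assert sorted(discarded) == [900.0, 1000.0, 1100.0]

    def test_square_puck_two_iterations_gap(self):
        beads = grid_beads(40, 40, spacing=40.0)
        ps = bc.make_patches(beads, n_iterations=2, boundary_width=400,
                             min_beads=10)
        ids = ps.patch.dropna()
        assert ids.nunique() <= 4
        xy = beads.obsm["spatial"]
        for a in ids.unique():
            for b in ids.unique():
                if a >= b:
                    continue
                pa = xy[(ps.patch == a).to_numpy()]
                pb = xy[(ps.patch == b).to_numpy()]
                d = np.sqrt(((pa[:, None] - pb[None]) ** 2).sum(-1)).min()
                assert d >= 400.0

    def test_min_beads_flags_unusable(self, line_beads):
        ps = bc.make_patches(line_beads, n_iterations=1, boundary_width=400,
                             min_beads=100)
        assert not ps.usable.any()

    def test_deterministic_and_monotone_in_boundary(self, line_beads):
        a = bc.make_patches(line_beads, 1, 400, 5)
        b = bc.make_patches(line_beads, 1, 400, 5)
        assert a.patch.equals(b.patch)
        wider = bc.make_patches(line_beads, 1, 600, 5)
        assert wider.patch.isna().sum() >= a.patch.isna().sum()


class TestPatchEnrichment:
    def _setup(self, va, vb):
        beads = grid_beads(21, 1, spacing=100.0, n_pucks=2)
        ps = bc.PatchSet(pd.Series([f"puck0/{i % 3}" for i in range(21)]
                                   + [f"puck1/{i % 3}" for i in range(21)],
                                   index=beads.obs_names),
                         boundary_width=0, n_iterations=0, min_beads=1)
        field = pd.Series(np.concatenate([va, vb]), index=beads.obs_names)
        return beads, ps, field

    def test_closed_form_u_statistic(self):
        # patch means (1,2,3) vs (4,5,6): U = 0, exact two-sided p = 0.1
        va = np.repeat([1.0, 2.0, 3.0], 7)
        vb = np.repeat([4.0, 5.0, 6.0], 7)
        beads, ps, field = self._setup(va, vb)
        groups = pd.Series({"puck0": "A", "puck1": "B"})
        out = bc.patch_enrichment(field, ps, groups)
        assert out["U"].iloc[0] == 0.0
        assert out["p"].iloc[0] == pytest.approx(0.1)

    def test_constant_field_p_one(self):
        beads, ps, field = self._setup(np.ones(21), np.ones(21))
        groups = pd.Series({"puck0": "A", "puck1": "B"})
        out = bc.patch_enrichment(field, ps, groups)
        assert out["p"].iloc[0] == 1.0

    def test_too_few_patches_skipped(self):
        beads = grid_beads(4, 1, n_pucks=2)
        ps = bc.PatchSet(pd.Series(["puck0/0"] * 4 + ["puck1/0"] * 4,
                                   index=beads.obs_names),
                         boundary_width=0, n_iterations=0, min_beads=1)
        field = pd.Series(np.arange(8.0), index=beads.obs_names)
        out = bc.patch_enrichment(field, ps, pd.Series({"puck0": "A",
                                                        "puck1": "B"}))
        assert np.isnan(out["p"].iloc[0])


def test_patch_test_calibrated_on_autocorrelated_null():
    """The pseudo-replication argument: on pucks carrying independent
    spatially autocorrelated fields (null), bead-level Mann-Whitney rejects
    far above nominal while patch-level rejection stays near 5%."""
    import anndata as ad
    from beadcomp.compositional import bead_level_test
    nx, ny, spacing = 70, 15, 40.0
    n = nx * ny
    coords = np.column_stack([np.repeat(np.arange(nx) * spacing, ny),
                              np.tile(np.arange(ny) * spacing, nx)])
    names, pucks, blocks = [], [], []
    for p in range(4):
        names += [f"b{p}_{i}" for i in range(n)]
        pucks += [f"puck{p}"] * n
        blocks.append(coords)
    beads = ad.AnnData(X=np.ones((4 * n, 2)),
                       obs=pd.DataFrame({"puck": pucks}, index=names),
                       var=pd.DataFrame(index=["g1", "g2"]))
    beads.obsm["spatial"] = np.vstack(blocks)
    groups = pd.Series({"puck0": "A", "puck1": "A", "puck2": "B",
                        "puck3": "B"})
    patches = bc.make_patches(beads, n_iterations=2, boundary_width=400,
                              min_beads=100)
    bead_rej = patch_rej = 0
    R = 40
    for rep in range(R):
        field = bc.make_autocorrelated_field(beads, 200.0, seed=500 + rep)
        bead_rej += bead_level_test(field, beads, groups) < 0.05
        out = bc.patch_enrichment(field, patches, groups)
        patch_rej += out["p"].iloc[0] < 0.05
    assert bead_rej / R > 0.20
    ci = 1.96 * np.sqrt(0.05 * 0.95 / R)
    assert patch_rej / R <= 0.05 + ci
    assert patch_rej <= bead_rej


class TestBootstrapComparison:
    def _comp(self, n, seed=0, alpha=(8, 4, 2)):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(rng.dirichlet(alpha, size=n),
                            index=[f"s{i}" for i in range(n)],
                            columns=list("abc"))

    def test_single_sample_sem_zero(self):
        comp = self._comp(1)
        out = bc.bootstrap_comparison(comp, pd.Series(["A"], index=comp.index))
        assert np.allclose(out["sem"]["A"], 0)

    def test_identical_methods_pearson_one(self):
        comp = self._comp(6)
        cond = pd.Series(["A"] * 6, index=comp.index)
        m = bc.bootstrap_comparison(comp, cond, seed=0)["mean"]["A"]
        assert bc.compositional.cross_method_pearson(m, m) == pytest.approx(1.0)

    def test_sem_close_to_analytic(self):
        """Bootstrap SEM tracks sd/√n of the CLR values over repeats."""
        comp = self._comp(30, seed=2)
        cond = pd.Series(["A"] * 30, index=comp.index)
        T = bc.clr(comp)
        analytic = T.std(axis=0, ddof=1) / np.sqrt(30)
        sems = []
        for s in range(50):
            out = bc.bootstrap_comparison(comp, cond, n_boot=100, seed=s)
            sems.append(out["sem"]["A"])
        mean_sem = pd.concat(sems, axis=1).mean(axis=1)
        assert np.allclose(mean_sem, analytic, rtol=0.2)

    def test_two_condition_difference(self):
        comp = pd.concat([self._comp(5, 1), self._comp(5, 2, alpha=(2, 4, 8))])
        comp.index = [f"s{i}" for i in range(10)]
        cond = pd.Series(["A"] * 5 + ["B"] * 5, index=comp.index)
        out = bc.bootstrap_comparison(comp, cond, seed=0)
        assert "difference" in out
        diff = out["mean"]["A"] - out["mean"]["B"]
        assert np.allclose(out["difference"]["mean"], diff, atol=0.05)
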