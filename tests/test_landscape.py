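import numpy as np
import pandas as pd
import pytest

from genecore import landscape
from genecore.containers import GenotypeMatrix
from genecore.landscape import RDA, EnvScaler
from genecore.simdata import SimConfig, simulate_dataset, simulate_landscape


@pytest.fixture(scope="module")
def ls():
    return simulate_landscape(SimConfig(seed=21, pop_sizes=(10, 12, 8), n_pops=3))


class TestExtractEnv:
    def test_shape_and_order(self, ls):
        coords = ls.coords.iloc[:3]
        env = landscape.extract_env(ls, coords)
        assert env.shape == (3, 6)
        assert list(env.index) == coords["accession_id"].tolist()

    def test_constant_raster(self, ls):
        flat = {v: np.full_like(g, 1.5) for v, g in ls.current.items()}
        import dataclasses

        ls2 = dataclasses.replace(ls, current=flat)
        env = landscape.extract_env(ls2, ls.coords)
        assert (env.to_numpy() == 1.5).all()

    def test_outside_extent_rejected(self, ls):
        coords = ls.coords.iloc[:1].copy()
        coords["lat"] = 1e6
        with pytest.raises(ValueError):
            landscape.extract_env(ls, coords)


class TestVif:
    def test_orthogonal_kept(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=50)
        b = rng.normal(size=50)
        b -= a * (a @ b) / (a @ a)  # exactly orthogonal
        env = pd.DataFrame({"a": a, "b": b})
        kept, log = landscape.vif_prune(env, threshold=2.0)
        assert list(kept.columns) == ["a", "b"]
        assert log.empty

    def test_duplicate_dropped_first(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=40)
        env = pd.DataFrame({"a": a, "dup": a.copy(), "b": rng.normal(size=40)})
        kept, log = landscape.vif_prune(env, threshold=2.0)
        assert np.isinf(log.iloc[0]["vif"])
        assert len([c for c in kept.columns if c in ("a", "dup")]) == 1

    def test_collinear_triple(self):
        rng = np.random.default_rng(2)
        x1, x2 = rng.normal(size=(2, 60))
        x3 = x1 + x2 + rng.normal(scale=1e-3, size=60)
        env = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3})
        kept, log = landscape.vif_prune(env, threshold=2.0)
        assert len(kept.columns) == 2
        # remaining variables all below threshold
        X = kept.to_numpy()
        r = abs(np.corrcoef(X, rowvar=False)[0, 1])
        assert 1.0 / (1.0 - r**2) < 2.0


def _fixture_rda():
    """Small multivariate response with known structure (seed-frozen)."""
    rng = np.random.default_rng(42)
    n, L, p = 30, 12, 3
    Z = rng.normal(size=(n, 2))
    X = rng.normal(size=(n, p)) + 0.5 * Z[:, :1]
    Y = X @ rng.normal(size=(p, L)) * 0.3 + Z @ rng.normal(size=(2, L)) * 0.5 + rng.normal(
        size=(n, L)
    )
    gm = GenotypeMatrix([f"a{i}" for i in range(n)], [f"m{j}" for j in range(L)], Y + 2)
    env = pd.DataFrame(X, columns=["x1", "x2", "x3"], index=gm.accessions)
    return gm, env, Z


class TestRDA:
    def test_against_reference_ordination(self):
        """Partition and eigenvalues match an independent constrained-
        ordination implementation run on the identical seed-frozen fixture
        (expected values computed once with vegan::rda and frozen here)."""
        gm, env, Z = _fixture_rda()
        res = RDA(gm, env, Z).fit()
        assert res.partition["conditioned"] == pytest.approx(0.283745, abs=1e-5)
        assert res.partition["constrained"] == pytest.approx(0.202784, abs=1e-5)
        np.testing.assert_allclose(
            res.eigenvalues, [1.96211, 1.335243, 0.5806882], rtol=1e-5
        )

    def test_noiseless_fully_constrained(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(25, 2))
        Y = X @ rng.normal(size=(2, 8))
        gm = GenotypeMatrix([f"a{i}" for i in range(25)], [f"m{j}" for j in range(8)], Y)
        env = pd.DataFrame(X, columns=["x1", "x2"], index=gm.accessions)
        res = RDA(gm, env).fit()
        assert res.partition["constrained"] == pytest.approx(1.0, abs=1e-9)
        assert res.partition["unexplained"] == pytest.approx(0.0, abs=1e-9)

    def test_conditioning_absorbs_identical_block(self):
        gm, env, _ = _fixture_rda()
        res = RDA(gm, env, env.to_numpy()).fit()
        assert res.partition["constrained"] == pytest.approx(0.0, abs=1e-9)

    def test_partition_sums_to_one(self):
        gm, env, Z = _fixture_rda()
        res = RDA(gm, env, Z).fit()
        assert sum(res.partition.values()) == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(res.proportion) <= 1e-12)

    def test_summary_mentions_partition(self):
        gm, env, Z = _fixture_rda()
        s = RDA(gm, env, Z).fit().summary()
        assert "constrained" in s and "axis 1" in s


class TestAxisSignificance:
    def test_planted_signal_minimum_p(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 2))
        Y = X @ rng.normal(size=(2, 30)) * 2.0 + rng.normal(size=(40, 30)) * 0.1
        gm = GenotypeMatrix([f"a{i}" for i in range(40)], [f"m{j}" for j in range(30)], Y)
        env = pd.DataFrame(X, columns=["x1", "x2"], index=gm.accessions)
        p = landscape.rda_axis_significance(gm, env, n_perm=199, seed=0)
        assert p[0] == pytest.approx(1.0 / 200.0)

    def test_null_rejection_rate(self):
        """Pure-noise response: axis-1 rejection close to the nominal level."""
        rej = 0
        n_sims = 100
        for s in range(n_sims):
            rng = np.random.default_rng(s)
            Y = rng.normal(size=(25, 15))
            X = rng.normal(size=(25, 2))
            gm = GenotypeMatrix(
                [f"a{i}" for i in range(25)], [f"m{j}" for j in range(15)], Y
            )
            env = pd.DataFrame(X, columns=["x1", "x2"], index=gm.accessions)
            p = landscape.rda_axis_significance(gm, env, n_perm=99, seed=s)
            rej += p[0] <= 0.05
        assert 0.0 <= rej / n_sims <= 0.12


class TestOutliers:
    def test_flag_rate_on_normal_loadings(self):
        """+/- 2 SD two-sided flag rate ~ 4.55% on Gaussian loadings."""
        rng = np.random.default_rng(5)
        lo = rng.normal(size=200_000)
        rate = np.mean(np.abs(lo - lo.mean()) > 2.0 * lo.std())
        assert rate == pytest.approx(0.0455, abs=0.005)

    def test_constant_loadings_guarded(self):
        gm, env, _ = _fixture_rda()
        res = RDA(gm, env).fit()
        res.loadings.iloc[:, 0] = 0.5  # degenerate axis
        out = landscape.rda_outliers(res, gm, env, n_axes=1)
        assert out.empty


class TestScans:
    def test_lfmm_planted_cline_detected(self):
        """Planted logit-linear cline at n=120 detected in >= 8/10 seeds."""
        hits = 0
        for s in range(10):
            rng = np.random.default_rng(s)
            n, L = 120, 150
            G = rng.binomial(2, 0.4, size=(n, L)).astype(float)
            x = rng.normal(size=n)
            from scipy.special import expit

            G[:, 0] = rng.binomial(2, expit(1.5 * (x - x.mean()) / x.std()))
            gm = GenotypeMatrix([f"a{i}" for i in range(n)], [f"m{j}" for j in range(L)], G)
            env = pd.DataFrame({"x": x}, index=gm.accessions)
            out = landscape.lfmm_ridge(gm, env, k=2)
            hits += bool(out.iloc[0]["candidate"])
        assert hits >= 8

    def test_lfmm_gif_near_one_on_null(self):
        rng = np.random.default_rng(7)
        G = rng.binomial(2, 0.3, size=(150, 400)).astype(float)
        gm = GenotypeMatrix([f"a{i}" for i in range(150)], [f"m{j}" for j in range(400)], G)
        env = pd.DataFrame({"x": rng.normal(size=150)}, index=gm.accessions)
        out = landscape.lfmm_ridge(gm, env, k=2)
        assert out.attrs["gif_x"] == pytest.approx(1.0, abs=0.15)

    def test_pcadapt_constructed_outlier(self):
        """A locus fixed-different between separated groups gets the smallest p."""
        rng = np.random.default_rng(8)
        n, L = 60, 100
        p_anc = rng.uniform(0.2, 0.8, size=L)
        F = 0.1  # mild background drift so PC1 captures the two groups
        a, b = p_anc * (1 - F) / F, (1 - p_anc) * (1 - F) / F
        p1, p2 = rng.beta(a, b), rng.beta(a, b)
        p1[0], p2[0] = 0.02, 0.98  # near-fixed difference at the outlier locus
        G = np.vstack(
            [rng.binomial(2, p1, size=(n // 2, L)), rng.binomial(2, p2, size=(n // 2, L))]
        ).astype(float)
        gm = GenotypeMatrix([f"a{i}" for i in range(n)], [f"m{j}" for j in range(L)], G)
        out = landscape.pcadapt_scan(gm, k_pcs=2)
        assert out["p_value"].idxmin() == "m0"
        assert (out["mahalanobis"].dropna() >= 0).all()

    def test_pcadapt_constant_locus_excluded(self):
        rng = np.random.default_rng(9)
        G = rng.binomial(2, 0.4, size=(30, 20)).astype(float)
        G[:, 5] = 1.0
        gm = GenotypeMatrix([f"a{i}" for i in range(30)], [f"m{j}" for j in range(20)], G)
        out = landscape.pcadapt_scan(gm, k_pcs=2)
        assert np.isnan(out.loc["m5", "p_value"])


class TestCombine:
    def test_reported_set_algebra(self):
        """41 + 3 + 7 with a 4-locus overlap between two methods unions to 47."""
        prda = [f"r{i}" for i in range(37)] + [f"s{i}" for i in range(4)]
        pca = [f"p{i}" for i in range(3)] + [f"s{i}" for i in range(4)]
        lfmm = [f"l{i}" for i in range(3)]
        out = landscape.combine_candidates(prda, lfmm, pca)
        assert out["n_union"] == 47
        assert out["overlap_prda_pcadapt"] == 4
        assert out["overlap_all"] == 0

    def test_union_superset_and_empty(self):
        out = landscape.combine_candidates([], [], [])
        assert out["n_union"] == 0
        out2 = landscape.combine_candidates(["a"], ["a"], ["a"])
        assert out2["union"] == {"a"}
        assert out2["overlap_all"] == 1


class TestOffset:
    @pytest.fixture(scope="class")
    def fitted(self):
        cfg = SimConfig(seed=31, n_loci=200, pop_sizes=(20, 20, 20), n_pops=3,
                        missing_rate=0.0, n_adaptive=10)
        ds = simulate_dataset(cfg)
        env_raw = landscape.extract_env(ds.landscape, ds.landscape.coords)
        envp, _ = landscape.vif_prune(env_raw, 2.0)
        sc = EnvScaler.fit(envp)
        res = landscape.enriched_rda(
            ds.genotypes, list(ds.truth.adaptive_loci["marker_id"]), sc.transform(envp),
            n_axes=2,
        )
        return ds, sc, res

    def test_identity_when_future_equals_current(self, fitted):
        ds, sc, res = fitted
        ls = ds.landscape
        om = landscape.genomic_offset(res, sc, ls.current, ls.current, ls, "same")
        assert np.nanmax(om.global_offset) == 0.0
        assert (om.accession_offset == 0).all()

    def test_linear_in_displacement(self, fitted):
        ds, sc, res = fitted
        ls = ds.landscape
        v = res.env_names[0]
        f1 = {k: g + (1.0 if k == v else 0.0) for k, g in ls.current.items()}
        f2 = {k: g + (2.0 if k == v else 0.0) for k, g in ls.current.items()}
        o1 = landscape.genomic_offset(res, sc, ls.current, f1, ls, "d1")
        o2 = landscape.genomic_offset(res, sc, ls.current, f2, ls, "d2")
        np.testing.assert_allclose(o2.global_offset, 2.0 * o1.global_offset, atol=1e-12)
        np.testing.assert_allclose(o2.axis_offset, 2.0 * o1.axis_offset, atol=1e-12)

    def test_gcm_averaging_commutes(self, fitted):
        ds, sc, res = fitted
        ls = ds.landscape
        rng = np.random.default_rng(0)
        futs = []
        for _ in range(3):
            futs.append({k: g + rng.normal(scale=0.3, size=g.shape) for k, g in ls.current.items()})
        mean_fut = {k: np.mean([f[k] for f in futs], axis=0) for k in ls.current}
        o_list = landscape.genomic_offset(res, sc, ls.current, futs, ls, "gcm")
        o_mean = landscape.genomic_offset(res, sc, ls.current, mean_fut, ls, "mean")
        np.testing.assert_allclose(o_list.global_offset, o_mean.global_offset, atol=1e-10)

    def test_band_classification(self, fitted):
        ds, sc, res = fitted
        ls = ds.landscape
        om = landscape.genomic_offset(res, sc, ls.current, ls.future["SSP370"], ls, "SSP370")
        grid_bands, acc_bands = landscape.classify_offset_bands(om, band_width=0.5)
        assert grid_bands.size == om.global_offset.size
        # half-open convention
        fake = om
        fake.global_offset = np.array([[0.49, 0.5]])
        fake.accession_offset = pd.Series({"a": 0.49, "b": 0.5})
        g, labels = landscape.classify_offset_bands(fake, 0.5)
        assert g.tolist() == [[0, 1]]
        assert labels["a"] == "[0, 0.5)" and labels["b"] == "[0.5, 1)"
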