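import numpy as np
import pandas as pd
import pytest

from genecore import structure
from genecore.containers import GenotypeMatrix
from genecore.simdata import SimConfig, simulate_dataset


@pytest.fixture(scope="module")
def two_pop_unadmixed():
    cfg = SimConfig(
        seed=5, n_loci=300, pop_sizes=(30, 30), n_pops=2, k_ancestral=2,
        admix_alpha=1e-6, n_adaptive=0, missing_rate=0.0, fst_drift=0.2,
    )
    return simulate_dataset(cfg)


class TestAdmixtureFit:
    def test_k1_degenerate(self):
        rng = np.random.default_rng(0)
        d = rng.binomial(2, 0.4, size=(12, 50)).astype(float)
        gm = GenotypeMatrix([f"a{i}" for i in range(12)], [f"m{j}" for j in range(50)], d)
        res = structure.fit_admixture(gm, 1)
        assert (res.q.to_numpy() == 1.0).all()
        # pooled-frequency binomial deviance
        p = np.clip(d.mean(axis=0) / 2.0, 1e-4, 1 - 1e-4)
        expected = -np.sum(d * np.log(2 * p) + (2 - d) * np.log(2 * (1 - p)))
        assert res.deviance == pytest.approx(expected, rel=1e-9)

    def test_recovery_unadmixed(self, two_pop_unadmixed):
        res = structure.fit_admixture(two_pop_unadmixed.genotypes, 2, seed=0)
        assert res.q.to_numpy().max(axis=1).mean() >= 0.9

    def test_deviance_descent(self, two_pop_unadmixed):
        res = structure.fit_admixture(two_pop_unadmixed.genotypes, 3, seed=1)
        path = res.deviance_path
        assert np.all(np.diff(path) <= 1e-8 * np.abs(path[:-1]) + 1e-6)

    def test_rows_on_simplex(self, two_pop_unadmixed):
        res = structure.fit_admixture(two_pop_unadmixed.genotypes, 4, seed=2)
        q = res.q.to_numpy()
        np.testing.assert_allclose(q.sum(axis=1), 1.0, atol=1e-6)
        assert (q >= 0).all()

    def test_rejects_missing(self):
        d = np.array([[np.nan, 1.0], [0.0, 2.0]])
        gm = GenotypeMatrix(["a", "b"], ["m0", "m1"], d)
        with pytest.raises(ValueError, match="complete"):
            structure.AdmixtureModel(gm, 2)


class TestGrid:
    def test_grid_size_and_reproducibility(self, two_pop_unadmixed):
        gm = two_pop_unadmixed.genotypes
        tab1, _ = structure.run_grid(gm, k_values=range(1, 4), replicates=2, seed=3,
                                     max_iter=50)
        tab2, _ = structure.run_grid(gm, k_values=range(1, 4), replicates=2, seed=3,
                                     max_iter=50)
        assert len(tab1) == 6
        pd.testing.assert_frame_equal(tab1, tab2)

    def test_best_deviance_nonincreasing_in_k(self, two_pop_unadmixed):
        tab, _ = structure.run_grid(
            two_pop_unadmixed.genotypes, k_values=range(1, 5), replicates=2, seed=4
        )
        best = tab.groupby("K")["deviance"].min()
        assert np.all(np.diff(best.to_numpy()) <= 1e-6 * np.abs(best.to_numpy()[:-1]))


class TestEvanno:
    def test_hand_arithmetic(self):
        """L = (-1000,-800,-795,-794,-793.8) with SD 1 peaks at K=2 (delta=195)."""
        L = {1: -1000.0, 2: -800.0, 3: -795.0, 4: -794.0, 5: -793.8}
        rows = []
        a = 1.0 / np.sqrt(2.0)  # two replicates at +/- a have sample SD exactly 1
        for k, l in L.items():
            rows += [
                {"K": k, "replicate": 0, "deviance": -(l - a)},
                {"K": k, "replicate": 1, "deviance": -(l + a)},
            ]
        dk = structure.evanno_delta_k(pd.DataFrame(rows))
        d = dk.set_index("K")["delta_K"]
        assert d[2] == pytest.approx(195.0)
        assert d[3] == pytest.approx(4.0)
        assert int(dk.loc[dk["optimal"], "K"].iloc[0]) == 2

    def test_linear_criterion_falls_back(self, caplog):
        rows = []
        for k in range(1, 5):
            for rep, off in [(0, -0.5), (1, 0.5)]:
                rows.append({"K": k, "replicate": rep, "deviance": -100.0 * k + off})
        with caplog.at_level("WARNING"):
            dk = structure.evanno_delta_k(pd.DataFrame(rows))
        assert int(dk.loc[dk["optimal"], "K"].iloc[0]) == 2  # smallest interior K


class TestAssignment:
    def test_boundary_and_ties(self):
        q = pd.DataFrame(
            [[0.6, 0.4], [0.5, 0.5], [0.3, 0.7]], index=["a", "b", "c"],
            columns=["K1", "K2"],
        )
        out = structure.assign_memberships(q, threshold=0.6)
        assert out.loc["a", "assigned_group"] == "1"  # >= 0.6 assigns
        assert out.loc["b", "assigned_group"] == "admixed"
        assert out.loc["c", "assigned_group"] == "2"

    def test_bookkeeping_counts(self):
        """74 of 305 rows below the 0.6 threshold yield exactly 74 admixed."""
        rng = np.random.default_rng(0)
        n = 305
        q = np.full((n, 4), 0.1)
        hi = rng.choice(n, size=n - 74, replace=False)
        q[hi, 0] = 0.7
        lo = np.setdiff1d(np.arange(n), hi)
        q[lo] = 0.25  # max membership 0.25 < 0.6
        q /= q.sum(axis=1, keepdims=True)
        out = structure.assign_memberships(
            pd.DataFrame(q, index=[f"a{i}" for i in range(n)], columns=list("ABCD"))
        )
        n_admixed = (out["assigned_group"] == "admixed").sum()
        assert n_admixed == 74
        assert (out["assigned_group"] != "admixed").sum() == 231


class TestAssociation:
    def test_confusion_matrix_df(self):
        """3 origins x 4 groups yields df = 6."""
        counts = {
            "GC": [6, 4, 2, 28],
            "SG": [6, 43, 14, 36],
            "Su": [36, 11, 12, 33],
        }
        rows, origins = [], []
        i = 0
        for origin, row in counts.items():
            for g, c in enumerate(row):
                for _ in range(c):
                    rows.append({"accession_id": f"a{i}", "assigned_group": str(g + 1),
                                 "max_membership": 0.9})
                    origins.append(origin)
                    i += 1
        assign = pd.DataFrame(rows).set_index("accession_id")
        res = structure.association_test(
            assign, pd.Series(origins, index=assign.index), n_mc=500, seed=0
        )
        assert res["df"] == 6
        assert res["n_assigned"] == 231

    def test_independence_gives_zero_chi2(self):
        rows, origins = [], []
        i = 0
        for origin, mult in [("A", 1), ("B", 2)]:
            for g, c in enumerate([10, 20]):
                for _ in range(c * mult):
                    rows.append({"accession_id": f"a{i}", "assigned_group": str(g + 1),
                                 "max_membership": 0.9})
                    origins.append(origin)
                    i += 1
        assign = pd.DataFrame(rows).set_index("accession_id")
        res = structure.association_test(
            assign, pd.Series(origins, index=assign.index), n_mc=200, seed=0
        )
        assert res["chi2"] == pytest.approx(0.0, abs=1e-9)

    def test_diagonal_table(self):
        rows, origins = [], []
        i = 0
        for origin, g in [("A", "1"), ("B", "2")]:
            for _ in range(10):
                rows.append({"accession_id": f"a{i}", "assigned_group": g,
                             "max_membership": 0.9})
                origins.append(origin)
                i += 1
        assign = pd.DataFrame(rows).set_index("accession_id")
        res = structure.association_test(
            assign, pd.Series(origins, index=assign.index), n_mc=2000, seed=0
        )
        assert res["chi2"] == pytest.approx(20.0)
        assert res["chi2_p"] < 0.001
        assert res["fisher_mc_p"] < 0.01
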