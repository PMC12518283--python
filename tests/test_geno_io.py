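import numpy as np
import pandas as pd
import pytest

from genecore import geno_io
from genecore.containers import GenotypeMatrix


def _marker_frame(n, ref="A", alt="G"):
    return pd.DataFrame(
        {
            "marker_id": [f"m{i}" for i in range(n)],
            "chrom": "Chr01",
            "pos": np.arange(1, n + 1),
            "ref": ref,
            "alt": alt,
            "call_rate": 1.0,
            "reproducibility": 0.99,
        }
    )


def test_dart_source_coding(tmp_path):
    """Source codes 0/1/2/NA map to dosage 0/2/1/missing."""
    path = tmp_path / "d.csv"
    path.write_text(
        "marker_id,chrom,pos,ref,alt,call_rate,reproducibility,A1,A2,A3,A4\n"
        "m1,Chr01,10,A,G,1.0,0.99,0,1,2,NA\n"
    )
    gm, markers = geno_io.read_dart_csv(path)
    np.testing.assert_array_equal(gm.dosage[:3, 0], [0.0, 2.0, 1.0])
    assert np.isnan(gm.dosage[3, 0])


def test_dart_unknown_code_and_missing_column(tmp_path):
    bad = tmp_path / "bad.csv"
    bad.write_text(
        "marker_id,chrom,pos,ref,alt,call_rate,reproducibility,A1\nm1,Chr01,1,A,G,1,1,7\n"
    )
    with pytest.raises(ValueError, match="unknown genotype code"):
        geno_io.read_dart_csv(bad)
    nohdr = tmp_path / "nohdr.csv"
    nohdr.write_text("marker_id,chrom,pos,A1\nm1,Chr01,1,0\n")
    with pytest.raises(ValueError, match="missing required column"):
        geno_io.read_dart_csv(nohdr)


def test_dart_empty_block_errors(tmp_path):
    empty = tmp_path / "empty.csv"
    empty.write_text("marker_id,chrom,pos,ref,alt,call_rate,reproducibility\n")
    with pytest.raises(ValueError, match="empty"):
        geno_io.read_dart_csv(empty)


def test_dart_write_read_identity(tmp_path):
    rng = np.random.default_rng(0)
    n, L = 6, 20
    dosage = rng.choice([0.0, 1.0, 2.0, np.nan], size=(n, L), p=[0.4, 0.2, 0.3, 0.1])
    gm = GenotypeMatrix([f"A{i}" for i in range(n)], [f"m{i}" for i in range(L)], dosage)
    mk = _marker_frame(L)
    path = tmp_path / "rt.csv"
    geno_io.write_dart_csv(gm, mk, path)
    gm2, mk2 = geno_io.read_dart_csv(path)
    obs = ~np.isnan(dosage)
    np.testing.assert_array_equal(gm2.dosage[obs], dosage[obs])
    assert np.isnan(gm2.dosage[~obs]).all()
    assert gm2.accessions == gm.accessions and gm2.markers == gm.markers


def test_vcf_read(tmp_path):
    vcf = tmp_path / "t.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=Chr01>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
        "Chr01\t100\tsnp1\tA\tG\t.\t.\t.\tGT\t0/1\t1/1\n"
        "Chr01\t200\tsnp2\tC\tT\t.\t.\t.\tGT\t./.\t0/0\n"
        "Chr01\t300\tsnp3\tC\tT,G\t.\t.\t.\tGT\t0/1\t0/0\n"
    )
    gm, markers = geno_io.read_vcf(vcf)
    assert gm.markers == ["snp1", "snp2"]  # triallelic skipped
    assert gm.dosage[0, 0] == 1.0 and gm.dosage[1, 0] == 2.0
    assert np.isnan(gm.dosage[0, 1]) and gm.dosage[1, 1] == 0.0


def test_marker_metrics_hand_counts():
    """Dosages [0,0,1,2] give alt frequency 3/8 and maf 0.375."""
    gm = GenotypeMatrix(
        ["a", "b", "c", "d"], ["m0", "m1"],
        np.array([[0.0, 1.0], [0.0, 1.0], [1.0, 1.0], [2.0, 1.0]]),
    )
    mk = geno_io.compute_marker_metrics(gm, _marker_frame(2))
    assert mk.loc[0, "maf"] == pytest.approx(0.375)
    # p = 0.5: gene diversity 0.5, Botstein PIC 0.375
    assert mk.loc[1, "gene_diversity"] == pytest.approx(0.5)
    assert mk.loc[1, "pic"] == pytest.approx(0.375)


def test_tstv_classification():
    mk = pd.DataFrame(
        {
            "marker_id": ["m1", "m2"],
            "chrom": "Chr01",
            "pos": [1, 2],
            "ref": ["A", "A"],
            "alt": ["G", "C"],
            "call_rate": 1.0,
            "reproducibility": 1.0,
        }
    )
    gm = GenotypeMatrix(["a"], ["m1", "m2"], np.array([[1.0, 1.0]]))
    out = geno_io.compute_marker_metrics(gm, mk)
    assert list(out["tstv_class"]) == ["transition", "transversion"]


@pytest.mark.parametrize(
    "maf,call,repro,expected_retained",
    [
        ([0.005, 0.02, 0.3, 0.3, 0.3, 0.3], [0.9, 0.7, 0.9, 0.9, 0.9, 0.9],
         [0.9, 0.9, 0.7, 0.9, 0.9, 0.9], 3),
    ],
)
def test_filter_toy_table(maf, call, repro, expected_retained):
    n = len(maf)
    gm = GenotypeMatrix(["a"], [f"m{i}" for i in range(n)], np.ones((1, n)))
    mk = _marker_frame(n)
    mk["maf"], mk["call_rate"], mk["reproducibility"] = maf, call, repro
    gm_f, mk_f, rep = geno_io.filter_markers(gm, mk)
    assert rep.n_retained == expected_retained
    assert rep.n_removed + rep.n_retained == rep.n_input


def test_filter_boundary_kept():
    """Exactly-at-threshold markers are retained ('< threshold' removal)."""
    gm = GenotypeMatrix(["a"], ["m0", "m1"], np.ones((1, 2)))
    mk = _marker_frame(2)
    mk["maf"] = [0.009, 0.010]
    _, mk_f, rep = geno_io.filter_markers(gm, mk)
    assert list(mk_f["marker_id"]) == ["m1"]
    assert rep.n_removed_maf == 1


def test_filter_idempotent(small_dataset):
    gm, markers = small_dataset.genotypes, small_dataset.markers
    markers = geno_io.compute_marker_metrics(gm, markers)
    gm1, mk1, _ = geno_io.filter_markers(gm, markers)
    gm2, mk2, rep2 = geno_io.filter_markers(gm1, mk1)
    assert rep2.n_removed == 0
    assert gm2.n_markers == gm1.n_markers


def test_impute_identity_on_complete():
    gm = GenotypeMatrix(["a", "b", "c"], ["m0", "m1"], np.array([[0.0, 2], [1, 1], [2, 0]]))
    out = geno_io.impute_svd(gm, rank=1)
    np.testing.assert_array_equal(out.dosage, gm.dosage)
    assert out.provenance == "imputed"


def test_impute_rank1_completion():
    """Rank-1 structure [[2,4],[1,2]] completes the missing cell to 4, clipped to 2."""
    gm = GenotypeMatrix(["a", "b"], ["m0", "m1"], np.array([[2.0, np.nan], [1.0, 2.0]]))
    out = geno_io.impute_svd(gm, rank=1, max_iter=500, tol=1e-10)
    assert out.dosage[0, 1] == pytest.approx(2.0)  # 4 before the [0, 2] clip
    assert out.dosage[1, 0] == 1.0  # observed cells untouched


def test_impute_beats_column_means():
    """Held-out imputation error below column-mean baseline on structured data."""
    rng = np.random.default_rng(0)
    errs_svd, errs_mean = [], []
    from genecore.simdata import SimConfig, simulate_dataset

    for s in range(5):
        ds = simulate_dataset(
            SimConfig(seed=40 + s, n_loci=250, pop_sizes=(25, 25), n_pops=2,
                      missing_rate=0.0, fst_drift=0.15, admix_alpha=0.05)
        )
        full = ds.genotypes.dosage.copy()
        mask = rng.random(full.shape) < 0.05
        holed = full.copy()
        holed[mask] = np.nan
        gm = GenotypeMatrix(ds.genotypes.accessions, ds.genotypes.markers, holed)
        imp = geno_io.impute_svd(gm, rank=4)
        errs_svd.append(np.abs(imp.dosage[mask] - full[mask]).mean())
        col = np.nanmean(holed, axis=0)
        errs_mean.append(np.abs(np.broadcast_to(col, full.shape)[mask] - full[mask]).mean())
    assert np.mean(errs_svd) < np.mean(errs_mean)


def test_impute_never_touches_observed(small_dataset):
    gm = small_dataset.genotypes
    out = geno_io.impute_svd(gm, rank=4)
    obs = ~np.isnan(gm.dosage)
    np.testing.assert_array_equal(out.dosage[obs], gm.dosage[obs])
    assert out.is_complete


def test_tstv_ratio_and_symmetry():
    mk = pd.DataFrame({"tstv_class": ["transition"] * 5 + ["transversion"] * 5})
    out = geno_io.tstv_ratio(mk)
    assert out["ratio"] == pytest.approx(1.0)
    assert out["ts_pct"] + out["tv_pct"] == pytest.approx(100.0)


def test_tstv_zero_transversions_warns(caplog):
    mk = pd.DataFrame({"tstv_class": ["transition"] * 3})
    with caplog.at_level("WARNING"):
        out = geno_io.tstv_ratio(mk)
    assert np.isinf(out["ratio"])


def test_snp_density_arithmetic():
    mk = pd.DataFrame(
        {"marker_id": [f"m{i}" for i in range(10)], "chrom": "Chr01",
         "pos": np.linspace(1, 999_000, 10).astype(int)}
    )
    dens, wins = geno_io.snp_density(mk, {"Chr01": 1_000_000, "Chr02": 500_000})
    row = dens.set_index("chrom").loc["Chr01"]
    assert row["kbp_per_snp"] == pytest.approx(100.0)
    assert wins.groupby("chrom")["count"].sum()["Chr01"] == 10
    assert np.isnan(dens.set_index("chrom").loc["Chr02", "kbp_per_snp"])
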