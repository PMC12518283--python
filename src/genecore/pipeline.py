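"""File-based pipeline stages over a working directory.

Each stage reads its inputs from, and writes its outputs to, a single
working directory, so the stages can be chained from the command line
(``genecore simulate|qc|diversity|structure|tree|core|gea|offset``) or
called programmatically.  All outputs are plain TSV/CSV/JSON/Newick/ASCII-
grid text files written deterministically (fixed seeds give byte-identical
reruns).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from genecore import coreset, geno_io, landscape, phylo, popdiv, simdata, structure
from genecore.containers import GenotypeMatrix
from genecore.rasters import read_esri_ascii, write_esri_ascii


def _read_dosage(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GenotypeMatrix(
        accessions=list(df.index),
        markers=list(df.columns),
        dosage=df.to_numpy(dtype=float),
        provenance="imputed",
    )


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, lineterminator="\n")


def stage_simulate(workdir: str | Path, seed: int = 0, **config_kwargs) -> simdata.SimulatedDataset:
    """Generate the synthetic study and write its files."""
    workdir = Path(workdir)
    cfg = simdata.SimConfig(seed=seed, **config_kwargs)
    ds = simdata.simulate_dataset(cfg)
    simdata.emit_dart_report(ds, workdir)
    return ds


def stage_qc(
    workdir: str | Path,
    maf_min: float = 0.01,
    callrate_min: float = 0.75,
    repro_min: float = 0.80,
    rank: int = 4,
) -> dict:
    """Recompute marker metrics, filter, impute by SVD, report Ts/Tv + density."""
    workdir = Path(workdir)
    gm, markers = geno_io.read_dart_csv(workdir / "dart_report.csv")
    markers = geno_io.compute_marker_metrics(gm, markers)
    gm_f, markers_f, report = geno_io.filter_markers(
        gm, markers, maf_min=maf_min, callrate_min=callrate_min, repro_min=repro_min
    )
    gm_i = geno_io.impute_svd(gm_f, rank=rank)
    markers_f = geno_io.compute_marker_metrics(gm_f, markers_f)
    tstv = geno_io.tstv_ratio(markers_f)
    chrom_lengths = {
        c: int(markers_f.loc[markers_f["chrom"] == c, "pos"].max())
        for c in sorted(markers_f["chrom"].dropna().unique())
    }
    density, windows = geno_io.snp_density(markers_f, chrom_lengths)

    _write_tsv(markers_f, workdir / "marker_metrics.tsv")
    _write_tsv(report.to_frame(), workdir / "filter_report.tsv")
    _write_tsv(gm_i.to_frame(), workdir / "imputed_dosage.tsv", index=True)
    _write_tsv(density, workdir / "snp_density.tsv")
    _write_tsv(windows, workdir / "snp_windows.tsv")
    (workdir / "tstv.json").write_text(json.dumps(tstv, indent=1) + "\n")
    return {"filter": report, "tstv": tstv, "n_retained": gm_i.n_markers}


def _load_core_inputs(workdir: Path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    gm = _read_dosage(workdir / "imputed_dosage.tsv")
    samples = pd.read_csv(workdir / "samples.csv")
    return gm, samples


def stage_diversity(
    workdir: str | Path,
    n_perm: int = 1000,
    seed: int = 0,
    n_invariant: int | None = None,
) -> dict:
    """Per-population diversity, FST and AMOVA on the imputed matrix."""
    workdir = Path(workdir)
    gm, samples = _load_core_inputs(workdir)
    labels = samples.set_index("accession_id").loc[gm.accessions, "population"]
    gm_r = gm.with_provenance(gm.provenance)
    gm_r.dosage = np.round(gm_r.dosage)

    div = popdiv.diversity_table(gm_r, labels, n_invariant=n_invariant)
    fst = popdiv.global_and_pairwise_fst(gm_r, labels)
    am = popdiv.amova(gm_r, labels, n_perm=n_perm, seed=seed)
    perm = popdiv.permtest_heterozygosity(gm_r, labels, n_perm=n_perm, seed=seed)

    _write_tsv(div.reset_index(names="population"), workdir / "diversity.tsv")
    _write_tsv(fst.pairwise.reset_index(names="population"), workdir / "fst_pairwise.tsv")
    _write_tsv(am.table, workdir / "amova.tsv")
    _write_tsv(perm, workdir / "hs_permtest.tsv")
    (workdir / "fst_global.json").write_text(
        json.dumps({"fst_global": fst.global_fst, "Ht": div.attrs["Ht"]}, indent=1) + "\n"
    )
    return {"diversity": div, "fst": fst, "amova": am}


def stage_structure(
    workdir: str | Path,
    k_max: int = 10,
    replicates: int = 3,
    seed: int = 0,
    threshold: float = 0.6,
    max_iter: int = 200,
) -> dict:
    """Admixture K-grid, Evanno delta-K, assignments and origin association."""
    workdir = Path(workdir)
    gm, samples = _load_core_inputs(workdir)
    labels = samples.set_index("accession_id").loc[gm.accessions, "population"]
    run_table, runs = structure.run_grid(
        gm, k_values=range(1, k_max + 1), replicates=replicates, seed=seed, max_iter=max_iter
    )
    dk = structure.evanno_delta_k(run_table)
    k_opt = int(dk.loc[dk["optimal"], "K"].iloc[0])
    sub = run_table[run_table["K"] == k_opt]
    best_rep = int(sub.loc[sub["deviance"].idxmin(), "replicate"])
    best = runs[(k_opt, best_rep)]
    assign = structure.assign_memberships(best.q, threshold=threshold)
    assoc = structure.association_test(assign, labels, seed=seed)

    _write_tsv(run_table, workdir / "structure_runs.tsv")
    _write_tsv(dk, workdir / "deltak.tsv")
    for (k, rep), res in runs.items():
        if k == k_opt:
            _write_tsv(res.q, workdir / f"qmatrix_K{k}_rep{rep}.tsv", index=True)
    _write_tsv(assign.reset_index(), workdir / "assignments.tsv")
    (workdir / "association.json").write_text(json.dumps(assoc, indent=1) + "\n")
    return {"k_opt": k_opt, "delta_k": dk, "assignments": assign, "association": assoc, "best": best}


def stage_tree(workdir: str | Path, n_boot: int = 100, seed: int = 0) -> dict:
    """Tajima-Nei distances + bootstrapped NJ tree in Newick."""
    workdir = Path(workdir)
    gm, _ = _load_core_inputs(workdir)
    gm.dosage = np.round(gm.dosage)
    markers = pd.read_csv(workdir / "marker_metrics.tsv", sep="\t")
    dm = phylo.tajima_nei_distance(gm, markers)
    tree = phylo.bootstrap_support(gm, markers, n_boot=n_boot, seed=seed)
    _write_tsv(dm.reset_index(names="accession_id"), workdir / "tajima_nei.tsv")
    phylo.write_newick(tree, workdir / "nj_tree.nwk")
    return {"tree": tree, "distances": dm}


def stage_core(workdir: str | Path, y: float = 0.98, z: float = 0.99) -> dict:
    """Two-phase core selection + evaluation against the whole collection."""
    workdir = Path(workdir)
    gm, samples = _load_core_inputs(workdir)
    gm.dosage = np.round(gm.dosage)
    labels = samples.set_index("accession_id").loc[gm.accessions, "population"]
    core = coreset.select_core(gm, y=y, z=z)
    ev = coreset.evaluate_core(core.selected, gm, labels)
    (workdir / "core_ids.txt").write_text("\n".join(core.selected) + "\n")
    sel = pd.DataFrame(
        {
            "accession_id": core.selected,
            "phase": ["coverage"] * core.ny + ["rarity"] * (core.size - core.ny),
            "total_rarity": [core.rarity[a] for a in core.selected],
        }
    )
    _write_tsv(sel, workdir / "core_selection.tsv")
    _write_tsv(core.coverage_curve, workdir / "core_coverage_curve.tsv")
    _write_tsv(ev.diversity, workdir / "core_diversity.tsv")
    _write_tsv(ev.composition, workdir / "core_composition.tsv")
    (workdir / "core_summary.json").write_text(
        json.dumps(
            {"size": core.size, "ny": core.ny, "nz": core.nz, "coverage": core.coverage},
            indent=1,
        )
        + "\n"
    )
    return {"core": core, "evaluation": ev}


def _load_rasters(workdir: Path, scenario: str) -> dict[str, np.ndarray]:
    d = workdir / "rasters" / scenario
    return {p.stem: read_esri_ascii(p)[0] for p in sorted(d.glob("*.asc"))}


def _landscape_from_files(workdir: Path) -> simdata.Landscape:
    current = _load_rasters(workdir, "current")
    future = {
        p.name: _load_rasters(workdir, p.name)
        for p in sorted((workdir / "rasters").iterdir())
        if p.is_dir() and p.name != "current"
    }
    any_asc = next((workdir / "rasters" / "current").glob("*.asc"))
    _, meta = read_esri_ascii(any_asc)
    coords = pd.read_csv(workdir / "samples.csv")
    return simdata.Landscape(
        current=current,
        future=future,
        xllcorner=meta["xllcorner"],
        yllcorner=meta["yllcorner"],
        cellsize=meta["cellsize"],
        coords=coords,
    )


def stage_gea(
    workdir: str | Path,
    vif_threshold: float = 2.0,
    n_axes_outlier: int = 3,
    sd_mult: float = 2.0,
    fdr: float = 0.05,
    alpha: float = 0.05,
    n_perm: int = 499,
    seed: int = 0,
) -> dict:
    """Genotype-environment association on the core set.

    Partial RDA conditioned on structure (optimal-K memberships, one
    column dropped), loading outliers on the first significant axes, the
    latent-factor ridge scan at the optimal K, the PC Mahalanobis scan,
    and the candidate union.
    """
    workdir = Path(workdir)
    gm, samples = _load_core_inputs(workdir)
    core_ids = (workdir / "core_ids.txt").read_text().split()
    idx = np.asarray([gm.accessions.index(a) for a in core_ids])
    sub = gm.subset_accessions(idx)

    ls = _landscape_from_files(workdir)
    coords = samples.set_index("accession_id").loc[core_ids].reset_index()
    env_raw = landscape.extract_env(ls, coords)
    env_raw["lat"] = coords.set_index("accession_id")["lat"]
    env_raw["lon"] = coords.set_index("accession_id")["lon"]
    env_pruned, vif_log = landscape.vif_prune(env_raw, threshold=vif_threshold)
    scaler = landscape.EnvScaler.fit(env_pruned)
    env = scaler.transform(env_pruned)

    dk = pd.read_csv(workdir / "deltak.tsv", sep="\t")
    k_opt = int(dk.loc[dk["optimal"], "K"].iloc[0])
    qfiles = sorted(workdir.glob(f"qmatrix_K{k_opt}_rep*.tsv"))
    q = pd.read_csv(qfiles[0], sep="\t", index_col=0).loc[core_ids]
    conditioning = q.to_numpy()[:, :-1]  # drop one column (simplex singularity)

    res = landscape.RDA(sub, env, conditioning).fit()
    res.axis_p = landscape.rda_axis_significance(
        sub, env, conditioning, n_perm=n_perm, seed=seed
    )[: res.n_axes]
    prda_out = landscape.rda_outliers(res, sub, env, n_axes=n_axes_outlier, sd_mult=sd_mult)
    lf = landscape.lfmm_ridge(sub, env, k=k_opt, fdr=fdr)
    pca = landscape.pcadapt_scan(sub, k_pcs=k_opt, alpha=alpha)
    combined = landscape.combine_candidates(prda_out, lf, pca)

    _write_tsv(env_pruned.reset_index(names="accession_id"), workdir / "env_pruned.tsv")
    _write_tsv(vif_log, workdir / "vif_removed.tsv")
    scaler_df = pd.DataFrame({"variable": scaler.mean.index, "mean": scaler.mean.values, "sd": scaler.sd.values})
    _write_tsv(scaler_df, workdir / "env_scaler.tsv")
    _write_tsv(prda_out, workdir / "candidates_prda.tsv")
    _write_tsv(lf.reset_index(names="marker_id"), workdir / "lfmm_scan.tsv")
    _write_tsv(pca.reset_index(names="marker_id"), workdir / "pcadapt_scan.tsv")
    union = sorted(combined["union"])
    (workdir / "candidates_union.txt").write_text("\n".join(union) + "\n")
    (workdir / "gea_summary.json").write_text(
        json.dumps(
            {
                "n_prda": len(combined["prda"]),
                "n_lfmm": len(combined["lfmm"]),
                "n_pcadapt": len(combined["pcadapt"]),
                "n_union": combined["n_union"],
                "overlap_prda_pcadapt": combined["overlap_prda_pcadapt"],
                "partition": res.partition,
                "axis_proportion": [float(v) for v in res.proportion[:3]],
                "axis_p": [float(v) for v in res.axis_p[:3]],
                "k_opt": k_opt,
            },
            indent=1,
        )
        + "\n"
    )
    (workdir / "rda_summary.txt").write_text(res.summary() + "\n")
    return {"rda": res, "candidates": combined, "env": env, "scaler": scaler, "k_opt": k_opt}


def stage_offset(workdir: str | Path, n_axes: int = 2, band_width: float = 0.5) -> dict:
    """Adaptively enriched RDA and genomic offset per future scenario."""
    workdir = Path(workdir)
    gm, samples = _load_core_inputs(workdir)
    core_ids = (workdir / "core_ids.txt").read_text().split()
    idx = np.asarray([gm.accessions.index(a) for a in core_ids])
    sub = gm.subset_accessions(idx)
    candidates = (workdir / "candidates_union.txt").read_text().split()

    ls = _landscape_from_files(workdir)
    ls.coords = ls.coords[ls.coords["accession_id"].isin(core_ids)].reset_index(drop=True)
    env_pruned = pd.read_csv(workdir / "env_pruned.tsv", sep="\t", index_col=0)
    scaler_df = pd.read_csv(workdir / "env_scaler.tsv", sep="\t", index_col=0)
    scaler = landscape.EnvScaler(mean=scaler_df["mean"], sd=scaler_df["sd"])
    env = scaler.transform(env_pruned)

    res = landscape.enriched_rda(sub, candidates, env, n_axes=n_axes)
    # raster variables only (lat/lon have no future grids): project on those
    raster_vars = [v for v in res.env_names if v in ls.current]
    results = {}
    meta = dict(
        xllcorner=ls.xllcorner, yllcorner=ls.yllcorner, cellsize=ls.cellsize, nodata=-9999.0
    )
    for scen in sorted(ls.future):
        om = _offset_on_raster_vars(res, scaler, ls, scen, raster_vars)
        write_esri_ascii(om.global_offset, workdir / f"offset_{scen}.asc", **meta)
        bands_grid, bands_acc = landscape.classify_offset_bands(om, band_width=band_width)
        out = pd.DataFrame(
            {
                "accession_id": om.accession_offset.index,
                "global_offset": om.accession_offset.values,
                "band": bands_acc.values,
            }
        )
        _write_tsv(out, workdir / f"offset_accessions_{scen}.tsv")
        results[scen] = om
    return {"offsets": results, "rda": res}


def _offset_on_raster_vars(res, scaler, ls, scen, raster_vars):
    """Offset using the raster-backed variables of the model (geographic
    coordinates are static across scenarios and contribute zero offset)."""
    keep = [res.env_names.index(v) for v in raster_vars]
    sub_res = landscape.RDAResults(
        site_scores=res.site_scores,
        loadings=res.loadings,
        env_scores=res.env_scores,
        eigenvalues=res.eigenvalues,
        proportion=res.proportion,
        partition=res.partition,
        coefficients=res.coefficients[keep],
        env_names=raster_vars,
        axis_p=res.axis_p,
    )
    sub_scaler = landscape.EnvScaler(
        mean=scaler.mean[raster_vars], sd=scaler.sd[raster_vars]
    )
    return landscape.genomic_offset(
        sub_res, sub_scaler, ls.current, ls.future[scen], ls, scenario=scen
    )


def run_full_pipeline(workdir: str | Path, seed: int = 0, scale: float = 1.0, **kwargs) -> dict:
    """Run every stage in order with defaults; returns per-stage results."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    out = {}
    out["dataset"] = stage_simulate(workdir, seed=seed, **kwargs.get("simulate", {}))
    out["qc"] = stage_qc(workdir, **kwargs.get("qc", {}))
    out["diversity"] = stage_diversity(workdir, seed=seed, **kwargs.get("diversity", {}))
    out["structure"] = stage_structure(workdir, seed=seed, **kwargs.get("structure", {}))
    out["tree"] = stage_tree(workdir, seed=seed, **kwargs.get("tree", {}))
    out["core"] = stage_core(workdir, **kwargs.get("core", {}))
    out["gea"] = stage_gea(workdir, seed=seed, **kwargs.get("gea", {}))
    out["offset"] = stage_offset(workdir, **kwargs.get("offset", {}))
    return out
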