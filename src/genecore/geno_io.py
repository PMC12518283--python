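"""Genotype I/O, marker metrics, filtering and SVD imputation.

The source report is a DArT-style one-row-per-marker CSV in which each call
is coded 0 (reference homozygote), 1 (alternative homozygote), 2
(heterozygote) or NA.  On read this is translated to alt-allele dosage
(0/2/1 respectively, NaN for missing), the internal representation used by
every downstream module.  VCF (biallelic SNPs) is supported read-only.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from genecore.containers import (
    MARKER_COLUMNS,
    TRANSITIONS,
    FilterReport,
    GenotypeMatrix,
)

logger = logging.getLogger(__name__)

_META_COLS = ["marker_id", "chrom", "pos", "ref", "alt", "call_rate", "reproducibility"]
#: source code -> alt-allele dosage
_DART_TO_DOSAGE = {"0": 0.0, "1": 2.0, "2": 1.0}
_DOSAGE_TO_DART = {0: "0", 2: "1", 1: "2"}


# ---------------------------------------------------------------------------
# DArT-style CSV
# ---------------------------------------------------------------------------

def read_dart_csv(path: str | Path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a DArT-style one-row SNP report.

    Expected header: ``marker_id,chrom,pos,ref,alt,call_rate,
    reproducibility`` followed by one column per accession; genotype cells
    in {0, 1, 2, NA}.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in _META_COLS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing required column(s) {missing_cols}")
    acc_cols = [c for c in df.columns if c not in _META_COLS]
    if not acc_cols or df.empty:
        raise ValueError(f"{path}: genotype block is empty")

    codes = df[acc_cols].to_numpy(dtype=object)
    dosage = np.full(codes.shape, np.nan)
    for code, dose in _DART_TO_DOSAGE.items():
        dosage[codes == code] = dose
    unknown = ~np.isin(codes, list(_DART_TO_DOSAGE) + ["NA", ""])
    if unknown.any():
        r, c = np.argwhere(unknown)[0]
        raise ValueError(
            f"{path}: unknown genotype code {codes[r, c]!r} at marker "
            f"{df['marker_id'].iloc[r]!r}, accession {acc_cols[c]!r}"
        )

    markers = df[_META_COLS].copy()
    markers["pos"] = pd.to_numeric(markers["pos"])
    markers["call_rate"] = pd.to_numeric(markers["call_rate"])
    markers["reproducibility"] = pd.to_numeric(markers["reproducibility"])
    for col in MARKER_COLUMNS:
        if col not in markers.columns:
            markers[col] = np.nan
    gm = GenotypeMatrix(
        accessions=acc_cols,
        markers=df["marker_id"].tolist(),
        dosage=dosage.T,  # rows were markers; internal layout is accessions x markers
        provenance="raw",
    )
    return gm, markers


def write_dart_csv(gm: GenotypeMatrix, markers: pd.DataFrame, path: str | Path) -> None:
    """Write the DArT-style report (inverse of :func:`read_dart_csv`).

    Fractional (imputed) dosages cannot be represented in the 0/1/2 source
    coding and are rejected.
    """
    dosage = gm.dosage
    obs = ~np.isnan(dosage)
    if not np.isin(dosage[obs], [0.0, 1.0, 2.0]).all():
        raise ValueError("dosage matrix holds fractional values; round before writing")
    markers = markers.set_index("marker_id").loc[gm.markers].reset_index()
    out = markers[_META_COLS].copy()
    for i, acc in enumerate(gm.accessions):
        col = np.full(gm.n_markers, "NA", dtype=object)
        row = dosage[i]
        for dose, code in _DOSAGE_TO_DART.items():
            col[row == dose] = code
        out[acc] = col
    try:
        out.to_csv(path, index=False, lineterminator="\n")
    except OSError as exc:
        raise OSError(f"cannot write DArT report to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read biallelic SNP records from a VCF; multiallelic records skipped."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    accessions = list(vcf.samples)
    rows, meta, n_skipped = [], [], 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        gts = rec.gt_types  # 0=hom ref, 1=het, 2=unknown, 3=hom alt
        dose = np.choose(gts, [0.0, 1.0, np.nan, 2.0])
        rows.append(dose)
        meta.append(
            {
                "marker_id": rec.ID or f"{rec.CHROM}:{rec.POS}",
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": rec.ALT[0],
            }
        )
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic record(s)", n_skipped)
    if not rows:
        raise ValueError(f"{path}: no biallelic SNP records found")
    markers = pd.DataFrame(meta)
    for col in MARKER_COLUMNS:
        if col not in markers.columns:
            markers[col] = np.nan
    gm = GenotypeMatrix(
        accessions=accessions,
        markers=markers["marker_id"].tolist(),
        dosage=np.asarray(rows).T,
        provenance="raw",
    )
    return gm, markers


# ---------------------------------------------------------------------------
# Marker metrics, filtering
# ---------------------------------------------------------------------------

def compute_marker_metrics(gm: GenotypeMatrix, markers: pd.DataFrame) -> pd.DataFrame:
    """Recompute per-marker metrics from the genotype calls.

    Over non-missing calls: alt frequency p, maf = min(p, 1-p), gene
    diversity 2p(1-p), PIC (Botstein biallelic form
    1 - p^2 - q^2 - 2 p^2 q^2), call rate, and the transition/transversion
    class from the ref/alt base pair.
    """
    markers = markers.set_index("marker_id").loc[gm.markers].reset_index()
    dosage = gm.dosage
    n_called = (~np.isnan(dosage)).sum(axis=0).astype(float)
    zero = n_called == 0
    if zero.any():
        logger.warning("compute_marker_metrics: %d marker(s) with zero calls", int(zero.sum()))
    with np.errstate(invalid="ignore"):
        p = np.nansum(dosage, axis=0) / (2.0 * n_called)
    p[zero] = np.nan
    q = 1.0 - p
    markers["call_rate"] = n_called / gm.n_accessions
    markers["maf"] = np.minimum(p, q)
    markers["gene_diversity"] = 2.0 * p * q
    markers["pic"] = 1.0 - p**2 - q**2 - 2.0 * p**2 * q**2
    markers["tstv_class"] = [
        _tstv_class(r, a) for r, a in zip(markers["ref"], markers["alt"])
    ]
    return markers


def _tstv_class(ref: object, alt: object) -> object:
    if not isinstance(ref, str) or not isinstance(alt, str) or ref == alt:
        return np.nan
    if not {ref, alt} <= {"A", "C", "G", "T"}:
        return np.nan
    return "transition" if frozenset((ref, alt)) in TRANSITIONS else "transversion"


def filter_markers(
    gm: GenotypeMatrix,
    markers: pd.DataFrame,
    maf_min: float = 0.01,
    callrate_min: float = 0.75,
    repro_min: float = 0.80,
) -> tuple[GenotypeMatrix, pd.DataFrame, FilterReport]:
    """Remove markers with maf/call-rate/reproducibility below thresholds.

    Values exactly at a threshold are retained (the removal rule is a
    strict "< threshold").  Per-criterion removal counts are non-exclusive.
    """
    markers = markers.set_index("marker_id").loc[gm.markers].reset_index()
    maf = markers["maf"].to_numpy(dtype=float)
    call = markers["call_rate"].to_numpy(dtype=float)
    repro = markers["reproducibility"].to_numpy(dtype=float)
    fail_maf = maf < maf_min
    fail_call = call < callrate_min
    fail_repro = repro < repro_min
    fail = fail_maf | fail_call | fail_repro
    keep = ~fail
    report = FilterReport(
        maf_min=maf_min,
        callrate_min=callrate_min,
        repro_min=repro_min,
        n_input=gm.n_markers,
        n_removed_maf=int(fail_maf.sum()),
        n_removed_callrate=int(fail_call.sum()),
        n_removed_repro=int(fail_repro.sum()),
        n_removed=int(fail.sum()),
        n_retained=int(keep.sum()),
    )
    gm_f = gm.subset_markers(keep)
    gm_f.provenance = "filtered"
    return gm_f, markers.loc[keep].reset_index(drop=True), report


# ---------------------------------------------------------------------------
# SVD imputation
# ---------------------------------------------------------------------------

def impute_svd(
    gm: GenotypeMatrix,
    rank: int = 4,
    max_iter: int = 100,
    tol: float = 1e-4,
    round_dosage: bool = False,
) -> GenotypeMatrix:
    """Iterative soft-SVD completion of missing genotype calls.

    Missing cells start at their column means; the matrix is repeatedly
    replaced by its rank-``rank`` truncated SVD reconstruction at the
    missing cells only, until the largest absolute change falls below
    ``tol`` (or ``max_iter``).  Observed cells are never altered; the
    output is clipped to [0, 2] and optionally rounded to integer dosage.
    """
    X = gm.dosage.copy()
    if not np.isnan(X).any():
        out = gm.with_provenance("imputed")
        if round_dosage:
            out.dosage = np.clip(np.round(out.dosage), 0, 2)
        return out
    if rank < 1 or rank >= min(X.shape):
        raise ValueError(f"rank must be in [1, {min(X.shape) - 1}]")
    obs = ~np.isnan(X)
    empty_rows = np.flatnonzero(~obs.any(axis=1))
    empty_cols = np.flatnonzero(~obs.any(axis=0))
    if empty_rows.size:
        raise ValueError(f"accession(s) with no observed calls: {[gm.accessions[i] for i in empty_rows]}")
    if empty_cols.size:
        raise ValueError(f"marker(s) with no observed calls: {[gm.markers[i] for i in empty_cols]}")

    col_means = np.nanmean(X, axis=0)
    miss = ~obs
    X[miss] = np.broadcast_to(col_means, X.shape)[miss]
    for _ in range(max_iter):
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        recon = (U[:, :rank] * s[:rank]) @ Vt[:rank]
        delta = np.abs(recon[miss] - X[miss]).max() if miss.any() else 0.0
        X[miss] = recon[miss]
        if delta < tol:
            break
    X = np.clip(X, 0.0, 2.0)
    if round_dosage:
        X[miss] = np.round(X[miss])
    X[obs] = gm.dosage[obs]  # observed cells untouched by construction
    return GenotypeMatrix(
        accessions=list(gm.accessions),
        markers=list(gm.markers),
        dosage=X,
        provenance="imputed",
    )


# ---------------------------------------------------------------------------
# Marker-level reports
# ---------------------------------------------------------------------------

def tstv_ratio(markers: pd.DataFrame) -> dict[str, float]:
    """Transition/transversion counts, percentages and ratio.

    Percentages are over classifiable markers and sum to 100; the ratio is
    Ts% / Tv% (equivalently the count ratio).
    """
    cls = markers["tstv_class"]
    n_ts = int((cls == "transition").sum())
    n_tv = int((cls == "transversion").sum())
    total = n_ts + n_tv
    if total == 0:
        raise ValueError("no classifiable markers (tstv_class unset?)")
    ts_pct = 100.0 * n_ts / total
    tv_pct = 100.0 * n_tv / total
    if n_tv == 0:
        logger.warning("tstv_ratio: zero transversions; ratio is infinite")
        ratio = np.inf
    else:
        ratio = ts_pct / tv_pct
    return {"n_ts": n_ts, "n_tv": n_tv, "ts_pct": ts_pct, "tv_pct": tv_pct, "ratio": ratio}


def aligned_fraction(markers: pd.DataFrame) -> float:
    """Fraction of markers placed on a chromosome (not 'unplaced'/unknown)."""
    chrom = markers["chrom"]
    placed = chrom.notna() & (chrom != "unplaced")
    return float(placed.sum() / len(markers))


def snp_density(
    markers: pd.DataFrame,
    chrom_lengths: dict[str, int],
    window: int = 1_000_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-chromosome marker density and per-window counts.

    Density is reported as kbp per SNP (chromosome length in kbp divided by
    its marker count); windows are fixed ``window``-bp bins, with markers
    positioned beyond the declared length counted in the last window.
    """
    dens_rows, win_rows = [], []
    for chrom, length in chrom_lengths.items():
        sub = markers[markers["chrom"] == chrom]
        count = len(sub)
        dens_rows.append(
            {
                "chrom": chrom,
                "length_bp": length,
                "n_snps": count,
                "kbp_per_snp": (length / 1000.0) / count if count else np.nan,
            }
        )
        n_win = max(int(np.ceil(length / window)), 1)
        counts = np.zeros(n_win, dtype=int)
        if count:
            pos = sub["pos"].to_numpy(dtype=float)
            beyond = pos > length
            if beyond.any():
                logger.warning(
                    "snp_density: %d marker(s) on %s beyond declared length", int(beyond.sum()), chrom
                )
            idx = np.minimum(((pos - 1) // window).astype(int), n_win - 1)
            np.add.at(counts, idx, 1)
        for w, c in enumerate(counts):
            win_rows.append(
                {"chrom": chrom, "window_start": w * window + 1, "count": int(c)}
            )
    return pd.DataFrame(dens_rows), pd.DataFrame(win_rows)
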