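"""Genotype-environment association and genomic-offset prediction.

The adaptive-landscape workflow: extract environmental values at accession
coordinates, prune collinear variables by variance inflation factor,
condition the genotype matrix on population structure and fit a (partial)
redundancy analysis, flag candidate adaptive loci by three routes (RDA
loading outliers, a latent-factor ridge association scan, and a
principal-component Mahalanobis outlier scan), refit an "adaptively
enriched" RDA on the candidate union without structure conditioning, and
project current and future environment grids through that model to obtain
per-axis and global genomic offsets.

The RDA is exposed statsmodels-style: ``RDA(Y, X, conditioning).fit()``
returns an :class:`RDAResults` carrying axes, eigenvalues, loadings,
biplot scores, the variance partition and a ``summary()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from sklearn.covariance import MinCovDet

from genecore.containers import GenotypeMatrix
from genecore.simdata import Landscape

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Environment table
# ---------------------------------------------------------------------------

def extract_env(landscape: Landscape, coords: pd.DataFrame) -> pd.DataFrame:
    """Nearest-cell environmental values per accession (current climate)."""
    missing = []
    table = landscape.values_at(coords)
    for acc, row in table.iterrows():
        if row.isna().any():
            missing.append(acc)
    if missing:
        raise ValueError(f"no-data raster cells for accessions: {missing}")
    return table


@dataclass
class EnvScaler:
    """Per-variable centering/scaling parameters, stored once and reused
    when projecting rasters (current and future) through a fitted model."""

    mean: pd.Series
    sd: pd.Series

    @classmethod
    def fit(cls, env: pd.DataFrame) -> "EnvScaler":
        sd = env.std(ddof=1)
        if (sd == 0).any():
            raise ValueError(f"constant environmental variable(s): {list(sd.index[sd == 0])}")
        return cls(mean=env.mean(), sd=sd)

    def transform(self, env: pd.DataFrame) -> pd.DataFrame:
        return (env[self.mean.index] - self.mean) / self.sd

    def transform_grids(self, grids: dict[str, np.ndarray], variables) -> np.ndarray:
        """Stack scaled variable grids into (n_vars, nrows, ncols)."""
        out = []
        for v in variables:
            if v not in grids:
                raise ValueError(f"variable {v!r} missing from raster set")
            out.append((grids[v] - self.mean[v]) / self.sd[v])
        return np.stack(out)


def vif_prune(env: pd.DataFrame, threshold: float = 2.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Iteratively drop the variable with the highest VIF until all < threshold.

    VIF_j = 1 / (1 - R^2_j) from regressing variable j on the remaining
    variables (with intercept); perfectly collinear variables have infinite
    VIF and fall first.
    """
    if env.shape[1] < 2:
        raise ValueError("need at least 2 variables")
    if env.shape[0] <= env.shape[1]:
        raise ValueError("need more sites than variables")
    cols = list(env.columns)
    log_rows = []
    while len(cols) > 1:
        X = env[cols].to_numpy(dtype=float)
        vifs = {}
        for j, name in enumerate(cols):
            yj = X[:, j] - X[:, j].mean()
            others = np.column_stack(
                [np.ones(X.shape[0])] + [X[:, k] for k in range(len(cols)) if k != j]
            )
            resid = yj - others @ np.linalg.lstsq(others, yj, rcond=None)[0]
            tss = float(yj @ yj)
            rss = float(resid @ resid)
            r2 = 1.0 - rss / tss if tss > 0 else 0.0
            vifs[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        worst = max(vifs, key=lambda k: vifs[k])
        if vifs[worst] < threshold:
            break
        log_rows.append({"removed": worst, "vif": vifs[worst]})
        cols.remove(worst)
    return env[cols].copy(), pd.DataFrame(log_rows, columns=["removed", "vif"])


# ---------------------------------------------------------------------------
# (partial) RDA
# ---------------------------------------------------------------------------

@dataclass
class RDAResults:
    """Constrained-ordination axes and the conditioned/constrained partition."""

    site_scores: pd.DataFrame  # accessions x axes (linear-combination scores)
    loadings: pd.DataFrame  # loci x axes
    env_scores: pd.DataFrame  # variables x axes (correlation biplot scores)
    eigenvalues: np.ndarray
    proportion: np.ndarray  # of constrained variance, non-increasing
    partition: dict[str, float]  # conditioned / constrained / unexplained
    coefficients: np.ndarray = field(repr=False)  # env -> axis projection map
    env_names: list[str] = field(default_factory=list)
    axis_p: np.ndarray | None = None

    @property
    def n_axes(self) -> int:
        return self.eigenvalues.size

    def summary(self) -> str:
        lines = ["Redundancy analysis", "-------------------"]
        lines.append(
            "variance partition: "
            + ", ".join(f"{k}={v:.4f}" for k, v in self.partition.items())
        )
        for a in range(min(self.n_axes, 6)):
            p = "" if self.axis_p is None else f"   p={self.axis_p[a]:.4g}"
            lines.append(
                f"  axis {a + 1}: eigenvalue={self.eigenvalues[a]:.4f} "
                f"({100 * self.proportion[a]:.2f}% of constrained){p}"
            )
        return "\n".join(lines)


class RDA:
    """(Partial) redundancy analysis of a genotype matrix on environment.

    Y (accessions x loci) is centered per locus; Y and the explanatory
    block X are optionally residualized on a conditioning block Z
    (population-structure covariates) before the multivariate least-squares
    fit.  Axes are the SVD of the fitted values.
    """

    def __init__(
        self,
        gm: GenotypeMatrix,
        env: pd.DataFrame,
        conditioning: pd.DataFrame | np.ndarray | None = None,
    ):
        if not gm.is_complete:
            raise ValueError("RDA requires a complete (imputed) genotype matrix")
        self.gm = gm
        self.env = env
        self.Z = None if conditioning is None else np.asarray(conditioning, dtype=float)

    def fit(self) -> RDAResults:
        Y = self.gm.dosage - self.gm.dosage.mean(axis=0)
        X = self.env.to_numpy(dtype=float)
        X = X - X.mean(axis=0)
        n = Y.shape[0]
        ss_total = float((Y**2).sum())

        if self.Z is not None and self.Z.size:
            Z = np.column_stack([np.ones(n), self.Z])
            Qz, _ = np.linalg.qr(Z)
            Y_fit_z = Qz @ (Qz.T @ Y)
            Yr = Y - Y_fit_z
            Xr = X - Qz @ (Qz.T @ X)
            ss_cond = float((Y_fit_z**2).sum())
        else:
            Yr, Xr = Y, X
            ss_cond = 0.0

        # scale-aware rank of the residualized explanatory block: a block
        # entirely absorbed by the conditioning contributes no constrained
        # variance; partial aliasing is an error naming the culprits
        x_scale = max(float(np.linalg.norm(X)), 1e-300)
        col_norm = np.linalg.norm(Xr, axis=0)
        aliased = [self.env.columns[j] for j in np.flatnonzero(col_norm < 1e-8 * x_scale)]
        rank = np.linalg.matrix_rank(Xr, tol=1e-8 * x_scale)
        if rank == 0:
            B = np.zeros((Xr.shape[1], Y.shape[1]))
            fitted = np.zeros_like(Yr)
        elif rank < Xr.shape[1]:
            raise ValueError(
                f"explanatory block rank-deficient after residualization; aliased: {aliased}"
            )
        else:
            Qx, Rx = np.linalg.qr(Xr)
            B = np.linalg.solve(Rx, Qx.T @ Yr)  # env coefficients per locus
            fitted = Xr @ B
        ss_constr = float((fitted**2).sum())
        U, s, Vt = np.linalg.svd(fitted, full_matrices=False)
        keep = s > max(s[0], 1e-12) * 1e-9 if s.size else np.array([], dtype=bool)
        U, s, Vt = U[:, keep], s[keep], Vt[keep]
        eig = s**2 / (n - 1)
        site = U * s  # linear-combination site scores
        axes = [f"RDA{a + 1}" for a in range(s.size)]
        loadings = pd.DataFrame(Vt.T, index=self.gm.markers, columns=axes)
        # correlation biplot scores for the environmental variables
        env_scores = np.zeros((X.shape[1], s.size))
        for j in range(X.shape[1]):
            xj = Xr[:, j]
            for a in range(s.size):
                sa = site[:, a]
                denom = np.sqrt((xj**2).sum() * (sa**2).sum())
                env_scores[j, a] = float(xj @ sa / denom) if denom > 0 else 0.0
        partition = {
            "conditioned": ss_cond / ss_total if ss_total else 0.0,
            "constrained": ss_constr / ss_total if ss_total else 0.0,
        }
        partition["unexplained"] = 1.0 - partition["conditioned"] - partition["constrained"]
        # map from centered scaled env space to axis projections: B @ V
        coefficients = B @ Vt.T
        return RDAResults(
            site_scores=pd.DataFrame(site, index=self.gm.accessions, columns=axes),
            loadings=loadings,
            env_scores=pd.DataFrame(env_scores, index=self.env.columns, columns=axes),
            eigenvalues=eig,
            proportion=eig / eig.sum() if eig.size else eig,
            partition=partition,
            coefficients=coefficients,
            env_names=list(self.env.columns),
        )


def partial_rda(
    gm: GenotypeMatrix, env: pd.DataFrame, conditioning=None
) -> RDAResults:
    """Convenience wrapper: ``RDA(gm, env, conditioning).fit()``."""
    return RDA(gm, env, conditioning).fit()


def rda_axis_significance(
    gm: GenotypeMatrix,
    env: pd.DataFrame,
    conditioning=None,
    n_perm: int = 5000,
    seed: int | None = None,
) -> np.ndarray:
    """Per-axis permutation p-values for a (partial) RDA.

    Rows of the residualized response are permuted under the reduced
    (conditioning-only) model; each permutation's axis eigenvalues come
    from the SVD of the projected response (cheap: p x loci).  The p-value
    per axis is the add-one exceedance probability of its eigenvalue.
    """
    Y = gm.dosage - gm.dosage.mean(axis=0)
    X = env.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    n = Y.shape[0]
    if conditioning is not None and np.asarray(conditioning).size:
        Z = np.column_stack([np.ones(n), np.asarray(conditioning, dtype=float)])
        Qz, _ = np.linalg.qr(Z)
        Yr = Y - Qz @ (Qz.T @ Y)
        Xr = X - Qz @ (Qz.T @ X)
    else:
        Yr, Xr = Y, X
    Qx, _ = np.linalg.qr(Xr)

    def axis_eigs(Ymat: np.ndarray) -> np.ndarray:
        proj = Qx.T @ Ymat  # p x loci; fitted values share its singular values
        s = np.linalg.svd(proj, compute_uv=False)
        return s**2 / (n - 1)

    obs = axis_eigs(Yr)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(obs.size)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        e = axis_eigs(Yr[perm])
        k = min(e.size, obs.size)
        exceed[:k] += e[:k] >= obs[:k]
    return (exceed + 1.0) / (n_perm + 1.0)


def rda_outliers(
    result: RDAResults,
    gm: GenotypeMatrix,
    env: pd.DataFrame,
    n_axes: int = 3,
    sd_mult: float = 2.0,
) -> pd.DataFrame:
    """Loci with |loading - mean| > sd_mult * SD on any of the first axes.

    Each candidate is annotated with the environmental variable of maximal
    absolute correlation with its dosage.
    """
    n_axes = min(n_axes, result.n_axes)
    flagged: set[str] = set()
    for a in range(n_axes):
        lo = result.loadings.iloc[:, a].to_numpy()
        sd = lo.std()
        if sd == 0:
            continue
        hits = np.abs(lo - lo.mean()) > sd_mult * sd
        flagged |= set(np.asarray(result.loadings.index)[hits])
    rows = []
    Xs = env.to_numpy(dtype=float)
    Xs = (Xs - Xs.mean(axis=0)) / np.maximum(Xs.std(axis=0), 1e-12)
    for mk in sorted(flagged, key=result.loadings.index.get_loc):
        j = gm.markers.index(mk)
        g = gm.dosage[:, j]
        gz = (g - g.mean()) / max(g.std(), 1e-12)
        corrs = gz @ Xs / len(gz)
        best = int(np.argmax(np.abs(corrs)))
        rows.append(
            {
                "marker_id": mk,
                "best_env": env.columns[best],
                "correlation": float(corrs[best]),
            }
        )
    return pd.DataFrame(rows, columns=["marker_id", "best_env", "correlation"])


# ---------------------------------------------------------------------------
# Latent-factor association scan (LFMM-style ridge)
# ---------------------------------------------------------------------------

def lfmm_ridge(
    gm: GenotypeMatrix,
    env: pd.DataFrame,
    k: int,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Latent-factor association scan with genomic-inflation calibration.

    Latent factors are the first ``k`` left singular vectors of the
    centered genotype matrix.  Each locus is regressed on [intercept,
    variable, factors]; variable z-scores are calibrated by the genomic
    inflation factor (median z^2 over the chi-square-1 median) and the
    per-locus p is the Bonferroni-adjusted minimum over variables, followed
    by Benjamini-Hochberg across loci at ``fdr``.

    Returns a per-locus frame with z/p columns per variable, the calibrated
    combined p, the BH q-value and the candidate flag.
    """
    if not gm.is_complete:
        raise ValueError("LFMM scan requires a complete genotype matrix")
    Y = gm.dosage - gm.dosage.mean(axis=0)
    n, L = Y.shape
    if k >= min(n, L):
        raise ValueError("k must be smaller than both matrix dimensions")
    U, s, _ = np.linalg.svd(Y, full_matrices=False)
    W = U[:, :k]
    out = pd.DataFrame(index=gm.markers)
    pvals = np.ones((L, env.shape[1]))
    for vi, var in enumerate(env.columns):
        x = env[var].to_numpy(dtype=float)
        x = (x - x.mean()) / max(x.std(), 1e-12)
        X = np.column_stack([np.ones(n), x, W])
        coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ coef
        dof = n - X.shape[1]
        sigma2 = (resid**2).sum(axis=0) / dof
        xtx_inv = np.linalg.inv(X.T @ X)
        se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 1e-300))
        z = _t_to_normal(coef[1] / se, dof)
        gif = np.median(z**2) / chi2_dist.ppf(0.5, 1)
        gif = max(gif, 1e-12)
        p = chi2_dist.sf(z**2 / gif, 1)
        pvals[:, vi] = p
        out[f"z_{var}"] = z
        out[f"p_{var}"] = p
        out.attrs[f"gif_{var}"] = float(gif)
    p_locus = np.minimum(pvals.min(axis=1) * env.shape[1], 1.0)  # Bonferroni over variables
    out["p_combined"] = p_locus
    out["q_value"] = _benjamini_hochberg(p_locus)
    out["candidate"] = out["q_value"] < fdr
    return out


def _t_to_normal(t: np.ndarray, dof: float) -> np.ndarray:
    """Map t-statistics to standard-normal scores of equal tail probability."""
    from scipy.stats import norm, t as t_dist

    logp = t_dist.logsf(np.abs(t), dof)  # one-sided tail, log scale
    z_abs = norm.isf(np.exp(np.clip(logp, -700.0, 0.0)))
    z_abs = np.where(np.isfinite(z_abs), z_abs, np.sqrt(-2.0 * logp))  # deep tail
    return np.sign(t) * z_abs


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


# ---------------------------------------------------------------------------
# PC-based outlier scan (PCAdapt-style)
# ---------------------------------------------------------------------------

def pcadapt_scan(
    gm: GenotypeMatrix,
    k_pcs: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Mahalanobis outlier scan on per-locus PC regression z-scores.

    Loci are regressed on the first ``k_pcs`` principal components of the
    scaled genotype matrix; the z-score vectors are screened by a robust
    Mahalanobis distance (minimum covariance determinant), calibrated by
    the genomic inflation factor against chi-square with ``k_pcs`` df, then
    Bonferroni-adjusted; candidates satisfy adjusted p <= alpha.  Constant
    loci are excluded (flagged NaN).
    """
    if k_pcs < 1:
        raise ValueError("k_pcs must be >= 1")
    Y = gm.dosage.copy()
    n, L = Y.shape
    sd = Y.std(axis=0)
    keep = sd > 0
    if (~keep).any():
        logger.info("pcadapt_scan: %d constant locus/loci excluded", int((~keep).sum()))
    Ys = (Y[:, keep] - Y[:, keep].mean(axis=0)) / sd[keep]
    U, s, _ = np.linalg.svd(Ys, full_matrices=False)
    k_pcs = min(k_pcs, s.size)
    PC = U[:, :k_pcs]  # orthonormal scores
    X = np.column_stack([np.ones(n), PC])
    coef, *_ = np.linalg.lstsq(X, Ys, rcond=None)
    resid = Ys - X @ coef
    dof = n - X.shape[1]
    sigma = np.sqrt(np.maximum((resid**2).sum(axis=0) / dof, 1e-300))
    # PCs are orthonormal: se(beta_j) = sigma / ||pc_j|| = sigma.  The raw
    # ratios are t-distributed (dof residual df); convert to exact normal
    # scores so the chi-square screen is tail-calibrated at finite n.
    T = (coef[1:] / sigma).T  # loci x k
    Z = _t_to_normal(T, dof)
    try:
        # high support fraction: tolerates up to ~10% outlying loci while
        # keeping near-classical efficiency (tail calibration) on null loci
        mcd = MinCovDet(random_state=0, support_fraction=0.9).fit(Z)
        center, cov = mcd.location_, mcd.covariance_
    except ValueError:  # degenerate spread; fall back to classical moments
        center, cov = Z.mean(axis=0), np.cov(Z, rowvar=False).reshape(k_pcs, k_pcs)
    dz = Z - center
    stat = np.einsum("ij,jk,ik->i", dz, np.linalg.pinv(cov), dz)
    gif = max(np.median(stat) / chi2_dist.ppf(0.5, k_pcs), 1e-12)
    p = chi2_dist.sf(stat / gif, k_pcs)
    p_adj = np.minimum(p * p.size, 1.0)  # Bonferroni
    out = pd.DataFrame(index=gm.markers)
    out["mahalanobis"] = np.nan
    out["p_value"] = np.nan
    out["p_bonferroni"] = np.nan
    out.loc[np.asarray(gm.markers)[keep], "mahalanobis"] = stat
    out.loc[np.asarray(gm.markers)[keep], "p_value"] = p
    out.loc[np.asarray(gm.markers)[keep], "p_bonferroni"] = p_adj
    out["candidate"] = out["p_bonferroni"] <= alpha
    out.attrs["gif"] = float(gif)
    return out


# ---------------------------------------------------------------------------
# Candidate union, enriched RDA, genomic offset
# ---------------------------------------------------------------------------

def combine_candidates(
    prda: list[str] | pd.DataFrame,
    lfmm: list[str] | pd.DataFrame,
    pcadapt: list[str] | pd.DataFrame,
) -> dict:
    """Union of per-method candidate sets with overlap bookkeeping."""

    def ids(obj, flag="candidate") -> set:
        if isinstance(obj, pd.DataFrame):
            if "marker_id" in obj.columns:
                return set(obj["marker_id"])
            return set(obj.index[obj[flag]])
        return set(obj)

    s_rda, s_lfmm, s_pca = ids(prda), ids(lfmm), ids(pcadapt)
    union = s_rda | s_lfmm | s_pca
    return {
        "prda": s_rda,
        "lfmm": s_lfmm,
        "pcadapt": s_pca,
        "union": union,
        "n_union": len(union),
        "overlap_prda_lfmm": len(s_rda & s_lfmm),
        "overlap_prda_pcadapt": len(s_rda & s_pca),
        "overlap_lfmm_pcadapt": len(s_lfmm & s_pca),
        "overlap_all": len(s_rda & s_lfmm & s_pca),
    }


def enriched_rda(
    gm: GenotypeMatrix, candidates: list[str], env: pd.DataFrame, n_axes: int = 2
) -> RDAResults:
    """Plain RDA (no conditioning) of candidate loci, truncated to n_axes."""
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate loci")
    idx = [gm.markers.index(m) for m in candidates]
    sub = gm.subset_markers(np.asarray(idx))
    res = RDA(sub, env, conditioning=None).fit()
    if res.n_axes < n_axes:
        logger.warning(
            "enriched_rda: only %d axis/axes available (requested %d)", res.n_axes, n_axes
        )
        n_axes = res.n_axes
    res.site_scores = res.site_scores.iloc[:, :n_axes]
    res.loadings = res.loadings.iloc[:, :n_axes]
    res.env_scores = res.env_scores.iloc[:, :n_axes]
    res.eigenvalues = res.eigenvalues[:n_axes]
    res.proportion = res.proportion[:n_axes]
    res.coefficients = res.coefficients[:, :n_axes]
    return res


@dataclass
class OffsetMap:
    """Per-cell and per-accession genomic offset for one future scenario."""

    scenario: str
    axis_offset: np.ndarray  # n_axes x nrows x ncols
    global_offset: np.ndarray  # nrows x ncols
    projections_current: np.ndarray  # n_axes x nrows x ncols
    projections_future: np.ndarray
    accession_offset: pd.Series


def genomic_offset(
    result: RDAResults,
    scaler: EnvScaler,
    current: dict[str, np.ndarray],
    future: dict[str, np.ndarray] | list[dict[str, np.ndarray]],
    landscape: Landscape,
    scenario: str = "future",
) -> OffsetMap:
    """Genomic offset between current and future adaptive projections.

    Every cell's scaled environment vector is projected onto each retained
    RDA axis (projection = env . coefficients); the per-axis offset is the
    absolute projection change and the global offset the eigenvalue-
    weighted Euclidean distance sqrt(sum_a w_a (delta_a)^2) with
    w_a = eigenvalue_a / sum(retained eigenvalues).  A list of future
    raster sets (e.g. several circulation models for one scenario) is
    averaged cell-wise before projection.  Per-accession offsets are read
    from each accession's collection cell.
    """
    variables = result.env_names
    cur = scaler.transform_grids(current, variables)
    if isinstance(future, list):
        stacks = [scaler.transform_grids(f, variables) for f in future]
        fut = np.mean(stacks, axis=0)
    else:
        fut = scaler.transform_grids(future, variables)
    # centering constant used in the fit: subtract the training means of the
    # scaled variables (scaled training env is ~0-mean already, but be exact)
    coeffs = result.coefficients  # n_vars x n_axes
    n_axes = coeffs.shape[1]
    proj_cur = np.einsum("va,vrc->arc", coeffs, cur)
    proj_fut = np.einsum("va,vrc->arc", coeffs, fut)
    delta = proj_fut - proj_cur
    axis_offset = np.abs(delta)
    w = result.eigenvalues / result.eigenvalues.sum()
    global_offset = np.sqrt(np.einsum("a,arc->rc", w, delta**2))

    acc_vals = {}
    for _, row in landscape.coords.iterrows():
        r, c = landscape.cell_of(row["lat"], row["lon"])
        acc_vals[row["accession_id"]] = float(global_offset[r, c])
    return OffsetMap(
        scenario=scenario,
        axis_offset=axis_offset,
        global_offset=global_offset,
        projections_current=proj_cur,
        projections_future=proj_fut,
        accession_offset=pd.Series(acc_vals, name="global_offset"),
    )


def classify_offset_bands(offset: OffsetMap, band_width: float = 0.5) -> tuple[np.ndarray, pd.Series]:
    """Bin offsets into half-open bands [0, w), [w, 2w), ...

    Returns the banded grid (band index per cell) and per-accession band
    labels.
    """
    grid_bands = np.floor(offset.global_offset / band_width).astype(int)
    acc_bands = np.floor(offset.accession_offset / band_width).astype(int)
    labels = acc_bands.map(
        lambda b: f"[{b * band_width:g}, {(b + 1) * band_width:g})"
    )
    return grid_bands, labels
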