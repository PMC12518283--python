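"""Population diversity and differentiation statistics.

Observed heterozygosity (Ho), unbiased within-population gene diversity
(Hs), total gene diversity (Ht), inbreeding coefficient (Fis), rarefied
allelic richness (Ar), invariant-site-adjusted heterozygosity (HsAdj),
Weir-Cockerham FST (global and pairwise) and a three-level AMOVA (groups >
accessions > gene copies) with permutation significance.

All functions accept a :class:`~genecore.containers.GenotypeMatrix` (alt
dosage, NaN missing) plus a per-accession population label sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from genecore.containers import GenotypeMatrix

logger = logging.getLogger(__name__)


def _groups(labels) -> tuple[np.ndarray, list]:
    labels = np.asarray(labels)
    pops = sorted(pd.unique(labels).tolist())
    return labels, pops


def _pop_counts(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus alt-copy count and diploid call count over the rows given."""
    called = ~np.isnan(dosage)
    n = called.sum(axis=0).astype(float)
    alt = np.nansum(dosage, axis=0)
    return alt, n


# ---------------------------------------------------------------------------
# Heterozygosity
# ---------------------------------------------------------------------------

def observed_heterozygosity(gm: GenotypeMatrix, labels) -> pd.Series:
    """Ho per population and overall: mean over loci of the het fraction.

    Heterozygotes are calls with dosage exactly 1 (round fractional imputed
    dosages before calling this).
    """
    labels, pops = _groups(labels)
    out = {}
    for pop in pops + ["overall"]:
        rows = slice(None) if pop == "overall" else labels == pop
        d = gm.dosage[rows]
        if d.shape[0] == 0:
            raise ValueError(f"population {pop!r} has no accessions")
        called = ~np.isnan(d)
        n = called.sum(axis=0).astype(float)
        het = (d == 1).sum(axis=0)
        with np.errstate(invalid="ignore"):
            ho = het / n
        out[pop] = float(np.nanmean(ho))
    return pd.Series(out, name="Ho")


def expected_heterozygosity(gm: GenotypeMatrix, labels) -> tuple[pd.Series, float]:
    """Unbiased Hs per population and total gene diversity Ht.

    Per locus within a population: (2n/(2n-1)) * (1 - p^2 - q^2) with n the
    diploid call count; Hs is the average over loci (loci with fewer than
    two calls are excluded from that population's average).  Ht applies the
    same formula to the pooled allele frequencies.
    """
    labels, pops = _groups(labels)
    out = {}
    for pop in pops:
        d = gm.dosage[labels == pop]
        alt, n = _pop_counts(d)
        ok = n >= 2
        if (~ok).any():
            logger.info(
                "expected_heterozygosity: %d locus/loci with <2 calls excluded in %s",
                int((~ok).sum()),
                pop,
            )
        p = alt[ok] / (2.0 * n[ok])
        h = (2.0 * n[ok] / (2.0 * n[ok] - 1.0)) * (1.0 - p**2 - (1.0 - p) ** 2)
        out[pop] = float(h.mean()) if h.size else np.nan
    alt, n = _pop_counts(gm.dosage)
    ok = n >= 2
    p = alt[ok] / (2.0 * n[ok])
    ht = float(((2.0 * n[ok] / (2.0 * n[ok] - 1.0)) * (1.0 - p**2 - (1.0 - p) ** 2)).mean())
    return pd.Series(out, name="Hs"), ht


def inbreeding_fis(ho: pd.Series, hs: pd.Series) -> pd.Series:
    """Fis = 1 - Ho/Hs on locus-averaged Ho and Hs (ratio of means)."""
    fis = {}
    for pop in hs.index:
        if hs[pop] == 0:
            fis[pop] = np.nan
        else:
            fis[pop] = 1.0 - ho[pop] / hs[pop]
    return pd.Series(fis, name="Fis")


def adjusted_heterozygosity(hs: float | pd.Series, n_polymorphic: int, n_invariant: int):
    """Invariant-site-adjusted (autosomal) heterozygosity.

    HsAdj = Hs * n_polymorphic / (n_polymorphic + n_invariant).  The
    invariant-site count must be supplied by the caller; SNP panels do not
    carry it.
    """
    if n_polymorphic < 0 or n_invariant < 0:
        raise ValueError("site counts must be non-negative")
    return hs * n_polymorphic / (n_polymorphic + n_invariant)


def allelic_richness(gm: GenotypeMatrix, labels, rarefy_to: int | None = None) -> pd.Series:
    """Rarefied allelic richness per population (alleles per locus in [1, 2]).

    Per locus, the expected number of distinct alleles in a hypergeometric
    draw of ``rarefy_to`` gene copies:
    E = 2 - C(N-n_alt, g)/C(N, g) - C(N-n_ref, g)/C(N, g).
    ``rarefy_to`` defaults to the smallest per-locus call count (in copies)
    across populations.
    """
    labels, pops = _groups(labels)
    copy_counts = []
    for pop in pops:
        _, n = _pop_counts(gm.dosage[labels == pop])
        copy_counts.append(2.0 * n)
    if rarefy_to is None:
        rarefy_to = int(min(c.min() for c in copy_counts))
    if rarefy_to < 2:
        raise ValueError("rarefy_to must be at least 2 gene copies")

    def log_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    out = {}
    g = float(rarefy_to)
    for pop, copies in zip(pops, copy_counts):
        d = gm.dosage[labels == pop]
        alt, n = _pop_counts(d)
        N = 2.0 * n
        n_alt = alt
        n_ref = N - alt
        # P(no alt in draw) = C(N - n_alt, g) / C(N, g), zero when N-n_alt < g
        def absent(n_other):
            ok = (N - n_other) >= g
            pr = np.zeros_like(N)
            pr[ok] = np.exp(log_comb(N[ok] - n_other[ok], g) - log_comb(N[ok], g))
            return pr

        usable = N >= g
        e = 2.0 - absent(n_alt) - absent(n_ref)
        out[pop] = float(e[usable].mean())
    return pd.Series(out, name="Ar")


def diversity_table(
    gm: GenotypeMatrix,
    labels,
    n_invariant: int | None = None,
    rarefy_to: int | None = None,
) -> pd.DataFrame:
    """Per-population Ho/Hs/Fis/Ar (and HsAdj when ``n_invariant`` given)."""
    ho = observed_heterozygosity(gm, labels)
    hs, ht = expected_heterozygosity(gm, labels)
    lab_arr, pops = _groups(labels)
    weights = pd.Series({p: float((lab_arr == p).sum()) for p in pops})
    weights /= weights.sum()
    hs = pd.concat([hs, pd.Series({"overall": float((hs * weights).sum())})])
    fis = inbreeding_fis(ho, hs)
    ar = allelic_richness(gm, labels, rarefy_to)
    ar = pd.concat([ar, pd.Series({"overall": float((ar * weights).sum())})])
    df = pd.DataFrame({"Ho": ho, "Hs": hs, "Fis": fis, "Ar": ar})
    df = df.loc[list(pops) + ["overall"]]
    if n_invariant is not None:
        df["HsAdj"] = adjusted_heterozygosity(df["Hs"], gm.n_markers, n_invariant)
    df.attrs["Ht"] = ht
    return df


def permtest_heterozygosity(
    gm: GenotypeMatrix, labels, n_perm: int = 1000, seed: int | None = None
) -> pd.DataFrame:
    """Pairwise permutation test of Hs differences between populations.

    The statistic is |Hs_i - Hs_j|; the null is built by re-randomizing the
    two populations' accession labels; p uses the add-one rule.
    """
    labels, pops = _groups(labels)
    rng = np.random.default_rng(seed)
    rows = []
    for a in range(len(pops)):
        for b in range(a + 1, len(pops)):
            ia = np.flatnonzero(labels == pops[a])
            ib = np.flatnonzero(labels == pops[b])
            pool = np.concatenate([ia, ib])
            na = ia.size

            def hs_of(rows_idx):
                alt, n = _pop_counts(gm.dosage[rows_idx])
                ok = n >= 2
                p = alt[ok] / (2.0 * n[ok])
                return float(
                    ((2 * n[ok] / (2 * n[ok] - 1)) * (1 - p**2 - (1 - p) ** 2)).mean()
                )

            obs = abs(hs_of(ia) - hs_of(ib))
            exceed = 0
            for _ in range(n_perm):
                perm = rng.permutation(pool)
                stat = abs(hs_of(perm[:na]) - hs_of(perm[na:]))
                if stat >= obs:
                    exceed += 1
            rows.append(
                {
                    "pop_a": pops[a],
                    "pop_b": pops[b],
                    "abs_hs_diff": obs,
                    "p_value": (exceed + 1) / (n_perm + 1),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Weir-Cockerham FST
# ---------------------------------------------------------------------------

def _wc_components(dosage: np.ndarray, labels: np.ndarray, pops: list) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus Weir-Cockerham variance components (a, a+b+c)."""
    r = len(pops)
    L = dosage.shape[1]
    n_i = np.zeros((r, L))
    p_i = np.zeros((r, L))
    h_i = np.zeros((r, L))
    for k, pop in enumerate(pops):
        d = dosage[labels == pop]
        called = ~np.isnan(d)
        n = called.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            n_i[k] = n
            p_i[k] = np.nansum(d, axis=0) / (2.0 * n)
            h_i[k] = (d == 1).sum(axis=0) / n
    n_tot = n_i.sum(axis=0)
    nbar = n_tot / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (n_tot - (n_i**2).sum(axis=0) / n_tot) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / n_tot
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / n_tot
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0
    tot = a + b + c
    ok = np.isfinite(a) & np.isfinite(tot)
    return a[ok], tot[ok]


@dataclass
class FstResult:
    global_fst: float
    pairwise: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        df = self.pairwise.copy()
        df.attrs["global_fst"] = self.global_fst
        return df


def global_and_pairwise_fst(gm: GenotypeMatrix, labels) -> FstResult:
    """Weir-Cockerham theta, multilocus ratio-of-sums.

    Pairwise values use only the two populations' calls.  Negative
    multilocus estimates are reported as computed.  A fully monomorphic
    dataset yields NaN.
    """
    labels, pops = _groups(labels)
    a, tot = _wc_components(gm.dosage, labels, pops)
    denom = tot.sum()
    global_fst = float(a.sum() / denom) if denom != 0 else np.nan
    if not np.isfinite(global_fst):
        logger.warning("global FST undefined (monomorphic data?)")
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            sel = (labels == pops[i]) | (labels == pops[j])
            a2, tot2 = _wc_components(gm.dosage[sel], labels[sel], [pops[i], pops[j]])
            v = float(a2.sum() / tot2.sum()) if tot2.sum() != 0 else np.nan
            mat.iloc[i, j] = v
            mat.iloc[j, i] = v
    return FstResult(global_fst=global_fst, pairwise=mat)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AMOVAResult:
    table: pd.DataFrame  # stratum rows + total

    def __str__(self) -> str:  # pragma: no cover
        return self.table.to_string(index=False)


def _amova_ss(dosage: np.ndarray, labels: np.ndarray, pops: list) -> tuple[float, float, float]:
    """Sums of squares (among groups, among accessions within, within accessions).

    Each diploid accession contributes two gene copies; per locus a copy's
    allele value is 0/1, so the within-accession squared deviation is 0.5
    for a heterozygous call and 0 otherwise.
    """
    M = dosage / 2.0  # accession means per locus
    ss_within = 0.5 * float((dosage == 1).sum())
    grand = M.mean(axis=0)
    ss_among_groups = 0.0
    ss_among_acc = 0.0
    for pop in pops:
        sub = M[labels == pop]
        gmean = sub.mean(axis=0)
        ss_among_acc += 2.0 * float(((sub - gmean) ** 2).sum())
        ss_among_groups += 2.0 * sub.shape[0] * float(((gmean - grand) ** 2).sum())
    return ss_among_groups, ss_among_acc, ss_within


def _variance_components(
    df_values: tuple[float, float, float],
    ss_values: tuple[float, float, float],
    group_sizes: tuple[int, ...],
) -> tuple[float, float, float]:
    """(sigma_groups, sigma_accessions, sigma_within) from df, SS, sizes."""
    df_g, df_a, df_w = df_values
    ss_g, ss_a, ss_w = ss_values
    ms_g, ms_a, ms_w = ss_g / df_g, ss_a / df_a, ss_w / df_w
    sizes = np.asarray(group_sizes, dtype=float)
    N_g = 2.0 * sizes
    N = N_g.sum()
    n0 = (N - (N_g**2).sum() / N) / (len(sizes) - 1)
    return (ms_g - ms_a) / n0, (ms_a - ms_w) / 2.0, ms_w


def amova_components_from_ss(
    df_values: tuple[float, float, float],
    ss_values: tuple[float, float, float],
    group_sizes: tuple[int, ...],
) -> pd.DataFrame:
    """Moment-equation variance components from df, SS and group sizes.

    With N total gene copies and N_g copies in group g, the among-group MS
    carries coefficient n0 = (N - sum N_g^2 / N) / (G - 1) on the
    among-group component and 2 on the among-accession component (two
    copies per accession).  Columns mirror the standard AMOVA table: df,
    SS, MS, variance component, percent variance.
    """
    df_g, df_a, df_w = df_values
    ss_g, ss_a, ss_w = ss_values
    ms_g, ms_a, ms_w = ss_g / df_g, ss_a / df_a, ss_w / df_w
    sigma_g, sigma_a, sigma_w = _variance_components(df_values, ss_values, group_sizes)
    total_var = sigma_g + sigma_a + sigma_w
    rows = [
        ("Among groups", df_g, ss_g, ms_g, sigma_g),
        ("Among accessions within groups", df_a, ss_a, ms_a, sigma_a),
        ("Within accessions", df_w, ss_w, ms_w, sigma_w),
    ]
    table = pd.DataFrame(
        rows, columns=["source", "df", "SS", "MS", "variance_component"]
    )
    table["pct_variance"] = 100.0 * table["variance_component"] / total_var
    total = pd.DataFrame(
        [
            (
                "Total",
                df_g + df_a + df_w,
                ss_g + ss_a + ss_w,
                (ss_g + ss_a + ss_w) / (df_g + df_a + df_w),
                total_var,
                100.0,
            )
        ],
        columns=["source", "df", "SS", "MS", "variance_component", "pct_variance"],
    )
    return pd.concat([table, total], ignore_index=True)


def amova(
    gm: GenotypeMatrix,
    labels,
    n_perm: int = 1000,
    seed: int | None = None,
) -> AMOVAResult:
    """Three-level AMOVA: groups > accessions > gene copies.

    Squared Euclidean distances on per-copy allele vectors; significance of
    the among-group component by permuting accessions among groups, and of
    the among-accession component by permuting the two gene copies among
    accessions within groups (per locus).  Requires a complete (imputed,
    integer-rounded) dosage matrix.
    """
    labels, pops = _groups(labels)
    dosage = gm.dosage
    if np.isnan(dosage).any():
        raise ValueError("AMOVA requires a complete dosage matrix (impute first)")
    dosage = np.round(dosage)
    n = dosage.shape[0]
    G = len(pops)
    sizes = tuple(int((labels == p).sum()) for p in pops)
    if min(sizes) < 2:
        logger.warning("amova: a group has a single accession; its test is skipped")

    ss = _amova_ss(dosage, labels, pops)
    dfs = (G - 1, n - G, n)
    table = amova_components_from_ss(dfs, ss, sizes)

    rng = np.random.default_rng(seed)
    # among-groups: permute accession labels
    obs_g = table.loc[0, "variance_component"]
    exceed_g = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        sg, _, _ = _variance_components(dfs, _amova_ss(dosage, perm, pops), sizes)
        if sg >= obs_g:
            exceed_g += 1
    p_g = (exceed_g + 1) / (n_perm + 1)

    # among-accessions-within-groups: permute gene copies among accessions
    # within each group, per locus (re-pair copies at random)
    obs_a = table.loc[1, "variance_component"]
    exceed_a = 0
    group_idx = [np.flatnonzero(labels == p) for p in pops]
    for _ in range(n_perm):
        d_perm = dosage.copy()
        for idx in group_idx:
            sub = dosage[idx]  # m x L
            m = sub.shape[0]
            # expand to copies: copy1 = ceil(g/2), copy2 = floor(g/2) in {0,1}
            c1 = (sub >= 1).astype(float)
            c2 = (sub == 2).astype(float)
            copies = np.concatenate([c1, c2], axis=0)  # 2m x L
            perm_rows = rng.permuted(
                np.tile(np.arange(2 * m), (sub.shape[1], 1)).T, axis=0
            )
            shuffled = np.take_along_axis(copies, perm_rows, axis=0)
            d_perm[idx] = shuffled[:m] + shuffled[m:]
        _, sa, _ = _variance_components(dfs, _amova_ss(d_perm, labels, pops), sizes)
        if sa >= obs_a:
            exceed_a += 1
    p_a = (exceed_a + 1) / (n_perm + 1)

    table["p_value"] = [p_g if min(sizes) >= 2 else np.nan, p_a, np.nan, np.nan]
    return AMOVAResult(table=table)
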