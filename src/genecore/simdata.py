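"""Synthetic genotype-environment-landscape generator.

Emulates a genebank study design: three geographical populations of sizes
51/152/102 sampled along a latitudinal ecological gradient, ~1,100 biallelic
SNPs on 7 chromosomes drawn from K=4 admixed ancestral groups under a
Balding-Nichols drift model, a handful of environment-associated ("adaptive")
loci whose allele frequencies follow logit-linear clines on an environmental
driver, uniform missingness, and current/future climate grids for two future
scenarios (SSP370 and SSP585).

All randomness flows from ``SimConfig.seed`` through a single
``numpy.random.Generator``, so identical configurations produce identical
datasets and files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit, logit

from genecore.containers import GenotypeMatrix

SCENARIOS = ("SSP370", "SSP585")
#: relative displacement multiplier per scenario (SSP585 is the stronger forcing)
SCENARIO_SCALE = {"SSP370": 1.0, "SSP585": 1.5}

_BASES = np.array(list("ACGT"))
#: transition pairs among the 6 unordered base pairs; the generator draws
#: marker ref/alt pairs with a transition probability of 0.57 so simulated
#: reports show a Ts/Tv ratio in the empirically typical 1.2-1.5 range
_TS_PAIRS = [("A", "G"), ("C", "T")]
_TV_PAIRS = [("A", "C"), ("A", "T"), ("C", "G"), ("G", "T")]
_TS_PROB = 0.57


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic generator.

    Defaults mirror the emulated collection: 305 accessions in three
    populations (51/152/102) on a south-north gradient, four ancestral
    groups, 1,100 SNPs on seven ~50 Mbp chromosomes, 5% missing calls and
    2% of markers with low (<0.8) reproducibility, a 40x25 landscape grid
    carrying six environmental variables, and a one-standard-deviation
    future displacement.
    """

    seed: int = 0
    n_pops: int = 3
    pop_sizes: tuple[int, ...] = (51, 152, 102)
    k_ancestral: int = 4
    n_loci: int = 1100
    n_chromosomes: int = 7
    chrom_length: int = 50_000_000
    fst_drift: float = 0.05
    admix_alpha: float = 0.2
    dominant_boost: float = 1.0
    n_adaptive: int = 20
    cline_strength: float = 1.5
    missing_rate: float = 0.05
    repro_low_fraction: float = 0.02
    grid_shape: tuple[int, int] = (40, 25)
    n_env: int = 6
    future_shift: float = 1.0

    def __post_init__(self) -> None:
        if len(self.pop_sizes) != self.n_pops:
            raise ValueError("pop_sizes length must equal n_pops")
        if not 0.0 < self.fst_drift < 1.0:
            raise ValueError("fst_drift must lie strictly in (0, 1)")
        for name in ("missing_rate", "repro_low_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_adaptive > self.n_loci:
            raise ValueError("n_adaptive cannot exceed n_loci")

    @property
    def n_accessions(self) -> int:
        return int(sum(self.pop_sizes))

    @property
    def pop_labels(self) -> np.ndarray:
        return np.repeat([f"pop{i + 1}" for i in range(self.n_pops)], self.pop_sizes)


@dataclass
class Landscape:
    """Gridded environment: current and per-scenario future variable rasters."""

    current: dict[str, np.ndarray]
    future: dict[str, dict[str, np.ndarray]]  # scenario -> variable -> grid
    xllcorner: float
    yllcorner: float
    cellsize: float
    coords: pd.DataFrame  # accession_id, population, lat, lon

    @property
    def variables(self) -> list[str]:
        return sorted(self.current)

    def cell_of(self, lat: float, lon: float) -> tuple[int, int]:
        """(row, col) of the grid cell containing a coordinate; row 0 is the top."""
        nrows = next(iter(self.current.values())).shape[0]
        col = int((lon - self.xllcorner) / self.cellsize)
        row_from_bottom = int((lat - self.yllcorner) / self.cellsize)
        row = nrows - 1 - row_from_bottom
        if not (0 <= row < nrows) or not (0 <= col < next(iter(self.current.values())).shape[1]):
            raise ValueError(f"coordinate ({lat}, {lon}) falls outside the raster extent")
        return row, col

    def values_at(self, coords: pd.DataFrame, scenario: str | None = None) -> pd.DataFrame:
        grids = self.current if scenario is None else self.future[scenario]
        rows_cols = [self.cell_of(la, lo) for la, lo in zip(coords["lat"], coords["lon"])]
        data = {v: [grids[v][r, c] for r, c in rows_cols] for v in self.variables}
        return pd.DataFrame(data, index=coords["accession_id"].tolist())


@dataclass
class TruthTables:
    """Ground truth retained for parameter-recovery tests."""

    ancestral_freqs: np.ndarray  # K x loci
    q_true: pd.DataFrame  # accessions x K, rows sum to 1
    adaptive_loci: pd.DataFrame  # marker_id, locus_index, driver, strength
    pop_labels: pd.Series
    complete_dosage: np.ndarray = field(repr=False, default=None)


@dataclass
class SimulatedDataset:
    """Bundle returned by :func:`simulate_dataset`."""

    config: SimConfig
    genotypes: GenotypeMatrix
    markers: pd.DataFrame
    samples: pd.DataFrame
    landscape: Landscape
    truth: TruthTables


def simulate_frequencies(config: SimConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Ancestral allele frequencies: K x loci Balding-Nichols draws.

    Each locus has a shared ancestral frequency p ~ U(0.05, 0.95); each of
    the K ancestral groups draws from Beta(p(1-F)/F, (1-p)(1-F)/F) with
    F = ``fst_drift``, giving an expected Weir-Cockerham FST of about F
    between groups.  Entries are clamped into the open interval (0, 1).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    F = config.fst_drift
    p = rng.uniform(0.05, 0.95, size=config.n_loci)
    a = p * (1.0 - F) / F
    b = (1.0 - p) * (1.0 - F) / F
    freqs = rng.beta(a, b, size=(config.k_ancestral, config.n_loci))
    bad = ~np.isfinite(freqs)
    while bad.any():  # pathological draws: resample
        freqs[bad] = rng.beta(
            np.broadcast_to(a, freqs.shape)[bad], np.broadcast_to(b, freqs.shape)[bad]
        )
        bad = ~np.isfinite(freqs)
    return np.clip(freqs, 1e-6, 1.0 - 1e-6)


def simulate_landscape(config: SimConfig, rng: np.random.Generator | None = None) -> Landscape:
    """Gridded environmental variables plus accession coordinates.

    Each variable is a smooth latitudinal gradient (random sign and slope)
    plus spatially correlated noise.  Future grids are the current grid
    displaced by ``future_shift`` standardized units along a per-variable
    direction (scenario SSP585 displaced 1.5x further), with small spatially
    correlated noise proportional to the shift.  Accessions are placed in
    population-specific latitude bands (population 1 southernmost).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    nrows, ncols = config.grid_shape
    cellsize = 0.1
    xll, yll = 0.0, 0.0
    # latitude of each grid row, row 0 = top (ESRI ASCII convention)
    lat_rows = yll + (np.arange(nrows)[::-1] + 0.5) * cellsize
    lat_norm = (lat_rows - lat_rows.min()) / (lat_rows.max() - lat_rows.min())

    current: dict[str, np.ndarray] = {}
    directions: dict[str, float] = {}
    for v in range(config.n_env):
        name = f"env{v + 1}"
        slope = rng.choice([-1.0, 1.0]) * rng.uniform(1.0, 2.0)
        base = slope * np.tile(lat_norm[:, None], (1, ncols))
        noise = gaussian_filter(rng.normal(size=(nrows, ncols)), sigma=3.0, mode="nearest")
        noise = 0.4 * noise / max(noise.std(), 1e-12)
        grid = base + noise
        current[name] = grid
        directions[name] = rng.choice([-1.0, 1.0])

    future: dict[str, dict[str, np.ndarray]] = {}
    for scen in SCENARIOS:
        scale = SCENARIO_SCALE[scen] * config.future_shift
        grids = {}
        for name, grid in current.items():
            sd = grid.std()
            shift = scale * directions[name] * sd
            if scale > 0:
                fnoise = gaussian_filter(rng.normal(size=grid.shape), sigma=3.0, mode="nearest")
                fnoise = 0.1 * scale * sd * fnoise / max(fnoise.std(), 1e-12)
            else:
                fnoise = 0.0
            grids[name] = grid + shift + fnoise
        future[scen] = grids

    # accession coordinates: population-specific latitude bands
    lat_lo, lat_hi = yll, yll + nrows * cellsize
    lon_lo, lon_hi = xll, xll + ncols * cellsize
    band = (lat_hi - lat_lo) / config.n_pops
    lats, lons = [], []
    for p, n in enumerate(config.pop_sizes):
        lo = lat_lo + p * band
        lats.append(rng.uniform(lo + 0.02 * band, lo + 0.98 * band, size=n))
        lons.append(rng.uniform(lon_lo + 0.02, lon_hi - 0.02, size=n))
    coords = pd.DataFrame(
        {
            "accession_id": [f"ACC{i + 1:04d}" for i in range(config.n_accessions)],
            "population": config.pop_labels,
            "lat": np.concatenate(lats),
            "lon": np.concatenate(lons),
        }
    )
    return Landscape(
        current=current,
        future=future,
        xllcorner=xll,
        yllcorner=yll,
        cellsize=cellsize,
        coords=coords,
    )


def plant_adaptive_loci(
    freqs: np.ndarray,
    landscape: Landscape,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Select adaptive loci and their per-accession logit-frequency shifts.

    Returns the adaptive truth table (locus index, driver variable,
    strength) and an accessions x loci matrix of additive logit shifts:
    ``cline_strength`` times the driver variable standardized across
    accession sites, zero at non-adaptive loci.  Applying a zero strength
    leaves frequencies untouched.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_acc = config.n_accessions
    shifts = np.zeros((n_acc, config.n_loci))
    idx = rng.choice(config.n_loci, size=config.n_adaptive, replace=False)
    env_at_sites = landscape.values_at(landscape.coords)
    records = []
    for j in idx:
        driver = landscape.variables[rng.integers(len(landscape.variables))]
        z = env_at_sites[driver].to_numpy()
        z = (z - z.mean()) / max(z.std(), 1e-12)
        shifts[:, j] = config.cline_strength * z
        records.append({"locus_index": int(j), "driver": driver, "strength": config.cline_strength})
    truth = pd.DataFrame(records, columns=["locus_index", "driver", "strength"])
    truth = truth.sort_values("locus_index").reset_index(drop=True)
    return truth, shifts


def simulate_admixture_and_genotypes(
    freqs: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    logit_shifts: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, TruthTables]:
    """Draw admixture proportions and binomial genotypes.

    Per accession i the ancestry vector q_i is Dirichlet with concentration
    ``admix_alpha`` on every component plus ``dominant_boost`` on the
    accession's dominant ancestral group (drawn from a soft population ->
    group preference, so every group contains accessions from all
    populations).  Dosage at locus j is Binomial(2, pi_ij) with
    pi_ij = sum_k q_ik f_kj, optionally displaced on the logit scale by a
    planted adaptive cline.  Missing cells are inserted uniformly at random
    at ``missing_rate``; the pre-missingness dosage matrix is preserved in
    the truth tables.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    K, L = freqs.shape
    n = config.n_accessions
    pops = np.repeat(np.arange(config.n_pops), config.pop_sizes)

    # soft preference of each population for a dominant ancestral group
    pref = np.full((config.n_pops, K), 0.3 / max(K - 1, 1))
    for p in range(config.n_pops):
        pref[p, p % K] = 0.0
        pref[p] *= 0.3 / max(pref[p].sum(), 1e-12)
        pref[p, p % K] = 0.7
    if K > config.n_pops:
        pref[:, config.n_pops :] += 0.15 / max(K - config.n_pops, 1)
    pref /= pref.sum(axis=1, keepdims=True)

    dominant = np.array([rng.choice(K, p=pref[p]) for p in pops])
    conc = np.full((n, K), config.admix_alpha)
    conc[np.arange(n), dominant] += config.dominant_boost
    # Dirichlet via normalized gammas (vectorized over accessions)
    gam = rng.gamma(shape=conc)
    zero_rows = gam.sum(axis=1) == 0  # alpha -> 0 limit: mass on boosted component
    if zero_rows.any():
        gam[zero_rows, dominant[zero_rows]] = 1.0
    q = gam / gam.sum(axis=1, keepdims=True)

    pi = q @ freqs
    if logit_shifts is not None:
        pi = expit(logit(np.clip(pi, 1e-9, 1 - 1e-9)) + logit_shifts)
    pi = np.clip(pi, 1e-9, 1.0 - 1e-9)
    dosage = rng.binomial(2, pi).astype(float)
    complete = dosage.copy()
    if config.missing_rate > 0:
        mask = rng.random(size=dosage.shape) < config.missing_rate
        dosage[mask] = np.nan

    ids = [f"ACC{i + 1:04d}" for i in range(n)]
    marker_ids = [f"SNP{j + 1:05d}" for j in range(L)]
    gm = GenotypeMatrix(accessions=ids, markers=marker_ids, dosage=dosage, provenance="raw")
    truth = TruthTables(
        ancestral_freqs=freqs,
        q_true=pd.DataFrame(q, index=ids, columns=[f"K{k + 1}" for k in range(K)]),
        adaptive_loci=pd.DataFrame(columns=["locus_index", "driver", "strength"]),
        pop_labels=pd.Series(config.pop_labels, index=ids, name="population"),
        complete_dosage=complete,
    )
    return gm, truth


def simulate_marker_metadata(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-marker metadata: position, ref/alt bases, reproducibility.

    Reproducibility is Beta(40, 1)-distributed (median ~0.98) except for a
    ``repro_low_fraction`` of markers drawn uniformly from [0.5, 0.8).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    L = config.n_loci
    chrom = rng.integers(1, config.n_chromosomes + 1, size=L)
    pos = rng.integers(1, config.chrom_length + 1, size=L)
    is_ts = rng.random(L) < _TS_PROB
    pairs = []
    for flag in is_ts:
        pool = _TS_PAIRS if flag else _TV_PAIRS
        ref, alt = pool[rng.integers(len(pool))]
        if rng.random() < 0.5:
            ref, alt = alt, ref
        pairs.append((ref, alt))
    repro = rng.beta(40.0, 1.0, size=L)
    low = rng.random(L) < config.repro_low_fraction
    repro[low] = rng.uniform(0.5, 0.8, size=int(low.sum()))
    df = pd.DataFrame(
        {
            "marker_id": [f"SNP{j + 1:05d}" for j in range(L)],
            "chrom": [f"Chr{c:02d}" for c in chrom],
            "pos": pos,
            "ref": [p[0] for p in pairs],
            "alt": [p[1] for p in pairs],
            "reproducibility": repro,
        }
    )
    return df


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Full synthetic study: landscape, genotypes, marker metadata, truth."""
    rng = np.random.default_rng(config.seed)
    freqs = simulate_frequencies(config, rng)
    landscape = simulate_landscape(config, rng)
    adaptive_truth, shifts = plant_adaptive_loci(freqs, landscape, config, rng)
    gm, truth = simulate_admixture_and_genotypes(freqs, config, rng, logit_shifts=shifts)
    truth.adaptive_loci = adaptive_truth.assign(
        marker_id=[gm.markers[i] for i in adaptive_truth["locus_index"]]
    )
    markers = simulate_marker_metadata(config, rng)
    markers["call_rate"] = 1.0 - np.isnan(gm.dosage).mean(axis=0)
    samples = landscape.coords.copy()
    return SimulatedDataset(
        config=config,
        genotypes=gm,
        markers=markers,
        samples=samples,
        landscape=landscape,
        truth=truth,
    )


def emit_dart_report(
    dataset: SimulatedDataset, outdir: str | Path
) -> dict[str, Path]:
    """Write the DArT-style one-row CSV, samples table, rasters and truth.

    Returns a mapping of logical names to the written paths.  Genotype
    cells use the source coding (0 = reference homozygote, 1 = alternative
    homozygote, 2 = heterozygote, NA = missing).
    """
    from genecore.geno_io import write_dart_csv
    from genecore.rasters import write_esri_ascii

    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover
        raise OSError(f"cannot create output directory {outdir}: {exc}") from exc

    paths: dict[str, Path] = {}
    paths["dart"] = outdir / "dart_report.csv"
    write_dart_csv(dataset.genotypes, dataset.markers, paths["dart"])
    paths["samples"] = outdir / "samples.csv"
    dataset.samples.to_csv(paths["samples"], index=False, lineterminator="\n")

    ls = dataset.landscape
    meta = dict(
        xllcorner=ls.xllcorner, yllcorner=ls.yllcorner, cellsize=ls.cellsize, nodata=-9999.0
    )
    for scen_name, grids in [("current", ls.current)] + [
        (s, ls.future[s]) for s in sorted(ls.future)
    ]:
        d = outdir / "rasters" / scen_name
        d.mkdir(parents=True, exist_ok=True)
        for var, grid in grids.items():
            p = d / f"{var}.asc"
            write_esri_ascii(grid, p, **meta)
            paths[f"raster:{scen_name}:{var}"] = p

    paths["q_true"] = outdir / "truth_q.csv"
    dataset.truth.q_true.to_csv(paths["q_true"], lineterminator="\n")
    paths["adaptive"] = outdir / "truth_adaptive.csv"
    dataset.truth.adaptive_loci.to_csv(paths["adaptive"], index=False, lineterminator="\n")
    return paths
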