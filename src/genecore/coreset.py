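"""Core-collection construction by two-phase allele-coverage + rarity selection.

Phase 1 is a greedy maximum-coverage pass over (locus, allele) pairs: start
from the empty set and repeatedly add the accession contributing the most
not-yet-covered pairs, recording Ny (first size whose coverage reaches the
minimum threshold y) and Nz (first size reaching the maximum threshold z).
Phase 2 tops the Ny-prefix up with the (Nz - Ny) not-yet-selected accessions
of highest total rarity, rewarding carriers of alleles held by few
accessions.  The rarity of a (locus, allele) pair is the inverse of its
carrier count; an accession's total rarity sums the rarities of all pairs
it carries.  An exhaustive-search mode over all subsets exists for small
instances and serves as the test oracle for the greedy phase.

Selection requires a complete dosage matrix (impute and round first).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from genecore.containers import GenotypeMatrix
from genecore.popdiv import expected_heterozygosity, observed_heterozygosity


def _presence(gm: GenotypeMatrix) -> np.ndarray:
    """Accessions x (2 * loci) boolean allele-presence matrix.

    Column 2j is "carries >= 1 ref copy at locus j" (dosage 0 or 1), column
    2j+1 is "carries >= 1 alt copy" (dosage 1 or 2).  Missing calls carry
    nothing.
    """
    d = gm.dosage
    ref = (d <= 1) & ~np.isnan(d)
    alt = (d >= 1) & ~np.isnan(d)
    out = np.empty((gm.n_accessions, 2 * gm.n_markers), dtype=bool)
    out[:, 0::2] = ref
    out[:, 1::2] = alt
    return out


def allele_coverage(subset: list[int] | np.ndarray, gm: GenotypeMatrix) -> float:
    """Fraction of the whole collection's (locus, allele) pairs in ``subset``."""
    P = _presence(gm)
    universe = P.any(axis=0)
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        return 0.0
    covered = P[subset].any(axis=0)
    return float((covered & universe).sum() / universe.sum())


def rarity_scores(gm: GenotypeMatrix) -> tuple[pd.DataFrame, pd.Series]:
    """Per-allele rarity (inverse carrier count) and per-accession totals."""
    P = _presence(gm)
    carriers = P.sum(axis=0).astype(float)
    with np.errstate(divide="ignore"):
        rarity = np.where(carriers > 0, 1.0 / np.maximum(carriers, 1), 0.0)
    allele_df = pd.DataFrame(
        {
            "marker_id": np.repeat(gm.markers, 2),
            "allele": np.tile(["ref", "alt"], gm.n_markers),
            "n_carriers": carriers.astype(int),
            "rarity": rarity,
        }
    )
    totals = pd.Series(P @ rarity, index=gm.accessions, name="total_rarity")
    return allele_df, totals


@dataclass
class CoreResult:
    """Outcome of the two-phase selection."""

    selected: list[str]  # final core, phase-1 order then rarity top-ups
    ny: int
    nz: int
    coverage: float  # achieved coverage of the final core
    rarity: pd.Series  # per-accession total rarity (whole collection)
    coverage_curve: pd.DataFrame  # greedy size -> coverage

    @property
    def size(self) -> int:
        return len(self.selected)


def select_core(gm: GenotypeMatrix, y: float = 0.98, z: float = 0.99) -> CoreResult:
    """Two-phase core selection at coverage thresholds y <= z (fractions).

    Greedy ties (equal coverage gain) break toward higher total rarity,
    then input order.
    """
    if not 0.0 < y <= z <= 1.0:
        raise ValueError("thresholds must satisfy 0 < y <= z <= 1")
    if not gm.is_complete:
        raise ValueError("core selection requires a complete dosage matrix (impute first)")
    P = _presence(gm)
    universe = P.any(axis=0)
    P = P[:, universe]
    n, u = P.shape
    _, totals = rarity_scores(gm)
    rarity_arr = totals.to_numpy()

    covered = np.zeros(u, dtype=bool)
    order: list[int] = []
    remaining = np.ones(n, dtype=bool)
    curve = [(0, 0.0)]
    ny = nz = None
    while covered.sum() < u and remaining.any():
        gains = (P[:, ~covered]).sum(axis=1)
        gains[~remaining] = -1
        best_gain = gains.max()
        cand = np.flatnonzero(gains == best_gain)
        best = cand[np.argmax(rarity_arr[cand])] if cand.size > 1 else cand[0]
        order.append(int(best))
        remaining[best] = False
        covered |= P[best]
        cv = covered.sum() / u
        curve.append((len(order), float(cv)))
        if ny is None and cv >= y:
            ny = len(order)
        if nz is None and cv >= z:
            nz = len(order)
    if ny is None:
        ny = len(order)
    if nz is None:
        nz = len(order)

    prefix = order[:ny]
    pool = [i for i in range(n) if i not in set(prefix)]
    pool.sort(key=lambda i: (-rarity_arr[i], i))
    topups = pool[: nz - ny]
    final_idx = prefix + topups
    final = [gm.accessions[i] for i in final_idx]
    return CoreResult(
        selected=final,
        ny=ny,
        nz=nz,
        coverage=allele_coverage(final_idx, gm),
        rarity=totals,
        coverage_curve=pd.DataFrame(curve, columns=["size", "coverage"]),
    )


def exhaustive_core_size(gm: GenotypeMatrix, y: float) -> int:
    """Smallest subset size achieving coverage >= y, by subset enumeration.

    Exponential; guarded to at most 15 accessions.  Test oracle for the
    greedy phase.
    """
    if gm.n_accessions > 15:
        raise ValueError("exhaustive search is limited to 15 accessions")
    P = _presence(gm)
    universe = P.any(axis=0)
    P = P[:, universe]
    u = universe.sum()
    need = int(np.ceil(y * u - 1e-9))
    for size in range(1, gm.n_accessions + 1):
        for combo in combinations(range(gm.n_accessions), size):
            if P[list(combo)].any(axis=0).sum() >= need:
                return size
    return gm.n_accessions


@dataclass
class CoreEvaluation:
    diversity: pd.DataFrame  # whole vs core: Ho, Hs, Ht
    composition: pd.DataFrame  # per population: count, pct_of_core, pct_of_population


def evaluate_core(core: list[str], gm: GenotypeMatrix, labels) -> CoreEvaluation:
    """Compare Ho/Hs/Ht between the whole collection and the core subset."""
    labels = pd.Series(np.asarray(labels), index=gm.accessions)
    idx = [gm.accessions.index(a) for a in core]
    sub = gm.subset_accessions(np.asarray(idx))
    rows = []
    for name, g, lab in [
        ("whole", gm, labels),
        ("core", sub, labels.loc[core]),
    ]:
        ho = observed_heterozygosity(g, lab)["overall"]
        hs, ht = expected_heterozygosity(g, lab)
        rows.append({"collection": name, "Ho": ho, "Hs": float(hs.mean()), "Ht": ht})
    diversity = pd.DataFrame(rows)

    core_labels = labels.loc[core]
    comp_rows = []
    for pop, count in core_labels.value_counts().sort_index().items():
        comp_rows.append(
            {
                "population": pop,
                "count": int(count),
                "pct_of_core": 100.0 * count / len(core),
                "pct_of_population": 100.0 * count / (labels == pop).sum(),
            }
        )
    return CoreEvaluation(diversity=diversity, composition=pd.DataFrame(comp_rows))
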