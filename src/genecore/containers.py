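"""Shared in-memory containers.

The universal exchange object is :class:`GenotypeMatrix`: accessions x
markers alt-allele dosage (0/1/2) with NaN as the missing sentinel.  Marker
metadata travels as a plain :class:`pandas.DataFrame` (the "marker table")
with the columns listed in :data:`MARKER_COLUMNS`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

#: canonical marker-table columns; metric columns are filled by
#: :func:`genecore.geno_io.compute_marker_metrics`
MARKER_COLUMNS = [
    "marker_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "call_rate",
    "reproducibility",
    "maf",
    "pic",
    "gene_diversity",
    "tstv_class",
]

TRANSITIONS = {frozenset("AG"), frozenset("CT")}


@dataclass
class GenotypeMatrix:
    """Accessions x markers alt-allele dosage matrix.

    dosage[i, j] is the number of alternative-allele copies carried by
    accession i at marker j (0, 1 or 2); missing calls are ``nan``.
    After imputation cells may hold fractional dosages in [0, 2].
    """

    accessions: list[str]
    markers: list[str]
    dosage: np.ndarray
    provenance: str = "raw"

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.accessions), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.accessions)} accessions x {len(self.markers)} markers"
            )

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def is_complete(self) -> bool:
        return not np.isnan(self.dosage).any()

    def subset_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            accessions=list(self.accessions),
            markers=[self.markers[i] for i in np.flatnonzero(index)]
            if index.dtype == bool
            else [self.markers[i] for i in index],
            dosage=self.dosage[:, index].copy(),
            provenance=self.provenance,
        )

    def subset_accessions(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        ids = (
            [self.accessions[i] for i in np.flatnonzero(index)]
            if index.dtype == bool
            else [self.accessions[i] for i in index]
        )
        return GenotypeMatrix(
            accessions=ids,
            markers=list(self.markers),
            dosage=self.dosage[index, :].copy(),
            provenance=self.provenance,
        )

    def with_provenance(self, provenance: str) -> "GenotypeMatrix":
        return replace(self, dosage=self.dosage.copy(), provenance=provenance)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=self.accessions, columns=self.markers)


@dataclass
class FilterReport:
    """Bookkeeping for marker filtering: thresholds and per-criterion counts.

    Per-criterion counts are non-exclusive (a marker failing two criteria is
    counted under both); ``n_removed`` is the size of the union.
    """

    maf_min: float
    callrate_min: float
    repro_min: float
    n_input: int
    n_removed_maf: int
    n_removed_callrate: int
    n_removed_repro: int
    n_removed: int
    n_retained: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "criterion": ["maf", "call_rate", "reproducibility", "union", "retained"],
                "threshold": [self.maf_min, self.callrate_min, self.repro_min, np.nan, np.nan],
                "count": [
                    self.n_removed_maf,
                    self.n_removed_callrate,
                    self.n_removed_repro,
                    self.n_removed,
                    self.n_retained,
                ],
            }
        )


def empty_marker_table(marker_ids: list[str]) -> pd.DataFrame:
    """Marker table skeleton with metric columns unset."""
    df = pd.DataFrame({"marker_id": marker_ids})
    for col in MARKER_COLUMNS[1:]:
        df[col] = np.nan
    df["chrom"] = df["chrom"].astype(object)
    df["tstv_class"] = df["tstv_class"].astype(object)
    return df
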