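"""Shared in-memory containers for the pipeline.

Genotypes are held as an individuals x variants additive dosage matrix
(counts of the alternate allele, 0..2).  The variant catalog is a pandas
DataFrame with one row per variant; functional-class labels live in a
``classes`` column holding frozensets, and simulation truth (causal flags
and effect sizes per trait) in ``causal_<trait>`` / ``effect_<trait>``
columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: recognised functional-class labels
FUNCTIONAL_CLASSES = (
    "GWAS",
    "eeQTL",
    "aseQTL",
    "ieQTL",
    "seQTL",
    "asbQTL",
    "ChIPseqQTL",
    "ATACQTL",
    "coding",
)

CATALOG_COLUMNS = [
    "variant_id",
    "chromosome",
    "position_bp",
    "ref_allele",
    "alt_allele",
    "maf",
    "classes",
]


class ConfigError(ValueError):
    """Raised when a configuration object fails validation."""


@dataclass
class GenotypeMatrix:
    """Individuals x variants dosage matrix with id indices.

    ``dosage`` stores alt-allele counts as float64 (integer-valued for
    simulated data); ``missing`` marks entries whose genotype call is
    absent.  Dosage values under the missing mask are undefined and must
    not be read without imputation.
    """

    individual_ids: list[str]
    variant_ids: list[str]
    dosage: np.ndarray
    missing: np.ndarray | None = None
    _vidx: dict[str, int] = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        n, m = self.dosage.shape
        if len(self.individual_ids) != n or len(self.variant_ids) != m:
            raise ValueError("dosage dimensions inconsistent with id lists")
        if len(set(self.variant_ids)) != m:
            raise ValueError("variant ids not unique")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual ids not unique")
        self._vidx = {v: j for j, v in enumerate(self.variant_ids)}

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def column(self, variant_id: str) -> np.ndarray:
        return self.dosage[:, self._vidx[variant_id]]

    def variant_indices(self, variant_ids) -> np.ndarray:
        try:
            return np.array([self._vidx[v] for v in variant_ids], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"variant id not in matrix: {exc.args[0]}") from None

    def subset_variants(self, variant_ids) -> "GenotypeMatrix":
        idx = self.variant_indices(variant_ids)
        return GenotypeMatrix(
            individual_ids=list(self.individual_ids),
            variant_ids=list(variant_ids),
            dosage=self.dosage[:, idx].copy(),
            missing=None if self.missing is None else self.missing[:, idx].copy(),
        )

    def subset_individuals(self, individual_ids) -> "GenotypeMatrix":
        iidx = {s: i for i, s in enumerate(self.individual_ids)}
        rows = np.array([iidx[s] for s in individual_ids], dtype=np.int64)
        return GenotypeMatrix(
            individual_ids=list(individual_ids),
            variant_ids=list(self.variant_ids),
            dosage=self.dosage[rows, :].copy(),
            missing=None if self.missing is None else self.missing[rows, :].copy(),
        )

    def allele_frequency(self) -> np.ndarray:
        """Alt-allele frequency per variant, ignoring missing entries."""
        if self.missing is None or not self.missing.any():
            return self.dosage.mean(axis=0) / 2.0
        d = np.where(self.missing, np.nan, self.dosage)
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_frequency()
        return np.minimum(p, 1.0 - p)

    def call_rate(self) -> np.ndarray:
        if self.missing is None:
            return np.ones(self.n_variants)
        return 1.0 - self.missing.mean(axis=0)

    def mean_imputed(self) -> np.ndarray:
        """Dosage matrix with missing entries replaced by the column mean."""
        if self.missing is None or not self.missing.any():
            return self.dosage.astype(np.float64, copy=True)
        d = np.where(self.missing, np.nan, self.dosage).astype(np.float64)
        mu = np.nanmean(d, axis=0)
        mu = np.where(np.isnan(mu), 0.0, mu)
        idx = np.where(np.isnan(d))
        d[idx] = mu[idx[1]]
        return d


def validate_catalog(catalog: pd.DataFrame) -> None:
    """Check catalog invariants: unique ids, increasing positions per chromosome."""
    missing_cols = [c for c in CATALOG_COLUMNS if c not in catalog.columns]
    if missing_cols:
        raise ValueError(f"catalog missing columns: {missing_cols}")
    if catalog["variant_id"].duplicated().any():
        raise ValueError("duplicate variant ids in catalog")
    for chrom, grp in catalog.groupby("chromosome"):
        pos = grp["position_bp"].to_numpy()
        if not np.all(np.diff(pos) > 0):
            raise ValueError(f"positions not strictly increasing on chromosome {chrom}")


def catalog_index(catalog: pd.DataFrame) -> pd.DataFrame:
    """Catalog reindexed by variant_id for O(1) metadata lookup."""
    return catalog.set_index("variant_id", drop=False)
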