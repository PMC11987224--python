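"""Molecular phenotypes and QTL tagging statistics.

Covers the construction of splicing-efficiency and intron-expression
phenotypes from spliced/unspliced read counts, the cis scan that tags
each significant feature with its most significant in-window variant,
and the two-stage allele-specific test (pooled Z-statistic gate, then a
linear model on the log allelic ratio).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._core import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "MolecularPhenotype",
    "QtlTagSet",
    "splicing_efficiency_phenotype",
    "intron_expression_phenotype",
    "cis_scan",
    "ase_two_stage_test",
]

#: Haldane-Anscombe pseudocount for log allelic ratios
LOG_RATIO_PSEUDOCOUNT = 0.5


@dataclass
class MolecularPhenotype:
    """Per-feature quantitative phenotypes with cis-window anchors.

    ``values`` is a wide DataFrame (rows = individual_id, columns =
    feature_id); ``meta`` has one row per feature with chromosome and a
    representative position (midpoint) for cis-window construction.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def feature_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class QtlTagSet:
    """Tag variants for one functional class, deduplicated across features."""

    class_label: str
    tags: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["variant_id", "feature_id", "p_value"]
        )
    )

    @property
    def variant_ids(self) -> list[str]:
        return self.tags["variant_id"].tolist()

    def __len__(self) -> int:
        return len(self.tags)


def _dedup_tags(rows: list[dict]) -> pd.DataFrame:
    """One row per variant, keeping the most significant source feature."""
    if not rows:
        return pd.DataFrame(columns=["variant_id", "feature_id", "p_value"])
    df = pd.DataFrame(rows).sort_values(["p_value", "variant_id"], kind="mergesort")
    return df.drop_duplicates("variant_id").reset_index(drop=True)


def _pivot(counts: pd.DataFrame, value: np.ndarray, meta: pd.DataFrame, min_individuals: int) -> MolecularPhenotype:
    long = counts[["individual_id", "feature_id"]].copy()
    long["value"] = value
    wide = long.pivot_table(index="individual_id", columns="feature_id", values="value")
    keep = [c for c in wide.columns if wide[c].notna().sum() >= min_individuals]
    if len(keep) < len(wide.columns):
        logger.info("dropped %d features with < %d individuals", len(wide.columns) - len(keep), min_individuals)
    wide = wide[keep]
    meta = meta[meta["feature_id"].isin(keep)].reset_index(drop=True)
    return MolecularPhenotype(values=wide, meta=meta)


def splicing_efficiency_phenotype(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    pseudocount: float = 0.5,
    min_individuals: int = 20,
) -> MolecularPhenotype:
    """logit of the spliced-read proportion per junction.

    value = logit((spliced + c) / (spliced + unspliced + 2c)); with
    pseudocount c = 0 any zero-total row is dropped and logged.
    """
    s = counts["spliced_count"].to_numpy(dtype=float)
    u = counts["unspliced_count"].to_numpy(dtype=float)
    if (s < 0).any() or (u < 0).any():
        raise ValueError("negative read counts")
    c = float(pseudocount)
    keep = np.ones(len(counts), dtype=bool)
    if c == 0:
        keep = (s > 0) & (u > 0)
        dropped = int((~keep).sum())
        if dropped:
            logger.info("dropped %d rows with zero counts at pseudocount 0", dropped)
    p = (s[keep] + c) / (s[keep] + u[keep] + 2 * c)
    value = np.log(p / (1.0 - p))
    return _pivot(counts[keep], value, meta, min_individuals)


def intron_expression_phenotype(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    min_individuals: int = 20,
) -> MolecularPhenotype:
    """Standardized log1p of the unspliced (pre-mRNA) read count.

    A monotone variance-reducing transform: value = log(unspliced + 1),
    centred and scaled within each feature (constant features map to 0).
    """
    u = counts["unspliced_count"].to_numpy(dtype=float)
    if (u < 0).any():
        raise ValueError("negative read counts")
    phen = _pivot(counts, np.log1p(u), meta, min_individuals)
    vals = phen.values
    sd = vals.std(axis=0, ddof=0)
    degenerate = sd <= 1e-12 * vals.abs().max(axis=0).clip(lower=1.0)
    centred = vals - vals.mean(axis=0)
    centred.loc[:, degenerate] = 0.0
    phen.values = centred.div(sd.where(~degenerate, 1.0), axis=1)
    return phen


def _simple_regression_p(y: np.ndarray, Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized OLS of y on each column of Z; returns (slope, two-sided p)."""
    n = len(y)
    yc = y - y.mean()
    Zc = Z - Z.mean(axis=0)
    zz = np.einsum("ij,ij->j", Zc, Zc)
    yy = float(yc @ yc)
    slope = np.zeros(Z.shape[1])
    pval = np.ones(Z.shape[1])
    ok = (zz > 0) & (yy > 0)
    if n <= 2 or not ok.any():
        return slope, pval
    zy = Zc.T @ yc
    slope[ok] = zy[ok] / zz[ok]
    r2 = np.clip(zy[ok] ** 2 / (zz[ok] * yy), 0.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore"):
        t2 = r2 * df / np.maximum(1.0 - r2, 1e-300)
    pval[ok] = np.clip(2.0 * stats.t.sf(np.sqrt(t2), df), np.finfo(float).tiny, 1.0)
    return slope, pval


def cis_scan(
    genotypes: GenotypeMatrix,
    catalog: pd.DataFrame,
    phen: MolecularPhenotype,
    class_label: str,
    window_bp: int = 1_000_000,
    p_threshold: float = 1e-6,
    maf_min: float = 0.1,
) -> QtlTagSet:
    """Tag each significant feature with its most significant cis variant.

    For every feature, the phenotype is regressed on dosage for every
    variant within ``window_bp`` of the feature position (closed window)
    with MAF > ``maf_min``; if the minimum p-value beats the threshold,
    that variant becomes the feature's tag.  Tags are deduplicated across
    features, keeping the most significant source.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    cat = catalog.reset_index(drop=True)
    maf = cat["maf"].to_numpy()
    chrom = cat["chromosome"].to_numpy()
    pos = cat["position_bp"].to_numpy()
    geno_ids = pd.Index(genotypes.individual_ids)

    rows: list[dict] = []
    for _, feat in phen.meta.iterrows():
        fid = feat["feature_id"]
        sel = (
            (chrom == feat["chromosome"])
            & (np.abs(pos - feat["position_bp"]) <= window_bp)
            & (maf > maf_min)
        )
        if not sel.any():
            logger.info("feature %s: no variant in cis window", fid)
            continue
        y_series = phen.values[fid].dropna()
        common = y_series.index.intersection(geno_ids)
        if len(common) < 3:
            continue
        y = y_series.loc[common].to_numpy(dtype=float)
        sub = genotypes.subset_individuals(list(common))
        idx = np.where(sel)[0]
        Z = sub.mean_imputed()[:, idx]
        _, pvals = _simple_regression_p(y, Z)
        order = np.lexsort((cat["variant_id"].to_numpy()[idx], pos[idx], pvals))
        best = order[0]
        if pvals[best] < p_threshold:
            rows.append(
                {
                    "variant_id": cat["variant_id"].iloc[idx[best]],
                    "feature_id": fid,
                    "p_value": float(pvals[best]),
                }
            )
    return QtlTagSet(class_label=class_label, tags=_dedup_tags(rows))


def ase_two_stage_test(
    counts: pd.DataFrame,
    features: pd.DataFrame,
    genotypes: GenotypeMatrix,
    catalog: pd.DataFrame,
    class_label: str = "aseQTL",
    stage1_gate: float = 1e-3,
    final_threshold: float = 1e-8,
    maf_min: float = 0.1,
    window_bp: int = 1_000_000,
    pseudocount: float = LOG_RATIO_PSEUDOCOUNT,
    min_informative: int = 10,
) -> QtlTagSet:
    """Two-stage allele-specific association test.

    Stage 1: for each candidate cis variant, maternal and paternal counts
    are pooled over the informative individuals heterozygous at the
    candidate and Z = (M - P) / sqrt(M + P) is referred to a standard
    normal (two-sided).  Stage 2: candidates passing the gate are tested
    by least-squares regression of log((maternal + c)/(paternal + c)) on
    candidate dosage over all informative individuals.  Each feature's
    most significant surviving candidate with final p below the threshold
    becomes a tag; tags are deduplicated across features.
    """
    cat = catalog.reset_index(drop=True)
    maf = cat["maf"].to_numpy()
    chrom_arr = cat["chromosome"].to_numpy()
    pos_arr = cat["position_bp"].to_numpy()
    iidx = {s: i for i, s in enumerate(genotypes.individual_ids)}

    rows: list[dict] = []
    for _, feat in features.iterrows():
        fid = feat["feature_id"]
        sub = counts[counts["feature_id"] == fid]
        sub = sub[sub["individual_id"].isin(iidx)]
        if len(sub) < min_informative:
            logger.info("feature %s: only %d informative individuals, skipped", fid, len(sub))
            continue
        ind_rows = np.array([iidx[s] for s in sub["individual_id"]])
        M = sub["maternal_count"].to_numpy(dtype=float)
        P = sub["paternal_count"].to_numpy(dtype=float)
        L = np.log((M + pseudocount) / (P + pseudocount))

        sel = (
            (chrom_arr == feat["chromosome"])
            & (np.abs(pos_arr - feat["position_bp"]) <= window_bp)
            & (maf > maf_min)
        )
        idx = np.where(sel)[0]
        if idx.size == 0:
            continue
        D = genotypes.mean_imputed()[np.ix_(ind_rows, idx)]

        best_p, best_j = np.inf, -1
        for k, j in enumerate(idx):
            het = np.isclose(D[:, k], 1.0)
            if het.sum() < 2:
                continue
            tot = M[het].sum() + P[het].sum()
            if tot <= 0:
                continue
            z = (M[het].sum() - P[het].sum()) / math.sqrt(tot)
            p1 = 2.0 * stats.norm.sf(abs(z))
            if p1 >= stage1_gate:
                continue
            _, p2 = _simple_regression_p(L, D[:, k : k + 1])
            p2 = float(p2[0])
            if p2 < best_p or (
                p2 == best_p
                and best_j >= 0
                and (pos_arr[j], cat["variant_id"].iloc[j])
                < (pos_arr[best_j], cat["variant_id"].iloc[best_j])
            ):
                best_p, best_j = p2, j
        if best_j >= 0 and best_p < final_threshold:
            rows.append(
                {
                    "variant_id": cat["variant_id"].iloc[best_j],
                    "feature_id": fid,
                    "p_value": best_p,
                }
            )
    return QtlTagSet(class_label=class_label, tags=_dedup_tags(rows))
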