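"""Single-marker association scans and the iterative conditional GWAS.

The scan regresses the adjusted phenotype on each variant's dosage plus
a conditioning set of previously selected tag variants (covariate-adjusted
least squares).  The iterative procedure repeatedly takes the single most
significant variant per chromosome below a fixed genome-wide threshold
(default p < 1.9e-10), refits it as a covariate, and rescans until no new
significant variant remains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._core import GenotypeMatrix, catalog_index

logger = logging.getLogger(__name__)

#: genome-wide significance threshold for conditional tag selection
GENOME_WIDE_P = 1.9e-10

__all__ = ["GENOME_WIDE_P", "single_marker_scan", "iterative_conditional_gwas"]


@dataclass
class GwasIteration:
    index: int
    conditioning: tuple[str, ...]
    results: pd.DataFrame
    new_tags: tuple[str, ...]


def _residualize(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Project columns of M onto the orthogonal complement of span(C)."""
    coef, *_ = np.linalg.lstsq(C, M, rcond=None)
    return M - C @ coef


def single_marker_scan(
    genotypes: GenotypeMatrix,
    phenotype: pd.Series,
    covariate_variant_ids: tuple[str, ...] = (),
    extra_covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-variant least-squares association test.

    ``phenotype`` is indexed by individual_id.  Conditioning variants are
    fitted as covariates and excluded from testing.  Monomorphic variants
    (or variants collinear with the conditioning set) get beta = 0,
    p = 1 and ``monomorphic = True``.

    Returns a DataFrame with columns variant_id, beta, se, p_value,
    monomorphic.
    """
    y = phenotype.reindex(genotypes.individual_ids).to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("phenotype missing for some genotyped individuals")
    n = len(y)

    cov_cols = [np.ones(n)]
    for v in covariate_variant_ids:
        cov_cols.append(genotypes.column(v).astype(float))
    if extra_covariates is not None:
        cov_cols.extend(np.atleast_2d(extra_covariates.T))
    C = np.column_stack(cov_cols)
    q = np.linalg.matrix_rank(C)

    test_ids = [v for v in genotypes.variant_ids if v not in set(covariate_variant_ids)]
    Z = genotypes.mean_imputed()[:, genotypes.variant_indices(test_ids)]
    raw_var = Z.var(axis=0)

    y_r = _residualize(y[:, None], C)[:, 0]
    Z_r = _residualize(Z, C)

    zz = np.einsum("ij,ij->j", Z_r, Z_r)
    zy = Z_r.T @ y_r
    yy = float(y_r @ y_r)
    df = n - q - 1
    if df <= 0:
        raise ValueError("not enough residual degrees of freedom")

    ok = (zz > n * 1e-12) & (raw_var > 0)
    beta = np.zeros(len(test_ids))
    se = np.full(len(test_ids), np.nan)
    pval = np.ones(len(test_ids))
    beta[ok] = zy[ok] / zz[ok]
    rss = np.maximum(yy - beta[ok] ** 2 * zz[ok], 0.0)
    sigma2 = rss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        se_ok = np.sqrt(sigma2 / zz[ok])
        t = np.where(se_ok > 0, beta[ok] / se_ok, np.inf)
    se[ok] = se_ok
    pval[ok] = np.clip(2.0 * stats.t.sf(np.abs(t), df), np.finfo(float).tiny, 1.0)

    return pd.DataFrame(
        {
            "variant_id": test_ids,
            "beta": beta,
            "se": se,
            "p_value": pval,
            "monomorphic": ~ok,
        }
    )


def iterative_conditional_gwas(
    genotypes: GenotypeMatrix,
    catalog: pd.DataFrame,
    phenotype: pd.Series,
    threshold: float = GENOME_WIDE_P,
    max_iterations: int = 20,
    extra_covariates: np.ndarray | None = None,
    return_history: bool = False,
):
    """Iterate scan-and-condition until no new genome-wide hit remains.

    Each iteration scans conditioning on all previously selected tags,
    then takes at most one variant per chromosome: the most significant
    one with p below ``threshold``, ties broken by (smaller p, lower
    position, lexicographic id).  Tags are never removed.  Returns the
    tag set (sorted by selection order) — and the per-iteration history
    when ``return_history`` is set.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0,1)")
    cat = catalog_index(catalog)
    tags: list[str] = []
    history: list[GwasIteration] = []
    for it in range(max_iterations):
        res = single_marker_scan(
            genotypes, phenotype, tuple(tags), extra_covariates=extra_covariates
        )
        res = res.merge(
            catalog[["variant_id", "chromosome", "position_bp"]], on="variant_id"
        )
        sig = res[res["p_value"] < threshold]
        new: list[str] = []
        for _, grp in sig.groupby("chromosome"):
            best = grp.sort_values(
                ["p_value", "position_bp", "variant_id"], kind="mergesort"
            ).iloc[0]
            new.append(best["variant_id"])
        history.append(
            GwasIteration(index=it, conditioning=tuple(tags), results=res, new_tags=tuple(new))
        )
        if not new:
            break
        tags.extend(sorted(new, key=lambda v: (cat.loc[v, "chromosome"], cat.loc[v, "position_bp"])))
    else:
        logger.warning("conditional GWAS hit max_iterations=%d without converging", max_iterations)
    if return_history:
        return tags, history
    return tags
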