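"""SNP panel construction: benchmark QC, LD blocking, representative
selection, MAF-spectrum matching, final filters and random baselines.

The functional panel pipeline mirrors chip-design practice: candidate tag
variants are collapsed into LD blocks (single-linkage at r2 >= 0.98), one
representative per block is kept with expression/coding/GWAS classes
prioritized, the survivor set is subsampled within MAF bins of width 0.05
to match the benchmark chip's allele-frequency spectrum, and a final
biallelic MAF >= 0.1 filter is applied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._core import GenotypeMatrix, catalog_index

logger = logging.getLogger(__name__)

__all__ = [
    "Panel",
    "LdBlockAssignment",
    "benchmark_qc_filter",
    "assign_ld_blocks",
    "select_block_representatives",
    "maf_bin_histogram",
    "match_maf_spectrum",
    "final_filter",
    "sample_matched_random_panel",
    "hwe_exact_midp",
    "pairwise_r2",
]

MAF_BIN_WIDTH = 0.05
N_MAF_BINS = 10

# representative-priority tiers, highest first
_TIER_EXPRESSION = frozenset({"eeQTL", "eQTL"})
_TIER_CODING = frozenset({"coding"})
_TIER_GWAS = frozenset({"GWAS"})


@dataclass
class Panel:
    """A named ordered set of variant ids with construction provenance."""

    name: str
    variant_ids: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError("panel variant ids not unique")

    def __len__(self) -> int:
        return len(self.variant_ids)

    def log(self, message: str) -> None:
        self.provenance.setdefault("log", []).append(message)


@dataclass
class LdBlockAssignment:
    variant_to_block: dict[str, int]
    block_members: dict[int, list[str]]

    def n_blocks(self) -> int:
        return len(self.block_members)


# ---------------------------------------------------------------------------
# statistics helpers
# ---------------------------------------------------------------------------

def pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage columns over complete pairs."""
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 2:
        return 0.0
    vx, vy = x.var(), y.var()
    if vx == 0 or vy == 0:
        return 0.0
    c = np.corrcoef(x, y)[0, 1]
    return float(c * c)


def hwe_exact_midp(n_het: int, n_hom_rare: int, n_hom_common: int) -> float:
    """Exact conditional Hardy-Weinberg test, mid-p convention.

    Enumerates all heterozygote counts compatible with the observed
    allele counts; the mid-p value sums the probabilities of tables less
    probable than the observed one plus half the probability of tables
    exactly as probable (including the observed).
    """
    if min(n_het, n_hom_rare, n_hom_common) < 0:
        raise ValueError("negative genotype count")
    n = n_het + n_hom_rare + n_hom_common
    if n == 0:
        return 1.0
    rare = 2 * n_hom_rare + n_het
    if rare > n:  # make 'rare' the minor allele count
        rare = 2 * n - rare
    hets = range(rare % 2, rare + 1, 2)
    logprobs = {}
    lognf = math.lgamma(n + 1)
    for h in hets:
        hr = (rare - h) // 2
        hc = n - h - hr
        if hc < 0:
            continue
        lp = (
            lognf
            - math.lgamma(h + 1)
            - math.lgamma(hr + 1)
            - math.lgamma(hc + 1)
            + h * math.log(2.0)
            + math.lgamma(rare + 1)
            + math.lgamma(2 * n - rare + 1)
            - math.lgamma(2 * n + 1)
        )
        logprobs[h] = lp
    # observed het count identifies the table regardless of which allele is minor
    obs = logprobs.get(n_het)
    if obs is None:
        raise ValueError("observed genotype counts incompatible with allele counts")
    p = 0.0
    for h, lp in logprobs.items():
        if lp < obs - 1e-12:
            p += math.exp(lp)
        elif lp <= obs + 1e-12:
            p += 0.5 * math.exp(lp)
    return min(1.0, p)


def _genotype_counts(dosage: np.ndarray, missing: np.ndarray | None) -> tuple[int, int, int]:
    d = dosage
    if missing is not None:
        d = d[~missing]
    d = np.rint(d).astype(int)
    n_ref = int((d == 0).sum())
    n_het = int((d == 1).sum())
    n_alt = int((d == 2).sum())
    return n_het, min(n_ref, n_alt), max(n_ref, n_alt)


# ---------------------------------------------------------------------------
# benchmark QC
# ---------------------------------------------------------------------------

def benchmark_qc_filter(
    genotypes: GenotypeMatrix,
    catalog: pd.DataFrame,
    maf_min: float = 0.02,
    call_rate_min: float = 0.9,
    ld_r2_max: float = 0.9,
    hwe_p_min: float = 0.15,
    window_bp: int = 1_000_000,
    name: str = "benchmark",
) -> Panel:
    """QC filters for the generic chip panel, applied in order.

    (1) MAF >= ``maf_min``; (2) call rate >= ``call_rate_min``;
    (3) greedy LD pruning, keeping the earlier-position member of any
    pair with r2 > ``ld_r2_max`` within ``window_bp``; (4) exact
    Hardy-Weinberg test (mid-p), removing variants with p < ``hwe_p_min``.
    """
    cat = catalog_index(catalog)
    maf = genotypes.maf()
    call = genotypes.call_rate()
    ids = np.array(genotypes.variant_ids)

    keep = (maf >= maf_min) & (call >= call_rate_min)
    log = [
        f"maf>={maf_min}: removed {int((maf < maf_min).sum())}",
        f"call_rate>={call_rate_min}: removed {int((call < call_rate_min).sum())}",
    ]

    # LD pruning per chromosome in position order
    imputed = genotypes.mean_imputed()
    survivors: list[str] = []
    sub = cat.loc[ids[keep]]
    for _, grp in sub.groupby("chromosome"):
        grp = grp.sort_values("position_bp")
        kept_rows: list[tuple[str, int, np.ndarray]] = []
        for vid, pos in zip(grp["variant_id"], grp["position_bp"]):
            col = imputed[:, genotypes.variant_indices([vid])[0]]
            pruned = False
            for kvid, kpos, kcol in kept_rows:
                if pos - kpos > window_bp:
                    continue
                if pairwise_r2(col, kcol) > ld_r2_max:
                    pruned = True
                    break
            if not pruned:
                kept_rows.append((vid, pos, col))
        survivors.extend(v for v, _, _ in kept_rows)
    log.append(f"ld_prune r2>{ld_r2_max}: kept {len(survivors)} of {int(keep.sum())}")

    final: list[str] = []
    for vid in survivors:
        j = genotypes.variant_indices([vid])[0]
        miss = None if genotypes.missing is None else genotypes.missing[:, j]
        n_het, n_rare, n_common = _genotype_counts(genotypes.dosage[:, j], miss)
        if hwe_exact_midp(n_het, n_rare, n_common) >= hwe_p_min:
            final.append(vid)
    log.append(f"hwe p<{hwe_p_min}: removed {len(survivors) - len(final)}")

    if not final:
        raise ValueError("benchmark QC left no surviving variants")
    panel = Panel(name=name, variant_ids=final, provenance={"log": log})
    _attach_provenance(panel, catalog)
    return panel


# ---------------------------------------------------------------------------
# LD blocks and representatives
# ---------------------------------------------------------------------------

def assign_ld_blocks(
    genotypes: GenotypeMatrix,
    candidates: list[str],
    catalog: pd.DataFrame,
    r2_threshold: float = 0.98,
    window_bp: int | None = 1_000_000,
) -> LdBlockAssignment:
    """Single-linkage LD blocks at r2 >= threshold within a window.

    Blocks are connected components of the graph joining candidate pairs
    on the same chromosome with r2 >= ``r2_threshold`` and positional
    distance <= ``window_bp`` (no distance restriction when None).
    """
    cat = catalog_index(catalog)
    parent = {v: v for v in candidates}

    def find(v: str) -> str:
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    imputed = genotypes.mean_imputed()
    cols = {v: imputed[:, genotypes.variant_indices([v])[0]] for v in candidates}
    sub = cat.loc[candidates]
    for _, grp in sub.groupby("chromosome"):
        grp = grp.sort_values("position_bp")
        vids = grp["variant_id"].tolist()
        poss = grp["position_bp"].tolist()
        for i in range(len(vids)):
            for j in range(i + 1, len(vids)):
                if window_bp is not None and poss[j] - poss[i] > window_bp:
                    break
                if pairwise_r2(cols[vids[i]], cols[vids[j]]) >= r2_threshold:
                    union(vids[i], vids[j])

    roots: dict[str, int] = {}
    variant_to_block: dict[str, int] = {}
    block_members: dict[int, list[str]] = {}
    for v in candidates:
        r = find(v)
        if r not in roots:
            roots[r] = len(roots)
        b = roots[r]
        variant_to_block[v] = b
        block_members.setdefault(b, []).append(v)
    return LdBlockAssignment(variant_to_block=variant_to_block, block_members=block_members)


def _priority_tier(classes: frozenset) -> int:
    if classes & _TIER_EXPRESSION:
        return 0
    if classes & _TIER_CODING:
        return 1
    if classes & _TIER_GWAS:
        return 2
    return 3


def select_block_representatives(
    blocks: LdBlockAssignment, catalog: pd.DataFrame
) -> list[str]:
    """One representative per block, expression QTL > coding > GWAS > rest.

    Within a tier, ties break toward the variant carrying more class
    labels, then the lower position, then lexicographic id.
    """
    cat = catalog_index(catalog)
    reps = []
    for b in sorted(blocks.block_members):
        members = blocks.block_members[b]
        best = min(
            members,
            key=lambda v: (
                _priority_tier(cat.loc[v, "classes"]),
                -len(cat.loc[v, "classes"]),
                cat.loc[v, "position_bp"],
                v,
            ),
        )
        reps.append(best)
    return reps


# ---------------------------------------------------------------------------
# MAF spectrum matching
# ---------------------------------------------------------------------------

def maf_bin_histogram(
    variant_ids: list[str], catalog: pd.DataFrame, bin_width: float = MAF_BIN_WIDTH
) -> np.ndarray:
    """Counts per half-open MAF bin [k*w, (k+1)*w); MAF 0.5 in the top bin."""
    cat = catalog_index(catalog)
    n_bins = int(round(0.5 / bin_width))
    counts = np.zeros(n_bins, dtype=np.int64)
    for v in variant_ids:
        maf = float(cat.loc[v, "maf"])
        if not 0.0 <= maf <= 0.5:
            raise ValueError(f"MAF of {v} outside [0, 0.5]: {maf}")
        k = min(int(maf / bin_width), n_bins - 1)
        counts[k] += 1
    return counts


def match_maf_spectrum(
    candidates: list[str],
    reference_histogram: np.ndarray,
    catalog: pd.DataFrame,
    seed: int,
    bin_width: float = MAF_BIN_WIDTH,
    name: str = "maf_matched",
) -> Panel:
    """Subsample candidates within MAF bins to match a reference histogram.

    Within each bin, candidates are drawn without replacement with
    probability proportional to the number of distinct functional-class
    labels they carry (variants tagging QTL in more categories are
    preferred).  Bins with fewer candidates than the reference count keep
    everything and log the shortfall.
    """
    cat = catalog_index(catalog)
    rng = np.random.default_rng(seed)
    n_bins = len(reference_histogram)
    binned: dict[int, list[str]] = {k: [] for k in range(n_bins)}
    for v in candidates:
        maf = float(cat.loc[v, "maf"])
        k = min(int(maf / bin_width), n_bins - 1)
        binned[k].append(v)

    chosen: list[str] = []
    shortfalls: dict[int, int] = {}
    for k in range(n_bins):
        want = int(reference_histogram[k])
        have = binned[k]
        if want <= 0:
            continue
        if len(have) <= want:
            chosen.extend(have)
            if len(have) < want:
                shortfalls[k] = want - len(have)
            continue
        weights = np.array([max(1, len(cat.loc[v, "classes"])) for v in have], dtype=float)
        pick = rng.choice(len(have), size=want, replace=False, p=weights / weights.sum())
        chosen.extend(have[i] for i in sorted(pick))
    if shortfalls:
        logger.warning("MAF-bin shortfalls (bin -> deficit): %s", shortfalls)

    panel = Panel(name=name, variant_ids=chosen)
    panel.provenance["shortfalls"] = shortfalls
    panel.log(f"matched to reference histogram with total {int(np.sum(reference_histogram))}")
    _attach_provenance(panel, catalog)
    return panel


def final_filter(panel: Panel, catalog: pd.DataFrame, maf_min: float = 0.1) -> Panel:
    """Keep biallelic variants with MAF >= ``maf_min``."""
    cat = catalog_index(catalog)
    kept = []
    for v in panel.variant_ids:
        row = cat.loc[v]
        if "," in str(row["alt_allele"]):
            continue
        if float(row["maf"]) < maf_min:
            continue
        kept.append(v)
    out = Panel(name=f"{panel.name}_final", variant_ids=kept, provenance=dict(panel.provenance))
    out.log(f"final filter: biallelic & maf>={maf_min}, kept {len(kept)} of {len(panel)}")
    _attach_provenance(out, catalog)
    return out


def sample_matched_random_panel(current_panel: Panel, n: int, seed: int) -> Panel:
    """Uniform sample without replacement from the benchmark panel."""
    if n > len(current_panel):
        raise ValueError(f"requested {n} > panel size {len(current_panel)}")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(current_panel), size=n, replace=False)
    ids = sorted(current_panel.variant_ids[i] for i in pick)
    return Panel(
        name=f"{current_panel.name}_random{n}",
        variant_ids=ids,
        provenance={"log": [f"uniform sample of {n} from {current_panel.name} (seed {seed})"]},
    )


def _attach_provenance(panel: Panel, catalog: pd.DataFrame) -> None:
    cat = catalog_index(catalog)
    counts: dict[str, int] = {}
    for v in panel.variant_ids:
        for c in cat.loc[v, "classes"]:
            counts[c] = counts.get(c, 0) + 1
    panel.provenance["class_counts"] = counts
    panel.provenance["maf_histogram"] = maf_bin_histogram(panel.variant_ids, catalog).tolist()
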