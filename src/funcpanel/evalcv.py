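"""Cross-validated genomic prediction accuracy and panel benchmarking.

Accuracy is the Pearson correlation between predicted GEBVs and adjusted
phenotypes within each validation fold; the improvement of a functional
panel over its size-matched random baseline is
100 x (functional - current) / current.  One fold plan is drawn per
experiment and reused for every panel so comparisons are paired.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._core import GenotypeMatrix
from .bayescpi import BayesCpiConfig, predict_gebv, run_bayescpi
from .panel import Panel, sample_matched_random_panel

logger = logging.getLogger(__name__)

__all__ = [
    "FoldPlan",
    "EvaluationReport",
    "make_folds",
    "cross_validate",
    "improvement",
    "benchmark_experiment",
]


@dataclass
class FoldPlan:
    k: int
    assignments: pd.Series  # individual_id -> fold index
    seed: int

    def validation_ids(self, fold: int) -> list[str]:
        return self.assignments.index[self.assignments == fold].tolist()

    def training_ids(self, fold: int) -> list[str]:
        return self.assignments.index[self.assignments != fold].tolist()

    def sizes(self) -> list[int]:
        return [int((self.assignments == f).sum()) for f in range(self.k)]


@dataclass
class EvaluationReport:
    """Per (panel, trait) accuracies and improvements over baselines."""

    rows: pd.DataFrame
    fold_seed: int
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "fold_seed": self.fold_seed,
                "config": self.config,
                "rows": self.rows.to_dict(orient="records"),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "EvaluationReport":
        obj = json.loads(text)
        return cls(
            rows=pd.DataFrame(obj["rows"]),
            fold_seed=obj["fold_seed"],
            config=obj.get("config", {}),
        )


def make_folds(individual_ids, k: int = 5, seed: int = 0) -> FoldPlan:
    """Random permutation split into k mutually exclusive near-equal folds.

    Fold sizes differ by at most one (the first n mod k folds get the
    extra individual).
    """
    ids = list(individual_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate individual ids")
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(ids) < k:
        raise ValueError("fewer individuals than folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    base, extra = divmod(len(ids), k)
    fold = np.empty(len(ids), dtype=np.int64)
    start = 0
    for f in range(k):
        size = base + (1 if f < extra else 0)
        fold[perm[start : start + size]] = f
        start += size
    return FoldPlan(k=k, assignments=pd.Series(fold, index=ids), seed=seed)


def cross_validate(
    panel: Panel,
    genotypes: GenotypeMatrix,
    phenotype: pd.Series,
    config: BayesCpiConfig,
    folds: FoldPlan,
    min_fold_size: int = 10,
) -> np.ndarray:
    """Per-fold prediction accuracies for one panel and trait.

    Each fold's model is trained on the remaining folds with a seed
    derived from the config seed and fold index; accuracy is the Pearson
    correlation of the validation GEBVs with the adjusted phenotypes.
    """
    missing = set(folds.assignments.index) - set(phenotype.index)
    if missing:
        raise ValueError(f"phenotype missing for {len(missing)} fold individuals")
    # canonical genomic order: marker-update order must not depend on how
    # the panel happened to list its ids
    wanted = set(panel.variant_ids)
    ordered = [v for v in genotypes.variant_ids if v in wanted]
    if len(ordered) != len(wanted):
        raise KeyError("panel contains variants absent from the genotype matrix")
    gm_panel = genotypes.subset_variants(ordered)
    accs = np.empty(folds.k)
    for f in range(folds.k):
        val_ids = folds.validation_ids(f)
        if len(val_ids) < min_fold_size:
            raise ValueError(f"fold {f} has only {len(val_ids)} individuals")
        train_ids = folds.training_ids(f)
        gm_train = gm_panel.subset_individuals(train_ids)
        gm_val = gm_panel.subset_individuals(val_ids)
        fit = run_bayescpi(
            gm_train,
            phenotype.loc[train_ids],
            replace(config, seed=(config.seed * 1000 + f) % (2**31 - 1)),
        )
        gebv = predict_gebv(fit, gm_val)
        y_val = phenotype.loc[val_ids].to_numpy(dtype=float)
        accs[f] = _safe_corr(gebv, y_val)
    return accs


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def improvement(functional_accuracy: float, current_accuracy: float) -> float:
    """Percent improvement: 100 x (functional - current) / current."""
    if current_accuracy == 0:
        raise ZeroDivisionError("baseline accuracy is zero; improvement undefined")
    return 100.0 * (functional_accuracy - current_accuracy) / current_accuracy


def benchmark_experiment(
    functional_panels: dict[str, Panel],
    current_panel: Panel,
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    traits: list[str],
    config: BayesCpiConfig,
    k: int = 5,
    seed: int = 0,
    n_baseline_draws: int = 1,
) -> EvaluationReport:
    """Functional panels vs size-matched random baselines, paired folds.

    For every functional panel and trait, cross-validated accuracy is
    computed for the panel and for a random sample of equal size drawn
    from the benchmark panel (averaged over ``n_baseline_draws`` draws);
    the identical fold plan is reused throughout so the comparison is
    paired.  ``phenotypes`` holds adjusted phenotypes, indexed by
    individual_id.
    """
    folds = make_folds(genotypes.individual_ids, k=k, seed=seed)
    rows = []
    for name, fpanel in functional_panels.items():
        n = len(fpanel)
        if n > len(current_panel):
            logger.warning(
                "panel %s larger than benchmark; baseline uses whole benchmark panel", name
            )
            n = len(current_panel)
        name_tag = zlib.crc32(name.encode()) % 1000  # stable across processes
        baselines = [
            sample_matched_random_panel(
                current_panel, n, seed=(seed * 10_000 + 7919 * d + name_tag) % (2**31 - 1)
            )
            for d in range(n_baseline_draws)
        ]
        for trait in traits:
            y = phenotypes[trait] if trait in phenotypes else phenotypes.set_index("individual_id")[trait]
            func_accs = cross_validate(fpanel, genotypes, y, config, folds)
            base_accs = np.mean(
                [cross_validate(b, genotypes, y, config, folds) for b in baselines], axis=0
            )
            rows.append(
                {
                    "panel": name,
                    "trait": trait,
                    "n_variants": n,
                    "fold_accuracies": [float(a) for a in func_accs],
                    "accuracy": float(func_accs.mean()),
                    "baseline_fold_accuracies": [float(a) for a in base_accs],
                    "baseline_accuracy": float(base_accs.mean()),
                    "improvement_pct": improvement(float(func_accs.mean()), float(base_accs.mean())),
                }
            )
    return EvaluationReport(
        rows=pd.DataFrame(rows),
        fold_seed=seed,
        config={
            "k": k,
            "chain_length": config.chain_length,
            "burn_in": config.burn_in,
            "thin": config.thin,
            "n_baseline_draws": n_baseline_draws,
        },
    )
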