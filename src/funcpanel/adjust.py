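"""Fixed-effects adjustment of raw phenotypes.

Raw phenotypes are modelled as y = X beta + e, where X carries
systematic genetic covariates (heterosis, breed, inbreeding) and
non-genetic factors (contemporary group, breed x age interactions,
polynomial lactation-curve covariates).  The residuals y - X beta_hat
("yield deviations") are the response used by every downstream genomic
analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

logger = logging.getLogger(__name__)

__all__ = [
    "DesignSpec",
    "DesignMatrix",
    "FixedEffectsFit",
    "build_design",
    "fit_and_adjust",
    "legendre_covariates",
]


@dataclass
class DesignSpec:
    """Which columns of the raw table enter the design.

    ``factors`` are expanded to treatment-coded indicator columns (first
    level dropped); ``covariates`` pass through; ``interactions`` are
    pairs of column names whose expanded bases are multiplied.
    """

    factors: tuple[str, ...] = ()
    covariates: tuple[str, ...] = ()
    interactions: tuple[tuple[str, str], ...] = ()
    intercept: bool = True


@dataclass
class DesignMatrix:
    X: np.ndarray
    column_names: list[str]
    individual_ids: list[str]
    dropped: list[str] = field(default_factory=list)


@dataclass
class FixedEffectsFit:
    trait: str
    column_names: list[str]
    coefficients: np.ndarray
    residual_variance: float
    n_used: int
    rank: int
    aliased_columns: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "trait": self.trait,
            "coefficients": dict(zip(self.column_names, map(float, self.coefficients))),
            "residual_variance": float(self.residual_variance),
            "n_used": self.n_used,
            "rank": self.rank,
            "aliased_columns": self.aliased_columns,
        }


def _factor_basis(series: pd.Series, name: str) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded indicators, first (sorted) level dropped."""
    levels = sorted(pd.unique(series.dropna()), key=str)
    cols, names = [], []
    for lev in levels[1:]:
        cols.append((series == lev).to_numpy(dtype=float))
        names.append(f"{name}[{lev}]")
    if not cols:
        return np.empty((len(series), 0)), []
    return np.column_stack(cols), names


def _term_basis(raw: pd.DataFrame, name: str, spec: DesignSpec) -> tuple[np.ndarray, list[str]]:
    if name in spec.factors:
        return _factor_basis(raw[name], name)
    return raw[name].to_numpy(dtype=float)[:, None], [name]


def build_design(raw: pd.DataFrame, spec: DesignSpec) -> DesignMatrix:
    """Expand the design: intercept, factor indicators, covariates, interactions.

    Column order is deterministic: intercept, factors in spec order,
    covariates in spec order, then interactions.  Single-level factors
    are dropped with a warning.
    """
    for name in list(spec.factors) + list(spec.covariates):
        if name not in raw.columns:
            raise KeyError(f"design term {name!r} not in table")
    blocks: list[np.ndarray] = []
    names: list[str] = []
    dropped: list[str] = []
    n = len(raw)
    if spec.intercept:
        blocks.append(np.ones((n, 1)))
        names.append("intercept")
    for f in spec.factors:
        B, bn = _factor_basis(raw[f], f)
        if not bn:
            logger.warning("factor %r has a single level; column dropped", f)
            dropped.append(f)
            continue
        blocks.append(B)
        names.extend(bn)
    for c in spec.covariates:
        blocks.append(raw[c].to_numpy(dtype=float)[:, None])
        names.append(c)
    for a, b in spec.interactions:
        A, an = _term_basis(raw, a, spec)
        B, bn = _term_basis(raw, b, spec)
        for i, na in enumerate(an):
            for j, nb in enumerate(bn):
                blocks.append((A[:, i] * B[:, j])[:, None])
                names.append(f"{na}:{nb}")
    X = np.column_stack(blocks) if blocks else np.empty((n, 0))
    ids = (
        raw["individual_id"].astype(str).tolist()
        if "individual_id" in raw.columns
        else [str(i) for i in range(n)]
    )
    return DesignMatrix(X=X, column_names=names, individual_ids=ids, dropped=dropped)


def fit_and_adjust(
    raw: pd.DataFrame,
    design: DesignMatrix,
    traits: list[str],
) -> tuple[dict[str, FixedEffectsFit], pd.DataFrame]:
    """Least-squares fit per trait; residuals are the adjusted phenotypes.

    Uses the minimum-norm solution under rank deficiency (LAPACK gelsd);
    aliased columns are detected by pivoted QR and logged.
    """
    X = design.X
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p ({n} rows, {p} design columns)")

    # pivoted QR to name aliased columns under rank deficiency
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(n, p) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    aliased = [design.column_names[j] for j in piv[rank:]] if rank < p else []
    if aliased:
        logger.warning("rank-deficient design; aliased columns: %s", aliased)

    adjusted = pd.DataFrame({"individual_id": design.individual_ids})
    fits: dict[str, FixedEffectsFit] = {}
    for trait in traits:
        y = raw[trait].to_numpy(dtype=float)
        beta, _, _, _ = scipy.linalg.lstsq(X, y, lapack_driver="gelsd")
        resid = y - X @ beta
        dof = max(1, n - rank)
        fits[trait] = FixedEffectsFit(
            trait=trait,
            column_names=design.column_names,
            coefficients=beta,
            residual_variance=float(resid @ resid / dof),
            n_used=n,
            rank=rank,
            aliased_columns=aliased,
        )
        adjusted[trait] = resid
    return fits, adjusted


def legendre_covariates(days, degree: int, d_min: float = 5.0, d_max: float = 305.0) -> np.ndarray:
    """Legendre polynomial basis of days-in-milk rescaled to [-1, 1].

    Returns an (n, degree) array of P_1..P_degree evaluated at the
    rescaled days (the constant P_0 is left to the intercept).
    """
    t = 2.0 * (np.asarray(days, dtype=float) - d_min) / (d_max - d_min) - 1.0
    V = np.polynomial.legendre.legvander(t, degree)
    return V[:, 1:]
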