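"""Multiple regression on distance matrices (MRM) and variation partitioning.

MRM regresses the pair vector of a response matrix (here, community
similarity) on the pair vectors of one or more predictor matrices by
OLS; significance comes from permuting the site labels of the response
matrix (rows and columns together) and refitting.

Variation partitioning decomposes the R² of the full three-predictor
model over geographic distance (G), environmental distance (E) and
mean-elevation difference (A) into seven Venn fractions — three pure
effects, three pairwise joint effects and one three-way joint effect —
by inclusion–exclusion over the R² of the seven nested predictor
subsets. Joint fractions can be negative (suppression), a well-known
property of this decomposition; they are reported as computed, never
clipped. Raw (not adjusted) R² is used throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np

from .containers import PairwiseMatrix, pair_vector

logger = logging.getLogger(__name__)


@dataclass
class MRMFit:
    predictors: list[str]
    coefficients: dict[str, float]  # per-predictor slopes + "intercept"
    r2: float
    n_pairs: int
    p_perm: float | None = None
    n_perm: int = 0


@dataclass
class VarPartResult:
    """Seven Venn fractions of the full-model R² plus the residual.

    Fractions sum to ``total_explained`` = R² of the G+E+A model;
    ``residual`` = 1 − total_explained. ``subset_r2`` retains the R² of
    each of the seven predictor subsets (keys like "G", "GE", "GEA") so
    the partition can be audited.
    """

    pure_g: float
    pure_e: float
    pure_a: float
    joint_ge: float
    joint_ga: float
    joint_ea: float
    joint_gea: float
    residual: float
    total_explained: float
    subset_r2: dict[str, float] = field(default_factory=dict)

    def fractions(self) -> dict[str, float]:
        return {
            "pure_g": self.pure_g,
            "pure_e": self.pure_e,
            "pure_a": self.pure_a,
            "joint_ge": self.joint_ge,
            "joint_ga": self.joint_ga,
            "joint_ea": self.joint_ea,
            "joint_gea": self.joint_gea,
        }


def _design(preds: list[np.ndarray]) -> np.ndarray:
    return np.column_stack([np.ones(len(preds[0])), *preds])


def _r2_ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("response pair vector is constant; R² undefined")
    return beta, 1.0 - float(np.sum(resid**2)) / ss_tot


def _check_collinear(X: np.ndarray, labels: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"collinear predictors: design with {labels} has rank {rank} < {X.shape[1]}"
        )


def mrm(
    sim: PairwiseMatrix,
    predictors: list[PairwiseMatrix],
    labels: list[str] | None = None,
    n_perm: int = 0,
    seed: int | None = None,
) -> MRMFit:
    """OLS of the response pair vector on predictor pair vectors.

    With ``n_perm > 0``, attaches a one-sided permutation p-value on R²
    (response matrix relabeled, model refitted each time, add-one
    correction; exhaustive enumeration when n! <= n_perm).
    """
    if not predictors:
        raise ValueError("MRM needs at least one predictor matrix")
    for m in predictors:
        if m.site_ids != sim.site_ids:
            raise ValueError("all matrices must share the same site set and order")
    labels = labels or [f"X{i + 1}" for i in range(len(predictors))]
    y, _ = pair_vector(sim)
    cols = [pair_vector(p)[0] for p in predictors]
    X = _design(cols)
    _check_collinear(X, labels)
    beta, r2 = _r2_ols(y, X)
    coefs = {"intercept": float(beta[0])}
    coefs.update({lab: float(b) for lab, b in zip(labels, beta[1:])})
    fit = MRMFit(predictors=list(labels), coefficients=coefs, r2=r2, n_pairs=len(y))

    if n_perm > 0:
        n = sim.n_sites
        iu, ju = np.triu_indices(n, k=1)

        def perm_r2(order: np.ndarray) -> float:
            yp = sim.values[np.ix_(order, order)][iu, ju]
            return _r2_ols(yp, X)[1]

        if math.factorial(n) <= n_perm:
            logger.warning("exhaustive enumeration of %d permutations", math.factorial(n))
            r2s = [perm_r2(np.array(p)) for p in permutations(range(n))]
            fit.p_perm = float(np.mean([v >= r2 - 1e-12 for v in r2s]))
            fit.n_perm = len(r2s)
        else:
            rng = np.random.default_rng(seed)
            hits = sum(perm_r2(rng.permutation(n)) >= r2 - 1e-12 for _ in range(n_perm))
            fit.p_perm = (1 + hits) / (n_perm + 1)
            fit.n_perm = n_perm
    return fit


def partition3(
    sim: PairwiseMatrix,
    G: PairwiseMatrix,
    E: PairwiseMatrix,
    A: PairwiseMatrix,
) -> VarPartResult:
    """Seven-fraction variation partitioning over three predictor matrices.

    Fits the seven MRMs (G; E; A; GE; GA; EA; GEA) and solves the Venn
    fractions by inclusion–exclusion:

    pure_G = R²(GEA) − R²(EA), and cyclically for E and A;
    joint_GEA = ΣR²(singles) − ΣR²(pairs) + R²(GEA);
    joint_GE = R²(G) + R²(E) − R²(GE) − joint_GEA, and cyclically.
    """
    subsets = {
        "G": [G], "E": [E], "A": [A],
        "GE": [G, E], "GA": [G, A], "EA": [E, A],
        "GEA": [G, E, A],
    }
    r2 = {k: mrm(sim, v, labels=list(k)).r2 for k, v in subsets.items()}
    pure_g = r2["GEA"] - r2["EA"]
    pure_e = r2["GEA"] - r2["GA"]
    pure_a = r2["GEA"] - r2["GE"]
    joint_gea = (
        r2["G"] + r2["E"] + r2["A"] - r2["GE"] - r2["GA"] - r2["EA"] + r2["GEA"]
    )
    joint_ge = r2["G"] + r2["E"] - r2["GE"] - joint_gea
    joint_ga = r2["G"] + r2["A"] - r2["GA"] - joint_gea
    joint_ea = r2["E"] + r2["A"] - r2["EA"] - joint_gea
    return VarPartResult(
        pure_g=pure_g,
        pure_e=pure_e,
        pure_a=pure_a,
        joint_ge=joint_ge,
        joint_ga=joint_ga,
        joint_ea=joint_ea,
        joint_gea=joint_gea,
        residual=1.0 - r2["GEA"],
        total_explained=r2["GEA"],
        subset_r2=r2,
    )


def incremental_r2(
    sim: PairwiseMatrix,
    base: list[PairwiseMatrix],
    extra: PairwiseMatrix,
) -> float:
    """ΔR² gained by adding ``extra`` to the ``base`` predictor set.

    Nested OLS guarantees ΔR² >= 0 (up to numerical round-off); used to
    quantify how much additional turnover the heterogeneity (elevation
    range) or area difference explains beyond the core predictors. When
    ``extra`` duplicates a base predictor exactly, the augmented design
    is rank-deficient and ΔR² is 0 by construction.
    """
    r2_base = mrm(sim, base).r2
    y, _ = pair_vector(sim)
    cols = [pair_vector(p)[0] for p in base] + [pair_vector(extra)[0]]
    X = _design(cols)
    # rank-deficient designs (extra in span of base) are fine here: lstsq
    # minimum-norm solution leaves the fitted subspace, hence R², unchanged
    _, r2_full = _r2_ols(y, X)
    return max(0.0, r2_full - r2_base)
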