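"""Simple and partial Mantel tests.

The Mantel statistic r is the Pearson correlation between the unrolled
pair vectors of two symmetric matrices. Because pairs sharing a site are
not independent, significance is assessed by permuting the site labels
of one matrix — rows and columns simultaneously — and recomputing r.

The partial Mantel test correlates the residuals of A and B after OLS
regression of each pair vector on the pair vectors of one or more
control matrices. Its null distribution is generated by permuting the
residuals of A (folded back into a symmetric matrix so the permutation
stays row/column-coherent) — the residual-permutation scheme of the
ecodist lineage.

p-values use the add-one correction p = (1 + #extreme) / (n_perm + 1)
and are two-sided by default; exhaustive enumeration replaces Monte
Carlo sampling when n! <= n_perm (the enumeration includes the identity,
giving an exact p with minimum 1/n!).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np

from .containers import PairwiseMatrix, pair_vector

logger = logging.getLogger(__name__)

TAILS = ("two-sided", "greater", "less")


@dataclass
class MantelResult:
    r: float
    p_perm: float
    n_perm: int
    kind: str  # "simple" | "partial"
    tail: str = "two-sided"
    controlled: list[str] = field(default_factory=list)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt(np.sum(xc**2)))
    sy = float(np.sqrt(np.sum(yc**2)))
    if sx == 0 or sy == 0:
        raise ValueError("Mantel r undefined: a pair vector is constant")
    return float(np.dot(xc, yc) / (sx * sy))


def _count_extreme(r_perm: float, r_obs: float, tail: str) -> bool:
    eps = 1e-12
    if tail == "two-sided":
        return abs(r_perm) >= abs(r_obs) - eps
    if tail == "greater":
        return r_perm >= r_obs - eps
    return r_perm <= r_obs + eps


def _to_symmetric(vec: np.ndarray, n: int) -> np.ndarray:
    m = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    m[iu, ju] = vec
    m[ju, iu] = vec
    return m


def _permuted_vec(mat: np.ndarray, order: np.ndarray) -> np.ndarray:
    iu, ju = np.triu_indices(mat.shape[0], k=1)
    p = mat[np.ix_(order, order)]
    return p[iu, ju]


def _perm_p(
    mat: np.ndarray,
    stat,
    r_obs: float,
    n: int,
    n_perm: int,
    seed,
    tail: str,
) -> tuple[float, int]:
    """Generic matrix-permutation p; ``stat`` maps a pair vector to r."""
    if math.factorial(n) <= n_perm:
        logger.warning(
            "only %d distinct permutations for n=%d sites; exhaustive enumeration",
            math.factorial(n), n,
        )
        hits = total = 0
        for p in permutations(range(n)):
            total += 1
            if _count_extreme(stat(_permuted_vec(mat, np.array(p))), r_obs, tail):
                hits += 1
        return hits / total, total
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        order = rng.permutation(n)
        if _count_extreme(stat(_permuted_vec(mat, order)), r_obs, tail):
            hits += 1
    return (1 + hits) / (n_perm + 1), n_perm


def mantel_simple(
    A: PairwiseMatrix,
    B: PairwiseMatrix,
    n_perm: int = 1000,
    seed: int | None = None,
    tail: str = "two-sided",
) -> MantelResult:
    """Simple Mantel test between two pairwise matrices."""
    if tail not in TAILS:
        raise ValueError(f"tail must be one of {TAILS}")
    if A.site_ids != B.site_ids:
        raise ValueError("matrices must share the same site set and order")
    a, _ = pair_vector(A)
    b, _ = pair_vector(B)
    r_obs = _pearson(a, b)
    p, used = _perm_p(
        A.values, lambda v: _pearson(v, b), r_obs, A.n_sites, n_perm, seed, tail
    )
    return MantelResult(r=r_obs, p_perm=p, n_perm=used, kind="simple", tail=tail)


def _residualize(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """OLS residuals of y on X (intercept included)."""
    design = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def mantel_partial(
    A: PairwiseMatrix,
    B: PairwiseMatrix,
    controls: PairwiseMatrix | list[PairwiseMatrix],
    n_perm: int = 1000,
    seed: int | None = None,
    tail: str = "two-sided",
) -> MantelResult:
    """Partial Mantel test of A vs B controlling for one or more matrices.

    r is the correlation of the OLS residuals of A's and B's pair
    vectors on the controls' pair vectors; significance by
    row/column-coherent permutation of A's residual matrix.
    """
    if tail not in TAILS:
        raise ValueError(f"tail must be one of {TAILS}")
    if isinstance(controls, PairwiseMatrix):
        controls = [controls]
    if not controls:
        raise ValueError("partial Mantel requires at least one control matrix")
    for m in [B, *controls]:
        if m.site_ids != A.site_ids:
            raise ValueError("all matrices must share the same site set and order")
    a, _ = pair_vector(A)
    b, _ = pair_vector(B)
    C = np.column_stack([pair_vector(c)[0] for c in controls])

    res_b = _residualize(b, C)
    if float(np.sum(res_b**2)) < 1e-12 * max(1.0, float(np.sum(b**2))):
        raise ValueError("B is collinear with the control matrices; partial r undefined")
    res_a = _residualize(a, C)
    r_obs = _pearson(res_a, res_b)

    res_a_mat = _to_symmetric(res_a, A.n_sites)
    p, used = _perm_p(
        res_a_mat, lambda v: _pearson(v, res_b), r_obs, A.n_sites, n_perm, seed, tail
    )
    return MantelResult(
        r=r_obs,
        p_perm=p,
        n_perm=used,
        kind="partial",
        tail=tail,
        controlled=[m.kind for m in controls],
    )
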