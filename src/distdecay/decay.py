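"""Distance-decay regression and the halving-distance statistic.

Community similarity y is regressed on geographic distance x (km) under
three classical forms, each fitted by ordinary least squares on its own
linearizing transform:

* linear        y = a x + b         (OLS of y on x)
* logarithmic   y = a ln x + b      (OLS of y on ln x; zero distances excluded)
* exponential   y = b e^(a x)       (OLS of ln y on x; zero similarities excluded)

R² is reported on the transformed scale of the fit. The halving distance
is the x at which the fitted curve predicts half the initial similarity
S0 (by default the maximum observed pairwise similarity); it is the
closed-form solution of model(x) = S0/2 and serves as a comparable
"speed of turnover" statistic across regions.

Because the n(n-1)/2 pairs sharing sites are not independent, parametric
p-values are invalid; significance comes from a matrix permutation test:
site labels of the similarity matrix are permuted (rows and columns
together), the model refitted, and p = (1 + #{R²_perm >= R²_obs}) /
(n_perm + 1), one-sided on R².
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from itertools import permutations

import numpy as np

from .containers import PairwiseMatrix, pair_vector

logger = logging.getLogger(__name__)

FORMS = ("linear", "logarithmic", "exponential")


@dataclass
class DecayFit:
    """A fitted decay model.

    ``a`` is the slope-like coefficient (per km for linear/exponential,
    per ln km for logarithmic); ``b`` the intercept-like coefficient (the
    exponential form's multiplier). ``r2`` is on the transformed scale of
    the fit. ``n_excluded`` counts pairs unusable under the form's
    transform (zero distance or zero similarity).
    """

    form: str
    a: float
    b: float
    r2: float
    n_pairs: int
    n_excluded: int = 0
    s0: float | None = None
    halving_distance: float | None = None
    p_perm: float | None = None

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        if self.form == "linear":
            return self.a * x + self.b
        if self.form == "logarithmic":
            return self.a * np.log(x) + self.b
        return self.b * np.exp(self.a * x)


def _transform(x: np.ndarray, y: np.ndarray, form: str) -> tuple[np.ndarray, np.ndarray, int]:
    """Linearizing transform; returns (x', y', n_excluded)."""
    if form == "linear":
        return x, y, 0
    if form == "logarithmic":
        ok = x > 0
        return np.log(x[ok]), y[ok], int((~ok).sum())
    if form == "exponential":
        ok = y > 0
        return x[ok], np.log(y[ok]), int((~ok).sum())
    raise ValueError(f"form must be one of {FORMS}, got {form!r}")


def _ols(xt: np.ndarray, yt: np.ndarray) -> tuple[float, float, float]:
    """Simple OLS slope, intercept and R² (on the given scale)."""
    if xt.size < 3:
        raise ValueError(f"need at least 3 usable pairs, got {xt.size}")
    xm, ym = xt.mean(), yt.mean()
    sxx = float(np.sum((xt - xm) ** 2))
    if sxx == 0:
        raise ValueError("zero variance in (transformed) distances")
    sxy = float(np.sum((xt - xm) * (yt - ym)))
    syy = float(np.sum((yt - ym) ** 2))
    slope = sxy / sxx
    r2 = 0.0 if syy == 0 else (sxy * sxy) / (sxx * syy)
    return slope, ym - slope * xm, r2


def fit_decay(
    sim: PairwiseMatrix,
    dist: PairwiseMatrix,
    form: str,
    s0: float | str = "auto",
) -> DecayFit:
    """Fit one decay form; attaches S0 and the halving distance.

    ``s0`` is ``"auto"`` (maximum observed pairwise similarity) or a
    fixed value in (0, 1]. ``p_perm`` is left unset; see
    :func:`permutation_significance`. When the fitted slope is
    non-negative (no decay) the halving distance is left as None.
    """
    if sim.site_ids != dist.site_ids:
        raise ValueError("similarity and distance matrices must share site order")
    y, _ = pair_vector(sim)
    x, _ = pair_vector(dist)
    xt, yt, n_exc = _transform(x, y, form)
    if n_exc:
        logger.info("%s fit: excluded %d unusable pairs", form, n_exc)
    slope, intercept, r2 = _ols(xt, yt)
    if form == "exponential":
        intercept = math.exp(intercept)
    fit = DecayFit(
        form=form, a=slope, b=intercept, r2=r2, n_pairs=x.size, n_excluded=n_exc
    )
    s0_value = initial_similarity(sim, "fixed", s0) if s0 != "auto" else initial_similarity(sim)
    fit.s0 = s0_value
    if fit.a < 0:
        try:
            fit.halving_distance = halving_distance(fit, s0_value)
        except ValueError as exc:
            logger.warning("halving distance undefined: %s", exc)
    return fit


def initial_similarity(
    sim: PairwiseMatrix, method: str = "max_observed", value: float | None = None
) -> float:
    """Initial similarity S0 for the halving computation.

    ``max_observed`` (default) takes the maximum off-diagonal similarity
    of the region — 1 wherever an identical site pair exists; ``fixed``
    returns a user-supplied value in (0, 1].
    """
    if method == "max_observed":
        v, _ = pair_vector(sim)
        return float(v.max())
    if method == "fixed":
        value = float(value)  # type: ignore[arg-type]
        if not 0 < value <= 1:
            raise ValueError(f"fixed initial similarity must be in (0, 1], got {value}")
        return value
    raise ValueError(f"method must be 'max_observed' or 'fixed', got {method!r}")


def halving_distance(fit: DecayFit, s0: float) -> float:
    """Distance (km) at which the fitted model predicts S0/2.

    Closed forms: linear (b − S0/2)/(−a); logarithmic exp((S0/2 − b)/a);
    exponential ln(2b/S0)/(−a). Requires a decaying fit (a < 0) that
    actually reaches S0/2 at a positive distance.
    """
    if fit.a >= 0:
        raise ValueError("no decay: slope coefficient is non-negative")
    if not 0 < s0 <= 1:
        raise ValueError(f"initial similarity must be in (0, 1], got {s0}")
    half = s0 / 2.0
    if fit.form == "linear":
        if fit.b <= half:
            raise ValueError("half-similarity not reached at positive distance")
        return (fit.b - half) / (-fit.a)
    if fit.form == "logarithmic":
        return math.exp((half - fit.b) / fit.a)
    if fit.form == "exponential":
        if 2 * fit.b / s0 <= 1:
            raise ValueError("half-similarity not reached at positive distance")
        return math.log(2 * fit.b / s0) / (-fit.a)
    raise ValueError(f"unknown form {fit.form!r}")


def _perm_r2(y_mat: np.ndarray, x: np.ndarray, form: str, order: np.ndarray) -> float:
    iu, ju = np.triu_indices(y_mat.shape[0], k=1)
    perm = y_mat[np.ix_(order, order)]
    yt = perm[iu, ju]
    xt, yt, _ = _transform(x, yt, form)
    try:
        return _ols(xt, yt)[2]
    except ValueError:
        return 0.0


def permutation_significance(
    sim: PairwiseMatrix,
    dist: PairwiseMatrix,
    form: str,
    n_perm: int = 1000,
    seed: int | None = None,
) -> float:
    """One-sided matrix permutation p-value for a decay fit.

    Site labels of the similarity matrix are permuted — rows and columns
    simultaneously, preserving the matrix's symmetric pair structure —
    and the model refitted each time. With the add-one correction,
    p = (1 + #{R²_perm >= R²_obs}) / (n_perm + 1), so the minimum
    attainable p is 1/(n_perm + 1).

    When n! <= n_perm, all n! relabelings are enumerated instead and the
    p-value is exact: #{R²_perm >= R²_obs} / n! (the identity counts
    itself, so p >= 1/n!).
    """
    if sim.site_ids != dist.site_ids:
        raise ValueError("similarity and distance matrices must share site order")
    n = sim.n_sites
    observed = fit_decay(sim, dist, form).r2
    x, _ = pair_vector(dist)
    y_mat = sim.values

    if math.factorial(n) <= n_perm:
        logger.warning(
            "only %d distinct permutations for n=%d sites; using exhaustive enumeration",
            math.factorial(n), n,
        )
        r2s = np.array(
            [_perm_r2(y_mat, x, form, np.array(p)) for p in permutations(range(n))]
        )
        return float(np.sum(r2s >= observed - 1e-12) / len(r2s))

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        order = rng.permutation(n)
        if _perm_r2(y_mat, x, form, order) >= observed - 1e-12:
            count += 1
    return (1 + count) / (n_perm + 1)


def attach_significance(
    fit: DecayFit,
    sim: PairwiseMatrix,
    dist: PairwiseMatrix,
    n_perm: int = 1000,
    seed: int | None = None,
) -> DecayFit:
    """Return a copy of ``fit`` with the permutation p-value filled in."""
    p = permutation_significance(sim, dist, fit.form, n_perm=n_perm, seed=seed)
    return replace(fit, p_perm=p)
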