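"""Phylogenetic comparative statistics.

Implements the allometry toolkit used to test Rensch's rule:

* Felsenstein's phylogenetic independent contrasts (PIC),
* type-II reduced major axis (RMA) regression, ordinary and through the
  origin (the form appropriate for contrasts), with bootstrap or analytic
  confidence intervals and an isometry check (is 1 inside the CI),
* contrast correlations between two traits on a common tree,
* Blomberg's K phylogenetic-signal statistic with a permutation test.

Contrasts are standardized (divided by the square root of their expected
variance) and, for through-origin regressions, positivized on the x trait
with the paired y contrast's sign flipped accordingly — the standard PDAP
convention, which makes the through-origin slope well defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .trees import Phylogeny

__all__ = [
    "ContrastSet",
    "RMAResult",
    "KResult",
    "pic",
    "rma",
    "contrast_correlation",
    "blomberg_k",
]

logger = logging.getLogger(__name__)

#: relative additive constant applied to zero-length branches inside PIC
#: variance terms only (polytomy-resolution inserts); scaled by tree depth.
ZERO_BRANCH_EPS = 1e-8


@dataclass
class ContrastSet:
    """Standardized independent contrasts for one trait.

    One contrast per internal node of a binary tree (n-1 for n tips),
    in postorder.  ``variances`` are the expected variances (sum of
    corrected branch lengths) used for standardization.
    """

    trait: str
    node_ids: list[str]
    contrasts: np.ndarray
    variances: np.ndarray

    @property
    def n(self) -> int:
        return len(self.contrasts)


@dataclass
class RMAResult:
    """Reduced-major-axis fit.  Slope is dimensionless for log-log data."""

    slope: float
    ci_low: float
    ci_high: float
    r2: float
    p: float
    n: int
    through_origin: bool
    intercept: float | None = None

    def excludes_isometry(self) -> bool:
        """True when slope 1 falls outside the 95% CI."""
        return not (self.ci_low <= 1.0 <= self.ci_high)


@dataclass
class KResult:
    """Blomberg's K with permutation p-value (K=1 under Brownian motion)."""

    k: float
    p: float | None
    n_perm: int
    seed: int | None


def pic(tree: Phylogeny, tip_values: dict[str, float], trait: str = "trait") -> ContrastSet:
    """Felsenstein's independent contrasts on a binary tree.

    Zero-length branches (from polytomy resolution) receive a small
    additive constant (``ZERO_BRANCH_EPS`` x tree depth) in the variance
    terms only; each application is logged.
    """
    if not tree.is_binary():
        raise ValueError("tree has polytomies; run resolve_polytomies first")
    missing = sorted(set(tree.tip_labels) - set(tip_values))
    if missing:
        raise ValueError(f"missing tip values for species: {missing}")
    eps = ZERO_BRANCH_EPS * max(tree.max_depth(), 1e-300)

    val: dict[str, float] = {}
    extra: dict[str, float] = {}  # corrected branch length above each node
    node_ids, cons, varis = [], [], []
    n_zero = 0
    for node in tree.postorder():
        nid = node._node_id
        if node.is_leaf():
            val[nid] = float(tip_values[nid])
            sub = 0.0
        else:
            c1, c2 = node.child_nodes()
            v1, v2 = extra[c1._node_id], extra[c2._node_id]
            x1, x2 = val[c1._node_id], val[c2._node_id]
            denom = v1 + v2
            if denom <= 0:
                raise ValueError(f"contrast variance is zero at node {nid}")
            node_ids.append(nid)
            cons.append((x1 - x2) / np.sqrt(denom))
            varis.append(denom)
            val[nid] = (x1 / v1 + x2 / v2) / (1.0 / v1 + 1.0 / v2)
            sub = v1 * v2 / denom
        if node.parent_node is not None:
            b = float(node.edge.length)
            if b == 0.0:
                b = eps
                n_zero += 1
            extra[nid] = b + sub
    if n_zero:
        logger.info(
            "pic(%s): added %.3g to %d zero-length branch variance terms",
            trait, eps, n_zero,
        )
    return ContrastSet(
        trait=trait,
        node_ids=node_ids,
        contrasts=np.asarray(cons, dtype=float),
        variances=np.asarray(varis, dtype=float),
    )


def _rma_slope(x: np.ndarray, y: np.ndarray, through_origin: bool, axis=None):
    if through_origin:
        sxy = np.sum(x * y, axis=axis)
        sxx = np.sum(x * x, axis=axis)
        syy = np.sum(y * y, axis=axis)
        return np.sign(sxy) * np.sqrt(syy / sxx)
    sx = np.std(x, axis=axis, ddof=1)
    sy = np.std(y, axis=axis, ddof=1)
    if axis is None:
        cov = np.cov(x, y)[0, 1]
    else:
        cov = np.mean(
            (x - x.mean(axis=axis, keepdims=True)) * (y - y.mean(axis=axis, keepdims=True)),
            axis=axis,
        )
    return np.where(cov < 0, -1.0, 1.0) * sy / sx if axis is not None else np.sign(cov or 1.0) * sy / sx


def rma(
    x,
    y,
    through_origin: bool = False,
    ci_method: str = "bootstrap",
    seed: int = 0,
    n_boot: int = 1999,
    alpha: float = 0.05,
) -> RMAResult:
    """Reduced major axis (type II) regression of y on x.

    Standard RMA: slope = sign(cov) * SD(y)/SD(x).  Through-origin RMA
    (for independent contrasts): slope = sign(sum xy) * sqrt(sum y^2 /
    sum x^2).  R^2 is the squared (through-origin, if requested) Pearson
    correlation; p tests that correlation against zero.  The CI is a
    seeded percentile bootstrap over pairs, or the analytic RMA interval.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    if through_origin:
        if np.sum(x * x) == 0 or np.sum(y * y) == 0:
            raise ValueError("zero sum of squares in x or y")
        r = np.sum(x * y) / np.sqrt(np.sum(x * x) * np.sum(y * y))
        df = n - 1
    else:
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError("zero variance in x or y")
        r = float(np.corrcoef(x, y)[0, 1])
        df = n - 2
    slope = float(_rma_slope(x, y, through_origin))
    r2 = float(r * r)
    if r2 >= 1.0:
        p = 0.0
    else:
        t = abs(r) * np.sqrt(df / (1.0 - r2))
        p = float(2.0 * stats.t.sf(t, df))

    if r2 >= 1.0:
        lo = hi = slope
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        bs = _rma_slope(x[idx], y[idx], through_origin, axis=1)
        bs = bs[np.isfinite(bs)]
        lo, hi = np.quantile(bs, [alpha / 2, 1 - alpha / 2])
    elif ci_method == "analytic":
        fcrit = stats.f.isf(alpha, 1, df)
        B = fcrit * (1.0 - r2) / df
        lo = slope * (np.sqrt(B + 1.0) - np.sqrt(B))
        hi = slope * (np.sqrt(B + 1.0) + np.sqrt(B))
        if slope < 0:
            lo, hi = hi, lo
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    intercept = None if through_origin else float(np.mean(y) - slope * np.mean(x))
    return RMAResult(
        slope=slope,
        ci_low=float(lo),
        ci_high=float(hi),
        r2=r2,
        p=p,
        n=n,
        through_origin=through_origin,
        intercept=intercept,
    )


def positivize(cx: np.ndarray, cy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip each contrast pair so the x member is non-negative."""
    s = np.where(cx < 0, -1.0, 1.0)
    return cx * s, cy * s


def contrast_correlation(
    tree: Phylogeny,
    trait_x: dict[str, float],
    trait_y: dict[str, float],
    seed: int = 0,
    n_boot: int = 1999,
) -> RMAResult:
    """Through-origin RMA between the independent contrasts of two traits."""
    sx = set(trait_x)
    sy = set(trait_y)
    if sx != sy:
        raise ValueError(
            f"tip-set mismatch: only-x={sorted(sx - sy)}, only-y={sorted(sy - sx)}"
        )
    px = pic(tree, trait_x, "x")
    py = pic(tree, trait_y, "y")
    cx, cy = positivize(px.contrasts, py.contrasts)
    return rma(cx, cy, through_origin=True, seed=seed, n_boot=n_boot)


def blomberg_k(
    tree: Phylogeny,
    tip_values: dict[str, float],
    n_perm: int = 999,
    seed: int = 0,
) -> KResult:
    """Blomberg's K with a permutation test for phylogenetic signal.

    K is the ratio of the observed MSE0/MSE (tip deviations from the
    phylogenetic mean over the GLS mean-squared error under the tree
    covariance) to its expectation under Brownian motion,
    (tr(V) - n / sum(V^-1)) / (n - 1).  K = 1 matches BM; larger K means
    more signal.  The p-value is the proportion of tip permutations whose
    GLS error indicates at least as much signal as observed (one-sided).
    Pass ``n_perm=0`` to skip the test (p is then None).
    """
    tips_order, V = tree.vcv()
    n = len(tips_order)
    if n < 4:
        raise ValueError("need at least 4 tips")
    missing = sorted(set(tips_order) - set(tip_values))
    if missing:
        raise ValueError(f"missing tip values for species: {missing}")
    x = np.array([float(tip_values[t]) for t in tips_order])
    if np.ptp(x) == 0:
        raise ValueError("constant tip data: K undefined")

    Vinv = np.linalg.inv(V)
    a = Vinv @ np.ones(n)
    denom = a.sum()
    mu = a @ x / denom
    # MSE0 from deviations around the phylogenetic (GLS) mean; MSE is the
    # GLS quadratic form.  Ratio observed/(BM expectation) defines K.
    ss0 = ((x - mu) ** 2).sum()
    q = x @ Vinv @ x - (a @ x) ** 2 / denom
    expected = (np.trace(V) - n / denom) / (n - 1)
    k = float((ss0 / q) / expected)

    p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        X = np.empty((n_perm, n))
        for i in range(n_perm):
            X[i] = rng.permutation(x)
        mus = X @ a / denom
        ss0s = np.einsum("ij,ij->i", X, X) - 2 * mus * X.sum(axis=1) + n * mus**2
        qs = np.einsum("ij,ij->i", X @ Vinv, X) - (X @ a) ** 2 / denom
        count = int(np.sum(ss0s / qs >= ss0 / q))
        p = (1.0 + count) / (n_perm + 1.0)
    return KResult(k=k, p=p, n_perm=n_perm, seed=seed)
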