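"""Single-CNVR mixed-model association under the animal model.

Model per trait and region:

    y = X b + Z u + e,   u ~ N(0, A sigma2_u),   e ~ N(0, I sigma2_e)

where y is the vector of pre-adjusted phenotypes, X = [1, g] with g the
CNVR genotype code in {-1, 0, +1}, u the polygenic effect with A the
pedigree numerator relationship matrix, and Z = I (one record per animal).

Variance components are estimated once per trait by EM-REML on the null
model (X = intercept only) and held fixed across all region tests.  Each
region's effect is then the GLS estimate

    b = (X' V^-1 X)^-1 X' V^-1 y,    V = A sigma2_u + I sigma2_e,

with SE from the inverse weighted cross-product, t = beta/SE and a
two-sided p-value on a t distribution with n - 2 degrees of freedom.
Family-wise error is controlled by Bonferroni: a region is significant
iff p < alpha / m with m the total number of CNVRs tested.

All per-region work is performed in the eigenbasis of A, which is
decomposed once; V is diagonal there, so one REML iteration and one GLS
fit cost O(n).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AEigen",
    "VarianceComponents",
    "AssociationResult",
    "MonomorphicRegionError",
    "estimate_variance_components",
    "test_cnvr",
    "bonferroni",
    "run_association",
]


class MonomorphicRegionError(ValueError):
    """Raised when the genotype code vector is constant."""


class AEigen:
    """Cached eigendecomposition of a (PSD) relationship matrix."""

    def __init__(self, A: np.ndarray, tol: float = 1e-8):
        A = np.asarray(A, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("A must be square")
        if not np.allclose(A, A.T, atol=1e-10):
            raise ValueError("A must be symmetric")
        d, U = np.linalg.eigh(A)
        if d.min() < -tol * max(1.0, d.max()):
            raise ValueError(f"A is not positive semidefinite (min eigenvalue {d.min():g})")
        self.d = np.clip(d, 0.0, None)
        self.U = U
        self.n = A.shape[0]

    def rotate(self, x: np.ndarray) -> np.ndarray:
        return self.U.T @ x


def _as_eigen(A) -> AEigen:
    return A if isinstance(A, AEigen) else AEigen(A)


@dataclass
class VarianceComponents:
    sigma2_u: float
    sigma2_e: float
    converged: bool
    n_iter: int
    loglik_trace: list[float] = field(default_factory=list)

    @property
    def heritability(self) -> float:
        tot = self.sigma2_u + self.sigma2_e
        return self.sigma2_u / tot if tot > 0 else float("nan")


def _reml_pieces(yt, Xt, d, su, se):
    """P y, REML log-likelihood and traces in the eigenbasis of A."""
    v = su * d + se
    w = 1.0 / v
    Xw = Xt * w[:, None]
    C = Xt.T @ Xw                      # X' V^-1 X
    beta = np.linalg.solve(C, Xw.T @ yt)
    r = yt - Xt @ beta
    Py = w * r
    yPy = float(r @ Py)
    sign, logdetC = np.linalg.slogdet(C)
    ll = -0.5 * (np.log(v).sum() + logdetC + yPy)
    Cinv = np.linalg.inv(C)
    trP = w.sum() - float(np.einsum("ij,ji->", Cinv, Xt.T @ (Xt * (w**2)[:, None])))
    trPA = float((w * d).sum()) - float(
        np.einsum("ij,ji->", Cinv, Xt.T @ (Xt * (w**2 * d)[:, None]))
    )
    return Py, ll, trP, trPA


def estimate_variance_components(
    y: np.ndarray,
    A,
    *,
    tol: float = 1e-8,
    max_iter: int = 500,
    init: tuple[float, float] | None = None,
) -> VarianceComponents:
    """EM-REML for (sigma2_u, sigma2_e) under y = 1*mu + u + e.

    The EM updates keep both components non-negative and the restricted
    log-likelihood non-decreasing.  Non-convergence within ``max_iter``
    is flagged on the result, not raised.
    """
    y = np.asarray(y, dtype=float).ravel()
    eig = _as_eigen(A)
    n = eig.n
    if y.shape[0] != n:
        raise ValueError("y length does not match A")
    if n < 10:
        raise ValueError("need at least 10 records for variance component estimation")

    yt = eig.rotate(y)
    Xt = eig.rotate(np.ones((n, 1)))
    d = eig.d

    var_y = float(np.var(y, ddof=1))
    su, se = init if init is not None else (0.5 * var_y, 0.5 * var_y)
    su = max(su, 1e-8 * max(var_y, 1.0))
    se = max(se, 1e-8 * max(var_y, 1.0))

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Py, ll, trP, trPA = _reml_pieces(yt, Xt, d, su, se)
        trace.append(ll)
        yPAPy = float((d * Py) @ Py)
        yPPy = float(Py @ Py)
        su_new = su + (su * su / n) * (yPAPy - trPA)
        se_new = se + (se * se / n) * (yPPy - trP)
        su_new = max(su_new, 0.0)
        se_new = max(se_new, 1e-12 * max(var_y, 1.0))
        rel = max(
            abs(su_new - su) / max(abs(su), 1e-12),
            abs(se_new - se) / max(abs(se), 1e-12),
        )
        su, se = su_new, se_new
        if rel < tol:
            converged = True
            break
    return VarianceComponents(
        sigma2_u=su, sigma2_e=se, converged=converged, n_iter=it, loglik_trace=trace
    )


@dataclass
class AssociationResult:
    region_id: str
    trait: str
    n: int
    beta: float
    se: float
    t: float
    p: float
    significant: bool | None = None


def test_cnvr(
    y: np.ndarray,
    g: np.ndarray,
    A,
    vc: VarianceComponents,
    *,
    region_id: str = "",
    trait: str = "",
) -> AssociationResult:
    """GLS test of one CNVR code vector against one adjusted trait.

    ``A`` may be a dense matrix or an :class:`AEigen` (reused across
    regions).  Raises :class:`MonomorphicRegionError` for constant g.
    """
    y = np.asarray(y, dtype=float).ravel()
    g = np.asarray(g, dtype=float).ravel()
    if y.shape != g.shape:
        raise ValueError("y and g lengths differ")
    if np.ptp(g) == 0:
        raise MonomorphicRegionError(f"region {region_id or '<g>'} is monomorphic")
    eig = _as_eigen(A)
    n = eig.n
    if y.shape[0] != n:
        raise ValueError("y length does not match A")

    X = np.column_stack([np.ones(n), g])
    Xt = eig.rotate(X)
    yt = eig.rotate(y)
    v = vc.sigma2_u * eig.d + vc.sigma2_e
    if np.any(v <= 0):
        raise np.linalg.LinAlgError("singular V (non-positive variance)")
    w = 1.0 / v
    Xw = Xt * w[:, None]
    C = Xt.T @ Xw
    Cinv = np.linalg.inv(C)
    beta = Cinv @ (Xw.T @ yt)
    se = float(np.sqrt(Cinv[1, 1]))
    b = float(beta[1])
    t = b / se
    df = n - 2
    p = float(2.0 * stats.t.sf(abs(t), df))
    return AssociationResult(region_id=region_id, trait=trait, n=n, beta=b, se=se, t=t, p=p)


def bonferroni(
    results: Sequence[AssociationResult],
    alpha: float = 0.05,
    m: int | None = None,
) -> tuple[list[AssociationResult], float]:
    """Flag results significant iff p < alpha/m (strict inequality).

    ``m`` defaults to the number of distinct regions among the results.
    """
    if m is None:
        m = len({r.region_id for r in results})
    if m < 1:
        raise ValueError("m must be >= 1")
    threshold = alpha / m
    for r in results:
        r.significant = r.p < threshold
    return list(results), threshold


def run_association(
    genotypes: pd.DataFrame,
    phenotypes: pd.DataFrame,
    A: np.ndarray,
    ids: Sequence[str],
    *,
    alpha: float = 0.05,
    m: int | None = None,
    vc_by_trait: Mapping[str, VarianceComponents] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Test every (region, trait) pair; Bonferroni over all CNVRs.

    Parameters
    ----------
    genotypes : samples x regions code matrix ({-1,0,1}).
    phenotypes : samples x traits adjusted phenotypes (NaN = no record).
    A, ids : relationship matrix and its animal ordering.
    m : Bonferroni divisor; defaults to the total number of regions in
        ``genotypes`` (tested or not), matching an alpha / #CNVR rule.
    vc_by_trait : optional precomputed variance components per trait.

    Returns the result table (deterministic row order: traits in column
    order, regions in column order) and a metadata dict with variance
    components, skip log, threshold and m.
    """
    idx = pd.Index(ids)
    if m is None:
        m = genotypes.shape[1]
    results: list[AssociationResult] = []
    meta: dict = {"m": m, "alpha": alpha, "variance_components": {}, "skipped": []}
    for trait in phenotypes.columns:
        yser = phenotypes[trait].dropna()
        animals = [a for a in ids if a in yser.index and a in genotypes.index]
        if len(animals) < 10:
            meta["skipped"].append({"trait": trait, "reason": "fewer than 10 phenotyped animals"})
            continue
        pos = idx.get_indexer(animals)
        eig = AEigen(A[np.ix_(pos, pos)])
        y = yser.loc[animals].to_numpy(dtype=float)
        if vc_by_trait is not None and trait in vc_by_trait:
            vc = vc_by_trait[trait]
        else:
            vc = estimate_variance_components(y, eig)
        meta["variance_components"][trait] = {
            "sigma2_u": vc.sigma2_u,
            "sigma2_e": vc.sigma2_e,
            "converged": vc.converged,
            "n_iter": vc.n_iter,
            "n": len(animals),
        }
        G = genotypes.loc[animals]
        for region in genotypes.columns:
            g = G[region].to_numpy(dtype=float)
            try:
                results.append(
                    test_cnvr(y, g, eig, vc, region_id=region, trait=trait)
                )
            except MonomorphicRegionError:
                meta["skipped"].append(
                    {"trait": trait, "region": region, "reason": "monomorphic"}
                )
    results, threshold = bonferroni(results, alpha=alpha, m=m) if results else ([], alpha / m)
    meta["threshold"] = threshold
    table = pd.DataFrame(
        [
            {
                "region_id": r.region_id,
                "trait": r.trait,
                "n": r.n,
                "beta": r.beta,
                "se": r.se,
                "t": r.t,
                "p": r.p,
                "significant": r.significant,
            }
            for r in results
        ],
        columns=["region_id", "trait", "n", "beta", "se", "t", "p", "significant"],
    )
    return table, meta
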