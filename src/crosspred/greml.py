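"""GBLUP-type prediction: genomic relationships, REML, and BLUP.

Model: y = Xb + Zg + e with g ~ N(0, G sigma2_a), e ~ N(0, I sigma2_e),
b a fixed breed effect.  G is the centered cross-product genomic
relationship matrix, G = WW' / (2 sum p_j q_j), with W the allele-count
matrix column-centered by twice the (combined-population) allele
frequency.  Variance components are estimated by average-information
REML with expectation-maximization fallback steps; GEBVs of unphenotyped
candidates are obtained by propagating reference information through G.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg


@dataclass
class GRM:
    matrix: np.ndarray            # symmetric, over reference + candidates
    allele_frequencies: np.ndarray
    scale: float                  # 2 sum p_j q_j
    ids: np.ndarray | None = None


@dataclass
class GREMLResult:
    sigma2_a: float
    sigma2_e: float
    fixed_effects: np.ndarray
    converged: bool
    n_iterations: int
    loglik_trace: np.ndarray

    @property
    def h2(self) -> float:
        return self.sigma2_a / (self.sigma2_a + self.sigma2_e)


def compute_grm(allele_counts: np.ndarray, allele_frequencies=None,
                ids=None) -> GRM:
    """Centered cross-product G = WW' / (2 sum p q).

    Frequencies default to the combined data of all rows (reference and
    candidates together).  Monomorphic markers contribute zero to both
    the numerator and the denominator; an all-monomorphic panel is an
    error.
    """
    M = np.asarray(allele_counts, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2:
        raise ValueError("need at least 2 individuals")
    if allele_frequencies is None:
        p = M.mean(axis=0) / 2.0
    else:
        p = np.asarray(allele_frequencies, dtype=float)
        if len(p) != M.shape[1]:
            raise ValueError("one frequency per marker required")
    poly = (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise ValueError("all markers are monomorphic; G is undefined")
    W = M[:, poly] - 2.0 * p[poly]
    scale = float(np.sum(2.0 * p[poly] * (1.0 - p[poly])))
    G = (W @ W.T) / scale
    return GRM(matrix=G, allele_frequencies=p, scale=scale,
               ids=None if ids is None else np.asarray(ids, dtype=object))


def _reml_loglik(y, X, V):
    """Restricted log-likelihood (up to a constant) and P-projections."""
    n, p = X.shape
    cf = linalg.cho_factor(V, lower=True)
    Viy = linalg.cho_solve(cf, y)
    ViX = linalg.cho_solve(cf, X)
    XtViX = X.T @ ViX
    cx = linalg.cho_factor(XtViX, lower=True)
    b = linalg.cho_solve(cx, X.T @ Viy)
    Py = Viy - ViX @ b
    logdet_V = 2.0 * np.sum(np.log(np.diag(cf[0])))
    logdet_X = 2.0 * np.sum(np.log(np.diag(cx[0])))
    ll = -0.5 * (logdet_V + logdet_X + float(y @ Py))
    Vi = linalg.cho_solve(cf, np.eye(n))
    P = Vi - ViX @ linalg.cho_solve(cx, ViX.T)
    return ll, Py, P, b


def fit_greml(phenotypes: np.ndarray, X: np.ndarray, G: np.ndarray,
              tol: float = 1e-8, max_iter: int = 200) -> GREMLResult:
    """Average-information REML for (sigma2_a, sigma2_e) with EM fallback.

    An AI step is accepted only if it keeps both components above the
    variance floor (1e-8 x phenotypic variance) and does not decrease
    the restricted log-likelihood; otherwise the monotone EM update is
    taken.  Convergence: relative log-likelihood change below ``tol``.
    Non-convergence is flagged on the result, not raised.
    """
    y = np.asarray(phenotypes, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        raise ValueError("design matrix rows must match phenotypes")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design matrix is rank deficient")
    n = len(y)
    G = np.asarray(G, dtype=float) + 1e-6 * np.eye(n)
    vary = float(np.var(y))
    floor = 1e-8 * vary
    sa, se = 0.5 * vary, 0.5 * vary
    I = np.eye(n)

    def em_step(sa, se, Py, P):
        trPG = float(np.sum(P * G.T))
        trP = float(np.trace(P))
        GPy = G @ Py
        sa_new = sa + sa * sa * (float(Py @ GPy) - trPG) / n
        se_new = se + se * se * (float(Py @ Py) - trP) / n
        return max(sa_new, floor), max(se_new, floor)

    ll, Py, P, b = _reml_loglik(y, X, sa * G + se * I)
    trace = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        GPy = G @ Py
        PGPy = P @ GPy
        PPy = P @ Py
        score = np.array([
            -0.5 * (float(np.sum(P * G.T)) - float(Py @ GPy)),
            -0.5 * (float(np.trace(P)) - float(Py @ Py)),
        ])
        AI = 0.5 * np.array([
            [float(GPy @ PGPy), float(GPy @ PPy)],
            [float(GPy @ PPy), float(Py @ PPy)],
        ])
        stepped = False
        try:
            delta = np.linalg.solve(AI, score)
            cand = np.array([sa, se]) + delta
            if np.all(cand > floor):
                ll_new, Py_new, P_new, b_new = _reml_loglik(y, X, cand[0] * G + cand[1] * I)
                if ll_new >= ll - 1e-10:
                    sa, se = float(cand[0]), float(cand[1])
                    ll_prev, ll, Py, P, b = ll, ll_new, Py_new, P_new, b_new
                    stepped = True
        except np.linalg.LinAlgError:
            pass
        if not stepped:
            sa, se = em_step(sa, se, Py, P)
            ll_prev = ll
            ll, Py, P, b = _reml_loglik(y, X, sa * G + se * I)
        trace.append(ll)
        if abs(ll - ll_prev) < tol * (abs(ll_prev) + 1.0):
            converged = True
            break

    return GREMLResult(sigma2_a=float(sa), sigma2_e=float(se),
                       fixed_effects=np.asarray(b).ravel(),
                       converged=converged, n_iterations=it,
                       loglik_trace=np.array(trace))


def solve_blup(sigma2_a: float, sigma2_e: float, phenotypes: np.ndarray,
               X: np.ndarray, G_full: np.ndarray, ref_idx: np.ndarray,
               cand_idx: np.ndarray | None = None):
    """BLUP of breeding values at fixed variance components.

    Solves b by generalized least squares on the reference individuals
    and propagates g_hat = sigma2_a G[:, ref] V^{-1} (y - X b_hat) to
    every individual in ``G_full`` — algebraically identical to solving
    the full mixed-model equations jointly.  Candidates carry no
    phenotype; a candidate genomically unrelated to every reference
    individual gets GEBV 0.

    Returns (gebv_all, b_hat); slice ``gebv_all[cand_idx]`` for the
    selection candidates.
    """
    y = np.asarray(phenotypes, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    ref_idx = np.asarray(ref_idx, dtype=int)
    Grr = G_full[np.ix_(ref_idx, ref_idx)]
    n = len(ref_idx)
    V = sigma2_a * Grr + sigma2_e * np.eye(n)
    try:
        cf = linalg.cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        warnings.warn("singular V in BLUP solve; adding ridge")
        cf = linalg.cho_factor(V + 1e-8 * np.trace(V) / n * np.eye(n),
                               lower=True)
    ViX = linalg.cho_solve(cf, X)
    Viy = linalg.cho_solve(cf, y)
    XtViX = X.T @ ViX
    b = np.linalg.solve(XtViX, X.T @ Viy)
    resid = linalg.cho_solve(cf, y - X @ b)
    gebv = sigma2_a * (G_full[:, ref_idx] @ resid)
    if cand_idx is not None:
        return gebv[np.asarray(cand_idx, dtype=int)], b
    return gebv, b
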