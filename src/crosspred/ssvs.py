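"""Bayesian stochastic search variable selection (SSVS) for genomic prediction.

Model: y = 1 mu + sum_j X_j beta_j + e, with a two-component mixture
prior on each SNP effect.  An indicator gamma_j switches marker j
between a large-variance component N(0, s2b) (prior probability
``pi_large`` = 1 - pi, default 0.01) and a small-variance component
N(0, s2b / variance_ratio) (default ratio 100).  s2b is sampled from a
scaled inverse chi-square full conditional shared by both components up
to the fixed ratio; the residual variance gets a flat prior.

The Gibbs sampler uses right-hand-side updating (incremental residual
maintenance) and runs in a numba kernel; see ``_kernels.ssvs_chain``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from crosspred._kernels import ssvs_chain


@dataclass(frozen=True)
class SSVSConfig:
    pi_large: float = 0.01          # prior P(gamma = 1), the paper's 1 - pi
    variance_ratio: float = 100.0   # large-to-small prior variance ratio
    n_iterations: int = 5000
    burn_in: int = 1000
    prior_df: float = 4.2
    prior_scale: float | None = None  # None -> auto-calibrated from y
    assumed_h2: float = 0.95          # used by the auto-calibration
    include_population_intercepts: bool = True
    random_update_order: bool = False
    debug: bool = False               # verify incremental residuals at the end
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.pi_large < 1.0:
            raise ValueError("pi_large must lie in (0, 1)")
        if self.variance_ratio <= 1.0:
            raise ValueError("variance_ratio must exceed 1")
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")


@dataclass
class SSVSResult:
    posterior_mean_beta: np.ndarray
    inclusion_probability: np.ndarray
    posterior_mean_sigma2_beta: float
    posterior_mean_sigma2_e: float
    posterior_mean_mu: np.ndarray
    gebv: np.ndarray                 # per selection candidate
    n_samples: int


def indicator_posterior(log_pd1: float, log_pd0: float, pi_large: float) -> float:
    """P(gamma = 1) = pd1 (1 - pi) / (pd1 (1 - pi) + pd0 pi), in log space.

    ``pi_large`` is 1 - pi, the prior probability of a large effect.
    Computed via the log-odds so that simultaneous underflow of both
    densities never yields 0/0.
    """
    if not 0.0 < pi_large < 1.0:
        raise ValueError("pi_large must lie in (0, 1)")
    if np.isneginf(log_pd1) and np.isneginf(log_pd0):
        raise ValueError("both component densities are zero")
    if np.isneginf(log_pd0):
        return 1.0
    if np.isneginf(log_pd1):
        return 0.0
    z = (log_pd0 + np.log1p(-pi_large)) - (log_pd1 + np.log(pi_large))
    if z > 35.0:
        return 0.0
    if z < -35.0:
        return 1.0
    return 1.0 / (1.0 + np.exp(z))


def marker_log_density(rhs: float, xtx: float, prior_var: float,
                       sigma2_e: float) -> float:
    """Log marginal density (up to a shared constant) of marker j's data.

    rhs = X_j'e + X_j'X_j beta_j is the right-hand side with marker j's
    own contribution restored; integrating beta_j out of its normal
    likelihood x N(0, prior_var) prior gives, dropping terms common to
    both mixture components:

        -(log v + log(xtx + s2e/v)) / 2 + rhs^2 / (2 s2e (xtx + s2e/v))
    """
    if prior_var <= 0 or sigma2_e <= 0:
        raise ValueError("variances must be positive")
    lhs = xtx + sigma2_e / prior_var
    return -0.5 * (np.log(prior_var) + np.log(lhs)) \
        + rhs * rhs / (2.0 * sigma2_e * lhs)


def indicator_posterior_from_stats(rhs: float, xtx: float, sigma2_beta: float,
                                   sigma2_e: float, pi_large: float,
                                   variance_ratio: float) -> float:
    """Indicator posterior from the right-hand-side statistics."""
    ll1 = marker_log_density(rhs, xtx, sigma2_beta, sigma2_e)
    ll0 = marker_log_density(rhs, xtx, sigma2_beta / variance_ratio, sigma2_e)
    return indicator_posterior(ll1, ll0, pi_large)


def sample_prior_variances(beta: np.ndarray, gamma: np.ndarray, e: np.ndarray,
                           config: SSVSConfig, prior_scale: float,
                           rng: np.random.Generator):
    """One draw of (s2b, s2e) from their full conditionals.

    s2b ~ scaled-inv-chi2(df + m, (df*scale + sum_j c_j beta_j^2)/(df + m))
    with c_j = 1 for gamma_j = 1 and c_j = variance_ratio otherwise (the
    small component is s2b/ratio, so beta_j^2 enters scaled up).  s2e is
    drawn from e'e / chi2(n) (flat prior).
    """
    m = len(beta)
    ssq = float(np.sum(np.where(gamma == 1, beta ** 2,
                                beta ** 2 * config.variance_ratio)))
    s2b = (config.prior_df * prior_scale + ssq) \
        / rng.chisquare(config.prior_df + m)
    n = len(e)
    s2e = float(e @ e) / rng.chisquare(n)
    return float(s2b), float(s2e)


def default_prior_scale(y: np.ndarray, freqs: np.ndarray,
                        config: SSVSConfig) -> float:
    """Scale of the s2b prior, calibrated to the phenotypic variance.

    Chosen so that the prior expected total marker variance,
    sum_j 2 p_j q_j [(1-pi) s2b + pi s2b/ratio], matches assumed_h2 x
    var(y) when s2b sits at the prior scale.
    """
    sum2pq = float(np.sum(2.0 * freqs * (1.0 - freqs)))
    if sum2pq <= 0:
        raise ValueError("all markers are monomorphic")
    mix = config.pi_large + (1.0 - config.pi_large) / config.variance_ratio
    return config.assumed_h2 * float(np.var(y)) / (sum2pq * mix)


def _center_columns(X_ref: np.ndarray, X_cand: np.ndarray):
    """Center marker columns by the combined-data mean allele count."""
    both = np.vstack([X_ref, X_cand]) if len(X_cand) else X_ref
    mean = both.mean(axis=0)
    return X_ref - mean, X_cand - mean, mean / 2.0


def run_ssvs(phenotypes: np.ndarray, X_ref: np.ndarray, X_cand: np.ndarray,
             config: SSVSConfig, ref_populations=None,
             fix_gamma: bool = False, fixed_variances=None) -> SSVSResult:
    """Run the Gibbs chain and predict GEBVs for the selection candidates.

    Parameters
    ----------
    phenotypes : (n_ref,) phenotypes of the reference individuals.
    X_ref, X_cand : raw allele-count matrices (same marker columns).
    ref_populations : optional per-reference-individual labels; with
        ``include_population_intercepts`` a separate intercept is fitted
        per population (mirroring the fixed breed effect of GBLUP).
    fix_gamma : force every indicator to 1 (ridge limit, for validation).
    fixed_variances : optional (s2b, s2e) to freeze instead of sampling.
    """
    y = np.asarray(phenotypes, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotypes contain non-finite values")
    X_ref = np.asarray(X_ref, dtype=float)
    X_cand = np.asarray(X_cand, dtype=float)
    if X_ref.shape[0] != len(y):
        raise ValueError("phenotype/reference row mismatch")
    if X_cand.size and X_cand.shape[1] != X_ref.shape[1]:
        raise ValueError("reference and candidate marker columns differ")

    Xr, Xc, freqs = _center_columns(X_ref, X_cand)
    n = len(y)

    if ref_populations is not None and config.include_population_intercepts:
        labels = np.asarray(ref_populations)
        uniq = list(dict.fromkeys(labels))
        group = np.array([uniq.index(l) for l in labels], dtype=np.int64)
        n_groups = len(uniq)
    else:
        group = np.zeros(n, dtype=np.int64)
        n_groups = 1

    scale = config.prior_scale
    if scale is None:
        scale = default_prior_scale(y, freqs, config)
    if fixed_variances is not None:
        s2b0, s2e0 = map(float, fixed_variances)
        fix_var = 1
    else:
        s2b0 = scale
        s2e0 = max(float(np.var(y)) * (1.0 - config.assumed_h2), 1e-8 * float(np.var(y)) + 1e-12)
        fix_var = 0

    Xt = np.ascontiguousarray(Xr.T)
    (beta_sum, gamma_sum, mu_sum, s2b_sum, s2e_sum, n_kept, e_final,
     beta_final, mu_final, fail_iter) = ssvs_chain(
        Xt, y, group, n_groups, config.pi_large, config.variance_ratio,
        config.n_iterations, config.burn_in, config.prior_df, scale,
        s2b0, s2e0, int(config.seed) & 0x7FFFFFFF,
        1 if fix_gamma else 0, fix_var,
        1 if config.random_update_order else 0)
    if fail_iter >= 0:
        raise RuntimeError(f"chain diverged (non-finite variance) at "
                           f"iteration {fail_iter}")

    if config.debug:
        recomputed = y - mu_final[group] - Xr @ beta_final
        if not np.allclose(recomputed, e_final, atol=1e-8):
            raise AssertionError("incremental residual drifted from full "
                                 "recomputation by more than 1e-8")

    beta_mean = beta_sum / n_kept
    gebv = predict_gebv(beta_mean, Xc) if len(Xc) else np.empty(0)
    return SSVSResult(
        posterior_mean_beta=beta_mean,
        inclusion_probability=gamma_sum / n_kept,
        posterior_mean_sigma2_beta=s2b_sum / n_kept if fix_var == 0 else s2b0,
        posterior_mean_sigma2_e=s2e_sum / n_kept if fix_var == 0 else s2e0,
        posterior_mean_mu=mu_sum / n_kept,
        gebv=gebv,
        n_samples=n_kept,
    )


def predict_gebv(posterior_mean_beta: np.ndarray, X_cand: np.ndarray) -> np.ndarray:
    """GEBV = candidate marker matrix x posterior-mean effects.

    Because GEBV accumulation is linear in beta, averaging per-iteration
    products equals this product with the posterior mean; column
    centering shifts all GEBVs by a constant, which leaves
    correlation-based accuracy untouched.
    """
    beta = np.asarray(posterior_mean_beta, dtype=float)
    X_cand = np.asarray(X_cand, dtype=float)
    if X_cand.shape[1] != len(beta):
        raise ValueError(f"marker mismatch: candidates have {X_cand.shape[1]} "
                         f"columns, effects {len(beta)}")
    return X_cand @ beta
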