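"""Trait simulation with population-correlated QTL effects.

A fixed set of candidate QTL is split off the SNP panel; the remaining
SNPs are the markers every predictor sees.  Each replicate activates m
candidate QTL, draws their allele substitution effects from a zero-mean
multivariate normal whose correlation across populations is the target
genetic correlation r_g, forms true breeding values (TBV) additively
from raw allele counts, and adds environmental noise scaled to a target
heritability (default 0.95, emulating deregressed bull proofs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from crosspred.popsim import GenotypePanel


@dataclass
class QTLArchitecture:
    """Partition of the SNP panel into candidate QTL and markers."""

    candidate_ids: np.ndarray   # SNP ids eligible to be QTL
    marker_ids: np.ndarray      # complement; what predictors use
    active_ids: np.ndarray      # subset of candidates with effects (may be empty)

    def __post_init__(self):
        self.candidate_ids = np.asarray(self.candidate_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.active_ids = np.asarray(self.active_ids, dtype=object)
        cand = set(self.candidate_ids)
        if not set(self.active_ids) <= cand:
            raise ValueError("active QTL must be a subset of the candidates")
        if cand & set(self.marker_ids):
            raise ValueError("markers and candidate QTL must be disjoint")

    @property
    def m(self) -> int:
        return len(self.active_ids)


@dataclass
class EffectMatrix:
    """Per-population allele substitution effects of the active QTL."""

    alpha: np.ndarray                 # (m, P) trait units per allele copy
    target_correlation: np.ndarray    # (P, P)
    populations: tuple[str, ...]

    def column(self, population: str) -> np.ndarray:
        return self.alpha[:, self.populations.index(population)]


@dataclass
class TraitReplicate:
    replicate: int
    tbv: np.ndarray
    phenotype: np.ndarray
    h2: float
    seed: int | None = None


def partition_candidate_qtl(panel_or_ids, n_candidates: int, seed=None) -> QTLArchitecture:
    """Randomly select candidate QTL; the complement becomes the markers.

    The draw is uniform without replacement, regardless of chromosome.
    Accepts a :class:`GenotypePanel` or an array of SNP ids.
    """
    if isinstance(panel_or_ids, GenotypePanel):
        snp_ids = panel_or_ids.snp_map["snp_id"].to_numpy(dtype=object)
    else:
        snp_ids = np.asarray(panel_or_ids, dtype=object)
    n_snps = len(snp_ids)
    if n_candidates >= n_snps:
        raise ValueError(f"n_candidates ({n_candidates}) must be smaller "
                         f"than the SNP count ({n_snps})")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n_snps, size=n_candidates, replace=False)
    mask = np.zeros(n_snps, dtype=bool)
    mask[idx] = True
    return QTLArchitecture(candidate_ids=snp_ids[mask],
                           marker_ids=snp_ids[~mask],
                           active_ids=np.empty(0, dtype=object))


def draw_active_qtl(arch: QTLArchitecture, m: int, seed=None) -> QTLArchitecture:
    """Uniformly draw m active QTL from the candidates (fresh per replicate)."""
    if m > len(arch.candidate_ids):
        raise ValueError(f"m ({m}) exceeds the candidate count "
                         f"({len(arch.candidate_ids)})")
    rng = np.random.default_rng(seed)
    active = rng.choice(arch.candidate_ids, size=m, replace=False)
    return QTLArchitecture(candidate_ids=arch.candidate_ids,
                           marker_ids=arch.marker_ids,
                           active_ids=active)


def _correlation_factor(corr: np.ndarray) -> np.ndarray:
    """Square root of a correlation matrix via eigendecomposition.

    Handles the singular r_g = 1 case (all-ones matrix) that a Cholesky
    factorization rejects.  Raises on genuinely negative eigenvalues,
    naming the offender.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
        raise ValueError("correlation matrix must have unit diagonal")
    w, v = np.linalg.eigh(corr)
    if w.min() < -1e-10:
        raise ValueError(f"correlation matrix is not positive semi-definite: "
                         f"eigenvalue {w.min():.6g} < 0")
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)[None, :]


def sample_correlated_effects(m: int, target_correlation, seed=None,
                              populations: tuple[str, ...] | None = None) -> EffectMatrix:
    """Draw m iid P-vectors of effects ~ N(0, R) with R the target correlation.

    Unit variances per population: prediction accuracy is scale-free, so
    only the correlation structure matters.  The underlying standard
    normal draws depend only on (m, P, seed), so re-running with a
    different correlation reuses the same randomness — paired designs
    across r_g values come for free.
    """
    corr = np.atleast_2d(np.asarray(target_correlation, dtype=float))
    P = corr.shape[0]
    if populations is None:
        populations = tuple(f"pop{i}" for i in range(P))
    if len(populations) != P:
        raise ValueError("one population label per correlation row required")
    fac = _correlation_factor(corr)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((m, P))
    alpha = z @ fac.T
    return EffectMatrix(alpha=alpha, target_correlation=corr,
                        populations=tuple(populations))


def compute_tbv(panel: GenotypePanel, arch: QTLArchitecture,
                effects: EffectMatrix) -> np.ndarray:
    """TBV_i = sum_k X_ik * alpha_k(pop_i): raw counts, own-population effects."""
    if arch.m == 0:
        raise ValueError("architecture has no active QTL")
    if effects.alpha.shape[0] != arch.m:
        raise ValueError("effects are not aligned to the active QTL")
    unknown = set(panel.population_labels) - set(effects.populations)
    if unknown:
        raise ValueError(f"individuals with unknown population label: {unknown}")
    X = panel.allele_counts[:, panel.snp_indices(arch.active_ids)].astype(float)
    tbv = np.empty(panel.n_individuals)
    for p, label in enumerate(effects.populations):
        rows = panel.individuals_of(label)
        if len(rows):
            tbv[rows] = X[rows] @ effects.alpha[:, p]
    return tbv


def simulate_phenotypes(tbv: np.ndarray, h2: float, population_labels,
                        seed=None, replicate: int = 0) -> TraitReplicate:
    """Add environmental noise to reach heritability h2 within each population.

    The environmental variance is (1/h2 - 1) times the within-population
    variance of TBV (mean-corrected within that population); phenotype =
    TBV + environment.  A zero-variance population with h2 < 1 gets zero
    noise with a warning.
    """
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must lie in (0, 1]")
    tbv = np.asarray(tbv, dtype=float)
    labels = np.asarray(population_labels)
    rng = np.random.default_rng(seed)
    phen = tbv.copy()
    if h2 < 1.0:
        for pop in pd.unique(labels):
            rows = np.flatnonzero(labels == pop)
            var_tbv = tbv[rows].var()  # mean-corrected, divisor N
            if var_tbv == 0.0:
                warnings.warn(f"population {pop!r} has zero TBV variance; "
                              "using zero environmental variance")
                continue
            var_env = (1.0 / h2 - 1.0) * var_tbv
            phen[rows] = tbv[rows] + rng.normal(0.0, np.sqrt(var_env),
                                                size=len(rows))
    return TraitReplicate(replicate=replicate, tbv=tbv, phenotype=phen, h2=h2,
                          seed=seed if isinstance(seed, int) else None)


def realized_genetic_correlation(effects: EffectMatrix) -> np.ndarray:
    """Pearson correlation of effect columns; the realized r_g of a replicate.

    m = 1 is undefined (NaN matrix with a warning); m = 2 always yields
    +/-1 and is flagged.  Zero-variance columns produce NaN entries.
    """
    m, P = effects.alpha.shape
    if m < 2:
        warnings.warn("realized correlation undefined for a single QTL")
        out = np.full((P, P), np.nan)
        np.fill_diagonal(out, 1.0)
        return out
    if m == 2:
        warnings.warn("realized correlation with 2 QTL is always +/-1")
    sd = effects.alpha.std(axis=0)
    if (sd == 0).any():
        warnings.warn("zero-variance effect column: correlation undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.corrcoef(effects.alpha, rowvar=False)
    return np.atleast_2d(out)
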