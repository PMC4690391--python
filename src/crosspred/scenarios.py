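"""Scenario orchestration: replicated prediction runs and model comparison.

A scenario names a reference population (one or two breeds) and a
candidate population; the base scenario predicts within one breed by
20-fold cross-validation.  For each replicate the active QTL, their
correlated effects and the environmental noise are redrawn; both
predictors see the reference phenotypes and the marker genotypes only,
and are scored by the Pearson correlation between candidate GEBVs and
TBVs.  Replicate seeds depend on (scenario seed, replicate index) but
not on r_g or the model, so runs at different genetic correlations are
paired draw-for-draw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from crosspred.popsim import PopSimConfig, GenotypePanel
from crosspred.phenosim import (QTLArchitecture, draw_active_qtl,
                                sample_correlated_effects, compute_tbv,
                                simulate_phenotypes)
from crosspred.ssvs import SSVSConfig, run_ssvs
from crosspred.greml import compute_grm, fit_greml, solve_blup


def desk_config(seed: int = 0) -> PopSimConfig:
    """Reduced-scale simulation profile for tests and quick studies.

    Three chromosomes, ~2.5k retained SNPs, populations 400/100/120.
    """
    return PopSimConfig(
        n_individuals=(400, 100, 120),
        n_snps_per_chromosome=1050,
        seed=seed,
    )


def paper_config(seed: int = 0) -> PopSimConfig:
    """Full-scale profile: 1033/105/147 individuals, ~31.5k retained SNPs."""
    return PopSimConfig(seed=seed)


def desk_ssvs_config(seed: int = 0) -> SSVSConfig:
    return SSVSConfig(n_iterations=2000, burn_in=400, seed=seed)


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the study design.

    ``reference_populations`` lists one or two breeds; the base
    (within-population) scenario uses the same breed on both sides and
    20-fold cross-validation.
    """

    scenario_id: str
    reference_populations: tuple[str, ...]
    candidate_population: str
    n_qtl: int
    r_g: float
    n_replicates: int = 100
    models: tuple[str, ...] = ("ssvs", "greml")
    h2: float = 0.95
    n_folds: int = 20
    seed: int = 0

    @property
    def is_base(self) -> bool:
        return self.candidate_population in self.reference_populations

    def __post_init__(self):
        if (self.candidate_population in self.reference_populations
                and len(self.reference_populations) > 1):
            raise ValueError("candidate population may coincide with the "
                             "reference only in the single-breed base scenario")


def make_cv_folds(n: int, k: int, seed=None) -> list[np.ndarray]:
    """Random partition of range(n) into k groups of size floor/ceil(n/k)."""
    if k > n:
        raise ValueError(f"cannot split {n} individuals into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, k)]


def accuracy(gebv, tbv) -> float:
    """Pearson correlation between predicted and true breeding values."""
    gebv = np.asarray(gebv, dtype=float)
    tbv = np.asarray(tbv, dtype=float)
    if len(gebv) != len(tbv) or len(gebv) < 3:
        raise ValueError("need >= 3 aligned candidates")
    if not (np.all(np.isfinite(gebv)) and np.all(np.isfinite(tbv))):
        raise ValueError("non-finite values in GEBV or TBV")
    if gebv.std() == 0.0 or tbv.std() == 0.0:
        warnings.warn("zero variance in GEBV or TBV: accuracy undefined")
        return np.nan
    return float(np.corrcoef(gebv, tbv)[0, 1])


def _child_seed(*parts) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1,
               dtype=np.uint32)[0]) & 0x7FFFFFFF


def _correlation_matrix(populations, r_g: float) -> np.ndarray:
    P = len(populations)
    corr = np.full((P, P), float(r_g))
    np.fill_diagonal(corr, 1.0)
    return corr


def run_scenario(spec: ScenarioSpec, panel: GenotypePanel,
                 arch: QTLArchitecture, ssvs_config: SSVSConfig | None = None,
                 greml_tol: float = 1e-8):
    """Run all replicates of one scenario.

    Returns (summary, replicates): ``summary`` has one row per model
    with mean accuracy, its standard error over replicates, and mean
    reliability (per-replicate squared accuracy averaged); ``replicates``
    has one row per (replicate, model).  Replicates in which any
    requested model failed are excluded pairwise from the summary so the
    model comparison stays paired; the count is reported.
    """
    if ssvs_config is None:
        ssvs_config = SSVSConfig()
    pops = panel.populations
    for p in (*spec.reference_populations, spec.candidate_population):
        if p not in pops:
            raise ValueError(f"population {p!r} not in panel")
    corr = _correlation_matrix(pops, spec.r_g)
    marker_idx = panel.snp_indices(arch.marker_ids)
    M = panel.allele_counts[:, marker_idx].astype(float)

    ref_rows = panel.individuals_of(*spec.reference_populations)
    cand_rows = panel.individuals_of(spec.candidate_population)

    if spec.is_base:
        union = ref_rows
    else:
        union = np.concatenate([ref_rows, cand_rows])
    grm = compute_grm(M[union])
    G = grm.matrix
    union_pos = {int(r): i for i, r in enumerate(union)}

    rows = []
    for rep in range(spec.n_replicates):
        qtl_seed = _child_seed(spec.seed, rep, 0)
        eff_seed = _child_seed(spec.seed, rep, 1)
        env_seed = _child_seed(spec.seed, rep, 2)
        fold_seed = _child_seed(spec.seed, rep, 3)
        chain_seed = _child_seed(spec.seed, rep, 4)

        arch_r = draw_active_qtl(arch, spec.n_qtl, qtl_seed)
        effects = sample_correlated_effects(arch_r.m, corr, eff_seed,
                                            populations=pops)
        tbv = compute_tbv(panel, arch_r, effects)
        trait = simulate_phenotypes(tbv, spec.h2, panel.population_labels,
                                    env_seed, replicate=rep)
        y = trait.phenotype

        for model in spec.models:
            try:
                if spec.is_base:
                    acc = _base_replicate(spec, model, M, G, union_pos, y,
                                          tbv, ref_rows, panel, ssvs_config,
                                          chain_seed, fold_seed, greml_tol)
                else:
                    acc = _across_replicate(spec, model, M, G, union_pos, y,
                                            tbv, ref_rows, cand_rows, panel,
                                            ssvs_config, chain_seed, greml_tol)
                rows.append((rep, model, acc, acc ** 2, True))
            except Exception as exc:  # recorded, replicate dropped pairwise
                warnings.warn(f"replicate {rep} model {model} failed: {exc}")
                rows.append((rep, model, np.nan, np.nan, False))

    replicates = pd.DataFrame(rows, columns=["replicate", "model", "accuracy",
                                             "reliability", "ok"])
    ok_reps = replicates.groupby("replicate")["ok"].all()
    good = replicates[replicates["replicate"].map(ok_reps)]
    summary_rows = []
    for model in spec.models:
        sub = good[good["model"] == model]
        n = len(sub)
        acc = sub["accuracy"].to_numpy()
        summary_rows.append({
            "scenario": spec.scenario_id,
            "model": model,
            "n_qtl": spec.n_qtl,
            "r_g": spec.r_g,
            "mean_accuracy": acc.mean() if n else np.nan,
            "se": acc.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
            "mean_reliability": sub["reliability"].mean() if n else np.nan,
            "n_replicates_used": n,
            "n_replicates_failed": spec.n_replicates - n,
        })
    return pd.DataFrame(summary_rows), replicates


def _breed_design(labels, populations):
    X = np.zeros((len(labels), len(populations)))
    for j, p in enumerate(populations):
        X[np.asarray(labels) == p, j] = 1.0
    return X


def _across_replicate(spec, model, M, G, union_pos, y, tbv, ref_rows,
                      cand_rows, panel, ssvs_config, chain_seed, greml_tol):
    y_ref = y[ref_rows]
    if model == "ssvs":
        cfg = SSVSConfig(**{**ssvs_config.__dict__, "seed": chain_seed})
        res = run_ssvs(y_ref, M[ref_rows], M[cand_rows], cfg,
                       ref_populations=panel.population_labels[ref_rows])
        gebv = res.gebv
    elif model == "greml":
        X = _breed_design(panel.population_labels[ref_rows],
                          spec.reference_populations)
        ridx = np.array([union_pos[int(r)] for r in ref_rows])
        cidx = np.array([union_pos[int(r)] for r in cand_rows])
        fit = fit_greml(y_ref, X, G[np.ix_(ridx, ridx)], tol=greml_tol)
        gebv, _ = solve_blup(fit.sigma2_a, fit.sigma2_e, y_ref, X, G,
                             ridx, cidx)
    else:
        raise ValueError(f"unknown model {model!r}")
    return accuracy(gebv, tbv[cand_rows])


def _base_replicate(spec, model, M, G, union_pos, y, tbv, pop_rows, panel,
                    ssvs_config, chain_seed, fold_seed, greml_tol):
    """Within-population k-fold CV; GEBVs pooled before correlating."""
    folds = make_cv_folds(len(pop_rows), spec.n_folds, fold_seed)
    gebv_pool = np.empty(len(pop_rows))
    local_idx = np.arange(len(pop_rows))
    for f, fold in enumerate(folds):
        test = fold
        train = np.setdiff1d(local_idx, fold)
        rows_tr = pop_rows[train]
        rows_te = pop_rows[test]
        y_tr = y[rows_tr]
        if model == "ssvs":
            cfg = SSVSConfig(**{**ssvs_config.__dict__,
                                "seed": _child_seed(chain_seed, f)})
            res = run_ssvs(y_tr, M[rows_tr], M[rows_te], cfg)
            gebv_pool[test] = res.gebv
        elif model == "greml":
            X = np.ones((len(rows_tr), 1))
            ridx = np.array([union_pos[int(r)] for r in rows_tr])
            cidx = np.array([union_pos[int(r)] for r in rows_te])
            fit = fit_greml(y_tr, X, G[np.ix_(ridx, ridx)], tol=greml_tol)
            gebv, _ = solve_blup(fit.sigma2_a, fit.sigma2_e, y_tr, X, G,
                                 ridx, cidx)
            gebv_pool[test] = gebv
        else:
            raise ValueError(f"unknown model {model!r}")
    return accuracy(gebv_pool, tbv[pop_rows])


def fit_reliability_regression(table: pd.DataFrame):
    """OLS of mean reliability on ln(n_qtl) for one scenario/model.

    ``table`` needs columns n_qtl and mean_reliability with at least two
    distinct QTL counts.  Returns (slope, intercept).
    """
    x = np.log(table["n_qtl"].to_numpy(dtype=float))
    yv = table["mean_reliability"].to_numpy(dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("need at least 2 distinct n_qtl levels")
    slope, intercept = np.polyfit(x, yv, 1)
    return float(slope), float(intercept)


@dataclass
class CrossingPoint:
    present: bool
    ln_n_qtl: float | None = None
    n_qtl: float | None = None
    delta_vs_ln_me: float | None = None


def find_crossing_point(fit_a, fit_b, me: float | None = None) -> CrossingPoint:
    """Where two reliability-vs-ln(n_qtl) lines intersect.

    Solves intercept_a + slope_a x = intercept_b + slope_b x; compared
    against ln(M_e) when an M_e estimate is supplied.  Parallel lines
    (|slope difference| < 1e-12) are flagged absent, not an error.
    """
    slope_a, int_a = fit_a
    slope_b, int_b = fit_b
    if abs(slope_a - slope_b) < 1e-12:
        return CrossingPoint(present=False)
    x = (int_b - int_a) / (slope_a - slope_b)
    delta = x - np.log(me) if me is not None else None
    return CrossingPoint(present=True, ln_n_qtl=float(x),
                         n_qtl=float(np.exp(x)),
                         delta_vs_ln_me=None if delta is None else float(delta))


def plot_reliability(tables: dict, path, me: float | None = None) -> None:
    """Reliability vs ln(n_qtl) per model, with an optional ln(M_e) line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for model, table in tables.items():
        x = np.log(table["n_qtl"].to_numpy(dtype=float))
        yv = table["mean_reliability"].to_numpy(dtype=float)
        o = np.argsort(x)
        ax.plot(x[o], yv[o], marker="o", label=model)
    if me is not None:
        ax.axvline(np.log(me), color="grey", ls="--", label="ln(M_e)")
    ax.set_xlabel("ln(number of QTL)")
    ax.set_ylabel("mean reliability")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
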