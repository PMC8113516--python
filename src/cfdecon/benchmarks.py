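"""Reproducible simulation benchmarks for the decomposition methods.

Each function regenerates one of the synthetic study designs from its
stated distributions, runs the requested estimators, and returns the
summary statistic(s) for that design.  All randomness flows from a
single seed, so a (seed, n_reps) pair pins the result exactly.

EM settings used here (2 restarts for fully-referenced designs, tighter
settings where unknowns are estimated, likelihood checked every few
iterations) are chosen for single-CPU throughput; the estimates are
insensitive to additional restarts on these well-conditioned designs.
"""

from __future__ import annotations

import numpy as np

from . import alt, em, evaluate, simulate
from .core import SimScenario

__all__ = [
    "mixture_recovery_benchmark",
    "beta_recovery_benchmark",
    "rare_case_control_benchmark",
    "missing_type_bias_benchmark",
    "unknown_mse_by_cohort_size",
]


def _rep_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)


def mixture_recovery_benchmark(
    n_reps: int = 50,
    seed: int = 0,
    T: int = 25,
    M: int = 6000,
    depth: float = 10.0,
    restarts: int = 2,
) -> dict[str, float]:
    """Proportion recovery of all four solvers on the T-type benchmark.

    One individual with triangular true proportions (1..T)/(T(T+1)/2),
    uniform true methylation, Poisson(depth) reference and cfDNA counts.
    Returns the mean squared Pearson correlation between estimated and
    true proportion vectors per method.
    """
    out = {k: [] for k in ("em", "projection", "ols", "nnls")}
    for rs in _rep_seeds(seed, n_reps):
        scen = SimScenario(T=T, M=M, N=1, alpha_design="triangular",
                           reference_depth_lambda=depth, cfdna_depth_lambda=depth,
                           seed=int(rs))
        beta, alpha, panel, samples = simulate.simulate_dataset(scen)
        res = em.run_em(panel, samples, restarts=restarts, max_iter=2500,
                        tol=1e-9, seed=int(rs) + 1, ll_interval=10)
        out["em"].append(evaluate.pearson_r2(res.alpha[0], alpha[0]))
        proj = alt.projected_binomial_mle(panel, (samples.X[0], samples.D_X[0]),
                                          seed=int(rs) + 2)
        out["projection"].append(evaluate.pearson_r2(proj, alpha[0]))
        ref, samp = alt.proportions_for_solvers(panel, samples, 0)
        out["ols"].append(evaluate.pearson_r2(alt.ols_deconvolve(ref, samp), alpha[0]))
        out["nnls"].append(evaluate.pearson_r2(alt.nnls_deconvolve(ref, samp), alpha[0]))
    return {k: float(np.mean(v)) for k, v in out.items()}


def beta_recovery_benchmark(
    depth: float,
    n_reps: int = 50,
    seed: int = 0,
    T: int = 10,
    M: int = 1000,
) -> float:
    """Methylation recovery of one swept cell type at a given coverage.

    The fixed cell type's true proportion sweeps evenly over [0, 1]
    across replicates; the other T-1 proportions are uniform draws
    scaled to the remainder.  Returns the mean r^2 between the EM's
    estimated and true methylation values for the fixed type.
    """
    r2s = []
    sweep = np.linspace(0.0, 1.0, n_reps)
    for fixed, rs in zip(sweep, _rep_seeds(seed, n_reps)):
        rng = np.random.default_rng(rs)
        beta = rng.uniform(size=(T, M))
        alpha = simulate.sweep_proportions(T, float(fixed), rng)[None, :]
        sites = simulate.make_sites(M)
        panel = simulate.simulate_reference(beta, depth, rng, sites=sites)
        samples = simulate.simulate_mixture(beta, alpha, depth, rng, sites=sites)
        res = em.run_em(panel, samples, restarts=2, max_iter=2000, tol=1e-9,
                        seed=int(rs) + 1, ll_interval=10)
        r2s.append(evaluate.pearson_r2(res.beta[0], beta[0]))
    return float(np.mean(r2s))


def rare_case_control_benchmark(
    fixed_pct: float = 0.05,
    depth: float = 5.0,
    n_reps: int = 50,
    seed: int = 0,
    M: int = 1000,
) -> dict[str, float]:
    """Joint decomposition of a 5-case / 5-control rare-cell-type cohort.

    Returns the mean estimated proportion of the fixed cell type in the
    case and control groups, pooled over replicates.
    """
    case_est, control_est = [], []
    for rs in _rep_seeds(seed, n_reps):
        bt, at, panel, samples = simulate.case_control_scenario(
            fixed_pct, M=M, depth=depth, seed=int(rs))
        res = em.run_em(panel, samples, restarts=2, max_iter=2000, tol=1e-9,
                        seed=int(rs) + 1, ll_interval=10)
        case_est.append(res.alpha[:5, 0].mean())
        control_est.append(res.alpha[5:, 0].mean())
    return {"case": float(np.mean(case_est)), "control": float(np.mean(control_est))}


def _tissue_mean_pct_diff(est: np.ndarray, truth: np.ndarray) -> float:
    """Relative difference of per-tissue mean estimates vs mean truths.

    Aggregating over people before taking the ratio keeps the statistic
    finite: individual people can carry a near-zero true proportion of
    some type, which makes per-person ratios arbitrarily large.
    """
    return float(evaluate.percent_difference(est.mean(axis=0), truth.mean(axis=0)))


def missing_type_bias_benchmark(
    n_reps: int = 50,
    seed: int = 0,
    n_people: int = 100,
    T: int = 10,
    M: int = 1000,
    depth: float = 100.0,
) -> dict[str, float]:
    """Estimation bias when the largest (~20%) cell type is missing.

    The masked type's per-person proportion is truncated-normal(0.2, 0.1);
    the EM runs once with no unknown component and once with one, and
    NNLS runs per person against the reduced reference.  Returns the
    average per-tissue relative difference of the known-type estimates
    (em_no_unknown, em_one_unknown) and the NNLS value in percent.
    """
    v0, v1, vn = [], [], []
    for rs in _rep_seeds(seed, n_reps):
        bt, at, panel, samples = simulate.unknown_scenario(
            n_people, mask=[0], T=T, M=M, depth=depth, seed=int(rs))
        truth_known = at[:, 1:]
        res0 = em.run_em(panel, samples, k_unknowns=0, restarts=1, max_iter=800,
                         tol=1e-8, seed=int(rs) + 1, ll_interval=10)
        v0.append(_tissue_mean_pct_diff(res0.alpha, truth_known))
        res1 = em.run_em(panel, samples, k_unknowns=1, restarts=2, max_iter=800,
                         tol=1e-8, seed=int(rs) + 2, ll_interval=10)
        v1.append(_tissue_mean_pct_diff(res1.alpha[:, : T - 1], truth_known))
        nnls_alpha = np.array([
            alt.nnls_deconvolve(*alt.proportions_for_solvers(panel, samples, n))
            for n in range(samples.n_samples)
        ])
        vn.append(_tissue_mean_pct_diff(nnls_alpha, truth_known))
    return {
        "em_no_unknown": float(np.mean(v0)),
        "em_one_unknown": float(np.mean(v1)),
        "nnls_percent": float(100.0 * np.mean(vn)),
    }


def unknown_mse_by_cohort_size(
    cohort_sizes=(10, 100),
    n_reps: int = 3,
    seed: int = 0,
    T: int = 10,
    M: int = 1000,
    depth: float = 10.0,
) -> dict[int, float]:
    """MSE of the estimated unknown proportion as the cohort grows."""
    out = {}
    for N in cohort_sizes:
        errs = []
        for rs in _rep_seeds(seed + N, n_reps):
            bt, at, panel, samples = simulate.unknown_scenario(
                N, mask=[0], T=T, M=M, depth=depth, seed=int(rs))
            res = em.run_em(panel, samples, k_unknowns=1, restarts=2,
                            max_iter=800, tol=1e-8, seed=int(rs) + 1, ll_interval=10)
            errs.append(evaluate.mse(res.alpha[:, -1], at[:, 0]))
        out[N] = float(np.mean(errs))
    return out
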