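"""Comparison deconvolution solvers.

Three simpler baselines against which the joint EM is benchmarked:

* sum-normalized ordinary least squares on methylation proportions,
* nonnegative least squares on methylation proportions (the approach
  used by array-era methylation atlases), and
* a binomial maximum-likelihood solver over the probability simplex
  with the reference methylation held fixed.

None of these re-estimates the reference methylation, so none can model
a cell type that is missing from the panel.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.optimize

from .core import CfdnaSamples, ReferencePanel

__all__ = [
    "ols_deconvolve",
    "nnls_deconvolve",
    "project_to_simplex",
    "projected_binomial_mle",
    "proportions_for_solvers",
]

_EPS = 1e-12


def _check_design(ref_props: np.ndarray, sample_props: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    A = np.asarray(ref_props, dtype=float)
    b = np.asarray(sample_props, dtype=float)
    if A.ndim != 2 or b.ndim != 1 or A.shape[0] != b.shape[0]:
        raise ValueError(f"design is {A.shape}, response is {b.shape}")
    if np.isnan(A).any() or np.isnan(b).any():
        raise ValueError("proportion inputs contain NaN; drop zero-depth sites first")
    return A, b


def proportions_for_solvers(
    panel: ReferencePanel, samples: CfdnaSamples, sample_index: int
) -> tuple[np.ndarray, np.ndarray]:
    """Convert counts to per-site methylation proportions for one sample.

    Sites where the sample or any reference cell type has zero depth are
    dropped (the proportion is undefined there).  Returns an M' x T
    design of reference proportions and the sample's M' proportion
    vector.
    """
    keep = (samples.D_X[sample_index] > 0) & np.all(panel.D_Y > 0, axis=0)
    ref = (panel.Y[:, keep] / panel.D_Y[:, keep]).T
    samp = samples.X[sample_index, keep] / samples.D_X[sample_index, keep]
    return ref, samp


def _reject_unknowns(ref_props: np.ndarray) -> None:
    # a column of an unknown-augmented panel would be all-NaN or undefined;
    # proportion-based solvers have no mechanism for missing cell types
    if np.isnan(ref_props).any():
        raise ValueError(
            "reference proportions contain undefined entries; proportion-based "
            "solvers cannot estimate unknown (all-zero) cell types"
        )


def ols_deconvolve(ref_props: np.ndarray, sample_props: np.ndarray) -> np.ndarray:
    """Unconstrained least squares, then divide the solution by its sum.

    Entries may be negative; the sum-normalization makes the result
    comparable to proportion vectors from the other solvers.
    """
    A, b = _check_design(ref_props, sample_props)
    _reject_unknowns(A)
    coef, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < A.shape[1]:
        warnings.warn("rank-deficient reference design; minimum-norm solution returned")
    total = coef.sum()
    if abs(total) < _EPS:
        warnings.warn("least-squares solution sums to ~0; returning unnormalized vector")
        return coef
    return coef / total


def nnls_deconvolve(
    ref_props: np.ndarray, sample_props: np.ndarray, normalize: bool = True
) -> np.ndarray:
    """Nonnegative least squares on methylation proportions.

    Solves min ||A a - b|| subject to a >= 0 and, by default, rescales
    the solution to sum to one.
    """
    A, b = _check_design(ref_props, sample_props)
    _reject_unknowns(A)
    coef, _ = scipy.optimize.nnls(A, b)
    if not normalize:
        return coef
    total = coef.sum()
    if total < _EPS:
        warnings.warn("all-zero NNLS solution; returning uniform proportions")
        return np.full(A.shape[1], 1.0 / A.shape[1])
    return coef / total


def project_to_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex.

    Returns the nearest point w with w >= 0 and sum(w) = 1, via the
    sorted water-filling threshold: w_i = max(v_i - tau, 0).
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("expected a nonempty 1-D vector")
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    rho = np.nonzero(u > css / np.arange(1, v.size + 1))[0][-1]
    tau = css[rho] / (rho + 1.0)
    return np.maximum(v - tau, 0.0)


def projected_binomial_mle(
    panel: ReferencePanel,
    sample_counts: tuple[np.ndarray, np.ndarray],
    restarts: int = 1,
    seed: int | np.random.Generator | None = None,
    max_iter: int = 2000,
    tol: float = 1e-8,
    method: str = "projected-gradient",
) -> np.ndarray:
    """Binomial ML estimate of proportions with fixed reference methylation.

    Maximizes sum_m [X_m log(sum_t a_t b_tm) + (D_m - X_m) log(sum_t a_t (1 - b_tm))]
    over the simplex, with b fixed at the observed reference proportions
    (regularized by one methylated + one unmethylated pseudocount).
    The default optimizer is projected gradient ascent with backtracking;
    ``method="lbfgs"`` instead runs box-constrained L-BFGS followed by a
    final simplex projection.
    """
    X, D = (np.asarray(a, dtype=float) for a in sample_counts)
    if panel.is_unknown().any():
        raise ValueError(
            "panel contains unknown (all-zero) rows; this solver cannot estimate "
            "missing cell types"
        )
    beta = (panel.Y + 1.0) / (panel.D_Y + 2.0)  # T x M, strictly inside (0,1)
    T = beta.shape[0]
    if T == 1:
        return np.ones(1)

    def negloglik_and_grad(a: np.ndarray) -> tuple[float, np.ndarray]:
        mix1 = a @ beta
        mix0 = a @ (1.0 - beta)
        ll = np.sum(X * np.log(mix1 + _EPS) + (D - X) * np.log(mix0 + _EPS))
        grad = beta @ (X / (mix1 + _EPS)) + (1.0 - beta) @ ((D - X) / (mix0 + _EPS))
        return -ll, -grad

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    best_a, best_obj = None, np.inf
    for r in range(restarts):
        a0 = rng.dirichlet(np.ones(T)) if r else np.full(T, 1.0 / T)
        if method == "lbfgs":
            # optimize over the sum-normalized vector (the raw likelihood is
            # scale-degenerate off the simplex), then project
            def fg_normalized(u: np.ndarray) -> tuple[float, np.ndarray]:
                s = u.sum()
                w = u / s
                f, g = negloglik_and_grad(w)
                return f, (g - g @ w) / s

            res = scipy.optimize.minimize(
                fg_normalized, a0, jac=True, method="L-BFGS-B",
                bounds=[(1e-9, 1.0)] * T,
            )
            a = project_to_simplex(res.x / res.x.sum())
            obj = negloglik_and_grad(a)[0]
        else:
            a, obj = _projected_gradient(negloglik_and_grad, a0, max_iter, tol)
        if obj < best_obj:
            best_a, best_obj = a, obj
    return best_a


def _projected_gradient(fun_grad, a0: np.ndarray, max_iter: int, tol: float):
    a = project_to_simplex(a0)
    obj, grad = fun_grad(a)
    step = 1.0 / (np.linalg.norm(grad) + 1.0)
    for _ in range(max_iter):
        # backtracking line search on the projected step
        improved = False
        for _ in range(40):
            cand = project_to_simplex(a - step * grad)
            cand_obj, cand_grad = fun_grad(cand)
            if cand_obj < obj:
                improved = True
                break
            step *= 0.5
        if not improved:
            break
        rel = (obj - cand_obj) / max(abs(obj), 1.0)
        a, obj, grad = cand, cand_obj, cand_grad
        step *= 2.0
        if rel < tol:
            break
    return a, obj
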