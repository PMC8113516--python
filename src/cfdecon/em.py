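"""Binomial-mixture EM for cfDNA cell-type deconvolution.

The model: reference counts Y_tm ~ Binomial(D_Y_tm, beta_tm) give noisy
observations of each cell type's methylation proportion beta_tm; each
cfDNA read from person n is assigned a cell type of origin with
probabilities alpha_n (the mixing proportions we want), and is then
methylated with probability beta at its site in its cell type of origin.
Both alpha and beta are estimated jointly by EM, so the reference panel
is treated as data rather than as a fixed design matrix -- this is what
lets low-coverage panels, and even all-zero "unknown" rows, be handled.

All E/M computations are closed-form and vectorized; per-iteration cost
is O(N*T*M) realized as a handful of matrix products.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import (
    CfdnaSamples,
    DecompositionResult,
    ReferencePanel,
    Responsibilities,
)

__all__ = [
    "compute_responsibilities",
    "update_alpha",
    "update_beta",
    "observed_loglik",
    "add_unknowns",
    "run_em",
]

_EPS = 1e-300  # guards exact-zero mixtures in degenerate hand-built inputs


def _responsibilities(alpha: np.ndarray, beta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(p0, p1), each N x T x M."""
    joint1 = alpha[:, :, None] * beta[None, :, :]
    joint0 = alpha[:, :, None] * (1.0 - beta)[None, :, :]
    p1 = joint1 / (joint1.sum(axis=1, keepdims=True) + _EPS)
    p0 = joint0 / (joint0.sum(axis=1, keepdims=True) + _EPS)
    return p0, p1


def _alpha_update(p0: np.ndarray, p1: np.ndarray, X: np.ndarray, U: np.ndarray) -> np.ndarray:
    num = np.einsum("ntm,nm->nt", p1, X) + np.einsum("ntm,nm->nt", p0, U)
    totals = num.sum(axis=1, keepdims=True)
    zero = totals[:, 0] == 0
    if np.any(zero):
        warnings.warn("sample(s) with zero total reads: proportion row set to uniform")
        num[zero] = 1.0
        totals[zero] = num.shape[1]
    return num / totals


def _beta_update(
    p0: np.ndarray, p1: np.ndarray, X: np.ndarray, U: np.ndarray,
    Y: np.ndarray, D_Y: np.ndarray,
) -> np.ndarray:
    meth = np.einsum("ntm,nm->tm", p1, X) + Y
    unmeth = np.einsum("ntm,nm->tm", p0, U) + (D_Y - Y)
    return meth / (meth + unmeth)


def _loglik(
    alpha: np.ndarray, beta: np.ndarray,
    X: np.ndarray, D_X: np.ndarray, Y: np.ndarray, D_Y: np.ndarray,
) -> float:
    mix1 = alpha @ beta          # N x M, P(read methylated)
    mix0 = alpha @ (1.0 - beta)
    ll = 0.0
    ll += np.sum(np.where(X > 0, X * np.log(mix1 + _EPS), 0.0))
    ll += np.sum(np.where(D_X - X > 0, (D_X - X) * np.log(mix0 + _EPS), 0.0))
    ll += np.sum(np.where(Y > 0, Y * np.log(beta + _EPS), 0.0))
    ll += np.sum(np.where(D_Y - Y > 0, (D_Y - Y) * np.log(1.0 - beta + _EPS), 0.0))
    return float(ll)


def compute_responsibilities(alpha: np.ndarray, beta: np.ndarray) -> Responsibilities:
    """E-step posteriors of read origin given methylation status.

    For a methylated read (j=1):  p[n,t,m,1] = beta_tm alpha_nt / sum_k beta_km alpha_nk
    and analogously with 1-beta for an unmethylated read (j=0).

    Parameters
    ----------
    alpha : (N, T) mixing proportions, rows on the simplex.
    beta : (T, M) methylation proportions in (0, 1).
    """
    alpha = np.atleast_2d(np.asarray(alpha, dtype=float))
    beta = np.asarray(beta, dtype=float)
    if np.isnan(alpha).any() or np.isnan(beta).any():
        raise FloatingPointError("NaN in EM parameters")
    p0, p1 = _responsibilities(alpha, beta)
    return Responsibilities(p=np.stack([p0, p1], axis=-1))


def update_alpha(resp: Responsibilities, samples: CfdnaSamples) -> np.ndarray:
    """M-step for the mixing proportions.

    The unnormalized weight of cell type t for person n is the expected
    number of that person's reads attributed to t: methylated reads enter
    with weight p[n,t,m,1], unmethylated with p[n,t,m,0].  Rows are then
    normalized to sum to one; a person with no reads at all gets a
    uniform row.
    """
    return _alpha_update(resp.p[..., 0], resp.p[..., 1], samples.X, samples.D_X - samples.X)


def update_beta(
    resp: Responsibilities, samples: CfdnaSamples, panel: ReferencePanel
) -> np.ndarray:
    """M-step for the methylation proportions.

    Expected methylated reads from cell type t at site m (cfDNA plus
    reference) over expected total reads from t at m.  With pseudocounts
    folded into the working counts the denominator is strictly positive.
    """
    return _beta_update(
        resp.p[..., 0], resp.p[..., 1],
        samples.X, samples.D_X - samples.X, panel.Y, panel.D_Y,
    )


def observed_loglik(
    alpha: np.ndarray,
    beta: np.ndarray,
    samples: CfdnaSamples,
    panel: ReferencePanel,
) -> float:
    """Observed-data log-likelihood, binomial coefficients omitted.

    Sum over people and sites of the mixture binomial kernel
    X log(sum_t alpha beta) + (D-X) log(sum_t alpha (1-beta)), plus the
    reference-panel binomial kernel in beta.
    """
    alpha = np.atleast_2d(np.asarray(alpha, dtype=float))
    beta = np.asarray(beta, dtype=float)
    return _loglik(alpha, beta, samples.X, samples.D_X, panel.Y, panel.D_Y)


def add_unknowns(panel: ReferencePanel, k: int, n_samples: int | None = None) -> ReferencePanel:
    """Append k all-zero reference rows labelled unknown_1..k.

    An all-zero row carries no reference information, so its methylation
    profile is learned entirely from the cfDNA.  More unknowns than cfDNA
    individuals makes the problem unidentified; this is warned about but
    allowed.
    """
    if k < 0:
        raise ValueError("number of unknowns must be nonnegative")
    if k == 0:
        return panel
    if n_samples is not None and k > n_samples:
        warnings.warn(
            f"{k} unknown components with only {n_samples} cfDNA individuals: "
            "the decomposition is not identified"
        )
    M = panel.Y.shape[1]
    zeros = np.zeros((k, M), dtype=panel.Y.dtype)
    return ReferencePanel(
        cell_types=panel.cell_types + [f"unknown_{i + 1}" for i in range(k)],
        sites=list(panel.sites),
        Y=np.vstack([panel.Y, zeros]),
        D_Y=np.vstack([panel.D_Y, zeros]),
    )


def _em_single_restart(
    Yp: np.ndarray,
    DYp: np.ndarray,
    Xp: np.ndarray,
    DXp: np.ndarray,
    unknown_mask: np.ndarray,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    check_monotone: bool,
    ll_interval: int,
) -> tuple[np.ndarray, np.ndarray, float, int, bool]:
    N, M = Xp.shape
    T = Yp.shape[0]
    alpha = rng.dirichlet(np.ones(T), size=N)
    beta = Yp / DYp
    if unknown_mask.any():
        beta = beta.copy()
        beta[unknown_mask] = rng.uniform(size=(int(unknown_mask.sum()), M))
    U = DXp - Xp

    ll_prev = -np.inf
    ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # fused E+M step: equivalent to the explicit-responsibility path but
        # realized as N x M / T x M matrix products instead of N x T x M arrays
        mix1 = alpha @ beta
        mix0 = alpha @ (1.0 - beta)
        A1 = Xp / (mix1 + _EPS)
        A0 = U / (mix0 + _EPS)
        alpha_num = alpha * (A1 @ beta.T + A0 @ (1.0 - beta).T)
        meth_cf = beta * (alpha.T @ A1)
        unmeth_cf = (1.0 - beta) * (alpha.T @ A0)
        alpha = alpha_num / alpha_num.sum(axis=1, keepdims=True)
        beta = (meth_cf + Yp) / (meth_cf + unmeth_cf + DYp)
        if check_monotone or it % ll_interval == 0 or it == max_iter:
            ll = _loglik(alpha, beta, Xp, DXp, Yp, DYp)
            if not np.isfinite(ll):
                raise FloatingPointError(f"non-finite log-likelihood at iteration {it}")
            if check_monotone and ll < ll_prev - 1e-6 * abs(ll_prev):
                raise AssertionError(
                    f"EM log-likelihood decreased at iteration {it}: {ll_prev} -> {ll}"
                )
            if np.isfinite(ll_prev) and abs(ll - ll_prev) / max(abs(ll_prev), 1.0) < tol:
                converged = True
                break
            ll_prev = ll
    return alpha, beta, ll, it, converged


def run_em(
    panel: ReferencePanel,
    samples: CfdnaSamples,
    k_unknowns: int = 0,
    restarts: int = 10,
    max_iter: int = 3000,
    tol: float = 1e-8,
    seed: int | np.random.Generator | None = None,
    pseudocount: float = 1.0,
    check_monotone: bool = False,
    ll_interval: int = 1,
) -> DecompositionResult:
    """Run the full decomposition and return the best of several restarts.

    A methylated and an unmethylated pseudocount (``pseudocount`` each)
    are added to every entry of the working count matrices, keeping every
    methylation proportion strictly inside (0, 1) and regularizing
    site/cell-type pairs with little or no coverage.  Each restart draws
    fresh starting values (Dirichlet(1) rows for alpha; moment estimates
    for known beta rows, uniform draws for unknown rows) from a stream
    derived from ``seed``; the restart with the highest observed-data
    log-likelihood wins, ties broken by lowest restart index.

    Parameters
    ----------
    panel, samples : harmonized inputs with identical site lists.
    k_unknowns : number of all-zero reference rows to append.
    restarts : independent random restarts.
    max_iter, tol : per-restart iteration cap and relative log-likelihood
        convergence threshold.
    seed : int or Generator controlling every random draw.
    pseudocount : count added as both a methylated and an unmethylated
        pseudo-observation to every matrix entry.
    check_monotone : assert the EM ascent property each iteration.
    ll_interval : evaluate the log-likelihood (and test convergence) every
        this many iterations; >1 trades convergence granularity for speed
        on large inputs.
    """
    if panel.n_sites and samples.n_sites and panel.sites != samples.sites:
        raise ValueError("panel and samples must be harmonized to identical sites")
    work = add_unknowns(panel, k_unknowns, n_samples=samples.n_samples)
    unknown_mask = work.is_unknown()

    Yp = work.Y.astype(float) + pseudocount
    DYp = work.D_Y.astype(float) + 2.0 * pseudocount
    Xp = samples.X.astype(float) + pseudocount
    DXp = samples.D_X.astype(float) + 2.0 * pseudocount

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    restart_seeds = rng.integers(0, 2**31 - 1, size=restarts)

    best = None
    logliks: list[float] = []
    for r in range(restarts):
        out = _em_single_restart(
            Yp, DYp, Xp, DXp, unknown_mask,
            np.random.default_rng(restart_seeds[r]),
            max_iter, tol, check_monotone, max(1, ll_interval),
        )
        logliks.append(out[2])
        if best is None or out[2] > best[2]:
            best = out
    alpha, beta, ll, n_iter, converged = best
    return DecompositionResult(
        alpha=alpha,
        beta=beta,
        loglik=ll,
        restart_logliks=logliks,
        n_iter=n_iter,
        converged=converged,
        cell_types=list(work.cell_types),
        samples=list(samples.samples),
    )
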