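"""Generators for synthetic WGBS reference panels and cfDNA mixtures.

Counts are drawn from the generative model the decomposition assumes:
per-site depths are Poisson, reference methylated counts are binomial in
the true methylation proportion, and each cfDNA read picks a cell type
of origin from the individual's mixing proportions before flipping a
methylation coin for that cell type.  Because the generator matches the
model, recovery here measures estimation error only, not model
misspecification; real WGBS data adds correlated CpGs, within-tissue
heterogeneity and heavy-tailed depths that these draws do not emulate.

Every public generator takes a seed (or Generator) and is
bit-reproducible.  Named child streams are derived with `SeedSequence`
so the reference panel, the mixtures, and the proportion draws can be
varied independently.
"""

from __future__ import annotations

import numpy as np

from .core import CfdnaSamples, ReferencePanel, SimScenario, Site

__all__ = [
    "make_sites",
    "triangular_proportions",
    "uniform_proportions",
    "sweep_proportions",
    "draw_betas",
    "simulate_reference",
    "simulate_mixture",
    "simulate_dataset",
    "case_control_scenario",
    "unknown_scenario",
    "truncated_normal",
]

# synthetic CpGs are spaced far enough apart that +/-250 bp regions never merge
_SITE_SPACING = 1000


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _streams(seed, n: int) -> list[np.random.Generator]:
    if isinstance(seed, np.random.Generator):
        return [seed] * n
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def make_sites(M: int, chrom: str = "chr1", spacing: int = _SITE_SPACING) -> list[Site]:
    """M synthetic CpG sites on one chromosome, 0-based half-open."""
    return [Site(chrom, i * spacing, i * spacing + 2) for i in range(M)]


def triangular_proportions(T: int) -> np.ndarray:
    """The proportion vector (1, ..., T) / (T(T+1)/2).

    Spans rare to abundant cell types in one draw-free design; sums to 1
    exactly.
    """
    if T < 1:
        raise ValueError("need at least one cell type")
    return np.arange(1, T + 1, dtype=float) / (T * (T + 1) / 2.0)


def uniform_proportions(T: int, rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """size x T rows of U(0,1) draws normalized to sum to one."""
    raw = rng.uniform(size=(size, T))
    return raw / raw.sum(axis=1, keepdims=True)


def sweep_proportions(T: int, fixed_value: float, rng: np.random.Generator) -> np.ndarray:
    """One cell type pinned at ``fixed_value``; the rest uniform, scaled.

    The fixed type is index 0.  The remaining T-1 proportions are drawn
    U(0,1) and rescaled to fill exactly 1 - fixed_value.
    """
    if not 0.0 <= fixed_value <= 1.0:
        raise ValueError("fixed proportion must be in [0, 1]")
    rest = rng.uniform(size=T - 1)
    rest = rest / rest.sum() * (1.0 - fixed_value)
    return np.concatenate([[fixed_value], rest])


def truncated_normal(
    mu: float, sigma: float, size, rng: np.random.Generator,
    low: float = 0.0, high: float = 1.0,
) -> np.ndarray:
    """Normal draws re-sampled (rejection) until inside [low, high]."""
    out = rng.normal(mu, sigma, size=size)
    bad = (out < low) | (out > high)
    while np.any(bad):
        out[bad] = rng.normal(mu, sigma, size=int(bad.sum()))
        bad = (out < low) | (out > high)
    return out


def draw_betas(scenario: SimScenario, seed=None) -> np.ndarray:
    """Draw the T x M matrix of true methylation proportions.

    Modes:

    * ``uniform`` -- iid U(0,1), maximal across-type variability.
    * ``normal`` -- iid N(mean, var) truncated to [0,1]; small variance
      means mostly uninformative CpGs.
    * ``correlated-pair`` -- the first two rows share a Gaussian copula
      with uniform marginals tuned so their Pearson correlation hits
      ``beta_pair_r``; remaining rows are iid uniform.
    """
    rng = _rng(scenario.seed if seed is None else seed)
    T, M = scenario.T, scenario.M
    mode = scenario.beta_distribution
    if mode == "uniform":
        return rng.uniform(size=(T, M))
    if mode == "normal":
        sd = float(np.sqrt(scenario.beta_normal_var))
        return truncated_normal(scenario.beta_normal_mean, sd, (T, M), rng)
    if mode == "correlated-pair":
        r = scenario.beta_pair_r
        if not 0.0 <= r <= 1.0:
            raise ValueError("target correlation must be in [0, 1]")
        beta = rng.uniform(size=(T, M))
        if r >= 1.0:
            beta[1] = beta[0]
            return beta
        # for uniform marginals under a Gaussian copula,
        # pearson(u1, u2) = (6/pi) asin(rho/2)  =>  invert for rho
        rho = 2.0 * np.sin(np.pi * r / 6.0)
        cov = np.array([[1.0, rho], [rho, 1.0]])
        z = rng.multivariate_normal(np.zeros(2), cov, size=M).T
        from scipy.stats import norm

        beta[0] = norm.cdf(z[0])
        beta[1] = norm.cdf(z[1])
        return beta
    raise ValueError(f"unknown beta distribution: {mode!r}")


def simulate_reference(
    beta_true: np.ndarray,
    depth_lambda: float,
    seed=None,
    cell_types: list[str] | None = None,
    sites: list[Site] | None = None,
) -> ReferencePanel:
    """Reference panel with Poisson depths and binomial methylated counts."""
    if depth_lambda < 0:
        raise ValueError("depth must be nonnegative")
    rng = _rng(seed)
    beta_true = np.asarray(beta_true, dtype=float)
    T, M = beta_true.shape
    D_Y = rng.poisson(depth_lambda, size=(T, M))
    Y = rng.binomial(D_Y, beta_true)
    return ReferencePanel(
        cell_types=cell_types or [f"celltype_{t + 1}" for t in range(T)],
        sites=sites or make_sites(M),
        Y=Y,
        D_Y=D_Y,
    )


def simulate_mixture(
    beta_true: np.ndarray,
    alpha_true: np.ndarray,
    depth_lambda: float,
    seed=None,
    samples: list[str] | None = None,
    sites: list[Site] | None = None,
) -> CfdnaSamples:
    """cfDNA mixture counts for N individuals.

    Per site, the D_X reads are split over cell types with one
    multinomial draw from the individual's proportions (equivalent to
    assigning each read independently), and each cell type's reads are
    methylated binomially at that cell type's true proportion.
    """
    if depth_lambda < 0:
        raise ValueError("depth must be nonnegative")
    rng = _rng(seed)
    beta_true = np.asarray(beta_true, dtype=float)
    alpha_true = np.atleast_2d(np.asarray(alpha_true, dtype=float))
    if not np.allclose(alpha_true.sum(axis=1), 1.0) or np.any(alpha_true < 0):
        raise ValueError("every true proportion row must lie on the simplex")
    N = alpha_true.shape[0]
    T, M = beta_true.shape
    X = np.zeros((N, M), dtype=np.int64)
    D_X = rng.poisson(depth_lambda, size=(N, M))
    for n in range(N):
        # reads_per_type[m, t]: multinomial split of this person's depth
        reads_per_type = rng.multinomial(D_X[n], alpha_true[n], size=M)
        X[n] = rng.binomial(reads_per_type, beta_true.T).sum(axis=1)
    return CfdnaSamples(
        samples=samples or [f"sample_{n + 1}" for n in range(N)],
        sites=sites or make_sites(M),
        X=X,
        D_X=D_X,
    )


def simulate_dataset(
    scenario: SimScenario, alpha_true: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, ReferencePanel, CfdnaSamples]:
    """Full data set from one scenario: (beta, alpha, panel, samples)."""
    beta_rng, ref_rng, mix_rng, prop_rng = _streams(scenario.seed, 4)
    beta = draw_betas(scenario, seed=beta_rng)
    if alpha_true is None:
        if scenario.alpha_design == "triangular":
            alpha_true = np.tile(triangular_proportions(scenario.T), (scenario.N, 1))
        elif scenario.alpha_design == "uniform":
            alpha_true = uniform_proportions(scenario.T, prop_rng, size=scenario.N)
        else:
            raise ValueError(
                f"alpha design {scenario.alpha_design!r} needs an explicit alpha_true"
            )
    sites = make_sites(scenario.M)
    panel = simulate_reference(beta, scenario.reference_depth_lambda, ref_rng, sites=sites)
    mixture = simulate_mixture(beta, alpha_true, scenario.cfdna_depth_lambda, mix_rng, sites=sites)
    return beta, np.atleast_2d(alpha_true), panel, mixture


def case_control_scenario(
    fixed_pct: float,
    n_cases: int = 5,
    n_controls: int = 5,
    T: int = 10,
    M: int = 1000,
    depth: float = 5.0,
    seed=None,
) -> tuple[np.ndarray, np.ndarray, ReferencePanel, CfdnaSamples]:
    """A small rare-cell-type case/control cohort.

    Cases carry the cell type of interest (index 0) at exactly
    ``fixed_pct`` of their cfDNA; controls carry none of it.  All other
    proportions are uniform draws rescaled to fill the remainder.
    Returns (beta_true, alpha_true, panel, samples) with cases first.
    """
    if not 0.0 <= fixed_pct <= 1.0:
        raise ValueError("fixed proportion must be in [0, 1]")
    beta_rng, ref_rng, mix_rng, prop_rng = _streams(seed, 4)
    beta = beta_rng.uniform(size=(T, M))
    rows = []
    for _ in range(n_cases):
        rows.append(sweep_proportions(T, fixed_pct, prop_rng))
    for _ in range(n_controls):
        rows.append(sweep_proportions(T, 0.0, prop_rng))
    alpha = np.array(rows)
    sites = make_sites(M)
    names = [f"case_{i + 1}" for i in range(n_cases)] + [
        f"control_{i + 1}" for i in range(n_controls)
    ]
    panel = simulate_reference(beta, depth, ref_rng, sites=sites)
    mixture = simulate_mixture(beta, alpha, depth, mix_rng, samples=names, sites=sites)
    return beta, alpha, panel, mixture


def unknown_scenario(
    n_people: int,
    mask: list[int] | None = None,
    mu_sigma: list[tuple[float, float]] | None = None,
    T: int = 10,
    M: int = 1000,
    depth: float = 10.0,
    seed=None,
) -> tuple[np.ndarray, np.ndarray, ReferencePanel, CfdnaSamples]:
    """Mixtures containing cell types absent from the returned panel.

    ``mask`` lists the indices of cell types to remove from the reference
    (their rows stay in the returned truth).  Each masked type's
    proportion is drawn per person from a normal truncated to [0, 1]
    with the matching (mu, sigma) in ``mu_sigma`` (default (0.2, 0.1)
    for one unknown, then (0.1, 0.1) for a second).  The known types
    share the remaining mass in uniform-draw ratios.

    Returns (beta_true, alpha_true, masked_panel, samples); truth
    matrices keep all T cell types in original order.
    """
    mask = list(mask or [])
    if len(mask) > T:
        raise ValueError("cannot mask more cell types than exist")
    if mu_sigma is None:
        defaults = [(0.2, 0.1), (0.1, 0.1)]
        mu_sigma = [defaults[min(i, 1)] for i in range(len(mask))]
    beta_rng, ref_rng, mix_rng, prop_rng = _streams(seed, 4)
    beta = beta_rng.uniform(size=(T, M))

    alpha = np.zeros((n_people, T))
    unknown_total = np.zeros(n_people)
    for idx, (mu, sigma) in zip(mask, mu_sigma):
        draw = truncated_normal(mu, sigma, n_people, prop_rng)
        alpha[:, idx] = draw
        unknown_total += draw
    # if the masked draws overshoot a person's budget, rescale them back
    over = np.where(unknown_total > 1.0)[0]
    if over.size:
        alpha[np.ix_(over, mask)] /= unknown_total[over, None]
        unknown_total[over] = 1.0
    known = [t for t in range(T) if t not in mask]
    raw = prop_rng.uniform(size=(n_people, len(known)))
    raw = raw / raw.sum(axis=1, keepdims=True) * (1.0 - unknown_total)[:, None]
    alpha[:, known] = raw

    sites = make_sites(M)
    panel_full = simulate_reference(beta, depth, ref_rng, sites=sites)
    masked_names = [panel_full.cell_types[t] for t in mask]
    panel = panel_full.drop_cell_types(masked_names)
    mixture = simulate_mixture(beta, alpha, depth, mix_rng, sites=sites)
    return beta, alpha, panel, mixture
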