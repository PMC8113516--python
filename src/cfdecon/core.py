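"""Core containers for count-based methylation deconvolution.

The data model mirrors how strand-merged CpG calls come off a WGBS
pipeline: for every genomic site we keep a pair of integers, the number
of methylated reads and the total read depth.  A reference panel holds
one such pair per cell type and site (T x M), and a cfDNA data set holds
one pair per individual and site (N x M).  Read-level methylation states
are never stored -- the count pair is their sufficient statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Site",
    "ReferencePanel",
    "CfdnaSamples",
    "Responsibilities",
    "DecompositionResult",
    "TimTable",
    "SimScenario",
    "DataError",
    "harmonize",
]


class DataError(ValueError):
    """Raised when counts violate their structural bounds."""


@dataclass(frozen=True, order=True)
class Site:
    """A genomic interval in 0-based, half-open coordinates.

    Strand is intentionally absent: CpG calls are assumed to be
    strand-merged upstream, so one record covers both strands.
    """

    chrom: str
    start: int
    end: int

    def as_tuple(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def _check_counts(meth: np.ndarray, depth: np.ndarray, row_labels: Sequence[str], kind: str) -> None:
    if meth.shape != depth.shape:
        raise DataError(f"{kind}: methylated and depth matrices differ in shape "
                        f"{meth.shape} vs {depth.shape}")
    if np.any(meth < 0) or np.any(depth < 0):
        raise DataError(f"{kind}: negative counts are not allowed")
    bad = meth > depth
    if np.any(bad):
        t, m = np.argwhere(bad)[0]
        raise DataError(
            f"{kind}: methylated count exceeds depth for '{row_labels[t]}' at site index {m} "
            f"({meth[t, m]} > {depth[t, m]})"
        )


@dataclass
class ReferencePanel:
    """Per-cell-type methylated/total read counts at M CpG sites.

    An *unknown* cell type is represented as an all-zero row in both
    matrices; its methylation profile is then estimated from the cfDNA
    alone during decomposition.
    """

    cell_types: list[str]
    sites: list[Site]
    Y: np.ndarray      # T x M methylated counts
    D_Y: np.ndarray    # T x M total depths

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y)
        self.D_Y = np.asarray(self.D_Y)
        T, M = len(self.cell_types), len(self.sites)
        if self.Y.shape != (T, M):
            raise DataError(f"panel matrices must be {T}x{M}, got {self.Y.shape}")
        _check_counts(self.Y, self.D_Y, self.cell_types, "reference panel")

    @property
    def n_cell_types(self) -> int:
        return len(self.cell_types)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def is_unknown(self) -> np.ndarray:
        """Boolean mask of all-zero (unknown) rows."""
        return (self.D_Y.sum(axis=1) == 0) & (self.Y.sum(axis=1) == 0)

    def methylation_proportions(self) -> np.ndarray:
        """Y / D_Y with NaN where depth is zero."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.D_Y > 0, self.Y / np.maximum(self.D_Y, 1), np.nan)

    def subset_sites(self, idx: np.ndarray) -> "ReferencePanel":
        return ReferencePanel(
            cell_types=list(self.cell_types),
            sites=[self.sites[i] for i in idx],
            Y=self.Y[:, idx].copy(),
            D_Y=self.D_Y[:, idx].copy(),
        )

    def drop_cell_types(self, names: Sequence[str]) -> "ReferencePanel":
        keep = [i for i, c in enumerate(self.cell_types) if c not in set(names)]
        return ReferencePanel(
            cell_types=[self.cell_types[i] for i in keep],
            sites=list(self.sites),
            Y=self.Y[keep].copy(),
            D_Y=self.D_Y[keep].copy(),
        )


@dataclass
class CfdnaSamples:
    """Methylated/total cfDNA read counts for N individuals at M sites.

    A zero depth encodes a missing observation; the methylated count is
    defined to be zero there as well.
    """

    samples: list[str]
    sites: list[Site]
    X: np.ndarray      # N x M methylated counts
    D_X: np.ndarray    # N x M total depths

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        self.D_X = np.asarray(self.D_X)
        N, M = len(self.samples), len(self.sites)
        if self.X.shape != (N, M):
            raise DataError(f"sample matrices must be {N}x{M}, got {self.X.shape}")
        _check_counts(self.X, self.D_X, self.samples, "cfDNA samples")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def methylation_proportions(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.D_X > 0, self.X / np.maximum(self.D_X, 1), np.nan)

    def subset_sites(self, idx: np.ndarray) -> "CfdnaSamples":
        return CfdnaSamples(
            samples=list(self.samples),
            sites=[self.sites[i] for i in idx],
            X=self.X[:, idx].copy(),
            D_X=self.D_X[:, idx].copy(),
        )


@dataclass
class Responsibilities:
    """E-step posteriors: p[n, t, m, j] is the probability that a read of
    methylation status j (0 = unmethylated, 1 = methylated) from sample n
    at site m originated from cell type t.  Each slice over t sums to 1.
    """

    p: np.ndarray  # N x T x M x 2


@dataclass
class DecompositionResult:
    """Output of one EM decomposition run."""

    alpha: np.ndarray             # N x T mixing proportions, rows on the simplex
    beta: np.ndarray              # T x M estimated methylation proportions
    loglik: float                 # observed-data log-likelihood of the winner
    restart_logliks: list[float]  # final log-likelihood of every restart
    n_iter: int                   # iterations used by the winning restart
    converged: bool
    cell_types: list[str] = field(default_factory=list)
    samples: list[str] = field(default_factory=list)


@dataclass
class TimTable:
    """Ranked tissue-informative markers.

    One row per (cell type, CpG): the score is the absolute distance of
    that cell type's methylation fraction from the across-type median at
    the CpG.  The same site may serve several cell types.
    """

    cell_types: list[str]
    sites: list[Site]
    scores: np.ndarray
    ranks: np.ndarray
    region_window: int = 250

    def __len__(self) -> int:
        return len(self.sites)


@dataclass
class SimScenario:
    """Declarative description of a simulation design.

    Holding every generator parameter plus a seed makes a data set
    bit-reproducible: the same scenario always yields identical counts.
    """

    T: int
    M: int
    N: int
    beta_distribution: str = "uniform"     # uniform | normal | correlated-pair
    beta_normal_mean: float = 0.5
    beta_normal_var: float = 0.1
    beta_pair_r: float = 1.0
    reference_depth_lambda: float = 10.0
    cfdna_depth_lambda: float = 10.0
    alpha_design: str = "triangular"       # triangular | uniform | fixed-sweep | ...
    n_unknowns_masked: int = 0
    seed: int = 0


def harmonize(
    panel: ReferencePanel, samples: CfdnaSamples
) -> tuple[ReferencePanel, CfdnaSamples, dict]:
    """Align a panel and a cfDNA data set on their common sites.

    Sites are matched by exact (chrom, start, end) identity, intersected,
    and put in identical sorted order on both sides.  Returns the aligned
    pair plus a report listing the sites dropped from each input.
    """
    panel_sites = {s.as_tuple(): i for i, s in enumerate(panel.sites)}
    sample_sites = {s.as_tuple(): i for i, s in enumerate(samples.sites)}
    common = sorted(set(panel_sites) & set(sample_sites))
    if not common:
        raise DataError("panel and samples share no sites")
    dropped_panel = sorted(set(panel_sites) - set(common))
    dropped_samples = sorted(set(sample_sites) - set(common))
    p_idx = np.array([panel_sites[s] for s in common], dtype=int)
    s_idx = np.array([sample_sites[s] for s in common], dtype=int)
    report = {
        "n_common": len(common),
        "dropped_from_panel": [Site(*s) for s in dropped_panel],
        "dropped_from_samples": [Site(*s) for s in dropped_samples],
    }
    if dropped_panel or dropped_samples:
        warnings.warn(
            f"harmonize: dropped {len(dropped_panel)} panel site(s) and "
            f"{len(dropped_samples)} sample site(s) absent from the other input"
        )
    return panel.subset_sites(p_idx), samples.subset_sites(s_idx), report
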