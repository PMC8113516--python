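"""Tissue-informative marker (TIM) selection and region summing.

A TIM for a cell type is a CpG whose methylation fraction in that cell
type lies far from the across-type median at that CpG — an uncurated
analogue of ancestry-informative markers.  Because methylation of
nearby CpGs is correlated, counts from CpGs within a fixed window
around each TIM are pooled into a single region to stabilize the
methylation signal.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np

from .core import CfdnaSamples, DataError, ReferencePanel, Site, TimTable

__all__ = ["compute_tims", "sum_regions"]


def compute_tims(
    panel: ReferencePanel,
    n_per_celltype: int = 100,
    min_median_depth: float = 15.0,
    exclude_sites: Sequence[Site] | None = None,
    region_window: int = 250,
) -> TimTable:
    """Select the top-N most informative CpGs per cell type.

    Per CpG and cell type, score = |methylation fraction of the cell
    type - across-type median fraction|.  CpGs are eligible only when
    the across-type median depth strictly exceeds ``min_median_depth``,
    every cell type has nonzero depth there (no missing data), and the
    site is not excluded.  The highest-scoring ``n_per_celltype`` CpGs
    per cell type are kept; one CpG may serve several cell types.  Ties
    at the cutoff break by genomic order for determinism.
    """
    if panel.n_cell_types < 2:
        raise DataError("TIM selection needs at least two cell types")
    depths = panel.D_Y
    eligible = (np.median(depths, axis=0) > min_median_depth) & np.all(depths > 0, axis=0)
    if exclude_sites:
        excluded = {s.as_tuple() for s in exclude_sites}
        eligible &= np.array([s.as_tuple() not in excluded for s in panel.sites])
    if not np.any(eligible):
        warnings.warn("no CpGs pass the TIM depth/missingness filters; empty table")
        return TimTable(cell_types=[], sites=[], scores=np.array([]),
                        ranks=np.array([], dtype=int), region_window=region_window)

    idx = np.where(eligible)[0]
    frac = panel.Y[:, idx] / depths[:, idx]
    dist = np.abs(frac - np.median(frac, axis=0))  # T x M_eligible

    out_ct: list[str] = []
    out_sites: list[Site] = []
    out_scores: list[float] = []
    out_ranks: list[int] = []
    genomic_order = np.array([(panel.sites[i].chrom, panel.sites[i].start) for i in idx],
                             dtype=object)
    for t, ct in enumerate(panel.cell_types):
        # sort by descending score, then genomic order for ties
        order = sorted(
            range(idx.size),
            key=lambda j: (-dist[t, j], genomic_order[j][0], genomic_order[j][1]),
        )[:n_per_celltype]
        for rank, j in enumerate(order, start=1):
            out_ct.append(ct)
            out_sites.append(panel.sites[idx[j]])
            out_scores.append(float(dist[t, j]))
            out_ranks.append(rank)
    return TimTable(
        cell_types=out_ct,
        sites=out_sites,
        scores=np.array(out_scores),
        ranks=np.array(out_ranks, dtype=int),
        region_window=region_window,
    )


def _unique_tim_sites(tims: TimTable) -> list[Site]:
    seen: dict[tuple, Site] = {}
    for s in tims.sites:
        seen.setdefault(s.as_tuple(), s)
    return sorted(seen.values())


def sum_regions(data, tims: TimTable, window: int | None = None):
    """Pool counts from all CpGs within +/-window bp of each TIM.

    For every distinct TIM site, methylated and total counts of all CpGs
    whose start lies in [tim.start - window, tim.start + window]
    (inclusive at both ends) on the same chromosome are summed, per cell
    type or per sample.  Windows of distinct TIMs are treated
    independently, so a CpG inside two windows contributes to both
    regions.  Returns an object of the input's type with one site per
    TIM region spanning the window.
    """
    window = tims.region_window if window is None else window
    sites = data.sites
    starts = np.array([s.start for s in sites])
    chroms = np.array([s.chrom for s in sites], dtype=object)
    order = np.lexsort((starts, chroms))
    if not np.array_equal(order, np.arange(len(sites))):
        warnings.warn("input sites were not sorted; sorting internally")

    if isinstance(data, ReferencePanel):
        meth, depth = data.Y, data.D_Y
    elif isinstance(data, CfdnaSamples):
        meth, depth = data.X, data.D_X
    else:
        raise TypeError("expected a ReferencePanel or CfdnaSamples")

    region_sites: list[Site] = []
    meth_cols: list[np.ndarray] = []
    depth_cols: list[np.ndarray] = []
    for tim in _unique_tim_sites(tims):
        member = (chroms == tim.chrom) & (starts >= tim.start - window) & (
            starts <= tim.start + window
        )
        if not member.any():
            continue
        region_sites.append(
            Site(tim.chrom, max(tim.start - window, 0), tim.start + window + 1)
        )
        meth_cols.append(meth[:, member].sum(axis=1))
        depth_cols.append(depth[:, member].sum(axis=1))

    meth_out = np.column_stack(meth_cols) if meth_cols else np.zeros((meth.shape[0], 0), dtype=int)
    depth_out = np.column_stack(depth_cols) if depth_cols else np.zeros((depth.shape[0], 0), dtype=int)
    if isinstance(data, ReferencePanel):
        return ReferencePanel(cell_types=list(data.cell_types), sites=region_sites,
                              Y=meth_out, D_Y=depth_out)
    return CfdnaSamples(samples=list(data.samples), sites=region_sites,
                        X=meth_out, D_X=depth_out)
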