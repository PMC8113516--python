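"""Reading and writing the package's text formats.

Count matrices travel as bedMethyl-like TSV: three coordinate columns
(chrom, start, end; 0-based half-open) followed by one
(methylated, depth) integer column pair per cell type or sample.  A '.'
encodes a missing observation and is read as the (0, 0) pair.  Files
ending in .gz are read and written transparently.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import CfdnaSamples, DataError, ReferencePanel, SimScenario, Site, TimTable

__all__ = [
    "read_methylation_tsv",
    "write_methylation_tsv",
    "combine_replicates",
    "write_tims_bed",
    "read_sites_bed",
    "write_proportions_tsv",
    "read_scenario_yaml",
    "write_metadata",
]


def _parse_count(value, line_no: int, col: str) -> int:
    if value == "." or (isinstance(value, float) and np.isnan(value)):
        return 0
    try:
        as_float = float(value)
    except (TypeError, ValueError):
        raise DataError(f"line {line_no}: non-numeric count in column '{col}': {value!r}")
    if as_float != int(as_float):
        raise DataError(f"line {line_no}: non-integer count in column '{col}': {value!r}")
    return int(as_float)


def read_methylation_tsv(path, kind: str = "panel"):
    """Read a count TSV as a ReferencePanel (kind='panel') or CfdnaSamples.

    The first row may be a header naming the entities as
    ``<label>_meth`` / ``<label>_depth`` pairs; without one, entities
    are labelled positionally.  Sites are sorted genomically on read.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    first = df.iloc[0]
    has_header = first.iloc[0].lower() in {"chrom", "chr", "chromosome"}
    if has_header:
        header = list(first)
        df = df.iloc[1:].reset_index(drop=True)
        labels = [h[: -len("_meth")] for h in header[3::2]]
    else:
        labels = [f"entity_{i + 1}" for i in range((df.shape[1] - 3) // 2)]
    if (df.shape[1] - 3) % 2 != 0 or df.shape[1] < 5:
        raise DataError(f"{path}: expected 3 coordinate columns plus (meth, depth) pairs")

    n_entities = (df.shape[1] - 3) // 2
    sites: list[Site] = []
    meth = np.zeros((n_entities, len(df)), dtype=np.int64)
    depth = np.zeros((n_entities, len(df)), dtype=np.int64)
    for m, (_, row) in enumerate(df.iterrows()):
        line_no = m + 1 + int(has_header)
        try:
            sites.append(Site(str(row.iloc[0]), int(row.iloc[1]), int(row.iloc[2])))
        except (TypeError, ValueError):
            raise DataError(f"line {line_no}: malformed coordinates {tuple(row.iloc[:3])}")
        for e in range(n_entities):
            mc = _parse_count(row.iloc[3 + 2 * e], line_no, f"{labels[e]}_meth")
            dc = _parse_count(row.iloc[4 + 2 * e], line_no, f"{labels[e]}_depth")
            if mc > dc:
                raise DataError(
                    f"line {line_no}: methylated count {mc} exceeds depth {dc} "
                    f"for '{labels[e]}'"
                )
            meth[e, m], depth[e, m] = mc, dc

    order = np.lexsort(([s.start for s in sites], [s.chrom for s in sites]))
    sites = [sites[i] for i in order]
    meth, depth = meth[:, order], depth[:, order]
    if kind == "panel":
        return ReferencePanel(cell_types=labels, sites=sites, Y=meth, D_Y=depth)
    if kind == "samples":
        return CfdnaSamples(samples=labels, sites=sites, X=meth, D_X=depth)
    raise ValueError(f"kind must be 'panel' or 'samples', got {kind!r}")


def write_methylation_tsv(obj, path) -> None:
    """Write a panel or sample set in the TSV dialect read back by
    :func:`read_methylation_tsv` (lossless round trip)."""
    if isinstance(obj, ReferencePanel):
        labels, meth, depth = obj.cell_types, obj.Y, obj.D_Y
    elif isinstance(obj, CfdnaSamples):
        labels, meth, depth = obj.samples, obj.X, obj.D_X
    else:
        raise TypeError("expected a ReferencePanel or CfdnaSamples")
    cols: dict[str, list] = {
        "chrom": [s.chrom for s in obj.sites],
        "start": [s.start for s in obj.sites],
        "end": [s.end for s in obj.sites],
    }
    for e, label in enumerate(labels):
        cols[f"{label}_meth"] = meth[e].tolist()
        cols[f"{label}_depth"] = depth[e].tolist()
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def combine_replicates(panels: list[ReferencePanel]) -> ReferencePanel:
    """Pool replicate panels of the same cell types by summing counts.

    Sites are intersected across replicates; counts at shared sites are
    added, so a cell type's pooled proportion is the read-weighted
    average of its replicates.
    """
    if not panels:
        raise ValueError("no panels given")
    if len(panels) == 1:
        return panels[0]
    cell_types = panels[0].cell_types
    for p in panels[1:]:
        if p.cell_types != cell_types:
            raise DataError("replicate panels must list identical cell types in order")
    common = set(s.as_tuple() for s in panels[0].sites)
    for p in panels[1:]:
        common &= set(s.as_tuple() for s in p.sites)
    if not common:
        raise DataError("replicate panels share no sites")
    ordered = sorted(common)
    Y = np.zeros((len(cell_types), len(ordered)), dtype=np.int64)
    D_Y = np.zeros_like(Y)
    for p in panels:
        lookup = {s.as_tuple(): i for i, s in enumerate(p.sites)}
        idx = np.array([lookup[s] for s in ordered])
        Y += p.Y[:, idx]
        D_Y += p.D_Y[:, idx]
    return ReferencePanel(
        cell_types=list(cell_types),
        sites=[Site(*s) for s in ordered],
        Y=Y,
        D_Y=D_Y,
    )


def write_tims_bed(tims: TimTable, path) -> None:
    """Write markers as 6-column BED-like TSV:
    chrom, start, end, cell_type, score, rank."""
    with open(path, "w") as fh:
        for site, ct, score, rank in zip(tims.sites, tims.cell_types, tims.scores, tims.ranks):
            fh.write(f"{site.chrom}\t{site.start}\t{site.end}\t{ct}\t{score:.6g}\t{rank}\n")


def read_sites_bed(path) -> list[Site]:
    """Read the first three columns of a BED file as exclusion sites."""
    sites = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            sites.append(Site(chrom, int(start), int(end)))
    return sites


def write_proportions_tsv(matrix: np.ndarray, row_labels, col_labels, path) -> None:
    """Write a labelled float matrix (e.g. alpha or beta) as TSV."""
    pd.DataFrame(matrix, index=row_labels, columns=col_labels).to_csv(
        path, sep="\t", float_format="%.8g"
    )


def read_scenario_yaml(path) -> SimScenario:
    """Load a declarative simulation scenario from a YAML mapping."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    fields = set(SimScenario.__dataclass_fields__)
    unknown = set(raw) - fields
    if unknown:
        raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
    return SimScenario(**raw)


def write_metadata(path, **params) -> None:
    """Sidecar JSON recording the parameters that produced an output."""
    with open(path, "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
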