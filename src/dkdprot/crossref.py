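"""Cross-study correlation, list overlap, and z-scaled clustering export.

Agreement with an external proteomics study is quantified by Spearman
rank-correlating per-protein mean normalized intensities (natural-log scale)
against the external study's reported means on the shared accessions, and by
the fraction of one protein list recovered in another.  For heatmap display,
selected rows are z-scaled and both rows and columns ordered by hierarchical
clustering (Euclidean distance, Ward linkage).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import spearmanr

from .io import MasterTable

logger = logging.getLogger(__name__)

__all__ = ["spearman_external", "overlap_fraction", "zscale_cluster"]


def spearman_external(
    table: MasterTable,
    samples: Iterable[str],
    external: Mapping[str, float],
) -> float:
    """Spearman rho between ln mean normalized intensity and an external
    accession -> mean-intensity summary, over shared accessions."""
    samples = list(samples)
    means = table.data[samples].mean(axis=1, skipna=True)
    means = means[means.notna() & (means > 0)]
    shared = sorted(set(means.index) & set(external))
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared accessions (need >= 3)")
    internal = np.log(means.loc[shared].to_numpy())
    other = np.asarray([external[a] for a in shared], dtype=float)
    rho, _ = spearmanr(internal, other)
    return float(rho)


def overlap_fraction(a: Iterable[str], b: Iterable[str]) -> float:
    """|a intersect b| / |a|."""
    a, b = set(a), set(b)
    if not a:
        raise ValueError("reference set is empty")
    return len(a & b) / len(a)


def zscale_cluster(
    table: MasterTable, rows: Iterable[str]
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Z-scale selected rows and cluster rows and columns for a heatmap.

    Each row is standardized to mean 0, unit variance (n-1 denominator) over
    its detected entries; missing entries become 0 after scaling (logged).
    Returns the z-matrix plus row and column leaf orders from Ward linkage
    on Euclidean distances.
    """
    rows = list(rows)
    sub = table.data.loc[rows]
    n_det = sub.notna().sum(axis=1)
    short = n_det.index[n_det < 2]
    if len(short):
        raise ValueError(f"row {short[0]!r} has fewer than 2 detected values")
    sd = sub.std(axis=1, ddof=1, skipna=True)
    flat = sd.index[sd == 0]
    if len(flat):
        raise ValueError(f"constant row {flat[0]!r} has zero variance")
    z = sub.sub(sub.mean(axis=1, skipna=True), axis=0).div(sd, axis=0)
    n_missing = int(z.isna().to_numpy().sum())
    if n_missing:
        logger.info("zscale_cluster: %d missing entries set to 0 after scaling", n_missing)
    z = z.fillna(0.0)
    row_order = [z.index[i] for i in _leaf_order(z.to_numpy())]
    col_order = [z.columns[i] for i in _leaf_order(z.to_numpy().T)]
    return z, row_order, col_order


def _leaf_order(matrix: np.ndarray) -> np.ndarray:
    if matrix.shape[0] < 2:
        return np.arange(matrix.shape[0])
    return leaves_list(linkage(matrix, method="ward", metric="euclidean"))
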