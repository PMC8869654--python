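"""Per-sample ppm normalization and the group-wise presence filter.

Normalization rescales each sample's detected intensities to parts per
million of that sample's total, X' = X / sum(X_i) * 1e6, making columns
comparable regardless of total ion current.  The presence filter then keeps
only proteins detected in at least a given fraction (default 55%) of the
samples of at least one group, so that group summaries and rank tests rest on
a minimum of observed values.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Iterable

from .io import GroupDesign, MasterTable

logger = logging.getLogger(__name__)

PPM_SCALE = 1e6
DEFAULT_PRESENCE_THRESHOLD = 0.55


def normalize_ppm(table: MasterTable) -> MasterTable:
    """Rescale every sample column to parts-per-million of its detected total.

    Missing entries stay missing and do not contribute to the per-sample sum.
    Raises if the table is already normalized or a sample has no detected
    protein.
    """
    if table.normalized:
        raise ValueError("table is already normalized")
    sums = table.data.sum(axis=0, skipna=True)
    empty = sums.index[(sums <= 0) | (table.data.notna().sum(axis=0) == 0)]
    if len(empty):
        raise ValueError(f"sample {empty[0]!r} has no detected proteins")
    data = table.data.div(sums, axis=1) * PPM_SCALE
    return replace(table, data=data, normalized=True)


def presence_filter(
    table: MasterTable,
    design: GroupDesign,
    threshold: float = DEFAULT_PRESENCE_THRESHOLD,
    groups: Iterable[str] | None = None,
) -> MasterTable:
    """Keep proteins detected in >= ``threshold`` of the samples of >=1 group.

    ``groups`` restricts the evaluation to the named groups (default: all
    groups of the design), which is how a per-comparison filter over the two
    compared groups is expressed.  The fraction test is exact: 4 of 7 samples
    (0.571) passes a 0.55 threshold, 3 of 7 (0.429) does not.  Columns are
    never dropped.
    """
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must be in [0,1], got {threshold}")
    names = list(groups) if groups is not None else list(design.groups)
    if not names:
        raise ValueError("no groups given")
    design.validate_against(table)
    keep = None
    for name in names:
        samples = list(design.samples(name))  # KeyError -> unknown group
        frac = table.data[samples].notna().sum(axis=1) / len(samples)
        ok = frac >= threshold
        keep = ok if keep is None else (keep | ok)
    kept = table.data.index[keep]
    dropped = len(table.data) - len(kept)
    if dropped:
        logger.info("presence filter removed %d of %d proteins", dropped, len(table.data))
    return replace(table, data=table.data.loc[kept])
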