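"""Cross-stage consistency, aging correction and cross-tissue overlap.

A protein is *consistent* when it classifies in the same direction (up or
down) in both the early and the late disease comparison.  Because age-matched
control groups exist at both stages, an aging comparison (late controls vs
early controls) identifies proteins that change with age alone; these are
subtracted from the consistent set so the remainder reflects disease rather
than aging.  Finally, a consistent set from one tissue/model can be
intersected with a comparison from another (glomeruli vs kidney cortex) to
find proteins deregulated in the same direction in both.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .diffabund import DiffRecord, RatioSentinel

__all__ = ["ConsistentSet", "consistent_across", "aging_correction", "cross_overlap"]


@dataclass(frozen=True)
class ConsistentSet:
    """Proteins concordantly classified in two comparisons.

    ``up`` and ``down`` map accession -> (early record, late record).
    """

    up: dict[str, tuple[DiffRecord, DiffRecord]]
    down: dict[str, tuple[DiffRecord, DiffRecord]]
    provenance: tuple[str, str]
    aging_corrected: bool = False

    def __post_init__(self) -> None:
        overlap = set(self.up) & set(self.down)
        if overlap:
            raise ValueError(f"proteins both up and down: {sorted(overlap)}")

    @property
    def accessions(self) -> set[str]:
        return set(self.up) | set(self.down)

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


def consistent_across(
    early: list[DiffRecord],
    late: list[DiffRecord],
    provenance: tuple[str, str] = ("early", "late"),
) -> ConsistentSet:
    """Proteins classified up in both comparisons, or down in both.

    Proteins absent from either comparison (e.g. removed by that
    comparison's presence filter) cannot be consistent and are excluded.
    """
    early_by = {r.accession: r for r in early}
    late_by = {r.accession: r for r in late}
    up: dict[str, tuple[DiffRecord, DiffRecord]] = {}
    down: dict[str, tuple[DiffRecord, DiffRecord]] = {}
    for acc in early_by.keys() & late_by.keys():
        e, l = early_by[acc], late_by[acc]
        if e.classification == "up" and l.classification == "up":
            up[acc] = (e, l)
        elif e.classification == "down" and l.classification == "down":
            down[acc] = (e, l)
    return ConsistentSet(up=up, down=down, provenance=provenance, aging_corrected=False)


def aging_correction(
    candidates: ConsistentSet,
    aging: list[DiffRecord],
    match_direction: bool = False,
) -> ConsistentSet:
    """Remove candidates that also change between the age-matched controls.

    By default any significant aging change (up or down) disqualifies a
    candidate; with ``match_direction`` only an aging change in the
    candidate's own direction does.
    """
    aging_by = {r.accession: r for r in aging if r.classification != "unchanged"}

    def keep(acc: str, direction: str) -> bool:
        r = aging_by.get(acc)
        if r is None:
            return True
        if match_direction:
            return r.classification != direction
        return False

    return replace(
        candidates,
        up={a: v for a, v in candidates.up.items() if keep(a, "up")},
        down={a: v for a, v in candidates.down.items() if keep(a, "down")},
        aging_corrected=True,
    )


def _fmt_ratio(ratio) -> str:
    return str(ratio) if isinstance(ratio, RatioSentinel) else repr(float(ratio))


def cross_overlap(reference: ConsistentSet, other: list[DiffRecord]) -> pd.DataFrame:
    """Proteins of ``reference`` deregulated the same way in another comparison.

    Returns a table with one row per protein whose classification in
    ``other`` matches its reference direction, carrying the ratios of all
    three comparisons and the shared direction.
    """
    other_by = {r.accession: r for r in other}
    rows = []
    for direction, members in (("up", reference.up), ("down", reference.down)):
        for acc, (e, l) in members.items():
            o = other_by.get(acc)
            if o is None or o.classification != direction:
                continue
            rows.append(
                {
                    "accession": acc,
                    "ratio_other": _fmt_ratio(o.ratio),
                    f"ratio_{reference.provenance[0]}": _fmt_ratio(e.ratio),
                    f"ratio_{reference.provenance[1]}": _fmt_ratio(l.ratio),
                    "direction": direction,
                }
            )
    cols = [
        "accession",
        "ratio_other",
        f"ratio_{reference.provenance[0]}",
        f"ratio_{reference.provenance[1]}",
        "direction",
    ]
    return pd.DataFrame(rows, columns=cols)
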