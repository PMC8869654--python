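#!/usr/bin/env python
"""Normalize, presence-filter and test each pair-wise comparison.

Reruns the deterministic simulation of 01, ppm-normalizes, then for each of
the four comparisons (early disease INS2 vs WT2, late disease INS4 vs WT4,
aging WT4 vs WT2, cortex model db/db vs db/dm) applies the 55% presence
filter over the two compared groups and the Mann-Whitney + fold-change
classification.  Writes one table per comparison.
"""

import sys
from pathlib import Path

from dkdprot import preprocess
from dkdprot.diffabund import differential_abundance
from dkdprot.pipeline import records_frame
from dkdprot.synthetic import generate_dataset, study_mirror_config

OUT = Path("results/02_differential")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1

COMPARISONS = [
    ("early", "INS2", "WT2"),
    ("late", "INS4", "WT4"),
    ("aging", "WT4", "WT2"),
    ("cortex", "dbdb", "dbdm"),
]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = study_mirror_config(seed=SEED)
    table, _ = generate_dataset(cfg)
    norm = preprocess.normalize_ppm(table)
    for label, case, control in COMPARISONS:
        flt = preprocess.presence_filter(norm, cfg.design, groups=[case, control])
        recs = differential_abundance(flt, case, control, cfg.design)
        frame = records_frame(recs)
        frame.to_csv(OUT / f"diff_{label}.tsv", sep="\t", index=False)
        n_up = (frame["classification"] == "up").sum()
        n_down = (frame["classification"] == "down").sum()
        print(f"{label} ({case} vs {control}): {len(frame)} proteins pass the filter, "
              f"{n_up} up, {n_down} down")


if __name__ == "__main__":
    main()
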