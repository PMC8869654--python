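#!/usr/bin/env python
"""Cross-stage consistent proteins, aging correction, cross-tissue overlap.

Intersects the early and late disease comparisons, subtracts proteins that
also change between the age-matched control groups, overlaps the corrected
set with the cortex comparison, and scores recovery against the simulation's
ground truth.
"""

import sys
from pathlib import Path

from dkdprot import preprocess
from dkdprot.consistency import aging_correction, consistent_across, cross_overlap
from dkdprot.diffabund import differential_abundance
from dkdprot.synthetic import generate_dataset, study_mirror_config

OUT = Path("results/03_consistency")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = study_mirror_config(seed=SEED)
    table, truth = generate_dataset(cfg)
    norm = preprocess.normalize_ppm(table)

    def comp(case, control):
        flt = preprocess.presence_filter(norm, cfg.design, groups=[case, control])
        return differential_abundance(flt, case, control, cfg.design)

    pre = consistent_across(comp("INS2", "WT2"), comp("INS4", "WT4"))
    post = aging_correction(pre, comp("WT4", "WT2"))
    overlap = cross_overlap(post, comp("dbdb", "dbdm"))
    overlap.to_csv(OUT / "cross_overlap.tsv", sep="\t", index=False)

    expected = truth.expected("up", "INS2", "WT2") | truth.expected("down", "INS2", "WT2")
    clean = expected - truth.aging_confounded
    tp = post.accessions & expected
    print(f"candidates before aging correction: {len(pre)} "
          f"({len(pre.up)} up, {len(pre.down)} down)")
    print(f"after aging correction: {len(post)} ({len(post.up)} up, {len(post.down)} down)")
    print(f"aging-confounded spikes subtracted: "
          f"{len(truth.aging_confounded & (pre.accessions - post.accessions))} of "
          f"{len(truth.aging_confounded)}")
    print(f"truth recovery: {len(tp)}/{len(clean)} spiked proteins, "
          f"{len(post.accessions - expected)} false positives")
    print(f"cortex overlap: {len(overlap)} proteins concordant across tissues")


if __name__ == "__main__":
    main()
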