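#!/usr/bin/env python
"""Over-representation analysis of the recovered consistent proteins.

Builds a gene-set collection in which one module contains the down-spiked
proteins (a stand-in for a peroxisomal module), one the up-spiked proteins
(mitochondrial-like), and several random modules, then tests the recovered
aging-corrected consistent set against the background of proteins passing
the early-comparison presence filter.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from dkdprot import preprocess
from dkdprot.consistency import aging_correction, consistent_across
from dkdprot.diffabund import differential_abundance
from dkdprot.enrichment import enrich
from dkdprot.io import GeneSetCollection
from dkdprot.synthetic import generate_dataset, study_mirror_config

OUT = Path("results/04_enrichment")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = study_mirror_config(seed=SEED)
    table, truth = generate_dataset(cfg)
    norm = preprocess.normalize_ppm(table)

    def comp(case, control):
        flt = preprocess.presence_filter(norm, cfg.design, groups=[case, control])
        return flt, differential_abundance(flt, case, control, cfg.design)

    early_table, early = comp("INS2", "WT2")
    _, late = comp("INS4", "WT4")
    _, aging = comp("WT4", "WT2")
    cs = aging_correction(consistent_across(early, late), aging)

    background = set(early_table.accessions)
    rng = np.random.default_rng(SEED)
    sets = {
        "down_module": ("down-spiked proteins",
                        frozenset(truth.expected("down", "INS2", "WT2"))),
        "up_module": ("up-spiked proteins",
                      frozenset(truth.expected("up", "INS2", "WT2"))),
    }
    for i in range(5):
        members = rng.choice(sorted(background), size=25, replace=False)
        sets[f"random_{i}"] = ("random module", frozenset(members))
    collection = GeneSetCollection(sets=sets)

    records = enrich(cs.accessions & background, background, collection)
    frame = pd.DataFrame([r.__dict__ for r in records]).drop(columns="members_hit")
    frame.to_csv(OUT / "enrichment.tsv", sep="\t", index=False)
    for r in records:
        flag = "significant" if r.significant else "not significant"
        print(f"{r.set_name}: k={r.k}/K={r.K}, adjusted p={r.p_adjusted:.3g} ({flag})")


if __name__ == "__main__":
    main()
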