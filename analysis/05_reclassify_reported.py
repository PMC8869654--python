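#!/usr/bin/env python
"""Re-derive the reported consistent-set sizes from the bundled tables.

Applies the classification thresholds (p <= 0.05, ratio >= 1.5 up /
<= 0.67 down, "only in wt" = down) and the cross-stage consistency rule to
the transcribed reference tables of glomerular proteins, and the
down-threshold to the cortex/glomeruli overlap ratios.
"""

from pathlib import Path

from dkdprot.pipeline import bundled_table, reclassify_table

OUT = Path("results/05_reclassify")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    up_counts, up_calls = reclassify_table(bundled_table("glomerular_consistent_up.tsv"))
    down_counts, down_calls = reclassify_table(bundled_table("glomerular_consistent_down.tsv"))
    cortex_counts, cortex_calls = reclassify_table(bundled_table("cortex_glomerular_overlap.tsv"))
    up_calls.to_csv(OUT / "up_calls.tsv", sep="\t", index=False)
    down_calls.to_csv(OUT / "down_calls.tsv", sep="\t", index=False)
    cortex_calls.to_csv(OUT / "cortex_calls.tsv", sep="\t", index=False)
    print(f"glomerular consistently up: {up_counts.up} (discordant {up_counts.discordant})")
    print(f"glomerular consistently down: {down_counts.down} (discordant {down_counts.discordant})")
    print(f"total consistent: {up_counts.total + down_counts.total}")
    print(f"cortex/glomeruli concordantly down: {cortex_counts.down}")


if __name__ == "__main__":
    main()
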