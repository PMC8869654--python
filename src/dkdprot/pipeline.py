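"""Configuration-driven orchestration of the full analysis workflow.

``run_pipeline`` ties the stages together the way the study ran them:
assemble (or simulate) a master table, ppm-normalize, presence-filter per
pair-wise comparison, test each comparison, intersect the early and late
disease comparisons, subtract the aging comparison, optionally overlap with
a second-tissue comparison, run over-representation analysis, and write
every result as a TSV plus a run log.  ``reclassify_table`` re-applies the
classification and consistency rules to a transcribed result table carrying
printed p-value/ratio columns.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, consistency, crossref, enrichment, preprocess, synthetic
from .diffabund import (
    DiffRecord,
    RatioSentinel,
    Thresholds,
    classify,
    differential_abundance,
)
from .io import (
    GroupDesign,
    MasterTable,
    build_master_table,
    read_gene_sets,
    read_group_design,
    read_quant_report,
    write_master_table,
)

__all__ = [
    "PipelineConfigError",
    "ReclassifyCounts",
    "run_pipeline",
    "reclassify_table",
    "records_frame",
    "bundled_table",
]

_ONLY_IN_CONTROL_TOKENS = {"only in wt", "only_in_control", "only in control"}
_ONLY_IN_CASE_TOKENS = {"only_in_case", "only in case"}


class PipelineConfigError(ValueError):
    """A missing or inconsistent key in the run configuration."""


def bundled_table(name: str) -> Path:
    """Path to a reference table shipped with the package.

    Available: ``glomerular_consistent_up.tsv`` and
    ``glomerular_consistent_down.tsv`` (consistently deregulated glomerular
    proteins of the Ins2Akita DKD study, with printed per-stage p-values and
    ratios) and ``cortex_glomerular_overlap.tsv`` (proteins concordantly
    downregulated in db/db cortex and Ins2Akita glomeruli).
    """
    path = importlib.resources.files("dkdprot") / "data" / name
    return Path(str(path))


def records_frame(records: list[DiffRecord]) -> pd.DataFrame:
    """Tabular view of DiffRecords with sentinel ratios as text."""
    return pd.DataFrame(
        [
            {
                "accession": r.accession,
                "p_value": r.p_value,
                "ratio": str(r.ratio) if isinstance(r.ratio, RatioSentinel) else r.ratio,
                "mean_case": r.mean_case,
                "mean_control": r.mean_control,
                "n_detected_case": r.n_detected_case,
                "n_detected_control": r.n_detected_control,
                "classification": r.classification,
            }
            for r in records
        ],
        columns=[
            "accession", "p_value", "ratio", "mean_case", "mean_control",
            "n_detected_case", "n_detected_control", "classification",
        ],
    )


def _consistent_frame(cs: consistency.ConsistentSet) -> pd.DataFrame:
    rows = []
    for direction, members in (("up", cs.up), ("down", cs.down)):
        for acc, (e, l) in sorted(members.items()):
            rows.append(
                {
                    "accession": acc,
                    "direction": direction,
                    f"p_{cs.provenance[0]}": e.p_value,
                    f"ratio_{cs.provenance[0]}": str(e.ratio)
                    if isinstance(e.ratio, RatioSentinel) else e.ratio,
                    f"p_{cs.provenance[1]}": l.p_value,
                    f"ratio_{cs.provenance[1]}": str(l.ratio)
                    if isinstance(l.ratio, RatioSentinel) else l.ratio,
                }
            )
    return pd.DataFrame(rows)


def _load_inputs(config: dict):
    if "synthetic" in config:
        syn = dict(config["synthetic"])
        scenario = syn.pop("scenario", "custom")
        seed = config.get("seed", 0)
        if scenario == "recovery":
            cfg = synthetic.recovery_config(seed=seed, **syn)
        elif scenario == "null":
            cfg = synthetic.null_config(seed=seed, **syn)
        elif scenario == "study_mirror":
            cfg = synthetic.study_mirror_config(seed=seed, **syn)
        else:
            raise PipelineConfigError(f"unknown synthetic scenario {scenario!r}")
        table, truth = synthetic.generate_dataset(cfg)
        return table, cfg.design, truth
    if "reports" not in config or "design" not in config:
        raise PipelineConfigError("config needs either 'synthetic' or 'reports' + 'design'")
    reports = [
        read_quant_report(r["path"], r["sample_id"]) for r in config["reports"]
    ]
    table = build_master_table(reports)
    design = read_group_design(config["design"])
    return table, design, None


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Execute the workflow described by ``config`` and write the bundle.

    ``config`` is a mapping or a path to a YAML file.  Returns a dict of the
    in-memory results keyed like the files written.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    out = Path(out_dir or config.get("output_dir", "results/pipeline"))
    out.mkdir(parents=True, exist_ok=True)

    comparisons = config.get("comparisons") or []
    if not comparisons:
        raise PipelineConfigError("config lists no comparisons")

    thr = Thresholds(**config.get("thresholds", {}))
    presence = float(config.get("presence_threshold", preprocess.DEFAULT_PRESENCE_THRESHOLD))
    filter_scope = config.get("filter_scope", "per_comparison")
    if filter_scope not in ("per_comparison", "global"):
        raise PipelineConfigError(f"unknown filter_scope {filter_scope!r}")

    table, design, truth = _load_inputs(config)
    design.validate_against(table)
    write_master_table(table, out / "master_raw.tsv")
    normalized = preprocess.normalize_ppm(table)

    results: dict = {"table": normalized, "design": design, "truth": truth}
    diffs: dict[str, list[DiffRecord]] = {}
    filtered: dict[str, MasterTable] = {}
    if filter_scope == "global":
        global_filtered = preprocess.presence_filter(normalized, design, presence)
    for comp in comparisons:
        try:
            case, control, label = comp["case"], comp["control"], comp["label"]
        except KeyError as e:
            raise PipelineConfigError(f"comparison missing key {e}") from None
        if filter_scope == "per_comparison":
            flt = preprocess.presence_filter(
                normalized, design, presence, groups=[case, control]
            )
        else:
            flt = global_filtered
        recs = differential_abundance(flt, case, control, design, thr)
        diffs[label] = recs
        filtered[label] = flt
        records_frame(recs).to_csv(out / f"diff_{label}.tsv", sep="\t", index=False)
    results["diff"] = diffs

    cons_cfg = config.get("consistency")
    if cons_cfg is None and len(comparisons) >= 2:
        cons_cfg = {
            "early": comparisons[0]["label"],
            "late": comparisons[1]["label"],
        }
    if cons_cfg:
        early_l, late_l = cons_cfg["early"], cons_cfg["late"]
        cs = consistency.consistent_across(
            diffs[early_l], diffs[late_l], provenance=(early_l, late_l)
        )
        _consistent_frame(cs).to_csv(out / "consistent_pre_aging.tsv", sep="\t", index=False)
        results["consistent_pre"] = cs
        aging_cfg = config.get("aging")
        if aging_cfg:
            flt = preprocess.presence_filter(
                normalized, design, presence,
                groups=[aging_cfg["case"], aging_cfg["control"]],
            )
            aging_recs = differential_abundance(
                flt, aging_cfg["case"], aging_cfg["control"], design, thr
            )
            records_frame(aging_recs).to_csv(out / "diff_aging.tsv", sep="\t", index=False)
            cs = consistency.aging_correction(
                cs, aging_recs,
                match_direction=bool(aging_cfg.get("match_direction", False)),
            )
            _consistent_frame(cs).to_csv(out / "consistent_post_aging.tsv", sep="\t", index=False)
            results["consistent_post"] = cs

        cross_label = config.get("cross")
        if cross_label:
            overlap = consistency.cross_overlap(cs, diffs[cross_label])
            overlap.to_csv(out / "cross_overlap.tsv", sep="\t", index=False)
            results["cross_overlap"] = overlap

        if config.get("gene_sets"):
            sets = read_gene_sets(config["gene_sets"])
            background = set(filtered[early_l].accessions)
            query = cs.accessions & background
            enr = enrichment.enrich(query, background, sets, alpha=thr.alpha)
            pd.DataFrame([asdict(r) for r in enr]).to_csv(
                out / "enrichment.tsv", sep="\t", index=False
            )
            results["enrichment"] = enr

        if config.get("heatmap", True) and cs.accessions:
            early_c = next(c for c in comparisons if c["label"] == early_l)
            late_c = next(c for c in comparisons if c["label"] == late_l)
            cols = []
            for g in (early_c["control"], early_c["case"], late_c["control"], late_c["case"]):
                cols.extend(design.samples(g))
            sub = normalized.data.loc[sorted(cs.accessions), cols]
            ok = sub.notna().sum(axis=1) >= 2
            ok &= sub.std(axis=1, ddof=1, skipna=True) > 0
            view = MasterTable(data=normalized.data[cols], normalized=True)
            z, row_order, col_order = crossref.zscale_cluster(view, sub.index[ok])
            z.loc[row_order, col_order].to_csv(out / "zmatrix.tsv", sep="\t")
            results["heatmap"] = (z, row_order, col_order)

    if config.get("external"):
        ext = pd.read_csv(config["external"], sep="\t", index_col=0).iloc[:, 0].to_dict()
        rho = crossref.spearman_external(normalized, normalized.sample_ids, ext)
        results["spearman_external"] = rho

    log = {
        "version": __version__,
        "seed": config.get("seed", 0),
        "thresholds": asdict(thr),
        "presence_threshold": presence,
        "filter_scope": filter_scope,
        "comparisons": [dict(c) for c in comparisons],
        "aging": config.get("aging"),
        "n_samples": len(normalized.sample_ids),
        "n_proteins_raw": len(table.accessions),
    }
    if "spearman_external" in results:
        log["spearman_external"] = float(results["spearman_external"])
    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=True)
    return results


@dataclass(frozen=True)
class ReclassifyCounts:
    up: int
    down: int
    discordant: int

    @property
    def total(self) -> int:
        return self.up + self.down


def _parse_ratio_cell(cell, row_label: str):
    text = str(cell).strip().lower()
    if text in _ONLY_IN_CONTROL_TOKENS:
        return RatioSentinel.ONLY_IN_CONTROL
    if text in _ONLY_IN_CASE_TOKENS:
        return RatioSentinel.ONLY_IN_CASE
    try:
        return float(cell)
    except (TypeError, ValueError):
        raise ValueError(f"row {row_label!r}: unparsable ratio {cell!r}") from None


def reclassify_table(
    path, thr: Thresholds = Thresholds(), id_col: str | None = None
) -> tuple[ReclassifyCounts, pd.DataFrame]:
    """Re-apply classification and consistency rules to a transcribed table.

    The table carries one or more comparisons as column pairs ``pval_X`` /
    ``ratio_X`` (matched by suffix); a ``ratio_Y`` column without a matching
    p-value column is classified on the ratio thresholds alone.  "only in
    wt" ratio cells are the detected-only-in-control sentinel.  Returns the
    counts of rows consistently up / down / discordant across all
    comparisons, plus the per-row classification table.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if id_col is None:
        id_col = df.columns[0]
    ratio_cols = {c[len("ratio_"):]: c for c in df.columns if c.lower().startswith("ratio_")}
    pval_cols = {c[len("pval_"):]: c for c in df.columns if c.lower().startswith("pval_")}
    if not ratio_cols:
        raise ValueError(f"{path}: no ratio_* columns found")
    up = down = discordant = 0
    out_rows = []
    for _, row in df.iterrows():
        label = row[id_col]
        calls = []
        rec = {"id": label}
        for suffix, rcol in ratio_cols.items():
            ratio = _parse_ratio_cell(row[rcol], label)
            if suffix in pval_cols:
                try:
                    p = float(row[pval_cols[suffix]])
                except (TypeError, ValueError):
                    raise ValueError(
                        f"row {label!r}: unparsable p-value {row[pval_cols[suffix]]!r}"
                    ) from None
                call = classify(p, ratio, thr)
            else:  # ratio-only comparison
                if ratio is RatioSentinel.ONLY_IN_CASE or (
                    not isinstance(ratio, RatioSentinel) and ratio >= thr.up_cut
                ):
                    call = "up"
                elif ratio is RatioSentinel.ONLY_IN_CONTROL or (
                    not isinstance(ratio, RatioSentinel) and ratio <= thr.down_cut
                ):
                    call = "down"
                else:
                    call = "unchanged"
            calls.append(call)
            rec[f"call_{suffix}"] = call
        if all(c == "up" for c in calls):
            up += 1
            rec["consistent"] = "up"
        elif all(c == "down" for c in calls):
            down += 1
            rec["consistent"] = "down"
        else:
            discordant += 1
            rec["consistent"] = "discordant"
        out_rows.append(rec)
    return ReclassifyCounts(up=up, down=down, discordant=discordant), pd.DataFrame(out_rows)
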