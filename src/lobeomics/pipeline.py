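"""End-to-end orchestration of the analysis stages over a fixture bundle.

Each stage is a pure function of (input files, config, seed): identical
inputs give byte-identical outputs. A JSON manifest records the seeds and
parameter echo of every completed run.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as lio
from .chromatin import (
    RegionSignal,
    promoter_comparison,
    promoter_fraction,
    shift_types_for_comparison,
    spikein_factors,
)
from .concordance import adegs_to_frame, find_adegs, overlap_with_labels
from .diff import COMPARISONS, ComparisonResult, ComparisonSpec, run_all_comparisons
from .enrichment import (
    gated_t_matrix,
    gsea_nes,
    qc_filter,
    rank_genes,
    score_matrix,
    signature_score,
    stratify,
)
from .io import CountMatrix, SampleSheet
from .simulate import write_fixture_bundle
from .trends import (
    TrendRuleTable,
    assign_trends,
    default_rule_table,
    intersection_table,
    shared_specific,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and parameters of one pipeline run."""

    data_dir: str
    out_dir: str
    alpha: float = 0.05
    focus_label: str = "Rein02"
    promoter_window: tuple[int, int] = (-3000, 3000)
    gsea_n_perm: int = 200
    gsea_comparison: str = "MvG"
    gsea_lobe: str = "L"
    seed: int = 0
    rule_table: str | None = None  # path; default table when None
    scale: str = "tiny"
    sc_focus_types: tuple[str, ...] = ("T",)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "promoter_window" in doc:
            doc["promoter_window"] = tuple(doc["promoter_window"])
        if "sc_focus_types" in doc:
            doc["sc_focus_types"] = tuple(doc["sc_focus_types"])
        return cls(**doc)

    def validate(self, need_bundle: bool = True) -> None:
        data = Path(self.data_dir)
        if need_bundle:
            required = [
                "sample_sheet.csv", "bulk_counts.tsv", "chrom_sample_sheet.csv",
                "chrom_promoter_counts.tsv", "chrom_other_counts.tsv",
                "gene_sets.gmt", "sc_matrix.tsv", "sc_cells.tsv", "sc_gene_sets.gmt",
            ]
            missing = [f for f in required if not (data / f).exists()]
            if missing:
                raise FileNotFoundError(
                    f"bundle at {data} is missing: {missing}"
                )
        if self.rule_table is not None and not Path(self.rule_table).exists():
            raise FileNotFoundError(f"rule table not found: {self.rule_table}")

    def load_rules(self) -> TrendRuleTable:
        if self.rule_table is not None:
            return TrendRuleTable.from_yaml(self.rule_table)
        bundled = Path(self.data_dir) / "rule_table.yaml"
        if bundled.exists():
            return TrendRuleTable.from_yaml(bundled)
        return default_rule_table()


def _log_stage(name: str, t0: float, **info) -> None:
    payload = " ".join(f"{k}={v}" for k, v in info.items())
    logger.info("stage=%s elapsed=%.2fs %s", name, time.monotonic() - t0, payload)


def _load_bulk(cfg: PipelineConfig) -> CountMatrix:
    data = Path(cfg.data_dir)
    sheet = SampleSheet.read_csv(data / "sample_sheet.csv")
    return lio.read_count_matrix(data / "bulk_counts.tsv", sheet)


def _load_chromatin(cfg: PipelineConfig) -> RegionSignal:
    data = Path(cfg.data_dir)
    sheet = SampleSheet.read_csv(data / "chrom_sample_sheet.csv")
    prom = lio.read_count_matrix(data / "chrom_promoter_counts.tsv", sheet)
    other = lio.read_count_matrix(data / "chrom_other_counts.tsv", sheet)
    return RegionSignal(prom.counts.astype(float), other.counts.astype(float), sheet)


def _result_path(out: Path, stage: str, lobe: str, comparison: str) -> Path:
    return out / stage / f"{lobe}_{comparison}.tsv"


def _write_comparison(res: ComparisonResult, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    lio.write_results_tsv(res.to_frame(), path)


def _read_comparison(path: Path) -> ComparisonResult:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    comparison = df["comparison"].iloc[0]
    lobe = str(df["lobe"].iloc[0])
    tab = df.set_index("gene_id")[["log2fc", "se", "p", "padj", "g"]]
    return ComparisonResult(tab, comparison, lobe)


# ---------------------------------------------------------------------------
# Stages


def cmd_simulate(cfg: PipelineConfig, force: bool = False) -> dict:
    t0 = time.monotonic()
    manifest = write_fixture_bundle(cfg.data_dir, scale=cfg.scale, seed=cfg.seed,
                                    force=force)
    _log_stage("simulate", t0, scale=cfg.scale, seed=cfg.seed)
    return manifest


def cmd_de(cfg: PipelineConfig) -> dict[tuple[str, str], ComparisonResult]:
    """Gated differential tables for all 4 comparisons x 5 lobes (RNA)."""
    t0 = time.monotonic()
    counts = _load_bulk(cfg)
    results = run_all_comparisons(counts, alpha=cfg.alpha)
    out = Path(cfg.out_dir)
    for (label, lobe), res in sorted(results.items()):
        _write_comparison(res, _result_path(out, "de", lobe, label))
    _log_stage("de", t0, n_tables=len(results), n_genes=len(counts.gene_ids))
    return results


def cmd_trend(cfg: PipelineConfig) -> dict:
    """Trend labels per lobe plus shared/specific sets of the focus label."""
    t0 = time.monotonic()
    out = Path(cfg.out_dir)
    rules = cfg.load_rules()
    lobes = sorted(
        {p.stem.rsplit("_", 1)[0] for p in (out / "de").glob("*.tsv")}
    )
    if not lobes:
        raise FileNotFoundError("no DE tables found; run the de stage first")
    label_sets: dict[str, set[str]] = {}
    (out / "trend").mkdir(parents=True, exist_ok=True)
    for lobe in lobes:
        results = {
            comp: _read_comparison(_result_path(out, "de", lobe, comp))
            for comp in COMPARISONS
        }
        assignment = assign_trends(results, lobe, rules=rules)
        lio.write_results_tsv(
            assignment.table.reset_index(), out / "trend" / f"{lobe}.tsv"
        )
        label_sets[lobe] = assignment.genes_with_label(cfg.focus_label)
    shared, specific, class_counts = shared_specific(label_sets)
    lio.write_results_tsv(
        intersection_table(class_counts, lobes), out / "trend" / "intersections.tsv"
    )
    summary = pd.DataFrame(
        [{"set_name": "shared", "n_genes": len(shared),
          "genes": ",".join(sorted(shared))}]
        + [
            {"set_name": f"{lb}_specific", "n_genes": len(specific[lb]),
             "genes": ",".join(sorted(specific[lb]))}
            for lb in lobes
        ]
    )
    summary.to_csv(out / "trend" / "shared_specific.tsv", sep="\t", index=False)
    _log_stage("trend", t0, label=cfg.focus_label, shared=len(shared))
    return {"shared": shared, "specific": specific, "class_counts": class_counts}


def cmd_chrom(cfg: PipelineConfig) -> dict:
    """Promoter fractions, promoter DE tables and shift types."""
    t0 = time.monotonic()
    out = Path(cfg.out_dir)
    signal = _load_chromatin(cfg)
    spike = signal.samples.table["spike_in_reads"]
    factors = spikein_factors(spike)
    scaled = signal.apply_spikein(factors)
    frac = promoter_fraction(scaled)
    (out / "chrom").mkdir(parents=True, exist_ok=True)
    frac.rename("promoter_fraction").reset_index().rename(
        columns={"index": "sample_id"}
    ).to_csv(out / "chrom" / "promoter_fraction.tsv", sep="\t", index=False,
             float_format="%.6g")

    lobes = sorted(signal.samples.table["lobe"].unique())
    groups_present = set(signal.samples.table["group"])
    n_prom_tables = 0
    for lobe in lobes:
        for label, (j, i) in sorted(COMPARISONS.items()):
            if j not in groups_present or i not in groups_present:
                continue
            spec = ComparisonSpec.from_label(label, lobe)
            res = promoter_comparison(signal, spec, alpha=cfg.alpha,
                                      spike_factors=factors)
            _write_comparison(res, _result_path(out, "chrom/prom_de", lobe, label))
            shifts = shift_types_for_comparison(signal, spec, alpha=cfg.alpha,
                                                spike_factors=factors)
            shift_path = _result_path(out, "chrom/shift", lobe, label)
            shift_path.parent.mkdir(parents=True, exist_ok=True)
            shifts.reset_index().to_csv(shift_path, sep="\t", index=False)
            n_prom_tables += 1
    _log_stage("chrom", t0, n_tables=n_prom_tables)
    return {"promoter_fraction": frac}


def cmd_adeg(cfg: PipelineConfig) -> dict:
    """a-DEGs per (comparison, lobe) present in both assays, plus overlaps."""
    t0 = time.monotonic()
    out = Path(cfg.out_dir)
    prom_dir = out / "chrom" / "prom_de"
    if not prom_dir.exists():
        raise FileNotFoundError("no promoter DE tables; run the chrom stage first")
    (out / "adeg").mkdir(parents=True, exist_ok=True)
    all_adegs = []
    for prom_path in sorted(prom_dir.glob("*.tsv")):
        lobe, label = prom_path.stem.rsplit("_", 1)
        rna_path = _result_path(out, "de", lobe, label)
        if not rna_path.exists():
            continue
        rna = _read_comparison(rna_path)
        prom = _read_comparison(prom_path)
        common = rna.table.index.intersection(prom.table.index)
        rna_sub = ComparisonResult(rna.table.loc[common], rna.comparison, rna.lobe)
        prom_sub = ComparisonResult(prom.table.loc[common], prom.comparison, prom.lobe)
        adegs = find_adegs(rna_sub, prom_sub)
        all_adegs.extend(adegs)
    frame = adegs_to_frame(all_adegs)
    lio.write_results_tsv(frame, out / "adeg" / "adegs.tsv")

    shared_path = out / "trend" / "shared_specific.tsv"
    overlaps = None
    if shared_path.exists():
        sets_tab = pd.read_csv(shared_path, sep="\t", keep_default_na=False)
        label_sets = {
            row["set_name"]: set(row["genes"].split(",")) - {""}
            for _, row in sets_tab.iterrows()
        }
        overlaps = overlap_with_labels(all_adegs, label_sets)
        lio.write_results_tsv(
            overlaps.drop(columns=["genes"]), out / "adeg" / "overlaps.tsv"
        )
    _log_stage("adeg", t0, n_adegs=len(all_adegs))
    return {"adegs": all_adegs, "overlaps": overlaps}


def cmd_enrich(cfg: PipelineConfig) -> dict:
    """Preranked GSEA on the focus DE table; single-cell QC, stratification
    and the gated-t matrix over the focus cell compartments."""
    t0 = time.monotonic()
    out = Path(cfg.out_dir)
    data = Path(cfg.data_dir)
    (out / "enrich").mkdir(parents=True, exist_ok=True)

    # bulk preranked GSEA
    sets = lio.read_gmt(data / "gene_sets.gmt")
    de_path = _result_path(out, "de", cfg.gsea_lobe, cfg.gsea_comparison)
    if not de_path.exists():
        raise FileNotFoundError(f"DE table {de_path} missing; run the de stage")
    ranked = rank_genes(_read_comparison(de_path))
    nes = gsea_nes(ranked, sets, n_perm=cfg.gsea_n_perm, seed=cfg.seed)
    nes.insert(1, "comparison", cfg.gsea_comparison)
    nes.insert(2, "lobe", cfg.gsea_lobe)
    lio.write_results_tsv(nes, out / "enrich" / "nes.tsv")

    # single cell: QC -> signature stratification -> gated t matrix
    matrix = pd.read_csv(data / "sc_matrix.tsv", sep="\t", index_col=0)
    cells = pd.read_csv(data / "sc_cells.tsv", sep="\t", index_col=0)
    cells = cells.loc[matrix.index]
    flagged = qc_filter(cells)
    kept = matrix.index[~flagged]
    sc_sets = lio.read_gmt(data / "sc_gene_sets.gmt")
    sig_genes = sc_sets["SIGNATURE"]
    sig = signature_score(matrix.loc[kept], sig_genes)
    strata = stratify(sig)
    pathway_sets = {name: genes for name, genes in sc_sets.items()
                    if name != "SIGNATURE"}
    focus = cells.loc[kept, "cell_type"].isin(cfg.sc_focus_types)
    focus_cells = kept[focus.to_numpy()]
    # score pathways on the matrix WITHOUT the stratifying signature genes:
    # selecting strata on the signature otherwise displaces every other
    # gene's within-cell rank and biases null pathways
    score_cols = [c for c in matrix.columns if c not in set(sig_genes)]
    scores = score_matrix(matrix.loc[focus_cells, score_cols], pathway_sets)
    gt = gated_t_matrix(
        scores, strata.loc[focus_cells], cells.loc[focus_cells, "cell_type"],
        alpha=cfg.alpha,
    )
    lio.write_results_tsv(gt, out / "enrich" / "gated_t.tsv")
    qc_tab = pd.DataFrame({"cell_id": matrix.index, "qc_flagged": flagged.to_numpy()})
    lio.write_results_tsv(qc_tab, out / "enrich" / "qc_flags.tsv")
    strata_tab = strata.reset_index().rename(columns={"index": "cell_id"})
    lio.write_results_tsv(strata_tab, out / "enrich" / "strata.tsv")
    _log_stage("enrich", t0, n_sets=len(sets), n_cells_kept=len(kept))
    return {"nes": nes, "gated_t": gt, "qc_flagged": flagged, "strata": strata}


def cmd_all(cfg: PipelineConfig, simulate: bool = False, force: bool = False) -> dict:
    """Run every stage in dependency order; write the run manifest."""
    t0 = time.monotonic()
    if simulate:
        cmd_simulate(cfg, force=force)
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cmd_de(cfg)
    cmd_trend(cfg)
    cmd_chrom(cfg)
    cmd_adeg(cfg)
    cmd_enrich(cfg)
    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "stages": ["de", "trend", "chrom", "adeg", "enrich"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _log_stage("all", t0)
    return manifest
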