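"""Seeded synthetic datasets with planted ground truth.

Generates the three data layers the study design needs — a 4-group
(control C, GVHD G, PBS P, hPMSC M) x 5-lobe x n-replicate bulk RNA count
table with planted trend-type genes, per-gene promoter/other H3K27ac
counts with planted shift types and spike-in reads, and a single-cell
matrix with cell types, marker genes, QC metrics and a planted signature
high/low axis — so every downstream stage is testable without the
deposited sequencing data.

Counts are negative-binomial with variance mu + phi * mu^2 (gamma-Poisson
mixture), matching the differential engine's noise model. Per-sample
library-size factors are drawn log-uniform in [0.5, 2] to exercise
normalization. One seed drives everything through deterministic
sub-streams, so identical (parameters, seed) give identical bytes.

The planted trend patterns are derived from the classifier's own rule
table: each label's canonical sign pattern is asserted against the active
table at generation time, so an incompatible table edit fails loudly
instead of silently planting mislabeled genes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as lio
from .io import (
    CountMatrix,
    GeneModel,
    GeneSetCollection,
    PeakInterval,
    SampleSheet,
)
from .chromatin import RegionSignal
from .trends import TrendRuleTable, default_rule_table

GROUPS = ("C", "G", "P", "M")
LOBES = ("H", "L", "R1", "R2", "R3")

#: canonical gated-sign pattern (s_GvC, s_MvG, s_PvG) per planted label;
#: the mirrored pattern is used for genes planted with a downward GvC change
CANONICAL_PATTERNS: dict[str, tuple[int, int, int]] = {
    "NE": (0, 0, 0),
    "Rein01": (1, -1, -1),
    "Rein02": (1, -1, 0),
    "SR": (1, 0, -1),
    "Whip01": (1, 1, 0),
}

DEFAULT_LABEL_PROPORTIONS = {
    "NE": 0.6,
    "Rein01": 0.1,
    "Rein02": 0.1,
    "SR": 0.1,
    "Whip01": 0.1,
}

#: cell-type marker genes (murine lung), elevated only in their own type
CELL_MARKERS: dict[str, list[str]] = {
    "epithelial": ["Epcam", "Krt19", "Krt18", "Cdh1"],
    "fibroblast": ["Dcn", "Thy1", "Col1a1", "Col1a2"],
    "endothelial": ["Pecam1", "Cldn5", "Flt1", "Ramp2"],
    "T": ["Cd3d", "Cd3e", "Cd3g", "Trac"],
    "NK": ["Nkg7", "Gnly", "Ncam1", "Klrd1"],
    "B": ["Cd79a", "Ighm", "Ighg3", "Igha2"],
    "myeloid": ["Lyz", "Marco", "Cd68", "Fcgr3a"],
    "mast": ["Kit", "Ms4a2"],
}

#: the 16-gene treatment signature used for high/low stratification
SIGNATURE_GENES = [
    "Fam174a", "Ifi204", "Slc7a11", "Chil3", "Capza2", "Clec5a", "Clec4a2",
    "Eif3f", "Cited2", "Crybg1", "Ndufs4", "Emb", "Blnk", "Alcam",
    "Chmp2b", "Metap2",
]

DEFAULT_TYPE_PROPORTIONS = {
    "epithelial": 0.15,
    "fibroblast": 0.10,
    "endothelial": 0.10,
    "T": 0.25,
    "NK": 0.05,
    "B": 0.10,
    "myeloid": 0.20,
    "mast": 0.05,
}

DEFAULT_SHIFT_PROPORTIONS = {"Type1": 0.05, "Type2": 0.05, "Type3": 0.10, "None": 0.80}


def _rng_streams(seed: int, n: int) -> list[np.random.Generator]:
    """Deterministic per-component sub-streams from one top-level seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, phi: float | np.ndarray) -> np.ndarray:
    """NB(mu, phi) draws via gamma-Poisson; Poisson when phi ~ 0."""
    mean = np.asarray(mean, dtype=float)
    phi_arr = np.broadcast_to(np.asarray(phi, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    poisson_like = phi_arr < 1e-12
    if poisson_like.any():
        out[poisson_like] = rng.poisson(mean[poisson_like])
    nb = ~poisson_like
    if nb.any():
        shape = 1.0 / phi_arr[nb]
        lam = rng.gamma(shape, phi_arr[nb] * mean[nb])
        out[nb] = rng.poisson(lam)
    return out


def _allocate_counts(n: int, proportions: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder integer allocation of n items to proportions."""
    total = sum(proportions.values())
    if not np.isclose(total, 1.0):
        raise ValueError(f"proportions must sum to 1, got {total}")
    raw = {k: n * v for k, v in proportions.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: (-(raw[k] - counts[k]), k))[:short]:
        counts[k] += 1
    return counts


# ---------------------------------------------------------------------------
# Bulk RNA


@dataclass
class BulkTruth:
    """Planted ground truth for the bulk simulation."""

    genes: pd.DataFrame  # index gene_id; columns mu, phi, label, sign
    offsets: pd.DataFrame  # index gene_id; columns (group, lobe) log2 offsets
    size_factors: pd.Series  # per sample

    def genes_with_label(self, label: str) -> set[str]:
        return set(self.genes.index[self.genes["label"] == label])


def sim_bulk(
    n_genes: int = 1000,
    n_reps_per_cell: int = 3,
    effect_log2fc: float = 2.5,
    dispersion: float = 0.1,
    depth: float = 1e4,
    label_proportions: Mapping[str, float] | None = None,
    seed: int = 0,
    rules: TrendRuleTable | None = None,
    lobe_specific_fraction: float = 0.0,
) -> tuple[CountMatrix, BulkTruth]:
    """Bulk RNA counts over 4 groups x 5 lobes with planted trend genes.

    ``depth`` is the mean per-gene baseline count at size factor 1;
    per-gene baselines are drawn log-normal around it. With
    ``lobe_specific_fraction`` > 0, that fraction of the non-NE genes is
    active in a single random lobe only (NE-patterned elsewhere), which
    populates the lobe-specific intersection classes.
    """
    if n_reps_per_cell < 2:
        raise ValueError("need >= 2 replicates per (group, lobe) cell")
    if effect_log2fc <= 0:
        raise ValueError("effect_log2fc must be > 0")
    props = dict(label_proportions or DEFAULT_LABEL_PROPORTIONS)
    if rules is None:
        rules = default_rule_table()
    for label, (s1, s2, s3) in CANONICAL_PATTERNS.items():
        for flip in (1, -1):
            pat = (flip * s1, flip * s2, flip * s3, 0)
            got = rules.classify(pat)
            if got != label:
                raise ValueError(
                    f"rule table classifies canonical {label} pattern {pat} as {got}"
                )

    rng_assign, rng_base, rng_sf, rng_counts = _rng_streams(seed, 4)

    gene_ids = [f"G{i:05d}" for i in range(1, n_genes + 1)]
    alloc = _allocate_counts(n_genes, props)
    labels = np.array(
        sum(([lab] * alloc[lab] for lab in sorted(alloc)), []), dtype=object
    )
    rng_assign.shuffle(labels)
    signs = rng_assign.choice([1, -1], size=n_genes)
    active_lobe = np.full(n_genes, "", dtype=object)  # "" = all lobes
    if lobe_specific_fraction > 0:
        non_ne = np.flatnonzero(labels != "NE")
        pick = rng_assign.random(len(non_ne)) < lobe_specific_fraction
        active_lobe[non_ne[pick]] = rng_assign.choice(LOBES, size=int(pick.sum()))

    w = rng_base.lognormal(mean=0.0, sigma=0.8, size=n_genes)
    mu = depth * w / w.mean()

    # per-group log2 offsets derived from the canonical pattern:
    # C = 0, G = s1 d, M = G + s2 d, P = G + s3 d
    group_offsets = np.zeros((n_genes, len(GROUPS)))
    for gi in range(n_genes):
        s1, s2, s3 = CANONICAL_PATTERNS[labels[gi]]
        d = effect_log2fc * signs[gi]
        g_off = s1 * d
        group_offsets[gi] = [0.0, g_off, g_off + s3 * d, g_off + s2 * d]  # C,G,P,M

    sample_rows = []
    for lobe in LOBES:
        for group in GROUPS:
            for rep in range(1, n_reps_per_cell + 1):
                sample_rows.append((f"{group}_{lobe}_r{rep}", group, lobe, rep))
    sample_ids = [r[0] for r in sample_rows]
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "group": [r[1] for r in sample_rows],
                "lobe": [r[2] for r in sample_rows],
                "replicate": [r[3] for r in sample_rows],
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    size_factors = pd.Series(
        np.exp(rng_sf.uniform(np.log(0.5), np.log(2.0), size=len(sample_ids))),
        index=sample_ids,
        name="size_factor",
    )

    offsets = pd.DataFrame(
        0.0,
        index=gene_ids,
        columns=pd.MultiIndex.from_product([GROUPS, LOBES], names=["group", "lobe"]),
    )
    gidx = {g: k for k, g in enumerate(GROUPS)}
    for lobe in LOBES:
        lobe_off = group_offsets.copy()
        masked = (active_lobe != "") & (active_lobe != lobe)
        lobe_off[masked] = 0.0
        for group in GROUPS:
            offsets[(group, lobe)] = lobe_off[:, gidx[group]]

    counts = np.empty((n_genes, len(sample_ids)), dtype=np.int64)
    for j, (sid, group, lobe, _rep) in enumerate(sample_rows):
        mean = size_factors[sid] * mu * 2.0 ** offsets[(group, lobe)].to_numpy()
        counts[:, j] = _nb_counts(rng_counts, mean, dispersion)

    cm = CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=sample_ids), sheet)
    truth = BulkTruth(
        genes=pd.DataFrame(
            {"mu": mu, "phi": dispersion, "label": labels, "sign": signs,
             "active_lobe": active_lobe},
            index=pd.Index(gene_ids, name="gene_id"),
        ),
        offsets=offsets,
        size_factors=size_factors,
    )
    return cm, truth


# ---------------------------------------------------------------------------
# Gene models


def sim_gene_models(
    n_genes: int = 100,
    chrom_sizes: Mapping[str, int] | None = None,
    min_gap: int = 1000,
    seed: int = 0,
    span_range: tuple[int, int] = (2000, 20000),
    promoter_disjoint: bool = False,
    promoter_halfwidth: int = 3000,
) -> list[GeneModel]:
    """Non-overlapping gene models packed onto the given chromosomes.

    With ``promoter_disjoint`` the inter-gene gap is raised so every
    TSS +/- ``promoter_halfwidth`` window is pairwise disjoint.
    """
    if chrom_sizes is None:
        chrom_sizes = {"chr1": 2_000_000}
    gap_floor = max(min_gap, 2 * promoter_halfwidth + 2) if promoter_disjoint else min_gap
    chroms = sorted(chrom_sizes)
    for chrom in chroms:
        if gap_floor >= chrom_sizes[chrom]:
            raise ValueError(f"min_gap {gap_floor} exceeds size of {chrom}")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    models: list[GeneModel] = []
    cursor = {c: gap_floor for c in chroms}
    ci = 0
    for i in range(1, n_genes + 1):
        placed = False
        for _attempt in range(len(chroms)):
            chrom = chroms[ci % len(chroms)]
            span = int(rng.integers(span_range[0], span_range[1] + 1))
            start = cursor[chrom]
            end = start + span
            if end + gap_floor <= chrom_sizes[chrom]:
                strand = "+" if rng.random() < 0.5 else "-"
                n_exons = int(rng.integers(1, 6))
                bounds = np.sort(rng.choice(np.arange(1, span), size=2 * n_exons - 2,
                                            replace=False)) if n_exons > 1 else np.array([], dtype=int)
                edges = np.concatenate([[0], bounds, [span]])
                exons = [
                    (start + int(edges[2 * k]), start + int(edges[2 * k + 1]))
                    for k in range(n_exons)
                ]
                thick = None
                if rng.random() < 0.8 and span > 400:
                    ts = start + int(rng.integers(100, span // 2))
                    te = ts + int(rng.integers(100, span - (ts - start)))
                    thick = (ts, min(te, end))
                models.append(
                    GeneModel(f"G{i:05d}", chrom, start, end, strand, exons, thick)
                )
                cursor[chrom] = end + gap_floor + int(rng.integers(0, min_gap + 1))
                ci += 1
                placed = True
                break
            ci += 1
        if not placed:
            raise ValueError(
                f"infeasible packing: placed {len(models)} of {n_genes} genes"
            )
    return models


# ---------------------------------------------------------------------------
# Chromatin (promoter / other H3K27ac signal)


@dataclass
class ChromatinTruth:
    """Planted ground truth for the chromatin simulation."""

    genes: pd.DataFrame  # index gene_id; prom_mean, other_mean, shift_type, sign flip
    spike_in_reads: pd.Series
    efficiencies: pd.Series
    contrast: tuple[str, str]  # (numerator, denominator) groups of the planting


def sim_chromatin(
    gene_models: Sequence[GeneModel],
    n_samples_per_group: int = 3,
    shift_proportions: Mapping[str, float] | None = None,
    promoter_fraction_baseline: float = 0.6,
    spike_mean: float = 10000.0,
    seed: int = 0,
    effect_log2fc: float = 1.0,
    dispersion: float = 0.03,
    depth: float = 1e4,
    lobe: str = "L",
    contrast: tuple[str, str] = ("G", "C"),
) -> tuple[RegionSignal, list[PeakInterval], ChromatinTruth]:
    """Per-gene promoter/other H3K27ac counts with planted shift types.

    Shift genes change only in the numerator group of ``contrast``:
    Type1 = promoter up 2^effect / other down, Type2 mirrored, Type3 both
    in the same direction, None flat. Per-sample pulldown efficiencies
    (log-uniform in [0.5, 2]) scale both the signal and the Poisson
    spike-in reads, so spike-in calibration can remove them. Peaks (one
    promoter and one gene-body interval per gene per sample, scored by
    their counts) reproduce the count table when annotated and aggregated.
    """
    if not 0 < promoter_fraction_baseline < 1:
        raise ValueError("promoter_fraction_baseline must be in (0, 1)")
    if spike_mean <= 0:
        raise ValueError("spike_mean must be > 0")
    if n_samples_per_group < 2:
        raise ValueError("need >= 2 samples per group")
    props = dict(shift_proportions or DEFAULT_SHIFT_PROPORTIONS)
    rng_assign, rng_base, rng_eff, rng_counts, rng_spike = _rng_streams(seed, 5)

    gene_ids = [m.gene_id for m in gene_models]
    n_genes = len(gene_ids)
    alloc = _allocate_counts(n_genes, props)
    types = np.array(sum(([t] * alloc[t] for t in sorted(alloc)), []), dtype=object)
    rng_assign.shuffle(types)
    signs = rng_assign.choice([1, -1], size=n_genes)  # direction flip for Type3

    w = rng_base.lognormal(0.0, 0.8, size=n_genes)
    total_mean = depth * w / w.mean()
    frac = np.clip(
        rng_base.beta(
            promoter_fraction_baseline * 20, (1 - promoter_fraction_baseline) * 20,
            size=n_genes,
        ),
        0.05,
        0.95,
    )
    prom_mean = total_mean * frac
    other_mean = total_mean * (1 - frac)

    sample_rows = []
    for group in GROUPS:
        for rep in range(1, n_samples_per_group + 1):
            sample_rows.append((f"K27_{group}_{lobe}_r{rep}", group, rep))
    sample_ids = [r[0] for r in sample_rows]
    eff = pd.Series(
        np.exp(rng_eff.uniform(np.log(0.5), np.log(2.0), size=len(sample_ids))),
        index=sample_ids,
        name="efficiency",
    )
    spike = pd.Series(
        np.maximum(1, rng_spike.poisson(spike_mean * eff.to_numpy())),
        index=sample_ids,
        name="spike_in_reads",
    )

    # log2 offsets in the shifted (numerator) group only
    prom_off = np.zeros(n_genes)
    other_off = np.zeros(n_genes)
    for gi, t in enumerate(types):
        if t == "Type1":
            prom_off[gi], other_off[gi] = effect_log2fc, -effect_log2fc
        elif t == "Type2":
            prom_off[gi], other_off[gi] = -effect_log2fc, effect_log2fc
        elif t == "Type3":
            d = effect_log2fc * signs[gi]
            prom_off[gi], other_off[gi] = d, d

    shifted_group = contrast[0]
    P = np.empty((n_genes, len(sample_ids)), dtype=np.int64)
    O = np.empty_like(P)
    for j, (sid, group, _rep) in enumerate(sample_rows):
        po = prom_off if group == shifted_group else 0.0
        oo = other_off if group == shifted_group else 0.0
        P[:, j] = _nb_counts(rng_counts, eff[sid] * prom_mean * 2.0**po, dispersion)
        O[:, j] = _nb_counts(rng_counts, eff[sid] * other_mean * 2.0**oo, dispersion)

    sheet = SampleSheet(
        pd.DataFrame(
            {
                "group": [r[1] for r in sample_rows],
                "lobe": lobe,
                "replicate": [r[2] for r in sample_rows],
                "spike_in_reads": spike.to_numpy(),
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    signal = RegionSignal(
        pd.DataFrame(P, index=gene_ids, columns=sample_ids),
        pd.DataFrame(O, index=gene_ids, columns=sample_ids),
        sheet,
    )

    peaks: list[PeakInterval] = []
    model_by_id = {m.gene_id: m for m in gene_models}
    for gi, gid in enumerate(gene_ids):
        m = model_by_id[gid]
        prom_iv = (max(0, m.tss - 250), m.tss + 250)
        body_mid = (m.start + m.end) // 2
        body_iv = (body_mid - 250, body_mid + 250)
        for j, sid in enumerate(sample_ids):
            if P[gi, j] > 0:
                peaks.append(
                    PeakInterval(m.chrom, prom_iv[0], prom_iv[1], sid, float(P[gi, j]))
                )
            if O[gi, j] > 0:
                peaks.append(
                    PeakInterval(m.chrom, body_iv[0], body_iv[1], sid, float(O[gi, j]))
                )

    truth = ChromatinTruth(
        genes=pd.DataFrame(
            {
                "prom_mean": prom_mean,
                "other_mean": other_mean,
                "shift_type": types,
                "sign": signs,
            },
            index=pd.Index(gene_ids, name="gene_id"),
        ),
        spike_in_reads=spike,
        efficiencies=eff,
        contrast=contrast,
    )
    return signal, peaks, truth


# ---------------------------------------------------------------------------
# Single cell


@dataclass
class SingleCellTruth:
    """Planted ground truth for the single-cell simulation."""

    cells: pd.DataFrame  # index cell_id; cell_type, stratum, qc metrics, qc_outlier
    signature_genes: list[str]
    pathway_genes: list[str] = field(default_factory=list)


def _qc_metrics(
    rng: np.random.Generator, n_cells: int, outlier_idx: np.ndarray
) -> pd.DataFrame:
    """QC metrics: clean cells strictly inside every printed bound,
    outlier cells violating exactly one randomly chosen bound."""
    nfeat = rng.uniform(600, 6000, n_cells)
    ncount = rng.uniform(1000, 60000, n_cells)
    mito = rng.uniform(0, 12, n_cells)
    ribo = rng.uniform(0, 35, n_cells)
    violations = (
        ("nFeature_low", lambda: rng.uniform(50, 390)),
        ("nFeature_high", lambda: rng.uniform(7100, 12000)),
        ("nCount_low", lambda: rng.uniform(50, 490)),
        ("nCount_high", lambda: rng.uniform(81000, 150000)),
        ("mito_high", lambda: rng.uniform(15.5, 60)),
        ("ribo_high", lambda: rng.uniform(40.5, 80)),
    )
    for k, ci in enumerate(outlier_idx):
        name, draw = violations[int(rng.integers(0, len(violations)))]
        val = draw()
        if name == "nFeature_low" or name == "nFeature_high":
            nfeat[ci] = val
        elif name == "nCount_low" or name == "nCount_high":
            ncount[ci] = val
        elif name == "mito_high":
            mito[ci] = val
        else:
            ribo[ci] = val
    return pd.DataFrame(
        {"nFeature": nfeat, "nCount": ncount, "pct_mito": mito, "pct_ribo": ribo}
    )


def sim_sc(
    n_cells: int = 2000,
    type_proportions: Mapping[str, float] | None = None,
    signature_genes: Sequence[str] | None = None,
    signature_effect_log2fc: float = 2.0,
    qc_outlier_fraction: float = 0.05,
    seed: int = 0,
    n_background_genes: int = 100,
    marker_effect_log2fc: float = 3.0,
    dispersion: float = 0.3,
    n_pathway_genes: int = 15,
    pathway_effect_log2fc: float = 1.0,
) -> tuple[pd.DataFrame, SingleCellTruth]:
    """Cell x gene count matrix with cell types, markers and a planted
    signature high/low axis.

    Marker genes are elevated (2^marker_effect) only in their own type;
    signature genes are elevated by 2^signature_effect in the planted
    'high' stratum (assigned 50/50 within each type). A separate planted
    pathway gene set (PW-prefixed, disjoint from the signature) co-moves
    with the stratum by 2^pathway_effect, so directional recovery of a
    pathway shift can be tested without scoring the stratifying genes
    themselves. A ``qc_outlier_fraction`` of cells gets QC metrics
    violating at least one printed bound; all other cells sit strictly
    inside every bound.
    """
    props = dict(type_proportions or DEFAULT_TYPE_PROPORTIONS)
    unknown = set(props) - set(CELL_MARKERS)
    if unknown:
        raise ValueError(f"unknown cell types: {sorted(unknown)}")
    sig = list(signature_genes if signature_genes is not None else SIGNATURE_GENES)
    if not sig:
        raise ValueError("signature_genes must be non-empty")
    if not 0 <= qc_outlier_fraction < 0.5:
        raise ValueError("qc_outlier_fraction must be in [0, 0.5)")

    rng_assign, rng_base, rng_counts, rng_qc = _rng_streams(seed, 4)

    alloc = _allocate_counts(n_cells, props)
    cell_types = np.array(sum(([t] * alloc[t] for t in sorted(alloc)), []), dtype=object)
    rng_assign.shuffle(cell_types)
    strata = np.empty(n_cells, dtype=object)
    for t in sorted(alloc):
        idx = np.flatnonzero(cell_types == t)
        half = len(idx) // 2
        chosen = rng_assign.permutation(idx)
        strata[chosen[:half]] = "high"
        strata[chosen[half:]] = "low"

    marker_genes = sorted({g for gs in CELL_MARKERS.values() for g in gs})
    background = [f"BG{i:04d}" for i in range(1, n_background_genes + 1)]
    pathway = [f"PW{i:04d}" for i in range(1, n_pathway_genes + 1)]
    genes = sorted(set(marker_genes) | set(sig)) + pathway + background
    n_genes = len(genes)
    gene_pos = {g: k for k, g in enumerate(genes)}

    base = rng_base.lognormal(np.log(2.0), 0.6, size=n_genes)
    mean = np.tile(base, (n_cells, 1))
    for t, markers in CELL_MARKERS.items():
        rows = cell_types == t
        for g in markers:
            mean[rows, gene_pos[g]] *= 2.0**marker_effect_log2fc
    hi_rows = strata == "high"
    for g in sig:
        mean[hi_rows, gene_pos[g]] *= 2.0**signature_effect_log2fc
    for g in pathway:
        mean[hi_rows, gene_pos[g]] *= 2.0**pathway_effect_log2fc
    counts = _nb_counts(rng_counts, mean, dispersion)

    cell_ids = [f"cell{i:05d}" for i in range(1, n_cells + 1)]
    matrix = pd.DataFrame(counts, index=pd.Index(cell_ids, name="cell_id"), columns=genes)

    n_out = int(round(qc_outlier_fraction * n_cells))
    outlier_idx = np.sort(rng_qc.permutation(n_cells)[:n_out])
    metrics = _qc_metrics(rng_qc, n_cells, outlier_idx)
    metrics.index = matrix.index
    qc_outlier = np.zeros(n_cells, dtype=bool)
    qc_outlier[outlier_idx] = True

    cells = metrics.copy()
    cells.insert(0, "cell_type", cell_types)
    cells.insert(1, "stratum", strata)
    cells["qc_outlier"] = qc_outlier
    return matrix, SingleCellTruth(cells, sig, pathway)


# ---------------------------------------------------------------------------
# Fixture bundle


SCALES = {
    "tiny": dict(bulk_genes=300, bulk_reps=2, chrom_genes=120, chrom_reps=2,
                 sc_cells=400, sc_background=60),
    "default": dict(bulk_genes=1000, bulk_reps=3, chrom_genes=300, chrom_reps=3,
                    sc_cells=2000, sc_background=100),
}


def _planted_gene_sets(truth: BulkTruth, rng: np.random.Generator) -> GeneSetCollection:
    """Gene sets over the bulk universe: one per planted label plus random."""
    sets: dict[str, list[str]] = {}
    for label in ("Rein01", "Rein02", "SR", "Whip01"):
        genes = sorted(truth.genes_with_label(label))
        if genes:
            sets[f"PLANTED_{label.upper()}"] = genes
    universe = np.array(truth.genes.index)
    for k in range(1, 4):
        size = min(30, len(universe))
        sets[f"RANDOM_{k:02d}"] = sorted(rng.choice(universe, size=size, replace=False))
    return GeneSetCollection(sets, {name: "synthetic" for name in sets})


def _sc_gene_sets(
    matrix: pd.DataFrame,
    sig: Sequence[str],
    rng: np.random.Generator,
    pathway: Sequence[str] = (),
    n_random: int = 4,
) -> GeneSetCollection:
    """Single-cell pathway sets: the stratifying signature, the planted
    pathway, and random null sets drawn from the remaining genes."""
    exclude = set(sig) | set(pathway)
    pool = np.array([g for g in matrix.columns if g not in exclude])
    sets = {"SIGNATURE": sorted(sig)}
    if pathway:
        sets["PLANTED_PATHWAY"] = sorted(pathway)
    for k in range(1, n_random + 1):
        size = min(15, len(pool))
        sets[f"NULL_{k:02d}"] = sorted(rng.choice(pool, size=size, replace=False))
    return GeneSetCollection(sets, {name: "synthetic" for name in sets})


def write_fixture_bundle(
    outdir: str | Path,
    scale: str = "tiny",
    seed: int = 0,
    force: bool = False,
    lobe_specific_fraction: float = 0.3,
) -> dict:
    """Write every file an end-to-end run needs; returns the manifest.

    Emits the bulk sample sheet and counts, chromatin sample sheet and
    promoter/other count tables, peaks BED, gene models BED12, bulk and
    single-cell GMTs, the single-cell matrix and metrics, truth tables and
    a manifest recording seed and parameters. Identical (scale, seed)
    reruns produce identical bytes.
    """
    if scale not in SCALES:
        raise ValueError(f"unknown scale {scale!r}; choose from {sorted(SCALES)}")
    params = SCALES[scale]
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} is not empty (use force=True)")
    outdir.mkdir(parents=True, exist_ok=True)

    seeds = {
        "bulk": seed,
        "models": seed + 1,
        "chromatin": seed + 2,
        "sc": seed + 3,
        "sets": seed + 4,
    }

    bulk, bulk_truth = sim_bulk(
        n_genes=params["bulk_genes"],
        n_reps_per_cell=params["bulk_reps"],
        seed=seeds["bulk"],
        lobe_specific_fraction=lobe_specific_fraction,
    )
    bulk.samples.write_csv(outdir / "sample_sheet.csv")
    lio.write_count_matrix(bulk, outdir / "bulk_counts.tsv")
    truth_tab = bulk_truth.genes.copy()
    lio.write_results_tsv(truth_tab.reset_index(), outdir / "bulk_truth.tsv")

    models = sim_gene_models(
        n_genes=params["chrom_genes"],
        chrom_sizes={"chr1": 4_000_000, "chr2": 4_000_000},
        seed=seeds["models"],
        promoter_disjoint=True,
    )
    lio.write_gene_models_bed12(models, outdir / "gene_models.bed")

    signal, peaks, chrom_truth = sim_chromatin(
        models, n_samples_per_group=params["chrom_reps"], seed=seeds["chromatin"]
    )
    signal.samples.write_csv(outdir / "chrom_sample_sheet.csv")
    lio.write_count_matrix(
        CountMatrix(signal.promoter.astype(np.int64), signal.samples),
        outdir / "chrom_promoter_counts.tsv",
    )
    lio.write_count_matrix(
        CountMatrix(signal.other.astype(np.int64), signal.samples),
        outdir / "chrom_other_counts.tsv",
    )
    lio.write_bed_peaks(peaks, outdir / "peaks.bed")
    lio.write_results_tsv(
        chrom_truth.genes.reset_index(), outdir / "chrom_truth.tsv"
    )

    rng_sets = np.random.default_rng(seeds["sets"])
    lio.write_gmt(_planted_gene_sets(bulk_truth, rng_sets), outdir / "gene_sets.gmt")

    matrix, sc_truth = sim_sc(
        n_cells=params["sc_cells"],
        n_background_genes=params["sc_background"],
        seed=seeds["sc"],
    )
    matrix.to_csv(outdir / "sc_matrix.tsv", sep="\t")
    lio.write_results_tsv(
        sc_truth.cells.reset_index().rename(columns={"index": "cell_id"}),
        outdir / "sc_cells.tsv",
    )
    lio.write_gmt(
        _sc_gene_sets(matrix, sc_truth.signature_genes, rng_sets,
                      pathway=sc_truth.pathway_genes),
        outdir / "sc_gene_sets.gmt",
    )
    default_rule_table().to_yaml(outdir / "rule_table.yaml")

    manifest = {
        "seed": seed,
        "scale": scale,
        "sub_seeds": seeds,
        "parameters": params,
        "lobe_specific_fraction": lobe_specific_fraction,
        "files": sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json"),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
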