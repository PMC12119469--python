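"""Gene-set enrichment, per-cell set scoring, single-cell QC, marker
testing and the signature high/low stratification with gated t statistics.

Preranked GSEA ranks genes by their gated change g (zeros excluded: only
significant genes carry rank information) and uses the classic weighted
running-sum enrichment statistic with a gene-set permutation null. The
per-cell score is a deterministic single-sample rank-walk statistic
(ssGSEA-style, weight rank^alpha), invariant under strictly monotone
transforms of the expression vector. Stratified testing compares per-cell
set scores between signature-high and signature-low cells with a Welch t
test, adjusts within each cell type (BH) and zeroes every t whose adjusted
p exceeds 0.05 — the same significance gate the differential stage uses.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diff import ComparisonResult, bh_adjust
from .io import GeneSetCollection

logger = logging.getLogger(__name__)

#: printed single-cell QC bounds: (low, high) per metric; None = unbounded
QC_THRESHOLDS: dict[str, tuple[float | None, float | None]] = {
    "nFeature": (400, 7000),
    "nCount": (500, 80000),
    "pct_mito": (None, 15.0),
    "pct_ribo": (None, 40.0),
}


# ---------------------------------------------------------------------------
# Preranked GSEA


@dataclass
class RankedList:
    """Genes ordered by descending score (ties broken by gene_id)."""

    gene_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.scores):
            raise ValueError("gene_ids and scores length mismatch")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate genes in ranked list")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")

    def __len__(self) -> int:
        return len(self.gene_ids)


def rank_genes(result: ComparisonResult) -> RankedList:
    """Ranked list from a gated comparison: order by g descending, zeros out."""
    g = result.table["g"]
    nz = g[g != 0]
    if len(nz) < 2:
        raise ValueError(
            f"need >= 2 genes with nonzero gated change, have {len(nz)}"
        )
    order = sorted(nz.index, key=lambda gene: (-nz[gene], gene))
    return RankedList(order, nz.loc[order].to_numpy(dtype=float))


def gsea_es(ranked: RankedList, gene_set: Iterable[str], weight: float = 1.0) -> float:
    """Weighted running-sum enrichment score (signed extremum).

    A hit at rank i adds |score_i|^weight / sum over hits; a miss subtracts
    1/(N - N_hits). ES is the running sum's value of largest magnitude.
    """
    members = set(gene_set)
    in_set = np.array([g in members for g in ranked.gene_ids])
    n_hits = int(in_set.sum())
    n = len(ranked)
    if n_hits == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if n_hits == n:
        raise ValueError("gene set covers the entire ranked list")
    w = np.abs(ranked.scores) ** weight
    hit_w = np.where(in_set, w, 0.0)
    total = hit_w.sum()
    if total == 0:
        # all in-set scores are exactly zero: fall back to unweighted hits
        hit_w = in_set.astype(float)
        total = hit_w.sum()
    steps = hit_w / total - (~in_set) / (n - n_hits)
    running = np.cumsum(steps)
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx])


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p: float
    padj: float
    n_hits: int
    flagged: bool = False


def gsea_nes(
    ranked: RankedList,
    sets: GeneSetCollection | Mapping[str, Sequence[str]],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> pd.DataFrame:
    """ES, NES and gene-set permutation p per set, BH-adjusted across sets.

    The null draws random same-size gene sets from the ranked universe;
    NES = ES / mean(|null ES| of matching sign); p is the empirical tail
    probability among matching-sign null draws (never below 1/(n_perm+1)).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    items = sets.items() if hasattr(sets, "items") else dict(sets).items()
    universe = np.array(ranked.gene_ids)
    rows = []
    for name, genes in items:
        members = set(genes) & set(ranked.gene_ids)
        n_hits = len(members)
        if n_hits == 0 or n_hits == len(universe):
            rows.append(
                {"set_name": name, "es": np.nan, "nes": np.nan, "p": np.nan,
                 "n_hits": n_hits, "flagged": True}
            )
            continue
        es = gsea_es(ranked, members, weight=weight)
        null = np.empty(n_perm)
        for k in range(n_perm):
            draw = rng.choice(universe, size=n_hits, replace=False)
            null[k] = gsea_es(ranked, draw, weight=weight)
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if len(same_sign) == 0:
            rows.append(
                {"set_name": name, "es": es, "nes": np.nan, "p": np.nan,
                 "n_hits": n_hits, "flagged": True}
            )
            continue
        nes = es / np.mean(np.abs(same_sign))
        p = (1 + int(np.sum(np.abs(same_sign) >= abs(es)))) / (1 + len(same_sign))
        rows.append(
            {"set_name": name, "es": es, "nes": nes, "p": min(p, 1.0),
             "n_hits": n_hits, "flagged": False}
        )
    df = pd.DataFrame(rows)
    ok = ~df["flagged"] & df["p"].notna()
    padj = np.full(len(df), np.nan)
    if ok.any():
        padj[ok.to_numpy()] = bh_adjust(df.loc[ok, "p"].to_numpy())
    df["padj"] = padj
    return df[["set_name", "es", "nes", "p", "padj", "n_hits", "flagged"]]


# ---------------------------------------------------------------------------
# Per-sample / per-cell gene-set scoring


def sample_set_score(
    expression: pd.Series | np.ndarray,
    gene_set: Iterable[str],
    alpha: float = 0.25,
    gene_ids: Sequence[str] | None = None,
) -> float:
    """Single-sample rank-walk gene-set score.

    Genes are ranked by expression within the sample (highest = rank N);
    the score is the sum over ranks of the difference between the weighted
    in-set ECDF (weights rank^alpha) and the unweighted out-of-set ECDF,
    normalized by N - |S|. Rank-based, hence invariant under strictly
    monotone transforms of the expression vector.
    """
    if isinstance(expression, pd.Series):
        gene_ids = list(expression.index)
        values = expression.to_numpy(dtype=float)
    else:
        if gene_ids is None:
            raise ValueError("gene_ids required with an array expression vector")
        values = np.asarray(expression, dtype=float)
    members = set(gene_set)
    in_set = np.array([g in members for g in gene_ids])
    n = len(values)
    n_s = int(in_set.sum())
    if n_s == 0:
        raise ValueError("gene set does not intersect the measured genes")
    if n_s == n:
        raise ValueError("gene set covers all measured genes")
    # descending order; ties broken by gene_id for determinism
    order = np.lexsort((np.array(gene_ids), -values))
    in_sorted = in_set[order]
    rank_value = np.arange(n, 0, -1, dtype=float)  # N at the top
    w = rank_value**alpha
    hit_w = np.where(in_sorted, w, 0.0)
    ecdf_in = np.cumsum(hit_w) / hit_w.sum()
    ecdf_out = np.cumsum(~in_sorted) / (n - n_s)
    return float(np.sum(ecdf_in - ecdf_out) / (n - n_s))


def score_matrix(
    matrix: pd.DataFrame,
    sets: GeneSetCollection | Mapping[str, Sequence[str]],
    alpha: float = 0.25,
) -> pd.DataFrame:
    """Per-cell (rows) x per-set rank-walk scores for a cell x gene matrix."""
    items = sets.items() if hasattr(sets, "items") else dict(sets).items()
    # order columns by gene_id first so a stable argsort of -values breaks
    # expression ties lexicographically, matching sample_set_score
    matrix = matrix[sorted(matrix.columns)]
    gene_ids = list(matrix.columns)
    values = matrix.to_numpy(dtype=float)
    n_cells, n = values.shape
    order = np.argsort(-values, axis=1, kind="stable")
    rank_value = np.arange(n, 0, -1, dtype=float)
    out = {}
    for name, genes in items:
        members = set(genes)
        in_set = np.array([g in members for g in gene_ids])
        n_s = int(in_set.sum())
        if n_s == 0 or n_s == n:
            raise ValueError(f"gene set {name!r} empty or covers all genes")
        in_sorted = in_set[order]  # n_cells x n
        w = rank_value**alpha
        hit_w = np.where(in_sorted, w, 0.0)
        ecdf_in = np.cumsum(hit_w, axis=1) / hit_w.sum(axis=1, keepdims=True)
        ecdf_out = np.cumsum(~in_sorted, axis=1) / (n - n_s)
        out[name] = (ecdf_in - ecdf_out).sum(axis=1) / (n - n_s)
    return pd.DataFrame(out, index=matrix.index)


# ---------------------------------------------------------------------------
# Single-cell QC, stratification, markers


def qc_filter(
    metrics: pd.DataFrame,
    thresholds: Mapping[str, tuple[float | None, float | None]] | None = None,
) -> pd.Series:
    """Flag poor-quality cells violating any QC bound.

    Default bounds: nFeature < 400 or > 7000; nCount < 500 or > 80000;
    pct_mito > 15; pct_ribo > 40. Returns a boolean Series, True = flagged.
    """
    if thresholds is None:
        thresholds = QC_THRESHOLDS
    missing = [m for m in thresholds if m not in metrics.columns]
    if missing:
        raise ValueError(f"missing QC metrics: {missing}")
    flagged = pd.Series(False, index=metrics.index)
    for metric, (low, high) in thresholds.items():
        vals = metrics[metric]
        if low is not None:
            flagged |= vals < low
        if high is not None:
            flagged |= vals > high
    flagged.name = "qc_flagged"
    return flagged


def signature_score(matrix: pd.DataFrame, signature_genes: Sequence[str]) -> pd.Series:
    """Mean per-gene standardized log1p expression of the signature genes."""
    present = [g for g in signature_genes if g in matrix.columns]
    if not present:
        raise ValueError("no signature gene is measured")
    logx = np.log1p(matrix[present].to_numpy(dtype=float))
    mu = logx.mean(axis=0, keepdims=True)
    sd = logx.std(axis=0, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    z = (logx - mu) / sd
    return pd.Series(z.mean(axis=1), index=matrix.index, name="signature_score")


def stratify(scores: pd.Series, split_quantile: float = 0.5) -> pd.Series:
    """High/low labels by quantile split; ties at the threshold go low."""
    if len(scores) < 4:
        raise ValueError("need >= 4 cells to stratify")
    if scores.nunique() == 1:
        raise ValueError("constant scores: no stratification possible")
    threshold = scores.quantile(split_quantile)
    labels = np.where(scores > threshold, "high", "low")
    return pd.Series(labels, index=scores.index, name="stratum")


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumeration of group assignments."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    center = ranks.sum() * n1 / len(pooled)
    observed = abs(ranks[:n1].sum() - center)
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(ranks[list(combo)].sum() - center) >= observed - 1e-9:
            count += 1
    return count / total


def ranksum_markers(
    matrix: pd.DataFrame,
    groups: pd.Series,
    min_pct: float = 0.3,
    exact_limit: int = 20000,
) -> pd.DataFrame:
    """Two-sided rank-sum marker test between two cell groups.

    A gene is tested only if detected (count > 0) in at least ``min_pct``
    of the cells of one group. P-values are exact (enumeration over group
    assignments) when C(n1+n2, n1) <= exact_limit, else the tie-corrected
    normal approximation. BH adjustment spans the tested genes.
    """
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(levels)}")
    g1, g2 = levels
    idx1 = groups.index[groups == g1]
    idx2 = groups.index[groups == g2]
    if len(idx1) < 3 or len(idx2) < 3:
        raise ValueError("both groups need >= 3 cells")
    m1 = matrix.loc[idx1]
    m2 = matrix.loc[idx2]
    pct1 = (m1 > 0).mean(axis=0)
    pct2 = (m2 > 0).mean(axis=0)
    tested = matrix.columns[(pct1 >= min_pct) | (pct2 >= min_pct)]
    if len(tested) == 0:
        logger.info("no genes pass min_pct=%.2f", min_pct)
        return pd.DataFrame(columns=["log2fc", "p", "padj", "pct_1", "pct_2"])
    use_exact = comb(len(idx1) + len(idx2), len(idx1)) <= exact_limit
    rows = {}
    for gene in tested:
        x = m1[gene].to_numpy(dtype=float)
        y = m2[gene].to_numpy(dtype=float)
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            p = 1.0
        elif use_exact:
            p = _exact_ranksum_p(x, y)
        else:
            p = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")[1]
        log2fc = float(np.log2((x.mean() + 1.0) / (y.mean() + 1.0)))
        rows[gene] = (log2fc, min(p, 1.0), float(pct1[gene]), float(pct2[gene]))
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["log2fc", "p", "pct_1", "pct_2"]
    )
    df["padj"] = bh_adjust(df["p"].to_numpy())
    df.index.name = "gene_id"
    return df[["log2fc", "p", "padj", "pct_1", "pct_2"]]


# ---------------------------------------------------------------------------
# Stratified gated-t matrix


@dataclass
class StratifiedTestResult:
    subset: str
    pathway: str
    t: float
    p: float
    padj: float
    gated_t: float
    flagged: bool = False


def gated_t_matrix(
    set_scores: pd.DataFrame,
    strata: pd.Series,
    cell_types: pd.Series,
    alpha: float = 0.05,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Welch t (high vs low) per cell type x pathway, BH-gated.

    ``set_scores`` is cell x pathway; BH runs within each cell type across
    pathways; gated_t = t where padj <= alpha, else 0. Cell types where a
    stratum has fewer than ``min_cells`` cells are flagged, not computed.
    """
    records: list[StratifiedTestResult] = []
    for ct in sorted(pd.unique(cell_types)):
        cells = cell_types.index[cell_types == ct]
        hi = [c for c in cells if strata.get(c) == "high"]
        lo = [c for c in cells if strata.get(c) == "low"]
        if len(hi) < min_cells or len(lo) < min_cells:
            for pw in set_scores.columns:
                records.append(
                    StratifiedTestResult(ct, pw, np.nan, np.nan, np.nan, 0.0, True)
                )
            continue
        ts, ps = [], []
        for pw in set_scores.columns:
            x = set_scores.loc[hi, pw].to_numpy()
            y = set_scores.loc[lo, pw].to_numpy()
            if np.array_equal(np.sort(x), np.sort(y)) or (x.std() == 0 and y.std() == 0):
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_ind(x, y, equal_var=False)
            ts.append(float(t))
            ps.append(float(p))
        padj = bh_adjust(np.array(ps))
        for pw, t, p, pa in zip(set_scores.columns, ts, ps, padj):
            gated = t if pa <= alpha else 0.0
            records.append(StratifiedTestResult(ct, pw, t, p, float(pa), gated))
    return pd.DataFrame(
        [
            {
                "subset": r.subset,
                "pathway": r.pathway,
                "t": r.t,
                "p": r.p,
                "padj": r.padj,
                "gated_t": r.gated_t,
                "flagged": r.flagged,
            }
            for r in records
        ]
    )
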