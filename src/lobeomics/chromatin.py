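"""H3K27ac regional signal: spike-in calibration, peak annotation with
promoter precedence, promoter-fraction summaries and promoter<->other
shift typing.

A peak is assigned a single genomic feature category from its midpoint.
Candidate categories from every gene the midpoint could relate to are
ranked by a fixed precedence,

    Promoter > 5'UTR > 3'UTR > Exon > Intron > Downstream > DistalIntergenic,

so any peak whose midpoint lies inside at least one promoter window
(TSS +/- 3 kb by default) is a promoter peak regardless of other overlaps.
Shift typing then asks, per gene and contrast, whether the significance-
gated change of promoter signal (dP) opposes the gated change of the
signal assigned to all other categories (dO): Type1 = promoter up / other
down, Type2 = the mirror image, Type3 = any other significant change,
None = neither region moved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .diff import ComparisonSpec, run_comparison
from .io import CountMatrix, GeneModel, PeakInterval, SampleSheet

FEATURE_PRECEDENCE = (
    "Promoter",
    "FivePrimeUTR",
    "ThreePrimeUTR",
    "Exon",
    "Intron",
    "Downstream",
    "DistalIntergenic",
)
_RANK = {cat: i for i, cat in enumerate(FEATURE_PRECEDENCE)}

SHIFT_TYPES = ("Type1", "Type2", "Type3", "None")


def spikein_factors(
    spike_in_reads: pd.Series | Mapping[str, int], constant: float = 10000.0
) -> pd.Series:
    """Per-sample calibration factors C / n_spike.

    Scaling a sample's signal by its factor equalizes the expected signal
    derived from a fixed quantity of exogenous (spike-in) chromatin, so
    samples with different pulldown efficiencies become comparable.
    """
    s = pd.Series(spike_in_reads, dtype=float)
    zero = s.index[s <= 0].tolist()
    if zero:
        raise ValueError(f"spike-in read count is zero for samples: {zero}")
    return constant / s


def _categorize_vs_gene(
    midpoint: int,
    gene: GeneModel,
    promoter_window: tuple[int, int],
    downstream_window: int,
) -> str | None:
    """Feature category of a midpoint relative to one gene, or None.

    The promoter window is strand-aware: (-3000, +3000) means 3 kb upstream
    through 3 kb downstream of the TSS in transcription direction.
    """
    up, down = promoter_window
    tss = gene.tss
    offset = midpoint - tss if gene.strand == "+" else tss - midpoint
    if up <= offset <= down:
        return "Promoter"
    if gene.start <= midpoint < gene.end:
        in_exon = any(s <= midpoint < e for s, e in gene.exons)
        if not in_exon:
            return "Intron"
        if gene.thick is None:
            return "Exon"
        ts, te = gene.thick
        if midpoint < ts:
            return "FivePrimeUTR" if gene.strand == "+" else "ThreePrimeUTR"
        if midpoint >= te:
            return "ThreePrimeUTR" if gene.strand == "+" else "FivePrimeUTR"
        return "Exon"
    tes = gene.tes
    ds_offset = midpoint - tes if gene.strand == "+" else tes - midpoint
    if 0 < ds_offset <= downstream_window:
        return "Downstream"
    return None


@dataclass
class PeakAnnotation:
    peak: PeakInterval
    category: str
    gene_id: str | None
    distance_to_tss: int | None  # signed, + downstream of TSS in gene orientation


def annotate_interval(
    peak: PeakInterval,
    models: Sequence[GeneModel],
    promoter_window: tuple[int, int] = (-3000, 3000),
    downstream_window: int = 3000,
) -> PeakAnnotation:
    """Assign one peak a feature category by midpoint with precedence.

    Among all genes on the peak's chromosome, the best (highest-precedence)
    category wins; ties break to the gene whose TSS is nearest, then by
    gene_id. A midpoint matching nothing is DistalIntergenic, reported with
    the nearest-TSS gene on the chromosome (None if the chromosome has no
    genes).
    """
    mid = peak.midpoint
    best: tuple[int, int, str, str] | None = None  # (rank, |dist|, gene_id, cat)
    chrom_genes = [g for g in models if g.chrom == peak.chrom]
    for gene in chrom_genes:
        cat = _categorize_vs_gene(mid, gene, promoter_window, downstream_window)
        if cat is None:
            continue
        dist = abs(mid - gene.tss)
        key = (_RANK[cat], dist, gene.gene_id, cat)
        if best is None or key[:3] < best[:3]:
            best = key
    if best is not None:
        rank, _, gene_id, cat = best
        gene = next(g for g in chrom_genes if g.gene_id == gene_id)
        signed = mid - gene.tss if gene.strand == "+" else gene.tss - mid
        return PeakAnnotation(peak, cat, gene_id, signed)
    if not chrom_genes:
        return PeakAnnotation(peak, "DistalIntergenic", None, None)
    nearest = min(chrom_genes, key=lambda g: (abs(mid - g.tss), g.gene_id))
    signed = mid - nearest.tss if nearest.strand == "+" else nearest.tss - mid
    return PeakAnnotation(peak, "DistalIntergenic", nearest.gene_id, signed)


def annotate_peaks(
    peaks: Iterable[PeakInterval],
    models: Sequence[GeneModel],
    promoter_window: tuple[int, int] = (-3000, 3000),
    downstream_window: int = 3000,
) -> list[PeakAnnotation]:
    return [
        annotate_interval(p, models, promoter_window, downstream_window) for p in peaks
    ]


@dataclass
class RegionSignal:
    """Per-gene, per-sample H3K27ac signal split into promoter vs other.

    ``promoter`` and ``other`` are gene x sample frames; ``fine`` holds the
    per-sample totals of every fine feature category; ``scale_factors``
    are the spike-in factors that have been applied when ``scaled``.
    """

    promoter: pd.DataFrame
    other: pd.DataFrame
    samples: SampleSheet
    fine: pd.DataFrame | None = None  # category x sample totals
    scale_factors: pd.Series | None = None
    scaled: bool = False

    def __post_init__(self) -> None:
        if not self.promoter.index.equals(self.other.index):
            raise ValueError("promoter and other frames must share gene index")
        if list(self.promoter.columns) != list(self.other.columns):
            raise ValueError("promoter and other frames must share sample columns")
        if (self.promoter.to_numpy() < 0).any() or (self.other.to_numpy() < 0).any():
            raise ValueError("region signal must be nonnegative")

    def apply_spikein(self, factors: pd.Series) -> "RegionSignal":
        f = factors.loc[self.promoter.columns]
        return RegionSignal(
            self.promoter * f,
            self.other * f,
            self.samples,
            fine=None if self.fine is None else self.fine * f,
            scale_factors=f,
            scaled=True,
        )


def aggregate_region_signal(
    annotations: Iterable[PeakAnnotation],
    samples: SampleSheet,
    scale_factors: pd.Series | None = None,
    max_distal_distance: int = 100_000,
) -> RegionSignal:
    """Sum annotated peak signal into per-gene promoter (P) and other (O).

    A peak's signal is its score (1.0 when absent). DistalIntergenic peaks
    credit the nearest gene's O only within ``max_distal_distance`` of its
    TSS; beyond that they are left unassigned (and excluded from P+O).
    """
    annotations = list(annotations)
    sample_ids = samples.sample_ids
    genes = sorted({a.gene_id for a in annotations if a.gene_id is not None})
    gene_idx = {g: i for i, g in enumerate(genes)}
    col_idx = {s: j for j, s in enumerate(sample_ids)}
    P = np.zeros((len(genes), len(sample_ids)))
    O = np.zeros_like(P)
    fine = pd.DataFrame(0.0, index=list(FEATURE_PRECEDENCE), columns=sample_ids)
    for a in annotations:
        signal = 1.0 if a.peak.score is None else a.peak.score
        j = col_idx[a.peak.sample_id]
        fine.loc[a.category, a.peak.sample_id] += signal
        if a.gene_id is None:
            continue
        if a.category == "DistalIntergenic" and (
            a.distance_to_tss is None or abs(a.distance_to_tss) > max_distal_distance
        ):
            continue
        i = gene_idx[a.gene_id]
        if a.category == "Promoter":
            P[i, j] += signal
        else:
            O[i, j] += signal
    rs = RegionSignal(
        pd.DataFrame(P, index=genes, columns=sample_ids),
        pd.DataFrame(O, index=genes, columns=sample_ids),
        samples,
        fine=fine,
    )
    if scale_factors is not None:
        rs = rs.apply_spikein(scale_factors)
    return rs


def promoter_fraction(signal: RegionSignal, sample_id: str | None = None) -> float | pd.Series:
    """Fraction of total assigned signal falling in promoter regions."""
    p = signal.promoter.sum(axis=0)
    o = signal.other.sum(axis=0)
    total = p + o
    if sample_id is not None:
        if total[sample_id] == 0:
            raise ValueError(f"sample {sample_id!r} has zero total signal")
        return float(p[sample_id] / total[sample_id])
    if (total == 0).any():
        bad = total.index[total == 0].tolist()
        raise ValueError(f"samples with zero total signal: {bad}")
    return p / total


def shift_type(dP: int, dO: int) -> str:
    """Promoter<->other shift class from the two gated sign trits."""
    if dP not in (-1, 0, 1) or dO not in (-1, 0, 1):
        raise ValueError(f"trits must be in -1/0/+1, got ({dP}, {dO})")
    if (dP, dO) == (1, -1):
        return "Type1"
    if (dP, dO) == (-1, 1):
        return "Type2"
    if (dP, dO) == (0, 0):
        return "None"
    return "Type3"


def _as_count_matrix(frame: pd.DataFrame, samples: SampleSheet) -> CountMatrix:
    return CountMatrix(frame.round().astype(np.int64), samples)


def _region_dispersion(
    signal: RegionSignal, sf: pd.Series | None
) -> tuple[pd.Series, int]:
    """Per-gene dispersion pooled over all groups and both region tracks.

    A gene's biological dispersion is assumed shared between its promoter
    and non-promoter signal, so the two method-of-moments estimates (each
    centered per group) are averaged, doubling the residual degrees of
    freedom behind the plug-in.
    """
    from .diff import PHI_MIN, estimate_dispersion

    groups = signal.samples.table["group"]
    sf_use = (
        pd.Series(1.0, index=signal.promoter.columns) if sf is None else sf
    )
    phi_p = estimate_dispersion(signal.promoter, sf_use, groups=groups, phi_min=0.0)
    phi_o = estimate_dispersion(signal.other, sf_use, groups=groups, phi_min=0.0)
    phi = np.maximum((phi_p + phi_o) / 2.0, PHI_MIN)
    df = 2 * (signal.promoter.shape[1] - groups.nunique())
    return phi, df


def shift_types_for_comparison(
    signal: RegionSignal,
    spec: ComparisonSpec,
    alpha: float = 0.05,
    spike_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Differential P and O via the shared gated NB engine, then shift types.

    Raw (unscaled) counts are tested with spike-in derived size factors
    (1 / calibration factor), so the one statistical engine also serves the
    chromatin arm. Returns a frame indexed by gene with dP, dO, shift_type.
    """
    if signal.scaled:
        raise ValueError("run shift typing on raw counts with spike-in size factors")
    factors = spike_factors if spike_factors is not None else signal.scale_factors
    sf = None if factors is None else 1.0 / factors
    phi, df = _region_dispersion(signal, sf)
    prom_cm = _as_count_matrix(signal.promoter, signal.samples)
    other_cm = _as_count_matrix(signal.other, signal.samples)
    res_p = run_comparison(prom_cm, spec, alpha=alpha, sf=sf, phi=phi, phi_df=df)
    res_o = run_comparison(other_cm, spec, alpha=alpha, sf=sf, phi=phi, phi_df=df)
    dP = np.sign(res_p.table["g"].to_numpy()).astype(int)
    dO = np.sign(res_o.table["g"].to_numpy()).astype(int)
    types = [shift_type(p, o) for p, o in zip(dP, dO)]
    out = pd.DataFrame(
        {"dP": dP, "dO": dO, "shift_type": types}, index=res_p.table.index
    )
    out.index.name = "gene_id"
    return out


def promoter_comparison(
    signal: RegionSignal,
    spec: ComparisonSpec,
    alpha: float = 0.05,
    spike_factors: pd.Series | None = None,
):
    """Gated differential test on the promoter signal alone.

    This is the chromatin-side input to the transcriptome/H3K27ac
    concordance step (only promoter-level changes are compared with RNA).
    """
    if signal.scaled:
        raise ValueError("run differential testing on raw counts")
    factors = spike_factors if spike_factors is not None else signal.scale_factors
    sf = None if factors is None else 1.0 / factors
    phi, df = _region_dispersion(signal, sf)
    prom_cm = _as_count_matrix(signal.promoter, signal.samples)
    return run_comparison(prom_cm, spec, alpha=alpha, sf=sf, phi=phi, phi_df=df)


def annotations_to_frame(annotations: Iterable[PeakAnnotation]) -> pd.DataFrame:
    rows = [
        {
            "chrom": a.peak.chrom,
            "start": a.peak.start,
            "end": a.peak.end,
            "sample_id": a.peak.sample_id,
            "category": a.category,
            "gene_id": a.gene_id if a.gene_id is not None else "",
            "distance_to_tss": a.distance_to_tss,
        }
        for a in annotations
    ]
    return pd.DataFrame(rows)
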