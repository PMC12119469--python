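"""Negative-binomial differential testing with significance-gated changes.

The signed, gated change g is the quantity the trend classifier consumes:
for a comparison of numerator group j versus denominator group i,

    g = log2fc   if padj <= alpha
    g = 0        otherwise

so a gene carries a nonzero signed change only when its adjusted p-value
clears the significance gate. The test itself is a Wald test on the log
ratio of normalized group means under an NB(mu, phi) noise model with
variance mu + phi * mu^2; library depth is removed with median-of-ratios
size factors and dispersion is a pooled method-of-moments estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, SampleSheet

#: numerator/denominator group per standard comparison label ("j v i")
COMPARISONS: dict[str, tuple[str, str]] = {
    "GvC": ("G", "C"),
    "MvG": ("M", "G"),
    "PvG": ("P", "G"),
    "MvP": ("M", "P"),
}

PHI_MIN = 1e-8
PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class ComparisonSpec:
    """A two-group contrast within one lobe (numerator vs denominator)."""

    numerator: str
    denominator: str
    lobe: str

    def __post_init__(self) -> None:
        if self.numerator == self.denominator:
            raise ValueError("numerator and denominator groups must differ")

    @classmethod
    def from_label(cls, label: str, lobe: str) -> "ComparisonSpec":
        if label not in COMPARISONS:
            raise ValueError(f"unknown comparison label {label!r}")
        j, i = COMPARISONS[label]
        return cls(j, i, lobe)

    @property
    def label(self) -> str:
        for lab, (j, i) in COMPARISONS.items():
            if (j, i) == (self.numerator, self.denominator):
                return lab
        return f"{self.numerator}v{self.denominator}"


@dataclass
class ComparisonResult:
    """Per-gene log2fc, se, p, padj and the gated signed change g."""

    table: pd.DataFrame  # index gene_id; columns log2fc, se, p, padj, g
    comparison: str
    lobe: str

    @property
    def g(self) -> pd.Series:
        return self.table["g"]

    def deg_genes(self) -> set[str]:
        """Genes passing the gate (g != 0)."""
        return set(self.table.index[self.table["g"] != 0])

    def to_frame(self) -> pd.DataFrame:
        out = self.table.reset_index().rename(columns={"index": "gene_id"})
        out.insert(1, "comparison", self.comparison)
        out.insert(2, "lobe", self.lobe)
        return out


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (ratio to the per-gene geometric mean).

    Genes with any zero count are excluded from the reference set; at least
    one all-nonzero gene is required.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    arr = mat.to_numpy(dtype=float)
    nonzero = (arr > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; supply explicit "
            "size factors or use a pseudo-reference"
        )
    ref = arr[nonzero]
    log_geo = np.mean(np.log(ref), axis=1, keepdims=True)
    ratios = ref / np.exp(log_geo)
    sf = np.median(ratios, axis=0)
    return pd.Series(sf, index=mat.columns, name="size_factor")


def estimate_dispersion(
    counts: CountMatrix | pd.DataFrame,
    sf: pd.Series,
    groups: pd.Series | None = None,
    phi_min: float = PHI_MIN,
) -> pd.Series:
    """Per-gene NB dispersion by method of moments on normalized counts.

    phi = max(phi_min, (s^2 - mean) / mean^2), with the variance pooled
    within groups (group means removed) when a grouping is supplied.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    if mat.shape[1] < 2:
        raise ValueError("dispersion estimation needs >= 2 samples")
    norm = mat.to_numpy(dtype=float) / sf.loc[mat.columns].to_numpy()
    n = norm.shape[1]
    if groups is None:
        resid = norm - norm.mean(axis=1, keepdims=True)
        dof = n - 1
    else:
        grp = np.asarray(groups.loc[mat.columns])
        resid = np.empty_like(norm)
        n_groups = 0
        for gname in np.unique(grp):
            cols = grp == gname
            resid[:, cols] = norm[:, cols] - norm[:, cols].mean(axis=1, keepdims=True)
            n_groups += 1
        dof = n - n_groups
    if dof < 1:
        raise ValueError("not enough residual degrees of freedom")
    s2 = (resid**2).sum(axis=1) / dof
    mu = norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(mu > 0, (s2 - mu) / mu**2, 0.0)
    phi = np.maximum(phi, phi_min)
    return pd.Series(phi, index=mat.index, name="phi")


def nb_wald_test(
    counts: CountMatrix,
    spec: ComparisonSpec,
    sf: pd.Series,
    phi: pd.Series,
    pseudocount: float = PSEUDOCOUNT,
    df: int | None = None,
) -> pd.DataFrame:
    """Wald test on the log ratio of normalized NB group means.

    Returns a frame (index gene_id) with log2fc, se, p. Two-sided p-values
    come from a t reference with ``df`` degrees of freedom — the residual
    degrees of freedom behind the plugged-in dispersion estimate — which
    reduces to the normal approximation as df grows (df None = normal).
    Genes with zero counts in both groups are reported with log2fc 0 and
    p 1 rather than dropped, so downstream set algebra keeps a common
    gene universe.
    """
    sheet = counts.samples
    num_ids = sheet.require_replicates(spec.numerator, spec.lobe)
    den_ids = sheet.require_replicates(spec.denominator, spec.lobe)

    norm = counts.counts.to_numpy(dtype=float) / sf.loc[counts.counts.columns].to_numpy()
    cols = {s: k for k, s in enumerate(counts.counts.columns)}
    num = norm[:, [cols[s] for s in num_ids]]
    den = norm[:, [cols[s] for s in den_ids]]

    m_num, m_den = num.mean(axis=1), den.mean(axis=1)
    phi_arr = phi.loc[counts.counts.index].to_numpy()

    log2fc = np.log2((m_num + pseudocount) / (m_den + pseudocount))
    # delta method on the shrunken log2 group mean: the count variance
    # (mu + phi mu^2)/n is evaluated at the observed mean, with a floor of
    # half the pseudocount so zero-count groups keep positive variance; the
    # shrinkage enters through the (m + pseudocount)^2 denominator. This
    # matches the Monte-Carlo sd of the shrunken estimator across depths.
    ln2sq = np.log(2.0) ** 2

    def _var_log2(m: np.ndarray, n: int) -> np.ndarray:
        num = m + phi_arr * m**2 + 0.5 * pseudocount
        return num / (n * (m + pseudocount) ** 2 * ln2sq)

    se = np.sqrt(_var_log2(m_num, num.shape[1]) + _var_log2(m_den, den.shape[1]))
    z = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    if df is None:
        p = 2.0 * stats.norm.sf(np.abs(z))
    else:
        p = 2.0 * stats.t.sf(np.abs(z), df=df)
    p = np.minimum(p, 1.0)

    both_zero = (num.sum(axis=1) == 0) & (den.sum(axis=1) == 0)
    log2fc[both_zero] = 0.0
    p[both_zero] = 1.0

    return pd.DataFrame(
        {"log2fc": log2fc, "se": se, "p": p}, index=counts.counts.index
    )


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def gate(log2fc, padj, alpha: float = 0.05):
    """Significance-gated signed change: log2fc where padj <= alpha, else 0.

    Missing (NaN) adjusted p-values gate to 0 (untested genes carry no
    signed change).
    """
    lfc = np.asarray(log2fc, dtype=float)
    pa = np.asarray(padj, dtype=float)
    keep = np.where(np.isnan(pa), False, pa <= alpha)
    return np.where(keep, lfc, 0.0)


def run_comparison(
    counts: CountMatrix,
    spec: ComparisonSpec,
    alpha: float = 0.05,
    sf: pd.Series | None = None,
    phi: pd.Series | None = None,
    phi_df: int | None = None,
) -> ComparisonResult:
    """Full gated differential pipeline for one two-group contrast.

    Size factors and dispersions are computed on the samples of the two
    contrasted groups within the lobe unless supplied explicitly (the
    chromatin stage passes spike-in derived factors).
    """
    sheet = counts.samples
    ids = sheet.require_replicates(spec.numerator, spec.lobe) + sheet.require_replicates(
        spec.denominator, spec.lobe
    )
    sub = counts.subset_samples(ids)
    if sf is None:
        sf_sub = size_factors(sub)
    else:
        sf_sub = sf.loc[ids]
    if phi is None:
        phi_sub = estimate_dispersion(sub, sf_sub, groups=sub.samples.table["group"])
        phi_df = len(ids) - 2
    else:
        phi_sub = phi
    tab = nb_wald_test(sub, spec, sf_sub, phi_sub, df=phi_df)
    tab["padj"] = bh_adjust(tab["p"].to_numpy())
    tab["g"] = gate(tab["log2fc"], tab["padj"], alpha=alpha)
    tab.index.name = "gene_id"
    return ComparisonResult(tab, spec.label, spec.lobe)


def run_all_comparisons(
    counts: CountMatrix,
    lobes: tuple[str, ...] | None = None,
    comparisons: tuple[str, ...] = tuple(COMPARISONS),
    alpha: float = 0.05,
    sf: pd.Series | None = None,
) -> dict[tuple[str, str], ComparisonResult]:
    """All requested comparison x lobe contrasts, keyed (label, lobe)."""
    if lobes is None:
        lobes = tuple(sorted(counts.samples.table["lobe"].unique()))
    # one size-factor vector over all samples, and one per-gene dispersion
    # pooled across every (group, lobe) cell (cell means removed): a gene's
    # dispersion is assumed shared across conditions, giving far more
    # residual degrees of freedom than any single two-group contrast
    sf_all = size_factors(counts) if sf is None else sf
    cells = (
        counts.samples.table["group"].astype(str)
        + ":"
        + counts.samples.table["lobe"].astype(str)
    )
    phi_all = estimate_dispersion(counts, sf_all, groups=cells)
    phi_df = counts.counts.shape[1] - cells.nunique()
    out: dict[tuple[str, str], ComparisonResult] = {}
    for lobe in lobes:
        for label in comparisons:
            spec = ComparisonSpec.from_label(label, lobe)
            out[(label, lobe)] = run_comparison(
                counts, spec, alpha=alpha, sf=sf_all, phi=phi_all, phi_df=phi_df
            )
    return out
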