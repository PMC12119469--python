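"""Readers, writers and validated containers for every external format.

All genomic coordinates are 0-based, half-open (BED-native), everywhere.
Output tables are written with a deterministic row order (sorted by
gene_id, then sample_id) so reruns are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("C", "G", "P", "M")
LOBES = ("H", "L", "R1", "R2", "R3")


class FormatError(ValueError):
    """Raised when an external file violates its format contract."""


# ---------------------------------------------------------------------------
# Sample sheet


@dataclass
class SampleSheet:
    """Sample metadata for the 4-group x 5-lobe bulk design.

    ``table`` is indexed by sample_id with columns ``group`` (C, G, P, M for
    control, GVHD, PBS and hPMSC), ``lobe`` (H, L, R1, R2, R3), integer
    ``replicate`` and optional ``spike_in_reads``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            dups = t.index[t.index.duplicated()].tolist()
            raise FormatError(f"duplicate sample_ids: {dups}")
        for col in ("group", "lobe", "replicate"):
            if col not in t.columns:
                raise FormatError(f"sample sheet missing column {col!r}")
        bad_group = set(t["group"]) - set(GROUPS)
        if bad_group:
            raise FormatError(f"unknown group labels: {sorted(bad_group)}")
        bad_lobe = set(t["lobe"]) - set(LOBES)
        if bad_lobe:
            raise FormatError(f"unknown lobe labels: {sorted(bad_lobe)}")
        if (t["replicate"].astype(int) < 1).any():
            raise FormatError("replicate numbers must be positive integers")
        self.table = t

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def select(self, group: str | None = None, lobe: str | None = None) -> list[str]:
        """Sample ids matching the given group and/or lobe."""
        mask = pd.Series(True, index=self.table.index)
        if group is not None:
            mask &= self.table["group"] == group
        if lobe is not None:
            mask &= self.table["lobe"] == lobe
        return list(self.table.index[mask])

    def require_replicates(self, group: str, lobe: str, min_n: int = 2) -> list[str]:
        ids = self.select(group=group, lobe=lobe)
        if len(ids) < min_n:
            raise FormatError(
                f"(group={group}, lobe={lobe}) has {len(ids)} replicates; "
                f"need >= {min_n}"
            )
        return ids

    @classmethod
    def read_csv(cls, path: str | Path) -> "SampleSheet":
        df = pd.read_csv(path, dtype={"sample_id": str})
        if "sample_id" not in df.columns:
            raise FormatError(f"{path}: sample sheet needs a sample_id column")
        return cls(df.set_index("sample_id"))

    def write_csv(self, path: str | Path) -> None:
        out = self.table.sort_index()
        out.to_csv(path, index_label="sample_id")


# ---------------------------------------------------------------------------
# Count matrix


@dataclass
class CountMatrix:
    """Nonnegative integer gene x sample counts plus sample metadata."""

    counts: pd.DataFrame
    samples: SampleSheet

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].tolist()
            raise FormatError(f"duplicate gene_ids: {dups[:5]}")
        sheet_ids = self.samples.sample_ids
        missing = [s for s in sheet_ids if s not in c.columns]
        if missing:
            raise FormatError(f"samples in sheet but not in counts: {missing}")
        # align column order to the sheet
        c = c[sheet_ids]
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            frac = arr - np.floor(arr)
            if np.any(frac != 0):
                g, s = np.argwhere(frac != 0)[0]
                raise FormatError(
                    f"non-integral count at gene {c.index[g]!r}, "
                    f"sample {c.columns[s]!r}"
                )
            c = c.astype(np.int64)
            arr = c.to_numpy()
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at gene {c.index[g]!r}, sample {c.columns[s]!r}"
            )
        self.counts = c

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        sheet = SampleSheet(self.samples.table.loc[list(sample_ids)])
        return CountMatrix(self.counts[list(sample_ids)], sheet)


def read_count_matrix(path: str | Path, sample_sheet: SampleSheet) -> CountMatrix:
    """Read a TSV count table (first column gene_id, header sample_ids).

    Cells must be nonnegative integers; errors name the offending gene and
    sample. Samples listed in the sheet must all appear in the header.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    missing = [s for s in sample_sheet.sample_ids if s not in df.columns]
    if missing:
        raise FormatError(f"{path}: samples missing from header: {missing}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            gene = df.index[vals.isna().to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"{path}: non-numeric count at gene {gene!r}, sample {col!r}"
            )
    return CountMatrix(df, sample_sheet)


def write_count_matrix(cm: CountMatrix, path: str | Path) -> None:
    out = cm.counts.sort_index()
    out.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Gene models (BED12)


@dataclass
class GeneModel:
    """One gene: span, strand, exon blocks and optional CDS (thick) span.

    Coordinates are 0-based half-open. The TSS is ``start`` on the + strand
    and ``end - 1`` on the - strand.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    thick: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(f"{self.gene_id}: start {self.start} >= end {self.end}")
        if self.strand not in ("+", "-"):
            raise FormatError(f"{self.gene_id}: bad strand {self.strand!r}")
        prev_end = self.start - 1
        for (s, e) in self.exons:
            if s >= e:
                raise FormatError(f"{self.gene_id}: empty exon [{s},{e})")
            if s < self.start or e > self.end:
                raise FormatError(f"{self.gene_id}: exon [{s},{e}) outside gene span")
            if s <= prev_end:
                raise FormatError(f"{self.gene_id}: exons unsorted or overlapping")
            prev_end = e

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        """Transcription end site (last transcribed base position)."""
        return self.end - 1 if self.strand == "+" else self.start


def read_gene_models_bed12(path: str | Path) -> list[GeneModel]:
    """Parse a BED12 file into GeneModel records.

    blockSizes/blockStarts must agree with blockCount; thickStart/thickEnd
    define the CDS (equal values mean noncoding, no UTRs).
    """
    models: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise FormatError(f"{path}:{lineno}: BED12 needs 12 fields")
            chrom, start, end, name, _score, strand = parts[:6]
            start, end = int(start), int(end)
            thick_s, thick_e = int(parts[6]), int(parts[7])
            n_blocks = int(parts[9])
            sizes = [int(x) for x in parts[10].rstrip(",").split(",") if x]
            starts = [int(x) for x in parts[11].rstrip(",").split(",") if x]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise FormatError(
                    f"{path}:{lineno}: blockCount={n_blocks} but "
                    f"{len(sizes)} sizes / {len(starts)} starts"
                )
            exons = [(start + off, start + off + sz) for off, sz in zip(starts, sizes)]
            thick = None if thick_s == thick_e else (thick_s, thick_e)
            models.append(
                GeneModel(name, chrom, start, end, strand, exons=exons, thick=thick)
            )
    return models


def write_gene_models_bed12(models: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in sorted(models, key=lambda g: (g.chrom, g.start, g.gene_id)):
            thick_s, thick_e = m.thick if m.thick else (m.start, m.start)
            sizes = ",".join(str(e - s) for s, e in m.exons) + ","
            offs = ",".join(str(s - m.start) for s, e in m.exons) + ","
            fh.write(
                f"{m.chrom}\t{m.start}\t{m.end}\t{m.gene_id}\t0\t{m.strand}\t"
                f"{thick_s}\t{thick_e}\t0\t{len(m.exons)}\t{sizes}\t{offs}\n"
            )


# ---------------------------------------------------------------------------
# Peaks (BED3+)


@dataclass
class PeakInterval:
    chrom: str
    start: int
    end: int
    sample_id: str
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"peak {self.chrom}:{self.start}-{self.end}: start >= end"
            )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def read_bed_peaks(path: str | Path, sample_id: str) -> list[PeakInterval]:
    """Read BED3+ peak intervals; column 4 (if numeric) is the score."""
    peaks: list[PeakInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates")
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            score = None
            if len(parts) >= 4:
                try:
                    score = float(parts[3])
                except ValueError:
                    score = None
            peaks.append(PeakInterval(chrom, start, end, sample_id, score))
    if not peaks:
        logger.info("no peaks in %s", path)
    return peaks


def write_bed_peaks(peaks: Iterable[PeakInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in sorted(peaks, key=lambda q: (q.chrom, q.start, q.end, q.sample_id)):
            score = "." if p.score is None else f"{p.score:g}"
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{score}\n")


# ---------------------------------------------------------------------------
# Gene sets (GMT)


@dataclass
class GeneSetCollection:
    """Named gene sets, e.g. MSigDB hallmark collections."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise FormatError(f"gene set {name!r} has duplicate genes")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (name, description, genes...), deduplicating genes
    within a line with a logged warning; duplicate set names are an error."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            deduped = list(dict.fromkeys(genes))
            if len(deduped) != len(genes):
                logger.warning(
                    "%s:%d: %d duplicate genes in set %s",
                    path, lineno, len(genes) - len(deduped), name,
                )
            sets[name] = deduped
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc] + collection.sets[name]) + "\n")


# ---------------------------------------------------------------------------
# Result tables


def write_results_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a result table with deterministic column and row order.

    Rows sort by gene_id then sample_id where those columns exist,
    otherwise by all columns left to right.
    """
    df = table.copy()
    if df.index.name is not None:
        df = df.reset_index()
    sort_cols = [c for c in ("gene_id", "sample_id") if c in df.columns]
    if not sort_cols:
        sort_cols = list(df.columns)
    df = df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
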