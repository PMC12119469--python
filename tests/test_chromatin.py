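import itertools

import numpy as np
import pandas as pd
import pytest

from lobeomics.chromatin import (
    FEATURE_PRECEDENCE,
    PeakAnnotation,
    RegionSignal,
    aggregate_region_signal,
    annotate_interval,
    promoter_fraction,
    shift_type,
    spikein_factors,
)
from lobeomics.io import GeneModel, PeakInterval, SampleSheet


# ---------------------------------------------------------------------------
# Independent annotation oracle: enumerate every (gene, category) pair the
# midpoint could take and pick by precedence, then |distance|, then gene_id.


def oracle_annotate(peak, models, promoter=(-3000, 3000), downstream=3000):
    mid = (peak.start + peak.end) // 2
    rank = {c: i for i, c in enumerate(FEATURE_PRECEDENCE)}
    candidates = []
    for g in models:
        if g.chrom != peak.chrom:
            continue
        tss = g.start if g.strand == "+" else g.end - 1
        off = mid - tss if g.strand == "+" else tss - mid
        cats = []
        if promoter[0] <= off <= promoter[1]:
            cats.append("Promoter")
        if g.start <= mid < g.end:
            exonic = any(s <= mid < e for s, e in g.exons)
            if not exonic:
                cats.append("Intron")
            elif g.thick is None:
                cats.append("Exon")
            else:
                ts, te = g.thick
                if mid < ts:
                    cats.append("FivePrimeUTR" if g.strand == "+" else "ThreePrimeUTR")
                elif mid >= te:
                    cats.append("ThreePrimeUTR" if g.strand == "+" else "FivePrimeUTR")
                else:
                    cats.append("Exon")
        tes = g.end - 1 if g.strand == "+" else g.start
        ds = mid - tes if g.strand == "+" else tes - mid
        if 0 < ds <= downstream:
            cats.append("Downstream")
        for c in cats:
            candidates.append((rank[c], abs(mid - tss), g.gene_id, c))
    if not candidates:
        chrom_genes = [g for g in models if g.chrom == peak.chrom]
        if not chrom_genes:
            return "DistalIntergenic", None
        tsss = [(abs(mid - (g.start if g.strand == "+" else g.end - 1)), g.gene_id)
                for g in chrom_genes]
        return "DistalIntergenic", min(tsss)[1]
    best = min(candidates)
    return best[3], best[2]


def random_genome(rng, n_genes, chrom_len=100_000):
    models = []
    cursor = 0
    for i in range(n_genes):
        start = cursor + int(rng.integers(0, 3000))
        span = int(rng.integers(500, 8000))
        end = start + span
        if end >= chrom_len:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(1, 4))
        if n_ex > 1 and span > 2 * n_ex + 2:
            cuts = np.sort(rng.choice(np.arange(1, span), size=2 * n_ex - 2, replace=False))
            edges = np.concatenate([[0], cuts, [span]])
            exons = [(start + int(edges[2 * k]), start + int(edges[2 * k + 1]))
                     for k in range(n_ex)]
        else:
            exons = [(start, end)]
        thick = None
        if rng.random() < 0.7 and span > 200:
            ts = start + int(rng.integers(1, span // 2))
            te = ts + int(rng.integers(1, span - (ts - start)))
            thick = (ts, te)
        models.append(GeneModel(f"g{i}", "chr1", start, end, strand, exons, thick))
        cursor = end
    return models


class TestSpikeinFactors:
    def test_unit_factor_at_constant(self):
        f = spikein_factors(pd.Series({"s1": 10000}))
        assert f["s1"] == 1.0

    def test_inverse_proportionality(self):
        f = spikein_factors(pd.Series({"s1": 5000, "s2": 20000}))
        assert f["s1"] == 2.0 and f["s2"] == 0.5

    def test_zero_reads_errors_with_sample_name(self):
        with pytest.raises(ValueError, match="s2"):
            spikein_factors(pd.Series({"s1": 100, "s2": 0}))


class TestAnnotateInterval:
    def _gene(self, **kw):
        defaults = dict(gene_id="g1", chrom="chr1", start=10000, end=20000,
                        strand="+", exons=[(10000, 11000), (19000, 20000)])
        defaults.update(kw)
        return GeneModel(**defaults)

    def test_midpoint_at_tss_is_promoter_distance_zero(self):
        gene = self._gene()
        ann = annotate_interval(PeakInterval("chr1", 9950, 10050, "s"), [gene])
        assert (ann.category, ann.gene_id, ann.distance_to_tss) == ("Promoter", "g1", 0)

    def test_intron_outside_promoter_window(self):
        gene = self._gene()
        ann = annotate_interval(PeakInterval("chr1", 14000, 14200, "s"), [gene])
        assert ann.category == "Intron"

    def test_far_peak_is_distal_with_nearest_gene(self):
        gene = self._gene()
        ann = annotate_interval(PeakInterval("chr1", 110000, 110100, "s"), [gene])
        assert ann.category == "DistalIntergenic"
        assert ann.gene_id == "g1"

    def test_promoter_precedence_over_exon(self):
        # exon of g1 inside g2's promoter window: promoter wins
        g1 = self._gene()
        g2 = GeneModel("g2", "chr1", 21000, 30000, "+", exons=[(21000, 30000)])
        ann = annotate_interval(PeakInterval("chr1", 19400, 19600, "s"), [g1, g2])
        assert ann.category == "Promoter"
        assert ann.gene_id == "g2"

    def test_unknown_chromosome_distal_no_gene(self):
        ann = annotate_interval(PeakInterval("chrX", 100, 200, "s"), [self._gene()])
        assert ann.category == "DistalIntergenic"
        assert ann.gene_id is None

    def test_fuzz_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(60):
            models = random_genome(rng, int(rng.integers(1, 15)))
            if not models:
                continue
            for _ in range(30):
                pos = int(rng.integers(0, 100_000))
                length = int(rng.integers(1, 400)) * 2 + 1  # odd length
                peak = PeakInterval("chr1", pos, pos + length, "s")
                ann = annotate_interval(peak, models)
                cat, gid = oracle_annotate(peak, models)
                assert (ann.category, ann.gene_id) == (cat, gid)

    def test_strand_mirror_invariance(self):
        rng = np.random.default_rng(7)
        L = 100_000
        for _ in range(40):
            models = random_genome(rng, int(rng.integers(1, 12)))
            if not models:
                continue
            mirrored = [
                GeneModel(
                    g.gene_id, g.chrom, L - g.end, L - g.start,
                    "-" if g.strand == "+" else "+",
                    [(L - e, L - s) for s, e in reversed(g.exons)],
                    None if g.thick is None else (L - g.thick[1], L - g.thick[0]),
                )
                for g in models
            ]
            for _ in range(20):
                pos = int(rng.integers(0, L - 1001))
                length = int(rng.integers(0, 500)) * 2 + 1
                peak = PeakInterval("chr1", pos, pos + length, "s")
                mpeak = PeakInterval("chr1", L - (pos + length), L - pos, "s")
                a = annotate_interval(peak, models)
                b = annotate_interval(mpeak, mirrored)
                assert a.category == b.category


class TestAggregateRegionSignal:
    def _sheet(self):
        return SampleSheet(
            pd.DataFrame(
                {"group": ["C", "G"], "lobe": ["L", "L"], "replicate": [1, 1]},
                index=pd.Index(["s1", "s2"], name="sample_id"),
            )
        )

    def _gene(self):
        return GeneModel("g1", "chr1", 10000, 20000, "+", exons=[(10000, 20000)])

    def test_all_promoter_peaks_give_zero_other(self):
        anns = [
            PeakAnnotation(PeakInterval("chr1", 9900, 10100, "s1", 5.0), "Promoter", "g1", 0),
            PeakAnnotation(PeakInterval("chr1", 10500, 10700, "s1", 3.0), "Promoter", "g1", 600),
        ]
        rs = aggregate_region_signal(anns, self._sheet())
        assert rs.promoter.loc["g1", "s1"] == 8.0
        assert rs.other.loc["g1", "s1"] == 0.0

    def test_hand_built_three_peak_tally(self):
        anns = [
            PeakAnnotation(PeakInterval("chr1", 9900, 10100, "s1", 5.0), "Promoter", "g1", 0),
            PeakAnnotation(PeakInterval("chr1", 15000, 15100, "s1", 2.0), "Intron", "g1", 5050),
            PeakAnnotation(PeakInterval("chr1", 19000, 19100, "s2", 7.0), "Exon", "g1", 9050),
        ]
        rs = aggregate_region_signal(anns, self._sheet())
        assert rs.promoter.loc["g1", "s1"] == 5.0
        assert rs.other.loc["g1", "s1"] == 2.0
        assert rs.other.loc["g1", "s2"] == 7.0

    def test_scale_factor_doubles_signal(self):
        anns = [
            PeakAnnotation(PeakInterval("chr1", 9900, 10100, "s1", 5.0), "Promoter", "g1", 0),
            PeakAnnotation(PeakInterval("chr1", 15000, 15100, "s1", 2.0), "Intron", "g1", 5050),
        ]
        factors = pd.Series({"s1": 2.0, "s2": 1.0})
        rs = aggregate_region_signal(anns, self._sheet(), scale_factors=factors)
        assert rs.promoter.loc["g1", "s1"] == 10.0
        assert rs.other.loc["g1", "s1"] == 4.0

    def test_distal_beyond_max_distance_unassigned(self):
        anns = [
            PeakAnnotation(
                PeakInterval("chr1", 500_000, 500_100, "s1", 9.0),
                "DistalIntergenic", "g1", 490_050,
            ),
        ]
        rs = aggregate_region_signal(anns, self._sheet(), max_distal_distance=100_000)
        assert rs.other.loc["g1", "s1"] == 0.0


class TestPromoterFraction:
    def _signal(self, p, o):
        sheet = SampleSheet(
            pd.DataFrame(
                {"group": ["C"], "lobe": ["L"], "replicate": [1]},
                index=pd.Index(["s1"], name="sample_id"),
            )
        )
        return RegionSignal(
            pd.DataFrame({"s1": p}, index=[f"g{i}" for i in range(len(p))]),
            pd.DataFrame({"s1": o}, index=[f"g{i}" for i in range(len(p))]),
            sheet,
        )

    def test_extremes(self):
        assert promoter_fraction(self._signal([5, 5], [0, 0]), "s1") == 1.0
        assert promoter_fraction(self._signal([0, 0], [4, 4]), "s1") == 0.0

    def test_zero_total_errors(self):
        with pytest.raises(ValueError, match="zero total"):
            promoter_fraction(self._signal([0], [0]), "s1")

    def test_synthetic_baseline_realized(self, chromatin_sim):
        _, (signal, _, truth) = chromatin_sim
        scaled = signal.apply_spikein(spikein_factors(truth.spike_in_reads))
        frac = promoter_fraction(scaled)
        assert ((frac >= 0.55) & (frac <= 0.65)).all()


class TestShiftType:
    @pytest.mark.parametrize(
        "dP,dO,expected",
        [
            (1, -1, "Type1"),
            (-1, 1, "Type2"),
            (1, 1, "Type3"),
            (0, -1, "Type3"),
            (0, 0, "None"),
        ],
    )
    def test_declared_convention(self, dP, dO, expected):
        assert shift_type(dP, dO) == expected

    def test_nine_cell_partition(self):
        cells = {
            (p, o): shift_type(p, o)
            for p, o in itertools.product((-1, 0, 1), repeat=2)
        }
        from collections import Counter

        counts = Counter(cells.values())
        assert counts == {"Type3": 6, "Type1": 1, "Type2": 1, "None": 1}

    def test_invalid_trit_rejected(self):
        with pytest.raises(ValueError):
            shift_type(2, 0)
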