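# lobeomics

Lobe-resolved multiomic analysis of graft-versus-host disease (GVHD) lungs
under mesenchymal stem cell (MSC) treatment.

Acute GVHD damages the lung unevenly across its five lobes (H, the lobe
behind the heart; L, left; R1/R2/R3, the right lobes), and placenta-derived
MSCs (group **M**) partially reverse both the transcriptional and the
chromatin (H3K27ac) disturbances seen in the GVHD (**G**) and vehicle PBS
(**P**) arms relative to healthy controls (**C**). `lobeomics` implements
the statistical machinery of that analysis as a reusable, tested pipeline
that runs end to end on synthetic data with planted ground truth — no
sequencing downloads required.

## What it computes

**Gated differential changes.** For each gene and each pairwise comparison
*j* vs *i* (GvC, MvG, PvG, MvP) within a lobe, a negative-binomial Wald
test yields a log2 fold change and BH-adjusted p-value, reduced to the
significance-gated signed change

```
g = log2FC   if p.adj <= 0.05
g = 0        otherwise
```

**Five-type trend taxonomy.** The sign pattern of *g* across comparisons
classifies each gene as NE (no effect), Rein01/Rein02 (GVHD change
reversed by treatment — Rein02 when the reversal is specific to the MSC
arm), SR (self-recovery: reversed in the vehicle arm alone) or Whip01
(treatment pushes in the GVHD direction). The rule table is configuration
(ordered trit patterns with wildcards), and shared / lobe-specific gene
sets are computed over all 2^5 lobe-membership classes.

**Chromatin arm.** H3K27ac signal is spike-in calibrated (factor
`10000 / spike reads`), peaks are annotated to genomic features by
midpoint with promoter precedence (TSS ± 3 kb), and per-gene
promoter (P) vs other (O) signal is tested with the same gated engine.
The pair of gated signs (dP, dO) types each gene: Type1 = promoter up /
other down, Type2 = the mirror, Type3 = any other significant change.

**Concordance (a-DEGs).** Genes whose gated RNA change and gated promoter
H3K27ac change are both nonzero with the same sign, intersected with the
shared/specific Rein02 sets.

**Enrichment and stratification.** Preranked GSEA (classic weighted
running sum, gene-set permutation NES) on the gated changes; a
deterministic single-sample rank-walk score (ssGSEA-style, weight
rank^0.25) per cell; single-cell QC at the published bounds
(nFeature 400–7000, nCount 500–80000, mito ≤ 15 %, ribo ≤ 40 %); median
stratification on a 16-gene treatment signature; and Welch t statistics
per pathway between signature-high and -low cells, zeroed wherever the
BH-adjusted p exceeds 0.05.

## Worked example

```bash
lobeomics simulate --data-dir bundle --seed 11
lobeomics all --data-dir bundle --out-dir out --seed 11
```

The first command writes a seeded synthetic bundle (bulk counts over
4 groups × 5 lobes, promoter/other chromatin counts with spike-in reads,
peaks, gene models, gene sets, a single-cell matrix with QC metrics, and
truth tables). The second runs every stage. Inspecting the outputs:

```
$ cut -f1,2 out/trend/shared_specific.tsv | head -3
set_name        n_genes
shared  16
H_specific      5
```

Sixteen Rein02-type genes are recovered in all five lobes of this tiny
bundle and five only in the H lobe (the generator plants a fraction of
lobe-specific effect genes). `out/chrom/promoter_fraction.tsv` shows each
chromatin sample's promoter share of total signal (0.609, 0.598, … — the
planted baseline is 0.6), `out/adeg/adegs.tsv` lists the accordant genes per comparison
and lobe, and `out/enrich/gated_t.tsv` holds the gated t matrix of the
T-cell compartment — pathways that do not separate signature-high from
signature-low cells at BH ≤ 0.05 appear as exact zeros.

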