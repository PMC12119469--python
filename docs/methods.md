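# Methods

This note documents the statistical models behind `lobeomics`, the
parameters that matter, what the synthetic data generator does and does
not emulate, and the design decisions taken where the design was open.

## Differential model and the significance gate

Bulk RNA and H3K27ac region counts are modelled as negative binomial with
mean `mu` and dispersion `phi`, variance `mu + phi * mu^2`. Library depth
is removed by median-of-ratios size factors (genes containing any zero
are excluded from the reference; if no gene is all-nonzero the caller
must supply explicit factors, e.g. spike-in derived ones). For a
comparison of numerator group *j* against denominator *i* within a lobe:

* `log2fc = log2((m_j + c) / (m_i + c))` on normalized group means, with
  pseudocount `c = 0.5` stabilising low counts;
* the Wald standard error comes from the delta method on the shrunken
  log mean. The count-variance numerator `m + phi * m^2 + c/2` is
  evaluated at the observed group mean with a floor of half the
  pseudocount (so zero-count groups keep positive variance), and the
  shrinkage enters through the `(m + c)^2` denominator. This form was
  calibrated against the Monte-Carlo standard deviation of the shrunken
  estimator across depths;
* two-sided p-values use a **t reference with the residual degrees of
  freedom behind the plugged-in dispersion estimate**, not the plain
  normal. At high counts the statistic is exactly a two-sample t with a
  few-dof variance estimate, and the normal reference is anti-conservative
  by more than a factor of two (null fraction ~0.12 instead of ~0.05 at
  n = 3 per group). The t reference restores near-nominal type-I error
  (measured 0.04–0.06) and converges to the normal as replication grows.

Dispersion is per-gene method of moments, `phi = max(phi_min,
(s^2 - mu) / mu^2)` on normalized counts with group means removed,
`phi_min = 1e-8`. When the full design is available
(`run_all_comparisons`), the residual variance is pooled across every
(group, lobe) cell — a per-gene assumption that dispersion is shared
across conditions, which raises the residual dof from 4 to 40 in the
default design. This is *not* shrinkage across genes, which the engine
deliberately avoids. The chromatin stage additionally averages the
promoter-track and other-track estimates per gene (dispersion shared
between a gene's two region tracks), doubling the dof again.

Multiple testing is Benjamini–Hochberg per comparison per lobe over all
tested genes (via `statsmodels`). The gate is

    g = log2fc  if p.adj <= alpha (default 0.05),  else 0

and every downstream stage consumes only `g`. Genes with zero counts
everywhere are reported with `g = 0` rather than dropped so set algebra
across lobes has a common universe.

## Trend taxonomy

The sign trits of `g` over (GvC, MvG, PvG, MvP) feed an ordered rule
table; the first matching rule wins and unmatched patterns fall back to
NE. With `s1 = sign(g_GvC)`, `s2 = sign(g_MvG)`, `s3 = sign(g_PvG)`:

1. **Rein02**: `s2 != 0` and either (`s1 != 0`, `s2 = -s1`, `s3 != -s1`)
   or (`s1 = 0`, `s3 != 0`, `s2 = -s3`) — the treatment arm reverses a
   GVHD-associated change that the vehicle arm does not reverse;
2. **Rein01**: `s1 != 0`, `s2 = -s1`, `s3 = -s1` — reversal in both arms;
3. **SR**: `s1 != 0`, `s3 = -s1`, `s2 = 0` — vehicle-only reversal;
4. **Whip01**: `s1 != 0`, `s2 = s1` — treatment pushes with the disease;
5. **NE** otherwise.

`s_MvP` is computed and stored but unused by the default rules. The table
is serialisable (YAML, trit patterns with `*` wildcards), every one of
the 81 patterns maps to exactly one label, and each default rule is
sign-symmetric, so negating a pattern never changes its label. Whether
Rein01 and Rein02 split exactly this way (vehicle-also-reversed vs
treatment-specific reversal) is a declared reading of the taxonomy's
prose description; alternative readings belong in the config, not the
engine.

## Chromatin arm

Spike-in calibration multiplies each sample's signal by `10000 / n_spike`,
equalising expected exogenous-chromatin signal. Peak annotation is by
midpoint: among every gene whose promoter window (TSS ± 3 kb,
strand-aware), gene body (exon / intron / UTRs from the BED12 thick
range) or downstream window (3 kb) contains the midpoint, the
highest-precedence category wins (Promoter > 5'UTR > 3'UTR > Exon >
Intron > Downstream > DistalIntergenic), with ties broken by TSS distance
then gene id. Midpoint assignment gives every peak exactly one category.
DistalIntergenic signal is credited to the nearest gene's "other" track
only within 100 kb; beyond that it is unassigned.

Shift typing runs the gated differential engine on the promoter track and
the other track separately (raw counts with spike-in size factors, same
alpha) and classifies the trit pair: Type1 = (+1, −1), Type2 = (−1, +1),
None = (0, 0), Type3 = the remaining six cells. The direction convention
(Type1 = promoter-gain/other-loss) is a label choice, not a finding.
Gating *both* regions on adjusted significance is a design decision; an
alternative would type raw sign changes.

## Concordance

An a-DEG for one (comparison, lobe) is a gene with nonzero gated change
in both the RNA result and the promoter H3K27ac result and the same sign.
No magnitude-agreement threshold is applied. By construction the a-DEG
set is a subset of the intersection of the two DEG sets.

## Enrichment and stratification

Preranked GSEA ranks genes by `g` descending (zeros excluded, ties by
gene id) and uses the classic weighted running sum: a hit adds
`|score|^p / sum_hits |score|^p` (p = 1), a miss subtracts
`1/(N - N_hits)`; ES is the extremum of largest magnitude. The null draws
`n_perm = 1000` random same-size gene sets from the ranked universe
(gene-set permutation, not phenotype permutation — the pipeline consumes
ranked lists); `NES = ES / mean |null ES of matching sign|`, p is the
empirical same-sign tail probability floored at `1/(n_perm+1)`, BH across
sets.

The per-cell score is the deterministic single-sample rank-walk: genes
ranked within the cell (descending, rank value N at the top), score =
sum over ranks of (weighted in-set ECDF with weights `rank^0.25` minus
unweighted out-of-set ECDF), normalized by `N − |S|`. It is invariant
under strictly monotone transforms of the expression vector, hence
insensitive to per-cell depth scaling.

Single-cell QC flags a cell when any printed bound is violated
(`nFeature < 400` or `> 7000`; `nCount < 500` or `> 80000`;
mitochondrial > 15 %; ribosomal > 40 %); bounds are strict inequalities,
so boundary values pass. The signature score is the mean per-gene
standardized log1p expression of the signature genes (no control-bin
correction), split at the median with ties going low. Marker testing is a
two-sided rank-sum test restricted to genes detected in ≥ 30 % of at
least one group, exact by enumeration when the assignment count is small
(≤ 20000 combinations), tie-corrected asymptotic otherwise.

The stratified test compares per-cell pathway scores between
signature-high and -low cells with Welch's t, BH-adjusted within each
cell type across pathways, and zeroes t wherever the adjusted p exceeds
0.05. Two deliberate safeguards:

* pathway scores are computed on the matrix **with the stratifying
  signature genes removed**, and the signature set itself is not part of
  the tested panel. Splitting cells on the signature score displaces the
  within-cell ranks of every other gene, and with the signature genes in
  the scored universe, null pathways test systematically negative (16 of
  20 null runs produced spurious BH-significant hits in development);
* the analysis focuses on the T-cell compartment (the biological target
  of the stratification question). Each cell type is one BH family, so
  each additional tested compartment adds an independent ~5 % chance of a
  false rejection under the global null; restricting to the compartment
  of interest keeps the family-wise behaviour interpretable.

## Synthetic data generator

The generator emulates the study's statistical structure, not its
biology: negative-binomial counts (gamma–Poisson) matching the engine's
noise model, per-sample size factors log-uniform in [0.5, 2], one RNG
stream per dataset with deterministic per-component sub-streams
(identical seed ⇒ identical bytes).

* **Bulk** (`sim_bulk`): 4 groups × 5 lobes × n replicates (default 3).
  `depth` is the mean per-gene baseline count at size factor 1 (default
  1e4, a deep bulk library); per-gene baselines are log-normal (σ = 0.8)
  around it. Planted labels (default 60 % NE, 10 % each effect class) map
  to group offsets derived from each label's canonical sign pattern
  (C = 0, G = s1·δ, M = G + s2·δ, P = G + s3·δ, with δ = ±effect,
  default 2.5 log2 units, sign random per gene). The canonical patterns
  are asserted against the active rule table at generation time, so a
  table edit that breaks them fails loudly.
* **Chromatin** (`sim_chromatin`): per-gene promoter/other counts for
  4 groups in one lobe, promoter share Beta-distributed around 0.6,
  spike-in reads Poisson around `spike_mean` scaled by a per-sample
  pulldown efficiency that also scales the signal (so calibration has
  something to remove). Shift genes change only in the contrast's
  numerator group. Dispersion defaults to 0.03 (CV ≈ 17 %): region-level
  counts aggregate many fragments across a track, and the default was
  chosen so that the generator's stated recovery contract (≥ 80 % exact
  typing of 2-fold opposing shifts at default depth and n = 3) is
  attainable — the closed-form information bound
  `sd(log2fc) = sqrt(2 phi / n) / ln 2` makes that contract infeasible
  for phi ≳ 0.045 regardless of the test used.
* **Single cell** (`sim_sc`): eight lung cell types with the published
  marker genes elevated only in their own type, the 16-gene treatment
  signature elevated in planted 'high' cells, a disjoint planted pathway
  set co-moving with the stratum, and QC metrics drawn strictly inside
  every bound for clean cells and strictly outside one bound for a
  planted outlier fraction.

What the generator does **not** emulate: batch effects beyond size
factors, gene–gene correlation, depth-driven QC metrics (metrics are
drawn independently of the matrix), zero inflation, doublets, or
chromatin peak shapes. Passing tests therefore demonstrate that the
statistical machinery is correct and calibrated under its own model
assumptions — not that those assumptions hold in any particular real
dataset.

## Numerical and degenerate-input conventions

Pseudocount 0.5; dispersion floor 1e-8; all-zero genes report (0, 1) not
NA; gate treats missing adjusted p as 0; ranked-list and within-cell ties
break lexicographically by gene id; stratification ties go low;
empirical permutation p is floored at `1/(n_perm+1)`; identical-multiset
groups short-circuit to p = 1. All coordinates are 0-based half-open
end to end; output tables are written in sorted order so reruns are
byte-identical.

## Problem sizes

The test suite and the acceptance script run the study conditions at
desk scale: 1000–2000 bulk genes with 3 replicates per (group, lobe)
cell, 300 chromatin genes with 4 × 3 samples, and 20 repetitions of a
2000-cell single-cell simulation. These sizes give stable Monte-Carlo
estimates of every reported rate while completing in seconds.

## Known limitations

Per-gene method-of-moments dispersion is noisy at small designs (the t
reference compensates for calibration, not for power); the GSEA null is
gene-set permutation only; the per-cell scorer implements the rank-walk
statistic, not the kernel-ECDF variant (exposed as the only method); the
annotation engine scans genes linearly per peak, which is fine for
desk-scale genomes but would want an interval index genome-wide; and the
trend taxonomy's Rein01/Rein02 boundary follows the declared reading
above.
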