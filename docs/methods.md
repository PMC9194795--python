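# Methods

## The quantity everything rests on

For a gene *g* in a sample, cluster or cell of an F1 hybrid cross, the
**allelic ratio** is

    r_g = a1 / (a1 + a2)

where `a1` and `a2` are the read counts assigned to the two parental
alleles. By convention allele 1 is the allele subject to inactivation —
X^mus in the in vitro system (the allele carrying the inducible silencing),
the paternal C57 allele in the CAST × C57 E6.5 cross — so silencing drives
*r* towards 0, biallelic expression sits near 0.5, and the silencing
cut-off (default **0.135**) is a lower bound: *r* ≤ 0.135 means the gene is
X-inactive, *r* > 0.135 means it is (still or again) active.

Figure legends in the source literature for this kind of analysis sometimes
describe mono-allelic expression of the *other* allele as ratios between
0.5 and 1, which is inconsistent with a lower silencing cut-off on the same
axis; this package fixes one orientation (allele 1 = the silencing-prone
allele, low = inactive) and exposes `inactive_side="high"` in the
classifiers plus `AllelicCountMatrix.swap_alleles()` for data delivered in
the opposite orientation.

A (gene, group) ratio is only reported when its pooled allelic read support
reaches `min_allelic_total_per_gene_group` (default 10, inclusive); below
that it is *undetected* (NaN) and propagates as such.

### Pooling

Replicates of a bulk stage, and cells of a cluster, are pooled by **summing
counts before dividing**, not by averaging per-unit ratios. At low counts a
per-unit ratio is ill-defined or wildly variable; summing weights every
read equally and is well-defined whenever the pooled support gate passes.
The per-**cell** average ratio (below) is the one deliberate exception.

## Estimating the silencing cut-off

The cut-off can be re-estimated from a reference population known to have
completed X-inactivation (e.g. neural progenitor cells): the distribution
of ratios over genes biallelic in ESCs is bimodal there — a silenced mode
near 0 and an escapee mode near 0.5 — and the cut-off is the valley between
them. `estimate_xci_threshold`:

1. fits a Gaussian KDE (Silverman bandwidth by default) to the ratios
   (≥ 30 finite values required),
2. evaluates it on a grid over [0, 1] with step 0.001,
3. locates the two highest-density modes (grid endpoints may host a mode),
4. returns the lowest-density local minimum strictly between them.

A **valley-prominence rule** guards against finite-sample wiggles: the
valley density must be at most 90% of the lower of the two mode densities,
otherwise the sample is treated as effectively unimodal and the configured
default (0.135) is returned with a warning. Without this rule a KDE of a
genuinely unimodal sample (e.g. a few hundred Beta(20,20) draws) routinely
presents a shallow spurious minimum on a flank.

## Gene classification

### Silencing kinetics (bulk)

Stages are ordered (reference ESC-like, intermediate EpiLC-like, final
XGFP⁻ PGCLC-like). Per gene, with threshold *t* and the open biallelic
window (0.3, 0.7):

1. reference ratio undetected → `undetected`;
2. reference ratio outside the open window → `excluded_nonbiallelic`
   (the gene was not informatively biallelic to begin with; 0.3 and 0.7
   themselves are excluded);
3. intermediate or final undetected → `undetected`;
4. intermediate ≤ *t* → `earlyXCI`;
5. else final ≤ *t* → `lateXCI`;
6. else → `escapee`.

Ties at the threshold are inactive (≤). The five categories are mutually
exclusive and exhaustive by construction.

### Reactivation kinetics (single cell)

Groups are ordered (bulk XGFP⁻ PGCLC, pooled pre-meiotic, pooled meiotic).
Rules, applied in order: all three above *t* → `escapee`; silent in PGCLCs
and active pre-meiotically → `earlyXCR`; silent through pre-meiosis and
active in meiosis → `lateXCR`; silent in meiosis → `noXCR` (checked last,
so a gene active earlier but silent in meiosis is `noXCR`). Any undetected
group, or a non-monotone residual none of the rules cover (active → silent
→ active), is `unclassified`.

## Bulk pipeline

- **Expression filter**: genes with mean total (non-allelic) count strictly
  above 10 across all samples are kept; genes flagged as annotation-patch
  entries are removed regardless.
- **Size factors**: median-of-ratios. Per gene the geometric mean across
  samples is formed over genes nonzero in *every* sample; a sample's factor
  is the median of its count/geomean ratios. Factors only enter
  expression-level comparisons — allelic ratios are scale-free within a
  sample, so normalisation cancels and ratios are always computed from raw
  pooled counts.
- **Category expression comparison**: two-sided Mann-Whitney U per category
  pair on log2(1 + normalised counts) of one allele layer in one stage;
  exact enumeration when both groups have ≤ 8 genes, otherwise the
  tie-corrected normal approximation with continuity correction (matching
  R's `wilcox.test` behaviour at those sizes). Categories with < 3 genes
  are skipped with a warning.
- **Escapee overlap** against an external escapee list is plain set
  arithmetic after removing *Xist* from both sides (its ratio reflects the
  silencing machinery itself, not escape).
- A fully hybrid autosome (chr13 by default) runs through the identical
  classifier as a negative control; its genes should never be called
  inactive.

## Single-cell pipeline

Gates quote their sources' wording and keep its strictness:

| gate | profile `invitro_sc` | profile `e65_sc` | profile `invivo_germ` |
|---|---|---|---|
| detected genes ≥ | 4,000 | 4,000 | 2,000 |
| molecules ≥ | 10,000 | 10,000 | 2,000 |
| mito fraction ≤ | 0.05 | 0.05 | 0.05 |
| allelic reads > (strict) | 3,500 | 400 | 3,500 |
| allelic genes ≥ | 25 | 25 | 25 |
| minor-genotype fraction ≥ | 0.03 | — | 0.03 |
| informative gene detected in ≥ | 25% of cells | 20% | 25% |

Chain: non-allelic QC → log normalisation (log2 of 1 + counts per 10,000)
→ marker subsetting (default Dazl > 1; the in vivo germ-cell variant uses
Dazl > 0.5 with somatic markers Nr5a1/Axl/Fosb/Emx2/Gata4 < 0.5 via
`exclude=`) → allelic QC → informative genes (summed allelic reads strictly
above 10 *and* detected in the profile's cell fraction) → per-cell
profiles. Every input cell lands in exactly one bin:
`nonallelic_qc_fail`, `marker_fail`, `allelic_qc_fail` or `profiled`.

The **per-cell average allelic ratio** is the unweighted mean of per-gene
ratios over informative X-linked genes with ≥ 1 allelic read in that cell:
each gene votes once, so a single deep gene cannot dominate the
chromosome-wide call. A read-weighted (pooled-count) variant is available
behind `weighted=True` for sensitivity analysis. X status uses the closed
window [0.4, 0.6]: inside → `XaXa`; below → `XaXi` (allele 1 inactive);
above → `XiXa`.

**Cluster summaries** report status fractions over status-called cells and
the escapee fraction among silenced cells: each XaXi/XiXa cell's counts are
first oriented so its *own* inactive allele is the numerator (random XCI
makes a fixed orientation wrong), oriented counts are pooled across the
cluster's silenced cells, and the fraction of detected X genes whose
inactive-allele ratio exceeds the cut-off is reported.

The **pluripotency score** is the per-cell mean of across-cell z-scores
(population SD; a constant gene contributes 0) of the log-normalised
expression of Pou5f1, Sox2, Nanog, Klf2, Esrrb, Dppa3, Tfcp2l1 and Prdm14;
absent genes are skipped with a warning.

The E6.5 mode (`run_e65`) applies the same machinery under the `e65_sc`
profile and stops after cluster summaries (no reactivation trajectory
exists at a single developmental time point). When a matrix carries no
totals layer the chain starts at the allelic gates.

## Synthetic data

The generators plant known truth at desk scale so recovery is measurable.

- **Depth**: negative binomial with mean `depth_mean` and gamma-Poisson
  dispersion (`dispersion=0` degenerates to Poisson) — per gene × sample in
  bulk, per cell in single-cell mode (allocated to genes by a multinomial
  over fixed gamma-distributed gene weights). Dropout emerges from
  sampling; there is no separate zero-inflation term.
- **Allelic split**: beta-binomial with mean = planted ratio and
  overdispersion ρ = 1/(α+β+1); ρ = 0 is an exact binomial. Defaults:
  ρ = 0.01, bulk NB dispersion 0.05, bulk depth 2,000 reads/gene/sample,
  single-cell allelic depth 5,000 reads/cell. No dispersion estimates exist
  for the original data; these are conventions, exposed as parameters.
- **Planted bulk trajectories** (reference → intermediate → final):
  escapees hold a per-gene base drawn from U(0.45, 0.50); earlyXCI
  0.5 → 0.05 → 0.05; lateXCI 0.5 → 0.25 → 0.05; non-biallelic decoys hold a
  value from U(0.05, 0.22) or U(0.78, 0.95); chr13 controls hold 0.5.
  The silenced plateau is 0.05 because a planted "silenced" gene must sit
  clearly below the 0.135 cut-off under the generator's own noise: at
  ρ = 0.01 and pooled depth ~6,000 the ratio SD is ≈ 0.016, so 0.05 is
  ~5 SD below the cut-off while 0.08 would be only ~3.5 SD — close enough
  that, over hundreds of genes, apparent escape from silencing would be a
  regular artefact of the noise model rather than a planted property.
- **Reactivation trajectories** (PGCLC → pre-meiotic → meiotic → mitotic):
  escapee base ∈ U(0.45, 0.50) throughout; earlyXCR 0.05 → 0.45 → 0.48 →
  0.50; lateXCR 0.05 → 0.08 → 0.45 → 0.50; noXCR 0.05 everywhere,
  including the mitotic clusters — with few such genes the mitotic cells'
  average ratio still sits inside [0.4, 0.6], i.e. the clusters are fully
  reactivated at the cell level while the refractory genes stay silent.
- **Exact planting**: requested category counts, the number of QC-failing
  cells (`round(frac · n)`, cycling through three deterministic failure
  modes: allelic reads drawn below the gate; expression confined to 10
  genes; near-complete single-genotype skew) and per-cluster XaXa counts
  (`round(f · n)`, silenced remainder split evenly between orientations)
  are hit exactly. Recovery tests therefore measure the pipeline, not
  binomial planting noise. Good cells draw their depth conditioned on
  exceeding the profile's read gate for the same reason.
- **Totals layer** (in vitro single-cell mode): 6,000 autosomal background
  genes (gamma weights), a 10-gene mitochondrial block at ~2.2% of reads, a
  Dazl-like marker at ~0.5%, and the eight pluripotency genes, allocated
  from ~30,000 molecules/cell; X-gene totals are the allelic totals plus
  Poisson extra reads, keeping totals ≥ allelic sums everywhere. Somatic
  contaminant cells carry zero marker expression and fall at the marker
  gate. The E6.5 generator emits no totals layer (its public source data
  are allelic tables), so analysis starts at the allelic gates. The default
  E6.5 scenario plants the proximal-epiblast conditions: XaXa fraction 0.25
  there vs 0.08 in the other epiblast clusters, escapee fraction 0.56 vs
  0.07, and imprinted silencing of allele 1 in all extraembryonic cells.
- **What the generators do not emulate**: real gene-length/GC biases,
  shared dispersion structure between genes, doublets, batch effects,
  cell-cycle covariation, spatially varying SNP density (every read is
  assignable), or clustering uncertainty (cluster labels are inputs
  throughout, as in the analysis this mirrors). Passing recovery tests
  therefore demonstrates the correctness of the decision rules and gates
  under the stated noise model, not robustness to those real-data effects.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed and is bitwise reproducible
(`numpy.random.default_rng`). The test-suite and acceptance scenarios use
the study-scale defaults: bulk 62/138/93 planted genes + 41 decoys + 294
chr13 controls, 3 replicates × 3 stages at depth 2,000; single-cell
78/58/17/8 genes over 379 cells in five clusters (or 20/15/5/3 over 500
cells for the recovery scenario) at depth 5,000; E6.5 120 genes with the
six observed cluster sizes (239 cells) or 200 cells/cluster for fraction
recovery. Grid step for the KDE is 0.001; serialised ratios carry 6
decimals.

## Known limitations

- The orientation convention must be supplied correctly for new crosses;
  nothing in the counts themselves identifies which allele is
  silencing-prone.
- The data-driven cut-off depends on the reference population being
  genuinely bimodal; the prominence rule falls back to 0.135 rather than
  guessing.
- `compare_category_expression` uses the asymptotic Mann-Whitney above
  n = 8 even with few ties, where R would enumerate exactly up to n = 50;
  p-values there can differ in the third decimal.
- Classification treats stage/cluster pooled ratios as point estimates; no
  uncertainty is propagated and no significance test for allelic imbalance
  is performed (the method is threshold-based by design).
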