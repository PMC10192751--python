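# Methods

`codonbias` implements the classical codon-usage-bias toolkit for sets of
mitochondrial protein-coding genes (PCGs), organized as strains × genes. The
target setting is the fungal mitochondrial core gene set: twelve conserved
PCGs per strain (atp6, cob, cox1–3, nad1–6, rps3) after excluding genes
shorter than 300 bp, extreme AT-richness, and strong third-position A/T
preference. Everything below operates on in-frame codon counts with the
terminal stop codon excluded.

## Genetic code and counting

Codon counts are taken over all in-frame triplets of a CDS, keyed in the RNA
alphabet. The default translation table is the NCBI standard code (table 1),
under which Met and Trp are singletons and 59 sense codons fall in
synonymous families of size k ∈ {2, 3, 4, 6}. The mold-mitochondrial code
(table 4, UGA → Trp) is available via configuration; it changes synonymy
(Trp becomes 2-fold, 62 sense codons), and with it GC3s, ENC and RSCU.
Table 1 is the default because the classical index definitions used in this
literature (CodonW/CAIcal conventions) assume Met, Trp and stops are
excluded as non-synonymous. Internal stop codons are reported as warnings —
mitochondrial annotations are frequently imperfect — and excluded, like
terminal stops, from every statistic. Triplets containing IUPAC ambiguity
codes are dropped with a logged count by default (strict mode raises).

## Usage indices

* **RSCU**: observed codon count divided by the mean count of its synonymous
  family; values in an observed family sum to k. Families with zero
  observations carry NaN, never 0.
* **GC3s**: fraction of synonymous codons (degenerate families only) ending
  G or C. **X3s** divides the count of synonymous codons ending in base X by
  the count of synonymous codons whose family offers an X-ending
  alternative; the four values may sum to more than 1, which is the
  convention under which published X3s tables exceed 100% in total.
* **ENC** (Wright): per amino acid with n ≥ 2 observations,
  F = (n·Σp² − 1)/(n − 1); F values are averaged within each degeneracy
  class (F ≤ 0 excluded), and ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆ under
  table 1 (general form: #singletons + Σ N_k/F̄_k). A missing 3-fold class
  (Ile unobserved) is imputed as mean(F̄₂, F̄₄); any other missing class
  makes ENC undefined. The estimate is capped at 61.
* **CAI / CBI / FOP** need a highly-expressed reference set, which no
  expression data exists to define for mitochondrial genomes. The default
  reference is dataset-internal: the pooled counts of the lowest-ENC decile
  of genes within each strain (strong bias as expression proxy). Relative
  adaptiveness is w = count / max family count with zero counts replaced by
  0.5 before normalization; the optimal set takes the most-used codon per
  family (alphabetical tie-break, logged). CAI is the geometric mean of w
  over a gene's synonymous codons; CBI = (N_opt − N_rand)/(N_tot − N_rand)
  with N_rand = Σ N_family/k; FOP = N_opt/N_syn. Because these three depend
  on the reference choice, cross-study comparisons of their absolute values
  are only meaningful under a shared reference policy; an explicit
  `ReferenceWeights` can be supplied to reproduce any external convention.
* **GRAVY** is the mean Kyte–Doolittle hydropathy per encoded residue
  (bounded by the scale, −4.5 to 4.5) and **AROMO** the fraction of Phe,
  Tyr and Trp residues.

Strain-level indicators are unweighted means over the genes of a strain
(mean-of-genes, the headline convention, recorded in output metadata);
pooled-count recomputation is available by pooling tables before the index
call.

## Bias diagnostics

* **Neutrality plot**: OLS of GC12 on GC3 across the genes of a strain,
  with the two-sided Pearson p (t, n−2 df). Slope near 1 indicates shared
  mutational pressure on all positions; near 0, selective constraint on
  positions 1–2 while the third drifts. Note that a moderate R² can coexist
  with a non-significant p at n = 12 genes; both numbers are emitted and no
  significance verdict is hard-coded.
* **ENC–GC3s**: the mutation-only null curve
  ENC_exp = 2 + s + 29/(s² + (1−s)²), with
  ENC_ratio = (ENC_exp − ENC_obs)/ENC_exp positive when observed usage is
  more biased than composition predicts.
* **PR2 bias**: y = A₃/(A₃+T₃) against x = G₃/(G₃+C₃). The default tally
  restricts to fourfold-degenerate families, where the third base is free
  of amino-acid constraint (Sueoka's construction); `all3rd` widens it to
  every degenerate family. Zero denominators yield flagged NaN coordinates.
* **Correspondence analysis** of the genes × 59-codon RSCU matrix:
  proportions P, standardized residuals S = D_r^{-1/2}(P − rcᵀ)D_c^{-1/2},
  SVD; principal inertias are squared singular values and the axis
  contribution is each inertia's share of the total. Undefined RSCU cells
  are imputed as 0 with a logged count; all-zero columns are dropped. With
  g genes the rank bound gives at most g − 1 axes. An all-identical-profile
  matrix is flagged degenerate rather than dividing by zero.
* **Indicator correlations**: pairwise Pearson r and two-sided p over the
  gene-level indicator records of a strain, with pairwise deletion of
  missing values.

## Optimal codons

Genes are ranked by ENC; max(1, round(0.1·N)) genes from each end form the
putative high-expression (low-ENC) and low-expression (high-ENC) sets —
with 12 genes, one gene per tail, ties broken by name. ΔRSCU is pooled RSCU
of the high set minus the low set. A codon is high-frequency when its
strain-wide pooled RSCU > 1, highly expressed when ΔRSCU > 0.08, and
optimal when both strict inequalities hold; the optimal set is exactly the
intersection. Whether to pool counts or average per-gene RSCU within the
10% sets is a genuine convention choice; pooling is the default because the
tail sets are single genes in the 12-gene design, where the two coincide.

## RSCU clustering

Each strain is a pooled 59-codon RSCU vector (undefined entries imputed 0,
logged). Default clustering is squared Euclidean distance with average
linkage — the defaults of the legacy SPSS hierarchical-clustering procedure
this analysis lineage used — with complete and Ward (Euclidean only)
available. Merge heights are emitted raw in the Newick output (leaf height
0; branch length = parent height − child height) rather than rescaled to
the 0–25 dendrogram axis some GUIs display. Robinson–Foulds comparison
treats both trees as unrooted and counts the symmetric difference of
non-trivial bipartitions, so a sequence-based reference topology can be
supplied as Newick for comparison with the RSCU dendrogram.

## Synthetic cohorts

The generator emulates the target dataset's statistical shape without any
download: 13 strains × 12 core genes, gene lengths uniform in 360–1990 bp
(whole codons; a UAA stop is appended), amino-acid usage derived from a
T-rich position-1/2 base model (A .26, U .42, G .17, C .15), and
third-position preference A .52 / U .34 / G .08 / C .06. Under these
defaults a cohort lands near T ≈ 40%, A ≈ 33% of the CDS, GC3 ≈ 11%,
mean ENC ≈ 32 and GRAVY ≈ 0.79, i.e. the regime the pipeline is meant for.

Regimes plant known structure:

* **mutation** — each gene draws a GC pressure g ~ U(gc_pressure ± 0.12)
  applied to all three positions (stop codons rejection-sampled away), so
  the expected neutrality slope is 1. The finite-length binomial noise in
  observed GC3 attenuates the OLS slope by roughly
  var(g)/(var(g) + p(1−p)/n₃) ≈ 0.9 at default lengths, which is why the
  recovery band is ±0.15 rather than tighter.
* **selection** — amino-acid usage is fixed while each gene draws its own
  third-position GC target from (0.06, 0.22); expected slope 0.
* **neutral** — uniform synonymous usage, optionally perturbed per gene by
  a Dirichlet draw with concentration κ (smaller κ = sharper preference =
  lower ENC).

An `expression_gradient` g mixes each family's preference with a point mass
on a planted optimal codon, with weight min(0.97, g·(1 − i/(G−1))) for gene
index i, so low-index genes have low ENC and the planted codons are the
ground truth for optimal-codon recovery. A small per-strain log-normal
jitter on the third-base weights (σ = 0.04) differentiates strains so the
clustering stage has structure. Per-gene random streams are keyed by
hashing (seed, strain, gene), making output byte-identical regardless of
generation order.

What the generator does **not** emulate: phylogenetic autocorrelation
between strains, within-gene spatial structure, indels/annotation noise, or
amino-acid composition differences between genes beyond sampling noise.
Passing recovery tests therefore demonstrates the estimators' correctness
on i.i.d. compositional data, not robustness to misannotation or to
evolutionary covariance.

## Numerical conventions

Undefined statistics are NaN with a logged or flagged reason, never silent
zeros. Fractions are used internally everywhere; percentages appear only in
the reporting layer (2 decimals, full precision in TSVs). All tie-breaks
(optimal-codon ties, ENC-split ties, clustering input order) are
alphabetical for run-to-run determinism, and rerunning the pipeline on
identical inputs produces byte-identical artifacts.

## Problem sizes used by the test suite and acceptance script

The bundled checks run on synthetic cohorts of 1–13 strains with genes at
the default 360–1990 bp (up to 30 kb for law-of-large-numbers checks),
20 seeds for slope recovery and 5 seeds for optimal-codon recall; these
sizes give standard errors comfortably inside the asserted bands. The
published-dataset reproduction tests run on the real 13-genome set whenever
its GenBank files are placed under `data/accessions/`.
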