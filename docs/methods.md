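# Methods

This note documents the models, statistics and design choices behind
`tmgate`, and what the synthetic-data tests do and do not establish.

## Data model and preprocessing

A `SampleBundle` holds one sample's UMI counts (genes × cells), per-cell
metadata, and two derived layers: `normalized` = ln(1 + 10⁴·c/total) (log
TP10K, natural logarithm, matching the convention of the single-cell
ecosystem this pipeline interoperates with) and `scaled` = per-gene z-scores
over the retained cells. Scaling is computed after QC and CD8 selection, on
exactly the cell set that will be compared; zero-variance genes scale to
zero. Cells being compared across conditions must share one bundle before
scaling — signature scores are relative quantities.

QC follows droplet-data convention: genes detected in < 3 cells and cells
with < 400 detected genes are dropped at load; cells must express strictly
more than half of a housekeeping list; human cells expressing > 500
mitochondrial genes are removed, mouse cells more than 2 SD *above* the
across-cell mean of expressed-mitochondrial-gene counts. The mouse rule is
deliberately one-sided: high mitochondrial content flags damaged cells,
while an unusually low count is not a recognised failure mode. Cluster
retention keeps human clusters with > 30% of cells co-expressing ≥ 2 of
CD3E/CD3D/CD3G and either a CD8⁺ Treg-free profile (CD8B or CD8A > 30%,
FOXP3 and CD4 each < 5%) or a proliferating profile (MKI67 > 70% with
CD8A/CD8B > 20%); mouse clusters need > 30% Cd3⁺, > 30% Cd3e⁺Cd8a⁺
co-expression and < 5% Foxp3⁺. Where the CD8-gene clause is textually
ambiguous we read CD8A/CD8B disjunctively, since a CD8B-dominant cluster is
unambiguously a CD8 T cell cluster.

## Clonotype matching

Clone keys are the sorted, deduplicated set of (chain, CDR3 amino-acid)
pairs per cell; V/J genes can optionally be appended. Non-productive chains
are excluded by default — they do not define antigen specificity. Cells
lacking an α or a β chain are excluded from every TM/non-TM comparison.
Matching is exact set identity across compartments; this is conservative: a
cell with an extra detected chain forms a different clone even if it shares
a chain pair. The strictness guarantees that matched cells derive from the
same clone with high probability, at the cost of losing matches to
incompletely detected cells. Multi-resection tumors are handled by taking
the union of their clonotype sets before matching. The cluster-consensus
alternative accepts two externally computed TM labelings (from TCR-sequence
clustering tools run on the joint blood+tumor TCR collection) and discards
cells where they disagree.

## Marker statistics

**Grid AUC.** The 39 candidate thresholds per gene are the 21
linear-interpolation percentiles (0, 5, …, 100) plus the 18 interior points
of a 20-point equipartition of [min, max]; the even spacing covers heavily
skewed distributions where useful thresholds sit beyond the 5th/95th
percentile. Duplicated thresholds are kept (identical ROC points are
harmless under trapezoid integration), positivity is strict (`> t`, or
`< t` in the negation direction), the trivial operating points (0,0) and
(1,1) are appended, and points are sorted by x before integration. A
constant gene degenerates to the endpoints and AUC 0.5. Against an exact
midrank AUC the grid is accurate to well within 0.02 at n ≥ 100 cells.

**XL-mHG.** With cells ranked by decreasing (possibly negated) expression,
label prefix counts b(n), and constraints n ≤ L, b(n) ≥ X, the statistic is
the minimal hypergeometric upper tail over admissible cutoffs;
X = ⌈0.15·K⌉ (0.15 read as a fraction of the K labeled cells) and
L = min(10·K, ⌊0.35·N⌋). Cutoffs are only admissible *between distinct
expression values*: a cutoff inside a tie block is not realisable as an
expression threshold. One practical consequence: a gene whose leading tie
block (e.g. the zero-count block on the negated scale) extends past L has
no admissible cutoff and is reported as p = 1 — which is why only genes
appreciably expressed in the background population can act as negation
markers, mirroring their real counterparts (CCR7, LTB and similar are
well-expressed in naive blood T cells).

The exact p-value is the null probability, uniform over all C(N, K) label
placements, that the statistic reaches the observed value. It is computed
by an O(N·K) dynamic programme propagating hypergeometric transition
probabilities across the prefix lattice and zeroing every admissible
lattice cell whose tail probability is at most the observed statistic. All
tails come from one gammaln-based log-binomial grid (one vectorised pass
per gene); cells sharing a rational tail value can differ in the last ulps
of that evaluation, so the zeroing comparison carries a 10⁻¹⁰ relative
guard. The DP null assumes a tie-free ranking; with ties it is (mildly)
conservative. Exactness is verified against full enumeration for every
configuration with N ≤ 10 to 10⁻¹². The reported `cutoff_val` is the
absolute expression value at the first excluded rank, following the
convention that negation-direction thresholds are reported unsigned.

Multiple testing uses Benjamini–Hochberg across all genes × both directions
within each sample; the correction method is a package choice (the source
procedure names only "multiple hypothesis test corrections").

**Consensus and similarity.** Markers pass if q < 0.05 in ≥ `min_samples`
samples (default 4 of 6) after removing an exclusion list (default: the
lineage marker CD8A and the cytokines CCL4/CCL5/MIF, which are not sortable
surface markers); ranking is by mean AUC, descending. Cross-sample AUC
similarity takes all sample pairs × shared genes, swaps x/y per point with
probability 0.5 under a fixed seed (default 27) to avoid biasing the x axis
toward earlier samples, and reports Pearson R per within-/between-patient
stratum. Cross-species overlap uses the hypergeometric upper tail over a
declared homolog-mapped universe.

## Gates

Gate literals are `GENE^low` (expression strictly below threshold) and
`GENE^high` (strictly above); with the universal 0.001-UMI threshold on
count data, `^low` means "zero counts" — any threshold in (0, 1) is
equivalent there. Enumeration closes the literal set under AND/OR and
deduplicates by truth table, yielding every distinct nonconstant monotone
boolean function (1, 4, 18, 166 for 1–4 literals) with a minimal canonical
expression per function. The selection penalty adds the *absolute*
sensitivity–specificity difference to the Euclidean distance from the
perfect corner; a signed difference would nonsensically reward
specificity-heavy gates. Pareto dominance is weak dominance with at least
one strict improvement — a gate tied on one axis and beaten on the other is
dominated. The penalty minimiser is provably on the frontier; ties break
toward fewer literals, then the canonical string.

## Resampling

Bootstrap CIs are percentile intervals over B resamples of cells (with
replacement, original size, thresholds fixed); B defaults to 10,000 and the
interval to (2.5, 97.5). Resamples that lose a class are redrawn so exactly
B valid iterations contribute; configurations where more than 10% of first
draws fail are rejected. The permutation null resamples cells and then
permutes TM labels within the resample — the null of a marker sorting cells
by chance alone. The empirical p is the upper-tail count divided by B
(deliberately *not* (count+1)/(B+1)); a zero count is reported as the bound
"< 1/B", never as p = 0. Percentile intervals may, in pathological cases,
exclude the point estimate; this is logged rather than silently corrected.

## Synthetic data

The generator emulates the *shape* of paired blood/tumor CD8 data: geometric
clone sizes (default success probability 0.4, mean 2.5 cells/clone), a
configurable fraction of blood cells in tumor-shared clones (default 0.1,
selected as a random clone subset whose sizes sum to the target), negative
binomial counts (var = μ + μ²/θ, θ = 2) with log-normal gene means
(median ≈ 0.6 UMI), 5% extra dropout, and per-clone TCR chains with
realistic CDR3 strings (C…F, length 8–20), clone-level multi-chain injection
(8% of cells), per-cell loss of a whole locus (10%), and occasional
non-productive contigs. Multi-chain structure is a *clone-level* property
here; injecting extra chains per cell would split clone keys and make the
planted truth internally inconsistent. Planted markers shift TM blood
cells' means by a stated log2 fold change (default: four negation markers
at −1.5, matching the magnitude used throughout the validation suite) and
fix the background mean at 4 UMI — an informative negation marker must be
appreciably expressed in non-TM cells, and the XL-mHG tie rule makes
near-silent genes untestable in the negation direction, exactly as in real
data.

The planted-gate generator draws an independent pass-state per marker per
cell (probability 0.5 unless overridden), realises the states as zero vs
nonzero counts, and labels cells by the planted gate's truth value with a
configurable flip noise. Markers outside the gate still receive planted
patterns, so they act as genuine decoys: gates that include them make
materially different predictions. For penalty-based recovery experiments
the literal probabilities should make the gate fire for about half the
cells; under symmetric label noise the planted gate is then both closest to
the perfect corner and balanced, hence the unique penalty optimum. (With an
unbalanced firing rate the noise shifts sensitivity and specificity
asymmetrically and the balance term legitimately prefers a neighbouring
gate — a property of the penalty, not an artifact.)

What the simulations do *not* model: transcriptome-wide gene–gene
correlation, V(D)J recombination statistics, batch effects, doublets and
ambient RNA, compartment-specific expression programmes beyond the planted
shifts. Passing tests therefore establish the correctness and calibration
of the algorithms under the stated generative model, not performance on any
particular patient cohort.

## Problem sizes and numerical choices

Test and acceptance runs use compact cohorts chosen to make the planted
effects comfortably detectable: samples of 800 blood / 600 tumor cells for
the 6-sample marker-recovery study (≈ 420 paired-chain blood cells,
K ≈ 45 TM cells per sample, 204 genes), 1,000 cells for the 100-replicate
gate-recovery study, 3,000 blood cells for matching-recovery checks, and
B = 2,000–10,000 for resampling. Calibration checks use 500 replicates at
n = 100 cells. Exactness sweeps (XL-mHG vs enumeration, gate enumeration vs
truth-table brute force) are exhaustive at their stated sizes. Seeds are
fixed throughout; every stochastic routine takes an explicit seed or
parameter object, and all simulator randomness derives from one
SeedSequence with named child streams.

## Known limitations

- Exact clonotype matching undercounts TM cells when tumor-side chain
  detection fails for a whole (small) clone; the recovered TM fraction is
  accordingly biased slightly below the planted value, within the dropout
  rate.
- The XL-mHG DP is exact under the tie-free null; heavy ties make it
  conservative rather than anti-conservative.
- The permutation p at B iterations resolves no further than 1/B; the bound
  string preserves that honestly.
- Gate thresholds are held fixed during resampling, so the CIs do not
  propagate threshold-selection uncertainty.
- The consensus step treats samples as exchangeable; longitudinal samples
  from one patient count as separate samples, as in the source procedure.
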