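# Methods

This note documents the statistical models, estimators, defaults, and design
choices behind `landgen`, and what the synthetic scenarios do and do not
demonstrate about real data.

## Genotype model and quality control

Genotypes are unordered diploid allele pairs over positive integer codes;
missing calls are a dedicated sentinel, never allele code 0 (a GENEPOP file
convention that must not leak into statistics). Pairs are stored sorted so
equal genotypes are bit-identical, which makes file round-trips exact.

*Missingness filter.* Individuals are retained when their missing fraction is
**strictly** below the threshold (default 0.30), matching the usual "<30%"
acceptance rule.

*Hardy–Weinberg.* The exact test conditions on allele counts (Levene's
distribution): the statistic is the negative log conditional probability of
the genotype table, and the p-value is Monte-Carlo — pooled alleles are
re-paired `n_perm` times, p = (1 + #{statistic ≥ observed})/(n_perm + 1).
Exact enumeration is tractable only for tiny tables and is used as a test
oracle, not in production. Monomorphic cells return p = 1 with a flag.
Screening across the cell × locus grid is corrected by Benjamini–Yekutieli
(step-up slopes divided by c(m) = Σ 1/i, valid under arbitrary dependence;
default α = 0.013), and a locus is flagged for removal when it is rejected in
a configurable fraction of testable cells (default: all of them). Linkage
equilibrium tests are out of scope; the QC report marks them "not computed".

*Null alleles.* Brookfield's estimator 1, r = (H_E − H_O)/(1 + H_E) with
unbiased H_E, clipped at zero. It is a closed-form summary, chosen over
iterative EM variants for testability.

## Diversity and differentiation

Per cell: H_O is the fraction of heterozygous complete genotypes; H_E is
Nei's unbiased expectation (2n/(2n−1))(1 − Σp²); allelic richness is
hypergeometric rarefaction to a common gene count g (default: the smallest
per-cell gene count at that locus — the most conservative common depth);
F_IS is the Weir–Cockerham (1984) within-population f, 1 − Σc/Σ(b+c) over
loci and alleles, with a percentile CI from bootstrap resampling of loci
(undefined, and flagged, with a single locus).

Pairwise F_ST is Weir–Cockerham θ with variance components summed over
alleles and loci (ratio of sums). Pairwise D_EST uses Nei–Chesser unbiased
H_S and H_T per locus, D_l = 2(H_T − H_S)/(1 − H_S), aggregated across loci
as a ratio of averages: 2·mean(H_T − H_S)/mean(1 − H_S). Negative point
estimates are reported as computed; only D_EST CIs are clipped at zero.
Missing genotypes are dropped pairwise per locus. p-values permute
individuals between the two cells; CIs bootstrap loci. Cells with fewer than
two individuals are excluded with a warning.

## Spatial tests

Mantel tests correlate upper triangles and permute rows+columns of the
*second* matrix jointly; the default tail is one-sided (greater) because
isolation by distance predicts a positive association. The partial Mantel
uses the first-order partial correlation, permuting B and recomputing the
statistic; a covariate affine in A forces the numerator to zero exactly, and
that 0/0 limit resolves to r = 0 rather than an error.

Rousset's â between individuals uses the identity-probability form: per
locus, Q_w is the mean within-individual allelic identity of the pair and
Q_b the between-individual identity; the multilocus estimator is
Σ(Q_w − Q_b)/Σ(1 − Q_w), which weights loci by information content (1 − Q_w).
A fully homozygous pair is degenerate: identical pairs give 0, disjointly
fixed pairs +inf, both flagged.

The autocorrelogram is Smouse–Peakall multivariate r: squared genetic
distances (the standard codominant 0/1/2/3/4 table summed over loci) are
double-centered; r(h) sums cross-covariances of pairs in distance class h
over half the summed diagonal terms of the individuals involved. Classes are
half-open [lo, hi), the final class includes the 2 km bound, and pairs beyond
it are excluded. The permutation null shuffles coordinates among individuals;
the CI around r bootstraps pairs within each class.

## Resistance surfaces and circuit theory

Land-cover classes map to per-class resistances (≥ 1; forest = 1 on all
parameterized surfaces). Two null surfaces are fixed: IBD (all 1) and IBB
(open water 500, all else 1). The four parameterized surfaces ship as
editable CSV tables; the defaults encode deliberately contrasting
hypotheses — the mortality family treats the crop matrix as the main hazard,
the movement family treats open grassland/wetland as the main impediment
(wetland = 5 for the specialist movement-low table), and the L/H variants
switch urban between permeable habitat and near-impassable roads. The strong
contrasts keep the six hypotheses statistically distinguishable on a single
landscape, which is what the recovery experiments require.

Effective resistance: each non-nodata pixel is a node; adjacent pixels
(8 neighbours by default) are joined with conductance 1/(0.5(r_i + r_j)·w),
w = 1 cardinal and √2 diagonal (geometric edge length). Study cells enter as
the single pixel containing their focal coordinate (an option to short a
supplied region into one node is deliberately not provided — determinism of
the focal-pixel convention is worth more at this scale). Pairwise effective
resistances come from one sparse LU factorization per connected component of
the reduced Laplacian and one solve per focal node; disconnected pairs are
+inf with a warning. Nodata pixels are removed from the graph entirely.
Raster convention: row 0 is the top row; world↔pixel mapping uses half-pixel
centres from the lower-left corner.

Connectivity indices S_i = Σ_{j≠i} exp(−α d_ij) default to
α = 1/median(off-diagonal d): a neutral scale when the species' dispersal
kernel is unknown; infinite entries contribute zero.

## Pattern metrics

prFor is the focal-class fraction of non-nodata pixels. Patch density counts
8-neighbour connected components per 100 ha. CLUMPY uses rook double-count
adjacencies with boundary segments excluded — like adjacencies counted from
both focal pixels, mixed ones once — and the minimum-perimeter correction
(4s, 4s+2, or 4s+4 pixel sides for the most compact arrangement), so a
single compact block scores 1, a checkerboard −1, and spatial randomness ~0.
Buffered clipping (default 1.6 km) truncates at the raster edge and buffer
pixels count toward the metrics. When the focal class is absent in a window
CLUMPY is undefined; the pipeline substitutes 0 (no aggregation information)
so the cell remains usable as a predictor, with a logged warning.

## Model selection

*MRDM* regresses the vectorized upper triangle of the differentiation matrix
on predictor matrices (one resistance-distance matrix plus pairwise means of
the cell metrics — the mean, not the difference, is the pairwise embedding
of a site variable here). Predictors are z-scored so coefficients are
comparable; raw-scale coefficients are also reported. All inference permutes
rows+columns of the response only (Legendre's raw-data method): the overall
test uses F, coefficients use |t|. Backward elimination repeatedly drops the
worst predictor with permutation p > α (default 0.05) until all retained
p ≤ α; an empty model is a legitimate outcome. Ill-conditioned designs are an
error in the library; the pipeline pre-drops constant, collinear, or
condition-inflating complexity predictors (logged) before fitting.

*dbRDA* extracts PCoA axes with positive eigenvalues (Gower double-centering,
eigenvalue threshold 1e−8 of the maximum, axes scaled by √eigenvalue) and
regresses them on centered predictors; R² is explained over total positive
inertia, pseudo-F uses n − m − 1 residual degrees of freedom, the p-value
permutes predictor rows, and adjusted R² is Ezekiel's. Forward selection adds
the candidate with the smallest permutation p of its partial F (candidate
rows permuted, current model fixed) while p ≤ α; the null model is returned
when nothing enters.

*Bootstrap CIs.* Individuals are resampled with replacement within cells
(cell sizes preserved); each replicate recomputes F_ST/D_EST and refits the
*fixed* reduced-model structures (re-running selection inside replicates
would mix model uncertainty into coefficient CIs; the structure is part of
the point estimate). Percentile 2.5/97.5 intervals; empty models contribute a
degenerate adjusted R² of 0. Replicate failures are logged and skipped; more
than 5% aborts.

*Comparison rule.* The winner is the surface with the highest adjusted R²; a
non-null surface is "distinct" when its adjusted-R² CI overlaps neither null
surface's CI, and surfaces overlapping the winner are listed as competing.

## Synthetic scenarios

The landscape generator thresholds one smoothed Gaussian field at cumulative
class proportions (forest, wetland, water at the wet end; grassland, urban,
agriculture at the dry end), so realized fractions are exact to a pixel and
patch size scales with the smoothing sigma (default 8 px). Defaults emulate a
heavily farmed basin: 8% forest, 64% agriculture, 10 remaining percent split
among wetland/water/grassland, with 14% urban — urban is deliberately not
adjacent to the water band so the two barrier classes do not trace the same
filaments.

Between cells, genotypes follow a deme-level forward Wright–Fisher model:
shared Dirichlet(1) ancestral frequencies, per-generation migration
m_ij = m_total·exp(−β d_ij) on the *true* surface's resistance distances
(rows capped at 0.5 total emigration, diagonal absorbing the remainder),
then multinomial drift of 2N_e gene copies. Migration is deliberately *not*
row-normalized: normalizing would make every deme receive the same total
immigration regardless of isolation, and the hidden surface would leave
almost no signature in differentiation — isolation must reduce gene flow for
resistance to be recoverable. Loci are k-allele (default 16, within the
typical microsatellite range) without mutation, a defensible simplification
when generations ≪ 1/μ. Sampled individuals are Hardy–Weinberg draws from
final deme frequencies with uniform missingness and jittered coordinates.

Presets: **specialist** — truth is the high-urban-mortality surface, β scaled
to 3.5/median resistance distance, m_total 0.3, N_e 100, 150 generations,
12 cells × 30 individuals × 10 loci on a 150×150 raster — produces F_ST in
the 0.01–0.3 range with strong distance decay; **generalist** — β = 0,
N_e 2000, 50 generations — effective panmixia. Within-cell data come from a
separate kin-structure model (family clusters of scale σ plus an east–west
ancestry cline of sharpness 1/σ), giving isolation by distance at two scales;
σ → ∞ recovers a structure-free scatter.

What passing the synthetic experiments shows: the estimators, permutation
machinery, and selection logic recover a known truth under the model's own
assumptions. What it does not show: robustness to null alleles and scoring
error, stepwise mutation, non-equilibrium history, anisotropic dispersal, or
misalignment between the true movement process and any candidate surface —
all present in real systems.

### Measured behaviour of the scaled scenarios

At the scaled-down study size (12 cells, 30 individuals, 10 loci) the true
surface wins MRDM model selection in roughly three quarters of replicates,
but the stricter event "wins *and* its bootstrap CI is disjoint from both
null surfaces" holds in only about half to two thirds: with 30 individuals
per cell the genotype-bootstrap adjusted-R² intervals are ~0.3 wide, and
geographic distance genuinely shares signal with every resistance surface.
Similarly, with four candidate predictors per model at α = 0.05, backward
elimination ends non-empty under a true null ~18% of the time by multiplicity
alone, so the expected fraction of null models under panmixia is ~0.82.
These ceilings are properties of the study size, not of the implementation;
the acceptance suite reports both rates as measured.

## Numerical choices

Laplacian solves use SuperLU on the grounded system (relative residuals well
below 1e−10 at these sizes); the dense oracle in tests uses the
(L + J/n)⁻¹ − J/n identity because a plain pseudoinverse loses 8+ digits on
ill-conditioned grids. Permutation p-values are (1 + #extreme)/(n_perm + 1)
throughout, with ≥-comparisons buffered by 1e−12 against float ties. All
randomness flows from a single master seed through `numpy.random.SeedSequence`
spawning, so a rerun with the same config is byte-identical. Pipeline
defaults: 10,000 permutations and 1,000 bootstrap replicates are the
full-scale values; the scaled presets use 999/200.
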