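# Methods

`hseqtl` implements an end-to-end analysis of expression quantitative
trait locus (eQTL) detection in complex mouse crosses — an F2
intercross, a four-way heterogeneous stock (HS4) and an eight-way HS
built from the Collaborative-Cross founder strains (HS-CC) — with a
focus on how data quality and population substructure distort detection
and how kinship-aware procedures recover it.  Because the expression
and genotype data of such studies are rarely redistributable, the
package ships a simulator of the breeding designs themselves; every
downstream claim is exercised against simulated crosses with known
ground truth.

## Breeding-design simulator (`popsim`)

**Pedigrees.** The three designs follow their published breeding
schemes. F2: two inbred founders, reciprocal F1 hybrids, the four
reciprocal F2 crosses. HS4: the 12 reciprocal F1 hybrids of four
strains, then four-way crosses (the 24 ordered type crosses, each bred
in duplicate, giving 48 families), then circle breeding — a male of
family *k* mated to a female of family *k*+1 — to generation 19.
HS-CC: eight founders lettered A–H, reciprocal two-way and four-way
crosses, 32 eight-way families at G3, circle breeding from G4, an
expansion to 48 families at G6 (male of family *k* × female of family
*k*+16), and sampling at G12.  All matings succeed (litter failure is a
stochastic detail irrelevant to the statistics), and sexes alternate
deterministically within families so circle breeding is always
feasible.  The default cohort takes one male and one female per family
(HS designs: n = 96).

**Meiosis.** Crossover counts per chromosome are Poisson with mean
L/100 (L = map length in cM) with uniformly placed crossovers and no
interference, which yields the Haldane map function
r = ½(1 − e^(−2d/100)) between markers d cM apart.  A piecewise-
constant hotspot profile can redistribute crossover positions while
preserving the expected total, concentrating recombination into a
narrow window; over many outbreeding generations this leaves the rest
of the chromosome in long-range linkage.

**Founder panels.** Founders are inbred and homozygous at biallelic
markers; panels are random but guaranteed polymorphic.  The default
marker map is 19 autosomes × 10 markers at 10 cM spacing (configurable)
— the density regime of real sparse HS marker panels.  A fixed scale of
2 Mb/cM maps genetic to physical coordinates for probe and SNP
annotations.

**Expression model.** Probe intensity = intercept + Σ planted
founder-contrast effects (cis effects sit inside their interval, trans
effects elsewhere) + polygenic component + strip batch effect + noise,
with four artifact classes layered on top:

- *polygenic component*: per-probe Gaussian draw with covariance
  σ²_poly · S, where S is the similarity conversion of a chosen
  relatedness matrix (genome-wide or one chromosome) — this is the
  generative mechanism behind "genetic differences dispersed throughout
  the genome collectively affect expression";
- *failed arrays*: designated samples replaced wholesale by
  high-variance (SD 6) noise;
- *unexpressed probes*: designated probes replaced by heavy-tailed
  background (Student t, 1.5 df, scale 2) — unexpressed probes measure
  non-specific background, which is distinctly non-Gaussian — and given
  detection p-values ≥ 0.01 in ~85% of samples;
- *SNP-in-probe artifacts*: designated probes gain an intensity term
  proportional to the allele dosage at the marker nearest the probe
  (hybridization tracks the sample's sequence under the probe).

The truth table lists every planted (probe, interval) pair.

## Expression QC (`exprqc`)

Filters run in pipeline order: (1) iterated inter-array-correlation
outlier removal — samples more than 2 SD *below* the mean IAC are
dropped, repeated to stability or three rounds (the low side only; a
high-correlation array is not anomalous — a `two_sided` flag restores
the literal symmetric rule); (2) strip-level quantile normalization
(classic mean-of-order-statistics quantile normalization within each
physical array strip, ties averaged); (3) SNP-in-probe removal with
0-based half-open probe intervals; (4) detection-call filtering — a
probe survives iff detected (p < 0.01) in at least ⌈0.25 n⌉ samples
(the boundary is inclusive).  Genotype outlier removal (kinship module)
runs independently; the pipeline intersects surviving samples.

## Relatedness (`kinship`)

All genetic relatedness is the manhattan distance between {0,1,2}
dosage vectors — genome-wide, per chromosome, or over the two markers
flanking an interval — arranged as square symmetric matrices.
Distances are raw sums (not normalized by marker count), which makes
per-chromosome matrices sum exactly to the genome-wide matrix; a
`normalize` flag divides by marker count for cross-scope comparisons.
Phenotype distance is the absolute expression difference.  Matrix
correlation is Pearson over strictly-upper-triangle entries; the Mantel
test permutes one matrix's rows and columns jointly, two-sided on |r|
with add-one p-values (an exhaustive n! mode exists for small n).
Missing dosages are mean-imputed per marker before distances.

The mixed model needs a PSD similarity: S = 1 − D/max(D) followed by a
nearest-PSD projection (negative eigenvalues zeroed).  The conversion
is deliberately the same for sampling polygenic phenotypes and for
fitting, and is isolated in one function.

## Founder-ancestry HMM (`ancestry`)

Hidden state at a marker = the founder pair carried by the two
chromosome copies (represented internally as ordered pairs, an F × F
grid, so transitions factor into per-copy kernels).  Emissions: the
observed dosage equals the founder-pair dosage with probability 1 − ε,
or either wrong value with probability ε/2 (ε default 0.01).
Transitions between adjacent markers apply, independently per copy,
retain-with-probability-(1 − r) / otherwise-uniform-over-founders,
with r from Haldane on the inter-marker distance; an optional
map-expansion scalar inflates distances to reflect breakpoint density
accumulated over outbreeding generations (the experiments use 8 for HS
crosses).  Forward–backward runs with per-step scaling; the forward and
backward total log-likelihoods agree to 1e−8 as an internal check.

The interval-scan design is the posterior expected additive dosage per
interval, taken as the mean of the two flanking markers' expected
dosage vectors (each sums to 2).  One founder column is dropped at fit
time for identifiability; intervals whose centred design is rank
deficient are flagged untestable.

Founder-pair recovery is identifiability-limited by marker density:
with eight founders and biallelic markers, a single marker carries at
most one bit per haplotype, so recovery requires several markers per
ancestry segment.  At the default sparse map (10 cM) unordered-pair
accuracy is ~0.65 in HS-CC; on a densely genotyped chromosome
(0.5 cM spacing) it exceeds 0.9.  The dosage *expectations* used by the
scans are well calibrated at either density; only hard assignment needs
dense markers.

## The three scans (`mapping`)

**Single-marker mixed model (SM).** y = 1·μ + g·β + u + e with
cov(u) = σ²_g S.  Per probe, the no-locus model is fitted once by REML
using the spectral trick — eigendecompose S once (cached in
`KinshipEigen`; an assertion-tested counter guarantees no
re-decomposition), rotate, and profile the likelihood in
δ = σ²_e/σ²_g on a log₁₀ grid over [−5, 5] with bounded local
refinement — then every marker is a 1-df GLS F-test with the variance
ratio held fixed (the efficient mixed-model approximation; exact
per-locus REML would multiply cost by the marker count for little
calibration gain at these sizes).  Monomorphic markers are skipped with
a reason.  Degenerate similarity (identity-like) is flagged and the
test falls back to OLS.

**Interval ancestry regression (HAP).** Per (probe, interval), an OLS
F-test of the additive founder-dosage design against intercept-only,
no relatedness correction; degrees of freedom follow the design rank.

**Joint model (JM).** The founder-dosage design tested inside the
mixed-model framework: per-probe null REML fit, rotation, F-test of
the founder columns with δ fixed.  `K_override` substitutes a
chromosome-specific similarity for the genome-wide one — implemented
as replacement, not as a second variance component (two-component
fitting is future work).

**cis/trans.** Interval methods: cis iff the gene lies between the two
markers defining the tested interval.  Single-marker: cis iff the
marker is one of the two markers flanking the gene.  Probes without
coordinates are `unknown`.

## Concordance ROC (`concord`)

The single-marker reference is fixed at p = 0.01; the interval-method
threshold sweeps 0→1 over the exact grid of distinct candidate
p-values.  An interval call matches a reference marker call through the
flanking-marker adjacency; both TP and FP are counted at the
(probe, interval)-pair level — TP = fraction of translated reference
pairs called, FP = fraction of the non-reference candidate space
called.  Pair-level counting is what keeps chance overlap on the main
diagonal (counting per reference *marker*, best of its two adjacent
intervals, would make chance TP rise at twice the FP rate).  Translated
reference pairs outside the candidate universe (another stratum, a
skipped interval) are excluded from the recovery denominator.  The
"false positives" here are operational — calls not matching the other
method — and a separate `truth_roc` evaluates against the simulator's
truth table under a different name to avoid conflation.  AUC is
trapezoidal with (0,0)/(1,1) anchors.

## Overabundance diagnostics (`overab`)

Probes are screened by correlating their absolute-difference expression
distance matrix with a kinship matrix (r > 0.1 default); intervals by
correlating their two-marker distance matrix with the same kinship
(plain matrix correlation by default, Mantel r optionally).  Every
(probe, interval) pair in the screened universes is cross-tabulated as
selected-both × has-eQTL-at-threshold, summarized by the sample odds
ratio ad/bc (conditional-MLE odds ratio behind a flag) and a two-sided
Fisher exact p-value.  Single-marker tables are recast onto adjacent
intervals (minimum p per pair) before pairing.  An interval-length
check (correlation of per-interval eQTL counts with interval cM length,
permutation p) guards the trivial explanation.
`adjusted_rescan_comparison` reruns the joint model with genome-wide vs
chromosome-specific kinship and reports both odds ratios for the same
selection set.

## Pipeline (`pipeline`) and problem sizes

`run_pipeline` chains simulate → QC → kinship → ancestry → scans →
concordance → overabundance, with one root seed feeding named
substreams per stage; a rerun with the same config is bit-identical
(the manifest stores SHA-256 digests of every artifact, and stage
timings go to the log, not the manifest, to keep it reproducible).

The experiment suite (`hseqtl.experiments`) fixes the study conditions
used by the analysis drivers, the test suite, and the reproduction
script.  Cohorts are always the designs' natural sizes (n = 96 for HS);
maps and probe counts are desk-scale: 8 × 10 markers for calibration
and recovery, 4 × 8 markers and 200 probes for the confounding studies,
5 × 5 markers at 20 cM and 1200 probes for the filtering-concordance
study, 5 × 24 markers at 3 cM for the hotspot study.  These sizes keep a
full replicate set in minutes on one CPU while leaving each phenomenon
visible.

## What the simulations do and do not show

The generator reproduces the *statistical structure* the analyses
assume: Mendelian transmission through real pedigrees, Haldane
recombination, founder-contrast effects, kinship-correlated polygenic
variation, and the artifact classes the QC stage targets.  It does not
emulate sequence-level reality (probe thermodynamics, bead-level
noise, X chromosome, crossover interference, litter failure, selection
or drift beyond the breeding rules), and biallelic random panels
understate real founder informativeness.  Passing tests therefore
demonstrate correctness of the procedures and directional reproduction
of the substructure phenomena under the stated generative model — not
performance guarantees on any particular real dataset.

Three desk-scale effects deserve note:

- *Cross-method concordance is intrinsically robust.*  Both scans see
  the same samples and probes, so most artifacts produce *concordant*
  spurious calls; the honest discordance channel (chance single-marker
  hits on background probes at a sparse map, which interval ancestry
  captures poorly) yields a mean AUC gain from filtering of only
  ~+0.02, and the gain direction holds in roughly 8–9 of 10 replicates,
  not uniformly.
- *A chromosome's kinship self-correlates with the genome matrix it is
  part of.*  With a handful of desk-scale chromosomes the hotspot
  study therefore uses leave-one-chromosome-out correlation, which is
  the faithful analogue of the genome-scale comparison.
- *Null variance recovery uses ML.*  REML's unbiasedness spreads
  σ²_g = 0 estimates well above the boundary at n = 96; the ML fit is
  the appropriate estimator for recovering a boundary value, while the
  scans keep REML.

## Numerical choices

Eigendecompositions are clipped at 0 for PSD repair; REML profile grid
log₁₀δ ∈ [−5, 5] × 61 points with bounded Brent refinement, boundary
optima flagged; rank decisions via SVD with a relative 1e−8 threshold;
quantile-normalization ties by averaged ranks; p-values floored at the
smallest positive double; Fisher tests via the exact hypergeometric
distribution; Mantel p-values use the add-one convention (never zero).
Degenerate cases — constant matrices, monomorphic markers or intervals,
empty strata, zero-probability HMM observations — are either flagged
with reasons or raise explicit errors, as specified per operation.
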