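# hseqtl

eQTL detection in complex mouse crosses: founder-ancestry
reconstruction, kinship-corrected mixed models, and population-
substructure diagnostics, exercised end to end on a simulator of the
breeding designs.

## The problem

Heterogeneous stock (HS) mouse populations — founded from four or
eight inbred strains and outbred for many generations — give far better
QTL mapping resolution than an F2 intercross, at the price of complex
relatedness between animals.  When gene-expression levels are the
phenotypes (eQTL mapping), two families of detection methods are in
common use and can disagree badly:

- **single-marker (SM) mixed-model association**: each marker tested
  against each probe with a random polygenic effect whose covariance
  follows a kinship matrix (the efficient mixed-model / EMMA approach);
- **interval ancestry regression (HAP)**: a hidden Markov model
  reconstructs, per genomic interval, the expected number of chromosome
  copies inherited from each founder strain, and the interval is tested
  by regressing the phenotype on these founder dosages (the HAPPY
  approach) — no relatedness correction.

This package implements both, plus the **joint model (JM)** that tests
the founder-dosage design *inside* the mixed-model framework, keeping
ancestral-allele effects while correcting for kinship.  Around the
scans it implements the full analysis the comparison requires:

- a simulator of the F2, HS4 (4 founders, 19 generations) and HS-CC
  (8 Collaborative-Cross founders, 12 generations) breeding designs,
  with Haldane meiosis, optional recombination hotspots, and an
  expression model with planted cis/trans eQTLs, kinship-driven
  polygenic structure, and realistic array pathologies;
- the expression QC suite (iterated inter-array-correlation outlier
  removal, strip-level quantile normalization, SNP-in-probe removal,
  detection-call filtering) and genotype outlier removal;
- relatedness machinery: manhattan-distance kinship matrices
  (genome-wide / per-chromosome / per-interval), phenotype distances,
  matrix correlation and the Mantel permutation test;
- cross-method concordance via an adapted ROC (interval calls matched
  to single-marker calls through flanking-marker adjacency);
- eQTL-overabundance diagnostics: Fisher-exact odds ratios for the
  excess of calls among kinship-correlated (probe, interval) pairs,
  and the chromosome-specific kinship substitution that absorbs
  chromosome-local relatedness the genome-wide matrix misses.

The core mixed model is y = Xβ + u + e, cov(u) = σ²_g S, with
S = 1 − D/max(D) the PSD-repaired similarity form of the manhattan
kinship D, fitted by REML via a single eigendecomposition of S and a
1-D profile search in δ = σ²_e/σ²_g.

## Worked example

```python
from hseqtl import *
from hseqtl.markers import default_marker_map
from hseqtl.ancestry import true_ancestry_design

mm  = default_marker_map(5, 8, 10.0)          # 5 chromosomes x 8 markers
pop = simulate_cross("HSCC", mm, seed=1)      # 48 families -> n = 96
geno = pop.genotypes(seed=2)
K    = genome_kinship(geno)

pm = random_pheno_model(mm, 8, n_probes=200, n_cis=10, cis_effect_sd=1.5,
                        seed=3, polygenic_var=0.5, noise_var=1.0)
expr, truth, snps = simulate_expression(pop, pm, K, seed=4)

kin    = KinshipEigen.from_distance(K)
design = true_ancestry_design(pop.true_dosage(), mm, pop.founder_panel.founder_ids)

hap, _ = interval_scan(expr, design)          # ancestry-regression scan
hits = sum(
    hap[hap.probe_id == r.probe_id].nsmallest(1, "p_value").locus_id.iloc[0] == r.interval_id
    for r in truth.itertuples()
)
row  = truth.iloc[0]
best = hap[hap.probe_id == row.probe_id].nsmallest(1, "p_value")
print(f"planted: {row.probe_id} @ {row.interval_id}")
print(f"interval-scan top hit: {best.locus_id.iloc[0]}  p = {best.p_value.iloc[0]:.2e}")
print(f"planted effects at scan minimum: {hits}/10")
```

prints (seed-for-seed):

```
planted: p00000 @ m5_0|m5_1
interval-scan top hit: m5_0|m5_1  p = 3.31e-31
planted effects at scan minimum: 10/10
```

i.e. all ten planted cis effects are recovered at the scan minimum when
the scan uses the simulator's ground-truth ancestry dosages (the HMM
path — `infer_ancestry` + `design_matrix` — does the same with inferred
dosages; at the sparse 10 cM default map inference noise costs exact
localization, which `analysis/04_eqtl_scans.py` quantifies).

The numbered drivers under `analysis/` run the full studies and write
their tables to `results/`:

```
python analysis/01_simulate_crosses.py     # designs, family counts, Haldane check
python analysis/02_expression_qc.py        # what each filter removes
python analysis/03_kinship_structure.py    # chromosome vs genome kinship, hotspot
python analysis/04_eqtl_scans.py           # three scans, planted-effect recovery
python analysis/05_method_concordance.py   # filtering and cis/trans ROC
python analysis/06_overabundance.py        # odds ratios and the kinship substitution
```

For example, `06_overabundance.py` prints:

```
overabundance odds ratios (seed medians): interval scan 2.11, single-marker 1.27, joint model 1.02
chromosome-specific kinship substitution: median OR 4.92 -> 0.98; reduced in 10/10 replicates
```

— under genome-wide polygenic confounding the uncorrected interval
scan shows the largest excess of calls among kinship-correlated pairs,
and substituting the confounding chromosome's kinship into the joint
model removes the excess the genome-wide matrix cannot.

A one-command pipeline (`hseqtl run --out DIR`) chains
simulate → QC → kinship → ancestry → scans → diagnostics with a
reproducibility manifest; individual stages are also exposed
(`hseqtl simulate|qc|kinship|ancestry|scan|concord|overab`).

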