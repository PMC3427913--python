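#!/usr/bin/env python
"""Run the three eQTL scans on one simulated HS-CC dataset.

Single-marker mixed model, interval ancestry regression, and the joint
model, on a cross with planted cis/trans effects and a polygenic
background; reports how many planted effects each scan recovers at its
scan-minimum and how many records pass p < 1e-5.

Writes results/04_scan_summary.tsv; the full per-record eQTL tables
go under scratch/ (they run to hundreds of thousands of rows).
"""

import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from hseqtl.ancestry import HmmParams, design_matrix, infer_ancestry
from hseqtl.kinship import genome_kinship
from hseqtl.mapping import KinshipEigen, classify_cis_trans, interval_scan, jm_scan, sm_scan
from hseqtl.markers import default_marker_map
from hseqtl.popsim import random_pheno_model, simulate_cross, simulate_expression

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"
SCRATCH.mkdir(exist_ok=True)
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
warnings.filterwarnings("ignore")

mm = default_marker_map(5, 8, 10.0)
pop = simulate_cross("HSCC", mm, seed=SEED)
geno = pop.genotypes(seed=SEED + 1)
K = genome_kinship(geno)
pm = random_pheno_model(
    mm, 8, 300, n_cis=20, n_trans=10, cis_effect_sd=1.0, trans_effect_sd=0.7,
    seed=SEED, noise_var=1.0, polygenic_var=0.5,
)
expr, truth, _ = simulate_expression(pop, pm, K, seed=SEED + 2)

kin = KinshipEigen.from_distance(K)
post = infer_ancestry(geno, HmmParams(pop.founder_panel, mm, map_expansion=8.0))
design = design_matrix(post)

tables = {}
tables["sm"], _ = sm_scan(expr, geno, kin, marker_ids=mm.marker_ids)
tables["hap"], _ = interval_scan(expr, design)
tables["jm"], _ = jm_scan(expr, design, kin)

truth_pairs = dict(zip(truth.probe_id, truth.interval_id))
iv_index = {iv.interval_id: k for k, iv in enumerate(mm.intervals())}
rows = []
for name, tab in tables.items():
    tab = classify_cis_trans(tab, expr.probes, mm)
    tab.to_csv(SCRATCH / f"04_eqtl_{name}.tsv", sep="\t", index=False)
    n_sig = int((tab.p_value < 1e-5).sum())
    # scan-minimum localization of planted effects (interval methods):
    # exact interval, and within one interval of it (HMM dosages at a
    # sparse 10 cM map localize to the neighbourhood, not always the
    # exact interval)
    exact = near = 0
    if name in ("hap", "jm"):
        for probe, iv in truth_pairs.items():
            sub = tab[tab.probe_id == probe]
            if not len(sub):
                continue
            best = sub.loc[sub.p_value.idxmin(), "locus_id"]
            exact += best == iv
            near += best in iv_index and abs(iv_index[best] - iv_index[iv]) <= 1
    rows.append(
        {
            "method": name.upper(),
            "records": len(tab),
            "p_below_1e-5": n_sig,
            "planted_exact_at_min": exact if name != "sm" else np.nan,
            "planted_within_one_interval": near if name != "sm" else np.nan,
            "planted_total": len(truth_pairs),
        }
    )
    print(
        f"{name.upper()}: {len(tab)} records, {n_sig} at p<1e-5"
        + (
            f", planted effects at scan minimum: {exact}/{len(truth_pairs)} exact, "
            f"{near}/{len(truth_pairs)} within one interval"
            if name != "sm"
            else ""
        )
    )

# contrast: the same interval scan with the simulator's ground-truth
# ancestry dosages isolates how much localization the sparse-map HMM
# inference costs
from hseqtl.ancestry import true_ancestry_design

design_true = true_ancestry_design(pop.true_dosage(), mm, pop.founder_panel.founder_ids)
tab_true, _ = interval_scan(expr, design_true)
exact_true = 0
for probe, iv in truth_pairs.items():
    sub = tab_true[tab_true.probe_id == probe]
    exact_true += len(sub) and sub.loc[sub.p_value.idxmin(), "locus_id"] == iv
print(
    f"HAP with ground-truth ancestry dosages: {exact_true}/{len(truth_pairs)} planted "
    "effects exact at scan minimum (the gap to the HMM design is ancestry-"
    "inference noise at the sparse 10 cM map)"
)
rows.append(
    {
        "method": "HAP_TRUE_ANCESTRY",
        "records": len(tab_true),
        "p_below_1e-5": int((tab_true.p_value < 1e-5).sum()),
        "planted_exact_at_min": exact_true,
        "planted_within_one_interval": np.nan,
        "planted_total": len(truth_pairs),
    }
)

pd.DataFrame(rows).to_csv(OUT / "04_scan_summary.tsv", sep="\t", index=False)
print(f"written {OUT / '04_scan_summary.tsv'}")
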