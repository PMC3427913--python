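"""Kinship-driven eQTL overabundance diagnostics.

Shared genetic background dispersed over the genome (or over one
chromosome) collectively shifts many expression levels.  Probes whose
pairwise expression-distance matrix correlates with a kinship matrix,
and genomic intervals whose local genetic-distance matrix does the same,
mark exactly the part of the (probe, interval) space where spurious
associations concentrate.  The diagnostic cross-tabulates membership in
this kinship-correlated selection against eQTL calls at a significance
threshold and summarizes the excess with a Fisher-exact odds ratio: an
odds ratio above 1 means the kinship-correlated pairs harbour more eQTLs
than chance.

Comparing the odds ratio across scan procedures shows how much of the
excess each procedure absorbs, and substituting a chromosome-specific
kinship matrix into the mixed model (``adjusted_rescan_comparison``)
quantifies how much chromosome-local relatedness the genome-wide matrix
misses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from hseqtl.kinship import interval_distance, mantel_test, matrix_correlation, phenotype_distance
from hseqtl.mapping import KinshipEigen, jm_scan
from hseqtl.markers import MarkerMap


@dataclass
class SelectionSet:
    """Probes or intervals whose distance matrix tracks a kinship matrix."""

    kind: str                      # "probe" | "interval"
    selected: list[str]
    universe: list[str]
    r_values: dict[str, float]
    excluded: dict[str, str] = field(default_factory=dict)  # id -> reason
    scope: str = "genome"
    threshold: float = 0.1

    def __post_init__(self) -> None:
        if not set(self.selected) <= set(self.universe):
            raise ValueError("selection is not a subset of its universe")


def screen_probes(
    expr,
    K: np.ndarray,
    threshold: float = 0.1,
    scope: str = "genome",
    statistic: str = "correlation",
    n_perm: int = 99,
    seed: int = 0,
) -> SelectionSet:
    """Select probes whose expression-distance matrix correlates with K.

    Per probe the absolute-difference sample distance matrix is
    correlated (upper-triangle Pearson) with the kinship matrix; probes
    with r > threshold are selected.  ``statistic='mantel'`` computes
    the Mantel permutation p-value alongside but still selects on r,
    the screening statistic.  Constant probes have no defined
    correlation and are excluded with a reason.
    """
    if statistic not in ("correlation", "mantel"):
        raise ValueError("statistic must be 'correlation' or 'mantel'")
    values = expr.values if hasattr(expr, "values") else np.asarray(expr, float)
    probe_ids = expr.probe_ids if hasattr(expr, "probe_ids") else [f"p{j:05d}" for j in range(values.shape[1])]
    K = np.asarray(K, float)
    if K.shape[0] != values.shape[0]:
        raise ValueError("kinship and expression sample mismatch")
    selected, r_values, excluded = [], {}, {}
    for j, pid in enumerate(probe_ids):
        D = phenotype_distance(values[:, j])
        if statistic == "mantel":
            try:
                r = mantel_test(D, K, n_perm=n_perm, seed=seed).r
            except ValueError:
                excluded[pid] = "constant_probe"
                continue
        else:
            r = matrix_correlation(D, K)
        if np.isnan(r):
            excluded[pid] = "constant_probe"
            continue
        r_values[pid] = r
        if r > threshold:
            selected.append(pid)
    universe = [p for p in probe_ids if p not in excluded]
    return SelectionSet("probe", selected, universe, r_values, excluded, scope, threshold)


def screen_intervals(
    genotypes: np.ndarray,
    marker_map: MarkerMap,
    K: np.ndarray,
    threshold: float = 0.1,
    statistic: str = "correlation",
    n_perm: int = 99,
    seed: int = 0,
    scope: str = "genome",
) -> SelectionSet:
    """Select intervals whose local genetic distance correlates with K.

    ``statistic='correlation'`` screens on the plain matrix correlation
    (r > threshold); ``'mantel'`` additionally computes the Mantel
    permutation p-value but still selects on r, the screening statistic.
    Monomorphic intervals are excluded.
    """
    if statistic not in ("correlation", "mantel"):
        raise ValueError("statistic must be 'correlation' or 'mantel'")
    G = np.asarray(genotypes, float)
    selected, r_values, excluded = [], {}, {}
    for iv in marker_map.intervals():
        D = interval_distance(G, iv)
        if statistic == "mantel":
            try:
                res = mantel_test(D, K, n_perm=n_perm, seed=seed)
                r = res.r
            except ValueError:
                excluded[iv.interval_id] = "monomorphic_interval"
                continue
        else:
            r = matrix_correlation(D, K)
        if np.isnan(r):
            excluded[iv.interval_id] = "monomorphic_interval"
            continue
        r_values[iv.interval_id] = r
        if r > threshold:
            selected.append(iv.interval_id)
    universe = [iv.interval_id for iv in marker_map.intervals() if iv.interval_id not in excluded]
    return SelectionSet("interval", selected, universe, r_values, excluded, scope, threshold)


@dataclass
class OverabundanceResult:
    """2x2 Fisher-exact summary of eQTL excess in the selected pairs."""

    table: np.ndarray  # [[sel & eqtl, sel & no], [unsel & eqtl, unsel & no]]
    odds_ratio: float
    p_value: float
    method: str
    scope: str
    p_threshold: float
    degenerate: bool = False


def translate_marker_to_intervals(eqtl_table: pd.DataFrame, marker_map: MarkerMap) -> pd.DataFrame:
    """Recast single-marker records onto adjacent intervals.

    Each marker eQTL maps to its one or two adjacent intervals; when both
    flanking markers of an interval hit the same probe, the smaller
    p-value is kept.  Interval-based tables pass through unchanged.
    """
    if (eqtl_table["locus_kind"] == "interval").all():
        return eqtl_table
    from hseqtl.concord import build_correspondence

    corr = build_correspondence(marker_map)
    rows = []
    for row in eqtl_table.itertuples(index=False):
        if row.locus_kind == "interval":
            rows.append(row._asdict())
            continue
        for iv in corr.marker_to_intervals.get(row.locus_id, ()):
            d = row._asdict()
            d["locus_id"] = iv
            d["locus_kind"] = "interval"
            rows.append(d)
    out = pd.DataFrame(rows, columns=eqtl_table.columns)
    return out.sort_values("p_value").drop_duplicates(["probe_id", "locus_id"], keep="first")


def overabundance_test(
    probe_selection: SelectionSet,
    interval_selection: SelectionSet,
    eqtl_table: pd.DataFrame,
    p_threshold: float = 1e-5,
    method: str | None = None,
    conditional: bool = False,
) -> OverabundanceResult:
    """Fisher-exact test of eQTL excess among kinship-correlated pairs.

    Every (probe, interval) pair in the two universes is classified by
    selection membership (both sides selected) x eQTL presence at
    ``p_threshold``; the sample odds ratio ad/bc is reported
    (``conditional=True`` switches to the conditional-MLE odds ratio),
    with the two-sided Fisher exact p-value from the hypergeometric
    distribution.
    """
    probes = probe_selection.universe
    intervals = interval_selection.universe
    sel_p = set(probe_selection.selected)
    sel_i = set(interval_selection.selected)
    sig = eqtl_table[(eqtl_table["p_value"] < p_threshold) & (eqtl_table["locus_kind"] == "interval")]
    probe_univ, interval_univ = set(probes), set(intervals)
    eqtl_pairs = {
        (p, i)
        for p, i in zip(sig["probe_id"], sig["locus_id"])
        if p in probe_univ and i in interval_univ
    }

    n_pairs = len(probes) * len(intervals)
    n_sel = len(sel_p) * len(sel_i)
    n_eqtl = len(eqtl_pairs)
    a = sum(1 for p, i in eqtl_pairs if p in sel_p and i in sel_i)
    b = n_sel - a
    c = n_eqtl - a
    d = n_pairs - n_sel - c
    table = np.array([[a, b], [c, d]], dtype=np.int64)
    if table.min() < 0:
        raise ValueError("inconsistent contingency table")
    degenerate = (b == 0 and d == 0) or (a == 0 and c == 0) or (a == 0 and b == 0) or (c == 0 and d == 0)
    if b * c == 0:
        odds = np.inf if a * d > 0 else (0.0 if a == 0 or d == 0 else np.nan)
    else:
        odds = (a * d) / (b * c)
    if conditional:
        odds = float(stats.contingency.odds_ratio(table, kind="conditional").statistic)
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    if method is None:
        method = ",".join(sorted(eqtl_table["method"].unique())) if len(eqtl_table) else "NA"
    return OverabundanceResult(table, float(odds), p, method, probe_selection.scope, p_threshold, degenerate)


def interval_length_check(
    eqtl_table: pd.DataFrame,
    marker_map: MarkerMap,
    p_threshold: float = 1e-5,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Correlation between per-interval eQTL counts and interval length.

    Guards against the trivial explanation that longer intervals simply
    accumulate more calls.  Returns (pearson r, permutation p); r is NaN
    when all intervals have equal length (undefined).
    """
    ivs = marker_map.intervals()
    lengths = np.array([iv.length_cM for iv in ivs])
    sig = eqtl_table[(eqtl_table["p_value"] < p_threshold) & (eqtl_table["locus_kind"] == "interval")]
    counts = sig.groupby("locus_id").size()
    y = np.array([counts.get(iv.interval_id, 0) for iv in ivs], dtype=float)
    if lengths.std() == 0 or y.std() == 0:
        return float("nan"), float("nan")
    r_obs = float(np.corrcoef(lengths, y)[0, 1])
    rng = np.random.default_rng(seed)
    count = sum(
        abs(float(np.corrcoef(rng.permutation(lengths), y)[0, 1])) >= abs(r_obs) - 1e-12
        for _ in range(n_perm)
    )
    return r_obs, (1 + count) / (1 + n_perm)


def adjusted_rescan_comparison(
    expr,
    design,
    kin_genome: KinshipEigen,
    kin_chrom: KinshipEigen,
    probe_selection: SelectionSet,
    interval_selection: SelectionSet,
    p_threshold: float = 1e-5,
) -> tuple[OverabundanceResult, OverabundanceResult]:
    """Overabundance before/after chromosome-specific kinship substitution.

    Runs the joint model twice — once with the genome-wide kinship, once
    with the chromosome-specific matrix substituted — and evaluates both
    eQTL tables against the same (typically chromosome-specific)
    selection set.  A drop in the odds ratio shows the substituted matrix
    absorbing relatedness the genome-wide one missed.
    """
    t_genome, _ = jm_scan(expr, design, kin_genome)
    t_chrom, _ = jm_scan(expr, design, kin_genome, K_override=kin_chrom)
    res_g = overabundance_test(probe_selection, interval_selection, t_genome, p_threshold, method="JM")
    res_c = overabundance_test(probe_selection, interval_selection, t_chrom, p_threshold, method="JM")
    return res_g, res_c
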