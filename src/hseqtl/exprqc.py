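"""Expression-array quality control.

The filtering suite applied before eQTL mapping, in order:

1. iterated inter-array-correlation (IAC) outlier removal — samples whose
   mean correlation with all other arrays falls more than a set number of
   standard deviations below the mean are dropped, repeated until stable
   (at most ``max_iters`` rounds);
2. strip-level quantile normalization — the array consists of two
   physical strips that behave differently, so classic quantile
   normalization is applied within each strip;
3. SNP-in-probe removal — probes overlapping a known polymorphism in any
   founder strain hybridize differentially by genotype and are removed;
4. detection-call filtering — probes not reliably detected (detection
   p-value below ``alpha``) in at least a quarter of samples are removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass
class ExpressionMatrix:
    """samples x probes log-scale intensities with probe annotations.

    ``probes`` must carry at least ``probe_id``; coordinate columns
    (``chromosome``, ``start``, ``end``) and ``strip_id`` enable the SNP
    and strip-aware steps.  ``detection_pvals`` aligns with ``values``.
    """

    values: np.ndarray
    sample_ids: list[str]
    probes: pd.DataFrame
    detection_pvals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.probes)):
            raise ValueError("values shape does not match sample_ids x probes")
        if self.detection_pvals is not None:
            self.detection_pvals = np.asarray(self.detection_pvals, dtype=float)
            if self.detection_pvals.shape != self.values.shape:
                raise ValueError("detection_pvals shape mismatch")
            if ((self.detection_pvals < 0) | (self.detection_pvals > 1)).any():
                raise ValueError("detection p-values must lie in [0, 1]")
        self.probes = self.probes.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    @property
    def probe_ids(self) -> list[str]:
        return self.probes["probe_id"].tolist()

    def subset_samples(self, idx: np.ndarray) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return ExpressionMatrix(
            values=self.values[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            probes=self.probes,
            detection_pvals=None if self.detection_pvals is None else self.detection_pvals[idx],
        )

    def subset_probes(self, idx: np.ndarray) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return ExpressionMatrix(
            values=self.values[:, idx],
            sample_ids=self.sample_ids,
            probes=self.probes.iloc[idx],
            detection_pvals=None if self.detection_pvals is None else self.detection_pvals[:, idx],
        )


@dataclass
class QcReport:
    """Bookkeeping of what each QC stage removed and why."""

    removed_samples: list[list[str]] = field(default_factory=list)  # per IAC iteration
    removed_probes: dict[str, list[str]] = field(default_factory=dict)  # reason -> probe ids
    n_samples_before: int = 0
    n_samples_after: int = 0
    n_probes_before: int = 0
    n_probes_after: int = 0

    @property
    def n_iterations(self) -> int:
        return len(self.removed_samples)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for it, samples in enumerate(self.removed_samples, start=1):
            for s in samples:
                rows.append({"stage": f"iac_iter{it}", "kind": "sample", "id": s})
        for reason, probes in self.removed_probes.items():
            for p in probes:
                rows.append({"stage": reason, "kind": "probe", "id": p})
        return pd.DataFrame(rows, columns=["stage", "kind", "id"])


# ---------------------------------------------------------------------------
# 1. IAC outlier removal
# ---------------------------------------------------------------------------
def mean_interarray_correlation(values: np.ndarray) -> np.ndarray:
    """Each sample's mean Pearson correlation with every other sample."""
    C = np.corrcoef(values)
    n = C.shape[0]
    return (C.sum(axis=1) - 1.0) / (n - 1)


def iac_outlier_removal(
    expr: ExpressionMatrix,
    sd_cutoff: float = 2.0,
    max_iters: int = 3,
    two_sided: bool = False,
) -> tuple[ExpressionMatrix, QcReport]:
    """Iteratively drop arrays with anomalously low inter-array correlation.

    Per iteration the mean IAC per sample is computed and samples more
    than ``sd_cutoff`` SDs below the mean of these values are removed;
    iteration stops when stable or after ``max_iters`` rounds.  Only the
    low side is anomalous by default (``two_sided=True`` also removes
    unusually high-IAC samples, the literal reading of "away from the
    mean").
    """
    if expr.n_samples < 3:
        raise ValueError("need at least 3 samples for IAC outlier removal")
    report = QcReport(n_samples_before=expr.n_samples, n_probes_before=expr.n_probes)
    cur = expr
    for _ in range(max_iters):
        iac = mean_interarray_correlation(cur.values)
        mu, sd = iac.mean(), iac.std()
        if sd == 0:
            break
        low = iac < mu - sd_cutoff * sd
        if two_sided:
            low |= iac > mu + sd_cutoff * sd
        if not low.any():
            break
        if (~low).sum() < 3:
            raise ValueError("IAC outlier removal would leave fewer than 3 samples")
        report.removed_samples.append([cur.sample_ids[i] for i in np.where(low)[0]])
        cur = cur.subset_samples(np.where(~low)[0])
    report.n_samples_after = cur.n_samples
    report.n_probes_after = cur.n_probes
    return cur, report


# ---------------------------------------------------------------------------
# 2. strip-level quantile normalization
# ---------------------------------------------------------------------------
def _quantile_normalize_block(block: np.ndarray) -> np.ndarray:
    """Classic quantile normalization of a samples x probes block.

    Each sample's sorted values are replaced by the across-sample mean of
    order statistics; ties within a sample get the average of the tied
    ranks' reference values.
    """
    ref = np.sort(block, axis=1).mean(axis=0)
    out = np.empty_like(block)
    for i in range(block.shape[0]):
        ranks = rankdata(block[i], method="average")  # 1-based, ties averaged
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        out[i] = 0.5 * (ref[lo] + ref[hi])
    return out


def strip_quantile_normalize(expr: ExpressionMatrix, strip_assignment: np.ndarray | None = None) -> ExpressionMatrix:
    """Quantile-normalize across samples within each physical array strip."""
    if strip_assignment is None:
        if "strip_id" not in expr.probes.columns:
            raise ValueError("no strip assignment available")
        strip_assignment = expr.probes["strip_id"].to_numpy()
    strip_assignment = np.asarray(strip_assignment)
    if len(strip_assignment) != expr.n_probes:
        raise ValueError("strip assignment must cover every probe exactly once")
    values = expr.values.copy()
    for strip in pd.unique(strip_assignment):
        cols = np.where(strip_assignment == strip)[0]
        if len(cols) < 2:
            warnings.warn(f"strip {strip!r} has a single probe; passed through unchanged")
            continue
        values[:, cols] = _quantile_normalize_block(values[:, cols])
    return ExpressionMatrix(values, expr.sample_ids, expr.probes, expr.detection_pvals)


# ---------------------------------------------------------------------------
# 3. SNP-in-probe filter
# ---------------------------------------------------------------------------
def snp_probe_filter(expr: ExpressionMatrix, snp_table: pd.DataFrame) -> tuple[ExpressionMatrix, QcReport]:
    """Remove probes whose [start, end) span contains a known SNP.

    Coordinates are 0-based half-open for probes; SNP positions 0-based.
    Probes lacking coordinates cannot be assessed and are retained with a
    warning.
    """
    report = QcReport(
        n_samples_before=expr.n_samples,
        n_samples_after=expr.n_samples,
        n_probes_before=expr.n_probes,
    )
    probes = expr.probes
    has_coords = {"chromosome", "start", "end"}.issubset(probes.columns)
    if not has_coords:
        warnings.warn("probes lack coordinates; SNP-in-probe filter skipped")
        report.n_probes_after = expr.n_probes
        report.removed_probes["snp_overlap"] = []
        return expr, report

    coord_ok = probes["start"].notna() & probes["end"].notna() & probes["chromosome"].notna()
    if not coord_ok.all():
        warnings.warn(f"{(~coord_ok).sum()} probes lack coordinates; retained (cannot be assessed)")
    snp_by_chrom = {
        str(c): np.sort(g["position"].to_numpy(np.int64))
        for c, g in snp_table.groupby("chromosome")
    }
    hit = np.zeros(expr.n_probes, dtype=bool)
    for j, row in enumerate(probes.itertuples(index=False)):
        if not coord_ok.iloc[j]:
            continue
        snps = snp_by_chrom.get(str(row.chromosome))
        if snps is None:
            continue
        lo = np.searchsorted(snps, int(row.start), side="left")
        hi = np.searchsorted(snps, int(row.end), side="left")
        hit[j] = hi > lo
    report.removed_probes["snp_overlap"] = probes.loc[hit, "probe_id"].tolist()
    out = expr.subset_probes(np.where(~hit)[0])
    report.n_probes_after = out.n_probes
    return out, report


# ---------------------------------------------------------------------------
# 4. detection-call filter
# ---------------------------------------------------------------------------
def detection_filter(
    expr: ExpressionMatrix, alpha: float = 0.01, min_fraction: float = 0.25
) -> tuple[ExpressionMatrix, QcReport]:
    """Keep probes detected (p < alpha) in at least ``min_fraction`` of samples.

    "At least a quarter" is inclusive: a probe detected in exactly
    ceil(min_fraction * n_samples) samples is kept.
    """
    if expr.detection_pvals is None:
        raise ValueError("detection p-values are required for the detection filter")
    need = int(np.ceil(min_fraction * expr.n_samples))
    detected = (expr.detection_pvals < alpha).sum(axis=0)
    keep = detected >= need
    report = QcReport(
        n_samples_before=expr.n_samples,
        n_samples_after=expr.n_samples,
        n_probes_before=expr.n_probes,
    )
    report.removed_probes["low_detection"] = expr.probes.loc[~keep, "probe_id"].tolist()
    out = expr.subset_probes(np.where(keep)[0])
    report.n_probes_after = out.n_probes
    return out, report


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------
def run_qc(
    expr: ExpressionMatrix,
    snp_table: pd.DataFrame | None = None,
    sd_cutoff: float = 2.0,
    max_iters: int = 3,
    alpha: float = 0.01,
    min_fraction: float = 0.25,
) -> tuple[ExpressionMatrix, QcReport]:
    """The full filter suite in pipeline order.

    Outlier removal -> strip quantile normalization -> SNP-in-probe
    filter -> detection filter, with one consolidated report.
    """
    out, rep_iac = iac_outlier_removal(expr, sd_cutoff=sd_cutoff, max_iters=max_iters)
    out = strip_quantile_normalize(out)
    report = QcReport(
        removed_samples=rep_iac.removed_samples,
        n_samples_before=expr.n_samples,
        n_probes_before=expr.n_probes,
    )
    if snp_table is not None:
        out, rep_snp = snp_probe_filter(out, snp_table)
        report.removed_probes.update(rep_snp.removed_probes)
    if out.detection_pvals is not None:
        out, rep_det = detection_filter(out, alpha=alpha, min_fraction=min_fraction)
        report.removed_probes.update(rep_det.removed_probes)
    report.n_samples_after = out.n_samples
    report.n_probes_after = out.n_probes
    return out, report
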