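"""The three eQTL scan procedures.

``sm_scan`` — single-marker mixed-model association: per probe a null
variance-components model with a kinship-derived similarity matrix is
fitted once by REML using the spectral (single eigendecomposition)
trick, then every marker is tested by generalized least squares with the
variance ratio held fixed — the efficient mixed-model approximation.

``interval_scan`` — founder-ancestry interval regression: per (probe,
interval) an OLS F-test of the additive founder-dosage design against
the intercept-only null, with no relatedness correction.

``jm_scan`` — the joint model: the founder-dosage design tested inside
the mixed-model framework, combining ancestral-allele effect estimation
with kinship correction.  A chromosome-specific kinship matrix may be
substituted for the genome-wide one (``K_override``) to absorb
chromosome-local relatedness that the genome-wide matrix misses.

The mixed model is y = Xb + u + e with cov(u) = sigma_g^2 S for a PSD
similarity S derived from the manhattan distance matrix, and
delta = sigma_e^2 / sigma_g^2 profiled out on a log grid with local
refinement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from hseqtl.ancestry import AncestryDesign
from hseqtl.kinship import distance_to_similarity
from hseqtl.markers import MarkerMap

EQTL_COLUMNS = ["probe_id", "locus_id", "locus_kind", "method", "statistic", "p_value", "cis_flag"]

# module-level counter so tests can assert the decomposition is cached
N_EIGENDECOMPOSITIONS = 0


class KinshipEigen:
    """Similarity matrix with its eigendecomposition, computed once.

    All scans share this cache; constructing it is the only place an
    eigendecomposition happens.
    """

    def __init__(self, S: np.ndarray):
        global N_EIGENDECOMPOSITIONS
        S = np.asarray(S, float)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.allclose(S, S.T, atol=1e-8):
            raise ValueError("similarity matrix must be symmetric")
        self.S = S
        self.eigenvalues, self.eigenvectors = np.linalg.eigh(S)
        N_EIGENDECOMPOSITIONS += 1
        if self.eigenvalues.min() < -1e-6:
            raise ValueError("similarity matrix is not PSD; repair it first (distance_to_similarity)")
        self.eigenvalues = np.clip(self.eigenvalues, 0.0, None)

    @classmethod
    def from_distance(cls, D: np.ndarray) -> "KinshipEigen":
        return cls(distance_to_similarity(D))

    @property
    def n(self) -> int:
        return self.S.shape[0]

    @property
    def degenerate(self) -> bool:
        """True when S is (numerically) a multiple of the identity."""
        w = self.eigenvalues
        return bool(w.max() - w.min() < 1e-10 * max(w.max(), 1.0))

    def rotate(self, a: np.ndarray) -> np.ndarray:
        return self.eigenvectors.T @ a


@dataclass
class MixedModelFit:
    """Null-model variance components for one phenotype."""

    delta: float          # sigma_e^2 / sigma_g^2
    sigma_g2: float
    sigma_e2: float
    loglik: float
    reml: bool
    flagged: bool         # optimizer at the grid boundary
    degenerate: bool      # S ~ identity: variance split unidentifiable

    @property
    def genetic_fraction(self) -> float:
        return self.sigma_g2 / (self.sigma_g2 + self.sigma_e2)


def _wls_rss(ystar: np.ndarray, Xstar: np.ndarray, w: np.ndarray):
    """Weighted RSS and log|X' W X| for rotated data with weights w."""
    sw = np.sqrt(w)
    Xw = Xstar * sw[:, None]
    yw = ystar * sw
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    sign, logdet = np.linalg.slogdet(Xw.T @ Xw)
    return rss, logdet, rank


def reml_loglik(delta: float, ystar: np.ndarray, Xstar: np.ndarray, lambdas: np.ndarray, reml: bool = True) -> float:
    """Profile (restricted) log-likelihood of the variance ratio delta.

    Evaluated in the eigenbasis of the similarity matrix: weights are
    1/(lambda_i + delta) and sigma_g^2 is profiled out analytically.
    """
    n, p = Xstar.shape
    w = 1.0 / (lambdas + delta)
    rss, logdet_xwx, rank = _wls_rss(ystar, Xstar, w)
    if rss <= 0:
        rss = 1e-300
    logw = np.log(w)
    if reml:
        df = n - rank
        sg2 = rss / df
        sign, logdet_xx = np.linalg.slogdet(Xstar.T @ Xstar)
        return -0.5 * (
            df * np.log(2 * np.pi * sg2) + df - logw.sum() + logdet_xwx - logdet_xx
        )
    sg2 = rss / n
    return -0.5 * (n * np.log(2 * np.pi * sg2) + n - logw.sum())


def fit_null_mixed(
    y: np.ndarray,
    kin: KinshipEigen,
    X: np.ndarray | None = None,
    reml: bool = True,
    grid: tuple[float, float, int] = (-5.0, 5.0, 61),
) -> MixedModelFit:
    """REML/ML fit of the single-variance-ratio null mixed model.

    delta is optimized over a log10 grid with local bounded refinement;
    the eigendecomposition comes from ``kin`` and is never recomputed.
    A degenerate similarity (identity-like) makes the variance split
    unidentifiable; the fit is flagged and downstream GLS reduces to OLS.
    """
    y = np.asarray(y, float).ravel()
    n = y.shape[0]
    if n != kin.n:
        raise ValueError("phenotype and kinship dimension mismatch")
    if n < 5:
        raise ValueError("need at least 5 individuals")
    if X is None:
        X = np.ones((n, 1))
    ystar = kin.rotate(y)
    Xstar = kin.rotate(X)
    lam = kin.eigenvalues

    if kin.degenerate:
        w = np.ones(n)
        rss, _, rank = _wls_rss(ystar, Xstar, w)
        s2 = rss / (n - rank if reml else n)
        ll = reml_loglik(1.0, ystar, Xstar, lam, reml=reml)
        return MixedModelFit(1.0, s2 / 2, s2 / 2, ll, reml, flagged=True, degenerate=True)

    lo, hi, npts = grid
    log_deltas = np.linspace(lo, hi, int(npts))
    lls = np.array([reml_loglik(10.0 ** ld, ystar, Xstar, lam, reml) for ld in log_deltas])
    k = int(np.argmax(lls))
    flagged = k in (0, len(log_deltas) - 1)
    if flagged:
        warnings.warn("variance-ratio optimum at grid boundary")
        best_ld = log_deltas[k]
    else:
        res = optimize.minimize_scalar(
            lambda ld: -reml_loglik(10.0 ** ld, ystar, Xstar, lam, reml),
            bounds=(log_deltas[k - 1], log_deltas[k + 1]),
            method="bounded",
        )
        best_ld = float(res.x)
    delta = 10.0 ** best_ld
    w = 1.0 / (lam + delta)
    rss, _, rank = _wls_rss(ystar, Xstar, w)
    sg2 = rss / (n - rank if reml else n)
    se2 = delta * sg2
    ll = reml_loglik(delta, ystar, Xstar, lam, reml)
    return MixedModelFit(delta, sg2, se2, ll, reml, flagged=flagged, degenerate=False)


def _as_values(expr) -> tuple[np.ndarray, list[str]]:
    """Accept an ExpressionMatrix or a plain (values, probe_ids)-like array."""
    if hasattr(expr, "values") and hasattr(expr, "probe_ids"):
        return expr.values, expr.probe_ids
    v = np.asarray(expr, float)
    return v, [f"p{j:05d}" for j in range(v.shape[1])]


def make_eqtl_table(records: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(records, columns=EQTL_COLUMNS)


# ---------------------------------------------------------------------------
# single-marker mixed-model scan
# ---------------------------------------------------------------------------
def sm_scan(
    expr,
    genotypes: np.ndarray,
    kin: KinshipEigen,
    marker_ids: list[str] | None = None,
    reml: bool = True,
    exact: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-marker scan for every (probe, marker) pair.

    Per probe the null variance components are estimated once and held
    fixed across markers; each marker is then a 1-df GLS F-test in the
    rotated (whitened) coordinates.  ``exact=True`` instead re-estimates
    the variance ratio under each (probe, marker) model — the full
    per-locus REML, at marker-count times the cost.  Monomorphic markers
    are skipped with a reason.  Returns (eqtl_table, skipped).
    """
    Y, probe_ids = _as_values(expr)
    G = np.asarray(genotypes, float)
    n, M = G.shape
    if Y.shape[0] != n or kin.n != n:
        raise ValueError("sample dimension mismatch")
    marker_ids = marker_ids or [f"m{j}" for j in range(M)]

    mono = G.std(axis=0) == 0
    skipped = pd.DataFrame(
        {"locus_id": [marker_ids[j] for j in np.where(mono)[0]], "reason": "monomorphic"}
    )
    test_cols = np.where(~mono)[0]

    Gstar = kin.rotate(G)
    ones_star = kin.rotate(np.ones(n))
    records: list[dict] = []
    for jp in range(Y.shape[1]):
        y = Y[:, jp]
        ystar = kin.rotate(y)
        if exact:
            for idx, j in enumerate(test_cols):
                Xj = np.column_stack([np.ones(n), G[:, j]])
                fitj = fit_null_mixed(y, kin, X=Xj, reml=reml)
                wj = np.ones(n) if fitj.degenerate else 1.0 / (kin.eigenvalues + fitj.delta)
                sw = np.sqrt(wj)
                Xw = kin.rotate(Xj) * sw[:, None]
                yw = ystar * sw
                beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
                r1 = yw - Xw @ beta
                rss1 = max(float(r1 @ r1), 1e-300)
                x0w = Xw[:, :1]
                b0 = float((x0w[:, 0] @ yw) / (x0w[:, 0] @ x0w[:, 0]))
                r0 = yw - b0 * x0w[:, 0]
                rss0 = float(r0 @ r0)
                Fj = max((rss0 - rss1) / (rss1 / (n - 2)), 0.0)
                records.append(
                    {
                        "probe_id": probe_ids[jp],
                        "locus_id": marker_ids[j],
                        "locus_kind": "marker",
                        "method": "SM",
                        "statistic": float(Fj),
                        "p_value": float(max(stats.f.sf(Fj, 1, n - 2), np.finfo(float).tiny)),
                        "cis_flag": None,
                    }
                )
            continue
        fit = fit_null_mixed(y, kin, reml=reml)
        w = np.ones(n) if fit.degenerate else 1.0 / (kin.eigenvalues + fit.delta)
        # weighted simple linear regression, vectorized across markers
        x0 = ones_star
        S0 = float(w @ (x0 * x0))
        Sy = float(w @ (x0 * ystar))
        Syy = float(w @ (ystar * ystar))
        rss0 = Syy - Sy * Sy / S0
        Gs = Gstar[:, test_cols]
        Sx = (w * x0) @ Gs
        Sxx = w @ (Gs * Gs)
        Sxy = (w * ystar) @ Gs
        vxx = Sxx - Sx * Sx / S0
        vxy = Sxy - Sx * Sy / S0
        ok = vxx > 1e-12
        rss1 = np.where(ok, rss0 - np.where(ok, vxy, 0.0) ** 2 / np.where(ok, vxx, 1.0), np.nan)
        rss1 = np.clip(rss1, 1e-300, None)
        df2 = n - 2
        Fstat = (rss0 - rss1) / (rss1 / df2)
        pvals = stats.f.sf(Fstat, 1, df2)
        pid = probe_ids[jp]
        for idx, j in enumerate(test_cols):
            if not ok[idx]:
                continue
            records.append(
                {
                    "probe_id": pid,
                    "locus_id": marker_ids[j],
                    "locus_kind": "marker",
                    "method": "SM",
                    "statistic": float(Fstat[idx]),
                    "p_value": float(max(pvals[idx], np.finfo(float).tiny)),
                    "cis_flag": None,
                }
            )
    return make_eqtl_table(records), skipped


# ---------------------------------------------------------------------------
# interval (ancestry regression) scan
# ---------------------------------------------------------------------------
def interval_scan(expr, design: AncestryDesign) -> tuple[pd.DataFrame, pd.DataFrame]:
    """OLS F-test of the additive founder design per (probe, interval).

    One founder column is implicitly dropped via the rank of the centred
    design; rank-deficient designs lose further columns with adjusted
    degrees of freedom.  No kinship correction — this is the pure
    ancestry-regression procedure.
    """
    Y, probe_ids = _as_values(expr)
    n = Y.shape[0]
    if design.dosage.shape[1] != n:
        raise ValueError("design and expression sample mismatch")
    Yc = Y - Y.mean(axis=0)
    tss = (Yc * Yc).sum(axis=0)
    records: list[dict] = []
    skipped_rows: list[dict] = []
    for k in range(design.n_intervals):
        iv = design.intervals[k]
        if not design.testable[k]:
            skipped_rows.append({"locus_id": iv.interval_id, "reason": "monomorphic_ancestry"})
            continue
        D = design.dosage[k]
        Dc = D - D.mean(axis=0)
        U, s, _ = np.linalg.svd(Dc, full_matrices=False)
        rank = int((s > 1e-8 * s[0]).sum())
        Q = U[:, :rank]
        proj = Q.T @ Yc
        rss1 = np.clip(tss - (proj * proj).sum(axis=0), 1e-300, None)
        df1, df2 = rank, n - rank - 1
        F = ((tss - rss1) / df1) / (rss1 / df2)
        P = stats.f.sf(F, df1, df2)
        for jp in range(Y.shape[1]):
            records.append(
                {
                    "probe_id": probe_ids[jp],
                    "locus_id": iv.interval_id,
                    "locus_kind": "interval",
                    "method": "HAP",
                    "statistic": float(F[jp]),
                    "p_value": float(max(P[jp], np.finfo(float).tiny)),
                    "cis_flag": None,
                }
            )
    return make_eqtl_table(records), pd.DataFrame(skipped_rows, columns=["locus_id", "reason"])


# ---------------------------------------------------------------------------
# joint model
# ---------------------------------------------------------------------------
def jm_scan(
    expr,
    design: AncestryDesign,
    kin: KinshipEigen,
    K_override: KinshipEigen | None = None,
    reml: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Founder-dosage design tested inside the mixed-model framework.

    Per probe the null variance components are fitted once (fixed across
    intervals); per (probe, interval) the founder columns are F-tested by
    GLS in the whitened coordinates.  ``K_override`` substitutes a
    different (e.g. chromosome-specific) kinship for the genome-wide one.
    """
    use = K_override if K_override is not None else kin
    Y, probe_ids = _as_values(expr)
    n = Y.shape[0]
    if design.dosage.shape[1] != n or use.n != n:
        raise ValueError("sample dimension mismatch")

    ones_star = use.rotate(np.ones(n))
    Dstars = []
    for k in range(design.n_intervals):
        Dstars.append(use.rotate(design.dosage[k]) if design.testable[k] else None)
    records: list[dict] = []
    skipped_rows = [
        {"locus_id": design.intervals[k].interval_id, "reason": "monomorphic_ancestry"}
        for k in range(design.n_intervals)
        if not design.testable[k]
    ]
    tiny = np.finfo(float).tiny
    for jp in range(Y.shape[1]):
        y = Y[:, jp]
        fit = fit_null_mixed(y, use, reml=reml)
        w = np.ones(n) if fit.degenerate else 1.0 / (use.eigenvalues + fit.delta)
        sw = np.sqrt(w)
        yw = use.rotate(y) * sw
        x0w = ones_star * sw
        b0 = (x0w @ yw) / (x0w @ x0w)
        r0 = yw - b0 * x0w
        rss0 = float(r0 @ r0)
        pid = probe_ids[jp]
        for k in range(design.n_intervals):
            Dstar = Dstars[k]
            if Dstar is None:
                continue
            Xw = np.column_stack([x0w, Dstar * sw[:, None]])
            U, s, _ = np.linalg.svd(Xw, full_matrices=False)
            rank = int((s > 1e-8 * s[0]).sum())
            Q = U[:, :rank]
            proj = Q.T @ yw
            rss1 = max(float(yw @ yw - proj @ proj), 1e-300)
            df1 = rank - 1
            df2 = n - rank
            if df1 < 1 or df2 < 1:
                continue
            F = ((rss0 - rss1) / df1) / (rss1 / df2)
            records.append(
                {
                    "probe_id": pid,
                    "locus_id": design.intervals[k].interval_id,
                    "locus_kind": "interval",
                    "method": "JM",
                    "statistic": float(max(F, 0.0)),
                    "p_value": float(max(stats.f.sf(max(F, 0.0), df1, df2), tiny)),
                    "cis_flag": None,
                }
            )
    return make_eqtl_table(records), pd.DataFrame(skipped_rows, columns=["locus_id", "reason"])


# ---------------------------------------------------------------------------
# cis/trans classification
# ---------------------------------------------------------------------------
def classify_cis_trans(
    eqtl_table: pd.DataFrame, probes: pd.DataFrame, marker_map: MarkerMap
) -> pd.DataFrame:
    """Set the cis/trans flag with method-specific rules.

    Interval methods (HAP/JM): cis when the gene lies between the two
    markers defining the tested interval.  Single-marker: cis when the
    significant marker is one of the two markers flanking the gene.
    Probes without coordinates get ``unknown``.
    """
    from hseqtl.popsim import CM_TO_BP

    probe_pos: dict[str, tuple[str, float] | None] = {}
    for row in probes.itertuples(index=False):
        if hasattr(row, "position_cM") and pd.notna(row.position_cM):
            probe_pos[row.probe_id] = (str(row.chromosome), float(row.position_cM))
        elif hasattr(row, "start") and pd.notna(row.start) and pd.notna(row.chromosome):
            probe_pos[row.probe_id] = (str(row.chromosome), float(row.start) / CM_TO_BP)
        else:
            probe_pos[row.probe_id] = None

    # flanking markers of a position: nearest marker at or left, nearest right
    def flanking_markers(chrom: str, cm: float) -> set[str]:
        sl = marker_map.chrom_slice(chrom)
        pos = marker_map.pos_cM[sl]
        ids = marker_map.marker_ids[sl.start:sl.stop]
        j = int(np.searchsorted(pos, cm, side="right"))
        out = set()
        if j > 0:
            out.add(ids[j - 1])
        if j < len(ids):
            out.add(ids[j])
        return out

    interval_bounds = {
        iv.interval_id: (iv.chrom, iv.left_cM, iv.right_cM) for iv in marker_map.intervals()
    }
    marker_chrom_pos = {
        marker_id: (str(marker_map.chrom[i]), float(marker_map.pos_cM[i]))
        for i, marker_id in enumerate(marker_map.marker_ids)
    }

    flags = []
    for row in eqtl_table.itertuples(index=False):
        loc = probe_pos.get(row.probe_id)
        if loc is None:
            flags.append("unknown")
            continue
        chrom, cm = loc
        if row.locus_kind == "interval":
            ic, lo, hi = interval_bounds[row.locus_id]
            flags.append("cis" if (ic == chrom and lo <= cm <= hi) else "trans")
        else:
            if chrom not in marker_map.chromosomes:
                flags.append("unknown")
                continue
            flags.append("cis" if row.locus_id in flanking_markers(chrom, cm) else "trans")
    out = eqtl_table.copy()
    out["cis_flag"] = flags
    return out
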