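"""Cross-method concordance via adapted ROC analysis.

The single-marker and interval scans address different genomic units, so
agreement is judged through the interval/marker adjacency: an interval
call reproduces a single-marker call when the marker is one of the two
flanking markers of the interval.  Holding the single-marker reference
fixed at a significance threshold and sweeping the interval-method
threshold from 0 to 1 traces a curve in the unit square: the "true
positive" proportion is the fraction of reference eQTLs recovered, the
"false positive" proportion the fraction of the non-reference candidate
space called.  Chance overlap follows the main diagonal; perfect overlap
passes through (0, 1).

"False positive" here is operational — disagreement with the reference
method — not a ground-truth error.  :func:`truth_roc` provides the
genuinely truth-based evaluation against a simulator truth table under a
distinct name to avoid conflation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hseqtl.markers import MarkerMap


@dataclass
class CorrespondenceMap:
    """Bidirectional interval <-> flanking-marker adjacency."""

    interval_to_markers: dict[str, tuple[str, str]]
    marker_to_intervals: dict[str, list[str]]


def build_correspondence(marker_map: MarkerMap) -> CorrespondenceMap:
    """Adjacency between intervals and their flanking markers.

    A chromosome-terminal marker is adjacent to one interval, inner
    markers to two; a single-marker chromosome contributes no intervals.
    """
    i2m: dict[str, tuple[str, str]] = {}
    m2i: dict[str, list[str]] = {m: [] for m in marker_map.marker_ids}
    for iv in marker_map.intervals():
        left_id = marker_map.marker_ids[iv.left]
        right_id = marker_map.marker_ids[iv.right]
        i2m[iv.interval_id] = (left_id, right_id)
        m2i[left_id].append(iv.interval_id)
        m2i[right_id].append(iv.interval_id)
    for c in marker_map.chromosomes:
        sl = marker_map.chrom_slice(c)
        if sl.stop - sl.start < 2:
            warnings.warn(f"chromosome {c} has a single marker: no intervals")
    return CorrespondenceMap(i2m, m2i)


@dataclass
class RocCurve:
    """Concordance curve: (FP, TP) per threshold, with trapezoidal AUC."""

    thresholds: np.ndarray
    fp: np.ndarray
    tp: np.ndarray
    auc: float = field(init=False)

    def __post_init__(self) -> None:
        order = np.argsort(self.fp, kind="stable")
        fp, tp = self.fp[order], self.tp[order]
        self.auc = float(np.trapezoid(tp, fp))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds, "fp": self.fp, "tp": self.tp})


def _reference_pairs(reference_eqtls: pd.DataFrame, ref_p: float) -> set[tuple[str, str]]:
    sig = reference_eqtls[reference_eqtls["p_value"] < ref_p]
    return set(zip(sig["probe_id"], sig["locus_id"]))


def roc_concordance(
    reference_eqtls: pd.DataFrame,
    candidate_eqtls: pd.DataFrame,
    correspondence: CorrespondenceMap,
    ref_p: float = 0.01,
    thresholds: np.ndarray | None = None,
) -> RocCurve:
    """Concordance curve of an interval method against a fixed reference.

    ``reference_eqtls`` are single-marker records (fixed at ``ref_p``);
    ``candidate_eqtls`` are interval records whose p-values act as the
    swept score.  The threshold grid defaults to every distinct candidate
    p-value plus {0, 1}, giving the exact step curve.
    """
    ref_pairs = _reference_pairs(reference_eqtls, ref_p)
    if not ref_pairs:
        raise ValueError("reference eQTL set is empty at the chosen threshold")

    cand = candidate_eqtls
    # translated reference: interval pairs adjacent to some reference marker
    refstar: set[tuple[str, str]] = set()
    for probe, marker in ref_pairs:
        for iv in correspondence.marker_to_intervals.get(marker, ()):
            refstar.add((probe, iv))

    cand_pairs = list(zip(cand["probe_id"], cand["locus_id"]))
    cand_p = cand["p_value"].to_numpy(float)
    # a reference pair the candidate method never tested (outside its
    # universe, e.g. a different stratum or a skipped interval) cannot be
    # recovered and is excluded from the recovery denominator
    refstar &= set(cand_pairs)
    if not refstar:
        raise ValueError("no translated reference pair lies in the candidate universe")
    is_refstar = np.array([pair in refstar for pair in cand_pairs], dtype=bool)

    if thresholds is None:
        thresholds = np.unique(np.concatenate([cand_p, [0.0, 1.0]]))
    thresholds = np.asarray(thresholds, float)

    # TP: fraction of translated reference pairs called; FP: fraction of
    # the non-reference candidate space called.  Counting both at the
    # pair level keeps chance overlap on the main diagonal.
    n_ref = len(refstar)
    ref_p = cand_p[is_refstar]
    nonref_p = cand_p[~is_refstar]
    n_nonref = int((~is_refstar).sum())
    fp = np.array([0.0 if n_nonref == 0 else (nonref_p <= t).mean() for t in thresholds])
    tp = np.array([(ref_p <= t).sum() / n_ref for t in thresholds])
    # anchor the curve at its corners
    thresholds = np.concatenate([[-np.inf], thresholds, [np.inf]])
    fp = np.concatenate([[0.0], fp, [1.0]])
    tp = np.concatenate([[0.0], tp, [1.0]])
    return RocCurve(thresholds, fp, tp)


def stratified_concordance(
    reference_eqtls: pd.DataFrame,
    candidate_eqtls: pd.DataFrame,
    correspondence: CorrespondenceMap,
    stratum: str = "all",
    ref_p: float = 0.01,
    thresholds: np.ndarray | None = None,
) -> RocCurve:
    """Concordance restricted to cis or trans pairs.

    Both tables must carry ``cis_flag`` (see ``classify_cis_trans``);
    ``stratum='all'`` is unrestricted.
    """
    if stratum not in ("cis", "trans", "all"):
        raise ValueError("stratum must be one of {'cis','trans','all'}")
    ref, cand = reference_eqtls, candidate_eqtls
    if stratum != "all":
        ref = ref[ref["cis_flag"] == stratum]
        cand = cand[cand["cis_flag"] == stratum]
        if len(ref) == 0 or len(cand) == 0:
            raise ValueError(f"stratum {stratum!r} is empty in the reference or candidate table")
    return roc_concordance(ref, cand, correspondence, ref_p=ref_p, thresholds=thresholds)


def truth_roc(candidate_eqtls: pd.DataFrame, truth: pd.DataFrame, thresholds: np.ndarray | None = None) -> RocCurve:
    """Truth-based ROC against the simulator's planted-eQTL table.

    A candidate (probe, interval) pair is a true positive when it appears
    in the truth table; the false-positive proportion is over the
    remaining candidate pairs.  Distinct from the cross-method
    concordance curve, whose "false positives" are mere disagreements.
    """
    truth_pairs = set(zip(truth["probe_id"], truth["interval_id"]))
    if not truth_pairs:
        raise ValueError("truth table is empty")
    cand_p = candidate_eqtls["p_value"].to_numpy(float)
    is_true = np.array(
        [
            (probe, iv) in truth_pairs
            for probe, iv in zip(candidate_eqtls["probe_id"], candidate_eqtls["locus_id"])
        ],
        dtype=bool,
    )
    if thresholds is None:
        thresholds = np.unique(np.concatenate([cand_p, [0.0, 1.0]]))
    thresholds = np.asarray(thresholds, float)
    pos_p, neg_p = cand_p[is_true], cand_p[~is_true]
    tp = np.array([(pos_p <= t).mean() if len(pos_p) else 0.0 for t in thresholds])
    fp = np.array([(neg_p <= t).mean() if len(neg_p) else 0.0 for t in thresholds])
    thresholds = np.concatenate([[-np.inf], thresholds, [np.inf]])
    fp = np.concatenate([[0.0], fp, [1.0]])
    tp = np.concatenate([[0.0], tp, [1.0]])
    return RocCurve(thresholds, fp, tp)
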