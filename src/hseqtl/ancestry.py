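"""Founder-ancestry reconstruction by hidden Markov model.

At each marker the hidden state is the (unordered) pair of founder
strains carried by the two chromosome copies; observed allele dosages are
emitted with a symmetric genotyping-error rate.  Transitions between
adjacent markers act independently on the two copies: with recombination
fraction r (Haldane, from the map distance) a copy keeps its founder with
probability 1 - r and otherwise switches to a founder drawn from the
stationary uniform distribution over founders — the standard
heterogeneous-stock approximation.  An optional map-expansion scalar
inflates distances to reflect the breakpoint density accumulated over
outbreeding generations.

Internally states are represented as *ordered* pairs (F x F), which makes
the transition a Kronecker product of the per-copy kernel and keeps the
forward-backward passes as small matrix operations; all reported
quantities (expected founder dosages, unordered-pair argmax) are
invariant to the ordering.

The scan design is the posterior expected additive dosage per *interval*,
taken as the mean of the two flanking markers' expected dosages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hseqtl.markers import Interval, MarkerMap
from hseqtl.popsim import FounderPanel


def haldane_r(d_cM: np.ndarray) -> np.ndarray:
    """Haldane map function: recombination fraction for distance d in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, float) / 100.0))


@dataclass
class HmmParams:
    """Founder panel, map, and error model for ancestry inference."""

    founder_panel: FounderPanel
    marker_map: MarkerMap
    epsilon: float = 0.01
    map_expansion: float = 1.0  # scales cM distances (outbreeding generations)

    def __post_init__(self) -> None:
        if not (0.0 <= self.epsilon < 0.5):
            raise ValueError("epsilon must lie in [0, 0.5)")
        if self.map_expansion <= 0:
            raise ValueError("map_expansion must be positive")
        if self.founder_panel.haplotypes.shape[1] != self.marker_map.n_markers:
            raise ValueError("founder panel does not cover the marker map")


@dataclass
class AncestryPosterior:
    """Posterior expected founder dosages from the HMM.

    ``marker_dosage``: (n, markers, founders), each vector summing to 2;
    ``interval_dosage``: (n, intervals, founders) mean of the flanking
    markers; ``pair_argmax``: (n, markers, 2) most probable unordered
    founder pair; forward/backward per-individual log-likelihoods agree
    up to numerical tolerance.
    """

    founder_ids: list[str]
    marker_dosage: np.ndarray
    interval_dosage: np.ndarray
    intervals: list[Interval]
    pair_argmax: np.ndarray
    loglik_forward: np.ndarray
    loglik_backward: np.ndarray

    def to_frame(self, individual_ids: list[str] | None = None) -> pd.DataFrame:
        """Long-format (individual, interval, founder, dosage)."""
        n, n_iv, F = self.interval_dosage.shape
        ind = individual_ids or [f"ind{i}" for i in range(n)]
        recs = []
        for i in range(n):
            for k, iv in enumerate(self.intervals):
                for f in range(F):
                    recs.append((ind[i], iv.interval_id, self.founder_ids[f], self.interval_dosage[i, k, f]))
        return pd.DataFrame(recs, columns=["individual", "interval", "founder", "dosage"])


def _emission_tables(hap_col: np.ndarray, eps: float) -> np.ndarray:
    """(3, F, F) emission probabilities P(obs dosage | ordered founder pair)."""
    F = len(hap_col)
    expected = hap_col[:, None] + hap_col[None, :]  # (F, F) in {0,1,2}
    emis = np.full((3, F, F), eps / 2.0)
    for d in range(3):
        emis[d][expected == d] = 1.0 - eps
    return emis


def infer_ancestry(genotypes: np.ndarray, params: HmmParams) -> AncestryPosterior:
    """Forward-backward founder-ancestry inference for all individuals.

    ``genotypes`` is individuals x markers allele dosages {0,1,2} on the
    panel's marker map.  Per-step scaling keeps the passes stable; the
    forward and backward total log-likelihoods are both returned as an
    internal consistency check.
    """
    G = np.asarray(genotypes)
    mm = params.marker_map
    panel = params.founder_panel
    F = panel.n_founders
    n, M = G.shape
    if M != mm.n_markers:
        raise ValueError("genotype matrix does not match the marker map")
    eps = max(params.epsilon, 0.0)
    eps_emit = eps if eps > 0 else 0.0

    marker_dosage = np.zeros((n, M, F))
    pair_argmax = np.zeros((n, M, 2), dtype=np.int64)
    ll_f = np.zeros(n)
    ll_b = np.zeros(n)

    for c in mm.chromosomes:
        sl = mm.chrom_slice(c)
        pos = mm.pos_cM[sl]
        T = len(pos)
        d = np.diff(pos) * params.map_expansion
        rs = haldane_r(d)
        emis = [
            _emission_tables(panel.haplotypes[:, sl.start + t].astype(float), eps_emit) for t in range(T)
        ]

        def emit(t: int) -> np.ndarray:
            e = emis[t][G[:, sl.start + t]]  # (n, F, F)
            bad = e.sum(axis=(1, 2)) <= 0
            if bad.any():
                warnings.warn("zero-probability observation; emission floored and renormalized")
                e[bad] = 1.0
            return e

        def trans_apply(A: np.ndarray, r: float) -> np.ndarray:
            # B = Tc A Tc with Tc = (1-r) I + (r/F) J, applied per individual
            col = A.sum(axis=1, keepdims=True)  # sums over first state index
            B = (1 - r) * A + (r / F) * col
            row = B.sum(axis=2, keepdims=True)
            return (1 - r) * B + (r / F) * row

        # forward
        alphas = np.empty((T, n, F, F))
        a = np.full((n, F, F), 1.0 / (F * F)) * emit(0)
        norm = a.sum(axis=(1, 2))
        a /= norm[:, None, None]
        ll_c = np.log(norm)
        alphas[0] = a
        for t in range(1, T):
            a = trans_apply(a, rs[t - 1]) * emit(t)
            norm = a.sum(axis=(1, 2))
            a /= norm[:, None, None]
            ll_c += np.log(norm)
            alphas[t] = a
        ll_f += ll_c

        # backward
        b = np.ones((n, F, F))
        gamma = alphas[T - 1] * b
        gamma /= gamma.sum(axis=(1, 2))[:, None, None]
        _accumulate_posterior(gamma, marker_dosage, pair_argmax, sl.start + T - 1)
        ll_bc = np.zeros(n)
        for t in range(T - 2, -1, -1):
            eb = emit(t + 1) * b
            b = trans_apply(eb, rs[t])
            norm = b.sum(axis=(1, 2))
            b /= norm[:, None, None]
            ll_bc += np.log(norm)
            gamma = alphas[t] * b
            gamma /= gamma.sum(axis=(1, 2))[:, None, None]
            _accumulate_posterior(gamma, marker_dosage, pair_argmax, sl.start + t)
        final = (np.full((n, F, F), 1.0 / (F * F)) * emit(0) * b).sum(axis=(1, 2))
        ll_b += ll_bc + np.log(final)

    intervals = mm.intervals()
    interval_dosage = np.stack(
        [0.5 * (marker_dosage[:, iv.left, :] + marker_dosage[:, iv.right, :]) for iv in intervals],
        axis=1,
    ) if intervals else np.zeros((n, 0, F))

    return AncestryPosterior(
        founder_ids=list(panel.founder_ids),
        marker_dosage=marker_dosage,
        interval_dosage=interval_dosage,
        intervals=intervals,
        pair_argmax=pair_argmax,
        loglik_forward=ll_f,
        loglik_backward=ll_b,
    )


def _accumulate_posterior(gamma: np.ndarray, dosage: np.ndarray, pair_argmax: np.ndarray, m: int) -> None:
    dosage[:, m, :] = gamma.sum(axis=2) + gamma.sum(axis=1)
    sym = gamma + np.transpose(gamma, (0, 2, 1))
    F = sym.shape[1]
    iu = np.triu_indices(F)
    flat = sym[:, iu[0], iu[1]]
    # diagonal pairs were double-counted by the symmetrization
    diag_mask = iu[0] == iu[1]
    flat[:, diag_mask] /= 2.0
    best = flat.argmax(axis=1)
    pair_argmax[:, m, 0] = iu[0][best]
    pair_argmax[:, m, 1] = iu[1][best]


@dataclass
class AncestryDesign:
    """Per-interval additive founder-dosage design matrices.

    ``dosage``: (intervals, n, founders); ``testable`` flags intervals
    whose centred design has rank >= 1 (ancestry actually varies).
    """

    dosage: np.ndarray
    intervals: list[Interval]
    founder_ids: list[str]
    testable: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        centred = self.dosage - self.dosage.mean(axis=1, keepdims=True)
        sv = np.linalg.svd(centred, compute_uv=False)
        self.testable = sv[:, 0] > 1e-8 if sv.size else np.zeros(0, bool)

    @property
    def n_intervals(self) -> int:
        return self.dosage.shape[0]


def design_matrix(posterior: AncestryPosterior, model: str = "additive") -> AncestryDesign:
    """Build the interval-scan regression designs from the posterior.

    Only the additive model (expected dosages, one column per founder) is
    implemented; one column is dropped at fit time since dosages sum to 2.
    """
    if model != "additive":
        raise NotImplementedError("only the additive founder-dosage model is implemented")
    dosage = np.transpose(posterior.interval_dosage, (1, 0, 2)).copy()
    return AncestryDesign(dosage=dosage, intervals=list(posterior.intervals), founder_ids=list(posterior.founder_ids))


def true_ancestry_design(dosage_truth: np.ndarray, marker_map: MarkerMap, founder_ids: list[str]) -> AncestryDesign:
    """Interval design from ground-truth simulator dosages (for oracles)."""
    ivs = marker_map.intervals()
    d = np.stack(
        [0.5 * (dosage_truth[:, iv.left, :] + dosage_truth[:, iv.right, :]) for iv in ivs], axis=0
    )
    return AncestryDesign(dosage=d, intervals=ivs, founder_ids=list(founder_ids))


def ancestry_accuracy(posterior: AncestryPosterior, truth_dosage: np.ndarray) -> float:
    """Fraction of (individual, marker) unordered founder pairs recovered.

    The truth pair is read off the simulator's dosage tensor; the
    predicted pair is the posterior argmax.  Markers where the truth is
    not a clean pair (should not happen) count as misses.
    """
    n, M, F = truth_dosage.shape
    correct = 0
    for i in range(n):
        for m in range(M):
            tv = truth_dosage[i, m]
            fs = np.where(tv > 0)[0]
            if len(fs) == 1:
                true_pair = (fs[0], fs[0])
            else:
                true_pair = (min(fs), max(fs))
            pred = tuple(sorted(posterior.pair_argmax[i, m]))
            correct += pred == true_pair
    return correct / (n * M)
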