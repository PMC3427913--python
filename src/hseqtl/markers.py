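"""Marker maps and genomic intervals.

A :class:`MarkerMap` is an ordered set of genetic markers with chromosome
labels and genetic positions (cM).  Consecutive markers on a chromosome
delimit *intervals*, the unit tested by the interval (ancestry-regression)
scan; single markers are the unit tested by the single-marker scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Interval:
    """A genomic interval between two adjacent markers on one chromosome."""

    interval_id: str
    chrom: str
    left: int   # global index of left flanking marker
    right: int  # global index of right flanking marker
    left_cM: float
    right_cM: float

    @property
    def length_cM(self) -> float:
        return self.right_cM - self.left_cM

    @property
    def mid_cM(self) -> float:
        return 0.5 * (self.left_cM + self.right_cM)


@dataclass
class MarkerMap:
    """Ordered markers with chromosome and genetic position.

    Parameters
    ----------
    marker_ids : sequence of str
        Unique marker labels.
    chrom : sequence of str
        Chromosome label per marker; markers of one chromosome must be
        contiguous.
    pos_cM : sequence of float
        Genetic position in centimorgans, strictly increasing within each
        chromosome.
    """

    marker_ids: list[str]
    chrom: np.ndarray
    pos_cM: np.ndarray
    _chrom_slices: dict[str, slice] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.marker_ids = list(self.marker_ids)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_cM = np.asarray(self.pos_cM, dtype=float)
        if len(self.marker_ids) == 0:
            raise ValueError("marker map is empty")
        if not (len(self.marker_ids) == len(self.chrom) == len(self.pos_cM)):
            raise ValueError("marker_ids, chrom and pos_cM must have equal length")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("marker ids must be unique")
        # contiguity + monotonicity per chromosome
        slices: dict[str, slice] = {}
        start = 0
        for i in range(1, len(self.chrom) + 1):
            if i == len(self.chrom) or self.chrom[i] != self.chrom[start]:
                c = str(self.chrom[start])
                if c in slices:
                    raise ValueError(f"markers of chromosome {c} are not contiguous")
                pos = self.pos_cM[start:i]
                if np.any(np.diff(pos) <= 0):
                    raise ValueError(f"positions not strictly increasing on chromosome {c}")
                slices[c] = slice(start, i)
                start = i
        object.__setattr__(self, "_chrom_slices", slices)

    # -- accessors ---------------------------------------------------------
    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._chrom_slices)

    def chrom_slice(self, chrom: str) -> slice:
        return self._chrom_slices[str(chrom)]

    def chrom_length(self, chrom: str) -> float:
        """Map length of a chromosome (position of its last marker, cM)."""
        return float(self.pos_cM[self.chrom_slice(chrom)][-1])

    def marker_index(self, marker_id: str) -> int:
        return self.marker_ids.index(marker_id)

    def intervals(self) -> list[Interval]:
        """All intervals between adjacent same-chromosome markers."""
        out = []
        for c, sl in self._chrom_slices.items():
            for k in range(sl.start, sl.stop - 1):
                out.append(
                    Interval(
                        interval_id=f"{self.marker_ids[k]}|{self.marker_ids[k + 1]}",
                        chrom=c,
                        left=k,
                        right=k + 1,
                        left_cM=float(self.pos_cM[k]),
                        right_cM=float(self.pos_cM[k + 1]),
                    )
                )
        return out

    # -- i/o ---------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker_id": self.marker_ids, "chromosome": self.chrom, "position_cM": self.pos_cM}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MarkerMap":
        return cls(
            marker_ids=df["marker_id"].astype(str).tolist(),
            chrom=df["chromosome"].astype(str).to_numpy(),
            pos_cM=df["position_cM"].to_numpy(float),
        )


def default_marker_map(
    n_chrom: int = 19, markers_per_chrom: int = 10, spacing_cM: float = 10.0
) -> MarkerMap:
    """Evenly spaced sparse map over autosomes.

    The real mouse panels behind this kind of study are a few hundred
    informative markers genome-wide; the default (19 autosomes x 10
    markers at 10 cM) matches that density and is fully configurable.
    """
    ids, chroms, pos = [], [], []
    for c in range(1, n_chrom + 1):
        for m in range(markers_per_chrom):
            ids.append(f"m{c}_{m}")
            chroms.append(str(c))
            pos.append(m * spacing_cM)
    return MarkerMap(ids, np.array(chroms, dtype=object), np.array(pos))
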