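"""Simulation of multiparental mouse breeding designs.

Three designs are supported, mirroring the crosses this pipeline is meant
to analyse:

``F2``
    Two inbred founders, reciprocal F1 hybrids, then the four possible
    reciprocal F2 crosses.
``HS4``
    Four founders; the 12 possible reciprocal F1 hybrids, then the 48
    possible reciprocal four-way crosses, then circle breeding (male of
    family k mated to female of family k+1) to G19.
``HSCC``
    Eight founders labelled A-H; reciprocal two-way then four-way crosses,
    32 eight-way families at G3 (each bred in duplicate), circle breeding
    from G4, expansion to 48 families at G6, and circle breeding to G12.

Meiosis is simulated without crossover interference: crossover counts per
chromosome are Poisson with mean L/100 for map length L in cM, which makes
the recombination fraction between markers d cM apart follow the Haldane
map function r = (1 - exp(-2d/100))/2.  A piecewise-constant hotspot
profile can reshape where crossovers land while preserving the total map
length, which is the mechanism by which one chromosome's relatedness
structure can drift away from the genome-wide kinship.

Expression phenotypes are built from planted cis/trans founder-effect
eQTLs, an optional polygenic component whose covariance follows a chosen
relatedness matrix, array-strip batch effects, outlier samples, probes
carrying a founder-linked SNP-in-probe artifact, and probes with failing
detection calls — the data features the QC and diagnostic stages of the
pipeline are designed to catch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd

from hseqtl.markers import Interval, MarkerMap

# Fixed genetic-to-physical scale used for probe/SNP coordinates (bp per cM).
CM_TO_BP = 2_000_000
PROBE_LENGTH_BP = 50

DESIGNS = ("F2", "HS4", "HSCC")


# ---------------------------------------------------------------------------
# founder panel
# ---------------------------------------------------------------------------
@dataclass
class FounderPanel:
    """Inbred founder strains: homozygous biallelic haplotypes.

    ``haplotypes`` is a founders x markers array of allele codes {0, 1};
    inbred founders are homozygous, so one haplotype per strain suffices.
    """

    founder_ids: list[str]
    haplotypes: np.ndarray

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if len(self.founder_ids) < 2:
            raise ValueError("need at least 2 founders")
        if len(set(self.founder_ids)) != len(self.founder_ids):
            raise ValueError("founder ids must be unique")
        if self.haplotypes.shape[0] != len(self.founder_ids):
            raise ValueError("haplotypes rows must match founder_ids")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("founder alleles must be 0/1 (inbred, homozygous)")

    @property
    def n_founders(self) -> int:
        return len(self.founder_ids)


def default_founder_ids(n_founders: int) -> list[str]:
    if n_founders == 8:
        return list("ABCDEFGH")
    return [chr(ord("A") + i) for i in range(n_founders)]


def random_founder_panel(
    n_founders: int, marker_map: MarkerMap, seed: int | np.random.Generator = 0
) -> FounderPanel:
    """Random polymorphic biallelic panel.

    Every marker is guaranteed polymorphic (not all founders identical);
    for two founders this yields the fully informative F2 configuration
    (alleles 0 and 1 at every marker).
    """
    rng = np.random.default_rng(seed)
    m = marker_map.n_markers
    if n_founders == 2:
        hap = np.vstack([np.zeros(m, dtype=np.int8), np.ones(m, dtype=np.int8)])
    else:
        hap = rng.integers(0, 2, size=(n_founders, m), dtype=np.int8)
        mono = (hap.min(axis=0) == hap.max(axis=0))
        for j in np.where(mono)[0]:
            hap[rng.integers(n_founders), j] ^= 1
    return FounderPanel(default_founder_ids(n_founders), hap)


# ---------------------------------------------------------------------------
# ancestry mosaics
# ---------------------------------------------------------------------------
@dataclass
class Gamete:
    """One chromosome-copy ancestry mosaic.

    Per chromosome: ``(ends, founders)`` where ``ends`` are strictly
    increasing segment right-boundaries in cM (the last equals the map
    length) and ``founders`` are founder indices; segment i covers
    (ends[i-1], ends[i]].
    """

    segments: dict[str, tuple[np.ndarray, np.ndarray]]

    def founder_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        ends, founders = self.segments[chrom]
        idx = np.searchsorted(ends, np.asarray(positions, dtype=float), side="left")
        idx = np.minimum(idx, len(founders) - 1)
        return founders[idx]


@dataclass
class AncestryMosaic:
    """The two chromosome-copy mosaics of one diploid individual."""

    copies: tuple[Gamete, Gamete]

    def founder_pair_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """(len(positions), 2) founder indices, one column per copy."""
        return np.stack(
            [self.copies[0].founder_at(chrom, positions), self.copies[1].founder_at(chrom, positions)],
            axis=1,
        )


def founder_gamete(founder_idx: int, marker_map: MarkerMap) -> Gamete:
    segs = {}
    for c in marker_map.chromosomes:
        L = max(marker_map.chrom_length(c), 1e-9)
        segs[c] = (np.array([L]), np.array([founder_idx], dtype=np.int64))
    return Gamete(segs)


def founder_mosaic(founder_idx: int, marker_map: MarkerMap) -> AncestryMosaic:
    return AncestryMosaic((founder_gamete(founder_idx, marker_map), founder_gamete(founder_idx, marker_map)))


# ---------------------------------------------------------------------------
# recombination profiles and meiosis
# ---------------------------------------------------------------------------
@dataclass
class HotspotProfile:
    """Piecewise-constant relative crossover intensity per chromosome.

    ``bins[chrom] = (edges, weights)``: ``edges`` are increasing cM
    boundaries starting at 0 and ending at the map length; ``weights`` are
    relative intensities per bin.  The profile only redistributes
    crossovers; the expected total per chromosome stays L/100, preserving
    total map length.  Chromosomes absent from ``bins`` recombine
    uniformly.
    """

    bins: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def sample_positions(self, chrom: str, n: int, L: float, rng: np.random.Generator) -> np.ndarray:
        if n == 0:
            return np.empty(0)
        if chrom not in self.bins:
            return rng.uniform(0.0, L, size=n)
        edges, weights = self.bins[chrom]
        widths = np.diff(edges)
        mass = widths * weights
        p = mass / mass.sum()
        which = rng.choice(len(widths), size=n, p=p)
        return edges[which] + rng.uniform(0.0, 1.0, size=n) * widths[which]


def hotspot_chromosome_profile(
    marker_map: MarkerMap, chrom: str, hotspot_span: tuple[float, float] | None = None, intensity: float = 20.0
) -> HotspotProfile:
    """Concentrate recombination of one chromosome into a narrow hotspot.

    Outside the hotspot the local rate is strongly reduced, producing
    long-range linkage along the chromosome — the situation described for
    mouse chromosome 1, where localized recombination gives a relatedness
    structure unlike the rest of the genome.
    """
    L = marker_map.chrom_length(chrom)
    if hotspot_span is None:
        hotspot_span = (0.45 * L, 0.55 * L)
    a, b = hotspot_span
    edges = np.array([0.0, a, b, L])
    weights = np.array([1.0, intensity, 1.0])
    return HotspotProfile({str(chrom): (edges, weights)})


def simulate_meiosis(
    mosaic: AncestryMosaic,
    marker_map: MarkerMap,
    hotspot_profile: HotspotProfile | None = None,
    seed: int | np.random.Generator = 0,
) -> Gamete:
    """One recombinant gamete from a diploid parent.

    Crossover counts per chromosome are Poisson(L/100); positions are
    uniform, or drawn from ``hotspot_profile`` where given.  No crossover
    interference is modelled.
    """
    if marker_map.n_markers == 0:
        raise ValueError("empty marker map")
    rng = np.random.default_rng(seed)
    profile = hotspot_profile or HotspotProfile()
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in marker_map.chromosomes:
        L = max(marker_map.chrom_length(c), 1e-9)
        n_x = rng.poisson(L / 100.0)
        xpos = np.sort(profile.sample_positions(c, n_x, L, rng))
        start = int(rng.integers(2))
        # boundaries where the active parental copy switches
        bounds = np.concatenate([xpos, [L]])
        ends_list: list[float] = []
        founders_list: list[int] = []
        prev = 0.0
        active = start
        for b in bounds:
            if b > prev:
                ends, fdr = mosaic.copies[active].segments[c]
                i0 = np.searchsorted(ends, prev, side="right")
                i1 = np.searchsorted(ends, b, side="left")
                for k in range(i0, i1 + 1):
                    seg_end = min(float(ends[k]), float(b))
                    if seg_end > prev:
                        ends_list.append(seg_end)
                        founders_list.append(int(fdr[k]))
                        prev = seg_end
            active = 1 - active
        ends_arr = np.array(ends_list)
        fdr_arr = np.array(founders_list, dtype=np.int64)
        # merge adjacent segments with the same founder
        if len(fdr_arr) > 1:
            keep = np.concatenate([fdr_arr[1:] != fdr_arr[:-1], [True]])
            ends_arr, fdr_arr = ends_arr[keep], fdr_arr[keep]
        ends_arr[-1] = L
        out[c] = (ends_arr, fdr_arr)
    return Gamete(out)


# ---------------------------------------------------------------------------
# pedigrees
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class MatingRecord:
    generation: int
    sire_family: str
    dam_family: str
    offspring_family: str


@dataclass
class Pedigree:
    """Mating plan for one breeding design.

    ``founder_families`` are the G0 strain "families"; ``records`` list
    one mating per offspring family per generation.  Circle-breeding
    generations keep the family count constant (except the documented
    HS-CC expansion from 32 to 48 families at G6).
    """

    design: str
    founder_families: list[str]
    records: list[MatingRecord]

    @property
    def n_generations(self) -> int:
        return max(r.generation for r in self.records)

    def families_at(self, generation: int) -> list[str]:
        if generation == 0:
            return list(self.founder_families)
        seen: dict[str, None] = {}
        for r in self.records:
            if r.generation == generation:
                seen[r.offspring_family] = None
        return list(seen)


def _circle(gen: int, fams: list[str]) -> list[MatingRecord]:
    n = len(fams)
    return [MatingRecord(gen, fams[k], fams[(k + 1) % n], fams[k]) for k in range(n)]


def simulate_pedigree(
    design: str,
    n_families: int | None = None,
    n_generations: int | None = None,
    seed: int = 0,
) -> Pedigree:
    """Mating plan for an F2, HS4, or HS-CC cross.

    ``n_generations`` overrides the design default (F2: 2, HS4: 19,
    HS-CC: 12) but cannot truncate the design's fixed early structure.
    The plan itself is deterministic; ``seed`` is accepted for interface
    symmetry with the rest of the simulator.
    """
    design = design.upper()
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}; expected one of {DESIGNS}")

    if design == "F2":
        founders = default_founder_ids(2)
        G = n_generations or 2
        if G != 2:
            raise ValueError("F2 design has exactly 2 generations beyond founders")
        a, b = founders
        recs = [
            MatingRecord(1, a, b, a + b),
            MatingRecord(1, b, a, b + a),
        ]
        for sire in (a + b, b + a):
            for dam in (a + b, b + a):
                recs.append(MatingRecord(2, sire, dam, f"F2:{sire}x{dam}"))
        return Pedigree("F2", founders, recs)

    if design == "HS4":
        founders = default_founder_ids(4)
        G = n_generations or 19
        if G < 3:
            raise ValueError("HS4 needs at least 3 generations")
        recs = []
        f1 = ["".join(p) for p in permutations(founders, 2)]  # 12 reciprocal F1
        for fam in f1:
            recs.append(MatingRecord(1, fam[0], fam[1], fam))
        # 24 distinct ordered four-way type crosses, each bred in duplicate
        # to form the 48 four-way families
        four_way = []
        seen = set()
        for perm in permutations(founders):
            s, d = "".join(perm[:2]), "".join(perm[2:])
            if (s, d) in seen:
                continue
            seen.add((s, d))
            seen.add((d, s))
            for sire, dam in ((s, d), (d, s)):
                for dup in (1, 2):
                    fam = f"{sire}{dam}#{dup}"
                    four_way.append(fam)
                    recs.append(MatingRecord(2, sire, dam, fam))
        if n_families is not None and n_families != len(four_way):
            raise ValueError(f"HS4 forms {len(four_way)} four-way families, got n_families={n_families}")
        for g in range(3, G + 1):
            recs.extend(_circle(g, four_way))
        return Pedigree("HS4", founders, recs)

    # HSCC
    founders = default_founder_ids(8)
    G = n_generations or 12
    if G < 3:
        raise ValueError("HS-CC needs at least 3 generations")
    if n_families is not None and n_families < 32:
        raise ValueError("HS-CC forms 32 eight-way families at G3")
    a, b, c, d, e, f, g_, h = founders
    recs = []
    f1_pairs = [(a, b), (c, d), (e, f), (g_, h)]
    for x, y in f1_pairs:
        recs.append(MatingRecord(1, x, y, x + y))
        recs.append(MatingRecord(1, y, x, y + x))
    four_left, four_right = [], []
    for (x, y), target in (((a + b, c + d), four_left), ((e + f, g_ + h), four_right)):
        rev_x, rev_y = x[::-1], y[::-1]
        for sire, dam in ((x, y), (y, x), (rev_x, rev_y), (rev_y, rev_x)):
            fam = f"{sire}{dam}"
            target.append(fam)
            recs.append(MatingRecord(2, sire, dam, fam))
    eight_way = []
    for lf in four_left:
        for rf in four_right:
            for sire, dam in ((lf, rf), (rf, lf)):
                fam = f"{sire}x{dam}"
                eight_way.append(fam)
                recs.append(MatingRecord(3, sire, dam, fam))
    assert len(eight_way) == 32
    fams = eight_way
    for g in range(4, G + 1):
        if g == 6 and G >= 6:
            # expansion: male of family k bred to female of family k+16
            new = [f"X{k}" for k in range(16)]
            recs.extend(_circle(g, fams))
            for k in range(16):
                recs.append(MatingRecord(g, fams[k], fams[k + 16], new[k]))
            fams = fams + new
        else:
            recs.extend(_circle(g, fams))
    return Pedigree("HSCC", founders, recs)


# ---------------------------------------------------------------------------
# population simulation
# ---------------------------------------------------------------------------
@dataclass
class Population:
    """Final-generation cohort with ground-truth ancestry."""

    design: str
    pedigree: Pedigree
    individual_ids: list[str]
    mosaics: list[AncestryMosaic]
    founder_panel: FounderPanel
    marker_map: MarkerMap

    @property
    def n(self) -> int:
        return len(self.mosaics)

    def true_dosage(self) -> np.ndarray:
        """(n, markers, founders) ground-truth founder ancestry dosages."""
        return true_dosage(self.mosaics, self.marker_map, self.founder_panel.n_founders)

    def genotypes(self, genotyping_error: float = 0.0, seed: int | np.random.Generator = 0) -> np.ndarray:
        return genotype_from_mosaic(
            self.mosaics, self.founder_panel, self.marker_map, genotyping_error, seed
        )


def simulate_cross(
    design: str,
    marker_map: MarkerMap,
    founder_panel: FounderPanel | None = None,
    seed: int | np.random.Generator = 0,
    n_offspring_final: int = 2,
    n_generations: int | None = None,
    hotspot_profile: HotspotProfile | None = None,
) -> Population:
    """Run a breeding design end to end and return the final cohort.

    Each family keeps one breeding male and one breeding female per
    generation (sexes alternate deterministically within a litter, which
    guarantees circle breeding is always feasible); the final generation
    contributes ``n_offspring_final`` individuals per family.
    """
    rng = np.random.default_rng(seed)
    ped = simulate_pedigree(design, n_generations=n_generations, seed=0)
    n_founders = {"F2": 2, "HS4": 4, "HSCC": 8}[ped.design]
    if founder_panel is None:
        founder_panel = random_founder_panel(n_founders, marker_map, rng)
    if founder_panel.n_founders != n_founders:
        raise ValueError(f"{ped.design} needs {n_founders} founders, panel has {founder_panel.n_founders}")
    if founder_panel.haplotypes.shape[1] != marker_map.n_markers:
        raise ValueError("founder panel does not cover the marker map")

    # family -> (breeding male, breeding female)
    breeders: dict[str, tuple[AncestryMosaic, AncestryMosaic]] = {}
    for i, fam in enumerate(ped.founder_families):
        m = founder_mosaic(i, marker_map)
        breeders[fam] = (m, m)

    G = ped.n_generations
    by_gen: dict[int, list[MatingRecord]] = {}
    for r in ped.records:
        by_gen.setdefault(r.generation, []).append(r)

    ids: list[str] = []
    cohort: list[AncestryMosaic] = []
    for g in range(1, G + 1):
        next_breeders: dict[str, tuple[AncestryMosaic, AncestryMosaic]] = {}
        for rec in by_gen[g]:
            sire = breeders[rec.sire_family][0]
            dam = breeders[rec.dam_family][1]
            n_off = n_offspring_final if g == G else 2
            offspring = [
                AncestryMosaic(
                    (
                        simulate_meiosis(sire, marker_map, hotspot_profile, rng),
                        simulate_meiosis(dam, marker_map, hotspot_profile, rng),
                    )
                )
                for _ in range(n_off)
            ]
            if g == G:
                for k, off in enumerate(offspring):
                    ids.append(f"{ped.design}_G{g}_{rec.offspring_family}_{k}")
                    cohort.append(off)
            else:
                if rec.offspring_family not in next_breeders:
                    next_breeders[rec.offspring_family] = (offspring[0], offspring[1])
        if g < G:
            # families not re-formed this generation keep their breeders
            for fam, pair in breeders.items():
                next_breeders.setdefault(fam, pair)
            breeders = next_breeders
    return Population(ped.design, ped, ids, cohort, founder_panel, marker_map)


def true_dosage(mosaics: list[AncestryMosaic], marker_map: MarkerMap, n_founders: int) -> np.ndarray:
    """(n, markers, founders) ancestry dosages from ground-truth mosaics."""
    n, m = len(mosaics), marker_map.n_markers
    out = np.zeros((n, m, n_founders))
    for c in marker_map.chromosomes:
        sl = marker_map.chrom_slice(c)
        pos = marker_map.pos_cM[sl]
        for i, mos in enumerate(mosaics):
            pair = mos.founder_pair_at(c, pos)
            for copy in (0, 1):
                np.add.at(out[i, sl], (np.arange(sl.stop - sl.start), pair[:, copy]), 1.0)
    return out


def genotype_from_mosaic(
    mosaics: list[AncestryMosaic],
    founder_panel: FounderPanel,
    marker_map: MarkerMap,
    genotyping_error: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """(n, markers) allele dosages {0,1,2} read off the ancestry mosaics.

    With ``genotyping_error`` > 0 each dosage is replaced, independently
    with that probability, by one of the two other dosage values.
    """
    rng = np.random.default_rng(seed)
    hap = founder_panel.haplotypes
    n, m = len(mosaics), marker_map.n_markers
    dos = np.zeros((n, m), dtype=np.int8)
    for c in marker_map.chromosomes:
        sl = marker_map.chrom_slice(c)
        pos = marker_map.pos_cM[sl]
        cols = np.arange(sl.start, sl.stop)
        for i, mos in enumerate(mosaics):
            pair = mos.founder_pair_at(c, pos)
            if pair.max() >= founder_panel.n_founders:
                raise ValueError("mosaic refers to a founder absent from the panel")
            dos[i, sl] = hap[pair[:, 0], cols] + hap[pair[:, 1], cols]
    if genotyping_error > 0:
        flip = rng.random((n, m)) < genotyping_error
        shift = rng.integers(1, 3, size=(n, m))
        dos = np.where(flip, (dos + shift) % 3, dos).astype(np.int8)
    return dos


# ---------------------------------------------------------------------------
# expression phenotypes
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class PlantedEffect:
    probe: int
    interval: Interval
    founder_effects: np.ndarray  # one entry per founder
    kind: str  # "cis" | "trans"


@dataclass
class PhenoModel:
    """Generative model for array expression phenotypes.

    Expression of probe p in sample i is
    ``intercept + sum_effects dosage(i, interval) . v + polygenic_i +
    strip(i, strip(p)) + noise``; see :func:`simulate_expression` for the
    artifact terms (outliers, SNP-in-probe, detection failures).
    """

    n_probes: int
    cis_effects: list[PlantedEffect] = field(default_factory=list)
    trans_effects: list[PlantedEffect] = field(default_factory=list)
    polygenic_var: float = 0.0
    noise_var: float = 1.0
    strip_sd: float = 0.0
    n_strips: int = 2
    outlier_samples: int = 0
    outlier_noise_sd: float = 6.0
    snp_probe_fraction: float = 0.0
    snp_artifact_sd: float = 1.0
    undetected_probe_fraction: float = 0.0
    background_scale: float = 2.0
    background_df: float = 1.5
    intercept: float = 8.0

    def __post_init__(self) -> None:
        for v in (self.polygenic_var, self.noise_var):
            if v < 0:
                raise ValueError("variances must be nonnegative")
        if self.strip_sd < 0 or self.snp_artifact_sd < 0:
            raise ValueError("effect SDs must be nonnegative")

    @property
    def effects(self) -> list[PlantedEffect]:
        return list(self.cis_effects) + list(self.trans_effects)


def random_pheno_model(
    marker_map: MarkerMap,
    n_founders: int,
    n_probes: int,
    n_cis: int = 0,
    n_trans: int = 0,
    cis_effect_sd: float = 1.0,
    trans_effect_sd: float = 1.0,
    seed: int | np.random.Generator = 0,
    **kwargs,
) -> PhenoModel:
    """Plant random founder-effect eQTLs on distinct probes.

    Founder effect vectors are drawn N(0, sd^2) and centred, so the
    planted signal is a contrast between founder ancestries rather than a
    shift; probes 0..n_cis-1 carry cis effects, the next n_trans probes
    carry trans effects.
    """
    rng = np.random.default_rng(seed)
    ivs = marker_map.intervals()
    if n_cis + n_trans > 0 and not ivs:
        raise ValueError("marker map has no intervals to plant effects in")
    if n_cis + n_trans > n_probes:
        raise ValueError("more planted effects than probes")

    def draw(probe: int, sd: float, kind: str) -> PlantedEffect:
        iv = ivs[rng.integers(len(ivs))]
        v = rng.normal(0.0, sd, size=n_founders)
        v -= v.mean()
        return PlantedEffect(probe, iv, v, kind)

    cis = [draw(p, cis_effect_sd, "cis") for p in range(n_cis)]
    trans = [draw(p, trans_effect_sd, "trans") for p in range(n_cis, n_cis + n_trans)]
    return PhenoModel(n_probes=n_probes, cis_effects=cis, trans_effects=trans, **kwargs)


def interval_true_dosage(dosage: np.ndarray, marker_map: MarkerMap, interval: Interval) -> np.ndarray:
    """(n, founders) ancestry dosage at an interval: mean of flanking markers."""
    return 0.5 * (dosage[:, interval.left, :] + dosage[:, interval.right, :])


def simulate_expression(
    population: Population,
    pheno_model: PhenoModel,
    relatedness_for_polygenic: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
):
    """Simulate an expression matrix with its eQTL truth table.

    Returns ``(expr, truth, snp_table)`` where ``expr`` is an
    :class:`hseqtl.exprqc.ExpressionMatrix` (values, probe annotations and
    detection p-values), ``truth`` lists every planted (probe, interval)
    pair, and ``snp_table`` gives SNP coordinates falling inside the
    probes designated as SNP-carrying (plus background SNPs), ready for
    the SNP-in-probe filter.

    The polygenic component, when requested, is a Gaussian draw per probe
    with covariance ``polygenic_var * S`` where ``S`` is the similarity
    conversion of ``relatedness_for_polygenic`` (a distance matrix,
    genome-wide or chromosome-specific).
    """
    from hseqtl.exprqc import ExpressionMatrix
    from hseqtl.kinship import distance_to_similarity

    pm = pheno_model
    rng = np.random.default_rng(seed)
    n, P = population.n, pm.n_probes
    mm = population.marker_map
    dosage = population.true_dosage()

    values = np.full((n, P), pm.intercept, dtype=float)
    probe_chrom = np.empty(P, dtype=object)
    probe_cM = np.empty(P, dtype=float)

    # locate probes: effect-carrying cis probes sit inside their interval,
    # everything else lands uniformly on the map
    ivs = mm.intervals()
    rand_iv = rng.integers(len(ivs), size=P)
    for p in range(P):
        iv = ivs[rand_iv[p]]
        probe_chrom[p] = iv.chrom
        probe_cM[p] = rng.uniform(iv.left_cM, iv.right_cM)
    truth_rows = []
    for eff in pm.effects:
        iv = eff.interval
        if eff.kind == "cis":
            probe_chrom[eff.probe] = iv.chrom
            probe_cM[eff.probe] = iv.mid_cM
        d_iv = interval_true_dosage(dosage, mm, iv)
        values[:, eff.probe] += d_iv @ eff.founder_effects
        truth_rows.append(
            {
                "probe_id": f"p{eff.probe:05d}",
                "interval_id": iv.interval_id,
                "kind": eff.kind,
                "effect_norm": float(np.linalg.norm(eff.founder_effects)),
            }
        )
    truth = pd.DataFrame(truth_rows, columns=["probe_id", "interval_id", "kind", "effect_norm"])

    if pm.polygenic_var > 0:
        if relatedness_for_polygenic is None:
            raise ValueError("polygenic_var > 0 requires a relatedness matrix")
        S = distance_to_similarity(relatedness_for_polygenic)
        w, U = np.linalg.eigh(S)
        L = U * np.sqrt(np.clip(w, 0.0, None))
        values += np.sqrt(pm.polygenic_var) * (L @ rng.standard_normal((n, P)))

    strip_id = np.arange(P) % pm.n_strips
    if pm.strip_sd > 0:
        strip_fx = rng.normal(0.0, pm.strip_sd, size=(n, pm.n_strips))
        values += strip_fx[:, strip_id]

    # founder-linked SNP-in-probe artifact: intensity tracks the allele
    # dosage at the marker nearest the probe
    n_snp_probes = int(round(pm.snp_probe_fraction * P))
    snp_probes = rng.choice(P, size=n_snp_probes, replace=False) if n_snp_probes else np.empty(0, int)
    snp_flag = np.zeros(P, dtype=bool)
    snp_flag[snp_probes] = True
    geno = population.genotypes(seed=rng)
    nearest_marker = np.empty(P, dtype=int)
    for p in range(P):
        sl = mm.chrom_slice(probe_chrom[p])
        pos = mm.pos_cM[sl]
        nearest_marker[p] = sl.start + int(np.argmin(np.abs(pos - probe_cM[p])))
    for p in snp_probes:
        g = geno[:, nearest_marker[p]].astype(float)
        values[:, p] += pm.snp_artifact_sd * (g - g.mean())

    if pm.noise_var > 0:
        values += rng.normal(0.0, np.sqrt(pm.noise_var), size=(n, P))

    # unexpressed probes measure non-specific background: heavy-tailed
    # noise unrelated to genotype, replacing any signal terms above
    n_undet = int(round(pm.undetected_probe_fraction * P))
    undet_probes = rng.choice(P, size=n_undet, replace=False) if n_undet else np.empty(0, int)
    undet_flag = np.zeros(P, dtype=bool)
    undet_flag[undet_probes] = True
    if n_undet:
        values[:, undet_probes] = pm.intercept + pm.background_scale * rng.standard_t(
            pm.background_df, size=(n, n_undet)
        )

    # failed arrays: the whole sample is replaced by high-variance noise
    outliers = (
        rng.choice(n, size=pm.outlier_samples, replace=False) if pm.outlier_samples else np.empty(0, int)
    )
    if len(outliers):
        values[outliers] = pm.intercept + rng.normal(0.0, pm.outlier_noise_sd, size=(len(outliers), P))

    # detection p-values: expressed probes detect nearly everywhere;
    # designated low-detection probes fail (p >= 0.01) in ~85% of samples
    det = rng.uniform(0.0, 0.005, size=(n, P))
    n_fail = int(np.ceil(0.85 * n))
    for p in undet_probes:
        fail = rng.choice(n, size=n_fail, replace=False)
        det[fail, p] = rng.uniform(0.011, 1.0, size=n_fail)

    start_bp = (probe_cM * CM_TO_BP).astype(np.int64)
    probes = pd.DataFrame(
        {
            "probe_id": [f"p{p:05d}" for p in range(P)],
            "chromosome": probe_chrom.astype(str),
            "start": start_bp,
            "end": start_bp + PROBE_LENGTH_BP,
            "position_cM": probe_cM,
            "strip_id": [f"strip{q}" for q in strip_id],
            "snp_overlap": snp_flag,
            "low_detection": undet_flag,
        }
    )

    # SNP table: one SNP inside each designated probe + uniform background
    snp_rows = [
        {"chromosome": probes.loc[p, "chromosome"], "position": int(probes.loc[p, "start"]) + 10}
        for p in snp_probes
    ]
    for _ in range(max(2 * n_snp_probes, 10)):
        c = mm.chromosomes[rng.integers(len(mm.chromosomes))]
        snp_rows.append(
            {"chromosome": c, "position": int(rng.uniform(0, mm.chrom_length(c)) * CM_TO_BP)}
        )
    snp_table = pd.DataFrame(snp_rows, columns=["chromosome", "position"])

    expr = ExpressionMatrix(
        values=values,
        sample_ids=list(population.individual_ids),
        probes=probes,
        detection_pvals=det,
    )
    return expr, truth, snp_table
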