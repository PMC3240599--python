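"""Synthetic admixed cohorts with known ground truth.

The generator follows the hybrid-isolation picture of admixture: source
populations differentiate from a shared ancestral pool (Balding-Nichols
frequencies at a stated FST), admix in a single founding event T generations
ago, and recombination thereafter breaks haplotypes into ancestry segments.
Ancestry switch points along a haplotype form a Poisson process at rate T
per Morgan; the ancestry after each point is redrawn from the individual's
proportion vector, so a fraction 2 z (1 - z) of points are effective
switches and the expected diploid block count is
``0.04 T L z (1 - z) + 2 * n_chrom``.

Haplotype LD within each source comes from a Markov copying process: a
minority of founder haplotypes is drawn site-independently and the rest are
template-switching mosaics of the founders, giving haplotype sharing that
decays with genetic distance — enough structure for EHH/iHS to be
exercised.  Selective sweeps are injected as founder-copy events: a chosen
fraction of haplotypes carry one founder's alleles around a core marker,
with geometrically truncated extents so homozygosity decays away from the
core.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .datamodel import (
    MISSING,
    MARKER_COLUMNS,
    AncestryTrack,
    HaplotypePanel,
    _runs,
)

# Human-like autosome genetic lengths (cM), rescaled to sum to 3435 cM.
_RAW_AUTOSOME_CM = np.array([
    284.2, 269.3, 223.2, 214.6, 204.1, 192.0, 187.2, 168.0, 166.4, 181.1,
    158.2, 174.7, 125.9, 120.8, 141.9, 134.0, 128.5, 117.2, 107.9, 108.3,
    62.8, 74.1,
])
DEFAULT_CHROM_LENGTHS_CM: np.ndarray = _RAW_AUTOSOME_CM / _RAW_AUTOSOME_CM.sum() * 3435.0


@dataclass
class SweepSpec:
    """A founder-copy sweep at ``core_marker`` carried by ``carrier_freq`` of haplotypes."""

    core_marker: int
    carrier_freq: float
    founder_span_cm: float = 2.0

    def __post_init__(self):
        if not 0 <= self.carrier_freq < 1:
            raise ValueError("carrier_freq must be in [0, 1)")
        if self.founder_span_cm <= 0:
            raise ValueError("founder_span_cm must be positive")


@dataclass
class MaskCorruptionConfig:
    """Segment-level ancestry-label corruption at per-segment switch rate epsilon."""

    epsilon: float
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.epsilon <= 1:
            raise ValueError("epsilon must be in [0, 1]")


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic admixed cohort.

    ``z_dist`` gives each individual's target-ancestry (ancestry 0)
    proportion: a fixed float, a ``(low, high)`` uniform range, or a callable
    ``rng -> z``.  Defaults mirror the hybrid-isolation analyses the toolkit
    implements: T = 12 generations, L = 3435 cM over 22 autosomes, M = 20000
    markers, fixed z = 0.5.
    """

    K: int = 2
    fst: float = 0.15
    M: int = 20000
    chrom_lengths_cm: np.ndarray = field(
        default_factory=lambda: DEFAULT_CHROM_LENGTHS_CM.copy())
    T: int = 12
    n_individuals: int = 100
    z_dist: Union[float, tuple, Callable] = 0.5
    ld_rho: float = 0.3          # template switches per cM in the copying model
    n_haps_per_source: int = 200
    founder_fraction: float = 0.2  # fraction of source haplotypes drawn independently
    sweep: Optional[SweepSpec] = None
    seed: int = 0

    def __post_init__(self):
        self.chrom_lengths_cm = np.asarray(self.chrom_lengths_cm, dtype=float)
        if not 0 < self.fst < 1:
            raise ValueError("fst must be in (0, 1)")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.chrom_lengths_cm.sum() <= 0:
            raise ValueError("total genome length must be positive")

    @property
    def L(self) -> float:
        return float(self.chrom_lengths_cm.sum())

    def draw_z(self, rng: np.random.Generator) -> float:
        if callable(self.z_dist):
            return float(self.z_dist(rng))
        if isinstance(self.z_dist, tuple):
            lo, hi = self.z_dist
            return float(rng.uniform(lo, hi))
        return float(self.z_dist)


# ---------------------------------------------------------------------------
# Markers and source populations
# ---------------------------------------------------------------------------

def simulate_markers(M: int, chrom_lengths_cm: Sequence[float],
                     rng: np.random.Generator, bp_per_cm: float = 1e6) -> pd.DataFrame:
    """Scatter M markers over chromosomes proportionally to cM length.

    Genetic positions are uniform within each chromosome; physical positions
    follow a uniform 1 cM/Mb map (``bp_per_cm``).
    """
    lengths = np.asarray(chrom_lengths_cm, float)
    counts = np.maximum(2, np.round(M * lengths / lengths.sum()).astype(int))
    # adjust the largest chromosome so counts sum exactly to M
    counts[np.argmax(counts)] += M - counts.sum()
    rows = []
    for c, (L_c, n_c) in enumerate(zip(lengths, counts), start=1):
        cm = np.sort(rng.uniform(0, L_c, size=n_c))
        bp = np.maximum(1, np.round(cm * bp_per_cm)).astype(np.int64)
        bp = np.maximum.accumulate(bp)
        bp += np.arange(n_c)  # enforce strictly increasing bp
        for p_cm, p_bp in zip(cm, bp):
            rows.append(dict(chrom=str(c), pos_bp=int(p_bp), pos_cm=float(p_cm),
                             ref="A", alt="G", ancestral_is_ref=True))
    return pd.DataFrame(rows, columns=MARKER_COLUMNS)


def draw_population_freqs(p_anc: np.ndarray, fst: float, K: int,
                          seed_or_rng) -> np.ndarray:
    """Balding-Nichols per-population frequencies around ancestral ``p_anc``.

    Each population's frequency at each marker is an independent draw from
    ``Beta(p (1-F)/F, (1-p)(1-F)/F)``, clipped to [0.01, 0.99].
    """
    rng = np.random.default_rng(seed_or_rng) if not isinstance(
        seed_or_rng, np.random.Generator) else seed_or_rng
    p = np.asarray(p_anc, dtype=float)
    if fst <= 0:
        raise ValueError("fst must be positive")
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("ancestral frequencies must lie strictly in (0, 1)")
    scale = (1 - fst) / fst
    freqs = rng.beta(p * scale, (1 - p) * scale, size=(K, len(p)))
    return np.clip(freqs, 0.01, 0.99)


def simulate_source_haplotypes(freqs: np.ndarray, n_per_pop: int, ld_rho: float,
                               markers: pd.DataFrame, seed_or_rng,
                               founder_fraction: float = 0.2) -> list[np.ndarray]:
    """Haplotypes for each source population under the Markov copying model.

    ``freqs`` is K x M.  The first ``max(2, founder_fraction * n)`` haplotypes
    per population are drawn site-independently from the population
    frequencies; the rest copy a random founder, switching template between
    adjacent markers with probability ``min(1, ld_rho * dcM)`` (templates
    also reset at chromosome boundaries).  Returns a list of K (n x M) uint8
    matrices.
    """
    rng = np.random.default_rng(seed_or_rng) if not isinstance(
        seed_or_rng, np.random.Generator) else seed_or_rng
    freqs = np.atleast_2d(np.asarray(freqs, float))
    K, M = freqs.shape
    cm = markers["pos_cm"].to_numpy(float)
    chrom = markers["chrom"].to_numpy()
    dcm = np.diff(cm)
    new_chrom = chrom[1:] != chrom[:-1]
    if np.isinf(ld_rho):
        p_switch = np.ones(M - 1)
    else:
        p_switch = np.minimum(1.0, ld_rho * np.maximum(dcm, 0.0))
    p_switch[new_chrom] = 1.0
    out = []
    for k in range(K):
        n_founder = min(n_per_pop, max(2, int(round(founder_fraction * n_per_pop))))
        founders = (rng.random((n_founder, M)) < freqs[k]).astype(np.uint8)
        haps = np.empty((n_per_pop, M), dtype=np.uint8)
        haps[:n_founder] = founders
        for i in range(n_founder, n_per_pop):
            switch = rng.random(M - 1) < p_switch
            seg = np.concatenate([[0], np.cumsum(switch)])
            templates = rng.integers(0, n_founder, size=seg[-1] + 1)
            haps[i] = founders[templates[seg], np.arange(M)]
        out.append(haps)
    return out


def simulate_source_panel(alleles: np.ndarray, markers: pd.DataFrame,
                          prefix: str) -> HaplotypePanel:
    """Wrap a (2n x M) source haplotype matrix as a panel."""
    if alleles.shape[0] % 2:
        alleles = alleles[:-1]
    n = alleles.shape[0] // 2
    return HaplotypePanel(alleles=alleles, markers=markers.copy(),
                          sample_ids=[f"{prefix}{i}" for i in range(n)],
                          population_labels=[prefix] * n)


# ---------------------------------------------------------------------------
# Admixture
# ---------------------------------------------------------------------------

def simulate_admixed_cohort(
    config: SimulationConfig,
    sources: Mapping[str, Union[np.ndarray, Sequence[np.ndarray]]],
    markers: pd.DataFrame,
    source_assignment: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
):
    """Simulate an admixed cohort under the hybrid-isolation model.

    ``sources`` maps ancestry name -> haplotype matrix (n x M) or a sequence
    of such matrices (sub-populations of that ancestry, e.g. northern vs
    southern variants of a continental source); ``source_assignment`` then
    picks, per individual, which sub-population donates that ancestry's
    segments.  Ancestry 0 (first key) is the "target" ancestry whose
    proportion is ``z``.

    Per haplotype and chromosome, switch points are a Poisson process at
    rate T per Morgan; the ancestry after each point (and at the chromosome
    start) is an independent draw from the individual's proportion vector.
    Each resulting segment copies one randomly chosen donor haplotype of the
    local ancestry (segment-coherent copying).

    Returns ``(panel, truth_track, z, info)``; ``info`` carries the
    continuous (marker-free) ground truth: per-haplotype effective switch
    counts and per-individual diploid block counts (switches + 2 * n_chrom),
    which match the hybrid-isolation expectation exactly, unlike counts read
    off marker labels, which miss switches finer than the marker spacing.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    names = list(sources.keys())
    K = len(names)
    pools: list[list[np.ndarray]] = []
    for name in names:
        v = sources[name]
        pools.append(list(v) if isinstance(v, (list, tuple)) else [np.asarray(v)])
    N = config.n_individuals
    if source_assignment is None:
        source_assignment = np.zeros(N, dtype=int)
    M = len(markers)
    cm = markers["pos_cm"].to_numpy(float)
    chrom = markers["chrom"].to_numpy()
    chrom_ids = pd.unique(chrom)
    chrom_slices = []
    for c in chrom_ids:
        idx = np.flatnonzero(chrom == c)
        chrom_slices.append((idx[0], idx[-1] + 1))
    # switch points are drawn over the full chromosome length, not just the
    # marker span, so expected block counts do not depend on marker density
    if len(config.chrom_lengths_cm) == len(chrom_slices):
        chrom_lengths = [max(L, cm[hi - 1] - cm[lo])
                         for L, (lo, hi) in zip(config.chrom_lengths_cm, chrom_slices)]
    else:
        chrom_lengths = [cm[hi - 1] - cm[lo] for lo, hi in chrom_slices]

    alleles = np.empty((2 * N, M), dtype=np.uint8)
    labels = np.empty((2 * N, M), dtype=np.int16)
    z = np.empty(N)
    eff_switches = np.zeros(2 * N, dtype=int)
    rate_per_cm = 0.01 * config.T
    for n in range(N):
        z[n] = config.draw_z(rng)
        q = np.empty(K)
        q[0] = z[n]
        q[1:] = (1 - z[n]) / max(K - 1, 1)
        for h in (2 * n, 2 * n + 1):
            for (lo, hi), L_c in zip(chrom_slices, chrom_lengths):
                c_cm = cm[lo:hi]
                n_sw = rng.poisson(rate_per_cm * L_c)
                points = np.sort(rng.uniform(0.0, max(L_c, c_cm[-1]), size=n_sw))
                states = rng.choice(K, size=n_sw + 1, p=q)
                eff_switches[h] += int(np.sum(states[1:] != states[:-1]))
                cuts = np.searchsorted(c_cm, points, side="right")
                starts = np.concatenate([[0], cuts])
                ends = np.concatenate([cuts, [hi - lo]])
                for s, e, st in zip(starts, ends, states):
                    if s >= e:
                        continue
                    pool = pools[st]
                    donor_pool = pool[source_assignment[n] % len(pool)] if len(pool) > 1 else pool[0]
                    donor = rng.integers(0, donor_pool.shape[0])
                    alleles[h, lo + s:lo + e] = donor_pool[donor, lo + s:lo + e]
                    labels[h, lo + s:lo + e] = st
    panel = HaplotypePanel(alleles=alleles, markers=markers.copy(),
                           sample_ids=[f"adm{i}" for i in range(N)])
    track = AncestryTrack(labels=labels, K=K, ancestry_names=names)
    n_chrom = len(chrom_slices)
    info = {
        "effective_switches": eff_switches,
        "diploid_blocks_truth": eff_switches.reshape(N, 2).sum(axis=1) + 2 * n_chrom,
    }
    return panel, track, z, info


# ---------------------------------------------------------------------------
# Sweep injection and mask corruption
# ---------------------------------------------------------------------------

def inject_sweep(panel: HaplotypePanel, spec: SweepSpec, seed_or_rng):
    """Overwrite a fraction of haplotypes with one founder's alleles around a core.

    Carrier extents truncate at exponentially distributed genetic distances
    (mean ``founder_span_cm / 2``, capped at ``founder_span_cm / 2`` per
    side) so haplotype homozygosity decays away from the core.  Returns
    ``(panel, info)`` where ``info`` records carriers, the founder haplotype
    and per-carrier truncation distances.
    """
    rng = np.random.default_rng(seed_or_rng) if not isinstance(
        seed_or_rng, np.random.Generator) else seed_or_rng
    if not 0 <= spec.core_marker < panel.n_markers:
        raise ValueError("core_marker out of range")
    alleles = panel.alleles.copy()
    H = panel.n_haplotypes
    n_car = int(round(spec.carrier_freq * H))
    info = {"carriers": np.array([], int), "founder": None,
            "trunc_left_cm": np.array([]), "trunc_right_cm": np.array([])}
    if n_car == 0:
        return HaplotypePanel(alleles=alleles, markers=panel.markers.copy(),
                              sample_ids=list(panel.sample_ids)), info
    carriers = rng.choice(H, size=n_car, replace=False)
    founder = alleles[carriers[0]].copy()
    cm = panel.markers["pos_cm"].to_numpy(float)
    chrom = panel.markers["chrom"].to_numpy()
    core_cm = cm[spec.core_marker]
    core_chrom = chrom[spec.core_marker]
    half = spec.founder_span_cm / 2.0
    t_left = np.minimum(rng.exponential(half, size=n_car), half)
    t_right = np.minimum(rng.exponential(half, size=n_car), half)
    on_chrom = chrom == core_chrom
    for i, hap in enumerate(carriers):
        sel = on_chrom & (cm >= core_cm - t_left[i]) & (cm <= core_cm + t_right[i])
        alleles[hap, sel] = founder[sel]
    info.update(carriers=carriers, founder=founder,
                trunc_left_cm=t_left, trunc_right_cm=t_right)
    return HaplotypePanel(alleles=alleles, markers=panel.markers.copy(),
                          sample_ids=list(panel.sample_ids)), info


def corrupt_ancestry_labels(track: AncestryTrack, config: MaskCorruptionConfig,
                            chrom: Optional[np.ndarray] = None) -> AncestryTrack:
    """Flip each maximal constant-ancestry segment with probability epsilon.

    For K = 2 a flipped segment takes the other ancestry; for K > 2 it takes
    a uniformly random different ancestry.  Segments never span chromosome
    boundaries when ``chrom`` (per-marker chromosome array) is given.
    """
    rng = np.random.default_rng(config.seed)
    labels = track.labels.copy()
    M = labels.shape[1]
    if chrom is not None:
        chrom = np.asarray(chrom)
        breaks = np.concatenate([[0], np.flatnonzero(chrom[1:] != chrom[:-1]) + 1, [M]])
    else:
        breaks = np.array([0, M])
    for h in range(labels.shape[0]):
        for b in range(len(breaks) - 1):
            lo, hi = breaks[b], breaks[b + 1]
            for s, e, v in _runs(track.labels[h, lo:hi]):
                if v == MISSING:
                    continue
                if rng.random() < config.epsilon:
                    if track.K == 2:
                        labels[h, lo + s:lo + e] = 1 - v
                    else:
                        others = [k for k in range(track.K) if k != v]
                        labels[h, lo + s:lo + e] = rng.choice(others)
    return AncestryTrack(labels=labels, K=track.K,
                         ancestry_names=list(track.ancestry_names))
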