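"""Ancestry masking into per-ancestry virtual genomes and block extraction.

A *virtual genome* keeps only the alleles a haplotype derives from one
ancestral population, setting everything else to missing.  Because the two
alleles of an individual at a SNP are unordered for PCA purposes, masking
produces a pair of N x M matrices (G1, G2) holding the per-individual allele
pair with NaN at masked entries — the substrate of subspace PCA.

Ancestry blocks are maximal constant-ancestry runs per haplotype per
chromosome.  Very short blocks (fewer than ``min_snps`` markers) typically
reflect decoding noise; they are absorbed into their flanking blocks before
block counts feed admixture dating.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import AncestryTrack, DataModelError, HaplotypePanel, _runs


@dataclass
class MaskedMatrixPair:
    """The two N x M per-allele matrices of one ancestry's virtual genomes."""

    G1: np.ndarray
    G2: np.ndarray
    target_ancestry: str
    sample_ids: list[str]
    markers: pd.DataFrame
    observed_fraction: np.ndarray   # per-individual fraction of observed cells

    @property
    def n_samples(self) -> int:
        return self.G1.shape[0]

    @property
    def n_markers(self) -> int:
        return self.G1.shape[1]


def mask_to_virtual(panel: HaplotypePanel, track: AncestryTrack, target: str,
                    posterior_threshold: float = 0.9) -> MaskedMatrixPair:
    """Mask a panel down to one ancestry's virtual genomes.

    An allele is retained iff its haplotype's ancestry call at that marker
    equals ``target`` and, when posteriors are available, the posterior of
    the call is at least ``posterior_threshold`` (below-threshold calls are
    conservatively masked).
    """
    if target not in track.ancestry_names:
        raise DataModelError(f"ancestry {target!r} not in {track.ancestry_names}")
    if track.labels.shape != panel.alleles.shape:
        raise DataModelError("track is not aligned to panel")
    k = track.ancestry_names.index(target)
    keep = track.labels == k
    if track.posteriors is not None:
        keep &= track.posteriors[:, :, k] >= posterior_threshold
    X = panel.alleles.astype(float)
    X[~keep] = np.nan
    G1, G2 = X[0::2], X[1::2]
    obs_frac = (~np.isnan(G1)).mean(axis=1) / 2 + (~np.isnan(G2)).mean(axis=1) / 2
    return MaskedMatrixPair(G1=G1, G2=G2, target_ancestry=target,
                            sample_ids=list(panel.sample_ids),
                            markers=panel.markers.copy(),
                            observed_fraction=obs_frac)


@dataclass(frozen=True)
class AncestryBlock:
    """One maximal (post-filter) constant-ancestry run on one haplotype."""

    haplotype: int
    chrom: str
    start_marker: int     # panel-wide 0-based index, inclusive
    end_marker: int       # inclusive
    ancestry: int
    n_snps: int
    length_cm: float


def _filter_runs(runs: list[tuple[int, int, int]], min_snps: int) -> list[tuple[int, int, int]]:
    """Absorb runs shorter than min_snps into their flanks (left flank wins ties)."""
    out: list[list[int]] = []
    for s, e, v in runs:
        if e - s < min_snps and out:
            out[-1][1] = e                    # absorb into left flank
        elif e - s < min_snps:
            out.append([s, e, v])             # chromosome starts short: keep for now
        else:
            if out and out[-1][1] - out[-1][0] < min_snps:
                # leading short run(s): absorb into this first long run
                s = out[-1][0]
                out.pop()
            if out and out[-1][2] == v:
                out[-1][1] = e
            else:
                out.append([s, e, v])
    # merge adjacent same-ancestry runs created by absorption
    merged: list[list[int]] = []
    for s, e, v in out:
        if merged and merged[-1][2] == v:
            merged[-1][1] = e
        else:
            merged.append([s, e, v])
    return [(s, e, v) for s, e, v in merged]


def extract_blocks(track: AncestryTrack, markers: pd.DataFrame, min_snps: int = 10):
    """Ancestry blocks per haplotype per chromosome, plus diploid block counts.

    Runs with fewer than ``min_snps`` markers are removed and their span
    merged into the flanking block (the left flank's ancestry wins when the
    flanks disagree; flanks of equal ancestry coalesce).  Returns
    ``(blocks_df, diploid_counts)`` where ``diploid_counts[i]`` sums blocks
    over individual i's two haplotypes and all chromosomes.
    """
    chrom = markers["chrom"].to_numpy()
    cm = markers["pos_cm"].to_numpy(float)
    bnds = []
    start = 0
    for i in range(1, len(chrom) + 1):
        if i == len(chrom) or chrom[i] != chrom[start]:
            bnds.append((str(chrom[start]), start, i))
            start = i
    rows = []
    H = track.n_haplotypes
    counts = np.zeros((H + 1) // 2, dtype=int)
    for h in range(H):
        for cname, lo, hi in bnds:
            runs = _filter_runs(_runs(track.labels[h, lo:hi]), min_snps)
            for s, e, v in runs:
                rows.append(AncestryBlock(
                    haplotype=h, chrom=cname, start_marker=lo + s, end_marker=lo + e - 1,
                    ancestry=v, n_snps=e - s,
                    length_cm=float(cm[lo + e - 1] - cm[lo + s])))
            counts[h // 2] += len(runs)
    df = pd.DataFrame([b.__dict__ for b in rows])
    return df, counts


def select_individuals(global_ancestry: np.ndarray, target_index: int,
                       min_prop: float = 0.25) -> np.ndarray:
    """Indices of individuals whose target-ancestry proportion is >= min_prop.

    The boundary is inclusive: individuals with *less than* ``min_prop`` are
    excluded.  Rows must sum to 1.
    """
    ga = np.asarray(global_ancestry, float)
    if not np.allclose(ga.sum(axis=1), 1.0, atol=1e-6):
        raise DataModelError("global-ancestry rows must sum to 1")
    idx = np.flatnonzero(ga[:, target_index] >= min_prop)
    if idx.size == 0:
        warnings.warn("no individuals pass the ancestry-proportion threshold")
    return idx


def write_masked_pair(pair: MaskedMatrixPair, prefix: str) -> None:
    """Serialize a masked pair as sparse triplet TSVs with sample/marker sidecars."""
    for tag, G in (("G1", pair.G1), ("G2", pair.G2)):
        r, c = np.nonzero(~np.isnan(G))
        pd.DataFrame({"row": r, "col": c, "allele": G[r, c].astype(int)}).to_csv(
            f"{prefix}.{tag}.tsv", sep="\t", index=False)
    pd.Series(pair.sample_ids, name="sample_id").to_csv(
        f"{prefix}.samples.tsv", sep="\t", index=False)
    pair.markers.to_csv(f"{prefix}.markers.tsv", sep="\t", index=False)


def read_masked_pair(prefix: str, target_ancestry: str = "") -> MaskedMatrixPair:
    samples = pd.read_csv(f"{prefix}.samples.tsv", sep="\t")["sample_id"].astype(str).tolist()
    markers = pd.read_csv(f"{prefix}.markers.tsv", sep="\t")
    N, M = len(samples), len(markers)
    mats = []
    for tag in ("G1", "G2"):
        t = pd.read_csv(f"{prefix}.{tag}.tsv", sep="\t")
        G = np.full((N, M), np.nan)
        G[t["row"], t["col"]] = t["allele"]
        mats.append(G)
    obs = (~np.isnan(mats[0])).mean(axis=1) / 2 + (~np.isnan(mats[1])).mean(axis=1) / 2
    return MaskedMatrixPair(G1=mats[0], G2=mats[1], target_ancestry=target_ancestry,
                            sample_ids=samples, markers=markers, observed_fraction=obs)
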