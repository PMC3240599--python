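"""Core data types and file I/O for phased haplotype panels and ancestry tracks.

The central container is :class:`HaplotypePanel`: a complete (no missing
entries) matrix of phased biallelic alleles over ``2N`` haplotypes and ``M``
markers, together with per-marker metadata (chromosome, bp and cM positions,
alleles, ancestral-allele flag).  Ancestry decoding produces an
:class:`AncestryTrack` aligned to the same panel.  Missingness enters the
workflow only through ancestry masking (see :mod:`admixkit.virtual_genomes`).

Coordinate conventions: VCF positions are 1-based; BED output is 0-based
half-open; internal marker indices are 0-based.  Ancestry blocks written to
BED end at the bp of their last member marker.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

__version__ = "0.1.0"

#: Sentinel for a missing ancestry label.
MISSING = -1

#: Columns of the marker metadata frame.
MARKER_COLUMNS = ["chrom", "pos_bp", "pos_cm", "ref", "alt", "ancestral_is_ref"]


class DataModelError(ValueError):
    """Raised for malformed inputs (unphased GT, misaligned tracks, ...)."""


@dataclass(frozen=True)
class MarkerInfo:
    """Metadata for a single biallelic marker."""

    chrom: str
    pos_bp: int
    pos_cm: float
    ref: str
    alt: str
    ancestral_is_ref: bool = True

    def __post_init__(self):
        if self.ref == self.alt:
            raise DataModelError(
                f"marker {self.chrom}:{self.pos_bp}: ref and alt alleles are equal"
            )


def _validate_markers(markers: pd.DataFrame) -> None:
    for col in MARKER_COLUMNS:
        if col not in markers.columns:
            raise DataModelError(f"marker frame is missing column {col!r}")
    if (markers["ref"] == markers["alt"]).any():
        bad = markers.index[markers["ref"] == markers["alt"]][0]
        raise DataModelError(f"marker row {bad}: ref equals alt")
    for chrom, sub in markers.groupby("chrom", sort=False):
        bp = sub["pos_bp"].to_numpy()
        cm = sub["pos_cm"].to_numpy()
        if np.any(np.diff(bp) <= 0):
            raise DataModelError(f"pos_bp not strictly increasing on chromosome {chrom}")
        if np.any(np.diff(cm) < 0):
            raise DataModelError(f"pos_cm decreasing on chromosome {chrom}")


@dataclass
class HaplotypePanel:
    """Phased allele matrix with marker metadata.

    ``alleles`` has shape ``(2N, M)`` over ``{0, 1}``; haplotypes ``2n`` and
    ``2n + 1`` belong to individual ``n`` (VCF order: sample0 hapA, sample0
    hapB, sample1 hapA, ...).
    """

    alleles: np.ndarray
    markers: pd.DataFrame
    sample_ids: list[str]
    population_labels: Optional[list[str]] = None

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2:
            raise DataModelError("allele matrix must be 2-dimensional")
        if self.alleles.shape[0] != 2 * len(self.sample_ids):
            raise DataModelError(
                f"{self.alleles.shape[0]} haplotype rows but {len(self.sample_ids)} samples"
            )
        if self.alleles.shape[1] != len(self.markers):
            raise DataModelError(
                f"{self.alleles.shape[1]} allele columns but {len(self.markers)} markers"
            )
        if self.alleles.size and self.alleles.max() > 1:
            raise DataModelError("allele matrix entries must be 0/1 (panel is complete)")
        _validate_markers(self.markers)
        self.markers = self.markers.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[1]

    def marker_info(self, m: int) -> MarkerInfo:
        row = self.markers.iloc[m]
        return MarkerInfo(
            chrom=str(row["chrom"]),
            pos_bp=int(row["pos_bp"]),
            pos_cm=float(row["pos_cm"]),
            ref=str(row["ref"]),
            alt=str(row["alt"]),
            ancestral_is_ref=bool(row["ancestral_is_ref"]),
        )

    def chrom_bounds(self) -> dict[str, tuple[int, int]]:
        """Half-open marker-index range of each chromosome, in panel order."""
        bounds: dict[str, tuple[int, int]] = {}
        chroms = self.markers["chrom"].to_numpy()
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                bounds[str(chroms[start])] = (start, i)
                start = i
        return bounds


@dataclass
class AncestryTrack:
    """Per-haplotype, per-marker ancestry calls.

    ``labels`` holds ancestry indices in ``{0..K-1}`` or :data:`MISSING`;
    ``posteriors`` (optional) holds forward-backward probabilities of shape
    ``(2N, M, K)`` summing to 1 at every cell, with
    ``labels == argmax(posteriors)`` wherever both are present.
    """

    labels: np.ndarray
    K: int
    ancestry_names: list[str]
    posteriors: Optional[np.ndarray] = None
    loglik: Optional[np.ndarray] = None  # per-haplotype decode log-likelihood

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int16)
        if len(self.ancestry_names) != self.K:
            raise DataModelError("ancestry_names length must equal K")
        valid = (self.labels >= 0) & (self.labels < self.K)
        if not np.all(valid | (self.labels == MISSING)):
            raise DataModelError("labels outside {0..K-1} or MISSING")
        if self.posteriors is not None:
            self.posteriors = np.asarray(self.posteriors, dtype=float)
            if self.posteriors.shape != self.labels.shape + (self.K,):
                raise DataModelError("posterior shape does not match labels")
            sums = self.posteriors.sum(axis=2)
            if not np.allclose(sums, 1.0, atol=1e-8):
                raise DataModelError("posteriors do not sum to 1")
            argmax = self.posteriors.argmax(axis=2)
            obs = self.labels != MISSING
            if not np.array_equal(argmax[obs], self.labels[obs]):
                raise DataModelError("labels disagree with posterior argmax")

    @property
    def n_haplotypes(self) -> int:
        return self.labels.shape[0]

    @property
    def n_markers(self) -> int:
        return self.labels.shape[1]


# ---------------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------------

def read_phased_vcf(path: str) -> HaplotypePanel:
    """Read a fully phased, biallelic-SNP VCF into a :class:`HaplotypePanel`.

    Every GT must be phased ("|") and complete; multiallelic records are
    rejected.  Haplotype rows follow VCF sample order.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    columns: list[np.ndarray] = []
    rows: list[dict] = []
    for variant in vcf:
        ident = f"{variant.CHROM}:{variant.POS}"
        if len(variant.ALT) != 1:
            raise DataModelError(f"record {ident}: multiallelic site (ALT={variant.ALT})")
        col = np.empty(2 * len(sample_ids), dtype=np.uint8)
        for i, gt in enumerate(variant.genotypes):
            a, b, phased = gt[0], gt[1], gt[2]
            if a < 0 or b < 0:
                raise DataModelError(f"record {ident}: missing GT for sample {sample_ids[i]}")
            if not phased:
                raise DataModelError(
                    f"record {ident}: unphased genotype for sample {sample_ids[i]}"
                )
            col[2 * i] = a
            col[2 * i + 1] = b
        columns.append(col)
        rows.append(
            dict(
                chrom=str(variant.CHROM),
                pos_bp=int(variant.POS),
                pos_cm=np.nan,
                ref=str(variant.REF),
                alt=str(variant.ALT[0]),
                ancestral_is_ref=("AA" not in dict(variant.INFO) or variant.INFO["AA"] == variant.REF),
            )
        )
    markers = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    # cM defaults to a uniform 1 cM/Mb map until a genetic map is attached
    markers["pos_cm"] = markers["pos_bp"].astype(float) * 1e-6
    alleles = np.column_stack(columns) if columns else np.empty((2 * len(sample_ids), 0), np.uint8)
    return HaplotypePanel(alleles=alleles, markers=markers, sample_ids=sample_ids)


def write_phased_vcf(panel: HaplotypePanel, path: str, seed: Optional[int] = None) -> None:
    """Write a panel as a phased VCF (with a provenance header line)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=admixkit {__version__} (seed={seed})\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(panel.markers["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(panel.sample_ids) + "\n")
        A = panel.alleles
        for m in range(panel.n_markers):
            row = panel.markers.iloc[m]
            aa = row["ref"] if row["ancestral_is_ref"] else row["alt"]
            gts = "\t".join(
                f"{A[2 * i, m]}|{A[2 * i + 1, m]}" for i in range(panel.n_samples)
            )
            fh.write(
                f"{row['chrom']}\t{row['pos_bp']}\t.\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\tAA={aa}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Haplotype TSV dialect (hand-writable fixtures)
# ---------------------------------------------------------------------------

def write_haplotype_tsv(panel: HaplotypePanel, path: str, seed: Optional[int] = None) -> None:
    """Write alleles as TSV: one row per haplotype, marker IDs ``chrom:bp`` as header."""
    with open(path, "w") as fh:
        fh.write(f"# admixkit {__version__} seed={seed}\n")
        ids = [f"{r['chrom']}:{r['pos_bp']}" for _, r in panel.markers.iterrows()]
        fh.write("haplotype\t" + "\t".join(ids) + "\n")
        for h in range(panel.n_haplotypes):
            name = f"{panel.sample_ids[h // 2]}_{h % 2}"
            fh.write(name + "\t" + "\t".join(map(str, panel.alleles[h])) + "\n")


def read_haplotype_tsv(path: str, markers: Optional[pd.DataFrame] = None) -> HaplotypePanel:
    """Read the haplotype TSV dialect.

    Marker metadata is taken from the ``chrom:bp`` header IDs (ref/alt default
    A/G, uniform 1 cM/Mb map) unless a full marker frame is supplied.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if not ln.startswith("#")]
    header = lines[0].split("\t")[1:]
    hap_names, rows = [], []
    for ln in lines[1:]:
        parts = ln.split("\t")
        hap_names.append(parts[0])
        rows.append([int(x) for x in parts[1:]])
    alleles = np.asarray(rows, dtype=np.uint8)
    if alleles.shape[0] % 2:
        raise DataModelError("haplotype TSV must contain an even number of haplotype rows")
    sample_ids = [hap_names[2 * i].rsplit("_", 1)[0] for i in range(alleles.shape[0] // 2)]
    if markers is None:
        recs = []
        for mid in header:
            chrom, bp = mid.rsplit(":", 1)
            recs.append(dict(chrom=chrom, pos_bp=int(bp), pos_cm=int(bp) * 1e-6,
                             ref="A", alt="G", ancestral_is_ref=True))
        markers = pd.DataFrame(recs, columns=MARKER_COLUMNS)
    return HaplotypePanel(alleles=alleles, markers=markers, sample_ids=sample_ids)


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

def read_genetic_map(path: str, panel: HaplotypePanel) -> HaplotypePanel:
    """Fill ``pos_cm`` by linear interpolation of a 3-column (chrom, bp, cM) map.

    Positions beyond the map ends take the terminal map value (constant
    extrapolation, which is ``np.interp``'s native behaviour).  A marker
    chromosome absent from the map is an error.
    """
    gmap = pd.read_csv(path, sep=r"\s+", comment="#", header=None,
                       names=["chrom", "pos_bp", "pos_cm"], dtype={0: str})
    markers = panel.markers.copy()
    cm = np.empty(len(markers))
    for chrom, sub in markers.groupby("chrom", sort=False):
        key = str(chrom)
        mchrom = gmap[gmap["chrom"].astype(str) == key]
        if mchrom.empty:
            raise DataModelError(f"chromosome {chrom} absent from genetic map")
        mchrom = mchrom.sort_values("pos_bp")
        cm[sub.index] = np.interp(
            sub["pos_bp"].to_numpy(float),
            mchrom["pos_bp"].to_numpy(float),
            mchrom["pos_cm"].to_numpy(float),
        )
    markers["pos_cm"] = cm
    return HaplotypePanel(alleles=panel.alleles.copy(), markers=markers,
                          sample_ids=list(panel.sample_ids),
                          population_labels=panel.population_labels)


# ---------------------------------------------------------------------------
# Ancestry BED
# ---------------------------------------------------------------------------

def _runs(values: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal constant runs of a 1-D array as (start, end_exclusive, value)."""
    if len(values) == 0:
        return []
    change = np.flatnonzero(np.diff(values)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(values)]])
    return [(int(s), int(e), int(values[s])) for s, e in zip(starts, ends)]


def write_ancestry_bed(track: AncestryTrack, panel: HaplotypePanel, path: str,
                       seed: Optional[int] = None) -> None:
    """Write maximal constant-ancestry runs as BED records.

    One record per run per haplotype; 0-based half-open intervals running
    from the first member marker's ``bp - 1`` to the last member marker's
    ``bp``; name field ``sampleID_hapIndex_ancestryName``.  MISSING runs are
    omitted.
    """
    bp = panel.markers["pos_bp"].to_numpy()
    bounds = panel.chrom_bounds()
    with open(path, "w") as fh:
        fh.write(f"#admixkit {__version__} seed={seed}\n")
        fh.write("#chrom\tstart\tend\tname\n")
        for h in range(track.n_haplotypes):
            sample = panel.sample_ids[h // 2]
            for chrom, (lo, hi) in bounds.items():
                for s, e, v in _runs(track.labels[h, lo:hi]):
                    if v == MISSING:
                        continue
                    name = f"{sample}_{h % 2}_{track.ancestry_names[v]}"
                    fh.write(f"{chrom}\t{bp[lo + s] - 1}\t{bp[lo + e - 1]}\t{name}\n")


def read_ancestry_bed(path: str, panel: HaplotypePanel, ancestry_names: Sequence[str]) -> AncestryTrack:
    """Reconstruct a label-only track from a BED written by :func:`write_ancestry_bed`."""
    name_to_idx = {n: i for i, n in enumerate(ancestry_names)}
    sample_to_idx = {s: i for i, s in enumerate(panel.sample_ids)}
    labels = np.full((panel.n_haplotypes, panel.n_markers), MISSING, dtype=np.int16)
    bp = panel.markers["pos_bp"].to_numpy()
    bounds = panel.chrom_bounds()
    with open(path) as fh:
        for ln in fh:
            if ln.startswith("#") or not ln.strip():
                continue
            chrom, start, end, name = ln.rstrip("\n").split("\t")[:4]
            sample, hap, anc = name.rsplit("_", 2)
            h = 2 * sample_to_idx[sample] + int(hap)
            lo, hi = bounds[chrom]
            sel = lo + np.flatnonzero((bp[lo:hi] > int(start)) & (bp[lo:hi] <= int(end)))
            labels[h, sel] = name_to_idx[anc]
    return AncestryTrack(labels=labels, K=len(ancestry_names),
                         ancestry_names=list(ancestry_names))


# ---------------------------------------------------------------------------
# Column standardization (the ssPCA contract)
# ---------------------------------------------------------------------------

class Standardized(NamedTuple):
    matrix: np.ndarray      # standardized copy, NaN where missing
    mean: np.ndarray        # per-column observed mean
    scale: np.ndarray       # per-column observed sample SD (ddof=1)
    kept: np.ndarray        # boolean: column usable downstream


def standardize_columns(matrix: np.ndarray) -> Standardized:
    """Standardize columns to observed mean 0, sample variance 1 (NaN = missing).

    Columns with fewer than two observed entries or zero observed variance
    are flagged (``kept=False``) and left NaN rather than raising: monomorphic
    -in-observed columns carry no substructure signal and would make the
    reconstruction error degenerate.
    """
    import warnings

    X = np.array(matrix, dtype=float)
    obs = ~np.isnan(X)
    n_obs = obs.sum(axis=0)
    with warnings.catch_warnings(), np.errstate(invalid="ignore"):
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(X, axis=0)
        sd = np.nanstd(X, axis=0, ddof=1)
    kept = (n_obs >= 2) & (sd > 0) & np.isfinite(sd)
    Z = np.full_like(X, np.nan)
    Z[:, kept] = (X[:, kept] - mean[kept]) / sd[kept]
    return Standardized(matrix=Z, mean=mean, scale=sd, kept=kept)
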