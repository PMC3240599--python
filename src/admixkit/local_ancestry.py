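"""Locus-specific ancestry inference with a (Markov-)hidden Markov model.

Each haplotype is decoded independently.  Hidden states are the K ancestral
populations; the chance of an ancestry switch over a gap of ``d`` Morgans is
``1 - exp(-tau * d)`` and the post-switch state is redrawn from the
individual's ancestry-proportion vector ``q`` — the stationary kernel of the
hybrid-isolation switch process.  Emissions are ancestry-specific allele
frequencies (``markov_order=0``) or two-site conditional haplotype
frequencies (``markov_order=1``), the latter absorbing background LD within
each ancestral population so that strings of correlated markers are not
over-counted as independent evidence.

Frequencies are clipped to [0.001, 0.999] before emission so that a finite
reference panel can never assign zero likelihood to a path.  Forward and
backward recursions are scaled per marker; log-likelihoods are sums of log
scaling factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .datamodel import AncestryTrack, DataModelError, HaplotypePanel

FREQ_CLIP = (0.001, 0.999)


@dataclass
class HmmParams:
    """Parameters of the ancestry HMM.

    ``q`` may be a single K-vector (shared by all haplotypes) or an (H, K)
    matrix of per-haplotype proportion vectors.  ``pair_freqs`` (required for
    ``markov_order=1``) holds per-ancestry joint frequencies of adjacent
    marker pairs, shape (K, M-1, 2, 2).
    """

    K: int
    ref_freqs: np.ndarray            # (K, M) ancestry-specific alt-allele freqs
    q: np.ndarray                    # (K,) or (H, K)
    tau: float = 12.0                # switch intensity, generations (per Morgan)
    markov_order: int = 0
    pair_freqs: Optional[np.ndarray] = None

    def __post_init__(self):
        self.ref_freqs = np.clip(np.asarray(self.ref_freqs, float), *FREQ_CLIP)
        self.q = np.asarray(self.q, float)
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.markov_order not in (0, 1):
            raise ValueError("markov_order must be 0 or 1")
        if self.markov_order == 1 and self.pair_freqs is None:
            raise ValueError("markov_order=1 requires pair_freqs")
        qsum = self.q.sum(axis=-1)
        if not np.allclose(qsum, 1.0, atol=1e-6):
            raise ValueError("ancestry proportions q must sum to 1")


def estimate_hmm_params(ref_panels: Mapping[str, np.ndarray], q, tau: float = 12.0,
                        markov_order: int = 0,
                        weights: Optional[Mapping[str, np.ndarray]] = None) -> HmmParams:
    """Empirical HMM parameters from per-ancestry reference haplotype matrices.

    ``weights`` optionally gives per-cell usage weights in [0, 1] (used by
    reference refinement to down-weight masked foreign segments).
    """
    names = list(ref_panels.keys())
    K = len(names)
    mats = [np.asarray(ref_panels[n], float) for n in names]
    M = mats[0].shape[1]
    freqs = np.empty((K, M))
    pair = np.full((K, M - 1, 2, 2), 0.25) if markov_order == 1 else None
    for k, (name, X) in enumerate(zip(names, mats)):
        if X.shape[0] == 0:
            raise DataModelError(f"reference population {name!r} has zero haplotypes")
        W = np.ones_like(X) if weights is None else np.asarray(weights[name], float)
        denom = W.sum(axis=0)
        if np.any(denom <= 0):
            raise DataModelError(
                f"reference population {name!r} has markers with zero retained haplotypes")
        freqs[k] = (X * W).sum(axis=0) / denom
        if markov_order == 1:
            Wp = W[:, :-1] * W[:, 1:]
            dp = Wp.sum(axis=0)
            a, b = X[:, :-1], X[:, 1:]
            with np.errstate(invalid="ignore", divide="ignore"):
                for u in (0, 1):
                    for v in (0, 1):
                        cnt = (Wp * (a == u) * (b == v)).sum(axis=0)
                        pair[k, :, u, v] = np.where(dp > 0, cnt / np.maximum(dp, 1e-12), 0.25)
    return HmmParams(K=K, ref_freqs=freqs, q=np.asarray(q, float), tau=tau,
                     markov_order=markov_order, pair_freqs=pair)


def _emissions(alleles: np.ndarray, params: HmmParams, m: int) -> np.ndarray:
    """Emission likelihoods at marker m for all haplotypes: (H, K)."""
    x = alleles[:, m]
    f = params.ref_freqs[:, m]  # (K,)
    if params.markov_order == 0 or m == 0:
        return np.where(x[:, None] == 1, f[None, :], 1.0 - f[None, :])
    # order 1: P(x_m | x_{m-1}, k) from two-site joint frequencies
    prev = alleles[:, m - 1]
    joint = params.pair_freqs[:, m - 1]          # (K, 2, 2)
    cond = joint / np.maximum(joint.sum(axis=2, keepdims=True), 1e-12)
    cond = np.clip(cond, *FREQ_CLIP)
    return cond[:, prev, x].T                    # (H, K)


def decode_ancestry(panel: HaplotypePanel, params: HmmParams) -> AncestryTrack:
    """Forward-backward posterior decoding of every haplotype.

    Deterministic given inputs.  Transitions reset (switch probability 1) at
    chromosome boundaries.  Returns a track with posteriors, argmax labels
    and per-haplotype log-likelihoods.
    """
    H, M = panel.alleles.shape
    K = params.K
    if params.ref_freqs.shape != (K, M):
        raise DataModelError(
            f"ref_freqs shape {params.ref_freqs.shape} does not match panel ({K}, {M})")
    q = params.q
    if q.ndim == 1:
        q = np.broadcast_to(q, (H, K))
    elif q.shape[0] == H // 2:   # per-individual vectors -> per-haplotype
        q = np.repeat(q, 2, axis=0)
    if q.shape != (H, K):
        raise DataModelError("q must be (K,), (N, K) or (2N, K)")

    cm = panel.markers["pos_cm"].to_numpy(float)
    chrom = panel.markers["chrom"].to_numpy()
    d_morgan = np.maximum(np.diff(cm), 0.0) / 100.0
    p_switch = 1.0 - np.exp(-params.tau * d_morgan)
    p_switch[chrom[1:] != chrom[:-1]] = 1.0

    alleles = panel.alleles
    alpha = np.empty((H, K))
    scale = np.empty((H, M))
    alphas = np.empty((M, H, K))
    e0 = _emissions(alleles, params, 0)
    np.multiply(q, e0, out=alpha)
    scale[:, 0] = alpha.sum(axis=1)
    alpha /= scale[:, [0]]
    alphas[0] = alpha
    for m in range(1, M):
        p = p_switch[m - 1]
        e = _emissions(alleles, params, m)
        # stay-or-redraw kernel: T_ij = (1-p) delta_ij + p q_j
        alpha = ((1 - p) * alpha + p * q) * e
        s = alpha.sum(axis=1)
        scale[:, m] = s
        alpha /= s[:, None]
        alphas[m] = alpha

    beta = np.ones((H, K))
    post = np.empty((H, M, K))
    post[:, M - 1] = alphas[M - 1] * beta
    for m in range(M - 2, -1, -1):
        p = p_switch[m]
        e = _emissions(alleles, params, m + 1)
        w = e * beta
        beta = ((1 - p) * w + p * (q * w).sum(axis=1, keepdims=True))
        beta /= scale[:, [m + 1]]
        post[:, m] = alphas[m] * beta
    post /= post.sum(axis=2, keepdims=True)
    labels = post.argmax(axis=2).astype(np.int16)
    loglik = np.log(scale).sum(axis=1)
    names = [f"anc{k}" for k in range(K)]
    return AncestryTrack(labels=labels, K=K, ancestry_names=names,
                         posteriors=post, loglik=loglik)


def refine_reference_panel(panel: HaplotypePanel,
                           initial_refs: Mapping[str, Sequence[int]],
                           tau: float = 12.0, markov_order: int = 0,
                           own_prior: float = 0.95, max_iter: int = 10,
                           change_tol: float = 1e-3):
    """Iteratively purge foreign segments from reference individuals.

    ``initial_refs`` maps ancestry name -> individual indices selected by a
    global-ancestry threshold (e.g. > 95% target ancestry).  Each round
    re-estimates ancestry-specific frequencies from reference haplotypes
    using only cells currently assigned to the target ancestry, re-decodes
    the references, and masks foreign segments; stops when assignments change
    at fewer than ``change_tol`` of cells or after ``max_iter`` rounds.

    Returns ``(params, assignment_masks)``.
    """
    names = list(initial_refs.keys())
    K = len(names)
    hap_idx = {}
    for name in names:
        inds = np.asarray(list(initial_refs[name]), dtype=int)
        if inds.size == 0:
            raise DataModelError(f"empty reference set for ancestry {name!r}")
        hap_idx[name] = np.sort(np.concatenate([2 * inds, 2 * inds + 1]))
    masks = {name: np.ones((len(hap_idx[name]), panel.n_markers)) for name in names}
    q_ref = {name: np.full(K, (1 - own_prior) / max(K - 1, 1)) for name in names}
    for k, name in enumerate(names):
        q_ref[name][k] = own_prior
    params = None
    for _ in range(max_iter):
        ref_mats = {name: panel.alleles[hap_idx[name]].astype(float) for name in names}
        params = estimate_hmm_params(ref_mats, q=np.full(K, 1.0 / K), tau=tau,
                                     markov_order=markov_order, weights=masks)
        changed = 0
        total = 0
        new_masks = {}
        for k, name in enumerate(names):
            sub = HaplotypePanel(alleles=panel.alleles[hap_idx[name]],
                                 markers=panel.markers,
                                 sample_ids=[f"r{i}" for i in range(len(hap_idx[name]) // 2)])
            p_k = HmmParams(K=K, ref_freqs=params.ref_freqs, q=q_ref[name], tau=tau,
                            markov_order=markov_order, pair_freqs=params.pair_freqs)
            track = decode_ancestry(sub, p_k)
            new = (track.labels == k).astype(float)
            changed += int(np.sum(new != masks[name]))
            total += new.size
            new_masks[name] = new
        masks = new_masks
        if changed / max(total, 1) < change_tol:
            break
    ref_mats = {name: panel.alleles[hap_idx[name]].astype(float) for name in names}
    params = estimate_hmm_params(ref_mats, q=np.full(K, 1.0 / K), tau=tau,
                                 markov_order=markov_order, weights=masks)
    return params, masks


def global_ancestry_from_local(track: AncestryTrack) -> np.ndarray:
    """Per-individual global ancestry: mean posterior over both haplotypes and markers."""
    if track.posteriors is None:
        raise DataModelError("global ancestry requires posteriors")
    H = track.n_haplotypes
    per_hap = track.posteriors.mean(axis=1)           # (2N, K)
    ga = per_hap.reshape(H // 2, 2, track.K).mean(axis=1)
    return ga / ga.sum(axis=1, keepdims=True)


@dataclass
class AncestryDeviationResult:
    """Per-marker ancestry-dosage deviation from the genome-wide average."""

    marker_means: np.ndarray     # (M, K) mean diploid dosage across individuals
    genome_mean: np.ndarray      # (K,)
    z_scores: np.ndarray         # (M, K); NaN when the across-marker SD is 0
    flagged: np.ndarray          # marker indices with any |z| above threshold
    threshold: float


def ancestry_deviation_scan(track: AncestryTrack, threshold: float = 4.0) -> AncestryDeviationResult:
    """Scan per-marker mean ancestry dosage for deviation from the genome-wide mean.

    The z-score of marker m for ancestry k is
    ``(mean_k(m) - genome_mean_k) / SD_over_markers(mean_k)``.  A locus can
    only be flagged when the across-marker SD is positive; an all-identical
    cohort yields no finite z and no flags.
    """
    H, M = track.labels.shape
    dosage = np.zeros((M, track.K))
    for k in range(track.K):
        dosage[:, k] = (track.labels == k).sum(axis=0) / (H / 2.0)
    dosage /= 2.0        # diploid dosage in [0, 1]
    genome_mean = dosage.mean(axis=0)
    sd = dosage.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (dosage - genome_mean) / sd
    z[:, sd == 0] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        flagged = np.flatnonzero(np.nanmax(np.abs(z), axis=1) > threshold) if M else np.array([], int)
    return AncestryDeviationResult(marker_means=dosage, genome_mean=genome_mean,
                                   z_scores=z, flagged=flagged, threshold=threshold)
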