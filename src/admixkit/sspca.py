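"""Subspace PCA: low-rank factorization fitted only to observed entries.

Covariance-based PCA mean-imputes missing genotypes, which biases
components when missingness varies wildly between individuals — exactly the
situation for ancestry-masked virtual genomes, where one individual's
observed loci barely overlap another's.  Subspace PCA instead minimizes the
reconstruction error

    R = sum over observed (h, n, m) of (G^h_nm - (A S^T)_nm)^2

over a shared N x d score matrix A (one score vector per individual, fed by
both allele matrices G1 and G2) and an M x d loading matrix S, using only
observed entries.  At convergence A's columns are orthonormalized and S's
orthogonalized, so the factor pair spans the leading-PC subspace; on
complete data the result coincides with covariance-eigendecomposition PCA.

Two solvers are provided: alternating least squares (default; each
half-step solves the exact weighted normal equations, so R is monotonically
non-increasing) and explicit gradient descent with learning-rate
backtracking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .datamodel import DataModelError, standardize_columns
from .virtual_genomes import MaskedMatrixPair


@dataclass
class SsPcaConfig:
    d: int = 2
    solver: str = "als"            # "als" | "gradient"
    lam: float = 1e-3              # learning rate (gradient solver)
    max_iter: int = 500
    tol: float = 1e-8              # relative decrease of R for convergence
    seed: int = 0

    def __post_init__(self):
        if self.solver not in ("als", "gradient"):
            raise ValueError("solver must be 'als' or 'gradient'")
        if self.solver == "gradient" and self.lam <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class FactorModel:
    """Fitted factor pair with the column statistics needed for projection."""

    A: np.ndarray                 # N x d, orthonormal columns
    S: np.ndarray                 # M_kept x d, orthogonal columns
    R: float                      # reconstruction error over observed entries
    n_iter: int
    converged: bool
    singular_values: np.ndarray   # column norms of S after orthogonalization
    col_mean: np.ndarray          # over the original M columns
    col_scale: np.ndarray
    kept: np.ndarray              # boolean over original M columns
    R_history: np.ndarray = field(default_factory=lambda: np.array([]))


def _objective(X: np.ndarray, W: np.ndarray, A: np.ndarray, S: np.ndarray) -> float:
    P = A @ S.T
    return float(np.sum(W * (X - P) ** 2))


def _solve_rows(C: np.ndarray, rhs: np.ndarray, ridge: float = 1e-10) -> np.ndarray:
    """Batch-solve per-row d x d normal equations C[i] x = rhs[i]."""
    d = rhs.shape[1]
    C = C + ridge * np.eye(d)[None]
    return np.linalg.solve(C, rhs[:, :, None])[:, :, 0]


def _stack_pair(pair: MaskedMatrixPair):
    """Standardize G1/G2 per matrix, keep columns usable in both, stack weights."""
    s1 = standardize_columns(pair.G1)
    s2 = standardize_columns(pair.G2)
    kept = s1.kept & s2.kept
    X1, X2 = s1.matrix[:, kept], s2.matrix[:, kept]
    W1 = (~np.isnan(X1)).astype(float)
    W2 = (~np.isnan(X2)).astype(float)
    X1 = np.nan_to_num(X1)
    X2 = np.nan_to_num(X2)
    col_mean = np.where(kept, (s1.mean + s2.mean) / 2, np.nan)
    col_scale = np.where(kept, (s1.scale + s2.scale) / 2, np.nan)
    return X1, X2, W1, W2, kept, col_mean, col_scale


def fit_sspca(pair: MaskedMatrixPair, config: SsPcaConfig) -> FactorModel:
    """Fit the shared-score factor model to a masked matrix pair.

    Raises if ``d >= N`` or if any individual has no observed entries at all
    (such rows are unconstrained and must be excluded upstream).
    """
    N = pair.n_samples
    if config.d >= N:
        raise DataModelError(f"d={config.d} must be smaller than N={N}")
    X1, X2, W1, W2, kept, col_mean, col_scale = _stack_pair(pair)
    Mk = X1.shape[1]
    row_obs = W1.sum(axis=1) + W2.sum(axis=1)
    if np.any(row_obs == 0):
        bad = [pair.sample_ids[i] for i in np.flatnonzero(row_obs == 0)]
        raise DataModelError(f"individuals with no observed entries: {bad}")

    rng = np.random.default_rng(config.seed)
    d = config.d
    A = rng.standard_normal((N, d))
    Wsum = W1 + W2
    Xsum = X1 + X2                      # missing entries are zero, so W*X == X
    SXX = float(np.sum(X1 ** 2) + np.sum(X2 ** 2))

    def update_S(A):
        """Exact LS half-step for S; returns (S, R) via the normal-equation
        identity R = sum(w x^2) - sum(s_hat . rhs)."""
        AA = (A[:, :, None] * A[:, None, :]).reshape(N, d * d)
        C = (Wsum.T @ AA).reshape(Mk, d, d)
        rhs = Xsum.T @ A
        S = _solve_rows(C, rhs)
        return S, SXX - float(np.sum(S * rhs))

    def update_A(S):
        SS = (S[:, :, None] * S[:, None, :]).reshape(Mk, d * d)
        C = (Wsum @ SS).reshape(N, d, d)
        rhs = Xsum @ S
        A = _solve_rows(C, rhs)
        return A, SXX - float(np.sum(A * rhs))

    def objective(A, S):
        return (_objective(X1, W1, A, S) + _objective(X2, W2, A, S))

    S, R_prev = update_S(A)
    history = [R_prev]
    converged = False
    n_iter = 0
    lam = config.lam
    for n_iter in range(1, config.max_iter + 1):
        if config.solver == "als":
            A, R_half = update_A(S)
            history.append(R_half)
            S, R = update_S(A)
        else:
            # gradient step on both factors with backtracking on R
            E1 = W1 * (X1 - A @ S.T)
            E2 = W2 * (X2 - A @ S.T)
            gA = -2 * (E1 @ S + E2 @ S)
            gS = -2 * (E1.T @ A + E2.T @ A)
            while True:
                A_new, S_new = A - lam * gA, S - lam * gS
                R = objective(A_new, S_new)
                if R <= R_prev or lam < 1e-15:
                    break
                lam /= 2
            A, S = A_new, S_new
        history.append(R)
        if R_prev - R <= config.tol * max(R_prev, 1e-30):
            converged = True
            R_prev = R
            break
        R_prev = R

    # enforce the constraints: orthonormal A columns, orthogonal S columns
    Qa, Ra = np.linalg.qr(A)
    Qs, Rs = np.linalg.qr(S)
    U, sv, Vt = np.linalg.svd(Ra @ Rs.T)
    A = Qa @ U
    S = Qs @ Vt.T * sv
    return FactorModel(A=A, S=S, R=float(R_prev), n_iter=n_iter, converged=converged,
                       singular_values=sv, col_mean=col_mean, col_scale=col_scale,
                       kept=kept, R_history=np.asarray(history))


def pcs_from_factors(model: FactorModel):
    """PC scores (N x d) and loadings (M_kept x d) ordered by explained reconstruction.

    Sign convention: the largest-magnitude loading of each component is
    positive.
    """
    order = np.argsort(model.singular_values)[::-1]
    sv = model.singular_values[order]
    scores = (model.A * model.singular_values)[:, order]
    norms = np.linalg.norm(model.S, axis=0)
    norms[norms == 0] = 1.0
    loadings = (model.S / norms)[:, order]
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return scores, loadings


def project_onto_pcs(new_matrix: np.ndarray, model: FactorModel):
    """Project rows with missing entries onto the fitted subspace.

    Rows are standardized with the model's column statistics, then each row's
    observed entries are least-squares regressed on the loadings restricted
    to observed positions.  Rows with fewer than d observed entries are
    flagged and their scores set to NaN.

    Returns ``(scores, flagged_row_indices)``.
    """
    X = np.asarray(new_matrix, float)[:, model.kept]
    mean = model.col_mean[model.kept]
    scale = model.col_scale[model.kept]
    Z = (X - mean) / scale
    d = model.S.shape[1]
    _, loadings = pcs_from_factors(model)
    order = np.argsort(model.singular_values)[::-1]
    scores = np.full((Z.shape[0], d), np.nan)
    flagged = []
    for i in range(Z.shape[0]):
        obs = ~np.isnan(Z[i])
        if obs.sum() < d:
            flagged.append(i)
            continue
        B = model.S[obs]
        coef, *_ = np.linalg.lstsq(B, Z[i, obs], rcond=None)
        # coef expresses the row in the (un-normalized) S basis; convert to
        # PC-score scale: score_j = coef_j * ||S_j||, then reorder/sign-match
        sc = coef * np.linalg.norm(model.S, axis=0)
        sc = sc[order]
        # apply the same sign convention as pcs_from_factors
        norms = np.linalg.norm(model.S, axis=0)
        norms[norms == 0] = 1.0
        L = (model.S / norms)[:, order]
        for j in range(d):
            k = np.argmax(np.abs(L[:, j]))
            if L[k, j] < 0:
                sc[j] *= -1
        scores[i] = sc
    return scores, np.asarray(flagged, int)


def project_pair_onto_pcs(pair: MaskedMatrixPair, model: FactorModel):
    """Project a masked pair: each individual's two rows regressed jointly."""
    X1 = np.asarray(pair.G1, float)[:, model.kept]
    X2 = np.asarray(pair.G2, float)[:, model.kept]
    mean = model.col_mean[model.kept]
    scale = model.col_scale[model.kept]
    Z = np.concatenate([(X1 - mean) / scale, (X2 - mean) / scale], axis=1)
    S2 = np.concatenate([model.S, model.S], axis=0)
    d = model.S.shape[1]
    order = np.argsort(model.singular_values)[::-1]
    norms = np.linalg.norm(model.S, axis=0)
    norms[norms == 0] = 1.0
    L = (model.S / norms)[:, order]
    signs = np.array([1.0 if L[np.argmax(np.abs(L[:, j])), j] >= 0 else -1.0
                      for j in range(d)])
    scores = np.full((Z.shape[0], d), np.nan)
    flagged = []
    for i in range(Z.shape[0]):
        obs = ~np.isnan(Z[i])
        if obs.sum() < d:
            flagged.append(i)
            continue
        coef, *_ = np.linalg.lstsq(S2[obs], Z[i, obs], rcond=None)
        scores[i] = (coef * np.linalg.norm(model.S, axis=0))[order] * signs
    return scores, np.asarray(flagged, int)


@dataclass
class EvaluationResult:
    xi: float
    threshold: float
    polarity: int       # +1: group-a below threshold; -1: group-a above
    component: int = 0


def confusion_fraction(scores: np.ndarray, labels: np.ndarray,
                       component: int = 0) -> EvaluationResult:
    """Minimum misclassification fraction of the best single threshold.

    Scans every midpoint between sorted scores (and both polarities); the
    result lies in [0, 0.5].
    """
    scores = np.asarray(scores, float)
    if scores.ndim > 1:
        scores = scores[:, component]
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise DataModelError(f"confusion fraction needs exactly two groups, got {len(uniq)}")
    ga = labels == uniq[0]
    if ga.all() or (~ga).all():
        raise DataModelError("one group is empty")
    order = np.argsort(scores, kind="stable")
    s, g = scores[order], ga[order]
    n = len(s)
    # after cutting below position t (0..n): left side has cum_a[t] of group a
    cum_a = np.concatenate([[0], np.cumsum(g)])
    cum_b = np.arange(n + 1) - cum_a
    na, nb = g.sum(), n - g.sum()
    # polarity +1: a left / b right -> errors = a on right + b on left
    err_plus = (na - cum_a) + cum_b
    err_minus = cum_a + (nb - cum_b)
    cuts = np.concatenate([[s[0] - 1], (s[1:] + s[:-1]) / 2, [s[-1] + 1]])
    i_p, i_m = np.argmin(err_plus), np.argmin(err_minus)
    if err_plus[i_p] <= err_minus[i_m]:
        best, thr, pol = err_plus[i_p], cuts[i_p], +1
    else:
        best, thr, pol = err_minus[i_m], cuts[i_m], -1
    return EvaluationResult(xi=float(best) / n, threshold=float(thr),
                            polarity=pol, component=component)


def mask_error_sweep(panel, truth_track, target: str, group_labels: np.ndarray,
                     epsilons, replicates: int = 1, d: int = 2, seed: int = 0,
                     chrom: Optional[np.ndarray] = None):
    """Mean confusion fraction as a function of the mask error rate.

    For each epsilon and replicate: corrupt the true ancestry labels
    segment-wise, mask to the target ancestry, fit ssPCA, and score PC1
    against the known sub-population labels.  Returns a DataFrame with one
    row per epsilon (mean and per-replicate xi values).
    """
    import pandas as pd

    from .simulate import MaskCorruptionConfig, corrupt_ancestry_labels
    from .virtual_genomes import mask_to_virtual

    if chrom is None:
        chrom = panel.markers["chrom"].to_numpy()
    rows = []
    base = np.random.SeedSequence(seed)
    for eps in epsilons:
        xis = []
        for rep in range(replicates):
            sub_seed = int(base.spawn(1)[0].generate_state(1)[0] % (2**31))
            corrupted = corrupt_ancestry_labels(
                truth_track, MaskCorruptionConfig(epsilon=float(eps), seed=sub_seed),
                chrom=chrom)
            pair = mask_to_virtual(panel, corrupted, target)
            model = fit_sspca(pair, SsPcaConfig(d=d, seed=sub_seed))
            scores, _ = pcs_from_factors(model)
            xis.append(confusion_fraction(scores[:, 0], group_labels).xi)
        rows.append(dict(epsilon=float(eps), mean_xi=float(np.mean(xis)),
                         xis=list(map(float, xis))))
    return pd.DataFrame(rows)
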