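"""Group spatial ICA with dual-regression back-reconstruction.

The decomposition pipeline follows the temporal-concatenation group ICA
scheme: each subject's time x voxel matrix is reduced by PCA along time,
the reduced matrices are concatenated and reduced again to the model order
C with whitening, Infomax ICA estimates C spatially independent group maps,
ICASSO stabilizes the estimate by re-running ICA and clustering the pooled
estimates, and dual (spatial-temporal) regression back-reconstructs each
subject's temporal components TC and spatial components SC from the group
maps Y:

    step 1 (spatial regression):  TC = argmin || X - TC @ Y ||   over time
    step 2 (temporal regression): SC = argmin || X - TC @ SC ||  over voxels

both steps including an intercept. The model order can be estimated from
the data by the minimum description length (MDL) criterion on the
eigenspectrum of the temporally standardized covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform
from scipy.stats import skew


@dataclass
class BOLDRun:
    """One subject's masked 4D run as a time x voxel matrix.

    ``mask_index`` maps each column back into the 3D grid (flat indices),
    so maps can be re-embedded for NIfTI export.
    """

    data: np.ndarray          # (T, V)
    tr: float
    subject: str
    mask_index: np.ndarray | None = None
    shape3d: tuple[int, int, int] | None = None
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be time x voxel")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.mask_index is not None and len(self.mask_index) != self.data.shape[1]:
            raise ValueError("mask size does not match voxel count")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]


@dataclass
class GroupSpatialMaps:
    """Group-level spatial components Y (component x voxel)."""

    maps: np.ndarray
    component_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if not self.component_ids:
            self.component_ids = list(range(self.maps.shape[0]))

    @property
    def order(self) -> int:
        return self.maps.shape[0]


@dataclass
class SubjectDecomposition:
    """Per-subject temporal (T x C) and spatial (C x V) components."""

    temporal: np.ndarray
    spatial: np.ndarray
    subject: str = ""
    zscored: bool = False


@dataclass
class IcassoResult:
    maps: GroupSpatialMaps           # centrotype maps
    stability: np.ndarray            # per-component cluster quality in [0, 1]
    n_runs: int


# ---------------------------------------------------------------------------
# model order

def _standardize_time(data: np.ndarray) -> np.ndarray:
    """Remove each voxel's temporal mean and scale to unit SD."""
    out = data - data.mean(axis=0)
    sd = out.std(axis=0)
    sd[sd == 0] = 1.0
    return out / sd


def _demean_time(data: np.ndarray) -> np.ndarray:
    """Remove each voxel's temporal mean (variance structure preserved).

    Variance normalization would rescale the spatial maps voxel-wise and
    distort the linear mixing model, so the PCA path only demeans.
    """
    return data - data.mean(axis=0)


def estimate_order_mdl(runs: list[BOLDRun], max_order: int | None = None) -> int:
    """MDL model order from the eigenspectrum of the temporal covariance.

    The temporal covariance (T x T) of the standardized data is averaged
    across runs; voxels act as the i.i.d. samples. For candidate order m the
    description length balances the mismatch between geometric and
    arithmetic means of the trailing eigenvalues against a parameter-count
    penalty; the minimizing m is returned. Exactly low-rank data (trailing
    eigenvalues numerically zero) short-circuits to the numerical rank.
    """
    if not runs:
        raise ValueError("need at least one run")
    t_len = min(r.n_volumes for r in runs)
    n_samples = runs[0].n_voxels
    cov = np.zeros((t_len, t_len))
    for r in runs:
        x = _standardize_time(r.data[:t_len])
        cov += x @ x.T / r.n_voxels
    cov /= len(runs)
    eig = np.linalg.eigvalsh(cov)[::-1]
    eig = np.clip(eig, 0.0, None)
    p = eig.size
    if eig[0] <= 0:
        raise ValueError("degenerate covariance")
    rank = int(np.sum(eig > 1e-10 * eig[0]))
    if rank < 2:
        raise ValueError("covariance rank below 2")
    # voxel-wise demeaning always costs one temporal df (rank p-1 for full-
    # rank data); a rank further below that means exactly low-rank data
    if rank < p - 1:
        return rank
    eig = eig[:rank]
    log_eig = np.log(eig)
    p = rank
    cap = max_order if max_order is not None else p - 1
    cap = min(cap, p - 1)
    best_m, best_val = 1, np.inf
    for m in range(1, cap + 1):
        tail = eig[m:]
        g = np.exp(np.mean(log_eig[m:]))
        a = np.mean(tail)
        ll = -(p - m) * n_samples * np.log(g / a)
        penalty = 0.5 * m * (2 * p - m + 1) * np.log(n_samples)
        mdl = ll + penalty
        if mdl < best_val:
            best_val, best_m = mdl, m
    return best_m


# ---------------------------------------------------------------------------
# two-step PCA

@dataclass
class PCAReduction:
    """Whitened group matrix plus the operators used to build it."""

    reduced: np.ndarray            # (C, V) whitened
    subject_bases: list[np.ndarray]   # per-subject (C1, T) projection rows
    group_basis: np.ndarray        # (C, n_subjects * C1) second-step rows
    whitener: np.ndarray           # (C, C) applied after group projection
    dewhitener: np.ndarray


def _pca_rows(x: np.ndarray, k: int) -> np.ndarray:
    """Top-k principal directions of the row space of x (rows = time)."""
    xc = x - x.mean(axis=1, keepdims=True)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    return u[:, :k].T  # (k, T)


def two_step_pca(runs: list[BOLDRun], order: int,
                 subject_order: int | None = None) -> PCAReduction:
    """Subject-wise temporal PCA, concatenation, then group PCA + whitening.

    ``subject_order`` (C1) defaults to ceil(1.5 * order), clipped to the
    shortest run. The reduced matrix has unit covariance across its C rows.
    """
    if not runs:
        raise ValueError("need at least one run")
    c1 = subject_order or int(np.ceil(1.5 * order))
    c1 = min(c1, min(r.n_volumes for r in runs))
    if order > c1:
        raise ValueError(f"order {order} exceeds subject retention {c1}")
    reduced_subjects = []
    bases = []
    for r in runs:
        x = _demean_time(r.data)
        x = x - x.mean(axis=1, keepdims=True)   # spatial demean, rows sum to 0
        basis = _pca_rows(x, c1)          # (C1, T)
        reduced_subjects.append(basis @ x)  # (C1, V)
        bases.append(basis)
    # rows of basis @ x inherit zero spatial mean, so no further centering
    stacked = np.vstack(reduced_subjects)   # (n*C1, V)
    u, s, vt = np.linalg.svd(stacked, full_matrices=False)
    v = stacked.shape[1]
    keep = s[:order]
    if np.any(keep <= 0):
        raise ValueError("group data rank below requested order")
    group_basis = u[:, :order].T                      # (C, n*C1)
    sigma = keep / np.sqrt(v)                         # singular -> SD scale
    whitener = np.diag(1.0 / sigma)
    dewhitener = np.diag(sigma)
    reduced = whitener @ (group_basis @ stacked)      # (C, V), unit variance
    return PCAReduction(reduced=reduced, subject_bases=bases,
                        group_basis=group_basis, whitener=whitener,
                        dewhitener=dewhitener)


def retained_variance(runs: list[BOLDRun], red: PCAReduction) -> float:
    """Fraction of (standardized, concatenated) variance kept by both steps."""
    total = 0.0
    for r in runs:
        x = _demean_time(r.data)
        x = x - x.mean(axis=1, keepdims=True)
        total += np.sum(x * x)
    # the group-step singular values carry everything both steps kept
    second = np.sum((red.dewhitener @ red.reduced) ** 2)
    return float(second / total) if total else 0.0


# ---------------------------------------------------------------------------
# Infomax ICA

def infomax_ica(whitened: np.ndarray, seed: int | np.random.Generator = 0,
                learning_rate: float = 0.1, max_iter: int = 2000,
                tol: float = 1e-7, anneal: float = 0.5
                ) -> tuple[GroupSpatialMaps, np.ndarray, bool]:
    """Natural-gradient Infomax with a logistic nonlinearity.

    Maximizes the entropy of logistic-squashed outputs, which recovers
    supergaussian (sparse) sources such as localized spatial networks.
    Input rows must be whitened. The full-batch natural gradient

        dW = lr * (I + (1 - 2 * logistic(WX)) (WX)^T / n) W

    is iterated with step-halving whenever the update overshoots (weight
    blow-up), until the relative weight change falls below ``tol``.
    Returns ``(maps, unmixing, converged)``; each map is sign-flipped to
    positive skewness so the activation lobe is positive.
    """
    x = np.asarray(whitened, dtype=float)
    c, n = x.shape
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    # random orthonormal start: restarts differ genuinely, so ICASSO's
    # stability index reflects identifiability rather than a shared init
    w, _ = np.linalg.qr(rng.standard_normal((c, c)))
    lr = learning_rate
    eye = np.eye(c)
    converged = False
    for _ in range(max_iter):
        u = w @ x
        y = 1.0 / (1.0 + np.exp(-u))
        grad = (eye + (1.0 - 2.0 * y) @ u.T / n) @ w
        w_new = w + lr * grad
        if not np.all(np.isfinite(w_new)) or np.max(np.abs(w_new)) > 1e8:
            lr *= anneal          # overshoot: halve the step and retry
            if lr < 1e-12:
                break
            continue
        delta = np.max(np.abs(w_new - w)) / max(np.max(np.abs(w)), 1e-300)
        w = w_new
        if delta * lr < tol * lr or delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn("Infomax did not reach tolerance; returning best estimate")
    maps = w @ x
    signs = np.where(skew(maps, axis=1) < 0, -1.0, 1.0)
    maps = maps * signs[:, None]
    w = w * signs[:, None]
    return GroupSpatialMaps(maps=maps), w, converged


# ---------------------------------------------------------------------------
# ICASSO

def _abs_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    az = (a - a.mean(axis=1, keepdims=True))
    bz = (b - b.mean(axis=1, keepdims=True))
    az /= np.linalg.norm(az, axis=1, keepdims=True)
    bz /= np.linalg.norm(bz, axis=1, keepdims=True)
    return np.abs(az @ bz.T)


def icasso(whitened: np.ndarray, order: int, n_runs: int = 100,
           seed: int = 0, **infomax_kwargs) -> IcassoResult:
    """Stability analysis: re-run Infomax, cluster estimates, keep centrotypes.

    All ``n_runs`` estimates are pooled and clustered by average linkage on
    the (1 - |correlation|) distance, cut at ``order`` clusters. The
    centrotype of a cluster is its most central member (max summed
    within-cluster similarity); the stability index is mean within-cluster
    similarity minus mean similarity to estimates outside the cluster.
    """
    if n_runs < 1:
        raise ValueError("need at least one run")
    rng = np.random.default_rng(seed)
    estimates = []
    for _ in range(n_runs):
        maps, _, _ = infomax_ica(whitened, seed=rng, **infomax_kwargs)
        estimates.append(maps.maps)
    pooled = np.vstack(estimates)
    if n_runs == 1:
        return IcassoResult(maps=GroupSpatialMaps(maps=pooled),
                            stability=np.ones(order), n_runs=1)
    sim = _abs_corr(pooled, pooled)
    np.clip(sim, 0.0, 1.0, out=sim)
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(z, t=order, criterion="maxclust")
    if labels.max() < order:
        warnings.warn("estimates formed fewer clusters than components")
    centrotypes = []
    stability = []
    for lab in range(1, labels.max() + 1):
        members = np.where(labels == lab)[0]
        sub = sim[np.ix_(members, members)]
        centro_local = int(np.argmax(sub.sum(axis=1)))
        centrotypes.append(pooled[members[centro_local]])
        if members.size > 1:
            within = (sub.sum() - members.size) / (members.size * (members.size - 1))
        else:
            within = 1.0
        outside = np.setdiff1d(np.arange(pooled.shape[0]), members)
        between = sim[np.ix_(members, outside)].mean() if outside.size else 0.0
        stability.append(float(np.clip(within - between, 0.0, 1.0)))
    cent = np.array(centrotypes)
    signs = np.where(skew(cent, axis=1) < 0, -1.0, 1.0)
    cent = cent * signs[:, None]
    return IcassoResult(maps=GroupSpatialMaps(maps=cent),
                        stability=np.array(stability), n_runs=n_runs)


# ---------------------------------------------------------------------------
# dual regression

def dual_regression(run: BOLDRun, group_maps: GroupSpatialMaps,
                    intercept: bool = True) -> SubjectDecomposition:
    """Back-reconstruct subject components from group maps.

    Spatial regression of each volume on the maps yields TC; temporal
    regression of each voxel on TC yields SC. Both steps include an
    intercept column by default.
    """
    x = run.data
    y = group_maps.maps
    if y.shape[1] != x.shape[1]:
        raise ValueError("voxel dimensions of run and maps disagree")
    rank = np.linalg.matrix_rank(y)
    if rank < y.shape[0]:
        raise ValueError(f"group maps are rank deficient (rank {rank} of {y.shape[0]})")
    design_s = y.T                                   # (V, C)
    if intercept:
        design_s = np.column_stack([np.ones(x.shape[1]), design_s])
    coef_s, *_ = np.linalg.lstsq(design_s, x.T, rcond=None)
    tc = coef_s[1:].T if intercept else coef_s.T     # (T, C)
    design_t = tc
    if intercept:
        design_t = np.column_stack([np.ones(x.shape[0]), tc])
    coef_t, *_ = np.linalg.lstsq(design_t, x, rcond=None)
    sc = coef_t[1:] if intercept else coef_t         # (C, V)
    return SubjectDecomposition(temporal=tc, spatial=sc, subject=run.subject)


def zscore_components(dec: SubjectDecomposition) -> SubjectDecomposition:
    """Standardize every spatial row and temporal column to mean 0, SD 1."""
    sd_s = dec.spatial.std(axis=1)
    sd_t = dec.temporal.std(axis=0)
    if np.any(sd_s == 0):
        bad = list(np.where(sd_s == 0)[0])
        raise ValueError(f"zero-variance spatial component(s): {bad}")
    if np.any(sd_t == 0):
        bad = list(np.where(sd_t == 0)[0])
        raise ValueError(f"zero-variance temporal component(s): {bad}")
    spatial = (dec.spatial - dec.spatial.mean(axis=1, keepdims=True)) / sd_s[:, None]
    temporal = (dec.temporal - dec.temporal.mean(axis=0)) / sd_t
    return SubjectDecomposition(temporal=temporal, spatial=spatial,
                                subject=dec.subject, zscored=True)


def match_components(estimated: np.ndarray, truth: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Hungarian matching of estimated to reference maps by |correlation|.

    Returns ``(permutation, matched_abs_corr)`` where ``permutation[i]`` is
    the estimated row assigned to reference row i.
    """
    corr = _abs_corr(truth, estimated)
    rows, cols = linear_sum_assignment(-corr)
    return cols, corr[rows, cols]
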