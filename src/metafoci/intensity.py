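"""Posterior intensity maps, region signatures, NNMF, and the profile test.

The voxelwise intensity map is the posterior mean of the level-2
(study-center-generating) intensity times the voxel volume, so values are
expected centers *per voxel* and the map sums to the posterior mean
expected center count over the mask.  Region mean intensities per
retained MCMC state form the T x R matrix from which signatures,
co-activation and the nonparametric profile-difference test all derive.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls
from statsmodels.stats.multitest import multipletests

from .io_atlas import Atlas, BrainMask, GeometryError
from .mcmc import PosteriorSamples
from .model import MaskGeometry, study_center_intensity

log = logging.getLogger("metafoci")


@dataclass
class IntensityGrid:
    """Posterior mean expected centers per voxel, plus conservation info."""

    grid: object  # VoxelGrid
    values: np.ndarray  # full 3-D array, zero outside mask
    category: str
    n_states: int
    expected_count: float  # posterior mean of K*mu_cent + background
    quad_bound: float  # reported quadrature error bound on the voxel sum

    @property
    def total(self) -> float:
        return float(self.values.sum())


@dataclass
class IntensityMatrix:
    """T x R per-iteration region mean intensities (per-voxel scale)."""

    values: np.ndarray
    category: str
    region_names: list


@dataclass
class NNMFResult:
    W: np.ndarray
    H: np.ndarray
    error: float
    error_trace: np.ndarray  # per-ALS-iteration error of the winning start
    restarts: int
    k: int


def _subsample(states: list, max_states: int | None) -> list:
    if max_states is None or len(states) <= max_states:
        return states
    idx = np.linspace(0, len(states) - 1, max_states).round().astype(int)
    return [states[i] for i in idx]


def _voxel_intensity(state, centers_xyz, geom: MaskGeometry) -> np.ndarray:
    """Per-inside-voxel expected center count for one state."""
    dens = study_center_intensity(state, centers_xyz, geom)
    return dens * geom.grid.voxel_volume


def intensity_map(
    samples: PosteriorSamples,
    mask: BrainMask,
    category: str | None = None,
    max_states: int | None = None,
    geom: MaskGeometry | None = None,
) -> IntensityGrid:
    """Posterior mean intensity map on the mask's voxel grid.

    Averages the per-state level-2 intensity at every inside-voxel
    center (times voxel volume).  ``quad_bound`` is the accumulated
    grid-quadrature error of the per-center kernel masses, against which
    the conservation property (voxel sum vs analytic expected count) is
    asserted.
    """
    geom = geom or MaskGeometry(mask)
    states = _subsample(samples.states, max_states)
    vox = mask.voxel_centers()
    v = mask.grid.voxel_volume
    acc = np.zeros(len(vox))
    expected = 0.0
    bound = 0.0
    for state in states:
        w = state.weights
        k = state.population.n_centers
        expected += k * w.mu_cent + w.nu_bg_single + w.nu_bg_center
        if k:
            from .model import _center_log_kernel

            lk = _center_log_kernel(vox, state.population.centers,
                                    state.kernels.sigma_study, geom)
            per_center = np.exp(lk) * v  # (n_vox, K); each column sums ~1
            acc += w.mu_cent * per_center.sum(axis=1)
            bound += w.mu_cent * np.abs(per_center.sum(axis=0) - 1.0).sum()
        acc += (w.nu_bg_single + w.nu_bg_center) / geom.volume * v
    t = len(states)
    values = np.zeros(mask.grid.shape)
    values[mask.inside] = acc / t
    return IntensityGrid(
        mask.grid, values, category or samples.category, t,
        expected / t, bound / t + 1e-9,
    )


def region_intensity_matrix(
    samples: PosteriorSamples,
    atlas: Atlas,
    mask: BrainMask,
    category: str | None = None,
    max_states: int | None = None,
    geom: MaskGeometry | None = None,
) -> IntensityMatrix:
    """T x R matrix of per-state mean intensity per atlas region.

    Entry [t, r] is the mean over region-r voxels of state t's per-voxel
    expected center count.  Empty regions yield NaN columns (warned).
    """
    if not atlas.grid.matches(mask.grid):
        raise GeometryError("atlas and mask geometries differ")
    geom = geom or MaskGeometry(mask)
    states = _subsample(samples.states, max_states)
    inside = mask.inside
    labels = atlas.labels[inside]
    vox = mask.voxel_centers()
    r = atlas.n_regions
    counts = np.bincount(labels, minlength=r + 1)[1:]
    empty = counts == 0
    if empty.any():
        log.warning("atlas regions with no voxels: %s",
                    [atlas.names[i] for i in np.where(empty)[0]])
    out = np.empty((len(states), r))
    for t, state in enumerate(states):
        vals = _voxel_intensity(state, vox, geom)
        sums = np.bincount(labels, weights=vals, minlength=r + 1)[1:]
        with np.errstate(invalid="ignore"):
            out[t] = np.where(empty, np.nan, sums / np.maximum(counts, 1))
    return IntensityMatrix(out, category or samples.category, list(atlas.names))


def signature(matrix: IntensityMatrix | np.ndarray) -> np.ndarray:
    """Per-category mean-intensity signature: exact column means of M."""
    values = matrix.values if isinstance(matrix, IntensityMatrix) else np.asarray(matrix)
    if values.shape[0] == 0:
        raise ValueError("empty intensity matrix")
    return values.mean(axis=0)


# ---------------------------------------------------------------------------
# non-negative matrix factorization (alternating least squares)
# ---------------------------------------------------------------------------

def _als_half(A: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Solve min_{H >= 0} ||A - W H||_F columnwise (exact NNLS)."""
    k = W.shape[1]
    H = np.empty((k, A.shape[1]))
    for j in range(A.shape[1]):
        H[:, j], _ = nnls(W, A[:, j])
    return H


def nnmf(
    A: np.ndarray,
    k: int,
    restarts: int = 20,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> NNMFResult:
    """A ≈ W H with nonnegative factors, by alternating least squares.

    Each half-step solves the exact nonnegative least-squares problem,
    so the squared Frobenius error is non-increasing within every run.
    The best of ``restarts`` seeded random starts wins (ties to the
    lowest start index).  Rows of H are the canonical profiles; rows of
    W the per-category profile expressions.
    """
    A = np.asarray(A, dtype=float)
    if np.any(A < 0):
        raise ValueError("NNMF input must be nonnegative")
    if k < 1 or k > min(A.shape):
        raise ValueError(f"k must be in [1, {min(A.shape)}]")
    rng = np.random.default_rng(seed)
    best = None
    for r in range(restarts):
        W = rng.uniform(0.1, 1.0, size=(A.shape[0], k)) * math.sqrt(A.mean() / k + 1e-12)
        errs = []
        for _ in range(max_iter):
            H = _als_half(A, W)
            W = _als_half(A.T, H.T).T
            err = float(((A - W @ H) ** 2).sum())
            if errs and errs[-1] - err < tol * max(errs[-1], 1.0):
                errs.append(err)
                break
            errs.append(err)
        if best is None or errs[-1] < best.error:
            best = NNMFResult(W, H, errs[-1], np.asarray(errs), restarts, k)
    return best


# ---------------------------------------------------------------------------
# nonparametric profile-difference test + FDR
# ---------------------------------------------------------------------------

def profile_difference_test(
    m_i: IntensityMatrix | np.ndarray,
    m_j: IntensityMatrix | np.ndarray,
    subset=None,
) -> float:
    """Nonparametric P-value for a difference in region intensity profiles.

    With per-iteration matrices M_i, M_j (same T x R) and mean difference
    Mbar_d, count iterations whose per-region signs disagree with Mbar_d
    by s_t = sum_r |sign(M_i - M_j) - sign(Mbar_d)| >= R, and set
    P = min(1, (2^R / T) * count), the 2^R factor accounting for the
    quadrant in which the mean difference lies.  ``subset`` restricts the
    test to a set of region indices (or names), with R the subset size.
    sign(0) counts as 0, so boundary iterations contribute partially.
    """
    names = None
    if isinstance(m_i, IntensityMatrix):
        names = m_i.region_names
        m_i = m_i.values
    if isinstance(m_j, IntensityMatrix):
        m_j = m_j.values
    m_i = np.asarray(m_i, dtype=float)
    m_j = np.asarray(m_j, dtype=float)
    if m_i.shape != m_j.shape:
        raise ValueError("intensity matrices must have identical shape")
    if subset is not None:
        if names is not None and len(subset) and isinstance(next(iter(subset)), str):
            subset = [names.index(s) for s in subset]
        subset = list(subset)
        m_i = m_i[:, subset]
        m_j = m_j[:, subset]
    t, r = m_i.shape
    if t < 1 or r < 1:
        raise ValueError("need at least one iteration and one region")
    d_bar = np.sign(m_i.mean(axis=0) - m_j.mean(axis=0))
    s = np.abs(np.sign(m_i - m_j) - d_bar[None, :]).sum(axis=1)
    count = int((s >= r).sum())
    return float(min(1.0, (2.0 ** r / t) * count))


def fdr_adjust(pvalues, q: float = 0.05) -> tuple:
    """Benjamini–Hochberg step-up: returns (q-values, reject-at-q array)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return qvals, reject


def pairwise_profile_tests(matrices: dict, subset=None, q: float = 0.05) -> dict:
    """All C(C-1)/2 pairwise profile tests with FDR control at q."""
    cats = sorted(matrices)
    pairs = [(a, b) for i, a in enumerate(cats) for b in cats[i + 1:]]
    p = [profile_difference_test(matrices[a], matrices[b], subset=subset)
         for a, b in pairs]
    qvals, reject = fdr_adjust(p, q=q)
    return {
        pair: {"p": pv, "q": qv, "reject": bool(rj)}
        for pair, pv, qv, rj in zip(pairs, p, qvals, reject)
    }
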