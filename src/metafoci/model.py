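"""The three-level hierarchical cluster-process model of activation foci.

Level 3: latent *population centers* for one category follow a homogeneous
Poisson process with rate ``eta`` (centers per mm^3) on the brain mask B.
Level 2: per study, each population center spawns Poisson(``mu_cent``)
attached points, each of which is a *study activation center* with
probability ``q_study`` or a *singly reported focus* otherwise, scattered
isotropically N(center, sigma_study^2 I); uniform background study centers
and singly reported foci arrive at per-study rates ``nu_bg_center`` and
``nu_bg_single``.
Level 1: each study center emits 1 + Poisson(``mu_multi``) multiply
reported foci scattered N(study center, sigma_foci^2 I).

Only the union of foci is observed; the single/multiple mark, the
cluster structure and all parents are latent.  Gaussian kernels are
truncated to the mask: by rejection when simulating, and through a cached
normalizing-mass correction (smoothed-mask grid quadrature) in densities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, stats

from .io_atlas import BrainMask, voxel_to_world

LOG_2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# mask geometry helper (uniform sampling + truncation masses)
# ---------------------------------------------------------------------------

class MaskGeometry:
    """Computational companion of a BrainMask.

    Provides uniform sampling on the mask interior, inside tests, and the
    normalizing mass of an isotropic Gaussian restricted to the mask
    (evaluated by smoothing the mask indicator on its own grid and
    interpolating — i.e. grid quadrature, cached per kernel width).
    """

    def __init__(self, mask: BrainMask):
        self.mask = mask
        self.grid = mask.grid
        self.volume = mask.volume
        self._inside_idx = np.argwhere(mask.inside)
        aff = self.grid.affine
        self._zooms = np.linalg.norm(aff[:3, :3], axis=0)
        self._inv = np.linalg.inv(aff)
        self._mass_cache: dict = {}

    # -- sampling ----------------------------------------------------------
    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """n points uniform over the inside region (voxel + in-voxel offset)."""
        if n == 0:
            return np.empty((0, 3))
        pick = rng.integers(0, len(self._inside_idx), size=n)
        ijk = self._inside_idx[pick] + rng.uniform(-0.5, 0.5, size=(n, 3))
        return voxel_to_world(self.grid, ijk)

    def contains(self, points: np.ndarray) -> np.ndarray:
        return self.mask.contains(points)

    def sample_truncated_normal(
        self, center: np.ndarray, sigma: float, n: int, rng: np.random.Generator,
        max_tries: int = 200,
    ) -> np.ndarray:
        """n draws from N(center, sigma^2 I) conditioned on the mask, by rejection."""
        if n == 0:
            return np.empty((0, 3))
        out = np.empty((n, 3))
        have = 0
        for _ in range(max_tries):
            need = n - have
            cand = rng.normal(center, sigma, size=(max(2 * need, 8), 3))
            ok = cand[self.contains(cand)]
            take = min(len(ok), need)
            out[have : have + take] = ok[:take]
            have += take
            if have == n:
                return out
        raise RuntimeError(
            "rejection sampling failed: kernel mass on the mask is ~0 "
            f"(center {center}, sigma {sigma})"
        )

    # -- truncation masses -------------------------------------------------
    def _smoothed(self, sigma: float) -> np.ndarray:
        key = round(sigma * 2.0) / 2.0  # cache at 0.5 mm resolution
        if key not in self._mass_cache:
            sig_vox = max(key, 0.25) / self._zooms
            self._mass_cache[key] = ndimage.gaussian_filter(
                self.mask.inside.astype(float), sig_vox, mode="constant", truncate=6.0
            )
        return self._mass_cache[key]

    def trunc_mass(self, points: np.ndarray, sigma: float) -> np.ndarray:
        """Mass of N(p, sigma^2 I) on the mask, per point (clamped to (0,1])."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        vol = self._smoothed(sigma)
        ijk = (pts @ self._inv[:3, :3].T + self._inv[:3, 3]).T
        # 'nearest' clamps edge coordinates onto the grid; the smoothing
        # itself already encodes zero mass outside the mask
        vals = ndimage.map_coordinates(vol, ijk, order=1, mode="nearest")
        return np.clip(vals, 1e-6, 1.0)


# ---------------------------------------------------------------------------
# parameter blocks
# ---------------------------------------------------------------------------

@dataclass
class ClusterKernels:
    """Isotropic Gaussian scatter scales, in mm."""

    sigma_study: float  # study centers / singly reported foci about population centers
    sigma_foci: float   # multiply reported foci about study centers

    def __post_init__(self):
        if self.sigma_study <= 0 or self.sigma_foci <= 0:
            raise ValueError("kernel scales must be positive")
        if self.sigma_foci > self.sigma_study:
            import logging

            logging.getLogger("metafoci").warning(
                "sigma_foci (%.3g) exceeds sigma_study (%.3g): unusual but allowed",
                self.sigma_foci, self.sigma_study,
            )


@dataclass
class MixtureWeights:
    """Offspring rates and background rates of the cluster process.

    ``mu_cent``: mean attached points (study centers + singly reported
    foci) per population center per study; ``q_study``: probability an
    attached point is a study center; ``mu_multi``: mean extra foci per
    study center (counts are 1 + Poisson); ``nu_bg_single`` and
    ``nu_bg_center``: expected uniform background singly reported foci and
    study centers per study.  The implied marginal background
    probabilities given the current number of centers K are exposed as
    ``p_bg_single(K)`` / ``p_bg_center(K)``.
    """

    mu_cent: float
    mu_multi: float
    q_study: float = 0.5
    nu_bg_single: float = 1.0
    nu_bg_center: float = 0.5

    def __post_init__(self):
        if self.mu_cent <= 0 or self.mu_multi <= 0:
            raise ValueError("offspring means must be positive")
        if not 0.0 <= self.q_study <= 1.0:
            raise ValueError("q_study must lie in [0, 1]")
        if self.nu_bg_single < 0 or self.nu_bg_center < 0:
            raise ValueError("background rates must be nonnegative")

    def p_bg_single(self, n_centers: int) -> float:
        att = n_centers * self.mu_cent * (1.0 - self.q_study)
        tot = att + self.nu_bg_single
        return 1.0 if tot == 0 else self.nu_bg_single / tot

    def p_bg_center(self, n_centers: int) -> float:
        att = n_centers * self.mu_cent * self.q_study
        tot = att + self.nu_bg_center
        return 1.0 if tot == 0 else self.nu_bg_center / tot


@dataclass
class PopulationProcess:
    """Homogeneous Poisson population-center process: rate + realized centers."""

    eta: float  # centers per mm^3
    centers: np.ndarray  # (K, 3) world mm

    def __post_init__(self):
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 3)

    @property
    def n_centers(self) -> int:
        return self.centers.shape[0]


@dataclass
class StudyLatents:
    """Latent structure of one study under the current state.

    ``mark``: per focus, 0 = singly reported, 1 = multiply reported.
    ``cluster``: per focus, index into ``cluster_loc`` (−1 for singles).
    ``single_parent``: per focus, population-center index (−1 background,
    only meaningful where mark == 0).
    ``cluster_loc``: (C, 3) instantiated study-center locations;
    ``cluster_parent``: per cluster, population-center index or −1.
    """

    mark: np.ndarray
    cluster: np.ndarray
    single_parent: np.ndarray
    cluster_loc: np.ndarray
    cluster_parent: np.ndarray

    @property
    def n_clusters(self) -> int:
        return self.cluster_loc.shape[0]

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(
            self.cluster[self.cluster >= 0], minlength=self.n_clusters
        )


@dataclass
class ModelState:
    """All parameters (lambda) of one category's model, plus latents if tracked."""

    population: PopulationProcess
    kernels: ClusterKernels
    weights: MixtureWeights
    latents: list | None = None  # list of StudyLatents, aligned with the data

    def clone_globals(self) -> "ModelState":
        return ModelState(
            PopulationProcess(self.population.eta, self.population.centers.copy()),
            replace(self.kernels),
            replace(self.weights),
            None,
        )


@dataclass
class Priors:
    """Weakly informative priors at MNI brain scale (all overridable).

    Gamma(a, rate b) on eta, the mu terms and background rates;
    inverse-Gamma(a, scale b) on the squared kernel scales (mm^2);
    Beta on the study-center share q.
    """

    a_eta: float = 1.0
    b_eta: float | None = None  # default |B| (≈ one expected center a priori)
    a_var: float = 3.0
    b_var: float = 200.0
    a_mu: float = 2.0
    b_mu: float = 1.0
    a_bg: float = 1.0
    b_bg: float = 0.5
    a_q: float = 1.0
    b_q: float = 1.0

    def with_volume(self, volume: float) -> "Priors":
        if self.b_eta is not None:
            return self
        return replace(self, b_eta=float(volume))


# ---------------------------------------------------------------------------
# density pieces
# ---------------------------------------------------------------------------

def iso_normal_logpdf(sq_dist, sigma: float):
    """log of the 3-D isotropic normal density at squared distance sq_dist."""
    s2 = sigma * sigma
    return -1.5 * (LOG_2PI + math.log(s2)) - np.asarray(sq_dist) / (2.0 * s2)


def _center_log_kernel(points, centers, sigma, geom: MaskGeometry):
    """(n_points, K) log of mask-truncated N(point; center, sigma^2 I)."""
    pts = np.atleast_2d(points)
    if centers.shape[0] == 0:
        return np.empty((pts.shape[0], 0))
    d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    logk = iso_normal_logpdf(d2, sigma)
    mass = geom.trunc_mass(centers, sigma)
    return logk - np.log(mass)[None, :]


def level2_log_intensity(state: ModelState, points, geom: MaskGeometry,
                         kind: str) -> np.ndarray:
    """Log marginal (over parents) intensity of the level-2 streams.

    ``kind``: "single" for singly reported foci, "center" for study
    centers.  The intensity is the Poisson-mixture sum over attached
    streams (one per population center) plus the uniform background term.
    """
    w, k = state.weights, state.kernels
    if kind == "single":
        rate_att = w.mu_cent * (1.0 - w.q_study)
        rate_bg = w.nu_bg_single
    else:
        rate_att = w.mu_cent * w.q_study
        rate_bg = w.nu_bg_center
    pts = np.atleast_2d(points)
    bg = rate_bg / geom.volume
    if state.population.n_centers == 0 or rate_att == 0.0:
        return np.full(pts.shape[0], -np.inf if bg == 0 else math.log(bg))
    logk = _center_log_kernel(pts, state.population.centers, k.sigma_study, geom)
    m = np.max(logk, axis=1)
    s = rate_att * np.exp(logk - m[:, None]).sum(axis=1)
    return m + np.log(s + bg * np.exp(-m))


def study_center_intensity(state: ModelState, points, geom: MaskGeometry) -> np.ndarray:
    """Conditional intensity of the level-2 point process at world points.

    Sum over population centers of mu_cent x truncated N(p; c_j,
    sigma_study^2 I) plus the total level-2 background rate / |B|;
    expected level-2 points per mm^3 per study.  Its integral over the
    mask is K mu_cent + nu_bg_single + nu_bg_center.
    """
    w = state.weights
    pts = np.atleast_2d(points)
    bg = (w.nu_bg_single + w.nu_bg_center) / geom.volume
    out = np.full(pts.shape[0], bg)
    if state.population.n_centers:
        logk = _center_log_kernel(
            pts, state.population.centers, state.kernels.sigma_study, geom
        )
        out = out + w.mu_cent * np.exp(logk).sum(axis=1)
    return out


def expected_foci_per_study(state: ModelState) -> float:
    """Closed-form expected number of observed foci per study."""
    w = state.weights
    k = state.population.n_centers
    per_sc = 1.0 + w.mu_multi
    return (
        k * w.mu_cent * (1.0 - w.q_study)
        + k * w.mu_cent * w.q_study * per_sc
        + w.nu_bg_single
        + w.nu_bg_center * per_sc
    )


def study_log_predictive(state: ModelState, foci, geom: MaskGeometry) -> float:
    """Collapsed marginal log density of a study's foci given lambda.

    The foci are treated as an inhomogeneous Poisson process with the
    marginal focus intensity (population-center mixture for singly
    reported foci, the sigma_study/sigma_foci convolution kernel for
    multiply reported foci, and the uniform background), which drops the
    within-cluster dependence of multiply reported foci.  This is the
    density used in posterior-predictive classification.
    """
    w, kern = state.weights, state.kernels
    per_sc = 1.0 + w.mu_multi
    total = expected_foci_per_study(state)
    foci = np.atleast_2d(foci)
    if foci.shape[0] == 0:
        return -total
    bg = (w.nu_bg_single + w.nu_bg_center * per_sc) / geom.volume
    lam = np.full(foci.shape[0], bg)
    if state.population.n_centers:
        centers = state.population.centers
        lk_single = _center_log_kernel(foci, centers, kern.sigma_study, geom)
        sig_conv = math.sqrt(kern.sigma_study ** 2 + kern.sigma_foci ** 2)
        lk_multi = _center_log_kernel(foci, centers, sig_conv, geom)
        lam = (
            lam
            + w.mu_cent * (1.0 - w.q_study) * np.exp(lk_single).sum(axis=1)
            + w.mu_cent * w.q_study * per_sc * np.exp(lk_multi).sum(axis=1)
        )
    if np.any(lam <= 0):
        return -np.inf
    return float(-total + np.log(lam).sum())


def log_complete_density(state: ModelState, foci, latents: StudyLatents,
                         geom: MaskGeometry) -> float:
    """Complete-data log density of one study given lambda and its latents.

    Janossy form: exp(-total level-2 rate) x the stream intensity at each
    level-2 point (attached points carry the truncated Gaussian kernel,
    background points 1/|B|), times per-cluster count terms
    Poisson(m-1; mu_multi) * m! and the foci kernels about their study
    centers.
    """
    w, kern = state.weights, state.kernels
    K = state.population.n_centers
    centers = state.population.centers
    foci = np.atleast_2d(foci)
    total_rate = K * w.mu_cent + w.nu_bg_single + w.nu_bg_center
    logp = -total_rate

    single = latents.mark == 0
    # singly reported foci
    for i in np.where(single)[0]:
        j = latents.single_parent[i]
        if j < 0:
            if w.nu_bg_single == 0:
                return -np.inf
            logp += math.log(w.nu_bg_single / geom.volume)
        else:
            if j >= K or w.mu_cent * (1 - w.q_study) == 0:
                return -np.inf
            lk = _center_log_kernel(foci[i], centers[j : j + 1], kern.sigma_study, geom)
            logp += math.log(w.mu_cent * (1.0 - w.q_study)) + float(lk[0, 0])

    # study centers and their foci
    sizes = latents.cluster_sizes()
    for c in range(latents.n_clusters):
        m = int(sizes[c])
        if m < 1:
            return -np.inf  # a study center always yields >= 1 focus
        s = latents.cluster_loc[c]
        j = latents.cluster_parent[c]
        if j < 0:
            if w.nu_bg_center == 0:
                return -np.inf
            logp += math.log(w.nu_bg_center / geom.volume)
        else:
            if j >= K or w.mu_cent * w.q_study == 0:
                return -np.inf
            lk = _center_log_kernel(s, centers[j : j + 1], kern.sigma_study, geom)
            logp += math.log(w.mu_cent * w.q_study) + float(lk[0, 0])
        logp += stats.poisson.logpmf(m - 1, w.mu_multi) + math.lgamma(m + 1)
        members = foci[latents.cluster == c]
        d2 = ((members - s[None, :]) ** 2).sum(axis=1)
        logp += float(iso_normal_logpdf(d2, kern.sigma_foci).sum())

    return float(logp)


def log_prior(state: ModelState, priors: Priors, geom: MaskGeometry) -> float:
    """Log prior density of the global parameters (−inf off support)."""
    pr = priors.with_volume(geom.volume)
    w, kern, pop = state.weights, state.kernels, state.population
    if kern.sigma_study <= 0 or kern.sigma_foci <= 0:
        return -np.inf
    vals = [
        stats.gamma.logpdf(pop.eta, pr.a_eta, scale=1.0 / pr.b_eta),
        stats.invgamma.logpdf(kern.sigma_study ** 2, pr.a_var, scale=pr.b_var),
        stats.invgamma.logpdf(kern.sigma_foci ** 2, pr.a_var, scale=pr.b_var),
        stats.gamma.logpdf(w.mu_cent, pr.a_mu, scale=1.0 / pr.b_mu),
        stats.gamma.logpdf(w.mu_multi, pr.a_mu, scale=1.0 / pr.b_mu),
        stats.gamma.logpdf(w.nu_bg_single, pr.a_bg, scale=1.0 / pr.b_bg),
        stats.gamma.logpdf(w.nu_bg_center, pr.a_bg, scale=1.0 / pr.b_bg),
        stats.beta.logpdf(w.q_study, pr.a_q, pr.b_q),
    ]
    tot = float(np.sum(vals))
    return tot if np.isfinite(tot) else -np.inf


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------

def simulate_study(state: ModelState, geom: MaskGeometry,
                   rng: np.random.Generator) -> tuple:
    """Draw one study's foci (and the latent truth) from the model.

    Returns ``(foci, truth)`` where ``foci`` is an (n, 3) array (possibly
    empty) and ``truth`` a StudyLatents describing marks, clusters and
    parents.  All scattered points are truncated to the mask by rejection.
    """
    if rng is None:
        raise ValueError("an explicit numpy Generator is required")
    w, kern = state.weights, state.kernels
    centers = state.population.centers

    single_pts, single_par = [], []
    sc_loc, sc_par = [], []
    for j, c in enumerate(centers):
        n_att = rng.poisson(w.mu_cent)
        if n_att == 0:
            continue
        is_sc = rng.random(n_att) < w.q_study
        pts = geom.sample_truncated_normal(c, kern.sigma_study, n_att, rng)
        for p, sc in zip(pts, is_sc):
            if sc:
                sc_loc.append(p)
                sc_par.append(j)
            else:
                single_pts.append(p)
                single_par.append(j)
    for p in geom.sample_uniform(rng.poisson(w.nu_bg_single), rng):
        single_pts.append(p)
        single_par.append(-1)
    for p in geom.sample_uniform(rng.poisson(w.nu_bg_center), rng):
        sc_loc.append(p)
        sc_par.append(-1)

    foci, mark, cluster, sparent = [], [], [], []
    for p, j in zip(single_pts, single_par):
        foci.append(p)
        mark.append(0)
        cluster.append(-1)
        sparent.append(j)
    for cidx, s in enumerate(sc_loc):
        m = 1 + rng.poisson(w.mu_multi)
        for p in geom.sample_truncated_normal(s, kern.sigma_foci, m, rng):
            foci.append(p)
            mark.append(1)
            cluster.append(cidx)
            sparent.append(-1)

    foci = np.asarray(foci, dtype=float).reshape(-1, 3)
    truth = StudyLatents(
        mark=np.asarray(mark, dtype=int),
        cluster=np.asarray(cluster, dtype=int),
        single_parent=np.asarray(sparent, dtype=int),
        cluster_loc=np.asarray(sc_loc, dtype=float).reshape(-1, 3),
        cluster_parent=np.asarray(sc_par, dtype=int),
    )
    return foci, truth
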