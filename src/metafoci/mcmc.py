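"""Posterior simulation for one category's model.

The sampler is Metropolis-within-Gibbs over

* focus-level marks and cluster memberships (sequential Gibbs with the
  study-center locations of existing clusters instantiated and the
  location of a newly created cluster integrated out in closed form),
* study-center locations and parents (conjugate Gaussian draws),
* global parameters (conjugate draws given auxiliary parent labels;
  the sigma_study draw is Metropolis-corrected for the mask-truncation
  masses),
* population-center locations (random-walk Metropolis, 4 mm default),
* the number of population centers (discrete-time birth–death
  Metropolis–Hastings, uniform birth location on the mask, uniform
  death choice).

Center moves evaluate the likelihood with the level-2 parent labels
marginalized analytically (a Poisson-mixture marginal).  Parent labels
are therefore not part of the chain state: they are re-drawn every sweep
as auxiliary variables for the conjugate updates and discarded.  Without
this marginalization a birth can essentially never be accepted (it is
penalized by exp(-n_studies * mu_cent) before any focus can re-attach),
and the number of centers would not mix.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

from .model import (
    ClusterKernels,
    MaskGeometry,
    MixtureWeights,
    ModelState,
    PopulationProcess,
    Priors,
    iso_normal_logpdf,
    _center_log_kernel,
)

log = logging.getLogger("metafoci")


@dataclass
class MCMCConfig:
    """Chain length and proposal settings.

    ``n_retained`` = (n_iter - burn_in) / thinning must be exact.  The
    default desk-scale configuration retains 5,000 states; analyses at
    the reference scale retain 10,000.
    """

    n_iter: int = 6000
    burn_in: int = 1000
    thinning: int = 1
    bd_substeps: int = 10
    proposal_scale: float = 4.0  # mm, center random walk
    seed: int = 0

    def __post_init__(self):
        if self.n_iter <= 0 or self.burn_in < 0 or self.thinning <= 0:
            raise ValueError("chain lengths must be positive")
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if (self.n_iter - self.burn_in) % self.thinning:
            raise ValueError("(n_iter - burn_in) must be divisible by thinning")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thinning


@dataclass
class PosteriorSamples:
    """Retained posterior states for one category."""

    category: str
    states: list  # ModelState snapshots (globals + centers)
    k_trace: np.ndarray  # K at every iteration (incl. burn-in)
    logpost_trace: np.ndarray
    counters: dict
    config: MCMCConfig
    seed: int

    @property
    def n_samples(self) -> int:
        return len(self.states)

    def k_values(self) -> np.ndarray:
        return np.array([s.population.n_centers for s in self.states])


class _Study:
    """Mutable latent bookkeeping for one study during sampling."""

    __slots__ = ("foci", "mark", "cl_id", "clusters", "next_id")

    def __init__(self, foci: np.ndarray):
        self.foci = np.atleast_2d(foci)
        n = self.foci.shape[0]
        self.mark = np.zeros(n, dtype=int)  # start: all singly reported
        self.cl_id = np.full(n, -1, dtype=int)
        self.clusters: dict = {}  # id -> dict(loc, count, sum, parent)
        self.next_id = 0

    def new_cluster(self, loc, parent) -> int:
        cid = self.next_id
        self.next_id += 1
        self.clusters[cid] = {
            "loc": np.asarray(loc, dtype=float),
            "count": 0,
            "sum": np.zeros(3),
            "parent": int(parent),
        }
        return cid

    def attach(self, i: int, cid: int):
        self.mark[i] = 1
        self.cl_id[i] = cid
        c = self.clusters[cid]
        c["count"] += 1
        c["sum"] = c["sum"] + self.foci[i]

    def detach(self, i: int):
        cid = self.cl_id[i]
        if cid >= 0:
            c = self.clusters[cid]
            c["count"] -= 1
            c["sum"] = c["sum"] - self.foci[i]
            if c["count"] == 0:
                del self.clusters[cid]
        self.mark[i] = 0
        self.cl_id[i] = -1


class CategorySampler:
    """Markov chain for one category's foci."""

    def __init__(
        self,
        foci_list: list,
        geom: MaskGeometry,
        priors: Priors,
        config: MCMCConfig,
        rng: np.random.Generator | None = None,
        init_state: ModelState | None = None,
    ):
        if not foci_list:
            raise ValueError("a category needs at least one study")
        self.geom = geom
        self.priors = priors.with_volume(geom.volume)
        self.config = config
        self.rng = rng if rng is not None else np.random.default_rng(config.seed)
        self.studies = [_Study(f) for f in foci_list]
        self.n_studies = len(self.studies)
        n_out = sum(int((~geom.contains(s.foci)).sum()) for s in self.studies)
        if n_out:
            # kept, not dropped: the uniform background term absorbs them
            log.warning("%d foci fall outside the mask; they will be "
                        "attributed to the background component", n_out)
        self.counters = {
            "birth_prop": 0, "birth_acc": 0,
            "death_prop": 0, "death_acc": 0,
            "move_prop": 0, "move_acc": 0,
            "sigma_rej": 0,
        }
        if init_state is None:
            self._default_init()
            self._init_latents()
        else:
            self.set_state(init_state)
            if init_state.latents is None:
                self._init_latents()

    # -- state access ------------------------------------------------------

    def _default_init(self):
        pr = self.priors
        pooled = np.vstack([s.foci for s in self.studies])
        # expected foci per center per study at the initial globals; the
        # 0.7 factor discounts anticipated uniform clutter
        f_bar = pooled.shape[0] / self.n_studies
        per_center = 2.0 * (1.0 + 0.5 * 2.0)
        k0 = int(np.clip(round(0.7 * f_bar / per_center), 1, min(30, len(pooled))))
        km = KMeans(n_clusters=k0, n_init=1, random_state=int(self.rng.integers(2**31)))
        centers = km.fit(pooled).cluster_centers_
        self.eta = pr.a_eta / pr.b_eta
        self.centers = np.asarray(centers, dtype=float)
        self.sig_st = 10.0
        self.sig_f = 5.0
        self.mu_c = pr.a_mu / pr.b_mu
        self.mu_m = pr.a_mu / pr.b_mu
        self.q = 0.5
        self.nu_s = 1.0
        self.nu_c = 0.5

    def _init_latents(self):
        """Seed the latent structure by single-linkage grouping of each
        study's foci at scale ~sigma_foci: tight groups start as clusters
        (multiply reported), isolated foci as singles.  This only sets
        the chain's starting point; the trap it avoids is the q -> 0
        feedback loop of an all-singles start."""
        from scipy.cluster.hierarchy import fcluster, linkage

        link_r = 2.0 * self.sig_f
        for st in self.studies:
            n = st.foci.shape[0]
            if n == 1:
                continue
            lab = fcluster(linkage(st.foci, method="single"), link_r,
                           criterion="distance")
            for g in np.unique(lab):
                idx = np.where(lab == g)[0]
                if len(idx) < 2:
                    continue
                loc = st.foci[idx].mean(axis=0)
                cid = st.new_cluster(loc, -1)
                for i in idx:
                    st.attach(i, cid)

    def get_state(self) -> ModelState:
        return ModelState(
            PopulationProcess(self.eta, self.centers.copy()),
            ClusterKernels(self.sig_st, self.sig_f),
            MixtureWeights(self.mu_c, self.mu_m, self.q, self.nu_s, self.nu_c),
        )

    def set_state(self, state: ModelState):
        self.eta = state.population.eta
        self.centers = state.population.centers.copy()
        self.sig_st = state.kernels.sigma_study
        self.sig_f = state.kernels.sigma_foci
        self.mu_c = state.weights.mu_cent
        self.mu_m = state.weights.mu_multi
        self.q = state.weights.q_study
        self.nu_s = state.weights.nu_bg_single
        self.nu_c = state.weights.nu_bg_center
        if state.latents is not None:
            for st, lat in zip(self.studies, state.latents):
                st.mark = lat.mark.copy()
                st.cl_id = np.full(len(st.mark), -1, dtype=int)
                st.clusters = {}
                st.next_id = 0
                remap = {}
                for c in range(lat.n_clusters):
                    remap[c] = st.new_cluster(lat.cluster_loc[c], lat.cluster_parent[c])
                for i in range(len(st.mark)):
                    if lat.mark[i] == 1:
                        st.attach(i, remap[int(lat.cluster[i])])

    # -- focus-level Gibbs -------------------------------------------------

    def _study_static_weights(self, st: _Study):
        """Parent-marginalized option weights that do not depend on clusters."""
        K = self.centers.shape[0]
        vol = self.geom.volume
        sig_eff = math.sqrt(self.sig_st**2 + self.sig_f**2)
        if K:
            lk1 = _center_log_kernel(st.foci, self.centers, self.sig_st, self.geom)
            lk2 = _center_log_kernel(st.foci, self.centers, sig_eff, self.geom)
            e1 = self.mu_c * (1.0 - self.q) * np.exp(lk1)  # (n, K)
            e2 = self.mu_c * self.q * np.exp(lk2)
        else:
            e1 = np.zeros((st.foci.shape[0], 0))
            e2 = np.zeros((st.foci.shape[0], 0))
        w_single = e1.sum(axis=1) + self.nu_s / vol
        w_new_by_parent = np.concatenate(
            [e2, np.full((st.foci.shape[0], 1), self.nu_c / vol)], axis=1
        )
        w_new = math.exp(-self.mu_m) * w_new_by_parent.sum(axis=1)
        return w_single, w_new, w_new_by_parent, e1

    def assignment_log_weights(self, st: _Study, i: int, statics=None):
        """Full-conditional (unnormalized) weights for focus i's options.

        Returns ``(labels, weights)`` with labels "single", ("cluster",
        cid) for each existing cluster, and "new".  The focus must be
        detached before calling (sampling handles this).
        """
        if statics is None:
            statics = self._study_static_weights(st)
        w_single, w_new, _, _ = statics
        labels = ["single"]
        weights = [w_single[i]]
        f = st.foci[i]
        for cid, c in st.clusters.items():
            m = c["count"]
            d2 = float(((f - c["loc"]) ** 2).sum())
            kern = math.exp(iso_normal_logpdf(d2, self.sig_f))
            weights.append(kern * self.mu_m * (m + 1) / m)
            labels.append(("cluster", cid))
        labels.append("new")
        weights.append(w_new[i])
        return labels, np.asarray(weights)

    def _draw_new_cluster(self, st: _Study, i: int, w_new_by_parent):
        """Create a singleton cluster for focus i: draw its parent then
        its location from the conjugate Gaussian conditional."""
        w = w_new_by_parent[i]
        parent = int(self.rng.choice(len(w), p=w / w.sum())) if w.sum() > 0 else len(w) - 1
        K = self.centers.shape[0]
        f = st.foci[i]
        if parent == K:
            parent = -1
            mean, var = f, self.sig_f**2
        else:
            prec = 1.0 / self.sig_st**2 + 1.0 / self.sig_f**2
            mean = (self.centers[parent] / self.sig_st**2 + f / self.sig_f**2) / prec
            var = 1.0 / prec
        loc = self._draw_location(mean, math.sqrt(var))
        return st.new_cluster(loc, parent)

    def _draw_location(self, mean, sd):
        """Gaussian draw kept on the mask (few rejection tries, then snap)."""
        for _ in range(10):
            cand = self.rng.normal(mean, sd, size=3)
            if self.geom.contains(cand)[0]:
                return cand
        if self.geom.contains(mean)[0]:
            return np.asarray(mean, dtype=float)
        idx = self.geom._inside_idx
        from .io_atlas import voxel_to_world

        centers = voxel_to_world(self.geom.grid, idx)
        return centers[np.argmin(((centers - mean) ** 2).sum(axis=1))]

    def update_assignments(self):
        """Sequential Gibbs over every focus's mark / membership."""
        for st in self.studies:
            statics = self._study_static_weights(st)
            _, _, w_new_by_parent, _ = statics
            for i in range(st.foci.shape[0]):
                st.detach(i)
                labels, w = self.assignment_log_weights(st, i, statics)
                tot = w.sum()
                if not np.isfinite(tot) or tot <= 0:
                    choice = "single"  # pathological: park in background
                else:
                    choice = labels[int(self.rng.choice(len(w), p=w / tot))]
                if choice == "single":
                    pass
                elif choice == "new":
                    st.attach(i, self._draw_new_cluster(st, i, w_new_by_parent))
                else:
                    st.attach(i, choice[1])

    # -- cluster refresh + auxiliary parents -------------------------------

    def _refresh_clusters(self):
        """Resample each cluster's parent (collapsed over its location)
        and then its location from the Gaussian full conditional."""
        K = self.centers.shape[0]
        vol = self.geom.volume
        for st in self.studies:
            for c in st.clusters.values():
                m = c["count"]
                xbar = c["sum"] / m
                sig_m = math.sqrt(self.sig_st**2 + self.sig_f**2 / m)
                w = []
                if K:
                    lk = _center_log_kernel(xbar, self.centers, sig_m, self.geom)[0]
                    w = list(self.mu_c * self.q * np.exp(lk))
                w.append(self.nu_c / vol)
                w = np.asarray(w)
                pick = int(self.rng.choice(len(w), p=w / w.sum())) if w.sum() > 0 else K
                c["parent"] = -1 if pick == K else pick
                prec = m / self.sig_f**2
                mean_num = c["sum"] / self.sig_f**2
                if c["parent"] >= 0:
                    prec += 1.0 / self.sig_st**2
                    mean_num = mean_num + self.centers[c["parent"]] / self.sig_st**2
                c["loc"] = self._draw_location(mean_num / prec, math.sqrt(1.0 / prec))

    def _draw_single_parents(self):
        """Auxiliary parent labels for singly reported foci; returns
        sufficient statistics for the conjugate global updates."""
        K = self.centers.shape[0]
        vol = self.geom.volume
        n_att_j = np.zeros(K)
        ssd_att = 0.0
        n_bg_single = 0
        n_att_single = 0
        for st in self.studies:
            idx = np.where(st.mark == 0)[0]
            if len(idx) == 0:
                continue
            if K == 0:
                n_bg_single += len(idx)
                continue
            f = st.foci[idx]
            lk = _center_log_kernel(f, self.centers, self.sig_st, self.geom)
            w = self.mu_c * (1.0 - self.q) * np.exp(lk)
            w = np.concatenate([w, np.full((len(idx), 1), self.nu_s / vol)], axis=1)
            # vectorized categorical draws (Gumbel-max)
            g = -np.log(-np.log(self.rng.random(w.shape) + 1e-300) + 1e-300)
            pick = np.argmax(np.log(w + 1e-300) + g, axis=1)
            bg = pick == K
            n_bg_single += int(bg.sum())
            n_att_single += int((~bg).sum())
            if (~bg).any():
                j = pick[~bg]
                d2 = ((f[~bg] - self.centers[j]) ** 2).sum(axis=1)
                ssd_att += float(d2.sum())
                n_att_j += np.bincount(j, minlength=K)
        return n_att_j, ssd_att, n_bg_single, n_att_single

    # -- conjugate global updates ------------------------------------------

    def update_globals(self):
        pr = self.priors
        K = self.centers.shape[0]
        vol = self.geom.volume
        rng = self.rng

        n_att_j, ssd_att, n_bg_single, n_att_single = self._draw_single_parents()

        n_att_sc = 0
        n_bg_sc = 0
        n_clusters = 0
        extra_foci = 0
        ssd_foci = 0.0
        n_multi = 0
        for st in self.studies:
            for c in st.clusters.values():
                n_clusters += 1
                extra_foci += c["count"] - 1
                n_multi += c["count"]
                members = st.foci[st.cl_id == _key_of(st, c)]
                ssd_foci += float(((members - c["loc"]) ** 2).sum())
                j = c["parent"]
                if j >= 0:
                    n_att_sc += 1
                    ssd_att += float(((c["loc"] - self.centers[j]) ** 2).sum())
                    n_att_j[j] += 1
                else:
                    n_bg_sc += 1

        n_att_units = n_att_single + n_att_sc

        # eta | K
        self.eta = rng.gamma(pr.a_eta + K, 1.0 / (pr.b_eta + vol))
        # offspring / background rates
        self.mu_c = rng.gamma(pr.a_mu + n_att_units, 1.0 / (pr.b_mu + self.n_studies * K))
        self.mu_m = rng.gamma(pr.a_mu + extra_foci, 1.0 / (pr.b_mu + n_clusters))
        self.q = rng.beta(pr.a_q + n_att_sc, pr.b_q + n_att_single)
        self.q = min(max(self.q, 1e-9), 1 - 1e-9)
        self.nu_s = max(rng.gamma(pr.a_bg + n_bg_single, 1.0 / (pr.b_bg + self.n_studies)), 1e-12)
        self.nu_c = max(rng.gamma(pr.a_bg + n_bg_sc, 1.0 / (pr.b_bg + self.n_studies)), 1e-12)

        # sigma_foci^2: exact conjugate (no truncation correction at level 1)
        var_f = stats.invgamma.rvs(
            pr.a_var + 1.5 * n_multi, scale=pr.b_var + 0.5 * ssd_foci,
            random_state=rng,
        )
        self.sig_f = math.sqrt(var_f)

        # sigma_study^2: conjugate proposal, Metropolis-corrected for the
        # per-center truncation masses of the attached units
        var_prop = stats.invgamma.rvs(
            pr.a_var + 1.5 * n_att_units, scale=pr.b_var + 0.5 * ssd_att,
            random_state=rng,
        )
        sig_prop = math.sqrt(var_prop)
        log_alpha = 0.0
        if K and n_att_j.sum() > 0:
            m_old = self.geom.trunc_mass(self.centers, self.sig_st)
            m_new = self.geom.trunc_mass(self.centers, sig_prop)
            log_alpha = float(np.dot(n_att_j, np.log(m_old) - np.log(m_new)))
        if math.log(rng.random() + 1e-300) < log_alpha:
            self.sig_st = sig_prop
        else:
            self.counters["sigma_rej"] += 1

        # supplementary random-walk move on log sigma_study^2: the
        # independence proposal above can be sticky when the truncation
        # masses tilt the conditional away from the conjugate shape
        a_post = pr.a_var + 1.5 * n_att_units
        b_post = pr.b_var + 0.5 * ssd_att
        var_old = self.sig_st**2
        var_new = var_old * math.exp(0.2 * rng.standard_normal())
        sig_new = math.sqrt(var_new)
        log_alpha = (
            stats.invgamma.logpdf(var_new, a_post, scale=b_post)
            - stats.invgamma.logpdf(var_old, a_post, scale=b_post)
            + math.log(var_new / var_old)  # log-scale proposal Jacobian
        )
        if K and n_att_j.sum() > 0:
            m_old = self.geom.trunc_mass(self.centers, self.sig_st)
            m_new = self.geom.trunc_mass(self.centers, sig_new)
            log_alpha += float(np.dot(n_att_j, np.log(m_old) - np.log(m_new)))
        if math.log(rng.random() + 1e-300) < log_alpha:
            self.sig_st = sig_new

    # -- marginal level-2 likelihood machinery -----------------------------

    def _pooled_units(self):
        singles = [st.foci[st.mark == 0] for st in self.studies]
        sc = [c["loc"] for st in self.studies for c in st.clusters.values()]
        u_s = np.vstack(singles) if singles else np.empty((0, 3))
        u_c = np.asarray(sc).reshape(-1, 3)
        return u_s, u_c

    def _unit_terms(self, u_s, u_c, centers):
        """Per-unit per-center attached-stream intensities (two matrices)."""
        if centers.shape[0] == 0:
            return (np.zeros((len(u_s), 0)), np.zeros((len(u_c), 0)))
        t_s = self.mu_c * (1.0 - self.q) * np.exp(
            _center_log_kernel(u_s, centers, self.sig_st, self.geom)
        ) if len(u_s) else np.zeros((0, centers.shape[0]))
        t_c = self.mu_c * self.q * np.exp(
            _center_log_kernel(u_c, centers, self.sig_st, self.geom)
        ) if len(u_c) else np.zeros((0, centers.shape[0]))
        return t_s, t_c

    def update_centers(self):
        """Random-walk Metropolis refresh of every center location."""
        K = self.centers.shape[0]
        if K == 0:
            return
        u_s, u_c = self._pooled_units()
        t_s, t_c = self._unit_terms(u_s, u_c, self.centers)
        bg_s = self.nu_s / self.geom.volume
        bg_c = self.nu_c / self.geom.volume
        lam_s = t_s.sum(axis=1) + bg_s
        lam_c = t_c.sum(axis=1) + bg_c
        scale = self.config.proposal_scale
        for j in range(K):
            self.counters["move_prop"] += 1
            cand = self.centers[j] + self.rng.normal(0.0, scale, size=3)
            if not self.geom.contains(cand)[0]:
                continue
            nt_s, nt_c = self._unit_terms(u_s, u_c, cand.reshape(1, 3))
            new_s = lam_s - t_s[:, j] + nt_s[:, 0]
            new_c = lam_c - t_c[:, j] + nt_c[:, 0]
            if np.any(new_s <= 0) or np.any(new_c <= 0):
                continue
            delta = np.log(new_s / lam_s).sum() + np.log(new_c / lam_c).sum()
            if math.log(self.rng.random() + 1e-300) < delta:
                self.centers[j] = cand
                t_s[:, j], t_c[:, j] = nt_s[:, 0], nt_c[:, 0]
                lam_s, lam_c = new_s, new_c
                self.counters["move_acc"] += 1

    def birth_death_step(self):
        """One birth/death proposal on the population-center configuration.

        Two flavours alternate at random, both with parents marginalized:

        * plain: mu_cent fixed; a birth pays the dimension penalty
          exp(-n_studies * mu_cent) until points attach, so it succeeds
          only near unexplained data;
        * rescaled: mu_cent is jointly scaled by K/(K±1) so the total
          attachment rate K*mu_cent is preserved (reversible jump with a
          deterministic mapping).  This is what lets K traverse between
          configurations that split one center's rate across near
          -duplicate locations.
        """
        u_s, u_c = self._pooled_units()
        bg_s = self.nu_s / self.geom.volume
        bg_c = self.nu_c / self.geom.volume
        t_s, t_c = self._unit_terms(u_s, u_c, self.centers)
        lam_s = t_s.sum(axis=1) + bg_s
        lam_c = t_c.sum(axis=1) + bg_c
        K = self.centers.shape[0]
        vol = self.geom.volume
        pr = self.priors
        rescaled = self.rng.random() < 0.5
        if self.rng.random() < 0.5:  # birth
            self.counters["birth_prop"] += 1
            cand = self.geom.sample_uniform(1, self.rng)[0]
            nt_s, nt_c = self._unit_terms(u_s, u_c, cand.reshape(1, 3))
            if rescaled and K > 0:
                f = K / (K + 1.0)
                new_s = f * (lam_s - bg_s + nt_s[:, 0]) + bg_s
                new_c = f * (lam_c - bg_c + nt_c[:, 0]) + bg_c
                delta = (
                    _safe_log_ratio(new_s, lam_s) + _safe_log_ratio(new_c, lam_c)
                    + stats.gamma.logpdf(self.mu_c * f, pr.a_mu, scale=1 / pr.b_mu)
                    - stats.gamma.logpdf(self.mu_c, pr.a_mu, scale=1 / pr.b_mu)
                    + math.log(f)  # Jacobian
                )
                mu_new = self.mu_c * f
            else:
                delta = (
                    -self.n_studies * self.mu_c
                    + np.log1p(nt_s[:, 0] / lam_s).sum()
                    + np.log1p(nt_c[:, 0] / lam_c).sum()
                )
                mu_new = self.mu_c
            log_alpha = delta + math.log(self.eta * vol / (K + 1))
            if math.log(self.rng.random() + 1e-300) < log_alpha:
                self.centers = np.vstack([self.centers, cand])
                self.mu_c = mu_new
                self.counters["birth_acc"] += 1
        else:  # death
            if K == 0:
                return
            self.counters["death_prop"] += 1
            j = int(self.rng.integers(K))
            if rescaled and K > 1:
                f = K / (K - 1.0)
                new_s = f * (lam_s - bg_s - t_s[:, j]) + bg_s
                new_c = f * (lam_c - bg_c - t_c[:, j]) + bg_c
                delta = (
                    _safe_log_ratio(new_s, lam_s) + _safe_log_ratio(new_c, lam_c)
                    + stats.gamma.logpdf(self.mu_c * f, pr.a_mu, scale=1 / pr.b_mu)
                    - stats.gamma.logpdf(self.mu_c, pr.a_mu, scale=1 / pr.b_mu)
                    + math.log(f)  # Jacobian
                )
                mu_new = self.mu_c * f
            else:
                new_s = lam_s - t_s[:, j]
                new_c = lam_c - t_c[:, j]
                delta = (
                    self.n_studies * self.mu_c
                    + _safe_log_ratio(new_s, lam_s) + _safe_log_ratio(new_c, lam_c)
                )
                mu_new = self.mu_c
            if not np.isfinite(delta):
                return
            log_alpha = delta + math.log(K / (self.eta * vol))
            if math.log(self.rng.random() + 1e-300) < log_alpha:
                self.centers = np.delete(self.centers, j, axis=0)
                self.mu_c = mu_new
                self.counters["death_acc"] += 1

    # -- diagnostics -------------------------------------------------------

    def log_posterior(self) -> float:
        """Log posterior of the current state (parents marginalized)."""
        from .model import log_prior

        state = self.get_state()
        u_s, u_c = self._pooled_units()
        t_s, t_c = self._unit_terms(u_s, u_c, self.centers)
        bg_s = self.nu_s / self.geom.volume
        bg_c = self.nu_c / self.geom.volume
        K = self.centers.shape[0]
        ll = -self.n_studies * (K * self.mu_c + self.nu_s + self.nu_c)
        lam_s = t_s.sum(axis=1) + bg_s
        lam_c = t_c.sum(axis=1) + bg_c
        if np.any(lam_s <= 0) or np.any(lam_c <= 0):
            return -np.inf
        ll += np.log(lam_s).sum() + np.log(lam_c).sum()
        for st in self.studies:
            for cid, c in st.clusters.items():
                m = c["count"]
                ll += stats.poisson.logpmf(m - 1, self.mu_m) + math.lgamma(m + 1)
                members = st.foci[st.cl_id == cid]
                d2 = ((members - c["loc"]) ** 2).sum(axis=1)
                ll += float(iso_normal_logpdf(d2, self.sig_f).sum())
        lp = log_prior(state, self.priors, self.geom)
        return float(ll + lp)

    # -- main loop ---------------------------------------------------------

    def sweep(self):
        self.update_assignments()
        self._refresh_clusters()
        self.update_globals()
        self.update_centers()
        for _ in range(self.config.bd_substeps):
            self.birth_death_step()

    def run(self, category: str = "") -> PosteriorSamples:
        cfg = self.config
        states, ks, lps = [], [], []
        for it in range(cfg.n_iter):
            self.sweep()
            ks.append(self.centers.shape[0])
            lp = self.log_posterior()
            if not np.isfinite(lp):
                raise RuntimeError(
                    f"non-finite log posterior at iteration {it}: "
                    f"state={self.get_state()!r}"
                )
            lps.append(lp)
            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thinning == 0:
                states.append(self.get_state())
            if (it + 1) % max(1, cfg.n_iter // 10) == 0:
                log.debug(
                    "cat=%s iter=%d K=%d logpost=%.1f", category, it + 1,
                    self.centers.shape[0], lp,
                )
        assert len(states) == cfg.n_retained
        return PosteriorSamples(
            category, states, np.asarray(ks), np.asarray(lps),
            dict(self.counters), cfg, cfg.seed,
        )


def _safe_log_ratio(new: np.ndarray, old: np.ndarray) -> float:
    if len(new) == 0:
        return 0.0
    if np.any(new <= 0):
        return -np.inf
    return float(np.log(new / old).sum())


def _key_of(st: _Study, cluster: dict) -> int:
    for cid, c in st.clusters.items():
        if c is cluster:
            return cid
    raise KeyError("cluster not found")


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def run_mcmc(
    data_by_category: dict,
    geom: MaskGeometry,
    priors: Priors | None = None,
    config: MCMCConfig | None = None,
) -> dict:
    """Fit every category independently; returns label -> PosteriorSamples.

    ``data_by_category`` maps label -> list of (n_i, 3) foci arrays.  The
    chain for category index c uses the seeded stream (config.seed, c) so
    runs are reproducible and categories independent.
    """
    priors = priors or Priors()
    config = config or MCMCConfig()
    out = {}
    for ci, label in enumerate(sorted(data_by_category)):
        foci_list = data_by_category[label]
        if not foci_list:
            raise ValueError(f"category {label!r} has no studies")
        rng = np.random.default_rng([config.seed, ci])
        sampler = CategorySampler(foci_list, geom, priors, config, rng)
        out[label] = sampler.run(category=label)
        log.info(
            "fitted %s: median K=%.0f, acc(birth)=%.2f",
            label,
            float(np.median(out[label].k_values())),
            out[label].counters["birth_acc"] / max(1, out[label].counters["birth_prop"]),
        )
    return out


def summarize_population_centers(samples: dict | PosteriorSamples) -> dict:
    """Posterior summaries of the number of population centers K.

    Returns per category: mean, sd, median and the central 95% credible
    interval (2.5 / 97.5 empirical percentiles) of K over the retained
    states.
    """
    if isinstance(samples, PosteriorSamples):
        samples = {samples.category: samples}
    out = {}
    for label, s in samples.items():
        k = s.k_values()
        if len(k) < 2:
            raise ValueError("need at least two retained states")
        out[label] = {
            "mean": float(np.mean(k)),
            "sd": float(np.std(k, ddof=1)),
            "median": float(np.median(k)),
            "ci_low": float(np.percentile(k, 2.5)),
            "ci_high": float(np.percentile(k, 97.5)),
        }
    return out
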