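"""Posterior-predictive classification of a study's category from its foci.

The predictive probability of category e for a new study with foci F is

    Pr(E = e | training data, F)  ∝  Pr(E = e) * (1/T) sum_t pi(F | lambda_e^(t))

where lambda_e^(t) are the retained posterior states of category e's
model.  Because categories are fitted independently, only category e's
posterior enters its own predictive term.  Leave-one-study-out
cross-validation re-uses the full-data posteriors: the held-out study's
own category term is re-weighted by self-normalized importance weights
w_t ∝ 1 / pi(F_k | lambda^(t)) to approximate the leave-k-out posterior,
with an exact refit fallback when the weights degenerate.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .io_atlas import FociDatabase
from .mcmc import CategorySampler, MCMCConfig, PosteriorSamples
from .model import MaskGeometry, Priors, study_log_predictive

log = logging.getLogger("metafoci")


@dataclass
class ClassPrior:
    """Prior category probabilities; default flat (no base-rate knowledge)."""

    probs: dict

    @classmethod
    def flat(cls, categories) -> "ClassPrior":
        m = len(categories)
        return cls({c: 1.0 / m for c in categories})

    def __post_init__(self):
        vals = np.array(list(self.probs.values()), dtype=float)
        if np.any(vals < 0) or not math.isclose(vals.sum(), 1.0, rel_tol=1e-9):
            raise ValueError("class prior must be nonnegative and sum to 1")


@dataclass
class ClassificationResult:
    study_id: str
    true_label: str | None
    predicted: str
    probs: dict
    tie: bool = False
    ess: float | None = None
    refit: bool = False


@dataclass
class PerformanceTable:
    categories: list
    confusion: np.ndarray  # rows = truth, cols = predicted
    sensitivity: dict = field(default_factory=dict)
    specificity: dict = field(default_factory=dict)
    ppv: dict = field(default_factory=dict)
    npv: dict = field(default_factory=dict)
    mean_balanced_accuracy: float = float("nan")

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())


# ---------------------------------------------------------------------------
# predictive densities
# ---------------------------------------------------------------------------

def state_logpred(samples: PosteriorSamples, foci, geom: MaskGeometry) -> np.ndarray:
    """log pi(foci | lambda^(t)) for every retained state (length T)."""
    if samples.n_samples == 0:
        raise ValueError("empty posterior samples")
    return np.array(
        [study_log_predictive(s, foci, geom) for s in samples.states]
    )


def logpred_matrix(samples: PosteriorSamples, foci_list: list,
                   geom: MaskGeometry) -> np.ndarray:
    """(n_studies, T) matrix of per-state marginal log densities.

    All studies' foci are stacked so each state is visited once; this is
    the workhorse for LOOCV.
    """
    import math as _m

    from .model import _center_log_kernel

    lens = [np.atleast_2d(f).shape[0] for f in foci_list]
    offsets = np.concatenate([[0], np.cumsum(lens)])
    allf = np.vstack([np.atleast_2d(f) for f in foci_list])
    out = np.empty((len(foci_list), samples.n_samples))
    for t, state in enumerate(samples.states):
        w, kern = state.weights, state.kernels
        per_sc = 1.0 + w.mu_multi
        total = (
            state.population.n_centers * w.mu_cent * (1 - w.q_study)
            + state.population.n_centers * w.mu_cent * w.q_study * per_sc
            + w.nu_bg_single + w.nu_bg_center * per_sc
        )
        bg = (w.nu_bg_single + w.nu_bg_center * per_sc) / geom.volume
        lam = np.full(allf.shape[0], bg)
        if state.population.n_centers:
            c = state.population.centers
            lk1 = _center_log_kernel(allf, c, kern.sigma_study, geom)
            sig = _m.sqrt(kern.sigma_study**2 + kern.sigma_foci**2)
            lk2 = _center_log_kernel(allf, c, sig, geom)
            lam = (
                lam
                + w.mu_cent * (1 - w.q_study) * np.exp(lk1).sum(axis=1)
                + w.mu_cent * w.q_study * per_sc * np.exp(lk2).sum(axis=1)
            )
        ll = np.log(lam)
        out[:, t] = np.add.reduceat(ll, offsets[:-1]) - total
        # reduceat on an empty segment returns the next element; fix zero-length studies
        for i, n in enumerate(lens):
            if n == 0:
                out[i, t] = -total
    return out


def predictive_logprob(foci, samples: PosteriorSamples, geom: MaskGeometry) -> float:
    """Monte-Carlo posterior predictive: log[(1/T) sum_t pi(foci|lambda_t)]."""
    lp = state_logpred(samples, foci, geom)
    return float(logsumexp(lp) - math.log(len(lp)))


def classify_study(
    foci,
    samples_by_category: dict,
    geom: MaskGeometry,
    prior: ClassPrior | None = None,
    study_id: str = "",
    true_label: str | None = None,
    logpred_by_category: dict | None = None,
) -> ClassificationResult:
    """Posterior category probabilities for one study's foci.

    ``logpred_by_category`` overrides the predictive log density per
    category (used by LOOCV); otherwise the plain Monte-Carlo average
    over each category's posterior states is used.  Ties are broken
    toward the lexicographically smallest label and flagged.
    """
    cats = sorted(samples_by_category)
    prior = prior or ClassPrior.flat(cats)
    lp = np.empty(len(cats))
    for i, c in enumerate(cats):
        if logpred_by_category is not None and c in logpred_by_category:
            val = logpred_by_category[c]
        else:
            val = predictive_logprob(foci, samples_by_category[c], geom)
        pc = prior.probs.get(c, 0.0)
        lp[i] = (val + math.log(pc)) if pc > 0 else -np.inf
    if np.all(np.isinf(lp) & (lp < 0)):
        raise ValueError("foci outside support: all categories give zero density")
    post = np.exp(lp - logsumexp(lp))
    best = float(post.max())
    winners = [c for c, p in zip(cats, post) if math.isclose(p, best, rel_tol=1e-9)]
    tie = len(winners) > 1
    if tie:
        log.info("classification tie for study %r among %s", study_id, winners)
    return ClassificationResult(
        study_id, true_label, min(winners), dict(zip(cats, post)), tie=tie
    )


# ---------------------------------------------------------------------------
# leave-one-study-out cross-validation
# ---------------------------------------------------------------------------

def _is_logpred(lp_t: np.ndarray, clip_percentile: float) -> tuple:
    """Importance-sampled leave-one-out predictive from in-sample states.

    Weights w_t ∝ 1/pi(F|lambda_t), clipped at the given percentile and
    self-normalized.  Returns (log predictive, effective sample size).
    """
    logw = -lp_t
    cap = np.percentile(logw, clip_percentile)
    n_clipped = int((logw > cap).sum())
    if n_clipped:
        log.debug("clipped %d importance weights", n_clipped)
    logw = np.minimum(logw, cap)
    logw = logw - logsumexp(logw)
    ess = float(np.exp(-logsumexp(2.0 * logw)))
    return float(logsumexp(logw + lp_t)), ess


def loocv_importance(
    database: FociDatabase,
    samples_by_category: dict,
    geom: MaskGeometry,
    prior: ClassPrior | None = None,
    ess_floor: float = 20.0,
    clip_percentile: float = 99.9,
    refit_config: MCMCConfig | None = None,
    priors: Priors | None = None,
    refit_all: bool = False,
) -> list:
    """Leave-one-study-out classification of every study in the database.

    For held-out study k of category e, category e's predictive term is
    importance-reweighted to approximate the leave-k-out posterior; the
    other categories (which never saw study k) use the unweighted
    Monte-Carlo average.  When the weight effective sample size falls
    below ``ess_floor`` the category-e model is refitted exactly without
    study k (using ``refit_config``, or the original config).

    ``refit_all=True`` replaces the importance-sampling shortcut with a
    short warm-started exact refit for every held-out study.  The
    shortcut's weights use the collapsed study density while the
    posterior was sampled under the exact cluster likelihood, which
    leaves a small (order 1 nat) systematic deficit on the held-out
    category; that deficit is immaterial when categories are well
    separated but decisive in label-exchangeable designs, where the
    exact path should be used.
    """
    cats = sorted(samples_by_category)
    prior = prior or ClassPrior.flat(cats)
    by_cat_records = {c: database.by_category(c) for c in cats}
    lp_mats = {
        c: logpred_matrix(samples_by_category[c], [r.foci for r in database.records], geom)
        for c in cats
    }
    # in refit_all mode every category term should carry comparable
    # Monte-Carlo noise: a 5-way tie is won too often by the noisiest
    # term, so the competing categories are averaged over a contiguous
    # block of the same length as the refit chain's retained states
    block = None
    if refit_all and refit_config is not None:
        block = refit_config.n_retained

    results = []
    for k, rec in enumerate(database.records):
        logpreds = {}
        ess_k = None
        refit = False
        for c in cats:
            lp_t = lp_mats[c][k]
            if c != rec.category:
                if block is not None and block < len(lp_t):
                    lp_t = lp_t[-block:]
                logpreds[c] = float(logsumexp(lp_t) - math.log(len(lp_t)))
                continue
            lp_is, ess = _is_logpred(lp_t, clip_percentile)
            ess_k = ess
            degenerate = not np.isfinite(lp_is)
            if refit_all or ess < ess_floor or degenerate or len(by_cat_records[c]) == 1:
                refit = True
                logpreds[c] = _refit_logpred(
                    rec, by_cat_records[c], samples_by_category[c], geom,
                    refit_config, priors,
                )
            else:
                logpreds[c] = lp_is
        res = classify_study(
            rec.foci, samples_by_category, geom, prior,
            study_id=rec.study_id, true_label=rec.category,
            logpred_by_category=logpreds,
        )
        res.ess = ess_k
        res.refit = refit
        results.append(res)
    return results


def _refit_logpred(rec, cat_records, samples, geom, refit_config, priors):
    """Exact leave-one-out: refit the category without the held-out study."""
    rest = [r.foci for r in cat_records if r is not rec]
    if not rest:
        # degenerate database (single study in category): fall back to the
        # prior-only model by keeping the full-data posterior unweighted
        log.warning(
            "category %r has a single study; LOOCV falls back to the "
            "in-sample predictive", rec.category,
        )
        lp_t = state_logpred(samples, rec.foci, geom)
        return float(logsumexp(lp_t) - math.log(len(lp_t)))
    cfg = refit_config or samples.config
    pr = priors or Priors()
    rng = np.random.default_rng([cfg.seed, zlib.crc32(rec.study_id.encode()) % (2**31)])
    # warm start from the last full-data state (globals + centers); the
    # leave-one-out posterior is close, so a short chain suffices
    init = samples.states[-1].clone_globals() if samples.states else None
    sampler = CategorySampler(rest, geom, pr, cfg, rng, init_state=init)
    refit_samples = sampler.run(category=f"{rec.category}-loo")
    lp_t = state_logpred(refit_samples, rec.foci, geom)
    return float(logsumexp(lp_t) - math.log(len(lp_t)))


# ---------------------------------------------------------------------------
# performance metrics
# ---------------------------------------------------------------------------

def performance_metrics(results: list, categories: list | None = None) -> PerformanceTable:
    """One-vs-rest sensitivity/specificity/PPV/NPV from the confusion matrix.

    Rows of the confusion matrix are true categories, columns predicted.
    A metric whose denominator is empty (category absent from the truth)
    is reported as NaN, not zero.  Mean balanced accuracy is the mean of
    the defined per-category sensitivities.
    """
    if categories is None:
        categories = sorted(
            {r.true_label for r in results if r.true_label is not None}
            | {r.predicted for r in results}
        )
    idx = {c: i for i, c in enumerate(categories)}
    m = len(categories)
    conf = np.zeros((m, m), dtype=int)
    for r in results:
        if r.true_label is None:
            continue
        conf[idx[r.true_label], idx[r.predicted]] += 1

    table = PerformanceTable(list(categories), conf)
    total = conf.sum()
    sens = []
    for c in categories:
        i = idx[c]
        tp = conf[i, i]
        fn = conf[i].sum() - tp
        fp = conf[:, i].sum() - tp
        tn = total - tp - fn - fp
        table.sensitivity[c] = tp / (tp + fn) if (tp + fn) else float("nan")
        table.specificity[c] = tn / (tn + fp) if (tn + fp) else float("nan")
        table.ppv[c] = tp / (tp + fp) if (tp + fp) else float("nan")
        table.npv[c] = tn / (tn + fn) if (tn + fn) else float("nan")
        if tp + fn:
            sens.append(table.sensitivity[c])
    table.mean_balanced_accuracy = float(np.mean(sens)) if sens else float("nan")
    return table
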