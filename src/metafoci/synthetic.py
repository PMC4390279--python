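"""Synthetic foci databases, toy masks and atlases with known ground truth.

The generator draws studies from the package's own three-level model:
known population centers per category, study-level Gaussian scatter, and
uniform background clutter on a box-shaped toy mask (a scaled-down MNI
extent).  Every fixture is reproducible bit-for-bit from (scenario,
seed).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .io_atlas import Atlas, BrainMask, FociDatabase, StudyRecord, VoxelGrid
from .model import (
    ClusterKernels,
    MaskGeometry,
    MixtureWeights,
    ModelState,
    PopulationProcess,
    simulate_study,
)

GROUP_NAMES = (
    "cortex", "basal_ganglia", "cerebellum_brainstem",
    "thalamus", "amygdala", "hippocampus",
)


@dataclass
class ScenarioConfig:
    """Study conditions for a synthetic multi-category foci database.

    ``separation`` is the spacing (mm) of the global center grid from
    which category center sets are drawn; 0 means all categories share
    one identical center set (the label-exchangeable null used for
    chance-level experiments).  When 0, within-set spacing defaults to
    6 sigma_study.  ``clutter_fraction`` is the expected fraction of
    foci arising from the uniform background component.
    """

    n_categories: int = 5
    studies_per_category: int = 20
    n_centers: int = 3
    sigma_study: float = 8.0
    sigma_foci: float = 4.0
    mu_cent: float = 2.0
    mu_multi: float = 2.0
    q_study: float = 0.5
    clutter_fraction: float = 0.3
    separation: float | None = None  # default 6 * sigma_study
    mask_shape: tuple = (40, 48, 40)
    voxel_size: float = 2.0
    n_regions: int = 8
    margin: float = 12.0  # mm kept clear of the mask boundary for centers

    def __post_init__(self):
        if self.n_categories < 1 or self.studies_per_category < 1:
            raise ValueError("need at least one category and one study")
        if self.n_centers < 0 or self.sigma_study <= 0 or self.sigma_foci <= 0:
            raise ValueError("invalid kernel/center configuration")
        if not 0.0 <= self.clutter_fraction < 1.0:
            raise ValueError("clutter fraction must be in [0, 1)")
        if self.separation is None:
            self.separation = 6.0 * self.sigma_study
        if self.separation < 0:
            raise ValueError("separation must be nonnegative")


@dataclass
class GroundTruth:
    """Everything the generator knew: per-category states and per-study latents."""

    scenario: ScenarioConfig
    seed: int
    centers_by_category: dict
    states_by_category: dict
    latents_by_study: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "scenario": asdict(self.scenario),
            "seed": self.seed,
            "centers_by_category": {
                c: np.asarray(v).tolist() for c, v in self.centers_by_category.items()
            },
        }


# ---------------------------------------------------------------------------
# toy mask and atlas
# ---------------------------------------------------------------------------

def _tiling(n: int, shape: tuple) -> tuple:
    """Split n into 3 factors (a, b, c) proportionate to the grid shape."""
    best, score = None, None
    for a in range(1, n + 1):
        if n % a:
            continue
        for b in range(1, n // a + 1):
            if (n // a) % b:
                continue
            c = n // (a * b)
            s = max(shape[0] / a, shape[1] / b, shape[2] / c) / min(
                shape[0] / a, shape[1] / b, shape[2] / c
            )
            if score is None or s < score:
                best, score = (a, b, c), s
    return best


def make_toy_mask_atlas(config: ScenarioConfig) -> tuple:
    """Box mask + contiguous-box parcellation with cycling group labels.

    The mask fills the whole grid; the atlas splits it into
    ``n_regions`` near-equal rectangular boxes whose groups cycle over
    six cerebral-zone names.
    """
    shape = tuple(config.mask_shape)
    r = config.n_regions
    if r < 1:
        raise ValueError("need at least one region")
    if r > int(np.prod(shape)):
        raise ValueError("more regions than voxels")
    vs = config.voxel_size
    affine = np.diag([vs, vs, vs, 1.0])
    affine[:3, 3] = -vs * (np.array(shape) - 1) / 2.0  # centered at origin
    grid = VoxelGrid(shape, affine)
    mask = BrainMask(grid, np.ones(shape, dtype=bool))

    a, b, c = _tiling(r, shape)
    labels = np.zeros(shape, dtype=np.int16)
    xs = np.array_split(np.arange(shape[0]), a)
    ys = np.array_split(np.arange(shape[1]), b)
    zs = np.array_split(np.arange(shape[2]), c)
    lbl = 1
    for sx in xs:
        for sy in ys:
            for sz in zs:
                labels[np.ix_(sx, sy, sz)] = lbl
                lbl += 1
    names = [f"region_{i:02d}" for i in range(1, r + 1)]
    groups = {n: GROUP_NAMES[i % len(GROUP_NAMES)] for i, n in enumerate(names)}
    atlas = Atlas(grid, labels, names, groups)
    return mask, atlas


# ---------------------------------------------------------------------------
# center placement and database generation
# ---------------------------------------------------------------------------

def _center_grid(config: ScenarioConfig, mask: BrainMask) -> np.ndarray:
    """Candidate center positions spaced by the scenario separation."""
    spacing = config.separation if config.separation > 0 else 6.0 * config.sigma_study
    lo = mask.voxel_centers().min(axis=0) + config.margin
    hi = mask.voxel_centers().max(axis=0) - config.margin
    axes = []
    for d in range(3):
        n = int(math.floor((hi[d] - lo[d]) / spacing)) + 1
        start = (lo[d] + hi[d]) / 2.0 - spacing * (n - 1) / 2.0
        axes.append(start + spacing * np.arange(n))
    pts = np.array(list(itertools.product(*axes)))
    # deterministic order: by distance from the mask center, then lexicographic
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0], (pts**2).sum(axis=1)))
    return pts[order]


def _background_rates(config: ScenarioConfig) -> tuple:
    """Background rates matching the scenario's clutter fraction."""
    k, w = config.n_centers, config
    per_sc = 1.0 + w.mu_multi
    attached = k * w.mu_cent * ((1 - w.q_study) + w.q_study * per_sc)
    if attached == 0 or config.clutter_fraction == 0:
        return (0.0 if attached else 1.0), 0.0
    total_bg = config.clutter_fraction / (1 - config.clutter_fraction) * attached
    nu_s = 0.6 * total_bg
    nu_c = 0.4 * total_bg / per_sc
    return nu_s, nu_c


def scenario_state(config: ScenarioConfig, centers: np.ndarray,
                   volume: float) -> ModelState:
    """The true ModelState for one category of the scenario."""
    nu_s, nu_c = _background_rates(config)
    eta = max(len(centers), 1) / volume
    return ModelState(
        PopulationProcess(eta, centers),
        ClusterKernels(config.sigma_study, config.sigma_foci),
        MixtureWeights(config.mu_cent, config.mu_multi, config.q_study,
                       max(nu_s, 1e-9), max(nu_c, 1e-9)),
    )


def generate_database(config: ScenarioConfig, seed: int) -> tuple:
    """Simulate a multi-category foci database with known ground truth.

    Categories are labelled cat_a, cat_b, ...; each gets
    ``studies_per_category`` studies simulated from its true state
    (studies are re-drawn until they contain at least one focus).
    Returns (FociDatabase, GroundTruth, BrainMask, Atlas).
    """
    mask, atlas = make_toy_mask_atlas(config)
    geom = MaskGeometry(mask)
    grid_pts = _center_grid(config, mask)
    m, k = config.n_categories, config.n_centers
    shared = config.separation == 0
    need = k if shared else m * k
    if need > len(grid_pts):
        raise ValueError(
            f"cannot place {need} centers at separation {config.separation} mm "
            f"inside the mask ({len(grid_pts)} slots)"
        )
    rng = np.random.default_rng(seed)
    labels = [f"cat_{chr(ord('a') + i)}" for i in range(m)]
    centers_by_cat, states, records, latents = {}, {}, [], {}
    for i, cat in enumerate(labels):
        block = grid_pts[:k] if shared else grid_pts[i * k : (i + 1) * k]
        centers_by_cat[cat] = block.copy()
        state = scenario_state(config, block, geom.volume)
        states[cat] = state
        for s in range(config.studies_per_category):
            for _ in range(100):
                foci, truth = simulate_study(state, geom, rng)
                if foci.shape[0] >= 1:
                    break
            else:
                raise RuntimeError("could not draw a nonempty study")
            sid = f"{cat}_{s:03d}"
            records.append(StudyRecord(sid, cat, foci))
            latents[sid] = truth
    db = FociDatabase(records, categories=labels)
    gt = GroundTruth(config, seed, centers_by_cat, states, latents)
    return db, gt, mask, atlas


# ---------------------------------------------------------------------------
# null intensity-matrix fixtures
# ---------------------------------------------------------------------------

def null_intensity_matrices(
    t: int, r: int, correlation_structure="identity", seed: int = 0,
) -> np.ndarray:
    """Nonnegative T x R matrix with a specified column correlation structure.

    Columns are exponentiated Gaussians: Z ~ N(0, Sigma) rowwise, M =
    exp(Z).  ``correlation_structure`` may be "identity", "rank1"
    (all columns share one factor), or an explicit R x R PSD matrix.
    """
    if t < 3:
        raise ValueError("need at least 3 rows")
    rng = np.random.default_rng(seed)
    if isinstance(correlation_structure, str):
        if correlation_structure == "identity":
            sigma = np.eye(r)
        elif correlation_structure == "rank1":
            sigma = np.full((r, r), 0.999)
            np.fill_diagonal(sigma, 1.0)
        else:
            raise ValueError(f"unknown structure {correlation_structure!r}")
    else:
        sigma = np.asarray(correlation_structure, dtype=float)
    try:
        chol = np.linalg.cholesky(sigma + 1e-12 * np.eye(r))
    except np.linalg.LinAlgError as exc:
        raise ValueError("requested correlation structure is not PSD") from exc
    z = rng.standard_normal((t, r)) @ chol.T
    return np.exp(z)
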