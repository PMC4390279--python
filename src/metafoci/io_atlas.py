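"""Foci tables, brain masks, atlases, and the grid/coordinate conventions.

All model-facing coordinates are world millimetres (MNI convention); voxel
grids appear only for masks, atlases and map evaluation.  Foci tables are
delimited text with one focus per row (``study_id, category, x, y, z``);
volumes are NIfTI-1.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

log = logging.getLogger("metafoci")

#: column aliases accepted when reading foci tables
DEFAULT_DIALECT = {
    "study_id": ("study_id", "study", "id"),
    "category": ("category", "emotion", "label", "class"),
    "x": ("x",),
    "y": ("y",),
    "z": ("z",),
}

DISPLAY_THRESHOLD = 0.001  # voxelwise intensity display threshold


class FociFormatError(ValueError):
    """Malformed foci table (missing column, bad coordinate, no records)."""


class GeometryError(ValueError):
    """Volume geometries (shape/affine) do not match."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class StudyRecord:
    """One study activation map: its identifier, category label and foci.

    ``foci`` is an (n, 3) float array of peak coordinates in MNI mm.
    Optional free-form string tags carry methodological covariates.
    """

    study_id: str
    category: str
    foci: np.ndarray
    tags: dict = field(default_factory=dict)

    def __post_init__(self):
        self.foci = np.asarray(self.foci, dtype=float).reshape(-1, 3)
        if self.foci.shape[0] < 1:
            raise FociFormatError(f"study {self.study_id!r} has no foci")
        if not np.all(np.isfinite(self.foci)):
            raise FociFormatError(f"study {self.study_id!r} has non-finite foci")

    @property
    def n_foci(self) -> int:
        return self.foci.shape[0]


@dataclass
class FociDatabase:
    """A collection of study records with an ordered category label set."""

    records: list
    categories: list = None

    def __post_init__(self):
        seen = sorted({r.category for r in self.records})
        if self.categories is None:
            self.categories = seen
        else:
            missing = set(seen) - set(self.categories)
            if missing:
                raise FociFormatError(f"records use unknown categories {sorted(missing)}")

    @property
    def n_studies(self) -> int:
        return len(self.records)

    @property
    def n_foci(self) -> int:
        return int(sum(r.n_foci for r in self.records))

    def counts(self) -> dict:
        out = {c: 0 for c in self.categories}
        for r in self.records:
            out[r.category] += 1
        return out

    def by_category(self, category: str) -> list:
        return [r for r in self.records if r.category == category]

    def subset(self, keep) -> "FociDatabase":
        """Database restricted to records selected by predicate or index list."""
        if callable(keep):
            recs = [r for r in self.records if keep(r)]
        else:
            recs = [self.records[i] for i in keep]
        return FociDatabase(recs, categories=list(self.categories))


@dataclass
class VoxelGrid:
    """Regular voxel grid: shape plus a 4x4 affine mapping ijk -> world mm."""

    shape: tuple
    affine: np.ndarray

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        self.affine = np.asarray(self.affine, dtype=float).reshape(4, 4)
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise GeometryError("affine is singular")

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def matches(self, other: "VoxelGrid", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


@dataclass
class BrainMask:
    """Binary support of the point process; |B| is its volume in mm^3."""

    grid: VoxelGrid
    inside: np.ndarray

    def __post_init__(self):
        self.inside = np.asarray(self.inside, dtype=bool)
        if self.inside.shape != self.grid.shape:
            raise GeometryError("mask array shape does not match grid")
        if not self.inside.any():
            raise GeometryError("mask is empty")

    @property
    def volume(self) -> float:
        """|B| = inside-voxel count x voxel volume (mm^3)."""
        return float(self.inside.sum()) * self.grid.voxel_volume

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean per point: does the point fall in an inside voxel?"""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        idx = world_to_voxel(self.grid, pts)
        ok = np.all((idx >= 0) & (idx < np.array(self.grid.shape)), axis=1)
        out = np.zeros(len(pts), dtype=bool)
        if ok.any():
            sel = idx[ok]
            out[ok] = self.inside[sel[:, 0], sel[:, 1], sel[:, 2]]
        return out

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all inside-voxel centers, (n_inside, 3)."""
        ijk = np.argwhere(self.inside)
        return voxel_to_world(self.grid, ijk)


@dataclass
class Atlas:
    """Integer parcellation aligned to a mask: label 0 = unlabelled."""

    grid: VoxelGrid
    labels: np.ndarray
    names: list
    groups: dict = None  # region name -> group name

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.allclose(self.labels, np.round(self.labels)):
                raise GeometryError("atlas values are not integers")
            self.labels = np.round(self.labels).astype(int)
        if self.labels.shape != self.grid.shape:
            raise GeometryError("atlas array shape does not match grid")
        r = int(self.labels.max())
        if r < 1:
            raise GeometryError("atlas has no labelled regions")
        if len(self.names) != r:
            raise GeometryError(
                f"atlas has {r} labels but {len(self.names)} region names"
            )
        if self.groups is None:
            self.groups = {n: "all" for n in self.names}

    @property
    def n_regions(self) -> int:
        return len(self.names)

    def region_voxels(self, label: int) -> np.ndarray:
        return self.labels == label


# ---------------------------------------------------------------------------
# coordinate transforms
# ---------------------------------------------------------------------------

def _round_half_away(x: np.ndarray) -> np.ndarray:
    # np.round rounds half to even; the convention here is half away from zero
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def world_to_voxel(grid: VoxelGrid, points: np.ndarray) -> np.ndarray:
    """Map world mm to nearest voxel indices (rounding half away from zero)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    inv = np.linalg.inv(grid.affine)
    ijk = pts @ inv[:3, :3].T + inv[:3, 3]
    return _round_half_away(ijk).astype(int)


def voxel_to_world(grid: VoxelGrid, indices: np.ndarray) -> np.ndarray:
    """Map voxel indices to the world-mm coordinates of their centers."""
    idx = np.atleast_2d(np.asarray(indices, dtype=float))
    return idx @ grid.affine[:3, :3].T + grid.affine[:3, 3]


# ---------------------------------------------------------------------------
# foci tables
# ---------------------------------------------------------------------------

def _resolve_columns(columns, dialect) -> dict:
    lower = {c.lower(): c for c in columns}
    resolved = {}
    for canonical, aliases in dialect.items():
        for a in aliases:
            if a.lower() in lower:
                resolved[canonical] = lower[a.lower()]
                break
        else:
            raise FociFormatError(f"missing required column {canonical!r}")
    return resolved


def read_foci_table(path, dialect: dict | None = None) -> FociDatabase:
    """Read a delimited foci table (one row per focus) into a FociDatabase.

    Required columns (aliases configurable via ``dialect``): study_id,
    category, x, y, z.  Rows are grouped by study_id; the category set is
    inferred and ordered lexicographically.  Duplicate (study, x, y, z)
    rows are kept but logged.
    """
    dialect = dict(DEFAULT_DIALECT, **(dialect or {}))
    df = pd.read_csv(path, sep=None, engine="python")
    cols = _resolve_columns(df.columns, dialect)
    if len(df) == 0:
        raise FociFormatError("no records")

    for ax in ("x", "y", "z"):
        raw = df[cols[ax]]
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna() & raw.notna() | raw.isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise FociFormatError(
                f"non-numeric coordinate {ax!r} at line {line}"
            )
        df[cols[ax]] = num.astype(float)

    dup = df.duplicated(subset=[cols["study_id"], cols["x"], cols["y"], cols["z"]])
    if dup.any():
        log.warning("foci table has %d duplicate (study, x, y, z) rows (kept)", dup.sum())

    records = []
    for (sid, cat), g in df.groupby(
        [cols["study_id"], cols["category"]], sort=True
    ):
        records.append(
            StudyRecord(str(sid), str(cat), g[[cols["x"], cols["y"], cols["z"]]].to_numpy())
        )
    db = FociDatabase(records)
    assert db.n_foci == len(df)
    return db


def write_foci_table(db: FociDatabase, path) -> None:
    rows = []
    for r in db.records:
        for x, y, z in r.foci:
            rows.append((r.study_id, r.category, x, y, z))
    pd.DataFrame(rows, columns=["study_id", "category", "x", "y", "z"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def load_mask(path) -> BrainMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise GeometryError("mask volume must be 3-D")
    grid = VoxelGrid(data.shape, img.affine)
    return BrainMask(grid, data > 0)


def save_mask(mask: BrainMask, path) -> None:
    nib.save(
        nib.Nifti1Image(mask.inside.astype(np.uint8), mask.grid.affine), str(path)
    )


def load_atlas(path, names, groups=None, mask: BrainMask | None = None) -> Atlas:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    grid = VoxelGrid(data.shape, img.affine)
    if mask is not None and not grid.matches(mask.grid):
        raise GeometryError("atlas geometry does not match mask geometry")
    return Atlas(grid, data, list(names), groups)


def save_atlas(atlas: Atlas, path, sidecar: bool = True) -> None:
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int16), atlas.grid.affine), str(path))
    if sidecar:
        meta = {"names": atlas.names, "groups": atlas.groups}
        with open(str(path).replace(".nii.gz", "").replace(".nii", "") + ".json", "w") as fh:
            json.dump(meta, fh, indent=1)


def load_atlas_with_sidecar(path, mask: BrainMask | None = None) -> Atlas:
    """Load an atlas whose region names/groups live in its JSON sidecar."""
    stem = str(path).replace(".nii.gz", "").replace(".nii", "")
    with open(stem + ".json") as fh:
        meta = json.load(fh)
    return load_atlas(path, meta["names"], meta.get("groups"), mask=mask)


def write_intensity_map(
    values: np.ndarray,
    grid: VoxelGrid,
    path,
    mask: BrainMask | None = None,
    threshold: float | None = None,
    metadata: dict | None = None,
) -> None:
    """Write a voxelwise intensity map; optionally a display-thresholded copy.

    ``threshold`` zeroes voxels below the given intensity (the conventional
    display threshold is ``DISPLAY_THRESHOLD`` = 0.001) and writes the copy
    alongside with a ``_thr`` suffix.  Metadata (category, T, seed, ...)
    goes to a JSON sidecar.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != tuple(grid.shape):
        raise GeometryError("intensity map shape does not match grid")
    if mask is not None and not grid.matches(mask.grid):
        raise GeometryError("intensity map geometry does not match mask")
    nib.save(nib.Nifti1Image(values, grid.affine), str(path))
    stem = str(path).replace(".nii.gz", "").replace(".nii", "")
    if threshold is not None:
        thr = np.where(values >= threshold, values, 0.0)
        nib.save(nib.Nifti1Image(thr, grid.affine), stem + "_thr.nii.gz")
    if metadata is not None:
        with open(stem + ".json", "w") as fh:
            json.dump(metadata, fh, indent=1, default=str)


def load_intensity_map(path) -> tuple:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), VoxelGrid(img.shape, img.affine)
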