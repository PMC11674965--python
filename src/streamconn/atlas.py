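"""Visual-stream ROI atlas, spherical masks and ROI time-series extraction.

The packaged atlas holds 14 regions of interest spanning the dorsal visual
stream (DVS: bilateral superior occipital gyrus, inferior/superior parietal
lobule), the ventral visual stream (VVS: bilateral inferior occipital gyrus,
inferior temporal gyrus, fusiform gyrus) and the primary visual-stream
connections from the calcarine cortex (VS).  Coordinates are MNI millimetres.
Twelve within-subsystem connections link these regions: four dorsal
(SOG-IPL and SOG-SPL, bilaterally), four ventral (IOG-ITG and IOG-FG) and
four primary (Calc-IOG and Calc-SOG).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import detrend as _linear_detrend

from .errors import DegenerateSignalError, SizingError, StructuralError, ValidationError

SUBSYSTEMS = ("DVS", "VVS", "VS")

#: (hub, spokes) templates per subsystem; instantiated for both hemispheres.
_CONNECTION_TEMPLATES = {
    "DVS": ("SOG", ("IPL", "SPL")),
    "VVS": ("IOG", ("ITG", "FG")),
    "VS": ("Calc", ("IOG", "SOG")),
}

#: Functional (6 mm) and structural (12 mm) sphere radii in millimetres.
FUNCTIONAL_RADIUS_MM = 6.0
STRUCTURAL_RADIUS_MM = 12.0


@dataclass(frozen=True)
class ROIDefinition:
    """A named spherical ROI at an MNI coordinate."""

    name: str
    mni_xyz: tuple[float, float, float]
    radius: float
    subsystems: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValidationError(f"ROI {self.name!r}: radius must be > 0")
        if not self.subsystems:
            raise ValidationError(f"ROI {self.name!r}: needs >= 1 subsystem tag")
        unknown = set(self.subsystems) - set(SUBSYSTEMS)
        if unknown:
            raise ValidationError(f"ROI {self.name!r}: unknown subsystems {sorted(unknown)}")


@dataclass(frozen=True)
class Connection:
    """An undirected within-subsystem ROI pair."""

    roi_a: str
    roi_b: str
    subsystem: str

    def __post_init__(self) -> None:
        if self.roi_a == self.roi_b:
            raise ValidationError("connection endpoints must differ")

    @property
    def label(self) -> str:
        return f"{self.roi_a}-{self.roi_b}"


def load_atlas(radius: float = FUNCTIONAL_RADIUS_MM, path=None) -> list[ROIDefinition]:
    """Load the packaged 14-ROI atlas (or a user CSV with the same columns).

    Parameters
    ----------
    radius:
        Sphere radius in mm attached to every ROI (6 mm for the functional
        analysis, 12 mm for tractography-style masks).
    path:
        Optional CSV with columns ``name,x,y,z,subsystems`` (subsystems
        separated by ``;``); defaults to the packaged atlas.
    """
    if path is None:
        with resources.files("streamconn.data").joinpath("atlas.csv").open() as fh:
            table = pd.read_csv(fh)
    else:
        table = pd.read_csv(path)
    rois = []
    for row in table.itertuples(index=False):
        rois.append(
            ROIDefinition(
                name=row.name,
                mni_xyz=(float(row.x), float(row.y), float(row.z)),
                radius=float(radius),
                subsystems=frozenset(str(row.subsystems).split(";")),
            )
        )
    names = [r.name for r in rois]
    if len(set(names)) != len(names):
        raise ValidationError("atlas contains duplicate ROI names")
    return rois


def enumerate_connections(atlas: Sequence[ROIDefinition]) -> list[Connection]:
    """Enumerate the 12 within-subsystem connections in a stable order.

    An empty atlas yields an empty list; a partially populated atlas missing
    a required member raises :class:`StructuralError` naming the ROI.
    The ordering (DVS, then VVS, then VS; left before right; hub-spoke
    template order) is deterministic so that Holm families are reproducible.
    """
    if not atlas:
        return []
    names = {r.name for r in atlas}
    by_name = {r.name: r for r in atlas}
    out: list[Connection] = []
    for subsystem in SUBSYSTEMS:
        hub, spokes = _CONNECTION_TEMPLATES[subsystem]
        for hemi in ("L", "R"):
            for spoke in spokes:
                a, b = f"{hemi} {hub}", f"{hemi} {spoke}"
                for roi in (a, b):
                    if roi not in names:
                        raise StructuralError(f"atlas is missing required ROI {roi!r}")
                    if subsystem not in by_name[roi].subsystems:
                        raise StructuralError(
                            f"ROI {roi!r} is not tagged with subsystem {subsystem!r}"
                        )
                out.append(Connection(a, b, subsystem))
    return out


def connection_families(
    connections: Sequence[Connection],
) -> dict[str, list[Connection]]:
    """Group connections by subsystem (the Holm correction families)."""
    fams: dict[str, list[Connection]] = {}
    for con in connections:
        fams.setdefault(con.subsystem, []).append(con)
    return fams


def default_grid(voxel_mm: float = 2.0) -> tuple[np.ndarray, tuple[int, int, int]]:
    """A 2 mm isotropic MNI-like grid (affine, shape).

    Matches the common 91 x 109 x 91 bounding box with RAS+ mm coordinates.
    """
    if voxel_mm <= 0:
        raise ValidationError("voxel size must be > 0")
    shape91 = (
        int(round(182 / voxel_mm)) + 1,
        int(round(218 / voxel_mm)) + 1,
        int(round(182 / voxel_mm)) + 1,
    )
    affine = np.array(
        [
            [-voxel_mm, 0, 0, 90.0],
            [0, voxel_mm, 0, -126.0],
            [0, 0, voxel_mm, -72.0],
            [0, 0, 0, 1.0],
        ]
    )
    return affine, shape91


def sphere_mask(
    center: Sequence[float],
    radius: float,
    affine: np.ndarray,
    shape: Sequence[int],
) -> np.ndarray:
    """Boolean voxel mask of a sphere given in mm coordinates.

    A voxel belongs to the mask iff the Euclidean distance from its center's
    mm coordinates to ``center`` is <= ``radius`` (voxel-center convention).
    The mask is implicitly clipped to the grid bounds; a sphere entirely
    outside the grid produces an empty mask with a warning.
    """
    if radius <= 0:
        raise ValidationError("radius must be > 0")
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4) or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValidationError("affine must be an invertible 4x4 matrix")
    center = np.asarray(center, dtype=float)
    shape = tuple(int(s) for s in shape)

    # Work on the bounding box of the sphere in voxel space to stay cheap.
    inv = np.linalg.inv(affine)
    c_vox = inv @ np.append(center, 1.0)
    # conservative voxel-extent of the radius along each axis
    spacing = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    pad = np.ceil(radius / spacing).astype(int) + 1
    lo = np.maximum(np.floor(c_vox[:3]).astype(int) - pad, 0)
    hi = np.minimum(np.ceil(c_vox[:3]).astype(int) + pad + 1, shape)

    mask = np.zeros(shape, dtype=bool)
    if np.any(lo >= hi):
        warnings.warn("sphere center lies entirely outside the grid; empty mask")
        return mask
    ii, jj, kk = np.meshgrid(
        np.arange(lo[0], hi[0]),
        np.arange(lo[1], hi[1]),
        np.arange(lo[2], hi[2]),
        indexing="ij",
    )
    vox = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    mm = vox @ affine[:3, :3].T + affine[:3, 3]
    inside = np.linalg.norm(mm - center, axis=1) <= radius
    mask[vox[inside, 0], vox[inside, 1], vox[inside, 2]] = True
    if not mask.any():
        warnings.warn("sphere contains no voxel centers; empty mask")
    return mask


def read_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns (data array, affine)."""
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), np.asarray(img.affine)


def write_mask(mask: np.ndarray, affine: np.ndarray, path) -> None:
    """Write a boolean voxel mask as a uint8 NIfTI volume."""
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), np.asarray(affine))
    nib.save(img, str(path))


def normalize_series(series: np.ndarray, run_lengths: Sequence[int] | None = None) -> np.ndarray:
    """Per-run linear detrend followed by z-normalization (mean 0, var 1).

    ``run_lengths`` splits the series into independently processed segments;
    by default the whole series is one run.  Raises
    :class:`DegenerateSignalError` if any segment has zero variance after
    detrending.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValidationError("expected a 1-D series")
    if run_lengths is None:
        run_lengths = [series.size]
    if sum(run_lengths) != series.size:
        raise ValidationError("run lengths do not sum to the series length")
    out = np.empty_like(series)
    start = 0
    for n in run_lengths:
        if n < 3:
            raise SizingError("each run needs >= 3 samples")
        seg = _linear_detrend(series[start : start + n], type="linear")
        sd = seg.std()
        if sd < 1e-12:
            raise DegenerateSignalError("zero-variance segment cannot be normalized")
        out[start : start + n] = seg / sd
        start += n
    return out


def extract_timeseries(
    volume4d: np.ndarray,
    mask: np.ndarray,
    run_lengths: Sequence[int] | None = None,
) -> np.ndarray:
    """Voxel-averaged, linearly detrended, z-normalized ROI time series.

    The pipeline order is fixed: voxel-average over the mask, then remove the
    least-squares linear trend, then normalize to zero mean / unit variance,
    each applied per run segment.
    """
    volume4d = np.asarray(volume4d, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if volume4d.ndim != 4:
        raise ValidationError("expected a 4-D array (x, y, z, t)")
    if mask.shape != volume4d.shape[:3]:
        raise ValidationError("mask shape does not match the volume grid")
    if not mask.any():
        raise StructuralError("mask is empty")
    averaged = volume4d[mask].mean(axis=0)
    return normalize_series(averaged, run_lengths)
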