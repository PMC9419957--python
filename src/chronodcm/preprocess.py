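"""Nuisance regression and ROI time-series extraction.

ROIs are 6 mm spheres at MNI coordinates; the default network holds the
eight nodes analyzed throughout the package: four default-mode nodes (mPFC,
PCC, bilateral inferior parietal cortex), two salience nodes (anterior
insula, anterior cingulate), and two central-executive nodes (dorsolateral
and posterior prefrontal cortex).  Each ROI is summarised by its first
eigenvariate (principal-component time course) after the voxel series have
been cleaned of motion, white-matter and CSF signals by linear regression;
the WM/CSF regressors are themselves sphere eigenvariates at two fixed
coordinates in the brainstem/ventricle region.  The affine is authoritative
for all mm <-> voxel conversions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NetworkSpec",
    "ConfoundSet",
    "default_network",
    "sphere_mask",
    "eigenvariate",
    "nuisance_regress",
    "extract_roi_series",
    "load_nifti_series",
]

#: WM- and CSF-like reference coordinates (mm) for nuisance eigenvariates
WM_COORD = (0.0, -24.0, -33.0)
CSF_COORD = (0.0, -40.0, -5.0)
DEFAULT_RADIUS_MM = 6.0


@dataclass(frozen=True)
class NetworkSpec:
    """Named ROIs with MNI centres (mm) and a common sphere radius."""

    roi_names: tuple[str, ...]
    mni_centers: tuple[tuple[float, float, float], ...]
    radius_mm: float = DEFAULT_RADIUS_MM

    def __post_init__(self) -> None:
        if len(self.roi_names) != len(self.mni_centers):
            raise ValueError("need one centre per ROI name")
        if self.radius_mm <= 0:
            raise ValueError("radius must be positive")

    @property
    def n_rois(self) -> int:
        return len(self.roi_names)

    def to_json(self) -> str:
        return json.dumps(
            {
                "roi_names": list(self.roi_names),
                "mni_centers": [list(c) for c in self.mni_centers],
                "radius_mm": self.radius_mm,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "NetworkSpec":
        d = json.loads(text)
        return cls(
            roi_names=tuple(d["roi_names"]),
            mni_centers=tuple(tuple(c) for c in d["mni_centers"]),
            radius_mm=float(d["radius_mm"]),
        )


def default_network() -> NetworkSpec:
    """The 8-node DMN/SN/CEN network with 6 mm spheres."""
    return NetworkSpec(
        roi_names=(
            "mPFC",
            "PCC",
            "rIPC",
            "lIPC",
            "AI",
            "ACC",
            "dlPFC",
            "pPFC",
        ),
        mni_centers=(
            (3.0, 54.0, -2.0),
            (0.0, -52.0, 26.0),
            (48.0, -69.0, 35.0),
            (-50.0, -63.0, 32.0),
            (37.0, 25.0, -4.0),
            (4.0, 30.0, 30.0),
            (45.0, 16.0, 45.0),
            (54.0, -50.0, 50.0),
        ),
        radius_mm=DEFAULT_RADIUS_MM,
    )


@dataclass
class ConfoundSet:
    """Nuisance regressor matrix with named columns."""

    matrix: np.ndarray  # volumes x K
    names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("need one name per confound column")


def sphere_mask(
    center_mm: tuple[float, float, float],
    radius_mm: float,
    affine: np.ndarray,
    grid_shape: tuple[int, int, int],
) -> np.ndarray:
    """0-based voxel indices whose centres lie within ``radius_mm`` of the
    centre (Euclidean distance in mm through the affine).

    Returns an (n_voxels, 3) integer array.  Raises when the sphere misses
    the grid entirely.
    """
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError("affine must be 4x4")
    inv = np.linalg.inv(affine)
    center_vox = (inv @ np.array([*center_mm, 1.0]))[:3]
    # conservative bounding box from the voxel size along each world axis
    voxel_extent = np.linalg.norm(inv[:3, :3], axis=1)
    lo = np.maximum(np.floor(center_vox - radius_mm * voxel_extent - 1), 0).astype(int)
    hi = np.minimum(
        np.ceil(center_vox + radius_mm * voxel_extent + 1), np.array(grid_shape) - 1
    ).astype(int)
    if np.any(lo > hi):
        raise ValueError(f"sphere at {center_mm} lies entirely outside the grid")
    ii, jj, kk = np.meshgrid(
        *(np.arange(lo[d], hi[d] + 1) for d in range(3)), indexing="ij"
    )
    vox = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    mm = vox @ affine[:3, :3].T + affine[:3, 3]
    dist2 = np.sum((mm - np.asarray(center_mm)) ** 2, axis=1)
    inside = vox[dist2 <= radius_mm**2]
    if inside.size == 0:
        raise ValueError(f"no voxel centre within {radius_mm} mm of {center_mm}")
    return inside


def eigenvariate(block: np.ndarray) -> np.ndarray:
    """First principal-component time course of a volumes x voxels block.

    The block is column-demeaned; the component is scaled to unit variance
    and its sign fixed so the mean voxel loading is positive.
    """
    block = np.atleast_2d(np.asarray(block, dtype=float))
    if block.ndim != 2 or block.shape[0] < 2:
        raise ValueError("need a volumes x voxels block with at least 2 volumes")
    demeaned = block - block.mean(axis=0)
    if np.allclose(demeaned, 0.0):
        raise ValueError("degenerate block: all voxel series are constant")
    u, s, vt = np.linalg.svd(demeaned, full_matrices=False)
    course = u[:, 0]
    if vt[0].mean() < 0:
        course = -course
    sd = course.std()
    return course / sd


def nuisance_regress(series: np.ndarray, confounds) -> np.ndarray:
    """Least-squares residuals of each column after projecting out an
    intercept plus all confound columns."""
    y = np.atleast_2d(np.asarray(series, dtype=float))
    if isinstance(confounds, ConfoundSet):
        X = confounds.matrix
        names = confounds.names
    else:
        X = np.atleast_2d(np.asarray(confounds, dtype=float))
        names = [f"confound{k + 1}" for k in range(X.shape[1])]
    if X.shape[0] != y.shape[0]:
        raise ValueError("confounds and series must have the same number of volumes")
    design = np.column_stack([np.ones(y.shape[0]), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name the collinear columns for the error message
        bad = []
        keep = [0]
        for k in range(1, design.shape[1]):
            if np.linalg.matrix_rank(design[:, keep + [k]]) == len(keep):
                bad.append(names[k - 1])
            else:
                keep.append(k)
        raise ValueError(f"rank-deficient confound design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def extract_roi_series(
    volume_series: np.ndarray,
    affine: np.ndarray,
    spec: NetworkSpec | None = None,
    motion: np.ndarray | None = None,
    radius_mm: float | None = None,
) -> np.ndarray:
    """Volumes x ROI matrix of sphere eigenvariates after nuisance cleaning.

    WM and CSF eigenvariates are extracted at the fixed reference
    coordinates, combined with the motion regressors (if given), and
    regressed out of every ROI's voxel series before the eigenvariate is
    taken.
    """
    spec = spec or default_network()
    vol = np.asarray(volume_series, dtype=float)
    if vol.ndim != 4:
        raise ValueError("volume_series must be 4-D (x, y, z, volumes)")
    grid_shape = vol.shape[:3]
    radius = radius_mm or spec.radius_mm

    def block_for(center, label):
        try:
            vox = sphere_mask(center, radius, affine, grid_shape)
        except ValueError as err:
            raise ValueError(f"empty sphere for {label}: {err}") from err
        return vol[vox[:, 0], vox[:, 1], vox[:, 2], :].T  # volumes x voxels

    wm = eigenvariate(block_for(WM_COORD, "WM reference"))
    csf = eigenvariate(block_for(CSF_COORD, "CSF reference"))
    cols = [wm[:, None], csf[:, None]]
    names = ["wm", "csf"]
    if motion is not None:
        motion = np.atleast_2d(np.asarray(motion, dtype=float))
        cols.insert(0, motion)
        names = [f"motion{k + 1}" for k in range(motion.shape[1])] + names
    confounds = ConfoundSet(matrix=np.hstack(cols), names=names)

    out = np.empty((vol.shape[3], spec.n_rois))
    for r, (name, center) in enumerate(zip(spec.roi_names, spec.mni_centers)):
        block = block_for(center, name)
        cleaned = nuisance_regress(block, confounds)
        out[:, r] = eigenvariate(cleaned)
    return out


def load_nifti_series(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 4-D NIfTI file; returns (data, affine)."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise ValueError("expected a 4-D NIfTI image")
    return data, np.asarray(img.affine, dtype=float)
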