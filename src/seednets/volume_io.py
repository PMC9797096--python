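"""Volumetric I/O and the two preprocessing steps applied to released data:
a hard DFT highpass filter (2000 s default cutoff) and CSF/WM nuisance
regression.  All arithmetic runs in float64 regardless of on-disk dtype.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

Z_CLIP = 38.0  # shared clip for normal-deviate maps


@dataclass
class VolumeSeries:
    """One subject-session 4D image: (X, Y, Z, T) data, affine, TR in s."""

    data: np.ndarray
    affine: np.ndarray
    tr: float

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class MaskedMatrix:
    """T x V matrix of in-mask time-courses plus the voxel index list.

    Column order is fixed lexicographic with x fastest, so extract/insert is
    a lossless bijection on mask voxels.
    """

    values: np.ndarray                 # T x V, float64
    voxel_coords: np.ndarray           # V x 3 integer coordinates
    grid_shape: tuple[int, int, int]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]


def read_series(path: str | os.PathLike) -> VolumeSeries:
    """Load a 4D NIfTI; rejects non-4D images and NaN/Inf voxels."""
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(
            f"{path}: expected a rank-4 image, got rank {img.ndim}")
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    bad = int(np.size(data) - np.isfinite(data).sum())
    if bad:
        raise ValueError(f"{path}: {bad} non-finite voxel values")
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    return VolumeSeries(data=data, affine=np.asarray(img.affine), tr=tr)


def write_series(series: VolumeSeries, path: str | os.PathLike) -> Path:
    """Write a VolumeSeries as float32 NIfTI-1, TR stored in the header."""
    img = nib.Nifti1Image(np.asarray(series.data, dtype=np.float32),
                          series.affine)
    zooms = list(img.header.get_zooms())
    zooms[3] = series.tr
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    return Path(path)


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Load a 3D integer mask/atlas volume."""
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"{path}: expected a rank-3 image, got {img.ndim}")
    return np.asarray(np.rint(img.get_fdata()), dtype=np.int32)


def _mask_coords(mask: np.ndarray) -> np.ndarray:
    """In-mask coordinates sorted lexicographically with x fastest."""
    coords = np.argwhere(mask != 0)
    order = np.lexsort((coords[:, 0], coords[:, 1], coords[:, 2]))
    return coords[order]


def extract_masked_matrix(series: VolumeSeries, mask: np.ndarray) -> MaskedMatrix:
    """Pull the time-courses of all in-mask voxels into a T x V matrix."""
    if mask.shape != series.grid_shape:
        raise ValueError(
            f"mask grid {mask.shape} != series grid {series.grid_shape}")
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary")
    if not mask.any():
        raise ValueError("mask is empty")
    coords = _mask_coords(mask)
    vals = series.data[coords[:, 0], coords[:, 1], coords[:, 2], :]
    return MaskedMatrix(values=np.asarray(vals.T, dtype=np.float64),
                        voxel_coords=coords, grid_shape=series.grid_shape)


def insert_masked_matrix(matrix: MaskedMatrix, fill: float = 0.0) -> np.ndarray:
    """Inverse of extract: (X, Y, Z, T) volume, out-of-mask voxels = fill."""
    T = matrix.values.shape[0]
    out = np.full(matrix.grid_shape + (T,), fill, dtype=np.float64)
    c = matrix.voxel_coords
    out[c[:, 0], c[:, 1], c[:, 2], :] = matrix.values.T
    return out


def map_to_volume(values: np.ndarray, coords: np.ndarray,
                  grid_shape: tuple[int, int, int],
                  fill: float = 0.0) -> np.ndarray:
    """Scatter a length-V vector back onto the 3D grid."""
    out = np.full(grid_shape, fill, dtype=np.float64)
    out[coords[:, 0], coords[:, 1], coords[:, 2]] = values
    return out


def highpass_filter(values: np.ndarray, tr: float,
                    cutoff_seconds: float = 2000.0) -> np.ndarray:
    """Hard DFT highpass: zero the DC bin and every bin strictly below
    1/cutoff Hz; all other bins pass with unit gain.  Output is zero-mean
    per column."""
    values = np.asarray(values, dtype=np.float64)
    T = values.shape[0]
    if T < 4:
        raise ValueError("need at least 4 time points to filter")
    if cutoff_seconds <= 2 * tr:
        raise ValueError("cutoff_seconds must exceed 2*TR")
    freqs = np.fft.rfftfreq(T, d=tr)
    keep = freqs >= (1.0 / cutoff_seconds)
    keep[0] = False  # DC always removed
    spec = np.fft.rfft(values, axis=0)
    spec[~keep] = 0.0
    return np.fft.irfft(spec, n=T, axis=0)


def regress_nuisance(values: np.ndarray, regressors: np.ndarray) -> np.ndarray:
    """Residualise each column against the regressors (intercept added).

    Output columns are zero-mean and orthogonal to every regressor column.
    """
    Y = np.asarray(values, dtype=np.float64)
    R = np.asarray(regressors, dtype=np.float64)
    if R.ndim == 1:
        R = R[:, None]
    T = Y.shape[0]
    if R.shape[0] != T:
        raise ValueError("regressor rows must match time points")
    if R.shape[1] >= T:
        raise ValueError("more regressors than time points")
    X = np.column_stack([np.ones(T), R])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the first column that adds no rank
        bad = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) <= np.linalg.matrix_rank(X[:, :j]):
                bad.append(j - 1)
        raise ValueError(f"collinear regressor columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ beta


def mean_timecourse(series: VolumeSeries, mask: np.ndarray) -> np.ndarray:
    """Unweighted mean over mask voxels at each time point (CSF/WM style)."""
    mm = extract_masked_matrix(series, (mask != 0).astype(np.uint8))
    return mm.values.mean(axis=1)


def preprocess_series(series: VolumeSeries, analysis_mask: np.ndarray,
                      nuisance_masks: "list[np.ndarray] | None" = None,
                      cutoff_seconds: float = 2000.0) -> MaskedMatrix:
    """Standard cleaning on top of released data: extract in-mask matrix,
    highpass filter, then regress out the (identically filtered) nuisance
    mean time-courses."""
    mm = extract_masked_matrix(series, analysis_mask)
    filtered = highpass_filter(mm.values, series.tr, cutoff_seconds)
    if nuisance_masks:
        regs = np.column_stack([mean_timecourse(series, m)
                                for m in nuisance_masks])
        regs = highpass_filter(regs, series.tr, cutoff_seconds)
        regs = regs[:, regs.std(axis=0) > 1e-12]  # drop degenerate regressors
        if regs.shape[1]:
            filtered = regress_nuisance(filtered, regs)
    return MaskedMatrix(values=filtered, voxel_coords=mm.voxel_coords,
                        grid_shape=mm.grid_shape)
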