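"""Seed-restricted group spatial ICA.

Per-session seed matrices are demeaned, variance-normalised and temporally
concatenated; the stacked matrix is whitened by PCA to exactly ``d``
components and unmixed along the voxel dimension with fixed-point (log-cosh)
ICA, so the components are spatial maps over seed voxels and the mixing
matrix holds their group time-courses.  Maps are z-scored over seed voxels,
oriented to nonnegative skewness and ordered by explained variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA, FastICA

from .volume_io import MaskedMatrix

logger = logging.getLogger(__name__)

ICA_TOL = 1e-6
ICA_MAX_ITER = 1000
ICA_RESTARTS = 5


@dataclass
class ICResult:
    """Result of a group spatial ICA at one model order."""

    dimension: int
    spatial_maps: np.ndarray        # d x V, z-scored per map
    mixing: np.ndarray              # (sum_s T_s) x d group time-courses
    explained_variance: np.ndarray  # d nonnegative reals, descending
    voxel_coords: np.ndarray
    grid_shape: tuple[int, int, int]
    block_order: "list | None" = None


def concat_subjects(matrices: "list[MaskedMatrix]",
                    order: "list | None" = None) -> MaskedMatrix:
    """Temporal concatenation with per-block column standardisation.

    Each session block is demeaned and scaled to unit column SD before
    stacking, so no session dominates the group decomposition.
    """
    if not matrices:
        raise ValueError("no matrices to concatenate")
    ref = matrices[0]
    blocks = []
    for i, m in enumerate(matrices):
        if m.n_voxels != ref.n_voxels:
            name = order[i] if order is not None else f"block {i}"
            raise ValueError(
                f"voxel count mismatch for {name}: {m.n_voxels} != {ref.n_voxels}")
        v = m.values - m.values.mean(axis=0)
        sd = v.std(axis=0)
        sd[sd == 0] = 1.0
        blocks.append(v / sd)
    return MaskedMatrix(values=np.vstack(blocks),
                        voxel_coords=ref.voxel_coords,
                        grid_shape=ref.grid_shape)


def group_spatial_ica(group: MaskedMatrix, d: int, rng_seed: int) -> ICResult:
    """PCA-whiten to d components, then fixed-point ICA on the voxel axis.

    Deterministic for a fixed seed; on non-convergence the unmixing is
    restarted with seeds rng_seed+1, ... (up to ICA_RESTARTS times).
    """
    X = np.asarray(group.values, dtype=np.float64)  # time x voxels
    n_rows, V = X.shape
    if not 1 <= d <= min(n_rows, V):
        raise ValueError(f"d={d} outside [1, {min(n_rows, V)}]")
    Xs = X.T  # voxels are observations, time points are features
    Xs = Xs - Xs.mean(axis=0)
    rank = np.linalg.matrix_rank(Xs)
    if d > rank:
        raise ValueError(f"d={d} exceeds numerical rank {rank}")

    pca = PCA(n_components=d, svd_solver="full")
    scores = pca.fit_transform(Xs)                    # V x d
    explained = pca.explained_variance_.copy()

    if d == 1:
        sources = scores
        mixing_red = np.eye(1)
    else:
        white = scores / np.sqrt(pca.explained_variance_)  # unit-variance
        sources = None
        import warnings

        for attempt in range(ICA_RESTARTS + 1):
            seed = rng_seed + attempt
            ica = FastICA(n_components=d, whiten=False, fun="logcosh",
                          tol=ICA_TOL, max_iter=ICA_MAX_ITER,
                          random_state=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                s = ica.fit_transform(white)
            if ica.n_iter_ >= ICA_MAX_ITER:
                logger.warning("ICA did not converge (seed %d), restarting", seed)
                continue
            sources = s
            mixing_white = ica.mixing_  # white = sources @ mixing_white.T
            break
        if sources is None:
            raise RuntimeError(
                f"fixed-point ICA failed to converge after {ICA_RESTARTS} restarts")
        # map back: scores = white * sqrt(ev) = sources @ (mixing_white.T * sqrt(ev))
        mixing_red = mixing_white * np.sqrt(pca.explained_variance_)[:, None]

    # time-courses: Xs ~ sources @ (mixing_red.T @ pca.components_) + mean
    # group mixing (time x d): rows of pca.components_ combined per source
    A_time = (pca.components_.T @ mixing_red)        # n_rows x d

    # per-component explained variance of the reconstruction
    src_var = sources.var(axis=0)
    ev = src_var * (A_time ** 2).sum(axis=0)
    order = np.argsort(-ev, kind="stable")
    sources = sources[:, order]
    A_time = A_time[:, order]
    ev = ev[order]

    maps = sources.T                                  # d x V
    maps, A_time = _zscore_and_record(maps, A_time)
    result = ICResult(dimension=d, spatial_maps=maps, mixing=A_time,
                      explained_variance=ev,
                      voxel_coords=group.voxel_coords,
                      grid_shape=group.grid_shape)
    return orient_components(result)


def _zscore_and_record(maps: np.ndarray, mixing: np.ndarray):
    """Z-score each map over voxels, rescaling mixing to keep the product."""
    mu = maps.mean(axis=1, keepdims=True)
    sd = maps.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    maps = (maps - mu) / sd
    mixing = mixing * sd.ravel()[None, :]
    return maps, mixing


def orient_components(result: ICResult) -> ICResult:
    """Flip map/mixing pairs so every spatial map has nonnegative skewness.

    The product mixing @ maps is invariant; exactly zero-skew maps are left
    unchanged (logged).
    """
    maps = result.spatial_maps.copy()
    mixing = result.mixing.copy()
    for k in range(result.dimension):
        sk = stats.skew(maps[k])
        if sk < 0:
            maps[k] = -maps[k]
            mixing[:, k] = -mixing[:, k]
        elif sk == 0:
            logger.info("component %d has exactly zero skewness; not flipped", k)
    return replace(result, spatial_maps=maps, mixing=mixing)
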