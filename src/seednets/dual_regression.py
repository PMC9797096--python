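"""Dual regression: seed IC maps -> session time-courses -> whole-brain
subject Z maps -> group-level one-sample Z maps with optional sign-flip
permutation p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .volume_io import MaskedMatrix, Z_CLIP

logger = logging.getLogger(__name__)

COND_LIMIT = 1e8


def t_to_z(t: np.ndarray, df: float) -> np.ndarray:
    """Map Student-t deviates to standard-normal deviates, clipped at
    +/-Z_CLIP.  Uses the survival function on the |t| side for stability."""
    t = np.asarray(t, dtype=np.float64)
    sf = stats.t.sf(np.abs(t), df)
    with np.errstate(divide="ignore"):
        z = stats.norm.isf(sf)
    z = np.where(np.isfinite(z), z, Z_CLIP)
    z = np.clip(z, -Z_CLIP, Z_CLIP)
    return np.sign(t) * z


def stage1_timecourses(seed: MaskedMatrix, spatial_maps: np.ndarray) -> np.ndarray:
    """Joint regression of every time point's seed pattern on all d maps.

    Returns a T x d matrix of least-squares time-courses, each demeaned and
    scaled to unit SD.
    """
    M = np.asarray(spatial_maps, dtype=np.float64)  # d x V
    if M.shape[1] != seed.n_voxels:
        raise ValueError("spatial maps are not on the seed voxel index list")
    X = M.T  # V x d design
    X = X - X.mean(axis=0)
    sv = np.linalg.svd(X, compute_uv=False)
    if sv[-1] == 0 or sv[0] / sv[-1] > COND_LIMIT:
        raise ValueError(
            f"degenerate stage-1 design (condition number "
            f"{np.inf if sv[-1] == 0 else sv[0] / sv[-1]:.3g})")
    Y = seed.values - seed.values.mean(axis=1, keepdims=True)  # demean patterns
    C, *_ = np.linalg.lstsq(X, Y.T, rcond=None)   # d x T
    C = C.T
    C = C - C.mean(axis=0)
    sd = C.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("a recovered time-course is constant")
    return C / sd


@dataclass
class SubjectFCMap:
    """Whole-brain per-component beta/t/Z maps for one subject-session."""

    subject_id: str
    session_id: str
    beta: np.ndarray   # d x V
    t: np.ndarray      # d x V
    z: np.ndarray      # d x V, clipped at +/-Z_CLIP
    voxel_coords: np.ndarray
    grid_shape: tuple[int, int, int]


def stage2_subject_maps(brain: MaskedMatrix, timecourses: np.ndarray,
                        subject_id: str = "", session_id: str = "") -> SubjectFCMap:
    """Per voxel, joint regression of its time-course on all d stage-1
    time-courses.  t uses T-d-1 df (intercept via demeaning); Z is the
    normal deviate of the t tail probability, clipped at +/-Z_CLIP."""
    C = np.asarray(timecourses, dtype=np.float64)
    T, d = C.shape
    if brain.values.shape[0] != T:
        raise ValueError("time-course length does not match data")
    if T <= d + 1:
        raise ValueError(f"need T > d+1 time points (T={T}, d={d})")
    X = C - C.mean(axis=0)
    Y = brain.values - brain.values.mean(axis=0)
    XtX = X.T @ X
    XtX_inv = np.linalg.pinv(XtX)
    beta = XtX_inv @ (X.T @ Y)                     # d x V
    resid = Y - X @ beta
    df = T - d - 1
    sigma2 = (resid ** 2).sum(axis=0) / df         # V
    se = np.sqrt(np.maximum(np.einsum("kk->k", XtX_inv)[:, None] * sigma2[None, :],
                            0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    # zero residual variance: perfect fit -> saturate, negligible beta -> 0
    exact = se == 0
    t = np.where(exact & (np.abs(beta) > 1e-8), np.sign(beta) * 1e6, t)
    z = t_to_z(t, df)
    return SubjectFCMap(subject_id=subject_id, session_id=session_id,
                        beta=beta, t=t, z=z,
                        voxel_coords=brain.voxel_coords,
                        grid_shape=brain.grid_shape)


@dataclass
class GroupFCMap:
    """Group one-sample Z map per component, plus permutation p if asked."""

    z: np.ndarray                    # d x V
    n_subjects: int
    voxel_coords: np.ndarray
    grid_shape: tuple[int, int, int]
    perm_p: "np.ndarray | None" = None
    n_permutations: int = 0
    rng_seed: "int | None" = None
    n_clipped: int = 0


def _average_sessions(subject_maps: "list[SubjectFCMap]") -> dict[str, np.ndarray]:
    per_subject: dict[str, list[np.ndarray]] = {}
    for m in subject_maps:
        per_subject.setdefault(m.subject_id, []).append(m.z)
    return {sid: np.mean(zs, axis=0) for sid, zs in sorted(per_subject.items())}


def group_map(subject_maps: "list[SubjectFCMap]",
              n_permutations: int = 0,
              rng_seed: int = 0) -> GroupFCMap:
    """Voxelwise one-sample test across subjects (sessions averaged first),
    converted to Z; optional sign-flip permutation p-values.

    Symmetric under subject and session reordering by construction.
    """
    if not subject_maps:
        raise ValueError("no subject maps")
    averaged = _average_sessions(subject_maps)
    if len(averaged) < 2:
        raise ValueError("need at least 2 subjects for a group map")
    stack = np.stack(list(averaged.values()))       # n x d x V
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    df = n - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_var = sd == 0
    n_clipped = int(np.count_nonzero(zero_var & (mean != 0)))
    if n_clipped:
        logger.warning("%d zero-variance voxels clipped to +/-%g",
                       n_clipped, Z_CLIP)
    t = np.where(zero_var, 0.0, t)
    z = t_to_z(t, df)
    z = np.where(zero_var, np.where(mean == 0, 0.0, np.sign(mean) * Z_CLIP), z)

    perm_p = None
    if n_permutations > 0:
        rng = np.random.default_rng(rng_seed)
        t_obs = np.abs(np.where(np.isfinite(t), t, np.sign(t) * 1e6))
        count = np.ones_like(t_obs)                  # include observed
        for _ in range(n_permutations):
            signs = rng.choice((-1.0, 1.0), size=n)[:, None, None]
            flipped = stack * signs
            m = flipped.mean(axis=0)
            s = flipped.std(axis=0, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                tp = np.abs(m / (s / np.sqrt(n)))
            tp = np.where(np.isnan(tp), 0.0, tp)
            count += tp >= t_obs - 1e-12
        perm_p = count / (n_permutations + 1)
    return GroupFCMap(z=z, n_subjects=n, voxel_coords=subject_maps[0].voxel_coords,
                      grid_shape=subject_maps[0].grid_shape, perm_p=perm_p,
                      n_permutations=n_permutations,
                      rng_seed=rng_seed if n_permutations else None,
                      n_clipped=n_clipped)
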