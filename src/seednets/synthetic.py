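"""Synthetic resting-state cohorts with known ground truth.

Generates multi-subject 4D volumes in which K latent network time-courses
drive (a) coupling patterns inside a labelled seed region whose clusters cut
across subregion boundaries and (b) disjoint whole-brain network blocks that
play the role of reference resting-state networks.  Noise is white or AR(1),
subjects carry a random intercept shared across their sessions, right-
hemisphere seed voxels get a multiplicative coupling offset, and one
designated subregion receives a fear-score-dependent coupling boost.  Every
quantity needed for parameter-recovery tests is returned as a ground-truth
record and serialised alongside the data.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .volume_io import VolumeSeries, write_series

# Nine seed subregions (amygdaloid nuclei) and their large-scale divisions.
NUCLEI: tuple[str, ...] = ("AB", "Ba", "La", "PL", "Ce", "Me", "AAA", "Co", "CAT")
DIVISIONS: dict[str, str] = {
    "AB": "LB", "Ba": "LB", "La": "LB", "PL": "LB",
    "Ce": "CM", "Me": "CM",
    "AAA": "SF", "Co": "SF", "CAT": "SF",
}

#: Canonical reference-network names, in template order.
NETWORK_NAMES: tuple[str, ...] = (
    "Visual", "Somatomotor", "DorsalAttention", "VentralAttention",
    "Limbic", "ExecutiveControl", "DefaultMode",
)


@dataclass(frozen=True)
class SubregionSpec:
    """One labelled block of the seed region."""

    label: int
    name: str
    hemisphere: str          # "L" or "R"
    division: str
    origin: tuple[int, int, int]
    shape: tuple[int, int, int]

    def slices(self) -> tuple[slice, slice, slice]:
        o, s = self.origin, self.shape
        return (slice(o[0], o[0] + s[0]),
                slice(o[1], o[1] + s[1]),
                slice(o[2], o[2] + s[2]))


@dataclass(frozen=True)
class FearEffect:
    """Coupling boost: gain 1 + slope * (score - cohort median) applied to
    the designated subregion's coupling with the designated network."""

    subregion: str = "Co"
    network: int = 1
    slope: float = 0.05


def default_seed_region_spec(grid_shape: tuple[int, int, int]) -> list[SubregionSpec]:
    """Nine 2x2x2 nucleus blocks per hemisphere in the anterior (low-y) part
    of the grid; the template lattice is restricted to y >= 10 so seed and
    network blocks never collide."""
    nx, ny, nz = grid_shape
    if nx < 16 or ny < 14 or nz < 12:
        raise ValueError(
            f"grid {grid_shape} too small for the default seed layout; "
            "need at least (16, 14, 12)"
        )
    specs: list[SubregionSpec] = []
    for i, name in enumerate(NUCLEI):
        y0 = 1 + 3 * (i % 3)
        z0 = 2 + 3 * (i // 3)
        for hemi, x0, base in (("L", 3, 1), ("R", nx - 6, 11)):
            specs.append(SubregionSpec(
                label=base + i, name=name, hemisphere=hemi,
                division=DIVISIONS[name],
                origin=(x0, y0, z0), shape=(3, 3, 2)))
    return specs


def default_loading_matrix(n_networks: int = 3) -> np.ndarray:
    """Subregion-by-network coupling weights (rows follow NUCLEI order).

    Each network loads a distinct dominant nucleus plus secondary ones and
    every configuration cuts across the LB/CM/SF divisions; the three
    subregion sets are disjoint (well-separated sources keep the spatial
    decomposition identifiable) and La is deliberately unloaded.
    """
    weights = {
        0: {"CAT": 1.0, "PL": 0.8, "Ba": 0.5},      # somatomotor-like
        1: {"Co": 1.0, "AAA": 0.7, "Ce": 0.4},      # ventral-attention-like
        2: {"Me": 1.0, "AB": 0.7},                  # default-mode-like
    }
    if n_networks > len(weights):
        raise ValueError(f"no default loadings for {n_networks} networks")
    L = np.zeros((len(NUCLEI), n_networks))
    for k in range(n_networks):
        for name, w in weights[k].items():
            L[NUCLEI.index(name), k] = w
    return L


@dataclass
class SyntheticConfig:
    """All knobs of the generator; defaults define the study conditions."""

    grid_shape: tuple[int, int, int] = (24, 24, 12)
    n_subjects: int = 20
    n_sessions_per_subject: int = 2
    n_timepoints: int = 200
    tr_seconds: float = 1.0
    n_networks: int = 3
    n_templates: int = 7
    seed_region_spec: list[SubregionSpec] | None = None
    loading_matrix: np.ndarray | None = None
    network_snr: float = 1.0
    ar1_coef: float = 0.3
    cluster_fraction: float = 0.4
    subject_sd: float = 0.1
    hemisphere_offset: float = 0.2
    fear_effect: FearEffect = field(default_factory=FearEffect)
    fear_group_means: tuple[float, float] = (44.0, 55.2)
    fear_group_sds: tuple[float, float] = (4.9, 4.5)
    rng_seed: int = 42

    def resolved_spec(self) -> list[SubregionSpec]:
        return (self.seed_region_spec if self.seed_region_spec is not None
                else default_seed_region_spec(self.grid_shape))

    def resolved_loading(self) -> np.ndarray:
        L = (self.loading_matrix if self.loading_matrix is not None
             else default_loading_matrix(self.n_networks))
        return np.asarray(L, dtype=float)

    def validate(self) -> None:
        if min(self.grid_shape) < 1 or len(self.grid_shape) != 3:
            raise ValueError("grid_shape must be 3 positive integers")
        for name in ("n_subjects", "n_sessions_per_subject", "n_timepoints",
                     "n_networks"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not 0 <= self.ar1_coef < 1:
            raise ValueError("ar1_coef must lie in [0, 1)")
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be nonnegative")
        if self.network_snr <= 0:
            raise ValueError("network_snr must be positive")
        if self.n_networks > self.n_templates:
            raise ValueError("n_networks must not exceed n_templates")
        spec = self.resolved_spec()
        n_seed = sum(int(np.prod(s.shape)) for s in spec)
        if int(np.prod(self.grid_shape)) < 8 * n_seed:
            raise ValueError(
                f"grid holds {int(np.prod(self.grid_shape))} voxels, fewer than "
                f"8x the {n_seed} seed voxels")
        L = self.resolved_loading()
        n_names = len({s.name for s in spec})
        if L.shape != (n_names, self.n_networks):
            raise ValueError(
                f"loading_matrix shape {L.shape} does not match "
                f"{n_names} subregions x {self.n_networks} networks")


@dataclass
class GroundTruth:
    """Everything a recovery test needs to score the pipeline."""

    latents: dict[tuple[str, str], np.ndarray]          # (sub, ses) -> T x K
    template_assignment: list[int]                      # network k -> template idx
    rankings: list[list[str]]                           # per network, loading desc
    fear_effect: FearEffect
    fear_scores: dict[str, float]
    subject_intercepts: dict[str, float]
    nucleus_order: tuple[str, ...] = NUCLEI
    seed_patterns: "np.ndarray | None" = None           # K x V_seed couplings
    seed_coords: "np.ndarray | None" = None             # V_seed x 3, x fastest

    def to_json_dict(self) -> dict:
        return {
            "template_assignment": list(map(int, self.template_assignment)),
            "rankings": self.rankings,
            "fear_effect": dataclasses.asdict(self.fear_effect),
            "fear_scores": {k: float(v) for k, v in self.fear_scores.items()},
            "subject_intercepts": {k: float(v)
                                   for k, v in self.subject_intercepts.items()},
            "nucleus_order": list(self.nucleus_order),
            "latents": {f"{s}/{e}": np.round(c, 10).tolist()
                        for (s, e), c in sorted(self.latents.items())},
            "seed_patterns": (None if self.seed_patterns is None
                              else np.round(self.seed_patterns, 10).tolist()),
        }


# ---------------------------------------------------------------------------
# Templates and brain mask

def brain_mask_for(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Binary brain mask: the grid minus a one-voxel margin."""
    mask = np.zeros(grid_shape, dtype=np.uint8)
    mask[1:-1, 1:-1, 1:-1] = 1
    return mask


_BLOCK = 4          # template block edge, voxels
_STRIDE = 5         # lattice stride; > _BLOCK ensures disjointness
_Y_RESERVE = 10     # y < 10 reserved for the seed region


def _template_cells(grid_shape):
    nx, ny, nz = grid_shape
    xs = [x for x in range(1, nx - 1, _STRIDE) if x + _BLOCK <= nx - 1]
    ys = [y for y in range(min(_Y_RESERVE, max(1, ny - _BLOCK - 1)), ny - 1,
                           _STRIDE) if y + _BLOCK <= ny - 1]
    zs = [z for z in range(1, nz - 1, _STRIDE) if z + _BLOCK <= nz - 1]
    return [(x, y, z) for x in xs for y in ys for z in zs]


def make_reference_templates(
    n_networks: int, grid_shape: tuple[int, int, int], rng_seed: int
) -> tuple[list[np.ndarray], np.ndarray]:
    """Binary, pairwise-disjoint network blocks inside the brain mask.

    Returns ``(templates, brain_mask)``.  Placement is a deterministic draw
    from a fixed block lattice, so equal seeds give voxelwise-identical
    volumes.
    """
    if n_networks < 1:
        raise ValueError("n_networks must be >= 1")
    mask = brain_mask_for(grid_shape)
    cells = _template_cells(grid_shape)
    if n_networks > len(cells):
        raise ValueError(
            f"grid {grid_shape} hosts only {len(cells)} disjoint "
            f"{_BLOCK}^3 template blocks but {n_networks} were requested; "
            f"enlarge the grid (roughly {_STRIDE} voxels per template per axis)")
    if n_networks * _BLOCK ** 3 >= 0.8 * mask.sum():
        raise ValueError("templates would cover >= 80% of the brain mask")
    rng = np.random.default_rng(rng_seed)
    chosen = sorted(rng.choice(len(cells), size=n_networks, replace=False))
    templates = []
    for ci in chosen:
        x, y, z = cells[ci]
        t = np.zeros(grid_shape, dtype=np.uint8)
        t[x:x + _BLOCK, y:y + _BLOCK, z:z + _BLOCK] = 1
        templates.append(t)
    return templates, mask


# ---------------------------------------------------------------------------
# Signal pieces

def latent_timecourses(T: int, k: int, tr: float, rng: np.random.Generator) -> np.ndarray:
    """Band-limited latents: white noise smoothed with a moving-average
    kernel (~10 s wide) and z-scored per column.  Zero mean by construction."""
    width = max(3, int(round(10.0 / tr)))
    raw = rng.standard_normal((T + width, k))
    kernel = np.ones(width) / width
    sm = np.apply_along_axis(lambda c: np.convolve(c, kernel, mode="valid"), 0, raw)
    sm = sm[:T]
    sm = sm - sm.mean(axis=0)
    sd = sm.std(axis=0)
    sd[sd == 0] = 1.0
    return sm / sd


def ar1_noise(T: int, n_series: int, coef: float, sd: float,
              rng: np.random.Generator) -> np.ndarray:
    """T x n stationary AR(1) noise with lag-1 autocorrelation ``coef`` and
    marginal standard deviation ``sd``."""
    if sd == 0:
        return np.zeros((T, n_series))
    if coef == 0:
        return sd * rng.standard_normal((T, n_series))
    burn = 50
    innov_sd = sd * math.sqrt(1.0 - coef ** 2)
    e = innov_sd * rng.standard_normal((T + burn, n_series))
    x = lfilter([1.0], [1.0, -coef], e, axis=0)
    return x[burn:]


def make_fear_scores(n_subjects: int,
                     group_means: tuple[float, float] = (44.0, 55.2),
                     group_sds: tuple[float, float] = (4.9, 4.5),
                     rng_seed: int = 0) -> np.ndarray:
    """Fear-affect scores: half from each of two normal groups, shuffled."""
    if n_subjects % 2:
        raise ValueError("n_subjects must be even for balanced fear groups")
    if any(s <= 0 for s in group_sds):
        raise ValueError("group SDs must be positive")
    rng = np.random.default_rng(rng_seed)
    half = n_subjects // 2
    lo = group_means[0] + group_sds[0] * rng.standard_normal(half)
    hi = group_means[1] + group_sds[1] * rng.standard_normal(half)
    scores = np.concatenate([lo, hi])
    return scores[rng.permutation(n_subjects)]


# ---------------------------------------------------------------------------
# Cohort assembly

@dataclass
class Cohort:
    """In-memory synthetic dataset (the on-disk layout mirrors this)."""

    config: SyntheticConfig
    sessions: dict[tuple[str, str], VolumeSeries]
    seed_mask: np.ndarray
    subregion_atlas: np.ndarray
    subregion_lookup: "list[dict]"
    brain_mask: np.ndarray
    templates: list[np.ndarray]
    parcellation: np.ndarray
    parcellation_lookup: "list[dict]"
    nuisance_atlas: np.ndarray
    participants: "list[dict]"
    truth: GroundTruth

    @property
    def subject_ids(self) -> list[str]:
        return sorted({s for s, _ in self.sessions})

    @property
    def session_ids(self) -> list[str]:
        return sorted({e for _, e in self.sessions})


def _build_parcellation(brain_mask, seed_mask, templates, block=6):
    """Whole-brain parcel atlas: cubic blocks intersected with the brain
    mask, excluding the seed region; hemisphere from the x midline."""
    nx, ny, nz = brain_mask.shape
    atlas = np.zeros(brain_mask.shape, dtype=np.int32)
    lookup = []
    label = 0
    for x0 in range(0, nx, block):
        for y0 in range(0, ny, block):
            for z0 in range(0, nz, block):
                sl = (slice(x0, x0 + block), slice(y0, y0 + block),
                      slice(z0, z0 + block))
                sel = (brain_mask[sl] > 0) & (seed_mask[sl] == 0)
                if not sel.any():
                    continue
                label += 1
                atlas[sl][sel] = label
                hemi = "L" if x0 + block / 2 <= nx / 2 else "R"
                # mirror-symmetric names so each region exists in L and R
                xm = min(x0, max(0, nx - block - x0))
                lookup.append({"label": label,
                               "name": f"parcel-{xm:02d}-{y0:02d}-{z0:02d}",
                               "hemisphere": hemi, "division": "cortex"})
    return atlas, lookup


def _nuisance_atlas(brain_mask, seed_mask, templates):
    """Two nuisance compartments (CSF-like, WM-like) taken from brain-mask
    voxels untouched by seed or templates."""
    occupied = seed_mask.astype(bool)
    for t in templates:
        occupied |= t.astype(bool)
    free = np.argwhere((brain_mask > 0) & ~occupied)
    n = min(len(free), 2 * 27)
    half = n // 2
    atlas = np.zeros(brain_mask.shape, dtype=np.int32)
    for i, (x, y, z) in enumerate(free[:n]):
        atlas[x, y, z] = 1 if i < half else 2
    return atlas


def simulate_cohort(config: SyntheticConfig) -> Cohort:
    """Generate a full cohort in memory; deterministic for fixed rng_seed."""
    config.validate()
    spec = config.resolved_spec()
    L = config.resolved_loading()
    names = list(dict.fromkeys(s.name for s in spec))  # stable order
    K = config.n_networks
    T = config.n_timepoints
    gx, gy, gz = config.grid_shape
    nvox = gx * gy * gz

    ss = np.random.SeedSequence(config.rng_seed)
    (s_templates, s_assign, s_fear, s_intercept, s_cov, s_jitter,
     s_data) = ss.spawn(7)

    templates, brain_mask = make_reference_templates(
        config.n_templates, config.grid_shape,
        int(s_templates.generate_state(1)[0] % (2 ** 31)))

    rng_assign = np.random.default_rng(s_assign)
    assignment = list(map(int, rng_assign.permutation(config.n_templates)[:K]))

    # seed masks / atlas
    seed_mask = np.zeros(config.grid_shape, dtype=np.uint8)
    atlas = np.zeros(config.grid_shape, dtype=np.int32)
    for s in spec:
        sl = s.slices()
        if atlas[sl].any():
            raise ValueError(f"subregion blocks overlap at label {s.label}")
        seed_mask[sl] = 1
        atlas[sl] = s.label
    if (seed_mask & np.any(np.stack(templates), axis=0).astype(np.uint8)).any():
        raise ValueError("seed region overlaps a reference template")
    lookup = [{"label": s.label, "name": s.name, "hemisphere": s.hemisphere,
               "division": s.division} for s in spec]

    # covariates
    n_sub = config.n_subjects
    subjects = [f"sub-{i + 1:02d}" for i in range(n_sub)]
    rng_cov = np.random.default_rng(s_cov)
    if n_sub % 2 == 0:
        scores = make_fear_scores(n_sub, config.fear_group_means,
                                  config.fear_group_sds,
                                  int(s_fear.generate_state(1)[0] % (2 ** 31)))
    else:  # odd cohorts draw from the pooled mixture
        mix = rng_cov.integers(0, 2, n_sub)
        scores = np.array([config.fear_group_means[m]
                           + config.fear_group_sds[m] * rng_cov.standard_normal()
                           for m in mix])
    median = float(np.median(scores))
    age_bands = rng_cov.choice(["22-25", "26-30", "31-35"], size=n_sub,
                               p=[0.3, 0.47, 0.23])
    genders = rng_cov.choice(["F", "M"], size=n_sub, p=[0.6, 0.4])
    rng_int = np.random.default_rng(s_intercept)
    intercepts = config.subject_sd * rng_int.standard_normal(n_sub)

    participants = [
        {"participant_id": sid, "age_band": age_bands[i], "gender": genders[i],
         "fear_score": float(np.round(scores[i], 6)), "qc_issues": ""}
        for i, sid in enumerate(subjects)
    ]

    # per-voxel coupling gain for seed voxels
    fear = config.fear_effect
    if fear.subregion not in names:
        raise ValueError(f"fear_effect subregion {fear.subregion!r} not in spec")
    if not 0 <= fear.network < K:
        raise ValueError("fear_effect network index out of range")

    flat = np.arange(nvox).reshape(config.grid_shape)
    tpl_flat = [flat[t.astype(bool)] for t in templates]
    brain_flat = flat[brain_mask.astype(bool)]
    noise_sd = 0.0 if math.isinf(config.network_snr) else 1.0 / config.network_snr

    # Per-network clusters inside the seed: each network activates a random
    # ~cluster_fraction subset of every subregion it loads, with mild
    # voxelwise gain variation.  Clusters are therefore graded hotspots
    # cutting across subregion labels rather than flat plateaus, which also
    # keeps the spatial sources sparse enough to be identifiable.
    from .volume_io import _mask_coords
    seed_coords = _mask_coords(seed_mask)
    n_seed = seed_coords.shape[0]
    seed_pos = {(int(x), int(y), int(z)): i
                for i, (x, y, z) in enumerate(seed_coords)}
    rng_jit = np.random.default_rng(s_jitter)

    block_pos: dict[int, np.ndarray] = {}
    block_flat: dict[int, np.ndarray] = {}
    for s in spec:
        sl = s.slices()
        xs, ys, zs = np.meshgrid(
            np.arange(sl[0].start, sl[0].stop),
            np.arange(sl[1].start, sl[1].stop),
            np.arange(sl[2].start, sl[2].stop), indexing="ij")
        pts = np.column_stack([xs.ravel(), ys.ravel(), zs.ravel()])
        block_pos[s.label] = np.array([seed_pos[tuple(p)] for p in map(tuple, pts)])
        block_flat[s.label] = flat[sl].ravel()

    seed_patterns = np.zeros((K, n_seed))
    for s in spec:
        g0 = L[names.index(s.name)].copy()
        if s.hemisphere == "R":
            g0 = g0 * (1.0 + config.hemisphere_offset)
        pos = block_pos[s.label]
        n_block = pos.size
        n_act = max(1, int(round(config.cluster_fraction * n_block)))
        for k in range(K):
            if g0[k] == 0:
                continue
            active = rng_jit.choice(n_block, size=n_act, replace=False)
            gains = rng_jit.uniform(0.7, 1.3, size=n_act)
            seed_patterns[k, pos[active]] = g0[k] * gains

    sessions: dict[tuple[str, str], VolumeSeries] = {}
    latents: dict[tuple[str, str], np.ndarray] = {}
    ses_ids = [f"ses-{j + 1:02d}" for j in range(config.n_sessions_per_subject)]
    data_children = s_data.spawn(n_sub * len(ses_ids))

    affine = np.diag([1.6, 1.6, 1.6, 1.0])
    for i, sid in enumerate(subjects):
        boost = 1.0 + fear.slope * (scores[i] - median)
        for j, ses in enumerate(ses_ids):
            rng = np.random.default_rng(data_children[i * len(ses_ids) + j])
            C = latent_timecourses(T, K, config.tr_seconds, rng)
            vol = np.zeros((T, nvox))
            for k, tpl_idx in enumerate(assignment):
                vol[:, tpl_flat[tpl_idx]] += C[:, [k]]
            for s in spec:
                pat = seed_patterns[:, block_pos[s.label]].copy()  # K x n_block
                if s.name == fear.subregion:
                    pat[fear.network] *= boost
                vol[:, block_flat[s.label]] += C @ pat
            vol[:, brain_flat] += intercepts[i]
            vol[:, brain_flat] += ar1_noise(T, brain_flat.size, config.ar1_coef,
                                            noise_sd, rng)
            data = vol.reshape(T, gx, gy, gz).transpose(1, 2, 3, 0)
            sessions[(sid, ses)] = VolumeSeries(
                data=data.astype(np.float32), affine=affine,
                tr=config.tr_seconds)
            latents[(sid, ses)] = C

    rankings = []
    for k in range(K):
        col = L[:, k]
        order = np.argsort(-col, kind="stable")
        rankings.append([names[i] for i in order if col[i] > 0])

    parcellation, parc_lookup = _build_parcellation(brain_mask, seed_mask,
                                                    templates)
    nuis = _nuisance_atlas(brain_mask, seed_mask, templates)

    truth = GroundTruth(
        latents=latents, template_assignment=assignment, rankings=rankings,
        fear_effect=fear,
        fear_scores={sid: float(scores[i]) for i, sid in enumerate(subjects)},
        subject_intercepts={sid: float(intercepts[i])
                            for i, sid in enumerate(subjects)},
        nucleus_order=tuple(names),
        seed_patterns=seed_patterns, seed_coords=seed_coords,
    )
    return Cohort(config=config, sessions=sessions, seed_mask=seed_mask,
                  subregion_atlas=atlas, subregion_lookup=lookup,
                  brain_mask=brain_mask, templates=templates,
                  parcellation=parcellation, parcellation_lookup=parc_lookup,
                  nuisance_atlas=nuis, participants=participants, truth=truth)


def _write_mask(arr: np.ndarray, affine: np.ndarray, path: Path) -> None:
    import nibabel as nib
    nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.int16), affine), str(path))


def write_cohort(cohort: Cohort, out_dir: str | os.PathLike) -> Path:
    """Write a cohort to disk in a BIDS-like layout; returns the root."""
    import pandas as pd

    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    if not os.access(root, os.W_OK):
        raise PermissionError(f"{root} is not writable")
    aff3 = np.diag([1.6, 1.6, 1.6, 1.0])

    _write_mask(cohort.seed_mask, aff3, root / "seed_mask.nii.gz")
    _write_mask(cohort.subregion_atlas, aff3, root / "subregion_atlas.nii.gz")
    _write_mask(cohort.brain_mask, aff3, root / "brain_mask.nii.gz")
    _write_mask(cohort.parcellation, aff3, root / "parcellation.nii.gz")
    _write_mask(cohort.nuisance_atlas, aff3, root / "nuisance_atlas.nii.gz")
    tdir = root / "templates"
    tdir.mkdir(exist_ok=True)
    for i, t in enumerate(cohort.templates):
        _write_mask(t, aff3, tdir / f"template-{i + 1:02d}.nii.gz")

    pd.DataFrame(cohort.subregion_lookup).to_csv(
        root / "subregion_labels.tsv", sep="\t", index=False)
    pd.DataFrame(cohort.parcellation_lookup).to_csv(
        root / "parcellation_labels.tsv", sep="\t", index=False)
    pd.DataFrame(cohort.participants).to_csv(
        root / "participants.tsv", sep="\t", index=False)

    for (sid, ses), series in sorted(cohort.sessions.items()):
        d = root / sid / ses
        d.mkdir(parents=True, exist_ok=True)
        write_series(series, d / "func.nii.gz")

    with open(root / "truth.json", "w") as fh:
        json.dump(cohort.truth.to_json_dict(), fh, sort_keys=True, indent=0)
    return root


def make_cohort(config: SyntheticConfig, out_dir: str | os.PathLike
                ) -> tuple[Path, GroundTruth]:
    """Generate and write a cohort; returns (root path, ground truth)."""
    cohort = simulate_cohort(config)
    root = write_cohort(cohort, out_dir)
    return root, cohort.truth
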