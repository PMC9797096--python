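"""End-to-end orchestration: QC filtering, preprocessing, the model-order
sweep, dual regression at the chosen order, template matching, parcel-level
mixed models, the split-half validation and the fear analysis.

``run_pipeline`` drives the on-disk layout written by the synthetic-data
generator (or any dataset following it); the in-memory helpers it wraps are
importable on their own and carry no I/O.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dual_regression as dr
from . import network_matching as nm
from . import parcel_stats as ps
from . import srica
from . import volume_io as vio
from .synthetic import Cohort, SyntheticConfig, simulate_cohort, write_cohort

logger = logging.getLogger(__name__)

QC_FLAGS = ("A", "B", "C", "D")


# ---------------------------------------------------------------------------
# QC

def apply_qc_filter(manifest: pd.DataFrame,
                    flags: tuple = QC_FLAGS) -> pd.DataFrame:
    """Drop participants carrying any of the given QC issue flags.

    ``manifest`` needs a unique ``participant_id`` column and a
    ``qc_issues`` column holding flag letters (empty string = clean).
    """
    ids = manifest["participant_id"]
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise ValueError(f"duplicate participant ids: {dupes}")
    issues = manifest.get("qc_issues", pd.Series("", index=manifest.index))
    issues = issues.fillna("").astype(str)
    flagged = issues.apply(lambda s: any(f in s for f in flags))
    retained = manifest.loc[~flagged].reset_index(drop=True)
    logger.info("QC filter: %d in, %d excluded, %d retained",
                len(manifest), int(flagged.sum()), len(retained))
    if retained.empty:
        logger.warning("QC filter removed every participant")
    return retained


# ---------------------------------------------------------------------------
# In-memory stages

def _submatrix(brain_mm: vio.MaskedMatrix, mask: np.ndarray) -> vio.MaskedMatrix:
    """Restrict a brain-mask matrix to the voxels of a nested mask."""
    gx, gy, gz = brain_mm.grid_shape
    def flat(c):
        return c[:, 0] + gx * c[:, 1] + gx * gy * c[:, 2]
    sub_coords = vio._mask_coords((mask != 0).astype(np.uint8))
    pos = {f: i for i, f in enumerate(flat(brain_mm.voxel_coords))}
    idx = np.array([pos[f] for f in flat(sub_coords)])
    return vio.MaskedMatrix(values=brain_mm.values[:, idx],
                            voxel_coords=sub_coords,
                            grid_shape=brain_mm.grid_shape)


def preprocess_cohort(cohort: Cohort, sessions: "list[str] | None" = None,
                      cutoff_seconds: float = 2000.0):
    """Highpass + nuisance-regress every session once over the brain mask,
    then carve out the seed sub-matrix.  Returns dicts keyed (sub, ses)."""
    nuis = [(cohort.nuisance_atlas == k).astype(np.uint8) for k in (1, 2)]
    nuis = [m for m in nuis if m.any()]
    brain, seed = {}, {}
    for key, series in sorted(cohort.sessions.items()):
        if sessions is not None and key[1] not in sessions:
            continue
        mm = vio.preprocess_series(series, cohort.brain_mask, nuis,
                                   cutoff_seconds)
        brain[key] = mm
        seed[key] = _submatrix(mm, cohort.seed_mask)
    return seed, brain


def dual_regress_sessions(ic: srica.ICResult, seed_mats: dict,
                          brain_mats: dict) -> "list[dr.SubjectFCMap]":
    maps = []
    for key in sorted(seed_mats):
        C = dr.stage1_timecourses(seed_mats[key], ic.spatial_maps)
        maps.append(dr.stage2_subject_maps(brain_mats[key], C,
                                           subject_id=key[0], session_id=key[1]))
    return maps


@dataclass
class SweepArtifacts:
    ic: srica.ICResult
    subject_maps: "list[dr.SubjectFCMap]"
    group: dr.GroupFCMap
    match: nm.MatchTable
    assignment: nm.Assignment


def dimension_sweep(seed_mats: dict, brain_mats: dict, templates,
                    brain_mask: np.ndarray, d_min: int, d_max: int,
                    r_star: float, rng_seed: int,
                    n_permutations: int = 0
                    ) -> tuple[nm.DimensionSweep, "dict[int, SweepArtifacts]"]:
    """Run srICA + dual regression + template matching over a model-order
    sweep.  Dimensions whose ICA degenerates (e.g. d above the data rank)
    are skipped with a warning."""
    group_matrix = srica.concat_subjects(
        [seed_mats[k] for k in sorted(seed_mats)], order=sorted(seed_mats))
    sweep = nm.DimensionSweep()
    artifacts: dict[int, SweepArtifacts] = {}
    for d in range(d_min, d_max + 1):
        try:
            ic = srica.group_spatial_ica(group_matrix, d, rng_seed + 100 * d)
            subject_maps = dual_regress_sessions(ic, seed_mats, brain_mats)
            group = dr.group_map(subject_maps, n_permutations=n_permutations,
                                 rng_seed=rng_seed + 7)
            match = nm.match_components(group.z, templates, brain_mask,
                                        group.voxel_coords, r_star=r_star)
            assignment = nm.assign_networks(match)
        except (ValueError, RuntimeError) as exc:
            logger.warning("dimension %d skipped: %s", d, exc)
            continue
        sweep.add(d, match, assignment)
        artifacts[d] = SweepArtifacts(ic, subject_maps, group, match, assignment)
    return sweep, artifacts


def _cached_preprocess(cohort: Cohort, sessions, out_dir: Path,
                       cfg_hash: str, tag: str):
    """Preprocess with an on-disk cache so reruns of the same configuration
    resume instead of recomputing."""
    cache = out_dir / "cache" / f"preproc-{cfg_hash}-{tag}.npz"
    if cache.exists():
        with np.load(cache, allow_pickle=False) as z:
            keys = [tuple(k.split("|")) for k in z["keys"]]
            seed = {k: vio.MaskedMatrix(z[f"seed{i}"], z["seed_coords"],
                                        tuple(z["grid"]))
                    for i, k in enumerate(keys)}
            brain = {k: vio.MaskedMatrix(z[f"brain{i}"], z["brain_coords"],
                                         tuple(z["grid"]))
                     for i, k in enumerate(keys)}
        logger.info("[preprocess] cache hit for %s split", tag)
        return seed, brain
    seed, brain = preprocess_cohort(cohort, sessions)
    cache.parent.mkdir(parents=True, exist_ok=True)
    keys = sorted(seed)
    payload = {"keys": np.array(["|".join(k) for k in keys]),
               "grid": np.array(next(iter(seed.values())).grid_shape),
               "seed_coords": next(iter(seed.values())).voxel_coords,
               "brain_coords": next(iter(brain.values())).voxel_coords}
    for i, k in enumerate(keys):
        payload[f"seed{i}"] = seed[k].values
        payload[f"brain{i}"] = brain[k].values
    np.savez_compressed(cache, **payload)
    return seed, brain


# ---------------------------------------------------------------------------
# Pipeline config and driver

@dataclass
class PipelineConfig:
    """Run configuration; ``synthetic`` holds the generator settings."""

    output_dir: str = "seednets-out"
    d_min: int = 1
    d_max: int = 10
    r_star: float = 0.4
    n_permutations: int = 0
    rng_seed: int = 0
    test_sessions: "list[str]" = field(default_factory=lambda: ["ses-01"])
    validation_sessions: "list[str]" = field(default_factory=lambda: ["ses-02"])
    qc_flags: tuple = QC_FLAGS
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    write_data: bool = False

    def validate(self) -> None:
        if not (1 <= self.d_min <= self.d_max):
            raise ValueError("need 1 <= d_min <= d_max")
        if not 0 < self.r_star < 1:
            raise ValueError("r_star must lie in (0, 1)")
        if self.n_permutations < 0:
            raise ValueError("n_permutations must be >= 0")
        overlap = set(self.test_sessions) & set(self.validation_sessions)
        if overlap:
            raise ValueError(f"sessions in both splits: {sorted(overlap)}")
        self.synthetic.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"].pop("seed_region_spec", None)
        lm = d["synthetic"].get("loading_matrix")
        if lm is not None:
            d["synthetic"]["loading_matrix"] = np.asarray(lm).tolist()
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("output_dir", None)  # analysis parameters only
        blob = yaml.safe_dump(json.loads(json.dumps(d, default=str)),
                              sort_keys=True)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        syn = raw.pop("synthetic", {})
        cfg = cls(**raw)
        if syn:
            fe = syn.pop("fear_effect", None)
            cfg.synthetic = SyntheticConfig(**syn)
            if fe:
                from .synthetic import FearEffect
                cfg.synthetic.fear_effect = FearEffect(**fe)
            if isinstance(cfg.synthetic.grid_shape, list):
                cfg.synthetic.grid_shape = tuple(cfg.synthetic.grid_shape)
        return cfg


def _write_table(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on a synthetic cohort and write the results tree.

    Returns a dict of the key results (also serialised under output_dir).
    Deterministic for a fixed rng_seed.
    """
    config.validate()
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()

    cohort = simulate_cohort(config.synthetic)
    if config.write_data:
        write_cohort(cohort, out / "data")

    manifest = pd.DataFrame(cohort.participants)
    retained = apply_qc_filter(manifest, config.qc_flags)
    if retained.empty:
        raise RuntimeError("QC filter retained no participants; refusing to run")
    keep = set(retained["participant_id"])
    cohort.sessions = {k: v for k, v in cohort.sessions.items() if k[0] in keep}

    logger.info("[preprocess] %d sessions", len(cohort.sessions))
    seed_t, brain_t = _cached_preprocess(cohort, config.test_sessions,
                                         out, cfg_hash, "test")
    seed_v, brain_v = _cached_preprocess(cohort, config.validation_sessions,
                                         out, cfg_hash, "validation")

    logger.info("[ica-sweep] d=%d..%d", config.d_min, config.d_max)
    sweep, artifacts = dimension_sweep(
        seed_t, brain_t, cohort.templates, cohort.brain_mask,
        config.d_min, config.d_max, config.r_star, config.rng_seed,
        n_permutations=config.n_permutations)
    choice = nm.select_dimension(sweep)
    _write_table(choice.sweep_table, out / "sweep.tsv", cfg_hash)
    results: dict = {"config_hash": cfg_hash, "chosen_dimension": choice.dimension,
                     "n_unique_networks": choice.n_unique,
                     "detected": choice.detected}
    if not choice.detected:
        logger.warning("no network detected at any dimension")
        (out / "manifest.json").write_text(json.dumps(results, indent=2))
        return results

    art = artifacts[choice.dimension]
    matched = sorted(art.assignment.mapping)          # matched component ids
    _write_table(art.match.to_frame().reset_index(names="component"),
                 out / "match_table.tsv", cfg_hash)

    # group Z maps as NIfTI plus their metadata
    import nibabel as nib

    map_dir = out / "group_maps"
    map_dir.mkdir(exist_ok=True)
    aff = np.diag([1.6, 1.6, 1.6, 1.0])
    for k in range(art.group.z.shape[0]):
        vol = vio.map_to_volume(art.group.z[k], art.group.voxel_coords,
                                art.group.grid_shape)
        nib.save(nib.Nifti1Image(vol.astype(np.float32), aff),
                 str(map_dir / f"group_z_ic{k}.nii.gz"))
    (map_dir / "metadata.json").write_text(json.dumps({
        "n_subjects": art.group.n_subjects,
        "n_permutations": art.group.n_permutations,
        "rng_seed": art.group.rng_seed,
        "z_clip": vio.Z_CLIP,
        "n_zero_variance_clipped": art.group.n_clipped,
        "dimension": choice.dimension,
        "config_hash": cfg_hash,
    }, indent=2))

    # parcel-level whole-brain model on the matched components
    parc_lookup = pd.DataFrame(cohort.parcellation_lookup)
    table = ps.build_parcel_table(art.subject_maps, cohort.parcellation,
                                  parc_lookup)
    table = table[table["fc_map"].isin([f"IC{c}" for c in matched])]
    _write_table(table, out / "parcel_z.tsv", cfg_hash)
    fit = ps.fit_lmm(table, ps.LmmFormula(
        "mean_z", ["hemisphere", "fc_map", "region", "fc_map:region"],
        "participant_id"))
    an = ps.anova_type3(fit)
    _write_table(an, out / "anova_regions.tsv", cfg_hash)
    p_int = float(an.loc[an["term"] == "fc_map:region", "p"].iloc[0])
    if p_int < ps.ALPHA:
        contrasts = ps.effect_contrasts(fit, "fc_map", by="region")
        _write_table(contrasts, out / "region_contrasts.tsv", cfg_hash)

    # subregion (nucleus) model + ranking
    sub_lookup = pd.DataFrame(cohort.subregion_lookup)
    ntable = ps.build_parcel_table(art.subject_maps, cohort.subregion_atlas,
                                   sub_lookup)
    ntable = ntable[ntable["fc_map"].isin([f"IC{c}" for c in matched])]
    _write_table(ntable, out / "nucleus_z.tsv", cfg_hash)
    nfit = ps.fit_lmm(ntable, ps.LmmFormula(
        "mean_z", ["hemisphere", "fc_map", "region", "fc_map:region"],
        "participant_id"))
    nan_ = ps.anova_type3(nfit)
    _write_table(nan_, out / "anova_nuclei.tsv", cfg_hash)
    rankings = ps.pairwise_nucleus_rankings(nfit)
    rank_rows = []
    for comp, ranking in rankings.items():
        t = ranking.table.copy()
        t.insert(0, "fc_map", comp)
        rank_rows.append(t)
    _write_table(pd.concat(rank_rows, ignore_index=True),
                 out / "nucleus_ranking.tsv", cfg_hash)

    # validation: test-set IC maps applied to validation sessions
    val_maps = dual_regress_sessions(art.ic, seed_v,
                                     {k: brain_v[k] for k in sorted(seed_v)})
    val_group = dr.group_map(val_maps, rng_seed=config.rng_seed + 13)
    rs, val_match, val_assign = ps.compare_test_validation(
        art.group, val_group, cohort.templates, cohort.brain_mask,
        r_star=config.r_star)
    _write_table(pd.DataFrame({"component": list(range(len(rs))),
                               "test_validation_r": rs}),
                 out / "validation.tsv", cfg_hash)
    results["validation_r_matched"] = {int(c): float(rs[c]) for c in matched}
    results["validation_assignment"] = {int(c): int(n) for c, n
                                        in val_assign.mapping.items()}

    # fear analysis on the nucleus table
    scores = {p["participant_id"]: p["fear_score"] for p in cohort.participants
              if p["participant_id"] in keep}
    age = {p["participant_id"]: p["age_band"] for p in cohort.participants}
    gender = {p["participant_id"]: p["gender"] for p in cohort.participants}
    fear = ps.fear_group_analysis(ntable, scores, age, gender)
    _write_table(fear.anova, out / "fear_anova.tsv", cfg_hash)
    if fear.posthoc_by_region is not None:
        _write_table(fear.posthoc_by_region, out / "fear_posthoc.tsv", cfg_hash)
    results["fear_significant_nuclei"] = fear.significant_nuclei
    results["fear_group_by_region_p"] = fear.group_by_region_p

    results["assignment"] = {int(c): int(n)
                             for c, n in art.assignment.mapping.items()}
    results["truth_assignment"] = list(cohort.truth.template_assignment)
    results["elapsed_s"] = round(time.time() - t0, 2)
    results["rng_seed"] = config.rng_seed
    import sklearn

    results["versions"] = {"numpy": np.__version__, "pandas": pd.__version__,
                           "scikit-learn": sklearn.__version__}
    (out / "manifest.json").write_text(json.dumps(results, indent=2))
    return results
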