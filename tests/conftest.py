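"""Shared fixtures: small cohorts for unit tests and session-scoped
simulation runs reused across recovery tests."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

import seednets as sn
from seednets.pipeline import preprocess_cohort, dimension_sweep, \
    dual_regress_sessions
from seednets.srica import concat_subjects, group_spatial_ica
import seednets.parcel_stats as ps


@pytest.fixture(scope="session")
def small_cohort():
    cfg = sn.SyntheticConfig(n_subjects=6, n_timepoints=80, rng_seed=5)
    return sn.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_preprocessed(small_cohort):
    return preprocess_cohort(small_cohort, ["ses-01", "ses-02"])


def run_dimension_recovery(seed_i: int, d_max: int = 10):
    """One full parameter-recovery run: default cohort -> sweep -> choice."""
    cfg = sn.SyntheticConfig(rng_seed=seed_i)
    co = sn.simulate_cohort(cfg)
    seed, brain = preprocess_cohort(co, ["ses-01", "ses-02"])
    sweep, _ = dimension_sweep(seed, brain, co.templates, co.brain_mask,
                               1, d_max, 0.4, 1000 + seed_i)
    choice = sn.select_dimension(sweep)
    truth = set(co.truth.template_assignment)
    mapped = (set(choice.assignment.mapping.values())
              if choice.assignment else set())
    return {"chosen": choice.dimension, "n_unique": choice.n_unique,
            "mapped_templates": mapped, "truth_templates": truth,
            "correct": mapped == truth and choice.n_unique == 3}


@pytest.fixture(scope="session")
def dimension_recovery_runs():
    return [run_dimension_recovery(s) for s in (7, 8, 9, 10, 11)]


def run_fear_analysis(seed_i: int, slope: float):
    """Default cohort -> srICA at the true order -> dual regression ->
    nucleus table -> median-split fear model."""
    cfg = sn.SyntheticConfig(rng_seed=seed_i,
                             fear_effect=sn.FearEffect(slope=slope))
    co = sn.simulate_cohort(cfg)
    seed, brain = preprocess_cohort(co, ["ses-01", "ses-02"])
    g = concat_subjects([seed[k] for k in sorted(seed)])
    ic = group_spatial_ica(g, cfg.n_networks, 500 + seed_i)
    maps = dual_regress_sessions(ic, seed, brain)
    lookup = pd.DataFrame(co.subregion_lookup)
    table = ps.build_parcel_table(maps, co.subregion_atlas, lookup)
    scores = co.truth.fear_scores
    age = {p["participant_id"]: p["age_band"] for p in co.participants}
    gender = {p["participant_id"]: p["gender"] for p in co.participants}
    fear = ps.fear_group_analysis(table, scores, age, gender)
    return {"significant": fear.significant_nuclei,
            "gate_p": fear.group_by_region_p,
            "designated": co.truth.fear_effect.subregion}


@pytest.fixture(scope="session")
def fear_effect_runs():
    return [run_fear_analysis(s, 0.05) for s in (21, 22, 23, 24, 25)]


@pytest.fixture(scope="session")
def fear_null_runs():
    return [run_fear_analysis(s, 0.0) for s in (31, 32, 33, 34, 35)]


@pytest.fixture(scope="session")
def noise_free_cohort():
    cfg = sn.SyntheticConfig(n_subjects=2, network_snr=math.inf,
                             subject_sd=0.0, rng_seed=13)
    return sn.simulate_cohort(cfg)


def align_truth_patterns(cohort, voxel_coords) -> np.ndarray:
    """Ground-truth seed coupling patterns reindexed to a matrix's voxels."""
    key = {tuple(c): i for i, c in enumerate(cohort.truth.seed_coords)}
    idx = [key[tuple(c)] for c in voxel_coords]
    return cohort.truth.seed_patterns[:, idx]


def truth_brain_maps(cohort, voxel_coords) -> np.ndarray:
    """Generative whole-brain coupling map per network on given voxels:
    1 inside the assigned template, the cluster coupling inside the seed."""
    K = cohort.config.n_networks
    maps = np.zeros((K, voxel_coords.shape[0]))
    for k, tpl in enumerate(cohort.truth.template_assignment):
        maps[k] = cohort.templates[tpl][voxel_coords[:, 0], voxel_coords[:, 1],
                                        voxel_coords[:, 2]]
    seed_key = {tuple(c): i for i, c in enumerate(cohort.truth.seed_coords)}
    for j, c in enumerate(map(tuple, voxel_coords)):
        if c in seed_key:
            maps[:, j] = cohort.truth.seed_patterns[:, seed_key[c]]
    return maps
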