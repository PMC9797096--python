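"""Parcel-level statistics: mean-Z extraction, the mixed model and its
Type-III/EMM machinery, the subregion ranking statistic, the fear-group
analysis and the test/validation comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dual_regression import GroupFCMap, SubjectFCMap
from .lmm import (LmmFormula, ModelFit, anova_type3, effect_contrasts, emmeans,
                  fit_lmm, pairwise_group_contrasts, pairwise_z_matrix)
from .network_matching import MatchTable, Assignment, assign_networks

__all__ = [
    "extract_parcel_z", "build_parcel_table", "fit_lmm", "anova_type3",
    "emmeans", "effect_contrasts", "LmmFormula", "ModelFit",
    "rank_nuclei", "pairwise_nucleus_rankings", "two_sample_t",
    "median_split", "fear_group_analysis", "compare_test_validation",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05


# ---------------------------------------------------------------------------
# Parcel extraction

def extract_parcel_z(z_map: np.ndarray, voxel_coords: np.ndarray,
                     atlas: np.ndarray, lookup: pd.DataFrame) -> pd.DataFrame:
    """Mean Z over each labelled region of ``atlas``, split by the
    hemisphere tag carried in the lookup table.

    ``z_map`` is a length-V vector on ``voxel_coords``; the lookup needs
    columns label/name/hemisphere.  Empty labels are omitted with a warning;
    labels present in the atlas but absent from the lookup are an error.
    """
    labels_img = atlas[voxel_coords[:, 0], voxel_coords[:, 1], voxel_coords[:, 2]]
    present = set(np.unique(labels_img[labels_img > 0]).tolist())
    known = set(int(l) for l in lookup["label"])
    unknown = present - known
    if unknown:
        raise ValueError(f"atlas labels missing from lookup: {sorted(unknown)}")
    rows = []
    for _, rec in lookup.iterrows():
        lab = int(rec["label"])
        sel = labels_img == lab
        if not sel.any():
            logger.warning("label %d (%s) has no voxels on this grid; omitted",
                           lab, rec["name"])
            continue
        rows.append({"region": rec["name"], "hemisphere": rec["hemisphere"],
                     "label": lab, "mean_z": float(z_map[sel].mean())})
    return pd.DataFrame(rows)


def build_parcel_table(subject_maps: "list[SubjectFCMap]", atlas: np.ndarray,
                       lookup: pd.DataFrame,
                       component_ids: "list[int] | None" = None) -> pd.DataFrame:
    """Long ParcelZTable: one row per (participant, hemisphere, region,
    component) with the session-averaged mean Z."""
    per_subject: dict[str, list[SubjectFCMap]] = {}
    for m in subject_maps:
        per_subject.setdefault(m.subject_id, []).append(m)
    frames = []
    for sid, maps in sorted(per_subject.items()):
        z = np.mean([m.z for m in maps], axis=0)   # d x V
        comps = component_ids or list(range(z.shape[0]))
        for ci, comp in enumerate(comps):
            tab = extract_parcel_z(z[ci], maps[0].voxel_coords, atlas, lookup)
            tab.insert(0, "participant_id", sid)
            tab["fc_map"] = f"IC{comp}"
            frames.append(tab)
    out = pd.concat(frames, ignore_index=True)
    return out[["participant_id", "hemisphere", "region", "fc_map", "mean_z",
                "label"]]


# ---------------------------------------------------------------------------
# Ranking statistic

@dataclass
class NucleusRanking:
    """Ranked subregion contributions for one component."""

    table: pd.DataFrame            # subregion, summed_z_ratio, rank
    all_sums: pd.Series            # before thresholding; sums to ~0


def rank_nuclei(pairwise_z: np.ndarray,
                names: "list[str]") -> NucleusRanking:
    """Sum each subregion's pairwise contrast z-ratios, keep strictly
    positive sums, order descending and rank 1..n.

    The input must be antisymmetric with a zero diagonal; row sums of an
    antisymmetric matrix always total zero, which is checked downstream as a
    conservation property.
    """
    Z = np.asarray(pairwise_z, dtype=np.float64)
    if Z.shape[0] != Z.shape[1] or Z.shape[0] != len(names):
        raise ValueError("pairwise matrix and name list sizes disagree")
    if np.abs(Z + Z.T).max() > 1e-8:
        raise ValueError("pairwise z matrix is not antisymmetric")
    sums = Z.sum(axis=1)
    all_sums = pd.Series(sums, index=list(names))
    order = np.argsort(-sums, kind="stable")
    rows = []
    rank = 0
    for i in order:
        if sums[i] > 0:
            rank += 1
            rows.append({"subregion": names[i],
                         "summed_z_ratio": float(sums[i]), "rank": rank})
    return NucleusRanking(table=pd.DataFrame(
        rows, columns=["subregion", "summed_z_ratio", "rank"]),
        all_sums=all_sums)


def pairwise_nucleus_rankings(fit: ModelFit, region_factor: str = "region",
                              map_factor: str = "fc_map"
                              ) -> "dict[str, NucleusRanking]":
    """Per component: pairwise subregion z-ratios from the EMM machinery,
    summed and ranked."""
    mats = pairwise_z_matrix(fit, factor=region_factor, by=map_factor)
    names = fit.info.factor_levels[region_factor]
    return {b: rank_nuclei(Z, names) for b, Z in mats.items()}


# ---------------------------------------------------------------------------
# Fear-group analysis

def two_sample_t(n1: int, mean1: float, sd1: float,
                 n2: int, mean2: float, sd2: float):
    """Pooled-variance two-sample t from group summaries.

    Returns (t, df, p) with df = n1 + n2 - 2.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("group SDs must be positive")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    t = (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return float(t), int(df), p


def median_split(scores: pd.Series) -> pd.Series:
    """'high' for scores strictly above the median, else 'low' (ties at the
    median go low)."""
    s = pd.Series(scores, dtype=float)
    if s.nunique() < 2:
        raise ValueError("all scores equal: median split impossible")
    med = float(s.median())
    return pd.Series(np.where(s > med, "high", "low"), index=s.index)


@dataclass
class FearAnalysis:
    fit: ModelFit
    anova: pd.DataFrame
    age_dropped: bool
    group_by_region_p: float
    posthoc_by_region: "pd.DataFrame | None"
    posthoc_by_cell: "pd.DataFrame | None"
    significant_nuclei: "list[str]"


def fear_group_analysis(table: pd.DataFrame, scores: "dict[str, float]",
                        age: "dict[str, str]", gender: "dict[str, str]",
                        alpha: float = ALPHA) -> FearAnalysis:
    """Median-split fear groups, extended mixed model with Age/Gender and a
    Group x FC-map x Region interaction, then Bonferroni post-hocs on the
    Group x Region interaction.

    Age is dropped and the model refitted when its main effect is not
    significant.  Post-hocs (low vs high per region and per region x map)
    run only when Group x Region is significant at ``alpha``.
    """
    df = table.copy()
    missing = set(df["participant_id"]) - set(scores)
    if missing:
        raise ValueError(f"missing fear scores for {sorted(missing)}")
    score_s = pd.Series({p: float(scores[p]) for p in df["participant_id"].unique()})
    groups = median_split(score_s)
    df["group"] = df["participant_id"].map(groups)
    df["age_band"] = df["participant_id"].map(age)
    df["gender"] = df["participant_id"].map(gender)

    base_terms = ["hemisphere", "gender", "group", "fc_map", "region",
                  "group:fc_map", "group:region", "fc_map:region",
                  "group:fc_map:region"]
    age_dropped = False
    if df["age_band"].nunique() > 1:
        terms = base_terms[:1] + ["age_band"] + base_terms[1:]
        fit = fit_lmm(df, LmmFormula("mean_z", terms, "participant_id"))
        an = anova_type3(fit)
        p_age = float(an.loc[an["term"] == "age_band", "p"].iloc[0])
        if p_age >= alpha:
            age_dropped = True
    else:
        age_dropped = True
    if age_dropped:
        fit = fit_lmm(df, LmmFormula("mean_z", base_terms, "participant_id"))
        an = anova_type3(fit)

    p_gr = float(an.loc[an["term"] == "group:region", "p"].iloc[0])
    posthoc_region = posthoc_cell = None
    significant: list[str] = []
    if p_gr < alpha:
        posthoc_region = pairwise_group_contrasts(
            fit, "group", ("low", "high"), within=["region"])
        posthoc_cell = pairwise_group_contrasts(
            fit, "group", ("low", "high"), within=["region", "fc_map"])
        significant = sorted(
            posthoc_region.loc[posthoc_region["p_bonf"] < alpha, "region"])
    return FearAnalysis(fit=fit, anova=an, age_dropped=age_dropped,
                        group_by_region_p=p_gr,
                        posthoc_by_region=posthoc_region,
                        posthoc_by_cell=posthoc_cell,
                        significant_nuclei=significant)


# ---------------------------------------------------------------------------
# Test / validation comparison

def compare_test_validation(test_maps: GroupFCMap, val_maps: GroupFCMap,
                            templates, brain_mask,
                            r_star: float = 0.4
                            ) -> tuple[np.ndarray, MatchTable, Assignment]:
    """Per-component Pearson r between test and validation group maps over
    brain-mask voxels, plus the template re-match of the validation maps."""
    if test_maps.grid_shape != val_maps.grid_shape:
        raise ValueError("grid mismatch between test and validation maps")
    if test_maps.z.shape != val_maps.z.shape:
        raise ValueError("component count mismatch")
    coords = test_maps.voxel_coords
    inside = brain_mask[coords[:, 0], coords[:, 1], coords[:, 2]] > 0
    rs = np.array([
        float(np.corrcoef(test_maps.z[k][inside], val_maps.z[k][inside])[0, 1])
        for k in range(test_maps.z.shape[0])
    ])
    from .network_matching import match_components
    match = match_components(val_maps.z, templates, brain_mask, coords,
                             r_star=r_star)
    assignment = assign_networks(match)
    return rs, match, assignment
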