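"""Match group FC maps to binary reference-network templates and select the
ICA model order that uniquely detects the most networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

R_STAR_DEFAULT = 0.4

UNIQUE = "unique"
AMBIGUOUS = "ambiguous"
UNMATCHED = "unmatched"


def correlate_with_templates(group_z: np.ndarray, templates: "list[np.ndarray]",
                             brain_mask: np.ndarray,
                             voxel_coords: np.ndarray) -> np.ndarray:
    """Pearson r between one component's group Z map and each template,
    computed over brain-mask voxels only."""
    inside = brain_mask[voxel_coords[:, 0], voxel_coords[:, 1],
                        voxel_coords[:, 2]] > 0
    z = np.asarray(group_z, dtype=np.float64)[inside]
    if np.ptp(z) == 0:
        raise ValueError("degenerate map: constant over the brain mask")
    rs = []
    for t in templates:
        tv = t[voxel_coords[:, 0], voxel_coords[:, 1], voxel_coords[:, 2]]
        tv = np.asarray(tv, dtype=np.float64)[inside]
        if np.ptp(tv) == 0:
            raise ValueError("template constant inside brain mask")
        rs.append(float(np.corrcoef(z, tv)[0, 1]))
    return np.array(rs)


@dataclass
class MatchTable:
    """d x R correlation matrix plus the detection threshold."""

    r: np.ndarray
    r_star: float = R_STAR_DEFAULT
    component_ids: "list[int] | None" = None
    network_names: "list[str] | None" = None

    def to_frame(self) -> pd.DataFrame:
        comps = self.component_ids or list(range(self.r.shape[0]))
        nets = self.network_names or [f"net-{j}" for j in range(self.r.shape[1])]
        return pd.DataFrame(self.r, index=[f"IC{c}" for c in comps], columns=nets)


def match_components(group_z_maps: np.ndarray, templates, brain_mask,
                     voxel_coords, r_star: float = R_STAR_DEFAULT) -> MatchTable:
    r = np.vstack([
        correlate_with_templates(group_z_maps[k], templates, brain_mask,
                                 voxel_coords)
        for k in range(group_z_maps.shape[0])
    ])
    return MatchTable(r=r, r_star=r_star)


@dataclass
class Assignment:
    """Injective component -> network assignment with per-component labels."""

    mapping: dict[int, int]          # component -> network, unique only
    labels: "list[str]"              # per component
    r_star: float
    n_unique: int
    summed_matched_r: float


def assign_networks(match: MatchTable, r_star: "float | None" = None) -> Assignment:
    """Classify components as unique / ambiguous / unmatched.

    Component c is UNIQUE for network n iff r(c,n) >= r*, r(c,m) < r* for
    every other network m, and no other component has a higher (or tied) r
    with n.  Components exceeding the threshold for several networks, or
    losing/tying a claimed network, are AMBIGUOUS; the rest are UNMATCHED.
    """
    r = match.r
    thr = match.r_star if r_star is None else r_star
    d, R = r.shape
    labels = [UNMATCHED] * d
    claims: dict[int, list[int]] = {}
    for c in range(d):
        above = np.nonzero(r[c] >= thr)[0]
        if len(above) == 0:
            continue
        if len(above) > 1:
            labels[c] = AMBIGUOUS
            continue
        claims.setdefault(int(above[0]), []).append(c)
    mapping: dict[int, int] = {}
    for n, cands in claims.items():
        best_r = max(r[c, n] for c in cands)
        best = [c for c in cands if r[c, n] == best_r]
        if len(best) == 1 and all(r[c, n] <= best_r for c in range(d)
                                  if c != best[0]):
            winner = best[0]
            # a non-claiming component with a strictly higher r also vetoes
            if any(r[c, n] > best_r for c in range(d) if c != winner):
                for c in cands:
                    labels[c] = AMBIGUOUS
                continue
            labels[winner] = UNIQUE
            mapping[winner] = n
            for c in cands:
                if c != winner:
                    labels[c] = AMBIGUOUS
        else:
            for c in cands:
                labels[c] = AMBIGUOUS
    summed = float(sum(r[c, n] for c, n in mapping.items()))
    return Assignment(mapping=mapping, labels=labels, r_star=thr,
                      n_unique=len(mapping), summed_matched_r=summed)


@dataclass
class DimensionSweep:
    """Per-dimension match tables and assignments over a model-order sweep."""

    dimensions: "list[int]" = field(default_factory=list)
    match_tables: "list[MatchTable]" = field(default_factory=list)
    assignments: "list[Assignment]" = field(default_factory=list)

    def add(self, d: int, match: MatchTable, assignment: Assignment) -> None:
        if self.dimensions and d <= self.dimensions[-1]:
            raise ValueError("dimensions must be strictly increasing")
        self.dimensions.append(d)
        self.match_tables.append(match)
        self.assignments.append(assignment)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d, a in zip(self.dimensions, self.assignments):
            rows.append({"dimension": d, "n_unique": a.n_unique,
                         "summed_matched_r": a.summed_matched_r,
                         "assignment": ";".join(
                             f"IC{c}->net{n}" for c, n in sorted(a.mapping.items()))})
        return pd.DataFrame(rows)


@dataclass
class DimensionChoice:
    dimension: "int | None"
    assignment: "Assignment | None"
    n_unique: int
    sweep_table: pd.DataFrame
    detected: bool


def select_dimension(sweep: DimensionSweep) -> DimensionChoice:
    """Smallest dimension attaining the maximum count of uniquely detected
    networks; the full sweep table is always part of the result.  A sweep
    where no network is ever detected yields an explicit undetected result."""
    if not sweep.dimensions:
        raise ValueError("empty dimension sweep")
    counts = [a.n_unique for a in sweep.assignments]
    best = max(counts)
    table = sweep.to_frame()
    if best == 0:
        return DimensionChoice(dimension=None, assignment=None, n_unique=0,
                               sweep_table=table, detected=False)
    idx = counts.index(best)  # first (smallest d) maximiser
    return DimensionChoice(dimension=sweep.dimensions[idx],
                           assignment=sweep.assignments[idx],
                           n_unique=best, sweep_table=table, detected=True)
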