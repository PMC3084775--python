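"""Resolution of total masticatory muscle force into nodal force vectors.

The total force (1000 N in every model) is split bilaterally by the
balancing-working activation ratio r (working = total/(1+r)), divided
among the jaw-closing muscle groups by the 55-26(9)-10
temporalis-masseter(zygomaticomandibularis)-pterygoid percentages, split
among subgroups of a group by attachment surface area, and finally
distributed over the attachment patch nodes in proportion to the surface
area each node carries.  Every nodal force points from its node toward the
group's cranial target (straight line of action at the 10 degree gape),
so the sum of nodal force magnitudes is conserved exactly at every level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import DistributionError, ParameterError
from .geometry import (BALANCING_SIDE, SUBGROUP_MAJOR, WORKING_SIDE,
                       LabeledMesh)

TOTAL_MUSCLE_FORCE = 1000.0  # N, all models
BASE_BW_RATIO = 0.6
BASE_RATIOS = (55.0, 26.0, 9.0, 10.0)  # temporalis, masseter, zygo, pterygoid
RATIO_ORDER = ("temporalis", "masseter", "zygomaticomandibularis", "pterygoid")

#: Load-group composition of the muscle-number sweep.  Model n uses exactly
#: n groups; subgroup splits of temporalis and masseter appear last.
MUSCLE_NUMBER_SCHEDULE: Dict[int, Tuple[Tuple[str, Tuple[str, ...]], ...]] = {
    1: (("temporalis", ("T.s", "T.p", "T.z")),),
    2: (("temporalis", ("T.s", "T.p", "T.z")),
        ("masseter", ("M.s", "M.p"))),
    3: (("temporalis", ("T.s", "T.p", "T.z")),
        ("masseter", ("M.s", "M.p")),
        ("zygomaticomandibularis", ("Z.m",))),
    4: (("temporalis", ("T.s", "T.p", "T.z")),
        ("masseter", ("M.s", "M.p")),
        ("zygomaticomandibularis", ("Z.m",)),
        ("pterygoid", ("P.i",))),
    5: (("T.s", ("T.s",)),
        ("T.pz", ("T.p", "T.z")),
        ("masseter", ("M.s", "M.p")),
        ("zygomaticomandibularis", ("Z.m",)),
        ("pterygoid", ("P.i",))),
    6: (("T.s", ("T.s",)),
        ("T.p", ("T.p",)),
        ("T.z", ("T.z",)),
        ("masseter", ("M.s", "M.p")),
        ("zygomaticomandibularis", ("Z.m",)),
        ("pterygoid", ("P.i",))),
    7: (("T.s", ("T.s",)),
        ("T.p", ("T.p",)),
        ("T.z", ("T.z",)),
        ("M.s", ("M.s",)),
        ("M.p", ("M.p",)),
        ("zygomaticomandibularis", ("Z.m",)),
        ("pterygoid", ("P.i",))),
}


@dataclass
class MuscleGroup:
    """One load group: a set of subgroup patches acting toward one target."""

    name: str
    side: str
    subpatches: Tuple[str, ...]     # subgroup names, e.g. ("T.s", "T.p")
    fraction: float                 # of the side budget


@dataclass
class MuscleScheme:
    """Activation scheme: groups, per-side fractions, total force, ratio r."""

    groups: List[MuscleGroup]
    total_force: float = TOTAL_MUSCLE_FORCE
    bw_ratio: float = BASE_BW_RATIO

    def __post_init__(self):
        if self.total_force <= 0:
            raise ParameterError("total_force must be positive")
        if not (0.0 <= self.bw_ratio <= 1.0):
            raise ParameterError("balancing-working ratio must lie in [0, 1]")
        for side in (WORKING_SIDE, BALANCING_SIDE):
            s = sum(g.fraction for g in self.groups if g.side == side)
            if abs(s - 1.0) > 1e-12:
                raise ParameterError(
                    f"{side}-side fractions sum to {s!r}, not 1")


@dataclass
class LoadCase:
    """Per-node force vectors and the budgets they were built from."""

    nodal_forces: np.ndarray               # (N, 3)
    per_group_budget: Dict[str, float]     # "group:side" -> N
    magnitude_total: float                 # sum of nodal |force|

    def vector_resultant(self) -> np.ndarray:
        return self.nodal_forces.sum(axis=0)


# --------------------------------------------------------------------------
# budget arithmetic
# --------------------------------------------------------------------------


def split_bilateral(total: float, r: float) -> Tuple[float, float]:
    """(working, balancing) = (total/(1+r), total*r/(1+r))."""
    if not (0.0 <= r <= 1.0):
        raise ParameterError("ratio must lie in [0, 1]")
    if total <= 0:
        raise ParameterError("total force must be positive")
    working = total / (1.0 + r)
    return working, total - working


def apply_proportions(side_budget: float,
                      ratios: Sequence[float],
                      present: Optional[Sequence[str]] = None
                      ) -> Dict[str, float]:
    """Per-major-group budgets from (T, M, Z, P) percentages.

    ``present`` restricts to the groups of a reduced model; an absent
    zygomaticomandibularis folds its share into the masseter (it is
    treated as part of the masseter complex), then percentages are
    renormalized.
    """
    ratios = [float(x) for x in ratios]
    if len(ratios) != len(RATIO_ORDER):
        raise ParameterError(f"expected {len(RATIO_ORDER)} percentages")
    if any(x < 0 for x in ratios):
        raise ParameterError("percentages must be non-negative")
    if abs(sum(ratios) - 100.0) > 1e-9:
        raise ParameterError("percentages must sum to 100")
    pct = dict(zip(RATIO_ORDER, ratios))
    if present is not None:
        present = set(present)
        if "zygomaticomandibularis" not in present and "masseter" in present:
            pct["masseter"] += pct.pop("zygomaticomandibularis")
        pct = {k: v for k, v in pct.items() if k in present}
        tot = sum(pct.values())
        if tot <= 0:
            raise ParameterError("no active muscle group has a positive share")
        pct = {k: 100.0 * v / tot for k, v in pct.items()}
    return {k: side_budget * v / 100.0 for k, v in pct.items()}


def subdivide_by_area(group_budget: float,
                      areas: Sequence[float]) -> np.ndarray:
    """Split a group budget among subpatches proportionally to their areas."""
    areas = np.asarray(areas, float)
    if np.any(areas <= 0):
        raise DistributionError("every subpatch must have positive area")
    return group_budget * areas / areas.sum()


# --------------------------------------------------------------------------
# traction distribution
# --------------------------------------------------------------------------


def patch_area_weights(mesh: LabeledMesh, patch_key: str) -> Tuple[np.ndarray, np.ndarray]:
    """(node ids, per-node area weights) of one attachment patch."""
    nodes = mesh.patch_nodes[patch_key]
    w = mesh.node_surface_weights()[nodes]
    return nodes, w


def distribute_traction(mesh: LabeledMesh, patch_nodes: np.ndarray,
                        node_weights: np.ndarray, budget: float,
                        target_point: np.ndarray,
                        out: Optional[np.ndarray] = None) -> np.ndarray:
    """Accumulate nodal forces of one group onto ``out`` ((N,3) array).

    Each node receives budget * (its area weight / patch area) directed
    from the node toward ``target_point``; the sum of magnitudes equals
    the budget exactly.
    """
    if budget < 0:
        raise ParameterError("budget must be non-negative")
    W = float(np.sum(node_weights))
    if W <= 0:
        raise DistributionError("zero patch area")
    if out is None:
        out = np.zeros((mesh.n_nodes, 3))
    d = np.asarray(target_point, float) - mesh.nodes[patch_nodes]
    norms = np.linalg.norm(d, axis=1)
    if np.any(norms < 1e-12):
        raise DistributionError("target point coincides with a patch node")
    mags = budget * node_weights / W
    out[patch_nodes] += (mags / norms)[:, None] * d
    return out


# --------------------------------------------------------------------------
# scheme construction and load-case assembly
# --------------------------------------------------------------------------


def default_scheme(mesh: LabeledMesh, n_groups: int = 4,
                   ratios: Sequence[float] = BASE_RATIOS,
                   r: float = BASE_BW_RATIO,
                   total: float = TOTAL_MUSCLE_FORCE) -> MuscleScheme:
    """Scheme for one model of the muscle-number schedule (n_groups 1..7)."""
    if n_groups not in MUSCLE_NUMBER_SCHEDULE:
        raise ParameterError("n_groups must lie in 1..7")
    schedule = MUSCLE_NUMBER_SCHEDULE[n_groups]
    majors_present = {SUBGROUP_MAJOR[sp] for _, sps in schedule for sp in sps}
    weights = mesh.node_surface_weights()
    groups: List[MuscleGroup] = []
    for side in (WORKING_SIDE, BALANCING_SIDE):
        major_budget = apply_proportions(1.0, ratios, present=majors_present)
        # area of each schedule entry and of its parent major group
        entry_area = {}
        major_area: Dict[str, float] = {}
        for name, sps in schedule:
            a = sum(float(weights[mesh.patch_nodes[f"{sp}:{side}"]].sum())
                    for sp in sps)
            entry_area[name] = a
            major = SUBGROUP_MAJOR[sps[0]]
            major_area[major] = major_area.get(major, 0.0) + a
        for name, sps in schedule:
            major = SUBGROUP_MAJOR[sps[0]]
            frac = major_budget.get(major, 0.0) * entry_area[name] / major_area[major]
            groups.append(MuscleGroup(name=name, side=side,
                                      subpatches=sps, fraction=frac))
        # normalize exactly (fractions already sum to 1 up to rounding)
        s = sum(g.fraction for g in groups if g.side == side)
        for g in groups:
            if g.side == side:
                g.fraction /= s
    return MuscleScheme(groups=groups, total_force=total, bw_ratio=r)


def group_target(mesh: LabeledMesh, group: MuscleGroup) -> np.ndarray:
    """Cranial target of a load group: the area-weighted mean of its
    subgroup targets (a subgroup's own target if it stands alone)."""
    weights = mesh.node_surface_weights()
    tw, ts = 0.0, np.zeros(3)
    for sp in group.subpatches:
        key = f"{sp}:{group.side}"
        a = float(weights[mesh.patch_nodes[key]].sum())
        ts += a * mesh.patch_targets[key]
        tw += a
    return ts / tw


def build_load_case(mesh: LabeledMesh,
                    scheme: Optional[MuscleScheme] = None,
                    n_groups: int = 4,
                    ratios: Sequence[float] = BASE_RATIOS,
                    r: float = BASE_BW_RATIO,
                    total: float = TOTAL_MUSCLE_FORCE) -> LoadCase:
    """Compose bilateral split, group proportions, area subdivision and
    traction distribution into per-node forces."""
    if scheme is None:
        scheme = default_scheme(mesh, n_groups=n_groups, ratios=ratios,
                                r=r, total=total)
    working, balancing = split_bilateral(scheme.total_force, scheme.bw_ratio)
    side_budget = {WORKING_SIDE: working, BALANCING_SIDE: balancing}
    weights = mesh.node_surface_weights()
    out = np.zeros((mesh.n_nodes, 3))
    budgets: Dict[str, float] = {}
    magnitude_total = 0.0
    for group in scheme.groups:
        budget = side_budget[group.side] * group.fraction
        budgets[f"{group.name}:{group.side}"] = budget
        if budget == 0.0:
            continue
        target = group_target(mesh, group)
        keys = [f"{sp}:{group.side}" for sp in group.subpatches]
        pnodes = np.concatenate([mesh.patch_nodes[k] for k in keys])
        distribute_traction(mesh, pnodes, weights[pnodes], budget, target,
                            out=out)
        magnitude_total += budget
    return LoadCase(nodal_forces=out, per_group_budget=budgets,
                    magnitude_total=magnitude_total)
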