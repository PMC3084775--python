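"""Performance measures of a solved mandible model.

Mirrors the measures used to compare sensitivity tests: the reaction force
at the carnassial bite point (vector, magnitude and anteroposterior /
dorsoventral / lateral components), the working- and balancing-side joint
reaction resultants, total strain energy, and von Mises stress/strain
summaries.  For link-type TMJ constraints there are no nodal reactions at
the joints; the forces transmitted through the rigid links are summed
instead.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Dict, Optional, Tuple

import numpy as np

from .errors import ParameterError
from .fem_core import SolveResult, von_mises_strain, von_mises_stress
from .geometry import BALANCING_SIDE, WORKING_SIDE, LabeledMesh
from .materials import MaterialTable

NODE_MODES = ("single_node", "row_nodes")
LINK_MODES = ("single_link", "row_links")


@dataclass
class PerformanceRecord:
    """Scalar outputs of one solved model."""

    bite_force_vector: Tuple[float, float, float]
    bite_force_mag: float
    bite_components: Tuple[float, float, float]   # (ap, dv, lat) N
    joint_reaction_working: float
    joint_reaction_balancing: float
    strain_energy: float                          # J
    vm_stress_mean: float                         # MPa, bone elements
    vm_stress_max: float
    vm_stress_p95: float
    joint_strain_working: Tuple[float, float]     # (mean, max)
    joint_strain_balancing: Tuple[float, float]

    def as_dict(self) -> Dict[str, float]:
        d = asdict(self)
        flat = {}
        for k, v in d.items():
            if isinstance(v, tuple):
                if k == "bite_force_vector":
                    flat.update({"bite_fx": v[0], "bite_fy": v[1], "bite_fz": v[2]})
                elif k == "bite_components":
                    flat.update({"m1_ap": v[0], "m1_dv": v[1], "m1_lat": v[2]})
                else:
                    flat.update({f"{k}_mean": v[0], f"{k}_max": v[1]})
            else:
                flat[k] = v
        return flat


def bite_force(result: SolveResult, bite_nodes: np.ndarray):
    """Vector sum of nodal reactions over the bite nodes.

    Returns (vector, magnitude, (ap, dv, lat) components); components map
    the axis convention x/z/y onto anteroposterior / dorsoventral /
    lateral.
    """
    vec = np.zeros(3)
    for n in np.asarray(bite_nodes, int):
        if int(n) not in result.reaction:
            raise ParameterError(f"bite node {n} is not constrained")
        vec += result.reaction[int(n)]
    mag = float(np.linalg.norm(vec))
    components = (float(vec[0]), float(vec[2]), float(vec[1]))
    return vec, mag, components


def joint_reactions(result: SolveResult, tmj_sets: Dict[str, np.ndarray],
                    constraint_mode: str) -> Dict[str, float]:
    """Per-side joint reaction resultant magnitude.

    Node modes sum fixed-DOF reactions; link modes sum the per-node forces
    transmitted through the rigid links.
    """
    if constraint_mode in NODE_MODES:
        source = result.reaction
    elif constraint_mode in LINK_MODES:
        source = result.link_force
    else:
        raise ParameterError(f"unknown constraint mode {constraint_mode!r}")
    out = {}
    for side in (WORKING_SIDE, BALANCING_SIDE):
        vec = np.zeros(3)
        for n in np.asarray(tmj_sets[side], int):
            vec += source.get(int(n), np.zeros(3))
        out[side] = float(np.linalg.norm(vec))
    return out


def field_summaries(result: SolveResult, mesh: LabeledMesh,
                    materials: MaterialTable,
                    region: Optional[np.ndarray] = None) -> Dict[str, float]:
    """Mean / max / 95th-percentile von Mises stress over a region.

    ``region`` is an element mask (default: bone elements).  The 95th
    percentile is a robust summary for regression testing of stress
    fields.
    """
    if result.element_stress is None:
        raise ParameterError("stresses not recovered yet")
    if region is None:
        region = mesh.element_region == "bone"
    if not np.any(region):
        raise ParameterError("empty summary region")
    vm = von_mises_stress(result.element_stress[region])
    return {"mean": float(vm.mean()), "max": float(vm.max()),
            "p95": float(np.percentile(vm, 95))}


def joint_strain_summary(result: SolveResult, mesh: LabeledMesh,
                         materials: MaterialTable) -> Dict[str, Tuple[float, float]]:
    """(mean, max) equivalent strain over elements touching each condyle."""
    if result.element_strain is None:
        raise ParameterError("strains not recovered yet")
    out = {}
    for side, key in ((WORKING_SIDE, "condyle_left"),
                      (BALANCING_SIDE, "condyle_right")):
        touch = np.isin(mesh.tets, mesh.node_sets[key]).any(axis=1)
        nu = materials.element_nu()[touch]
        # per-element Poisson ratio: divide the raw deviatoric magnitude
        vm = von_mises_strain(result.element_strain[touch], 0.0) / (1.0 + nu)
        out[side] = (float(vm.mean()), float(vm.max()))
    return out


def performance_record(result: SolveResult, mesh: LabeledMesh,
                       materials: MaterialTable, bite_nodes: np.ndarray,
                       tmj_sets: Dict[str, np.ndarray],
                       constraint_mode: str) -> PerformanceRecord:
    """Assemble the full record for one solved model."""
    vec, mag, comps = bite_force(result, bite_nodes)
    joints = joint_reactions(result, tmj_sets, constraint_mode)
    stress = field_summaries(result, mesh, materials)
    jstrain = joint_strain_summary(result, mesh, materials)
    return PerformanceRecord(
        bite_force_vector=tuple(float(v) for v in vec),
        bite_force_mag=mag,
        bite_components=comps,
        joint_reaction_working=joints[WORKING_SIDE],
        joint_reaction_balancing=joints[BALANCING_SIDE],
        strain_energy=result.total_strain_energy,
        vm_stress_mean=stress["mean"],
        vm_stress_max=stress["max"],
        vm_stress_p95=stress["p95"],
        joint_strain_working=jstrain[WORKING_SIDE],
        joint_strain_balancing=jstrain[BALANCING_SIDE],
    )
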