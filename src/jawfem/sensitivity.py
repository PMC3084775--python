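"""Orchestration of the seven model-building parameter sweeps.

Every sweep varies exactly one parameter around a shared base
configuration (balancing-working ratio 0.6, 55-26(9)-10 muscle ratios,
four muscle groups, single-node bite and TMJ constraints, homogeneous
E = 20 GPa / nu = 0.3, mid refinement) and records the performance
measures of each solved model.  The summary statistic is the maximum
signed percent change of a measure relative to its base-configuration
value.  The pipeline is fully deterministic; a seed field exists in the
run config only as a reserved extension point and is recorded in logs.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ParameterError, SolverError
from .fem_core import assemble, build_constraints, recover_stress, solve_static
from .geometry import (BALANCING_SIDE, WORKING_SIDE, LabeledMesh,
                       MandibleParams, build_mandible, select_bite_nodes,
                       select_tmj_nodes)
from .io_interface import DEFAULT_CONFIG, log
from .materials import bin_properties, homogeneous_table
from .metrics import LINK_MODES, NODE_MODES, PerformanceRecord, \
    performance_record
from .muscle_loads import build_load_case

SWEEP_NAMES: Dict[int, str] = {
    1: "elements", 2: "bw-ratio", 3: "muscle-ratio", 4: "muscle-number",
    5: "bite-nodes", 6: "tmj", 7: "materials",
}


@dataclass(frozen=True)
class ModelConfig:
    """One fully specified model; the defaults are the base configuration."""

    refine_level: int = 2
    bw_ratio: float = 0.6
    ratios: Tuple[float, ...] = (55.0, 26.0, 9.0, 10.0)
    n_groups: int = 4
    bite_k: int = 1
    tmj_mode: str = "single_node"
    n_materials: int = 1
    total_force: float = 1000.0
    homogeneous_E: float = 20.0
    homogeneous_nu: float = 0.3
    binning: str = "equal_width"


@dataclass
class SweepSpec:
    """One sensitivity test: id, grid and the base configuration."""

    test_id: int
    grid: List
    base: ModelConfig = field(default_factory=ModelConfig)

    def __post_init__(self):
        if self.test_id not in SWEEP_NAMES:
            raise ParameterError(f"unknown test id {self.test_id}")
        if not self.grid:
            raise ParameterError("sweep grid must be non-empty")

    @property
    def name(self) -> str:
        return SWEEP_NAMES[self.test_id]


@dataclass
class SweepTable:
    """One row (PerformanceRecord + varied value) per grid point."""

    spec: SweepSpec
    frame: pd.DataFrame
    base_index: int

    @property
    def name(self) -> str:
        return self.spec.name


def apply_grid_value(base: ModelConfig, test_id: int, value) -> ModelConfig:
    if test_id == 1:
        return replace(base, refine_level=int(value))
    if test_id == 2:
        return replace(base, bw_ratio=float(value))
    if test_id == 3:
        return replace(base, ratios=tuple(float(v) for v in value))
    if test_id == 4:
        return replace(base, n_groups=int(value))
    if test_id == 5:
        return replace(base, bite_k=int(value))
    if test_id == 6:
        return replace(base, tmj_mode=str(value))
    if test_id == 7:
        return replace(base, n_materials=int(value))
    raise ParameterError(f"unknown test id {test_id}")


def _grid_label(test_id: int, value) -> str:
    if test_id == 3:
        return "-".join("%g" % v for v in value)
    return str(value)


def _is_base_point(base: ModelConfig, test_id: int, value) -> bool:
    return apply_grid_value(base, test_id, value) == base


class ModelRunner:
    """Builds, solves and measures models, caching meshes and stiffness."""

    def __init__(self, geometry_kw: Optional[dict] = None):
        self.geometry_kw = dict(geometry_kw or {})
        self.geometry_kw.pop("refine_level", None)
        self._mesh: Dict[int, LabeledMesh] = {}
        self._stiffness: Dict[Tuple, object] = {}
        self._materials: Dict[Tuple, object] = {}

    def mesh(self, refine_level: int) -> LabeledMesh:
        if refine_level not in self._mesh:
            params = MandibleParams(refine_level=refine_level,
                                    **self.geometry_kw)
            self._mesh[refine_level] = build_mandible(params)
        return self._mesh[refine_level]

    def materials_for(self, mc: ModelConfig):
        key = (mc.refine_level, mc.n_materials, mc.binning,
               mc.homogeneous_E, mc.homogeneous_nu)
        if key not in self._materials:
            mesh = self.mesh(mc.refine_level)
            if mc.n_materials == 1:
                tab = homogeneous_table(mesh, mc.homogeneous_E,
                                        mc.homogeneous_nu)
            else:
                tab = bin_properties(mesh, mc.n_materials,
                                     schedule=mc.binning,
                                     homogeneous_E=mc.homogeneous_E)
            self._materials[key] = tab
        return self._materials[key]

    def stiffness(self, mc: ModelConfig):
        key = (mc.refine_level, mc.n_materials, mc.binning,
               mc.homogeneous_E, mc.homogeneous_nu)
        if key not in self._stiffness:
            self._stiffness[key] = assemble(self.mesh(mc.refine_level),
                                            self.materials_for(mc))
        return self._stiffness[key]

    def solve(self, mc: ModelConfig):
        """Returns (PerformanceRecord, SolveResult, mesh, extras dict)."""
        t0 = time.perf_counter()
        mesh = self.mesh(mc.refine_level)
        materials = self.materials_for(mc)
        K = self.stiffness(mc)
        bite = select_bite_nodes(mesh, mc.bite_k)
        constraints = build_constraints(mesh, bite, mc.tmj_mode)
        lc = build_load_case(mesh, n_groups=mc.n_groups, ratios=mc.ratios,
                             r=mc.bw_ratio, total=mc.total_force)
        result = solve_static(K, lc.nodal_forces, constraints)
        recover_stress(mesh, materials, result.displacement, result)
        if mc.tmj_mode in LINK_MODES:
            tmj_sets = {g.label: g.linked_nodes
                        for g in constraints.link_groups}
            for side in (WORKING_SIDE, BALANCING_SIDE):  # on-axis fallback
                tmj_sets.setdefault(side, select_tmj_nodes(mesh, side, "single"))
        else:
            sel_mode = "single" if mc.tmj_mode == "single_node" else "row"
            tmj_sets = {side: select_tmj_nodes(mesh, side, sel_mode)
                        for side in (WORKING_SIDE, BALANCING_SIDE)}
        record = performance_record(result, mesh, materials, bite,
                                    tmj_sets, mc.tmj_mode)
        extras = {
            "n_tets": mesh.n_tets,
            "equilibrium_residual": result.equilibrium_residual(),
            "load_magnitude_total": lc.magnitude_total,
            "wall_time_s": time.perf_counter() - t0,
            "bite_nodes": bite,
            "tmj_sets": tmj_sets,
            "load_case": lc,
        }
        log.info("model solved: %s in %.2f s (%d tets)",
                 mc, extras["wall_time_s"], mesh.n_tets)
        return record, result, mesh, extras


def run_sweep(spec: SweepSpec, runner: Optional[ModelRunner] = None
              ) -> SweepTable:
    """Solve one model per grid point; all other settings stay at base."""
    runner = runner or ModelRunner()
    rows = []
    base_index = None
    for i, value in enumerate(spec.grid):
        mc = apply_grid_value(spec.base, spec.test_id, value)
        try:
            record, result, mesh, extras = runner.solve(mc)
        except Exception as exc:
            raise SolverError(
                f"sweep {spec.name!r} failed at grid point "
                f"{_grid_label(spec.test_id, value)!r}: {exc}") from exc
        row = {"parameter": _grid_label(spec.test_id, value)}
        row.update(record.as_dict())
        row["n_tets"] = extras["n_tets"]
        row["equilibrium_residual"] = extras["equilibrium_residual"]
        row["wall_time_s"] = extras["wall_time_s"]
        rows.append(row)
        if _is_base_point(spec.base, spec.test_id, value):
            base_index = i
    frame = pd.DataFrame(rows)
    if base_index is None:
        base_index = 0
    return SweepTable(spec=spec, frame=frame, base_index=base_index)


def default_sweep_specs(base: Optional[ModelConfig] = None,
                        grids: Optional[dict] = None) -> List[SweepSpec]:
    base = base or ModelConfig()
    cfg = DEFAULT_CONFIG["sweeps"]
    grids = grids or {}
    key_by_id = {1: "elements", 2: "bw_ratio", 3: "muscle_ratio",
                 4: "muscle_number", 5: "bite_nodes", 6: "tmj",
                 7: "materials"}
    return [SweepSpec(test_id=i,
                      grid=list(grids.get(key_by_id[i], cfg[key_by_id[i]])),
                      base=base)
            for i in range(1, 8)]


def run_all_sweeps(base: Optional[ModelConfig] = None,
                   runner: Optional[ModelRunner] = None,
                   grids: Optional[dict] = None,
                   tests: Optional[Sequence[int]] = None
                   ) -> Dict[str, SweepTable]:
    runner = runner or ModelRunner()
    out = {}
    for spec in default_sweep_specs(base, grids):
        if tests is not None and spec.test_id not in tests:
            continue
        out[spec.name] = run_sweep(spec, runner)
    return out


# --------------------------------------------------------------------------
# summary statistics
# --------------------------------------------------------------------------


def max_percent_change(table: SweepTable, measure: str) -> float:
    """Signed percent change, relative to the base grid point, of the grid
    value deviating most from it in absolute terms."""
    v = table.frame[measure].to_numpy(float)
    v_base = v[table.base_index]
    if v_base == 0.0 or not np.isfinite(v_base):
        return float("nan")
    star = v[np.argmax(np.abs(v - v_base))]
    return 100.0 * (star - v_base) / v_base


def summary_table(tables: Dict[str, SweepTable]) -> pd.DataFrame:
    """Maximum % changes in bite force and strain energy per sweep."""
    rows = []
    for tid in range(1, 8):
        name = SWEEP_NAMES[tid]
        if name not in tables:
            rows.append({"test": name, "max_pct_bite_force": "not run",
                         "max_pct_strain_energy": "not run"})
            continue
        t = tables[name]
        rows.append({
            "test": name,
            "max_pct_bite_force":
                "%.10g" % max_percent_change(t, "bite_force_mag"),
            "max_pct_strain_energy":
                "%.10g" % max_percent_change(t, "strain_energy"),
        })
    return pd.DataFrame(rows)


def write_report(tables: Dict[str, SweepTable], outdir) -> List[Path]:
    """One CSV per sweep plus the summary CSV; deterministic content."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for tid in range(1, 8):
        name = SWEEP_NAMES[tid]
        if name not in tables:
            continue
        path = outdir / f"sweep_{name}.csv"
        frame = tables[name].frame.drop(columns=["wall_time_s"])
        frame.to_csv(path, index=False, float_format="%.10g")
        written.append(path)
    path = outdir / "summary.csv"
    summary_table(tables).to_csv(path, index=False)
    written.append(path)
    return written
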