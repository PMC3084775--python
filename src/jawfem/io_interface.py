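"""Readers/writers, run configuration and logging.

Exports meshes and results as ASCII VTK XML unstructured grids (VTU,
readable by ParaView and other VTK consumers) and as a plain-text
node/element format ("id x y z" / "id n1 n2 n3 n4", 0-based).  The run
configuration is a YAML file with geometry / materials / muscles /
constraints / sweeps / output sections; unknown keys are rejected and the
fully resolved configuration is written to the run log.
"""

from __future__ import annotations

import hashlib
import logging
import time
from contextlib import contextmanager
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import yaml

from .errors import ConfigError
from .geometry import LabeledMesh

log = logging.getLogger("jawfem")

VTK_TET = 10


def setup_logging(logfile: Optional[Path] = None,
                  level: int = logging.INFO) -> logging.Logger:
    log.setLevel(level)
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    if not any(isinstance(h, logging.StreamHandler) for h in log.handlers):
        h = logging.StreamHandler()
        h.setFormatter(fmt)
        log.addHandler(h)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(fmt)
        log.addHandler(fh)
    return log


@contextmanager
def stage_timer(name: str):
    """Log the wall time of a pipeline stage (informational only)."""
    t0 = time.perf_counter()
    yield
    log.info("stage %s: %.2f s", name, time.perf_counter() - t0)


# --------------------------------------------------------------------------
# VTU (ASCII VTK XML unstructured grid)
# --------------------------------------------------------------------------


def _ascii(arr: np.ndarray, fmt: str = "%.9g") -> str:
    return "\n".join(" ".join(fmt % v for v in np.atleast_1d(row))
                     for row in np.asarray(arr))


def write_vtu(path, mesh: LabeledMesh,
              point_data: Optional[Dict[str, np.ndarray]] = None,
              cell_data: Optional[Dict[str, np.ndarray]] = None) -> None:
    """Write the tet mesh with optional point/cell arrays as ASCII VTU.

    Node sets are always included as integer point arrays (1 = member).
    """
    point_data = dict(point_data or {})
    cell_data = dict(cell_data or {})
    for name, ids in mesh.node_sets.items():
        flag = np.zeros(mesh.n_nodes, dtype=int)
        flag[np.asarray(ids, int)] = 1
        point_data.setdefault(f"set_{name}", flag)
    n, t = mesh.n_nodes, mesh.n_tets
    parts = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        '<UnstructuredGrid>',
        f'<Piece NumberOfPoints="{n}" NumberOfCells="{t}">',
        '<Points>',
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        _ascii(mesh.nodes, "%.12g"),
        '</DataArray>', '</Points>', '<Cells>',
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        _ascii(mesh.tets, "%d"),
        '</DataArray>',
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        _ascii(4 * np.arange(1, t + 1), "%d"),
        '</DataArray>',
        '<DataArray type="UInt8" Name="types" format="ascii">',
        _ascii(np.full(t, VTK_TET), "%d"),
        '</DataArray>', '</Cells>',
    ]
    parts.append('<PointData>')
    for name, arr in point_data.items():
        arr = np.asarray(arr)
        ncomp = 1 if arr.ndim == 1 else arr.shape[1]
        typ = "Float64" if np.issubdtype(arr.dtype, np.floating) else "Int64"
        parts += [f'<DataArray type="{typ}" Name="{name}" '
                  f'NumberOfComponents="{ncomp}" format="ascii">',
                  _ascii(arr, "%.9g" if typ == "Float64" else "%d"),
                  '</DataArray>']
    parts.append('</PointData>')
    parts.append('<CellData>')
    for name, arr in cell_data.items():
        arr = np.asarray(arr)
        typ = "Float64" if np.issubdtype(arr.dtype, np.floating) else "Int64"
        parts += [f'<DataArray type="{typ}" Name="{name}" '
                  f'NumberOfComponents="1" format="ascii">',
                  _ascii(arr, "%.9g" if typ == "Float64" else "%d"),
                  '</DataArray>']
    parts.append('</CellData>')
    parts += ['</Piece>', '</UnstructuredGrid>', '</VTKFile>']
    Path(path).write_text("\n".join(parts))


# --------------------------------------------------------------------------
# plain-text node/element format
# --------------------------------------------------------------------------


def write_mesh_text(path, mesh: LabeledMesh) -> None:
    """One node per line "id x y z"; one tet per line "id n1 n2 n3 n4"."""
    lines = [f"nodes {mesh.n_nodes}"]
    for i, (x, y, z) in enumerate(mesh.nodes):
        lines.append(f"{i} {x:.17g} {y:.17g} {z:.17g}")
    lines.append(f"tets {mesh.n_tets}")
    for i, t in enumerate(mesh.tets):
        lines.append(f"{i} {t[0]} {t[1]} {t[2]} {t[3]}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_mesh_text(path):
    """Read the text format back; returns (nodes, tets)."""
    toks = Path(path).read_text().split("\n")
    it = iter(l for l in toks if l.strip())
    head = next(it).split()
    if head[0] != "nodes":
        raise ConfigError("malformed mesh text file: expected 'nodes N'")
    n = int(head[1])
    nodes = np.empty((n, 3))
    for _ in range(n):
        parts = next(it).split()
        nodes[int(parts[0])] = [float(v) for v in parts[1:4]]
    head = next(it).split()
    if head[0] != "tets":
        raise ConfigError("malformed mesh text file: expected 'tets T'")
    t = int(head[1])
    tets = np.empty((t, 4), dtype=np.int64)
    for _ in range(t):
        parts = next(it).split()
        tets[int(parts[0])] = [int(v) for v in parts[1:5]]
    return nodes, tets


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

DEFAULT_CONFIG: Dict = {
    "geometry": {
        "corpus_length": 120.0,
        "corpus_depth": 24.0,
        "bicondylar_width": 70.0,
        "ramus_height": 60.0,
        "refine_level": 2,
        "cusp_radius": 20.0,
    },
    "materials": {
        "n_classes": 1,
        "binning": "equal_width",
        "enamel_E": 80.0,
        "enamel_nu": 0.30,
        "dentine_E": 20.0,
        "dentine_nu": 0.31,
        "homogeneous_E": 20.0,
        "homogeneous_nu": 0.3,
    },
    "muscles": {
        "total_force": 1000.0,
        "bw_ratio": 0.6,
        "ratios": [55.0, 26.0, 9.0, 10.0],
        "n_groups": 4,
    },
    "constraints": {
        "bite_nodes": 1,
        "tmj_mode": "single_node",
    },
    "sweeps": {
        "elements": [1, 2, 3, 4, 5],
        "bw_ratio": [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0],
        "muscle_ratio": [[55, 26, 9, 10], [55, 30, 0, 15],
                         [100, 0, 0, 0], [0, 100, 0, 0], [0, 0, 0, 100]],
        "muscle_number": [1, 2, 3, 4, 5, 6, 7],
        "bite_nodes": [1, 6, 12, 24, 48, 66],
        "tmj": ["single_node", "row_nodes", "single_link", "row_links"],
        "materials": [1, 3, 4, 6, 8, 10],
    },
    "output": {"dir": "results"},
    "seed": 0,  # reserved: the pipeline is fully deterministic
}


def _merge(defaults: Dict, user: Dict, path: str = "") -> Dict:
    out = {}
    for k, v in defaults.items():
        if isinstance(v, dict):
            out[k] = _merge(v, user.get(k, {}) or {}, f"{path}{k}.")
        else:
            out[k] = user.get(k, v)
    unknown = set(user) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown config keys: "
                          f"{sorted(path + k for k in unknown)}")
    return out


def load_config(path=None) -> Dict:
    """Load a YAML run config, validate keys, materialize all defaults."""
    user = {}
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(user, dict):
            raise ConfigError("config root must be a mapping")
    return _merge(DEFAULT_CONFIG, user)


def config_hash(cfg: Dict) -> str:
    blob = yaml.safe_dump(cfg, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def dump_resolved_config(cfg: Dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))
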