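"""Parameterized mandible-like solids and verification fixtures as labeled tet4 meshes.

The mandible generator stands in for a CT-derived carnivoran mandible: a
bilaterally mirrored pair of hemimandibles (corpus + ascending ramus +
coronoid + condyle) joined at an anterior symphysis, with a carnassial
tooth crown on each side.  The solid is defined implicitly as a union of
capsules and ellipsoids, voxelized on a regular grid whose pitch is set by
``refine_level``, and each occupied cube is split into six tetrahedra
(Kuhn subdivision, consistent across cell faces).  Generation is fully
deterministic: identical parameters yield a bit-identical mesh.

Coordinate convention (mm throughout):
  +x anteroposterior (rostral), +y mediolateral (toward the balancing
  side), +z dorsoventral (dorsal).  The temporomandibular (TMJ) axis is
  parallel to +y; the working side (bite side) is y < 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .errors import GenerationError, MeshAuditError, ParameterError, SelectionError

WORKING_SIDE = "working"
BALANCING_SIDE = "balancing"

#: Subgroup naming follows comparative-myology convention:
#: T.s/T.p/T.z superficial/deep/zygomatic temporalis, M.s/M.p superficial/deep
#: masseter, Z.m zygomaticomandibularis, P.i internal pterygoid.
SUBGROUPS = ("T.s", "T.p", "T.z", "M.s", "M.p", "Z.m", "P.i")

#: Major jaw-closing muscle group of each subgroup.
SUBGROUP_MAJOR = {
    "T.s": "temporalis",
    "T.p": "temporalis",
    "T.z": "temporalis",
    "M.s": "masseter",
    "M.p": "masseter",
    "Z.m": "zygomaticomandibularis",
    "P.i": "pterygoid",
}

MAJOR_GROUPS = ("temporalis", "masseter", "zygomaticomandibularis", "pterygoid")


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class HUProfile:
    """Pseudo-Hounsfield profile of the synthetic bone and teeth.

    The cortical value is chosen so that the density regression applied to
    it yields ~1.77 g/cm^3, a typical mammalian cortical bone density; the
    core value gives a markedly softer trabecular-like interior.
    """

    cortical_hu: float = 2030.0
    core_hu: float = 200.0  # trabecular/marrow-like interior
    enamel_hu: float = 3000.0
    dentine_hu: float = 1500.0
    shell_mm: float = 2.0       # cortical shell thickness
    enamel_shell_mm: float = 2.0


@dataclass(frozen=True)
class PatchSpec:
    """Ellipsoidal surface region of a muscle attachment plus its cranial
    target point (straight line of action at the modeled 10 degree gape)."""

    name: str
    side: str                    # "working" | "balancing"
    center: np.ndarray           # (3,) mm
    radii: np.ndarray            # (3,) mm
    target: np.ndarray           # (3,) mm, must lie outside the solid
    group: str                   # major muscle group


@dataclass
class MandibleParams:
    """Dimensions and labeling parameters of the synthetic mandible.

    Defaults give wolf-like proportions: corpus noticeably longer than the
    ramus is tall, and the carnassial cusp located between symphysis and
    condyle, nearer the ramus.
    """

    corpus_length: float = 120.0
    corpus_depth: float = 34.0
    bicondylar_width: float = 70.0
    ramus_height: float = 60.0
    refine_level: int = 2
    base_pitch: float = 3.2          # voxel pitch at refine_level 1 (mm)
    refine_factor: float = 0.85      # pitch multiplier per refinement level
    cusp_radius: float = 20.0        # bite-cusp region radius around the apex
    hu_profile: HUProfile = field(default_factory=HUProfile)
    cusp_position: Optional[np.ndarray] = None          # working m1 protoconid apex
    condyle_center_left: Optional[np.ndarray] = None    # working side (y<0)
    condyle_center_right: Optional[np.ndarray] = None   # balancing side (y>0)
    attachment_patch_specs: Optional[list] = None

    def __post_init__(self) -> None:
        for nm in ("corpus_length", "corpus_depth", "bicondylar_width",
                   "ramus_height", "base_pitch", "cusp_radius"):
            if getattr(self, nm) <= 0:
                raise ParameterError(f"{nm} must be positive")
        if not isinstance(self.refine_level, (int, np.integer)) or self.refine_level < 1:
            raise ParameterError("refine_level must be an integer >= 1")
        if not (0 < self.refine_factor < 1):
            raise ParameterError("refine_factor must lie in (0, 1)")
        W2, D = self.bicondylar_width / 2.0, self.corpus_depth
        # carnivoran configuration: the condyle sits at tooth-row level,
        # well below the coronoid tip (ramus_height)
        zc = self.condyle_height
        if self.condyle_center_left is None:
            self.condyle_center_left = np.array([0.0, -W2, zc])
        if self.condyle_center_right is None:
            self.condyle_center_right = np.array([0.0, +W2, zc])
        self.condyle_center_left = np.asarray(self.condyle_center_left, float)
        self.condyle_center_right = np.asarray(self.condyle_center_right, float)
        if self.cusp_position is None:
            self.cusp_position = np.array(
                [self._tooth_x(), -self._tooth_y(), D + self._tooth_rz()])
        self.cusp_position = np.asarray(self.cusp_position, float)
        if self.attachment_patch_specs is None:
            self.attachment_patch_specs = _default_patch_specs(self)

    # tooth crown placement helpers (shared with the implicit solid);
    # the crown sits on the corpus centerline, medial to the condyles
    # (the tooth rows converge anteriorly)
    def _tooth_x(self) -> float:
        return 0.35 * self.corpus_length

    def _tooth_y(self) -> float:
        W2, L = self.bicondylar_width / 2.0, self.corpus_length
        t = (self._tooth_x() - 22.0) / (L - 6.0 - 22.0)
        return W2 - t * (W2 - 7.0)

    def _tooth_rz(self) -> float:
        return 9.0

    @property
    def condyle_height(self) -> float:
        """Dorsoventral position of the TMJ axis: just above the tooth row."""
        return self.corpus_depth + 4.0

    @property
    def pitch(self) -> float:
        return self.base_pitch * self.refine_factor ** (self.refine_level - 1)

    @property
    def tmj_axis_point(self) -> np.ndarray:
        return 0.5 * (self.condyle_center_left + self.condyle_center_right)

    @property
    def tmj_axis_direction(self) -> np.ndarray:
        return np.array([0.0, 1.0, 0.0])


def _default_patch_specs(p: MandibleParams) -> list:
    """Seven subgroup attachment patches per side, mirrored about y=0.

    Temporalis subgroups insert on the coronoid process and pull
    posterodorsally toward the temporal fossa; masseter subgroups and the
    zygomaticomandibularis insert on the lateral ramus and pull
    anterodorsally toward the zygomatic arch; the internal pterygoid
    inserts medially and pulls anterodorsomedially.
    """
    W2, H = p.bicondylar_width / 2.0, p.ramus_height
    lat, med = 5.0, -5.0  # patch-center offsets beyond the ramus plate faces
    rows = [
        # name, center(x, y-off, z), radii, target(x, y-off, z); lines of
        # action are predominantly dorsal (small gape), temporalis slightly
        # posterior, masseter/pterygoid slightly anterior
        ("T.s", (13.5, 0.0, H + 6), (10.0, 9.0, 10.0), (7.0, -4.0, H + 50)),
        ("T.p", (12.0, med, H - 12), (9.0, 4.5, 11.0), (4.0, -8.0, H + 40)),
        ("T.z", (12.0, lat, H - 12), (9.0, 4.5, 11.0), (6.0, 10.0, H + 35)),
        ("M.s", (6.0, lat, 18.0), (12.0, 4.5, 8.0), (20.0, 8.0, H + 15)),
        ("M.p", (9.0, lat, 32.0), (10.0, 4.5, 8.0), (18.0, 8.0, H + 18)),
        ("Z.m", (18.0, lat, 40.0), (6.5, 4.5, 9.0), (19.0, 10.0, H + 22)),
        ("P.i", (6.0, med, 20.0), (11.0, 4.5, 9.0), (14.0, -18.0, H + 8)),
    ]
    specs = []
    for side, s in ((WORKING_SIDE, -1.0), (BALANCING_SIDE, +1.0)):
        for name, (cx, cy, cz), radii, (tx, ty, tz) in rows:
            specs.append(PatchSpec(
                name=name, side=side,
                center=np.array([cx, s * (W2 + cy), cz]),
                radii=np.asarray(radii, float),
                target=np.array([tx, s * (W2 + ty), tz]),
                group=SUBGROUP_MAJOR[name],
            ))
    return specs


# --------------------------------------------------------------------------
# labeled mesh container
# --------------------------------------------------------------------------


@dataclass
class LabeledMesh:
    """Tet4 mesh with named node sets, muscle patches and a pseudo-HU field.

    ``patches`` maps a subgroup name like ``"T.s:working"`` to surface
    triangle indices; ``patch_nodes`` holds the node-exclusive ownership
    used for traction distribution (each surface node belongs to at most
    one patch).  Node indexing is 0-based everywhere.
    """

    nodes: np.ndarray                      # (N, 3) mm
    tets: np.ndarray                       # (T, 4) int
    surface_tris: np.ndarray               # (S, 3) int, outward-oriented
    surface_tri_tet: np.ndarray            # (S,) parent tet of each surface tri
    node_sets: Dict[str, np.ndarray]
    patches: Dict[str, np.ndarray]         # patch -> surface tri indices
    patch_nodes: Dict[str, np.ndarray]     # patch -> owned surface node indices
    patch_targets: Dict[str, np.ndarray]   # patch -> cranial target point
    element_hu: np.ndarray                 # (T,)
    element_region: np.ndarray             # (T,) in {"bone","enamel","dentine"}
    pitch: float
    condyle_centers: Dict[str, np.ndarray] = field(default_factory=dict)
    tmj_axis_point: Optional[np.ndarray] = None
    tmj_axis_direction: Optional[np.ndarray] = None
    cusp_apex_node: Optional[int] = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def tet_volumes(self) -> np.ndarray:
        x = self.nodes[self.tets]
        a, b, c = x[:, 1] - x[:, 0], x[:, 2] - x[:, 0], x[:, 3] - x[:, 0]
        return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0

    def tet_centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    def surface_tri_areas(self) -> np.ndarray:
        x = self.nodes[self.surface_tris]
        return 0.5 * np.linalg.norm(
            np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0]), axis=1)

    def node_surface_weights(self) -> np.ndarray:
        """Per-node share of surface area: one third of incident tri areas."""
        w = np.zeros(self.n_nodes)
        areas = self.surface_tri_areas()
        for k in range(3):
            np.add.at(w, self.surface_tris[:, k], areas / 3.0)
        return w


# --------------------------------------------------------------------------
# implicit solid
# --------------------------------------------------------------------------


def _q_ellipsoid(pts: np.ndarray, center, radii) -> np.ndarray:
    """Scaled squared distance; < 1 inside."""
    d = (pts - np.asarray(center)) / np.asarray(radii)
    return np.einsum("ij,ij->i", d, d)


def _q_capsule(pts: np.ndarray, p0, p1, r1: float, r2: float,
               n1=None) -> np.ndarray:
    """Capsule along segment p0-p1 with elliptical cross-section.

    ``n1`` (optional) fixes the first cross-section direction (radius r1);
    the second (radius r2) completes the frame.  End caps use radius r1.
    """
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    axis = p1 - p0
    L = np.linalg.norm(axis)
    a = axis / L
    if n1 is None:
        ref = np.array([0.0, 0.0, 1.0])
        if abs(a @ ref) > 0.9:
            ref = np.array([1.0, 0.0, 0.0])
        n1 = np.cross(a, ref)
        n1 /= np.linalg.norm(n1)
    else:
        n1 = np.asarray(n1, float)
        n1 = n1 - (n1 @ a) * a
        n1 /= np.linalg.norm(n1)
    n2 = np.cross(a, n1)
    v = pts - p0
    t = np.clip(v @ a, 0.0, L)
    w = v - t[:, None] * a
    ax_over = (v @ a) - t  # beyond-cap axial excess
    r_cap = min(r1, r2)
    return (w @ n1 / r1) ** 2 + (w @ n2 / r2) ** 2 + (ax_over / r_cap) ** 2


#: Condyle ellipsoid semi-axes (ap, ml, dv), mm.
CONDYLE_RADII = (8.0, 12.0, 6.5)


def _mandible_primitives(p: MandibleParams):
    """(name, q-function) list; point is inside the solid if min q < 1.

    Carnivoran configuration: the condyle lies at tooth-row level while
    the coronoid process rises to ``ramus_height``.
    """
    W2, H, D, L = (p.bicondylar_width / 2.0, p.ramus_height,
                   p.corpus_depth, p.corpus_length)
    zc = p.condyle_height
    prims = []
    ex = np.array([1.0, 0.0, 0.0])
    for s in (-1.0, +1.0):
        y = s * W2
        prims += [
            ("corpus", lambda pts, y=y: _q_capsule(
                pts, (L - 6.0, s_sign(y) * 7.0, D / 2), (22.0, y, D / 2),
                8.0, D / 2, n1=np.array([0.0, 1.0, 0.0]))),
            ("ramus", lambda pts, y=y: _q_capsule(
                pts, (10.0, y, 14.0), (12.0, y, H - 8.0), 14.0, 5.0, n1=ex)),
            ("coronoid", lambda pts, y=y: _q_capsule(
                pts, (12.0, y, H - 14.0), (15.0, y, H + 10.0), 7.5, 4.0, n1=ex)),
            ("condyle", lambda pts, y=y: _q_ellipsoid(
                pts, (0.0, y, zc), CONDYLE_RADII)),
            ("neck", lambda pts, y=y: _q_capsule(
                pts, (2.0, y, zc), (10.0, y, zc + 3.0), 6.0, 5.0, n1=ex)),
            ("angular", lambda pts, y=y: _q_ellipsoid(
                pts, (0.0, y, 14.0), (9.0, 5.5, 6.0))),
            # blade-like carnassial crown: long anteroposteriorly, thin
            # mediolaterally, as in shearing carnivoran teeth
            ("crown", lambda pts, s=s: _q_ellipsoid(
                pts, (p._tooth_x(), s * p._tooth_y(), D),
                (10.0, 4.5, p._tooth_rz()))),
        ]
    prims.append(("symphysis", lambda pts: _q_ellipsoid(
        pts, (L - 6.0, 0.0, D / 2), (11.0, 8.5, D / 2))))
    return prims


def s_sign(y: float) -> float:
    return -1.0 if y < 0 else 1.0


def _implicit_value(p: MandibleParams, pts: np.ndarray) -> np.ndarray:
    """1 - min_q: positive inside the solid, larger = deeper."""
    qmin = np.full(len(pts), np.inf)
    for _, qf in _mandible_primitives(p):
        np.minimum(qmin, qf(pts), out=qmin)
    return 1.0 - qmin


def _crown_q(p: MandibleParams, pts: np.ndarray) -> np.ndarray:
    D, yt = p.corpus_depth, p._tooth_y()
    q = np.minimum(
        _q_ellipsoid(pts, (p._tooth_x(), -yt, D), (10.0, 4.5, p._tooth_rz())),
        _q_ellipsoid(pts, (p._tooth_x(), +yt, D), (10.0, 4.5, p._tooth_rz())))
    return q


def point_inside_solid(p: MandibleParams, pts: np.ndarray) -> np.ndarray:
    return _implicit_value(p, np.atleast_2d(pts)) > 0.0


# --------------------------------------------------------------------------
# voxelization -> tet4
# --------------------------------------------------------------------------

# Kuhn subdivision of the unit cube into 6 tets sharing the main diagonal
# (corner bit order: bit0=x, bit1=y, bit2=z).  Face-consistent across cells.
_KUHN_PERMS = ((0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0))
_KUHN_TETS = tuple(
    (0, 1 << p[0], (1 << p[0]) | (1 << p[1]), 7) for p in _KUHN_PERMS
)


def _fill_nonmanifold_edges(occ: np.ndarray, val: np.ndarray) -> bool:
    """Fill cells so no grid edge is shared by exactly two diagonal cells.

    Of the two empty cells completing the 2x2 block, the one with the
    larger implicit value is filled (ties: the lexicographically first).
    Returns True if anything changed.
    """
    changed = False
    # For each pair of axes (a, b) examine 2x2 blocks in that plane.
    for a, b in ((0, 1), (0, 2), (1, 2)):
        sl = [slice(None)] * 3

        def block(da, db):
            s = [slice(None)] * 3
            s[a] = slice(1, None) if da else slice(None, -1)
            s[b] = slice(1, None) if db else slice(None, -1)
            return tuple(s)

        o00, o10 = occ[block(0, 0)], occ[block(1, 0)]
        o01, o11 = occ[block(0, 1)], occ[block(1, 1)]
        for diag in (o00 & o11 & ~o10 & ~o01, o10 & o01 & ~o00 & ~o11):
            idx = np.argwhere(diag)
            for ijk in idx:
                base = ijk.copy()
                # the two empty candidates in this 2x2 block
                cands = []
                for da in (0, 1):
                    for db in (0, 1):
                        c = base.copy()
                        c[a] += da
                        c[b] += db
                        if not occ[tuple(c)]:
                            cands.append(tuple(c))
                if not cands:
                    continue
                pick = max(cands, key=lambda c: (val[c], [-x for x in c]))
                occ[pick] = True
                changed = True
        del sl
    return changed


def _voxel_occupancy(p: MandibleParams):
    """Occupancy grid (cells), its origin and pitch, symmetric about y=0."""
    h = p.pitch
    W2, H, L = p.bicondylar_width / 2.0, p.ramus_height, p.corpus_length
    xlo, xhi = -14.0, L + 10.0
    ymax = W2 + 16.0
    zlo, zhi = -3.0, H + 18.0
    nx = int(np.ceil((xhi - xlo) / h))
    ny2 = int(np.ceil(ymax / h))        # cells per half-width; node plane at y=0
    nz = int(np.ceil((zhi - zlo) / h))
    origin = np.array([xlo, -ny2 * h, zlo])
    shape = (nx, 2 * ny2, nz)
    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    centers = origin + (np.stack([ii, jj, kk], axis=-1) + 0.5) * h
    val = _implicit_value(p, centers.reshape(-1, 3)).reshape(shape)
    occ = val > 0.0
    if not occ.any():
        raise GenerationError("empty voxelization: solid degenerate at this pitch")
    # iterate: repair non-manifold edges, keep largest face-connected component
    for _ in range(20):
        changed = _fill_nonmanifold_edges(occ, val)
        lab, nlab = ndimage.label(occ)
        if nlab > 1:
            sizes = ndimage.sum_labels(np.ones_like(lab), lab, range(1, nlab + 1))
            keep = 1 + int(np.argmax(sizes))
            occ2 = lab == keep
            changed = changed or (occ2.sum() != occ.sum())
            occ = occ2
        if not changed:
            break
    else:  # pragma: no cover - safety net
        raise GenerationError("voxel cleanup did not converge")
    return occ, origin, h, val


def _cells_to_tets(occ: np.ndarray, origin: np.ndarray, h: float):
    """Structured cube-to-tet subdivision with globally consistent diagonals."""
    nx, ny, nz = occ.shape
    ci, cj, ck = np.nonzero(occ)
    if len(ci) == 0:
        raise GenerationError("no occupied cells")
    # corner node grid ids
    nyn, nzn = ny + 1, nz + 1

    def nid(i, j, k):
        return (i * nyn + j) * nzn + k

    corners = np.empty((len(ci), 8), dtype=np.int64)
    for c in range(8):
        di, dj, dk = c & 1, (c >> 1) & 1, (c >> 2) & 1
        corners[:, c] = nid(ci + di, cj + dj, ck + dk)
    used, inv = np.unique(corners, return_inverse=True)
    corners = inv.reshape(corners.shape).astype(np.int64)
    gi = used // (nyn * nzn)
    gj = (used // nzn) % nyn
    gk = used % nzn
    nodes = origin + np.stack([gi, gj, gk], axis=-1) * h
    tets = np.concatenate([corners[:, list(t)] for t in _KUHN_TETS], axis=0)
    # fix orientation: positive signed volume
    x = nodes[tets]
    vol6 = np.einsum("ij,ij->i", x[:, 1] - x[:, 0],
                     np.cross(x[:, 2] - x[:, 0], x[:, 3] - x[:, 0]))
    flip = vol6 < 0
    tets[flip, 0], tets[flip, 1] = tets[flip, 1], tets[flip, 0].copy()
    # deterministic ordering: sort tets lexicographically
    order = np.lexsort(tets.T[::-1])
    return nodes.astype(float), tets[order].astype(np.int64)


_TET_FACES = ((1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1))  # outward for +vol


def extract_surface(tets: np.ndarray):
    """Boundary triangles (outward-oriented) and their parent tets."""
    faces = np.concatenate([tets[:, list(f)] for f in _TET_FACES], axis=0)
    parent = np.tile(np.arange(len(tets)), 4)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True,
                               return_counts=True)
    boundary = counts[inv] == 1
    return faces[boundary], parent[boundary]


# --------------------------------------------------------------------------
# labeling
# --------------------------------------------------------------------------


def _label_mesh(p: MandibleParams, nodes, tets) -> LabeledMesh:
    h = p.pitch
    surface_tris, surf_parent = extract_surface(tets)
    surf_nodes = np.unique(surface_tris)
    tree = cKDTree(nodes[surf_nodes])
    centroids = nodes[tets].mean(axis=1)
    depth, _ = tree.query(centroids)

    # region: tooth crown above the bone line, enamel shell outside
    hu = p.hu_profile
    crown = (_crown_q(p, centroids) < 1.0) & (centroids[:, 2] > p.corpus_depth)
    enamel_thr = max(hu.enamel_shell_mm, 0.9 * h)
    region = np.full(len(tets), "bone", dtype="U7")
    region[crown & (depth < enamel_thr)] = "enamel"
    region[crown & (depth >= enamel_thr)] = "dentine"

    ehu = np.empty(len(tets))
    bone = region == "bone"
    d = depth[bone]
    t = hu.shell_mm
    w = np.where(d <= t, 1.0, np.exp(-(d - t) / t))
    ehu[bone] = hu.core_hu + (hu.cortical_hu - hu.core_hu) * w
    ehu[region == "enamel"] = hu.enamel_hu
    ehu[region == "dentine"] = hu.dentine_hu

    # ---- node sets -------------------------------------------------------
    node_sets: Dict[str, np.ndarray] = {}
    xyz = nodes[surf_nodes]

    # condyles: surface nodes inside a slightly inflated condyle ellipsoid
    for key, center, sgn in (("condyle_left", p.condyle_center_left, -1),
                             ("condyle_right", p.condyle_center_right, +1)):
        q = _q_ellipsoid(xyz, center, np.asarray(CONDYLE_RADII) * 1.25)
        sel = surf_nodes[(q < 1.0) & (sgn * xyz[:, 1] > 0)]
        if len(sel) == 0:
            raise GenerationError(f"empty condyle node set {key}")
        node_sets[key] = np.sort(sel)

    # symphysis: midline surface nodes in the anterior fifth
    mid = surf_nodes[(np.abs(xyz[:, 1]) < 0.51 * h)
                     & (xyz[:, 0] > p.corpus_length - 22.0)]
    node_sets["symphysis"] = np.sort(mid)

    # bite cusp: tooth-surface nodes (working side) near the apex
    tooth_tris = region[surf_parent] != "bone"
    tooth_nodes = np.unique(surface_tris[tooth_tris])
    tooth_nodes = tooth_nodes[nodes[tooth_nodes, 1] < 0]
    if len(tooth_nodes) == 0:
        raise GenerationError("no working-side tooth surface nodes")
    d_apex = np.linalg.norm(nodes[tooth_nodes] - p.cusp_position, axis=1)
    apex = int(tooth_nodes[np.lexsort((tooth_nodes, d_apex))[0]])
    d_from_apex = np.linalg.norm(nodes[tooth_nodes] - nodes[apex], axis=1)
    in_cusp = d_from_apex <= p.cusp_radius
    order = np.lexsort((tooth_nodes[in_cusp], d_from_apex[in_cusp]))
    node_sets["bite_cusp"] = tooth_nodes[in_cusp][order]  # sorted by distance

    # ---- muscle patches (node-exclusive ownership) -----------------------
    patches: Dict[str, np.ndarray] = {}
    patch_nodes: Dict[str, np.ndarray] = {}
    patch_targets: Dict[str, np.ndarray] = {}
    qmat = np.full((len(p.attachment_patch_specs), len(surf_nodes)), np.inf)
    for i, spec in enumerate(p.attachment_patch_specs):
        qmat[i] = _q_ellipsoid(xyz, spec.center, spec.radii)
    owner = np.argmin(qmat, axis=0)
    covered = qmat[owner, np.arange(len(surf_nodes))] < 1.0
    node_owner = np.full(len(nodes), -1, dtype=int)
    node_owner[surf_nodes[covered]] = owner[covered]
    for i, spec in enumerate(p.attachment_patch_specs):
        key = f"{spec.name}:{spec.side}"
        own = np.sort(surf_nodes[covered & (owner == i)])
        if len(own) == 0:
            raise GenerationError(f"empty muscle attachment patch {key}")
        patch_nodes[key] = own
        patch_targets[key] = spec.target.copy()
        # triangles with at least 2 owned corners (for export/inspection)
        hits = (node_owner[surface_tris] == i).sum(axis=1)
        patches[key] = np.nonzero(hits >= 2)[0]

    return LabeledMesh(
        nodes=nodes, tets=tets,
        surface_tris=surface_tris, surface_tri_tet=surf_parent,
        node_sets=node_sets, patches=patches, patch_nodes=patch_nodes,
        patch_targets=patch_targets,
        element_hu=ehu, element_region=region, pitch=h,
        condyle_centers={WORKING_SIDE: p.condyle_center_left,
                         BALANCING_SIDE: p.condyle_center_right},
        tmj_axis_point=p.tmj_axis_point,
        tmj_axis_direction=p.tmj_axis_direction,
        cusp_apex_node=apex,
    )


# --------------------------------------------------------------------------
# public builders
# --------------------------------------------------------------------------


def build_mandible(params: Optional[MandibleParams] = None, **kw) -> LabeledMesh:
    """Generate the labeled synthetic mandible mesh.

    Deterministic: identical parameters give a bit-identical mesh.  Raises
    :class:`ParameterError` for invalid parameters and
    :class:`GenerationError` for a degenerate solid or empty label.
    """
    if params is None:
        params = MandibleParams(**kw)
    occ, origin, h, _ = _voxel_occupancy(params)
    nodes, tets = _cells_to_tets(occ, origin, h)
    return _label_mesh(params, nodes, tets)


def _structured_box(origin, lengths, ncells) -> tuple:
    """Nodes and tets of a fully occupied structured box."""
    nx, ny, nz = ncells
    occ = np.ones((nx, ny, nz), dtype=bool)
    pitch = 1.0  # placeholder; rescale after
    nodes, tets = _cells_to_tets(occ, np.zeros(3), pitch)
    nodes = nodes * (np.asarray(lengths, float) / np.asarray(ncells, float))
    return np.asarray(origin, float) + nodes, tets


def build_beam_fixture(length: float, width: float, height: float,
                       resolution: int) -> LabeledMesh:
    """Rectangular cantilever fixture with ``fixed_end`` and ``tip`` node sets.

    The section is divided into ``resolution`` cells across the width (and
    proportionally across the height); cell length along the beam is twice
    the cell width, e.g. (100, 10, 10, resolution=2) gives a 10 x 2 x 2 cell
    grid, i.e. 240 tets.
    """
    if length <= 0 or width <= 0 or height <= 0:
        raise ParameterError("beam dimensions must be positive")
    if resolution < 1:
        raise ParameterError("resolution must be >= 1")
    ny = int(resolution)
    nz = max(1, round(resolution * height / width))
    nx = max(1, round(length * resolution / (2.0 * width)))
    nodes, tets = _structured_box((0, 0, 0), (length, width, height),
                                  (nx, ny, nz))
    surface_tris, parent = extract_surface(tets)
    node_sets = {
        "fixed_end": np.nonzero(np.abs(nodes[:, 0]) < 1e-12)[0],
        "tip": np.nonzero(np.abs(nodes[:, 0] - length) < 1e-9 * max(length, 1))[0],
    }
    return LabeledMesh(
        nodes=nodes, tets=tets, surface_tris=surface_tris,
        surface_tri_tet=parent, node_sets=node_sets,
        patches={}, patch_nodes={}, patch_targets={},
        element_hu=np.zeros(len(tets)),
        element_region=np.full(len(tets), "bone", dtype="U7"),
        pitch=width / ny,
    )


def build_patch_cube() -> LabeledMesh:
    """Unit cube with an interior node and a labeled boundary node set."""
    nodes, tets = _structured_box((0, 0, 0), (1, 1, 1), (2, 2, 2))
    surface_tris, parent = extract_surface(tets)
    on_face = np.any(np.isclose(nodes, 0.0) | np.isclose(nodes, 1.0), axis=1)
    node_sets = {
        "boundary": np.nonzero(on_face)[0],
        "interior": np.nonzero(~on_face)[0],
    }
    return LabeledMesh(
        nodes=nodes, tets=tets, surface_tris=surface_tris,
        surface_tri_tet=parent, node_sets=node_sets,
        patches={}, patch_nodes={}, patch_targets={},
        element_hu=np.zeros(len(tets)),
        element_region=np.full(len(tets), "bone", dtype="U7"),
        pitch=0.5,
    )


# --------------------------------------------------------------------------
# selections
# --------------------------------------------------------------------------


def select_bite_nodes(mesh: LabeledMesh, k: int) -> np.ndarray:
    """The ``k`` cusp-surface nodes nearest the carnassial apex.

    Results are nested: the selection for ``k`` is a prefix of the one for
    ``k + 1``; ``k = 1`` returns exactly the apex node.
    """
    cusp = mesh.node_sets["bite_cusp"]
    if k < 1 or k > len(cusp):
        raise SelectionError(
            f"requested {k} bite nodes; cusp region has {len(cusp)}")
    return cusp[:k].copy()


def select_tmj_nodes(mesh: LabeledMesh, side: str, mode: str) -> np.ndarray:
    """Condyle nodes used for the TMJ constraint.

    ``mode='single'`` returns the node nearest the condyle center;
    ``mode='row'`` returns 10 nodes spanning the condyle mediolaterally.
    """
    key = "condyle_left" if side == WORKING_SIDE else "condyle_right"
    if side not in (WORKING_SIDE, BALANCING_SIDE):
        raise SelectionError(f"unknown side {side!r}")
    cond = mesh.node_sets[key]
    center = mesh.condyle_centers[side]
    if mode == "single":
        d = np.linalg.norm(mesh.nodes[cond] - center, axis=1)
        return np.array([cond[np.lexsort((cond, d))[0]]])
    if mode == "row":
        n_row = 10
        if len(cond) < n_row:
            raise SelectionError(
                f"condyle set {key} has {len(cond)} nodes; need {n_row}")
        order = np.lexsort((cond, mesh.nodes[cond, 1]))
        idx = np.round(np.linspace(0, len(cond) - 1, n_row)).astype(int)
        return cond[order][idx]
    raise SelectionError(f"unknown TMJ selection mode {mode!r}")


# --------------------------------------------------------------------------
# audit
# --------------------------------------------------------------------------


def audit_mesh(mesh: LabeledMesh) -> Dict[str, float]:
    """Structural audit; raises :class:`MeshAuditError` on any violation.

    Checks: strictly positive tet volumes, a single connected component,
    index validity, a closed surface (every surface edge shared by exactly
    two surface triangles), and non-empty condyle sets.
    """
    n = mesh.n_nodes
    if mesh.tets.min() < 0 or mesh.tets.max() >= n:
        raise MeshAuditError("tet node index out of range")
    if mesh.surface_tris.min() < 0 or mesh.surface_tris.max() >= n:
        raise MeshAuditError("surface tri node index out of range")
    vols = mesh.tet_volumes()
    if not (vols > 0).all():
        raise MeshAuditError(f"{(vols <= 0).sum()} non-positive tet volumes")
    # connectivity via shared nodes
    t = np.arange(mesh.n_tets)
    rows = np.repeat(t, 4)
    cols = mesh.tets.ravel()
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)),
                     shape=(mesh.n_tets, n))
    ncomp, _ = connected_components((adj @ adj.T) > 0, directed=False)
    if ncomp != 1:
        raise MeshAuditError(f"mesh has {ncomp} connected components")
    # closed surface: each surface edge in exactly 2 surface triangles
    e = np.concatenate([mesh.surface_tris[:, [0, 1]],
                        mesh.surface_tris[:, [1, 2]],
                        mesh.surface_tris[:, [2, 0]]], axis=0)
    e = np.sort(e, axis=1)
    _, counts = np.unique(e, axis=0, return_counts=True)
    if not (counts == 2).all():
        bad = int((counts != 2).sum())
        raise MeshAuditError(f"{bad} surface edges not shared by exactly 2 tris")
    for key in ("condyle_left", "condyle_right"):
        if key in mesh.node_sets and len(mesh.node_sets[key]) == 0:
            raise MeshAuditError(f"empty node set {key}")
    for name, tris in mesh.patches.items():
        if len(tris) and tris.max() >= len(mesh.surface_tris):
            raise MeshAuditError(f"patch {name} references invalid surface tri")
    return {"n_nodes": n, "n_tets": mesh.n_tets,
            "volume": float(vols.sum()), "min_volume": float(vols.min())}
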