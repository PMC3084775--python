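"""Linear-static elasticity on tet4 meshes.

Four-noded (constant-strain) tetrahedra with three translational DOFs per
node.  Units are mm-N-MPa internally (moduli supplied in GPa are scaled by
1e3); strain energy is reported in Joules (N.mm x 1e-3).

Constraints are either fixed translational DOFs (optionally with prescribed
values, used by the patch test) or rigid-link groups: all nodes of a group
move as u = theta * (e x (x - p)) for one unknown small-rotation scalar
theta about the axis (p, e) — the joint-axis beam idealization of the TMJ.
Links are enforced by exact multipoint-constraint elimination, not penalty
stiffness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu, cg

from .errors import GeometryError, AssemblyError, SolverError, ParameterError
from .geometry import LabeledMesh, select_bite_nodes, select_tmj_nodes, \
    WORKING_SIDE, BALANCING_SIDE
from .materials import MaterialTable

GPA_TO_MPA = 1.0e3
NMM_TO_J = 1.0e-3


# --------------------------------------------------------------------------
# constraints
# --------------------------------------------------------------------------


@dataclass
class LinkGroup:
    """Rigid links from ``linked_nodes`` to a beam along the axis (p, e).

    All nodes share one small-rotation scalar; ``arms`` caches e x (x - p)
    per node.
    """

    axis_point: np.ndarray
    axis_direction: np.ndarray
    linked_nodes: np.ndarray
    arms: Optional[np.ndarray] = None
    label: str = ""

    def __post_init__(self):
        self.axis_direction = np.asarray(self.axis_direction, float)
        n = np.linalg.norm(self.axis_direction)
        if not np.isclose(n, 1.0, atol=1e-9):
            raise ParameterError("link axis_direction must be a unit vector")
        self.axis_point = np.asarray(self.axis_point, float)
        self.linked_nodes = np.asarray(self.linked_nodes, int)

    def compute_arms(self, nodes: np.ndarray) -> None:
        r = nodes[self.linked_nodes] - self.axis_point
        self.arms = np.cross(self.axis_direction[None, :], r)


@dataclass
class ConstraintSet:
    """Fixed translational DOFs plus rigid-link-to-axis groups."""

    fixed_dofs: List[Tuple[int, int]] = field(default_factory=list)
    link_groups: List[LinkGroup] = field(default_factory=list)
    prescribed: Dict[Tuple[int, int], float] = field(default_factory=dict)

    def fix_node(self, node: int, value: Sequence[float] = (0.0, 0.0, 0.0)) -> None:
        for ax in range(3):
            self.fixed_dofs.append((int(node), ax))
            if value[ax] != 0.0:
                self.prescribed[(int(node), ax)] = float(value[ax])

    def fix_nodes(self, nodes: Sequence[int]) -> None:
        for n in nodes:
            self.fix_node(n)

    def validate(self) -> None:
        fixed = set(self.fixed_dofs)
        linked = {(int(n), ax) for g in self.link_groups
                  for n in g.linked_nodes for ax in range(3)}
        overlap = fixed & linked
        if overlap:
            raise ParameterError(
                f"DOFs appear both fixed and linked: {sorted(overlap)[:5]}")


def _link_anchor_node(mesh: LabeledMesh, side: str) -> np.ndarray:
    """Condyle node anchoring the single rigid link: the ventral condylar
    surface point, so the link hangs from the axis beam with a finite
    lever arm and a well-defined sagittal (dorsoventral-plane) tangent."""
    from .geometry import CONDYLE_RADII
    key = "condyle_left" if side == WORKING_SIDE else "condyle_right"
    cond = mesh.node_sets[key]
    anchor = mesh.condyle_centers[side] - np.array([0.0, 0.0, CONDYLE_RADII[2]])
    d = np.linalg.norm(mesh.nodes[cond] - anchor, axis=1)
    return np.array([cond[np.lexsort((cond, d))[0]]])


def build_constraints(mesh: LabeledMesh, bite_nodes: np.ndarray,
                      tmj_mode: str = "single_node") -> ConstraintSet:
    """Bite-point fixations plus one of the four TMJ constraint types:
    ``single_node``, ``row_nodes``, ``single_link``, ``row_links``.
    """
    cs = ConstraintSet()
    cs.fix_nodes(np.asarray(bite_nodes, int))
    node_mode = {"single_node": "single", "row_nodes": "row"}
    link_mode = {"single_link": "single", "row_links": "row"}
    if tmj_mode in node_mode:
        for side in (WORKING_SIDE, BALANCING_SIDE):
            cs.fix_nodes(select_tmj_nodes(mesh, side, node_mode[tmj_mode]))
    elif tmj_mode in link_mode:
        for side in (WORKING_SIDE, BALANCING_SIDE):
            if tmj_mode == "single_link":
                sel = _link_anchor_node(mesh, side)
            else:
                sel = select_tmj_nodes(mesh, side, link_mode[tmj_mode])
            g = LinkGroup(axis_point=mesh.tmj_axis_point,
                          axis_direction=mesh.tmj_axis_direction,
                          linked_nodes=sel, label=side)
            g.compute_arms(mesh.nodes)
            # a node exactly on the axis cannot carry a rotation DOF
            if np.linalg.norm(g.arms) < 1e-9:
                cs.fix_nodes(sel)
            else:
                cs.link_groups.append(g)
    else:
        raise ParameterError(f"unknown TMJ constraint mode {tmj_mode!r}")
    cs.validate()
    return cs


# --------------------------------------------------------------------------
# element matrices
# --------------------------------------------------------------------------


def _elastic_d(E_mpa: float, nu: float) -> np.ndarray:
    """Isotropic 6x6 constitutive matrix (Voigt order xx,yy,zz,xy,yz,zx)."""
    lam = E_mpa * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E_mpa / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * mu
    D[np.arange(3, 6), np.arange(3, 6)] = mu
    return D


def _tet_gradients(coords: np.ndarray):
    """Shape-function gradients (n_tets, 4, 3) and volumes of tet batches."""
    x = coords  # (T, 4, 3)
    J = x[:, 1:] - x[:, 0:1]              # (T, 3, 3) rows = edge vectors
    vol = np.linalg.det(J) / 6.0
    if np.any(vol <= 0):
        bad = int(np.argmax(vol <= 0))
        raise GeometryError(f"degenerate or inverted tet at index {bad}")
    Jinv = np.linalg.inv(J)               # d(xi)/d(x)
    g = np.empty((len(x), 4, 3))
    g[:, 1:, :] = np.transpose(Jinv, (0, 2, 1))
    g[:, 0, :] = -g[:, 1:, :].sum(axis=1)
    return g, vol


def _b_matrices(grads: np.ndarray) -> np.ndarray:
    """Strain-displacement matrices (T, 6, 12) from gradients (T, 4, 3)."""
    T = len(grads)
    B = np.zeros((T, 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        c = 3 * a
        B[:, 0, c + 0] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c + 0] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c + 0] = gz
        B[:, 5, c + 2] = gx
    return B


def element_stiffness(tet_coords: np.ndarray, E: float, nu: float) -> np.ndarray:
    """12x12 stiffness of one constant-strain tetrahedron (E in GPa)."""
    coords = np.asarray(tet_coords, float)[None, :, :]
    g, vol = _tet_gradients(coords)
    B = _b_matrices(g)[0]
    D = _elastic_d(E * GPA_TO_MPA, nu)
    return float(vol[0]) * B.T @ D @ B


def assemble(mesh: LabeledMesh, materials: MaterialTable) -> sparse.csr_matrix:
    """Global sparse symmetric stiffness, dimension 3 * n_nodes."""
    if len(materials.element_class) != mesh.n_tets:
        raise AssemblyError(
            f"material map covers {len(materials.element_class)} elements; "
            f"mesh has {mesh.n_tets}")
    coords = mesh.nodes[mesh.tets]
    grads, vol = _tet_gradients(coords)
    B = _b_matrices(grads)
    Ke = np.zeros((mesh.n_tets, 12, 12))
    ec = materials.element_class
    for ci, (E_gpa, nu, _) in enumerate(materials.classes):
        m = ec == ci
        if not m.any():
            continue
        D = _elastic_d(E_gpa * GPA_TO_MPA, nu)
        Ke[m] = np.einsum("tji,jk,tkl->til", B[m], D, B[m],
                          optimize=True) * vol[m, None, None]
    edof = (3 * mesh.tets[:, :, None] + np.arange(3)[None, None, :]).reshape(
        mesh.n_tets, 12)
    rows = np.repeat(edof, 12, axis=1).ravel()
    cols = np.tile(edof, (1, 12)).ravel()
    n = 3 * mesh.n_nodes
    K = sparse.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    return K


# --------------------------------------------------------------------------
# solve
# --------------------------------------------------------------------------


@dataclass
class SolveResult:
    """Solved state: displacements, constraint forces, energy, stresses."""

    displacement: np.ndarray                 # (N, 3) mm
    reaction: Dict[int, np.ndarray]          # fixed node -> force N
    link_force: Dict[int, np.ndarray]        # linked node -> transmitted force N
    link_theta: Dict[str, float]             # link group label -> rotation
    total_strain_energy: float               # J
    applied: np.ndarray                      # (N, 3) the load vector used
    element_stress: Optional[np.ndarray] = None   # (T, 3, 3) MPa
    element_strain: Optional[np.ndarray] = None   # (T, 3, 3)

    def equilibrium_residual(self) -> float:
        """|sum applied + sum reactions + sum link forces| (N)."""
        total = self.applied.sum(axis=0).astype(float).copy()
        for f in self.reaction.values():
            total += f
        for f in self.link_force.values():
            total += f
        return float(np.linalg.norm(total))


def _reduction(n_dofs: int, constraints: ConstraintSet):
    """Transformation u = T q + g eliminating fixed and linked DOFs."""
    constraints.validate()
    fixed = {}
    for node, ax in constraints.fixed_dofs:
        fixed[3 * node + ax] = constraints.prescribed.get((node, ax), 0.0)
    linked_dofs = set()
    for gI in constraints.link_groups:
        for node in gI.linked_nodes:
            for ax in range(3):
                linked_dofs.add(3 * int(node) + ax)
    g = np.zeros(n_dofs)
    for d, v in fixed.items():
        g[d] = v
    eliminated = set(fixed) | linked_dofs
    free = np.array(sorted(set(range(n_dofs)) - eliminated), dtype=int)
    n_free = len(free)
    n_links = len(constraints.link_groups)
    rows = list(free)
    cols = list(range(n_free))
    vals = [1.0] * n_free
    for li, grp in enumerate(constraints.link_groups):
        if grp.arms is None:
            raise ParameterError("link group arms not computed")
        col = n_free + li
        for node, arm in zip(grp.linked_nodes, grp.arms):
            for ax in range(3):
                rows.append(3 * int(node) + ax)
                cols.append(col)
                vals.append(arm[ax])
    T = sparse.coo_matrix((vals, (rows, cols)),
                          shape=(n_dofs, n_free + n_links)).tocsr()
    return T, g


def solve_static(K: sparse.spmatrix, loads: np.ndarray,
                 constraints: ConstraintSet,
                 method: str = "direct", cg_tol: float = 1e-10) -> SolveResult:
    """Solve K u = f under the constraint set; recover constraint forces.

    ``loads`` is (N, 3) nodal forces in Newtons.  Raises
    :class:`SolverError` for a singular (insufficiently constrained) or
    ill-conditioned reduced system.
    """
    n_dofs = K.shape[0]
    f = np.asarray(loads, float).reshape(-1)
    if f.shape[0] != n_dofs:
        raise ParameterError("load vector length does not match stiffness")
    T, g = _reduction(n_dofs, constraints)
    if T.shape[1] == 0:
        u = g
    else:
        rhs_full = f - (K @ g if np.any(g) else np.zeros(n_dofs))
        Kr = (T.T @ K @ T).tocsc()
        fr = T.T @ rhs_full
        if method == "direct":
            try:
                lu = splu(Kr)
            except RuntimeError as exc:
                raise SolverError(
                    f"insufficiently constrained system: {exc}") from exc
            q = lu.solve(fr)
        elif method == "cg":
            M = sparse.diags(1.0 / Kr.diagonal())
            q, info = cg(Kr, fr, rtol=cg_tol, M=M, maxiter=20000)
            if info != 0:
                raise SolverError(f"iterative solve did not converge (info={info})")
        else:
            raise ParameterError(f"unknown solver method {method!r}")
        if not np.all(np.isfinite(q)):
            raise SolverError("insufficiently constrained system: NaN in solution")
        res = np.linalg.norm(Kr @ q - fr)
        scale = max(np.linalg.norm(fr), 1e-30)
        if res > 1e-6 * scale:
            raise SolverError(
                "ill-conditioned solve: relative residual "
                f"{res / scale:.2e} (diag range {Kr.diagonal().min():.2e}.."
                f"{Kr.diagonal().max():.2e})")
        u = T @ q + g
    # constraint forces = K u - f on eliminated DOFs (zero on free DOFs)
    resid = K @ u - f
    reaction = {}
    for node in sorted({nd for nd, _ in constraints.fixed_dofs}):
        reaction[node] = resid[3 * node: 3 * node + 3].copy()
    link_force = {}
    link_theta = {}
    for li, grp in enumerate(constraints.link_groups):
        for node in grp.linked_nodes:
            link_force[int(node)] = resid[3 * node: 3 * node + 3].copy()
        label = grp.label or f"link_{li}"
        link_theta[label] = float(u[3 * grp.linked_nodes[0]: 3 * grp.linked_nodes[0] + 3]
                                  @ grp.arms[0] / max(grp.arms[0] @ grp.arms[0], 1e-300)) \
            if np.linalg.norm(grp.arms[0]) > 0 else 0.0
    energy = 0.5 * float(u @ (K @ u)) * NMM_TO_J
    return SolveResult(
        displacement=u.reshape(-1, 3),
        reaction=reaction, link_force=link_force, link_theta=link_theta,
        total_strain_energy=energy,
        applied=np.asarray(loads, float).reshape(-1, 3).copy())


# --------------------------------------------------------------------------
# recovery
# --------------------------------------------------------------------------


def recover_stress(mesh: LabeledMesh, materials: MaterialTable,
                   displacement: np.ndarray,
                   result: Optional[SolveResult] = None):
    """Per-element constant stress (MPa) and strain tensors via Hooke's law.

    If ``result`` is given the tensors are stored on it.
    """
    u = np.asarray(displacement, float).reshape(-1, 3)
    coords = mesh.nodes[mesh.tets]
    grads, _ = _tet_gradients(coords)
    ue = u[mesh.tets]                                  # (T, 4, 3)
    grad_u = np.einsum("tai,taj->tij", grads, ue)      # du_j/dx_i
    strain = 0.5 * (grad_u + np.transpose(grad_u, (0, 2, 1)))
    stress = np.zeros_like(strain)
    tr = np.trace(strain, axis1=1, axis2=2)
    eye = np.eye(3)
    ec = materials.element_class
    for ci, (E_gpa, nu, _) in enumerate(materials.classes):
        m = ec == ci
        if not m.any():
            continue
        E = E_gpa * GPA_TO_MPA
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        stress[m] = lam * tr[m, None, None] * eye + 2 * mu * strain[m]
    if result is not None:
        result.element_stress = stress
        result.element_strain = strain
    return stress, strain


def element_energies(mesh: LabeledMesh, stress: np.ndarray,
                     strain: np.ndarray) -> np.ndarray:
    """Per-element strain energy in J: 1/2 sigma:eps * V."""
    coords = mesh.nodes[mesh.tets]
    _, vol = _tet_gradients(coords)
    dens = 0.5 * np.einsum("tij,tij->t", stress, strain)
    return dens * vol * NMM_TO_J


def _check_symmetric(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, float)
    single = t.ndim == 2
    tt = t[None] if single else t
    scale = np.abs(tt).max() if tt.size else 0.0
    if not np.allclose(tt, np.transpose(tt, (0, 2, 1)),
                       atol=1e-9 * max(scale, 1e-30)):
        raise ParameterError("tensor must be symmetric")
    return tt, single


def von_mises_stress(tensor: np.ndarray):
    """Equivalent (von Mises) stress of symmetric tensor(s), MPa."""
    tt, single = _check_symmetric(tensor)
    tr = np.trace(tt, axis1=1, axis2=2)
    dev = tt - tr[:, None, None] / 3.0 * np.eye(3)
    vm = np.sqrt(1.5 * np.einsum("tij,tij->t", dev, dev))
    return float(vm[0]) if single else vm


def von_mises_strain(tensor: np.ndarray, nu: float):
    """Equivalent strain: (1/(1+nu)) * sqrt(3/2 e:e) with e the deviator.

    Normalized so a uniaxial stress state gives eps_vm = sigma/E.
    """
    tt, single = _check_symmetric(tensor)
    tr = np.trace(tt, axis1=1, axis2=2)
    dev = tt - tr[:, None, None] / 3.0 * np.eye(3)
    vm = np.sqrt(1.5 * np.einsum("tij,tij->t", dev, dev)) / (1.0 + nu)
    return float(vm[0]) if single else vm


def total_strain_energy(displacement: np.ndarray, loads: np.ndarray) -> float:
    """U = 1/2 sum(u . f), converted from N.mm to J."""
    u = np.asarray(displacement, float).ravel()
    f = np.asarray(loads, float).ravel()
    return 0.5 * float(u @ f) * NMM_TO_J
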