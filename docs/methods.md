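# Methods

## Scope and model class

`jawfem` solves linear-static isotropic elasticity on four-noded
tetrahedral (constant-strain) meshes of a synthetic mandible under
distributed masticatory muscle loads, with the jaw supported at a
unilateral bite point and at both temporomandibular joints (TMJ). All
analyses are linear and static; materials are isotropic; ten-noded
elements, contact, sutures and periodontal tissues are out of scope.
Units are mm–N–MPa internally; moduli are supplied in GPa and strain
energy is reported in Joules (1 N·mm = 10⁻³ J).

## The synthetic mandible

The geometry stands in for a CT-derived carnivoran mandible. It is an
implicit solid — a union of capsules and ellipsoids for the corpora,
symphysis, rami, coronoid processes, condyles, angular processes and the
two carnassial crowns — voxelized on a regular grid and subdivided into
six tetrahedra per cube (Kuhn subdivision, which is conforming across
cells). The voxel grid is mirror-symmetric about the midsagittal plane,
so the mesh is exactly bilaterally symmetric; only the bite labels
distinguish the working (y < 0) from the balancing side. Generation is
fully deterministic: identical parameters give a bit-identical mesh.

Two cleanup passes make the mesh structurally sound at any pitch: cells
are added where two voxels would meet only along an edge (so every
surface edge is shared by exactly two surface triangles), and only the
largest face-connected component is kept. A mesh audit (positive volumes,
single component, closed surface, valid indices, non-empty labels) runs
in the test suite on every generated mesh.

Key default dimensions (mm) and why:

| parameter | default | rationale |
| --- | --- | --- |
| corpus length | 120 | wolf-like dentary length at desk scale |
| corpus depth | 34 | robust carnivoran corpus; sagittal bending stiffness controls a statically indeterminate anteroposterior force at the bite pin (see below) |
| bicondylar width | 70 | wolf-like proportions |
| ramus (coronoid) height | 60 | tall coronoid for temporalis insertion |
| condyle height | corpus depth + 4 | carnivoran condyles lie essentially at tooth-row level |
| carnassial position | 0.35 × corpus length, on the corpus centerline | tooth rows converge anteriorly, so the bite point is medial to the condyles |
| crown semi-axes | 10 × 4.5 × 9 | blade-like shearing carnassial |
| voxel pitch | 3.2 × 0.85^(level−1) | ~22k tets at level 1 to ~155k at level 5; base level 2 ≈ 36k |

Two of these numbers matter mechanically, not just cosmetically. First,
with the condyle high above the tooth row the statically determinate
bite-force component is tilted and a large indeterminate "thrust"
(anteroposterior force at the bite pin, reacted by the joints) varies
with the activation ratio; placing the joint axis at tooth-row level and
deepening the corpus makes the bite reaction statics-dominated, which is
what published wolf models show (bite force nearly invariant in *r*).
Second, a mediolaterally slender crown keeps the single-node bite
constraint from attracting an artificial lateral force through the
stiff tooth post. These defaults are the package's study conditions and
are used unchanged by every sweep and test.

The pseudo-CT field assigns each element a Hounsfield-like value:
cortical (HU 2030, chosen so the density regression returns
1.77 g/cm³ — typical cortical bone) within a 2 mm shell, decaying
exponentially to a trabecular/marrow-like core (HU 200); crown elements
are enamel (HU 3000) in the outer shell and dentine (HU 1500) inside.

What the generator does **not** emulate: real cortical/trabecular
microarchitecture, anisotropy, the unfused fibrous symphysis (modeled
here as a narrow bony bridge), tooth roots and periodontal ligament, and
subject-specific muscle maps. Passing sweeps therefore demonstrate the
*direction* and *relative sensitivity* of each modeling choice on a
mandible-like structure, not wolf-specific magnitudes.

## Muscle loads

Total muscle force is 1000 N in every model. The balancing-working
ratio r ∈ [0, 1] splits it as working = total/(1+r) (the only reading
consistent with a fixed total), the 55-26(9)-10
temporalis-masseter(zygomaticomandibularis)-pterygoid percentages divide
each side, and subgroups of a group share its budget in proportion to
attachment area. The lateral pterygoid is excluded (a few percent of
total muscle cross-section).

Tractions are distributed Boneload-style: each attachment node receives
a force aimed from the node straight at the group's cranial target point
(line of action at 10° gape), with magnitude proportional to the surface
area the node carries (one third of its incident patch-triangle area).
Node→patch ownership is exclusive — a surface node belongs to exactly one
subgroup patch (nearest containing ellipsoid) — so the sum of nodal force
magnitudes equals the budget *exactly* at every composition level. This
is the node-dual of distributing per triangle and splitting equally among
corners; the two coincide on patch interiors, but the node-exclusive form
conserves the budget even where patches abut. The tangential "wrapping"
variant of Boneload is noted as an extension point and not implemented.

For models with fewer than four major groups, an absent
zygomaticomandibularis folds its 9% share into the masseter (it is part
of the masseter complex) before renormalization. The muscle-number
schedule uses exactly n load groups for model n: temporalis; +masseter;
+zygomaticomandibularis; +pterygoid (the base four-muscle model); then
the temporalis splits (superficial vs deep+zygomatic, then fully), and
finally the masseter splits, giving seven groups. A merged group's
target is the area-weighted mean of its subgroup targets.

## Constraints and solver

Bite nodes (the k cusp-surface nodes nearest the carnassial apex; the
selections are nested and k = 1 is exactly the apex) are fixed in all
three translations, as are TMJ nodes in the two node-type models. The two
link-type models tie condylar nodes to a beam along the transverse joint
axis: every linked node moves as u = θ·(ê × (x − p)) for one unknown
rotation θ per side, enforced by exact multipoint-constraint elimination
(no penalty stiffness to tune). The single link anchors at the ventral
condylar surface pole rather than the node nearest the condyle center:
an anchor on the axis itself would have a vanishing lever arm and a
mesh-dependent tangent direction, making the model ill-conditioned.

The reduced system is solved by direct sparse LU factorization; an
optional Jacobi-preconditioned conjugate-gradient path (relative
tolerance 10⁻¹⁰) exists behind a flag. A relative residual above 10⁻⁶
raises an error with a conditioning diagnostic rather than returning a
questionable solution. Constraint forces are recovered as K·u − f at the
eliminated DOFs, which closes global equilibrium to solver precision
(measured residuals are ~10⁻¹¹ of the applied load). Strain energy is
½·uᵀKu, identical to ½·Σu·f for force-loaded models and verified against
the per-element ½σ:ε·V sum to 10⁻⁸ relative.

## Verification oracles

* **Patch test** — prescribing any linear displacement field on the
  boundary of a unit cube with an interior node reproduces the field and
  a uniform stress to machine precision (constant-strain elements are
  exact for linear fields).
* **Cantilever** — a 100×10×10 mm beam, E = 20 GPa, 10 N tip load, has
  an Euler–Bernoulli tip deflection PL³/3EI = 0.2 mm. Constant-strain
  tetrahedra are stiff in bending and converge from below; at the
  resolution used for verification (14 cells through the section,
  ~82k tets) the error is 3.9%, and the error decreases monotonically
  with refinement.
* **Lever oracle** — with both TMJ constraints at single points, joint
  reactions have no moment about the line through those points, so the
  bite-reaction component perpendicular to the plane of that axis and
  the bite point is fixed by the muscle moment alone. The FE solution
  reproduces this statically determinate component to ~10⁻¹¹ relative.

## The seven sweeps

All sweeps share the base configuration (refine level 2, r = 0.6,
55-26(9)-10 ratios, four muscle groups, single-node bite and TMJ
constraints, homogeneous E = 20 GPa, ν = 0.3) and vary one parameter:

1. **elements** — refine levels 1–5 (~22k–155k tets; scaled down from
   the 10⁵–1.4×10⁶ range typical of CT-based studies to desk-scale
   runtimes).
2. **bw-ratio** — r from 0 to 1 in steps of 0.1 (11 models).
3. **muscle-ratio** — base, 55-30-15, and the three single-group
   isolation cases; arbitrary ratio sets accepted via config.
4. **muscle-number** — 1 to 7 load groups per the schedule above.
5. **bite-nodes** — k ∈ {1, 6, 12, 24, 48, 66}; endpoints follow the
   single-node and whole-cusp (~66 node) bracketing, intermediate counts
   are doublings.
6. **tmj** — single node, node row (10 nodes spanning each condyle
   mediolaterally), single link, row of links.
7. **materials** — {1, 3, 4, 6, 8, 10} property classes; bone classes
   are equal-width HU bins (quantile binning available via config),
   enamel/dentine get dedicated classes from four classes upward
   (defaults E = 80/20 GPa, ν = 0.30/0.31, configurable since published
   tooth-tissue values vary).

The summary statistic per sweep and measure is the maximum signed percent
change relative to the base grid point, 100·(v* − v_base)/v_base with v*
the most deviating value. Solve wall time is logged but never asserted.

Observed patterns on the default mandible: bite force varies < 4% over
the full r range while the working joint reaction falls and the balancing
rises monotonically, crossing at r = 0.6; bite force increases
monotonically (+4%) with bite-constraint size while joint reactions stay
within 3%; heterogeneous models of six or more properties store more
strain energy than the homogeneous model; the node-row TMJ model loads
the working joint above the balancing joint; link models lower the bite
force only slightly.

## Numerical choices and degenerate inputs

* Branch boundary of the modulus power law at ρ = 1 g/cm³ assigned to
  the high-density branch (gives the printed 9.11 GPa coefficient at
  unit density); binning midpoints are checked never to land on the
  boundary. Density is floored at 0.01 g/cm³.
* Equivalent strain uses ε_vm = (1/(1+ν))·√(½Σ(εᵢ−εⱼ)²), normalized so a
  uniaxial stress state gives ε_vm = σ/E.
* Voxel fill tie-breaks (equal implicit values) resolve by grid index;
  tet orientation is repaired by node swap; all orderings are sorted, so
  outputs are byte-reproducible run to run.
* Inverted/degenerate tets, unmapped elements, over- or under-sized
  selections, non-unit link axes, overlapping fixed/linked DOFs,
  percentages not summing to 100, ratios outside [0, 1] and unknown
  config keys all raise typed errors early.
* A link group whose every lever arm is numerically zero degrades to
  fixed nodes (a pin on the axis) instead of producing a singular
  system.

## Known limitations

* **Point-constraint energy divergence.** With single-node bite and TMJ
  constraints, total strain energy contains a support-compliance term
  that scales like P²/(E·h) and therefore grows without bound under
  uniform refinement — a well-known property of point constraints in 3D
  elasticity, and the reason the element sweep's strain energy rises
  steadily with element count (reaction forces, by contrast, converge to
  within a few percent). Energy comparisons are meaningful *across*
  models at a fixed resolution, not across resolutions; distributed
  constraints (node rows, link rows, multi-node bite points) restore
  conventional convergence (~6% between the two finest levels here).
* Constant-strain tetrahedra are stiff in bending; absolute deflections
  and stresses at coarse resolution are underestimated, which is why all
  sweep comparisons hold every non-swept setting fixed.
* The synthetic mandible's magnitudes (bite force ≈ 330 N at 1000 N
  muscle force, strain energies of a few mJ) are properties of this
  geometry, not of any real taxon.
* Muscle tractions are straight lines to a single target per group; no
  fiber architecture, pennation or wrapping.
* The coarse cusp (≈ 75 surface nodes at base resolution) quantizes the
  bite-constraint-size sweep; intermediate k values sample discrete node
  rings.
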