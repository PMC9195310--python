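# Methods

## The model

The pipeline simulates how orbital soft tissue relocates when parts of
the bony orbital walls are resected. Soft tissue (fat, extraocular
muscle, globe) is treated as an isotropic, per-tissue-homogeneous Hooke
material under small strains:

    σ(ε) = E/(1+ν) ( ε + ν/(1−2ν) tr(ε) I )

equivalently the Lamé form σ = 2μ ε + λ tr(ε) I with μ = E/(2(1+ν)),
λ = Eν/((1+ν)(1−2ν)). The boundary value problem per resection
scenario:

* **Dirichlet**: u = 0 at every soft-tissue node lying on a
  bone-backed boundary triangle whose patch tag is *not* resected in
  the scenario. This includes the rims of resected patches (Dirichlet
  wins at shared nodes), modelling tissue tethered at the bony
  resection margin.
* **Neumann**: resected patches carry a dead-load traction along the
  undeformed outward surface normal — the pressure-driven outflow of
  orbital tissue. Lateral-wall tags (l1..l3 rings, kp1) receive the
  lateral magnitude, floor tags (f1..f4, kp2) the floor magnitude.
  The anterior opening is traction-free.

The released volume is measured geometrically, not linearized:
dV = Σ_e V_e(X+u) − Σ_e V_e(X) over soft-tissue tetrahedra. If any
displaced element inverts, the computation aborts with an error
advising load reduction — the small-strain model has then been pushed
past validity.

### Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| E | reference modulus (fat) | 1 (normalized) | only p/E enters u; absolute stiffness unidentifiable from volume data |
| ν | effective Poisson ratio | 0.1 | calibrated value; an effective macroscopic parameter, not a tissue compressibility claim |
| m | muscle/fat stiffness ratio | 5 | calibrated value; the globe inherits m (configurable) |
| p_lat | lateral-wall traction | 0.02 (normalized force/area) | chosen so strains stay ≪ 1 on the synthetic orbit |
| p_floor | floor-wall traction | 2.5 × p_lat | calibrated ratio; the floor offers almost no resistance to prolapse, the lateral wall is backed by muscle/connective layers |

The traction scale keeps peak strains in the few-percent range; at the
published released-volume magnitudes (≈18 % of orbital volume) a
small-strain model is outside its formal regime, so absolute dV values
here are reported in normalized units and only relative comparisons
between scenarios carry meaning.

### Discretization

Voxels of the label volume are split into six positively oriented
tetrahedra around the main cube diagonal (Kuhn/Freudenthal), identical
in every voxel, which makes the mesh conforming, the meshed volume
exactly equal to the labelled voxel volume, and the boundary watertight
on manifold solids. Boundary triangles inherit the voxel face they lie
on, which links them to the resection-patch masks. No surface
smoothing is applied; areas are voxel-face areas, hence the 5 %
tolerance against analytic patch areas. The global stiffness is
assembled from constant-strain tetrahedra and solved by sparse LU with
Dirichlet rows eliminated; the relative residual must stay below 1e−8
(direct solves land near 1e−14). A factorization is reused across load
cases with the same material and resected-tag set, and grid searches
superpose two unit-traction solutions (lateral, floor) per (m, ν)
pair, which is exact by linearity.

### Calibration

The four free parameters are sampled on an equidistant 4(m) × 4(ν) ×
4(p_lat) × 5(p_floor) grid — 320 combinations — and scored by
|dV_sim − dV_target| for the two-wall scenario l4+f4; ties break to the
lexicographically first tuple and every grid point is retained in an
audit table. The grid ranges (m ∈ [2, 6.5], ν ∈ [0.05, 0.2], p_lat ∈
[0.01, 0.04], p_floor ∈ [0.025, 0.125]) were chosen so the reference
optimum (m = 5, ν = 0.1, p_floor/p_lat = 2.5) is an interior grid
point. With no post-surgery CT available, dV_target is produced by a
forward simulation at that reference point; the search must recover it
exactly (self-consistency), which the acceptance suite checks.

## Synthetic anatomy

The generator emulates the geometric and radiological structure the
pipeline assumes, not a patient:

* **Cavity**: a posteriorly tapered elliptic cone (aperture plane to
  apex) plus a half-ellipsoid anterior cap standing in for the open
  aperture. All cavity lengths are scaled uniformly so the analytic
  volume equals the target (default 59.6 cm³, a severely enlarged
  orbit); the voxelized soft-tissue volume is validated within 2 %.
* **Bone**: a shell of constant thickness from binary dilation of the
  cavity, removed anterior of the aperture plane (the opening). On
  grids coarser than the shell, the shell is thickened to one voxel —
  it only supplies the rigid boundary.
* **Bulbus**: a sphere near the aperture, validated strictly inside
  the cavity. **Muscles**: four straight capsules from the apex to the
  globe equator (lateral/superior/medial/inferior rectus), clipped to
  the cavity. **Fat** fills the remainder.
* **Resection patches**: boundary faces between cavity and bone,
  grown greedily by distance from a wall anchor inside an azimuthal
  sector (lateral |θ| ≤ 45°, floor θ ∈ [−135°, −45°)). Nested areas
  are prefix sets of one ordering, so l1 ⊂ l2 ⊂ l3 ⊂ l4 holds as exact
  set inclusion and area(l4) − area(l3) = area(kp1) exactly. kp2
  (0.44 cm²) grows from the posterior lateral–floor junction, disjoint
  from both families.
* **Hounsfield units**: per tissue a truncated normal on the stated
  [min, max], fitted by weighted least squares to the stated
  mean/median with min/max as 0.5/99.5 percentiles, then refined so
  the distribution mean equals the stated mean *exactly*; σ is shrunk
  stepwise when that leaves the true median more than 1.5 HU off
  (possible for fat/muscle/bulbus, not for bone — a truncated normal
  cannot place its mean below its median on an interval whose lower
  bound is the near one, so bone's median sits low while its mean is
  exact). Background is air at −1000 HU. Geometry is deterministic;
  only HU rendering consumes the seed.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: anatomical wall curvature and thickness
variation, partial-volume and beam-hardening effects at tissue
interfaces, scanner noise correlation, the optic nerve, lacrimal gland
and sinuses, and any patient-specific asymmetry. Segmentation recovery
rates on the pseudo-CT (bone 100 %, fat 99.8 %) are upper bounds,
because the synthetic HU field is drawn from exactly the distributions
the thresholds encode.

Muscle/bulbus HU ranges overlap entirely and muscle overlaps the top of
the fat range, so thresholding alone cannot separate them; the
segmenter supports spatial seed regions (sphere for the globe, capsules
for the muscles, tissue shape + 1 mm) with priority
bone > bulbus > muscle > fat.

## Problem sizes

Image statistics run at the native 1 mm spacing (≈60 k soft voxels).
FEM work uses coarser grids chosen for accuracy at interactive cost:
scenario sweeps at 2 mm (≈45 k tets) and calibration at 2.5 mm (≈23 k
tets, 16 factorizations + 320 objective evaluations). The FEM core is
verified against a patch test (exact), the uniaxial closed form
(< 0.2 % at traction 0.001, where the exact displaced-volume measure
is within first order of the linearized formula), and the Lamé
thick-walled sphere (error 5.9 % → 2.0 % → 1.5 % at h = 2, 1.25, 1 mm;
monotone).

## Design choices and known limitations

* Single linear branch: the constitutive law is one linear segment; no
  strain-dependent stiffness segments are modelled (none are
  specified anywhere), no geometric nonlinearity, no contact.
* Dead loads on the undeformed surface; follower-load effects are
  second order at these strains.
* The bulbus is meshed as deformable tissue with the muscle stiffness
  ratio; its rigidity is not separately modelled, and globe (Hertel)
  displacement is *not* predicted — clinical Hertel values are passed
  through arithmetically (D = B − B′), in the units of their source.
* Two-wall coupling: in this linear dead-load model the combined
  l4+f4 release is slightly *super*-additive (unfixing both walls
  lengthens the shared free boundary), whereas measured clinical
  releases combine sub-additively — plausibly an open-system effect
  (fluid influx, mass redistribution) that the closed-domain model
  excludes by design. The tests assert the coupling (combined ≠ sum),
  not a sign.
* The four-patient cohort table is carried as curated data for
  arithmetic only; no statistical inference is attempted over n = 4.
  One source row reports dV = 3.1 cm³ where its own operands give
  2.4 cm³; the pipeline recomputes and flags, never reconciles.
* Relative released volumes (dV_rel) are computed from full-precision
  dV and rounded only for display; recomputing them from rounded
  published dV values reproduces the published percentages to ≈0.2
  points.
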