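# Methods

## Model overview and assumptions

`angiosprout` couples three layers on one square lattice (2 μm per site
side):

1. **Cellular Potts dynamics.** Cells are connected patches of sites sharing
   an identifier σ; the ECM is σ = 0. Amoeboid motility is mimicked by random
   copy attempts between 8-adjacent sites, accepted by a Metropolis-style
   rule on the energy change of a Hamiltonian with contact energies J(τ, τ′)
   and an elastic area constraint λ(τ)(a − A(τ))². The acceptance
   "temperature" is the motility μ(τ): min(μ, μ′) for cell–cell copies,
   max(μ, μ′) otherwise, so a cell–ECM copy uses the cell's motility
   (μ(ECM) = 0). One MCS is |Λ| attempts and represents 30 s.
2. **Autocrine chemoattractant.** Cells secrete a diffusible factor at rate
   α(τ); it decays at rate ε only in the ECM and is absorbed at the lattice
   boundary. Chemotaxis is contact-inhibited: the energy bias
   −χ(τ)·Δ(c/(1+sc)) applies only to copies in which exactly one participant
   is ECM (both extensions and retractions), using the participating cell's
   sensitivity. This is the mechanism that makes a cell blob first aggregate
   and then sprout into a network.
3. **Tip/stalk identity.** Static mode fixes a fraction F_tip of tip cells at
   initialization (round-half-up, uniformly chosen). Dynamic mode recomputes
   each cell's NICD level I(σ) = N(τ(σ))/a(σ) · Σ_n D(τ(n))·L_{σ∩n} once per
   MCS (after the field update) and sets the type by I ≤ Θ_NICD → tip, else
   stalk. Because N(tip) < N(stalk), the threshold a tip cell must exceed to
   switch back is higher than a stalk cell's — a hysteresis band that
   prevents rapid flipping.

Deliberately out of scope: three-dimensional lattices, proliferation and
apoptosis, ECM mechanics, an explicit VEGF field, explicit
Dll4/Notch/VEGFR kinetics, and connectivity-preserving CPM variants. Cells
may fragment (no connectivity constraint); a cell whose area reaches zero is
dropped from the registry.

## Parameters

Nominal values (the model's calibration); all overridable per cell type in
the config:

| symbol | meaning | default | units |
|---|---|---|---|
| J(cell, cell) | cell–cell contact energy | 40 | energy |
| J(cell, ECM) | cell–ECM contact energy | 20 | energy |
| A(τ) | target area | 100 | sites (= 400 μm²) |
| λ(τ) | area elasticity | 25 | energy/site² |
| μ(τ) | motility (acceptance temperature) | 50 | energy |
| χ(τ) | chemoattractant sensitivity | 500 | energy per unit c |
| s | receptor saturation | 0 | 1/c |
| α(τ) | secretion rate | 10⁻³ | s⁻¹ |
| ε | ECM decay rate | 10⁻³ | s⁻¹ |
| D | diffusion coefficient | 10⁻¹³ | m²/s |
| Δx, Δt | PDE grid and step | 2 μm, 2 s | 15 steps/MCS |
| N(tip), N(stalk) | Notch levels | 0.3, 0.5 | a.u. |
| D(tip), D(stalk) | Dll4 levels | 4, 1 | a.u. |
| Θ_NICD | selection threshold | 0.2 | a.u. |

The diffusion number D·Δt/Δx² = 0.05 is validated against the explicit
scheme's stability bound of 0.25; configs beyond it are rejected.

## Numerical choices

- **Adjacency.** Copy attempts and contact energies use the 8-neighborhood,
  each unordered pair counted once (a config flag doubles the count for
  compatibility with per-ordered-pair conventions, which rescales J by 2).
  Interface lengths for NICD and the cell graph use 4-adjacency as the
  boundary-length proxy (configurable to 8). The PDE uses the standard
  5-point Laplacian — the CPM's kernel does not dictate the stencil.
- **Boundaries.** Copy attempts whose target falls outside the box are not
  generated, and the Hamiltonian sums only site pairs inside the box, so a
  homogeneous filled lattice has exactly zero energy. The field's boundary
  ring is reset to zero every Euler step.
- **Blob initialization.** The initial condition is a centered disk of area
  n_cells·A(stalk) tessellated by nearest-center assignment of uniformly
  sampled centers (a Voronoi partition); stray fragments from discretization
  are reassigned to adjacent cells so every cell starts 4-connected. A
  10-site ECM margin is enforced; too-small lattices are rejected with the
  required size in the message.
- **Synchronous type update.** All NICD levels are computed against the
  pre-pass type map, then all types are set. Order-dependent artifacts of a
  sequential update are thereby avoided; the update runs once per MCS, after
  the PDE step.
- **Skeletonization.** Morphological closing with a disk of radius 3
  removes boundary roughness; homotopic hit-and-miss thinning (scikit-image's
  `thin`, the rotated-operator scheme run to convergence) produces the
  1-pixel skeleton, preserving connectivity and holes. Branch points are
  skeleton pixels with more than two 8-neighbors, end points those with
  exactly one.
- **Node merging.** Nodes within radius 10 are merged by single-linkage
  clustering to their mean position — deterministic regardless of input
  order. End and branch nodes are clustered *separately*: sprout detection
  needs every sprout to keep a distinct end node, and merging an end into a
  nearby branch cluster would silently delete short sprouts from the counts.
- **Node→cell mapping.** A merged node's (possibly fractional) position is
  rounded to a site; if that site is ECM the nearest cell site within radius
  3 is used, else the sprout is flagged and excluded from occupancy
  statistics — as are isolated filaments with no branch point, and sprouts
  whose end cell cannot reach the branch cell on the cell graph.
- **Degenerate statistics.** Compactness of an empty mask, the lacuna-area
  SD of a lacuna-free network, the occupancy of a sprout-free morphology and
  the McCutcheon index of a stationary track are reported as undefined
  (raised/NaN), never as 0. Welch's test with two zero-variance samples and
  equal means returns t = 0, one-sided p = 0.5.
- **Determinism.** Each replicate derives three independent seed streams
  (blob, type assignment, copy kernel) from its integer seed; replicate
  summaries are bit-reproducible from (config, seed).

## Experiments and study conditions

The experiments module mirrors the in-silico assays: the one-at-a-time
screen over tip-cell parameters (μ(tip), J(tip,ECM), J(tip,stalk), χ(tip),
α(tip), J(stalk,ECM), Θ_NICD) with occupancy read-outs tested one-sided
(greater) against the identical-cells control and morphology read-outs
two-sided; the averaged-parameter control model
P = (1−F_tip)·P(stalk) + F_tip·P(tip); tip–stalk pair migration quantified
by the McCutcheon index of the pair centroid (per-cell indices are emitted
alongside, the pair centroid being the less noisy observable); the
Θ_NICD × χ(tip) morphospace; and the chemoattractant-knockdown assay.

The knockdown assay uses the refined differential-secretion model — tip
cells secrete ten times faster (α(tip) = 10⁻², α(stalk) = 10⁻³ s⁻¹) and are
five times less sensitive (χ(tip) = 100) — with knockdown meaning a 90%
reduction of both rates (α(tip) = 10⁻³, α(stalk) = 10⁻⁴ s⁻¹), assessed as
the sprout count of the largest component at 750 MCS across four arms
(Θ_NICD ∈ {0.2, 0} × {control, inhibited}), identical seeds across arms.

Desk-scale defaults, chosen once as the package's standard conditions:
150×150 sites with 50 cells for network assays (2000 MCS; 750 MCS for the
knockdown assay) and 200×200 sites for the two-cell migration runs
(2000 MCS), 10 replicates per condition, tracks sampled every 10 MCS. These
reproduce every directional result; the cluster-scale settings
(10 000 MCS, 50–100 replicates, reported per experiment in the CLI's
`--scale full`) remain available for quantitative sweeps. Raw p-values are
reported without multiple-testing correction and are flagged as such in the
screen's documentation.

## What the simulations do and do not show

The simulator itself is the data generator: all tests run on simulated
morphologies or constructed fixtures. The model reproduces the *mechanisms*
— self-generated gradients, contact-inhibited chemotaxis, lateral
inhibition — not the full biology: no proliferation (so sprout elongation
saturates), a single implicit chemoattractant, 2D geometry (lacunae are
areas, not volumes), and cell-intrinsic parameters constant per type.
Passing tests therefore show that the implementation realizes the stated
model and its published directional behaviors, not that the model captures
any particular in-vitro system quantitatively. The skeleton-based sprout
count replaces manual image-software counting; on compact blobs thinning can
leave one spurious end point, which affects all experimental arms equally.

## Known limitations

- The hit-and-miss structuring elements of scikit-image's thinning differ in
  detail from other morphology libraries; skeletons agree topologically
  (components, holes, node counts on test shapes) but not pixel-for-pixel.
- Very dense networks can merge many branch clusters, making the branch-point
  count a conservative measure.
- The copy kernel uses one RNG stream per process (numba's per-thread
  generator); replicates are sequential, not parallel, within a process.
- The receptor-saturation constant s defaults to 0; no published value is
  claimed for the saturated variant.
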