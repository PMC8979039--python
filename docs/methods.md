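# Methods

## Scope and model summary

hexrupture simulates the rupture of two-dimensional, approximately
trivalent biopolymer networks (the collagen-IV-like meshes of basement
membranes) with a two-level description: an abstract periodic graph for
building and damaging network *topology*, and a coarse-grained bead-spring
system for the *dynamics* of deformation and bond scission. Everything is
strictly two-dimensional; out-of-plane rumpling is outside the model.

## Network representation

A `PeriodicGraph` stores node positions, an edge list, and a rectangular
box with per-axis periodicity. Every edge carries an explicit integer
image-shift vector for its second endpoint, so edge displacements are exact
rather than minimum-image guesses. This matters on small tori: a 1×1 unit
cell genuinely has 4 nodes and 6 edges, two of which are parallel under
minimum image and are only distinguished by how they wrap.

The lattice generator uses a rectangular 4-node cell with the armchair
axis along x: box lengths (3 a nx, √3 a ny) with a = one edge length
(1.0 graph unit = one molecule length). Stretching is applied along x; the
armchair orientation puts one third of the molecules parallel to the
stretch axis, and tears propagate along y.

Faces ("polygons") are enumerated with a combinatorial map: half-edges at
each node are ordered by bearing and faces are orbits of the
next-half-edge permutation. All closed walks are returned; the walks sum
to 2E half-edges and satisfy V − E + F = 0 on the torus. Interior-polygon
selection is separate: on a torus all walks are interior; on a cylinder
(strips) walks that wind the periodic axis are boundary; on a finite
cluster the single largest-perimeter walk is the outer face. For *damaged*
networks the polygon statistic additionally (i) reduces the graph to its
2-core (a dangling chain is not part of any polygon, although the face
walk traverses it twice) and (ii) drops any face larger than twice the
median interior face size — rupture voids span many hexagons and are holes,
not polygons. Merged faces of ordinary size (decagons from a single
missing edge) are deliberately kept: they are the polygons of a damaged
network.

## Defects

* **Edge removal** deletes ⌈fraction·E⌉ edges uniformly at random, then
  prunes k = 1 nodes recursively. In *progressive* mode a single
  permutation is drawn once, and larger fractions remove prefixes of it, so
  the edges removed at 10% are a superset of those removed at 5%. Pruned
  edges are tracked separately from the nominal removals.
* **Bond switch** (Stone–Wales move): pick a random edge (u, v), then
  neighbours a of u and b of v with all four nodes distinct and (a, u),
  (v, b) in different polygons; replace those two edges with (a, v) and
  (u, b). Degree sequences are preserved; moves creating duplicate edges or
  self-loops are resampled (budget 100 attempts, then an error). Candidate
  neighbours are sampled uniformly.
* **Holes** remove every node within a breadth-first (topological) radius
  of a centre node, then prune.
* **Strips** are lattices periodic along y only, cut free along x; boundary
  nodes have k = 2, never k = 1.

After every defect operation node positions are relaxed to a local minimum
of the graph energy U = Σ k_bond (r − r_eqm)² + Σ K_angle (cos θ − cos
θ_eqm)², with θ_eqm = 2π/k for a k-coordinated node and angle terms taken
between angularly adjacent neighbour pairs (k terms for k ≥ 3, one for
k = 2) — the unique convention that leaves the ideal lattice at zero
energy with 120° equilibrium angles. By default relaxation uses bonds only
(k_bond = 1, K_angle = 0, cheap and sufficient to remove local strain) and
frees only nodes within topological distance 3 of the modified region;
a global relax and K_angle > 0 are available. Minimisation is scipy
L-BFGS-B with the analytic gradient (gated in the tests against central
finite differences); convergence is a gradient max-norm below 10⁻⁶ graph
units.

## Polymer model

Each graph edge becomes one six-bead molecule. Beads are spaced exactly
r_eqm = 50 nm along the edge and centred on it, so for the default 300 nm
node spacing the arc-length offsets are 25, 75, …, 275 nm: the bead chain
spans 250 nm and the two head beads sit 25 nm short of the nodes. The
three heads meeting at a trivalent node therefore form a small triangle
(43.3 nm sides when fresh) instead of a singular point. Edges shorter than
4 r_eqm after scaling are rejected.

Interactions (unit system nm / ns / zJ / 10⁻²¹ kg, which is self-consistent
with 1 zJ = 1 mass-unit·nm²/ns²; k_B = 0.01380649 zJ/K, so
k_B T = 1.38 zJ at 100 K):

| term | form | defaults |
|---|---|---|
| bond (breakable) | shifted Morse, D_e[1 − e^(−α(r−r_eqm))]² − D_e | D_e = 16.5 zJ, α = 0.15 nm⁻¹, r_eqm = 50 nm |
| bend | K_θ cos²(θ/2) | K_θ = 200 zJ |
| body–body | LJ 12-6 truncated at its zero crossing | ε_BB = 64 zJ, σ_BB = 138 nm |
| head–head | LJ 12-6 truncated + shifted at 2.5 σ_HH | ε_HH = 16.5 zJ (1200 K k_B), σ_HH = 45 nm |
| thermostat | Langevin (BAOAB) | T = 100 K, damping 1 ns |

All nonbonded pairs within one molecule are excluded; the exclusion is
keyed on a live molecule label, so the moment a molecule splits its
fragments interact as separate molecules. Head–body cross interactions are
absent. A bond whose length exceeds r_c = σ_BB = 138 nm (checked every
N = 10 steps) is deleted together with the angles that contain it, and
molecule labels are recomputed by connected components; broken bonds never
re-form. Because the Morse energy at r_c is ≈ −6×10⁻⁵ zJ (≈ 4×10⁻⁶ D_e),
deleting a bond there injects no appreciable energy, and because the
truncated body repulsion vanishes at σ_BB, r_c = σ_BB is safe.

**Choice of σ_HH = 45 nm.** The junction geometry is set by the body
exclusion: three arms whose first body beads sit mutually at σ_BB = 138 nm
place the head triplet ~51 nm apart. The head attraction can only act as a
cross-link if its well reaches that separation, so the default puts the LJ
minimum (2^{1/6} σ_HH ≈ 50.5 nm) there; the cross-link then binds with
well depth ≈ ε_HH while the body repulsion supplies the junction's angular
stiffness. Substantially shorter ranges cannot reach across the junction
and leave the network unbound.

**Bead mass 0.1 × 10⁻²¹ kg** approximates one sixth of a ~300 kDa
tropocollagen; equilibrium properties are thermostatted and
mass-insensitive.

## Dynamics

BAOAB Langevin integration confined to the plane (plain velocity Verlet
when the thermostat is off), default dt = 0.02 ns, safely below the
stability bound of one fiftieth of the stiffest bond period
(2π/50)·√(m/2D_eα²) ≈ 0.046 ns at default parameters. The thermostat noise
uses its own counter-based stream, separate from the stream used for
initial velocities and from any defect RNG, so recipes and dynamics are
independently reproducible from one seed. Neighbour lists are cell-binned
with a 0.3 σ_BB skin and rebuilt when any coordinate has moved half a
skin; exclusions are evaluated live against molecule labels so a list
rebuild is never required after a break. Inner loops are numba kernels.

Box deformation: L_x(t) = L_x0 λ(t) with λ either linear (constant
engineering strain rate) or sinusoidal, 1 + A sin ωt, with A the
*fractional* amplitude (0 ≤ A < 1; a "peak stretch ratio of 1.5" is
A = 0.5 — values ≥ 1 would drive the box length negative and are
rejected), plus a ramped variant A(t) = A_max·t/duration. On every step
bead x-coordinates are remapped affinely with the box. The non-affine MSD
subtracts the affine map of the initial positions, so purely affine motion
scores zero.

Two known artefacts of this (standard) deformation protocol are documented
here deliberately. First, the truncated-at-zero-crossing body repulsion
has a force step (~11 zJ/nm) at σ_BB; junction beads sit exactly there, so
a smooth minimiser retains O(10 zJ/nm) residuals on those beads and
microcanonical energy conservation only holds cleanly for configurations
away from the cutoff (the NVE check uses a single molecule). Second, the
thermostat acts in the lab frame while the remap stretches all
x-coordinates, so a sheet that has torn free continues to feel a drag
tension of order (L/2)·(dλ/dt)·m/τ per bead column; at the default study
size (below) this is ~0.25 zJ/nm, an order of magnitude below the Morse
force maximum αD_e/2, but it grows with box size.

## Study conditions

The rupture scenario stretches an ideal 3×6-cell armchair lattice
(2.70 × 3.12 μm, 108 molecules, 648 beads) from λ = 1 to 2 over 10 μs at
100 K with *balanced* energy scales ε_HH = D_e = 32 zJ (≈ 23 k_B T). The
balance puts the system in the network-damage regime — bonds and
cross-links comparably strong and both well above thermal energy. The
scale matters: at 16.5 zJ (≈ 12 k_B T) a Kramers estimate (confirmed by
simulation) gives several spontaneous thermal scissions per microsecond
across a few thousand bonds, which swamps strain-driven rupture; at
23 k_B T spontaneous scission is negligible over 10 μs and the first
damage is mechanical, arriving at λ ≈ 1.1 when the tension in x-aligned
molecules approaches the Morse force maximum. The onset of tear
propagation is detected from the break-event train as the first event
whose subsequent rate (0.5 μs window) exceeds five times the run-average
rate over all earlier events; metrics at onset are evaluated on the stored
frame at that time (50 ns sampling cadence).

The oscillation sweep uses a 3×3 lattice, ε = D_e = 32 zJ, amplitudes
0.15–0.45 and frequencies 0.003–0.012 rad/ns for 1.5–2 μs; the
size-comparison study uses 3×3 vs 6×6 lattices at 5% edges removed with
ε = D_e = 16 zJ (the thermally assisted regime, where first damage is
nucleation-limited and scales with system size). These reduced problem
sizes are the package's default desk-scale conditions; the presets expose
`--paper-scale` for full-size runs (100 μs, tens of repeats).

## What the generator does and does not emulate

Generated networks are ideal honeycombs plus *prescribed* defects. Real
basement-membrane networks are disordered (measured mean connectivities
run above 3), polydisperse in molecule length, and three-dimensional at
short scales; none of that is represented. Passing tests therefore
demonstrate that the model mechanics and metrics behave as designed on
controlled topologies — not that a particular biological tissue is
quantitatively reproduced.

## Numerical choices and degenerate inputs

* Face enumeration raises on coincident neighbour bearings (degenerate
  embeddings); effective-graph reconstruction deduplicates parallel
  edges and drops self-loops before face enumeration only.
* Head clustering is single linkage with default cutoff
  2·2^{1/6}·σ_HH ≈ 101 nm — wide enough to hold a fresh, unbound head
  triplet together, far below the ~240 nm separation of neighbouring
  clusters.
* Aggregation over repeats uses linear interpolation onto a common grid
  and the population (n) standard-deviation convention.
* `rupture_onset` requires at least one event before the candidate (a lone
  first break is not a cascade) and falls back to the maximum-windowed-rate
  time if the threshold never fires.
* Zero-bond systems report N_broken = 0; empty graphs are rejected by the
  coordination and polygon metrics.

## Known limitations

* The tear-spanned polygon statistic stabilises near ~6.2–6.5 rather than
  returning fully to 6: a few cascade breaks land off the tear line and
  their merged decagons are genuine polygons of the surviving network, so
  the metric honestly reports them. A single clean tear with no stray
  breaks would give exactly 6.
* No bonded-interaction reformation, no stress/pressure coupling, no 3D.
* Correlated defect placement is limited to a simple
  near-previous-defect option; energy-biased bond-switch annealing toward
  target ring statistics is not implemented.
* The LAMMPS data exporter is for cross-validation convenience; hexrupture
  does not run LAMMPS.
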