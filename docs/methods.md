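# Methods

## Model and scope

`bindsteer` studies *protocols*, not force fields.  The question the
package answers is: given a binding site at a known location, how do a
gated constant-force push, a flat-bottom containment restraint, and a
high-concentration unbiased ensemble compare at producing spontaneous
binding events, and what do the standard trajectory observables look
like under each?  To make that question cheap to answer and exactly
reproducible, the receptor is rigid, the solvent is implicit in an
overdamped Langevin update, and the all-atom binding pocket is replaced
by a single attractive Gaussian well.  Anything that depends on
protein flexibility (gate opening/closing, ion-site coupling,
binding-pose detail) is outside the testbed's physics; the gate
distance exists only as an observable computed on supplied
coordinates.

### Coordinate frame and cell

The membrane normal is *z*; the membrane surface is the plane *z* = 0
and the extracellular space is *z* > 0.  The default cell is
120 × 120 × 100 Å, periodic in *x* and *y*, bounded in *z* by
reflective walls at 0 and L_z.  Positions are wrapped into the
origin-centred cell on periodic axes.  Engine-side distances (steering
gate, binding well) are computed in this wrapped frame *without*
minimum-image wrapping, because a steering force acting "through" the
periodic boundary is meaningless; the analysis module does apply the
minimum-image convention, and for any ligand within the analysis
ranges used here the two agree.

### Dynamics

Positions evolve by the overdamped (inertia-free) Euler–Maruyama update

  x' = x + (D/k_BT)·F·Δt + √(2 D Δt)·ξ,

with D = 0.6 Å² ps⁻¹, Δt = 0.01 ps, T = 300 K and ξ i.i.d. standard
normal.  k_B = 0.0019872 kcal mol⁻¹ K⁻¹, so k_BT = 0.59616 kcal/mol at
the default temperature.  The time unit is a nominal picosecond of
this toy diffusion model; it is *not* an all-atom time scale, and
protocol comparisons should be read as orderings and ratios, not
absolute kinetics.  After the update, non-periodic axes are mirror
reflected at the walls and periodic axes wrapped.  A single seeded
`numpy` Generator drives each run with a fixed draw order (per step,
then particle, then axis), so a config + seed pair reproduces a
trajectory bit for bit.

### Receptor potential

The binding site is a Gaussian well centred on the reference atom,
U(r) = −ε·exp(−|r − r₀|²/2σ²), with ε = 5 kcal/mol (≈ 8.4 k_BT, deep
enough that a captured ligand stays for the remainder of a typical
run) and σ = 2 Å (a binding funnel a few ångström wide, consistent
with a bound-state distance distribution peaking a few Å from the
reference atom).  Its force is analytic.  Ligands are ideal
(non-interacting) by default, as appropriate for independent binders;
a soft-sphere repulsion is available for crowding studies.

## The bias protocols

Both controllers are pure functions from (ligand position, reference
position, config) to a decision {active flag, force vector, reason
code}, evaluated every step and recorded at every stored frame, so the
central guarantee — *zero bias force wherever binding happens* — is
assertable from the output alone.

**Steering.**  Gate 1: the extracellular cone x² + y² < (z + a)², z > 0
with apex offset a = 15 Å.  The printed form of this region compares
an area to a length; the dimensionally consistent reading, a 45°
half-opening cone with apex at z = −a on the pore axis, matches the
drawn region and is the implemented default (both the offset and the
exponent are exposed).  Gate 2: distance to the reference > d_cut
(default 7 Å).  When both pass, the force is F₀ times the unit vector
toward the reference; F₀ = 5 kcal mol⁻¹ Å⁻¹.  The source protocol
prints the magnitude with stiffness units, but describes a
constant-strength push, which is what is implemented.  The force
direction is recomputed at every evaluation; applying the force every
step or every second step are both supported (default every step).  A
ligand exactly coincident with the reference is reported as a
degenerate zero, never an exception.

**Flat-bottom.**  U = 0 up to the cut-off d_c and ½k(d − d_c)² beyond,
k = 0.1 kcal mol⁻¹ Å⁻², d_c ∈ {7, 10, 12} Å with 12 as default; the
energy is continuous and once-differentiable at d_c and the force is
the negative gradient.  The printed stiffness unit is ambiguous
(kcal/mol·Å); the harmonic reading follows from the restraint's own
name, and a linear (constant-force) wall is available as an option.

**High concentration.**  76 ligands placed uniformly at random in the
extracellular slab with a 6 Å minimum separation (rejection sampling,
seeded).  76 in the full default cell is 0.0876 M by
n/(N_A·V); the conventional "~0.1 M" figure refers to the aqueous
sub-volume of a membrane system, so the molarity helper reports
whatever volume the caller supplies.

### Event definitions

First binding: earliest recorded time at which the binding distance
stays below 7 Å for 10 consecutive recorded frames.  Binding events
for residency analysis use hysteresis: open below 7 Å (sustained for
the dwell), close above 9 Å.  These definitions are package choices —
exposed as parameters — motivated by a bound-state distance
distribution peaking at 5–6.5 Å; hysteresis prevents boundary
re-crossings from fragmenting one residency into many.

## Synthetic fixture

The fixture emulates the binding-site neighbourhood of an
aspartate-transporter structure: anchor atoms ARG397:CZ and CG (the
reference residue), SER277:CA and PRO356:CA (gate tips), ASP390:CG and
ASP394:CG (the intermediate-state anchors), all within 5 Å of the
membrane surface, plus a bound four-bead aspartate-like ligand
(C, CA, CB, CG) with a prescribed side-chain torsion.  Coordinates are
synthetic — not copied from any deposited structure — but laid out so
the two measured crystal-state distances (gate tip-to-tip and
reference-to-bound-CA, both 5.6 Å in the occluded state) are exact.
This validates the parse → select → measure pipeline without network
access; `read_pdb_subset` works unchanged on a real deposited PDB file
when one is supplied locally.  The mobile ligand starts 18 Å above the
reference along +z by default (23 and 27 Å are the other documented
placements).

The scheduled-torsion generator builds four-bead frames whose
C–CA–CB–CG torsion follows any prescribed schedule to ~1e-6°, by
placing the fourth bead with the same construction used for the
dihedral sign convention (IUPAC, range (−180°, 180°]).  This is the
test feed for conformer-occupancy analysis: a 70 %/30 % anti/syn
schedule must be recovered exactly.

### What the testbed does and does not show

Passing tests demonstrate that the protocols are implemented with the
stated decision logic, that the unbiased region really is unbiased,
that the engine samples the correct equilibrium and diffusion
statistics, and that the acceleration ordering
steer < flat-bottom(7 Å) < flat-bottom(12 Å) < unbiased holds under
the testbed's conditions.  They do not show anything about all-atom
kinetics, force-field accuracy, binding poses, or gate dynamics; real
data additionally contain receptor flexibility, solvent structure,
electrostatics and a rugged binding funnel that the Gaussian well does
not emulate.

## Numerical and statistical choices

- **Boltzmann check.**  The flat-bottom excursion x = d − d_c of a
  restraint-only particle is a *radial* coordinate, so its stationary
  density carries an r² Jacobian; the raw second moment at d_c = 12 Å
  is ~30 % above k_BT/k.  The check therefore weights samples by 1/d²
  (the same shell-volume correction as the RDF normalisation), whose
  second moment is exactly k_BT/k = 5.9616 Å².  Excursions decorrelate
  over k_BT/(Dk) ≈ 10 ps, so the estimator uses many independent
  particles (600 × 24 000 steps, first 8 000 discarded as burn-in)
  rather than denser recording; seed-to-seed spread is ~2 %, against a
  5 % acceptance band.
- **RDF.**  Exact shell volumes (4π/3)(r₂³ − r₁³), bin width 0.1 Å,
  r_max 10 Å; g(r) is normalised by the mean density within the
  analysis sphere (stated in the output metadata), because the
  analysis is deliberately local to the reference — a bulk-density
  normalisation is not defined for a single tracked ligand.
- **Free-diffusion law.**  MSD slope over 10⁴ particles × 10³ steps on
  unwrapped coordinates in a fully periodic cell, fitted by least
  squares; expected 6D within 3 %.
- **Acceleration ordering.**  50 replicates per protocol are run as one
  batch of 50 independent non-interacting ligands sharing a seeded
  stream (statistically identical to 50 separate runs for ideal
  ligands, and much faster).  Never-bound replicates are censored at
  the 2 000 ps budget; adjacent protocols are compared by one-sided
  Mann-Whitney tests at α = 0.05 in addition to the median ordering.
- **Degenerate inputs.**  Collinear/coincident torsion points raise a
  distinct error and analysis frames so affected are labelled
  undefined and excluded from occupancies; a collinear point set makes
  the superposition fit ill-defined and raises; the steering
  controller treats ligand/reference coincidence as an inactive
  degenerate-zero decision.
- **Ties and boundaries.**  d = d_cut and d = d_c are *unbiased* (the
  force switches on strictly beyond the cut-off); cone membership is a
  strict inequality and z = 0 is outside; torsions are reported in
  (−180°, 180°] with −180° mapped to +180°.

## Known limitations

Orthorhombic cells only; no mass-weighted RMSD; the engine propagates
a single bead per ligand (the four-bead geometry is an analysis-side
construct); reflecting walls are first-order accurate in Δt; the
Euler–Maruyama step requires the per-step drift to stay below the well
width (the engine warns when the configured Δt violates this); and
absolute times are toy-clock times, meaningful only for comparisons
within the testbed.
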