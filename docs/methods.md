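# Methods

## Scope and model

`scrambletrack` analyses membrane MD trajectories of TMEM16-family lipid
scramblases, whose defining feature is a membrane-exposed hydrophilic
groove (the *aqueduct*) on each subunit of the homodimer through which
both phospholipid head groups and ions cross the membrane. The package
implements the standard trajectory-analysis battery for this system —
membrane deformation, aqueduct hydration, lipid tracing and flip-flop
event detection, ion-permeation counting, contact/coordination
statistics, and gating metrics — plus the Goldman–Hodgkin–Katz (GHK)
dilution-potential arithmetic used to turn reversal-potential shifts into
permeability ratios.

Conventions throughout: coordinates in Å, times in ns, angles in degrees;
the bilayer midplane defines z = 0 with the extracellular side at
positive z; leaflet phosphates sit near z = ±18 Å. Only orthorhombic
boxes are supported (triclinic boxes are rejected with an error); all
bins and voxels are half-open `[low, high)`.

## Membrane frame

The midplane is the midpoint of the two leaflets' mean phosphate z,
with leaflets split about the overall phosphate mean. It is recomputed
per frame by default (the membrane drifts under pressure coupling); a
fixed-reference mode is available (`per_frame=False`). **Assumption:**
lipids in mid-translocation pollute the leaflet means, so the estimate
is only accurate when transiting lipids are a small fraction of all
phosphates. With realistic lipid counts (≥100 per leaflet) the residual
bias is ≲0.3 Å; in very small test systems it can reach several Å, which
is why the bundled scenarios use at least 32 lipids per leaflet.

Leaflet labels are assigned once at the analysis start frame by the sign
of the head-group phosphorus z; a phosphorus exactly at z = 0 inherits
its previous label. z traces are unwrapped before event detection under
the assumption that true frame-to-frame displacements are below half the
box height, so a periodic wrap is never mistaken for a crossing.

## Aqueduct cylinder

Each subunit gets a membrane-normal cylinder of radius 13 Å through the
geometric (x, y) center of the lining-helix atoms, divided into 2 Å
slabs over z ∈ [−18, 18] Å. The axis is recomputed per frame by default
(switchable). Hydration profiles bin water oxygens into slabs;
phosphate occupancy applies the cylinder radius and the 20 Å core
(|z| ≤ 10 Å) jointly.

## Event detection

The detectors are hysteresis state machines with two configurable bands:

* **leaflet zones** |z| ≥ 15 Å — 3 Å inside the ±18 Å leaflet planes;
* **midplane band** |z| ≤ 5 Å — containing the central dwell site
  (z ≈ −3 Å) where translocating head groups pause.

A lipid event becomes pending when the lipid leaves a leaflet zone while
radially inside the cylinder. Reaching the opposite zone completes a
full event (`full_flop` inner→outer, `full_flip` outer→inner); the
completion time is the first frame beyond the far zone. Returning to the
entry zone cancels the pending event; a radial excursion out of the
cylinder suspends but does not cancel it. A pending event that has
touched the midplane band (while inside the cylinder) when the
trajectory ends is a half event. The source study states no numeric
entry/exit thresholds; the 15/5 Å bands are this package's declared
choice, sized so that positional noise up to σ = 1 Å cannot produce
spurious transitions (the margin between a band edge and the nearest
scripted rest position is ≥3σ).

Ion permeation uses boundary planes at ±15 Å, mirroring the lipid
detector, and requires the ion to be radially inside the cylinder only
while |z| ≤ 10 Å — ions approach through wide vestibules outside the
cylinder mouth, so whole-path confinement would be too strict. An ion
that reverses before the far plane produces no event. Applied-field
potentials are V = −E·L_z (inward-negative) for a field along −z.

## Contacts and coordination

Polar contacts: protein N/O vs lipid head-group N/O/P within 4 Å, head
groups restricted to the cylinder. Hydrophobic contacts: protein C vs
tail C within 4 Å, unrestricted. Coordination: donor atoms (water O,
protein N/O, lipid N/O) within 3 Å of an ion, or of a lipid head group's
P/O/N atoms. All cutoffs inclusive (≤). A residue donating two oxygens
in a frame contributes **two** coordinations (the coordination ratio is
a total divided by time, in coordinations/ns) but only **one** frame to
a contact fraction. Frame weights equal the time to the next frame; the
last frame reuses the previous spacing.

## Gating

Superposition is a Kabsch SVD fit; per-residue RMSD uses a single global
alignment with no per-residue re-fitting. "Sidechain–sidechain distance"
for the TM4–TM6 gate is the minimum heavy-atom distance between
sidechain atoms — the only reading compatible with reported contact
distances of 2.6–2.7 Å — and the pinch criterion is strict (< 3.0 Å; a
pair exactly at 3.0 Å is open). Default gate pairs: {F330, T333, L336,
V337} × {Y439, T443}.

## GHK analysis

ΔE_rev = rtf·ln[(X_o + Cl_i·r)/(X_i + Cl_o·r)] with r = P_Cl/P_X and
rtf fixed at the conventional 25.7 mV (≈RT/F near 25 °C), not recomputed
from temperature. In the dilution protocol Cl⁻ follows the cation salt
on each side (osmolarity held with mannitol), and the small Cl⁻
contribution of divalent salts in the pipette (<3 mM) is ignored; this
reading exactly reproduces the published Cs⁺ worked examples
(+45 mV ↔ P_Cl:P_Cs = 9.7; −17 mV ↔ 0.45; a ~21-fold selectivity
change). The inversion is closed-form and guarded by the achievable
shift range; symmetric solutions (range collapsed to one point) return
ratio 1 by convention. The published Na⁺ example (−7 mV for a 150→30 mM
switch giving P_Na:P_Cl = 2.3) is not self-consistent under this
equation (it yields ≈1.5) and is therefore not used as a reference
value anywhere in the package.

## Synthetic data generator

The generator emulates the *statistical structure the analyses assume*,
not membrane physics: a 204 × 162 × 130 Å box; a two-subunit rigid
pseudo-protein (six 21-atom lining "helices" per subunit on a 9 Å circle
around each axis, subunits related by the dimer's C2 symmetry) plus six
gate pseudo-residues per subunit; an asymmetric bilayer (outer leaflet
pure POPC, inner 2:1 POPC:POPS, phosphates at ±18 Å) of minimal lipids
(P, N, two 8-carbon tails — exactly the atoms the tilt, dipole, and
contact analyses need); cylinder water at a configurable per-slab count
(default 6, matching a hydrated aqueduct) or scattered uniformly for
analytic checks; bulk ions and a bound Ca²⁺ pair per subunit.

Scripted events follow piecewise-linear z paths: full flip-flops run
leaflet to leaflet with a dwell at the central site (z ≈ ∓3 Å, 30% of
the event by default); half events reach the dwell site and hold it to
the trajectory end; ions idle at z = ±30 Å and cross linearly. Gate
pinching moves the TM4 gate atoms so the closest pair sits at 2.5 Å
(closed) vs 8 Å (open), interleaved to an exact 40% duty cycle by
default. The default schedule scripts the reported event census — 5 full
floppings (2 POPS + 3 POPC), 3 half-flops (2 POPC + 1 POPS), 1 half-flip
(POPC), 24 inward Na⁺ crossings — over 2000 frames at 0.5 ns/frame.

I.i.d. Gaussian positional noise (default σ = 0.5 Å, a typical thermal
jitter scale) is added to every atom of every frame; there is no
velocity model. Event recovery is exact by construction for σ ≤ 1 Å
(the detector hysteresis margin); the *pinch* schedule, by contrast, is
only recovered exactly at σ = 0, since sub-Å gate distances have no
hysteresis — the pinch acceptance check therefore runs the noise-free
scenario. The same seed yields byte-identical output.

**What a green test does not establish:** the generator has no
diffusion, no membrane undulations, no realistic lipid packing or
protein flexibility, and its event shapes are idealized. Green detector
tests establish correctness of the bookkeeping (classification,
thresholds, hysteresis, conservation), not detector performance on real
trajectories with ambiguous, diffusive crossings.

## Numerical choices

* Bulk densities for `relative_to_bulk` maps are measured ≥20 Å from the
  protein; the accessible bulk volume is estimated by Monte-Carlo
  sampling with a fixed internal seed, so the estimate is deterministic.
* Degenerate orientation geometry (antiparallel tails, coincident P/N)
  yields NaN flagged frames rather than errors.
* Superposition requires ≥3 non-collinear atoms (SVD-conditioned check).
* Boundary conventions: contact/coordination cutoffs and the 10 Å shell
  are inclusive; the pinch cutoff is strict; spatial bins half-open.

## Known limitations

* Minimum-image handling is orthorhombic-only.
* Coordination uses plain distances (no PBC images); valid when the
  analysis region is far from the box boundary, as for an aqueduct at
  the box center.
* The per-frame cylinder axis follows the lining-helix centroid and will
  track large protein deformations; for strongly drifting systems a
  fixed axis (per_frame=False) may be preferable.
* The simulation-derived headline numbers of the original study (mean
  3.3 aqueduct phosphates, Na⁺ coordination 5.70 ± 0.51, 40.3%/6.3%
  pinch fractions) arose from multi-microsecond all-atom trajectories
  that are not deposited; they parameterize the synthetic scenario and
  are not re-derivable here.
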