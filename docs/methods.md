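# Methods

`tactoid` simulates the complexation of a single cationic polyelectrolyte
(PE) with anisotropically charged clay-like nanoplatelets (NPs) in implicit
solvent, and analyses the structures that form — band-like complexes,
face-to-face stacks (tactoids), or dissolved states — as a function of the
charge stoichiometry and of the chain's length, linear charge density and
stiffness.

## The coarse-grained model

**Nanoplatelet.** A rigid-ish hexagonal monolayer of bonded spherical sites
(diameter σ_site = 1 nm) on a triangular lattice with 1 nm spacing.  The
default platelet has 5 shells → 91 sites, 11 sites (11 nm) across.  Unit
charges sit at site centres: the 61 interior ("face") sites carry −1 each
and the six outermost hexagon corners carry +1, giving Z_face = −61,
Z_rim = +6, net Z_p = −55.  The printed inputs constrain the diameter, the
unit charges and both charge totals but not the exact rim placement; the
corner convention is the reconstruction that satisfies all of them
simultaneously.  A rim-free variant (corner charge 0, net −61) is one of
the six tabulated system variants (S.VI).

**Polyelectrolyte.** A bead-spring chain of N_b beads (σ_b = 0.4 nm, bond
length b = 0.5 nm) with uniform charge Z_b per bead.  Fractional Z_b
(0.5, 0.25) models reduced linear charge density at fixed length.  Chain
stiffness enters through a harmonic angle potential with equilibrium angle
π and force constant k_θ ∈ {0, 40, 400} k_BT/rad² (flexible, semiflexible,
stiff).

**Counterions.** Explicit monovalent ions neutralise the *net* charge of
each macro-species: 55 cations per default platelet and N_b·Z_b anions for
the chain.  (Neutralising face and rim separately — 61 cations + 6 anions
per platelet — is the other reading of the source description; the net
convention uses the minimal ion count and both close the total charge to
exactly zero, which is asserted at assembly.)

**Interactions.** All pairs interact through

* Coulomb, u = z_i z_j λ_B / r in k_BT, with the Bjerrum length
  λ_B = e²/(4π ε₀ ε_r k_B T) ≈ 0.716 nm at T = 298 K, ε_r = 78.3;
* a strictly repulsive truncated-shifted Lennard-Jones core,
  u = ε[(σ_ij/r)¹² − 2(σ_ij/r)⁶ + 1] for r < σ_ij and 0 beyond, with
  βε = 1 and σ_ij = (σ_i + σ_j)/2 — it vanishes with zero slope at contact;
* harmonic bonds ½k_b(r − b)² and harmonic angles ½k_θ(θ − π)².

Directly bonded neighbours are excluded from the non-bonded terms
(configurable).  The bond and the NP angle force constants are not printed
in the source description; the defaults k_b = 500 (PE) and 5000 (NP)
k_BT/nm², k_θ,NP = 5000 k_BT/rad² were chosen once so that bond-length
fluctuations stay below 5% of b and the platelet stays planar
(RMSD < 0.1 nm) at 298 K; all are configurable.

**Electrostatics routes.** Three interchangeable methods: (i) full
minimum-image summation (no cutoff; exact for an isolated box image and
the default for desk-scale boxes, where every pair is within L/2); (ii)
plain truncation at a cutoff (6 nm default); (iii) a direct Ewald sum —
real-space erfc part + dense reciprocal sum + self term, with analytic
removal of excluded pairs — whose splitting parameter and k-space cutoff
derive from one requested accuracy.  A direct (non-mesh) Ewald was chosen
over PME because it is bit-controllable and can be validated against an
independently written, conservatively converged reference sum; the two
agree to better than 1 part in 10⁴ on random neutral boxes, and analytic
forces match central-difference gradients of every term to better than
1 part in 10⁵.

Inner loops are numba-compiled O(N²) pair sweeps.  At the desk scales this
package targets (N ≲ 2000) a full sweep costs ~2 ms, so no neighbour or
cell lists are used; they would add bookkeeping without changing any
result.

## Dynamics

Leap-frog integration (positions on integer steps, velocities on half
steps), 10 fs timestep, cubic periodic box.  Temperature is controlled by
stochastic velocity rescaling (canonical sampling through a rescaling
factor with one Gaussian and one chi-squared variate per step; coupling
time 0.1 ps by default).  With the thermostat off the integrator is plain
NVE and is time-reversible; total-energy drift over 10⁴ steps is below
10⁻³ of the kinetic scale.

Internal units are nm / ps / k_BT; all species share one reduced mass
(≈100 g/mol equivalent).  Equilibrium observables — everything this
package reports — are independent of the mass choice; only time scales
change.  The centre-of-mass velocity is removed at every output stride.
Runs are bit-reproducible from (seed, config, method), and a stored final
state continues a run bit-identically.

`anneal_fixture` runs a staged temperature schedule (e.g. 600 → 298 K) to
produce near-equilibrium configurations quickly at reduced scale; it is
plumbing for scaled-down studies, not part of the full-scale protocol,
which ran 10⁷ steps at 298 K in a 100 nm box.

## Observables

* **Complexation.** A bead is complexed when its centre is within
  R_site + R_bead + 0.7 nm = 1.4 nm of any platelet site (minimum image);
  a platelet is complexed when any of its sites is within that distance of
  any bead.  The per-bead probability P_c(i_b) doubles as a convergence
  diagnostic (both chain ends should see the same environment).  ⟨N⟩ is
  the frame-averaged complexed-platelet count (time average, reported with
  its standard error; a snapshot count would be the other reading), and
  β_c uses the rounded ⟨N⟩ as the plateau count.  Membership is by direct
  contact, matching the P_c diagnostic; interior platelets of a stack
  virtually always touch the threading chain.
* **Gyration.** Mass-uniform R_g from the gyration tensor, chain-unwrapped
  across periodic boundaries, normalised by an R_g0 from a platelet-free
  reference run of the same chain.
* **Structure.** The site-site structure factor is computed either
  directly, S(q) = (1/N) Σ_ij sinc(q r_ij) (self term = 1), or from the
  site-site g(r) by quadrature with the window sin(πr/R_c)/(πr/R_c),
  which damps the finite-box truncation of g(r).  The tactoid d-spacing is
  2π/q_max of the stacking peak, searched in a 2–4 nm⁻¹ window (bracketing
  face-to-face clay stacking) with a 5%-of-baseline prominence gate; a
  curve with no qualifying local maximum reports "no peak".  Kratky
  presentation is the pointwise transform q²S(q), never smoothed; exported
  data are never smoothed either.
* **Shape label.** A heuristic for state-diagram sweeps: *dissolved* if no
  platelet touches the chain; otherwise *compact_stack* if the median
  nearest-neighbour platelet-centre spacing is tactoid-like (< 3.5 nm),
  else *extended_band*.  Thresholds are configurable and reported with the
  label alongside the measured spacing and the relative shape anisotropy.

Frame averages discard the first 20% of frames as equilibration by
default.  The default q grid is 200 log-spaced points from 2π/L to
20 nm⁻¹.

### Accuracy of the windowed route

For an isolated cluster in a periodic box, g(r) never approaches 1, so the
plain truncated transform of g − 1 carries a finite-box artifact; the
window damps it but a residual survives that scales with the box-to-
cluster size ratio.  Measured on an ideal 4-platelet stack: the windowed
route matches the direct sum to ~4.5% (of the S(q) scale, q > 2 nm⁻¹) in
a 40 nm box and to ≤2% in an 80 nm box.  Peak *positions* — all the
d-spacing analysis needs — are far less sensitive than peak amplitudes.

## Reduced-scale protocols and what they show

Full-scale runs (100 nm box, 10⁷ steps, up to 16 platelets with an
800-bead chain) are out of desk reach, so the package ships "desk"
protocols: 30 nm box, 10⁵-scale step counts, and for the platelet-number
sweeps an optional 3-shell platelet (37 sites, net −13) with a
proportionally shortened chain.  Problem sizes used by the shipped
protocols: the annealed pair runs 2 platelets + 110 beads + 220 ions
(512 particles) for ~2.2 ns; the overcharging sweep runs 4 points of up to
~500 particles for ~0.8 ns each.

* **Annealed pair.**  Two default platelets, a charge-matched 110-bead
  chain and counterions are placed at random and self-assemble during a
  600 → 298 K anneal plus a 298 K production run; the mid-plane spacing is
  then measured from the S_w Bragg peak.  The complex robustly forms a
  chain-glued face-to-face pair.  Note the scale caveat: with a single
  inter-platelet gap the whole chain charge concentrates in that gap
  (110 charges for 122 face charges), twice the per-gap density of the
  full-scale 8-platelet tactoid, which biases the pair towards a thinner,
  single-bead-layer sandwich than the multi-platelet stacks of the
  full-scale study.
* **Overcharging sweep.**  Small platelets (net −13) with a chain matched
  to four of them (β = 0.25·N_p).  Each point starts fully intercalated
  and relaxes at 298 K; the diagnostic is whether excess platelets beyond
  charge neutrality are expelled down to an overcharged plateau
  (β_c > 1), the reduced-scale analogue of the full-scale ~25% overcharging
  plateau.  Starting from the bound state tests expulsion rather than
  association (association would need far longer runs); it can overstate
  β_c but cannot manufacture expulsion.

What passing desk-scale tests does *not* show: quantitative reproduction
of the full-scale R_g/R_g0 columns or Kratky curves, which depend on
chain lengths and platelet counts outside the desk budget.  Those are
covered instead by the exact closed forms, the oracle equivalences and
the constructed-fixture recoveries in the test suite.

## Numerical choices and degenerate inputs

* Angle forces use the analytic θ → π limit when sin θ underflows (the
  harmonic-angle force is finite there for a straight equilibrium).
* The TLJ term is evaluated only inside σ_ij, so its truncation is exact.
* Cutoff Coulomb is plain truncation (no shift): it coincides exactly with
  the minimum-image route whenever all pairs are inside the cutoff, which
  is the regime it is used in.
* Random assembly retries overlapping insertions up to a bound and reports
  the seed on failure.  NaN positions are rejected; positions outside the
  box are wrapped, never rejected.
* A platelet with 0 shells is a single neutral-bond-free site; a 2-bead
  chain has one bond and no angles; β/β_c reject a zero-charge chain.
* Seeds: every stochastic stage (placement, velocities, thermostat,
  anneal stages) derives from one user seed; derived seeds stay small
  offsets of it.

## Known limitations

* No salt beyond counterions, no dispersion attraction, no dielectric
  discontinuities, one chain per box, monodisperse platelets.
* The shape classifier is a labelled heuristic, not an order parameter.
* Desk-scale annealing finds low-energy basins efficiently but, like the
  original protocol, can trap semi-equilibrium structures; replicate seeds
  are the recommended check.
* The direct Ewald route is O(N·K) and intended for validation and small
  boxes, not large production runs.
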