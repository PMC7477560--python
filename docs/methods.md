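# Methods

## Model

Beads evolve under Newton's equations with three pairwise, centre-to-centre
forces acting inside the cut-off radius r_C (= 1 in reduced units):

* conservative soft repulsion  F^C = a_ij (1 − r/r_C) r̂,
* dissipative friction         F^D = −γ ω^D(r) (v_ij · r̂) r̂,
* random kicks                 F^R = σ ω^R(r) ξ_ij Δt^(−1/2) r̂,

with ω^D(r) = (1 − r/r_C)^s, ω^R = √(ω^D) (enforced *identically* in the
kernel by computing ω^R first and squaring it), and ξ_ij one standard-normal
draw per pair per force evaluation, shared symmetrically by the pair.  With
σ² = 2γk_BT the dissipative/random pair is a momentum-conserving thermostat
whose stationary state is canonical at k_BT.  Chains add harmonic distance
bonds U = ½k_S(r − l₀)² and harmonic angles U = ½k_A(θ − θ₀)² on interior
triplets; bonded beads also feel the non-bonded forces (no exclusions — with
soft potentials the conservative shift of the bond minimum is
a(1 − l₀)/k_S ≈ 0.7%, negligible against the tabulated parameters).

All pair interactions share one cut-off; every force is central, so linear
momentum is conserved pairwise and exactly.

### Reduced units

Length r_C = (ρV/N)^⅓ = 7.2 Å derived from the reference coarse-grained
water system (ρ = 3, V = 29,894 Å³, N = 240); mass = one (H₂O)₄ bead
(11.968·10⁻²⁶ kg; GalA and GalA(−) are 2.623 and 2.609 of it); energy =
k_B·298 K = 4.115·10⁻²¹ J; time τ deliberately *unset* until calibrated —
conversions that need it raise an error rather than assuming a value.  The
packaged thermostat stores σ derived from γ through σ = √(2γk_BT) so the
fluctuation–dissipation identity holds to machine precision (the tabulated
6.86 is that number printed to two decimals).

## Integration and neighbour search

Modified velocity-Verlet with velocity-prediction factor λ = 0.5 (the
canonical choice; at Δt = 0.001 τ the λ-dependence of measured observables
is far below sampling noise): position update with the current force,
velocity prediction v + λΔt f/m, one force evaluation at the new positions
and predicted velocities, velocity correction with the averaged forces.
One noise draw per pair per step.  Unwrapped coordinates are tracked
exactly alongside the wrapped ones, so MSDs need no unwrapping heuristics.

Neighbour pairs come from a cell list (≥3 cells per axis; smaller boxes
fall back to a brute-force scan that is exact by construction), refreshed
every 8 steps with zero skin — the plain protocol.  A pair that *enters*
the cut-off between refreshes is therefore missed for up to 8 steps; a
monitoring mode (`check_missed_pairs`) quantifies this against a
brute-force rescan at every rebuild.  The tests pin the behaviour: with a
0.25 r_C skin nothing is ever missed; with zero skin a percent-level
fraction of boundary pairs (where all weight functions vanish) is
transiently missed.  `neighbor_skin` is exposed for users who want the
guarantee at a small cost.

Degenerate geometry: exactly overlapping beads (r = 0) contribute zero pair
force (the direction is undefined and the potential is soft) and are
counted in the diagnostics; near-collinear angle triplets clamp cos θ into
(−1, 1) and are counted likewise.  Non-finite forces or positions abort the
run with a diagnostic naming the affected beads and parameters.

## Canonical sampling of bonded terms: two subtleties

**Angle statistics.**  The configurational marginal of an interior angle is
p(θ) ∝ sin θ · exp(−βk_A(θ − θ₀)²/2) on (0, π): the sin θ phase-space
factor and the θ < π truncation matter for this force field's soft,
near-straight angles (k_A = 17–32, θ₀ ≈ 2.8 rad).  Numerical quadrature of
the exact density gives raw variances 0.67–0.79 × (k_BT/k_A) — the naive
harmonic expectation overshoots by up to a third.  The engine tests
therefore validate simulated angle distributions against the *exact*
integrals, and the harmonic-equivalent stiffness the package reports is the
maximum-likelihood estimate under the exact density
(`fit_harmonic_angle_mle`), which recovers the input k_A unbiasedly.  Raw
and sin-corrected moments are both returned by `bonded_distributions`.
Bond lengths are unaffected in practice (the r² Jacobian correction at
k_S ≈ 3000 is ~0.1%), so raw moments are used there.

**Isolated molecules are not ergodic.**  All DPD forces are central, so an
isolated dimer or trimer conserves its total angular momentum and the
thermostat cannot thermalize rotational degrees of freedom; the angle of an
isolated trimer samples a constrained ensemble with measurably (≈20%) too
little variance.  Bonded-statistics simulations therefore immerse the
molecule in an ideal-gas DPD bath (all a_ij = 0, thermostat on, density 3):
bath collisions exchange angular momentum and restore canonical sampling,
while the structureless bath contributes no potential of mean force to the
bonded coordinates.  The same setup backs the optional simulation
refinement in `fit_bonded_parameters`.

## Coarse-graining algorithm

Per frame, `cg_ratio` sequential rounds; in each round every bead acquires
exactly one new molecule by iterated unique-nearest-neighbour claims with
minimum-image distances: each bead claims its nearest still-unassigned
molecule; a molecule claimed by several beads goes to the closest claimant;
losing beads re-search until every bead has gained one.  Bead positions are
fixed while a frame is assigned and updated afterwards to the cloud centres
of mass (members unwrapped relative to the bead, so clouds straddling the
periodic boundary average on the short arc).  Ties — zero-probability for
continuous data but required for determinism — go to the lower bead index,
then the lower molecule id.  Each round terminates in at most n_beads
iterations because the globally closest claimant always wins its molecule.

Frames are chained: frame t starts from frame t−1's updated positions.
For a static configuration the map reaches a fixed point after at most a
couple of frames (immediately when clouds are distinct); a warning is
logged when a cloud's radius exceeds a configurable threshold, flagging
assignments that have degenerated into space-filling rather than
molecule-tracking behaviour.

Bead velocities: default is the mean of the member molecules' velocities;
a displacement-based estimator (bead displacement / frame interval) is the
fallback when the fine trajectory carries no velocities.  The choice is a
config switch because the two conventions differ at the few-percent level
on diffusive data, which propagates directly into τ.

## Calibration workflow

1. **Repulsion from structure:** a_ww is chosen by least-squares matching
   of g(r) between candidate simulations and the reference curve
   (unweighted, bins up to 3 r_C — RDF differences between candidate a
   values dwarf bin-level noise).
2. **Time scale from velocities:** τ = (v_DPD/v_MD)·r_C with v_DPD the RMS
   reduced bead speed over production frames (RMS is the closed-form
   equipartition statistic, √(3k_BT/m); a mean-speed mode is provided).
3. **Transport check:** D_red·r_C²/τ against D_MD; the scan
   (`parameter_scan`) tabulates both statistics over a (s, γ, a) grid with
   σ always derived from γ, and `timescale_report` prints the velocity- and
   diffusion-matched τ side by side with their ratio — at the calibrated
   set (s = 0.5, γ = 23.53, a = 50) the ratio is ≈1, at the standard set
   (s = 2, γ = 4.5, a = 25) it is ≈10, which is the entire argument for
   re-tuning (s, γ) rather than keeping the literature defaults.
4. **Bonded terms:** rest value = sample mean and k = k_BT/variance from
   reference samples (exact for Gaussian-distributed coordinates); angle
   samples taken from 3-D simulations go through the MLE above; optional
   refinement simulates the dimer/trimer in the ideal bath and rescales k
   by the measured/target variance ratio (variance ∝ 1/k to leading order).

## Observables

* RDF: pair-count histogram over minimum-image distances normalised by the
  ideal-gas shell expectation at the partial densities, frame-averaged;
  r_max capped at half the box edge.
* Diffusion: MSD over all particles and all time origins; D = slope/6 from
  a linear fit over lags in [20%, 80%] of the maximum lag (excludes the
  short-time ballistic regime and the noisy longest lags); the fit reports
  R², a log–log exponent, and flags exponents > 1.5 as ballistic.
* Kinetic temperature: equipartition, T = ⟨Σm v²⟩/(3N k_B), frame-averaged.

## Synthetic reference data

`generate_brownian_water` emulates the *statistics* the coarse-graining
pipeline consumes — per-frame molecule positions and velocities in a
periodic box — not water physics: molecules perform independent Brownian
motion (Gaussian steps of variance 2DΔt per axis) with Maxwell–Boltzmann
velocities redrawn each frame.  Defaults mirror the reference system
geometry (967 molecules, 31.036 Å box, 298 K, frames every 2 ps) with
molecular D = 0.6 Å²/ps, so clouds of four average to the ≈0.15 Å²/ps
coarse-grained regime.  Because molecules are uncorrelated, the fixture has
no liquid structure (g(r) ≡ 1) and no hydrodynamics; passing recovery tests
on it demonstrates the estimators and the mapping machinery, not water
realism.  Ground truth is embedded in the trajectory metadata.

## Problem sizes

Full-scale checks use the production protocol (3,000 beads, 2,000 warm-up
+ 20,000 production steps, three seeds); unit and property tests use a
375-bead, 5³ box variant and 60–150 k-step dimer/trimer runs, sizes chosen
so the statistical error of each checked moment sits well inside its
assertion band.  The chain self-assembly demonstration runs 10 chains × 35
GalA among 3,000 beads for 12,000 steps and checks the qualitative
signature (growth of inter-chain GalA contacts at constant temperature);
the full 100,000-bead, 1.68M-step aggregation run is reproducible with the
same builders (`build_system(216, 35, ...)`) given patience.

## Known limitations

* The printed reduced diffusivity of standard-parameter DPD water is quoted
  from a parameter-space plot; this engine (energy-conserving in the NVE
  limit, canonical under the thermostat) converges ≈11% below it, in line
  with commonly reported values for that parameter set.  The acceptance
  script reports the computed value as-is.
* No barostat, electrostatics, non-cubic boxes, or transverse/rotational
  DPD variants; esterified GalA and Ca²⁺ cross-linking are outside the bead
  vocabulary.
* The zero-skin neighbour protocol transiently misses a small fraction of
  boundary pairs (see above); set `neighbor_skin > 0` for exactness.
* CG bead velocities depend on the estimator convention (member-mean vs
  displacement) at the few-percent level; both are provided and the choice
  is recorded in trajectory metadata.
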