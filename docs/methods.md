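# Methods

This note records the models, conventions and numerical choices behind
`glycomech`, in the spirit of the methods documentation of packages like
msprime or statsmodels: enough detail that every number the package
produces can be traced to a formula and a convention.

## Ring puckering (Cremer–Pople)

A six-membered ring is described by out-of-plane displacements `z_j` of
its atoms from the mean plane through the geometric center, with the
plane normal taken along the cross product of the sine- and
cosine-weighted position sums. The displacements decompose into an m=2
wave (amplitude `q2`, phase `φ`) and an alternating m=3 component `q3`:

    q2 cos φ =  (1/√3) Σ z_j cos(4πj/6)
    q2 sin φ = −(1/√3) Σ z_j sin(4πj/6)
    q3       =  (1/√6) Σ (−1)^j z_j
    Q² = q2² + q3²,  cos θ = q3/Q

Index `j = 0` is the ring oxygen, proceeding O5→C1→…→C5. With this
origin and direction a β-D-glucopyranose ⁴C₁ chair maps to the north
pole (θ ≈ 0), which fixes all conformer names. Cartesian coordinates are
`qx = Q sinθ cosφ`, `qy = Q sinθ sinφ`, `qz = Q cosθ`; the conformational
collective variables are `u = qx/Q`, `v = qy/Q` on the closed unit disk.

φ is undefined at the poles; it is reported as 0 with an `at_pole` flag.
Rings with `Q < 0.1 Å` are labelled planar. Cyclic relabeling of the
starting atom leaves Q unchanged, shifts φ by 120°·k, and mirrors θ for
odd k — a property locked by test.

**Conformer reference table.** The 38 canonical conformers (2 chairs,
6 boats, 6 twist-boats, 12 envelopes, 12 half-chairs) are not hard-coded:
each is generated from its ideal displacement pattern (chair = alternating
pattern; boat = two para atoms displaced to one side; twist-boat = two
para atoms displaced oppositely; envelope = one atom out of plane;
half-chair = two adjacent atoms displaced oppositely) and projected
through the formulas above. This reproduces the standard layout — boats
and twist-boats on the equator every 30° of φ starting with ³,ᴼB at φ=0,
envelopes at θ = 54.74°/125.26°, half-chairs at θ = 50.77°/129.23°, ¹S₃
at (90°, 210°), ⁴H₃ at (50.8°, 210°), ⁴E at (54.7°, 240°). Assignment
minimizes the unweighted great-circle distance on the (θ, φ) sphere;
exact ties break to the lexicographically first label.

**Stoddart regions.** Each hemisphere of the puckering sphere is split
into a polar chair cap (within 25° of the pole) and four 90°-wide φ
quadrants starting at φ = 0. A point exactly on a quadrant boundary
belongs to the lower-φ quadrant. Region tags list the canonical
conformers whose reference points fall inside.

**Inverse transform.** `inverse_cp` applies the ideal displacement
pattern for (Q, θ, φ) to a regular planar hexagon (circumradius 1.46 Å).
Because the displaced ring's mean plane tilts slightly, re-analysis
reproduces the inputs to ~2°/0.01 Å (in practice far better); amplitudes
above 1.2 Å trigger a warning as chemically implausible.

## Linkage and protonation geometry

Torsions follow the standard convention in which the angle is invariant
under reversing the four atoms (checked against an independent library in
the tests). The glycosidic torsion is O5–C1–O_gly–C4′ (β-1,4) or
O5–C1–O_gly–C3′ (β-1,3).

**Lone pairs** at the glycosidic oxygen use an idealized sp³ model — a
geometric proxy, not an electronic-structure statement. The two lone-pair
vectors lie in the plane perpendicular to the C–O–C plane containing the
external bisector, with their opening angle solved so each makes exactly
the tetrahedral angle (109.47°) with both C–O bonds:
`cos γ = −cos(109.47°)/cos(∠COC/2)`. This is well defined for
∠COC ∈ (90°, 140°), the precondition of the model.

**Protonation class.** Elevation is the signed angle between the
O_gly→donor direction and the donor-ring Cremer–Pople mean plane (the
same plane as the puckering analysis, not a least-squares fit), positive
on the side of the oriented ring normal. Defaults, exposed as
configuration and echoed in every result: |elevation| ≥ 45° →
perpendicular (above/below by sign); 30–45° → intermediate; < 30° →
lateral, split syn/anti by whether the donor's in-plane position falls on
the same side of the C1→O_gly axis as the endocyclic O5 (exactly on the
axis → intermediate). The reported `targeted_lp` is the nearer of the two
model lone pairs. No numeric cutoff for "perpendicular" exists in the
experimental literature this mirrors; the intermediate band plus the raw
elevation avoid forcing borderline calls.

**Hydroxymethyl rotamers.** ω = O5–C5–C6–O6 and ω′ = C4–C5–C6–O6; the
gg/gt/tg labels use ±60°-half-width windows around the canonical pairs
gg = (−60°, +60°), gt = (+60°, 180°), tg = (180°, −60°), both torsions
required to agree; anything else is `undefined`. Angles wrap mod 360°.

**Catalytic distances.** Because the atom pair behind published
nucleophile↔acid/base distances is rarely stated, the rule is explicit:
`min-carboxyl-O-pair` (default; closest approach of side-chain carboxyl
oxygens), `carboxyl-C-to-carboxyl-C`, or `explicit-atoms`. The rule used
is recorded with the output.

## Metadynamics engine

Standard (non-well-tempered) metadynamics in CV space: repulsive
Gaussians `V(s) = Σ h_i exp(−Σ_d (s_d−c_id)²/2σ_d²)` deposited every
`pace` steps at the pre-step CV value, heights scheduled from
`height_start` to `height_end` either linearly in deposition index
(default) or as a step at a configurable fraction — both exposed because
published protocols state only start/end heights. Dynamics are BAOAB
underdamped Langevin; units are kcal/mol, Å (or the CV's own unit), and a
model time unit; `kT = R·T` with R in kcal/(mol·K). Runs are bitwise
reproducible from (seed, config). Normalized-puckering-CV runs can be
confined to the physical unit disk by a reflective wall.

**Free-energy estimate.** `reconstruct_fel` returns −V_bias normalized to
min 0. The instantaneous bias of standard metadynamics does not converge;
it oscillates around −F with amplitude of a few hill heights. For barrier
estimates the engine therefore offers the time-averaged bias over the
tail of the run (default: last 70%), which — because the bias is a sum of
hills — is itself a hill sum with each height scaled by the fraction of
the averaging window the hill existed in. `replicate_barriers` runs
independent seeds and reports per-replicate barriers, mean and sample SD,
mirroring the common practice of averaging several independent runs.

Validation protocol (the package's chosen study condition): a 5 kcal/mol
quartic double well, 2000 hills at pace 150 (300 000 steps), widths
0.2, heights 0.3→0.2 kcal/mol, T = 300 K, friction 2, dt 0.005, averaging
from 30% of the run. Over 20 development seeds the replicate error was
0.03 ± 0.16 kcal/mol; the acceptance check requires the 5-seed mean
within 1.5× the final hill height (0.3 kcal/mol).

## Landscape analysis

Minima are found by a persistence watershed: grid cells are flooded in
order of increasing value; when a basin first touches a deeper one, the
contact level is its escape saddle and saddle − minimum its persistence.
Only minima with persistence above the threshold (default 0.5 kcal/mol)
are reported; the global minimum's persistence is the grid maximum minus
its value. Barriers use the minimax path — the path whose highest point
is as low as possible — computed by a widest-path Dijkstra over the
Moore adjacency; this replaces hand-drawn reaction coordinates with a
deterministic construction. `barrier_height(A→B)` first relaxes the given
point A to its local grid minimum, then subtracts that minimum from the
path maximum; it is gauge-invariant and satisfies
barrier(A→B) − barrier(B→A) = F(B_min) − F(A_min).

**Committor.** p_B(x) is estimated by independent Langevin shots with
Maxwell–Boltzmann velocities, each trial seeded from a spawned
sub-sequence of the spec seed. Trials resolving into neither basin within
`max_steps` are excluded from p_B and counted separately. The 95% CI is
the Wilson interval. `locate_ts` picks the candidate with p_B nearest
0.5, accepted inside a window (default 0.4–0.6, i.e. at worst 60:40);
otherwise the best candidate is returned flagged rejected.

## Kinetics

Eyring–Polanyi: ΔG‡ = RT ln(k_B T / (h k)), transmission coefficient
fixed at 1 (deliberately not configurable); constants are CODATA 2018
(R = 1.98720425864083×10⁻³ kcal mol⁻¹ K⁻¹; k_B, h exact SI). 60 °C is
333.15 K. `eyring_rate` is the exact inverse.

Michaelis–Menten fits use scipy's trust-region least squares on
v = k_cat·S/(K_m+S), initial guesses from a Hanes–Woolf linearization
with documented fallbacks. The default weighting is relative (σ_i ∝ v_i,
the classical 1/v² weighting for initial-rate data whose error scales
with signal); SEs come from the residual-scaled covariance and the 95%
half-widths use the t distribution with n−2 degrees of freedom. Fits in
which K_m exceeds the largest measured concentration carry a wide-K_m
flag. Activity bookkeeping rounds percentages and fold-reductions to 2
significant figures and efficiencies to 3, always retaining the raw
values alongside.

## Synthetic data

The generator produces every input the pipeline needs, with no downloads:

* **Surfaces** are sums of negative Gaussian wells (optionally rotated
  anisotropic in 2-D) plus a smooth quartic-hinge radial confinement
  `k·max(0,(r−r₀)/w)⁴` — analytic energy and gradient everywhere.
* **Reaction preset** (glycosylation landscape in the two
  distance-difference CVs): reactant wells MC at (1.14, 1.14) and MC′ at
  (0.5, 0.5) joined by a shallow connector well at their midpoint (giving
  a low inter-reactant saddle, ~12% of the depth scale), and a product
  well GEI at (−0.9, −1.0) — reactants at positive CVs, product at
  negative, matching the sign convention of distance-difference CVs for
  bond exchange. The overall reactant depth scale is calibrated by Brent
  root-finding on the straight-segment MC′→GEI barrier (valid because the
  flanking wells are isotropic Gaussians, so the saddle lies on the line
  joining their centers); an *independent* dense-grid minimax computation
  verifies the calibration to ±0.05 kcal/mol. Default target barrier:
  17.6 kcal/mol, the replicate-averaged glycosylation barrier the
  workflow is sized to emulate.
* **Pucker preset** (conformational landscape on the (u,v) disk): a single
  broad anisotropic well at the ⁴C₁ center (0,0), elongated toward the
  ⁴E/⁴H₃ longitude (φ ≈ 225°); the long-axis width is solved in closed
  form so the energy at the ⁴E-tropic shelf point sits exactly
  `shelf_offset` (default 3 kcal/mol) above the minimum. One minimum by
  construction; the confinement keeps dynamics inside the physical disk.
* **Rings** come from the inverse Cremer–Pople transform at a canonical
  label or explicit (Q, θ, φ); default amplitude 0.57 Å, a typical
  pyranose value.
* **Disaccharides** are minimal atom sets (donor ring with C6/O6 arm,
  bridging oxygen, acceptor ring, one proxy acid/base atom, one proxy
  nucleophile oxygen) built by natural-extension-reference-frame
  placement. Defaults mirror the crystallographic geometry the package
  analyzes: glycosidic torsion −77.2°, gt hydroxymethyl (ω = 60°),
  perpendicular donor at 2.9 Å. Every builder satisfies measurement
  closure: re-analysis reproduces the generating torsion within 0.5°, and
  rotamer and protonation classes exactly.
* **Kinetic data** are Michaelis–Menten velocities with seeded
  multiplicative Gaussian noise (default conditions for recovery studies:
  K_m = 0.203 mM, k_cat = 36.1 s⁻¹, 8 concentrations spanning 0.25–32×
  K_m, σ = 5%).

**What the synthetic data do not emulate:** real force-field or QM/MM
energetics (only the topology and one calibrated barrier of the true
surfaces), hydrogens and solvent, crystallographic disorder and
measurement noise in structures, and substrate-depletion or product
inhibition in kinetics. Passing tests therefore demonstrate correctness
of the measurement and estimation machinery under known ground truth, not
agreement of the emulated surfaces with the physical system.

## Problem sizes and numerical guards

Grids default to ~160–240 points per axis (barrier discretization error
≲0.005 kcal/mol at the presets' curvatures); metadynamics validation uses
300k-step runs; committor estimates use 200 shots (binomial σ ≈ 0.035).
Degenerate geometry (coincident/collinear points, near-linear C–O–C,
planar rings where φ or the CVs are undefined) raises typed errors rather
than returning garbage; diverging dynamics abort naming the step. All
stochastic code paths take explicit integer seeds and are reproducible.

## Known limitations

* Conformer assignment uses unweighted great-circle distance; no
  puckering-amplitude weighting between θ bands.
* The lone-pair model is purely geometric; donors hydrogen-bonded through
  intervening atoms are not recognized.
* Saddles are located at grid resolution (no Newton refinement), and the
  committor integrates the model Langevin dynamics, not physical MD.
* The CLI's metadynamics subcommand exposes the preset surfaces only;
  arbitrary user surfaces are a library-level feature.
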