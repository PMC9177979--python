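# Methods

This note documents the models, numerical choices and defaults behind
`salt_twist`, what the synthetic-data generator does and does not emulate,
and the limitations a user should know before applying the pipeline to real
ensembles.

## Reference frames and step parameters

Every nucleobase carries a right-handed orthonormal frame obtained by
least-squares rigid superposition (proper rotation only, via SVD with a
determinant correction) of an idealized planar base template onto the
observed ring atoms (purines: N9, C8, N7, C5, C6, O6/N6, N1, C2, N3, C4;
pyrimidines: N1, C2, O2, N3, C4, O4/N4, C5, C6). Template superposition is
preferred over three-atom triad constructions because it degrades gracefully
under coordinate noise and tolerates a missing atom in principle (the
current implementation requires the full set and names the missing atom in
its error).

A base-pair frame averages the two base frames after flipping the
complementary frame's y and z axes (anti-parallel convention): the origin is
the midpoint, the orientation the quaternion mean. Quaternion averaging uses
the dominant-eigenvector method — sign-align all quaternions to the first,
accumulate M = Σ q qᵀ, take the eigenvector of the largest eigenvalue. For
the small orientation spreads that occur here this is the minimizer of the
summed squared chordal distance; a test verifies that against a brute-force
perturbation search and against an independent library implementation.

Step parameters use the mid-frame construction: the two base-pair z-axes are
symmetrically rotated onto their bisector about the hinge z₁×z₂; twist is
the signed angle between the rotated x-axes about the mid z; roll and tilt
are the polar decomposition of the hinge rotation; shift/slide/rise are the
origin displacement in mid-frame coordinates. Helical twist and helical rise
come from the screw decomposition of the full relative rotation (angle about,
and translation along, the invariant axis; a step with rotation below 1e-12
falls back to the mid-frame z as the axis). The construction is exactly
invertible; `rebuild_step` is that inverse, and round-trip identity at 1e-9
is part of the test suite. All frame operations are equivariant under global
rigid motions (tested to 1e-9).

## The three twist measures

* `local_helical`: Σ helical twist over steps, / (n−1).
* `bp_twist`: Σ mid-frame twist over steps, / (n−1).
* `end_to_end`: each end of the helix gets a frame — the quaternion mean of
  the first or last `terminal_k` base-pair frames (`terminal_k = 1` by
  default; how many terminal base pairs define an end frame is an open
  choice, so it is exposed as a parameter). The raw twist is the angle
  between the two end-frame x-axes, projected into the plane normal to the
  mean of the two z-axes. That angle is only defined modulo 360°; it is
  unwrapped to the branch nearest the cumulative bp-twist sum, which is the
  natural anchor because the cumulative sum changes continuously with
  conformation. Per-bp normalization always divides by (n−1).

With `terminal_k = k > 1` the end frames sit (k−1)/2 steps inside the helix,
so the absolute per-bp value is scaled by (n−k)/(n−1); this constant offset
cancels in the condition-to-condition changes that the pipeline reports.
The end-to-end measure is invariant under any constant rigid rotation of
the whole trajectory (tested at 1e-9 for z-rotations, which is the case of
interest when comparing runs with arbitrary initial orientation).

`subhelix_scan` repeats the per-bp twist on centered sub-sequences, trimming
base pairs symmetrically from both ends, and reports mean ± SE per length —
the robustness check that motivates trusting ≥15-bp helices.

## Conformational observables

* **Crookedness** β: cos β = h/d with h the distance between the terminal
  base-pair origins and d the summed per-step rises. The ratio is clamped
  into [0, 1]: with thermal shift/slide noise h can exceed Σ rise by a part
  in 10³, and clamping (β = 0) is preferred over NaN. `d_estimator =
  "polyline"` instead uses the origin-polyline length, for which h ≤ d is a
  theorem; `h_estimator = "sum_helical_rise"` matches the equivalent
  definition via summed helical rises (identical on straight helices).
* **Radius** r: mean distance of backbone P atoms to the base-pair-origin
  polyline (point-to-segment minima). No operational definition of "radius"
  is standard; this one is declared, and a brute-force per-atom oracle pins
  the implementation.
* **Sugar pucker**: phase and amplitude from the five endocyclic torsions by
  tan P = ((ν₄+ν₁) − (ν₃+ν₀)) / (2 ν₂ (sin 36° + sin 72°)), quadrant-resolved
  with the two-argument arctangent (ν₂ < 0 adds 180°), νmax = ν₂ / cos P;
  ν₂ ≈ 0 with a vanishing numerator is flagged undefined (NaN). The per-frame
  summary uses a circular mean over residues, excluding one terminal base
  pair per end.
* **Minor-groove width**: for each strand-I phosphorus P(i), the minimum
  cross-strand P–P distance over pairing offsets i−6 … i−2 (configurable),
  minus 5.8 Å for two phosphate radii. The window matches B-DNA register;
  an unbounded window reproduces the brute-force all-pairs minimum in tests.
* **BI/BII**: a step is BI iff (ε − ζ) wrapped to (−180°, 180°] is negative
  (ε = C4'-C3'-O3'-P(+1), ζ = C3'-O3'-P(+1)-O5'(+1)); the fraction is
  averaged over steps and frames, with incomplete backbones excluded and
  warned about. The 0° threshold is the standard convention.
* **Block averaging**: contiguous blocks of `block_ns` (default 200 ns) after
  an equilibration discard (default 200 ns), trailing partial block dropped,
  SE = SD(block means)/√n_blocks; at least two complete blocks are required.
  Tests cover the iid CLT limit and the SE inflation on an AR(1) series.

## Ion atmosphere

Curvilinear coordinates: r is the distance to the nearest segment of the
base-pair-origin polyline, z the arclength of the foot point, φ the azimuth
in the local base-pair frame (0° along +x, toward the major groove). Ions
whose foot point lies beyond the polyline caps plus a padding (default 5 Å)
are flagged out of range and excluded from profiles.

Radial profiles are cylindrical-shell molarities c_k = N_k/(N_A V_k F) with
V_k = π(r_{k+1}² − r_k²) L_z in litres; the axial window defaults to the
polyline trimmed one base pair per end to avoid end effects. Per-groove
volume normalization is not attempted; shell molarity is the declared
convention. Number conservation (bins + out-of-range = total) is exact and
tested.

Site occupancy assigns each ion to the nearest qualifying site within a
cutoff (default 3.5 Å, first contact shell): backbone = O1P/O2P, nucleobase
= N7/O6, with exact ties resolved toward the backbone; unassigned ions
within 12 Å of the axis are classed minor groove (φ ∈ [120°, 240°)) or major
groove, the rest diffuse. The sector constants are declared conventions, not
measurements. Fractions sum to one per species.

The 3D grid density superposes all frames onto the first using the base-pair
origins (stable against base fluctuations), histograms positions on a
regular grid, and reports mol/L per voxel; the density integral equals the
mean ion count exactly.

## Magnetic-tweezers analysis

`gaussian_fit` fits z(n) = z₀ + a·exp(−(n−N_max)²/2w²) to the full
rotation–extension curve by weighted least squares (per-point SDs when
available, unweighted otherwise, flagged on the result), initialized from
the argmax and curve span; a configurable window around the apex is provided
because plectonemic wings are not Gaussian, but the full-curve fit is the
default protocol. Monotonic curves raise a no-peak error.

ΔTw = 360°(N_max − N_max,ref)/n_bp with n_bp = 7900 for the reference
construct; positive means overwinding. Per-molecule values are aggregated
as plain mean ± SD.

`fit_power_law` fits ΔTw = A c^B + C by weighted least squares,
multi-started over B ∈ {0.1, …, 1.0} because A and B trade off strongly on
five-point designs (ties broken by lowest χ², then smallest B); B can be
frozen. `fit_log_linear` solves the 2-parameter weighted normal equations in
closed form on log₁₀(c) — base-10 is the declared convention and affects
only the slope scale. Both report reduced χ² = Σ((y−ŷ)/σ)²/(N−k);
`compare_models` ranks fits of identical data (verified by a data hash) and
flags ratios below 1.5 as indistinguishable.

## The synthetic-data generator

The generator defines the study conditions for all tests; it emulates the
statistics of a fluctuating B-DNA ensemble, not its physics.

**Duplex construction.** Base-pair frames are chained from per-step
parameters using the exact inverse of the mid-frame analysis, so re-analysis
reproduces the inputs to machine precision (the central construction
identity: an ideal helix at 34.286°/step and 3.4 Å rise re-analyzes to
34.286°/bp by all three twist measures). Strand I base frames equal the
base-pair frame; strand II frames are flipped. Base atoms are planar
templates; C1' anchors a five-atom sugar ring built by a batched Newton
solve that realizes the five pseudorotation torsions ν_j = νmax·cos(P +
144°(j−2)) exactly (three bond angles plus two log-bond stretches as
unknowns, minimal-norm steps keeping geometry near ideal; a continuation
sweep around the pucker circle supplies initial guesses, cached per
amplitude). Backbone atoms (C5', O5', P, O1P, O2P, O3') follow by fixed
idealized internal coordinates; the handful of free torsion constants was
calibrated once so an ideal helix has a continuous backbone
(O3'–P distance 1.60 ± 0.01 Å on both strands) and a phosphorus radius of
≈9.1 Å. Defaults: the 33-bp reference sequence, twist 34.286°, rise 3.4 Å,
pucker P = 147° (South), νmax = 38°.

**Fluctuations.** Independent Gaussian draws per frame and step (and per
residue for pucker). No literature values exist for these magnitudes in the
abstract; the defaults (σ_twist 4°, σ_roll 4°, σ_tilt 3°, σ_shift/slide/rise
0.3 Å, σ_pucker 8°) are plausible B-DNA room-temperature scales and are
configurable. Frames are temporally uncorrelated — deliberately, so that
plain SEs are valid in tests; real MD is autocorrelated, which is exactly
what the block-averaging utilities are for. Pseudo-time is 0.1 ns/frame so a
200-ns block is 2000 frames.

**Salt-condition ladder.** A condition that shifts mean step twist by δ also
shifts pucker by +5.56 δ (the ratio of the reported conformational
covariation, 10° pucker per 1.8° twist), slide by −0.35 δ Å, intrinsic roll
by −1.2 δ, and scales bending-fluctuation SDs by (1 − 0.3 δ). The slide and
bending couplings are what make the phosphorus radius and the crookedness
respond with the physically observed signs in this rigid-base generator —
twist alone moves neither, because phosphates ride rigidly on the bases and
independent bends average out over full helical turns. On this ladder the
pipeline reproduces the expected pattern: twist↑ with pucker↑ (Pearson
R ≈ +0.997), radius↓ (R ≈ −0.994), crookedness↓ (R ≈ −0.983). Passing these
tests shows the *analysis* correctly quantifies co-variation present in the
data; it is not evidence about the mechanism in real DNA.

**Ion clouds.** Diffuse ions follow ρ(r) = bulk + excess·exp(−(r−r₀)²/2σ²)
(clipped at zero) inside a bounding cylinder around the straight axis
through the terminal C1' midpoints; the count is Poisson about the density
integral, radii are drawn by inverse-CDF on a fine grid, so a uniform cloud
is exactly uniform and its expected count is c·N_A·V. Site-pinned ions sit
at a fixed distance (default 2.3 Å) in a random direction from a randomly
chosen O1P/O2P or N7/O6 atom. No excluded volume, no correlations, no
water.

**Tweezers curves.** Extension = apex − depth·(1 − exp(−(n−N_max)²/2w²))
within the buckling offset, then linear wings continuous at the junction,
plus Gaussian noise. Defaults (cap width 8 turns, depth 0.25 μm, wing slope
−0.04 μm/turn, buckling at 12 turns, apex 2.2 μm, 2-turn grid) mimic a
7.9-kb tether at 0.5 pN. The cap+wings shape is *not* a Gaussian, which is
the point of the recovery test: fitting the full curve with a Gaussian
recovers N_max with |bias| < 0.1 turn at 5 nm noise over 200 replicates.

**Concentration series.** ΔTw_i = A·c_i^B + C + noise, σ_i = noise SD (unit
σ when noise-free, giving zero-residual unweighted fits). Study-design
recovery: at 5 concentrations (50–1000 mM), σ = 0.02°/bp, true B = 0.5, the
median |B̂ − 0.5| over 100 seeds is ≈0.08 and the power law beats the
log-linear model in reduced χ² in ≥90% of seeds.

All generators take explicit integer seeds and never touch global RNG
state; identical seeds give bitwise-identical outputs.

## Numerical choices and degenerate inputs

* Angles in degrees at every public boundary; coordinates Å, time ns,
  concentrations mM; column names carry units.
* Parallel step z-axes: the hinge is undefined, rotation by Γ/2 ≈ 0 about an
  arbitrary perpendicular is used; zero-rotation steps take the mid-frame z
  as helical axis.
* Quaternion means are unique only for dispersions below 90°, far above
  anything a base-paired duplex produces.
* Twist unwrapping breaks only if a conformation jumps by >180° of total
  twist between evaluation and anchor — impossible for the per-frame usage
  here.
* The Gaussian, power-law and log-linear fits propagate per-point SDs when
  present; σ must be positive in `ConcSeries`.
* h/d is clamped; pucker on a flat ring is NaN, never an exception.

## Problem sizes

Default test and acceptance runs use a 33-bp duplex, trajectories of
200–2000 frames, 200 tweezers curves, 100 concentration-series seeds and 80
ion-cloud frames. These sizes put every statistical bound (3σ Poisson,
2 SE consistency, 0.1-turn bias) comfortably beyond its noise floor while
keeping a full run in minutes on a single CPU; all are parameters, not
constants.

## Known limitations

* The duplex builder is a statistical surrogate: no sequence-dependent
  step-parameter means, no base-pair-level degrees of freedom (buckle,
  propeller, opening), no hydrogens, no solvent, idealized backbone
  internals (ε/ζ are constants of the construction, so BI/BII fractions on
  built structures are degenerate 0 or 1).
* The helical axis is the base-pair-origin polyline, not a global curvilinear
  axis fit; for strongly bent helices the radius and curvilinear coordinates
  inherit that choice.
* Groove sectors in φ are fixed conventions; curved-groove path integration
  is out of scope.
* Ion sampling has no ion–ion or ion–DNA correlations beyond the imposed
  radial density and pinned sites; occupancy fractions on synthetic clouds
  reflect that geometry only.
* Divalent-specific structure (bridging, hydration shells) is not modelled;
  valence is metadata.
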