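# Methods

This note records the models implemented in `kokflash`, the assumptions
behind them, the defaults that matter, and the limits of what the synthetic
test surface can demonstrate.

## Kok-chain population model

A flash train acts on the S-state distribution as a column-stochastic 4×4
matrix per flash: advance one step with probability 1 − m − d (S₃ wraps to
S₀), stay with the miss probability m, advance twice with the double-hit
probability d. Misses are treated as state-independent, and back-reactions
between flashes (200 ms spacing in the emulated protocol) are neglected.
The dark-adapted sample starts in S₁.

The two-flash starting state is anchored to the measured 65% S₃ / 35%
(S₂+S₁) mixture, which fixes the default miss factor through
(1 − m)² = 0.65, i.e. m ≈ 0.194. For the component split of a time point,
the final flash is treated as saturating (the advancing fraction is the
population arriving in the product state), so the advancing fraction after
the third flash is the full 0.65; the completed fraction at delay t follows
the monotone default 1 − exp(−t/τ) with τ ≈ 2,470 µs, calibrated once so
that the 1,200 µs point reproduces the canonical 0.40/0.35/0.25
primary/secondary/tertiary split. Components below the 10% noise floor
cannot be refined as separate structures; their mass is redistributed
proportionally among the survivors (this is what collapses the earliest
time point to a two-component model). Direct entry of a tabulated split is
equally supported — the kinetic model is a convenience, not a commitment.

## Crystallographic engine

Everything runs in space group P1 on small (~24 Å) cells; the algorithms
under test are space-group-agnostic, and a desk-scale cell keeps direct
summation exact and cheap. Conventions, fixed once:

* s = sin θ/λ = 1/(2d); Debye–Waller factor exp(−B s²); four-Gaussian
  scattering factors (f(0) within 2% of the electron count).
* F(h) = Σⱼ occⱼ fⱼ(s) exp(−Bⱼ s²) exp(2πi h·xⱼ); density by inverse FFT
  with F000 excluded, so maps are zero-mean. Default grid spacing is a
  third of the resolution limit.
* Reflection lists are Friedel-unique and lexicographically sorted;
  negative difference amplitudes are stored as positive amplitudes with the
  phase shifted 180°.
* Difference maps use unit m and D weights by default; per-reflection
  weights can be supplied. Per-resolution-bin scaling uses equal-count bins
  in s with the least-squares factor Σ|F_ref||F| / Σ|F|² per bin; empty
  bins merge with a neighbour.
* Distances between atoms use the minimum-image convention — positions are
  defined modulo the lattice, and amplitude-only refinement of an
  unanchored component may legitimately translate it (in P1 the origin is
  free), possibly across a cell boundary.

## Multicomponent mixture refinement

A time point is modelled as ordered components sharing one cell, exactly
one refinable. The composite structure factor is the population-weighted
complex sum (the alternate-conformer convention). The refinement target is

  Σ_h w_h (|Fobs| − |Fcalc|)² + λ Σ_r (Δ_r / esd_r)²

over the primary component's fractional coordinates and per-atom isotropic
B factors (bounded below by B ≥ 2 Å² to prevent collapse), plus one group-B
offset per fixed component (so known endpoint structures can be adjusted to
the dataset's resolution without moving); fixed-component coordinates are
untouched bit for bit.

Numerical choices. The data weights default to inverse variance,
w_h = 1/σ_h², which puts the data term and the reduced restraint residuals
on the same dimensionless scale; the restraint weight λ therefore defaults
to 1 (restraints act as additional observations with their stated esds,
0.1 Å for bonds and 10° for angles — deliberately loose so atoms can follow
the density while the cluster keeps its shape). The minimization is
trust-region least squares (scipy `least_squares`, method `trf`) with an
analytic Jacobian for all parameter classes; it converges in ~10–30
residual evaluations where a quasi-Newton scalar minimizer needed hundreds
and wandered along the noise valley. Parameter scaling is ~0.1 Å for
coordinates and 5 Å² for B factors. Descent is monotone by construction;
`max_cycles` (default 100) bounds residual evaluations and `tol` (1e-10)
is the relative cost tolerance. The refinement aborts with diagnostics on
non-finite residuals (e.g. exactly overlapping atoms).

Omit maps recompute the composite Fcalc without the omitted primary atoms
— no re-refinement after omission — and return the σ-normalized mFₒ−DF꜀
map. Peak heights are the mean over a fixed deterministic cubic lattice of
~380 points inside a 0.5 Å-radius sphere (trilinear interpolation, periodic
wrap), so repeated calls are bit-identical.

Population/occupancy scans re-refine at each grid fraction, starting every
grid point from one common pre-refined geometry (deterministic, and free of
the path-dependent bias that chaining refinements along the grid
introduces). Ties resolve toward the smaller fraction — conservative
detection. Because the composite Fcalc is linear in populations, scanning
the Ox atom's occupancy inside the primary is the same computation as
splitting the primary into Ox-bearing/Ox-free variants and scanning the
Ox-bearing population with the endpoint components held; `estimate_population`
exposes the general component scan (with an optional `hold` list), and
`estimate_ox_occupancy` the single-atom parameterization.

## END/RAPID resampling errors

Each replica draws every observed amplitude uniformly within
±|m|Fobs| − D|Fcalc|| (clipped at zero — amplitudes are nonnegative;
perturbation acts on amplitudes only, phases belong to the model), jitters
the primary component's coordinates with an isotropic Gaussian of sd
0.05 Å (the distribution and default amplitude are this package's choice;
only the primary is perturbed), re-refines, and measures the requested
metrics. Replica RNG streams are spawned from the master seed by replica
index, so results are independent of execution order; failed replicas are
excluded and counted, and more than 20% failures aborts the run. The
reported per-metric standard deviation is an upper-bound error: the
injected amplitude perturbation overestimates the experimental noise.

## Trajectories and onsets

Marker trajectories over the delay grid are fitted with either a step
model (brute force over change points, weighted plateau means, onset at
the geometric mean of the bracketing delays) or a logistic in log-time
(weighted `curve_fit`; onset at the fitted midpoint). Both are equivariant
under uniform time rescaling. Because the delay grid is sparse and
logarithmic, the onset is always reported together with its bracket — the
pair of adjacent sampled delays around the fitted midpoint — and
comparisons between markers should use brackets, not pointwise times. A
constant series raises ("no transition detected"). The 2F and 3F(200 ms)
endpoint states serve as plateau anchors when included.

The population hypothesis test re-refines a time point under a base and a
deliberately misassigned alternative split and reports a metric under
both; the default robustness tolerance is 0.05 Å, the scale on which two
refits of the same elongated metal–metal distance are considered
indistinguishable.

## The synthetic scenario: what it emulates, and what it does not

The toy model is an abstracted analog, not the real cluster: four Mn, one
Ca and bridging oxygens with literature-like metal frame distances
(Mn1–Mn4 = 5.14 Å with the Ox bridge, 4.90 Å without), terminal waters on
Mn4 (riding with it) and Ca (static), a Tyr-OH/His-NE2 pair at 2.6 Å with
a phenol-ring scaffold, a carboxylate proton-gate dyad and two channel
waters, in a 24 Å P1 cube. B factors are room-temperature-like (metals
20 Å², light atoms 25–30 Å², channel waters 37 Å²), consistent with the
~37 Å² stable-water anchor.

Kinetic laws of the interpolated intermediate (all in log₁₀ time, all
configurable): Ox occupancy decays logistically with midpoint 1,000 µs
(≈0.95 at 250 µs, ≈0.18 at 2,000 µs); the Mn1–Mn4 analog contracts
5.14 → 4.90 Å with a later midpoint (1,400 µs), so contraction lags Ox
loss; the Yz–His distance rises 2.6 → 2.8 Å with a ~10 µs time constant
and recovers around 600 µs; the gate dyad transiently elongates
2.6 → 3.2 Å around 1,200 µs; the mobile channel water's B inflates to
50 Å² near 1,200 µs and relaxes. At t = 0 the intermediate is exactly the
S₃-like endpoint, and at t → ∞ exactly the S₀-like endpoint with vanishing
Ox occupancy. Observed amplitudes are |Σₖ pₖ Fₖ| plus fractional Gaussian
noise (default 3% per reflection); the starting guess always uses the
S₃-like geometry for the primary, so refinement must genuinely move it.

Limits of the emulation, hence of what green tests show about real data:

* **No model error.** Real difference maps' σ is dominated by
  whole-structure model error (R ≈ 0.18); the toy model is near-perfect
  (R ≈ 0.024), so its maps are far cleaner. A fully occupied O omit peak
  reads tens of σ here versus ~5–10σ in real maps. Presence thresholds
  behave realistically only when the atom's crystal-level occupancy
  (atom occupancy × primary population) is small.
* **σ-normalized peak heights are not linear in occupancy in a small
  cell**: the omitted atom's own peak contributes substantially to the
  cell rms, deflating the σ-value at high occupancy. Linearity holds
  exactly on the raw difference density, which is what linearity checks
  use.
* **Occupancy recovery degrades with population.** The scan recovers Ox
  occupancy to ±0.05 while the primary population is ≳0.4 (t ≤ 1,200 µs);
  by 2,000–4,000 µs a 0.05-occupancy step falls below the amplitude-noise
  floor and only an upper bound remains meaningful — the same regime in
  which the real analysis could only bound the Ox population.
* **Coordinate precision is information-limited.** At 3% noise the
  converged least-squares minimum sits ~0.05–0.07 Å RMS from the truth
  (the Cramér–Rao positional bound of this toy is ~0.035 Å RMS), matching
  the scale of END/RAPID error bars; noiseless data recover coordinates to
  <0.001 Å. Distances between restrained cluster atoms are much more
  precise than per-atom positions because collective errors cancel.
* No bulk solvent, no anisotropic displacement, no anomalous scattering,
  no space-group symmetry, no detector or partiality effects, and no
  XFEL merging artefacts. Restraint geometry assumes bonded pairs do not
  straddle a cell boundary in the starting model (the generator centers
  its motif).

## Side-chain rotation metric

The rotation of a side chain relative to a reference state is measured
after superposing the residue's backbone (N, CA, C): it is the magnitude
of the best-fit rotation, about the last common origin atom (CG for
Glu/Arg), that carries the reference's distal arm atoms onto the current
ones. A vector-to-centroid angle was rejected: a Glu carboxylate's
centroid lies essentially on the CG–CD axis, so a pure twist about that
axis — precisely the motion of interest for the proton-gate glutamate —
would read near zero. The best-fit-rotation form reads a pure torsion
change exactly and is invariant to whole-model rigid motion.

## Deposited-entry validation

Checks against deposited coordinate files are evaluated only on local
copies; a missing entry, or a label the map cannot resolve (the study's
water numbering lives in its supplementary table and ships unguessed), is
reported as *skipped*, never as a failure. Tolerances: ±0.1 Å for "about"
distances, ±0.15 Å for two-model distance differences, exact for
occupancy reads, upper bounds where the claim is a bound. Monomer I
(uppercase chains) is used unless monomer II is requested explicitly.

## Problem sizes

Default study conditions: ~27-atom models, 24 Å P1 cell, 2.0 Å resolution
(≈3,600 Friedel-unique reflections), ~110 refinable parameters per
mixture, 21-point occupancy scans, 100 END/RAPID replicas. A full
seven-point scenario analysis with per-point occupancy scans runs in a few
minutes on one CPU.
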