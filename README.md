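# kokflash

Desk-scale inference machinery for time-resolved crystallographic snapshots
of the photosystem II S₃→S₀ transition — the O₂-forming, clock-resetting
step of the Kok cycle.

## The problem

In a flash-pumped serial crystallography experiment on photosystem II, each
dataset at pump–probe delay Δt after the third flash is not a single
structure. Because every saturating flash fails to advance a fraction of
reaction centers (the *miss factor*), and because at long delays some
centers have already completed the transition, the crystal is a mixture of

1. a **primary** population advancing from S₃ toward S₀ — the refinable
   intermediate of interest,
2. a **secondary** population lagging one transition behind (S₃-like), and
3. a **tertiary** population that has completed the transition (S₀-like).

Extracting the intermediate's structure and its kinetics therefore requires
a chain of non-standard steps: propagating Kok-cycle populations through the
flash protocol (a miss-parameter Markov chain on {S₀…S₃}), refining a
multicomponent model in which the calculated structure factor is the
population-weighted complex sum F꜀(h) = Σₖ pₖ Fₖ(h) with only the primary's
coordinates/B factors free, quantifying atom appearance/disappearance from
mFₒ−DF꜀ omit maps (0.5 Å-radius sphere average, 2.5σ presence threshold),
scanning the occupancy of the transient Ox bridge against the refinement
R factor, estimating END/RAPID resampling errors (perturb amplitudes within
±(mFₒ−DF꜀), jitter coordinates, re-refine n = 100 replicas), and bracketing
the onset times of the kinetic markers (Yz–His190 hydrogen bond, Mn1–Mn4
distance, proton-gate rearrangements) on the logarithmic delay grid
50 µs – 4 ms.

`kokflash` implements this chain against a self-contained synthetic test
surface: a ~30-atom analog of the Mn₄CaO₅(-Ox) cluster and its environment
in a small P1 cell, with a ground-truth generator that reproduces the
statistical structure of the real study (two-state 65/35 starting mixture,
per-time-point three-component splits with a 10% population noise floor,
logistic Ox-occupancy decay, 5.14 → 4.90 Å metal–metal contraction, water
B-factor inflation). Deposited coordinate sets can optionally be validated
against the printed geometry/occupancy claims when local copies are
available.

## Worked example

Analyze the 1,200 µs time point — the 0.40/0.35/0.25 mixture — of a
simulated scenario: estimate the Ox occupancy by a population scan, refine
the primary intermediate and read off the Mn1–Mn4 marker.

```python
import numpy as np
from kokflash.simulate import (ScenarioConfig, simulate_timepoint,
                               default_restraints, OX_LABEL, MN1_LABEL, MN4_LABEL)
from kokflash.mixture import MixtureRefinement, estimate_ox_occupancy
from kokflash.metrics import atom_distance

config = ScenarioConfig()                      # 7 time points, 2.0 A, 3% noise
fobs, guess, truth = simulate_timepoint(1200.0, config)
restraints = default_restraints(guess.primary.model)

occ, profile = estimate_ox_occupancy(guess, OX_LABEL, fobs,
                                     np.arange(0, 1.01, 0.05), restraints)
print(f"Ox occupancy estimate: {occ:.2f} (truth {truth.ox_occupancy:.3f})")

guess.primary.model.atom(OX_LABEL).occupancy = occ
result = MixtureRefinement(fobs, guess, restraints).fit()
print(result.summary())

d = atom_distance(result.mcm_refined.primary.model, MN1_LABEL, MN4_LABEL)
print(f"Mn1-Mn4 analog distance: {d.value:.3f} A (truth {truth.markers['mn1_mn4']:.3f} A)")
```

Output:

```
Ox occupancy estimate: 0.45 (truth 0.402)
Mixture refinement results
==================================
n reflections    : 3576
n primary atoms  : 27
n restraints     : 35
restraint weight : 1
R before         : 0.0335
R after          : 0.0236
target initial   : 22848.8
target final     : 3499.74
iterations       : 23
converged        : True
populations      : primary=0.400*, s3=0.350, s0=0.250 (* refined)
Mn1-Mn4 analog distance: 5.046 A (truth 5.046 A)
```

The scan recovers the decaying Ox bridge's occupancy to within the grid
resolution, the restrained trust-region refinement converges in 23 residual
evaluations to R = 0.024 (the level set by the 3% amplitude noise), and the
refined intermediate reproduces the generating Mn1–Mn4 distance to
0.001 Å — even though the refinement started from the elongated S₃-like
geometry.

Higher-level drivers live in `kokflash.pipeline`: `analyze_timepoint` runs
scan → refine → omit map → marker measurement for one delay, and
`run_scenario` assembles the full seven-point marker trajectories from
which `kokflash.timeline.estimate_onset` brackets the transition times.

## Validating against deposited structures

`kokflash.validation` evaluates the printed geometry and occupancy claims
(Yz–His190 2.6 Å → 2.8 Å, the proton-gate dyad elongation, the W20 return
at 40% occupancy, …) against local copies of the deposited entries
(8EZ5, 8F4D–8F4K). Entries that are not present, and labels whose residue
numbering requires the study's supplementary water table, are reported as
*skipped*, never as failures, so the check table runs offline.
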