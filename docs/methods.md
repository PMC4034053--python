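# Methods

## Overview

`fgspike` simulates a feed-forward hierarchy of five areas of Izhikevich
spiking neurons that (i) segregates a binary display into figure and
ground, and (ii) classifies the display's shape by which of two output
cells fires first.  The functional analogy is retina/LGN (area 1), V1
(area 2), V2/V4 (areas 3–4) and IT (area 5).  There is no feedback, no
plasticity and no noise: a run is a deterministic function of the stimulus
and the configuration.

## Stimuli

Displays are `N x N` binary arrays (1 = white) with an inner square of side
`n = 64` px and a black margin of `m = 6` px (`N = 76`).  A polygon figure
is bounded by straight frame edges on the top, bottom and one side, and by
a single-valued "profile" line on the other side.  The profile is pinned to
the mid-points of the top and bottom inner edges; under this constraint the
total border length (counted as 4-adjacent differing pixel pairs) is exactly
equal across the original, its mirror reversal, its contrast reversal and
its figure-ground (FG) reversal, which makes the four displays geometrically
comparable.

The two built-in originals share a white count of 1720 px (area ratio 0.42
of the inner square, 0.30 of the full array).  Set 1 uses a smooth staircase
profile, so vertical borders dominate (`Bv > Bh`); set 2 uses a comb-like
profile with large total variation, so horizontal borders dominate.  The
exact silhouettes are not constrained beyond this: the generator adjusts
interior profile columns deterministically (round-robin, endpoints never
moved) until the target white count is met, and the figure remains
4-connected because every row keeps at least one pixel against the frame.

Two circle controls exist.  The *disconnected* control is a centred disc
whose radius is solved by grid search (1/16-px steps) so the inner area
ratio is as close to 0.42 as possible; its FG reversal does not conserve
border length (the complement of a disc also borders the whole inner-square
boundary) and the image set records that inequality instead of failing.
The *connected* control is a profile-class display whose profile line runs
from the top mid-point around the circle to the bottom mid-point, with the
white count adjusted to 1720: it conserves border length exactly and admits
the ordinary FG-reversal reading.  A literal disc-plus-bridges construction
is also provided (`generate_circle_stimulus(connected=True)`); it is useful
as a stimulus but cannot conserve border length under FG reversal, which is
why the experiment set uses the profile-class variant.

## Drive equations

With `x` denoting exponentially filtered spike activity ("traces") and `F`
the contrast channel (T1 = stimulus, T2 = its negation):

    I1F  = w1 * TF
    I2F  = w2e * x1F − |w2i| * mean(x1F) + I_bias
    I3Fj = w3 * Θ(S2F ⋆ fj − 1)
    I4Fj = kappa4 * w4 * mean(x3Fj)
    I5i  = Σ_F Σ_j w5[i][F][j] * x4Fj

with `w1 = 10`, `w2e = 400`, `w2i = −750`, `w3 = 500`, `w4 = 5.0` µA, and
`w5` built from `A = 100` µA (row F=1) and `B = 5` µA (row F=2).  `S2F` is
the binarized area-2 trace map, `fj` one of the four two-pixel ±1 kernels
(along-row kernels at even `j` detect vertical borders, along-column
kernels at odd `j` horizontal ones), `Θ` the step function with `Θ(0)=1`,
and the correlation is anchored at the first pixel of the pair with zero
padding (irrelevant for framed stimuli, whose margins are black).

Cell 1 of area 5 reads the even (vertical-contrast) subchannels and cell 2
the odd ones, each weighting channel F=1 by `A` and F=2 by `B < A`.

## Segregation mechanism and the area-2 operating point

The mean-field term in `I2F` scales with the white fraction ρ of the
channel.  For the shipped geometry the per-site drive amplitudes fall into
a small ladder (in units of the area-1 trace): white sites receive
`w2e − |w2i|·ρ` (≈ +177 for ρ ≈ 0.30, ≈ +92 for ρ ≈ 0.41, negative
beyond ρ ≈ 0.53) and black sites receive `−|w2i|·ρ` (≈ −223 … −527).  The
intended regimes are: driven spiking on moderately covered white regions,
silence under weak and intermediate inhibition, and inhibition-driven
("rebound") spiking under the strongest inhibition — so that in the channel
whose white region is the majority of the display, the *complementary*
(figure) region is the one that fires.

Realizing all three regimes in one neuron population is the delicate part
of the model, and the shipped operating point was designed around three
ingredients:

1. **Pulsed inhibition.**  Area-1 cells (a=0.02, b=0.2, c=−60, d=2) fire a
   short dense volley and then tonically every ~15–25 ms at `w1 = 10`.
   Their output trace uses a short time constant (`tau_syn_input = 0.4`
   ms), so downstream drive arrives as brief strong kicks separated by
   long release windows.
2. **A strong, slowly recovering coupling.**  Area-2 cells use `b = 0.5`
   with `a = 0.25`: each hyperpolarizing kick drags the recovery variable
   `u` down by an amount graded in the kick depth, and `u` integrates this
   over the run into well-separated levels for the different inhibition
   classes.
3. **A tonic hyperpolarizing bias** (`area2_bias = −17.4` µA, added to
   `I2`).  The bias plays two roles.  It deepens the resting state, which
   both stabilizes the `b = 0.5` fixed point and widens the subthreshold
   gap so that +92-class kicks are near threshold (sparse spiking) while
   +177-class kicks fire reliably.  And it positions the escape gate — the
   `u` level below which the membrane has no rest and fires through — in
   the gap between the `u` levels reached under −308-class and −441-class
   inhibition.  The −41/−127/−223/−308 classes stay silent; the −441/−527
   classes fire during the release windows.

The result, measured per unit over a 100 ms run on the shipped fixtures:
~12 spikes at +177, ~7 at +92, 0 for all intermediate inhibition levels,
and ~4 at −441/−527.  Area-2 spiking sites then coincide exactly with the
figure region in both channels (Dice 1.0 on all fixture members), which is
the segregation property the rest of the hierarchy consumes.

These neuron parameters are a designed operating point, not biophysical
estimates; the configuration exposes every one of them, and `kappa4 = 1`
with `tau_syn → 0` recovers the literal (unsmoothed) drive equations.

## Downstream plumbing

* **Binarization** (`theta_b = 0.4` of `trace_saturation = 1.0`): a site of
  the area-2 map counts as active for ~4.6 ms after each spike
  (`tau_syn = 5` ms), so the duty cycle of the border-detection stage
  reflects the area-2 firing rate.  This is what converts the rate ladder
  into graded area-4/5 responses.
* **Area-4 gain** `kappa4 = 250`: the literal mean-normalized drive
  (`w4 = 5` µA spread over `N² = 5776` sites of which only a border
  fraction is active) is far below threshold; `kappa4` rescales it equally
  for every subchannel, preserving all orderings.
* **Timing**: synchronous update with a one-step feed-forward delay — every
  drive at step k uses traces from the end of step k−1, so onsets
  accumulate causally across areas.

## Numerical choices

* Forward Euler, `dt = 0.25` ms, membrane advanced in two half-steps per
  step (the common practice for this model); recovery in one full step
  using the updated voltage; spike cutoff +30 mV, reset applied after the
  update.  Initial state `v = −65` mV, `u = b·v`.
* All spatial means use a permutation-invariant reduction (sort before
  summing) and the area-5 weighted sum uses a fixed balanced reduction
  tree.  Consequently a mirrored stimulus yields bit-identical area-4/5
  drive series, a contrast-reversed stimulus yields exactly channel-swapped
  areas 1–3, and a quarter-turned stimulus exactly exchanges the two output
  cells — these symmetries are asserted in the test suite at zero
  tolerance.
* Classification: the cell with the strictly earlier first spike wins;
  exact onset ties fall back to the larger spike count; full ties (or two
  silent cells) are reported as `none`.  Suppression flags use non-strict
  comparisons against mirror/contrast and strict ones against the original.
* Degenerate stimuli (uniform images) run normally — one channel is simply
  silent — and classification reports `none` when both output cells stay
  silent or tie exactly, as for the perfectly symmetric disconnected disc.
* No randomness is used anywhere by default.  A seeded uniform ±jitter on
  initial voltages is available (`jitter_mv`, `jitter_seed`) to break the
  lockstep synchrony of identical units; it is off by default and unused by
  the shipped experiments, and the seed is part of the recorded
  configuration hash when used.

## What the fixtures do and do not establish

The generator emulates the *constraints* of the original displays — frame
and profile construction, mid-point anchoring, equal areas (0.42/0.30),
border-length conservation, orientation dominance — not their hand-drawn
silhouettes.  Every behavioural result (segregation quality,
classification, suppression orderings, rotation swap) is therefore a
statement about this constraint class under the shipped configuration, not
about any particular silhouette, and not about noisy or greyscale input.

## Known limitations

* **FG suppression is strict against the original and mirror, but not
  against the contrast reversal.**  In this implementation the
  contrast-reversed display — whose dominant (A-weighted) channel is
  rebound-driven — responds somewhat less than the FG-reversed display,
  whose dominant channel is weakly excitation-driven.  Flipping that
  ordering would require inhibition-driven firing to match or exceed
  weak-excitation-driven firing per unit time; an extensive search of the
  single-cell parameter space (rhythms, trace time constants, bias,
  recovery dynamics) found no such regime for the standard two-variable
  quadratic model under this drive family.  The `fg_suppressed_by_*`
  flags, which compare FG against *all* other transforms, therefore come
  out `False` on the shipped fixtures, while the strict FG-vs-original
  suppression (counts and onsets, both cells, both sets) holds with a
  comfortable margin.
* The two output cells only separate vertical- from horizontal-border
  dominance; displays with `Bh ≈ Bv` (e.g. the symmetric disc) classify as
  ties by construction.
* Exactness of the mirror/rotation symmetries depends on the
  permutation-invariant reductions; replacing them with plain `np.mean`
  keeps results statistically identical but breaks bit-level equality.
* 100 ms of simulated time and the 76×76 geometry are the defaults
  throughout; the half-scale 38×38 geometry used by the fast tests
  preserves the inner/outer proportion (and hence the drive ladder), and
  behaves identically in kind.
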