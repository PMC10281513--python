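# Methods

## The channel pheromone model

The agent walks on a discrete lattice of integer body-length (BL) positions
wrapped around a circular channel (default circumference 26 BL for the
alternating-zone protocol, 52 BL for the multi-reward protocol). Each time
step is Δt = 0.5 s and each moving step covers exactly 1 BL; the source
description fixes the time step but not a step length, and the unit lattice
is the simplest choice that makes "stepping on" a zone or droplet well
defined. The agent starts in global search — continuous forward walking,
effectively an infinite run — and switches permanently to local
run-and-reversal search at its first reward contact.

Events and their run-length laws (all Normal, truncated below at 1 BL by
resampling):

| event | law | default |
|---|---|---|
| reversal (run exhausted) | N(μ₀, σ₀) | μ₀ = 80, σ₀ = 20 BL |
| eating (active zone) | N(μ_rew, σ_rew) | μ_rew = 4.125, σ_rew = 2.625 BL |
| smelling (odor value c) | N(k_μ·c, k_σ·c) | k_μ = k_σ = 3 BL |

The smelling law is the simplest form consistent with the named
odor-scaling parameters; we do not claim it is the only candidate. After
eating or smelling the agent keeps its direction for the fresh run, then
reverses; eating additionally pauses the agent for 10 steps, deposits a
droplet at the zone, and makes the zone refractory for 16 steps. Droplet
odor decays linearly from 1 to 0 over τ = 500 steps; τ is taken in time
steps (250 s), which makes deposits decay within one 10-min trial — the
mechanism behind the model's lack of 180° periodicity across alternating
trials. When several droplets share a site the effective odor is the
maximum (equivalently, the freshest droplet). Event precedence on a step is
eating > smelling > reversal. Smelling is ignored in global-search mode,
since an interrupted "run" would cause reversals before any reward has been
encountered, contradicting the global-search definition; in practice no
droplets exist before the first reward.

Truncation matters more than intuition suggests: for the eating law,
P(X < 1 BL) ≈ 0.12, so the realized mean run after eating is ≈ 4.71 BL,
not 4.125. Tests therefore validate draws against the closed-form
truncated-normal mean, not the nominal μ. The resample-until-≥1 loop is
capped at 64 attempts (then returns the 1 BL floor) because the smelling
law concentrates all its mass below 1 BL as c → 0.

The run midpoint between consecutive reversals is the point half the
travelled arc beyond the first reversal (runs may lap the channel several
times; pauses contribute no arc), wrapped to the channel.

Protocols: the alternating ("circling") protocol runs 6 trials of 5 min
activation (AP) + 5 min post-AP on one persistent agent, with the single
active zone alternating between two diametrically opposite coordinates;
droplets and their clocks persist across trials. The multi-reward protocol
is a single trial with three simultaneously active zones (0, ±5 BL), each
with its own refractory clock.

## Displacement analysis

All positions are arena-centered cm, y up. Zone membership is the closed
disc (a measure-zero convention fixed for determinism). The fictive reward
zone is the actual zone translated by the per-trial displacement vector;
equivalently the trajectory may be translated by the negative vector — the
two give identical distances and all analyses are invariant to the choice.

Pipeline defaults (each echoed into reports): artifact speed threshold
50 cm/s (roughly ten times walking pace; a speed filter plus an optional
explicit exclusion mask replaces manual curation), time downsampling to
0.1 s bins (first sample per bin, bins anchored at the first timestamp),
distance downsampling in 1 mm steps (existing samples only, never
interpolated — stops therefore vanish, which is the purpose), occupancy
bins of 1×1 cm anchored on the integer-cm lattice, a 100 s test window
timed from the annotated displacement end (shorter recordings are included
with their available window and flagged), a 5 s initial-direction window
whose endpoint is the last sample inside the window (no interpolation),
and intersection-score parameters of a 2 cm restriction window with 2.5 mm
overlap proximity.

Because distance downsampling emits existing samples, re-applying it can
drop further points (inter-sample path lengths collapse to chords); the
procedure is convergent rather than strictly idempotent, and the suite
tests exactly that.

Statistics: the two-proportion z-test is the pooled-variance form with a
two-tailed normal p. The Rayleigh statistic is z = nR² with the Zar series
approximation for p (via `pingouin.circ_rayleigh`), so printed p-values are
comparable with the circular-statistics literature. Welch's and the paired
t-test are the standard scipy implementations. No multiple-testing
correction is applied; reported p-values are unadjusted. The per-fly
initial direction uses the 5 s endpoint offset from the release point; the
condition-level mean trajectory vector is the vector sum of those offsets.

The intersection score restricts both the pre-displacement path and the
post-displacement path to the 2 cm disc around the fly's position at
displacement; an "after" point overlaps if some "before" point lies within
2.5 mm; the score is the largest Euclidean distance between the endpoints
of a maximal contiguous overlapping run (an along-path variant is available
via `endpoint_metric="path"`; the Euclidean reading is primary). In the
end-to-end analysis the post-displacement segment is translated back by the
displacement vector before scoring: any chemical trail rides on the
displaced slider, so retracing is only visible after undoing the
displacement.

The pheromone residency analysis downsamples to 10 Hz, discards the first
5 min of the test stage (freshly introduced flies sit still at random
places), computes one pooled zone fraction and one normalised residency
histogram per trial (group of flies), averages histograms within condition,
and compares per-trial fractions across conditions with Welch's t.

## Synthetic data

Walkers are discrete-time correlated random walks: heading noise with
variance scaling ∝ Δt plus an optional steering term pulling the heading a
fixed fraction toward the bearing to a target each step; walls act like the
experimental heat barrier by turning the walker back toward the arena
center. Local search is this steering toward a search center, which yields
looping dwells covering a 2.8 cm zone well within a 100 s window. Defaults:
25 Hz frames, 1.5 cm/s walking speed, stop bouts at 0.05 s⁻¹ with 4 s mean
exponential duration, 0.02 cm Gaussian tracking noise, 60 cm (displacement)
and 20 cm (pheromone) arenas, a 5.6 cm-diameter reward zone at
(−9.8, 6.7) cm, and a passive displacement of length N(9.2, 2.78) cm
truncated positive with the direction re-drawn until the endpoint stays
inside the arena. The annotated displacement vector is measured from the
noisy recording (as an experimenter would), while the ground-truth file
stores the noiseless vector, stop intervals and injected outlier indices.

Behaviors: `pi-searcher` searches around the fictive zone, emulating an
intact path integrator; `site-fixed-searcher` around the actual zone,
emulating cue following; `random-walker` has no target. Pheromone-trial
flies add an initial sitting period (uniform up to 6 min) so the 5-min
exclusion rule is exercised, and a turning bias toward the zone whose
strength stands in for emitter-deposit attractiveness (0 = no emitter).

What the generator does not emulate: real fly locomotor statistics
(velocity autocorrelations, thigmotaxis, grooming), realistic effect sizes,
or any pheromone physics in 2-D. Recovery tests on these data show the
pipeline detects the structure it targets when present and stays silent
under the null; they do not show how large such effects are in real flies.

## Problem sizes

The test suite and the acceptance script use compressed synthetic-trial
timelines (30 s baseline, 20 s stimulation, 10 s post-stimulation, 110 s
test at 25 Hz) — every protocol phase is present and the analysed test
window is full length, while cohort batches (100 × 20 flies) stay cheap.
The channel-model checks use the full published protocol (100 replicate
agents, 6 × 1200-step trials). Null calibrations use 500 simulated datasets
each; the two-proportion null uses binomial counts of n = 5000 per group so
the discrete p-value distribution is close enough to uniform for a
meaningful KS comparison.

## Known limitations

- The channel model's smelling law and step length are plausible choices,
  not measured quantities; conclusions should rest on qualitative behavior
  (midpoint concentration, decay-driven asymmetry), which is robust to
  these choices.
- The artifact filter is a greedy last-kept-anchor speed gate; it removes
  isolated teleports reliably but, like any automatic rule, is not a
  substitute for inspecting recordings with systematic tracking faults.
- The intersection score depends on sampling density through run
  contiguity; compare scores only between identically downsampled
  trajectories.
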