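# Methods

This note documents the models, conventions and numerical choices behind
`fishstim`, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic swimmer

The generator emulates the structure that the skeletal converter assumes: a
smooth planar swimming trajectory carrying a travelling undulation wave
along a 6-point trunk midline at 60 fps.

**Locomotion.** The head follows a constant-speed correlated random walk in
the horizontal plane. Heading is an Ornstein–Uhlenbeck-style process with
correlation time `heading_persistence` (default 2 s), steered back toward
the tank centre whenever the head enters a wall margin of one body length
plus the maximum lateral amplitude; the head position is additionally
clamped to that margin box, which guarantees every body point stays inside
the tank for any heading. Depth is a slow OU process (relaxation 8 s,
≈1.5 mm·s^-1/2) around mid-depth, and the whole body carries a small smooth
pitch (|pitch| ≤ 0.15 rad), so tracks are genuinely three-dimensional but
dominated by horizontal motion — matching the assumption that the fish's
dorsoventral axis stays vertical. Setting `speed_mean = 0` switches all of
these locomotion sources off (a non-swimming fish holds position and
heading), so a zero-amplitude, zero-speed parameterisation produces a
perfectly rigid, stationary track.

**Body motion.** In the body frame the midline is an analytic curve: a
straight backbone with lateral offset `A(s)·sin(2π(s/λL − f t))`, a wave
travelling head→tail. `A(s)` interpolates the per-point amplitude envelope
(non-negative, non-decreasing head→tail; default 0.3→4.5 mm for a 30 mm
fish), `λ` defaults to one body length and `f` to 2.5 Hz. No kinematic
measurements of the original recordings are published, so these defaults
are assumptions chosen to resemble relaxed cruising (~1 body length/s,
modest tail beat); they are parameters, not facts about any real fish.

**Equal spacing.** The 6 points are placed on the analytic curve with
*exactly equal chord spacing* `body_length/5`, found by sphere-crossing
interpolation along a dense (600-sample) polyline. Equal chords — rather
than equal arc length — were chosen deliberately: the skeletal conversion
models the body as five rigid links of fixed length, and constant chords
make that model exact, so the forward-kinematics round trip reconstructs
the generated points to machine precision. The analytic curve extends 25%
past the nominal body length so the chord walk never runs off the end;
consequently the undulating body is not arc-length-conserving (the "body"
stretches slightly along its own curve at high curvature). This is
invisible to every downstream consumer, which only ever sees the 6 points.

## Synthetic assay cohort

Each subject is a two-state Markov chain — head inside vs outside the 10 mm
display zone — sampled at 30 fps over a 1-min baseline plus 5-min stimulus
period. Entry and exit hazards (per second) are piecewise constant per
minute bin and per group; per-frame transition probabilities are
`1 − exp(−rate/fps)`. Reported head distances are uniform on [0, 10) mm
while in the zone and (10, 140] mm while out, so the distance trace has the
right support without modelling spatial dynamics. Default hazards (entry
0.05/s, exit 0.25/s) give a stationary in-zone fraction of 1/6 — about
10 s/min at baseline, comfortably below the 55 s exclusion ceiling. The
demo's planted effect multiplies the entry hazard during the stimulus
period: ×4 for the Normal group, ×1.5 for other stimulus groups, ×1 for
Blank, encoding "the Normal stimulus attracts most".

What the simulator deliberately does **not** emulate: spatial
autocorrelation of the head trace within a state, tracking dropouts
(supported by the scorer but not generated), inter-subject heterogeneity in
baseline tendency, and non-Markovian bout structure. Passing tests
therefore demonstrate that the pipeline recovers effects expressed as
hazard changes in a memoryless occupancy process — not that it would be
robust to every pathology of real video tracking.

## Skeletal conversion and BVH

Each frame's five adjacent-point unit vectors are described by two global
angles: yaw (heading of the horizontal projection, via `atan2`) and pitch
(elevation, via `asin`). Roll is identically zero — the vertical-axis lock.
The root carries the head path and the first segment's angles; each joint
carries its segment's yaw and pitch *increments* over the parent segment,
and forward kinematics accumulates these increments down the chain.

This heading/elevation composition was chosen over strict hierarchical
Euler-matrix composition because the relative rotation between two
roll-free orientations generally contains a twist component: decomposing it
into matrix-composed Euler channels would either break the roll-lock
invariant or lose exactness. With the increment convention, roll stays
exactly zero, the global segment directions are reproduced exactly, and for
planar poses (pitch = 0) the two conventions coincide. The practical cost:
a third-party BVH player composing rotation matrices will show
sub-degree-scale deviations on frames where both yaw and pitch vary — the
pitch here is bounded at ~8.6°, so the discrepancy is far below visual
relevance, and `forward_kinematics` is the package's authoritative decoder.

Other conventions: segment offsets are per-segment median chord lengths
(robust to jitter; exact when chords are constant); near-vertical segments
(horizontal norm < 1e-6) carry the previous frame's yaw forward to avoid
channel discontinuities; yaw is unwrapped along time; degrees in files
(BVH convention, channels `Zrotation Yrotation Xrotation` with
`Yrotation = −pitch`), radians internally; motion values printed with 6
decimals, so a write/read round trip is exact to 5e-7.

## Manipulations

* *No locomotion* freezes root translation **and** root yaw at their
  frame-0 values; a drifting heading is itself locomotion, and the figure-
  level description has the tail-fin motion intact while the fish stays
  put. Root pitch is retained as body motion. Freezing translation only is
  available via `freeze_heading=False`. The held pose is frame 0; where the
  original stationary fish was pinned is not documented, and frame 0 is the
  one pose every variant shares.
* *No body motion* zeroes all joint channels, leaving the root bit-intact.
  The two operators commute (they touch disjoint channels), and their
  composition has the same motion content as the static stimulus up to the
  choice of held pose.
* *Pressed* scales body-local geometry by (length 1, width 3, height ⅓) —
  volume-preserving by construction.
* *Grey scale* uses ITU-R BT.709 luma weights (0.2126, 0.7152, 0.0722),
  normalised and configurable; the original conversion tool's mode is
  unknown. Output keeps 3 equal channels, making the operator idempotent.
* *Static* holds frame 0; *looping* tiles the one-minute block 5× with a
  hard cut (the join discontinuity equals the block's last-to-first jump).

Composition order in `apply_spec` is shape → colour → motion edits →
static/loop; the operators commute, so the order is a convention that
cannot silently matter.

## Scoring

Occupancy is the count of frames with head distance ≤ 10 mm (boundary
inclusive) divided by the frame rate, over half-open intervals `[t0, t1)`;
stimulus minutes are `[m, m+1)`. "Over 55 s" exclusion is a strict
inequality (55.0 s retained), configurable. Frames with missing positions
are dropped from numerator and denominator and the occupancy rescaled to
the bin length, so dropouts do not read as absence. Difference scores are
signed seconds, bounded in [−60, +60].

The ANOVA response is the difference-score matrix with time levels
(baseline, min 1–5); the baseline level carries 0 by construction, so each
subject is its own control. A structural consequence: the baseline level
has zero variance, so sphericity is always violated in this design and the
Huynh–Feldt correction is engaged in practice. Raw per-minute occupancy is
also emitted for plotting.

## Statistics

**Split-plot ANOVA.** Sums of squares by the classical weighted marginal-
means decomposition; with groups of (possibly) unequal size the group and
cell terms are weighted by group n. Group is tested against subject-within-
group (df g−1, N−g); time and group×time against time×subject-within-group
(df (k−1)·(N−g)). Exact agreement with an independent implementation
(pingouin) is asserted in the tests. Zero error variance yields F = NaN
plus a warning rather than an exception — degenerate fixtures are
legitimate (e.g. the all-zero baseline slice in simple main effects).

**Sphericity.** Scores are projected on a normalised Helmert contrast basis
(`scipy.linalg.helmert`, p = k−1 orthonormal rows). The within-group
contrast SSCP matrices are pooled over groups (error df e = N−g) and the
likelihood-ratio sphericity criterion `W = det(S) / (tr(S)/p)^p` is
referred to chi-square with `X² = −(e − (2p²+p+2)/(6p))·ln W` on
p(p+1)/2 − 1 df — the Mauchly (1940) one-sample approximation applied to
the pooled multisample covariance. This pooled formulation only requires
the *pooled* SSCP to be nonsingular (e ≥ p), not each group's own. Null
calibration at g=3, n=20, k=4 is verified by simulation (2000 replicates;
rejection within the 99% binomial band of α = 0.05). ε̂_GG =
tr(S)²/(p·tr(S²)); ε̂_HF uses the multi-group form
`((e+1)·p·ε_GG − 2) / (p·(e − p·ε_GG))` with e = N−g, clipped to
[ε_GG, 1]. The HF correction multiplies both numerator and denominator df
of the within effects by ε and re-evaluates p; F itself is unchanged.

**Simple main effects** use slice-specific error terms: group at time t is
a one-way ANOVA on that column; time within group G is a one-way
repeated-measures ANOVA on that group's rows (and is verified to equal the
standalone RM ANOVA). Pooled-error variants exist in the literature; the
slice-specific choice keeps each test interpretable in isolation and robust
to heteroscedasticity across slices.

**Ryan's procedure.** Means are rank-ordered; the pair spanning r ordered
means is tested by a two-sided t-test on the pooled error term at nominal
level `α_r = 2α / (k(r−1))` — α itself for k = 2, the Bonferroni level at
full range. Stepwise coherence is enforced: a pair is significant only if
its own test rejects and every enclosing span's test rejected, so no
isolated significance appears inside a non-significant stretch. The exact
small print of "Ryan's method" varies across sources (the REGWQ
studentized-range variant is a common alternative); the adjusted-α t-test
formulation implemented here is the one isolated in `ryan_posthoc`, and the
simulated family-wise error rate under a complete null (k=6) stays below α.

**Analysis chain defaults** (`analyze_scores`): HF correction is applied
when the sphericity test rejects at α; simple main effects when the
(corrected) interaction is significant; group post-hoc runs on per-subject
means pooled over time against the between-subjects error (MS scaled by
1/k because subject means average k scores); time post-hoc runs on time
means against the within error.

## Problem sizes and determinism

Monte-Carlo checks use 2000 null replicates for the type-I-error and
sphericity calibrations and for the Ryan family-wise error, and 24
replicate cohorts for end-to-end planted-effect power — sizes at which the
99% binomial band is a few points wide and the full run completes in tens
of seconds. All generators take explicit seeds and are bit-reproducible;
there is no global random state anywhere in the package.

## Known limitations

* No mesh modelling, texturing, rendering or video encoding: the stimulus
  artefact is the BVH animation plus geometry/texture transforms, not a
  movie file.
* The two-view merger assumes synchronised cameras, known mm/px scales and
  complete detections; no lens distortion or dropout model.
* The split-plot ANOVA handles unequal group sizes by weighted means, not
  Type-III sums of squares; heavily unbalanced designs are out of scope.
* The swimmer is a single fish; multi-fish interaction, hydrodynamics and
  vertical swimming (pitch beyond ±~9°) are not modelled.
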