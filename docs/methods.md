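# Methods

This note documents the models, rules and numerical choices behind the
package, in the spirit of a methods appendix: what is computed, under
which assumptions, and what passing tests do and do not demonstrate.

## Coordinate model and geometry

All geometry is planar (floor-plan projection), in metres, with the
origin at a designated room corner and right-handed x/y axes. A room
layout is a simple boundary polygon, named doorway segments on that
boundary, object footprints (simple polygons) marked `fixed` or
`movable`, and optional named interaction points. People are modelled as
discs of radius `person_radius` (default 0.25 m); no body model is
standard in this literature, and a disc is the weakest assumption that
still gives contacts and clearances a scale.

Obstacle inflation (Minkowski dilation with mitred corners, via shapely
buffering) converts person-centre planning into point planning: the free
space is the boundary eroded by the body radius minus every fixed
footprint dilated by it. Movable objects are *never* part of the static
obstacle set — they are precisely the candidate causes of detours.

Shortest feasible paths are computed on the visibility graph over the
free-space polygon's vertices (plus the two endpoints), with Dijkstra
over Euclidean edge weights. In a polygonal world the optimal path bends
only at obstacle corners, so this is exact, not an approximation; the
test suite nevertheless cross-checks it against an independent
32-connected lattice Dijkstra oracle (cell 0.05 m, worst-case lattice
overestimate ≈ 1%) at a 2% tolerance.

## Behavioural coding rules

**Visits.** A visit opens when a subject's smoothed speed stays below
`dwell_speed_threshold` (0.1 m/s) for at least `dwell_min_duration`
(1.5 s) while inside an object's interaction zone (footprint dilated by
`interaction_radius`, default 0.6 m), and closes when the subject leaves
the zone. Speed is estimated by box-smoothing positions over 0.4 s and
central-differencing over 0.5 s; a raw two-point estimate at 10 Hz is
dominated by tracking jitter at dwell speeds and misses genuine dwells.
Overlapping zones tie-break to the nearest footprint. Zone membership
for movable objects uses their layout (parked) pose; visits at a cart
that is currently being pushed elsewhere are therefore approximate.

**Legs.** One leg joins each consecutive pair of anchors (visits or
doorway crossings) per subject. The actual length is the walked polyline
measured on a 0.5 s grid — fine enough to follow real corners, coarse
enough that the per-sample positional noise (s.d. 0.02 m) inflates a
typical leg by well under 1% rather than the ≈15% a 10 Hz polyline
accumulates. The baseline is the visibility-graph shortest path between
the same endpoints at body inflation; anchors that sit marginally
outside the free space (boundary crossings, noise) are snapped to the
nearest free point first. Unreachable baselines exclude the leg from
impediment analysis with a warning.

**Impediments.** A leg is an impediment iff
`actual > 1.20 × baseline` (strict — "more than 20 per cent") **and**
`actual − baseline ≥ 1.0 m` ("at least one metre") **and** the
attribution rule holds: some other person or movable object intruded the
baseline corridor (baseline dilated by `2 × person_radius`) during the
leg's time window, sampled at 0.25 s. The corridor-intrusion rule is
this package's operationalization — the field definition names the
cause ("needed to go around a person or moveable object") but no test;
dilating by two body radii makes "would have had to pass through them"
checkable. An obstacle-aware (rather than straight-line) baseline is
used because fixed furniture legitimately forces detours that are not
impediments. Note the scale asymmetry: the 20% ratio is invariant under
scaling all coordinates by k, the 1 m absolute test is not; both
behaviours are tested explicitly.

**Bumps.** Entities are agent discs, tracked movable-object footprints
(translated to the current pose) and untracked objects at their layout
pose. A contact exists when two shapes come within `contact_margin`
(default 0 m); contacts of the same pair separated by gaps ≤
`bump_merge_gap` (0.5 s) merge into one event. Contacts with the object
a subject is visiting, or is next to visit, are *intended* (operating
equipment requires touching it) and are excluded. Two permanently parked
objects in static contact are geometry, not behaviour, and are skipped.

**Interruptions.** Annotation-driven only: an interruption is a
diversion of attention, which trajectories cannot witness, so a
positional heuristic would be unvalidatable. Annotations are counted
when they fall inside the interrupted subject's open task window
(task_start/task_end events); others are dropped with a warning.

**Task completion times.** First inward doorway crossing to last
outward crossing, per agent. Re-entries are folded into that single
span by the declared rule; agents who never exit are timed to their last
sample and flagged.

**Link analysis.** Agent tracks are resampled to the nominal rate; each
sample (except the last) adds its sample interval to the occupancy cell
(default 0.25 m) containing it while inside the boundary, so total grid
dwell equals total in-room time by construction (tested to 1e-6
relative). High-traffic cells are those at or above the 90th percentile
of positive-dwell cells.

## The scenario simulator

The simulator is the package's synthetic-data generator. It emulates the
structure of a medication-room enactment study: four scenario scripts
staffed by 1, 2, 3 and 4 concurrent roles (two nurses on a morning
medication pass, one nurse preparing a STAT medication, one pharmacy
technician stocking), enacted in an existing and a proposed layout.
Agents enter through a doorway at scripted times (entries through the
same doorway are staggered by 2 s with a warning if they collide), walk
visibility-graph paths at scripted speed, dwell at targets for drawn
durations (fixed, uniform or lognormal), and exit. Avoidance is a
priority rule: the earlier-entering agent has right of way and the other
pauses, up to 8 s — only the resulting measures matter, not locomotion
realism.

Numerical guarantees the generator maintains:

* **Noise.** Per-sample, zero-mean Gaussian with s.d. 0.02 m, truncated
  at ±0.05 m, applied after planning. Agent paths are planned at
  inflation `person_radius + 0.08 m`, so no noisy sample can enter a
  body-radius-inflated fixed obstacle — a hard invariant of the output.
* **Determinism.** One seeded generator per scenario drives every draw
  in a fixed order; identical seeds give byte-identical logs.
* **Planted ground truth.** Block obstructions park a cart across a
  corridor for a window, and the affected agent replans around it; the
  detour is recorded as ground truth only when it clears the detection
  thresholds with a margin (ratio > 1.25, excess ≥ 1.1 m vs 1.20/1.0),
  so planted events are unambiguous under measurement noise rather than
  borderline. Contact obstructions place a cart 0.35 m abeam of a
  walking agent for ≈0.5 s — inside disc-footprint contact range even at
  worst-case truncated noise, and away from fixed furniture. Planted
  interruptions are annotations emitted inside the victim's task window.
  Carts travel between stations along obstacle-aware routes at 1 m/s.

What the simulator does **not** emulate: human gait and pace variation,
social walking behaviour, groups, queues forming by social convention,
hesitation, or VR-specific artifacts (tether constraints, tracking
dropouts). Recovery tests therefore demonstrate that the detectors
recover *the definitions as planted*, not that the definitions capture
every real-world congestion event; applying the pipeline to observed
tracking data would additionally face sensor noise far above 0.02 m.

## Comparative analytics

**Layout comparison** tabulates any subset of measures for two reports
computed under identical thresholds (a config mismatch is an error —
counts are threshold-sensitive). Rows may carry the status
`not_programmed` or `not_possible` with no values, mirroring how
evaluation reports document measures their instrumentation missed.

**Percent differences** use round-half-away-from-zero to integers; the
summary reports the arithmetic mean (rounded to integer) and the sample
SD (n−1) *of the rounded percents*, to one decimal — the convention that
reproduces published summaries of this kind. The statistic is
deliberately asymmetric: observed time is the denominator.

**Survey comparison** is a Welch two-sample t-test (hand-computed
statistic and Welch–Satterthwaite df, cross-checked against scipy to
1e-8 in tests). The default is one-sided in the direction of the
observed difference, because each survey item states a directional
design hypothesis ("the proposed layout is less congested"); two-sided
doubles the p. Zero-variance equal-mean degenerate input returns t = 0,
one-sided p = 0.5 by convention.

**ROI** follows the Phillips convention: benefits are the most
conservative renovation-cost avoidance (`n_rooms × per_room_cost_low`),
costs are hard costs plus `labor_hours × (hourly_rate + overhead_rate)`.
An explicit `total_cost_override` exists because published totals are
sometimes stated directly and need not equal the printed component sum —
the bundled worked example uses a stated total of CAD 99,016 whose
components (84,838 + 152 × 92.87 = 98,954.24) sum 61.76 short of it; the
override reproduces the stated figure while the component path remains
available. ROI is homogeneous of degree zero in money (tested).

**Survey bookkeeping.** `count_enactment_surveys` models the enactment
schedule — one survey per enacted role, every scenario re-enacted in
every layout on every day: with 4+2+3+4 roles, two layouts and three
days, 13 × 2 × 3 = 78 surveys.

## Fixtures and problem sizes

The bundled layouts are 9 × 7 m rooms whose dimensions are illustrative
(no floor-plan measurements exist to reproduce); what matters is the
topology: the existing layout's dispensing cabinet is a central island
between preparation counters and supplies, the sharps container is far
from preparation, and patient bins are split; the proposed layout moves
the cabinet to a wall, puts sharps within arm's reach of preparation and
consolidates the bins. The recovery fixture is a 10 × 8 m room with a
shelving divider forming a short southern corridor (blockable by a cart)
and a long northern one, so planted detours are large and unambiguous
(ratio ≈ 2.2, excess ≈ 8.8 m).

Tests and the acceptance script use scenario enactments of 40–90
simulated seconds at 10 Hz with 2–4 agents, 10–20 seeded replicates per
property, and 12–50 random instances for the path oracle — sizes chosen
so the full suite completes in well under a minute while every property
is exercised end to end.

## Known limitations

* Interruptions require an annotation channel; logs without one yield
  zero interruptions, not an estimate.
* Visit zones for movable objects use the parked pose.
* Bump intent is inferred from the visit/leg structure only; a contact
  with equipment the subject was *about* to use is always treated as
  intended.
* The impediment attribution rule names one intruder per leg (the first
  found); simultaneous multi-cause detours are attributed to a single
  entity.
* Surveys are summarized and tested at the item level; no multiple-
  comparison correction is applied across items, matching reporting
  practice in mock-up evaluation studies.
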