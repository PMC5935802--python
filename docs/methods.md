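# Methods

## Model and assumptions

The localization problem is posed as discrete Bayesian filtering on a graph
whose nodes are *grouped areas* — a room, a social area, a corridor
section, or the stairway — rather than raw beacons: long corridors and
large social areas carry several beacons that all identify the same
behavioral context, so beacons sharing an area label collapse onto one
state at graph-construction time, and per-beacon RSSI is aggregated to area
level (maximum mapped probability; summing would overweight multi-beacon
areas). The adjacency matrix has a unit diagonal: motion model 1 sets
`M = A` and the step-modulated models assign self-transition weights, so
staying put must be representable.

The filter assumes (i) the wearer occupies exactly one area per 10-s
epoch, (ii) at most one pathway hop per epoch, and (iii) RSSI is
informative only through the clipped linear proximity map. Assumption (ii)
is the graph constraint that gives the method its robustness, and also its
characteristic failure mode: any transition faster than the sampling
interval produces unavoidable transition-epoch error, which is why
evaluation separates transition from nontransition time.

The state recursion `X_k = norm(norm(X_{k-1}·M_k) ⊙ Y_k)` starts from a
uniform `X_0` and applies the motion prediction at every epoch, including
the first. `norm()` on an all-zero vector is undefined by design; every
such occurrence must route through exception management (asserted in
tests).

### Exception rules

1. **Degenerate posterior** (readings present, posterior product zero): the
   probability vector is resampled to uniform and the *reported* area is
   held at the previous epoch's value. Both clauses are implemented
   literally: the full vector resets, the report holds.
2. **No measurement** (`c = 0`): state and report carry forward unchanged;
   no prediction is applied, so a dropout gap does not diffuse the
   posterior.
3. **Anti-hopping**: the reported area switches only when the new area has
   persisted ≥ 2 consecutive samples (`min_run = 2`, i.e. 20 s), and then
   retroactively from the first sample of the stable run. This is
   implemented as a run-length pass over the raw MAP sequence, equivalent
   to an online filter with a one-epoch lookahead; the pipeline processes
   recorded epochs in batch, so the delay is harmless. The posterior itself
   is never modified by rule 3. Ties in the MAP argmax break to the lowest
   area index (stable and documented).

### Measurement map

The proximity map is the clipped linear ramp `y = (rssi + 90)/45` on
[−90, −45] dBm: 1 within ~1 m of a beacon, 0 where communication stops,
monotone in between. It is deliberately crude — indoor RSSI-distance
fingerprinting is brittle under reflection and scattering, and the filter
only needs a monotone contrast, not calibrated distances. The map is a
pluggable argument of `build_measurement` so alternatives (e.g. log-distance
inversion) can be swapped without touching the filter.

### Motion-model details

`step_threshold = 2` steps/epoch separates "likely stationary" from "likely
moving"; the dwelling diagonal is 2.0 and the moving diagonal 0.5. The rule
is implemented numerically as printed in its source convention (≤ 2 steps →
2.0 on the diagonal, i.e. low step counts favor *staying*); the
accompanying prose rationale is self-contradictory on the direction, and
the numeric rule is the one that makes behavioral sense and is used here.
In model 3 the constant-`w` branch covers **corridors only**: the stated
rationale (transition likelihood decoupled from steps because corridors are
long, walked-through spaces) does not apply to the stairway, which is
occupied briefly and deliberately like a room, so stairs rows remain
step-modulated. Epochs with a missing step record count as 0 steps
(conservative "likely stationary") with a logged warning.

Multiple receivers are filtered independently; an optional post-hoc
majority vote per epoch (`majority_vote`) is provided for studies that
overlay several wrist units, since no principled fusion is defined for the
hardware.

## Activity metric

Magnitude → centered 5-sample moving SD → mean over nonoverlapping
1000-sample blocks (10 s at 100 Hz), trailing partial block dropped. Window
alignment and SD flavour are free choices; this package fixes **centered**
windows, **sample** SD (denominator n−1), and shrunken windows at the
series edges, and the per-window oracle test freezes those semantics. The
moving SD is computed two-pass per window, which is numerically
shift-invariant — a constant (gravity) offset cancels exactly rather than
amplifying round-off, matching the metric's stated purpose. The k-means
classifier (k = 3, 10 restarts, fixed seed) is fitted per recording;
clusters are relabelled by ascending center so the mapping metric → level
is monotone. Cross-recording calibration is out of scope.

## Evaluation

Transition periods are operationalized as ± 1 epoch around each
ground-truth area change: the 10-s sampling makes one epoch the natural
atom of transition ambiguity, and the window is a parameter
(`transition_window`). Misclassification is counted on the smoothed
(anti-hopped) output, which is the algorithm's reported estimate. Relative
errors follow `e_t = 100·ê_t/T_t`, `e_nt = 100·ê_nt/T_nt`,
`ē = 100·ê_t/T_l` (the transition-caused share of the whole trial) and
`e = 100·(ê_t+ê_nt)/T_l`; zero-duration denominators leave a quantity NaN,
never 0. Trial averages are arithmetic means of the relative quantities.

Dwelling-time agreement is scored **per visit** (continuous occupancy
bout): each ground-truth visit pairs its duration with the time the
algorithm spent in that area during the visit's span. The OLS fit and its
SSE/R²/adjusted-R²/RMSE are the regression goodness of fit (RMSE is the
standard error of the regression, `sqrt(SSE/df_resid)`); the ICC is the
two-way mixed absolute-agreement single-rater coefficient, computed
directly from the ANOVA mean squares (McGraw–Wong ICC(A,1)) so that perfect
agreement yields exactly 1; the implementation is cross-checked against
`pingouin` in the tests. An optional stratification splits visits at 100 s,
the dwell length above which quantization error falls below 10%. Confusion
matrices are time-weighted and row-normalized by true-area time, in an
all-epochs and a nontransition-only variant.

## Simulator design

The simulator abstracts geometry to walking distances along graph edges —
the filter never consumes coordinates, so a full floorplan would add
nothing. Travel between stops follows the distance-shortest path; each
edge's travel time is split half-and-half between its endpoint areas, and
the ground-truth area of an epoch is the area occupied at the epoch's
midpoint.

The RSSI channel is the standard indoor log-distance model:
`rssi = −45 − 10·2.5·log10(d) + N(0, 4²)` dBm with d in metres (1 m within
the serving area), readings below −90 dBm dropped, a 2% per-epoch chance of
a +15 dB glitch on a non-adjacent beacon (reflection artifact), and a 5%
per-epoch dropout of all readings. Beacons on the other floor are
suppressed entirely, reflecting the observation that cross-floor confusion
does not occur in practice; the stairway beacon serves both floors. All
channel parameters are exposed in `RssiModel`.

The packaged example building mirrors the reference deployment's topology:
17 beacons grouped into 14 areas over two floors (5 single-beacon rooms,
2 two-beacon social areas, 6 corridor sections of which one long corridor
carries two beacons, and a stairway beacon shared by both floors). Edge
distances are 22–30 m, the beacon density the placement rules produce (one
beacon per straight corridor passage, another at each direction change).
This spacing also means every area takes at least one epoch to traverse at
the fastest prescribed pace — the regime the graph constraint presupposes;
with beacons packed much closer than ~20 m a walker can cross two pathway
hops within one sample, and no one-hop-per-epoch filter can follow.

Step counts follow a cadence model `2.0·√(v/1.4)` steps/s (≈ 20
steps/epoch at normal pace; always > 2 while moving, 0–2 while dwelling).
Acceleration is a 1 g baseline plus, in moving epochs, a cadence-frequency
oscillation with amplitude `0.08·v` g — doubled on stairs, where gait is
jerkiest — plus white noise. The generator reproduces the features the
pipeline consumes (epoch-scale RSSI contrast, step thresholding, jerk-level
separation); it does **not** emulate multipath fading statistics, body
shadowing, device clock drift, or individual gait variability, so passing
tests demonstrate algorithmic correctness under the stated channel
assumptions, not field performance in an arbitrary building.

All generators are driven by `numpy` `SeedSequence` children of one seed;
regeneration with the same seed is bit-identical.

## Problem sizes and defaults

Simulation-based tests use the packaged building (N = 14) with the trial
presets: ~150–190 epochs per trial, 20 seeds for noisy-channel averages,
and the five-point corridor-weight grid. The filter is O(T·N²) and runs a
trial in milliseconds, so these sizes give stable averages while keeping
the whole suite fast. Defaults throughout: 10-s epochs, −45/−90 dBm
anchors, `w = 1.0`, `min_run = 2`, `transition_window = 1`.

## Known limitations

* Transition-epoch error is irreducible at 0.1 Hz sampling and dominates
  every error budget; the package reports it separately rather than hiding
  it in an overall figure.
* The measurement map, channel model and cadence model are deliberately
  simple; none is calibrated to a particular building or device.
* Receiver fusion is a bare majority vote; a probabilistic multi-receiver
  update is future work.
* Dwelling-time agreement needs ≥ 3 visit pairs and nonzero variance;
  degenerate inputs yield NaN statistics by design.
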