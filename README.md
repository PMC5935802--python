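# beaconloc

Room-level indoor localization for wearable movement-behavior research:
graph-constrained Bayesian filtering of BLE-beacon RSSI fused with
accelerometer-derived step counts, plus per-epoch activity-level
classification and full evaluation machinery.

Behavioral scientists measuring physical activity with wrist-worn
accelerometers usually know *what* and *when*, but not *where*. When the
same device also logs received signal strength (RSSI) from Bluetooth
low-energy beacons placed around a building, the "where" becomes
recoverable — but raw RSSI is noisy (reflection, scattering, 0.1 Hz
sampling), so per-epoch nearest-beacon guessing is unreliable. `beaconloc`
implements the algorithm that turns those streams into a robust per-epoch
room estimate, and pairs it with a jerk-based activity level so that time,
place and intensity of behavior come from a single sensor.

## The model

The building is a graph of grouped areas with walking-pathway adjacency
matrix *A* (unit diagonal, `a_ij = 1` iff a pathway joins areas *i* and
*j*). The wearer's state is a probability vector over areas, updated each
10-s epoch *k* by a discrete Bayes filter

```
X̃_k = norm(X_{k-1} · M_k)          (a priori motion model)
X_k  = norm(X̃_k ⊙ Y_k)             (state update)
```

where `Y_k` is the per-area measurement vector obtained by mapping each
beacon's RSSI to a proximity probability (1 at ≥ −45 dBm, 0 below −90 dBm,
linear between) and normalizing, and `M_k` is one of three motion models:

* **model 1** `M = A` — constant connection weights;
* **model 2** — diagonal `m_ii = 0.5` when the device counted > 2 steps in
  the epoch, `2.0` otherwise (step counts modulate the probability of
  staying put);
* **model 3** — as model 2 for rooms, social areas and stairs, but corridor
  diagonals carry a constant weight *w* (corridors are always walked
  through, so steps say little there); *w* is conventionally swept over
  0.25–1.25.

Three exception rules harden the recursion: a contradictory measurement
(nonzero readings but an all-zero posterior product) resamples the state to
uniform while holding the reported area; an epoch with no readings carries
everything forward; and an area change is only reported once the new area
has persisted for ≥ 2 samples (20 s), suppressing single-epoch hops.

Per-epoch activity is the mean over 10-s blocks of the 5-sample moving SD
of the acceleration magnitude at 100 Hz — a gravity-invariant,
jerk-proportional metric — classified into low/middle/high by 3-means.

Evaluation decomposes misclassified time into *transition* epochs (± 1
epoch around each true area change, where the 10-s sampling makes error
unavoidable) and *nontransition* (dwelling) epochs:
`e_t = 100·ê_t/T_t`, `e_nt = 100·ê_nt/T_nt`, `ē = 100·ê_t/T_l`,
`e = 100·(ê_t+ê_nt)/T_l`, plus per-visit dwelling-time agreement (OLS fit
`y = p₁x + p₂`, two-way mixed absolute-agreement ICC, SSE/R²/RMSE) and
time-weighted confusion matrices.

Because no recorded trials are distributed, the package ships a simulator
(`beaconloc.simulate`) that generates complete trials — ground-truth walks
over the packaged two-floor, 17-beacon, 14-area example building, RSSI from
a log-distance path-loss channel with shadowing/glitches/dropout, step
counts and raw 100 Hz acceleration — at the standard trial presets (normal
1.4 m/s / slow 0.9 m/s / fast 2.0 m/s paces with 3/2/1-min dwells, plus an
unprescribed random trial).

## Worked example

```bash
python examples/02_simulate_and_localize.py
```

```
simulated 184 epochs (1840 s), 1178 RSSI readings
filter ran; exception rules fired on 12 epochs
nontransition error e_nt = 0.00%  (misclassified dwelling time; low = reliable room-level tracking)
transition error    e_t  = 10.20%  (errors while moving between areas; dominated by the 10-s sampling)
overall error       e    = 2.72%
```

A normal-pace trial under the default noisy channel is tracked essentially
perfectly while dwelling; the residual error is concentrated in transition
epochs, where a 10-s proximity sample can legitimately straddle two areas.
Dwelling-time agreement on the unprescribed trial
(`examples/04_evaluate_agreement.py`):

```
all              n= 35  slope=1.010  intercept=-1.6 s  R2=0.9934  ICC=0.9965  RMSE=4.7 s
under_threshold  n= 31  slope=1.028  intercept=-2.1 s  R2=0.9465  ICC=0.9704  RMSE=5.0 s
over_threshold   n=  4  slope=1.000  intercept=-0.0 s  R2=1.0000  ICC=1.0000  RMSE=0.0 s
```

Visits longer than 100 s are recovered exactly; short visits carry the
quantization error. The other examples build the map (`01`), classify
activity levels (`03`) and sweep the corridor weight (`05`).

The same pipeline is available as a CLI:

```bash
beaconloc simulate --map src/beaconloc/data/example_map.yaml --trial 1 --seed 7 --out-dir /tmp/t1
beaconloc localize --map src/beaconloc/data/example_map.yaml --model model3 --w 1.0 \
    --rssi /tmp/t1/rssi.csv --steps /tmp/t1/steps.csv --out /tmp/t1/trace.csv
beaconloc classify-activity --accel /tmp/t1/accel.csv --out /tmp/t1/activity.csv
beaconloc evaluate --trace /tmp/t1/trace.csv --truth /tmp/t1/truth.csv --out /tmp/t1/report.json
beaconloc plot --kind lasagna --trace /tmp/t1/trace.csv --activity /tmp/t1/activity.csv \
    --out /tmp/t1/lasagna.png
```

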