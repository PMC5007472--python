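# Methods

## The measurement being modelled

A perfused microfluidic chamber keeps cells in a monolayer under constant
medium flow carrying 0.1 µM propidium iodide (PI) plus a counterstain —
calcein-AM (CAL; violet in corynebacteria, green in yeast) or PO-PRO-1.
Time-lapse imaging at a fixed frame interval (8 min for *C. glutamicum*,
5 min for *E. coli*/*B. subtilis*/*V. harveyi*, 30 min for *S. cerevisiae*,
60 min for *M. luteus*; `preset_acquisition`) produces one mean-fluorescence
value per cell, channel and frame, in arbitrary units (AU), plus a cell-size
proxy. All analysis operates on these per-cell trajectories; image
segmentation and particle tracking are upstream of this package and out of
scope. External tracking output plugs in through the trace CSV schema.

## Kinetic model

Dye content of one cell in one channel is modelled with three closed forms
(`vitrace.kinetics`):

* uptake to a plateau, `B + A(1 − e^{−k_in(t−t0)})` — PI entering a
  membrane-compromised cell, calcein accumulating after AM-ester conversion,
  PO-PRO-1 after membrane-potential loss;
* the Bateman (one-compartment absorption/elimination) curve,
  `B + A·k_in/(k_in−k_out)·(e^{−k_out τ} − e^{−k_in τ})`, with the analytic
  limit `B + A k_in τ e^{−k_in τ}` as `k_out → k_in` — dead cells whose PI
  signal slowly declines (DNA decay / fractional DNA loss);
* first-order decay `B + A e^{−k_out(t−t0)}` — ghost-cell collapse after
  lysis and post-recovery PO-PRO-1 loss.

Curves return exactly `B` before `t0` (strict causality). Photobleaching is a
separate multiplicative channel: each imaging exposure retains a fraction
`b ∈ (0,1]` of the current pool, so a noiseless plateau decays geometrically
with frame number. `b` is parameterized by cumulative loss over the movie
(`BleachModel.from_cumulative_loss`); the default simulator draw corresponds
to 1–3% total loss, the magnitude reported for this assay class.

## The simulator

`simulate_population` realizes a population of *fate programs*: per-cell
event times (arrest, PO-PRO-1/PI onsets, lysis, recovery, divisions) plus
per-channel kinetic parameters, which double as ground truth for evaluation.
The generated phenotypes and their defaults:

| label | events | channels |
|---|---|---|
| GROWING | divisions every ~doubling time (default 60 min) | PI, CAL |
| ARRESTED_VIABLE | arrest at ~5–15% of the movie; calcein moderate | PI, CAL |
| TOLERANT | arrest + calcein accumulation to 2.5× the growing mean | PI, CAL |
| DEAD | PI uptake to a 1000–1500 AU plateau (30% with slow Bateman decline); calcein lost | PI, CAL |
| LYSED_DIRECT | all channels collapse fast (≥2.5 e-folds/frame) without prior PI | PI, CAL |
| DEAD_THEN_LYSED | PI plateau, then collapse ≥6 frames later | PI, CAL |
| SEGMENTED_BIPOLAR | two pole traces sharing the arrest time: one DEAD, one TOLERANT | PI, CAL |
| NECROTIC_LIKE | PO-PRO-1 and PI onsets on the same frame | PI, POPRO |
| APOPTOTIC_LIKE | PO-PRO-1 leads PI by 4–14 frames | PI, POPRO |
| RESUSCITATED | PO-PRO-1 plateau, slow loss (≤0.7 e-folds/frame) from recovery, division afterwards | PI, POPRO |

Key modelling choices:

* **Rates scale with the frame interval.** Uptake/decay rates are drawn per
  frame interval (e.g. uptake 0.5–1.2 e-folds per frame), so the classifier
  sees comparable per-frame dynamics across the 5–60 min presets. Lysis decay
  is drawn fast (≥2.5/frame) and recovery decay slow (≤0.7/frame): rapid
  all-channel loss is the defining ghost-cell feature, while recovery is a
  gradual fading.
* **Content recursion.** Per frame, `F_n = b·F_{n−1} + Δc_n` (influx from the
  kinetic curve, bleaching per exposure); programmed decay multiplies the
  whole pool, inherited dye included. With `b = 1` and zero noise the series
  telescopes to the closed-form curve exactly — the generative-identity tests
  rely on this.
* **Division and dilution.** A division at frame *f* hands the daughter a
  fraction `partition` (default 0.5) of the mother's current content and half
  her size; mother+daughter totals are conserved exactly at *f*. Calcein, fed
  by continuous AM-ester perfusion, then refills toward the cell's steady
  state at the conversion rate (and a daughter's inherited surplus drains the
  same way); PI and PO-PRO-1 are one-shot dyes and stay diluted — the
  "dilution across filial generations" observable. Lineages are capped
  (default 8 cells per ancestor) to keep 16-h benchmarks at desk scale;
  growth-rate analyses use short windows below the cap.
* **Spontaneous death** converts growing cells (hazard per frame, geometric
  waiting time) to a sudden simultaneous-onset death, keeping the cell's
  channel set: with PO-PRO-1 recorded the truth label is NECROTIC_LIKE,
  otherwise DEAD.
* **Noise.** Observation = background (default 100 AU) + content, times a
  multiplicative illumination term (CV 2%), plus additive read noise
  (SD 5 AU), clipped at zero; size noise CV 1%. Seeds flow through
  per-cell `numpy.random.SeedSequence` children of the single run seed, so
  trace tables are bit-identical across runs.

What the generator does **not** emulate: spatial information (sub-pole
fluorescence patches, e.g. ERC-like spots near the membrane), chamber
crowding and focus drift, media-switch transients, segmentation/tracking
errors, and non-exponential growth. Passing benchmarks therefore demonstrate
that the decision rules are implemented correctly and are robust to
photometric noise, bleaching and dye dilution — not that they are robust to
tracking artifacts in real images.

## Classification rules

All rules operate on background-subtracted values; the population background
per channel is the median first-frame value of ancestor traces (no dye has
accumulated at acquisition start). This makes every call invariant under a
constant offset applied to background and values.

**Channel positivity** (`call_channel`): positive from the earliest frame
with either
(a) a jump `Δ > max(5σ̂, 50 AU)` between consecutive frames (σ̂ is 1.4826 ×
median |successive difference| / √2, re-estimated on the pre-onset segment
once an onset is found), or
(b) ≥3 consecutive frames above `basal + max(0.05·basal, 25 AU)` with an
increasing Mann–Kendall trend (S ≥ ⌈0.8·w(w−1)/2⌉ over a 5-frame window) and
a downstream equilibrium (5-frame window with relative range ≤2% at or above
the rise threshold). A series already elevated at track start (>max(10σ̂,
150 AU)) is positive from frame 0 — cells stained before observation begins,
e.g. pre-culture deaths present at seeding. The 50/25 AU floors guard the
zero-noise and zero-basal limits where purely relative rules degenerate; on a
subtracted series the basal is near zero, so the absolute floor is the
operative rise threshold. Raising `rel_rise` can only delay or remove onsets
(monotonicity is exercised in the tests).

**Calcein level** (`call_cal_level`): the trailing 5-frame mean against the
median of co-cultivated growing reference cells; ≥2.0× is CAL⁺⁺ ("high"),
at background is negative, otherwise CAL⁺. With no reference available the
call falls back to an absolute threshold (400 AU) and warns.

**Lysis** (`detect_lysis`): earliest frame from which *every* recorded
channel stays within the background envelope (3× noise SD, floor 10 AU) for
≥2 frames, provided (i) some channel was previously clearly stained (>2× the
envelope) and (ii) the loss was abrupt — a stained channel still held ≥50% of
its recent peak (last 10 frames) within the 3 frames before the collapse. The
recent-peak window keeps dye partitioned to daughters from masking a
genuine collapse; the abruptness guard separates ghost cells from gradual
recovery-like fading and from bleaching.

**Fate state machine** (`classify_fate`), evaluated in precedence order:

1. lysis without prior PI onset → LYSED_DIRECT;
2. PI onset, then lysis → DEAD_THEN_LYSED;
3. PI and PO-PRO-1 onsets with lag ≥ `apoptosis_lag_frames` (default 2) →
   APOPTOTIC_LIKE;
4. PI onset with simultaneous/absent PO-PRO-1 → NECROTIC_LIKE, reported as
   DEAD when no PO-PRO-1 channel was recorded (PI-only experiments cannot
   distinguish the two);
5. PO-PRO-1 onset, no PI, signal falling below 50% of its peak beyond the
   bleaching extrapolation, and a later division → RESUSCITATED;
6. arrested with calcein high → TOLERANT;
7. arrested otherwise → ARRESTED_VIABLE (PI-only runs collapse TOLERANT into
   this state);
8. otherwise GROWING.

A two-frame apoptosis lag is the smallest unambiguous separation from
"sudden" double-positivity occurring within one imaging interval. Slow
Bateman-like PI decline stays DEAD (rule 2 requires the all-channel
background test). "Arrested" means the trailing-window log-size slope falls
below 10% of the population reference rate (the 0.8 quantile of per-cell
rates, floored at 1e-3/min) *and* the cell never divided; an observed
division is growth evidence regardless of the saw-toothed size slope of a
dividing mother. Each call carries a state sequence
(ALIVE/MORIBUND/DEAD/LYSED) restricted to the allowed transition graph
(moribund may return to alive — resuscitation; dead may only proceed to
lysed). Pole pairs are merged per cell: discordant dead-class vs viable-class
poles give SEGMENTED_BIPOLAR.

With cumulative bleaching at the 1–3% level, a 50% drop always exceeds the
bleaching envelope, so the default extrapolation factor in rule 5 is 1; the
hook accepts an estimated retention `b̂` for deeper-bleaching regimes.

## Population summaries

Per frame, over the cells present (born at or before the frame; ghosts remain
present): counts and fractions of the four states (they partition to 1),
live fraction (ALIVE only — moribund frames are not live, so a resuscitated
cell contributes per its state sequence), and colony mean ± SD per channel
over cells present at that frame (no carry-forward). Experiment-level:
final-label fractions at the last frame, PI⁺ frequency (cells whose state is
DEAD) at seeding (ancestors only, by construction) and at the end, and the
population growth rate as the log-linear slope of total live biomass,
reported normalized to an untreated reference. Evaluation against ground
truth is a per-cell confusion matrix with accuracy, per-class recall and
precision.

## Default benchmark and scenario sizes

The mixed benchmark uses 500 ancestors (~1500 cells after lineage growth) on
the 8-min/120-frame grid, composition 20% growing, 10% arrested, 10%
tolerant, 12% dead, 8% each of the remaining six classes, default noise and
1–3% bleaching — sizes chosen so that every class contributes tens of cells
and the whole run stays in seconds. The lytic-induction scenario seeds 24
ancestors (5% stained pre-culture deaths), divides until induction at frame
31 (5-min frames), then converts cells to lysis except 1.4% incidental
non-lytic deaths and 1.5% non-replicating PI⁻ resistant cells; its live
fraction rises toward 1 and peaks at the induction frame. The
spontaneous-death run uses 200 non-dividing ancestors at hazard 1e-3/frame
for 100 frames (expected ever-dead fraction 1 − 0.999⁹⁹ ≈ 9.4%).

## Numerical choices

* Curve fits (`fit_rise`) use bounded trust-region least squares with
  feature-based initialization; the onset is feature-detected and refined
  only within ±2 frames, rates are capped at 50 e-folds per frame interval
  (faster rates are unidentifiable step functions at the sampling rate), the
  Bateman fit multi-starts over three uptake-rate guesses and enforces
  `k_in ≥ k_out` by symmetry, and the half-rise interval used to seed the
  rate is floored at half a frame. Non-convergence is flagged in the result,
  never silent.
* The Bateman implementation switches to the degenerate limit form at a
  relative rate difference of 1e-12; the analytic branch is accurate to
  better than 1e-6 relative down to differences of 1e-8.
* The bleaching estimator pools per-segment demeaned log-values (fixed
  per-segment intercepts, common slope) — exact on noiseless geometric decay.
* Ties between jump and sustained-rise evidence at different frames go to the
  earlier frame; on the same frame the jump is reported.
* Trace CSVs are read with round-trip float parsing so write→read is
  bit-exact; all tables are plain UTF-8 with '.' decimals and empty-string
  NA.

## Known limitations

Compartments are whole cells or two poles — sub-compartment localization
(patches) is not representable in the trace contract. The classifier is
deliberately rule-based and deterministic; no probabilistic calibration of
the calls is attempted. Cells classified from very short tracks (<4 frames,
e.g. daughters born at the movie edge) default to GROWING when nothing is
positive. The growth-arrest test needs either a usable size series or lineage
information; with neither, arrest-based states are unreachable. Fate
fractions are reported at the final frame (cells that died *and* lysed count
as lysed, not dead).
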