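# Methods

## Overview

`dareservoir` implements a driven/autonomous (D/A) construction for
recurrent spiking reservoirs, together with a microsaccade-style video
spike encoder and a five-model ensemble classifier, aimed at recognizing
actions from very few labelled clips.

The pipeline, in the order the method runs:

1. **Encoding.** Consecutive grayscale frames are differenced, thresholded
   at the ladder ε ∈ {1, 2, 4, 8, 16, 32}, fused into a weighted spike map
   WSpike = Σ ε_i [P_diff ≥ ε_i] / Σ ε_i, and binarized.  Per spike frame a
   41×41 bounding box at the activity center of gravity (C) and four copies
   shifted ±10 px (R, L, T, B) emulate a fixed microsaccade sequence.
   Whole frames with active fraction outside [8 %, 75 %] are deleted
   (flash/jitter filter), and a directional window is deleted when its
   activity departs from the center window by more than the mean center
   activity.
2. **Driven network.** A reservoir of N leaky integrate-and-fire neurons
   with sparse random fast connections J_fast receives a filtered copy of
   its own target, f_D = f_out + τ_fast · df_out/dt, with τ_fast
   apportioned across the X input channels (Σ_k τ^k = τ_fast).  A linear
   rate readout w is trained by recursive least squares (RLS) on the fast
   synaptic traces so that w·f(t) ≈ f_out(t).
3. **Autonomous networks.** Each autonomous model imports J_fast, sets
   u = u_D·u_R, draws B ~ Uniform[0, b_max]^(X×Y) and adds slow recurrent
   connections J_slow = u_D B w (rank ≤ Y).  Its spiking readout w′ learns
   by supervised STDP, Δw′ = η·x_trace·(target(t) − actual(t)), against
   one-hot periodic spike targets.
4. **Ensemble.** One driven network begets five autonomous models (one per
   scan); a test clip is classified by the majority vote of the five
   models' most-active readout neurons, ties resolved by summed spike
   counts and then lowest class index.

## Units, time step, and neuron model

All times are in milliseconds, potentials in millivolts, and dt = 1 ms, so
one encoded spike frame maps to one simulation step and a 300-step trial is
300 ms.  LIF constants: τ_mem = 20 ms, V_rest = V_reset = −70 mV,
V_th = −50 mV, absolute refractory 5 ms.  Integration is exponential-Euler
(exact for piecewise-constant current), with forward Euler behind a flag.
Refractory clocks run down before integration, so a neuron that fired at
step t can fire again at step t + t_ref.  The membrane has a reflecting
floor at V_reset: net-inhibitory fluctuations cannot hyperpolarize below
the reset value, keeping V within [V_reset, V_th) at every recorded step.

Synaptic activity is carried by per-neuron traces that decay exponentially
(τ_fast = 5 ms, τ_slow = 100 ms) and jump by 1 on each spike.  Binary spike
input enters through its fast trace; the driven drive f_D enters as a
continuous current.

## Weight scales at millivolt granularity

The recurrent weight standard deviation is g/√(pN).  The classic rate-unit
choice g ≈ 1.5 produces recurrent currents of well under a millivolt in
this voltage-explicit model — dynamically inert against the 20 mV distance
from rest to threshold.  We therefore default to g = 50 (ensemble
experiments) so that a handful of presynaptic spikes move a neuron a
sizeable fraction of the threshold distance, and g = 300 in the two-input
reconstruction demo, where only two input channels are available and the
reservoir must sustain its own irregular activity.  Input weights u_D are
N(0, 1/X); because a binary scan frame activates only a few hundred of the
1681 pixels, the autonomous input gain u_R (a scalar) defaults to 100 in
the video configuration rather than the nominal 1 — with u_R = 1 the
reservoir would be silent.  These scales were chosen so that reservoir
firing sits in the tens of Hz during stimulation; they are all exposed in
`ExperimentConfig`.

## One-hot targets

Each class target is a raised-cosine rate bump (amplitude 30, i.e. tens of
mV of drive) spanning steps [30, 270) of the 300-step trial, plus a
periodic spike target of period 6 ms in the same window.  The period
deliberately equals t_ref + dt: a readout neuron driven strongly above
threshold then reproduces the target grid exactly, with the refractory
period acting as the clock.  The long window leaves only 60 steps in which
spurious spikes must be suppressed and makes the van Rossum comparison
well-conditioned.  Shape, placement, amplitude and period are configurable
(`BumpSpec`).

## Learning rules

**RLS (driven readout).**  Standard recursive least squares with
P₀ = I/α and no forgetting; one update per time step on the fast-trace
basis.  After a single pass this is exactly the ridge solution with
penalty α.  The demo uses α = 1.  The ensemble configuration uses a large
ridge (α = 10⁵ by default): with ~13 000 RLS samples per training run the
ridge must be of the order of the accumulated trace energy to have any
shrinking effect, and shrinking w is the package's means of controlling
the gain of the slow feedback loop J_slow = u_D B w (below).

**Supervised STDP (autonomous readout).**  Δw′ = η·x_trace·(target −
actual) applied per time step; x_trace is the presynaptic (reservoir)
trace with τ_pre of the order of τ_fast (default 3 ms; the sharper trace
strengthens the one-step phase-correction signal).  η defaults to 0.05
with per-epoch decay 0.95 in the classifier and to 3.0 with decay 0.9 in
the reconstruction demo, where the readout must reach strongly
suprathreshold currents within 30 epochs.  Within an epoch, patterns are
presented in cyclic class order (Class1→Class2→Class3→Class1→…); block
presentation (all patterns of a class back to back) is available but
suffers severe last-class interference when several examples per class are
trained, and is not the default.

## The slow-loop gain and what B does

J_slow = u_D B w is a rank-Y product, so it has at most Y nonzero
eigenvalues, and scaling b_max scales its spectrum linearly — the spectral
radius and the number of Re(EV) > 1 modes grow with b_max, which the
diagnostics in `dynamics` verify.  Dynamically the loop feeds the Y-dim
projection w·s of the slow traces back into the reservoir through u_D B.
Three regimes matter:

- **dead** (b_max → 0, or w strongly shrunk): activity collapses within
  τ_fast once input ends;
- **marginal**: post-stimulus activity decays over ~τ_slow, during which
  it remains stimulus-specific, because s(t) is literally a low-passed
  record of the stimulus-driven spiking;
- **saturated**: the loop sustains a high-rate attractor indefinitely, but
  the attractor is near-stimulus-independent — the reservoir's "memory" is
  rank-limited to the Y numbers w·s, and once self-sustained firing
  overwrites s the class information is gone.

The default classifier runs with the loop effectively dead (large α):
with 120-frame clips and a readout window overlapping the stimulus, input-
driven traces carry all class information and any stronger loop only adds
common-mode activity that degrades discrimination.  The memory-contrast
experiment (`b_contrast_experiment`) instead uses short (60-frame) clips,
a readout window placed entirely after the stimulus, and a marginal loop
(α = 10³): there, b_max = 0.005 yields chance accuracy (the window is
silent) while b_max = 0.15 sustains stimulus-specific activity into the
window and classifies well above chance.  This isolates the memory role of
the slow synapses.

## Synthetic clips

`synth` renders short grayscale clips of a single textured square moving
over a uniform background.  Design choices that matter:

- **Fine-grained texture.**  A rigidly translating textured patch changes
  almost every interior pixel by a random amount each frame, the way a
  real articulated subject fills its silhouette with motion energy.  This
  is what keeps the encoded active-pixel fraction above the codec's 8 %
  whole-frame minimum — a solid object's thin leading edge alone would be
  deleted wholesale by that filter.
- **Object ≈ half the frame side** (44 px in an 80×80 frame): footprint
  large enough for the 8 % floor, edges within reach of the 41×41 fixation
  windows.
- **Moderate texture contrast** (±10 grey levels) so the always-spiking
  leading edge stands out against the ~30 % interior churn.
- **Class signatures**: horizontal oscillation (fast, ~13-frame period),
  vertical bounce (slow, ~35), circular orbit (~21).  The speeds are
  spread so the rhythms do not coincide; within-class variation randomizes
  phase and scales size ±5 % and speed ±8 %.  Circular motion necessarily
  contains horizontal- and vertical-sweep episodes, so it is the
  structurally hardest class to separate.
- Nuisance knobs (camera jitter, clutter, pixel flips, textured
  background) default to off — the clean-background few-shot setting — and
  are exercised by dedicated tests.  Heavy jitter on a textured background
  trips the 75 % upper activity bound when the encoder is run in
  absolute-difference mode (with the default signed difference, at most
  ~half the pixels can brighten, so the upper bound is unreachable by
  camera shake alone).

What the generator does **not** emulate: articulated or deformable
subjects, photometric variation, occlusion, depth, camera pans with
parallax, or background motion that carries meaning.  Passing the few-shot
benchmark here shows that the pipeline extracts and discriminates clean
motion signatures under the paper-style filtering rules — not that it
reaches any particular accuracy on natural video.

## Reference experiment sizes

Chosen so the full suite runs on one CPU in minutes:

- Reconstruction demo: 2×400×1, RLS 15 epochs, STDP 30 epochs on a fixed
  Bernoulli(0.3) 2-channel spike input.
- Few-shot benchmark: 3 classes × (8 train + 20 test) 80×80 clips,
  N = 400, p = 0.10, five-scan ensemble, 15 + 5×30 training epochs.
- Memory contrast: 3 classes × (3 train + 5 test) 64×64 60-frame clips,
  N = 200, three independent dataset/network seeds per B value.
- Trajectory separation: 2 classes × (4 train + 3 test), N = 200,
  center-scan model, three seeds; rates by causal exponential smoothing
  (τ = 20 ms, unit-area kernel, spikes/s).

## Numerical details and edge cases

- Delay apportionment stores τ^k with the last part nudged so the floating
  sum equals τ_fast exactly; both equal and random (Dirichlet) splits.
  The alternative normalization that divides τ_fast by N instead of X is
  selectable (`apportion_over="reservoir"`).
- Target derivative by central finite differences (`np.gradient`).
- J_slow is stored dense for spectra but applied in factored form
  (u_D B)(w s) — O(NY) per step; the two differ only by rounding.
- Ties in the per-model argmax resolve to the lowest class index; ensemble
  ties by summed counts then lowest index.  Both are deterministic.
- Inference is deterministic, so the sd over repeated evaluation passes is
  0 unless the optional spike-deletion noise mode is enabled.
- State (membrane, refractory, fast/slow traces) is fully reset between
  patterns; keeping traces across patterns is available behind a flag.
- Empty spike frames put the fixation at the image center; windows are
  zero-padded at borders so the reservoir input is always 41×41.

## Known limitations

- The slow-loop memory is rank-limited to Y dimensions by construction
  (J_slow = u_D B w); post-stimulus class information decays within about
  one τ_slow and cannot survive loop saturation.
- Excitatory-only reservoirs synchronize readily; there is no inhibitory
  population to decorrelate activity.
- The supervised-STDP readout reproduces dense periodic spike targets via
  refractory locking; arbitrary precisely-timed spike patterns at
  millisecond precision are outside its reliable regime at these sizes.
- The encoder's signed difference responds to brightening edges only;
  absolute-difference mode is available but changes the activity
  statistics that the deletion thresholds assume.
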