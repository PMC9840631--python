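# Methods

`chemonav` re-implements, as a tested and reusable pipeline, the
quantitative analyses of a fluidics-based chemosensory assay for larval
zebrafish: laminar-flow characterization of the swimming arena,
navigation kinematics around a static chemical border, and
mutual-information statistics of brainwide calcium recordings under
lateralized nasal stimulation.  Raw video tracking, image registration
and ROI segmentation are upstream of this package; it consumes extracted
head coordinates, tail angles and ROI fluorescence matrices.  A
synthetic-data generator with known ground truth stands in for the raw
recordings so that every stage is testable end to end.

## Laminar-flow characterization (`chemonav.fluidics`)

The arena (60 × 30 × 1.5 mm) and the stimulus-delivery front channel
(0.54 × 0.5 mm) are treated as rectangular ducts with hydraulic diameter
`D_H = 2ab/(a+b)` and mean velocity `v = Q_total / (a·b)`.  The Reynolds
number `Re = ρ v D_H / μ` and Péclet number `Pe = v D_H / D` summarize
the transport regime: `Re << 2000` implies laminar flow, and `Pe >> 1`
negligible cross-stream diffusion, together predicting a static, sharp
chemical border.  All functions are SI-internal; the CLI converts from
mm and µL/min at the boundary.  Note one units subtlety in the source
protocol: the dynamic viscosity of water at 28 °C is quoted with
kinematic units, but its value (8.32 × 10⁻⁴) is the dynamic viscosity in
Pa·s, and the package treats it as such — this reproduces the printed
dimensionless numbers.

Border sharpness is quantified from intensity line profiles sampled along
border-normal vectors.  Each profile is affinely rescaled so its mean
over a configurable "outside" window is 0 and over an "inside" window
is 1 (the window bounds are free parameters because they are a
measurement choice, not a physical constant), and the transition width is
reported as the 10–90% rise distance of the pointwise-mean profile,
matching the 10–90% convention used for the temporal stimulus kinetics.
For a logistic border of scale `s` this width is `s·ln 81`, which the
tests use as a closed-form oracle.

## Navigation kinematics (`chemonav.behavior`)

Head trajectories `(x, y, θ)` arrive at 240 fps in arena-frame mm;
positive Δθ is a leftward (counter-clockwise) turn.  Swim bouts are
frames whose instantaneous angular velocity ≥ 1.2 °/ms **or** linear
velocity ≥ 12 µm/ms.  The thresholds are protocol constants; the
differentiation scheme is not, so the package states its choice
explicitly: central differences on boxcar-smoothed (3-frame ≈ 12.5 ms)
x, y and unwrapped θ, one-sided at the ends.  Active runs separated by
gaps < 50 ms are merged and runs shorter than 2 frames dropped — a
deterministic stand-in for the manual verification step of the original
protocol; both knobs are configurable.  Bout kinematics (signed net
Δθ, |Δθ|/Δt, displacement, peak linear velocity) are computed from the
run's endpoint states.  Raising either threshold cannot add active
frames, and on bout-structured swims (where each bout is one contiguous
active run) this means bout counts are monotone non-increasing in the
thresholds; for arbitrary signals a raised threshold could in principle
split a run into two runs separated by more than the merge gap, so the
monotonicity check is performed on simulated swims.

Border-crossing events use a 1-mm diffusion margin as hysteresis: entry
requires crossing `border + 1 mm` into the stimulus zone, escape
requires crossing back past `border − 1 mm`.  This makes dithering
within the ±1 mm band create no events, which is the intended meaning of
the margin.  Escape metrics (bout count, path length, escape time,
fraction of escapes within ≤ 2 bouts) retain proximity-flagged events;
turn statistics (first-bout turn angle and angular velocity, |Δθ| by
bout index, signed-direction tallies against the entry angle) exclude
events whose span overlaps frames where the larva is within 4 mm of a
wall or another larva, mirroring the original exclusion rule, which
applies to turn behaviors only.

Occupancy footprints sum per-frame dwell time into a pixel grid
normalized by larva count and assay duration; zone fractions are the
dwell-time proportions in the stimulus zone, mirror zone and remainder,
and Δ-mirror is their stimulus-minus-mirror difference.

The tail-flip helpers compute the angle between the body long axis and
the undirected waist→tail-tip line.  Because the line is undirected the
angle lives in [0°, 90°] (0° when the tip lies on the axis, 90° when
perpendicular).  Tail-flick events are contiguous runs of frames above a
configurable angle threshold (default 10°, no protocol value exists),
counted at 200 fps.

## Encoding statistics (`chemonav.mi`, `chemonav.encoding`)

dF/F drops the first 21 frames (10.5 s at 2 Hz, illumination-onset
transient) of each trial and takes the minimum of the next 9 frames as
the baseline `F`, returning `(F_t − F)/F` for all retained frames.
Stimulus-ROI traces are min-max normalized per side; the bilateral
profile is the renormalized mean of the two sides.  Motor output is the
proportion of 200-fps frames with active tail flipping per 0.5-s bin,
which aligns one-to-one with the 2-Hz imaging frames (partial trailing
bins dropped).

Mutual information is estimated with a product of Gaussian kernels, one
Silverman-rule bandwidth per variable (`0.9·min(sd, IQR/1.34)·n^{−1/5}`),
in bits.  Two evaluation strategies exist.  The default is leave-one-out
resubstitution: the expectation of `log2 p(x,y)/(p(x)p(y))` over the
sample itself with each point's own kernel removed; smoothing biases of
the joint and marginal terms largely cancel, and on the oracle suite
(bivariate Gaussians at ρ ∈ {0, 0.5, 0.9} with the closed form
`−½log2(1−ρ²)`, and 4-level quantized signals against the plug-in
discrete estimator) its error stays within ~0.06 bits at n = 2000.  The
alternative `grid` method integrates the same product-kernel densities
on a 64 × 64 lattice padded by 3 bandwidths with a 10⁻¹² density floor;
it is retained because it is the more literal plug-in integral, but its
smoothing bias reaches ~0.18 bits on strongly dependent data, so it is
not the default.  Both are exactly symmetric and invariant under affine
maps of either argument; estimates are floored at zero.  Per condition,
dF/F frames of all retained trials are concatenated in register with the
matching stimulus profile before a single MI evaluation (maximizing the
sample count at 2 Hz), giving `I_S` against the left, right and
bilateral profiles and `I_M` against motor output across all conditions.

Significance uses shuffled nulls: each ROI's concatenated dF/F is fully
permuted (one shuffle per ROI per condition by default; configurable),
the stimulus-side nulls pooled across the three conditions, and the
motor nulls kept separate.  An ROI is sensory-encoding when any `I_S`
exceeds 2.5× the pooled null maximum, motor-encoding when `I_M` exceeds
2.5× its null maximum; sensorimotor requires both above 1.25×;
sensory-only and motor-only add the complementary below-1.25×
constraint; a baseline-motor subclass applies the 2.5× rule to
null-stimulus trials alone.  Ipsilateral selectivity is
`I_ipsi/(I_ipsi + I_contra)` with the left/right→ipsi/contra mapping by
hemisphere; right selectivity is `I_r/(I_l + I_r)`, and a larva is
right-/left-biased when the mean right selectivity of non-OE sensory
ROIs leaves the [0.35, 0.65] band.  `I_N` divides `I_S` by the mean
`I_S` of the matching olfactory-bulb population (left OB for l-STIM,
right OB for r-STIM, all OB for b-STIM).

The fraction of nonlinear information is
`F_Is = (I_S_b − I_S_u_sum)/I_S_b`, where `I_S_u_sum` is the MI between
the bilateral profile and traces built by adding the trial-averaged
non-preferred-side response to each preferred-side trial (the preferred
side has the higher unilateral `I_S`; with unequal trial counts the
summed set inherits the preferred side's count).  Positive F_Is means
supralinear binasal summation, negative means saturating.

## Synthetic data (`chemonav.synthetic`)

The behavior generator produces bout-and-glide swims: exponential
inter-bout intervals at a position-dependent rate (baseline 1 Hz;
multiplied inside the chemical zone — klinokinesis), zero-mean normal
heading changes with position-dependent spread and a first-in-zone gain
(angular orthokinesis), a fast turn phase (50 ms) followed by a glide at
15 µm/ms for 200 ms, and reflective walls.  Turns are undirected by
default, matching the absence of directional bias in the real escape
data; a bias knob exists but is off.  The ground-truth bout log permits
oracle-path computation of every downstream behavioral metric.

The calcium generator follows the imaging protocol: 2-Hz frames, trials
of 30-s baseline, 10-s stimulus and 10-s post epoch (100 frames), four
trials per condition (within the 2–4 included for analysis in the
protocol), stimulus pulses with exponential 10–90% rise 0.9 s and
90–10% decay 1.6 s, and a GCaMP6f-like double-exponential kernel
(0.1 s rise, 1.6 s decay).  ROI drive is
`f(w_ipsi·C_ipsi + w_contra·C_contra)` with `f` linear, supralinear
(`u^γ`, γ = 2) or saturating (`tanh(βu)/tanh β`, β = 3), convolved with
the kernel; raw fluorescence is `F₀(1 + dF/F + noise)` with Gaussian
noise.  Tail-flick trains are Poisson (default 0.33 Hz, the observed
spontaneous rate) with 0.3-s active windows.

The default operating point — response amplitude 0.4 dF/F, raw-noise
s.d. 0.15 — was chosen once, on three grounds.  First, the 9-frame
minimum-baseline rule makes dF/F explode when raw noise s.d. exceeds
roughly 0.3 (the minimum of nine noisy frames approaches zero), so raw
noise must stay moderate.  Second, F_Is discriminates summation rules
only through signal-to-noise: with a near-plateau pulse profile the MI
saturates once per-frame SNR exceeds ≈ 1.5, so the summed-unilateral
trace (half the bilateral amplitude under γ = 2) must sit below that
ceiling for supralinearity to register.  Third, the trial-averaged
non-preferred summand carries a frozen noise template, repeated across
trials, which contributes spurious information to `I_S_u_sum`; its share
must stay small relative to `I_S_b` for the linear case to read ≈ 0.
The amplitude 0.3–0.5 × noise 0.15–0.2 region satisfies all three with
margin, and the medians are stable across seeds.  This tension is not an
artifact of the simulation: on real data too, F_Is is an SNR-mediated
statistic and the trial-averaged summand biases it toward negative
values at low SNR.

What the generators do **not** emulate: social interactions, rheotaxis
near inlets, tracker quantization (10° heading, 0.1 mm position),
slow drift or bleaching in fluorescence, correlated (shot/pixel) noise,
and hemodynamic-like artifacts.  Passing tests therefore demonstrate
the correctness and statistical behavior of the analysis rules under
the stated model, not robustness to every failure mode of real
recordings.

## Numerical choices and degenerate inputs

Zero-variance inputs to the MI estimator return 0 with a warning;
mismatched lengths and non-finite values raise.  Constant stimulus
traces on a required side raise a degenerate-profile error, as do border
profiles with no dynamic range between the window means.  A non-positive
dF/F baseline raises.  Crossing events are detected by a two-state
machine, so they are disjoint and strictly ordered by construction.
Occupancy fractions sum to one exactly.  All generators are
bit-reproducible given (config, seed); the orchestration layer demands a
seed for every stochastic stage and writes manifests without timestamps
so that identical configs produce byte-identical outputs.

## Problem sizes used in the test suite

Simulation sizes in the tests and the acceptance script are chosen as
the smallest cohorts at which the checked statistics are stable:
bivariate-Gaussian MI oracles at n = 2000; 500 null ROIs for the
false-positive rate; 50 ROIs per condition for selectivity and F_Is
recovery; behavioral cohorts of 6 larvae × 600 s (tens of crossing
events per cohort); 100 short random swims for the bout-detector oracle.

## Known limitations

* The KDE-MI estimator's absolute scale depends on the bandwidth rule;
  only comparisons made with the same settings are meaningful.
* `F_Is` inherits a small negative bias from the frozen-template effect
  of trial averaging (see above); interpret magnitudes near zero with
  care.
* The behavior simulator's kinematics are schematic (fixed bout
  duration and speed); it reproduces strategy orderings, not absolute
  escape magnitudes, and the package makes no claims about the latter.
* `mixed_population` reuses the first population's stimulus and tail
  data; concatenated populations should not mix motor-coupled configs
  beyond the first.
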