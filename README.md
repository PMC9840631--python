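# chemonav

Analysis pipeline for fluidics-based chemosensory assays in larval
zebrafish: laminar-flow characterization of the swimming arena,
swim-bout and border-crossing kinematics of chemical avoidance, and
mutual-information statistics of brainwide calcium recordings under
lateralized nasal stimulation.

It is written for experimenters who already have upstream outputs —
tracked head coordinates `(x, y, θ)` at 240 fps, tail angles at 200 fps,
and ROI × time fluorescence matrices at 2 Hz with atlas labels — and
want the downstream quantities: escape metrics, occupancy footprints,
sensory/motor encoding classification, input selectivity, and binasal
summation indices.  A seeded synthetic-data generator with known ground
truth substitutes for raw recordings, so the whole pipeline is testable
without external data.

## What it computes

* **Fluidics** — hydraulic diameter `D_H = 2ab/(a+b)`, mean velocity,
  Reynolds number `Re = ρvD_H/μ` and Péclet number `Pe = vD_H/D` for
  rectangular ducts, plus chemical-border sharpness (10–90% transition
  width) from intensity line profiles.
* **Behavior** — swim bouts (angular velocity ≥ 1.2 °/ms or linear
  velocity ≥ 12 µm/ms), border-crossing escape events with a 1-mm
  hysteresis margin, escape bout counts / path lengths / times,
  turn-angle statistics, occupancy maps, and 4-mm wall/conspecific
  proximity exclusion.
* **Encoding** — dF/F (drop 21 frames, baseline = min of next 9),
  KDE mutual information `I_S` between each ROI's dF/F and the left /
  right / bilateral stimulus profiles and `I_M` against binned motor
  output; shuffled-null classification (sensory > 2.5× pooled null max,
  sensorimotor > 1.25× both); ipsilateral selectivity
  `I_ipsi/(I_ipsi+I_contra)`; normalized information `I_N` relative to
  the olfactory-bulb mean; and the fraction of nonlinear information
  `F_Is = (I_S_b − I_S_u_sum)/I_S_b` probing binasal summation.

See `docs/methods.md` for the full model description and the design
decisions behind each estimator.

## Worked example

Compute the arena's flow regime from its printed parameters:

```python
from chemonav.fluidics import ChannelSpec, characterize_channel

spec = ChannelSpec.from_lab_units(
    a_mm=1.5, b_mm=60.0, q_inlet_ul_min=220.0, n_inlets=3,
    rho=996.0, mu=8.32e-4, diffusivity=0.66e-9,
)
nums = characterize_channel(spec)
print(f"D_H = {nums.d_h:.3g} m, v = {nums.velocity:.3g} m/s")
print(f"Re = {nums.reynolds:.3g}, Pe = {nums.peclet:.3g}")
```

```
D_H = 0.00293 m, v = 0.000122 m/s
Re = 0.428, Pe = 542
```

`Re << 2000` means the three inlet streams flow laminarly, and
`Pe >> 1` means the dissolved chemical barely diffuses across them —
together, the rightmost chemical zone keeps a static, sharp border.

Simulate a small cohort and measure its escape behavior:

```python
from chemonav.behavior import ArenaGeometry, detect_bouts, \
    escape_metrics, segment_crossings
from chemonav.synthetic import BehaviorGenConfig, gen_trajectory

arena = ArenaGeometry()                      # 60 x 30 mm, border at x = 40
cfg = BehaviorGenConfig(n_larvae=6, duration_s=600.0, seed=400,
                        zone_rate_multiplier=3.0,
                        turn_angle_sd_zone=60.0, first_bout_gain=2.0)
trajs, truth = gen_trajectory(cfg)
events = [e for t in trajs
          for e in segment_crossings(t, arena, bouts=detect_bouts(t))]
s = escape_metrics(events)["summary"]
print(len(events), s["n_bouts"]["median"], round(s["escape_time_s"]["median"], 2))
```

```
45 13.0 7.42
```

Forty-five crossing events; with klinokinesis (3× bout rate in the
zone) and angular orthokinesis (larger, faster first turns) the cohort
escapes the chemical zone in a median of 13 bouts and ~7 s — faster than cohorts
simulated without those strategies, reproducing the strategy ordering
of bilateral- vs unilateral- vs non-sensing groups.

The same pipeline is available from the shell:

```sh
chemonav simulate --seed 1 --out out/        # synthetic data + truth tables
chemonav behavior out/trajectories.csv --out out/
chemonav encode out/calcium.h5 --seed 1 --out out/
chemonav fluidics params.yaml --out out/
chemonav report config.yaml                  # full configured pipeline
```

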