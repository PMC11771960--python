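# hemigait

Bilateral spinal locomotor circuit model and split-belt gait analysis after a
lateral thoracic hemisection.

The package contains two connected pipelines:

1. **Circuit simulation** — two rhythm generators (flexor/extensor
   conditional bursters with persistent-sodium dynamics, coupled through
   inhibitory interneurons) interacting via commissural pathways (V0D,
   V2a→V0V→Ini, V3, V3E). Supraspinal drives (α to flexor circuits, γ to
   extensors) and two belt-speed-dependent somatosensory feedback signals
   (SF-E1, SF-E2) drive the network; feedback is attenuated by
   drive-dependent presynaptic inhibition. Lesions (right/left hemisection,
   full transection) remove the affected side's drives, which opens the
   presynaptic gate on that side's feedback. Speed sweeps over tied-belt and
   split-belt protocols produce per-side cycle/stance/swing/duty tables and
   swing–stance crossing speeds, and an operational classifier labels each
   side's operating regime (state machine, flexor-driven, half-center).

2. **Gait-event analysis** — experimental-style per-limb contact /
   stance-end event streams (from the simulator, from CSV, or from the
   seeded synthetic generator) are turned into per-cycle temporal metrics,
   speed-indexed summaries, and intact-vs-hemisected comparison tables.

## CLI

The console script `hemigait` exposes five commands:

```bash
# integrate one condition, write traces + phase events
hemigait simulate --model right-hemisected --protocol tied --beta 0.6 --out out/

# speed sweep -> per-side metrics table (+ crossing report, optional figures)
hemigait sweep --model right-hemisected --protocol split-ls-rf --out out/ --plot

# operating-regime labels for both sides
hemigait classify --model transected --protocol tied --beta 0.5

# seeded synthetic gait events (experimental CSV dialect)
hemigait synth --condition split-ls-rf --seed 12345 --out out/

# events -> per-cycle metrics -> summaries -> intact/hemisected comparison
hemigait analyze --condition tied --seed 12345 --out out/
```

Every command echoes its run configuration into the output directory; exit
codes are 0 (success), 2 (usage error), 3 (numerical failure).

Model parameters ship in `src/hemigait/data/default_network.yaml`; pass an
edited copy with `--config` to run variants.

## Layout

- `src/hemigait/model_core.py` — network/config types, lesions, drives,
  feedback, right-hand side of the ODE system
- `src/hemigait/sim_engine.py` — integration, event detection, gait
  metrics, speed sweeps, swing/stance crossing
- `src/hemigait/regimes.py` — operating-regime classification
- `src/hemigait/gait_analysis.py` — event-stream metrics, summaries,
  state comparisons, CSV dialect
- `src/hemigait/synthetic_data.py` — seeded generator of experimental-style
  gait event streams with injected hemisection effects
- `src/hemigait/io_cli.py` — command-line interface and figure export
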