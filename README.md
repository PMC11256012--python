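# nanofrac

Toolkit for programmable nano-flow fraction collection and 2D RP–RP
evaluation, aimed at proteomics labs running offline high-pH
reversed-phase fractionation on a 3D-printer-derived collector.

At nano-LC flow rates (~500 nL/min) fraction collection must be done by
*dip collection*: the column outlet is held ~1 mm below the surface of
~50 µL of buffer preloaded in each destination well while the gantry of
a converted consumer 3D printer moves the outlet from well to well.
`nanofrac` provides the full software stack for such an instrument,
testable without hardware:

* **Concatenation scheduling** — map *n* timed fractions onto *m* wells.
  The canonical scheme pools 40 one-minute fractions round-robin into
  8 main fractions (8 × 5: fractions *i*, *i*+8, *i*+16, … share a
  well), which preserves orthogonality with the second dimension;
  blocked, identity and custom patterns are also supported.
* **Motion planning and G-code** — raise → XY transit → dip sequences
  with device-timed collection dwells, emitted as a minimal Marlin-style
  dialect (`G21/G90/G28/G1/G4/M400`), with a hard bound on well-to-well
  transition time.
* **Virtual printer** — executes the emitted G-code with a
  distance/feed time model, axis limits and homing semantics, so plans
  can be verified end to end; a thin serial driver targets real
  hardware (optional `pyserial`).
* **Evaluation metrics** — peak capacity
  (*Pc* = 1 + *t*_g/*w*_b, with the 2D upper bound *n*·*Pc*),
  fraction-overlap histograms, intensity recovery
  (Σ test / Σ reference over common peptides), and retention-time
  orthogonality (Pearson/Spearman + rank-grid occupancy).
* **Synthetic fixtures** — Gaussian-copula RT pairs, Gaussian-elution
  detection sets with an analytic singleton-share oracle, and paired
  intensity tables with a known loss factor.

## Worked example

Build the default run (40 fractions → 8 wells at 1 min), emit its
G-code, and execute it on the virtual printer:

```bash
$ nanofrac plan --csv schedule.csv --gcode plan.gcode
40 fractions -> 8 wells, span 2400 s, plan duration 2403.8 s
per-well final volume: 52.5-52.5 uL
wrote schedule.csv and plan.gcode

$ nanofrac simulate plan.gcode
simulated 367 commands in 2403.8 s; final pose (113.000, 50.000, 50.000)
```

The schedule spans exactly 40 min; the plan adds ~4 s of approach and
park moves. Each of the 8 wells receives 5 × 1 min × 500 nL/min
= 2.5 µL on top of its 50 µL preload. The simulated clock equals the
nominal plan duration and the head parks at the safe-travel height
(Z = 50 mm) over the last well. `schedule.csv` lists
`fraction,row,col,t_start_s,t_end_s`; fraction 9 pools back into well
A1, the signature of the 8 × 5 concatenation.

Metrics from the same library:

```bash
$ nanofrac metrics peak-capacity --gradient-s 2640 --width-s 47 --n-fractions 8
{
  "t_gradient_s": 2640.0,
  "w_base_s": 47.0,
  "pc_1d": 57.170212765957444,
  "n_fractions": 8,
  "pc_2d_upper": 457.36170212765956
}
```

A 44 min gradient with 47 s baseline peaks resolves ~57 peaks in one
dimension; with 8 concatenated fractions the fully-orthogonal upper
bound is ~457. `nanofrac synth ...` writes peptide TSV tables with
known ground truth, and `nanofrac metrics overlap|recovery|orthogonality`
evaluates them.

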