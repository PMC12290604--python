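# lamvaso

Laminar VASO/BOLD fMRI analysis with a generative layered-cortex simulator.

## The problem

Cerebral-blood-volume (CBV) weighted fMRI with SS-SI VASO (slice-selective
slab-inversion vascular space occupancy) acquires an interleaved pair of
volumes every cycle: a blood-nulled image, whose signal *drops* when CBV
rises, and an ordinary T2\*-weighted BOLD image. Laminar studies use this
pairing to measure depth-dependent haemodynamic responses with microvascular
specificity that gradient-echo BOLD — biased toward pial draining veins —
cannot provide. Getting from the raw interleaved series to layer-resolved
response curves takes a chain of non-trivial steps, each of which this
package implements and tests:

- **Symmetric acquisition bookkeeping.** The cycle consists of four equally
  spaced 785 ms blocks (inversion delay, nulled readout, delay, BOLD
  readout). Stimulus onsets are jittered four-fold across the block grid, so
  trial averaging samples the response every 0.785 s even though each
  contrast is only acquired once per 3.14 s cycle.
- **BOLD correction (BOCO).** The nulled signal carries a multiplicative
  T2\* contamination. Dividing the nulled by the BOLD series volume-by-volume
  removes it: with nulled `S0·(1−v(t))·(1+g·δ(t))` and BOLD `S0·(1+δ(t))`,
  the ratio recovers `1−v(t)`, the pure CBV response.
- **Event-related averaging.** Trials are extracted from stimulus onset to
  the end of their rest period on the 4×-upsampled grid, interleaved across
  jitters, converted to percent signal change against a 30 s edge baseline,
  sign-inverted for VASO, offset-stitched across short/long inter-trial-
  interval sessions, and zeroed at the first time point.
- **Equivolume layering.** Cortical depth is computed so that equal depth
  increments enclose equal local volume under curvature (Bok's principle),
  binned into 3 layers for temporal analyses and 11 for profiles, with a
  geodesic disc ROI grown inside the gray-matter ribbon.
- **GLM.** One regressor per stimulus duration (1, 2, 4, 12, 24 s boxcars
  convolved with a gamma HRF of mean lag 6 s, sd 3 s), discrete-cosine
  high-pass at 0.01 Hz, OLS with t→z conversion, Stouffer fixed-effects
  session combination, and min–max normalised layer profiles.
- **Headline metrics.** Time to peak (TTP), defined on the span between the
  initial deflection above zero and the subsequent fall below zero, and the
  ratio of peak signal change in vessel-dominated voxels to that in gray
  matter, per stimulus duration.

Because real laminar VASO data require hours of 7 T scanning, the package
ships a generative simulator (`lamvaso.simulate`) producing interleaved
nulled/BOLD series over an annular cortical ribbon with compartment-specific
gamma-variate responses, a hard saturation ceiling for vessel CBV, per-cycle
multiplicative BOLD contamination, Gaussian noise, and rigid motion traces.
Every analysis stage is validated against this generator's analytic ground
truth.

## Worked example

```python
import lamvaso as lv

model = lv.CompartmentModel(noise_sd=0.0)           # noise-free for clarity
participant = lv.simulate_participant(n_runs=4, iti_class="long",
                                      seed=0, model=model)
result = lv.analyze_participant(participant)
print(result["ttp"].query("contrast == 'vaso' and roi in ('gm', 'vessel')")
      .to_string(index=False))
print(result["ratios"].query("contrast == 'vaso'").to_string(index=False))
```

```
contrast    roi  duration_s  ttp_s  peak_pct  valid
    vaso     gm         1.0  4.710  0.329360   True
    vaso     gm         2.0  4.710  0.642508   True
    vaso     gm         4.0  6.280  1.174179   True
    vaso     gm        12.0 12.560  1.855485   True
    vaso     gm        24.0 16.485  1.877402   True
    vaso vessel         1.0  6.280  0.581584   True
    vaso vessel         2.0  6.280  1.030771   True
    vaso vessel         4.0  5.495  1.030998   True
    vaso vessel        12.0  5.495  1.029279   True
    vaso vessel        24.0  5.495  1.031006   True

contrast  duration_s    ratio
    vaso         1.0 1.765801
    vaso         2.0 1.604294
    vaso         4.0 0.878058
    vaso        12.0 0.554722
    vaso        24.0 0.549166
```

Reading the output: gray-matter CBV responses peak *after* stimulus offset
for stimuli up to 12 s (e.g. TTP 4.7 s for a 1 s stimulus) and keep growing
with duration, while the vessel-dominated response saturates by 2 s
(`peak_pct` ≈ 1.03 from 2 s onward) and peaks on a fixed latency. The
vessel/GM peak ratio therefore falls monotonically with stimulus duration,
crossing 1 between 2 s and 4 s — short stimuli weight the measurement toward
large vessels, long stimuli toward gray-matter microvasculature.

The same stages are available from the shell:

```bash
lamvaso simulate   --out-dir sim --seed 1 --n-runs 4
lamvaso preprocess --nulled sim/run-01_nulled.nii --bold sim/run-01_bold.nii \
                   --motion sim/run-01_motion.tsv --out-dir pre
lamvaso layering   --labels sim/labels.nii --layers 3,11 --out-dir lay
lamvaso glm        --series pre/vaso.nii --contrast vaso \
                   --events sim/run-01_events.tsv --out-dir glm-out
```

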