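# curtainkit

Quantification tools for single-molecule DNA-curtain experiments on the
Rdh54 translocase and for the colony-count genetics that accompany them:

* **photobleaching stoichiometry** — segment per-focus intensity traces into
  discrete bleaching steps, calibrate the single-fluorophore unit intensity
  from pooled drop amplitudes, and size clusters as
  `(I - background) / unit`;
* **kymograph kinematics** — extract 1-pixel kymographs from image stacks,
  track particles by sub-pixel windowed centroids, classify motion by the
  standard scoring rules (start when displacement > 2 px; pauses = 2–4-frame
  stalls; termination = a stall of > 10 frames), and compute the net
  velocity `|Y_f − Y_i| · bp/px / (X_f − X_i)` and the track length in kb;
* **two-color colocalization** — greedy one-to-one nearest-neighbor
  matching within a capture radius, replicate-level occupancy
  percentages, and Pearson correlation of matched-pair intensities;
* **genetic-outcome arithmetic** — gene-conversion frequencies from
  dilution-adjusted plate counts, CO/NCO/BIR percentages among sectored
  colonies, MMS survival percentages, and the Mann–Whitney and Welch t
  tests used to compare them;
* **a synthetic-data generator** (`curtainkit.simgen`) that emulates all of
  the above — stepwise-bleaching traces, log-normal cluster fields,
  translocating particles rendered into kymographs or TIFF stacks,
  two-channel point fields, Poisson colony counts — with explicit seeds and
  a ground-truth record per object, so every estimator can be scored
  against known truth.

Step detection is penalized least squares: the trace is fit by the
piecewise-constant signal minimizing `RSS + β·k` over all placements of
`k` change points (segments ≥ 2 frames), solved exactly by a pruned
dynamic program and, in the tests, verified against exhaustive enumeration.
The default penalty is Schwarz-style, `β = 3·σ̂²·log T`, with σ̂ estimated
robustly from first differences.

## Worked example

Simulate a dimer's photobleaching trace at SNR 5, detect its steps, then
calibrate and size a 201-focus field:

```python
from curtainkit import simgen, detect_steps, workflows
from curtainkit.config import ImagingConfig

cfg = ImagingConfig.unshuttered(frames=1200)          # 0.2 s/frame
trace, truth = simgen.simulate_photobleach_trace(
    n_fluors=2, unit_intensity=100.0, unit_sd=10.0, bleach_rate=0.025,
    noise_sd=20.0, background=50.0, config=cfg, seed=11)
for e in detect_steps(trace):
    if e.direction == "drop":
        print(f"drop at frame {e.frame}: amplitude {e.amplitude:.1f} a.u.")

res = workflows.cluster_sizing_recovery(seed=1618)
cal = res["calibration"]
print(f"unit intensity: {cal.unit_mean:.1f} +/- {cal.unit_sd:.1f} a.u. "
      f"(n={cal.n_events} drops)")
print(f"median cluster size: {res['median_estimated']:.2f} molecules")
```

prints

```
drop at frame 10: amplitude 115.0 a.u.
drop at frame 225: amplitude 99.9 a.u.
unit intensity: 100.6 +/- 16.2 a.u. (n=441 drops)
median cluster size: 7.11 molecules
```

The two detected drops are the two fluorophores (true bleach frames 10 and
225); their amplitudes scatter around the configured 100 a.u. unit. Pooling
441 such drops calibrates the unit to 100.6 a.u., and dividing
background-subtracted focus intensities by it recovers the field's median
copy number (7.11 vs a true median of 7.0).

The same experiments are available from the shell, e.g.

```bash
curtainkit simulate trace --seed 7 --out sim/
curtainkit steps --traces sim/traces.csv --out steps.csv
curtainkit coloc --a chA.csv --b chB.csv --radius 1
```

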