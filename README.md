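# picketqa

Picket-fence MLC quality assurance from EPID portal images, anchored to the
accelerator's delivery log.

Multi-leaf collimators (MLC) shape every intensity-modulated treatment
field, and sub-millimetre leaf-positioning errors translate directly into
dose errors at segment abutments. `picketqa` measures leaf positions from a
routine picket-fence portal image: a train of adjacent step-and-shoot
segments with a deliberate abutment gap (nominal width `W_Abu`, 2–14 mm)
at every internal boundary.  Each gap appears in the open-field-normalized
image `I_norm = ΔI_raw / ΔI_open` as a valley per leaf pair, and three
scalar features of that valley are each inverted to a gap width through a
fifth-order calibration curve

```
W_Abu = c0 + c1·W_F + c2·W_F² + c3·W_F³ + c4·W_F⁴ + c5·W_F⁵
```

where `W_F` is the FWHM (distance between the per-side half-level crossings
`P_r − P_l`), the valley area (summed deficit below the flanking peaks) or
the valley depth (the valley value itself).  The measured valley center
splits the estimated width into the two leaf edges, `P_l = P_peak − W/2`
and `P_r = P_peak + W/2`, which are scored against the *actual* positions
recovered from the delivery log — the 40 ms record stream of every leaf,
averaged per segment.  The calibration itself can be built per strip
(Scheme A), per leaf pair against planned widths (Scheme B) or per leaf
pair against log-derived widths (Scheme C); the *integration method* keeps,
per leaf, whichever feature method lands closest to the log.  A synthetic
linac (erf-kernel penumbra with a rounded-leaf-end ramp and panel glare,
per-record leaf jitter, session output fluctuation, pixel noise) generates
matching DICOM images and CSV logs so the entire loop runs with no
hardware.

The package is written for medical physicists and QA-tool developers:
library first (`numpy`/`scipy`/`pandas`/`pydicom`, plus a scikit-learn
compatible `QuinticCalibrator`), with a thin `picketqa` CLI
(`simulate` / `calibrate` / `analyze` / `logstats`) on top.

## Worked example

Calibrate a simulated linac (8 sessions × 13 picket-fence fields), then
analyze a fresh 8 mm field carrying a deliberate +1.2 mm displacement of
one bank-A leaf:

```python
from picketqa import single_bank_error_plan, normalize_images, analyze_field, summarize
from picketqa.replication import ReplicationConfig, run_calibration

cfg = ReplicationConfig(n_pairs=12, n_sessions=8)
sim = cfg.simulator(seed=42)
nominal, calibration = run_calibration(sim, cfg)

plan = single_bank_error_plan(8.0, strip=3, magnitudes=(1.2,), first_pair=5,
                              n_pairs=cfg.n_pairs)
image, log = sim.acquire_picket_fence(plan, session=100)
norm = normalize_images(image, sim.acquire_open_field(session=100))
result = analyze_field(norm, calibration, log, plan, cfg.beam,
                       scheme="C", strips=[3])

print(summarize(result).round(3).to_string())
err = result.integrated.set_index(["pair", "leaf"])["error"]
print(f"\ndetected displacement on pair 5 (right leaf): "
      f"{err.loc[(5, 'right')] + 1.2:+.2f} mm (introduced: +1.20 mm)")
```

prints

```
               mean     sd  mean_abs  sd_abs  max_abs   n  frac_beyond_action  frac_beyond_investigate      verdict
method
fwhm         -0.004  0.030     0.023   0.019    0.070  24               0.000                    0.000         pass
valley_area  -0.004  0.050     0.043   0.027    0.107  24               0.083                    0.000       action
valley_depth -0.004  0.251     0.249   0.033    0.322  24               1.000                    0.875  investigate
integration  -0.004  0.021     0.016   0.013    0.059  24               0.000                    0.000         pass

detected displacement on pair 5 (right leaf): +1.18 mm (introduced: +1.20 mm)
```

The rows are per-leaf signed errors (mm) of each method against the
log-derived actual positions over the field's 12 pairs × 2 leaves.  The
integration row dominates every individual method by construction, and the
ordering integration < FWHM < valley area < valley depth reflects each
feature's sensitivity at this gap width.  The deliberate 1.2 mm
displacement is recovered to 0.02 mm.

The same flow is available from the shell:

```sh
picketqa simulate --width 8 --n-pairs 12 --seed 42 --out field8
picketqa logstats --log field8/delivery_log.csv --plan field8/plan.yaml
picketqa analyze --field field8/picket.dcm --open-field field8/open.dcm \
    --log field8/delivery_log.csv --calibration cal.json \
    --plan field8/plan.yaml --out qa_report
```

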