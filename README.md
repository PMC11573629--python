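# colonykymo

Quantification of spatiotemporal cell-death patterns in bacterial colony
time-lapse fluorescence imaging.

Colonies of *Vibrio cholerae* undergo a programmed, quorum-sensing-controlled
cell-death sequence: an early episode confined to the expanding colony rim
(**phase 1**, roughly 8–40 h after spotting), and a later ring that nucleates
in the colony interior (**phase 2**, ~44 h) and propagates inward and outward
over ~6 h. Experiments image two channels over time: a constitutive
fluorescent protein marking live cells and a membrane-impermeant DNA stain
marking dead cells. `colonykymo` turns such two-channel stacks into
space–time **kymographs** of the log dead/live intensity ratio and extracts
automated phase metrics, so strains (wild type, ΔhapR-like, luxO-locked, …)
can be compared quantitatively instead of by eye.

## The pipeline

Given a calibrated stack (mm/px, h/frame), the stages are:

1. **Background subtraction** — rolling-ball (default radius 1000 px), the
   envelope traced by a ball rolled under the intensity surface.
2. **Rigid registration** — translation + rotation per frame, estimated on
   the live channel (phase correlation + 1-D angular search on edge maps)
   and applied to both channels.
3. **Colony geometry** — Triangle-algorithm threshold on the live channel,
   largest connected component, per-frame centroid and Feret angle; a fixed
   sampling ray from the first frame's centroid along its Feret angle, whose
   endpoint follows the colony boundary (sub-pixel refined).
4. **Kymograph** — both channels sampled along the ray onto a fixed 10 µm
   radial grid; values are
   `log10((dead + 1) / (live + 1))`, a matrix of time × radial position.
5. **Phase metrics** — a rim band (outermost 0.25 mm, tracking the moving
   boundary) and an interior-band detector score activity as a rise of the
   log-ratio above its pre-death baseline (mean + 3 SD, with a 0.2
   log-unit floor), yielding phase-1 onset/end/magnitude, phase-2
   onset/origin radius/propagation duration, and rim-band fold differences
   between strains: `fold = 10^(mean_A − mean_B)`.

A synthetic-colony generator (`colonykymo.simulate`) reproduces the
statistical structure of the imaging data — linear colony growth to a 3 mm
final radius, the two death schedules, shot noise, background gradients,
stage drift, optional 3×3 tiling and z-stacks — with full ground truth, so
the entire pipeline is testable without a microscope. Plate-reader assay
arithmetic (RLU = luminescence/OD600, fold changes, two-tailed Student *t*
tests) is in `colonykymo.assays`.

## Worked example

```python
from colonykymo import SimulationConfig, simulate_colony, run_analysis

config = SimulationConfig(seed=1)      # WT-like colony, 512 px, 1 h frames
stack, truth = simulate_colony(config)
result = run_analysis(stack)
print(result.metrics.to_json())
```

prints (seed 1):

```json
{
  "p1_detected": true,
  "p1_onset": 8.0,
  "p1_end": 40.0,
  "p1_magnitude": 0.9838489070419376,
  "p2_detected": true,
  "p2_onset": 44.0,
  "p2_origin_radius": 1.0,
  "p2_duration": 6.0,
  "final_radius_mm": 2.996456700861454,
  "p1_fold_vs_reference": null
}
```

Reading: rim death is active from 8 h to 40 h with a mean rim-band log-ratio
near 1 (a ~10:1 dead/live intensity ratio); the interior ring nucleates at
44 h at ~1 mm from the colony center and its fronts advance for 6 h; the
final colony radius is ~3 mm. Comparing against a mutant-like colony whose
rim death is 10-fold attenuated:

```python
from colonykymo.kymograph import compare_strains

mut_stack, _ = simulate_colony(SimulationConfig(p1_attenuation=10.0, seed=2))
mut = run_analysis(mut_stack)
print(compare_strains(result.kymograph, mut.kymograph))   # 9.779  (truth 10)
```

The same pipeline is available from the shell:

```bash
colonykymo simulate --out run_wt --seed 1
colonykymo analyze  --in run_wt --out out_wt
colonykymo assays   --table reporter.csv --reference WT --out out_assays
```

Every output directory carries its fully resolved configuration, a log, the
kymograph matrix (CSV + PNG) and the phase metrics (JSON).

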