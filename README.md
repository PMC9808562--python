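# origamipore

Nanopore resistive-pulse fingerprinting and assembly-yield quantification of
supramolecular DNA origami.

## The problem

Higher-order DNA origami assemblies — a single 85 × 85 nm tile (monomer) and
its dimer, L-shaped trimer and 2 × 2 array — are traditionally characterised
by AFM imaging or agarose gel electrophoresis. A solid-state nanopore
(a ~160 nm glass nanopipette in a PEG-enriched bath) offers a label-free,
single-molecule alternative: each structure translocating the pore produces a
conductive current peak whose properties encode the assembly state. This
package implements the complete analysis chain for such measurements, plus a
calibrated simulator that generates recordings with known ground truth:

1. **Event detection** — robust baseline estimation and 7σ threshold
   detection on ion-current traces (100 kHz sampling, 20 kHz low-pass);
2. **Feature extraction** — peak current maximum (pA), dwell time (ms) and
   the **equivalent charge surplus** (ECS): the area of the
   baseline-subtracted conductive peak,

   ECS = ∫ ΔI(t) dt  [pA·ms],

   which is conserved for a given assembly state and scales linearly with
   the number of tiles;
3. **Sequentially anchored Gaussian deconvolution** — the monomer sample's
   ECS histogram is fitted with one Gaussian; each more complex sample adds
   one component while the means identified in simpler samples are held
   fixed (components I–IV at ≈143, 332, 481, 636 pA·ms);
4. **Assembly yields** — the relative areas `A_i σ_i √(2π)` of the fitted
   components, with size-corrected gel densitometry as a benchmark.

It is intended for single-molecule biophysicists analysing resistive-pulse
recordings of DNA nanostructures, and for method development against the
bundled synthetic ground truth.

## Worked example

```python
import origamipore as op

config = op.GeneratorConfig(duration=60.0, seed=2)           # 100 kHz, 20 kHz LP, 5 events/s
monomer = op.SampleComposition.pure(op.species_by_name("monomer"))
trace, truth = op.simulate_trace(config, monomer, label="monomer")

baseline = op.estimate_baseline(trace)
table = op.detect_events(trace, baseline)
peak_mean, peak_sd, _ = op.fit_gaussian_1d(table.events["peak_max_pA"])
dwell_mean, dwell_sd, _ = op.fit_gaussian_1d(table.events["dwell_ms"])
```

which prints (via `examples/02_detect_and_characterise_events.py`):

```
noise sigma: 6.00 pA -> 7-sigma threshold at 42.0 pA above baseline
detected 287 events vs 287 inserted (4.78 events/s)
peak current maxima: 122 +/- 26 pA (reported for this tile: 123 +/- 27)
dwell times:         2.16 +/- 0.53 ms (reported: 2.1 +/- 0.6)
analyte-free control: 0 events detected
```

Every inserted event is recovered, the marginal Gaussian fits reproduce the
tile's published translocation signature, and an analyte-free trace yields
no detections. Continuing up the assembly ladder
(`examples/03_ecs_ladder_and_yields.py`):

```
ECS components (pA*ms; * = mean anchored from a simpler sample):
  monomer  I=144   target yield 100.0%
  dimer    I=144*, II=333   target yield 54.9%
  ...
ECS vs tile count: slope 153.1 pA*ms per tile, intercept 4.1, r^2 = 0.993
```

The anchored component means land on the 143/332/481/636 ladder and are
collinear in the tile count — the charge a structure carries through the
pore reads out its size. The dimer sample's target yield (~55%) estimates
the fraction of molecules in the intended end state.

The `examples/` directory holds one short narrative script per capability
(simulation, detection, ECS deconvolution and yields, gel comparison and
event slicing). A thin CLI mirrors the pipeline stages:

```bash
origamipore simulate --composition monomer:0.4,dimer:0.6 --out dimer.csv --seed 7 --duration 60
origamipore detect --trace dimer.csv --out dimer_events.csv
origamipore gel --lanes lanes.csv --out gel_yields.csv
```

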