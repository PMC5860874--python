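# flygroom

Automated detection of grooming behavior in *Drosophila melanogaster*
from long-term video of single flies in activity-monitor tubes, with
circadian analysis of the resulting ethograms.

Grooming — a fly rubbing its legs together or sweeping them over its
body and wings — is hard to score by eye over circadian timescales.
`flygroom` implements a complete analysis pipeline for tube-housed
single flies filmed from above under infrared illumination
(nominally 8-bit grayscale, 10 Hz):

1. **Background modeling.** A fly-free reference frame is built by
   comparing one randomly drawn template frame against seven contrast
   frames and replacing every template pixel that is darker than the
   contrast pixel by more than a threshold C0 = 10 gray levels (the fly
   is always darker than its surroundings). The background is
   regenerated every 1000 s to follow food level and debris.
2. **Segmentation.** Foreground = pixels darker than the background by
   more than C0; connected components smaller than C1 = 25 px are
   erased; the largest remaining blob in each tube ROI is the fly. The
   body is split at its median gray value into a darker *core*
   (thorax/abdomen) and a lighter *periphery* (legs, head, wings) of
   nearly equal size.
3. **Features.** For each pair of consecutive analyzed frames (every
   second frame, 5 Hz) three features are computed: periphery movement
   PM and core movement CM (non-overlapping pixels of each part between
   the frames) and centroid displacement CD along the tube axis
   (displacements under 0.5 px are noise and zeroed). With the scale
   parameter SP = √area, the classifier operates on

       nPM = √PM / SP,  nCM = √CM / SP,  nCD = CD / SP.

4. **Classification.** A k-nearest-neighbors classifier (k = 10,
   Euclidean distance, k-d tree search) labels each frame pair
   grooming / locomotion / rest. Grooming labels are then pruned with a
   12/15 sliding window: a grooming frame survives only if it lies in
   some 15-frame window containing at least 12 grooming labels
   (grooming bouts last seconds; stretch-like movements do not).
5. **Ethograms.** Feeding (fly within one body length of the food end
   for > 3 s) and sleep (quiescence ≥ 5 min) are overlaid, giving five
   mutually exclusive behaviors per frame: grooming, locomotion,
   feeding, short rest, sleep; wake is the complement of sleep.
6. **Rhythm analysis.** Behavior fractions binned at 30 min are tested
   for circadian rhythmicity with a variance-normalized Lomb-Scargle
   periodogram and the analytic significance threshold
   `Power = −ln(1 − (1 − p)^{1/N})`; a two-peak (morning/evening)
   piecewise-exponential activity model is fit by least squares;
   grooming can be shuffled in time with locomotion or wake adjusted to
   conserve their sum; behavior-behavior Pearson correlations get
   permutation (bootstrap) p-values.

Because no recordings ship with the package, `flygroom.synthetic`
renders scripted ground-truth videos — a two-tone fly (core gray ≈ 40,
periphery ≈ 90, area ≈ 300 px on a ≈ 120 background) performing
grooming, locomotion, rest, and feeding bouts with sensor noise — so
every stage is testable end to end.

## Worked example

```python
import flygroom as fg
from flygroom.pipeline import synthetic_training_set, run_detect, RunConfig
from flygroom.pipeline import BENCHMARK_BEHAVIORS, BENCHMARK_BOUT_MEANS
from flygroom.synthetic import generate_ethogram_script, render_video, \
    FlyAppearance, default_roi

config = RunConfig()                      # C0=10, C1=25, k=10, 12/15, ...
training = synthetic_training_set(seed=1234)
model = fg.fit_knn(training, k=10)

script = generate_ethogram_script(600.0, bout_means_s=BENCHMARK_BOUT_MEANS,
                                  behaviors=BENCHMARK_BEHAVIORS, seed=77)
roi = default_roi()
video = render_video(script, FlyAppearance(), roi, seed=78)

result = run_detect(video, roi, model, config)
truth = fg.truth_for_features(script, config.clock)
precision, recall = fg.evaluate(result.pruned_labels, truth)
print(f"precision {precision:.3f} recall {recall:.3f}")
```

prints

```
precision 0.997 recall 0.998
```

i.e. on a 10-minute synthetic video, 99.7% of the frames the pipeline
labels grooming are true grooming frames, and it finds 99.8% of the
scripted grooming frames, after 12/15 pruning.

For rhythm analysis:

```python
from flygroom.synthetic import generate_rhythmic_series
from flygroom.pipeline import run_rhythm

series = generate_rhythmic_series(24.0, days=4, amplitude=0.2,
                                  noise_sd=0.03, seed=0)
out = run_rhythm(series.fractions["activity"].to_numpy(), 30.0)
print(out["period_h"], out["significant_at"])   # 24.0 0.01
```

A `flygroom` command-line tool wraps the same stages
(`simulate`, `train`, `detect`, `evaluate`, `ethogram`, `rhythm`); see
`flygroom --help`.

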