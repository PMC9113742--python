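# wormcal

Quantification pipeline for age-dependent loss of *C. elegans* body-wall
muscle function, built around the ryanodine receptor (RyR) homolog UNC-68
and its stabilising immunophilin FKB-2 (the worm calstabin).

Muscle aging in the worm shows up in several complementary readouts, and
`wormcal` implements the quantitative side of each of them:

* **Ca²⁺ transient imaging** — 20-s GCaMP fluorescence videos of single,
  partially immobilised worms. Each frame is segmented, the worm perimeter
  is extracted and registered across frames, and the muscle signal is laid
  out as a perimeter × time "line-scan" **kymograph**. Rows are normalised
  to ΔF/F₀ (per-row percentile baseline), contraction-associated transients
  are detected as connected supra-threshold regions, and the recording is
  summarised by the **average of the event peak ΔF/F₀**. A caffeine
  readout scores whole-worm SR store release within a fixed post-addition
  window.
* **SR Ca²⁺ leak** — Fluo-4 plate-reader traces of microsomes: ATP starts
  SERCA uptake (exponential decay with rate *k*<sub>up</sub> to a plateau),
  thapsigargin blocks re-uptake, and the subsequent linear rise
  *s*<sub>leak</sub> measures passive channel leak. The slope is normalised
  by uptake depth, *s*<sub>leak</sub>/(F_b − plateau), so wells with
  different microsome loads are comparable.
* **Swimming fatigue** — bends/min and the curl fraction
  (100 · curls/bends) from scored swim trials.
* **Lifespan** — product-limit survival curves and a self-implemented
  **Gehan–Breslow–Wilcoxon** test (weighted log-rank with weight
  *w*<sub>j</sub> = *n*<sub>j</sub>; asymptotic χ²(1) or permutation p,
  exact enumeration for tiny cohorts).
* **Immunoblot densitometry** — band ratios relative to UNC-68 with the
  standard battery: Student *t*, one-way ANOVA + Tukey–Kramer, two-way
  ANOVA (type-II).
* **Sequence conservation** — affine-gap global alignment (BLOSUM62,
  gap open 10 / extend 0.5) with percent identity/similarity, and
  amino-acid composition tables, for the UNC-68 ↔ RyR1 and FKB-2 ↔ FKBP12
  comparisons.

Because the raw assays are live-animal measurements, a first-class
synthetic-data module (`wormcal.synth`) generates every input modality with
a ground-truth manifest — rendered worm videos with scripted Poisson
transients, piecewise leak traces, Poisson/Binomial behaviour tables,
Weibull lifespans, lognormal blot replicates — so every downstream stage is
verified by parameter recovery.

## Worked example

```python
import pandas as pd
from wormcal.config import PipelineConfig
from wormcal.pipeline import run_video_pipeline
from wormcal.synth import WormVideoParams, gen_worm_video, gen_survival_cohort
from wormcal.survival import gehan_breslow_wilcoxon, mean_survival

params = WormVideoParams(seed=1)          # 20 s, 10 fps, A = 0.8, 5% noise
video, truth = gen_worm_video(params)
result = run_video_pipeline(video, PipelineConfig())
peak = result["peak_summary"]
print(f"scripted events: {len(truth.event_times)}, detected: {peak.n_events}")
print(f"mean peak dF/F0: {peak.mean_peak:.3f} (true amplitude {params.transient_amplitude})")

wt, _ = gen_survival_cohort(scale=20.0, group="WT", seed=2)
ko, _ = gen_survival_cohort(scale=15.5, group="KO", seed=3)
cohort = pd.concat([wt, ko])
res = gehan_breslow_wilcoxon(cohort, "WT", "KO")
print(f"mean lifespan WT: {mean_survival(cohort, 'WT')['mean']:.1f} d, "
      f"KO: {mean_survival(cohort, 'KO')['mean']:.1f} d")
print(f"GBW chi-square = {res.statistic:.2f}, p = {res.p_value:.2e}")
```

prints

```
scripted events: 7, detected: 6
mean peak dF/F0: 0.847 (true amplitude 0.8)
mean lifespan WT: 18.7 d, KO: 14.9 d
GBW chi-square = 20.09, p = 7.40e-06
```

i.e. the pipeline recovers the scripted transient amplitude to ~6% on this
recording (one brief event is missed), and a short-lived cohort is cleanly
separated from wild type by the lifespan test.

The same stages are available from the shell:

```bash
wormcal demo --seed 1 --out demo_out        # everything, with a JSON report
wormcal simulate --seed 1 --out sim         # synthetic inputs + manifests
wormcal kymo --video sim/video.tif --frame-interval 0.1 --out kymo_out
wormcal survival --csv cohort.csv --groups WT KO --out surv_out
wormcal conserve --fasta proteins.fasta --out cons_out
```

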