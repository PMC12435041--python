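# romtraj

Longitudinal range-of-motion (ROM) trajectory analysis for shoulder
arthroplasty cohorts.

After anatomic (aTSA) or reverse (rTSA) total shoulder arthroplasty,
patients recover active motion at very different speeds, peak 2–3 years
after surgery, and then slowly lose motion over long-term follow-up. This
package implements the full analysis a clinical-outcomes group would run on
such a cohort:

* **ROI** — per-visit rate of improvement during the 0–2-year recovery
  period: `(value − preop) / months since surgery` for each of four ROM
  measures (abduction, forward elevation, external rotation in degrees; the
  ordinal 0–6 internal-rotation score);
* **peak extraction** — each patient's highest value per measure in the
  2–3-year window;
* **ROD** — per-visit rate of decline at 96+-month visits:
  `(peak − value) / (months since the peak visit)`, decline-positive;
* **fast/average/slow classification** — each rate record votes against the
  cohort-average rate for its (prosthesis, measure, interval) cell; patients
  whose exceedance fraction is > 2/3 are FAST, < 1/3 SLOW, otherwise
  AVERAGE (UNCLASSIFIED below 4 votes);
* **risk screening** — univariate comparison between classes (Welch t-test
  for continuous factors, Fisher's exact test for binary ones), with
  univariate-significant factors entering one multivariate logistic
  regression fitted by IRLS and reported as Wald odds ratios with 95% CIs:
  `OR = exp(β)`, `CI = exp(β ± 1.96·se)`;
* **a synthetic cohort generator** whose trajectories reproduce the
  dynamics this analysis assumes — including the characteristic early
  post-surgical *dip*: patients with high preoperative motion (e.g. ≥120°
  abduction) transiently lose ~25–30° over the first 3 months before
  recovering, while low-preop patients gain ~40° in the same window.

The audience is biostatisticians and outcomes researchers working with
long-format visit data; everything is plain CSV in and CSV out, with a
library API and a thin `romtraj` command-line wrapper
(`simulate`, `rates`, `classify`, `screen`, `report`, `run`).

## Worked example

```python
import romtraj as rt
from romtraj.rate_classifier import label_counts

cfg = rt.SimulationConfig(n_atsa=100, n_rtsa=100, seed=1)
ds = rt.simulate_cohort(cfg)                       # 200 patients, 17127 visits

roi = rt.compute_roi_records(ds)                   # per-visit ROI records
labels = rt.classify_cohort(ds, roi.records, "ROI")
print(label_counts(labels))
# {'FAST': 82, 'AVERAGE': 54, 'SLOW': 64, 'UNCLASSIFIED': 0}

report = rt.run_screen(ds, labels, "roi-slow", prosthesis="aTSA")
print(report.to_frame()[["factor", "p_univariate", "p_multivariate",
                         "odds_ratio"]].head())
```

In this run the slow-ROI aTSA class carries much higher preoperative motion
than the fast/average class (preop abduction 102.8 ± 27.7 vs. 67.9 ± 24.5,
univariate p = 3.8e-07), and preop abduction stays significant in the
multivariate model with OR 1.05 per degree (95% CI 1.006–1.093) — slow
recovery is largely a property of shoulders that had little room to
improve, not of comorbidity (diabetes here: p = 1.0). That is exactly the
structure the generator plants, so the screen is recovering what was put in.

The decline summary works directly from per-measure means. Feeding the
published full-cohort peak (2–3-year) and latest (8+-year) means for aTSA:

```python
from romtraj import decline_from_peak
from romtraj.reference import PEAK_ROM, LATEST_ROM, rom_means

decline_from_peak(rom_means(PEAK_ROM, "aTSA"), rom_means(LATEST_ROM, "aTSA"))
# {'abduction': 16.0, 'forward_elevation': 12.0,
#  'external_rotation': 10.0, 'ir_score': 1.0}
```

i.e. a mean long-term loss of 16° abduction, 12° forward elevation, 10°
external rotation and 1 IR-score point from peak for aTSA (the rTSA figures
are 8°/10°/3°/0.5).

The same analysis end to end, from a shell:

```bash
romtraj run --seed 1 --n-atsa 100 --n-rtsa 100 --out out/
# out/: patients.csv visits.csv roi_rates.csv rod_rates.csv peaks.csv
#       labels.csv screen.csv summary_*.csv decline_summary.csv run.log
```

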