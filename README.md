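# gazedyn

Temporal gaze dynamics during mental-image maintenance: a reusable pipeline
for simulating pattern-maintenance experiments, quantifying scanpath
recurrence, and fitting the hierarchical Bayesian models that distinguish
two maintenance mechanisms — *gaze restriction* and *reactivation of
place-bound content*.

## The scientific problem

When people hold a mental image over a blank screen, they keep moving their
eyes, and they refixate previously fixated locations far more than during
perception. Two mechanisms can produce such refixations:

- **Gaze restriction** — confining gaze to a small area shields the mental
  image from interfering visual input. Restriction predicts that as image
  complexity rises, recurrence and determinism *increase* while the spread
  of fixations and CORM *decrease* (or, if restriction is released under
  load, recurrence falls while spread grows).
- **Reactivation of place-bound content** — refixating the remembered
  locations refreshes a fading image ("looking at nothing"). Reactivation
  predicts recurrence, spread, *and* CORM all increase with complexity.

The discriminating evidence is the joint behaviour of four per-trial
statistics computed on the maintenance-phase scanpath
(fixations $f_1,\dots,f_N$, threshold $d$, recurrence indicator
$r_{ij}=\mathbb 1[\lVert f_i-f_j\rVert \le d]$ for $i<j$,
$R=\sum_{i<j} r_{ij}$):

- **Recurrence** $\%REC = 100\,\frac{2R}{N(N-1)}$ — how often the observer
  refixates previously inspected areas;
- **Determinism** $\%DET$ — the percentage of recurrent points lying on
  diagonal lines (length $\ge L$) of the recurrence matrix, i.e. repeated
  *sequences* of fixations;
- **CORM** $=100\,\frac{\sum_{i<j}(j-i)\,r_{ij}}{(N-1)R}$ — the mean
  temporal separation of recurrent pairs (low = refixations come soon);
- **Spread** — the median Euclidean distance of the trial's fixations from
  their centroid.

Per-trial measures are modelled with Bayesian generalized hierarchical
regressions: a zero-one-inflated beta family for the RQA percentages, an
ex-Gaussian family for the (positive, right-skewed) spread, and a binomial
family for probe accuracy, with correlated random intercepts and slopes per
participant. An effect is "present" when its 95% credibility interval
excludes zero. Because no public trial-level dataset accompanies this
design, the package ships a first-class synthetic-experiment module that
generates every input the analysis consumes — grid-pattern stimuli composed
of 1–4 straight segments, dynamic visual noise, mechanism-driven
maintenance scanpaths, probe responses and maintainability ratings — with
the statistical structure the models assume.

## Worked example

Simulate the reference design (20 participants x 120 trials, four
complexity levels, 20-s maintenance), compute per-trial measures at the
2-degree threshold (~104 px), and fit the recurrence model:

```python
import gazedyn as gd
from gazedyn.pipeline import build_trial_measures
from gazedyn.preprocess import exclude_trials
from gazedyn.inference import ModelSpec, fit_model, spread_recurrence_summary

design = gd.ExperimentDesign(n_participants=20, trials_per_participant=120, seed=1)
data = gd.generate_experiment(design)
per_trial, _, report = build_trial_measures(data.trials, data.fixations, d=103.5)
analyzed, _ = exclude_trials(per_trial)   # correct answers, rating >= 3
print(analyzed.groupby("segments")[["recurrence", "determinism", "corm", "spread_px"]].mean())

fit = fit_model(analyzed, ModelSpec(response="recurrence", family="zoib", seed=1))
print(fit.coefficients)
```

which prints (1718 of 2400 trials analysed):

```
          recurrence  determinism  corm  spread_px
segments
1               76.7         90.4  34.5       49.0
2               50.8         70.7  34.6       78.9
3               33.1         52.2  34.5      109.9
4               24.3         40.9  34.5      139.0

             median    ci_low   ci_high effect_present
intercept  0.052298 -0.317526  0.427332          False
segments  -0.902848 -1.030089 -0.774982           True
```

Reading the output: as complexity rises from 1 to 4 segments, recurrence
and determinism fall, spread roughly triples, and CORM stays flat at ~34.5%
— the signature of complexity-released gaze restriction. The `segments`
row is the posterior slope on the logit scale of the beta mean, with its
95% credibility interval: each added segment lowers the odds of a
recurrent fixation pair by about half. The quadrant check

```python
q = spread_recurrence_summary(analyzed, rec_cut=50.0, spread_cut=103.5)
print(q.high_rec_high_spread)   # 0
```

confirms that no trial combines high recurrence with a spread above the
recurrence threshold: refixations arise from keeping gaze in one place,
not from repeatedly revisiting distant locations.

The same pipeline runs from the shell:

```bash
gazedyn run-all --seed 1 --out runs/demo       # simulate -> filter -> RQA -> fit -> report
gazedyn rqa runs/demo/fixations.csv --out rqa.csv --threshold-deg 2
gazedyn fit runs/demo/per_trial_measures.csv --response recurrence --family zoib --out fit.json
```

`run-all` writes the trial tables, per-trial measures, model summaries,
figures, a human-readable `report.md` and a `manifest.json` with per-stage
row counts; a config file plus seed reproduces every output byte for byte.

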