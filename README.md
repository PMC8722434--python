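# eegfp — specificity and permanence of EEG connectivity fingerprints

Resting-state EEG functional connectivity is subject-specific enough to act
as a biometric "fingerprint": a classifier trained on the connectivity of a
group of people can tell them apart from a single 2-second segment, and that
specificity persists — with gradual decay — across recording sessions spread
over months. `eegfp` is a library for studying exactly this: it estimates
directed and symmetric connectivity between scalp electrodes, identifies
subjects within and across longitudinal sessions, and localises the most
subject-specific connections by scalp region. Because suitable public
longitudinal cohorts are scarce, the package ships a synthetic-cohort
simulator with a known ground truth (subject-specific couplings, monotone
session drift, sensor noise) so every stage of the pipeline is testable end
to end; real EDF/BrainVision recordings can be substituted where available.

It is aimed at researchers in EEG biometrics, test–retest reliability, and
network neuroscience methods.

## The method

Connectivity is computed per 2-s epoch on a 32-channel 10/20 montage
(Fp1 … O2) after 1–40 Hz band-pass + 50 Hz notch filtering and a Hjorth
nearest-neighbour surface Laplacian:

- **Granger causality (GC)** — for each ordered electrode pair, a bivariate
  autoregressive model of order p = 15,

  x(n) = Σₖ a_{x|x,k} x(n−k) + Σₖ a_{x|y,k} y(n−k) + u_xy(n)

  is fitted by OLS together with the restricted model (x on its own lags
  only), and

  GC_{y→x} = ln( V_{x|x̄} / V_{x|x̄,ȳ} ) ≥ 0

  is the log-ratio of restricted to full residual variances. The full
  32 × 32 directed matrix (diagonal 0) gives a 1024-length feature vector
  per epoch.

- **Mutual information (MI)** — the plug-in histogram estimate of
  MI_xy = Σ p(x,y) log₂ [p(x,y) / (p(x)p(y))] in bits (16 equal-width
  bins). The strict upper triangle gives 496 features per epoch.

- **Identification** — a one-against-one RBF-kernel SVM on z-scored
  features. *Specificity* is the pooled accuracy of stratified ten-fold
  cross-validation within one session; *permanence* is the accuracy when
  training on session A (day 1) and testing on sessions B–F (days 2, 7, 30,
  90, 180).

- **Major connections** — each feature gets a contribution weight (mean
  absolute coefficient over all pairwise linear margin classifiers, or
  permutation importance of the RBF model); the top 10% are tabulated into
  a 5 × 5 scalp-region matrix to measure, e.g., intra-frontal enrichment.

## Worked example

```python
import eegfp
from eegfp.connectivity import connectivity_dataset
from eegfp.identify import cross_session_eval, intra_session_cv

sessions = eegfp.default_sessions()[:4]            # A, B, C, D
recs = eegfp.make_cohort(n_subjects=5, sessions=sessions,
                         duration_s=60.0, fs=125.0, seed=3)
by_sess = {s.session_id: [] for s in sessions}
for rec in recs:
    by_sess[rec.session_id].extend(eegfp.preprocess_recording(rec))
feats = {s: connectivity_dataset(e, "GC", order=8) for s, e in by_sess.items()}

print(f"intra-session: {intra_session_cv(feats['A'], 5, seed=0):.3f}")
perm = cross_session_eval(feats["A"], {s: feats[s] for s in "BCD"}, seed=0)
print({s: round(a, 3) for s, a in perm.per_session_accuracy.items()})
```

prints

```
intra-session: 0.940
{'B': 0.987, 'C': 0.867, 'D': 0.613}
```

— within session A, 94% of held-out 2-s epochs are assigned to the correct
subject (chance 20%); trained on day 1, accuracy decays from 98.7% on day 2
to 61.3% on day 30 as the simulated coefficients drift, which is the
permanence curve. The `examples/` directory has one narrative script per
capability (simulation, connectivity indices, identification, major
connections), and the `eegfp` CLI (`eegfp simulate`, `eegfp run`) drives the
same pipeline from a shell.

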