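# ieegnet

Interictal intracranial-EEG (iEEG) functional networks, distance-aware
normalization, and the **D_RS** statistic for relating resected-tissue
network properties to epilepsy-surgery outcome.

## The problem

After resective epilepsy surgery, roughly half of patients become seizure
free. A candidate explanation for failures is incomplete removal of the
epileptogenic network. Interictal iEEG functional networks — Pearson
correlations between electrode contacts, averaged over 2-second windows —
carry a signature of that network in the **node strength** (each contact's
mean correlation with all others). Three obstacles stand between that signal
and a usable predictor:

1. **Spatial bias** — nearby contacts correlate strongly for proximity
   reasons alone, and every patient's implantation is different;
2. **Coverage** — patients differ in how many contacts sample removed vs
   spared tissue;
3. **Time** — networks fluctuate, and a static analysis must be robust to
   the segment analyzed.

`ieegnet` addresses all three. Correlations are normalized against a
baseline decay curve

    f(d) = (p1 · d + p2) / (d + q1)

(the "rat11" rational function) fitted to spared-contact pairs of
good-outcome patients — i.e. non-epileptogenic tissue — so residuals
measure coupling *beyond* what distance predicts. Per patient, the
separation of removed vs spared node strengths is summarized by

    D_RS = P(spared strength > removed strength)   (ties half-weighted),

the normalized Mann–Whitney U statistic: 1 if all spared contacts out-rank
all removed ones, 0 for the reverse, 0.5 for no separation. Cohort-level
discrimination of poor (ILAE class ≥ 2) from good (class 1) outcome by D_RS
is measured as an AUC with logit-transformed Hanley–McNeil confidence
intervals and a rank-sum test, scanned over the minimum per-compartment
contact count n_x, over segment lengths from 4 s to 10 min, and across
separate recording segments.

Because the underlying clinical recordings are not public, the package
includes a fully tested synthetic-cohort generator (`ieegnet.simulate`) that
plants distance-decaying correlation, a hypersynchronous epileptogenic
cluster, resection masks tied to outcome, and realistic channel-amplitude
heterogeneity — with ground truth recorded for every patient.

## Worked example

```python
from ieegnet.simulate import SynthConfig, make_cohort
from ieegnet.cohort import from_synthetic, run_cohort, group_auc

patients, _ = make_cohort(n_good=20, n_poor=20, cfg=SynthConfig(),
                          seed=1, duration_s=60.0)
result = run_cohort(from_synthetic(patients))

drs, ilae = result.drs_values(normalized=True)
g = group_auc(drs, ilae)
print(f"normalized AUC  {g.auc:.3f}  [{g.ci_low:.3f}, {g.ci_high:.3f}]  p = {g.p_value:.2g}")

raw, _ = result.drs_values(normalized=False)
print(f"unnormalized AUC {group_auc(raw, ilae).auc:.3f}")
```

prints

```
normalized AUC  0.968  [0.827, 0.995]  p = 4.5e-07
unnormalized AUC 0.955
```

The normalized networks separate the outcome groups more cleanly than the
raw ones (good-outcome patients sit at mean D_RS ≈ 0.25 — their removed
contacts carry distinctly *higher* strength — while poor-outcome patients
sit near 0.53), and the rank-sum test confirms the group difference. The
per-patient table, fitted baseline, and coverage scan live on the returned
`CohortResult`.

A thin command line mirrors the library:

```bash
ieegnet simulate-cohort --out cohort/ --seed 3
ieegnet run-cohort --manifest cohort/manifest.json --out results/
ieegnet fit-baseline --manifest cohort/manifest.json --out baseline.json
ieegnet patient-drs --edf cohort/P000_seg0.edf \
    --contacts cohort/P000_contacts.csv --baseline baseline.json
```

`run-cohort` writes `patient_drs.csv`, `baseline.json`, `coverage_scan.csv`
and a machine-readable run report including every exclusion.

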