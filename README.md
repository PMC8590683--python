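# apneascreen

HRV-based screening for moderate-to-severe sleep apnea syndrome (SAS)
from a single channel of beat-to-beat R-R intervals (RRI).

Most people with sleep apnea are never diagnosed: the gold-standard
test, polysomnography, needs a sleep lab. But repetitive apneas leave a
strong autonomic fingerprint on the heart — a bradycardia–tachycardia
oscillation with a period near 60 s (cyclical variation of heart rate,
CVHR) — and RRI can be measured at home by inexpensive wearable
sensors. This package implements a screening pipeline that exploits
that fingerprint, for researchers working on HRV-based apnea detection
and for anyone needing a reproducible, fully synthetic testbed for such
pipelines.

## Method

For each subject with raw RRI series `z = [z_1, …, z_T]` (seconds):

1. standardize to zero mean and unit variance per subject:
   `z̃ = (z − mean z)/sd z`;
2. split `z̃` into windows of fixed wall-clock width *w* = 60 s by
   cumulative elapsed time (interval *i* belongs to window *n* when
   `(n−1)w < z_1+…+z_i ≤ nw`); the trailing partial window is dropped;
3. classify every window apnea/normal with a sequence model `m(·)` —
   a 32-unit LSTM with final-state sigmoid read-out, trained 150 epochs
   with Adam (lr 0.01) on expert-style window labels;
4. aggregate into the apnea/sleep ratio `A = T_a / T_s` (fraction of
   analyzed time classified apnea);
5. flag the subject as a potential moderate-to-severe SAS patient
   (AHI ≥ 15) when `A ≥ Ā`, where the threshold `Ā` is the AS ratio of
   the training patient with the smallest AHI ≥ 15 (borderline-case
   rule).

A feature-mode variant replaces each window's beat sequence with the 11
guideline HRV features (meanNN, SDNN, RMSSD, NN50, pNN50, TotalPower,
LF, HF, LF/HF, LFnu, HFnu). A Pan–Tompkins QRS detector turns raw
single-lead ECG into RRI, and a seeded synthetic cohort generator
produces nights of RRI with ground-truth apnea annotations whose apnea
spans carry CVHR — so the whole pipeline runs and is tested without any
clinical data. See `docs/methods.md` for assumptions, parameters, and
limitations.

## Worked example

```python
from dataclasses import replace
from apneascreen import ApneaScreeningModel, ModelConfig, SyntheticCohortSpec, synthetic

base = SyntheticCohortSpec(record_duration_s=3600, seed=0)   # 1-h records
mild = replace(base, event_rate_per_h=16)                    # borderline patient

train = [
    synthetic.generate_subject(mild, "patient", "P1", seed=1),
    synthetic.generate_subject(base, "patient", "P2", seed=2),
    synthetic.generate_subject(base, "healthy", "H1", seed=3),
    synthetic.generate_subject(base, "healthy", "H2", seed=4),
]
test = [
    synthetic.generate_subject(base, "patient", "P3", seed=5),
    synthetic.generate_subject(replace(base, event_rate_per_h=25), "patient", "P4", seed=6),
    synthetic.generate_subject(base, "healthy", "H3", seed=7),
]

results = ApneaScreeningModel(train, config=ModelConfig(epochs=60, seed=0)).fit()
print(results.summary())
print(results.screen(test)[["subject_id", "ahi", "as_ratio", "decision"]].to_string(index=False))
metrics = results.evaluate(test)
print({k: metrics[k] for k in ("sensitivity", "specificity", "auc")})
```

prints

```
Apnea screening model
==========================================================
mode:            raw_rri
window width:    60 s
LSTM units:      32   epochs: 60   lr: 0.01
segments:        236 (A: 75, N: 161)
final BCE loss:  0.0520
AS threshold:    0.441 (borderline-case rule)
----------------------------------------------------------
training subjects:
subject_id  ahi   group as_ratio          decision
        P1 18.0 patient    0.441 potential_patient
        P2 40.0 patient    0.864 potential_patient
        H1  0.0 healthy    0.017           healthy
        H2  0.0 healthy    0.000           healthy
subject_id  ahi  as_ratio          decision
        P3 38.0  0.847458 potential_patient
        P4 23.0  0.559322 potential_patient
        H3  0.0  0.000000           healthy
{'sensitivity': 1.0, 'specificity': 1.0, 'auc': 1.0}
```

Reading it: the mild training patient P1 (AHI 18) spends 44.1% of
analyzed time in model-flagged apnea, and that 0.441 becomes the
screening threshold. Both held-out patients sit above it (their nights
are 85% and 56% apneic by the model's account), every healthy subject
sits at ~0, and the cohort screens with sensitivity, specificity, and
AUC of 1.0. The threshold rule needs a severity-heterogeneous training
cohort to behave like this — see `docs/methods.md`.

The same pipeline is scriptable from the shell:

```sh
apneascreen simulate --out data/ --seed 5 --n-patients 2 --n-healthy 2 --duration-h 1
apneascreen train    --data data/ --out model/ --seed 3
apneascreen screen   --model-dir model/ --data data/ --out screening.csv
apneascreen evaluate --screening screening.csv --subjects data/subjects.csv --out metrics.json
apneascreen run      --out results/ --seed 7        # end-to-end, one command
```

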