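# voa — explainable skill assessment for simulation-based surgical training

`voa` is a complete, reproducible implementation of an explainable
skill-assessment and formative-feedback engine for simulation-based training
in surgery. It targets the bimanual virtual-reality subpial tumour-resection
task: an operator works with a simulated ultrasonic aspirator (dominant hand)
and bipolar forceps (non-dominant hand), and the simulator streams tip
positions, applied forces, and bleeding volume. The package turns those raw
recordings into a transparent verdict a trainee can act on — not just
"novice", but *which* behaviours sit on the wrong side of the expert
benchmark and by how much.

It is intended for researchers in surgical education and medical-education
informatics who want an end-to-end, inspectable pipeline: synthetic cohort
generation (no public dataset of raw trials exists), metric extraction,
z-score normalization, metric selection, linear-SVM training,
leave-one-out validation, and mastery-gated feedback reports.

## The model

Each trial is summarized by named, unit-bearing metrics; the validated set is

| Category | Metric                  | Units  |
|----------|-------------------------|--------|
| safety   | Max Force w/ Bipolar    | N      |
| safety   | Rate of Bleeding        | mL/s   |
| movement | Instrument Tip Distance | mm     |
| movement | Acceleration w/ Bipolar | mm/s²  |

Metrics are z-scored against the training cohort, so z = 0 is the cohort
mean — the proficiency benchmark. A linear support vector machine scores a
trial as

    h = θ · z + b,        y = +1 (skilled) if h > 0, else −1 (novice)

trained by iterative cost reduction: deterministic subgradient descent on the
L2-regularized hinge loss ½‖θ‖² + C Σᵢ max(0, 1 − yᵢ(θ·zᵢ + b)). Expertise is
also reported as a gradient, p(skilled) = σ(h) = 1/(1 + e^(−h)).

Because the model is linear, the score decomposes exactly:
h = Σᵢ θᵢzᵢ + b. Each θᵢzᵢ is a per-metric verdict — positive means the
trainee is on the expert side of the benchmark for that metric (with the
all-negative weights above, that means *below* the cohort mean). The bias is
a weight without a corresponding metric: it shifts the decision boundary but
is excluded from per-metric feedback. Feedback is delivered in two
mastery-learning steps — safety metrics first, then movement — and the
trainee must reach competency on **every** safety metric before step 2
unlocks; otherwise the scenario must be redone.

Metric selection is a wrapper search maximizing leave-one-out
cross-validation (LOOCV) accuracy: forward steps add the best metric while
accuracy strictly improves, backward steps drop any metric whose removal does
not hurt, alternating to a fixed point. The package ships a reference model
(`voa.load_reference_model()`) carrying the published four-metric weights
(−0.6002, −0.5106, −1.4902, −0.2710) from the original 28-skilled /
22-novice validation cohort.

## Worked example

Run the whole pipeline on the default synthetic cohort (28 skilled, 22
novice trials):

```bash
voa pipeline --out demo --seed 7
```

```
INFO voa: select done in 2.64s: ['Max Force w/ Bipolar', 'Rate of Bleeding',
          'Acceleration w/ Bipolar'] (LOOCV 98.0%)
INFO voa: train done in 0.74s; LOOCV accuracy 98.0% sensitivity 100.0% specificity 95.5%
```

The wrapper search kept three of the four candidate metrics for this cohort;
LOOCV classified 49 of the 50 trials correctly (all 28 skilled, hence
sensitivity 100%; 21 of 22 novices, specificity 95.5%). Assessing one novice
trial against the trained model:

```bash
voa assess --model demo/model.json --recording demo/recordings/trial_028.csv
```

```
Classification: NOVICE  (skilled 10.9% / novice 89.1%)
Raw score h = -2.0970

Step 1 (safety): NOT PASSED
  [-] Max Force w/ Bipolar: z = +1.63, weight = -1.6844, contribution = -2.7525
      Competency not yet achieved on Max Force w/ Bipolar — focus on improving this behaviour.
  [+] Rate of Bleeding: z = -0.42, weight = -1.2080, contribution = +0.5087
      Competency achieved on Rate of Bleeding — keep reinforcing this behaviour.

Step 2 (movement): NOT PASSED
  [-] Acceleration w/ Bipolar: z = +0.40, weight = -0.5044, contribution = -0.2029
      Competency not yet achieved on Acceleration w/ Bipolar — focus on improving this behaviour.

Safety competency not yet achieved: redo the scenario before moving on to movement feedback.
```

Reading it: this trainee applied bipolar force 1.63 standard deviations above
the cohort mean, which multiplied by its negative weight contributes −2.75 to
the score — the main reason for the novice call (89.1% novice). Bleeding was
better than the benchmark (+0.51 contribution), so that behaviour is
reinforced. Because one safety metric failed, step 2 stays locked and the
scenario must be repeated.

Each stage is also available separately (`voa simulate`, `voa extract`,
`voa select`, `voa train`, `voa cv`, `voa assess`), reading and writing plain
CSV/JSON artifacts; see `voa --help`.

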