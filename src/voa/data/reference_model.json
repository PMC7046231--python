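{
  "schema_version": "voa-model/1",
  "metric_names": [
    "Max Force w/ Bipolar",
    "Rate of Bleeding",
    "Instrument Tip Distance",
    "Acceleration w/ Bipolar"
  ],
  "categories": ["safety", "safety", "movement", "movement"],
  "weights": [-0.6002, -0.5106, -1.4902, -0.271],
  "bias": 0.0,
  "normalization": {
    "means": [0.0, 0.0, 0.0, 0.0],
    "sds": [1.0, 1.0, 1.0, 1.0]
  },
  "class_encoding": {"1": "skilled", "-1": "novice"},
  "training_meta": {
    "source": "validated two-group subpial tumour-resection model (28 skilled, 22 novice)",
    "source_loocv_accuracy_pct": 92.0,
    "source_sensitivity_pct": 100.0,
    "source_specificity_pct": 82.0,
    "note": "Normalization is the identity: the source cohort's metric means and standard deviations were not published, so inputs must already be z-scored. The bias was not published and is set to 0."
  }
}
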