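"""Trainee assessment: classification, probability gradient, gated feedback.

A new trial is scored as h = theta . z + b on z-scored metrics.  The sign of h
gives the class (positive = skilled), and the logistic transform of the raw
margin expresses expertise as a gradient: p_skilled = sigmoid(h).  Because the
model is linear, h decomposes exactly into per-metric contributions
theta_i * z_i plus the bias, and each contribution is an interpretable verdict:
a positive contribution means the trainee sits on the skilled side of the
training-cohort mean (z = 0) for that metric, the proficiency benchmark.

Feedback is assembled in mastery-learning steps: safety metrics first, then
movement.  A trainee must be competent on *every* step-1 (safety) metric to
unlock step 2; otherwise the scenario must be repeated.  Ambiguity fails
toward more practice — a score of exactly h = 0 classifies as novice, and a
contribution of exactly zero (z = 0, the benchmark boundary) counts as not
yet competent.

The bias enters the score and the probabilities but is excluded from the
per-metric verdicts: it is a weight without a corresponding metric.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit

from .errors import ConfigurationError, NumericError, SchemaError
from .learning import LinearModel, normalize
from .metrics import MOVEMENT, SAFETY, MetricVector
from .recording import NOVICE, SKILLED

__all__ = [
    "score",
    "classify",
    "class_probabilities",
    "metric_feedback",
    "rank_metrics",
    "ClassificationResult",
    "MetricFeedback",
    "StepResult",
    "FeedbackReport",
    "default_step_plan",
    "build_report",
    "assess_recording",
    "MESSAGE_TEMPLATES",
]

#: Externalized feedback text, keyed by verdict; callers may swap in their own.
MESSAGE_TEMPLATES = {
    "reinforce": "Competency achieved on {name} — keep reinforcing this behaviour.",
    "improve": "Competency not yet achieved on {name} — focus on improving this behaviour.",
}


def score(model: LinearModel, z: Sequence[float]) -> float:
    """Raw decision value h = theta . z + b for a z-scored metric vector."""
    z = np.asarray(z, dtype=float)
    if z.shape != model.weights.shape:
        raise SchemaError(
            f"z-vector has shape {z.shape}, model expects {model.weights.shape}"
        )
    return float(model.weights @ z + model.bias)


def classify(h: float) -> str:
    """Sign rule: h > 0 is skilled, h <= 0 is novice (ties fail toward practice)."""
    if not math.isfinite(h):
        raise NumericError(f"decision value must be finite, got {h!r}")
    return SKILLED if h > 0.0 else NOVICE


def class_probabilities(h: float) -> tuple[float, float]:
    """Expertise as a gradient: (p_skilled, p_novice) = (sigmoid(h), sigmoid(-h)).

    The raw margin is passed through a unit-slope logistic; no further
    calibration is applied (see the methods note).
    """
    if not math.isfinite(h):
        raise NumericError(f"decision value must be finite, got {h!r}")
    return float(expit(h)), float(expit(-h))


@dataclass(frozen=True)
class ClassificationResult:
    """Raw score, class label, and the class-probability gradient."""

    score: float
    label: str
    p_skilled: float
    p_novice: float

    @classmethod
    def from_score(cls, h: float) -> "ClassificationResult":
        p_s, p_n = class_probabilities(h)
        return cls(score=h, label=classify(h), p_skilled=p_s, p_novice=p_n)


@dataclass(frozen=True)
class MetricFeedback:
    """One metric's verdict: contribution theta_i * z_i and its reading."""

    metric_name: str
    category: str
    z: float
    weight: float
    contribution: float
    competent: bool
    message_key: str

    def message(self, templates: dict[str, str] | None = None) -> str:
        templates = templates or MESSAGE_TEMPLATES
        return templates[self.message_key].format(name=self.metric_name)


def metric_feedback(model: LinearModel, z: Sequence[float]) -> list[MetricFeedback]:
    """Per-metric competency verdicts from the weight-by-z decomposition.

    Competent iff theta_i * z_i > 0; at the benchmark boundary (z = 0) the
    contribution vanishes and the verdict is "not yet competent".
    """
    z = np.asarray(z, dtype=float)
    if z.shape != model.weights.shape:
        raise SchemaError(
            f"z-vector has shape {z.shape}, model expects {model.weights.shape}"
        )
    out = []
    for name, category, zi, wi in zip(
        model.metric_names, model.categories, z, model.weights
    ):
        contribution = float(wi * zi)
        competent = contribution > 0.0
        out.append(
            MetricFeedback(
                metric_name=name,
                category=category,
                z=float(zi),
                weight=float(wi),
                contribution=contribution,
                competent=competent,
                message_key="reinforce" if competent else "improve",
            )
        )
    return out


def rank_metrics(model: LinearModel) -> list[str]:
    """Metric names by decreasing weight magnitude (model order breaks ties);
    larger |theta_i| means a larger role in the decision."""
    order = np.argsort(-np.abs(model.weights), kind="stable")
    return [model.metric_names[i] for i in order]


# -- stepwise mastery-gated report -------------------------------------------

@dataclass(frozen=True)
class StepResult:
    name: str
    metrics: tuple[MetricFeedback, ...]
    passed: bool


@dataclass(frozen=True)
class FeedbackReport:
    """Pure-data feedback report: classification plus gated per-metric steps.

    ``step2_unlocked`` is true iff every step-1 metric is competent;
    ``must_redo`` is its negation — the trainee repeats the scenario until
    full step-1 (safety) competency is achieved.
    """

    classification: ClassificationResult
    steps: tuple[StepResult, ...]
    step1_passed: bool
    step2_unlocked: bool
    must_redo: bool

    def to_dict(self) -> dict:
        return {
            "schema_version": "voa-report/1",
            "classification": {
                "label": self.classification.label,
                "p_skilled": self.classification.p_skilled,
                "p_novice": self.classification.p_novice,
                "score": self.classification.score,
            },
            "steps": [
                {
                    "name": s.name,
                    "metrics": [
                        {
                            "name": m.metric_name,
                            "z": m.z,
                            "weight": m.weight,
                            "contribution": m.contribution,
                            "competent": m.competent,
                        }
                        for m in s.metrics
                    ],
                    "passed": s.passed,
                }
                for s in self.steps
            ],
            "step2_unlocked": self.step2_unlocked,
            "must_redo": self.must_redo,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def render_text(self, templates: dict[str, str] | None = None) -> str:
        """Plain-text rendering of the report."""
        c = self.classification
        lines = [
            f"Classification: {c.label.upper()}  "
            f"(skilled {100 * c.p_skilled:.1f}% / novice {100 * c.p_novice:.1f}%)",
            f"Raw score h = {c.score:+.4f}",
            "",
        ]
        for i, step in enumerate(self.steps, start=1):
            state = "PASSED" if step.passed else "NOT PASSED"
            lines.append(f"Step {i} ({step.name}): {state}")
            for m in step.metrics:
                mark = "+" if m.competent else "-"
                lines.append(
                    f"  [{mark}] {m.metric_name}: z = {m.z:+.2f}, "
                    f"weight = {m.weight:+.4f}, contribution = {m.contribution:+.4f}"
                )
                lines.append(f"      {m.message(templates)}")
            lines.append("")
        if self.must_redo:
            lines.append(
                "Safety competency not yet achieved: redo the scenario before "
                "moving on to movement feedback."
            )
        else:
            lines.append("All safety metrics competent: step 2 unlocked.")
        return "\n".join(lines)


def default_step_plan(model: LinearModel) -> list[tuple[str, list[str]]]:
    """Two-step plan: safety metrics first, then movement, then any others.

    Within a step, metrics keep their model order.  Safety precedes movement
    by design: it mirrors how instructors prioritize what to teach first.
    """
    plan = []
    for category in (SAFETY, MOVEMENT):
        names = [
            n for n, c in zip(model.metric_names, model.categories) if c == category
        ]
        if names:
            plan.append((category, names))
    other = [
        n for n, c in zip(model.metric_names, model.categories)
        if c not in (SAFETY, MOVEMENT)
    ]
    if other:
        plan.append(("other", other))
    if not plan:  # pragma: no cover - a model always has >= 1 metric
        raise ConfigurationError("model has no metrics to plan steps over")
    return plan


def _validate_step_plan(
    model: LinearModel, step_plan: Sequence[tuple[str, Sequence[str]]]
) -> None:
    seen: list[str] = []
    for _, names in step_plan:
        seen.extend(names)
    if sorted(seen) != sorted(model.metric_names) or len(seen) != len(set(seen)):
        raise ConfigurationError(
            "step plan must partition the model's metric set exactly"
        )


def build_report(
    model: LinearModel,
    metrics: MetricVector | None = None,
    *,
    z: Sequence[float] | None = None,
    step_plan: Sequence[tuple[str, Sequence[str]]] | None = None,
) -> FeedbackReport:
    """Assemble the full feedback report for one trial.

    Provide either a raw ``metrics`` vector (normalized here with the model's
    frozen parameters) or an already z-scored ``z``.  The default step plan
    puts safety metrics in step 1 and movement metrics in step 2.
    """
    if (metrics is None) == (z is None):
        raise ConfigurationError("provide exactly one of `metrics` or `z`")
    if metrics is not None:
        z_arr = normalize(metrics, model.normalization)
    else:
        z_arr = np.asarray(z, dtype=float)
    if step_plan is None:
        step_plan = default_step_plan(model)
    _validate_step_plan(model, step_plan)

    h = score(model, z_arr)
    classification = ClassificationResult.from_score(h)
    per_metric = {f.metric_name: f for f in metric_feedback(model, z_arr)}

    steps = []
    for name, metric_names in step_plan:
        fbs = tuple(per_metric[m] for m in metric_names)
        steps.append(StepResult(name=name, metrics=fbs, passed=all(f.competent for f in fbs)))
    step1_passed = steps[0].passed
    return FeedbackReport(
        classification=classification,
        steps=tuple(steps),
        step1_passed=step1_passed,
        step2_unlocked=step1_passed,
        must_redo=not step1_passed,
    )


def assess_recording(
    model: LinearModel,
    rec,
    registry=None,
    step_plan: Sequence[tuple[str, Sequence[str]]] | None = None,
) -> FeedbackReport:
    """Extract the model's metrics from a raw recording and build its report."""
    from .metrics import compute_metric_vector, default_registry

    vec = compute_metric_vector(rec, registry if registry is not None else default_registry())
    return build_report(model, vec.subset(model.metric_names), step_plan=step_plan)
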