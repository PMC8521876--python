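"""Exercise assessment: online safety/correctness messaging and the offline
motor score.

The *online* pass evaluates a rule set against the metrics of each
processing window and emits safety alerts (stop the exercise) and
correction advice (fix the movement) with at most one window of latency.
Rules come in two categories: patient-independent (absolute thresholds) and
baseline-dependent (thresholds expressed relative to the patient's profile,
as an offset or ratio), which personalizes the interaction.

The *offline* pass recomputes every analytic over the complete recording
and produces the motor score

    MS = (1/k) * sum_j (M_j - Mb_j) / (T_j - Mb_j)

where M_j is the mean per-repetition value of analytic j, Mb_j the
patient's baseline and T_j the target.  Each term is clamped to [0, 1]
before averaging (the raw terms are also kept), so MS measures normalized
progress from baseline toward target and is 0 at baseline, 1 at target.
The ratio handles lower-is-better analytics (T < Mb) without special
casing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import stats

from .errors import ConfigurationError, DegenerateTargetError

SEVERITIES = ("safety_alert", "correction_advice")
_OPS = {
    ">": lambda v, thr: v > thr,
    ">=": lambda v, thr: v >= thr,
    "<": lambda v, thr: v < thr,
    "<=": lambda v, thr: v <= thr,
}


@dataclass
class Rule:
    id: str
    metric: str
    op: str
    threshold: float
    severity: str
    message: str
    category: str = "patient_independent"  # or "baseline_dependent"
    baseline_key: str | None = None
    baseline_mode: str = "offset"  # threshold = baseline + thr | baseline * thr

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise ConfigurationError(f"rule {self.id}: unknown comparator {self.op!r}")
        if self.severity not in SEVERITIES:
            raise ConfigurationError(f"rule {self.id}: unknown severity {self.severity!r}")
        if self.category == "baseline_dependent" and not self.baseline_key:
            raise ConfigurationError(f"rule {self.id}: baseline_dependent needs baseline_key")

    def effective_threshold(self, baseline: dict[str, float]) -> float:
        if self.category != "baseline_dependent":
            return self.threshold
        base = baseline[self.baseline_key]
        return base * self.threshold if self.baseline_mode == "ratio" else base + self.threshold

    def fires(self, value: float, baseline: dict[str, float]) -> bool:
        return _OPS[self.op](value, self.effective_threshold(baseline))


@dataclass
class Message:
    t: float
    rule_id: str
    severity: str
    text: str

    def to_dict(self) -> dict:
        return {"t": self.t, "rule_id": self.rule_id, "severity": self.severity, "text": self.text}


def load_rules(
    path: str | Path,
    known_metrics: set[str] | None = None,
    baseline: dict[str, float] | None = None,
) -> list[Rule]:
    """Load and validate a rules YAML.

    A rule referencing an unknown metric or a missing baseline key fails
    here, at load time, never during evaluation.
    """
    raw = yaml.safe_load(Path(path).read_text())
    rules = [Rule(**r) for r in raw.get("rules", [])]
    for r in rules:
        if known_metrics is not None and r.metric not in known_metrics:
            raise ConfigurationError(f"rule {r.id}: unknown metric {r.metric!r}")
        if r.category == "baseline_dependent" and baseline is not None:
            if r.baseline_key not in baseline:
                raise ConfigurationError(
                    f"rule {r.id}: baseline key {r.baseline_key!r} absent from profile"
                )
    return rules


def evaluate_online(
    window_metrics: dict[str, float],
    rules: list[Rule],
    baseline: dict[str, float] | None = None,
    t: float = 0.0,
) -> list[Message]:
    """Evaluate one window's metrics against the rule set.

    Pure function: identical metrics, rules and baseline yield identical
    messages.  Every firing rule emits exactly one message; safety alerts
    are ordered before correction advice.
    """
    baseline = baseline or {}
    fired = [
        Message(t, r.id, r.severity, r.message.format(value=window_metrics[r.metric], **window_metrics))
        for r in rules
        if r.metric in window_metrics
        and window_metrics[r.metric] is not None
        and np.isfinite(window_metrics[r.metric])
        and r.fires(window_metrics[r.metric], baseline)
    ]
    fired.sort(key=lambda m: (SEVERITIES.index(m.severity), m.t))
    return fired


def aggregate_analytic(values: list[float]) -> float | None:
    """Per-analytic aggregate M^t: arithmetic mean over captured repetitions.

    Returns None for an empty list (missing-analytic marker).
    """
    if len(values) == 0:
        return None
    return float(np.mean(values))


def motor_score(
    M: dict[str, float],
    Mb: dict[str, float],
    T: dict[str, float],
) -> tuple[float, dict[str, float]]:
    """Motor score over the configured analytics.

    Returns ``(MS, raw_terms)``: MS averages the per-analytic progress
    ratios clamped to [0, 1]; ``raw_terms`` keeps the unclamped ratios for
    research use (they may exceed 1 past the target or go negative below
    baseline).
    """
    keys = list(M)
    if not keys:
        raise ConfigurationError("motor_score needs at least one analytic")
    raw: dict[str, float] = {}
    clamped = []
    for j in keys:
        denom = T[j] - Mb[j]
        if denom == 0:
            raise DegenerateTargetError(f"analytic {j!r}: target equals baseline")
        term = (M[j] - Mb[j]) / denom
        raw[j] = term
        clamped.append(min(max(term, 0.0), 1.0))
    return float(np.mean(clamped)), raw


@dataclass
class ExerciseScore:
    analytics: dict[str, list[float]]          # per-repetition values m_i^t
    baselines: dict[str, float]
    targets: dict[str, float]
    message_log: list[Message] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.analytics)

    @property
    def aggregates(self) -> dict[str, float | None]:
        return {name: aggregate_analytic(v) for name, v in self.analytics.items()}

    def score(self) -> tuple[float, dict[str, float]]:
        M = {k: v for k, v in self.aggregates.items() if v is not None}
        return motor_score(M, self.baselines, self.targets)


def score_report(score: ExerciseScore) -> dict:
    """JSON-serializable assessment report.

    The message-class tally (A: correct & would deliver, B: correct but
    would not deliver, C: incorrect, D: missed) is left null for expert
    annotation.
    """
    ms, raw = score.score()
    return {
        "analytics": {
            name: {
                "repetitions": values,
                "aggregate": score.aggregates[name],
                "baseline": score.baselines.get(name),
                "target": score.targets.get(name),
                "raw_term": raw.get(name),
            }
            for name, values in score.analytics.items()
        },
        "k": score.k,
        "motor_score": ms,
        "message_log": [m.to_dict() for m in score.message_log],
        "message_classes": {"A": None, "B": None, "C": None, "D": None},
    }


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))


def agreement_stats(x: np.ndarray, y: np.ndarray) -> dict:
    """Method-agreement statistics: OLS R^2 of y on x and Bland-Altman
    bias with 1.96-sd limits of agreement of the differences x - y."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ConfigurationError("agreement_stats needs >= 3 paired values")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    if np.var(x) == 0:
        r2 = None
    elif np.var(y) == 0:
        r2 = 1.0 if np.allclose(y, y[0]) and np.allclose(d, d[0]) else 0.0
    else:
        r = stats.pearsonr(x, y).statistic
        r2 = float(r**2)
    return {
        "r_squared": r2,
        "bland_altman": {"bias": bias, "loa_low": bias - 1.96 * sd, "loa_high": bias + 1.96 * sd},
    }
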