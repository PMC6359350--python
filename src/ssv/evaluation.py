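"""Benchmarking of sign-based predictions against labeled mutation sets.

Ships the 27-mutation literature benchmark as package data and computes
the confusion-matrix metric panel (precision, accuracy, specificity,
sensitivity, F-measure).  Ratios with a zero denominator are reported as
NaN, never silently as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

from .scoring import LABEL_BENEFICIAL, LABEL_NOT_BENEFICIAL, classify

__all__ = [
    "LabeledMutation",
    "ConfusionMetrics",
    "read_benchmark",
    "load_shipped_benchmark",
    "evaluate_benchmark",
]

_VALID_LABELS = {LABEL_BENEFICIAL, LABEL_NOT_BENEFICIAL}


@dataclass(frozen=True)
class LabeledMutation:
    mutation: str
    expected_label: str
    ddssv: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.expected_label not in _VALID_LABELS:
            raise ValueError(
                f"expected_label must be one of {sorted(_VALID_LABELS)}, "
                f"got {self.expected_label!r}"
            )
        if not math.isfinite(self.ddssv):
            raise ValueError(f"non-finite score for {self.mutation}")


@dataclass(frozen=True)
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    precision: float
    accuracy: float
    specificity: float
    sensitivity: float
    f_measure: float

    @classmethod
    def from_counts(cls, tp: int, fp: int, tn: int, fn: int) -> "ConfusionMetrics":
        def ratio(num: int, den: int) -> float:
            return num / den if den else math.nan

        precision = ratio(tp, tp + fp)
        sensitivity = ratio(tp, tp + fn)
        if math.isnan(precision) or math.isnan(sensitivity) or precision + sensitivity == 0:
            f_measure = math.nan
        else:
            f_measure = 2 * precision * sensitivity / (precision + sensitivity)
        return cls(
            tp=tp,
            fp=fp,
            tn=tn,
            fn=fn,
            precision=precision,
            accuracy=ratio(tp + tn, tp + fp + tn + fn),
            specificity=ratio(tn, tn + fp),
            sensitivity=sensitivity,
            f_measure=f_measure,
        )


def read_benchmark(path: str | Path) -> list[LabeledMutation]:
    """Load a TSV benchmark with mutation, expected_label, ddssv[, source]."""
    path = Path(path)
    records: list[LabeledMutation] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["mutation", "expected_label", "ddssv"]
        missing = [c for c in required if c not in header]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        idx = {c: header.index(c) for c in header}
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < len(required):
                raise ValueError(f"{path}:{lineno}: too few columns")
            records.append(
                LabeledMutation(
                    mutation=parts[idx["mutation"]],
                    expected_label=parts[idx["expected_label"]],
                    ddssv=float(parts[idx["ddssv"]].replace("−", "-")),
                    source=parts[idx["source"]] if "source" in idx else "",
                )
            )
    return records


def load_shipped_benchmark() -> list[LabeledMutation]:
    """The packaged 27-mutation β-glucosidase benchmark."""
    with resources.as_file(
        resources.files("ssv.data").joinpath("benchmark_mutations.tsv")
    ) as p:
        return read_benchmark(p)


def evaluate_benchmark(
    records: Sequence[LabeledMutation],
    positive_class: str = LABEL_BENEFICIAL,
    neutral_tol: float = 0.0,
) -> tuple[ConfusionMetrics, list[tuple[LabeledMutation, str, bool]]]:
    """Score each record by the sign rule and tally the metric panel.

    Returns the metrics plus per-record rows ``(record, predicted, hit)``.
    Records falling inside the neutral band count as misses against the
    binary expectation.
    """
    if not records:
        raise ValueError("benchmark requires at least one record")
    if positive_class not in _VALID_LABELS:
        raise ValueError(f"positive_class must be one of {sorted(_VALID_LABELS)}")
    tp = fp = tn = fn = 0
    per_record: list[tuple[LabeledMutation, str, bool]] = []
    for rec in records:
        predicted = classify(rec.ddssv, neutral_tol)
        hit = predicted == rec.expected_label
        expected_pos = rec.expected_label == positive_class
        # A neutral prediction is a miss against the binary expectation:
        # book it on the wrong side of whatever was expected.
        if predicted == "neutral":
            predicted_pos = not expected_pos
        else:
            predicted_pos = predicted == positive_class
        if expected_pos and predicted_pos:
            tp += 1
        elif expected_pos:
            fn += 1
        elif predicted_pos:
            fp += 1
        else:
            tn += 1
        per_record.append((rec, predicted, hit))
    return ConfusionMetrics.from_counts(tp, fp, tn, fn), per_record
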