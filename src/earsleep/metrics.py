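"""Agreement metrics between hypnograms: confusion matrix, per-class
sensitivity/precision, accuracy and Cohen's kappa.

For a C-class confusion matrix ``n[i, j]`` (rows = truth, columns =
prediction, total N) the reported quantities are

    SE_i  = TP_i / (TP_i + FN_i)            (per-class sensitivity)
    PR_i  = TP_i / (TP_i + FP_i)            (per-class precision)
    AC    = sum_i TP_i / N                  (overall accuracy)
    pi_e  = sum_i (TP_i+FP_i)(TP_i+FN_i) / N**2   (chance agreement)
    kappa = (AC - pi_e) / (1 - pi_e)

kappa is evaluated in the algebraically equivalent integer form
``(N * sum_i n_ii - sum_i row_i * col_i) / (N**2 - sum_i row_i * col_i)``
so hand-checkable matrices reproduce their textbook values to the last
bit.  Verbal kappa categories follow the Landis–Koch bands, closed on the
right (kappa = 0.80 is "Substantial").
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .containers import Hypnogram
from .errors import DegenerateDataError, InputError

#: Landis–Koch interpretation bands for kappa, right-closed.
KAPPA_BANDS: tuple[tuple[float, str], ...] = (
    (0.0, "Poor"),
    (0.2, "Slight"),
    (0.4, "Fair"),
    (0.6, "Moderate"),
    (0.8, "Substantial"),
    (1.0, "Almost Perfect"),
)


@dataclass
class ConfusionMatrix:
    """Square count matrix with rows = truth, columns = prediction."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.classes = tuple(str(c) for c in self.classes)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        c = len(self.classes)
        if self.counts.shape != (c, c):
            raise InputError(
                f"counts shape {self.counts.shape} does not match "
                f"{c} classes"
            )
        if np.any(self.counts < 0):
            raise InputError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def confusion_matrix(
    truth: Sequence,
    predicted: Sequence,
    classes: Sequence[str] | None = None,
) -> ConfusionMatrix:
    """Tally a confusion matrix from two aligned label sequences.

    ``classes`` fixes the row/column order; by default it is the sorted
    union of observed labels.  Labels outside ``classes`` raise.
    """
    truth = list(truth)
    predicted = list(predicted)
    if len(truth) != len(predicted):
        raise InputError(
            f"length mismatch: {len(truth)} truth vs {len(predicted)} predicted"
        )
    if not truth:
        raise InputError("cannot build a confusion matrix from empty sequences")
    if classes is None:
        classes = sorted({str(x) for x in truth} | {str(x) for x in predicted})
    classes = tuple(str(c) for c in classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(truth, predicted):
        t, p = str(t), str(p)
        if t not in index or p not in index:
            bad = t if t not in index else p
            raise InputError(f"label {bad!r} not in classes {classes}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(classes, counts)


@dataclass
class EvalReport:
    """Agreement report: per-class SE/PR plus AC, pi_e, kappa and its band.

    Per-class entries with a zero denominator are NaN (flagged by a
    warning at construction), never silently zero.
    """

    classes: tuple[str, ...]
    counts: np.ndarray
    sensitivity: dict[str, float] = field(default_factory=dict)
    precision: dict[str, float] = field(default_factory=dict)
    accuracy: float = np.nan
    pi_e: float = np.nan
    kappa: float = np.nan
    kappa_band: str = ""

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "counts": np.asarray(self.counts).tolist(),
            "n_epochs": int(np.asarray(self.counts).sum()),
            "sensitivity": {k: _none_if_nan(v) for k, v in self.sensitivity.items()},
            "precision": {k: _none_if_nan(v) for k, v in self.precision.items()},
            "accuracy": _none_if_nan(self.accuracy),
            "pi_e": _none_if_nan(self.pi_e),
            "kappa": _none_if_nan(self.kappa),
            "kappa_band": self.kappa_band,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="ascii") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def summary(self) -> str:
        """Plain-text table of the report."""
        lines = [
            "class        SE        PR",
            "-" * 26,
        ]
        for c in self.classes:
            se, pr = self.sensitivity[c], self.precision[c]
            se_s = f"{se:.3f}" if np.isfinite(se) else "  n/a"
            pr_s = f"{pr:.3f}" if np.isfinite(pr) else "  n/a"
            lines.append(f"{c:<8} {se_s:>9} {pr_s:>9}")
        lines.append("-" * 26)
        lines.append(f"accuracy {self.accuracy:.3f}   pi_e {self.pi_e:.3f}")
        kap = f"{self.kappa:.3f}" if np.isfinite(self.kappa) else "undefined"
        lines.append(f"kappa    {kap} ({self.kappa_band})")
        return "\n".join(lines)


def _none_if_nan(x: float):
    return None if x is None or not np.isfinite(x) else float(x)


def kappa_category(kappa: float) -> str:
    """Landis–Koch verbal band for a kappa value (right-closed bands)."""
    if kappa > 1.0 + 1e-12:
        raise InputError(f"kappa cannot exceed 1, got {kappa}")
    if not np.isfinite(kappa):
        return "undefined"
    for upper, name in KAPPA_BANDS:
        if kappa <= upper:
            return name
    return "Almost Perfect"


def classification_report(cm: ConfusionMatrix) -> EvalReport:
    """Evaluate SE/PR/AC/pi_e/kappa from a confusion matrix.

    Integer marginal sums feed single floating divisions, so exact
    rational results (e.g. kappa = 0.7) come out bit-exact.
    """
    if cm.n == 0:
        raise InputError("empty confusion matrix")
    counts = cm.counts
    n = cm.n
    row = counts.sum(axis=1)  # TP_i + FN_i
    col = counts.sum(axis=0)  # TP_i + FP_i
    diag = np.diag(counts)

    sensitivity: dict[str, float] = {}
    precision: dict[str, float] = {}
    for i, c in enumerate(cm.classes):
        if row[i] == 0:
            warnings.warn(
                f"class {c!r} absent from truth: sensitivity undefined",
                stacklevel=2,
            )
            sensitivity[c] = np.nan
        else:
            sensitivity[c] = float(int(diag[i]) / int(row[i]))
        if col[i] == 0:
            warnings.warn(
                f"class {c!r} never predicted: precision undefined",
                stacklevel=2,
            )
            precision[c] = np.nan
        else:
            precision[c] = float(int(diag[i]) / int(col[i]))

    diag_sum = int(diag.sum())
    s = int(np.dot(row, col))
    accuracy = diag_sum / n
    pi_e = s / (n * n)
    if n * n == s:
        warnings.warn(
            "degenerate single-class marginals: kappa undefined", stacklevel=2
        )
        kappa = np.nan
    else:
        kappa = (n * diag_sum - s) / (n * n - s)
    return EvalReport(
        classes=cm.classes,
        counts=counts,
        sensitivity=sensitivity,
        precision=precision,
        accuracy=accuracy,
        pi_e=pi_e,
        kappa=kappa,
        kappa_band=kappa_category(kappa),
    )


def compare_hypnograms(a: Hypnogram, b: Hypnogram, task) -> EvalReport:
    """Score hypnogram ``b`` against ``a`` (truth) under a staging task.

    Both hypnograms are collapsed with the task's label mapping (see
    :mod:`earsleep.classify`), tallied into one confusion matrix and
    reported.  Lengths and epoch durations must match.
    """
    from .classify import collapse_labels  # local import avoids a cycle

    if len(a) != len(b):
        raise InputError(
            f"hypnogram lengths differ: {len(a)} vs {len(b)}"
        )
    if a.epoch_duration != b.epoch_duration:
        raise InputError(
            f"epoch durations differ: {a.epoch_duration} vs {b.epoch_duration}"
        )
    ya = collapse_labels(a, task)
    yb = collapse_labels(b, task)
    names = task.class_names
    cm = confusion_matrix(
        [names[i] for i in ya], [names[i] for i in yb], classes=names
    )
    return classification_report(cm)
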