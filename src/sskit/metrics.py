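"""Per-class and aggregate metrics for imbalanced SS classification.

Secondary-structure prediction is heavily imbalanced (alpha-helix H is
roughly an order of magnitude more frequent than 3₁₀-helix G, and
pi-helix I is nearly absent), so overall accuracy Q8/Q3 is a poor guide
to per-class quality.  The central statistic here is the Adjusted
Geometric Mean for one class against the rest::

    AGM = (GM + Specificity * N_n) / (1 + N_n)   if Sensitivity > 0
        = 0                                      if Sensitivity = 0

    GM  = sqrt(Precision * Sensitivity)
    N_n = proportion of negative samples = (TN + FP) / total

AGM rewards sensitivity while penalising loss of specificity, and the
more imbalanced the class (larger N_n) the more weight specificity
carries.  It ranges from 0 (worst) to 1 (perfect).

Definedness convention (reports render UNDEFINED as a dash):

* any metric whose denominator is zero is UNDEFINED (``None``);
* AGM is UNDEFINED when the class is absent from the ground truth
  (tp + fn = 0); when the class occurs but is never recovered
  (tp = 0 < tp + fn) the zero-sensitivity branch gives AGM = 0;
* when there are no negatives (N_n = 0) AGM reduces to GM;
* macro-averages are taken over the classes whose value is defined, and
  the number of included classes is reported alongside.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .core import SS8_STATES, PredictionRecord, ProteinRecord

__all__ = [
    "UNDEFINED",
    "BinaryConfusion",
    "ClassMetrics",
    "MetricReport",
    "confusion_counts",
    "sensitivity",
    "specificity",
    "precision",
    "gm",
    "agm",
    "f1",
    "q_accuracy",
    "macro_average",
    "evaluate_residue_level",
    "evaluate_sequence_level",
    "report_to_tsv",
    "report_to_json",
]

#: Marker for a metric that cannot be computed (zero denominator);
#: rendered as "-" in reports, skipped by macro-averages.
UNDEFINED = None


@dataclass(frozen=True)
class BinaryConfusion:
    """One-vs-rest confusion counts for a single structure class."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "BinaryConfusion") -> "BinaryConfusion":
        return BinaryConfusion(
            self.tp + other.tp, self.fp + other.fp,
            self.fn + other.fn, self.tn + other.tn,
        )


def confusion_counts(truth: str, pred: str, cls: str) -> BinaryConfusion:
    """One-vs-rest counts of ``cls`` over all positions."""
    if len(truth) != len(pred):
        raise ValueError(f"length mismatch: truth {len(truth)} vs pred {len(pred)}")
    t = np.frombuffer(truth.encode(), dtype="S1") == cls.encode()
    p = np.frombuffer(pred.encode(), dtype="S1") == cls.encode()
    return BinaryConfusion(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
        tn=int(np.sum(~t & ~p)),
    )


def sensitivity(c: BinaryConfusion) -> Optional[float]:
    """TP / (TP + FN); UNDEFINED when the class is absent from truth."""
    d = c.tp + c.fn
    return UNDEFINED if d == 0 else c.tp / d


def specificity(c: BinaryConfusion) -> Optional[float]:
    """TN / (TN + FP); UNDEFINED when there are no negatives."""
    d = c.tn + c.fp
    return UNDEFINED if d == 0 else c.tn / d


def precision(c: BinaryConfusion) -> Optional[float]:
    """TP / (TP + FP); UNDEFINED when the class is never predicted."""
    d = c.tp + c.fp
    return UNDEFINED if d == 0 else c.tp / d


def gm(c: BinaryConfusion) -> Optional[float]:
    """Geometric mean of precision and sensitivity."""
    sen = sensitivity(c)
    if sen is UNDEFINED:
        return UNDEFINED
    if sen == 0.0:
        return 0.0
    pre = precision(c)
    if pre is UNDEFINED:
        return UNDEFINED
    return math.sqrt(pre * sen)


def agm(c: BinaryConfusion) -> Optional[float]:
    """Adjusted Geometric Mean (see module docstring)."""
    sen = sensitivity(c)
    if sen is UNDEFINED:  # class absent from ground truth
        return UNDEFINED
    if sen == 0.0:
        return 0.0
    g = gm(c)
    n_n = (c.tn + c.fp) / c.total
    if n_n == 0.0:  # no negatives: specificity term vanishes
        return g
    spe = specificity(c)
    if g is UNDEFINED or spe is UNDEFINED:
        return UNDEFINED
    return (g + spe * n_n) / (1.0 + n_n)


def f1(c: BinaryConfusion) -> Optional[float]:
    """Harmonic mean of precision and sensitivity."""
    pre, sen = precision(c), sensitivity(c)
    if pre is UNDEFINED or sen is UNDEFINED or (pre + sen) == 0.0:
        return UNDEFINED
    return 2.0 * pre * sen / (pre + sen)


def q_accuracy(truth: str, pred: str) -> float:
    """Overall per-residue accuracy (Q8 on SS8 strings, Q3 on SS3)."""
    if len(truth) != len(pred):
        raise ValueError(f"length mismatch: truth {len(truth)} vs pred {len(pred)}")
    if not truth:
        raise ValueError("q_accuracy of empty strings is undefined")
    t = np.frombuffer(truth.encode(), dtype="S1")
    p = np.frombuffer(pred.encode(), dtype="S1")
    return float(np.mean(t == p))


def macro_average(per_class: dict[str, Optional[float]]) -> tuple[Optional[float], int]:
    """Mean over classes with a defined value; returns (mean, n_included)."""
    vals = [v for v in per_class.values() if v is not UNDEFINED]
    if not vals:
        return UNDEFINED, 0
    return float(np.mean(vals)), len(vals)


@dataclass
class ClassMetrics:
    """All per-class scores for one structure state."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    precision: Optional[float]
    gm: Optional[float]
    agm: Optional[float]
    f1: Optional[float]
    support: int
    n_n: float

    @classmethod
    def from_confusion(cls, c: BinaryConfusion) -> "ClassMetrics":
        return cls(
            sensitivity=sensitivity(c),
            specificity=specificity(c),
            precision=precision(c),
            gm=gm(c),
            agm=agm(c),
            f1=f1(c),
            support=c.tp + c.fn,
            n_n=(c.tn + c.fp) / c.total if c.total else 0.0,
        )


@dataclass
class MetricReport:
    """Per-class and macro metrics over a prediction set."""

    per_class: dict[str, ClassMetrics]
    q_accuracy: float
    macro_agm: Optional[float]
    macro_agm_classes: int
    macro_f1: Optional[float]
    macro_f1_classes: int
    n_residues: int
    n_chains: int


def _pair_labels(
    records: Sequence[ProteinRecord],
    predictions: dict[str, PredictionRecord] | Sequence[PredictionRecord],
) -> list[tuple[str, str, str]]:
    """Align records with predictions by id -> (id, truth, predicted)."""
    if not isinstance(predictions, dict):
        predictions = {p.id: p for p in predictions}
    pairs = []
    for rec in records:
        if rec.ss8 is None:
            raise ValueError(f"record {rec.id} has no ss8 labels")
        if rec.id not in predictions:
            raise KeyError(f"no prediction for chain {rec.id!r}")
        pred = predictions[rec.id]
        labels = pred.labels8 if hasattr(pred, "labels8") else str(pred)
        if len(labels) != len(rec.ss8):
            raise ValueError(f"{rec.id}: prediction length {len(labels)} != {len(rec.ss8)}")
        pairs.append((rec.id, rec.ss8, labels))
    return pairs


def evaluate_residue_level(
    records: Sequence[ProteinRecord],
    predictions: dict[str, PredictionRecord] | Sequence[PredictionRecord],
    classes: Sequence[str] = SS8_STATES,
) -> MetricReport:
    """Pool confusions over all residues of all chains, then score.

    A class absent from both truth and prediction everywhere yields an
    UNDEFINED row (the dash of published comparison tables).
    """
    pairs = _pair_labels(records, predictions)
    truth = "".join(t for _, t, _ in pairs)
    pred = "".join(p for _, _, p in pairs)
    per_class = {
        cls: ClassMetrics.from_confusion(confusion_counts(truth, pred, cls))
        for cls in classes
    }
    macro_agm_v, n_agm = macro_average({k: m.agm for k, m in per_class.items()})
    macro_f1_v, n_f1 = macro_average({k: m.f1 for k, m in per_class.items()})
    return MetricReport(
        per_class=per_class,
        q_accuracy=q_accuracy(truth, pred),
        macro_agm=macro_agm_v,
        macro_agm_classes=n_agm,
        macro_f1=macro_f1_v,
        macro_f1_classes=n_f1,
        n_residues=len(truth),
        n_chains=len(pairs),
    )


#: metric selectors accepted by evaluate_sequence_level / the analysis layer
_SELECTORS: dict[str, Callable[[str, str], Optional[float]]] = {}


def _chain_metric(name: str, classes: Sequence[str]) -> Callable[[str, str], Optional[float]]:
    """Build a per-chain metric function from a selector name.

    Names: ``q8``, ``macro_agm``, ``macro_f1`` or ``<metric>:<class>``
    with metric in {agm, f1, gm, precision, recall/sensitivity,
    specificity}, e.g. ``agm:H``.
    """
    if name == "q8":
        return q_accuracy
    if name in ("macro_agm", "macro_f1"):
        fn = agm if name == "macro_agm" else f1
        def macro(truth: str, pred: str) -> Optional[float]:
            vals = {c: fn(confusion_counts(truth, pred, c)) for c in classes}
            return macro_average(vals)[0]
        return macro
    if ":" in name:
        metric_name, cls = name.split(":", 1)
        per_cls = {
            "agm": agm, "f1": f1, "gm": gm, "precision": precision,
            "recall": sensitivity, "sensitivity": sensitivity,
            "specificity": specificity,
        }[metric_name]
        return lambda truth, pred: per_cls(confusion_counts(truth, pred, cls))
    raise ValueError(f"unknown metric selector {name!r}")


def evaluate_sequence_level(
    records: Sequence[ProteinRecord],
    predictions: dict[str, PredictionRecord] | Sequence[PredictionRecord],
    metric: str = "macro_agm",
    classes: Sequence[str] = SS8_STATES,
) -> dict[str, Optional[float]]:
    """Compute the selected metric independently for every chain.

    UNDEFINED chain values are preserved (never imputed); downstream
    tests drop those chains pairwise.
    """
    fn = _chain_metric(metric, classes)
    pairs = _pair_labels(records, predictions)
    return {cid: fn(truth, pred) for cid, truth, pred in pairs}


# ------------------------------------------------------------- rendering

def _fmt(v: Optional[float], digits: int = 4) -> str:
    return "-" if v is UNDEFINED else f"{v:.{digits}f}"


def report_to_tsv(report: MetricReport) -> str:
    """Render a MetricReport as TSV with '-' for UNDEFINED entries."""
    lines = ["class\tsupport\tN_n\tsensitivity\tspecificity\tprecision\tGM\tAGM\tF1"]
    for cls, m in report.per_class.items():
        lines.append(
            f"{cls}\t{m.support}\t{m.n_n:.4f}\t{_fmt(m.sensitivity)}\t"
            f"{_fmt(m.specificity)}\t{_fmt(m.precision)}\t{_fmt(m.gm)}\t"
            f"{_fmt(m.agm)}\t{_fmt(m.f1)}"
        )
    lines.append("")
    lines.append(f"Q\t{report.q_accuracy:.4f}")
    lines.append(f"macro_AGM\t{_fmt(report.macro_agm)}\t({report.macro_agm_classes} classes)")
    lines.append(f"macro_F1\t{_fmt(report.macro_f1)}\t({report.macro_f1_classes} classes)")
    return "\n".join(lines) + "\n"


def report_to_json(report: MetricReport) -> str:
    obj = {
        "per_class": {
            cls: {
                "support": m.support,
                "n_n": m.n_n,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "precision": m.precision,
                "gm": m.gm,
                "agm": m.agm,
                "f1": m.f1,
            }
            for cls, m in report.per_class.items()
        },
        "q_accuracy": report.q_accuracy,
        "macro_agm": report.macro_agm,
        "macro_agm_classes": report.macro_agm_classes,
        "macro_f1": report.macro_f1,
        "macro_f1_classes": report.macro_f1_classes,
        "n_residues": report.n_residues,
        "n_chains": report.n_chains,
    }
    return json.dumps(obj, indent=2)
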