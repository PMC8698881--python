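"""Scoring a predicted correspondence against the native (true) one.

The confusion is counted per model-side element i = 1..m:

* **TP** — i is predicted to match its native partner;
* **TN** — i has no native partner and is (correctly) left unmatched;
* **FP** — i is matched to a wrong or nonexistent partner;
* **FN** — i has a native partner but is left unmatched.

Accuracy, precision, sensitivity and F-measure are reported as percentages.
A zero-denominator ratio is reported as 0 and flagged as undefined.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import NativeCorrespondence


@dataclass
class EvalReport:
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    precision: float
    sensitivity: float
    f_measure: float
    undefined: frozenset[str] = frozenset()

    def to_tsv(self) -> str:
        header = "tp\ttn\tfp\tfn\taccuracy\tprecision\tsensitivity\tf_measure"
        row = (
            f"{self.tp}\t{self.tn}\t{self.fp}\t{self.fn}\t"
            f"{self.accuracy:.2f}\t{self.precision:.2f}\t"
            f"{self.sensitivity:.2f}\t{self.f_measure:.2f}"
        )
        lines = [header, row]
        if self.undefined:
            lines.append("# undefined (zero denominator): " + ", ".join(sorted(self.undefined)))
        return "\n".join(lines) + "\n"

    def __str__(self) -> str:
        return (
            f"TP={self.tp} TN={self.tn} FP={self.fp} FN={self.fn} | "
            f"accuracy={self.accuracy:.2f}% precision={self.precision:.2f}% "
            f"sensitivity={self.sensitivity:.2f}% F={self.f_measure:.2f}%"
        )


def confusion(pred, native: NativeCorrespondence, m: int) -> tuple[int, int, int, int]:
    """Per-element confusion counts (tp, tn, fp, fn) over A-side 1..m."""
    pred_map = pred.as_dict()
    native_map = native.as_dict()
    if len(set(pred_map.values())) != len(pred_map):
        raise ValueError("prediction is not injective")
    for a in list(pred_map) + list(native_map):
        if a < 1 or a > m:
            raise ValueError(f"a_index {a} outside 1..{m}")
    tp = tn = fp = fn = 0
    for a in range(1, m + 1):
        want = native_map.get(a)
        got = pred_map.get(a)
        if got is None:
            if want is None:
                tn += 1
            else:
                fn += 1
        else:
            if got == want:
                tp += 1
            else:
                fp += 1
    return tp, tn, fp, fn


def metrics(tp: int, tn: int, fp: int, fn: int) -> EvalReport:
    """Accuracy / precision / sensitivity / F-measure as percentages."""
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("confusion counts are all zero")
    undefined: set[str] = set()

    accuracy = (tp + tn) / total * 100.0

    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        precision = 0.0
        undefined.add("precision")
    if tp + fn > 0:
        sensitivity = tp / (tp + fn)
    else:
        sensitivity = 0.0
        undefined.add("sensitivity")
    if precision + sensitivity > 0:
        f_measure = 2 * precision * sensitivity / (precision + sensitivity)
    else:
        f_measure = 0.0
        undefined.add("f_measure")

    return EvalReport(
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        accuracy=accuracy,
        precision=precision * 100.0,
        sensitivity=sensitivity * 100.0,
        f_measure=f_measure * 100.0,
        undefined=frozenset(undefined),
    )


def evaluate(pred, native: NativeCorrespondence, m: int) -> EvalReport:
    """Confusion + metrics in one call."""
    return metrics(*confusion(pred, native, m))
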