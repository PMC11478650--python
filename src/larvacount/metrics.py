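"""Counting accuracy, receptive-field arithmetic and detection diagnostics."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np

from .boxes import Box


@dataclass(frozen=True, slots=True)
class LayerSpec:
    """One convolutional layer: kernel size and stride."""

    kernel_size: int
    stride: int

    def __post_init__(self) -> None:
        if self.kernel_size < 1 or self.stride < 1:
            raise ValueError(f"kernel_size and stride must be >= 1, got {self!r}")


@dataclass(frozen=True)
class CountEvaluation:
    actual: int  # Ac, true number of objects
    detected: int  # Id, number the pipeline reported
    accuracy: float  # A, percent


def counting_accuracy(actual: int, detected: int) -> float:
    """Counting accuracy A = (Ac - |Id - Ac|) / Ac * 100.

    100 exactly when the counts agree; symmetric in over- vs undercounting;
    negative once the absolute error exceeds the true count.
    """
    if actual < 1:
        raise ValueError(f"actual count must be >= 1, got {actual}")
    return (actual - abs(detected - actual)) / actual * 100.0


def evaluate_count(actual: int, detected: int) -> CountEvaluation:
    return CountEvaluation(actual, detected, counting_accuracy(actual, detected))


def receptive_field(layers: Sequence[LayerSpec], r_out: int = 1) -> List[int]:
    """Receptive field trace of a convolutional stack.

    ``layers`` run from input to output.  Starting from a receptive field of
    ``r_out`` at the output, the recursion
    ``R_i = (R_{i+1} - 1) * stride_i + kernel_i`` is applied backwards; the
    returned list is ``[R_1, ..., R_n]`` with ``R_1`` the receptive field on
    the input image.
    """
    if r_out < 1:
        raise ValueError(f"r_out must be >= 1, got {r_out}")
    trace: List[int] = []
    r = r_out
    for layer in reversed(layers):
        r = (r - 1) * layer.stride + layer.kernel_size
        trace.append(r)
    trace.reverse()
    return trace


@dataclass(frozen=True)
class DetectionEvaluation:
    true_positives: int
    false_positives: int
    false_negatives: int
    precision: float
    recall: float
    precision_defined: bool
    recall_defined: bool

    def as_dict(self) -> Dict[str, float]:
        return {
            "true_positives": self.true_positives,
            "false_positives": self.false_positives,
            "false_negatives": self.false_negatives,
            "precision": self.precision,
            "recall": self.recall,
        }


def evaluate_detections(
    final_boxes: Sequence[Box],
    truth_boxes: Sequence[Box],
    match_radius_px: float = 5.0,
) -> DetectionEvaluation:
    """Localisation diagnostic: greedy one-to-one centre matching.

    Pairs are accepted in ascending centre distance while the distance is at
    most ``match_radius_px``; each box matches at most once.  Order of the
    inputs does not affect the result.  An undefined precision (no
    detections) or recall (no truth) is reported as 0 with its flag down.
    """
    n_f, n_t = len(final_boxes), len(truth_boxes)
    tp = 0
    if n_f and n_t:
        fc = np.array([b.center for b in final_boxes])
        tc = np.array([b.center for b in truth_boxes])
        d = np.hypot(fc[:, 0, None] - tc[None, :, 0], fc[:, 1, None] - tc[None, :, 1])
        order = np.argsort(d, axis=None, kind="stable")
        used_f = np.zeros(n_f, dtype=bool)
        used_t = np.zeros(n_t, dtype=bool)
        flat = d.ravel()
        for idx in order:
            if flat[idx] > match_radius_px:
                break
            i, j = divmod(int(idx), n_t)
            if used_f[i] or used_t[j]:
                continue
            used_f[i] = used_t[j] = True
            tp += 1
    fp = n_f - tp
    fn = n_t - tp
    precision_defined = n_f > 0
    recall_defined = n_t > 0
    return DetectionEvaluation(
        true_positives=tp,
        false_positives=fp,
        false_negatives=fn,
        precision=tp / n_f if precision_defined else 0.0,
        recall=tp / n_t if recall_defined else 0.0,
        precision_defined=precision_defined,
        recall_defined=recall_defined,
    )


def straddle_census(truth_boxes: Sequence[Box], grid) -> int:
    """Extra detections a no-dedup run incurs: for every truth box, the
    number of tiles it intersects minus one (a corner straddle counts 3)."""
    extra = 0
    for box in truth_boxes:
        n_tiles = sum(1 for tile in grid if tile.bounds.intersects(box))
        extra += max(0, n_tiles - 1)
    return extra


def mean_accuracy(evaluations: Sequence[CountEvaluation]) -> float:
    if not evaluations:
        raise ValueError("mean_accuracy requires at least one evaluation")
    return float(np.mean([e.accuracy for e in evaluations]))
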