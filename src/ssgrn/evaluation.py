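"""Precision/recall scoring of predicted networks against a known truth.

Edges are directed (target, regulator) pairs scored by exact match: an edge
with the right endpoints but reversed direction counts as one false
positive plus one false negative.  Only topology is scored — the sign or
magnitude of the interaction plays no role.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Metrics:
    """Directed-edge confusion counts and derived fractions.

    ``precision`` is NaN (with a warning at computation time) when nothing
    was predicted: 0/0 is reported as undefined rather than silently 0 or 1,
    so threshold sweeps cannot paint misleading plateaus.
    """

    tp: int
    fp: int
    fn: int
    recall: float
    precision: float


def edges_of(obj) -> frozenset:
    """Coerce a network-ish object to a set of directed (target, regulator) pairs.

    Accepts anything with an ``edges()`` method (connectivity matrices,
    identified networks), an S-system parameter set (nonzero kinetic
    orders), a binary/real matrix (nonzero entries), or an iterable of
    index pairs.
    """
    if hasattr(obj, "edges"):
        return frozenset(obj.edges())
    if hasattr(obj, "G"):
        return frozenset((int(i), int(j)) for i, j in np.argwhere(np.asarray(obj.G) != 0))
    arr = np.asarray(obj)
    if arr.ndim == 2 and arr.shape[0] == arr.shape[1] and np.issubdtype(arr.dtype, np.number):
        return frozenset((int(i), int(j)) for i, j in np.argwhere(arr != 0))
    def _c(v):
        return int(v) if isinstance(v, (int, np.integer)) else v

    return frozenset((_c(i), _c(j)) for i, j in obj)


def precision_recall(predicted, truth) -> Metrics:
    """Score a predicted directed edge set against the true network.

    recall = TP / (TP + FN) — the fraction of true connections captured;
    precision = TP / (TP + FP) — the fraction of predictions that are real.
    """
    pred = edges_of(predicted)
    true = edges_of(truth)
    if not true:
        raise ValueError("truth edge set is empty; recall is undefined")
    tp = len(pred & true)
    fp = len(pred - true)
    fn = len(true - pred)
    recall = tp / (tp + fn)
    if tp + fp == 0:
        warnings.warn("empty prediction: precision is undefined (0/0)", stacklevel=2)
        precision = float("nan")
    else:
        precision = tp / (tp + fp)
    return Metrics(tp=tp, fp=fp, fn=fn, recall=recall, precision=precision)
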