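"""Distinguishing immediate from delayed effects across history lengths.

Local storage and transfer signals condition on a finite k-step past, so a
prominent past event produces a spurious "echo" at the step where it drops
out of the conditioned window.  Such an echo moves forward by exactly s
steps when k grows by s; a feature caused by the concurrent abundance
transition stays put.  Computing a signal at three equally spaced history
lengths therefore separates the two: features recurring at t, t+s, t+2s
are *delayed* (artefactual echoes), features stable at t across all
history lengths are *immediate*.

Feature detection itself is simple change-point picking on the signal's
first difference; the threshold (nats) and matching tolerance (steps) are
free parameters of the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .measures import LocalSignal

__all__ = [
    "Feature",
    "KVariantSet",
    "EffectAnnotation",
    "detect_features",
    "classify_effects",
    "filtered_signal",
]

LABELS = ("immediate", "delayed", "ambiguous", "none")


@dataclass(frozen=True)
class Feature:
    """A sharp change in a local signal: 1-based step of the strongest first
    difference in a merged group, its sign, magnitude, and group extent."""

    step: int
    polarity: int
    magnitude: float
    start: int
    end: int


@dataclass
class KVariantSet:
    """One measure computed at three equally spaced history lengths."""

    measure: str
    species: str
    signals: list[LocalSignal]

    def __post_init__(self):
        ks = [s.k for s in self.signals]
        if sorted(ks) != ks or len(ks) != 3:
            raise ValueError("need exactly three signals ordered by increasing k")
        if ks[1] - ks[0] != ks[2] - ks[1]:
            raise ValueError(f"history lengths {ks} must be equally spaced")

    @property
    def spacing(self) -> int:
        return self.signals[1].k - self.signals[0].k


@dataclass
class EffectAnnotation:
    """Per-time-step effect labels on the smallest-k signal's timeline."""

    labels: np.ndarray  # array of strings from LABELS, length T
    shift: Optional[int]  # matched shift s of delayed features, if any
    features: dict[str, list[Feature]] = field(default_factory=dict)


def detect_features(signal: LocalSignal, threshold: float) -> list[Feature]:
    """Find sharp changes in a signal's first difference.

    Steps whose first difference exceeds ``threshold`` in magnitude are
    feature candidates; adjacent candidates (within one step) of the same
    polarity merge into a single feature located at the strongest
    difference.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    steps = signal.steps()
    vals = signal.values[steps - 1]
    if steps.size < 2:
        return []
    diff = np.diff(vals)
    dsteps = steps[1:]
    cand = np.flatnonzero(np.abs(diff) > threshold)
    features: list[Feature] = []
    group: list[int] = []

    def flush(group):
        if not group:
            return
        best = max(group, key=lambda i: abs(diff[i]))
        features.append(Feature(
            step=int(dsteps[best]),
            polarity=int(np.sign(diff[best])),
            magnitude=float(abs(diff[best])),
            start=int(dsteps[group[0]]),
            end=int(dsteps[group[-1]]),
        ))

    for i in cand:
        if group and dsteps[i] - dsteps[group[-1]] <= 2 and np.sign(diff[i]) == np.sign(diff[group[-1]]):
            group.append(i)
        else:
            flush(group)
            group = [i]
    flush(group)
    return features


def _match(features: list[Feature], step: int, polarity: int, tolerance: int) -> Optional[Feature]:
    hits = [f for f in features if f.polarity == polarity and abs(f.step - step) <= tolerance]
    if not hits:
        return None
    return min(hits, key=lambda f: abs(f.step - step))


def classify_effects(
    kset: KVariantSet,
    threshold: float = 0.5,
    tolerance: int = 1,
) -> EffectAnnotation:
    """Label each feature of the smallest-k signal as immediate or delayed.

    A feature at step t is *delayed* when same-polarity features recur at
    t+s in the middle-k signal and t+2s in the largest-k signal (s = the k
    spacing); *immediate* when features recur at t in all three signals;
    *ambiguous* when both patterns match; *none* otherwise.  Ambiguity is
    never resolved by guessing.
    """
    s = kset.spacing
    feats = [detect_features(sig, threshold) for sig in kset.signals]
    T = kset.signals[0].n_steps
    labels = np.array(["none"] * T, dtype=object)
    shift: Optional[int] = None
    ann_features: dict[str, list[Feature]] = {lab: [] for lab in LABELS}
    for f in feats[0]:
        d2 = _match(feats[1], f.step + s, f.polarity, tolerance)
        d3 = _match(feats[2], f.step + 2 * s, f.polarity, tolerance)
        i2 = _match(feats[1], f.step, f.polarity, tolerance)
        i3 = _match(feats[2], f.step, f.polarity, tolerance)
        delayed = d2 is not None and d3 is not None
        immediate = i2 is not None and i3 is not None
        if delayed and immediate:
            label = "ambiguous"
        elif delayed:
            label = "delayed"
            shift = d2.step - f.step
        elif immediate:
            label = "immediate"
        else:
            label = "none"
        ann_features[label].append(f)
        if label != "none":
            lo, hi = f.start, f.end
            if label in ("delayed", "ambiguous") and d2 is not None and d3 is not None:
                hi = max(hi, d3.end)  # echo extent spans the shifted recurrences
            labels[lo - 1:hi] = label
    return EffectAnnotation(labels=labels, shift=shift, features=ann_features)


def filtered_signal(signal: LocalSignal, annotation: EffectAnnotation) -> LocalSignal:
    """Mask delayed and ambiguous segments of a signal.

    Masked steps stay valid and keep their values; downstream consumers
    (plots, summaries) render them as unreliable, mirroring dotted-line
    conventions for superposed echoes.
    """
    masked = np.isin(annotation.labels, ("delayed", "ambiguous"))
    if masked.size != signal.values.size:
        raise ValueError("annotation and signal lengths differ")
    return replace(signal, masked=signal.masked | masked)
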