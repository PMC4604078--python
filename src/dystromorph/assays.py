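"""Scalar assay metrics: object recognition, grip strength, ex vivo force.

Small, exactly specified arithmetic with input checking:

* discrimination index = 100 * novel / (novel + familiar), so 50 is chance;
* grip strength = mean of the (by default two) trial maxima;
* twitch / tetanic force = tallest baseline-corrected peak across the
  repeated traces of each stimulus kind, normalized to muscle wet weight
  (N/g).  The baseline is the median of the pre-stimulus window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class AssayError(ValueError):
    pass


@dataclass
class ForceTrace:
    time_s: np.ndarray
    force_n: np.ndarray
    kind: str                      # "twitch" or "tetanus"
    wet_weight_g: float
    baseline_window_s: float = 0.05   # pre-stimulus span used for the baseline

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.force_n = np.asarray(self.force_n, dtype=float)
        if self.kind not in {"twitch", "tetanus"}:
            raise AssayError(f"unknown stimulus kind {self.kind!r}")
        if self.wet_weight_g <= 0:
            raise AssayError("wet weight must be positive")
        if self.time_s.shape != self.force_n.shape or self.time_s.size < 2:
            raise AssayError("trace needs matching time/force arrays, n >= 2")


def discrimination_index(novel: float, familiar: float) -> float:
    """Percent of total exploration spent on the novel object."""
    if novel < 0 or familiar < 0:
        raise AssayError("exploration measures must be non-negative")
    total = novel + familiar
    if total == 0:
        raise AssayError("no exploration at all; index undefined")
    return 100.0 * novel / total


def grip_strength(trial_forces: list[float], expected_trials: int = 2) -> float:
    """Mean of the per-trial maximal forces."""
    if len(trial_forces) != expected_trials:
        raise AssayError(
            f"expected {expected_trials} trials, got {len(trial_forces)}")
    return float(np.mean(trial_forces))


def peak_force(trace: ForceTrace) -> float:
    """Baseline-corrected peak of one trace, in N."""
    pre = trace.force_n[trace.time_s <= trace.time_s[0] + trace.baseline_window_s]
    baseline = float(np.median(pre)) if pre.size else float(trace.force_n[0])
    return float(trace.force_n.max() - baseline)


def force_summary(traces: list[ForceTrace]) -> dict[str, float]:
    """Max twitch / tetanus specific force in N/g across repeated traces.

    Per stimulus kind, the tallest baseline-corrected peak over its traces
    divided by wet weight.  A kind with no traces is absent from the
    result, not reported as zero.
    """
    if not traces:
        raise AssayError("no traces")
    weights = {t.wet_weight_g for t in traces}
    if len(weights) > 1:
        raise AssayError("traces come from muscles of different wet weights")
    out: dict[str, float] = {}
    for kind in ("twitch", "tetanus"):
        peaks = [peak_force(t) for t in traces if t.kind == kind]
        if peaks:
            out[kind] = max(peaks) / traces[0].wet_weight_g
    return out
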