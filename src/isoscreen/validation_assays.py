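"""Deterministic arithmetic behind the follow-up validation figures:
competitive sgRNA depletion normalization, relative qPCR expression
(delta-delta-Ct), ChIP percent-input recovery, and promoter-luciferase
normalization to empty-vector controls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "DepletionSeries",
    "competitive_depletion_normalize",
    "delta_delta_ct",
    "percent_input",
    "luciferase_normalize",
]


@dataclass(frozen=True)
class DepletionSeries:
    """Marker-positive fraction over time for one arm of a competition assay."""

    timepoints: tuple[float, ...]
    fraction_positive: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.timepoints) != len(self.fraction_positive):
            raise ValueError("timepoints and fractions differ in length")
        if not self.timepoints:
            raise ValueError("need at least one timepoint")
        if any(not 0 <= f <= 1 for f in self.fraction_positive):
            raise ValueError("fractions must lie in [0, 1]")


def competitive_depletion_normalize(
    ko: DepletionSeries, wt: DepletionSeries
) -> list[float]:
    """Knockout-arm depletion relative to wild-type, anchored at 100%.

    r_t = ko_t / wt_t, reported as 100 * r_t / r_first so the first
    timepoint is by definition 100%.
    """
    if ko.timepoints != wt.timepoints:
        raise ValueError("ko and wt series have mismatched timepoints")
    if any(f == 0 for f in wt.fraction_positive):
        raise ValueError("wild-type fraction of 0 makes the ratio undefined")
    ratios = [k / w for k, w in zip(ko.fraction_positive, wt.fraction_positive)]
    anchor = ratios[0]
    if anchor == 0:
        raise ValueError("first-timepoint ratio is 0; cannot anchor at 100%")
    return [100.0 * r / anchor for r in ratios]


def delta_delta_ct(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression fold change, 2^-((dCt_sample) - (dCt_control))."""
    values = (ct_target_sample, ct_ref_sample, ct_target_control, ct_ref_control)
    if not all(np.isfinite(v) for v in values):
        raise ValueError("all Ct values must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_control - ct_ref_control)
    return float(2.0 ** (-ddct))


def percent_input(ct_input: float, ct_ip: float, input_fraction: float) -> float:
    """ChIP recovery as percent of input chromatin.

    percent = 100 * input_fraction * 2^(ct_input - ct_ip).  The input
    fraction enters multiplicatively (equivalent to the usual Ct-offset
    convention of subtracting log2(1/fraction) from ct_input).
    """
    if not 0 < input_fraction <= 1:
        raise ValueError("input_fraction must be in (0, 1]")
    if not (np.isfinite(ct_input) and np.isfinite(ct_ip)):
        raise ValueError("Ct values must be finite")
    return float(100.0 * input_fraction * 2.0 ** (ct_input - ct_ip))


def luciferase_normalize(
    signals: Sequence[float], empty_vector_signals: Sequence[float]
) -> tuple[float, list[float]]:
    """Promoter activity as fold over empty-vector controls.

    Returns ``(fold, per_replicate_folds)`` where fold is the ratio of the
    arithmetic means and the per-replicate values are each signal divided
    by the control mean.
    """
    if not signals or not empty_vector_signals:
        raise ValueError("need at least one signal and one control")
    control_mean = float(np.mean(empty_vector_signals))
    if control_mean <= 0:
        raise ValueError("empty-vector control mean must be > 0")
    per_rep = [float(s) / control_mean for s in signals]
    return float(np.mean(signals)) / control_mean, per_rep
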