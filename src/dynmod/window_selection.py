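"""Data-driven sliding-window length selection and the instantaneous-configuration
extrapolation.

Short windows give noisy correlation estimates and therefore noisy Q*; long
windows average over state switches.  The selection rule scans candidate
window lengths, computes the standard deviation of Q* pooled over every
window of every subject, expresses each length's sd as a percentage above
the sd at the reference length (half the available volumes), and picks the
smallest odd length at which that relative excess falls to a cutoff
(default 10%).

The "instantaneous" proportion of 2-module configurations is estimated by
fitting a straight line to log10(proportion) versus log10(length) over the
reliable lengths and reading off the intercept (log10 L = 0), i.e. the
extrapolated proportion at a window of one volume, reported as a percentage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .signed_modularity import detect_modules
from .synthetic_bold import RoiTimeSeries
from .windows import WindowConfig, dynamic_graphs

__all__ = [
    "QstarVarianceCurve",
    "ModuleCountCurve",
    "qstar_variance_curve",
    "select_window",
    "module_count_curve",
    "powerlaw_intercept",
]


@dataclass
class QstarVarianceCurve:
    """Pooled sd of Q* per window length, relative to the reference length."""

    window_lengths: list
    sd_qstar: list
    relative_variance_pct: list
    reference_length: int

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.window_lengths, self.window_lengths[1:])):
            raise ValueError("window lengths must be strictly increasing")


@dataclass
class ModuleCountCurve:
    """Per-length distribution of detected module counts, pooled over all graphs."""

    window_lengths: list
    proportions: dict  # length -> {module_count: proportion}

    def __post_init__(self) -> None:
        for length in self.window_lengths:
            total = sum(self.proportions[length].values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"proportions at length {length} sum to {total}, not 1")


def _qstars_at_length(
    cohort: Sequence[RoiTimeSeries],
    length: int,
    rng: np.random.Generator,
    n_restarts: int,
    stride: int,
) -> tuple:
    qs = []
    counts = []
    # even lengths are allowed in the scans (the reference length floor(T/2)
    # may be even): centering is irrelevant when pooling Q*, so the odd-length
    # constraint of WindowConfig is bypassed here
    config = object.__new__(WindowConfig)
    object.__setattr__(config, "length_volumes", length)
    object.__setattr__(config, "stride_volumes", stride)
    for ts in cohort:
        for graph in dynamic_graphs(ts, config).graphs:
            part = detect_modules(graph, n_restarts=n_restarts, seed=rng)
            qs.append(part.qstar)
            counts.append(part.n_modules)
    return np.asarray(qs), np.asarray(counts)


def qstar_variance_curve(
    cohort: Sequence[RoiTimeSeries],
    lengths: Sequence[int],
    seed: int = 0,
    n_restarts: int = 10,
    stride: int = 1,
) -> QstarVarianceCurve:
    """Standard deviation of Q* across all cohort graphs, per window length.

    The reference length is half the series length (floor(T/2)); it is added
    to the scan automatically if absent.  The relative curve is
    ``100 * (sd(L) / sd(reference) - 1)``.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    T = cohort[0].n_volumes
    reference = T // 2
    lengths = sorted(set(int(x) for x in lengths) | {reference})
    if lengths[-1] > T:
        raise ValueError(f"window length {lengths[-1]} exceeds series length {T}")
    rng = np.random.default_rng(seed)
    sds = []
    for length in lengths:
        qs, _ = _qstars_at_length(cohort, length, rng, n_restarts, stride)
        sds.append(float(qs.std(ddof=1)) if qs.size > 1 else 0.0)
    ref_sd = sds[lengths.index(reference)]
    if ref_sd > 0:
        rel = [100.0 * (sd / ref_sd - 1.0) for sd in sds]
    else:
        rel = [0.0 for _ in sds]
    return QstarVarianceCurve(
        window_lengths=list(lengths),
        sd_qstar=sds,
        relative_variance_pct=rel,
        reference_length=reference,
    )


def select_window(curve: QstarVarianceCurve, cutoff_pct: float = 10.0) -> int:
    """Smallest odd window length whose relative Q* variance is at or below the cutoff.

    Scans the curve in increasing length order; the first length meeting the
    cutoff defines the crossing, and the first odd length at or after it is
    returned.  Raises if no length qualifies.
    """
    if not curve.window_lengths:
        raise ValueError("curve is empty")
    crossing = None
    for length, rel in zip(curve.window_lengths, curve.relative_variance_pct):
        if rel <= cutoff_pct:
            crossing = length
            break
    if crossing is None:
        raise ValueError(f"no window length reaches relative Q* variance <= {cutoff_pct}%")
    for length in curve.window_lengths:
        if length >= crossing and length % 2 == 1:
            return length
    # no odd length at/after the crossing in the scanned set: parity-adjust up
    return crossing + 1


def module_count_curve(
    cohort: Sequence[RoiTimeSeries],
    lengths: Sequence[int],
    seed: int = 0,
    n_restarts: int = 10,
    stride: int = 1,
) -> ModuleCountCurve:
    """Distribution of detected module counts per window length, pooled over the cohort."""
    if not cohort:
        raise ValueError("cohort must be non-empty")
    T = cohort[0].n_volumes
    lengths = sorted(set(int(x) for x in lengths))
    if lengths[-1] > T:
        raise ValueError(f"window length {lengths[-1]} exceeds series length {T}")
    rng = np.random.default_rng(seed)
    proportions = {}
    for length in lengths:
        _, counts = _qstars_at_length(cohort, length, rng, n_restarts, stride)
        uniq, tallies = np.unique(counts, return_counts=True)
        proportions[length] = {int(m): float(c) / counts.size for m, c in zip(uniq, tallies)}
    return ModuleCountCurve(window_lengths=list(lengths), proportions=proportions)


def powerlaw_intercept(
    curve: ModuleCountCurve,
    fit_range: Sequence[int] | None = None,
    target_count: int = 2,
) -> float:
    """Extrapolated percentage of ``target_count``-module graphs at log10(L) = 0.

    Ordinary least squares of log10(proportion) on log10(length) over
    ``fit_range`` (default: odd lengths 11-49 present in the curve); returns
    ``100 * 10**intercept``.  A zero proportion anywhere in the fit range is
    an error because its log is undefined.
    """
    if fit_range is None:
        fit_range = [x for x in curve.window_lengths if 11 <= x <= 49 and x % 2 == 1]
    fit_range = sorted(int(x) for x in fit_range)
    if len(fit_range) < 2:
        raise ValueError("fit range must contain at least 2 window lengths")
    props = []
    for length in fit_range:
        if length not in curve.proportions:
            raise ValueError(f"window length {length} not present in curve")
        p = curve.proportions[length].get(target_count, 0.0)
        if p <= 0:
            raise ValueError(
                f"proportion of {target_count}-module graphs at length {length} is zero; "
                "log-log fit undefined"
            )
        props.append(p)
    slope, intercept = np.polyfit(np.log10(fit_range), np.log10(props), 1)
    return float(100.0 * 10.0**intercept)
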