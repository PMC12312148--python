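"""FRAP analysis: half-time estimation, diffusion coefficients, group comparison.

A bleached circular region of interest (ROI) of radius r refills by lateral
diffusion. After normalizing a trace to its pre-bleach mean, the half-recovery
time t_1/2 is read off as the post-bleach sample closest to the midpoint
between the intensity directly after bleaching (I0) and the final intensity
(I_inf). The lateral diffusion coefficient follows from the uniform-disk
relation

    D = 0.224 · r² / t_1/2

and the mobile (recovered) fraction from

    R = (I_inf − I0) / (I_pre − I0).

Populations measured inside vs outside bright membrane domains are compared
through group means, the ratio of means, and a paired sign count.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "FrapTrace",
    "FrapResult",
    "GroupComparison",
    "normalize_trace",
    "estimate_half_time",
    "diffusion_coefficient",
    "recovery_fraction",
    "analyze_trace",
    "compare_groups",
    "HALF_TIME_CONSTANT",
]

#: D = HALF_TIME_CONSTANT * r^2 / t_half for a uniformly bleached disk.
HALF_TIME_CONSTANT = 0.224


@dataclass(frozen=True)
class FrapTrace:
    """Time–intensity record of one bleached ROI.

    ``bleach_index`` is the index of the first post-bleach sample; at least
    one pre-bleach sample must precede it.
    """

    time: np.ndarray
    intensity: np.ndarray
    bleach_index: int
    roi_radius_um: float
    label: str = ""
    vesicle_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "intensity", i)
        if t.ndim != 1 or i.shape != t.shape:
            raise ValueError("time and intensity must be 1D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if not 1 <= self.bleach_index < t.size:
            raise ValueError("bleach_index must leave >= 1 pre-bleach sample")
        if not 0 < self.roi_radius_um <= 10:
            raise ValueError("ROI radius must lie in (0, 10] um")


@dataclass(frozen=True)
class FrapResult:
    """Derived quantities for one trace; ``valid`` is False when the trace
    shows no recovery (I_inf <= I0), in which case t_half/D are NaN."""

    t_half: float
    D: float
    recovery_R: float
    i_pre: float
    i_0: float
    i_inf: float
    valid: bool = True
    label: str = ""
    vesicle_id: str = ""
    roi_radius_um: float = float("nan")


@dataclass(frozen=True)
class GroupComparison:
    mean_inside: float
    sd_inside: float
    n_inside: int
    mean_outside: float
    sd_outside: float
    n_outside: int
    ratio_outside_over_inside: float
    n_pairs: int = 0
    n_slower_inside: int = 0


def normalize_trace(trace: FrapTrace) -> FrapTrace:
    """Divide all intensities by the mean pre-bleach intensity.

    The normalized pre-bleach mean is exactly 1; normalization is idempotent.
    """
    pre = trace.intensity[: trace.bleach_index]
    mean_pre = float(np.mean(pre))
    if mean_pre <= 0:
        raise ValueError("pre-bleach mean must be positive")
    return replace(trace, intensity=trace.intensity / mean_pre)


def estimate_half_time(trace: FrapTrace) -> tuple[float, float, float]:
    """Half-recovery time and the (I0, I_inf) anchors of one trace.

    I0 is the first post-bleach sample, I_inf the last sample. t_half is the
    time, measured from the I0 sample, of the post-bleach sample whose
    intensity is nearest to (I0 + I_inf)/2; exact ties resolve to the
    earlier sample. No interpolation or asymptote fitting is performed.

    Returns NaN for t_half when the trace shows no recovery (I_inf <= I0).
    """
    post_t = trace.time[trace.bleach_index :]
    post_i = trace.intensity[trace.bleach_index :]
    if post_i.size < 3:
        raise ValueError("need at least 3 post-bleach samples")
    i0 = float(post_i[0])
    i_inf = float(post_i[-1])
    if i_inf <= i0:
        return float("nan"), i0, i_inf
    target = 0.5 * (i0 + i_inf)
    # argmin returns the first (earliest) index on ties
    k = int(np.argmin(np.abs(post_i - target)))
    return float(post_t[k] - post_t[0]), i0, i_inf


def diffusion_coefficient(roi_radius_um: float, t_half: float) -> float:
    """Uniform-disk diffusion coefficient D = 0.224 r² / t_half (μm²/s)."""
    if roi_radius_um <= 0 or t_half <= 0:
        raise ValueError("radius and half-time must be positive")
    return HALF_TIME_CONSTANT * roi_radius_um**2 / t_half


def recovery_fraction(i_pre: float, i_0: float, i_inf: float) -> float:
    """Mobile fraction R = (I_inf − I0)/(I_pre − I0); requires I_pre ≠ I0."""
    if i_pre == i_0:
        raise ValueError("recovery undefined when I_pre equals I0")
    return (i_inf - i_0) / (i_pre - i_0)


def analyze_trace(trace: FrapTrace) -> FrapResult:
    """Full single-trace pipeline: normalize, half-time, D, recovery."""
    norm = normalize_trace(trace)
    i_pre = float(np.mean(norm.intensity[: norm.bleach_index]))
    t_half, i0, i_inf = estimate_half_time(norm)
    if not np.isfinite(t_half) or t_half <= 0:
        return FrapResult(
            t_half=float("nan"),
            D=float("nan"),
            recovery_R=float("nan"),
            i_pre=i_pre,
            i_0=i0,
            i_inf=i_inf,
            valid=False,
            label=trace.label,
            vesicle_id=trace.vesicle_id,
            roi_radius_um=trace.roi_radius_um,
        )
    d = diffusion_coefficient(trace.roi_radius_um, t_half)
    r = recovery_fraction(i_pre, i0, i_inf)
    return FrapResult(
        t_half=t_half,
        D=d,
        recovery_R=r,
        i_pre=i_pre,
        i_0=i0,
        i_inf=i_inf,
        valid=True,
        label=trace.label,
        vesicle_id=trace.vesicle_id,
        roi_radius_um=trace.roi_radius_um,
    )


def compare_groups(
    inside: Sequence[FrapResult],
    outside: Sequence[FrapResult],
    pairs: Sequence[tuple[FrapResult, FrapResult]] | None = None,
) -> GroupComparison:
    """Summarize inside-domain vs outside-domain diffusion.

    Reports per-group mean and sample standard deviation of D, the ratio of
    the outside mean over the inside mean, and — if ``pairs`` of
    (inside, outside) results from the same vesicle are supplied — the
    number of pairs with strictly slower diffusion inside.
    """
    if len(inside) == 0 or len(outside) == 0:
        raise ValueError("both groups must be nonempty")
    d_in = np.array([r.D for r in inside], dtype=float)
    d_out = np.array([r.D for r in outside], dtype=float)
    mean_in = float(np.mean(d_in))
    mean_out = float(np.mean(d_out))
    sd_in = float(np.std(d_in, ddof=1)) if d_in.size > 1 else 0.0
    sd_out = float(np.std(d_out, ddof=1)) if d_out.size > 1 else 0.0
    n_pairs = 0
    n_slower = 0
    if pairs:
        n_pairs = len(pairs)
        n_slower = sum(1 for rin, rout in pairs if rin.D < rout.D)
    return GroupComparison(
        mean_inside=mean_in,
        sd_inside=sd_in,
        n_inside=len(inside),
        mean_outside=mean_out,
        sd_outside=sd_out,
        n_outside=len(outside),
        ratio_outside_over_inside=mean_out / mean_in,
        n_pairs=n_pairs,
        n_slower_inside=n_slower,
    )
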