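"""Per-run feature extraction from turbidity growth curves.

A turbidimetric polymerization assay records optical density (O.D.) against
time as tubulin assembles into microtubules; the trace is sigmoidal, with a
nucleation lag, a growth phase and a saturation plateau.  This module turns
one such trace into the scalar features used for cohort comparison:

* ``od_final`` — the raw plateau optical density,
* ``t10`` / ``t50`` — times at which the normalized curve first reaches
  10% / 50% of its plateau,
* ``b`` and ``A`` — the exponent and amplitude of the early-phase power law
  ``O.D.(t) = A * (t / t_u)**b``, estimated as the slope and intercept of an
  ordinary least-squares line on ln(O.D.) versus ln(t) over the part of the
  normalized curve lying between 0.1 and 0.4.

It also implements the *time-stretching* transform: rescaling one group's
time axis so that the t50 of its average curve matches that of a reference
group.  Stretching changes crossing times but, because a log-log slope is
invariant under a rescaling of the abscissa, it can never change ``b``;
comparing stretched t10 values therefore tests whether two conditions share
a curve *shape* independently of their overall rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .errors import (
    DegenerateTraceError,
    InputError,
    InsufficientWindowError,
    TraceRejected,
    UndefinedCrossingError,
)

__all__ = [
    "Trace",
    "RunFeatures",
    "PowerLawFit",
    "StretchResult",
    "screen_trace",
    "normalize_trace",
    "crossing_time",
    "fit_power_law",
    "extract_features",
    "mean_curve",
    "stretch_time",
]


@dataclass
class Trace:
    """One run's sampled (time, optical density[, temperature]) series.

    Times are in seconds and must be strictly increasing; optical density is
    in absorbance units at the instrument wavelength; temperature, when
    present, is in degrees Celsius and sampled at the same instants.
    """

    times: np.ndarray
    od: np.ndarray
    temperature: Optional[np.ndarray] = None
    condition_label: str = ""
    run_id: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.ndim != 1 or self.times.size == 0:
            raise InputError("times must be a non-empty 1-D array")
        if self.od.shape != self.times.shape:
            raise InputError("od and times must have the same length")
        if not np.all(np.diff(self.times) > 0):
            raise InputError("times must be strictly increasing")
        if self.temperature is not None:
            self.temperature = np.asarray(self.temperature, dtype=float)
            if self.temperature.shape != self.times.shape:
                raise InputError("temperature and times must have the same length")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class PowerLawFit:
    """Result of the early-phase log-log regression."""

    b: float
    A: float
    fit_n: int
    fit_r2: float
    t_u: float = 1.0


@dataclass
class RunFeatures:
    """Scalar summary of one growth curve (one table row per run)."""

    od_final: float
    t10: float
    t50: float
    b: float
    A: float
    fit_n: int
    fit_r2: float
    t_u: float = 1.0
    run_id: str = ""
    condition_label: str = ""


def _plateau(od: np.ndarray, tail_frac: float = 0.05, min_tail: int = 3) -> float:
    """Mean of the last ``tail_frac`` of samples (at least ``min_tail``)."""
    k = max(min_tail, int(math.ceil(tail_frac * od.size)))
    k = min(k, od.size)
    return float(np.mean(od[-k:]))


def screen_trace(trace: Trace) -> Trace:
    """Screen a raw trace for recording artifacts before analysis.

    Bubbles in the light path either end a recording early (a non-finite
    tail) or produce a short, isolated O.D. excursion far above the local
    curve.  Rejection reasons:

    ``incomplete``
        all non-finite values form a contiguous tail;
    ``nonfinite``
        non-finite values elsewhere in the trace;
    ``spike``
        some sample deviates from a 7-point rolling median by more than
        five times the median absolute inter-sample step.  A monotone curve
        deviates from its own rolling median by exactly zero, so clean
        sigmoids — noiseless or noisy — pass this test.

    Returns the trace unchanged when clean; raises :class:`TraceRejected`
    otherwise.
    """
    od = trace.od
    finite = np.isfinite(od)
    if not finite.all():
        first_bad = int(np.argmax(~finite))
        if (~finite[first_bad:]).all():
            raise TraceRejected("incomplete", trace.run_id)
        raise TraceRejected("nonfinite", trace.run_id)
    if od.size >= 3:
        steps = np.abs(np.diff(od))
        med_step = float(np.median(steps))
        rolling = ndimage.median_filter(od, size=7, mode="nearest")
        if np.any(np.abs(od - rolling) > 5.0 * med_step):
            raise TraceRejected("spike", trace.run_id)
    return trace


def normalize_trace(trace: Trace, head: int = 3, tail_frac: float = 0.05) -> Trace:
    """Rescale a trace so it starts at ~0 and plateaus at ~1.

    The baseline is the mean of the first ``head`` samples and the plateau
    the mean of the last ``tail_frac`` of samples (at least three); the
    transform is ``od' = (od - od_i) / (od_f - od_i)``.  Affine changes of
    the O.D. axis therefore leave the result unchanged, and normalizing an
    already-normalized trace is a no-op up to edge averaging.
    """
    od = trace.od
    od_i = float(np.mean(od[: min(head, od.size)]))
    od_f = _plateau(od, tail_frac=tail_frac)
    span = od_f - od_i
    if span <= 1e-9 * max(1.0, abs(od_f), abs(od_i)):
        raise DegenerateTraceError(
            f"flat trace: plateau {od_f:.4g} indistinguishable from baseline {od_i:.4g}"
            + (f" [run {trace.run_id}]" if trace.run_id else "")
        )
    return replace(trace, od=(od - od_i) / span)


def crossing_time(trace: Trace, fraction: float) -> float:
    """Time of the first upward crossing of ``fraction`` on a normalized trace.

    The crossing is linearly interpolated between the two bracketing
    samples, which makes the estimate independent of the sampling rate for
    smooth curves.
    """
    if not 0.0 < fraction < 1.0:
        raise InputError("fraction must lie strictly between 0 and 1")
    od, t = trace.od, trace.times
    if od[0] >= fraction:
        return float(t[0])
    below = od[:-1] < fraction
    above = od[1:] >= fraction
    hits = np.flatnonzero(below & above)
    if hits.size == 0:
        raise UndefinedCrossingError(
            f"trace never reaches fraction {fraction:g}"
            + (f" [run {trace.run_id}]" if trace.run_id else "")
        )
    i = int(hits[0])
    frac = (fraction - od[i]) / (od[i + 1] - od[i])
    return float(t[i] + frac * (t[i + 1] - t[i]))


def fit_power_law(
    trace: Trace,
    window_lo: float = 0.1,
    window_hi: float = 0.4,
    t_u: float = 1.0,
) -> PowerLawFit:
    """Fit the early-phase power law on a normalized trace.

    Ordinary least squares of ``ln(od)`` on ``ln(t / t_u)`` over the samples
    whose normalized O.D. lies in ``[window_lo, window_hi]`` (zero-time
    samples are excluded, since ln 0 is undefined).  The slope is the
    exponent ``b``; ``A = exp(intercept)``.  The unit time ``t_u`` only
    shifts the intercept and can never change the slope, and neither can a
    rescaling of the time axis — ``b`` is scale invariant.
    """
    if not 0.0 < window_lo < window_hi:
        raise InputError("require 0 < window_lo < window_hi")
    od, t = trace.od, trace.times
    mask = (od >= window_lo) & (od <= window_hi) & (t > 0) & (od > 0)
    n = int(mask.sum())
    if n < 3:
        raise InsufficientWindowError(
            f"only {n} samples with normalized O.D. in "
            f"[{window_lo:g}, {window_hi:g}]; need >= 3"
            + (f" [run {trace.run_id}]" if trace.run_id else "")
        )
    x = np.log(t[mask] / t_u)
    y = np.log(od[mask])
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    sxy = float(np.sum((x - xm) * (y - ym)))
    syy = float(np.sum((y - ym) ** 2))
    slope = sxy / sxx
    intercept = ym - slope * xm
    r2 = 1.0 if syy == 0.0 else (sxy * sxy) / (sxx * syy)
    return PowerLawFit(b=slope, A=math.exp(intercept), fit_n=n, fit_r2=r2, t_u=t_u)


def extract_features(
    trace: Trace,
    window_lo: float = 0.1,
    window_hi: float = 0.4,
    t_u: float = 1.0,
) -> RunFeatures:
    """Compute all per-run features from a (screened) raw trace.

    ``od_final`` is the plateau of the *raw* trace; ``t10``, ``t50`` and the
    power-law fit are computed on the normalized trace.
    """
    od_final = _plateau(trace.od)
    norm = normalize_trace(trace)
    t10 = crossing_time(norm, 0.10)
    t50 = crossing_time(norm, 0.50)
    fit = fit_power_law(norm, window_lo=window_lo, window_hi=window_hi, t_u=t_u)
    return RunFeatures(
        od_final=od_final,
        t10=t10,
        t50=t50,
        b=fit.b,
        A=fit.A,
        fit_n=fit.fit_n,
        fit_r2=fit.fit_r2,
        t_u=t_u,
        run_id=trace.run_id,
        condition_label=trace.condition_label,
    )


def mean_curve(traces: Sequence[Trace], normalize: bool = True) -> Trace:
    """Pointwise average of (normalized) traces on a common time grid.

    The grid spans the overlap of all traces with the median sampling step
    of the first trace; each trace is linearly interpolated onto it.
    """
    if len(traces) == 0:
        raise InputError("need at least one trace to average")
    curves = [normalize_trace(tr) if normalize else tr for tr in traces]
    t_lo = max(float(c.times[0]) for c in curves)
    t_hi = min(float(c.times[-1]) for c in curves)
    if t_hi <= t_lo:
        raise InputError("traces have no overlapping time range")
    dt = float(np.median(np.diff(curves[0].times)))
    grid = np.arange(t_lo, t_hi + 0.5 * dt, dt)
    grid = grid[grid <= t_hi]
    od = np.mean([np.interp(grid, c.times, c.od) for c in curves], axis=0)
    return Trace(times=grid, od=od, condition_label="mean")


@dataclass
class StretchResult:
    """Outcome of time-stretching a group onto a reference."""

    factor: float
    t50_reference: float
    t50_group: float
    features: Optional[list] = field(default=None)


def stretch_time(
    group: Sequence[Trace],
    reference: Sequence[Trace],
    group_features: Optional[Sequence[RunFeatures]] = None,
    mode: str = "mean_curve",
) -> StretchResult:
    """Stretch a group's time axis so its average-curve t50 matches a reference.

    ``mode="mean_curve"`` (default) takes t50 from the pointwise average of
    each group's normalized traces; ``mode="per_run"`` uses the mean of the
    per-run t50 values instead.  The stretch factor
    ``s = t50(reference) / t50(group)`` multiplies every crossing time of
    the group (t10 and t50 alike); the exponent ``b`` and ``od_final`` are
    untouched, since neither depends on the time scale.
    """
    if len(group) == 0 or len(reference) == 0:
        raise InputError("both groups must be non-empty")
    if mode == "mean_curve":
        t50_grp = crossing_time(mean_curve(group), 0.5)
        t50_ref = crossing_time(mean_curve(reference), 0.5)
    elif mode == "per_run":
        t50_grp = float(np.mean([crossing_time(normalize_trace(tr), 0.5) for tr in group]))
        t50_ref = float(np.mean([crossing_time(normalize_trace(tr), 0.5) for tr in reference]))
    else:
        raise InputError(f"unknown stretch mode {mode!r}")
    s = t50_ref / t50_grp
    stretched = None
    if group_features is not None:
        stretched = [replace(f, t10=f.t10 * s, t50=f.t50 * s) for f in group_features]
    return StretchResult(factor=s, t50_reference=t50_ref, t50_group=t50_grp,
                         features=stretched)
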