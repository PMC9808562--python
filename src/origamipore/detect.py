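"""Baseline estimation, 7-sigma event detection and feature extraction.

The detection rule mirrors standard resistive-pulse practice: a robust
per-sample baseline is estimated first, translocation events are the maximal
runs whose excursion from that baseline exceeds ``sigma_multiplier`` (default
7) times the noise standard deviation, and each event is extended outward to
the nearest samples where the excursion falls back below
``boundary_multiplier`` (default 1) sigma.  Per-event features are the dwell
time (ms), the peak current maximum (pA, from a lightly smoothed excursion;
see :func:`compute_event_features`) and the equivalent charge surplus (ECS,
pA*ms) — the signed trapezoidal integral of the baseline-subtracted peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .trace import TraceRecording

EVENT_COLUMNS = [
    "start_s",
    "end_s",
    "dwell_ms",
    "peak_max_pA",
    "ecs",
    "local_baseline_pA",
]

_MAD_SCALE = 1.4826  # MAD -> sigma for a normal distribution


@dataclass(frozen=True)
class DetectionConfig:
    """Detection thresholds and gates.

    ``sigma_multiplier`` is the detection threshold in noise sigmas (7 by
    convention for these measurements); ``boundary_multiplier`` sets the
    excursion level at which event boundaries are placed.  ``smoothing``
    is the boxcar width (ms) used for peak-amplitude measurement; 0
    disables it.  ``boundary_debounce`` is the quiet-run length (ms) a
    boundary search requires before declaring the excursion back at
    baseline: single noise dips below the boundary level do not terminate
    an event, which keeps the measured base width unbiased at the default
    noise floor.
    """

    sigma_multiplier: float = 7.0
    boundary_multiplier: float = 1.0
    baseline_window: float = 50.0  # ms
    min_duration: float = 0.1  # ms
    max_duration: float = 50.0  # ms
    min_separation: float = 0.2  # ms
    polarity: str = "positive"
    smoothing: float = 0.1  # ms
    boundary_debounce: float = 0.05  # ms

    def __post_init__(self) -> None:
        if not self.sigma_multiplier > self.boundary_multiplier > 0:
            raise ValueError("need sigma_multiplier > boundary_multiplier > 0")
        if not self.min_duration < self.max_duration:
            raise ValueError("need min_duration < max_duration")
        if self.polarity not in ("positive", "negative"):
            raise ValueError("polarity must be 'positive' or 'negative'")

    @property
    def sign(self) -> float:
        return 1.0 if self.polarity == "positive" else -1.0


@dataclass
class BaselineModel:
    """Per-sample baseline estimate with noise sigma and event mask."""

    baseline: np.ndarray
    sigma: float
    event_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if not np.all(np.isfinite(self.baseline)):
            raise ValueError("baseline must be finite everywhere")


@dataclass
class EventTable:
    """Detected translocation events for one trace.

    ``events`` is a DataFrame with columns ``start_s, end_s, dwell_ms,
    peak_max_pA, ecs, local_baseline_pA``, time-ordered and non-overlapping.
    """

    events: pd.DataFrame
    sample_label: str = ""
    trace_duration: float = 0.0

    def __post_init__(self) -> None:
        missing = [c for c in EVENT_COLUMNS if c not in self.events.columns]
        if missing:
            raise ValueError(f"event table missing columns: {missing}")

    @property
    def n(self) -> int:
        return len(self.events)

    def __len__(self) -> int:
        return len(self.events)


def estimate_baseline(trace: TraceRecording, config: DetectionConfig | None = None) -> BaselineModel:
    """Two-pass robust baseline and noise-sigma estimate.

    Pass 1 masks samples more than 3 sigma (global median / scaled MAD)
    beyond the baseline in the event polarity.  Pass 2 takes a moving median
    of the unmasked samples over ``baseline_window`` (evaluated on a
    half-window stride and linearly interpolated, which is indistinguishable
    from the dense moving median at the <2% event duty cycles this targets)
    and re-estimates sigma from the unmasked residuals via the scaled MAD.

    Raises
    ------
    ValueError
        If the trace is constant (sigma 0; inject a noise floor) or more
        than half the samples are masked (saturated trace).
    """
    config = config or DetectionConfig()
    x = trace.current
    s = config.sign
    med = float(np.median(x))
    sigma0 = _MAD_SCALE * float(np.median(np.abs(x - med)))
    if sigma0 == 0.0:
        raise ValueError(
            "trace noise sigma is zero (constant trace); detection thresholds are "
            "undefined — inject a noise floor or supply BaselineModel directly"
        )
    mask = s * (x - med) > 3.0 * sigma0
    if mask.mean() > 0.5:
        raise ValueError("more than 50% of samples masked as events; trace saturated")

    window = max(int(round(config.baseline_window * 1e-3 * trace.sampling_rate)), 2)
    baseline = _strided_median(x, mask, window)

    resid = (x - baseline)[~mask]
    sigma = _MAD_SCALE * float(np.median(np.abs(resid - np.median(resid))))
    if sigma == 0.0:
        raise ValueError("residual noise sigma is zero; inject a noise floor")
    return BaselineModel(baseline=baseline, sigma=sigma, event_mask=mask)


def _strided_median(x: np.ndarray, mask: np.ndarray, window: int) -> np.ndarray:
    """Moving median of unmasked samples, evaluated every window/2 samples
    and linearly interpolated (masked gaps interpolated across)."""
    n = x.size
    stride = max(window // 2, 1)
    centers, meds = [], []
    for c in range(0, n, stride):
        lo, hi = max(c - window // 2, 0), min(c + window // 2 + 1, n)
        seg = x[lo:hi][~mask[lo:hi]]
        if seg.size:
            centers.append(c)
            meds.append(np.median(seg))
    if not centers:
        raise ValueError("no unmasked samples available for baseline estimation")
    return np.interp(np.arange(n), centers, meds)


def _smoothed(exc: np.ndarray, config: DetectionConfig, sampling_rate: float) -> np.ndarray:
    w = int(round(config.smoothing * 1e-3 * sampling_rate))
    if w <= 1:
        return exc
    return ndimage.uniform_filter1d(exc, w, mode="nearest")


def detect_events(
    trace: TraceRecording, baseline: BaselineModel, config: DetectionConfig | None = None
) -> EventTable:
    """Threshold detection of translocation events.

    Candidate events are maximal runs of excursion >= ``sigma_multiplier *
    sigma``; each run is extended outward to the nearest quiet run
    (``boundary_debounce`` consecutive samples below ``boundary_multiplier *
    sigma``), whose inner end is the event boundary.  Events separated by
    less than ``min_separation`` are merged, and events outside the
    ``[min_duration, max_duration]`` window are discarded.  An empty result
    is a valid (empty) table.
    """
    config = config or DetectionConfig()
    fs = trace.sampling_rate
    exc = config.sign * (trace.current - baseline.baseline)
    exc_s = _smoothed(exc, config, fs)
    thr = config.sigma_multiplier * baseline.sigma
    bnd = config.boundary_multiplier * baseline.sigma

    core = exc >= thr
    if not core.any():
        return EventTable(_empty_events(), trace.label, trace.duration)

    starts, ends = _runs(core)  # inclusive sample indices of above-threshold runs

    # Boundary search with debounce: a boundary is the inner end of a quiet
    # run of >= k consecutive below-boundary samples on the raw excursion.
    k = max(int(round(config.boundary_debounce * 1e-3 * fs)), 1)
    if k > 1:
        mx_trail = ndimage.maximum_filter1d(exc, k, origin=(k - 1) // 2)
        mx_lead = ndimage.maximum_filter1d(exc, k, origin=-(k // 2))
    else:
        mx_trail = mx_lead = exc
    idx = np.arange(exc.size)
    last_below = np.maximum.accumulate(np.where(mx_trail < bnd, idx, -1))
    first_below = np.minimum.accumulate(np.where(mx_lead < bnd, idx, exc.size)[::-1])[::-1]
    # boundaries exclude the quiet samples themselves: the event spans the
    # first to the last above-boundary sample
    ev_start = last_below[starts] + 1  # 0 if never below before
    ev_end = first_below[ends] - 1  # n-1 if never below after
    ev_start = np.clip(ev_start, 0, exc.size - 1)
    ev_end = np.clip(ev_end, 0, exc.size - 1)

    # merge overlapping / closely spaced events
    min_sep = int(round(config.min_separation * 1e-3 * fs))
    merged: list[list[int]] = []
    for s0, e0 in zip(ev_start, ev_end):
        if merged and s0 - merged[-1][1] <= min_sep:
            merged[-1][1] = max(merged[-1][1], int(e0))
        else:
            merged.append([int(s0), int(e0)])

    rows = []
    for s0, e0 in merged:
        dwell = (e0 - s0) / fs * 1e3
        if not (config.min_duration <= dwell <= config.max_duration):
            continue
        rows.append(_features_from_excursion(exc, exc_s, baseline.baseline, s0, e0, fs))
    events = pd.DataFrame(rows, columns=EVENT_COLUMNS) if rows else _empty_events()
    return EventTable(events, trace.label, trace.duration)


def _runs(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start/end (inclusive) indices of True runs."""
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1)
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        ends = np.r_[ends, mask.size - 1]
    return starts, ends


def _features_from_excursion(exc, exc_s, baseline, i0, i1, fs) -> dict:
    sl = slice(i0, i1 + 1)
    dt_ms = 1e3 / fs
    return {
        "start_s": i0 / fs,
        "end_s": i1 / fs,
        "dwell_ms": (i1 - i0) * dt_ms,
        "peak_max_pA": float(np.max(exc_s[sl])),
        "ecs": float(np.trapezoid(exc[sl], dx=dt_ms)),
        "local_baseline_pA": float(np.mean(baseline[sl])),
    }


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=float) for c in EVENT_COLUMNS})


def compute_event_features(
    trace: TraceRecording,
    baseline: BaselineModel,
    start: float,
    end: float,
    config: DetectionConfig | None = None,
) -> dict:
    """Features of a single event on ``[start, end]`` (seconds).

    ``peak_max_pA`` is the maximum signed excursion of the boxcar-smoothed
    trace (window ``config.smoothing`` ms, far below any event duration):
    the raw per-sample maximum of a noisy excursion is biased upward by the
    expected extreme of the noise over the event window (~2 sigma), and the
    short smoother removes that bias without attenuating the pulse top.
    ``ecs`` is the signed trapezoidal integral of the *unsmoothed* excursion
    in pA*ms (zero-mean noise cancels in the integral, so no rectification
    is applied), and ``dwell_ms`` is ``(end - start) * 1000``.
    """
    config = config or DetectionConfig()
    fs = trace.sampling_rate
    if end <= start:
        raise ValueError("end must exceed start")
    i0 = int(round(start * fs))
    i1 = int(round(end * fs))
    if i1 - i0 < 1 or i0 < 0 or i1 >= trace.n_samples:
        raise ValueError("event interval must span at least 2 samples inside the trace")
    exc = config.sign * (trace.current - baseline.baseline)
    exc_s = _smoothed(exc, config, fs)
    return _features_from_excursion(exc, exc_s, baseline.baseline, i0, i1, fs)


def fit_gaussian_1d(values, bins="fd") -> tuple[float, float, float]:
    """Fit a single Gaussian to the histogram of ``values``.

    Histogram bins follow the Freedman-Diaconis rule by default (any
    ``numpy.histogram`` bin spec is accepted); the Gaussian
    ``A * exp(-(x-mu)^2 / (2 sd^2))`` is fitted to the bin counts by
    unweighted least squares, initialised at the sample moments.

    Returns
    -------
    (mean, sd, amplitude)
    """
    values = np.asarray(values, dtype=float)
    if values.size < 50:
        raise ValueError("need at least 50 values for a histogram fit")
    if np.ptp(values) == 0:
        raise ValueError("all values identical; spread is zero")
    counts, edges = np.histogram(values, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p0 = [float(counts.max()), float(values.mean()), float(values.std(ddof=1))]

    def model(x, amp, mu, sd):
        return amp * np.exp(-0.5 * ((x - mu) / sd) ** 2)

    lo, hi = float(values.min()), float(values.max())
    popt, _ = optimize.curve_fit(
        model,
        centers,
        counts,
        p0=[p0[0], np.clip(p0[1], lo, hi), p0[2]],
        bounds=([0.0, lo, np.finfo(float).tiny], [np.inf, hi, 10 * (hi - lo)]),
        maxfev=10_000,
    )
    amp, mu, sd = popt
    return float(mu), float(abs(sd)), float(amp)


def event_rate(table: EventTable) -> float:
    """Detected capture rate in events/s."""
    if table.trace_duration <= 0:
        raise ValueError("trace_duration must be positive")
    return table.n / table.trace_duration


def population_summary(table: EventTable, amplitude_split: float) -> dict:
    """Count events below/above an amplitude split (e.g. the 150 pA line
    separating the monomer cluster from higher-order assemblies)."""
    if amplitude_split < 0:
        raise ValueError("amplitude_split must be non-negative")
    peaks = table.events["peak_max_pA"].to_numpy()
    below = int((peaks < amplitude_split).sum())
    return {"below": below, "above": int(peaks.size - below), "split_pA": amplitude_split}
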