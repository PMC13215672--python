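"""Summaries and evaluation scores computed from posterior samples."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .engine import PosteriorSamples
from .model import DomainError

__all__ = [
    "SpikeSummary",
    "summarize",
    "filtered_correlation",
    "error_and_bias",
    "isi_posterior",
    "detection_metrics",
    "correlation_vs_binsize",
    "downsample_counts",
    "detect_events",
]


@dataclass
class SpikeSummary:
    """Per-step posterior summaries and per-bin count distributions."""

    mean_spikes: np.ndarray
    sd_spikes: np.ndarray
    burst_probability: np.ndarray
    mean_baseline: np.ndarray
    sd_baseline: np.ndarray
    bin_width: float
    bin_edges: np.ndarray
    bin_counts: np.ndarray      # (n_samples, n_bins) per-draw binned counts
    bin_distributions: list     # per bin: dict {count: probability}


def summarize(samples: PosteriorSamples, bin_width: float = 1.0) -> SpikeSummary:
    """Posterior means/sds per step plus binned spike-count distributions."""
    if samples.n_samples == 0:
        raise DomainError("empty posterior samples")
    dt = samples.dt
    t = samples.n_steps
    edges = np.arange(0.0, t * dt + bin_width, bin_width)
    if edges[-1] < t * dt - 1e-12:
        edges = np.append(edges, t * dt)
    step_bins = np.minimum(
        np.searchsorted(edges, (np.arange(t) + 0.5) * dt) - 1, len(edges) - 2
    )
    n_bins = len(edges) - 1
    bin_counts = np.zeros((samples.n_samples, n_bins), dtype=np.int64)
    for k in range(samples.n_samples):
        np.add.at(bin_counts[k], step_bins, samples.spikes[k])
    distributions = []
    for j in range(n_bins):
        vals, freq = np.unique(bin_counts[:, j], return_counts=True)
        distributions.append(
            {int(v): f / samples.n_samples for v, f in zip(vals, freq)}
        )
    return SpikeSummary(
        mean_spikes=samples.spikes.mean(axis=0),
        sd_spikes=samples.spikes.std(axis=0),
        burst_probability=samples.q.mean(axis=0),
        mean_baseline=samples.baseline.mean(axis=0),
        sd_baseline=samples.baseline.std(axis=0),
        bin_width=bin_width,
        bin_edges=edges,
        bin_counts=bin_counts,
        bin_distributions=distributions,
    )


def filtered_correlation(
    est: np.ndarray,
    truth: np.ndarray,
    dt: float,
    bandwidth: float = 0.2,
) -> float:
    """Pearson correlation of two per-step count signals after Gaussian
    smoothing.  ``bandwidth`` is the standard deviation of the smoothing
    kernel, in seconds.

    Returns NaN (with a warning) if either smoothed signal has zero
    variance.
    """
    est = np.asarray(est, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if est.shape != truth.shape:
        raise DomainError("est and truth must have equal length")
    if bandwidth <= 0:
        raise DomainError("bandwidth must be positive")
    sigma = bandwidth / dt
    # reflect padding maps constants to constants, keeping the Pearson
    # score invariant to affine rescaling of either signal
    a = gaussian_filter1d(est, sigma, mode="reflect")
    b = gaussian_filter1d(truth, sigma, mode="reflect")
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn(
            "zero-variance smoothed signal; correlation undefined",
            RuntimeWarning,
        )
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def error_and_bias(est: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """Average absolute error and signed bias per time step."""
    est = np.asarray(est, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if est.shape != truth.shape:
        raise DomainError("est and truth must have equal length")
    diff = est - truth
    return float(np.mean(np.abs(diff))), float(np.mean(diff))


@dataclass
class ISIPosterior:
    """Posterior over the interval between the first two spikes in a
    window, conditioned on draws containing spikes there."""

    isis: np.ndarray            # one ISI (s) per draw with >= 2 spikes
    count_distribution: dict    # window spike-count histogram over draws
    two_spike_fraction: float
    mode: float | None          # modal ISI (s); None if undefined
    hist_edges: np.ndarray
    hist_probs: np.ndarray


def isi_posterior(
    samples: PosteriorSamples,
    window: tuple[float, float],
    bin_width: float = 0.003,
) -> ISIPosterior:
    """Distribution of the interval between the first two spike events in
    ``window`` (seconds) across retained draws.

    Draws whose window spike count differs from two still contribute an ISI
    when they have at least two spikes, and are tallied in the side
    spike-count distribution either way.  The mode is the mass-weighted
    center of the fullest bin of a histogram with ``bin_width`` bins.
    """
    dt = samples.dt
    lo = max(int(np.floor(window[0] / dt)), 0)
    hi = min(int(np.ceil(window[1] / dt)) + 1, samples.n_steps)
    if lo >= hi:
        raise DomainError("window lies outside the trace")
    sub = samples.spikes[:, lo:hi]
    counts = sub.sum(axis=1)
    vals, freq = np.unique(counts, return_counts=True)
    count_distribution = {int(v): f / len(counts) for v, f in zip(vals, freq)}
    isis = []
    for row in sub:
        nz = np.flatnonzero(row)
        if len(nz) == 0:
            continue
        times = np.repeat(nz, row[nz])
        if len(times) >= 2:
            isis.append((times[1] - times[0]) * dt)
    isis = np.asarray(isis)
    two_frac = float(np.mean(counts == 2))
    if len(isis) == 0:
        warnings.warn("no draw with >= 2 spikes in window", RuntimeWarning)
        return ISIPosterior(
            isis, count_distribution, two_frac, None,
            np.array([0.0, bin_width]), np.array([0.0]),
        )
    n_bins = max(int(np.ceil((isis.max() + bin_width / 2) / bin_width)), 1)
    edges = np.arange(n_bins + 1) * bin_width
    hist, _ = np.histogram(isis, bins=edges)
    probs = hist / hist.sum()
    j = int(np.argmax(hist))
    in_bin = (isis >= edges[j]) & (isis < edges[j + 1])
    mode = float(np.mean(isis[in_bin]))
    return ISIPosterior(isis, count_distribution, two_frac, mode, edges, probs)


def detect_events(
    samples: PosteriorSamples, threshold: float = 0.5
) -> np.ndarray:
    """Point detections (seconds) from the per-step posterior spike
    probability: supra-threshold steps are merged into runs and each run is
    reduced to its probability-weighted center."""
    prob = (samples.spikes >= 1).mean(axis=0)
    above = prob > threshold
    if not above.any():
        return np.array([])
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above))
    events = []
    for s0, s1 in zip(starts, ends):
        idx = np.arange(s0, s1)
        events.append(np.average(idx, weights=prob[idx]) * samples.dt)
    return np.asarray(events)


def detection_metrics(
    samples: PosteriorSamples,
    truth_times: np.ndarray,
    threshold: float = 0.5,
) -> tuple[float, float]:
    """Temporal accuracy (mean |truth - nearest detection|, seconds) and
    false detection rate ((n_detected - n_truth) / n_truth).

    With no detections the accuracy is NaN and the rate -1 (flagged with a
    warning).
    """
    truth_times = np.asarray(truth_times, dtype=float)
    if truth_times.size == 0:
        raise DomainError("truth spike times must be non-empty")
    det = detect_events(samples, threshold)
    if det.size == 0:
        warnings.warn("no detections above threshold", RuntimeWarning)
        return float("nan"), -1.0
    nearest = np.min(np.abs(truth_times[:, None] - det[None, :]), axis=1)
    accuracy = float(np.mean(nearest))
    rate = (det.size - truth_times.size) / truth_times.size
    return accuracy, float(rate)


def correlation_vs_binsize(
    est_times: np.ndarray,
    truth_times: np.ndarray,
    duration: float,
    bin_sizes: np.ndarray | None = None,
) -> dict:
    """Pearson correlation of binned event-time histograms across bin
    sizes (default 2-50 ms).  Zero-variance binnings yield NaN."""
    if bin_sizes is None:
        bin_sizes = np.arange(0.002, 0.0501, 0.002)
    est_times = np.asarray(est_times, dtype=float)
    truth_times = np.asarray(truth_times, dtype=float)
    out = {}
    for width in np.atleast_1d(bin_sizes):
        if width <= 0:
            raise DomainError("bin sizes must be positive")
        edges = np.arange(0.0, duration + width, width)
        a, _ = np.histogram(est_times, bins=edges)
        b, _ = np.histogram(truth_times, bins=edges)
        if np.std(a) == 0 or np.std(b) == 0:
            out[float(width)] = float("nan")
        else:
            out[float(width)] = float(np.corrcoef(a, b)[0, 1])
    return out


def downsample_counts(
    counts: np.ndarray, dt: float, target_rate: float
) -> np.ndarray:
    """Sum-pool per-step counts into windows of width ``1/target_rate``."""
    if target_rate > 1.0 / dt + 1e-12:
        raise DomainError("target rate exceeds the sampling rate")
    counts = np.asarray(counts)
    window = 1.0 / target_rate
    t = len(counts)
    idx = np.minimum(
        (np.arange(t) * dt / window).astype(np.int64),
        int(np.ceil(t * dt / window)) - 1,
    )
    out = np.zeros(idx[-1] + 1, dtype=counts.dtype)
    np.add.at(out, idx, counts)
    return out
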