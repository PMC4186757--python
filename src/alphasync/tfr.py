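"""Morlet time-frequency decomposition, 1/f spectral normalization, pseudo-z
power time courses and interval analytics.

Kernel convention: "n cycles" is the *total* temporal support of the kernel,
i.e. the complex exponential under a Gaussian envelope truncated at
``+/- n_cycles / 2`` cycles. A 7-cycle kernel at 10 Hz therefore spans
+/-350 ms, and masking a -500..2000 ms epoch leaves the valid range
-150..1650 ms.

Baseline standardization: wavelet power is divided by a fitted ``beta/f**gamma``
aperiodic model and converted to a pseudo z-score using moments of the
prestimulus baseline pooled over a band of frequencies (default 6-14 Hz in
1 Hz steps). The pooled *mean* is the grand mean over baseline samples and
frequencies. For the variance two estimators are available:

``trial`` (default)
    sampling variance of the trial-averaged baseline power: the across-trial
    variance pooled over baseline samples and frequencies, divided by the
    trial count, plus the sampling variance of the pooled baseline mean
    itself (the baseline spans only a couple of kernel widths, so the
    uncertainty of the estimated mean is not negligible). Unbiased under the
    strong temporal autocorrelation the wavelet kernel imposes, so the
    resulting z is calibrated (~N(0,1) on stationary noise) while a
    narrowband oscillation sitting above the band average scores a large
    positive z.
``within_freq``
    mean over baseline frequencies of the *temporal* variance of the
    trial-averaged power within each frequency. Matches ``trial`` in
    expectation for long baselines but is biased low when the baseline is
    short relative to the kernel autocorrelation length.
``pooled``
    variance over all baseline samples and frequencies together. Note that
    with K pooled frequencies this bounds the attainable |z| of any single
    frequency by sqrt(K - 1) (~2.83 for K=9), so an oscillation can never
    reach |z| > 3 under this estimator; it is provided as the literal
    reading of "mean and variance of baseline coefficients" only.

Baseline moments are computed per frequency on the intersection of the
baseline window with that frequency's validity mask; frequencies whose
kernel exceeds the whole prestimulus span (e.g. 6-7 Hz for a 7-cycle kernel
and a 500 ms baseline) contribute no unbiased baseline samples and are
excluded from the moment pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocess import EpochSet

__all__ = [
    "TFR",
    "SpectralFit",
    "PowerTimecourse",
    "IntervalSet",
    "morlet_kernel",
    "morlet_tfr",
    "fit_one_over_f",
    "normalize_power",
    "pool_subjects",
    "active_intervals",
    "divergence_intervals",
    "subset_average",
]


@dataclass
class TFR:
    """Complex wavelet coefficients: trials x frequencies x samples."""

    coeffs: np.ndarray
    freqs: np.ndarray
    times_ms: np.ndarray
    fs: float
    n_cycles: float
    valid_mask: np.ndarray  # frequencies x samples
    roi: str = ""
    trial_meta: pd.DataFrame | None = None

    @property
    def n_trials(self) -> int:
        return self.coeffs.shape[0]

    def freq_index(self, freq: float) -> int:
        i = int(np.argmin(np.abs(self.freqs - freq)))
        if abs(self.freqs[i] - freq) > 1e-6:
            raise ValueError(f"frequency {freq} Hz not present in this TFR")
        return i

    def valid_times(self, freq: float) -> np.ndarray:
        return self.times_ms[self.valid_mask[self.freq_index(freq)]]


@dataclass
class SpectralFit:
    """Aperiodic spectrum model P(f) = beta / f**gamma."""

    beta: float
    gamma: float
    fit_range: tuple[float, float] = (5.0, 60.0)
    residual: float = 0.0

    def __post_init__(self) -> None:
        if self.beta <= 0 or not np.isfinite(self.gamma):
            raise ValueError("beta must be positive and gamma finite")

    def model(self, freqs: np.ndarray) -> np.ndarray:
        return self.beta / np.asarray(freqs, dtype=float) ** self.gamma


@dataclass
class PowerTimecourse:
    z: np.ndarray
    dispersion: np.ndarray  # per-sample standard error of z
    times_ms: np.ndarray
    condition: str = ""
    roi: str = ""
    n: int = 0  # trials (or subjects) the series was averaged over

    def __post_init__(self) -> None:
        if self.z.shape != self.dispersion.shape or self.z.shape != self.times_ms.shape:
            raise ValueError("z, dispersion and times_ms must share one shape")
        if (self.dispersion < 0).any():
            raise ValueError("dispersion must be non-negative")


@dataclass
class IntervalSet:
    intervals: list[tuple[float, float]]
    kind: str  # "active" | "divergent"
    threshold: float
    roi: str = ""
    condition: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "roi": self.roi,
                    "condition": self.condition,
                    "start_ms": s,
                    "end_ms": e,
                    "kind": self.kind,
                }
                for s, e in self.intervals
            ]
        )


def morlet_kernel(freq: float, fs: float, n_cycles: float = 7.0) -> np.ndarray:
    """Complex Morlet kernel with total support of ``n_cycles`` cycles.

    The Gaussian envelope SD is ``n_cycles / (2*pi*freq)`` so the truncation
    at +/- ``n_cycles/2`` cycles sits at ~3.1 SD. The kernel is scaled to
    unit gain: convolving a unit-amplitude sinusoid at ``freq`` yields
    coefficients of magnitude ~1.
    """
    half_samples = int(round(n_cycles / 2.0 / freq * fs))
    t = np.arange(-half_samples, half_samples + 1) / fs
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    env = np.exp(-(t**2) / (2.0 * sigma_t**2))
    kernel = env * np.exp(2j * np.pi * freq * t)
    return kernel * (2.0 / env.sum())


def morlet_tfr(
    epochs: EpochSet, freqs: Sequence[float], n_cycles: float = 7.0
) -> TFR:
    """Morlet decomposition with an edge-validity mask per frequency.

    A sample at time t is valid for frequency f when the half-kernel fits
    inside the epoch *window*: ``t0 + h <= t <= t1 - h`` with
    ``h = (n_cycles/2) / f`` and ``t1`` the half-open window end.
    """
    freqs = np.asarray(freqs, dtype=float)
    if (freqs >= epochs.fs / 2.0).any():
        bad = freqs[freqs >= epochs.fs / 2.0]
        raise ValueError(f"frequencies {bad.tolist()} Hz are at or above Nyquist")
    if (freqs <= 0).any():
        raise ValueError("frequencies must be positive")
    t = epochs.times_ms
    t_end = epochs.window_end_ms
    coeffs = np.empty((epochs.n_trials, freqs.size, epochs.n_samples), dtype=complex)
    valid = np.zeros((freqs.size, epochs.n_samples), dtype=bool)
    for i, f in enumerate(freqs):
        k = morlet_kernel(f, epochs.fs, n_cycles)
        coeffs[:, i, :] = sps.fftconvolve(
            epochs.data, k[None, :], mode="same", axes=1
        )
        half_ms = 1000.0 * (n_cycles / 2.0) / f
        valid[i] = (t >= epochs.t0_offset_ms + half_ms - 1e-6) & (t <= t_end - half_ms + 1e-6)
    return TFR(
        coeffs=coeffs,
        freqs=freqs,
        times_ms=t,
        fs=epochs.fs,
        n_cycles=n_cycles,
        valid_mask=valid,
        roi=epochs.roi,
        trial_meta=epochs.trial_meta,
    )


def fit_one_over_f(
    freqs: np.ndarray,
    mean_power: np.ndarray,
    fit_range: tuple[float, float] = (5.0, 60.0),
) -> SpectralFit:
    """Least-squares line on (log f, log P); gamma = -slope, beta = exp(intercept)."""
    freqs = np.asarray(freqs, dtype=float)
    mean_power = np.asarray(mean_power, dtype=float)
    lo, hi = fit_range
    sel = (freqs >= lo) & (freqs <= hi)
    if sel.sum() < 3:
        raise ValueError("need at least 3 frequencies inside the fit range")
    if (mean_power[sel] <= 0).any():
        raise ValueError("power values must be positive for a log-log fit")
    x = np.log(freqs[sel])
    y = np.log(mean_power[sel])
    slope, intercept = np.polyfit(x, y, 1)
    resid = float(np.sqrt(np.mean((y - (slope * x + intercept)) ** 2)))
    return SpectralFit(
        beta=float(np.exp(intercept)), gamma=float(-slope),
        fit_range=fit_range, residual=resid,
    )


def prestim_spectrum(tfr: TFR) -> np.ndarray:
    """Trial- and time-averaged power per frequency over the prestimulus span.

    Uses valid prestimulus samples where available, otherwise (for low
    frequencies whose kernel exceeds the prestimulus span) all prestimulus
    samples.
    """
    power = np.abs(tfr.coeffs) ** 2
    pre = tfr.times_ms < 0
    out = np.empty(tfr.freqs.size)
    for i in range(tfr.freqs.size):
        sel = pre & tfr.valid_mask[i]
        if not sel.any():
            sel = pre
        out[i] = power[:, i, sel].mean()
    return out


def _baseline_moments(
    power: np.ndarray,  # trials x baseline-freqs x samples, normalized power
    valid_mask: np.ndarray,  # baseline-freqs x samples
    times_ms: np.ndarray,
    baseline_window_ms: tuple[float, float],
    var_mode: str,
) -> tuple[float, float]:
    b0, b1 = baseline_window_ms
    bsel = (times_ms >= b0 - 1e-9) & (times_ms < b1 + 1e-9)
    if not bsel.any():
        raise ValueError("baseline window contains no samples")
    n_trials = power.shape[0]
    q = power.mean(axis=0)  # freqs x samples
    means, variances = [], []
    per_trial_base = []  # per-trial mean over the pooled baseline samples
    for i in range(power.shape[1]):
        sel = bsel & valid_mask[i]
        if not sel.any():
            continue  # kernel exceeds the prestimulus span at this frequency
        means.append(q[i, sel].mean())
        if var_mode == "trial":
            variances.append(power[:, i, sel].var(axis=0, ddof=1).mean() / n_trials)
            per_trial_base.append(power[:, i, sel].mean(axis=1))
        elif var_mode == "within_freq":
            if sel.sum() > 1:
                variances.append(q[i, sel].var(ddof=1))
        elif var_mode == "pooled":
            variances.extend(q[i, sel].tolist())
        else:
            raise ValueError(f"unknown var_mode {var_mode!r}")
    if not means:
        raise ValueError(
            "no baseline frequency has valid (edge-free) baseline samples"
        )
    mean = float(np.mean(means))
    if var_mode == "pooled":
        var = float(np.var(variances, ddof=1))
    else:
        var = float(np.mean(variances))
    if var_mode == "trial" and n_trials > 1:
        # uncertainty of the estimated baseline mean, from the across-trial
        # spread of per-trial (freq- and sample-pooled) baseline power
        b = np.mean(per_trial_base, axis=0)
        var += float(b.var(ddof=1)) / n_trials
    if var <= 0:
        raise ValueError("baseline variance is zero; cannot standardize")
    return mean, var


def normalize_power(
    tfr: TFR,
    fit: SpectralFit | None = None,
    baseline_window_ms: tuple[float, float] = (-500.0, 0.0),
    baseline_freqs: Sequence[float] = tuple(range(6, 15)),
    analysis_freq: float = 10.0,
    var_mode: str = "trial",
    trial_sel: np.ndarray | None = None,
    condition: str = "",
) -> PowerTimecourse:
    """Pseudo-z 10 Hz power time course.

    Wavelet power is divided by the aperiodic model (if ``fit`` is given),
    averaged over trials, and standardized against baseline moments pooled
    over ``baseline_freqs`` (see module docstring for the variance modes and
    the edge handling of baseline samples). When ``trial_sel`` is given the
    series is averaged over that trial subset, but baseline moments always
    come from all trials so subsets remain mutually comparable.
    """
    fa = tfr.freq_index(analysis_freq)
    power = np.abs(tfr.coeffs) ** 2
    if fit is not None:
        power = power / fit.model(tfr.freqs)[None, :, None]

    bidx = [tfr.freq_index(f) for f in baseline_freqs]
    mean, var = _baseline_moments(
        power[:, bidx, :], tfr.valid_mask[bidx], tfr.times_ms,
        baseline_window_ms, var_mode,
    )
    sd = np.sqrt(var)

    sel = np.arange(tfr.n_trials) if trial_sel is None else np.asarray(trial_sel)
    if sel.dtype == bool:
        sel = np.flatnonzero(sel)
    if sel.size == 0:
        raise ValueError("empty trial selection")
    vmask = tfr.valid_mask[fa]
    p_sub = power[sel][:, fa, :][:, vmask]  # trials x valid samples
    z = (p_sub.mean(axis=0) - mean) / sd
    if sel.size > 1:
        se = p_sub.std(axis=0, ddof=1) / np.sqrt(sel.size) / sd
    else:
        se = np.zeros_like(z)
    return PowerTimecourse(
        z=z,
        dispersion=se,
        times_ms=tfr.times_ms[vmask],
        condition=condition,
        roi=tfr.roi,
        n=int(sel.size),
    )


def pool_subjects(series: Sequence[PowerTimecourse]) -> PowerTimecourse:
    """Average pseudo-z series across subjects; dispersion becomes the
    across-subject standard error when two or more subjects are pooled."""
    if len(series) == 0:
        raise ValueError("need at least one series")
    t0 = series[0].times_ms
    for s in series[1:]:
        if s.times_ms.shape != t0.shape or not np.allclose(s.times_ms, t0):
            raise ValueError("all series must share one time axis")
    if len(series) == 1:
        return series[0]
    zs = np.stack([s.z for s in series])
    return PowerTimecourse(
        z=zs.mean(axis=0),
        dispersion=zs.std(axis=0, ddof=1) / np.sqrt(len(series)),
        times_ms=t0.copy(),
        condition=series[0].condition,
        roi=series[0].roi,
        n=len(series),
    )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs as (first_index, last_index) pairs."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def active_intervals(power: PowerTimecourse, z_hi: float = 3.0) -> IntervalSet:
    """Maximal contiguous runs with z > z_hi, endpoints in ms at sample resolution."""
    if power.z.size == 0:
        raise ValueError("empty power series")
    ivals = [
        (float(power.times_ms[a]), float(power.times_ms[b]))
        for a, b in _runs(power.z > z_hi)
    ]
    return IntervalSet(ivals, kind="active", threshold=z_hi,
                       roi=power.roi, condition=power.condition)


def divergence_intervals(
    power_a: PowerTimecourse, power_b: PowerTimecourse, k: float = 4.0
) -> IntervalSet:
    """Runs where the two series differ by more than ``k`` pooled standard errors."""
    if power_a.times_ms.shape != power_b.times_ms.shape or not np.allclose(
        power_a.times_ms, power_b.times_ms
    ):
        raise ValueError("power series must share one time axis")
    se_diff = np.sqrt(power_a.dispersion**2 + power_b.dispersion**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        mask = np.abs(power_a.z - power_b.z) > k * se_diff
    mask &= se_diff > 0
    ivals = [
        (float(power_a.times_ms[a]), float(power_a.times_ms[b]))
        for a, b in _runs(mask)
    ]
    return IntervalSet(
        ivals, kind="divergent", threshold=k,
        roi=power_a.roi, condition=f"{power_a.condition}|{power_b.condition}",
    )


def subset_average(
    tfr: TFR,
    selector: str,
    fit: SpectralFit | None = None,
    speed_split_cms: float = 5.0,
    **kwargs,
) -> dict[str, PowerTimecourse]:
    """Per-class pseudo-z series for a metadata selector.

    ``selector`` is one of ``hemifield`` (ipsi vs contra), ``speed-class``
    (|speed| above/below ``speed_split_cms``) or ``correctness``. All classes
    share the all-trials baseline moments, so differences between class
    curves are not rescaled by per-class baselines.
    """
    if tfr.trial_meta is None:
        raise ValueError("TFR carries no trial metadata")
    meta = tfr.trial_meta
    if selector == "hemifield":
        classes = {h: (meta["hemifield"] == h).to_numpy() for h in ("ipsi", "contra")}
    elif selector == "speed-class":
        speed = meta["speed_cms"].abs().to_numpy()
        classes = {"slow": speed < speed_split_cms, "fast": speed > speed_split_cms}
    elif selector == "correctness":
        corr = meta["correct"].astype(bool).to_numpy()
        classes = {"correct": corr, "incorrect": ~corr}
    else:
        raise ValueError(f"unknown selector {selector!r}")
    out = {}
    for label, mask in classes.items():
        if not mask.any():
            raise ValueError(f"class {label!r} contains no trials")
        out[label] = normalize_power(
            tfr, fit=fit, trial_sel=mask, condition=label, **kwargs
        )
    return out
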