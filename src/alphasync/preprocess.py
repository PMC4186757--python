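"""Epoch extraction, artifact rejection, prestimulus standardization and
behavioral summaries.

Epoching uses half-open sample windows: a window ``[start_ms, end_ms)`` at
sampling rate ``fs`` always yields ``round((end - start) / 1000 * fs)``
samples, so a -500..2000 ms window at 600 samples/s is exactly 1500 samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "EpochSet",
    "RejectionReport",
    "extract_epochs",
    "reject_epochs",
    "prestim_standardize",
    "detect_erf_peak",
    "behavior_summary",
]


@dataclass
class EpochSet:
    """Trials x samples array for a single ROI or channel.

    The time axis is ``t0_offset_ms + 1000 * arange(n_samples) / fs`` with the
    event at 0 ms.
    """

    data: np.ndarray
    fs: float
    t0_offset_ms: float
    roi: str = ""
    trial_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("EpochSet.data must be 2-D (trials x samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.trial_meta is not None and len(self.trial_meta) != self.n_trials:
            raise ValueError("trial_meta length does not match trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_offset_ms + 1000.0 * np.arange(self.n_samples) / self.fs

    @property
    def window_end_ms(self) -> float:
        """End of the half-open epoch window (one sample period past the last sample)."""
        return self.t0_offset_ms + 1000.0 * self.n_samples / self.fs

    def select_trials(self, idx: Sequence[int] | np.ndarray) -> "EpochSet":
        idx = np.asarray(idx, dtype=int)
        meta = None
        if self.trial_meta is not None:
            meta = self.trial_meta.iloc[idx].reset_index(drop=True)
        return EpochSet(self.data[idx], self.fs, self.t0_offset_ms, self.roi, meta)

    def copy_with(self, data: np.ndarray) -> "EpochSet":
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass
class RejectionReport:
    kept: np.ndarray
    rejected: np.ndarray
    reasons: dict[int, str] = field(default_factory=dict)
    grad_p2p_limit: float | None = None
    mag_p2p_limit: float | None = None

    def __post_init__(self) -> None:
        self.kept = np.asarray(self.kept, dtype=int)
        self.rejected = np.asarray(self.rejected, dtype=int)
        n = len(self.kept) + len(self.rejected)
        all_idx = np.sort(np.concatenate([self.kept, self.rejected]))
        if not np.array_equal(all_idx, np.arange(n)):
            raise ValueError("kept and rejected must partition the trial indices")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"trial": int(i), "kept": True, "reason": ""} for i in self.kept]
        rows += [
            {"trial": int(i), "kept": False, "reason": self.reasons.get(int(i), "")}
            for i in self.rejected
        ]
        return pd.DataFrame(rows).sort_values("trial").reset_index(drop=True)


def extract_epochs(
    continuous: np.ndarray,
    event_times_s: Sequence[float],
    window_ms: tuple[float, float],
    fs: float,
    trial_meta: pd.DataFrame | None = None,
    roi: str = "",
) -> EpochSet:
    """Cut a continuous record into event-locked epochs.

    ``window_ms`` is half-open: samples lie in ``[start_ms, end_ms)`` relative
    to each event, so a (-500, 2000) window at 600 samples/s gives 1500
    samples per trial starting ``0.5 * fs`` samples before the event sample.
    """
    continuous = np.asarray(continuous, dtype=float)
    if continuous.ndim != 1:
        raise ValueError("continuous record must be 1-D")
    start_ms, end_ms = window_ms
    if end_ms <= start_ms:
        raise ValueError("epoch window must have positive length")
    n_samp = int(round((end_ms - start_ms) / 1000.0 * fs))
    trials = []
    for k, ev in enumerate(event_times_s):
        first = int(round(ev * fs + start_ms / 1000.0 * fs))
        last = first + n_samp
        if first < 0 or last > continuous.size:
            raise ValueError(
                f"event {k} at {ev} s: window [{start_ms}, {end_ms}) ms falls "
                f"outside the record (samples {first}..{last} of {continuous.size})"
            )
        trials.append(continuous[first:last])
    return EpochSet(np.asarray(trials), fs, start_ms, roi, trial_meta)


def reject_epochs(
    data: np.ndarray,
    channel_kinds: Sequence[str],
    grad_p2p_limit: float,
    mag_p2p_limit: float,
) -> tuple[np.ndarray, RejectionReport]:
    """Peak-to-peak amplitude rejection over a trials x channels x samples array.

    A trial is dropped when any gradiometer channel exceeds ``grad_p2p_limit``
    peak-to-peak or any magnetometer channel exceeds ``mag_p2p_limit``
    peak-to-peak anywhere within the epoch. Returns the surviving sub-array
    and a report with per-trial reasons.
    """
    if grad_p2p_limit <= 0 or mag_p2p_limit <= 0:
        raise ValueError("peak-to-peak limits must be positive")
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError("data must be 3-D (trials x channels x samples)")
    kinds = np.asarray(channel_kinds)
    if kinds.size != data.shape[1]:
        raise ValueError("channel_kinds length must match channel count")
    unknown = set(kinds) - {"grad", "mag"}
    if unknown:
        raise ValueError(f"unknown channel kinds: {sorted(unknown)}")

    p2p = data.max(axis=2) - data.min(axis=2)  # trials x channels
    grad_bad = (p2p[:, kinds == "grad"] > grad_p2p_limit).any(axis=1)
    mag_bad = (p2p[:, kinds == "mag"] > mag_p2p_limit).any(axis=1)
    bad = grad_bad | mag_bad

    reasons = {}
    for i in np.flatnonzero(bad):
        reasons[int(i)] = "gradiometer-p2p" if grad_bad[i] else "magnetometer-p2p"
    kept = np.flatnonzero(~bad)
    report = RejectionReport(
        kept=kept,
        rejected=np.flatnonzero(bad),
        reasons=reasons,
        grad_p2p_limit=grad_p2p_limit,
        mag_p2p_limit=mag_p2p_limit,
    )
    return data[kept], report


def prestim_standardize(
    epochs: EpochSet, baseline_ms: tuple[float, float] | None = None
) -> EpochSet:
    """Per trial, subtract the prestimulus mean and divide by the prestimulus SD.

    The default baseline is the full prestimulus span (epoch start to 0 ms).
    """
    if baseline_ms is None:
        baseline_ms = (epochs.t0_offset_ms, 0.0)
    b0, b1 = baseline_ms
    if b0 < epochs.t0_offset_ms - 1e-9 or b1 > epochs.window_end_ms + 1e-9:
        raise ValueError("baseline window must lie inside the epoch")
    t = epochs.times_ms
    mask = (t >= b0 - 1e-9) & (t < b1 - 1e-9) if b1 <= 0 else (t >= b0 - 1e-9) & (t < b1)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    base = epochs.data[:, mask]
    mu = base.mean(axis=1, keepdims=True)
    sd = base.std(axis=1, ddof=0, keepdims=True)
    flat = np.flatnonzero(sd[:, 0] == 0)
    if flat.size:
        raise ValueError(f"zero baseline variance in trial(s) {flat.tolist()}")
    return epochs.copy_with((epochs.data - mu) / sd)


def detect_erf_peak(
    evoked: np.ndarray,
    fs: float,
    t0_offset_ms: float,
    band_hz: tuple[float, float] = (0.5, 40.0),
    center_ms: float = 230.0,
    halfwidth_ms: float = 20.0,
    filter_order: int = 4,
    min_relative_amplitude: float = 0.1,
) -> tuple[float, float] | None:
    """Locate an evoked-response peak near ``center_ms``.

    The evoked series is band-passed with a zero-phase Butterworth filter
    (``filter_order`` poles per edge, applied forward and backward so peak
    latencies are not shifted) and the local extremum of largest absolute
    amplitude within ``center_ms +/- halfwidth_ms`` is returned as
    ``(time_ms, amplitude)``. Returns ``None`` when no local extremum falls
    in the window; extrema smaller than ``min_relative_amplitude`` times the
    largest absolute filtered value (filter ringing) do not count.
    """
    evoked = np.asarray(evoked, dtype=float)
    lo, hi = band_hz
    if not (0.0 < lo < hi < fs / 2.0):
        raise ValueError("band edges must satisfy 0 < lo < hi < fs/2")
    t = t0_offset_ms + 1000.0 * np.arange(evoked.size) / fs
    w0, w1 = center_ms - halfwidth_ms, center_ms + halfwidth_ms
    if w0 < t[0] or w1 > t[-1]:
        raise ValueError("peak search window must lie inside the epoch")

    sos = signal.butter(filter_order, band_hz, btype="bandpass", fs=fs, output="sos")
    filt = signal.sosfiltfilt(sos, evoked)

    # interior local extrema: sign change of the first difference
    d = np.diff(filt)
    ext = np.flatnonzero(d[:-1] * d[1:] < 0) + 1
    in_win = ext[(t[ext] >= w0 - 1e-9) & (t[ext] <= w1 + 1e-9)]
    floor = min_relative_amplitude * np.max(np.abs(filt))
    in_win = in_win[np.abs(filt[in_win]) >= floor]
    if in_win.size == 0:
        return None
    best = in_win[np.argmax(np.abs(filt[in_win]))]
    return float(t[best]), float(filt[best])


def behavior_summary(trial_meta: pd.DataFrame, n_alternatives: int = 4) -> dict:
    """Accuracy and response-time summary for a forced-choice task.

    Trials without a response (NaN ``response_time_ms``) are discarded before
    computing percent correct. Significance against chance ``1/n_alternatives``
    uses a one-sided exact binomial test.
    """
    if n_alternatives < 2:
        raise ValueError("n_alternatives must be at least 2")
    if "correct" not in trial_meta:
        raise ValueError("trial_meta must have a 'correct' column")
    responded = trial_meta
    if "response_time_ms" in trial_meta:
        responded = trial_meta[trial_meta["response_time_ms"].notna()]
    n = len(responded)
    if n == 0:
        raise ValueError("no responded trials")
    k = int(responded["correct"].astype(bool).sum())
    chance = 1.0 / n_alternatives
    test = stats.binomtest(k, n, chance, alternative="greater")
    out = {
        "n_responded": n,
        "n_correct": k,
        "percent_correct": 100.0 * k / n,
        "chance_percent": 100.0 * chance,
        "p_value": float(test.pvalue),
    }
    if "response_time_ms" in responded:
        rt = responded["response_time_ms"].to_numpy(dtype=float)
        out.update(
            rt_mean_ms=float(np.mean(rt)),
            rt_median_ms=float(np.median(rt)),
            rt_sd_ms=float(np.std(rt, ddof=1)) if n > 1 else 0.0,
        )
    return out
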