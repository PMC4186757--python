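"""Synthetic multi-subject ROI epoch generator with known ground truth.

Each ROI time course is the sum of a 10 Hz (configurable) oscillation whose
amplitude follows an event-related envelope, and 1/f^gamma background noise.
Phase relations between coupled ROIs are drawn per trial from a von Mises
distribution, which makes downstream phase-synchrony estimates directly
checkable against the configured coupling graph.

Reproducibility: every generator is a pure function of its parameters and
seed. Per-subject streams are derived from the master seed as
``numpy.random.default_rng([seed, subject_index])``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import EpochSet

__all__ = [
    "CouplingEdge",
    "SimConfig",
    "SyntheticDataset",
    "onef_noise",
    "coupled_oscillators",
    "power_envelope",
    "apply_power_envelope",
    "mix_with_crosstalk",
    "simulate_subject",
    "simulate_cohort",
    "save_dataset",
    "load_dataset",
]

_PROFILES = ("early-drop", "sustained", "null")


@dataclass(frozen=True)
class CouplingEdge:
    """Directed phase-coupling edge: ``roi_b``'s oscillation phase is
    ``roi_a``'s phase plus ``phase_lag_rad`` plus von Mises noise of
    concentration ``kappa``. ``window_ms`` restricts the lock to a time
    window (outside it ``roi_b`` oscillates with an independent phase)."""

    roi_a: str
    roi_b: str
    phase_lag_rad: float = 0.0  # positive: roi_b lags roi_a
    kappa: float = 8.0
    window_ms: tuple[float, float] | None = None


@dataclass
class SimConfig:
    n_subjects: int = 8
    n_trials: int = 160
    fs: float = 600.0
    epoch_window_ms: tuple[float, float] = (-500.0, 2000.0)
    rois: dict[str, str] = field(
        default_factory=lambda: {"V3a": "early-drop", "MT+": "early-drop",
                                 "FEF": "sustained", "SPL": "sustained"}
    )
    coupling_edges: list[CouplingEdge] = field(default_factory=list)
    onef_gamma: float = 1.0
    onef_scale: float = 1.0
    osc_freq: float = 10.0
    osc_amp: float = 1.0
    amp_jitter: float = 0.0  # relative SD of per-trial oscillation amplitude
    erd_onset_ms: float = 300.0
    erd_depth: float = 0.8
    stim_end_ms: float = 1000.0
    ramp_ms: float = 100.0
    p_correct: float = 0.5
    mixing: np.ndarray | None = None
    condition: str = "main"
    seed: int = 0

    def __post_init__(self) -> None:
        start, end = self.epoch_window_ms
        if not (start < 0.0 < end):
            raise ValueError("epoch window must contain 0 (start < 0 < end)")
        if self.fs <= 2.0 * self.osc_freq:
            raise ValueError("fs must exceed twice the oscillation frequency")
        if not (0.0 <= self.erd_depth <= 1.0):
            raise ValueError("erd_depth must lie in [0, 1]")
        if not np.isfinite(self.onef_gamma) or not (0.0 <= self.onef_gamma <= 3.0):
            raise ValueError("onef_gamma must be finite and within [0, 3]")
        if not np.isfinite(self.onef_scale) or self.onef_scale < 0:
            raise ValueError("onef_scale must be finite and non-negative")
        for name, profile in self.rois.items():
            if profile not in _PROFILES:
                raise ValueError(f"ROI {name!r}: unknown profile {profile!r}")
        targets = [e.roi_b for e in self.coupling_edges]
        if len(targets) != len(set(targets)):
            raise ValueError("each ROI may be the target of at most one coupling edge")
        for e in self.coupling_edges:
            if e.kappa < 0:
                raise ValueError(f"edge {e.roi_a}->{e.roi_b}: kappa must be >= 0")
            if e.roi_a not in self.rois or e.roi_b not in self.rois:
                raise ValueError(f"edge {e.roi_a}->{e.roi_b}: unknown ROI")
        if self.mixing is not None:
            self.mixing = np.asarray(self.mixing, dtype=float)
            n = len(self.rois)
            if self.mixing.shape != (n, n):
                raise ValueError("mixing matrix must be square, one row/column per ROI")
            if (self.mixing < 0).any():
                raise ValueError("mixing matrix entries must be non-negative")

    @property
    def n_samples(self) -> int:
        start, end = self.epoch_window_ms
        return int(round((end - start) / 1000.0 * self.fs))

    @property
    def times_ms(self) -> np.ndarray:
        return self.epoch_window_ms[0] + 1000.0 * np.arange(self.n_samples) / self.fs

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["coupling_edges"] = [dataclasses.asdict(e) for e in self.coupling_edges]
        if self.mixing is not None:
            d["mixing"] = self.mixing.tolist()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        d["coupling_edges"] = [
            CouplingEdge(**{**e, "phase_lag_rad": float(e.get("phase_lag_rad", 0.0)),
                            "window_ms": tuple(e["window_ms"]) if e.get("window_ms") else None})
            for e in d.get("coupling_edges", [])
        ]
        d["epoch_window_ms"] = tuple(d.get("epoch_window_ms", (-500.0, 2000.0)))
        if d.get("mixing") is not None:
            d["mixing"] = np.asarray(d["mixing"], dtype=float)
        return cls(**d)


@dataclass
class SyntheticDataset:
    subjects: list[dict[str, EpochSet]]
    config: SimConfig
    realized_lags: list[dict[tuple[str, str], np.ndarray]]


def onef_noise(
    gamma: float,
    scale: float,
    n: int,
    fs: float,
    seed: int | None = None,
    n_series: int = 1,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Gaussian noise with one-sided power spectral density ``scale / f**gamma``.

    Synthesized by spectrally shaping white noise: the rFFT of unit-variance
    white noise is multiplied by ``sqrt(scale * fs / 2) * f**(-gamma/2)`` (DC
    zeroed) and inverted, so a Welch PSD estimate of a long realization
    recovers both parameters. Returns shape ``(n,)`` for ``n_series=1``,
    otherwise ``(n_series, n)``.
    """
    if not np.isfinite(gamma) or not (0.0 <= gamma <= 3.0):
        raise ValueError("gamma must be finite and within [0, 3]")
    if not np.isfinite(scale) or scale < 0:
        raise ValueError("scale must be finite and non-negative")
    if n < 2:
        raise ValueError("n must be at least 2")
    if fs <= 0:
        raise ValueError("fs must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    white = rng.standard_normal((n_series, n))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(f)
    shape[1:] = np.sqrt(scale * fs / 2.0) * f[1:] ** (-gamma / 2.0)
    out = np.fft.irfft(spec * shape, n=n, axis=-1)
    return out[0] if n_series == 1 else out


def coupled_oscillators(
    freq: float,
    phase_lag: float,
    kappa: float,
    n_trials: int,
    n_samples: int,
    fs: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    return_lags: bool = False,
):
    """Pairs of sinusoids with a per-trial phase lag drawn around ``phase_lag``.

    Trial ``i`` holds ``cos(2*pi*freq*t + phi_i)`` and
    ``cos(2*pi*freq*t + phi_i - lag_i)`` with ``phi_i`` uniform and
    ``lag_i ~ phase_lag + vonMises(0, kappa)`` (``kappa=0`` gives a uniform
    lag, large ``kappa`` a fixed lag). Positive ``phase_lag`` means the
    second series lags the first, so the cross-spectrum
    ``a * conj(b)`` has phase ``+phase_lag``.
    """
    if n_trials < 1 or n_samples < 1:
        raise ValueError("n_trials and n_samples must be positive")
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n_trials)
    lags = phase_lag + rng.vonmises(0.0, kappa, size=n_trials)
    t = np.arange(n_samples) / fs
    carrier = 2.0 * np.pi * freq * t
    a = np.cos(carrier[None, :] + phi[:, None])
    b = np.cos(carrier[None, :] + (phi - lags)[:, None])
    if return_lags:
        return a, b, lags
    return a, b


def _smoothstep(u: np.ndarray) -> np.ndarray:
    """Raised-cosine ramp from 0 to 1 over u in [0, 1]."""
    u = np.clip(u, 0.0, 1.0)
    return 0.5 - 0.5 * np.cos(np.pi * u)


def power_envelope(
    profile: str,
    times_ms: np.ndarray,
    onset_ms: float,
    depth: float,
    stim_end_ms: float = 1000.0,
    ramp_ms: float = 100.0,
) -> np.ndarray:
    """Amplitude envelope for a trial: 1 before the drop, ``1 - depth`` after.

    ``early-drop`` ramps down at ``onset_ms``; ``sustained`` holds until
    ``stim_end_ms`` then ramps down; ``null`` stays at 1.
    """
    if profile not in _PROFILES:
        raise ValueError(f"unknown profile {profile!r}")
    t = np.asarray(times_ms, dtype=float)
    if profile == "null":
        return np.ones_like(t)
    drop_at = onset_ms if profile == "early-drop" else stim_end_ms
    return 1.0 - depth * _smoothstep((t - drop_at) / max(ramp_ms, 1e-9))


def apply_power_envelope(
    epochs: EpochSet,
    profile: str,
    onset_ms: float,
    depth: float | np.ndarray,
    stim_end_ms: float = 1000.0,
    ramp_ms: float = 100.0,
) -> EpochSet:
    """Scale an oscillatory EpochSet by a per-profile amplitude envelope.

    Meant for the pure oscillatory component (before noise is added), so the
    configured envelope maps one-to-one onto band-limited power. ``depth`` may
    be a scalar or a per-trial array.
    """
    t = epochs.times_ms
    if not (t[0] - 1e-9 <= onset_ms <= epochs.window_end_ms + 1e-9):
        raise ValueError("onset must lie inside the epoch window")
    depth_arr = np.atleast_1d(np.asarray(depth, dtype=float))
    if ((depth_arr < 0) | (depth_arr > 1)).any():
        raise ValueError("depth must lie in [0, 1]")
    if depth_arr.size == 1:
        env = power_envelope(profile, t, onset_ms, float(depth_arr[0]), stim_end_ms, ramp_ms)
        return epochs.copy_with(epochs.data * env[None, :])
    if depth_arr.size != epochs.n_trials:
        raise ValueError("per-trial depth must have one entry per trial")
    env = np.stack([
        power_envelope(profile, t, onset_ms, float(d), stim_end_ms, ramp_ms)
        for d in depth_arr
    ])
    return epochs.copy_with(epochs.data * env)


def mix_with_crosstalk(
    datasets: Mapping[str, EpochSet], mixing: np.ndarray,
    roi_order: Sequence[str] | None = None,
) -> dict[str, EpochSet]:
    """Linear leakage: output ROI ``i`` is ``sum_j mixing[i, j] * input ROI j``,
    applied identically to every trial and sample."""
    order = list(roi_order) if roi_order is not None else list(datasets)
    mixing = np.asarray(mixing, dtype=float)
    n = len(order)
    if mixing.shape != (n, n):
        raise ValueError(f"mixing must be {n}x{n} to match the ROI count, got {mixing.shape}")
    stack = np.stack([datasets[r].data for r in order])  # roi x trial x time
    mixed = np.einsum("ij,jkt->ikt", mixing, stack)
    return {
        r: datasets[r].copy_with(mixed[i]) for i, r in enumerate(order)
    }


def _trial_metadata(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_trials
    rt = rng.uniform(1000.0, 3000.0, size=n)
    return pd.DataFrame(
        {
            "condition": config.condition,
            "hemifield": rng.choice(["ipsi", "contra"], size=n),
            "speed_cms": rng.uniform(0.5, 10.0, size=n),
            "correct": rng.random(n) < config.p_correct,
            "response_time_ms": rt,
        }
    )


def simulate_subject(
    config: SimConfig, subject_index: int = 0
) -> tuple[dict[str, EpochSet], dict[tuple[str, str], np.ndarray]]:
    """One subject's ROI -> EpochSet map plus realized per-trial phase lags."""
    rng = np.random.default_rng([config.seed, subject_index])
    t_ms = config.times_ms
    t_s = t_ms / 1000.0
    n_tr, n_samp = config.n_trials, config.n_samples
    carrier = 2.0 * np.pi * config.osc_freq * t_s

    meta = _trial_metadata(config, rng)

    # independent base phase per ROI per trial, then overridden by coupling
    phases = {r: rng.uniform(0.0, 2.0 * np.pi, size=n_tr) for r in config.rois}
    amps = {
        r: np.clip(config.osc_amp * (1.0 + config.amp_jitter * rng.standard_normal(n_tr)),
                   0.0, None)
        for r in config.rois
    }
    locked: dict[str, tuple[np.ndarray, tuple[float, float] | None]] = {}
    realized: dict[tuple[str, str], np.ndarray] = {}
    for edge in config.coupling_edges:
        lag = edge.phase_lag_rad + rng.vonmises(0.0, edge.kappa, size=n_tr)
        realized[(edge.roi_a, edge.roi_b)] = lag
        # positive lag: roi_b trails roi_a, giving a positive imaginary CSD
        locked[edge.roi_b] = (phases[edge.roi_a] - lag, edge.window_ms)

    out: dict[str, EpochSet] = {}
    for roi, profile in config.rois.items():
        env = power_envelope(
            profile, t_ms, config.erd_onset_ms, config.erd_depth,
            config.stim_end_ms, config.ramp_ms,
        )
        if roi in locked:
            phi_lock, window = locked[roi]
            osc_lock = np.cos(carrier[None, :] + phi_lock[:, None])
            if window is None:
                osc = osc_lock
            else:
                w0, w1 = window
                w = _smoothstep((t_ms - w0) / 50.0) * (1.0 - _smoothstep((t_ms - w1) / 50.0))
                osc_free = np.cos(carrier[None, :] + phases[roi][:, None])
                osc = w[None, :] * osc_lock + (1.0 - w[None, :]) * osc_free
        else:
            osc = np.cos(carrier[None, :] + phases[roi][:, None])
        sig = amps[roi][:, None] * env[None, :] * osc
        sig = sig + onef_noise(
            config.onef_gamma, config.onef_scale, n_samp, config.fs,
            n_series=n_tr, rng=rng,
        )
        out[roi] = EpochSet(sig, config.fs, config.epoch_window_ms[0], roi, meta.copy())

    if config.mixing is not None:
        out = mix_with_crosstalk(out, config.mixing, roi_order=list(config.rois))
    return out, realized


def simulate_cohort(config: SimConfig) -> SyntheticDataset:
    """Independent per-subject datasets from per-subject derived seeds."""
    subjects, lags = [], []
    for i in range(config.n_subjects):
        data, realized = simulate_subject(config, i)
        subjects.append(data)
        lags.append(realized)
    return SyntheticDataset(subjects=subjects, config=config, realized_lags=lags)


# ---------------------------------------------------------------------------
# array container: one .npz per subject (ROI x trial x time) + meta.json


def save_dataset(dataset: SyntheticDataset, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rois = list(dataset.config.rois)
    for i, subject in enumerate(dataset.subjects):
        arr = np.stack([subject[r].data for r in rois])
        np.savez(outdir / f"subject-{i:02d}.npz", data=arr)
        meta = next(iter(subject.values())).trial_meta
        meta.to_csv(outdir / f"subject-{i:02d}_trials.tsv", sep="\t", index=False)
    payload = {
        "config": dataset.config.to_dict(),
        "rois": rois,
        "realized_lags": [
            {f"{a}->{b}": lag.tolist() for (a, b), lag in subj.items()}
            for subj in dataset.realized_lags
        ],
    }
    (outdir / "meta.json").write_text(json.dumps(payload, indent=1))
    return outdir


def load_dataset(indir: str | Path) -> SyntheticDataset:
    indir = Path(indir)
    payload = json.loads((indir / "meta.json").read_text())
    config = SimConfig.from_dict(payload["config"])
    rois = payload["rois"]
    subjects = []
    for i in range(config.n_subjects):
        arr = np.load(indir / f"subject-{i:02d}.npz")["data"]
        meta = pd.read_csv(indir / f"subject-{i:02d}_trials.tsv", sep="\t")
        subjects.append(
            {
                r: EpochSet(arr[j], config.fs, config.epoch_window_ms[0], r, meta.copy())
                for j, r in enumerate(rois)
            }
        )
    lags = [
        {tuple(k.split("->")): np.asarray(v) for k, v in subj.items()}
        for subj in payload["realized_lags"]
    ]
    return SyntheticDataset(subjects=subjects, config=config, realized_lags=lags)
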