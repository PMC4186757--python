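import numpy as np
import pytest

from alphasync import simulate as sim
from alphasync import tfr as tfrmod
from alphasync.preprocess import prestim_standardize

POWER_FREQS = tuple(sorted(set(range(6, 15)) | {10.0}))


def cohort_coeffs(cfg: sim.SimConfig, freq: float = 10.0):
    """Analysis-frequency wavelet coefficients per ROI per subject on the
    shared valid time axis (the input cluster_permutation expects)."""
    dataset = sim.simulate_cohort(cfg)
    coeffs = {r: [] for r in cfg.rois}
    times = None
    for subject in dataset.subjects:
        for roi, ep in subject.items():
            tf = tfrmod.morlet_tfr(ep, [freq])
            mask = tf.valid_mask[0]
            coeffs[roi].append(tf.coeffs[:, 0, mask])
            times = tf.times_ms[mask]
    return coeffs, times


def single_roi_power(
    profile: str,
    seed: int,
    osc_amp: float = 3.0,
    n_trials: int = 160,
    erd_depth: float = 1.0,
    fs: float = 200.0,
    erd_onset_ms: float = 300.0,
) -> tfrmod.PowerTimecourse:
    """Full power chain (standardize -> TFR -> 1/f fit -> pseudo-z) for one
    simulated ROI."""
    cfg = sim.SimConfig(
        n_subjects=1, n_trials=n_trials, fs=fs, epoch_window_ms=(-500.0, 2000.0),
        rois={"roi": profile}, erd_onset_ms=erd_onset_ms, erd_depth=erd_depth,
        osc_amp=osc_amp, seed=seed,
    )
    subject, _ = sim.simulate_subject(cfg, 0)
    ep = prestim_standardize(subject["roi"])
    tf = tfrmod.morlet_tfr(ep, POWER_FREQS)
    fit = tfrmod.fit_one_over_f(tf.freqs, tfrmod.prestim_spectrum(tf), fit_range=(6, 14))
    return tfrmod.normalize_power(tf, fit=fit, condition=profile)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
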