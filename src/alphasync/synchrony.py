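"""Time-resolved phase synchrony between ROI pairs.

Estimator: the debiased squared weighted phase lag index (WPLI) computed
across trials from the imaginary part of the per-trial cross-spectral
density, with the signed square root reported so the magnitude bound
(|wpli| <= 1) and the sign-flip equivariance under conjugation hold:

    num = (sum_i x_i)^2 - sum_i x_i^2
    den = (sum_i |x_i|)^2 - sum_i x_i^2
    wpli = sign(sum_i x_i) * sqrt(clip(num / den, 0, 1))

where x_i is the imaginary CSD of trial i at one time sample. The pairwise
-product form debiases the small-sample positive bias of WPLI^2 and is
insensitive to instantaneous (zero-lag) linear mixing.

Uncertainty: leave-one-trial-out jackknife with the standard (n-1)/n scaled
variance of the replicates; pseudo-z = wpli / SEM. Subject-level pseudo-z
series are pooled with Stouffer's method (sum / sqrt(N)).

Inference: maximal runs of the pooled z above a threshold (the mean pooled z
over all pairs and valid samples), each scored by the time integral of z.
The null distribution is built by permuting each ROI's trial order
independently and rerunning the whole chain; by default the per-permutation
statistic is the maximum cluster integral across all pairs, which makes a
"any significant cluster" decision calibrated across the pair family
(``null="pooled"`` instead pools every permuted cluster integral).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tfr import TFR, _runs

try:  # optional fast path for the permutation loop
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "CrossSpectrum",
    "SynchronyStat",
    "ClusterResult",
    "ClusterPermutationResult",
    "csd_pair",
    "wpli_debiased",
    "jackknife_pseudo_z",
    "pair_synchrony",
    "stouffer_combine",
    "cluster_permutation",
]


@dataclass
class CrossSpectrum:
    """Per-trial complex CSD of one ROI pair at one frequency (trials x samples)."""

    csd: np.ndarray
    times_ms: np.ndarray
    pair: tuple[str, str]
    freq: float

    @property
    def imag(self) -> np.ndarray:
        return self.csd.imag

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.csd)


@dataclass
class SynchronyStat:
    wpli: np.ndarray
    sem: np.ndarray
    z: np.ndarray
    times_ms: np.ndarray
    pair: tuple[str, str]
    subject_id: str = ""
    zero_sem: np.ndarray | None = None  # mask of samples where SEM was 0


@dataclass
class ClusterResult:
    pair: tuple[str, str]
    start_ms: float
    end_ms: float
    statistic: float
    p_value: float


@dataclass
class ClusterPermutationResult:
    clusters: list[ClusterResult]
    threshold: float
    pooled_z: dict[tuple[str, str], np.ndarray]
    times_ms: np.ndarray
    n_perm: int
    null_stats: np.ndarray = field(repr=False, default=None)

    def significant(self, alpha: float = 0.05) -> list[ClusterResult]:
        return [c for c in self.clusters if c.p_value < alpha]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "roi_a": c.pair[0],
                    "roi_b": c.pair[1],
                    "start_ms": c.start_ms,
                    "end_ms": c.end_ms,
                    "statistic": c.statistic,
                    "p_value": c.p_value,
                }
                for c in self.clusters
            ]
        )


def csd_pair(tfr_a: TFR, tfr_b: TFR, freq: float) -> CrossSpectrum:
    """Per-trial, per-sample product coeff_a * conj(coeff_b) at ``freq``,
    restricted to the intersection of the two validity masks."""
    if tfr_a.n_trials != tfr_b.n_trials:
        raise ValueError(
            f"trial counts differ: {tfr_a.n_trials} vs {tfr_b.n_trials}"
        )
    ia, ib = tfr_a.freq_index(freq), tfr_b.freq_index(freq)
    mask = tfr_a.valid_mask[ia] & tfr_b.valid_mask[ib]
    if not mask.any():
        raise ValueError("validity masks do not overlap")
    csd = tfr_a.coeffs[:, ia, mask] * np.conj(tfr_b.coeffs[:, ib, mask])
    return CrossSpectrum(csd, tfr_a.times_ms[mask], (tfr_a.roi, tfr_b.roi), freq)


def _dwpli_core(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Debiased WPLI with jackknife SEM and pseudo-z.

    ``x``: imaginary CSD with trials on axis -2; returns (wpli, sem, z) with
    that axis reduced.
    """
    n = x.shape[-2]
    s = x.sum(axis=-2)
    s2 = (x * x).sum(axis=-2)
    a = np.abs(x).sum(axis=-2)
    wpli = _signed_root(s, s2, a)

    xs = x
    si = s[..., None, :] - xs
    s2i = s2[..., None, :] - xs * xs
    ai = a[..., None, :] - np.abs(xs)
    reps = _signed_root(si, s2i, ai)
    m = reps.mean(axis=-2)
    var = (n - 1) / n * ((reps - m[..., None, :]) ** 2).sum(axis=-2)
    sem = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sem > 0, wpli / np.where(sem > 0, sem, 1.0),
                     np.where(wpli == 0, 0.0, np.sign(wpli) * np.inf))
    return wpli, sem, z


def _signed_root(s: np.ndarray, s2: np.ndarray, a: np.ndarray) -> np.ndarray:
    num = s * s - s2
    den = a * a - s2
    with np.errstate(divide="ignore", invalid="ignore"):
        dw = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return np.sign(s) * np.sqrt(np.clip(dw, 0.0, 1.0))


def _batch_perm_z_numpy(
    a: np.ndarray, b: np.ndarray, perm_a: np.ndarray, perm_b: np.ndarray
) -> np.ndarray:
    """Jackknife pseudo-z for a batch of trial permutations (reference path).

    ``a``, ``b``: complex (n_trials, n_samples); ``perm_a``, ``perm_b``:
    (n_perms, n_trials) index arrays. Returns z of shape (n_perms, n_samples).
    """
    x = np.imag(a[perm_a] * np.conj(b[perm_b]))
    _, _, z = _dwpli_core(x)
    return z


if _HAVE_NUMBA:

    @njit(cache=True, fastmath=False)
    def _batch_perm_z_kernel(ar, ai, br, bi, perm_a, perm_b, out):  # pragma: no cover
        n_perms, n = perm_a.shape
        n_samp = ar.shape[1]
        buf = np.empty(n)
        for c in range(n_perms):
            for t in range(n_samp):
                s = 0.0
                s2 = 0.0
                amag = 0.0
                for i in range(n):
                    pa = perm_a[c, i]
                    pb = perm_b[c, i]
                    x = ai[pa, t] * br[pb, t] - ar[pa, t] * bi[pb, t]
                    buf[i] = x
                    s += x
                    s2 += x * x
                    amag += abs(x)
                den = amag * amag - s2
                num = s * s - s2
                if den > 0.0:
                    dw = num / den
                    if dw < 0.0:
                        dw = 0.0
                    elif dw > 1.0:
                        dw = 1.0
                else:
                    dw = 0.0
                root = np.sqrt(dw)
                wpli = root if s > 0 else (-root if s < 0 else 0.0)
                # leave-one-out replicates from the totals, single pass
                rsum = 0.0
                rsum2 = 0.0
                for i in range(n):
                    x = buf[i]
                    si = s - x
                    s2i = s2 - x * x
                    ai_ = amag - abs(x)
                    deni = ai_ * ai_ - s2i
                    numi = si * si - s2i
                    if deni > 0.0:
                        dwi = numi / deni
                        if dwi < 0.0:
                            dwi = 0.0
                        elif dwi > 1.0:
                            dwi = 1.0
                    else:
                        dwi = 0.0
                    ri = np.sqrt(dwi)
                    rep = ri if si > 0 else (-ri if si < 0 else 0.0)
                    rsum += rep
                    rsum2 += rep * rep
                var = (n - 1) / n * (rsum2 - rsum * rsum / n)
                if var > 0.0:
                    out[c, t] = wpli / np.sqrt(var)
                elif wpli == 0.0:
                    out[c, t] = 0.0
                else:
                    out[c, t] = np.inf if wpli > 0 else -np.inf

    def _batch_perm_z(a, b, perm_a, perm_b):
        out = np.empty((perm_a.shape[0], a.shape[1]))
        _batch_perm_z_kernel(
            np.ascontiguousarray(a.real), np.ascontiguousarray(a.imag),
            np.ascontiguousarray(b.real), np.ascontiguousarray(b.imag),
            perm_a, perm_b, out,
        )
        return out

else:  # pragma: no cover
    _batch_perm_z = _batch_perm_z_numpy


def wpli_debiased(cs: CrossSpectrum | np.ndarray) -> np.ndarray:
    """Per-sample debiased WPLI (signed root of the debiased square).

    Accepts a CrossSpectrum or a raw array with trials on axis -2 (complex
    CSD values or their imaginary components).
    """
    if isinstance(cs, CrossSpectrum):
        x = cs.imag
    else:
        x = np.asarray(cs)
        if np.iscomplexobj(x):
            x = x.imag
    if x.shape[-2] < 2:
        raise ValueError("debiased WPLI needs at least 2 trials")
    s = x.sum(axis=-2)
    s2 = (x * x).sum(axis=-2)
    a = np.abs(x).sum(axis=-2)
    return _signed_root(s, s2, a)


def jackknife_pseudo_z(cs: CrossSpectrum, subject_id: str = "") -> SynchronyStat:
    """Leave-one-trial-out jackknife SEM and pseudo-z of the debiased WPLI."""
    x = cs.imag
    if x.shape[0] < 3:
        raise ValueError("jackknife needs at least 3 trials")
    wpli, sem, z = _dwpli_core(x)
    return SynchronyStat(
        wpli=wpli, sem=sem, z=z, times_ms=cs.times_ms,
        pair=cs.pair, subject_id=subject_id, zero_sem=sem == 0,
    )


def pair_synchrony(tfr_a: TFR, tfr_b: TFR, freq: float, subject_id: str = "") -> SynchronyStat:
    return jackknife_pseudo_z(csd_pair(tfr_a, tfr_b, freq), subject_id=subject_id)


def stouffer_combine(z_list: Sequence[np.ndarray]) -> np.ndarray:
    """Pooled z = sum(z_i) / sqrt(N), per sample."""
    if len(z_list) == 0:
        raise ValueError("need at least one series")
    shape = np.shape(z_list[0])
    for z in z_list[1:]:
        if np.shape(z) != shape:
            raise ValueError("all series must share one time axis")
    return np.sum(z_list, axis=0) / np.sqrt(len(z_list))


def _clusters_above(z: np.ndarray, threshold: float, dt_s: float) -> list[tuple[int, int, float]]:
    out = []
    for a, b in _runs(z > threshold):
        stat = float(z[a : b + 1].sum() * dt_s)
        out.append((a, b, stat))
    return out


def cluster_permutation(
    subject_coeffs: Mapping[str, Sequence[np.ndarray]],
    times_ms: np.ndarray,
    pairs: Sequence[tuple[str, str]] | None = None,
    n_perm: int = 5000,
    seed: int = 0,
    null: str = "max",
    perm_chunk: int = 25,
) -> ClusterPermutationResult:
    """Integral-of-z cluster permutation test over all ROI pairs.

    ``subject_coeffs[roi][s]`` holds subject ``s``'s complex wavelet
    coefficients for that ROI at the analysis frequency, shape
    (n_trials_s, n_samples) on a common valid time axis. Per permutation each
    ROI's trial order is shuffled independently within every subject and the
    full WPLI -> jackknife-z -> Stouffer chain is recomputed; the observed
    threshold (mean pooled z over pairs and samples) is reused.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rois = list(subject_coeffs)
    if pairs is None:
        pairs = list(combinations(rois, 2))
    times_arr = np.asarray(times_ms, dtype=float)
    if not pairs:
        return ClusterPermutationResult(
            clusters=[], threshold=0.0, pooled_z={}, times_ms=times_arr,
            n_perm=n_perm, null_stats=np.empty(0),
        )
    n_subjects = len(subject_coeffs[rois[0]])
    for r in rois:
        if len(subject_coeffs[r]) != n_subjects:
            raise ValueError("all ROIs must have the same number of subjects")
    times_ms = np.asarray(times_ms, dtype=float)
    n_samples = times_ms.size
    dt_s = float(np.median(np.diff(times_ms))) / 1000.0 if n_samples > 1 else 1.0
    trials_per_subject = [np.asarray(subject_coeffs[rois[0]][s]).shape[0]
                          for s in range(n_subjects)]
    for r in rois:
        for s in range(n_subjects):
            arr = np.asarray(subject_coeffs[r][s])
            if arr.shape != (trials_per_subject[s], n_samples):
                raise ValueError(
                    f"ROI {r!r} subject {s}: expected shape "
                    f"({trials_per_subject[s]}, {n_samples}), got {arr.shape}"
                )

    # observed pooled z per pair
    pooled = {}
    for a, b in pairs:
        zs = []
        for s in range(n_subjects):
            x = np.imag(subject_coeffs[a][s] * np.conj(subject_coeffs[b][s]))
            _, _, z = _dwpli_core(x)
            zs.append(z)
        pooled[(a, b)] = stouffer_combine(zs)
    all_z = np.stack([pooled[p] for p in pairs])
    finite = np.isfinite(all_z)
    threshold = float(all_z[finite].mean()) if finite.any() else 0.0

    observed: list[tuple[tuple[str, str], int, int, float]] = []
    for p in pairs:
        for a_i, b_i, stat in _clusters_above(pooled[p], threshold, dt_s):
            observed.append((p, a_i, b_i, stat))

    rng = np.random.default_rng(seed)
    sqrt_n = np.sqrt(n_subjects)
    arrays = {
        r: [np.ascontiguousarray(np.asarray(subject_coeffs[r][s], dtype=complex))
            for s in range(n_subjects)]
        for r in rois
    }
    null_stats: list[float] = []
    done = 0
    while done < n_perm:
        chunk = min(perm_chunk, n_perm - done)
        # pooled z accumulator: chunk x pairs x samples
        zsum = np.zeros((chunk, len(pairs), n_samples))
        for s in range(n_subjects):
            n_tr = trials_per_subject[s]
            perms = {
                r: rng.permuted(
                    np.tile(np.arange(n_tr), (chunk, 1)), axis=1
                )
                for r in rois
            }
            for pi, (a, b) in enumerate(pairs):
                zsum[:, pi, :] += _batch_perm_z(
                    arrays[a][s], arrays[b][s], perms[a], perms[b]
                )
        zperm = zsum / sqrt_n
        for c in range(chunk):
            stats_c = [
                stat
                for pi in range(len(pairs))
                for _, _, stat in _clusters_above(zperm[c, pi], threshold, dt_s)
            ]
            if null == "max":
                null_stats.append(max(stats_c) if stats_c else 0.0)
            elif null == "pooled":
                null_stats.extend(stats_c if stats_c else [0.0])
            else:
                raise ValueError(f"unknown null mode {null!r}")
        done += chunk
    null_arr = np.asarray(null_stats)

    clusters = [
        ClusterResult(
            pair=p,
            start_ms=float(times_ms[a_i]),
            end_ms=float(times_ms[b_i]),
            statistic=stat,
            p_value=float((null_arr > stat).mean()),
        )
        for p, a_i, b_i, stat in observed
    ]
    return ClusterPermutationResult(
        clusters=clusters,
        threshold=threshold,
        pooled_z=pooled,
        times_ms=times_ms,
        n_perm=n_perm,
        null_stats=null_arr,
    )
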