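"""Configuration-driven orchestration: simulate -> preprocess -> (crosstalk)
-> power -> synchrony, with deterministic TSV/JSON reports."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import crosstalk as xt
from . import synchrony as syn
from . import tfr as tfrmod
from .preprocess import EpochSet, behavior_summary, prestim_standardize
from .simulate import SimConfig, SyntheticDataset, simulate_cohort

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "compare_conditions"]

_DEFAULT_FIT_FREQS = tuple(float(f) for f in range(5, 61, 5))


@dataclass
class PipelineConfig:
    conditions: dict[str, SimConfig]
    analysis_freq: float = 10.0
    n_cycles: float = 7.0
    baseline_window_ms: tuple[float, float] = (-500.0, 0.0)
    baseline_freqs: tuple[float, ...] = tuple(float(f) for f in range(6, 15))
    fit_range: tuple[float, float] = (5.0, 60.0)
    fit_freqs: tuple[float, ...] = _DEFAULT_FIT_FREQS
    z_hi: float = 3.0
    divergence_k: float = 4.0
    crosstalk_threshold: float = 0.20
    cluster_alpha: float = 0.01
    n_perm: int = 5000
    seed: int = 0
    var_mode: str = "trial"
    operators: list[xt.OperatorPair] | None = None
    report_dir: str = "report"

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("at least one condition is required")
        for thr in (self.z_hi, self.divergence_k, self.crosstalk_threshold,
                    self.cluster_alpha):
            if thr <= 0:
                raise ValueError("all thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        conditions = {
            name: SimConfig.from_dict(c) for name, c in raw.pop("conditions").items()
        }
        for key in ("baseline_window_ms", "baseline_freqs", "fit_range", "fit_freqs"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(conditions=conditions, **raw)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["conditions"] = {k: v.to_dict() for k, v in self.conditions.items()}
        d.pop("operators")
        return d


@dataclass
class RunReport:
    config_echo: dict
    seed: int
    behavior: dict[str, dict]
    power: dict[str, dict[str, tfrmod.PowerTimecourse]]
    intervals: pd.DataFrame
    clusters: dict[str, syn.ClusterPermutationResult]
    decisions: xt.ROIDecisions | None
    comparison: pd.DataFrame | None
    resolution: xt.ResolutionMatrix | None = None
    logs: list[str] = field(default_factory=list)

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.intervals.to_csv(outdir / "intervals.tsv", sep="\t", index=False,
                              float_format="%.6g")
        for cond, res in self.clusters.items():
            res.to_frame().to_csv(outdir / f"clusters_{cond}.tsv", sep="\t",
                                  index=False, float_format="%.6g")
        for cond, by_roi in self.power.items():
            frames = []
            for roi, pt in sorted(by_roi.items()):
                frames.append(pd.DataFrame({
                    "roi": roi, "time_ms": pt.times_ms, "z": pt.z, "se": pt.dispersion,
                }))
            pd.concat(frames).to_csv(outdir / f"power_{cond}.tsv", sep="\t",
                                     index=False, float_format="%.6g")
        if self.comparison is not None:
            self.comparison.to_csv(outdir / "comparison.tsv", sep="\t", index=False)
        if self.resolution is not None:
            # percent contribution table, columns = measured ROI
            (100.0 * self.resolution.to_frame()).to_csv(
                outdir / "resolution.tsv", sep="\t", float_format="%.2f"
            )
        summary = {
            "seed": self.seed,
            "behavior": self.behavior,
            "decisions": self.decisions.to_dict() if self.decisions else None,
            "cluster_thresholds": {
                c: r.threshold for c, r in self.clusters.items()
            },
            "n_significant_clusters": {
                c: len(r.significant(self.config_echo["cluster_alpha"]))
                for c, r in self.clusters.items()
            },
            "logs": self.logs,
            "config": self.config_echo,
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        return outdir


def _format_intervals(ivals: Sequence[tuple[float, float]]) -> str:
    return "; ".join(f"{a:.0f}-{b:.0f} ms" for a, b in ivals) if ivals else "-"


def compare_conditions(
    power: Mapping[str, Mapping[str, tfrmod.PowerTimecourse]],
    z_hi: float = 3.0,
    k: float = 4.0,
) -> pd.DataFrame:
    """Per-ROI above-threshold intervals per condition plus divergence intervals."""
    conds = list(power)
    if len(conds) != 2:
        raise ValueError("comparison requires exactly two conditions")
    ca, cb = conds
    rois = sorted(set(power[ca]) & set(power[cb]))
    rows = []
    for roi in rois:
        pa, pb = power[ca][roi], power[cb][roi]
        rows.append({
            "roi": roi,
            ca: _format_intervals(tfrmod.active_intervals(pa, z_hi).intervals),
            cb: _format_intervals(tfrmod.active_intervals(pb, z_hi).intervals),
            "divergence": _format_intervals(
                tfrmod.divergence_intervals(pa, pb, k).intervals
            ),
        })
    return pd.DataFrame(rows, columns=["roi", ca, cb, "divergence"])


def _merge_rois(
    subject: dict[str, EpochSet], decisions: xt.ROIDecisions
) -> dict[str, EpochSet]:
    out = {r: subject[r] for r in decisions.kept if r in subject}
    for members, name in decisions.merged:
        present = [m for m in members if m in subject]
        if not present:
            continue
        data = np.mean([subject[m].data for m in present], axis=0)
        proto = subject[present[0]]
        out[name] = EpochSet(data, proto.fs, proto.t0_offset_ms, name,
                             proto.trial_meta)
    return out


def run_pipeline(config: PipelineConfig) -> RunReport:
    logs: list[str] = []

    # crosstalk stage (optional): averaged resolution matrix -> ROI decisions
    decisions = None
    avg = None
    if config.operators:
        mats = []
        for i, ops in enumerate(config.operators):
            w, a = xt.roi_operators(ops)
            mats.append(xt.resolution_matrix(w, a, ops.roi_names, subject_id=str(i)))
        avg = xt.average_resolution(mats)
        decisions = xt.prune_and_merge(avg, config.crosstalk_threshold)
        logs.append(
            f"crosstalk: kept {len(decisions.kept)}, merged "
            f"{len(decisions.merged)} group(s), dropped {len(decisions.dropped)}"
        )
    else:
        logs.append("crosstalk: skipped (no operators provided)")

    tfr_freqs = tuple(sorted(set(config.baseline_freqs)
                             | set(config.fit_freqs)
                             | {config.analysis_freq}))

    behavior: dict[str, dict] = {}
    power: dict[str, dict[str, tfrmod.PowerTimecourse]] = {}
    clusters: dict[str, syn.ClusterPermutationResult] = {}
    interval_frames: list[pd.DataFrame] = []

    for ci, (cond, simcfg) in enumerate(config.conditions.items()):
        simcfg = replace(
            simcfg, seed=config.seed * 7919 + ci, condition=cond
        )
        dataset: SyntheticDataset = simulate_cohort(simcfg)
        logs.append(f"{cond}: simulated {simcfg.n_subjects} subjects x "
                    f"{simcfg.n_trials} trials")

        meta = pd.concat(
            [next(iter(s.values())).trial_meta for s in dataset.subjects],
            ignore_index=True,
        )
        behavior[cond] = behavior_summary(meta)

        per_roi_series: dict[str, list[tfrmod.PowerTimecourse]] = {}
        coeffs: dict[str, list[np.ndarray]] = {}
        shared_valid_times = None
        for subject in dataset.subjects:
            if decisions is not None:
                subject = _merge_rois(subject, decisions)
            for roi, epochs in subject.items():
                epochs = prestim_standardize(epochs)
                tf = tfrmod.morlet_tfr(epochs, tfr_freqs, config.n_cycles)
                fit = tfrmod.fit_one_over_f(
                    tf.freqs, tfrmod.prestim_spectrum(tf), config.fit_range
                )
                pt = tfrmod.normalize_power(
                    tf, fit=fit,
                    baseline_window_ms=config.baseline_window_ms,
                    baseline_freqs=config.baseline_freqs,
                    analysis_freq=config.analysis_freq,
                    var_mode=config.var_mode,
                    condition=cond,
                )
                per_roi_series.setdefault(roi, []).append(pt)
                fa = tf.freq_index(config.analysis_freq)
                vmask = tf.valid_mask[fa]
                coeffs.setdefault(roi, []).append(tf.coeffs[:, fa, vmask])
                shared_valid_times = tf.times_ms[vmask]

        power[cond] = {
            roi: tfrmod.pool_subjects(series)
            for roi, series in per_roi_series.items()
        }
        for roi, pt in sorted(power[cond].items()):
            iv = tfrmod.active_intervals(pt, config.z_hi)
            interval_frames.append(iv.to_frame())

        res = syn.cluster_permutation(
            coeffs, shared_valid_times,
            n_perm=config.n_perm, seed=config.seed * 104729 + ci,
        )
        clusters[cond] = res
        logs.append(
            f"{cond}: {len(res.significant(config.cluster_alpha))} cluster(s) "
            f"significant at alpha={config.cluster_alpha}"
        )

    comparison = None
    if len(power) == 2:
        conds = list(power)
        comparison = compare_conditions(power, config.z_hi, config.divergence_k)
        for roi in comparison["roi"]:
            pa, pb = power[conds[0]][roi], power[conds[1]][roi]
            div = tfrmod.divergence_intervals(pa, pb, config.divergence_k)
            interval_frames.append(div.to_frame())

    intervals = (
        pd.concat([f for f in interval_frames if not f.empty], ignore_index=True)
        if any(not f.empty for f in interval_frames)
        else pd.DataFrame(columns=["roi", "condition", "start_ms", "end_ms", "kind"])
    )
    return RunReport(
        config_echo=config.echo(),
        seed=config.seed,
        behavior=behavior,
        power=power,
        intervals=intervals,
        clusters=clusters,
        decisions=decisions,
        comparison=comparison,
        resolution=avg,
        logs=logs,
    )
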