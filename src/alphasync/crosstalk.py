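"""ROI-level signal-leakage analysis via the resolution matrix.

The resolution matrix R = W_roi @ A_roi maps true ROI activity into estimated
ROI activity; its column-normalized form gives the fractional signal
contribution of each ROI (row) to each estimated ROI time course (column).
ROI pairs with strong mutual leakage are merged, dominated or weakly
self-represented ROIs are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OperatorPair",
    "ResolutionMatrix",
    "ROIDecisions",
    "roi_operators",
    "resolution_matrix",
    "average_resolution",
    "prune_and_merge",
    "toy_operators",
    "save_operators",
    "load_operators",
]


@dataclass
class OperatorPair:
    """Inverse/forward operator pair with ROI membership.

    ``W`` has shape (n_sources, 3, n_sensors): per-source vector inverse
    operator. ``A`` has shape (n_sensors, n_sources, 3). ``orientations``
    maps each ROI to its principal dipole direction (unit 3-vector).
    """

    W: np.ndarray
    A: np.ndarray
    roi_membership: dict[str, np.ndarray]
    orientations: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        if self.W.ndim != 3 or self.W.shape[1] != 3:
            raise ValueError("W must have shape (n_sources, 3, n_sensors)")
        if self.A.ndim != 3 or self.A.shape[2] != 3:
            raise ValueError("A must have shape (n_sensors, n_sources, 3)")
        if self.A.shape[1] != self.W.shape[0] or self.A.shape[0] != self.W.shape[2]:
            raise ValueError("W and A dimensions are inconsistent")
        for roi, ori in self.orientations.items():
            ori = np.asarray(ori, dtype=float)
            if ori.shape != (3,) or not np.isclose(np.linalg.norm(ori), 1.0, atol=1e-6):
                raise ValueError(f"orientation of ROI {roi!r} must be a unit 3-vector")
            self.orientations[roi] = ori

    @property
    def roi_names(self) -> list[str]:
        return list(self.roi_membership)


@dataclass
class ResolutionMatrix:
    R: np.ndarray
    R_rel: np.ndarray
    roi_names: list[str]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        self.R_rel = np.asarray(self.R_rel, dtype=float)
        if not np.all(np.isfinite(self.R_rel)):
            raise ValueError("R_rel contains non-finite entries")
        colsums = self.R_rel.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError("columns of R_rel must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.R_rel, index=self.roi_names, columns=self.roi_names)


@dataclass
class ROIDecisions:
    kept: list[str] = field(default_factory=list)
    merged: list[tuple[list[str], str]] = field(default_factory=list)
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def all_rois(self) -> list[str]:
        out = list(self.kept)
        for group, _ in self.merged:
            out.extend(group)
        out.extend(r for r, _ in self.dropped)
        return out

    def to_dict(self) -> dict:
        return {
            "kept": self.kept,
            "merged": [{"members": g, "name": n} for g, n in self.merged],
            "dropped": [{"roi": r, "reason": why} for r, why in self.dropped],
        }


def roi_operators(ops: OperatorPair) -> tuple[np.ndarray, np.ndarray]:
    """Collapse source-space operators to ROI-space (W_roi, A_roi).

    Each ROI's row of W_roi is the orientation-projected inverse operator
    averaged over its member sources; columns of A_roi analogously for the
    forward operator.
    """
    names = ops.roi_names
    n_sensors = ops.W.shape[2]
    W_roi = np.zeros((len(names), n_sensors))
    A_roi = np.zeros((n_sensors, len(names)))
    for i, roi in enumerate(names):
        members = np.asarray(ops.roi_membership[roi], dtype=int)
        if members.size == 0:
            raise ValueError(f"ROI {roi!r} has no member sources")
        ori = ops.orientations[roi]
        # (members, 3, sensors) . (3,) -> (members, sensors), then average
        W_roi[i] = np.einsum("k,mks->ms", ori, ops.W[members]).mean(axis=0)
        A_roi[:, i] = np.einsum("k,smk->sm", ori, ops.A[:, members]).mean(axis=1)
    return W_roi, A_roi


def resolution_matrix(
    W_roi: np.ndarray, A_roi: np.ndarray, roi_names: Sequence[str],
    subject_id: str = "",
) -> ResolutionMatrix:
    """R = W_roi @ A_roi, column-normalized by the column sum to R_rel."""
    W_roi = np.asarray(W_roi, dtype=float)
    A_roi = np.asarray(A_roi, dtype=float)
    if W_roi.shape[1] != A_roi.shape[0]:
        raise ValueError("inner dimensions of W_roi and A_roi do not agree")
    R = W_roi @ A_roi
    colsums = R.sum(axis=0)
    zero = np.flatnonzero(colsums == 0)
    if zero.size:
        bad = [roi_names[i] for i in zero]
        raise ValueError(f"column sum is zero for ROI(s) {bad}; cannot normalize")
    return ResolutionMatrix(R, R / colsums[None, :], list(roi_names), subject_id)


def average_resolution(matrices: Sequence[ResolutionMatrix]) -> ResolutionMatrix:
    """Elementwise mean of the column-normalized matrices across subjects."""
    if len(matrices) == 0:
        raise ValueError("need at least one resolution matrix")
    names = matrices[0].roi_names
    for m in matrices[1:]:
        if m.roi_names != names:
            raise ValueError("all matrices must share the same ROI set and order")
    mean_rel = np.mean([m.R_rel for m in matrices], axis=0)
    mean_raw = np.mean([m.R for m in matrices], axis=0)
    return ResolutionMatrix(mean_raw, mean_rel, list(names), subject_id="average")


def _connected_components(adjacency: np.ndarray) -> list[list[int]]:
    n = adjacency.shape[0]
    seen = np.zeros(n, dtype=bool)
    comps = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in np.flatnonzero(adjacency[u]):
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
        comps.append(sorted(comp))
    return comps


def prune_and_merge(avg: ResolutionMatrix, threshold: float = 0.20) -> ROIDecisions:
    """Merge mutually leaking ROIs, then drop dominated / weakly-self ROIs.

    1. ROIs whose cross-contribution exceeds ``threshold`` in *both*
       directions are joined; merging follows connected components of that
       mutual-leakage graph. Merged-group contributions are sums of member
       entries with columns renormalized.
    2. Any remaining ROI receiving more than ``threshold`` contribution from
       another ROI is dropped (``external-contribution``).
    3. Any ROI whose self-contribution is below ``threshold`` is dropped
       (``weak-self``).

    Comparisons are strict: exactly ``threshold`` neither merges nor drops.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    rel = avg.R_rel
    names = avg.roi_names
    n = len(names)

    off = rel.copy()
    np.fill_diagonal(off, 0.0)
    mutual = (off > threshold) & (off.T > threshold)
    comps = _connected_components(mutual)

    decisions = ROIDecisions()
    # collapse merged groups and renormalize columns
    group_names = []
    for comp in comps:
        members = [names[i] for i in comp]
        group_names.append("+".join(members) if len(members) > 1 else members[0])
        if len(members) > 1:
            decisions.merged.append((members, "+".join(members)))
    collapsed = np.zeros((len(comps), len(comps)))
    for gi, ci in enumerate(comps):
        for gj, cj in enumerate(comps):
            collapsed[gi, gj] = rel[np.ix_(ci, cj)].sum()
    collapsed = collapsed / collapsed.sum(axis=0, keepdims=True)

    # re-evaluate drops once on the post-merge matrix
    for gj, gname in enumerate(group_names):
        ext = np.delete(collapsed[:, gj], gj)
        members = [names[i] for i in comps[gj]]
        if ext.size and ext.max() > threshold:
            for m in members:
                decisions.dropped.append((m, "external-contribution"))
        elif collapsed[gj, gj] < threshold:
            for m in members:
                decisions.dropped.append((m, "weak-self"))
        elif len(members) == 1:
            decisions.kept.append(gname)
    # merged groups that survived the drop rules stay in `merged`; remove
    # groups whose members were dropped
    surviving = {r for r, _ in decisions.dropped}
    decisions.merged = [
        (g, nm) for g, nm in decisions.merged if not set(g) & surviving
    ]
    # sanity: partition check
    accounted = set(decisions.kept)
    for g, _ in decisions.merged:
        accounted |= set(g)
    accounted |= {r for r, _ in decisions.dropped}
    assert accounted == set(names), "decisions must partition the ROI set"
    return decisions


def save_operators(ops: OperatorPair, path) -> None:
    """Persist an operator pair to a single .npz file."""
    arrays = {"W": ops.W, "A": ops.A,
              "roi_names": np.array(ops.roi_names, dtype=object)}
    for roi in ops.roi_names:
        arrays[f"membership_{roi}"] = np.asarray(ops.roi_membership[roi], dtype=int)
        arrays[f"orientation_{roi}"] = ops.orientations[roi]
    np.savez(path, **arrays, allow_pickle=True)


def load_operators(path) -> OperatorPair:
    with np.load(path, allow_pickle=True) as f:
        names = [str(n) for n in f["roi_names"]]
        return OperatorPair(
            W=f["W"],
            A=f["A"],
            roi_membership={n: f[f"membership_{n}"] for n in names},
            orientations={n: f[f"orientation_{n}"] for n in names},
        )


def toy_operators(
    n_rois: int,
    n_sensors: int = 32,
    seed: int = 0,
    overlap: float = 0.0,
    duplicate_pairs: Sequence[tuple[int, int]] = (),
) -> OperatorPair:
    """Random single-source-per-ROI operators for testing the leakage chain.

    ``overlap`` blends each ROI's sensor topography with its neighbour's;
    ``duplicate_pairs`` forces identical topographies for the given ROI index
    pairs. W is the pseudo-inverse of the forward matrix, so with
    ``overlap=0`` and no duplicates the resolution matrix is the identity.
    """
    rng = np.random.default_rng(seed)
    topo = rng.standard_normal((n_sensors, n_rois))
    topo /= np.linalg.norm(topo, axis=0, keepdims=True)
    if overlap:
        rolled = np.roll(topo, 1, axis=1)
        topo = (1 - overlap) * topo + overlap * rolled
    for i, j in duplicate_pairs:
        topo[:, j] = topo[:, i]

    ori = np.array([0.0, 0.0, 1.0])
    A = np.zeros((n_sensors, n_rois, 3))
    A[:, :, 2] = topo
    Winv = np.linalg.pinv(topo)  # (n_rois, n_sensors)
    W = np.zeros((n_rois, 3, n_sensors))
    W[:, 2, :] = Winv
    names = [f"roi{i}" for i in range(n_rois)]
    return OperatorPair(
        W=W,
        A=A,
        roi_membership={nm: np.array([i]) for i, nm in enumerate(names)},
        orientations={nm: ori.copy() for nm in names},
    )
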