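"""Recovery scoring of reconstructions against phantom ground truth."""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .cluster import resample_tract
from .io import TractSet
from .phantom import PhantomSpec, PhantomTruth

__all__ = [
    "mean_orientation_error",
    "mean_tangent_error",
    "crossing_continuation_rate",
    "midline_crossing_fraction",
    "assign_bundle_labels",
]


def mean_orientation_error(cfg, truth: PhantomTruth) -> float:
    """Mean angular error (degrees) of segment orientations vs the truth map.

    Each particle is compared with the best-matching stick of the voxel it
    sits in (antipodal); particles in voxels without truth sticks are
    skipped.
    """
    model = cfg.model
    errors = []
    for pid in cfg.alive_ids:
        ijk = model.world_to_voxel(cfg.pos[pid][None, :])[0]
        entries = truth.per_voxel_orientations.get(tuple(int(x) for x in ijk))
        if not entries:
            continue
        cosines = [abs(float(cfg.ori[pid] @ n)) for n, _ in entries]
        errors.append(np.degrees(np.arccos(min(1.0, max(cosines)))))
    if not errors:
        raise ValueError("no particles located in truth voxels")
    return float(np.mean(errors))


def mean_tangent_error(ts: TractSet, direction) -> float:
    """Mean angle (degrees) between tract segment tangents and a fixed axis."""
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    errs = []
    for t in ts:
        seg = np.diff(t.points, axis=0)
        unit = seg / np.linalg.norm(seg, axis=1, keepdims=True)
        cos = np.abs(unit @ d).clip(0.0, 1.0)
        errs.append(np.degrees(np.arccos(cos)))
    if not errs:
        raise ValueError("empty tract set")
    return float(np.concatenate(errs).mean())


def crossing_continuation_rate(ts: TractSet, spec: PhantomSpec) -> float:
    """Fraction of crossing-region tracts that continue straight through.

    For the two-bundle crossing phantom: among tracts that enter the
    central crossing region (a box of the bundle-radius half-width), the
    fraction whose two endpoints lie in *opposite arms of the same bundle*
    — i.e. the tract traversed the crossing without stopping or turning
    onto the other bundle. Scored purely geometrically from the generator's
    bundle axes.
    """
    if spec.geometry_kind != "crossing":
        raise ValueError("continuation rate is defined for the crossing phantom")
    p = spec.geometry_params
    w = p["bundle_radius"]
    ang = np.deg2rad(p["crossing_angle_deg"])
    axes = [np.array([1.0, 0.0, 0.0]), np.array([np.cos(ang), np.sin(ang), 0.0])]

    n_enter = 0
    n_through = 0
    for t in ts:
        pts = t.points
        in_region = np.all(np.abs(pts[:, :2]) <= w, axis=1)
        if not in_region.any():
            continue
        n_enter += 1
        s0, s1 = pts[0], pts[-1]
        for ax in axes:
            a0, a1 = float(s0 @ ax), float(s1 @ ax)
            if a0 * a1 < 0 and min(abs(a0), abs(a1)) > w:
                n_through += 1
                break
    if n_enter == 0:
        return 0.0
    return n_through / n_enter


def midline_crossing_fraction(ts: TractSet) -> float:
    """Fraction of tracts whose endpoints lie in opposite lateral (x) halves."""
    if len(ts) == 0:
        return 0.0
    n = sum(1 for t in ts if t.points[0, 0] * t.points[-1, 0] < 0)
    return n / len(ts)


def assign_bundle_labels(ts: TractSet, truth_tracts: TractSet) -> np.ndarray:
    """Label each tract with the bundle of its nearest truth tract.

    Nearest by mean distance from the tract's resampled points to the
    pooled truth point cloud of each bundle.
    """
    labels = sorted({t.bundle_label for t in truth_tracts})
    trees = []
    for lab in labels:
        pts = np.concatenate(
            [t.points for t in truth_tracts if t.bundle_label == lab]
        )
        trees.append(cKDTree(pts))
    out = np.empty(len(ts), dtype=int)
    for i, t in enumerate(ts):
        pts = resample_tract(t)
        dists = [tree.query(pts)[0].mean() for tree in trees]
        out[i] = labels[int(np.argmin(dists))]
    return out
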