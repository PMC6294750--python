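"""Synthetic crossing-fiber phantoms with known ground truth.

The generator emulates a muscle diffusion acquisition: tubular fiber bundles
on a coarse anisotropic-voxel grid, a stick-mixture diffusion signal at
b = 400 s/mm^2 with 1 baseline + 32 non-collinear directions, and Rician
magnitude noise at a target b0 SNR. Four geometry kinds are provided:

``straight``
    one tube along +x — the sanity-check bundle.
``arc``
    one curved tube (circular arc in the x-y plane).
``crossing``
    two straight tubes through the grid centre at a configurable angle —
    the classic local-tracker failure case.
``purse_string``
    two mirrored arcs that cross the midline and continue contralaterally,
    meeting in a central "perineal body" region; each truth fiber starts on
    one lateral side and ends on the other.

Ground truth (tracts with bundle labels and per-voxel orientation/fraction
maps) is kept alongside the simulated volume for recovery scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .io import (
    DWIVolume,
    GeometryError,
    GradientTable,
    LabelMask,
    Tract,
    TractSet,
    save_dwi,
    save_gradient_table,
    save_mask,
    save_tracts,
)

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "default_gradient_table",
    "electrostatic_directions",
    "make_geometry",
    "simulate_dwi",
    "anatomy_mask",
    "bundle_mask",
    "write_phantom",
    "load_phantom",
]

GEOMETRY_KINDS = ("straight", "arc", "crossing", "purse_string")

# kind-specific geometry parameters and their defaults (mm / degrees)
_GEOMETRY_DEFAULTS = {
    "straight": {"bundle_radius": 2.5, "half_span": 19.0},
    "arc": {"bundle_radius": 2.5, "arc_radius": 15.0, "arc_span_deg": 120.0},
    "crossing": {"bundle_radius": 2.5, "half_span": 19.0, "crossing_angle_deg": 90.0},
    "purse_string": {
        "bundle_radius": 2.0,
        "arc_radius": 40.0,
        "midline_gap": 5.0,
        "half_span": 19.0,
    },
}

_CENTERLINE_STEP = 0.3  # mm; dense sampling used for distance queries
_TRACT_STEP = 1.0  # mm; sampling of emitted truth tracts
_SUPERSAMPLE = 3  # subdivisions per voxel axis for partial-volume fractions
_AIR_BORDER_XY = 2  # voxels of signal-free "air" at the x/y grid border


@dataclass
class PhantomSpec:
    """Declarative description of a synthetic acquisition.

    Diffusivities default to physiologic values for muscle tissue and free
    fluid (the stick compartment at 1.5e-3 mm^2/s, isotropic at 2.0e-3);
    ``iso_fraction`` is the isotropic volume fraction inside a fully
    fiber-occupied voxel. ``target_b0_snr`` is the per-channel Gaussian SNR
    of the Rician noise model (``np.inf`` disables noise).
    """

    geometry_kind: str = "straight"
    grid_shape: tuple[int, int, int] = (32, 32, 12)
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 1.5)
    geometry_params: dict = field(default_factory=dict)
    n_truth_tracts: int = 25
    b0_intensity: float = 1000.0
    stick_diffusivity: float = 1.5e-3
    iso_diffusivity: float = 2.0e-3
    iso_fraction: float = 0.1
    target_b0_snr: float = np.inf
    seed: int = 0

    def __post_init__(self) -> None:
        if self.geometry_kind not in GEOMETRY_KINDS:
            raise ValueError(f"unknown geometry kind {self.geometry_kind!r}")
        if min(self.voxel_size) <= 0:
            raise ValueError("voxel_size must be positive")
        if not 0.0 <= self.iso_fraction <= 1.0:
            raise ValueError("iso_fraction must lie in [0, 1]")
        if not self.target_b0_snr > 0:
            raise ValueError("target_b0_snr must be positive (np.inf for noise-free)")
        merged = dict(_GEOMETRY_DEFAULTS[self.geometry_kind])
        unknown = set(self.geometry_params) - set(merged)
        if unknown:
            raise ValueError(f"unknown geometry_params for kind: {sorted(unknown)}")
        merged.update(self.geometry_params)
        self.geometry_params = merged

    @property
    def affine(self) -> np.ndarray:
        """Grid centred on the world origin, RAS axes, voxel-centre convention."""
        aff = np.eye(4)
        vox = np.asarray(self.voxel_size, dtype=float)
        aff[:3, :3] = np.diag(vox)
        aff[:3, 3] = -(np.asarray(self.grid_shape) - 1) / 2.0 * vox
        return aff

    @property
    def world_halfextent(self) -> np.ndarray:
        """Distance from the origin to the outer voxel edge, per axis."""
        return np.asarray(self.grid_shape) * np.asarray(self.voxel_size) / 2.0

    def to_json(self) -> str:
        d = {
            "geometry_kind": self.geometry_kind,
            "grid_shape": list(self.grid_shape),
            "voxel_size": list(self.voxel_size),
            "geometry_params": self.geometry_params,
            "n_truth_tracts": self.n_truth_tracts,
            "b0_intensity": self.b0_intensity,
            "stick_diffusivity": self.stick_diffusivity,
            "iso_diffusivity": self.iso_diffusivity,
            "iso_fraction": self.iso_fraction,
            "target_b0_snr": None if np.isinf(self.target_b0_snr) else self.target_b0_snr,
            "seed": self.seed,
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        d = json.loads(text)
        d["grid_shape"] = tuple(d["grid_shape"])
        d["voxel_size"] = tuple(d["voxel_size"])
        if d["target_b0_snr"] is None:
            d["target_b0_snr"] = np.inf
        return cls(**d)


@dataclass
class PhantomTruth:
    """Ground truth: labelled tracts plus per-voxel stick orientations."""

    tracts: TractSet
    per_voxel_orientations: dict  # (i,j,k) -> list of (unit vector, volume fraction)
    spec: PhantomSpec

    def orientation_array(self):
        """Flattened view: (voxel index array, orientation array, fraction array)."""
        vox, ori, frac = [], [], []
        for ijk, entries in self.per_voxel_orientations.items():
            for n, f in entries:
                vox.append(ijk)
                ori.append(n)
                frac.append(f)
        return (
            np.asarray(vox, dtype=int).reshape(-1, 3),
            np.asarray(ori, dtype=float).reshape(-1, 3),
            np.asarray(frac, dtype=float),
        )


# ---------------------------------------------------------------------------
# gradient directions


def electrostatic_directions(n: int, n_iter: int = 200) -> np.ndarray:
    """`n` unit vectors spread by antipodal electrostatic repulsion.

    Deterministic: starts from a Fibonacci hemisphere and relaxes with
    projected gradient steps on the antipodally-symmetric Coulomb energy.
    """
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = (i + 0.5) / n  # upper hemisphere
    r = np.sqrt(1.0 - z**2)
    pts = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    step = 0.01
    for _ in range(n_iter):
        force = np.zeros_like(pts)
        for sign in (1.0, -1.0):
            diff = pts[:, None, :] - sign * pts[None, :, :]
            d2 = (diff**2).sum(axis=2)
            np.fill_diagonal(d2, np.inf)
            d2[d2 < 1e-12] = 1e-12
            force += (diff / d2[..., None] ** 1.5).sum(axis=1)
        force -= (force * pts).sum(axis=1, keepdims=True) * pts  # tangential part
        pts = pts + step * force
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return pts


def default_gradient_table(n_dirs: int = 32, bval: float = 400.0) -> GradientTable:
    """1 baseline + ``n_dirs`` directions at ``bval``, mirroring the muscle protocol."""
    dirs = electrostatic_directions(n_dirs)
    bvals = np.concatenate([[0.0], np.full(n_dirs, bval)])
    bvecs = np.vstack([np.zeros(3), dirs])
    b0_mask = bvals <= 50.0
    return GradientTable(bvals=bvals, bvecs=bvecs, b0_mask=b0_mask)


# ---------------------------------------------------------------------------
# bundle centerlines


@dataclass
class _Bundle:
    label: int
    name: str
    points: np.ndarray  # dense centerline (N, 3), ordered along canonical direction
    tangents: np.ndarray  # (N, 3), unit
    radius: float


def _resample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    n = max(int(np.ceil(s[-1] / step)) + 1, 2)
    si = np.linspace(0.0, s[-1], n)
    return np.stack([np.interp(si, s, points[:, k]) for k in range(3)], axis=1)


def _tangents_of(points: np.ndarray) -> np.ndarray:
    t = np.gradient(points, axis=0)
    return t / np.linalg.norm(t, axis=1, keepdims=True)


def _line_bundle(label, name, origin, direction, half_span, radius) -> _Bundle:
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    s = np.arange(-half_span, half_span + _CENTERLINE_STEP / 2, _CENTERLINE_STEP)
    pts = np.asarray(origin, float) + s[:, None] * direction
    return _Bundle(label, name, pts, np.tile(direction, (len(pts), 1)), radius)


def _purse_arc(radius_c: float, delta: float, half_span: float) -> np.ndarray:
    """Arc through (0, -delta), convex down, spanning x in [-half_span, half_span]."""
    phi1 = np.arcsin(half_span / radius_c)
    n = max(int(np.ceil(2 * phi1 * radius_c / _CENTERLINE_STEP)), 2)
    phi = np.linspace(-phi1, phi1, n)
    x = radius_c * np.sin(phi)
    y = (radius_c - delta) - radius_c * np.cos(phi)
    return np.stack([x, y, np.zeros_like(x)], axis=1)


def _build_bundles(spec: PhantomSpec) -> list[_Bundle]:
    p = spec.geometry_params
    kind = spec.geometry_kind
    if kind == "straight":
        return [
            _line_bundle(1, "bundle_a", (0, 0, 0), (1, 0, 0), p["half_span"], p["bundle_radius"])
        ]
    if kind == "arc":
        R, span = p["arc_radius"], np.deg2rad(p["arc_span_deg"])
        n = max(int(np.ceil(span * R / _CENTERLINE_STEP)), 2)
        phi = np.linspace(-span / 2, span / 2, n)
        # arc convex toward -y, apex at the origin
        pts = np.stack(
            [R * np.sin(phi), R * (1 - np.cos(phi)), np.zeros_like(phi)], axis=1
        )
        return [_Bundle(1, "bundle_a", pts, _tangents_of(pts), p["bundle_radius"])]
    if kind == "crossing":
        ang = np.deg2rad(p["crossing_angle_deg"])
        d2 = (np.cos(ang), np.sin(ang), 0.0)
        return [
            _line_bundle(1, "bundle_a", (0, 0, 0), (1, 0, 0), p["half_span"], p["bundle_radius"]),
            _line_bundle(2, "bundle_b", (0, 0, 0), d2, p["half_span"], p["bundle_radius"]),
        ]
    if kind == "purse_string":
        R, gap, span = p["arc_radius"], p["midline_gap"], p["half_span"]
        delta = gap / 2.0
        arc_a = _purse_arc(R, delta, span)  # crosses midline at (0, -delta)
        arc_b = -arc_a  # 180-degree rotation about z: crosses at (0, +delta)
        return [
            _Bundle(1, "bundle_a", arc_a, _tangents_of(arc_a), p["bundle_radius"]),
            _Bundle(2, "bundle_b", arc_b, _tangents_of(arc_b), p["bundle_radius"]),
        ]
    raise ValueError(kind)


def _normal_frame(tangents: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """In-plane normal and binormal (z-ish) frames along a mostly-planar curve."""
    zhat = np.array([0.0, 0.0, 1.0])
    n1 = np.cross(zhat, tangents)
    norms = np.linalg.norm(n1, axis=1, keepdims=True)
    bad = norms[:, 0] < 1e-8
    if bad.any():  # tangent along z: pick x as the normal
        n1[bad] = [1.0, 0.0, 0.0]
        norms[bad] = 1.0
    n1 = n1 / norms
    n2 = np.cross(tangents, n1)
    n2 /= np.linalg.norm(n2, axis=1, keepdims=True)
    return n1, n2


# ---------------------------------------------------------------------------
# geometry -> truth


def make_geometry(spec: PhantomSpec) -> PhantomTruth:
    """Build bundle geometry: labelled truth tracts + per-voxel stick map.

    Truth tracts are parallel offset copies of each bundle centerline, with
    offsets drawn uniformly from the tube cross-section (deterministic given
    ``spec.seed``). Per-voxel volume fractions come from 3x3x3 supersampling
    of each voxel against the tube geometry.
    """
    bundles = _build_bundles(spec)
    rng = np.random.default_rng(spec.seed)
    halfext = spec.world_halfextent

    tracts: list[Tract] = []
    for b in bundles:
        center = _resample_polyline(b.points, _TRACT_STEP)
        ct = _tangents_of(center)
        cn1, cn2 = _normal_frame(ct)
        max_off = max(b.radius - 0.3, 0.2)
        for _ in range(spec.n_truth_tracts):
            r = max_off * np.sqrt(rng.uniform())
            th = rng.uniform(0.0, 2 * np.pi)
            u, w = r * np.cos(th), r * np.sin(th)
            pts = center + u * cn1 + w * cn2
            if np.any(np.abs(pts) > halfext[None, :]):
                raise GeometryError(
                    f"bundle {b.name!r} leaves the grid "
                    f"(extent {halfext}, point range {np.abs(pts).max(axis=0)})"
                )
            tracts.append(Tract(points=pts, bundle_label=b.label))

    per_voxel = _per_voxel_orientations(spec, bundles)
    return PhantomTruth(
        tracts=TractSet(tracts=tracts),
        per_voxel_orientations=per_voxel,
        spec=spec,
    )


def _per_voxel_orientations(spec: PhantomSpec, bundles: list[_Bundle]) -> dict:
    aff = spec.affine
    shape = spec.grid_shape
    vox = np.asarray(spec.voxel_size)
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    centers = idx @ aff[:3, :3].T + aff[:3, 3]

    half_diag = float(np.linalg.norm(vox)) / 2.0
    trees = [cKDTree(b.points) for b in bundles]

    # candidate voxels: center within radius + half voxel diagonal of any bundle
    cand = np.zeros(len(idx), dtype=bool)
    for b, tree in zip(bundles, trees):
        d, _ = tree.query(centers, workers=-1)
        cand |= d <= b.radius + half_diag
    cand_idx = idx[cand]
    cand_centers = centers[cand]

    # supersample each candidate voxel
    offs = (np.arange(_SUPERSAMPLE) + 0.5) / _SUPERSAMPLE - 0.5
    oi, oj, ok = np.meshgrid(offs, offs, offs, indexing="ij")
    sub_off = np.stack([oi, oj, ok], axis=-1).reshape(-1, 3) * vox  # (S, 3)
    n_sub = len(sub_off)
    sub_pts = (cand_centers[:, None, :] + sub_off[None, :, :]).reshape(-1, 3)

    occupancy = np.zeros((len(cand_idx), len(bundles)))
    mean_tan = np.zeros((len(cand_idx), len(bundles), 3))
    for bi, (b, tree) in enumerate(zip(bundles, trees)):
        d, near = tree.query(sub_pts, workers=-1)
        inside = (d <= b.radius).reshape(len(cand_idx), n_sub)
        occupancy[:, bi] = inside.mean(axis=1)
        tan = b.tangents[near].reshape(len(cand_idx), n_sub, 3)
        tan = np.where(inside[..., None], tan, 0.0)
        mean_tan[:, bi] = tan.sum(axis=1)

    per_voxel: dict = {}
    scale = 1.0 - spec.iso_fraction
    for vi in range(len(cand_idx)):
        total = occupancy[vi].sum()
        if total <= 0:
            continue
        norm = scale / max(1.0, total)
        entries = []
        for bi in range(len(bundles)):
            if occupancy[vi, bi] <= 0:
                continue
            n = mean_tan[vi, bi]
            nn = np.linalg.norm(n)
            if nn < 1e-12:
                continue
            entries.append((n / nn, occupancy[vi, bi] * norm))
        if entries:
            per_voxel[tuple(int(x) for x in cand_idx[vi])] = entries
    return per_voxel


# ---------------------------------------------------------------------------
# signal simulation


def anatomy_mask(spec: PhantomSpec) -> np.ndarray:
    """Boolean support of the 'body': everything except an air border in x/y."""
    m = np.zeros(spec.grid_shape, dtype=bool)
    b = _AIR_BORDER_XY
    m[b:-b, b:-b, :] = True
    return m


def simulate_dwi(
    truth: PhantomTruth, spec: PhantomSpec, gtab: GradientTable
) -> DWIVolume:
    """Noise-free stick-mixture signal plus Rician noise at the target b0 SNR.

    Per voxel: ``S(g) = S0 * [c_iso * exp(-b d_iso) + sum_f v_f exp(-b d_stick (g.n_f)^2)]``
    where the isotropic compartment fills whatever volume the sticks do not
    (``c_iso = 1 - sum v_f``, equal to ``iso_fraction`` inside a fully
    occupied voxel). Rician noise is the magnitude of two independent
    Gaussian channels with a single global ``sigma = b0_intensity / target_b0_snr``.
    """
    if gtab.n_dwi < 6:
        raise ValueError("need at least 6 non-b0 directions")
    shape = spec.grid_shape
    n_acq = len(gtab)
    bvals = gtab.bvals
    bvecs = gtab.bvecs

    body = anatomy_mask(spec)
    s0 = np.where(body, spec.b0_intensity, 0.0)

    # start from the pure-isotropic signal everywhere in the body
    iso_att = np.exp(-bvals * spec.iso_diffusivity)  # (n_acq,)
    signal = s0[..., None] * iso_att[None, None, None, :]

    # add stick compartments (replacing the matching isotropic volume)
    for (i, j, k), entries in truth.per_voxel_orientations.items():
        if not body[i, j, k]:
            continue
        stick_total = 0.0
        stick_sig = np.zeros(n_acq)
        for n, f in entries:
            dot = bvecs @ n
            stick_sig += f * np.exp(-bvals * spec.stick_diffusivity * dot**2)
            stick_total += f
        signal[i, j, k, :] = spec.b0_intensity * (
            (1.0 - stick_total) * iso_att + stick_sig
        )

    if np.isfinite(spec.target_b0_snr):
        sigma = spec.b0_intensity / spec.target_b0_snr
        rng = np.random.default_rng(spec.seed + 1)
        n1 = rng.standard_normal(signal.shape)
        n2 = rng.standard_normal(signal.shape)
        signal = np.sqrt((signal + sigma * n1) ** 2 + (sigma * n2) ** 2)

    return DWIVolume(data=signal, affine=spec.affine, gtab=gtab)


def bundle_mask(truth: PhantomTruth) -> LabelMask:
    """Label mask of fiber-occupied voxels (label = dominant bundle).

    Restricted to the anatomy support: fiber geometry reaching into the
    signal-free air border is not labelled.
    """
    spec = truth.spec
    body = anatomy_mask(spec)
    data = np.zeros(spec.grid_shape, dtype=np.int32)
    names: dict[int, str] = {}
    tree_pts, tree_labels = [], []
    for t in truth.tracts:
        tree_pts.append(t.points)
        tree_labels.append(np.full(len(t.points), t.bundle_label))
    pts = np.concatenate(tree_pts)
    labs = np.concatenate(tree_labels)
    tree = cKDTree(pts)
    aff = spec.affine
    for ijk in truth.per_voxel_orientations:
        if not body[ijk]:
            continue
        center = np.asarray(ijk) @ aff[:3, :3].T + aff[:3, 3]
        _, i = tree.query(center)
        data[ijk] = int(labs[i])
    for b in _build_bundles(spec):
        names[b.label] = b.name
    return LabelMask(data=data, affine=spec.affine, label_names=names)


# ---------------------------------------------------------------------------
# on-disk phantom


def write_phantom(
    spec: PhantomSpec, out_dir, gtab: GradientTable | None = None
) -> dict[str, Path]:
    """Generate and write a complete phantom dataset.

    Emits the DWI NIfTI, bval/bvec, a whole-bundle label mask, truth tracts
    (TCK + JSON labels) and the spec itself. Re-loading reproduces the
    simulated volume bit-exactly for the same spec and seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if gtab is None:
        gtab = default_gradient_table()
    truth = make_geometry(spec)
    dwi = simulate_dwi(truth, spec, gtab)
    mask = bundle_mask(truth)

    paths = {
        "dwi": out_dir / "dwi.nii.gz",
        "bval": out_dir / "dwi.bval",
        "bvec": out_dir / "dwi.bvec",
        "mask": out_dir / "mask.nii.gz",
        "truth_tracts": out_dir / "truth.tck",
        "spec": out_dir / "phantom_spec.json",
    }
    save_dwi(dwi, paths["dwi"])
    save_gradient_table(gtab, paths["bval"], paths["bvec"])
    save_mask(mask, paths["mask"])
    save_tracts(truth.tracts, paths["truth_tracts"])
    paths["spec"].write_text(spec.to_json())
    return paths


def load_phantom(out_dir):
    """Reload a written phantom: (DWIVolume, LabelMask, truth TractSet, PhantomSpec)."""
    from .io import load_dwi, load_gradient_table, load_mask, load_tracts

    out_dir = Path(out_dir)
    spec = PhantomSpec.from_json((out_dir / "phantom_spec.json").read_text())
    gtab = load_gradient_table(out_dir / "dwi.bval", out_dir / "dwi.bvec")
    dwi = load_dwi(out_dir / "dwi.nii.gz", gtab)
    mask = load_mask(out_dir / "mask.nii.gz", dwi)
    truth_tracts = load_tracts(out_dir / "truth.tck")
    return dwi, mask, truth_tracts, spec
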