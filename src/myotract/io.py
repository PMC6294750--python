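"""On-disk formats and the coordinate contract.

Everything downstream works in *world RAS millimetres*. Voxel indices are
0-based and a voxel's world position is the centre of its cell, so index
``(i, j, k)`` maps to ``affine @ (i, j, k, 1)``. Streamline files store
world-mm points (TCK natively; TRK is converted on read/write by nibabel).

Gradient tables are FSL-style ``.bval``/``.bvec`` whitespace text; both the
3xN and Nx3 bvec dialects are accepted and auto-detected by shape.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "GradientTable",
    "DWIVolume",
    "LabelMask",
    "Tract",
    "TractSet",
    "FormatError",
    "GeometryError",
    "load_gradient_table",
    "save_gradient_table",
    "load_dwi",
    "save_dwi",
    "load_mask",
    "save_mask",
    "save_tracts",
    "load_tracts",
]

DEFAULT_B0_THRESHOLD = 50.0  # s/mm^2; tolerant of vendor jitter, unambiguous at b=400


class FormatError(ValueError):
    """A file does not conform to its expected on-disk dialect."""


class GeometryError(ValueError):
    """Two volumes that must share a grid/affine do not."""


@dataclass
class GradientTable:
    """Diffusion encoding: b-values (s/mm^2) and unit gradient directions."""

    bvals: np.ndarray  # (n,)
    bvecs: np.ndarray  # (n, 3), unit norm for non-b0 entries
    b0_mask: np.ndarray  # (n,) bool

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float)
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        self.b0_mask = np.asarray(self.b0_mask, dtype=bool)
        if len(self.bvals) != len(self.bvecs) or len(self.bvals) != len(self.b0_mask):
            raise FormatError("bvals, bvecs and b0_mask must have equal length")
        if not self.b0_mask.any():
            raise FormatError("gradient table must contain at least one b0 entry")
        norms = np.linalg.norm(self.bvecs[~self.b0_mask], axis=1)
        if norms.size and not np.allclose(norms, 1.0, atol=1e-8):
            raise FormatError("non-b0 gradient directions must be unit vectors")

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def n_b0(self) -> int:
        return int(self.b0_mask.sum())

    @property
    def n_dwi(self) -> int:
        return int((~self.b0_mask).sum())


@dataclass
class DWIVolume:
    """4-D diffusion-weighted volume with its affine and gradient table."""

    data: np.ndarray  # (nx, ny, nz, n_acq), signal >= 0
    affine: np.ndarray  # (4, 4) voxel-index -> world-mm (RAS)
    gtab: GradientTable

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise FormatError(f"DWI data must be 4-D, got {self.data.ndim}-D")
        if self.data.shape[3] != len(self.gtab):
            raise FormatError(
                f"4th dimension ({self.data.shape[3]}) does not match "
                f"gradient table length ({len(self.gtab)})"
            )
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise GeometryError("affine is singular")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def b0_image(self) -> np.ndarray:
        """Mean over all baseline acquisitions."""
        return self.data[..., self.gtab.b0_mask].mean(axis=3)

    def index_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]


@dataclass
class LabelMask:
    """Integer ROI labels on the same grid as a companion DWIVolume."""

    data: np.ndarray  # (nx, ny, nz) int, 0 = background
    affine: np.ndarray
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        as_int = np.rint(arr).astype(np.int32)
        if not np.allclose(arr, as_int, atol=1e-6):
            raise FormatError("mask values are not integral")
        self.data = as_int
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def labels(self) -> np.ndarray:
        u = np.unique(self.data)
        return u[u > 0]

    def binary(self) -> np.ndarray:
        return self.data > 0


@dataclass
class Tract:
    """Ordered 3-D polyline in world millimetres."""

    points: np.ndarray  # (n, 3)
    bundle_label: int | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("tract points must be (n, 3)")
        if len(self.points) < 2:
            raise ValueError("a tract needs at least 2 points")
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(steps == 0):
            raise ValueError("consecutive tract points must be distinct")

    def __len__(self) -> int:
        return len(self.points)

    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class TractSet:
    tracts: list[Tract]
    space: str = "RAS-mm"

    def __len__(self) -> int:
        return len(self.tracts)

    def __iter__(self):
        return iter(self.tracts)

    def __getitem__(self, i: int) -> Tract:
        return self.tracts[i]

    @property
    def labels(self) -> list[int | None]:
        return [t.bundle_label for t in self.tracts]


# ---------------------------------------------------------------------------
# gradient tables


def load_gradient_table(
    bval_path, bvec_path, b0_threshold: float = DEFAULT_B0_THRESHOLD
) -> GradientTable:
    """Read FSL-style bval/bvec text files.

    Directions are normalized to unit length; entries with ``b <= b0_threshold``
    are flagged as baselines (their direction is irrelevant and stored as-is,
    typically zero).
    """
    bvals = np.atleast_1d(np.loadtxt(bval_path, dtype=float).ravel())
    bvecs = np.atleast_2d(np.loadtxt(bvec_path, dtype=float))
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape[1] != 3:
        if bvecs.shape[0] == 3:  # 3x3 is ambiguous: FSL convention is rows=axes
            bvecs = bvecs.T
        else:
            raise FormatError(f"bvec file has shape {bvecs.shape}, expected 3xN or Nx3")
    if len(bvals) != len(bvecs):
        raise FormatError(
            f"bval count ({len(bvals)}) does not match bvec count ({len(bvecs)})"
        )
    b0_mask = bvals <= b0_threshold
    norms = np.linalg.norm(bvecs, axis=1)
    if np.any((~b0_mask) & (norms < 1e-12)):
        raise ValueError("zero-norm direction for a non-b0 acquisition")
    out = bvecs.copy()
    nz = norms > 1e-12
    out[nz] = bvecs[nz] / norms[nz, None]
    out[b0_mask & ~nz] = 0.0
    return GradientTable(bvals=bvals, bvecs=out, b0_mask=b0_mask)


def save_gradient_table(gtab: GradientTable, bval_path, bvec_path) -> None:
    np.savetxt(bval_path, gtab.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, gtab.bvecs.T, fmt="%.10f")  # FSL 3xN dialect


# ---------------------------------------------------------------------------
# NIfTI volumes


def load_dwi(path, gtab: GradientTable) -> DWIVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise FormatError(f"expected a 4-D DWI image, got {data.ndim}-D")
    if data.shape[3] != len(gtab):
        raise FormatError(
            f"4th dimension ({data.shape[3]}) does not match gradient table "
            f"({len(gtab)} entries)"
        )
    return DWIVolume(data=data, affine=np.asarray(img.affine), gtab=gtab)


def save_dwi(dwi: DWIVolume, path) -> None:
    nib.save(nib.Nifti1Image(dwi.data.astype(np.float32), dwi.affine), str(path))


def load_mask(path, ref: DWIVolume, affine_tol: float = 1e-4) -> LabelMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.shape != ref.shape:
        raise GeometryError(
            f"mask grid {data.shape} does not match reference {ref.shape}"
        )
    if not np.allclose(img.affine, ref.affine, atol=affine_tol):
        raise GeometryError("mask affine differs from reference beyond tolerance")
    return LabelMask(data=data, affine=np.asarray(img.affine))


def save_mask(mask: LabelMask, path) -> None:
    nib.save(nib.Nifti1Image(mask.data.astype(np.int16), mask.affine), str(path))


# ---------------------------------------------------------------------------
# streamlines

_LABEL_SIDECAR_SUFFIX = ".labels.json"


def _label_sidecar(path: Path) -> Path:
    return path.with_name(path.name + _LABEL_SIDECAR_SUFFIX)


def save_tracts(ts: TractSet, path) -> None:
    """Write TCK or TRK (selected by extension), points in world mm.

    Bundle labels, when any tract carries one, go to a JSON sidecar.
    """
    path = Path(path)
    streamlines = [t.points.astype(np.float32) for t in ts.tracts]
    tractogram = nib.streamlines.Tractogram(streamlines, affine_to_rasmm=np.eye(4))
    ext = path.suffix.lower()
    if ext == ".tck":
        nib.streamlines.save(tractogram, str(path))
    elif ext == ".trk":
        header = nib.streamlines.TrkFile.create_empty_header()
        header["voxel_sizes"] = (1.0, 1.0, 1.0)
        header["voxel_to_rasmm"] = np.eye(4, dtype=np.float32)
        header["voxel_order"] = "RAS"
        nib.streamlines.save(tractogram, str(path), header=header)
    else:
        raise FormatError(f"unknown streamline extension {ext!r} (use .tck or .trk)")
    labels = ts.labels
    if any(lab is not None for lab in labels):
        sidecar = _label_sidecar(path)
        sidecar.write_text(
            json.dumps([None if lab is None else int(lab) for lab in labels])
        )


def load_tracts(path) -> TractSet:
    path = Path(path)
    ext = path.suffix.lower()
    if ext not in (".tck", ".trk"):
        raise FormatError(f"unknown streamline extension {ext!r} (use .tck or .trk)")
    tfile = nib.streamlines.load(str(path))
    streamlines = [np.asarray(s, dtype=float) for s in tfile.tractogram.streamlines]
    labels: list[int | None] = [None] * len(streamlines)
    sidecar = _label_sidecar(path)
    if sidecar.exists():
        raw = json.loads(sidecar.read_text())
        if len(raw) == len(streamlines):
            labels = [None if lab is None else int(lab) for lab in raw]
    tracts = [
        Tract(points=pts, bundle_label=lab) for pts, lab in zip(streamlines, labels)
    ]
    return TractSet(tracts=tracts)
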