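"""Global tractography as a Gibbs point process of oriented segments.

The state is a set of short oriented line segments ("particles"), each
contributing a stick-model template signal to the voxels its axis
traverses. Segments carry two endpoints that can bind pairwise into chains;
chains are read out as streamlines. The posterior energy is

    E = E_ext + E_int

``E_ext``
    scaled sum of squared differences between the predicted and observed
    *anisotropic* signal (both mean-subtracted across gradient directions,
    so the isotropic baseline drops out) over masked voxels.
``E_int``
    ``+density_penalty`` per free endpoint, and
    ``+connection_strength * (1 - exp(-gap^2/sigma_gap^2 - bend^2/sigma_bend^2))``
    per bound endpoint pair (gap in mm between the bound endpoints, bend in
    radians between the antipodally-aligned axes): a geometrically perfect
    join costs nothing, a strained one up to ``connection_strength``. With
    ``connection_strength > 2 * density_penalty`` a geometry-blind bind is
    energetically unfavorable, so chains only grow along coherent paths and
    the particle count stays data-driven.

Optimization is Metropolis-Hastings over birth/death (reversible-jump with
a unit-rate Poisson reference), shift, rotate, and connect/disconnect
moves, with an exponential simulated-annealing temperature schedule.
Energies are tracked incrementally and must agree with full recomputation
— :func:`check_integrity` verifies this together with link symmetry and
the endpoint spatial index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import DWIVolume, LabelMask, Tract, TractSet

__all__ = [
    "GibbsParams",
    "GibbsModel",
    "SegmentConfiguration",
    "EnergyBreakdown",
    "Move",
    "predict_signal",
    "external_energy",
    "internal_energy",
    "total_energy",
    "propose_move",
    "metropolis_step",
    "run_chain",
    "anneal",
    "extract_streamlines",
    "check_integrity",
]

# phase 1 (orientation refinement; binding disabled) and phase 2 (chain
# assembly) of the annealing schedule; see GibbsParams.binding_delay_fraction
DEFAULT_REFINE_MOVES = {
    "birth": 0.15,
    "death": 0.15,
    "shift": 0.20,
    "rotate": 0.50,
    "connect": 0.0,
    "disconnect": 0.0,
}
DEFAULT_ASSEMBLY_MOVES = {
    "birth": 0.05,
    "death": 0.05,
    "shift": 0.10,
    "rotate": 0.20,
    "connect": 0.30,
    "disconnect": 0.30,
}
_MOVE_KINDS = ("birth", "death", "shift", "rotate", "connect", "disconnect")

_N_AXIS_SAMPLES = 5  # quadrature points apportioning a segment across voxels


@dataclass
class GibbsParams:
    """Configuration of the segment model and the annealing run.

    Segment length/width/weight and the density penalty default to the
    values used for muscle reconstructions at acquisition scale
    (length 1.172 mm, width 0.3 mm, weight 0.096, penalty 0.2); the desk
    default of 2e5 iterations suits phantom grids, with the full-scale
    budget available by raising ``n_iterations``.
    """

    n_iterations: int = 200_000
    t_start: float = 0.1
    t_end: float = 0.001
    segment_length: float = 1.172  # mm (full length)
    segment_width: float = 0.3  # mm; sets the contribution kernel, not attenuation
    segment_weight: float = 0.096
    density_penalty: float = 0.2  # prior cost per free endpoint
    connection_strength: float = 0.45
    sigma_gap: float | None = None  # mm; gap scale of the join kernel, default 2 * segment_length
    sigma_bend: float = 0.45  # rad; bend scale of the join kernel
    connect_radius: float | None = None  # default 3.5 * segment_length
    stick_diffusivity: float = 1.5e-3  # mm^2/s in the template signal
    external_scale: float | None = None  # default 0.4 * segment_weight**-2
    move_probabilities: dict = field(
        default_factory=lambda: dict(DEFAULT_REFINE_MOVES)
    )
    assembly_move_probabilities: dict = field(
        default_factory=lambda: dict(DEFAULT_ASSEMBLY_MOVES)
    )
    binding_delay_fraction: float = 0.75  # fraction of the schedule run without
    # connection moves: the orientation field is annealed first, chains are
    # assembled in the remaining low-temperature phase
    assembly_width_scale: float = 0.5  # extra shift/rotate width shrink in phase 2
    shift_sigma: float | None = None  # mm; default segment_length/4
    rotate_sigma: float = 0.35  # rad
    init_density: float = 5.0  # initial particles per masked voxel
    init_mode: str = "tensor"  # "tensor": orientations seeded from the local
    # principal eigenvector (+ jitter); "random": uniform orientations
    init_jitter: float = 0.1  # rad, jitter of tensor-informed init orientations
    anneal_proposal_scaling: bool = True  # scale shift/rotate widths with sqrt(T/t_start)
    rng_seed: int = 0
    max_particles: int | None = None
    # discrete toy mode: births draw orientations from this set and positions
    # sit at masked-voxel centres, making the state space enumerable
    orientation_set: np.ndarray | None = None
    fixed_position: bool = False

    def __post_init__(self) -> None:
        if not (self.t_start >= self.t_end > 0):
            raise ValueError("need t_start >= t_end > 0")
        for probs in (self.move_probabilities, self.assembly_move_probabilities):
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("move probabilities must sum to 1")
            unknown = set(probs) - set(_MOVE_KINDS)
            if unknown:
                raise ValueError(f"unknown move types: {sorted(unknown)}")
        if not 0.0 <= self.binding_delay_fraction <= 1.0:
            raise ValueError("binding_delay_fraction must lie in [0, 1]")
        if self.init_mode not in ("tensor", "random"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")
        if self.orientation_set is not None:
            self.orientation_set = np.asarray(self.orientation_set, dtype=float)
            norms = np.linalg.norm(self.orientation_set, axis=1)
            self.orientation_set = self.orientation_set / norms[:, None]
            self.init_mode = "random"  # discrete mode draws from the set

    @property
    def half_length(self) -> float:
        return self.segment_length / 2.0

    @property
    def sigma_gap_val(self) -> float:
        return self.sigma_gap if self.sigma_gap is not None else 2.0 * self.segment_length

    @property
    def connect_radius_val(self) -> float:
        return (
            self.connect_radius
            if self.connect_radius is not None
            else 3.5 * self.segment_length
        )

    @property
    def shift_sigma_val(self) -> float:
        return (
            self.shift_sigma if self.shift_sigma is not None else self.segment_length / 4.0
        )

    @property
    def external_scale_val(self) -> float:
        """Data-term scale; calibrated so typical per-particle energies sit
        between the start and end temperatures of the annealing schedule."""
        if self.external_scale is not None:
            return self.external_scale
        return 0.4 * self.segment_weight**-2


@dataclass
class EnergyBreakdown:
    external: float
    internal: float

    @property
    def total(self) -> float:
        return self.external + self.internal


class GibbsModel:
    """Precomputed data context: observed anisotropic signal on the mask."""

    def __init__(self, dwi: DWIVolume, mask: LabelMask, params: GibbsParams):
        self.params = params
        gtab = dwi.gtab
        dirsel = ~gtab.b0_mask
        self.bvecs = gtab.bvecs[dirsel]  # (G, 3)
        self.bd = gtab.bvals[dirsel] * params.stick_diffusivity  # (G,)
        self.n_dirs = len(self.bd)

        s0 = dwi.b0_image()
        m = mask.binary() & (s0 > 0)
        if not m.any():
            raise ValueError("mask selects no voxels with signal")
        self.mask = m
        self.shape = dwi.shape
        self.affine = dwi.affine.copy()
        self.inv_affine = np.linalg.inv(self.affine)
        self.voxel_size = dwi.voxel_size

        self.rows = -np.ones(self.shape, dtype=np.int64)
        vox_idx = np.argwhere(m)
        self.rows[m] = np.arange(len(vox_idx))
        self.vox_idx = vox_idx
        self.n_voxels = len(vox_idx)
        self.voxel_centers = vox_idx @ self.affine[:3, :3].T + self.affine[:3, 3]

        att = dwi.data[m][:, dirsel] / s0[m][:, None]
        self.obs = att - att.mean(axis=1, keepdims=True)  # (V, G)

        self.scale = params.external_scale_val
        # hot-path caches
        self._axis_t = np.linspace(
            -params.half_length, params.half_length, _N_AXIS_SAMPLES
        )[:, None]
        self._inv_lin = self.inv_affine[:3, :3].T.copy()
        self._inv_off = self.inv_affine[:3, 3].copy()
        self._shape_arr = np.asarray(self.shape)
        self.set_move_probabilities(params.move_probabilities)
        self.width_scale = 1.0
        self._weight_per_sample = params.segment_weight / _N_AXIS_SAMPLES

        # tensor-informed initialization: principal eigenvector per masked voxel
        self.init_directions = None
        if params.init_mode == "tensor" and params.init_density > 0:
            from .tensor import fit_tensor

            tf = fit_tensor(dwi, mask)
            pd = tf.eigenvectors[..., :, 0][m]  # (V, 3)
            ok = tf.valid_mask[m]
            rnd = np.random.default_rng(params.rng_seed + 101).standard_normal(
                pd.shape
            )
            pd = np.where(ok[:, None], pd, rnd)
            self.init_directions = pd / np.linalg.norm(pd, axis=1, keepdims=True)
        # reference measure of the birth/death point process
        if params.orientation_set is not None:
            n_orient = len(params.orientation_set)
        else:
            n_orient = 2.0 * np.pi  # antipodal orientation classes, uniform density
        if params.fixed_position:
            self.birth_measure = self.n_voxels * n_orient
        else:
            self.birth_measure = self.n_voxels * float(np.prod(self.voxel_size)) * n_orient

    def set_move_probabilities(self, probs: dict) -> None:
        """Switch the active move-kind distribution (annealing phases)."""
        self.move_probs = {k: probs.get(k, 0.0) for k in _MOVE_KINDS}
        self._move_kinds = [k for k in _MOVE_KINDS if self.move_probs[k] > 0]
        self._move_cum = np.cumsum([self.move_probs[k] for k in self._move_kinds])

    # -- geometry helpers ---------------------------------------------------

    def world_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        return np.rint(
            pts @ self.inv_affine[:3, :3].T + self.inv_affine[:3, 3]
        ).astype(np.int64)

    def contributions(self, pos: np.ndarray, ori: np.ndarray):
        """Voxel rows a segment touches and its per-row signal coefficients.

        The axis is sampled at ``_N_AXIS_SAMPLES`` points; each carries an
        equal share of the segment weight, apportioning the contribution by
        traversed length. Returns ``(rows, coef, attenuation)`` where the
        contribution of the segment to row r, direction g is
        ``coef[r] * attenuation[g]``.
        """
        pts = pos + self._axis_t * ori
        ijk = np.rint(pts @ self._inv_lin + self._inv_off).astype(np.int64)
        counts: dict[int, int] = {}
        shape = self.shape
        rows_grid = self.rows
        for i, j, k in ijk:
            if 0 <= i < shape[0] and 0 <= j < shape[1] and 0 <= k < shape[2]:
                r = rows_grid[i, j, k]
                if r >= 0:
                    counts[r] = counts.get(r, 0) + 1
        if not counts:
            return np.empty(0, dtype=np.int64), np.empty(0), np.empty(self.n_dirs)
        urows = np.fromiter(counts.keys(), dtype=np.int64, count=len(counts))
        coef = (
            np.fromiter(counts.values(), dtype=np.float64, count=len(counts))
            * self._weight_per_sample
        )
        dots = self.bvecs @ ori
        att = np.exp(-self.bd * dots**2)
        return urows, coef, att

    def row_energy(self, rows: np.ndarray, P_rows: np.ndarray) -> np.ndarray:
        """External energy of the given voxel rows for predicted signal P_rows."""
        resid = (P_rows - P_rows.mean(axis=1, keepdims=True)) - self.obs[rows]
        return self.scale * (resid**2).sum(axis=1)


@dataclass
class Move:
    kind: str
    null: bool = False
    log_q_ratio: float = 0.0  # log(q_reverse / q_forward), incl. state-space factors
    delta_external: float = 0.0
    delta_internal: float = 0.0
    payload: dict = field(default_factory=dict)

    @property
    def delta_total(self) -> float:
        return self.delta_external + self.delta_internal


class SegmentConfiguration:
    """Mutable particle configuration with cached energies and indices.

    Maintains, incrementally under every accepted move: the predicted
    signal per masked voxel, per-voxel external energy, total internal
    energy, link symmetry, a spatial hash of *free* endpoints (cell size =
    connect radius), and O(1)-pick lists of alive particles, unbound
    particles and bound pairs.
    """

    def __init__(self, model: GibbsModel):
        self.model = model
        p = model.params
        cap = 1024
        self.pos = np.zeros((cap, 3))
        self.ori = np.zeros((cap, 3))
        self.alive = np.zeros(cap, dtype=bool)
        self.link_p = -np.ones((cap, 2), dtype=np.int64)  # partner particle
        self.link_e = np.zeros((cap, 2), dtype=np.int8)  # partner endpoint slot
        self.rows_of: list = [None] * cap
        self.coef_of: list = [None] * cap
        self.att_of: list = [None] * cap

        self.free_slots = list(range(cap - 1, -1, -1))
        self.alive_ids: list[int] = []
        self.apos = -np.ones(cap, dtype=np.int64)
        self.unbound_ids: list[int] = []
        self.upos = -np.ones(cap, dtype=np.int64)

        self.free_ends: list[tuple[int, int]] = []
        self.fe_pos: dict[tuple[int, int], int] = {}
        self.pairs: list[tuple[int, int]] = []  # canonical endpoint of each pair
        self.pair_pos: dict[tuple[int, int], int] = {}
        self.pair_val: dict[tuple[int, int], float] = {}  # cached compat of pair

        self.cell_size = p.connect_radius_val
        self.hash: dict[tuple[int, int, int], set] = {}

        self.P = np.zeros((model.n_voxels, model.n_dirs))
        self.Ev = model.row_energy(
            np.arange(model.n_voxels), self.P
        )  # all-zero prediction
        self.e_ext = float(self.Ev.sum())
        self.e_int = 0.0

    # -- basic queries ------------------------------------------------------

    @property
    def n_particles(self) -> int:
        return len(self.alive_ids)

    @property
    def n_unbound(self) -> int:
        return len(self.unbound_ids)

    @property
    def n_free_ends(self) -> int:
        return len(self.free_ends)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def energy(self) -> EnergyBreakdown:
        return EnergyBreakdown(external=self.e_ext, internal=self.e_int)

    def endpoint_position(self, pid: int, e: int) -> np.ndarray:
        sign = 1.0 if e == 1 else -1.0
        return self.pos[pid] + sign * self.model.params.half_length * self.ori[pid]

    def is_bound(self, pid: int, e: int) -> bool:
        return self.link_p[pid, e] >= 0

    # -- capacity -----------------------------------------------------------

    def _grow(self) -> None:
        old = len(self.alive)
        new = old * 2
        self.pos = np.vstack([self.pos, np.zeros((old, 3))])
        self.ori = np.vstack([self.ori, np.zeros((old, 3))])
        self.alive = np.concatenate([self.alive, np.zeros(old, dtype=bool)])
        self.link_p = np.vstack([self.link_p, -np.ones((old, 2), dtype=np.int64)])
        self.link_e = np.vstack([self.link_e, np.zeros((old, 2), dtype=np.int8)])
        self.apos = np.concatenate([self.apos, -np.ones(old, dtype=np.int64)])
        self.upos = np.concatenate([self.upos, -np.ones(old, dtype=np.int64)])
        self.rows_of.extend([None] * old)
        self.coef_of.extend([None] * old)
        self.att_of.extend([None] * old)
        self.free_slots.extend(range(new - 1, old - 1, -1))

    # -- spatial hash of free endpoints --------------------------------------

    def _cell(self, x: np.ndarray) -> tuple[int, int, int]:
        c = np.floor(x / self.cell_size).astype(int)
        return (int(c[0]), int(c[1]), int(c[2]))

    def _hash_add(self, pid: int, e: int) -> None:
        cell = self._cell(self.endpoint_position(pid, e))
        self.hash.setdefault(cell, set()).add((pid, e))

    def _hash_remove(self, pid: int, e: int) -> None:
        cell = self._cell(self.endpoint_position(pid, e))
        s = self.hash.get(cell)
        if s is None or (pid, e) not in s:
            raise RuntimeError("spatial index inconsistent")
        s.remove((pid, e))
        if not s:
            del self.hash[cell]

    def nearby_free_ends(self, x: np.ndarray, exclude_pid: int):
        """Free endpoints within the connect radius of world point ``x``."""
        c = np.floor(x / self.cell_size).astype(int)
        out = []
        r = self.model.params.connect_radius_val
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    s = self.hash.get((int(c[0] + di), int(c[1] + dj), int(c[2] + dk)))
                    if not s:
                        continue
                    for pid, e in s:
                        if pid == exclude_pid:
                            continue
                        if np.linalg.norm(self.endpoint_position(pid, e) - x) <= r:
                            out.append((pid, e))
        out.sort()  # deterministic candidate order
        return out

    # -- free/unbound bookkeeping --------------------------------------------

    def _free_add(self, pid: int, e: int) -> None:
        self.fe_pos[(pid, e)] = len(self.free_ends)
        self.free_ends.append((pid, e))
        self._hash_add(pid, e)

    def _free_remove(self, pid: int, e: int) -> None:
        self._hash_remove(pid, e)
        i = self.fe_pos.pop((pid, e))
        last = self.free_ends.pop()
        if i < len(self.free_ends):
            self.free_ends[i] = last
            self.fe_pos[last] = i

    def _unbound_add(self, pid: int) -> None:
        self.upos[pid] = len(self.unbound_ids)
        self.unbound_ids.append(pid)

    def _unbound_remove(self, pid: int) -> None:
        i = self.upos[pid]
        last = self.unbound_ids.pop()
        if i < len(self.unbound_ids):
            self.unbound_ids[i] = last
            self.upos[last] = i
        self.upos[pid] = -1

    # -- external energy updates ----------------------------------------------

    def _apply_contribution(self, rows, coef, att, sign: float) -> float:
        """Add/remove a particle's predicted signal; returns the Ev delta."""
        if len(rows) == 0:
            return 0.0
        self.P[rows] += sign * coef[:, None] * att[None, :]
        new_e = self.model.row_energy(rows, self.P[rows])
        delta = float(new_e.sum() - self.Ev[rows].sum())
        self.Ev[rows] = new_e
        return delta

    def _peek_contribution_delta(self, rows, coef, att, sign: float) -> float:
        """Ev delta the contribution *would* cause, without applying it."""
        if len(rows) == 0:
            return 0.0
        newP = self.P[rows] + sign * coef[:, None] * att[None, :]
        return float(
            self.model.row_energy(rows, newP).sum() - self.Ev[rows].sum()
        )

    # -- compatibility -------------------------------------------------------

    def compat(self, a: tuple[int, int], b: tuple[int, int]) -> float:
        """Join quality in (0, 1]: 1 for abutting, collinear, head-to-tail.

        The bend uses chain-directed vectors (the outgoing direction of each
        endpoint), not antipodal axes: binding two parallel neighbours
        head-to-head is a 180-degree fold of the chain and scores ~0 even
        though their axes are parallel.
        """
        (p, e), (q, f) = a, b
        gap = float(
            np.linalg.norm(self.endpoint_position(p, e) - self.endpoint_position(q, f))
        )
        d_p = self.ori[p] if e == 1 else -self.ori[p]
        d_q = self.ori[q] if f == 1 else -self.ori[q]
        cosb = -float(d_p @ d_q)  # straight continuation has opposite outgoing dirs
        bend = math.acos(max(-1.0, min(1.0, cosb)))
        par = self.model.params
        return math.exp(
            -(gap**2) / par.sigma_gap_val**2 - bend**2 / par.sigma_bend**2
        )

    def pair_energy(self, a, b) -> float:
        cs = self.model.params.connection_strength
        return cs * (1.0 - self.compat(a, b))

    def _canonical_pair(self, pid: int, e: int) -> tuple[int, int]:
        q, f = int(self.link_p[pid, e]), int(self.link_e[pid, e])
        return (pid, e) if pid < q else (q, f)

    # -- structural mutations (used by metropolis_step) ------------------------

    def insert_particle(self, pos: np.ndarray, ori: np.ndarray) -> int:
        if not self.free_slots:
            self._grow()
        pid = self.free_slots.pop()
        self.pos[pid] = pos
        self.ori[pid] = ori
        self.alive[pid] = True
        self.link_p[pid] = -1
        rows, coef, att = self.model.contributions(pos, ori)
        self.rows_of[pid], self.coef_of[pid], self.att_of[pid] = rows, coef, att
        self.e_ext += self._apply_contribution(rows, coef, att, +1.0)
        self.e_int += 2.0 * self.model.params.density_penalty
        self.apos[pid] = len(self.alive_ids)
        self.alive_ids.append(pid)
        self._unbound_add(pid)
        self._free_add(pid, 0)
        self._free_add(pid, 1)
        return pid

    def remove_particle(self, pid: int) -> None:
        if self.is_bound(pid, 0) or self.is_bound(pid, 1):
            raise RuntimeError("cannot remove a bound particle")
        self._free_remove(pid, 0)
        self._free_remove(pid, 1)
        self._unbound_remove(pid)
        i = self.apos[pid]
        last = self.alive_ids.pop()
        if i < len(self.alive_ids):
            self.alive_ids[i] = last
            self.apos[last] = i
        self.apos[pid] = -1
        self.e_ext += self._apply_contribution(
            self.rows_of[pid], self.coef_of[pid], self.att_of[pid], -1.0
        )
        self.e_int -= 2.0 * self.model.params.density_penalty
        self.alive[pid] = False
        self.rows_of[pid] = self.coef_of[pid] = self.att_of[pid] = None
        self.free_slots.append(pid)

    def reshape_particle(self, pid: int, new_pos: np.ndarray, new_ori: np.ndarray) -> None:
        """Move/rotate a particle, updating signal, pair terms and the hash."""
        for e in (0, 1):
            if not self.is_bound(pid, e):
                self._hash_remove(pid, e)
        self.e_ext += self._apply_contribution(
            self.rows_of[pid], self.coef_of[pid], self.att_of[pid], -1.0
        )
        self.pos[pid] = new_pos
        self.ori[pid] = new_ori
        rows, coef, att = self.model.contributions(new_pos, new_ori)
        self.rows_of[pid], self.coef_of[pid], self.att_of[pid] = rows, coef, att
        self.e_ext += self._apply_contribution(rows, coef, att, +1.0)
        cs = self.model.params.connection_strength
        for e in (0, 1):
            if self.is_bound(pid, e):
                key = self._canonical_pair(pid, e)
                partner = (int(self.link_p[pid, e]), int(self.link_e[pid, e]))
                new_c = self.compat((pid, e), partner)
                self.e_int += cs * (1.0 - new_c) - cs * (1.0 - self.pair_val[key])
                self.pair_val[key] = new_c
            else:
                self._hash_add(pid, e)

    def bind(self, a: tuple[int, int], b: tuple[int, int]) -> None:
        (p, e), (q, f) = a, b
        if p == q:
            raise RuntimeError("a particle cannot bind to itself")
        if self.is_bound(p, e) or self.is_bound(q, f):
            raise RuntimeError("endpoint already bound")
        self._free_remove(p, e)
        self._free_remove(q, f)
        if self.upos[p] >= 0:
            self._unbound_remove(p)
        if self.upos[q] >= 0:
            self._unbound_remove(q)
        self.link_p[p, e], self.link_e[p, e] = q, f
        self.link_p[q, f], self.link_e[q, f] = p, e
        key = (p, e) if p < q else (q, f)
        self.pair_pos[key] = len(self.pairs)
        self.pairs.append(key)
        c = self.compat(a, b)
        self.pair_val[key] = c
        par = self.model.params
        self.e_int += -2.0 * par.density_penalty + par.connection_strength * (1.0 - c)

    def unbind(self, key: tuple[int, int]) -> None:
        p, e = key
        q, f = int(self.link_p[p, e]), int(self.link_e[p, e])
        if q < 0:
            raise RuntimeError("endpoint is not bound")
        key = self._canonical_pair(p, e)
        i = self.pair_pos.pop(key)
        last = self.pairs.pop()
        if i < len(self.pairs):
            self.pairs[i] = last
            self.pair_pos[last] = i
        c = self.pair_val.pop(key)
        self.link_p[p, e] = -1
        self.link_p[q, f] = -1
        self._free_add(p, e)
        self._free_add(q, f)
        if not (self.is_bound(p, 1 - e)):
            self._unbound_add(p)
        if not (self.is_bound(q, 1 - f)):
            self._unbound_add(q)
        par = self.model.params
        self.e_int -= -2.0 * par.density_penalty + par.connection_strength * (1.0 - c)


# ---------------------------------------------------------------------------
# energies from scratch (oracles for the incremental bookkeeping)


def predict_signal(cfg: SegmentConfiguration) -> np.ndarray:
    """Predicted anisotropic signal, (n_masked_voxels, n_dirs), from scratch."""
    model = cfg.model
    P = np.zeros((model.n_voxels, model.n_dirs))
    for pid in cfg.alive_ids:
        rows, coef, att = model.contributions(cfg.pos[pid], cfg.ori[pid])
        if len(rows):
            P[rows] += coef[:, None] * att[None, :]
    return P


def external_energy(cfg: SegmentConfiguration) -> float:
    """Full recomputation of the data-mismatch energy."""
    model = cfg.model
    P = predict_signal(cfg)
    return float(model.row_energy(np.arange(model.n_voxels), P).sum())


def internal_energy(cfg: SegmentConfiguration) -> float:
    """Full recomputation of the connection + density prior energy."""
    par = cfg.model.params
    e = par.density_penalty * cfg.n_free_ends
    for key in cfg.pairs:
        p, ep = key
        partner = (int(cfg.link_p[p, ep]), int(cfg.link_e[p, ep]))
        if (int(cfg.link_p[partner[0], partner[1]]), int(cfg.link_e[partner[0], partner[1]])) != key:
            raise RuntimeError("asymmetric link detected")
        e += par.connection_strength * (1.0 - cfg.compat(key, partner))
    return float(e)


def total_energy(cfg: SegmentConfiguration) -> EnergyBreakdown:
    return EnergyBreakdown(external=external_energy(cfg), internal=internal_energy(cfg))


# ---------------------------------------------------------------------------
# moves


def _sample_orientation(params: GibbsParams, rng: np.random.Generator) -> np.ndarray:
    if params.orientation_set is not None:
        return params.orientation_set[rng.integers(len(params.orientation_set))]
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _connect_weights(cfg, endpoint, candidates, temperature):
    """Boltzmann proposal weights over candidate partners of an endpoint."""
    if not candidates:
        return np.empty(0)
    e_pair = np.array([cfg.pair_energy(endpoint, c) for c in candidates])
    w = np.exp(-(e_pair - e_pair.min()) / temperature)
    return w / w.sum()


def propose_move(
    cfg: SegmentConfiguration,
    rng: np.random.Generator,
    temperature: float,
) -> Move:
    """Draw a move and precompute its energy deltas and proposal ratio.

    Impossible draws (death on an empty configuration, connect with no
    candidate in range, ...) return a null move, counted as rejected.
    """
    model = cfg.model
    par = model.params
    ki = int(np.searchsorted(model._move_cum, rng.random()))
    kind = model._move_kinds[min(ki, len(model._move_kinds) - 1)]
    p_of = model.move_probs

    if kind == "birth":
        if par.max_particles is not None and cfg.n_particles >= par.max_particles:
            return Move(kind, null=True)
        vi = rng.integers(model.n_voxels)
        center = model.voxel_centers[vi]
        if par.fixed_position:
            pos = center.copy()
        else:
            pos = center + (rng.uniform(-0.5, 0.5, 3) * model.voxel_size)
        ori = _sample_orientation(par, rng)
        rows, coef, att = model.contributions(pos, ori)
        d_ext = cfg._peek_contribution_delta(rows, coef, att, +1.0)
        d_int = 2.0 * par.density_penalty
        log_q = math.log(
            p_of["death"] * model.birth_measure / (p_of["birth"] * (cfg.n_unbound + 1))
        )
        return Move(
            kind,
            log_q_ratio=log_q,
            delta_external=d_ext,
            delta_internal=d_int,
            payload={"pos": pos, "ori": ori},
        )

    if kind == "death":
        if cfg.n_unbound == 0:
            return Move(kind, null=True)
        pid = cfg.unbound_ids[rng.integers(cfg.n_unbound)]
        d_ext = cfg._peek_contribution_delta(
            cfg.rows_of[pid], cfg.coef_of[pid], cfg.att_of[pid], -1.0
        )
        d_int = -2.0 * par.density_penalty
        log_q = math.log(
            p_of["birth"] * cfg.n_unbound / (p_of["death"] * model.birth_measure)
        )
        return Move(
            kind,
            log_q_ratio=log_q,
            delta_external=d_ext,
            delta_internal=d_int,
            payload={"pid": pid},
        )

    if kind in ("shift", "rotate"):
        if cfg.n_particles == 0:
            return Move(kind, null=True)
        pid = cfg.alive_ids[rng.integers(cfg.n_particles)]
        if par.anneal_proposal_scaling:
            width = min(1.0, max(0.1, math.sqrt(temperature / par.t_start)))
        else:
            width = 1.0
        width *= model.width_scale
        if kind == "shift":
            if par.fixed_position:
                return Move(kind, null=True)
            new_pos = cfg.pos[pid] + width * par.shift_sigma_val * rng.standard_normal(3)
            ijk = model.world_to_voxel(new_pos[None, :])[0]
            if np.any(ijk < 0) or np.any(ijk >= np.asarray(model.shape)):
                return Move(kind, null=True)
            if model.rows[ijk[0], ijk[1], ijk[2]] < 0:
                return Move(kind, null=True)  # support is the masked region
            new_ori = cfg.ori[pid].copy()
        else:
            if par.orientation_set is not None:
                new_ori = par.orientation_set[
                    rng.integers(len(par.orientation_set))
                ].copy()
            else:
                v = cfg.ori[pid] + width * par.rotate_sigma * rng.standard_normal(3)
                nv = np.linalg.norm(v)
                if nv < 1e-12:
                    return Move(kind, null=True)
                new_ori = v / nv
            new_pos = cfg.pos[pid].copy()
        d_ext, d_int = _reshape_deltas(cfg, pid, new_pos, new_ori)
        return Move(
            kind,
            delta_external=d_ext,
            delta_internal=d_int,
            payload={"pid": pid, "pos": new_pos, "ori": new_ori},
        )

    if kind == "connect":
        if cfg.n_free_ends == 0 or p_of["disconnect"] <= 0:
            return Move(kind, null=True)
        a = cfg.free_ends[rng.integers(cfg.n_free_ends)]
        xa = cfg.endpoint_position(*a)
        cands = cfg.nearby_free_ends(xa, exclude_pid=a[0])
        if not cands:
            return Move(kind, null=True)
        w = _connect_weights(cfg, a, cands, temperature)
        b = cands[rng.choice(len(cands), p=w)]
        p_a_to_b = w[cands.index(b)]
        xb = cfg.endpoint_position(*b)
        cands_b = cfg.nearby_free_ends(xb, exclude_pid=b[0])
        w_b = _connect_weights(cfg, b, cands_b, temperature)
        p_b_to_a = float(w_b[cands_b.index(a)]) if a in cands_b else 0.0
        q_fwd = (p_of["connect"] / cfg.n_free_ends) * (float(p_a_to_b) + p_b_to_a)
        q_rev = p_of["disconnect"] / (cfg.n_pairs + 1)
        c = cfg.compat(a, b)
        d_int = -2.0 * par.density_penalty + par.connection_strength * (1.0 - c)
        return Move(
            kind,
            log_q_ratio=math.log(q_rev) - math.log(q_fwd),
            delta_internal=d_int,
            payload={"a": a, "b": b},
        )

    if kind == "disconnect":
        if cfg.n_pairs == 0 or p_of["connect"] <= 0:
            return Move(kind, null=True)
        key = cfg.pairs[rng.integers(cfg.n_pairs)]
        a = key
        b = (int(cfg.link_p[a[0], a[1]]), int(cfg.link_e[a[0], a[1]]))
        c = cfg.pair_val[key]
        q_fwd = p_of["disconnect"] / cfg.n_pairs
        # reverse connect probability, evaluated in the post-unbind state:
        # current free endpoints plus the two endpoints this move frees
        xa = cfg.endpoint_position(*a)
        xb = cfg.endpoint_position(*b)
        r = par.connect_radius_val
        cands_a = cfg.nearby_free_ends(xa, exclude_pid=a[0])
        if b[0] != a[0] and np.linalg.norm(xb - xa) <= r:
            cands_a = sorted(cands_a + [b])
        cands_b = cfg.nearby_free_ends(xb, exclude_pid=b[0])
        if a[0] != b[0] and np.linalg.norm(xa - xb) <= r:
            cands_b = sorted(cands_b + [a])
        w_a = _connect_weights(cfg, a, cands_a, temperature)
        w_b = _connect_weights(cfg, b, cands_b, temperature)
        p_a_to_b = float(w_a[cands_a.index(b)]) if b in cands_a else 0.0
        p_b_to_a = float(w_b[cands_b.index(a)]) if a in cands_b else 0.0
        n_free_after = cfg.n_free_ends + 2
        q_rev = (p_of["connect"] / n_free_after) * (p_a_to_b + p_b_to_a)
        if q_rev <= 0.0:
            return Move(kind, null=True)  # unreachable reverse; reject for balance
        d_int = 2.0 * par.density_penalty - par.connection_strength * (1.0 - c)
        return Move(
            kind,
            log_q_ratio=math.log(q_rev) - math.log(q_fwd),
            delta_internal=d_int,
            payload={"key": key},
        )

    raise ValueError(kind)


def _reshape_deltas(cfg, pid, new_pos, new_ori):
    """Energy deltas of a shift/rotate without applying it."""
    model = cfg.model
    par = model.params
    old_rows, old_coef, old_att = cfg.rows_of[pid], cfg.coef_of[pid], cfg.att_of[pid]
    new_rows, new_coef, new_att = model.contributions(new_pos, new_ori)
    rows = np.union1d(old_rows, new_rows)
    if len(rows):
        newP = cfg.P[rows].copy()
        if len(old_rows):
            idx = np.searchsorted(rows, old_rows)
            newP[idx] -= old_coef[:, None] * old_att[None, :]
        if len(new_rows):
            idx = np.searchsorted(rows, new_rows)
            newP[idx] += new_coef[:, None] * new_att[None, :]
        d_ext = float(
            model.row_energy(rows, newP).sum() - cfg.Ev[rows].sum()
        )
    else:
        d_ext = 0.0
    d_int = 0.0
    half = par.half_length
    for e in (0, 1):
        if cfg.is_bound(pid, e):
            q, f = int(cfg.link_p[pid, e]), int(cfg.link_e[pid, e])
            key = cfg._canonical_pair(pid, e)
            sign = 1.0 if e == 1 else -1.0
            new_end = new_pos + sign * half * new_ori
            other = cfg.endpoint_position(q, f)
            gap = float(np.linalg.norm(new_end - other))
            d_p = sign * new_ori
            d_q = cfg.ori[q] if f == 1 else -cfg.ori[q]
            cosb = -float(d_p @ d_q)
            bend = math.acos(max(-1.0, min(1.0, cosb)))
            new_c = math.exp(
                -(gap**2) / par.sigma_gap_val**2 - bend**2 / par.sigma_bend**2
            )
            d_int += par.connection_strength * (cfg.pair_val[key] - new_c)
    return d_ext, d_int


def metropolis_step(
    cfg: SegmentConfiguration,
    move: Move,
    temperature: float,
    rng: np.random.Generator,
) -> bool:
    """Accept/reject with min(1, exp(-dE/T) * q_rev/q_fwd); apply on accept."""
    if move.null:
        return False
    log_alpha = -move.delta_total / temperature + move.log_q_ratio
    if log_alpha < 0 and math.log(rng.uniform()) >= log_alpha:
        return False
    kind = move.kind
    pay = move.payload
    if kind == "birth":
        cfg.insert_particle(pay["pos"], pay["ori"])
    elif kind == "death":
        cfg.remove_particle(pay["pid"])
    elif kind in ("shift", "rotate"):
        cfg.reshape_particle(pay["pid"], pay["pos"], pay["ori"])
    elif kind == "connect":
        cfg.bind(pay["a"], pay["b"])
    elif kind == "disconnect":
        cfg.unbind(pay["key"])
    else:
        raise ValueError(kind)
    return True


# ---------------------------------------------------------------------------
# chains


def run_chain(
    cfg: SegmentConfiguration,
    n_steps: int,
    temperature: float | tuple[float, float],
    rng: np.random.Generator,
    callback=None,
    record_every: int | None = None,
):
    """Run Metropolis steps at fixed or exponentially-interpolated temperature.

    Returns an energy-trace record array. ``callback(step, cfg, accepted)``
    is invoked after every step (used by the Boltzmann-sampling tests).
    """
    if isinstance(temperature, tuple):
        t0, t1 = temperature
        temps = t0 * (t1 / t0) ** (np.arange(n_steps) / max(n_steps - 1, 1))
    else:
        temps = np.full(n_steps, float(temperature))
    if record_every is None:
        record_every = max(1, n_steps // 1000)
    trace = []
    n_acc = 0
    for i in range(n_steps):
        move = propose_move(cfg, rng, temps[i])
        accepted = metropolis_step(cfg, move, temps[i], rng)
        n_acc += accepted
        if callback is not None:
            callback(i, cfg, accepted)
        if i % record_every == 0 or i == n_steps - 1:
            trace.append(
                (i, temps[i], cfg.e_ext, cfg.e_int, cfg.n_particles, cfg.n_pairs, n_acc)
            )
    return np.array(
        trace,
        dtype=[
            ("iteration", "i8"),
            ("temperature", "f8"),
            ("external", "f8"),
            ("internal", "f8"),
            ("n_particles", "i8"),
            ("n_pairs", "i8"),
            ("n_accepted", "i8"),
        ],
    )


def _init_configuration(
    model: GibbsModel, params: GibbsParams, rng: np.random.Generator
) -> SegmentConfiguration:
    cfg = SegmentConfiguration(model)
    n_init = int(round(params.init_density * model.n_voxels))
    for _ in range(n_init):
        vi = rng.integers(model.n_voxels)
        if params.fixed_position:
            pos = model.voxel_centers[vi].copy()
        else:
            pos = model.voxel_centers[vi] + rng.uniform(-0.5, 0.5, 3) * model.voxel_size
        if model.init_directions is not None:
            v = model.init_directions[vi] + params.init_jitter * rng.standard_normal(3)
            ori = v / np.linalg.norm(v)
        else:
            ori = _sample_orientation(params, rng)
        cfg.insert_particle(pos, ori)
    return cfg


def anneal(
    dwi: DWIVolume,
    mask: LabelMask,
    params: GibbsParams | None = None,
):
    """Simulated-annealing optimization of the segment configuration.

    Runs ``n_iterations`` Metropolis steps with the temperature following
    an exponential schedule from ``t_start`` to ``t_end``; deterministic
    given ``rng_seed``. Returns ``(configuration, energy_trace)``.
    """
    params = params or GibbsParams()
    model = GibbsModel(dwi, mask, params)
    rng = np.random.default_rng(params.rng_seed)
    cfg = _init_configuration(model, params, rng)
    n1 = int(round(params.n_iterations * params.binding_delay_fraction))
    n2 = params.n_iterations - n1
    # geometric interpolation keeps one continuous exponential schedule
    t_mid = params.t_start * (params.t_end / params.t_start) ** (
        params.binding_delay_fraction
    )
    traces = []
    if n1 > 0:
        traces.append(run_chain(cfg, n1, (params.t_start, t_mid), rng))
    if n2 > 0:
        model.set_move_probabilities(params.assembly_move_probabilities)
        model.width_scale = params.assembly_width_scale
        t2 = run_chain(cfg, n2, (t_mid, params.t_end), rng)
        t2["iteration"] += n1
        traces.append(t2)
    trace = np.concatenate(traces) if traces else run_chain(cfg, 0, params.t_end, rng)
    return cfg, trace


# ---------------------------------------------------------------------------
# streamline extraction


def _chain_from(cfg: SegmentConfiguration, pid: int, e_in: int, visited: set):
    """Ordered particles and axis signs walking from a chain end."""
    chain = []
    while True:
        visited.add(pid)
        sign = 1.0 if e_in == 0 else -1.0  # traverse from e_in toward the other end
        chain.append((pid, sign))
        e_out = 1 - e_in
        q = int(cfg.link_p[pid, e_out])
        if q < 0 or q in visited:
            break
        e_in = int(cfg.link_e[pid, e_out])
        pid = q
    return chain


def _chain_points(cfg: SegmentConfiguration, chain) -> np.ndarray:
    half = cfg.model.params.half_length
    pts = []
    first_pid, first_sign = chain[0]
    pts.append(cfg.pos[first_pid] - first_sign * half * cfg.ori[first_pid])
    for i, (pid, sign) in enumerate(chain):
        tail = cfg.pos[pid] + sign * half * cfg.ori[pid]
        if i + 1 < len(chain):
            npid, nsign = chain[i + 1]
            head = cfg.pos[npid] - nsign * half * cfg.ori[npid]
            pts.append(0.5 * (tail + head))
        else:
            pts.append(tail)
    out = [pts[0]]
    for q in pts[1:]:
        if np.linalg.norm(q - out[-1]) > 1e-9:
            out.append(q)
    return np.asarray(out)


def extract_streamlines(
    cfg: SegmentConfiguration,
    min_chain: int = 2,
    stitch_radius: float | None = None,
    stitch_bend: float = 0.7,
) -> TractSet:
    """Read bound chains out as polylines through segment endpoints.

    Every particle lands in exactly one chain; chains shorter than
    ``min_chain`` particles are dropped. Cycles are broken at the link with
    the largest bend angle (deterministic tie-break on index).

    ``stitch_radius`` enables the deterministic fiber-building pass applied
    after optimization: chain ends closer than the radius whose
    continuation directions agree within ``stitch_bend`` radians (and with
    the partner lying ahead, not behind) are greedily merged, nearest gaps
    first. This bridges the sub-voxel strand holes the voxel-level data
    term cannot see; the bend gate keeps it from ever joining crossing
    bundles.
    """
    visited: set[int] = set()
    chains: list[list] = []

    def emit(chain):
        if len(chain) >= min_chain:
            chains.append(chain)

    # open chains: start from every free endpoint
    for pid, e in sorted(cfg.free_ends):
        if pid in visited:
            continue
        emit(_chain_from(cfg, pid, e, visited))
    # remaining bound structures are cycles
    for pid in sorted(cfg.alive_ids):
        if pid in visited:
            continue
        cycle = []
        p, e_in = pid, 0
        while True:
            cycle.append((p, e_in))
            e_out = 1 - e_in
            q = int(cfg.link_p[p, e_out])
            e_in = int(cfg.link_e[p, e_out])
            if q == pid:
                break
            p = q
        # break at the largest-bend link: bend between consecutive axes
        bends = []
        for i in range(len(cycle)):
            p0, _ = cycle[i]
            p1, _ = cycle[(i + 1) % len(cycle)]
            cosb = abs(float(cfg.ori[p0] @ cfg.ori[p1]))
            bends.append(math.acos(min(1.0, cosb)))
        cut = int(np.argmax(bends))
        start_p, start_e = cycle[(cut + 1) % len(cycle)]
        emit(_chain_from(cfg, start_p, start_e, visited))

    if stitch_radius is not None and len(chains) > 1:
        chains = _stitch_chains(cfg, chains, stitch_radius, stitch_bend)

    tracts: list[Tract] = []
    for chain in chains:
        pts = _chain_points(cfg, chain)
        if len(pts) >= 2:
            tracts.append(Tract(points=pts))
    return TractSet(tracts=tracts)


def _chain_end_state(cfg, chain, which: str):
    """Outward endpoint position and outgoing unit direction of a chain end."""
    half = cfg.model.params.half_length
    if which == "tail":
        pid, sign = chain[-1]
        pos = cfg.pos[pid] + sign * half * cfg.ori[pid]
        d = sign * cfg.ori[pid]
    else:
        pid, sign = chain[0]
        pos = cfg.pos[pid] - sign * half * cfg.ori[pid]
        d = -sign * cfg.ori[pid]
    return pos, d


def _stitch_chains(cfg, chains, radius: float, max_bend: float):
    """Greedily merge chain ends, nearest gaps first, gated on continuation
    bend and forward geometry. Deterministic."""
    ends = []  # (chain index, 'head'|'tail', position, outgoing direction)
    for ci, chain in enumerate(chains):
        for which in ("head", "tail"):
            pos, d = _chain_end_state(cfg, chain, which)
            ends.append((ci, which, pos, d))
    cand = []
    cos_gate = math.cos(max_bend)
    for i in range(len(ends)):
        ci, wi, pi, di = ends[i]
        for j in range(i + 1, len(ends)):
            cj, wj, pj, dj = ends[j]
            if ci == cj:
                continue
            gap = float(np.linalg.norm(pj - pi))
            if gap > radius:
                continue
            # continuation: outgoing directions must oppose, partner ahead
            if -float(di @ dj) < cos_gate:
                continue
            if gap > 1e-9:
                v = (pj - pi) / gap
                if float(v @ di) < 0.0 or float(v @ dj) > 0.0:
                    continue
            cand.append((gap, i, j))
    cand.sort()

    parent = list(range(len(chains)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    used_ends: set[int] = set()
    merged: dict[int, list] = {ci: list(chain) for ci, chain in enumerate(chains)}
    end_of: dict[tuple[int, str], int] = {}
    for idx, (ci, wi, _, _) in enumerate(ends):
        end_of[(ci, wi)] = idx
    # track, per live merged chain, which original ends are its current ends
    live_ends: dict[int, dict[str, int]] = {
        ci: {"head": end_of[(ci, "head")], "tail": end_of[(ci, "tail")]}
        for ci in range(len(chains))
    }

    def flip(chain):
        return [(pid, -sign) for pid, sign in reversed(chain)]

    for gap, i, j in cand:
        if i in used_ends or j in used_ends:
            continue
        ci, wi = ends[i][0], ends[i][1]
        cj, wj = ends[j][0], ends[j][1]
        ri, rj = find(ci), find(cj)
        if ri == rj:
            continue
        # the ends must still be exposed ends of their merged chains
        li, lj = live_ends[ri], live_ends[rj]
        side_i = "head" if li["head"] == i else "tail" if li["tail"] == i else None
        side_j = "head" if lj["head"] == j else "tail" if lj["tail"] == j else None
        if side_i is None or side_j is None:
            continue
        a, b = merged[ri], merged[rj]
        if side_i == "head":
            a = flip(a)
            li = {"head": li["tail"], "tail": li["head"]}
        if side_j == "tail":
            b = flip(b)
            lj = {"head": lj["tail"], "tail": lj["head"]}
        new_chain = a + b
        parent[rj] = ri
        merged[ri] = new_chain
        live_ends[ri] = {"head": li["head"], "tail": lj["tail"]}
        used_ends.add(i)
        used_ends.add(j)
    return [merged[ci] for ci in range(len(chains)) if find(ci) == ci]


# ---------------------------------------------------------------------------
# integrity


def check_integrity(cfg: SegmentConfiguration, rtol: float = 1e-6) -> None:
    """Verify link symmetry, index consistency and cached-vs-recomputed energy."""
    for pid in cfg.alive_ids:
        for e in (0, 1):
            q = int(cfg.link_p[pid, e])
            if q >= 0:
                f = int(cfg.link_e[pid, e])
                if q == pid:
                    raise AssertionError("self-link")
                if (int(cfg.link_p[q, f]), int(cfg.link_e[q, f])) != (pid, e):
                    raise AssertionError("asymmetric link")
            else:
                if (pid, e) not in cfg.fe_pos:
                    raise AssertionError("free endpoint missing from free list")
    hashed = set()
    for cell, members in cfg.hash.items():
        for pid, e in members:
            if cfg._cell(cfg.endpoint_position(pid, e)) != cell:
                raise AssertionError("endpoint hashed to wrong cell")
            hashed.add((pid, e))
    if hashed != set(cfg.free_ends):
        raise AssertionError("spatial index out of sync with free-endpoint list")

    e_ext = external_energy(cfg)
    e_int = internal_energy(cfg)
    scale_ext = max(abs(e_ext), 1.0)
    scale_int = max(abs(e_int), 1.0)
    if abs(e_ext - cfg.e_ext) > rtol * scale_ext:
        raise AssertionError(
            f"external energy drift: cached {cfg.e_ext}, recomputed {e_ext}"
        )
    if abs(e_int - cfg.e_int) > rtol * scale_int:
        raise AssertionError(
            f"internal energy drift: cached {cfg.e_int}, recomputed {e_int}"
        )
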