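"""Probabilistic streamline propagation on a fiber-ODF field.

The fODF is an antipodally symmetric spherical function per voxel,
stored as real even-order spherical-harmonic (SH) coefficients.  The
tracker grows each streamline unidirectionally from a random seed point
with a fixed step, sampling each step direction with probability
proportional to the fODF amplitude inside the curvature-limited cone
around the previous direction.  Directions whose amplitude falls below
a cutoff fraction of the field's global maximum amplitude are rejected;
streamlines are accepted when they enter a target region and discarded
on entering an exclusion region, on leaving the field domain, on
direction-sampling failure, or on exceeding the maximum length.

This is a first-order per-step sampler: it shares the contract surface
(step size, curvature radius, amplitude cutoff, seed cone) of
path-integral samplers such as iFOD2 but integrates one step at a time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
import nibabel as nib
import numpy as np
from scipy.special import sph_harm_y

from .io import FormatError, ScalarMap, StreamlineSet, _check_affine

REJECTION_REASONS = ("entered_exclusion", "missed_include", "no_direction",
                     "max_length", "left_domain", "no_target")


class ParameterError(ValueError):
    pass


class DomainError(ValueError):
    pass


class TrackingError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# real even-order spherical harmonics
# --------------------------------------------------------------------------

def n_coefficients(max_order: int) -> int:
    """Number of real even-order SH coefficients up to ``max_order``."""
    if max_order % 2 or max_order < 0:
        raise ParameterError("SH order must be a non-negative even integer")
    return (max_order + 1) * (max_order + 2) // 2


def sh_orders(max_order: int) -> tuple[np.ndarray, np.ndarray]:
    """(l, m) index pairs in MRtrix-style ordering: l ascending, m from -l to l."""
    ls, ms = [], []
    for l in range(0, max_order + 1, 2):
        for m in range(-l, l + 1):
            ls.append(l)
            ms.append(m)
    return np.asarray(ls), np.asarray(ms)


def sh_basis(max_order: int, directions: np.ndarray) -> np.ndarray:
    """Real SH basis matrix of shape (n_directions, n_coefficients).

    Real basis built from the complex harmonics: sqrt(2)*Im(Y_l^|m|) for
    m < 0, Y_l^0 for m = 0, sqrt(2)*Re(Y_l^m) for m > 0.
    """
    dirs = np.atleast_2d(np.asarray(directions, dtype=float))
    norms = np.linalg.norm(dirs, axis=1, keepdims=True)
    dirs = dirs / norms
    theta = np.arccos(np.clip(dirs[:, 2], -1.0, 1.0))   # polar
    phi = np.arctan2(dirs[:, 1], dirs[:, 0])            # azimuth
    ls, ms = sh_orders(max_order)
    ycplx = sph_harm_y(ls[None, :], np.abs(ms)[None, :],
                       theta[:, None], phi[:, None])
    out = np.empty(ycplx.shape, dtype=float)
    neg, zero, pos = ms < 0, ms == 0, ms > 0
    out[:, neg] = math.sqrt(2.0) * ycplx[:, neg].imag
    out[:, zero] = ycplx[:, zero].real
    out[:, pos] = math.sqrt(2.0) * ycplx[:, pos].real
    return out


def fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit directions (Fibonacci spiral), shape (n, 3)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    golden = math.pi * (3.0 - math.sqrt(5.0))
    phi = golden * i
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


# --------------------------------------------------------------------------
# fODF field
# --------------------------------------------------------------------------

@dataclass
class FodfField:
    """Grid of real even-order SH coefficient vectors with an affine."""

    coefficients: np.ndarray      # (X, Y, Z, n_coef)
    max_order: int
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
        if self.coefficients.ndim != 4:
            raise FormatError("fODF coefficient grid must be 4D (X, Y, Z, n_coef)")
        expected = n_coefficients(self.max_order)
        if self.coefficients.shape[3] != expected:
            raise FormatError(
                f"order {self.max_order} needs {expected} coefficients, "
                f"got {self.coefficients.shape[3]}")
        if not np.all(np.isfinite(self.coefficients)):
            raise FormatError("fODF coefficients must be finite")
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.coefficients.shape[:3]  # type: ignore[return-value]

    def _world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        inv = getattr(self, "_inv_cache", None)
        if inv is None:
            inv = np.linalg.inv(self.affine)
            object.__setattr__(self, "_inv_cache", inv)
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def contains(self, points: np.ndarray) -> np.ndarray:
        vox = self._world_to_voxel(points)
        shape = np.asarray(self.shape, dtype=float)
        return np.all((vox >= -0.5) & (vox < shape - 0.5), axis=1)

    def interpolate_coefficients(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of coefficient vectors at world points."""
        vox = self._world_to_voxel(points)
        shape = np.asarray(self.shape)
        if np.any(vox < -0.5) or np.any(vox >= shape - 0.5):
            raise DomainError("point outside fODF field domain")
        base = np.floor(vox).astype(np.intp)
        frac = vox - base
        coefs = np.zeros((len(vox), self.coefficients.shape[3]))
        for corner in range(8):
            off = np.array([(corner >> 2) & 1, (corner >> 1) & 1, corner & 1])
            idx = np.clip(base + off, 0, shape - 1)
            w = np.prod(np.where(off, frac, 1.0 - frac), axis=1)
            coefs += w[:, None] * self.coefficients[idx[:, 0], idx[:, 1], idx[:, 2]]
        return coefs

    def global_max_amplitude(self, n_directions: int = 724) -> float:
        """Maximum fODF amplitude over all voxels and a dense direction set.

        Cached on the field (the coefficient grid is treated as
        immutable after construction).
        """
        cached = getattr(self, "_gmax_cache", None)
        if cached is not None and cached[0] == n_directions:
            return cached[1]
        dirs = fibonacci_sphere(n_directions)
        basis = sh_basis(self.max_order, dirs)          # (D, C)
        flat = self.coefficients.reshape(-1, self.coefficients.shape[3])
        # chunk to bound memory on large fields
        best = 0.0
        for start in range(0, len(flat), 65536):
            amp = flat[start:start + 65536] @ basis.T
            best = max(best, float(amp.max(initial=0.0)))
        object.__setattr__(self, "_gmax_cache", (n_directions, best))
        return best


def fodf_amplitude(field: FodfField, point: np.ndarray,
                   direction: np.ndarray) -> float:
    """fODF amplitude at one world point along one direction, clamped at 0."""
    coefs = field.interpolate_coefficients(np.atleast_2d(point))
    basis = sh_basis(field.max_order, np.atleast_2d(direction))
    return float(max(0.0, coefs[0] @ basis[0]))


def read_fodf(path, max_order: int | None = None) -> FodfField:
    """Read a 4D NIfTI of real SH coefficients (MRtrix coefficient layout)."""
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise FormatError(f"fODF file must be 4D, got shape {data.shape}")
    if max_order is None:
        # invert n = (L+1)(L+2)/2 for even L
        n = data.shape[3]
        max_order = int(round((math.sqrt(8 * n + 1) - 3) / 2))
        if n_coefficients(max_order) != n:
            raise FormatError(f"{n} volumes is not a valid even-order SH count")
    return FodfField(coefficients=data, max_order=max_order, affine=img.affine)


def write_fodf(field: FodfField, path) -> None:
    nib.save(nib.Nifti1Image(field.coefficients.astype(np.float32), field.affine),
             str(path))


# --------------------------------------------------------------------------
# geometry of the step constraint
# --------------------------------------------------------------------------

def max_step_angle(step_mm: float, curvature_radius_mm: float) -> float:
    """Largest angle (degrees) between consecutive fixed-length steps on a
    circle of the given radius: 2*arcsin(step / (2*radius))."""
    if step_mm <= 0 or curvature_radius_mm <= 0:
        raise ParameterError("step and curvature radius must be positive")
    if step_mm > 2.0 * curvature_radius_mm:
        raise ParameterError("step size exceeds the curvature diameter")
    return math.degrees(2.0 * math.asin(step_mm / (2.0 * curvature_radius_mm)))


# --------------------------------------------------------------------------
# direction sampling
# --------------------------------------------------------------------------

class _DirectionTable:
    """Fixed quasi-uniform direction set with a precomputed SH basis.

    Sampling a direction with probability proportional to the fODF
    amplitude over this table is the discrete analogue of rejection
    sampling from the continuous amplitude density; the table is shared
    so the (expensive) SH basis is evaluated once per order, and the
    per-direction neighbour lists inside a given cone angle once per
    angle.
    """

    _cache: dict[tuple[int, int], "_DirectionTable"] = {}

    def __init__(self, max_order: int, n: int = 4096):
        self.directions = fibonacci_sphere(n)
        self.basis = sh_basis(max_order, self.directions)
        self._nbrs: dict[float, list[np.ndarray]] = {}

    def cone_neighbors(self, angle_deg: float) -> list[np.ndarray]:
        """Indices of table directions within angle_deg of each direction."""
        key = round(angle_deg, 6)
        if key not in self._nbrs:
            cos_t = math.cos(math.radians(angle_deg)) - 1e-12
            dirs = self.directions
            out = []
            for start in range(0, len(dirs), 512):
                dots = dirs[start:start + 512] @ dirs.T
                for row in dots:
                    out.append(np.flatnonzero(row >= cos_t))
            self._nbrs[key] = out
        return self._nbrs[key]

    @classmethod
    def get(cls, max_order: int, n: int = 4096) -> "_DirectionTable":
        key = (max_order, n)
        if key not in cls._cache:
            cls._cache[key] = cls(max_order, n)
        return cls._cache[key]


def sample_direction(field: FodfField, point: np.ndarray,
                     prev_dir: np.ndarray | None,
                     cutoff: float, rng: np.random.Generator,
                     cone_axis: np.ndarray | None = None,
                     cone_half_angle_deg: float | None = None,
                     max_angle_deg: float | None = None,
                     table: "_DirectionTable | None" = None) -> np.ndarray | None:
    """Draw a propagation direction, or return None on failure.

    The candidate set is the fixed direction table restricted to the
    curvature cone around ``prev_dir`` (or, at the first step, to the
    seed cone around ``cone_axis`` when one is given; otherwise the full
    sphere).  Candidates with amplitude below ``cutoff`` (an absolute
    amplitude, normally cutoff_fraction x global max) carry zero
    probability; the draw is proportional to amplitude.  Failure (all
    candidates below cutoff) is a value, not an error.
    """
    if table is None:
        table = _DirectionTable.get(field.max_order)
    dirs, basis = table.directions, table.basis
    if prev_dir is not None:
        if max_angle_deg is None:
            raise ParameterError("max_angle_deg required with prev_dir")
        keep = dirs @ np.asarray(prev_dir) >= math.cos(math.radians(max_angle_deg)) - 1e-12
    elif cone_axis is not None:
        half = 45.0 if cone_half_angle_deg is None else cone_half_angle_deg
        keep = dirs @ np.asarray(cone_axis) >= math.cos(math.radians(half)) - 1e-12
    else:
        keep = np.ones(len(dirs), dtype=bool)
    cand = np.flatnonzero(keep)
    if cand.size == 0:
        return None
    coefs = field.interpolate_coefficients(np.atleast_2d(point))[0]
    amp = basis[cand] @ coefs
    np.maximum(amp, 0.0, out=amp)
    amp[amp < cutoff] = 0.0
    total = amp.sum()
    if total <= 0.0:
        return None
    pick = cand[rng.choice(amp.size, p=amp / total)]
    return dirs[pick].copy()


# --------------------------------------------------------------------------
# propagation
# --------------------------------------------------------------------------

@dataclass
class TrackingOutcome:
    """Either an accepted streamline or a rejection reason."""

    streamline: np.ndarray | None = None
    reason: str | None = None

    @property
    def accepted(self) -> bool:
        return self.streamline is not None

    @classmethod
    def reject(cls, reason: str) -> "TrackingOutcome":
        if reason not in REJECTION_REASONS:
            raise ValueError(f"unknown rejection reason {reason!r}")
        return cls(streamline=None, reason=reason)


@dataclass
class TrackingParams:
    """Propagation parameters (defaults follow the published protocol)."""

    step_mm: float = 0.2
    curvature_radius_mm: float = 1.0
    cutoff_fraction: float = 0.1
    max_length_mm: float = 250.0
    max_attempts_per_seed: int = 10_000
    seed_cone_axis: np.ndarray | None = None     # unit vector; 45 deg half-angle
    seed_cone_half_angle_deg: float = 45.0

    def __post_init__(self) -> None:
        if not 0.0 < self.cutoff_fraction < 1.0:
            raise ParameterError("cutoff fraction must be in (0, 1)")
        if self.step_mm > 2.0 * self.curvature_radius_mm:
            raise ParameterError("step size exceeds the curvature diameter")

    @property
    def max_angle_deg(self) -> float:
        return max_step_angle(self.step_mm, self.curvature_radius_mm)

    @property
    def max_steps(self) -> int:
        return int(math.ceil(self.max_length_mm / self.step_mm))


try:
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:          # pragma: no cover - numba is an optional speedup
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f
        return deco


@_njit(cache=False)
def _walk_kernel(p0, invA, invb, C, shape, basis, dirs,
                 nbr_idx, nbr_ptr, first_cand,
                 exclude_any, target_any,
                 cutoff, step, max_steps, randoms, out_pts):
    """Inner propagation loop over flat arrays (JIT-compiled when available).

    Returns (status, n_points) with status codes: 0 accepted,
    1 no_direction (dead first step), 2 no_target (died later),
    3 left_domain, 4 entered_exclusion, 5 max_length.
    """
    ncoef = C.shape[3]
    coefs = np.empty(ncoef)
    x, y, z = p0[0], p0[1], p0[2]
    out_pts[0, 0], out_pts[0, 1], out_pts[0, 2] = x, y, z
    n = 1
    prev = -1
    for s in range(max_steps):
        vx = invA[0, 0] * x + invA[0, 1] * y + invA[0, 2] * z + invb[0]
        vy = invA[1, 0] * x + invA[1, 1] * y + invA[1, 2] * z + invb[1]
        vz = invA[2, 0] * x + invA[2, 1] * y + invA[2, 2] * z + invb[2]
        if (vx < -0.5 or vx >= shape[0] - 0.5 or vy < -0.5
                or vy >= shape[1] - 0.5 or vz < -0.5 or vz >= shape[2] - 0.5):
            return (1 if prev < 0 else 2), n
        bx, by, bz = int(math.floor(vx)), int(math.floor(vy)), int(math.floor(vz))
        fx, fy, fz = vx - bx, vy - by, vz - bz
        i0 = min(max(bx, 0), shape[0] - 1)
        j0 = min(max(by, 0), shape[1] - 1)
        k0 = min(max(bz, 0), shape[2] - 1)
        i1 = min(max(bx + 1, 0), shape[0] - 1)
        j1 = min(max(by + 1, 0), shape[1] - 1)
        k1 = min(max(bz + 1, 0), shape[2] - 1)
        for c in range(ncoef):
            c00 = C[i0, j0, k0, c] * (1 - fz) + C[i0, j0, k1, c] * fz
            c01 = C[i0, j1, k0, c] * (1 - fz) + C[i0, j1, k1, c] * fz
            c10 = C[i1, j0, k0, c] * (1 - fz) + C[i1, j0, k1, c] * fz
            c11 = C[i1, j1, k0, c] * (1 - fz) + C[i1, j1, k1, c] * fz
            coefs[c] = (c00 * (1 - fy) + c01 * fy) * (1 - fx) \
                + (c10 * (1 - fy) + c11 * fy) * fx
        if prev >= 0:
            cand = nbr_idx[nbr_ptr[prev]:nbr_ptr[prev + 1]]
        else:
            cand = first_cand
        ncand = cand.shape[0]
        amps = np.empty(ncand)
        total = 0.0
        for ci in range(ncand):
            a = 0.0
            row = cand[ci]
            for c in range(ncoef):
                a += basis[row, c] * coefs[c]
            if a < cutoff:
                a = 0.0
            amps[ci] = a
            total += a
        if total <= 0.0:
            return (1 if prev < 0 else 2), n
        r = randoms[s] * total
        acc = 0.0
        pick = ncand - 1
        for ci in range(ncand):
            acc += amps[ci]
            if r < acc:
                pick = ci
                break
        d = cand[pick]
        nx = x + step * dirs[d, 0]
        ny = y + step * dirs[d, 1]
        nz = z + step * dirs[d, 2]
        gx = invA[0, 0] * nx + invA[0, 1] * ny + invA[0, 2] * nz + invb[0]
        gy = invA[1, 0] * nx + invA[1, 1] * ny + invA[1, 2] * nz + invb[1]
        gz = invA[2, 0] * nx + invA[2, 1] * ny + invA[2, 2] * nz + invb[2]
        ix = int(math.floor(gx + 0.5))
        iy = int(math.floor(gy + 0.5))
        iz = int(math.floor(gz + 0.5))
        if (ix < 0 or ix >= shape[0] or iy < 0 or iy >= shape[1]
                or iz < 0 or iz >= shape[2]):
            return 3, n
        if exclude_any[ix, iy, iz]:
            return 4, n
        out_pts[n, 0], out_pts[n, 1], out_pts[n, 2] = nx, ny, nz
        n += 1
        prev = d
        x, y, z = nx, ny, nz
        if target_any[ix, iy, iz]:
            return 0, n
    return 5, n


_STATUS_REASONS = {1: "no_direction", 2: "no_target", 3: "left_domain",
                   4: "entered_exclusion", 5: "max_length"}


class _TrackContext:
    """Precomputed state for fast repeated propagation on one ROI set.

    When every target/exclude mask shares the field's grid geometry the
    per-step membership tests collapse to lookups in two combined
    boolean grids and the walk runs in the flat-array kernel; otherwise
    the per-mask path is used.
    """

    def __init__(self, field: FodfField, rois: dict, params: TrackingParams,
                 cutoff_abs: float, table: _DirectionTable):
        self.field = field
        self.params = params
        self.cutoff = cutoff_abs
        self.table = table
        self.nbrs = table.cone_neighbors(params.max_angle_deg)
        inv = np.linalg.inv(field.affine)
        self.invA, self.invb = inv[:3, :3], inv[:3, 3]
        self.C = field.coefficients
        self.shape = np.asarray(field.shape)
        self.maxidx = self.shape - 1
        self.targets = rois.get("targets", [])
        self.excludes = rois.get("excludes", [])
        self.includes = rois.get("includes", [])

        def shared(masks):
            return all(m.shape == tuple(field.shape)
                       and np.allclose(m.affine, field.affine) for m in masks)

        self.shared_grids = shared(self.targets) and shared(self.excludes)
        if self.shared_grids:
            self.target_any = np.zeros(field.shape, dtype=bool)
            for m in self.targets:
                self.target_any |= m.grid != 0
            self.exclude_any = np.zeros(field.shape, dtype=bool)
            for m in self.excludes:
                self.exclude_any |= m.grid != 0

        # seed-cone candidate set (first step only); without a cone the
        # first step samples the full table
        if params.seed_cone_axis is not None:
            cos_t = math.cos(math.radians(params.seed_cone_half_angle_deg)) - 1e-12
            self.seed_cand = np.flatnonzero(
                table.directions @ np.asarray(params.seed_cone_axis) >= cos_t)
        else:
            self.seed_cand = None
        self.first_cand = (self.seed_cand if self.seed_cand is not None
                           else np.arange(len(table.directions))).astype(np.int64)

        # CSR layout of the cone-neighbour lists for the flat kernel
        nbrs = self.nbrs
        self.nbr_ptr = np.zeros(len(nbrs) + 1, dtype=np.int64)
        np.cumsum([len(v) for v in nbrs], out=self.nbr_ptr[1:])
        self.nbr_idx = np.concatenate(nbrs).astype(np.int64)
        self.shape_arr = self.shape.astype(np.int64)
        if self.shared_grids:
            self.exclude_u8 = self.exclude_any.astype(np.uint8)
            self.target_u8 = self.target_any.astype(np.uint8)

    def interp(self, p: np.ndarray) -> np.ndarray | None:
        """Trilinear coefficient interpolation; None when p leaves the field."""
        v = self.invA @ p + self.invb
        if np.any(v < -0.5) or np.any(v >= self.shape - 0.5):
            return None
        base = np.floor(v).astype(np.intp)
        f = v - base
        lo = np.clip(base, 0, self.maxidx)
        hi = np.clip(base + 1, 0, self.maxidx)
        C = self.C
        fx, fy, fz = f
        i0, j0, k0 = lo
        i1, j1, k1 = hi
        c00 = C[i0, j0, k0] * (1 - fz) + C[i0, j0, k1] * fz
        c01 = C[i0, j1, k0] * (1 - fz) + C[i0, j1, k1] * fz
        c10 = C[i1, j0, k0] * (1 - fz) + C[i1, j0, k1] * fz
        c11 = C[i1, j1, k0] * (1 - fz) + C[i1, j1, k1] * fz
        return ((c00 * (1 - fy) + c01 * fy) * (1 - fx)
                + (c10 * (1 - fy) + c11 * fy) * fx)

    def grid_index(self, p: np.ndarray) -> tuple | None:
        v = self.invA @ p + self.invb
        idx = np.floor(v + 0.5).astype(np.intp)
        if np.any(idx < 0) or np.any(idx > self.maxidx):
            return None
        return tuple(idx)

    def step_direction(self, p: np.ndarray, prev_idx: int | None,
                       u: float) -> int | None:
        """Table index of the next direction, or None on sampling failure.

        ``u`` is the uniform variate driving the proportional draw.
        """
        coefs = self.interp(p)
        if coefs is None:
            return None
        cand = self.nbrs[prev_idx] if prev_idx is not None else self.first_cand
        amp = self.table.basis[cand] @ coefs
        amp[amp < self.cutoff] = 0.0
        total = amp.sum()
        if total <= 0.0:
            return None
        pick = int(np.searchsorted(np.cumsum(amp), u * total, side="right"))
        pick = min(pick, amp.size - 1)
        return int(cand[pick])


def _propagate_ctx(seed_point: np.ndarray, ctx: _TrackContext,
                   rng: np.random.Generator) -> TrackingOutcome:
    """One walk; each attempt consumes exactly max_steps uniforms."""
    params = ctx.params
    p0 = np.asarray(seed_point, dtype=float)
    randoms = rng.random(params.max_steps)

    if ctx.shared_grids:
        out_pts = np.empty((params.max_steps + 1, 3))
        status, n = _walk_kernel(
            p0, ctx.invA, ctx.invb, ctx.C, ctx.shape_arr,
            ctx.table.basis, ctx.table.directions,
            ctx.nbr_idx, ctx.nbr_ptr, ctx.first_cand,
            ctx.exclude_u8, ctx.target_u8,
            ctx.cutoff, params.step_mm, params.max_steps, randoms, out_pts)
        if status != 0:
            return TrackingOutcome.reject(_STATUS_REASONS[status])
        sl = out_pts[:n].copy()
        if ctx.includes and not all(m.contains(sl).any() for m in ctx.includes):
            return TrackingOutcome.reject("missed_include")
        return TrackingOutcome(streamline=sl)

    # generic path: masks on arbitrary grids
    dirs = ctx.table.directions
    points = [p0]
    prev_idx: int | None = None
    for s in range(params.max_steps):
        di = ctx.step_direction(points[-1], prev_idx, randoms[s])
        if di is None:
            # a dead first step means the seed voxel itself is untrackable;
            # later failures mean the walk petered out before any target
            return TrackingOutcome.reject(
                "no_direction" if prev_idx is None else "no_target")
        nxt = points[-1] + params.step_mm * dirs[di]
        if not ctx.field.contains(nxt[None])[0]:
            return TrackingOutcome.reject("left_domain")
        if any(m.contains(nxt[None])[0] for m in ctx.excludes):
            return TrackingOutcome.reject("entered_exclusion")
        hit_target = any(m.contains(nxt[None])[0] for m in ctx.targets)
        points.append(nxt)
        prev_idx = di
        if hit_target:
            sl = np.asarray(points)
            if ctx.includes and not all(m.contains(sl).any()
                                        for m in ctx.includes):
                return TrackingOutcome.reject("missed_include")
            return TrackingOutcome(streamline=sl)
    return TrackingOutcome.reject("max_length")


def propagate(seed_point: np.ndarray, field: FodfField, rois: dict,
              params: TrackingParams, rng: np.random.Generator,
              cutoff_abs: float | None = None,
              table: "_DirectionTable | None" = None) -> TrackingOutcome:
    """Grow one streamline unidirectionally from a seed point.

    ``rois`` maps 'seed' to a binary ScalarMap and 'targets', 'excludes',
    'includes' to lists of binary ScalarMaps.  Acceptance requires the
    final point inside a target; include regions (if any) must all be
    intersected, checked post hoc.
    """
    seed_point = np.asarray(seed_point, dtype=float)
    seed_mask: ScalarMap = rois["seed"]
    if not seed_mask.contains(seed_point[None])[0]:
        raise ValueError("seed point lies outside the seed mask")
    if cutoff_abs is None:
        cutoff_abs = params.cutoff_fraction * field.global_max_amplitude()
    if table is None:
        table = _DirectionTable.get(field.max_order)
    ctx = _TrackContext(field, rois, params, cutoff_abs, table)
    return _propagate_ctx(seed_point, ctx, rng)


def _seed_voxels(seed: ScalarMap) -> np.ndarray:
    return np.argwhere(seed.grid != 0)


def track(protocol, field: FodfField, rois: dict,
          rng: np.random.Generator,
          n_streamlines: int | None = None) -> StreamlineSet:
    """Accumulate accepted streamlines for one tract protocol.

    Seed voxels are drawn uniformly from the seed mask and the seed
    position uniformly within the chosen voxel cell.  Propagation
    repeats until ``n_streamlines`` are accepted or the pooled attempt
    budget (max_attempts_per_seed x number of seed voxels) is spent.
    """
    params: TrackingParams = protocol.tracking_params()
    n_wanted = protocol.n_streamlines if n_streamlines is None else n_streamlines
    if n_wanted <= 0:
        raise ParameterError("n_streamlines must be positive")
    seed: ScalarMap = rois["seed"]
    voxels = _seed_voxels(seed)
    if len(voxels) == 0:
        raise TrackingError(f"{protocol.name}: empty seed region")
    if not rois.get("targets"):
        raise TrackingError(f"{protocol.name}: no target region")
    budget = params.max_attempts_per_seed * len(voxels)
    cutoff_abs = params.cutoff_fraction * field.global_max_amplitude()
    table = _DirectionTable.get(field.max_order)
    ctx = _TrackContext(field, rois, params, cutoff_abs, table)
    aff = seed.affine

    accepted: list[np.ndarray] = []
    counts = {r: 0 for r in REJECTION_REASONS}
    attempts = 0
    while len(accepted) < n_wanted and attempts < budget:
        attempts += 1
        vox = voxels[rng.integers(len(voxels))]
        offset = rng.uniform(-0.5, 0.5, size=3)
        pt = (vox + offset) @ aff[:3, :3].T + aff[:3, 3]
        outcome = _propagate_ctx(pt, ctx, rng)
        if outcome.accepted:
            accepted.append(outcome.streamline)
        else:
            counts[outcome.reason] += 1
    if not accepted:
        dominant = max(counts, key=counts.get)
        raise TrackingError(
            f"{protocol.name}: no streamline accepted in {attempts} attempts "
            f"(dominant rejection: {dominant}, counts={counts})")
    meta = {
        "tract": protocol.name,
        "n_accepted": len(accepted),
        "attempts": attempts,
        "acceptance_rate": len(accepted) / attempts,
        "rejections": counts,
        "step_mm": params.step_mm,
        "curvature_radius_mm": params.curvature_radius_mm,
        "cutoff_fraction": params.cutoff_fraction,
        "cutoff_abs": cutoff_abs,
    }
    return StreamlineSet(streamlines=accepted, meta=meta)
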