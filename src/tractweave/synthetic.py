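"""Synthetic phantoms: parcellations, fODF fields, bundles, cohorts.

The default phantom is a schematic two-hemisphere "brain" built from
axis-aligned boxes on a 2 mm RAS+ grid, containing every structure the
six shipped tract protocols reference, plus one analytic bundle
centerline per tract and hemisphere connecting seed to target.  The
anatomy is deliberately schematic (boxes and tubes, not realistic
cortical geometry): it exercises the computation, not the anatomy.

The grid is chosen so voxel centres are mirror-symmetric about the
midsagittal plane x = 0, making left/right structures exact voxel-wise
reflections of each other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.spatial import cKDTree

from .io import LabelVolume, ScalarMap, SpatialTransform, StreamlineSet
from .tracking import FodfField, fibonacci_sphere, n_coefficients, sh_basis


class SpecError(ValueError):
    pass


Box = tuple[tuple[float, float], tuple[float, float], tuple[float, float]]

# Left-hemisphere structures, world-mm half-open boxes [lo, hi).
# x: right+, y: anterior+, z: superior+.  Mirrored to the right hemisphere
# by negating x.  All bounds are even integers so no voxel centre (odd
# integers on the 2 mm default grid) sits on a box face.
_LEFT_BOXES: dict[str, Box] = {
    "brainstem":          ((-8, 0),    (-14, 2),  (-50, -22)),
    "precentral":         ((-44, -16), (6, 14),   (24, 44)),
    "thalamus":           ((-20, -8),  (-16, -6), (-10, 2)),
    "lgn":                ((-26, -20), (-20, -14), (-6, 0)),
    "posterior_insula":   ((-38, -30), (-12, -2), (-4, 8)),
    "anterior_insula":    ((-38, -30), (-2, 10),  (-4, 8)),
    "putamen":            ((-28, -20), (-6, 8),   (-6, 6)),
    "pars_opercularis":   ((-48, -36), (14, 22),  (4, 16)),
    "pars_triangularis":  ((-48, -36), (22, 30),  (4, 16)),
    "pars_orbitalis":     ((-46, -34), (30, 38),  (-4, 6)),
    "anterior_orbital":   ((-36, -24), (38, 48),  (-14, -4)),
    "posterior_orbital":  ((-36, -24), (28, 38),  (-14, -4)),
    "frontal_pole":       ((-24, -6),  (52, 64),  (-6, 10)),
    "occipital_superior": ((-20, -8),  (-72, -60), (10, 20)),
    "occipital_middle":   ((-28, -16), (-72, -60), (-2, 10)),
    "occipital_inferior": ((-28, -16), (-72, -60), (-14, -2)),
    "calcarine":          ((-12, -2),  (-70, -58), (-4, 6)),
    "lingual":            ((-16, -4),  (-70, -58), (-16, -8)),
    "precuneus":          ((-14, -2),  (-52, -40), (20, 32)),
    "basal_forebrain":    ((-12, -2),  (0, 10),   (-14, -6)),
    "superior_temporal":  ((-48, -38), (-38, -2), (-10, 0)),
    "middle_temporal":    ((-48, -38), (-38, -2), (-20, -10)),
    "supramarginal":      ((-48, -36), (-44, -30), (8, 20)),
    "angular":            ((-48, -36), (-58, -46), (8, 20)),
    "smc":                ((-14, -4),  (2, 30),   (30, 44)),
}

# Midline structures spanning both hemispheres (single label).
_MIDLINE_BOXES: dict[str, Box] = {
    "fourth_ventricle": ((-4, 4), (-20, -14), (-44, -28)),
    "corpus_callosum":  ((-6, 6), (14, 26),  (0, 10)),
}

# White matter fills the remaining interior of this box, per hemisphere.
_WM_BOX_LEFT: Box = ((-52, 0), (-70, 58), (-44, 44))

# Bundle centerlines, left hemisphere, world mm.  Each connects the
# protocol's seed region to its target region along a smooth low-curvature
# path avoiding that protocol's exclusion regions.
_LEFT_CENTERLINES: dict[str, np.ndarray] = {
    "CST": np.array([(-4, -2, -46), (-4, -2, -26), (-10, 2, -6),
                     (-20, 8, 16), (-28, 10, 30), (-30, 10, 40)], float),
    "IFOF": np.array([(-42, 26, 10), (-38, 14, 6), (-32, 2, 2), (-29, -3, 1),
                      (-28, -12, 1), (-26, -30, 2), (-24, -48, 3),
                      (-22, -62, 4)], float),
    "OR": np.array([(-23, -17, -3), (-34, -19, -3), (-40, -26, -2),
                    (-40, -40, 0), (-30, -54, 1), (-16, -62, 1),
                    (-7, -64, 1)], float),
    "AF": np.array([(-42, 18, 10), (-41, 10, 22), (-40, 0, 28),
                    (-40, -12, 26), (-41, -22, 14), (-42, -28, 2),
                    (-43, -30, -4)], float),
    "FAT": np.array([(-9, 12, 36), (-16, 16, 30), (-26, 18, 22),
                     (-36, 18, 14), (-42, 18, 10)], float),
    "SLF3": np.array([(-43, 16, 11), (-44, 4, 13), (-44, -12, 14),
                      (-43, -26, 14), (-42, -34, 14)], float),
}


def _mirror_box(box: Box) -> Box:
    (x0, x1), yy, zz = box
    return ((-x1, -x0), yy, zz)


def _mirror_polyline(line: np.ndarray) -> np.ndarray:
    out = np.asarray(line, float).copy()
    out[:, 0] *= -1.0
    return out


@dataclass
class PhantomSpec:
    """Geometry of the synthetic parcellation phantom."""

    grid_shape: tuple[int, int, int] = (60, 72, 54)
    voxel_mm: float = 2.0
    left_boxes: dict = dc_field(default_factory=lambda: dict(_LEFT_BOXES))
    midline_boxes: dict = dc_field(default_factory=lambda: dict(_MIDLINE_BOXES))
    wm_box_left: Box = _WM_BOX_LEFT
    centerlines_left: dict = dc_field(
        default_factory=lambda: {k: v.copy() for k, v in _LEFT_CENTERLINES.items()})
    seed: int = 0

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[0, 0] = a[1, 1] = a[2, 2] = self.voxel_mm
        a[:3, 3] = [-(n - 1) * self.voxel_mm / 2.0 for n in self.grid_shape]
        return a

    def centerlines(self) -> dict[str, np.ndarray]:
        """All bundle centerlines, both hemispheres (keys like 'CST_L')."""
        out = {}
        for tract, line in self.centerlines_left.items():
            out[f"{tract}_L"] = np.asarray(line, float)
            out[f"{tract}_R"] = _mirror_polyline(line)
        return out


def default_phantom_spec() -> PhantomSpec:
    return PhantomSpec()


def make_phantom(spec: PhantomSpec | None = None) -> LabelVolume:
    """Deterministic labeled phantom with mirrored hemispheres.

    Raises SpecError if any two structures overlap.  White matter fills
    the remaining interior of its hemisphere box after all structures
    are painted, so it is disjoint from them by construction.
    """
    spec = spec or default_phantom_spec()
    shape = spec.grid_shape
    aff = spec.affine
    cx = aff[0, 3] + spec.voxel_mm * np.arange(shape[0])
    cy = aff[1, 3] + spec.voxel_mm * np.arange(shape[1])
    cz = aff[2, 3] + spec.voxel_mm * np.arange(shape[2])

    def box_mask(box: Box) -> np.ndarray:
        (x0, x1), (y0, y1), (z0, z1) = box
        return ((cx >= x0) & (cx < x1))[:, None, None] \
            & ((cy >= y0) & (cy < y1))[None, :, None] \
            & ((cz >= z0) & (cz < z1))[None, None, :]

    structures: list[tuple[str, Box]] = []
    for name, box in spec.left_boxes.items():
        structures.append((f"{name}_L", box))
        structures.append((f"{name}_R", _mirror_box(box)))
    for name, box in spec.midline_boxes.items():
        structures.append((name, box))

    names = [n for n, _ in structures] + ["white_matter_L", "white_matter_R"]
    labels = {n: i + 1 for i, n in enumerate(sorted(names))}

    grid = np.zeros(shape, dtype=np.int32)
    for name, box in structures:
        m = box_mask(box)
        clash = m & (grid != 0)
        if clash.any():
            other = int(grid[clash][0])
            hit = next(n for n, v in labels.items() if v == other)
            raise SpecError(f"structure {name} overlaps {hit}")
        grid[m] = labels[name]
    for name, box in (("white_matter_L", spec.wm_box_left),
                      ("white_matter_R", _mirror_box(spec.wm_box_left))):
        grid[box_mask(box) & (grid == 0)] = labels[name]
    return LabelVolume(grid=grid, affine=aff, labels=labels)


# --------------------------------------------------------------------------
# fODF synthesis
# --------------------------------------------------------------------------

def _resample_polyline(line: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a polyline at (approximately) uniform arc-length spacing."""
    line = np.asarray(line, float)
    seg = np.linalg.norm(np.diff(line, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(2, int(round(total / spacing)) + 1)
    si = np.linspace(0.0, total, n)
    return np.stack([np.interp(si, s, line[:, c]) for c in range(3)], axis=1)


def _polyline_tangents(line: np.ndarray) -> np.ndarray:
    d = np.gradient(line, axis=0)
    return d / np.linalg.norm(d, axis=1, keepdims=True)


def make_fodf(centerlines: list[np.ndarray] | dict[str, np.ndarray],
              grid_shape: tuple[int, int, int],
              affine: np.ndarray,
              max_order: int = 8,
              tube_radius_mm: float = 3.0,
              lobe_sharpness: float = 12.0,
              background: float = 0.03) -> FodfField:
    """Analytic fODF field: antipodal lobes along nearby bundle tangents.

    Per voxel the spherical function is
    ``background + sum_j exp(kappa * ((d . t_j)^2 - 1))`` over the
    tangents t_j of centerlines passing within ``tube_radius_mm``, then
    projected onto the real even-order SH basis by least squares on a
    quasi-uniform direction set.  Voxels near two crossing centerlines
    therefore carry a two-lobed fODF.
    """
    if isinstance(centerlines, dict):
        centerlines = list(centerlines.values())
    if not centerlines:
        raise SpecError("at least one centerline is required")
    affine = np.asarray(affine, float)
    ncoef = n_coefficients(max_order)
    quad = fibonacci_sphere(400)
    basis = sh_basis(max_order, quad)                     # (Q, C)
    proj = np.linalg.pinv(basis)                          # (C, Q)

    coeffs = np.zeros(tuple(grid_shape) + (ncoef,))
    # isotropic background: amplitude `background` in every direction
    coeffs[..., 0] = background * math.sqrt(4.0 * math.pi)

    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in grid_shape], indexing="ij")
    centers = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1) \
        @ affine[:3, :3].T + affine[:3, 3]

    # accumulate lobe tangents per voxel
    lobe_vox: dict[int, list[np.ndarray]] = {}
    for line in centerlines:
        pts = _resample_polyline(np.asarray(line, float), 1.0)
        tans = _polyline_tangents(pts)
        tree = cKDTree(pts)
        near = tree.query_ball_point(centers, tube_radius_mm)
        for vi, hits in enumerate(near):
            if hits:
                d = np.linalg.norm(pts[hits] - centers[vi], axis=1)
                lobe_vox.setdefault(vi, []).append(tans[hits[int(np.argmin(d))]])

    if lobe_vox:
        vids = np.fromiter(lobe_vox.keys(), dtype=np.intp)
        # evaluate per-voxel spherical function on the quadrature and project
        for start in range(0, len(vids), 4096):
            chunk = vids[start:start + 4096]
            f = np.zeros((len(chunk), len(quad)))
            for row, vi in enumerate(chunk):
                for t in lobe_vox[vi]:
                    ca = quad @ t
                    f[row] += np.exp(lobe_sharpness * (ca * ca - 1.0))
            add = f @ proj.T                              # (n, C)
            flat = coeffs.reshape(-1, ncoef)
            flat[chunk] += add
    return FodfField(coefficients=coeffs, max_order=max_order, affine=affine)


def make_default_fodf(spec: PhantomSpec | None = None,
                      max_order: int = 8, **kwargs) -> FodfField:
    """fODF field for the default phantom: all twelve bundle centerlines."""
    spec = spec or default_phantom_spec()
    return make_fodf(spec.centerlines(), spec.grid_shape, spec.affine,
                     max_order=max_order, **kwargs)


def make_bundle_phantom(n_streamlines: int = 50,
                        with_exclusion_wall: bool = False,
                        tube_radius_mm: float = 3.0,
                        max_order: int = 8,
                        cutoff_fraction: float = 0.1,
                        **fodf_kwargs) -> dict:
    """Small straight-bundle phantom for tracker and reliability tests.

    One straight centerline along +y on a 2 mm grid, a seed box at the
    posterior end and a full-cross-section target wall at the anterior
    end; optionally an exclusion wall fully crossing the bundle halfway.
    Returns {'field', 'rois', 'centerline', 'protocol', 'template'}.
    """
    from .roi import RoiRecipe, TractProtocol

    shape = (15, 30, 15)
    vox = 2.0
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = vox
    aff[:3, 3] = [-(n - 1) * vox / 2.0 for n in shape]
    centerline = np.array([(0.0, -23.0, 0.0), (0.0, 23.0, 0.0)])
    field = make_fodf([centerline], shape, aff, max_order=max_order,
                      tube_radius_mm=tube_radius_mm, **fodf_kwargs)

    cx = aff[0, 3] + vox * np.arange(shape[0])
    cy = aff[1, 3] + vox * np.arange(shape[1])
    cz = aff[2, 3] + vox * np.arange(shape[2])

    def box(x0, x1, y0, y1, z0, z1):
        m = ((cx >= x0) & (cx < x1))[:, None, None] \
            & ((cy >= y0) & (cy < y1))[None, :, None] \
            & ((cz >= z0) & (cz < z1))[None, None, :]
        return ScalarMap(m.astype(np.uint8), aff, role="binary")

    seed = box(-4, 4, -26, -20, -4, 4)
    target = box(-14, 14, 20, 26, -14, 14)
    excludes = [box(-14, 14, -2, 2, -14, 14)] if with_exclusion_wall else []
    rois = {"seed": seed, "targets": [target], "excludes": excludes,
            "includes": []}
    dummy = RoiRecipe(tree={"op": "select", "labels": []})
    protocol = TractProtocol(
        name="bundle", seed_recipe=dummy, target_recipes=[dummy],
        n_streamlines=n_streamlines,
        amplitude_cutoff_fraction=cutoff_fraction)
    template = ScalarMap(np.zeros(shape, dtype=np.int32), aff, role="density")
    return {"field": field, "rois": rois, "centerline": centerline,
            "protocol": protocol, "template": template}


# --------------------------------------------------------------------------
# streamline bundles and spurious injection
# --------------------------------------------------------------------------

def _perp_frame(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t = t / np.linalg.norm(t)
    ref = np.array([0.0, 0.0, 1.0]) if abs(t[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(t, ref)
    u /= np.linalg.norm(u)
    return u, np.cross(t, u)


def make_bundle(centerline: np.ndarray, n: int, tube_radius: float = 2.0,
                jitter: float = 0.0,
                rng: np.random.Generator | None = None,
                spacing_mm: float = 1.0) -> StreamlineSet:
    """n smooth streamlines parallel to the centerline.

    With ``jitter == 0`` the offsets form a regular polar lattice inside
    the tube cross-section; positive jitter adds bounded smooth
    transverse noise per streamline.
    """
    if n <= 0:
        raise SpecError("n must be positive")
    rng = rng or np.random.default_rng(0)
    line = _resample_polyline(np.asarray(centerline, float), spacing_mm)
    tans = _polyline_tangents(line)
    u, v = _perp_frame(tans[0])

    # regular polar lattice of n offsets within the tube
    offsets = []
    k = 0
    ring = 0
    while len(offsets) < n:
        if ring == 0:
            offsets.append(np.zeros(2))
            ring += 1
            continue
        r = tube_radius * ring / max(1, math.ceil((math.sqrt(n) - 1) / 2) + 1)
        m = 6 * ring
        for a in range(m):
            if len(offsets) >= n:
                break
            ang = 2.0 * math.pi * a / m
            offsets.append(np.array([min(r, tube_radius) * math.cos(ang),
                                     min(r, tube_radius) * math.sin(ang)]))
        ring += 1
        k += 1

    sls = []
    for off in offsets[:n]:
        base = line + off[0] * u + off[1] * v
        if jitter > 0:
            # smooth bounded transverse noise: random low-order sinusoid
            s = np.linspace(0, 1, len(line))
            amp = rng.uniform(0, jitter, size=2)
            ph = rng.uniform(0, 2 * math.pi, size=2)
            wig = (amp[0] * np.sin(2 * math.pi * s + ph[0]))[:, None] * u \
                + (amp[1] * np.sin(2 * math.pi * s + ph[1]))[:, None] * v
            base = base + wig
        sls.append(base)
    out = StreamlineSet(streamlines=sls,
                        meta={"generator": "make_bundle", "n": n,
                              "tube_radius": tube_radius, "jitter": jitter})
    out.meta["ground_truth"] = ["coherent"] * n
    return out


def _bundle_frame(streamlines, labels):
    """Centroid, mean direction and perpendicular frame of the coherent part."""
    coherent = [s for s, lab in zip(streamlines, labels) if lab == "coherent"]
    coherent = coherent or streamlines
    allpts = np.concatenate(coherent, axis=0)
    centroid = allpts.mean(axis=0)
    tangents = np.concatenate([np.diff(s, axis=0) for s in coherent], axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    mean_dir = tangents.mean(axis=0)
    mean_dir /= np.linalg.norm(mean_dir)
    u, v = _perp_frame(mean_dir)
    return centroid, mean_dir, u, v


def inject_deviating(sset: StreamlineSet, fraction: float,
                     rng: np.random.Generator,
                     sigma_s: float = 2.0,
                     offset_sigmas: float = 1.5,
                     angle_deg: float = 30.0,
                     length_mm: float = 30.0) -> StreamlineSet:
    """Add mildly deviating streamlines of intermediate coherence.

    Unlike :func:`inject_spurious` (distant and/or orthogonal, coherence
    negligible), these run obliquely through the bundle's neighbourhood
    — default 1.5 sigma_s transverse offset, 30 degrees off the mean
    direction — so their coherence is low but not vanishing.  They model
    the borderline streamlines that only a strong filter setting
    removes; the ground-truth label is still "spurious".
    """
    if not 0.0 <= fraction < 1.0:
        raise SpecError("fraction must be in [0, 1)")
    base = [s.copy() for s in sset.streamlines]
    labels = list(sset.meta.get("ground_truth", ["coherent"] * len(base)))
    n_add = int(round(fraction * labels.count("coherent")))
    out_meta = dict(sset.meta)
    if n_add == 0:
        out = StreamlineSet(streamlines=base, meta=out_meta)
        out.meta["ground_truth"] = labels
        return out
    centroid, mean_dir, u, v = _bundle_frame(base, labels)
    a = math.radians(angle_deg)
    added = []
    for _ in range(n_add):
        ang = rng.uniform(0.0, 2.0 * math.pi)
        radial = math.cos(ang) * u + math.sin(ang) * v
        center = centroid + offset_sigmas * sigma_s * radial
        orient = math.cos(a) * mean_dir + math.sin(a) * radial
        ts = np.linspace(-length_mm / 2, length_mm / 2, 31)
        added.append(center + ts[:, None] * orient)
    out = StreamlineSet(streamlines=base + added, meta=out_meta)
    out.meta["ground_truth"] = labels + ["spurious"] * n_add
    return out


def inject_spurious(sset: StreamlineSet, fraction: float,
                    rng: np.random.Generator,
                    sigma_s: float = 2.0,
                    offset_mm: float | None = None,
                    length_mm: float = 20.0) -> StreamlineSet:
    """Add round(fraction * n) spurious streamlines with ground-truth labels.

    Each injected streamline is straight and oriented orthogonally to
    the bundle's mean direction, displaced transversally by
    ``offset_mm`` (default 5 * sigma_s) from the bundle centroid.  The
    combination of distance and near-orthogonality makes its
    position-orientation coherence with the bundle negligible by
    construction, while keeping it inside the imaging field of view so
    it shows up in density maps until filtered out.
    """
    if not 0.0 <= fraction < 1.0:
        raise SpecError("fraction must be in [0, 1)")
    n_add = int(round(fraction * len(sset)))
    base = [s.copy() for s in sset.streamlines]
    labels = list(sset.meta.get("ground_truth", ["coherent"] * len(base)))
    if n_add == 0:
        out = StreamlineSet(streamlines=base, meta=dict(sset.meta))
        out.meta["ground_truth"] = labels
        return out

    centroid, mean_dir, u, v = _bundle_frame(base, labels)

    dist = 5.0 * sigma_s if offset_mm is None else offset_mm
    allpts = np.concatenate(
        [s for s, lab in zip(base, labels)
         if lab == "coherent"] or base, axis=0)
    added = []
    for _ in range(n_add):
        ang = rng.uniform(0.0, 2.0 * math.pi)
        offset_dir = math.cos(ang) * u + math.sin(ang) * v
        along = rng.uniform(-0.3, 0.3) * (np.ptp(allpts[:, 0]) + 1.0)
        center = centroid + dist * offset_dir + along * mean_dir
        # orthogonal orientation within the transverse plane
        orient = math.sin(ang) * u - math.cos(ang) * v
        ts = np.linspace(-length_mm / 2, length_mm / 2, 21)
        added.append(center + ts[:, None] * orient)
    out = StreamlineSet(streamlines=base + added, meta=dict(sset.meta))
    out.meta["ground_truth"] = labels + ["spurious"] * n_add
    return out


# --------------------------------------------------------------------------
# multi-subject cohorts
# --------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Controllable inter-subject variability for desk-scale cohorts."""

    n_subjects: int = 10
    jitter_mm: float = 2.0          # sd of per-subject translation
    jitter_deg: float = 2.0         # sd of per-subject rotation angles
    scale_sd: float = 0.05          # sd of per-axis scale about 1
    spurious_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise SpecError("n_subjects must be >= 1")
        if min(self.jitter_mm, self.jitter_deg, self.scale_sd) < 0:
            raise SpecError("jitter parameters must be >= 0")
        if not 0.0 <= self.spurious_fraction < 1.0:
            raise SpecError("spurious_fraction must be in [0, 1)")


def _jitter_affine(rng: np.random.Generator, spec: CohortSpec,
                   center: np.ndarray) -> np.ndarray:
    """Small rigid+scale affine about the phantom centre (closed-form inverse)."""
    angles = np.radians(rng.normal(0.0, spec.jitter_deg, size=3))
    cx, sx = math.cos(angles[0]), math.sin(angles[0])
    cy, sy = math.cos(angles[1]), math.sin(angles[1])
    cz, sz = math.cos(angles[2]), math.sin(angles[2])
    rot = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]]) \
        @ np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]]) \
        @ np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    scale = np.diag(rng.normal(1.0, spec.scale_sd, size=3))
    lin = rot @ scale
    trans = rng.normal(0.0, spec.jitter_mm, size=3)
    a = np.eye(4)
    a[:3, :3] = lin
    a[:3, 3] = center - lin @ center + trans
    return a


def make_cohort(spec: CohortSpec,
                base_phantom: LabelVolume,
                base_centerlines: dict[str, np.ndarray] | None = None,
                fodf_kwargs: dict | None = None
                ) -> list[tuple[LabelVolume, FodfField, SpatialTransform]]:
    """Jittered copies of the base phantom with exact inverse transforms.

    Each subject's parcellation is the base grid resampled through a
    small rigid+scale affine; the subject fODF is regenerated from the
    affinely transformed bundle centerlines (exact, no SH reorientation
    needed).  The returned transform maps subject space back to base
    space and exactly inverts the applied jitter.
    """
    from .io import apply_transform  # local import to avoid cycle at module load

    spec_obj = spec
    rng = np.random.default_rng(spec_obj.seed)
    if base_centerlines is None:
        base_centerlines = default_phantom_spec().centerlines()
    fodf_kwargs = fodf_kwargs or {}
    shape = base_phantom.shape
    aff = base_phantom.affine
    center = np.asarray(aff[:3, :3]) @ (np.asarray(shape) / 2.0) + aff[:3, 3]

    subjects = []
    for _ in range(spec_obj.n_subjects):
        if spec_obj.jitter_mm == 0 and spec_obj.jitter_deg == 0 \
                and spec_obj.scale_sd == 0:
            a = np.eye(4)
        else:
            a = _jitter_affine(rng, spec_obj, center)
        fwd = SpatialTransform.from_affine(a)
        vol = apply_transform(base_phantom, fwd)
        lines = {k: fwd.apply_points(v) for k, v in base_centerlines.items()}
        fodf = make_fodf(lines, shape, aff, **fodf_kwargs)
        back = SpatialTransform.from_affine(np.linalg.inv(a))
        subjects.append((vol, fodf, back))
    return subjects
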