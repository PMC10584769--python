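"""Geometric ROI construction from a labeled parcellation.

Seed/target/exclude/include masks for each tract are built by a small
set of deterministic geometric operators applied to named parcellation
labels, driven by a declarative protocol (YAML/JSON).  Label references
may carry a hemisphere qualifier: ``name@ipsi`` / ``name@contra``
resolve to the ``_L``/``_R`` instance for the hemisphere being built,
``name@both`` takes the union of both instances, and a bare name must
match a label exactly (midline structures).
"""

from __future__ import annotations

import math
import importlib.resources
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

from .io import LabelVolume, ScalarMap, voxel_to_world

AXES = {"LR": 0, "AP": 1, "IS": 2}
# sides keeping the high-coordinate half of each axis in RAS+
_HIGH_SIDES = {"right": 0, "anterior": 1, "superior": 2}
_LOW_SIDES = {"left": 0, "posterior": 1, "inferior": 2}


class ProtocolError(ValueError):
    pass


class GeometryError(ValueError):
    pass


# --------------------------------------------------------------------------
# primitive operators
# --------------------------------------------------------------------------

def _voxel_axis_coords(mask: ScalarMap, axis: int) -> np.ndarray:
    """World coordinate along one axis for every nonzero voxel."""
    idx = np.argwhere(mask.grid != 0)
    return voxel_to_world(mask.affine, idx)[:, axis], idx


def select_labels(vol: LabelVolume, names: list[str]) -> ScalarMap:
    """Union mask of the named labels; [] gives the empty mask."""
    grid = np.zeros(vol.shape, dtype=np.uint8)
    for name in names:
        if name not in vol.labels:
            raise ProtocolError(f"unresolvable label name: {name!r}")
        grid |= (vol.grid == vol.labels[name]).astype(np.uint8)
    return ScalarMap(grid, vol.affine, role="binary")


def split_axis(mask: ScalarMap, axis: str, side: str,
               fraction: float = 0.5) -> ScalarMap:
    """Keep voxels on one side of a plane across the mask's bounding extent.

    The plane sits at ``fraction`` of the bounding extent measured from
    the end *opposite* the kept side, so the kept part spans
    ``(1 - fraction)`` of the extent: side='anterior', fraction=0.5 keeps
    the anterior half; side='posterior', fraction=1/3 keeps the
    posterior two-thirds; fraction=0 keeps the whole mask.  Voxels whose
    centre lies exactly on the plane belong to the kept side.
    """
    if mask.voxel_count() == 0:
        raise GeometryError("split_axis: empty mask")
    if axis not in AXES:
        raise ProtocolError(f"unknown axis {axis!r}")
    a = AXES[axis]
    if side in _HIGH_SIDES:
        if _HIGH_SIDES[side] != a:
            raise ProtocolError(f"side {side!r} does not lie on axis {axis}")
        high = True
    elif side in _LOW_SIDES:
        if _LOW_SIDES[side] != a:
            raise ProtocolError(f"side {side!r} does not lie on axis {axis}")
        high = False
    else:
        raise ProtocolError(f"unknown side {side!r}")
    coords, idx = _voxel_axis_coords(mask, a)
    lo, hi = coords.min(), coords.max()
    plane = lo + fraction * (hi - lo) if high else hi - fraction * (hi - lo)
    keep = coords >= plane - 1e-9 if high else coords <= plane + 1e-9
    grid = np.zeros(mask.shape, dtype=np.uint8)
    kept = idx[keep]
    grid[kept[:, 0], kept[:, 1], kept[:, 2]] = 1
    return ScalarMap(grid, mask.affine, role="binary")


def axial_slab(mask: ScalarMap, reference: ScalarMap,
               thickness_mm: float) -> ScalarMap:
    """Keep mask voxels within thickness/2 of the reference's axial midpoint.

    The slab is centred on the midpoint of the reference mask's
    world-z extent (e.g. a 4 mm slab at the anatomical midpoint of the
    fourth ventricle).
    """
    if reference.voxel_count() == 0:
        raise GeometryError("axial_slab: empty reference")
    if mask.voxel_count() == 0:
        raise GeometryError("axial_slab: empty mask")
    zref, _ = _voxel_axis_coords(reference, 2)
    mid = 0.5 * (zref.min() + zref.max())
    z, idx = _voxel_axis_coords(mask, 2)
    keep = np.abs(z - mid) <= thickness_mm / 2.0 + 1e-9
    grid = np.zeros(mask.shape, dtype=np.uint8)
    kept = idx[keep]
    grid[kept[:, 0], kept[:, 1], kept[:, 2]] = 1
    if not keep.any():
        warnings.warn("axial_slab: mask disjoint from slab", stacklevel=2)
    return ScalarMap(grid, mask.affine, role="binary")


def gaussian_dilate(mask: ScalarMap, sigma_mm: float,
                    constraint: ScalarMap | None = None,
                    threshold: float = 0.3) -> ScalarMap:
    """Dilate a binary mask by Gaussian smoothing and thresholding.

    The {0,1} mask is smoothed with an isotropic Gaussian of standard
    deviation ``sigma_mm`` and kept where the smoothed value reaches
    ``threshold`` (default 0.3) times the smoothed maximum — relative
    thresholding so small structures (single voxels included) still
    dilate on coarse grids.  The result is intersected with
    ``constraint`` when given, and always contains the original mask
    (within the constraint).
    """
    if sigma_mm <= 0:
        raise ProtocolError("sigma_mm must be positive")
    vox_sizes = np.sqrt((np.asarray(mask.affine)[:3, :3] ** 2).sum(axis=0))
    smooth = gaussian_filter(mask.grid.astype(float), sigma=sigma_mm / vox_sizes)
    out = (smooth >= threshold * smooth.max()).astype(np.uint8)
    out |= mask.grid.astype(np.uint8)        # dilation is a superset
    if constraint is not None:
        out &= (constraint.grid != 0).astype(np.uint8)
        out |= mask.grid.astype(np.uint8) & (constraint.grid != 0).astype(np.uint8)
    return ScalarMap(out, mask.affine, role="binary")


def sphere_between(mask_a: ScalarMap, mask_b: ScalarMap, volume_mm3: float,
                   constraint: ScalarMap) -> ScalarMap:
    """Ball of the given volume centred between two structures.

    The radius is r = (3 V / 4 pi)^(1/3); the centre is the midpoint of
    the two mask centroids snapped to the nearest constraint
    (white-matter) voxel centre, ties broken by lowest linear index.
    """
    for m, nm in ((mask_a, "mask_a"), (mask_b, "mask_b"), (constraint, "constraint")):
        if m.voxel_count() == 0:
            raise GeometryError(f"sphere_between: empty {nm}")
    r = (3.0 * volume_mm3 / (4.0 * math.pi)) ** (1.0 / 3.0)

    def centroid(m: ScalarMap) -> np.ndarray:
        idx = np.argwhere(m.grid != 0)
        return voxel_to_world(m.affine, idx).mean(axis=0)

    mid = 0.5 * (centroid(mask_a) + centroid(mask_b))
    cidx = np.argwhere(constraint.grid != 0)
    cpts = voxel_to_world(constraint.affine, cidx)
    d = np.linalg.norm(cpts - mid, axis=1)
    best = np.flatnonzero(d == d.min())
    lin = np.ravel_multi_index(cidx[best].T, constraint.shape)
    center = cpts[best[np.argmin(lin)]]

    shape = constraint.shape
    aff = constraint.affine
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    pts = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    w = voxel_to_world(aff, pts)
    inside = np.linalg.norm(w - center, axis=1) <= r + 1e-9
    grid = inside.reshape(shape).astype(np.uint8)
    return ScalarMap(grid, aff, role="binary")


def split_by_plane(mask: ScalarMap, landmark: ScalarMap) -> tuple[ScalarMap, ScalarMap]:
    """Split a mask at a coronal plane through the landmark's anterior edge.

    Returns (posterior_part, anterior_part); the plane sits at the
    anterior-most world y of the landmark mask, with plane voxels
    assigned to the posterior part.  The parts partition the mask.
    """
    if landmark.voxel_count() == 0:
        raise GeometryError("split_by_plane: empty landmark")
    if mask.voxel_count() == 0:
        raise GeometryError("split_by_plane: empty mask")
    ylm, _ = _voxel_axis_coords(landmark, 1)
    plane = ylm.max()
    y, idx = _voxel_axis_coords(mask, 1)
    post = np.zeros(mask.shape, dtype=np.uint8)
    ant = np.zeros(mask.shape, dtype=np.uint8)
    sel = y <= plane + 1e-9
    p, a = idx[sel], idx[~sel]
    post[p[:, 0], p[:, 1], p[:, 2]] = 1
    ant[a[:, 0], a[:, 1], a[:, 2]] = 1
    return (ScalarMap(post, mask.affine, role="binary"),
            ScalarMap(ant, mask.affine, role="binary"))


def union(*masks: ScalarMap) -> ScalarMap:
    if not masks:
        raise ProtocolError("union of no masks")
    grid = np.zeros(masks[0].shape, dtype=np.uint8)
    for m in masks:
        grid |= (m.grid != 0).astype(np.uint8)
    return ScalarMap(grid, masks[0].affine, role="binary")


# --------------------------------------------------------------------------
# declarative protocol
# --------------------------------------------------------------------------

@dataclass
class RoiRecipe:
    """Operator tree for one ROI, evaluated against a LabelVolume."""

    tree: dict
    name: str = ""

    def build(self, vol: LabelVolume, hemisphere: str) -> ScalarMap:
        return _eval_tree(self.tree, vol, hemisphere)


def _resolve_name(name: str, hemisphere: str) -> list[str]:
    if "@" in name:
        base, qual = name.split("@", 1)
        if qual == "ipsi":
            return [f"{base}_{'L' if hemisphere == 'left' else 'R'}"]
        if qual == "contra":
            return [f"{base}_{'R' if hemisphere == 'left' else 'L'}"]
        if qual == "both":
            return [f"{base}_L", f"{base}_R"]
        raise ProtocolError(f"unknown hemisphere qualifier in {name!r}")
    return [name]


def _eval_tree(node: dict, vol: LabelVolume, hemisphere: str) -> ScalarMap:
    if not isinstance(node, dict) or "op" not in node:
        raise ProtocolError(f"malformed recipe node: {node!r}")
    op = node["op"]
    if op == "select":
        names: list[str] = []
        for n in node.get("labels", []):
            names.extend(_resolve_name(n, hemisphere))
        return select_labels(vol, names)
    if op == "union":
        parts = [_eval_tree(c, vol, hemisphere) for c in node["of"]]
        return union(*parts)
    if op == "split_axis":
        base = _eval_tree(node["of"], vol, hemisphere)
        side = node["side"]
        # left/right sides are hemisphere-relative only if marked lateral/medial
        if side == "lateral":
            side = "left" if hemisphere == "left" else "right"
        elif side == "medial":
            side = "right" if hemisphere == "left" else "left"
        return split_axis(base, node["axis"], side, node.get("fraction", 0.5))
    if op == "axial_slab":
        base = _eval_tree(node["of"], vol, hemisphere)
        ref = _eval_tree(node["reference"], vol, hemisphere)
        return axial_slab(base, ref, float(node["thickness_mm"]))
    if op == "gaussian_dilate":
        base = _eval_tree(node["of"], vol, hemisphere)
        constraint = None
        if "constraint" in node:
            constraint = _eval_tree(node["constraint"], vol, hemisphere)
        return gaussian_dilate(base, float(node["sigma_mm"]), constraint,
                               threshold=float(node.get("threshold", 0.3)))
    if op == "sphere_between":
        a = _eval_tree(node["a"], vol, hemisphere)
        b = _eval_tree(node["b"], vol, hemisphere)
        constraint = _eval_tree(node["constraint"], vol, hemisphere)
        return sphere_between(a, b, float(node["volume_mm3"]), constraint)
    if op == "split_by_plane":
        base = _eval_tree(node["of"], vol, hemisphere)
        landmark = _eval_tree(node["landmark"], vol, hemisphere)
        post, ant = split_by_plane(base, landmark)
        return post if node.get("keep", "posterior") == "posterior" else ant
    raise ProtocolError(f"unknown recipe operator {op!r}")


@dataclass
class TractProtocol:
    """Declarative recipe for one tract: ROIs plus tracking/filter settings."""

    name: str
    seed_recipe: RoiRecipe
    target_recipes: list[RoiRecipe]
    exclude_recipes: list[RoiRecipe] = dc_field(default_factory=list)
    include_recipes: list[RoiRecipe] = dc_field(default_factory=list)
    n_streamlines: int = 5000
    amplitude_cutoff_fraction: float = 0.1
    seed_cone: str | None = None            # e.g. 'lateral' (45 deg half-angle)
    rfbc_threshold: float | None = None     # None = no filtering
    step_mm: float = 0.2
    curvature_radius_mm: float = 1.0
    max_attempts_per_seed: int = 10_000
    max_length_mm: float = 250.0
    hemisphere: str = "left"

    def __post_init__(self) -> None:
        if self.n_streamlines <= 0:
            raise ProtocolError("n_streamlines must be positive")
        if not 0.0 < self.amplitude_cutoff_fraction < 1.0:
            raise ProtocolError("amplitude cutoff fraction must be in (0, 1)")
        if self.step_mm > 2.0 * self.curvature_radius_mm:
            raise ProtocolError("step size exceeds the curvature diameter")
        if self.hemisphere not in ("left", "right"):
            raise ProtocolError("hemisphere must be 'left' or 'right'")

    def cone_axis(self) -> np.ndarray | None:
        if self.seed_cone is None:
            return None
        if self.seed_cone == "lateral":
            return np.array([-1.0, 0.0, 0.0]) if self.hemisphere == "left" \
                else np.array([1.0, 0.0, 0.0])
        if self.seed_cone == "medial":
            return np.array([1.0, 0.0, 0.0]) if self.hemisphere == "left" \
                else np.array([-1.0, 0.0, 0.0])
        axis = np.asarray(self.seed_cone, dtype=float)
        return axis / np.linalg.norm(axis)

    def tracking_params(self):
        from .tracking import TrackingParams
        return TrackingParams(
            step_mm=self.step_mm,
            curvature_radius_mm=self.curvature_radius_mm,
            cutoff_fraction=self.amplitude_cutoff_fraction,
            max_length_mm=self.max_length_mm,
            max_attempts_per_seed=self.max_attempts_per_seed,
            seed_cone_axis=self.cone_axis(),
        )

    def with_hemisphere(self, hemisphere: str) -> "TractProtocol":
        import copy
        p = copy.deepcopy(self)
        p.hemisphere = hemisphere
        return p


def build_rois(protocol: TractProtocol, vol: LabelVolume) -> dict:
    """Evaluate all recipe trees of a protocol into binary masks.

    Returns {'seed': ScalarMap, 'targets': [...], 'excludes': [...],
    'includes': [...]}.  An empty seed or target is a protocol error
    naming the tract.
    """
    h = protocol.hemisphere
    seed = protocol.seed_recipe.build(vol, h)
    targets = [r.build(vol, h) for r in protocol.target_recipes]
    excludes = [r.build(vol, h) for r in protocol.exclude_recipes]
    includes = [r.build(vol, h) for r in protocol.include_recipes]
    if seed.voxel_count() == 0:
        raise ProtocolError(f"{protocol.name}: seed region is empty")
    if not targets or all(t.voxel_count() == 0 for t in targets):
        raise ProtocolError(f"{protocol.name}: all target regions are empty")
    return {"seed": seed, "targets": targets,
            "excludes": excludes, "includes": includes}


def roi_volume_stats(masks_per_subject: list[ScalarMap]) -> dict:
    """Across-subject ROI volume statistics (mean, sd, sd as % of mean)."""
    if len(masks_per_subject) < 2:
        raise ValueError("need at least 2 subjects")
    vols = np.array([m.volume_mm3() for m in masks_per_subject])
    mean = float(vols.mean())
    sd = float(vols.std(ddof=1))
    return {"mean_mm3": mean, "sd_mm3": sd,
            "sd_percent": 100.0 * sd / mean if mean > 0 else 0.0}


# --------------------------------------------------------------------------
# protocol files
# --------------------------------------------------------------------------

def _recipe(node: dict, name: str = "") -> RoiRecipe:
    return RoiRecipe(tree=node, name=name)


def load_protocols(path=None) -> dict[str, TractProtocol]:
    """Load tract protocols from YAML; default: the shipped six-tract file."""
    if path is None:
        src = importlib.resources.files("tractweave").joinpath(
            "protocols/default_six_tracts.yaml")
        doc = yaml.safe_load(src.read_text())
    else:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    out = {}
    for name, cfg in doc["tracts"].items():
        rfbc = cfg.get("rfbc_threshold")
        out[name] = TractProtocol(
            name=name,
            seed_recipe=_recipe(cfg["seed"], f"{name}.seed"),
            target_recipes=[_recipe(t, f"{name}.target") for t in cfg["targets"]],
            exclude_recipes=[_recipe(t, f"{name}.exclude")
                             for t in cfg.get("excludes", [])],
            include_recipes=[_recipe(t, f"{name}.include")
                             for t in cfg.get("includes", [])],
            n_streamlines=int(cfg["n_streamlines"]),
            amplitude_cutoff_fraction=float(cfg["amplitude_cutoff_fraction"]),
            seed_cone=cfg.get("seed_cone"),
            rfbc_threshold=None if rfbc in (None, "none") else float(rfbc),
            step_mm=float(cfg.get("step_mm", 0.2)),
            curvature_radius_mm=float(cfg.get("curvature_radius_mm", 1.0)),
            max_attempts_per_seed=int(cfg.get("max_attempts_per_seed", 10_000)),
            max_length_mm=float(cfg.get("max_length_mm", 250.0)),
        )
    return out
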