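"""Tract density imaging, binarization, and group probability maps.

A tract density image (TDI) counts, per voxel, the number of distinct
streamlines traversing it.  Binarizing at K >= 1 and averaging the
binarized, spatially normalized maps over subjects yields the tractogram
probability map: the fraction of subjects with at least one streamline
in each voxel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import (GeometryError, ScalarMap, SpatialTransform, StreamlineSet,
                 apply_transform, world_to_voxel)


class RoleError(TypeError):
    pass


def _supersample(sl: np.ndarray, max_spacing: float) -> np.ndarray:
    """Insert points so consecutive spacing never exceeds max_spacing."""
    seg = np.linalg.norm(np.diff(sl, axis=0), axis=1)
    if np.all(seg <= max_spacing):
        return sl
    pieces = [sl[:1]]
    for i, d in enumerate(seg):
        n = int(np.ceil(d / max_spacing))
        ts = np.linspace(0.0, 1.0, n + 1)[1:]
        pieces.append(sl[i] + ts[:, None] * (sl[i + 1] - sl[i]))
    return np.concatenate(pieces, axis=0)


def tract_density(sset: StreamlineSet, template: ScalarMap,
                  supersample_factor: float = 0.25) -> ScalarMap:
    """Per-voxel count of distinct streamlines traversing the voxel.

    Each streamline contributes at most 1 per voxel regardless of loops.
    Segments are supersampled at ``supersample_factor`` times the
    smallest voxel edge so no traversed voxel is skipped; halving the
    factor must not change the binarized result (resolution sufficiency
    is a tested invariant).  Points outside the template are ignored
    with a warning.
    """
    if template.role not in ("density", "binary", "probability"):
        raise RoleError("template must be a ScalarMap")
    vox_edges = np.sqrt((np.asarray(template.affine)[:3, :3] ** 2).sum(axis=0))
    spacing = supersample_factor * float(vox_edges.min())
    shape = np.asarray(template.shape)
    counts = np.zeros(template.shape, dtype=np.int32)
    outside_seen = False
    for sl in sset.streamlines:
        dense = _supersample(np.asarray(sl, float), spacing)
        idx = np.floor(world_to_voxel(template.affine, dense) + 0.5).astype(np.intp)
        ok = np.all((idx >= 0) & (idx < shape), axis=1)
        if not ok.all():
            outside_seen = True
        idx = idx[ok]
        if len(idx) == 0:
            continue
        uniq = np.unique(idx, axis=0)
        counts[uniq[:, 0], uniq[:, 1], uniq[:, 2]] += 1
    if outside_seen:
        warnings.warn("streamline points outside the template were ignored",
                      stacklevel=2)
    return ScalarMap(counts, template.affine, role="density")


def binarize(density: ScalarMap, k_min: int = 1) -> ScalarMap:
    """Indicator of streamline count >= k_min (the K >= 1 rule by default)."""
    if density.role != "density":
        raise RoleError(f"binarize expects a density map, got role={density.role!r}")
    return ScalarMap((density.grid >= k_min).astype(np.uint8),
                     density.affine, role="binary")


@dataclass
class ProbabilityMapBundle:
    """Group probability map: voxelwise mean of normalized binary maps."""

    map: ScalarMap
    n_subjects: int

    def __post_init__(self) -> None:
        if self.map.role != "probability":
            raise RoleError("bundle map must have role='probability'")


def probability_map(binary_maps: list[ScalarMap],
                    transforms: list[SpatialTransform] | None = None,
                    template: ScalarMap | None = None) -> ProbabilityMapBundle:
    """Voxelwise mean of binarized maps after spatial normalization.

    Each subject map is mapped into template space through its transform
    (identity when none given) with nearest-neighbour resampling, so
    binarity is preserved before averaging; the resulting probabilities
    are exact multiples of 1/n_subjects.
    """
    if not binary_maps:
        raise ValueError("need at least one subject map")
    if transforms is None:
        transforms = [SpatialTransform.identity()] * len(binary_maps)
    if len(transforms) != len(binary_maps):
        raise ValueError("one transform per subject map required")
    ref = template if template is not None else binary_maps[0]
    acc = np.zeros(ref.shape, dtype=float)
    for m, t in zip(binary_maps, transforms):
        if m.role != "binary":
            raise RoleError("probability_map expects binary maps")
        warped = apply_transform(m, t, template=ref)
        if warped.shape != tuple(ref.shape):
            raise GeometryError("subject map does not resample onto the template")
        acc += warped.grid
    prob = acc / len(binary_maps)
    return ProbabilityMapBundle(
        map=ScalarMap(prob, np.asarray(ref.affine, float), role="probability"),
        n_subjects=len(binary_maps))


def threshold_probability(bundle: ProbabilityMapBundle,
                          confidence: float) -> ScalarMap:
    """Binary mask of voxels with probability >= confidence (in (0, 1])."""
    if not 0.0 < confidence <= 1.0:
        raise ValueError("confidence must be in (0, 1]")
    return ScalarMap((bundle.map.grid >= confidence - 1e-12).astype(np.uint8),
                     bundle.map.affine, role="binary")
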