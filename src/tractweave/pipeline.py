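"""End-to-end pipeline orchestration and the four evaluation experiments.

For each tract: build ROIs -> track -> FBC-filter at the protocol's
setting -> tract density map -> binarized map, writing every artifact
together with a run manifest (config snapshot, seeds, timings,
checksums).  One global seed fans out to per-stage child seeds through
``numpy.random.SeedSequence.spawn`` so stages are independently
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from . import __version__
from .fbc import FbcParams, fbc_filter
from .io import ScalarMap, write_scalar_map, write_streamlines
from .maps import binarize, probability_map, threshold_probability, tract_density
from .roi import ProtocolError, TractProtocol, build_rois, load_protocols
from .synthetic import (CohortSpec, default_phantom_spec, make_cohort,
                        make_default_fodf, make_phantom)
from .tracking import TrackingError, track
from .evaluate import holdout_cv, repeated_processing, test_retest


class ConfigError(ValueError):
    pass


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    seed: int | None = None
    stage_seeds: dict = dc_field(default_factory=dict)
    timings_s: dict = dc_field(default_factory=dict)
    checksums: dict = dc_field(default_factory=dict)
    errors: dict = dc_field(default_factory=dict)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))


def _stage_seed(root: int, index: int) -> int:
    """Deterministic child seed: counter scheme below 2**31."""
    return int(np.random.SeedSequence([root, index]).generate_state(1)[0] % (2**31))


def run_pipeline(config: dict, out_dir, seed: int = 0) -> RunManifest:
    """Run build-ROIs / track / filter / density / binarize per tract.

    ``config`` keys: 'protocols' (path or None for the shipped six),
    'tracts' (names, default all), 'hemisphere', 'n_streamlines'
    (override for desk-scale runs), 'fodf'/'labels' (paths, or 'phantom'
    to generate the default phantom in memory).  A failing tract is
    recorded in the manifest and does not abort the others.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dict(config), seed=seed)

    source = config.get("source", "phantom")
    if source == "phantom":
        vol = make_phantom()
        field = make_default_fodf()
    else:
        from .io import read_label_volume
        from .tracking import read_fodf
        import yaml as _yaml
        if not all(k in config for k in ("labels", "fodf", "label_table")):
            raise ConfigError("config must name a label volume, a label table "
                              "and an fODF field")
        with open(config["label_table"]) as fh:
            table = _yaml.safe_load(fh)
        vol = read_label_volume(config["labels"], table)
        field = read_fodf(config["fodf"])

    protocols = load_protocols(config.get("protocols"))
    tract_names = config.get("tracts", list(protocols))
    hemisphere = config.get("hemisphere", "left")
    n_override = config.get("n_streamlines")
    fbc_params = FbcParams(**config.get("fbc", {}))
    template = ScalarMap(np.zeros(vol.shape, dtype=np.int32), vol.affine,
                         role="density")

    for i, name in enumerate(tract_names):
        if name not in protocols:
            manifest.errors[name] = "unknown tract protocol"
            continue
        t0 = time.perf_counter()
        stage_seed = _stage_seed(seed, i)
        manifest.stage_seeds[name] = stage_seed
        try:
            proto = protocols[name].with_hemisphere(hemisphere)
            rois = build_rois(proto, vol)
            rng = np.random.default_rng(stage_seed)
            sset = track(proto, field, rois, rng, n_streamlines=n_override)
            if proto.rfbc_threshold is not None and len(sset) >= 2:
                sset = fbc_filter(sset, proto.rfbc_threshold, fbc_params)
            density = tract_density(sset, template)
            binary = binarize(density)

            tck = out_dir / f"{name}_{hemisphere}.tck"
            write_streamlines(sset, tck)
            dpath = out_dir / f"{name}_{hemisphere}_tdi.nii"
            bpath = out_dir / f"{name}_{hemisphere}_binary.nii"
            write_scalar_map(density, dpath)
            write_scalar_map(binary, bpath)
            for p in (tck, dpath, bpath):
                manifest.checksums[p.name] = _sha256(p)
            manifest.timings_s[name] = round(time.perf_counter() - t0, 3)
        except (ProtocolError, TrackingError, ConfigError) as exc:
            manifest.errors[name] = f"{type(exc).__name__}: {exc}"
    manifest.write(out_dir / "manifest.json")
    return manifest


# --------------------------------------------------------------------------
# experiments
# --------------------------------------------------------------------------

def _bundle_phantom_rois(tract: str = "CST", hemisphere: str = "left"):
    """Default phantom, fODF field and ROI set for one tract."""
    vol = make_phantom()
    field = make_default_fodf()
    proto = load_protocols()[tract].with_hemisphere(hemisphere)
    rois = build_rois(proto, vol)
    return vol, field, proto, rois


def _track_binary_map(proto: TractProtocol, field, rois, template, seed: int,
                      n_streamlines: int, epsilon=None,
                      fbc_params: FbcParams | None = None) -> ScalarMap:
    rng = np.random.default_rng(seed)
    sset = track(proto, field, rois, rng, n_streamlines=n_streamlines)
    if epsilon is not None and len(sset) >= 2:
        sset = fbc_filter(sset, epsilon, fbc_params)
    return binarize(tract_density(sset, template))


def run_experiment(which: str, config: dict | None = None,
                   seed: int = 0) -> dict:
    """Run one of the four evaluation experiments at desk scale.

    which: 'probability_maps', 'holdout', 'repeat', or 'retest'.
    Returns a JSON-serializable report; see each branch for the config
    keys honoured.
    """
    if which not in ("probability_maps", "holdout", "repeat", "retest"):
        raise ConfigError(f"unknown experiment {which!r}")
    config = dict(config or {})
    tract = config.get("tract", "CST")
    n_streamlines = int(config.get("n_streamlines", 50))

    if which == "repeat":
        n_runs = int(config.get("runs", 10))
        if n_runs < 2:
            raise ConfigError("repeated processing needs runs >= 2")
        if config.get("phantom", "bundle") == "bundle":
            from .synthetic import make_bundle_phantom
            bp = make_bundle_phantom(n_streamlines=n_streamlines)
            field, rois, proto = bp["field"], bp["rois"], bp["protocol"]
            template = bp["template"]
        else:
            _, field, proto, rois = _bundle_phantom_rois(tract)
            template = ScalarMap(np.zeros(field.shape, dtype=np.int32),
                                 field.affine, role="density")
        settings = config.get("filter_settings", [None, 1e-3, 1e-1])
        fbc_params = FbcParams(**config.get("fbc", {}))
        # each run adds noise streamlines of two severities: grossly
        # spurious (removed by any filter setting) and mildly deviating
        # (removed only by the strong setting) — a desk-scale stand-in
        # for the spectrum of deviating streamlines probabilistic
        # tracking produces on real data
        spurious_fraction = float(config.get("spurious_fraction", 0.1))
        deviating_fraction = float(config.get("deviating_fraction", 0.1))
        rngs = [_stage_seed(seed, r) for r in range(n_runs)]
        from .tracking import track as _track
        from .maps import tract_density as _tdi
        from .synthetic import inject_deviating, inject_spurious
        runs = []
        for s in rngs:
            rng_run = np.random.default_rng(s)
            sset = _track(proto, field, rois, rng_run,
                          n_streamlines=n_streamlines)
            if spurious_fraction > 0:
                sset = inject_spurious(sset, spurious_fraction, rng_run,
                                       sigma_s=fbc_params.sigma_s)
            if deviating_fraction > 0:
                sset = inject_deviating(sset, deviating_fraction, rng_run,
                                        sigma_s=fbc_params.sigma_s)
            runs.append(sset)
        report = {"experiment": "repeat", "tract": tract, "runs": n_runs,
                  "settings": {}}
        for eps in settings:
            maps_ = []
            for sset in runs:
                filtered = fbc_filter(sset, eps, fbc_params) if len(sset) >= 2 \
                    else sset
                maps_.append(binarize(_tdi(filtered, template)))
            rel = repeated_processing(maps_, filtering=eps)
            key = "none" if eps is None else f"{eps:g}"
            report["settings"][key] = {
                "n_pairs": len(rel.dice_values),
                "mean_dice": float(rel.dice_values.mean()),
                "summary": rel.summary,
            }
        return report

    # cohort-based experiments share subject generation
    n_subjects = int(config.get("n_subjects", 10))
    jitter = config.get("jitter", {})
    cohort_spec = CohortSpec(
        n_subjects=n_subjects,
        jitter_mm=float(jitter.get("mm", 2.0)),
        jitter_deg=float(jitter.get("deg", 2.0)),
        scale_sd=float(jitter.get("scale_sd", 0.05)),
        seed=_stage_seed(seed, 1000))
    base = make_phantom()
    spec = default_phantom_spec()
    # only the studied tract's bundles are needed in the subject fODFs
    lines = {k: v for k, v in spec.centerlines().items()
             if k.startswith(f"{tract}_")}
    subjects = make_cohort(cohort_spec, base, lines)
    protocols = load_protocols()
    proto = protocols[tract]
    template = ScalarMap(np.zeros(base.shape, dtype=np.int32), base.affine,
                         role="density")
    # one fixed tracker seed across subjects: the cohort experiments
    # isolate anatomical variability, not tracker stochasticity
    tracker_seed = _stage_seed(seed, 2000)

    def subject_map(vol, field, back) -> ScalarMap:
        rois = build_rois(proto, vol)
        bmap = _track_binary_map(proto, field, rois, template, tracker_seed,
                                 n_streamlines, epsilon=proto.rfbc_threshold)
        from .io import apply_transform
        return apply_transform(bmap, back, template=template)

    maps_ = [subject_map(v, f, b) for v, f, b in subjects]

    if which == "probability_maps":
        bundle = probability_map(maps_)
        confidences = config.get("confidences", [0.05, 0.50, 0.90])
        report = {"experiment": "probability_maps", "tract": tract,
                  "n_subjects": n_subjects, "thresholded_voxels": {}}
        for c in confidences:
            report["thresholded_voxels"][f"{c:g}"] = \
                int(threshold_probability(bundle, c).voxel_count())
        report["max_probability"] = float(bundle.map.grid.max())
        return report

    if which == "holdout":
        res = holdout_cv(
            maps_,
            ratio=float(config.get("ratio", 0.10)),
            n_iterations=int(config.get("iterations", 300)),
            confidence=float(config.get("confidence", 0.05)),
            rng=np.random.default_rng(_stage_seed(seed, 3000)))
        return {"experiment": "holdout", "tract": tract,
                "n_subjects": n_subjects,
                "n_iterations": res.n_iterations,
                "mean_dice": float(res.dice_values.mean()),
                "dice_values": res.dice_values.tolist(),
                "summary": res.summary}

    if which == "retest":
        # consecutive subject pairs play the role of session 1 / session 2
        reports = []
        for i in range(0, len(subjects) - 1, 2):
            r = test_retest(maps_[i], maps_[i + 1])
            reports.append(r.dice)
        return {"experiment": "retest", "tract": tract,
                "n_pairs": len(reports),
                "dice_values": reports,
                "mean_dice": float(np.mean(reports)) if reports else None}

    raise ConfigError(f"unknown experiment {which!r}")
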