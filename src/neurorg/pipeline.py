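"""End-to-end orchestration: simulate, segment, detect, track, summarise.

These functions tie the stage modules together the way the acceptance runs
and the CLI use them; everything is deterministic given (inputs, config,
seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .config import RunConfig
from .detection import DetectionParams, detect_regions, detect_stack, regions_to_frame
from .errors import FixtureIOError
from .geometry import make_geometry
from .imaging import ImageStack, ImagingConfig
from .io import read_fixture, write_fixture
from .kinetics import PRESETS, sample_tracks
from .motility import (
    cohort_summary,
    directionality,
    make_kymograph,
    soma_distance_map,
    track_statistics,
)
from .distribution import (
    compare_groups,
    contact_fraction,
    distribution_summary,
    proximal_region,
)
from .render import (
    CONTACT_PRESETS,
    fixed_spec_from_preset,
    make_contact_fixture,
    render_fixed_neuron,
    render_timelapse,
)
from .segmentation import (
    DogParams,
    FrangiParams,
    SegmentationMasks,
    detect_soma,
    finalize_masks,
    frangi_response,
    otsu_threshold,
    segment_image,
    segmentation_input,
)
from .tracking import build_tracks

log = logging.getLogger("neurorg")

#: Frame size used for full-scale cohort simulations (neurites >= 40 um).
COHORT_FRAME = (1024, 1024)
COHORT_NEURITES = 6
COHORT_ORGANELLES = 26


def _frangi_params(config: RunConfig) -> FrangiParams:
    return FrangiParams(
        scales=tuple(config.frangi.scales),
        beta=config.frangi.beta,
        gamma=config.frangi.gamma,
    )


def _dog_params(config: RunConfig) -> DogParams:
    return DogParams(
        scales=tuple(config.soma.dog_scales),
        open_radius_px=config.soma.open_radius_px,
        soma_margin_px=config.soma.soma_margin_px,
        downsample=config.soma.downsample,
    )


def segment_stack(stack: ImageStack, config: RunConfig | None = None) -> SegmentationMasks:
    """Segment soma and neurites from the summed temporal max projections."""
    config = config or RunConfig()
    image = segmentation_input(stack)
    return segment_image(
        image,
        pixel_size=stack.config.pixel_size,
        frangi_params=_frangi_params(config),
        dog_params=_dog_params(config),
        noise_mult=config.hysteresis.noise_mult,
    )


def detection_params(config: RunConfig) -> dict[str, DetectionParams]:
    return {
        "PO": DetectionParams(sigma=config.detection.sigma_po, min_size=config.detection.min_size),
        "MITO": DetectionParams(
            sigma=config.detection.sigma_mito, min_size=config.detection.min_size
        ),
    }


def analyze_timelapse(stack: ImageStack, config: RunConfig | None = None):
    """Full motility chain; returns (masks, detections, tracks_by_channel, summaries)."""
    config = config or RunConfig()
    masks = segment_stack(stack, config)
    detections = detect_stack(stack, masks, detection_params(config))
    tracks = {
        ch: build_tracks(frames, config.tracking.max_link_dist, organelle=ch)
        for ch, frames in detections.items()
    }
    summaries = {
        ch: [
            track_statistics(
                tr, stack.config.frame_interval, config.motility.displacement_floor
            )
            for tr in trs
            if len(tr) >= 2
        ]
        for ch, trs in tracks.items()
    }
    return masks, detections, tracks, summaries


def simulate_timelapse_neuron(
    preset_name: str,
    seed: int,
    organelle: str = "PO",
    n_organelles: int = COHORT_ORGANELLES,
    n_neurites: int = COHORT_NEURITES,
    frame_shape=COHORT_FRAME,
    config: ImagingConfig | None = None,
):
    """Simulate one neuron with the named motility preset (single channel).

    If track territories do not fit the generated neurites, the geometry is
    regenerated with one extra neurite (up to +2) before failing.
    """
    preset = PRESETS[preset_name]
    config = config or ImagingConfig(frame_shape=frame_shape, channels=(organelle,))
    from .errors import TrackPlacementError

    last_exc: Exception | None = None
    for extra in range(3):
        geometry = make_geometry(config, n_neurites + extra, seed=seed)
        try:
            tracks = sample_tracks(
                geometry, preset, n_organelles, config, seed=seed + 7919, organelle=organelle
            )
        except TrackPlacementError as exc:
            last_exc = exc
            continue
        po = tracks if organelle == "PO" else None
        mito = tracks if organelle == "MITO" else None
        stack, truth = render_timelapse(geometry, po, mito, config, seed=seed + 104729)
        truth.meta["preset"] = preset_name
        return stack, truth
    raise last_exc  # type: ignore[misc]


def match_tracks(measured, truth_tracks, pixel_size: float, max_dist: float = 0.5):
    """Match measured tracks to planted tracks by mean distance on shared frames.

    Returns ``{measured_track_id: truth_track_id}`` for matches whose mean
    centroid distance is below ``max_dist`` um.
    """
    out = {}
    truth_xy = {
        t.track_id: np.stack([t.px[:, 1], t.px[:, 0]], axis=1) * pixel_size
        for t in truth_tracks
    }
    for m in measured:
        best = (np.inf, None)
        for t in truth_tracks:
            xy = truth_xy[t.track_id][m.frames]
            d = float(np.mean(np.linalg.norm(xy - m.xy_um, axis=1)))
            if d < best[0]:
                best = (d, t.track_id)
        if best[0] <= max_dist:
            out[m.track_id] = best[1]
    return out


def run_cohort(
    preset_name: str,
    organelle: str,
    n_neurons: int,
    seeds: list[int],
    config: RunConfig | None = None,
    n_organelles: int = COHORT_ORGANELLES,
):
    """Simulate ``n_neurons`` neurons and push them through the full pipeline.

    Returns a dict with measured per-track summaries, the truth-matched
    planted classes, and cohort fractions over tracks spanning at least
    ``min_track_fraction`` of the session.
    """
    config = config or RunConfig()
    all_summaries = []
    matched_truth = []          # (summary, truth_track) pairs
    n_planted = 0
    for k in range(n_neurons):
        stack, truth = simulate_timelapse_neuron(
            preset_name, seed=seeds[k], organelle=organelle, n_organelles=n_organelles
        )
        _, _, tracks, _ = analyze_timelapse(stack, config)
        trs = tracks[organelle]
        n_planted += len(truth.tracks)
        min_len = config.motility.min_track_fraction * stack.config.n_frames
        keep = [
            (
                tr,
                track_statistics(
                    tr, stack.config.frame_interval, config.motility.displacement_floor
                ),
            )
            for tr in trs
            if len(tr) >= min_len
        ]
        mapping = match_tracks([tr for tr, _ in keep], truth.tracks, stack.config.pixel_size)
        truth_by_id = {t.track_id: t for t in truth.tracks}
        for tr, s in keep:
            all_summaries.append(s)
            tid = mapping.get(tr.track_id)
            matched_truth.append(truth_by_id[tid] if tid is not None else None)
    cohort = cohort_summary(all_summaries)
    return {
        "preset": preset_name,
        "summaries": all_summaries,
        "matched_truth": matched_truth,
        "cohort": cohort,
        "n_planted": n_planted,
    }


# ---------------------------------------------------------------------------
# fixed-cell / contact analysis


def morphology_masks(cyto_frame: np.ndarray, config: RunConfig | None = None) -> SegmentationMasks:
    """Fixed-cell masks: Otsu + largest component morphology, DoG soma."""
    from scipy import ndimage as ndi

    config = config or RunConfig()
    image = np.asarray(cyto_frame, dtype=np.float64)
    thr = otsu_threshold(image.ravel())
    binary = ndi.binary_fill_holes(image > thr.threshold)
    labels, n = ndi.label(binary, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        raise FixtureIOError("cytosol channel segmented to nothing")
    counts = np.bincount(labels.ravel())[1:]
    morphology = labels == (int(np.argmax(counts)) + 1)
    soma = detect_soma(image, _dog_params(config)) & morphology
    return finalize_masks(morphology, soma, margin_px=config.soma.soma_margin_px)


def analyze_fixed(stack: ImageStack, config: RunConfig | None = None):
    """Distribution pipeline on a fixed-cell fixture (PO + CYTO channels)."""
    config = config or RunConfig()
    masks = morphology_masks(stack.channel("CYTO")[0], config)
    partition = proximal_region(
        masks, stack.config.pixel_size, config.distribution.proximal_length
    )
    # per-compartment Otsu: thresholds are computed within the outlined soma
    # and proximal neurite areas separately (matching the fixed-cell workflow)
    params = DetectionParams(
        sigma=config.detection.sigma_fixed, min_size=config.detection.min_size
    )
    regions = []
    for compartment in (partition.soma_region, partition.proximal_region):
        if compartment.any():
            regs, _ = detect_regions(
                stack.channel("PO")[0], compartment, params, stack.config.pixel_size
            )
            regions.extend(regs)
    summary = distribution_summary(regions, partition, stack.config.pixel_size)
    return masks, partition, regions, summary


def measure_contacts(stack: ImageStack, config: RunConfig | None = None):
    """Contact pipeline on the first frame of a two-channel stack."""
    config = config or RunConfig()
    masks = segment_stack(stack, config)
    ps = stack.config.pixel_size
    po_regions, _ = detect_regions(
        stack.channel("PO")[0],
        masks.neurite_mask,
        DetectionParams(sigma=config.detection.sigma_po, min_size=config.detection.min_size),
        ps,
        keep_coords=True,
    )
    from scipy import ndimage as ndi

    mito_frame = ndi.gaussian_filter(
        stack.channel("MITO")[0].astype(np.float32), config.detection.sigma_mito
    )
    thr = otsu_threshold(mito_frame[masks.neurite_mask])
    mito_mask = (mito_frame > thr.threshold) & masks.neurite_mask
    return contact_fraction(
        po_regions, mito_mask, masks.neurite_mask, config.distribution.contact_dilation_px
    )


# ---------------------------------------------------------------------------
# run commands with manifests


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(out: Path, extra: dict | None = None) -> Path:
    manifest = {
        "artifacts": {
            p.name: _sha256(p) for p in sorted(out.iterdir()) if p.is_file() and p.name != "manifest.json"
        },
    }
    if extra:
        manifest.update(extra)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out / "manifest.json"


def run_motility(config: RunConfig) -> Path:
    """Motility command: fixture dir in, masks/detections/tracks/summaries out."""
    if not config.input_dir:
        raise FixtureIOError("run_motility needs input_dir")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stack, truth = read_fixture(config.input_dir)
    for required in stack.config.channels:
        if required not in stack.channels:
            raise FixtureIOError(f"missing channel {required!r} in {config.input_dir}")
    log.info("run_motility: config=%s", config.model_dump())
    masks, detections, tracks, summaries = analyze_timelapse(stack, config)
    tifffile.imwrite(out / "soma_mask.tif", (masks.soma_mask * np.uint8(255)))
    tifffile.imwrite(out / "neurite_mask.tif", (masks.neurite_mask * np.uint8(255)))
    regions_to_frame(detections).to_csv(out / "detections.csv", index=False)
    rows = []
    for ch, trs in tracks.items():
        for tr in trs:
            for f, xy in zip(tr.frames, tr.xy_um):
                rows.append(
                    {"track_id": tr.track_id, "organelle": ch, "frame": int(f),
                     "x_um": xy[0], "y_um": xy[1]}
                )
    pd.DataFrame(rows, columns=["track_id", "organelle", "frame", "x_um", "y_um"]).to_csv(
        out / "tracks.csv", index=False
    )
    summary_rows = []
    cohorts = {}
    from .errors import TrackOutsideMaskError

    try:
        dmap = soma_distance_map(masks, stack.config.pixel_size)
    except ValueError:
        dmap = None
    for ch, sums in summaries.items():
        by_id = {tr.track_id: tr for tr in tracks[ch]}
        for s in sums:
            signed = float("nan")
            if dmap is not None:
                try:
                    signed = directionality(
                        by_id[s.track_id], masks, stack.config.pixel_size, dmap
                    )
                except TrackOutsideMaskError:
                    pass
            summary_rows.append(
                {
                    "organelle": ch,
                    "track_id": s.track_id,
                    "max_speed": s.max_speed,
                    "avg_speed": s.avg_speed,
                    "total_distance": s.total_distance,
                    "net_distance": s.net_distance,
                    "motility_class": s.motility_class,
                    "signed_net_along_path": signed,
                }
            )
        if sums:
            c = cohort_summary(sums)
            cohorts[ch] = {
                "n_tracks": c.n_tracks,
                "class_fractions": c.class_fractions,
                "mean_avg_speed": c.mean_avg_speed,
                "mean_max_speed": c.mean_max_speed,
                "mean_total_distance": c.mean_total_distance,
            }
    pd.DataFrame(
        summary_rows,
        columns=["organelle", "track_id", "max_speed", "avg_speed", "total_distance",
                 "net_distance", "motility_class", "signed_net_along_path"],
    ).to_csv(out / "track_summaries.csv", index=False)
    (out / "cohort.json").write_text(json.dumps(cohorts, indent=1))
    (out / "soma.json").write_text(json.dumps({"soma_centroid": list(masks.soma_centroid)}))
    # kymographs along planted neurite paths when ground truth is available
    if truth is not None and truth.geometry is not None:
        for i, _ in enumerate(truth.geometry.neurite_paths):
            try:
                kymo = make_kymograph(
                    next(iter(stack.channels.values())),
                    truth.geometry.neurite_paths[i],
                    width=5,
                )
            except Exception:  # path may graze the frame edge
                continue
            tifffile.imwrite(out / f"kymograph_{i}.tif", kymo.data.astype(np.float32))
    _write_manifest(out, {"config": config.model_dump(mode="json")})
    return out


def run_distribution(config: RunConfig) -> Path:
    """Distribution command: one or two groups of fixed-cell fixture dirs."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    groups = {"a": config.group_a or ([] if config.group_a is not None else None),
              "b": config.group_b}
    if config.group_a is None and config.input_dir:
        groups["a"] = [config.input_dir]
    if not groups["a"]:
        raise FixtureIOError("run_distribution needs group_a (or input_dir)")
    rows = []
    per_group: dict[str, list] = {"a": [], "b": []}
    for gname in ("a", "b"):
        dirs = groups[gname]
        if not dirs:
            continue
        for d in dirs:
            stack, _ = read_fixture(d)
            _, partition, regions, summary = analyze_fixed(stack, config)
            per_group[gname].append(summary)
            rows.append(
                {
                    "group": gname,
                    "input": str(d),
                    "soma_count": summary.soma_count,
                    "neurite_count": summary.neurite_count,
                    "soma_area_um2": summary.soma_area_um2,
                    "neurite_area_um2": summary.neurite_area_um2,
                    "soma_percent_area": summary.soma_percent_area,
                    "neurite_percent_area": summary.neurite_percent_area,
                }
            )
    pd.DataFrame(rows).to_csv(out / "distribution.csv", index=False)
    report: dict = {}
    if per_group["b"] and len(per_group["a"]) >= 2 and len(per_group["b"]) >= 2:
        for metric in ("soma_count", "soma_area_um2", "neurite_count", "neurite_area_um2"):
            a = [getattr(s, metric) for s in per_group["a"]]
            b = [getattr(s, metric) for s in per_group["b"]]
            direction = "greater" if metric.startswith("neurite") else "less"
            res = compare_groups(a, b, direction)
            report[metric] = {"t": res.t, "df": res.df, "p": res.p, "stars": res.stars}
    else:
        report["notice"] = "comparison skipped: need two groups with n >= 2 each"
    (out / "comparison.json").write_text(json.dumps(report, indent=1))
    _write_manifest(out, {"config": config.model_dump(mode="json")})
    return out


# ---------------------------------------------------------------------------
# simulation entry points used by the CLI


def simulate_to_dir(
    mode: str, preset: str, seed: int, out_dir: str | Path, n_neurons: int = 1
) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if mode == "timelapse":
        organelle = "MITO" if "MITO" in preset else "PO"
        for k in range(n_neurons):
            stack, truth = simulate_timelapse_neuron(preset, seed=seed + k, organelle=organelle)
            write_fixture(stack, truth, out / f"neuron_{k:02d}" if n_neurons > 1 else out)
    elif mode == "fixed":
        config = ImagingConfig(frame_shape=(1024, 1024), channels=("PO", "CYTO"))
        for k in range(n_neurons):
            spec = fixed_spec_from_preset(preset, config, seed=seed + k)
            stack, truth = render_fixed_neuron(spec, config, seed=seed + k)
            write_fixture(stack, truth, out / f"neuron_{k:02d}" if n_neurons > 1 else out)
    elif mode == "contacts":
        config = ImagingConfig(frame_shape=(1024, 1024), channels=("PO", "MITO"))
        stack, truth = make_contact_fixture(
            config, preset=CONTACT_PRESETS[preset], seed=seed
        )
        write_fixture(stack, truth, out)
    else:
        raise ValueError(f"unknown simulate mode {mode!r}")
    return out
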