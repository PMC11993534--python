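"""Batch orchestration: one feature-table row per image, CSV + manifest out.

Per-image analysis is fault-isolated by feature group: if, say, the
vessel channel is missing or degenerate, the vessel and selective columns
of that row are null with a reason recorded in the matching ``*_error``
column while the nuclear block is still produced.  A run fails as a whole
only if every image fails.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .config import AnalysisConfig
from .errors import CardioQuantError, InputError
from .image_io import MultichannelImage, load_image
from .morphometry import measure_nuclei, summarize_morphometry
from .orientation import rotation_histogram, summarize_orientation
from .segmentation import segment_matrix, segment_nuclei, segment_vessels
from .texture import extracellular_texture, nuclear_texture, wga_thickness
from .vessels import select_cardiomyocyte_nuclei, selective_summaries, vessel_metrics

logger = logging.getLogger(__name__)

#: fixed column order: identical across rows regardless of which groups ran
COLUMNS = [
    "image_id",
    # nuclear morphometry
    "n_nuclei",
    "selected_sensitivity",
    "mean_nuclear_size",
    "sd_nuclear_size",
    "relative_sd_nuclear_size",
    "mean_eccentricity",
    "median_dapi_intensity",
    # nuclear orientation
    "orientation_hist_mean",
    "orientation_hist_sd",
    "orientation_hist_kurtosis",
    "orientation_hist_skewness",
    "oop",
    "mu0_deg",
    "ocp",
    "n_ocp_pairs",
    "nuclear_rotation_stat",
    "nuclear_rotation_sd",
    "nuclear_rotation_kurtosis",
    "nuclear_rotation_skewness",
    # nuclear texture
    "nuclear_contrast",
    "nuclear_correlation",
    "nuclear_energy",
    "nuclear_homogeneity",
    "nuclear_entropy",
    # extracellular
    "extracellular_rotation_stat",
    "extracellular_rotation_sd",
    "extracellular_rotation_kurtosis",
    "extracellular_rotation_skewness",
    "extracellular_contrast",
    "extracellular_correlation",
    "extracellular_energy",
    "extracellular_homogeneity",
    "extracellular_entropy",
    "wga_mean_thickness",
    "wga_median_thickness",
    "wga_max_thickness",
    # vessels
    "n_vessels",
    "total_vessel_area",
    "median_vessel_size",
    "mean_vessel_size",
    "sd_vessel_size",
    "relative_sd_vessel_size",
    # cardiomyocyte-selective
    "n_cardiomyocyte_nuclei",
    "n_excluded_nuclei",
    "selective_mean_nuclear_size",
    "selective_relative_sd_nuclear_size",
    "selective_mean_eccentricity",
    "selective_oop",
    "selective_ocp",
    "selective_nuclear_contrast",
    "selective_nuclear_correlation",
    "selective_nuclear_energy",
    "selective_nuclear_homogeneity",
    "selective_nuclear_entropy",
    # per-group failure reasons (null = group succeeded)
    "nuclear_error",
    "extracellular_error",
    "vessel_error",
    "selective_error",
]


def analyze_image(
    img: MultichannelImage, config: AnalysisConfig, image_id: str = "image"
) -> dict:
    """Compute one feature-table row; failures are captured per group."""
    row: dict = {c: None for c in COLUMNS}
    row["image_id"] = image_id

    labels = None
    features = None
    try:
        labels, sweep = segment_nuclei(
            img,
            clahe_clip=config.clahe_clip,
            clahe_grid=config.clahe_grid,
            sigma=config.gaussian_sigma,
            window=config.threshold_window,
            sweep=config.sweep(),
            min_area=config.min_area,
            exclude_border=not config.keep_border,
        )
        row["selected_sensitivity"] = sweep.selected_sensitivity
        row["n_nuclei"] = labels.n_objects
        features = measure_nuclei(labels, img.require("nuclear"))
        morph = summarize_morphometry(features)
        row.update(
            mean_nuclear_size=morph.mean_area,
            sd_nuclear_size=morph.sd_area,
            relative_sd_nuclear_size=morph.relative_sd_area,
            mean_eccentricity=morph.mean_eccentricity,
            median_dapi_intensity=morph.median_intensity,
        )
        orient = summarize_orientation(
            features,
            config.ocp_direction_deg,
            config.ocp_cone_half_angle_deg,
            config.ocp_max_distance,
        )
        row.update(
            orientation_hist_mean=orient.hist_mean,
            orientation_hist_sd=orient.hist_sd,
            orientation_hist_kurtosis=orient.hist_kurtosis,
            orientation_hist_skewness=orient.hist_skewness,
            oop=orient.f2d,
            mu0_deg=orient.mu0_deg,
            ocp=orient.ocp,
            n_ocp_pairs=orient.n_ocp_pairs,
        )
        rot = rotation_histogram(labels.mask)
        row.update(
            nuclear_rotation_stat=rot.rotation_stat,
            nuclear_rotation_sd=rot.sd,
            nuclear_rotation_kurtosis=rot.kurtosis,
            nuclear_rotation_skewness=rot.skewness,
        )
        tex = nuclear_texture(img, labels, n_levels=config.glcm_levels)
        row.update(
            nuclear_contrast=tex.contrast,
            nuclear_correlation=tex.correlation,
            nuclear_energy=tex.energy,
            nuclear_homogeneity=tex.homogeneity,
            nuclear_entropy=tex.entropy,
        )
    except CardioQuantError as exc:
        row["nuclear_error"] = f"{type(exc).__name__}: {exc}"

    if img.matrix is not None:
        try:
            wga = segment_matrix(
                img, window=config.threshold_window, sensitivity=config.matrix_sensitivity
            )
            rot = rotation_histogram(wga)
            row.update(
                extracellular_rotation_stat=rot.rotation_stat,
                extracellular_rotation_sd=rot.sd,
                extracellular_rotation_kurtosis=rot.kurtosis,
                extracellular_rotation_skewness=rot.skewness,
            )
            tex = extracellular_texture(img, wga, n_levels=config.glcm_levels)
            row.update(
                extracellular_contrast=tex.contrast,
                extracellular_correlation=tex.correlation,
                extracellular_energy=tex.energy,
                extracellular_homogeneity=tex.homogeneity,
                extracellular_entropy=tex.entropy,
            )
            thick = wga_thickness(wga)
            row.update(
                wga_mean_thickness=thick.mean_thickness,
                wga_median_thickness=thick.median_thickness,
                wga_max_thickness=thick.max_thickness,
            )
        except CardioQuantError as exc:
            row["extracellular_error"] = f"{type(exc).__name__}: {exc}"
    else:
        row["extracellular_error"] = "missing-channel"

    vessel_map = None
    if img.vessel is not None:
        try:
            vessel_map = segment_vessels(img, min_area=config.vessel_min_area)
            vm = vessel_metrics(vessel_map)
            row.update(
                n_vessels=vm.n_vessels,
                total_vessel_area=vm.total_area,
                median_vessel_size=vm.median_size,
                mean_vessel_size=vm.mean_size,
                sd_vessel_size=vm.sd_size,
                relative_sd_vessel_size=vm.relative_sd_size,
            )
        except CardioQuantError as exc:
            row["vessel_error"] = f"{type(exc).__name__}: {exc}"
    else:
        row["vessel_error"] = "missing-channel"

    if not config.selective:
        row["selective_error"] = "disabled"
    elif vessel_map is None or labels is None or features is None:
        row["selective_error"] = "missing-channel" if img.vessel is None else "upstream-failure"
    else:
        try:
            selection = select_cardiomyocyte_nuclei(
                features, vessel_map.mask, config.proximity_threshold
            )
            sel = selective_summaries(
                selection,
                features,
                img,
                labels,
                n_levels=config.glcm_levels,
                ocp_direction_deg=config.ocp_direction_deg,
                ocp_cone_half_angle_deg=config.ocp_cone_half_angle_deg,
                ocp_max_distance=config.ocp_max_distance,
            )
            row.update(
                n_cardiomyocyte_nuclei=len(selection.kept_labels),
                n_excluded_nuclei=len(selection.excluded_labels),
                selective_mean_nuclear_size=sel.morphometry.mean_area,
                selective_relative_sd_nuclear_size=sel.morphometry.relative_sd_area,
                selective_mean_eccentricity=sel.morphometry.mean_eccentricity,
                selective_oop=sel.orientation.f2d,
                selective_ocp=sel.orientation.ocp,
                selective_nuclear_contrast=sel.texture.contrast,
                selective_nuclear_correlation=sel.texture.correlation,
                selective_nuclear_energy=sel.texture.energy,
                selective_nuclear_homogeneity=sel.texture.homogeneity,
                selective_nuclear_entropy=sel.texture.entropy,
            )
        except CardioQuantError as exc:
            row["selective_error"] = f"{type(exc).__name__}: {exc}"

    return row


def run_batch(
    input_dir: str | Path,
    config: AnalysisConfig,
    out_dir: str | Path,
) -> pd.DataFrame:
    """Analyze every TIFF in *input_dir* (lexicographic order).

    Writes ``features.csv``, ``run_manifest.json``, and the effective
    ``config.yaml`` into *out_dir* and returns the feature table.
    """
    input_dir = Path(input_dir)
    out_dir = Path(out_dir)
    tiffs = sorted(p for p in input_dir.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
    if not tiffs:
        raise InputError(f"no TIFF files in {input_dir}")
    out_dir.mkdir(parents=True, exist_ok=True)

    rows, statuses = [], {}
    for path in tiffs:
        try:
            img = load_image(path, config.channel_map)
        except CardioQuantError as exc:
            logger.error("failed to load %s: %s", path.name, exc)
            statuses[path.name] = f"failed: {exc}"
            continue
        row = analyze_image(img, config, image_id=path.stem)
        rows.append(row)
        statuses[path.name] = "ok" if row["nuclear_error"] is None else "partial"

    table = pd.DataFrame(rows, columns=COLUMNS)
    table.to_csv(out_dir / "features.csv", index=False)
    config.save(out_dir / "config.yaml")
    manifest = {
        "version": __version__,
        "config_digest": config.digest(),
        "n_images": len(tiffs),
        "images": statuses,
    }
    (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    if not rows:
        raise InputError("all images failed to load")
    return table


__all__ = ["COLUMNS", "analyze_image", "run_batch"]
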