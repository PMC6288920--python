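"""End-to-end orchestration: simulate, quantify, analyse repeatability.

Inputs are discovered through a metadata CSV (``subject_id, eye,
scan_type, segment, scan_index, path[, ssi]``; paths relative to the CSV)
rather than filename parsing. Every run writes a JSON manifest holding the
resolved config snapshot, input checksums, seeds, software version and
per-stage counts, so each output row is traceable.
"""

from __future__ import annotations

import datetime
import logging
from pathlib import Path
from typing import Any, Dict, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .config import load_config
from .density import density_table
from .io import read_annotations, read_image, sha256_file, write_image, write_json, write_mask
from .preprocess import (MACULA_SEGMENTS, EnFaceImage, count_white_lines,
                         gaussian_bandpass, qc_evaluate)
from .regions import build_region_set
from .repeatability import repeatability_report
from .scird import ScirdBank, binarize_vessels, scird_response
from .synthetic import (PairedScanConfig, PhantomConfig, add_motion_artifacts,
                        generate_paired_scans, generate_vessel_network)

logger = logging.getLogger(__name__)

__all__ = ["run_simulate", "run_density", "run_repeatability"]

QC_COLUMNS = ["subject_id", "eye", "scan_type", "segment", "scan_index",
              "white_lines", "ssi", "discarded", "reason"]


def _manifest(config: Dict[str, Any], seed: Optional[int],
              inputs: list[dict], counts: Dict[str, int]) -> Dict[str, Any]:
    return {
        "software_version": __version__,
        "timestamp": datetime.datetime.now().isoformat(),
        "seed": seed,
        "config": config,
        "inputs": inputs,
        "counts": counts,
    }


def process_image(pixels: np.ndarray, bank: ScirdBank,
                  config: Dict[str, Any]) -> Tuple[np.ndarray, np.ndarray]:
    """Bandpass-filter one segment image and detect its vessel map.

    Returns ``(filtered, vessel_map)``.
    """
    filtered = gaussian_bandpass(
        pixels,
        sigma_low=float(config["bandpass.sigma_low"]),
        sigma_high=float(config["bandpass.sigma_high"]),
        stripe_notch=bool(config["bandpass.stripe_notch"]),
        boundary=str(config["bandpass.boundary"]),
    )
    response = scird_response(filtered, bank,
                              scale_norm=str(config["scird.scale_norm"]))
    vessel_map = binarize_vessels(response,
                                  method=str(config["scird.threshold_method"]),
                                  param=float(config["scird.threshold_param"]))
    return filtered, vessel_map


def run_density(metadata_csv: str | Path, out_dir: str | Path,
                annotations_csv: Optional[str | Path] = None,
                config: Optional[Dict[str, Any]] = None,
                ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify vessel density for every image listed in a metadata CSV.

    Each segment image is QC-gated (white lines, SSI), de-striped,
    ridge-filtered and thresholded; densities are computed over the whole
    segment and the four quadrants. Writes ``density.csv``, ``qc.csv`` and
    ``manifest.json`` into ``out_dir`` and returns the two tables.
    Per-file failures are collected; the run fails only if no file
    succeeds.
    """
    config = config or load_config()
    metadata_csv = Path(metadata_csv)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = pd.read_csv(metadata_csv)
    if meta.empty:
        raise ValueError("no input images listed in metadata")
    required = {"subject_id", "eye", "scan_type", "segment", "scan_index", "path"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    annotations = read_annotations(annotations_csv) if annotations_csv else {}

    bank = ScirdBank.from_config(config)
    qc_rows: list[dict] = []
    density_frames: list[pd.DataFrame] = []
    errors: list[str] = []
    inputs: list[dict] = []
    n_discarded = 0

    group_cols = ["subject_id", "eye", "scan_type", "scan_index"]
    for (subject, eye, scan_type, scan_index), group in meta.groupby(group_cols, sort=True):
        vessel_maps: Dict[str, np.ndarray] = {}
        region_sets: Dict[str, Any] = {}
        for _, row in group.iterrows():
            segment = str(row["segment"])
            path = metadata_csv.parent / str(row["path"])
            ssi = float(row["ssi"]) if "ssi" in row and pd.notna(row.get("ssi")) else None
            try:
                pixels = read_image(path)
                image = EnFaceImage(pixels=pixels, scan_type=str(scan_type),
                                    segment_label=segment, laterality=str(eye),
                                    subject_id=str(subject),
                                    scan_index=int(scan_index),
                                    signal_strength_index=ssi)
                inputs.append({"path": str(row["path"]), "sha256": sha256_file(path)})
                lines = count_white_lines(pixels,
                                          z_thresh=float(config["qc.z_thresh"]),
                                          max_row_cv=float(config["qc.max_row_cv"]))
                qc = qc_evaluate(image, lines, ssi_min=float(config["qc.ssi_min"]))
                reason = ("high_motion" if qc.high_motion else
                          "low_ssi" if not qc.ssi_pass else "")
                qc_rows.append(dict(subject_id=subject, eye=eye,
                                    scan_type=scan_type, segment=segment,
                                    scan_index=scan_index,
                                    white_lines=qc.white_line_count, ssi=ssi,
                                    discarded=qc.discarded, reason=reason))
                if qc.discarded:
                    n_discarded += 1
                    continue
                annotation = annotations.get((str(subject), str(eye)))
                if scan_type == "disc" and annotation is None:
                    raise ValueError(
                        f"disc scan {subject}/{eye} has no disc annotation")
                if scan_type == "macula":
                    annotation = None
                _, vessel_map = process_image(pixels, bank, config)
                region_sets[segment] = build_region_set(
                    image, annotation,
                    disc_interior=str(config["region.disc_interior"]),
                    od_nasal_side=str(config["region.od_nasal_side"]))
                vessel_maps[segment] = vessel_map
            except (OSError, ValueError) as exc:
                errors.append(f"{path}: {exc}")
                logger.error("failed to process %s: %s", path, exc)
        if vessel_maps:
            density_frames.append(density_table(vessel_maps, region_sets,
                                                subject_id=str(subject),
                                                eye=str(eye),
                                                scan_type=str(scan_type),
                                                scan_index=int(scan_index)))

    if not density_frames and not qc_rows:
        raise RuntimeError("no input image could be processed: "
                           + "; ".join(errors[:5]))
    density = (pd.concat(density_frames, ignore_index=True)
               if density_frames else pd.DataFrame())
    qc_df = pd.DataFrame(qc_rows, columns=QC_COLUMNS)
    density.to_csv(out_dir / "density.csv", index=False)
    qc_df.to_csv(out_dir / "qc.csv", index=False)
    write_json(out_dir / "manifest.json", _manifest(
        config, None, inputs,
        {"images_in": len(meta), "images_discarded": n_discarded,
         "images_failed": len(errors), "density_records": len(density)}))
    logger.info("density run: %d images in, %d discarded, %d failed, %d records",
                len(meta), n_discarded, len(errors), len(density))
    return density, qc_df


def run_repeatability(density_csv: str | Path, out_dir: str | Path,
                      config: Optional[Dict[str, Any]] = None) -> pd.DataFrame:
    """Pair scan 1 / scan 2 densities and emit the repeatability report."""
    config = config or load_config()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    density = pd.read_csv(density_csv)
    present = set(density["scan_index"].unique())
    for needed in (1, 2):
        if needed not in present:
            raise ValueError(f"density table has no scan_index {needed} rows")

    keys = ["subject_id", "eye", "scan_type", "segment_label", "region"]
    wide = density.pivot_table(index=keys, columns="scan_index",
                               values="density", aggfunc="first").reset_index()
    pairs = wide.rename(columns={1: "value_1", 2: "value_2"})
    report = repeatability_report(pairs,
                                  ci_method=str(config["repeatability.ci_method"]))
    report.to_csv(out_dir / "repeatability.csv", index=False)
    write_json(out_dir / "repeatability_manifest.json", _manifest(
        config, None, [{"path": str(density_csv),
                        "sha256": sha256_file(density_csv)}],
        {"pair_rows": len(pairs), "report_rows": len(report)}))
    return report


def run_simulate(out_dir: str | Path, seed: int = 0,
                 config: Optional[Dict[str, Any]] = None) -> Dict[str, Any]:
    """Write a self-contained synthetic dataset exercising every stage.

    Produces phantom segment images (two scans per subject sharing the
    vessel network, with independent noise) plus truth masks, a metadata
    CSV consumable by :func:`run_density`, a paired-density CSV at the
    study's scale consumable by :func:`run_repeatability`, and a manifest.
    """
    config = config or load_config()
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(seed)
    meta_rows = []
    n_images = 0
    for s in range(int(config["simulate.n_image_subjects"])):
        subject = f"SIM{s + 1:03d}"
        for segment in MACULA_SEGMENTS:
            net_seed = int(rng.integers(2**31))
            base_cfg = PhantomConfig(
                grid_size=int(config["simulate.grid_size"]),
                n_vessels=int(config["simulate.n_vessels"]),
                width_range=(float(config["simulate.width_min"]),
                             float(config["simulate.width_max"])),
                curvature_range=(float(config["simulate.curvature_min"]),
                                 float(config["simulate.curvature_max"])),
                vessel_intensity=float(config["simulate.vessel_intensity"]),
                background_noise_sd=0.0,
                seed=net_seed)
            clean, mask = generate_vessel_network(base_cfg)
            mask_name = f"{subject}_OD_macula_{segment}_truth.png"
            write_mask(out_dir / "masks" / mask_name, mask)
            for scan_index in (1, 2):
                noisy = clean + rng.normal(
                    0.0, float(config["simulate.background_noise_sd"]),
                    size=clean.shape)
                np.clip(noisy, 0.0, None, out=noisy)
                n_lines = int(config["simulate.n_artifact_lines"])
                if n_lines:
                    noisy = add_motion_artifacts(noisy, n_lines,
                                                 seed=int(rng.integers(2**31)))
                name = f"{subject}_OD_macula_{segment}_scan{scan_index}.png"
                write_image(out_dir / "images" / name, noisy)
                meta_rows.append(dict(subject_id=subject, eye="OD",
                                      scan_type="macula", segment=segment,
                                      scan_index=scan_index,
                                      path=f"images/{name}", ssi=""))
                n_images += 1
    meta = pd.DataFrame(meta_rows)
    meta.to_csv(out_dir / "metadata.csv", index=False)

    paired_cfg = PairedScanConfig(
        n_subjects=int(config["simulate.n_subjects"]),
        true_density_mean=float(config["simulate.true_density_mean"]),
        between_subject_sd=float(config["simulate.between_subject_sd"]),
        within_subject_sd=float(config["simulate.within_subject_sd"]),
        seed=int(rng.integers(2**31)))
    paired = generate_paired_scans(paired_cfg)
    long_rows = []
    for _, row in paired.iterrows():
        for scan_index, col in ((1, "value_1"), (2, "value_2")):
            long_rows.append(dict(subject_id=row["subject_id"], eye="OD",
                                  scan_type="macula", segment_label="deep_retina",
                                  region="segment", scan_index=scan_index,
                                  density=row[col], vessel_pixels="",
                                  region_pixels=""))
    pd.DataFrame(long_rows).to_csv(out_dir / "paired_densities.csv", index=False)

    manifest = _manifest(config, seed, [],
                         {"phantom_images": n_images,
                          "paired_subjects": paired_cfg.n_subjects})
    write_json(out_dir / "manifest.json", manifest)
    logger.info("simulate: wrote %d phantom images and %d paired subjects to %s",
                n_images, paired_cfg.n_subjects, out_dir)
    return manifest
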