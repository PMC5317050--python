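"""End-to-end runs: calibrate, quantify, simulate, analyze, QC.

Each run writes a machine-readable log of every parameter and seed next to
its outputs, sufficient to reproduce the run exactly.  The quantification
run emits the three-artifact output bundle into a ``Results`` directory
sibling to the input image folder: a PDF montage of the elaboration stages,
a text file of per-image cell densities, and a text file of per-cell
fluorescence intensities.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import segmentation as seg
from . import stats as st
from .config import RunConfig
from .crf import (
    CRFModel,
    InverseLUT,
    VignettingField,
    build_vignetting_field,
    check_vignetting_needed,
    collect_intensity_pairs,
    fit_crf,
    invert_crf,
)
from .images import (
    METADATA_COLUMNS,
    RawImage,
    read_image,
    read_metadata_table,
    write_image,
    write_metadata_table,
)
from .preprocessing import apply_vignetting, linearize, subtract_background, to_gray
from .synthetic import (
    AcquisitionSpec,
    SceneSpec,
    generate_scene,
    render_slide_series,
    write_truth_table,
)

__all__ = [
    "run_calibrate",
    "run_quantify",
    "run_simulate",
    "run_analyze",
    "run_qc_photobleach",
    "run_qc_vignetting",
]

logger = logging.getLogger(__name__)


def _write_run_log(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")


# ---------------------------------------------------------------------------
# calibrate
# ---------------------------------------------------------------------------

def run_calibrate(
    config: RunConfig,
    flat_paths: list[str] | None = None,
    degree: int = 3,
    seed: int | None = None,
) -> dict:
    """Fit the CRF from an exposure-bracketed stack and write the
    correction artifacts.

    Reads every image listed in the metadata table under ``input_dir``,
    collects cross-exposure intensity pairs, fits the cubic CRF
    (Tikhonov-regularized, L-curve weight selection), inverts it with
    Cardano's formula into the 256-entry LUT and saves the LUT as a text
    file.  Optional flat-field images produce a vignetting report and,
    when correction is warranted, an additive vignetting field.
    """
    config.validate()
    input_dir = Path(config.input_dir)
    meta_path = Path(config.metadata_path) if config.metadata_path else input_dir / "metadata.tsv"
    if not meta_path.exists():
        raise FileNotFoundError(f"no calibration inputs: metadata table {meta_path} not found")
    meta = read_metadata_table(meta_path)
    stack = []
    for row in meta.itertuples():
        p = input_dir / row.filename
        if not p.exists():
            logger.warning("calibration image %s missing; skipped", p)
            continue
        stack.append(read_image(p, exposure_ms=float(row.exposure_ms)))
    if len(stack) < 2:
        raise FileNotFoundError("no calibration inputs: need >= 2 bracketed images")
    stack = [img.with_pixels(to_gray(img)) for img in stack]

    pairs = collect_intensity_pairs(stack, seed=config.seed if seed is None else seed)
    model = fit_crf(pairs, degree=degree)
    lut = invert_crf(model)

    out_dir = Path(config.output_dir) if config.output_dir else input_dir / "calibration"
    out_dir.mkdir(parents=True, exist_ok=True)
    lut_path = lut.save(out_dir / "lut.txt")

    report = {
        "n_images": len(stack),
        "n_pairs": len(pairs),
        "excluded_fraction": pairs.excluded_fraction,
        "crf_coefficients": model.coefficients.tolist(),
        "regularization_weight": model.regularization_weight,
        "fit_residual": model.fit_residual,
        "lut_path": str(lut_path),
        "seed": config.seed if seed is None else seed,
    }

    if flat_paths:
        flats = [read_image(p) for p in flat_paths]
        flats = [f.with_pixels(to_gray(f)) for f in flats]
        vig_report = check_vignetting_needed(
            flats, threshold=config.vignetting_nonuniformity_threshold
        )
        report["vignetting_nonuniformity"] = vig_report.nonuniformity
        report["vignetting_correction_recommended"] = vig_report.correction_recommended
        if vig_report.correction_recommended:
            field = build_vignetting_field(flats[0])
            field.save(out_dir / "vignetting.tif")
            report["vignetting_field_path"] = str(out_dir / "vignetting.tif")

    _write_run_log(out_dir / "calibration_log.json", report)
    return report


# ---------------------------------------------------------------------------
# quantify
# ---------------------------------------------------------------------------

def _montage_pdf(pages: list[dict], path: Path) -> None:
    """One page per image: raw → background-subtracted → edges → filled →
    labeled panels."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.backends.backend_pdf import PdfPages

    titles = ["raw", "background-subtracted", "edges", "filled", "labeled"]
    with PdfPages(path) as pdf:
        for page in pages:
            fig, axes = plt.subplots(1, 5, figsize=(16, 3.4))
            for ax, key, title in zip(axes, ("raw", "sub", "edges", "filled", "labels"), titles):
                arr = page[key]
                cmap = "nipy_spectral" if key == "labels" else "gray"
                ax.imshow(arr, cmap=cmap, interpolation="nearest")
                ax.set_title(title, fontsize=9)
                ax.axis("off")
            fig.suptitle(page["image_id"], fontsize=10)
            pdf.savefig(fig)
            plt.close(fig)


def run_quantify(config: RunConfig, montage: bool = True) -> dict:
    """Segment and quantify every image in the input folder.

    Per image: gray conversion, optional vignetting correction, grayscale
    opening background subtraction, LUT linearization (dividing by the
    exposure time), zero-crossing segmentation, per-cell mean irradiance
    and per-image density.  Images without a metadata row are skipped with
    a warning.  Outputs go to a ``Results`` directory sibling to the input
    image folder: ``montage.pdf``, ``cell_fluorescence.txt`` (one value
    per line, image-tagged), ``densities.txt``, ``run_log.json``.
    """
    config.validate()
    input_dir = Path(config.input_dir)
    meta_path = Path(config.metadata_path) if config.metadata_path else input_dir / "metadata.tsv"
    meta = read_metadata_table(meta_path)
    meta_by_file = {row.filename: row for row in meta.itertuples()}

    lut = InverseLUT.load(config.lut_path) if config.lut_path else InverseLUT.identity()
    vignetting = (
        VignettingField.load(config.vignetting_path) if config.vignetting_path else None
    )

    image_paths = sorted(
        p for p in input_dir.iterdir()
        if p.suffix.lower() in (".png", ".tif", ".tiff")
    )
    if not image_paths:
        raise FileNotFoundError(f"no images found in {input_dir}")

    gradient_threshold = (
        None if config.gradient_threshold < 0 else config.gradient_threshold
    )

    cell_rows: list[tuple[str, float]] = []
    density_rows: list[seg.DensityEstimate] = []
    per_image: list[dict] = []
    pages: list[dict] = []
    n_skipped = 0

    for p in image_paths:
        row = meta_by_file.get(p.name)
        if row is None:
            logger.warning("no metadata row for %s; image skipped", p.name)
            n_skipped += 1
            continue
        raw = read_image(
            p,
            exposure_ms=float(row.exposure_ms),
            slide_id=str(row.slide),
            acquisition_index=int(row.acquisition_index),
            sample=str(row.sample),
            is_calibrator=bool(row.is_calibrator),
            volume_uL=float(row.volume_uL),
        )
        gray = to_gray(raw)
        gray = apply_vignetting(gray, vignetting)
        sub = subtract_background(np.asarray(gray), se_radius_px=config.se_radius_px)
        irr = linearize(sub, lut, raw.exposure_ms, source_id=raw.image_id)

        edges = seg.detect_edges(
            irr.values,
            sigma_px=config.sigma_px,
            gradient_threshold=gradient_threshold,
            threshold_multiplier=config.threshold_multiplier,
        )
        mask = seg.edges_to_mask(edges, erosion_iterations=config.erosion_iterations)
        labeled = seg.label_cells(
            mask, min_area_px=config.min_area_px, max_area_px=config.max_area_px
        )
        records = seg.measure_cells(labeled, irr)
        density = seg.estimate_density(
            labeled, float(row.volume_uL), image_id=raw.image_id,
            fov_fraction=config.fov_fraction,
        )
        cell_rows += [(raw.image_id, r.mean_irradiance_per_ms) for r in records]
        density_rows.append(density)
        per_image.append(
            {
                "image_id": raw.image_id,
                "sample": raw.sample,
                "slide": raw.slide_id,
                "acquisition_index": raw.acquisition_index,
                "is_calibrator": raw.is_calibrator,
                "n_cells": labeled.n_cells,
                "mean_cell_irradiance": (
                    float(np.mean([r.mean_irradiance_per_ms for r in records]))
                    if records else float("nan")
                ),
                "saturated_fraction": irr.saturated_fraction,
            }
        )
        if montage:
            pages.append(
                {
                    "image_id": raw.image_id,
                    "raw": np.asarray(gray),
                    "sub": sub,
                    "edges": edges,
                    "filled": mask,
                    "labels": labeled.labels,
                }
            )

    if not per_image:
        raise ValueError("all images missing metadata; nothing processed")

    out_dir = Path(config.output_dir) if config.output_dir else input_dir.parent / "Results"
    out_dir.mkdir(parents=True, exist_ok=True)

    with open(out_dir / "cell_fluorescence.txt", "w") as fh:
        for image_id, value in cell_rows:
            fh.write(f"{image_id}\t{value:.8g}\n")
    with open(out_dir / "densities.txt", "w") as fh:
        for d in density_rows:
            fh.write(f"{d.image_id}\t{d.n_cells}\t{d.density:.6g}\n")
    if montage:
        _montage_pdf(pages, out_dir / "montage.pdf")

    log = {
        "config": config.to_dict(),
        "n_images_processed": len(per_image),
        "n_images_skipped": n_skipped,
        "n_cells_total": len(cell_rows),
        "per_image": per_image,
    }
    _write_run_log(out_dir / "run_log.json", log)
    return log


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

def run_simulate(
    out_dir: str | Path,
    scene: SceneSpec | None = None,
    acquisition: AcquisitionSpec | None = None,
    n_scenes: int = 1,
    images_per_scene: int = 1,
    interval_s: float = 8.0,
    sample: str = "sample",
    is_calibrator: bool = False,
    volume_uL: float = 3.0,
    seed: int = 0,
    image_format: str = "png",
) -> dict:
    """Render synthetic micrographs plus ground truth and a metadata table
    consumable by :func:`run_quantify` (closing the validation loop).

    Each scene becomes one slide whose ``images_per_scene`` frames carry
    cumulative excitation time ``k · interval_s``.
    """
    scene = scene if scene is not None else SceneSpec()
    acq = acquisition if acquisition is not None else AcquisitionSpec()
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)

    meta_rows = []
    for s in range(n_scenes):
        spec_s = replace(scene, seed=seed + 1000 * s)
        truth = generate_scene(spec_s)
        write_truth_table(truth, out_dir / f"truth_scene{s:03d}.tsv")
        slide = f"slide{s:03d}"
        series = render_slide_series(
            truth, acq, images_per_scene, interval_s, slide_id=slide,
            sample=sample, is_calibrator=is_calibrator, volume_uL=volume_uL,
        )
        for img in series:
            fname = f"{img.image_id}.{image_format}"
            write_image(img, img_dir / fname)
            meta_rows.append(
                {
                    "filename": fname,
                    "sample": sample,
                    "replicate": 1,
                    "slide": slide,
                    "acquisition_index": img.acquisition_index,
                    "exposure_ms": img.exposure_ms,
                    "volume_uL": volume_uL,
                    "is_calibrator": is_calibrator,
                }
            )
    meta = pd.DataFrame(meta_rows, columns=METADATA_COLUMNS)
    write_metadata_table(meta, img_dir / "metadata.tsv")

    log = {
        "scene": asdict(scene),
        "acquisition": {
            **{k: v for k, v in asdict(acq).items() if k != "crf"},
            "crf_coefficients": (
                acq.crf.coefficients.tolist() if acq.crf is not None else None
            ),
        },
        "n_scenes": n_scenes,
        "images_per_scene": images_per_scene,
        "interval_s": interval_s,
        "seed": seed,
    }
    _write_run_log(out_dir / "simulation_log.json", log)
    return log


# ---------------------------------------------------------------------------
# analyze
# ---------------------------------------------------------------------------

def read_cell_file(path: str | Path) -> pd.DataFrame:
    """Read a per-cell fluorescence text file (image-tagged values)."""
    return pd.read_csv(path, sep="\t", names=["image_id", "value"])


def run_analyze(
    cell_files: dict[str, str | Path],
    calibrator_sample: str | None = None,
    n_target: int | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Population statistics from per-cell fluorescence files.

    ``cell_files`` maps sample label → per-cell text file.  When a
    calibrator sample is named, every population (the calibrator included)
    is normalized by the calibrator's mean; when ``n_target`` is given,
    cardinalities are equalized by seeded subsampling first.  Returns (and
    optionally writes) the per-sample stats table: n, mean, sd, SE, CV².
    """
    samples = []
    for label, path in cell_files.items():
        df = read_cell_file(path)
        samples.append(
            st.SampleDistribution(
                sample_id=label,
                values=df["value"].to_numpy(),
                is_calibrator=(label == calibrator_sample),
            )
        )
    if n_target is not None:
        samples = st.equalize_cardinality(samples, n_target, seed=seed)
    if calibrator_sample is not None:
        cal = next(s for s in samples if s.sample_id == calibrator_sample)
        samples = [st.normalize_to_calibrator(s, cal) for s in samples]

    rows = []
    for s in samples:
        ps = st.population_stats(s)
        rows.append(
            {
                "sample": s.sample_id,
                "n": ps.n,
                "mean": ps.mean,
                "sd": ps.sd,
                "se": ps.se,
                "cv2": ps.cv2,
            }
        )
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "population_stats.tsv", sep="\t", index=False)
    return table


# ---------------------------------------------------------------------------
# qc
# ---------------------------------------------------------------------------

def run_qc_photobleach(
    results_dir: str | Path,
    threshold: float = 0.95,
) -> list[st.PhotobleachReport]:
    """Photobleaching QC from a quantification run's log: per slide,
    compare mean cell fluorescence of the first and last third of images
    (in acquisition order)."""
    log = json.loads((Path(results_dir) / "run_log.json").read_text())
    frame = pd.DataFrame(log["per_image"])
    reports = []
    for slide, grp in frame.groupby("slide"):
        grp = grp.sort_values("acquisition_index")
        means = grp["mean_cell_irradiance"].to_numpy()
        if len(means) < 3 or np.any(~np.isfinite(means)):
            logger.warning("slide %s: too few images or empty frames; skipped", slide)
            continue
        reports.append(
            st.assess_photobleaching(means, threshold=threshold, slide_id=str(slide))
        )
    return reports


def run_qc_vignetting(
    flat_paths: list[str | Path],
    exposures_ms: list[float] | None = None,
    threshold: float = 0.02,
):
    """Vignetting QC from flat-field images of a uniform emitter."""
    flats = []
    for i, p in enumerate(flat_paths):
        exp = exposures_ms[i] if exposures_ms else 1.0
        img = read_image(p, exposure_ms=exp)
        flats.append(img.with_pixels(to_gray(img)))
    return check_vignetting_needed(flats, threshold=threshold)
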