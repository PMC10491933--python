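"""End-to-end orchestration: simulate → reconstruct → segment → quantify →
profile → stats.

Every run writes a machine-readable manifest (``run_manifest.json``) listing
the resolved config, the stage outputs and their SHA-256 digests. Given the
same config and seed, reruns are bit-identical — all randomness flows
through seeded generators.

Reconstruction operates on the analysis plane (the widest lumen slice) of
each stack; full-stack reconstruction is a straightforward per-slice loop
but is not needed by any downstream metric.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from vesselqpi import breakprofile, morphometry, optics, phantom, segmentation, stats, tiffio
from vesselqpi.config import RunConfig

logger = logging.getLogger(__name__)

STAGES = ("simulate", "reconstruct", "segment", "quantify", "profile", "stats")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))


def run(config: RunConfig, force: bool = False) -> Path:
    """Execute the configured stages in order; returns the run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": json.loads(config.model_dump_json()),
        "outputs": {},
    }
    stage_fns = {
        "simulate": _stage_simulate,
        "reconstruct": _stage_reconstruct,
        "segment": _stage_segment,
        "quantify": _stage_quantify,
        "profile": _stage_profile,
        "stats": _stage_stats,
    }
    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        try:
            produced = stage_fns[stage](config, outdir, force)
        except Exception as exc:  # partial outputs retained on disk
            manifest["failed_stage"] = stage
            _write_json(outdir / "run_manifest.json", manifest)
            raise StageError(stage, exc) from exc
        manifest["outputs"][stage] = {
            p.name: _sha256(p) for p in sorted(produced)
        }
        logger.info(
            "stage=%s files=%d elapsed=%.2fs", stage, len(produced), time.perf_counter() - t0
        )
    _write_json(outdir / "run_manifest.json", manifest)
    return outdir


def _stage_simulate(config: RunConfig, outdir: Path, force: bool) -> list[Path]:
    if config.external_stacks is not None:
        logger.info("external stacks supplied; simulate skipped")
        return []
    if not config.groups:
        raise ValueError("no groups configured")
    phantom.generate_cohort(
        config.groups, config.optical, outdir, seed=config.seed, force=force
    )
    return sorted(outdir.glob("*.tif")) + [outdir / "manifest.csv"]


def _load_manifest(config: RunConfig, outdir: Path) -> tuple[pd.DataFrame, Path]:
    src = Path(config.external_stacks) if config.external_stacks else outdir
    path = src / "manifest.csv"
    if not path.exists():
        raise FileNotFoundError(f"no manifest at {path}; run simulate first")
    return pd.read_csv(path), src


def _analysis_slice_index(labels: np.ndarray) -> int:
    interior = [(sl == 1) | (sl == 3) for sl in labels]
    return segmentation.select_widest_slice(interior)


def _stage_reconstruct(config: RunConfig, outdir: Path, force: bool) -> list[Path]:
    manifest, src = _load_manifest(config, outdir)
    produced = []
    tfs_cache: dict[tuple[int, int], optics.TransferFunctionSet] = {}
    for _, row in manifest.iterrows():
        truth = tiffio.read_stack(src / row["stack_path"]).astype(np.float64)
        labels = tiffio.read_stack(src / row["label_path"])
        zc = _analysis_slice_index(labels)
        ri_slice = truth[zc]
        if ri_slice.shape not in tfs_cache:
            tfs_cache[ri_slice.shape] = optics.compute_transfer_functions(
                config.optical, ri_slice.shape
            )
        budget = row.get("noise_photon_budget", None)
        sidecar = (src / row["stack_path"]).with_suffix(".json")
        if sidecar.exists():
            budget = json.loads(sidecar.read_text())["spec"].get("noise_photon_budget")
        vessel_seed = int(row["seed"]) ^ config.seed
        recovered = optics.reconstruct_ri_slice(
            ri_slice,
            config.optical,
            photon_budget=budget,
            seed=vessel_seed,
            tfs=tfs_cache[ri_slice.shape],
        )
        out = outdir / f"{row['vessel_id']}_recovered.tif"
        tiffio.write_stack(out, recovered.astype(np.float32))
        meta = outdir / f"{row['vessel_id']}_recovered.json"
        _write_json(meta, {"slice_index": int(zc), "seed": vessel_seed})
        produced += [out, meta]
    return produced


def _stage_segment(config: RunConfig, outdir: Path, force: bool) -> list[Path]:
    manifest, src = _load_manifest(config, outdir)
    produced = []
    for _, row in manifest.iterrows():
        meta = json.loads((outdir / f"{row['vessel_id']}_recovered.json").read_text())
        zc = meta["slice_index"]
        recovered = tiffio.read_stack(outdir / f"{row['vessel_id']}_recovered.tif")[0]
        if config.mask_source == "ground-truth":
            labels = tiffio.read_stack(src / row["label_path"])
            masks = segmentation.masks_from_labels(
                labels, zc, config.optical.pixel_size
            )
        else:
            masks = segmentation.load_masks(
                Path(config.mask_source) / f"{row['vessel_id']}_masks.tif",
                config.optical.pixel_size,
            )
        cells = segmentation.segment_cells(
            recovered,
            masks.interior_mask,
            canny_sigma=config.canny_sigma,
            canny_low=config.canny_low,
            canny_high=config.canny_high,
            closing_radius=config.closing_radius,
            min_size_px=config.min_cell_px,
        )
        out = segmentation.VesselMaskSet(
            interior_mask=masks.interior_mask,
            wall_mask=masks.wall_mask,
            cell_mask=cells,
            slice_index=zc,
            pixel_size=config.optical.pixel_size,
        )
        path = outdir / f"{row['vessel_id']}_masks.tif"
        segmentation.save_masks(out, path)
        produced.append(path)
    return produced


def _stage_quantify(config: RunConfig, outdir: Path, force: bool) -> list[Path]:
    manifest, src = _load_manifest(config, outdir)
    rows = []
    samples: dict[str, list[float]] = {}
    for _, row in manifest.iterrows():
        recovered = tiffio.read_stack(outdir / f"{row['vessel_id']}_recovered.tif")[0]
        meta = json.loads((outdir / f"{row['vessel_id']}_recovered.json").read_text())
        masks = segmentation.load_masks(
            outdir / f"{row['vessel_id']}_masks.tif",
            config.optical.pixel_size,
            slice_index=0,
        )
        m = morphometry.compute_vessel_metrics(
            vessel_id=row["vessel_id"],
            ri_slice=recovered,
            interior_mask=masks.interior_mask,
            wall_mask=masks.wall_mask,
            cell_mask=masks.cell_mask,
            pixel_size=config.optical.pixel_size,
            diameter_threshold=config.diameter_threshold,
            provenance={
                "slice_index": meta["slice_index"],
                "mask_source": config.mask_source,
                "canny_sigma": config.canny_sigma,
            },
        )
        rows.append(
            {
                "group": row["group"],
                "animal_id": row["animal_id"],
                "vessel_id": row["vessel_id"],
                "mean_thickness": m.mean_thickness,
                "diameter": m.diameter,
                "percent_fill": m.percent_fill,
                "wall_ri_mean": m.wall_ri_mean,
                "wall_ri_sd": m.wall_ri_sd,
                "included": m.included,
            }
        )
        samples[row["vessel_id"]] = [float(v) for v in m.thickness_samples]
    table = pd.DataFrame(rows)
    csv_path = outdir / "vessel_metrics.csv"
    table.to_csv(csv_path, index=False, float_format="%.10g")
    json_path = outdir / "thickness_samples.json"
    _write_json(json_path, samples)
    return [csv_path, json_path]


def _stage_profile(config: RunConfig, outdir: Path, force: bool) -> list[Path]:
    manifest, src = _load_manifest(config, outdir)
    produced = []
    for _, row in manifest.iterrows():
        if "has_break" in row and not row["has_break"]:
            continue
        recovered = tiffio.read_stack(outdir / f"{row['vessel_id']}_recovered.tif")[0]
        masks = segmentation.load_masks(
            outdir / f"{row['vessel_id']}_masks.tif", config.optical.pixel_size
        )
        try:
            profile = breakprofile.build_break_profile(
                masks.wall_mask,
                recovered,
                config.optical.pixel_size,
                window=config.profile_window,
                exclude_border=2,
            )
        except ValueError:
            continue  # closed wall: nothing to profile
        frame = breakprofile.profile_to_frame(profile)
        csv_path = outdir / f"{row['vessel_id']}_break_profile.csv"
        frame.to_csv(csv_path, index=False, float_format="%.10g")
        _, summaries = breakprofile.classify_regions(
            profile.distances, profile.ri_values, bounds=profile.region_bounds
        )
        json_path = outdir / f"{row['vessel_id']}_break_regions.json"
        _write_json(json_path, summaries)
        produced += [csv_path, json_path]
    return produced


def _stage_stats(config: RunConfig, outdir: Path, force: bool) -> list[Path]:
    table = pd.read_csv(outdir / "vessel_metrics.csv")
    groups = sorted(table["group"].unique())
    if len(groups) < 2:
        logger.warning("fewer than two groups; stats stage writes nothing")
        return []
    rows = []
    metric_names = ("mean_thickness", "diameter", "percent_fill", "wall_ri_mean")
    for metric in metric_names:
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                cmp = stats.compare_groups(
                    table,
                    metric,
                    groups[i],
                    groups[j],
                    unit=config.unit,
                    alpha=config.alpha_level,
                    welch=config.welch,
                )
                rows.append(
                    {
                        k: getattr(cmp, k)
                        for k in (
                            "group_a",
                            "group_b",
                            "unit",
                            "metric",
                            "n_a",
                            "n_b",
                            "mean_a",
                            "mean_b",
                            "t_statistic",
                            "t_p_value",
                            "f_statistic",
                            "f_p_value",
                            "significant_t",
                            "significant_f",
                        )
                    }
                )
    report = pd.DataFrame(rows)
    csv_path = outdir / "group_comparisons.csv"
    report.to_csv(csv_path, index=False, float_format="%.10g")
    json_path = outdir / "group_comparisons.json"
    _write_json(json_path, {"comparisons": rows, "alpha": config.alpha_level})
    return [csv_path, json_path]
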