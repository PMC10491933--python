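"""Seeded synthetic refractive-index phantoms.

A phantom is a straight (optionally tilted) tubular vessel whose axis runs
along the x grid axis. The cross-section lives in the (z, y) plane, so
axial slices cut the tube lengthwise and the widest lumen band appears at
the tube's central z plane — the geometry the widest-slice analysis
assumes. Background voxels are exactly the medium RI; the wall is a
uniform RI excess (plus optional fiber-like segments); cell inclusions are
spheres confined to the lumen; an optional angular arc of the wall can be
removed to create a break.

All randomness flows from explicit seeds: outputs are pure functions of
(spec, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion

from vesselqpi.config import GroupSpec, OpticalConfig, PhantomSpec
from vesselqpi import tiffio


@dataclass(frozen=True)
class RIVolume:
    """3D absolute refractive-index grid with its sampling metadata."""

    grid: np.ndarray  # (z, y, x), float
    pixel_size: float  # μm/px, lateral
    z_step: float  # μm

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("RI values must be finite")
        if self.grid.min() < 1.0:
            raise ValueError("absolute RI must be >= 1.0")


@dataclass(frozen=True)
class PhantomTruth:
    """A generated phantom plus its ground-truth label volume.

    ``labels``: 0 background, 1 lumen interior, 2 wall, 3 cell.
    """

    volume: RIVolume
    labels: np.ndarray
    spec: PhantomSpec
    config: OpticalConfig


def _cross_section_distance(
    spec: PhantomSpec, config: OpticalConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel distance from the vessel axis (μm) and polar angle.

    Returns arrays of shape (z, y, x). The axis runs along x through the
    volume center; a nonzero tilt makes the axis depth vary linearly with x.
    """
    nz, ny, nx = spec.volume_shape
    z_um = (np.arange(nz) - (nz - 1) / 2.0) * config.z_step
    y_um = (np.arange(ny) - (ny - 1) / 2.0) * config.pixel_size
    x_um = (np.arange(nx) - (nx - 1) / 2.0) * config.pixel_size
    tilt = np.tan(np.deg2rad(spec.tilt_deg))
    # axis depth offset as a function of x
    z_axis = tilt * x_um  # (nx,)
    dz = z_um[:, None, None] - z_axis[None, None, :]
    dy = y_um[None, :, None] + np.zeros((nz, ny, nx))
    dzf = dz + np.zeros((nz, ny, nx))
    dist = np.hypot(dzf, dy)
    angle = np.arctan2(dzf, dy)  # (-π, π], 0 along +y
    return dist, angle


def _in_arc(angle: np.ndarray, arc: tuple[float, float]) -> np.ndarray:
    """Membership of polar angles in an arc, handling wrap-around."""
    a0, a1 = (np.mod(arc[0], 2 * np.pi), np.mod(arc[1], 2 * np.pi))
    th = np.mod(angle, 2 * np.pi)
    if a0 <= a1:
        return (th >= a0) & (th <= a1)
    return (th >= a0) | (th <= a1)


def realize_fill(
    spec: PhantomSpec,
    lumen_mask: np.ndarray,
    seed: int,
    pixel_size: float = 1.0,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Place disc cells in a 2D lumen mask to hit ``target_fill_fraction``.

    Cells are discs of radius ``spec.cell_radius`` (μm) that never cross
    the lumen boundary and never overlap each other (random sequential
    adsorption; tangency allowed). Placement stops once the achieved
    fraction reaches the target or the attempt budget is exhausted —
    targets near the packing limit are best-effort by construction.

    Returns ``(cell_mask, centers)``; pure function of ``seed``.
    """
    lumen_mask = np.asarray(lumen_mask, dtype=bool)
    r_px = max(1, int(round(spec.cell_radius / pixel_size)))
    lumen_area = int(lumen_mask.sum())
    if lumen_area <= np.pi * r_px**2:
        raise ValueError("lumen area must exceed one cell's area")
    cell_mask = np.zeros_like(lumen_mask)
    centers: list[tuple[int, int]] = []
    if spec.target_fill_fraction <= 0:
        return cell_mask, centers

    disc = _disc_footprint(r_px)
    # centers keep a 2 px margin beyond the cell radius so a cell's rim
    # never abuts the lumen boundary (edge detection needs the clearance)
    allowed = binary_erosion(
        lumen_mask, structure=_disc_footprint(r_px + 2), border_value=0
    )
    idx = np.flatnonzero(allowed)
    if idx.size == 0:
        return cell_mask, centers
    rng = np.random.default_rng(seed)
    target_px = spec.target_fill_fraction / 100.0 * lumen_area
    max_attempts = 20000
    min_sep_sq = (2 * r_px) ** 2
    occupied = cell_mask.sum()
    h = r_px  # footprint half-size
    for _ in range(max_attempts):
        if occupied >= target_px:
            break
        flat = rng.choice(idx)
        cy, cx = np.unravel_index(flat, lumen_mask.shape)
        if centers:
            c = np.asarray(centers)
            if np.min((c[:, 0] - cy) ** 2 + (c[:, 1] - cx) ** 2) < min_sep_sq:
                continue
        cell_mask[cy - h : cy + h + 1, cx - h : cx + h + 1] |= disc
        centers.append((int(cy), int(cx)))
        occupied += int(disc.sum())
    return cell_mask, centers


def _disc_footprint(r_px: int) -> np.ndarray:
    yy, xx = np.mgrid[-r_px : r_px + 1, -r_px : r_px + 1]
    return yy**2 + xx**2 <= r_px**2


def build_ri_volume(
    spec: PhantomSpec, config: OpticalConfig, with_labels: bool = False
) -> RIVolume | PhantomTruth:
    """Generate a phantom RI volume (optionally with ground-truth labels).

    Background voxels equal ``medium_ri_nm`` exactly; wall voxels equal
    ``medium_ri_nm + wall_delta_n`` (plus fiber excess where fibers are
    placed); cells only inside the lumen; the break arc, if set, restores
    wall voxels to the medium RI. Pure function of ``spec.seed``.
    """
    nm = config.medium_ri_nm
    for name in ("wall_delta_n", "cell_delta_n", "fiber_delta_n"):
        if nm + getattr(spec, name) < 1.0:
            raise ValueError(f"{name} would push absolute RI below 1.0")

    nz, ny, nx = spec.volume_shape
    r_out = spec.lumen_radius + spec.wall_thickness
    half_z = (nz - 1) / 2.0 * config.z_step
    half_y = (ny - 1) / 2.0 * config.pixel_size
    if r_out >= min(half_z, half_y):
        raise ValueError(
            f"vessel (outer radius {r_out:.1f} μm) does not fit the volume"
        )

    dist, angle = _cross_section_distance(spec, config)
    lumen = dist < spec.lumen_radius
    wall = (dist >= spec.lumen_radius) & (dist < r_out)
    if spec.break_arc is not None:
        removed = _in_arc(angle, spec.break_arc)
        if spec.break_length is not None:
            # localized rupture: restrict to an axial window mid-volume
            x_um = (np.arange(nx) - (nx - 1) / 2.0) * config.pixel_size
            in_x = np.abs(x_um) <= spec.break_length / 2.0
            removed &= in_x[None, None, :]
        wall &= ~removed

    grid = np.full(spec.volume_shape, nm, dtype=np.float64)
    grid[wall] = nm + spec.wall_delta_n

    rng = np.random.default_rng(spec.seed)

    # fiber-like high-RI segments within the wall, running along the axis;
    # fiber_length is the fragmentation knob (short = fragmented).
    axis_len_um = nx * config.pixel_size
    n_fibers = int(round(spec.fiber_density * axis_len_um / 100.0))
    if n_fibers > 0:
        r_mid = spec.lumen_radius + spec.wall_thickness / 2.0
        half_width = max(spec.wall_thickness / 4.0, config.pixel_size)
        x_um = (np.arange(nx) - (nx - 1) / 2.0) * config.pixel_size
        for _ in range(n_fibers):
            theta0 = rng.uniform(-np.pi, np.pi)
            x0 = rng.uniform(x_um.min(), x_um.max() - spec.fiber_length)
            in_x = (x_um >= x0) & (x_um <= x0 + spec.fiber_length)
            ang_half = half_width / r_mid
            dtheta = np.abs(np.angle(np.exp(1j * (angle - theta0))))
            fiber = (
                wall
                & (np.abs(dist - r_mid) < half_width)
                & (dtheta < ang_half * 4)
                & in_x[None, None, :]
            )
            grid[fiber] += spec.fiber_delta_n

    # cell inclusions: spheres whose equators lie in the analysis plane —
    # the widest lumen slice as downstream selection will find it (ties to
    # the smallest index), so the fill target holds where it is measured
    labels = np.zeros(spec.volume_shape, dtype=np.uint8)
    labels[lumen] = 1
    labels[wall] = 2
    from vesselqpi.segmentation import select_widest_slice  # deferred: no cycle at load

    zc = select_widest_slice(list(lumen))
    if spec.target_fill_fraction > 0:
        lumen_slice = lumen[zc]
        cell_seed = int(rng.integers(0, 2**31 - 1))
        _, centers = realize_fill(
            spec, lumen_slice, seed=cell_seed, pixel_size=config.pixel_size
        )
        if centers:
            z_um = (np.arange(nz) - (nz - 1) / 2.0) * config.z_step
            y_idx = np.arange(ny)
            x_idx = np.arange(nx)
            r_cell = spec.cell_radius
            for cy, cx in centers:
                dz2 = (z_um - z_um[zc]) ** 2
                dy2 = ((y_idx - cy) * config.pixel_size) ** 2
                dx2 = ((x_idx - cx) * config.pixel_size) ** 2
                sphere = (
                    dz2[:, None, None] + dy2[None, :, None] + dx2[None, None, :]
                ) <= r_cell**2
                sphere &= lumen  # hard containment
                grid[sphere] = nm + spec.cell_delta_n
                labels[sphere] = 3

    volume = RIVolume(grid=grid, pixel_size=config.pixel_size, z_step=config.z_step)
    if with_labels:
        return PhantomTruth(volume=volume, labels=labels, spec=spec, config=config)
    return volume


def _draw_spec(
    base: PhantomSpec,
    means: dict[str, float],
    sds: dict[str, float],
    rng: np.random.Generator,
    seed: int,
) -> PhantomSpec:
    """Per-animal phantom parameters: Gaussian jitter around group means."""
    updates: dict[str, float | int] = {"seed": seed}
    for name, mu in means.items():
        sd = sds.get(name, 0.0)
        v = float(rng.normal(mu, sd)) if sd > 0 else float(mu)
        if name == "target_fill_fraction":
            v = float(np.clip(v, 0.0, 100.0))
        updates[name] = v
    return base.model_copy(update=updates)


def generate_cohort(
    group_specs: Sequence[GroupSpec],
    config: OpticalConfig,
    outdir: str | Path,
    seed: int,
    force: bool = False,
) -> pd.DataFrame:
    """Write one phantom stack per animal per vessel plus a manifest.

    Each stack is a 32-bit float multi-page TIFF (one page per z slice)
    with a JSON metadata sidecar and an 8-bit ground-truth label stack.
    The manifest CSV records group, animal, vessel, paths and the drawn
    ground-truth parameters. Fully reproducible from ``seed``.
    """
    if not group_specs:
        raise ValueError("need at least one group")
    outdir = Path(outdir)
    manifest_path = outdir / "manifest.csv"
    if manifest_path.exists() and not force:
        raise FileExistsError(
            f"{manifest_path} exists; pass force=True to overwrite"
        )
    outdir.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(seed)
    rows = []
    for gi, group in enumerate(group_specs):
        for ai in range(group.n_animals):
            animal_id = f"{group.label}_a{ai:02d}"
            animal_ss = np.random.SeedSequence([seed, gi, ai])
            rng = np.random.default_rng(animal_ss)
            animal_seed = int(rng.integers(0, 2**31 - 1))
            spec_a = _draw_spec(
                group.base, group.param_means, group.param_sds, rng, animal_seed
            )
            for vi in range(group.n_vessels):
                vessel_id = f"{animal_id}_v{vi:02d}"
                vseed = int(rng.integers(0, 2**31 - 1))
                spec_v = spec_a.model_copy(update={"seed": vseed})
                truth = build_ri_volume(spec_v, config, with_labels=True)
                stack_path = outdir / f"{vessel_id}_ri.tif"
                label_path = outdir / f"{vessel_id}_labels.tif"
                tiffio.write_stack(stack_path, truth.volume.grid.astype(np.float32))
                tiffio.write_stack(label_path, truth.labels)
                meta = {
                    "pixel_size": config.pixel_size,
                    "z_step": config.z_step,
                    "seed": vseed,
                    "spec": json.loads(spec_v.model_dump_json()),
                }
                sidecar = stack_path.with_suffix(".json")
                sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True))
                rows.append(
                    {
                        "group": group.label,
                        "animal_id": animal_id,
                        "vessel_id": vessel_id,
                        "stack_path": stack_path.name,
                        "label_path": label_path.name,
                        "lumen_radius": spec_v.lumen_radius,
                        "wall_thickness": spec_v.wall_thickness,
                        "wall_delta_n": spec_v.wall_delta_n,
                        "cell_delta_n": spec_v.cell_delta_n,
                        "target_fill_fraction": spec_v.target_fill_fraction,
                        "has_break": spec_v.break_arc is not None,
                        "seed": vseed,
                    }
                )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(manifest_path, index=False)
    return manifest


def manifest_digest(manifest: pd.DataFrame) -> str:
    """Stable digest of a manifest's contents (reproducibility checks)."""
    payload = manifest.to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()
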