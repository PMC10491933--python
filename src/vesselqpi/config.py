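"""Validated parameter models.

All lengths are in micrometers (μm) throughout the package; pixel units
appear only transiently inside mask/image operations.
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, Field, field_validator, model_validator


class OpticalConfig(BaseModel):
    """Optical system parameters.

    Defaults marked *(convention)* are implementation choices, not measured
    system values; the rest follow the imaging geometry the analysis assumes
    (720 nm illumination, 3.2 μm optical section, medium RI 1.3440, 1 μm
    z step).
    """

    wavelength: float = Field(default=0.72, description="Illumination wavelength, μm")
    slice_thickness_dz: float = Field(
        default=3.2, description="Effective optical-section thickness, μm"
    )
    pixel_size: float = Field(default=0.5, description="Lateral sampling, μm/px")
    medium_ri_nm: float = Field(default=1.3440, description="Background medium RI")
    numerical_aperture: float = Field(default=0.6, description="Objective NA")
    tikhonov_alpha: float = Field(
        default=1e-3, description="Deconvolution regularization (convention)"
    )
    z_step: float = Field(default=1.0, description="Axial stack step, μm")

    model_config = {"frozen": True}

    @field_validator("wavelength", "slice_thickness_dz", "pixel_size", "z_step")
    @classmethod
    def _positive_length(cls, v: float) -> float:
        if not v > 0:
            raise ValueError("lengths must be > 0")
        return v

    @field_validator("numerical_aperture")
    @classmethod
    def _na_range(cls, v: float) -> float:
        if not (0 < v < 1.5):
            raise ValueError("numerical_aperture must be in (0, 1.5)")
        return v

    @field_validator("medium_ri_nm")
    @classmethod
    def _ri_range(cls, v: float) -> float:
        if not v > 1:
            raise ValueError("medium_ri_nm must be > 1")
        return v

    @field_validator("tikhonov_alpha")
    @classmethod
    def _alpha_nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("tikhonov_alpha must be >= 0")
        return v


class PhantomSpec(BaseModel):
    """Geometry and contrast of one synthetic vessel phantom.

    RI excess values (``*_delta_n``) are assumptions of the generator, not
    measured tissue values; only the background medium RI is anchored to
    1.3440 via :class:`OpticalConfig`.
    """

    volume_shape: tuple[int, int, int] = Field(
        default=(33, 128, 128), description="(z, y, x) voxels"
    )
    lumen_radius: float = Field(default=11.0, description="μm")
    wall_thickness: float = Field(default=4.0, description="μm")
    wall_delta_n: float = Field(default=0.020, description="RI excess of the wall")
    cell_radius: float = Field(default=3.0, description="μm")
    cell_delta_n: float = Field(default=0.015, description="RI excess of cells")
    target_fill_fraction: float = Field(default=40.0, description="percent, [0, 100]")
    break_arc: Optional[tuple[float, float]] = Field(
        default=None,
        description="Angular interval (radians) where the wall is removed",
    )
    break_length: Optional[float] = Field(
        default=30.0,
        description=(
            "Axial extent of the break, μm, centered mid-volume; None "
            "removes the arc along the whole axis"
        ),
    )
    fiber_density: float = Field(
        default=0.0, description="fibers per 100 μm of vessel axis"
    )
    fiber_delta_n: float = Field(default=0.010, description="RI excess of fibers")
    fiber_length: float = Field(
        default=20.0,
        description="fiber segment length, μm (small = fragmented walls)",
    )
    noise_photon_budget: Optional[float] = Field(
        default=10000.0, description="expected counts/pixel; None = noiseless"
    )
    tilt_deg: float = Field(
        default=0.0, description="axis tilt out of the slicing plane, degrees"
    )
    seed: int = 0

    model_config = {"frozen": True}

    @field_validator("volume_shape")
    @classmethod
    def _shape_positive(cls, v: tuple[int, int, int]) -> tuple[int, int, int]:
        if len(v) != 3 or any(s < 1 for s in v):
            raise ValueError("volume_shape must be three positive integers")
        return v

    @field_validator("wall_thickness", "fiber_length")
    @classmethod
    def _positive(cls, v: float) -> float:
        if not v > 0:
            raise ValueError("must be > 0")
        return v

    @field_validator("target_fill_fraction")
    @classmethod
    def _fill_range(cls, v: float) -> float:
        if not (0 <= v <= 100):
            raise ValueError("target_fill_fraction must be in [0, 100]")
        return v

    @field_validator("fiber_density")
    @classmethod
    def _density_nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("fiber_density must be >= 0")
        return v

    @field_validator("noise_photon_budget")
    @classmethod
    def _budget_positive(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and not v > 0:
            raise ValueError("noise_photon_budget must be > 0 or None")
        return v

    @model_validator(mode="after")
    def _radii_order(self) -> "PhantomSpec":
        if not (self.lumen_radius > self.cell_radius > 0):
            raise ValueError("require lumen_radius > cell_radius > 0")
        for name in ("wall_delta_n", "cell_delta_n", "fiber_delta_n"):
            v = getattr(self, name)
            if not (v == v and abs(v) < 1):  # finite, sane
                raise ValueError(f"{name} must be finite and |v| < 1")
        return self


class GroupSpec(BaseModel):
    """One cohort group: a label, animal/vessel counts, a base phantom spec
    and Gaussian per-animal jitter on selected spec parameters."""

    label: str
    n_animals: int = Field(ge=1)
    n_vessels: int = Field(default=1, ge=1)
    base: PhantomSpec = PhantomSpec()
    param_means: dict[str, float] = Field(default_factory=dict)
    param_sds: dict[str, float] = Field(default_factory=dict)


class RunConfig(BaseModel):
    """Resolved configuration for a full pipeline run."""

    optical: OpticalConfig = OpticalConfig()
    groups: list[GroupSpec] = Field(default_factory=list)
    seed: int = 0
    outdir: str = "run"
    # stage toggles
    stages: list[str] = Field(
        default_factory=lambda: [
            "simulate",
            "reconstruct",
            "segment",
            "quantify",
            "profile",
            "stats",
        ]
    )
    # segmentation parameters (conventions; echoed into provenance)
    canny_sigma: float = 1.0
    canny_low: Optional[float] = None
    canny_high: Optional[float] = None
    closing_radius: int = 2
    min_cell_px: int = 8
    # analysis parameters
    diameter_threshold: float = Field(
        default=20.0, description="strict > filter, μm"
    )
    profile_window: float = Field(default=20.0, description="moving window, μm")
    unit: str = Field(default="animal", description="'animal' or 'vessel'")
    alpha_level: float = 0.05
    welch: bool = False
    # mask source: "ground-truth" (from the phantom) or a directory of files
    mask_source: str = "ground-truth"
    # external input stacks (skip the simulate stage)
    external_stacks: Optional[str] = None

    @field_validator("unit")
    @classmethod
    def _unit(cls, v: str) -> str:
        if v not in ("animal", "vessel"):
            raise ValueError("unit must be 'animal' or 'vessel'")
        return v
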