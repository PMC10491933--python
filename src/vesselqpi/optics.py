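"""Forward DPC acquisition model and its Tikhonov-regularized inverse.

The forward model is a first-order weak-object approximation: a thin phase
slice imaged under oblique partially coherent illumination produces an
intensity modulation that is linear in the phase, with a purely imaginary,
odd transfer function per shear axis. The source is modeled as a signed
half-pupil (one half-disc per azimuth); opposing azimuths carry opposite
sign, so the normalized difference of an opposing pair isolates the phase
term.

Conventions (not measured-system facts):

* DPC images are sum-normalized: ``(I_a - I_b) / (I_a + I_b)``.
* The recovered phase is mean-zero — the transfer function has no DC
  response, so the absolute phase offset is unrecoverable. RI maps built
  from recovered phase therefore carry the medium RI plus a *relative*
  Δn; see :func:`phase_to_ri` and the pipeline's background re-anchoring.
* Frequencies are in cycles/μm on the unitary FFT grid implied by
  ``pixel_size``; image origin top-left, x rightward, y downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numpy.fft import fft2, fftfreq, fftshift, ifft2, ifftshift
from scipy.signal import fftconvolve

from vesselqpi.config import OpticalConfig

AZIMUTHS = (0, 90, 180, 270)


class WeakPhaseError(ValueError):
    """Phase modulation too strong for the linear forward model."""


@dataclass(frozen=True)
class PhaseImage:
    """2D phase difference map, radians."""

    grid: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("phase values must be finite")


@dataclass(frozen=True)
class RawIntensityQuad:
    """Four intensity images indexed by source azimuth (degrees)."""

    images: dict[int, np.ndarray]
    exposure: Optional[float] = None  # expected counts/pixel; None = noiseless

    def __post_init__(self) -> None:
        if set(self.images) != set(AZIMUTHS):
            raise ValueError(f"need azimuths {AZIMUTHS}")
        shapes = {im.shape for im in self.images.values()}
        if len(shapes) != 1:
            raise ValueError("azimuth images must share one shape")
        for az, im in self.images.items():
            if np.any(im < 0):
                raise ValueError(f"negative intensity at azimuth {az}")


@dataclass(frozen=True)
class DPCPair:
    """Normalized-difference DPC images for the two shear axes."""

    dpc_x: np.ndarray
    dpc_y: np.ndarray
    zero_sum_mask: Optional[np.ndarray] = None
    tfs: Optional["TransferFunctionSet"] = None


@dataclass(frozen=True)
class TransferFunctionSet:
    """Frequency-domain phase transfer functions H_x, H_y (fft order)."""

    h_x: np.ndarray
    h_y: np.ndarray
    config: OpticalConfig = field(compare=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.h_x.shape


def _oddify(h: np.ndarray) -> np.ndarray:
    """Project onto the odd part under frequency negation (fft order)."""
    neg = np.roll(h[::-1, ::-1], shift=(1, 1), axis=(0, 1))
    return (h - neg) / 2.0


def compute_transfer_functions(
    config: OpticalConfig, image_shape: tuple[int, int]
) -> TransferFunctionSet:
    """Weak-object phase transfer functions for the two DPC shear axes.

    The source per axis is a signed half-pupil (sign of the frequency
    coordinate along the shear axis, inside the coherent cutoff NA/λ).
    H is purely imaginary, odd under frequency negation (hence zero at DC),
    and supported within twice the coherent cutoff.
    """
    ny, nx = image_shape
    if ny < 8 or nx < 8:
        raise ValueError("image_shape must be at least 8x8")
    fy = fftshift(fftfreq(ny, d=config.pixel_size))
    fx = fftshift(fftfreq(nx, d=config.pixel_size))
    FX, FY = np.meshgrid(fx, fy)
    rho = np.hypot(FX, FY)
    cutoff = config.numerical_aperture / config.wavelength
    pupil = (rho <= cutoff).astype(np.float64)
    if pupil.sum() <= 1:
        raise ValueError(
            "numerical_aperture yields an empty passband on this grid; "
            "increase image size or NA"
        )

    norm = float(np.sum(pupil * pupil))  # total transmitted source power

    def axis_tf(signed_source: np.ndarray) -> np.ndarray:
        # Gamma(u) = sum_f S(f) P(f) P(f+u): linear cross-correlation on the
        # centered grid (zero-padded internally; no circular wraparound).
        gamma = fftconvolve(pupil, (signed_source * pupil)[::-1, ::-1], mode="same")
        h = 1j * gamma / norm
        h[rho > 2 * cutoff] = 0.0  # true support bound; clip fft round-off
        return ifftshift(h)

    h_x = _oddify(axis_tf(np.sign(FX) * pupil))
    h_y = _oddify(axis_tf(np.sign(FY) * pupil))
    return TransferFunctionSet(h_x=h_x, h_y=h_y, config=config)


def simulate_acquisition(
    phase: PhaseImage,
    tfs: TransferFunctionSet,
    photon_budget: Optional[float] = None,
    seed: Optional[int] = None,
) -> RawIntensityQuad:
    """Forward-simulate the four-azimuth acquisition of a phase slice.

    Noiseless intensities are ``0.25 * (1 ± g_axis)`` where ``g_axis`` is
    the real part of the inverse transform of ``H_axis · F[φ]``; azimuths
    0/180 carry the x shear with opposite sign, 90/270 the y shear. With a
    ``photon_budget`` the images are scaled to that budget and Poisson
    sampled (pure function of ``seed``).

    Raises :class:`WeakPhaseError` when the linear modulation reaches
    unit magnitude (negative intensities — outside the model's regime).
    """
    if phase.grid.shape != tfs.shape:
        raise ValueError("phase and transfer functions must share a grid")
    spec = fft2(phase.grid)
    g_x = ifft2(tfs.h_x * spec).real
    g_y = ifft2(tfs.h_y * spec).real
    peak = max(np.abs(g_x).max(), np.abs(g_y).max())
    if peak >= 1.0:
        raise WeakPhaseError(
            f"phase modulation |g|={peak:.3f} >= 1; reduce phase amplitude"
        )
    base = {0: 1.0 + g_x, 180: 1.0 - g_x, 90: 1.0 + g_y, 270: 1.0 - g_y}
    if photon_budget is None:
        images = {az: 0.25 * im for az, im in base.items()}
        return RawIntensityQuad(images=images, exposure=None)
    if photon_budget <= 0:
        raise ValueError("photon_budget must be > 0 (or None for noiseless)")
    rng = np.random.default_rng(seed)
    images = {
        az: rng.poisson(0.25 * photon_budget * im).astype(np.float64)
        for az, im in base.items()
    }
    return RawIntensityQuad(images=images, exposure=photon_budget)


def form_dpc(quad: RawIntensityQuad, tfs: Optional[TransferFunctionSet] = None) -> DPCPair:
    """Sum-normalized differential phase contrast from opposing azimuths.

    ``dpc = (I_a - I_b) / (I_a + I_b)`` per pixel; pixels where the sum is
    zero are mapped to 0 and flagged in ``zero_sum_mask``.
    """

    def normalized(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        s = a + b
        zero = s == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(zero, 0.0, (a - b) / np.where(zero, 1.0, s))
        return d, zero

    dpc_x, zx = normalized(quad.images[0], quad.images[180])
    dpc_y, zy = normalized(quad.images[90], quad.images[270])
    return DPCPair(dpc_x=dpc_x, dpc_y=dpc_y, zero_sum_mask=zx | zy, tfs=tfs)


def recover_phase(
    dpc: DPCPair, tfs: TransferFunctionSet, alpha: float
) -> PhaseImage:
    """Tikhonov-regularized least-squares phase from a DPC pair.

    ``φ̂ = F⁻¹[ (H_x* D_x + H_y* D_y) / (|H_x|² + |H_y|² + α) ]``

    The output is real and exactly mean-zero (the DC component is
    unrecoverable by construction; this is a stated convention).
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if dpc.dpc_x.shape != tfs.shape or dpc.dpc_y.shape != tfs.shape:
        raise ValueError("DPC images and transfer functions must share a grid")
    num = np.conj(tfs.h_x) * fft2(dpc.dpc_x) + np.conj(tfs.h_y) * fft2(dpc.dpc_y)
    den = np.abs(tfs.h_x) ** 2 + np.abs(tfs.h_y) ** 2 + alpha
    phi = ifft2(num / den).real
    return PhaseImage(grid=phi - phi.mean(), pixel_size=tfs.config.pixel_size)


def phase_to_ri(phase: PhaseImage, config: OpticalConfig) -> np.ndarray:
    """Absolute RI from phase: ``n = nm + λ·Δφ / (2π·Δz)`` (exact)."""
    return config.medium_ri_nm + config.wavelength * phase.grid / (
        2.0 * np.pi * config.slice_thickness_dz
    )


def ri_to_phase(ri_map: np.ndarray, config: OpticalConfig) -> PhaseImage:
    """Exact inverse of :func:`phase_to_ri`:
    ``Δφ = 2π·Δz·(n − nm) / λ``."""
    grid = (
        2.0
        * np.pi
        * config.slice_thickness_dz
        * (np.asarray(ri_map, dtype=np.float64) - config.medium_ri_nm)
        / config.wavelength
    )
    return PhaseImage(grid=grid, pixel_size=config.pixel_size)


def reconstruct_ri_slice(
    truth_ri: np.ndarray,
    config: OpticalConfig,
    photon_budget: Optional[float] = None,
    seed: Optional[int] = None,
    alpha: Optional[float] = None,
    tfs: Optional[TransferFunctionSet] = None,
    anchor_background: bool = True,
) -> np.ndarray:
    """Simulate acquisition of a ground-truth RI slice and invert it.

    Because the DC phase is lost, the recovered map is re-anchored so its
    median equals the medium RI (the background dominates the field of
    view); set ``anchor_background=False`` to keep the raw mean-zero
    convention.
    """
    if tfs is None:
        tfs = compute_transfer_functions(config, truth_ri.shape)
    if alpha is None:
        alpha = config.tikhonov_alpha
    phase = ri_to_phase(truth_ri, config)
    quad = simulate_acquisition(phase, tfs, photon_budget=photon_budget, seed=seed)
    recovered = recover_phase(form_dpc(quad, tfs), tfs, alpha=alpha)
    ri = phase_to_ri(recovered, config)
    if anchor_background:
        ri = ri + (config.medium_ri_nm - np.median(ri))
    return ri
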