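"""Forward simulator: low-resolution intensity stacks from a known object.

The coherent image of a thin sample o(r) under the n'th tilted plane wave is

    I_n(r) = | { o(r) ⊙ exp(i k_n · r) } * F⁻¹{C(k)} |²,

which in the Fourier domain is the shifted sub-aperture O(k + k_n) ⊙ C(k):
the high-resolution spectrum is rolled by the LED's pixel shift, the central
low-resolution window is cropped, multiplied by the complex pupil and
inverse-transformed.  Downsampling is realized purely by this Fourier crop;
intensities are scaled so a unit-amplitude flat object under the ideal
on-axis pupil yields a flat image of ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .fields import ComplexField, fft2c, ifft2c, crop_window
from .optics import IlluminationSet, SystemConfig, led_wave_vectors, make_ctf
from .zernike import CoeffVector, basis_from_config, pupil_phase

__all__ = [
    "NoiseSpec", "GroundTruth", "MeasurementStack", "forward_intensity",
    "simulate_dataset", "make_phantom", "add_noise",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise description.

    kind
        ``"none"``, ``"gaussian"`` (additive, ``sigma`` expressed as a
        fraction of the stack's peak intensity) or ``"poisson"``
        (``photons`` = photon budget at the peak intensity).
    """

    kind: str = "none"
    sigma: float = 0.0
    photons: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.kind == "gaussian" and self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.kind == "poisson" and (self.photons is None or self.photons <= 0):
            raise ValueError("poisson noise needs a positive photon budget")


@dataclass
class GroundTruth:
    object: ComplexField
    coeffs: CoeffVector


@dataclass
class MeasurementStack:
    """N low-resolution intensity images with their illumination geometry."""

    images: np.ndarray                      # (N, n, n) non-negative
    illumination: IlluminationSet
    config: SystemConfig
    ground_truth: GroundTruth | None = None

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 3:
            raise ValueError("images must be a (N, n, n) array")
        if self.images.shape[0] != self.illumination.n:
            raise ValueError("image count does not match the illumination set")
        if self.images.shape[1] != self.config.lowres_size:
            raise ValueError("image size does not match the configuration")
        if np.any(self.images < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n(self) -> int:
        return self.images.shape[0]


def forward_intensity(obj: ComplexField | np.ndarray, pupil: np.ndarray,
                      shift: tuple[int, int], factor: int) -> np.ndarray:
    """One low-resolution intensity image of a high-resolution object.

    Parameters
    ----------
    obj
        High-resolution complex transmission (spatial plane), side
        ``factor ×`` the pupil side.
    pupil
        Complex pupil (amplitude ⊙ exp(i·phase)) on the low-res grid.
    shift
        Integer Fourier-pixel shift of this LED on the high-res grid.
    factor
        Linear upsampling factor between the two grids.
    """
    values = obj.values if isinstance(obj, ComplexField) else np.asarray(obj)
    pupil = np.asarray(pupil)
    n_lo = pupil.shape[0]
    if values.shape[0] != factor * n_lo:
        raise ValueError(
            f"object side {values.shape[0]} != factor {factor} x pupil side {n_lo}")
    spectrum = fft2c(values)
    rows, cols = crop_window(spectrum, shift, n_lo)
    phi_l = spectrum[rows, cols] * pupil
    psi = ifft2c(phi_l)
    # 1/factor² restores the flat-field normalization lost by the unitary crop
    return np.abs(psi) ** 2 / factor ** 2


def simulate_dataset(obj: ComplexField, coeffs: CoeffVector, cfg: SystemConfig,
                     noise: NoiseSpec | None = None) -> MeasurementStack:
    """Full measurement stack for a known object and pupil aberration.

    One image per LED of the matrix, aberrated by the Zernike phase of
    ``coeffs`` on the ideal binary CTF; noiseless unless a
    :class:`NoiseSpec` says otherwise.  The ground truth is embedded in the
    returned stack.
    """
    if obj.size != cfg.highres_size:
        raise ValueError(
            f"object side {obj.size} != configured high-res side {cfg.highres_size}")
    illum = led_wave_vectors(cfg)
    ctf = make_ctf(cfg).values.real
    basis = basis_from_config(cfg, len(coeffs))
    pupil = ctf * np.exp(1j * pupil_phase(coeffs, basis))
    images = np.empty((illum.n, cfg.lowres_size, cfg.lowres_size))
    for i in range(illum.n):
        images[i] = forward_intensity(obj, pupil, tuple(illum.pixel_shifts[i]),
                                      cfg.upsample_factor)
    stack = MeasurementStack(images=images, illumination=illum, config=cfg,
                             ground_truth=GroundTruth(obj, coeffs))
    if noise is not None and noise.kind != "none":
        stack = add_noise(stack, noise)
    return stack


def make_phantom(size: int, kind: str = "mixed", seed: int = 0) -> ComplexField:
    """Synthetic complex phantom: amplitude in [0.1, 1], phase in [−π/2, π/2].

    ``kind``:

    * ``"mixed"`` (default) — smooth seeded blobs plus sharp bars and a
      step edge, in both amplitude and an independent phase pattern;
      exercises low and high spatial frequencies at once.
    * ``"smooth"`` — blobs only.
    * ``"flat"``  — unit amplitude, zero phase.
    """
    if size < 32:
        raise ValueError("phantom size must be at least 32")
    if kind == "flat":
        return ComplexField(np.ones((size, size), dtype=complex))
    if kind not in ("mixed", "smooth"):
        raise ValueError(f"unknown phantom kind {kind!r}")
    rng = np.random.default_rng(seed)

    def blobs(r: np.random.Generator) -> np.ndarray:
        raw = gaussian_filter(r.standard_normal((size, size)), sigma=size / 16)
        lo, hi = raw.min(), raw.max()
        return (raw - lo) / (hi - lo)

    amp01 = blobs(rng)
    ph01 = blobs(rng)
    if kind == "mixed":
        y, x = np.mgrid[0:size, 0:size]
        bars = ((x // max(2, size // 32)) % 2).astype(float)
        band = (y > size // 3) & (y < size // 2)
        amp01 = np.where(band, 0.15 + 0.7 * bars, amp01)
        step = (x > 2 * size // 3).astype(float)
        hband = (y > 2 * size // 3) & (y < 5 * size // 6)
        ph01 = np.where(hband, step, ph01)
    amplitude = 0.1 + 0.9 * amp01
    phase = (np.pi / 2) * (2 * ph01 - 1)
    return ComplexField(amplitude * np.exp(1j * phase))


def add_noise(stack: MeasurementStack, spec: NoiseSpec) -> MeasurementStack:
    """Apply the measurement noise of ``spec``; non-negativity is preserved."""
    if spec.kind == "none":
        return stack
    rng = np.random.default_rng(spec.seed)
    peak = float(stack.images.max())
    if spec.kind == "gaussian":
        if spec.sigma == 0 or peak == 0:
            return stack
        noisy = stack.images + spec.sigma * peak * rng.standard_normal(
            stack.images.shape)
    else:  # poisson
        if peak == 0:
            return stack
        scale = spec.photons / peak
        noisy = rng.poisson(stack.images * scale) / scale
    return MeasurementStack(images=np.clip(noisy, 0.0, None),
                            illumination=stack.illumination,
                            config=stack.config,
                            ground_truth=stack.ground_truth)
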