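"""System geometry of an LED-array Fourier ptychographic microscope.

The microscope is described by a :class:`SystemConfig`: a programmable LED
matrix a distance ``led_distance_mm`` below the sample illuminates it with
tilted plane waves; a low-NA objective relays the exit wave to a camera.
Each LED shifts the sample spectrum by its illumination wave vector, so the
set of captured images samples Fourier space on a grid of overlapping
pupil-sized discs whose union defines the synthetic numerical aperture.

Conventions
-----------
* Fourier grids are DC-centered; the frequency step is ``1 / (lowres_size *
  object-plane pixel pitch)`` on both the low- and high-resolution grids
  (same field of view, different extent).
* Illumination angles use the exact sine, not the paraxial tangent: the
  outer LEDs of a wide matrix sit well outside the paraxial regime.
* Sign convention: an LED at positive physical offset ``(dx, dy)`` produces
  the directional-sine pair ``(-dx, -dy) / sqrt(dx^2 + dy^2 + h^2)``.  The
  simulator and every reconstructor share the resulting
  :class:`IlluminationSet`, so the convention only has to be consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from .fields import ComplexField

__all__ = [
    "SystemConfig", "IlluminationSet", "led_wave_vectors", "make_ctf",
    "synthetic_na", "overlap_ratio", "overlap_ratio_area", "default_config",
]


@dataclass(frozen=True)
class SystemConfig:
    """Optical and geometric parameters of the FP microscope."""

    wavelength_um: float = 0.532
    led_rows: int = 15
    led_cols: int = 15
    led_pitch_mm: float = 4.0
    led_distance_mm: float = 90.0
    na_obj: float = 0.1
    magnification: float = 2.0
    camera_pixel_um: float = 3.45
    lowres_size: int = 32
    upsample_factor: int = 4

    def __post_init__(self) -> None:
        if self.wavelength_um <= 0:
            raise ValueError("wavelength_um must be positive")
        if not 0 < self.na_obj < 1:
            raise ValueError("na_obj must lie in (0, 1)")
        if self.led_pitch_mm <= 0 or self.led_distance_mm <= 0:
            raise ValueError("LED pitch and distance must be positive")
        if self.led_rows < 1 or self.led_cols < 1:
            raise ValueError("LED grid must be at least 1x1")
        if self.upsample_factor < 2:
            raise ValueError("upsample_factor must be >= 2")
        if self.lowres_size < 4 or self.lowres_size % 2:
            raise ValueError("lowres_size must be an even integer >= 4")
        if self.magnification <= 0 or self.camera_pixel_um <= 0:
            raise ValueError("magnification and camera pixel size must be positive")

    # ---- derived geometry -------------------------------------------------
    @property
    def pixel_um(self) -> float:
        """Object-plane pixel pitch of the raw images, µm."""
        return self.camera_pixel_um / self.magnification

    @property
    def highres_size(self) -> int:
        return self.lowres_size * self.upsample_factor

    @property
    def highres_pixel_um(self) -> float:
        return self.pixel_um / self.upsample_factor

    @property
    def freq_step_um(self) -> float:
        """Fourier-grid step in cycles/µm (1 / field of view)."""
        return 1.0 / (self.lowres_size * self.pixel_um)

    @property
    def cutoff_freq_um(self) -> float:
        """Objective cutoff frequency NA/λ in cycles/µm."""
        return self.na_obj / self.wavelength_um

    @property
    def cutoff_radius_px(self) -> float:
        """Objective passband radius in Fourier-grid pixels."""
        return self.cutoff_freq_um / self.freq_step_um

    @property
    def n_leds(self) -> int:
        return self.led_rows * self.led_cols

    # ---- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "SystemConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} does not hold a mapping")
        return cls(**data)


def default_config() -> SystemConfig:
    """The reference bench: 15×15 LEDs on a 4 mm pitch 90 mm below the
    sample, 532 nm illumination, a 2×/0.1 NA objective and a 3.45 µm camera,
    with 32×32 raw images reconstructed on a 4× upsampled grid."""
    return SystemConfig()


def reference_config_path() -> Path:
    """Path of the bundled reference-bench YAML (same as default_config)."""
    return Path(__file__).parent / "data" / "reference_bench.yaml"


@dataclass
class IlluminationSet:
    """Per-LED illumination wave vectors.

    ``na_shifts``   -- (N, 2) dimensionless directional sines (NAy, NAx)
                       ordered (row-axis, col-axis) to match array indexing.
    ``pixel_shifts``-- (N, 2) integer offsets on the high-res Fourier grid.
    ``ordering``    -- list mapping sequence index n to LED (row, col).
    """

    na_shifts: np.ndarray
    pixel_shifts: np.ndarray
    ordering: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.na_shifts = np.asarray(self.na_shifts, dtype=float)
        self.pixel_shifts = np.asarray(self.pixel_shifts, dtype=int)
        if len(self.ordering) != len(self.na_shifts):
            raise ValueError("ordering length mismatch")
        if np.any(np.linalg.norm(self.na_shifts, axis=1) >= 1):
            raise ValueError("illumination NA must stay below 1")

    @property
    def n(self) -> int:
        return len(self.ordering)

    @property
    def center_index(self) -> int:
        """Sequence index of the on-axis LED (na_shift == 0)."""
        mags = np.linalg.norm(self.na_shifts, axis=1)
        idx = int(np.argmin(mags))
        if mags[idx] > 1e-12:
            raise ValueError("illumination set has no on-axis (center) LED")
        return idx


def _led_offsets_mm(cfg: SystemConfig) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Physical (dy, dx) offsets of every LED and a center-outward spiral
    ordering (radius first, then azimuth) starting at the central LED."""
    r0 = (cfg.led_rows - 1) / 2.0
    c0 = (cfg.led_cols - 1) / 2.0
    coords = [(r, c) for r in range(cfg.led_rows) for c in range(cfg.led_cols)]

    def key(rc: tuple[int, int]) -> tuple[float, float]:
        dy = (rc[0] - r0) * cfg.led_pitch_mm
        dx = (rc[1] - c0) * cfg.led_pitch_mm
        return (np.hypot(dx, dy), np.arctan2(dy, dx))

    coords.sort(key=key)
    offsets = np.array([[(r - r0) * cfg.led_pitch_mm, (c - c0) * cfg.led_pitch_mm]
                        for r, c in coords])
    return offsets, coords


def led_wave_vectors(cfg: SystemConfig) -> IlluminationSet:
    """Directional sines and Fourier-pixel shifts for every LED.

    For an LED at physical offset ``(dx, dy)`` mm the illumination
    directional sine is ``-offset / sqrt(dx² + dy² + h²)`` with ``h`` the
    LED-to-sample distance; the spectrum shift in high-res Fourier pixels is
    ``na_shift / λ`` divided by the grid frequency step, rounded to the
    nearest integer (the reconstruction rolls spectra by whole pixels).
    """
    offsets, ordering = _led_offsets_mm(cfg)
    h = cfg.led_distance_mm
    denom = np.sqrt(np.sum(offsets ** 2, axis=1) + h * h)
    na_shifts = -offsets / denom[:, None]
    px = np.rint(na_shifts / cfg.wavelength_um / cfg.freq_step_um).astype(int)
    return IlluminationSet(na_shifts=na_shifts, pixel_shifts=px, ordering=ordering)


def make_ctf(cfg: SystemConfig) -> ComplexField:
    """Binary coherent transfer function of the objective on the low-res grid.

    Unity inside the disc of radius NA/λ around DC, zero outside (ideal
    aberration-free pupil).  Rejects configurations whose passband would
    touch the grid edge (aliased pupil).
    """
    n = cfg.lowres_size
    if cfg.cutoff_radius_px >= n / 2:
        raise ValueError(
            f"CTF cutoff radius {cfg.cutoff_radius_px:.1f} px reaches half the "
            f"{n}-pixel grid; increase sampling or reduce NA")
    f = (np.arange(n) - n // 2) * cfg.freq_step_um
    fy, fx = np.meshgrid(f, f, indexing="ij")
    disk = (fx ** 2 + fy ** 2) < cfg.cutoff_freq_um ** 2
    return ComplexField(disk.astype(complex), plane="pupil")


def synthetic_na(cfg: SystemConfig) -> float:
    """Synthetic NA of the reconstruction: objective NA plus the largest
    illumination NA across the LED matrix."""
    illum = led_wave_vectors(cfg)
    return cfg.na_obj + float(np.max(np.linalg.norm(illum.na_shifts, axis=1)))


def _adjacent_delta_na(cfg: SystemConfig) -> float:
    """Illumination-NA spacing between the center LED and its neighbour one
    pitch away along a grid axis."""
    p, h = cfg.led_pitch_mm, cfg.led_distance_mm
    return p / np.sqrt(p * p + h * h)


def overlap_ratio(cfg: SystemConfig) -> float:
    """Linear (1-D) overlap of adjacent pupil passbands in Fourier space.

    ``(2·NA_obj − ΔNA) / (2·NA_obj)`` with ΔNA the illumination-NA spacing of
    adjacent LEDs, clipped to [0, 1].  This is the common rule-of-thumb
    figure; :func:`overlap_ratio_area` gives the stricter area fraction.
    """
    d = _adjacent_delta_na(cfg)
    return float(np.clip((2 * cfg.na_obj - d) / (2 * cfg.na_obj), 0.0, 1.0))


def overlap_ratio_area(cfg: SystemConfig) -> float:
    """Area fraction of the intersection of two adjacent pupil discs."""
    r = cfg.na_obj
    d = _adjacent_delta_na(cfg)
    if d >= 2 * r:
        return 0.0
    lens = 2 * r * r * np.arccos(d / (2 * r)) - (d / 2) * np.sqrt(4 * r * r - d * d)
    return float(lens / (np.pi * r * r))
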