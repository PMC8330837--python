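"""Complex-field container and centered FFT helpers.

All spectra in this package are stored DC-centered: the zero-frequency
component sits at index ``n // 2`` of each axis.  The transforms below are
unitary (``norm="ortho"``), so Parseval's identity holds without extra
factors and the adjoint of :func:`ifft2c` is :func:`fft2c`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def fft2c(x: np.ndarray) -> np.ndarray:
    """Unitary 2-D FFT with DC at the array center."""
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(x), norm="ortho"))


def ifft2c(x: np.ndarray) -> np.ndarray:
    """Unitary 2-D inverse FFT, input and output DC-centered."""
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(x), norm="ortho"))


@dataclass
class ComplexField:
    """A 2-D complex array tagged with the plane it lives in.

    Parameters
    ----------
    values
        Square 2-D complex array.
    plane
        One of ``"object-spatial"``, ``"object-spectrum"``, ``"pupil"``.
        Spectrum and pupil fields are DC-centered.
    pitch_um
        Pixel pitch in micrometres where applicable (spatial planes).
    """

    values: np.ndarray
    plane: str = "object-spatial"
    pitch_um: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("ComplexField requires a square 2-D array")
        if self.plane not in ("object-spatial", "object-spectrum", "pupil"):
            raise ValueError(f"unknown plane {self.plane!r}")

    @property
    def size(self) -> int:
        return self.values.shape[0]

    def to_spectrum(self) -> "ComplexField":
        if self.plane != "object-spatial":
            raise ValueError("to_spectrum expects an object-spatial field")
        return ComplexField(fft2c(self.values), plane="object-spectrum")

    def to_spatial(self) -> "ComplexField":
        if self.plane != "object-spectrum":
            raise ValueError("to_spatial expects an object-spectrum field")
        return ComplexField(ifft2c(self.values), plane="object-spatial",
                            pitch_um=self.pitch_um)


def crop_window(spectrum: np.ndarray, shift: tuple[int, int],
                out_size: int) -> tuple[slice, slice]:
    """Slices of the ``out_size`` window centered at DC + ``shift``.

    ``spectrum`` is a DC-centered high-resolution spectrum; the window
    realizes the sub-aperture O(k + k_n) of the forward model.  Raises if
    the window would leave the grid (no wrap-around is permitted).
    """
    n = spectrum.shape[0]
    c = n // 2
    half = out_size // 2
    r0 = c + int(shift[0]) - half
    c0 = c + int(shift[1]) - half
    if r0 < 0 or c0 < 0 or r0 + out_size > n or c0 + out_size > n:
        raise ValueError(
            f"shift {shift} moves the {out_size}x{out_size} crop window off the "
            f"{n}x{n} grid")
    return slice(r0, r0 + out_size), slice(c0, c0 + out_size)
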