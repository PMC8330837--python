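"""Zernike polynomial basis on the pupil disc.

The pupil phase of the objective is modelled as a weighted sum of Zernike
polynomials, ``∠C(k) = Σ_l c_l · Z_l(k)``, which collapses the number of
free aberration parameters from one per pupil pixel to the handful of modes
that describe common microscope aberrations (tilt, defocus, astigmatism,
coma, ...).

Conventions
-----------
* OSA/ANSI single-index ordering: ``j = (n(n+2) + m) / 2`` with radial
  order ``n`` and azimuthal frequency ``m``; ``j = 0`` is piston, ``j = 4``
  is defocus Z2^0.
* Radial polynomials are *unnormalized* (peak value 1 at the disc edge for
  rotationally symmetric modes): defocus is ``2ρ² − 1``, not ``√3(2ρ² − 1)``.
  With this convention 50 µm of defocus behind a 0.1 NA objective at 532 nm
  corresponds to a defocus coefficient near −1.48 rad.
* ρ is the radial spatial frequency normalized by the objective cutoff
  NA/λ, so the basis lives exactly on the support of the coherent transfer
  function.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from pathlib import Path

import json
import numpy as np
from scipy.integrate import quad

from .optics import SystemConfig

__all__ = [
    "ZernikeBasis", "CoeffVector", "osa_to_nm", "nm_to_osa", "zernike_eval",
    "zernike_basis", "basis_from_config", "pupil_phase", "defocus_to_z20",
    "decompose_pupil",
]

#: OSA single index of the defocus mode Z2^0.
DEFOCUS_INDEX = 4


def osa_to_nm(j: int) -> tuple[int, int]:
    """Radial order n and azimuthal frequency m of OSA/ANSI index ``j``."""
    if j < 0:
        raise ValueError("OSA index must be non-negative")
    n = int(np.ceil((-3 + np.sqrt(9 + 8 * j)) / 2))
    m = 2 * j - n * (n + 2)
    return n, m


def nm_to_osa(n: int, m: int) -> int:
    if (n - abs(m)) % 2 or abs(m) > n:
        raise ValueError(f"invalid Zernike orders (n={n}, m={m})")
    return (n * (n + 2) + m) // 2


def _radial(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    """Unnormalized radial polynomial R_n^|m|(ρ)."""
    m = abs(m)
    out = np.zeros_like(rho, dtype=float)
    for k in range((n - m) // 2 + 1):
        coef = ((-1) ** k * comb(n - k, k)
                * comb(n - 2 * k, (n - m) // 2 - k))
        out += coef * rho ** (n - 2 * k)
    return out


def zernike_eval(j: int, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Evaluate the j'th (OSA) unnormalized Zernike polynomial at (ρ, θ)."""
    n, m = osa_to_nm(j)
    r = _radial(n, m, np.asarray(rho, dtype=float))
    if m > 0:
        return r * np.cos(m * np.asarray(theta))
    if m < 0:
        return r * np.sin(-m * np.asarray(theta))
    return r


@dataclass
class ZernikeBasis:
    """First L Zernike modes sampled on the pupil pixel grid.

    ``modes`` has shape (L, size, size); every mode is identically zero
    outside the unit pupil disc (``mask``).
    """

    modes: np.ndarray
    index_scheme: list[tuple[int, int]]
    mask: np.ndarray
    normalization: str = "unit-peak"

    def __post_init__(self) -> None:
        self.modes = np.asarray(self.modes, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.modes.shape[0] != len(self.index_scheme):
            raise ValueError("index_scheme length mismatch")

    @property
    def n_modes(self) -> int:
        return self.modes.shape[0]

    @property
    def size(self) -> int:
        return self.modes.shape[1]


@dataclass
class CoeffVector:
    """Real Zernike coefficients in radians, index scheme matching a basis."""

    values: np.ndarray
    index_scheme: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != len(self.index_scheme):
            raise ValueError("coefficient/index length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("coefficients must be finite")

    def __len__(self) -> int:
        return len(self.values)

    def to_csv(self, path: str | Path) -> None:
        lines = ["index,n,m,value_rad"]
        for j, ((n, m), v) in enumerate(zip(self.index_scheme, self.values)):
            lines.append(f"{j},{n},{m},{float(v)!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CoeffVector":
        rows = Path(path).read_text().strip().splitlines()[1:]
        scheme, vals = [], []
        for row in rows:
            _, n, m, v = row.split(",")
            scheme.append((int(n), int(m)))
            vals.append(float(v))
        return cls(np.array(vals), scheme)

    def to_json(self, path: str | Path) -> None:
        payload = [{"index": j, "n": n, "m": m, "value_rad": float(v)}
                   for j, ((n, m), v) in enumerate(zip(self.index_scheme, self.values))]
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def zeros_like(cls, basis: ZernikeBasis) -> "CoeffVector":
        return cls(np.zeros(basis.n_modes), list(basis.index_scheme))


def zernike_basis(L: int, size: int, cutoff_px: float) -> ZernikeBasis:
    """First ``L`` OSA-ordered modes on a ``size``×``size`` DC-centered grid.

    ``cutoff_px`` is the pupil radius in pixels; ρ is the pixel radius
    divided by it, and modes vanish for ρ ≥ 1 (matching the strict-inequality
    support of the binary CTF).
    """
    if L < 1:
        raise ValueError("need at least one mode")
    if cutoff_px < 4:
        raise ValueError("pupil radius must span at least 4 pixels")
    idx = np.arange(size) - size // 2
    y, x = np.meshgrid(idx, idx, indexing="ij")
    r = np.hypot(x, y) / cutoff_px
    theta = np.arctan2(y, x)
    mask = r < 1.0
    modes = np.stack([np.where(mask, zernike_eval(j, r, theta), 0.0)
                      for j in range(L)])
    scheme = [osa_to_nm(j) for j in range(L)]
    return ZernikeBasis(modes=modes, index_scheme=scheme, mask=mask)


def basis_from_config(cfg: SystemConfig, L: int) -> ZernikeBasis:
    """Basis on the low-resolution pupil grid implied by a system config."""
    return zernike_basis(L, cfg.lowres_size, cfg.cutoff_radius_px)


def pupil_phase(coeffs: CoeffVector, basis: ZernikeBasis) -> np.ndarray:
    """Pupil phase map Σ c_l Z_l, zero outside the disc (radians)."""
    if len(coeffs) != basis.n_modes:
        raise ValueError(
            f"coefficient vector has {len(coeffs)} entries, basis {basis.n_modes}")
    return np.tensordot(coeffs.values, basis.modes, axes=(0, 0))


def defocus_to_z20(defocus_um: float, na: float, wavelength_um: float) -> float:
    """Defocus coefficient (unnormalized Z2^0 = 2ρ²−1) for a defocus of
    ``defocus_um`` micrometres.

    The defocus pupil phase is φ(ρ) = (2π/λ)·z·(√(1 − NA²ρ²) − 1); its
    least-squares projection onto 2ρ²−1 over the unit disc is returned.  The
    small-NA closed form is −(2π/λ)·z·NA²/4.
    """
    if not 0 < na < 1:
        raise ValueError("na must lie in (0, 1)")
    if defocus_um == 0:
        return 0.0
    k0 = 2 * np.pi / wavelength_um

    def phi(rho: float) -> float:
        return k0 * defocus_um * (np.sqrt(1 - (na * rho) ** 2) - 1)

    num, _ = quad(lambda r: phi(r) * (2 * r * r - 1) * r, 0.0, 1.0)
    # ∫ (2ρ²−1)² ρ dρ over [0,1] = 1/6
    return float(num / (1.0 / 6.0))


def decompose_pupil(phase_map: np.ndarray, basis: ZernikeBasis) -> CoeffVector:
    """Least-squares Zernike decomposition of a pupil phase map.

    Solves the ridge-stabilized normal equations (ridge 1e−12 relative to
    the mean diagonal) restricted to pixels inside the pupil disc.
    """
    phase_map = np.asarray(phase_map, dtype=float)
    if phase_map.shape != basis.mask.shape:
        raise ValueError("phase map does not match the basis grid")
    g = basis.modes[:, basis.mask]          # (L, n_pix)
    rhs = g @ phase_map[basis.mask]
    gram = g @ g.T
    scale = np.mean(np.diag(gram))
    if scale == 0:
        raise np.linalg.LinAlgError("degenerate pupil grid: no disc pixels")
    coef = np.linalg.solve(gram + 1e-12 * scale * np.eye(len(gram)), rhs)
    return CoeffVector(coef, list(basis.index_scheme))
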