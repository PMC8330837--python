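"""Reconstruction quality metrics, aware of FP's intrinsic ambiguities.

A Fourier-ptychography reconstruction is only defined up to a global phase,
and carries no information beyond the synthetic NA.  Comparisons therefore
align the global phase first and, by default, low-pass the ground truth to
the synthetic-NA disc before measuring errors.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .fields import ComplexField, fft2c, ifft2c
from .optics import SystemConfig, synthetic_na
from .reconstruct import ReconResult
from .zernike import CoeffVector

__all__ = ["EvalReport", "align_global_phase", "band_limit_field", "evaluate",
           "save_montage"]


@dataclass
class EvalReport:
    """Errors of a reconstruction against ground truth.

    amp_rel_error   -- relative L2 error of the amplitudes.
    phase_rmse_rad  -- RMSE of the wrapped phase difference after global-
                       phase alignment, radians.
    coeff_abs_error -- per-mode |recovered − true| in radians (empty when
                       the engine has no coefficient representation).
    band_limited    -- whether the truth was low-passed to the synthetic NA.
    """

    amp_rel_error: float
    phase_rmse_rad: float
    coeff_abs_error: list[float]
    band_limited: bool

    def __post_init__(self) -> None:
        if self.amp_rel_error < 0 or self.phase_rmse_rad < 0:
            raise ValueError("errors must be non-negative")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def align_global_phase(recon: ComplexField | np.ndarray,
                       truth: ComplexField | np.ndarray) -> np.ndarray:
    """Remove the global-phase ambiguity of ``recon`` relative to ``truth``.

    Multiplies ``recon`` by the unit phasor that maximizes the real part of
    the inner product with ``truth`` (closed form: the conjugate phase of
    ⟨recon, truth⟩).  A vanishing inner product leaves ``recon`` unchanged.
    """
    r = recon.values if isinstance(recon, ComplexField) else np.asarray(recon)
    t = truth.values if isinstance(truth, ComplexField) else np.asarray(truth)
    if r.shape != t.shape:
        raise ValueError("shape mismatch between reconstruction and truth")
    inner = np.sum(r * np.conj(t))
    if np.abs(inner) == 0:
        return r.copy()
    return r * np.exp(-1j * np.angle(inner))


def band_limit_field(values: np.ndarray, cfg: SystemConfig) -> np.ndarray:
    """Low-pass a high-resolution field to the synthetic-NA disc."""
    n = values.shape[0]
    radius_px = synthetic_na(cfg) / cfg.wavelength_um / cfg.freq_step_um
    idx = np.arange(n) - n // 2
    y, x = np.meshgrid(idx, idx, indexing="ij")
    disk = (x * x + y * y) < radius_px ** 2
    return ifft2c(fft2c(values) * disk)


def _wrap(phase: np.ndarray) -> np.ndarray:
    """Map phase differences to the principal interval (−π, π]."""
    return np.angle(np.exp(1j * phase))


def evaluate(result: ReconResult, truth_obj: ComplexField,
             truth_coeffs: CoeffVector | None, cfg: SystemConfig,
             band_limit: bool = True) -> EvalReport:
    """Compare a reconstruction with its ground truth.

    With ``band_limit`` (default), the truth is low-passed to the synthetic
    NA first — information beyond it is physically unrecoverable, so the
    full-band comparison would penalize every engine equally for it.
    """
    rec = result.object.values
    tru = truth_obj.values
    if rec.shape != tru.shape:
        raise ValueError("reconstruction and truth have different shapes")
    if band_limit:
        tru = band_limit_field(tru, cfg)
    rec = align_global_phase(rec, tru)
    t_amp = np.abs(tru)
    amp_rel = float(np.linalg.norm(np.abs(rec) - t_amp) /
                    max(np.linalg.norm(t_amp), 1e-300))
    dphi = _wrap(np.angle(rec) - np.angle(tru))
    phase_rmse = float(np.sqrt(np.mean(dphi ** 2)))
    coeff_err: list[float] = []
    if truth_coeffs is not None and result.coeffs is not None:
        n_cmp = min(len(truth_coeffs), len(result.coeffs))
        rec_c = result.coeffs.values[:n_cmp]
        tru_c = truth_coeffs.values[:n_cmp]
        err = np.abs(rec_c - tru_c)
        err[0] = 0.0        # piston: global phase, already aligned away
        coeff_err = [float(e) for e in err]
    return EvalReport(amp_rel_error=amp_rel, phase_rmse_rad=phase_rmse,
                      coeff_abs_error=coeff_err, band_limited=band_limit)


def save_montage(result: ReconResult, truth_obj: ComplexField | None,
                 path: str | Path) -> None:
    """Side-by-side PNG of recovered amplitude, phase and pupil phase."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ncols = 3 + (2 if truth_obj is not None else 0)
    fig, axes = plt.subplots(1, ncols, figsize=(3 * ncols, 3))
    panels = [(np.abs(result.object.values), "recovered amplitude"),
              (np.angle(result.object.values), "recovered phase"),
              (np.angle(result.pupil_complex), "pupil phase (rad)")]
    if truth_obj is not None:
        panels += [(np.abs(truth_obj.values), "true amplitude"),
                   (np.angle(truth_obj.values), "true phase")]
    for ax, (img, title) in zip(axes, panels):
        im = ax.imshow(img, cmap="gray")
        ax.set_title(title, fontsize=8)
        ax.axis("off")
        fig.colorbar(im, ax=ax, fraction=0.046)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
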