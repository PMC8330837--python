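"""Classical iterative FP baseline: alternating projection with ePIE-style
pupil recovery.

Per iteration and per LED (center-outward order, matching the gradient
reconstructor), the sub-aperture is extracted, its spatial modulus replaced
by the square root of the captured image, and the standard conjugate-
weighted ePIE update pair is applied:

    O_patch += α · conj(P) / max|P|²        · (φ_h − φ_l)
    P       += β · conj(O_patch) / max|O|²  · (φ_h − φ_l)

with the pupil re-masked to the NA disc after each update.  The recovered
pupil is free-form (no Zernike constraint); its phase can be decomposed
onto a Zernike basis afterwards for comparison.  The step-size formulas
follow the standard ePIE literature.
"""

from __future__ import annotations

import numpy as np

from .fields import ComplexField, crop_window, fft2c, ifft2c
from .optics import make_ctf
from .reconstruct import (ReconResult, ReconstructionDiverged, ap_update,
                          upsample_sqrt)
from .simulate import MeasurementStack

__all__ = ["epie_reconstruct"]


def epie_reconstruct(stack: MeasurementStack, iters: int = 50,
                     alpha_obj: float = 1.0, beta_pupil: float = 1.0,
                     initial_pupil: np.ndarray | None = None) -> ReconResult:
    """Alternating-projection FP reconstruction with ePIE pupil recovery.

    Parameters
    ----------
    stack
        Measurement stack (images + illumination + system config).
    iters
        Number of full sweeps over the LED sequence.
    alpha_obj, beta_pupil
        ePIE step sizes for the object patch and the pupil;
        ``beta_pupil = 0`` disables pupil recovery (plain AP).
    initial_pupil
        Optional complex pupil to start from (e.g. the known truth);
        defaults to the ideal binary CTF.

    Returns a :class:`ReconResult` whose ``pupil_complex`` is the free-form
    recovered pupil (``pupil``/``coeffs`` are ``None``) and whose
    ``loss_history`` holds the per-iteration mean spatial-modulus residual.
    """
    if iters < 1:
        raise ValueError("iters must be >= 1")
    if alpha_obj < 0 or beta_pupil < 0:
        raise ValueError("step sizes must be non-negative")
    cfg = stack.config
    factor = cfg.upsample_factor
    n_lo = cfg.lowres_size

    center = stack.illumination.center_index
    up = upsample_sqrt(stack.images[center], factor)
    obj_spectrum = fft2c(up.astype(complex))
    mask = make_ctf(cfg).values.real.astype(bool)
    pupil = (mask.astype(complex) if initial_pupil is None
             else np.asarray(initial_pupil, dtype=complex).copy())

    shifts = stack.illumination.pixel_shifts
    windows = [crop_window(obj_spectrum, tuple(sh), n_lo) for sh in shifts]
    s_all = factor * np.sqrt(stack.images)

    def residual() -> float:
        tot = 0.0
        for i in range(stack.n):
            rows, cols = windows[i]
            psi = ifft2c(obj_spectrum[rows, cols] * pupil)
            tot += float(np.sum(np.abs(s_all[i] - np.abs(psi))))
        return tot / stack.n

    initial_res = residual()
    history: list[dict] = []
    for it in range(1, iters + 1):
        for i in range(stack.n):
            rows, cols = windows[i]
            patch = obj_spectrum[rows, cols]
            phi_l = patch * pupil
            phi_h = ap_update(phi_l, s_all[i] ** 2)
            delta = phi_h - phi_l
            if alpha_obj > 0:
                denom_p = np.max(np.abs(pupil) ** 2)
                if denom_p > 0:
                    obj_spectrum[rows, cols] = (
                        patch + alpha_obj * np.conj(pupil) / denom_p * delta)
            if beta_pupil > 0:
                denom_o = np.max(np.abs(patch) ** 2)
                if denom_o > 0:
                    pupil = pupil + beta_pupil * np.conj(patch) / denom_o * delta
                    pupil[~mask] = 0.0
        res = residual()
        history.append({"iteration": it, "residual": res})
        if res > 1e3 * max(initial_res, 1e-300):
            raise ReconstructionDiverged(
                f"residual {res:.3e} exceeds 1000x the initial "
                f"{initial_res:.3e} at iteration {it}")

    obj_spatial = ComplexField(ifft2c(obj_spectrum), plane="object-spatial",
                               pitch_um=cfg.highres_pixel_um)
    return ReconResult(object=obj_spatial, pupil=None, pupil_complex=pupil,
                       coeffs=None, loss_history=history,
                       stage_log=[{"stage": 1, "active": ["object", "pupil"]}])
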