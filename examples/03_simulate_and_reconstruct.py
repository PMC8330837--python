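"""Full pipeline: simulate a defocus-aberrated dataset and recover both the
sample and the aberration with the gradient reconstructor.

Uses the reference bench: 225 images of 32x32 from a 128x128 complex
phantom, 50 um defocus (Z2^0 = -1.48 rad).  Runs in well under a minute on
one CPU core.
"""

import numpy as np

import fptycho as fp

cfg = fp.default_config()
basis = fp.basis_from_config(cfg, 10)
true_coeffs = fp.CoeffVector(np.zeros(10), list(basis.index_scheme))
true_coeffs.values[4] = fp.defocus_to_z20(50.0, cfg.na_obj, cfg.wavelength_um)

phantom = fp.make_phantom(cfg.highres_size, seed=1)
stack = fp.simulate_dataset(phantom, true_coeffs, cfg)
print(f"simulated {stack.n} images of "
      f"{cfg.lowres_size}x{cfg.lowres_size}, "
      f"injected Z2^0 = {true_coeffs.values[4]:+.3f} rad")

result = fp.reconstruct(stack, fp.ReconConfig(seed=0))
first, last = result.loss_history[0], result.loss_history[-1]
print(f"data loss: {first['data']:.2f} (epoch 1) -> "
      f"{last['data']:.2f} (epoch {len(result.loss_history)})")

rec = result.coeffs.values
print(f"recovered Z2^0 = {rec[4]:+.3f} rad "
      f"({100 * abs(rec[4] - true_coeffs.values[4]) / abs(true_coeffs.values[4]):.1f}% error)")
print(f"largest spurious coefficient: "
      f"{np.abs(np.delete(rec, [0, 4])).max():.3f} rad")

report = fp.evaluate(result, stack.ground_truth.object, true_coeffs, cfg)
print(f"band-limited amplitude error: {report.amp_rel_error:.3f}")
print(f"phase RMSE: {report.phase_rmse_rad:.3f} rad")
# The alternate-updating schedule recovers the defocus coefficient to a
# few percent while the other eight trainable modes stay near zero, and
# the complex sample is recovered up to the synthetic-NA band limit.
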