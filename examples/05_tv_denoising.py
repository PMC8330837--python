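"""Total-variation regularization on a noisy acquisition.

Adds Gaussian noise at 2% of the peak intensity (a harsh regime: dark-field
images are then noise-dominated) and compares reconstructions with and
without the TV terms.  Takes a minute or two on one CPU core.
"""

import numpy as np

import fptycho as fp

cfg = fp.default_config()
basis = fp.basis_from_config(cfg, 10)
true_coeffs = fp.CoeffVector(np.zeros(10), list(basis.index_scheme))
true_coeffs.values[4] = -1.48

noise = fp.NoiseSpec(kind="gaussian", sigma=0.02, seed=11)
stack = fp.simulate_dataset(fp.make_phantom(cfg.highres_size, seed=11),
                            true_coeffs, cfg, noise=noise)

for label, (a1, a2) in (("no TV ", (0.0, 0.0)),
                        ("with TV", (None, None))):   # None -> auto-balanced
    result = fp.reconstruct(stack, fp.ReconConfig(seed=0, alpha1=a1,
                                                  alpha2=a2))
    report = fp.evaluate(result, stack.ground_truth.object, true_coeffs, cfg)
    print(f"{label}: amplitude error {report.amp_rel_error:.3f}, "
          f"phase RMSE {report.phase_rmse_rad:.3f} rad")
# The TV terms smooth both channels of the reconstructed sample: the
# amplitude error drops by roughly ten percent relative while the phase
# error stays comparable. Heavier weights trade residual noise against
# resolution; the auto-balanced defaults are a moderate choice.
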