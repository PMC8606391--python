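"""Audit identifiability of the wall parameters by closed-loop recovery.

Generates synthetic volume tables from known materials, refits, and
reports relative bias and RMSE per parameter.  Noiseless data recovers
the truth essentially exactly; realistic noise exposes a sloppy
inter-layer direction (see docs/methods.md).
"""

from sleevesim import DEFAULT_STACK, recovery_report

for noise_cv in (0.0, 0.05):
    report = recovery_report(
        DEFAULT_STACK, noise_sd=noise_cv, n_replicates=2, seed=11,
        sizes=(27, 36, 46, 54), flare=1.3, n_starts=2,
    )
    print(f"noise CV = {noise_cv:.2f}")
    print(report.round(4).to_string(index=False))
    print()
print("rel_bias/rel_rmse are relative to the generating truth; layer-"
      "stiffness separation degrades quickly once noise is present.")
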