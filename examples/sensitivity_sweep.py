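"""Robustness of the per-amino-acid sign pattern to parameter choices.

Recomputes the E. coli sign of the eps_M vs R_c relationship while scaling
the background drop-off rate over two orders of magnitude and perturbing
both wobble penalties, and reports the fraction of amino acids whose sign
is unchanged relative to the default parameterization.
"""

import trnaerr as te

pool = te.ecoli_k12_pool()
params = te.default_params()

res = te.sensitivity_sweep(
    pool,
    params,
    d_factors=(0.1, 1.0, 10.0),
    wobble_tables=((0.64, 0.60), (0.74, 0.70), (0.54, 0.50)),
)
print(res.to_string(index=False, float_format=lambda x: f"{x:.3g}"))
print("\nfraction_sign_stable = 1.0 everywhere means the qualitative "
      "conclusions do not hinge on the drop-off or wobble constants.")
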