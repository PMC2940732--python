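"""Focal/neighbor tRNA abundance correlation on a synthetic genome panel.

Generates a 60-genome panel with a latent neighbor correlation of 0.4,
computes per-genome (t_F, t_N) records and per-degeneracy-class
correlations, and runs the panel-level Wilcoxon and sign tests. Positive
median rho_t with a small sign-test p-value means tRNAs with abundant
one-step non-synonymous neighbors tend to be abundant themselves.
"""

import trnaerr as te
from trnaerr.correlation import correlate_by_class, focal_neighbor_table, panel_tests

pools = te.synth_panel(te.SynthConfig(n_genomes=60, rho_target=0.4, seed=42))
records = focal_neighbor_table(pools)
corr = correlate_by_class(records)
tests = panel_tests(corr)

print(f"{len(records)} focal/neighbor records across {len(pools)} genomes\n")
print(tests.to_string(index=False, float_format=lambda x: f"{x:.3g}"))
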