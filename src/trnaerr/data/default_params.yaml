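# Default model parameterization. Probabilities are per-tRNA-entry
# acceptance probabilities on the ensemble-kinetics scale (P_p defaults to
# P_n when omitted); wobble penalties are multipliers on P_c; the drop-off
# rate reproduces a 4e-4 per-codon nonsense frequency at the 10 codons/s
# bulk elongation target.
probabilities:
  P_c: 0.99
  P_n: 0.0045
wobble:
  noncanonical_pupy: 0.64   # G.U, U.G, A.C: reduce acceptance by 36%
  pupu_pypy: 0.60           # purine-purine / pyrimidine-pyrimidine: by 40%
  c34_pseudo: true          # C.U / C.A wobble reads -> pseudo-cognate
  ac_is_cognate: true
  internal_pseudo: true     # same-aa mismatch at codon pos 1-2 -> pseudo-cognate
model:
  target_mean_rate: 10.0    # codons/s, harmonic mean over the 61 sense codons
  dropoff_d: 4.0016e-3      # 1/s
  harmonic_mean_on: R_c
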