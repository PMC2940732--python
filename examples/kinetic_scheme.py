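"""Per-entry elongation probabilities from a tRNA selection scheme.

Builds a three-step selection pathway (codon recognition, GTPase
activation, accommodation with proofreading rejection) for cognate-like
and near-cognate-like rate constants and solves the absorption probability
of peptidyl transfer. The near-cognate complex is lost almost every entry
because its codon-recognition complex dissociates ~350x faster and its
GTPase activation is ~650x slower -- kinetic proofreading in action.
"""

from trnaerr import KineticScheme, KineticStep, elongation_success_probability

cognate = KineticScheme((
    KineticStep(forward=190, backward=25),     # codon recognition vs dissociation
    KineticStep(forward=260, backward=0.23),   # GTPase activation, near-irreversible
    KineticStep(forward=200, reject=0.6),      # accommodation vs proofreading loss
))
near = KineticScheme((
    KineticStep(forward=190, backward=25),
    KineticStep(forward=0.4, backward=80),     # recognition complex falls apart
    KineticStep(forward=60, reject=200),       # mostly rejected at proofreading
))

p_c = elongation_success_probability(cognate)
p_n = elongation_success_probability(near)
print(f"P(elongation | cognate entry)      = {p_c:.4f}")
print(f"P(elongation | near-cognate entry) = {p_n:.3e}")
print(f"discrimination ratio               = {p_c / p_n:.0f}x")
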