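"""Codon-anticodon pairing classification and wobble penalties.

Pairing geometry: codon position k (1-based, 5'->3') pairs anticodon
position 4-k, so the codon's third (wobble) position pairs the anticodon's
first written base (position 34). A pair with zero Watson-Crick mismatches
is a perfect cognate. A single mismatch splits by position and by whether
the tRNA carries the codon's amino acid:

* wobble-position mismatch, same amino acid: an accepted wobble read. A
  purine-purine or pyrimidine-pyrimidine wobble cuts the cognate acceptance
  probability by 40% (multiplier 0.60); the non-canonical purine-pyrimidine
  wobbles G.U, U.G and A.C cut it by 36% (multiplier 0.64). Anticodon-C34
  wobbles (C.U, C.A) are stereochemically non-standard reads: the tRNA still
  delivers the right amino acid but is accepted only at the near-cognate
  probability -- a "pseudo-cognate".
* wobble-position mismatch, different amino acid: near-cognate (its
  acceptance causes a missense error).
* mismatch at codon position 1 or 2: near-cognate if the amino acids
  differ, pseudo-cognate if they coincide (configurable).
* two or more mismatches: non-cognate; such tRNAs are rejected so fast that
  they do not measurably compete.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

from . import genetic_code as gc

__all__ = [
    "PairClass",
    "WobbleRules",
    "PairingResult",
    "classify_pair",
    "enumerate_classes",
    "TRNAPartition",
]

_PURINES = frozenset("AG")
_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}


class PairClass(enum.Enum):
    COGNATE_WC = "cognate_wc"
    COGNATE_WOBBLE = "cognate_wobble"
    PSEUDO_COGNATE = "pseudo_cognate"
    NEAR_COGNATE = "near_cognate"
    NON_COGNATE = "non_cognate"

    @property
    def is_cognate(self) -> bool:
        return self in (PairClass.COGNATE_WC, PairClass.COGNATE_WOBBLE)


@dataclass(frozen=True)
class WobbleRules:
    """Tunable wobble rule table.

    Penalties are stored as multipliers on the cognate acceptance
    probability: ``noncanonical_pupy`` covers G.U / U.G (and A.C when
    ``ac_is_cognate``); ``pupu_pypy`` covers same-chemistry wobbles
    (A.A, A.G, G.A, G.G, U.U, U.C, C.C).
    """

    noncanonical_pupy: float = 0.64   # "reduce by 36%"
    pupu_pypy: float = 0.60           # "reduce by 40%"
    c34_pseudo: bool = True           # C.U / C.A wobble -> pseudo-cognate
    ac_is_cognate: bool = True        # anticodon A34 . codon C treated like G.U
    internal_pseudo: bool = True      # same-aa mismatch at codon pos 1-2 -> pseudo
    identity_overrides: Mapping[str, str] | None = field(default=None, hash=False)

    def wobble_penalty(self, a34: str, c3: str) -> float:
        """Penalty multiplier for a same-amino-acid wobble-position pair."""
        if (a34, c3) in _WC:
            return 1.0
        if {a34, c3} == {"G", "U"}:
            return self.noncanonical_pupy
        if (a34, c3) == ("A", "C"):
            return self.noncanonical_pupy if self.ac_is_cognate else self.pupu_pypy
        return self.pupu_pypy


@dataclass(frozen=True)
class PairingResult:
    pair_class: PairClass
    wobble_penalty: float | None = None  # defined for cognate classes only


def _mismatch_positions(cdn: str, ac: str) -> list[int]:
    # codon index k pairs anticodon index 2-k
    return [k for k in range(3) if (ac[2 - k], cdn[k]) not in _WC]


def classify_pair(cdn: str, ac: str, rules: WobbleRules | None = None) -> PairingResult:
    """Classify one (codon, anticodon) pair under a wobble rule table."""
    rules = rules or WobbleRules()
    cdn = gc.codon(cdn)
    ac = gc.anticodon(ac)
    codon_aa = gc.translate(cdn)
    if codon_aa == gc.STOP:
        raise ValueError(f"{cdn} is a stop codon; pairing classes are defined for sense codons")
    mm = _mismatch_positions(cdn, ac)
    if len(mm) == 0:
        return PairingResult(PairClass.COGNATE_WC, 1.0)
    if len(mm) >= 2:
        return PairingResult(PairClass.NON_COGNATE)

    trna_aa = gc.amino_acid_of_anticodon(ac, rules.identity_overrides)
    same_aa = trna_aa == codon_aa
    if mm[0] == 2:  # wobble position: codon 3 vs anticodon 34
        a34, c3 = ac[0], cdn[2]
        if not same_aa:
            return PairingResult(PairClass.NEAR_COGNATE)
        if rules.c34_pseudo and a34 == "C":  # C.U / C.A non-standard reads
            return PairingResult(PairClass.PSEUDO_COGNATE)
        return PairingResult(PairClass.COGNATE_WOBBLE, rules.wobble_penalty(a34, c3))
    # mismatch in the codon's first or second position
    if same_aa and rules.internal_pseudo:
        return PairingResult(PairClass.PSEUDO_COGNATE)
    if same_aa:
        return PairingResult(PairClass.NON_COGNATE)
    return PairingResult(PairClass.NEAR_COGNATE)


@dataclass
class TRNAPartition:
    """A pool's tRNA species partitioned relative to one codon.

    ``cognate`` carries (anticodon, gcn, w) triples; ``pseudo`` and ``near``
    carry (anticodon, gcn) pairs. Non-cognate species are discarded.
    """

    codon: str
    cognate: list[tuple[str, float, float]]
    pseudo: list[tuple[str, float]]
    near: list[tuple[str, float]]


def enumerate_classes(pool, cdn: str, rules: WobbleRules | None = None) -> TRNAPartition:
    """Partition a tRNA pool's species into cognate / pseudo-cognate /
    near-cognate sets for one sense codon."""
    rules = rules or WobbleRules()
    cdn = gc.codon(cdn)
    part = TRNAPartition(cdn, [], [], [])
    for sp in pool.species.values():
        res = classify_pair(cdn, sp.anticodon, rules)
        if res.pair_class.is_cognate:
            part.cognate.append((sp.anticodon, sp.gcn, res.wobble_penalty))
        elif res.pair_class is PairClass.PSEUDO_COGNATE:
            part.pseudo.append((sp.anticodon, sp.gcn))
        elif res.pair_class is PairClass.NEAR_COGNATE:
            part.near.append((sp.anticodon, sp.gcn))
    return part
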